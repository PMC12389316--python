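"""Expression matrices and 2^-ddCT relative expression with t-tests.

TPM matrices are log2(x + offset)-transformed for heatmap display (offset 1
so zero TPM maps to 0). Relative expression from qPCR cycle thresholds uses
the 2^-ddCT method: per biological replicate, dCT = CT(target) -
CT(reference); ddCT = dCT(treated) - mean dCT(control); rq = 2^-ddCT.
Technical replicates are averaged into their biological replicate before
any statistics; significance is a two-sided Welch t-test on the dCT values
at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05


@dataclass
class ExpressionMatrix:
    """Genes x samples TPM matrix with an at-most-once log2 transform."""

    values: pd.DataFrame  # index: genes, columns: samples
    transformed: bool = False
    sample_metadata: pd.DataFrame | None = None

    def __post_init__(self):
        if (self.values.values < 0).any() and not self.transformed:
            raise ValueError("TPM values must be >= 0")


def log2_matrix(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Entry-wise log2(x + offset); rejects a second transform."""
    if m.transformed:
        raise ValueError("matrix is already log2-transformed")
    return ExpressionMatrix(values=np.log2(m.values + offset),
                            transformed=True,
                            sample_metadata=m.sample_metadata)


@dataclass(frozen=True)
class RelativeExpressionResult:
    gene: str
    condition: str
    mean_rq: float
    rq_values: tuple[float, ...]  # per treated biological replicate
    p_value: float | None
    significant: bool


def _delta_cts(measurements: pd.DataFrame, condition: str, target: str,
               reference: str) -> pd.Series:
    """Per-biological-replicate dCT, technical replicates averaged first."""
    sub = measurements[measurements["condition"] == condition]
    samples = sorted(sub["sample"].unique())
    dcts = {}
    for sample in samples:
        ss = sub[sub["sample"] == sample]
        ref = ss.loc[ss["gene"] == reference, "ct"]
        tgt = ss.loc[ss["gene"] == target, "ct"]
        if ref.empty:
            raise ValueError(f"reference gene missing in sample {sample!r}")
        if tgt.empty:
            continue
        dcts[sample] = float(tgt.mean() - ref.mean())
    return pd.Series(dcts)


def delta_delta_ct(
    measurements: pd.DataFrame,
    target: str,
    reference: str,
    control_condition: str = "control",
    treated_condition: str = "treated",
) -> RelativeExpressionResult:
    """2^-ddCT relative expression of ``target`` normalized to ``reference``.

    ``measurements`` columns: sample, condition, gene, replicate, ct.
    By construction the control group's mean rq is 1.
    """
    for col in ("sample", "condition", "gene", "replicate", "ct"):
        if col not in measurements.columns:
            raise ValueError(f"measurements lack column {col!r}")
    control = _delta_cts(measurements, control_condition, target, reference)
    treated = _delta_cts(measurements, treated_condition, target, reference)
    if control.empty or treated.empty:
        raise ValueError("need at least one replicate per condition")
    ddct = treated - control.mean()
    rq = np.power(2.0, -ddct)
    p = None
    if len(control) >= 2 and len(treated) >= 2:
        p = significance_test(control.to_numpy(), treated.to_numpy())
    return RelativeExpressionResult(
        gene=target,
        condition=treated_condition,
        mean_rq=float(rq.mean()),
        rq_values=tuple(float(x) for x in rq),
        p_value=p,
        significant=(p is not None and p < ALPHA),
    )


def significance_test(control_dcts: np.ndarray,
                      treated_dcts: np.ndarray) -> float:
    """Two-sided Welch t-test on dCT values; p in (0, 1].

    Degenerate inputs: identical constant groups give p = 1 (t = 0); two
    zero-variance groups with different means give an arbitrarily small p
    (reported as the smallest positive float).
    """
    control = np.asarray(control_dcts, dtype=float)
    treated = np.asarray(treated_dcts, dtype=float)
    if len(control) < 2 or len(treated) < 2:
        raise ValueError("need at least 2 values per group")
    if np.var(control) == 0 and np.var(treated) == 0:
        if control.mean() == treated.mean():
            return 1.0
        return float(np.finfo(float).tiny)
    p = float(stats.ttest_ind(control, treated, equal_var=False).pvalue)
    return min(max(p, float(np.finfo(float).tiny)), 1.0)


def relative_expression_table(
    measurements: pd.DataFrame,
    targets: list[str],
    reference: str,
    control_condition: str = "control",
    treated_condition: str = "treated",
) -> pd.DataFrame:
    """delta_delta_ct over several targets as a tidy results table."""
    rows = []
    for gene in targets:
        r = delta_delta_ct(measurements, gene, reference,
                           control_condition, treated_condition)
        rows.append({"gene": r.gene, "condition": r.condition,
                     "mean_rq": r.mean_rq, "p_value": r.p_value,
                     "significant": r.significant})
    return pd.DataFrame(rows)
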