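"""Family-specific profile HMMs from information-scored alignment blocks.

The mining strategy: score each MSA column by its information content
against a background residue distribution (and, when subgroup labels are
given, by residue/label mutual information), extract high-scoring
low-gap blocks, build one profile HMM per block, validate the model set on
known positive sequences to record per-model acceptance cutoffs, then
prospect new proteomes at a reduced cutoff (rc): a protein passes when some
model scores it at >= rc x that model's minimum training-positive bit score.

The rc semantics (fraction of the minimum positive training score) is this
package's explicit definition of "reduced cutoff" prospecting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._codons import PROTEIN_ALPHABET
from .align import Msa
from .hmm import ProfileHMM, read_hmmer3, viterbi_score, write_hmmer3

_AIDX = {ch: i for i, ch in enumerate(PROTEIN_ALPHABET)}

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_MIN_BLOCK_LEN = 20
DEFAULT_MAX_GAP_FRACTION = 0.3
DEFAULT_MIN_MEAN_SCORE = 1.0
DEFAULT_COLUMN_FLOOR = 0.5


@dataclass(frozen=True)
class ColumnScore:
    """Information content of one alignment column.

    ``information`` is the KL divergence (bits) of the gap-excluded,
    pseudocount-smoothed residue frequencies from the background;
    ``discrimination`` (present when group labels were supplied) is the
    mutual information (bits) between residue and group label.
    """

    column_index: int
    information: float
    gap_fraction: float
    discrimination: float | None = None


@dataclass(frozen=True)
class AlignmentBlock:
    """A run of consecutive high-scoring columns (0-based half-open)."""

    start: int
    end: int
    mode: str  # conserved | discriminative
    mean_score: float


@dataclass
class FamilyModelSet:
    """Block HMMs plus the validation cutoffs needed for rc prospecting."""

    models: list[ProfileHMM]
    training_positive_ids: list[str] = field(default_factory=list)
    per_model_min_positive_bits: dict[str, float] = field(default_factory=dict)

    @property
    def validated(self) -> bool:
        return bool(self.per_model_min_positive_bits)


@dataclass(frozen=True)
class CandidateHit:
    """A prospected protein with its best model and pass/fail flag."""

    protein_id: str
    species: str
    best_model: str
    bit_score: float
    passes: bool


def score_columns(
    msa: Msa,
    background: np.ndarray | None = None,
    labels: dict[str, str] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[ColumnScore]:
    """Position-specific information (and optional discrimination) scores."""
    if not msa.rows:
        raise ValueError("empty MSA")
    if background is None:
        background = np.full(20, 1.0 / 20.0)
    groups: list[str] | None = None
    if labels is not None:
        missing = [rid for rid in msa.ids if rid not in labels]
        if missing:
            raise ValueError(f"labels missing for rows: {missing}")
        groups = [labels[rid] for rid in msa.ids]
        if len(set(groups)) < 2:
            raise ValueError("labels must define at least two groups")
    scores = []
    for j in range(msa.column_count):
        col = msa.column(j)
        residues = [(g, ch) for g, ch in zip(groups or [""] * len(col), col)
                    if ch != "-"]
        gap_fraction = 1.0 - len(residues) / len(col)
        if not residues:
            scores.append(ColumnScore(j, 0.0, 1.0,
                                      0.0 if labels is not None else None))
            continue
        counts = np.zeros(20)
        for _, ch in residues:
            counts[_AIDX[ch]] += 1
        freq = (counts + pseudocount) / (counts.sum() + 20 * pseudocount)
        nz = freq > 0
        information = float(np.sum(freq[nz] * np.log2(freq[nz] / background[nz])))
        discrimination = None
        if labels is not None:
            discrimination = _mutual_information(residues, pseudocount)
        scores.append(ColumnScore(j, information, gap_fraction, discrimination))
    return scores


def _mutual_information(residues: list[tuple[str, str]],
                        pseudocount: float) -> float:
    gs = sorted({g for g, _ in residues})
    joint = np.zeros((len(gs), 20))
    gidx = {g: i for i, g in enumerate(gs)}
    for g, ch in residues:
        joint[gidx[g], _AIDX[ch]] += 1
    joint = joint + pseudocount
    joint /= joint.sum()
    pg = joint.sum(axis=1, keepdims=True)
    px = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (pg @ px)[nz])))


def extract_blocks(
    scores: list[ColumnScore],
    min_block_len: int = DEFAULT_MIN_BLOCK_LEN,
    min_mean_score: float = DEFAULT_MIN_MEAN_SCORE,
    max_gap_fraction: float = DEFAULT_MAX_GAP_FRACTION,
    column_floor: float = DEFAULT_COLUMN_FLOOR,
    mode: str = "conserved",
) -> list[AlignmentBlock]:
    """Maximal runs of informative, low-gap columns, filtered by length/mean."""
    if min_block_len <= 0 or min_mean_score <= 0:
        raise ValueError("block parameters must be positive")

    def value(s: ColumnScore) -> float:
        if mode == "discriminative":
            if s.discrimination is None:
                raise ValueError("discriminative mode needs labeled scores")
            return s.discrimination
        return s.information

    blocks = []
    run: list[ColumnScore] = []
    for s in scores + [None]:  # sentinel flushes the final run
        ok = s is not None and value(s) >= column_floor \
            and s.gap_fraction <= max_gap_fraction
        if ok:
            run.append(s)
            continue
        if run:
            mean = float(np.mean([value(r) for r in run]))
            if len(run) >= min_block_len and mean >= min_mean_score:
                blocks.append(AlignmentBlock(run[0].column_index,
                                             run[-1].column_index + 1,
                                             mode, mean))
            run = []
    return sorted(blocks, key=lambda b: b.start)


def build_block_hmm(
    msa: Msa,
    block: AlignmentBlock,
    pseudocount_weight: float = DEFAULT_PSEUDOCOUNT,
    name: str | None = None,
    background: np.ndarray | None = None,
    min_occupancy: float = 0.5,
) -> ProfileHMM:
    """Profile HMM over a block: one match state per >=50%-occupied column.

    Emissions are pseudocount-smoothed column frequencies; transitions are
    estimated from the observed gap structure with Laplace smoothing.
    """
    if not (0 <= block.start < block.end <= msa.column_count):
        raise ValueError("block outside MSA bounds")
    if background is None:
        background = np.full(20, 1.0 / 20.0)
    nrow = len(msa.rows)
    cols = list(range(block.start, block.end))
    match_cols = [j for j in cols
                  if sum(1 for ch in msa.column(j) if ch != "-") / nrow
                  >= min_occupancy]
    if not match_cols:
        raise ValueError("no block column reaches the occupancy threshold")
    L = len(match_cols)
    a = pseudocount_weight
    match_em = np.zeros((L, 20))
    for k, j in enumerate(match_cols):
        counts = np.zeros(20)
        for ch in msa.column(j):
            if ch != "-":
                counts[_AIDX[ch]] += 1
        match_em[k] = (counts + a) / (counts.sum() + 20 * a)
    insert_em = np.tile(background, (L + 1, 1))

    # transition counts per node from observed paths through the block
    tcounts = np.zeros((L + 1, 7))  # mm mi md im ii dm dd
    col_kind = {}
    for j in cols:
        col_kind[j] = "M" if j in set(match_cols) else "I"
    node_of = {j: k + 1 for k, j in enumerate(match_cols)}
    for _, seq in msa.rows:
        node = 0
        state = "M"  # begin state behaves like a match source
        for j in cols:
            ch = seq[j]
            if col_kind[j] == "M":
                new_state = "M" if ch != "-" else "D"
                key = {"MM": 0, "MD": 2, "IM": 3, "DM": 5, "DD": 6}.get(
                    state + new_state)
                if key is None:  # I -> D and D -> I are not representable;
                    key = 3 if new_state == "M" else 6  # fold to nearest
                tcounts[node, key] += 1
                node = node_of[j]
                state = new_state
            elif ch != "-":
                key = {"M": 1, "I": 4, "D": 1}[state]  # D->I folded to M->I
                tcounts[node, key] += 1
                state = "I"
    transitions = np.zeros((L + 1, 7))
    for k in range(L + 1):
        m = tcounts[k, :3] + a
        i = tcounts[k, 3:5] + a
        d = tcounts[k, 5:] + a
        transitions[k, :3] = m / m.sum()
        transitions[k, 3:5] = i / i.sum()
        transitions[k, 5:] = d / d.sum()
    # final node: no onward M/D targets; route mass to m->m (exit)
    transitions[L, 2] = 0.0
    transitions[L, :3] /= transitions[L, :3].sum()
    return ProfileHMM(
        name=name or f"block_{block.start}_{block.end}",
        match_emissions=match_em,
        insert_emissions=insert_em,
        transitions=transitions,
        background=background,
    )


#: Minimum bit score for a local hit to count as a detection during model
#: validation: 20 bits = 10^6:1 odds over background, far above the few bits
#: a random protein can reach by chance yet far below any true positive.
MIN_HIT_BITS = 20.0


def validate_models(
    model_set: FamilyModelSet,
    positives: list[tuple[str, str]],
    full_dataset: list[tuple[str, str]],
    min_hit_bits: float = MIN_HIT_BITS,
) -> tuple[bool, dict[str, float]]:
    """Check that every known positive is detected; record per-model cutoffs.

    A model's cutoff is the minimum bit score it assigns to any positive it
    hits (score >= min_hit_bits). Models hitting no positive are dropped
    with a warning. Returns (all_positives_detected, cutoffs) and stores the
    cutoffs on the model set.
    """
    if not positives:
        raise ValueError("positives must be nonempty")
    dataset_ids = {pid for pid, _ in full_dataset}
    missing = [pid for pid, _ in positives if pid not in dataset_ids]
    if missing:
        raise ValueError(f"positives not in full dataset: {missing}")
    if not model_set.models:
        return False, {}
    cutoffs: dict[str, float] = {}
    detected: set[str] = set()
    kept = []
    for model in model_set.models:
        pos_scores = []
        for pid, seq in positives:
            hit = viterbi_score(model, seq, protein_id=pid)
            if hit is not None and hit.bit_score >= min_hit_bits:
                pos_scores.append(hit.bit_score)
                detected.add(pid)
        if not pos_scores:
            warnings.warn(f"model {model.name!r} hits no positive; dropped")
            continue
        cutoffs[model.name] = float(min(pos_scores))
        model.bit_cutoff = cutoffs[model.name]
        kept.append(model)
    model_set.models = kept
    model_set.per_model_min_positive_bits = cutoffs
    model_set.training_positive_ids = [pid for pid, _ in positives]
    ok = bool(cutoffs) and all(pid in detected for pid, _ in positives)
    return ok, cutoffs


def prospect(
    model_set: FamilyModelSet,
    proteomes: dict[str, list[tuple[str, str]]],
    rc: float,
    min_hit_bits: float = MIN_HIT_BITS,
) -> list[CandidateHit]:
    """Scan proteomes at reduced cutoffs.

    A protein passes iff some model scores it at >= max(rc x that model's
    cutoff, min_hit_bits) — the same noise floor that defines a "hit"
    during validation, so rc can never dilute a cutoff into the range
    random sequences reach. The scoring model is the one maximizing the
    margin (bit score - rc x cutoff), so the pass flag is always
    recomputable from the reported (bit_score, rc, cutoff) triple.
    """
    if not model_set.validated:
        raise ValueError("model set must be validated before prospecting")
    if not 0.0 < rc <= 1.0:
        raise ValueError("rc must lie in (0, 1]")
    cutoffs = model_set.per_model_min_positive_bits
    out = []
    for species in sorted(proteomes):
        for pid, seq in proteomes[species]:
            best: tuple[float, str, float] | None = None  # margin, model, bits
            for model in model_set.models:
                hit = viterbi_score(model, seq, protein_id=pid)
                if hit is None or hit.bit_score <= 0:
                    continue
                margin = hit.bit_score - rc * cutoffs[model.name]
                if best is None or margin > best[0]:
                    best = (margin, model.name, hit.bit_score)
            if best is not None:
                margin, model_name, bits = best
                out.append(CandidateHit(
                    pid, species, model_name, bits,
                    margin >= 0.0 and bits >= min_hit_bits))
    return out


def candidates_to_tsv(candidates: list[CandidateHit], rc: float,
                      path: str | Path) -> None:
    lines = ["species\tprotein\tmodel\tbits\trc\tpass"]
    for c in candidates:
        lines.append(f"{c.species}\t{c.protein_id}\t{c.best_model}"
                     f"\t{c.bit_score:.2f}\t{rc}\t{int(c.passes)}")
    Path(path).write_text("\n".join(lines) + "\n")


def save_model_set(model_set: FamilyModelSet, directory: str | Path) -> None:
    """Serialize models (HMMER3-subset text) plus a sidecar cutoff TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_hmmer3(model_set.models, directory / "models.hmm")
    rows = [{"model": m, "min_positive_bits": b}
            for m, b in sorted(model_set.per_model_min_positive_bits.items())]
    pd.DataFrame(rows, columns=["model", "min_positive_bits"]).to_csv(
        directory / "cutoffs.tsv", sep="\t", index=False)
    (directory / "training_positives.txt").write_text(
        "\n".join(model_set.training_positive_ids) + "\n")


def load_model_set(directory: str | Path) -> FamilyModelSet:
    directory = Path(directory)
    models = read_hmmer3(directory / "models.hmm")
    cut = pd.read_csv(directory / "cutoffs.tsv", sep="\t")
    cutoffs = dict(zip(cut["model"], cut["min_positive_bits"].astype(float)))
    for m in models:
        m.bit_cutoff = cutoffs.get(m.name)
    ids_file = directory / "training_positives.txt"
    ids = [ln for ln in ids_file.read_text().splitlines() if ln] \
        if ids_file.exists() else []
    return FamilyModelSet(models=models, training_positive_ids=ids,
                          per_model_min_positive_bits=cutoffs)
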