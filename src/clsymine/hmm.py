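"""Profile-HMM scoring of proteomes and two-domain architecture filtering.

A self-contained profile HMM (match/insert/delete states, Plan7-like node
transitions) scored in log2-odds bits against a background distribution with
Smith-Waterman-style local entry/exit: uniform entry into any match state,
free exit from any match state. Scores are Viterbi bits against raw cutoffs;
no E-value calibration is attempted, and parity with HMMER's forward-score
E-values is deliberately not claimed.

Internally protein coordinates are 0-based half-open; TSV reports are
1-based inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._codons import PROTEIN_ALPHABET

#: Bit-score thresholds used when scanning with the two Pfam-style domain
#: models: 60 bits for the SNF2-like model, 50 for the Helicase-C-like model.
DEFAULT_THRESHOLDS = {"SNF2": 60.0, "HELC": 50.0}

_AIDX = {ch: i for i, ch in enumerate(PROTEIN_ALPHABET)}
_LOG0 = -1e30

# transition column order, HMMER3 convention
TRANS_ORDER = ("mm", "mi", "md", "im", "ii", "dm", "dd")


@dataclass
class ProfileHMM:
    """A profile HMM over the 20-residue alphabet.

    ``match_emissions``: (L, 20) row-stochastic; ``insert_emissions``:
    (L + 1, 20), row k emitting from insert state I_k (I_0 precedes M_1);
    ``transitions``: (L + 1, 7) columns (m->m, m->i, m->d, i->m, i->i,
    d->m, d->d) leaving node k. ``bit_cutoff`` is an optional acceptance
    threshold recorded at validation time.
    """

    name: str
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(20, 1.0 / 20.0)
    )
    bit_cutoff: float | None = None

    def __post_init__(self):
        L = self.length
        if L < 1:
            raise ValueError("model needs at least one match state")
        if self.insert_emissions.shape != (L + 1, 20):
            raise ValueError("insert_emissions must be (L+1, 20)")
        if self.transitions.shape != (L + 1, 7):
            raise ValueError("transitions must be (L+1, 7)")
        for arr, what in ((self.match_emissions, "match emissions"),
                          (self.insert_emissions, "insert emissions"),
                          (self.background[None, :], "background")):
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{what} rows must sum to 1")

    @property
    def length(self) -> int:
        return self.match_emissions.shape[0]

    def consensus(self) -> str:
        """Most probable residue per match state."""
        return "".join(PROTEIN_ALPHABET[i]
                       for i in self.match_emissions.argmax(axis=1))


@dataclass(frozen=True)
class DomainHit:
    """Best-scoring local alignment of a protein under one model."""

    protein_id: str
    model_name: str
    bit_score: float
    start: int  # 0-based half-open envelope
    end: int


def _log2(x: np.ndarray) -> np.ndarray:
    out = np.full_like(x, _LOG0, dtype=float)
    nz = x > 0
    out[nz] = np.log2(x[nz])
    return out


def hmm_from_consensus(name: str, consensus: str, match_prob: float = 0.6,
                       background: np.ndarray | None = None) -> ProfileHMM:
    """A match-dominated profile from a single consensus sequence.

    Each match state emits its consensus residue with ``match_prob`` and
    spreads the rest uniformly; transitions strongly favor match->match.
    Stands in for a curated domain model when only a consensus is available.
    """
    if background is None:
        background = np.full(20, 1.0 / 20.0)
    L = len(consensus)
    if L < 1:
        raise ValueError("empty consensus")
    match = np.full((L, 20), (1.0 - match_prob) / 19.0)
    for k, ch in enumerate(consensus):
        match[k, _AIDX[ch]] = match_prob
    insert = np.tile(background, (L + 1, 1))
    trans = np.tile(
        np.array([0.95, 0.02, 0.03, 0.5, 0.5, 0.6, 0.4]), (L + 1, 1))
    trans[L] = [0.98, 0.02, 0.0, 0.5, 0.5, 1.0, 0.0]
    return ProfileHMM(name=name, match_emissions=match,
                      insert_emissions=insert, transitions=trans,
                      background=background)


def viterbi_score(hmm: ProfileHMM, protein: str,
                  protein_id: str = "query") -> DomainHit | None:
    """Best local hit of ``protein`` under ``hmm`` in log2-odds bits.

    Entry into match state k costs log2(1/L); exit from any match state is
    free. Residues outside the hit score zero under the background null.
    Returns None for an empty protein.
    """
    if not protein:
        return None
    try:
        obs = np.array([_AIDX[ch] for ch in protein])
    except KeyError as exc:
        raise ValueError(f"residue {exc} outside the model alphabet") from exc
    L = hmm.length
    lbg = _log2(hmm.background)
    lm = _log2(hmm.match_emissions) - lbg[None, :]   # (L, 20)
    li = _log2(hmm.insert_emissions) - lbg[None, :]  # (L+1, 20)
    t = _log2(hmm.transitions)                       # (L+1, 7)
    tmm, tmi, tmd, tim, tii, tdm, tdd = (t[:, i] for i in range(7))
    entry = math.log2(1.0 / L)

    n = len(protein)
    vm = np.full(L, _LOG0)
    vi = np.full(L + 1, _LOG0)
    vd = np.full(L, _LOG0)
    sm = np.zeros(L, dtype=int)
    si = np.zeros(L + 1, dtype=int)
    sd = np.zeros(L, dtype=int)
    best_score, best_end, best_start = _LOG0, 0, 0
    # delete-chain prefix: cumulative d->d cost up to node k
    cdd = np.concatenate([[0.0], np.cumsum(tdd[1:L])])  # index by match state

    for i in range(n):
        x = obs[i]
        emit = lm[:, x]
        # candidates for M_k at residue i (k vectorized)
        cand = np.full((4, L), _LOG0)
        cand[0] = entry
        cand[1, 1:] = vm[:-1] + tmm[1:L]
        cand[2, 1:] = vi[1:L] + tim[1:L]
        cand[3, 1:] = vd[:-1] + tdm[1:L]
        choice = cand.argmax(axis=0)
        new_vm = emit + cand[choice, np.arange(L)]
        prev_starts = np.stack([
            np.full(L, i), np.concatenate([[i], sm[:-1]]),
            np.concatenate([[i], si[1:L]]), np.concatenate([[i], sd[:-1]]),
        ])
        new_sm = prev_starts[choice, np.arange(L)]
        # inserts I_k (k = 1..L-1 interior; I_0 / I_L allowed but never on a
        # scoring path since entry/exit are via match states)
        ci = np.stack([vm + tmi[1:], vi[1:] + tii[1:]])
        ichoice = ci.argmax(axis=0)
        new_vi_tail = li[1:, x] + ci[ichoice, np.arange(L)]
        new_si_tail = np.where(ichoice == 0, sm, si[1:])
        vm, sm = new_vm, new_sm
        vi = np.concatenate([[_LOG0], new_vi_tail])
        si = np.concatenate([[0], new_si_tail])
        # deletes within row i: D_k best over source match j < k
        arr = np.full(L, _LOG0)
        arr[:-1] = vm[:-1] + tmd[1:L] - cdd[1:]
        runmax = np.maximum.accumulate(arr)
        achieves = arr >= runmax
        runarg = np.maximum.accumulate(np.where(achieves, np.arange(L), -1))
        vd = np.full(L, _LOG0)
        vd[1:] = runmax[:-1] + cdd[1:]
        sd = np.zeros(L, dtype=int)
        sd[1:] = sm[np.maximum(runarg[:-1], 0)]
        # exit: best match state ending at residue i
        k_best = int(vm.argmax())
        if vm[k_best] > best_score:
            best_score = float(vm[k_best])
            best_end = i + 1
            best_start = int(sm[k_best])
    if best_score <= _LOG0 / 2:
        return None
    return DomainHit(protein_id, hmm.name, best_score, best_start, best_end)


def scan_proteome(
    hmms: list[ProfileHMM],
    proteome: list[tuple[str, str]],
    thresholds: dict[str, float],
) -> list[DomainHit]:
    """All (protein, model) best hits with bit score >= the model's threshold.

    A missing threshold for any model is an error, never a silent default.
    Hits are sorted by (protein_id, model_name, -score).
    """
    for hmm in hmms:
        if hmm.name not in thresholds:
            raise ValueError(f"no bit threshold defined for model {hmm.name!r}")
    hits = []
    for pid, seq in proteome:
        for hmm in hmms:
            hit = viterbi_score(hmm, seq, protein_id=pid)
            if hit is not None and hit.bit_score >= thresholds[hmm.name]:
                hits.append(hit)
    hits.sort(key=lambda h: (h.protein_id, h.model_name, -h.bit_score))
    return hits


def classify_architecture(
    hits: list[DomainHit],
    protein_ids: list[str],
    model_classes: dict[str, str] | None = None,
) -> dict[str, str]:
    """Partition proteins into SNF2_only / HelC_only / both / neither.

    ``model_classes`` maps model name -> "SNF2" or "HELC"; by default the
    class is inferred from the model name (substring match).
    """
    def infer(name: str) -> str:
        u = name.upper()
        if "SNF2" in u:
            return "SNF2"
        if "HEL" in u:
            return "HELC"
        return name

    classes = model_classes or {}
    has_snf2: set[str] = set()
    has_helc: set[str] = set()
    known = set(protein_ids)
    for h in hits:
        if h.protein_id not in known:
            raise ValueError(f"hit references unknown protein {h.protein_id!r}")
        cls = classes.get(h.model_name, infer(h.model_name))
        if cls == "SNF2":
            has_snf2.add(h.protein_id)
        elif cls == "HELC":
            has_helc.add(h.protein_id)
    out = {}
    for pid in protein_ids:
        if pid in has_snf2 and pid in has_helc:
            out[pid] = "both"
        elif pid in has_snf2:
            out[pid] = "SNF2_only"
        elif pid in has_helc:
            out[pid] = "HelC_only"
        else:
            out[pid] = "neither"
    return out


# ---------------------------------------------------------------------------
# HMMER3-format text I/O (documented subset)
# ---------------------------------------------------------------------------
# Read/written fields: HMMER3 magic, NAME, LENG, ALPH amino, the HMM header,
# per-node match/insert emission and transition lines (negative natural
# logs, '*' for zero). COMPO and annotation columns are ignored on read and
# not written.


def _fmt(p: float) -> str:
    if p <= 0:
        return "*"
    return f"{-math.log(p):.5f}"


def _parse(tok: str) -> float:
    if tok == "*":
        return 0.0
    return math.exp(-float(tok))


def write_hmmer3(hmms: list[ProfileHMM], path: str | Path) -> None:
    lines = []
    for hmm in hmms:
        L = hmm.length
        lines.append("HMMER3/f [clsymine profile subset]")
        lines.append(f"NAME  {hmm.name}")
        lines.append(f"LENG  {L}")
        lines.append("ALPH  amino")
        lines.append("HMM          " + "        ".join(PROTEIN_ALPHABET))
        lines.append("            " + "     ".join(TRANS_ORDER))
        lines.append("  " + " ".join(_fmt(p) for p in hmm.insert_emissions[0]))
        lines.append("  " + " ".join(_fmt(p) for p in hmm.transitions[0]))
        for k in range(1, L + 1):
            lines.append(f"  {k:4d} " +
                         " ".join(_fmt(p) for p in hmm.match_emissions[k - 1]))
            lines.append("  " + " ".join(_fmt(p) for p in hmm.insert_emissions[k]))
            lines.append("  " + " ".join(_fmt(p) for p in hmm.transitions[k]))
        lines.append("//")
    Path(path).write_text("\n".join(lines) + "\n")


def read_hmmer3(path: str | Path) -> list[ProfileHMM]:
    text = Path(path).read_text()
    models = []
    block: list[str] = []
    for line in text.splitlines():
        if line.strip() == "//":
            models.append(_parse_block(block))
            block = []
        elif line.strip():
            block.append(line)
    return models


def _parse_block(block: list[str]) -> ProfileHMM:
    name, leng = None, None
    body_start = None
    for i, line in enumerate(block):
        tok = line.split()
        if tok[0] == "NAME":
            name = tok[1]
        elif tok[0] == "LENG":
            leng = int(tok[1])
        elif tok[0] == "ALPH" and tok[1].lower() != "amino":
            raise ValueError("only amino-alphabet profiles are supported")
        elif tok[0] == "HMM":
            body_start = i + 2  # skip transition-order header line
            break
    if name is None or leng is None or body_start is None:
        raise ValueError("malformed profile text: missing NAME/LENG/HMM")
    rows = [ln.split() for ln in block[body_start:]]
    if rows and rows[0][0] == "COMPO":
        rows = rows[1:]
    insert0 = [_parse(t) for t in rows[0][:20]]
    trans0 = [_parse(t) for t in rows[1][:7]]
    match_em, insert_em, trans = [], [insert0], [trans0]
    idx = 2
    for _ in range(leng):
        match_em.append([_parse(t) for t in rows[idx][1:21]])
        insert_em.append([_parse(t) for t in rows[idx + 1][:20]])
        trans.append([_parse(t) for t in rows[idx + 2][:7]])
        idx += 3
    def _norm(rows_: list[list[float]]) -> np.ndarray:
        arr = np.array(rows_)
        sums = arr.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        return arr / sums

    trans_arr = np.array(trans)
    for lo, hi in ((0, 3), (3, 5), (5, 7)):  # per-source-state groups
        sums = trans_arr[:, lo:hi].sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        trans_arr[:, lo:hi] /= sums
    return ProfileHMM(
        name=name,
        match_emissions=_norm(match_em),
        insert_emissions=_norm(insert_em),
        transitions=trans_arr,
    )


def hits_to_tsv(hits: list[DomainHit], path: str | Path) -> None:
    """Report hits as TSV with 1-based inclusive coordinates."""
    lines = ["protein\tmodel\tbits\tstart1\tend1"]
    for h in hits:
        lines.append(f"{h.protein_id}\t{h.model_name}\t{h.bit_score:.2f}"
                     f"\t{h.start + 1}\t{h.end}")
    Path(path).write_text("\n".join(lines) + "\n")
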