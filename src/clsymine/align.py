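"""Pairwise and progressive multiple protein alignment.

Global affine-gap alignment (Gotoh) and a progressive MSA built from a
k-mer-distance UPGMA guide tree with profile-profile merging. This is a
deterministic stand-in for external aligners: curated family alignments from
MUSCLE or ClustalW can be supplied as aligned FASTA and bypass it entirely.

Gap costs: a gap of length L costs gap_open + (L - 1) * gap_extend.
Traceback ties are broken diagonal, then up (gap in b), then left (gap in a),
fixed for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from Bio.Align import substitution_matrices

from ._codons import PROTEIN_ALPHABET

NEG = -1e30  # effectively -inf, safe in float arithmetic

DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0


@dataclass(frozen=True)
class PairwiseAlignment:
    """An optimal global alignment of two sequences."""

    aligned_a: str
    aligned_b: str
    score: float

    def degapped(self) -> tuple[str, str]:
        return (self.aligned_a.replace("-", ""), self.aligned_b.replace("-", ""))


@dataclass(frozen=True)
class Msa:
    """A multiple sequence alignment: equal-length gapped rows, unique ids."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self):
        ids = [r[0] for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate row ids in MSA")
        lengths = {len(r[1]) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("MSA rows have unequal lengths")

    @property
    def column_count(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.rows]

    def sequence(self, row_id: str) -> str:
        for rid, seq in self.rows:
            if rid == row_id:
                return seq
        raise KeyError(row_id)

    def column(self, j: int) -> list[str]:
        return [seq[j] for _, seq in self.rows]


def load_matrix(name: str = "BLOSUM62") -> dict[tuple[str, str], float]:
    """A named substitution matrix as a symmetric {(a, b): score} dict."""
    m = substitution_matrices.load(name)
    return {
        (a, b): float(m[a, b])
        for a in m.alphabet
        for b in m.alphabet
    }


def read_matrix(path: str | Path) -> dict[tuple[str, str], float]:
    """Read a whitespace-separated square score table with a residue header."""
    lines = [ln.split() for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    header = lines[0]
    out: dict[tuple[str, str], float] = {}
    for row in lines[1:]:
        a = row[0]
        for b, v in zip(header, row[1:]):
            out[(a, b)] = float(v)
    return out


def _check_alphabet(seq: str, matrix: dict[tuple[str, str], float]) -> None:
    known = {a for a, _ in matrix}
    bad = set(seq) - known
    if bad:
        raise ValueError(f"residues without matrix rows: {sorted(bad)}")


def global_align(
    a: str,
    b: str,
    matrix: dict[tuple[str, str], float] | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> PairwiseAlignment:
    """Optimal global alignment with affine gap penalties (Gotoh)."""
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    if matrix is None:
        matrix = load_matrix()
    _check_alphabet(a, matrix)
    _check_alphabet(b, matrix)
    n, m = len(a), len(b)
    # M: a[i] aligned to b[j]; X: gap in b (consume a); Y: gap in a (consume b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        sa = a[i - 1]
        for j in range(1, m + 1):
            s = matrix[(sa, b[j - 1])]
            M[i, j] = s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend,
                          Y[i - 1, j] - gap_open)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend,
                          X[i, j - 1] - gap_open)
    score = max(M[n, m], X[n, m], Y[n, m])

    # traceback; tie order fixed: M (diagonal), then X (up), then Y (left)
    out_a, out_b = [], []
    i, j = n, m
    state = "M" if M[n, m] >= max(X[n, m], Y[n, m]) else (
        "X" if X[n, m] >= Y[n, m] else "Y")
    while i > 0 or j > 0:
        if state == "M":
            prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
            state = ("M" if M[i, j] == prev else
                     "X" if X[i, j] == prev else "Y")
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append("-")
            came_m = M[i - 1, j] - gap_open
            came_x = X[i - 1, j] - gap_extend
            came_y = Y[i - 1, j] - gap_open
            best = max(came_m, came_x, came_y)
            i -= 1
            state = "M" if came_m == best else ("X" if came_x == best else "Y")
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            came_m = M[i, j - 1] - gap_open
            came_y = Y[i, j - 1] - gap_extend
            came_x = X[i, j - 1] - gap_open
            best = max(came_m, came_y, came_x)
            j -= 1
            state = "M" if came_m == best else ("Y" if came_y == best else "X")
        if i == 0 and j == 0:
            break
    return PairwiseAlignment("".join(reversed(out_a)), "".join(reversed(out_b)),
                             float(score))


# ---------------------------------------------------------------------------
# progressive MSA
# ---------------------------------------------------------------------------


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    """1 - fractional shared k-mer count; crude but adequate for a guide tree."""
    if len(a) < k or len(b) < k:
        return 1.0
    ka: dict[str, int] = {}
    kb: dict[str, int] = {}
    for i in range(len(a) - k + 1):
        ka[a[i:i + k]] = ka.get(a[i:i + k], 0) + 1
    for i in range(len(b) - k + 1):
        kb[b[i:i + k]] = kb.get(b[i:i + k], 0) + 1
    shared = sum(min(ka[w], kb[w]) for w in ka.keys() & kb.keys())
    return 1.0 - shared / (min(len(a), len(b)) - k + 1)


class _Profile:
    """Alignment profile: rows plus per-column residue frequency vectors."""

    def __init__(self, rows: list[tuple[str, str]]):
        self.rows = rows
        ncol = len(rows[0][1])
        alpha = PROTEIN_ALPHABET
        idx = {ch: i for i, ch in enumerate(alpha)}
        freq = np.zeros((ncol, len(alpha)))
        gaps = np.zeros(ncol)
        for _, seq in rows:
            for j, ch in enumerate(seq):
                if ch == "-":
                    gaps[j] += 1
                elif ch in idx:
                    freq[j, idx[ch]] += 1
        nres = freq.sum(axis=1, keepdims=True)
        nres[nres == 0] = 1.0
        self.freq = freq / nres
        self.gap_frac = gaps / len(rows)


def _profile_score_matrix(p: _Profile, q: _Profile,
                          matrix: dict[tuple[str, str], float]) -> np.ndarray:
    alpha = PROTEIN_ALPHABET
    S = np.array([[matrix[(x, y)] for y in alpha] for x in alpha])
    return p.freq @ S @ q.freq.T


def _align_profiles(p: _Profile, q: _Profile,
                    matrix: dict[tuple[str, str], float],
                    gap_open: float, gap_extend: float) -> list[tuple[str, str]]:
    """Affine profile-profile alignment; merges two sub-alignments."""
    col = _profile_score_matrix(p, q, matrix)
    n, m = col.shape
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        ci = col[i - 1]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            M[i, j] = ci[j - 1] + max(Mp[j - 1], Xp[j - 1], Yp[j - 1])
            X[i, j] = max(Mp[j] - gap_open, Xp[j] - gap_extend, Yp[j] - gap_open)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend,
                          X[i, j - 1] - gap_open)
    i, j = n, m
    state = "M" if M[n, m] >= max(X[n, m], Y[n, m]) else (
        "X" if X[n, m] >= Y[n, m] else "Y")
    ops = []  # 'D' both advance, 'U' p only, 'L' q only
    while i > 0 or j > 0:
        if state == "M":
            ops.append("D")
            prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            i, j = i - 1, j - 1
            state = ("M" if M[i, j] == prev else
                     "X" if X[i, j] == prev else "Y")
        elif state == "X":
            ops.append("U")
            came = (M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend,
                    Y[i - 1, j] - gap_open)
            i -= 1
            best = max(came)
            state = "M" if came[0] == best else ("X" if came[1] == best else "Y")
        else:
            ops.append("L")
            came = (M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend,
                    X[i, j - 1] - gap_open)
            j -= 1
            best = max(came)
            state = "M" if came[0] == best else ("Y" if came[1] == best else "X")
    ops.reverse()
    out = []
    for rid, seq in p.rows + q.rows:
        from_p = any(rid == r for r, _ in p.rows)
        merged, k = [], 0
        for op in ops:
            if op == "D" or (op == "U" and from_p) or (op == "L" and not from_p):
                merged.append(seq[k])
                k += 1
            else:
                merged.append("-")
        out.append((rid, "".join(merged)))
    return out


def progressive_msa(
    sequences: list[tuple[str, str]],
    matrix: dict[tuple[str, str], float] | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> Msa:
    """Progressive MSA along a k-mer-distance UPGMA guide tree."""
    if not sequences:
        raise ValueError("no sequences")
    if len(sequences) == 1:
        return Msa(tuple(sequences))
    if matrix is None:
        matrix = load_matrix()
    for _, seq in sequences:
        _check_alphabet(seq, matrix)
    n = len(sequences)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = _kmer_distance(sequences[i][1], sequences[j][1])
    Z = linkage(squareform(dm, checks=False), method="average")
    profiles: dict[int, _Profile] = {
        i: _Profile([sequences[i]]) for i in range(n)
    }
    for k, (left, right, _, _) in enumerate(Z):
        p, q = profiles.pop(int(left)), profiles.pop(int(right))
        profiles[n + k] = _Profile(_align_profiles(p, q, matrix,
                                                   gap_open, gap_extend))
    (merged,) = profiles.values()
    order = {rid: k for k, (rid, _) in enumerate(sequences)}
    rows = tuple(sorted(merged.rows, key=lambda r: order[r[0]]))
    return Msa(rows)


def read_aligned_fasta(path: str | Path) -> Msa:
    """Ingest an externally produced MSA (e.g. MUSCLE output)."""
    from .io import read_fasta

    return Msa(tuple(read_fasta(path)))


def write_aligned_fasta(msa: Msa, path: str | Path) -> None:
    from .io import write_fasta

    write_fasta(list(msa.rows), path, width=60)
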