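"""Molecular evolution of duplicate gene pairs.

Protein-guided codon alignment, Nei-Gojobori (1986) Ka/Ks with pathway
averaging and Jukes-Cantor correction, duplication dating
T = Ks / (2 lambda) x 10^-6 Mya with lambda the synonymous substitution rate
per site per year, selection-pressure classification, collinear-block
detection by rank-monotone chaining of homolog pairs, and duplication-type
classification (WGD/segmental vs tandem vs proximal vs dispersed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable

import numpy as np
import pandas as pd

from ._codons import (
    STOP_CODONS,
    codons_of,
    synonymous_site_fractions,
    translate_codon,
)
from .align import PairwiseAlignment

#: Synonymous substitutions per site per year used for duplication dating.
DEFAULT_LAMBDA = 6.5e-9

NEUTRAL_TOLERANCE = 1e-9


@dataclass(frozen=True)
class CodonAlignment:
    """Two gapless codon sequences of equal length; gapped columns removed."""

    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]
    removed_column_count: int

    def __post_init__(self):
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon rows must have equal length")
        for c in (*self.codons_a, *self.codons_b):
            if c in STOP_CODONS:
                raise ValueError(f"stop codon {c} retained in codon alignment")


@dataclass(frozen=True)
class KaKsResult:
    """NG86 site/difference counts and JC-corrected rates."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    ka: float
    ks: float
    ratio: float | None  # None when Ks == 0 (undefined)


def codon_align(cds_a: str, cds_b: str,
                protein_alignment: PairwiseAlignment) -> CodonAlignment:
    """Back-map a protein alignment onto the two CDSs, dropping gap columns."""
    for label, cds in (("a", cds_a), ("b", cds_b)):
        if len(cds) % 3 != 0:
            raise ValueError(f"cds_{label} length is not a multiple of 3")
    ca, cb = codons_of(cds_a), codons_of(cds_b)
    for label, cod in (("a", ca), ("b", cb)):
        stops = [c for c in cod if c in STOP_CODONS]
        if stops:
            raise ValueError(f"internal stop codon in cds_{label}: {stops[0]}")
    pa = "".join(translate_codon(c) for c in ca)
    pb = "".join(translate_codon(c) for c in cb)
    da, db = protein_alignment.degapped()
    if pa != da or pb != db:
        raise ValueError("protein alignment does not match CDS translations")
    out_a, out_b = [], []
    removed = 0
    i = j = 0
    for ra, rb in zip(protein_alignment.aligned_a, protein_alignment.aligned_b):
        if ra != "-" and rb != "-":
            out_a.append(ca[i])
            out_b.append(cb[j])
        else:
            removed += 1
        if ra != "-":
            i += 1
        if rb != "-":
            j += 1
    return CodonAlignment(tuple(out_a), tuple(out_b), removed)


@lru_cache(maxsize=None)
def _pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences for one codon pair,
    uniformly averaged over minimal mutational pathways that avoid stop
    codons (weights renormalized). If every pathway passes through a stop,
    all pathways are used and stop-passing steps count as nonsynonymous."""
    diff_pos = [p for p in range(3) if codon_a[p] != codon_b[p]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff_pos):
        current = codon_a
        syn = non = 0
        blocked = False
        for p in order:
            nxt = current[:p] + codon_b[p] + current[p + 1:]
            if nxt in STOP_CODONS:
                blocked = True
                non += 1
            elif translate_codon(nxt) == translate_codon(current):
                syn += 1
            else:
                non += 1
            current = nxt
        pathways.append((blocked, syn, non))
    valid = [(s, n) for blocked, s, n in pathways if not blocked]
    if not valid:
        valid = [(s, n) for _, s, n in pathways]
    sd = sum(s for s, _ in valid) / len(valid)
    nd = sum(n for _, n in valid) / len(valid)
    return sd, nd


def _jc(p: float) -> float:
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def ng86(ca: CodonAlignment) -> KaKsResult:
    """Nei-Gojobori Ka/Ks with pathway averaging and JC correction.

    Site counts are per-codon synonymous fractions averaged over the two
    sequences; S + N = 3 x codon count. The Ka/Ks ratio is None (undefined)
    when Ks = 0.
    """
    L = len(ca.codons_a)
    if L == 0:
        raise ValueError("codon alignment is empty")
    S = 0.0
    Sd = Nd = 0.0
    for a, b in zip(ca.codons_a, ca.codons_b):
        sa = sum(synonymous_site_fractions(a))
        sb = sum(synonymous_site_fractions(b))
        S += 0.5 * (sa + sb)
        ds, dn = _pathway_differences(a, b)
        Sd += ds
        Nd += dn
    N = 3.0 * L - S
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    if pS >= 0.75 or pN >= 0.75:
        raise ValueError("saturated alignment: p-distance >= 3/4")
    ks = float(_jc(pS))
    ka = float(_jc(pN))
    ratio = (ka / ks) if ks > 0 else None
    return KaKsResult(S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN,
                      ka=ka, ks=ks, ratio=ratio)


def duplication_date(ks: float, lam: float = DEFAULT_LAMBDA) -> float:
    """Divergence date in Mya: T = Ks / (2 lambda) x 10^-6."""
    if ks < 0:
        raise ValueError("Ks must be >= 0")
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    return ks / (2.0 * lam) * 1e-6


def classify_selection(ratio: float | None) -> str:
    """purifying (<1), neutral (=1 within 1e-9), positive (>1), undefined."""
    if ratio is None:
        return "undefined"
    if ratio < 0:
        raise ValueError("Ka/Ks ratio must be >= 0")
    if abs(ratio - 1.0) <= NEUTRAL_TOLERANCE:
        return "neutral"
    return "purifying" if ratio < 1.0 else "positive"


# ---------------------------------------------------------------------------
# collinearity and duplication typing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenePosition:
    gene_id: str
    chromosome: str
    rank: int
    start: int
    end: int
    strand: str = "+"


@dataclass(frozen=True)
class CollinearBlock:
    """A rank-monotone chain of homolog anchor pairs between two regions."""

    anchors: tuple[tuple[str, str], ...]
    a_chrom: str
    b_chrom: str
    score: float


def positions_from_gene_models(models: Iterable) -> dict[str, GenePosition]:
    """Rank genes along each chromosome by start coordinate."""
    by_chrom: dict[str, list] = {}
    for m in models:
        by_chrom.setdefault(m.chromosome, []).append(m)
    out = {}
    for chrom, ms in by_chrom.items():
        for rank, m in enumerate(sorted(ms, key=lambda g: g.start)):
            out[m.gene_id] = GenePosition(m.gene_id, chrom, rank,
                                          m.start, m.end, m.strand)
    return out


DEFAULT_ANCHOR_SCORE = 1.0
DEFAULT_GAP_PENALTY = 0.1


def find_collinear_blocks(
    positions: dict[str, GenePosition],
    homolog_pairs: list[tuple[str, str]],
    min_anchors: int = 3,
    max_gap: int = 3,
) -> list[CollinearBlock]:
    """Chain homolog pairs into collinear blocks between chromosome pairs.

    Dynamic-programming chaining requires strictly monotone ranks on both
    sides (either orientation) with per-step rank gaps <= max_gap; chain
    score is +1 per anchor minus 0.1 per skipped rank unit. Maximal-scoring
    non-overlapping chains with >= min_anchors anchors are reported.
    """
    if min_anchors < 2:
        raise ValueError("min_anchors must be >= 2")
    grouped: dict[tuple[str, str], list[tuple[int, int, tuple[str, str]]]] = {}
    for ga, gb in homolog_pairs:
        if ga not in positions or gb not in positions:
            missing = ga if ga not in positions else gb
            raise ValueError(f"no position for gene {missing!r}")
        pa, pb = positions[ga], positions[gb]
        if (pa.chromosome, pa.rank) > (pb.chromosome, pb.rank):
            pa, pb = pb, pa
            ga, gb = gb, ga
        grouped.setdefault((pa.chromosome, pb.chromosome), []).append(
            (pa.rank, pb.rank, (ga, gb)))
    blocks = []
    for (ca, cb), anchors in grouped.items():
        for orientation in (+1, -1):
            pool = list(anchors)
            while True:
                chain = _best_chain(pool, orientation, max_gap)
                if chain is None or len(chain[0]) < min_anchors:
                    break
                members, score = chain
                blocks.append(CollinearBlock(
                    tuple(pair for _, _, pair in members), ca, cb, score))
                used = {id(a) for a in members}
                pool = [a for a in pool if id(a) not in used]
    return sorted(blocks, key=lambda b: (-b.score, b.a_chrom, b.b_chrom))


def _best_chain(anchors, orientation, max_gap):
    if not anchors:
        return None
    items = sorted(anchors, key=lambda t: (t[0], orientation * t[1]))
    n = len(items)
    score = [DEFAULT_ANCHOR_SCORE] * n
    prev = [-1] * n
    for i in range(n):
        ra, rb, _ = items[i]
        for j in range(i):
            qa, qb, _ = items[j]
            da = ra - qa
            db = orientation * (rb - qb)
            if da < 1 or db < 1 or da > max_gap or db > max_gap:
                continue
            gap_units = (da - 1) + (db - 1)
            cand = score[j] + DEFAULT_ANCHOR_SCORE \
                - DEFAULT_GAP_PENALTY * gap_units
            if cand > score[i]:
                score[i] = cand
                prev[i] = j
    best = int(np.argmax(score))
    chain = []
    k = best
    while k != -1:
        chain.append(items[k])
        k = prev[k]
    chain.reverse()
    return chain, score[best]


def classify_duplication(
    pair: tuple[str, str],
    blocks: list[CollinearBlock],
    positions: dict[str, GenePosition],
    tandem_max_rank_gap: int = 1,
    proximal_window: int = 10,
) -> str:
    """wgd_segmental if the pair anchors a collinear block; else tandem /
    proximal by same-chromosome rank distance; else dispersed."""
    ga, gb = pair
    for g in pair:
        if g not in positions:
            raise ValueError(f"no position for gene {g!r}")
    unordered = {ga, gb}
    for block in blocks:
        for a, b in block.anchors:
            if {a, b} == unordered:
                return "wgd_segmental"
    pa, pb = positions[ga], positions[gb]
    if pa.chromosome == pb.chromosome:
        gap = abs(pa.rank - pb.rank)
        if gap <= tandem_max_rank_gap:
            return "tandem"
        if gap <= proximal_window:
            return "proximal"
    return "dispersed"


# ---------------------------------------------------------------------------
# per-pair report mirroring the paralog-pair table
# ---------------------------------------------------------------------------


def duplication_events(
    pairs: list[tuple[str, str]],
    cds: dict[str, str],
    positions: dict[str, GenePosition],
    blocks: list[CollinearBlock],
    lam: float = DEFAULT_LAMBDA,
    tandem_max_rank_gap: int = 1,
    proximal_window: int = 10,
) -> pd.DataFrame:
    """Full per-pair analysis: Ka, Ks, ratio, date, selection, dup type."""
    from .align import global_align

    rows = []
    for ga, gb in pairs:
        aln = global_align(
            "".join(translate_codon(c) for c in codons_of(cds[ga])),
            "".join(translate_codon(c) for c in codons_of(cds[gb])),
        )
        res = ng86(codon_align(cds[ga], cds[gb], aln))
        dup = classify_duplication((ga, gb), blocks, positions,
                                   tandem_max_rank_gap, proximal_window)
        rows.append({
            "gene_a": ga, "gene_b": gb,
            "ka": res.ka, "ks": res.ks,
            "kaks": res.ratio if res.ratio is not None else float("nan"),
            "date_mya": duplication_date(res.ks, lam),
            "selection": classify_selection(res.ratio),
            "dup_type": dup,
        })
    return pd.DataFrame(rows)
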