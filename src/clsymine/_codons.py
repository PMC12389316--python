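"""Shared codon-level utilities: genetic code, neighbor enumeration, site fractions.

Standard genetic code (table 1) only. Changes to stop codons are never counted
as synonymous; synonymous site fractions are (# synonymous single-nucleotide
neighbors) / 3 per codon position, the NG86 counting convention.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(
    "".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)
    if "".join(c) not in STOP_CODONS
)


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon, '*' for a stop codon."""
    if codon in STOP_CODONS:
        return "*"
    return _TABLE.forward_table[codon]


def translate_cds(cds: str) -> str:
    if len(cds) % 3 != 0:
        raise ValueError("CDS length is not a multiple of 3")
    return "".join(translate_codon(cds[i:i + 3]) for i in range(0, len(cds), 3))


def codons_of(cds: str) -> list[str]:
    if len(cds) % 3 != 0:
        raise ValueError("CDS length is not a multiple of 3")
    return [cds[i:i + 3] for i in range(0, len(cds), 3)]


def neighbors(codon: str, pos: int) -> list[str]:
    """The three codons reachable by substituting position ``pos`` (0..2)."""
    return [
        codon[:pos] + nt + codon[pos + 1:]
        for nt in NUCLEOTIDES
        if nt != codon[pos]
    ]


@lru_cache(maxsize=None)
def synonymous_site_fractions(codon: str) -> tuple[float, ...]:
    """Per-position synonymous site fraction for a sense codon.

    Fraction = (# single-nucleotide neighbors encoding the same amino acid,
    stop codons excluded) / 3.
    """
    aa = translate_codon(codon)
    fracs = []
    for pos in range(3):
        syn = sum(
            1 for n in neighbors(codon, pos)
            if n not in STOP_CODONS and translate_codon(n) == aa
        )
        fracs.append(syn / 3.0)
    return tuple(fracs)


def codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon; they sum to 3."""
    s = sum(synonymous_site_fractions(codon))
    return s, 3.0 - s
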