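"""Synthetic inputs with the statistical structure the pipeline assumes.

Four generators cover the four kinds of real input the analysis consumes:

* multi-species proteomes carrying a two-domain target family (SNF2-like +
  Helicase-C-like) split into subfamilies by private conserved blocks, plus
  one-domain decoys and background proteins;
* duplicated CDS pairs evolved at controlled synonymous / nonsynonymous
  densities (ground truth for Ka/Ks estimation);
* annotated genomes with collinear duplicated segments, tandem arrays,
  proximal and dispersed duplicates (ground truth for duplication typing);
* replicate RT-qPCR CT tables with a constitutive reference gene (ground
  truth for 2^-ddCT recovery).

All generators take an explicit integer seed and are deterministic for a
fixed (config, seed); seeds are never read from global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._codons import (
    PROTEIN_ALPHABET,
    SENSE_CODONS,
    STOP_CODONS,
    codons_of,
    synonymous_site_fractions,
    translate_codon,
)

# ---------------------------------------------------------------------------
# family proteome generator
# ---------------------------------------------------------------------------

# Fixed consensus motifs for the two shared domains and the subfamily-private
# blocks. Arbitrary but frozen: the detection problem only needs motifs that
# are long enough to score well above background under a profile HMM.
SNF2_MOTIF = (
    "LDAHQVGKTLMEWFRYPSNICGDEKAVTHLRWQMFYSEDNPKAGICLVTWRHEQYMFSDN"
)
HELC_MOTIF = "GRVLIFTQWHEDYSMKANPCGLRVETIFWQHYDKSMANPEWCVLTHQRFY"
CLADE1_BLOCK = "WKEPHNDYRVCQMGTSLAIFWKDEH"
CLADE2_BLOCK = "FMRTSGAYLVHQNEDKPCIWFMRSG"

# Family-wide conserved context flanking each domain in true family members
# (absent in one-domain decoys). This emulates the family-specific
# conservation beyond the generic domains that family-trained profile HMMs
# exploit to separate true members from other domain-bearing proteins.
FAMILY_CONTEXT = {
    "SNF2": ("QWTYDMHKERLVANSGCPFIDWYEQTHRLMSDKYVQWTEG",
             "KVSNEYGQWLMATCHRPDFIYKWEQSNVGTLHDMRYQWCE"),
    "HELC": ("EHLWMQDYTNRKVGSAPCIFEWHLQMYDTRNKSGVWQEYL",
             "RGYVNWSEKQTMHALDPCFIGRWYNVESKQDTHLMWYQRG"),
}

DOMAIN_SNF2 = "SNF2"
DOMAIN_HELC = "HELC"


@dataclass(frozen=True)
class FamilyProteomeConfig:
    """Composition of a synthetic multi-species proteome."""

    domain_motifs: dict[str, str] = field(
        default_factory=lambda: {DOMAIN_SNF2: SNF2_MOTIF, DOMAIN_HELC: HELC_MOTIF}
    )
    subfamilies: dict[str, int] = field(
        default_factory=lambda: {"clade1": 10, "clade2": 10}
    )
    subfamily_blocks: dict[str, str] = field(
        default_factory=lambda: {"clade1": CLADE1_BLOCK, "clade2": CLADE2_BLOCK}
    )
    family_context: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(FAMILY_CONTEXT)
    )
    n_decoys: int = 20
    n_background: int = 100
    length_range: tuple[int, int] = (420, 560)
    conservation: float = 0.9
    species: tuple[str, ...] = ("speciesA", "speciesB")

    def validate(self) -> None:
        if len(self.domain_motifs) < 2:
            raise ValueError("config must name at least two domain motifs")
        if len(self.subfamilies) < 2:
            raise ValueError("config must name at least two family subgroups")
        if any(n <= 0 for n in self.subfamilies.values()):
            raise ValueError("empty family subgroup in config")
        if any(len(m) == 0 for m in self.domain_motifs.values()):
            raise ValueError("zero-length domain motif")
        for name in self.subfamilies:
            if len(self.subfamily_blocks.get(name, "")) == 0:
                raise ValueError(f"zero-length or missing block for {name!r}")
        if self.n_decoys < 0 or self.n_background < 0:
            raise ValueError("decoy/background counts must be >= 0")
        if not 0.0 <= self.conservation <= 1.0:
            raise ValueError("conservation must lie in [0, 1]")
        motif_span = sum(
            len(m) + sum(len(c) for c in self.family_context.get(d, ("", "")))
            for d, m in self.domain_motifs.items()
        ) + max(len(b) for b in self.subfamily_blocks.values())
        if self.length_range[0] <= motif_span:
            raise ValueError("minimum protein length does not fit the motifs")


def _random_protein(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(list(PROTEIN_ALPHABET), size=n))


def _mutate_motif(rng: np.random.Generator, motif: str, conservation: float) -> str:
    out = []
    for ch in motif:
        if rng.random() < conservation:
            out.append(ch)
        else:
            out.append(str(rng.choice(list(PROTEIN_ALPHABET))))
    return "".join(out)


def gen_family_proteome(
    config: FamilyProteomeConfig, seed: int
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate (records, truth_table) for a planted two-domain family.

    Family members carry every domain motif plus their subgroup's private
    block; decoys carry exactly one domain motif; background proteins carry
    none. The truth table partitions every emitted protein and records the
    planted block coordinates (0-based half-open).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str]] = []
    truth_rows = []
    domain_names = sorted(config.domain_motifs)
    n_species = len(config.species)
    counter = 0

    def _plant(seq: list[str], motifs: list[tuple[str, str]]) -> list[tuple[int, int]]:
        """Place motif copies left-to-right with random spacing; return coords."""
        total = sum(len(m) for _, m in motifs)
        slack = len(seq) - total
        gaps = rng.multinomial(slack, [1.0 / (len(motifs) + 1)] * (len(motifs) + 1))
        coords = []
        pos = int(gaps[0])
        for k, (_, motif) in enumerate(motifs):
            copy = _mutate_motif(rng, motif, config.conservation)
            seq[pos:pos + len(copy)] = list(copy)
            coords.append((pos, pos + len(copy)))
            pos += len(copy) + int(gaps[k + 1])
        return coords

    def _plant_consensus(seq: list[str], motifs: list[tuple[str, str]],
                         rng: np.random.Generator) -> list[tuple[int, int]]:
        """Place exact motif copies left-to-right with random spacing
        (per-member divergence is applied afterwards)."""
        total = sum(len(m) for _, m in motifs)
        slack = len(seq) - total
        gaps = rng.multinomial(slack,
                               [1.0 / (len(motifs) + 1)] * (len(motifs) + 1))
        coords = []
        pos = int(gaps[0])
        for k, (_, motif) in enumerate(motifs):
            seq[pos:pos + len(motif)] = list(motif)
            coords.append((pos, pos + len(motif)))
            pos += len(motif) + int(gaps[k + 1])
        return coords

    def _family_region(domain: str) -> str:
        left, right = config.family_context.get(domain, ("", ""))
        return left + config.domain_motifs[domain] + right

    for subfamily in sorted(config.subfamilies):
        block = config.subfamily_blocks[subfamily]
        # one ancestral layout per subfamily: motifs sit at homologous
        # backbone positions, and members diverge from the ancestor at
        # 1 - conservation per position (paralogs share ancestry beyond
        # their functional domains), plus a variable-length random tail
        anc_len = int(rng.integers(*config.length_range, endpoint=True))
        ancestor = _random_protein(rng, anc_len)
        motifs = [(d, _family_region(d)) for d in domain_names]
        motifs.append(("block", block))
        coords = _plant_consensus(ancestor, motifs, rng)
        for i in range(config.subfamilies[subfamily]):
            seq = [
                ch if rng.random() < config.conservation
                else str(rng.choice(list(PROTEIN_ALPHABET)))
                for ch in ancestor
            ]
            tail = _random_protein(rng, int(rng.integers(0, 30)))
            pid = f"{subfamily}_{i:03d}"
            species = config.species[counter % n_species]
            counter += 1
            records.append((pid, "".join(seq) + "".join(tail)))
            truth_rows.append((pid, species, subfamily, list(coords)))

    for i in range(config.n_decoys):
        length = int(rng.integers(*config.length_range, endpoint=True))
        seq = _random_protein(rng, length)
        domain = domain_names[i % len(domain_names)]
        coords = _plant(seq, [(domain, config.domain_motifs[domain])])
        pid = f"decoy_{i:03d}"
        species = config.species[counter % n_species]
        counter += 1
        records.append((pid, "".join(seq)))
        truth_rows.append((pid, species, "decoy_one_domain", coords))

    for i in range(config.n_background):
        length = int(rng.integers(*config.length_range, endpoint=True))
        pid = f"background_{i:03d}"
        species = config.species[counter % n_species]
        counter += 1
        records.append((pid, "".join(_random_protein(rng, length))))
        truth_rows.append((pid, species, "background", []))

    truth = pd.DataFrame(
        truth_rows,
        columns=["protein_id", "species", "family_label", "planted_block_coords"],
    )
    return records, truth


# ---------------------------------------------------------------------------
# CDS pair evolution
# ---------------------------------------------------------------------------

# codon -> per-position (synonymous alternatives, nonsynonymous alternatives),
# stop codons excluded from both classes.
_ALTERNATIVES: dict[str, list[tuple[tuple[str, ...], tuple[str, ...]]]] = {}
for _codon in SENSE_CODONS:
    _aa = translate_codon(_codon)
    _per_pos = []
    for _pos in range(3):
        _syn, _non = [], []
        for _nt in "ACGT":
            if _nt == _codon[_pos]:
                continue
            _alt = _codon[:_pos] + _nt + _codon[_pos + 1:]
            if _alt in STOP_CODONS:
                continue
            (_syn if translate_codon(_alt) == _aa else _non).append(_alt)
        _per_pos.append((tuple(_syn), tuple(_non)))
    _ALTERNATIVES[_codon] = _per_pos


def _jc_expected_p(d: float) -> float:
    """Expected observed difference proportion under Jukes-Cantor at distance d."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def evolve_cds_pair(
    ancestor_cds: str, target_ka: float, target_ks: float, seed: int
) -> tuple[str, str, dict[str, int]]:
    """Diverge a CDS from its ancestor at controlled Ka / Ks densities.

    Substitution counts are Poisson-drawn around the expected number of
    *observed* differences (Jukes-Cantor forward-mapped from the target
    rates), placed at distinct nucleotide sites weighted by their NG86 site
    fractions, so that NG86 estimation recovers the targets in expectation.
    Changes creating stop codons are never introduced. Returns
    (cds_a == ancestor, cds_b, realized counts).
    """
    if target_ka < 0 or target_ks < 0:
        raise ValueError("target rates must be >= 0")
    if not (math.isfinite(target_ka) and math.isfinite(target_ks)):
        raise ValueError("target rates must be finite")
    codons = codons_of(ancestor_cds)
    if not codons:
        raise ValueError("empty ancestor CDS")
    for c in codons:
        if c in STOP_CODONS:
            raise ValueError(f"internal stop codon {c} in ancestor")

    p_syn = _jc_expected_p(target_ks)
    p_non = _jc_expected_p(target_ka)
    if p_syn >= 0.75 - 1e-12 or p_non >= 0.75 - 1e-12:
        raise ValueError("target implies p-distance >= 3/4 (JC-uninvertible)")

    fracs = np.array([synonymous_site_fractions(c) for c in codons])  # (L, 3)
    s_total = float(fracs.sum())
    n_total = 3.0 * len(codons) - s_total

    rng = np.random.default_rng(seed)
    n_syn = int(rng.poisson(p_syn * s_total)) if target_ks > 0 else 0
    n_non = int(rng.poisson(p_non * n_total)) if target_ka > 0 else 0

    evolved = list(codons)
    # per-site class weights, kept in sync with the evolving sequence
    w_syn = fracs.flatten().copy()
    w_non = (1.0 - fracs).flatten()
    # sites with no legal (non-stop) alternative in a class get weight 0
    for i, c in enumerate(codons):
        for pos in range(3):
            syn_alts, non_alts = _ALTERNATIVES[c][pos]
            if not syn_alts:
                w_syn[3 * i + pos] = 0.0
            if not non_alts:
                w_non[3 * i + pos] = 0.0

    def _refresh(i: int) -> None:
        c = evolved[i]
        fr = synonymous_site_fractions(c)
        for pos in range(3):
            site = 3 * i + pos
            if site in used:
                continue
            syn_alts, non_alts = _ALTERNATIVES[c][pos]
            w_syn[site] = fr[pos] if syn_alts else 0.0
            w_non[site] = (1.0 - fr[pos]) if non_alts else 0.0

    used: set[int] = set()
    realized = {"syn": 0, "nonsyn": 0}
    events = ["syn"] * n_syn + ["nonsyn"] * n_non
    rng.shuffle(events)
    for kind in events:
        w = w_syn if kind == "syn" else w_non
        total = w.sum()
        if total <= 0:
            break  # no plantable site left in this class
        site = int(rng.choice(w.size, p=w / total))
        i, pos = divmod(site, 3)
        syn_alts, non_alts = _ALTERNATIVES[evolved[i]][pos]
        alts = syn_alts if kind == "syn" else non_alts
        evolved[i] = str(rng.choice(alts))
        realized[kind] += 1
        used.add(site)
        w_syn[site] = 0.0
        w_non[site] = 0.0
        _refresh(i)

    return ancestor_cds, "".join(evolved), realized


# ---------------------------------------------------------------------------
# genome with duplications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeConfig:
    """Layout of a synthetic annotated genome with duplicated genes.

    WGD blocks are (src_chrom, src_start_rank, size, dest_chrom,
    dest_start_rank); tandem pairs duplicate rank -> rank+1 on one
    chromosome; proximal pairs duplicate rank -> rank+gap; dispersed pairs
    copy a gene to another chromosome outside any collinear block.
    """

    n_chromosomes: int = 4
    genes_per_chromosome: int = 30
    codon_range: tuple[int, int] = (150, 300)
    wgd_blocks: tuple[tuple[int, int, int, int, int], ...] = ((0, 4, 8, 1, 12),)
    tandem_pairs: tuple[tuple[int, int], ...] = ((2, 5),)
    proximal_pairs: tuple[tuple[int, int, int], ...] = ((2, 14, 4),)
    dispersed_pairs: tuple[tuple[int, int, int, int], ...] = ((3, 3, 0, 25),)
    ka_range: tuple[float, float] = (0.05, 0.2)
    ks_range: tuple[float, float] = (0.15, 0.45)
    intergenic_range: tuple[int, int] = (500, 2000)
    max_exons: int = 4

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise ValueError("need at least one chromosome and one gene")
        for src_c, src_r, size, dst_c, dst_r in self.wgd_blocks:
            if size > self.genes_per_chromosome:
                raise ValueError("block size exceeds chromosome gene count")
            for c, r in ((src_c, src_r), (dst_c, dst_r)):
                if c >= self.n_chromosomes or r + size > self.genes_per_chromosome:
                    raise ValueError("block does not fit on chromosome")
        for c, r in self.tandem_pairs:
            if c >= self.n_chromosomes or r + 1 >= self.genes_per_chromosome:
                raise ValueError("tandem pair does not fit")
        for c, r, g in self.proximal_pairs:
            if g < 2:
                raise ValueError("proximal gap must be >= 2 (gap 1 is tandem)")
            if c >= self.n_chromosomes or r + g >= self.genes_per_chromosome:
                raise ValueError("proximal pair does not fit")
        for sc, sr, dc, dr in self.dispersed_pairs:
            if sc == dc:
                raise ValueError("dispersed pair must span two chromosomes")
            if max(sc, dc) >= self.n_chromosomes:
                raise ValueError("dispersed pair chromosome out of range")
            if max(sr, dr) >= self.genes_per_chromosome:
                raise ValueError("dispersed pair rank out of range")


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def gen_genome_with_duplications(
    config: GenomeConfig, seed: int
) -> tuple[str, list[tuple[str, str]], pd.DataFrame]:
    """Generate (gff3_text, cds_records, duplication_truth_table).

    Collinear blocks preserve gene order across two chromosomes; every
    duplicate pair's CDSs are diverged with :func:`evolve_cds_pair` at
    pair-specific target rates recorded in the truth table.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n_chr, n_genes = config.n_chromosomes, config.genes_per_chromosome

    def gene_id(c: int, r: int) -> str:
        return f"gene_c{c + 1}r{r:03d}"

    cds: dict[str, str] = {}
    for c in range(n_chr):
        for r in range(n_genes):
            n_codons = int(rng.integers(*config.codon_range, endpoint=True))
            cds[gene_id(c, r)] = random_cds(rng, n_codons)

    truth_rows = []

    def duplicate(src: str, dst: str, true_type: str) -> None:
        ka = float(rng.uniform(*config.ka_range))
        ks = float(rng.uniform(*config.ks_range))
        child_seed = int(rng.integers(0, 2**31 - 1))
        a, b, _ = evolve_cds_pair(cds[src], ka, ks, child_seed)
        cds[src], cds[dst] = a, b
        truth_rows.append((src, dst, true_type, ka, ks))

    for src_c, src_r, size, dst_c, dst_r in config.wgd_blocks:
        for k in range(size):
            duplicate(gene_id(src_c, src_r + k), gene_id(dst_c, dst_r + k),
                      "wgd_segmental")
    for c, r in config.tandem_pairs:
        duplicate(gene_id(c, r), gene_id(c, r + 1), "tandem")
    for c, r, gap in config.proximal_pairs:
        duplicate(gene_id(c, r), gene_id(c, r + gap), "proximal")
    for sc, sr, dc, dr in config.dispersed_pairs:
        duplicate(gene_id(sc, sr), gene_id(dc, dr), "dispersed")

    # annotation: genes laid out in rank order, CDS split into exons
    lines = ["##gff-version 3"]
    for c in range(n_chr):
        chrom = f"chr{c + 1}"
        pos = 1
        for r in range(n_genes):
            gid = gene_id(c, r)
            seq_len = len(cds[gid])
            pos += int(rng.integers(*config.intergenic_range, endpoint=True))
            n_ex = int(rng.integers(1, config.max_exons, endpoint=True))
            n_ex = min(n_ex, seq_len // 3)
            cuts = sorted(rng.choice(np.arange(1, seq_len), size=n_ex - 1,
                                     replace=False)) if n_ex > 1 else []
            pieces = np.diff([0, *[int(x) for x in cuts], seq_len])
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            epos = pos
            for plen in pieces:
                exons.append((epos, epos + int(plen) - 1))
                epos = exons[-1][1] + 1 + int(rng.integers(60, 400))
            gstart, gend = exons[0][0], exons[-1][1]
            lines.append("\t".join(
                [chrom, "clsymine", "gene", str(gstart), str(gend), ".",
                 strand, ".", f"ID={gid}"]))
            mrna = f"{gid}.1"
            lines.append("\t".join(
                [chrom, "clsymine", "mRNA", str(gstart), str(gend), ".",
                 strand, ".", f"ID={mrna};Parent={gid}"]))
            # exon order in the file is genomic; transcription order is
            # recovered from the strand at parse time
            for estart, eend in exons:
                lines.append("\t".join(
                    [chrom, "clsymine", "exon", str(estart), str(eend), ".",
                     strand, ".", f"Parent={mrna}"]))
                lines.append("\t".join(
                    [chrom, "clsymine", "CDS", str(estart), str(eend), ".",
                     strand, "0", f"Parent={mrna}"]))
            pos = gend + 1
    gff3_text = "\n".join(lines) + "\n"

    truth = pd.DataFrame(
        truth_rows, columns=["gene_a", "gene_b", "true_type", "true_ka", "true_ks"]
    )
    records = [(gid, cds[gid]) for gid in sorted(cds)]
    return gff3_text, records, truth


# ---------------------------------------------------------------------------
# qPCR CT tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QpcrConfig:
    """Replicated CT measurements with a constitutive reference gene.

    ``fold_changes`` maps each target gene to its true fold change in the
    treated condition; E[ddCT] = -log2(fold change). Two biological x three
    technical replicates by default, mirroring a typical germination-stress
    RT-qPCR design.
    """

    fold_changes: dict[str, float] = field(default_factory=lambda: {"CLSY": 2.0})
    reference_gene: str = "METK4"
    conditions: tuple[str, str] = ("control", "treated")
    n_biological: int = 2
    n_technical: int = 3
    noise_sd: float = 0.2
    base_ct_reference: float = 20.0
    base_dct: float = 3.0

    def validate(self) -> None:
        if not self.reference_gene:
            raise ValueError("reference gene must be named")
        if any(f <= 0 for f in self.fold_changes.values()):
            raise ValueError("fold changes must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_biological < 1 or self.n_technical < 1:
            raise ValueError("replicate counts must be >= 1")


def gen_qpcr_table(config: QpcrConfig, seed: int) -> pd.DataFrame:
    """Generate a CT table with columns (sample, condition, gene, replicate, ct)."""
    config.validate()
    rng = np.random.default_rng(seed)
    control, treated = config.conditions
    rows = []
    for condition in config.conditions:
        for bio in range(1, config.n_biological + 1):
            sample = f"{condition}_b{bio}"
            for gene in [config.reference_gene, *sorted(config.fold_changes)]:
                if gene == config.reference_gene:
                    mean_ct = config.base_ct_reference
                else:
                    mean_ct = config.base_ct_reference + config.base_dct
                    if condition == treated:
                        mean_ct -= math.log2(config.fold_changes[gene])
                for tech in range(1, config.n_technical + 1):
                    ct = mean_ct + (rng.normal(0.0, config.noise_sd)
                                    if config.noise_sd > 0 else 0.0)
                    rows.append((sample, condition, gene, tech, float(ct)))
    return pd.DataFrame(rows, columns=["sample", "condition", "gene",
                                       "replicate", "ct"])
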