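"""Codon alignment, NG86 Ka/Ks, dating, collinearity, duplication typing."""

import itertools
import warnings

import numpy as np
import pytest

from clsymine._codons import (
    STOP_CODONS,
    SENSE_CODONS,
    codons_of,
    synonymous_site_fractions,
    translate_codon,
)
from clsymine.align import PairwiseAlignment, global_align
from clsymine.evolution import (
    CodonAlignment,
    GenePosition,
    classify_duplication,
    classify_selection,
    codon_align,
    duplication_date,
    find_collinear_blocks,
    ng86,
    positions_from_gene_models,
)
from clsymine.fixtures import load_table2
from clsymine.synthetic import random_cds, evolve_cds_pair


def brute_force_ng86(codons_a, codons_b):
    """Independent NG86 oracle: explicit per-codon neighbor enumeration for
    sites and full pathway enumeration for differences."""
    S = Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        for codon in (ca, cb):
            syn = 0
            for pos, nt in itertools.product(range(3), "ACGT"):
                if nt == codon[pos]:
                    continue
                alt = codon[:pos] + nt + codon[pos + 1:]
                if alt not in STOP_CODONS and \
                        translate_codon(alt) == translate_codon(codon):
                    syn += 1
            S += syn / 6.0  # averaged over the two sequences
        positions = [p for p in range(3) if ca[p] != cb[p]]
        if not positions:
            continue
        paths = []
        for order in itertools.permutations(positions):
            cur, syn, non, blocked = ca, 0, 0, False
            for p in order:
                nxt = cur[:p] + cb[p] + cur[p + 1:]
                if nxt in STOP_CODONS:
                    blocked = True
                    non += 1
                elif translate_codon(nxt) == translate_codon(cur):
                    syn += 1
                else:
                    non += 1
                cur = nxt
            paths.append((blocked, syn, non))
        valid = [(s, n) for bl, s, n in paths if not bl] or \
            [(s, n) for _, s, n in paths]
        Sd += sum(s for s, _ in valid) / len(valid)
        Nd += sum(n for _, n in valid) / len(valid)
    N = 3 * len(codons_a) - S
    pS, pN = Sd / S, Nd / N
    jc = lambda p: -0.75 * np.log(1 - 4 * p / 3)
    return S, N, Sd, Nd, jc(pS), jc(pN)


def make_ca(cds_a, cds_b):
    return CodonAlignment(tuple(codons_of(cds_a)), tuple(codons_of(cds_b)), 0)


class TestCodonAlign:
    def test_identical_cds_identity_alignment(self):
        cds = "ATGGCTAAGGTTCCA"
        prot = "".join(translate_codon(c) for c in codons_of(cds))
        aln = PairwiseAlignment(prot, prot, 0.0)
        ca = codon_align(cds, cds, aln)
        assert ca.codons_a == ca.codons_b == tuple(codons_of(cds))
        assert ca.removed_column_count == 0

    def test_gap_column_dropped_and_counted(self):
        cds_a = "ATGGCTAAG"      # MAK
        cds_b = "ATGAAG"        # MK
        aln = PairwiseAlignment("MAK", "M-K", 0.0)
        ca = codon_align(cds_a, cds_b, aln)
        assert len(ca.codons_a) == 2
        assert ca.removed_column_count == 1

    def test_generator_pairs_roundtrip(self):
        rng = np.random.default_rng(4)
        anc = random_cds(rng, 40)
        a, b, _ = evolve_cds_pair(anc, 0.05, 0.2, seed=2)
        pa = "".join(translate_codon(c) for c in codons_of(a))
        pb = "".join(translate_codon(c) for c in codons_of(b))
        aln = global_align(pa, pb)
        ca = codon_align(a, b, aln)
        assert "".join(ca.codons_a) == a
        assert "".join(ca.codons_b) == b

    def test_distinct_errors(self):
        prot = PairwiseAlignment("M", "M", 0.0)
        with pytest.raises(ValueError, match="multiple of 3"):
            codon_align("ATGA", "ATG", prot)
        with pytest.raises(ValueError, match="stop"):
            codon_align("ATGTAAATG", "ATGTAAATG",
                        PairwiseAlignment("M*M", "M*M", 0.0))
        with pytest.raises(ValueError, match="does not match"):
            codon_align("ATGGCT", "ATGGCT", PairwiseAlignment("MK", "MK", 0.0))


class TestNg86:
    def test_identical_sequences(self):
        res = ng86(make_ca("ATGGCTAAG", "ATGGCTAAG"))
        assert res.Sd == res.Nd == 0.0
        assert res.ka == res.ks == 0.0
        assert res.ratio is None

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        anc = random_cds(rng, 30)
        a, b, _ = evolve_cds_pair(anc, 0.1, 0.2, seed=3)
        fwd, rev = ng86(make_ca(a, b)), ng86(make_ca(b, a))
        for field in ("S", "N", "Sd", "Nd", "ka", "ks"):
            assert getattr(fwd, field) == pytest.approx(
                getattr(rev, field), abs=1e-12)

    def test_site_conservation(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            n = int(rng.integers(5, 40))
            a = random_cds(rng, n)
            b, = (evolve_cds_pair(a, 0.1, 0.2, seed=1)[1],)
            res = ng86(make_ca(a, b))
            assert res.S + res.N == pytest.approx(3 * n)

    def test_planted_differences_match_oracle(self):
        """30 codons with a handful of planted substitutions: exact oracle
        agreement on sites, differences, and corrected rates."""
        rng = np.random.default_rng(13)
        anc = random_cds(rng, 30)
        a, b, realized = evolve_cds_pair(anc, 0.035, 0.03, seed=13)
        assert realized["syn"] + realized["nonsyn"] > 0
        res = ng86(make_ca(a, b))
        S, N, Sd, Nd, ks, ka = brute_force_ng86(codons_of(a), codons_of(b))
        assert res.S == pytest.approx(S, abs=1e-12)
        assert res.Sd == pytest.approx(Sd, abs=1e-12)
        assert res.Nd == pytest.approx(Nd, abs=1e-12)
        assert res.ks == pytest.approx(ks, abs=1e-12)
        assert res.ka == pytest.approx(ka, abs=1e-12)

    def test_biopython_cross_check(self):
        """Biopython's NG86 averages over stop-passing pathways where this
        implementation excludes them; rates still agree closely."""
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        rng = np.random.default_rng(5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(8):
                anc = random_cds(rng, 80)
                a, b, _ = evolve_cds_pair(anc, 0.08, 0.25, seed=seed)
                res = ng86(make_ca(a, b))
                dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
                assert res.ka == pytest.approx(dn, abs=0.03)
                assert res.ks == pytest.approx(ds, abs=0.03)

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            ng86(CodonAlignment((), (), 0))

    def test_stop_codon_rejected_in_container(self):
        with pytest.raises(ValueError, match="stop"):
            CodonAlignment(("TAA",), ("ATG",), 0)


class TestDatingAndSelection:
    def test_paper_dates(self):
        assert duplication_date(0.117351) == pytest.approx(9.03, abs=0.005)
        assert duplication_date(0.618747) == pytest.approx(47.60, abs=0.005)
        assert duplication_date(0.0) == 0.0

    def test_linearity(self):
        assert duplication_date(0.4) == pytest.approx(
            2 * duplication_date(0.2))

    def test_negative_ks_rejected(self):
        with pytest.raises(ValueError):
            duplication_date(-0.1)

    @pytest.mark.parametrize("ratio,label", [
        (0.361573, "purifying"), (1.0, "neutral"), (1.5, "positive"),
        (None, "undefined"),
    ])
    def test_selection_classes(self, ratio, label):
        assert classify_selection(ratio) == label

    def test_all_fixture_ratios_purifying(self):
        t2 = load_table2()
        for ratio in t2["ka"] / t2["ks"]:
            assert classify_selection(ratio) == "purifying"


def grid_positions(spec):
    """spec: {chrom: [gene ids in rank order]} -> positions dict."""
    out = {}
    for chrom, genes in spec.items():
        for rank, gid in enumerate(genes):
            out[gid] = GenePosition(gid, chrom, rank, 1000 * rank + 1,
                                    1000 * rank + 500, "+")
    return out


class TestCollinearity:
    def test_intact_copied_segment_is_one_block(self):
        n = 10
        positions = grid_positions({
            "c1": [f"a{i}" for i in range(n)],
            "c2": [f"b{i}" for i in range(n)],
        })
        pairs = [(f"a{i}", f"b{i}") for i in range(n)]
        blocks = find_collinear_blocks(positions, pairs, min_anchors=3)
        assert len(blocks) == 1
        assert len(blocks[0].anchors) == n

    def test_reversed_copy_detected(self):
        n = 8
        positions = grid_positions({
            "c1": [f"a{i}" for i in range(n)],
            "c2": [f"b{i}" for i in range(n)],
        })
        pairs = [(f"a{i}", f"b{n - 1 - i}") for i in range(n)]
        blocks = find_collinear_blocks(positions, pairs, min_anchors=3)
        assert len(blocks) == 1 and len(blocks[0].anchors) == n

    def test_shuffled_pairs_rarely_chain(self):
        """Null: random homolog pairs between two 100-gene chromosomes form
        no block with >= 5 anchors in at least 95% of seeds."""
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(17 + seed)
            positions = grid_positions({
                "c1": [f"a{i}" for i in range(100)],
                "c2": [f"b{i}" for i in range(100)],
            })
            pairs = [(f"a{int(rng.integers(100))}",
                      f"b{int(rng.integers(100))}") for _ in range(100)]
            blocks = find_collinear_blocks(positions, pairs, min_anchors=5)
            hits += bool(blocks)
        assert hits <= 0.05 * n_seeds

    def test_missing_position_named(self):
        with pytest.raises(ValueError, match="ghost"):
            find_collinear_blocks({}, [("ghost", "ghost2")])

    def test_min_anchors_validated(self):
        with pytest.raises(ValueError):
            find_collinear_blocks({}, [], min_anchors=1)


class TestClassifyDuplication:
    def test_rank_adjacent_pair_outside_blocks_is_tandem(self):
        positions = grid_positions({"c1": ["g0", "g1", "g2"]})
        assert classify_duplication(("g0", "g1"), [], positions) == "tandem"

    def test_proximal_and_dispersed(self):
        positions = grid_positions({
            "c1": [f"g{i}" for i in range(20)],
            "c2": ["h0"],
        })
        assert classify_duplication(("g0", "g5"), [], positions) == "proximal"
        assert classify_duplication(("g0", "g15"), [], positions) \
            == "dispersed"
        assert classify_duplication(("g0", "h0"), [], positions) \
            == "dispersed"

    def test_truth_table_recovery(self, genome_chain):
        positions = positions_from_gene_models(genome_chain["models"])
        truth = genome_chain["truth"]
        pairs = list(zip(truth["gene_a"], truth["gene_b"]))
        blocks = find_collinear_blocks(positions, pairs)
        predicted = [classify_duplication(p, blocks, positions)
                     for p in pairs]
        accuracy = np.mean([p == t for p, t
                            in zip(predicted, truth["true_type"])])
        assert accuracy >= 0.95

    def test_missing_gene_named(self):
        with pytest.raises(ValueError, match="nowhere"):
            classify_duplication(("nowhere", "g0"), [],
                                 grid_positions({"c1": ["g0"]}))
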