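"""Profile-HMM scoring: brute-force path oracle, thresholds, architecture."""

import math

import numpy as np
import pytest

from clsymine._codons import PROTEIN_ALPHABET
from clsymine.hmm import (
    DomainHit,
    ProfileHMM,
    classify_architecture,
    hmm_from_consensus,
    read_hmmer3,
    scan_proteome,
    viterbi_score,
    write_hmmer3,
)

AIDX = {c: i for i, c in enumerate(PROTEIN_ALPHABET)}


def random_profile(rng, L):
    match = rng.dirichlet(np.ones(20) * 0.3, size=L)
    insert = rng.dirichlet(np.ones(20), size=L + 1)
    trans = np.zeros((L + 1, 7))
    for k in range(L + 1):
        trans[k, :3] = rng.dirichlet(np.ones(3))
        trans[k, 3:5] = rng.dirichlet(np.ones(2))
        trans[k, 5:] = rng.dirichlet(np.ones(2))
    return ProfileHMM("toy", match, insert, trans)


def brute_force_best_local(hmm, protein):
    """Exhaustive enumeration of every local state path (entry at any match
    state, exit from any match state), independent of the DP implementation."""
    L, n = hmm.length, len(protein)
    lbg = np.log2(hmm.background)
    lm = np.log2(hmm.match_emissions) - lbg
    li = np.log2(hmm.insert_emissions) - lbg
    with np.errstate(divide="ignore"):
        t = np.where(hmm.transitions > 0,
                     np.log2(np.maximum(hmm.transitions, 1e-300)), -1e30)
    entry = math.log2(1.0 / L)
    best = [-1e30]

    def rec(state, k, i, score):
        if state == "M":
            best[0] = max(best[0], score)
        if state == "M":
            if k < L and i < n:
                rec("M", k + 1, i + 1,
                    score + t[k, 0] + lm[k, AIDX[protein[i]]])
            if i < n:
                rec("I", k, i + 1, score + t[k, 1] + li[k, AIDX[protein[i]]])
            if k < L:
                rec("D", k + 1, i, score + t[k, 2])
        elif state == "I":
            if k < L and i < n:
                rec("M", k + 1, i + 1,
                    score + t[k, 3] + lm[k, AIDX[protein[i]]])
            if i < n:
                rec("I", k, i + 1, score + t[k, 4] + li[k, AIDX[protein[i]]])
        else:
            if k < L and i < n:
                rec("M", k + 1, i + 1,
                    score + t[k, 5] + lm[k, AIDX[protein[i]]])
            if k < L:
                rec("D", k + 1, i, score + t[k, 6])

    for s in range(n):
        for k in range(1, L + 1):
            rec("M", k, s + 1, entry + lm[k - 1, AIDX[protein[s]]])
    return best[0]


class TestViterbi:
    def test_equals_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            hmm = random_profile(rng, int(rng.integers(2, 7)))
            protein = "".join(rng.choice(list(PROTEIN_ALPHABET),
                                         size=rng.integers(1, 9)))
            hit = viterbi_score(hmm, protein)
            assert hit is not None
            assert hit.bit_score == pytest.approx(
                brute_force_best_local(hmm, protein), abs=1e-9)

    def test_consensus_scores_at_least_mutants(self):
        hmm = hmm_from_consensus("C", "WKDEHRLMYQNVTSGA", match_prob=0.9)
        consensus = hmm.consensus()
        base = viterbi_score(hmm, consensus).bit_score
        assert base > 0
        rng = np.random.default_rng(0)
        for pos in range(len(consensus)):
            alt = rng.choice([c for c in PROTEIN_ALPHABET
                              if c != consensus[pos]])
            mutant = consensus[:pos] + alt + consensus[pos + 1:]
            assert viterbi_score(hmm, mutant).bit_score <= base

    def test_background_emissions_score_nonpositive(self):
        """Uniform emissions equal to background: zero emission log-odds, so
        transition costs leave the total at or below zero."""
        L = 5
        bg = np.full(20, 1 / 20)
        hmm = ProfileHMM("flat", np.tile(bg, (L, 1)), np.tile(bg, (L + 1, 1)),
                         np.tile([0.9, 0.05, 0.05, 0.5, 0.5, 0.5, 0.5],
                                 (L + 1, 1)))
        hit = viterbi_score(hmm, "MKWVTFISLL")
        assert hit.bit_score <= 0

    def test_empty_protein_gives_no_hit(self):
        hmm = hmm_from_consensus("C", "WKD")
        assert viterbi_score(hmm, "") is None

    def test_envelope_within_protein(self):
        hmm = hmm_from_consensus("C", "WKDEHRLMYQ")
        protein = "AAAAA" + "WKDEHRLMYQ" + "AAAAA"
        hit = viterbi_score(hmm, protein)
        assert 0 <= hit.start < hit.end <= len(protein)
        assert protein[hit.start:hit.end].startswith("WKD")


class TestScanProteome:
    def test_infinite_threshold_empties_hit_list(self, family_chain):
        hits = scan_proteome(family_chain["domain_hmms"],
                             family_chain["records"][:10],
                             {"SNF2": math.inf, "HELC": math.inf})
        assert hits == []

    def test_missing_threshold_is_an_error(self, family_chain):
        with pytest.raises(ValueError, match="threshold"):
            scan_proteome(family_chain["domain_hmms"],
                          family_chain["records"][:2], {"SNF2": 60.0})

    def test_lowering_threshold_never_removes_hits(self, family_chain):
        sub = family_chain["records"][:40]
        strict = scan_proteome(family_chain["domain_hmms"], sub,
                               {"SNF2": 80.0, "HELC": 70.0})
        loose = scan_proteome(family_chain["domain_hmms"], sub,
                              {"SNF2": 60.0, "HELC": 50.0})
        assert {(h.protein_id, h.model_name) for h in strict} <= \
            {(h.protein_id, h.model_name) for h in loose}

    def test_planted_domains_recovered_no_background(self, family_chain):
        """Recall/precision 1 on the synthetic truth at calibrated cutoffs."""
        truth = family_chain["truth"]
        label = dict(zip(truth["protein_id"], truth["family_label"]))
        hit_proteins = {h.protein_id for h in family_chain["domain_hits"]}
        planted = {p for p, lab in label.items() if lab != "background"}
        assert hit_proteins == planted


class TestArchitecture:
    def test_both_requires_one_hit_per_domain(self):
        hits = [DomainHit("p1", "SNF2", 70, 0, 50),
                DomainHit("p1", "HELC", 60, 60, 100)]
        assert classify_architecture(hits, ["p1"]) == {"p1": "both"}

    def test_partition_identity(self, family_chain):
        """|SNF2_only| + |both| equals the number of SNF2-hit proteins
        (the arithmetic behind 6 + 35 = 41 and 88 + 35 = 123)."""
        arch = family_chain["architecture"]
        hits = family_chain["domain_hits"]
        snf2_hit = {h.protein_id for h in hits if h.model_name == "SNF2"}
        helc_hit = {h.protein_id for h in hits if h.model_name == "HELC"}
        n = lambda c: sum(1 for v in arch.values() if v == c)
        assert n("SNF2_only") + n("both") == len(snf2_hit)
        assert n("HelC_only") + n("both") == len(helc_hit)
        assert sum(map(n, ("SNF2_only", "HelC_only", "both", "neither"))) \
            == len(arch)

    def test_empty_hits_all_neither(self):
        arch = classify_architecture([], ["a", "b"])
        assert set(arch.values()) == {"neither"}

    def test_unknown_protein_in_hits_rejected(self):
        with pytest.raises(ValueError):
            classify_architecture([DomainHit("ghost", "SNF2", 70, 0, 5)],
                                  ["a"])


class TestHmmer3IO:
    def test_write_read_roundtrip(self, tmp_path):
        rng = np.random.default_rng(3)
        models = [random_profile(rng, 4), hmm_from_consensus("c1", "WKDEH")]
        models[0].name = "toy0"
        path = tmp_path / "models.hmm"
        write_hmmer3(models, path)
        back = read_hmmer3(path)
        assert [m.name for m in back] == ["toy0", "c1"]
        for orig, re in zip(models, back):
            assert re.length == orig.length
            np.testing.assert_allclose(re.match_emissions,
                                       orig.match_emissions, atol=1e-4)
            np.testing.assert_allclose(re.transitions, orig.transitions,
                                       atol=1e-4)

    def test_rejects_non_amino_alphabet(self, tmp_path):
        path = tmp_path / "dna.hmm"
        path.write_text("HMMER3/f\nNAME x\nLENG 1\nALPH DNA\nHMM\n//\n")
        with pytest.raises(ValueError, match="amino"):
            read_hmmer3(path)
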