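"""Shared fixtures: expensive synthetic-data chains built once per session."""

from __future__ import annotations

import dendropy
import numpy as np
import pytest

from clsymine.align import progressive_msa
from clsymine.family import (
    FamilyModelSet,
    build_block_hmm,
    extract_blocks,
    prospect,
    score_columns,
    validate_models,
)
from clsymine.hmm import classify_architecture, hmm_from_consensus, scan_proteome
from clsymine.phylo import DistanceMatrix
from clsymine.structure import parse_gff3
from clsymine.synthetic import (
    HELC_MOTIF,
    SNF2_MOTIF,
    FamilyProteomeConfig,
    GenomeConfig,
    gen_family_proteome,
    gen_genome_with_duplications,
)


@pytest.fixture(scope="session")
def family_chain():
    """Full mining chain on the default synthetic proteome (seed 1):
    scan -> architecture -> train MSA -> blocks -> models -> validate ->
    prospect at rc 1.0 and 0.6."""
    config = FamilyProteomeConfig()
    records, truth = gen_family_proteome(config, seed=1)
    proteome = dict(records)
    hmms = [hmm_from_consensus("SNF2", SNF2_MOTIF),
            hmm_from_consensus("HELC", HELC_MOTIF)]
    hits = scan_proteome(hmms, records, {"SNF2": 60.0, "HELC": 50.0})
    arch = classify_architecture(hits, [pid for pid, _ in records])
    both = sorted(p for p, c in arch.items() if c == "both")
    training = [(p, proteome[p]) for p in both]
    msa = progressive_msa(training)
    scores = score_columns(msa)
    blocks = extract_blocks(scores)
    models = [build_block_hmm(msa, b, name=f"fam_{i}")
              for i, b in enumerate(blocks)]
    model_set = FamilyModelSet(models=models)
    ok, cutoffs = validate_models(model_set, training, records)
    proteomes = {"all": records}
    return {
        "config": config,
        "records": records,
        "proteome": proteome,
        "truth": truth,
        "domain_hmms": hmms,
        "domain_hits": hits,
        "architecture": arch,
        "training": training,
        "msa": msa,
        "scores": scores,
        "blocks": blocks,
        "model_set": model_set,
        "validated": ok,
        "cutoffs": cutoffs,
        "candidates_rc06": prospect(model_set, proteomes, 0.6),
        "candidates_rc10": prospect(model_set, proteomes, 1.0),
    }


@pytest.fixture(scope="session")
def genome_chain(tmp_path_factory):
    """Synthetic annotated genome (seed 42), parsed back from GFF3."""
    gff3, cds, truth = gen_genome_with_duplications(GenomeConfig(), seed=42)
    path = tmp_path_factory.mktemp("genome") / "genome.gff3"
    path.write_text(gff3)
    models = parse_gff3(path)
    return {"gff3": gff3, "gff3_path": path, "cds": dict(cds),
            "truth": truth, "models": models}


@pytest.fixture(scope="session")
def subfamily_msa():
    """Two clearly separated six-member subfamilies, aligned (no decoys)."""
    config = FamilyProteomeConfig(
        subfamilies={"clade1": 6, "clade2": 6}, n_decoys=0, n_background=0)
    records, truth = gen_family_proteome(config, seed=1)
    return {"records": records, "truth": truth,
            "msa": progressive_msa(records)}


def random_additive_matrix(n: int, rng: np.random.Generator):
    """A random binary tree with random branch lengths and its exact
    path-length distance matrix (additive by construction)."""
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    labels = [f"t{i}" for i in range(n)]
    leaves = []
    for label in labels[:3]:
        node = dendropy.Node(taxon=tns.new_taxon(label=label))
        node.edge.length = rng.uniform(0.05, 1.0)
        tree.seed_node.add_child(node)
        leaves.append(node)
    for label in labels[3:]:
        target = leaves[int(rng.integers(len(leaves)))]
        parent = target.parent_node
        mid = dendropy.Node()
        parent.remove_child(target)
        parent.add_child(mid)
        mid.edge.length = target.edge.length * 0.5
        target.edge.length *= 0.5
        mid.add_child(target)
        new = dendropy.Node(taxon=tns.new_taxon(label=label))
        new.edge.length = rng.uniform(0.05, 1.0)
        mid.add_child(new)
        leaves.append(new)
    pdm = tree.phylogenetic_distance_matrix()
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                d[i, j] = pdm.distance(tns.get_taxon(labels[i]),
                                       tns.get_taxon(labels[j]))
    return tree, DistanceMatrix(tuple(labels), d)
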