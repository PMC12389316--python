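"""Stage orchestration: configuration, manifests, and the table replay.

Stages form a declared DAG (synth -> scan -> build -> prospect -> phylo;
synth -> evolution / structure / expression). Each stage writes its outputs
plus a JSON manifest recording the stage name, a config hash, the seed and
the package version, so every number is traceable to (config, seed) and
reruns are byte-identical for deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .align import progressive_msa
from .evolution import (
    classify_duplication,
    classify_selection,
    duplication_date,
    duplication_events,
    find_collinear_blocks,
    positions_from_gene_models,
)
from .family import (
    FamilyModelSet,
    build_block_hmm,
    candidates_to_tsv,
    extract_blocks,
    load_model_set,
    prospect,
    save_model_set,
    score_columns,
    validate_models,
)
from .fixtures import load_table1, load_table2, load_table2_raw
from .hmm import (
    classify_architecture,
    hits_to_tsv,
    hmm_from_consensus,
    read_hmmer3,
    scan_proteome,
)
from .io import read_fasta, write_fasta
from .phylo import assign_clades, bootstrap_support, write_newick
from .structure import parse_gff3, summarize_structures
from .synthetic import (
    DOMAIN_HELC,
    DOMAIN_SNF2,
    FamilyProteomeConfig,
    GenomeConfig,
    HELC_MOTIF,
    QpcrConfig,
    SNF2_MOTIF,
    gen_family_proteome,
    gen_genome_with_duplications,
    gen_qpcr_table,
)
from .expression import relative_expression_table

STAGE_DEPENDENCIES = {
    "synth": [],
    "scan": ["synth"],
    "build": ["scan"],
    "prospect": ["build"],
    "phylo": ["prospect"],
    "evolution": ["synth"],
    "structure": ["synth"],
    "expression": ["synth"],
    "replay": [],
}


@dataclass
class PipelineConfig:
    """All tunables of the pipeline in one place.

    ``rc`` is the reduced-cutoff fraction for prospecting; ``lam`` the
    synonymous substitution rate per site per year used for duplication
    dating; domain thresholds are bit-score cutoffs per domain model.
    """

    seed: int = 1
    rc: float = 0.6
    lam: float = 6.5e-9
    domain_thresholds: dict = field(
        default_factory=lambda: {DOMAIN_SNF2: 60.0, DOMAIN_HELC: 50.0})
    hmm_file: str | None = None  # external HMMER3-subset domain models
    proteome_fasta: str | None = None
    positives_file: str | None = None
    min_block_len: int = 20
    min_mean_score: float = 1.0
    max_gap_fraction: float = 0.3
    min_anchors: int = 3
    max_gap: int = 3
    tandem_max_rank_gap: int = 1
    proximal_window: int = 10
    bootstrap_replicates: int = 100

    def validate(self) -> None:
        if not 0.0 < self.rc <= 1.0:
            raise ValueError("rc must lie in (0, 1]")
        if self.lam <= 0:
            raise ValueError("lambda must be > 0")
        for path in (self.hmm_file, self.proteome_fasta, self.positives_file):
            if path is not None and not Path(path).exists():
                raise ValueError(f"configured path does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _require(outdir: Path, filename: str, stage: str) -> Path:
    path = outdir / filename
    if not path.exists():
        raise FileNotFoundError(
            f"missing {filename}: run prerequisite stage {stage!r} first")
    return path


def _write_manifest(outdir: Path, stage: str, config: PipelineConfig,
                    outputs: list[str]) -> dict:
    manifest = {
        "stage": stage,
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "outputs": sorted(outputs),
    }
    (outdir / f"manifest_{stage}.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2) + "\n")
    return manifest


def run_stage(stage: str, config: PipelineConfig, outdir: str | Path) -> dict:
    """Run one pipeline stage; returns its manifest."""
    if stage not in STAGE_DEPENDENCIES:
        raise ValueError(f"unknown stage {stage!r}")
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    runner = {
        "synth": _stage_synth,
        "scan": _stage_scan,
        "build": _stage_build,
        "prospect": _stage_prospect,
        "phylo": _stage_phylo,
        "evolution": _stage_evolution,
        "structure": _stage_structure,
        "expression": _stage_expression,
        "replay": _stage_replay,
    }[stage]
    outputs = runner(config, outdir)
    return _write_manifest(outdir, stage, config, outputs)


def _stage_synth(config: PipelineConfig, outdir: Path) -> list[str]:
    records, truth = gen_family_proteome(FamilyProteomeConfig(), config.seed)
    write_fasta(records, outdir / "proteome.fasta")
    truth.assign(planted_block_coords=truth["planted_block_coords"].apply(
        json.dumps)).to_csv(outdir / "proteome_truth.tsv", sep="\t",
                            index=False)
    gff3, cds, dup_truth = gen_genome_with_duplications(GenomeConfig(),
                                                        config.seed + 1)
    (outdir / "genome.gff3").write_text(gff3)
    write_fasta(cds, outdir / "cds.fasta")
    dup_truth.to_csv(outdir / "duplication_truth.tsv", sep="\t", index=False)
    gen_qpcr_table(QpcrConfig(), config.seed + 2).to_csv(
        outdir / "qpcr_ct.csv", index=False)
    return ["proteome.fasta", "proteome_truth.tsv", "genome.gff3",
            "cds.fasta", "duplication_truth.tsv", "qpcr_ct.csv"]


def _domain_models(config: PipelineConfig):
    if config.hmm_file:
        return read_hmmer3(config.hmm_file)
    return [hmm_from_consensus(DOMAIN_SNF2, SNF2_MOTIF),
            hmm_from_consensus(DOMAIN_HELC, HELC_MOTIF)]


def _proteome(config: PipelineConfig, outdir: Path):
    if config.proteome_fasta:
        return read_fasta(config.proteome_fasta)
    return read_fasta(_require(outdir, "proteome.fasta", "synth"))


def _stage_scan(config: PipelineConfig, outdir: Path) -> list[str]:
    proteome = _proteome(config, outdir)
    hmms = _domain_models(config)
    hits = scan_proteome(hmms, proteome, config.domain_thresholds)
    hits_to_tsv(hits, outdir / "domain_hits.tsv")
    arch = classify_architecture(hits, [pid for pid, _ in proteome])
    pd.DataFrame(sorted(arch.items()),
                 columns=["protein", "architecture"]).to_csv(
        outdir / "architecture.tsv", sep="\t", index=False)
    return ["domain_hits.tsv", "architecture.tsv"]


def _stage_build(config: PipelineConfig, outdir: Path) -> list[str]:
    proteome = dict(_proteome(config, outdir))
    arch = pd.read_csv(_require(outdir, "architecture.tsv", "scan"), sep="\t")
    both = arch.loc[arch["architecture"] == "both", "protein"].tolist()
    if not both:
        raise ValueError("no two-domain proteins to train on")
    training = [(pid, proteome[pid]) for pid in both]
    msa = progressive_msa(training)
    scores = score_columns(msa)
    blocks = extract_blocks(scores, config.min_block_len,
                            config.min_mean_score, config.max_gap_fraction)
    if not blocks:
        raise ValueError("no conserved blocks found in the training MSA")
    models = [build_block_hmm(msa, b, name=f"fam_{i}")
              for i, b in enumerate(blocks)]
    model_set = FamilyModelSet(models=models)
    if config.positives_file:
        pos_ids = [ln.strip() for ln in
                   Path(config.positives_file).read_text().splitlines()
                   if ln.strip()]
        positives = [(pid, proteome[pid]) for pid in pos_ids]
    else:
        positives = training
    ok, _ = validate_models(model_set, positives, list(proteome.items()))
    if not ok:
        raise ValueError("family models fail to detect all known positives")
    save_model_set(model_set, outdir / "family_models")
    return ["family_models/models.hmm", "family_models/cutoffs.tsv",
            "family_models/training_positives.txt"]


def _stage_prospect(config: PipelineConfig, outdir: Path) -> list[str]:
    _require(outdir, "family_models/models.hmm", "build")
    model_set = load_model_set(outdir / "family_models")
    proteome = _proteome(config, outdir)
    truth_path = outdir / "proteome_truth.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t")
        species_of = dict(zip(truth["protein_id"], truth["species"]))
    else:
        species_of = {}
    by_species: dict[str, list[tuple[str, str]]] = {}
    for pid, seq in proteome:
        by_species.setdefault(species_of.get(pid, "unknown"), []).append(
            (pid, seq))
    candidates = prospect(model_set, by_species, config.rc)
    candidates_to_tsv(candidates, config.rc, outdir / "candidates.tsv")
    return ["candidates.tsv"]


def _stage_phylo(config: PipelineConfig, outdir: Path) -> list[str]:
    cand = pd.read_csv(_require(outdir, "candidates.tsv", "prospect"),
                       sep="\t")
    passing = cand.loc[cand["pass"] == 1, "protein"].tolist()
    if len(passing) < 3:
        raise ValueError("fewer than 3 passing candidates; no tree to build")
    proteome = dict(_proteome(config, outdir))
    msa = progressive_msa([(pid, proteome[pid]) for pid in passing])
    tree = bootstrap_support(msa, config.bootstrap_replicates, config.seed)
    write_newick(tree, outdir / "candidates.nwk")
    # anchors: the first training positive of each subfamily when the
    # synthetic truth table is available
    truth_path = outdir / "proteome_truth.tsv"
    outputs = ["candidates.nwk"]
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t")
        fam = truth[truth["family_label"].str.startswith("clade")]
        anchors = {}
        for label, sub in fam.groupby("family_label"):
            for pid in sub["protein_id"]:
                if pid in passing:
                    anchors[pid] = label
                    break
        if len(anchors) >= 2:
            clades = assign_clades(tree, anchors)
            pd.DataFrame(sorted(clades.items()),
                         columns=["protein", "clade"]).to_csv(
                outdir / "clades.tsv", sep="\t", index=False)
            outputs.append("clades.tsv")
    return outputs


def _stage_evolution(config: PipelineConfig, outdir: Path) -> list[str]:
    gff3 = _require(outdir, "genome.gff3", "synth")
    cds = dict(read_fasta(_require(outdir, "cds.fasta", "synth")))
    truth = pd.read_csv(_require(outdir, "duplication_truth.tsv", "synth"),
                        sep="\t")
    models = parse_gff3(gff3)
    positions = positions_from_gene_models(models)
    pairs = list(zip(truth["gene_a"], truth["gene_b"]))
    blocks = find_collinear_blocks(positions, pairs, config.min_anchors,
                                   config.max_gap)
    pd.DataFrame([{"a_chrom": b.a_chrom, "b_chrom": b.b_chrom,
                   "n_anchors": len(b.anchors), "score": b.score}
                  for b in blocks]).to_csv(outdir / "collinear_blocks.tsv",
                                           sep="\t", index=False)
    events = duplication_events(pairs, cds, positions, blocks, config.lam,
                                config.tandem_max_rank_gap,
                                config.proximal_window)
    events.to_csv(outdir / "kaks.tsv", sep="\t", index=False)
    return ["collinear_blocks.tsv", "kaks.tsv"]


def _stage_structure(config: PipelineConfig, outdir: Path) -> list[str]:
    models = parse_gff3(_require(outdir, "genome.gff3", "synth"))
    clade_map = {m.gene_id: "all" for m in models}
    summary = summarize_structures(models, clade_map)
    rows = [{"clade": name, **dataclasses.asdict(s)}
            for name, s in sorted(summary.per_clade.items())]
    rows.append({"clade": "overall", **dataclasses.asdict(summary.overall)})
    pd.DataFrame(rows).to_csv(outdir / "structure_summary.tsv", sep="\t",
                              index=False)
    return ["structure_summary.tsv"]


def _stage_expression(config: PipelineConfig, outdir: Path) -> list[str]:
    ct = pd.read_csv(_require(outdir, "qpcr_ct.csv", "synth"))
    qc = QpcrConfig()
    table = relative_expression_table(ct, sorted(qc.fold_changes),
                                      qc.reference_gene)
    table.to_csv(outdir / "relative_expression.tsv", sep="\t", index=False)
    return ["relative_expression.tsv"]


def _stage_replay(config: PipelineConfig, outdir: Path) -> list[str]:
    report = replay_paper_tables(lam=config.lam)
    (outdir / "replay_report.json").write_text(
        json.dumps(report, sort_keys=True, indent=2) + "\n")
    return ["replay_report.json"]


# ---------------------------------------------------------------------------
# fixture replay
# ---------------------------------------------------------------------------

DATE_TOLERANCE = 0.005   # the printed dates carry 2 decimals
RATIO_TOLERANCE = 5e-4   # the printed ratios carry ~4-6 significant digits


def replay_paper_tables(lam: float = 6.5e-9) -> dict:
    """Recompute every derivable cell of the packaged tables.

    Dates are recomputed from the printed Ks via T = Ks/(2 lambda) x 1e-6;
    ratios from printed Ka and Ks; selection labels from the ratios; the
    structural range/mode statistics from the 56-row characteristics table.
    Returns a per-check report with pass flags.
    """
    t2 = load_table2()
    raw = load_table2_raw()
    checks = []
    for (_, row), kaks_str in zip(t2.iterrows(), raw["kaks"]):
        # never compare tighter than the printed precision of the cell
        # (one ratio is printed at 3 decimals, truncated)
        decimals = len(kaks_str.split(".")[1]) if "." in kaks_str else 0
        ratio_tol = max(RATIO_TOLERANCE, 10.0 ** -decimals)
        date = duplication_date(row["ks"], lam)
        checks.append({
            "check": f"date:{row['gene_a']}/{row['gene_b']}",
            "computed": round(date, 4), "printed": row["date_mya"],
            "pass": bool(abs(date - row["date_mya"]) <= DATE_TOLERANCE),
        })
        ratio = row["ka"] / row["ks"]
        checks.append({
            "check": f"ratio:{row['gene_a']}/{row['gene_b']}",
            "computed": round(ratio, 6), "printed": row["kaks"],
            "pass": bool(abs(ratio - row["kaks"]) <= ratio_tol),
        })
        checks.append({
            "check": f"selection:{row['gene_a']}/{row['gene_b']}",
            "computed": classify_selection(ratio), "printed": row["selection"],
            "pass": classify_selection(ratio) == "purifying",
        })
    summary = summarize_structures(load_table1())
    expectations = [
        ("gene_length_min", summary.overall.gene_length_min, 1938),
        ("gene_length_max", summary.overall.gene_length_max, 15347),
        ("exon_count_max", summary.overall.exon_count_max, 12),
        ("exon_count_min", summary.overall.exon_count_min, 1),
        ("protein_length_max", summary.overall.protein_length_max, 1875),
        ("protein_length_min", summary.overall.protein_length_min, 405),
        ("clade1_exon_mode", summary.per_clade["1"].exon_count_mode, 5),
        ("clade1_exon_mode_freq", summary.per_clade["1"].exon_mode_frequency,
         12),
        ("clade1_n", summary.per_clade["1"].n_genes, 13),
        ("clade2_exon_mode", summary.per_clade["2"].exon_count_mode, 3),
        ("clade2_exon_mode_freq", summary.per_clade["2"].exon_mode_frequency,
         18),
        ("clade2_n", summary.per_clade["2"].n_genes, 22),
        ("clade3_n", summary.per_clade["3"].n_genes, 20),
        ("extra_domain_proteins",
         sum(summary.overall.other_domain_counts.values()), 3),
    ]
    for name, computed, expected in expectations:
        checks.append({"check": f"table1:{name}", "computed": computed,
                       "printed": expected, "pass": computed == expected})
    n_pass = sum(1 for c in checks if c["pass"])
    return {"checks": checks, "n_checks": len(checks), "n_pass": n_pass,
            "all_pass": n_pass == len(checks)}
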