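"""Gene models from GFF3 and Table-1-style structural summaries.

GFF3 coordinates are 1-based inclusive on disk (the GFF3 convention) and
kept that way on the GeneModel; exon lists are ordered in transcription
order (reverse genomic order on the minus strand). The representative
transcript of a gene is the mRNA with the longest total CDS. "Gene length"
is the span of the gene feature, introns and UTRs included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .hmm import DomainHit


@dataclass
class GeneModel:
    gene_id: str
    chromosome: str
    strand: str
    gene_start: int
    gene_end: int
    exons: list[tuple[int, int]]  # 1-based inclusive, transcription order
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    cds_length: int = 0

    @property
    def start(self) -> int:
        return self.gene_start

    @property
    def end(self) -> int:
        return self.gene_end

    @property
    def gene_length_bp(self) -> int:
        return self.gene_end - self.gene_start + 1

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def protein_length_aa(self) -> int:
        return self.cds_length // 3


def _attributes(field9: str) -> dict[str, str]:
    out = {}
    for part in field9.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def parse_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features into GeneModels.

    One representative mRNA per gene (longest total CDS). Orphan exons and
    mRNAs raise with the offending line number; a gene feature is required
    for every mRNA parent.
    """
    genes: dict[str, dict] = {}
    mrnas: dict[str, dict] = {}
    order: list[str] = []
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"line {lineno}: expected 9 GFF3 columns")
        chrom, _, ftype, start, end, _, strand, _, attrs = cols
        start, end = int(start), int(end)
        a = _attributes(attrs)
        if ftype == "gene":
            gid = a.get("ID")
            if gid is None:
                raise ValueError(f"line {lineno}: gene feature without ID")
            genes[gid] = {"chrom": chrom, "strand": strand,
                          "start": start, "end": end}
            order.append(gid)
        elif ftype == "mRNA":
            mid, parent = a.get("ID"), a.get("Parent")
            if mid is None or parent is None:
                raise ValueError(f"line {lineno}: mRNA without ID/Parent")
            mrnas[mid] = {"gene": parent, "line": lineno, "exons": [],
                          "cds": [], "utr5": [], "utr3": []}
        elif ftype in ("exon", "CDS", "five_prime_UTR", "three_prime_UTR"):
            parent = a.get("Parent")
            if parent is None or parent not in mrnas:
                raise ValueError(
                    f"line {lineno}: {ftype} with no known parent mRNA")
            key = {"exon": "exons", "CDS": "cds",
                   "five_prime_UTR": "utr5", "three_prime_UTR": "utr3"}[ftype]
            mrnas[parent][key].append((start, end))
    for mid, m in mrnas.items():
        if m["gene"] not in genes:
            raise ValueError(
                f"line {m['line']}: mRNA parent {m['gene']!r} has no "
                f"gene feature")
    models = []
    for gid in order:
        g = genes[gid]
        candidates = [(mid, m) for mid, m in mrnas.items() if m["gene"] == gid]
        if not candidates:
            continue
        mid, m = max(candidates,
                     key=lambda t: sum(e - s + 1 for s, e in t[1]["cds"]))
        exons = sorted(m["exons"])
        if g["strand"] == "-":
            exons = exons[::-1]  # transcription order
        models.append(GeneModel(
            gene_id=gid, chromosome=g["chrom"], strand=g["strand"],
            gene_start=g["start"], gene_end=g["end"], exons=exons,
            utr5=sorted(m["utr5"]), utr3=sorted(m["utr3"]),
            cds_length=sum(e - s + 1 for s, e in m["cds"])))
    return models


def write_gff3(models: list[GeneModel], path: str | Path,
               source: str = "clsymine") -> None:
    """Write models back to GFF3 (exons doubling as CDS features)."""
    lines = ["##gff-version 3"]
    for m in models:
        base = [m.chromosome, source]
        lines.append("\t".join([*base, "gene", str(m.gene_start),
                                str(m.gene_end), ".", m.strand, ".",
                                f"ID={m.gene_id}"]))
        mid = f"{m.gene_id}.1"
        lines.append("\t".join([*base, "mRNA", str(m.gene_start),
                                str(m.gene_end), ".", m.strand, ".",
                                f"ID={mid};Parent={m.gene_id}"]))
        for s, e in sorted(m.exons):
            lines.append("\t".join([*base, "exon", str(s), str(e), ".",
                                    m.strand, ".", f"Parent={mid}"]))
            lines.append("\t".join([*base, "CDS", str(s), str(e), ".",
                                    m.strand, "0", f"Parent={mid}"]))
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class CladeSummary:
    n_genes: int
    exon_count_mode: int
    exon_mode_frequency: int
    exon_count_min: int
    exon_count_max: int
    gene_length_min: int
    gene_length_max: int
    protein_length_min: int
    protein_length_max: int
    other_domain_counts: dict


@dataclass(frozen=True)
class StructureSummary:
    per_clade: dict[str, CladeSummary]
    overall: CladeSummary


def _summarize(df: pd.DataFrame) -> CladeSummary:
    mode = df["exon_count"].mode().min()
    domains = df.loc[df["other_domains"] != "0", "other_domains"]
    return CladeSummary(
        n_genes=len(df),
        exon_count_mode=int(mode),
        exon_mode_frequency=int((df["exon_count"] == mode).sum()),
        exon_count_min=int(df["exon_count"].min()),
        exon_count_max=int(df["exon_count"].max()),
        gene_length_min=int(df["gene_length_bp"].min()),
        gene_length_max=int(df["gene_length_bp"].max()),
        protein_length_min=int(df["protein_length_aa"].min()),
        protein_length_max=int(df["protein_length_aa"].max()),
        other_domain_counts={k: int(v)
                             for k, v in domains.value_counts().items()},
    )


def summarize_structures(
    data: list[GeneModel] | pd.DataFrame,
    clade_map: dict[str, str] | None = None,
) -> StructureSummary:
    """Clade-level structural statistics (min/max/mode), from GeneModels or
    a pre-tabulated characteristics table with a clade column."""
    if isinstance(data, pd.DataFrame):
        df = data.copy()
        if clade_map is not None:
            df["clade"] = df["gene_id"].map(clade_map)
    else:
        if not data:
            raise ValueError("no gene models")
        if clade_map is None:
            raise ValueError("clade_map required for GeneModel input")
        df = pd.DataFrame([{
            "gene_id": m.gene_id,
            "gene_length_bp": m.gene_length_bp,
            "exon_count": m.exon_count,
            "protein_length_aa": m.protein_length_aa,
            "other_domains": "0",
            "clade": clade_map[m.gene_id],
        } for m in data])
    if df.empty:
        raise ValueError("empty input")
    if df["clade"].isna().any():
        missing = df.loc[df["clade"].isna(), "gene_id"].tolist()
        raise ValueError(f"genes without clade assignment: {missing}")
    per_clade = {str(c): _summarize(sub) for c, sub in df.groupby("clade")}
    return StructureSummary(per_clade=per_clade, overall=_summarize(df))


def domain_architecture_table(
    hits: list[DomainHit],
) -> dict[str, list[tuple[str, int, int]]]:
    """Per-protein ordered domain list; overlapping same-model hits merged."""
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    out: dict[str, list[tuple[str, int, int]]] = {}
    for pid, phits in by_protein.items():
        merged: list[tuple[str, int, int]] = []
        for h in sorted(phits, key=lambda h: (h.model_name, h.start)):
            if merged and merged[-1][0] == h.model_name \
                    and h.start < merged[-1][2]:
                prev = merged.pop()
                merged.append((prev[0], prev[1], max(prev[2], h.end)))
            else:
                merged.append((h.model_name, h.start, h.end))
        out[pid] = sorted(merged, key=lambda d: d[1])
    return out
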