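"""Packaged reference tables for the 56-member CLSY/DRD1 survey.

Two machine-readable tables ship with the package:

* gene/protein structural characteristics of the 56 family members recovered
  across 12 plant proteomes (gene length, exon count, protein length, extra
  domains, chromosome, clade), and
* the ten soybean paralog pairs with their NG86 Ka, Ks, Ka/Ks, duplication
  date (Mya) and duplication type.

Integer fields may carry thousands separators exactly as printed; the loaders
strip them. Decimal points only (locale-independent).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

TABLE1_RESOURCE = "table1_gene_characteristics.tsv"
TABLE2_RESOURCE = "table2_paralog_pairs.tsv"

#: Expected clade composition of the 56-member table: clades 1/2/3 + 1 outlier.
TABLE1_CLADE_COUNTS = {"1": 13, "2": 22, "3": 20, "outlier": 1}


def _read(resource: str) -> pd.DataFrame:
    with resources.files("clsymine.data").joinpath(resource).open("r") as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def load_table1() -> pd.DataFrame:
    """The 56-row gene-characteristics table, numeric columns parsed."""
    df = _read(TABLE1_RESOURCE)
    for col in ("gene_length_bp", "exon_count", "protein_length_aa"):
        df[col] = df[col].str.replace(",", "", regex=False).astype(int)
    return df


def load_table2_raw() -> pd.DataFrame:
    """The paralog-pair table with every cell as its exact printed string."""
    return _read(TABLE2_RESOURCE)


def load_table2() -> pd.DataFrame:
    """The 10-row soybean paralog-pair table, numeric columns parsed."""
    df = _read(TABLE2_RESOURCE)
    for col in ("ka", "ks", "kaks", "date_mya"):
        df[col] = df[col].astype(float)
    return df
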