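"""Readers and writers for the shared tabular formats.

Everything is tab-delimited UTF-8 with a header row and ``NA`` for
missing values, matching the cohort's printed tables:

* expression TSV - first column ``gene_id``, one column per sample (TPM);
* clinical TSV - ``sample_id, phenotype, time, event, response``;
* variant TSV - ``sample_id, gene, dna_variant, dna_vaf, rna_variant, rna_vaf``;
* single-cell long TSV - ``cell_id, sample_id, gene_id, value``;
* score TSV - ``sample_id, U, D, score, label``.

The package ships two faithful transcriptions of the cohort's printed
tables (``table1``: 26 patients; ``table2``: per-sample DNA/RNA variant
pairs) plus the default eight-gene signature JSON.
"""

from __future__ import annotations

from importlib import resources
from io import StringIO
from pathlib import Path

import pandas as pd
import yaml

from .simulate import SimulationConfig

NA = "NA"

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_clinical_tsv",
    "write_clinical_tsv",
    "read_variant_tsv",
    "write_variant_tsv",
    "read_score_tsv",
    "write_score_tsv",
    "read_single_cell_tsv",
    "write_single_cell_tsv",
    "load_table1",
    "load_table2",
    "load_config_yaml",
    "save_config_yaml",
]


def read_expression_tsv(path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", index_col="gene_id", na_values=[NA])
    if m.shape[1] == 0 or m.shape[0] == 0:
        raise ValueError(f"empty expression matrix: {path}")
    return m


def write_expression_tsv(m: pd.DataFrame, path) -> None:
    out = m.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", na_rep=NA, float_format="%.6g")


def read_clinical_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA])
    if "sample_id" not in df.columns:
        raise ValueError(f"clinical table needs a sample_id column: {path}")
    return df.set_index("sample_id")


def write_clinical_tsv(df: pd.DataFrame, path) -> None:
    df.reset_index().to_csv(path, sep="\t", index=False, na_rep=NA, float_format="%.6g")


def read_variant_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", na_values=[NA], keep_default_na=True, dtype={"sample_id": str}
    )
    required = {"sample_id", "gene", "dna_variant", "dna_vaf", "rna_variant", "rna_vaf"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns {sorted(missing)}: {path}")
    return df


def write_variant_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=NA, float_format="%g")


def read_score_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA]).set_index("sample_id")


def write_score_tsv(scores: pd.DataFrame, path) -> None:
    scores.reset_index().to_csv(path, sep="\t", index=False, na_rep=NA, float_format="%.6g")


def write_single_cell_tsv(cells: pd.DataFrame, cell_map: pd.Series, path) -> None:
    long = cells.stack().rename("value").reset_index()
    long.columns = ["cell_id", "gene_id", "value"]
    long.insert(1, "sample_id", cell_map.reindex(long["cell_id"]).to_numpy())
    long.to_csv(path, sep="\t", index=False, na_rep=NA, float_format="%.6g")


def read_single_cell_tsv(path) -> tuple[pd.DataFrame, pd.Series]:
    long = pd.read_csv(path, sep="\t", na_values=[NA])
    cells = long.pivot(index="cell_id", columns="gene_id", values="value").fillna(0.0)
    cell_map = (
        long.drop_duplicates("cell_id").set_index("cell_id")["sample_id"].reindex(cells.index)
    )
    return cells, cell_map


def _packaged(name: str) -> StringIO:
    return StringIO(resources.files("dormsig.data").joinpath(name).read_text())


def load_table1() -> pd.DataFrame:
    """The transcribed 26-patient cohort description table."""
    return pd.read_csv(_packaged("table1.tsv"), sep="\t", na_values=[NA], dtype=str)


def load_table2() -> pd.DataFrame:
    """The transcribed per-sample DNA/RNA mutational-status table."""
    return read_variant_tsv(_packaged("table2.tsv"))


def load_config_yaml(path) -> SimulationConfig:
    with open(path, encoding="utf-8") as fh:
        d = yaml.safe_load(fh) or {}
    return SimulationConfig.from_dict(d)


def save_config_yaml(config: SimulationConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False), encoding="utf-8")
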