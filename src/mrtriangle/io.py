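"""Readers and writers for the flat-file formats used across the pipeline.

GWAS summary statistics are exchanged as tab-separated text in a
GWAS-SSF-style dialect (one row per variant, columns listed in
:data:`GWAS_FILE_COLUMNS`).  In memory the same table uses shorter column
names (``eaf``, ``se``) which are the names the rest of the package operates
on.  The LD matrix travels as a square whitespace-delimited file whose first
line is a header of variant identifiers; in memory it is a square
:class:`pandas.DataFrame` indexed by variant id on both axes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: in-memory column name -> column name used in summary-statistic files
GWAS_FILE_COLUMNS = {
    "variant_id": "variant_id",
    "chromosome": "chromosome",
    "position": "position",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "effect_allele_frequency",
    "beta": "beta",
    "se": "standard_error",
    "p_value": "p_value",
    "n": "n",
}

GWAS_COLUMNS = list(GWAS_FILE_COLUMNS)

GENE_COLUMNS = ["gene_id", "chromosome", "start", "end", "encoded_protein"]


class FormatError(ValueError):
    """A table does not conform to the expected schema."""


def validate_gwas(table: pd.DataFrame) -> pd.DataFrame:
    """Check a summary-statistic frame against the schema invariants.

    Requires all columns of :data:`GWAS_COLUMNS`, standard errors > 0,
    allele frequencies in [0, 1] and p-values in (0, 1].  Returns the frame
    (with ``chromosome`` coerced to string) so calls can be chained.
    """
    missing = [c for c in GWAS_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"summary statistics missing columns: {missing}")
    table = table.assign(chromosome=table["chromosome"].astype(str))
    if (table["se"] <= 0).any():
        raise FormatError("standard errors must be strictly positive")
    if ((table["eaf"] < 0) | (table["eaf"] > 1)).any():
        raise FormatError("allele frequencies must lie in [0, 1]")
    if ((table["p_value"] <= 0) | (table["p_value"] > 1)).any():
        raise FormatError("p-values must lie in (0, 1]")
    return table


def read_gwas(path) -> pd.DataFrame:
    """Read a GWAS summary-statistic TSV into the in-memory schema."""
    raw = pd.read_table(path, dtype={"chromosome": str})
    rename = {v: k for k, v in GWAS_FILE_COLUMNS.items()}
    table = raw.rename(columns=rename)
    return validate_gwas(table[GWAS_COLUMNS])


def write_gwas(table: pd.DataFrame, path) -> None:
    """Write a summary-statistic frame in the file dialect."""
    out = validate_gwas(table[GWAS_COLUMNS].copy()).rename(columns=GWAS_FILE_COLUMNS)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_ld(path) -> pd.DataFrame:
    """Read an LD matrix file (header of variant ids, then a square matrix)."""
    with open(path) as fh:
        ids = fh.readline().split()
        values = np.loadtxt(fh, ndmin=2)
    if values.shape != (len(ids), len(ids)):
        raise FormatError(
            f"LD matrix shape {values.shape} does not match {len(ids)} header ids"
        )
    return pd.DataFrame(values, index=ids, columns=ids)


def write_ld(ld: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, ld.columns)) + "\n")
        np.savetxt(fh, ld.to_numpy(), fmt="%.10g", delimiter="\t")


def read_gene_annotation(path) -> pd.DataFrame:
    """Read gene loci (1-based, closed intervals) as a TSV."""
    table = pd.read_table(path, dtype={"chromosome": str})
    missing = [c for c in GENE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"gene annotation missing columns: {missing}")
    if (table["start"] > table["end"]).any():
        raise FormatError("gene start must not exceed end")
    return table[GENE_COLUMNS]


def write_table(table: pd.DataFrame, path) -> None:
    """Write any tidy annotation/result table as TSV with stable formatting."""
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
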