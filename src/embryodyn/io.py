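"""Tab-delimited readers and writers shared by every stage of the pipeline.

All tables are UTF-8 TSV with a header row. Missing gene names are written
as ``"."`` (the annotation convention for genes without an assigned symbol)
and read back as missing values. Floats are written with ``%.6g`` so that
repeated runs of the same seeded pipeline produce byte-identical files.
"""

from __future__ import annotations

import pandas as pd

FLOAT_FORMAT = "%.6g"
MISSING_NAME = "."

SHEET_COLUMNS = ["sample_id", "group", "stage", "replicate", "lineage"]


def read_counts(path) -> pd.DataFrame:
    """Read a gene × sample count matrix (first column ``gene_id``)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if (counts.values < 0).any():
        raise ValueError(f"negative counts in {path}")
    return counts.astype("int64")


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_annotation(path) -> pd.DataFrame:
    """Read gene annotation: gene_id, gene_name (``.`` = missing), length_bp."""
    ann = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING_NAME],
                      keep_default_na=False, dtype={"length_bp": "int64"})
    return ann


def write_annotation(annotation: pd.DataFrame, path) -> None:
    out = annotation.copy()
    if "gene_name" in out:
        out["gene_name"] = out["gene_name"].fillna(MISSING_NAME)
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"replicate": "int64"},
                        keep_default_na=False)
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet {path} lacks columns {missing}")
    return sheet[SHEET_COLUMNS]


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet[SHEET_COLUMNS].to_csv(path, sep="\t", index=False)


def read_matrix(path) -> pd.DataFrame:
    """Read any gene × sample real-valued matrix (FPKM, true FPKM, ...)."""
    return pd.read_csv(path, sep="\t", index_col=0).astype(float)


def write_matrix(matrix: pd.DataFrame, path, index_label: str = "gene_id") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label,
                  float_format=FLOAT_FORMAT)


def write_table(table: pd.DataFrame, path, index: bool = False) -> None:
    table.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets in GMT format: name <tab> description <tab> members..."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line in {path}: {line!r}")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "") -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name, members in sets.items():
            handle.write("\t".join([name, description, *members]) + "\n")
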