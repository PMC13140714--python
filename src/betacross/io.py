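"""Readers and writers for the pipeline's plain-text table formats.

Conventions:

* beta / M-value matrices: TSV, first column ``probe_id``, remaining
  columns sample ids; missing entries are empty fields (NaN in memory).
* sample sheet: CSV with columns ``sample_id``, ``group``
  (Control / Periodontitis), ``dataset_id``.
* probe manifest: TSV with the Illumina 450K column vocabulary
  (IlmnID, CHR, MAPINFO, UCSC_RefGene_Name, UCSC_RefGene_Group,
  Relation_to_Island, RefSeq_ID); multi-valued fields are
  semicolon-delimited.
* gene sets: standard GMT (term, description, tab-separated members).

All tables round-trip bit-identically through write/read.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

MANIFEST_COLUMNS = [
    "IlmnID",
    "CHR",
    "MAPINFO",
    "UCSC_RefGene_Name",
    "UCSC_RefGene_Group",
    "Relation_to_Island",
    "RefSeq_ID",
]

GROUP_CONTROL = "Control"
GROUP_CASE = "Periodontitis"


# ---------------------------------------------------------------- matrices

def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a probe-by-sample matrix (beta or M) as TSV."""
    out = matrix.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", na_rep="")


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    df.columns = df.columns.astype(str)
    return df


# ------------------------------------------------------------ sample sheet

def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet[["sample_id", "group", "dataset_id"]].to_csv(path, index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, dtype={"sample_id": str, "group": str, "dataset_id": str})
    return sheet


# ---------------------------------------------------------------- manifest

def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    manifest["MAPINFO"] = manifest["MAPINFO"].astype(int)
    return manifest


def split_multi(value: str | float) -> list[str]:
    """Split a semicolon-delimited manifest field into a list (blank -> [])."""
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return []
    return str(value).split(";")


# ------------------------------------------------------------ ground truth

def write_ground_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"probe_id": str, "planted_class": str})


# --------------------------------------------------------------- DMP table

DMP_COLUMNS = ["probe_id", "logFC", "t", "P.Value", "adj.P.Val", "B"]


def write_dmp_table(dmps: pd.DataFrame, path: str | Path) -> None:
    dmps[DMP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_dmp_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"probe_id": str})


# --------------------------------------------------------------------- GMT

def write_gmt(sets: dict[str, tuple[str, list[str]]], path: str | Path) -> None:
    """Write gene sets as GMT; ``sets`` maps term id -> (description, members)."""
    with open(path, "w") as fh:
        for term, (desc, genes) in sets.items():
            fh.write("\t".join([term, desc, *genes]) + "\n")


def load_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line (need term, description, >=1 gene): {line!r}")
            sets[fields[0]] = (fields[1], fields[2:])
    return sets
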