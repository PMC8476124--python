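"""Readers/writers for the pipeline's tabular interchange formats (TSV/JSON)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .errors import InputError


def read_counts(path: str | Path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index.name = "gene_id"
    if counts.shape[1] < 2:
        raise InputError("count matrix needs at least two sample columns")
    return counts


def read_conditions(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "condition"}.issubset(df.columns):
        raise InputError("condition file needs columns: sample, condition")
    cond = df.set_index("sample")["condition"]
    cond.index.name = "sample"
    return cond


def read_families(path: str | Path) -> pd.DataFrame:
    fam = pd.read_csv(path, sep="\t")
    if not {"family_id", "member_mirna"}.issubset(fam.columns):
        raise InputError("family table needs columns: family_id, member_mirna")
    return fam


def read_targets(path: str | Path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t")
    if not {"family_id", "gene_id"}.issubset(df.columns):
        raise InputError("target table needs columns: family_id, gene_id")
    return {
        fam: sorted(set(grp["gene_id"]))
        for fam, grp in df.groupby("family_id", sort=True)
    }


def read_abundance(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"family_id", "abundance_log10"}.issubset(df.columns):
        raise InputError("abundance table needs columns: family_id, abundance_log10")
    return df.set_index("family_id")["abundance_log10"]


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")
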