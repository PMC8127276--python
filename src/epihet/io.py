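"""Readers and writers for the plain-text formats the pipeline exchanges.

BED is 0-based half-open, tab separated, with columns chrom/start/end/name
(optionally a 5th score column).  Matrices are TSV with a header row of
sample IDs and the feature ID in the first column.  Gene sets use GMT.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .intervals import sort_intervals, validate_intervals


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    names = ["chrom", "start", "end", "peak_id", "score"]
    df = df.iloc[:, : len(names)]
    df.columns = names[: df.shape[1]]
    if "peak_id" not in df.columns:
        df["peak_id"] = [f"iv_{i}" for i in range(len(df))]
    return validate_intervals(df)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    validate_intervals(df)
    cols = ["chrom", "start", "end"]
    for extra in ("peak_id", "score"):
        if extra in df.columns:
            cols.append(extra)
    sort_intervals(df)[cols].to_csv(path, sep="\t", header=False, index=False)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Feature-by-sample TSV matrix; first column holds feature IDs."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "feature_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str} )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, list[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, "epihet"] + list(genes)) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")
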