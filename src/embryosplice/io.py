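"""Readers and writers for the plain-text formats used across the pipeline.

Matrices are TSV with the feature id in the first column and one column
per sample.  Gene sets use GMT (name, description, members, tab
separated).  Interval tracks use BED6 with 0-based half-open coordinates.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "write_gmt",
    "read_bed",
    "write_bed",
    "read_sample_meta",
]


def read_matrix(path) -> pd.DataFrame:
    """Read a feature x sample TSV matrix (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids in {path}: {dups[:5]}")
    return df


def write_matrix(df: pd.DataFrame, path, index_label: str = "feature") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file into {set name -> member set}."""
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs >=3 fields")
        name = fields[0]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = {g for g in fields[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sets:
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def read_bed(path) -> pd.DataFrame:
    """Read BED (>=4 columns) into columns chrom/start/end/name[/score/strand]."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    if (df["start"] < 0).any():
        raise ValueError(f"negative coordinates in {path}")
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"empty or inverted interval in {path}")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_sample_meta(path) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id, cohort, timepoint/stage...)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: expected a 'sample_id' column")
    return df.set_index("sample_id")
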