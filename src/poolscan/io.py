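"""Tabular readers and writers for the pipeline's TSV interchange formats."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

DEPTH_COLUMNS = ["marker_id", "chrom", "pos", "Maa", "Mab", "Paa", "Pab"]
INDEL_COLUMNS = ["indel_id", "linked_marker_id", "chrom", "pos", "Maa", "Mab", "Paa", "Pab"]


def read_depth_table(path: str | Path) -> pd.DataFrame:
    """Pooled depth table: marker_id, chrom, pos (1-based), four channel depths."""
    df = pd.read_csv(path, sep="\t")
    missing = set(DEPTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"depth table {path} missing columns: {sorted(missing)}")
    return df


def write_depth_table(df: pd.DataFrame, path: str | Path) -> None:
    df[DEPTH_COLUMNS].to_csv(path, sep="\t", index=False)


def read_indel_counts(path: str | Path) -> pd.DataFrame:
    """Indel genotype-count table (individuals per pool per channel)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(INDEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"indel table {path} missing columns: {sorted(missing)}")
    return df


def write_indel_counts(df: pd.DataFrame, path: str | Path) -> None:
    df[INDEL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_long_expression(path: str | Path) -> pd.DataFrame:
    """Long-format expression: gene_id, label, value."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "label", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"expression table {path} missing columns: {sorted(missing)}")
    return df


def read_two_column(path: str | Path, key: str, value: str) -> pd.Series:
    """A keyed value table (e.g. strain->CSW or day->volume) as a Series."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index(key)[value]


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column chromosome length table (name, bp)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], comment="#")
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_linked_bed(scan_table: pd.DataFrame, path: str | Path) -> None:
    """Linked markers as BED6 (1-based inclusive -> 0-based half-open)."""
    linked = scan_table.loc[scan_table["linked"]]
    bed = pd.DataFrame(
        {
            "chrom": linked["chrom"],
            "start": linked["pos"] - 1,
            "end": linked["pos"],
            "name": linked["marker_id"],
            "score": 0,
            "strand": ".",
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)
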