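"""Small text-format helpers shared by the CLI and tests."""

from __future__ import annotations

import os

import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """BED3/BED6 into a frame with standard column names."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED_COLUMNS[: df.shape[1]]
    if "strand" not in df:
        df["strand"] = "+"
    if "name" not in df:
        df["name"] = [f"region{i}" for i in range(len(df))]
    return df


def bed_to_points(bed: pd.DataFrame, use: str = "start") -> pd.DataFrame:
    """Point features (TSS / motif centers) from BED intervals.

    ``use='start'`` takes the strand-aware 5' end; ``use='midpoint'``
    the interval center.
    """
    out = bed.copy()
    if use == "start":
        out["pos"] = out["start"].where(out["strand"] != "-", out["end"] - 1)
    elif use == "midpoint":
        out["pos"] = (out["start"] + out["end"]) // 2
    else:
        raise ValueError("use must be 'start' or 'midpoint'")
    return out[["name", "chrom", "pos", "strand"]]


def read_whitelist(path: str | os.PathLike) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_whitelist(entries, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(entries) + "\n")


def read_calls(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_calls(calls: pd.DataFrame, path: str | os.PathLike) -> None:
    calls.to_csv(path, sep="\t", index=False)
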