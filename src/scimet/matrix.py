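"""Cells x genomic-window methylation matrices.

The windowed methylome is the clustering substrate: CH methylation in
250 kbp tiles (neuronal subtyping) or CG methylation in 50 kbp tiles
(the context available outside brain).  A window's value for a cell is
the methylated fraction of its calls there; the paired site-count
matrix drives the two-pass coverage filter, which judges cells against
ALL windows first and then windows against the RETAINED cells only —
the order matters and is part of the contract.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

# two-pass filter defaults per context: (min_sites, cell_frac, window_frac)
FILTER_DEFAULTS = {"CH": (20, 0.75, 0.75), "CG": (5, 0.25, 0.50)}
DEFAULT_WINDOW_SIZE = {"CH": 250_000, "CG": 50_000}


@dataclass(frozen=True)
class WindowSet:
    """Non-overlapping windows tiling each chromosome exactly."""

    windows: pd.DataFrame  # chrom, start, end (0-based half-open)
    window_size: int
    context: str

    def __post_init__(self) -> None:
        if self.context not in ("CG", "CH"):
            raise ValueError("context must be CG or CH")

    def __len__(self) -> int:
        return len(self.windows)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, WindowSet)
            and self.window_size == other.window_size
            and self.context == other.context
            and self.windows.reset_index(drop=True).equals(
                other.windows.reset_index(drop=True)
            )
        )

    def chrom_offsets(self) -> dict[str, int]:
        """First window index of each chromosome."""
        offsets = {}
        i = 0
        for chrom, grp in self.windows.groupby("chrom", sort=False):
            offsets[chrom] = i
            i += len(grp)
        return offsets

    def window_of(self, chrom: pd.Series, pos: pd.Series) -> np.ndarray:
        """Window index for each (chrom, pos); -1 for unknown chroms."""
        offsets = self.chrom_offsets()
        out = np.full(len(chrom), -1, dtype=np.int64)
        arr_chrom = chrom.to_numpy()
        arr_pos = pos.to_numpy()
        for c, off in offsets.items():
            sel = arr_chrom == c
            out[sel] = off + arr_pos[sel] // self.window_size
        return out

    def to_bed(self, path: str | os.PathLike) -> None:
        self.windows.to_csv(path, sep="\t", header=False, index=False)


def make_windows(
    chrom_sizes: Mapping[str, int], window_size: int, context: str
) -> WindowSet:
    """ceil(L / size) half-open windows per chromosome, tiling exactly."""
    if window_size < 1:
        raise ValueError("window_size must be positive")
    rows = []
    for chrom, size in chrom_sizes.items():
        if size < 1:
            raise ValueError(f"chromosome {chrom} has nonpositive size")
        for start in range(0, size, window_size):
            rows.append((chrom, start, min(start + window_size, size)))
    return WindowSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end"]), window_size, context
    )


@dataclass
class WindowMatrix:
    """Methylation-fraction and site-count matrices over a WindowSet.

    ``frac[i, j]`` is methylated calls / total calls of cell i in
    window j (NaN where the cell has no calls); ``sites[i, j]`` counts
    distinct called cytosines.  ``frac`` is defined exactly where
    ``sites > 0``.
    """

    barcodes: np.ndarray
    windows: WindowSet
    frac: np.ndarray
    sites: np.ndarray

    def __post_init__(self) -> None:
        n, m = self.frac.shape
        assert self.sites.shape == (n, m) and len(self.barcodes) == n
        assert m == len(self.windows)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frac.shape

    @property
    def is_empty(self) -> bool:
        return self.frac.size == 0

    # -- I/O -----------------------------------------------------------
    def write(self, outdir: str | os.PathLike, dense: bool = False) -> None:
        """MTX (sparse) matrices + sidecar window BED and barcode list."""
        from scipy import io as spio
        from scipy import sparse

        os.makedirs(outdir, exist_ok=True)
        filled = np.nan_to_num(self.frac, nan=0.0)
        spio.mmwrite(os.path.join(outdir, "meth_fraction.mtx"), sparse.csr_matrix(filled))
        spio.mmwrite(os.path.join(outdir, "site_count.mtx"), sparse.csr_matrix(self.sites))
        self.windows.to_bed(os.path.join(outdir, "windows.bed"))
        with open(os.path.join(outdir, "barcodes.txt"), "w") as fh:
            fh.write("\n".join(map(str, self.barcodes)) + "\n")
        if dense:
            pd.DataFrame(self.frac, index=self.barcodes).to_csv(
                os.path.join(outdir, "meth_fraction.tsv"), sep="\t"
            )


def build_matrix(calls: pd.DataFrame, windows: WindowSet) -> WindowMatrix:
    """Aggregate a call table into a WindowMatrix.

    Only calls matching the WindowSet context are used.  Total call and
    methylated-call counts are conserved into the matrix cells; an
    internal assertion verifies every in-context call landed in a
    window.
    """
    sub = calls[calls["context"] == windows.context]
    barcodes = np.array(sorted(sub["barcode"].unique()))
    n, m = len(barcodes), len(windows)
    frac = np.full((n, m), np.nan)
    sites = np.zeros((n, m), dtype=np.int64)
    if n == 0:
        return WindowMatrix(barcodes, windows, frac, sites)

    widx = windows.window_of(sub["chrom"], sub["pos"])
    assert (widx >= 0).all(), "call outside all windows (window tiling broken?)"
    cidx = pd.Categorical(sub["barcode"], categories=barcodes).codes
    flat = cidx.astype(np.int64) * m + widx
    n_calls = np.bincount(flat, minlength=n * m).reshape(n, m)
    n_meth = np.bincount(flat, weights=sub["state"].to_numpy(dtype=float),
                         minlength=n * m).reshape(n, m)
    uniq = sub.assign(_w=widx).drop_duplicates(["barcode", "chrom", "pos", "strand"])
    cidx_u = pd.Categorical(uniq["barcode"], categories=barcodes).codes
    flat_u = cidx_u.astype(np.int64) * m + uniq["_w"].to_numpy()
    sites = np.bincount(flat_u, minlength=n * m).reshape(n, m)

    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_calls > 0, n_meth / np.maximum(n_calls, 1), np.nan)
    return WindowMatrix(barcodes, windows, frac, sites)


@dataclass
class FilterReport:
    n_cells_in: int
    n_cells_kept: int
    n_windows_in: int
    n_windows_kept: int
    min_sites: int
    cell_frac: float
    window_frac: float


def filter_matrix(
    m: WindowMatrix,
    min_sites: int | None = None,
    cell_frac: float | None = None,
    window_frac: float | None = None,
) -> tuple[WindowMatrix, FilterReport]:
    """Two-pass coverage filter (cells first, then windows).

    Pass 1 keeps cells whose fraction of ALL windows with
    ``sites >= min_sites`` is at least ``cell_frac``; pass 2 keeps
    windows whose fraction of the RETAINED cells meeting the same
    site threshold is at least ``window_frac``.  Defaults come from the
    matrix context: CH -> (20, 0.75, 0.75), CG -> (5, 0.25, 0.50).
    An empty result is returned as an empty matrix, not an error.
    """
    d_min, d_cell, d_win = FILTER_DEFAULTS[m.windows.context]
    min_sites = d_min if min_sites is None else min_sites
    cell_frac = d_cell if cell_frac is None else cell_frac
    window_frac = d_win if window_frac is None else window_frac
    if min_sites < 0 or not 0 <= cell_frac <= 1 or not 0 <= window_frac <= 1:
        raise ValueError("filter thresholds out of range")

    ok = m.sites >= min_sites
    keep_cells = ok.mean(axis=1) >= cell_frac if m.shape[1] else np.zeros(m.shape[0], bool)
    ok2 = ok[keep_cells]
    if ok2.shape[0] == 0:
        keep_windows = np.zeros(m.shape[1], dtype=bool)
    else:
        keep_windows = ok2.mean(axis=0) >= window_frac
    out = WindowMatrix(
        m.barcodes[keep_cells],
        WindowSet(
            m.windows.windows[keep_windows].reset_index(drop=True),
            m.windows.window_size,
            m.windows.context,
        ),
        m.frac[np.ix_(keep_cells, keep_windows)],
        m.sites[np.ix_(keep_cells, keep_windows)],
    )
    report = FilterReport(
        m.shape[0], int(keep_cells.sum()), m.shape[1], int(keep_windows.sum()),
        min_sites, cell_frac, window_frac,
    )
    return out, report


def merge_matrices(
    matrices: Sequence[WindowMatrix],
    experiment_ids: Sequence[str] | None = None,
) -> WindowMatrix:
    """Row-concatenate experiments sharing one WindowSet definition.

    Barcodes are prefixed ``{experiment_id}:`` to guarantee uniqueness;
    no batch normalization of any kind is applied.  Mismatched window
    definitions are fatal, with a diff summary in the message.
    """
    if not matrices:
        raise ValueError("nothing to merge")
    ref = matrices[0].windows
    for i, m in enumerate(matrices[1:], start=1):
        if m.windows != ref:
            diff = []
            if m.windows.window_size != ref.window_size:
                diff.append(f"window_size {m.windows.window_size} != {ref.window_size}")
            if m.windows.context != ref.context:
                diff.append(f"context {m.windows.context} != {ref.context}")
            if len(m.windows) != len(ref):
                diff.append(f"n_windows {len(m.windows)} != {len(ref)}")
            raise ValueError(
                f"matrix {i} windows differ from matrix 0: {'; '.join(diff) or 'coordinates differ'}"
            )
    if experiment_ids is None:
        experiment_ids = [f"e{i}" for i in range(len(matrices))]
    if len(experiment_ids) != len(matrices):
        raise ValueError("one experiment id per matrix required")
    barcodes = np.concatenate(
        [
            np.array([f"{eid}:{b}" for b in m.barcodes])
            for eid, m in zip(experiment_ids, matrices)
        ]
    )
    return WindowMatrix(
        barcodes,
        ref,
        np.vstack([m.frac for m in matrices]),
        np.vstack([m.sites for m in matrices]),
    )
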