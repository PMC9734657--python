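"""Post-clustering methylome analysis.

Coverage saturation (how many cells of a type rebuild a full
methylome), cluster-level region methylation with cross-cluster
z-scores, cell-cell CG concordance in regulatory regions, and
motif-centered methylation profiles.  Region and motif statistics pool
calls across a cluster's member cells before taking fractions: per-cell
coverage is far too sparse for stable per-cell means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


# ---------------------------------------------------------------------
# region presets
# ---------------------------------------------------------------------
def regions_from_tss(
    tss: pd.DataFrame,
    upstream: int,
    downstream: int,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Strand-aware intervals around TSSs, clipped to chromosome bounds.

    ``tss`` needs (name, chrom, pos, strand); upstream/downstream are
    measured along the gene's own orientation.
    """
    rows = []
    for row in tss.itertuples(index=False):
        if getattr(row, "strand", "+") == "-":
            start, end = row.pos - downstream, row.pos + upstream
        else:
            start, end = row.pos - upstream, row.pos + downstream
        start = max(start, 0)
        if chrom_sizes is not None:
            end = min(end, chrom_sizes[row.chrom])
        rows.append((getattr(row, "name", f"{row.chrom}:{row.pos}"), row.chrom,
                     start, end, getattr(row, "strand", "+")))
    return pd.DataFrame(rows, columns=["name", "chrom", "start", "end", "strand"])


def promoter_call_regions(tss, chrom_sizes=None):
    """Promoters for region methylation calls: TSS -1500 .. +1000."""
    return regions_from_tss(tss, 1500, 1000, chrom_sizes)


def promoter_wide_regions(tss, chrom_sizes=None):
    """Wide promoters: TSS -5000 .. +2500."""
    return regions_from_tss(tss, 5000, 2500, chrom_sizes)


def gene_body_flank_regions(
    genes: pd.DataFrame, flank: int = 2000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Gene bodies extended by ``flank`` on both sides, clipped."""
    out = genes.copy()
    out["start"] = (out["start"] - flank).clip(lower=0)
    out["end"] = out["end"] + flank
    if chrom_sizes is not None:
        out["end"] = out.apply(lambda r: min(r["end"], chrom_sizes[r["chrom"]]), axis=1)
    cols = ["name", "chrom", "start", "end"]
    if "strand" in out:
        cols.append("strand")
    return out[cols]


# ---------------------------------------------------------------------
# coverage saturation
# ---------------------------------------------------------------------
@dataclass
class SaturationCurve:
    """Cumulative covered-site fraction as cells are added."""

    curves: np.ndarray  # n_iter x n_cells, non-decreasing fractions
    cells_to_threshold: np.ndarray  # per iteration; inf if never reached
    threshold: float

    @property
    def mean_curve(self) -> np.ndarray:
        return self.curves.mean(axis=0)

    @property
    def mean_cells_to_threshold(self) -> float:
        return float(self.cells_to_threshold.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cells": np.arange(1, self.curves.shape[1] + 1),
                "mean_fraction": self.mean_curve,
                "min_fraction": self.curves.min(axis=0),
                "max_fraction": self.curves.max(axis=0),
            }
        )


def coverage_saturation(
    cell_sites: Sequence[np.ndarray],
    universe_size: int,
    n_iter: int = 100,
    n_cells: int = 250,
    threshold: float = 0.8,
    seed: int = 0,
) -> SaturationCurve:
    """Randomized cumulative methylome-coverage accumulation.

    Per iteration, ``n_cells`` cells are sampled without replacement in
    random order and the union of their covered-site sets accumulated.
    ``cell_sites`` holds each cell's covered site indices (ints in
    ``[0, universe_size)``); the reported cells-to-threshold is the
    number of cells at which coverage first reaches
    ``threshold * universe_size`` (inf if never).
    """
    if universe_size <= 0:
        raise ValueError("universe_size must be positive")
    if n_cells > len(cell_sites):
        raise ValueError("n_cells exceeds available cells")
    rng = np.random.default_rng(seed)
    curves = np.empty((n_iter, n_cells))
    to_thresh = np.full(n_iter, np.inf)
    for it in range(n_iter):
        order = rng.choice(len(cell_sites), size=n_cells, replace=False)
        seen = np.zeros(universe_size, dtype=bool)
        covered = 0
        for j, ci in enumerate(order):
            sites = cell_sites[ci]
            new = sites[~seen[sites]]
            covered += len(np.unique(new)) if len(new) else 0
            seen[sites] = True
            frac = covered / universe_size
            curves[it, j] = frac
            if frac >= threshold and not np.isfinite(to_thresh[it]):
                to_thresh[it] = j + 1
    return SaturationCurve(curves, to_thresh, threshold)


# ---------------------------------------------------------------------
# region methylation
# ---------------------------------------------------------------------
def _region_counts(
    calls: pd.DataFrame, regions: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """(methylated, total) call counts per region for one call subset."""
    meth = np.zeros(len(regions))
    total = np.zeros(len(regions))
    for chrom, sub in calls.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        cum = np.concatenate([[0], np.cumsum(sub["state"].to_numpy())])
        sel = regions["chrom"] == chrom
        starts = regions.loc[sel, "start"].to_numpy()
        ends = regions.loc[sel, "end"].to_numpy()
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        total[sel.to_numpy()] = hi - lo
        meth[sel.to_numpy()] = cum[hi] - cum[lo]
    return meth, total


def region_methylation(
    calls: pd.DataFrame,
    regions: pd.DataFrame,
    labels: Mapping[str, int] | pd.Series,
    context: str = "CG",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster x region pooled methylation plus cross-cluster z-scores.

    Per (cluster, region): pooled methylated calls / total calls over
    the cluster's member cells.  The z-score standardizes each region
    across clusters with the sample (ddof=1) standard deviation;
    clusters without calls in a region are missing and excluded from
    that region's z-scoring, and an all-equal region z-scores to 0.
    """
    if len(regions) == 0:
        raise ValueError("regions must be non-empty")
    labels = pd.Series(labels)
    sub = calls[calls["context"] == context]
    unlabeled = set(sub["barcode"]) - set(labels.index)
    if unlabeled:
        raise ValueError(f"{len(unlabeled)} barcodes lack a cluster label")
    clusters = sorted(labels.unique())
    meth_tab = pd.DataFrame(index=clusters, columns=regions["name"], dtype=float)
    for cl in clusters:
        members = labels.index[labels == cl]
        m, t = _region_counts(sub[sub["barcode"].isin(members)], regions)
        with np.errstate(invalid="ignore", divide="ignore"):
            meth_tab.loc[cl] = np.where(t > 0, m / np.maximum(t, 1), np.nan)
    mean = meth_tab.mean(axis=0, skipna=True)
    sd = meth_tab.std(axis=0, ddof=1, skipna=True)
    z = (meth_tab - mean).div(sd.replace(0, np.nan), axis=1)
    z = z.where(~(meth_tab.notna() & (sd == 0)), 0.0)  # sd 0 -> z 0, keep NaN holes
    meth_tab.index.name = z.index.name = "cluster"
    return meth_tab, z


# ---------------------------------------------------------------------
# cell-cell similarity
# ---------------------------------------------------------------------
def binarize_sites(calls: pd.DataFrame) -> pd.DataFrame:
    """Per (cell, site) binary state: methylated iff call fraction >= 0.5.

    Most sites carry a single read, so this is usually that read's
    state; ties at exactly 0.5 go to methylated.
    """
    g = calls.groupby(["barcode", "chrom", "pos", "strand"], sort=False)["state"]
    frac = g.mean().reset_index(name="frac")
    frac["state"] = (frac["frac"] >= 0.5).astype(np.int8)
    return frac.drop(columns="frac")


def filter_calls_to_regions(calls: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Calls whose position falls in any region (regions may overlap)."""
    keep = np.zeros(len(calls), dtype=bool)
    pos = calls["pos"].to_numpy()
    chrom_arr = calls["chrom"].to_numpy()
    for chrom, sub in regions.groupby("chrom"):
        sel = chrom_arr == chrom
        if not sel.any():
            continue
        p = pos[sel]
        hit = np.zeros(p.size, dtype=bool)
        for s, e in zip(sub["start"], sub["end"]):
            hit |= (p >= s) & (p < e)
        keep[sel] = hit
    return calls[keep]


def pairwise_similarity(
    site_states: pd.DataFrame,
    min_shared_sites: int = 1,
) -> pd.DataFrame:
    """All-by-all methylation-state concordance matrix.

    ``site_states`` is a binarized table (barcode, chrom, pos, strand,
    state).  For each cell pair, concordance = sites with equal state /
    sites covered by both; pairs sharing fewer than
    ``min_shared_sites`` sites are NaN.  The matrix is symmetric with a
    unit diagonal.
    """
    cells = np.array(sorted(site_states["barcode"].unique()))
    site_key = pd.MultiIndex.from_frame(site_states[["chrom", "pos", "strand"]])
    site_codes, _ = pd.factorize(site_key)
    cell_codes = pd.Categorical(site_states["barcode"], categories=cells).codes
    n, s = len(cells), site_codes.max() + 1
    state = site_states["state"].to_numpy()
    m = sparse.csr_matrix(
        (np.ones(len(site_states)), (cell_codes, site_codes)), shape=(n, s)
    ).minimum(1)
    meth = sparse.csr_matrix(
        (state.astype(float), (cell_codes, site_codes)), shape=(n, s)
    ).minimum(1)
    unmeth = m - meth
    shared = np.asarray((m @ m.T).todense())
    same = np.asarray((meth @ meth.T).todense() + (unmeth @ unmeth.T).todense())
    with np.errstate(invalid="ignore", divide="ignore"):
        conc = np.where(shared >= max(min_shared_sites, 1), same / np.maximum(shared, 1), np.nan)
    return pd.DataFrame(conc, index=cells, columns=cells)


@dataclass
class SimilaritySummary:
    within: pd.Series  # per-cluster mean within-cluster concordance
    between_matrix: pd.DataFrame  # cluster x cluster mean, display-ordered

    @property
    def mean_within(self) -> float:
        return float(self.within.mean())

    @property
    def mean_between(self) -> float:
        m = self.between_matrix
        off = m.values[~np.eye(len(m), dtype=bool)]
        return float(np.nanmean(off))


def similarity_by_cluster(
    conc: pd.DataFrame, labels: Mapping[str, int] | pd.Series
) -> SimilaritySummary:
    """Within/between-cluster concordance summaries.

    The cluster x cluster matrix is hierarchically ordered (average
    linkage on 1 - similarity) for display when it has >= 3 clusters.
    Self-pairs (the unit diagonal) are excluded from within-cluster
    means.
    """
    labels = pd.Series(labels).reindex(conc.index)
    clusters = sorted(labels.dropna().unique())
    mat = pd.DataFrame(index=clusters, columns=clusters, dtype=float)
    for a in clusters:
        ia = labels.index[labels == a]
        for b in clusters:
            ib = labels.index[labels == b]
            block = conc.loc[ia, ib].to_numpy(dtype=float)
            if a == b:
                mask = ~np.eye(len(ia), dtype=bool)
                vals = block[mask]
            else:
                vals = block.ravel()
            mat.loc[a, b] = np.nanmean(vals) if np.isfinite(vals).any() else np.nan
    within = pd.Series({c: mat.loc[c, c] for c in clusters})
    if len(clusters) >= 3 and not mat.isna().any().any():
        dist = squareform((1 - mat.values), checks=False)
        order = hierarchy.leaves_list(hierarchy.linkage(dist, method="average"))
        mat = mat.iloc[order, order]
    return SimilaritySummary(within, mat)


# ---------------------------------------------------------------------
# motif profiles
# ---------------------------------------------------------------------
def motif_profile(
    calls: pd.DataFrame,
    motifs: pd.DataFrame,
    labels: Mapping[str, int] | pd.Series,
    context: str = "CG",
    step: int = 10,
    span: int = 500,
) -> pd.DataFrame:
    """Cluster x position-bin pooled methylation around motif centers.

    Bins are ``step``-bp half-open tiles covering ``[-span, span)``
    relative to each motif center (``2 * span / step`` bins, boundary
    at the center), strand-flipped for minus-strand motifs.
    ``motifs`` needs (chrom, pos, strand); out-of-bounds bins at
    chromosome edges simply collect no calls.  Returns a frame indexed
    by cluster whose columns are bin start offsets.
    """
    if span % step:
        raise ValueError("span must be a multiple of step")
    labels = pd.Series(labels)
    sub = calls[calls["context"] == context]
    n_bins = 2 * span // step
    offsets = np.arange(-span, span, step)
    clusters = sorted(labels.unique())
    meth = np.zeros((len(clusters), n_bins))
    total = np.zeros((len(clusters), n_bins))
    cl_of = labels.to_dict()

    cl_codes = sub["barcode"].map(cl_of)
    if cl_codes.isna().any():
        raise ValueError("every cell with calls needs a cluster label")
    cl_idx = pd.Categorical(cl_codes, categories=clusters).codes

    pos = sub["pos"].to_numpy()
    state = sub["state"].to_numpy(dtype=float)
    chrom_arr = sub["chrom"].to_numpy()
    for motif in motifs.itertuples(index=False):
        sel = chrom_arr == motif.chrom
        if not sel.any():
            continue
        rel = pos[sel] - motif.pos
        if getattr(motif, "strand", "+") == "-":
            rel = -rel - 1  # mirror; keeps half-open bins aligned
        inside = (rel >= -span) & (rel < span)
        if not inside.any():
            continue
        b = (rel[inside] + span) // step
        c = cl_idx[sel][inside]
        np.add.at(total, (c, b), 1)
        np.add.at(meth, (c, b), state[sel][inside])
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, meth / np.maximum(total, 1), np.nan)
    out = pd.DataFrame(frac, index=clusters, columns=offsets)
    out.index.name = "cluster"
    return out
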