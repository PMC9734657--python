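"""Call-level and count-level fast simulation paths.

The read-level simulator exercises the full demux -> align -> extract
chain; matrix/clustering and barnyard-statistics work only needs the
methylation *calls* or the per-barcode species read *counts*.  These
generators draw those directly from the same statistical model, which
keeps large-replicate experiments cheap.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from ..reference import CTX_CG, CTX_CH
from .cells import CellAssignment
from .design import CellTypeProfile, MarkerRegion
from .genome import SpeciesGenome
from .reads import _profile_p_vectors


def _site_pool(genome: SpeciesGenome, contexts: Sequence[str]) -> pd.DataFrame:
    """All cytosine sites of a genome as one table (both strands)."""
    want = {"CG": CTX_CG, "CH": CTX_CH}
    codes = {want[c] for c in contexts}
    frames = []
    for chrom in genome.chroms:
        for strand, ctx_arr in (("+", genome.fwd_context(chrom)), ("-", genome.rev_context(chrom))):
            pos = np.flatnonzero(ctx_arr > 0)
            ctx = ctx_arr[pos]
            keep = np.isin(ctx, list(codes))
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos[keep],
                        "strand": strand,
                        "context": np.where(ctx[keep] == CTX_CG, "CG", "CH"),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def simulate_site_calls(
    genome: SpeciesGenome,
    cell_types: Sequence[str],
    profiles: Sequence[CellTypeProfile],
    sites_per_cell: int,
    seed: int = 0,
    contexts: Sequence[str] = ("CG", "CH"),
    barcodes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One methylation call per sampled site per cell.

    Each cell covers ``sites_per_cell`` distinct cytosines drawn
    uniformly; the call state is Bernoulli with the cell type's
    site-specific methylation probability (marker-region overrides
    included).  Returns the standard call table
    (barcode, chrom, pos, strand, context, state).
    """
    rng = np.random.default_rng(seed)
    by_label = {p.type_label: p for p in profiles}
    pool = _site_pool(genome, contexts)
    n_sites = len(pool)
    if sites_per_cell > n_sites:
        raise ValueError("sites_per_cell exceeds available sites")

    # per-type site probability vector aligned with the pool
    p_of_type: dict[str, np.ndarray] = {}
    for label, prof in by_label.items():
        pvec = np.empty(n_sites)
        vecs = _profile_p_vectors(prof, genome)
        offset = 0
        for chrom in genome.chroms:
            p_f, p_r = vecs[chrom]
            for strand, p_all, ctx_arr in (
                ("+", p_f, genome.fwd_context(chrom)),
                ("-", p_r, genome.rev_context(chrom)),
            ):
                pos_all = np.flatnonzero(ctx_arr > 0)
                keep = np.isin(ctx_arr[pos_all], [1, 2] if len(contexts) == 2 else
                               [CTX_CG if contexts[0] == "CG" else CTX_CH])
                k = int(keep.sum())
                pvec[offset : offset + k] = p_all[keep]
                offset += k
        p_of_type[label] = pvec

    if barcodes is None:
        barcodes = [f"cell{i:04d}" for i in range(len(cell_types))]
    frames = []
    for bc, ctype in zip(barcodes, cell_types):
        if ctype not in p_of_type:
            raise ValueError(f"no profile for cell type {ctype!r}")
        idx = rng.choice(n_sites, size=sites_per_cell, replace=False)
        idx.sort()
        state = (rng.random(sites_per_cell) < p_of_type[ctype][idx]).astype(np.int8)
        sub = pool.iloc[idx].copy()
        sub["barcode"] = bc
        sub["state"] = state
        frames.append(sub)
    calls = pd.concat(frames, ignore_index=True)
    return calls[["barcode", "chrom", "pos", "strand", "context", "state"]]


def make_separated_profiles(
    genome: SpeciesGenome,
    n_types: int,
    window_size: int,
    base_mch: float = 0.08,
    low_mch: float = 0.02,
    high_mch: float = 0.35,
    frac_marker_windows: float = 0.3,
    mcg: float = 0.80,
    seed: int = 0,
) -> list[CellTypeProfile]:
    """Cell types with type-specific window-level CH methylation.

    Each type flips a random ~``frac_marker_windows`` of genomic windows
    to a high or low CH level, giving well-separated windowed methylomes
    for clustering-recovery experiments.
    """
    rng = np.random.default_rng(seed)
    windows = []
    for chrom, size in genome.chrom_sizes().items():
        for start in range(0, size, window_size):
            windows.append((chrom, start, min(start + window_size, size)))
    profiles = []
    for t in range(n_types):
        n_marked = max(1, int(round(frac_marker_windows * len(windows))))
        chosen = rng.choice(len(windows), size=n_marked, replace=False)
        markers = []
        for j, w in enumerate(chosen):
            chrom, start, end = windows[w]
            level = high_mch if j % 2 == 0 else low_mch
            markers.append(MarkerRegion(chrom, start, end, "CH", level))
        profiles.append(
            CellTypeProfile(f"type{t}", base_mch, mcg, tuple(markers))
        )
    return profiles


def simulate_species_counts(
    assignment: CellAssignment,
    reads_per_cell: int = 1000,
    crosstalk_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per observed barcode, read counts aligning to each species.

    Count-level equivalent of the read simulator: every cell's reads
    align to its own species; a ``crosstalk_rate`` fraction is
    reassigned to uniformly random other barcode units (keeping the
    donor's species label, which is what crosstalk looks like in a
    barnyard alignment).
    """
    rng = np.random.default_rng(seed)
    table = assignment.cell_table
    species_labels = sorted(set(table["species"]))
    units = table["barcode"].unique()
    unit_idx = {b: i for i, b in enumerate(units)}
    counts = np.zeros((len(units), len(species_labels)), dtype=np.int64)
    sp_idx = {s: i for i, s in enumerate(species_labels)}

    for cell in table.itertuples(index=False):
        n_cross = rng.binomial(reads_per_cell, crosstalk_rate)
        counts[unit_idx[cell.barcode], sp_idx[cell.species]] += reads_per_cell - n_cross
        if n_cross:
            targets = rng.integers(0, len(units), size=n_cross)
            np.add.at(counts[:, sp_idx[cell.species]], targets, 1)
    out = pd.DataFrame(counts, columns=[f"reads_{s}" for s in species_labels])
    out.insert(0, "barcode", units)
    return out
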