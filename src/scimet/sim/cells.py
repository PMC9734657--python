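"""Barcode whitelists and cell-to-barcode assignment.

A nucleus receives a tagmentation (tag) barcode in the first indexing
round and lands in one PCR well (i5 x i7 pair) in the second.  Two nuclei
that share both are physically indistinguishable downstream: they form a
collision doublet under one merged observed barcode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .design import CellTypeProfile, ExperimentDesign, PCR_INDEX_LEN, TAG_INDEX_LEN

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def random_whitelist(
    n: int,
    length: int,
    min_dist: int,
    rng: np.random.Generator,
    max_tries: int = 500_000,
) -> list[str]:
    """Rejection-sample ``n`` barcodes with pairwise Hamming >= min_dist.

    Raises if the requested code is not reachable within ``max_tries``
    draws (e.g. 96 length-8 codes at distance 5 exceed what random
    search — and, close to it, coding-theory bounds — can deliver).
    """
    kept = np.empty((0, length), dtype=np.int8)
    for _ in range(max_tries):
        cand = rng.integers(0, 4, size=length, dtype=np.int8)
        if kept.size == 0 or int((kept != cand).sum(axis=1).min()) >= min_dist:
            kept = np.vstack([kept, cand])
            if len(kept) == n:
                return ["".join("ACGT"[b] for b in row) for row in kept]
    raise ValueError(
        f"could not build {n} length-{length} barcodes at min distance "
        f"{min_dist} within {max_tries} draws"
    )


@dataclass
class CellAssignment:
    """Realized barcoding of one experiment plus its whitelists."""

    cell_table: pd.DataFrame
    tag_whitelist: list[str]
    i5_whitelist: list[str]
    i7_whitelist: list[str]
    design: ExperimentDesign

    @property
    def n_barcode_units(self) -> int:
        """Distinct observed barcodes (doublets merged)."""
        return self.cell_table["barcode"].nunique()

    def collision_fraction(self) -> float:
        """Fraction of observed barcode units that are collision doublets."""
        per_bc = self.cell_table.groupby("barcode")["cell_id"].size()
        return float((per_bc > 1).sum() / len(per_bc))


def assign_cells(
    design: ExperimentDesign,
    profiles: Sequence[CellTypeProfile],
    seed: int | None = None,
) -> CellAssignment:
    """Draw species, cell types, wells and barcodes for every nucleus.

    Each nucleus independently draws a tag barcode (uniform over the
    whitelist) and is deposited into a PCR well filled with
    ``events_per_well`` nuclei.  Nuclei sharing (well, tag) are flagged
    ``is_collision_doublet`` and share one observed composite barcode
    ``i5 + i7 + tag``.
    """
    if len(profiles) == 0:
        raise ValueError("at least one cell-type profile required")
    if len(profiles) > design.n_cells:
        raise ValueError("more cell-type profiles than cells")
    labels = [p.type_label for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValueError("cell-type labels must be unique")

    rng = np.random.default_rng(design.seed if seed is None else seed)
    n = design.n_cells
    n_wells_needed = -(-n // design.events_per_well)
    if n_wells_needed > design.n_pcr_wells:
        raise ValueError(
            f"{n} cells at {design.events_per_well}/well need "
            f"{n_wells_needed} wells but only {design.n_pcr_wells} exist"
        )

    tag_wl = random_whitelist(
        design.n_tag_barcodes, TAG_INDEX_LEN, design.tag_whitelist_min_dist, rng
    )
    n_i7 = int(np.ceil(np.sqrt(design.n_pcr_wells)))
    n_i5 = -(-design.n_pcr_wells // n_i7)
    i5_wl = random_whitelist(n_i5, PCR_INDEX_LEN, design.pcr_whitelist_min_dist, rng)
    i7_wl = random_whitelist(n_i7, PCR_INDEX_LEN, design.pcr_whitelist_min_dist, rng)

    species_labels = list(design.species_mix.keys())
    mix = np.array([design.species_mix[s] for s in species_labels], dtype=float)
    species = rng.choice(species_labels, size=n, p=mix / mix.sum())
    cell_type = rng.choice(labels, size=n)

    well = np.repeat(np.arange(n_wells_needed), design.events_per_well)[:n]
    tag_idx = rng.integers(0, design.n_tag_barcodes, size=n)

    i5_of_well = np.array([w // n_i7 for w in range(n_wells_needed)])
    i7_of_well = np.array([w % n_i7 for w in range(n_wells_needed)])
    barcodes = np.array(
        [
            i5_wl[i5_of_well[w]] + i7_wl[i7_of_well[w]] + tag_wl[t]
            for w, t in zip(well, tag_idx)
        ]
    )

    table = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "species": species,
            "cell_type": cell_type,
            "pcr_well": well,
            "tag_index": tag_idx,
            "barcode": barcodes,
        }
    )
    sizes = table.groupby("barcode")["cell_id"].transform("size")
    table["is_collision_doublet"] = sizes > 1
    return CellAssignment(table, tag_wl, i5_wl, i7_wl, design)
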