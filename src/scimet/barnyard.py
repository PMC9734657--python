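"""Barnyard (two-species mixing) quality control.

A deliberate mix of nuclei from two species turns barcode collisions
into an observable: a barcode whose reads align to both genomes must
cover at least two nuclei.  Cross-species collisions are only a fraction
``2 * p_A * p_B`` of all collisions (same-species collisions are
invisible), so the observed mixed fraction is scaled up by that factor
— the package's documented correction model, with singlet-derived
species proportions.  The expected collision probability under uniform
first-round barcoding of ``n`` nuclei per well over ``B`` tag barcodes
is the birthday bound ``1 - (1 - 1/B)^(n-1)``.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

MIXED = "mixed"


def assign_species(
    counts: pd.DataFrame,
    purity_threshold: float = 0.9,
    min_reads: int = 1,
) -> pd.DataFrame:
    """Assign each barcode to a species or call it mixed.

    ``counts`` needs a ``barcode`` column plus exactly two
    ``reads_<species>`` columns.  Purity is
    ``max(reads_A, reads_B) / (reads_A + reads_B)``; a barcode is
    assigned to the majority species iff purity >= threshold, else
    ``mixed``.  Barcodes with fewer than ``min_reads`` total are
    excluded.
    """
    if not 0.5 <= purity_threshold <= 1.0:
        raise ValueError("purity_threshold must be in [0.5, 1]")
    read_cols = [c for c in counts.columns if c.startswith("reads_")]
    if len(read_cols) != 2:
        raise ValueError("expected exactly two reads_<species> columns")
    species = [c[len("reads_") :] for c in read_cols]
    a = counts[read_cols[0]].to_numpy(dtype=float)
    b = counts[read_cols[1]].to_numpy(dtype=float)
    total = a + b
    keep = total >= max(min_reads, 1)
    table = counts.loc[keep, ["barcode", *read_cols]].reset_index(drop=True)
    a, b, total = a[keep], b[keep], total[keep]
    purity = np.maximum(a, b) / total
    majority = np.where(a >= b, species[0], species[1])
    table["purity"] = purity
    table["assignment"] = np.where(purity >= purity_threshold, majority, MIXED)
    return table


@dataclass
class DoubletEstimate:
    n_cells: int
    n_mixed: int
    observed: float
    observed_ci: tuple[float, float]
    p_a: float
    p_b: float
    corrected: float | None
    corrected_ci: tuple[float, float] | None

    def as_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "n_mixed": self.n_mixed,
            "observed_mixed_fraction": self.observed,
            "observed_ci_low": self.observed_ci[0],
            "observed_ci_high": self.observed_ci[1],
            "p_a": self.p_a,
            "p_b": self.p_b,
            "corrected_doublet_rate": self.corrected,
            "corrected_ci_low": None if self.corrected_ci is None else self.corrected_ci[0],
            "corrected_ci_high": None if self.corrected_ci is None else self.corrected_ci[1],
        }


def doublet_estimate(table: pd.DataFrame, alpha: float = 0.05) -> DoubletEstimate:
    """Observed mixed fraction and mixing-corrected total doublet rate.

    The correction divides the observed cross-species fraction by
    ``2 * p_A * p_B`` where the singlet proportions p come from the
    assigned (non-mixed) cells; its CI is the observed binomial
    (Wilson) CI scaled by the same factor.  With one species absent the
    correction is undefined and only the observed fraction is returned.
    """
    n = len(table)
    if n == 0:
        raise ValueError("empty species table")
    n_mixed = int((table["assignment"] == MIXED).sum())
    observed = n_mixed / n
    obs_ci = proportion_confint(n_mixed, n, alpha=alpha, method="wilson")
    singlets = table[table["assignment"] != MIXED]
    species = sorted(set(singlets["assignment"]))
    if len(species) < 2:
        return DoubletEstimate(n, n_mixed, observed, obs_ci, float("nan"),
                               float("nan"), None, None)
    counts = singlets["assignment"].value_counts()
    p_a = counts[species[0]] / len(singlets)
    p_b = counts[species[1]] / len(singlets)
    scale = 2.0 * p_a * p_b
    corrected = observed / scale
    corr_ci = (obs_ci[0] / scale, obs_ci[1] / scale)
    return DoubletEstimate(n, n_mixed, observed, obs_ci, float(p_a), float(p_b),
                           float(corrected), corr_ci)


def expected_collision(events_per_well: int, n_tag_barcodes: int) -> float:
    """P(a nucleus shares its tag barcode with >= 1 well-mate).

    ``1 - (1 - 1/B)^(n-1)`` for ``n`` events per well and ``B`` tag
    barcodes, assuming uniform independent barcode draws.
    """
    if events_per_well < 1 or n_tag_barcodes < 1:
        raise ValueError("events_per_well and n_tag_barcodes must be >= 1")
    return 1.0 - (1.0 - 1.0 / n_tag_barcodes) ** (events_per_well - 1)


def crosstalk(table: pd.DataFrame) -> pd.DataFrame:
    """Per-species read contamination of singlet cells.

    For cells assigned to species A, the fraction of their reads
    aligning to species B (and vice versa); reported per cell with
    species means available via groupby.  Raises if no singlets exist.
    """
    read_cols = [c for c in table.columns if c.startswith("reads_")]
    species = [c[len("reads_") :] for c in read_cols]
    singlets = table[table["assignment"] != MIXED].copy()
    if len(singlets) == 0:
        raise ValueError("no singlet cells: crosstalk undefined")
    own = np.where(
        singlets["assignment"] == species[0],
        singlets[read_cols[0]],
        singlets[read_cols[1]],
    )
    other = np.where(
        singlets["assignment"] == species[0],
        singlets[read_cols[1]],
        singlets[read_cols[0]],
    )
    singlets["crosstalk_fraction"] = other / (own + other)
    return singlets[["barcode", "assignment", "crosstalk_fraction"]]


def crosstalk_summary(table: pd.DataFrame) -> pd.Series:
    return crosstalk(table).groupby("assignment")["crosstalk_fraction"].mean()


def split_by_species(
    reads: Iterable[tuple[str, str]],
    assignment: Mapping[str, str] | pd.DataFrame,
    outdir: str | os.PathLike | None = None,
    suffix: str = "R1",
) -> dict[str, list[tuple[str, str]] | int]:
    """Route barcode-tagged reads into per-species files.

    ``assignment`` maps barcode -> species (or is an assign_species
    frame).  Reads of mixed cells are dropped; reads whose barcode is
    absent go to ``unassigned``.  Returns per-route read lists (and
    writes ``{species}_{suffix}.fastq.gz`` under ``outdir`` if given);
    counts across routes conserve the input.
    """
    if isinstance(assignment, pd.DataFrame):
        assignment = dict(zip(assignment["barcode"], assignment["assignment"]))
    routes: dict[str, list[tuple[str, str]]] = {"dropped_mixed": [], "unassigned": []}
    for name, seq in reads:
        bc = name.rsplit(":", 1)[-1]
        species = assignment.get(bc)
        if species is None:
            routes["unassigned"].append((name, seq))
        elif species == MIXED:
            routes["dropped_mixed"].append((name, seq))
        else:
            routes.setdefault(species, []).append((name, seq))
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        for route, recs in routes.items():
            path = os.path.join(outdir, f"{route}_{suffix}.fastq.gz")
            with gzip.open(path, "wt") as fh:
                for name, seq in recs:
                    fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
    return routes
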