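"""Experiment design and cell-type methylation profiles.

The defaults describe the mixing experiment the downstream QC is built
for: a skewed two-species nucleus mix (90/10), 22 sort events deposited
per PCR well, 96 tagmentation barcodes, and realistic nuisance rates
(PCR duplication, index/sequencing errors, bisulfite conversion noise).
Per-cell sequencing depth defaults to a desk-scale value; real
experiments run orders of magnitude deeper but share the same structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

# Canonical 19-base Tn5 mosaic-end recognition sequence, plus a 2-base pad
# so that the index (8 nt) + ME segment spans bases 1-29 of read 2.
MOSAIC_END = "AGATGTGTATAAGAGACAG"
ME_PAD = "CT"
ME_SEGMENT = MOSAIC_END + ME_PAD  # 21 nt
assert len(ME_SEGMENT) == 21

TAG_INDEX_LEN = 8
PCR_INDEX_LEN = 10
R1_PRIMER_LEN = 10  # random-priming region at the start of read 1
R2_STRUCT_LEN = TAG_INDEX_LEN + len(ME_SEGMENT)  # 29
R2_TAIL_TRIM = 10  # 3' bases of read 2 that may re-enter the random primer


@dataclass(frozen=True)
class MarkerRegion:
    """A genomic interval where a cell type overrides its global rate."""

    chrom: str
    start: int
    end: int
    context: str  # "CG" or "CH"
    meth_prob: float

    def __post_init__(self) -> None:
        if self.context not in ("CG", "CH"):
            raise ValueError("context must be CG or CH")
        if not 0.0 <= self.meth_prob <= 1.0:
            raise ValueError("meth_prob must be in [0, 1]")


@dataclass(frozen=True)
class CellTypeProfile:
    """Global CG/CH methylation levels plus marker-region overrides.

    ``global_mch`` is the headline neuron/glia discriminator: neuronal
    types carry abundant non-CG methylation (several percent), glial
    types very little (~1%).
    """

    type_label: str
    global_mch: float
    global_mcg: float
    marker_regions: tuple[MarkerRegion, ...] = ()

    def __post_init__(self) -> None:
        for name in ("global_mch", "global_mcg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def neuron_like(label: str = "neuron", mch: float = 0.06, mcg: float = 0.82,
                markers: Sequence[MarkerRegion] = ()) -> CellTypeProfile:
    return CellTypeProfile(label, mch, mcg, tuple(markers))


def glia_like(label: str = "glia", mch: float = 0.01, mcg: float = 0.78,
              markers: Sequence[MarkerRegion] = ()) -> CellTypeProfile:
    return CellTypeProfile(label, mch, mcg, tuple(markers))


_RATE_FIELDS = (
    "duplicate_rate",
    "barcode_error_rate",
    "seq_error_rate",
    "conversion_failure_rate",
    "overconversion_rate",
    "crosstalk_rate",
)


@dataclass(frozen=True)
class ExperimentDesign:
    """Parameters of one simulated combinatorial-indexing experiment.

    Parameters
    ----------
    n_cells
        Total sorted nuclei across the plate.
    species_mix
        Species label -> proportion; must sum to 1.
    events_per_well
        Nuclei deposited per PCR well (the doublet-rate dial).
    n_tag_barcodes, n_pcr_wells
        First-round (tagmentation) barcode count and PCR well count.
    duplicate_rate
        Mean number of *extra* PCR copies per unique molecule
        (copies = 1 + Poisson(duplicate_rate); 0 means no duplicates,
        0.5 gives a mean of 1.5 copies).
    barcode_error_rate, seq_error_rate
        Per-base substitution probabilities on index segments and on
        genomic bases respectively.
    conversion_failure_rate
        P(unmethylated C read as C) — incomplete bisulfite conversion.
    overconversion_rate
        P(methylated C read as T).
    crosstalk_rate
        Fraction of molecules reassigned to a random other cell barcode
        (models cell-cell crosstalk; 0 by default).
    reads_per_cell
        Unique molecules (read pairs before duplication) per cell.
    tag_whitelist_min_dist
        Minimum pairwise Hamming distance of the 8-base tagmentation
        whitelist.  Distance 5 makes distance-2 correction exact but
        caps the whitelist near 45 codes; the 96-barcode default uses
        distance 4, at which correction can reject but never
        mis-assign.
    """

    n_cells: int = 2112
    species_mix: Mapping[str, float] = field(
        default_factory=lambda: {"hsap": 0.9, "mmus": 0.1}
    )
    events_per_well: int = 22
    n_tag_barcodes: int = 96
    n_pcr_wells: int = 96
    duplicate_rate: float = 0.3
    barcode_error_rate: float = 0.002
    seq_error_rate: float = 0.005
    conversion_failure_rate: float = 0.005
    overconversion_rate: float = 0.005
    crosstalk_rate: float = 0.0
    reads_per_cell: int = 2000
    read_length: int = 100
    tag_whitelist_min_dist: int = 4
    pcr_whitelist_min_dist: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        total = float(sum(self.species_mix.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError("species_mix must sum to 1")
        if any(v < 0 for v in self.species_mix.values()):
            raise ValueError("species_mix entries must be nonnegative")
        for name in _RATE_FIELDS:
            v = getattr(self, name)
            if name != "duplicate_rate" and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.duplicate_rate < 0:
            raise ValueError("duplicate_rate must be >= 0")
        for name in ("n_cells", "events_per_well", "n_tag_barcodes",
                     "n_pcr_wells", "reads_per_cell", "read_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.read_length <= R2_STRUCT_LEN + R2_TAIL_TRIM:
            raise ValueError(
                f"read_length must exceed the structural prefixes "
                f"({R2_STRUCT_LEN + R2_TAIL_TRIM} nt)"
            )

    def with_(self, **kwargs) -> "ExperimentDesign":
        return replace(self, **kwargs)
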