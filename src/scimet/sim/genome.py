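"""Toy species genomes for barnyard simulations.

Sequences are i.i.d. draws from a base composition with a given GC
fraction.  Two independent draws share ~26% per-base identity at GC 0.42,
far below any threshold that could confuse species assignment, which is
all the downstream barnyard logic needs from them.
"""

from __future__ import annotations

import numpy as np

from ..reference import Reference

BASES = np.frombuffer(b"ACGT", dtype="S1")


class SpeciesGenome(Reference):
    """A :class:`~scimet.reference.Reference` carrying a species label.

    Chromosome names are prefixed with the species label so that a joint
    (merged) reference still identifies the species of every alignment.
    """

    def __init__(self, species_label: str, chroms: dict[str, str]):
        self.species_label = species_label
        super().__init__(chroms)


def random_sequence(length: int, gc_fraction: float, rng: np.random.Generator) -> str:
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    draws = rng.choice(BASES, size=length, p=[p_at, p_gc, p_gc, p_at])
    return draws.tobytes().decode("ascii")


def make_genomes(
    n_chroms: int,
    chrom_length: int,
    gc_fraction: float = 0.42,
    seed: int = 0,
    labels: tuple[str, str] = ("hsap", "mmus"),
) -> tuple[SpeciesGenome, SpeciesGenome]:
    """Two mutually divergent species genomes with CG/CH site indexes.

    Parameters
    ----------
    n_chroms, chrom_length
        Chromosome count and length (>= 10 kb) per species.
    gc_fraction
        G+C fraction of the i.i.d. base composition, in [0, 1]
        (0 is a legal degenerate genome with no cytosines).
    labels
        Distinct species labels; chromosomes are named
        ``{label}_chr{i}``.
    """
    if n_chroms < 1:
        raise ValueError("n_chroms must be >= 1")
    if chrom_length < 10_000:
        raise ValueError("chrom_length must be >= 10 kb")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    if labels[0] == labels[1]:
        raise ValueError("species labels must be distinct")
    rng = np.random.default_rng(seed)
    genomes = []
    for label in labels:
        chroms = {
            f"{label}_chr{i + 1}": random_sequence(chrom_length, gc_fraction, rng)
            for i in range(n_chroms)
        }
        genomes.append(SpeciesGenome(label, chroms))
    return genomes[0], genomes[1]
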