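"""Reference sequences with cytosine-context indexes.

Bisulfite methylation calls are made against a reference, never from the
read itself: a cytosine's context (CG vs. CH, where H = A/C/T) is the
reference dinucleotide at the site.  This module holds the reference and
precomputes, for every chromosome, the context of every cytosine on both
strands so that per-read calling is a vectorised lookup.

Context codes (int8):
    0 - position is not a cytosine on that strand
    1 - CG context
    2 - CH context (CHG and CHH merged)

Forward-strand cytosines sit at positions where the sequence is ``C``; the
following base decides the context (a terminal ``C`` has no following base
and is treated as CH).  Reverse-strand cytosines sit at positions where the
forward sequence is ``G``; their context is read from the reverse
complement, i.e. ``CG`` iff the *preceding* forward base is ``C``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

CTX_NONE = 0
CTX_CG = 1
CTX_CH = 2

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype="S1")


def _context_arrays(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(fwd, rev) context codes for one chromosome byte array."""
    n = arr.size
    fwd = np.zeros(n, dtype=np.int8)
    rev = np.zeros(n, dtype=np.int8)
    is_c = arr == b"C"
    is_g = arr == b"G"
    # forward strand: C followed by G -> CG, else CH
    fwd[is_c] = CTX_CH
    if n > 1:
        cg = is_c[:-1] & is_g[1:]
        fwd[:-1][cg] = CTX_CG
    # reverse strand: G preceded by C -> CG (revcomp dinucleotide is CG)
    rev[is_g] = CTX_CH
    if n > 1:
        gc = is_g[1:] & is_c[:-1]
        rev[1:][gc] = CTX_CG
    return fwd, rev


@dataclass
class Reference:
    """A set of named chromosome sequences with cached context indexes."""

    chroms: dict[str, str]
    _arrays: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _fwd_ctx: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _rev_ctx: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for name, seq in self.chroms.items():
            arr = _seq_to_array(seq)
            self._arrays[name] = arr
            self._fwd_ctx[name], self._rev_ctx[name] = _context_arrays(arr)

    # -- constructors -------------------------------------------------
    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "Reference":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    # -- accessors ----------------------------------------------------
    def seq_array(self, chrom: str) -> np.ndarray:
        return self._arrays[chrom]

    def fwd_context(self, chrom: str) -> np.ndarray:
        return self._fwd_ctx[chrom]

    def rev_context(self, chrom: str) -> np.ndarray:
        return self._rev_ctx[chrom]

    def cg_sites(self, chrom: str) -> np.ndarray:
        """Forward-strand CG cytosine positions (0-based)."""
        return np.flatnonzero(self._fwd_ctx[chrom] == CTX_CG)

    def ch_sites(self, chrom: str) -> np.ndarray:
        """Forward-strand CH cytosine positions (0-based)."""
        return np.flatnonzero(self._fwd_ctx[chrom] == CTX_CH)

    def cg_sites_rev(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self._rev_ctx[chrom] == CTX_CG)

    def ch_sites_rev(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self._rev_ctx[chrom] == CTX_CH)

    def chrom_sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chroms.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms

    # -- writers ------------------------------------------------------
    def write_fasta(self, path: str | os.PathLike, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chroms.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_chrom_sizes(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for name, size in self.chrom_sizes().items():
                fh.write(f"{name}\t{size}\n")


def merge_references(refs: Iterable[Reference]) -> Reference:
    """Joint reference (e.g. two species for a barnyard alignment)."""
    merged: dict[str, str] = {}
    for ref in refs:
        for name, seq in ref.chroms.items():
            if name in merged:
                raise ValueError(f"duplicate chromosome name {name!r}")
            merged[name] = seq
    return Reference(merged)
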