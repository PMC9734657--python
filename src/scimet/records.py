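"""Lightweight alignment records shared by the simulator and extractor.

Real pipelines hand SAM/BAM between stages; in-process the same
information travels as :class:`AlignmentRecord` so the extractor can be
driven either from a file (via pysam) or from simulator output directly.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned single-end read.

    ``conversion_strand`` is the bisulfite conversion strand of the
    molecule ("CT" for original-top, "GA" for original-bottom; the
    bismark ``XG`` tag convention).  ``seq`` is stored in
    reference-forward projection, i.e. exactly the bases that sit over
    ``[start, start + len(seq))`` of the forward reference.
    """

    name: str
    barcode: str
    chrom: str
    start: int
    strand: str  # "+" or "-"
    conversion_strand: str  # "CT" or "GA"
    seq: str
    mapped: bool = True

    @property
    def end(self) -> int:
        return self.start + len(self.seq)


def barcode_from_name(name: str) -> str:
    """Composite cell barcode stored after the last ':' of a read name."""
    return name.rsplit(":", 1)[-1]
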