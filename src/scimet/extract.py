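"""Barcode-aware deduplication, methylation calling and per-cell QC.

Methylation is called against the reference from the conversion strand
of each read (``XG`` tag): on a CT (original-top) read, every reference
C covered by the read is scored C -> methylated / T -> unmethylated; on
a GA (original-bottom) read the mirrored logic applies at reference G
positions.  Any other read base is a sequencing error or SNV and yields
no call.  Context (CG vs. merged CH) always comes from the reference
dinucleotide.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .records import AlignmentRecord, barcode_from_name
from .reference import CTX_CG, Reference

CALL_COLUMNS = ["barcode", "chrom", "pos", "strand", "context", "state"]


# ---------------------------------------------------------------------
# input adaptation
# ---------------------------------------------------------------------
def read_alignments(path: str | os.PathLike) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from a SAM/BAM file.

    The cell barcode is taken from the CB/BC tag if present, else from
    the read name (after the last ':').  Reads without an XG
    conversion-strand tag are yielded with ``conversion_strand=""`` so
    the caller can count and skip them.
    """
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.reference_id < 0:
                yield AlignmentRecord(
                    aln.query_name or "", "", "", 0, "+", "", aln.query_sequence or "",
                    mapped=False,
                )
                continue
            if aln.has_tag("CB"):
                bc = aln.get_tag("CB")
            elif aln.has_tag("BC"):
                bc = aln.get_tag("BC")
            else:
                bc = barcode_from_name(aln.query_name or "")
            xg = aln.get_tag("XG") if aln.has_tag("XG") else ""
            yield AlignmentRecord(
                name=aln.query_name or "",
                barcode=str(bc),
                chrom=aln.reference_name,
                start=aln.reference_start,
                strand="-" if aln.is_reverse else "+",
                conversion_strand=str(xg),
                seq=aln.query_sequence or "",
            )


# ---------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------
@dataclass
class DedupStats:
    per_cell: pd.DataFrame  # barcode, total_reads, unique_reads
    n_unmapped: int

    def unique_fraction(self) -> pd.Series:
        return self.per_cell.set_index("barcode").eval("unique_reads / total_reads")


def dedup(
    alignments: Iterable[AlignmentRecord],
) -> tuple[list[AlignmentRecord], DedupStats]:
    """Barcode-aware duplicate removal.

    Exactly one record is retained per (barcode, chrom, start, strand)
    key — the one with the lexicographically smallest read name, which
    makes the retained set invariant to input order.  Unmapped records
    are skipped and counted.
    """
    kept: dict[tuple, AlignmentRecord] = {}
    totals: dict[str, int] = {}
    n_unmapped = 0
    for rec in alignments:
        if not rec.mapped:
            n_unmapped += 1
            continue
        totals[rec.barcode] = totals.get(rec.barcode, 0) + 1
        key = (rec.barcode, rec.chrom, rec.start, rec.strand)
        prev = kept.get(key)
        if prev is None or rec.name < prev.name:
            kept[key] = rec
    records = sorted(kept.values(), key=lambda r: (r.chrom, r.start, r.strand, r.barcode))
    uniques: dict[str, int] = {}
    for rec in records:
        uniques[rec.barcode] = uniques.get(rec.barcode, 0) + 1
    per_cell = pd.DataFrame(
        {
            "barcode": list(totals),
            "total_reads": [totals[b] for b in totals],
            "unique_reads": [uniques.get(b, 0) for b in totals],
        }
    ).sort_values("barcode", ignore_index=True)
    return records, DedupStats(per_cell, n_unmapped)


# ---------------------------------------------------------------------
# methylation calling
# ---------------------------------------------------------------------
def call_methylation(rec: AlignmentRecord, ref: Reference) -> pd.DataFrame:
    """Per-cytosine methylation calls for one aligned read.

    Raises KeyError for a chromosome absent from the reference and
    ValueError for an alignment outside chromosome bounds or a missing
    conversion-strand tag (callers batching records should pre-filter;
    see :func:`extract_cells`).
    """
    if rec.conversion_strand not in ("CT", "GA"):
        raise ValueError(f"read {rec.name}: missing/invalid conversion strand tag")
    seq = ref.seq_array(rec.chrom)
    if rec.start < 0 or rec.end > seq.size:
        raise ValueError(f"read {rec.name}: alignment outside {rec.chrom} bounds")
    read = np.frombuffer(rec.seq.upper().encode(), dtype="S1")
    window = seq[rec.start : rec.end]
    if rec.conversion_strand == "CT":
        ctx = ref.fwd_context(rec.chrom)[rec.start : rec.end]
        site = ctx > 0  # reference C on forward strand
        meth = read == b"C"
        unmeth = read == b"T"
        strand = "+"
    else:
        ctx = ref.rev_context(rec.chrom)[rec.start : rec.end]
        site = ctx > 0  # reference G = C on reverse strand
        meth = read == b"G"
        unmeth = read == b"A"
        strand = "-"
    callable_ = site & (meth | unmeth)
    rel = np.flatnonzero(callable_)
    return pd.DataFrame(
        {
            "barcode": rec.barcode,
            "chrom": rec.chrom,
            "pos": rec.start + rel,
            "strand": strand,
            "context": np.where(ctx[rel] == CTX_CG, "CG", "CH"),
            "state": meth[rel].astype(np.int8),
        }
    )


def extract_calls(
    alignments: Iterable[AlignmentRecord], ref: Reference
) -> tuple[pd.DataFrame, int]:
    """All methylation calls for a record stream.

    Returns (call table, number of records skipped for a missing
    conversion-strand tag).  The table is sorted by
    (context, chrom, barcode, pos).
    """
    frames = []
    n_skipped = 0
    for rec in alignments:
        if rec.conversion_strand not in ("CT", "GA"):
            n_skipped += 1
            continue
        frames.append(call_methylation(rec, ref))
    if frames:
        calls = pd.concat(frames, ignore_index=True)
        calls = calls.sort_values(
            ["context", "chrom", "barcode", "pos"], ignore_index=True
        )
    else:
        calls = pd.DataFrame(columns=CALL_COLUMNS)
    return calls, n_skipped


def extract_cells(
    alignments: Iterable[AlignmentRecord],
    ref: Reference,
    outdir: str | os.PathLike,
) -> tuple[pd.DataFrame, int]:
    """Call methylation and write the per-context/per-chromosome layout.

    Files land in ``{outdir}/{CG|CH}/{chrom}.tsv`` sorted by
    (barcode, pos); both context directories are always created so an
    empty input still yields a valid layout.
    """
    calls, n_skipped = extract_calls(alignments, ref)
    for context in ("CG", "CH"):
        ctx_dir = os.path.join(outdir, context)
        os.makedirs(ctx_dir, exist_ok=True)
        sub = calls[calls["context"] == context]
        for chrom, chunk in sub.groupby("chrom", sort=True):
            chunk = chunk.sort_values(["barcode", "pos"])
            chunk.to_csv(os.path.join(ctx_dir, f"{chrom}.tsv"), sep="\t", index=False)
    return calls, n_skipped


def read_call_layout(outdir: str | os.PathLike) -> pd.DataFrame:
    """Load a {context}/{chrom}.tsv layout back into one call table."""
    frames = []
    for context in ("CG", "CH"):
        ctx_dir = os.path.join(outdir, context)
        if not os.path.isdir(ctx_dir):
            continue
        for fname in sorted(os.listdir(ctx_dir)):
            if fname.endswith(".tsv"):
                frames.append(pd.read_csv(os.path.join(ctx_dir, fname), sep="\t"))
    if not frames:
        return pd.DataFrame(columns=CALL_COLUMNS)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------
# per-cell QC
# ---------------------------------------------------------------------
def cell_qc(
    calls: pd.DataFrame,
    min_unique_reads: int,
    max_global_mch: float = 0.10,
    read_stats: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-cell QC profiles.

    A cell passes iff it has at least ``min_unique_reads`` unique reads
    and a global mCH fraction strictly below ``max_global_mch`` (cells
    with no CH calls fail: an undefined conversion-noise estimate is
    not evidence of quality).  ``read_stats`` is the per-cell frame from
    :func:`dedup`; without it read counts are reported as 0 and only
    the mCH criterion can pass cells, so supply it in real use.
    """
    if not 0.0 < max_global_mch <= 1.0:
        raise ValueError("max_global_mch must be in (0, 1]")
    if len(calls) == 0:
        return pd.DataFrame(
            columns=[
                "barcode", "global_mch", "global_mcg", "covered_ch_sites",
                "covered_cg_sites", "total_reads", "unique_reads", "pass_qc",
            ]
        )
    g = calls.groupby(["barcode", "context"])
    agg = g["state"].agg(["sum", "count"]).unstack("context")
    barcodes = agg.index if len(agg) else pd.Index([], name="barcode")

    def _col(stat: str, ctx: str) -> pd.Series:
        if (stat, ctx) in agg.columns:
            return agg[(stat, ctx)].fillna(0)
        return pd.Series(0, index=barcodes, dtype=float)

    ch_m, ch_n = _col("sum", "CH"), _col("count", "CH")
    cg_m, cg_n = _col("sum", "CG"), _col("count", "CG")
    sites = calls.drop_duplicates(["barcode", "chrom", "pos", "strand"])
    site_counts = sites.groupby(["barcode", "context"]).size().unstack(fill_value=0)

    prof = pd.DataFrame(index=barcodes)
    with np.errstate(invalid="ignore", divide="ignore"):
        prof["global_mch"] = (ch_m / ch_n).where(ch_n > 0)
        prof["global_mcg"] = (cg_m / cg_n).where(cg_n > 0)
    prof["covered_ch_sites"] = (
        site_counts["CH"] if "CH" in site_counts else 0
    )
    prof["covered_cg_sites"] = (
        site_counts["CG"] if "CG" in site_counts else 0
    )
    prof = prof.fillna({"covered_ch_sites": 0, "covered_cg_sites": 0})

    if read_stats is not None:
        rs = read_stats.set_index("barcode")
        prof["total_reads"] = rs["total_reads"].reindex(barcodes).fillna(0).astype(int)
        prof["unique_reads"] = rs["unique_reads"].reindex(barcodes).fillna(0).astype(int)
    else:
        prof["total_reads"] = 0
        prof["unique_reads"] = 0

    prof["pass_qc"] = (
        (prof["unique_reads"] >= min_unique_reads)
        & prof["global_mch"].notna()
        & (prof["global_mch"] < max_global_mch)
    )
    return prof.reset_index().rename(columns={"index": "barcode"})


# ---------------------------------------------------------------------
# TSS enrichment
# ---------------------------------------------------------------------
def tss_enrichment(
    alignments: Iterable[AlignmentRecord],
    tss: pd.DataFrame,
    chrom_sizes: dict[str, int],
    signal_halfwidth: int = 100,
    background_offset: int = 1000,
    background_width: int = 200,
) -> float:
    """Library-level TSS enrichment score.

    Signal is the mean per-base read coverage in
    ``[TSS - signal_halfwidth, TSS + signal_halfwidth)``; background is
    the mean over two ``background_width`` windows centered
    ``background_offset`` bp up- and downstream (strand-aware).
    Coverage is aggregated over all TSSs before the ratio is taken.
    Returns NaN when background coverage is zero.

    ``tss`` needs columns (chrom, pos, strand).
    """
    if len(tss) == 0:
        raise ValueError("at least one TSS required")
    cov = {c: np.zeros(n + 1) for c, n in chrom_sizes.items()}
    for rec in alignments:
        if not rec.mapped or rec.chrom not in cov:
            continue
        d = cov[rec.chrom]
        d[rec.start] += 1
        d[min(rec.end, len(d) - 1)] -= 1
    cov = {c: np.cumsum(d)[:-1] for c, d in cov.items()}

    span = background_offset + background_width // 2
    profile = np.zeros(2 * span)
    n_used = 0
    for row in tss.itertuples(index=False):
        if row.chrom not in cov:
            continue
        c = cov[row.chrom]
        lo, hi = row.pos - span, row.pos + span
        if lo < 0 or hi > len(c):
            continue
        window = c[lo:hi]
        if getattr(row, "strand", "+") == "-":
            window = window[::-1]
        profile += window
        n_used += 1
    if n_used == 0:
        raise ValueError("no TSS fully inside the genome with the required flanks")

    center = span
    signal = profile[center - signal_halfwidth : center + signal_halfwidth].mean()
    half_bg = background_width // 2
    up = profile[
        center - background_offset - half_bg : center - background_offset + half_bg
    ].mean()
    down = profile[
        center + background_offset - half_bg : center + background_offset + half_bg
    ].mean()
    background = (up + down) / 2.0
    if background == 0:
        return float("nan")
    return float(signal / background)
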