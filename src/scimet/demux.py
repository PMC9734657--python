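"""Three-index barcode demultiplexing and structural trimming.

Every read pair carries three cell-identifying indexes: the i5 and i7
PCR indexes (separate index reads, or embedded in the read header) and
the 8-base tagmentation index at the start of read 2.  Each index is
corrected independently against its whitelist allowing up to
``max_hamming`` (default 2) mismatches; a pair is assigned only if all
three correct uniquely, and the corrected composite barcode
``i5 + i7 + tag`` is appended to the read name after a ':' separator.

Structural trims: read 1 loses its first 10 bases (random priming
region); read 2 loses bases 1-29 (index + mosaic end) and then its last
10 bases (which may re-enter the random primer region), after removing
any perfect 3'-suffix match of the sequencing adapter.
"""

from __future__ import annotations

import gzip
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import pandas as pd
import yaml

NO_MATCH = "no_match"
AMBIGUOUS = "ambiguous"
MALFORMED = "malformed"

# common read-through adapter (Illumina TruSeq stem)
DEFAULT_ADAPTER = "AGATCGGAAGAGC"


@dataclass
class BarcodeScheme:
    """Whitelists and read-structure offsets for the three indexes."""

    tag_whitelist: list[str]
    i5_whitelist: list[str]
    i7_whitelist: list[str]
    max_hamming: int = 2
    r1_prefix_trim: int = 10
    r2_index_len: int = 8
    r2_me_len: int = 21
    r2_tail_trim: int = 10
    adapter: str = DEFAULT_ADAPTER

    def __post_init__(self) -> None:
        if self.max_hamming < 0:
            raise ValueError("max_hamming must be >= 0")
        for name in ("tag_whitelist", "i5_whitelist", "i7_whitelist"):
            wl = getattr(self, name)
            if not wl:
                raise ValueError(f"{name} is empty")
            lengths = {len(w) for w in wl}
            if len(lengths) != 1:
                raise ValueError(f"{name} entries differ in length")
            bad = set("".join(wl)) - set("ACGT")
            if bad:
                raise ValueError(f"{name} contains non-ACGT characters: {bad}")
        if len(self.tag_whitelist[0]) != self.r2_index_len:
            raise ValueError("tag whitelist length != r2_index_len")

    @property
    def r2_struct_len(self) -> int:
        return self.r2_index_len + self.r2_me_len

    @property
    def barcode_len(self) -> int:
        return len(self.i5_whitelist[0]) + len(self.i7_whitelist[0]) + self.r2_index_len

    # -- serialization -------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "BarcodeScheme":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path: str | os.PathLike) -> None:
        data = {
            "tag_whitelist": list(self.tag_whitelist),
            "i5_whitelist": list(self.i5_whitelist),
            "i7_whitelist": list(self.i7_whitelist),
            "max_hamming": self.max_hamming,
            "r1_prefix_trim": self.r1_prefix_trim,
            "r2_index_len": self.r2_index_len,
            "r2_me_len": self.r2_me_len,
            "r2_tail_trim": self.r2_tail_trim,
            "adapter": self.adapter,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


def hamming(a: str, b: str) -> int:
    """Hamming distance; N (or any non-matching symbol) is a mismatch."""
    return sum(x != y for x, y in zip(a, b))


def correct_barcode(
    observed: str, whitelist: Sequence[str], max_hamming: int = 2
) -> tuple[str | None, str]:
    """Correct one index against its whitelist.

    Returns ``(entry, "ok")`` when a unique whitelist entry lies within
    ``max_hamming``; ``(None, reason)`` otherwise, with reason one of
    ``no_match`` (nothing within range), ``ambiguous`` (>= 2 entries tie
    at the minimal distance) or ``malformed`` (length mismatch).
    """
    wl_len = len(whitelist[0])
    if len(observed) != wl_len:
        return None, MALFORMED
    best: str | None = None
    best_d = max_hamming + 1
    tied = False
    for entry in whitelist:
        d = 0
        for x, y in zip(observed, entry):
            if x != y:
                d += 1
                if d > max_hamming:
                    break
        if d < best_d:
            best, best_d, tied = entry, d, False
            if d == 0:
                return best, "ok"
        elif d == best_d:
            tied = True
    if best is None:
        return None, NO_MATCH
    if tied:
        return None, AMBIGUOUS
    return best, "ok"


class _Corrector:
    """Memoized whitelist correction (observed index -> result)."""

    def __init__(self, whitelist: Sequence[str], max_hamming: int):
        self.whitelist = list(whitelist)
        self.max_hamming = max_hamming
        self._exact = set(self.whitelist)
        self._cache: dict[str, tuple[str | None, str]] = {}

    def __call__(self, observed: str) -> tuple[str | None, str]:
        if observed in self._exact:
            return observed, "ok"
        hit = self._cache.get(observed)
        if hit is None:
            hit = correct_barcode(observed, self.whitelist, self.max_hamming)
            self._cache[observed] = hit
        return hit


def adapter_tail_trim(
    seq: str,
    adapter: str = DEFAULT_ADAPTER,
    tail: int = 10,
    min_overlap: int = 5,
) -> str:
    """Remove a 3' adapter read-through, then the last ``tail`` bases.

    The adapter match is a perfect suffix/prefix overlap of at least
    ``min_overlap`` bases (the longest such overlap wins); returns the
    empty string when the read is shorter than the trim.
    """
    if adapter:
        for k in range(min(len(adapter), len(seq)), min_overlap - 1, -1):
            if seq.endswith(adapter[:k]):
                seq = seq[:-k]
                break
    if len(seq) <= tail:
        return ""
    return seq[:-tail]


@dataclass
class DemuxResult:
    """Assignment bookkeeping for one demultiplexing run."""

    n_pairs: int = 0
    n_assigned: int = 0
    rejects: Counter = field(default_factory=Counter)
    per_barcode: Counter = field(default_factory=Counter)
    assignments: list[tuple[str, str | None, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return sum(self.rejects.values())

    def summary_frame(self) -> pd.DataFrame:
        rows = [("assigned", self.n_assigned)]
        rows += [(f"rejected_{k}", v) for k, v in sorted(self.rejects.items())]
        rows.append(("total_pairs", self.n_pairs))
        return pd.DataFrame(rows, columns=["category", "read_pairs"])

    def write_summary(self, path: str | os.PathLike) -> None:
        self.summary_frame().to_csv(path, sep="\t", index=False)


def _fastq_records(source) -> Iterator[tuple[str, str]]:
    """(name, sequence) pairs from a path, or pass through an iterable."""
    if isinstance(source, (str, os.PathLike)):
        import pysam

        with pysam.FastxFile(str(source)) as fh:
            for rec in fh:
                yield rec.name, rec.sequence
    else:
        for item in source:
            yield item[0], item[1]


def _header_indexes(name: str, i5_len: int, i7_len: int) -> tuple[str, str] | None:
    """Parse 'i7+i5' from the final ':'-field of an Illumina-style header."""
    last = name.rsplit(":", 1)[-1]
    if "+" not in last:
        return None
    i7, _, i5 = last.partition("+")
    if len(i7) != i7_len or len(i5) != i5_len:
        return None
    return i5, i7


def demultiplex(
    r1,
    r2,
    scheme: BarcodeScheme,
    i1=None,
    i2=None,
    out_prefix: str | None = None,
    tail_trim: bool = True,
) -> DemuxResult:
    """Assign, correct and trim a read-pair stream.

    ``r1``/``r2`` (and optional index reads ``i1`` = i7, ``i2`` = i5)
    are FASTQ paths or iterables of ``(name, sequence)``.  With no index
    files the i5/i7 indexes are read from the read-1 header
    (``...:<i7>+<i5>`` dialect).  Already-tagged input (read names
    ending in ':<valid composite barcode>') passes through unchanged,
    making demultiplexing idempotent.

    When ``out_prefix`` is given, assigned pairs are written to
    ``{out_prefix}_R1.fastq.gz`` / ``_R2.fastq.gz``; the result object
    records every pair's assignment either way.
    """
    corr_tag = _Corrector(scheme.tag_whitelist, scheme.max_hamming)
    corr_i5 = _Corrector(scheme.i5_whitelist, scheme.max_hamming)
    corr_i7 = _Corrector(scheme.i7_whitelist, scheme.max_hamming)
    i5_len = len(scheme.i5_whitelist[0])
    i7_len = len(scheme.i7_whitelist[0])
    i5_set, i7_set = set(scheme.i5_whitelist), set(scheme.i7_whitelist)
    tag_set = set(scheme.tag_whitelist)

    res = DemuxResult()
    out1 = out2 = None
    if out_prefix is not None:
        os.makedirs(os.path.dirname(out_prefix) or ".", exist_ok=True)
        out1 = gzip.open(f"{out_prefix}_R1.fastq.gz", "wt")
        out2 = gzip.open(f"{out_prefix}_R2.fastq.gz", "wt")

    def _already_tagged(name: str) -> bool:
        bc = name.rsplit(":", 1)[-1]
        if len(bc) != scheme.barcode_len:
            return False
        return (
            bc[:i5_len] in i5_set
            and bc[i5_len : i5_len + i7_len] in i7_set
            and bc[i5_len + i7_len :] in tag_set
        )

    streams = [_fastq_records(r1), _fastq_records(r2)]
    idx_streams = None
    if i1 is not None and i2 is not None:
        idx_streams = [_fastq_records(i1), _fastq_records(i2)]

    try:
        for pair in zip(*streams):
            (name1, seq1), (name2, seq2) = pair
            res.n_pairs += 1

            if _already_tagged(name1):
                # idempotence: pass through previously demultiplexed output
                bc = name1.rsplit(":", 1)[-1]
                res.n_assigned += 1
                res.per_barcode[bc] += 1
                res.assignments.append((name1, bc, "ok"))
                if out1 is not None:
                    out1.write(f"@{name1}\n{seq1}\n+\n{'I' * len(seq1)}\n")
                    out2.write(f"@{name2}\n{seq2}\n+\n{'I' * len(seq2)}\n")
                continue

            if idx_streams is not None:
                try:
                    _, i7_obs = next(idx_streams[0])
                    _, i5_obs = next(idx_streams[1])
                except StopIteration:
                    res.rejects[MALFORMED] += 1
                    res.assignments.append((name1, None, MALFORMED))
                    continue
            else:
                parsed = _header_indexes(name1, i5_len, i7_len)
                if parsed is None:
                    res.rejects[MALFORMED] += 1
                    res.assignments.append((name1, None, MALFORMED))
                    continue
                i5_obs, i7_obs = parsed

            if len(seq2) < scheme.r2_struct_len:
                res.rejects[MALFORMED] += 1
                res.assignments.append((name1, None, MALFORMED))
                continue
            tag_obs = seq2[: scheme.r2_index_len]

            status = "ok"
            parts = []
            for corrector, obs in (
                (corr_i5, i5_obs),
                (corr_i7, i7_obs),
                (corr_tag, tag_obs),
            ):
                entry, st = corrector(obs)
                if entry is None:
                    status = st
                    break
                parts.append(entry)
            if status != "ok":
                res.rejects[status] += 1
                res.assignments.append((name1, None, status))
                continue

            barcode = "".join(parts)
            trimmed1 = seq1[scheme.r1_prefix_trim :]
            trimmed2 = seq2[scheme.r2_struct_len :]
            if tail_trim:
                trimmed2 = adapter_tail_trim(
                    trimmed2, scheme.adapter, scheme.r2_tail_trim
                )
            if not trimmed1 or not trimmed2:
                # too short after trimming; counted as a rejection so
                # assigned + rejected still equals the input pair count
                res.rejects["dropped_short"] += 1
                res.assignments.append((name1, barcode, "dropped_short"))
                continue
            res.n_assigned += 1
            res.per_barcode[barcode] += 1
            res.assignments.append((name1, barcode, "ok"))
            if out1 is not None:
                tagged = f"{name1}:{barcode}"
                out1.write(f"@{tagged}\n{trimmed1}\n+\n{'I' * len(trimmed1)}\n")
                out2.write(f"@{tagged}\n{trimmed2}\n+\n{'I' * len(trimmed2)}\n")
    finally:
        if out1 is not None:
            out1.close()
            out2.close()
    return res
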