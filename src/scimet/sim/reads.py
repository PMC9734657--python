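"""Read-level simulation: molecules, bisulfite conversion, PCR and errors.

Each unique molecule is a genomic fragment from one cell.  Its two
sequenced segments follow the library structure:

    read 1:  [10 nt H-composition random primer][genomic]
    read 2:  [8 nt tag index][21 nt mosaic end][genomic ... 10 nt tail]

plus separate i7/i5 index reads.  Bisulfite chemistry happens once per
molecule (conversion strand drawn OT/OB at 50/50, conversion noise fixed
before PCR); PCR then emits 1 + Poisson(duplicate_rate) copies, each with
fresh sequencing/index errors.  The truth SAM doubles as the
aligner-output stand-in: every emitted read segment is recorded at its
true coordinates in reference-forward projection with the conversion
strand in the ``XG`` tag, so the downstream extractor runs on it
unchanged.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ..records import AlignmentRecord
from ..reference import CTX_CG
from .cells import CellAssignment
from .design import (
    CellTypeProfile,
    ExperimentDesign,
    ME_SEGMENT,
    PCR_INDEX_LEN,
    R1_PRIMER_LEN,
    R2_STRUCT_LEN,
    R2_TAIL_TRIM,
    TAG_INDEX_LEN,
)
from .genome import SpeciesGenome

_H_BASES = np.frombuffer(b"ACT", dtype="S1")  # H-composition random primer
_BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------
# ground-truth site states
# ---------------------------------------------------------------------
@dataclass
class _ChromStates:
    fwd_pos: np.ndarray  # C positions, forward strand
    rev_pos: np.ndarray  # G positions (C on reverse strand)
    fwd_state: np.ndarray  # (n_cells, n_fwd) uint8
    rev_state: np.ndarray  # (n_cells, n_rev) uint8


@dataclass
class SimTruth:
    """Ground truth of a simulated experiment."""

    cell_table: pd.DataFrame
    molecule_table: pd.DataFrame
    # species -> cell_id -> row in the state matrices
    cell_rows: dict[str, dict[int, int]]
    states: dict[str, _ChromStates]  # keyed by chromosome name
    chrom_species: dict[str, str] = field(default_factory=dict)

    def site_state(self, cell_id: int, chrom: str, pos: int, strand: str) -> int:
        """True methylation state (1/0) of one cytosine in one cell."""
        st = self.states[chrom]
        positions = st.fwd_pos if strand == "+" else st.rev_pos
        mat = st.fwd_state if strand == "+" else st.rev_state
        i = int(np.searchsorted(positions, pos))
        if i >= len(positions) or positions[i] != pos:
            raise KeyError(f"no cytosine at {chrom}:{pos}:{strand}")
        species = self.cell_table.loc[
            self.cell_table["cell_id"] == cell_id, "species"
        ].iloc[0]
        return int(mat[self.cell_rows[species][cell_id], i])

    def type_mch(self, cell_ids: Sequence[int]) -> float:
        """Empirical global mCH of the true states of a set of cells."""
        num = den = 0
        ids = set(int(c) for c in cell_ids)
        by_species = self.cell_table.set_index("cell_id")["species"]
        for chrom, st in self.states.items():
            ch_f = self._ch_mask[chrom]["fwd"]
            ch_r = self._ch_mask[chrom]["rev"]
            for cid in ids:
                if self.chrom_species.get(chrom) != by_species[cid]:
                    continue
                row = self.cell_rows[by_species[cid]].get(cid)
                if row is None:
                    continue
                num += int(st.fwd_state[row, ch_f].sum()) + int(
                    st.rev_state[row, ch_r].sum()
                )
                den += int(ch_f.sum()) + int(ch_r.sum())
        return num / den if den else float("nan")

    _ch_mask: dict = field(default_factory=dict, repr=False)


@dataclass
class SimReads:
    """In-memory simulated read set plus ground truth.

    FASTQ entries are (name, sequence) pairs (constant quality is added
    on write); ``alignments`` are the truth alignments for every emitted
    read segment.
    """

    r1: list[tuple[str, str]]
    r2: list[tuple[str, str]]
    i1: list[tuple[str, str]]  # i7 index read
    i2: list[tuple[str, str]]  # i5 index read
    alignments: list[AlignmentRecord]
    truth: SimTruth
    chrom_sizes: dict[str, int]

    def write_fastqs(self, outdir: str | os.PathLike, prefix: str = "sim") -> dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        paths = {}
        for tag, records in (("R1", self.r1), ("R2", self.r2), ("I1", self.i1), ("I2", self.i2)):
            path = os.path.join(outdir, f"{prefix}_{tag}.fastq.gz")
            with gzip.open(path, "wt") as fh:
                for name, seq in records:
                    fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
            paths[tag] = path
        return paths

    def write_sam(self, path: str | os.PathLike) -> None:
        import pysam

        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": n} for c, n in self.chrom_sizes.items()],
        }
        names = list(self.chrom_sizes)
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for rec in self.alignments:
                a = pysam.AlignedSegment(out.header)
                a.query_name = rec.name
                a.query_sequence = rec.seq
                a.flag = 0 if rec.strand == "+" else 16
                a.reference_id = names.index(rec.chrom)
                a.reference_start = rec.start
                a.mapping_quality = 42
                a.cigarstring = f"{len(rec.seq)}M"
                a.query_qualities = pysam.qualitystring_to_array("I" * len(rec.seq))
                a.set_tag("XG", rec.conversion_strand, "Z")
                out.write(a)

    def write_truth_tables(self, outdir: str | os.PathLike) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.truth.cell_table.to_csv(
            os.path.join(outdir, "truth_cells.tsv"), sep="\t", index=False
        )
        self.truth.molecule_table.to_csv(
            os.path.join(outdir, "truth_molecules.tsv"), sep="\t", index=False
        )


# ---------------------------------------------------------------------
def _profile_p_vectors(
    profile: CellTypeProfile, genome: SpeciesGenome
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (p_fwd, p_rev) site methylation probabilities."""
    out = {}
    for chrom in genome.chroms:
        fwd_pos = np.flatnonzero(genome.fwd_context(chrom) > 0)
        rev_pos = np.flatnonzero(genome.rev_context(chrom) > 0)
        fwd_ctx = genome.fwd_context(chrom)[fwd_pos]
        rev_ctx = genome.rev_context(chrom)[rev_pos]
        p_f = np.where(fwd_ctx == CTX_CG, profile.global_mcg, profile.global_mch)
        p_r = np.where(rev_ctx == CTX_CG, profile.global_mcg, profile.global_mch)
        for m in profile.marker_regions:
            if m.chrom != chrom:
                continue
            want = CTX_CG if m.context == "CG" else 2
            sel_f = (fwd_pos >= m.start) & (fwd_pos < m.end) & (fwd_ctx == want)
            sel_r = (rev_pos >= m.start) & (rev_pos < m.end) & (rev_ctx == want)
            p_f = np.where(sel_f, m.meth_prob, p_f)
            p_r = np.where(sel_r, m.meth_prob, p_r)
        out[chrom] = (p_f, p_r)
    return out


def draw_site_states(
    genomes: Mapping[str, SpeciesGenome],
    cell_table: pd.DataFrame,
    profiles: Sequence[CellTypeProfile],
    rng: np.random.Generator,
) -> SimTruth:
    """Draw the true methylation state of every cytosine in every cell."""
    by_label = {p.type_label: p for p in profiles}
    missing = set(cell_table["cell_type"]) - set(by_label)
    if missing:
        raise ValueError(f"no profile for cell types: {sorted(missing)}")

    cell_rows: dict[str, dict[int, int]] = {}
    states: dict[str, _ChromStates] = {}
    ch_mask: dict[str, dict[str, np.ndarray]] = {}
    chrom_species: dict[str, str] = {}

    for species, genome in genomes.items():
        sub = cell_table[cell_table["species"] == species]
        ids = sub["cell_id"].to_numpy()
        cell_rows[species] = {int(c): i for i, c in enumerate(ids)}
        type_labels = sorted(set(sub["cell_type"]))
        type_idx = sub["cell_type"].map({t: i for i, t in enumerate(type_labels)}).to_numpy()
        for chrom in genome.chroms:
            fwd_pos = np.flatnonzero(genome.fwd_context(chrom) > 0)
            rev_pos = np.flatnonzero(genome.rev_context(chrom) > 0)
            p_f = np.empty((len(type_labels), len(fwd_pos)))
            p_r = np.empty((len(type_labels), len(rev_pos)))
            for i, t in enumerate(type_labels):
                pf, pr = _profile_p_vectors(by_label[t], genome)[chrom]
                p_f[i], p_r[i] = pf, pr
            fwd_state = np.empty((len(ids), len(fwd_pos)), dtype=np.uint8)
            rev_state = np.empty((len(ids), len(rev_pos)), dtype=np.uint8)
            chunk = 256  # bound the temporary float draw
            for lo in range(0, len(ids), chunk):
                hi = min(lo + chunk, len(ids))
                pf = p_f[type_idx[lo:hi]]
                pr = p_r[type_idx[lo:hi]]
                fwd_state[lo:hi] = rng.random(pf.shape) < pf
                rev_state[lo:hi] = rng.random(pr.shape) < pr
            states[chrom] = _ChromStates(fwd_pos, rev_pos, fwd_state, rev_state)
            chrom_species[chrom] = species
            ch_mask[chrom] = {
                "fwd": genome.fwd_context(chrom)[fwd_pos] == 2,
                "rev": genome.rev_context(chrom)[rev_pos] == 2,
            }

    truth = SimTruth(cell_table.copy(), pd.DataFrame(), cell_rows, states, chrom_species)
    truth._ch_mask = ch_mask
    return truth


def _apply_seq_errors(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return arr
    out = arr.copy()
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    if hit.size:
        # substitute with a uniformly random *different* base
        shift = rng.integers(1, 4, size=hit.size)
        idx = np.searchsorted(_BASES, out[hit])
        out[hit] = _BASES[(idx + shift) % 4]
    return out


def _mutate_index(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1")
    return _apply_seq_errors(arr, rate, rng).tobytes().decode()


def simulate_reads(
    genomes: Sequence[SpeciesGenome],
    assignment: CellAssignment,
    profiles: Sequence[CellTypeProfile],
    seed: int | None = None,
) -> SimReads:
    """Simulate the full read set for an assigned experiment.

    Returns an in-memory :class:`SimReads`; call its writers to produce
    gzipped FASTQs / truth SAM / truth TSVs.
    """
    design = assignment.design
    rng = np.random.default_rng(design.seed + 1 if seed is None else seed)
    genome_of = {g.species_label: g for g in genomes}
    missing = set(assignment.cell_table["species"]) - set(genome_of)
    if missing:
        raise ValueError(f"no genome for species: {sorted(missing)}")

    truth = draw_site_states(genome_of, assignment.cell_table, profiles, rng)

    g1 = design.read_length - R1_PRIMER_LEN
    g2 = design.read_length - R2_STRUCT_LEN
    frag_len = g1 + g2
    for g in genomes:
        for chrom, size in g.chrom_sizes().items():
            if size <= frag_len:
                raise ValueError(f"chromosome {chrom} shorter than a fragment")

    all_barcodes = assignment.cell_table["barcode"].unique()
    cell_table = assignment.cell_table

    r1_out: list[tuple[str, str]] = []
    r2_out: list[tuple[str, str]] = []
    i1_out: list[tuple[str, str]] = []
    i2_out: list[tuple[str, str]] = []
    alignments: list[AlignmentRecord] = []
    mol_rows: list[tuple] = []

    frag_id = 0
    for cell in cell_table.itertuples(index=False):
        genome = genome_of[cell.species]
        chroms = list(genome.chroms)
        sizes = np.array([len(genome.chroms[c]) for c in chroms], dtype=float)
        n_mol = design.reads_per_cell
        chrom_idx = rng.choice(len(chroms), size=n_mol, p=sizes / sizes.sum())
        starts = rng.integers(0, (sizes[chrom_idx] - frag_len).astype(int) + 1)
        ot = rng.random(n_mol) < 0.5
        copies = 1 + rng.poisson(design.duplicate_rate, size=n_mol)
        cross = rng.random(n_mol) < design.crosstalk_rate
        row = truth.cell_rows[cell.species][int(cell.cell_id)]

        for m in range(n_mol):
            chrom = chroms[chrom_idx[m]]
            start = int(starts[m])
            st = truth.states[chrom]
            frag = genome.seq_array(chrom)[start : start + frag_len].copy()
            conv = "CT" if ot[m] else "GA"
            if ot[m]:
                lo, hi = np.searchsorted(st.fwd_pos, (start, start + frag_len))
                pos = st.fwd_pos[lo:hi]
                meth = st.fwd_state[row, lo:hi].astype(bool)
            else:
                lo, hi = np.searchsorted(st.rev_pos, (start, start + frag_len))
                pos = st.rev_pos[lo:hi]
                meth = st.rev_state[row, lo:hi].astype(bool)
            if pos.size:
                # conversion chemistry, fixed per molecule before PCR
                keep = np.where(
                    meth,
                    rng.random(pos.size) >= design.overconversion_rate,
                    rng.random(pos.size) < design.conversion_failure_rate,
                )
                rel = pos - start
                if ot[m]:
                    frag[rel] = np.where(keep, b"C", b"T")
                else:
                    frag[rel] = np.where(keep, b"G", b"A")

            barcode = cell.barcode
            if cross[m]:
                others = all_barcodes[all_barcodes != cell.barcode]
                if others.size:
                    barcode = str(rng.choice(others))
            i5_seq = barcode[:PCR_INDEX_LEN]
            i7_seq = barcode[PCR_INDEX_LEN : 2 * PCR_INDEX_LEN]
            tag_seq = barcode[2 * PCR_INDEX_LEN :]

            primer = rng.choice(_H_BASES, size=R1_PRIMER_LEN).tobytes().decode()
            strand = "+" if ot[m] else "-"
            for mate, seg_start, seg_len in (
                (1, start, g1),
                (2, start + g1, g2 - R2_TAIL_TRIM),
            ):
                mol_rows.append(
                    (
                        2 * frag_id + (mate - 1),
                        frag_id,
                        int(cell.cell_id),
                        barcode,
                        chrom,
                        seg_start,
                        seg_start + seg_len,
                        strand,
                        mate,
                        conv,
                        int(copies[m]),
                    )
                )
            for k in range(int(copies[m])):
                frag_read = _apply_seq_errors(frag, design.seq_error_rate, rng)
                name = f"f{frag_id}c{k}"
                seq1 = frag_read[:g1].tobytes().decode()
                seq2 = frag_read[g1:].tobytes().decode()
                r1_out.append((name, primer + seq1))
                r2_out.append(
                    (
                        name,
                        _mutate_index(tag_seq, design.barcode_error_rate, rng)
                        + ME_SEGMENT
                        + seq2,
                    )
                )
                i1_out.append((name, _mutate_index(i7_seq, design.barcode_error_rate, rng)))
                i2_out.append((name, _mutate_index(i5_seq, design.barcode_error_rate, rng)))
                alignments.append(
                    AlignmentRecord(
                        name=f"{name}r1:{barcode}",
                        barcode=barcode,
                        chrom=chrom,
                        start=start,
                        strand=strand,
                        conversion_strand=conv,
                        seq=seq1,
                    )
                )
                alignments.append(
                    AlignmentRecord(
                        name=f"{name}r2:{barcode}",
                        barcode=barcode,
                        chrom=chrom,
                        start=start + g1,
                        strand=strand,
                        conversion_strand=conv,
                        seq=seq2[: g2 - R2_TAIL_TRIM],
                    )
                )
            frag_id += 1

    truth.molecule_table = pd.DataFrame(
        mol_rows,
        columns=[
            "molecule_id",
            "fragment_id",
            "cell_id",
            "barcode",
            "chrom",
            "start",
            "end",
            "strand",
            "mate",
            "conversion_strand",
            "copies",
        ],
    )
    chrom_sizes: dict[str, int] = {}
    for g in genomes:
        chrom_sizes.update(g.chrom_sizes())
    return SimReads(r1_out, r2_out, i1_out, i2_out, alignments, truth, chrom_sizes)
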