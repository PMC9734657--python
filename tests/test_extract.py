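"""Deduplication, methylation calling, per-cell QC and TSS enrichment."""

import numpy as np
import pandas as pd
import pytest

from scimet.extract import (
    call_methylation,
    cell_qc,
    dedup,
    extract_calls,
    extract_cells,
    read_alignments,
    read_call_layout,
    tss_enrichment,
)
from scimet.records import AlignmentRecord
from scimet.reference import Reference


def _rec(name="r1:bc1", bc="bc1", chrom="c", start=0, strand="+", conv="CT",
         seq="ACGT", mapped=True):
    return AlignmentRecord(name, bc, chrom, start, strand, conv, seq, mapped)


class TestDedup:
    def test_identical_key_collapses(self):
        recs = [_rec(name=f"r{i}:bc1") for i in range(3)]
        kept, stats = dedup(recs)
        assert len(kept) == 1
        assert kept[0].name == "r0:bc1"  # lexicographically smallest name

    def test_barcode_aware(self):
        recs = [_rec(name="a:bc1", bc="bc1"), _rec(name="b:bc2", bc="bc2")]
        kept, _ = dedup(recs)
        assert len(kept) == 2

    def test_strand_in_key(self):
        recs = [_rec(name="a:bc1"), _rec(name="b:bc1", strand="-", conv="GA")]
        kept, _ = dedup(recs)
        assert len(kept) == 2

    def test_order_invariance_and_idempotence(self, rng):
        recs = [
            _rec(name=f"r{i}:bc{i % 3}", bc=f"bc{i % 3}", start=int(rng.integers(0, 5)))
            for i in range(40)
        ]
        kept1, _ = dedup(recs)
        shuffled = list(recs)
        rng.shuffle(shuffled)
        kept2, _ = dedup(shuffled)
        assert kept1 == kept2
        kept3, _ = dedup(kept1)
        assert kept3 == kept1

    def test_unmapped_skipped_and_counted(self):
        recs = [_rec(), _rec(name="u", mapped=False)]
        kept, stats = dedup(recs)
        assert len(kept) == 1
        assert stats.n_unmapped == 1

    def test_matches_brute_force_and_molecule_count(self, clean_run):
        """Oracle: retained keys equal the set of unique keys; with
        coordinate-identical PCR copies the unique count equals the
        simulator's molecule count."""
        _, reads = clean_run
        kept, stats = dedup(reads.alignments)
        brute = {(r.barcode, r.chrom, r.start, r.strand) for r in reads.alignments}
        assert {(r.barcode, r.chrom, r.start, r.strand) for r in kept} == brute
        assert len(kept) == len(brute)
        assert len(kept) == len(reads.truth.molecule_table)
        per_cell = stats.per_cell
        assert (per_cell["unique_reads"] <= per_cell["total_reads"]).all()


class TestCallMethylation:
    REF = Reference({"c": "ACGT"})

    def test_ct_methylated_cg(self):
        calls = call_methylation(_rec(seq="ACGT"), self.REF)
        assert len(calls) == 1
        row = calls.iloc[0]
        assert (row["pos"], row["context"], int(row["state"])) == (1, "CG", 1)
        assert row["strand"] == "+"

    def test_ct_converted_base_unmethylated(self):
        calls = call_methylation(_rec(seq="ATGT"), self.REF)
        row = calls.iloc[0]
        assert (row["pos"], row["context"], int(row["state"])) == (1, "CG", 0)

    def test_ch_context_from_reference(self):
        ref = Reference({"c": "ACAT"})
        calls = call_methylation(_rec(seq="ACAT"), ref)
        row = calls.iloc[0]
        assert (row["pos"], row["context"], int(row["state"])) == (1, "CH", 1)

    def test_ga_strand_mirror(self):
        # reverse-strand C at the G (pos 2); GA chemistry reads G/A there
        calls = call_methylation(_rec(conv="GA", strand="-", seq="ACGT"), self.REF)
        row = calls.iloc[0]
        assert (row["pos"], row["context"], row["strand"], int(row["state"])) == (
            2, "CG", "-", 1)
        calls = call_methylation(_rec(conv="GA", strand="-", seq="ACAT"), self.REF)
        row = calls.iloc[0]
        assert int(row["state"]) == 0

    def test_mismatch_base_yields_no_call(self):
        calls = call_methylation(_rec(seq="AGGT"), self.REF)  # G over ref C
        assert len(calls) == 0

    def test_missing_tag_raises(self):
        with pytest.raises(ValueError):
            call_methylation(_rec(conv=""), self.REF)

    def test_out_of_bounds_raises(self):
        with pytest.raises(ValueError):
            call_methylation(_rec(start=2, seq="GTAA"), self.REF)

    def test_context_matches_reference_dinucleotide(self, clean_run, joint_reference):
        """Oracle re-check on simulated reads: every call context equals
        the reference dinucleotide at the call position."""
        _, reads = clean_run
        calls, _ = extract_calls(reads.alignments[:200], joint_reference)
        for row in calls.sample(min(500, len(calls)), random_state=1).itertuples():
            seq = joint_reference.chroms[row.chrom]
            if row.strand == "+":
                dinuc = seq[row.pos : row.pos + 2]
                expect = "CG" if dinuc == "CG" else "CH"
                assert seq[row.pos] == "C"
            else:
                expect = "CG" if seq[row.pos - 1 : row.pos + 1] == "CG" else "CH"
                assert seq[row.pos] == "G"
            assert row.context == expect


class TestExtractCells:
    def test_zero_noise_states_match_truth(self, clean_run, joint_reference,
                                           clean_cell_of_barcode):
        """Every call equals the simulator's true site state."""
        _, reads = clean_run
        kept, _ = dedup(reads.alignments)
        calls, n_skipped = extract_calls(kept, joint_reference)
        assert n_skipped == 0
        truth = reads.truth
        for row in calls.itertuples():
            cid = clean_cell_of_barcode[row.barcode]
            assert truth.site_state(cid, row.chrom, row.pos, row.strand) == row.state

    def test_layout_and_conservation(self, clean_run, joint_reference, tmp_path):
        _, reads = clean_run
        kept, _ = dedup(reads.alignments)
        calls, _ = extract_cells(kept, joint_reference, tmp_path)
        back = read_call_layout(tmp_path)
        assert len(back) == len(calls)
        for context in ("CG", "CH"):
            sub = calls[calls["context"] == context]
            assert (tmp_path / context).is_dir()
            for chrom in sub["chrom"].unique():
                f = tmp_path / context / f"{chrom}.tsv"
                assert f.exists()
                df = pd.read_csv(f, sep="\t")
                assert len(df) == (sub["chrom"] == chrom).sum()
                assert df["pos"].groupby(df["barcode"]).is_monotonic_increasing.all()

    def test_empty_input_valid_layout(self, joint_reference, tmp_path):
        calls, _ = extract_cells([], joint_reference, tmp_path)
        assert len(calls) == 0
        assert (tmp_path / "CG").is_dir() and (tmp_path / "CH").is_dir()

    def test_sam_roundtrip(self, clean_run, joint_reference, tmp_path):
        """Writing the truth SAM and re-reading it reproduces the calls."""
        _, reads = clean_run
        path = tmp_path / "truth.sam"
        reads.write_sam(path)
        from_file = list(read_alignments(path))
        calls_file, _ = extract_calls(from_file, joint_reference)
        calls_mem, _ = extract_calls(reads.alignments, joint_reference)
        pd.testing.assert_frame_equal(calls_file, calls_mem)


class TestCellQC:
    def _calls(self, bc, n_ch, n_meth_ch, n_cg=10, n_meth_cg=8):
        state = np.r_[np.ones(n_meth_ch), np.zeros(n_ch - n_meth_ch),
                      np.ones(n_meth_cg), np.zeros(n_cg - n_meth_cg)].astype(int)
        return pd.DataFrame(
            {
                "barcode": bc,
                "chrom": "c",
                "pos": np.arange(n_ch + n_cg),
                "strand": "+",
                "context": ["CH"] * n_ch + ["CG"] * n_cg,
                "state": state,
            }
        )

    def _stats(self, bc, unique=1000):
        return pd.DataFrame({"barcode": [bc], "total_reads": [2000],
                             "unique_reads": [unique]})

    def test_five_percent_mch_passes(self):
        calls = self._calls("b1", 1000, 50)
        prof = cell_qc(calls, min_unique_reads=100, read_stats=self._stats("b1"))
        assert prof.loc[0, "pass_qc"]
        assert abs(prof.loc[0, "global_mch"] - 0.05) < 1e-12

    def test_fifteen_percent_mch_fails(self):
        calls = self._calls("b1", 1000, 150)
        prof = cell_qc(calls, min_unique_reads=100, read_stats=self._stats("b1"))
        assert not prof.loc[0, "pass_qc"]

    def test_boundary_is_strict(self):
        calls = self._calls("b1", 1000, 100)  # exactly 10%
        prof = cell_qc(calls, min_unique_reads=100, read_stats=self._stats("b1"))
        assert not prof.loc[0, "pass_qc"]

    def test_zero_ch_calls_fails(self):
        calls = self._calls("b1", 0, 0)
        prof = cell_qc(calls, min_unique_reads=1, read_stats=self._stats("b1"))
        assert not prof.loc[0, "pass_qc"]
        assert np.isnan(prof.loc[0, "global_mch"])

    def test_read_threshold(self):
        calls = self._calls("b1", 1000, 50)
        prof = cell_qc(calls, min_unique_reads=5000, read_stats=self._stats("b1"))
        assert not prof.loc[0, "pass_qc"]

    def test_noise_free_mch_recovers_profile(self, clean_run, joint_reference,
                                             clean_cell_of_barcode, base_profiles):
        _, reads = clean_run
        kept, stats = dedup(reads.alignments)
        calls, _ = extract_calls(kept, joint_reference)
        prof = cell_qc(calls, min_unique_reads=1, read_stats=stats.per_cell)
        truth = reads.truth.cell_table.set_index("barcode")
        by_label = {p.type_label: p for p in base_profiles}
        for row in prof.itertuples():
            expect = by_label[truth.loc[row.barcode, "cell_type"]].global_mch
            n = calls[(calls["barcode"] == row.barcode) & (calls["context"] == "CH")]
            se = np.sqrt(expect * (1 - expect) / len(n))
            assert abs(row.global_mch - expect) < 4 * se


class TestTSSEnrichment:
    L = 20_000

    def _uniform(self, depth=1):
        return [
            _rec(name=f"r{i}.{k}", start=i, seq="A" * 50)
            for i in range(0, self.L - 50)
            for k in range(depth)
        ]

    def _tss(self, pos=10_000, strand="+"):
        return pd.DataFrame({"chrom": ["c"], "pos": [pos], "strand": [strand]})

    def test_uniform_coverage_scores_one(self):
        score = tss_enrichment(self._uniform(), self._tss(), {"c": self.L})
        assert score == pytest.approx(1.0, abs=0.02)

    def test_doubled_center_scores_two(self):
        boost = [_rec(name=f"b{k}", start=9_900, seq="A" * 200) for k in range(50)]
        score = tss_enrichment(self._uniform() + boost, self._tss(), {"c": self.L})
        assert score == pytest.approx(2.0, abs=0.05)

    def test_depleted_center_scores_zero(self):
        recs = [r for r in self._uniform() if not (9_750 <= r.start < 10_100)]
        score = tss_enrichment(recs, self._tss(), {"c": self.L})
        assert score == pytest.approx(0.0, abs=0.02)

    def test_zero_background_undefined(self):
        recs = [_rec(start=9_990, seq="A" * 20)]
        assert np.isnan(tss_enrichment(recs, self._tss(), {"c": self.L}))

    def test_requires_tss(self):
        with pytest.raises(ValueError):
            tss_enrichment([], pd.DataFrame(columns=["chrom", "pos", "strand"]),
                           {"c": self.L})
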