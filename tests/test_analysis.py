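"""Saturation curves, region methylation, concordance, motif profiles."""

import numpy as np
import pandas as pd
import pytest

from scimet.analysis import (
    binarize_sites,
    coverage_saturation,
    filter_calls_to_regions,
    gene_body_flank_regions,
    motif_profile,
    pairwise_similarity,
    promoter_call_regions,
    region_methylation,
    regions_from_tss,
    similarity_by_cluster,
)


# ---------------------------------------------------------------------
class TestRegionPresets:
    def test_strand_aware_promoters(self):
        tss = pd.DataFrame(
            {"name": ["g+", "g-"], "chrom": ["c", "c"], "pos": [10_000, 10_000],
             "strand": ["+", "-"]}
        )
        r = promoter_call_regions(tss)
        plus = r[r["name"] == "g+"].iloc[0]
        minus = r[r["name"] == "g-"].iloc[0]
        assert (plus["start"], plus["end"]) == (8_500, 11_000)
        assert (minus["start"], minus["end"]) == (9_000, 11_500)

    def test_clipping(self):
        tss = pd.DataFrame({"name": ["g"], "chrom": ["c"], "pos": [100], "strand": ["+"]})
        r = regions_from_tss(tss, 5000, 2500, {"c": 1000})
        assert (r.iloc[0]["start"], r.iloc[0]["end"]) == (0, 1000)

    def test_gene_body_flank(self):
        genes = pd.DataFrame(
            {"name": ["g"], "chrom": ["c"], "start": [1000], "end": [5000],
             "strand": ["+"]}
        )
        r = gene_body_flank_regions(genes, 2000, {"c": 6000})
        assert (r.iloc[0]["start"], r.iloc[0]["end"]) == (0, 6000)


# ---------------------------------------------------------------------
class TestCoverageSaturation:
    def test_full_coverage_one_cell(self):
        cells = [np.arange(100) for _ in range(5)]
        sat = coverage_saturation(cells, 100, n_iter=10, n_cells=5, seed=0)
        assert set(sat.cells_to_threshold) == {1.0}

    def test_disjoint_ten_percent_needs_eight(self):
        cells = [np.arange(i * 100, (i + 1) * 100) for i in range(10)]
        sat = coverage_saturation(cells, 1000, n_iter=25, n_cells=10,
                                  threshold=0.8, seed=1)
        assert set(sat.cells_to_threshold) == {8.0}

    def test_independent_twenty_percent_close_to_eight(self, rng):
        cells = [rng.choice(1000, 200, replace=False) for _ in range(40)]
        sat = coverage_saturation(cells, 1000, n_iter=100, n_cells=30,
                                  threshold=0.8, seed=2)
        # smallest n with 1 - 0.8^n >= 0.8 is 8
        assert abs(sat.mean_cells_to_threshold - 8) <= 1

    def test_curves_monotone_bounded(self, rng):
        cells = [rng.choice(500, rng.integers(10, 80), replace=False)
                 for _ in range(30)]
        sat = coverage_saturation(cells, 500, n_iter=20, n_cells=25, seed=3)
        assert (np.diff(sat.curves, axis=1) >= 0).all()
        assert (sat.curves <= 1).all()

    def test_variance_shrinks_with_cells(self, rng):
        cells = [rng.choice(500, 50, replace=False) for _ in range(30)]
        sat = coverage_saturation(cells, 500, n_iter=50, n_cells=30, seed=4)
        assert sat.curves[:, -1].std() <= sat.curves[:, 2].std()

    def test_never_reached_is_inf(self):
        cells = [np.arange(10) for _ in range(5)]
        sat = coverage_saturation(cells, 1000, n_iter=5, n_cells=5, seed=5)
        assert np.isinf(sat.cells_to_threshold).all()

    def test_validation(self):
        with pytest.raises(ValueError):
            coverage_saturation([np.arange(5)], 0)
        with pytest.raises(ValueError):
            coverage_saturation([np.arange(5)], 10, n_cells=2)


# ---------------------------------------------------------------------
def _calls_for(bc, n, k_meth, start=0, context="CG"):
    state = np.r_[np.ones(k_meth), np.zeros(n - k_meth)].astype(int)
    return pd.DataFrame(
        {"barcode": bc, "chrom": "c", "pos": np.arange(start, start + n),
         "strand": "+", "context": context, "state": state}
    )


class TestRegionMethylation:
    REGIONS = pd.DataFrame(
        {"name": ["r1"], "chrom": ["c"], "start": [0], "end": [100], "strand": ["+"]}
    )

    def test_zscore_example(self):
        calls = pd.concat(
            [_calls_for("c0", 100, 20), _calls_for("c1", 100, 40),
             _calls_for("c2", 100, 60)]
        )
        labels = pd.Series({"c0": 0, "c1": 1, "c2": 2})
        meth, z = region_methylation(calls, self.REGIONS, labels)
        assert meth["r1"].tolist() == pytest.approx([0.2, 0.4, 0.6])
        assert z["r1"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_identical_values_zscore_zero(self):
        calls = pd.concat([_calls_for(f"c{i}", 100, 30) for i in range(3)])
        labels = pd.Series({f"c{i}": i for i in range(3)})
        _, z = region_methylation(calls, self.REGIONS, labels)
        assert z["r1"].tolist() == pytest.approx([0.0, 0.0, 0.0])

    def test_cluster_without_calls_excluded(self):
        regions = pd.DataFrame(
            {"name": ["r1", "r2"], "chrom": ["c", "c"], "start": [0, 200],
             "end": [100, 300], "strand": ["+", "+"]}
        )
        calls = pd.concat(
            [_calls_for("c0", 100, 20), _calls_for("c1", 100, 80),
             _calls_for("c2", 50, 10, start=200)]
        )
        labels = pd.Series({"c0": 0, "c1": 1, "c2": 2})
        meth, z = region_methylation(calls, regions, labels)
        assert np.isnan(meth.loc[2, "r1"]) is np.True_ or np.isnan(meth.loc[2, "r1"])
        assert np.isnan(z.loc[2, "r1"])
        # r2 has calls only from cluster 2
        assert meth.loc[2, "r2"] == pytest.approx(0.2)

    def test_pooling_conserves_counts(self, rng):
        """Pooled fraction equals the coverage-weighted per-cell mean."""
        frames, labels = [], {}
        for i in range(6):
            n = int(rng.integers(20, 80))
            frames.append(_calls_for(f"c{i}", n, int(rng.integers(0, n))))
            labels[f"c{i}"] = 0
        calls = pd.concat(frames)
        meth, _ = region_methylation(calls, self.REGIONS, pd.Series(labels))
        assert meth.loc[0, "r1"] == pytest.approx(calls["state"].mean())

    def test_marker_promoter_recovered(self):
        """A promoter hypomethylated only in one type gets that
        cluster's minimum z-score."""
        from scimet.sim import CellTypeProfile, MarkerRegion, make_genomes, simulate_site_calls

        g, _ = make_genomes(1, 20_000, 0.42, seed=31)
        chrom = next(iter(g.chroms))
        marker = MarkerRegion(chrom, 5_000, 7_000, "CG", 0.05)
        profiles = [
            CellTypeProfile("typeA", 0.02, 0.8, (marker,)),
            CellTypeProfile("typeB", 0.02, 0.8),
            CellTypeProfile("typeC", 0.02, 0.8),
        ]
        types = ["typeA"] * 20 + ["typeB"] * 20 + ["typeC"] * 20
        calls = simulate_site_calls(g, types, profiles, 1200, seed=32,
                                    contexts=("CG",))
        labels = pd.Series(
            {bc: t for bc, t in zip(sorted(calls["barcode"].unique()), types)}
        )
        regions = pd.DataFrame(
            {"name": ["marker", "bg"], "chrom": [chrom, chrom],
             "start": [5_000, 10_000], "end": [7_000, 12_000],
             "strand": ["+", "+"]}
        )
        _, z = region_methylation(calls, regions, labels)
        assert z["marker"].idxmin() == "typeA"
        assert z.loc["typeA", "marker"] < -1


# ---------------------------------------------------------------------
class TestPairwiseSimilarity:
    def _states(self, spec):
        """spec: {barcode: array of 0/1 states over positions 0..n}."""
        frames = []
        for bc, states in spec.items():
            frames.append(
                pd.DataFrame(
                    {"barcode": bc, "chrom": "c", "pos": np.arange(len(states)),
                     "strand": "+", "state": np.asarray(states, dtype=int)}
                )
            )
        return pd.concat(frames, ignore_index=True)

    def test_identical_cells(self):
        st = np.array([0, 1, 1, 0, 1])
        conc = pairwise_similarity(self._states({"a": st, "b": st}))
        assert conc.loc["a", "b"] == 1.0

    def test_complementary_cells(self):
        st = np.array([0, 1, 1, 0, 1])
        conc = pairwise_similarity(self._states({"a": st, "b": 1 - st}))
        assert conc.loc["a", "b"] == 0.0

    def test_independent_half_methylated(self, rng):
        a = rng.integers(0, 2, 12_000)
        b = rng.integers(0, 2, 12_000)
        conc = pairwise_similarity(self._states({"a": a, "b": b}))
        assert conc.loc["a", "b"] == pytest.approx(0.5, abs=0.02)

    def test_symmetric_unit_diagonal_order_invariant(self, rng):
        spec = {f"c{i}": rng.integers(0, 2, 50) for i in range(5)}
        conc = pairwise_similarity(self._states(spec))
        np.testing.assert_allclose(conc.values, conc.values.T)
        assert (np.diag(conc.values) == 1.0).all()
        spec2 = dict(reversed(list(spec.items())))
        conc2 = pairwise_similarity(self._states(spec2))
        pd.testing.assert_frame_equal(conc, conc2)

    def test_min_shared_sites(self):
        states = self._states({"a": [1, 0], "b": [1, 1]})
        conc = pairwise_similarity(states, min_shared_sites=5)
        assert np.isnan(conc.loc["a", "b"])

    def test_no_shared_sites_missing(self):
        frames = self._states({"a": [1, 0, 1]})
        other = pd.DataFrame(
            {"barcode": "b", "chrom": "c", "pos": [10, 11], "strand": "+",
             "state": [1, 0]}
        )
        conc = pairwise_similarity(pd.concat([frames, other]))
        assert np.isnan(conc.loc["a", "b"])

    def test_binarize_ties_go_methylated(self):
        calls = pd.DataFrame(
            {"barcode": ["a"] * 2, "chrom": ["c"] * 2, "pos": [5, 5],
             "strand": ["+"] * 2, "context": ["CG"] * 2, "state": [1, 0]}
        )
        st = binarize_sites(calls)
        assert len(st) == 1 and st.iloc[0]["state"] == 1

    def test_within_exceeds_between_on_typed_simulation(self):
        from scimet.sim import CellTypeProfile, MarkerRegion, make_genomes, simulate_site_calls

        g, _ = make_genomes(1, 20_000, 0.42, seed=41)
        chrom = next(iter(g.chroms))
        mk = lambda lo, hi, p: MarkerRegion(chrom, lo, hi, "CG", p)
        profiles = [
            CellTypeProfile("t0", 0.02, 0.8, (mk(0, 7_000, 0.1),)),
            CellTypeProfile("t1", 0.02, 0.8, (mk(7_000, 14_000, 0.1),)),
            CellTypeProfile("t2", 0.02, 0.8, (mk(14_000, 20_000, 0.1),)),
        ]
        types = ["t0"] * 15 + ["t1"] * 15 + ["t2"] * 15
        calls = simulate_site_calls(g, types, profiles, 1200, seed=42,
                                    contexts=("CG",))
        labels = pd.Series(
            {bc: t for bc, t in zip(sorted(calls["barcode"].unique()), types)}
        )
        conc = pairwise_similarity(binarize_sites(calls), min_shared_sites=50)
        summary = similarity_by_cluster(conc, labels)
        assert summary.mean_within > summary.mean_between


def test_filter_calls_to_regions():
    calls = _calls_for("a", 50, 25)
    regions = pd.DataFrame(
        {"name": ["r"], "chrom": ["c"], "start": [10], "end": [20], "strand": ["+"]}
    )
    sub = filter_calls_to_regions(calls, regions)
    assert sub["pos"].between(10, 19).all()
    assert len(sub) == 10


# ---------------------------------------------------------------------
class TestMotifProfile:
    def _uniform_calls(self, p_in=0.8, dip=None, span=1000, center=1000):
        """Exact-fraction construction: 4:1 or 1:4 calls per position."""
        frames = []
        for pos in range(center - span, center + span):
            if dip is not None and dip[0] <= pos - center < dip[1]:
                m, u = 1, 4
            else:
                m, u = 4, 1
            frames.append(
                pd.DataFrame(
                    {"barcode": "x", "chrom": "c", "pos": [pos] * (m + u),
                     "strand": "+", "context": "CG", "state": [1] * m + [0] * u}
                )
            )
        return pd.concat(frames, ignore_index=True)

    LABELS = pd.Series({"x": 0})

    def _motif(self, strand="+"):
        return pd.DataFrame({"chrom": ["c"], "pos": [1000], "strand": [strand]})

    def test_uniform_methylation_flat_profile(self):
        prof = motif_profile(self._uniform_calls(), self._motif(), self.LABELS)
        assert prof.shape == (1, 100)
        assert np.allclose(prof.loc[0].to_numpy(), 0.8)

    def test_dip_recovered_in_central_bins_only(self):
        prof = motif_profile(
            self._uniform_calls(dip=(-50, 50)), self._motif(), self.LABELS
        )
        vals = prof.loc[0]
        dip_bins = [o for o in vals.index if vals[o] < 0.5]
        assert dip_bins == list(range(-50, 50, 10))
        assert np.allclose([vals[o] for o in dip_bins], 0.2)

    def test_minus_strand_mirrors_plus(self):
        calls = self._uniform_calls(dip=(0, 30))  # asymmetric dip
        plus = motif_profile(calls, self._motif("+"), self.LABELS)
        minus = motif_profile(calls, self._motif("-"), self.LABELS)
        np.testing.assert_allclose(
            plus.loc[0].to_numpy(), minus.loc[0].to_numpy()[::-1]
        )

    def test_chromosome_edge_bins_skipped(self):
        calls = self._uniform_calls()
        motif = pd.DataFrame({"chrom": ["c"], "pos": [200], "strand": ["+"]})
        prof = motif_profile(calls, motif, self.LABELS)
        vals = prof.loc[0]
        assert vals[[-500, -400]].isna().all()  # nothing upstream of pos 0
        assert np.isfinite(vals[0])

    def test_span_step_validation(self):
        with pytest.raises(ValueError):
            motif_profile(self._uniform_calls(), self._motif(), self.LABELS, step=7)
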