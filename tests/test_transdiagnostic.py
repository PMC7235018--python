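"""Component selection, |Z| thresholding, overlap, ROI correlation, BH-FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symfuse import (
    FeatureMatrix,
    bh_fdr,
    correlate_with_measures,
    overlap_masks,
    roi_mean,
    select_symptom_component,
    threshold_map,
)
from symfuse.fusion import FusionResults
from symfuse.transdiagnostic import ComponentMap, OverlapMask


def _results_stub(r, p):
    """Minimal FusionResults carrying only reference correlations."""
    r = np.asarray(r, float)
    M = r.shape[1]
    return FusionResults(
        model=None, canonical_variates=[], assoc_maps=[],
        ica_unmixing=np.eye(M), joint_sources=[],
        mixing=[np.zeros((1, M))] * r.shape[0],
        ref_r=r, ref_p=np.asarray(p, float),
        modality_names=["fALFF", "GMV"][: r.shape[0]],
    )


def brute_force_bh(p, alpha=0.05):
    """Independent step-up oracle: literal scan over sorted p-values."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * alpha / m:
            k_star = i
    flags = np.zeros(m, dtype=bool)
    flags[order[:k_star]] = True
    return flags


class TestSelectSymptomComponent:
    def test_dominant_component_chosen(self):
        r = np.full((2, 6), 0.03)
        p = np.full((2, 6), 0.8)
        r[0, 2], p[0, 2] = 0.9, 1e-30
        r[1, 2], p[1, 2] = -0.88, 1e-28
        sel = select_symptom_component(_results_stub(r, p))
        assert sel.component == {"fALFF": 2, "GMV": 2}
        assert sel.r["GMV"] == pytest.approx(-0.88)

    def test_no_survivor_returns_falsy_result(self):
        r = np.full((2, 5), 0.1)
        p = np.full((2, 5), 0.7)
        sel = select_symptom_component(_results_stub(r, p))
        assert not sel
        assert sel.component == {"fALFF": None, "GMV": None}

    def test_tie_broken_toward_lower_index(self):
        r = np.zeros((1, 4))
        p = np.ones((1, 4))
        r[0, 1] = r[0, 3] = 0.8
        p[0, 1] = p[0, 3] = 1e-20
        sel = select_symptom_component(_results_stub(r[:1], p[:1]))
        assert sel.component["fALFF"] == 1

    def test_null_grid_rarely_selects(self, rng):
        hits = 0
        n_runs = 400
        for _ in range(n_runs):
            p = rng.uniform(size=(2, 8))
            r = rng.uniform(-0.2, 0.2, size=(2, 8))
            if select_symptom_component(_results_stub(r, p)):
                hits += 1
        # BH controls the family false-positive probability near alpha
        assert hits / n_runs <= 0.10


class TestThresholdMap:
    def test_strict_inequality(self):
        z = np.array([2.5, -2.5, 1.9, 0.0, 2.0])
        np.testing.assert_array_equal(
            threshold_map(ComponentMap(z)), [True, True, False, False, False])

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            threshold_map(ComponentMap(np.array([1.0, 2.0, 3.0])), z_thresh=0.0)

    def test_gaussian_exceedance_rate(self, rng):
        z = rng.standard_normal(10_000)
        frac = threshold_map(ComponentMap(z)).mean()
        assert frac == pytest.approx(0.0455, abs=0.01)


class TestOverlapMasks:
    def test_identical_masks_idempotent(self, rng):
        m = rng.random(50) < 0.4
        out = overlap_masks([m, m.copy()])
        np.testing.assert_array_equal(out.mask, m)

    def test_disjoint_masks_warn_empty(self):
        a = np.array([True, False, False])
        b = np.array([False, True, False])
        with pytest.warns(UserWarning, match="empty"):
            out = overlap_masks([a, b])
        assert out.n_voxels == 0

    def test_matches_set_intersection_oracle(self, rng):
        masks = [rng.random(200) < 0.5 for _ in range(3)]
        out = overlap_masks(masks)
        oracle = set(np.flatnonzero(masks[0]))
        for m in masks[1:]:
            oracle &= set(np.flatnonzero(m))
        assert set(np.flatnonzero(out.mask)) == oracle

    def test_adding_group_never_grows_intersection(self, rng):
        masks = [rng.random(100) < 0.6 for _ in range(4)]
        prev = overlap_masks(masks[:2]).mask
        for k in range(3, 5):
            cur = overlap_masks(masks[:k]).mask
            assert np.all(cur <= prev)
            prev = cur

    def test_output_subset_of_every_input(self, rng):
        masks = [rng.random(80) < 0.5 for _ in range(3)]
        out = overlap_masks(masks)
        for m in masks:
            assert np.all(~out.mask | m)

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError, match="geometry"):
            overlap_masks([np.ones(5, bool), np.ones(6, bool)])


class TestRoiMean:
    def test_hand_case(self):
        X = FeatureMatrix(np.array([[1.0, 3.0, 5.0]]), "GMV", ["s0"])
        mask = np.array([True, False, True])
        assert roi_mean(X, mask)[0] == pytest.approx(3.0)

    def test_single_voxel_mask_returns_column(self, rng):
        vals = rng.standard_normal((6, 4))
        X = FeatureMatrix(vals, "GMV", [f"s{i}" for i in range(6)])
        mask = np.array([False, False, True, False])
        np.testing.assert_array_equal(roi_mean(X, mask), vals[:, 2])

    def test_constant_matrix(self):
        X = FeatureMatrix(np.full((4, 5), 2.5), "GMV",
                          [f"s{i}" for i in range(4)])
        np.testing.assert_allclose(roi_mean(X, np.ones(5, bool)), 2.5)

    def test_empty_mask_rejected(self):
        X = FeatureMatrix(np.ones((2, 3)), "GMV", ["a", "b"])
        with pytest.raises(ValueError, match="empty"):
            roi_mean(X, np.zeros(3, bool))


class TestCorrelateWithMeasures:
    def test_perfect_linear_relations(self):
        roi = np.arange(12, dtype=float)
        measures = pd.DataFrame({"up": 2 * roi, "down": -roi})
        rep = correlate_with_measures(roi, measures)
        t = rep.table.set_index("measure")
        assert t.loc["up", "pearson_r"] == pytest.approx(1.0)
        assert t.loc["down", "pearson_r"] == pytest.approx(-1.0)
        assert t.loc["up", "significant"]

    def test_spearman_only_for_discrete_flags(self, rng):
        roi = rng.standard_normal(30)
        measures = pd.DataFrame({"cont": rng.standard_normal(30),
                                 "disc": rng.integers(0, 5, 30)})
        rep = correlate_with_measures(roi, measures, discrete_flags=["disc"])
        t = rep.table.set_index("measure")
        assert np.isnan(t.loc["cont", "spearman_rho"])
        assert np.isfinite(t.loc["disc", "spearman_rho"])

    def test_pairwise_deletion_of_missing_values(self, rng):
        roi = rng.standard_normal(30)
        y = roi + 0.1 * rng.standard_normal(30)
        y_missing = y.copy()
        y_missing[:5] = np.nan
        rep = correlate_with_measures(
            roi, pd.DataFrame({"m": y_missing}))
        assert rep.table.loc[0, "n"] == 25

    def test_zero_variance_measure_not_computable(self, rng):
        roi = rng.standard_normal(20)
        rep = correlate_with_measures(
            roi, pd.DataFrame({"flat": np.ones(20),
                               "ok": rng.standard_normal(20)}))
        t = rep.table.set_index("measure")
        assert np.isnan(t.loc["flat", "pearson_p"])
        assert not t.loc["flat", "significant"]

    def test_too_few_pairs_rejected(self, rng):
        with pytest.raises(ValueError, match="complete pairs"):
            correlate_with_measures(rng.standard_normal(5),
                                    pd.DataFrame({"m": rng.standard_normal(5)}))

    def test_fdr_exceeds_raw_p(self, rng):
        roi = rng.standard_normal(40)
        measures = pd.DataFrame(
            {f"m{i}": rng.standard_normal(40) for i in range(6)})
        rep = correlate_with_measures(roi, measures)
        assert np.all(rep.table["p_fdr"] >= rep.table["pearson_p"] - 1e-15)

    def test_removing_measure_keeps_other_raw_stats(self, rng):
        roi = rng.standard_normal(40)
        measures = pd.DataFrame(
            {f"m{i}": rng.standard_normal(40) for i in range(4)})
        full = correlate_with_measures(roi, measures).table.set_index("measure")
        part = correlate_with_measures(
            roi, measures.drop(columns="m3")).table.set_index("measure")
        for m in ("m0", "m1", "m2"):
            assert part.loc[m, "pearson_r"] == full.loc[m, "pearson_r"]
            assert part.loc[m, "pearson_p"] == full.loc[m, "pearson_p"]


class TestBhFdr:
    def test_hand_applied_step_up(self):
        p = [0.001, 0.008, 0.039, 0.041]
        adj, flags = bh_fdr(p, alpha=0.05)
        assert flags.all()          # k* = 4 since 0.041 <= 4*0.05/4

    def test_all_ones(self):
        adj, flags = bh_fdr(np.ones(5))
        assert not flags.any()
        np.testing.assert_allclose(adj, 1.0)

    def test_single_p_reduces_to_alpha_test(self):
        assert bh_fdr([0.04])[1][0]
        assert not bh_fdr([0.06])[1][0]

    def test_empty_input(self):
        adj, flags = bh_fdr([])
        assert adj.size == 0 and flags.size == 0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            m = int(rng.integers(1, 50))
            p = rng.uniform(size=m)
            _, flags = bh_fdr(p)
            np.testing.assert_array_equal(flags, brute_force_bh(p))

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=30),
           st.permutations(range(2)))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_flags_invariant_to_permutation(self, p, _):
        p = np.asarray(p)
        perm = np.argsort(np.sin(np.arange(len(p)) * 12.9898))  # fixed shuffle
        adj, flags = bh_fdr(p)
        adj_p, flags_p = bh_fdr(p[perm])
        np.testing.assert_array_equal(flags[perm], flags_p)
        np.testing.assert_allclose(adj[perm], adj_p, atol=1e-12)

    def test_adjusted_p_monotone_in_raw_p(self, rng):
        p = rng.uniform(size=40)
        adj, _ = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
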