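"""Geometric feature extraction, normalization, correlation and pruning."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_geometric_features, random_profile
from octffr.features import (
    FEATURE_COLUMNS,
    GEOMETRIC_FEATURES,
    assemble_feature_matrix,
    compute_geometric_features,
    l1_normalize,
    pearson_correlation_matrix,
    prune_perfectly_correlated,
)
from octffr.profile import RadiiProfile


def toy_profile(radii, spacing=0.2, seg=(0, None), les=(1, 3)):
    radii = np.asarray(radii, float)
    seg_end = len(radii) - 1 if seg[1] is None else seg[1]
    return RadiiProfile(lesion_id="toy", radii=radii, frame_spacing=spacing,
                        segment_start=seg[0], segment_end=seg_end,
                        lesion_start=les[0], lesion_end=les[1])


class TestGeometricFeatures:
    def test_worked_five_frame_profile(self):
        """Hand-computed values for a 5-frame profile with a central dip."""
        g = compute_geometric_features(toy_profile([1.0, 1.0, 0.5, 1.0, 1.0]))
        assert g.mean_lumen_radius == pytest.approx(0.9)
        assert g.minimum_lumen_radius == pytest.approx(0.5)
        assert g.maximum_lumen_radius == pytest.approx(1.0)
        assert g.mean_lumen_radius_stenosis == pytest.approx(2.5 / 3)
        assert g.mean_radius_per_length == pytest.approx(0.9 / 0.8)
        assert g.maximum_radius_rapport == pytest.approx(0.5)
        assert g.stenosis_lesion_length == pytest.approx(0.4)
        assert g.percentage_diameter_reduction == pytest.approx(10.0)
        assert g.proximal_radius_rapport == pytest.approx(0.0)
        assert g.radius_rapport == pytest.approx(0.5)
        assert g.proximal_area == pytest.approx(np.pi)
        assert g.distal_area == pytest.approx(np.pi)

    def test_constant_profile_has_zero_ratios(self):
        g = compute_geometric_features(toy_profile([1.3] * 7, les=(2, 4)))
        assert g.percentage_diameter_reduction == pytest.approx(0.0)
        assert g.radius_rapport == pytest.approx(0.0)
        assert g.maximum_radius_rapport == pytest.approx(0.0)

    def test_scale_invariance_of_ratios_and_area_scaling(self):
        rng = np.random.default_rng(0)
        base = toy_profile(rng.uniform(0.5, 2.0, 11), les=(3, 8))
        doubled = toy_profile(2 * base.radii, les=(3, 8))
        g1, g2 = compute_geometric_features(base), compute_geometric_features(doubled)
        for name in ("percentage_diameter_reduction", "proximal_radius_rapport",
                     "radius_rapport", "maximum_radius_rapport"):
            assert getattr(g2, name) == pytest.approx(getattr(g1, name))
        assert g2.proximal_area == pytest.approx(4 * g1.proximal_area)
        assert g2.distal_area == pytest.approx(4 * g1.distal_area)

    def test_brute_force_oracle_on_random_profiles(self):
        """Vectorized extraction matches literal per-frame loops."""
        rng = np.random.default_rng(42)
        for _ in range(300):
            prof = random_profile(rng)
            if prof.segment_end == prof.segment_start:
                continue
            got = compute_geometric_features(prof).as_dict()
            want = brute_force_geometric_features(prof)
            for name in GEOMETRIC_FEATURES:
                assert got[name] == pytest.approx(want[name], abs=1e-12), name

    def test_reversal_swaps_proximal_and_distal(self):
        rng = np.random.default_rng(3)
        prof = toy_profile(rng.uniform(0.5, 2.0, 15), les=(4, 11))
        fwd = compute_geometric_features(prof)
        rev = compute_geometric_features(prof.reversed())
        assert rev.proximal_area == pytest.approx(fwd.distal_area)
        assert rev.distal_area == pytest.approx(fwd.proximal_area)
        # numerator changes sign, denominator switches to the other boundary
        assert rev.proximal_radius_rapport == pytest.approx(
            (prof.r_distal - prof.r_proximal) / prof.r_distal)
        for name in ("mean_lumen_radius", "minimum_lumen_radius",
                     "maximum_lumen_radius", "stenosis_lesion_length"):
            assert getattr(rev, name) == pytest.approx(getattr(fwd, name))

    def test_reduction_and_rapport_coincide_iff_mean_equals_min(self):
        # flat lesion floor: r_mean over a fully-lesioned segment equals r_min
        flat = RadiiProfile(lesion_id="flat", radii=np.array([0.5, 0.5, 0.5]),
                            frame_spacing=0.2, segment_start=0, segment_end=2,
                            lesion_start=0, lesion_end=2)
        g = compute_geometric_features(flat)
        assert g.percentage_diameter_reduction == pytest.approx(100 * g.radius_rapport)
        # generic profile: the two formulas differ
        g2 = compute_geometric_features(toy_profile([1.0, 1.0, 0.5, 1.0, 1.0]))
        assert g2.percentage_diameter_reduction != pytest.approx(
            100 * g2.radius_rapport)

    def test_zero_length_segment_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            compute_geometric_features(RadiiProfile(
                lesion_id="z", radii=np.array([1.0]), segment_start=0,
                segment_end=0, lesion_start=0, lesion_end=0))


class TestAssembly:
    def test_matrix_shape_and_schema(self, default_cohort):
        m = assemble_feature_matrix(default_cohort)
        assert m.shape == (102, 26)
        assert list(m.columns) == FEATURE_COLUMNS
        assert not m.isna().any().any()

    def test_missing_covariate_names_lesion_and_column(self, default_cohort):
        import dataclasses
        broken = dataclasses.replace(default_cohort)
        bad = dataclasses.replace(broken.patients[0], hb=float("nan"))
        broken.patients = [bad] + broken.patients[1:]
        lid = next(l.lesion_id for l in broken.lesions
                   if l.patient_id == bad.patient_id)
        with pytest.raises(ValueError, match=f"{lid}.*hb"):
            assemble_feature_matrix(broken)

    def test_mld_differs_from_profile_minimum(self, default_cohort):
        m = assemble_feature_matrix(default_cohort)
        assert not np.allclose(m["minimal_lumen_diameter"],
                               2 * m["minimum_lumen_radius"])


class TestNormalization:
    def test_worked_column(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 2.0]})
        out = l1_normalize(df)
        assert list(out["a"]) == pytest.approx([0.25, 0.25, 0.5])

    def test_columns_sum_to_one(self, default_features):
        assert np.allclose(default_features.abs().sum(axis=0), 1.0, atol=1e-12)

    def test_preserves_correlations(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(5, 2, (50, 4)), columns=list("abcd"))
        before = df.corr()
        after = l1_normalize(df).corr()
        assert np.allclose(before, after, atol=1e-12)

    def test_double_normalization_rejected(self, default_features):
        with pytest.raises(ValueError, match="already"):
            l1_normalize(default_features)

    def test_zero_column_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            l1_normalize(pd.DataFrame({"a": [0.0, 0.0]}))


class TestCorrelationAndPruning:
    def test_self_and_perfect_linear(self):
        x = np.arange(10, dtype=float)
        df = pd.DataFrame({"x": x, "y": -2 * x + 5})
        corr = pearson_correlation_matrix(df)
        assert corr.loc["x", "x"] == pytest.approx(1.0)
        assert corr.loc["x", "y"] == pytest.approx(-1.0)
        assert np.allclose(corr, corr.T, atol=1e-12)

    def test_independent_columns_nearly_uncorrelated(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(10000, 2)), columns=["a", "b"])
        assert abs(pearson_correlation_matrix(df).loc["a", "b"]) < 0.05

    def test_constant_column_warns_and_reports_zero(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "c": [1.0, 1.0, 1.0]})
        with pytest.warns(UserWarning, match="constant"):
            corr = pearson_correlation_matrix(df)
        assert corr.loc["a", "c"] == 0.0

    def test_duplicate_pair_drops_later_ranked(self):
        x = np.arange(6, dtype=float)
        df = pd.DataFrame({"keep": x, "noise": x[::-1] ** 2, "dup": 3 * x + 1})
        pruned, removed = prune_perfectly_correlated(df)
        assert removed == ["dup"]
        assert "keep" in pruned.columns

    def test_no_pair_above_threshold_is_identity(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        pruned, removed = prune_perfectly_correlated(df)
        assert removed == [] and list(pruned.columns) == list("abc")

    def test_three_mutual_duplicates_keep_first_ranked(self):
        x = np.arange(8, dtype=float)
        df = pd.DataFrame({"c3": x * 2, "c1": x, "c2": -x})
        pruned, removed = prune_perfectly_correlated(
            df, rank_order=["c1", "c2", "c3"])
        assert set(removed) == {"c2", "c3"}
        assert list(pruned.columns) == ["c1"]

    def test_pruning_is_idempotent(self):
        x = np.arange(6, dtype=float)
        df = pd.DataFrame({"a": x, "b": x + 1, "c": np.cos(x)})
        once, removed1 = prune_perfectly_correlated(df)
        twice, removed2 = prune_perfectly_correlated(once)
        assert removed2 == []
        pd.testing.assert_frame_equal(once, twice)
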