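"""Volumetric diagnostic features: algebraic identities, statistics and
the logistic scorer."""

import numpy as np
import pandas as pd
import pytest

from gliopipe.diag import compute_diag_features, diag_feature_frame, feature_stats, train_diag_model
from gliopipe.volume_io import LesionLabelMap, MultiSequenceStudy, VolumeGrid
from conftest import random_label_map


def fake_study(v_et, v_ncr, v_ed, grade, sid):
    """Study whose label map carries prescribed compartment volumes
    (geometry is irrelevant for volume-ratio features)."""
    side = 12
    data = np.zeros(side**3, dtype=np.int16)
    data[:v_et] = 4
    data[v_et : v_et + v_ncr] = 1
    data[v_et + v_ncr : v_et + v_ncr + v_ed] = 2
    labels = LesionLabelMap(data.reshape(side, side, side))
    vol = VolumeGrid(np.ones((side, side, side)))
    return MultiSequenceStudy(sid, {"FLAIR": vol, "T1CE": vol, "T2": vol}, labels=labels, grade=grade)


class TestComputeDiagFeatures:
    def test_empty_map_guarded_by_n(self):
        f = compute_diag_features(np.zeros((4, 4, 4), dtype=np.int16), N=1)
        assert f.F3 == 1.0 and f.F4 == 1.0
        assert f.F1 == 0.0 and f.F2 == 0.0

    def test_arithmetic_oracle(self):
        labels = np.zeros(400, dtype=np.int16)
        labels[:99] = 4
        labels[99:199] = 1
        f = compute_diag_features(labels.reshape(4, 10, 10), N=1)
        assert f.F3 == pytest.approx(100 / 200)
        assert f.F1 == pytest.approx(np.log(0.5))

    def test_log_identities_on_random_maps(self, rng):
        for _ in range(30):
            f = compute_diag_features(random_label_map(rng).data, N=1)
            assert abs(f.F1 - np.log(f.F3)) < 1e-12
            assert abs(f.F2 - np.log(f.F4)) < 1e-12
            assert 0 < f.F3 <= 1 and 0 < f.F4 <= 1
            assert f.F1 <= 0 and f.F2 <= 0

    def test_volumes_match_histogram(self, rng):
        labels = random_label_map(rng)
        f = compute_diag_features(labels)
        hist = {lab: int((labels.data == lab).sum()) for lab in (1, 2, 4)}
        assert (f.V_ET, f.V_NCR_NET, f.V_ED) == (hist[4], hist[1], hist[2])

    def test_monotonicity_in_volumes(self):
        def f3(v_et, v_ncr):
            labels = np.zeros(1000, dtype=np.int16)
            labels[:v_et] = 4
            labels[v_et : v_et + v_ncr] = 1
            return compute_diag_features(labels.reshape(10, 10, 10)).F3

        assert f3(200, 100) > f3(100, 100)  # increasing in V_ET
        assert f3(100, 200) < f3(100, 100)  # decreasing in V_NCR/NET

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError, match="N must be > 0"):
            compute_diag_features(np.zeros((2, 2, 2), dtype=np.int16), N=0)

    def test_mm3_option_scales_volumes(self):
        data = np.zeros((4, 4, 4), dtype=np.int16)
        data[0] = 4
        labels = LesionLabelMap(data, spacing=(2.0, 1.0, 1.0))
        f = compute_diag_features(labels, use_mm3=True)
        assert f.V_ET == pytest.approx(16 * 2.0)


class TestFeatureStats:
    @staticmethod
    def _frame(x, y):
        df = pd.DataFrame({"F1": x, "F2": x, "F3": x, "F4": x})
        grades = pd.Series(["GBM" if v else "nonGBM" for v in y])
        return df, grades

    def test_feature_equal_to_coding_has_unit_correlation(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        df, grades = self._frame(y.astype(float), y)
        out = feature_stats(df, grades)
        assert out.loc["F3", "pearson_r"] == pytest.approx(1.0)

    def test_welch_t_matches_hand_formula(self):
        x = np.array([0.0, 0.1, -0.1, 1.0, 1.1, 0.9])
        y = np.array([0, 0, 0, 1, 1, 1])
        df, grades = self._frame(x, y)
        out = feature_stats(df, grades)
        a, b = x[y == 1], x[y == 0]
        t_hand = (a.mean() - b.mean()) / np.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
        assert out.loc["F1", "t_stat"] == pytest.approx(t_hand)

    def test_null_p_values_roughly_uniform(self, rng):
        x = rng.normal(size=60)
        ps = []
        for _ in range(200):
            y = rng.permutation(np.repeat([0, 1], 30))
            df, grades = self._frame(x, y)
            ps.append(feature_stats(df, grades).loc["F3", "p_value"])
        ps = np.asarray(ps)
        assert abs(np.mean(ps) - 0.5) < 0.12
        assert (ps < 0.05).mean() < 0.15

    def test_constant_feature_flagged(self):
        df = pd.DataFrame({"F1": np.ones(6), "F2": np.ones(6), "F3": np.ones(6), "F4": np.arange(6.0)})
        grades = pd.Series(["GBM"] * 3 + ["nonGBM"] * 3)
        out = feature_stats(df, grades)
        assert bool(out.loc["F1", "constant"])
        assert np.isnan(out.loc["F1", "pearson_r"])
        assert not bool(out.loc["F4", "constant"])

    def test_too_few_per_class_rejected(self):
        df = pd.DataFrame({k: np.arange(4.0) for k in ("F1", "F2", "F3", "F4")})
        with pytest.raises(ValueError, match="at least 3"):
            feature_stats(df, pd.Series(["GBM", "GBM", "nonGBM", "nonGBM"]))


class TestTrainDiagModel:
    @pytest.fixture()
    def noisy_cohort(self, rng):
        """Overlapping feature distributions: a finite, non-separable fit."""
        cohort = []
        for i in range(12):
            v_et = int(rng.integers(150, 400))
            cohort.append(fake_study(v_et, int(rng.integers(100, 300)), int(rng.integers(50, 200)), "GBM", f"g{i}"))
        for i in range(12):
            v_et = int(rng.integers(100, 350))
            cohort.append(fake_study(v_et, int(rng.integers(150, 350)), int(rng.integers(100, 250)), "nonGBM", f"n{i}"))
        return cohort

    def test_scores_are_probabilities(self, cohort_small):
        res = train_diag_model(cohort_small, seed=0)
        assert all(0.0 <= s <= 1.0 for s in res.scores.values())

    def test_replicating_studies_keeps_fitted_model(self, noisy_cohort):
        """Replicating every study rescales the likelihood without moving
        its optimum, so the fitted probabilities must not change.  (Raw
        coefficients are not comparable: F1 = ln F3 and F2 = ln F4 make
        the design collinear, leaving flat likelihood directions.)"""
        res1 = train_diag_model(noisy_cohort, C=np.inf, test_fraction=0.0, seed=0)
        doubled = noisy_cohort + [
            fake_study(int(f.V_ET), int(f.V_NCR_NET), int(f.V_ED), s.grade, s.study_id + "b")
            for s, f in ((s, compute_diag_features(s.labels)) for s in noisy_cohort)
        ]
        res2 = train_diag_model(doubled, C=np.inf, test_fraction=0.0, seed=0)
        for sid, p in res1.scores.items():
            assert p == pytest.approx(res2.scores[sid], abs=1e-5)

    def test_single_class_rejected(self):
        cohort = [fake_study(100, 50, 20, "GBM", f"s{i}") for i in range(6)]
        with pytest.raises(ValueError, match="both classes"):
            train_diag_model(cohort)

    def test_phantom_f3_direction(self, cohort_small):
        df = diag_feature_frame(cohort_small)
        out = feature_stats(df)
        assert out.loc["F3", "t_stat"] > 0  # GBM mean exceeds non-GBM mean
        assert out.loc["F3", "p_value"] < 0.01
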