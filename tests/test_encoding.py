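"""Encoding model: design matrix expansion, SVD reduction, ridge fit,
cross-validated explained variance, and permutation delta-R^2."""
from __future__ import annotations

import numpy as np
import pytest

from duobrain.core import EventSeries, PhaseSchedule
from duobrain.encoding import (
    DEFAULT_KERNEL_WINDOWS,
    LAMBDA_GRID,
    N_COMPONENTS,
    N_FOLDS,
    ReducedNeural,
    build_design_matrix,
    cv_explained_variance,
    fit_encoding_model,
    permute_variable,
    ridge_fit,
    select_lambda,
    svd_reduce,
    unique_contribution,
    variables_from_events,
)

FS = 28.9


def _sources(T, events, name="stat_forelimb"):
    src = np.zeros(T)
    src[list(events)] = 1.0
    return {name: src}


class TestDesignMatrix:
    def test_two_second_window_is_58_columns_at_28p9_fps(self):
        dm = build_design_matrix(_sources(400, [100]), fs=FS)
        s, e = dm.column_groups["stat_forelimb"]
        assert e - s == 58  # ceil(2 * 28.9)
        X = dm.X[:, s:e]
        for lag in range(58):
            col = X[:, lag]
            assert col.sum() == 1.0
            assert col[100 + lag] == 1.0

    def test_pre_event_window_uses_negative_lags(self):
        dm = build_design_matrix(
            {"approach": _sources(400, [200], "approach")["approach"]}, fs=FS
        )
        s, e = dm.column_groups["approach"]
        assert e - s == int(np.ceil(5 * FS)) + 1  # lags -145..0
        X = dm.X[:, s:e]
        lags = dm.lags_for("approach")
        for ci, lag in enumerate(lags):
            assert X[200 + lag, ci] == 1.0

    def test_empty_variable_kept_but_flagged(self):
        srcs = _sources(200, [50])
        srcs["stage_translation"] = np.zeros(200)
        dm = build_design_matrix(srcs, fs=FS)
        assert dm.empty_variables == ["stage_translation"]
        s, e = dm.column_groups["stage_translation"]
        assert not dm.X[:, s:e].any()

    def test_kernels_do_not_cross_trial_boundaries(self):
        fs = 10.0
        src = np.zeros(400)
        src[190] = 1.0  # 1 s before the boundary at 200
        dm = build_design_matrix(
            {"stat_forelimb": src},
            fs=fs,
            trial_bounds=[(0, 200), (200, 400)],
        )
        s, e = dm.column_groups["stat_forelimb"]
        X = dm.X[:, s:e]
        assert e - s == 20
        for lag in range(20):
            expected = 1.0 if 190 + lag < 200 else 0.0
            assert X[:, lag].sum() == expected
        assert not X[200:].any()

    def test_non_binary_source_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            build_design_matrix({"stat_forelimb": np.full(100, 0.5)}, fs=FS)

    def test_context_split_of_whisking(self):
        """Stationary whisk bouts are split into alone/together
        variables by the phase at bout onset."""
        sched = PhaseSchedule.from_durations(60.0, 10.0)
        clock = np.arange(int(200 * FS)) / FS
        ev = {
            ("stationary", "whisker"): EventSeries.from_events(
                clock, [(30.0, 31.0), (90.0, 91.0)], "whisker", "stationary"
            ),
            ("moving", "whisker"): EventSeries.from_events(
                clock, [(95.0, 96.0)], "whisker", "moving"
            ),
        }
        out = variables_from_events(ev, sched, clock)
        assert out["stat_whisk_alone"].sum() == 1
        assert out["stat_whisk_together"].sum() == 1
        assert out["partner_whisk_together"].sum() == 1
        assert np.argmax(out["stat_whisk_alone"]) == int(
            np.argmin(np.abs(clock - 30.0))
        )
        # trial events come from the schedule
        assert out["stage_translation"].sum() == 2
        assert out["approach"].sum() == 1
        assert out["leave"].sum() == 1


class TestSvdReduce:
    def test_rank_one_data_single_component(self, rng):
        t = rng.normal(0, 1, 100)
        s = rng.normal(0, 1, 40)
        data = np.outer(t, s)
        red = svd_reduce(data, k=5)
        recon = red.reconstruct()
        assert np.allclose(recon, data, atol=1e-10)
        energy = (red.temporal**2).sum(axis=0)
        assert energy[1:].max() < 1e-16 * energy[0]

    def test_reconstruction_error_matches_full_svd_oracle(self, rng):
        data = rng.normal(0, 1, (50, 500))
        k = 10
        red = svd_reduce(data, k=k)
        err = ((data - red.reconstruct()) ** 2).sum()
        sv = np.linalg.svd(data - data.mean(axis=0), compute_uv=False)
        assert err == pytest.approx((sv[k:] ** 2).sum(), rel=1e-6)

    def test_temporal_components_orthogonal(self, rng):
        red = svd_reduce(rng.normal(0, 1, (80, 60)), k=8)
        gram = red.temporal.T @ red.temporal
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.diag(gram).max()

    def test_oversized_k_truncated_with_warning(self, rng):
        with pytest.warns(UserWarning, match="truncated"):
            red = svd_reduce(rng.normal(0, 1, (30, 20)), k=50)
        assert red.k == 20

    def test_default_component_count_is_200(self):
        assert N_COMPONENTS == 200


class TestRidge:
    def test_lambda_zero_equals_normal_equations_oracle(self, rng):
        X = rng.normal(0, 1, (200, 12))
        Y = rng.normal(0, 1, (200, 3))
        B = ridge_fit(Y, X, 0.0)
        B_ols = np.linalg.lstsq(X, Y, rcond=None)[0]
        assert np.max(np.abs(B - B_ols)) / np.max(np.abs(B_ols)) < 1e-8

    def test_large_penalty_shrinks_to_zero(self, rng):
        X = rng.normal(0, 1, (100, 5))
        Y = rng.normal(0, 1, (100, 2))
        B = ridge_fit(Y, X, 1e12)
        assert np.abs(B).max() < 1e-6

    def test_recovers_true_coefficients_noiselessly(self, rng):
        X = rng.normal(0, 1, (300, 8))
        B_true = rng.normal(0, 2, (8, 4))
        Y = X @ B_true
        B = ridge_fit(Y, X, 1e-8)
        assert np.max(np.abs(B - B_true)) / np.max(np.abs(B_true)) < 1e-4

    def test_negative_penalty_rejected(self, rng):
        with pytest.raises(ValueError):
            ridge_fit(rng.normal(0, 1, (10, 2)), rng.normal(0, 1, (10, 2)), -1.0)


def _toy_model(rng, T=600, noise=0.0):
    """Two variables; variable 1 drives components/pixels 0-4 exactly,
    variable 2 is pure nuisance."""
    fs = 10.0
    src1 = np.zeros(T)
    src1[rng.choice(np.arange(10, T - 30), 25, replace=False)] = 1.0
    src2 = np.zeros(T)
    src2[rng.choice(np.arange(10, T - 30), 25, replace=False)] = 1.0
    windows = {"v1": (0.0, 1.0), "v2": (0.0, 1.0)}
    dm = build_design_matrix(
        {"v1": src1, "v2": src2}, fs=fs, kernel_windows=windows
    )
    s, e = dm.column_groups["v1"]
    b = rng.normal(1.0, 0.3, e - s)
    drive = dm.X[:, s:e] @ b
    drive = drive - drive.mean()
    temporal = np.zeros((T, 2))
    temporal[:, 0] = drive + noise * rng.normal(0, 1, T)
    temporal[:, 1] = rng.normal(0, 1, T)
    spatial = np.zeros((2, 10))
    spatial[0, :5] = 1.0
    spatial[1, 5:] = 1.0
    mask = np.ones((1, 10), bool)
    red = ReducedNeural(temporal, spatial, np.zeros(10), mask)
    return red, dm


class TestCrossValidation:
    def test_noiseless_model_explains_driven_pixels(self, rng):
        red, dm = _toy_model(rng)
        r2, per_fold = cv_explained_variance(red, dm, folds=5, lam=1e-6)
        assert np.all(r2[:5] > 0.98)
        assert per_fold.shape == (5, 10)

    def test_unrelated_design_explains_nothing(self, rng):
        red, dm = _toy_model(rng)
        red.temporal = rng.normal(0, 1, red.temporal.shape)
        r2, _ = cv_explained_variance(red, dm, folds=5, lam=1.0)
        assert np.nanmean(r2) < 0.1

    def test_default_folds_is_10(self):
        assert N_FOLDS == 10

    def test_row_mismatch_rejected(self, rng):
        red, dm = _toy_model(rng)
        red.temporal = red.temporal[:-5]
        with pytest.raises(ValueError):
            cv_explained_variance(red, dm, folds=5, lam=1.0)


class TestPermutation:
    def test_fixed_seed_reproducible_bit_exact(self, rng):
        _, dm = _toy_model(rng)
        X1 = permute_variable(dm, "v1", seed=42)
        X2 = permute_variable(dm, "v1", seed=42)
        assert np.array_equal(X1, X2)
        X3 = permute_variable(dm, "v1", seed=43)
        assert not np.array_equal(X1, X3)

    def test_permutation_keeps_other_variables(self, rng):
        _, dm = _toy_model(rng)
        Xp = permute_variable(dm, "v1", seed=0)
        s, e = dm.column_groups["v2"]
        assert np.array_equal(Xp[:, s:e], dm.X[:, s:e])

    def test_unknown_variable_rejected(self, rng):
        _, dm = _toy_model(rng)
        with pytest.raises(KeyError):
            permute_variable(dm, "nope", seed=0)


class TestUniqueContribution:
    def test_driving_variable_owns_its_pixels(self, rng):
        red, dm = _toy_model(rng, noise=0.05)
        r2, _ = cv_explained_variance(red, dm, folds=5, lam=1e-3)
        d1 = unique_contribution(
            red, dm, "v1", folds=5, lam=1e-3, seed=0, r2_full=r2
        )
        d2 = unique_contribution(
            red, dm, "v2", folds=5, lam=1e-3, seed=0, r2_full=r2
        )
        # variable 1 uniquely explains the driven pixels
        assert np.all(d1[:5] > 0.9)
        # nuisance variable explains ~nothing anywhere
        assert np.nanmax(np.abs(d2)) < 0.1
        # delta R^2 never exceeds the full model's R^2 by more than the
        # sampling tolerance (the permuted model can overfit to a
        # slightly negative held-out R^2)
        assert np.all(d1 <= r2 + 0.1)
        assert np.all(d1 >= -0.05) and np.all(d2 >= -0.05)

    def test_all_zero_variable_contributes_nothing(self, rng):
        red, dm = _toy_model(rng)
        dm.sources["v2"][:] = 0.0
        s, e = dm.column_groups["v2"]
        dm.X[:, s:e] = 0.0
        r2, _ = cv_explained_variance(red, dm, folds=5, lam=1e-3)
        d = unique_contribution(
            red, dm, "v2", folds=5, lam=1e-3, seed=0, r2_full=r2
        )
        assert np.nanmax(np.abs(d)) < 1e-9


class TestModelSelection:
    def test_lambda_grid_default(self):
        assert LAMBDA_GRID == (0.1, 1.0, 10.0, 100.0, 1000.0)

    def test_select_lambda_prefers_small_penalty_for_clean_data(self, rng):
        red, dm = _toy_model(rng, noise=0.01)
        lam = select_lambda(red, dm, folds=5)
        assert lam in LAMBDA_GRID
        assert lam <= 10.0

    def test_fit_encoding_model_bundles_results(self, rng):
        red, dm = _toy_model(rng, noise=0.05)
        result = fit_encoding_model(
            red, dm, variables=["v1"], folds=5, lam=1.0, seed=0
        )
        assert result.r2_map.shape == (1, 10)
        assert "v1" in result.dr2_maps
        assert result.folds == 5
        assert result.ridge_penalty == 1.0
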