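"""Model fitting: self-consistency, recovery, bootstrap, changepoint."""

import numpy as np
import pytest
from sklearn.base import clone

from oligoeq import (
    DEFAULT_GRID,
    LabelScheme,
    MeasurementDataset,
    MixedDimerFit,
    MixedSystemParams,
    NoiseModel,
    SelfOligomerFit,
    SelfSystemParams,
    bootstrap_ci,
    estimate_plateau_onset,
    fit_mixed_dG,
    fit_self_system,
    generate_mixed_dataset,
    generate_self_dataset,
    model_curve,
    read_measurements,
    write_measurements,
)
from oligoeq.exceptions import FitError, InvalidParameterError
from oligoeq.inference import NO_PLATEAU

NM = 1e-9
GRID = np.asarray(DEFAULT_GRID)


class TestModelCurve:
    def test_quadratic_below_cac(self, ctx, self_A):
        grid = np.array([0.5, 1.0]) * NM
        curve = model_curve(self_A, grid, ctx=ctx)
        assert curve[1] / curve[0] == pytest.approx(4.0, rel=0.01)

    def test_plateau_above_fitted_cac(self, ctx, self_A):
        curve = model_curve(self_A, np.array([100, 400, 800]) * NM, ctx=ctx)
        assert curve[1] == pytest.approx(curve[2], rel=1e-9)
        assert curve[0] < curve[1]

    def test_non_decreasing(self, ctx, self_A):
        curve = model_curve(self_A, np.linspace(1, 600, 300) * NM, ctx=ctx)
        assert np.all(np.diff(curve) >= 0)

    def test_mixed_observed_below_self_at_equal_free_energies(self, ctx):
        self_params = SelfSystemParams(label="x", dG_oligo=-36.3)
        mixed = MixedSystemParams(dG_AA=-36.3, dG_BB=-36.3, dG_AB=-36.3)
        grid = np.array([10, 50, 100]) * NM
        self_curve = model_curve(self_params, grid, ctx=ctx)
        mixed_curve = model_curve(mixed, grid, ctx=ctx)
        assert np.all(mixed_curve < self_curve)

    def test_matches_state_based_computation(self, ctx, self_A):
        from oligoeq import observed_oligomer_concentration, solve_self_equilibrium

        grid = np.array([1, 50, 222, 400]) * NM
        curve = model_curve(self_A, grid, ctx=ctx)
        for t, value in zip(grid, curve):
            state = solve_self_equilibrium(t, self_A, ctx)
            assert value == pytest.approx(
                observed_oligomer_concentration(state, LabelScheme()), rel=1e-12
            )


class TestSelfFit:
    def test_noiseless_self_consistency(self, ctx, self_A):
        ds = generate_self_dataset(self_A, ctx, noise=NoiseModel(cv=0.0))
        res = fit_self_system(ds, ctx)
        assert res.params["dG_oligo_kJ_mol"] == pytest.approx(-36.3, rel=1e-3)
        assert res.params["cac_fib_nM"] == pytest.approx(222.0, rel=1e-3)

    def test_sklearn_estimator_contract(self, ctx, self_A):
        ds = generate_self_dataset(self_A, ctx, noise=NoiseModel(cv=0.0))
        df = ds.to_frame()
        for template in (SelfOligomerFit(), MixedDimerFit()):
            assert clone(template).get_params() == template.get_params()
        est = SelfOligomerFit()
        est.set_params(n_starts=3)
        est.fit(df["total_conc"].to_numpy()[:, None], df["oligomer_conc"].to_numpy())
        assert est.dG_oligo_ == pytest.approx(-36.3, rel=1e-3)
        pred = est.predict(df["total_conc"].to_numpy()[:, None])
        assert pred == pytest.approx(df["oligomer_conc"].to_numpy(), rel=1e-3)

    def test_all_zero_observations_fail(self, ctx):
        ds = MeasurementDataset.from_arrays(
            "self_A", [1 * NM, 10 * NM, 100 * NM], [0, 0, 0], ["r1", "r1", "r1"]
        )
        with pytest.raises(FitError):
            fit_self_system(ds, ctx)

    def test_no_plateau_in_range_is_flagged(self, ctx):
        truth = SelfSystemParams(label="self_A", dG_oligo=-36.3, cac_fib=5000 * NM)
        ds = generate_self_dataset(truth, ctx, noise=NoiseModel(cv=0.0))
        res = fit_self_system(ds, ctx)
        assert any("bound" in f or "no_plateau" in f for f in res.flags)

    def test_fit_invariant_under_csv_round_trip(self, ctx, self_A, tmp_path):
        ds = generate_self_dataset(self_A, ctx, noise=NoiseModel(cv=0.35, seed=7))
        res_mem = fit_self_system(ds, ctx)
        path = tmp_path / "m.csv"
        write_measurements([ds], path)
        res_csv = fit_self_system(read_measurements(path)["self_A"], ctx)
        assert res_csv.params["dG_oligo_kJ_mol"] == pytest.approx(
            res_mem.params["dG_oligo_kJ_mol"], rel=1e-6
        )

    def test_weighted_fit_runs_and_stays_close(self, ctx, self_A):
        ds = generate_self_dataset(self_A, ctx, noise=NoiseModel(cv=0.35, seed=3))
        res = fit_self_system(ds, ctx, weighted=True)
        assert abs(res.params["dG_oligo_kJ_mol"] + 36.3) < 3.0


class TestMixedFit:
    def test_noiseless_self_consistency(self, ctx, self_A, self_B, mixed_params):
        ds = generate_mixed_dataset(mixed_params, ctx, noise=NoiseModel(cv=0.0))
        res = fit_mixed_dG(ds, (self_A, self_B), ctx)
        assert res.params["dG_AB_kJ_mol"] == pytest.approx(-32.6, rel=1e-3)

    def test_residual_unimodal_in_dG_AB(self, ctx, mixed_params):
        ds = generate_mixed_dataset(mixed_params, ctx, noise=NoiseModel(cv=0.35, seed=5))
        df = ds.to_frame()
        X, y = df["total_conc"].to_numpy(), df["oligomer_conc"].to_numpy()
        grid = np.linspace(-40, -24, 33)
        sse = []
        for dg in grid:
            pred = model_curve(MixedSystemParams(dG_AB=dg), X, ctx=ctx)
            sse.append(np.sum((pred / NM - y / NM) ** 2))
        sse = np.array(sse)
        k = sse.argmin()
        assert 0 < k < len(sse) - 1
        assert np.all(np.diff(sse[: k + 1]) <= 0) and np.all(np.diff(sse[k:]) >= 0)

    def test_all_zero_observations_pin_upper_bound(self, ctx, self_A, self_B):
        ds = MeasurementDataset.from_arrays(
            "mixed",
            np.array([10, 50, 100]) * NM,
            [0.0, 0.0, 0.0],
            ["r1", "r1", "r1"],
        )
        res = fit_mixed_dG(ds, (self_A, self_B), ctx)
        assert "dG_AB_at_upper_bound" in res.flags


class TestBootstrap:
    def _dataset(self, ctx, mixed_params, seed=11):
        return generate_mixed_dataset(
            mixed_params, ctx, noise=NoiseModel(cv=0.35, seed=seed)
        )

    def test_reproducible_given_seed(self, ctx, self_A, self_B, mixed_params):
        ds = self._dataset(ctx, mixed_params)
        refit = lambda d: fit_mixed_dG(d, (self_A, self_B), ctx)
        ci1 = bootstrap_ci(ds, refit, n_boot=20, seed=42)
        ci2 = bootstrap_ci(ds, refit, n_boot=20, seed=42)
        assert ci1 == ci2
        ci3 = bootstrap_ci(ds, refit, n_boot=20, seed=43)
        assert ci1 != ci3

    def test_interval_contains_point_estimate(self, ctx, self_A, self_B, mixed_params):
        ds = self._dataset(ctx, mixed_params)
        res = fit_mixed_dG(ds, (self_A, self_B), ctx, n_boot=30, seed=1)
        lo, hi = res.confidence_intervals["dG_AB_kJ_mol"]
        assert lo <= hi
        # percentile interval from mild resampling noise should bracket a
        # neighbourhood of the point estimate
        assert lo - 2.0 < res.params["dG_AB_kJ_mol"] < hi + 2.0

    def test_single_replicate_rejected(self, ctx, self_A, self_B, mixed_params):
        ds = generate_mixed_dataset(
            mixed_params, ctx, n_rep=1, noise=NoiseModel(cv=0.35, seed=2)
        )
        with pytest.raises(InvalidParameterError):
            bootstrap_ci(ds, lambda d: fit_mixed_dG(d, (self_A, self_B), ctx), n_boot=5)

    def test_noise_widens_intervals(self, ctx, self_A, self_B, mixed_params):
        refit = lambda d: fit_mixed_dG(d, (self_A, self_B), ctx)
        widths = []
        for cv in (0.15, 0.60):
            ds = generate_mixed_dataset(
                mixed_params, ctx, noise=NoiseModel(cv=cv, seed=9)
            )
            ci = bootstrap_ci(ds, refit, n_boot=25, seed=4)
            lo, hi = ci["dG_AB_kJ_mol"]
            widths.append(hi - lo)
        assert widths[1] > widths[0]


class TestPlateauOnset:
    def test_recovers_known_cap(self, ctx, self_A):
        ds = generate_self_dataset(self_A, ctx, noise=NoiseModel(cv=0.0))
        onset = estimate_plateau_onset(ds)
        assert abs(onset - 222 * NM) <= 50 * NM  # within local grid spacing

    def test_strictly_rising_data_gives_sentinel(self, ctx):
        truth = SelfSystemParams(label="self_A", dG_oligo=-36.3, cac_fib=5000 * NM)
        ds = generate_self_dataset(truth, ctx, noise=NoiseModel(cv=0.0))
        assert estimate_plateau_onset(ds) == NO_PLATEAU

    def test_flat_data_onset_at_first_point(self, ctx):
        grid = GRID
        ds = MeasurementDataset.from_arrays(
            "self_A", grid, np.full(len(grid), 5 * NM), ["r1"] * len(grid)
        )
        assert estimate_plateau_onset(ds) == pytest.approx(grid[0])

    def test_too_few_concentrations_rejected(self, ctx):
        ds = MeasurementDataset.from_arrays(
            "self_A", np.array([1, 5, 10, 25]) * NM, [1, 2, 3, 4], list("abcd")
        )
        with pytest.raises(InvalidParameterError):
            estimate_plateau_onset(ds)
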