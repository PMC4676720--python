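"""Staged fitter: round-trip recovery, boundary handling, bootstrap."""

import dataclasses

import numpy as np
import pytest

from shieldfit.fitting import (
    DoseResponseDataset,
    bootstrap_ci,
    fit_stage_K,
    fit_stage_L,
    fit_stage_W,
    fit_stage_Y,
    joint_fit,
    read_dose_response_csv,
    staged_fit,
    write_dose_response_csv,
)
from shieldfit.shielding import CationSpec, ShieldingParams
from shieldfit.synthetic import NoiseModel, default_dose_grid, generate_dose_response

NOISELESS = NoiseModel(n_replicates=1, sd=0.0, seed=0)


def _mg_like(k=1.0):
    return CationSpec("Mg", valence=2, y_factor=1.0, k_assoc=k)


class TestStageRoundTrips:
    def test_round_trip_random_parameter_draws(self, rng):
        """Generator -> staged fitter on noiseless data recovers every free
        parameter to <= 1e-3 relative over random draws within bounds."""
        for _ in range(50):
            l_true = float(10 ** rng.uniform(-2.3, -0.9))       # 5-130 mM
            k_true = float(10 ** rng.uniform(1.0, 3.3))         # 10-2000 M-1
            y_true = float(rng.uniform(0.05, 0.6))
            w_true = float(rng.uniform(0.5e-6, 15e-6))
            params = ShieldingParams(l_ref=l_true, w=0.0)
            mg = generate_dose_response(_mg_like(), params, noise=NOISELESS)
            res_l = fit_stage_L([mg], params.with_(l_ref=0.02))
            assert res_l.parameters["L_ref"] == pytest.approx(l_true, rel=1e-3)
            fixed = params.with_(l_ref=res_l.parameters["L_ref"])

            ba = generate_dose_response(
                CationSpec("Ba", 2, 1.0, k_true), params, noise=NOISELESS)
            res_k = fit_stage_K(ba, fixed)
            assert res_k.parameters["K:Ba"] == pytest.approx(k_true, rel=1e-3)

            put = generate_dose_response(
                CationSpec("putrescine", 2, y_true, 0.3), params, noise=NOISELESS)
            res_y = fit_stage_Y(put, mg, fixed)
            assert res_y.parameters["Y"] == pytest.approx(y_true, rel=1e-3)

            neo_cat = CationSpec("neomycin", 6, y_true, 1000.0, plateau_capable=True)
            neo = generate_dose_response(neo_cat, params.with_(w=w_true),
                                         noise=NOISELESS)
            res_w = fit_stage_W(neo, fixed)
            assert res_w.parameters["W"] == pytest.approx(w_true, rel=1e-3)

    def test_flat_curve_flags_no_signal(self, params):
        doses = default_dose_grid(_mg_like())
        flat = DoseResponseDataset("PLCb1", _mg_like(), doses,
                                   np.ones_like(doses))
        res = fit_stage_L([flat], params)
        assert not res.converged
        assert np.isnan(res.parameters["L_ref"])
        assert any("flat" in w for w in res.diagnostics["warnings"])

    def test_zero_k_hits_lower_bound_with_flag(self, params):
        ds = generate_dose_response(CationSpec("Ba", 2, 1.0, 0.0), params,
                                    noise=NOISELESS)
        res = fit_stage_K(ds, params)
        assert res.parameters["K:Ba"] == pytest.approx(0.0, abs=1e-6)
        assert any(":K" in b for b in res.diagnostics["boundary"])

    def test_y_of_one_hits_upper_bound_with_flag(self, params):
        mg = generate_dose_response(_mg_like(), params, noise=NOISELESS)
        put = generate_dose_response(
            CationSpec("putrescine", 2, 1.0, 1.0), params, noise=NOISELESS)
        res = fit_stage_Y(put, mg, params)
        assert res.parameters["Y"] == pytest.approx(1.0, rel=1e-6)
        assert any(":Y" in b for b in res.diagnostics["boundary"])

    def test_zero_w_recovered_at_lower_bound(self, params):
        neo_cat = CationSpec("neomycin", 6, 0.12, 1000.0, plateau_capable=True)
        ds = generate_dose_response(neo_cat, params, noise=NOISELESS)
        res = fit_stage_W(ds, params)
        assert res.parameters["W"] == pytest.approx(0.0, abs=1e-10)

    def test_w_matches_plateau_inversion_oracle(self, params):
        """The fitted W agrees with back-calculating W from the saturating
        dose activity: W = Kd*s/(1-s) with s the plateau saturation."""
        neo_cat = CationSpec("neomycin", 6, 0.12, 1000.0, plateau_capable=True)
        p_true = params.with_(w=4.1e-6)
        doses = np.logspace(-7, 0, 16)  # extend to 1 M so the plateau is reached
        ds = generate_dose_response(neo_cat, p_true, doses=doses, noise=NOISELESS)
        res = fit_stage_W(ds, params)
        s = ds.activities[-1] * params.pip2_total / (params.pip2_total + params.kd)
        w_oracle = params.kd * s / (1 - s)
        assert res.parameters["W"] == pytest.approx(w_oracle, rel=0.02)

    def test_objective_nonincreasing_from_grid_start(self, params):
        ds = generate_dose_response(_mg_like(), params, noise=NOISELESS)
        res = fit_stage_L([ds], params)
        for start, final in res.diagnostics["cost_path"]:
            assert final <= start + 1e-15


class TestPipeline:
    def test_joint_fit_agrees_with_staged_on_noiseless_data(self, params, cations):
        datasets = [generate_dose_response(cations["Mg"], params, noise=NOISELESS),
                    generate_dose_response(cations["Ba"], params, noise=NOISELESS),
                    generate_dose_response(cations["putrescine"], params,
                                           noise=NOISELESS)]
        staged = staged_fit(datasets, params, compute_ic50=False)
        joint = joint_fit(datasets, params)
        for name in ("L_ref", "Y", "K:Ba", "K:putrescine"):
            assert joint.parameters[name] == pytest.approx(
                staged.parameters[name], rel=1e-4)

    def test_row_order_and_unit_invariance(self, params, cations, tmp_path, rng):
        ds = generate_dose_response(cations["Ba"], params,
                                    noise=NoiseModel(4, 0.03, 7))
        path_m = tmp_path / "m.csv"
        write_dose_response_csv([ds], path_m)
        table = __import__("pandas").read_csv(path_m)
        # same data in mM with shuffled rows
        shuffled = table.sample(frac=1.0, random_state=3).copy()
        shuffled["dose"] = shuffled["dose"] * 1e3
        shuffled["dose_unit"] = "mM"
        path_mm = tmp_path / "mm.csv"
        shuffled.to_csv(path_mm, index=False)
        k_m = fit_stage_K(read_dose_response_csv(path_m, cations)[0],
                          params).parameters["K:Ba"]
        k_mm = fit_stage_K(read_dose_response_csv(path_mm, cations)[0],
                           params).parameters["K:Ba"]
        assert k_m == pytest.approx(k_mm, rel=1e-6)

    def test_stage_y_requires_matching_enzyme(self, params, cations):
        mg = generate_dose_response(cations["Mg"], params, noise=NOISELESS,
                                    enzyme="PLCb1")
        put = generate_dose_response(cations["putrescine"], params,
                                     noise=NOISELESS, enzyme="PLCd1")
        with pytest.raises(ValueError):
            fit_stage_Y(put, mg, params)


class TestBootstrap:
    def test_noiseless_interval_has_zero_width(self, params, cations):
        ds = generate_dose_response(cations["Mg"], params,
                                    noise=NoiseModel(6, 0.0, 1))
        ci = bootstrap_ci(lambda d: fit_stage_L([d], params), ds,
                          n_boot=100, seed=0)
        lo, hi = ci["L_ref"]
        assert hi - lo == pytest.approx(0.0, abs=1e-9)

    def test_fixed_seed_reproducible(self, params, cations):
        ds = generate_dose_response(cations["Mg"], params,
                                    noise=NoiseModel(6, 0.05, 1))
        fit = lambda d: fit_stage_L([d], params)
        assert bootstrap_ci(fit, ds, 100, seed=5) == bootstrap_ci(fit, ds, 100, seed=5)

    def test_too_few_replicates_rejected(self, params, cations):
        ds = generate_dose_response(cations["Mg"], params,
                                    noise=NoiseModel(6, 0.05, 1))
        with pytest.raises(ValueError):
            bootstrap_ci(lambda d: fit_stage_L([d], params), ds, n_boot=50, seed=0)

    def test_stage_y_recovery_bias_small_under_noise(self, params, cations):
        """|E[Y_hat] - Y| < 0.02 at replicate noise SD 0.05 over seeded
        repeats (standard-error-limited simulation study)."""
        estimates = []
        for seed in range(60):
            mg = generate_dose_response(cations["Mg"], params,
                                        noise=NoiseModel(6, 0.05, seed))
            put = generate_dose_response(cations["putrescine"], params,
                                         noise=NoiseModel(6, 0.05, 10_000 + seed))
            estimates.append(fit_stage_Y(put, mg, params).parameters["Y"])
        assert abs(np.mean(estimates) - 0.12) < 0.02


class TestDatasetValidation:
    def test_requires_four_doses(self, cations):
        with pytest.raises(ValueError):
            DoseResponseDataset("PLCb1", cations["Mg"], [1e-3, 2e-3, 4e-3],
                                [1.0, 0.9, 0.8])

    def test_requires_increasing_doses(self, cations):
        with pytest.raises(ValueError):
            DoseResponseDataset("PLCb1", cations["Mg"], [1e-3, 1e-3, 4e-3, 8e-3],
                                [1.0, 0.9, 0.8, 0.7])

    def test_rejects_out_of_range_activity(self, cations):
        with pytest.raises(ValueError):
            DoseResponseDataset("PLCb1", cations["Mg"], [1e-3, 2e-3, 4e-3, 8e-3],
                                [1.5, 0.9, 0.8, 0.7])
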