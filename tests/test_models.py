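"""DIA model assembly, regression, cross-validation and statistics."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from diaffinity.models import (
    ComplexData,
    FittedModel,
    ModelSpec,
    assemble_features,
    consensus_score,
    fit_dias_exponents,
    fit_linear,
    loocv,
    mean_abs_error,
    optimize_gamma,
    pearson,
    predict_dg,
    sd_diff,
    spearman,
)
from diaffinity.synth import SyntheticSpec, generate_dataset


def make_data(**overrides):
    base = dict(
        complex_id="c0",
        dg_exptl=-8.0,
        e_vdw=np.array([-10.0, -2.0, -0.5]),
        e_ele=np.array([-4.0, 1.0, -0.2]),
        s_vdw=np.array([1.0, 0.5, 0.1]),
        s_ele=np.array([0.8, 0.3, 0.1]),
        h_w=np.array([0.0, 0.08, 0.16]),
        h_c=np.array([30.0, 70.0, 100.0]),
        s_dih=1.0e5,
        s_asa=40.0,
        n_rot=5,
        e_ele_mod=np.array([-2.0, 0.5, -0.1]),
    )
    base.update(overrides)
    return ComplexData(**base)


class TestAssembleFeatures:
    def test_diav_reduces_to_plain_sums(self):
        d = make_data()
        f = assemble_features(d, ModelSpec("DIAV"))
        assert f[0] == pytest.approx(d.e_vdw.sum())
        assert f[1] == pytest.approx(d.e_ele.sum())
        assert f[2] == d.s_dih
        assert len(f) == 3

    def test_weighted_model_with_gamma_zero_equals_diav(self):
        d = make_data()
        fw = assemble_features(d, ModelSpec("DIAV_W"), gamma=0.0)
        fv = assemble_features(d, ModelSpec("DIAV"))
        np.testing.assert_allclose(fw, fv)

    def test_entropy_channel_switch(self):
        d = make_data()
        assert assemble_features(d, ModelSpec("DIAV", entropy_channel="ASA"))[2] == d.s_asa

    def test_dias_uses_modified_electrostatics(self):
        d = make_data()
        f = assemble_features(d, ModelSpec("DIAS"))
        assert f[1] == pytest.approx(d.e_ele_mod.sum())

    def test_dias_without_modified_profile_raises(self):
        d = make_data(e_ele_mod=None)
        with pytest.raises(ValueError, match="dielectric"):
            assemble_features(d, ModelSpec("DIAS"))

    def test_three_residue_loop_oracle(self):
        d = make_data()
        gamma, a2, b2 = -3.0, 0.4, 0.2
        f = assemble_features(d, ModelSpec("DIAS", gamma=gamma, alpha2=a2, beta2=b2))
        # DIAS takes no hydration weight; brute-force residue loop
        xv = sum(d.e_vdw[i] * np.exp(-a2 * d.s_vdw[i]) for i in range(3))
        xe = sum(d.e_ele_mod[i] * np.exp(-b2 * d.s_ele[i]) for i in range(3))
        assert f[0] == pytest.approx(xv, rel=1e-12)
        assert f[1] == pytest.approx(xe, rel=1e-12)
        # weighted model with gamma: loop with exp(gamma h) on both channels
        flw = assemble_features(d, ModelSpec("DIAV_LW"), gamma=gamma)
        xvw = sum(np.exp(gamma * d.h_w[i]) * d.e_vdw[i] for i in range(3))
        xew = sum(np.exp(gamma * d.h_w[i]) * d.e_ele[i] for i in range(3))
        assert flw[0] == pytest.approx(xvw, rel=1e-12)
        assert flw[1] == pytest.approx(xew, rel=1e-12)
        assert flw[3] == d.n_rot

    def test_residue_set_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            make_data(h_w=np.array([0.0, 0.1]))


class TestPredict:
    def test_single_active_coefficient(self):
        m = FittedModel(alpha=1.0, beta=0.0, tau=0.0)
        assert predict_dg(m, np.array([-5.0, 99.0, 99.0]), ModelSpec("DIAV")) == -5.0

    def test_zero_features(self):
        m = FittedModel(alpha=1.0, beta=2.0, tau=3.0, w=4.0)
        assert predict_dg(m, np.zeros(4), ModelSpec("DIAV_LW")) == 0.0

    def test_dot_product_oracle_with_reference_params(self):
        from diaffinity.models import REFERENCE_PARAMS

        p = REFERENCE_PARAMS["DIAV_LW"]
        m = FittedModel(alpha=p["alpha"], beta=p["beta"], tau=p["tau"], w=p["w"])
        feats = np.array([-250.0, -90.0, 1.1e5, 7.0])
        expected = (p["alpha"] * -250 + p["beta"] * -90 + p["tau"] * 1.1e5 + p["w"] * 7)
        assert predict_dg(m, feats, ModelSpec("DIAV_LW")) == pytest.approx(expected)


@pytest.fixture(scope="module")
def dataset():
    data, _ = generate_dataset(SyntheticSpec(seed=21, noise_sigma=0.3), 30)
    return data


class TestNesting:
    """The model family is nested: switching terms off recovers the smaller model."""

    def test_diav_l_with_w_zero_is_diav(self, dataset):
        mv = fit_linear(dataset, ModelSpec("DIAV"))
        for d in dataset:
            fv = assemble_features(d, ModelSpec("DIAV"))
            fl = assemble_features(d, ModelSpec("DIAV_L"))
            ml = FittedModel(alpha=mv.alpha, beta=mv.beta, tau=mv.tau, w=0.0)
            assert predict_dg(ml, fl, ModelSpec("DIAV_L")) == pytest.approx(
                predict_dg(mv, fv, ModelSpec("DIAV")), rel=1e-12
            )

    def test_diav_lw_with_gamma_zero_is_diav_l(self, dataset):
        for d in dataset:
            flw = assemble_features(d, ModelSpec("DIAV_LW"), gamma=0.0)
            fl = assemble_features(d, ModelSpec("DIAV_L"))
            np.testing.assert_allclose(flw, fl, rtol=1e-14)

    def test_dias_neutral_settings_reproduce_diav(self, dataset):
        for d in dataset:
            neutral = dataclasses.replace(d, e_ele_mod=d.e_ele.copy())  # all s_j = 1
            fs = assemble_features(neutral, ModelSpec("DIAS", alpha2=0.0, beta2=0.0))
            fv = assemble_features(d, ModelSpec("DIAV"))
            np.testing.assert_allclose(fs, fv, rtol=1e-14)

    def test_dias_in_sample_error_never_above_diav(self, dataset):
        # with exponents free, DIAS at its optimum nests DIAV (alpha2=beta2=0)
        neutral = [dataclasses.replace(d, e_ele_mod=d.e_ele.copy()) for d in dataset]
        mv = fit_linear(neutral, ModelSpec("DIAV"))
        fv = np.array([predict_dg(mv, assemble_features(d, ModelSpec("DIAV")), ModelSpec("DIAV"))
                       for d in neutral])
        obs = np.array([d.dg_exptl for d in neutral])
        err_v = mean_abs_error(fv, obs)
        a2, b2 = fit_dias_exponents(neutral, ModelSpec("DIAS"))
        ms = fit_linear(neutral, ModelSpec("DIAS"), alpha2=a2, beta2=b2)
        fs = np.array([
            predict_dg(ms, assemble_features(d, ModelSpec("DIAS"), alpha2=a2, beta2=b2), ModelSpec("DIAS"))
            for d in neutral
        ])
        # compare on the residual-norm objective both optimizers see
        assert np.sum(np.abs(fs - obs) ** 2) <= np.sum(np.abs(fv - obs) ** 2) * (1 + 1e-9)


class TestFitLinear:
    def test_zero_noise_exact_recovery(self):
        data, truth = generate_dataset(SyntheticSpec(seed=1, noise_sigma=0.0), 34)
        m = fit_linear(data, ModelSpec("DIAV_LW"), gamma=truth["gamma"])
        assert m.alpha == pytest.approx(truth["alpha"], abs=1e-8)
        assert m.beta == pytest.approx(truth["beta"], abs=1e-8)
        assert m.tau == pytest.approx(truth["tau"], abs=1e-8)
        assert m.w == pytest.approx(truth["w"], abs=1e-8)

    def test_duplicate_columns_rank_error(self):
        data, _ = generate_dataset(SyntheticSpec(seed=2, noise_sigma=0.0), 20)
        clones = [dataclasses.replace(d, s_dih=float(d.n_rot)) for d in data]
        with pytest.raises(ValueError, match="collinear"):
            fit_linear(clones, ModelSpec("DIAV_LW"), gamma=0.0)

    def test_too_few_records(self):
        data, _ = generate_dataset(SyntheticSpec(seed=3), 3)
        with pytest.raises(ValueError, match="at least"):
            fit_linear(data, ModelSpec("DIAV_LW"), gamma=0.0)

    def test_noisy_recovery_within_3_se(self):
        spec = SyntheticSpec(seed=8, noise_sigma=0.5)
        data, truth = generate_dataset(spec, 50)
        ms = ModelSpec("DIAV_LW")
        m = fit_linear(data, ms, gamma=truth["gamma"])
        # normal-equations oracle with parameter covariance
        x = np.array([assemble_features(d, ms, gamma=truth["gamma"]) for d in data])
        y = np.array([d.dg_exptl for d in data])
        beta_hat = np.linalg.solve(x.T @ x, x.T @ y)
        resid = y - x @ beta_hat
        sigma2 = resid @ resid / (len(y) - x.shape[1])
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(x.T @ x)))
        got = np.array([m.alpha, m.beta, m.tau, m.w])
        true = np.array([truth["alpha"], truth["beta"], truth["tau"], truth["w"]])
        np.testing.assert_allclose(got, beta_hat, rtol=1e-8)
        assert np.all(np.abs(got - true) < 3 * se + 1e-12)

    def test_recovery_error_shrinks_with_n(self):
        # the alpha standard error contracts ~1/sqrt(n) and the estimate
        # stays within 3 SE of truth at every n
        ms = ModelSpec("DIAV_LW")
        ses, errs = [], []
        for n in (20, 80, 320):
            data, truth = generate_dataset(SyntheticSpec(seed=42, noise_sigma=0.5), n)
            m = fit_linear(data, ms, gamma=truth["gamma"])
            x = np.array([assemble_features(d, ms, gamma=truth["gamma"]) for d in data])
            y = np.array([d.dg_exptl for d in data])
            resid = y - x @ np.linalg.solve(x.T @ x, x.T @ y)
            sigma2 = resid @ resid / (n - x.shape[1])
            ses.append(np.sqrt(sigma2 * np.linalg.inv(x.T @ x)[0, 0]))
            errs.append(abs(m.alpha - truth["alpha"]))
        assert ses[2] < ses[1] < ses[0]
        assert ses[0] / ses[2] == pytest.approx(np.sqrt(320 / 20), rel=0.5)
        assert all(e < 3 * s for e, s in zip(errs, ses))


class TestGammaOptimization:
    def test_recovers_known_gamma(self):
        tp = dict(alpha=0.0413, beta=0.0062, tau=-6.7e-6, w=0.154, gamma=-5.0)
        data, _ = generate_dataset(SyntheticSpec(seed=4, noise_sigma=0.0, true_params=tp), 20)
        g = optimize_gamma(data, ModelSpec("DIAV_LW"))
        assert abs(g - (-5.0)) < 0.1

    def test_flat_objective_returns_zero(self):
        tp = dict(alpha=0.04, beta=0.006, tau=-6.7e-6, w=0.15, gamma=0.0)
        data, _ = generate_dataset(SyntheticSpec(seed=5, noise_sigma=0.0, true_params=tp), 15)
        flat = [dataclasses.replace(d, h_w=np.full_like(d.h_w, 0.05)) for d in data]
        assert optimize_gamma(flat, ModelSpec("DIAV_LW")) == 0.0

    def test_result_within_bounds(self):
        data, _ = generate_dataset(SyntheticSpec(seed=6, noise_sigma=1.0), 15)
        g = optimize_gamma(data, ModelSpec("DIAV_LW"), bounds=(-20, 20), n_grid=21)
        assert -20.0 <= g <= 20.0


class TestDIASExponents:
    def test_zero_truth_recovered(self):
        tp = dict(alpha=0.04, beta=0.006, tau=-6.7e-6, w=0.0, gamma=0.0, alpha2=0.0, beta2=0.0)
        data, _ = generate_dataset(
            SyntheticSpec(seed=7, noise_sigma=0.0, true_params=tp), 20, model_id="DIAS"
        )
        a2, b2 = fit_dias_exponents(data, ModelSpec("DIAS"))
        assert abs(a2) < 0.05 and abs(b2) < 0.05

    def test_known_exponents_recovered(self):
        tp = dict(alpha=0.04, beta=0.006, tau=-6.7e-6, w=0.0, gamma=0.0, alpha2=0.5, beta2=0.3)
        data, _ = generate_dataset(
            SyntheticSpec(seed=9, noise_sigma=0.0, true_params=tp), 25, model_id="DIAS"
        )
        a2, b2 = fit_dias_exponents(data, ModelSpec("DIAS"))
        assert abs(a2 - 0.5) < 0.05
        assert abs(b2 - 0.3) < 0.05


class TestLOOCV:
    def test_zero_noise_loocv_error_vanishes(self):
        data, truth = generate_dataset(SyntheticSpec(seed=10, noise_sigma=0.0), 20)
        report, _ = loocv(data, ModelSpec("DIAV_LW"), gamma=truth["gamma"])
        assert report.mean_abs_error < 1e-9

    def test_fold_count_and_order(self):
        data, truth = generate_dataset(SyntheticSpec(seed=11, noise_sigma=0.4), 12)
        report, summary = loocv(data, ModelSpec("DIAV_LW"), gamma=truth["gamma"])
        assert len(report.predictions) == 12
        assert list(report.predictions["complex_id"]) == [d.complex_id for d in data]
        assert set(summary.columns) == {"average", "sd", "min", "max", "fraction_negative"}

    @pytest.mark.parametrize("seed", [13, 14, 15])
    def test_loocv_error_at_least_in_sample(self, seed):
        data, truth = generate_dataset(SyntheticSpec(seed=seed, noise_sigma=0.6), 25)
        ms = ModelSpec("DIAV_LW")
        report, _ = loocv(data, ms, gamma=truth["gamma"])
        m = fit_linear(data, ms, gamma=truth["gamma"])
        preds = np.array([
            predict_dg(m, assemble_features(d, ms, gamma=truth["gamma"]), ms) for d in data
        ])
        obs = np.array([d.dg_exptl for d in data])
        assert report.mean_abs_error >= mean_abs_error(preds, obs) - 1e-12

    def test_needs_three_records(self):
        data, _ = generate_dataset(SyntheticSpec(seed=16), 2)
        with pytest.raises(ValueError, match="at least 3"):
            loocv(data, ModelSpec("DIAV"))


class TestStatistics:
    def test_mean_abs_error_identities(self):
        v = np.array([-3.0, -5.0, -7.0])
        assert mean_abs_error(v, v) == 0.0
        assert mean_abs_error(v + 1.3, v) == pytest.approx(1.3)
        with pytest.raises(ValueError):
            mean_abs_error(v, v[:2])

    def test_sd_diff_conventions(self):
        obs = np.zeros(2)
        pred = np.array([1.0, -1.0])
        assert sd_diff(pred, obs) == pytest.approx(1.0)
        assert sd_diff(pred, obs, centered=False) == pytest.approx(1.0)
        # two-pass oracle on arbitrary vectors
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=20), rng.normal(size=20)
        d = a - b
        assert sd_diff(a, b) == pytest.approx(np.sqrt(np.mean((d - d.mean()) ** 2)))

    def test_pearson_identities(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)
        with pytest.raises(ValueError):
            pearson(x, np.ones(4))

    def test_spearman_monotone(self):
        x = np.array([-14.0, -11.0, -9.0, -4.0])
        assert spearman(x, np.exp(x)) == pytest.approx(1.0)

    def test_consensus_score(self):
        assert consensus_score(-10.0, -5.0) == -15.0
        assert consensus_score(-7.3, 0.0) == -7.3
        assert consensus_score(-2.0, -4.0) == consensus_score(-4.0, -2.0)
        with pytest.raises(ValueError):
            consensus_score(np.nan, 1.0)
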