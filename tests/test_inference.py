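"""Likelihood, fitting, diagnostics and model comparison."""

import warnings

import numpy as np
import pytest
from scipy import stats
from scipy.special import logit

from memkin import (LabellingDataset, NoiseScales, SamplerConfig,
                    StudyDesign, compare_models, default_priors, fit_model,
                    generate_labelling_dataset, log_likelihood)
from memkin.inference import (build_kinetic_params, predict_observables,
                              _FREE_KINETIC)
from memkin.model_core import LabellingSchedule, NoEquilibriumError
from memkin.priors import LogNormal

from conftest import QUICK, recovery_truth


def make_dataset(seed=3, logit_sd=0.25, log_sd=0.2):
    p = recovery_truth()
    design = StudyDesign(logit_sd=logit_sd, log_sd=log_sd)
    ds = generate_labelling_dataset("branched", {"TCM": {"donor": p}},
                                    design, seed=seed)
    return p, ds.select(lineage="donor")


class TestLogLikelihood:
    def test_brute_force_oracle(self):
        # independent straight-sum over rows with scipy.stats kernels
        p, tc = make_dataset()
        small = LabellingDataset(tc.data.iloc[:10].copy())
        noise = NoiseScales(0.2, 0.25, 0.3, 0.35, 0.15)
        sched = LabellingSchedule()
        total, pw = log_likelihood("branched", p, small, noise, sched)

        days = small.data["day"].to_numpy(float)
        preds = predict_observables("branched", p, sched, np.unique(days))
        lookup = {d: i for i, d in enumerate(np.unique(days))}
        sigmas = {"f_ki67hi": 0.2, "f_brdu": 0.25,
                  "f_brdu_in_ki67hi": 0.3, "f_brdu_in_ki67lo": 0.35}
        expected = 0.0
        for _, row in small.data.iterrows():
            i = lookup[row["day"]]
            c = 1.0 / (2.0 * row["n_cells"])
            expected += stats.norm.logpdf(
                np.log(row["n_cells"]), np.log(preds["n_cells"][i]), 0.15
            ) - np.log(row["n_cells"])
            for col, s in sigmas.items():
                y = np.clip(row[col], c, 1 - c)
                m = np.clip(preds[col][i], c, 1 - c)
                expected += stats.norm.logpdf(logit(y), logit(m), s) \
                    - np.log(y) - np.log(1 - y)
        assert total == pytest.approx(expected, rel=1e-10)
        assert len(pw) == 10

    def test_noise_free_data_attains_kernel_maximum(self):
        p, tc = make_dataset(logit_sd=0.0, log_sd=0.0)
        noise = NoiseScales()
        _, pw = log_likelihood("branched", p, tc, noise)
        # residuals are zero: each row's contribution equals the maximum of
        # its kernels, so perturbing any single parameter can only lower it
        worse = build_kinetic_params("branched", dict(
            alpha_A=p.alpha_A * 1.3, lambda_A=p.delta_A - p.alpha_A,
            alpha_B=p.alpha_B, lambda_B=p.delta_B - p.alpha_B, psi=p.psi,
            Phi=p.Phi, beta=p.beta, epsilon=p.epsilon))
        _, pw_worse = log_likelihood("branched", worse, tc, noise)
        assert pw.sum() > pw_worse.sum()

    def test_quadratic_residual_penalty(self):
        # doubling a logit residual at fixed scale lowers the contribution
        # by exactly the quadratic increment of the normal kernel
        p, tc = make_dataset(logit_sd=0.0, log_sd=0.0)
        sched = LabellingSchedule()
        noise = NoiseScales()
        df = tc.data.copy()
        i = 5
        pred = predict_observables("branched", p, sched,
                                   np.array([df.loc[i, "day"]]))
        m = logit(pred["f_ki67hi"][0])
        for mult in (1.0, 2.0):
            df.loc[i, "f_ki67hi"] = float(1 / (1 + np.exp(-(m + mult * 0.3))))
            _, pw = log_likelihood("branched", p, LabellingDataset(df),
                                   noise, sched)
            if mult == 1.0:
                base = pw[i]
        diff = base - pw[i]
        y1 = 1 / (1 + np.exp(-(m + 0.3)))
        y2 = 1 / (1 + np.exp(-(m + 0.6)))
        # quadratic increment of the normal kernel plus the (observation-
        # dependent) logit-normal Jacobian term
        expected = (0.6 ** 2 - 0.3 ** 2) / (2 * noise.sigma_ki67 ** 2) \
            + np.log(y2 * (1 - y2)) - np.log(y1 * (1 - y1))
        assert diff == pytest.approx(expected, rel=1e-9)

    def test_row_permutation_invariance(self):
        p, tc = make_dataset()
        total, _ = log_likelihood("branched", p, tc)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(tc))
        shuffled = LabellingDataset(tc.data.iloc[perm].reset_index(drop=True))
        total2, _ = log_likelihood("branched", p, shuffled)
        assert total == pytest.approx(total2, rel=1e-12)

    def test_undefined_rows_contribute_zero(self):
        p, tc = make_dataset()
        df = tc.data.copy()
        base_total, base_pw = log_likelihood("branched", p, tc)
        df.loc[0, "f_brdu_in_ki67lo"] = np.nan
        with pytest.warns(RuntimeWarning, match="undefined"):
            total, pw = log_likelihood("branched", p, LabellingDataset(df))
        assert pw[1:] == pytest.approx(base_pw[1:])
        assert pw[0] > base_pw[0] - 10  # only that row changed
        assert total != pytest.approx(base_total)


class TestFitModel:
    def test_seed_determinism_bitwise(self):
        _, tc = make_dataset()
        fits = [fit_model("branched", tc, sampler_config=SamplerConfig(
            n_walkers=32, n_steps=120, burn=60, n_store=50), seed=9)
            for _ in range(2)]
        np.testing.assert_array_equal(fits[0].chain, fits[1].chain)
        np.testing.assert_array_equal(fits[0].log_lik, fits[1].log_lik)

    def test_low_noise_posterior_concentrates(self):
        p = recovery_truth()
        design = StudyDesign(logit_sd=0.02, log_sd=0.02)
        ds = generate_labelling_dataset("branched", {"TCM": {"donor": p}},
                                        design, seed=21)
        tc = ds.select(lineage="donor")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_model("branched", tc,
                            priors={"Phi": LogNormal(p.Phi, 0.1)},
                            sampler_config=QUICK, seed=5)
        s = fit.summary(["epsilon", "T_ki67", "N0"])
        assert s.loc["epsilon", "median"] == pytest.approx(0.5, abs=0.12)
        assert s.loc["T_ki67", "median"] == pytest.approx(3.1, abs=0.6)
        assert s.loc["N0", "median"] == pytest.approx(5e4, rel=0.05)
        # the pool size is pinned to a few percent by near-noiseless counts
        # (against a prior spanning orders of magnitude)
        width = s.loc["N0", "hi95"] - s.loc["N0", "lo95"]
        assert width / 5e4 < 0.1

    def test_posterior_object_shapes(self, quick_fit):
        assert quick_fit.log_lik.shape == (len(quick_fit.draws), 24)
        assert set(quick_fit.param_names) <= set(quick_fit.draws.columns)
        assert {"N0", "N_A", "N_B", "lambda_A", "lambda_B"} \
            <= set(quick_fit.draws.columns)
        assert "max_rhat" in quick_fit.diagnostics
        ci = quick_fit.credible_interval("epsilon")
        assert ci[0] < ci[1]

    def test_prior_predictive_integrates(self):
        # draws from the default priors must admit a steady state and a
        # finite trajectory in at least 99% of cases
        rng = np.random.default_rng(3)
        priors = default_priors("branched")
        sched = LabellingSchedule()
        failures = 0
        n = 1000
        for _ in range(n):
            vals = {k: float(priors[k].sample(rng))
                    for k, _ in _FREE_KINETIC["branched"]}
            try:
                p = build_kinetic_params("branched", vals)
                preds = predict_observables("branched", p, sched,
                                            np.array([1.0, 21.0, 35.0]))
                if not np.all(np.isfinite(preds["n_cells"])):
                    failures += 1
            except (NoEquilibriumError, ValueError):
                failures += 1
        assert failures < 0.01 * n

    def test_unknown_structure_rejected(self):
        _, tc = make_dataset()
        with pytest.raises(ValueError):
            fit_model("spaghetti", tc)


class TestCompareModels:
    def test_model_against_itself_indistinguishable(self, quick_fit):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab = compare_models([quick_fit, quick_fit],
                                 names=["a", "b"])
        assert tab["delta_elpd"].abs().max() == pytest.approx(0.0, abs=1e-9)
        assert tab["indistinguishable"].all()

    def test_true_model_beats_misspecified(self):
        # high-signal branched data: the branched fit must not trail a
        # deliberately simplified homogeneous model
        p = recovery_truth()
        design = StudyDesign(logit_sd=0.1, log_sd=0.1)
        ds = generate_labelling_dataset("branched", {"TCM": {"donor": p}},
                                        design, seed=33)
        tc = ds.select(lineage="donor")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fb = fit_model("branched", tc,
                           priors={"Phi": LogNormal(p.Phi, 0.15)},
                           sampler_config=QUICK, seed=1)
            fh = fit_model("homogeneous", tc,
                           priors={"Phi": LogNormal(p.Phi, 0.15)},
                           sampler_config=QUICK, seed=1)
            tab = compare_models([fb, fh], names=["branched", "homogeneous"])
        tab = tab.set_index("model")
        assert tab.loc["branched", "elpd"] \
            >= tab.loc["homogeneous", "elpd"] - 4.0

    def test_mismatched_datasets_rejected(self, quick_fit):
        other = quick_fit
        import copy
        bad = copy.copy(other)
        bad.log_lik = other.log_lik[:, :-1]
        with pytest.raises(ValueError):
            compare_models([other, bad])
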