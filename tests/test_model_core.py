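"""Core ODE model: steady states, closed-form limits, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memkin import (KineticParams, LabellingSchedule,
                    NoEquilibriumError, equilibrium_influx,
                    integrate_labelling, ki67_steady_fraction, observables,
                    steady_state, with_equilibrium_influx)
from memkin.model_core import LabelState
from memkin.inference import predict_observables


def homogeneous(alpha, delta, n0=1e5, **kw):
    kw.setdefault("N0", n0)
    return KineticParams(alpha_A=alpha, delta_A=delta, psi=1.0,
                         beta=kw.pop("beta", 1 / 3.1), **kw)


class TestSteadyState:
    def test_balanced_birth_death_is_constant(self):
        # zero influx, alpha = delta: population constant, all unlabelled
        p = homogeneous(0.05, 0.05, Phi=0.0, epsilon=0.0)
        ss = steady_state("branched", p)
        assert ss.total == pytest.approx(1e5, rel=1e-8)
        assert ss.brdu_fraction() == 0.0
        traj = integrate_labelling("branched", p, LabellingSchedule(), [0, 35])
        assert traj[-1].total == pytest.approx(1e5, rel=1e-6)

    def test_influx_fed_ki67_fraction_closed_form(self):
        # dK_hi/dt = 0 with influx all Ki67-high and Phi = (delta-alpha) N0
        # gives k* = (delta + alpha) / (alpha + beta + delta); the oracle is
        # long-time integration of the same system.
        a, d, beta, n0 = 0.05, 0.1, 1 / 3.1, 1e6
        p = homogeneous(a, d, n0=n0, beta=beta, Phi=(d - a) * n0)
        ss = steady_state("branched", p)
        assert ss.ki67hi_fraction() == pytest.approx(
            (d + a) / (a + beta + d), rel=1e-8)
        # oracle: frozen value from integrating to t = 1e4 d
        sched = LabellingSchedule(t_pulse_end=0.0, t_chase_end=1e4)
        far = integrate_labelling("branched", p, sched, [1e4],
                                  initial=LabelState(ss.x * 1.1))
        assert far[0].ki67hi_fraction() == pytest.approx(
            ss.ki67hi_fraction(), abs=1e-8)

    def test_branched_subpopulation_balance(self):
        # each branch balances its own share of the influx
        p = KineticParams(alpha_A=0.01, delta_A=0.02, alpha_B=0.2,
                          delta_B=0.27, psi=0.3, Phi=1000.0, beta=1 / 3.1)
        ss = steady_state("branched", p)
        assert ss.subpop_total(0) == pytest.approx(0.3 * 1000 / 0.01, rel=1e-8)
        assert ss.subpop_total(1) == pytest.approx(0.7 * 1000 / 0.07, rel=1e-8)

    def test_no_equilibrium_raises(self):
        # a growing branch (delta_B < alpha_B) admits no steady state
        p = KineticParams(alpha_A=0.01, delta_A=0.02, alpha_B=0.3,
                          delta_B=0.2, psi=0.3, Phi=1000.0)
        with pytest.raises(NoEquilibriumError):
            steady_state("branched", p)

    def test_zero_influx_unbalanced_raises(self):
        p = homogeneous(0.05, 0.1, Phi=0.0)
        with pytest.raises(NoEquilibriumError):
            steady_state("branched", p)

    def test_n0_consistency_check(self):
        p = KineticParams(alpha_A=0.01, delta_A=0.02, psi=1.0, Phi=500.0,
                          N0=1e4)
        with pytest.raises(ValueError, match="N0"):
            steady_state("branched", p)
        fixed = with_equilibrium_influx("branched", p)
        assert steady_state("branched", fixed).total == pytest.approx(1e4)

    def test_lineage_split_follows_chi0(self):
        p = KineticParams(alpha_A=0.01, delta_A=0.02, psi=1.0, Phi=500.0,
                          chi0=0.3)
        ss = steady_state("branched", p)
        assert ss.lineage_total(1) / ss.total == pytest.approx(0.3)

    @pytest.mark.parametrize("structure,extra", [
        ("linear", dict(gamma=0.05)),
        ("burst", dict(omega=0.01, rho=0.02)),
        ("temporal", dict(delta_hi=0.3, delta_lo=0.05)),
    ])
    def test_steady_state_is_fixed_point(self, structure, extra):
        p = KineticParams(alpha_A=0.05, delta_A=0.1, alpha_B=0.2,
                          delta_B=0.3, Phi=2000.0, beta=1 / 3.1, **extra)
        ss = steady_state(structure, p)
        sched = LabellingSchedule(t_pulse_end=0.0, t_chase_end=200.0)
        later = integrate_labelling(structure, p, sched, [200.0], initial=ss)
        np.testing.assert_allclose(later[0].x, ss.x, rtol=1e-6,
                                   atol=1e-8 * ss.total)


class TestKi67SteadyFraction:
    def test_no_division_no_influx_gives_zero(self):
        p = homogeneous(0.0, 0.0, Phi=0.0)
        assert ki67_steady_fraction(p) == 0.0

    def test_balanced_closed_form_vs_integration(self):
        a, beta = 0.05, 1 / 3.1
        p = homogeneous(a, a, Phi=0.0)
        k = ki67_steady_fraction(p)
        assert k == pytest.approx(2 * a / (2 * a + beta), rel=1e-8)
        sched = LabellingSchedule(t_pulse_end=0.0, t_chase_end=2000.0)
        ss = steady_state("branched", p)
        far = integrate_labelling("branched", p, sched, [2000.0],
                                  initial=LabelState(ss.x * 1.2))[0]
        assert far.ki67hi_fraction() == pytest.approx(k, abs=1e-8)

    def test_influx_fed_quiescent_pool(self):
        # no division: Ki67-high balance is influx in, beta + loss out
        d, beta = 0.05, 1 / 3.1
        p = homogeneous(0.0, d, Phi=500.0, N0=None)
        k = ki67_steady_fraction(p)
        assert k == pytest.approx(d / (d + beta), rel=1e-8)
        assert ki67_steady_fraction(p) == pytest.approx(
            steady_state("branched", p).ki67hi_fraction(), rel=1e-8)


class TestLabelling:
    def test_full_efficiency_closed_form(self, schedule):
        # epsilon=1, Phi=0: BrdU+ fraction is exactly 1 - exp(-2 alpha t)
        alpha = 0.1
        p = homogeneous(alpha, alpha, Phi=0.0, epsilon=1.0)
        ts = [0.0, 1.0, 2.0, 5.0, 10.0, 21.0]
        traj = integrate_labelling("branched", p, schedule, ts)
        obs = observables(traj, per_lineage=False)
        np.testing.assert_allclose(obs["f_brdu"].to_numpy(),
                                   1 - np.exp(-2 * alpha * np.array(ts)),
                                   atol=1e-6)

    def test_no_labelling_pathway_stays_zero(self):
        p = homogeneous(0.1, 0.1, Phi=0.0, epsilon=0.0)
        sched = LabellingSchedule(s_max=0.0, r_s=1.0, r_decay=1.0)
        traj = integrate_labelling("branched", p, sched, [5.0, 21.0, 30.0])
        assert all(s.brdu_fraction() == 0.0 for s in traj)

    def test_pulse_shape_branched(self, young_truth, schedule):
        # BrdU within Ki67-high rises steeply toward an asymptote below 1
        # when epsilon < 1; BrdU+ Ki67-low cells appear only after a delay
        # of about the Ki67 lifetime.
        p = young_truth["TCM"]["donor"]
        days = np.array([0.5, 1, 2, 3.1, 7, 14, 21])
        pr = predict_observables("branched", p, schedule, days)
        hi = pr["f_brdu_in_ki67hi"]
        assert np.all(np.diff(hi) > 0)
        assert hi[-1] < 0.95          # asymptote < 1 for epsilon = 0.5
        assert hi[3] > 0.6            # steep early rise
        lo = pr["f_brdu_in_ki67lo"]
        assert lo[1] < 0.1            # delayed by about 1/beta = 3.1 d
        assert lo[-1] > 0.2

    def test_label_monotone_during_pulse(self, young_truth, schedule):
        p = young_truth["TEM"]["host"]
        days = np.linspace(0.5, 21, 15)
        pr = predict_observables("branched", p, schedule, days)
        assert np.all(np.diff(pr["f_brdu_in_ki67hi"]) >= -1e-10)

    def test_chase_label_declines(self, young_truth, schedule):
        p = young_truth["TCM"]["donor"]
        days = np.array([21.0, 25.0, 30.0, 35.0])
        pr = predict_observables("branched", p, schedule, days)
        assert pr["f_brdu"][-1] < pr["f_brdu"][0]

    @pytest.mark.parametrize("structure,extra", [
        ("branched", dict(psi=0.3)),
        ("linear", dict(gamma=0.04)),
        ("burst", dict(omega=0.02, rho=0.05)),
        ("temporal", dict(delta_hi=0.3, delta_lo=0.04)),
    ])
    def test_fast_path_matches_solve_ivp(self, structure, extra, schedule):
        p = KineticParams(alpha_A=0.02, delta_A=0.05, alpha_B=0.2,
                          delta_B=0.3, Phi=3000.0, beta=1 / 3.1,
                          epsilon=0.5, **extra)
        days = np.array([1.0, 5.0, 14.0, 21.0, 28.0, 35.0])
        fast = predict_observables(structure, p, schedule, days,
                                   method="expm")
        slow = predict_observables(structure, p, schedule, days,
                                   method="ivp")
        for key in fast:
            np.testing.assert_allclose(fast[key], slow[key], rtol=2e-6,
                                       atol=1e-8)

    def test_erlang_stages_conserve_mass(self, schedule):
        p = KineticParams(alpha_A=0.05, delta_A=0.1, psi=1.0, Phi=5000.0,
                          beta=1 / 3.1, epsilon=0.6, ki67_stages=3)
        ss = steady_state("branched", p)
        traj = integrate_labelling("branched", p, schedule, [0, 10, 21, 35],
                                   initial=ss)
        for s in traj:
            assert s.total == pytest.approx(ss.total, rel=1e-6)

    def test_mass_balance_out_of_equilibrium(self):
        # d(total)/dt must equal Phi + sum (alpha_i - delta_i) N_i even when
        # the initial state is not the steady state
        p = KineticParams(alpha_A=0.02, delta_A=0.05, alpha_B=0.2,
                          delta_B=0.3, psi=0.4, Phi=3000.0, epsilon=0.7)
        ss = steady_state("branched", p)
        x0 = LabelState(ss.x * 1.5)
        sched = LabellingSchedule()
        h = 1e-4
        traj = integrate_labelling("branched", p, sched,
                                   [5.0 - h, 5.0, 5.0 + h], initial=x0)
        dN = (traj[2].total - traj[0].total) / (2 * h)
        n_a = traj[1].subpop_total(0)
        n_b = traj[1].subpop_total(1)
        expect = p.Phi + (p.alpha_A - p.delta_A) * n_a \
            + (p.alpha_B - p.delta_B) * n_b
        assert dN == pytest.approx(expect, rel=1e-4)

    def test_quasi_equilibrium_constancy(self, young_truth, schedule):
        # numbers and Ki67-high fractions stay constant through the assay
        p = young_truth["TEM"]["host"]
        traj = integrate_labelling("branched", p, schedule,
                                   np.linspace(0, 35, 8))
        n0, k0 = traj[0].total, traj[0].ki67hi_fraction()
        for s in traj:
            assert s.total == pytest.approx(n0, rel=1e-6)
            assert s.ki67hi_fraction() == pytest.approx(k0, rel=1e-6)

    @settings(max_examples=10, deadline=None)
    @given(alpha=st.floats(0.01, 0.3), lam=st.floats(0.001, 0.1),
           eps=st.floats(0.1, 1.0))
    def test_population_constant_property(self, alpha, lam, eps):
        # quasi-equilibrium holds for any admissible parameter combination
        p = KineticParams(alpha_A=alpha, delta_A=alpha + lam, psi=1.0,
                          Phi=lam * 1e5, epsilon=eps)
        traj = integrate_labelling("branched", p, LabellingSchedule(),
                                   [0.0, 17.0, 35.0])
        assert traj[-1].total == pytest.approx(traj[0].total, rel=1e-6)


class TestObservables:
    def test_all_unlabelled_gives_zero_brdu(self, young_truth):
        ss = steady_state("branched", young_truth["TCM"]["host"])
        obs = observables([ss])
        assert (obs["f_brdu"].dropna() == 0).all()

    def test_equal_compartments_give_half(self):
        state = LabelState(np.full((2, 2, 2, 2), 10.0))
        obs = observables([state], per_lineage=False)
        row = obs.iloc[0]
        for col in ("f_ki67hi", "f_brdu", "f_brdu_in_ki67hi",
                    "f_brdu_in_ki67lo"):
            assert row[col] == pytest.approx(0.5)

    def test_empty_denominator_is_nan_with_warning(self):
        x = np.zeros((2, 2, 2, 2))
        x[0, 0, 0, 0] = 5.0  # only Ki67-high cells: the ki67-low gate is empty
        with pytest.warns(RuntimeWarning, match="empty denominator"):
            obs = observables([LabelState(x)], per_lineage=False)
        assert np.isnan(obs.iloc[0]["f_brdu_in_ki67lo"])

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            observables([])


class TestValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            KineticParams(alpha_A=-0.1)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            KineticParams(psi=1.2)

    def test_negative_state_rejected(self):
        x = np.zeros((2, 2, 2, 2))
        x[0, 0, 0, 0] = -5.0
        with pytest.raises(ValueError):
            LabelState(x)

    def test_schedule_ordering_enforced(self):
        with pytest.raises(ValueError):
            LabellingSchedule(t_pulse_end=10.0, t_chase_end=5.0)

    def test_times_outside_window_rejected(self, young_truth, schedule):
        with pytest.raises(ValueError):
            integrate_labelling("branched", young_truth["TCM"]["host"],
                                schedule, [40.0])
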