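"""Forward predictions for the two fate-reporter validation experiments.

1. **Cohort transfer** (Ki67 reporter, YFP fate label): cells expressing
   Ki67 at tamoxifen treatment become YFP-positive — a cohort enriched for
   recently divided (fast) cells.  After transfer into a new host the model
   predicts the Ki67-high fraction of the whole cohort and of the YFP+ /
   YFP- subcohorts: decline of bulk Ki67 without influx, maintenance with
   influx, and convergence of YFP+ and YFP- Ki67 levels within about a
   week.  A homogeneous population with loss balanced by self-renewal and
   no influx would preserve the cohort's Ki67 level — the falsification
   logic for the uniform-rate null model.

2. **mTom dilution** (CD4 reporter): cells expressing CD4 at tamoxifen
   heritably express mTomato, so in a closed population the mTom+ fraction
   is constant and any dilution measures the influx of unlabelled
   precursors.  Given the fitted kinetics and an empirical description of
   the naive-pool mTom+ fraction, the model predicts the mTom+ timecourses
   in central and effector memory; driving the effector-memory prediction
   with the predicted central-memory trajectory (naive -> TCM -> TEM) is
   compared against driving it with the naive curve directly.

Both reuse the labelling machinery of :mod:`memkin.model_core` with the
label axis reinterpreted as the heritable reporter (labelling efficiency 0:
division preserves the label, only influx composition moves the fraction).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import model_core as mc
from .inference import _FREE_KINETIC, PosteriorDraws, build_kinetic_params, kinetic_structure
from .model_core import KineticParams, LabellingSchedule, ModelStructure

__all__ = ["NaiveLabelCurve", "simulate_cohort_transfer", "predict_mtom"]


@dataclass
class NaiveLabelCurve:
    """Empirical mTom+ fraction among naive CD4 T cells vs days post tamoxifen.

    Parametric form ``g(t) = f_inf + (f_0 - f_inf) exp(-r t)`` with
    ``0 <= f_inf <= f_0 <= 1`` and ``r >= 0``, so ``g`` is non-increasing
    (dilution by unlabelled thymic influx) and stays in [0, 1].
    """

    f0: float
    f_inf: float
    r: float
    data: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_inf <= self.f0 <= 1.0) or self.r < 0:
            raise ValueError("require 0 <= f_inf <= f0 <= 1 and r >= 0")

    def __call__(self, t):
        return self.f_inf + (self.f0 - self.f_inf) * np.exp(-self.r * np.asarray(t, float))

    @classmethod
    def fit(cls, days, fractions) -> "NaiveLabelCurve":
        """Least-squares fit of the exponential-decay form."""
        days = np.asarray(days, float)
        y = np.asarray(fractions, float)

        def form(t, f_inf, drop, r):
            return f_inf + drop * np.exp(-r * t)

        p0 = (max(y.min(), 1e-3), max(y.max() - y.min(), 1e-3), 0.02)
        popt, _ = curve_fit(form, days, y, p0=p0,
                            bounds=([0, 0, 0], [1, 1, 10]), maxfev=10000)
        f_inf, drop, r = popt
        f0 = min(f_inf + drop, 1.0)
        return cls(f0=float(f0), f_inf=float(f_inf), r=float(r),
                   data=pd.DataFrame({"day": days, "f_mtom": y}))


def _reporter_schedule(horizon: float, source_fn=None) -> LabellingSchedule:
    """Schedule for reporter dynamics: no division-linked labelling; the
    influx carries labelled fraction ``source_fn(t)`` (default 0)."""
    if source_fn is None:
        return LabellingSchedule(t_pulse_end=0.0, t_chase_end=horizon,
                                 s_max=0.0, r_s=1.0, r_decay=1.0)
    return LabellingSchedule(t_pulse_end=horizon, t_chase_end=horizon,
                             source_label_fn=source_fn)


def _evolve(structure: ModelStructure, params: KineticParams,
            x0: np.ndarray, days: np.ndarray,
            source_fn=None) -> np.ndarray:
    """Evolve one lineage's (subpop, ki67, label) state; returns
    trajectory of shape (len(days), 2, stages+1, 2)."""
    horizon = float(max(days.max(), 1e-6))
    sched = _reporter_schedule(horizon, source_fn)
    p = replace(params, epsilon=0.0, N0=None)
    y0 = x0.ravel()
    sol = mc._integrate_lineage_ivp(structure, p, sched, days, y0, p.Phi,
                                    rtol=1e-8, atol=1e-10 * max(y0.sum(), 1.0))
    return np.clip(sol.reshape((len(days),) + x0.shape), 0.0, None)


def simulate_cohort_transfer(structure: ModelStructure | str,
                             params: KineticParams,
                             with_influx: bool,
                             horizon: float = 7.0,
                             pre_transfer_days: float = 3.0,
                             readout_days=None) -> pd.DataFrame:
    """Ki67 timecourses of a transferred cohort labelled while Ki67-high.

    The initial cohort is the fitted steady state with every Ki67-high cell
    YFP-labelled; it evolves ``pre_transfer_days`` in the donor animal
    (influx present) and is then transferred, keeping the influx (bulk
    transfer) or removing it (purified-subset transfer).  Returns the
    Ki67-high fraction of the whole cohort and within YFP+ / YFP- cells,
    plus the YFP+ fraction, at days after transfer.
    """
    structure = ModelStructure(structure)
    ss = mc.steady_state(structure, params)
    m = ss.stages
    x = ss.x.sum(axis=3)  # collapse lineage: (subpop, ki67, label)
    if x.sum() <= 0:
        raise ValueError("empty cohort")
    # label = YFP: Ki67-high cells at tamoxifen become YFP+
    x[:, :m, 1] = x[:, :m, 0]
    x[:, :m, 0] = 0.0
    if pre_transfer_days > 0:
        x = _evolve(structure, params, x,
                    np.array([pre_transfer_days]))[0]
    p_post = params if with_influx else replace(params, Phi=0.0, N0=None)
    days = np.asarray(readout_days if readout_days is not None
                      else np.linspace(0.0, horizon, 15), float)
    traj = _evolve(structure, p_post, x, days)

    hi = traj[:, :, :m].sum(axis=(1, 2, 3))
    tot = traj.sum(axis=(1, 2, 3))
    yfp = traj[..., 1].sum(axis=(1, 2))
    hi_yfp = traj[:, :, :m, 1].sum(axis=(1, 2))
    neg = traj[..., 0].sum(axis=(1, 2))
    hi_neg = traj[:, :, :m, 0].sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        return pd.DataFrame({
            "day": days,
            "f_ki67hi_cohort": np.where(tot > 0, hi / tot, np.nan),
            "f_ki67hi_yfp_pos": np.where(yfp > 0, hi_yfp / yfp, np.nan),
            "f_ki67hi_yfp_neg": np.where(neg > 0, hi_neg / neg, np.nan),
            "f_yfp": np.where(tot > 0, yfp / tot, np.nan),
        })


def _params_from_draw(fit: PosteriorDraws, row: pd.Series) -> KineticParams:
    kin = {n: float(row[n]) for n, _ in _FREE_KINETIC[fit.structure]}
    return build_kinetic_params(fit.structure, kin)


def _mtom_fraction_traj(structure, params, m0, days, source_fn):
    if params.Phi == 0 and params.N0 is None:
        # the labelled fraction is scale-invariant; any pool size serves
        params = replace(params, N0=1.0)
    ss_grid = mc._unlabelled_steady(structure, params).reshape(
        2, params.ki67_stages + 1)
    x0 = np.zeros(ss_grid.shape + (2,))
    x0[..., 0] = (1.0 - m0) * ss_grid
    x0[..., 1] = m0 * ss_grid
    traj = _evolve(structure, params, x0, days, source_fn=source_fn)
    tot = traj.sum(axis=(1, 2, 3))
    lab = traj[..., 1].sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(tot > 0, lab / tot, np.nan)


def predict_mtom(fits: dict[str, PosteriorDraws],
                 naive_curve: NaiveLabelCurve,
                 initial_fractions: dict[str, float],
                 times,
                 n_draws: int = 1000,
                 seed: int = 0,
                 tem_source: str = "TCM") -> dict[str, dict]:
    """Predicted mTom+ fractions in central and effector memory.

    Per posterior draw the labelled fraction of each subset evolves under
    the fitted influx/division/loss rates with a heritable label: the
    central-memory source is the naive curve ``g(t)``, the effector-memory
    source is the predicted central-memory trajectory (``tem_source="TCM"``,
    the naive -> TCM -> TEM pathway) or the naive curve directly
    (``tem_source="naive"``).  Returns per subset the draw matrix and the
    2.5/50/97.5 percentile band.
    """
    for key in ("TCM", "TEM"):
        if key in fits and key not in initial_fractions:
            raise ValueError(f"missing initial mTom fraction for {key}")
    if tem_source not in ("TCM", "naive"):
        raise ValueError("tem_source must be 'TCM' or 'naive'")
    if tem_source == "TCM" and "TEM" in fits and "TCM" not in fits:
        raise ValueError("TEM prediction driven by TCM needs a TCM fit")
    times = np.asarray(times, float)
    dense = np.union1d(times, np.linspace(0, times.max(), 60))
    rng = np.random.default_rng(seed)
    out: dict[str, dict] = {}

    def band(mat):
        return {"times": times,
                "draws": mat,
                "median": np.median(mat, axis=0),
                "lo95": np.quantile(mat, 0.025, axis=0),
                "hi95": np.quantile(mat, 0.975, axis=0)}

    mat_dense_tcm = None
    for subset in ("TCM", "TEM"):
        if subset not in fits:
            continue
        fit = fits[subset]
        struct = kinetic_structure(fit.structure)
        n_avail = len(fit.draws)
        idx = rng.choice(n_avail, size=min(n_draws, n_avail),
                         replace=n_draws > n_avail)
        mat = np.empty((len(idx), len(times)))
        mat_dense = np.empty((len(idx), len(dense)))
        for j, i in enumerate(idx):
            params = _params_from_draw(fit, fit.draws.iloc[int(i)])
            if subset == "TCM" or tem_source == "naive":
                src = naive_curve
            else:
                mcm = mat_dense_tcm[j % mat_dense_tcm.shape[0]]
                src = (lambda t, m=mcm: float(np.interp(t, dense, m)))
            y = _mtom_fraction_traj(struct, params,
                                    initial_fractions[subset], dense, src)
            mat_dense[j] = y
            mat[j] = np.interp(times, dense, y)
        if subset == "TCM":
            mat_dense_tcm = mat_dense
        out[subset] = band(mat)
    return out
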