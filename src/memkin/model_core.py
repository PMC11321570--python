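"""Compartmental ODE models of BrdU/Ki67 labelling in memory T cell subsets.

A memory subset (central or effector memory CD4 T cells) is modelled as one
or two kinetically distinct subpopulations fed by a constant influx ``Phi``
of newly generated memory cells.  Each cell is classified by

* subpopulation (``A``/``B``; which rates apply depends on the structure),
* Ki67 status (high for a mean duration ``T = 1/beta`` after division, then
  low; optionally Erlang-staged),
* BrdU content (labelled / unlabelled), and
* lineage (host- or donor-derived, in busulfan chimeras).

Division removes the parent and creates two Ki67-high daughters; during a
BrdU pulse the daughters of an unlabelled parent are labelled with
probability ``epsilon`` (the per-division labelling efficiency), and
daughters of a labelled parent inherit the label.  Influx enters Ki67-high,
split between lineages by the influx donor fraction ``f_d`` and carrying a
time-varying labelled fraction set by the labelling schedule.

Structures
----------
``branched``
    Influx bifurcates: fraction ``psi`` enters slow subpopulation A, the
    rest enters fast subpopulation B; no flows between A and B.
``linear``
    Influx enters the fast entry state A, which matures into the slow
    descendant state B at rate ``gamma`` (Ki67 and BrdU status preserved).
``burst``
    Quiescent cells A are activated into a fast "burst" state B at rate
    ``omega`` and return at rate ``rho``; influx enters the burst state B
    (new memory cells have divided recently).
``temporal``
    A single population whose loss rate depends on Ki67 status
    (``delta_hi`` / ``delta_lo``) rather than on membership of a
    subpopulation.

The whole system is linear in the state, so steady states are obtained by
direct linear solves and trajectories by a stiff-capable ODE integrator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm, null_space

__all__ = [
    "ModelStructure",
    "KineticParams",
    "LabelState",
    "LabellingSchedule",
    "NoEquilibriumError",
    "IntegrationError",
    "steady_state",
    "integrate_labelling",
    "observables",
    "ki67_steady_fraction",
    "equilibrium_influx",
    "with_equilibrium_influx",
]

HOST, DONOR = 0, 1
SUBPOP_A, SUBPOP_B = 0, 1


class NoEquilibriumError(ValueError):
    """No non-negative steady state exists for the requested parameters."""


class IntegrationError(RuntimeError):
    """The ODE integrator failed or produced an inadmissible trajectory."""


class ModelStructure(str, Enum):
    """Topology of kinetic heterogeneity within one memory subset."""

    branched = "branched"
    linear = "linear"
    burst = "burst"
    temporal = "temporal"

    @property
    def description(self) -> str:
        return _STRUCTURE_DESCRIPTIONS[self]

    @property
    def active_params(self) -> tuple[str, ...]:
        """Structure-specific transition parameters that are read."""
        return _ACTIVE[self]


_STRUCTURE_DESCRIPTIONS = {
    ModelStructure.branched: (
        "independent slow (A) and fast (B) lineages branching from the "
        "precursor; influx split psi into A"
    ),
    ModelStructure.linear: (
        "fast entry state A maturing into slow descendant B at rate gamma"
    ),
    ModelStructure.burst: (
        "quiescent A cycling into a fast burst state B (omega) and back (rho); "
        "influx enters B"
    ),
    ModelStructure.temporal: (
        "single population with Ki67-dependent loss rates delta_hi/delta_lo"
    ),
}

_ACTIVE = {
    ModelStructure.branched: ("alpha_A", "delta_A", "alpha_B", "delta_B", "psi"),
    ModelStructure.linear: ("alpha_A", "delta_A", "alpha_B", "delta_B", "gamma"),
    ModelStructure.burst: (
        "alpha_A", "delta_A", "alpha_B", "delta_B", "omega", "rho",
    ),
    ModelStructure.temporal: ("alpha_A", "delta_hi", "delta_lo"),
}

_FRACTION_FIELDS = ("psi", "epsilon", "f_d", "chi0")


@dataclass
class KineticParams:
    """All rates and fractions for one memory subset in one cohort.

    Rates are per day; fractions are dimensionless in [0, 1].  Parameters
    that are inactive for a given structure are ignored, not required to be
    zero.  Subpopulation conventions: for ``branched`` and ``burst``,
    A = slow/quiescent and B = fast/burst; for ``linear``, A = fast entry
    state and B = slow descendant.
    """

    alpha_A: float = 0.0       #: division rate of A
    delta_A: float = 0.0       #: loss rate (death + onward differentiation) of A
    alpha_B: float = 0.0       #: division rate of B
    delta_B: float = 0.0       #: loss rate of B
    psi: float = 1.0           #: fraction of influx entering A (branched)
    gamma: float = 0.0         #: A -> B maturation rate (linear)
    omega: float = 0.0         #: quiescent -> burst activation rate (burst)
    rho: float = 0.0           #: burst -> quiescent return rate (burst)
    beta: float = 1.0 / 3.1    #: Ki67-high -> low rate; mean high duration T = 1/beta
    epsilon: float = 1.0       #: per-division BrdU labelling efficiency
    Phi: float = 0.0           #: total influx of new memory cells, cells/day
    f_d: float = 0.0           #: donor fraction of the influx
    N0: float | None = None    #: total population size at pulse start (None: implied)
    chi0: float = 0.0          #: donor fraction of the standing population at t=0
    delta_hi: float = 0.0      #: loss rate of Ki67-high cells (temporal only)
    delta_lo: float = 0.0      #: loss rate of Ki67-low cells (temporal only)
    ki67_stages: int = 1       #: Erlang stages for the Ki67-high duration

    def __post_init__(self) -> None:
        for name in ("alpha_A", "delta_A", "alpha_B", "delta_B", "gamma",
                     "omega", "rho", "beta", "Phi", "delta_hi", "delta_lo"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in _FRACTION_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.ki67_stages < 1:
            raise ValueError("ki67_stages must be >= 1")
        if self.N0 is not None and self.N0 < 0:
            raise ValueError("N0 must be non-negative")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParams":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass
class LabellingSchedule:
    """BrdU administration window and the labelled fraction of the influx.

    ``t = 0`` is the first BrdU administration.  During the pulse the influx
    carries the labelled fraction ``source_label_fn(t)``; the chase is
    modelled by switching the labelling efficiency to zero and the source
    labelling to its decay branch at ``t_pulse_end``.
    """

    t_pulse_end: float = 21.0
    t_chase_end: float = 35.0
    source_label_fn: Callable[[float], float] | None = None
    # Parameters of the default parametric source-labelling form; present
    # (not None) iff source_label_fn follows s_max*(1 - exp(-r_s t)) during
    # the pulse and exponential decay at rate r_decay afterwards.  The fast
    # semi-analytic solver requires them.
    s_max: float | None = 0.3
    r_s: float | None = 0.1
    r_decay: float | None = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.t_pulse_end <= self.t_chase_end:
            raise ValueError("require 0 <= t_pulse_end <= t_chase_end")
        if self.source_label_fn is None:
            if None in (self.s_max, self.r_s, self.r_decay):
                raise ValueError("parametric schedule needs s_max, r_s, r_decay")
            self.source_label_fn = self._parametric_source
        else:
            # custom callable supplied: disable the parametric fast path
            self.s_max = self.r_s = self.r_decay = None

    def _parametric_source(self, t: float) -> float:
        if t <= self.t_pulse_end:
            return self.s_max * (1.0 - np.exp(-self.r_s * t))
        s_pe = self.s_max * (1.0 - np.exp(-self.r_s * self.t_pulse_end))
        return s_pe * np.exp(-self.r_decay * (t - self.t_pulse_end))

    @property
    def is_parametric(self) -> bool:
        return self.s_max is not None


@dataclass
class LabelState:
    """Compartment cell counts at one time point.

    ``x`` has shape ``(2 subpop, stages+1 Ki67, 2 BrdU, 2 lineage)``;
    Ki67 axis: indices ``0..stages-1`` are Ki67-high Erlang stages and the
    last index is Ki67-low.  BrdU axis: 0 = unlabelled, 1 = labelled.
    Lineage axis: 0 = host, 1 = donor.
    """

    x: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 4 or self.x.shape[0] != 2 or self.x.shape[2:] != (2, 2):
            raise ValueError("LabelState array must have shape (2, stages+1, 2, 2)")
        if np.any(self.x < -1e-9 * max(self.total, 1.0)):
            raise ValueError("negative compartment count")

    @property
    def stages(self) -> int:
        return self.x.shape[1] - 1

    @property
    def total(self) -> float:
        return float(self.x.sum())

    def ki67_collapsed(self) -> np.ndarray:
        """Counts with the Erlang stages merged: shape (2, 2 hi/lo, 2, 2)."""
        hi = self.x[:, : self.stages].sum(axis=1)
        lo = self.x[:, self.stages]
        return np.stack([hi, lo], axis=1)

    def lineage_total(self, lineage: int) -> float:
        return float(self.x[..., lineage].sum())

    def subpop_total(self, subpop: int) -> float:
        return float(self.x[subpop].sum())

    def ki67hi_fraction(self, lineage: int | None = None) -> float:
        x = self.x if lineage is None else self.x[..., [lineage]]
        tot = x.sum()
        if tot == 0:
            return np.nan
        return float(x[:, : self.stages].sum() / tot)

    def brdu_fraction(self, lineage: int | None = None) -> float:
        x = self.x if lineage is None else self.x[..., [lineage]]
        tot = x.sum()
        if tot == 0:
            return np.nan
        return float(x[:, :, 1].sum() / tot)


# ---------------------------------------------------------------------------
# system assembly


def _influx_split(structure: ModelStructure, p: KineticParams) -> np.ndarray:
    """Fraction of the influx entering each subpopulation (A, B)."""
    if structure is ModelStructure.branched:
        return np.array([p.psi, 1.0 - p.psi])
    if structure is ModelStructure.linear:
        return np.array([1.0, 0.0])
    if structure is ModelStructure.burst:
        return np.array([0.0, 1.0])
    return np.array([1.0, 0.0])  # temporal: single pool stored in A


def _loss_rate(structure: ModelStructure, p: KineticParams,
               subpop: int, k: int, stages: int) -> float:
    if structure is ModelStructure.temporal:
        return p.delta_hi if k < stages else p.delta_lo
    return p.delta_A if subpop == SUBPOP_A else p.delta_B


def _idx(subpop: int, k: int, b: int, stages: int) -> int:
    return (subpop * (stages + 1) + k) * 2 + b


def _build_matrix(structure: ModelStructure, p: KineticParams,
                  eps: float) -> np.ndarray:
    """Rate matrix of the per-lineage labelled system, dim 4*(stages+1)."""
    m = p.ki67_stages
    n = 4 * (m + 1)
    A = np.zeros((n, n))
    alphas = (p.alpha_A, p.alpha_B)
    beta_stage = m * p.beta
    for i in (SUBPOP_A, SUBPOP_B):
        for k in range(m + 1):
            for b in (0, 1):
                x = _idx(i, k, b, m)
                A[x, x] -= _loss_rate(structure, p, i, k, m)
                if k < m:  # Ki67 stage progression, hi -> ... -> lo
                    A[x, x] -= beta_stage
                    A[_idx(i, k + 1, b, m), x] += beta_stage
                # division: parent removed, 2 daughters Ki67-high stage 0
                a = alphas[i] if structure is not ModelStructure.temporal \
                    else p.alpha_A
                if i == SUBPOP_B and structure is ModelStructure.temporal:
                    a = 0.0
                A[x, x] -= a
                if b == 0:
                    A[_idx(i, 0, 0, m), x] += 2.0 * (1.0 - eps) * a
                    A[_idx(i, 0, 1, m), x] += 2.0 * eps * a
                else:
                    A[_idx(i, 0, 1, m), x] += 2.0 * a
                # structure-specific transitions preserve (Ki67, BrdU) status
                if structure is ModelStructure.linear and i == SUBPOP_A:
                    A[x, x] -= p.gamma
                    A[_idx(SUBPOP_B, k, b, m), x] += p.gamma
                elif structure is ModelStructure.burst:
                    rate = p.omega if i == SUBPOP_A else p.rho
                    A[x, x] -= rate
                    A[_idx(1 - i, k, b, m), x] += rate
    return A


def _influx_vectors(structure: ModelStructure, p: KineticParams,
                    phi: float) -> tuple[np.ndarray, np.ndarray]:
    """(unlabelled, labelled) influx vectors for lineage influx ``phi``."""
    m = p.ki67_stages
    n = 4 * (m + 1)
    c = _influx_split(structure, p)
    b_unl = np.zeros(n)
    b_lab = np.zeros(n)
    for i in (SUBPOP_A, SUBPOP_B):
        b_unl[_idx(i, 0, 0, m)] = phi * c[i]
        b_lab[_idx(i, 0, 1, m)] = phi * c[i]
    return b_unl, b_lab


def _unlabelled_indices(stages: int) -> np.ndarray:
    return np.array([_idx(i, k, 0, stages)
                     for i in (0, 1) for k in range(stages + 1)])


# ---------------------------------------------------------------------------
# steady state


def _active_subpops(structure: ModelStructure, p: KineticParams) -> list[int]:
    """Subpopulations that receive cells (influx or transition inflow).

    An unreachable subpopulation is structurally empty at steady state and
    is excluded from the balance equations (its inert block would otherwise
    make them singular)."""
    c = _influx_split(structure, p)
    active = [c[0] > 0, c[1] > 0]
    if structure is ModelStructure.linear and p.gamma > 0:
        active[SUBPOP_B] = True
    if structure is ModelStructure.burst:
        active[SUBPOP_B] = True
        if p.rho > 0:
            active[SUBPOP_A] = True
    return [i for i in (SUBPOP_A, SUBPOP_B) if active[i]]


def _unlabelled_steady(structure: ModelStructure,
                       p: KineticParams) -> np.ndarray:
    """Lineage-summed pre-pulse steady state of the unlabelled system.

    Returns a vector over (subpop, Ki67 stage) of length 2*(stages+1).
    """
    m = p.ki67_stages
    full = _build_matrix(structure, p, eps=0.0)
    uidx = _unlabelled_indices(m)
    A = full[np.ix_(uidx, uidx)]
    b_unl, _ = _influx_vectors(structure, p, phi=1.0)
    b = b_unl[uidx]

    # restrict to reachable subpopulations; uidx is ordered (subpop, stage)
    subs = _active_subpops(structure, p)
    keep = np.array([j for j in range(2 * (m + 1)) if j // (m + 1) in subs])
    full_x = np.zeros(2 * (m + 1))
    A = A[np.ix_(keep, keep)]
    b = b[keep]

    if p.Phi > 0:
        try:
            x = np.linalg.solve(A, -p.Phi * b)
        except np.linalg.LinAlgError as exc:
            raise NoEquilibriumError(f"singular balance equations: {exc}")
        scale = max(abs(x).max(), 1.0)
        if np.any(x < -1e-9 * scale):
            raise NoEquilibriumError(
                "influx-fed balance equations have no non-negative solution "
                "(e.g. a subpopulation with delta < alpha grows unboundedly)")
        full_x[keep] = np.clip(x, 0.0, None)
        return full_x

    # Phi = 0: a non-trivial equilibrium requires a non-negative null vector
    # (balanced birth-death, delta_i = alpha_i).
    ns = null_space(A, rcond=1e-10)
    for j in range(ns.shape[1]):
        v = ns[:, j]
        if abs(v).max() == 0:
            continue
        v = v * np.sign(v[np.argmax(abs(v))])
        if np.all(v >= -1e-10):
            v = np.clip(v, 0.0, None)
            if p.N0 is None:
                raise NoEquilibriumError(
                    "Phi = 0 equilibrium is scale-free; N0 must be given")
            full_x[keep] = v * (p.N0 / v.sum())
            return full_x
    raise NoEquilibriumError(
        "no equilibrium with Phi = 0: the zero-influx system only admits "
        "the empty population (loss and self-renewal are not balanced)")


def steady_state(structure: ModelStructure | str,
                 params: KineticParams,
                 rtol_n0: float = 1e-6) -> LabelState:
    """Pre-pulse steady state: all cells unlabelled, lineages split by chi0.

    Subpopulation sizes and Ki67-high fractions solve the zero-derivative
    equations of the unlabelled system.  The host/donor split of every
    compartment is set to the standing donor fraction ``chi0``; this is the
    quasi-equilibrium of the busulfan-chimera setting (the lineage split
    itself drifts on much longer timescales than the labelling assay).

    Raises
    ------
    NoEquilibriumError
        If no non-negative steady state exists.
    ValueError
        If ``params.N0`` is set and disagrees with the total implied by
        ``Phi`` and the rates beyond ``rtol_n0`` (use
        :func:`with_equilibrium_influx` to make them consistent).
    """
    structure = ModelStructure(structure)
    x_u = _unlabelled_steady(structure, params)
    total = x_u.sum()
    if params.N0 is not None and params.Phi > 0:
        if not np.isclose(total, params.N0, rtol=rtol_n0, atol=0.0):
            raise ValueError(
                f"steady-state total {total:.6g} disagrees with N0="
                f"{params.N0:.6g}; set Phi with with_equilibrium_influx()")
    m = params.ki67_stages
    x = np.zeros((2, m + 1, 2, 2))
    grid = x_u.reshape(2, m + 1)
    x[:, :, 0, HOST] = grid * (1.0 - params.chi0)
    x[:, :, 0, DONOR] = grid * params.chi0
    return LabelState(x, t=0.0)


def equilibrium_influx(structure: ModelStructure | str,
                       params: KineticParams) -> float:
    """Influx ``Phi`` for which the steady-state total equals ``params.N0``.

    Steady-state sizes scale linearly with ``Phi``, so this is a single
    linear solve at ``Phi = 1``.
    """
    structure = ModelStructure(structure)
    if params.N0 is None:
        raise ValueError("params.N0 must be set")
    probe = replace(params, Phi=1.0, N0=None)
    total_unit = _unlabelled_steady(structure, probe).sum()
    if total_unit <= 0:
        raise NoEquilibriumError("unit influx yields a non-positive total")
    return params.N0 / total_unit


def with_equilibrium_influx(structure: ModelStructure | str,
                            params: KineticParams) -> KineticParams:
    """Copy of ``params`` with ``Phi`` set so the equilibrium total is N0."""
    return replace(params, Phi=equilibrium_influx(structure, params))


def ki67_steady_fraction(params: KineticParams,
                         subpop: int | None = None,
                         structure: ModelStructure | str = ModelStructure.branched,
                         ) -> float:
    """Analytic Ki67-high fraction at demographic steady state.

    ``subpop`` 0 (A) / 1 (B) selects a subpopulation; ``None`` gives the
    population-wide fraction.  Agrees with :func:`steady_state` by
    construction (both solve the same balance equations) and with long-time
    ODE integration, which the tests verify.
    """
    structure = ModelStructure(structure)
    x_u = _unlabelled_steady(structure, params).reshape(2, params.ki67_stages + 1)
    if subpop is not None:
        x_u = x_u[[subpop]]
    tot = x_u.sum()
    if tot == 0:
        return 0.0
    return float(x_u[:, : params.ki67_stages].sum() / tot)


# ---------------------------------------------------------------------------
# trajectory integration


def _lineage_influxes(params: KineticParams) -> tuple[float, float]:
    return (params.Phi * (1.0 - params.f_d), params.Phi * params.f_d)


def _rhs_factory(structure, params, eps, phi_lineage, schedule):
    A = _build_matrix(structure, params, eps)
    b_unl, b_lab = _influx_vectors(structure, params, phi_lineage)

    def rhs(t, y):
        s = schedule.source_label_fn(t)
        return A @ y + (1.0 - s) * b_unl + s * b_lab

    return rhs


def _integrate_lineage_ivp(structure, params, schedule, times, y0,
                           phi_lineage, rtol, atol):
    """solve_ivp path, phase-split at the pulse -> chase switch."""
    times = np.asarray(times, float)
    out = np.empty((len(times), y0.size))
    t_pe = schedule.t_pulse_end
    segments = []  # (t0, t1, eps)
    if t_pe > 0:
        segments.append((0.0, t_pe, params.epsilon))
    if schedule.t_chase_end > t_pe:
        segments.append((t_pe, schedule.t_chase_end, 0.0))
    y = y0.copy()
    filled = np.zeros(len(times), bool)
    if np.any(times == 0.0):
        out[times == 0.0] = y0
        filled[times == 0.0] = True
    for (t0, t1, eps) in segments:
        sel = (times > t0) & (times <= t1) & ~filled
        t_eval = np.unique(times[sel])
        rhs = _rhs_factory(structure, params, eps, phi_lineage, schedule)
        sol = solve_ivp(rhs, (t0, t1), y, method="LSODA",
                        t_eval=np.concatenate([t_eval, [t1]])
                        if len(t_eval) == 0 or t_eval[-1] < t1 else t_eval,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(
                f"ODE integration failed on [{t0}, {t1}]: {sol.message}")
        for tv in np.flatnonzero(sel):
            j = int(np.searchsorted(sol.t, times[tv]))
            j = min(j, len(sol.t) - 1)
            out[tv] = sol.y[:, j]
        filled |= sel
        y = sol.y[:, -1]
    if not filled.all():
        raise ValueError("requested times outside [0, t_chase_end]")
    return out


def _expm_phase(A, b_const, b_exp, mu, y0, taus):
    """y' = A y + b_const + b_exp * exp(-mu * tau), evaluated at taus.

    Solved exactly via the augmented autonomous system; eigendecomposition
    when well conditioned, dense ``expm`` otherwise.
    """
    n = y0.size
    M = np.zeros((n + 2, n + 2))
    M[:n, :n] = A
    M[:n, n] = b_exp
    M[:n, n + 1] = b_const
    M[n, n] = -mu
    z0 = np.concatenate([y0, [1.0, 1.0]])
    taus = np.asarray(taus, float)
    try:
        lam, V = np.linalg.eig(M)
        c = np.linalg.solve(V, z0)
        # cheap defectiveness guard: the eigenbasis must reproduce z0
        if np.max(np.abs(V @ c - z0)) > 1e-8 * max(np.max(np.abs(z0)), 1.0):
            raise np.linalg.LinAlgError("ill-conditioned eigenbasis")
        Z = (V[None, :, :] * np.exp(np.outer(taus, lam))[:, None, :]) @ c
        out = Z.real[:, :n]
    except np.linalg.LinAlgError:
        out = np.stack([(expm(M * t) @ z0)[:n] for t in taus])
    return out


def _integrate_lineage_expm(structure, params, schedule, times, y0,
                            phi_lineage):
    """Semi-analytic path; requires the parametric labelling schedule."""
    if not schedule.is_parametric:
        raise ValueError("fast path needs a parametric schedule")
    times = np.asarray(times, float)
    t_pe = schedule.t_pulse_end
    out = np.empty((len(times), y0.size))
    b_unl, b_lab = _influx_vectors(structure, params, phi_lineage)
    s_max, r_s, r_d = schedule.s_max, schedule.r_s, schedule.r_decay

    pulse_sel = times <= t_pe
    A_pulse = _build_matrix(structure, params, params.epsilon)
    # s(t) = s_max (1 - e^{-r_s t}):  b(t) = const + exp-part
    b_const = (1.0 - s_max) * b_unl + s_max * b_lab
    b_exp = s_max * (b_unl - b_lab)
    pulse_eval = np.concatenate([times[pulse_sel], [t_pe]])
    pulse_out = _expm_phase(A_pulse, b_const, b_exp, r_s, y0, pulse_eval)
    out[pulse_sel] = pulse_out[:-1]
    y_pe = pulse_out[-1]
    chase_sel = ~pulse_sel
    if chase_sel.any():
        s_pe = s_max * (1.0 - np.exp(-r_s * t_pe))
        A_chase = _build_matrix(structure, params, 0.0)
        out[chase_sel] = _expm_phase(
            A_chase, b_unl, s_pe * (b_lab - b_unl), r_d, y_pe,
            times[chase_sel] - t_pe)
    return out


def integrate_labelling(structure: ModelStructure | str,
                        params: KineticParams,
                        schedule: LabellingSchedule,
                        times: Sequence[float],
                        initial: LabelState | None = None,
                        method: str = "ivp",
                        rtol: float = 1e-8,
                        atol_scale: float = 1e-10,
                        ) -> list[LabelState]:
    """Integrate the labelled system from the pre-pulse steady state.

    Host and donor lineages evolve independently (there are no host<->donor
    flows), each receiving its share of the influx (``(1-f_d) Phi`` and
    ``f_d Phi``).  The chase is the same system with labelling efficiency
    zero and the source labelling on its decay branch.

    Parameters
    ----------
    method
        ``"ivp"`` (stiff-capable LSODA, the reference path) or ``"expm"``
        (exact semi-analytic solution of the piecewise-linear system; needs
        the parametric labelling schedule).
    """
    structure = ModelStructure(structure)
    times = np.asarray(times, float)
    if np.any(times < 0) or np.any(times > schedule.t_chase_end + 1e-9):
        raise ValueError("times must lie within [0, t_chase_end]")
    if initial is None:
        initial = steady_state(structure, params)
    n0 = max(initial.total, 1.0)
    atol = atol_scale * n0
    phis = _lineage_influxes(params)

    traj = np.zeros((len(times),) + initial.x.shape)
    for lineage in (HOST, DONOR):
        y0 = initial.x[..., lineage].ravel()
        if y0.sum() == 0 and phis[lineage] == 0:
            continue
        if method == "expm":
            sol = _integrate_lineage_expm(structure, params, schedule,
                                          times, y0, phis[lineage])
        else:
            sol = _integrate_lineage_ivp(structure, params, schedule, times,
                                         y0, phis[lineage], rtol, atol)
        traj[..., lineage] = sol.reshape((len(times),) + initial.x.shape[:3])

    states = []
    neg_tol = 1e-6 * n0
    for k, t in enumerate(times):
        xk = traj[k]
        if xk.min() < -neg_tol:
            raise IntegrationError(
                f"negative compartment ({xk.min():.3g}) at t={t}")
        states.append(LabelState(np.clip(xk, 0.0, None), t=float(t)))
    return states


# ---------------------------------------------------------------------------
# observables


def observables(trajectory: Sequence[LabelState],
                per_lineage: bool = True) -> pd.DataFrame:
    """Summarise a trajectory as the measured flow-cytometry quantities.

    Returns a tidy frame with one row per (time, lineage): total count,
    Ki67-high fraction, BrdU-positive fraction overall and within
    Ki67-high / Ki67-low cells.  Fractions with an empty denominator are
    returned as NaN (the undefined marker) with a logged warning, so they
    can be distinguished and excluded downstream rather than silently
    propagated.
    """
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    rows = []
    lineages = [("host", HOST), ("donor", DONOR)] if per_lineage else []
    lineages.append(("total", None))
    n_undefined = 0
    for state in trajectory:
        xc = state.ki67_collapsed()  # (subpop, hi/lo, brdu, lineage)
        for name, lin in lineages:
            x = xc.sum(axis=3) if lin is None else xc[..., lin]
            n = x.sum()
            hi = x[:, 0].sum()
            lo = x[:, 1].sum()
            lab = x[:, :, 1].sum()
            lab_hi = x[:, 0, 1].sum()
            lab_lo = x[:, 1, 1].sum()

            def frac(num, den):
                nonlocal n_undefined
                if den <= 0:
                    n_undefined += 1
                    return np.nan
                return num / den

            rows.append({
                "t": state.t,
                "lineage": name,
                "n_cells": n,
                "f_ki67hi": frac(hi, n),
                "f_brdu": frac(lab, n),
                "f_brdu_in_ki67hi": frac(lab_hi, hi),
                "f_brdu_in_ki67lo": frac(lab_lo, lo),
            })
    if n_undefined:
        warnings.warn(
            f"{n_undefined} fraction(s) had an empty denominator and were "
            "returned as NaN (undefined)", RuntimeWarning, stacklevel=2)
    return pd.DataFrame(rows)
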