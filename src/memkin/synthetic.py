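"""Study-shaped synthetic data with known ground truth.

Emulates the design of a BrdU/Ki67 labelling assay in busulfan chimeric
mice: a 21-day pulse and 14-day chase, 2 mice per timepoint per lineage,
two age cohorts labelled at different times after bone-marrow transplant,
quasi-equilibrium population sizes, and proportion-valued observables with
logit-normal noise (log-normal for counts), which keeps generated fractions
strictly inside (0, 1).

The default ground-truth parameters are fixed once to mirror the biology of
the system under study: fast cells dividing and dying over a few days with
a small net loss rate, slow cells with interdivision times of 100-200 days
and lifespans of 60-100 days, a Ki67-high lifetime of 3.1 days, donor cells
enriched for fast cells relative to host in the young cohort, and Ki67-high
fractions near 0.44/0.2 for central/effector memory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .chimerism import ReplacementCurve
from .datasets import FRACTION_COLUMNS, LabellingDataset
from .model_core import (KineticParams, LabellingSchedule, ModelStructure,
                         integrate_labelling, observables,
                         with_equilibrium_influx)

__all__ = ["StudyDesign", "generate_labelling_dataset",
           "generate_chimerism_dataset", "default_truth", "default_design"]


@dataclass
class StudyDesign:
    """Observation schedule and noise scales of the labelling assay."""

    observation_days: tuple = (1.0, 2.0, 4.0, 7.0, 10.0, 14.0, 17.0, 21.0,
                               24.0, 28.0, 31.0, 35.0)
    mice_per_timepoint: int = 2
    t_pulse_end: float = 21.0
    t_chase_end: float = 35.0
    logit_sd: float = 0.25      #: logit-normal SD for fraction observables
    log_sd: float = 0.2         #: log-normal SD for counts
    bmt_offset_days: float = 70.0  #: labelling start relative to transplant
    source_s_max: float = 0.3
    source_r_s: float = 0.1
    source_r_decay: float = 0.05

    def __post_init__(self) -> None:
        days = np.asarray(self.observation_days, float)
        if np.any(days < 0) or np.any(days > self.t_chase_end):
            raise ValueError("observation days must lie in [0, t_chase_end]")
        if self.mice_per_timepoint < 1:
            raise ValueError("need at least one mouse per timepoint")

    def schedule(self) -> LabellingSchedule:
        return LabellingSchedule(
            t_pulse_end=self.t_pulse_end, t_chase_end=self.t_chase_end,
            s_max=self.source_s_max, r_s=self.source_r_s,
            r_decay=self.source_r_decay)


def default_design(cohort: str = "young") -> StudyDesign:
    offset = 70.0 if cohort == "young" else 250.0
    return StudyDesign(bmt_offset_days=offset)


# Ground truth for the branched structure, one parameter set per
# (subset, lineage).  Shared fast/slow rates; host and donor differ in the
# influx split psi (donor influx is more fast-weighted) — the mechanism the
# fits are expected to recover.  Sizes give an EM:CM abundance ratio ~7.5.
_RATES = dict(alpha_A=0.007, delta_A=0.013, alpha_B=0.25, delta_B=0.265,
              beta=1.0 / 3.1, epsilon=0.5)

_TRUTH_TABLE = {
    # (cohort, subset, lineage): (psi, N0)
    ("young", "TCM", "host"): (0.27, 1.5e5),
    ("young", "TCM", "donor"): (0.05, 0.5e5),
    ("young", "TEM", "host"): (0.69, 1.2e6),
    ("young", "TEM", "donor"): (0.43, 0.3e6),
    ("old", "TCM", "host"): (0.32, 0.9e5),
    ("old", "TCM", "donor"): (0.20, 1.1e5),
    ("old", "TEM", "host"): (0.72, 0.83e6),
    ("old", "TEM", "donor"): (0.55, 0.67e6),
}


def default_truth(cohort: str = "young",
                  structure: ModelStructure = ModelStructure.branched,
                  ) -> dict[str, dict[str, KineticParams]]:
    """Ground-truth parameters per subset and lineage for one cohort."""
    if structure is not ModelStructure.branched:
        raise NotImplementedError("defaults are stated for the branched model")
    out: dict[str, dict[str, KineticParams]] = {}
    for (coh, subset, lineage), (psi, n0) in _TRUTH_TABLE.items():
        if coh != cohort:
            continue
        p = KineticParams(psi=psi, N0=n0, **_RATES)
        out.setdefault(subset, {})[lineage] = with_equilibrium_influx(
            structure, p)
    if not out:
        raise ValueError(f"unknown cohort {cohort!r}")
    return out


def _noisy_fractions(values: np.ndarray, sd: float,
                     rng: np.random.Generator) -> np.ndarray:
    out = np.full_like(values, np.nan, dtype=float)
    ok = ~np.isnan(values)
    v = np.clip(values[ok], 1e-6, 1.0 - 1e-6)
    out[ok] = expit(logit(v) + sd * rng.standard_normal(v.shape))
    return out


def generate_labelling_dataset(structure: ModelStructure | str,
                               truth: dict,
                               design: StudyDesign | None = None,
                               cohort: str = "young",
                               seed: int = 0) -> LabellingDataset:
    """Simulate a tidy labelling dataset from known parameters.

    ``truth`` maps subset name to either a single :class:`KineticParams`
    (host/donor handled through ``chi0``/``f_d``) or a
    ``{"host": ..., "donor": ...}`` dict of lineage-specific parameters.
    With zero noise scales the rows equal the model observables exactly;
    the ground truth is stored on the returned dataset for recovery tests.
    """
    structure = ModelStructure(structure)
    design = design or StudyDesign()
    rng = np.random.default_rng(seed)
    schedule = design.schedule()
    days = np.asarray(design.observation_days, float)
    rows = []
    mouse_no = 0
    for subset, entry in truth.items():
        per_lineage = isinstance(entry, dict)
        lineage_params = entry if per_lineage else {"both": entry}
        for lin_name, params in lineage_params.items():
            traj = integrate_labelling(structure, params, schedule, days)
            if per_lineage:
                lineages = [lin_name]
            else:
                # skip a lineage with no standing cells and no influx share
                lineages = [l for l, frac in
                            (("host", (1 - params.chi0) + (1 - params.f_d)),
                             ("donor", params.chi0 + params.f_d))
                            if frac > 0]
            obs = observables(traj, per_lineage=not per_lineage)
            for lineage in lineages:
                sel = obs[obs["lineage"] == ("total" if per_lineage
                                             else lineage)]
                sel = sel.set_index("t")
                for day in days:
                    for m in range(design.mice_per_timepoint):
                        mouse_no += 1
                        true_row = sel.loc[day]
                        fr = np.array([true_row[c] for c in FRACTION_COLUMNS])
                        noisy = _noisy_fractions(fr, design.logit_sd, rng)
                        n_true = float(true_row["n_cells"])
                        n_obs = n_true * np.exp(
                            design.log_sd * rng.standard_normal())
                        row = {"mouse_id": f"m{mouse_no:04d}",
                               "cohort": cohort, "subset": subset,
                               "lineage": lineage, "day": day,
                               "n_cells": n_obs}
                        row.update(dict(zip(FRACTION_COLUMNS, noisy)))
                        rows.append(row)
    df = pd.DataFrame(rows)
    return LabellingDataset(df, max_day=design.t_chase_end,
                            truth={"structure": structure.value,
                                   "params": truth, "design": design,
                                   "seed": seed})


def generate_chimerism_dataset(phi: float,
                               asymptote: float = 1.0,
                               chi_source: float = 0.8,
                               days: tuple = tuple(np.linspace(40, 400, 12)),
                               mice_per_timepoint: int = 2,
                               logit_sd: float = 0.2,
                               population: str = "TCM",
                               n_total: float = 2e5,
                               log_sd: float = 0.2,
                               seed: int = 0) -> ReplacementCurve:
    """Donor-replacement observations from the closed-form curve.

    ``F(t) = asymptote * chi_source * (1 - exp(-phi t))`` with logit-normal
    noise on the donor fraction and log-normal noise on the total count;
    ``days=()`` gives an empty but valid curve.  The ground truth is stored
    on the returned object.
    """
    rng = np.random.default_rng(seed)
    rows = []
    mouse = 0
    for day in days:
        f_true = asymptote * chi_source * (1.0 - np.exp(-phi * day))
        for _ in range(mice_per_timepoint):
            mouse += 1
            f_obs = float(expit(logit(np.clip(f_true, 1e-6, 1 - 1e-6))
                                + logit_sd * rng.standard_normal()))
            n = n_total * np.exp(log_sd * rng.standard_normal())
            rows.append({"mouse_id": f"c{mouse:04d}",
                         "days_post_bmt": float(day),
                         "donor_count": f_obs * n,
                         "host_count": (1 - f_obs) * n})
    df = pd.DataFrame(rows, columns=["mouse_id", "days_post_bmt",
                                     "donor_count", "host_count"])
    return ReplacementCurve(population=population, data=df,
                            truth={"phi": phi, "asymptote": asymptote,
                                   "chi_source": chi_source, "seed": seed})
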