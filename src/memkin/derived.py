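"""Derived turnover quantities: clonal half-lives and mean lifespans.

A population in bulk declines at the net loss rate ``lambda = delta -
alpha`` (loss minus self-renewal); the time for a cohort of cells entering
a population — equivalently a TCR clone — to halve is ``ln(2)/lambda``.
The mean cell lifespan, in contrast, is the inverse of the average loss
rate ``delta`` weighted over subpopulations by their sizes.

Two quick estimators of the mean lifespan that need no model fit:

* from the early upslope ``p`` of the BrdU-positive fraction and the
  labelling efficiency ``epsilon``: lifespan ~ ``2 epsilon / p``;
* from the Ki67-high fraction ``k`` and the Ki67-high lifetime ``T``:
  lifespan ~ ``-T / ln(1 - k/2)``.

All posterior-based quantities are computed per draw and summarised
afterwards, never on posterior means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import LabellingDataset

__all__ = ["clonal_half_life", "LifespanSummary", "weighted_mean_lifespan",
           "subset_mean_loss_rate", "aggregate_lifespan",
           "lifespan_from_upslope", "lifespan_from_ki67"]


def clonal_half_life(delta, alpha):
    """``ln(2) / (delta - alpha)`` in days; ``inf`` when loss does not
    exceed self-renewal (the population is sustained indefinitely)."""
    delta = np.asarray(delta, float)
    alpha = np.asarray(alpha, float)
    lam = delta - alpha
    with np.errstate(divide="ignore"):
        out = np.where(lam > 0, np.log(2.0) / np.where(lam > 0, lam, 1.0),
                       np.inf)
    return out if out.ndim else float(out)


@dataclass
class LifespanSummary:
    """Posterior lifespans per subset plus the abundance-weighted aggregate."""

    per_subset: dict[str, np.ndarray]       #: lifespan draws, days
    aggregate: np.ndarray                   #: rate-weighted aggregate draws
    aggregate_lifespan_weighted: np.ndarray #: alternative aggregation
    weights: dict[str, float]               #: normalised subset abundances

    def summary(self) -> pd.DataFrame:
        rows = {}
        for name, v in {**self.per_subset, "aggregate": self.aggregate}.items():
            rows[name] = {"median": float(np.median(v)),
                          "lo95": float(np.quantile(v, 0.025)),
                          "hi95": float(np.quantile(v, 0.975))}
        return pd.DataFrame(rows).T


def subset_mean_loss_rate(fits: dict[str, "PosteriorDraws"]) -> np.ndarray:
    """Per-draw mean loss rate of one memory subset.

    ``fits`` maps lineage name (host/donor) to a fitted posterior; per draw
    the loss rates delta of the fast and slow subpopulations of every
    lineage are weighted by the subpopulation sizes.  Draws are paired by
    index across lineages (independent fits).  Lineages with zero total
    size in a draw are excluded with a warning.
    """
    n_draws = min(len(f.draws) for f in fits.values())
    num = np.zeros(n_draws)
    den = np.zeros(n_draws)
    for lineage, fit in fits.items():
        d = fit.draws.iloc[:n_draws]
        na = d["N_A"].to_numpy(float)
        nb = d["N_B"].to_numpy(float)
        if fit.structure == "temporal":
            raise NotImplementedError(
                "temporal-structure lifespans need Ki67-resolved sizes")
        num += na * d["delta_A"].to_numpy(float) \
            + nb * d["delta_B"].to_numpy(float)
        den += na + nb
    if np.any(den <= 0):
        warnings.warn("draws with empty populations excluded",
                      RuntimeWarning, stacklevel=2)
    ok = den > 0
    out = np.full(n_draws, np.nan)
    out[ok] = num[ok] / den[ok]
    return out[ok]


def aggregate_lifespan(loss_rates: dict[str, np.ndarray],
                       em_cm_ratio: float) -> tuple[np.ndarray, np.ndarray, dict]:
    """Combine per-subset loss-rate draws into a population average.

    The canonical aggregation weights the *loss rates* by subset abundance
    (1 : em_cm_ratio for TCM : TEM) and inverts the mean rate; the
    lifespan-weighted alternative is returned alongside.
    """
    if em_cm_ratio < 0:
        raise ValueError("abundance ratio must be non-negative")
    w = {"TCM": 1.0 / (1.0 + em_cm_ratio),
         "TEM": em_cm_ratio / (1.0 + em_cm_ratio)}
    n = min(len(v) for v in loss_rates.values())
    mean_rate = sum(w[s] * np.asarray(loss_rates[s][:n], float)
                    for s in loss_rates)
    rate_weighted = 1.0 / mean_rate
    mean_lifespan = sum(w[s] / np.asarray(loss_rates[s][:n], float)
                        for s in loss_rates)
    return rate_weighted, mean_lifespan, w


def weighted_mean_lifespan(fits_by_subset: dict[str, dict[str, "PosteriorDraws"]],
                           em_cm_ratio: float = 7.5) -> LifespanSummary:
    """Population-size-weighted mean lifespan from fitted posteriors.

    ``fits_by_subset`` maps subset (``TCM``/``TEM``) to per-lineage fits.
    Per draw: mean loss rate over {fast, slow} x {host, donor} weighted by
    subpopulation sizes, inverted to a lifespan per subset; the aggregate
    weights the subset loss rates by relative abundance (EM:CM ratio) and
    inverts.
    """
    rates = {s: subset_mean_loss_rate(f) for s, f in fits_by_subset.items()}
    agg_rate, agg_life, w = aggregate_lifespan(rates, em_cm_ratio)
    return LifespanSummary(
        per_subset={s: 1.0 / r for s, r in rates.items()},
        aggregate=agg_rate,
        aggregate_lifespan_weighted=agg_life,
        weights=w)


def lifespan_from_upslope(timecourse: LabellingDataset | pd.DataFrame,
                          epsilon: float,
                          window: tuple[float, float] = (0.0, 4.0),
                          ) -> float:
    """Lifespan ``2 epsilon / p`` from the early BrdU uptake rate ``p``.

    ``p`` is the slope of a least-squares line through the origin fitted to
    the BrdU-positive fraction over the early ``window`` (days).  Returns
    NaN when the slope is not positive.
    """
    df = timecourse.data if isinstance(timecourse, LabellingDataset) \
        else timecourse
    sel = df[(df["day"] >= window[0]) & (df["day"] <= window[1])]
    sel = sel.dropna(subset=["f_brdu"])
    if len(sel) < 3:
        raise ValueError("need at least 3 points in the early window")
    t = sel["day"].to_numpy(float)
    y = sel["f_brdu"].to_numpy(float)
    denom = float(np.sum(t * t))
    if denom == 0:
        return np.nan
    p = float(np.sum(t * y)) / denom
    if p <= 0:
        warnings.warn("non-positive early slope: lifespan undefined",
                      RuntimeWarning, stacklevel=2)
        return np.nan
    return 2.0 * epsilon / p


def lifespan_from_ki67(k_tcm: float, k_tem: float, T: float = 3.1,
                       em_cm_ratio: float = 7.5,
                       cap: float = 1e6) -> dict:
    """Lifespans from Ki67-high fractions: ``-T / ln(1 - k/2)`` per subset.

    Per-subset loss rates ``-ln(1 - k/2) / T`` are abundance-weighted
    (1 : em_cm_ratio, TCM : TEM) and the mean rate inverted — the canonical
    aggregate; the lifespan-weighted variant is also returned.  Lifespans
    above ``cap`` (the ``k -> 0`` divergence) are reported as ``inf``.
    """
    for name, k in (("k_tcm", k_tcm), ("k_tem", k_tem)):
        if not 0.0 <= k < 1.0:
            raise ValueError(f"{name} must lie in [0, 1)")
    if T <= 0 or em_cm_ratio < 0:
        raise ValueError("T must be positive and the ratio non-negative")

    def rate(k):
        return -np.log1p(-k / 2.0) / T

    def life(r):
        if r <= 0:
            return np.inf
        ls = 1.0 / r
        return np.inf if ls > cap else ls

    r_cm, r_em = rate(k_tcm), rate(k_tem)
    w_cm = 1.0 / (1.0 + em_cm_ratio)
    w_em = em_cm_ratio / (1.0 + em_cm_ratio)
    mean_rate = w_cm * r_cm + w_em * r_em
    per = {"TCM": life(r_cm), "TEM": life(r_em)}
    return {
        "per_subset": per,
        "aggregate": life(mean_rate),
        "aggregate_lifespan_weighted":
            w_cm * per["TCM"] + w_em * per["TEM"],
        "loss_rates": {"TCM": r_cm, "TEM": r_em},
        "weights": {"TCM": w_cm, "TEM": w_em},
    }
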