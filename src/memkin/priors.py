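"""Prior distributions and the transforms used by the sampler.

Priors are specified on the natural parameter scale; the sampler explores an
unconstrained space (log for positive parameters, logit for fractions), and
the change-of-variables Jacobian is added automatically.  Every prior can be
serialised to a plain dict/YAML entry so fits are fully reproducible from
config.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, expit, logit

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)

__all__ = ["LogNormal", "Beta", "HalfNormal", "Normal", "Uniform",
           "prior_from_dict", "transform_forward", "transform_backward",
           "log_jacobian"]


class Prior:
    support: str = "real"  # "positive" | "unit" | "real"

    def logpdf(self, x: float) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def sample(self, rng: np.random.Generator, size=None):
        raise NotImplementedError

    def to_dict(self) -> dict:
        d = {"dist": type(self).__name__.lower()}
        d.update(self.__dict__)
        return d


@dataclass(init=False)
class LogNormal(Prior):
    """Log-normal prior given by its median and the SD on the log scale."""

    median: float
    sdlog: float
    support = "positive"

    def __init__(self, median: float, sdlog: float):
        if median <= 0 or sdlog <= 0:
            raise ValueError("median and sdlog must be positive")
        self.median = median
        self.sdlog = sdlog

    def logpdf(self, x):
        if x <= 0:
            return -np.inf
        z = (np.log(x) - np.log(self.median)) / self.sdlog
        return -np.log(x) - np.log(self.sdlog) - _LOG_SQRT_2PI - 0.5 * z * z

    def sample(self, rng, size=None):
        return self.median * np.exp(self.sdlog * rng.standard_normal(size))


@dataclass(init=False)
class Beta(Prior):
    a: float
    b: float
    support = "unit"

    def __init__(self, a: float, b: float):
        self.a, self.b = a, b

    def logpdf(self, x):
        if not 0.0 < x < 1.0:
            return -np.inf
        return ((self.a - 1) * np.log(x) + (self.b - 1) * np.log1p(-x)
                - betaln(self.a, self.b))

    def sample(self, rng, size=None):
        return rng.beta(self.a, self.b, size)


@dataclass(init=False)
class HalfNormal(Prior):
    scale: float
    support = "positive"

    def __init__(self, scale: float):
        self.scale = scale

    def logpdf(self, x):
        if x < 0:
            return -np.inf
        return (0.5 * np.log(2.0 / np.pi) - np.log(self.scale)
                - 0.5 * (x / self.scale) ** 2)

    def sample(self, rng, size=None):
        return np.abs(self.scale * rng.standard_normal(size))


@dataclass(init=False)
class Normal(Prior):
    loc: float
    scale: float
    support = "real"

    def __init__(self, loc: float, scale: float):
        self.loc, self.scale = loc, scale

    def logpdf(self, x):
        z = (x - self.loc) / self.scale
        return -_LOG_SQRT_2PI - np.log(self.scale) - 0.5 * z * z

    def sample(self, rng, size=None):
        return self.loc + self.scale * rng.standard_normal(size)


@dataclass(init=False)
class Uniform(Prior):
    lo: float
    hi: float

    def __init__(self, lo: float, hi: float):
        if hi <= lo:
            raise ValueError("need hi > lo")
        self.lo, self.hi = lo, hi
        if lo >= 0.0 and hi <= 1.0:
            self.support = "unit"
        elif lo >= 0.0:
            self.support = "positive"
        else:
            self.support = "real"

    def logpdf(self, x):
        if self.lo <= x <= self.hi:
            return -np.log(self.hi - self.lo)
        return -np.inf

    def sample(self, rng, size=None):
        return rng.uniform(self.lo, self.hi, size)


_DISTS = {"lognormal": LogNormal, "beta": Beta, "halfnormal": HalfNormal,
          "normal": Normal, "uniform": Uniform}


def prior_from_dict(d: dict) -> Prior:
    d = dict(d)
    name = d.pop("dist")
    try:
        cls = _DISTS[name]
    except KeyError:
        raise ValueError(f"unknown prior distribution {name!r}")
    return cls(**d)


# -- unconstrained-space transforms -----------------------------------------

def transform_forward(x: float, support: str) -> float:
    """Natural scale -> unconstrained sampler coordinate."""
    if support == "positive":
        return np.log(x)
    if support == "unit":
        return logit(x)
    return x


def transform_backward(z: float, support: str) -> float:
    if support == "positive":
        return np.exp(z)
    if support == "unit":
        return expit(z)
    return z


def log_jacobian(z: float, support: str) -> float:
    """log |dx/dz| for the backward transform."""
    if support == "positive":
        return z
    if support == "unit":
        x = expit(z)
        return np.log(x) + np.log1p(-x)
    return 0.0
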