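"""Affine-invariant ensemble MCMC (Goodman & Weare stretch move).

A small, dependency-free sampler sufficient for the posteriors in this
package (tens of parameters, smooth likelihoods).  The contract is
diagnostics-gated draws rather than a specific algorithm: walkers are split
into pseudo-chains and convergence is assessed with split-R-hat and bulk
effective sample size via arviz.

The stretch move proposes, for walker ``x`` and a randomly chosen walker
``y`` from the complementary half of the ensemble,

    x' = y + z (x - y),   z ~ g(z) proportional to 1/sqrt(z) on [1/a, a],

accepted with probability ``min(1, z^(d-1) exp(logp(x') - logp(x)))``.
Updates alternate between ensemble halves so proposals always condition on
the current state of the other half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EnsembleSampler", "run_ensemble", "SamplerResult"]


@dataclass
class SamplerResult:
    """Raw output of an ensemble run.

    ``chain`` has shape (n_steps_kept, n_walkers, n_dim); ``log_prob``
    matches its first two axes.  ``acceptance`` is the per-walker mean
    acceptance fraction over the whole run (including burn-in).
    """

    chain: np.ndarray
    log_prob: np.ndarray
    acceptance: np.ndarray

    def flat(self, thin: int = 1) -> np.ndarray:
        return self.chain[::thin].reshape(-1, self.chain.shape[-1])


class EnsembleSampler:
    """Ensemble sampler mixing stretch and differential-evolution moves.

    The differential-evolution move proposes ``x' = x + g (a - b)`` with
    ``a, b`` distinct walkers of the complementary half and
    ``g = 2.38 / sqrt(2 d)`` (occasionally 1 to allow mode jumps); being
    symmetric it is accepted on the posterior ratio alone.  It follows the
    ensemble's own correlation structure, which mixes far better than the
    stretch move on the elongated posteriors of ODE fits; a fraction of
    stretch moves is retained for scale adaptation.
    """

    def __init__(self, log_prob_fn, n_walkers: int, n_dim: int,
                 a: float = 2.0, de_fraction: float = 0.8,
                 rng: np.random.Generator | None = None):
        if n_walkers < 2 * n_dim:
            raise ValueError("need at least 2*n_dim walkers")
        if n_walkers % 2:
            raise ValueError("n_walkers must be even")
        self.log_prob_fn = log_prob_fn
        self.n_walkers = n_walkers
        self.n_dim = n_dim
        self.a = a
        self.de_fraction = de_fraction
        self.rng = rng if rng is not None else np.random.default_rng()

    def run(self, x0: np.ndarray, n_steps: int, burn: int = 0,
            progress: bool = False) -> SamplerResult:
        nw, nd = self.n_walkers, self.n_dim
        x = np.array(x0, float)
        if x.shape != (nw, nd):
            raise ValueError(f"x0 must have shape ({nw}, {nd})")
        lp = np.array([self.log_prob_fn(xi) for xi in x])
        if not np.any(np.isfinite(lp)):
            raise ValueError("no walker has finite initial log-probability")
        # replace non-finite starters with the best walker, tiny jitter
        bad = ~np.isfinite(lp)
        if bad.any():
            best = int(np.argmax(lp))
            for i in np.flatnonzero(bad):
                for _ in range(50):
                    cand = x[best] * (1 + 1e-4 * self.rng.standard_normal(nd))
                    cand += 1e-8 * self.rng.standard_normal(nd)
                    lpc = self.log_prob_fn(cand)
                    if np.isfinite(lpc):
                        x[i], lp[i] = cand, lpc
                        break
                else:
                    raise ValueError("could not initialise all walkers")

        halves = (np.arange(nw) < nw // 2)
        accepted = np.zeros(nw)
        kept = n_steps - burn
        chain = np.empty((kept, nw, nd))
        logp = np.empty((kept, nw))
        g0 = 2.38 / np.sqrt(2.0 * nd)
        g_scale = 1.0
        recent_acc = 0.0
        recent_tot = 0
        for step in range(n_steps):
            # adapt the DE step size toward ~25% acceptance during burn-in
            # only (the kernel is fixed for all retained draws)
            if step < burn and recent_tot >= 25 * nw:
                rate = recent_acc / recent_tot
                g_scale = float(np.clip(
                    g_scale * np.exp(rate - 0.25), 0.2, 2.0))
                recent_acc, recent_tot = 0.0, 0
            for first in (True, False):
                move = halves if first else ~halves
                idx_move = np.flatnonzero(move)
                idx_other = np.flatnonzero(~move)
                n_m = len(idx_move)
                use_de = self.rng.random() < self.de_fraction
                if use_de:
                    ia = self.rng.integers(0, len(idx_other), n_m)
                    ib = (ia + 1 + self.rng.integers(
                        0, len(idx_other) - 1, n_m)) % len(idx_other)
                    g = np.where(self.rng.random(n_m) < 0.1, 1.0,
                                 g0 * g_scale)
                    diff = x[idx_other[ia]] - x[idx_other[ib]]
                    jitter = 1e-5 * self.rng.standard_normal((n_m, nd))
                    prop = x[idx_move] + g[:, None] * diff + jitter
                    log_hastings = np.zeros(n_m)
                else:
                    z = ((self.a - 1.0) * self.rng.random(n_m) + 1.0) ** 2 \
                        / self.a
                    partners = self.rng.integers(0, len(idx_other), n_m)
                    y = x[idx_other[partners]]
                    prop = y + z[:, None] * (x[idx_move] - y)
                    log_hastings = (nd - 1) * np.log(z)
                lp_prop = np.array([self.log_prob_fn(p) for p in prop])
                log_accept = log_hastings + lp_prop - lp[idx_move]
                u = np.log(self.rng.random(n_m))
                acc = u < log_accept
                x[idx_move[acc]] = prop[acc]
                lp[idx_move[acc]] = lp_prop[acc]
                accepted[idx_move[acc]] += 1.0
                recent_acc += float(acc.sum())
                recent_tot += n_m
            if step >= burn:
                chain[step - burn] = x
                logp[step - burn] = lp
        return SamplerResult(chain, logp, accepted / n_steps)


def run_ensemble(log_prob_fn, x0: np.ndarray, n_steps: int, burn: int,
                 rng: np.random.Generator, a: float = 2.0) -> SamplerResult:
    """Convenience wrapper: build a sampler sized from ``x0`` and run it."""
    nw, nd = x0.shape
    return EnsembleSampler(log_prob_fn, nw, nd, a=a, rng=rng).run(
        x0, n_steps=n_steps, burn=burn)
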