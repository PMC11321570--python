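"""Shared helper for the example scripts."""

import numpy as np
import pandas as pd

from memkin.inference import PosteriorDraws


def fake_posterior(params, n=100, jitter=0.05, seed=0) -> PosteriorDraws:
    """Posterior-shaped draws scattered around a known parameter point.

    Stands in for a fitted posterior where an example only needs plausible
    uncertainty, sparing the example an MCMC run; see example 02 for a
    real fit.
    """
    rng = np.random.default_rng(seed)

    def col(v):
        return v * np.exp(jitter * rng.standard_normal(n))

    draws = pd.DataFrame({
        "alpha_A": col(params.alpha_A),
        "lambda_A": col(params.delta_A - params.alpha_A),
        "alpha_B": col(params.alpha_B),
        "lambda_B": col(params.delta_B - params.alpha_B),
        "psi": np.clip(col(params.psi), 0.01, 0.99),
        "Phi": col(params.Phi),
        "beta": col(params.beta),
        "epsilon": np.clip(col(params.epsilon), 0.01, 0.99),
    })
    return PosteriorDraws("branched", draws, np.zeros((n, 1)),
                          np.zeros(n), {}, [])
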