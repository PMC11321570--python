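"""Exact stochastic simulation (Gillespie SSA) of the labelling scheme.

Independent oracle for the deterministic model: the same reaction scheme —
division with per-division labelling, Ki67 decay, loss, structural
transitions, Poisson influx with time-varying label composition — simulated
event by event for a single lineage with one Ki67 stage.  Used only in
tests; intentionally simple and separate from the package implementation.
"""

from __future__ import annotations

import numpy as np

from memkin.model_core import ModelStructure

# compartment order: (subpop, ki67 hi/lo, brdu -/+) flattened C-style
N_COMP = 8


def _cidx(sub, k, b):
    return (sub * 2 + k) * 2 + b


def simulate(structure, params, schedule, t_checkpoints, rng):
    """One SSA realisation; returns counts (len(t_checkpoints), 8).

    The initial state is the rounded deterministic steady state.
    """
    from memkin import model_core as mc

    structure = ModelStructure(structure)
    if params.ki67_stages != 1:
        raise ValueError("oracle supports a single Ki67 stage")
    grid = mc._unlabelled_steady(structure, params).reshape(2, 2)
    x = np.zeros(N_COMP, dtype=np.int64)
    for sub in (0, 1):
        for k in (0, 1):
            x[_cidx(sub, k, 0)] = int(round(grid[sub, k]))

    alphas = (params.alpha_A, params.alpha_B)
    if structure is ModelStructure.temporal:
        alphas = (params.alpha_A, 0.0)

    def delta(sub, k):
        if structure is ModelStructure.temporal:
            return params.delta_hi if k == 0 else params.delta_lo
        return params.delta_A if sub == 0 else params.delta_B

    # per-compartment per-capita rates for: division, ki67 decay, death, move
    div = np.zeros(N_COMP)
    ki = np.zeros(N_COMP)
    die = np.zeros(N_COMP)
    move = np.zeros(N_COMP)
    for sub in (0, 1):
        for k in (0, 1):
            for b in (0, 1):
                c = _cidx(sub, k, b)
                div[c] = alphas[sub]
                ki[c] = params.beta if k == 0 else 0.0
                die[c] = delta(sub, k)
                if structure is ModelStructure.linear and sub == 0:
                    move[c] = params.gamma
                elif structure is ModelStructure.burst:
                    move[c] = params.omega if sub == 0 else params.rho
    influx_split = mc._influx_split(structure, params)

    t = 0.0
    out = np.zeros((len(t_checkpoints), N_COMP))
    next_cp = 0
    checkpoints = np.asarray(t_checkpoints, float)
    t_end = checkpoints.max()
    while t <= t_end:
        props = np.concatenate([div * x, ki * x, die * x, move * x,
                                [params.Phi]])
        total = props.sum()
        if total <= 0:
            break
        dt = rng.exponential(1.0 / total)
        while next_cp < len(checkpoints) and t + dt > checkpoints[next_cp]:
            out[next_cp] = x
            next_cp += 1
        t += dt
        if t > t_end:
            break
        r = rng.random() * total
        cum = np.cumsum(props)
        j = int(np.searchsorted(cum, r))
        kind, c = divmod(j, N_COMP) if j < 4 * N_COMP else (4, 0)
        in_pulse = t <= schedule.t_pulse_end
        if kind == 0:  # division -> two Ki67-high daughters
            sub, kk, b = c // 4, (c // 2) % 2, c % 2
            x[c] -= 1
            if b == 1:
                x[_cidx(sub, 0, 1)] += 2
            else:
                eps = params.epsilon if in_pulse else 0.0
                lab = 1 if rng.random() < eps else 0
                x[_cidx(sub, 0, lab)] += 2
        elif kind == 1:  # Ki67 high -> low
            sub, b = c // 4, c % 2
            x[c] -= 1
            x[_cidx(sub, 1, b)] += 1
        elif kind == 2:  # death / onward loss
            x[c] -= 1
        elif kind == 3:  # structural transition, state preserved
            sub, kk, b = c // 4, (c // 2) % 2, c % 2
            x[c] -= 1
            x[_cidx(1 - sub, kk, b)] += 1
        else:  # influx: Ki67-high, labelled per the source composition
            sub = 0 if rng.random() < influx_split[0] else 1
            lab = 1 if rng.random() < schedule.source_label_fn(t) else 0
            x[_cidx(sub, 0, lab)] += 1
    while next_cp < len(checkpoints):
        out[next_cp] = x
        next_cp += 1
    return out


def observable_fractions(counts):
    """(f_ki67hi, f_brdu) per checkpoint from SSA counts."""
    counts = np.asarray(counts, float)
    tot = counts.sum(axis=1)
    hi = counts[:, [0, 1, 4, 5]].sum(axis=1)
    lab = counts[:, 1::2].sum(axis=1)
    return hi / tot, lab / tot
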