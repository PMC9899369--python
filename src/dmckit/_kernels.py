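"""Compiled inner loop for first-passage simulation.

The per-trial Euler-Maruyama walk is the hot path of every stage (cohort
scenarios, objective evaluations); it is JIT-compiled with numba.  The mean
drift depends on time only, so it is precomputed once per condition as a
profile over integration steps and shared by all trials.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _first_passage(profile, boundary, sigma, dt, starts, seed):
    np.random.seed(seed)
    n = starts.shape[0]
    n_steps = profile.shape[0]
    sqrt_dt = np.sqrt(dt)
    steps = np.empty(n, dtype=np.int64)
    correct = np.zeros(n, dtype=np.bool_)
    censored = np.zeros(n, dtype=np.bool_)
    for i in range(n):
        x = starts[i]
        k = 0
        while k < n_steps:
            x += profile[k] * dt + sigma * sqrt_dt * np.random.normal()
            k += 1
            if x >= boundary:
                correct[i] = True
                break
            if x <= -boundary:
                break
        steps[i] = k
        if k == n_steps and -boundary < x < boundary:
            censored[i] = True
    return steps, correct, censored


def simulate_first_passage(profile, boundary, sigma, dt, starts, seed):
    """First-passage steps, accuracy, and censoring for a batch of trials.

    Noise-free trials (sigma == 0) follow the deterministic Euler path; the
    random stream is still seeded for bit-reproducibility of the call.
    """
    return _first_passage(
        np.ascontiguousarray(profile, dtype=np.float64),
        float(boundary),
        float(sigma),
        float(dt),
        np.ascontiguousarray(starts, dtype=np.float64),
        int(seed),
    )
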