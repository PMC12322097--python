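"""Quasi-random draws for simulated maximum likelihood."""

from __future__ import annotations

import numpy as np
from scipy.stats import norm, qmc


def halton_normal(n_resp: int, n_draws: int, n_dims: int, seed: int = 0) -> np.ndarray:
    """Scrambled-Halton standard-normal draws, shape (n_resp, n_draws, n_dims).

    Each respondent receives a contiguous slice of a single scrambled Halton
    sequence, so draws are reproducible given the seed and low-discrepancy
    within respondent.
    """
    if n_draws < 1:
        raise ValueError("need at least one draw")
    if n_dims == 0:
        return np.zeros((n_resp, n_draws, 0))
    eng = qmc.Halton(d=n_dims, scramble=True, seed=seed)
    u = eng.random(n_resp * n_draws)
    # clip away exact 0/1 before the normal inverse CDF
    u = np.clip(u, 1e-12, 1 - 1e-12)
    return norm.ppf(u).reshape(n_resp, n_draws, n_dims)
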