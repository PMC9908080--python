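"""Numba kernels for Ornstein-Uhlenbeck evidence-accumulation simulation.

All kernels integrate the discrete-time OU update

    EA(t+1) = EA(t) + (lambda * EA(t) + kappa * VD) * dt + noise

with noise ~ N(0, sig_step) per unit step and absorbing bounds at +/-alpha
(+ = equal option).  ``stride`` > 1 aggregates that many unit steps into a
single exact AR(1) transition (the aggregated increment is Gaussian with
the matching mean and variance) and checks the bounds only once per block;
this is an efficiency device for simulation-based likelihoods where RTs
are later histogrammed at a much coarser resolution.
"""

import numpy as np
from numba import njit

__all__ = ["sim_choices", "sim_choices_shared_noise", "sim_paths"]


@njit(cache=True)
def _block_constants(lam, kappa_vd, sig_step, dt, stride):
    a = 1.0 + lam * dt
    m = a ** stride
    if abs(a - 1.0) > 1e-14:
        gsum = (m - 1.0) / (a - 1.0)
    else:
        gsum = float(stride)
    if abs(a * a - 1.0) > 1e-14:
        vsum = (m * m - 1.0) / (a * a - 1.0)
    else:
        vsum = float(stride)
    drift = kappa_vd * dt * gsum
    sig = sig_step * np.sqrt(vsum)
    return m, drift, sig


@njit(cache=True)
def sim_choices(vds, n_sim, alpha, beta, kappa, lam, sig_step, dt,
                max_steps, stride, seed):
    """Independent-noise simulation of choices and decision steps.

    Returns (choices, steps): choices is +1 (equal bound), -1 (unequal
    bound) or 0 (no crossing within max_steps); steps is the unit-step
    count at crossing (max_steps for timeouts).
    """
    np.random.seed(seed)
    n_vd = vds.shape[0]
    choices = np.zeros((n_vd, n_sim), np.int8)
    steps = np.full((n_vd, n_sim), max_steps, np.int32)
    n_blocks = max_steps // stride
    for i in range(n_vd):
        m, drift, sig = _block_constants(lam, kappa * vds[i], sig_step, dt, stride)
        for j in range(n_sim):
            ea = beta
            for b in range(n_blocks):
                ea = m * ea + drift + sig * np.random.standard_normal()
                if ea > alpha:
                    choices[i, j] = 1
                    steps[i, j] = (b + 1) * stride
                    break
                elif ea < -alpha:
                    choices[i, j] = -1
                    steps[i, j] = (b + 1) * stride
                    break
    return choices, steps


@njit(cache=True)
def sim_choices_shared_noise(vds, alpha, beta, kappa, lam, sig_step, dt,
                             max_steps, stride, noise):
    """Common-random-number variant: one standard-normal matrix ``noise``
    of shape (n_sim, n_blocks) is reused across all value differences (and,
    by the caller holding it fixed, across optimiser candidates), making
    the simulated likelihood a deterministic function of the parameters.
    """
    n_vd = vds.shape[0]
    n_sim, n_blocks = noise.shape
    if n_blocks < max_steps // stride:
        raise ValueError("noise matrix too short for max_steps/stride")
    choices = np.zeros((n_vd, n_sim), np.int8)
    steps = np.full((n_vd, n_sim), max_steps, np.int32)
    nb = max_steps // stride
    for i in range(n_vd):
        m, drift, sig = _block_constants(lam, kappa * vds[i], sig_step, dt, stride)
        for j in range(n_sim):
            ea = beta
            for b in range(nb):
                ea = m * ea + drift + sig * noise[j, b]
                if ea > alpha:
                    choices[i, j] = 1
                    steps[i, j] = (b + 1) * stride
                    break
                elif ea < -alpha:
                    choices[i, j] = -1
                    steps[i, j] = (b + 1) * stride
                    break
    return choices, steps


@njit(cache=True)
def sim_paths(vd, n_sim, alpha, beta, kappa, lam, sig_step, dt, max_steps, seed):
    """Full Euler paths at unit-step resolution.

    Returns (paths, choices, steps); paths[j, k] is EA after k steps and is
    held at the crossing value after absorption.
    """
    np.random.seed(seed)
    paths = np.empty((n_sim, max_steps + 1), np.float64)
    choices = np.zeros(n_sim, np.int8)
    steps = np.full(n_sim, max_steps, np.int32)
    for j in range(n_sim):
        ea = beta
        paths[j, 0] = ea
        crossed = False
        for k in range(1, max_steps + 1):
            if not crossed:
                ea = ea + (lam * ea + kappa * vd) * dt + sig_step * np.random.standard_normal()
                if ea > alpha:
                    choices[j] = 1
                    steps[j] = k
                    crossed = True
                elif ea < -alpha:
                    choices[j] = -1
                    steps[j] = k
                    crossed = True
            paths[j, k] = ea
    return paths, choices, steps
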