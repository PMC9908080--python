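"""Charness-Rabin valuation and OU evidence-accumulation behaviour.

The subjective value difference between the equal and the unequal option is

    VD = (1 - omega) * E_self + omega * E_other
         - [(1 - omega) * I_self + omega * I_other]

where (E_self, E_other) are the payoffs of the more equal option and
(I_self, I_other) those of the more unequal one; ``omega`` is the weight
placed on the other's payoff (altruism weight).  Evidence accumulates from
the starting point ``beta`` as a leaky (Ornstein-Uhlenbeck) process with
drift ``kappa * VD``, leak ``lambda_``, per-step noise, and absorbing
thresholds at ``+alpha`` (equal choice) and ``-alpha`` (unequal choice).
Response time is accumulation time plus the non-decision time ``tau``;
accumulation is cut off at the 3 s response deadline (timeout).

By default the per-step Gaussian increment has scale ``sigma * sqrt(dt)``
so that ``sigma`` is a diffusion coefficient per sqrt-second and the
process has a well-defined continuum limit; ``literal_noise=True`` instead
uses scale ``sigma`` per step exactly as in the discrete update rule.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import _sim
from .design import TrialDesign, equal_unequal_diffs

__all__ = [
    "OUParams",
    "BehavioralRecord",
    "EATrace",
    "value_difference",
    "simulate_trial",
    "simulate_choices",
    "simulate_behavior",
    "predict_ea_trace",
    "predictive_accuracy",
    "DECISION_DEADLINE",
]

DECISION_DEADLINE = 3.0  # s, response window from alternative onset


@dataclass(frozen=True)
class OUParams:
    """Free parameters of the OU decision model (one context, one person).

    alpha   : decision threshold (evidence units, > 0)
    beta    : starting point; positive values bias toward the equal bound
    kappa   : drift-rate modulator (evidence per token per second)
    omega   : weight on the other's payoff, in [-1, 1]
    lambda_ : leak strength (1/s); negative values decay toward zero
    tau     : non-decision time (s)
    sigma   : within-trial noise scale, fixed at 1.4
    dt      : integration step, fixed at 0.001 s
    """

    alpha: float
    beta: float
    kappa: float
    omega: float
    lambda_: float
    tau: float
    sigma: float = 1.4
    dt: float = 0.001

    def validate(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if abs(self.beta) >= self.alpha:
            raise ValueError("|beta| must be below alpha")
        if not -1.0 <= self.omega <= 1.0:
            raise ValueError("omega must lie in [-1, 1]")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.sigma <= 0 or self.dt <= 0:
            raise ValueError("sigma and dt must be positive")

    def with_(self, **kw) -> "OUParams":
        return replace(self, **kw)

    def sig_step(self, literal_noise: bool = False) -> float:
        return self.sigma if literal_noise else self.sigma * np.sqrt(self.dt)


@dataclass(frozen=True)
class BehavioralRecord:
    trial_index: int
    choice: str  # "equal" | "unequal" | "timeout"
    rt: float


@dataclass(frozen=True)
class EATrace:
    """Response-locked, trial-averaged evidence-accumulation prediction."""

    times: np.ndarray  # s, negative up to 0 = response
    values: np.ndarray
    n_averaged: int


def _payoffs(pair) -> tuple[float, float]:
    if hasattr(pair, "self_tokens"):
        return float(pair.self_tokens), float(pair.other_tokens)
    s, o = pair
    return float(s), float(o)


def value_difference(params: OUParams, equal, unequal) -> float:
    """Charness-Rabin utility difference, equal minus unequal option."""
    es, eo = _payoffs(equal)
    is_, io = _payoffs(unequal)
    w = params.omega
    return (1.0 - w) * es + w * eo - ((1.0 - w) * is_ + w * io)


def _max_steps(params: OUParams) -> int:
    return int(round(DECISION_DEADLINE / params.dt))


_CHOICE_LABEL = {1: "equal", -1: "unequal", 0: "timeout"}


def simulate_choices(
    params: OUParams,
    vds: np.ndarray,
    n_sim: int,
    seed: int,
    literal_noise: bool = False,
    stride: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate choices/RTs for an array of value differences.

    Returns (choices, rts) of shape (len(vds), n_sim); choices are +1
    equal, -1 unequal, 0 timeout; rts include the non-decision time and
    are NaN for timeouts.
    """
    params.validate()
    vds = np.ascontiguousarray(np.asarray(vds, dtype=np.float64))
    if not np.all(np.isfinite(vds)):
        raise ValueError("non-finite value difference")
    choices, steps = _sim.sim_choices(
        vds, int(n_sim), params.alpha, params.beta, params.kappa,
        params.lambda_, params.sig_step(literal_noise), params.dt,
        _max_steps(params), int(stride), int(seed),
    )
    rts = steps * params.dt + params.tau
    rts[choices == 0] = np.nan
    return choices, rts


def simulate_trial(
    params: OUParams, vd: float, seed: int, literal_noise: bool = False
) -> tuple[BehavioralRecord, np.ndarray]:
    """Simulate one trial; returns the record and the raw EA path."""
    params.validate()
    if not np.isfinite(vd):
        raise ValueError("non-finite value difference")
    paths, choices, steps = _sim.sim_paths(
        float(vd), 1, params.alpha, params.beta, params.kappa, params.lambda_,
        params.sig_step(literal_noise), params.dt, _max_steps(params), int(seed),
    )
    c = int(choices[0])
    k = int(steps[0])
    rt = k * params.dt + params.tau if c != 0 else float("nan")
    rec = BehavioralRecord(trial_index=0, choice=_CHOICE_LABEL[c], rt=rt)
    return rec, paths[0, : k + 1]


def simulate_behavior(
    params_by_context: dict[str, OUParams],
    design: TrialDesign,
    seed: int,
    participant_id: str | None = None,
    literal_noise: bool = False,
) -> pd.DataFrame:
    """Simulate one participant's choices/RTs over a full trial design.

    One independent path per trial, at the model's native 1 ms step.
    Returns a table with participant_id, trial_index, context, choice, rt.
    """
    pid = participant_id or design.participant_id
    out = []
    rng = np.random.default_rng(seed)
    for context, params in params_by_context.items():
        sub = design.context_table(context)
        ds, do = equal_unequal_diffs(sub)
        vds = (1.0 - params.omega) * ds + params.omega * do
        choices, rts = simulate_choices(
            params, vds, 1, int(rng.integers(2**31 - 1)), literal_noise
        )
        for ti, c, rt in zip(sub["trial_index"], choices[:, 0], rts[:, 0]):
            out.append(
                dict(participant_id=pid, trial_index=int(ti), context=context,
                     choice=_CHOICE_LABEL[int(c)], rt=float(rt))
            )
    return (
        pd.DataFrame.from_records(out)
        .sort_values("trial_index")
        .reset_index(drop=True)
    )


def predict_ea_trace(
    params: OUParams,
    vd: float,
    seed: int,
    n: int = 500,
    window: tuple[float, float] = (-0.6, -0.1),
    dt_out: float = 0.002,
    literal_noise: bool = False,
) -> EATrace:
    """Average of ``n`` response-locked simulated EA paths for one trial.

    Each path is aligned at its own threshold crossing (t = 0); samples
    before a path's start are padded with the starting point.  Timeout
    paths are discarded; the average runs over the remaining paths on the
    ``window`` grid (default -600..-100 ms in 2 ms steps).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params.validate()
    paths, choices, steps = _sim.sim_paths(
        float(vd), int(n), params.alpha, params.beta, params.kappa,
        params.lambda_, params.sig_step(literal_noise), params.dt,
        _max_steps(params), int(seed),
    )
    ok = choices != 0
    if not ok.any():
        raise RuntimeError("all simulated paths timed out")
    paths, steps = paths[ok], steps[ok]
    times = np.arange(window[0], window[1] + dt_out / 2, dt_out)
    offsets = np.round(times / params.dt).astype(int)  # negative step offsets
    idx = steps[:, None] + offsets[None, :]
    clipped = np.clip(idx, 0, None)
    vals = np.take_along_axis(paths, clipped, axis=1)
    vals[idx < 0] = params.beta
    return EATrace(times=times, values=vals.mean(axis=0), n_averaged=int(ok.sum()))


def predictive_accuracy(
    params_by_context: dict[str, OUParams],
    behavior: pd.DataFrame,
    design: TrialDesign,
    n_sim: int = 500,
    seed: int = 0,
    stride: int = 1,
) -> dict[str, dict[str, float]]:
    """Sensitivity, specificity and balanced accuracy per context.

    The model's predicted choice for a trial is the modal choice over
    ``n_sim`` simulations.  Sensitivity = correctly predicted equal trials
    / observed equal trials; specificity is the unequal analogue; balanced
    accuracy is their mean.  Observed timeouts are excluded.  A context
    with no observed equal (unequal) trials reports NaN for that metric.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, float]] = {}
    for context, params in params_by_context.items():
        sub = design.context_table(context)
        beh = behavior[behavior["context"] == context].set_index("trial_index")
        obs = beh.loc[sub["trial_index"], "choice"].to_numpy()
        keep = obs != "timeout"
        sub = sub[keep]
        obs = obs[keep]
        ds, do = equal_unequal_diffs(sub)
        vds = (1.0 - params.omega) * ds + params.omega * do
        uniq, inv = np.unique(vds, return_inverse=True)
        choices, _ = simulate_choices(
            params, uniq, n_sim, int(rng.integers(2**31 - 1)), stride=stride
        )
        # modal choice among decided simulations
        n_eq = (choices == 1).sum(axis=1)
        n_un = (choices == -1).sum(axis=1)
        pred = np.where(n_eq >= n_un, "equal", "unequal")[inv]
        obs_eq = obs == "equal"
        obs_un = obs == "unequal"
        sens = (
            float((pred[obs_eq] == "equal").mean()) if obs_eq.any() else float("nan")
        )
        spec = (
            float((pred[obs_un] == "unequal").mean()) if obs_un.any() else float("nan")
        )
        out[context] = dict(
            sensitivity=sens,
            specificity=spec,
            balanced_accuracy=(sens + spec) / 2.0,
            n_trials=int(keep.sum()),
        )
    return out
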