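"""Simulation-based likelihood and differential-evolution estimation.

For a candidate parameter set the likelihood of a trial's observed
(choice, RT) is read off a joint choice x RT-bin histogram built from
``n_sim`` model simulations of that trial's value difference.  Parameters
are estimated per participant (and per context, unless a model variant
ties parameters across contexts) by differential evolution (DE/rand/1/bin)
with 60 population members over 150 iterations at full scale.

One standard-normal matrix, drawn once per fit, supplies the simulation
noise for every candidate and iteration (common random numbers), so the
objective is a deterministic function of the parameters and the best
objective found is non-increasing over iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution
from scipy.stats import qmc

from . import _sim
from .behavior import DECISION_DEADLINE, OUParams
from .design import TrialDesign, equal_unequal_diffs

__all__ = [
    "FitConfig",
    "FitResult",
    "MODEL_NAMES",
    "simulate_likelihood",
    "fit_de",
    "compare_models",
    "bic",
]

CONTEXTS = ("DIS", "ADV")

MODEL_NAMES = (
    "OU_full", "DDM", "OU_shared_omega", "OU_shared_alpha",
    "OU_shared_both", "OU_order",
)

#: parameters tied across contexts, and parameters fixed at zero, per model
_SHARED: dict[str, tuple[str, ...]] = {
    "OU_full": (),
    "DDM": (),
    "OU_shared_omega": ("omega",),
    "OU_shared_alpha": ("alpha",),
    "OU_shared_both": ("omega", "alpha"),
    "OU_order": (),
}
_FIXED_ZERO: dict[str, tuple[str, ...]] = {name: () for name in MODEL_NAMES}
_FIXED_ZERO["DDM"] = ("lambda_",)

_PARAM_ORDER = ("alpha", "beta_frac", "kappa", "omega", "lambda_", "tau")

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (0.1, 4.0),
    "beta_frac": (-0.9, 0.9),  # starting point as a fraction of alpha
    "kappa": (0.0, 2.0),
    "omega": (-1.0, 1.0),
    "lambda_": (-5.0, 5.0),
    "tau": (0.1, 0.8),
}


@dataclass
class FitConfig:
    """Estimation settings.

    ``n_pop``/``n_iter``/``n_sim`` default to the full-scale procedure (60
    members, 150 iterations, 3000 simulated decisions per likelihood
    evaluation).  ``check_every`` is the bound-check interval of the
    block-aggregated simulator in unit (1 ms) steps; RTs enter a histogram
    of ``rt_bin_width`` (s) so a 10 ms check interval is far below the
    histogram resolution.  ``pseudocount`` smooths empty histogram cells.
    """

    n_pop: int = 60
    n_iter: int = 150
    n_sim: int = 3000
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    rt_bin_width: float = 0.1
    pseudocount: float = 1.0
    check_every: int = 10
    seed: int = 0
    sigma: float = 1.4
    dt: float = 0.001

    @property
    def n_rt_bins(self) -> int:
        return int(round(DECISION_DEADLINE / self.rt_bin_width))


@dataclass
class FitResult:
    model_name: str
    params: dict[str, OUParams]
    log_likelihood: float
    bic: float
    n_trials: int
    n_free_params: int
    log_likelihood_by_context: dict[str, float]
    convergence: list[float]
    participant_id: str = ""

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = {c: asdict(p) for c, p in self.params.items()}
        return d


def bic(log_likelihood: float, k: int, n: int) -> float:
    """Bayesian information criterion, k ln n - 2 lnL."""
    return k * np.log(n) - 2.0 * log_likelihood


def n_free_params(model_name: str) -> int:
    if model_name not in MODEL_NAMES:
        raise ValueError(f"unknown model {model_name!r}")
    per_context = 6 - len(_FIXED_ZERO[model_name])
    return 2 * per_context - len(_SHARED[model_name])


class _ContextData:
    """Observed choices/RTs and per-trial payoff differences, one context.

    ``boundary="equal"`` codes the upper boundary as the more equal option
    (+1); ``boundary="order"`` codes it as the second-presented
    (alternative) option, for the presentation-order model variant.
    """

    def __init__(self, behavior: pd.DataFrame, design_table: pd.DataFrame,
                 boundary: str = "equal"):
        beh = behavior.set_index("trial_index")
        tbl = design_table[design_table["equal_option"] != "tie"]
        obs_choice = beh.loc[tbl["trial_index"], "choice"].to_numpy()
        keep = obs_choice != "timeout"
        tbl = tbl[keep]
        if len(tbl) == 0:
            raise ValueError("no decided trials to fit")
        self.rt = beh.loc[tbl["trial_index"], "rt"].to_numpy(dtype=float)
        if boundary == "equal":
            ds, do = equal_unequal_diffs(tbl)
            self.obs_up = obs_choice[keep] == "equal"
        elif boundary == "order":
            ds = tbl["delta_self"].to_numpy(dtype=float)
            do = tbl["delta_other"].to_numpy(dtype=float)
            chose_alt = (
                beh.loc[tbl["trial_index"], "choice"]
                == np.where(tbl["equal_option"] == "alternative", "equal", "unequal")
            ).to_numpy()
            self.obs_up = chose_alt
        else:
            raise ValueError(f"unknown boundary coding {boundary!r}")
        self.d_self = ds
        self.d_other = do
        self.n_trials = len(tbl)


def _loglik_arrays(
    theta: np.ndarray, data: _ContextData, config: FitConfig, noise: np.ndarray
) -> float:
    alpha, beta_frac, kappa, omega, lambda_, tau = theta
    vds = (1.0 - omega) * data.d_self + omega * data.d_other
    uniq, inv = np.unique(vds, return_inverse=True)
    max_steps = int(round(DECISION_DEADLINE / config.dt))
    choices, steps = _sim.sim_choices_shared_noise(
        np.ascontiguousarray(uniq), alpha, beta_frac * alpha, kappa, lambda_,
        config.sigma * np.sqrt(config.dt), config.dt, max_steps,
        config.check_every, noise,
    )
    n_sim = choices.shape[1]
    nb = config.n_rt_bins
    n_cells = 2 * nb
    # joint (choice, rt-bin) histogram per unique value difference
    rts = steps * config.dt + tau
    bins = np.clip((rts / config.rt_bin_width).astype(np.int64), 0, nb - 1)
    cell = np.where(choices == 1, bins, nb + bins)  # 0..nb-1 equal, nb.. unequal
    cell[choices == 0] = -1  # simulated timeouts carry no cell
    counts = np.zeros((len(uniq), n_cells), dtype=np.int64)
    for i in range(len(uniq)):
        c = cell[i]
        np.add.at(counts[i], c[c >= 0], 1)
    eps = config.pseudocount
    probs = (counts + eps) / (n_sim + eps * n_cells)
    obs_bin = np.clip(
        (data.rt / config.rt_bin_width).astype(np.int64), 0, nb - 1
    )
    obs_cell = np.where(data.obs_up, obs_bin, nb + obs_bin)
    return float(np.log(probs[inv, obs_cell]).sum())


def simulate_likelihood(
    params: OUParams,
    behavior: pd.DataFrame,
    design: TrialDesign,
    context: str,
    config: FitConfig | None = None,
    seed: int | None = None,
    boundary: str = "equal",
) -> float:
    """Simulated log-likelihood of one context's observed choices/RTs."""
    config = config or FitConfig()
    params.validate()
    for name in ("alpha", "kappa", "omega", "lambda_", "tau"):
        lo, hi = config.bounds[name]
        if not lo <= getattr(params, name) <= hi:
            return -np.inf
    if not abs(params.beta) <= config.bounds["beta_frac"][1] * params.alpha:
        return -np.inf
    data = _ContextData(
        behavior[behavior["context"] == context],
        design.context_table(context),
        boundary=boundary,
    )
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_blocks = int(round(DECISION_DEADLINE / config.dt)) // config.check_every
    noise = rng.standard_normal((config.n_sim, n_blocks))
    theta = np.array([
        params.alpha, params.beta / params.alpha, params.kappa,
        params.omega, params.lambda_, params.tau,
    ])
    return _loglik_arrays(theta, data, config, noise)


def _expand(theta: np.ndarray, model_name: str) -> dict[str, np.ndarray]:
    """Map a flat DE vector to per-context 6-parameter vectors."""
    shared = _SHARED[model_name]
    fixed = _FIXED_ZERO[model_name]
    out = {}
    pos = 0
    shared_vals = {}
    for p in shared:
        shared_vals[p] = theta[pos]
        pos += 1
    for ctx in CONTEXTS:
        vec = np.zeros(6)
        for k, p in enumerate(_PARAM_ORDER):
            if p in fixed:
                vec[k] = 0.0
            elif p in shared:
                vec[k] = shared_vals[p]
            else:
                vec[k] = theta[pos]
                pos += 1
        out[ctx] = vec
    return out


def _layout_bounds(model_name: str, bounds: dict) -> list[tuple[float, float]]:
    shared = _SHARED[model_name]
    fixed = _FIXED_ZERO[model_name]
    free = [p for p in _PARAM_ORDER if p not in fixed and p not in shared]
    out = [bounds[p] for p in shared]
    for _ctx in CONTEXTS:
        out.extend(bounds[p] for p in free)
    return out


def _run_de(objective, bounds, config: FitConfig, rng) -> tuple[np.ndarray, list[float]]:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    init = lo + qmc.LatinHypercube(
        d=len(bounds), seed=int(rng.integers(2**31 - 1))
    ).random(config.n_pop) * (hi - lo)
    trace: list[float] = []

    def callback(xk, convergence=0.0):
        trace.append(float(objective(np.asarray(xk))))

    result = differential_evolution(
        objective,
        bounds,
        strategy="rand1bin",
        maxiter=config.n_iter,
        init=init,
        tol=0.01,
        seed=int(rng.integers(2**31 - 1)),
        polish=False,
        callback=callback,
    )
    best_trace = [float(min(trace[: i + 1])) for i in range(len(trace))]
    return result.x, best_trace


def fit_de(
    behavior: pd.DataFrame,
    design: TrialDesign,
    model_name: str = "OU_full",
    config: FitConfig | None = None,
) -> FitResult:
    """Differential-evolution fit of one participant's behaviour.

    Contexts are fitted jointly over a single flat parameter vector;
    parameters listed as shared by the model variant are tied across
    contexts.  Fully reproducible for a given ``config.seed``.
    """
    config = config or FitConfig()
    if model_name not in MODEL_NAMES:
        raise ValueError(f"unknown model {model_name!r}")
    boundary = "order" if model_name == "OU_order" else "equal"
    data = {
        ctx: _ContextData(
            behavior[behavior["context"] == ctx],
            design.context_table(ctx),
            boundary=boundary,
        )
        for ctx in CONTEXTS
    }
    rng = np.random.default_rng(config.seed)
    n_blocks = int(round(DECISION_DEADLINE / config.dt)) // config.check_every
    noise = rng.standard_normal((config.n_sim, n_blocks))

    fixed = _FIXED_ZERO[model_name]
    free = [p for p in _PARAM_ORDER if p not in fixed]

    if not _SHARED[model_name]:
        # contexts are separable: estimate each with its own 5/6-dim search
        vecs = {}
        traces = []
        for ctx in CONTEXTS:
            ctx_bounds = [config.bounds[p] for p in free]

            def objective(theta: np.ndarray, _ctx=ctx) -> float:
                vec = np.zeros(6)
                for k, p in enumerate(_PARAM_ORDER):
                    if p not in fixed:
                        vec[k] = theta[free.index(p)]
                return -_loglik_arrays(vec, data[_ctx], config, noise)

            x, trace = _run_de(objective, ctx_bounds, config, rng)
            vec = np.zeros(6)
            for k, p in enumerate(_PARAM_ORDER):
                if p not in fixed:
                    vec[k] = x[free.index(p)]
            vecs[ctx] = vec
            traces.append(trace)
        # total-objective trace: pad the shorter context trace with its
        # final value and sum element-wise
        m = max(len(t) for t in traces)
        padded = [t + [t[-1]] * (m - len(t)) for t in traces]
        trace = [a + b for a, b in zip(*padded)]
    else:
        bounds = _layout_bounds(model_name, config.bounds)

        def objective(theta: np.ndarray) -> float:
            v = _expand(theta, model_name)
            return -sum(
                _loglik_arrays(v[ctx], data[ctx], config, noise) for ctx in CONTEXTS
            )

        best, trace = _run_de(objective, bounds, config, rng)
        vecs = _expand(best, model_name)
    ll_by_ctx = {
        ctx: _loglik_arrays(vecs[ctx], data[ctx], config, noise) for ctx in CONTEXTS
    }
    params = {}
    for ctx in CONTEXTS:
        a, bf, k, w, l, t = vecs[ctx]
        params[ctx] = OUParams(
            alpha=a, beta=bf * a, kappa=k, omega=w, lambda_=l, tau=t,
            sigma=config.sigma, dt=config.dt,
        )
    ll = float(sum(ll_by_ctx.values()))
    n = sum(d.n_trials for d in data.values())
    k_free = n_free_params(model_name)
    pid = str(behavior["participant_id"].iloc[0]) if "participant_id" in behavior else ""
    return FitResult(
        model_name=model_name,
        params=params,
        log_likelihood=ll,
        bic=float(bic(ll, k_free, n)),
        n_trials=int(n),
        n_free_params=k_free,
        log_likelihood_by_context={c: float(v) for c, v in ll_by_ctx.items()},
        convergence=trace,
        participant_id=pid,
    )


def compare_models(fits: list[FitResult]) -> pd.DataFrame:
    """Rank a participant's fitted model variants by BIC (ascending)."""
    if len({f.n_trials for f in fits}) > 1:
        raise ValueError("fits compare different trial sets")
    rows = [
        dict(model_name=f.model_name, bic=f.bic, k=f.n_free_params,
             log_likelihood=f.log_likelihood)
        for f in fits
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["bic", "k"], kind="stable")
        .reset_index(drop=True)
    )


def winner_counts(fits_by_participant: dict[str, list[FitResult]]) -> pd.Series:
    """How often each model variant wins (lowest BIC) across participants."""
    winners = [
        compare_models(fits).iloc[0]["model_name"]
        for fits in fits_by_participant.values()
    ]
    return pd.Series(winners).value_counts()
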