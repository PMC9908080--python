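"""Synthetic cohort generator: ground-truth parameters, behaviour, a
hexagonal sensor montage, and epoched EEG with planted effects.

The generator emulates the study conditions end-to-end so that every
downstream analysis stage can be validated without any recorded data:

* behaviour is simulated from the OU model on the 416-trial schedule, with
  altruism weights and thresholds drawn around the group means
  (omega: 0.15 ADV / 0.10 DIS; alpha: 1.11 ADV / 1.34 DIS);
* response-locked epochs carry a parietal component proportional to the
  model-predicted evidence-accumulation trace of each trial;
* stimulus-locked epochs carry amplitudes linear in the standardized
  self- and other-payoff changes, with context-dependent self-payoff
  coefficients (sign flip between contexts in two centroparietal windows)
  and a group-dependent other-payoff coefficient in a centrofrontal
  window;
* a 64-79 Hz frontal-parietal oscillation with a consistent cross-region
  phase lag in a -520..-460 ms pre-response window is added for more
  altruistic (MA) participants only; less altruistic (LA) participants
  receive amplitude-matched bursts with trial-random relative phase.

Background activity is 1/f (pink) noise, spatially correlated over the
montage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .behavior import OUParams, predict_ea_trace, simulate_behavior
from .container import EpochedEEG
from .design import TrialDesign, equal_unequal_diffs

__all__ = [
    "Montage",
    "CohortTruth",
    "CONTEXT_MEANS",
    "generate_montage",
    "generate_cohort",
    "generate_response_locked_eeg",
    "generate_stimulus_locked_eeg",
    "generate_gamma_coupling",
    "pink_noise",
    "ea_traces_for_design",
]

#: Group-mean generating parameters per inequality context.  omega and
#: alpha sit at the printed group means; kappa, lambda, tau and the
#: starting-point fraction were calibrated once so that the simulated
#: cohort reproduces the printed choice/RT regime (P(equal) ~ 0.74 DIS /
#: 0.27 ADV; mean RT ~ 0.8 s; equal choices faster in DIS, unequal in ADV).
CONTEXT_MEANS: dict[str, dict[str, float]] = {
    "DIS": dict(alpha=1.34, beta_frac=0.10, kappa=0.7, omega=0.10,
                lambda_=-1.0, tau=0.30),
    "ADV": dict(alpha=1.11, beta_frac=-0.15, kappa=0.7, omega=0.15,
                lambda_=-1.0, tau=0.30),
}

#: Between-participant SDs (truncated draws); omega is drawn tightly
#: around the group mean.
CONTEXT_SDS: dict[str, float] = dict(
    alpha=0.12, beta_frac=0.04, kappa=0.08, omega=0.03, lambda_=0.25, tau=0.03
)

SFREQ = 500.0
RESPONSE_EPOCH = (-1.0, 0.2)
STIMULUS_EPOCH = (-0.5, 1.0)
EA_WINDOW = (-0.6, -0.1)
GAMMA_BAND = (64.0, 79.0)
GAMMA_WINDOW = (-0.52, -0.46)


@dataclass
class Montage:
    """Sensor layout: names, 2-D head-plane positions, neighbour graph and
    labelled channel sets (parietal / centroparietal / centrofrontal)."""

    ch_names: list[str]
    positions: np.ndarray  # (n, 2)
    adjacency: csr_matrix  # boolean, symmetric, no self-edges
    sets: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return len(self.ch_names)

    def neighbors(self, i: int) -> np.ndarray:
        return self.adjacency[i].indices

    def set_with_neighbors(self, name: str) -> np.ndarray:
        idx = set(self.sets[name].tolist())
        for i in list(idx):
            idx.update(self.neighbors(i).tolist())
        return np.array(sorted(idx))


def _hex_lattice(n: int) -> np.ndarray:
    """First ``n`` nodes of a unit-spacing hexagonal lattice, sorted by
    distance from the centre (ties broken by angle)."""
    ring = 1
    axial = [(0, 0)]
    while len(axial) < 4 * n:
        for q in range(-ring, ring + 1):
            for r in range(-ring, ring + 1):
                s = -q - r
                if max(abs(q), abs(r), abs(s)) == ring:
                    axial.append((q, r))
        ring += 1
    pts = np.array([(q + r / 2.0, r * np.sqrt(3) / 2.0) for q, r in axial])
    order = np.lexsort((np.arctan2(pts[:, 1], pts[:, 0]), np.linalg.norm(pts, axis=1)))
    return pts[order[:n]]


def generate_montage(n: int = 128, neighbor_radius: float = 1.3) -> Montage:
    """Equidistant hexagonal montage with distance-threshold adjacency.

    Positive y is anterior.  Channel sets are discs around canonical
    centrofrontal, centroparietal and parietal locations.
    """
    if n < 16:
        raise ValueError("montage needs at least 16 channels")
    pos = _hex_lattice(n)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    adj = (d > 1e-9) & (d <= neighbor_radius)
    if not np.array_equal(adj, adj.T):  # pragma: no cover - construction
        raise RuntimeError("adjacency not symmetric")
    n_comp, _ = connected_components(csr_matrix(adj), directed=False)
    if n_comp != 1:
        raise ValueError("neighbor_radius yields a disconnected montage")
    extent = np.abs(pos[:, 1]).max()
    centers = {
        "parietal_cluster": (0.0, -0.68 * extent),
        "centroparietal_cluster": (0.0, -0.22 * extent),
        "centrofrontal_cluster": (0.0, 0.48 * extent),
    }
    sets = {}
    for name, c in centers.items():
        # nearest lattice node plus its immediate neighbours (a 7-channel
        # hexagon for interior seeds)
        seed_ch = int(np.argmin(np.linalg.norm(pos - np.array(c), axis=1)))
        idx = np.unique(np.r_[seed_ch, np.where(adj[seed_ch])[0]])
        sub = csr_matrix(adj[np.ix_(idx, idx)])
        ncomp, _ = connected_components(sub, directed=False)
        if ncomp != 1:
            raise ValueError(f"labelled set {name} not internally connected")
        sets[name] = idx
    names = [f"E{i + 1:03d}" for i in range(n)]
    return Montage(ch_names=names, positions=pos, adjacency=csr_matrix(adj), sets=sets)


@dataclass
class CohortTruth:
    """Ground truth for a synthetic cohort: per-participant generating
    parameters per context, MA/LA group labels (median split on the DIS
    altruism weight), and planted EEG effect coefficients."""

    participants: list[dict]

    def __len__(self) -> int:
        return len(self.participants)

    def groups(self) -> list[str]:
        return [p["group"] for p in self.participants]


def _draw_params(rng: np.random.Generator, context: str) -> OUParams:
    m = CONTEXT_MEANS[context]
    s = CONTEXT_SDS
    draw = {}
    for key in ("alpha", "beta_frac", "kappa", "omega", "lambda_", "tau"):
        lo = m[key] - 2.0 * s[key]
        hi = m[key] + 2.0 * s[key]
        draw[key] = float(np.clip(rng.normal(m[key], s[key]), lo, hi))
    draw["alpha"] = max(draw["alpha"], 0.3)
    draw["tau"] = max(draw["tau"], 0.1)
    return OUParams(
        alpha=draw["alpha"], beta=draw["beta_frac"] * draw["alpha"],
        kappa=draw["kappa"], omega=draw["omega"], lambda_=draw["lambda_"],
        tau=draw["tau"],
    )


def generate_cohort(
    n_participants: int,
    design: TrialDesign,
    seed: int,
) -> tuple[CohortTruth, dict[str, pd.DataFrame]]:
    """Draw ground-truth parameters and simulate behaviour for a cohort.

    Group labels split the cohort at the median DIS altruism weight
    (MA above, LA below; balanced to within one participant).  Planted
    stimulus-locked coefficients (microvolts per SD of the regressor):
    the self-payoff coefficient flips sign between contexts in an early
    (240-360 ms) and, reversed, a late (440-800 ms) centroparietal window;
    the other-payoff coefficient in the centrofrontal 320-400 ms window
    (DIS context) is positive for MA and negative for LA participants,
    with magnitude increasing in the participant's DIS altruism weight.
    """
    if n_participants < 2:
        raise ValueError("cohort needs at least 2 participants")
    rng = np.random.default_rng(seed)
    participants = []
    for i in range(n_participants):
        params = {ctx: _draw_params(rng, ctx) for ctx in ("DIS", "ADV")}
        participants.append(dict(participant_id=f"sub-{i:02d}", params=params))
    omegas = np.array([p["params"]["DIS"].omega for p in participants])
    med = float(np.median(omegas))
    ranks = np.argsort(np.argsort(omegas))
    for p, w, rk in zip(participants, omegas, ranks):
        # median split; rank-based tie-break keeps the split balanced
        p["group"] = "MA" if rk >= n_participants / 2 else "LA"
        dev = float(w - med)
        p["planted"] = dict(
            b1_early={"DIS": 0.8, "ADV": -0.8},
            b1_late={"DIS": -0.8, "ADV": 0.8},
            b2_dis=float(np.sign(dev) if dev != 0 else 1.0) * (0.25 + 4.0 * abs(dev)),
            ea_gain=1.0,
        )
    behavior = {}
    for p in participants:
        behavior[p["participant_id"]] = simulate_behavior(
            p["params"], design, seed=int(rng.integers(2**31 - 1)),
            participant_id=p["participant_id"],
        )
    return CohortTruth(participants=participants), behavior


def pink_noise(
    rng: np.random.Generator,
    n_ch: int,
    n_samples: int,
    n_trials: int,
    sfreq: float = SFREQ,
    spatial_scale: float = 1.0,
    positions: np.ndarray | None = None,
) -> np.ndarray:
    """1/f-power background noise, unit RMS, optionally spatially
    correlated over the montage with a Gaussian distance kernel."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sfreq)
    amp = np.zeros_like(freqs)
    amp[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = (
        rng.standard_normal((n_ch, n_trials, freqs.size))
        + 1j * rng.standard_normal((n_ch, n_trials, freqs.size))
    ) * amp
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    if positions is not None and spatial_scale > 0:
        d = np.linalg.norm(positions[:, None] - positions[None, :], axis=-1)
        k = np.exp(-(d**2) / (2.0 * spatial_scale**2))
        k += 1e-6 * np.eye(n_ch)
        chol = np.linalg.cholesky(k)
        x = np.einsum("ij,jts->its", chol, x)
    x /= x.std()
    return np.transpose(x, (0, 2, 1))  # (n_ch, n_samples, n_trials)


def ea_traces_for_design(
    params_by_context: dict[str, OUParams],
    design: TrialDesign,
    seed: int,
    n: int = 500,
    window: tuple[float, float] = EA_WINDOW,
    dt_out: float = 0.002,
) -> tuple[np.ndarray, np.ndarray]:
    """Model-predicted EA trace per trial (n_trials x n_window_samples).

    Traces are computed per unique value difference within each context
    (trials sharing a value difference share the prediction) by averaging
    ``n`` response-locked simulated paths.
    """
    rng = np.random.default_rng(seed)
    n_samp = len(np.arange(window[0], window[1] + dt_out / 2, dt_out))
    traces = np.zeros((len(design), n_samp))
    times = None
    for ctx, params in params_by_context.items():
        sub = design.context_table(ctx)
        ds, do = equal_unequal_diffs(sub)
        vds = (1.0 - params.omega) * ds + params.omega * do
        uniq, inv = np.unique(vds, return_inverse=True)
        per_vd = []
        for vd in uniq:
            tr = predict_ea_trace(params, float(vd), seed=int(rng.integers(2**31 - 1)),
                                  n=n, window=window, dt_out=dt_out)
            per_vd.append(tr.values)
            times = tr.times
        per_vd = np.array(per_vd)
        traces[sub.index.to_numpy()] = per_vd[inv]
    return traces, times


def generate_response_locked_eeg(
    behavior: pd.DataFrame,
    traces: np.ndarray,
    trace_times: np.ndarray,
    montage: Montage,
    seed: int,
    snr: float = 1.5,
    trial_table: pd.DataFrame | None = None,
) -> EpochedEEG:
    """Response-locked epochs with a planted parietal EA component.

    Channel weights are positive on the parietal set only (Gaussian taper
    around the set centroid, zero elsewhere); each trial's planted signal
    is its EA trace, flat-padded outside the trace window over the
    -1000..+200 ms epoch.  ``snr`` is planted-signal RMS over noise RMS on
    the planted channels within the trace window.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    times = np.arange(RESPONSE_EPOCH[0], RESPONSE_EPOCH[1] + 1e-9, 1.0 / SFREQ)
    n_ch = montage.n_channels
    n_trials = traces.shape[0]

    # flat-padded per-trial signal over the full epoch
    sig = np.empty((n_trials, times.size))
    inside = (times >= trace_times[0] - 1e-9) & (times <= trace_times[-1] + 1e-9)
    interp = np.array([np.interp(times[inside], trace_times, tr) for tr in traces])
    sig[:, inside] = interp
    sig[:, times < trace_times[0]] = traces[:, :1]
    sig[:, times > trace_times[-1]] = traces[:, -1:]

    par = montage.sets["parietal_cluster"]
    centroid = montage.positions[par].mean(axis=0)
    w = np.zeros(n_ch)
    dist = np.linalg.norm(montage.positions[par] - centroid, axis=1)
    w[par] = np.exp(-(dist**2) / (2.0 * 1.0**2))

    noise = pink_noise(rng, n_ch, times.size, n_trials, positions=montage.positions)
    planted = w[:, None, None] * np.transpose(sig)[None, :, :]
    # SNR is defined on the dynamic (per-trial mean-removed) part of the
    # planted signal: the flat pre-accumulation padding carries no
    # information and should not inflate the nominal signal power
    dyn = planted[par][:, inside, :]
    dyn = dyn - dyn.mean(axis=1, keepdims=True)
    rms_sig = np.sqrt(np.mean(dyn**2))
    rms_noise = np.sqrt(np.mean(noise[par][:, inside, :] ** 2))
    data = planted + noise * (rms_sig / (snr * rms_noise))

    table = trial_table if trial_table is not None else behavior.reset_index(drop=True)
    return EpochedEEG(
        data=data, times=times, sfreq=SFREQ, ch_names=list(montage.ch_names),
        positions=montage.positions, trial_table=table.reset_index(drop=True),
        alignment="response",
    )


#: (channel set, time window, regressor) blocks carrying planted
#: stimulus-locked effects; windows in seconds after alternative onset.
STIM_BLOCKS = (
    dict(set="centroparietal_cluster", window=(0.24, 0.36), coef="b1_early",
         regressor="delta_self"),
    dict(set="centroparietal_cluster", window=(0.44, 0.80), coef="b1_late",
         regressor="delta_self"),
    dict(set="centrofrontal_cluster", window=(0.32, 0.40), coef="b2_dis",
         regressor="delta_other"),
)


def generate_stimulus_locked_eeg(
    design: TrialDesign,
    planted: dict,
    montage: Montage,
    seed: int,
    noise_rms: float = 1.0,
    context_of_b2: str = "DIS",
) -> EpochedEEG:
    """Stimulus-locked epochs for one participant.

    Within each planted block, the per-trial amplitude added to the block's
    channels is ``coef * z`` where ``z`` is the within-context standardized
    payoff change named by the block (microvolts per SD); a Hann taper
    shapes the block in time.  The other-payoff (b2) block is planted in
    the DIS context only.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(STIMULUS_EPOCH[0], STIMULUS_EPOCH[1] + 1e-9, 1.0 / SFREQ)
    tbl = design.table
    n_trials = len(tbl)
    n_ch = montage.n_channels
    if times[0] > 0 or times[-1] < max(b["window"][1] for b in STIM_BLOCKS):
        raise ValueError("planted windows fall outside the epoch")

    z = {}
    for reg in ("delta_self", "delta_other"):
        vals = tbl[reg].to_numpy(dtype=float)
        zz = np.empty_like(vals)
        for ctx in ("DIS", "ADV"):
            m = (tbl["context"] == ctx).to_numpy()
            zz[m] = (vals[m] - vals[m].mean()) / vals[m].std()
        z[reg] = zz

    data = pink_noise(rng, n_ch, times.size, n_trials,
                      positions=montage.positions) * noise_rms
    for block in STIM_BLOCKS:
        idx = montage.sets[block["set"]]
        t0, t1 = block["window"]
        m = (times >= t0) & (times < t1)
        taper = np.ones(int(m.sum()))  # rectangular block
        coef = planted[block["coef"]]
        amp = np.zeros(n_trials)
        for ctx in ("DIS", "ADV"):
            cm = (tbl["context"] == ctx).to_numpy()
            if isinstance(coef, dict):
                c = coef[ctx]
            else:
                c = coef if ctx == context_of_b2 else 0.0
            amp[cm] = c * z[block["regressor"]][cm]
        data[np.ix_(idx, m)] += taper[None, :, None] * amp[None, None, :]
    return EpochedEEG(
        data=data, times=times, sfreq=SFREQ, ch_names=list(montage.ch_names),
        positions=montage.positions, trial_table=tbl.copy(),
        alignment="stimulus",
    )


def generate_gamma_coupling(
    eeg: EpochedEEG,
    group: str,
    montage: Montage,
    seed: int,
    amplitude: float = 0.5,
    band: tuple[float, float] = GAMMA_BAND,
    window: tuple[float, float] = GAMMA_WINDOW,
    phase_lag: float = np.pi / 2,
) -> EpochedEEG:
    """Add frontal-parietal gamma bursts to response-locked epochs.

    Each trial receives a burst at a frequency drawn uniformly from
    ``band``, Hann-tapered over ``window`` (plus 20 ms ramps), on the
    centrofrontal and parietal channel sets.  For MA participants the
    parietal burst lags the frontal one by a fixed ``phase_lag``; for LA
    participants the relative phase is re-drawn uniformly per trial, so
    the two groups are amplitude-matched but only MA carries consistent
    phase coupling.
    """
    if group not in ("MA", "LA"):
        raise ValueError("group must be 'MA' or 'LA'")
    rng = np.random.default_rng(seed)
    times = eeg.times
    data = eeg.data.copy()
    front = montage.sets["centrofrontal_cluster"]
    par = montage.sets["parietal_cluster"]
    ramp = 0.02
    m = (times >= window[0] - ramp) & (times <= window[1] + ramp)
    taper = np.hanning(int(m.sum()))
    tt = times[m]
    for j in range(eeg.n_trials):
        f0 = rng.uniform(*band)
        phi = rng.uniform(0, 2 * np.pi)
        lag = phase_lag if group == "MA" else rng.uniform(0, 2 * np.pi)
        burst_f = amplitude * taper * np.cos(2 * np.pi * f0 * tt + phi)
        burst_p = amplitude * taper * np.cos(2 * np.pi * f0 * tt + phi + lag)
        data[np.ix_(front, np.where(m)[0], [j])] += burst_f[None, :, None]
        data[np.ix_(par, np.where(m)[0], [j])] += burst_p[None, :, None]
    return EpochedEEG(
        data=data, times=times, sfreq=eeg.sfreq, ch_names=list(eeg.ch_names),
        positions=eeg.positions, trial_table=eeg.trial_table,
        alignment=eeg.alignment, baseline_corrected=eeg.baseline_corrected,
    )
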