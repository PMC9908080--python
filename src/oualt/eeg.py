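"""Model-based and GLM analyses of epoched EEG, with cluster-permutation
inference.

* ``crossval_ea_regression``: even trials identify channels whose single
  -trial voltages track the model-predicted evidence-accumulation (EA)
  trace (per-channel regression over 250 time points x trials,
  Bonferroni p < 0.05, plus a 1-SE closeness check of the averaged
  waveform); odd trials then quantify the match (R^2) in the selected
  channels.  The two halves partition the trials, so selection and
  evaluation never share data.
* ``buildup_rate``: least-squares slope of the grand-average response-
  locked waveform over -300..-100 ms (microvolts/second).
* ``glm_beta_maps``: per channel and 40 ms bin (0..1000 ms post-stimulus,
  25 bins), OLS of trial amplitudes on standardized payoff changes
  [1, z(dS), z(dO)].
* ``cluster_permutation``: point-wise t-tests thresholded at p < 0.05,
  supra-threshold points grouped over the sensor neighbour graph plus
  temporal adjacency, clusters requiring at least three distinct
  channels; cluster mass is the summed t and significance comes from a
  label-shuffling permutation distribution of the maximum mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix, eye, kron
from scipy.sparse.csgraph import connected_components

from .container import EpochedEEG
from .synth import Montage

__all__ = [
    "EARegressionResult",
    "BetaMap",
    "ClusterResult",
    "crossval_ea_regression",
    "buildup_rate",
    "glm_beta_maps",
    "cluster_permutation",
    "EA_REGRESSION_WINDOW",
    "BUILDUP_WINDOW",
]

EA_REGRESSION_WINDOW = (-0.6, -0.1)
BUILDUP_WINDOW = (-0.3, -0.1)
GLM_SPAN = (0.0, 1.0)
GLM_BIN = 0.04


@dataclass
class EARegressionResult:
    selected_channels: np.ndarray  # indices into the montage
    heldout_r2: float  # NaN when no channel selected
    channel_t: np.ndarray  # stage-1 t statistic per channel
    channel_p_bonferroni: np.ndarray
    within_band: np.ndarray  # stage-1 closeness criterion per channel
    status: str  # "ok" | "empty"


@dataclass
class BetaMap:
    """OLS coefficients per channel x 40 ms bin: beta0 (intercept), beta1
    (standardized self-payoff change), beta2 (other-payoff change)."""

    coefficients: np.ndarray  # (3, n_channels, n_bins)
    bin_edges: np.ndarray  # (n_bins + 1,), s
    context: str
    participant_id: str = ""

    @property
    def n_bins(self) -> int:
        return self.coefficients.shape[2]

    def beta(self, which: int) -> np.ndarray:
        return self.coefficients[which]


@dataclass
class ClusterResult:
    points: list[tuple[int, int]]  # (channel, bin) or (time, frequency)
    channels: np.ndarray
    mass: float
    p_value: float
    polarity: int  # +1 / -1


def _stack_window(eeg: EpochedEEG, trials: np.ndarray,
                  window=EA_REGRESSION_WINDOW):
    m = (eeg.times >= window[0] - 1e-9) & (eeg.times < window[1] - 1e-9)
    return eeg.data[:, m, :][:, :, trials], m


def crossval_ea_regression(
    eeg: EpochedEEG,
    traces: np.ndarray,
    montage: Montage,
    alpha: float = 0.05,
) -> EARegressionResult:
    """Two-stage cross-validated test of model-predicted EA signals.

    ``traces`` holds one model-predicted EA trace per trial on the same
    -600..-100 ms grid as the EEG (rows align with the epochs).  Stage 1
    (even trials): per channel, regress the stacked time x trial voltages
    on the stacked EA predictions; keep channels that survive Bonferroni
    correction at ``alpha`` and whose trial-averaged waveform stays, on
    average, within one SE of the gain-rescaled model prediction.  Stage 2
    (odd trials): regress the selected-channel average waveform on the
    mean model trace and report R^2.
    """
    if traces.shape[0] != eeg.n_trials:
        raise ValueError("one trace per epoch required")
    n_ch = montage.n_channels
    idx = np.arange(eeg.n_trials)
    even, odd = idx[idx % 2 == 0], idx[idx % 2 == 1]

    y_ev, m = _stack_window(eeg, even)
    x_ev = traces[even][:, : m.sum()].T  # (samples, trials)
    if x_ev.shape[0] != y_ev.shape[1]:
        raise ValueError("traces not on the EEG sampling grid")

    # pooled time x trial regression; the SE is clustered by trial, since
    # EEG noise is strongly autocorrelated within an epoch and only trials
    # are exchangeable
    xc = x_ev - x_ev.mean()  # (samples, trials)
    sxx = float((xc**2).sum())
    yc = y_ev - y_ev.mean(axis=(1, 2), keepdims=True)
    slope = np.einsum("cst,st->c", yc, xc) / sxx
    resid = yc - slope[:, None, None] * xc[None, :, :]
    scores = np.einsum("st,cst->ct", xc, resid)  # per-trial score sums
    n_tr = x_ev.shape[1]
    var = (scores**2).sum(axis=1) / sxx**2 * n_tr / (n_tr - 1)
    tstat = slope / np.sqrt(var)
    dof = n_tr - 1
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    p_bonf = np.minimum(p * n_ch, 1.0)
    survives = p_bonf < alpha

    # closeness criterion: the averaged even-trial waveform must lie, on
    # average over the window, within one standard error of the rescaled
    # model prediction.  The SE combines the across-trial SEM of the model
    # traces (rescaled by the same gain) with the SEM of the averaged ERP,
    # since both curves are trial averages with sampling noise.
    mean_model = x_ev.mean(axis=1)
    sem_model = x_ev.std(axis=1, ddof=1) / np.sqrt(x_ev.shape[1])
    erp = y_ev.mean(axis=2)  # (n_ch, samples)
    sem_erp = (
        y_ev.std(axis=2, ddof=1) / np.sqrt(y_ev.shape[2])
    ).mean(axis=1)
    mm = mean_model - mean_model.mean()
    gain = (erp - erp.mean(axis=1, keepdims=True)) @ mm / float(mm @ mm)
    offset = erp.mean(axis=1) - gain * mean_model.mean()
    pred = gain[:, None] * mean_model[None, :] + offset[:, None]
    dev = np.abs(erp - pred).mean(axis=1)
    band = np.sqrt((np.abs(gain) * sem_model.mean()) ** 2 + sem_erp**2)
    within = dev <= band

    selected = np.where(survives & within)[0]
    if selected.size == 0:
        return EARegressionResult(
            selected_channels=selected, heldout_r2=float("nan"),
            channel_t=tstat, channel_p_bonferroni=p_bonf,
            within_band=within, status="empty",
        )

    y_od, _ = _stack_window(eeg, odd)
    wave = y_od[selected].mean(axis=(0, 2))
    model = traces[odd][:, : m.sum()].mean(axis=0)
    r = np.corrcoef(wave, model)[0, 1]
    return EARegressionResult(
        selected_channels=selected, heldout_r2=float(r**2),
        channel_t=tstat, channel_p_bonferroni=p_bonf,
        within_band=within, status="ok",
    )


def buildup_rate(
    eeg: EpochedEEG, channels, window=BUILDUP_WINDOW
) -> float:
    """Slope (microvolts/s) of the grand-average waveform over ``window``."""
    channels = np.asarray(channels)
    m = eeg.time_mask(*window)
    wave = eeg.data[channels][:, m, :].mean(axis=(0, 2))
    t = eeg.times[m]
    return float(np.polyfit(t, wave, 1)[0])


def glm_beta_maps(
    eeg: EpochedEEG,
    context: str | None = None,
    participant_id: str = "",
) -> BetaMap:
    """Per-channel, per-40 ms-bin OLS on standardized payoff changes.

    Trial amplitudes are epoch averages within each bin; regressors are
    the within-context standardized self- and other-payoff changes from
    the trial table.  Raises on collinear regressors.
    """
    tbl = eeg.trial_table
    sel = np.arange(len(tbl))
    if context is not None:
        sel = np.where((tbl["context"] == context).to_numpy())[0]
        tbl = tbl.iloc[sel]
    ds = tbl["delta_self"].to_numpy(dtype=float)
    do = tbl["delta_other"].to_numpy(dtype=float)
    if ds.std() == 0 or do.std() == 0 or abs(np.corrcoef(ds, do)[0, 1]) > 0.999:
        raise ValueError(
            "collinear regressors: delta_self and delta_other are not "
            "separately identifiable"
        )
    zds = (ds - ds.mean()) / ds.std()
    zdo = (do - do.mean()) / do.std()

    edges = np.arange(GLM_SPAN[0], GLM_SPAN[1] + GLM_BIN / 2, GLM_BIN)
    n_bins = edges.size - 1
    n_ch = eeg.data.shape[0]
    binned = np.empty((n_ch, n_bins, sel.size))
    for b in range(n_bins):
        m = (eeg.times >= edges[b] - 1e-9) & (eeg.times < edges[b + 1] - 1e-9)
        binned[:, b, :] = eeg.data[:, m, :][:, :, sel].mean(axis=1)

    design = np.column_stack([np.ones_like(zds), zds, zdo])
    y = binned.reshape(n_ch * n_bins, sel.size).T
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    coefficients = coef.reshape(3, n_ch, n_bins)
    return BetaMap(
        coefficients=coefficients, bin_edges=edges,
        context=context or "all", participant_id=participant_id,
    )


def _grid_adjacency(n_ch: int, n_bins: int, ch_adjacency: csr_matrix | None):
    """Adjacency over (channel, bin) points: neighbouring channels within a
    bin plus identical channels in adjacent bins.  With ``ch_adjacency``
    None the first axis is treated as an ordinary grid axis (used for
    time-frequency maps)."""
    if ch_adjacency is None:
        ch_adjacency = _chain(n_ch)
    bins_chain = _chain(n_bins)
    a = kron(eye(n_bins), ch_adjacency) + kron(bins_chain, eye(n_ch))
    return csr_matrix(a)


def _chain(n: int) -> csr_matrix:
    i = np.arange(n - 1)
    data = np.ones(2 * (n - 1))
    rows = np.concatenate([i, i + 1])
    cols = np.concatenate([i + 1, i])
    return csr_matrix((data, (rows, cols)), shape=(n, n))


def _clusters_from_tmap(
    tmap: np.ndarray, t_crit: float, adjacency: csr_matrix,
    n_ch: int, min_channels: int,
):
    """Split a (points,) t-map into signed supra-threshold clusters."""
    out = []
    for polarity in (1, -1):
        mask = (polarity * tmap) > t_crit
        pts = np.where(mask)[0]
        if pts.size == 0:
            continue
        sub = adjacency[np.ix_(pts, pts)]
        n_comp, labels = connected_components(sub, directed=False)
        for c in range(n_comp):
            members = pts[labels == c]
            chans = np.unique(members % n_ch)
            if min_channels and chans.size < min_channels:
                continue
            out.append((members, chans, float(tmap[members].sum()), polarity))
    return out


def _perm_tmaps_paired(diffs: np.ndarray, n_perm: int, rng) -> np.ndarray:
    """t-maps of sign-flipped paired differences; row 0 is observed."""
    n, p = diffs.shape
    signs = np.ones((n_perm + 1, n))
    signs[1:] = rng.choice([-1.0, 1.0], size=(n_perm, n))
    means = (signs @ diffs) / n
    sq = (diffs**2).sum(axis=0) / n
    var = (sq[None, :] - means**2) * n / (n - 1)
    var = np.maximum(var, 1e-300)
    return means / np.sqrt(var / n)


def _perm_tmaps_independent(
    a: np.ndarray, b: np.ndarray, n_perm: int, rng
) -> np.ndarray:
    """Welch t-maps under group-label shuffling; row 0 is observed."""
    x = np.vstack([a, b])
    n1, n2 = a.shape[0], b.shape[0]
    n = n1 + n2
    member = np.zeros((n_perm + 1, n), dtype=bool)
    member[0, :n1] = True
    for i in range(n_perm):
        member[i + 1, rng.permutation(n)[:n1]] = True
    mf = member.astype(float)
    cf = (~member).astype(float)
    s1 = mf @ x
    s2 = cf @ x
    q1 = mf @ (x**2)
    q2 = cf @ (x**2)
    m1, m2 = s1 / n1, s2 / n2
    v1 = np.maximum((q1 / n1 - m1**2) * n1 / (n1 - 1), 1e-300)
    v2 = np.maximum((q2 / n2 - m2**2) * n2 / (n2 - 1), 1e-300)
    return (m1 - m2) / np.sqrt(v1 / n1 + v2 / n2)


def cluster_permutation(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    contrast: str,
    montage: Montage | None,
    n_perm: int = 5000,
    threshold_p: float = 0.05,
    min_neighbors: int = 3,
    seed: int = 0,
) -> list[ClusterResult]:
    """Neighbour-based cluster-permutation test of a map contrast.

    ``maps_a``/``maps_b`` are (participants, channels, bins) stacks.  A
    ``"paired"`` contrast t-tests the within-participant difference and
    permutes by sign flips; an ``"independent"`` contrast Welch-tests two
    groups and permutes group labels.  Supra-threshold points (point-wise
    p < ``threshold_p``) are clustered over sensor adjacency plus
    neighbouring bins; clusters spanning fewer than ``min_neighbors``
    distinct channels are discarded; the corrected p-value of a cluster is
    the fraction of permutations whose maximum cluster |mass| reaches the
    observed |mass|.  Positive and negative clusters are formed separately.
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 yields unstable p-values")
    if maps_a.ndim != 3 or maps_b.ndim != 3 or maps_a.shape[1:] != maps_b.shape[1:]:
        raise ValueError("map stacks must share (channels, bins) dimensions")
    if maps_a.shape[0] == 0 or maps_b.shape[0] == 0:
        raise ValueError("empty group")
    if min(maps_a.shape[0], maps_b.shape[0]) < 2:
        raise ValueError("need at least two maps per group")
    n_sub, n_ch, n_bins = maps_a.shape
    rng = np.random.default_rng(seed)
    # bin-major point layout: index = bin * n_ch + channel
    flat_a = maps_a.transpose(0, 2, 1).reshape(maps_a.shape[0], -1)
    flat_b = maps_b.transpose(0, 2, 1).reshape(maps_b.shape[0], -1)
    if contrast == "paired":
        if maps_a.shape[0] != maps_b.shape[0]:
            raise ValueError("paired contrast needs matched stacks")
        tmaps = _perm_tmaps_paired(flat_a - flat_b, n_perm, rng)
        dof = maps_a.shape[0] - 1
    elif contrast == "independent":
        tmaps = _perm_tmaps_independent(flat_a, flat_b, n_perm, rng)
        dof = maps_a.shape[0] + maps_b.shape[0] - 2
    else:
        raise ValueError("contrast must be 'paired' or 'independent'")
    t_crit = stats.t.ppf(1.0 - threshold_p / 2.0, dof)

    ch_adj = montage.adjacency if montage is not None else None
    adjacency = _grid_adjacency(n_ch, n_bins, ch_adj)
    # points are laid out bin-major: index = bin * n_ch + channel
    observed = _clusters_from_tmap(
        tmaps[0], t_crit, adjacency, n_ch, min_neighbors
    )
    max_mass = np.zeros(n_perm)
    for i in range(n_perm):
        cl = _clusters_from_tmap(
            tmaps[i + 1], t_crit, adjacency, n_ch, min_neighbors
        )
        if cl:
            max_mass[i] = max(abs(m) for _, _, m, _ in cl)
    results = []
    for members, chans, mass, polarity in observed:
        p = float((1 + np.sum(max_mass >= abs(mass))) / (n_perm + 1))
        points = [(int(m % n_ch), int(m // n_ch)) for m in members]
        results.append(
            ClusterResult(points=points, channels=chans, mass=mass,
                          p_value=p, polarity=polarity)
        )
    results.sort(key=lambda c: c.p_value)
    return results
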