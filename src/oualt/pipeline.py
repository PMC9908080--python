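"""End-to-end orchestration on a synthetic cohort.

``run_full`` chains: trial-design generation -> cohort ground truth and
simulated behaviour -> per-participant model fitting and predictive
accuracy -> response-locked EA regression and build-up rates ->
stimulus-locked GLM maps with context and group cluster contrasts ->
frontal-parietal dWPLI group contrast.  Every stage consumes only
serialized outputs of earlier stages, all seeds derive from the run seed,
and the JSON report plus a checksummed manifest make a run reproducible
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn
from . import eeg as eeg_mod
from . import synth
from .behavior import predictive_accuracy
from .design import generate_schedule
from .fitting import FitConfig, fit_de

__all__ = ["RunConfig", "run_full"]


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "oualt_run"
    n_participants: int = 8
    montage_channels: int = 128
    snr: float = 1.5
    noise_rms: float = 1.0
    n_trace_sims: int = 500
    fit: dict = field(default_factory=lambda: dict(n_pop=30, n_iter=60, n_sim=500))
    n_perm: int = 1000
    run_fitting: bool = True
    run_eeg: bool = True
    run_connectivity: bool = True
    conn_fmin: float = 30.0
    conn_fmax: float = 100.0
    conn_max_trials: int = 120
    gamma_amplitude: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls(**(yaml.safe_load(f) or {}))


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not serializable: {type(o)}")


def run_full(config: RunConfig) -> dict:
    """Run every stage and return the report dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: int(s.generate_state(1)[0] % (2**31 - 1)) for name, s in zip(
        ["design", "cohort", "fit", "traces", "eeg", "glm", "gamma", "perm"],
        ss.spawn(8),
    )}
    cfg_dict = asdict(config)
    cfg_dict.pop("out_dir")  # keep reports byte-identical across locations
    report: dict = {"config": cfg_dict, "seeds": seeds, "stages": {}}

    def fail(stage, exc):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---- design -----------------------------------------------------
    design = generate_schedule(seed=seeds["design"])
    design.to_csv(out / "design.csv")
    report["stages"]["design"] = dict(n_trials=len(design))

    # ---- cohort behaviour -------------------------------------------
    truth, behavior = synth.generate_cohort(
        config.n_participants, design, seed=seeds["cohort"]
    )
    pd.concat(behavior.values()).to_csv(out / "behavior.csv", index=False)
    _dump(
        [
            dict(participant_id=p["participant_id"], group=p["group"],
                 params={c: asdict(v) for c, v in p["params"].items()},
                 planted={k: v for k, v in p["planted"].items()})
            for p in truth.participants
        ],
        out / "truth.json",
    )
    report["stages"]["cohort"] = dict(
        n=len(truth), groups=truth.groups(),
        mean_omega_dis=float(np.mean([p["params"]["DIS"].omega for p in truth.participants])),
        mean_omega_adv=float(np.mean([p["params"]["ADV"].omega for p in truth.participants])),
    )

    montage = synth.generate_montage(config.montage_channels)
    rng = np.random.default_rng(seeds["eeg"])

    # ---- fitting + predictive accuracy ------------------------------
    params_for_traces = {}
    if config.run_fitting:
        fits = {}
        accs = {}
        for i, p in enumerate(truth.participants):
            pid = p["participant_id"]
            cfg = FitConfig(**config.fit, seed=(seeds["fit"] + i) % (2**31 - 1))
            try:
                fit = fit_de(behavior[pid], design, "OU_full", cfg)
            except Exception as exc:  # pragma: no cover - stage isolation
                fail("fitting", exc)
            fits[pid] = fit
            accs[pid] = predictive_accuracy(
                fit.params, behavior[pid], design, n_sim=500,
                seed=(seeds["fit"] + 1000 + i) % (2**31 - 1),
            )
            params_for_traces[pid] = fit.params
        _dump({pid: f.to_dict() for pid, f in fits.items()}, out / "fits.json")
        _dump(accs, out / "accuracy.json")
        report["stages"]["fitting"] = {
            ctx: dict(
                balanced_accuracy=float(np.mean(
                    [accs[pid][ctx]["balanced_accuracy"] for pid in accs])),
                sensitivity=float(np.mean(
                    [accs[pid][ctx]["sensitivity"] for pid in accs])),
                specificity=float(np.mean(
                    [accs[pid][ctx]["specificity"] for pid in accs])),
            )
            for ctx in ("DIS", "ADV")
        }
    else:
        params_for_traces = {
            p["participant_id"]: p["params"] for p in truth.participants
        }

    ea_summary = {}
    glm_summary = {}
    conn_summary = {}
    if config.run_eeg:
        # ---- response-locked EA regression --------------------------
        selected = {c: {} for c in ("DIS", "ADV")}
        buildups = {c: {} for c in ("DIS", "ADV")}
        r2s = {c: {} for c in ("DIS", "ADV")}
        response_eeg = {}
        for i, p in enumerate(truth.participants):
            pid = p["participant_id"]
            traces, ttimes = synth.ea_traces_for_design(
                params_for_traces[pid], design, seed=(seeds["traces"] + i) % (2**31 - 1),
                n=config.n_trace_sims,
            )
            eeg = synth.generate_response_locked_eeg(
                behavior[pid], traces, ttimes, montage,
                seed=(seeds["eeg"] + i) % (2**31 - 1), snr=config.snr,
                trial_table=design.table,
            )
            for ctx in ("DIS", "ADV"):
                idx = np.where((design.table["context"] == ctx).to_numpy())[0]
                res = eeg_mod.crossval_ea_regression(
                    eeg.pick_trials(idx), traces[idx], montage
                )
                selected[ctx][pid] = res.selected_channels.tolist()
                r2s[ctx][pid] = res.heldout_r2
                if res.selected_channels.size:
                    buildups[ctx][pid] = eeg_mod.buildup_rate(
                        eeg.pick_trials(idx), res.selected_channels
                    )
            response_eeg[pid] = eeg
        ea_summary = dict(
            selected_channels=selected,
            heldout_r2={c: {k: float(v) for k, v in r2s[c].items()} for c in r2s},
            buildup_rate={c: {k: float(v) for k, v in buildups[c].items()} for c in buildups},
        )
        _dump(ea_summary, out / "ea_regression.json")
        report["stages"]["ea_regression"] = {
            ctx: dict(
                median_heldout_r2=float(np.nanmedian(list(r2s[ctx].values()))),
                n_selected=float(np.mean([len(v) for v in selected[ctx].values()])),
            )
            for ctx in ("DIS", "ADV")
        }

        # ---- stimulus-locked GLM + cluster contrasts ----------------
        beta1 = {"DIS": [], "ADV": []}
        beta2 = {"DIS": [], "ADV": []}
        for i, p in enumerate(truth.participants):
            pid = p["participant_id"]
            eeg = synth.generate_stimulus_locked_eeg(
                design, p["planted"], montage,
                seed=(seeds["glm"] + i) % (2**31 - 1), noise_rms=config.noise_rms,
            )
            for ctx in ("DIS", "ADV"):
                bm = eeg_mod.glm_beta_maps(eeg, context=ctx, participant_id=pid)
                beta1[ctx].append(bm.beta(1))
                beta2[ctx].append(bm.beta(2))
        b1_dis = np.array(beta1["DIS"])
        b1_adv = np.array(beta1["ADV"])
        ctx_clusters = eeg_mod.cluster_permutation(
            b1_dis, b1_adv, "paired", montage, n_perm=config.n_perm,
            seed=seeds["perm"],
        )
        groups = np.array(truth.groups())
        b2_dis = np.array(beta2["DIS"])
        grp_clusters = eeg_mod.cluster_permutation(
            b2_dis[groups == "MA"], b2_dis[groups == "LA"], "independent",
            montage, n_perm=config.n_perm, seed=seeds["perm"] + 1,
        )
        glm_summary = dict(
            context_clusters=[_cluster_dict(c) for c in ctx_clusters],
            group_clusters=[_cluster_dict(c) for c in grp_clusters],
        )
        _dump(glm_summary, out / "glm_clusters.json")
        report["stages"]["glm"] = dict(
            n_significant_context=sum(c.p_value < 0.05 for c in ctx_clusters),
            n_significant_group=sum(c.p_value < 0.05 for c in grp_clusters),
        )

        # ---- connectivity -------------------------------------------
        if config.run_connectivity:
            maps = []
            for i, p in enumerate(truth.participants):
                pid = p["participant_id"]
                eeg = response_eeg[pid]
                dis_idx = np.where(
                    (eeg.trial_table["context"] == "DIS").to_numpy()
                )[0][: config.conn_max_trials]
                sub = eeg.pick_trials(dis_idx)
                sub = synth.generate_gamma_coupling(
                    sub, p["group"], montage,
                    seed=(seeds["gamma"] + i) % (2**31 - 1),
                    amplitude=config.gamma_amplitude,
                )
                spec = conn.multitaper_crossspectra(
                    sub, montage.sets["centrofrontal_cluster"],
                    montage.sets["parietal_cluster"],
                    fmin=config.conn_fmin, fmax=config.conn_fmax,
                )
                maps.append(conn.dwpli(spec))
            clusters = conn.group_dwpli_contrast(
                maps, truth.groups(), n_perm=config.n_perm,
                seed=seeds["perm"] + 2,
                fmin=config.conn_fmin, fmax=min(config.conn_fmax, 90.0),
            )
            conn_summary = dict(clusters=[_cluster_dict(c) for c in clusters])
            _dump(conn_summary, out / "dwpli_clusters.json")
            report["stages"]["connectivity"] = dict(
                n_significant=sum(c.p_value < 0.05 for c in clusters),
            )

    _dump(report, out / "report.json")
    manifest = {
        f.name: hashlib.sha256(f.read_bytes()).hexdigest()
        for f in sorted(out.glob("*"))
        if f.is_file() and f.name != "manifest.json"
    }
    _dump({"seed": config.seed, "files": manifest}, out / "manifest.json")
    return report


def _cluster_dict(c) -> dict:
    return dict(points=[list(p) for p in c.points],
                channels=c.channels.tolist(), mass=c.mass,
                p_value=c.p_value, polarity=c.polarity)
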