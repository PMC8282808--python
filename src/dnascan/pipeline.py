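"""End-to-end driver: simulate → track → diffuse → classify → metrics.

Each stage reads and writes plain files in a run directory (CSV tables,
JSON summaries), so any stage can be re-run or replaced by user data; a
manifest records the resolved configuration, its hash, the seed, and the
row counts entering and leaving each stage.  A fixed seed makes the whole
run, including the manifest hash, reproducible bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as cls
from . import diffusion as diff
from . import metrics as met
from . import simulate as sim
from . import tracking as trk

STAGE_FILES = {
    "simulate": ["localizations.csv", "ground_truth.csv"],
    "track": ["trajectories.csv", "filter_report.json"],
    "diffuse": ["d_inst.csv", "distribution.json"],
    "classify": ["labels.csv", "classification.json"],
    "metrics": ["event_metrics.csv", "metrics.json"],
}

DEFAULT_CONFIG: dict = {
    "label": "simulated",
    "rng_seed": 0,
    "simulation": {**sim.SimulationConfig().to_dict(), "axis_anchor": [0.0, 0.0]},
    "tracking": {
        "max_jump": 500.0,
        "min_frames": 5,
        "min_path": 600.0,
        "linearity_min": 0.9,
        "n_use": 10,
        "min_x_span": 300.0,
        "max_y_dev": 200.0,
        "y_criterion": "max",
    },
    "diffusion": {"window_width": 5, "floor": 1e-4},
    "classification": {
        "d_ideal": 0.49,
        "barrier_threshold": 2.0,
        "recognition_threshold": 5.0,
        "sliding_range": 1.5,
        "hmm_restarts": 10,
        "noise_correction": True,
    },
    "metrics": {"bp_scale": "auto", "counting": "entries", "denominator": "spanned"},
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _merge_strict(defaults: dict, override: dict, path: str = "") -> dict:
    out = {}
    for key, dval in defaults.items():
        if isinstance(dval, dict) and key in override:
            oval = override[key]
            if not isinstance(oval, dict):
                raise ValueError(f"config key {path + key!r} must be a mapping")
            out[key] = _merge_strict(dval, oval, path + key + ".")
        else:
            out[key] = override.get(key, dval)
    unknown = set(override) - set(defaults)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(path + k for k in unknown)}")
    return out


def resolve_config(config: dict | None = None, seed: int | None = None) -> dict:
    """Merge a partial config onto the defaults (strict: unknown keys reject)."""
    cfg = _merge_strict(DEFAULT_CONFIG, config or {})
    if seed is not None:
        cfg["rng_seed"] = int(seed)
    anchor = cfg["simulation"]["axis_anchor"]  # keep YAML-serializable
    cfg["simulation"]["axis_anchor"] = [float(anchor[0]), float(anchor[1])]
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=float).encode()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def _aligned_from_frame(df: pd.DataFrame) -> list[trk.AlignedTrajectory]:
    out = []
    for mid, grp in df.groupby("molecule_id", sort=True):
        grp = grp.sort_values("frame")
        out.append(
            trk.AlignedTrajectory(
                molecule_id=int(mid),
                frames=grp["frame"].to_numpy(dtype=int),
                positions=grp[["x_nm", "y_nm"]].to_numpy(),
                x_axis=grp["x_axis_nm"].to_numpy(),
                y_perp=grp["y_perp_nm"].to_numpy(),
            )
        )
    return out


def run_tracking_stage(table: pd.DataFrame, tcfg: dict) -> tuple[list[trk.AlignedTrajectory], dict]:
    """Link, filter and align a localization table; returns (events, report)."""
    trajs = trk.link_localizations(table, max_jump=tcfg["max_jump"])
    long_enough = trk.prefilter_short(trajs, min_frames=tcfg["min_frames"])
    linear = trk.detect_linear_scanners(
        long_enough, min_path=tcfg["min_path"], linearity_min=tcfg["linearity_min"]
    )
    report = {
        "n_localizations": int(len(table)),
        "n_linked": len(trajs),
        "n_after_prefilter": len(long_enough),
        "n_linear_scanners": len(linear),
    }
    if not linear:
        report.update({"axis": None, "n_final": 0})
        return [], report
    axis = trk.estimate_dna_axis(linear, n_use=tcfg["n_use"])
    aligned = trk.align_to_axis(long_enough, axis)
    final = trk.final_scan_filter(
        aligned,
        min_frames=tcfg["min_frames"],
        min_x_span=tcfg["min_x_span"],
        max_y_dev=tcfg["max_y_dev"],
        y_criterion=tcfg["y_criterion"],
    )
    report.update(
        {
            "axis": {
                "angle_rad": axis.angle,
                "anchor_nm": list(axis.anchor),
                "rms_residual_nm": axis.rms_residual,
            },
            "n_final": len(final),
        }
    )
    return final, report


def run_pipeline(config: dict | None = None, out_dir=None, seed: int | None = None) -> dict:
    """Execute the full pipeline into ``out_dir`` and return the manifest."""
    if out_dir is None:
        raise ValueError("out_dir is required")
    cfg = resolve_config(config, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    ss = np.random.SeedSequence(cfg["rng_seed"])
    sim_seed, hmm_seed = (int(c.generate_state(1, np.uint32)[0]) for c in ss.spawn(2))
    manifest: dict = {"label": cfg["label"], "config": cfg, "config_hash": chash, "stages": {}}

    # -- simulate ----------------------------------------------------------
    try:
        sim_cfg = sim.SimulationConfig(**{**cfg["simulation"], "rng_seed": sim_seed})
        table, truth = sim.simulate_field(sim_cfg)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate", str(e)) from e
    table.to_csv(out / "localizations.csv", index=False)
    truth.to_csv(out / "ground_truth.csv", index=False)
    manifest["stages"]["simulate"] = {"n_localizations": int(len(table))}

    # -- track -------------------------------------------------------------
    try:
        final, report = run_tracking_stage(table, cfg["tracking"])
    except Exception as e:  # noqa: BLE001
        raise PipelineError("track", str(e)) from e
    trk.trajectories_to_frame(final).to_csv(out / "trajectories.csv", index=False)
    _write_json(out / "filter_report.json", report)
    manifest["stages"]["track"] = report

    dt = sim_cfg.frame_interval
    w = cfg["diffusion"]["window_width"]

    # -- diffuse -----------------------------------------------------------
    try:
        traces = [diff.instantaneous_diffusion(t, window_width=w, frame_interval=dt) for t in final]
        traces = [t for t in traces if len(t) > 0]
        rows = [
            {"molecule_id": t.molecule_id, "frame": int(f), "d_inst_um2_s": d}
            for t in traces
            for f, d in zip(t.frames, t.d_inst)
        ]
        d_table = pd.DataFrame(rows, columns=["molecule_id", "frame", "d_inst_um2_s"])
        if traces:
            dist = diff.pooled_distribution(traces, floor=cfg["diffusion"]["floor"])
            dist_summary = {
                "n_samples": int(len(dist.samples)),
                "mean_d": dist.mean,
                "median_d": dist.median,
                "mode_count": dist.mode_count,
                "mode_locations_log10": dist.mode_locations_log10.tolist(),
                "n_floored": dist.n_floored,
                "bandwidth_decades": dist.bandwidth,
            }
        else:
            dist_summary = {"n_samples": 0}
    except Exception as e:  # noqa: BLE001
        raise PipelineError("diffuse", str(e)) from e
    d_table.to_csv(out / "d_inst.csv", index=False)
    _write_json(out / "distribution.json", dist_summary)
    manifest["stages"]["diffuse"] = {"n_traces": len(traces), "n_values": int(len(d_table))}

    # -- classify ----------------------------------------------------------
    try:
        ccfg = cfg["classification"]
        kin = cls.KineticBarrierClassifier(
            d_ideal=ccfg["d_ideal"],
            barrier_threshold=ccfg["barrier_threshold"],
            recognition_threshold=ccfg["recognition_threshold"],
        ).fit()
        label_rows = []
        summary: dict = {"hmm": None, "kinetic": None, "confusion": None}
        if traces:
            segs = {t.molecule_id: kin.segment(t) for t in traces}
            disp = {t.molecule_id: np.diff(t.x_axis) for t in final}
            order = [t.molecule_id for t in traces]
            hmm = cls.TwoStateDiffusionHMM(
                frame_interval=dt,
                loc_sigma_nm=sim_cfg.loc_sigma,
                n_restarts=ccfg["hmm_restarts"],
                noise_correction=ccfg["noise_correction"],
                random_state=hmm_seed,
            ).fit([disp[m] for m in order])
            states = hmm.predict([disp[m] for m in order])
            probs = hmm.predict_proba([disp[m] for m in order])
            kin_all, hmm_all = [], []
            for m, st, pr in zip(order, states, probs):
                seg = segs[m]
                n = len(seg.frames)
                for i in range(n):
                    label_rows.append(
                        {
                            "molecule_id": m,
                            "frame": int(seg.frames[i]),
                            "d_inst_um2_s": seg.d_inst[i],
                            "e_a_kBT": seg.e_a[i],
                            "kinetic_label": seg.labels[i],
                            "hmm_state": st[i],
                            "posterior_slow": pr[i, 0],
                        }
                    )
                kin_all.append(seg.labels[:n])
                hmm_all.append(st[:n])
            conf = cls.confusion_matrix(np.concatenate(kin_all), np.concatenate(hmm_all))
            pooled = np.concatenate([t.d_inst for t in traces])
            labels = kin.predict(pooled)
            okmask = pooled > 0
            occ_high = float(np.mean(labels[okmask] == cls.HIGH_BARRIER)) if okmask.any() else float("nan")
            gap = hmm.delta_e_a_
            summary = {
                "hmm": hmm.result(),
                "kinetic": {
                    "d_ideal": ccfg["d_ideal"],
                    "occupancy_high_barrier": occ_high,
                    "occupancy_low_barrier": 1.0 - occ_high,
                },
                "confusion": {
                    "tp": conf.tp,
                    "fn": conf.fn,
                    "fp": conf.fp,
                    "tn": conf.tn,
                    "accuracy": conf.accuracy,
                    "sensitivity": conf.sensitivity,
                    "specificity": conf.specificity,
                },
                "barrier_excess_percent": cls.barrier_excess(gap, ccfg["sliding_range"]),
            }
    except Exception as e:  # noqa: BLE001
        raise PipelineError("classify", str(e)) from e
    pd.DataFrame(
        label_rows,
        columns=[
            "molecule_id",
            "frame",
            "d_inst_um2_s",
            "e_a_kBT",
            "kinetic_label",
            "hmm_state",
            "posterior_slow",
        ],
    ).to_csv(out / "labels.csv", index=False)
    _write_json(out / "classification.json", summary)
    manifest["stages"]["classify"] = {"n_labeled_frames": len(label_rows)}

    # -- metrics -----------------------------------------------------------
    try:
        mcfg = cfg["metrics"]
        bp_scale = sim_cfg.bp_scale_nm if mcfg["bp_scale"] == "auto" else float(mcfg["bp_scale"])
        tracks = [to_track for to_track in (met.to_basepair_track(t, bp_scale=bp_scale, frame_interval=dt) for t in final)]
        ev = met.event_metrics(tracks, counting=mcfg["counting"], denominator=mcfg["denominator"]) if tracks else pd.DataFrame(
            columns=["molecule_id", "redundancy", "efficiency_bp_ms", "duration_ms", "span_bp"]
        )
        if tracks:
            agg = met.efficiency_redundancy_table(
                {cfg["label"]: tracks}, counting=mcfg["counting"], denominator=mcfg["denominator"]
            ).iloc[0]
            agg_summary = {k: (None if pd.isna(v) else v) for k, v in agg.drop("dataset").items()}
        else:
            agg_summary = {"n_events": 0}
    except Exception as e:  # noqa: BLE001
        raise PipelineError("metrics", str(e)) from e
    ev.to_csv(out / "event_metrics.csv", index=False)
    _write_json(out / "metrics.json", agg_summary)
    manifest["stages"]["metrics"] = {"n_events": int(len(ev))}

    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True, default=float).encode()
    ).hexdigest()
    _write_json(out / "manifest.json", manifest)
    return manifest


def report(run_dir, out_dir=None) -> list[Path]:
    """Render summary figures from a completed run directory.

    Produces the diffusion-rate distribution overlay (data vs matched
    single-mode random walk), the kinetic-vs-HMM occupancy and mean-D
    comparison, and the efficiency–redundancy scatter.  Raises listing the
    missing stage files if the run is incomplete.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run = Path(run_dir)
    out = Path(out_dir) if out_dir else run
    out.mkdir(parents=True, exist_ok=True)
    missing = [f for files in STAGE_FILES.values() for f in files if not (run / f).exists()]
    if not (run / "manifest.json").exists():
        missing.append("manifest.json")
    if missing:
        raise FileNotFoundError(f"incomplete run, missing: {missing}")

    manifest = json.loads((run / "manifest.json").read_text())
    cfg = manifest["config"]
    d_table = pd.read_csv(run / "d_inst.csv")
    labels = pd.read_csv(run / "labels.csv")
    ev = pd.read_csv(run / "event_metrics.csv")
    classification = json.loads((run / "classification.json").read_text())
    paths = []

    # 1: diffusion-rate distribution, data vs matched single-mode walk
    fig, ax = plt.subplots(figsize=(5, 4))
    if len(d_table):
        d = np.clip(d_table["d_inst_um2_s"].to_numpy(), cfg["diffusion"]["floor"], None)
        sim_cfg = sim.SimulationConfig(**{**cfg["simulation"], "rng_seed": 12345})
        refs = sim.simulate_single_mode_reference(
            float(np.mean(d)), 50, max(len(d) // 50 + 6, 10), sim_cfg
        )
        ref_traces = [
            diff.instantaneous_diffusion(
                t, cfg["diffusion"]["window_width"], cfg["simulation"]["frame_interval"]
            )
            for t in refs
        ]
        dist = diff.pooled_distribution(
            [diff.DiffusionTrace(0, np.arange(len(d)), d, 5, cfg["simulation"]["frame_interval"])],
            floor=cfg["diffusion"]["floor"],
        )
        ref = diff.pooled_distribution(ref_traces, floor=cfg["diffusion"]["floor"])
        ax.plot(dist.log10_grid, dist.density, color="crimson", label="data")
        ax.plot(ref.log10_grid, ref.density, color="black", label="matched random walk")
        ax.legend(frameon=False)
    ax.set_xlabel(r"$\log_{10} D$ ($\mu$m$^2$/s)")
    ax.set_ylabel("density")
    fig.tight_layout()
    p = out / "fig_diffusion_distribution.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    paths.append(p)

    # 2: kinetic vs HMM mode comparison
    fig, ax = plt.subplots(figsize=(5, 4))
    if classification.get("hmm"):
        hmm = classification["hmm"]
        kin = classification["kinetic"]
        ax.bar(
            [0, 1, 3, 4],
            [
                hmm["occupancy_slow"],
                kin["occupancy_high_barrier"],
                hmm["occupancy_fast"],
                kin["occupancy_low_barrier"],
            ],
            color=["goldenrod", "khaki", "steelblue", "lightblue"],
        )
        ax.set_xticks([0, 1, 3, 4])
        ax.set_xticklabels(["HMM\nslow", "kinetic\nhigh $E_a$", "HMM\nfast", "kinetic\nlow $E_a$"])
        ax.set_ylabel("occupancy")
        ax.set_title(
            f"$\\Delta E_a$ = {hmm['delta_e_a_kBT']:.2f} $k_BT$, "
            f"agreement {classification['confusion']['accuracy'] * 100:.0f}%"
        )
    fig.tight_layout()
    p = out / "fig_mode_comparison.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    paths.append(p)

    # 3: efficiency vs redundancy
    fig, ax = plt.subplots(figsize=(5, 4))
    if len(ev):
        ax.scatter(ev["efficiency_bp_ms"], ev["redundancy"], s=18, alpha=0.6)
        ax.scatter(
            [ev["efficiency_bp_ms"].mean()], [ev["redundancy"].mean()],
            marker="x", s=80, color="crimson", label="dataset mean",
        )
        ax.legend(frameon=False)
    ax.set_xlabel("efficiency (bp/ms)")
    ax.set_ylabel("redundancy (visits/bp)")
    fig.tight_layout()
    p = out / "fig_efficiency_redundancy.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    paths.append(p)
    return paths
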