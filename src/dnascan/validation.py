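"""Parameter-recovery experiments on synthetic scanning data.

Self-contained studies that exercise the full stack — simulator, sliding
window diffusion, kinetic and HMM classification — and quantify how well
known ground-truth parameters are recovered.  These are the package's
calibration experiments: they are what passing tests demonstrate about the
method, at desk scale, in place of the unshared experimental trajectories.
"""

from __future__ import annotations

import numpy as np

from .classify import (
    ConfusionSummary,
    KineticBarrierClassifier,
    TwoStateDiffusionHMM,
    confusion_matrix,
)
from .diffusion import instantaneous_diffusion
from .simulate import SimulationConfig, simulate_switching_dataset
from .tracking import AlignedTrajectory


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1, np.uint32)[0]) % (2**31) for c in ss.spawn(n)]


def hmm_mode_gap_recovery(
    d_slow: float = 0.043,
    ratio: float = 4.3,
    n_seeds: int = 20,
    n_frames_total: int = 50_000,
    traj_len: int = 501,
    p_switch: float = 0.05,
    loc_sigma: float = 18.7,
    frame_interval: float = 1.0 / 30.0,
    n_restarts: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Fitted mode energy gaps ΔE_a over seeded replicates.

    Each replicate simulates two-state scanning trajectories (symmetric
    per-frame switching probability ``p_switch``) totalling at least
    ``n_frames_total`` displacements, fits the noise-corrected two-state
    displacement HMM, and records ln(D_fast/D_slow).  The median over
    replicates estimates the recovered gap.
    """
    n_traj = int(np.ceil(n_frames_total / (traj_len - 1)))
    gaps = []
    for s in _child_seeds(seed, n_seeds):
        cfg = SimulationConfig(
            d_slow=d_slow,
            d_fast=d_slow * ratio,
            p_slow_to_fast=p_switch,
            p_fast_to_slow=p_switch,
            loc_sigma=loc_sigma,
            frame_interval=frame_interval,
            n_frames=traj_len,
            mean_event_frames=None,
        )
        _, disps = simulate_switching_dataset(cfg, n_traj, traj_len, np.random.default_rng(s))
        model = TwoStateDiffusionHMM(
            frame_interval=frame_interval,
            loc_sigma_nm=loc_sigma,
            n_restarts=n_restarts,
            random_state=s,
        ).fit(disps)
        gaps.append(model.delta_e_a_)
    return np.asarray(gaps)


def kinetic_hmm_concordance(
    d_slow: float = 0.02,
    d_fast: float = 0.2,
    d_ideal: float = 0.49,
    p_switch: float = 0.02,
    n_trajectories: int = 40,
    traj_len: int = 501,
    window_width: int = 5,
    loc_sigma: float = 18.7,
    frame_interval: float = 1.0 / 30.0,
    n_restarts: int = 3,
    seed: int = 0,
) -> ConfusionSummary:
    """Frame-level agreement between the kinetic and HMM segmentations.

    Simulates two-state scanning whose mode diffusivities straddle the
    2 k_B·T activation-barrier boundary at the given ``d_ideal``, segments
    every trajectory with both classifiers independently, and returns their
    confusion matrix (HMM slow vs kinetic high-barrier).
    """
    cfg = SimulationConfig(
        d_slow=d_slow,
        d_fast=d_fast,
        p_slow_to_fast=p_switch,
        p_fast_to_slow=p_switch,
        loc_sigma=loc_sigma,
        frame_interval=frame_interval,
        n_frames=traj_len,
        mean_event_frames=None,
    )
    events, disps = simulate_switching_dataset(
        cfg, n_trajectories, traj_len, np.random.default_rng(seed)
    )
    clf = KineticBarrierClassifier(d_ideal=d_ideal)
    hmm = TwoStateDiffusionHMM(
        frame_interval=frame_interval,
        loc_sigma_nm=loc_sigma,
        n_restarts=n_restarts,
        random_state=seed,
    ).fit(disps)
    states = hmm.predict(disps)
    kin_all, hmm_all = [], []
    for i, (ev, st) in enumerate(zip(events, states)):
        x = ev.trajectory.positions[:, 0]
        at = AlignedTrajectory(
            i, ev.trajectory.frames, ev.trajectory.positions,
            x_axis=x, y_perp=ev.trajectory.positions[:, 1],
        )
        trace = instantaneous_diffusion(at, window_width, frame_interval)
        labels = clf.predict(trace.d_inst)
        kin_all.append(labels)
        hmm_all.append(st[: len(labels)])
    return confusion_matrix(np.concatenate(kin_all), np.concatenate(hmm_all))


def diffusion_estimator_calibration(
    d_true: float = 0.1,
    loc_sigma: float = 18.7,
    n_trajectories: int = 20,
    traj_len: int = 5001,
    window_width: int = 5,
    frame_interval: float = 1.0 / 30.0,
    seed: int = 0,
) -> dict:
    """Bias check of the sliding-window estimator on a single-mode walk.

    Returns the pooled mean of the instantaneous diffusion rate, the
    noise-corrected estimate (subtracting the σ²/Δt floor), and the analytic
    standard error of the mean implied by the chi-square sampling law.
    """
    cfg = SimulationConfig(loc_sigma=loc_sigma, frame_interval=frame_interval)
    from .simulate import simulate_single_mode_reference

    refs = simulate_single_mode_reference(
        d_true, n_trajectories, traj_len, cfg, np.random.default_rng(seed)
    )
    traces = [instantaneous_diffusion(t, window_width, frame_interval) for t in refs]
    pooled = np.concatenate([t.d_inst for t in traces])
    n_inc = sum(len(t.x_axis) - 1 for t in refs)
    noise_d = loc_sigma**2 / frame_interval * 1e-6
    se = (d_true + noise_d) * np.sqrt(2.0 / n_inc)
    return {
        "d_true": d_true,
        "pooled_mean": float(pooled.mean()),
        "noise_corrected_mean": float(pooled.mean() - noise_d),
        "analytic_se": float(se),
        "n_increments": int(n_inc),
    }
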