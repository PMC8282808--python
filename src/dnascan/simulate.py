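"""Forward simulator of the single-molecule DNA-scanning field of view.

Generates ThunderSTORM-style localization tables with ground truth attached.
The simulated field contains three molecule classes:

* **scanners** — DNA-bound molecules diffusing in 1D along an elongated,
  tilted DNA axis, switching between a slow and a fast diffusive mode via a
  memoryless two-state Markov chain;
* **free** — short-lived 2D Brownian molecules drifting through the
  illumination field;
* **stuck** — stationary molecules adsorbed to the coverslip, whose apparent
  motion is pure localization noise.

All positions are in nanometres, diffusion coefficients in µm²/s, times in
seconds.  Localization noise is isotropic Gaussian per image axis, applied
after embedding the 1D scanning coordinate on the tilted DNA axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from .tracking import AlignedTrajectory, Trajectory

NM2_PER_UM2 = 1e6  # 1 µm² = 1e6 nm²
BP_NM = 0.34  # rise per base pair of B-DNA, nm

SLOW, FAST = 0, 1
MODE_NAMES = {SLOW: "slow", FAST: "fast"}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated field of view.

    Defaults mirror the experimental conditions of the study this package
    models: 30 Hz imaging of a 12 kbp DNA stretched to ~95% of its contour
    length, 18.7 nm localization precision, and a slow scanning mode of
    0.043 µm²/s with a 4.3-fold faster second mode.
    """

    frame_interval: float = 1.0 / 30.0  # s
    n_frames: int = 600
    dna_length_bp: int = 12000
    elongation_fraction: float = 0.95
    axis_angle: float = 0.0  # rad, orientation of the DNA in the image plane
    axis_anchor: tuple[float, float] = (0.0, 0.0)  # nm
    d_slow: float = 0.043  # µm²/s
    d_fast: float = 0.185  # µm²/s (= 4.3 × d_slow)
    p_slow_to_fast: float = 0.05  # per-frame
    p_fast_to_slow: float = 0.05  # per-frame
    loc_sigma: float = 18.7  # nm, per-axis localization precision
    n_scanners: int = 8
    n_free: int = 15
    n_stuck: int = 5
    mean_event_frames: int | None = 150  # geometric dwell; None = whole movie
    free_dwell_frames: float = 3.0  # mean dwell of free molecules, frames
    stuck_dwell_frames: float = 300.0  # mean visible lifetime of stuck molecules
    # (photobleaching-limited; a surface-stuck dye does not survive a whole movie)
    d_free: float = 20.0  # µm²/s, 2D Brownian (free ~30 kDa protein in buffer)
    mean_photons: float = 500.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.frame_interval > 0 and math.isfinite(self.frame_interval)):
            raise ValueError("frame_interval must be finite and > 0")
        if not (0 < self.d_slow <= self.d_fast):
            raise ValueError("require 0 < d_slow <= d_fast")
        for name in ("p_slow_to_fast", "p_fast_to_slow"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0.0 < self.elongation_fraction <= 1.0):
            raise ValueError("elongation_fraction must be in (0, 1]")
        if self.loc_sigma < 0 or not math.isfinite(self.loc_sigma):
            raise ValueError("loc_sigma must be finite and >= 0")
        if self.n_frames < 1 or self.dna_length_bp < 1:
            raise ValueError("n_frames and dna_length_bp must be >= 1")
        for name in ("d_free", "mean_photons", "free_dwell_frames", "stuck_dwell_frames"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be finite and > 0")
        if min(self.n_scanners, self.n_free, self.n_stuck) < 0:
            raise ValueError("molecule counts must be >= 0")

    @property
    def contour_length_nm(self) -> float:
        return self.dna_length_bp * BP_NM

    @property
    def extension_nm(self) -> float:
        """End-to-end extension of the anchored DNA."""
        return self.contour_length_nm * self.elongation_fraction

    @property
    def bp_scale_nm(self) -> float:
        """Nanometres per base pair along the *stretched* DNA."""
        return BP_NM * self.elongation_fraction

    def replace(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def step_sigma_nm(d_um2_s: float, frame_interval: float) -> float:
    """Std dev (nm) of a 1D Brownian displacement over one frame."""
    return math.sqrt(2.0 * d_um2_s * NM2_PER_UM2 * frame_interval)


def _mode_chain(n: int, p_sf: float, p_fs: float, rng: np.random.Generator) -> np.ndarray:
    """Sample a two-state {slow, fast} Markov chain of length n.

    The initial state is drawn from the stationary distribution; if both
    transition probabilities are zero the chain starts (and stays) slow.
    """
    modes = np.empty(n, dtype=np.int8)
    total = p_sf + p_fs
    if total > 0:
        pi_slow = p_fs / total
    else:
        pi_slow = 1.0
    u = rng.random(n)
    modes[0] = SLOW if u[0] < pi_slow else FAST
    for t in range(1, n):
        if modes[t - 1] == SLOW:
            modes[t] = FAST if u[t] < p_sf else SLOW
        else:
            modes[t] = SLOW if u[t] < p_fs else FAST
    return modes


def _reflect(x: np.ndarray, length: float) -> np.ndarray:
    """Fold a free path into [0, length] (reflecting boundaries)."""
    period = 2.0 * length
    y = np.mod(x, period)
    return np.where(y > length, period - y, y)


@dataclass
class ScannerEvent:
    """One binding-and-scanning event with ground truth.

    ``trajectory`` holds the *reported* (noisy, image-plane) coordinates;
    ``x_true_nm`` the noise-free position along the DNA; ``modes`` the
    per-frame diffusive state (0 = slow, 1 = fast).
    """

    trajectory: Trajectory
    x_true_nm: np.ndarray
    modes: np.ndarray


def simulate_scanner(
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    molecule_id: int = 0,
    start_frame: int | None = None,
    n_frames: int | None = None,
) -> ScannerEvent:
    """Simulate one DNA-bound scanner.

    The 1D position along the DNA performs Brownian steps
    ``x_{t+1} = x_t + N(0, 2 D(mode_t) Δt)`` with reflection at the DNA ends;
    the diffusive mode follows a two-state Markov chain.  The reported
    coordinates embed the path on the tilted DNA axis and add isotropic
    Gaussian localization noise per image axis.

    Event length is ``n_frames`` if given, else drawn geometrically with mean
    ``config.mean_event_frames`` (capped by the movie length); events shorter
    than two frames are extended to two so a trajectory always exists.
    """
    if n_frames is None:
        if config.mean_event_frames is None:
            n_frames = config.n_frames
        else:
            n_frames = int(rng.geometric(1.0 / config.mean_event_frames))
        n_frames = min(n_frames, config.n_frames)
    n_frames = max(int(n_frames), 2)
    if start_frame is None:
        start_frame = int(rng.integers(0, config.n_frames - n_frames + 1))

    length = config.extension_nm
    modes = _mode_chain(n_frames, config.p_slow_to_fast, config.p_fast_to_slow, rng)
    sigmas = np.where(
        modes[:-1] == SLOW,
        step_sigma_nm(config.d_slow, config.frame_interval),
        step_sigma_nm(config.d_fast, config.frame_interval),
    )
    steps = rng.normal(0.0, 1.0, size=n_frames - 1) * sigmas
    x0 = rng.uniform(0.0, length)
    x_true = _reflect(x0 + np.concatenate(([0.0], np.cumsum(steps))), length)

    ax, ay = config.axis_anchor
    ca, sa = math.cos(config.axis_angle), math.sin(config.axis_angle)
    noise = rng.normal(0.0, config.loc_sigma, size=(n_frames, 2))
    positions = np.column_stack(
        [ax + x_true * ca + noise[:, 0], ay + x_true * sa + noise[:, 1]]
    )
    frames = np.arange(start_frame, start_frame + n_frames)
    traj = Trajectory(molecule_id=molecule_id, frames=frames, positions=positions)
    return ScannerEvent(trajectory=traj, x_true_nm=x_true, modes=modes)


def simulate_single_mode_reference(
    d_mean: float,
    n_trajectories: int,
    lengths,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[AlignedTrajectory]:
    """Simulate the matched single-mode ("monomodal") random-walk reference.

    Pure 1D random walks at constant diffusion coefficient ``d_mean``, with
    the same frame interval and localization noise as the dataset they are
    compared against.  No protein–DNA interaction of any kind is modelled, so
    the instantaneous-diffusion distribution of these walks is the
    null distribution for a homogeneous binding-energy landscape.

    ``lengths`` may be a single integer or a sequence to resample from
    (matching an empirical trajectory-length distribution).
    """
    if d_mean < 0:
        raise ValueError("d_mean must be >= 0")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    lengths = np.atleast_1d(np.asarray(lengths, dtype=int))
    if np.any(lengths < 2):
        raise ValueError("trajectory lengths must be >= 2")
    sigma_step = step_sigma_nm(d_mean, config.frame_interval)
    out: list[AlignedTrajectory] = []
    for i in range(n_trajectories):
        n = int(lengths[i % len(lengths)] if len(lengths) < n_trajectories else rng.choice(lengths))
        steps = rng.normal(0.0, sigma_step, size=n - 1) if sigma_step > 0 else np.zeros(n - 1)
        x_true = np.concatenate(([0.0], np.cumsum(steps)))
        noise = rng.normal(0.0, config.loc_sigma, size=(n, 2))
        x = x_true + noise[:, 0]
        y = noise[:, 1]
        out.append(
            AlignedTrajectory(
                molecule_id=i,
                frames=np.arange(n),
                positions=np.column_stack([x, y]),
                x_axis=x,
                y_perp=y,
            )
        )
    return out


def _fov_bounds(config: SimulationConfig, margin: float = 1000.0):
    ax, ay = config.axis_anchor
    ex = config.extension_nm * math.cos(config.axis_angle)
    ey = config.extension_nm * math.sin(config.axis_angle)
    x0, x1 = sorted((ax, ax + ex))
    y0, y1 = sorted((ay, ay + ey))
    return (x0 - margin, x1 + margin), (y0 - margin, y1 + margin)


def simulate_field(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full field of view and emit a localization table.

    Returns ``(localizations, ground_truth)``.  The localization table has
    ThunderSTORM-style columns ``frame, x_nm, y_nm, sigma_nm, photons`` and is
    sorted by frame.  ``ground_truth`` has one row per localization row, in
    identical order (``loc_index`` gives the row position), with columns
    ``loc_index, frame, molecule_id, class, mode, true_position_along_dna``.
    """
    rng = np.random.default_rng(config.rng_seed)
    (fx0, fx1), (fy0, fy1) = _fov_bounds(config)

    rows = []  # (frame, x, y, molecule_id, class, mode, true_x)
    mol_id = 0

    for _ in range(config.n_scanners):
        ev = simulate_scanner(config, rng, molecule_id=mol_id)
        tr = ev.trajectory
        for k in range(len(tr.frames)):
            rows.append(
                (
                    int(tr.frames[k]),
                    tr.positions[k, 0],
                    tr.positions[k, 1],
                    mol_id,
                    "scanner",
                    MODE_NAMES[int(ev.modes[k])],
                    float(ev.x_true_nm[k]),
                )
            )
        mol_id += 1

    sigma_free = step_sigma_nm(config.d_free, config.frame_interval)
    for _ in range(config.n_free):
        n = max(int(rng.geometric(1.0 / config.free_dwell_frames)), 1)
        n = min(n, config.n_frames)
        f0 = int(rng.integers(0, config.n_frames - n + 1))
        pos0 = np.array([rng.uniform(fx0, fx1), rng.uniform(fy0, fy1)])
        steps = rng.normal(0.0, sigma_free, size=(n - 1, 2))
        path = pos0 + np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
        noisy = path + rng.normal(0.0, config.loc_sigma, size=(n, 2))
        for k in range(n):
            rows.append((f0 + k, noisy[k, 0], noisy[k, 1], mol_id, "free", "n/a", np.nan))
        mol_id += 1

    for _ in range(config.n_stuck):
        n = min(int(rng.geometric(1.0 / config.stuck_dwell_frames)), config.n_frames)
        f0 = int(rng.integers(0, config.n_frames - n + 1))
        pos0 = np.array([rng.uniform(fx0, fx1), rng.uniform(fy0, fy1)])
        noisy = pos0 + rng.normal(0.0, config.loc_sigma, size=(n, 2))
        for k in range(n):
            rows.append((f0 + k, noisy[k, 0], noisy[k, 1], mol_id, "stuck", "n/a", np.nan))
        mol_id += 1

    df = pd.DataFrame(
        rows,
        columns=["frame", "x_nm", "y_nm", "molecule_id", "class", "mode", "true_position_along_dna"],
    )
    # stable sort keeps within-frame order deterministic
    df = df.sort_values("frame", kind="stable").reset_index(drop=True)
    n_rows = len(df)
    photons = rng.poisson(config.mean_photons, size=n_rows).astype(float)

    localizations = pd.DataFrame(
        {
            "frame": df["frame"].to_numpy(dtype=int),
            "x_nm": df["x_nm"].to_numpy(),
            "y_nm": df["y_nm"].to_numpy(),
            "sigma_nm": np.full(n_rows, config.loc_sigma),
            "photons": photons,
        }
    )
    ground_truth = pd.DataFrame(
        {
            "loc_index": np.arange(n_rows),
            "frame": df["frame"].to_numpy(dtype=int),
            "molecule_id": df["molecule_id"].to_numpy(dtype=int),
            "class": df["class"].to_numpy(),
            "mode": df["mode"].to_numpy(),
            "true_position_along_dna": df["true_position_along_dna"].to_numpy(),
        }
    )
    return localizations, ground_truth


def simulate_switching_dataset(
    config: SimulationConfig,
    n_trajectories: int,
    traj_len: int,
    rng: np.random.Generator | None = None,
) -> tuple[list[ScannerEvent], list[np.ndarray]]:
    """Simulate fixed-length two-state scanning events plus their 1D
    displacement series (nm, noisy), the input shape expected by the
    displacement HMM.  Convenience wrapper used for parameter-recovery
    studies."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    cfg = config.replace(n_frames=max(config.n_frames, traj_len))
    events, disps = [], []
    for i in range(n_trajectories):
        ev = simulate_scanner(cfg, rng, molecule_id=i, n_frames=traj_len, start_frame=0)
        # noisy 1D coordinate along the (known) axis
        ca, sa = math.cos(cfg.axis_angle), math.sin(cfg.axis_angle)
        rel = ev.trajectory.positions - np.asarray(cfg.axis_anchor)
        x = rel[:, 0] * ca + rel[:, 1] * sa
        events.append(ev)
        disps.append(np.diff(x))
    return events, disps
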