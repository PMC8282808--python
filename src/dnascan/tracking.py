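"""Trajectory reconstruction and geometric selection of DNA scanners.

Links per-frame localizations into trajectories (greedy nearest-neighbour,
no gap closing), selects DNA-scanning molecules with the geometric filters
used in the experiment (>= 5 consecutive frames; >= 600 nm travelled along a
linear path; after rotation, >= 300 nm span along the DNA and never more
than 200 nm away from it), estimates the unlabelled DNA's axis from the
longest scanning traces by a total-least-squares line fit, and rotates all
trajectories onto that axis.

Units: nanometres and 0-based frame indices throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class Trajectory:
    """A linked, gap-free per-molecule time series of 2D positions (nm)."""

    molecule_id: int
    frames: np.ndarray  # strictly increasing consecutive integers
    positions: np.ndarray  # (N, 2) nm
    source_table_id: str | None = None
    source_rows: np.ndarray | None = None  # row indices into the source table

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.frames) < 2:
            raise ValueError("trajectory must have length >= 2")
        if self.positions.shape != (len(self.frames), 2):
            raise ValueError("positions must be (n_frames, 2)")
        if np.any(np.diff(self.frames) != 1):
            raise ValueError("frames must be consecutive integers (no gaps)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class AlignedTrajectory(Trajectory):
    """Trajectory with coordinates along (x_axis) and across (y_perp) the DNA."""

    x_axis: np.ndarray = field(default=None)  # nm along the DNA
    y_perp: np.ndarray = field(default=None)  # nm perpendicular distance

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.x_axis is None or self.y_perp is None:
            raise ValueError("x_axis and y_perp are required")
        self.x_axis = np.asarray(self.x_axis, dtype=float)
        self.y_perp = np.asarray(self.y_perp, dtype=float)
        if self.x_axis.shape != self.frames.shape or self.y_perp.shape != self.frames.shape:
            raise ValueError("x_axis/y_perp must match frames in length")


@dataclass(frozen=True)
class DnaAxis:
    """Total-least-squares estimate of the DNA's line in the image plane."""

    angle: float  # rad, normalized to (-pi/2, pi/2]
    anchor: tuple[float, float]  # nm, a point on the line
    rms_residual: float  # nm, rms perpendicular scatter of the fit points

    def __post_init__(self) -> None:
        if not (-math.pi / 2 < self.angle <= math.pi / 2):
            raise ValueError("angle must be normalized to (-pi/2, pi/2]")


def _normalize_angle(angle: float) -> float:
    a = math.remainder(angle, math.pi)
    if a <= -math.pi / 2:
        a += math.pi
    elif a > math.pi / 2:
        a -= math.pi
    return a


def link_localizations(table: pd.DataFrame, max_jump: float) -> list[Trajectory]:
    """Greedy nearest-neighbour frame-to-frame linking.

    A localization joins the nearest live trajectory (one whose last frame is
    the immediately preceding frame) within ``max_jump`` nm; candidate pairs
    are assigned in order of increasing distance, ties broken by lower
    trajectory id.  Unmatched localizations start new trajectories, and a
    trajectory that misses a frame is closed — no gap closing.  Trajectories
    shorter than two frames are discarded.
    """
    if len(table) == 0:
        return []
    frames = table["frame"].to_numpy(dtype=int)
    if np.any(np.diff(frames) < 0):
        raise ValueError("localization table must be sorted by frame")
    xy = table[["x_nm", "y_nm"]].to_numpy(dtype=float)
    row_idx = np.arange(len(table))

    # live[tid] = (last_frame, last_xy); built[tid] = list of row indices
    live: dict[int, tuple[int, np.ndarray]] = {}
    built: dict[int, list[int]] = {}
    next_id = 0

    for f in np.unique(frames):
        sel = np.nonzero(frames == f)[0]
        live = {tid: v for tid, v in live.items() if v[0] == f - 1}
        pairs = []
        for tid, (_, pos) in live.items():
            d = np.hypot(xy[sel, 0] - pos[0], xy[sel, 1] - pos[1])
            for j, dist in zip(sel, d):
                if dist <= max_jump:
                    pairs.append((dist, tid, int(j)))
        pairs.sort(key=lambda p: (p[0], p[1]))
        taken_t: set[int] = set()
        taken_l: set[int] = set()
        for dist, tid, j in pairs:
            if tid in taken_t or j in taken_l:
                continue
            taken_t.add(tid)
            taken_l.add(j)
            built[tid].append(j)
            live[tid] = (int(f), xy[j])
        for j in sel:
            if int(j) not in taken_l:
                built[next_id] = [int(j)]
                live[next_id] = (int(f), xy[j])
                next_id += 1

    out = []
    for tid in sorted(built):
        idx = np.asarray(built[tid])
        if len(idx) < 2:
            continue
        out.append(
            Trajectory(
                molecule_id=tid,
                frames=frames[idx],
                positions=xy[idx],
                source_rows=row_idx[idx],
            )
        )
    return out


def prefilter_short(trajs: list[Trajectory], min_frames: int = 5) -> list[Trajectory]:
    """Drop short-lived signals (free molecules blinking through focus)."""
    return [t for t in trajs if len(t) >= min_frames]


def _principal_axis(positions: np.ndarray):
    """Return (unit vector, extent along it, linearity) of a point cloud.

    Linearity is the fraction of total positional variance carried by the
    principal axis; 1.0 for a perfect line, 0.5 for an isotropic cloud.
    """
    centered = positions - positions.mean(axis=0)
    cov = centered.T @ centered / len(positions)
    evals, evecs = np.linalg.eigh(cov)
    total = evals.sum()
    if total <= 0:
        return None
    v = evecs[:, -1]
    proj = centered @ v
    return v, float(np.ptp(proj)), float(evals[-1] / total)


def detect_linear_scanners(
    trajs: list[Trajectory],
    min_path: float = 600.0,
    linearity_min: float = 0.9,
    return_status: bool = False,
):
    """Select molecules moving a long way along a straight path.

    Keeps trajectories whose extent along their principal axis is at least
    ``min_path`` nm and whose linearity (principal-axis variance fraction) is
    at least ``linearity_min``.  Degenerate clouds (zero variance) are
    rejected with status ``"degenerate"``.
    """
    kept, status = [], []
    for t in trajs:
        pa = _principal_axis(t.positions)
        if pa is None:
            status.append("degenerate")
            continue
        _, extent, linearity = pa
        if extent >= min_path and linearity >= linearity_min:
            kept.append(t)
            status.append("kept")
        else:
            status.append("rejected")
    if return_status:
        return kept, status
    return kept


def estimate_dna_axis(scanners: list[Trajectory], n_use: int = 10) -> DnaAxis:
    """Fit the DNA's line from the pooled points of the longest scanning traces.

    Orthogonal (total-least-squares) line fit on the localizations of the
    ``n_use`` qualifying trajectories with the largest principal-axis extent.
    """
    if not scanners:
        raise ValueError("no qualifying trajectories to estimate the DNA axis")
    if len(scanners) < n_use:
        warnings.warn(
            f"only {len(scanners)} trajectories available for axis estimation "
            f"(requested {n_use})",
            stacklevel=2,
        )
    extents = []
    for t in scanners:
        pa = _principal_axis(t.positions)
        extents.append(pa[1] if pa is not None else 0.0)
    order = np.argsort(extents)[::-1][:n_use]
    pts = np.vstack([scanners[i].positions for i in order])
    center = pts.mean(axis=0)
    centered = pts - center
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, -1]
    angle = _normalize_angle(math.atan2(v[1], v[0]))
    rms = math.sqrt(max(evals[0], 0.0))
    return DnaAxis(angle=angle, anchor=(float(center[0]), float(center[1])), rms_residual=rms)


def align_to_axis(trajs: list[Trajectory], axis: DnaAxis) -> list[AlignedTrajectory]:
    """Rigidly rotate trajectories so the DNA lies along the x axis.

    The rotation is about ``axis.anchor``; ``x_axis`` is the coordinate along
    the DNA and ``y_perp`` the signed perpendicular distance to it.  The
    transform is an isometry of the image plane.
    """
    ca, sa = math.cos(axis.angle), math.sin(axis.angle)
    anchor = np.asarray(axis.anchor)
    out = []
    for t in trajs:
        rel = t.positions - anchor
        x_axis = rel[:, 0] * ca + rel[:, 1] * sa
        y_perp = -rel[:, 0] * sa + rel[:, 1] * ca
        out.append(
            AlignedTrajectory(
                molecule_id=t.molecule_id,
                frames=t.frames.copy(),
                positions=t.positions.copy(),
                source_table_id=t.source_table_id,
                source_rows=None if t.source_rows is None else t.source_rows.copy(),
                x_axis=x_axis,
                y_perp=y_perp,
            )
        )
    return out


def final_scan_filter(
    aligned: list[AlignedTrajectory],
    min_frames: int = 5,
    min_x_span: float = 300.0,
    max_y_dev: float = 200.0,
    y_criterion: str = "max",
) -> list[AlignedTrajectory]:
    """Final conjunctive selection of DNA-scanning signals.

    Keeps trajectories lasting at least ``min_frames`` consecutive frames,
    spanning at least ``min_x_span`` nm along the DNA, and staying within
    ``max_y_dev`` nm of the DNA in the perpendicular direction.  The distance
    criterion is the per-frame maximum (``y_criterion="max"``, strictest
    reading) or the mean (``"mean"``).
    """
    if y_criterion not in ("max", "mean"):
        raise ValueError("y_criterion must be 'max' or 'mean'")
    out = []
    for t in aligned:
        if len(t) < min_frames:
            continue
        if np.ptp(t.x_axis) < min_x_span:
            continue
        ydev = np.abs(t.y_perp)
        stat = ydev.max() if y_criterion == "max" else ydev.mean()
        if stat > max_y_dev:
            continue
        out.append(t)
    return out


@dataclass(frozen=True)
class PrecisionEstimate:
    sigma_nm: float  # per-axis localization precision
    d_error_um2_s: float  # apparent diffusion of stationary molecules


def estimate_precision(
    stuck_trajectories: list[Trajectory],
    frame_interval: float,
    window_width: int = 5,
    min_frames: int = 10,
) -> PrecisionEstimate:
    """Localization precision and its diffusion-rate error from stuck molecules.

    ``sigma_nm`` is the per-axis standard deviation of positions of
    stationary molecules (each centred on its own mean); ``d_error_um2_s``
    is the mean apparent instantaneous diffusion rate of the same molecules,
    i.e. the empirical noise floor of the diffusion estimator.
    """
    from .diffusion import instantaneous_diffusion

    usable = [t for t in stuck_trajectories if len(t) >= min_frames]
    if not usable:
        raise ValueError(f"need at least one stationary trajectory of >= {min_frames} frames")
    devs = []
    d_vals = []
    for t in usable:
        centered = t.positions - t.positions.mean(axis=0)
        devs.append(centered.ravel())
        if len(t) > window_width:
            x = t.positions[:, 0]
            aligned = AlignedTrajectory(
                molecule_id=t.molecule_id,
                frames=t.frames,
                positions=t.positions,
                x_axis=x,
                y_perp=t.positions[:, 1] - t.positions[:, 1].mean(),
            )
            trace = instantaneous_diffusion(aligned, window_width=window_width, frame_interval=frame_interval)
            d_vals.append(trace.d_inst)
    sigma = float(np.concatenate(devs).std(ddof=1))
    d_error = float(np.concatenate(d_vals).mean()) if d_vals else float("nan")
    return PrecisionEstimate(sigma_nm=sigma, d_error_um2_s=d_error)


def trajectories_to_frame(trajs: list[Trajectory]) -> pd.DataFrame:
    """Flatten trajectories to a tidy table (one row per localization)."""
    recs = []
    for t in trajs:
        aligned = isinstance(t, AlignedTrajectory)
        for k in range(len(t)):
            rec = {
                "molecule_id": t.molecule_id,
                "frame": int(t.frames[k]),
                "x_nm": t.positions[k, 0],
                "y_nm": t.positions[k, 1],
            }
            if aligned:
                rec["x_axis_nm"] = t.x_axis[k]
                rec["y_perp_nm"] = t.y_perp[k]
            recs.append(rec)
    return pd.DataFrame(recs)
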