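"""Redundancy and efficiency of DNA scanning per binding event.

A filtered trajectory is one binding-and-scanning event.  Its coordinate
along the DNA is discretized into base-pair bins (0.34 nm per bp times the
elongation fraction of the stretched molecule).  Two per-event quantities
summarise how the event covers the DNA:

* **redundancy** — the average number of times each base pair is visited
  during the event.  A "visit" to bin b is an entry event: the first frame
  counts as a visit to its bin, every change of bin credits the landing bin,
  and bins skipped within one frame step are each credited one pass-through
  visit.  A single monotone pass therefore has redundancy exactly 1.
* **efficiency** — base pairs covered per millisecond: the number of
  distinct bins visited divided by the event duration.

High-redundancy, low-efficiency scanners re-check bases in confined
regions; low-redundancy, high-efficiency scanners (e.g. hoppers) cover DNA
fast at the expense of repeated inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tracking import AlignedTrajectory

DEFAULT_BP_SCALE_NM = 0.34 * 0.95  # nm per bp on ~95%-stretched DNA


@dataclass
class BasePairTrack:
    """Per-frame base-pair bin indices of one binding event."""

    molecule_id: int
    bp: np.ndarray  # integer bin per frame, >= 0
    bp_scale: float  # nm per bp
    duration_ms: float

    def __post_init__(self) -> None:
        self.bp = np.asarray(self.bp, dtype=int)
        if len(self.bp) == 0:
            raise ValueError("track is empty")
        if np.any(self.bp < 0):
            raise ValueError("bp indices must be >= 0")


def to_basepair_track(
    aligned: AlignedTrajectory,
    bp_scale: float = DEFAULT_BP_SCALE_NM,
    frame_interval: float = 1.0 / 30.0,
) -> BasePairTrack:
    """Discretize an aligned trajectory into base-pair bins.

    Bin = floor((x − min x) / bp_scale); duration = (n_frames − 1)·Δt in ms.
    """
    if bp_scale <= 0:
        raise ValueError("bp_scale must be > 0")
    x = aligned.x_axis
    bp = np.floor((x - x.min()) / bp_scale).astype(int)
    duration_ms = (len(x) - 1) * frame_interval * 1e3
    return BasePairTrack(
        molecule_id=aligned.molecule_id, bp=bp, bp_scale=bp_scale, duration_ms=duration_ms
    )


def visit_counts(track: BasePairTrack, counting: str = "entries") -> np.ndarray:
    """Number of visits per bin over the spanned range [min bp, max bp].

    ``counting="entries"``: the first frame is one visit to its bin; each
    change of bin credits one visit to the landing bin and one to every bin
    passed through in that step.  ``counting="frames"``: every frame counts
    one visit to its bin (no pass-through crediting).
    """
    bp = track.bp
    lo, hi = int(bp.min()), int(bp.max())
    counts = np.zeros(hi - lo + 1, dtype=int)
    if counting == "frames":
        np.add.at(counts, bp - lo, 1)
    elif counting == "entries":
        counts[bp[0] - lo] += 1
        for prev, cur in zip(bp[:-1], bp[1:]):
            if cur == prev:
                continue
            step = 1 if cur > prev else -1
            for b in range(prev + step, cur + step, step):
                counts[b - lo] += 1
    else:
        raise ValueError("counting must be 'entries' or 'frames'")
    return counts


def redundancy(
    track: BasePairTrack,
    counting: str = "entries",
    denominator: str = "spanned",
) -> float:
    """Average number of visits per base pair within one event.

    ``denominator="spanned"`` divides total visits by all bins between the
    minimum and maximum visited bin (hopping gaps lower redundancy);
    ``"visited"`` divides by bins actually visited.
    """
    counts = visit_counts(track, counting=counting)
    if denominator == "spanned":
        denom = len(counts)
    elif denominator == "visited":
        denom = int(np.count_nonzero(counts))
    else:
        raise ValueError("denominator must be 'spanned' or 'visited'")
    return float(counts.sum() / denom)


def efficiency(track: BasePairTrack, counting: str = "entries") -> float:
    """Base pairs covered per millisecond within one event."""
    if track.duration_ms <= 0:
        raise ValueError("event duration must be > 0")
    counts = visit_counts(track, counting=counting)
    return float(np.count_nonzero(counts) / track.duration_ms)


def event_metrics(
    tracks: list[BasePairTrack],
    counting: str = "entries",
    denominator: str = "spanned",
) -> pd.DataFrame:
    """Per-event metrics table: redundancy, efficiency, duration, span."""
    recs = []
    for t in tracks:
        recs.append(
            {
                "molecule_id": t.molecule_id,
                "redundancy": redundancy(t, counting=counting, denominator=denominator),
                "efficiency_bp_ms": efficiency(t, counting=counting),
                "duration_ms": t.duration_ms,
                "span_bp": int(t.bp.max() - t.bp.min() + 1),
            }
        )
    return pd.DataFrame(recs)


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")


def efficiency_redundancy_table(datasets: dict[str, list[BasePairTrack]], **kwargs) -> pd.DataFrame:
    """Aggregate per-dataset means ± SEM for the efficiency–redundancy plane.

    One row per dataset (protein / condition); SEM is reported as NaN for
    single-event datasets.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    rows = []
    for label, tracks in datasets.items():
        if not tracks:
            raise ValueError(f"dataset {label!r} has no events")
        ev = event_metrics(tracks, **kwargs)
        rows.append(
            {
                "dataset": label,
                "n_events": len(ev),
                "efficiency_mean": ev["efficiency_bp_ms"].mean(),
                "efficiency_sem": _sem(ev["efficiency_bp_ms"].to_numpy()),
                "redundancy_mean": ev["redundancy"].mean(),
                "redundancy_sem": _sem(ev["redundancy"].to_numpy()),
            }
        )
    return pd.DataFrame(rows)


def salt_series_summary(frames: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-mode mean diffusion rate vs salt concentration, with trend tests.

    ``frames`` is a tidy table with columns ``salt_mM``, ``mode`` (per-frame
    mode label, e.g. low/high barrier) and ``d_inst`` (µm²/s).  Returns a
    summary table of mean ± SEM per (salt, mode) and, per mode, a Spearman
    monotone-trend statistic of the per-salt means against salt.  With a
    single salt level the trend is undefined and flagged.
    """
    required = {"salt_mM", "mode", "d_inst"}
    if not required.issubset(frames.columns):
        raise ValueError(f"frames must have columns {sorted(required)}")
    rows = []
    for (salt, mode), grp in frames.groupby(["salt_mM", "mode"], sort=True):
        d = grp["d_inst"].to_numpy()
        rows.append(
            {
                "salt_mM": salt,
                "mode": mode,
                "mean_d": float(d.mean()),
                "sem_d": _sem(d),
                "n_frames": len(d),
            }
        )
    summary = pd.DataFrame(rows)
    trends: dict = {}
    for mode, grp in frames.groupby("mode"):
        if grp["salt_mM"].nunique() < 2:
            trends[mode] = {"rho": float("nan"), "p_value": float("nan"), "flag": "single_salt_level"}
            continue
        # frame-level correlation: uses all observations, not just per-salt means
        rho, p = stats.spearmanr(grp["salt_mM"], grp["d_inst"])
        trends[mode] = {"rho": float(rho), "p_value": float(p), "flag": None}
    return summary, trends
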