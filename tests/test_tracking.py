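"""Linking, geometric filtering, axis estimation and alignment."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from dnascan import (
    AlignedTrajectory,
    DnaAxis,
    SimulationConfig,
    Trajectory,
    align_to_axis,
    detect_linear_scanners,
    estimate_dna_axis,
    estimate_precision,
    final_scan_filter,
    link_localizations,
    prefilter_short,
    simulate_field,
)
from dnascan.pipeline import DEFAULT_CONFIG, run_tracking_stage


def table_from(points):
    """points: list of (frame, x, y)"""
    df = pd.DataFrame(points, columns=["frame", "x_nm", "y_nm"])
    return df.sort_values("frame", kind="stable").reset_index(drop=True)


def brute_force_link(table, max_jump):
    """Independent oracle: repeated argmin over an explicit distance matrix."""
    tracks = []  # each: {"rows": [...], "last_frame": f, "pos": (x, y)}
    for f in sorted(table["frame"].unique()):
        sub = table[table["frame"] == f]
        live = [t for t in tracks if t["last_frame"] == f - 1]
        loc_idx = list(sub.index)
        dist = {}
        for ti, t in enumerate(live):
            for j in loc_idx:
                d = math.hypot(sub.loc[j, "x_nm"] - t["pos"][0], sub.loc[j, "y_nm"] - t["pos"][1])
                if d <= max_jump:
                    dist[(ti, j)] = d
        used_t, used_j = set(), set()
        while dist:
            (ti, j), d = min(dist.items(), key=lambda kv: (kv[1], tracks.index(live[kv[0][0]])))
            live[ti]["rows"].append(j)
            live[ti]["last_frame"] = f
            live[ti]["pos"] = (sub.loc[j, "x_nm"], sub.loc[j, "y_nm"])
            used_t.add(ti)
            used_j.add(j)
            dist = {k: v for k, v in dist.items() if k[0] not in used_t and k[1] not in used_j}
        for j in loc_idx:
            if j not in used_j:
                tracks.append({"rows": [j], "last_frame": f, "pos": (sub.loc[j, "x_nm"], sub.loc[j, "y_nm"])})
    return [t["rows"] for t in tracks if len(t["rows"]) >= 2]


class TestLinking:
    def test_single_molecule_one_trajectory(self):
        pts = [(f, 10.0 * f, 5.0) for f in range(10)]
        trajs = link_localizations(table_from(pts), max_jump=500)
        assert len(trajs) == 1
        assert len(trajs[0]) == 10

    def test_two_distant_molecules_no_switches(self):
        pts = [(f, 1.0 * f, 0.0) for f in range(8)]
        pts += [(f, 1.0 * f, 5000.0) for f in range(8)]
        trajs = link_localizations(table_from(pts), max_jump=500)
        assert len(trajs) == 2
        ys = sorted(t.positions[0, 1] for t in trajs)
        assert ys == [0.0, 5000.0]
        for t in trajs:
            assert np.ptp(t.positions[:, 1]) == 0.0

    def test_gap_terminates_trajectory(self):
        pts = [(0, 0, 0), (1, 10, 0), (3, 20, 0), (4, 30, 0)]
        trajs = link_localizations(table_from(pts), max_jump=500)
        assert sorted(len(t) for t in trajs) == [2, 2]

    def test_empty_table(self):
        assert link_localizations(pd.DataFrame(columns=["frame", "x_nm", "y_nm"]), 500) == []

    def test_matches_brute_force_oracle(self, rng):
        # small random instance, <= 100 rows
        pts = []
        for m in range(5):
            x, y = rng.uniform(0, 2000, 2)
            f0 = int(rng.integers(0, 5))
            for f in range(f0, f0 + int(rng.integers(2, 15))):
                x += rng.normal(0, 60)
                y += rng.normal(0, 60)
                pts.append((f, x, y))
        table = table_from(pts[:100])
        got = sorted(tuple(t.source_rows) for t in link_localizations(table, max_jump=300))
        expected = sorted(tuple(r) for r in brute_force_link(table, 300))
        assert got == expected

    def test_groundtruth_identity_on_default_field(self, default_field):
        _, loc, gt = default_field
        trajs = link_localizations(loc, max_jump=500)
        ids = gt["molecule_id"].to_numpy()
        total = correct = 0
        for t in trajs:
            tid = ids[t.source_rows]
            majority = np.bincount(tid).argmax()
            correct += int(np.sum(tid == majority))
            total += len(tid)
        assert correct / total >= 0.99


class TestPrefilter:
    def test_five_frame_threshold(self):
        t4 = Trajectory(0, np.arange(4), np.zeros((4, 2)) + np.arange(4)[:, None])
        t5 = Trajectory(1, np.arange(5), np.zeros((5, 2)) + np.arange(5)[:, None])
        assert prefilter_short([t4, t5]) == [t5]

    def test_empty(self):
        assert prefilter_short([]) == []

    def test_count_matches_enumeration(self, rng):
        trajs = []
        for i in range(30):
            n = int(rng.integers(2, 12))
            trajs.append(Trajectory(i, np.arange(n), rng.normal(size=(n, 2))))
        kept = prefilter_short(trajs, min_frames=5)
        assert len(kept) == len(trajs) - sum(1 for t in trajs if len(t) < 5)


class TestLinearScanners:
    def test_collinear_700nm_kept(self):
        x = np.linspace(0, 700, 20)
        t = Trajectory(0, np.arange(20), np.column_stack([x, 0.5 * x]))
        assert detect_linear_scanners([t]) == [t]

    def test_isotropic_cloud_rejected(self, rng):
        # ~700 nm extent but linearity ~0.5
        pts = rng.uniform(-350, 350, size=(60, 2))
        t = Trajectory(0, np.arange(60), pts)
        kept, status = detect_linear_scanners([t], return_status=True)
        assert kept == []
        assert status == ["rejected"]

    def test_degenerate_cloud_distinct_status(self):
        t = Trajectory(0, np.arange(5), np.ones((5, 2)))
        kept, status = detect_linear_scanners([t], return_status=True)
        assert kept == []
        assert status == ["degenerate"]

    def test_simulated_scanner_retention_and_free_rejection(self):
        cfg = SimulationConfig(
            rng_seed=11, n_scanners=30, n_free=400, n_stuck=0,
            n_frames=1500, mean_event_frames=200,
        )
        loc, gt = simulate_field(cfg)
        trajs = link_localizations(loc, max_jump=500)
        classes = gt["class"].to_numpy()
        true_x = gt["true_position_along_dna"].to_numpy()
        kept_ids = {t.molecule_id for t in detect_linear_scanners(trajs)}
        n_scan = n_scan_kept = n_free = n_free_kept = 0
        for t in trajs:
            cls_rows = classes[t.source_rows]
            vals, counts = np.unique(cls_rows, return_counts=True)
            majority = vals[counts.argmax()]
            if majority == "scanner":
                if np.ptp(true_x[t.source_rows]) >= 700:
                    n_scan += 1
                    n_scan_kept += t.molecule_id in kept_ids
            elif majority == "free":
                n_free += 1
                n_free_kept += t.molecule_id in kept_ids
        assert n_scan >= 10 and n_free >= 50
        assert n_scan_kept / n_scan >= 0.95
        assert (n_free - n_free_kept) / n_free >= 0.95


class TestAxis:
    def test_exact_horizontal_line(self):
        x = np.linspace(0, 800, 30)
        t = Trajectory(0, np.arange(30), np.column_stack([x, np.zeros(30)]))
        axis = estimate_dna_axis([t], n_use=1)
        assert axis.angle == pytest.approx(0.0, abs=1e-9)
        assert axis.rms_residual == pytest.approx(0.0, abs=1e-9)

    def test_exact_30_degree_line(self):
        a = math.radians(30)
        s = np.linspace(0, 900, 40)
        pts = np.column_stack([s * math.cos(a) + 100, s * math.sin(a) - 50])
        t = Trajectory(0, np.arange(40), pts)
        axis = estimate_dna_axis([t], n_use=1)
        assert axis.angle == pytest.approx(a, abs=1e-6)

    def test_no_trajectories_errors(self):
        with pytest.raises(ValueError):
            estimate_dna_axis([])

    def test_monte_carlo_recovery_tilted_dna(self):
        cfg = SimulationConfig(
            rng_seed=5, n_scanners=12, n_free=0, n_stuck=0,
            axis_angle=0.3, mean_event_frames=None, n_frames=400,
        )
        loc, _ = simulate_field(cfg)
        trajs = prefilter_short(link_localizations(loc, max_jump=500))
        linear = detect_linear_scanners(trajs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            axis = estimate_dna_axis(linear)
        assert axis.angle == pytest.approx(0.3, abs=0.01)

    def test_warns_below_n_use(self):
        x = np.linspace(0, 800, 30)
        t = Trajectory(0, np.arange(30), np.column_stack([x, np.zeros(30)]))
        with pytest.warns(UserWarning):
            estimate_dna_axis([t], n_use=10)


class TestAlign:
    @staticmethod
    def _traj(rng, n=20):
        return Trajectory(0, np.arange(n), rng.normal(0, 300, size=(n, 2)))

    def test_zero_angle_is_translation_only(self, rng):
        t = self._traj(rng)
        axis = DnaAxis(angle=0.0, anchor=(10.0, -5.0), rms_residual=0.0)
        (a,) = align_to_axis([t], axis)
        assert np.allclose(a.x_axis, t.positions[:, 0] - 10.0)
        assert np.allclose(a.y_perp, t.positions[:, 1] + 5.0)

    def test_isometry(self, rng):
        t = self._traj(rng)
        axis = DnaAxis(angle=0.7, anchor=(100.0, 200.0), rms_residual=0.0)
        (a,) = align_to_axis([t], axis)
        rot = np.column_stack([a.x_axis, a.y_perp])
        d0 = np.linalg.norm(t.positions[:, None] - t.positions[None, :], axis=-1)
        d1 = np.linalg.norm(rot[:, None] - rot[None, :], axis=-1)
        assert np.allclose(d0, d1, rtol=1e-9, atol=1e-9)

    def test_inverse_rotation_roundtrip(self, rng):
        t = self._traj(rng)
        anchor = (55.0, -30.0)
        fwd = DnaAxis(angle=0.4, anchor=anchor, rms_residual=0.0)
        (a,) = align_to_axis([t], fwd)
        back_in = Trajectory(
            0, t.frames, np.column_stack([a.x_axis, a.y_perp]) + np.asarray(anchor)
        )
        inv = DnaAxis(angle=-0.4, anchor=anchor, rms_residual=0.0)
        (b,) = align_to_axis([back_in], inv)
        recovered = np.column_stack([b.x_axis, b.y_perp]) + np.asarray(anchor)
        assert np.allclose(recovered, t.positions, atol=1e-9)


def make_aligned(x, y, mid=0):
    x, y = np.asarray(x, float), np.asarray(y, float)
    return AlignedTrajectory(
        molecule_id=mid,
        frames=np.arange(len(x)),
        positions=np.column_stack([x, y]),
        x_axis=x,
        y_perp=y,
    )


class TestFinalFilter:
    def test_x_span_boundary(self):
        near = make_aligned(np.linspace(0, 299, 10), np.zeros(10))
        past = make_aligned(np.linspace(0, 301, 10), np.zeros(10), mid=1)
        assert final_scan_filter([near, past]) == [past]

    def test_single_y_excursion_rejects(self):
        y = np.zeros(10)
        y[4] = 250.0
        t = make_aligned(np.linspace(0, 400, 10), y)
        assert final_scan_filter([t]) == []
        # mean-based reading keeps it
        assert final_scan_filter([t], y_criterion="mean") == [t]

    def test_min_frames(self):
        t = make_aligned(np.linspace(0, 400, 4), np.zeros(4))
        assert final_scan_filter([t]) == []

    def test_idempotent(self, rng):
        trajs = []
        for i in range(40):
            n = int(rng.integers(4, 30))
            trajs.append(
                make_aligned(np.cumsum(rng.normal(0, 80, n)), rng.normal(0, 120, n), mid=i)
            )
        once = final_scan_filter(trajs)
        twice = final_scan_filter(once)
        assert once == twice

    def test_matches_brute_force_predicates(self, rng):
        trajs = []
        for i in range(60):
            n = int(rng.integers(3, 25))
            trajs.append(
                make_aligned(np.cumsum(rng.normal(0, 90, n)), rng.normal(0, 110, n), mid=i)
            )
        kept = final_scan_filter(trajs)
        expected = [
            t
            for t in trajs
            if len(t) >= 5
            and (t.x_axis.max() - t.x_axis.min()) >= 300
            and max(abs(v) for v in t.y_perp) <= 200
        ]
        assert kept == expected


class TestPrecision:
    def test_noiseless_static(self):
        t = Trajectory(0, np.arange(20), np.full((20, 2), 7.0))
        est = estimate_precision([t], frame_interval=1 / 30)
        assert est.sigma_nm == pytest.approx(0.0, abs=1e-12)
        assert est.d_error_um2_s == pytest.approx(0.0, abs=1e-15)

    def test_recovers_sigma(self, rng):
        sigma = 18.7
        t = Trajectory(0, np.arange(10000), rng.normal(0, sigma, size=(10000, 2)))
        est = estimate_precision([t], frame_interval=1 / 30)
        assert est.sigma_nm == pytest.approx(sigma, abs=0.5)

    def test_d_error_scales_quadratically(self):
        rng1, rng2 = np.random.default_rng(3), np.random.default_rng(3)
        t1 = Trajectory(0, np.arange(20000), rng1.normal(0, 10.0, size=(20000, 2)))
        t2 = Trajectory(0, np.arange(20000), rng2.normal(0, 20.0, size=(20000, 2)))
        e1 = estimate_precision([t1], frame_interval=1 / 30)
        e2 = estimate_precision([t2], frame_interval=1 / 30)
        assert e2.d_error_um2_s / e1.d_error_um2_s == pytest.approx(4.0, rel=1e-9)

    def test_insufficient_data_errors(self):
        t = Trajectory(0, np.arange(5), np.zeros((5, 2)))
        with pytest.raises(ValueError):
            estimate_precision([t], frame_interval=1 / 30)


def test_end_to_end_scanner_classification(default_field):
    """Frames selected by the full filter chain vs ground-truth scanner frames."""
    _, loc, gt = default_field
    final, _ = run_tracking_stage(loc, DEFAULT_CONFIG["tracking"])
    selected = np.zeros(len(gt), dtype=bool)
    for t in final:
        selected[t.source_rows] = True
    is_scanner = (gt["class"] == "scanner").to_numpy()
    precision = np.sum(selected & is_scanner) / selected.sum()
    recall = np.sum(selected & is_scanner) / is_scanner.sum()
    assert precision >= 0.90
    assert recall >= 0.90
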