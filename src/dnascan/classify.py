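"""Two-mode classification of DNA-scanning trajectories.

Two independent classifiers are provided, mirroring the two analyses a
practitioner would run on the same trajectories:

* :class:`KineticBarrierClassifier` — the Arrhenius (kinetic) method.  The
  per-frame instantaneous diffusion rate D is converted to a base-stepping
  rate k = 2D/<x²> (with <x²> = one base-pair step squared) and an
  activation barrier E_a = ln(D_ideal / D) in units of k_B·T, where D_ideal
  is the theoretical barrier-free sliding coefficient.  Frames with
  E_a > 2 k_B T are labelled ``high_barrier`` (interrogation-like movement),
  the rest ``low_barrier`` (free helical sliding); a stable recognition
  complex corresponds to E_a > 5 k_B T.

* :class:`TwoStateDiffusionHMM` — a two-state hidden Markov model over 1D
  displacements, fitted by expectation–maximization.  Each frame's
  displacement is a zero-mean Gaussian whose variance 2·D_state·Δt + 2σ²
  depends on the hidden slow/fast mode; σ is the localization precision.
  States are decoded by the posterior mode per frame, and the fitted
  per-mode diffusion coefficients give the mode energy gap
  ΔE_a = ln(D_fast / D_slow).

The agreement between the two segmentations is summarised by a confusion
matrix in which the HMM's slow mode is matched to the kinetic high-barrier
mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .diffusion import DiffusionTrace

NM2_PER_UM2 = 1e6
BASE_STEP_NM = 0.34

LOW_BARRIER, HIGH_BARRIER = "low_barrier", "high_barrier"
SLOW, FAST = "slow", "fast"


# ---------------------------------------------------------------------------
# Energy-barrier arithmetic
# ---------------------------------------------------------------------------

def stepping_rate(d_inst, base_step_nm: float = BASE_STEP_NM):
    """Base-to-base stepping rate k = 2D/<x²> in 1/s.

    ``d_inst`` in µm²/s, ``base_step_nm`` the distance between adjacent base
    pairs in nm.  A zero diffusion rate maps to k = 0.
    """
    d = np.asarray(d_inst, dtype=float)
    if np.any(d < 0):
        raise ValueError("d_inst must be >= 0")
    if base_step_nm <= 0:
        raise ValueError("base_step_nm must be > 0")
    k = 2.0 * d * NM2_PER_UM2 / base_step_nm**2
    return float(k) if np.isscalar(d_inst) else k


def activation_barrier(d_inst, d_ideal: float):
    """Arrhenius activation barrier E_a = ln(D_ideal / D) in k_B·T units.

    Values below zero (D exceeding the ideal sliding coefficient) are
    returned raw; D = 0 maps to +inf.
    """
    if d_ideal <= 0:
        raise ValueError("d_ideal must be > 0")
    d = np.asarray(d_inst, dtype=float)
    if np.any(d < 0):
        raise ValueError("d_inst must be >= 0")
    with np.errstate(divide="ignore"):
        ea = np.log(d_ideal / d)
    return float(ea) if np.isscalar(d_inst) else ea


def mode_energy_gap(d_fast: float, d_slow: float) -> float:
    """Energy-barrier difference between two modes, ln(D_fast/D_slow) in k_B·T."""
    if not (d_fast >= d_slow > 0):
        raise ValueError("require d_fast >= d_slow > 0")
    return math.log(d_fast / d_slow)


def barrier_excess(delta_e_a: float, sliding_range: float = 1.5) -> float:
    """Percent by which a mode gap exceeds the helical-sliding barrier range.

    ``100 × (ΔE_a − sliding_range) / sliding_range``; negative values mean
    the gap lies within the normal sliding range (≈1.5 k_B·T of roughness).
    """
    if delta_e_a < 0:
        raise ValueError("delta_e_a must be >= 0")
    if sliding_range <= 0:
        raise ValueError("sliding_range must be > 0")
    return 100.0 * (delta_e_a - sliding_range) / sliding_range


# ---------------------------------------------------------------------------
# Kinetic classifier
# ---------------------------------------------------------------------------

@dataclass
class KineticSegmentation:
    """Per-frame kinetic labels of one diffusion trace."""

    molecule_id: int
    frames: np.ndarray
    d_inst: np.ndarray
    e_a: np.ndarray  # k_B·T
    k: np.ndarray  # 1/s
    labels: np.ndarray  # "low_barrier" / "high_barrier"
    occupancy: dict  # fraction of classifiable frames per label
    mean_d: dict  # mean d_inst per label (µm²/s)
    n_zero_flagged: int  # frames with d_inst = 0, excluded from occupancy


class KineticBarrierClassifier(BaseEstimator):
    """Threshold classifier on the Arrhenius activation barrier.

    Parameters
    ----------
    d_ideal : float
        Barrier-free sliding diffusion coefficient (µm²/s); the theoretical
        upper limit for the dataset (0.49 for AlkD-like, 0.80 for AlkF-like
        conditions).
    barrier_threshold : float
        Boundary (k_B·T) between free sliding and interrogation-like
        movement; frames are ``high_barrier`` iff E_a is strictly greater.
    recognition_threshold : float
        Barrier (k_B·T) above which movement is recognition-like; reported
        for diagnostics, not used in the two-way labels.
    base_step_nm : float
        Base-pair step used for the kinetic rate constant.
    """

    def __init__(
        self,
        d_ideal: float = 0.49,
        barrier_threshold: float = 2.0,
        recognition_threshold: float = 5.0,
        base_step_nm: float = BASE_STEP_NM,
    ):
        self.d_ideal = d_ideal
        self.barrier_threshold = barrier_threshold
        self.recognition_threshold = recognition_threshold
        self.base_step_nm = base_step_nm

    def fit(self, X=None, y=None):
        """No-op (the classifier is a fixed threshold rule); returns self."""
        self.is_fitted_ = True
        return self

    def predict(self, d_inst) -> np.ndarray:
        """Label each instantaneous diffusion value low/high barrier.

        The tie E_a == barrier_threshold is labelled ``low_barrier`` (the
        high-barrier class requires strict exceedance).
        """
        ea = activation_barrier(np.asarray(d_inst, dtype=float), self.d_ideal)
        return np.where(ea > self.barrier_threshold, HIGH_BARRIER, LOW_BARRIER)

    def segment(self, trace: DiffusionTrace) -> KineticSegmentation:
        """Segment a diffusion trace and summarise occupancy per mode.

        Frames with d_inst = 0 have an undefined (infinite) barrier; they are
        labelled ``high_barrier`` but excluded from occupancy and mean-D
        statistics, and counted in ``n_zero_flagged``.
        """
        if len(trace) == 0:
            raise ValueError("trace is empty")
        d = trace.d_inst
        ea = activation_barrier(d, self.d_ideal)
        k = stepping_rate(d, self.base_step_nm)
        labels = np.where(ea > self.barrier_threshold, HIGH_BARRIER, LOW_BARRIER)
        ok = d > 0
        occ, mean_d = {}, {}
        n_ok = int(ok.sum())
        for lab in (LOW_BARRIER, HIGH_BARRIER):
            sel = ok & (labels == lab)
            occ[lab] = float(sel.sum() / n_ok) if n_ok else float("nan")
            mean_d[lab] = float(d[sel].mean()) if sel.any() else float("nan")
        return KineticSegmentation(
            molecule_id=trace.molecule_id,
            frames=trace.frames.copy(),
            d_inst=d.copy(),
            e_a=ea,
            k=k,
            labels=labels,
            occupancy=occ,
            mean_d=mean_d,
            n_zero_flagged=int((~ok).sum()),
        )


def kinetic_segmentation(trace: DiffusionTrace, profile: KineticBarrierClassifier) -> KineticSegmentation:
    """Functional wrapper over :meth:`KineticBarrierClassifier.segment`."""
    return profile.segment(trace)


# ---------------------------------------------------------------------------
# Two-state displacement HMM
# ---------------------------------------------------------------------------

def _pad_sequences(seqs: list[np.ndarray]):
    """Stack variable-length 1D arrays into (S, Tmax) with an active mask."""
    lengths = np.array([len(s) for s in seqs])
    tmax = int(lengths.max())
    X = np.zeros((len(seqs), tmax))
    mask = np.zeros((len(seqs), tmax), dtype=bool)
    for i, s in enumerate(seqs):
        X[i, : len(s)] = s
        mask[i, : len(s)] = True
    return X, mask


class TwoStateDiffusionHMM(BaseEstimator):
    """Two-state Gaussian displacement HMM fitted by EM (Baum–Welch).

    The observable is the per-frame 1D displacement along the DNA (nm).  In
    hidden state k the displacement is N(0, 2·D_k·Δt + 2σ²), where σ is the
    static localization precision; the hidden state performs memoryless
    (Markov) transitions between a slow and a fast scanning mode.

    Parameters
    ----------
    frame_interval : float
        Camera frame interval Δt in seconds.
    loc_sigma_nm : float
        Per-axis localization precision σ in nm.
    noise_correction : bool
        If True (default) subtract 2σ² from the fitted state variances when
        reporting D; disable for a literal uncorrected fit.
    n_restarts, max_iter, tol :
        EM restarts (best likelihood kept), iteration cap, and relative
        log-likelihood convergence tolerance.
    min_occupancy : float
        Below this occupancy a state is flagged as collapsed.
    random_state : int | numpy Generator | None
        Seeds the restart initializations.

    Attributes (after fit)
    ----------------------
    d_slow_, d_fast_ : µm²/s, sorted so d_slow_ <= d_fast_.
    variances_ : fitted emission variances (nm²), sorted.
    transmat_ : 2×2 row-stochastic transition matrix (slow, fast) order.
    startprob_ : initial state distribution.
    occupancy_slow_, occupancy_fast_ : posterior state mass fractions.
    delta_e_a_ : ln(d_fast_/d_slow_) in k_B·T.
    log_likelihood_, n_iter_, converged_, flags_.
    """

    def __init__(
        self,
        frame_interval: float = 1.0 / 30.0,
        loc_sigma_nm: float = 18.7,
        noise_correction: bool = True,
        n_restarts: int = 10,
        max_iter: int = 500,
        tol: float = 1e-8,
        min_occupancy: float = 0.01,
        d_floor_um2_s: float = 1e-6,
        random_state=None,
    ):
        self.frame_interval = frame_interval
        self.loc_sigma_nm = loc_sigma_nm
        self.noise_correction = noise_correction
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.min_occupancy = min_occupancy
        self.d_floor_um2_s = d_floor_um2_s
        self.random_state = random_state

    # -- internals ----------------------------------------------------------

    @staticmethod
    def _emission_prob(X, var):
        """Gaussian pdf of each observation under each state, (S, T, 2)."""
        v = var[None, None, :]
        return np.exp(-0.5 * X[..., None] ** 2 / v) / np.sqrt(2 * np.pi * v)

    @staticmethod
    def _forward_backward(B, mask, A, pi):
        """Scaled forward-backward, batched over sequences.

        B : (S, T, 2) emission probabilities, padded entries overwritten to 1
        so inactive steps contribute scale 1 (log 0) and leave alpha frozen
        as a distribution.
        Returns (gamma, xi_sum, loglik): posteriors (S, T, 2), summed
        two-slice statistics (2, 2), and total log-likelihood.
        """
        S, T, K = B.shape
        B = np.where(mask[..., None], B, 1.0)
        alpha = np.empty((S, T, K))
        c = np.empty((S, T))
        a = pi[None, :] * B[:, 0, :]
        c[:, 0] = a.sum(axis=1)
        alpha[:, 0, :] = a / c[:, 0, None]
        for t in range(1, T):
            a = (alpha[:, t - 1, :] @ A) * B[:, t, :]
            c[:, t] = a.sum(axis=1)
            alpha[:, t, :] = a / c[:, t, None]
        beta = np.empty((S, T, K))
        beta[:, T - 1, :] = 1.0
        xi_sum = np.zeros((K, K))
        for t in range(T - 2, -1, -1):
            bb = B[:, t + 1, :] * beta[:, t + 1, :]
            # two-slice posterior, only where both t and t+1 are observed
            w = (mask[:, t] & mask[:, t + 1]).astype(float)
            xi = alpha[:, t, :, None] * A[None, :, :] * bb[:, None, :] / c[:, t + 1, None, None]
            xi_sum += np.einsum("s,sij->ij", w, xi)
            beta[:, t, :] = (bb @ A.T) / c[:, t + 1, None]
        gamma = alpha * beta
        gamma = gamma / gamma.sum(axis=2, keepdims=True)
        loglik = float(np.log(c[mask]).sum())
        return gamma, xi_sum, loglik

    def _run_em(self, X, mask, var0, A0, pi0):
        var, A, pi = var0.copy(), A0.copy(), pi0.copy()
        var_floor = 1e-6 * max(float(np.mean(X[mask] ** 2)), 1e-12)
        prev_ll = -np.inf
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            B = self._emission_prob(X, var)
            gamma, xi_sum, ll = self._forward_backward(B, mask, A, pi)
            w = gamma * mask[..., None]
            denom = w.sum(axis=(0, 1))
            var = np.maximum((w * X[..., None] ** 2).sum(axis=(0, 1)) / denom, var_floor)
            A = xi_sum / xi_sum.sum(axis=1, keepdims=True)
            pi = gamma[:, 0, :].mean(axis=0)
            pi = pi / pi.sum()
            if np.isfinite(prev_ll) and abs(ll - prev_ll) <= self.tol * abs(prev_ll):
                converged = True
                prev_ll = ll
                break
            prev_ll = ll
        return dict(var=var, A=A, pi=pi, loglik=prev_ll, converged=converged, n_iter=n_iter)

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y=None):
        """Fit the HMM to displacement series.

        ``X`` is a list of 1D arrays (nm displacements, one per trajectory)
        or a single 1D array treated as one series.
        """
        if isinstance(X, np.ndarray) and X.ndim == 1:
            X = [X]
        seqs = [np.asarray(s, dtype=float).ravel() for s in X if len(s) > 0]
        if not seqs:
            raise ValueError("no displacement data")
        n_obs = sum(len(s) for s in seqs)
        if n_obs < 2:
            raise ValueError("need at least 2 displacements")
        Xp, mask = _pad_sequences(seqs)
        rng = (
            self.random_state
            if isinstance(self.random_state, np.random.Generator)
            else np.random.default_rng(self.random_state)
        )
        total_var = float(np.mean(Xp[mask] ** 2))

        best = None
        for r in range(max(self.n_restarts, 1)):
            if r == 0:
                f = 3.0  # deterministic moment-based start around the overall variance
            else:
                f = float(np.exp(rng.uniform(np.log(1.5), np.log(20.0))))
            var0 = np.array([total_var / f, total_var * f])
            stay = 0.9 if r == 0 else float(rng.uniform(0.6, 0.99))
            A0 = np.array([[stay, 1 - stay], [1 - stay, stay]])
            pi0 = np.array([0.5, 0.5])
            res = self._run_em(Xp, mask, var0, A0, pi0)
            if best is None or res["loglik"] > best["loglik"]:
                best = res

        order = np.argsort(best["var"])
        var = best["var"][order]
        A = best["A"][np.ix_(order, order)]
        pi = best["pi"][order]

        # final posterior pass with the selected parameters
        B = self._emission_prob(Xp, var)
        gamma, _, ll = self._forward_backward(B, mask, A, pi)
        w = gamma * mask[..., None]
        occ = w.sum(axis=(0, 1))
        occ = occ / occ.sum()

        noise_var = 2.0 * self.loc_sigma_nm**2 if self.noise_correction else 0.0
        d = (var - noise_var) / (2.0 * self.frame_interval) / NM2_PER_UM2

        self.flags_ = []
        if not best["converged"]:
            self.flags_.append("non_convergence")
        if occ.min() < self.min_occupancy:
            self.flags_.append("state_collapse")
        if np.any(d <= 0):
            self.flags_.append("noise_floor")
            d = np.maximum(d, self.d_floor_um2_s)

        self.variances_ = var
        self.transmat_ = A
        self.startprob_ = pi
        self.d_slow_ = float(d[0])
        self.d_fast_ = float(d[1])
        self.occupancy_slow_ = float(occ[0])
        self.occupancy_fast_ = float(occ[1])
        self.delta_e_a_ = mode_energy_gap(self.d_fast_, self.d_slow_)
        self.log_likelihood_ = ll
        self.converged_ = best["converged"]
        self.n_iter_ = best["n_iter"]
        self._seq_posteriors = [gamma[i, mask[i], :] for i in range(len(seqs))]
        return self

    def predict_proba(self, X) -> list[np.ndarray]:
        """Posterior state probabilities per displacement, one array per series."""
        if isinstance(X, np.ndarray) and X.ndim == 1:
            X = [X]
        seqs = [np.asarray(s, dtype=float).ravel() for s in X]
        Xp, mask = _pad_sequences(seqs)
        B = self._emission_prob(Xp, self.variances_)
        gamma, _, _ = self._forward_backward(B, mask, self.transmat_, self.startprob_)
        return [gamma[i, mask[i], :] for i in range(len(seqs))]

    def predict(self, X) -> list[np.ndarray]:
        """Per-frame slow/fast labels decoded by the posterior mode."""
        return [
            np.where(g[:, 1] > g[:, 0], FAST, SLOW) for g in self.predict_proba(X)
        ]

    def result(self) -> dict:
        """Fitted parameters as a plain dict (JSON-friendly)."""
        return {
            "d_slow_um2_s": self.d_slow_,
            "d_fast_um2_s": self.d_fast_,
            "occupancy_slow": self.occupancy_slow_,
            "occupancy_fast": self.occupancy_fast_,
            "transition_matrix": self.transmat_.tolist(),
            "delta_e_a_kBT": self.delta_e_a_,
            "log_likelihood": self.log_likelihood_,
            "converged": self.converged_,
            "n_iter": self.n_iter_,
            "flags": list(self.flags_),
        }


def fit_two_state_hmm(
    displacements: list[np.ndarray],
    frame_interval: float,
    loc_sigma: float,
    **kwargs,
) -> TwoStateDiffusionHMM:
    """Fit a :class:`TwoStateDiffusionHMM` to per-trajectory displacement
    series (nm) and return the fitted estimator."""
    model = TwoStateDiffusionHMM(
        frame_interval=frame_interval, loc_sigma_nm=loc_sigma, **kwargs
    )
    return model.fit(displacements)


# ---------------------------------------------------------------------------
# Cross-method agreement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionSummary:
    """Frame-level agreement between the HMM and kinetic segmentations.

    Positive class: HMM ``slow`` matched against kinetic ``high_barrier``
    (slow scanning corresponds to interrogation-like, high-barrier movement).
    Truth is taken as the kinetic label for sensitivity/specificity.
    """

    tp: int  # HMM slow  & kinetic high_barrier
    fn: int  # HMM fast  & kinetic high_barrier
    fp: int  # HMM slow  & kinetic low_barrier
    tn: int  # HMM fast  & kinetic low_barrier

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


def confusion_matrix(kinetic_labels, hmm_labels) -> ConfusionSummary:
    """Frame-aligned confusion matrix between the two classifiers."""
    kin = np.asarray(kinetic_labels)
    hmm = np.asarray(hmm_labels)
    if kin.shape != hmm.shape:
        raise ValueError("label sequences must have equal length")
    high = kin == HIGH_BARRIER
    slow = hmm == SLOW
    return ConfusionSummary(
        tp=int(np.sum(slow & high)),
        fn=int(np.sum(~slow & high)),
        fp=int(np.sum(slow & ~high)),
        tn=int(np.sum(~slow & ~high)),
    )
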