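# Methods

This note describes the models and procedures implemented in `dnascan`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## The measurement being modelled

A DNA-repair protein bound non-specifically to an elongated, surface-anchored
DNA performs 1D diffusion ("scanning") along the molecule while it searches
for target bases. In the imaging experiment this package analyses, the
protein is fluorescently labelled and localized frame by frame at ~30–75 Hz
with a localization precision of σ ≈ 18.7 nm per image axis; the DNA itself
(~12 kbp, stretched to ~95% of its 4.1 µm contour length) is not labelled
and its position must be inferred from the scanning trajectories themselves.
The field of view also contains free-floating molecules that blink through
the illumination volume for a few frames, and molecules stuck to the
coverslip that report pure localization noise.

## Synthetic data generator

`simulate_field` emulates this field of view with three molecule classes:

* **Scanners.** The position along the DNA follows
  `x_{t+1} = x_t + N(0, 2 D(m_t) Δt)` where the diffusive mode `m_t` (slow or
  fast) is a two-state Markov chain with per-frame switching probabilities.
  Positions reflect at the DNA ends (the fold-into-interval construction of
  reflected Brownian motion), which preserves the uniform stationary
  occupancy and avoids artificial truncation. The 1D coordinate is embedded
  on a tilted line (angle and anchor configurable) and isotropic Gaussian
  noise of std `loc_sigma` is added per image axis — noise is applied after
  embedding because precision is a property of the camera-plane fit.
  Binding-event durations are geometric per frame (memoryless unbinding);
  photobleaching is not modelled separately, it is subsumed in the event
  length.
* **Free molecules.** 2D Brownian motion at `d_free = 20 µm²/s` (a typical
  free-solution diffusivity for a ~30 kDa protein) with a short geometric
  dwell (mean 3 frames), mimicking molecules drifting through the
  illumination sheet. At 30 Hz these move ~1.2 µm per frame, so they appear
  as nearly uncorrelated flashes — which is exactly how they behave in the
  real data and why a 5-consecutive-frame filter removes them.
* **Stuck molecules.** A fixed position plus localization noise, visible
  for a photobleaching-limited geometric lifetime (mean 300 frames); these
  calibrate σ and the diffusion-rate noise floor.

Defaults are the study conditions: `frame_interval = 1/30 s`,
`loc_sigma = 18.7 nm`, 12 kbp DNA at 95% elongation, `d_slow = 0.043 µm²/s`
with `d_fast = 4.3 × d_slow`, symmetric per-frame switching 0.05, 8 scanners
/ 15 free / 5 stuck molecules per 600-frame movie (sparse single-molecule
occupancy, ~1–2 concurrent scanners). The generator does **not** render
camera frames or point-spread functions, does not model blinking,
bleaching, drift, or localization failures, and free molecules carry no
axial (z) structure. Passing tests therefore demonstrate correctness of the
analysis chain under idealized Gaussian localization statistics, not
robustness to segmentation or fitting artefacts of real raw images.

## Trajectory reconstruction and scanner selection

Localizations are linked frame-to-frame by greedy nearest-neighbour
assignment: candidate (track, localization) pairs within `max_jump`
(default 500 nm) are assigned in order of increasing distance; a trajectory
that misses a frame is closed (no gap closing — consecutive-frame semantics).
Known limitation: when two scanners cross on the DNA, nearest-neighbour
linking can permanently swap their identities; per-row identity accuracy is
therefore excellent in sparse fields but degrades whenever trajectories
intersect, which no frame-by-frame linker can resolve.

Scanner selection uses the experiment's geometric filters, in order:

1. at least 5 consecutive frames;
2. movement of at least 600 nm along a linear path. "Linear path" is
   operationalized as: extent along the trajectory's principal axis ≥ 600 nm
   **and** principal-axis variance fraction ≥ 0.9 (scale-free, robust to
   trajectory length; 1.0 = perfect line, 0.5 = isotropic);
3. the DNA axis is fit by total least squares (orthogonal regression) to the
   pooled localizations of the 10 qualifying trajectories with the largest
   extent (largest-extent selection maximizes leverage on the line fit), and
   all trajectories are rigidly rotated so the DNA lies along x;
4. final conjunctive filter: ≥ 5 frames, x-span ≥ 300 nm, and never more
   than 200 nm from the DNA in y. The y-criterion is the per-frame maximum
   (strictest reading); a mean-based variant is available via
   `y_criterion="mean"`.

Localization precision is estimated from stuck molecules as the per-axis
standard deviation about each molecule's mean, and the diffusion-rate noise
floor as the mean apparent instantaneous diffusion rate of the same
molecules — an empirical, not analytic, propagation.

## Instantaneous diffusion

For frame *i* of an aligned trajectory, the mean squared displacement of
the window is the mean of the `w = 5` lag-1 squared increments of the
along-DNA coordinate starting at frame *i*, and

    D_i = <x²> / (2 Δt)

is assigned to frame *i* (1D diffusion; the time in the denominator is one
frame interval — the only reading under which the quantity is a per-frame
instantaneous rate). The trace has `n − w` values. Segment-average diffusion
rates are arithmetic means of per-frame values. For a noiseless single-mode
walk, `D_i ~ D·χ²_w/w`; static localization noise adds `σ²/Δt` to the
expectation (0.0105 µm²/s at the defaults), which is why all mode
diffusivities sit on a noise floor that the HMM emission model subtracts
explicitly.

Pooled distributions are Gaussian KDEs on log10(D) with Silverman
bandwidth; values at or below a configurable floor (default 1e-4 µm²/s,
needed because log of an exactly-zero window is undefined) are clamped to
the floor and counted separately. Window widths of 7, 10 and 15 frames are
re-run by `window_robustness` to confirm distribution features are not
artefacts of the window choice.

## Mode classification

**Kinetic (Arrhenius) method.** Scanning is modelled as a thermally
activated base-to-base stepping reaction with rate `k = 2D/δ²`
(δ = 0.34 nm per bp) and activation barrier

    E_a = ln(D_ideal / D)   [k_B·T]

where `D_ideal` is the barrier-free sliding coefficient — a required input
with defaults 0.49 µm²/s (AlkD-like) and 0.80 µm²/s (AlkF-like), since its
derivation is dataset-specific and not computable from trajectories alone.
Frames with `E_a > 2 k_BT` are labelled high-barrier (interrogation-like);
`E_a > 5 k_BT` marks recognition-like immobility. The tie `E_a = 2` is
low-barrier (the high class requires strict exceedance). Frames with
`D = 0` have an undefined barrier; they are excluded from occupancy
statistics and counted separately. Occupancies are frame-weighted.

**Two-state displacement HMM.** Per-frame 1D displacements are emitted from
zero-mean Gaussians whose variance `2·D_state·Δt + 2σ²` depends on a hidden
slow/fast state with memoryless transitions. Fitting is maximum-likelihood
EM (Baum–Welch, scaled forward–backward, batched over trajectories) to a
relative log-likelihood tolerance of 1e-8 or 500 iterations, with 10
restarts by default (one moment-based, the rest with log-uniform variance
splits) keeping the best likelihood. EM with an explicit noise term was
chosen over a variational-Bayes treatment because it is fully specifiable
without prior hyperparameters; the contract (two states, per-frame labels,
per-mode D, occupancy, transition matrix) is unchanged and a variational
extension would slot in behind the same interface. States are decoded by
the per-frame posterior mode; `2σ²` is subtracted from fitted variances
before reporting `D_state` (switchable off for a literal uncorrected fit;
without the correction `d_slow` is biased upward at the noise floor).
Negative corrected diffusivities are floored at 1e-6 µm²/s and flagged, as
is non-convergence and state collapse (occupancy < 1%). The mode energy gap
is `ΔE_a = ln(D_fast/D_slow)` and its percent excess over the ~1.5 k_BT
roughness of normal helical sliding is `100·(ΔE_a − 1.5)/1.5`.

The two segmentations are compared frame-by-frame with a confusion matrix
whose positive class pairs HMM-slow with kinetic-high-barrier, treating the
kinetic label as truth for sensitivity/specificity.

## Scanning redundancy and efficiency

Each filtered trajectory is one binding-and-scanning event. The along-DNA
coordinate is binned at `0.34 nm × elongation_fraction` per bp — the
*stretched* spacing, since positions are measured on elongated DNA. A visit
is a bin entry: the first frame counts one visit, each bin change credits
the landing bin, and bins skipped within a single frame step are credited
one pass-through visit each (so a monotone pass has redundancy exactly 1
regardless of frame rate). Redundancy divides total visits by the spanned
bins (min..max visited) so hopping gaps lower redundancy rather than
inflate it; efficiency divides distinct visited bins by the event duration
in ms. Both the frames-per-bin counting alternative and the visited-bins
denominator are exposed as options, since the verbal definitions admit
either reading. Salt-series summaries report per-(salt, mode) means ± SEM
and a frame-level Spearman trend per mode, which uses all observations and
retains power at as few as four salt levels.

## Numerical and reproducibility choices

* Units: nm and 0-based frames in simulation/tracking; µm²/s in diffusion
  and classification; ms in metrics. Energies are dimensionless multiples of
  k_B·T.
* One pipeline seed fans out to per-stage `SeedSequence` substreams; a fixed
  seed reproduces every table, summary and the manifest hash bit for bit.
* The pipeline config is strict: unknown keys are rejected, and the resolved
  config plus per-stage row counts are written to `manifest.json`.
* Validation experiments (`dnascan.validation`) run at desk scale:
  parameter-recovery uses 20 replicates of 5×10⁴ displacements (100
  trajectories × 500 frames each), which puts the Monte-Carlo spread of the
  fitted mode gap at ±0.03–0.05 k_BT, comfortably inside the ±0.1 k_BT
  acceptance band; concordance uses 2×10⁴ frames.

## Known limitations

* Greedy linking swaps identities when trajectories cross (see above), and
  can append a surface-stuck molecule's signal to a scanner track when the
  scanner unbinds within `max_jump` of it; a stuck molecule lying within
  200 nm of the DNA is observationally indistinguishable from a paused
  scanner, so such hybrid events contaminate downstream statistics in dense
  fields.
* `D_ideal` is an input, not an estimate; kinetic occupancies shift with it.
* The HMM assumes exactly two states and Gaussian displacements; confined
  or anomalous diffusion, and dwells shorter than a frame, bias the fitted
  diffusivities toward each other.
* The sliding-window estimator blurs mode switches over the window width,
  so kinetic occupancies are biased at fast switching rates (dwell ≲ window).
* Redundancy/efficiency depend on the bp discretization near the
  localization noise scale: bins (0.32 nm) are far below σ (18.7 nm), so
  apparent noise-driven bin entries inflate visit counts for slow events;
  comparisons are meaningful between datasets analysed identically.
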