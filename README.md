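# dnascan

Analysis of single-molecule DNA-scanning experiments: fluorescently
labelled DNA-repair proteins (e.g. DNA glycosylases) are imaged at
~30–75 Hz while they diffuse along an elongated, surface-anchored DNA in
search of damaged bases. `dnascan` turns per-frame localization tables into
filtered 1D scanning trajectories and quantifies *how* each protein scans:

* **Instantaneous diffusion rates.** For each frame, the mean squared
  displacement of a 5-frame sliding window gives `D = ⟨x²⟩/2Δt`; pooled
  distributions on log₁₀ D reveal mono- vs multimodal scanning against a
  matched single-mode random-walk reference.
* **Kinetic (Arrhenius) mode classification.** Base stepping is a thermally
  activated reaction with rate `k = 2D/δ²` (δ = 0.34 nm/bp) and barrier
  `E_a = ln(D_ideal/D) k_BT`; frames with `E_a > 2 k_BT` are
  interrogation-like, `E_a > 5 k_BT` recognition-like.
* **Two-state displacement HMM.** Displacements are zero-mean Gaussians
  with state variance `2 D_state Δt + 2σ²` (σ = localization precision),
  fitted by EM; the mode energy gap is `ΔE_a = ln(D_fast/D_slow) k_BT` and
  is compared against the ~1.5 k_BT barrier roughness of normal helical
  sliding. The two segmentations are cross-validated with a frame-level
  confusion matrix.
* **Redundancy and efficiency of scanning.** Per binding event: average
  visits per base pair, and base pairs covered per millisecond — the
  trade-off plane separating thorough, confined scanners from fast,
  hopping-capable ones.

Raw experimental trajectories of this kind are rarely shared, so the
package includes a forward simulator of the whole field of view (DNA-bound
two-state scanners on a tilted axis, free molecules, surface-stuck
molecules, Gaussian localization noise) with per-row ground truth; every
stage of the pipeline is tested against it. The classifiers follow
scikit-learn conventions (`fit`/`predict`, `get_params`) and compose with
sklearn tooling.

## Worked example

```bash
dna-scan run --out demo_run --seed 11
dna-scan report --run-dir demo_run
```

or equivalently from Python:

```python
from dnascan.pipeline import run_pipeline, report
manifest = run_pipeline({"classification": {"hmm_restarts": 5}},
                        out_dir="demo_run", seed=11)
```

simulates a default field (600 frames at 30 Hz, 12 kbp DNA stretched to
95%, d_slow = 0.043 µm²/s, d_fast = 4.3×d_slow, σ = 18.7 nm), links and
filters trajectories, and writes per-stage CSV/JSON plus three figures.
With seed 11 the run prints counts and summaries equivalent to:

```
track:    2837 localizations -> 15 linked -> 13 after 5-frame filter
          -> 5 linear scanners; DNA axis angle -0.0006 rad (true 0),
          rms residual 18.7 nm; 6 final scanning events
classify: d_slow = 0.037, d_fast = 0.180 um^2/s  (truth 0.043 / 0.185)
          delta_E_a = 1.59 kBT (truth ln 4.3 = 1.46), occupancy_slow = 0.42
          kinetic vs HMM agreement: accuracy 0.81, sens 0.78, spec 0.83
metrics:  efficiency 1.10 +/- 0.33 bp/ms, redundancy 9.1 +/- 2.7 visits/bp
```

Reading the output: the fitted mode diffusivities and their ~1.5 k_BT gap
recover the simulation's ground truth from six short binding events; the
two independent classifiers agree on ~80% of frames; and the events sit in
the low-efficiency / high-redundancy corner of the scanning plane, as
expected for a slow two-mode scanner confined to short stretches of DNA.

Each stage is also a standalone command (`dna-scan simulate / track /
diffuse / classify / metrics`) operating on the same CSV layout, so user
localization tables (ThunderSTORM-style columns `frame, x_nm, y_nm,
sigma_nm, photons`) drop in at the `track` stage.

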