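# spheroquant

Quantification pipeline for tumor-spheroid invasion assays under
interstitial flow, validated end to end on synthetic phantoms with known
ground truth.

## The problem

Slow interstitial flows (~2 µm/s) through the extracellular matrix can
drive the dissociation of tumor spheroids embedded in collagen: cells
detach from the compact core, invade the matrix as singles, and change
both shape and motility. Quantifying this from two-channel time-lapse
fluorescence microscopy (co-cultures of metastatic MDA-MB-231 and
non-tumorigenic MCF-10A breast cells, one frame every 20 min for 36 h)
requires four measurements:

1. **Spheroid size over time** — the azimuthally averaged radial
   intensity profile around the spheroid center is fitted per frame to a
   Gaussian, `I(r) = A·exp(−r²/2σ²) + B`; the fitted σ is the spheroid
   radius, and `σ(t)/σ(0)` is the normalized size. Dissociated single
   cells beyond a cutoff radius are segmented and counted.
2. **Single-cell motility** — per-cell speed (path length / elapsed
   time), the time-averaged mean-squared displacement pooled across
   cells, the 2D diffusion coefficient from the first-order model
   `MSD(τ) = 4Dτ`, and directional statistics along the flow axis
   (net velocity `Vx` and the forward-migration index
   `Px = Δx_net / path length`).
3. **Morphology** — each segmented cell is reduced to its
   moment-equivalent ellipse; aspect ratio `AR = major/minor ≥ 2`
   classifies a cell as mesenchymal (elongated), `AR < 2` as amoeboid.
4. **Adhesion-marker intensity** — confocal z-stacks are sum-projected,
   background-subtracted, and summed to the total marker intensity per
   spheroid; distributions and totals are compared between conditions
   with Student's t-test (mean ± SEM throughout).

Because raw assay data of this kind is rarely shareable, the package
ships a first-class phantom generator (`spheroquant.phantoms`): Gaussian
cell clouds with a programmed dissociation schedule, Brownian /
fixed-step / persistent random-walk trajectory cohorts, non-overlapping
ellipse fields with a calibrated aspect-ratio mixture, and marker
z-stacks — each with a ground-truth sidecar, so every estimator is
validated by parameter recovery rather than by eye.

## Worked example

Simulate a flow-condition tumor-cell cohort (121 Brownian walkers at
D = 6.41 µm²/min, tracked 17 h at 20-min intervals) and recover its
motility statistics:

```python
import numpy as np
from spheroquant import phantoms, motility

spec = phantoms.TrajectoryPhantomSpec(n_cells=121, mode="brownian",
                                      D=6.41, duration=17 * 60)
tracks, truth = phantoms.generate_trajectories(spec, seed=42)

speed = motility.compute_speed(tracks)
msd = motility.compute_msd(tracks, max_lag_fraction=0.25)
D, D_se = motility.fit_diffusion_coefficient(msd)
percell, group = motility.directional_stats(tracks)

print(f"group mean speed : {speed.mean_speed:.3f} +/- {speed.sem_speed:.3f} um/min")
print(f"fitted D         : {D:.2f} +/- {D_se:.2f} um^2/min (truth 6.41)")
print(f"flow-axis bias   : mean Vx = {group['mean_vx']:+.4f} um/min, p = {group['p_value']:.2f}")
```

prints

```
group mean speed : 1.006 +/- 0.006 um/min
fitted D         : 6.48 +/- 0.01 um^2/min (truth 6.41)
flow-axis bias   : mean Vx = -0.0143 um/min, p = 0.17
```

The fitted diffusion coefficient recovers the ground truth within ~1%,
and the isotropic cohort shows no significant flow-axis bias. (The
step-based speed of a Brownian walk depends on the sampling interval —
E|step|/Δt = √(πDΔt)/Δt ≈ 1.0 µm/min here — which is why speed-targeted
phantoms use the fixed-step mode instead; see `docs/methods.md`.)

## Repository layout

- `src/spheroquant/` — the library: `phantoms` (generators + sidecars),
  `io` (calibrated TIFF / trajectory-CSV round trips), `dissociation`
  (radial profiles, Gaussian sizing, single-cell counts), `motility`
  (speed, MSD, 4Dτ fit, Vx/Px, LoG detector + nearest-neighbor linker),
  `morphology` (segmentation, moment ellipses, AR classification),
  `marker` (sum projection, totals, group comparison), `stats`
  (t-test, mean ± SEM), `conditions` (the per-condition ground-truth
  calibrations), `benchmarks` (recovery runs used by the acceptance
  machinery).
- `analysis/01…05_*.py` — numbered drivers that run each stage on
  calibrated phantoms and write tables under `results/`.
- `spheroquant` CLI — `simulate`, `dissociation`, `motility`,
  `morphology`, `marker` subcommands for shell use.
- `tests/` — unit, property, and oracle-equivalence suites plus the
  end-to-end recovery benchmarks.

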