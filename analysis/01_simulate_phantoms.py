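#!/usr/bin/env python
"""Generate one example phantom of each kind with its ground-truth sidecar.

Writes a short dissociating-spheroid movie (TIFF + sidecar), a
fixed-step and a Brownian trajectory cohort (CSV), an ellipse field, and
a marker z-stack under results/phantoms/.  These are small demonstration
artifacts; the recovery analyses in the later scripts regenerate their
own phantoms at full size.
"""

import json
from pathlib import Path

import numpy as np

from spheroquant import phantoms
from spheroquant.io import write_trajectories

OUT = Path(__file__).resolve().parent.parent / "results" / "phantoms"
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    fs = phantoms.PhantomSpec(image_shape=(768, 768), n_frames=12,
                              rng_seed=SEED)
    spec = phantoms.SpheroidPhantomSpec(n_cells=300, sigma0=40.0,
                                        fold_final=2.0, detach_fraction=0.05)
    series, sidecar = phantoms.generate_spheroid_timelapse(spec, fs)
    phantoms.save_phantom_movie(series, sidecar, OUT, name="spheroid_demo")
    print(f"spheroid movie: {series.n_frames} frames, "
          f"sigma {sidecar.sigma_schedule[0]:.0f} -> "
          f"{sidecar.sigma_schedule[-1]:.0f} µm, "
          f"{len(sidecar.detached_ids)} detached singles")

    for mode, kw in [("fixed_step", {"step_length": 6.0}),
                     ("brownian", {"D": 4.0})]:
        tspec = phantoms.TrajectoryPhantomSpec(n_cells=50, mode=mode,
                                               duration=600, **kw)
        ts, side = phantoms.generate_trajectories(tspec, seed=SEED)
        write_trajectories(ts, OUT / f"tracks_{mode}.csv")
        (OUT / f"tracks_{mode}_truth.json").write_text(
            json.dumps(side, indent=2))
        print(f"{mode} tracks: {ts.n_cells} cells x {tspec.n_steps} steps")

    w = phantoms.mixture_weight_for_fraction(0.5)
    sspec = phantoms.ShapePhantomSpec(
        n_cells=100, ar_mixture=(w, phantoms.ELONGATED_COMPONENT,
                                 phantoms.ROUNDED_COMPONENT),
        image_shape=(1200, 1200))
    img, side = phantoms.generate_shape_image(sspec, seed=SEED)
    np.save(OUT / "shapes.npy", img.astype(np.float32))
    side.to_csv(OUT / "shapes_truth.csv", index=False)
    print(f"shape field: {len(side)} ellipses, "
          f"true AR>=2 fraction {(side['aspect_ratio'] >= 2).mean():.2f}")

    zspec = phantoms.StackPhantomSpec(n_positive_cells=10)
    stack, side = phantoms.generate_marker_zstack(zspec, seed=SEED)
    np.save(OUT / "zstack.npy", stack.astype(np.float32))
    side.to_csv(OUT / "zstack_truth.csv", index=False)
    print(f"marker z-stack: {zspec.n_slices} slices, "
          f"total signal {side['integrated_intensity'].sum():.0f}")


if __name__ == "__main__":
    main()
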