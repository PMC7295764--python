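"""Parameter-recovery benchmarks on calibrated phantoms.

Each benchmark generates a phantom whose ground truth is set to one of
the study conditions (see :mod:`spheroquant.conditions`), runs the
corresponding pipeline stage end to end, and returns the recovered
quantity.  These are the package's headline validation runs: if the
pipeline is correct, the recovered speed / diffusion coefficient /
mesenchymal percentage / size fold must agree with the phantom's ground
truth within sampling error.
"""

from __future__ import annotations

import numpy as np

from . import dissociation, morphology, motility, phantoms
from .conditions import FRAME_INTERVAL_MIN, N_FRAMES, MotilityCondition

__all__ = [
    "recover_speed",
    "recover_diffusion",
    "recover_mesenchymal_percent",
    "recover_size_fold",
]

#: field used for dissociating-spheroid movies: 1536 px at 0.65 µm/px
#: (~1 mm across) keeps the fully dissociated cloud (sigma up to
#: ~190 µm) well inside the field so the radial fit sees > 2.5 sigma
SPHEROID_FIELD = (1536, 1536)


def recover_speed(cond: MotilityCondition, rng: np.random.Generator):
    """Generate the condition's cohort as fixed-step walkers at the
    condition's true speed and recover the group mean speed.

    Returns (mean_speed, sem_speed, n_cells), µm/min.
    """
    spec = phantoms.TrajectoryPhantomSpec(
        n_cells=cond.n_cells,
        mode="fixed_step",
        step_length=cond.mean_speed * FRAME_INTERVAL_MIN,
        duration=cond.duration_h * 60.0,
        frame_interval=FRAME_INTERVAL_MIN,
    )
    ts, _ = phantoms.generate_trajectories(spec, rng=rng)
    out = motility.compute_speed(ts)
    return out.mean_speed, out.sem_speed, cond.n_cells


def recover_diffusion(cond: MotilityCondition, rng: np.random.Generator):
    """Generate the condition's cohort as Brownian walkers at the
    condition's true D and recover D from the MSD = 4 D tau fit
    (lags up to a quarter of the track duration).

    Returns (D, D_se, n_cells), µm²/min.
    """
    spec = phantoms.TrajectoryPhantomSpec(
        n_cells=cond.n_cells,
        mode="brownian",
        D=cond.D,
        duration=cond.duration_h * 60.0,
        frame_interval=FRAME_INTERVAL_MIN,
    )
    ts, _ = phantoms.generate_trajectories(spec, rng=rng)
    curve = motility.compute_msd(ts, max_lag_fraction=0.25)
    D, se = motility.fit_diffusion_coefficient(curve)
    return D, se, cond.n_cells


def recover_mesenchymal_percent(
    true_percent: float, rng: np.random.Generator, n_cells: int = 150
):
    """Render an ellipse phantom whose AR mixture is calibrated so the
    expected fraction with AR >= 2 equals ``true_percent``, run
    segmentation + moment-ellipse fitting + classification, and return
    (percent, n_classified).
    """
    w = phantoms.mixture_weight_for_fraction(true_percent / 100.0)
    spec = phantoms.ShapePhantomSpec(
        n_cells=n_cells,
        ar_mixture=(w, phantoms.ELONGATED_COMPONENT, phantoms.ROUNDED_COMPONENT),
    )
    img, _ = phantoms.generate_shape_image(spec, rng=rng)
    regions = morphology.segment_cells(img, spec.pixel_size)
    records = [morphology.ellipse_aspect_ratio(rp, spec.pixel_size, cell_id=i)
               for i, rp in enumerate(regions)]
    result = morphology.classify_population(records)
    return 100.0 * result["fraction_mesenchymal"], result["n_cells"]


def recover_size_fold(
    true_fold: float,
    rng: np.random.Generator,
    n_frames: int = N_FRAMES,
    n_cells: int = 300,
    sigma0: float = 50.0,
):
    """Recover the final normalized spheroid size from one rendered
    dissociating-spheroid movie whose sigma schedule ends at
    ``true_fold * sigma0``.
    """
    frame_spec = phantoms.PhantomSpec(
        image_shape=SPHEROID_FIELD, n_frames=n_frames,
        frame_interval=FRAME_INTERVAL_MIN,
    )
    spec = phantoms.SpheroidPhantomSpec(
        n_cells=n_cells, sigma0=sigma0, fold_final=true_fold,
    )
    series, _ = phantoms.generate_spheroid_timelapse(spec, frame_spec, rng=rng)
    ss = dissociation.size_series(series)
    return ss.final_normalized_size


def recover_size_fold_mean(
    true_fold: float,
    seed_seq: np.random.SeedSequence,
    n_seeds: int = 10,
    n_frames: int = N_FRAMES,
):
    """Mean recovered fold over ``n_seeds`` independent movies."""
    children = seed_seq.spawn(n_seeds)
    folds = [
        recover_size_fold(true_fold, np.random.default_rng(child),
                          n_frames=n_frames)
        for child in children
    ]
    return float(np.mean(folds)), folds
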