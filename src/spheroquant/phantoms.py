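"""Synthetic phantom generators with ground-truth sidecars.

Every input the quantification pipeline consumes can be generated here
with known ground truth: a dissociating spheroid rendered as a 2D
Gaussian cell cloud whose scale grows over time, single-cell random-walk
trajectories sampled at the acquisition interval, fields of
non-overlapping elliptical cells with a controlled aspect-ratio
distribution, and confocal-style z-stacks with controlled per-cell
marker intensity.  Sidecars record everything a downstream estimator is
supposed to recover (sigma schedule, positions, diffusion coefficient,
speed, aspect ratios, integrated intensities), so pipeline estimates are
always validated against the sidecar, never against the rendered image
alone.

Defaults mirror the acquisition used in the co-culture spheroid assay:
10X field sampled at 0.65 µm/pixel, one frame every 20 minutes, 109
frames (36 h).  All randomness flows from a single seeded generator per
artifact and the seed is recorded in the sidecar.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .io import ImageSeries, TrajectorySet, write_image_series

__all__ = [
    "PhantomSpec",
    "SpheroidPhantomSpec",
    "TrajectoryPhantomSpec",
    "ShapePhantomSpec",
    "StackPhantomSpec",
    "SpheroidSidecar",
    "generate_spheroid_timelapse",
    "generate_trajectories",
    "generate_shape_image",
    "generate_marker_zstack",
    "render_trajectory_movie",
    "mixture_weight_for_fraction",
]

#: default physical pixel size, µm/pixel (typical 10X objective + CCD)
DEFAULT_PIXEL_SIZE = 0.65
#: acquisition interval, minutes
DEFAULT_FRAME_INTERVAL = 20.0
#: frames per time-lapse movie (36 h at 20 min)
DEFAULT_N_FRAMES = 109


@dataclasses.dataclass
class PhantomSpec:
    """Acquisition geometry shared by all rendered phantoms."""

    image_shape: tuple[int, int] = (1024, 1024)
    pixel_size: float = DEFAULT_PIXEL_SIZE
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    n_frames: int = DEFAULT_N_FRAMES
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def field_um(self) -> tuple[float, float]:
        return (self.image_shape[0] * self.pixel_size,
                self.image_shape[1] * self.pixel_size)


@dataclasses.dataclass
class SpheroidPhantomSpec:
    """A dissociating spheroid: an isotropic 2D Gaussian cell cloud whose
    scale sigma(t) grows linearly from sigma0 to fold_final * sigma0.

    A ``detach_fraction`` of the cells is re-seeded as isolated singles
    uniformly in the annulus [3 * sigma0, field edge], where they stay for
    the whole movie, so dissociated-single counting has unambiguous ground
    truth.
    """

    n_cells: int = 300
    sigma0: float = 50.0           # µm
    fold_final: float = 1.0
    center: tuple[float, float] | None = None  # µm (x, y); None = field center
    cell_radius: float = 5.0       # µm, Gaussian spot scale per cell
    detach_fraction: float = 0.0
    spot_amplitude: float = 100.0  # peak intensity per cell
    background_level: float = 10.0
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.fold_final < 1:
            raise ValueError("fold_final must be >= 1")
        if not 0 <= self.detach_fraction <= 1:
            raise ValueError("detach_fraction must be in [0, 1]")
        if self.n_cells < 1 or self.sigma0 <= 0 or self.cell_radius <= 0:
            raise ValueError("invalid spheroid phantom spec")


@dataclasses.dataclass
class SpheroidSidecar:
    """Ground truth for a rendered spheroid movie (one channel)."""

    sigma_schedule: np.ndarray          # µm per frame
    positions: np.ndarray               # (n_frames, n_cells, 2) µm, (x, y)
    detached_ids: np.ndarray            # cell indices seeded as singles
    clipped: np.ndarray                 # (n_frames, n_cells) bool, outside field
    center: tuple[float, float]         # µm
    seed: int

    def to_frame(self) -> pd.DataFrame:
        n_frames, n_cells, _ = self.positions.shape
        frame = np.repeat(np.arange(n_frames), n_cells)
        cell = np.tile(np.arange(n_cells), n_frames)
        det = np.isin(cell, self.detached_ids)
        return pd.DataFrame({
            "frame": frame,
            "cell_id": cell,
            "x": self.positions[..., 0].ravel(),
            "y": self.positions[..., 1].ravel(),
            "detached": det,
            "clipped": self.clipped.ravel(),
        })

    def save(self, out_dir: str | Path, channel: str = "spheroid") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / f"{channel}_positions.csv", index=False)
        pd.DataFrame({
            "frame": np.arange(len(self.sigma_schedule)),
            "sigma_um": self.sigma_schedule,
        }).to_csv(out / f"{channel}_sigma_schedule.csv", index=False)
        with open(out / f"{channel}_manifest.yaml", "w") as fh:
            yaml.safe_dump({
                "channel": channel,
                "seed": int(self.seed),
                "center_um": [float(self.center[0]), float(self.center[1])],
                "n_detached": int(len(self.detached_ids)),
            }, fh)


def _sigma_schedule(sigma0: float, fold_final: float, n_frames: int) -> np.ndarray:
    if n_frames == 1:
        return np.array([sigma0])
    t = np.linspace(0.0, 1.0, n_frames)
    return sigma0 * (1.0 + (fold_final - 1.0) * t)


def _render_spots(img: np.ndarray, xy_um: np.ndarray, pixel_size: float,
                  radius_um: float, amplitude: float) -> None:
    """Add an isotropic Gaussian spot of scale radius_um at each (x, y)."""
    rows, cols = img.shape
    r_px = radius_um / pixel_size
    half = max(2, int(math.ceil(4 * r_px)))
    for x_um, y_um in xy_um:
        cx = x_um / pixel_size - 0.5  # pixel-center convention
        cy = y_um / pixel_size - 0.5
        c0, r0 = int(round(cx)), int(round(cy))
        rlo, rhi = max(0, r0 - half), min(rows, r0 + half + 1)
        clo, chi = max(0, c0 - half), min(cols, c0 + half + 1)
        if rlo >= rhi or clo >= chi:
            continue
        # separable Gaussian: one outer product instead of a 2D exp grid
        gy = np.exp(-(np.arange(rlo, rhi) - cy)**2 / (2 * r_px * r_px))
        gx = np.exp(-(np.arange(clo, chi) - cx)**2 / (2 * r_px * r_px))
        img[rlo:rhi, clo:chi] += amplitude * np.outer(gy, gx)


def generate_spheroid_timelapse(
    spec: SpheroidPhantomSpec,
    frame_spec: PhantomSpec | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ImageSeries, SpheroidSidecar]:
    """Render a dissociating-spheroid time-lapse with ground truth.

    Core-cell positions are ``center + sigma(t) * z_i`` with per-cell unit
    normals ``z_i`` drawn once, so positions at every frame are an exact
    sample from the isotropic Gaussian of scale sigma(t), trajectories are
    coherent in time, and a static schedule (fold_final = 1) freezes the
    cloud.  Cells whose spot center leaves the field are clipped by the
    renderer and flagged in the sidecar.
    """
    fs = frame_spec or PhantomSpec()
    if rng is None:
        rng = np.random.default_rng(fs.rng_seed)
    rows, cols = fs.image_shape
    field_y, field_x = fs.field_um
    center = spec.center or (field_x / 2, field_y / 2)
    sigma = _sigma_schedule(spec.sigma0, spec.fold_final, fs.n_frames)

    n_det = int(round(spec.detach_fraction * spec.n_cells))
    n_core = spec.n_cells - n_det
    z = rng.standard_normal((n_core, 2))

    # singles: uniform by area in the annulus [3 sigma0, field edge)
    r_outer = min(center[0], center[1], field_x - center[0], field_y - center[1])
    r_outer = max(r_outer - 2 * spec.cell_radius, 3 * spec.sigma0 + spec.cell_radius)
    r_inner = 3 * spec.sigma0
    u = rng.random(n_det)
    r_det = np.sqrt(u * (r_outer**2 - r_inner**2) + r_inner**2)
    th = rng.uniform(0, 2 * np.pi, n_det)
    det_xy = np.column_stack([center[0] + r_det * np.cos(th),
                              center[1] + r_det * np.sin(th)])
    detached_ids = np.arange(n_core, spec.n_cells)

    positions = np.empty((fs.n_frames, spec.n_cells, 2))
    clipped = np.zeros((fs.n_frames, spec.n_cells), dtype=bool)
    stack = np.empty((fs.n_frames, rows, cols), dtype=np.float32)
    for t in range(fs.n_frames):
        xy = np.empty((spec.n_cells, 2))
        xy[:n_core] = np.asarray(center) + sigma[t] * z
        xy[n_core:] = det_xy
        positions[t] = xy
        clipped[t] = ((xy[:, 0] < 0) | (xy[:, 0] >= field_x)
                      | (xy[:, 1] < 0) | (xy[:, 1] >= field_y))
        if spec.noise_sd > 0:
            img = rng.standard_normal((rows, cols), dtype=np.float32)
            img *= spec.noise_sd
            img += spec.background_level
        else:
            img = np.full((rows, cols), spec.background_level, dtype=np.float32)
        _render_spots(img, xy, fs.pixel_size, spec.cell_radius, spec.spot_amplitude)
        np.clip(img, 0, None, out=img)
        stack[t] = img

    series = ImageSeries(stack, fs.pixel_size, fs.frame_interval)
    sidecar = SpheroidSidecar(
        sigma_schedule=sigma, positions=positions, detached_ids=detached_ids,
        clipped=clipped, center=tuple(center), seed=int(fs.rng_seed),
    )
    return series, sidecar


# ---------------------------------------------------------------------------
# trajectories


@dataclasses.dataclass
class TrajectoryPhantomSpec:
    """Random-walk trajectories sampled at the acquisition interval.

    Modes
    -----
    brownian
        i.i.d. Gaussian steps; per-axis step variance 2 * D * dt.
    fixed_step
        every frame-to-frame displacement has magnitude ``step_length``
        exactly, direction uniform on [0, 2pi); speed is then exactly
        step_length / dt.
    prw
        persistent random walk (discrete Ornstein-Uhlenbeck velocity)
        with mean speed scale v and persistence time P; its long-time
        diffusion coefficient is D = v^2 * P / 2.
    """

    n_cells: int = 100
    mode: str = "brownian"
    D: float | None = None            # µm²/min (brownian)
    step_length: float | None = None  # µm per frame (fixed_step)
    v: float | None = None            # µm/min (prw)
    P: float | None = None            # min (prw)
    duration: float = 1020.0          # minutes
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    start_extent: float = 500.0       # µm, initial positions uniform in a box

    def __post_init__(self) -> None:
        if self.mode not in ("brownian", "fixed_step", "prw"):
            raise ValueError(f"unknown mode {self.mode!r}")
        need = {"brownian": ("D",), "fixed_step": ("step_length",),
                "prw": ("v", "P")}[self.mode]
        for name in need:
            val = getattr(self, name)
            if val is None:
                raise ValueError(f"mode {self.mode!r} requires {name}")
            if val < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_cells < 1 or self.duration <= 0 or self.frame_interval <= 0:
            raise ValueError("invalid trajectory phantom spec")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.frame_interval))


def generate_trajectories(
    spec: TrajectoryPhantomSpec,
    rng: np.random.Generator | None = None,
    seed: int = 0,
    condition: str = "",
) -> tuple[TrajectorySet, dict]:
    """Simulate trajectories; the sidecar dict records the true parameters."""
    if rng is None:
        rng = np.random.default_rng(seed)
    dt = spec.frame_interval
    n, m = spec.n_cells, spec.n_steps
    if spec.mode == "brownian":
        steps = rng.normal(0.0, math.sqrt(2 * spec.D * dt), size=(n, m, 2))
    elif spec.mode == "fixed_step":
        th = rng.uniform(0, 2 * np.pi, size=(n, m))
        steps = spec.step_length * np.stack([np.cos(th), np.sin(th)], axis=-1)
    else:  # prw: OU velocity, stationary per-axis sd v/sqrt(2)
        alpha = math.exp(-dt / spec.P) if spec.P > 0 else 0.0
        s = spec.v / math.sqrt(2)
        vel = np.empty((n, m, 2))
        vel[:, 0] = rng.normal(0.0, s, size=(n, 2))
        innov_sd = s * math.sqrt(1 - alpha**2)
        for k in range(1, m):
            vel[:, k] = alpha * vel[:, k - 1] + rng.normal(0, innov_sd, (n, 2))
        steps = vel * dt
    start = rng.uniform(0, spec.start_extent, size=(n, 1, 2))
    pos = np.concatenate([start, start + np.cumsum(steps, axis=1)], axis=1)
    frames = np.tile(np.arange(m + 1), n)
    cells = np.repeat(np.arange(n), m + 1)
    df = pd.DataFrame({
        "cell_id": cells, "frame": frames,
        "x": pos[..., 0].ravel(), "y": pos[..., 1].ravel(),
    })
    ts = TrajectorySet(df, frame_interval=dt, condition=condition)
    sidecar = {
        "mode": spec.mode, "n_cells": n, "n_steps": m,
        "frame_interval": dt, "seed": int(seed),
        "D": spec.D, "step_length": spec.step_length,
        "v": spec.v, "P": spec.P,
        "true_speed": (spec.step_length / dt if spec.mode == "fixed_step"
                       else None),
        "true_D": (spec.D if spec.mode == "brownian"
                   else spec.v**2 * spec.P / 2 if spec.mode == "prw"
                   else None),
    }
    return ts, sidecar


def render_trajectory_movie(
    ts: TrajectorySet,
    frame_spec: PhantomSpec,
    cell_radius: float = 5.0,
    spot_amplitude: float = 100.0,
    background_level: float = 10.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> ImageSeries:
    """Render a trajectory set as a spot movie (detector/linker substrate)."""
    if rng is None:
        rng = np.random.default_rng(frame_spec.rng_seed)
    rows, cols = frame_spec.image_shape
    n_frames = int(ts.data["frame"].max()) + 1
    stack = np.empty((n_frames, rows, cols), dtype=np.float32)
    by_frame = dict(tuple(ts.data.groupby("frame")))
    for t in range(n_frames):
        img = np.full((rows, cols), background_level, dtype=float)
        grp = by_frame.get(t)
        if grp is not None:
            _render_spots(img, grp[["x", "y"]].to_numpy(),
                          frame_spec.pixel_size, cell_radius, spot_amplitude)
        if noise_sd > 0:
            img += rng.normal(0, noise_sd, img.shape)
        stack[t] = np.clip(img, 0, None)
    return ImageSeries(stack, frame_spec.pixel_size, frame_spec.frame_interval)


# ---------------------------------------------------------------------------
# cell shapes


@dataclasses.dataclass
class ShapePhantomSpec:
    """Field of non-overlapping elliptical cells with known aspect ratios.

    Aspect ratios come either from an explicit list (``ar_values``) or from
    a two-component mixture where ``AR - 1`` is lognormal within each
    component (keeping AR >= 1 by construction): ``ar_mixture`` is
    (weight_elongated, (mu_e, sd_e), (mu_r, sd_r)) with mu/sd on the log
    scale of AR - 1.
    """

    n_cells: int = 150
    ar_values: Sequence[float] | None = None
    ar_mixture: tuple[float, tuple[float, float], tuple[float, float]] | None = None
    cell_area: float = 400.0      # µm²
    image_shape: tuple[int, int] = (1500, 1500)
    pixel_size: float = DEFAULT_PIXEL_SIZE
    intensity: float = 100.0
    max_retries: int = 2000

    def __post_init__(self) -> None:
        if (self.ar_values is None) == (self.ar_mixture is None):
            raise ValueError("exactly one of ar_values / ar_mixture required")
        if self.ar_values is not None:
            if len(self.ar_values) != self.n_cells:
                raise ValueError("ar_values length must equal n_cells")
            if any(a < 1 for a in self.ar_values):
                raise ValueError("aspect ratios must be >= 1")


#: default mixture components: log-scale (mu, sd) of AR - 1 for the
#: elongated (mesenchymal-like) and rounded (amoeboid-like) populations
ELONGATED_COMPONENT = (math.log(1.8), 0.35)
ROUNDED_COMPONENT = (math.log(0.45), 0.40)


def mixture_weight_for_fraction(
    target_fraction: float,
    elongated: tuple[float, float] = ELONGATED_COMPONENT,
    rounded: tuple[float, float] = ROUNDED_COMPONENT,
    threshold: float = 2.0,
) -> float:
    """Weight of the elongated component so P(AR >= threshold) = target.

    Within each component AR - 1 is lognormal, so
    P(AR >= thr) = Phi((mu - ln(thr - 1)) / sd) per component, and the
    mixture probability is linear in the weight.
    """
    lt = math.log(threshold - 1.0)
    p_e = float(norm.sf(lt, loc=elongated[0], scale=elongated[1]))
    p_r = float(norm.sf(lt, loc=rounded[0], scale=rounded[1]))
    if not (min(p_e, p_r) - 1e-12 <= target_fraction <= max(p_e, p_r) + 1e-12):
        raise ValueError(
            f"target fraction {target_fraction} outside attainable range "
            f"[{min(p_e, p_r):.3f}, {max(p_e, p_r):.3f}]")
    return float(np.clip((target_fraction - p_r) / (p_e - p_r), 0.0, 1.0))


def _draw_aspect_ratios(spec: ShapePhantomSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.ar_values is not None:
        return np.asarray(spec.ar_values, dtype=float)
    w, (mu_e, sd_e), (mu_r, sd_r) = spec.ar_mixture
    elongated = rng.random(spec.n_cells) < w
    logs = np.where(elongated,
                    rng.normal(mu_e, sd_e, spec.n_cells),
                    rng.normal(mu_r, sd_r, spec.n_cells))
    return 1.0 + np.exp(logs)


def generate_shape_image(
    spec: ShapePhantomSpec,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render non-overlapping ellipses; sidecar lists true geometry per cell.

    Placement is rejection sampling on bounding circles; if the requested
    cells cannot be placed within the retry budget a RuntimeError is
    raised.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    ars = _draw_aspect_ratios(spec, rng)
    rows, cols = spec.image_shape
    px = spec.pixel_size
    area_px = spec.cell_area / px**2
    # semi-axes in px: area = pi * a * b, AR = b / a
    b_semi = np.sqrt(area_px * ars / np.pi)
    a_semi = np.sqrt(area_px / (ars * np.pi))
    order = np.argsort(-b_semi)  # place big cells first

    centers = np.full((spec.n_cells, 2), np.nan)  # (row, col) px
    placed_r = []
    margin = 2.0  # px clearance between bounding circles
    for idx in order:
        r_bound = b_semi[idx]
        ok = False
        for _ in range(spec.max_retries):
            cr = rng.uniform(r_bound + 1, rows - r_bound - 1)
            cc = rng.uniform(r_bound + 1, cols - r_bound - 1)
            if all((cr - pr)**2 + (cc - pc)**2 >= (r_bound + rb + margin)**2
                   for pr, pc, rb in placed_r):
                centers[idx] = (cr, cc)
                placed_r.append((cr, cc, r_bound))
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place {spec.n_cells} non-overlapping cells in "
                f"{spec.image_shape} after {spec.max_retries} retries")

    img = np.zeros((rows, cols), dtype=float)
    thetas = rng.uniform(0, np.pi, spec.n_cells)
    rr_grid, cc_grid = np.mgrid[0:rows, 0:cols]
    for i in range(spec.n_cells):
        cr, cc = centers[i]
        th = thetas[i]
        half = int(math.ceil(b_semi[i])) + 2
        r0, r1 = max(0, int(cr) - half), min(rows, int(cr) + half + 1)
        c0, c1 = max(0, int(cc) - half), min(cols, int(cc) + half + 1)
        dy = rr_grid[r0:r1, c0:c1] - cr
        dx = cc_grid[r0:r1, c0:c1] - cc
        # rotate into the ellipse frame; major axis along theta
        u = dx * math.cos(th) + dy * math.sin(th)
        v = -dx * math.sin(th) + dy * math.cos(th)
        inside = (u / b_semi[i])**2 + (v / a_semi[i])**2 <= 1.0
        img[r0:r1, c0:c1][inside] = spec.intensity

    sidecar = pd.DataFrame({
        "cell_id": np.arange(spec.n_cells),
        "center_row": centers[:, 0], "center_col": centers[:, 1],
        "semi_major_px": b_semi, "semi_minor_px": a_semi,
        "orientation_rad": thetas,
        "aspect_ratio": ars,
    })
    return img, sidecar


# ---------------------------------------------------------------------------
# marker z-stacks


@dataclasses.dataclass
class StackPhantomSpec:
    """Confocal-style z-stack with controlled per-cell marker intensity.

    Each positive cell is rendered in one slice as a Gaussian spot whose
    pixel sum equals ``per_cell_intensity`` exactly, on a constant
    ``background_level`` per slice, so total signal above background is
    n_positive_cells * per_cell_intensity before noise and is conserved
    under any permutation of the slices.
    """

    n_slices: int = 6
    slice_thickness: float = 13.36   # µm
    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = DEFAULT_PIXEL_SIZE
    per_cell_intensity: float = 1000.0
    background_level: float = 5.0
    n_positive_cells: int = 10
    cell_radius: float = 5.0         # µm
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.n_positive_cells < 0 or self.per_cell_intensity < 0:
            raise ValueError("invalid stack phantom spec")


def generate_marker_zstack(
    spec: StackPhantomSpec,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render the z-stack; sidecar records per-cell integrated intensity."""
    if rng is None:
        rng = np.random.default_rng(seed)
    rows, cols = spec.image_shape
    stack = np.full((spec.n_slices, rows, cols), spec.background_level,
                    dtype=float)
    r_px = spec.cell_radius / spec.pixel_size
    half = max(2, int(math.ceil(4 * r_px)))
    recs = []
    for i in range(spec.n_positive_cells):
        z = int(rng.integers(spec.n_slices))
        cr = rng.uniform(half + 1, rows - half - 2)
        cc = rng.uniform(half + 1, cols - half - 2)
        yy = np.arange(int(cr) - half, int(cr) + half + 1)[:, None] - cr
        xx = np.arange(int(cc) - half, int(cc) + half + 1)[None, :] - cc
        kernel = np.exp(-(xx**2 + yy**2) / (2 * r_px**2))
        kernel *= spec.per_cell_intensity / kernel.sum()
        stack[z, int(cr) - half:int(cr) + half + 1,
              int(cc) - half:int(cc) + half + 1] += kernel
        recs.append({"cell_id": i, "slice": z,
                     "row": cr, "col": cc,
                     "integrated_intensity": spec.per_cell_intensity})
    if spec.noise_sd > 0:
        stack += rng.normal(0, spec.noise_sd, stack.shape)
        stack = np.clip(stack, 0, None)
    sidecar = pd.DataFrame(
        recs, columns=["cell_id", "slice", "row", "col", "integrated_intensity"])
    return stack, sidecar


def save_phantom_movie(series: ImageSeries, sidecar: SpheroidSidecar,
                       out_dir: str | Path, name: str = "spheroid") -> None:
    """Write a rendered movie plus its ground-truth sidecar files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_image_series(series, out / name)
    sidecar.save(out, channel=name)
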