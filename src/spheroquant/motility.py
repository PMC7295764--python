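"""Cell motility statistics from trajectories.

Speed, time-averaged mean-squared displacement (MSD), the 2D diffusion
coefficient from the first-order model MSD = 4 D tau, and directional
statistics with respect to the flow axis (+x): net velocity Vx and the
forward-migration persistence index Px = net x-displacement / path
length.  A minimal detector/linker (Laplacian-of-Gaussian spot detection
plus gated mutual-nearest-neighbor linking) produces trajectories from
movies of sparse cells.

Cells enter tracking at different times; all statistics use
track-relative time, so tracks of different absolute start are pooled.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage.feature import blob_log

from .io import ImageSeries, TrajectorySet

__all__ = [
    "MSDCurve",
    "MotilitySummary",
    "DetectLinkParams",
    "compute_speed",
    "compute_msd",
    "fit_diffusion_coefficient",
    "directional_stats",
    "detect_and_link",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class MSDCurve:
    lags: np.ndarray      # minutes, starting at 0
    msd: np.ndarray       # µm²
    n_pairs: np.ndarray   # displacement pairs contributing per lag

    def __post_init__(self) -> None:
        if self.msd[0] != 0:
            raise ValueError("msd at lag 0 must be 0")
        if np.any(self.n_pairs[1:] <= 0):
            raise ValueError("reported lags must have positive pair counts")


@dataclasses.dataclass
class MotilitySummary:
    per_cell: pd.DataFrame   # cell_id, speed, vx, px, n_steps
    mean_speed: float
    sem_speed: float
    D: float | None = None
    D_se: float | None = None


def _cell_arrays(ts: TrajectorySet):
    """Yield (cell_id, frames, xy) with track-relative frame indices."""
    for cid, grp in ts.data.groupby("cell_id", sort=False):
        f = grp["frame"].to_numpy()
        xy = grp[["x", "y"]].to_numpy(dtype=float)
        yield cid, f - f[0], xy


def compute_speed(ts: TrajectorySet) -> MotilitySummary:
    """Per-cell mean speed and the group mean ± SEM over cells.

    Per-cell speed is total path length divided by elapsed time
    (frame gaps contribute their true elapsed time).  Cells observed in a
    single frame are excluded with a logged count.
    """
    recs, skipped = [], 0
    for cid, f, xy in _cell_arrays(ts):
        if len(f) < 2:
            skipped += 1
            continue
        path = float(np.sum(np.hypot(*np.diff(xy, axis=0).T)))
        elapsed = float(f[-1]) * ts.frame_interval
        recs.append({"cell_id": cid, "speed": path / elapsed,
                     "n_steps": len(f) - 1})
    if skipped:
        log.info("excluded %d single-frame cells from speed", skipped)
    if not recs:
        raise ValueError("no cell has >= 2 frames")
    df = pd.DataFrame(recs)
    speeds = df["speed"].to_numpy()
    sem = speeds.std(ddof=1) / np.sqrt(speeds.size) if speeds.size > 1 else np.nan
    return MotilitySummary(per_cell=df, mean_speed=float(speeds.mean()),
                           sem_speed=float(sem))


def compute_msd(ts: TrajectorySet, max_lag_fraction: float = 0.25) -> MSDCurve:
    """Time-averaged then ensemble-averaged MSD with pair-count weighting.

    Within each cell the squared displacement at lag k frames is averaged
    over all start times (overlapping windows); cells are pooled by
    summing squared displacements and pair counts per lag.  Lags are
    reported up to ``max_lag_fraction`` of the shortest track duration.
    """
    if not 0 < max_lag_fraction <= 1:
        raise ValueError("max_lag_fraction in (0, 1] required")
    cells = [(f, xy) for _, f, xy in _cell_arrays(ts) if len(f) >= 2]
    if not cells:
        raise ValueError("need at least one cell with >= 2 frames")
    min_span = min(int(f[-1]) for f, _ in cells)
    max_lag = max(1, int(np.floor(max_lag_fraction * min_span)))
    sums = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1)
    counts[0] = sum(len(f) for f, _ in cells)
    for f, xy in cells:
        span = int(f[-1])
        grid = np.full((span + 1, 2), np.nan)
        grid[f.astype(int)] = xy
        for k in range(1, min(max_lag, span) + 1):
            d = grid[k:] - grid[:-k]
            sq = d[:, 0] ** 2 + d[:, 1] ** 2
            valid = ~np.isnan(sq)
            sums[k] += np.nansum(sq[valid])
            counts[k] += valid.sum()
    reported = counts > 0
    reported[0] = True
    lags = np.arange(max_lag + 1)[reported] * ts.frame_interval
    msd = np.zeros(reported.sum())
    msd[1:] = sums[reported][1:] / counts[reported][1:]
    return MSDCurve(lags=lags, msd=msd, n_pairs=counts[reported])


def fit_diffusion_coefficient(curve: MSDCurve) -> tuple[float, float]:
    """Fit MSD = 4 D tau through the origin, weighted by pair counts.

    Returns (D, SE).  The model has no intercept (the first-order 2D
    diffusion form); a negative slope is reported with a warning rather
    than clamped.
    """
    tau = curve.lags[1:]
    msd = curve.msd[1:]
    w = curve.n_pairs[1:].astype(float)
    if tau.size < 3:
        raise ValueError("need >= 3 nonzero lags to fit")
    sw = np.sqrt(w)
    X = (4.0 * tau * sw)[:, None]
    yv = msd * sw
    sol, *_ = np.linalg.lstsq(X, yv, rcond=None)
    D = float(sol[0])
    resid = yv - X[:, 0] * D
    dof = max(tau.size - 1, 1)
    se = float(np.sqrt((resid @ resid) / dof / (X[:, 0] @ X[:, 0])))
    if D < 0:
        log.warning("negative diffusion slope fitted (D = %g)", D)
    return D, se


def directional_stats(
    ts: TrajectorySet, flow_axis: tuple[float, float] = (1.0, 0.0)
) -> tuple[pd.DataFrame, dict]:
    """Net velocity Vx and persistence Px along the flow axis per cell.

    Vx = net displacement along the axis / elapsed time; Px = net
    displacement along the axis / total path length (forward-migration
    index, in [-1, 1]).  The group test is a one-sample t-test of Vx
    against 0 (no directional bias).
    """
    ax = np.asarray(flow_axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    recs, excluded = [], 0
    for cid, f, xy in _cell_arrays(ts):
        if len(f) < 2:
            continue
        net = xy[-1] - xy[0]
        net_ax = float(net @ ax)
        path = float(np.sum(np.hypot(*np.diff(xy, axis=0).T)))
        elapsed = float(f[-1]) * ts.frame_interval
        if path == 0:
            excluded += 1
            continue
        recs.append({"cell_id": cid, "vx": net_ax / elapsed, "px": net_ax / path})
    if excluded:
        log.info("excluded %d zero-path cells from Px", excluded)
    if not recs:
        raise ValueError("no usable cells")
    df = pd.DataFrame(recs)
    vx = df["vx"].to_numpy()
    if vx.size > 1 and vx.std(ddof=1) > 0:
        t, p = sps.ttest_1samp(vx, 0.0)
    else:
        t, p = (0.0, 1.0) if np.allclose(vx, 0) else (np.inf, 0.0)
    group = {
        "mean_vx": float(vx.mean()),
        "sem_vx": float(vx.std(ddof=1) / np.sqrt(vx.size)) if vx.size > 1 else np.nan,
        "mean_px": float(df["px"].mean()),
        "t_statistic": float(t),
        "p_value": float(p),
        "n_cells": int(vx.size),
    }
    return df, group


# ---------------------------------------------------------------------------
# detection and linking


@dataclasses.dataclass
class DetectLinkParams:
    """Parameters for the LoG detector and nearest-neighbor linker.

    ``gate`` (µm) is the maximum frame-to-frame displacement accepted by
    the linker; a sensible default is 4x the expected step.  ``exclude_center``
    and ``exclude_radius`` mask a circular core region (e.g. the spheroid
    body) where single cells cannot be resolved.
    """

    spot_radius: float = 5.0       # µm, expected cell spot scale
    threshold: float = 0.05        # blob_log threshold on normalized image
    gate: float = 16.0             # µm
    min_track_length: int = 5      # frames
    exclude_center: tuple[float, float] | None = None  # µm
    exclude_radius: float = 0.0    # µm


def _detect_frame(img: np.ndarray, pixel_size: float,
                  params: DetectLinkParams) -> np.ndarray:
    """LoG spot detection; returns (n, 2) array of (x, y) in µm."""
    img = np.asarray(img, dtype=float)
    lo = np.percentile(img, 5)
    hi = img.max()
    if hi <= lo:
        return np.empty((0, 2))
    normed = np.clip((img - lo) / (hi - lo), 0, 1)
    sigma_px = params.spot_radius / pixel_size
    blobs = blob_log(normed, min_sigma=0.5 * sigma_px, max_sigma=1.5 * sigma_px,
                     num_sigma=5, threshold=params.threshold)
    if blobs.size == 0:
        return np.empty((0, 2))
    xy = np.column_stack([blobs[:, 1], blobs[:, 0]]) * pixel_size
    if params.exclude_center is not None and params.exclude_radius > 0:
        d = np.hypot(xy[:, 0] - params.exclude_center[0],
                     xy[:, 1] - params.exclude_center[1])
        xy = xy[d > params.exclude_radius]
    return xy


def _mutual_nn_links(prev: np.ndarray, new: np.ndarray, gate: float):
    """Pairs (i, j) where prev[i] and new[j] are mutual nearest neighbors
    within the gate distance."""
    if len(prev) == 0 or len(new) == 0:
        return []
    d = np.hypot(prev[:, None, 0] - new[None, :, 0],
                 prev[:, None, 1] - new[None, :, 1])
    nn_fwd = d.argmin(axis=1)
    nn_bwd = d.argmin(axis=0)
    links = []
    for i, j in enumerate(nn_fwd):
        if nn_bwd[j] == i and d[i, j] <= gate:
            links.append((i, int(j)))
    return links


def detect_and_link(
    series: ImageSeries,
    channel: str | None = None,
    params: DetectLinkParams | None = None,
) -> TrajectorySet:
    """Detect spots per frame and link them into tracks.

    Greedy mutual-nearest-neighbor linking with a displacement gate and
    no gap closing: a track that misses one frame terminates, and an
    unmatched detection starts a new track.  Tracks shorter than
    ``min_track_length`` frames are dropped.  A gate smaller than the
    true step fragments tracks — the documented failure mode.
    """
    params = params or DetectLinkParams()
    stack = series.channel(channel)
    records: list[dict] = []
    active: dict[int, np.ndarray] = {}   # track_id -> last position
    next_id = 0
    n_detections = 0
    for t in range(series.n_frames):
        det = _detect_frame(stack[t], series.pixel_size, params)
        n_detections += len(det)
        ids = list(active.keys())
        prev = np.array([active[i] for i in ids]) if ids else np.empty((0, 2))
        links = _mutual_nn_links(prev, det, params.gate)
        linked_tracks = set()
        linked_dets = set()
        for i, j in links:
            tid = ids[i]
            records.append({"cell_id": tid, "frame": t,
                            "x": det[j, 0], "y": det[j, 1]})
            active[tid] = det[j]
            linked_tracks.add(tid)
            linked_dets.add(j)
        for tid in list(active):
            if tid not in linked_tracks:
                del active[tid]        # no gap closing
        for j in range(len(det)):
            if j not in linked_dets:
                records.append({"cell_id": next_id, "frame": t,
                                "x": det[j, 0], "y": det[j, 1]})
                active[next_id] = det[j]
                next_id += 1
    if not records:
        log.warning("zero detections in movie")
        df = pd.DataFrame(columns=["cell_id", "frame", "x", "y"])
        return TrajectorySet(df, frame_interval=series.frame_interval)
    df = pd.DataFrame(records)
    lengths = df.groupby("cell_id")["frame"].size()
    keep = lengths[lengths >= params.min_track_length].index
    df = df[df["cell_id"].isin(keep)].reset_index(drop=True)
    return TrajectorySet(df, frame_interval=series.frame_interval)
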