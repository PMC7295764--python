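"""Study conditions of the co-culture spheroid interstitial-flow assay.

These constants parameterize the synthetic phantoms so that recovery
benchmarks run under the same conditions as the assay they emulate:
cohort sizes, track durations, acquisition timing, and the per-condition
ground-truth values (mean speed, diffusion coefficient, endpoint
spheroid-size fold, mesenchymal percentage) that the pipeline is asked
to recover.
"""

from __future__ import annotations

import dataclasses

__all__ = [
    "MotilityCondition",
    "MOTILITY_CONDITIONS",
    "SIZE_FOLD_CONDITIONS",
    "MESENCHYMAL_PERCENT",
    "FRAME_INTERVAL_MIN",
    "N_FRAMES",
    "MOVIE_DURATION_H",
]

#: time-lapse acquisition: one frame every 20 min, 109 frames = 36 h
FRAME_INTERVAL_MIN = 20.0
N_FRAMES = 109
MOVIE_DURATION_H = 36.0


@dataclasses.dataclass(frozen=True)
class MotilityCondition:
    """Ground truth for one cell line x flow condition motility cohort."""

    cell_line: str
    flow: bool
    n_cells: int
    duration_h: float       # common track duration used for the MSD
    mean_speed: float       # µm/min
    D: float                # µm²/min


MOTILITY_CONDITIONS = {
    # metastatic line, tracked 17 h
    "mda_flow": MotilityCondition("MDA-MB-231", True, 121, 17.0, 0.30, 6.41),
    "mda_control": MotilityCondition("MDA-MB-231", False, 169, 17.0, 0.23, 4.23),
    # non-tumorigenic epithelial line, tracked 10 h
    "mcf_flow": MotilityCondition("MCF-10A", True, 107, 10.0, 0.33, 3.44),
    "mcf_control": MotilityCondition("MCF-10A", False, 46, 10.0, 0.20, 0.55),
}

#: normalized spheroid size (sigma at 36 h / sigma at 0 h) per condition
SIZE_FOLD_CONDITIONS = {
    "mda_flow": 3.8,
    "mda_control": 1.7,
    "mcf_flow": 3.6,
    "mcf_control": 1.5,
}

#: percentage of mesenchymal (AR >= 2) cells among invading tumor cells
MESENCHYMAL_PERCENT = {"control": 79.0, "flow": 24.0}
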