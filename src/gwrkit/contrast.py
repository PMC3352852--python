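"""Gray-to-white matter intensity ratio (GWR).

GWR(v) = GM(v) / WM(v), the per-vertex ratio of the gray-matter sample
inside the ribbon to the white-matter sample just below the gray/white
border.  On T1-weighted data WM is brighter than GM, so GWR lies in (0, 1);
values approaching 1 mean the two tissues are becoming indistinguishable,
i.e. *reduced* tissue contrast.  A ratio (not a difference) is used because
it is invariant to any global intensity scaling of the volume — scanner
gain drops out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .mesh import VertexMap

__all__ = ["ContrastConfig", "compute_gwr", "default_wm_floor"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContrastConfig:
    """Denominator guard for the ratio.

    ``min_wm_intensity``: WM samples below this floor (near-zero or
    CSF-contaminated) make the ratio explode; such vertices are marked
    missing instead.
    """

    min_wm_intensity: float = 1e-6

    def __post_init__(self) -> None:
        if self.min_wm_intensity <= 0:
            raise ValueError("min_wm_intensity must be positive")


def default_wm_floor(wm: VertexMap, fraction: float = 0.05) -> float:
    """Default denominator floor: ``fraction`` of the robust WM median."""
    valid = wm.valid_values()
    if valid.size == 0:
        return 1e-6
    return max(float(fraction * np.median(valid)), 1e-6)


def compute_gwr(gm: VertexMap, wm: VertexMap, cfg: ContrastConfig | None = None) -> VertexMap:
    """Per-vertex GWR = gm / wm; missing where either input is missing or
    the WM sample falls below the configured floor.

    With ``cfg=None`` the floor defaults to 5% of the robust WM median.
    Values outside the T1-expected (0, 1) range are kept (they are data) but
    counted and logged.
    """
    if len(gm) != len(wm):
        raise ValueError(f"map lengths differ: gm {len(gm)} vs wm {len(wm)}")
    if cfg is None:
        cfg = ContrastConfig(min_wm_intensity=default_wm_floor(wm))
    low_wm = ~wm.missing & (wm.values < cfg.min_wm_intensity)
    missing = gm.missing | wm.missing | low_wm
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = gm.values / wm.values
    ratio[missing] = np.nan
    out_of_range = ~missing & ((ratio <= 0) | (ratio >= 1))
    if low_wm.any() or out_of_range.any():
        logger.info(
            "GWR: %d vertices below WM floor %.3g, %d outside (0, 1)",
            int(low_wm.sum()),
            cfg.min_wm_intensity,
            int(out_of_range.sum()),
        )
    return VertexMap(ratio, name="gwr")
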