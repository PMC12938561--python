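"""Percentile-based intensity normalization.

MRI intensities are not on a standard scale; scanner and protocol
differences shift and stretch histograms arbitrarily. Each modality is
therefore mapped to [0, 1] using robust percentile bounds computed over
brain voxels only (strictly positive intensities, the skull-stripped
convention): values at or below the lower percentile map to 0, values at
or above the upper percentile map to 1, and the map is linear in between.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormalizationParams:
    """Percentile bounds for intensity normalization.

    ``low_percentile=2`` and ``high_percentile=98`` trim extreme outliers
    (hemorrhage, saturation artifacts) before rescaling. ``epsilon`` guards
    against a degenerate (near-constant) intensity range.
    """

    low_percentile: float = 2.0
    high_percentile: float = 98.0
    epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if not (0 <= self.low_percentile < self.high_percentile <= 100):
            raise ValueError(
                f"require 0 <= low < high <= 100, got "
                f"({self.low_percentile}, {self.high_percentile})"
            )


def percentile_normalize(channel: np.ndarray,
                         params: NormalizationParams = NormalizationParams()
                         ) -> np.ndarray:
    """Map one modality grid to [0, 1] by robust percentile rescaling.

    Percentiles (linear interpolation between order statistics) are
    computed only over strictly positive voxels; the zero background stays
    at 0. Values outside the percentile window are clamped so the output
    is always within [0, 1].

    A degenerate range (``p_high - p_low < epsilon``, e.g. a constant
    foreground) yields all positive voxels set to 0 with a logged
    diagnostic rather than an exception, so flat inputs do not abort
    batch runs.

    Raises
    ------
    ValueError
        If the grid contains no strictly positive voxel.
    """
    channel = np.asarray(channel, dtype=np.float64)
    positive = channel > 0
    if not positive.any():
        raise ValueError("no strictly positive voxel: cannot normalize")
    vals = channel[positive]
    p_lo, p_hi = np.percentile(vals, [params.low_percentile, params.high_percentile])
    out = np.zeros_like(channel)
    if p_hi - p_lo < params.epsilon:
        log.warning(
            "degenerate intensity range (p%g=%g, p%g=%g): positive voxels set to 0",
            params.low_percentile, p_lo, params.high_percentile, p_hi,
        )
        return out
    out[positive] = np.clip((vals - p_lo) / (p_hi - p_lo), 0.0, 1.0)
    return out


def minmax_normalize(channel: np.ndarray) -> np.ndarray:
    """Plain min-max rescaling over positive voxels (ablation arm).

    Unlike the percentile map this is sensitive to single-voxel outliers;
    it exists to quantify what the robust percentile bounds contribute.
    """
    channel = np.asarray(channel, dtype=np.float64)
    positive = channel > 0
    if not positive.any():
        raise ValueError("no strictly positive voxel: cannot normalize")
    vals = channel[positive]
    lo, hi = vals.min(), vals.max()
    out = np.zeros_like(channel)
    if hi - lo < 1e-12:
        return out
    out[positive] = (vals - lo) / (hi - lo)
    return out
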