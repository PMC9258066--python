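"""Refractometry-to-density conversion and heavy/middle/light classification.

Gradient fractions are characterized by refractive index (nD at 20 degC)
measured after isopycnic centrifugation in CsTFA; a linear calibration
maps nD to buoyant density (g/mL). The paper-level analysis then only
needs each fraction assigned to a density class: *heavy* (where
13C-labelled RNA equilibrates), *light* (unlabelled RNA), *middle*
(between the windows) or *unassigned* (outside the gradient span).

The default calibration (slope 10.0, intercept -12.0) places the
RNA-in-CsTFA working range 1.76-1.83 g/mL at nD 1.376-1.383 and is a
package convention, not a measured constant: calibrate your own
refractometer and override ``ri_calibration`` in the config.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ConfigError, ValidationError
from .io_tables import FractionMeta, PipelineConfig


@dataclass(frozen=True)
class DensityCalibration:
    """Linear nD -> buoyant density map: density = slope * ri + intercept."""

    slope: float  # (g/mL) per refractive-index unit
    intercept: float  # g/mL

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ConfigError(f"calibration slope must be > 0, got {self.slope}")


def calibration_from_config(cfg: PipelineConfig) -> DensityCalibration:
    return DensityCalibration(
        slope=float(cfg.ri_calibration["slope"]),
        intercept=float(cfg.ri_calibration["intercept"]),
    )


def ri_to_density(
    ri: float | np.ndarray,
    cal: DensityCalibration,
    ri_window: tuple[float, float] = (1.35, 1.42),
) -> float | np.ndarray:
    """Convert refractive index to buoyant density (g/mL).

    Values outside `ri_window` raise :class:`ValidationError` — the usual
    cause is a swapped nD / density column, so the guard is strict.
    """
    arr = np.asarray(ri, dtype=float)
    lo, hi = ri_window
    if np.any(arr < lo) or np.any(arr > hi):
        bad = arr[(arr < lo) | (arr > hi)]
        raise ValidationError(
            f"refractive index {np.atleast_1d(bad)[0]} outside plausible "
            f"window [{lo}, {hi}] (nD/density columns swapped?)"
        )
    out = cal.slope * arr + cal.intercept
    return float(out) if np.isscalar(ri) else out


def density_to_ri(density: float, cal: DensityCalibration) -> float:
    """Inverse calibration, used by the simulator to emit realistic nD."""
    return (density - cal.intercept) / cal.slope


def classify_density(
    density: float,
    heavy_window: tuple[float, float],
    light_window: tuple[float, float],
) -> str:
    if heavy_window[0] <= density <= heavy_window[1]:
        return "heavy"
    if light_window[0] <= density <= light_window[1]:
        return "light"
    # between the two windows -> middle; outside the gradient span -> unassigned
    inner_lo = min(heavy_window[1], light_window[1])
    inner_hi = max(heavy_window[0], light_window[0])
    if inner_lo < density < inner_hi:
        return "middle"
    return "unassigned"


def classify_fractions(
    fractions: Sequence[FractionMeta], cfg: PipelineConfig
) -> list[FractionMeta]:
    """Assign each fraction a density class from the configured windows.

    Buoyant density is taken from the metadata when present, otherwise
    computed from the refractive index through the configured calibration.
    Returns new records; the inputs are not mutated. Classification
    depends only on density and windows (order-independent).
    """
    cal = calibration_from_config(cfg)
    out = []
    for frac in fractions:
        density = frac.buoyant_density
        if density is None:
            density = ri_to_density(frac.refractive_index, cal, cfg.ri_window)
        cls = classify_density(density, cfg.heavy_density_window, cfg.light_density_window)
        out.append(replace(frac, buoyant_density=density, density_class=cls))
    return out
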