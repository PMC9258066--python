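"""delta-13C computation and two-point normalization to the VPDB scale.

Stable carbon isotope ratios are reported in delta notation,

    delta = (R_sample / R_reference - 1) * 1000   [per mil],

and instrument-scale deltas are normalized to the international VPDB
scale by a linear map fitted through certified reference standards
(commonly USGS40 and USGS41) measured within the sequence. With exactly
two distinct standards the map is exact; with more it is least squares.
Certified values are inputs, never constants baked into the package.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import NumericalError, ValidationError

#: wide default plausibility window — 13C-labelled tissue can reach
#: strongly positive deltas
DELTA_WINDOW = (-100.0, 1000.0)


@dataclass
class DeltaMeasurement:
    sample_id: str
    delta_raw: float  # per mil, instrument scale
    material: str = "sample"  # "sample" | "standard"
    certified_delta: float | None = None  # per mil, standards only
    delta_vpdb: float | None = None

    def __post_init__(self) -> None:
        if self.material not in ("sample", "standard"):
            raise ValidationError(
                f"{self.sample_id!r}: material must be 'sample' or 'standard'"
            )
        if self.material == "standard" and self.certified_delta is None:
            raise ValidationError(
                f"standard {self.sample_id!r} lacks a certified delta value"
            )
        if not (DELTA_WINDOW[0] <= self.delta_raw <= DELTA_WINDOW[1]):
            raise ValidationError(
                f"{self.sample_id!r}: delta {self.delta_raw} per mil outside "
                f"plausibility window {DELTA_WINDOW}"
            )


def delta_from_ratio(r_sample: float, r_reference: float) -> float:
    """Per-mil delta of an isotope ratio against a reference ratio."""
    if r_sample <= 0 or r_reference <= 0:
        raise ValidationError("isotope ratios must be > 0")
    return (r_sample / r_reference - 1.0) * 1000.0


def ratio_from_delta(delta: float, r_reference: float) -> float:
    """Inverse of :func:`delta_from_ratio`."""
    if r_reference <= 0:
        raise ValidationError("reference ratio must be > 0")
    return (delta / 1000.0 + 1.0) * r_reference


def fit_normalization(measurements: Sequence[DeltaMeasurement]) -> tuple[float, float]:
    """Fit the linear instrument-scale -> certified-scale map.

    Replicate measurements of a standard (same sample_id) are averaged
    before fitting. Exact through two distinct standards; least squares
    beyond. Raises :class:`NumericalError` when all standards share one
    certified value (degenerate calibration).
    """
    standards: dict[str, list[float]] = {}
    certified: dict[str, float] = {}
    for m in measurements:
        if m.material == "standard":
            standards.setdefault(m.sample_id, []).append(m.delta_raw)
            certified[m.sample_id] = float(m.certified_delta)
    if len(standards) < 2:
        raise ValidationError("two-point normalization needs >= 2 standards")
    measured = np.array([np.mean(standards[s]) for s in sorted(standards)])
    cert = np.array([certified[s] for s in sorted(standards)])
    if np.ptp(cert) == 0:
        raise NumericalError("standards share one certified value; calibration degenerate")
    if np.ptp(measured) == 0:
        raise NumericalError("standards measured identically; calibration degenerate")
    slope, intercept = np.polyfit(measured, cert, 1)
    return float(slope), float(intercept)


def normalize_two_point(
    measurements: Sequence[DeltaMeasurement],
) -> list[DeltaMeasurement]:
    """Apply the fitted standard calibration to every measurement."""
    slope, intercept = fit_normalization(measurements)
    return [
        replace(m, delta_vpdb=slope * m.delta_raw + intercept) for m in measurements
    ]


def read_delta_table(path: str | Path) -> list[DeltaMeasurement]:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "delta_raw", "material"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    out = []
    for _, row in df.iterrows():
        cert = row.get("certified_delta")
        out.append(
            DeltaMeasurement(
                sample_id=str(row["sample_id"]),
                delta_raw=float(row["delta_raw"]),
                material=str(row["material"]),
                certified_delta=float(cert) if pd.notna(cert) else None,
            )
        )
    return out


def write_delta_table(measurements: Sequence[DeltaMeasurement], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "delta_raw": m.delta_raw,
                "material": m.material,
                "certified_delta": m.certified_delta,
                "delta_vpdb": m.delta_vpdb,
            }
            for m in measurements
        ]
    ).to_csv(path, sep="\t", index=False)
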