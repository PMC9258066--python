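"""Potential methanol consumption rates from 14C-methanol incubations.

Plant material incubated with 14C-methanol releases 14CO2 through
biological oxidation; the CO2 is captured in NaOH traps collected at
intervals, while volatilized methanol is caught in a cold-water trap.
The cumulative trapped 14C activity grows linearly over short
incubations, so the consumption rate follows from the regression slope:

    rate [nmol / (g dry wt h)] = slope [Bq/h] / (specific_activity [Bq/nmol] * dry_mass [g])

The specific activity of the administered methanol is a required user
input — there is no defensible default. The regression keeps a free
intercept (it absorbs trap lag and is reported for audit); a negative
fitted slope is reported as rate 0 with an explicit flag, since
consumption is physically non-negative.

QC helpers: `mass_balance` accounts administered activity recovered as
CO2 vs volatile methanol, and `cross_check` compares NaOH-trap
activities against BaCO3-precipitate recounts (percent excess and R²).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import NumericalError, ValidationError

#: recoveries above 1 + this are flagged, not fatal
RECOVERY_TOLERANCE = 0.02


@dataclass
class TrapSeries:
    """One radiotracer incubation: CO2-trap time series plus bookkeeping.

    `co2_activity` is CUMULATIVE trapped activity (Bq); use
    :func:`interval_to_cumulative` for per-collection increments.
    """

    times: np.ndarray  # h, strictly increasing
    co2_activity: np.ndarray  # Bq, cumulative
    administered_activity: float  # Bq
    dry_mass: float  # g dry weight
    specific_activity: float | None = None  # Bq / nmol, user-supplied
    methanol_trap_activity: float = 0.0  # Bq, end-of-run water trap
    label: dict = field(default_factory=dict)  # species / compartment / replicate

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.co2_activity = np.asarray(self.co2_activity, dtype=float)
        if self.times.size < 2:
            raise ValidationError("trap series needs >= 2 timepoints")
        if self.times.shape != self.co2_activity.shape:
            raise ValidationError("times and co2_activity lengths differ")
        if not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")
        if (self.co2_activity < 0).any():
            raise ValidationError("negative trapped activity")
        if self.administered_activity <= 0:
            raise ValidationError("administered_activity must be > 0")
        if self.dry_mass <= 0:
            raise ValidationError("dry_mass must be > 0")
        if self.specific_activity is not None and self.specific_activity <= 0:
            raise ValidationError("specific_activity must be > 0 when given")
        if self.methanol_trap_activity < 0:
            raise ValidationError("negative methanol trap activity")


@dataclass
class RateResult:
    slope: float  # Bq/h
    intercept: float  # Bq
    r_squared: float
    rate: float  # nmol / (g dry wt h)
    co2_recovery: float
    methanol_recovery: float
    total_recovery: float
    negative_slope: bool = False
    recovery_flag: bool = False
    label: dict = field(default_factory=dict)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS with intercept; R² defined as 1 for an exact fit to constant y."""
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-12 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), float(min(max(r2, 0.0), 1.0))


def fit_turnover_slope(series: TrapSeries) -> dict:
    """Regress cumulative CO2-trap activity on time (OLS, free intercept)."""
    slope, intercept, r2 = _ols(series.times, series.co2_activity)
    return {"slope": slope, "intercept": intercept, "r_squared": r2}


def consumption_rate(slope: float, series: TrapSeries) -> float:
    """Convert a trap-accumulation slope (Bq/h) to nmol / (g dry wt h).

    Negative slopes map to rate 0 (flagged by :func:`analyze_series`).
    """
    if series.specific_activity is None:
        raise ValidationError(
            "specific_activity (Bq/nmol) is required to convert slope to a rate"
        )
    return max(slope, 0.0) / (series.specific_activity * series.dry_mass)


def mass_balance(series: TrapSeries) -> dict:
    """Proportions of administered activity recovered in each trap."""
    co2 = float(series.co2_activity[-1]) / series.administered_activity
    meoh = series.methanol_trap_activity / series.administered_activity
    total = co2 + meoh
    return {
        "co2_recovery": co2,
        "methanol_recovery": meoh,
        "total_recovery": total,
        "recovery_flag": total > 1.0 + RECOVERY_TOLERANCE,
    }


def cross_check(naoh_activities: np.ndarray, baco3_activities: np.ndarray) -> dict:
    """Compare NaOH-trap activities to BaCO3 recounts of the same CO2.

    Returns the percent excess of total BaCO3 activity over total NaOH
    activity, and R² from an OLS of BaCO3 on NaOH.
    """
    naoh = np.asarray(naoh_activities, dtype=float)
    baco3 = np.asarray(baco3_activities, dtype=float)
    if naoh.shape != baco3.shape or naoh.size < 2:
        raise ValidationError("cross_check needs equal-length vectors with n >= 2")
    total_naoh = naoh.sum()
    if total_naoh == 0:
        raise NumericalError("total NaOH activity is zero; percent excess undefined")
    _, _, r2 = _ols(naoh, baco3)
    return {
        "percent_excess": 100.0 * (baco3.sum() - total_naoh) / total_naoh,
        "r_squared": r2,
    }


def interval_to_cumulative(interval_activities: np.ndarray) -> np.ndarray:
    """Running sum converting per-collection trap activities to cumulative."""
    arr = np.asarray(interval_activities, dtype=float)
    if (arr < 0).any():
        raise ValidationError("negative interval activity")
    return np.cumsum(arr)


def analyze_series(series: TrapSeries) -> RateResult:
    """Full per-incubation analysis: slope fit, rate, mass balance."""
    fit = fit_turnover_slope(series)
    bal = mass_balance(series)
    return RateResult(
        slope=fit["slope"],
        intercept=fit["intercept"],
        r_squared=fit["r_squared"],
        rate=consumption_rate(fit["slope"], series),
        co2_recovery=bal["co2_recovery"],
        methanol_recovery=bal["methanol_recovery"],
        total_recovery=bal["total_recovery"],
        negative_slope=fit["slope"] < 0,
        recovery_flag=bal["recovery_flag"],
        label=dict(series.label),
    )


def read_trap_tables(traps_path: str | Path, incubations_path: str | Path) -> list[TrapSeries]:
    """Read the long-format trap TSV plus the per-incubation header table.

    `traps_path` columns: incubation_id, time_h, co2_bq (cumulative).
    `incubations_path` columns: incubation_id, administered_bq,
    methanol_trap_bq, dry_mass_g, specific_activity_bq_per_nmol, and
    optional species / compartment / replicate labels.
    """
    traps = pd.read_csv(traps_path, sep="\t")
    head = pd.read_csv(incubations_path, sep="\t")
    for col in ("incubation_id", "time_h", "co2_bq"):
        if col not in traps.columns:
            raise ValidationError(f"{traps_path}: missing column {col!r}")
    for col in ("incubation_id", "administered_bq", "methanol_trap_bq",
                "dry_mass_g", "specific_activity_bq_per_nmol"):
        if col not in head.columns:
            raise ValidationError(f"{incubations_path}: missing column {col!r}")
    series = []
    head = head.set_index("incubation_id")
    for inc_id, grp in traps.groupby("incubation_id", sort=True):
        if inc_id not in head.index:
            raise ValidationError(f"incubation {inc_id!r} missing from header table")
        row = head.loc[inc_id]
        grp = grp.sort_values("time_h")
        label = {"incubation_id": str(inc_id)}
        for k in ("species", "compartment", "replicate"):
            if k in head.columns and pd.notna(row.get(k)):
                label[k] = str(row[k])
        series.append(
            TrapSeries(
                times=grp["time_h"].to_numpy(),
                co2_activity=grp["co2_bq"].to_numpy(),
                administered_activity=float(row["administered_bq"]),
                dry_mass=float(row["dry_mass_g"]),
                specific_activity=float(row["specific_activity_bq_per_nmol"]),
                methanol_trap_activity=float(row["methanol_trap_bq"]),
                label=label,
            )
        )
    return series


def results_to_frame(results: list[RateResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = dict(r.label)
        row.update({
            "slope_bq_per_h": r.slope,
            "intercept_bq": r.intercept,
            "r_squared": r.r_squared,
            "rate_nmol_per_g_per_h": r.rate,
            "co2_recovery": r.co2_recovery,
            "methanol_recovery": r.methanol_recovery,
            "total_recovery": r.total_recovery,
            "negative_slope": r.negative_slope,
            "recovery_flag": r.recovery_flag,
        })
        rows.append(row)
    return pd.DataFrame(rows)
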