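"""Synthetic SIP gradients and radiotracer series with known ground truth.

The gradient simulator emulates isopycnic RNA-SIP: each taxon's rRNA
mass is spread over buoyant density as a Gaussian centred at a
taxon-specific unlabelled density (GC-content variation); in 13C
gradients, labelled taxa carry an additional Gaussian component of
weight `label_fraction` shifted up by `density_shift` — short
incubations label RNA only partially, which is exactly what makes the
K-factor criterion discriminative. Fraction counts are multinomial
draws at fixed per-fraction read depth, so compositional closure holds
by construction.

The trap simulator produces cumulative 14CO2 activities growing
linearly at slope ``true_rate * specific_activity * dry_mass`` scaled
by the trap efficiency, with additive Gaussian measurement noise,
clipped non-negative and monotonized; the water trap receives a fixed
volatile share of the administered activity.

Everything is reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .errors import ValidationError
from .gradient import DensityCalibration, classify_density, density_to_ri
from .io_tables import FractionMeta, OtuTable, PipelineConfig
from .radiotracer import TrapSeries

#: contexts mirroring the study design: 2 plant species x 3 compartments
SPECIES = ("F_arundinacea", "T_officinale")
COMPARTMENTS = ("phyllosphere", "roots", "rhizosphere_soil")
TIMEPOINTS_H = (8.0, 24.0)


@dataclass
class SipSimParams:
    """Generating parameters of one simulated SIP experiment.

    Defaults define the strong-signal regime: 20 taxa, 5 labelled, a
    0.03 g/mL buoyant-density shift for fully labelled RNA, 80 % of a
    labelled taxon's RNA heavy, 50 000 reads per sequenced fraction.
    """

    n_taxa: int = 20
    n_labelled: int = 5
    labelled_taxa: list[str] | None = None  # default: drawn from taxa
    base_abundances: np.ndarray | None = None  # default: log-normal, normalized
    abundance_sigma: float = 1.0  # log-normal shape of base abundances
    unlabelled_density_mean: float = 1.770  # g/mL, population centre
    unlabelled_density_sd: float = 0.004  # g/mL, GC-linked taxon spread
    density_shift: float = 0.03  # g/mL added to the labelled component
    profile_sd: float = 0.008  # g/mL within-gradient spread
    fraction_edges: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(1.730, 1.8501, 0.010), 4)
    )
    reads_per_fraction: int = 50_000
    label_fraction: float = 0.8  # heavy share of a labelled taxon's RNA
    background_mass: float = 1e-6  # uniform smear of RNA across all fractions
    depth_mode: str = "fixed"  # "fixed": reads_per_fraction each; "mass": depth ~ RNA mass
    seed: int = 0

    def __post_init__(self) -> None:
        self.fraction_edges = np.asarray(self.fraction_edges, dtype=float)
        if self.n_taxa < 1:
            raise ValidationError("n_taxa must be >= 1")
        if not 0 <= self.n_labelled <= self.n_taxa:
            raise ValidationError("n_labelled must be in [0, n_taxa]")
        if self.density_shift < 0:
            raise ValidationError("density_shift must be >= 0")
        if not 0 <= self.label_fraction <= 1:
            raise ValidationError("label_fraction must be in [0, 1]")
        if not np.all(np.diff(self.fraction_edges) > 0):
            raise ValidationError("fraction_edges must be strictly increasing")
        if self.reads_per_fraction < 1:
            raise ValidationError("reads_per_fraction must be >= 1")
        if not 0 <= self.background_mass < 1:
            raise ValidationError("background_mass must be in [0, 1)")
        if self.depth_mode not in ("fixed", "mass"):
            raise ValidationError("depth_mode must be 'fixed' or 'mass'")
        if self.base_abundances is not None:
            p = np.asarray(self.base_abundances, dtype=float)
            if p.shape != (self.n_taxa,) or (p < 0).any():
                raise ValidationError("base_abundances must be n_taxa non-negative values")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValidationError("base_abundances must sum to 1")
            self.base_abundances = p


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated experiment."""

    labelled_taxa: list[str]
    base_abundances: np.ndarray
    density_means: np.ndarray
    params: SipSimParams
    warnings: list[str] = field(default_factory=list)


@dataclass
class SimulatedSip:
    table: OtuTable
    meta: list[FractionMeta]
    truth: SyntheticTruth


def _bin_masses(
    mean: float, sd: float, edges: np.ndarray
) -> np.ndarray:
    cdf = norm.cdf(edges, loc=mean, scale=sd)
    return np.diff(cdf)


def _gradient_fraction_probs(
    params: SipSimParams,
    density_means: np.ndarray,
    abundances: np.ndarray,
    labelled_mask: np.ndarray,
    is_c13: bool,
) -> np.ndarray:
    """Expected per-taxon mass in each density bin (taxa x fractions)."""
    n_bins = params.fraction_edges.size - 1
    mass = np.empty((params.n_taxa, n_bins))
    for i in range(params.n_taxa):
        unlab = _bin_masses(density_means[i], params.profile_sd, params.fraction_edges)
        if is_c13 and labelled_mask[i]:
            heavy = _bin_masses(
                density_means[i] + params.density_shift,
                params.profile_sd,
                params.fraction_edges,
            )
            prof = (1.0 - params.label_fraction) * unlab + params.label_fraction * heavy
        else:
            prof = unlab
        # gradient smearing: a small uniform share of every taxon's RNA
        # appears in all fractions, as on real CsTFA gradients
        bg = params.background_mass
        prof = (1.0 - bg) * prof + bg / n_bins
        mass[i] = abundances[i] * prof
    return mass


def _coverage_warnings(params: SipSimParams, density_means: np.ndarray) -> list[str]:
    lo, hi = params.fraction_edges[0], params.fraction_edges[-1]
    warns = []
    means = list(density_means) + [
        m + params.density_shift for m in density_means
    ]
    worst_lo = min(means) - 3 * params.profile_sd
    worst_hi = max(means) + 3 * params.profile_sd
    if worst_lo < lo or worst_hi > hi:
        warns.append(
            "fraction grid does not cover +-3 profile_sd around all density "
            f"means ({worst_lo:.4f}-{worst_hi:.4f} vs grid {lo:.4f}-{hi:.4f}); "
            "some RNA mass leaks off the gradient"
        )
    return warns


def _draw_community(params: SipSimParams, rng: np.random.Generator):
    taxon_ids = [f"OTU{i + 1:03d}" for i in range(params.n_taxa)]
    if params.base_abundances is None:
        raw = rng.lognormal(mean=0.0, sigma=params.abundance_sigma, size=params.n_taxa)
        abundances = raw / raw.sum()
    else:
        abundances = params.base_abundances
    density_means = rng.normal(
        params.unlabelled_density_mean, params.unlabelled_density_sd, params.n_taxa
    )
    if params.labelled_taxa is None:
        labelled = sorted(
            rng.choice(params.n_taxa, size=params.n_labelled, replace=False).tolist()
        )
        labelled_taxa = [taxon_ids[i] for i in labelled]
    else:
        labelled_taxa = list(params.labelled_taxa)
        missing = set(labelled_taxa) - set(taxon_ids)
        if missing:
            raise ValidationError(f"labelled_taxa not in community: {sorted(missing)}")
    labelled_mask = np.array([t in set(labelled_taxa) for t in taxon_ids])
    return taxon_ids, abundances, density_means, labelled_taxa, labelled_mask


def _default_contexts() -> list[dict]:
    return [{"species": SPECIES[1], "compartment": COMPARTMENTS[0], "timepoint_h": 8.0}]


def simulate_gradient_experiment(
    params: SipSimParams,
    contexts: Sequence[dict] | None = None,
    keep_classes: dict[str, tuple[str, ...]] | None = None,
    config: PipelineConfig | None = None,
) -> SimulatedSip:
    """Simulate paired 12C/13C gradients for one or more contexts.

    One community (abundances, density means, labelled set) is drawn per
    experiment and shared across contexts, as for aliquots of one
    system. For every context a 12C control and a 13C treatment gradient
    are fractionated on `params.fraction_edges`; each fraction receives
    `reads_per_fraction` multinomial reads.

    `keep_classes` optionally restricts which density classes are
    "sequenced" per isotope, e.g. ``{"C13": ("heavy", "middle",
    "light"), "C12": ("heavy", "light")}``; the class of each fraction
    is judged at its bin midpoint with the configured windows, and only
    one representative fraction per retained class is emitted (the one
    nearest the class-window centre). Default: every fraction is kept.
    """
    cfg = config or PipelineConfig()
    cal = DensityCalibration(
        slope=float(cfg.ri_calibration["slope"]),
        intercept=float(cfg.ri_calibration["intercept"]),
    )
    rng = np.random.default_rng(params.seed)
    taxon_ids, abundances, density_means, labelled_taxa, labelled_mask = _draw_community(
        params, rng
    )
    contexts = list(contexts) if contexts is not None else _default_contexts()
    midpoints = 0.5 * (params.fraction_edges[:-1] + params.fraction_edges[1:])
    mid_classes = [
        classify_density(m, cfg.heavy_density_window, cfg.light_density_window)
        for m in midpoints
    ]

    columns: list[np.ndarray] = []
    sample_ids: list[str] = []
    meta: list[FractionMeta] = []
    for ctx in contexts:
        for iso in ("C12", "C13"):
            probs = _gradient_fraction_probs(
                params, density_means, abundances, labelled_mask, is_c13=(iso == "C13")
            )
            gid = f"{ctx['species']}.{ctx['compartment']}.{ctx['timepoint_h']:g}h.{iso}"
            keep = _select_fractions(mid_classes, midpoints, cfg, keep_classes, iso)
            kept_mass = probs[:, keep]
            if params.depth_mode == "mass":
                # sequencing effort follows RNA mass, as when profiling a
                # gradient by per-fraction RNA quantity
                total_reads = params.reads_per_fraction * len(keep)
                flat = rng.multinomial(total_reads, (kept_mass / kept_mass.sum()).ravel())
                count_matrix = flat.reshape(kept_mass.shape)
            else:
                count_matrix = np.empty((params.n_taxa, len(keep)), dtype=np.int64)
                for col, j in enumerate(keep):
                    p = kept_mass[:, col]
                    total = p.sum()
                    if total <= 0:
                        raise ValidationError(
                            f"fraction {j + 1} of {gid} has zero expected mass"
                        )
                    count_matrix[:, col] = rng.multinomial(
                        params.reads_per_fraction, p / total
                    )
            for col, j in enumerate(keep):
                counts = count_matrix[:, col]
                sid = f"{gid}.F{j + 1:02d}"
                columns.append(counts)
                sample_ids.append(sid)
                meta.append(
                    FractionMeta(
                        sample_id=sid,
                        isotope=iso,
                        gradient_id=gid,
                        fraction_index=j + 1,
                        refractive_index=round(density_to_ri(midpoints[j], cal), 6),
                        buoyant_density=float(midpoints[j]),
                        compartment=ctx["compartment"],
                        timepoint_h=float(ctx["timepoint_h"]),
                        species=ctx["species"],
                    )
                )
    table = OtuTable(
        taxon_ids=taxon_ids,
        sample_ids=sample_ids,
        counts=np.column_stack(columns),
    )
    truth = SyntheticTruth(
        labelled_taxa=labelled_taxa,
        base_abundances=abundances,
        density_means=density_means,
        params=params,
        warnings=_coverage_warnings(params, density_means),
    )
    return SimulatedSip(table=table, meta=meta, truth=truth)


def _select_fractions(
    mid_classes: list[str],
    midpoints: np.ndarray,
    cfg: PipelineConfig,
    keep_classes: dict[str, tuple[str, ...]] | None,
    isotope: str,
) -> list[int]:
    if keep_classes is None or isotope not in keep_classes:
        return list(range(len(mid_classes)))
    centres = {
        "heavy": 0.5 * sum(cfg.heavy_density_window),
        "light": 0.5 * sum(cfg.light_density_window),
        "middle": 0.5 * (cfg.light_density_window[1] + cfg.heavy_density_window[0]),
    }
    keep = []
    for cls in keep_classes[isotope]:
        idx = [j for j, c in enumerate(mid_classes) if c == cls]
        if not idx:
            raise ValidationError(f"no fraction bin classifies as {cls!r}")
        keep.append(min(idx, key=lambda j: abs(midpoints[j] - centres[cls])))
    return sorted(keep)


def make_study_design(
    seed: int = 0, params: SipSimParams | None = None
) -> SimulatedSip:
    """Simulate the full labelling design: 60 sequenced fractions.

    2 species x 3 compartments x 2 timepoints (8 h, 24 h) x 2 isotopes
    gives 24 gradients; treatment (13C) gradients are sequenced at one
    heavy, one middle and one light fraction, controls (12C) at one
    heavy and one light fraction — 12 x 3 + 12 x 2 = 60 samples.
    """
    base = params or SipSimParams()
    base = replace(base, seed=seed)
    contexts = [
        {"species": sp, "compartment": cp, "timepoint_h": tp}
        for sp in SPECIES
        for cp in COMPARTMENTS
        for tp in TIMEPOINTS_H
    ]
    return simulate_gradient_experiment(
        base,
        contexts=contexts,
        keep_classes={"C13": ("heavy", "middle", "light"), "C12": ("heavy", "light")},
    )


@dataclass
class TrapSimParams:
    """Generating parameters of one simulated 14C-methanol incubation.

    Defaults mirror the incubation setup: 631 kBq administered, 3.5 h
    duration, 30-min trap collections, ~50 mg dry leaf material. The
    specific activity (Bq/nmol) converts consumption to trapped Bq;
    `noise_sd` is the per-measurement scintillation + handling error.
    """

    true_rate: float = 100.0  # nmol / (g dry wt h)
    dry_mass: float = 0.05  # g
    specific_activity: float = 10.0  # Bq / nmol
    administered_activity: float = 631_000.0  # Bq
    duration_h: float = 3.5
    interval_h: float = 0.5
    noise_sd: float = 1.0  # Bq
    trap_efficiency: float = 1.0
    methanol_volatile_fraction: float = 0.875
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_rate < 0:
            raise ValidationError("true_rate must be >= 0")
        for name in ("dry_mass", "specific_activity", "administered_activity",
                     "duration_h", "interval_h"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not 0 < self.trap_efficiency <= 1:
            raise ValidationError("trap_efficiency must be in (0, 1]")
        if not 0 <= self.methanol_volatile_fraction <= 1:
            raise ValidationError("methanol_volatile_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def simulate_trap_series(params: TrapSimParams) -> tuple[TrapSeries, float]:
    """Simulate one incubation; returns (series, true_rate).

    The true production slope is ``true_rate * specific_activity *
    dry_mass``; the trapped cumulative activity grows at
    ``trap_efficiency`` times that slope with additive Gaussian noise on
    every collected sample (the trap starts empty, so t = 0 is exact),
    clipped non-negative and forced non-decreasing.
    """
    slope = params.true_rate * params.specific_activity * params.dry_mass
    final_co2 = params.trap_efficiency * slope * params.duration_h
    implied = (
        final_co2 / params.administered_activity + params.methanol_volatile_fraction
    )
    if implied > 1.0:
        raise ValidationError(
            f"implied total recovery {implied:.3f} > 1: lower true_rate, "
            "trap_efficiency or methanol_volatile_fraction"
        )
    rng = np.random.default_rng(params.seed)
    times = np.round(
        np.arange(0.0, params.duration_h + 1e-9, params.interval_h), 10
    )
    y = params.trap_efficiency * slope * times
    if params.noise_sd > 0:
        y = y + rng.normal(0.0, params.noise_sd, times.size)
    y[0] = 0.0
    y = np.maximum.accumulate(np.clip(y, 0.0, None))
    series = TrapSeries(
        times=times,
        co2_activity=y,
        administered_activity=params.administered_activity,
        dry_mass=params.dry_mass,
        specific_activity=params.specific_activity,
        methanol_trap_activity=(
            params.methanol_volatile_fraction * params.administered_activity
        ),
        label={"simulated": "true", "true_rate": params.true_rate},
    )
    return series, params.true_rate
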