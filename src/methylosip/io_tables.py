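"""Tabular I/O for OTU tables, gradient-fraction metadata and configuration.

All canonical inputs are plain TSV (UTF-8, ``.`` decimal); the OTU table
stores raw integer read counts — relative abundances are always derived
downstream, never stored. Sample identifiers are opaque strings; every
piece of sample semantics (isotope treatment, gradient membership,
buoyant density, compartment, timepoint) lives in the fraction-metadata
table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, PairingError, ValidationError

ISOTOPES = ("C12", "C13")
COMPARTMENTS = ("phyllosphere", "roots", "rhizosphere_soil")
DENSITY_CLASSES = ("heavy", "middle", "light", "unassigned")

#: accepted spellings of the isotope treatment in input files
_ISOTOPE_ALIASES = {
    "12c": "C12", "c12": "C12", "12": "C12",
    "13c": "C13", "c13": "C13", "13": "C13",
}


@dataclass
class OtuTable:
    """Integer read counts of taxa (rows) by samples (columns).

    Parameters
    ----------
    taxon_ids : sequence of str
        Unique taxon (OTU) identifiers, one per row of `counts`.
    sample_ids : sequence of str
        Unique sample identifiers, one per column of `counts`.
    counts : ndarray of int, shape (n_taxa, n_samples)
        Non-negative raw read counts.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix (taxa x samples)")
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                bad = np.argwhere(np.mod(counts, 1) != 0)[0]
                raise ValidationError(
                    f"non-integer count at taxon {self.taxon_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
            counts = counts.astype(np.int64)
        self.counts = counts.astype(np.int64, copy=False)
        if len(self.taxon_ids) < 1 or len(self.sample_ids) < 1:
            raise ValidationError("table needs at least 1 taxon and 1 sample")
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        for name, ids in (("taxon", self.taxon_ids), ("sample", self.sample_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValidationError(f"duplicate {name} IDs: {sorted(dupes)}")
        if (self.counts < 0).any():
            bad = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at taxon {self.taxon_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    def sample_counts(self, sample_id: str) -> np.ndarray:
        try:
            j = self.sample_ids.index(sample_id)
        except ValueError:
            raise PairingError(f"sample {sample_id!r} not in OTU table") from None
        return self.counts[:, j]


@dataclass
class FractionMeta:
    """Per-sample gradient-fraction metadata.

    One record per sequenced density-gradient fraction. At least one of
    `refractive_index` / `buoyant_density` must be present; density class
    is assigned by :func:`methylosip.gradient.classify_fractions`.
    """

    sample_id: str
    isotope: str
    gradient_id: str
    fraction_index: int
    compartment: str
    timepoint_h: float
    refractive_index: float | None = None
    buoyant_density: float | None = None
    species: str = ""
    density_class: str = "unassigned"

    def __post_init__(self) -> None:
        self.isotope = _normalize_isotope(self.isotope)
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown compartment "
                f"{self.compartment!r} (expected one of {COMPARTMENTS})"
            )
        self.fraction_index = int(self.fraction_index)
        if self.fraction_index < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: fraction_index must be >= 1"
            )
        self.timepoint_h = float(self.timepoint_h)
        if self.timepoint_h < 0:
            raise ValidationError(f"sample {self.sample_id!r}: timepoint_h < 0")
        if self.refractive_index is None and self.buoyant_density is None:
            raise ValidationError(
                f"sample {self.sample_id!r}: need refractive_index or buoyant_density"
            )
        if self.buoyant_density is not None and self.buoyant_density < 1.0:
            raise ValidationError(
                f"sample {self.sample_id!r}: buoyant_density "
                f"{self.buoyant_density} g/mL implausibly low"
            )
        if self.density_class not in DENSITY_CLASSES:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown density_class "
                f"{self.density_class!r}"
            )

    @property
    def context(self) -> tuple[str, str, float]:
        """Pairing key: (species, compartment, timepoint)."""
        return (self.species, self.compartment, self.timepoint_h)


@dataclass
class PipelineConfig:
    """Tunable parameters of the labelling pipeline.

    Attributes
    ----------
    K : float
        Enrichment factor for the heavy-vs-light criterion; a taxon's
        heavy-fraction relative abundance must exceed K times its
        light-fraction abundance. Default 2.
    min_heavy_abundance : float
        Minimum heavy-fraction relative abundance (proportion) for a
        labelling call; default 0.0005 (0.05 %).
    heavy_density_window, light_density_window : (float, float)
        Buoyant-density windows (g/mL) defining the heavy and light
        fraction classes; must not overlap.
    ri_calibration : dict
        ``{"slope", "intercept"}`` of the linear refractive-index to
        buoyant-density calibration (CsTFA at 20 degC).
    ri_window : (float, float)
        Plausibility window for refractive indices.
    pseudo_abundance : float or None
        Abundance substituted for a zero light-fraction abundance in the
        K-factor criterion. ``None`` (default) means 1/(2 x pooled light
        read depth) per gradient pair.
    rng_seed : int
        Seed for any stochastic pipeline stage.
    """

    K: float = 2.0
    min_heavy_abundance: float = 0.0005
    heavy_density_window: tuple[float, float] = (1.795, 1.825)
    light_density_window: tuple[float, float] = (1.760, 1.780)
    ri_calibration: dict = field(default_factory=lambda: {"slope": 10.0, "intercept": -12.0})
    ri_window: tuple[float, float] = (1.35, 1.42)
    pseudo_abundance: float | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.heavy_density_window = tuple(float(x) for x in self.heavy_density_window)
        self.light_density_window = tuple(float(x) for x in self.light_density_window)
        self.ri_window = tuple(float(x) for x in self.ri_window)
        if self.K <= 0:
            raise ConfigError(f"K must be > 0, got {self.K}")
        if not (0 <= self.min_heavy_abundance < 1):
            raise ConfigError(
                f"min_heavy_abundance must be in [0, 1), got {self.min_heavy_abundance}"
            )
        for name, win in (
            ("heavy_density_window", self.heavy_density_window),
            ("light_density_window", self.light_density_window),
            ("ri_window", self.ri_window),
        ):
            if len(win) != 2 or not win[0] < win[1]:
                raise ConfigError(f"{name} must be (low, high) with low < high: {win}")
        lo = max(self.heavy_density_window[0], self.light_density_window[0])
        hi = min(self.heavy_density_window[1], self.light_density_window[1])
        if lo <= hi:
            raise ConfigError(
                "heavy and light density windows overlap: "
                f"{self.heavy_density_window} vs {self.light_density_window}"
            )
        if float(self.ri_calibration.get("slope", 0.0)) <= 0:
            raise ConfigError("ri_calibration.slope must be > 0")
        if self.pseudo_abundance is not None and not (0 < self.pseudo_abundance < 1):
            raise ConfigError("pseudo_abundance must be in (0, 1) when set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["heavy_density_window"] = list(self.heavy_density_window)
        d["light_density_window"] = list(self.light_density_window)
        d["ri_window"] = list(self.ri_window)
        return d


def _duplicates(ids: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in ids:
        (dup if x in seen else seen).add(x)
    return dup


def _normalize_isotope(value: str) -> str:
    if value in ISOTOPES:
        return value
    norm = _ISOTOPE_ALIASES.get(str(value).strip().lower())
    if norm is None:
        raise ValidationError(
            f"unknown isotope {value!r} (expected 12C/13C or C12/C13)"
        )
    return norm


def read_otu_table(path: str | Path) -> OtuTable:
    """Read a taxa-by-samples TSV count table.

    First column holds taxon IDs, header row holds sample IDs. Raises
    :class:`ValidationError` naming the offending ID or cell on duplicate
    identifiers, negative or non-integer counts.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise ValidationError(f"{path}: expected taxon_id column plus >= 1 sample")
    sample_ids = header[1:]
    dupes = _duplicates(sample_ids)
    if dupes:
        raise ValidationError(f"{path}: duplicate sample IDs in header: {sorted(dupes)}")
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    taxon_ids = df.iloc[:, 0].astype(str).tolist()
    try:
        counts = df.iloc[:, 1:].to_numpy(dtype=float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric count value ({exc})") from exc
    if np.isnan(counts).any():
        i, j = np.argwhere(np.isnan(counts))[0]
        raise ValidationError(
            f"{path}: missing count at taxon {taxon_ids[i]!r}, sample {sample_ids[j]!r}"
        )
    return OtuTable(taxon_ids=taxon_ids, sample_ids=sample_ids, counts=counts)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    df = table.to_frame()
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t")


_META_COLUMNS = [
    "sample_id", "isotope", "gradient_id", "fraction_index",
    "refractive_index", "buoyant_density", "compartment", "timepoint_h",
]


def read_fraction_meta(path: str | Path) -> list[FractionMeta]:
    """Read per-sample gradient metadata from TSV.

    Required columns: sample_id, isotope, gradient_id, fraction_index,
    compartment, timepoint_h and at least one of refractive_index /
    buoyant_density per row. Optional columns: species, density_class.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "isotope", "gradient_id", "fraction_index",
               "compartment", "timepoint_h"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing metadata columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            FractionMeta(
                sample_id=str(row["sample_id"]),
                isotope=str(row["isotope"]),
                gradient_id=str(row["gradient_id"]),
                fraction_index=int(row["fraction_index"]),
                refractive_index=_opt_float(row.get("refractive_index")),
                buoyant_density=_opt_float(row.get("buoyant_density")),
                compartment=str(row["compartment"]),
                timepoint_h=float(row["timepoint_h"]),
                species=str(row["species"]) if _present(row.get("species")) else "",
                density_class=(
                    str(row["density_class"])
                    if _present(row.get("density_class"))
                    else "unassigned"
                ),
            )
        )
    dupes = _duplicates([r.sample_id for r in records])
    if dupes:
        raise ValidationError(f"{path}: duplicate sample_id in metadata: {sorted(dupes)}")
    return records


def write_fraction_meta(records: Iterable[FractionMeta], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "sample_id": r.sample_id,
            "isotope": r.isotope,
            "gradient_id": r.gradient_id,
            "fraction_index": r.fraction_index,
            "refractive_index": "" if r.refractive_index is None else repr(float(r.refractive_index)),
            "buoyant_density": "" if r.buoyant_density is None else repr(float(r.buoyant_density)),
            "compartment": r.compartment,
            "timepoint_h": repr(float(r.timepoint_h)),
            "species": r.species,
            "density_class": r.density_class,
        })
    pd.DataFrame(rows, columns=_META_COLUMNS + ["species", "density_class"]).to_csv(
        path, sep="\t", index=False
    )


def join_validate(table: OtuTable, meta: Sequence[FractionMeta]) -> None:
    """Require the OTU-table and metadata sample-ID sets to be equal."""
    table_ids = set(table.sample_ids)
    meta_ids = {m.sample_id for m in meta}
    only_table = table_ids - meta_ids
    only_meta = meta_ids - table_ids
    if only_table or only_meta:
        raise PairingError(
            "sample sets differ between OTU table and metadata: "
            f"only in table={sorted(only_table)}, only in metadata={sorted(only_meta)}"
        )


def _present(v) -> bool:
    return v is not None and not (isinstance(v, float) and np.isnan(v)) and str(v) != "" and str(v) != "nan"


def _opt_float(v) -> float | None:
    return float(v) if _present(v) else None
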