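"""Identification of 13C-labelled taxa from paired SIP gradients.

An organism that assimilates a 13C substrate builds isotopically heavy
rRNA, which equilibrates at higher buoyant density. A taxon is called
labelled when, for a matched pair of gradients (13C treatment and 12C
control from the same species, compartment and timepoint), all three
criteria hold:

1. its relative abundance in the heavy fraction of the 13C treatment
   exceeds its relative abundance in the heavy fraction of the 12C
   control (strict);
2. its heavy-fraction relative abundance in the 13C treatment exceeds
   its light-fraction relative abundance in the same gradient by a
   factor K (default 2, strict) — short incubations only partially
   label RNA, so the heavy enrichment must clear a multiplicative bar;
3. its heavy-fraction relative abundance in the 13C treatment is at
   least 0.05 % (non-strict), excluding noise-level detections.

Relative abundances are computed after pooling counts of all fractions
of a gradient that fall in the same density class. A taxon absent from
the light fraction passes criterion 2 iff its heavy abundance exceeds
K times a pseudo-abundance (default: half a read at the pooled light
depth), keeping the rule monotone and depth-aware.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import PairingError, ValidationError
from .io_tables import FractionMeta, OtuTable, PipelineConfig, join_validate


@dataclass
class GradientPair:
    """Pooled relative-abundance vectors for one 13C/12C gradient pair.

    Vectors share `taxon_ids` ordering and each sums to 1. `light_depth`
    is the pooled read depth of the 13C light fraction, used for the
    default pseudo-abundance of the zero-denominator rule.
    """

    taxon_ids: list[str]
    c13_heavy: np.ndarray
    c13_light: np.ndarray
    c12_heavy: np.ndarray
    context: dict = field(default_factory=dict)
    light_depth: int = 0

    def __post_init__(self) -> None:
        for name in ("c13_heavy", "c13_light", "c12_heavy"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (len(self.taxon_ids),):
                raise ValidationError(f"{name}: length mismatch with taxon_ids")
            if (v < 0).any():
                raise ValidationError(f"{name}: negative relative abundance")
            if abs(v.sum() - 1.0) > 1e-9:
                raise ValidationError(f"{name}: does not sum to 1 (got {v.sum()!r})")
            setattr(self, name, v)


@dataclass
class LabelCall:
    """Outcome of the three labelling criteria for one taxon in one pair."""

    taxon_id: str
    c1_pass: bool
    c2_pass: bool
    c3_pass: bool
    labelled: bool
    abund_heavy_c13: float
    abund_light_c13: float
    abund_heavy_c12: float


def relative_abundance(counts: np.ndarray) -> np.ndarray:
    """Normalize a count vector to proportions summing to 1."""
    v = np.asarray(counts, dtype=float)
    if (v < 0).any():
        raise ValidationError("negative counts in relative_abundance")
    total = v.sum()
    if total <= 0:
        raise ValidationError("all-zero count vector (empty fraction)")
    return v / total


def pool_gradient_classes(
    table: OtuTable, fractions: Sequence[FractionMeta]
) -> dict[str, np.ndarray]:
    """Sum counts of one gradient's fractions by density class.

    Returns a mapping density_class -> pooled count vector over
    `table.taxon_ids`; classes with no fraction are absent.
    """
    pooled: dict[str, np.ndarray] = {}
    for frac in fractions:
        vec = table.sample_counts(frac.sample_id)
        cls = frac.density_class
        pooled[cls] = pooled.get(cls, np.zeros(table.n_taxa, dtype=np.int64)) + vec
    return pooled


def build_gradient_pairs(
    table: OtuTable,
    meta: Sequence[FractionMeta],
    cfg: PipelineConfig,
) -> list[GradientPair]:
    """Match each 13C gradient to its 12C control and pool fractions.

    The pairing key is (species, compartment, timepoint); exactly one
    control per treatment gradient is required, and orphan contexts or
    gradients lacking a heavy or light fraction raise
    :class:`PairingError` naming the offender.
    """
    join_validate(table, meta)
    unclassified = [m.sample_id for m in meta if m.density_class == "unassigned"]
    by_gradient: dict[str, list[FractionMeta]] = {}
    for m in meta:
        by_gradient.setdefault(m.gradient_id, []).append(m)

    # one (context, isotope) cell per gradient; ambiguity is an error
    cells: dict[tuple, dict[str, str]] = {}
    for gid, fracs in by_gradient.items():
        ctxs = {f.context for f in fracs}
        isos = {f.isotope for f in fracs}
        if len(ctxs) != 1 or len(isos) != 1:
            raise PairingError(
                f"gradient {gid!r} mixes contexts {sorted(ctxs)} or isotopes {sorted(isos)}"
            )
        ctx, iso = ctxs.pop(), isos.pop()
        slot = cells.setdefault(ctx, {})
        if iso in slot:
            raise PairingError(
                f"context {ctx}: multiple {iso} gradients ({slot[iso]!r}, {gid!r})"
            )
        slot[iso] = gid

    pairs = []
    for ctx in sorted(cells):
        slot = cells[ctx]
        if "C13" not in slot:
            continue  # control-only context: nothing to call
        if "C12" not in slot:
            raise PairingError(
                f"13C gradient {slot['C13']!r} has no 12C control for context "
                f"(species={ctx[0]!r}, compartment={ctx[1]!r}, timepoint_h={ctx[2]})"
            )
        pooled13 = pool_gradient_classes(table, by_gradient[slot["C13"]])
        pooled12 = pool_gradient_classes(table, by_gradient[slot["C12"]])
        for need, pooled, gid in (
            ("heavy", pooled13, slot["C13"]), ("light", pooled13, slot["C13"]),
            ("heavy", pooled12, slot["C12"]),
        ):
            if need not in pooled or pooled[need].sum() == 0:
                raise PairingError(
                    f"gradient {gid!r} has no usable {need} fraction"
                    + (f" (unclassified samples: {unclassified})" if unclassified else "")
                )
        pairs.append(
            GradientPair(
                taxon_ids=list(table.taxon_ids),
                c13_heavy=relative_abundance(pooled13["heavy"]),
                c13_light=relative_abundance(pooled13["light"]),
                c12_heavy=relative_abundance(pooled12["heavy"]),
                context={"species": ctx[0], "compartment": ctx[1], "timepoint_h": ctx[2]},
                light_depth=int(pooled13["light"].sum()),
            )
        )
    return pairs


def call_labelled(pair: GradientPair, cfg: PipelineConfig) -> list[LabelCall]:
    """Apply the three labelling criteria to every taxon of a pair."""
    pseudo = cfg.pseudo_abundance
    if pseudo is None:
        if pair.light_depth <= 0:
            raise ValidationError(
                "pseudo_abundance unset and light-fraction depth unknown"
            )
        pseudo = 1.0 / (2.0 * pair.light_depth)
    light_eff = np.where(pair.c13_light > 0, pair.c13_light, pseudo)
    c1 = pair.c13_heavy > pair.c12_heavy
    c2 = pair.c13_heavy > cfg.K * light_eff
    c3 = pair.c13_heavy >= cfg.min_heavy_abundance
    labelled = c1 & c2 & c3
    return [
        LabelCall(
            taxon_id=t,
            c1_pass=bool(c1[i]),
            c2_pass=bool(c2[i]),
            c3_pass=bool(c3[i]),
            labelled=bool(labelled[i]),
            abund_heavy_c13=float(pair.c13_heavy[i]),
            abund_light_c13=float(pair.c13_light[i]),
            abund_heavy_c12=float(pair.c12_heavy[i]),
        )
        for i, t in enumerate(pair.taxon_ids)
    ]


def summarize_calls(
    calls: Sequence[LabelCall],
    taxonomy: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Aggregate labelled taxa by lineage group (e.g. class level).

    Heavy-13C abundances of labelled taxa are renormalized over the
    labelled set, so the summary describes the composition of the
    labelled community, mirroring class-level labelled-profile plots.
    Returns an empty frame (no error) when nothing is labelled.
    """
    labelled = [c for c in calls if c.labelled]
    if not labelled:
        return pd.DataFrame(columns=["group", "labelled_abundance"])
    total = sum(c.abund_heavy_c13 for c in labelled)
    groups: dict[str, float] = {}
    for c in labelled:
        g = taxonomy.get(c.taxon_id, c.taxon_id) if taxonomy else c.taxon_id
        groups[g] = groups.get(g, 0.0) + c.abund_heavy_c13 / total
    return (
        pd.DataFrame(
            {"group": list(groups), "labelled_abundance": list(groups.values())}
        )
        .sort_values("labelled_abundance", ascending=False)
        .reset_index(drop=True)
    )


def calls_to_frame(
    calls_by_context: Mapping[str, Sequence[LabelCall]]
) -> pd.DataFrame:
    """Flatten per-pair calls to the long output table written by the CLI."""
    rows = []
    for ctx, calls in calls_by_context.items():
        for c in calls:
            rows.append({
                "context": ctx,
                "taxon_id": c.taxon_id,
                "abund_heavy_c13": c.abund_heavy_c13,
                "abund_heavy_c12": c.abund_heavy_c12,
                "abund_light_c13": c.abund_light_c13,
                "c1": c.c1_pass, "c2": c.c2_pass, "c3": c.c3_pass,
                "labelled": c.labelled,
            })
    return pd.DataFrame(rows)
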