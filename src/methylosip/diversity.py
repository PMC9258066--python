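"""Alpha/beta diversity summaries for OTU count tables.

Implements the summary statistics applied to SIP amplicon datasets:
dataset-wide singleton removal, Shannon entropy, bias-corrected Chao1
richness, the analytic (hypergeometric) rarefaction expectation,
a Michaelis-Menten fit of the rarefaction curve yielding the asymptotic
OTU richness n_max, and Bray-Curtis dissimilarity for downstream
ordination. Ordination itself is out of scope — feed `bray_curtis`
distances to any NMDS implementation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import gammaln, xlogy

from .errors import NumericalError, ValidationError
from .io_tables import OtuTable


def remove_singletons(table: OtuTable) -> OtuTable:
    """Drop OTUs represented by exactly one read in the whole dataset.

    The criterion is the TOTAL count across all samples, not per-sample;
    an OTU seen once in each of two samples is retained.
    """
    totals = table.counts.sum(axis=1)
    keep = totals != 1
    if keep.all():
        return table
    return OtuTable(
        taxon_ids=[t for t, k in zip(table.taxon_ids, keep) if k],
        sample_ids=list(table.sample_ids),
        counts=table.counts[keep, :],
    )


def shannon(p: np.ndarray, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i (natural log by default).

    `p` must be proportions summing to 1; zero entries contribute 0.
    Pass ``base=2`` for bits.
    """
    v = np.asarray(p, dtype=float)
    if (v < 0).any():
        raise ValidationError("negative proportions")
    if abs(v.sum() - 1.0) > 1e-8:
        raise ValidationError(f"proportions sum to {v.sum()!r}, not 1")
    h = float(-xlogy(v, v).sum())
    if base is not None:
        h /= np.log(base)
    return h


def chao1(counts: np.ndarray) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1)).

    F1 and F2 are the numbers of singleton and doubleton OTUs in the
    sample; the +1 denominator keeps the estimator defined at F2 = 0.
    """
    v = np.asarray(counts)
    if (v < 0).any():
        raise ValidationError("negative counts")
    s_obs = int((v > 0).sum())
    f1 = int((v == 1).sum())
    f2 = int((v == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def rarefy_expected(counts: np.ndarray, depth: int) -> float:
    """Expected OTU richness of a random subsample of `depth` reads.

    Analytic hypergeometric expectation
    ``sum_i [1 - C(N - N_i, d) / C(N, d)]`` computed in log space, so it
    is exact (no Monte-Carlo) and stable at large depths.
    """
    v = np.asarray(counts, dtype=np.int64)
    if (v < 0).any():
        raise ValidationError("negative counts")
    v = v[v > 0]
    total = int(v.sum())
    depth = int(depth)
    if depth < 0 or depth > total:
        raise ValidationError(f"depth {depth} exceeds total count {total}")
    if depth == 0:
        return 0.0
    # log C(N - N_i, d) - log C(N, d); taxa with N_i > N - d always appear
    rem = total - v
    with np.errstate(invalid="ignore"):
        log_miss = (
            gammaln(rem + 1) - gammaln(depth + 1) - gammaln(rem - depth + 1)
            - (gammaln(total + 1) - gammaln(depth + 1) - gammaln(total - depth + 1))
        )
    miss = np.where(rem >= depth, np.exp(log_miss), 0.0)
    return float((1.0 - miss).sum())


def rarefaction_curve(counts: np.ndarray, depths: np.ndarray) -> pd.DataFrame:
    rows = [{"depth": int(d), "expected_richness": rarefy_expected(counts, int(d))}
            for d in depths]
    return pd.DataFrame(rows)


def fit_nmax(depths: np.ndarray, richness: np.ndarray) -> dict:
    """Fit r(d) = n_max * d / (k + d) and return the asymptote n_max.

    Initialized at (max observed richness, median depth), both parameters
    bounded positive. Non-convergence is flagged (``converged=False``),
    never silently replaced by a fallback value.
    """
    d = np.asarray(depths, dtype=float)
    r = np.asarray(richness, dtype=float)
    if d.size < 3:
        raise ValidationError("fit_nmax needs >= 3 points")
    if not np.all(np.diff(d) > 0):
        raise ValidationError("depths must be strictly increasing")
    p0 = (max(r.max(), 1.0), max(float(np.median(d)), 1e-6))

    def mm(x, n_max, k):
        return n_max * x / (k + x)

    try:
        popt, _ = curve_fit(mm, d, r, p0=p0, bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                            maxfev=10000)
    except RuntimeError:
        return {"n_max": np.nan, "half_saturation": np.nan, "converged": False}
    return {"n_max": float(popt[0]), "half_saturation": float(popt[1]), "converged": True}


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity 1 - 2 sum min(x, y) / (sum x + sum y)."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("vectors differ in length")
    if (a < 0).any() or (b < 0).any():
        raise ValidationError("negative entries")
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValidationError("both vectors are all-zero")
    return float(1.0 - 2.0 * np.minimum(a, b).sum() / denom)


def diversity_table(
    table: OtuTable,
    metrics: tuple[str, ...] = ("shannon", "chao1"),
    rarefy_depths: tuple[int, ...] = (),
    nmax_depths: int = 12,
) -> pd.DataFrame:
    """Per-sample diversity summary used by the CLI.

    `nmax_depths` sets how many geometrically spaced depths the
    rarefaction curve for the Michaelis-Menten fit is evaluated at.
    """
    known = {"shannon", "chao1", "nmax"}
    bad = set(metrics) - known
    if bad:
        raise ValidationError(f"unknown metrics {sorted(bad)}; choose from {sorted(known)}")
    rows = []
    for j, sid in enumerate(table.sample_ids):
        counts = table.counts[:, j]
        total = int(counts.sum())
        row: dict = {"sample_id": sid, "reads": total,
                     "observed_richness": int((counts > 0).sum())}
        if total == 0:
            raise ValidationError(f"sample {sid!r} has zero reads")
        if "shannon" in metrics:
            row["shannon"] = shannon(counts / total)
        if "chao1" in metrics:
            row["chao1"] = chao1(counts)
        if "nmax" in metrics:
            depths = np.unique(
                np.geomspace(1, total, nmax_depths).astype(int)
            )
            curve = rarefaction_curve(counts, depths)
            fit = fit_nmax(curve["depth"].to_numpy(), curve["expected_richness"].to_numpy())
            row["n_max"] = fit["n_max"]
            row["nmax_converged"] = fit["converged"]
        for d in rarefy_depths:
            if d <= total:
                row[f"rarefied_{d}"] = rarefy_expected(counts, d)
        rows.append(row)
    return pd.DataFrame(rows)
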