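import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from skbio.diversity.alpha import chao1 as skbio_chao1
from skbio.diversity.alpha import shannon as skbio_shannon

from methylosip.errors import ValidationError
from methylosip.diversity import (
    bray_curtis,
    chao1,
    diversity_table,
    fit_nmax,
    rarefaction_curve,
    rarefy_expected,
    remove_singletons,
    shannon,
)
from methylosip.io_tables import OtuTable


def test_remove_singletons_dataset_wide():
    t = OtuTable(
        taxon_ids=["a", "b", "c"],
        sample_ids=["s1", "s2", "s3"],
        counts=np.array([[1, 0, 0], [1, 1, 0], [5, 2, 3]]),
    )
    out = remove_singletons(t)
    assert out.taxon_ids == ["b", "c"]  # total-1 dropped, per-sample-1 kept
    assert out.counts.sum() == t.counts.sum() - 1


def test_remove_singletons_idempotent_and_total_preserving():
    rng = np.random.default_rng(4)
    t = OtuTable(
        taxon_ids=[f"t{i}" for i in range(40)],
        sample_ids=[f"s{j}" for j in range(5)],
        counts=rng.poisson(0.6, size=(40, 5)),
    )
    n_singletons = int((t.counts.sum(axis=1) == 1).sum())
    once = remove_singletons(t)
    assert once.counts.sum() == t.counts.sum() - n_singletons
    twice = remove_singletons(once)
    assert twice.taxon_ids == once.taxon_ids


def test_shannon_closed_forms():
    assert shannon(np.full(4, 0.25)) == pytest.approx(np.log(4))
    assert shannon(np.array([1.0])) == 0.0
    assert shannon(np.full(4, 0.25), base=2) == pytest.approx(2.0)


@settings(max_examples=200, deadline=None)
@given(st.lists(st.floats(0.01, 10.0), min_size=1, max_size=30), st.integers(0, 5))
def test_shannon_bounds(weights, n_zeros):
    p = np.array(weights + [0.0] * n_zeros)
    p = p / p.sum()
    h = shannon(p)
    assert -1e-12 <= h <= np.log((p > 0).sum()) + 1e-12


def test_shannon_matches_reference_implementation():
    rng = np.random.default_rng(8)
    for _ in range(10):
        counts = rng.integers(0, 50, 25)
        if counts.sum() == 0:
            continue
        p = counts / counts.sum()
        assert shannon(p) == pytest.approx(skbio_shannon(counts, base=np.e))


def test_chao1_closed_forms():
    assert chao1(np.array([5, 3, 2, 2])) == 4.0  # no singletons
    counts = np.array([1, 1, 1, 1, 2, 2, 5, 5, 5, 5])  # S=10? no: S_obs=10 needs 10 taxa
    # S_obs 10, F1 4, F2 2 -> 10 + 12/6 = 12
    assert chao1(counts) == pytest.approx(12.0)
    assert len(counts) == 10


def test_chao1_at_least_observed_and_matches_reference():
    rng = np.random.default_rng(6)
    for _ in range(20):
        counts = rng.poisson(1.0, 60)
        s_obs = (counts > 0).sum()
        est = chao1(counts)
        assert est >= s_obs
        assert est == pytest.approx(skbio_chao1(counts, bias_corrected=True))


def test_rarefy_expected_trivial_depths():
    counts = np.array([5, 3, 2])
    assert rarefy_expected(counts, 10) == pytest.approx(3.0)  # full depth
    assert rarefy_expected(counts, 1) == pytest.approx(1.0)
    assert rarefy_expected(counts, 0) == 0.0
    with pytest.raises(ValidationError):
        rarefy_expected(counts, 11)


def test_rarefy_expected_matches_monte_carlo():
    rng = np.random.default_rng(77)
    counts = rng.integers(0, 60, 30)
    total = int(counts.sum())
    reads = np.repeat(np.arange(counts.size), counts)
    for depth in (5, total // 4, total // 2):
        richness = np.empty(2000)
        for i in range(2000):
            sub = rng.choice(reads, size=depth, replace=False)
            richness[i] = np.unique(sub).size
        se = richness.std(ddof=1) / np.sqrt(richness.size)
        assert rarefy_expected(counts, depth) == pytest.approx(
            richness.mean(), abs=max(3 * se, 1e-9)
        )


def test_rarefaction_curve_concave_nondecreasing():
    rng = np.random.default_rng(12)
    counts = rng.integers(0, 80, 40)
    depths = np.linspace(1, counts.sum(), 25).astype(int)
    r = rarefaction_curve(counts, depths)["expected_richness"].to_numpy()
    diffs = np.diff(r)
    assert (diffs >= -1e-9).all()
    assert (np.diff(diffs) <= 1e-9).all()
    assert r[-1] <= (counts > 0).sum() + 1e-9


def test_fit_nmax_inverts_noiseless_curve():
    d = np.array([10, 50, 100, 500, 1000, 5000], dtype=float)
    r = 100.0 * d / (50.0 + d)
    fit = fit_nmax(d, r)
    assert fit["converged"]
    assert fit["n_max"] == pytest.approx(100.0, rel=1e-6)
    assert fit["half_saturation"] == pytest.approx(50.0, rel=1e-6)


def test_fit_nmax_saturated_limit():
    d = np.geomspace(1e4, 1e7, 8)
    r = 42.0 * d / (3.0 + d)  # essentially flat at 42
    fit = fit_nmax(d, r)
    assert fit["n_max"] == pytest.approx(42.0, rel=0.01)


def test_fit_nmax_asymptote_bounds_observed_richness():
    rng = np.random.default_rng(3)
    counts = rng.integers(0, 100, 50)
    depths = np.unique(np.geomspace(1, counts.sum(), 12).astype(int))
    curve = rarefaction_curve(counts, depths)
    fit = fit_nmax(curve["depth"].to_numpy(), curve["expected_richness"].to_numpy())
    assert fit["n_max"] >= curve["expected_richness"].max() * (1 - 1e-6)


def test_bray_curtis_closed_forms():
    assert bray_curtis([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)
    assert bray_curtis([1, 0, 2], [0, 5, 0]) == pytest.approx(1.0)
    with pytest.raises(ValidationError):
        bray_curtis([0, 0], [0, 0])


def test_bray_curtis_metric_properties_and_reference():
    rng = np.random.default_rng(19)
    for _ in range(50):
        x, y, z = rng.integers(0, 30, (3, 12)).astype(float)
        if not (x.sum() and y.sum() and z.sum()):
            continue
        dxy, dyz, dxz = bray_curtis(x, y), bray_curtis(y, z), bray_curtis(x, z)
        assert dxy == pytest.approx(bray_curtis(y, x))
        assert 0 <= dxy <= 1
        assert dxz <= dxy + dyz + 1e-12
        assert dxy == pytest.approx(scipy_braycurtis(x, y))


def test_diversity_table_per_sample(small_table):
    df = diversity_table(small_table, metrics=("shannon", "chao1", "nmax"),
                         rarefy_depths=(10,))
    assert len(df) == small_table.n_samples
    assert {"shannon", "chao1", "n_max", "rarefied_10"} <= set(df.columns)
    assert (df["rarefied_10"] <= df["observed_richness"]).all()
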