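import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylosip.errors import PairingError, ValidationError
from methylosip.gradient import classify_fractions
from methylosip.io_tables import FractionMeta, OtuTable, PipelineConfig
from methylosip.label_caller import (
    GradientPair,
    build_gradient_pairs,
    call_labelled,
    relative_abundance,
    summarize_calls,
)


def make_pair(heavy13, light13, heavy12, light_depth=1000):
    n = len(heavy13)
    return GradientPair(
        taxon_ids=[f"T{i}" for i in range(n)],
        c13_heavy=np.asarray(heavy13, dtype=float),
        c13_light=np.asarray(light13, dtype=float),
        c12_heavy=np.asarray(heavy12, dtype=float),
        light_depth=light_depth,
    )


def test_relative_abundance_normalizes():
    assert np.allclose(relative_abundance([5, 5, 10]), [0.25, 0.25, 0.5])
    assert relative_abundance([7]) == pytest.approx([1.0])
    with pytest.raises(ValidationError, match="all-zero"):
        relative_abundance([0, 0])


@settings(max_examples=200, deadline=None)
@given(st.lists(st.integers(0, 10_000), min_size=1, max_size=50).filter(lambda v: sum(v) > 0))
def test_relative_abundance_sums_to_one(counts):
    p = relative_abundance(counts)
    assert p.sum() == pytest.approx(1.0)
    assert (p >= 0).all()


def test_worked_labelling_example(cfg):
    """Taxon at 0.20% heavy-13C vs 0.05% heavy-12C and 0.08% light passes all three."""
    rest = lambda x: [x, 1.0 - x]
    pair = make_pair(rest(0.0020), rest(0.0008), rest(0.0005))
    call = call_labelled(pair, cfg)[0]
    assert call.c1_pass and call.c2_pass and call.c3_pass and call.labelled


def test_floor_criterion_blocks_rare_taxa(cfg):
    pair = make_pair([0.0004, 0.9996], [0.0001, 0.9999], [0.0001, 0.9999])
    call = call_labelled(pair, cfg)[0]
    assert call.c1_pass and call.c2_pass
    assert not call.c3_pass and not call.labelled


def test_k_factor_criterion_is_strict(cfg):
    # heavy = 0.0010 vs K * light = 2 * 0.0006 = 0.0012 -> fails
    pair = make_pair([0.0010, 0.9990], [0.0006, 0.9994], [0.0001, 0.9999])
    call = call_labelled(pair, cfg)[0]
    assert not call.c2_pass and not call.labelled
    # exactly equal heavy = K * light also fails (strict inequality)
    pair = make_pair([0.0012, 0.9988], [0.0006, 0.9994], [0.0001, 0.9999])
    assert not call_labelled(pair, cfg)[0].c2_pass


def test_zero_light_abundance_uses_pseudo_abundance():
    cfg = PipelineConfig()
    # light depth 1000 -> pseudo = 1/2000 = 0.0005; K * pseudo = 0.001
    pair = make_pair([0.0020, 0.9980], [0.0, 1.0], [0.0005, 0.9995], light_depth=1000)
    assert call_labelled(pair, cfg)[0].labelled
    pair = make_pair([0.0008, 0.9992], [0.0, 1.0], [0.0001, 0.9999], light_depth=1000)
    assert not call_labelled(pair, cfg)[0].c2_pass


def brute_force_oracle(pair, K, floor, pseudo):
    """Direct per-taxon transcription of the three criteria."""
    verdicts = []
    for h13, l13, h12 in zip(pair.c13_heavy, pair.c13_light, pair.c12_heavy):
        c1 = h13 > h12
        light = l13 if l13 > 0 else pseudo
        c2 = h13 > K * light
        c3 = h13 >= floor
        verdicts.append((c1, c2, c3, c1 and c2 and c3))
    return verdicts


def random_pair(rng, max_taxa=50):
    n = int(rng.integers(2, max_taxa + 1))
    alpha = rng.uniform(0.1, 2.0)
    depth = int(rng.integers(200, 5000))
    vecs = []
    for _ in range(3):
        counts = rng.multinomial(depth, rng.dirichlet(np.full(n, alpha)))
        while counts.sum() == 0:  # pragma: no cover
            counts = rng.multinomial(depth, rng.dirichlet(np.full(n, alpha)))
        vecs.append(counts / counts.sum())
    return make_pair(*vecs, light_depth=depth)


def test_caller_matches_brute_force_oracle(cfg):
    rng = np.random.default_rng(42)
    for _ in range(200):
        pair = random_pair(rng)
        pseudo = 1.0 / (2.0 * pair.light_depth)
        calls = call_labelled(pair, cfg)
        oracle = brute_force_oracle(pair, cfg.K, cfg.min_heavy_abundance, pseudo)
        for call, (c1, c2, c3, lab) in zip(calls, oracle):
            assert (call.c1_pass, call.c2_pass, call.c3_pass, call.labelled) == (c1, c2, c3, lab)


def test_labelled_set_shrinks_with_stricter_thresholds():
    rng = np.random.default_rng(5)
    pairs = [random_pair(rng) for _ in range(20)]
    for pair in pairs:
        prev = None
        for K in (1.0, 2.0, 4.0, 8.0):
            cfg = PipelineConfig(K=K)
            called = {c.taxon_id for c in call_labelled(pair, cfg) if c.labelled}
            if prev is not None:
                assert called <= prev
            prev = called
        prev = None
        for floor in (0.0, 0.0005, 0.005):
            cfg = PipelineConfig(min_heavy_abundance=floor)
            called = {c.taxon_id for c in call_labelled(pair, cfg) if c.labelled}
            if prev is not None:
                assert called <= prev
            prev = called


def test_build_pairs_minimal(small_table, paired_meta, cfg):
    meta = classify_fractions(paired_meta, cfg)
    pairs = build_gradient_pairs(small_table, meta, cfg)
    assert len(pairs) == 1
    p = pairs[0]
    assert p.context == {
        "species": "T_officinale", "compartment": "phyllosphere", "timepoint_h": 8.0
    }
    # heavy fractions of g13 are s1 (bd 1.805) and s5 (1.815): pooled then normalized
    pooled = small_table.counts[:, 0] + small_table.counts[:, 4]
    assert np.allclose(p.c13_heavy, pooled / pooled.sum())
    assert p.light_depth == small_table.counts[:, 1].sum()


def test_build_pairs_keys_by_timepoint(small_table, paired_meta, cfg):
    from dataclasses import replace

    # second context at 24 h reusing samples s5/s6 as its own gradients
    meta24 = [
        replace(paired_meta[0], sample_id="s5", gradient_id="g13b", timepoint_h=24.0),
        replace(paired_meta[1], sample_id="s6", gradient_id="g13b", timepoint_h=24.0,
                buoyant_density=1.770),
    ]
    # needs both heavy+light and a control; give the 24 h context a control too
    table = OtuTable(
        taxon_ids=small_table.taxon_ids,
        sample_ids=["s1", "s2", "s3", "s4", "s5", "s6", "s7", "s8"],
        counts=np.hstack([small_table.counts, small_table.counts[:, :2]]),
    )
    meta = paired_meta[:4] + meta24 + [
        replace(paired_meta[2], sample_id="s7", gradient_id="g12b", timepoint_h=24.0),
        replace(paired_meta[3], sample_id="s8", gradient_id="g12b", timepoint_h=24.0),
    ]
    pairs = build_gradient_pairs(table, classify_fractions(meta, cfg), cfg)
    assert len(pairs) == 2
    assert sorted(p.context["timepoint_h"] for p in pairs) == [8.0, 24.0]


def test_orphan_treatment_gradient_raises(small_table, paired_meta, cfg):
    meta = classify_fractions([m for m in paired_meta if m.isotope == "C13"], cfg)
    table = OtuTable(
        taxon_ids=small_table.taxon_ids,
        sample_ids=["s1", "s2", "s5"],
        counts=small_table.counts[:, [0, 1, 4]],
    )
    with pytest.raises(PairingError, match="no 12C control"):
        build_gradient_pairs(table, meta, cfg)


def test_missing_light_fraction_raises(small_table, paired_meta, cfg):
    from dataclasses import replace

    meta = [replace(m, buoyant_density=1.805) for m in paired_meta]  # all heavy
    with pytest.raises(PairingError, match="light"):
        build_gradient_pairs(small_table, classify_fractions(meta, cfg), cfg)


def test_summarize_calls_groups_and_renormalizes(cfg):
    pair = make_pair([0.02, 0.03, 0.95], [0.001, 0.001, 0.998], [0.001, 0.001, 0.998])
    calls = call_labelled(pair, cfg)
    taxonomy = {"T0": "Alphaproteobacteria", "T1": "Alphaproteobacteria", "T2": "Bacilli"}
    out = summarize_calls(calls, taxonomy)
    # T2 fails c1/c2; the two labelled taxa share one class summing to 1
    assert out["group"].tolist() == ["Alphaproteobacteria"]
    assert out["labelled_abundance"].iloc[0] == pytest.approx(1.0)


def test_summarize_no_labelled_is_empty_not_error(cfg):
    pair = make_pair([0.5, 0.5], [0.5, 0.5], [0.5, 0.5])
    out = summarize_calls(call_labelled(pair, cfg))
    assert len(out) == 0


def test_summarize_recovers_labelled_classes(cfg):
    """Three labelled lineage groups appear as exactly three summary rows."""
    heavy = [0.10, 0.08, 0.06, 0.0001, 0.7599]
    light = [0.001, 0.001, 0.001, 0.001, 0.996]
    c12 = [0.001, 0.001, 0.001, 0.001, 0.996]
    pair = make_pair(heavy, light, c12)
    taxonomy = {"T0": "ClassA", "T1": "ClassB", "T2": "ClassC", "T3": "ClassD", "T4": "ClassE"}
    out = summarize_calls(call_labelled(pair, cfg), taxonomy)
    assert sorted(out["group"]) == ["ClassA", "ClassB", "ClassC"]
    assert out["labelled_abundance"].sum() == pytest.approx(1.0)
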