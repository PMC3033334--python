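"""Hypergeometric tails, the expected-count formula, and flagging rules."""

from math import comb

import numpy as np
import pytest

import stageset as ss
from stageset.enrich import EnrichConfig, enrich, hypergeom_tail, list_overlap
from stageset.io import GeneSetCollection, PairTable


def enum_tail(N, m, n, k, tail):
    """Oracle: full enumeration of the hypergeometric pmf."""
    total = comb(N, n)
    pmf = [comb(m, x) * comb(N - m, n - x) / total for x in range(min(m, n) + 1)]
    return sum(pmf[k:]) if tail == "upper" else sum(pmf[: k + 1])


def test_tail_matches_enumeration_up_to_N60(rng):
    for _ in range(150):
        N = int(rng.integers(2, 61))
        m = int(rng.integers(0, N + 1))
        n = int(rng.integers(0, N + 1))
        k_max = min(m, n)
        k = int(rng.integers(0, k_max + 1))
        for tail in ("upper", "lower"):
            assert hypergeom_tail(N, m, n, k, tail) == pytest.approx(
                enum_tail(N, m, n, k, tail), rel=1e-10
            )


def test_published_style_example():
    # C(5,4)*C(5,0)/C(10,4) = 5/210
    assert hypergeom_tail(10, 5, 4, 4, "upper") == pytest.approx(5 / 210)


def test_boundary_tails():
    assert hypergeom_tail(50, 10, 5, 0, "upper") == 1.0
    assert hypergeom_tail(50, 10, 5, 0, "lower") == pytest.approx(
        comb(40, 5) / comb(50, 5)
    )


def test_parameter_violations_raise():
    with pytest.raises(ValueError):
        hypergeom_tail(10, 11, 4, 2, "upper")
    with pytest.raises(ValueError):
        hypergeom_tail(10, 5, 4, 5, "upper")


def test_expected_count_formula_and_partition_sums():
    universe = frozenset(f"u{i}" for i in range(100))
    ids = sorted(universe)
    cats = GeneSetCollection(
        sets={"a": frozenset(ids[:30]), "b": frozenset(ids[30:70]), "c": frozenset(ids[70:])}
    )
    cluster = frozenset(ids[10:40])
    res = enrich({"cl": cluster}, cats, cfg=EnrichConfig())
    np.testing.assert_allclose(res["expected"], res["m"] * res["n"] / res["N"])
    assert res["observed"].sum() == len(cluster)  # categories partition the universe


def test_cluster_category_role_symmetry():
    universe = frozenset(f"u{i}" for i in range(60))
    ids = sorted(universe)
    a, b = frozenset(ids[:20]), frozenset(ids[10:35])
    cats_b = GeneSetCollection(sets={"b": b}, universe=universe)
    cats_a = GeneSetCollection(sets={"a": a}, universe=universe)
    cfg = EnrichConfig(universe_mode="full_array")
    r1 = enrich({"a": a}, cats_b, universe=universe, cfg=cfg).iloc[0]
    r2 = enrich({"b": b}, cats_a, universe=universe, cfg=cfg).iloc[0]
    for col in ("observed", "expected", "p_enrich", "p_deplete"):
        assert r1[col] == pytest.approx(r2[col])


def test_k_at_expectation_is_not_flagged():
    universe = frozenset(f"u{i}" for i in range(100))
    ids = sorted(universe)
    cat = frozenset(ids[:20])
    cluster = frozenset(ids[18:28])  # k=2 = 20*10/100
    res = enrich(
        {"cl": cluster},
        GeneSetCollection(sets={"cat": cat}, universe=universe),
        universe=universe,
        cfg=EnrichConfig(universe_mode="full_array"),
    ).iloc[0]
    assert res["expected"] == pytest.approx(2.0)
    assert res["flag"] == "none"


def test_disjoint_category_flagged_depleted():
    universe = frozenset(f"u{i}" for i in range(200))
    ids = sorted(universe)
    cat = frozenset(ids[:80])
    cluster = frozenset(ids[80:160])  # zero overlap, expected 32
    res = enrich(
        {"cl": cluster},
        GeneSetCollection(sets={"cat": cat}, universe=universe),
        universe=universe,
        cfg=EnrichConfig(universe_mode="full_array"),
    ).iloc[0]
    assert res["observed"] == 0
    assert res["flag"] == "depleted"
    assert res["p_deplete"] == pytest.approx(enum_tail(200, 80, 80, 0, "lower"), rel=1e-9)


def test_planted_category_flagged_on_synthetic_run(default_run):
    import pandas as pd

    _, _, out = default_run
    res = pd.read_csv(out / "enrichment.tsv", sep="\t")
    planted = res[res.apply(lambda r: r["category"] == f"cat_{r['cluster'][:-4]}", axis=1)]
    assert (planted["flag"] == "enriched").all()
    nulls = res[res["category"].str.startswith("null_")]
    # type-I control: 80 null tests at p<0.001 with the k>=4 floor
    assert (nulls["flag"] == "enriched").sum() <= 1


def test_list_overlap_identity_map_matches_untranslated():
    universe = frozenset(f"u{i}" for i in range(50))
    ids = sorted(universe)
    clusters = {"cl": frozenset(ids[:15])}
    ext = GeneSetCollection(sets={"ext": frozenset(ids[5:25])})
    identity = PairTable(rows=tuple((i, i) for i in ids))
    r_plain = list_overlap(clusters, ext, universe).iloc[0]
    r_mapped = list_overlap(clusters, ext, universe, ortholog_map=identity).iloc[0]
    for col in ("observed", "expected", "p_enrich", "p_deplete"):
        assert r_plain[col] == pytest.approx(r_mapped[col])


def test_list_overlap_many_to_many_counts_once_and_logs_untranslated():
    universe = frozenset({"r1", "r2", "r3", "r4"})
    clusters = {"cl": frozenset({"r1", "r2"})}
    ext = GeneSetCollection(sets={"ext": frozenset({"H1", "H2", "HX"})})
    # H1 and H2 both map onto r1; HX untranslatable
    mapping = PairTable(rows=(("r1", "H1"), ("r1", "H2"), ("r2", "H9")))
    row = list_overlap(clusters, ext, universe, ortholog_map=mapping).iloc[0]
    assert row["observed"] == 1  # r1 once, despite two partners
    assert row["untranslated"] == 1


def test_empty_external_list_gives_zero_row():
    universe = frozenset({"a", "b", "c"})
    ext = GeneSetCollection(sets={"ext": frozenset({"zz"})})
    mapping = PairTable(rows=(("a", "other"),))
    row = list_overlap({"cl": frozenset({"a"})}, ext, universe, ortholog_map=mapping).iloc[0]
    assert row["observed"] == 0 and row["expected"] == 0.0


def test_empty_universe_rejected():
    with pytest.raises(ValueError):
        enrich({"cl": frozenset()}, GeneSetCollection(sets={}), cfg=EnrichConfig())
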