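from __future__ import annotations

import math
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcscensus import (
    OperonSpec,
    SimulationConfig,
    arrangement_multiplicity,
    cluster_type_catalog,
    detect_clusters,
    expected_frequency,
    neighborhood_stat,
    observed_frequency,
    odds_ratio,
    permutation_null,
    simulate_genome,
)

from conftest import make_genome

# ------------------------------------------------------------- cluster calls


def test_detect_clusters_pair_plus_orphan(toy_genome):
    calls = detect_clusters(toy_genome)
    assert len(calls) == 1
    assert calls[0].member_positions == (1, 2)
    assert calls[0].label == "HK-RR"


def test_detect_clusters_allows_one_gap():
    calls = detect_clusters(make_genome([("HK",), (), ("RR",)]))
    assert len(calls) == 1
    assert calls[0].gap_positions == (2,)
    assert calls[0].label == "HK-RR"


def test_detect_clusters_two_gap_genes_break_the_run():
    calls = detect_clusters(make_genome([("HK",), (), (), ("RR",)]))
    assert calls == []  # two orphans, no cluster


def test_cluster_labels_preserve_order_and_hybrids():
    genes = make_genome([("HK",), ("RR",), ("RR",), (), (), ("RR",), ("HK",)])
    catalog = cluster_type_catalog(detect_clusters(genes))
    assert catalog == {"HK-RR-RR": 1, "RR-HK": 1}  # mirror orders distinct


def test_clusters_never_span_replicons():
    a = make_genome([("HK",), ("RR",)], replicon="chr1")
    b = make_genome([("RR",), ("HK",)], replicon="chr2")
    calls = detect_clusters(a + b)
    assert sorted(c.label for c in calls) == ["HK-RR", "RR-HK"]


@given(
    st.lists(
        st.sampled_from([(), ("HK",), ("RR",), ("HK", "RR")]), min_size=1, max_size=40
    )
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_cluster_partition_invariant(layout):
    """Every IST gene is in exactly one cluster or is an orphan; with
    max_gap=1 a cluster of m members spans at most 2m−1 positions."""
    genes = make_genome(layout)
    calls = detect_clusters(genes)
    covered = [p for c in calls for p in c.member_positions]
    assert len(covered) == len(set(covered))
    ist_positions = {g.position for g in genes if g.is_ist}
    assert set(covered) <= ist_positions
    for c in calls:
        m = len(c.member_positions)
        span = c.member_positions[-1] - c.member_positions[0] + 1
        assert span <= 2 * m - 1
    # orphans = IST genes not covered; none may be adjacent-or-one-gap to
    # another IST gene outside its own cluster
    orphans = ist_positions - set(covered)
    for p in orphans:
        assert not any(
            0 < abs(p - q) <= 2 for q in ist_positions if q != p
        )


# ------------------------------------------------------- multiplicity


def test_arrangement_multiplicity_printed_values():
    assert arrangement_multiplicity(["HK", "RR", "HK2"]) == 6
    assert arrangement_multiplicity(["HK", "HK2", "RR", "RR"]) == 12
    assert arrangement_multiplicity(["A", "A"]) == 1


@given(st.lists(st.sampled_from("ABC"), min_size=2, max_size=6))
@settings(max_examples=300, deadline=None, derandomize=True)
def test_arrangement_multiplicity_matches_multinomial_formula(pattern):
    counts = Counter(pattern)
    formula = math.factorial(len(pattern))
    for m in counts.values():
        formula //= math.factorial(m)
    assert arrangement_multiplicity(pattern) == formula


# ------------------------------------------------------- expected frequency


def test_expected_frequency_pair_arithmetic():
    f = expected_frequency("HK-RR", {"n_RR": 100}, 4001)
    assert f == pytest.approx(100 / 4000 + 100 / 3999, rel=1e-12)
    assert expected_frequency("HK-RR", {"n_RR": 0}, 1000) == 0.0


def test_expected_frequency_triple_and_quadruple_forms():
    f3 = expected_frequency("HK-RR-HK2", {"n_HK": 10, "n_RR": 20}, 1000)
    assert f3 == pytest.approx(6 * 10 / 999 * 20 / 998, rel=1e-12)
    f4 = expected_frequency("HK-RR-HK2-RR2", {"n_HK": 1, "n_RR": 20}, 1000)
    assert f4 == 0.0  # factor (n_HK − 1) forces zero


def test_expected_frequency_rejects_dense_counts_and_unknown_patterns():
    with pytest.raises(ValueError, match="exceeds 1"):
        expected_frequency("HK-RR", {"n_RR": 600}, 1000)
    with pytest.raises(ValueError, match="unknown pattern"):
        expected_frequency("RR-HK", {"n_RR": 1}, 1000)


# ------------------------------------------------------- observed frequency


def test_observed_frequency_pair(toy_genome):
    frac, n = observed_frequency(toy_genome, "HK-RR")
    assert (frac, n) == (0.5, 2)


def test_observed_frequency_counts_double_sided_anchor_once():
    genes = make_genome([("RR",), ("HK",), ("RR",)])
    frac, n = observed_frequency(genes, "HK-RR")
    assert (frac, n) == (1.0, 1)


def test_observed_frequency_triple_window():
    genes = make_genome([("RR",), ("HK",), ("RR",), ("HK",)])
    frac, n = observed_frequency(genes, "HK-RR-HK2")
    assert n == 2
    assert frac == 1.0  # both HK anchors sit in a contiguous {HK,RR,HK} window


def test_observed_frequency_gap_genes_do_not_satisfy_patterns():
    genes = make_genome([("HK",), (), ("RR",)])
    frac, _ = observed_frequency(genes, "HK-RR")
    assert frac == 0.0  # strict adjacency, unlike cluster detection


def test_observed_frequency_without_anchors_is_undefined():
    genes = make_genome([("RR",), ("RR",)])
    frac, n = observed_frequency(genes, "HKRRHPt-RR")
    assert frac is None and n == 0


def test_observed_frequency_hybrid_anchor():
    genes = make_genome([("HK", "RR", "HPt"), ("RR",), (), ("HK", "RR", "HK")])
    frac, n = observed_frequency(genes, "HKRRHPt-RR")
    assert (frac, n) == (1.0, 1)
    frac, n = observed_frequency(genes, "HKRRHK-RR")
    assert (frac, n) == (0.0, 1)


# ------------------------------------------------------- odds ratio


def test_odds_ratio_values():
    assert odds_ratio(0.5, 0.005) == pytest.approx(100.0)
    assert odds_ratio(0.02, 0.02) == 1.0
    assert odds_ratio(0.0, 0.02) == 0.0
    assert odds_ratio(None, 0.02) is None
    assert odds_ratio(0.5, 0.0) is None


def test_neighborhood_stat_flags_planted_enrichment():
    config = SimulationConfig(
        genes_per_organism=2000,
        protein_type_counts={"HK": 20, "RR": 20},
        operons=[OperonSpec("HK-RR", 10)],
        seed=3,
    )
    genes, _ = simulate_genome(config)
    stat = neighborhood_stat(
        genes, "HK-RR", {"n_HK": 20, "n_RR": 20}, P=2000
    )
    assert stat.anchor_count == 20
    assert stat.observed >= 0.5
    assert stat.odds_ratio > 10


# ------------------------------------------------------- permutation null


def test_permutation_null_is_seeded_and_reproducible():
    genes = make_genome([("HK",), ("RR",)] + [()] * 98)
    a = permutation_null(genes, "HK-RR", n_permutations=100, seed=5)
    b = permutation_null(genes, "HK-RR", n_permutations=100, seed=5)
    assert a == b


def test_permutation_null_single_ist_gene_gives_zero():
    genes = make_genome([("HK",)] + [()] * 99)
    mean, se = permutation_null(genes, "HK-RR", n_permutations=100, seed=1)
    assert mean == 0.0


def test_permutation_null_agrees_with_closed_form_on_random_genome():
    config = SimulationConfig(
        genes_per_organism=1000,
        protein_type_counts={"HK": 20, "RR": 20},
        seed=17,
    )
    genes, _ = simulate_genome(config)
    mean, se = permutation_null(genes, "HK-RR", n_permutations=300, seed=17)
    f = expected_frequency("HK-RR", {"n_RR": 20}, 1000)
    assert abs(mean - f) <= 3 * se


def test_permutation_null_sits_far_below_planted_observation():
    config = SimulationConfig(
        genes_per_organism=2000,
        protein_type_counts={"HK": 20, "RR": 20},
        operons=[OperonSpec("HK-RR", 10)],
        seed=23,
    )
    genes, _ = simulate_genome(config)
    observed, _ = observed_frequency(genes, "HK-RR")
    mean, se = permutation_null(genes, "HK-RR", n_permutations=200, seed=23)
    assert observed > mean + 10 * se
    f = expected_frequency("HK-RR", {"n_RR": 20}, 2000)
    assert abs(mean - f) <= 3 * se
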