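import math

import numpy as np
import pytest

from tuarch.genome_io import GeneModel
from tuarch.tep_caller import (
    TepCluster,
    cluster_teps,
    collect_tep_candidates,
    filter_teps,
    intersection_window,
    modified_zscore,
    reconcile_replicates,
)
from .conftest import profile


def brute_force_zscore(span_counts: dict, first: int, last: int, x: int) -> float:
    """Independent oracle: explicit leave-one-out moments by enumeration."""
    others = [span_counts.get(p, 0) for p in range(first, last + 1) if p != x]
    rx = span_counts.get(x, 0)
    if not others:
        return math.inf
    mu = sum(others) / len(others)
    mu2 = sum(v * v for v in others) / len(others)
    sigma = math.sqrt(max(mu2 - mu * mu, 0.0))
    if sigma == 0:
        return math.inf if rx > mu else 0.0
    return (rx - mu) / sigma


def make_cluster(counts: dict, strand="+"):
    return TepCluster(strand, min(counts), max(counts), dict(counts))


# --- candidate collection -------------------------------------------------

GENES = [GeneModel("g1", "+", 100, 1000), GeneModel("g2", "+", 1005, 2000)]


@pytest.mark.parametrize(
    "pos,expected",
    [
        (2500, True),  # intergenic
        (800, False),  # inside gene body, far from any 3' end
        (1008, True),  # inside g2 but within 10 nt downstream of g1's end
    ],
)
def test_candidate_intergenic_and_tail_rule(pos, expected):
    cands = collect_tep_candidates(profile({pos: 5}, label="TERMSEQ_R1"), GENES)
    assert ([p for p, _ in cands] == [pos]) is expected


def test_candidates_minus_strand_tail_runs_upstream_in_coordinates():
    genes = [GeneModel("m1", "-", 500, 900)]
    prof = profile({495: 4, 700: 4, 300: 4}, strand="-", label="TERMSEQ_R1")
    cands = [p for p, _ in collect_tep_candidates(prof, genes)]
    assert cands == [300, 495]  # 495 is in the 10-nt tail, 700 is in-body


# --- clustering -----------------------------------------------------------


def test_cluster_span_and_zero_padding():
    clusters = cluster_teps([(50, 2), (55, 1), (58, 4)], "+")
    assert len(clusters) == 1
    c = clusters[0]
    assert (c.first, c.last, c.length) == (50, 58, 9)
    assert c.count(53) == 0 and c.count(58) == 4


def test_cluster_gap_boundary():
    assert len(cluster_teps([(50, 1), (60, 1)], "+")) == 2  # gap 10 splits
    assert len(cluster_teps([(50, 1), (59, 1)], "+")) == 1  # gap 9 joins
    singleton = cluster_teps([(70, 3)], "+")[0]
    assert (singleton.first, singleton.last, singleton.length) == (70, 70, 1)


# --- modified z-score -----------------------------------------------------


def test_zscore_worked_example():
    # counts (2,1,10,1,3) at consecutive positions, evaluating the 10:
    # mu = 1.75, mu(r^2) = 3.75, sigma = sqrt(0.6875) ~ 0.82916, Z ~ 9.9498
    c = make_cluster({10: 2, 11: 1, 12: 10, 13: 1, 14: 3})
    z = modified_zscore(c, 12)
    assert z == pytest.approx(8.25 / math.sqrt(0.6875), abs=1e-9)
    assert z == pytest.approx(9.9498, abs=1e-4)


def test_zscore_degenerate_conventions():
    flat = make_cluster({1: 5, 2: 5, 3: 5, 4: 5})
    assert modified_zscore(flat, 2) == 0.0  # sigma = 0, r = mu
    single = make_cluster({70: 7})
    assert modified_zscore(single, 70) == math.inf
    spike = make_cluster({1: 0, 3: 7})  # sigma = 0 among zeros, r > mu
    assert modified_zscore(spike, 3) == math.inf
    with pytest.raises(ValueError):
        modified_zscore(flat, 99)


def test_zscore_matches_brute_force_on_random_clusters():
    rng = np.random.default_rng(2024)
    for _ in range(300):
        n = int(rng.integers(2, 51))
        first = int(rng.integers(1, 10_000))
        counts = {
            first + int(i): int(rng.integers(0, 101))
            for i in rng.choice(n, size=max(1, int(rng.integers(1, n + 1))), replace=False)
        }
        counts[first] = counts.get(first, 1) or 1
        counts[first + n - 1] = counts.get(first + n - 1, 1) or 1
        c = TepCluster("+", first, first + n - 1, counts)
        for x in c.positions():
            assert modified_zscore(c, x) == pytest.approx(
                brute_force_zscore(counts, c.first, c.last, x), abs=1e-9
            )


def test_zscore_invariant_under_constant_shift():
    """Adding a constant to every count leaves Z unchanged when sigma > 0."""
    base = {10: 2, 11: 1, 12: 10, 13: 1, 14: 3}
    c0 = make_cluster(base)
    for const in (1, 5, 40):
        shifted = make_cluster({p: v + const for p, v in base.items()})
        for x in c0.positions():
            assert modified_zscore(shifted, x) == pytest.approx(
                modified_zscore(c0, x), rel=1e-12
            )


# --- filtering and replicate reconciliation -------------------------------


def test_filter_boundaries():
    c = make_cluster({10: 2, 11: 1, 12: 10, 13: 1, 14: 3})
    assert 12 in filter_teps([c])  # r=10, Z~9.95
    assert 10 not in filter_teps([c])  # r=2 below count threshold
    exact = make_cluster({1: 3, 2: 0, 3: 1, 4: 0, 5: 1})
    z = modified_zscore(exact, 1)
    surviving = filter_teps([exact], min_reads=3, min_z=min(z, 3.0))
    assert 1 in surviving  # r=3 and Z at threshold are both kept


def test_reconciliation_window_matches_worked_example():
    """Replicate clusters spanning 3-25 and 13-42 are reconciled within 13-25."""
    c1 = make_cluster({3: 5, 25: 5})
    c2 = make_cluster({13: 5, 42: 5})
    assert intersection_window(c1, c2) == (13, 25)
    assert intersection_window(make_cluster({3: 1, 25: 1}), make_cluster({30: 1, 42: 1})) is None


def test_reconciliation_picks_highest_combined_count():
    c1 = make_cluster({13: 1, 15: 5, 20: 6, 25: 1})
    c2 = make_cluster({13: 1, 15: 4, 20: 6, 26: 1})
    s1 = {15: (5, 10.0), 20: (6, 10.0)}
    s2 = {15: (4, 10.0), 20: (6, 10.0)}
    recs = reconcile_replicates([c1], [c2], s1, s2)
    assert [(r.position, r.count_r1, r.count_r2) for r in recs] == [(20, 6, 6)]


def test_single_replicate_peaks_never_emitted():
    c1 = make_cluster({100: 9})
    c2 = make_cluster({100: 1})  # fails the count filter in replicate 2
    recs = reconcile_replicates([c1], [c2], {100: (9, math.inf)}, {})
    assert recs == []


def test_emitted_teps_lie_inside_both_replicate_spans(noisy_result, noisy_sim):
    _, _, truth, ends, _ = noisy_sim
    for rec in noisy_result.tep:
        assert rec.count_r1 >= 3 and rec.count_r2 >= 3
        assert min(rec.zscore_r1, rec.zscore_r2) >= 3
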