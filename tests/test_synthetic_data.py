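import pytest

from tuarch.regulatory_features import expression_table
from tuarch.synthetic_data import (
    PackingError,
    SimConfig,
    simulate_all,
    simulate_coverage,
    simulate_end_profiles,
    simulate_truth,
)


SMALL = dict(n_genes=20, genome_length=80_000)


def test_full_determinism_under_seed():
    a = simulate_all(SimConfig(seed=1, **SMALL))
    b = simulate_all(SimConfig(seed=1, **SMALL))
    assert a[0].sequence == b[0].sequence
    assert a[1].genes == b[1].genes
    assert a[1].true_tu == b[1].true_tu
    assert {k: p.counts for k, p in a[2].items()} == {k: p.counts for k, p in b[2].items()}
    assert {k: p.counts for k, p in a[3].items()} == {k: p.counts for k, p in b[3].items()}
    c = simulate_all(SimConfig(seed=2, **SMALL))
    assert a[0].sequence != c[0].sequence


def test_leaderless_fraction_one_puts_every_tss_at_start_codon():
    _, truth = simulate_truth(SimConfig(seed=3, leaderless_fraction=1.0, **SMALL))
    by_id = {g.gene_id: g for g in truth.genes}
    for site in truth.true_tss:
        assert site.position == by_id[site.gene_id].five_prime


def test_planted_leaderless_fraction_matches_flags():
    _, truth = simulate_truth(SimConfig(seed=4, leaderless_fraction=0.2, **SMALL))
    by_id = {g.gene_id: g for g in truth.genes}
    n_at_codon = sum(
        1
        for s in truth.true_tss
        if s.position == by_id[s.gene_id].five_prime
    )
    operons = {tu.gene_ids[0]: tu.leaderless for tu in truth.true_tu}
    assert n_at_codon == sum(operons.values())


def test_gene_placement_respects_operon_gap_structure():
    _, truth = simulate_truth(SimConfig(seed=5, **SMALL))
    for tu in truth.true_tu:
        by_id = {g.gene_id: g for g in truth.genes}
        members = sorted((by_id[g] for g in tu.gene_ids), key=lambda g: g.start)
        for a, b in zip(members, members[1:]):
            assert 0 < b.start - a.end - 1 <= 500
        lo, hi = sorted((tu.tss, tu.tep))
        assert lo <= members[0].start and members[-1].end <= hi


def test_noise_free_profiles_land_only_on_planted_sites():
    config = SimConfig(
        seed=6,
        background_rate=0.0,
        peak_jitter_sd=0.0,
        tap_minus_processed_site_rate=0.0,
        noise_free=True,
        **SMALL,
    )
    _, truth = simulate_truth(config)
    ends = simulate_end_profiles(truth, config)
    tss_pos = {(s.position, s.strand) for s in truth.true_tss}
    for strand in "+-":
        prof = ends[("TAP_PLUS", strand)]
        assert {(p, strand) for p, _ in prof.items_sorted()} == {
            t for t in tss_pos if t[1] == strand
        }
        for pos, count in prof.items_sorted():
            assert count == round(config.tss_peak_count_mean)
            # TAP(-) sees only the thinned share of primary 5' ends
            assert ends[("TAP_MINUS", strand)].get(pos) == round(0.2 * count)
    tep_pos = {(s.position, s.strand) for s in truth.true_tep}
    for strand in "+-":
        for label in ("TERMSEQ_R1", "TERMSEQ_R2"):
            prof = ends[(label, strand)]
            assert {(p, strand) for p, _ in prof.items_sorted()} == {
                t for t in tep_pos if t[1] == strand
            }


def test_processed_sites_raise_tap_minus_toward_tap_plus():
    """True TSSs reach TAP(-) only through thinning (~20% of reads), while
    processed sites contribute full-strength peaks to both libraries."""
    base = dict(seed=7, background_rate=0.0, **SMALL)
    _, truth = simulate_truth(SimConfig(**base))
    thinned_only = simulate_end_profiles(
        truth, SimConfig(tap_minus_processed_site_rate=0.0, **base)
    )
    with_processed = simulate_end_profiles(
        truth, SimConfig(tap_minus_processed_site_rate=2.0, **base)
    )

    def ratio(profiles):
        minus = sum(profiles[("TAP_MINUS", s)].total() for s in "+-")
        plus = sum(profiles[("TAP_PLUS", s)].total() for s in "+-")
        return minus / plus

    assert ratio(thinned_only) == pytest.approx(0.2, abs=0.05)
    assert ratio(with_processed) > 0.4


def test_coverage_is_a_plateau_between_tss_and_tep():
    config = SimConfig(seed=8, background_rate=0.0, **SMALL)
    _, truth = simulate_truth(config)
    cov = simulate_coverage(truth, config)
    tu = max(truth.true_tu, key=lambda t: abs(t.tep - t.tss))
    lo, hi = sorted((tu.tss, tu.tep))
    prof = cov[("RNASEQ", tu.strand)]
    inside = sum(prof.get(p) for p in range(lo, hi + 1)) / (hi - lo + 1)
    # positions outside every transcribed span on this strand
    spans = [
        sorted((t.tss, t.tep)) for t in truth.true_tu if t.strand == tu.strand
    ]
    desert = [
        p
        for p in range(1, config.genome_length, 97)
        if not any(a <= p <= b for a, b in spans)
    ]
    outside = sum(prof.get(p) for p in desert) / len(desert)
    assert inside > 10 * max(outside, 1e-9)


def test_noiseless_te_factors_recovered_through_rpkm_ratio():
    config = SimConfig(
        seed=9,
        background_rate=0.0,
        peak_jitter_sd=0.0,
        tap_minus_processed_site_rate=0.0,
        internal_tep_fraction=0.0,
        rna_level_log_sd=0.0,
        noise_free=True,
        **SMALL,
    )
    _, truth = simulate_truth(config)
    cov = simulate_coverage(truth, config)
    rna = {"+": cov[("RNASEQ", "+")], "-": cov[("RNASEQ", "-")]}
    ribo = {"+": cov[("RIBOSEQ", "+")], "-": cov[("RIBOSEQ", "-")]}
    # normalise both libraries with the same total so the planted factor is
    # recovered on its own scale
    table = expression_table(truth.genes, rna, ribo, total_rna=1e6, total_ribo=1e6)
    for rec in table:
        assert rec.te == pytest.approx(truth.te_factor[rec.gene_id], rel=1e-9)
    # and the ratio between genes is normalisation-free
    t0, t1 = table[0], table[1]
    assert t0.te / t1.te == pytest.approx(
        truth.te_factor[t0.gene_id] / truth.te_factor[t1.gene_id], rel=1e-9
    )


def test_infeasible_packing_raises():
    with pytest.raises((PackingError, ValueError)):
        simulate_truth(SimConfig(seed=10, n_genes=100, genome_length=30_000))
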