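import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tuarch.genome_io import GeneModel, Genome
from tuarch.regulatory_features import (
    expression_table,
    extract_windows,
    nucleotide_stats,
    rbs_windows,
    rpkm,
    spacer_length,
    start_codon_tally,
    translation_efficiency,
    utr_lengths,
)
from tuarch.tss_caller import TssRecord
from .conftest import profile


def tss(pos, strand="+"):
    return TssRecord(pos, strand, tap_plus_count=10, category="P")


GENOME = Genome("A" * 5000)


@pytest.mark.parametrize(
    "tss_pos,expected_len,leaderless",
    [(900, 100, False), (1000, 0, True), (995, 5, True), (991, 9, True), (990, 10, False)],
)
def test_utr_length_and_leaderless_boundary(tss_pos, expected_len, leaderless):
    genes = [GeneModel("g1", "+", 1000, 2000)]
    (rec,) = utr_lengths({"g1": tss(tss_pos)}, genes)
    assert rec.utr_length == expected_len
    assert rec.leaderless is leaderless
    assert not rec.tss_internal


def test_utr_internal_tss_recorded_as_zero():
    genes = [GeneModel("g1", "+", 1000, 2000)]
    (rec,) = utr_lengths({"g1": tss(1050)}, genes)
    assert rec.utr_length == 0 and rec.tss_internal


def test_utr_minus_strand_mirrors_plus():
    plus = utr_lengths({"gp": tss(900)}, [GeneModel("gp", "+", 1000, 2000)])
    minus = utr_lengths(
        {"gm": tss(2100, "-")}, [GeneModel("gm", "-", 1000, 2000)]
    )
    assert plus[0].utr_length == minus[0].utr_length == 100


def test_start_codon_tally_counts_by_class():
    seq = ["C"] * 5000
    seq[99:102] = list("ATG")  # + gene at 100
    seq[199:202] = list("ATG")  # + gene at 200
    # - strand gene ending at 900: reverse complement of ATG is CAT
    seq[897:900] = list("CAT")
    genome = Genome("".join(seq))
    genes = [
        GeneModel("a", "+", 100, 150),
        GeneModel("b", "+", 200, 250),
        GeneModel("c", "-", 850, 900),
    ]
    utrs = utr_lengths(
        {"a": tss(100), "b": tss(200), "c": tss(950, "-")}, genes
    )
    table = start_codon_tally(genes, genome, utrs)
    assert table.loc["ATG", "leaderless"] == 2  # a and b start at their TSS
    assert table.loc["ATG", "leadered"] == 1  # c has a 50-nt 5'-UTR
    assert table.loc["ATG", "all"] == 3
    assert table["all"].sum() == 3


def test_promoter_window_coordinates():
    (name, seq) = extract_windows([(1000, "+")], GENOME, "minus10")[0]
    assert len(seq) == 22  # 20 upstream .. 1 downstream inclusive of the TSS
    (n2, s2) = extract_windows([(1000, "+")], GENOME, "minus35")[0]
    assert len(s2) == 16
    (n3, s3) = extract_windows([(1000, "+")], GENOME, "tep_context")[0]
    assert len(s3) == 62
    (n4, s4) = extract_windows([(1000, "+")], GENOME, "tep_upstream")[0]
    assert len(s4) == 41


def test_minus_strand_window_is_reverse_complemented():
    seq = list("A" * 2000)
    seq[1024:1040] = list("G" * 16)  # genomic 1025..1040
    genome = Genome("".join(seq))
    (_, window) = extract_windows([(1000, "-")], genome, "minus35")[0]
    assert window == "C" * 16  # -40..-25 upstream on '-' is genomic 1025..1040


def test_window_off_genome_edge_dropped():
    with pytest.warns(UserWarning):
        assert extract_windows([(5, "+")], GENOME, "minus10") == []


def test_rbs_window_requires_utr_longer_than_10():
    genes = [GeneModel("short", "+", 1000, 1500), GeneModel("long", "+", 3000, 3500)]
    utrs = utr_lengths({"short": tss(992), "long": tss(2950)}, genes)
    windows = dict(rbs_windows(utrs, genes, GENOME))
    assert "rbs_short" not in windows  # UTR of 8 nt has no RBS window
    assert len(windows["rbs_long"]) == 25


def test_spacer_length_from_element_intervals():
    # TSS-relative: -35 element at [-34,-31], -10 element at [-12,-7] -> 18 nt
    assert spacer_length((-34, -31), (-12, -7)) == 18
    assert spacer_length((-34, -31), (-30, -25)) == 0  # abutting
    with pytest.warns(UserWarning):
        assert spacer_length((-34, -25), (-27, -20)) == 0  # overlapping
    # genomic coordinates on the minus strand mirror: the -35 element sits
    # at higher coordinates than the -10 element
    assert spacer_length((1009, 1012), (988, 993), strand="-") == 15


def test_nucleotide_frequencies_sum_to_one_and_flag_planted_base():
    rng = np.random.default_rng(0)
    seq = rng.choice(list("ACGT"), size=20_000)
    sites = []
    for pos in range(1000, 11000, 100):
        seq[pos] = "T"  # offset +1 relative to a site at `pos` (1-based)
        sites.append((pos, "+"))
    genome = Genome("".join(seq))
    freq, enrich = nucleotide_stats(
        sites, genome, genes=[], offsets=(-5, 5), n_background=2000, seed=1
    )
    assert np.allclose(freq.sum(axis=1).to_numpy(), 1.0)
    assert freq.loc[1, "T"] == 1.0
    # uniform background: enrichment of the planted base ~ 1/0.25 = 4
    assert enrich.loc[1, "T"] == pytest.approx(4.0, rel=0.2)


def test_rpkm_definition_and_examples():
    assert rpkm(10, 1000, 1_000_000) == 10.0
    assert rpkm(0, 1000, 1_000_000) == 0.0
    assert rpkm(50, 500, 2_000_000) == 50.0
    with pytest.raises(ValueError):
        rpkm(10, 0, 1_000_000)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    st.integers(min_value=1, max_value=10_000),
    st.integers(min_value=100, max_value=100_000),
    st.integers(min_value=1, max_value=10),
)
def test_rpkm_scaling_laws(count, length, k):
    base = rpkm(count, length, 1e6)
    assert rpkm(k * count, length, 1e6) == pytest.approx(k * base)
    assert rpkm(count, k * length, 1e6) == pytest.approx(base / k)
    assert rpkm(count, length, k * 1e6) == pytest.approx(base / k)


def test_translation_efficiency_ratio_and_missing_value():
    assert translation_efficiency(30.0, 10.0) == 3.0
    assert translation_efficiency(0.0, 10.0) == 0.0
    assert np.isnan(translation_efficiency(5.0, 0.0))


def test_expression_table_on_uniform_coverage():
    genes = [GeneModel("g1", "+", 1, 1000)]
    rna = {"+": profile({p: 10 for p in range(1, 1001)}, label="RNASEQ"),
           "-": profile({}, strand="-", label="RNASEQ")}
    ribo = {"+": profile({p: 30 for p in range(1, 1001)}, label="RIBOSEQ"),
            "-": profile({}, strand="-", label="RIBOSEQ")}
    (rec,) = expression_table(genes, rna, ribo, total_rna=1e6, total_ribo=1e6)
    assert rec.te == pytest.approx(3.0)
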