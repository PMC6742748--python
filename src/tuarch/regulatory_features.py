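"""Sequence- and expression-level features around called sites.

Covers 5'-UTR lengths and leaderless calls (UTR of 0-9 nt), start-codon
usage, promoter/RBS/terminator window extraction for external motif or
folding tools, promoter spacer lengths, per-position nucleotide frequency
and enrichment over random intergenic background, and RPKM-based
translation efficiency (Ribo-Seq RPKM / RNA-Seq RPKM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import EndProfile, GeneModel, Genome
from .tss_caller import TssRecord

LEADERLESS_MAX_UTR = 9

#: start codons tallied individually; anything else lands in "other"
START_CODON_WATCHLIST = ("ATG", "GTG", "TTG", "CTG", "ATT", "ATC")

#: window kinds as (upstream, downstream) offsets relative to the site,
#: inclusive at both ends in transcript orientation
WINDOW_KINDS = {
    "minus10": (-20, 1),  # 22 nt around the TSS for -10 element search
    "minus35": (-40, -25),  # 16 nt for -35 element search
    "tep_context": (-41, 20),  # 62 nt for terminator alignment
    "tep_upstream": (-41, -1),  # 41 nt fed to folding-energy prediction
}


@dataclass
class UtrRecord:
    gene_id: str
    utr_length: int
    leaderless: bool
    start_codon: str
    tss_internal: bool = False


@dataclass
class ExpressionRecord:
    gene_id: str
    rpkm_rna: float
    rpkm_ribo: float
    te: float  # NaN when rpkm_rna == 0


@dataclass
class SpacerRecord:
    tss_position: int
    minus35_end: int
    minus10_start: int
    spacer_length: int


def utr_lengths(
    primary_tss: dict[str, TssRecord],
    genes: list[GeneModel],
    genome: Genome | None = None,
) -> list[UtrRecord]:
    """5'-UTR lengths for genes with a primary TSS.

    The UTR is the distance from the TSS to the start codon along the
    strand. A TSS downstream of the start codon (possible through the
    +100 nt assignment window) is recorded as length 0 with
    ``tss_internal`` set. Leaderless means 0-9 nt.
    """
    records = []
    by_id = {g.gene_id: g for g in genes}
    for gene_id in sorted(primary_tss):
        tss = primary_tss[gene_id]
        gene = by_id.get(gene_id)
        if gene is None:
            continue
        g5 = gene.five_prime
        raw = g5 - tss.position if gene.strand == "+" else tss.position - g5
        internal = raw < 0
        length = max(raw, 0)
        codon = ""
        if genome is not None:
            if gene.strand == "+":
                codon = genome.subseq(g5, g5 + 2, "+")
            else:
                codon = genome.subseq(g5 - 2, g5, "-")
        records.append(
            UtrRecord(
                gene_id=gene_id,
                utr_length=length,
                leaderless=length <= LEADERLESS_MAX_UTR,
                start_codon=codon,
                tss_internal=internal,
            )
        )
    return records


def start_codon_tally(
    genes: list[GeneModel],
    genome: Genome,
    utrs: list[UtrRecord],
    watchlist: tuple[str, ...] = START_CODON_WATCHLIST,
) -> pd.DataFrame:
    """Start-codon usage per UTR class.

    Returns a codon x {leaderless, leadered, all} count table over the genes
    carrying a UTR record; codons outside the watchlist count as "other".
    """
    by_id = {g.gene_id: g for g in genes}
    index = list(watchlist) + ["other"]
    table = pd.DataFrame(0, index=index, columns=["leaderless", "leadered", "all"])
    for rec in utrs:
        gene = by_id.get(rec.gene_id)
        if gene is None:
            continue
        g5 = gene.five_prime
        codon = (
            genome.subseq(g5, g5 + 2, "+")
            if gene.strand == "+"
            else genome.subseq(g5 - 2, g5, "-")
        )
        row = codon if codon in watchlist else "other"
        cls = "leaderless" if rec.leaderless else "leadered"
        table.loc[row, cls] += 1
        table.loc[row, "all"] += 1
    return table


def _window_bounds(position: int, strand: str, rel: tuple[int, int]) -> tuple[int, int]:
    a, b = rel
    if strand == "+":
        return position + a, position + b
    return position - b, position - a


def extract_windows(
    sites: list[tuple[int, str]],
    genome: Genome,
    kind: str,
) -> list[tuple[str, str]]:
    """Extract fixed windows around sites, in transcript orientation.

    ``sites`` are (position, strand) pairs; windows are taken relative to
    the site per :data:`WINDOW_KINDS`, reverse-complemented on the minus
    strand. Windows that would run off the genome are dropped with a
    warning. Returns (name, sequence) pairs.
    """
    if kind not in WINDOW_KINDS:
        raise ValueError(f"unknown window kind {kind!r}")
    rel = WINDOW_KINDS[kind]
    out = []
    for pos, strand in sites:
        lo, hi = _window_bounds(pos, strand, rel)
        if lo < 1 or hi > genome.length:
            warnings.warn(f"{kind} window at {pos}{strand} truncated by genome edge; dropped")
            continue
        out.append((f"{kind}_{pos}{strand}", genome.subseq(lo, hi, strand)))
    return out


def rbs_windows(
    utrs: list[UtrRecord],
    genes: list[GeneModel],
    genome: Genome,
    max_len: int = 25,
    min_utr: int = 10,
) -> list[tuple[str, str]]:
    """5'-UTR windows ending at the start codon, for RBS motif search.

    Only genes whose UTR is longer than ``min_utr`` qualify; the window is
    the last min(max_len, utr_length) UTR nucleotides.
    """
    by_id = {g.gene_id: g for g in genes}
    out = []
    for rec in utrs:
        if rec.utr_length <= min_utr:
            continue
        gene = by_id.get(rec.gene_id)
        if gene is None:
            continue
        n = min(max_len, rec.utr_length)
        g5 = gene.five_prime
        if gene.strand == "+":
            lo, hi = g5 - n, g5 - 1
        else:
            lo, hi = g5 + 1, g5 + n
        if lo < 1 or hi > genome.length:
            warnings.warn(f"rbs window for {rec.gene_id} truncated by genome edge; dropped")
            continue
        out.append((f"rbs_{rec.gene_id}", genome.subseq(lo, hi, gene.strand)))
    return out


def write_windows_fasta(windows: list[tuple[str, str]], path: str) -> None:
    with open(path, "w") as out:
        for name, seq in windows:
            out.write(f">{name}\n{seq}\n")


def spacer_length(
    minus35: tuple[int, int],
    minus10: tuple[int, int],
    strand: str = "+",
) -> int:
    """Nucleotides strictly between the -35 element's 3' end and the -10
    element's 5' end.

    Elements are (low, high) genomic intervals on the TSS strand; TSS-
    relative coordinates work too as long as both use the same frame.
    Overlapping or abutting elements give spacer 0 (with a warning when
    they overlap).
    """
    m35_lo, m35_hi = sorted(minus35)
    m10_lo, m10_hi = sorted(minus10)
    if strand == "+":
        spacer = m10_lo - m35_hi - 1
    else:
        spacer = m35_lo - m10_hi - 1
    if spacer < 0:
        warnings.warn("promoter elements overlap; spacer reported as 0")
        return 0
    return spacer


def intergenic_positions(genes: list[GeneModel], genome_length: int) -> np.ndarray:
    """1-based positions outside every gene body on either strand."""
    mask = np.ones(genome_length + 1, dtype=bool)
    mask[0] = False
    for g in genes:
        mask[g.start : g.end + 1] = False
    return np.flatnonzero(mask)


def nucleotide_stats(
    sites: list[tuple[int, str]],
    genome: Genome,
    genes: list[GeneModel],
    offsets: tuple[int, int] = (-41, 20),
    n_background: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-offset nucleotide frequency at sites and enrichment over background.

    Background positions are drawn uniformly (seeded) from intergenic space
    with random strand, and the same windows are tabulated; enrichment is
    site frequency divided by background frequency at the matched offset.
    """
    if not sites:
        raise ValueError("no sites given")
    rng = np.random.default_rng(seed)
    pool = intergenic_positions(genes, genome.length)
    lo_off, hi_off = offsets
    margin = max(abs(lo_off), abs(hi_off))
    pool = pool[(pool > margin) & (pool <= genome.length - margin)]
    if pool.size == 0:
        raise ValueError("no intergenic background positions available")
    bg_pos = rng.choice(pool, size=n_background, replace=True)
    bg_strand = rng.choice(np.array(["+", "-"]), size=n_background)
    background = list(zip((int(p) for p in bg_pos), bg_strand))

    def freq_table(site_list):
        rows = []
        for pos, strand in site_list:
            glo, ghi = _window_bounds(pos, strand, (lo_off, hi_off))
            if glo < 1 or ghi > genome.length:
                continue
            rows.append(genome.subseq(glo, ghi, strand))
        if not rows:
            raise ValueError("all windows fell off the genome")
        arr = np.array([list(s) for s in rows])
        cols = range(lo_off, hi_off + 1)
        table = pd.DataFrame(index=list(cols), columns=list("ACGT"), dtype=float)
        for j, off in enumerate(cols):
            col = arr[:, j]
            for base in "ACGT":
                table.loc[off, base] = float(np.mean(col == base))
        return table

    site_freq = freq_table(sites)
    bg_freq = freq_table(background)
    enrichment = site_freq / bg_freq.replace(0.0, np.nan)
    return site_freq, enrichment


def rpkm(read_count: float, gene_length: int, total_mapped: float) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if gene_length <= 0:
        raise ValueError("gene_length must be positive")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return read_count / (gene_length / 1000.0) / (total_mapped / 1e6)


def translation_efficiency(rpkm_ribo: float, rpkm_rna: float) -> float:
    """Ribo-Seq RPKM over RNA-Seq RPKM; NaN when the transcript is absent."""
    if rpkm_rna == 0:
        return float("nan")
    return rpkm_ribo / rpkm_rna


def reads_from_coverage(
    profile: EndProfile, start: int, end: int, read_length: int = 50
) -> float:
    """Approximate read count over [start, end] from a coverage profile:
    summed depth divided by the read length."""
    depth = sum(profile.get(p) for p in range(start, end + 1))
    return depth / read_length


def expression_table(
    genes: list[GeneModel],
    rnaseq: dict[str, EndProfile],
    riboseq: dict[str, EndProfile],
    read_length: int = 50,
    total_rna: float | None = None,
    total_ribo: float | None = None,
) -> list[ExpressionRecord]:
    """Per-gene RPKM for both libraries and their translation-efficiency ratio.

    ``rnaseq``/``riboseq`` map strand to coverage profile. Library totals
    default to the total mapped reads implied by each library's coverage;
    pass explicit totals to normalise both libraries identically.
    """
    if total_rna is None:
        total_rna = sum(p.total() for p in rnaseq.values()) / read_length
    if total_ribo is None:
        total_ribo = sum(p.total() for p in riboseq.values()) / read_length
    out = []
    for gene in genes:
        n_rna = reads_from_coverage(rnaseq[gene.strand], gene.start, gene.end, read_length)
        n_ribo = reads_from_coverage(riboseq[gene.strand], gene.start, gene.end, read_length)
        r_rna = rpkm(n_rna, gene.length, total_rna) if total_rna > 0 else 0.0
        r_ribo = rpkm(n_ribo, gene.length, total_ribo) if total_ribo > 0 else 0.0
        out.append(
            ExpressionRecord(
                gene_id=gene.gene_id,
                rpkm_rna=r_rna,
                rpkm_ribo=r_ribo,
                te=translation_efficiency(r_ribo, r_rna),
            )
        )
    return out
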