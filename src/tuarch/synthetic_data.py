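"""Synthetic genome, TU ground truth, and end/coverage profile simulator.

The generator emulates the data a bacterial TU-architecture experiment
produces over a GC-rich genome: an operon-structured annotation (intergenic
gaps within an operon stay at or below 500 bp, gaps between operons exceed
it), one true TSS and one true TEP per operon, and the six library profiles
the pipeline consumes:

* TAP(+) dRNA-Seq 5'-end peaks at every true TSS, spread by integer-rounded
  Gaussian jitter; the TAP(-) library sees only a binomial thinning of those
  reads (primary 5' triphosphate ends are not ligatable without TAP).
* Processed 5' ends at a low per-kb rate produce equal-mean peaks in both
  TAP libraries - exactly the contrast the TAP filter exploits.
* Two independent Term-Seq replicates with Poisson peaks at each true TEP.
* Uniform Poisson background in all end libraries.
* RNA-Seq coverage as a per-TU plateau between TSS and TEP, and Ribo-Seq
  coverage over each CDS scaled by that gene's true translation-efficiency
  factor.

With ``noise_free=True`` every count becomes its expected value (and jitter
and background are suppressed), so downstream recovery can be checked for
exact equality with the planted architecture. Everything is deterministic
under (seed, config).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .genome_io import (
    EndProfile,
    GeneModel,
    Genome,
    write_annotation,
    write_end_profile,
    write_genome,
)

START_CODONS = ("ATG", "GTG", "TTG")
START_CODON_PROBS = (0.7, 0.2, 0.1)
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class SimConfig:
    seed: int = 0
    genome_length: int = 150_000
    gc_fraction: float = 0.72
    n_genes: int = 60
    gene_length_range: tuple[int, int] = (300, 1500)
    #: P(operon has 1, 2, 3 genes) - the intergenic-gap mixture follows
    operon_size_probs: tuple[float, ...] = (0.75, 0.15, 0.10)
    intra_operon_gap_range: tuple[int, int] = (20, 400)
    inter_operon_gap_range: tuple[int, int] = (700, 1500)
    leaderless_fraction: float = 0.20
    utr_length_range: tuple[int, int] = (10, 300)
    tep_offset_range: tuple[int, int] = (20, 200)
    #: probability that an intra-operon gap carries an additional transcript
    #: 3' end, yielding overlapping TU variants (a processed poly-cistronic
    #: transcript ends between two of its genes)
    internal_tep_fraction: float = 0.3
    tss_peak_count_mean: float = 10.0
    tep_peak_count_mean: float = 10.0
    peak_jitter_sd: float = 1.0
    background_rate: float = 0.01  # expected reads per nt per library/strand
    tap_minus_processed_site_rate: float = 0.01  # sites per kb per strand
    tap_minus_thinning: float = 0.2
    rna_level: float = 50.0
    rna_level_log_sd: float = 0.3
    te_log_sd: float = 0.5
    read_length: int = 50
    noise_free: bool = False

    def validate(self) -> None:
        if not 0 <= self.gc_fraction <= 1:
            raise ValueError("gc_fraction must be in [0,1]")
        if not 0 <= self.leaderless_fraction <= 1:
            raise ValueError("leaderless_fraction must be in [0,1]")
        for name in (
            "tss_peak_count_mean",
            "tep_peak_count_mean",
            "peak_jitter_sd",
            "background_rate",
            "tap_minus_processed_site_rate",
            "rna_level",
            "te_log_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.tap_minus_thinning <= 1:
            raise ValueError("tap_minus_thinning must be in [0,1]")
        mean_gene = sum(self.gene_length_range) / 2
        if self.n_genes * mean_gene >= self.genome_length:
            raise ValueError("genes cannot fit: n_genes * mean length >= genome_length")


@dataclass(frozen=True)
class TrueSite:
    position: int
    strand: str
    gene_id: str | None = None


@dataclass(frozen=True)
class TrueTu:
    tss: int
    tep: int
    strand: str
    gene_ids: tuple[str, ...]
    leaderless: bool
    level: float


@dataclass
class GroundTruth:
    genes: list[GeneModel]
    true_tss: list[TrueSite]
    true_tep: list[TrueSite]
    true_tu: list[TrueTu]
    te_factor: dict[str, float] = field(default_factory=dict)


class PackingError(ValueError):
    """Raised when the requested genes do not fit in the genome."""


def _draw_int(rng, lo_hi: tuple[int, int]) -> int:
    lo, hi = lo_hi
    return int(rng.integers(lo, hi + 1))


def simulate_truth(config: SimConfig) -> tuple[Genome, GroundTruth]:
    """Place operons along a random GC-rich genome and derive ground truth.

    Each operon gets a TSS 5' of its first gene (at the start codon for
    leaderless operons, 10-300 nt upstream otherwise) and a TEP 20-200 nt
    past its last stop codon; both always land inside the inter-operon gap,
    clear of the neighbouring operon's sites.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    L = config.genome_length

    genes: list[GeneModel] = []
    operons: list[dict] = []
    cursor = _draw_int(rng, config.inter_operon_gap_range)
    placed = 0
    while placed < config.n_genes:
        k = 1 + int(rng.choice(len(config.operon_size_probs), p=config.operon_size_probs))
        k = min(k, config.n_genes - placed)
        strand = "+" if rng.random() < 0.5 else "-"
        members = []
        for i in range(k):
            length = _draw_int(rng, config.gene_length_range)
            length -= length % 3
            start = cursor
            end = start + length - 1
            gid = f"SIM_{placed + len(members) + 1:04d}"
            members.append(GeneModel(gid, strand, start, end))
            cursor = end + 1 + _draw_int(rng, config.intra_operon_gap_range)
        cursor = members[-1].end + 1 + _draw_int(rng, config.inter_operon_gap_range)
        max_utr = config.utr_length_range[1]
        margin = max_utr + config.tep_offset_range[1]
        if members[-1].end + margin >= L or cursor + max_utr >= L:
            raise PackingError(
                f"placed only {placed} of {config.n_genes} genes in {L} nt; "
                "increase genome_length"
            )
        genes.extend(members)
        operons.append({"strand": strand, "genes": members})
        placed += k

    true_tss: list[TrueSite] = []
    true_tep: list[TrueSite] = []
    true_tu: list[TrueTu] = []
    te_factor: dict[str, float] = {}
    for op in operons:
        strand = op["strand"]
        members = op["genes"]
        first = members[0] if strand == "+" else members[-1]
        last = members[-1] if strand == "+" else members[0]
        leaderless = rng.random() < config.leaderless_fraction
        utr = 0 if leaderless else _draw_int(rng, config.utr_length_range)
        tep_off = _draw_int(rng, config.tep_offset_range)
        if strand == "+":
            tss = first.start - utr
            tep = last.end + tep_off
            ordered = members
        else:
            tss = first.end + utr
            tep = last.start - tep_off
            ordered = list(reversed(members))
        first_gene_id = ordered[0].gene_id
        level = config.rna_level * float(
            np.exp(rng.normal(0.0, config.rna_level_log_sd))
        )
        true_tss.append(TrueSite(tss, strand, first_gene_id))
        true_tep.append(TrueSite(tep, strand))
        true_tu.append(
            TrueTu(
                tss=tss,
                tep=tep,
                strand=strand,
                gene_ids=tuple(g.gene_id for g in ordered),
                leaderless=leaderless,
                level=level,
            )
        )
        # optional additional 3' ends inside intra-operon gaps: a processed
        # poly-cistronic transcript also ends between two of its genes,
        # creating an overlapping TU variant covering the prefix genes
        for i in range(len(ordered) - 1):
            if rng.random() >= config.internal_tep_fraction:
                continue
            if strand == "+":
                gap = ordered[i + 1].start - ordered[i].end - 1
            else:
                gap = ordered[i].start - ordered[i + 1].end - 1
            if gap < 25:
                continue
            d = _draw_int(rng, (10, gap - 10))
            pos = (
                ordered[i].end + d if strand == "+" else ordered[i].start - d
            )
            true_tep.append(TrueSite(pos, strand))
            true_tu.append(
                TrueTu(
                    tss=tss,
                    tep=pos,
                    strand=strand,
                    gene_ids=tuple(g.gene_id for g in ordered[: i + 1]),
                    leaderless=leaderless,
                    level=level,
                )
            )
    for g in genes:
        te_factor[g.gene_id] = float(np.exp(rng.normal(0.0, config.te_log_sd)))

    # random GC-rich sequence with planted start and stop codons
    p = np.array(
        [
            (1 - config.gc_fraction) / 2,
            config.gc_fraction / 2,
            config.gc_fraction / 2,
            (1 - config.gc_fraction) / 2,
        ]
    )
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=L, p=p)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for g in genes:
        start_codon = str(rng.choice(np.array(START_CODONS), p=np.array(START_CODON_PROBS)))
        stop_codon = str(rng.choice(np.array(STOP_CODONS)))
        if g.strand == "+":
            seq[g.start - 1 : g.start + 2] = list(start_codon)
            seq[g.end - 3 : g.end] = list(stop_codon)
        else:
            seq[g.end - 3 : g.end] = [comp[b] for b in reversed(start_codon)]
            seq[g.start - 1 : g.start + 2] = [comp[b] for b in reversed(stop_codon)]
    genome = Genome(sequence="".join(seq), name="simchr")

    genes_sorted = sorted(genes, key=lambda g: (g.start, g.gene_id))
    return genome, GroundTruth(genes_sorted, true_tss, true_tep, true_tu, te_factor)


def _add_peak(array, position, n_reads, jitter_sd, rng, noise_free):
    """Spread ``n_reads`` around ``position`` with rounded Gaussian jitter."""
    L = len(array) - 1
    if n_reads <= 0:
        return
    if noise_free or jitter_sd == 0:
        array[min(max(position, 1), L)] += n_reads
        return
    offsets = np.rint(rng.normal(0.0, jitter_sd, size=n_reads)).astype(int)
    positions = np.clip(position + offsets, 1, L)
    np.add.at(array, positions, 1)


def _add_background(array, rate, rng, noise_free):
    if noise_free or rate <= 0:
        return
    L = len(array) - 1
    n = rng.poisson(rate * L)
    if n:
        positions = rng.integers(1, L + 1, size=n)
        np.add.at(array, positions, 1)


def _count(mean, rng, noise_free):
    return int(round(mean)) if noise_free else int(rng.poisson(mean))


def simulate_end_profiles(
    truth: GroundTruth, config: SimConfig
) -> dict[tuple[str, str], EndProfile]:
    """TAP(+)/TAP(-) and two Term-Seq replicate profiles, keyed (label, strand)."""
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    L = config.genome_length
    arrays = {
        (label, strand): np.zeros(L + 1, dtype=np.int64)
        for label in ("TAP_PLUS", "TAP_MINUS", "TERMSEQ_R1", "TERMSEQ_R2")
        for strand in "+-"
    }

    for site in truth.true_tss:
        n = _count(config.tss_peak_count_mean, rng, config.noise_free)
        plus = arrays[("TAP_PLUS", site.strand)]
        minus = arrays[("TAP_MINUS", site.strand)]
        if config.noise_free or config.peak_jitter_sd == 0:
            pos = min(max(site.position, 1), L)
            plus[pos] += n
            thinned = (
                int(round(config.tap_minus_thinning * n))
                if config.noise_free
                else int(rng.binomial(n, config.tap_minus_thinning))
            )
            minus[pos] += thinned
        else:
            offsets = np.rint(
                rng.normal(0.0, config.peak_jitter_sd, size=n)
            ).astype(int)
            positions = np.clip(site.position + offsets, 1, L)
            np.add.at(plus, positions, 1)
            keep = rng.random(n) < config.tap_minus_thinning
            np.add.at(minus, positions[keep], 1)

    # processed 5' ends: equal-mean peaks in both TAP libraries
    for strand in "+-":
        if config.noise_free:
            n_sites = int(round(config.tap_minus_processed_site_rate * L / 1000))
        else:
            n_sites = int(rng.poisson(config.tap_minus_processed_site_rate * L / 1000))
        positions = rng.integers(1, L + 1, size=n_sites)
        for pos in positions:
            for label in ("TAP_PLUS", "TAP_MINUS"):
                n = _count(config.tss_peak_count_mean, rng, config.noise_free)
                _add_peak(
                    arrays[(label, strand)],
                    int(pos),
                    n,
                    config.peak_jitter_sd,
                    rng,
                    config.noise_free,
                )

    for site in truth.true_tep:
        for label in ("TERMSEQ_R1", "TERMSEQ_R2"):
            n = _count(config.tep_peak_count_mean, rng, config.noise_free)
            arrays[(label, site.strand)][site.position] += n

    for key, array in arrays.items():
        _add_background(array, config.background_rate, rng, config.noise_free)

    return {
        (label, strand): EndProfile(
            label=label,
            strand=strand,
            counts={int(i): int(c) for i, c in zip(*[np.flatnonzero(arr), arr[np.flatnonzero(arr)]])},
        )
        for (label, strand), arr in arrays.items()
    }


def simulate_coverage(
    truth: GroundTruth, config: SimConfig
) -> dict[tuple[str, str], EndProfile]:
    """RNA-Seq plateau coverage per TU and TE-scaled Ribo-Seq coverage per CDS."""
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    L = config.genome_length
    arrays = {
        (label, strand): np.zeros(L + 1, dtype=float)
        for label in ("RNASEQ", "RIBOSEQ")
        for strand in "+-"
    }
    gene_by_id = {g.gene_id: g for g in truth.genes}
    tu_of_gene: dict[str, TrueTu] = {}
    for tu in truth.true_tu:
        for gid in tu.gene_ids:
            tu_of_gene[gid] = tu
        lo, hi = sorted((tu.tss, tu.tep))
        span = hi - lo + 1
        arr = arrays[("RNASEQ", tu.strand)]
        if config.noise_free:
            arr[lo : hi + 1] += tu.level
        else:
            arr[lo : hi + 1] += rng.poisson(tu.level, size=span)
    for gid, gene in gene_by_id.items():
        tu = tu_of_gene.get(gid)
        if tu is None:
            continue
        level = tu.level * truth.te_factor[gid]
        arr = arrays[("RIBOSEQ", gene.strand)]
        if config.noise_free:
            arr[gene.start : gene.end + 1] += level
        else:
            arr[gene.start : gene.end + 1] += rng.poisson(level, size=gene.length)
    for key, arr in arrays.items():
        if not config.noise_free and config.background_rate > 0:
            n = rng.poisson(config.background_rate * L)
            if n:
                positions = rng.integers(1, L + 1, size=n)
                np.add.at(arr, positions, 1.0)
    out = {}
    for (label, strand), arr in arrays.items():
        nz = np.flatnonzero(arr)
        counts = {int(i): (int(arr[i]) if float(arr[i]).is_integer() else float(arr[i])) for i in nz}
        out[(label, strand)] = EndProfile(label=label, strand=strand, counts=counts)
    return out


def simulate_all(config: SimConfig):
    """Convenience wrapper returning (genome, truth, end_profiles, coverage)."""
    genome, truth = simulate_truth(config)
    ends = simulate_end_profiles(truth, config)
    cov = simulate_coverage(truth, config)
    return genome, truth, ends, cov


def write_simulation(outdir: str, config: SimConfig) -> None:
    """Write FASTA, GFF3, all bedGraphs and a ground-truth TSV to ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    genome, truth, ends, cov = simulate_all(config)
    write_genome(genome, os.path.join(outdir, "genome.fa"))
    write_annotation(truth.genes, os.path.join(outdir, "genes.gff3"), chrom=genome.name)
    suffix = {"+": "plus", "-": "minus"}
    for (label, strand), profile in {**ends, **cov}.items():
        path = os.path.join(outdir, f"{label.lower()}.{suffix[strand]}.bedgraph")
        write_end_profile(profile, path, chrom=genome.name)
    with open(os.path.join(outdir, "ground_truth.tsv"), "w") as out:
        out.write("kind\tposition\tstrand\tgenes\tleaderless\tlevel\n")
        for tu in truth.true_tu:
            out.write(
                f"TU\t{tu.tss}-{tu.tep}\t{tu.strand}\t{','.join(tu.gene_ids)}\t"
                f"{int(tu.leaderless)}\t{tu.level:.4f}\n"
            )
        for site in truth.true_tss:
            out.write(f"TSS\t{site.position}\t{site.strand}\t{site.gene_id or ''}\t\t\n")
        for site in truth.true_tep:
            out.write(f"TEP\t{site.position}\t{site.strand}\t\t\t\n")
    with open(os.path.join(outdir, "te_factors.tsv"), "w") as out:
        out.write("gene_id\tte_factor\n")
        for gid in sorted(truth.te_factor):
            out.write(f"{gid}\t{truth.te_factor[gid]:.6f}\n")
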