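"""Transcription-unit assembly from classified TSSs and TEPs.

A TU runs from one TSS to one TEP on the same strand. Starting from each
primary/secondary/internal TSS the builder walks downstream gene by gene,
stopping at the first intergenic gap above 500 bp (the assumed maximum
intra-operon distance); every TEP inside the valid extent closes one TU, so
nested and overlapping TU variants are enumerated. Cis-regulatory TEPs may
only pair with TSSs assigned to the same gene. Antisense/intergenic TSSs
scan 1 kbp downstream for the first TEP or gene start codon, falling back to
the walking rules when a gene starts first.

TUs are categorized by associated genes (same-strand genes fully inside the
span, excluding the host gene of an internal TSS): one gene -> mono-
cistronic, several -> poly-cistronic, none -> cis-regulatory when the next
gene start is within 500 bp of the TSS, else sRNA. An RNA-Seq consistency
score (covered fraction of the span) flags TUs the transcriptome does not
support; TUs sharing genes, directly or through intermediates, form TU
clusters (connected components of the TU-gene graph).
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import EndProfile, GeneModel
from .tep_caller import TepRecord
from .tss_caller import TssRecord


@dataclass
class TranscriptionUnit:
    tss: TssRecord
    tep: TepRecord
    strand: str
    genes: tuple[str, ...] = ()
    category: str | None = None
    coverage_score: float | None = None
    coverage_pass: bool | None = None

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (low, high) bounds of the TU."""
        return (
            min(self.tss.position, self.tep.position),
            max(self.tss.position, self.tep.position),
        )

    @property
    def five_prime(self) -> int:
        return self.tss.position

    @property
    def three_prime(self) -> int:
        return self.tep.position


@dataclass
class TuCluster:
    tu_indices: tuple[int, ...]
    gene_ids: frozenset

    @property
    def n_tus(self) -> int:
        return len(self.tu_indices)


def _downstream_genes(genes: list[GeneModel], strand: str, from_pos: int):
    """Same-strand genes whose 5' coding start is at/after from_pos, 5'->3'."""
    same = [g for g in genes if g.strand == strand]
    if strand == "+":
        return sorted(
            (g for g in same if g.five_prime >= from_pos), key=lambda g: g.start
        )
    return sorted(
        (g for g in same if g.five_prime <= from_pos),
        key=lambda g: -g.end,
    )


def _chain_limit(
    anchor: GeneModel, genes: list[GeneModel], max_gap: int
) -> int:
    """Walk downstream from the anchor gene while intergenic gaps stay within
    ``max_gap``; the valid TU extent ends ``max_gap`` past the last chained
    gene's 3' end."""
    strand = anchor.strand
    same = sorted(
        (g for g in genes if g.strand == strand),
        key=lambda g: g.start if strand == "+" else -g.end,
    )
    i = same.index(anchor)
    last = anchor
    for nxt in same[i + 1 :]:
        gap = (
            nxt.start - last.end - 1 if strand == "+" else last.start - nxt.end - 1
        )
        if gap > max_gap:
            break
        last = nxt
    return last.three_prime + max_gap if strand == "+" else last.three_prime - max_gap


def _contained_genes(
    genes: list[GeneModel], strand: str, lo: int, hi: int
) -> tuple[str, ...]:
    inside = [
        g
        for g in genes
        if g.strand == strand and lo <= g.start and g.end <= hi
    ]
    inside.sort(key=lambda g: g.start if strand == "+" else -g.end)
    return tuple(g.gene_id for g in inside)


def assemble_tus(
    tss_records: list[TssRecord],
    tep_records: list[TepRecord],
    genes: list[GeneModel],
    max_gap: int = 500,
    scan: int = 1000,
    scan_all: bool = False,
) -> list[TranscriptionUnit]:
    """Pair classified TSSs and TEPs into TUs (see module docstring)."""
    gene_by_id = {g.gene_id: g for g in genes}
    tus: list[TranscriptionUnit] = []
    seen: set[tuple[int, int, str]] = set()

    def emit(tss: TssRecord, tep: TepRecord) -> None:
        key = (tss.position, tep.position, tss.strand)
        if key in seen:
            return
        seen.add(key)
        tu = TranscriptionUnit(tss=tss, tep=tep, strand=tss.strand)
        lo, hi = tu.span
        tu.genes = _contained_genes(genes, tss.strand, lo, hi)
        tus.append(tu)

    def teps_between(strand: str, start_excl: int, limit: int, allow_cis_gene=None):
        """Non-cis TEPs strictly downstream of the TSS and within the extent."""
        out = []
        for tep in tep_records:
            if tep.strand != strand:
                continue
            if tep.category == "C" and tep.assigned_gene != allow_cis_gene:
                continue
            if strand == "+" and start_excl < tep.position <= limit:
                out.append(tep)
            elif strand == "-" and limit <= tep.position < start_excl:
                out.append(tep)
        return out

    def walk_from_gene(tss: TssRecord, anchor: GeneModel) -> None:
        limit = _chain_limit(anchor, genes, max_gap)
        cis_gene = tss.assigned_gene
        for tep in teps_between(tss.strand, tss.position, limit, cis_gene):
            emit(tss, tep)

    for tss in tss_records:
        if tss.category in ("P", "S"):
            anchor = gene_by_id.get(tss.assigned_gene)
            if anchor is not None:
                walk_from_gene(tss, anchor)
        elif tss.category == "I":
            host = next(
                (
                    g
                    for g in genes
                    if g.strand == tss.strand and g.contains(tss.position)
                ),
                None,
            )
            if host is not None:
                walk_from_gene(tss, host)
        elif tss.category in ("A", "N"):
            strand = tss.strand
            sign = 1 if strand == "+" else -1
            window_end = tss.position + sign * scan
            lo, hi = sorted((tss.position + sign, window_end))
            in_window_teps = [
                t
                for t in tep_records
                if t.strand == strand and t.category != "C" and lo <= t.position <= hi
            ]
            in_window_starts = [
                g
                for g in genes
                if g.strand == strand and lo <= g.five_prime <= hi
            ]
            d_tep = min(
                (abs(t.position - tss.position) for t in in_window_teps),
                default=None,
            )
            d_gene = min(
                (abs(g.five_prime - tss.position) for g in in_window_starts),
                default=None,
            )
            if d_tep is not None and (d_gene is None or d_tep <= d_gene):
                chosen = [
                    t
                    for t in in_window_teps
                    if scan_all or abs(t.position - tss.position) == d_tep
                ]
                for tep in chosen:
                    emit(tss, tep)
            elif d_gene is not None:
                anchor = min(
                    (g for g in in_window_starts),
                    key=lambda g: abs(g.five_prime - tss.position),
                )
                walk_from_gene(tss, anchor)
    tus.sort(key=lambda t: (t.span[0], t.span[1], t.strand))
    return tus


def categorize_tu(
    tus: list[TranscriptionUnit],
    genes: list[GeneModel],
    srna_cutoff: int = 500,
) -> list[TranscriptionUnit]:
    """Set mono/poly-cistronic, cis_regulatory or sRNA categories in place.

    The host gene of an internal TSS never counts as associated. A gene-less
    TU is cis-regulatory when the next same-strand gene start lies within
    ``srna_cutoff`` bp of the TSS, sRNA otherwise.
    """
    for tu in tus:
        associated = list(tu.genes)
        if tu.tss.category == "I":
            host = next(
                (
                    g.gene_id
                    for g in genes
                    if g.strand == tu.strand and g.contains(tu.tss.position)
                ),
                None,
            )
            associated = [g for g in associated if g != host]
        tu.genes = tuple(associated)
        if len(associated) >= 2:
            tu.category = "polycistronic"
        elif len(associated) == 1:
            tu.category = "monocistronic"
        else:
            sign = 1 if tu.strand == "+" else -1
            dists = [
                sign * (g.five_prime - tu.tss.position)
                for g in genes
                if g.strand == tu.strand
                and sign * (g.five_prime - tu.tss.position) > 0
            ]
            nearest = min(dists, default=None)
            tu.category = (
                "cis_regulatory"
                if nearest is not None and nearest < srna_cutoff
                else "sRNA"
            )
    return tus


def coverage_consistency(
    tu: TranscriptionUnit,
    rnaseq: EndProfile,
    min_frac: float = 0.9,
    min_depth: float = 1,
) -> tuple[float, bool]:
    """Fraction of TU span positions with RNA-Seq depth >= min_depth.

    An automated surrogate for manual inspection against the transcriptome;
    failing TUs are flagged, never silently removed.
    """
    lo, hi = tu.span
    covered = sum(1 for p in range(lo, hi + 1) if rnaseq.get(p) >= min_depth)
    score = covered / (hi - lo + 1)
    tu.coverage_score = score
    tu.coverage_pass = score >= min_frac
    return score, tu.coverage_pass


def tss_coverage_step(
    tss: TssRecord,
    rnaseq: EndProfile,
    window: int = 50,
    min_depth: float = 1.0,
    min_ratio: float = 2.0,
) -> tuple[float, bool]:
    """RNA-Seq consistency flag for a called TSS.

    Transcription initiation produces a step in RNA-Seq density: depth just
    downstream of a genuine TSS is substantial and exceeds the depth just
    upstream. The flag passes when mean depth over the ``window`` nt
    downstream reaches ``min_depth`` and is at least ``min_ratio`` times the
    upstream mean. This is the automated stand-in for inspecting calls
    against the transcriptome; callers should flag, not silently delete.
    """
    sign = 1 if tss.strand == "+" else -1
    down = [tss.position + sign * k for k in range(window)]
    up = [tss.position - sign * k for k in range(1, window + 1)]
    down_mean = sum(rnaseq.get(p) for p in down) / window
    up_mean = sum(rnaseq.get(p) for p in up) / window
    passes = down_mean >= min_depth and down_mean >= min_ratio * max(up_mean, 1e-9)
    return down_mean, passes


def cluster_tus(tus: list[TranscriptionUnit]) -> list[TuCluster]:
    """Connected components of the TU-gene bipartite graph (union-find).

    TUs sharing at least one gene, directly or through a chain of TUs, join
    one cluster; gene-less TUs are singletons.
    """
    parent = list(range(len(tus)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    by_gene: dict[str, int] = {}
    for i, tu in enumerate(tus):
        for gid in tu.genes:
            if gid in by_gene:
                union(by_gene[gid], i)
            else:
                by_gene[gid] = i
    groups: dict[int, list[int]] = {}
    for i in range(len(tus)):
        groups.setdefault(find(i), []).append(i)
    clusters = [
        TuCluster(
            tu_indices=tuple(sorted(members)),
            gene_ids=frozenset(g for i in members for g in tus[i].genes),
        )
        for members in groups.values()
    ]
    clusters.sort(key=lambda c: c.tu_indices)
    return clusters
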