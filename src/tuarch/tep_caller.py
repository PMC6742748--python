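"""Transcript 3'-end position (TEP) calling from Term-Seq 3'-end profiles.

Term-Seq ligates an adaptor to transcript 3' termini, so the 3'-end of each
read marks an in vivo transcript boundary (termination or processing; the
protocol cannot distinguish the two). Candidate positions are restricted to
intergenic space (plus a short tail just downstream of each gene), clustered
when less than 10 bp apart, scored with a leave-one-out modified z-score
within each cluster, thresholded on read count and score, and finally
reconciled between two biological replicates: within the intersection of
overlapping replicate clusters the reproducible position with the highest
read count becomes the TEP.

For a cluster spanning positions C(x) with span length N(x) and per-position
read counts r (zero where no reads map), the score of position x is

    Z(x) = (r(x) - mu) / sigma
    mu      = (sum_{y in C} r(y) - r(x)) / (N - 1)
    mu2     = (sum_{y in C} r(y)^2 - r(x)^2) / (N - 1)
    sigma   = sqrt(mu2 - mu^2)

i.e. mean and SD of the other positions in the cluster. Degenerate cases:
a singleton cluster scores +inf; sigma = 0 scores +inf when r(x) > mu and 0
otherwise, so isolated clean spikes survive on the count filter alone.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass

from .genome_io import EndProfile, GeneModel


@dataclass
class TepCluster:
    """Positions closer than 10 bp chained together; zero-count positions
    inside the span belong to the cluster and dilute its moments."""

    strand: str
    first: int
    last: int
    r: dict  # position -> read count, only read-bearing positions stored

    @property
    def length(self) -> int:
        return self.last - self.first + 1

    def count(self, position: int) -> int:
        return self.r.get(position, 0)

    def positions(self) -> range:
        return range(self.first, self.last + 1)


@dataclass
class TepRecord:
    position: int
    strand: str
    count_r1: int
    count_r2: int
    zscore_r1: float
    zscore_r2: float
    category: str | None = None
    assigned_gene: str | None = None


def collect_tep_candidates(
    termseq: EndProfile,
    genes: list[GeneModel],
    tail_allow: int = 10,
) -> list[tuple[int, int]]:
    """Candidate positions: read-bearing, outside every same-strand gene body,
    or within ``tail_allow`` nt downstream of a same-strand gene 3' end (the
    tail wins even when it overlaps another annotation)."""
    same = [g for g in genes if g.strand == termseq.strand]
    bodies = sorted((g.start, g.end) for g in same)
    merged: list[list[int]] = []
    for s, e in bodies:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    starts = [iv[0] for iv in merged]
    tails = []
    for g in same:
        if g.strand == "+":
            tails.append((g.end + 1, g.end + tail_allow))
        else:
            tails.append((max(1, g.start - tail_allow), g.start - 1))
    tails.sort()
    tail_starts = [iv[0] for iv in tails]

    def in_intervals(pos, ivs, ivs_starts):
        i = bisect_right(ivs_starts, pos) - 1
        return i >= 0 and ivs[i][0] <= pos <= ivs[i][1]

    out = []
    for pos, cnt in termseq.items_sorted():
        if in_intervals(pos, tails, tail_starts) or not in_intervals(
            pos, merged, starts
        ):
            out.append((pos, cnt))
    return out


def cluster_teps(
    candidates: list[tuple[int, int]], strand: str, max_gap: int = 10
) -> list[TepCluster]:
    """Chain candidates with gaps below ``max_gap`` (gap <= 9 joins at the
    default). The cluster span runs from the first to the last read-bearing
    member; span positions without reads carry count 0."""
    clusters: list[TepCluster] = []
    cur: dict[int, int] = {}
    prev = None
    for pos, cnt in candidates:
        if prev is not None and pos - prev >= max_gap:
            clusters.append(TepCluster(strand, min(cur), max(cur), cur))
            cur = {}
        cur[pos] = cnt
        prev = pos
    if cur:
        clusters.append(TepCluster(strand, min(cur), max(cur), cur))
    return clusters


def modified_zscore(cluster: TepCluster, x: int) -> float:
    """Leave-one-out modified z-score of position ``x`` within its cluster."""
    if not cluster.first <= x <= cluster.last:
        raise ValueError(f"position {x} outside cluster span {cluster.first}..{cluster.last}")
    n = cluster.length
    rx = cluster.count(x)
    if n == 1:
        return math.inf
    total = sum(cluster.r.values())
    total_sq = sum(v * v for v in cluster.r.values())
    mu = (total - rx) / (n - 1)
    mu2 = (total_sq - rx * rx) / (n - 1)
    var = mu2 - mu * mu
    sigma = math.sqrt(var) if var > 0 else 0.0
    if sigma == 0.0:
        return math.inf if rx > mu else 0.0
    return (rx - mu) / sigma


def filter_teps(
    clusters: list[TepCluster], min_reads: int = 3, min_z: float = 3.0
) -> dict[int, tuple[int, float]]:
    """Surviving positions: read count >= min_reads and z-score >= min_z.

    Returns position -> (count, zscore) across all clusters of one replicate.
    """
    surviving: dict[int, tuple[int, float]] = {}
    for cluster in clusters:
        for pos, cnt in cluster.r.items():
            if cnt < min_reads:
                continue
            z = modified_zscore(cluster, pos)
            if z >= min_z:
                surviving[pos] = (cnt, z)
    return surviving


def intersection_window(c1: TepCluster, c2: TepCluster) -> tuple[int, int] | None:
    """Span intersection of two replicate clusters; None when disjoint."""
    lo, hi = max(c1.first, c2.first), min(c1.last, c2.last)
    return (lo, hi) if lo <= hi else None


def reconcile_replicates(
    clusters_r1: list[TepCluster],
    clusters_r2: list[TepCluster],
    surviving_r1: dict[int, tuple[int, float]],
    surviving_r2: dict[int, tuple[int, float]],
    rank: str = "sum",
) -> list[TepRecord]:
    """Select reproducible TEPs from two replicates.

    For every pair of overlapping clusters the selection window is the span
    intersection; among positions surviving the count/z filters in *both*
    replicates inside that window, the one with the highest read count is
    emitted (``rank``: "sum" of both replicates, "max" of either, or "r1").
    Ties go to the 5'-most position; duplicates from clusters overlapping
    more than one partner are emitted once.
    """
    if rank not in ("sum", "max", "r1"):
        raise ValueError(f"unknown rank {rank!r}")
    strand = clusters_r1[0].strand if clusters_r1 else (
        clusters_r2[0].strand if clusters_r2 else "+"
    )
    records: dict[int, TepRecord] = {}
    for c1 in sorted(clusters_r1, key=lambda c: c.first):
        for c2 in clusters_r2:
            window = intersection_window(c1, c2)
            if window is None:
                continue
            lo, hi = window
            common = [
                p
                for p in range(lo, hi + 1)
                if p in surviving_r1 and p in surviving_r2
            ]
            if not common:
                continue

            def score(p):
                a, b = surviving_r1[p][0], surviving_r2[p][0]
                if rank == "sum":
                    return a + b
                if rank == "max":
                    return max(a, b)
                return a
            best = max(score(p) for p in common)
            tied = [p for p in common if score(p) == best]
            pos = min(tied) if strand == "+" else max(tied)
            if pos not in records:
                records[pos] = TepRecord(
                    position=pos,
                    strand=strand,
                    count_r1=surviving_r1[pos][0],
                    count_r2=surviving_r2[pos][0],
                    zscore_r1=surviving_r1[pos][1],
                    zscore_r2=surviving_r2[pos][1],
                )
    return [records[p] for p in sorted(records)]


def call_teps_from_profiles(
    rep1: EndProfile,
    rep2: EndProfile,
    genes: list[GeneModel],
    tail_allow: int = 10,
    max_gap: int = 10,
    min_reads: int = 3,
    min_z: float = 3.0,
    rank: str = "sum",
) -> list[TepRecord]:
    """Full single-strand TEP calling over two Term-Seq replicates."""
    if rep1.strand != rep2.strand:
        raise ValueError("replicates must be on the same strand")
    c1 = cluster_teps(
        collect_tep_candidates(rep1, genes, tail_allow), rep1.strand, max_gap
    )
    c2 = cluster_teps(
        collect_tep_candidates(rep2, genes, tail_allow), rep2.strand, max_gap
    )
    s1 = filter_teps(c1, min_reads, min_z)
    s2 = filter_teps(c2, min_reads, min_z)
    return reconcile_replicates(c1, c2, s1, s2, rank=rank)
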