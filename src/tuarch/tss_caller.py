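"""Transcription start site calling from TAP(+)/TAP(-) dRNA-Seq 5'-end profiles.

Primary transcripts carry a 5'-triphosphate and are ligatable only after TAP
treatment, so genuine initiation sites are enriched in the TAP(+) library
while processed 5' monophosphate ends appear equally in both. The caller
clusters TAP(+) 5'-end positions (<100 bp apart), sub-clusters them under a
positional standard-deviation bound (<10 nt), keeps sub-clusters with more
than three reads, emits the maximum-count member of each sub-cluster, and
discards sites with strictly more TAP(-) than TAP(+) reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .genome_io import EndProfile


@dataclass
class TssRecord:
    position: int
    strand: str
    tap_plus_count: int
    tap_minus_count: int = 0
    category: str | None = None
    assigned_gene: str | None = None


@dataclass
class TssCandidateCluster:
    """A run of candidate positions with consecutive gaps < max_gap."""

    strand: str
    positions: list[int]
    counts: list[int]
    subclusters: list[list[int]] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return sum(self.counts)

    def count_at(self, position: int) -> int:
        return self.counts[self.positions.index(position)]


def collect_candidates(tap_plus: EndProfile) -> list[tuple[int, int]]:
    """All positions with at least one TAP(+) 5'-end read, sorted ascending."""
    return tap_plus.items_sorted()


def cluster_candidates(
    candidates: list[tuple[int, int]], strand: str, max_gap: int = 100
) -> list[TssCandidateCluster]:
    """Single-linkage chaining: a gap of ``max_gap`` or more starts a new cluster.

    "Less than 100 bp apart" joins, so with the default a gap of 99 still
    chains and a gap of 100 splits.
    """
    clusters: list[TssCandidateCluster] = []
    cur_pos: list[int] = []
    cur_cnt: list[int] = []
    prev = None
    for pos, cnt in candidates:
        if prev is not None and pos - prev >= max_gap:
            clusters.append(TssCandidateCluster(strand, cur_pos, cur_cnt))
            cur_pos, cur_cnt = [], []
        cur_pos.append(pos)
        cur_cnt.append(cnt)
        prev = pos
    if cur_pos:
        clusters.append(TssCandidateCluster(strand, cur_pos, cur_cnt))
    return clusters


def _population_sd(values: list[int]) -> float:
    n = len(values)
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / n)


def subcluster(cluster: TssCandidateCluster, sd_limit: float = 10.0) -> list[list[int]]:
    """Greedy left-to-right split keeping each subcluster's positional SD < limit.

    The SD is the population standard deviation of the member positions
    (each position once, counts not weighted). The result is stored on the
    cluster and returned.
    """
    subs: list[list[int]] = []
    current: list[int] = []
    for pos in cluster.positions:
        if not current or _population_sd(current + [pos]) < sd_limit:
            current.append(pos)
        else:
            subs.append(current)
            current = [pos]
    if current:
        subs.append(current)
    cluster.subclusters = subs
    return subs


def call_tss(
    clusters: list[TssCandidateCluster],
    min_total_reads: int = 4,
    count_filter_level: str = "subcluster",
) -> list[TssRecord]:
    """Emit one TSS per sufficiently supported sub-cluster.

    A sub-cluster needs a TAP(+) total of more than three reads
    (``min_total_reads`` = 4 keeps totals >= 4); the member with the maximum
    count is emitted, ties resolved toward the 5'-most position. With
    ``count_filter_level="cluster"`` the read-count filter is applied to the
    100-bp cluster total instead of the sub-cluster total.
    """
    if count_filter_level not in ("subcluster", "cluster"):
        raise ValueError(f"unknown count_filter_level {count_filter_level!r}")
    records: list[TssRecord] = []
    for cluster in clusters:
        if not cluster.subclusters:
            subcluster(cluster)
        for sub in cluster.subclusters:
            counts = {p: cluster.count_at(p) for p in sub}
            total = (
                cluster.total_count
                if count_filter_level == "cluster"
                else sum(counts.values())
            )
            if total < min_total_reads:
                continue
            best = max(counts.values())
            tied = [p for p, c in counts.items() if c == best]
            pos = min(tied) if cluster.strand == "+" else max(tied)
            records.append(TssRecord(pos, cluster.strand, tap_plus_count=best))
    records.sort(key=lambda r: r.position)
    return records


def tap_filter(records: list[TssRecord], tap_minus: EndProfile) -> list[TssRecord]:
    """Drop TSSs with strictly more TAP(-) than TAP(+) reads; ties are kept."""
    kept: list[TssRecord] = []
    for rec in records:
        minus = tap_minus.get(rec.position)
        rec.tap_minus_count = minus
        if minus <= rec.tap_plus_count:
            kept.append(rec)
    return kept


def call_tss_from_profiles(
    tap_plus: EndProfile,
    tap_minus: EndProfile,
    max_gap: int = 100,
    sd_limit: float = 10.0,
    min_total_reads: int = 4,
    count_filter_level: str = "subcluster",
) -> list[TssRecord]:
    """Full single-strand TSS calling: cluster, sub-cluster, call, TAP-filter."""
    if tap_plus.strand != tap_minus.strand:
        raise ValueError("TAP(+) and TAP(-) profiles must be on the same strand")
    clusters = cluster_candidates(
        collect_candidates(tap_plus), tap_plus.strand, max_gap=max_gap
    )
    for cluster in clusters:
        subcluster(cluster, sd_limit=sd_limit)
    called = call_tss(
        clusters,
        min_total_reads=min_total_reads,
        count_filter_level=count_filter_level,
    )
    return tap_filter(called, tap_minus)
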