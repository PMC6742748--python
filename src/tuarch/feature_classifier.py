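"""Positional classification of called TSSs and TEPs against the annotation.

TSS categories: primary (P) / secondary (S) for sites assigned to a gene
(within 500 nt upstream to 100 nt downstream of its start codon; the
assigned site with the most TAP(+) reads per gene is primary), internal (I)
inside a same-strand gene body, antisense (A) inside an opposite-strand gene
body, intergenic (N) otherwise.

TEP categories: cis-regulatory (C) between a gene's primary TSS and its
start codon (at least 60 nt from the TSS), primary (P) / secondary (S) for
sites within 500 nt downstream of a same-strand gene (most Term-Seq reads is
primary), antisense (A) inside an opposite-strand gene body, intergenic (N)
otherwise. C takes precedence so 5'-UTR-internal ends are not absorbed by an
upstream gene's call.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import GeneModel
from .tep_caller import TepRecord
from .tss_caller import TssRecord

TSS_CATEGORIES = ("P", "S", "I", "A", "N")
TEP_CATEGORIES = ("P", "S", "N", "A", "C")


@dataclass
class ClassParams:
    tss_upstream_window: int = 500
    tss_downstream_window: int = 100
    tep_gene_distance: int = 500
    cis_min_tss_distance: int = 60

    def __post_init__(self) -> None:
        for name in (
            "tss_upstream_window",
            "tss_downstream_window",
            "tep_gene_distance",
            "cis_min_tss_distance",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _in_tss_window(tss_pos: int, gene: GeneModel, params: ClassParams) -> bool:
    g5 = gene.five_prime
    if gene.strand == "+":
        return g5 - params.tss_upstream_window <= tss_pos <= g5 + params.tss_downstream_window
    return g5 - params.tss_downstream_window <= tss_pos <= g5 + params.tss_upstream_window


def classify_tss(
    records: list[TssRecord],
    genes: list[GeneModel],
    params: ClassParams | None = None,
) -> list[TssRecord]:
    """Assign P/S/I/A/N categories in place and return the records.

    Assignment to a gene (window rule, nearest start codon on ties between
    genes) takes precedence over the positional I/A/N fallbacks.
    """
    params = params or ClassParams()
    assigned: dict[str, list[TssRecord]] = {}
    for rec in records:
        rec.category = None
        rec.assigned_gene = None
        candidates = [
            g
            for g in genes
            if g.strand == rec.strand and _in_tss_window(rec.position, g, params)
        ]
        if candidates:
            gene = min(
                candidates, key=lambda g: (abs(rec.position - g.five_prime), g.gene_id)
            )
            rec.assigned_gene = gene.gene_id
            assigned.setdefault(gene.gene_id, []).append(rec)
    for gene_id, recs in assigned.items():
        strand = recs[0].strand
        best = max(r.tap_plus_count for r in recs)
        tied = [r for r in recs if r.tap_plus_count == best]
        primary = min(tied, key=lambda r: r.position if strand == "+" else -r.position)
        for r in recs:
            r.category = "P" if r is primary else "S"
    for rec in records:
        if rec.category is not None:
            continue
        if any(
            g.strand == rec.strand and g.contains(rec.position) for g in genes
        ):
            rec.category = "I"
        elif any(
            g.strand != rec.strand and g.contains(rec.position) for g in genes
        ):
            rec.category = "A"
        else:
            rec.category = "N"
    return records


def primary_tss_map(records: list[TssRecord]) -> dict[str, TssRecord]:
    """gene_id -> primary TSS, from classified records."""
    return {r.assigned_gene: r for r in records if r.category == "P"}


def _is_cis(
    rec: TepRecord, gene: GeneModel, tss: TssRecord, params: ClassParams
) -> bool:
    g5 = gene.five_prime
    if gene.strand == "+":
        between = tss.position < rec.position < g5
        dist = rec.position - tss.position
    else:
        between = g5 < rec.position < tss.position
        dist = tss.position - rec.position
    return between and dist >= params.cis_min_tss_distance


def classify_tep(
    records: list[TepRecord],
    genes: list[GeneModel],
    primary_tss: dict[str, TssRecord] | None,
    params: ClassParams | None = None,
) -> list[TepRecord]:
    """Assign C/P/S/A/N categories in place and return the records.

    Rules are evaluated in order C, then gene assignment (P/S), then A, then
    N. Without a primary-TSS map the C rule is skipped. C and P/S records
    carry the implicated gene in ``assigned_gene`` (downstream gene for C,
    upstream gene for P/S).
    """
    params = params or ClassParams()
    if primary_tss is None:
        import warnings

        warnings.warn("no primary TSS map given; cis-regulatory rule skipped")
        primary_tss = {}
    gene_by_id = {g.gene_id: g for g in genes}
    assigned: dict[str, list[TepRecord]] = {}
    for rec in records:
        rec.category = None
        rec.assigned_gene = None
        cis_genes = [
            gene_by_id[gid]
            for gid, tss in primary_tss.items()
            if gid in gene_by_id
            and gene_by_id[gid].strand == rec.strand
            and _is_cis(rec, gene_by_id[gid], tss, params)
        ]
        if cis_genes:
            gene = min(
                cis_genes, key=lambda g: (abs(g.five_prime - rec.position), g.gene_id)
            )
            rec.category = "C"
            rec.assigned_gene = gene.gene_id
            continue
        upstream = []
        for g in genes:
            if g.strand != rec.strand:
                continue
            dist = (
                rec.position - g.three_prime
                if g.strand == "+"
                else g.three_prime - rec.position
            )
            if 0 <= dist < params.tep_gene_distance:
                upstream.append((dist, g))
        if upstream:
            dist, gene = min(upstream, key=lambda t: (t[0], t[1].gene_id))
            rec.assigned_gene = gene.gene_id
            assigned.setdefault(gene.gene_id, []).append(rec)
    for gene_id, recs in assigned.items():
        strand = recs[0].strand
        best = max(r.count_r1 + r.count_r2 for r in recs)
        tied = [r for r in recs if r.count_r1 + r.count_r2 == best]
        primary = min(tied, key=lambda r: r.position if strand == "+" else -r.position)
        for r in recs:
            r.category = "P" if r is primary else "S"
    for rec in records:
        if rec.category is not None:
            continue
        if any(g.strand != rec.strand and g.contains(rec.position) for g in genes):
            rec.category = "A"
        else:
            rec.category = "N"
    return records
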