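"""End-to-end orchestration: profiles in, classified sites and TUs out."""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from . import tss_caller, tep_caller
from .feature_classifier import ClassParams, classify_tep, classify_tss, primary_tss_map
from .genome_io import EndProfile, GeneModel, write_sites
from .reporting import category_counts
from .tep_caller import TepRecord
from .tss_caller import TssRecord
from .tu_builder import (
    TranscriptionUnit,
    TuCluster,
    assemble_tus,
    categorize_tu,
    cluster_tus,
    coverage_consistency,
)


@dataclass
class PipelineParams:
    tss_max_gap: int = 100
    tss_sd_limit: float = 10.0
    tss_min_reads: int = 4
    tep_tail_allow: int = 10
    tep_max_gap: int = 10
    tep_min_reads: int = 3
    tep_min_z: float = 3.0
    tep_rank: str = "sum"
    class_params: ClassParams = field(default_factory=ClassParams)
    tu_max_gap: int = 500
    tu_scan: int = 1000
    coverage_min_frac: float = 0.9
    coverage_min_depth: float = 1
    #: RNA-Seq consistency handling for called TSSs when coverage is given:
    #: "off" skips the check, "flag" records it, "drop" removes failing calls
    #: (the automated analogue of inspecting calls against the transcriptome)
    tss_coverage_filter: str = "off"


@dataclass
class PipelineResult:
    tss: list[TssRecord]
    tep: list[TepRecord]
    tus: list[TranscriptionUnit]
    clusters: list[TuCluster]

    def summary(self) -> dict:
        return {
            "n_tss": len(self.tss),
            "n_tep": len(self.tep),
            "n_tu": len(self.tus),
            "n_tu_cluster": len(self.clusters),
            "tss_categories": category_counts(self.tss),
            "tep_categories": category_counts(self.tep),
            "tu_categories": category_counts(self.tus),
        }


def run_pipeline(
    genes: list[GeneModel],
    end_profiles: dict[tuple[str, str], EndProfile],
    coverage: dict[tuple[str, str], EndProfile] | None = None,
    params: PipelineParams | None = None,
) -> PipelineResult:
    """Call, classify and assemble on both strands.

    ``end_profiles`` maps (label, strand) to a profile for TAP_PLUS,
    TAP_MINUS, TERMSEQ_R1 and TERMSEQ_R2; ``coverage`` optionally supplies
    (RNASEQ, strand) profiles for the consistency score.
    """
    params = params or PipelineParams()
    tss: list[TssRecord] = []
    tep: list[TepRecord] = []
    for strand in "+-":
        tss.extend(
            tss_caller.call_tss_from_profiles(
                end_profiles[("TAP_PLUS", strand)],
                end_profiles[("TAP_MINUS", strand)],
                max_gap=params.tss_max_gap,
                sd_limit=params.tss_sd_limit,
                min_total_reads=params.tss_min_reads,
            )
        )
        tep.extend(
            tep_caller.call_teps_from_profiles(
                end_profiles[("TERMSEQ_R1", strand)],
                end_profiles[("TERMSEQ_R2", strand)],
                genes,
                tail_allow=params.tep_tail_allow,
                max_gap=params.tep_max_gap,
                min_reads=params.tep_min_reads,
                min_z=params.tep_min_z,
                rank=params.tep_rank,
            )
        )
    if coverage is not None and params.tss_coverage_filter != "off":
        from .tu_builder import tss_coverage_step

        checked = []
        for rec in tss:
            _, ok = tss_coverage_step(rec, coverage[("RNASEQ", rec.strand)])
            if ok or params.tss_coverage_filter == "flag":
                checked.append(rec)
        tss = checked
    classify_tss(tss, genes, params.class_params)
    classify_tep(tep, genes, primary_tss_map(tss), params.class_params)
    tus = assemble_tus(
        tss, tep, genes, max_gap=params.tu_max_gap, scan=params.tu_scan
    )
    categorize_tu(tus, genes, srna_cutoff=params.tu_max_gap)
    if coverage is not None:
        for tu in tus:
            coverage_consistency(
                tu,
                coverage[("RNASEQ", tu.strand)],
                min_frac=params.coverage_min_frac,
                min_depth=params.coverage_min_depth,
            )
    clusters = cluster_tus(tus)
    return PipelineResult(tss=tss, tep=tep, tus=tus, clusters=clusters)


def write_result(result: PipelineResult, outdir: str, chrom: str = "chr") -> None:
    """Write sites (BED6 + TSV), TUs (GFF3) and TU clusters (TSV)."""
    os.makedirs(outdir, exist_ok=True)
    write_sites(
        result.tss,
        os.path.join(outdir, "tss.bed"),
        os.path.join(outdir, "tss.tsv"),
        chrom=chrom,
    )
    write_sites(
        result.tep,
        os.path.join(outdir, "tep.bed"),
        os.path.join(outdir, "tep.tsv"),
        chrom=chrom,
    )
    with open(os.path.join(outdir, "tu.gff3"), "w") as out:
        out.write("##gff-version 3\n")
        for i, tu in enumerate(result.tus, start=1):
            lo, hi = tu.span
            attrs = (
                f"ID=TU{i:04d};category={tu.category};tss={tu.tss.position};"
                f"tep={tu.tep.position};genes={','.join(tu.genes)}"
            )
            if tu.coverage_score is not None:
                attrs += f";coverage_score={tu.coverage_score:.4f}"
            out.write(
                f"{chrom}\ttuarch\ttranscription_unit\t{lo}\t{hi}\t.\t{tu.strand}\t.\t{attrs}\n"
            )
    with open(os.path.join(outdir, "tu_clusters.tsv"), "w") as out:
        out.write("cluster_id\tn_tus\ttu_ids\tgene_ids\n")
        for i, cluster in enumerate(result.clusters, start=1):
            tu_ids = ",".join(f"TU{j + 1:04d}" for j in cluster.tu_indices)
            gene_ids = ",".join(sorted(cluster.gene_ids))
            out.write(f"CL{i:04d}\t{cluster.n_tus}\t{tu_ids}\t{gene_ids}\n")
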