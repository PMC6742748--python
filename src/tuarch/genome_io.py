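"""Coordinate model and file I/O shared by every pipeline stage.

All internal coordinates are 1-based inclusive, matching GFF3. bedGraph and
BED use 0-based half-open intervals; conversion happens only at the file
boundary. Strand is carried per profile (bedGraph has no strand column), so
every stranded library is represented by two :class:`EndProfile` objects.

A single replicon is modelled per run; multi-contig inputs must be split
upstream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

STRANDS = ("+", "-")

#: canonical library labels used across the pipeline
LIBRARY_LABELS = (
    "TAP_PLUS",
    "TAP_MINUS",
    "TERMSEQ_R1",
    "TERMSEQ_R2",
    "RNASEQ",
    "RIBOSEQ",
)


class AnnotationError(ValueError):
    """Raised for malformed or empty annotation files."""


class ProfileError(ValueError):
    """Raised for malformed bedGraph input."""


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene, 1-based inclusive coordinates.

    The 5'-most coding position (the start codon) is ``start`` on the plus
    strand and ``end`` on the minus strand.
    """

    gene_id: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"require 1 <= start <= end, got {self.start}..{self.end}"
            )

    @property
    def five_prime(self) -> int:
        """5'-most coding position (start-codon position)."""
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        """3'-most coding position (stop-codon end)."""
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class Genome:
    """A single replicon: a nucleotide sequence plus its name."""

    sequence: str
    name: str = "chr"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")
        self.sequence = self.sequence.upper()

    @property
    def length(self) -> int:
        return len(self.sequence)

    def subseq(self, start: int, end: int, strand: str = "+") -> str:
        """1-based inclusive slice, reverse-complemented on the minus strand."""
        if not 1 <= start <= end <= self.length:
            raise ValueError(f"window {start}..{end} outside genome 1..{self.length}")
        s = self.sequence[start - 1 : end]
        return str(Seq(s).reverse_complement()) if strand == "-" else s


@dataclass
class EndProfile:
    """Strand-aware sparse map position -> end count for one library.

    Absent positions carry count 0. End-count libraries hold integers;
    coverage libraries (RNASEQ/RIBOSEQ) may carry fractional depth.
    """

    label: str
    strand: str
    counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def get(self, position: int):
        return self.counts.get(position, 0)

    def total(self):
        return sum(self.counts.values())

    def items_sorted(self):
        """(position, count) pairs with count > 0, ascending position."""
        return sorted((p, c) for p, c in self.counts.items() if c > 0)

    def __len__(self) -> int:
        return sum(1 for c in self.counts.values() if c > 0)


# ---------------------------------------------------------------------------
# readers


def read_genome(path: str) -> Genome:
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if len(records) > 1:
        raise ValueError(
            f"{path} holds {len(records)} sequences; one replicon per run"
        )
    rec = records[0]
    return Genome(sequence=str(rec.seq), name=rec.id)


def _gene_id_of(feature) -> str:
    for key in ("ID", "locus_tag", "gene", "Name"):
        if key in feature.attributes:
            return feature.attributes[key][0]
    return f"{feature.featuretype}:{feature.start}-{feature.end}"


def _validate_gff_lines(path: str) -> None:
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer coordinates {cols[3]!r}/{cols[4]!r}"
                ) from exc
            if start > end:
                raise AnnotationError(f"{path}:{lineno}: start {start} > end {end}")
            if cols[6] not in ("+", "-", ".", "?"):
                raise AnnotationError(f"{path}:{lineno}: bad strand {cols[6]!r}")


def read_annotation(
    path: str, feature_types: Sequence[str] = ("gene", "CDS")
) -> list[GeneModel]:
    """Read gene models from GFF3, ordered by (start, gene_id).

    The first feature type in ``feature_types`` that is present in the file
    is used, so CDS features back up annotations without explicit genes.
    """
    _validate_gff_lines(path)
    try:
        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:
        raise AnnotationError(f"cannot parse {path}: {exc}") from exc
    genes: list[GeneModel] = []
    for ftype in feature_types:
        feats = list(db.features_of_type(ftype))
        if not feats:
            continue
        seen: set[str] = set()
        for f in feats:
            if f.strand not in STRANDS:
                continue
            gid = _gene_id_of(f)
            if gid in seen:
                raise AnnotationError(f"duplicate gene_id {gid!r} in {path}")
            seen.add(gid)
            genes.append(GeneModel(gid, f.strand, f.start, f.end))
        break
    if not genes:
        raise AnnotationError(
            f"no features of type {'/'.join(feature_types)} in {path}"
        )
    genes.sort(key=lambda g: (g.start, g.gene_id))
    return genes


def read_end_profile(
    path: str,
    strand: str,
    label: str,
    genome_length: int | None = None,
) -> EndProfile:
    """Read a bedGraph file into an :class:`EndProfile`.

    Each 0-based half-open interval [a, b) with value v becomes counts v at
    1-based positions a+1..b. Overlapping intervals are rejected.
    """
    intervals: list[tuple[int, int, float]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) != 4:
                raise ProfileError(f"{path}:{lineno}: expected 4 columns")
            try:
                a, b = int(cols[1]), int(cols[2])
                value = float(cols[3])
            except ValueError as exc:
                raise ProfileError(f"{path}:{lineno}: bad numeric field") from exc
            if value != int(value):
                raise ProfileError(
                    f"{path}:{lineno}: non-integer count {cols[3]!r}"
                )
            value = int(value)
            if value < 0:
                raise ProfileError(f"{path}:{lineno}: negative count {value}")
            if a < 0 or b <= a:
                raise ProfileError(f"{path}:{lineno}: bad interval [{a},{b})")
            if genome_length is not None and b > genome_length:
                raise ProfileError(
                    f"{path}:{lineno}: interval end {b} beyond genome length {genome_length}"
                )
            intervals.append((a, b, value))
    intervals.sort()
    counts: dict[int, int] = {}
    prev_end = -1
    for a, b, value in intervals:
        if a < prev_end:
            raise ProfileError(f"{path}: overlapping intervals at position {a}")
        prev_end = b
        if value == 0:
            continue
        for pos in range(a + 1, b + 1):
            counts[pos] = value
    return EndProfile(label=label, strand=strand, counts=counts)


# ---------------------------------------------------------------------------
# writers


def _format_count(c) -> str:
    if float(c) == int(c):
        return str(int(c))
    return repr(float(c))


def write_end_profile(profile: EndProfile, path: str, chrom: str = "chr") -> None:
    """Write an EndProfile as bedGraph, merging runs of equal counts."""
    items = profile.items_sorted()
    with open(path, "w") as out:
        run_start = None
        run_end = None
        run_val = None
        for pos, count in items:
            if run_val is not None and pos == run_end + 1 and count == run_val:
                run_end = pos
                continue
            if run_val is not None:
                out.write(f"{chrom}\t{run_start - 1}\t{run_end}\t{_format_count(run_val)}\n")
            run_start, run_end, run_val = pos, pos, count
        if run_val is not None:
            out.write(f"{chrom}\t{run_start - 1}\t{run_end}\t{_format_count(run_val)}\n")


def write_sites(records: Sequence, bed_path: str, tsv_path: str, chrom: str = "chr") -> None:
    """Write called sites as BED6 plus a full-field TSV.

    BED intervals are single-nucleotide, 0-based half-open; the BED score is
    the site read count. Every record must already carry a category.
    """
    for rec in records:
        if getattr(rec, "category", None) is None:
            raise ValueError(
                f"unclassified record at position {rec.position}; classify before writing"
            )
    rows = []
    bed_lines = []
    for rec in records:
        d = {k: v for k, v in vars(rec).items()}
        rows.append(d)
        if hasattr(rec, "tap_plus_count"):
            score = rec.tap_plus_count
            name = f"TSS_{rec.category}_{rec.position}"
        else:
            score = rec.count_r1 + rec.count_r2
            name = f"TEP_{rec.category}_{rec.position}"
        bed_lines.append(
            f"{chrom}\t{rec.position - 1}\t{rec.position}\t{name}\t{score}\t{rec.strand}"
        )
    with open(bed_path, "w") as out:
        out.write("\n".join(bed_lines) + ("\n" if bed_lines else ""))
    if rows:
        frame = pd.DataFrame(rows)
    else:
        frame = pd.DataFrame(
            columns=["position", "strand", "category", "assigned_gene"]
        )
    for col in frame.columns:
        if col.startswith("zscore"):
            frame[col] = frame[col].map(lambda z: f"{z:.4f}")
    frame.to_csv(tsv_path, sep="\t", index=False)


def write_genome(genome: Genome, path: str) -> None:
    with open(path, "w") as out:
        out.write(f">{genome.name}\n")
        for i in range(0, genome.length, 70):
            out.write(genome.sequence[i : i + 70] + "\n")


def write_annotation(genes: Iterable[GeneModel], path: str, chrom: str = "chr") -> None:
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.start, g.gene_id)):
            out.write(
                f"{chrom}\ttuarch\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
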