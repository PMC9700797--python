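"""Gene models, gene sets, and strand-aware TSS windows.

Every downstream score in this package is anchored to a transcription
start site (TSS). This module loads gene annotations (BED6 or GTF),
derives one TSS per gene from the strand, and builds the windows around
it (e.g. -2 kb/+3 kb for histone scores, -1 kb/+1 kb for methylation).

Coordinates are 0-based half-open (BED convention) throughout; GTF input
(1-based closed) is converted on read.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

GERM_LAYERS = ("mesoderm", "endoderm", "ectoderm", "other")


class AnnotationError(ValueError):
    """Raised for malformed annotation or gene-set input."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise AnnotationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval [{self.start}, {self.end}): "
                "need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", min_bp: int = 1) -> bool:
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_bp


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene: identifier, location, strand and derived TSS.

    The TSS is ``body_start`` on the + strand and ``body_end - 1`` on the
    - strand (the last covered base of the half-open body interval).
    One TSS per gene; transcript-level models are out of scope.
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    tss: int
    body_start: int
    body_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.chrom:
            raise AnnotationError("chrom must be non-empty")
        if not self.body_start < self.body_end:
            raise AnnotationError("body_start must be < body_end")
        expected = self.body_start if self.strand == "+" else self.body_end - 1
        if self.tss != expected:
            raise AnnotationError(
                f"tss={self.tss} inconsistent with strand {self.strand} "
                f"and body [{self.body_start}, {self.body_end})"
            )

    @classmethod
    def from_body(
        cls, gene_id: str, symbol: str, chrom: str, strand: str, start: int, end: int
    ) -> "GeneAnnotation":
        tss = start if strand == "+" else end - 1
        return cls(gene_id, symbol, chrom, strand, tss, start, end)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols tagged by germ layer of origin."""

    name: str
    germ_layer: str
    members: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.germ_layer not in GERM_LAYERS:
            raise AnnotationError(
                f"unknown germ layer {self.germ_layer!r}; allowed: {GERM_LAYERS}"
            )
        if not self.members:
            raise AnnotationError(f"gene set {self.name!r} has no members")


def normalize_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: stripped and uppercased.

    Matching between annotation and gene sets is case-insensitive exact
    match; no alias resolution.
    """
    return symbol.strip().upper()


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def load_gene_annotation(path, format: str = "bed6") -> list[GeneAnnotation]:
    """Load gene annotations from a BED6 or GTF file.

    One record per gene; duplicate gene_ids are rejected. Records lacking
    a strand are skipped with a warning.
    """
    path = Path(path)
    if format not in ("bed6", "gtf"):
        raise AnnotationError(f"unknown annotation format {format!r}")
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            try:
                rec = (
                    _parse_bed6_line(line) if format == "bed6" else _parse_gtf_line(line)
                )
            except AnnotationError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from None
            if rec is None:
                continue
            if rec.strand not in ("+", "-"):
                logger.warning("%s:%d: missing strand, record skipped", path, lineno)
                continue
            if rec.gene_id in seen:
                raise AnnotationError(
                    f"{path}:{lineno}: duplicate gene_id {rec.gene_id!r}"
                )
            seen.add(rec.gene_id)
            genes.append(rec)
    return genes


def _parse_bed6_line(line: str):
    fields = line.split("\t") if "\t" in line else line.split()
    if len(fields) < 6:
        raise AnnotationError(f"BED6 needs >= 6 columns, got {len(fields)}")
    chrom, start, end, name, _score, strand = fields[:6]
    try:
        start_i, end_i = int(start), int(end)
    except ValueError:
        raise AnnotationError(f"non-integer coordinates {start!r}/{end!r}")
    if strand not in ("+", "-"):
        # caller decides: skipped with warning
        return _Unstranded(name)
    return GeneAnnotation.from_body(name, name, chrom, strand, start_i, end_i)


def _parse_gtf_line(line: str):
    fields = line.split("\t")
    if len(fields) < 9:
        raise AnnotationError(f"GTF needs 9 columns, got {len(fields)}")
    chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
    if feature != "gene":
        return None
    try:
        # GTF is 1-based closed; convert to 0-based half-open
        start_i, end_i = int(start) - 1, int(end)
    except ValueError:
        raise AnnotationError(f"non-integer coordinates {start!r}/{end!r}")
    attr = dict(_GTF_ATTR.findall(attrs))
    gene_id = attr.get("gene_id")
    if not gene_id:
        raise AnnotationError("GTF record lacks gene_id attribute")
    symbol = attr.get("gene_name", gene_id)
    if strand not in ("+", "-"):
        return _Unstranded(gene_id)
    return GeneAnnotation.from_body(gene_id, symbol, chrom, strand, start_i, end_i)


class _Unstranded:
    """Sentinel for a record without strand information."""

    strand = "."

    def __init__(self, gene_id: str):
        self.gene_id = gene_id


def write_gene_annotation(genes: Iterable[GeneAnnotation], path) -> None:
    """Write annotations as BED6 (symbol goes in the name column when it
    equals gene_id; otherwise gene_id is written and symbols round-trip
    only via gene_id)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.body_start}\t{g.body_end}\t{g.gene_id}\t0\t{g.strand}\n"
            )


def tss_window(
    gene: GeneAnnotation,
    upstream_bp: int,
    downstream_bp: int,
    strand_aware: bool = True,
) -> GenomicInterval:
    """Window around the TSS, clipped at the chromosome start.

    Strand-aware by default: upstream means 5' of the gene, so on the -
    strand the window extends to larger coordinates upstream. With
    ``strand_aware=False`` upstream is genomic-left regardless of strand.
    """
    if upstream_bp < 0 or downstream_bp < 0:
        raise AnnotationError("window extents must be >= 0")
    if upstream_bp == 0 and downstream_bp == 0:
        raise AnnotationError("window cannot be empty")
    if strand_aware and gene.strand == "-":
        start = gene.tss - downstream_bp
        end = gene.tss + upstream_bp
    else:
        start = gene.tss - upstream_bp
        end = gene.tss + downstream_bp
    start = max(start, 0)
    if end <= 0:
        raise AnnotationError(
            f"TSS window for {gene.gene_id} lies entirely off-chromosome"
        )
    return GenomicInterval(gene.chrom, start, end)


def load_gene_sets(path) -> list[GeneSet]:
    """Load gene sets from a tab-separated membership table.

    One row per membership: ``set_name<TAB>germ_layer<TAB>symbol``.
    Symbols are normalized (uppercased); blank symbols are skipped with a
    warning; duplicate symbols within a set are deduplicated.
    """
    path = Path(path)
    rows: dict[str, tuple[str, set]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise AnnotationError(
                    f"{path}:{lineno}: need 3 tab-separated columns "
                    "(set_name, germ_layer, symbol)"
                )
            name, layer, symbol = fields[0].strip(), fields[1].strip(), fields[2]
            if layer not in GERM_LAYERS:
                raise AnnotationError(
                    f"{path}:{lineno}: unknown germ layer {layer!r}; "
                    f"allowed: {', '.join(GERM_LAYERS)}"
                )
            if not symbol.strip():
                logger.warning("%s:%d: blank symbol skipped", path, lineno)
                continue
            if name in rows and rows[name][0] != layer:
                raise AnnotationError(
                    f"{path}:{lineno}: gene set {name!r} tagged with two "
                    f"different germ layers"
                )
            rows.setdefault(name, (layer, set()))[1].add(normalize_symbol(symbol))
    return [
        GeneSet(name, layer, frozenset(members))
        for name, (layer, members) in rows.items()
    ]


def write_gene_sets(gene_sets: Sequence[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            for symbol in sorted(gs.members):
                fh.write(f"{gs.name}\t{gs.germ_layer}\t{symbol}\n")
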