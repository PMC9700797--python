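"""ChIP-seq peak quantification: background-adjusted RPKM and TSS scores.

Pipeline stage mirroring a multicov-style workflow: raw read counts are
obtained within each called peak for both the ChIP sample and its input
(background) sample, converted to RPKM against each library's own size,
and the input RPKM is subtracted from the ChIP RPKM. Peaks whose
background-adjusted RPKM is <= 0 are excluded. Retained peak values are
then averaged over a -2 kb/+3 kb window around each gene's TSS to give
one score per (gene, sample, mark). Per-locus coverage tracks are
reported in RPM (reads per million uniquely mapped reads).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneAnnotation, GenomicInterval, tss_window

logger = logging.getLogger(__name__)

MARKS = ("H3K4me3", "H3K27me3", "H3K36me3")
ALLOWED_MARKS = MARKS + ("input",)

#: default TSS aggregation window: -2 kb upstream, +3 kb downstream
TSS_WINDOW = (2000, 3000)


@dataclass(frozen=True)
class SampleLibrary:
    """One sequencing library: aligned read intervals plus metadata."""

    sample_id: str
    group: str
    mark: str
    reads: tuple
    library_size: int

    def __post_init__(self) -> None:
        if self.mark not in ALLOWED_MARKS:
            raise ValueError(
                f"mark {self.mark!r} not in allowed vocabulary {ALLOWED_MARKS}"
            )
        if not (self.library_size >= len(self.reads) > 0):
            raise ValueError(
                "library_size must be >= number of stored reads, which must be > 0"
            )


@dataclass(frozen=True)
class QuantifiedPeak:
    """A peak with its ChIP/input counts and RPKM arithmetic."""

    interval: GenomicInterval
    mark: str
    sample_id: str
    chip_count: int
    input_count: int
    chip_rpkm: float
    input_rpkm: float
    adjusted_rpkm: float


@dataclass(frozen=True)
class GeneScore:
    """One (gene, sample, assay) scalar; missing when nothing supports it."""

    gene_id: str
    sample_id: str
    assay: str
    score: float  # NaN when n_support == 0
    n_support: int


# ---------------------------------------------------------------------------
# interval counting


def _as_arrays(intervals):
    """Group intervals by chromosome into (starts, ends, original index).

    Accepts a sequence of GenomicInterval or a DataFrame with
    chrom/start/end columns (bulk read tables).
    """
    if isinstance(intervals, pd.DataFrame):
        out = {}
        idx = np.arange(len(intervals))
        chroms = intervals["chrom"].to_numpy()
        starts = intervals["start"].to_numpy(dtype=np.int64)
        ends = intervals["end"].to_numpy(dtype=np.int64)
        for chrom in pd.unique(chroms):
            m = chroms == chrom
            out[str(chrom)] = (starts[m], ends[m], idx[m])
        return out
    by_chrom: dict[str, list] = {}
    for i, iv in enumerate(intervals):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, i))
    out = {}
    for chrom, triples in by_chrom.items():
        arr = np.asarray(triples, dtype=np.int64)
        out[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])
    return out


def _is_empty(intervals) -> bool:
    return len(intervals) == 0


def count_reads_in_intervals(
    reads: Sequence[GenomicInterval],
    targets: Sequence[GenomicInterval],
    min_overlap_bp: int = 1,
) -> np.ndarray:
    """Count reads overlapping each target by >= ``min_overlap_bp``.

    A read overlapping two targets counts in both (multicov semantics).
    Returns an int array aligned with ``targets``.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    counts = np.zeros(len(targets), dtype=np.int64)
    if _is_empty(reads) or _is_empty(targets):
        return counts
    reads_by_chrom = _as_arrays(reads)
    targets_by_chrom = _as_arrays(targets)
    for chrom, (tstarts, tends, tidx) in targets_by_chrom.items():
        if chrom not in reads_by_chrom:
            continue
        rstarts, rends, _ = reads_by_chrom[chrom]
        if min_overlap_bp == 1:
            # overlap >= 1  <=>  read.start < target.end and read.end > target.start
            starts_sorted = np.sort(rstarts)
            ends_sorted = np.sort(rends)
            n = len(rstarts)
            n_start_ok = np.searchsorted(starts_sorted, tends, side="left")
            n_end_bad = np.searchsorted(ends_sorted, tstarts, side="right")
            counts[tidx] = n_start_ok - n_end_bad
        else:
            for s, e, i in zip(tstarts, tends, tidx):
                ov = np.minimum(rends, e) - np.maximum(rstarts, s)
                counts[i] = int(np.count_nonzero(ov >= min_overlap_bp))
    return counts


# ---------------------------------------------------------------------------
# RPKM / background adjustment


def rpkm(count: int, length_bp: int, library_size: int) -> float:
    """Reads per kilobase of interval per million mapped reads."""
    if length_bp <= 0:
        raise ValueError("length_bp must be > 0")
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return count / ((length_bp / 1000.0) * (library_size / 1e6))


def quantify_peaks(
    peaks: Sequence[GenomicInterval],
    chip_reads: Sequence[GenomicInterval],
    input_reads: Sequence[GenomicInterval],
    chip_library_size: int,
    input_library_size: int,
    mark: str,
    sample_id: str,
) -> list[QuantifiedPeak]:
    """Count ChIP and input reads in each peak and compute the RPKM pair.

    Input counts are computed within the same peak intervals using the
    input sample's reads and its own library size.
    """
    chip_counts = count_reads_in_intervals(chip_reads, peaks)
    input_counts = count_reads_in_intervals(input_reads, peaks)
    out = []
    for iv, cc, ic in zip(peaks, chip_counts, input_counts):
        c_rpkm = rpkm(int(cc), len(iv), chip_library_size)
        i_rpkm = rpkm(int(ic), len(iv), input_library_size)
        out.append(
            QuantifiedPeak(
                interval=iv,
                mark=mark,
                sample_id=sample_id,
                chip_count=int(cc),
                input_count=int(ic),
                chip_rpkm=c_rpkm,
                input_rpkm=i_rpkm,
                adjusted_rpkm=c_rpkm - i_rpkm,
            )
        )
    return out


def background_adjust(
    peaks: Iterable[QuantifiedPeak],
) -> tuple[list[QuantifiedPeak], int]:
    """Recompute adjusted RPKM and drop peaks with adjusted RPKM <= 0.

    Returns (retained peaks in input order, number dropped).
    """
    retained: list[QuantifiedPeak] = []
    dropped = 0
    for p in peaks:
        adj = p.chip_rpkm - p.input_rpkm
        if adj > 0:
            retained.append(replace(p, adjusted_rpkm=adj))
        else:
            dropped += 1
    if dropped:
        logger.info("background_adjust: excluded %d peaks with adjusted RPKM <= 0", dropped)
    return retained, dropped


# ---------------------------------------------------------------------------
# per-gene TSS scores


def gene_tss_score(
    retained_peaks: Sequence[QuantifiedPeak],
    gene: GeneAnnotation,
    window: tuple[int, int] = TSS_WINDOW,
    strand_aware: bool = True,
) -> GeneScore:
    """Unweighted mean adjusted RPKM of retained peaks overlapping the
    TSS window by >= 1 bp; missing (NaN) when no peak overlaps.

    A peak overlapping the window by >= 1 bp contributes fully; no
    proportional clipping.
    """
    win = tss_window(gene, window[0], window[1], strand_aware=strand_aware)
    values = [
        p.adjusted_rpkm for p in retained_peaks if p.interval.overlaps(win)
    ]
    assay = retained_peaks[0].mark if retained_peaks else "chip"
    sample = retained_peaks[0].sample_id if retained_peaks else ""
    if not values:
        return GeneScore(gene.gene_id, sample, assay, float("nan"), 0)
    return GeneScore(
        gene.gene_id, sample, assay, float(np.mean(values)), len(values)
    )


def gene_score_matrix(
    peaks_by_sample: dict[str, Sequence[QuantifiedPeak]],
    genes: Sequence[GeneAnnotation],
    window: tuple[int, int] = TSS_WINDOW,
    strand_aware: bool = True,
    zero_fill: bool = False,
) -> pd.DataFrame:
    """Genes x samples matrix of TSS scores for one mark.

    Genes with no overlapping retained peak get NaN (excluded from
    downstream distributions) unless ``zero_fill`` is set.
    """
    windows = [tss_window(g, window[0], window[1], strand_aware=strand_aware) for g in genes]
    data = {}
    for sample_id, peaks in peaks_by_sample.items():
        chroms = np.array([p.interval.chrom for p in peaks])
        starts = np.array([p.interval.start for p in peaks], dtype=np.int64)
        ends = np.array([p.interval.end for p in peaks], dtype=np.int64)
        adj = np.array([p.adjusted_rpkm for p in peaks], dtype=float)
        col = np.full(len(genes), np.nan)
        for i, win in enumerate(windows):
            if len(peaks) == 0:
                continue
            m = (chroms == win.chrom) & (starts < win.end) & (ends > win.start)
            if m.any():
                col[i] = adj[m].mean()
        data[sample_id] = col
    df = pd.DataFrame(data, index=[g.gene_id for g in genes])
    df.index.name = "gene_id"
    if zero_fill:
        df = df.fillna(0.0)
    return df


# ---------------------------------------------------------------------------
# coverage tracks


def coverage_track(
    reads: Sequence[GenomicInterval],
    region: GenomicInterval,
    bin_bp: int,
    library_size: int,
) -> pd.DataFrame:
    """Per-bin RPM coverage over ``region``.

    Bins tile the region left to right; the last bin may be short. A read
    overlapping a bin by >= 1 bp counts in that bin. Values are counts
    normalized to millions of uniquely mapped reads (RPM).
    """
    if bin_bp < 1:
        raise ValueError("bin_bp must be >= 1")
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    edges = list(range(region.start, region.end, bin_bp)) + [region.end]
    bins = [
        GenomicInterval(region.chrom, s, e)
        for s, e in zip(edges[:-1], edges[1:])
    ]
    counts = count_reads_in_intervals(reads, bins)
    rpm = counts / (library_size / 1e6)
    return pd.DataFrame(
        {
            "chrom": region.chrom,
            "start": [b.start for b in bins],
            "end": [b.end for b in bins],
            "rpm": rpm,
        }
    )


# ---------------------------------------------------------------------------
# readers / writers

_PEAK_MIN_COLS = 3


def read_peaks(path) -> list[GenomicInterval]:
    """Read peak intervals from BED3+/narrowPeak/broadPeak files.

    Only the first three columns are used; extra MACS columns are ignored.
    """
    path = Path(path)
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < _PEAK_MIN_COLS:
                raise ValueError(f"{path}:{lineno}: need >= 3 columns")
            try:
                peaks.append(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return peaks


def read_reads_bed(path) -> pd.DataFrame:
    """Read aligned-read intervals (BED3, one row per uniquely mapped
    read) into a chrom/start/end table. Read tables are bulk data, so
    they stay columnar instead of becoming per-read objects."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        comment="#",
    )
    if len(df) and (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: read intervals must satisfy start < end")
    return df


def write_intervals_bed(intervals: Sequence[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


MANIFEST_COLUMNS = ["sample_id", "group", "mark", "library_size", "reads_path", "peaks_path"]


def read_library_manifest(path) -> pd.DataFrame:
    """Per-sample manifest TSV: sample_id, group, mark, library_size, paths."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MANIFEST_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {missing}")
    bad = set(df["mark"]) - set(ALLOWED_MARKS)
    if bad:
        raise ValueError(f"manifest {path} has unknown marks: {sorted(bad)}")
    return df


def write_retained_peaks(peaks: Sequence[QuantifiedPeak], path) -> None:
    rows = [
        {
            "chrom": p.interval.chrom,
            "start": p.interval.start,
            "end": p.interval.end,
            "mark": p.mark,
            "sample_id": p.sample_id,
            "chip_count": p.chip_count,
            "input_count": p.input_count,
            "chip_rpkm": p.chip_rpkm,
            "input_rpkm": p.input_rpkm,
            "adjusted_rpkm": p.adjusted_rpkm,
        }
        for p in peaks
    ]
    pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "mark", "sample_id", "chip_count",
            "input_count", "chip_rpkm", "input_rpkm", "adjusted_rpkm",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_bedgraph(track: pd.DataFrame, path, name: str = "coverage") -> None:
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for row in track.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.rpm:.6g}\n")
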