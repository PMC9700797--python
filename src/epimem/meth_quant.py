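"""CpG methylation quantification around transcription start sites.

Consumes per-CpG methylation frequency tables (the Nanopolish
``calculate_methylation_frequency.py`` dialect) or per-read call tables,
computes sliding-window methylated fractions over the -1 kb/+1 kb TSS
region (300 bp windows, 30 bp step), reduces each gene's profile to one
raw fraction, mean-centers within each sample to correct sample-to-sample
differences, and averages the two animal replicates.

Window fractions pool calls (sum methylated / sum called) across the CpG
sites in a window rather than averaging per-site frequencies; a
per-site-average mode exists for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GeneAnnotation

logger = logging.getLogger(__name__)

#: methylation profiling defaults: -1 kb/+1 kb, 300 bp window, 30 bp step
METH_REGION = (1000, 1000)
WINDOW_BP = 300
STEP_BP = 30

FREQ_COLUMNS = [
    "chromosome",
    "start",
    "end",
    "num_motifs_in_group",
    "called_sites",
    "called_sites_methylated",
    "methylated_frequency",
    "group_sequence",
]


@dataclass(frozen=True)
class MethSiteRecord:
    """One CpG (or grouped CpG motif) with call tallies."""

    chrom: str
    start: int
    end: int
    num_motifs: int
    called_sites: int
    called_sites_methylated: int
    methylated_frequency: float

    def __post_init__(self) -> None:
        if not (0 <= self.called_sites_methylated <= self.called_sites):
            raise ValueError("0 <= methylated calls <= called sites violated")
        if self.num_motifs < 1:
            raise ValueError("num_motifs must be >= 1")
        if self.called_sites > 0:
            expect = self.called_sites_methylated / self.called_sites
            if abs(self.methylated_frequency - expect) > 1e-9:
                raise ValueError("methylated_frequency inconsistent with tallies")


def site_frequency(calls: pd.DataFrame, llr_threshold: float = 0.0) -> pd.DataFrame:
    """Aggregate per-read methylation calls into per-site frequencies.

    ``calls`` columns: chromosome, start, end, read_name, and either a
    boolean ``methylated`` or a ``log_lik_ratio`` (positive = methylated).
    With a log-likelihood ratio, calls with |LLR| < ``llr_threshold`` are
    ambiguous and dropped. Sites with zero passing calls are omitted.
    Returns a frame with the frequency-table columns.
    """
    df = calls.copy()
    if "methylated" not in df.columns:
        if "log_lik_ratio" not in df.columns:
            raise ValueError("calls need a 'methylated' or 'log_lik_ratio' column")
        df = df[df["log_lik_ratio"].abs() >= llr_threshold]
        df["methylated"] = df["log_lik_ratio"] > 0
    if "num_motifs_in_group" not in df.columns:
        df["num_motifs_in_group"] = 1
    grouped = (
        df.groupby(["chromosome", "start", "end"], sort=True)
        .agg(
            num_motifs_in_group=("num_motifs_in_group", "first"),
            called_sites=("methylated", "size"),
            called_sites_methylated=("methylated", "sum"),
        )
        .reset_index()
    )
    grouped = grouped[grouped["called_sites"] > 0]
    grouped["methylated_frequency"] = (
        grouped["called_sites_methylated"] / grouped["called_sites"]
    )
    grouped["group_sequence"] = "CG"
    return grouped[FREQ_COLUMNS]


def sliding_windows(
    region_len: int = 2000, window: int = WINDOW_BP, step: int = STEP_BP
) -> np.ndarray:
    """Window start offsets relative to the TSS for a centred region.

    The region spans [-region_len/2, +region_len/2); only windows fully
    inside it are kept (no partial windows). Defaults give 57 windows:
    [-1000, -700), [-970, -670), ..., [680, 980).
    """
    if window > region_len:
        raise ValueError("window must be <= region_len")
    if step < 1:
        raise ValueError("step must be >= 1")
    half = region_len // 2
    lo, hi = -half, region_len - half
    return np.arange(lo, hi - window + 1, step, dtype=np.int64)


@dataclass
class TssMethProfile:
    """Sliding-window methylated fractions around one gene's TSS."""

    gene_id: str
    sample_id: str
    window_starts: np.ndarray  # offsets relative to TSS
    window_fractions: np.ndarray  # NaN where no CpG
    n_cpg_per_window: np.ndarray


def tss_meth_profile(
    sites: pd.DataFrame,
    gene: GeneAnnotation,
    sample_id: str = "",
    region: tuple[int, int] = METH_REGION,
    window: int = WINDOW_BP,
    step: int = STEP_BP,
    strand_aware: bool = True,
    pooled: bool = True,
) -> TssMethProfile:
    """Sliding-window methylation profile over the TSS region.

    A grouped CpG motif is assigned to every window containing the
    group's start (strand-aware offset). Pooled mode (default) computes
    sum(methylated calls) / sum(called sites) per window; the alternative
    averages per-site frequencies. Windows with no CpG are NaN.
    """
    up, down = region
    starts = sliding_windows(up + down, window, step)
    mask = sites["chromosome"] == gene.chrom
    sub = sites.loc[mask]
    if gene.strand == "+" or not strand_aware:
        offsets = sub["start"].to_numpy() - gene.tss
    else:
        offsets = gene.tss - sub["start"].to_numpy()
    called = sub["called_sites"].to_numpy(dtype=float)
    meth = sub["called_sites_methylated"].to_numpy(dtype=float)
    freq = sub["methylated_frequency"].to_numpy(dtype=float)
    fractions, n_cpg = _profile_arrays(
        offsets, called, meth, freq, starts, window, pooled
    )
    return TssMethProfile(gene.gene_id, sample_id, starts, fractions, n_cpg)


def _profile_arrays(offsets, called, meth, freq, starts, window, pooled):
    """Window fractions from TSS-relative site offsets (inner kernel)."""
    n_win = len(starts)
    fractions = np.full(n_win, np.nan)
    n_cpg = np.zeros(n_win, dtype=np.int64)
    if offsets.size:
        order = np.argsort(offsets)
        offsets = offsets[order]
        called, meth, freq = called[order], meth[order], freq[order]
        lo = np.searchsorted(offsets, starts, side="left")
        hi = np.searchsorted(offsets, starts + window, side="left")
        for i in range(n_win):
            a, b = lo[i], hi[i]
            k = b - a
            n_cpg[i] = k
            if k == 0:
                continue
            if pooled:
                tot = called[a:b].sum()
                if tot > 0:
                    fractions[i] = meth[a:b].sum() / tot
                else:
                    n_cpg[i] = 0
            else:
                fractions[i] = float(np.mean(freq[a:b]))
    return fractions, n_cpg


def gene_meth_score(profile: TssMethProfile, reduce: str = "mean") -> float:
    """Reduce a gene's window profile to one raw methylated fraction.

    NaN windows are ignored; an all-missing profile yields NaN (the gene
    is excluded downstream).
    """
    vals = profile.window_fractions[~np.isnan(profile.window_fractions)]
    if vals.size == 0:
        logger.info("gene %s: no scored window, excluded", profile.gene_id)
        return float("nan")
    if reduce == "mean":
        return float(np.mean(vals))
    if reduce == "median":
        return float(np.median(vals))
    if reduce == "min":
        return float(np.min(vals))
    raise ValueError(f"unknown reduction {reduce!r}; use mean|median|min")


def meth_score_matrix(
    sites_by_sample: dict[str, pd.DataFrame],
    genes,
    reduce: str = "mean",
    strand_aware: bool = True,
    pooled: bool = True,
) -> pd.DataFrame:
    """Genes x samples matrix of raw TSS methylated fractions."""
    up, down = METH_REGION
    starts = sliding_windows(up + down, WINDOW_BP, STEP_BP)
    data = {}
    for sample_id, sites in sites_by_sample.items():
        # pre-sort once per sample; slice the TSS neighbourhood per gene
        srt = sites.sort_values(["chromosome", "start"], kind="mergesort")
        by_chrom = {
            str(chrom): (
                sub["start"].to_numpy(dtype=np.int64),
                sub["called_sites"].to_numpy(dtype=float),
                sub["called_sites_methylated"].to_numpy(dtype=float),
                sub["methylated_frequency"].to_numpy(dtype=float),
            )
            for chrom, sub in srt.groupby("chromosome", sort=False)
        }
        col = []
        for g in genes:
            if g.chrom not in by_chrom:
                col.append(float("nan"))
                continue
            pos, called, meth, freq = by_chrom[g.chrom]
            a = np.searchsorted(pos, g.tss - (up + WINDOW_BP), side="left")
            b = np.searchsorted(pos, g.tss + (down + WINDOW_BP), side="right")
            if g.strand == "+" or not strand_aware:
                offs = pos[a:b] - g.tss
            else:
                offs = g.tss - pos[a:b]
            fr, _ = _profile_arrays(
                offs, called[a:b], meth[a:b], freq[a:b], starts, WINDOW_BP, pooled
            )
            prof = TssMethProfile(g.gene_id, sample_id, starts, fr, _)
            col.append(gene_meth_score(prof, reduce=reduce))
        data[sample_id] = col
    df = pd.DataFrame(data, index=[g.gene_id for g in genes])
    df.index.name = "gene_id"
    return df


def center_and_average(
    raw_scores: pd.DataFrame,
    replicate_pairs: list[tuple[str, str, str]],
    keep_single: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample mean-centering, then averaging of replicate pairs.

    Centering subtracts each sample's own mean over its scored genes
    (sample-to-sample correction). ``replicate_pairs`` is a list of
    (sample_a, sample_b, label); the returned averaged frame has one
    ``label`` column per pair, the unweighted mean of the two centered
    values. Genes scored in only one replicate are excluded unless
    ``keep_single`` (then the single centered value is used).

    Returns (centered genes x samples, averaged genes x labels).
    """
    for a, b, _label in replicate_pairs:
        for s in (a, b):
            if s not in raw_scores.columns:
                raise KeyError(f"replicate pair references missing sample {s!r}")
    centered = raw_scores - raw_scores.mean(axis=0, skipna=True)
    avg = {}
    for a, b, label in replicate_pairs:
        pair = centered[[a, b]]
        if keep_single:
            avg[label] = pair.mean(axis=1, skipna=True)
        else:
            avg[label] = pair.mean(axis=1, skipna=False)
    out = pd.DataFrame(avg, index=raw_scores.index)
    out.index.name = "gene_id"
    return centered, out


# ---------------------------------------------------------------------------
# readers / writers


def read_methylation_frequency(path) -> pd.DataFrame:
    """Read a calculate_methylation_frequency-style TSV."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in FREQ_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise ValueError(f"methylation table {path} lacks columns: {missing}")
    bad = df["called_sites_methylated"] > df["called_sites"]
    if bad.any():
        raise ValueError(
            f"methylation table {path}: methylated calls exceed called sites "
            f"on {int(bad.sum())} rows"
        )
    return df


def write_methylation_frequency(df: pd.DataFrame, path) -> None:
    cols = [c for c in FREQ_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols)


def profile_long_table(profiles: list[TssMethProfile]) -> pd.DataFrame:
    """Long-format per-gene window table for per-locus methylation plots."""
    rows = []
    for p in profiles:
        for w, f, n in zip(p.window_starts, p.window_fractions, p.n_cpg_per_window):
            rows.append(
                {
                    "gene_id": p.gene_id,
                    "sample_id": p.sample_id,
                    "window_start": int(w),
                    "fraction": f,
                    "n_cpg": int(n),
                }
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "sample_id", "window_start", "fraction", "n_cpg"]
    )
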