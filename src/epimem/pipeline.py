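"""End-to-end orchestration: simulate -> quantify -> compare -> report.

One configuration drives a full run. Every under-specified analysis
choice (strand-awareness of TSS windows, zero-filling of unscored genes,
the per-gene reduction over methylation windows, pooled versus per-site
window fractions) is a named option echoed to the log and the manifest,
so each run is auditable.

Outputs are plain tab-separated tables plus bedGraph tracks; re-running
with the same seed reproduces byte-identical files (the manifest records
checksums; its own timestamp is excluded from them).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import (
    load_gene_annotation,
    load_gene_sets,
    tss_window,
    write_gene_annotation,
    write_gene_sets,
)
from .chip_quant import (
    GenomicInterval,
    background_adjust,
    coverage_track,
    gene_score_matrix,
    quantify_peaks,
    read_library_manifest,
    read_peaks,
    read_reads_bed,
    write_intervals_bed,
    write_retained_peaks,
)
from .expression_stats import compare_panel, read_ct_table, relative_expression, write_ct_table
from .geneset_stats import (
    anova_tukey,
    assemble_distribution,
    summarize,
    values_long_table,
)
from .meth_quant import (
    center_and_average,
    meth_score_matrix,
    profile_long_table,
    read_methylation_frequency,
    tss_meth_profile,
    write_methylation_frequency,
)
from .synthetic import SimConfig, generate_annotation, generate_chip, generate_meth, generate_qpcr, meth_replicate_pairs

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class AnalysisOptions:
    """Analysis-side switches, separate from the generator's knobs."""

    alpha: float = 0.05
    strand_aware: bool = True
    zero_fill: bool = False
    window_reduce: str = "mean"  # mean | median | min
    pooled_window_fractions: bool = True
    track_bin_bp: int = 100
    track_flank_bp: int = 5000
    n_track_genes: int = 9


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


# ---------------------------------------------------------------------------
# stage: simulate


def simulate(cfg: SimConfig, outdir: Path) -> dict:
    """Generate the full synthetic cohort and write it as input files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    genes, gene_sets = generate_annotation(cfg, rng)
    write_gene_annotation(genes, outdir / "annotation.bed")
    write_gene_sets(gene_sets, outdir / "gene_sets.tsv")

    chip_samples, chip_truth = generate_chip(cfg, genes, gene_sets, rng)
    chip_dir = outdir / "chip"
    chip_dir.mkdir(exist_ok=True)
    manifest_rows = []
    for s in chip_samples:
        reads_path = chip_dir / f"{s.sample_id}.reads.bed"
        s.reads.to_csv(reads_path, sep="\t", header=False, index=False)
        peaks_path = ""
        if s.peaks:
            peaks_path = chip_dir / f"{s.sample_id}.peaks.bed"
            write_intervals_bed(s.peaks, peaks_path)
        manifest_rows.append(
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "mark": s.mark,
                "library_size": s.library_size,
                "reads_path": str(reads_path.relative_to(outdir)),
                "peaks_path": str(peaks_path and Path(peaks_path).relative_to(outdir)),
                "line_id": s.line_id,
                "replicate": s.replicate,
            }
        )
    manifest = pd.DataFrame(manifest_rows)
    _write_tsv(manifest, outdir / "library_manifest.tsv")

    meth_samples, meth_truth = generate_meth(cfg, genes, gene_sets, rng)
    meth_dir = outdir / "meth"
    meth_dir.mkdir(exist_ok=True)
    for sample_id, df in meth_samples.items():
        write_methylation_frequency(df, meth_dir / f"{sample_id}.methfreq.tsv")

    ct = generate_qpcr(cfg, rng)
    write_ct_table(ct, outdir / "ct_table.tsv")

    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=2, sort_keys=True)
    return {
        "genes": genes,
        "gene_sets": gene_sets,
        "chip_truth": chip_truth,
        "meth_truth": meth_truth,
    }


# ---------------------------------------------------------------------------
# stage: quantify ChIP


def quantify_chip(indir: Path, outdir: Path, opts: AnalysisOptions) -> dict:
    """Peaks + reads -> retained peak table and per-mark TSS score matrices."""
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = load_gene_annotation(indir / "annotation.bed", format="bed6")
    manifest = read_library_manifest(indir / "library_manifest.tsv")

    inputs = {}
    for row in manifest[manifest["mark"] == "input"].itertuples(index=False):
        reads = read_reads_bed(indir / row.reads_path)
        inputs[(row.line_id, row.replicate)] = (reads, int(row.library_size))

    retained_all = []
    counts_log = []
    peaks_by_mark: dict[str, dict[str, list]] = {}
    chip_rows = manifest[manifest["mark"] != "input"]
    for row in chip_rows.itertuples(index=False):
        peaks = read_peaks(indir / row.peaks_path)
        reads = read_reads_bed(indir / row.reads_path)
        key = (row.line_id, row.replicate)
        if key not in inputs:
            raise ValueError(f"no input library for chromatin prep {key}")
        in_reads, in_lib = inputs[key]
        quantified = quantify_peaks(
            peaks, reads, in_reads, int(row.library_size), in_lib,
            mark=row.mark, sample_id=row.sample_id,
        )
        retained, dropped = background_adjust(quantified)
        retained_all.extend(retained)
        counts_log.append(
            {
                "sample_id": row.sample_id,
                "mark": row.mark,
                "peaks_called": len(peaks),
                "peaks_retained": len(retained),
                "peaks_dropped": dropped,
            }
        )
        peaks_by_mark.setdefault(row.mark, {})[row.sample_id] = retained

    write_retained_peaks(retained_all, outdir / "retained_peaks.tsv")
    _write_tsv(pd.DataFrame(counts_log), outdir / "peak_counts.tsv")

    score_matrices = {}
    for mark, by_sample in peaks_by_mark.items():
        mat = gene_score_matrix(
            by_sample, genes,
            strand_aware=opts.strand_aware, zero_fill=opts.zero_fill,
        )
        mat = mat.reindex(sorted(mat.columns), axis=1)
        _write_tsv(mat, outdir / f"chip_scores_{mark}.tsv", index=True)
        score_matrices[mark] = mat
    return {
        "genes": genes,
        "manifest": manifest,
        "score_matrices": score_matrices,
        "peak_counts": pd.DataFrame(counts_log),
    }


def group_average_chip(
    score_matrices: dict[str, pd.DataFrame], manifest: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Average each group's replicate samples into one column per group."""
    group_of = dict(zip(manifest["sample_id"], manifest["group"]))
    out = {}
    for mark, mat in score_matrices.items():
        cols = {}
        for grp in sorted(set(group_of.values())):
            members = [c for c in mat.columns if group_of.get(c) == grp]
            cols[grp] = mat[members].mean(axis=1, skipna=True)
        out[mark] = pd.DataFrame(cols)
    return out


# ---------------------------------------------------------------------------
# stage: quantify methylation


def quantify_meth(indir: Path, outdir: Path, cfg: SimConfig, opts: AnalysisOptions) -> dict:
    """Frequency tables -> raw, centered and replicate-averaged scores."""
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = load_gene_annotation(indir / "annotation.bed", format="bed6")
    meth_dir = indir / "meth"
    sites_by_sample = {
        p.name.replace(".methfreq.tsv", ""): read_methylation_frequency(p)
        for p in sorted(meth_dir.glob("*.methfreq.tsv"))
    }
    raw = meth_score_matrix(
        sites_by_sample, genes,
        reduce=opts.window_reduce,
        strand_aware=opts.strand_aware,
        pooled=opts.pooled_window_fractions,
    )
    pairs = meth_replicate_pairs(cfg)
    centered, averaged = center_and_average(raw, pairs)
    _write_tsv(raw, outdir / "meth_scores_raw.tsv", index=True)
    _write_tsv(centered, outdir / "meth_scores_centered.tsv", index=True)
    _write_tsv(averaged, outdir / "meth_scores_group.tsv", index=True)
    return {
        "genes": genes,
        "sites_by_sample": sites_by_sample,
        "raw": raw,
        "centered": centered,
        "averaged": averaged,
    }


# ---------------------------------------------------------------------------
# stage: compare


def compare_gene_sets(
    group_scores_by_assay: dict[str, pd.DataFrame],
    gene_sets,
    alpha: float = 0.05,
):
    """Per (gene set, assay): group distributions + ANOVA/Tukey."""
    distributions, results = [], []
    for assay in sorted(group_scores_by_assay):
        mat = group_scores_by_assay[assay]
        for gs in sorted(gene_sets, key=lambda g: g.name):
            dists = []
            ok = True
            for grp in mat.columns:
                try:
                    d = assemble_distribution(mat[grp], gs, grp, assay=assay)
                except ValueError:
                    ok = False
                    break
                if d.n_genes_scored < 2:
                    ok = False
                    break
                dists.append(d)
            if not ok:
                logger.warning(
                    "set %s / assay %s skipped: fewer than 2 scored genes "
                    "in some group", gs.name, assay,
                )
                continue
            distributions.extend(dists)
            results.append(anova_tukey(dists, alpha=alpha))
    return distributions, results


# ---------------------------------------------------------------------------
# stage: tracks / plot tables


def track_tables(
    indir: Path,
    outdir: Path,
    genes,
    manifest: pd.DataFrame,
    sites_by_sample: dict[str, pd.DataFrame],
    track_genes: list[str],
    opts: AnalysisOptions,
) -> None:
    """Per-locus RPM coverage and TSS methylation profile long tables."""
    indir, outdir = Path(indir), Path(outdir)
    tracks_dir = outdir / "tracks"
    tracks_dir.mkdir(parents=True, exist_ok=True)
    by_id = {g.gene_id: g for g in genes}
    chip_rows = manifest[manifest["mark"] != "input"]
    reads_cache = {
        row.sample_id: read_reads_bed(indir / row.reads_path)
        for row in chip_rows.itertuples(index=False)
    }
    for gene_id in track_genes:
        if gene_id not in by_id:
            logger.warning("track gene %s absent from annotation, skipped", gene_id)
            continue
        g = by_id[gene_id]
        lo = max(min(g.body_start, g.tss) - opts.track_flank_bp, 0)
        hi = max(g.body_end, g.tss + 1) + opts.track_flank_bp
        region = GenomicInterval(g.chrom, lo, hi)
        frames = []
        for row in chip_rows.itertuples(index=False):
            tr = coverage_track(reads_cache[row.sample_id], region, opts.track_bin_bp, int(row.library_size))
            tr.insert(0, "sample_id", row.sample_id)
            tr.insert(1, "mark", row.mark)
            frames.append(tr)
        _write_tsv(pd.concat(frames, ignore_index=True), tracks_dir / f"{gene_id}.coverage.tsv")
        profs = [
            tss_meth_profile(
                sites, g, sample_id,
                strand_aware=opts.strand_aware,
                pooled=opts.pooled_window_fractions,
            )
            for sample_id, sites in sorted(sites_by_sample.items())
        ]
        _write_tsv(profile_long_table(profs), tracks_dir / f"{gene_id}.meth_profile.tsv")


# ---------------------------------------------------------------------------
# run-all


def run_pipeline(
    cfg: SimConfig,
    outdir,
    opts: AnalysisOptions | None = None,
    track_genes: list[str] | None = None,
    write_tracks: bool = True,
) -> dict:
    """Simulate, quantify both assay families, compare gene sets, analyse
    the qPCR layer, and write all result tables plus a run manifest."""
    opts = opts or AnalysisOptions()
    outdir = Path(outdir)
    t0 = time.time()
    sim = simulate(cfg, outdir)
    logger.info(
        "options in effect: strand_aware=%s zero_fill=%s window_reduce=%s pooled=%s alpha=%s",
        opts.strand_aware, opts.zero_fill, opts.window_reduce,
        opts.pooled_window_fractions, opts.alpha,
    )
    results_dir = outdir / "results"
    chip = quantify_chip(outdir, results_dir, opts)
    meth = quantify_meth(outdir, results_dir, cfg, opts)
    gene_sets = load_gene_sets(outdir / "gene_sets.tsv")

    group_scores = group_average_chip(
        chip["score_matrices"],
        chip["manifest"][chip["manifest"]["mark"] != "input"],
    )
    group_scores["meth"] = meth["averaged"]
    for mark, mat in group_scores.items():
        if mark != "meth":
            _write_tsv(mat.rename_axis("gene_id"), results_dir / f"chip_scores_group_{mark}.tsv", index=True)
    distributions, comparisons = compare_gene_sets(
        group_scores, gene_sets, alpha=opts.alpha
    )
    summary = summarize(comparisons, distributions)
    _write_tsv(summary, results_dir / "comparison_summary.tsv")
    _write_tsv(values_long_table(distributions), results_dir / "values_long.tsv")

    ct = read_ct_table(outdir / "ct_table.tsv")
    rel = relative_expression(ct, cfg.qpcr_calibrator_group)
    qpcr_cmp = compare_panel(rel, cfg.groups[0], cfg.groups[1], alpha=opts.alpha)
    _write_tsv(rel, results_dir / "qpcr_relative_expression.tsv")
    _write_tsv(qpcr_cmp, results_dir / "qpcr_comparison.tsv")

    if write_tracks:
        if track_genes is None:
            kidney = next(gs for gs in gene_sets if gs.name == "kidney_dev")
            track_genes = sorted(kidney.members)[: opts.n_track_genes]
        track_tables(
            outdir, results_dir, chip["genes"], chip["manifest"],
            meth["sites_by_sample"], track_genes, opts,
        )

    manifest = build_run_manifest(cfg, opts, outdir, t0)
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {
        "summary": summary,
        "group_scores": group_scores,
        "distributions": distributions,
        "comparisons": comparisons,
        "qpcr": qpcr_cmp,
        "chip": chip,
        "meth": meth,
        "sim": sim,
        "manifest": manifest,
        "outdir": outdir,
    }


def build_run_manifest(cfg: SimConfig, opts: AnalysisOptions, outdir: Path, t0: float) -> dict:
    """Checksums + row counts for every file the run wrote. Timestamps are
    recorded but live outside the checksummed content."""
    outdir = Path(outdir)
    files = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "run_manifest.json":
            rel = str(p.relative_to(outdir))
            files[rel] = {"sha256": _sha256(p), "bytes": p.stat().st_size}
    return {
        "tool_version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "options": dataclasses.asdict(opts),
        "files": files,
        "elapsed_s": round(time.time() - t0, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
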