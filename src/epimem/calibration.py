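"""Monte-Carlo validation studies: null calibration and signal recovery.

These runs answer the two questions any memory-detection pipeline must
pass before its null result means anything: (1) with no injected
cell-of-origin signal, how often does the gene-set comparison call a
difference (it should essentially never, at the configured alpha)?
(2) with a known signal injected into one gene set, is that set — and
only that set — flagged, and is the injected magnitude recovered?

Everything here runs in memory on the synthetic cohort, seed-derived and
deterministic, using the same quantification code paths as the file-based
pipeline.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .chip_quant import background_adjust, gene_score_matrix, quantify_peaks
from .expression_stats import compare_panel, relative_expression
from .geneset_stats import anova_tukey, assemble_distribution
from .meth_quant import center_and_average, meth_score_matrix
from .synthetic import (
    MemoryEffect,
    SimConfig,
    generate_annotation,
    generate_chip,
    generate_meth,
    generate_qpcr,
    meth_replicate_pairs,
)

logger = logging.getLogger(__name__)


def score_chip_cohort(cfg: SimConfig, rng: np.random.Generator, genes, gene_sets):
    """Simulate ChIP libraries and return per-mark group-averaged TSS
    score matrices (genes x groups) plus the generator truth."""
    samples, truth = generate_chip(cfg, genes, gene_sets, rng)
    inputs = {
        (s.line_id, s.replicate): s for s in samples if s.mark == "input"
    }
    by_mark: dict[str, dict[str, list]] = {}
    group_of: dict[str, str] = {}
    for s in samples:
        if s.mark == "input":
            continue
        inp = inputs[(s.line_id, s.replicate)]
        quantified = quantify_peaks(
            s.peaks, s.reads, inp.reads, s.library_size, inp.library_size,
            mark=s.mark, sample_id=s.sample_id,
        )
        retained, _ = background_adjust(quantified)
        by_mark.setdefault(s.mark, {})[s.sample_id] = retained
        group_of[s.sample_id] = s.group
    group_mats = {}
    for mark, by_sample in by_mark.items():
        mat = gene_score_matrix(by_sample, genes)
        cols = {
            grp: mat[[c for c in mat.columns if group_of[c] == grp]].mean(axis=1)
            for grp in cfg.groups
        }
        group_mats[mark] = pd.DataFrame(cols)
    return group_mats, truth


def score_meth_cohort(cfg: SimConfig, rng: np.random.Generator, genes, gene_sets):
    """Simulate methylation tables and return the centered, replicate-
    averaged genes x groups matrix."""
    tables, truth = generate_meth(cfg, genes, gene_sets, rng)
    raw = meth_score_matrix(tables, genes)
    _, averaged = center_and_average(raw, meth_replicate_pairs(cfg))
    return averaged, truth


def compare_all_sets(group_mats: dict[str, pd.DataFrame], gene_sets, alpha=0.05):
    """One Tukey-adjusted p per (gene set, assay) for the two-group design."""
    rows = []
    for assay in sorted(group_mats):
        mat = group_mats[assay]
        for gs in sorted(gene_sets, key=lambda g: g.name):
            dists = []
            try:
                for grp in mat.columns:
                    dists.append(assemble_distribution(mat[grp], gs, grp, assay))
                res = anova_tukey(dists, alpha=alpha)
            except ValueError:
                logger.warning("set %s / %s skipped in comparison", gs.name, assay)
                continue
            (_a, _b, diff, p, label) = res.pairwise[0]
            rows.append(
                {
                    "gene_set": gs.name,
                    "assay": assay,
                    "mean_diff": diff,
                    "tukey_p": p,
                    "label": label,
                    "median_diff": dists[0].median - dists[1].median,
                }
            )
    return pd.DataFrame(rows)


def null_calibration(
    n_seeds: int = 20,
    base_seed: int = 0,
    cfg: SimConfig | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Gene-set comparisons across seeds with memory_effect = 0.

    Returns the long table of (seed, gene_set, assay, tukey_p, label)
    over both assay families; the fraction labelled n.s. is the
    calibration statistic.
    """
    frames = []
    for i in range(n_seeds):
        seed = int(base_seed) + i
        c = cfg or SimConfig()
        c = SimConfig.from_dict({**c.to_dict(), "seed": seed,
                                 "memory_effect": {"effect_size": 0.0}})
        rng = np.random.default_rng(seed)
        genes, gene_sets = generate_annotation(c, rng)
        group_mats, _ = score_chip_cohort(c, rng, genes, gene_sets)
        group_mats["meth"], _ = score_meth_cohort(c, rng, genes, gene_sets)
        table = compare_all_sets(group_mats, gene_sets, alpha=alpha)
        table.insert(0, "seed", seed)
        frames.append(table)
    return pd.concat(frames, ignore_index=True)


def power_study(
    n_seeds: int = 50,
    base_seed: int = 0,
    effect_size: float = 2.0,
    target_set: str = "kidney_dev",
    assay: str = "H3K4me3",
    cfg: SimConfig | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Inject a memory effect into one gene set and measure detection.

    Per seed: whether the target set is flagged in the affected assay,
    how many other (set, assay) pairs are flagged anywhere in the ChIP
    assays, the measured difference of group medians at the target set,
    and the generator-truth expected difference.
    """
    rows = []
    for i in range(n_seeds):
        seed = int(base_seed) + i
        c = cfg or SimConfig()
        c = SimConfig.from_dict(
            {
                **c.to_dict(),
                "seed": seed,
                "memory_effect": {
                    "target_sets": [target_set],
                    "assay": assay,
                    "effect_size": effect_size,
                    "group": c.groups[0],
                },
            }
        )
        rng = np.random.default_rng(seed)
        genes, gene_sets = generate_annotation(c, rng)
        group_mats, truth = score_chip_cohort(c, rng, genes, gene_sets)
        table = compare_all_sets(group_mats, gene_sets, alpha=alpha)
        hit = table[(table.gene_set == target_set) & (table.assay == assay)]
        others = table[(table.gene_set != target_set) | (table.assay != assay)]
        measured = float(hit["median_diff"].iloc[0])
        # generator truth: median expected score per group over target genes
        members = next(g for g in gene_sets if g.name == target_set).members
        exp = truth["expected_score"][assay]
        sel = exp.loc[[gid for gid in exp.index if gid.upper() in members]].dropna()
        truth_diff = float(
            sel[c.groups[0]].median() - sel[c.groups[1]].median()
        )
        rows.append(
            {
                "seed": seed,
                "target_flagged": bool(hit["tukey_p"].iloc[0] < alpha),
                "n_other_flagged": int((others["tukey_p"] < alpha).sum()),
                "measured_diff": measured,
                "truth_diff": truth_diff,
            }
        )
    return pd.DataFrame(rows)


def qpcr_null_rejection(
    n_genes: int = 1000, seed: int = 0, alpha: float = 0.05
) -> float:
    """Type-I error of the per-gene two-group t-test on simulated null
    genes (all fold changes = 1); should sit at ~alpha."""
    cfg = SimConfig(
        seed=seed,
        qpcr_genes=tuple(f"null{i:04d}" for i in range(n_genes)),
        qpcr_fold_changes={},
    )
    ct = generate_qpcr(cfg, np.random.default_rng(seed))
    rel = relative_expression(ct, cfg.qpcr_calibrator_group)
    panel = compare_panel(rel, cfg.groups[0], cfg.groups[1], alpha=alpha)
    return float((panel["p_value"] < alpha).mean())
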