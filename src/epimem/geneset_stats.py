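"""Gene-set distribution assembly and group comparison statistics.

Genes are the units of replication: for each gene set and assay, the
replicate-averaged per-gene scores of each group (e.g. iPSCs of proximal
tubule versus tail-tip fibroblast origin) form a distribution, compared
by one-way ANOVA followed by Tukey's honest significant difference test
(Tukey-Kramer form, valid for unequal sizes). Two-sample comparisons use
a classical two-tailed t-test. Significance labels follow the
*, **, ***, **** convention at 0.05 / 0.01 / 0.001 / 0.0001.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GeneSet, normalize_symbol

logger = logging.getLogger(__name__)

STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_label(p: float, alpha: float = 0.05) -> str:
    """Star label for a p-value; 'n.s.' at or above alpha."""
    if np.isnan(p):
        return "n.s."
    for cut, stars in STAR_LEVELS:
        if p < cut:
            return stars
    return "*" if p < alpha else "n.s."


@dataclass
class GroupDistribution:
    """Scores of one group's genes within one gene set and assay."""

    gene_set: str
    group: str
    assay: str
    values: np.ndarray

    @property
    def n_genes_scored(self) -> int:
        return len(self.values)

    @property
    def median(self) -> float:
        return float(np.median(self.values))


@dataclass
class ComparisonResult:
    """Omnibus ANOVA plus Tukey-adjusted pairwise results for one set."""

    gene_set: str
    assay: str
    f_stat: float
    anova_p: float
    # (group_a, group_b, mean_diff, tukey_adjusted_p, label)
    pairwise: list = field(default_factory=list)
    alpha: float = 0.05


def assemble_distribution(
    scores: pd.Series, gene_set: GeneSet, group: str, assay: str = ""
) -> GroupDistribution:
    """Pick the gene set's members out of a per-gene score vector.

    ``scores`` is indexed by gene symbol (or gene_id acting as symbol);
    membership is by normalized (case-insensitive) symbol. Members with a
    missing (NaN) score are excluded.
    """
    normalized_index = scores.index.map(normalize_symbol)
    members = {normalize_symbol(m) for m in gene_set.members}
    mask = normalized_index.isin(members)
    values = scores[mask].dropna().to_numpy(dtype=float)
    if values.size == 0:
        raise ValueError(
            f"gene set {gene_set.name!r} has no scored members in this matrix"
        )
    return GroupDistribution(gene_set.name, group, assay, values)


def anova_tukey(
    distributions: list[GroupDistribution], alpha: float = 0.05
) -> ComparisonResult:
    """One-way fixed-effects ANOVA with Tukey-Kramer post-hoc pairs.

    Requires >= 2 groups of >= 2 values each; unequal sizes are fine.
    Exact separation (zero within-group variance) is resolved without
    jitter: pairs with different means get p = 0, identical means p = 1.
    """
    if len(distributions) < 2:
        raise ValueError("need at least two group distributions")
    for d in distributions:
        if d.n_genes_scored < 2:
            raise ValueError(
                f"group {d.group!r} in set {d.gene_set!r} has < 2 values"
            )
    gene_set = distributions[0].gene_set
    assay = distributions[0].assay
    groups = [d.group for d in distributions]
    arrays = [np.asarray(d.values, dtype=float) for d in distributions]

    within_ss = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if within_ss == 0.0:
        return _exact_separation_result(gene_set, assay, groups, arrays, alpha)

    f_stat, anova_p = stats.f_oneway(*arrays)

    # Tukey-Kramer: q_ij = |mean_i - mean_j| / sqrt(MSE/2 (1/n_i + 1/n_j)),
    # referred to the studentized range with k groups and N - k df
    k = len(arrays)
    n_total = sum(len(a) for a in arrays)
    df_within = n_total - k
    mse = within_ss / df_within
    by_group = dict(zip(groups, arrays))
    pairwise = []
    for a, b in itertools.combinations(sorted(groups), 2):
        xa, xb = by_group[a], by_group[b]
        diff = xb.mean() - xa.mean()
        se = np.sqrt(mse / 2.0 * (1.0 / len(xa) + 1.0 / len(xb)))
        q = abs(diff) / se
        p_adj = float(stats.studentized_range.sf(q, k, df_within))
        p_adj = min(max(p_adj, 0.0), 1.0)
        pairwise.append((a, b, diff, p_adj, significance_label(p_adj, alpha)))
    return ComparisonResult(gene_set, assay, float(f_stat), float(anova_p), pairwise, alpha)


def _exact_separation_result(gene_set, assay, groups, arrays, alpha):
    """Degenerate case: every group is constant. Any difference in means
    is then infinitely significant; identical means are a perfect null."""
    means = [a.mean() for a in arrays]
    any_diff = max(means) > min(means)
    f_stat = float("inf") if any_diff else 0.0
    anova_p = 0.0 if any_diff else 1.0
    logger.info(
        "anova_tukey: zero within-group variance in set %r, exact-separation rule",
        gene_set,
    )
    pairwise = []
    for (ga, ma), (gb, mb) in itertools.combinations(zip(groups, means), 2):
        p = 0.0 if ma != mb else 1.0
        pairwise.append((ga, gb, mb - ma, p, significance_label(p, alpha)))
    return ComparisonResult(gene_set, assay, f_stat, anova_p, pairwise, alpha)


def two_group_test(
    a, b, equal_var: bool = True, alpha: float = 0.05
) -> tuple[float, float, str]:
    """Two-sample two-tailed t-test (Student by default, Welch by flag).

    Degenerate identical zero-variance vectors give (t=0, p=1) by
    convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # degenerate: no within-group variance; exact-separation rule
        if a.mean() == b.mean():
            logger.info("two_group_test: identical zero-variance vectors, p=1")
            return 0.0, 1.0, "n.s."
        return float("inf"), 0.0, significance_label(0.0, alpha)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p), significance_label(float(p), alpha)


def summarize(
    results: list[ComparisonResult],
    distributions: list[GroupDistribution] | None = None,
) -> pd.DataFrame:
    """One row per (gene_set, assay, pair), deterministically ordered.

    Includes group medians and sizes when the distributions are supplied.
    A Benjamini-Hochberg column over all rows is appended as a clearly
    labelled supplementary quantity (the per-set tests themselves are not
    corrected across sets).
    """
    if not results:
        raise ValueError("no comparison results to summarize")
    dist_lookup = {}
    if distributions:
        dist_lookup = {(d.gene_set, d.assay, d.group): d for d in distributions}
    rows = []
    for r in results:
        for a, b, diff, p, label in r.pairwise:
            da = dist_lookup.get((r.gene_set, r.assay, a))
            db = dist_lookup.get((r.gene_set, r.assay, b))
            rows.append(
                {
                    "gene_set": r.gene_set,
                    "assay": r.assay,
                    "group_a": a,
                    "group_b": b,
                    "median_a": da.median if da else np.nan,
                    "median_b": db.median if db else np.nan,
                    "n_a": da.n_genes_scored if da else np.nan,
                    "n_b": db.n_genes_scored if db else np.nan,
                    "mean_diff": diff,
                    "f_stat": r.f_stat,
                    "anova_p": r.anova_p,
                    "tukey_p": p,
                    "label": label,
                }
            )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["gene_set", "assay", "group_a", "group_b"], kind="mergesort"
    ).reset_index(drop=True)
    finite = df["tukey_p"].fillna(1.0).clip(0.0, 1.0)
    df["bh_fdr_across_sets"] = multipletests(finite, method="fdr_bh")[1]
    return df


def values_long_table(distributions: list[GroupDistribution]) -> pd.DataFrame:
    """Long-format per-gene values for violin-style plotting."""
    rows = []
    for d in distributions:
        for v in d.values:
            rows.append(
                {
                    "gene_set": d.gene_set,
                    "group": d.group,
                    "assay": d.assay,
                    "value": v,
                }
            )
    df = pd.DataFrame(rows, columns=["gene_set", "group", "assay", "value"])
    return df.sort_values(
        ["gene_set", "assay", "group"], kind="mergesort"
    ).reset_index(drop=True)
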