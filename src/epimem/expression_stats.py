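"""qPCR relative expression (2^-ddCt) and per-gene group comparisons.

Expression is reported relative to a calibrator group (e.g. E13.5 mouse
embryonic kidney) whose mean is 1.0 by construction: per well,
dCt = Ct(target) - Ct(reference gene); ddCt = dCt - mean dCt of the
calibrator for that gene; relative quantity = 2^-ddCt. Group comparisons
average wells within each cell line first (lines, not wells, are the
statistical replicates: n = 4 vs 4) and run a two-tailed t-test per gene.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .geneset_stats import two_group_test

logger = logging.getLogger(__name__)

CT_COLUMNS = ["sample_id", "group", "line_id", "gene", "ct_target", "ct_reference"]


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table {path} lacks columns: {missing}")
    for col in ("ct_target", "ct_reference"):
        bad = ~df[col].between(0, 45, inclusive="neither")
        if bad.any():
            raise ValueError(
                f"Ct table {path}: {int(bad.sum())} {col} values outside (0, 45)"
            )
    return df


def write_ct_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=CT_COLUMNS)


def relative_expression(records: pd.DataFrame, calibrator_group: str) -> pd.DataFrame:
    """Per-well relative quantity 2^-ddCt against the calibrator group.

    Returns the input rows with ``delta_ct``, ``delta_delta_ct`` and
    ``rel_quantity`` columns; the calibrator group's mean dCt per gene is
    the reference, so its mean relative quantity is 1.0 by construction
    (of the dCt scale; see compare layer for the measurement scale).
    """
    df = records.copy()
    df["delta_ct"] = df["ct_target"] - df["ct_reference"]
    calib = df[df["group"] == calibrator_group]
    if calib.empty:
        raise ValueError(f"no records for calibrator group {calibrator_group!r}")
    calib_mean = calib.groupby("gene")["delta_ct"].mean()
    missing = set(df["gene"]) - set(calib_mean.index)
    if missing:
        raise ValueError(
            f"genes missing from calibrator group: {sorted(missing)}"
        )
    df["delta_delta_ct"] = df["delta_ct"] - df["gene"].map(calib_mean)
    df["rel_quantity"] = np.power(2.0, -df["delta_delta_ct"])
    return df


def per_line_means(rel: pd.DataFrame) -> pd.DataFrame:
    """Average wells within each (group, line, gene): lines are the
    replication unit ('3 replicates per line' are technical wells)."""
    return (
        rel.groupby(["group", "line_id", "gene"], sort=True)["rel_quantity"]
        .mean()
        .reset_index()
    )


def compare_groups(
    rel: pd.DataFrame,
    gene: str,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
) -> tuple[float, float, str]:
    """Two-tailed t-test on per-line mean relative quantities for a gene."""
    lines = per_line_means(rel)
    sub = lines[lines["gene"] == gene]
    a = sub.loc[sub["group"] == group_a, "rel_quantity"].to_numpy()
    b = sub.loc[sub["group"] == group_b, "rel_quantity"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"gene {gene!r}: need >= 2 lines per group "
            f"(got {len(a)} vs {len(b)})"
        )
    t, p, label = two_group_test(a, b, alpha=alpha)
    return t, p, label


def compare_panel(
    rel: pd.DataFrame, group_a: str, group_b: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Run compare_groups for every gene; one deterministic row per gene."""
    lines = per_line_means(rel)
    rows = []
    for gene in sorted(lines["gene"].unique()):
        t, p, label = compare_groups(rel, gene, group_a, group_b, alpha=alpha)
        sub = lines[lines["gene"] == gene]
        rows.append(
            {
                "gene": gene,
                "group_a": group_a,
                "group_b": group_b,
                "mean_a": sub.loc[sub["group"] == group_a, "rel_quantity"].mean(),
                "mean_b": sub.loc[sub["group"] == group_b, "rel_quantity"].mean(),
                "t_stat": t,
                "p_value": p,
                "label": label,
            }
        )
    return pd.DataFrame(rows)
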