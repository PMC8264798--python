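"""Differential expression between tumor and normal samples.

The procedure is the classic per-gene recipe for processed abundance data:
drop genes expressed in fewer than 10% of samples, Welch t-test on
log2(x + pseudocount), and call a gene differentially expressed when the
raw two-sided p-value is below ``p_threshold`` and the linear fold change
(max ratio of group means) exceeds ``fc_threshold``.

Scale conventions: the test runs on the log2 scale (variance
stabilization); the fold change is the ratio of linear-scale group means,
so "fold change > 2" is equivalent to |log2FC| > 1.  The 10% expression
filter is inclusive: a gene non-zero in exactly 10% of samples is kept.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("cernet")


@dataclass
class DeConfig:
    p_threshold: float = 0.05
    fc_threshold: float = 2.0
    min_expressed_fraction: float = 0.10
    pseudocount: float = 0.01
    adjust: str = "none"  # none | BH

    def validate(self) -> None:
        if self.p_threshold <= 0 or self.fc_threshold <= 0:
            raise ValueError("thresholds must be > 0")
        if not 0.0 <= self.min_expressed_fraction <= 1.0:
            raise ValueError("min_expressed_fraction must be in [0, 1]")
        if self.adjust not in ("none", "BH"):
            raise ValueError(f"unknown adjust mode {self.adjust!r}")


def filter_low_expression(matrix: pd.DataFrame, min_fraction: float = 0.10) -> pd.DataFrame:
    """Drop genes with a non-zero value in less than ``min_fraction`` of samples."""
    frac = (matrix.to_numpy() > 0).mean(axis=1)
    keep = frac >= min_fraction
    if not keep.any():
        warnings.warn("expression filter removed every gene", stacklevel=2)
    return matrix.loc[keep]


def welch_t(x, y) -> tuple[float, float]:
    """Welch two-sample t-test, two-sided.

    Degenerate inputs are given the documented limits instead of NaN:
    zero variance in both groups with equal means -> (0, 1); zero variance
    with unequal means -> (+/-inf, 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_t requires >= 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return (np.inf if x.mean() > y.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def run_de(matrix: pd.DataFrame, samples: pd.DataFrame, cfg: DeConfig | None = None) -> pd.DataFrame:
    """Per-gene tumor-vs-normal testing.

    Returns one row per gene (post low-expression filter) with columns
    ``gene_id, mean_tumor, mean_normal, fold_change, log2fc, t_stat, p, q,
    direction``.  ``direction`` is ``up`` when the tumor mean is higher,
    the fold change clears ``fc_threshold`` and p (or q when adjust=BH)
    clears ``p_threshold``; ``down`` symmetrically; else ``ns``.
    """
    cfg = cfg or DeConfig()
    cfg.validate()
    cond = samples.set_index("sample_id")["condition"]
    tumor_ids = [s for s in matrix.columns if cond.get(s) == "tumor"]
    normal_ids = [s for s in matrix.columns if cond.get(s) == "normal"]
    if len(tumor_ids) < 3 or len(normal_ids) < 3:
        raise ValueError(
            f"need >= 3 samples per condition (tumor={len(tumor_ids)}, normal={len(normal_ids)})"
        )

    matrix = filter_low_expression(matrix, cfg.min_expressed_fraction)
    xt = matrix[tumor_ids].to_numpy()
    xn = matrix[normal_ids].to_numpy()

    lt = np.log2(xt + cfg.pseudocount)
    ln = np.log2(xn + cfg.pseudocount)
    # vectorized Welch on the log scale; degenerate rows fixed up below
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(lt, ln, axis=1, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        for i in np.flatnonzero(degenerate):
            t[i], p[i] = welch_t(lt[i], ln[i])

    mean_t = xt.mean(axis=1) + cfg.pseudocount
    mean_n = xn.mean(axis=1) + cfg.pseudocount
    log2fc = np.log2(mean_t) - np.log2(mean_n)
    fold_change = np.exp2(np.abs(log2fc))

    if cfg.adjust == "BH":
        q = multipletests(p, method="fdr_bh")[1]
        gate_p = q
    else:
        q = np.full_like(p, np.nan)
        gate_p = p

    passing = (fold_change > cfg.fc_threshold) & (gate_p < cfg.p_threshold)
    direction = np.where(passing & (log2fc > 0), "up", np.where(passing & (log2fc < 0), "down", "ns"))

    out = pd.DataFrame(
        {
            "gene_id": matrix.index,
            "mean_tumor": mean_t - cfg.pseudocount,
            "mean_normal": mean_n - cfg.pseudocount,
            "fold_change": fold_change,
            "log2fc": log2fc,
            "t_stat": t,
            "p": p,
            "q": q,
            "direction": direction,
        }
    ).reset_index(drop=True)
    n_up = int((out["direction"] == "up").sum())
    n_down = int((out["direction"] == "down").sum())
    logger.info("run_de: %d genes tested, %d up, %d down", len(out), n_up, n_down)
    return out


def de_gene_sets(de_table: pd.DataFrame) -> dict[str, set[str]]:
    """Split a DE table into {'up': ..., 'down': ..., 'all': ...} id sets."""
    up = set(de_table.loc[de_table["direction"] == "up", "gene_id"])
    down = set(de_table.loc[de_table["direction"] == "down", "gene_id"])
    return {"up": up, "down": down, "all": up | down}
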