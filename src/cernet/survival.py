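"""Survival stratification of tumor samples by module expression.

For each module, tumor samples are split into two groups by k-means (k=2)
on per-gene z-scored log2 abundance of the module RNAs, and the two
survival curves are compared with the log-rank test.  Module expression is
additionally compared between tumor and normal samples with a Wilcoxon
rank-sum test, matching the usual check that a prognostic module is itself
dysregulated.

Kaplan-Meier estimation and the log-rank statistic are delegated to
lifelines; the rank-sum test uses the exact null distribution for small
samples (combined n <= 20, no ties) and the tie-corrected normal
approximation otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from sklearn.cluster import KMeans

from .io import ExpressionBundle
from .modules import Module

logger = logging.getLogger("cernet")


@dataclass
class Stratification:
    module_id: str
    labels: pd.Series  # sample_id -> group in {1, 2}
    group_sizes: dict[int, int]
    chi_square: float
    p_logrank: float
    km_curves: dict[int, pd.DataFrame]  # group -> columns (time, survival)


def _module_score_matrix(
    module_nodes: list[str], bundle: ExpressionBundle, sample_ids: list[str], pseudocount: float = 0.01
) -> pd.DataFrame:
    """log2 abundance of the module RNAs, samples x genes."""
    stacked = bundle.stacked()
    missing = [g for g in module_nodes if g not in stacked.index]
    if missing:
        raise KeyError(f"module RNAs absent from expression matrices: {missing}")
    sub = stacked.loc[sorted(module_nodes), sample_ids]
    return np.log2(sub + pseudocount).T


def kmeans_stratify(features: pd.DataFrame, seed: int = 0) -> pd.Series:
    """Two-group k-means labels, canonicalized.

    ``features`` is samples x genes (log2 abundance); each gene is z-scored
    before clustering so no single high-abundance RNA dominates the
    distance.  Ten restarts from a seeded k-means++ initialization keep the
    result reproducible; group 1 is the cluster with the higher mean module
    expression.
    """
    if len(features) < 2:
        raise ValueError("k-means stratification needs >= 2 samples")
    x = features.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    raw = km.fit_predict(z)
    # canonical orientation: group 1 = higher mean log2 module expression
    mean_expr = features.mean(axis=1).to_numpy()
    if mean_expr[raw == 0].mean() >= mean_expr[raw == 1].mean():
        labels = np.where(raw == 0, 1, 2)
    else:
        labels = np.where(raw == 1, 1, 2)
    return pd.Series(labels, index=features.index, name="group")


def km_estimator(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve as a (time, survival) step table.

    Starts at S(0) = 1; censored observations reduce the risk set without
    introducing a step.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("km_estimator requires at least one observation")
    if (times < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()})


def logrank_test(times, events, labels) -> tuple[float, float]:
    """Two-group log-rank test: (chi_square, p) with 1 degree of freedom."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"log-rank requires exactly 2 groups, got {len(groups)}")
    if events.sum() == 0:
        raise ValueError("log-rank statistic undefined with zero events")
    a, b = labels == groups[0], labels == groups[1]
    res = _ll_logrank(times[a], times[b], event_observed_A=events[a], event_observed_B=events[b])
    return float(res.test_statistic), float(res.p_value)


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact p for combined n <= 20 without ties, tie-corrected normal
    approximation otherwise.  Returns (U of the first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def stratify_module(
    module: Module,
    bundle: ExpressionBundle,
    samples: pd.DataFrame,
    seed: int = 0,
    pseudocount: float = 0.01,
) -> Stratification:
    """k-means split of tumor samples on module expression + log-rank test."""
    tumor = samples.loc[samples["condition"] == "tumor"].copy()
    usable = tumor.dropna(subset=["survival_days", "event"])
    n_dropped = len(tumor) - len(usable)
    if n_dropped:
        logger.info("stratify_module %s: excluded %d samples lacking survival", module.module_id, n_dropped)
    sample_ids = [s for s in bundle.sample_ids if s in set(usable["sample_id"])]
    feats = _module_score_matrix(sorted(module.nodes), bundle, sample_ids, pseudocount)
    labels = kmeans_stratify(feats, seed=seed)

    meta = usable.set_index("sample_id").loc[sample_ids]
    chi2, p = logrank_test(
        meta["survival_days"].to_numpy(), meta["event"].to_numpy(int), labels.to_numpy()
    )
    curves = {}
    for grp in (1, 2):
        mask = labels.to_numpy() == grp
        curves[grp] = km_estimator(
            meta["survival_days"].to_numpy()[mask], meta["event"].to_numpy(int)[mask]
        )
    sizes = {1: int((labels == 1).sum()), 2: int((labels == 2).sum())}
    return Stratification(
        module_id=module.module_id,
        labels=labels,
        group_sizes=sizes,
        chi_square=chi2,
        p_logrank=p,
        km_curves=curves,
    )


def module_expression_test(
    module: Module,
    bundle: ExpressionBundle,
    samples: pd.DataFrame,
    pseudocount: float = 0.01,
) -> tuple[float, float, str]:
    """Rank-sum test of per-sample module score, tumor vs normal.

    The module score is the mean log2(x + pseudocount) over module RNAs;
    direction is the sign of the tumor-minus-normal median difference.
    """
    cond = samples.set_index("sample_id")["condition"]
    tumor_ids = [s for s in bundle.sample_ids if cond.get(s) == "tumor"]
    normal_ids = [s for s in bundle.sample_ids if cond.get(s) == "normal"]
    if not tumor_ids or not normal_ids:
        raise ValueError("both conditions required for the module expression test")
    feats = _module_score_matrix(sorted(module.nodes), bundle, tumor_ids + normal_ids, pseudocount)
    score = feats.mean(axis=1)
    xt, xn = score.loc[tumor_ids].to_numpy(), score.loc[normal_ids].to_numpy()
    u, p = rank_sum_test(xt, xn)
    med_diff = float(np.median(xt) - np.median(xn))
    direction = "up" if med_diff > 0 else ("down" if med_diff < 0 else "none")
    return u, p, direction
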