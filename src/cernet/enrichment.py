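"""Gene-set machinery: co-expression annotation, over-representation,
preranked GSEA and single-sample GSEA (ssGSEA) scoring.

Non-coding RNAs carry no direct functional annotation, so they are
annotated by proxy: the mRNAs most co-expressed with an ncRNA set (top-N
by average Pearson r) are handed to the set-based tests.  The
over-representation test is the hypergeometric upper tail with
Benjamini-Hochberg adjustment across a collection.  Preranked GSEA follows
the classic weighted Kolmogorov-Smirnov running sum with a gene-label
permutation null.  ssGSEA produces one enrichment score per gene set and
sample from within-sample expression ranks, so scores are invariant to any
within-sample monotone transform of expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection
from .survival import rank_sum_test


@dataclass
class EnrichmentResult:
    set_name: str
    k: int  # overlap
    K: int  # set size (within universe)
    n: int  # query size
    N: int  # universe size
    p: float
    q: float = float("nan")
    es: float = float("nan")
    nes: float = float("nan")
    p_perm: float = float("nan")


# ---------------------------------------------------------------------------
# Co-expression annotation of ncRNAs


def coexpression_partners(
    ncrna_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    top_n: int = 500,
    absolute: bool = False,
) -> pd.Series:
    """Top mRNAs by average Pearson correlation with a set of ncRNAs.

    Both matrices are genes x samples over identical sample columns; the
    ncRNA matrix holds the ncRNAs of interest.  Returns a Series mapping
    the top ``top_n`` mRNA ids to their average r, descending (ties broken
    lexicographically).  Constant rows are dropped with a warning.  When
    fewer than ``top_n`` mRNAs are available, all are returned.
    """
    if list(ncrna_expr.columns) != list(mrna_expr.columns):
        raise ValueError("ncRNA and mRNA matrices must share sample columns")
    if ncrna_expr.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation")

    def _drop_constant(m: pd.DataFrame, name: str) -> pd.DataFrame:
        keep = m.std(axis=1, ddof=0) > 0
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} constant {name} rows", stacklevel=2)
        return m.loc[keep]

    ncrna_expr = _drop_constant(ncrna_expr, "ncRNA")
    mrna_expr = _drop_constant(mrna_expr, "mRNA")

    a = ncrna_expr.to_numpy(dtype=float)
    b = mrna_expr.to_numpy(dtype=float)
    a = (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)
    b = (b - b.mean(axis=1, keepdims=True)) / b.std(axis=1, keepdims=True)
    r = a @ b.T / a.shape[1]  # ncRNA x mRNA correlation matrix
    avg = r.mean(axis=0)
    if absolute:
        avg_rank = np.abs(avg)
    else:
        avg_rank = avg
    order = sorted(range(len(avg)), key=lambda i: (-avg_rank[i], mrna_expr.index[i]))
    if len(order) < top_n:
        warnings.warn(
            f"only {len(order)} mRNAs available for top_n={top_n}", stacklevel=2
        )
    top = order[:top_n]
    return pd.Series(avg[top], index=mrna_expr.index[top], name="avg_r")


# ---------------------------------------------------------------------------
# Over-representation (hypergeometric)


def ora_hypergeometric(query: set[str], gene_set: set[str], universe: set[str]) -> EnrichmentResult:
    """Hypergeometric upper-tail over-representation test.

    p = P(X >= k) for X ~ Hypergeom(N, K, n) where N is the universe size,
    K the gene-set size within the universe, n the query size and k the
    observed overlap.
    """
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    gs = gene_set & universe
    k = len(query & gs)
    K, n, N = len(gs), len(query), len(universe)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(set_name="", k=k, K=K, n=n, N=N, p=min(p, 1.0))


def ora_collection(
    query: set[str], collection: GeneSetCollection, universe: set[str]
) -> pd.DataFrame:
    """ORA across a whole collection with BH adjustment."""
    rows = []
    for name in collection.names():
        res = ora_hypergeometric(query, collection[name], universe)
        rows.append((name, res.k, res.K, res.n, res.N, res.p))
    out = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Preranked GSEA


def _running_es(is_member: np.ndarray, weights: np.ndarray) -> float:
    """Signed maximum deviation of the weighted KS running sum."""
    w = np.abs(weights) * is_member
    denom_in = w.sum()
    if denom_in == 0:
        # all member weights zero: fall back to unweighted increments
        w = is_member.astype(float)
        denom_in = w.sum()
    n_out = (~is_member.astype(bool)).sum()
    step = w / denom_in - (~is_member.astype(bool)) / max(n_out, 1)
    running = np.cumsum(step)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def preranked_gsea(
    ranked_genes: list[str],
    weights,
    gene_set: set[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Preranked GSEA for one gene set.

    ``ranked_genes`` is the full gene list ordered by the ranking metric
    (best first) with one weight per gene (e.g. log2 fold change).  The
    enrichment score is the maximum deviation of the running sum that adds
    |weight| (normalized over members) at members and subtracts 1/(N-K) at
    non-members.  The null is a gene-label permutation; p_perm counts
    same-sign null scores at least as extreme, with the +1 smoothing, and
    NES divides ES by the mean |null ES| of the same sign.
    """
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(ranked_genes):
        raise ValueError("one weight per ranked gene required")
    if not np.isfinite(weights).all():
        raise ValueError("weights must be finite")
    is_member = np.array([g in gene_set for g in ranked_genes])
    k = int(is_member.sum())
    if k == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    es = _running_es(is_member, weights)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    idx = np.arange(len(ranked_genes))
    for b in range(n_perm):
        perm = rng.permutation(idx)
        null[b] = _running_es(is_member[perm], weights)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    n_extreme = int((np.abs(same_sign) >= abs(es)).sum())
    p_perm = (1 + n_extreme) / (1 + n_perm)
    mean_null = float(np.mean(np.abs(same_sign))) if len(same_sign) else float("nan")
    nes = es / mean_null if mean_null and np.isfinite(mean_null) else float("nan")
    return EnrichmentResult(
        set_name="",
        k=k,
        K=len(gene_set),
        n=len(ranked_genes),
        N=len(ranked_genes),
        p=p_perm,
        es=es,
        nes=nes,
        p_perm=p_perm,
    )


# ---------------------------------------------------------------------------
# ssGSEA


def _ssgsea_sample_es(order: np.ndarray, ranks: np.ndarray, member_mask: np.ndarray, tau: float) -> float:
    """ssGSEA enrichment score for one sample.

    ``order`` indexes genes by descending expression; ``ranks`` are the
    (tie-averaged) descending ranks converted to weights N..1; the score is
    the sum over the whole walk of the weighted in-set cumulative fraction
    minus the out-of-set cumulative fraction.
    """
    n = len(order)
    member = member_mask[order]
    w = ranks[order] ** tau
    w_in = np.where(member, w, 0.0)
    denom_in = w_in.sum()
    p_in = np.cumsum(w_in) / denom_in
    n_out = n - member.sum()
    p_out = np.cumsum(~member) / max(n_out, 1)
    return float(np.sum(p_in - p_out))


def ssgsea_scores(
    expr: pd.DataFrame,
    sets: GeneSetCollection,
    tau: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """Single-sample GSEA score matrix (gene sets x samples).

    Per sample, genes are ranked by expression descending (average ranks
    for ties); the enrichment score accumulates the |rank|^tau-weighted
    cumulative fraction of set members minus the unweighted cumulative
    fraction of non-members over the full ranked list.  With ``normalize``,
    all scores are divided by the overall score range (max - min), the
    customary ssGSEA normalization.  Sets with no expressed member yield a
    NaN row with a warning.
    """
    genes = list(expr.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    values = expr.to_numpy(dtype=float)
    # descending tie-averaged ranks: highest expression -> rank n
    asc = stats.rankdata(values, axis=0)
    ranks = asc  # rank n for the max; used as the ssGSEA weight base

    member_masks: dict[str, np.ndarray] = {}
    for name in sets.names():
        mask = np.zeros(n, dtype=bool)
        hit = [gene_pos[g] for g in sets[name] if g in gene_pos]
        if not hit:
            warnings.warn(f"gene set {name!r} has no expressed member; scores are NaN", stacklevel=2)
            member_masks[name] = mask
            continue
        mask[hit] = True
        member_masks[name] = mask

    scores = np.full((len(sets), expr.shape[1]), np.nan)
    for j in range(expr.shape[1]):
        order = np.argsort(-values[:, j], kind="stable")
        col_ranks = ranks[:, j]
        for i, name in enumerate(sets.names()):
            mask = member_masks[name]
            if mask.any():
                scores[i, j] = _ssgsea_sample_es(order, col_ranks, mask, tau)
    if normalize and np.isfinite(scores).any():
        rng_ = np.nanmax(scores) - np.nanmin(scores)
        if rng_ > 0:
            scores = scores / rng_
    return pd.DataFrame(scores, index=sets.names(), columns=expr.columns)


# ---------------------------------------------------------------------------
# Module-pathway correlation and group comparison


def module_pathway_correlation(
    module_scores: pd.Series, score_matrix: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r and p between a per-sample module score and each gene set.

    ``module_scores`` is indexed by sample; the score matrix is gene sets x
    samples.  Pairs with a constant vector are flagged undefined
    (r = p = NaN) rather than dropped.
    """
    common = [s for s in score_matrix.columns if s in module_scores.index]
    if len(common) < 3:
        raise ValueError("need >= 3 shared samples")
    x = module_scores.loc[common].to_numpy(dtype=float)
    rows = []
    for name in score_matrix.index:
        y = score_matrix.loc[name, common].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0 or np.isnan(y).any():
            rows.append((name, np.nan, np.nan, False))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((name, float(r), float(p), True))
    return pd.DataFrame(rows, columns=["set_name", "r", "p", "defined"])


def rna_pathway_correlation(
    expr: pd.DataFrame, score_matrix: pd.DataFrame, pseudocount: float = 0.01
) -> pd.DataFrame:
    """Per-RNA version: correlation of each gene's log2 abundance with each set score."""
    rows = []
    for gene in expr.index:
        g = np.log2(expr.loc[gene] + pseudocount)
        tab = module_pathway_correlation(g, score_matrix)
        tab.insert(0, "gene_id", gene)
        rows.append(tab)
    return pd.concat(rows, ignore_index=True)


def compare_group_scores(score_matrix: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Two-sided rank-sum test per gene set between two sample groups.

    ``labels`` maps sample id to one of exactly two group labels; returns a
    table (set_name, statistic, p, q) with BH adjustment across sets.
    """
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    ids_a = [s for s in score_matrix.columns if labels.get(s) == groups[0]]
    ids_b = [s for s in score_matrix.columns if labels.get(s) == groups[1]]
    if not ids_a or not ids_b:
        raise ValueError("one group has no samples in the score matrix")
    rows = []
    for name in score_matrix.index:
        u, p = rank_sum_test(
            score_matrix.loc[name, ids_a].to_numpy(dtype=float),
            score_matrix.loc[name, ids_b].to_numpy(dtype=float),
        )
        rows.append((name, u, p))
    out = pd.DataFrame(rows, columns=["set_name", "statistic", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
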