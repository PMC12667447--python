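"""Differential expression of a gene signature between two sample classes.

The per-gene test is a two-sided Wilcoxon rank-sum on log2 values: exact
(full enumeration of rank assignments, midranks for ties) when the pooled
sample size is at most 20, otherwise the normal approximation with tie
correction.  Log2 fold change is class2 minus class1 group means.  The
volcano call uses raw p < alpha and |log2FC| >= fc_min by default, with
Benjamini-Hochberg q-values reported alongside (and usable as the gate in
strict-FDR mode).  Welch's t-test is available behind a switch.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, GeneSet

EXACT_MAX_N = 20  # pooled size at or below which the rank-sum test is exact


@dataclass
class DEResult:
    """Per-gene differential-expression outcome.

    ``log2fc`` is class2 minus class1 mean (log2 units); ``direction`` is
    up/down only when the gene passes the volcano thresholds, else ns.
    """

    gene: str
    log2fc: float
    p: float
    q: float
    direction: Literal["up", "down", "ns"]
    n1: int
    n2: int


@dataclass
class CorrelationMap:
    gene_ids: list[str]
    r_matrix: np.ndarray
    method: Literal["pearson", "spearman"]


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def _exact_ranksum_p(ranks: np.ndarray, n1: int) -> float:
    """Two-sided exact rank-sum p by full enumeration of group assignments.

    With midrank scores the permutation distribution of the group-2 rank sum
    is enumerated over all C(N, n2) assignments; the two-sided p is
    2 * min(P(W <= w), P(W >= w)) capped at 1.
    """
    n = len(ranks)
    n2 = n - n1
    w_obs = float(ranks[n1:].sum())
    le = ge = total = 0
    eps = 1e-9
    for idx in combinations(range(n), n2):
        w = float(ranks[list(idx)].sum())
        total += 1
        if w <= w_obs + eps:
            le += 1
        if w >= w_obs - eps:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def _approx_ranksum_p(ranks: np.ndarray, n1: int) -> float:
    """Normal approximation with tie correction for the rank-sum statistic."""
    n = len(ranks)
    n2 = n - n1
    w = ranks[n1:].sum()
    mu = n2 * (n + 1) / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (w - mu) / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def test_gene(
    x1: Sequence[float],
    x2: Sequence[float],
    test: Literal["wilcoxon", "welch"] = "wilcoxon",
) -> tuple[float, float]:
    """Test one gene between two groups; returns (log2fc, p).

    ``log2fc = mean(x2) - mean(x1)``.  Missing values (NaN) are dropped;
    each group must retain at least 2 observations.
    """
    a = np.asarray(x1, dtype=float)
    b = np.asarray(x2, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 non-missing values")
    log2fc = float(b.mean() - a.mean())
    if test == "welch":
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            return log2fc, 1.0
        p = float(stats.ttest_ind(b, a, equal_var=False).pvalue)
        return log2fc, p
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    if len(pooled) <= EXACT_MAX_N:
        p = _exact_ranksum_p(ranks, len(a))
    else:
        p = _approx_ranksum_p(ranks, len(a))
    return log2fc, p


def bh_adjust(p_vector: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(p_vector, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _call_direction(
    log2fc: float, gate_p: float, alpha: float, fc_min: float
) -> Literal["up", "down", "ns"]:
    if gate_p < alpha and abs(log2fc) >= fc_min:
        return "up" if log2fc > 0 else "down"
    return "ns"


def signature_screen(
    expr: ExpressionMatrix,
    gene_set: GeneSet,
    alpha: float = 0.05,
    fc_min: float = 1.0,
    adjust: Literal["raw", "bh"] = "raw",
    class_order: Sequence[str] | None = None,
    test: Literal["wilcoxon", "welch"] = "wilcoxon",
) -> tuple[list[DEResult], list[str]]:
    """Screen a gene set for differential expression between two classes.

    Returns (results, unmeasured): one DEResult per signature gene present
    in the matrix, plus the signature genes absent from it.  ``class_order``
    fixes (class1, class2); by default classes are taken in first-appearance
    order so log2fc is class2 - class1.  ``adjust="raw"`` gates the
    direction call on raw p (the volcano dialect); ``"bh"`` gates on q.
    """
    groups = expr.classes()
    if class_order is None:
        class_order = list(groups)
    if len(class_order) != 2 or any(c not in groups for c in class_order):
        raise ValueError(f"need exactly 2 classes, have {list(groups)}")
    c1, c2 = class_order
    if not groups[c1] or not groups[c2]:
        raise ValueError("one class is empty")
    cols1, cols2 = groups[c1], groups[c2]

    present = [g for g in gene_set.genes if g in expr.data.index]
    unmeasured = [g for g in gene_set.genes if g not in expr.data.index]

    rows: list[tuple[str, float, float, int, int]] = []
    for g in present:
        x1 = expr.data.loc[g, cols1].to_numpy(dtype=float)
        x2 = expr.data.loc[g, cols2].to_numpy(dtype=float)
        try:
            log2fc, p = test_gene(x1, x2, test=test)
        except ValueError as exc:
            warnings.warn(f"gene {g}: {exc}", stacklevel=2)
            continue
        n1 = int(np.sum(~np.isnan(x1)))
        n2 = int(np.sum(~np.isnan(x2)))
        rows.append((g, log2fc, p, n1, n2))

    qs = bh_adjust([r[2] for r in rows]) if rows else np.array([])
    results = []
    for (g, log2fc, p, n1, n2), q in zip(rows, qs):
        gate = p if adjust == "raw" else q
        results.append(
            DEResult(g, log2fc, p, float(q), _call_direction(log2fc, gate, alpha, fc_min), n1, n2)
        )
    return results, unmeasured


def availability_filter(
    gene_list: Iterable[str], panel_expr: ExpressionMatrix
) -> tuple[list[str], list[str]]:
    """Split genes into (kept, dropped) by presence in the panel matrix."""
    rows = set(panel_expr.data.index)
    kept, dropped = [], []
    for g in gene_list:
        (kept if g in rows else dropped).append(g)
    return kept, dropped


def contrast_overlap(
    de_sets: Mapping[str, Iterable[str]],
) -> tuple[pd.DataFrame, dict[tuple[str, ...], int]]:
    """Membership table and per-region counts across named DE gene sets.

    Regions are keyed by the sorted tuple of set names containing the gene
    (the Venn-region decomposition over all combinations).
    """
    names = list(de_sets)
    if len(names) < 2:
        raise ValueError("need >= 2 named DE sets")
    sets = {k: set(v) for k, v in de_sets.items()}
    universe = sorted(set().union(*sets.values()))
    table = pd.DataFrame(
        {k: [g in sets[k] for g in universe] for k in names},
        index=pd.Index(universe, name="gene"),
    )
    regions: dict[tuple[str, ...], int] = {}
    for g in universe:
        key = tuple(sorted(k for k in names if g in sets[k]))
        regions[key] = regions.get(key, 0) + 1
    return table, regions


def coexpression(
    expr: ExpressionMatrix,
    gene_set: GeneSet,
    method: Literal["pearson", "spearman"] = "pearson",
) -> CorrelationMap:
    """Pairwise gene-gene correlation over samples, pairwise-complete.

    Zero-variance genes yield missing correlations with a warning.
    """
    present = [g for g in gene_set.genes if g in expr.data.index]
    if len(present) < 2:
        raise ValueError("need >= 2 signature genes present")
    if expr.data.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    sub = expr.data.loc[present].T  # samples x genes
    flat = sub.std(ddof=0)
    zero_var = list(flat.index[flat == 0])
    if zero_var:
        warnings.warn(f"zero-variance genes, correlations set missing: {zero_var}",
                      stacklevel=2)
    r = sub.corr(method=method, min_periods=2)
    np.fill_diagonal(r.values, 1.0)
    for g in zero_var:
        r.loc[g, :] = np.nan
        r.loc[:, g] = np.nan
        r.loc[g, g] = np.nan
    return CorrelationMap(present, r.to_numpy(), method)


def results_to_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    """Tabular export: gene, n1, n2, log2fc (class2 - class1), p, q, direction."""
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "n1": r.n1,
                "n2": r.n2,
                "log2fc": r.log2fc,
                "p": r.p,
                "q": r.q,
                "direction": r.direction,
            }
            for r in results
        ]
    )
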