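"""Candidate-drug funnel over a cell-line panel.

Drugs are first filtered to those with a curated chemical-gene link to at
least one signature regulator; each surviving (drug, regulator) catalog
pair is then tested for Pearson correlation between the drug's
replicate-averaged activity z-score and the regulator's expression across
the panel.  The activity z-score convention is higher = more sensitive
(lower IC50), so all reporting uses ``r_ic50 = -r``: a negative r_ic50
means high expression sensitizes cells to the drug.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import DrugActivityPanel, ExpressionMatrix, InteractionCatalog
from .signature_deg import bh_adjust

DEFAULT_MIN_LINES = 10  # Pearson p is unstable below this panel size


@dataclass
class GeneDrugEdge:
    """Signed, tested correlation between a drug and a gene across the panel.

    ``r`` is on the activity scale (sensitivity); ``r_ic50 = -r`` is the
    reported IC50-scale correlation (negative = sensitizing); ``sign`` is
    the sign of r_ic50.
    """

    gene: str
    drug: str
    r: float
    p: float
    n: int

    @property
    def r_ic50(self) -> float:
        return -self.r

    @property
    def sign(self) -> Literal["positive", "negative"]:
        return "negative" if self.r_ic50 < 0 else "positive"


def mean_activity(
    replicates: Mapping[str, Sequence[pd.DataFrame]] | Sequence[pd.DataFrame] | np.ndarray,
    drug_ids: Sequence[str] | None = None,
    cell_line_ids: Sequence[str] | None = None,
) -> DrugActivityPanel:
    """Average per-drug replicate activity measurements into one panel.

    Accepts a replicate-axis stack: either a 3-D array (replicate x drug x
    cell line) with explicit ids, or a sequence of aligned drugs-x-lines
    DataFrames.  Missing replicates are ignored; a drug with zero
    measurements anywhere is dropped with a warning.  Replicate counts per
    cell are stored on the panel.
    """
    if isinstance(replicates, np.ndarray):
        if drug_ids is None or cell_line_ids is None:
            raise ValueError("array input requires drug_ids and cell_line_ids")
        stack = [pd.DataFrame(r, index=drug_ids, columns=cell_line_ids)
                 for r in replicates]
    else:
        stack = list(replicates)
        if not stack:
            raise ValueError("no replicate tables given")
        for r in stack[1:]:
            if not (r.index.equals(stack[0].index) and r.columns.equals(stack[0].columns)):
                raise ValueError("replicate tables must share drug/cell-line axes")
    arr = np.stack([r.to_numpy(dtype=float) for r in stack])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(arr, axis=0)
    counts = np.sum(~np.isnan(arr), axis=0)
    idx, cols = stack[0].index, stack[0].columns
    empty = [str(d) for d, c in zip(idx, counts.sum(axis=1)) if c == 0]
    if empty:
        warnings.warn(f"drugs with zero measurements dropped: {empty}", stacklevel=2)
        keep = counts.sum(axis=1) > 0
        mean, counts = mean[keep], counts[keep]
        idx = idx[keep]
    return DrugActivityPanel(
        pd.DataFrame(mean, index=idx, columns=cols),
        pd.DataFrame(counts, index=idx, columns=cols),
    )


def catalog_filter(
    drugs: Iterable[str], catalog: InteractionCatalog, regulators: Iterable[str]
) -> list[str]:
    """Keep drugs whose catalog gene set intersects the regulator set."""
    regs = {r.upper() for r in regulators}
    return [d for d in drugs if catalog.genes_for(d) & regs]


def correlate_drug_gene(
    panel: DrugActivityPanel,
    expr: ExpressionMatrix,
    drug: str,
    gene: str,
    min_lines: int = DEFAULT_MIN_LINES,
    method: Literal["pearson", "spearman"] = "pearson",
) -> GeneDrugEdge | None:
    """Correlate one drug's activity with one gene's expression.

    Pairwise-complete over shared cell lines; two-sided t-distribution p
    with n-2 df.  Returns None (edge rejected) when fewer than ``min_lines``
    complete pairs remain or either vector has zero variance.
    """
    shared = [c for c in panel.cell_line_ids if c in set(expr.sample_ids)]
    a = panel.activity.loc[drug, shared].to_numpy(dtype=float)
    x = expr.data.loc[gene, shared].to_numpy(dtype=float)
    ok = ~(np.isnan(a) | np.isnan(x))
    a, x = a[ok], x[ok]
    n = len(a)
    if n < min_lines:
        return None
    if np.ptp(a) == 0 or np.ptp(x) == 0:
        return None
    if method == "spearman":
        r, p = stats.spearmanr(a, x)
        return GeneDrugEdge(gene, drug, float(r), float(p), n)
    r = float(np.corrcoef(a, x)[0, 1])
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return GeneDrugEdge(gene, drug, r, p, n)


@dataclass
class ScreenResult:
    edges: list[GeneDrugEdge]  # all tested edges (catalog pairs)
    significant_edges: list[GeneDrugEdge]
    candidate_drugs: list[str]
    funnel: dict[str, int]  # input drugs -> catalog-kept -> significant


def screen(
    panel: DrugActivityPanel,
    expr: ExpressionMatrix,
    catalog: InteractionCatalog,
    regulators: Sequence[str],
    alpha: float = 0.05,
    min_lines: int = DEFAULT_MIN_LINES,
    adjust: Literal["raw", "bh"] = "raw",
    method: Literal["pearson", "spearman"] = "pearson",
) -> ScreenResult:
    """Run the full drug funnel: catalog filter then correlation screen.

    Only (drug, regulator) pairs present in the catalog are tested.
    Candidate drugs carry at least one edge significant at ``alpha``
    (raw per-pair p by default; BH-adjusted across all tested edges in
    ``adjust="bh"`` mode).
    """
    regs = [r.upper() for r in regulators]
    if not regs:
        raise ValueError("empty regulator set")
    measurable = [r for r in regs if r in set(expr.data.index)]
    kept_drugs = catalog_filter(panel.drug_ids, catalog, measurable)

    edges: list[GeneDrugEdge] = []
    for d in kept_drugs:
        for g in measurable:
            if g not in catalog.genes_for(d):
                continue
            edge = correlate_drug_gene(panel, expr, d, g, min_lines, method)
            if edge is not None:
                edges.append(edge)

    if adjust == "bh" and edges:
        qs = bh_adjust([e.p for e in edges])
        gate = {id(e): q for e, q in zip(edges, qs)}
        sig = [e for e in edges if gate[id(e)] < alpha]
    else:
        sig = [e for e in edges if e.p < alpha]
    candidates = sorted({e.drug for e in sig})
    funnel = {
        "input_drugs": len(panel.drug_ids),
        "catalog_kept": len(kept_drugs),
        "tested_edges": len(edges),
        "significant_edges": len(sig),
        "candidate_drugs": len(candidates),
    }
    return ScreenResult(edges, sig, candidates, funnel)


def edges_to_frame(edges: Sequence[GeneDrugEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "drug": e.drug,
                "gene": e.gene,
                "r_ic50": e.r_ic50,
                "p": e.p,
                "n": e.n,
                "sign": e.sign,
            }
            for e in edges
        ]
    )
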