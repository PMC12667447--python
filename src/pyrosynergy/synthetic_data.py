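"""Synthetic-world generators with planted ground truth.

Every input the screening funnel consumes can be generated here: a
tumor/normal cohort with planted differentially expressed genes and
proportional-hazards survival, a cell-line panel with planted
expression-activity correlations plus a chemical-gene link catalog, a
two-condition perturbation experiment, and 4PL dose-response curves.  The
truth object returned alongside each dataset records what was planted, so
every downstream stage can be scored for recovery without external data.

Defaults emulate the study conditions the pipeline was designed around: a
cohort of 169 tumors vs 36 normals over a 238-gene signature with 28
planted DE genes at |log2FC| = 2 and noise SD 0.5; a 60-cell-line panel
with ~2,000 drugs; 5-replicate perturbation arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_formats import (
    DrugActivityPanel,
    ExpressionMatrix,
    GeneSet,
    InteractionCatalog,
    SurvivalTable,
)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic world.

    Expression is on the log2 scale throughout; ``de_log2fc`` is the mean
    planted tumor-vs-normal shift, ``noise_sd`` the per-gene log2 noise SD.
    ``risk_betas`` are log-hazard increments per log2-expression unit for
    the planted risk genes; ``baseline_hazard`` is in events/month.
    ``planted_corr`` is the population Pearson correlation between a planted
    drug's activity z-score and its target gene's expression (positive =
    higher expression, more sensitive).
    """

    seed: int = 0
    n_tumor: int = 169
    n_normal: int = 36
    n_genes: int = 238
    de_fraction: float = 28 / 238
    de_log2fc: float = 2.0
    noise_sd: float = 0.5
    n_risk_genes: int = 5
    risk_betas: tuple[float, ...] | None = None  # default: +/-0.7 alternating
    baseline_hazard: float = 0.01
    censor_rate: float = 0.2
    n_cell_lines: int = 60
    n_drugs: int = 2000
    planted_corr: float = 0.9
    corr_fraction: float = 94 / 2000
    perturb_log2fc: float = 2.0
    perturb_replicates: int = 5
    catalog_link_prob: float = 0.05

    def __post_init__(self) -> None:
        for name in ("de_fraction", "corr_fraction", "censor_rate",
                     "catalog_link_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not abs(self.planted_corr) < 1.0:
            raise ValueError("|planted_corr| must be < 1")
        for name in ("n_tumor", "n_normal", "n_genes", "n_cell_lines",
                     "n_drugs", "perturb_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_risk_genes > self.n_genes:
            raise ValueError("n_risk_genes > n_genes")


@dataclass
class CohortTruth:
    de_genes: list[str]
    de_directions: dict[str, str]  # gene -> up|down (tumor vs normal)
    risk_genes: list[str]
    risk_betas: dict[str, float]
    censor_hazard: float


@dataclass
class PanelTruth:
    planted_pairs: list[tuple[str, str, float]]  # (drug, gene, rho)
    planted_drugs: list[str]
    withheld_genes: list[str]


@dataclass
class PerturbationTruth:
    directions: dict[str, str]  # gene -> up|down|ns
    log2fc: dict[str, float]


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def gen_cohort(
    config: SyntheticConfig,
    gene_set: GeneSet | None = None,
) -> tuple[ExpressionMatrix, SurvivalTable, CohortTruth]:
    """Generate a two-class cohort with planted DE genes and PH survival.

    Per gene, log2 expression ~ Normal(baseline, noise_sd); a de_fraction
    subset is shifted by +/-de_log2fc in tumors.  Survival times follow an
    exponential proportional-hazards model whose linear predictor sums
    ``risk_betas`` over the centered expression of ``n_risk_genes`` genes
    drawn from the planted DE set (falling back to non-DE genes if the DE
    set is smaller).  Independent exponential censoring is tuned so the
    expected censored fraction equals ``censor_rate``.
    """
    rng = np.random.default_rng(config.seed)
    genes = list(gene_set.genes) if gene_set is not None else _gene_names(config.n_genes)
    if len(genes) != config.n_genes:
        raise ValueError("gene_set size must equal config.n_genes")
    n_t, n_n = config.n_tumor, config.n_normal
    samples = [f"T{i:04d}" for i in range(1, n_t + 1)] + [
        f"N{i:04d}" for i in range(1, n_n + 1)
    ]
    classes = dict(zip(samples, ["tumor"] * n_t + ["normal"] * n_n))

    baselines = rng.normal(8.0, 1.0, size=config.n_genes)
    values = rng.normal(
        baselines[:, None], config.noise_sd, size=(config.n_genes, n_t + n_n)
    )

    n_de = int(round(config.de_fraction * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    signs = rng.choice([1.0, -1.0], size=n_de)
    values[de_idx, :n_t] += signs[:, None] * config.de_log2fc
    de_genes = [genes[i] for i in de_idx]
    de_dirs = {
        genes[i]: ("up" if s > 0 else "down") for i, s in zip(de_idx, signs)
    }

    # survival tied to a subset of the planted DE genes
    k = config.n_risk_genes
    risk_pool = list(de_idx) + [i for i in range(config.n_genes) if i not in set(de_idx)]
    risk_idx = np.array(risk_pool[:k], dtype=int)
    if config.risk_betas is not None:
        betas = np.asarray(config.risk_betas, dtype=float)
        if betas.shape != (k,):
            raise ValueError("risk_betas length must equal n_risk_genes")
    else:
        betas = 0.7 * np.array([1.0 if j % 2 == 0 else -1.0 for j in range(k)])

    tumor_expr = values[:, :n_t]
    centered = tumor_expr[risk_idx] - tumor_expr[risk_idx].mean(axis=1, keepdims=True)
    lp = betas @ centered
    rates = config.baseline_hazard * np.exp(lp)
    event_times = rng.exponential(1.0 / rates)

    # censoring hazard c solving mean_i c/(c+rate_i) = censor_rate
    if config.censor_rate <= 0:
        c_haz = 0.0
        censor_times = np.full(n_t, np.inf)
    else:
        def frac(c: float) -> float:
            return float(np.mean(c / (c + rates))) - config.censor_rate

        hi = rates.max() * 1e6
        c_haz = brentq(frac, 1e-12, hi)
        censor_times = rng.exponential(1.0 / c_haz, size=n_t)
    time = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), classes, "log2"
    )
    surv = SurvivalTable(
        pd.DataFrame(
            {"time": time, "event": event},
            index=pd.Index(samples[:n_t], name="sample"),
        )
    )
    truth = CohortTruth(
        de_genes=de_genes,
        de_directions=de_dirs,
        risk_genes=[genes[i] for i in risk_idx],
        risk_betas={genes[i]: float(b) for i, b in zip(risk_idx, betas)},
        censor_hazard=float(c_haz),
    )
    return expr, surv, truth


def gen_panel(
    config: SyntheticConfig,
    gene_set: GeneSet,
    withheld_genes: Sequence[str] = (),
    synergy_genes: Sequence[str] = (),
    n_synergy_drugs: int = 0,
) -> tuple[ExpressionMatrix, DrugActivityPanel, InteractionCatalog, PanelTruth]:
    """Generate a cell-line panel, drug-activity z-scores, and a catalog.

    A ``corr_fraction`` share of drugs is planted: each planted drug's
    activity vector is ``rho * z(expression of its target gene) +
    sqrt(1-rho^2) * noise``, so the population Pearson correlation with the
    target equals ``planted_corr`` (positive: higher expression = more
    sensitive = lower IC50).  The catalog links every drug to each signature
    gene independently with ``catalog_link_prob`` and always contains the
    planted pairs.  ``withheld_genes`` are omitted from the panel expression
    matrix, emulating signature genes unmeasured in the reference panel.

    If ``n_synergy_drugs`` > 0, the first that many planted drugs target
    genes drawn from ``synergy_genes`` (round-robin); the remaining planted
    drugs target other available genes.  This carves out a known set of
    drugs whose sensitizing edges point at perturbation-responsive genes.
    """
    if len(gene_set) == 0:
        raise ValueError("gene_set is empty")
    rng = np.random.default_rng(config.seed + 1)
    withheld = [g.upper() for g in withheld_genes]
    available = [g for g in gene_set.genes if g not in set(withheld)]
    if not available:
        raise ValueError("all signature genes withheld from panel")

    lines = [f"CL{i:02d}" for i in range(1, config.n_cell_lines + 1)]
    expr_vals = rng.normal(0.0, 1.0, size=(len(available), config.n_cell_lines))
    expr = ExpressionMatrix(
        pd.DataFrame(expr_vals, index=available, columns=lines),
        {c: "cell_line" for c in lines},
        "log2",
    )

    drugs = [f"D{i:05d}" for i in range(1, config.n_drugs + 1)]
    n_planted = int(round(config.corr_fraction * config.n_drugs))
    if n_planted < 1 and config.corr_fraction > 0:
        import warnings

        warnings.warn("corr_fraction too small: no planted pairs", stacklevel=2)
    planted_drugs = list(rng.choice(drugs, size=n_planted, replace=False))

    syn = [g for g in synergy_genes if g in set(available)]
    non_syn = [g for g in available if g not in set(syn)]
    targets: list[str] = []
    for j in range(n_planted):
        if j < n_synergy_drugs and syn:
            targets.append(syn[j % len(syn)])
        else:
            pool = non_syn if non_syn else available
            targets.append(pool[int(rng.integers(len(pool)))])

    rho = config.planted_corr
    activity = rng.normal(0.0, 1.0, size=(config.n_drugs, config.n_cell_lines))
    gene_row = {g: i for i, g in enumerate(available)}
    drug_row = {d: i for i, d in enumerate(drugs)}
    planted_pairs: list[tuple[str, str, float]] = []
    for d, g in zip(planted_drugs, targets):
        z = expr_vals[gene_row[g]]
        z = (z - z.mean()) / z.std()
        noise = rng.normal(0.0, 1.0, size=config.n_cell_lines)
        activity[drug_row[d]] = rho * z + np.sqrt(1 - rho**2) * noise
        planted_pairs.append((d, g, rho))

    panel = DrugActivityPanel(pd.DataFrame(activity, index=drugs, columns=lines))

    link_mask = rng.random((config.n_drugs, len(gene_set))) < config.catalog_link_prob
    links: dict[str, set[str]] = {}
    all_genes = list(gene_set.genes)
    for i, d in enumerate(drugs):
        linked = {all_genes[j] for j in np.nonzero(link_mask[i])[0]}
        if linked:
            links[d] = linked
    for d, g, _ in planted_pairs:
        links.setdefault(d, set()).add(g)
    catalog = InteractionCatalog(links, provenance="synthetic")

    truth = PanelTruth(
        planted_pairs=planted_pairs,
        planted_drugs=planted_drugs,
        withheld_genes=withheld,
    )
    return expr, panel, catalog, truth


def gen_perturbation(
    config: SyntheticConfig,
    gene_set: GeneSet,
    planted_directions: dict[str, str] | None = None,
) -> tuple[ExpressionMatrix, PerturbationTruth]:
    """Generate a two-condition (control vs perturbed) replicate experiment.

    ``planted_directions`` maps gene -> "up"|"down" for the genes shifted by
    +/-perturb_log2fc in the perturbed arm; unlisted genes are null ("ns").
    When omitted, half the signature (rounded down) is planted, alternating
    up/down in gene-set order.
    """
    if config.perturb_replicates < 3:
        raise ValueError("perturbation needs >= 3 replicates per condition")
    rng = np.random.default_rng(config.seed + 2)
    genes = list(gene_set.genes)
    if planted_directions is None:
        planted = genes[: len(genes) // 2]
        planted_directions = {
            g: ("up" if i % 2 == 0 else "down") for i, g in enumerate(planted)
        }
    unknown = set(planted_directions) - set(genes)
    if unknown:
        raise ValueError(f"planted genes not in gene set: {sorted(unknown)}")

    n_rep = config.perturb_replicates
    samples = [f"CTRL{i}" for i in range(1, n_rep + 1)] + [
        f"PERT{i}" for i in range(1, n_rep + 1)
    ]
    classes = dict(zip(samples, ["control"] * n_rep + ["perturbed"] * n_rep))
    baselines = rng.normal(8.0, 1.0, size=len(genes))
    values = rng.normal(baselines[:, None], config.noise_sd, size=(len(genes), 2 * n_rep))
    log2fc: dict[str, float] = {}
    directions: dict[str, str] = {}
    for i, g in enumerate(genes):
        d = planted_directions.get(g, "ns")
        directions[g] = d if config.perturb_log2fc != 0 else ("ns" if d == "ns" else "ns")
        shift = {"up": config.perturb_log2fc, "down": -config.perturb_log2fc}.get(d, 0.0)
        if config.perturb_log2fc == 0:
            directions[g] = "ns"
            shift = 0.0
        values[i, n_rep:] += shift
        log2fc[g] = shift
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), classes, "log2"
    )
    return expr, PerturbationTruth(directions=directions, log2fc=log2fc)


def gen_dose_response(
    params: tuple[float, float, float, float],
    doses: Sequence[float],
    noise_sd: float,
    seed: int = 0,
) -> np.ndarray:
    """Generate 4PL viability responses at the given doses.

    ``params`` = (top, bottom, ic50, hill); response(d) = bottom +
    (top - bottom) / (1 + (d / ic50) ** hill) + Normal(0, noise_sd).
    """
    top, bottom, ic50, hill = params
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    if top <= bottom:
        raise ValueError("top must exceed bottom")
    d = np.asarray(doses, dtype=float)
    if (d <= 0).any():
        raise ValueError("doses must be positive")
    if not (np.diff(d) >= 0).all():
        raise ValueError("doses must be sorted ascending")
    rng = np.random.default_rng(seed)
    clean = bottom + (top - bottom) / (1.0 + (d / ic50) ** hill)
    if noise_sd == 0:
        return clean
    return clean + rng.normal(0.0, noise_sd, size=d.shape)
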