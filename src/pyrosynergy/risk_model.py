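"""Proportional-hazards risk modeling over a gene signature.

Fits per-gene Cox models for a hazard-ratio forest, selects a multivariate
model by greedy bidirectional stepwise search on the Akaike Information
Criterion (AIC = 2k - 2 log partial likelihood), stratifies patients at
the median risk score, and reports Kaplan-Meier curves, the two-group
log-rank test, and Harrell's concordance index.  Cox fits use lifelines
(Efron handling of tied event times); the stepwise search, the null-model
partial likelihood, and the concordance index follow the contracts below.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

from .io_formats import ExpressionMatrix, SurvivalTable

STEP_TOL = 1e-6  # strict AIC improvement required to accept a stepwise move


@dataclass
class ForestRow:
    gene: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    significant: bool
    failed: bool = False


@dataclass
class CoxFitResult:
    selected_genes: list[str]
    betas: np.ndarray
    log_partial_likelihood: float
    aic: float
    c_index: float
    risk_scores: dict[str, float]
    endpoint: str = "RFS"


@dataclass
class StratifiedSurvival:
    group: dict[str, str]  # sample -> high|low
    km_curves: dict[str, pd.DataFrame]  # group -> (time, survival)
    logrank_chi2: float
    logrank_p: float


def _design(
    expr: ExpressionMatrix, surv: SurvivalTable, genes: Sequence[str]
) -> pd.DataFrame:
    samples = [s for s in surv.sample_ids if s in set(expr.sample_ids)]
    if len(samples) < len(surv.sample_ids):
        missing = set(surv.sample_ids) - set(samples)
        raise ValueError(f"survival samples absent from expression: {sorted(missing)}")
    df = expr.data.loc[list(genes), samples].T.copy()
    df["time"] = surv.table.loc[samples, "time"].values
    df["event"] = surv.table.loc[samples, "event"].values
    return df


def univariate_forest(
    expr: ExpressionMatrix, surv: SurvivalTable, genes: Sequence[str]
) -> list[ForestRow]:
    """One single-covariate Cox fit per gene; HR per log2-expression unit.

    Significance = the Wald 95% CI excludes 1.  A gene whose fit fails to
    converge yields a row flagged ``failed`` rather than aborting the batch.
    """
    if surv.n_events < 3 or len(surv.sample_ids) < 10:
        raise ValueError("need >= 10 samples with >= 3 events")
    rows: list[ForestRow] = []
    for g in genes:
        df = _design(expr, surv, [g])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = CoxPHFitter()
                cph.fit(df, duration_col="time", event_col="event")
            s = cph.summary.loc[g]
            hr = float(s["exp(coef)"])
            lo = float(s["exp(coef) lower 95%"])
            hi = float(s["exp(coef) upper 95%"])
            rows.append(
                ForestRow(g, hr, lo, hi, float(s["p"]), lo > 1.0 or hi < 1.0)
            )
        except (ConvergenceError, ValueError, np.linalg.LinAlgError):
            rows.append(ForestRow(g, np.nan, np.nan, np.nan, np.nan, False, True))
    return rows


def _null_log_partial_likelihood(surv_df: pd.DataFrame) -> float:
    """Efron partial log-likelihood of the covariate-free Cox model.

    With all linear predictors zero the Efron denominator at a death time
    with d tied deaths and n at risk reduces to prod_{j<d} (n - j).
    """
    t = surv_df["time"].to_numpy()
    e = surv_df["event"].to_numpy().astype(bool)
    ll = 0.0
    for dt in np.unique(t[e]):
        d = int(np.sum((t == dt) & e))
        n_risk = int(np.sum(t >= dt))
        ll -= sum(np.log(n_risk - j) for j in range(d))
    return ll


def _fit_aic(df: pd.DataFrame, genes: Sequence[str]) -> tuple[float, CoxPHFitter]:
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df[list(genes) + ["time", "event"]], duration_col="time",
                event_col="event")
    aic = 2 * len(genes) - 2 * float(cph.log_likelihood_)
    return aic, cph


def stepwise_aic_cox(
    expr: ExpressionMatrix,
    surv: SurvivalTable,
    candidate_genes: Sequence[str],
    direction: Literal["both", "forward", "backward"] = "both",
    events_per_covariate: int = 5,
) -> CoxFitResult:
    """Greedy stepwise Cox model selection minimizing AIC.

    Starts from the null model ("forward"/"both") or the full model
    ("backward"); at each iteration evaluates every allowed single-gene
    addition and removal with candidates scanned in input order, and takes
    the move with the largest AIC drop, requiring strict improvement.
    Additions stop when events per covariate would fall below
    ``events_per_covariate``.  Deterministic: ties go to the earlier
    candidate.  Risk scores are the centered linear predictor.
    """
    if surv.n_events == 0:
        raise ValueError("no events: cannot fit a Cox model")
    candidates = list(candidate_genes)
    df = _design(expr, surv, candidates)
    k_max = surv.n_events // events_per_covariate

    if direction == "backward":
        selected = candidates[: max(1, min(len(candidates), k_max))]
        current_aic, _ = _fit_aic(df, selected)
    else:
        selected = []
        current_aic = -2.0 * _null_log_partial_likelihood(df)

    allow_add = direction in ("both", "forward")
    allow_drop = direction in ("both", "backward")

    while True:
        best_aic = current_aic
        best_move: tuple[str, str] | None = None  # ("add"|"drop", gene)
        if allow_add and len(selected) < k_max:
            for g in candidates:
                if g in selected:
                    continue
                try:
                    aic, _ = _fit_aic(df, selected + [g])
                except (ConvergenceError, ValueError, np.linalg.LinAlgError):
                    warnings.warn(f"stepwise: adding {g} failed to converge; skipped",
                                  stacklevel=2)
                    continue
                if aic < best_aic - STEP_TOL:
                    best_aic, best_move = aic, ("add", g)
        if allow_drop:
            for g in selected:
                remaining = [x for x in selected if x != g]
                if remaining:
                    try:
                        aic, _ = _fit_aic(df, remaining)
                    except (ConvergenceError, ValueError, np.linalg.LinAlgError):
                        continue
                else:
                    aic = -2.0 * _null_log_partial_likelihood(df)
                if aic < best_aic - STEP_TOL:
                    best_aic, best_move = aic, ("drop", g)
        if best_move is None:
            break
        kind, gene = best_move
        if kind == "add":
            selected = selected + [gene]
        else:
            selected = [x for x in selected if x != gene]
        current_aic = best_aic

    if not selected:
        ll = _null_log_partial_likelihood(df)
        scores = {s: 0.0 for s in df.index}
        return CoxFitResult([], np.array([]), ll, -2 * ll, 0.5, scores)

    aic, cph = _fit_aic(df, selected)
    betas = cph.params_.loc[selected].to_numpy()
    x = df[selected].to_numpy()
    lp = (x - x.mean(axis=0)) @ betas
    scores = dict(zip(df.index, lp.astype(float)))
    c = harrell_c(scores, surv)
    return CoxFitResult(selected, betas, float(cph.log_likelihood_), aic, c, scores)


def stratify_km(
    risk_scores: Mapping[str, float], surv: SurvivalTable
) -> StratifiedSurvival:
    """Median-split risk stratification with KM curves and log-rank test.

    Samples at or below the median score go to the low-risk group.
    """
    samples = [s for s in surv.sample_ids if s in risk_scores]
    scores = np.array([risk_scores[s] for s in samples])
    if np.ptp(scores) == 0:
        raise ValueError("degenerate stratification: all risk scores identical")
    med = float(np.median(scores))
    group = {s: ("low" if sc <= med else "high") for s, sc in zip(samples, scores)}
    members = {g: [s for s in samples if group[s] == g] for g in ("low", "high")}
    if min(len(v) for v in members.values()) < 2:
        raise ValueError("need >= 2 samples per risk group")

    km_curves: dict[str, pd.DataFrame] = {}
    arm = {}
    for g, ss in members.items():
        t = surv.table.loc[ss, "time"].to_numpy()
        e = surv.table.loc[ss, "event"].to_numpy()
        arm[g] = (t, e)
        kmf = KaplanMeierFitter()
        kmf.fit(t, e, label=g)
        sf = kmf.survival_function_
        km_curves[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf[g].to_numpy()}
        )
    res = logrank_test(arm["low"][0], arm["high"][0], arm["low"][1], arm["high"][1])
    return StratifiedSurvival(group, km_curves, float(res.test_statistic),
                              float(res.p_value))


def harrell_c(risk_scores: Mapping[str, float], surv: SurvivalTable) -> float:
    """Harrell's concordance index: concordant / (concordant + discordant).

    A pair is usable when censoring determines its ordering: the earlier
    time carries an event and the times differ.  The pair is concordant
    when the earlier-failing sample has the higher risk score; score ties
    count 0.5.
    """
    samples = [s for s in surv.sample_ids if s in risk_scores]
    t = surv.table.loc[samples, "time"].to_numpy()
    e = surv.table.loc[samples, "event"].to_numpy().astype(bool)
    s = np.array([risk_scores[x] for x in samples])
    n = len(samples)
    conc = disc = ties = 0
    for i in range(n):
        if not e[i]:
            continue
        later = t > t[i]  # j fails/censors strictly after i's event
        si = s[i]
        conc += int(np.sum(s[later] < si))
        disc += int(np.sum(s[later] > si))
        ties += int(np.sum(s[later] == si))
    usable = conc + disc + ties
    if usable == 0:
        raise ValueError("no usable pairs for concordance")
    return (conc + 0.5 * ties) / usable


def forest_to_frame(rows: Sequence[ForestRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "hr": r.hr,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "significant": r.significant,
                "failed": r.failed,
            }
            for r in rows
        ]
    )
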