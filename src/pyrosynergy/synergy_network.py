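"""Signed perturbation-gene-drug network and synergy ranking.

The synergy sign rule: a drug whose sensitivity rises with a gene's
expression (IC50-scale correlation r_ic50 < 0) combined with a
perturbation that raises that gene predicts combination benefit.  The
mirrored case (r_ic50 > 0 with a down-regulated gene) is included by
symmetry under the default rule and excluded under ``rule="paper_literal"``
(the single-case reading).  Genes with no significant perturbation
direction are excluded from every verdict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd

from .drug_screen import GeneDrugEdge
from .io_formats import NetworkEdge
from .signature_deg import DEResult


@dataclass
class PerturbationEffect:
    gene: str
    log2fc: float
    p: float
    direction: Literal["up", "down", "ns"]


def effects_from_de(results: Sequence[DEResult]) -> list[PerturbationEffect]:
    """Convert control-vs-perturbed DE results into perturbation effects."""
    return [PerturbationEffect(r.gene, r.log2fc, r.p, r.direction) for r in results]


@dataclass
class SupportingEdge:
    gene: str
    r_ic50: float
    perturb_direction: str
    concordant: bool
    weight: float


@dataclass
class SynergyPrediction:
    drug: str
    supporting_edges: list[SupportingEdge]
    score: float
    label: Literal["synergy", "no_call"]

    @property
    def n_concordant(self) -> int:
        return sum(e.concordant for e in self.supporting_edges)


def classify_pair(
    edge: GeneDrugEdge,
    effect: PerturbationEffect,
    rule: Literal["symmetric", "paper_literal"] = "symmetric",
) -> Literal["concordant", "discordant", "no_call"]:
    """Apply the synergy sign rule to one (gene-drug edge, gene effect) pair.

    concordant: sensitizing edge (r_ic50 < 0) with an up-regulated gene, or
    — under the symmetric rule — desensitizing edge (r_ic50 > 0) with a
    down-regulated gene.  ns direction always yields no_call.
    """
    if edge.gene != effect.gene:
        raise ValueError(f"gene mismatch: edge {edge.gene!r} vs effect {effect.gene!r}")
    if effect.direction == "ns":
        return "no_call"
    if edge.r_ic50 < 0 and effect.direction == "up":
        return "concordant"
    if edge.r_ic50 > 0 and effect.direction == "down":
        return "concordant" if rule == "symmetric" else "no_call"
    return "discordant"


def predict_synergy(
    edges: Sequence[GeneDrugEdge],
    effects: Sequence[PerturbationEffect],
    weight_mode: Literal["wsum", "count"] = "wsum",
    rule: Literal["symmetric", "paper_literal"] = "symmetric",
) -> list[SynergyPrediction]:
    """Aggregate sign-rule verdicts per drug and rank by synergy score.

    Edge weight is |r_ic50| * |log2fc| ("wsum") or 1 ("count"); the score
    sums weights over concordant edges.  Drugs sorted by descending score,
    ties broken by drug id.  A drug with no concordant edge is no_call.
    """
    if not effects:
        raise ValueError("empty perturbation effects")
    by_gene = {e.gene: e for e in effects}
    per_drug: dict[str, list[SupportingEdge]] = {}
    for edge in edges:
        eff = by_gene.get(edge.gene)
        if eff is None or eff.direction == "ns":
            continue
        verdict = classify_pair(edge, eff, rule)
        if verdict == "no_call":
            continue
        w = abs(edge.r_ic50) * abs(eff.log2fc) if weight_mode == "wsum" else 1.0
        per_drug.setdefault(edge.drug, []).append(
            SupportingEdge(edge.gene, edge.r_ic50, eff.direction,
                           verdict == "concordant", w)
        )
    preds = []
    for drug in sorted(per_drug):
        support = per_drug[drug]
        score = sum(e.weight for e in support if e.concordant)
        label = "synergy" if any(e.concordant for e in support) else "no_call"
        preds.append(SynergyPrediction(drug, support, score, label))
    preds.sort(key=lambda p: (-p.score, p.drug))
    return preds


def build_network(
    predictions: Sequence[SynergyPrediction],
    edges: Sequence[GeneDrugEdge],
    effects: Sequence[PerturbationEffect],
    perturbation_label: str = "HIFU",
    top_k: int | None = None,
) -> tuple[dict[str, str], list[NetworkEdge]]:
    """Assemble the signed tripartite perturbation-gene-drug network.

    Nodes: the perturbation, every gene with a non-ns direction, and every
    synergy-labelled drug (optionally truncated to the top_k by rank).
    Edges: perturbation->gene signed by direction; gene->drug signed by the
    IC50-scale correlation, weighted |r_ic50|.  Returns (node class map,
    edge list) ready for io_formats.write_network.
    """
    if not predictions:
        raise ValueError("no predictions to build a network from")
    ranked = [p for p in predictions if p.label == "synergy"]
    if top_k is not None:
        ranked = ranked[:top_k]
    drugs = {p.drug for p in ranked}
    directed = {e.gene: e for e in effects if e.direction != "ns"}

    nodes: dict[str, str] = {perturbation_label: "perturbation"}
    net_edges: list[NetworkEdge] = []
    used_genes: set[str] = set()
    for e in edges:
        if e.drug not in drugs or e.gene not in directed:
            continue
        nodes[e.drug] = "drug"
        used_genes.add(e.gene)
        sign = 1 if e.r_ic50 > 0 else -1
        net_edges.append(
            NetworkEdge(e.gene, "gene-drug", e.drug, sign, abs(e.r_ic50), e.p)
        )
    for g in used_genes:
        eff = directed[g]
        nodes[g] = "gene"
        sign = 1 if eff.direction == "up" else -1
        net_edges.append(
            NetworkEdge(perturbation_label, "perturbation-gene", g, sign,
                        abs(eff.log2fc), eff.p)
        )
    return nodes, net_edges


def predictions_to_frame(preds: Sequence[SynergyPrediction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "drug": p.drug,
                "score": p.score,
                "label": p.label,
                "n_concordant": p.n_concordant,
                "genes": ",".join(
                    sorted({e.gene for e in p.supporting_edges if e.concordant})
                ),
            }
            for p in preds
        ]
    )
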