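"""Readers and writers for every external table the pipeline touches.

All files are UTF-8, tab-separated, Unix newlines.  Missing values are
written and parsed as ``NA`` (the empty string also parses as missing);
any other non-numeric cell in a numeric column is an error.  Gene symbols
are case-normalized to uppercase, with an optional alias table mapping
e.g. mouse symbols to their human orthologs (Ctsl -> CTSV).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_TOKENS = {"NA", ""}


class ParseError(ValueError):
    """Raised when an input file violates its dialect."""


# ---------------------------------------------------------------------------
# symbol normalization


def normalize_symbol(symbol: str, aliases: Mapping[str, str] | None = None) -> str:
    """Uppercase a gene symbol and apply an optional alias map.

    Idempotent: ``normalize_symbol(normalize_symbol(s)) == normalize_symbol(s)``.
    """
    s = symbol.strip().upper()
    if not s or any(c.isspace() for c in s):
        raise ParseError(f"invalid gene symbol: {symbol!r}")
    if aliases:
        s = aliases.get(s, s)
    return s


def read_alias_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (symbol, canonical symbol) into an alias map.

    Both columns are uppercased; the map is closed so that chains resolve in
    one application (A->B, B->C stored as A->C).
    """
    aliases: dict[str, str] = {}
    for lineno, line in enumerate(_read_lines(path), start=1):
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ParseError(f"{path}:{lineno}: alias line needs 2 fields")
        aliases[parts[0].strip().upper()] = parts[1].strip().upper()
    # resolve chains
    for k in list(aliases):
        v = aliases[k]
        seen = {k}
        while v in aliases and v not in seen:
            seen.add(v)
            v = aliases[v]
        aliases[k] = v
    return aliases


def _read_lines(path: str | Path) -> list[str]:
    text = Path(path).read_text(encoding="utf-8")
    return text.splitlines()


# ---------------------------------------------------------------------------
# domain types


@dataclass
class GeneSet:
    """A named, ordered, deduplicated list of uppercase gene symbols."""

    name: str
    description: str = ""
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for g in self.genes:
            s = normalize_symbol(g)
            if s not in seen:
                seen[s] = None
        if not seen:
            raise ValueError(f"gene set {self.name!r} is empty")
        self.genes = list(seen)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in set(self.genes)


@dataclass
class ExpressionMatrix:
    """Genes x samples real matrix with per-sample class labels.

    ``data`` is a pandas DataFrame indexed by gene symbol with sample-id
    columns; ``sample_class`` maps each sample to its class label (e.g.
    tumor/normal, or a cell-line name).  ``scale_tag`` records whether the
    values are log2 or linear; unit semantics beyond that are the caller's.
    """

    data: pd.DataFrame
    sample_class: dict[str, str]
    scale_tag: str = "log2"

    def __post_init__(self) -> None:
        if self.scale_tag not in ("log2", "linear"):
            raise ValueError(f"scale_tag must be log2|linear, got {self.scale_tag!r}")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes}")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        missing = [s for s in self.data.columns if s not in self.sample_class]
        if missing:
            raise ValueError(f"samples without class label: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def classes(self) -> dict[str, list[str]]:
        """Samples grouped by class label, preserving column order."""
        out: dict[str, list[str]] = {}
        for s in self.data.columns:
            out.setdefault(self.sample_class[s], []).append(s)
        return out

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.data[list(samples)],
            {s: self.sample_class[s] for s in samples},
            self.scale_tag,
        )


@dataclass
class SurvivalTable:
    """Right-censored survival outcomes: (sample, time in months, event flag).

    ``event`` = 1 means the endpoint (e.g. recurrence) was observed, 0 means
    censored.  Model fitting requires at least one event.
    """

    table: pd.DataFrame  # columns: time, event; index: sample_id

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            raise ValueError("duplicate sample ids in survival table")
        if (t["time"] < 0).any():
            raise ValueError("negative survival times")
        if not t["event"].isin([0, 1]).all():
            raise ValueError("event must be 0 or 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def n_events(self) -> int:
        return int(self.table["event"].sum())


@dataclass
class InteractionCatalog:
    """Curated chemical-gene interaction links: drug id -> set of gene symbols."""

    links: dict[str, set[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        clean: dict[str, set[str]] = {}
        for drug, genes in self.links.items():
            gs = {normalize_symbol(g) for g in genes}
            if gs:
                clean[drug] = gs
        self.links = clean

    @property
    def drug_ids(self) -> list[str]:
        return list(self.links)

    def genes_for(self, drug: str) -> set[str]:
        return self.links.get(drug, set())


@dataclass
class DrugActivityPanel:
    """Drugs x cell-lines activity z-scores, higher = more sensitive.

    Missing values are permitted; a drug is testable against a gene only
    where at least ``min_lines`` cell lines carry both measurements (the
    correlation stage enforces that floor).
    """

    activity: pd.DataFrame  # drugs x cell lines
    replicate_counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.activity.index.duplicated().any():
            raise ValueError("duplicate drug ids")
        if self.activity.columns.duplicated().any():
            raise ValueError("duplicate cell-line ids")
        if self.replicate_counts is not None:
            if not self.replicate_counts.index.equals(self.activity.index):
                raise ValueError("replicate_counts index mismatch")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.activity.index)

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.activity.columns)


# ---------------------------------------------------------------------------
# readers


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    lines = _read_lines(path)
    if not any(line.strip() for line in lines):
        raise ParseError(f"{path}: empty GMT file")
    sets: list[GeneSet] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
            )
        sets.append(GeneSet(name=fields[0], description=fields[1], genes=fields[2:]))
    return sets


def write_gmt(gene_sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def _parse_numeric_frame(path: str | Path, index_name: str) -> pd.DataFrame:
    """Parse a TSV with an id first column into a float frame, NA-aware.

    Non-numeric cells other than NA/empty raise with coordinates.
    """
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False,
        encoding="utf-8",
    )
    if raw.columns.duplicated().any():
        dupes = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate sample column(s): {dupes}")

    def convert(cell: str, row: str, col: str) -> float:
        cell = cell.strip()
        if cell in MISSING_TOKENS:
            return np.nan
        try:
            return float(cell)
        except ValueError:
            raise ParseError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}: {cell!r}"
            ) from None

    out = pd.DataFrame(
        [
            [convert(raw.iat[i, j], str(raw.index[i]), str(raw.columns[j]))
             for j in range(raw.shape[1])]
            for i in range(raw.shape[0])
        ],
        index=raw.index,
        columns=raw.columns,
        dtype=float,
    )
    out.index.name = index_name
    return out


def read_expression(
    path: str | Path,
    class_map_path: str | Path,
    scale_tag: str = "log2",
    aliases: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read an expression TSV (genes x samples) plus a (sample, class) map.

    Samples missing from the class map are rejected.  Duplicate gene rows
    (after symbol normalization) are collapsed by mean with a logged warning.
    """
    df = _parse_numeric_frame(path, index_name="gene")
    df.index = [normalize_symbol(g, aliases) for g in df.index]
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        logger.warning("collapsing duplicate gene rows by mean: %s", dupes)
        df = df.groupby(level=0, sort=False).mean()

    cmap: dict[str, str] = {}
    for lineno, line in enumerate(_read_lines(class_map_path), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ParseError(f"{class_map_path}:{lineno}: class map needs 2 fields")
        cmap[parts[0]] = parts[1]
    unknown = [s for s in df.columns if s not in cmap]
    if unknown:
        raise ParseError(f"{path}: samples missing from class map: {unknown}")
    return ExpressionMatrix(df, {s: cmap[s] for s in df.columns}, scale_tag)


def write_expression(
    expr: ExpressionMatrix, path: str | Path, class_map_path: str | Path
) -> None:
    expr.data.to_csv(path, sep="\t", na_rep="NA", encoding="utf-8",
                     lineterminator="\n", index_label="gene")
    with open(class_map_path, "w", encoding="utf-8", newline="\n") as fh:
        for s in expr.sample_ids:
            fh.write(f"{s}\t{expr.sample_class[s]}\n")


def read_survival(path: str | Path) -> SurvivalTable:
    """Read a survival TSV with columns (sample, time_months, event)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     encoding="utf-8")
    required = {"sample", "time_months", "event"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: survival table needs columns {sorted(required)}")
    try:
        table = pd.DataFrame(
            {
                "time": df["time_months"].astype(float).values,
                "event": df["event"].astype(int).values,
            },
            index=pd.Index(df["sample"], name="sample"),
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None
    return SurvivalTable(table)


def write_survival(surv: SurvivalTable, path: str | Path) -> None:
    out = surv.table.reset_index()
    out.columns = ["sample", "time_months", "event"]
    out.to_csv(path, sep="\t", index=False, encoding="utf-8", lineterminator="\n")


def read_catalog(
    path: str | Path, aliases: Mapping[str, str] | None = None
) -> InteractionCatalog:
    """Read a flat chemical-gene catalog TSV (drug_id, gene_symbol[, count])."""
    links: dict[str, set[str]] = {}
    lines = _read_lines(path)
    start = 0
    if lines and lines[0].lower().startswith("drug_id\t"):
        start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ParseError(f"{path}:{lineno}: catalog line needs >= 2 fields")
        links.setdefault(parts[0], set()).add(normalize_symbol(parts[1], aliases))
    return InteractionCatalog(links, provenance=str(path))


def write_catalog(catalog: InteractionCatalog, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("drug_id\tgene_symbol\n")
        for drug in sorted(catalog.links):
            for gene in sorted(catalog.links[drug]):
                fh.write(f"{drug}\t{gene}\n")


def read_activity(path: str | Path) -> DrugActivityPanel:
    """Read a drugs x cell-lines activity z-score TSV."""
    return DrugActivityPanel(_parse_numeric_frame(path, index_name="drug"))


def write_activity(panel: DrugActivityPanel, path: str | Path) -> None:
    panel.activity.to_csv(path, sep="\t", na_rep="NA", encoding="utf-8",
                          lineterminator="\n", index_label="drug")


# ---------------------------------------------------------------------------
# network export


@dataclass(frozen=True)
class NetworkEdge:
    source: str
    interaction_type: str
    target: str
    sign: int  # +1 or -1
    weight: float
    p: float | None = None


def write_network(
    nodes: Mapping[str, str],
    edges: Sequence[NetworkEdge],
    path_prefix: str | Path,
) -> dict[str, Path]:
    """Write a signed network as SIF plus node/edge attribute TSVs.

    ``nodes`` maps node id -> node class (perturbation | gene | drug).
    Ordering is byte-stable: nodes lexicographic, edges by (source, type,
    target).  An edge referencing an unknown node is an error.
    """
    for e in edges:
        for n in (e.source, e.target):
            if n not in nodes:
                raise ValueError(f"edge references unknown node: {n!r}")
        if e.sign not in (1, -1):
            raise ValueError(f"edge sign must be +1/-1, got {e.sign}")
    prefix = Path(path_prefix)
    sif = prefix.with_suffix(".sif")
    edge_attr = Path(str(prefix) + "_edges.tsv")
    node_attr = Path(str(prefix) + "_nodes.tsv")

    ordered = sorted(edges, key=lambda e: (e.source, e.interaction_type, e.target))
    with open(sif, "w", encoding="utf-8", newline="\n") as fh:
        for e in ordered:
            fh.write(f"{e.source}\t{e.interaction_type}\t{e.target}\n")
    with open(edge_attr, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("source\ttype\ttarget\tsign\tweight\tp\n")
        for e in ordered:
            p = "NA" if e.p is None else format(e.p, ".6g")
            fh.write(
                f"{e.source}\t{e.interaction_type}\t{e.target}\t"
                f"{e.sign:+d}\t{e.weight:.6g}\t{p}\n"
            )
    with open(node_attr, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("node\tclass\n")
        for n in sorted(nodes):
            fh.write(f"{n}\t{nodes[n]}\n")
    return {"sif": sif, "edges": edge_attr, "nodes": node_attr}
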