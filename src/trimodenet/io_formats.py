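"""File formats consumed and produced by the pipeline.

The pipeline ingests plain-text gene lists (one symbol per line), GMT
gene-set collections, DAVID-style functional-annotation-chart TSVs, DEG
tables (gene, log2 fold change, FDR) and component content tables (peak
areas).  Graphs are exchanged as Pajek ``.net`` and GraphML.  All tabular
I/O is TSV with a header row, ``.`` as the decimal point and no thousands
separators.

Gene symbols are normalized on ingestion: surrounding whitespace stripped,
uppercased, duplicates dropped.  No alias or orthology mapping is applied
unless an explicit two-column alias map is supplied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "ParseError",
    "SchemaError",
    "TargetSet",
    "GeneSet",
    "GeneSetCollection",
    "DegTable",
    "ContentProfile",
    "normalize_symbols",
    "read_alias_map",
    "read_gene_list",
    "write_gene_list",
    "read_gmt",
    "write_gmt",
    "read_enrichment_chart",
    "read_deg_table",
    "read_content_table",
    "write_pajek",
    "read_pajek",
    "write_graphml",
]


class ValidationError(ValueError):
    """Input violates a semantic invariant (empty set, bad range, duplicate id)."""


class ParseError(ValueError):
    """Input file is syntactically malformed."""


class SchemaError(ValueError):
    """A tabular input is missing a required column."""


TARGET_SOURCES = frozenset(
    {"database", "reference", "geo", "component", "effect", "integrated"}
)


def normalize_symbols(
    symbols: Iterable[str], alias_map: Mapping[str, str] | None = None
) -> tuple[list[str], int]:
    """Strip, remap through ``alias_map`` (if given), uppercase and deduplicate.

    Returns the ordered unique symbols and the number of duplicates dropped.
    """
    seen: dict[str, None] = {}
    n_dupes = 0
    for raw in symbols:
        sym = raw.strip()
        if not sym:
            continue
        if alias_map is not None:
            sym = alias_map.get(sym, alias_map.get(sym.upper(), sym))
        sym = sym.upper()
        if sym in seen:
            n_dupes += 1
        else:
            seen[sym] = None
    return list(seen), n_dupes


@dataclass(frozen=True)
class TargetSet:
    """A named, source-tagged set of normalized gene symbols."""

    name: str
    source: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.source not in TARGET_SOURCES:
            raise ValidationError(
                f"unknown source {self.source!r}; expected one of {sorted(TARGET_SOURCES)}"
            )
        object.__setattr__(self, "members", frozenset(self.members))
        for sym in self.members:
            if not sym or sym != sym.strip().upper():
                raise ValidationError(f"symbol {sym!r} is not normalized")

    @classmethod
    def from_symbols(
        cls,
        name: str,
        source: str,
        symbols: Iterable[str],
        alias_map: Mapping[str, str] | None = None,
        allow_empty: bool = False,
    ) -> "TargetSet":
        uniq, n_dupes = normalize_symbols(symbols, alias_map)
        if n_dupes:
            logger.info("%s: dropped %d duplicate symbol(s)", name, n_dupes)
        if not uniq and not allow_empty:
            raise ValidationError(f"{name}: no valid gene symbols")
        return cls(name=name, source=source, members=frozenset(uniq))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, sym: str) -> bool:
        return sym in self.members

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"{self.term_id}: gene set has no members")


@dataclass(frozen=True)
class GeneSetCollection:
    """An ordered collection of gene sets with unique term ids."""

    sets: tuple[GeneSet, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sets", tuple(self.sets))
        ids = [s.term_id for s in self.sets]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate term id(s): {dup}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, term_id: str) -> GeneSet:
        for s in self.sets:
            if s.term_id == term_id:
                return s
        raise KeyError(term_id)


@dataclass(frozen=True)
class DegTable:
    """Differential-expression results: one row per gene.

    Columns: ``gene`` (normalized symbol), ``log2_fold_change`` (unitless),
    ``fdr`` (Benjamini-Hochberg adjusted p, in [0, 1]).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene", "log2_fold_change", "fdr"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"DEG table missing column(s): {missing}")
        frame = self.frame.loc[:, required].copy()
        frame["gene"] = frame["gene"].astype(str).str.strip().str.upper()
        if frame["gene"].duplicated().any():
            dup = sorted(frame.loc[frame["gene"].duplicated(), "gene"].unique())
            raise ValidationError(f"duplicate gene(s) in DEG table: {dup[:5]}")
        bad = ~frame["fdr"].between(0.0, 1.0)
        if bad.any():
            raise ValidationError(
                f"FDR outside [0,1] for gene(s): {sorted(frame.loc[bad, 'gene'])[:5]}"
            )
        object.__setattr__(self, "frame", frame.reset_index(drop=True))

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, float, float]]
    ) -> "DegTable":
        frame = pd.DataFrame(
            records, columns=["gene", "log2_fold_change", "fdr"]
        )
        return cls(frame)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class ContentProfile:
    """Per-component chromatographic peak areas and the derived content ratios.

    ``ratio(c) = area_c / sum(areas)``; ratios sum to one.
    """

    areas: Mapping[str, float]

    def __post_init__(self) -> None:
        areas = dict(self.areas)
        if not areas:
            raise ValidationError("content profile is empty")
        for comp, area in areas.items():
            if not math.isfinite(area) or area < 0:
                raise ValidationError(f"{comp}: area must be finite and >= 0, got {area}")
        if sum(areas.values()) <= 0:
            raise ValidationError("at least one peak area must be positive")
        object.__setattr__(self, "areas", areas)

    @property
    def components(self) -> list[str]:
        return list(self.areas)

    @property
    def ratios(self) -> dict[str, float]:
        total = sum(self.areas.values())
        return {c: a / total for c, a in self.areas.items()}

    def ratio(self, component: str) -> float:
        return self.ratios[component]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_alias_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (alias, official symbol); no header."""
    out: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{path}:{i}: expected 2 tab-separated fields")
        out[fields[0].strip()] = fields[1].strip().upper()
    return out


def read_gene_list(
    path: str | Path,
    name: str,
    source: str,
    alias_map: Mapping[str, str] | None = None,
) -> TargetSet:
    """Read a one-symbol-per-line gene list; ``#`` lines are comments."""
    lines = Path(path).read_text().splitlines()
    symbols = [ln for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
    return TargetSet.from_symbols(name, source, symbols, alias_map)


def write_gene_list(targets: TargetSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(targets.sorted_members()) + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: term_id <tab> description <tab> gene [<tab> gene ...]."""
    sets: list[GeneSet] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{i}: GMT line has {len(fields)} field(s), need >= 3")
        term_id, description = fields[0].strip(), fields[1].strip()
        members, _ = normalize_symbols(fields[2:])
        if not members:
            raise ParseError(f"{path}:{i}: gene set {term_id!r} has no valid genes")
        sets.append(GeneSet(term_id, description, tuple(members)))
    return GeneSetCollection(tuple(sets))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([s.term_id, s.description, *s.members]) for s in collection
    ]
    Path(path).write_text("\n".join(lines) + "\n")


_CHART_REQUIRED = {"term": "Term", "pvalue": "PValue", "genes": "Genes",
                   "count": "Count", "list total": "List Total"}


def read_enrichment_chart(path: str | Path):
    """Read a DAVID-style functional annotation chart (TSV with header).

    Required columns (matched case-insensitively): Term, PValue, Genes,
    Count, List Total.  ``Term`` of the form ``GO:0006915~apoptotic process``
    is split into id and name on the first ``~``; terms without ``~`` (KEGG,
    Biocarta charts) are kept whole as both id and name.  The gene ratio is
    Count / List Total.  A ``Benjamini`` column, if present, is carried along
    as the term's FDR.  Rows with PValue < 0 or > 1 are dropped (logged);
    PValue == 0 is clamped to 1e-300 with a warning.
    """
    from .enrichment import EnrichedTerm

    frame = pd.read_csv(path, sep="\t")
    lower = {str(c).strip().lower(): c for c in frame.columns}
    missing = [orig for key, orig in _CHART_REQUIRED.items() if key not in lower]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")
    benjamini = lower.get("benjamini")
    category = lower.get("category")

    terms = []
    for _, row in frame.iterrows():
        p = float(row[lower["pvalue"]])
        if p < 0 or p > 1:
            logger.info("%s: dropping row with PValue=%g outside (0,1]", path, p)
            continue
        if p == 0:
            logger.warning("%s: PValue of 0 clamped to 1e-300", path)
            p = 1e-300
        term = str(row[lower["term"]]).strip()
        term_id, _, name = term.partition("~")
        if not name:
            term_id = name = term
        members, _ = normalize_symbols(str(row[lower["genes"]]).split(","))
        ratio = float(row[lower["count"]]) / float(row[lower["list total"]])
        cat = _chart_category(str(row[category])) if category else "unknown"
        terms.append(
            EnrichedTerm(
                term_id=term_id,
                name=name,
                category=cat,
                members=tuple(members),
                p_value=p,
                ratio=ratio,
                fdr=float(row[benjamini]) if benjamini is not None else None,
            )
        )
    return terms


def _chart_category(raw: str) -> str:
    raw = raw.upper()
    if "BP" in raw:
        return "BP"
    if "MF" in raw:
        return "MF"
    if "CC" in raw:
        return "CC"
    if "KEGG" in raw or "BIOCARTA" in raw or "PATHWAY" in raw:
        return "pathway"
    return "unknown"


def read_deg_table(path: str | Path) -> DegTable:
    """Read a DEG TSV with header columns gene, log2_fold_change, fdr."""
    frame = pd.read_csv(path, sep="\t")
    lower = {str(c).strip().lower(): c for c in frame.columns}
    rename = {}
    for want, aliases in {
        "gene": ("gene", "symbol", "gene_symbol"),
        "log2_fold_change": ("log2_fold_change", "log2fc", "logfc", "log2 fc"),
        "fdr": ("fdr", "adj_p", "adj.p.val", "padj"),
    }.items():
        col = next((lower[a] for a in aliases if a in lower), None)
        if col is None:
            raise SchemaError(f"{path}: missing required column {want!r}")
        rename[col] = want
    return DegTable(frame.rename(columns=rename))


def read_content_table(path: str | Path) -> ContentProfile:
    """Read a component content TSV with header columns component, area."""
    frame = pd.read_csv(path, sep="\t")
    lower = {str(c).strip().lower(): c for c in frame.columns}
    for col in ("component", "area"):
        if col not in lower:
            raise SchemaError(f"{path}: missing required column {col!r}")
    areas = {
        str(row[lower["component"]]).strip(): float(row[lower["area"]])
        for _, row in frame.iterrows()
    }
    return ContentProfile(areas)


# ---------------------------------------------------------------------------
# Graph exchange
# ---------------------------------------------------------------------------

def write_pajek(network, path: str | Path) -> None:
    """Write a capacity network in Pajek ``.net`` form.

    ``*Vertices n`` with 1-based ids and quoted labels, then ``*Arcs`` lines
    ``src dst capacity``.  Node order is components, GO terms, effects, each
    in the network's stored order.
    """
    nodes = list(network.node_order())
    index = {v: i + 1 for i, v in enumerate(nodes)}
    lines = [f"*Vertices {len(nodes)}"]
    lines += [f'{index[v]} "{v}"' for v in nodes]
    lines.append("*Arcs")
    for (u, v), cap in sorted(network.arcs.items()):
        lines.append(f"{index[u]} {index[v]} {cap:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pajek(path: str | Path):
    """Read a Pajek ``.net`` file into a directed capacity graph."""
    import networkx as nx

    graph = nx.DiGraph()
    labels: dict[int, str] = {}
    mode = None
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        low = line.lower()
        if low.startswith("*vertices"):
            mode = "vertices"
            continue
        if low.startswith("*arcs") or low.startswith("*edges"):
            mode = "arcs"
            continue
        if mode == "vertices":
            idx_str, _, rest = line.partition(" ")
            label = rest.strip().strip('"')
            labels[int(idx_str)] = label
            graph.add_node(label)
        elif mode == "arcs":
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{i}: arc line needs src dst capacity")
            graph.add_edge(
                labels[int(fields[0])], labels[int(fields[1])],
                capacity=float(fields[2]),
            )
        else:
            raise ParseError(f"{path}:{i}: content before *Vertices section")
    return graph


def write_graphml(network, path: str | Path) -> None:
    """Write the capacity network as GraphML with a ``capacity`` edge attribute."""
    import networkx as nx

    graph = nx.DiGraph()
    for v in network.node_order():
        graph.add_node(v, mode=network.node_mode(v))
    for (u, v), cap in sorted(network.arcs.items()):
        graph.add_edge(u, v, capacity=float(cap))
    nx.write_graphml(graph, path)
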