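"""Over-representation analysis and the weighted-score layers.

Each entity (a chemical component or a pharmacological effect) has a target
gene set.  The entity's targets are tested for over-representation in each
GO-like gene set by a one-sided hypergeometric test, and the enriched terms
are turned into edge weights

    W = norm( norm(r) + norm(-log p) )

where ``r`` is the gene ratio (overlap / targets), ``p`` the enrichment
p-value and ``norm`` min-max normalization taken across that entity's own
term list.  Because min-max normalization is invariant under positive affine
maps, the base of the logarithm is immaterial to the weights.

Pathway-level prioritisation sums the per-component raw score
``norm(r) + norm(-log p)`` over components, weighted by each component's
content ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .io_formats import (
    ContentProfile,
    GeneSetCollection,
    TargetSet,
    ValidationError,
)

__all__ = [
    "EnrichedTerm",
    "EntityTermWeights",
    "PathwayScore",
    "minmax_norm",
    "enrich_terms",
    "term_weights",
    "pathway_scores",
]

CATEGORIES = frozenset({"BP", "MF", "CC", "pathway", "unknown"})


@dataclass(frozen=True)
class EnrichedTerm:
    """One enriched GO term or pathway for a single entity's target list."""

    term_id: str
    name: str
    members: tuple[str, ...]
    p_value: float
    ratio: float
    category: str = "unknown"
    fdr: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValidationError(
                f"{self.term_id}: p_value must be in (0,1], got {self.p_value}"
            )
        if not (0 < self.ratio <= 1):
            raise ValidationError(
                f"{self.term_id}: ratio must be in (0,1], got {self.ratio}"
            )
        if not self.members:
            raise ValidationError(f"{self.term_id}: no member genes")
        if self.category not in CATEGORIES:
            raise ValidationError(f"{self.term_id}: unknown category {self.category!r}")


@dataclass(frozen=True)
class EntityTermWeights:
    """Min-max-scaled term weights for one component or effect.

    All weights lie in [0, 1]; whenever the entity has two or more distinct
    raw scores, at least one term attains 0 and one attains 1.
    """

    entity: str
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        weights = dict(self.weights)
        for term_id, w in weights.items():
            if not (0.0 <= w <= 1.0):
                raise ValidationError(f"{term_id}: weight {w} outside [0,1]")
        object.__setattr__(self, "weights", weights)

    def __len__(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class PathwayScore:
    pathway_id: str
    score: float


def minmax_norm(values: Sequence[float]) -> np.ndarray:
    """Min-max normalization ``(x - min) / (max - min)`` onto [0, 1].

    A constant (or singleton) input maps to all zeros: a flat score layer
    carries no discriminating information, so it contributes none.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("minmax_norm: empty input")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("minmax_norm: non-finite input")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def enrich_terms(
    targets: TargetSet,
    collection: GeneSetCollection,
    universe: Iterable[str],
) -> list[EnrichedTerm]:
    """One-sided hypergeometric over-representation of ``targets`` in each set.

    With a universe of ``N`` genes, a term annotating ``K`` of them, and
    ``n`` target genes of which ``o`` fall in the term, the p-value is
    ``P[X >= o]`` for ``X ~ Hypergeometric(N, K, n)``.  Terms with no
    overlap are omitted.  A Benjamini-Hochberg FDR across the emitted terms
    is attached for reporting (it does not enter the weight formulas).
    Results are sorted by ascending p-value, ties by term id.
    """
    universe_set = (
        universe.members if isinstance(universe, TargetSet) else frozenset(universe)
    )
    if not universe_set:
        raise ValidationError("empty universe")
    if not targets.members <= universe_set:
        extra = sorted(targets.members - universe_set)
        raise ValidationError(f"targets outside universe: {extra[:5]}")

    big_n = len(universe_set)
    n = len(targets.members)
    raw: list[tuple[str, str, tuple[str, ...], float, float]] = []
    for gs in collection:
        term_members = frozenset(gs.members) & universe_set
        overlap = sorted(frozenset(gs.members) & targets.members)
        o = len(overlap)
        if o == 0:
            continue
        p = float(hypergeom.sf(o - 1, big_n, len(term_members), n))
        p = min(max(p, 1e-300), 1.0)  # guard fp tails
        raw.append((gs.term_id, gs.description, tuple(overlap), p, o / n))

    if not raw:
        return []
    from statsmodels.stats.multitest import multipletests

    fdrs = multipletests([r[3] for r in raw], method="fdr_bh")[1]
    terms = [
        EnrichedTerm(
            term_id=tid, name=name, members=members,
            p_value=p, ratio=ratio, fdr=float(fdr),
        )
        for (tid, name, members, p, ratio), fdr in zip(raw, fdrs)
    ]
    terms.sort(key=lambda t: (t.p_value, t.term_id))
    return terms


def _raw_scores(terms: Sequence[EnrichedTerm], log_base: float) -> np.ndarray:
    ratios = [t.ratio for t in terms]
    neglogp = [-math.log(t.p_value, log_base) for t in terms]
    return minmax_norm(ratios) + minmax_norm(neglogp)


def term_weights(
    entity: str, terms: Sequence[EnrichedTerm], log_base: float = 10.0
) -> EntityTermWeights:
    """Weighted scores ``W = norm(norm(r) + norm(-log p))`` for one entity.

    Both inner norms and the outer norm are taken across this entity's own
    term list only, so one entity's outlier cannot rescale another's layer.
    """
    if not terms:
        raise ValidationError(f"{entity}: no enriched terms to weight")
    ids = [t.term_id for t in terms]
    if len(ids) != len(set(ids)):
        raise ValidationError(f"{entity}: duplicate term ids in weight input")
    w = minmax_norm(_raw_scores(terms, log_base))
    return EntityTermWeights(entity=entity, weights=dict(zip(ids, map(float, w))))


def pathway_scores(
    per_component_terms: Mapping[str, Sequence[EnrichedTerm]],
    content: ContentProfile,
    log_base: float = 10.0,
) -> list[PathwayScore]:
    """Content-weighted cumulative pathway scores across components.

    ``score(pathway) = sum_i [norm(r) + norm(-log p)] * R_i`` over the
    components ``i`` whose enrichment contains the pathway, with the norms
    taken within component ``i``'s own term list.  Output is sorted by
    descending score, ties by pathway id.
    """
    ratios = content.ratios
    missing = [c for c in per_component_terms if c not in ratios]
    if missing:
        raise ValidationError(f"component(s) missing from content profile: {missing}")

    totals: dict[str, float] = {}
    for component, terms in per_component_terms.items():
        if not terms:
            continue
        r_i = ratios[component]
        for term, raw in zip(terms, _raw_scores(terms, log_base)):
            totals[term.term_id] = totals.get(term.term_id, 0.0) + float(raw) * r_i
    out = [PathwayScore(pid, score) for pid, score in totals.items()]
    out.sort(key=lambda s: (-s.score, s.pathway_id))
    return out
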