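"""The gene-ontology-interaction (GOI) layer.

Enriched GO terms are linked when their member-gene sets are similar.
Similarity is the overlap coefficient |A∩B| / min(|A|,|B|) (1.0 when one
set contains the other), with Jaccard available as an alternative metric.
Edges at or above the cutoff (default 0.5) are retained; pairs that share
no genes are never linked, even at cutoff 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .enrichment import EnrichedTerm
from .io_formats import ValidationError

__all__ = ["GoiEdge", "overlap_coefficient", "jaccard", "build_goi"]


@dataclass(frozen=True)
class GoiEdge:
    """An unordered similarity edge between two enriched terms."""

    term_a: str
    term_b: str
    overlap_count: int
    coefficient: float

    def __post_init__(self) -> None:
        if self.term_a == self.term_b:
            raise ValidationError(f"self-edge on {self.term_a}")
        if self.overlap_count < 0:
            raise ValidationError("negative overlap count")
        if not (0.0 <= self.coefficient <= 1.0):
            raise ValidationError(f"coefficient {self.coefficient} outside [0,1]")


def overlap_coefficient(a: Iterable[str], b: Iterable[str]) -> float:
    """|a ∩ b| / min(|a|, |b|); both sets must be non-empty."""
    sa, sb = frozenset(a), frozenset(b)
    if not sa or not sb:
        raise ValidationError("overlap coefficient of an empty set is undefined")
    return len(sa & sb) / min(len(sa), len(sb))


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """|a ∩ b| / |a ∪ b|; both sets must be non-empty."""
    sa, sb = frozenset(a), frozenset(b)
    if not sa or not sb:
        raise ValidationError("Jaccard of an empty set is undefined")
    return len(sa & sb) / len(sa | sb)


_METRICS = {"overlap": overlap_coefficient, "jaccard": jaccard}


def build_goi(
    terms: Sequence[EnrichedTerm],
    cutoff: float = 0.5,
    metric: str = "overlap",
) -> list[GoiEdge]:
    """Similarity edges between all term pairs with coefficient >= cutoff.

    Pairs are enumerated lexicographically by term id, so the edge list is
    independent of input order.  Zero-overlap pairs are never emitted.
    """
    if not (0.0 <= cutoff <= 1.0):
        raise ValidationError(f"cutoff {cutoff} outside [0,1]")
    if metric not in _METRICS:
        raise ValidationError(f"unknown metric {metric!r}; use one of {sorted(_METRICS)}")
    ids = [t.term_id for t in terms]
    if len(ids) != len(set(ids)):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate term id(s): {dup}")
    sim = _METRICS[metric]

    ordered = sorted(terms, key=lambda t: t.term_id)
    edges: list[GoiEdge] = []
    for i, ta in enumerate(ordered):
        sa = frozenset(ta.members)
        for tb in ordered[i + 1:]:
            sb = frozenset(tb.members)
            n_shared = len(sa & sb)
            if n_shared == 0:
                continue
            coeff = sim(sa, sb)
            if coeff >= cutoff:
                edges.append(
                    GoiEdge(
                        term_a=ta.term_id, term_b=tb.term_id,
                        overlap_count=n_shared, coefficient=coeff,
                    )
                )
    return edges
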