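"""End-to-end driver: raw target lists to the ranked score tables.

Stages: (1) DEG filter and disease-target integration; (2) hypergeometric
enrichment of the disease, component and effect target sets against one
gene universe; (3) GOI layer from the disease enrichment; (4) per-entity
term weights; (5) three-mode network assembly and pairwise max-flow scores;
(6) entropy weighting, content adjustment and ranking.
"""

from __future__ import annotations

from dataclasses import dataclass


from .enrichment import EntityTermWeights, enrich_terms, term_weights
from .goi import GoiEdge, build_goi
from .io_formats import TargetSet, ValidationError
from .network import FlowScoreMatrix, TriModeNetwork, assemble, score_matrix
from .scoring import ScoreTable, adjust_scores, entropy_weights, rank
from .synthetic import StudyBundle
from .targets import filter_degs, integrate_targets

__all__ = ["PipelineResult", "run_study"]


@dataclass(frozen=True)
class PipelineResult:
    """All intermediates of one pipeline run, for inspection and export."""

    disease_targets: TargetSet
    goi_edges: tuple[GoiEdge, ...]
    component_weights: tuple[EntityTermWeights, ...]
    effect_weights: tuple[EntityTermWeights, ...]
    network: TriModeNetwork
    flow: FlowScoreMatrix
    table: ScoreTable

    @property
    def ranking(self) -> tuple[list[str], list[str]]:
        return rank(self.table)


def run_study(
    bundle: StudyBundle,
    lfc_min: float = 1.5,
    fdr_max: float = 0.05,
    signed: bool = False,
    goi_cutoff: float = 0.5,
    goi_metric: str = "overlap",
    goi_capacity: str = "coefficient",
) -> PipelineResult:
    """Run the whole scoring pipeline on one study bundle."""
    t_geo = filter_degs(bundle.deg_table, lfc_min=lfc_min, fdr_max=fdr_max, signed=signed)
    disease_targets = integrate_targets(bundle.db_targets, bundle.ref_targets, t_geo)
    if not disease_targets.members:
        raise ValidationError("integrated disease target set is empty")

    universe = bundle.universe
    disease_terms = enrich_terms(disease_targets, bundle.collection, universe)
    goi_edges = tuple(build_goi(disease_terms, cutoff=goi_cutoff, metric=goi_metric))

    # an entity with no enriched terms keeps an (empty) layer: its node
    # exists with no arcs, so its flow scores are zero rather than an error
    component_weights = []
    for name in sorted(bundle.component_targets):
        terms = enrich_terms(bundle.component_targets[name], bundle.collection, universe)
        component_weights.append(
            term_weights(name, terms) if terms else EntityTermWeights(name, {})
        )
    effect_weights = []
    for name in sorted(bundle.effect_targets):
        terms = enrich_terms(bundle.effect_targets[name], bundle.collection, universe)
        effect_weights.append(
            term_weights(name, terms) if terms else EntityTermWeights(name, {})
        )

    network = assemble(
        component_weights, list(goi_edges), effect_weights, goi_capacity=goi_capacity
    )
    flow = score_matrix(network)
    H, omega = entropy_weights(flow)
    table = adjust_scores(flow, omega, bundle.content, H=H)
    return PipelineResult(
        disease_targets=disease_targets,
        goi_edges=goi_edges,
        component_weights=tuple(component_weights),
        effect_weights=tuple(effect_weights),
        network=network,
        flow=flow,
        table=table,
    )
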