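"""Seeded synthetic studies with planted component→effect signal.

The generator emulates every input the pipeline consumes: a gene universe of
synthetic symbols ("G000001"-style, so collisions with real symbols are
impossible), GO-like gene sets with controlled pairwise overlap, component
and effect target sets, a DEG table with known fold changes and FDRs,
database/reference disease target lists, and a Dirichlet-drawn content
profile.

Signal is planted per (component, effect, strength) link: both entities draw
a ``strength`` fraction of their targets from the link's dedicated signal
terms, so the pair becomes connected through shared enriched GO terms and
the downstream max-flow score ``z_ij`` rises with the strength.  Unlinked
entities share only background overlap (``noise_overlap``).  Identical
seeds yield identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_formats import (
    ContentProfile,
    DegTable,
    GeneSet,
    GeneSetCollection,
    TargetSet,
    ValidationError,
    write_gene_list,
    write_gmt,
)

__all__ = ["SyntheticStudyConfig", "StudyBundle", "generate_study", "worked_example"]


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Conditions for one synthetic study.

    Defaults describe a small but non-trivial extract: 3 components and 3
    effects over a 1000-gene universe annotated by 24 terms of 10-30 genes,
    so the annotation is sparse the way real GO slims are and chance
    overlaps between unrelated entities stay modest.  Odd-indexed terms
    share ``term_overlap`` of their genes with their predecessor so the GOI
    layer has edges at the usual 0.5 cutoff.
    """

    seed: int = 0
    universe_size: int = 1000
    n_components: int = 3
    n_effects: int = 3
    n_terms: int = 24
    term_size_range: tuple[int, int] = (10, 30)
    term_overlap: float = 0.6
    targets_per_entity: int = 40
    signal_terms_per_link: int = 3
    planted_links: tuple[tuple[str, str, float], ...] = ()
    deg_fraction: float = 0.6
    noise_overlap: float = 0.1
    content_concentration: float = 1.0

    def __post_init__(self) -> None:
        for name in ("universe_size", "n_components", "n_effects", "n_terms",
                     "targets_per_entity"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.targets_per_entity > self.universe_size:
            raise ValidationError("targets_per_entity exceeds universe_size")
        lo, hi = self.term_size_range
        if not (1 <= lo <= hi <= self.universe_size):
            raise ValidationError(f"bad term_size_range {self.term_size_range}")
        for frac_name in ("term_overlap", "deg_fraction", "noise_overlap"):
            if not (0.0 <= getattr(self, frac_name) <= 1.0):
                raise ValidationError(f"{frac_name} must be in [0,1]")
        for c, e, s in self.planted_links:
            if not (0.0 <= s <= 1.0):
                raise ValidationError(f"link ({c},{e}) strength {s} outside [0,1]")


@dataclass(frozen=True)
class StudyBundle:
    """Everything one synthetic study produces, in pipeline-ready form."""

    universe: tuple[str, ...]
    collection: GeneSetCollection
    component_targets: dict[str, TargetSet]
    effect_targets: dict[str, TargetSet]
    deg_table: DegTable
    db_targets: TargetSet
    ref_targets: TargetSet
    content: ContentProfile

    def write(self, out_dir: str | Path) -> None:
        """Write the bundle in the plain-text formats the readers accept."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        Path(out, "universe.txt").write_text("\n".join(self.universe) + "\n")
        write_gmt(self.collection, out / "terms.gmt")
        for name, ts in self.component_targets.items():
            write_gene_list(ts, out / f"component_{name}.txt")
        for name, ts in self.effect_targets.items():
            write_gene_list(ts, out / f"effect_{name}.txt")
        write_gene_list(self.db_targets, out / "disease_db.txt")
        write_gene_list(self.ref_targets, out / "disease_ref.txt")
        self.deg_table.frame.to_csv(out / "deg.tsv", sep="\t", index=False)
        with open(out / "content.tsv", "w") as fh:
            fh.write("component\tarea\n")
            for comp, area in self.content.areas.items():
                fh.write(f"{comp}\t{area:.17g}\n")


def _draw_targets(
    rng: np.random.Generator,
    signal_pool: list[str],
    n_signal: int,
    annotated: list[str],
    unannotated: list[str],
    n_total: int,
    noise_overlap: float,
) -> list[str]:
    """Signal genes from the link's terms, a ``noise_overlap`` share from the
    annotated background, and the remainder from unannotated genes — so with
    no signal and no noise an entity shares nothing with any term."""
    picked: dict[str, None] = {}
    if signal_pool and n_signal > 0:
        k = min(n_signal, len(signal_pool))
        for g in rng.choice(signal_pool, size=k, replace=False):
            picked[str(g)] = None
    n_noise = int(round(noise_overlap * max(n_total - len(picked), 0)))
    if annotated and n_noise > 0:
        k = min(n_noise, len(annotated))
        for g in rng.choice(annotated, size=k, replace=False):
            picked.setdefault(str(g), None)
    need = n_total - len(picked)
    pool = [g for g in unannotated if g not in picked]
    if need > 0:
        if need > len(pool):
            raise ValidationError(
                "universe too small: not enough unannotated genes to fill targets"
            )
        for g in rng.choice(pool, size=need, replace=False):
            picked[str(g)] = None
    return list(picked)[:n_total]


def generate_study(config: SyntheticStudyConfig) -> StudyBundle:
    """Generate one complete seeded study bundle (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    universe = np.array([f"G{i:06d}" for i in range(1, config.universe_size + 1)])

    # GO-like terms; odd-indexed terms copy term_overlap of the previous
    # term's genes so the collection has pairs above the GOI cutoff
    lo, hi = config.term_size_range
    sets: list[GeneSet] = []
    for t in range(config.n_terms):
        size = int(rng.integers(lo, hi + 1))
        if t % 2 == 1 and config.term_overlap > 0:
            prev = list(sets[-1].members)
            n_shared = min(int(round(config.term_overlap * size)), len(prev))
            shared = [str(g) for g in rng.choice(prev, size=n_shared, replace=False)]
            rest_pool = np.setdiff1d(universe, np.array(shared), assume_unique=False)
            fresh = [str(g) for g in rng.choice(rest_pool, size=size - n_shared, replace=False)]
            members = sorted(set(shared + fresh))
        else:
            members = sorted(
                str(g) for g in rng.choice(universe, size=size, replace=False)
            )
        sets.append(GeneSet(f"T{t + 1:04d}", f"synthetic term {t + 1}", tuple(members)))
    collection = GeneSetCollection(tuple(sets))

    components = [f"comp_{i + 1}" for i in range(config.n_components)]
    effects = [f"eff_{j + 1}" for j in range(config.n_effects)]
    for c, e, _ in config.planted_links:
        if c not in components or e not in effects:
            raise ValidationError(f"planted link ({c},{e}) names an unknown entity")

    # dedicate signal terms to each planted link, in order
    term_ids = [s.term_id for s in sets]
    link_terms: dict[tuple[str, str], list[str]] = {}
    cursor = 0
    for c, e, s in config.planted_links:
        take = term_ids[cursor:cursor + config.signal_terms_per_link]
        if len(take) < config.signal_terms_per_link:
            raise ValidationError("not enough terms to dedicate to planted links")
        link_terms[(c, e)] = take
        cursor += config.signal_terms_per_link

    all_term_genes = sorted({g for s in sets for g in s.members})
    unannotated = sorted(set(str(g) for g in universe) - set(all_term_genes))

    def signal_for(entity: str, is_component: bool) -> tuple[list[str], int]:
        pool: list[str] = []
        n_sig = 0
        for (c, e, s) in config.planted_links:
            if (c if is_component else e) != entity:
                continue
            genes = sorted({
                g for tid in link_terms[(c, e)] for g in collection[tid].members
            })
            pool.extend(g for g in genes if g not in pool)
            n_sig += int(round(s * config.targets_per_entity))
        return pool, min(n_sig, config.targets_per_entity)

    component_targets: dict[str, TargetSet] = {}
    for name in components:
        pool, n_sig = signal_for(name, True)
        members = _draw_targets(
            rng, pool, n_sig, all_term_genes, unannotated,
            config.targets_per_entity, config.noise_overlap,
        )
        component_targets[name] = TargetSet(name, "component", frozenset(members))

    effect_targets: dict[str, TargetSet] = {}
    for name in effects:
        pool, n_sig = signal_for(name, False)
        members = _draw_targets(
            rng, pool, n_sig, all_term_genes, unannotated,
            config.targets_per_entity, config.noise_overlap,
        )
        effect_targets[name] = TargetSet(name, "effect", frozenset(members))

    # disease biology spans the annotated genes; a deg_fraction of them pass
    # the thresholds, everything else in the universe clearly fails
    disease_pool = np.array(all_term_genes)
    n_pass = int(round(config.deg_fraction * len(disease_pool)))
    passing = sorted(
        str(g) for g in rng.choice(disease_pool, size=n_pass, replace=False)
    )
    passing_set = set(passing)
    records = []
    for g in universe:
        g = str(g)
        if g in passing_set:
            lfc = float(rng.uniform(1.6, 4.0)) * (1 if rng.random() < 0.5 else -1)
            fdr = float(rng.uniform(1e-6, 0.049))
        else:
            lfc = float(rng.normal(0.0, 0.5))
            fdr = float(rng.uniform(0.05, 1.0))
        records.append((g, lfc, fdr))
    deg_table = DegTable.from_records(records)

    # db/ref lists each cover ~70% of disease biology; their union is wide
    def disease_subset(name: str, source: str) -> TargetSet:
        k = int(round(0.7 * len(disease_pool)))
        members = frozenset(
            str(g) for g in rng.choice(disease_pool, size=k, replace=False)
        )
        return TargetSet(name, source, members)

    db_targets = disease_subset("disease_db", "database")
    ref_targets = disease_subset("disease_ref", "reference")

    alpha = np.full(config.n_components, config.content_concentration)
    areas = rng.dirichlet(alpha)
    content = ContentProfile({c: float(a) for c, a in zip(components, areas)})

    return StudyBundle(
        universe=tuple(str(g) for g in universe),
        collection=collection,
        component_targets=component_targets,
        effect_targets=effect_targets,
        deg_table=deg_table,
        db_targets=db_targets,
        ref_targets=ref_targets,
        content=content,
    )


def worked_example() -> tuple["TriModeNetwork", ContentProfile]:
    """A fixed, seed-free, hand-auditable network for end-to-end checks.

    Three components, six GO terms and two effects with simple capacities:
    every pairwise max flow can be traced by eye (single bottlenecked paths
    plus one GOI detour), and the entropy weights and adjusted scores follow
    from the formulas by hand arithmetic.  ``T0006`` is isolated and is
    pruned during assembly, so it does not appear here.
    """
    from .network import TriModeNetwork

    arcs = {
        ("c1", "g1"): 0.8,
        ("c1", "g2"): 0.6,
        ("c2", "g3"): 1.0,
        ("c2", "g4"): 0.5,
        ("c3", "g5"): 0.7,
        ("g1", "e1"): 0.9,
        ("g2", "e2"): 0.4,
        ("g3", "e1"): 0.6,
        ("g4", "e2"): 1.0,
        ("g5", "e1"): 0.3,
        ("g5", "e2"): 0.3,
        ("g1", "g3"): 0.5,
        ("g3", "g1"): 0.5,
    }
    net = TriModeNetwork(
        components=("c1", "c2", "c3"),
        go_terms=("g1", "g2", "g3", "g4", "g5"),
        effects=("e1", "e2"),
        arcs=arcs,
    )
    content = ContentProfile({"c1": 0.5, "c2": 0.3, "c3": 0.2})
    return net, content
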