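"""Enrich a target list and turn the terms into edge weights.

The hypergeometric test asks how surprising each term's overlap with the
targets is; the weight layer W = norm(norm(r) + norm(-log p)) rescales
gene ratio and significance onto [0, 1] within the entity's own term list.
"""

from trimodenet import (
    GeneSet,
    GeneSetCollection,
    TargetSet,
    enrich_terms,
    term_weights,
)

universe = [f"G{i:03d}" for i in range(60)]
collection = GeneSetCollection((
    GeneSet("GO:0001", "muscle contraction", tuple(universe[0:10])),
    GeneSet("GO:0002", "coagulation", tuple(universe[8:20])),
    GeneSet("GO:0003", "lipid metabolism", tuple(universe[40:55])),
))

targets = TargetSet("comp_A", "component", frozenset(universe[0:8] + universe[12:14]))

terms = enrich_terms(targets, collection, universe)
for t in terms:
    print(f"{t.term_id}  overlap={len(t.members):2d}  ratio={t.ratio:.2f}  "
          f"p={t.p_value:.2e}  BH-FDR={t.fdr:.2e}")

weights = term_weights("comp_A", terms)
print("edge weights:", {k: round(v, 3) for k, v in weights.weights.items()})
# The most enriched term gets weight 1, the least gets 0: these become the
# component->GO arc capacities of the three-mode network.
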