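"""Entropy-weight and content-adjust the flow matrix; rank effects/components.

Effects whose flow column discriminates between components (low entropy)
receive larger weights; each component's scores are then multiplied by its
content ratio so abundant components dominate the extract-level ranking.
"""

from trimodenet import (
    adjust_scores,
    component_table,
    effect_table,
    entropy_weights,
    score_matrix,
    worked_example,
)

net, content = worked_example()
zm = score_matrix(net)
H, omega = entropy_weights(zm)
print("effect entropies H:", H.round(4))
print("entropy weights omega:", omega.round(4))

table = adjust_scores(zm, omega, content, H=H)
print("\nranked effects:")
print(effect_table(table).to_string(index=False))
print("\nranked components (score = network_score x content_ratio):")
print(component_table(table).to_string(index=False))
# The effect totals and component totals are marginals of one adjusted
# matrix, so the two score columns sum to the same number.
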