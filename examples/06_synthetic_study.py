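"""Generate a synthetic study with one planted link and recover it.

The generator plants a component->effect association by making both
entities draw targets from shared signal terms; the pipeline should give
that pair the dominant flow score.
"""

import numpy as np

from trimodenet import SyntheticStudyConfig, generate_study, run_study

cfg = SyntheticStudyConfig(seed=42, planted_links=(("comp_2", "eff_3", 1.0),))
bundle = generate_study(cfg)
result = run_study(bundle)

print("flow matrix:")
print(result.flow.to_frame().round(3))

i = result.flow.components.index("comp_2")
best = result.flow.effects[int(np.argmax(result.flow.z[i]))]
print(f"\nplanted link comp_2 -> eff_3; recovered top effect for comp_2: {best}")

effects, components = result.ranking
print("effect ranking:", effects)
print("component ranking:", components)
# With strength 1.0 the planted pair's row maximum lands on eff_3; the
# global rankings additionally fold in entropy weights and content ratios.
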