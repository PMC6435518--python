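"""Integrate disease targets from three sources.

Database-curated and literature-mined target lists are united, then
intersected with genes passing the differential-expression filter
(|log2FC| > 1.5 and FDR < 0.05), keeping only disease genes with measured
dysregulation.
"""

from trimodenet import DegTable, TargetSet, filter_degs, integrate_targets

t_db = TargetSet("disease_db", "database", frozenset({"NCOR2", "NFAT", "ACE", "AGT"}))
t_ref = TargetSet("disease_ref", "reference", frozenset({"NFAT", "CAMK2A", "REN"}))

deg = DegTable.from_records([
    ("NCOR2", 2.1, 0.01),   # passes: strong up-regulation, low FDR
    ("NFAT", -1.8, 0.02),   # passes: strong down-regulation counts too
    ("ACE", 1.2, 0.01),     # fails: |log2FC| below threshold
    ("CAMK2A", 2.5, 0.20),  # fails: FDR too high
    ("REN", 1.7, 0.04),     # passes
])

t_geo = filter_degs(deg)
disease_targets = integrate_targets(t_db, t_ref, t_geo)

print("DEG-passing genes:", sorted(t_geo.members))
print("integrated disease targets:", sorted(disease_targets.members))
# The integrated set is the evidence-backed core: genes named by a database
# or the literature AND differentially expressed in the disease tissue.
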