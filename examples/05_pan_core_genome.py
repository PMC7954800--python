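"""Pan/core orthogroup analysis over trophic-mode groups.

Builds an orthogroup table with known structure — universally shared OGs,
mode-specific OGs and strain-private OGs — and summarises pan and core sizes
plus the KEGG-category composition for every combination of phototrophic
(P), mixotrophic (M) and heterotrophic (H) strains.
"""

from chrysokit.pangenome import group_summaries
from chrysokit.synthgen import OGTableSpec, make_og_table

spec = OGTableSpec(
    strains={"P1": "phototroph", "M1": "mixotroph", "M2": "mixotroph",
             "H1": "heterotroph", "H2": "heterotroph", "H3": "heterotroph"},
    core_all=30,
    per_mode_shared={"mixotroph": 8, "heterotroph": 5},
    per_strain_private={"H1": 12, "H2": 9, "H3": 7, "M1": 4},
    annotated_fraction=0.3,
    seed=21,
)
table, annotation, truth = make_og_table(spec)

print(f"{'group':8}{'pan':>6}{'core':>6}  annotated")
for s in group_summaries(table, annotation, spec.strains):
    print(f"{s.name:8}{s.pan_size:>6}{s.core_size:>6}  {s.annotated_pct:5.1f}%")
# Heterotrophs carry many private OGs, so their pan genome is large while
# their core genome stays small — the pan/core asymmetry the group
# comparison is designed to expose. Generator truth confirms the H row:
print(f"\ntruth for H: pan={truth.pan[('heterotroph',)]} core={truth.core[('heterotroph',)]}")
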