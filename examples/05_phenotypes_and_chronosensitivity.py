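"""Phenotype clustering and drug chronosensitivity on a synthetic panel.

Clusters a feature table with four planted circadian archetypes, then
scores two synthetic drugs — one whose sensitivity is tied to clock
strength, one independent of it — with the LDA-based chronosensitivity
index (BCD/WCD of the one-dimensional discriminant scores).
"""

import numpy as np
import pandas as pd

from circapheno import chronosense, phenotyping
from circapheno.simulate import generate_phenotype_table

features, truth = generate_phenotype_table(4, seed=11)
assign = phenotyping.select_k_and_cluster(features, seed=0)
print(f"elbow-selected k = {assign.k}, silhouette = {assign.silhouette:.3f}")
print("phenotype counts:", assign.labels.value_counts().to_dict())
agreement = (assign.labels == truth).mean()
print(f"agreement with planted archetypes: {agreement:.0%}\n")

rng = np.random.default_rng(0)
clock_strength = phenotyping.minmax_scale(features)["circadian_band_pct"]
sensitivity = pd.DataFrame({
    "clock_dependent_drug": -clock_strength + rng.normal(0, 0.05, len(features)),
    "clock_independent_drug": rng.normal(0, 1, len(features)),
}, index=features.index)

ranking = chronosense.rank_drugs(features, sensitivity, run_validation=True)
print(ranking.round(3).to_string(index=False))
print()
print("The clock-dependent drug scores an index above the effectiveness")
print("cut-off of 2 (its sensitivity groups separate cleanly on LD1);")
print("the clock-independent drug does not.")
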