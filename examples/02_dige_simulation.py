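"""A six-technical-replicate 2D-DIGE study on a synthetic proteome.

Generates a 150-protein proteome with proteoform structure, forms gel spots,
simulates three gels (Cy3/Cy5 samples over a Cy2 internal standard each),
standardizes abundances, matches spots across replicates and summarizes the
technical variation of the 100%-matched spots.
"""

import pandas as pd

from proteoformsim import (
    NoiseModel,
    ProteomeConfig,
    form_spots,
    generate_proteome,
    match_spots,
    simulate_gels,
    standardize_abundance,
    summarize_variation,
)
from proteoformsim.dige import technical_replicate_design
from proteoformsim.variation import reproducible_entities

model = generate_proteome(ProteomeConfig(n_proteins=150), seed=42)
base = pd.DataFrame(
    {"IS": [p.base_abundance for p in model.proteoforms]},
    index=[p.proteoform_id for p in model.proteoforms],
)
design = technical_replicate_design(n_gels=3)
spots = form_spots(model, base, design)
obs = standardize_abundance(
    simulate_gels(spots, base, design, NoiseModel(), seed=42), design
)
matched = match_spots(obs, design)
counts = reproducible_entities(matched.sa, by_range=matched.positions["ph_range"])
summary = summarize_variation(matched.complete(), tech_cols=list(matched.sa.columns))

print(f"{model.n_proteoforms} proteoforms of {len(model.proteins)} proteins")
print(f"spot map: {len(spots)} spots "
      f"({(spots['n_proteoforms'] > 1).mean():.1%} hold >1 proteoform)")
print("100%-matched spots per pH range:", {k: v for k, v in counts.items() if k != 'composed'})
print(f"composed across ranges: {counts['composed']}")
print(f"median technical CV of SA values: {summary.median_cv_tech:.1f}%")
print("-> the internal standard keeps the technical CV in the single digits;")
print("   the composed count is what every downstream analysis is limited to.")
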