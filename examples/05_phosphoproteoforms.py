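"""Phosphoproteoform detection by phosphatase contrast, on both sides.

Gel side: untreated vs lambda-phosphatase-treated volumes at each spot
position; a spot losing more than a third of its volume (ratio > 1.5) is
called phosphorylated. Shotgun side: direct (enrichment-free) phosphopeptide
detection is rare by construction.
"""

import pandas as pd

from proteoformsim import (
    NoiseModel,
    ProteomeConfig,
    generate_proteome,
    phospho_fraction,
    ppase_ratio_classify,
    simulate_ppase_contrast,
    simulate_runs,
    spot_pair_stoichiometry,
)

model = generate_proteome(ProteomeConfig(n_proteins=200), seed=7)
pairs = simulate_ppase_contrast(model, NoiseModel(), efficiency=1.0, seed=7)
calls = ppase_ratio_classify(pairs)

n_flagged = int(calls["flagged"].sum())
headline, unrounded = phospho_fraction(n_flagged, len(calls))
tp = calls[calls["flagged"] & calls["true_phospho"]]
print(f"{len(calls)} spot positions; {n_flagged} flagged as phosphorylated "
      f"({unrounded:.1f}% -> headline {headline}%)")
print(f"of the flagged spots, {len(tp)} are true phosphoproteoforms "
      f"(ground truth known in simulation)")

one = calls[calls["true_phospho"] & (calls['vol_treated'] > 0)].iloc[0]
ratio, label = spot_pair_stoichiometry(one["vol_untreated"] - one["vol_treated"],
                                       one["vol_treated"])
print(f"example spot: untreated/treated ratio {one['ratio']:.2f}, "
      f"phospho:dephospho stoichiometry {ratio:.2f} ({label})")

runs = pd.DataFrame(
    {"r1": [p.base_abundance for p in model.proteoforms]},
    index=[p.proteoform_id for p in model.proteoforms],
)
peps = simulate_runs(model, runs, seed=7)
ph = set(peps.loc[peps["phospho_site"] >= 0, "accession"])
print(f"\ndirect shotgun on the same proteome: {len(ph)} of "
      f"{peps['accession'].nunique()} identified proteins show any phosphopeptide")
print("-> the gel contrast preserves phosphorylation stoichiometry; direct")
print("   shotgun sees phosphopeptides only circumstantially.")
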