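"""Sequence chemistry: mass, isoelectric point, and tryptic digestion.

Builds a short peptide, computes its physico-chemical coordinates with and
without a phosphate group, and digests a protein the way the shotgun
workflow would.
"""

from proteoformsim import digest, isoelectric_point, molecular_weight, theoretical_peptide_count

peptide = "MSKGEELFTGVVPILVELDGDVNGHKFSVSGEGEGDATYGK"

mw = molecular_weight(peptide)
pi = isoelectric_point(peptide)
site = peptide.index("S")
pi_p = isoelectric_point(peptide, [(site, "phospho")])

print(f"peptide length {len(peptide)}, MW {mw/1000:.1f} kDa, pI {pi:.2f}")
print(f"with one phosphate at residue {site}: pI {pi_p:.2f}")
print("-> phosphorylation adds acidic charge, shifting the molecule toward")
print("   lower pH on a 2D gel; dephosphorylation reverses the shift.")

peps = digest(peptide, max_missed=1)
print(f"\ntryptic peptides (<=1 missed cleavage): {len(peps)}")
for p in sorted({x.sequence for x in peps if len(x.sequence) >= 6}):
    print("  ", p)
print("measurable (6-30 residue, fully cleaved) peptides:",
      theoretical_peptide_count(peptide), "- the iBAQ denominator")
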