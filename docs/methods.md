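# Methods

This note records the models, parameter choices and numerical conventions
behind `proteoformsim`, and what the simulations do and do not establish
about real data.

## Ground-truth proteome

A synthetic proteome stands in for a cell lysate so that every downstream
statistic can be validated against known truth. Canonical sequences are
drawn i.i.d. from human average amino-acid frequencies with log-normal
lengths (median 450 residues, ln-scale sd 0.35, floor 50); users can
substitute real FASTA sequences. Proteoform counts per protein follow a
shifted Poisson `1 + Poisson(μ − 1)` with default mean μ = 3 — the classic
2D-gel-era estimate for eukaryotes. (Top-down atlas work suggests an order
of magnitude more forms per gene, mostly small ones; that regime is
reachable by raising `mean_proteoforms`, but it is not the default study
condition.) Extra proteoforms split evenly between:

* **phosphoproteoforms** — one uniformly chosen S/T/Y site, occupancy
  `o ~ U(0.1, 0.9)`;
* **cleavage proteoforms** — a single truncation at a uniform internal
  position, N- or C-terminal half retained with equal probability, the cut
  recorded as ground truth.

Base abundances are log-normal with ln-scale sd 2.3 (≈1 decade per sd), so
a default proteome spans well over three orders of magnitude, as complex
lysates do. Abundance units are arbitrary "volume units"; only ratios and
ranks carry meaning, which is also all the downstream statistics use.

### What "occupancy" means here (the stoichiometric spot model)

A phosphoproteoform record with abundance *A* and occupancy *o* represents
a pool of which fraction *o* actually carries the phosphate; the whole pool
is modelled as migrating at the modified (pI-shifted) position. Phosphatase
treatment with efficiency *e* moves mass `A·o·e` to the unmodified
counterpart, so the untreated/treated volume ratio at the modified position
is `1/(1 − o·e)`, and at full efficiency exactly the spots with `o > 1/3`
exceed the 1.5 classification threshold. This is deliberately a
stoichiometry-preserving caricature: physically, the unphosphorylated
remainder of a partially occupied form would migrate at the unmodified
position (making the spot ratio a function of *e* only). The caricature was
chosen because it keeps per-spot occupancy identifiable from a single
treated/untreated contrast — the quantity the gel-side phospho analysis is
about — at the cost of spot-position purity. A proteoform's *chemical
identity* (used when merging after dephosphorylation) is its parent,
sequence and modification-site set; occupancy is an annotation, so a
partially dephosphorylated record keeps its position while its moved mass
merges into the counterpart. Dephosphorylation is mass-conserving per
parent protein and idempotent at full efficiency.

## Sequence chemistry

Molecular weight is residue-mass summation (average-mass scale for gel MW,
reported in kDa at 0.1 precision; monoisotopic masses available). Net charge
is the Henderson–Hasselbalch sum over ionizable groups with the Bjellqvist
pKa table — the de-facto standard for IPG-strip pI estimation — shipped as
an editable TSV. Phosphate adds a two-stage acidic group (pKa 1.2 / 6.5);
phospho-Tyr silences the phenol, acetyl-Lys the amine. The pI is found by
bisection on [0, 14] to |charge| < 1e-4; the charge curve is strictly
decreasing so the root is unique, and all-basic/all-acidic edge cases clamp
to the interval ends. Tests verify the bisection against a 1e-4-step grid
oracle. Trypsin cleaves C-terminal of K/R except before P; Lys-C after K;
the digest enumerates peptides up to a missed-cleavage bound (default 2) and
is checked against exhaustive site enumeration. "Theoretically measurable"
peptides — the iBAQ denominator — are fully cleaved peptides of 6–30
residues; the bounds are conventional, not canonical, and configurable.

## 2D-DIGE measurement model

Proteoforms inside a pH range (defaults 4–7 and 6–9) merge into one spot
when within Δ pI = 0.05 **and** relative ΔMW = 2 % (greedy single pass in pI
order, deterministic); the merge records contributing proteoform ids. Per
gel and channel, raw volume = true volume × channel gain (ln-sd 0.2) ×
technical noise. The noise parameter `sigma_tech_dige` (default 0.0759) is
defined at the **SA level**; since SA divides two independently noisy
channel measurements, each channel applies `sigma/√2`. Detection is
Bernoulli with probability logistic in log volume (midpoint 2 ln-units
below the median spot volume, slope 1.2), multiplied by 0.9 in the
technically harder pH 6–9 range — the direction, not the magnitude, of that
penalty is the claim. Observed positions carry small jitter (pI sd 0.01, MW
0.5 %), below the matching tolerance.

SA follows the internal-standard convention: channel-normalized volume
divided by the same spot's channel-normalized volume in the gel's IS
channel; the IS channel's own SA is identically 1, and SA is missing
wherever the IS did not detect the spot. Matching across replicates is
greedy nearest-neighbour against a master list (first replicate), one to
one, closest pairs first, within the same tolerances; representative spot
volume is the arithmetic mean of normalized volumes over all replicates,
computed only for 100 %-matched spots. Nothing is imputed anywhere.

## Shotgun measurement model

Peptide true intensity sums contributing proteoform abundances (a peptide
covering a phosphosite splits `o` : `1 − o` between its modified and
unmodified species), times a per-peptide ionization factor (log-normal,
ln-sd 1.0, fixed across runs), times run-level technical noise. The
technical noise `sigma_tech_shotgun` (default 0.2367) is split into a
component shared by all peptides of a protein within a run (80 % of the
variance — digestion efficiency and LC drift act protein-wise) and an
independent per-peptide remainder; without the shared part, summing ~dozens
of peptides would average protein-level CV away, which is not what
label-free data show. Detection is logistic in log intensity (an emulation
of top-N precursor selection, not an explicit scan queue), with
phosphopeptide probability multiplied by 0.004 — calibrated so that a
direct, enrichment-free run on a 10,000-protein proteome yields under 1 %
phosphoproteins among identifications. Site-localization confidence is
simulated as Beta(8, 1.5) with the conventional 0.75 acceptance threshold.

Protein inference collapses peptides to canonical accessions (shared
sequences go to the accession with more distinct detected peptides, ties
lexicographic). LFQ is a simplified median-ratio normalization to the first
run followed by summation — not the full pairwise least-squares MaxLFQ — on
the grounds that the comparison only needs a scale-free protein intensity.
Match-between-runs is not emulated.

## Statistics

* **CV** is `100·sd/mean` on the raw scale, sample (n−1) sd (configurable;
  at n = 6 and 3 the choice matters). Cohort summary is the median.
* **`cv_on_log2`** applies the same formula to log2 values and returns a
  non-comparability flag; it exists to demonstrate, and let tests assert,
  that the log-scale shortcut understates variability on multiplicative
  data.
* **Small-sample bias.** The median of per-entity sample CVs is biased low
  (chi-distribution median factor ≈ 0.93 at n = 6, ≈ 0.83 at n = 3). The
  calibration study therefore also reports a de-biased recovery: the pooled
  per-entity variance of ln-values (unbiased at any n) pushed through the
  log-normal closed form `CV = √(e^σ² − 1)`. At n = 6 the raw median lands
  within a percentage point of the population value; at n = 3 only the
  de-biased recovery does.
* **Spearman** uses midranks (scipy); per-spot correlations repeat a
  protein's LFQ across its spots, so ties in y are structural and midranks
  are required, not optional.
* **Reproducibility** counts entities with no missing value across all
  replicates, per pH range and composed (sum over disjoint ranges).
* **Phospho classification** flags ratio strictly > 1.5; a treated volume
  at or below the detection floor with detectable untreated volume is
  flagged through a separate "fully shifted" branch rather than a division.
  The headline percentage is rounded half-up to an integer.

## Noise calibration

Defaults encode the study conditions the package emulates: SA-level
technical ln-sd 0.0759 (median CV_tech ≈ 7.6 %), shotgun technical ln-sd
0.2367 (≈ 24 %), biological ln-sd 0.1049 chosen so the gel-side total
(√(0.1049² + 0.0759²) = 0.1295) gives ≈ 13 %. The far larger shotgun total
variation reported for real month-separated run sets (≈ 59 %, ln-sd 0.5466)
reflects instrument drift that shared biology cannot produce; the
calibration study drives the CV machinery at that sigma directly, and the
simulator exposes gain drift only as a knob.

## Problem sizes and determinism

Default study sizes are desk-scale by design: 60–300 proteins for
end-to-end studies, 2,000 entities for CV calibration, 200 replicate
studies for the summing-vs-per-spot comparison, 10,000 proteins for the
phosphoprotein-rarity check. Every stochastic stage takes an explicit seed;
sub-seeds derive from one master seed via a PCG64 stream, and identical
(config, seed) pairs reproduce byte-identical outputs.

## Known limitations

* No isotope envelopes, MS2 spectra, retention-time modelling, search-engine
  scoring, FDR, or match-between-runs; no gel-image synthesis — the
  simulators operate on spot/peptide tables directly.
* Random sequences lack homology, splice structure and real PTM site
  preferences; spot-merging statistics on random proteomes only caricature
  the crowding of a real 2D map (image-analysis artifacts such as dust
  spots are not modelled at all), so absolute matched-spot counts are not
  comparable to real gels.
* The stoichiometric spot model trades positional purity for identifiable
  occupancy (above); sensitivity claims for the phosphatase contrast
  therefore apply to the model, not to gel optics.
* Passing tests establish internal consistency and calibration-recovery of
  the stated models, not instrument-level realism.
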