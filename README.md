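# proteoformsim

Comparative simulation and statistics for the two workhorse proteomics
strategies: **gel-based top-down** (two-dimensional difference gel
electrophoresis, 2D-DIGE), which separates and quantifies intact
*proteoforms*, and **gel-free bottom-up** (label-free shotgun LC-MS/MS),
which digests everything into peptides and reassembles them into *canonical
proteins*, erasing proteoform identity.

The package is for proteomics methodologists and statisticians who want to
reason quantitatively about what each platform can and cannot see: it
generates ground-truth proteomes with proteoform structure (phosphorylation,
proteolytic truncation), pushes them through explicit models of both
measurement processes, and computes the statistics the comparison turns on.

## The models in brief

**Ground truth.** Each canonical protein *i* carries `1 + Poisson(μ − 1)`
proteoforms (default mean μ = 3), with base abundances
`A ~ LogNormal(·, σ²)` spanning >3 decades. A phosphoproteoform has one
phosphosite with occupancy *o* ∈ [0, 1]; a cleavage proteoform is a
contiguous truncation. Replicates carry multiplicative noise:
`x = A · exp(σ_bio z_b) · exp(σ_tech z_t)`.

**2D-DIGE.** Proteoforms land on (pI, MW) coordinates — pI from
Henderson–Hasselbalch charge balance with the Bjellqvist pKa set, MW from
residue-mass summation. Forms closer than the gel resolution (Δ pI < 0.05,
ΔMW/MW < 2 %) merge into one spot. Each gel runs up to two samples plus a
pooled internal standard (IS, Cy2); the **standardized abundance** of a spot
is

    SA = (V_spot / ΣV_channel) / (V_spot,IS / ΣV_IS)

which cancels channel gains and makes gels comparable. Weak spots go missing
stochastically (logistic in log volume, worse at pH 6–9); no value is ever
imputed — analyses use only spots matched in **all** replicates.

**Shotgun.** All proteoforms are trypsin-digested (cleave after K/R, not
before P, ≤2 missed cleavages) into one peptide pool, so a peptide intensity
sums every contributing proteoform (occupancy-weighted for modified forms).
Detection emulates data-dependent acquisition: probability increasing with
intensity, with a strong penalty for phosphopeptides. Protein groups get

    LFQ  = median-ratio-normalized Σ peptide intensities
    iBAQ = Σ peptide intensities / #(theoretically measurable tryptic peptides)

**Statistics.** Coefficients of variation are always raw-scale
(`100·sd/mean`, sample sd); the deliberately wrong log2-scale CV is provided
to demonstrate how it understates variability. Cross-method agreement uses
Spearman's r_S with midranks; reproducibility counts entities present in
every replicate. Phosphoproteoforms are classified from a λ-phosphatase
contrast: a spot with untreated/treated volume ratio > 1.5 is called
phosphorylated (noise-free expectation `1/(1 − o·e)` for occupancy *o*,
treatment efficiency *e*).

## Worked example

The packaged DU145 benchmark panel holds 36 gel spots of 11 proteins, each
protein also quantified as a single shotgun LFQ intensity:

```bash
python examples/04_spot_panel_correlations.py
```

prints

```
panel: 36 spots, 11 proteins (excluded from correlation: CALM1)
per-spot      r_S = 0.380  (n = 34 spots)
summed        r_S = 0.758  (n = 10 proteins)
```

Pairing each *spot* with its protein's one LFQ value gives a weak rank
correlation (0.380) because shotgun contrasts a canonical total against
individual proteoform amounts; summing a protein's spot volumes first raises
it to 0.758. That asymmetry — proteoform-resolved versus proteoform-blind —
is the package's central object of study. The other `examples/*.py` scripts
walk through sequence chemistry, both simulators, phosphoproteoform
classification and the workload calculator, each printing a short
explanation with its numbers.

A thin CLI wraps the same functions (`proteoformsim simulate-proteome |
simulate-dige | simulate-shotgun | analyze | spot-panel | report`).

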