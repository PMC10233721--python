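# blastoquant

Quantitative analysis of lineage segregation in the human blastocyst inner
cell mass (ICM), for developmental biologists quantifying confocal
immunofluorescence and ordering lineage-marker activation in single-cell
expression data.

During blastocyst expansion (day 5 to day 7 post fertilisation) the ICM
resolves into the pluripotent **epiblast** and the extra-embryonic
**hypoblast** (primitive endoderm).  This package implements two analysis
arms over that process, with a synthetic-data module supplying image stacks
and expression matrices with known ground truth so every stage is testable
without embryo material:

1. **Lineage classification from nuclear intensities.**  Per-nucleus volume,
   mean fluorescence intensity and integrated density are measured from a
   multi-channel 3D stack and a nuclear label mask.  At D7 the pooled
   intensity histogram of an epiblast marker (OCT4) or hypoblast marker
   (SOX17) is bimodal; a two-component Gaussian mixture

   `p(x) = w₁·N(x; μ₁, σ₁²) + w₂·N(x; μ₂, σ₂²)`,  μ₁ < μ₂,

   is fitted by multi-start EM and the positivity threshold is the density
   intersection — the root of `w₁·N(x; μ₁, σ₁²) = w₂·N(x; μ₂, σ₂²)` in
   (μ₁, μ₂), the Bayes boundary between negative and positive cells.  The
   D7-anchored cuts are applied unchanged to earlier stages, sorting ICM
   cells into epiblast (OCT4⁺ SOX17⁻), hypoblast (OCT4⁻ SOX17⁺),
   co-expressing (double-positive "undefined ICM") and negative quadrants,
   summarised per embryo and per stage.

2. **Gene-activation ordering along pseudotime.**  Along a hypoblast-branch
   pseudotime `t ∈ [0, 1]` (imported, or computed as a mutual-kNN graph
   geodesic from a root cell), each gene's expression is smoothed over the
   cell and its 30 most similar cells, then fitted by least squares to a
   four-parameter logistic

   `y(t) = b + A / (1 + exp(−s·(t − t₀)))`

   (and its mirrored decreasing form).  The midpoint `t₀` — where the curve
   crosses `b + A/2` — is the activation tipping point; genes sorted by
   ascending `t₀` give the activation order of the hypoblast programme
   (PDGFRA → … → SYT13 for the canonical 16-gene panel).

## Worked example

The numbered drivers under `analysis/` run both arms on synthetic cohorts
and write their tables under `results/`:

```bash
python analysis/01_simulate_cohorts.py --seed 1   # 4 stages x 5 embryos x 200 cells
python analysis/02_classify_lineages.py           # D7-anchored thresholds -> calls
python analysis/03_simulate_trajectory.py --seed 1
python analysis/04_activation_order.py
```

`02_classify_lineages.py` prints the fitted D7 cuts and the recovered
stage-wise percentages against the generator truth:

```
D7-anchored thresholds: {'OCT4': 48.33, 'SOX17': 44.62}
   D7 epiblast       recovered  25.4%  truth  25.4%  (|delta| 0.00 pp)
   D7 co_expressing  recovered   9.3%  truth   9.3%  (|delta| 0.00 pp)
   D7 hypoblast      recovered  65.3%  truth  65.3%  (|delta| 0.00 pp)
```

i.e. with well-separated intensity modes the mixture threshold reproduces the
generated lineage composition exactly; deviations from the preset fractions
(63/27/10 at D7) are multinomial sampling noise in the cohort itself.
`04_activation_order.py` reports the recovered activation sequence:

```
recovered order: PDGFRA -> BMP2 -> OTX2 -> LGALS2 -> VIL1 -> SOX17 -> FOXA2
  -> SALL1 -> GATA4 -> COL4A1 -> RSPO3 -> FRZB -> IGF1 -> FLRT3 -> CPN1 -> SYT13
median |midpoint error|: 0.0109 (max 0.0763) on the unit pseudotime scale
Kendall tau vs truth: 1.000
```

so under negative-binomial counting noise (dispersion 0.1, 600 cells) the
smoothing + logistic pipeline recovers all 16 design midpoints to ~0.01 and
the full activation order without inversions.

The same pipelines are available as a CLI (`blastoquant simulate / quantify /
threshold / classify / summarize / pseudotime / fit-order / demo`); every
subcommand writes its resolved configuration JSON next to its outputs, and
`blastoquant demo --seed 1 --out DIR` runs both arms end to end with a
self-check report.

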