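# mae-lipidomics

Design-of-experiments optimization and chemometric screening for
microwave-assisted extraction (MAE) of lipids from soft cheese, with lipid
shorthand annotation. The package is aimed at analytical chemists and
computational lipidomics researchers who develop extraction methods: it
covers the full statistical side of such a method-development study —
everything downstream of the mass spectrometer and the identification
software.

## What it computes

**Factorial modelling.** Three extraction factors — solvent-to-solid ratio
X₁ (16–32 mL g⁻¹), time X₂ (6–30 min), temperature X₃ (50–80 °C) — are
screened with a 2³ full factorial design plus 3 center replicates (11 runs).
Each lipid-subclass abundance sum Y, range-scaled to [0, 1], is fitted by
ordinary least squares to the 8-term model

    Y = b₀ + b₁X₁ + b₂X₂ + b₃X₃ + b₁₂X₁X₂ + b₁₃X₁X₃ + b₂₃X₂X₃ + b₁₂₃X₁X₂X₃

with the factors in coded units (−1, 0, +1). Coefficient p-values come from
two-sided t tests on the 3 residual degrees of freedom; a subclass is
retained when its overall F test gives p ≤ 0.05.

**Solvent screening.** Extraction replicates of three solvent mixtures
(methanol/, ethanol/ and isopropanol/ethyl acetate — ME, EE, IE) are
compared by PCA, UPGMA hierarchical clustering on squared Euclidean
distances of [0, 1]-scaled subclass sums, and PLS-DA. PLS-DA quality is
estimated two ways: a double (nested) cross-validation where the inner
folds pick the number of latent variables and the outer held-out
predictions yield RMSECV, Q² = 1 − PRESS/TSS, the discriminant DQ² (class
predictions beyond their label are not penalized, so DQ² ≥ Q²), accuracy,
sensitivity and specificity per class; and a stratified out-of-bag
bootstrap of the same statistics.

**Pareto optimization.** The retained subclasses are projected onto PC1/PC2;
8-term surfaces are fitted to the scores and evaluated on a grid of 40
equally spaced levels per factor (64,000 points). The non-dominated
settings form the Pareto front, and the front point closest to the utopia
point (in min–max-normalized objective space) is the compromise setting.
Because which end of a PC favors which lipid group is data-dependent, the
objective senses are configuration; alternatively, `objectives="groups"`
maximizes the mean-recovery surfaces of the two antagonistic subclass
groups (positive vs negative solvent-to-solid effect) directly.

**Lipid annotation.** A parser for shorthand names (`TG(4:0/18:1/18:2)`,
`Cer(d18:1/16:0)`, oxidized chains `18:2+OO`; `/` = resolved sn positions,
`_` = unresolved) feeds inventory summaries: subclass counts, per-sn-position
saturation (SFA/MUFA/PUFA) and chain-length (S-C 4–10, M-C 11–15, L-C ≥16)
composition, oxidized↔parent matching, method comparisons, and an RSD% < 20
quality-control gate for deuterated standards.

**Synthetic data.** The study's raw tables are not public, so a first-class
generator module reproduces their statistical structure: factorial responses
drawn from the published coefficient models, a three-solvent screening
structure with EE the heterogeneous group, a deterministic 449-species
identification fixture matching every reported inventory tally, and QC
replicate tables. See `docs/methods.md` for what the generators do and do
not emulate.

## Worked example

```bash
python examples/04_pareto_optimization.py
```

prints

```
evaluated grid points: 64000
Pareto front size: 312
compromise setting: 27.1 mL/g, 6.0 min, 56.2 degC
```

Reading: the lyso-lipids want the most solvent (32 mL g⁻¹), the
phospholipids and ceramides the least (16 mL g⁻¹); the 64,000-point grid of
the two group-recovery surfaces yields a 312-point trade-off front whose
utopia-nearest member settles the solvent-to-solid ratio strictly between
the extremes. The other examples (`examples/01…05`) walk through design
construction, the per-subclass significance table, the screening report
(per-class RMSECV/Q²/DQ²/accuracy/sensitivity/specificity for double CV and
bootstrap), and the inventory summary (449 species, 18 subclass groups,
322 TG with 274 SFA / 48 MUFA / 0 PUFA at sn-1).

A thin CLI mirrors the workflows:

```bash
mae-lipidomics simulate --outdir data --seed 1
mae-lipidomics screen data/screening.csv --outdir out/screen
mae-lipidomics optimize data/design.csv data/responses.csv --outdir out/opt --objectives groups
mae-lipidomics annotate data/identifications.csv --outdir out/annot
```

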