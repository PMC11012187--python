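# Methods

This note records the statistical models the package implements, the
defaults and why they were chosen, what the synthetic generators emulate,
and the numerical choices a maintainer should know about.

## Factorial design and per-subclass models

The design is a two-level full factorial in k ≤ 6 factors with optional
center replicates; the study configuration is k = 3 (solvent-to-solid
16–32 mL g⁻¹, time 6–30 min, temperature 50–80 °C) with 3 centers, 11 runs.
Corners are emitted in standard Yates order with the first factor
alternating fastest; run order is treated as metadata only (the original
execution order is unknown and irrelevant to OLS), and
`DesignTable.reorder_to_match` aligns to any externally printed order.
Coded levels are stored as exact integers for corners/centers so the
orthogonality of the 8-term model matrix over the corners is exact.

Each response is fitted by OLS on the fixed basis
[1, x₁, x₂, x₃, x₁x₂, x₁x₃, x₂x₃, x₁x₂x₃]. Inference pools the residual
variance over all runs (df = n − 8 = 3) rather than using pure error from
the center replicates only — standard OLS, and no lack-of-fit analysis is
attempted (a 2-level design cannot estimate quadratic curvature anyway).
Significance tiers are p < 0.05 and p < 0.01; adjusted R² uses
1 − (1 − R²)(n − 1)/(n − 8).

Pretreatment: responses are range-scaled to [0, 1] per column before
fitting. The published intercepts (0.33–0.51) sit where [0, 1]-scaled
responses would put them, and the same scaling is explicit for the
clustering step, so it is adopted as the modelling scale throughout. A
`ResponseTable.scaled` flag prevents double scaling; `fit_ffd` itself fits
whatever it is given.

Interpretation choice: the significance table reports the full 8-term fit
with non-significant entries hidden, not reduced refitted models. No
multiple-testing correction is applied across the 18 responses (nominal
p-values are reported); with 8 truly inert subclasses, about one false
retention per analysis is expected at the 5% level — a documented
limitation, visible in the worked example where TG and TG_1OX slip in.

Numerical choice — exact fits: when residuals are numerically zero
(relative R² within 1e−12 of 1), t statistics are 0/0. The fit is then
declared exact: model p = 0, coefficient p = 0 for estimates above 64 eps
of the coefficient scale and 1 otherwise. This keeps the zero-noise closure
(generate from a coefficient table, refit, recover it identically) well
defined.

## Chemometrics

PCA autoscales by default (subclass sums span orders of magnitude);
components carry a deterministic sign convention — the largest-magnitude
loading of each component is positive. Explained variance is reported
against the total variance of the pretreated matrix.

Hierarchical clustering is UPGMA (average linkage) on squared Euclidean
distances of [0, 1]-scaled variables; heights are therefore on the squared
scale (a Euclidean cut of 2 is a height of 4). `cut(height)` groups leaves
connected by merges strictly below the cut. Newick export writes the
ultrametric tree with leaf depth = height/2.

PLS-DA regresses a one-hot class matrix on autoscaled X with NIPALS PLS2
(components deflated sequentially); class assignment is arg-max over the
predicted columns. Validation defaults: 6 outer × 5 inner stratified,
shuffled folds (36 samples / 3 classes make 6-fold stratification exact),
at most 5 latent variables, inner selection by pooled inner Q². Reported
per class, one-vs-rest on the continuous predicted responses:
RMSECV = √(PRESS/n), Q² = 1 − PRESS/TSS, DQ² (residuals of predictions
beyond their label in the correct direction are zeroed before PRESS, hence
DQ² ≥ Q² always), accuracy, sensitivity, specificity. The bootstrap
(default B = 1000) resamples within class, evaluates out-of-bag, skips
replicates whose out-of-bag set misses a class, and averages; the number of
latent variables is chosen once by a 5-fold CV on the full data unless
given.

## Pareto optimization

PC1/PC2 scores of the retained subclasses get 8-term OLS surfaces; a grid
of n equally spaced levels per factor (default 40 → 64,000 points,
endpoints inclusive) is evaluated in coded units and reported in real
units. Dominance: p dominates q iff p ≥ q in both oriented objectives and
> in at least one; exact ties on both coordinates are all retained. The
front is computed by an O(n log n) sort-and-scan and is invariant under
positive scaling of the objectives. The compromise is the front point
nearest the utopia point after min–max normalization over the front — a
standard knee heuristic chosen because no explicit rule is available; a
flat objective contributes nothing to the distance, and a single-point
front is returned directly.

Objective orientation is genuinely open: which end of a PC favors which
lipid group depends on the data and on the sign convention. The design here
is (a) directions are configuration, default (max, max), with the loadings
always persisted for audit, plus `directions_from_loadings` to orient each
PC toward a named subclass's recovery; and (b) an `objectives="groups"`
mode that skips the PC ambiguity entirely — the responses with
significantly positive vs negative solvent-to-solid coefficients form two
groups, their mean [0, 1]-recovery surfaces (coefficient averages on the
shared basis) are both maximized, and the front exposes the
lyso-vs-phospholipid trade-off directly. Under the packaged generative
truth the two raw PC surfaces happen to share their optimum corner, so
mode (a) can yield a single-point front; mode (b) always shows the
trade-off and puts the compromise solvent-to-solid ratio strictly inside
the experimental range, which is the "extract everything at once" reading.

## Lipid annotation

Grammar: `Class(chain[/|_chain]...)`, chain `[d]C:D[+O|+OO]`; `d` marks a
sphingoid base, `+O`/`+OO` added oxygens; `/` marks resolved sn positions
(in written order), `_` unresolved. Oxidation promotes TG → TG_1OX/TG_2OX
(by total added oxygens) and DG → DG_OX. Parsing failures are typed
(unknown class, chain count, malformed chain). Species identity is the
canonical name keyed by ion mode; positive- and negative-mode PC species
are kept distinct.

Chain-length boundary: long-chain means ≥ 16 carbons (configurable). The
S-C/M-C/L-C classes only partition the chains under that reading, and
16:0 is conventionally long-chain. DG positional isomers sn-1,2 / sn-2,3
are indistinguishable in untargeted data; positions are labelled sn-1/sn-2
by convention. Oxidized↔parent matching compares chain compositions with
added oxygens stripped, ignoring order when positions are unresolved.
QC: RSD% = 100·sd/mean (sample sd), pass iff strictly below the threshold
(default 20%); a zero mean fails with a reason.

## Synthetic data: what it emulates, what it does not

The generators reproduce the statistical structure the analysis assumes,
not the raw measurements:

* **Factorial responses** — Y = Xβ + N(0, σ) per subclass on the scaled
  response scale, with β from the published coefficient table (blank terms
  as exact zeros — they are non-significant, not necessarily zero; a
  documented approximation) and intercept-only models for the 8 inert
  subclasses. Default σ = 0.01: small against effects of 0.02–0.35, so the
  significance pattern is stable at 3 residual df, while the true replicate
  variance is unknowable from the published summary. Hexosylceramides enter
  the 18 response columns as the single column the coefficient table names
  (Hex1Cer).
* **Solvent screening** — 12 replicates per solvent, 18 subclass columns.
  EE is the reference mean; ME is shifted by ±5–10% per subclass (always
  below 20%, matching the reported ME-vs-EE bound) and IE by 25–35% to the
  opposite side, so the group means are ordered ME…EE…IE. Within-group
  CV is 0.05 for ME/IE and 1.6× that for EE: the EE heterogeneity — not a
  mean displacement — is what makes EE the poorly discriminated, overlapping
  group, the structure the diagnostics are meant to detect. A consequence of
  one-vs-rest accuracy is that when all confusions are EE↔ME the two
  accuracies tie; the ranking ME, IE ≥ EE still holds and sensitivity
  separates the classes.
* **Identification fixture** — fully deterministic, no randomness: 449
  species whose subclass/adduct/ion-mode counts and TG/DG per-position
  saturation and chain-length tallies match the reported inventory exactly
  (322 TG; sn-1 274/48/0, sn-2 205/101/16 with 18:1 in 60 species, sn-3
  balanced with 80% long-chain; DG sn-1 87%/13%/0). Per-position fatty-acid
  multisets are arranged into unique species by a greedy constructor that
  pairs the most-abundant remaining chains first. Chains beyond the
  reported constraints are drawn deterministically from a fixed dairy FA
  pool; six oxidized species share chain composition with a non-oxidized
  parent, the rest carry an 11:0 chain absent from the TG pools so no
  accidental parent exists.
* **QC tables** — Gaussian replicate areas at a configurable true RSD per
  deuterated standard.

What passing tests on these data do **not** show: recovery of any real
instrument behaviour (drift, censoring, heteroscedastic peak areas,
correlated subclasses), the actual cluster memberships of the study's
dendrogram, or its PLS-DA statistics — those are data-dependent and the raw
data are not public. The generators give the analysis chain the structure it
assumes; they cannot validate the assumptions themselves.

## Problem sizes and determinism

Defaults keep everything desk-scale: the 11-run design, 36 screening
samples, 64,000-point grids and B = 1000 bootstrap replicates all run in
seconds; the test suite completes in well under a minute on one CPU. Every
stochastic routine takes an explicit seed and is bit-reproducible for a
fixed configuration; workflow outputs are plain delimited text plus a JSON
manifest (config snapshot, input digests, seed, version) from which reruns
are byte-identical.

## Known limitations

* No lack-of-fit or curvature diagnostics from the center replicates; no
  multiple-testing control across subclasses.
* The compromise rule (nearest-to-utopia) is one defensible choice among
  several; desirability functions are out of scope.
* DQ2 is computed per class one-vs-rest; other conventions pool classes.
* The shorthand grammar covers the subclasses of this inventory, not the
  full shorthand nomenclature (no ether/plasmalogen links, no ring or
  hydroxyl annotations beyond +O/+OO).
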