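# Methods

## Model and procedure

For each feature g the observations are modelled as a cell-means one-way
layout over the four conditions of the 2×2 design,
y<sub>gci</sub> ~ N(μ<sub>gc</sub>, σ²<sub>g</sub>), c ∈ {C, A, B, AB},
i = 1…n<sub>c</sub>, on the log2 scale (the scale the data arrive on; the
package never re-transforms). Condition means are estimated by arithmetic
means, and the residual variance is pooled within conditions:
s²<sub>g</sub> = ΣΣ(y<sub>gci</sub>−ȳ<sub>gc</sub>)²/(N−4), d<sub>g</sub> =
N−4. The pooled formula handles unequal replicate counts; balance is never
assumed. A design with d<sub>g</sub> = 0 is rejected; d<sub>g</sub> = 1
is accepted with a warning.

### Variance moderation

Per-feature variances with a handful of replicates are unstable, so they
are shrunk with the standard empirical-Bayes hierarchy: a scaled
inverse-chi-square prior σ²<sub>g</sub> ~ s₀²·d₀/χ²<sub>d₀</sub> gives the
posterior mean

    s̃²_g = (d0·s0² + d_g·s²_g) / (d0 + d_g),    df̃ = d0 + d_g.

The hyperparameters are estimated by moment matching on z<sub>g</sub> =
log s²<sub>g</sub>, whose variance decomposes into a known sampling
component trigamma(d<sub>g</sub>/2) plus trigamma(d₀/2). The excess spread
is inverted through a monotone Brent root-find (bracket grown
geometrically; residual target 1e−8, achieved by an xtol several orders
tighter); s₀² follows from the mean of z<sub>g</sub> with the corresponding
digamma corrections. When the observed spread does not exceed the sampling
component (or the solution exceeds 1e8) d₀ = +∞ is returned: all features
share s₀², and downstream tests use normal instead of Student-t tails
(the df̃ → ∞ limit). Two special cases:

* **All variances exactly equal.** The log-scale bias correction presumes
  sampling scatter; with none present the common value itself is the only
  defensible estimate of s₀², and that is what is returned.
* **d₀ = 0** is admitted as the explicit no-shrinkage limit; it reproduces
  classical per-feature contrast t-tests exactly (verified to 1e−10 in the
  tests against an independent brute-force implementation, and the
  moment estimator itself is cross-checked against Bioconductor limma's
  `squeezeVar` on simulated variances).

Zero-variance ("degenerate") features — all replicates identical — have no
standard error; they are excluded from prior estimation, carried through
with a status flag, and never classified. Features with missing values are
dropped with a logged count rather than imputed; no principled imputation
rule exists for this design and n.

The moderation is the plain variance shrinkage described above; no
mean-variance trend and no robust down-weighting of outlier variances is
applied, and the metadata sidecar records this.

### Partial tests

Strict relations are one-sided tests of contrasts ψ = Σw<sub>c</sub>μ<sub>c</sub>
with t = ψ̂/SE(ψ̂), SE(ψ̂) = s̃<sub>g</sub>·√(Σw²<sub>c</sub>/n<sub>c</sub>),
on df̃ degrees of freedom. Near-equality uses TOST with a symmetric
tolerance [−ε, ε]: both U<sub>upper</sub> = (ε−ψ̂)/SE and U<sub>lower</sub> =
(ψ̂+ε)/SE must exceed t<sub>df̃,1−α</sub>; the TOST p-value is the larger of
the two one-sided p-values. The same ε applies to every near-equality
partial, including the interaction contrast — nothing in the method
motivates contrast-specific tolerances, and a single knob is far easier to
reason about. p-values are canonical; acceptance is the strict comparison
p < α throughout.

### Compounding and classification

Each of the ten forms (× two directions) is the conjunction of its cell's
partial alternatives; the intersection–union principle gives compound
p = max(partial p's), level α whenever each partial is level α. By default
an explicit AB-vs-C one-sided partial is appended to every pattern
(`require_ab_effective=True`), making the taxonomy's premise of an
effective combination a tested component rather than an assumption; the
switch exists because for several cells (synergism, potentiation, emergent,
and additive/redundance up to the tolerance) the premise is already implied
by the other partials, and an implementation that relies on that implication
is equally defensible. Down-regulated variants mirror every strict
inequality; TOST partials are direction-free.

A feature's label is the unique accepted pattern; an empty acceptance set
is `none`, several acceptances are reported `ambiguous` — never silently
resolved by a priority order. Ambiguity is intrinsic, not a bug: whenever a
truly null contrast is tested both ways, with probability ≈ α the strict
one-sided test rejects *while* TOST accepts, so the feature satisfies two
neighbouring cells simultaneously; it also becomes common when standard
errors are small relative to ε. Consequently unique-label sensitivity is
capped near (1−α)^k for a pattern with k near-equality components, which is
why recovery is scored on acceptance-set membership (see below).

No multiple-testing correction across features is applied by default — the
method is defined at per-feature level α. Optional Benjamini–Hochberg
adjustment of the compound p-values across features, per pattern, is
available (`fdr=True`); adjusting compound p-values controls FDR for each
pattern's discovery list separately.

## The synthetic-data generator

The simulator emulates the structure of a small-replicate microarray
combination experiment: 3 replicates per condition by default, i.i.d.
Gaussian noise on the log2 scale, and per-feature variances drawn from the
scaled inverse-chi-square prior (default d₀ = 4, s₀² = 0.04, i.e. a typical
residual SD of 0.2 log2 units — mid-range for RMA-summarised arrays — with
genuine heterogeneity for the moderation step to work on; `d0 = inf` yields
the fixed-σ designs used in the operating-characteristic runs). Planted
patterns satisfy their taxonomy cell exactly: strict single effects at
±effect_size (default 1.0 log2 unit, a clear two-fold change), near-equality
components at exactly 0, and the interaction at ±effect_size for
super/sub-additive cells — except the reductive cells, where an interaction
of −effect_size would null the combined effect entirely and contradict the
premise of an effective combination; they use −effect_size/2 so the
combination retains half the partner's effect. A boundary mode plants
near-equality components at ±ε instead of 0 for TOST size checks.

What the simulator does **not** emulate: probe-level effects, correlated
features, mean-variance trends, batch structure, or non-Gaussian tails.
Passing recovery tests therefore demonstrates correctness of the inferential
machinery under its own assumptions, not robustness to real-array artefacts.

Recovery is scored two ways: **sensitivity** (the planted pattern is in the
acceptance set — the power of its compound test) and **unique-label
sensitivity** (the planted pattern is the sole label). The former is the
operating characteristic of the method; the latter is additionally eroded
by the intrinsic ambiguity described above.

### Operating characteristics at the study conditions

Two fixed-σ regimes recur in the tests and the acceptance script, both with
unit effects, n = 3, α = 0.05, ε = 0.15:

* **σ = 0.1.** Strict partials are essentially always powered (contrast SEs
  ≈ 0.082–0.115 against effects of 1.0). TOST partials are not: equivalence
  of a difference contrast requires |ψ̂| < ε − z₀.₉₅·SE ≈ 0.016 (probability
  ≈ 0.15 under the truth), and for the interaction contrast
  ε − z₀.₉₅·SE < 0, so near-equality can never be accepted at any ψ̂. Hence
  only the pure-inequality forms (synergism, antagonism, both directions)
  are recoverable — sensitivity ≈ 1.0 — while every form containing a
  near-equality component has sensitivity between 0 and ≈ 0.15. This is a
  property of TOST at this noise level, not an implementation limit; the
  size of the synergy compound test at its null boundary is controlled at
  α in the same regime.
* **σ = 0.03.** All TOST partials are powered (ε/SE ≈ 4.3–6.1) and all 20
  direction-specific forms are recovered with acceptance-set sensitivity
  ≥ 0.95 and specificity ≥ 0.95.

Problem sizes used in the shipped checks — 10 000 features for size
control, 500 features per pattern for recovery, 20 000 variances for
hyperparameter recovery, 100 features × 4 contrasts for the classical-t
cross-check — give Monte-Carlo standard errors comfortably below the
asserted tolerances while keeping any single run under a few seconds.

## Numerical choices

* Student-t tails and quantiles from scipy; infinite df̃ switches to the
  standard normal (the exact limit).
* Degenerate features propagate NaN p-values, which the intersection-union
  rule treats as 1 (never accepted).
* TOST at ψ̂ = ±ε gives a one-sided p of exactly 0.5: equivalence is
  unattainable at the tolerance edge for any α < 0.5, and as ε → 0 the
  compound TOST p is ≥ 0.5 for all data.
* Results TSVs serialise estimates with 6 significant digits and p-values
  in scientific notation; the expression/truth writers round-trip floats
  exactly.
* Classification is a pure function of (matrix, targets, config): reruns
  are byte-identical.

## Reproducing the dendritic-cell case study (parity note)

The reference application is GEO series GSE32986: bone-marrow-derived
mouse dendritic cells, 2×2 design of curdlan (100 μg/ml or 1 μg/ml) ×
GM-CSF (5 ng/ml), 3 arrays per condition on Affymetrix Mouse Genome 430 2.0
(45 101 probesets), RMA-normalised. With α = 0.05 and ε = 0.15 the
reference analysis classifies 1 997 probesets in the high-dose setup
(1 005 antagonistic; 49 synergistic-up) and 1 693 in the low-dose setup.
The integration test `tests/test_acceptance.py::TestCaseStudyReproduction`
asserts those counts whenever `data/gse32986/curdlan_100ug.{matrix,targets}.tsv`
(and `curdlan_1ug.*`) are present, and skips otherwise — the matrices are
several megabytes and are not bundled. To reproduce: download the GSE32986
CEL files, RMA-normalise (e.g. Bioconductor `affy::rma`, which emits log2
values), export the expression matrix as TSV with probeset ids in the first
column, write the 12-row targets file, and rename conditions with the
UNSTIMULATED/CURDLAN/GM-CSF/COMBINATION → C/A/B/AB map. Exact count parity
additionally requires matching the reference pipeline's numerics: the RMA
implementation and version, and the variance-moderation variant (this
package implements plain moderation; trend or robust variants would shift
borderline probesets). Small count differences should be interpreted
against that background.

## Known limitations

* Mixed-sign interplay (one constituent up-regulating, the other
  down-regulating) and forms where singles are effective but the
  combination is not are outside the taxonomy and not tested for.
* No probeset-to-gene annotation or enrichment analysis; feature ids are
  passed through verbatim.
* The compound test is conservative for patterns with several partials
  (level *at most* α is guaranteed, attained on the least-favourable null
  boundary).
* TOST power collapses once contrast SEs approach ε/z₁₋α; with n = 3 this
  puts a hard ceiling on detecting near-equality forms at residual SDs
  above ≈ 0.05–0.09 log2 units (difference vs interaction contrasts) for
  the default ε = 0.15. Moderation raises df̃ but cannot lift this ceiling,
  since it is set by the true sampling SE, not by its estimate.
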