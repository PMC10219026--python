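# Methods

## The model

`tatascan` estimates the affinity of the TATA-binding protein (TBP) for a
proximal promoter — expressed as the equilibrium dissociation constant
K_D of the TBP–DNA complex — from the promoter sequence alone, and uses
allele-specific estimates to classify promoter SNPs by their predicted
effect on gene expression.

The sequence model follows the three-stage picture of TBP–promoter
complex formation:

1. **Slide** — TBP translocates along the duplex; this nonspecific
   interaction depends on overall duplex composition.  The slide term is
   minus the mean nearest-neighbour duplex stability (ΔG°37, kcal/mol,
   SantaLucia 1998 unified parameters) over all dinucleotides of the
   promoter.
2. **Stop** — TBP halts at a potential binding site; the stop term is the
   additive position-weight-matrix (PWM) score of a candidate TATA-box
   window.
3. **Bend** — the duplex bends by ~90° and the complex locks; the bend
   term is a dinucleotide bend-propensity sum over the candidate window.

The three terms combine linearly on the −ln(K_D) scale (K_D in mol/L):

    −ln K_D = b₀ + b_slide·slide + b_stop·stop(w*) + b_bend·bend(w*)

where `w*` is the **best site**: the window maximizing the site-dependent
part `b_stop·stop(w) + b_bend·bend(w)` over every window of PWM width on
the given strand (the minimal-K_D window).  Ties break toward the most
upstream window.  Ranking windows by the combined value rather than by
raw PWM score guarantees that a substitution can only move K_D in the
direction implied by its effect on the site values — important for
stable allele comparisons.  Nanomolar K_D and its SE are presentation
derived: `kd_nM = exp(−(−ln K_D))·10⁹`, `se_nM = kd_nM · se_ln`.

Assumptions: promoters are pre-oriented to the transcribed strand (no
reverse-complement scan); TBP occupies a single best site per promoter
(no multi-site occupancy averaging); equilibrium binding (no kinetics).

## Coordinates

The transcription start site is position +1; a length-L promoter covers
positions −L..−1 with **no position 0**.  Internally 0-based indices run
5′→3′; position `pos` maps to index `pos + L`.  Promoter length is a
parameter (default 90 nt) so short printed contexts are first-class
inputs.

## Shipped tables (data, not code)

* `data/tata_pwm.tsv` — 15-position TATA-box frequency matrix
  (`tatascan-default-v1`): a TATAWAWR core (offsets 3–10), weakly
  GC-biased upstream flank, weakly G-biased downstream flank.  Scores are
  ln(freq/0.25).  Any matrix in the same TSV layout is a drop-in
  replacement.
* `data/slide_dinucleotides.tsv` — SantaLucia (1998) unified
  nearest-neighbour ΔG°37 values.
* `data/bend_dinucleotides.tsv` — a package-defined bend-propensity
  ranking following the established base-step flexibility hierarchy
  (pyrimidine–purine steps TA > CA/TG > CG most bendable; G/C-only steps
  stiffest).  Dimensionless; only relative order and spread matter, as
  the calibrated weight sets the scale.

## Coefficients and calibration

Model coefficients are configuration, not constants.  The default set is
obtained by `calibrate_coefficients`: bounded least squares of
(b₀, b_slide, b_stop, b_bend) against −ln(K_D) of six published
worked-example estimates (two promoters × three alleles, shipped in
`data/calibration_examples.tsv`), with b_stop ≥ 0 and b_bend ≥ 0 — a
stronger or more bendable site can only increase affinity.  Because the
best window itself depends on the weights, window selection and fitting
alternate until the selected windows are stable (initially ranked by PWM
score).  Rank-deficient designs (fewer than four examples, or examples
that do not vary all three terms) are rejected.

**Known limitation — non-identifiability.**  On the six calibration
points the stop and bend features are nearly collinear (within-promoter
correlation ≈ 0.98), and the two promoters imply inconsistent
stop-weights; the bounded least-squares optimum puts the within-site
signal on the bend/slide terms and drives b_stop to its zero bound.
Exact interpolation of all six values is impossible for any coefficient
vector (six equations, four unknowns, inconsistent contrasts — the two
CRP minor alleles have nearly identical features yet different published
K_D).  The default calibration therefore reproduces the six values only
to ≈ 0.25 ln-units (≈ 25% in K_D); `CalibrationResult.residuals_ln`
exposes the residuals, and an externally supplied coefficient file
(`load_coefficients`) takes precedence over the fallback whenever a
transcribed coefficient set is available.

## Standard errors

Published worked-example SEs are ≈ 7–11% of K_D, so the default SE model
is relative: `se_ln = 0.10` (10% of K_D), overridable by an absolute
ln-unit SE.  SEs printed in nM propagate to ln-units by the delta method,
`se_ln = SE_nM / Kd_nM`.

## Allele comparison and classification

For ancestral estimate *a* and minor estimate *b*:

    Z = |ln Kd_b − ln Kd_a| / sqrt(se_ln_a² + se_ln_b²),  p = 2(1 − Φ(Z))

Significant K_D increase → affinity *deficiency* → predicted
**underexpression**; significant decrease → *excess* →
**overexpression**.  Health effects per disease process (atherogenesis,
atherosclerosis, atheroprotection) come solely from the annotation
table's per-process effect maps for under-/over-expression.  α defaults
to 0.05 per comparison; multiplicity is handled in the downstream
summaries (a screen-time Bonferroni flag exists for sensitivity checks).

## Screening and counting

The screen runs one comparison per (transcript, SNP) pair; a SNP resolved
at gene level is compared against every transcript of its gene.  Both
tallies — transcript-level comparisons and unique rsIDs — are reported,
since "number of markers" is ambiguous between the two readings.

## Statistics

* `binom_tail` — exact binomial tail (regularized-incomplete-beta
  implementation, verified against rational enumeration in the tests).
* Directional tests are one-sided in the direction of the observed
  excess, Bonferroni-adjusted with caller-supplied multiplicity m (for
  marker summaries, the number of candidate markers in the run).  The
  neutral-drift reference ratio θ₀ has **no default**: it is an external
  whole-genome quantity and must be supplied.
* `lowest_bar_sign_test` — p = 0.5^(s−1) when the focal subset's mean is
  strictly the lowest of s subsets, else p = 1 (ties flagged).
* `mannwhitney_u` — exact null distribution by full enumeration when
  min(n₁, n₂) ≤ 8 with no ties, otherwise the normal approximation with
  tie correction; the method used is recorded in the result.
* The parametric companion comparison of two region means is a two-sample
  z on means with SEMs (`mean_z_test`) — an interpretation, flagged as
  such, since a mean-based "Z-test" admits several formulations.

## Phylostratigraphy

The 29-rank molecular-evolution scale (0 = Cellular organisms … 28 =
Homo) ships as `PAI_SCALE`.  Phylostratigraphic age indices are inputs
read from the annotation TSV, never computed (BLAST-based orthology is
out of scope).  The Venn partition reports all 7 regions (including
empty ones) so any inconsistency between claimed set sizes and the
partition is visible rather than hidden.

## Synthetic data

The generator emulates the study-shaped inputs end to end: a 1067-gene
annotation universe with planted Venn region sizes (default
16/106/0/21/58/856/10) and per-region PAI distributions (clipped normal,
SD 3); 16 hub genes × 7 transcripts with 90-nt promoters; ~45 SNPs per
promoter; a 26-record hub-matched DEG table with planted concordance
24/26.  One global seed; sub-generators draw from streams split by
stable labels, so adding a generator never perturbs existing fixtures.

* **Truth model.**  Parameter-recovery experiments simulate under a known
  coefficient set, `SIM_TRUTH_COEFFICIENTS` (b₀ = 16.5, b_slide = −1.0,
  b_stop = 0.4, b_bend = 0.15): recognition-dominant, so an embedded
  consensus box is always its promoter's operative site, with K_D ≈ 2 nM
  for a consensus-box promoter and tens of nM for boxless background —
  the scale of the worked examples.
* **Box embedding.**  A box is embedded by setting each of 15 positions
  to the consensus base with probability `tata_strength` (1.0 embeds the
  exact consensus).  The embedding is rejection-sampled (≤ 50 draws)
  until the box's combined site value leads every non-overlapping window
  by ≥ 1 ln-unit, so planted effects are not confounded by a competing
  background site; the truth table records the *operative* site (the
  best window after embedding — strength dropout can shift the optimal
  alignment a few bases, because the consensus is internally repetitive).
* **SNP planting.**  Each boxed promoter receives at most one planted
  effect SNP at a high-information box position (row score range ≥ 2
  ln-units).  With probability `direction_bias` the plant moves toward
  the consensus (ancestral allele set to the row's weakest base, minor =
  consensus: expected *excess*), otherwise away (ancestral = consensus,
  minor = weakest: expected *deficiency*).  Setting the ancestral allele
  keeps both directions always plantable — the configured bias is
  realized as an unconstrained Bernoulli draw — and makes the planted
  score change large and sign-unambiguous.  All other SNPs are
  out-of-box background substitutions labelled neutral.
* **DEG planting.**  Concordance is planted as exact counts
  (`round(rate·n)` relief records per process, randomized assignment),
  and the mapped hub genes' effect maps are rewritten for consistency;
  each record carries a unique (gene, direction) pair so planted effects
  are well defined.

What the generator does **not** emulate: allele frequencies and linkage,
real TBP binding energetics (the truth model is a convenient linear
world, not physics), promoter G/C heterogeneity beyond a single
background composition, multi-SNP haplotypes, and real orthology
structure (homology is 1:1 by construction).  Passing recovery tests
therefore demonstrate that the pipeline's inference machinery recovers
planted truth in a well-specified world — not that the default
calibration is accurate on real promoters.

## Numerical choices

* Window-score ties break toward the most upstream window.
* The site search is an exhaustive scan by default; `estimate_affinity`
  also accepts a `fixed_site` pinning the evaluation to one annotated
  window (a sensitivity mode).
* Ambiguity codes: strict input policy rejects them; lenient policy masks
  any window containing one out of the site search.
* p-values from the normal tail are floored at the smallest positive
  double to keep them in (0, 1].
* Exact Mann–Whitney enumeration caps at min(n) ≤ 8 (≤ 12 870 labelings).
* Problem sizes in the test-suite experiments: 200 single-transcript
  promoters × 3 SNPs (~600 comparisons) for planted-effect recovery, 100
  seeded replicates for the box-vs-background contrast, and 200 seeded
  replicates of the 26-record concordance experiment — sizes chosen to
  give stable proportions while keeping each experiment in seconds.

## Known limitations

* The default coefficients are calibrated on six points from two
  promoters and are under-identified (see above); they order alleles
  correctly within each calibration promoter but carry ≈ 25% K_D-scale
  uncertainty.
* Single-site occupancy means a variant that merely relocates the best
  site between near-equal windows yields a near-zero affinity change.
* The p-values of the allele comparison are conditional on the SE model;
  with the default relative SE, |Δln K_D| ≳ 0.28 is the 5% significance
  scale regardless of promoter.
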