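# Methods

## The harmonization model

`phenoz` treats every experiment in a mutant screen as producing, per line,
one signed statistic Z whose null distribution is approximately standard
normal. Three adapters cover the assay catalogue:

* **Pooled two-sample contrast** (`z_linear_contrast`):
  z = (x̄ − ȳ) / √(s²_p (1/n₁ + 1/n₂)) with the usual pooled variance.
  Used for endpoint assays without block structure, for per-dish germination
  percentages at a designated timepoint, and for burst totals.
* **Mann–Whitney** (`z_mann_whitney`): U from midranks,
  z = (U − n₁n₂/2) / √(tie-corrected variance), no continuity correction.
  Used for ordinal 0–3 severity scores, where mean contrasts are
  inappropriate. With no correction, z ↔ p is exactly invertible through Φ,
  which the Z-space FDR adjustment relies on.
* **Random-intercept mixed model** (`z_mixed_timecourse`): at one timepoint,
  y = μ + β·genotype + u_block + ε with u_block ~ N(0, σ²_b). The variance
  ratio λ = σ²_b/σ²_ε is profiled on a log-spaced grid (λ = 0 included, 121
  points over 10⁻⁶…10⁶ plus one 41-point local refinement) maximizing the
  restricted likelihood; because the random effect is a single intercept per
  block, V = I + λ·J is block-diagonal and all REML quantities have O(n)
  closed forms. The genotype contrast and its GLS standard error give
  z = β̂/se(β̂). Time courses are analysed one timepoint at a time — fitting
  each timepoint separately keeps the per-endpoint statistical power
  comparable to endpoint assays. A design with a single block degrades to
  the plain contrast with a logged warning. Agreement with statsmodels
  MixedLM (REML) is ~1e-5 on the estimate and SE in tests.

All p-values come from Φ, never from t distributions. This is a deliberate
property of the pipeline: every statistic must live on the same Z scale for
the downstream steps, and the small-sample anti-conservatism it introduces
is quantified below.

## Bootstrap commensuration

Experiments differ wildly in replication, so Z values are made comparable by
resampling every condition cell (genotype × arm × timepoint) with
replacement to a common size **n_boot = 15**, computing the adapter Z on
each of **B** bootstrap replicates, and averaging. The reference (Col-0)
cell is resampled like any other. Defaults: n_boot = 15; B = 200 (B is a
free parameter of the method — nothing in the procedure pins it — and is
exposed everywhere; the validation experiments below use B = 50 to keep
their runtime proportionate).

Cells are drawn in sorted key order from a per-cell seeded substream, so
matrices are reproducible cell by cell and masking one cell never perturbs
another. Per-replicate |z| is clamped to **Z_CAP = 8** (a two-sided p below
~1e-15 underflows through the quantile function; ±8 keeps degenerate
resamples finite without affecting any realistic value).

Known operating characteristic: when a cell's original size is already 15,
resampling 15-from-15 inflates the null spread of Z̄ to sd ≈ 1.12 (Jensen
effect of 1/ŝe under resampling plus the (n−1)/n bias of the resampled
variance, on top of the t-vs-normal tail difference at 28 df). The
commensuration step is designed for bootstrapping *down* from larger
experiments, where the inflation shrinks; at the worst case n = 15 → 15 with
B = 50 the realized false-discovery level of the 5% tier is ≈ 0.08 rather
than 0.05 (measured over 1200 null families; see `null_fdp_experiment`).
Users who need exact finite-sample control at n = 15 should treat the tier
labels as approximate.

## FDR adjustment in Z-space

Within each experiment (matrix column — `family_scope="per_experiment"`,
with `"global"` available), Z̄ → p = 2(1 − Φ(|Z̄|)) → Benjamini–Hochberg
step-up → p_adj → Z_adj = sign(Z̄)·Φ⁻¹(1 − p_adj/2), clamped to ±Z_CAP;
p_adj = 1 maps to 0 and an underflowed p_adj = 0 to Z_CAP. The chain is
monotone, so |Z_adj| thresholding reproduces BH rejection sets exactly
(verified against statsmodels on 1000 random p-vectors at q = 0.01, 0.05,
0.10). Tiers use the rounded guideline cutpoints |Z_adj| > 1.67, 2, 2.6 for
FDR < 10%, 5%, 1%; the exact quantiles (1.6449, 1.9600, 2.5758) are slightly
smaller, so the tiers are marginally conservative. Missing cells carry
through as missing and do not count toward the family size m.

Alleles of one gene are averaged on the adjusted-Z scale (missing-aware
mean); a raw-Z averaging mode is available through the library for
sensitivity analysis.

## Clustering recipes

* **Ward / Euclidean** on matrix rows, with missing cells set to 0 — the
  neutral "no difference from reference" adjusted Z. Chosen over row
  deletion because screens are systematically sparse (not every line enters
  every assay).
* **Complete linkage / 1 − Pearson** with pairwise-complete columns; every
  row pair must share ≥ 3 measured columns and rows must have nonzero
  variance (hard errors naming the offender).

Both use scipy's linkage (deterministic; ties between equal merge distances
are resolved by scipy's nearest-neighbor-chain order, which is fixed for a
given input — on continuous data exact ties have measure zero). Heights were
verified to 1e-8 against naive O(n³) agglomeration oracles. Newick export
writes half-height branch lengths so leaf-to-leaf path lengths equal
cophenetic distances; a two-leaf merge of height h reads `(A:h/2,B:h/2);`.

## The synthetic screen generator

`phenoz.simulate` emulates the structure of a ~40-line insertion-mutant
screen: a Col-0 reference, 33 genes with six carrying two independent
alleles (39 lines), and assays from five families. Ground truth is the
gene × assay effect matrix in units of residual SD. Family models:

* endpoint / time-course continuous: cell mean = baseline + effect·σ +
  block·σ + N(0, σ²), with a N(0, block_sd²) intercept per experiment block;
* ordinal 0–3: latent N(effect + block, 1) thresholded at fixed cutpoints
  (−1, 0, 1), reproducing a severity scale with a controllable latent shift;
* germination: per-seed germination times ~ Logistic(t50, 5 h) observed
  every 5 h to 51 h, 30 seeds per dish; a +1σ effect advances t50 by 2.5 h,
  so curves are monotone within a dish by construction and genotype shifts
  the half-time. The default scoring endpoint is the median observation
  time, where the logistic is steepest; the final timepoint sits on the
  ceiling (germination near 100%) and carries almost no signal;
* burst totals: log-normal, effects and noise on the log scale.

Defaults: noise_sd = 1 (effects are *defined* in residual-SD units, so this
is a scale convention, not an estimate), block_sd = 0.5 (between-experiment
shifts half as large as residual noise — typical for repeated plant
experiments), n_per_cell = 15 (the commensuration target size), 2–3 blocks
per assay, 15% of gene × assay cells carrying effects of typical magnitude
2σ with both signs. One global seed is split per assay by stable hashing of
the assay id, so adding an assay never changes another assay's draws.

What the generator does **not** emulate: instrument-level noise spectra,
non-Gaussian heavy tails, time-correlated residuals within a plant,
dose-response structure across arms, or genotype-dependent variance.
Passing tests therefore demonstrate correctness of the statistical
machinery under idealized noise, not robustness to real instrument
artifacts.

A note on null calibration: within a single dataset all lines share one
reference cell, so their Z values carry a common shift of the reference's
sampling error (pairwise correlation ≈ 0.5) and are jointly, not
individually, standard normal. Calibration is therefore checked on the
ensemble (500 lines pooled over 50 independent screens, KS < 0.1), and BH's
validity within a family rests on positive regression dependence, which
equicorrelated normals satisfy.

## Validation problem sizes

The built-in experiments (`phenoz.evaluation`) use scaled-down screens
chosen to exercise the full pipeline while keeping the suite quick: null
calibration on 200 datasets of 50 lines × 6 assays (4 continuous + 2
ordinal, single block, B = 50), reported as mean false discovery proportion
per BH family; power on 50 datasets of 20 lines × 3 assays with +2σ planted
in every fifth cell (B = 50), reported as the fraction of planted cells
called at FDR < 5% with the correct sign, benchmarked against a direct
(no-bootstrap) Monte-Carlo oracle of the same layout.

## Known limitations

* Mann–Whitney p-values use the normal approximation at all sample sizes; at
  n ≤ 8 the discrete exact two-sided p can differ from the normal value by
  up to ~0.24 at extreme U. The approximation is what the Z-space pipeline
  requires; for standalone small-sample ordinal tests an exact method is the
  better tool.
* The mixed model supports one random intercept (experiment block); no
  nested or crossed random effects, no Satterthwaite/Kenward–Roger degrees
  of freedom (the pipeline is normal-based by design).
* `single_step_adjust` estimates max-|z| adjusted p by Monte Carlo (100 000
  draws, fixed seed 186283) and floors the result at the unadjusted p; its
  resolution is ~1e-4.
* Gene-level averaging from a bare CSV requires an explicit allele map via
  the library; the CSV schema itself does not carry gene identity.
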