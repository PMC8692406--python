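# Methods

## 1. The qSIP estimation chain

qSIP converts a labeling-induced shift in a taxon's DNA buoyant density into
the excess atom fraction (EAF) of the heavy isotope in that DNA. The chain,
per OTU and per treatment (substrate × ±H₂):

1. **Absolute copies.** Read counts per density fraction are relative; the
   fraction's total 16S copy number from qPCR makes them absolute:
   `copies_ik = f_k · count_ik / Σ_i count_ik`. Fractions with zero
   sequencing depth or zero qPCR signal contribute nothing (they are not
   errors — gradients routinely have empty tails).
2. **Weighted average density (WAD).** `W = Σ_k x_k y_ik` with
   `y_ik = copies_ik / Σ_k copies_ik`. One WAD per OTU per replicate
   incubation; an OTU with zero copies in a replicate is *absent* there, not
   at zero density.
3. **Light baseline.** `W_light` is the unweighted mean of the unlabeled
   control replicate WADs of the same treatment. OTUs absent from every
   control replicate have no baseline and are reported as *not evaluable* —
   deliberately distinct from *unlabeled*.
4. **Isotope model.** GC fraction `G = (W_light − 1.646057)/0.083506`
   (clamped to [0, 1] with a warning when noisy WADs push it outside; the
   unclamped value is what the warning reports), average nucleotide weight
   `M_light = 0.496·G + 307.691`, maximum-labeling weight
   `M_heavymax = M_light + 9.974564 − 0.4987282·G`, observed labeled weight
   `M_lab = (ΔW/W_light + 1)·M_light`, and
   `EAF = (M_lab − M_light)/(M_heavymax − M_light)·(1 − 0.01111233)`.
   EAF is not truncated at 0: negative values are legitimate sampling noise
   and truncation would bias treatment means upward.
5. **Bootstrap CI and labeling call.** The resampling unit is the biological
   replicate WAD; the labeled and control arms are resampled independently
   with replacement, the EAF recomputed 1000 times, and the two-sided 90%
   percentile interval taken. An OTU is called a ¹³C-assimilator iff the
   lower bound exceeds 0. All randomness flows from one seeded generator, so
   results are bit-reproducible for a given seed.

### Known limitation: anti-conservatism at three replicates

With 3 + 3 replicates the percentile bootstrap has only 27 × 27 distinct
resample pairs, and the "lower 90% bound > 0" rule has a one-sided false-call
probability near 0.125 rather than the nominal 0.05 — we measured ≈ 0.125 by
exhaustive enumeration with iid normal and lognormal replicate noise, and
≈ 0.10–0.15 end-to-end on simulated null gradients (the spread across runs is
wide because qPCR noise is shared within a gradient, which correlates calls
across taxa). Users should read labeling calls at this design as having a
~10–15% per-OTU false-positive rate, not 5%. More replicates or a stricter CI
shrink it; both are configurable (`--ci`, replicate count in the design), but
the defaults deliberately match the 3-replicate, 90%-CI protocol that this
kind of study uses.

## 2. Filters

* **Contamination.** An OTU is kept iff its total sample reads are *strictly*
  greater than `ratio` (default 10) × its aggregate reads in the
  contaminant profile (dust/extraction controls); OTUs absent from the
  profile are kept. The boundary (100 reads vs 10 contaminant reads) removes.
* **Low abundance.** Within each substrate × H₂ comparison an OTU must have
  *strictly more than* `min_reads` (default 12) reads summed over density
  fractions in **every** replicate incubation of that comparison — both the
  ¹³C and the control arm, since the WAD comparison needs both. An OTU may
  qualify in one treatment and not another; per-treatment keep sets are
  carried through to the EAF stage and recorded in the filter report.
* Order is fixed: contaminants first, then abundance. Both filters are
  idempotent and read-conserving (tested), and the contamination rule is
  monotone in `ratio`.

Percentages in rendered reports are rounded (two decimals for read removal,
one for labeled-OTU percentages, integers for H₂ percent change); full
precision is kept internally.

## 3. Treatment summaries

Per treatment: labeled/unlabeled counts, percent labeled, and the mean EAF
over *evaluable* OTUs (labeled and unlabeled alike — restricting to labeled
OTUs is available as a sensitivity flag, since which subset enters a
"mean EAF per treatment" is a genuine reporting choice). The H₂ effect per
substrate is `100·(mean_H2 − mean_noH2)/mean_noH2`, with an uncertainty from
bootstrapping OTUs within each arm (how published ± figures for this contrast
were derived is generally unstated; ours is labeled as a bootstrap SD and not
claimed to match any particular convention). Community statistics are
implemented at formula level: Chao1 (`S_obs + f1²/(2f2)`, bias-corrected
`S_obs + f1(f1−1)/(2(f2+1))` when `f2 = 0`), Welch's two-sample t on per-sample
Chao1 values, and ANOSIM (`R = (r̄_between − r̄_within)/(n(n−1)/4)` on average
ranks of Bray–Curtis distances, permutation p with the observed configuration
counted in numerator and denominator).

## 4. Phylogenetic signal

The trait is the per-OTU EAF within one treatment (a binary labeled/unlabeled
mode is provided, since "assimilation patterns" can be read either way); OTUs
not evaluable in a treatment are dropped from the tree before testing.

* **Blomberg's K** = observed MSE₀/MSE over its Brownian-motion expectation
  `(tr(C) − n/Σ(C⁻¹))/(n−1)`, where C is the BM variance–covariance matrix of
  the tree (root-to-MRCA shared path lengths), MSE₀ the mean squared deviation
  from the GLS mean `(1'C⁻¹x)/(1'C⁻¹1)` and MSE the GLS error. Significance by
  tip permutation (default 999 + the observed, which is included in both
  numerator and denominator). K is exactly invariant to affine trait
  transforms (tested).
* **Pagel's λ** multiplies the off-diagonal of C; the mean and scale are
  profiled analytically, and a single symmetric eigendecomposition of
  `D^{-1/2}(C−D)D^{-1/2}` (D = diag C) makes every λ evaluation O(n). λ is
  searched on [0, λ_max] where λ_max = −(1−10⁻⁸)/min-eigenvalue keeps C(λ)
  positive definite (≥ 1 on ultrametric trees). A 201-point scan brackets the
  global maximum before bounded refinement (tolerance 10⁻⁸) — the profile can
  be nearly flat or weakly multimodal; the optimizer agrees with a 10⁻³-step
  grid search to 2×10⁻³ (tested). The p-value is a likelihood-ratio test of
  λ̂ against λ = 0 with the 50:50 boundary mixture (halved χ²₁ tail; p = 1
  when the LRT statistic is ≤ 0). ML, not REML. On a star tree the
  off-diagonal is identically zero and λ is reported as non-identifiable
  rather than as a number.
* Implementation checks: K matches an independent ML implementation
  (R `phytools::phylosig`) to 10⁻⁸ on a fixed 6-tip fixture, λ and its
  log-likelihood to optimizer tolerance (that implementation does not halve
  the boundary LRT; the test accounts for the convention difference).
  Zero-length terminal branches are perturbed by 10⁻⁸ of tree depth with a
  warning (C would be singular).

## 5. The synthetic-gradient generator

The generator emulates the statistical structure of a ¹³C qSIP study, not its
physics: no rotor dynamics, PCR bias, or chimeras, and no FASTQ level — it
produces the count tables, qPCR totals, metadata, contaminant profile and
tree that the pipeline consumes, along with complete ground truth.

* **Design defaults = study conditions.** Three substrates × ±H₂, 3 labeled +
  3 unlabeled-control replicates each, 20 fractions spanning 1.640–1.780
  g ml⁻¹. Default mean true EAFs per treatment (0.13/0.32 bicarbonate ∓/+H₂,
  0.27/0.42 acetate, 0.32/0.14 formate) follow the magnitudes reported for
  rock-hosted incubations and put peak-density shifts in the 0.002–0.028
  g ml⁻¹ range.
* **Community.** Lognormal relative abundances (σ = 1.5); GC ~ Beta(5, 5)
  scaled to [0.3, 0.7]; a pure-birth tree rescaled to unit depth, with
  terminal branches extended 5% past the last speciation (the birth process
  ends exactly at a split, which would otherwise create zero-length terminals
  and a singular trait covariance).
* **Truth.** Either independent per-taxon labeling (probability 0.5, EAF ~
  normal around the treatment mean with 30% CV, floored at 0.005) or
  tree-structured truth (Brownian motion at a chosen λ added to the treatment
  mean, clipped to [0, 1−0.0111]) for end-to-end signal tests.
* **Gradient.** Each taxon's DNA bands as a Gaussian in density (isopycnic
  diffusion approximation) centered at the model's band center for its GC and
  true EAF, σ = 0.006 g ml⁻¹ — so roughly ten fractions carry signal, matching
  typical per-replicate sequencing selections. Masses are integrated over
  fraction bins. qPCR totals get multiplicative lognormal noise (CV 20%,
  mean-corrected — typical inter-fraction qPCR variability; per-fraction
  depth and CV are assumptions exposed in the config, as studies rarely
  report them). Read counts are multinomial at fixed depth (default 20 000
  per fraction). A `top_k_fractions` knob optionally keeps only the
  highest-qPCR fractions per replicate, since real studies sequence a
  selected subset and the selection criterion is usually under-specified.
* **Noise-free mode.** `band_profile="delta"` places each band's mass on the
  two flanking grid points by the lever rule, so the discretized WAD equals
  the band center *exactly*; with `counts_mode="expected"` and `qpcr_cv=0`
  the full pipeline returns every true EAF to ≤ 10⁻⁶ (tested). The Gaussian
  profile cannot support this identity: assigning bin mass to bin centers
  shifts the discretized mean at second order in the bin width, which is why
  the analytic-WAD oracle test uses a 10⁻³ g ml⁻¹ tolerance instead.
* **Contaminants.** Extra taxa present in the contaminant profile (5000 reads
  each) leak into the community at 5×10⁻⁴ relative abundance — low enough
  that the 10× rule removes them, while the rule's boundary itself is tested
  on constructed tables.
* **Determinism.** Everything derives from `SimConfig.seed` through one
  generator; equal seeds give byte-identical outputs (tested).

What passing these tests shows — and does not. Recovery within ±0.05 EAF for
taxa ≥ 0.5% abundance and correct null calibration *under this generator*
demonstrate the estimation chain is implemented correctly and behaves sanely
at realistic noise; they do not certify accuracy on real gradients, where
tube-to-tube density miscalibration (no between-gradient standardization is
applied, as none is described for this protocol), PCR bias, and non-Gaussian
banding add errors the simulator does not model.

## 6. Numerical and interface choices

* Problem sizes in the shipped tests: the full-scale simulated experiment
  uses 600 taxa × 6 treatments × 6 replicates × 20 fractions; null
  calibration pools 10 independent 200-taxon experiments (single-run rates
  vary widely because qPCR noise is shared within a gradient); K calibration
  uses 500 Brownian replicates on 64 tips and λ recovery 200 on 100 tips.
* WAD bootstrap vectorized per OTU; λ likelihood via one eigendecomposition
  per tree. The full pipeline on the 600-taxon experiment runs in seconds.
* BIOM 2.1 (HDF5) tables are read directly through h5py (ids + CSR matrix +
  optional taxonomy); TSV is the primary interchange format.
* Ties in ANOSIM ranks use average ranks; permutation p-values are never 0 by
  construction.
* The CLI (`qsiplab simulate|filter|qsip|summarize|signal|all`) writes outputs
  atomically and a JSON manifest with config, package version, seed, input
  SHA-256 checksums and stage timings; flags override YAML config keys.
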