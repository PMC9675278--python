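# Methods

`methmark` re-creates, as a tested software pipeline, a urine-DNA
methylation-biomarker study design for bladder cancer (BCa): candidate
discovery on paired tumor/nontumor CpG-island microarrays, confirmation by
bisulfite-pyrosequencing methylation index (MtI), and clinical validation
of a methylation-specific real-time PCR (qMSP) assay on urine sediment DNA,
with the full diagnostic-statistics layer on top. Real raw data are not
required: a synthetic-data module generates every input with the
statistical structure the study design implies, and a deterministic
fixture cohort encodes the printed clinical counts exactly.

## Discovery: paired-array filter cascade

Input is a probe x pair matrix of methylation-enrichment log-ratios for
`n_pairs` tumor/nontumor tissue pairs, with each probe mapped to one gene.
The cascade is:

1. drop probes outside the reliable-probe mask (upstream array QC is an
   input, not recomputed);
2. per probe, a two-sided paired t-test on the per-pair tumor - normal
   differences. With two paired conditions, one-way repeated-measures
   ANOVA reduces exactly to this test, which is why a generic "parametric
   ANOVA" array workflow is realized this way;
3. Benjamini-Hochberg step-up adjustment across all reliable probes;
   a probe is significant when adjusted p < alpha (default 0.01);
4. linear-scale fold change `mean(2^tumor) / mean(2^normal)` must reach
   `fc_min` (default 2.0; the upstream study never printed its cutoff, so
   it is configurable), and the shift must be in the hypermethylation
   direction (tumor mean > normal mean);
5. genes with at least `min_probes` (default 2) positive probes become
   candidates, ranked by positive-probe count, then mean fold change,
   then gene id (a deterministic tie-break).

Degenerate probes (zero-variance differences) are handled explicitly: a
constant nonzero difference is treated as infinitely significant (p = 0
sentinel); a constant zero difference carries no evidence and is never
called.

## Methylation index

MtI = 100 x mean of the per-CpG methylated fraction mC/(mC + C) over the
3-5 CpGs of a pyrosequencing amplicon, on the percent scale. A tissue
pair is methylation-positive iff tumor MtI strictly exceeds nontumor MtI.
No minimum CpG count beyond >= 1 is enforced; missing CpGs are simply
absent from the list. No-template controls are flagged records; any
control CpG fraction above 0.05 (configurable) fails batch QC.

## qMSP scoring

Per sample, the assay exports a CT pair: target (methylation-specific
PENK amplicon) and reference (CpG-free COL2A1 amplicon, a control for the
presence of amplifiable bisulfite-converted DNA). The score is

    40-dCT = 40 - (CT_target - CT_reference),

higher meaning more methylated target. Rules, in order:

- reference undetected or above 38 cycles (configurable): the sample is
  *invalid* — there is no evidence DNA was present, so no call is made;
- target undetected with a valid reference: score imputed to 25, a floor
  just below the smallest score producible from detected CT pairs under
  the default bounds (CT_target <= 40, CT_reference >= 25 gives score
  >= 25; asserted in the tests);
- otherwise the formula above.

Classification is positive iff score > cutoff, default 31.35. The strict
">" at the boundary is a convention: an ROC-optimal cutoff chosen between
observed scores makes ">" vs ">=" empirically indistinguishable, so the
choice is documented and configurable rather than load-bearing. Run
adequacy requires a fully methylated control classifying positive, an
unmethylated control not classifying positive, and a non-template control
with no amplification in either channel.

## Diagnostics

- **ROC/AUC** — thresholds are midpoints between distinct scores plus
  +/- infinity sentinels, with the same strict-">" positivity convention
  as the assay. AUC is the Mann-Whitney pair statistic (ties count 1/2),
  which equals trapezoidal integration of the empirical curve; both
  routes and a brute-force pair enumeration are cross-checked in the
  tests. The AUC CI uses the DeLong placement-value variance with a
  normal approximation.
- **Optimal cutoff** — maximum Youden J = sens + spec - 1, ties broken
  toward higher specificity (the larger threshold). A fully degenerate
  curve returns the +infinity sentinel (everything negative).
- **Sensitivity/specificity CIs** — Clopper-Pearson exact binomial
  intervals from beta quantiles. This method choice is pinned by the
  data: the reconstructed study counts (32/37 and 98/106) reproduce the
  printed intervals (71.2-95.5 and 85.7-96.7) to one decimal only under
  the exact interval.
- **Fisher exact test** — conventional two-sided definition: the sum of
  hypergeometric point probabilities not exceeding the observed table's
  (with a 1 + 1e-7 relative tolerance against float noise). Degenerate
  margins return p = 1 by convention.
- **Kruskal-Wallis** — rank-based H with the tie correction
  1 - sum(t^3 - t)/(n^3 - n), p from the chi-square approximation with
  k - 1 degrees of freedom.
- Report parity rounding: percentages to 1 decimal, p values to 3
  decimals, AUC to 3 decimals. Age dichotomizes at 65; the stage table
  contrasts Ta,T1 vs T2-T4; unknown-grade samples are excluded from the
  grade table only.

## Synthetic data

**Arrays.** Planted genes (default 9 of 200, 4 probes each, 9 pairs)
have *all* their probes shifted by `effect_size` (default 1.5) in the
tumor channel — hypermethylation of a CpG island moves its whole probe
set — guaranteeing at least `min_planted_probes` shifted probes.
`noise_sd` (default 0.5) parameterizes the sd of the paired
tumor - normal contrast, the noise scale the paired test actually sees;
each channel receives independent noise of `noise_sd / sqrt(2)`. With
the defaults the planted effect is a 3-sigma separation on the contrast,
at which the cascade recovers >= 95% of planted genes over 20 seeds and
selects essentially no false genes under the null (both asserted in the
acceptance tests). Noise streams are partitioned per pair.

**MtI cohorts.** MtI is bounded on [0, 100] and the study prints only
group means +/- SDs, so the simplest bounded two-moment family is used: a
normal truncated to [0, 100] whose *post-truncation* mean and SD are
matched to the targets by numeric root search over the untruncated
(mu, sigma). Infeasible targets (e.g. an SD at the hard bound
sd^2 >= mean x (100 - mean)) raise a calibration error. The default
calibration table is the printed 3-gene x 3-group mean/SD grid
(e.g. PENK: healthy 6.4 +/- 5.4, benign urologic disease 13.3 +/- 9.9,
BCa 51.0 +/- 23.2). Sampling is inverse-CDF on one uniform per sample,
drawn in sample order, so extending a cohort never perturbs earlier
samples. Per-CpG pyrosequencing fractions are the sample's MtI plus
mean-centered jitter (sd 0.03), clipped to [0, 1].

**qMSP cohorts.** Each stratum has an explicit positivity probability;
per sample, four uniforms decide status, dropout, reference CT and
target CT. Reference CTs are truncated-normal (mean 28, sd 1.5) below
the reference-QC bound; positive samples get a target CT placed in the
region where the score exceeds the cutoff, negative samples drop out
(undetected target, imputed to 25) with probability 0.8 — a split the
study does not report, chosen as a plausible default and configurable —
or get a detected sub-cutoff pair. Default strata follow the validation
design (18 Ta low-grade at 10/18, 37 other cancers at 32/37, 106
controls at 8/106, 8 other urologic cancers at 0).

**What the generators do not emulate:** raw two-color intensities, dye
normalization, probe sequences, bisulfite-conversion errors, pyrogram
chemistry, amplification-curve fitting, or any correlation between a
subject's MtI and their qMSP score. Passing tests therefore demonstrate
that the *analysis* layer is correct and calibrated, not that the assay
would perform identically on real urine DNA.

## Fixture cohort

The printed per-stage validation counts are not all mutually consistent
(the stage-specific percentages cannot be partitioned into integers that
also sum to the printed 32/37), so the deterministic 169-sample fixture
cohort is built only from the explicitly printed fraction pairs, with one
joint stage x grade x call assignment consistent with every printed
margin: Ta low-grade 18 (10 positive), Ta high-grade 4 (4), T1 low-grade
8 (6), T1 high-grade 19 (17), T2-T4 5 (5), one unknown-grade Ta negative;
controls 25 benign + 81 healthy with 8 positives, and 8 other urologic
cancers, all negative. Sex and age are assigned independently within the
positive and negative lists. Every clinical statistic the pipeline
reports from this cohort (42/55 overall, 32/37 headline stratum, 98/106
specificity, all four association tables) is recomputed, not stored.

## Problem sizes and determinism

Default simulations are desk-scale by design: 200 genes x 4 probes x 9
pairs for discovery, cohorts of tens to ~170 samples for the assays, and
n = 10,000 draws where generator calibration is being measured. All
randomness flows from explicit integer seeds through NumPy
`SeedSequence`; every generator is a pure function of (config, seed), and
a full pipeline rerun with the same seed is byte-identical.

## Known limitations

- The qMSP score distributions are a construct; the simulated AUC
  (~0.79 with defaults) is not, and is not meant to be, the study's
  real-data AUC, which depends on unpublished per-sample scores.
- The DeLong-type AUC CI is validated by construction and simulation
  coverage only; no printed AUC CI can be checked without raw scores.
- The truncated-normal MtI family matches two moments; real MtI
  distributions may be skewed or multimodal (e.g. mixtures of shedding
  and non-shedding tumors).
- Fisher p values are exact, but the association tables inherit the
  fixture cohort's arbitrary choices where the study's joint
  distribution was unprinted (sex/age vs stage independence).
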