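# Methods

## Model and estimands

The package works entirely at the summary level. For each variant *i* and
trait pair, the inputs are estimated per-allele effects and standard errors
(β̂, se). Continuous traits (immune-cell phenotypes, plasma protein levels)
are in SD units; the binary outcome is on the log-odds scale, and odds
ratios are produced only at reporting time by exponentiation.

The causal quantities are: the total exposure → outcome effect β; the two
mediation legs β₁ (exposure → mediator) and β₂ (mediator → outcome); the
indirect (mediated) effect β₁β₂; and the mediated proportion β₁β₂/β. All
per-variant inference is normal-theory and two-sided; no small-sample *t*
corrections are applied, following the summary-data convention.

### Estimators

With ratio estimates ρᵢ = β_out,i/β_exp,i and first-order weights
wᵢ = β²_exp,i/se²_out,i:

- **IVW**: β̂ = Σwᵢρᵢ/Σwᵢ, algebraically the zero-intercept weighted
  least-squares regression of β_out on β_exp with weights 1/se²_out. The
  default flavour is multiplicative random effects: the fixed-effects SE
  (Σwᵢ)^(−1/2) is inflated by √max(1, Q/(k−1)) and never deflated, so the
  two flavours coincide under homogeneity. Fixed effects is available by
  flag.
- **MR-Egger**: weighted regression with a free intercept after orienting
  all exposure effects non-negative; the intercept estimates average
  directional pleiotropy under InSIDE. SEs carry a multiplicative
  overdispersion factor floored at 1 (residual-based, df = k−2).
- **Weighted median**: ratios ordered, weights normalised; the estimate is
  the ratio where the midpoint cumulative weight (cumsum − w/2) crosses
  0.5, linearly interpolated between bracketing ratios. SE by parametric
  bootstrap (both effect columns redrawn from their normal approximations),
  n_boot = 1000 by default, seeded.
- **Weighted mode**: peak of the weighted normal-kernel density of the
  ratios on a 512-point grid. Bandwidth = factor × 0.9 × (1.4826 ×
  weighted MAD) × k^(−1/5), guarded away from zero so degenerate
  (all-equal-ratio) inputs return that ratio. Bootstrap SE as above.
- **Wald ratio** for single-instrument exposures: β_out/β_exp with
  first-order SE se_out/|β_exp| (adequate for strong instruments; the
  F > 10 filter upstream enforces that regime).

### Sensitivity battery

Cochran's Q = Σwᵢ(ρᵢ − β̂_fe)² on k−1 df; the Egger intercept test;
leave-one-out IVW re-estimates (flagging variants whose removal flips the
sign or exits the full-set CI); and a simulation-based pleiotropy test:
each variant's weighted squared residual is computed against the IVW slope
re-fitted *without* that variant, the global statistic is the residual sum,
and its null distribution is built by redrawing outcome effects from
normal(fitted, se_out) and pushing every replicate through the same
leave-one-out computation — re-fitting inside the replicates is what keeps
the test calibrated, since the observed residuals carry slope-estimation
noise. Global p is the rank-based tail probability (1+#{≥obs})/(n_sim+1);
per-variant outlier p-values are the analogous single-residual tails with
Bonferroni flagging at 0.05/k.

## Instrument selection

Significance filter at P < 5×10⁻⁸, relaxed per exposure to P < 1×10⁻⁶ when
fewer than `min_snps` (default 1) survive, with the relaxation recorded in
the provenance log. Greedy clumping: sort by (p, variant_id) — the
identifier tie-break makes output independent of input row order — accept
the best, remove linked neighbours (r² > 0.001 within 10,000 kb on the same
chromosome), repeat; pairs missing from the r² matrix count as unlinked and
are logged. Instrument strength uses the single-SNP approximation
F = (β/se)², the only form available from summary data without per-variant
R² decompositions.

## Harmonization

Variants are matched by identifier (positional matching is a documented
extension point), alleles uppercased, coordinates 1-based. Swapped allele
labels sign-flip the outcome effect and reflect its allele frequency;
strand flips of non-palindromic pairs are resolved by complementing.
Palindromic variants are kept only when both allele frequencies are on the
same side of 0.5 and both are outside [limit, 1−limit]; the limit defaults
to 0.42, the common convention for frequency-based strand inference, and is
configurable. Missing frequency on either side drops the variant
(conservative). Every removal carries a reason code, and kept + dropped =
matched by construction.

## Two-step mediation

β₁ is estimated with the exposure's instruments against the mediator, β₂
with the mediator's instruments against the outcome *without* adjusting for
the exposure — the standard summary-data approximation of the controlled
mediator effect, which is exact when the instrument sets are disjoint and
valid. `run_mediation` optionally restricts leg-2 selection to a stated set
of mediator loci, mirroring the cis-QTL convention for protein mediators;
this matters in the vanishing-noise limit, where chain-transmitted
associations of exposure loci become genome-wide significant in the
mediator scan and would otherwise blend into β₂.

The mediated effect uses the Sobel SE √(β₁²se₂² + β₂²se₁²). The normal CI
is cheap and standard but symmetric: against a 10⁶-draw Monte-Carlo product
distribution at leg z-scores ≈ 3–4, the SE agrees within ~2% while the CI
endpoints can differ by ~0.02 because the product distribution is skewed —
acceptable at the leg strengths the screen passes through, and the reason
the mediated *proportion* (a ratio, more skewed still) gets a percentile
parametric bootstrap instead, drawing the indirect and total effects
independently from their normal approximations (equivalent to first order
to redrawing the legs, since the indirect effect enters through its Sobel
SE). Proportions are reported unclipped — with noisy totals they
legitimately exceed 100% — and are flagged unstable, with no CI, when
|β_total| < 3 × se_total, where the ratio distribution is too heavy-tailed
to summarise.

## Screening pipeline

The primary estimate is the Wald ratio for one instrument and IVW
otherwise; Egger/weighted-median/weighted-mode are reported when k permits
(≥3) but significance gating uses the primary estimate only, with the other
estimators serving as direction-consistency checks. Benjamini–Hochberg FDR
(via statsmodels, step-up with cumulative minimum) is applied within one
exposure manifest, treated as a testing family; screens of separate panels
correct separately by default. Per-exposure failures (missing file, no
instruments, no overlap) are recorded in the report row and never abort the
run. All outputs are byte-identical for a fixed config and seed.

Direction classification runs MR both ways between two traits and labels
the pair a→b, b→a, bidirectional, or null from which directions are
significant; a direction with no instruments is reported "untestable",
which is deliberately distinct from a tested null.

## Synthetic generator

The generator emulates the statistical structure of the real data sources:
per-SNP instrument strengths γⱼ ~ N(0.25, 0.05²) (single-SNP F ≈ 69, so the
F > 10 filter passes by construction; a weak-instrument scenario is made by
shrinking γ), independent Gaussian sampling noise at configurable SEs
(default 0.03 for all three traits), sample sizes echoing an immune-trait
GWAS (n ≈ 3.8k), a proteomic cohort (n ≈ 36k) and a large case-control
outcome (n ≈ 392k), optional horizontal pleiotropy αⱼ ~ N(mean, sd) added
to exposure-instrument outcome effects, a configurable fraction of
palindromic allele pairs, and LD blocks realised as near-duplicate records
with noise correlated at r = √r², shipped with an explicit r² matrix
(clumping against a reference panel is out of scope, so LD is always
explicit data). Exposure loci carry the chain — mediator effects β₁γⱼ,
outcome effects (β_direct + β₁β₂)γⱼ + αⱼ — while mediator loci are
independent of the exposure and hit the outcome through β₂ only.

Default chain: β₁ = −0.3, β₂ = −0.6, β_direct = +0.2, 30 + 30 SNPs. This
mirrors the observed pattern of the motivating application — a risk
exposure (total log-odds +0.38) acting partly by suppressing a protective
mediator, true mediated proportion 0.18/0.38 ≈ 47% — and keeps the total
effect strong enough that the mediated proportion is well-defined under the
stability rule above; a direct effect of −0.2 would put the total at −0.02
≈ 0 and make every proportion unstable by construction.

What the generator does **not** emulate: realistic human LD maps,
case-control ascertainment, allele-frequency-dependent power, sample
overlap between cohorts, and winner's-curse selection on the exposure
scan. Passing tests therefore demonstrate estimator and pipeline
correctness under the stated generative model, not robustness to those
real-data pathologies.

## Validation experiments and problem sizes

The Monte-Carlo suites (in `twostepmr.experiments`, driven by the tests and
by `scripts/acceptance.py`) use: 2,000 replicates for IVW type-I error
under the null chain (expected rejection 5% at α = 0.05; multiplicative-RE
IVW is mildly conservative, landing ≈ 4%); 500 replicates × 1,000 inner
simulations for MR-PRESSO calibration; 200 replicates for CI coverage of
β₁, β₂ and the mediated proportion (all ≈ 92–96%); 500 replicates for mean
total-effect recovery; and 200 replicates for Egger-intercept recovery of a
planted 0.02 directional offset. Sizes were chosen so each suite resolves
its target to ~1% Monte-Carlo error while the whole battery runs in well
under a minute.

Two deliberate designs in these experiments:

- The Egger-intercept experiment plants the pleiotropic offset on the
  *null* chain. With a non-null causal effect, sampling noise in the
  exposure effects attenuates the fitted slope (the no-measurement-error
  assumption is violated at finite instrument strength) and the intercept
  absorbs part of the causal effect — ≈ 0.025 at the default scenario,
  larger than the planted 0.02. On the null chain the intercept isolates
  the pleiotropy (recovered 0.021 ± 0.002).
- Mean IVW recovery is asserted to 2.5% relative tolerance, not to
  Monte-Carlo error alone: first-order ratio estimators are attenuated
  toward the null by ≈ 2% at F ≈ 69. This is the standard
  finite-instrument-strength bias of two-sample MR with first-order
  weights, visible here only because the generator's truth is known.

## Known limitations

Single mediators only (no multivariable MR, no joint mediation); no Steiger
directionality filtering; rsID-style matching only; first-order Wald SEs
throughout (slight undercoverage for legs with large |β|·se_exp/β_exp,
partly compensated by the random-effects inflation); the
leave-one-out-based pleiotropy test is rank-based, so its smallest
attainable p is 1/(n_sim+1).
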