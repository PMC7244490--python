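# Methods

## From reads to observations

A read is assigned to a variant if its barcode window (fixed offset,
fixed length) lies within Hamming distance `max_mismatch` of exactly one
barcode in the map. The default `max_mismatch = 1` is safe whenever the
map's minimum pairwise distance is ≥ 3, which both the barcode-map
loader and the synthetic generator enforce; ties and no-hits are never
force-assigned and are reported per sample as unassigned, preserving
the conservation identity assigned + unassigned = total. Zero counts
are stored explicitly so that downstream pseudocount handling is
deterministic.

Relative viability is the ratio of a variant's count proportion in a
drug sample to its proportion in the paired vehicle (DMSO) sample, with
a pseudocount (default 0.5) added to every count so that fully depleted
variants keep a finite ratio. Working in proportions makes the fold
change invariant to sequencing depth, but also means the raw log10 fold
change of a variant is its batch-scaled effect only up to a per-sample
compositional constant (the renormalization of fixed-depth sequencing).
That constant, together with all other per-batch scale and location
structure, is removed by anchoring: within each batch × drug group an
affine map sends the mean log10 fold change of the wild-type control to
0 and of the pathogenic anchor (D2723H) to log10(0.003) ≈ −2.523. The
map is order-preserving by construction; a batch in which the wild-type
mean does not exceed the pathogenic-anchor mean is rejected as a failed
assay. Anchoring is per batch × drug by default (per batch available as
an option) because drugs are analyzed separately and each drug's
selection strength differs. Observations are kept at replicate level,
not averaged: the model's residual term is meant to absorb exactly that
replicate noise.

## The mixture model

The anchored viabilities follow a hierarchical two-component Gaussian
mixture (a VarCall-family model adapted to pooled drug-sensitivity
data):

* likelihood: `f ~ Normal(beta_b + tau_b*eta_v, tau_b*psi)` — each batch
  may shift (`beta_b`) and stretch (`tau_b > 0`) the effect scale, and
  the replicate noise scales with the stretch;
* effects: unknown variants' `eta_v` come from a two-component mixture
  with centres `eta_abn` (abnormal) and `eta_nor` (normal) and spreads
  `sigma1`, `sigma2`; reference-labelled variants contribute to their
  known component; the two anchor controls have `eta` fixed at 0 and
  log10(0.003);
* priors: `kappa1 ~ N(0,5)`, `kappa2 ~ N(1,5)` for the batch-effect
  centres; HalfNormal(0,5) for all five scale parameters; a Beta prior
  per unknown variant on its probability of being abnormal.

`eta_nor` is a fixed constant, estimated by expectation–maximization on
the labelled training data. The EM module fits 1- and 2-component
candidates with equal and unequal variances from a median-split plus
random restarts, discards collapsed starts (a component SD under 1e-6
of the data scale), selects by BIC under the convention
`BIC = 2 logL − k log n` (higher is better), and takes the upper
component's mean as `eta_nor`. Two-stage analysis: the training fit
(labelled variants plus anchors) samples `eta_abn` under
`Normal(log10(0.003), 5)`; the full fit then fixes `eta_abn` at its
training posterior mean and includes the training batches' data, so
batches shared between the stages keep the scale aligned. The
truncation constant of the positive-slope prior `tau_b` is omitted from
the joint density (the conventional treatment of a boundary-constrained
parameter without an explicit truncation statement), keeping the slope
hyperparameters' updates conjugate.

Beta priors in `align_gvgd` mode (nonsense 387/1.07; inside key domains
by grade C65 15.00/3.48, C35–C55 5.38/2.57, C15–C25 3.76/9.00, C0
1.43/73.1; outside domains 1.64/120.44) encode external missense
predictions; domain intervals are closed 1-based amino-acid ranges
(10–40, 2481–3186, 3269–3305) and boundary positions count as inside.
The default mode is noninformative, Beta(1,1). Whether `pi_v` is
sampled (default) or fixed at the Beta mean is a switch on the prior
specification.

## Posterior computation

Sampling is by blocked Gibbs with exact conditional updates:

* conjugate normal draws for `beta_b`, `eta_v`, `eta_abn`, `kappa1`,
  `kappa2`;
* exact Bernoulli/Beta data augmentation for the mixture indicator and
  `pi_v`;
* stepping-out slice sampling (on the log scale) for `tau_b`, `psi`,
  `sigma1`, `sigma2`, `lambda1`, `lambda2`.

The strongly coupled block (batch effects, variant effects, indicator,
component centres/spreads) is swept three times per iteration, which
empirically brings the slowest R-hat from ~1.1 to ~1.03 at negligible
cost. Chains are initialized from data-driven values (batch intercepts
from the wild-type anchor means, slopes from the anchor separation,
effects from per-variant means) with chain-indexed overdispersion.
Defaults are 4 chains × (1500 warmup + 3500 kept) iterations;
convergence is checked with split R-hat on every non-constant parameter
and a fit failing the R-hat < 1.1 contract raises an error naming the
offenders rather than returning silently. Fixed seeds give bit-identical
draws. Tests and the acceptance script run smaller chains (typically
4 × (300 + 900)), which this sampler's mixing makes sufficient for the
experiments performed there; the API defaults are unchanged.

The joint density used for testing marginalizes the mixture indicator
analytically; the augmented sampler targets the same marginal
posterior.

## Bayes factors and classes

For each variant the per-draw posterior probability of abnormal
membership is averaged over draws, converted to odds, and divided by
the prior odds (the Beta prior mean; 0.5 for the control sanity panel);
the result is clamped to [1e−8, 1e8], beyond which finite MCMC carries
no resolution and the tier mapping needs none. By default the per-draw
responsibility integrates the variant effect out analytically — given
the draw's global parameters, `(f − beta_b)/tau_b` is iid
`Normal(eta_v, psi)`, so the responsibility is a closed-form normal
convolution evaluated at the variant's mean — which removes the
slow-mixing effect coordinate from the estimator; the plain
sampled-effect form is available as `method="draws"`. Both estimate
the same posterior probability; the marginal form matches a quadrature
oracle to machine precision when the globals are clamped.

Tiers: fClass 1 BF ≤ 0.003, 2 ≤ 0.053, 3 < 18.7, 4 < 350, 5 ≥ 350
(boundaries as written). Functional zone thresholds are the weakest
labelled-benign effect (normal/intermediate boundary) and the strongest
labelled-pathogenic effect (intermediate/abnormal); non-separating
thresholds are flagged, not raised. Credible intervals are central
posterior quantile intervals.

## Evaluation and diagnostics

Sensitivity and specificity against reference labels carry
Clopper–Pearson exact intervals (via `scipy.stats.binomtest`); the ROC
operating point maximizes the Youden index over all observed score
thresholds in both calling directions, breaking ties toward higher
specificity; LR+ = sensitivity/(1 − specificity), with perfect
specificity reported as infinite rather than an error. Display
rounding follows screening-report convention: whole percentages, one
decimal for LR.

Split R-hat is computed from half-chains with the standard
between/within variance ratio and cross-checked against arviz in the
test suite. QQ diagnostics use the posterior expectation of
`(f − beta_b − tau_b eta_v)/(tau_b psi)` per observation against
standard normal quantiles, with a 95% simultaneous band found by
bisecting the pointwise level over simulated sorted normal samples.
Posterior predictive checks draw 512 parameter samples and generate 612
replicate values per variant, sampling batches proportionally to each
variant's observed batch shares; replicate and observed densities are
Gaussian KDEs evaluated at the same absolute bandwidth (the observed
curve's), since the replicate sets are much larger and would otherwise
be systematically smoother than the observed curve.

## Companion-diagnostic workflow

New variants arrive in small batches containing a four-control panel
(two functionally normal: wild-type and T2515I; two abnormal: Y2660D
and D2723H) plus up to a few queries. Each new batch is classified by a
joint full-mode fit with the reference dataset — the batch terms exist
precisely to absorb the new transfection's offset and stretch — and a
combined analysis pools all new batches with the full reference (not a
controls-matched subset). Combination is a joint hierarchical fit, not
an average of per-batch Bayes factors; on simulated runs the combined
credible interval is no wider than the worst single-batch interval.
The consistency report compares each batch's tier with the combined
call and flags any disagreement while retaining the combined call.

## Synthetic data: what it emulates and what it does not

The generator reproduces the screen's statistical structure: ~10^2
variants with unique distance-≥3 barcodes, exactly one wild-type and
one pathogenic anchor, two-component effects centred at 0 and
log10(0.003), 2 batches × triplicates by default, batch intercepts
(SD 0.3) and strictly positive slopes (1.0 ± 0.15), replicate noise
`tau_b * 0.3`, near-even vehicle pools with log-normal jitter (SD 0.15
in log10, which reproduces the reported ~90% of variants within
0.5–2-fold of the mean), and multinomial reads at fixed per-sample
depth (default 5 × 10^5, giving median per-variant counts in the
thousands). Component spreads default to 0.4 (normal) and 0.3
(abnormal), matching the spans of labelled benign and pathogenic
effects on the anchored scale. FASTQ emission places the barcode in a
fixed synthetic flanking context with constant qualities and
substitution errors only.

Not modelled: PCR amplification bias, duplicate or paired-end reads,
indels, day-0 growth differences, drug-concentration response, and any
cell-biological realism beyond the count model. Passing tests on this
generator therefore demonstrate correctness of the inference machinery
under the model's own assumptions, not robustness to real-data
violations of them (e.g. overdispersed counts or non-Gaussian effect
distributions).

## Numerical choices and limitations

Degenerate inputs are rejected loudly: empty observation tables, data
without anchors in training mode, identical values in EM, negative
counts, missing controls in a companion-diagnostic batch. EM tolerance
is a relative log-likelihood change of 1e-8; the slice sampler uses
width 0.3–0.7 steps on the log scale with stepping-out. The
fold-change pseudocount (0.5) biases extremely depleted variants'
scores slightly toward viability; at the default depths this is well
below the residual noise. The model assumes a common residual scale
`psi` across variants and batches (scaled by `tau_b`) and exactly two
effect components; variants of genuinely intermediate mechanism are
represented only through the intermediate Bayes-factor tier, not a
third component.
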