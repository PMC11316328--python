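# Methods

`svpredict` implements a genomic-prediction study design for a rice-like
diversity panel in which genome-wide variation is split into six marker
classes — biallelic SNPs plus five structural-variant (SV) classes:
MITE-DTX and RLX-RIX transposon insertion polymorphisms, deletions (DEL),
duplications (DUP) and inversions (INV) — and Bayesian kernel regressions
are compared with small neural networks under several marker-input
strategies and two cross-validation designs. Everything runs on synthetic
panels with known genetic architecture, so every stage is testable without
external downloads.

## Data model and preprocessing

Genotypes are dosage matrices: SNPs on {0, 1, 2} (alternate-allele count),
SVs on {0, 1} (absence/presence). SNPs read/write PLINK BED/BIM/FAM (a
minimal bit-packed codec is part of the package) or VCF; SVs use a wide
TSV with marker metadata columns followed by one column per accession.
Binary traits are stored on the {1, 2} class scale and mapped to {0, 1}
(class 1 → 0, class 2 → 1) wherever a loss or likelihood needs it; ordinal
scores are binned so that score 1 becomes class 1 and everything else
class 2; designated quantitative traits (e.g. time to flowering) are
log-transformed with the natural log (a `log_base` flag switches base —
the choice is monotone-equivalent).

Markers with folded minor allele frequency ≤ 0.01 (strict at the boundary)
or missing rate > 1% are removed. For SVs the folded presence frequency
min(f, 1−f) is used; whether a presence or folded frequency is the right
notion for presence/absence markers is genuinely ambiguous, and the folded
choice is flagged in the filter log. Missing genotypes are imputed with
per-marker means (rounded to {0, 1} for SVs) rather than haplotype-based
imputation; the means can be supplied from training rows only, which is
exactly what the cross-validation runner does, keeping test information
out of every statistic.

## Kernels

* Additive GRM (VanRaden): `K = ZZᵀ / (2 Σ_j p_j(1−p_j))`, `Z = M − 2p`.
  SV columns run through the same formula as dosages on {0, 1}; this keeps
  one formula for all six classes and yields a PSD kernel per class.
* Dominance GRM (Vitezica): covariates (−2p², 2pq, −2q²) for genotypes
  (0, 1, 2), `D = HHᵀ / Σ_j (2p_j q_j)²`; defined for diploid SNPs only.
* Additive×additive epistasis: the Hadamard product `A⊙A`, unnormalized by
  default (a flag divides by the mean diagonal); PSD by the Schur product
  theorem.

Allele frequencies are always estimable on a supplied row subset (the
training fold) and reused for test rows. Kernel principal components are
eigenvectors scaled by √eigenvalue, negative numerical eigenvalues clamped
to zero; by default the smallest component count explaining 95% of the
trace is kept (configurable, and capped at desk scale by the runner).

## Bayesian regressions

Both samplers are Gibbs samplers written in numpy.

**Multi-kernel RKHS.** `y = μ + Σ_k g_k + e`, `g_k ~ N(0, K_k σ²_k)`.
Each kernel is eigendecomposed once (eigenvalues below 1e-10 of the
maximum dropped) and its effect is sampled in the eigenbasis, where the
full conditional is diagonal. Variance components use conjugate
scaled-inverse-χ² updates with df = 5 and scales set so the prior modes
split half the phenotypic variance equally among the model terms and half
to the residual (the common R² heuristic of the reference software's
default priors). Six class-specific kernels give the variance-partition
model; additive + dominance + epistatic SNP kernels give the non-additive
SNP model, sharing a single residual.

For variance partitioning the sampler reports, besides the raw σ²_k, the
posterior mean of the *realized* variance of each kernel's genetic values,
Var_n(g_k) per sweep. When a class has more markers than there are
accessions its kernel approaches the identity and σ²_k is partially
confounded with the residual (and with every other kernel's identity-like
part); the realized component variance is the better-identified
attribution and is what the recovery experiments compare against truth.

**BayesC.** `y = μ + Xβ + e` over column-standardized dosages. Each
marker's effect is included with probability π (one common effect
variance, spike at zero otherwise); the inclusion indicator is sampled
from its marginal odds, effects from their conditional normal, and
π ~ Beta parameterized by prior counts p0 = 5 and prior mean π0 = 0.01.
The effect-variance hyperprior (unspecified in the study design) follows
the same df = 5 / R² heuristic with the prior mass spread over the π0·p
markers expected to be active.

**Binary traits** use Albert–Chib probit augmentation: a latent liability
with a single threshold at 0 and residual variance fixed at 1 for
identifiability. **Prediction** masks the phenotypes of the accessions to
be predicted: they never enter the likelihood, are re-imputed from the
current state each sweep (Gaussian case) or drawn unconstrained (probit
case), and the reported prediction is the posterior mean of μ + g — for
binary traits the normal CDF of that mean, a probability in (0, 1).
Requesting a prediction for an unmasked accession is an error (it would be
an in-sample fit).

Chain-length defaults come in two scales: `paper_scale` (100,000
iterations, burn-in 500, thinning 5) matching the published analysis, and
`test_scale` (5,000 iterations) used throughout the test suite. The oracle
cross-checks in the acceptance tests use thin = 1 because the quantity
checked — the maximum deviation over 200 posterior means — needs the full
retained sample count to push Monte-Carlo error below the 0.02 tolerance.

## Neural networks

A small numpy engine provides dense and 1-D convolutional layers
(ReLU/tanh/linear/sigmoid), L1+L2 weight penalties on the hidden layers,
max pooling, inverted dropout placed just before the output layer, a
concatenation trunk for multi-input networks, and SGD / RMSprop / Adam
with the usual library default learning rates (0.01 / 0.001 / 0.001).
Gradients are hand-derived and checked against finite differences.
Hyperparameters live on fixed grids: first-layer units/filters
{16, 38, 64, 128}; hidden dense layers 0–3 (MLP) or 1–3 (CNN); hidden
units {2, 4, 8, 16}; activations {relu, tanh, linear}; optimizers
{adam, rmsprop, sgd}; dropout {0, 0.05, …, 0.3}; penalty weights
{0.001, 0.01, 0.1} with 0 switching a regularizer off. The output is one
unit, linear for quantitative traits, sigmoid for binary.

CNN inputs are markers ordered by (chromosome, position); kernel width 3,
stride 1 and max-pool width 2 are package defaults (these widths are not
part of the stated grids) and configurable. Principal components are never
fed to the CNN — they have no spatial order. The multi-input network gives
each of the six per-class PC blocks its own dense branch and merges them
with a concatenation layer.

Hyperparameter search is successive halving — the allocation mechanism
inside Hyperband: sample n configurations from the grids, train each for a
small epoch budget, promote the best half with the budget multiplied by
the halving factor, down to a single survivor, which is then retrained in
full. Epoch budgets, batch size (32) and early-stopping patience (10) are
config-exposed defaults, not claims about the original analysis. Training
minimizes MSE or binary cross-entropy plus penalties, early-stops on
validation loss, and restores the best epoch's parameters; evaluation-mode
prediction is deterministic (dropout off).

## Cross-validation and the experiment runner

Two designs: k-fold (default k = 10; folds of size ⌊n/k⌋ or ⌈n/k⌉) and
across-population (train on the three large groups, test on the aromatic
and admixed stand-ins). Deep-learning fits split 20% of each training set
off as an inner validation set (floor rounding); Bayesian fits use the
whole training set — so both see identical test sets but different
training subsets, as in the study design.

Marker-input strategies, materialized per fold from training rows only:
COMBINED_VARIANTS (top-k markers by pooled single-marker-regression
p-value across all six classes; ties broken by |t| then marker id so
selection is deterministic), SNPS (top-k SNPs only), LINKED_SNPS (SNPs
with dosage r² ≥ 0.8 to some SV — the genotype-likelihood LD machinery of
the original pipeline is replaced by dosage Pearson r², appropriate for
hard-called genotypes), PCS (the six per-class GRM PC sets merged into one
matrix, MLP input), and MULTIPLE_INPUTS (the six PC blocks for the
six-branch network, or the six GRMs fitted jointly by RKHS). Markers
monomorphic within a training fold are excluded from ranking rather than
erroring; pooled ranking can select zero markers from a class, which is
logged, not corrected.

The runner crosses traits × schemes × folds × (model, strategy) cells,
computes MSE (quantitative) or binary cross-entropy (binary, natural log,
probabilities clipped at 1e-12) on the untouched test fold, and emits one
row per attempted cell — failures keep their row with the error message.
A summary table reports the best (model, strategy) per trait × scheme.
One master seed fans out to fold, simulator, sampler and network seeds via
an md5-based derivation, so runs are reproducible end to end.

## Synthetic panels

The generator emulates the study panel: five population groups with the
real panel's sizes by default (IND 451, JAP 166, AUS 75, ARO 17, ADM 29)
and six marker classes in the real panel's proportions at about 1/205
scale (1,117 SNPs, 254 MITE-DTX, 105 RLX-RIX, 362 DEL, 125 DUP, 37 INV).
Group structure is Balding–Nichols: each marker's ancestral frequency is
uniform on (0.05, 0.95) and each group draws from
Beta(p(1−F)/F, (1−p)(1−F)/F). The default Fst of 0.15 reflects the strong
differentiation among rice groups; the two holdout groups get 2× that, so
the across-population scenario is genuinely harder. SNP genotypes are
binomial(2, p) dosages, SVs Bernoulli presence/absence.

SV–SNP linkage is planted: an SV column is constructed from a partner SNP
column — recoded homozygous (0/2), as in inbred rice lines — with a
flip-noise rate calibrated by bisection until the realized dosage r² is
within ±0.05 of the requested target (a target of 1 is an exact copy).
Defaults plant 56 linked SNPs (~5% of SNPs), mirroring the order of
magnitude of tagged SVs reported at full scale.

Traits: per-class additive effects are Gaussian, then rescaled so each
class's realized genetic-variance share matches the requested share
*exactly* on the realized genotypes; optional dominance (heterozygosity
deviations on causal SNPs) and additive×additive epistasis (products of
centered causal dosages) take stated fractions of the genetic variance.
Environmental noise is scaled to the target narrow-sense h² on the
realized genetic variance. Binary traits threshold the liability (class 1
above the threshold), and a single-class outcome is an error.

What the generator does **not** emulate: coalescent-realistic LD decay
along chromosomes (marker positions are uniform and exchangeable apart
from the planted pairs), recombination maps, genotyping error, and trait
architectures with major-effect loci shared across classes. Passing tests
therefore demonstrate correctness of the machinery and qualitative
behavior under a known architecture, not performance claims about real
rice data.

## Recovery experiments and problem sizes

The test suite and the acceptance script use desk-scale problem sizes
chosen so each experiment isolates what it measures:

* Sampler oracles: n = 200, 20,000 sweeps (RKHS vs the exact joint
  intercept+effect posterior mean, tolerance 0.02); BayesC with π = 1 and
  fixed variances vs ridge, n = 150, tolerance 0.02.
* Variance partition: n = 400, h² = 0.6, shares SNP 0.4 / MITE-DTX 0.3 /
  DEL 0.3 with three null classes. The panel uses Fst 0.02 — shared group
  structure appears in every class's kernel and is inherently
  unattributable between classes, so a weakly structured panel is the
  informative design — and every class marker is causal so the realized
  shares equal the targets by construction. Posterior-mean shares are
  averaged over three replicate panels; the ranking (active above null,
  SNP largest) and a ±0.15 share tolerance then hold robustly.
* BayesC recovery: n = 300, p = 1,000, 20 causal markers with
  equal-magnitude standardized effects (±1), h² = 0.7; at least 15 of the
  top 20 inclusion probabilities are causal, and a permuted phenotype
  leaves every inclusion probability below 0.5.
* End-to-end: n = 300 panels whose trait draws 60% of causal variance
  from SV classes; pooled six-class selection beats SNP-only selection in
  at least 8 of 10 replicates (3-fold CV, multi-kernel RKHS), and the
  distant-group holdout loss exceeds the k-fold loss on average over five
  replicates and two models (RKHS and an MLP tuned with a 4-configuration
  successive-halving search). Raw MSE comparisons across test sets carry a
  scale caveat: the drifted holdout groups have somewhat lower phenotypic
  variance, which works against the expected direction, so the comparison
  is made on replicate-averaged means.

## Known limitations

* The dominance GRM is undefined for presence/absence SVs (no
  heterozygote state); non-additive kernels are SNP-only by design.
* Mean imputation ignores LD; with the ≤1% missingness allowed through
  the filter this is immaterial, but the module should not be used as a
  general imputation tool.
* Variance partitioning between marker classes is weakly identified
  whenever kernels are collinear (shared structure, or marker counts far
  above n); the realized-component-variance report mitigates but cannot
  remove this.
* The neural-network engine is CPU-only numpy and intended for
  desk-scale panels (hundreds of accessions, thousands of markers), not
  for full-size datasets.
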