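# svpredict

Genomic prediction from SNPs **and** structural variants, for quantitative
geneticists and breeders who want to ask: does adding structural variation
(transposon insertion polymorphisms, deletions, duplications, inversions)
to the marker panel improve trait prediction, and do neural networks beat
Bayesian linear models at it?

The package partitions genome-wide variation into six marker classes —
SNPs plus five structural-variant (SV) classes (MITE-DTX, RLX-RIX, DEL,
DUP, INV) — builds class-specific relationship kernels, and compares
Bayesian regressions against small neural networks under several
marker-input strategies and two cross-validation designs. A synthetic
panel generator with known genetic architecture (population structure,
class-specific causal variance shares, planted SV–SNP linkage, liability
thresholds for binary traits) makes every stage testable end to end.

## Models

**Multi-kernel RKHS.** For accession phenotypes *y* and per-class VanRaden
kernels *A₁ … A₆* (one per marker class),

    y = μ1 + Σₖ gₖ + e,   gₖ ~ N(0, Aₖ σₖ²),   e ~ N(0, I σₑ²)

fitted by a Gibbs sampler that works in each kernel's eigenbasis, with
scaled-inverse-χ² updates for all variance components. The same machinery
fits the non-additive SNP model *y = μ + a + d + (a·a) + e* with the
Vitezica dominance kernel *D* and the Hadamard epistatic kernel *A⊙A*.

**BayesC.** *y = μ + Xβ + e* over standardized dosages, each marker
having an effect with probability π (common effect variance, spike at
zero otherwise), π ~ Beta with prior counts p₀ = 5 and prior mean
π₀ = 0.01. Binary traits use probit data augmentation (liability
threshold at 0, residual variance fixed to 1) in both samplers.

**Neural networks.** MLP, 1-D CNN over coordinate-ordered markers, and a
six-branch multi-input network over per-class kernel principal
components, with hyperparameters tuned by successive halving (the
mechanism inside Hyperband) over fixed grids; losses are MSE
(quantitative) and binary cross-entropy (binary).

**Marker-input strategies**, always derived from training folds only:
`COMBINED_VARIANTS` (top-k markers by pooled GWAS p-value across all six
classes), `SNPS` (top-k SNPs), `LINKED_SNPS` (SNPs with dosage r² ≥ 0.8
to a structural variant — SV proxies that are cheap to genotype), `PCS`
and `MULTIPLE_INPUTS` (merged or per-class kernel PCs).

## Worked example

```python
import svpredict as sv
from svpredict import selection, validation

# 1. simulate a structured panel: 5 groups, six marker classes, planted SV-SNP linkage
pop = sv.simulate_population(sv.PopulationConfig(
    n_per_group={"IND": 120, "JAP": 80, "AUS": 50, "ARO": 25, "ADM": 25},
    marker_counts={"SNP": 500, "MITE-DTX": 100, "RLX-RIX": 50,
                   "DEL": 150, "DUP": 60, "INV": 20},
    linked_pairs=[("DEL", 0.9, 20)], seed=11))

# 2. a quantitative trait drawing 60% of its causal variance from SV classes
pheno, truth = sv.simulate_phenotypes(pop.genotypes, sv.TraitSpec(
    h2=0.6, class_variance_shares={"SNP": 0.4, "MITE-DTX": 0.2,
                                   "DEL": 0.3, "DUP": 0.1},
    n_causal_per_class=20, seed=12), groups=pop.groups)

# 3. SNPs tagging structural variants at r^2 >= 0.8
linked = selection.linked_snps(pop.genotypes, threshold=0.8)
print(f"linked SNPs: {len(linked.snp_ids)} (planted: {len(pop.linked_pairs)})")

# 4. compare marker-input strategies under 3-fold and across-population CV
report = validation.run_experiment(pop.genotypes, pheno, validation.ExperimentConfig(
    schemes=("kfold", "across_population"), k=3, top_k=200,
    cells=(("rkhs", "COMBINED_VARIANTS"), ("rkhs", "SNPS"),
           ("bayesc", "COMBINED_VARIANTS")),
    mcmc=sv.MCMCSettings(2000, 400, 2, 0), seed=13))
print(report.summary().to_string(index=False))
```

Output:

```
linked SNPs: 20 (planted: 20)
trait            scheme  model          strategy     loss
trait across_population bayesc COMBINED_VARIANTS 1.670385
trait across_population   rkhs COMBINED_VARIANTS 1.696441
trait across_population   rkhs              SNPS 1.868882
trait             kfold bayesc COMBINED_VARIANTS 1.516141
trait             kfold   rkhs COMBINED_VARIANTS 1.600658
trait             kfold   rkhs              SNPS 1.614506
```

Reading the numbers: the LD scan recovers exactly the 20 planted SV-proxy
SNPs. Because this trait draws most of its causal variance from SV
classes, pooling all six classes (`COMBINED_VARIANTS`, test MSE 1.60
under k-fold) predicts better than SNPs alone (1.61, and 1.70 vs 1.87 on
the distant-group holdout), and the across-population scenario — training
on the three large groups, predicting the small aromatic/admixed
stand-ins — is harder than random k-fold splits for every model.

A `svpredict` command-line tool wraps the same library
(`simulate`, `filter`, `transform`, `grm`, `select`, `link`, `fit-bayes`,
`fit-dl`, `run-cv`); `svpredict run-cv --config cv.yaml --out-prefix out`
runs a full study from a YAML config and writes per-fold losses, mean
losses, and the best (model, strategy) per trait and validation scheme.

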