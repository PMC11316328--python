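"""Cross-validation planning, loss metrics, and the experiment runner.

Two validation designs mirror the study: a 10-fold cross-validation over
randomly partitioned accessions, and an across-population design that
holds out the two small, genetically distant groups (aromatic and admixed
stand-ins) and trains on the rest. Deep-learning fits additionally carve a
20% inner validation split out of each training set; Bayesian fits use the
full training set.

The runner crosses traits x schemes x (model, input strategy) cells,
materializing each marker-input strategy from training rows only:

* ``COMBINED_VARIANTS`` — the top-k markers by pooled GWAS p-value across
  all six classes;
* ``SNPS`` — the top-k SNPs only;
* ``LINKED_SNPS`` — SNPs tagging a structural variant at r² >= 0.8;
* ``PCS`` — principal components of the six class-specific GRMs merged
  into one matrix (MLP input);
* ``MULTIPLE_INPUTS`` — the six PC blocks fed to a six-branch network, or
  the six GRMs fitted jointly by multi-kernel RKHS.

Every training-fold statistic (allele frequency, imputation mean, GWAS
p-value, LD pair, standardization constant) is computed on training rows
alone; test phenotypes only ever meet the final loss.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from . import bayes, deep, kernels, selection
from .containers import MARKER_CLASSES, GenotypeMatrix, PhenotypeTable
from .io import impute_missing

STRATEGIES = ("COMBINED_VARIANTS", "SNPS", "LINKED_SNPS", "PCS", "MULTIPLE_INPUTS")
MODELS = ("rkhs", "bayesc", "mlp", "cnn", "mlp_pcs", "multi_input")

#: (model, strategy) cells implemented, mirroring the study's model table.
DEFAULT_CELLS = (
    ("rkhs", "COMBINED_VARIANTS"), ("rkhs", "SNPS"), ("rkhs", "LINKED_SNPS"),
    ("rkhs", "MULTIPLE_INPUTS"),
    ("bayesc", "COMBINED_VARIANTS"), ("bayesc", "SNPS"), ("bayesc", "LINKED_SNPS"),
    ("mlp", "COMBINED_VARIANTS"), ("mlp", "SNPS"), ("mlp", "LINKED_SNPS"),
    ("cnn", "COMBINED_VARIANTS"), ("cnn", "SNPS"), ("cnn", "LINKED_SNPS"),
    ("mlp_pcs", "PCS"), ("multi_input", "MULTIPLE_INPUTS"),
)


# ---------------------------------------------------------------------------
# fold planning
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    fold_id: str
    train: np.ndarray
    test: np.ndarray
    validation: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    scheme: str = "kfold"
    seed: int = 0

    def __post_init__(self) -> None:
        sets = [set(self.train), set(self.validation), set(self.test)]
        if sets[0] & sets[2] or sets[0] & sets[1] or sets[1] & sets[2]:
            raise ValueError("train/validation/test sets must be disjoint")
        if len(self.test) == 0:
            raise ValueError("test set must be nonempty")


def kfold_plan(n: int, k: int = 10, seed: int = 0) -> list[FoldPlan]:
    """Random partition into k folds of size floor(n/k) or ceil(n/k); each
    fold serves once as the test set. Deterministic given ``seed``."""
    if k <= 1:
        raise ValueError("k must be > 1")
    if n < k:
        raise ValueError("need n >= k")
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        FoldPlan(fold_id=f"fold{i}", train=tr, test=te, scheme="kfold", seed=seed)
        for i, (tr, te) in enumerate(splitter.split(np.arange(n)))
    ]


def across_population_plan(groups: np.ndarray,
                           holdout_labels=("ARO", "ADM")) -> FoldPlan:
    """Test on the holdout groups, train on everything else."""
    groups = np.asarray(groups)
    test = np.flatnonzero(np.isin(groups, list(holdout_labels)))
    if test.size == 0:
        raise ValueError(f"no accessions in holdout groups {holdout_labels}")
    train = np.flatnonzero(~np.isin(groups, list(holdout_labels)))
    if train.size == 0:
        raise ValueError("holdout covers every group: empty training set")
    return FoldPlan(fold_id="across_population", train=train, test=test,
                    scheme="across_population")


def inner_split(train: np.ndarray, fraction: float = 0.2,
                seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Split a training set into (subtrain, validation), validation share =
    floor(fraction * n). Used only for deep-learning fits."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    train = np.asarray(train)
    if train.size < 5:
        raise ValueError("training set too small to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(train)
    n_val = int(np.floor(fraction * train.size))
    return np.sort(perm[n_val:]), np.sort(perm[:n_val])


# ---------------------------------------------------------------------------
# loss metrics
# ---------------------------------------------------------------------------

def mse(observed, predicted) -> float:
    """Mean squared error (quantitative-trait loss)."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.size == 0:
        raise ValueError("observed/predicted must share a nonzero length")
    if np.isnan(observed).any() or np.isnan(predicted).any():
        raise ValueError("missing values in loss inputs")
    return float(np.mean((observed - predicted) ** 2))


def binary_cross_entropy(labels, probabilities, eps: float = 1e-12) -> float:
    """Binary cross-entropy, natural log, probabilities clipped to
    [eps, 1-eps]. Labels must be 0/1."""
    y = np.asarray(labels, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape or y.size == 0:
        raise ValueError("labels/probabilities must share a nonzero length")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must lie in {0, 1}")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


# ---------------------------------------------------------------------------
# experiment runner
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Everything the runner needs besides the data themselves."""

    traits: list[str] | None = None  # default: every trait in the table
    schemes: tuple[str, ...] = ("kfold",)
    cells: tuple[tuple[str, str], ...] = DEFAULT_CELLS
    k: int = 10
    top_k: int = 10_000
    ld_threshold: float = 0.8
    ld_window: int | None = None
    n_pcs: int | None = None  # None -> smallest count explaining 95% of trace
    mcmc: bayes.MCMCSettings = field(default_factory=bayes.MCMCSettings.test_scale)
    tuner: deep.SearchSettings | None = None  # None -> fixed default spec
    epochs: int = 100
    batch_size: int = 32
    patience: int = 10
    inner_val_fraction: float = 0.2
    holdout_labels: tuple[str, ...] = ("ARO", "ADM")
    snp_kernel_ade: bool = True  # additive+dominance+epistatic for SNP-only RKHS
    seed: int = 0

    def digest(self) -> str:
        return hashlib.md5(repr(self).encode()).hexdigest()[:8]

    def derive_seed(self, *labels) -> int:
        """Fan the master seed out to a stage-specific seed (< 2^31)."""
        h = hashlib.md5(("|".join(map(str, (self.seed,) + labels))).encode())
        return int.from_bytes(h.digest()[:4], "little") % (2**31)


@dataclass
class LossReport:
    rows: pd.DataFrame  # trait, model, strategy, scheme, fold, loss, metric, seed, config

    def summary(self) -> pd.DataFrame:
        """Mean loss per trait x scheme x (model, strategy) cell."""
        ok = self.rows.dropna(subset=["loss"])
        return (ok.groupby(["trait", "scheme", "model", "strategy"], as_index=False)
                  ["loss"].mean())

    def minimum_loss_table(self) -> pd.DataFrame:
        """Best (model, strategy) per trait x scheme — the study's headline
        report shape (trait rows, one winner per validation strategy)."""
        s = self.summary()
        idx = s.groupby(["trait", "scheme"])["loss"].idxmin()
        return s.loc[idx].reset_index(drop=True)


class _FoldContext:
    """Training-fold statistics and strategy inputs, built without ever
    touching a test-row phenotype."""

    def __init__(self, G: GenotypeMatrix, y: np.ndarray, kind: str,
                 plan: FoldPlan, cfg: ExperimentConfig, trait: str):
        self.plan = plan
        self.kind = kind
        self.cfg = cfg
        train = plan.train
        with np.errstate(invalid="ignore"):
            train_means = np.nanmean(G.dosages[train], axis=0)
        if np.isnan(train_means).any():
            raise ValueError("marker fully missing within a training fold")
        self.G = impute_missing(G, means=train_means)
        self.y = y
        self.freqs = kernels.allele_frequencies(self.G, rows=train)
        self.scan = selection.gwas_scan(self.G.subset(rows=train), y[train],
                                        trait=trait, fold_id=plan.fold_id)
        self._marker_sets: dict[str, list[str]] = {}
        self._pc_blocks = None

    # ---- marker-id sets per strategy -----------------------------------
    def marker_ids(self, strategy: str) -> list[str]:
        if strategy in self._marker_sets:
            return self._marker_sets[strategy]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if strategy == "COMBINED_VARIANTS":
                ids = selection.select_top_k(self.scan, self.cfg.top_k)
            elif strategy == "SNPS":
                ids = selection.select_top_k(self.scan, self.cfg.top_k, classes="SNP")
            elif strategy == "LINKED_SNPS":
                linked = selection.linked_snps(
                    self.G.subset(rows=self.plan.train),
                    threshold=self.cfg.ld_threshold, window=self.cfg.ld_window)
                ids = linked.snp_ids
                if not ids:
                    raise ValueError("no linked SNPs found in this fold")
            else:
                raise ValueError(f"no marker set for strategy {strategy!r}")
        self._marker_sets[strategy] = ids
        return ids

    def genotype_subset(self, strategy: str) -> GenotypeMatrix:
        ids = self.marker_ids(strategy)
        pos = pd.Index(self.G.markers["id"]).get_indexer(ids)
        return self.G.subset(cols=np.sort(pos))

    def design(self, strategy: str) -> np.ndarray:
        """Standardized marker matrix (training statistics), all rows."""
        sub = self.genotype_subset(strategy)
        X, _, _ = bayes.standardize_design(sub.dosages, rows=self.plan.train)
        return X

    def cnn_design(self, strategy: str) -> np.ndarray:
        """Standardized markers ordered by (chromosome, position)."""
        sub = self.genotype_subset(strategy)
        order = np.lexsort((sub.markers["pos"].to_numpy(),
                            sub.markers["chrom"].to_numpy()))
        sub = sub.subset(cols=order)
        X, _, _ = bayes.standardize_design(sub.dosages, rows=self.plan.train)
        return X

    # ---- kernels and PCs ------------------------------------------------
    def additive_kernel(self, strategy: str) -> kernels.KernelMatrix:
        sub = self.genotype_subset(strategy)
        return kernels.additive_grm(sub, rows=self.plan.train)

    def snp_ade_kernels(self, strategy: str) -> list[kernels.KernelMatrix]:
        sub = self.genotype_subset(strategy)
        snp = sub.subset(cols=sub.class_columns("SNP"))
        A = kernels.additive_grm(snp, rows=self.plan.train)
        D = kernels.dominance_grm(snp, rows=self.plan.train)
        E = kernels.epistatic_grm(A)
        return [A, D, E]

    def class_kernels(self) -> tuple[list[kernels.KernelMatrix], list[str]]:
        """One additive GRM per marker class present (the six-kernel model)."""
        out, names = [], []
        for cls in MARKER_CLASSES:
            mask = self.G.class_columns(cls)
            if mask.sum() < 2:
                continue
            sub = self.G.subset(cols=mask)
            try:
                out.append(kernels.additive_grm(sub, rows=self.plan.train))
                names.append(cls)
            except ValueError:
                continue
        if not out:
            raise ValueError("no usable marker class for the multi-kernel model")
        return out, names

    def pc_blocks(self) -> list[np.ndarray]:
        if self._pc_blocks is None:
            ks, _ = self.class_kernels()
            self._pc_blocks = [kernels.grm_pcs(K, self.cfg.n_pcs).scores for K in ks]
        return self._pc_blocks


def _fit_bayes_cell(ctx: _FoldContext, model: str, strategy: str) -> np.ndarray:
    cfg, plan = ctx.cfg, ctx.plan
    response = "ordinal" if ctx.kind == "binary" else "gaussian"
    mask = np.zeros(len(ctx.y), dtype=bool)
    mask[plan.test] = True
    settings = bayes.MCMCSettings(cfg.mcmc.n_iter, cfg.mcmc.burn_in, cfg.mcmc.thin,
                                  cfg.derive_seed("mcmc", plan.fold_id, model, strategy))
    if model == "rkhs":
        if strategy == "MULTIPLE_INPUTS":
            ks, names = ctx.class_kernels()
        elif strategy in ("SNPS", "LINKED_SNPS") and cfg.snp_kernel_ade:
            ks = ctx.snp_ade_kernels(strategy)
            names = ["additive", "dominance", "epistatic"]
        else:
            ks, names = [ctx.additive_kernel(strategy)], ["additive"]
        spec = bayes.KernelRegressionSpec(ks, kernel_names=names, response=response)
        summary = bayes.fit_rkhs(ctx.y, spec, settings, mask=mask)
    else:  # bayesc
        X = ctx.design(strategy)
        spec = bayes.BayesCSpec(X, response=response)
        summary = bayes.fit_bayesc(ctx.y, spec, settings, mask=mask)
    return bayes.predict(summary, plan.test)


def _fit_deep_cell(ctx: _FoldContext, model: str, strategy: str) -> np.ndarray:
    cfg, plan = ctx.cfg, ctx.plan
    out_act = "sigmoid" if ctx.kind == "binary" else "linear"
    seed = cfg.derive_seed("dl", plan.fold_id, model, strategy)
    subtrain, val = inner_split(plan.train, cfg.inner_val_fraction,
                                seed=cfg.derive_seed("split", plan.fold_id))

    if model == "mlp_pcs":
        X = np.hstack(ctx.pc_blocks())
        arch = "mlp"
    elif model == "multi_input":
        blocks = ctx.pc_blocks()
        if len(blocks) != 6:
            raise ValueError(f"multi-input network needs 6 PC blocks, have {len(blocks)}")
        X = blocks
        arch = "multi_input"
    elif model == "cnn":
        X = ctx.cnn_design(strategy)
        arch = "cnn"
    else:
        X = ctx.design(strategy)
        arch = "mlp"

    def rows(idx):
        return [b[idx] for b in X] if isinstance(X, list) else X[idx]

    y = ctx.y
    if cfg.tuner is not None:
        tset = deep.SearchSettings(cfg.tuner.n_configs, cfg.tuner.halving_factor,
                                   cfg.tuner.min_epochs, cfg.batch_size,
                                   cfg.patience, seed)
        result = deep.hyperband_search((arch, out_act), tset, X=rows(subtrain),
                                       y=y[subtrain], X_val=rows(val), y_val=y[val])
        spec = result.best_spec
    else:
        spec = deep.NetworkSpec(arch=arch, out_activation=out_act)
    fitted = deep.train(spec, rows(subtrain), y[subtrain], rows(val), y[val],
                        epochs=cfg.epochs, batch_size=cfg.batch_size,
                        patience=cfg.patience, seed=seed)
    pred = fitted.predict(deep._prep_input(spec, rows(plan.test)))
    return pred.ravel()


def run_experiment(G: GenotypeMatrix, P: PhenotypeTable,
                   config: ExperimentConfig) -> LossReport:
    """Cross every trait x scheme x fold x (model, strategy) cell.

    Returns one loss row per attempted cell; failed cells keep their row
    with a NaN loss and the error message, never silently dropped.
    """
    P = P.aligned_to(G.accession_ids)
    traits = config.traits or P.traits
    rows = []
    digest = config.digest()
    for trait in traits:
        kind = P.trait_kinds[trait]
        y = P.values(trait)
        if np.isnan(y).any():
            raise ValueError(f"trait {trait!r} has missing values; drop or impute first")
        for scheme in config.schemes:
            if scheme == "kfold":
                plans = kfold_plan(G.n_accessions, config.k,
                                   seed=config.derive_seed("kfold", trait))
            elif scheme == "across_population":
                plans = [across_population_plan(P.groups, config.holdout_labels)]
            else:
                raise ValueError(f"unknown scheme {scheme!r}")
            for plan in plans:
                ctx = _FoldContext(G, y, kind, plan, config, trait)
                for model, strategy in config.cells:
                    row = {"trait": trait, "model": model, "strategy": strategy,
                           "scheme": scheme, "fold": plan.fold_id,
                           "metric": "binary_cross_entropy" if kind == "binary" else "MSE",
                           "seed": config.seed, "config": digest,
                           "loss": np.nan, "error": ""}
                    try:
                        if model in ("rkhs", "bayesc"):
                            pred = _fit_bayes_cell(ctx, model, strategy)
                        elif model in ("mlp", "cnn", "mlp_pcs", "multi_input"):
                            pred = _fit_deep_cell(ctx, model, strategy)
                        else:
                            raise ValueError(f"unknown model {model!r}")
                        y_test = y[plan.test]
                        if kind == "binary":
                            row["loss"] = binary_cross_entropy(y_test, pred)
                        else:
                            row["loss"] = mse(y_test, pred)
                    except Exception as exc:  # logged, not dropped
                        row["error"] = f"{type(exc).__name__}: {exc}"
                    rows.append(row)
    return LossReport(pd.DataFrame(rows))
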