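"""Fold planning, loss metrics, and the experiment runner with its
leakage guarantees."""

import numpy as np
import pytest

import svpredict as sv
from svpredict import validation
from svpredict.bayes import MCMCSettings
from svpredict.deep import SearchSettings
from svpredict.validation import _FoldContext, ExperimentConfig


class TestKfoldPlan:
    def test_panel_sized_fold_multiset(self):
        plans = validation.kfold_plan(738, k=10, seed=0)
        sizes = sorted(len(p.test) for p in plans)
        assert sizes == [73, 73, 74, 74, 74, 74, 74, 74, 74, 74]

    def test_partition_property(self):
        plans = validation.kfold_plan(53, k=5, seed=1)
        all_test = np.concatenate([p.test for p in plans])
        assert sorted(all_test) == list(range(53))
        for p in plans:
            assert set(p.train) | set(p.test) == set(range(53))
            assert not set(p.train) & set(p.test)

    def test_seed_determinism(self):
        a = validation.kfold_plan(100, 10, seed=3)
        b = validation.kfold_plan(100, 10, seed=3)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.test, pb.test)

    def test_degenerate_k_rejected(self):
        with pytest.raises(ValueError):
            validation.kfold_plan(10, k=1)


class TestAcrossPopulationPlan:
    def test_panel_group_counts(self):
        groups = np.repeat(["IND", "JAP", "AUS", "ARO", "ADM"],
                           [451, 166, 75, 17, 29])
        plan = validation.across_population_plan(groups)
        assert len(plan.test) == 46
        assert len(plan.train) == 692
        assert set(groups[plan.test]) == {"ARO", "ADM"}

    def test_total_holdout_rejected(self):
        groups = np.array(["ARO", "ADM", "ARO"])
        with pytest.raises(ValueError, match="empty training"):
            validation.across_population_plan(groups)

    def test_missing_holdout_rejected(self):
        with pytest.raises(ValueError, match="holdout"):
            validation.across_population_plan(np.array(["IND", "JAP"]))


class TestInnerSplit:
    @pytest.mark.parametrize("n,expected_val", [(100, 20), (101, 20), (99, 19)])
    def test_validation_share_rounding(self, n, expected_val):
        tr, val = validation.inner_split(np.arange(n), 0.2, seed=0)
        assert len(val) == expected_val
        assert len(tr) + len(val) == n
        assert not set(tr) & set(val)

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            validation.inner_split(np.arange(10), 1.0)


class TestMetrics:
    def test_mse_values(self):
        assert validation.mse([1.0, 2, 3], [1.0, 2, 3]) == 0.0
        assert validation.mse([0.0, 0.0], [1.0, 3.0]) == pytest.approx(5.0)

    def test_mse_quadratic_homogeneity(self, rng):
        y, p = rng.normal(size=20), rng.normal(size=20)
        assert validation.mse(3 * y, 3 * p) == pytest.approx(9 * validation.mse(y, p))

    def test_mse_length_mismatch(self):
        with pytest.raises(ValueError):
            validation.mse([1.0], [1.0, 2.0])

    def test_bce_values(self):
        assert validation.binary_cross_entropy(
            [0, 1, 0, 1], [0.5] * 4) == pytest.approx(np.log(2), abs=1e-9)
        assert validation.binary_cross_entropy(
            [1, 0], [0.9, 0.2]) == pytest.approx(0.16425, abs=1e-5)
        assert validation.binary_cross_entropy([1, 0], [1.0, 0.0]) < 1e-10

    def test_bce_label_domain(self):
        with pytest.raises(ValueError, match="labels"):
            validation.binary_cross_entropy([1, 2], [0.5, 0.5])


def _smoke_inputs(seed=0, n_causal=15):
    cfg = sv.PopulationConfig(
        n_per_group={"IND": 40, "JAP": 30, "AUS": 20, "ARO": 15, "ADM": 15},
        marker_counts={"SNP": 120, "MITE-DTX": 30, "RLX-RIX": 20,
                       "DEL": 40, "DUP": 20, "INV": 10},
        linked_pairs=[("DEL", 1.0, 5), ("MITE-DTX", 0.9, 3)], seed=seed)
    pop = sv.simulate_population(cfg)
    spec = sv.TraitSpec(
        h2=0.6, class_variance_shares={"SNP": 0.5, "DEL": 0.5},
        n_causal_per_class=n_causal, seed=seed + 1)
    pheno, _ = sv.simulate_phenotypes(pop.genotypes, spec, groups=pop.groups)
    return pop, pheno


SMOKE_CELLS = (("rkhs", "COMBINED_VARIANTS"), ("bayesc", "COMBINED_VARIANTS"),
               ("mlp", "SNPS"), ("cnn", "LINKED_SNPS"),
               ("mlp_pcs", "PCS"), ("multi_input", "MULTIPLE_INPUTS"))


def _smoke_config(**kw):
    base = dict(
        schemes=("kfold", "across_population"), cells=SMOKE_CELLS, k=2,
        top_k=60, n_pcs=8, mcmc=MCMCSettings(600, 100, 2, 0),
        tuner=SearchSettings(n_configs=2, min_epochs=1), epochs=8, patience=3,
        seed=5)
    base.update(kw)
    return ExperimentConfig(**base)


@pytest.fixture(scope="module")
def smoke_report():
    pop, pheno = _smoke_inputs()
    return validation.run_experiment(pop.genotypes, pheno, _smoke_config())


class TestRunExperiment:

    def test_one_row_per_cell_and_fold(self, smoke_report):
        rows = smoke_report.rows
        # kfold contributes k folds, across-population one
        assert len(rows) == len(SMOKE_CELLS) * (2 + 1)
        assert (rows["error"] == "").all(), rows.loc[rows["error"] != "", "error"]
        assert (rows["loss"] >= 0).all()

    def test_summary_and_minimum_loss_shapes(self, smoke_report):
        summary = smoke_report.summary()
        assert len(summary) == len(SMOKE_CELLS) * 2
        best = smoke_report.minimum_loss_table()
        assert len(best) == 2  # one winner per trait x scheme
        assert set(best["scheme"]) == {"kfold", "across_population"}

    def test_binary_trait_uses_cross_entropy(self):
        pop, _ = _smoke_inputs()
        spec = sv.TraitSpec(
            kind="binary", h2=0.6, class_variance_shares={"SNP": 0.5, "DEL": 0.5},
            n_causal_per_class=15, seed=9)
        pheno, _ = sv.simulate_phenotypes(pop.genotypes, spec, groups=pop.groups)
        cfg = _smoke_config(schemes=("kfold",),
                            cells=(("rkhs", "COMBINED_VARIANTS"), ("mlp", "SNPS")))
        report = validation.run_experiment(pop.genotypes, pheno, cfg)
        assert (report.rows["metric"] == "binary_cross_entropy").all()
        assert (report.rows["error"] == "").all()
        assert np.isfinite(report.rows["loss"]).all()

    def test_leakage_guard_selections_blind_to_test_phenotypes(self):
        """Perturbing test-fold phenotypes changes no selection and no
        training statistic, hence identical predictions."""
        pop, pheno = _smoke_inputs()
        cfg = _smoke_config(schemes=("kfold",))
        y = pheno.values("trait")
        plan = validation.kfold_plan(len(y), 2, seed=cfg.derive_seed("kfold", "trait"))[0]
        y_perturbed = y.copy()
        y_perturbed[plan.test] += 100.0
        ctx1 = _FoldContext(pop.genotypes, y, "quantitative", plan, cfg, "trait")
        ctx2 = _FoldContext(pop.genotypes, y_perturbed, "quantitative", plan, cfg, "trait")
        for strategy in ("COMBINED_VARIANTS", "SNPS", "LINKED_SNPS"):
            assert ctx1.marker_ids(strategy) == ctx2.marker_ids(strategy)
        assert np.array_equal(ctx1.freqs, ctx2.freqs)
        p1 = validation._fit_bayes_cell(ctx1, "rkhs", "COMBINED_VARIANTS")
        p2 = validation._fit_bayes_cell(ctx2, "rkhs", "COMBINED_VARIANTS")
        assert np.array_equal(p1, p2)
        d1 = validation._fit_deep_cell(ctx1, "mlp", "SNPS")
        d2 = validation._fit_deep_cell(ctx2, "mlp", "SNPS")
        assert np.array_equal(d1, d2)

    def test_metrics_match_rescoring_oracle(self, smoke_report):
        """Reported losses re-derive from the metric functions (already the
        runner's path) and are metric-consistent per trait kind."""
        rows = smoke_report.rows
        assert (rows["metric"] == "MSE").all()

    def test_failed_cells_keep_rows(self):
        pop, pheno = _smoke_inputs()
        cfg = _smoke_config(schemes=("kfold",), ld_threshold=1.01,
                            cells=(("bayesc", "LINKED_SNPS"),))
        report = validation.run_experiment(pop.genotypes, pheno, cfg)
        assert len(report.rows) == 2
        assert (report.rows["error"] != "").all()
        assert report.rows["loss"].isna().all()

    def test_missing_trait_values_rejected(self):
        pop, pheno = _smoke_inputs()
        pheno.data.loc[0, "trait"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            validation.run_experiment(pop.genotypes, pheno,
                                      _smoke_config(schemes=("kfold",)))
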