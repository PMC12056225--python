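"""Synthetic-cohort generator: determinism, calibration, parameter recovery."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from vpptbench import (
    CategoricalToolModel,
    CohortConfig,
    GaussianToolModel,
    SyntheticConfig,
    build_benchmark,
    evaluate_all_tools,
    expected_performance,
    filter_rare,
    generate_cohort,
    write_variant_table,
)
from vpptbench.errors import ConfigError
from vpptbench.registry import call_matrix
from vpptbench.simulate import default_config, expected_rare_fraction, models_from_reference


def _tiny_config(seed=3, n=2000, **kwargs):
    cc = CohortConfig(
        name="T",
        n_variants=n,
        tool_models={
            "CADD": GaussianToolModel(mu_pathogenic=24, mu_benign=16, sigma_pathogenic=4,
                                      sigma_benign=4, missing_prob=0.05),
            "SIFT": CategoricalToolModel(0.8, 0.2, missing_prob=0.05),
        },
        **kwargs,
    )
    return SyntheticConfig(seed=seed, cohorts=(cc,))


class TestDeterminism:
    def test_same_seed_identical_objects(self, registry):
        config = _tiny_config()
        v1, t1 = generate_cohort(config, registry=registry)
        v2, t2 = generate_cohort(config, registry=registry)
        assert v1 == v2 and t1 == t2

    def test_same_seed_byte_identical_tsv(self, tmp_path, registry):
        config = _tiny_config()
        paths = []
        for run in (1, 2):
            v, _ = generate_cohort(config, registry=registry)
            p = tmp_path / f"run{run}.tsv"
            write_variant_table(v, p, registry)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_different_seed_differs(self, registry):
        v1, _ = generate_cohort(_tiny_config(seed=3), registry=registry)
        v2, _ = generate_cohort(_tiny_config(seed=4), registry=registry)
        assert v1 != v2

    def test_adding_a_tool_does_not_perturb_other_columns(self, registry):
        """Per-tool substreams: other columns are stable under registry edits."""
        base = _tiny_config()
        cc = base.cohorts[0]
        extended = SyntheticConfig(
            seed=base.seed,
            cohorts=(
                CohortConfig(
                    name=cc.name,
                    n_variants=cc.n_variants,
                    tool_models={**cc.tool_models,
                                 "DANN": GaussianToolModel(mu_pathogenic=1, mu_benign=0)},
                ),
            ),
        )
        v1, _ = generate_cohort(base, registry=registry)
        v2, _ = generate_cohort(extended, registry=registry)
        for a, b in zip(v1, v2):
            assert a.key == b.key and a.cohort_maf == b.cohort_maf
            assert a.scores.get("CADD") == b.scores.get("CADD")
            assert a.preds.get("SIFT") == b.preds.get("SIFT")
        assert any("DANN" in v.scores for v in v2)


class TestCalibration:
    def test_pv_truth_count_within_binomial_bound(self, registry):
        n, p = 100_000, 0.001
        cc = CohortConfig(name="T", n_variants=n, frac_pv=p, frac_bv=0.0)
        _, truths = generate_cohort(SyntheticConfig(seed=5, cohorts=(cc,)), registry=registry)
        n_pv = sum(t.true_class == "pathogenic" for t in truths)
        assert abs(n_pv - n * p) <= 3 * math.sqrt(n * p * (1 - p))

    def test_rare_fraction_matches_expectation(self, registry):
        config = _tiny_config(n=20_000)
        variants, _ = generate_cohort(config, registry=registry)
        with_maf = [v for v in variants if v.cohort_maf is not None]
        frac = sum(v.cohort_maf < 0.01 for v in with_maf) / len(with_maf)
        expected = expected_rare_fraction(config.cohorts[0])
        se = math.sqrt(expected * (1 - expected) / len(with_maf))
        assert abs(frac - expected) <= 3 * se


class TestExpectedPerformance:
    def test_degenerate_threshold(self, registry):
        import dataclasses

        tool = dataclasses.replace(registry.get("CADD"), cutoff=-1e9)
        model = GaussianToolModel(mu_pathogenic=1, mu_benign=0)
        sen, spec = expected_performance(model, tool)
        assert sen == pytest.approx(1.0) and spec == pytest.approx(0.0)

    def test_uninformative_tool(self, registry):
        tool = registry.get("REVEL")  # cutoff 0.5
        model = GaussianToolModel(mu_pathogenic=0.4, mu_benign=0.4, sigma_pathogenic=0.2,
                                  sigma_benign=0.2)
        sen, spec = expected_performance(model, tool)
        assert sen == pytest.approx(1 - spec)

    def test_gaussian_closed_form_vs_monte_carlo(self, registry):
        """mu1=1, mu0=0, sigma=1, cutoff 0.5: sen = spec = Phi(0.5)."""
        tool = registry.get("REVEL")
        model = GaussianToolModel(mu_pathogenic=1.0, mu_benign=0.0)
        sen, spec = expected_performance(model, tool)
        assert sen == pytest.approx(norm.cdf(0.5))
        assert spec == pytest.approx(norm.cdf(0.5))
        rng = np.random.default_rng(0)
        n = 1_000_000
        mc_sen = (rng.normal(1.0, 1.0, n) >= 0.5).mean()
        mc_spec = (rng.normal(0.0, 1.0, n) < 0.5).mean()
        assert sen == pytest.approx(mc_sen, abs=3 * 0.5 / math.sqrt(n))
        assert spec == pytest.approx(mc_spec, abs=3 * 0.5 / math.sqrt(n))

    def test_categorical_passthrough(self, registry):
        sen, spec = expected_performance(CategoricalToolModel(0.9, 0.25), registry.get("SIFT"))
        assert (sen, spec) == (0.9, 0.75)


class TestRecovery:
    def test_operating_points_recovered_within_3se(self, registry):
        """Pipeline metric estimates match the analytic tool operating points."""
        config = _tiny_config(
            n=4000,
            frac_pv=0.3,
            frac_bv=0.7,
            rare_fraction=1.0,
            labelled_rare_prob=1.0,
            label_probs={
                "pathogenic": {"clinvar": 1.0},
                "benign": {"clinvar": 1.0},
                "neutral_vus": {},
            },
            missing_maf_prob=0.0,
        )
        cc = config.cohorts[0]
        variants, _ = generate_cohort(config, registry=registry)
        rare = filter_rare(variants)
        bench = build_benchmark(rare, "clinvar")
        tools = [registry.get(t) for t in cc.tool_models]
        perfs = {p.tool: p for p in evaluate_all_tools(bench, call_matrix(rare, tools))}
        for tool in tools:
            exp_sen, exp_spec = expected_performance(cc.tool_models[tool.name], tool)
            p = perfs[tool.name]
            se_sen = math.sqrt(exp_sen * (1 - exp_sen) / p.n_scored_pos)
            se_spec = math.sqrt(exp_spec * (1 - exp_spec) / p.n_scored_neg)
            assert abs(p.sensitivity - exp_sen) <= 3 * se_sen, tool.name
            assert abs(p.specificity - exp_spec) <= 3 * se_spec, tool.name

    def test_recovery_error_shrinks_with_sample_size(self, registry):
        """sqrt(n) convergence: 4x the variants roughly halves the error."""

        def mean_abs_err(n, seeds):
            errs = []
            for seed in seeds:
                config = _tiny_config(
                    seed=seed, n=n, frac_pv=0.5, frac_bv=0.5, rare_fraction=1.0,
                    labelled_rare_prob=1.0,
                    label_probs={"pathogenic": {"clinvar": 1.0},
                                 "benign": {"clinvar": 1.0}, "neutral_vus": {}},
                    missing_maf_prob=0.0,
                )
                cc = config.cohorts[0]
                variants, _ = generate_cohort(config, registry=registry)
                bench = build_benchmark(variants, "clinvar")
                tools = [registry.get(t) for t in cc.tool_models]
                perfs = evaluate_all_tools(bench, call_matrix(variants, tools))
                for p in perfs:
                    exp_sen, _ = expected_performance(cc.tool_models[p.tool],
                                                      registry.get(p.tool))
                    errs.append(abs(p.sensitivity - exp_sen))
            return float(np.mean(errs))

        seeds = range(10, 18)
        small, large = mean_abs_err(500, seeds), mean_abs_err(2000, seeds)
        assert large < small * 0.75  # expected ratio 0.5, generous margin


class TestConfigValidation:
    def test_bad_probability_partition(self):
        with pytest.raises(ConfigError):
            CohortConfig(name="T", frac_pv=0.7, frac_bv=0.6)
        with pytest.raises(ConfigError):
            CohortConfig(name="T", consequence_probs={"missense": 0.5, "other": 0.3})

    def test_unknown_cohort(self):
        config = _tiny_config()
        with pytest.raises(ConfigError):
            config.cohort("missing")

    def test_default_config_shapes_two_ancestral_cohorts(self, registry):
        config = default_config(seed=1)
        names = [c.name for c in config.cohorts]
        assert names == ["AFR", "EUR"]
        afr, eur = config.cohorts
        assert afr.n_variants > eur.n_variants          # more African variation
        assert afr.rare_fraction < eur.rare_fraction    # lower African rare share
        assert len(afr.tool_models) == 54

    def test_models_from_reference_hit_published_operating_points(self, registry,
                                                                  reference_metrics):
        models = models_from_reference("AFR")
        by_tool = {r.tool: r for r in reference_metrics["AFR"]}
        for name in ("CADD", "SIFT", "BayesDel-noAF", "DANN"):
            sen, spec = expected_performance(models[name], registry.get(name))
            assert sen == pytest.approx(by_tool[name].sensitivity, abs=1e-6)
            assert spec == pytest.approx(by_tool[name].specificity, abs=1e-6)
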