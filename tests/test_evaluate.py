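"""Validation metrics, WA-GEBV combination and the experiment grid."""
import numpy as np
import pandas as pd
import pytest

import crossgp as cg
from crossgp.breeds import BreedComposition
from crossgp.evaluate import accuracy, bias, build_panels, run_experiment, wa_gebv
from crossgp.population import ReferenceDesign


class TestMetrics:
    @pytest.mark.parametrize("g,d,expected", [
        ([1, 2, 3], [1, 2, 3], 1.0),
        ([1, 2, 3], [-1, -2, -3], -1.0),
        ([1, 2, 3], [2, 4, 6], 1.0),
    ])
    def test_accuracy_examples(self, g, d, expected):
        assert accuracy(g, d) == pytest.approx(expected)

    @pytest.mark.parametrize("g,d,expected", [
        ([1.0, 2.0, 4.0], [1.0, 2.0, 4.0], 1.0),
        ([1.0, 2.0, 4.0], [7.0, 9.0, 13.0], 2.0),
    ])
    def test_bias_examples(self, g, d, expected):
        assert bias(g, d) == pytest.approx(expected)

    def test_bias_ols_consistency(self):
        rng = np.random.default_rng(0)
        g = rng.normal(0, 1, 10_000)
        d = 0.5 * g + rng.normal(0, 0.1, 10_000)
        assert bias(g, d) == pytest.approx(0.5, abs=0.02)

    def test_zero_variance_returns_nan_with_warning(self):
        with pytest.warns(UserWarning):
            assert np.isnan(accuracy([1.0, 1.0], [1.0, 2.0]))
        with pytest.warns(UserWarning):
            assert np.isnan(bias([2.0, 2.0], [1.0, 2.0]))


class TestWaGebv:
    def _frac(self, ids, fh):
        fr = np.column_stack([fh, 1.0 - np.asarray(fh)])
        groups = np.array(["H"] * len(ids), dtype=object)
        return BreedComposition(np.asarray(ids, dtype=object), fr, groups,
                                source="truth")

    def test_pure_h_fraction_returns_h_gebv(self):
        gH = pd.Series([1.5, -0.5], index=["a", "b"])
        gJ = pd.Series([9.0, 9.0], index=["a", "b"])
        out = wa_gebv(gH, gJ, self._frac(["a", "b"], [1.0, 1.0]))
        assert np.allclose(out.to_numpy(), gH.to_numpy())

    def test_even_fractions_average(self):
        gH = pd.Series([2.0], index=["a"])
        gJ = pd.Series([4.0], index=["a"])
        out = wa_gebv(gH, gJ, self._frac(["a"], [0.5]))
        assert out["a"] == pytest.approx(3.0)

    def test_missing_component_gebv_named(self):
        gH = pd.Series([2.0], index=["a"])
        gJ = pd.Series([4.0], index=["b"])
        with pytest.raises(KeyError, match="a"):
            wa_gebv(gH, gJ, self._frac(["a"], [0.5]), target_ids=["a"])


class TestPanels:
    def test_tag_panel_excludes_qtl(self, small_population):
        panels = build_panels(small_population, seed=1)
        qtl = small_population.qtl_indices
        assert not panels["tag"][qtl].any()

    def test_causal_enriched_contains_most_qtl(self, small_population):
        panels = build_panels(small_population, seed=1)
        qtl = small_population.qtl_indices
        assert panels["causal_enriched"][qtl].mean() >= 0.85

    def test_tag_and_enriched_same_size(self, small_population):
        panels = build_panels(small_population, seed=1)
        assert panels["tag"].sum() == panels["causal_enriched"].sum()


@pytest.fixture(scope="module")
def small_grid(small_population, small_config, small_designs):
    drps = cg.simulate_drp_traits(small_population, small_config, seed=55,
                                  traits=("milk", "fat"))
    designs, validation = small_designs
    keep = [d for d in designs if d.name in ("Ref1", "Ref2", "Ref3", "Ref4")]
    table = run_experiment(
        small_population, drps, keep, validation, methods=("gblup",),
        params=small_config.weight_params, sigma2_g=small_config.sigma2_g,
        base_seed=77,
    )
    return table, keep, validation


class TestRunExperiment:
    def test_row_counts_match_validation_groups(self, small_grid):
        table, keep, validation = small_grid
        ok = table[(table.status == "ok") & (table.trait == "milk")]
        for d in keep:
            sub = ok[ok.design == d.name]
            for _, row in sub.iterrows():
                assert row.n_validation == len(validation[row.validation_group])

    def test_contains_per_trait_and_mean_rows(self, small_grid):
        table, _, _ = small_grid
        assert set(table.trait.unique()) == {"milk", "fat", "(mean)"}

    def test_mean_rows_average_traits(self, small_grid):
        table, _, _ = small_grid
        one = table[(table.design == "Ref3") & (table.validation_group == "H")]
        per_trait = one[one.trait != "(mean)"].accuracy.mean()
        mean_row = one[one.trait == "(mean)"].accuracy.iloc[0]
        assert mean_row == pytest.approx(per_trait)

    def test_rerun_is_bit_identical(self, small_population, small_config,
                                    small_designs):
        drp = cg.simulate_drp(small_population, small_config, seed=56)
        designs, validation = small_designs
        keep = [d for d in designs if d.name in ("Ref1", "Ref3")]
        kw = dict(methods=("gblup",), params=small_config.weight_params,
                  sigma2_g=small_config.sigma2_g, base_seed=5)
        t1 = run_experiment(small_population, drp, keep, validation, **kw)
        t2 = run_experiment(small_population, drp, keep, validation, **kw)
        pd.testing.assert_frame_equal(t1, t2)

    def test_failed_cell_is_recorded_not_raised(self, small_population,
                                                small_config, small_drp,
                                                small_designs):
        designs, validation = small_designs
        ok_design = [d for d in designs if d.name == "Ref1"]
        tiny = ReferenceDesign("broken",
                               np.array(["no_such_animal"], dtype=object),
                               designs[0].validation_ids)
        table = run_experiment(small_population, small_drp,
                               ok_design + [tiny], validation,
                               methods=("gblup",),
                               params=small_config.weight_params,
                               sigma2_g=small_config.sigma2_g, base_seed=6)
        broken = table[table.design == "broken"]
        assert (broken.status != "ok").all()
        good = table[table.design == "Ref1"]
        assert (good.status == "ok").all()

    def test_weighted_average_design_scored(self, small_grid):
        table, _, _ = small_grid
        ref4 = table[(table.design == "Ref4") & (table.status == "ok")]
        assert len(ref4) > 0
        assert ref4.accuracy.between(-1, 1).all()

    def test_embayesr_method_runs_in_grid(self, small_population, small_config,
                                          small_designs):
        drp = cg.simulate_drp(small_population, small_config, seed=57)
        designs, validation = small_designs
        keep = [d for d in designs if d.name == "Ref1"]
        table = run_experiment(
            small_population, drp, keep, validation, methods=("embayesr",),
            params=small_config.weight_params, sigma2_g=small_config.sigma2_g,
            base_seed=8,
            bayes_config=cg.BayesRConfig(gibbs_iters=400, burnin=100,
                                         n_chains=1, base_seed=8,
                                         em_max_iter=50),
        )
        assert (table.status == "ok").all()
        assert table.accuracy.notna().all()


class TestWaGebvSourcesAgree:
    def test_pca_and_admixture_wa_gebv_similar(self):
        # the two breed-fraction sources drive nearly identical combined GEBV
        agree = 0
        n_rep = 6
        for rep in range(n_rep):
            cfg = cg.SimConfig(seed=300 + rep, n_snp=800, n_qtl=60,
                               group_sizes={"H_bull": 30, "J_bull": 20,
                                            "H_cow": 100, "J_cow": 80,
                                            "75H25J_cow": 90, "50H50J_cow": 90,
                                            "25H75J_cow": 80})
            pop = cg.simulate_population(cfg)
            drp = cg.simulate_drp(pop, cfg, seed=400 + rep)
            designs, validation = cg.build_reference_designs(
                pop, seed=rep, validation_fraction=0.3)
            keep = [d for d in designs
                    if d.name in ("Ref1", "Ref2", "Ref4", "Ref4p")]
            table = run_experiment(pop, drp, keep, validation,
                                   methods=("gblup",),
                                   params=cfg.weight_params,
                                   sigma2_g=cfg.sigma2_g, base_seed=rep)
            cross = table[table.validation_group.isin(
                ["75H25J", "50H50J", "25H75J"]) & (table.status == "ok")]
            a4 = cross[cross.design == "Ref4"].set_index("validation_group").accuracy
            a4p = cross[cross.design == "Ref4p"].set_index("validation_group").accuracy
            # per-group accuracies carry ~0.02 sampling noise at these
            # validation sizes; the similarity claim is tested on the
            # across-group mean difference
            agree += bool(np.abs(a4 - a4p).mean() <= 0.02)
        assert agree >= n_rep - 1
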