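"""Synthetic-population generator: moments, calibration and design layout."""
import numpy as np
import pytest

import crossgp as cg
from crossgp.bayesr import MixturePrior
from crossgp.population import assign_qtl_effects, draw_breed_allele_freqs


class TestBreedAlleleFreqs:
    def test_zero_divergence_returns_ancestral_exactly(self):
        p = np.linspace(0.1, 0.9, 50)
        pH, pJ = draw_breed_allele_freqs(p, 0.0, seed=1)
        assert np.array_equal(pH, p) and np.array_equal(pJ, p)

    def test_balding_nichols_variance(self):
        # var of drawn frequencies should be fst * p * (1 - p)
        p = np.full(10_000, 0.5)
        pH, _ = draw_breed_allele_freqs(p, 0.1, seed=2)
        expected = 0.1 * 0.5 * 0.5
        assert abs(pH.var() - expected) / expected < 0.2

    def test_same_seed_is_deterministic(self):
        p = np.linspace(0.2, 0.8, 100)
        a = draw_breed_allele_freqs(p, 0.2, seed=3)
        b = draw_breed_allele_freqs(p, 0.2, seed=3)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    @pytest.mark.parametrize("bad_fst", [-0.1, 0.6, float("nan")])
    def test_invalid_fst_rejected(self, bad_fst):
        with pytest.raises(ValueError):
            draw_breed_allele_freqs(np.array([0.5]), bad_fst, seed=0)

    def test_out_of_range_frequency_names_index(self):
        p = np.array([0.5, 1.5, 0.4])
        with pytest.raises(ValueError, match="index 1"):
            draw_breed_allele_freqs(p, 0.1, seed=0)


class TestSimulateGenotypes:
    def test_purebred_binomial_mean(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.2, 0.8, 400)
        pop = cg.simulate_genotypes({"H": p, "J": p}, {"H_cow": 10}, seed=4)
        assert pop.genotypes.n_animals == 10
        mean = pop.genotypes.dosages.mean(axis=0)
        sd = np.sqrt(2 * p * (1 - p) / 10)
        z = np.abs(mean - 2 * p) / sd
        # ~3-SD binomial agreement per locus, allowing for multiplicity
        assert (z <= 3.0).mean() > 0.99 and z.max() < 5.0

    def test_f1_fixed_difference_locus_is_heterozygous(self):
        pH = np.array([0.999, 0.5])
        pJ = np.array([0.001, 0.5])
        pop = cg.simulate_genotypes({"H": pH, "J": pJ}, {"50H50J_cow": 50}, seed=5)
        # with p_H ~ 1, p_J ~ 0 almost every F1 carries exactly one alt allele
        assert (pop.genotypes.dosages[:, 0] == 1).mean() > 0.95

    def test_backcross_mean_dosage(self):
        pH = np.full(200, 0.999)
        pJ = np.full(200, 0.001)
        pop = cg.simulate_genotypes({"H": pH, "J": pJ}, {"75H25J_cow": 200}, seed=6)
        # expectation 2 * 0.75 = 1.5 at an (almost) fixed-difference locus
        assert abs(pop.genotypes.dosages.mean() - 1.5) < 0.05

    def test_empty_group_map_rejected(self):
        with pytest.raises(ValueError):
            cg.simulate_genotypes({"H": np.array([0.5]), "J": np.array([0.5])},
                                  {}, seed=0)

    def test_breed_fractions_exact(self, small_population):
        allowed = {(1.0, 0.0), (0.75, 0.25), (0.5, 0.5), (0.25, 0.75), (0.0, 1.0)}
        fr = small_population.breed_fractions_true
        assert set(map(tuple, fr)) <= allowed
        assert np.all(fr.sum(axis=1) == 1.0)

    def test_fst_recovered_from_purebreds(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.1, 0.9, 2500)
        pH, pJ = cg.draw_breed_allele_freqs(p, 0.1, seed=7)
        pop = cg.simulate_genotypes({"H": pH, "J": pJ},
                                    {"H_cow": 200, "J_cow": 200}, seed=8)
        grp = pop.breed_group_true
        p1 = pop.genotypes.dosages[grp == "H"].mean(axis=0) / 2
        p2 = pop.genotypes.dosages[grp == "J"].mean(axis=0) / 2
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / 399 - p2 * (1 - p2) / 399
        den = p1 * (1 - p2) + p2 * (1 - p1)
        fst_hat = num.sum() / den.sum()
        assert abs(fst_hat - 0.1) / 0.1 < 0.2


class TestQtlEffects:
    def test_no_qtl_gives_zero_effects(self):
        eff, qtl = assign_qtl_effects(100, 0, MixturePrior(), 1.0, seed=1)
        assert not eff.any() and len(qtl) == 0

    def test_all_snps_largest_component_all_nonzero(self):
        prior = MixturePrior((0.0, 0.0, 0.0, 1.0), (0.0, 1e-4, 1e-3, 1e-2))
        eff, _ = assign_qtl_effects(50, 50, prior, 1.0, seed=2)
        assert np.all(eff != 0)

    def test_rescaling_makes_h_tbv_variance_exact(self):
        rng = np.random.default_rng(3)
        dos = rng.binomial(2, 0.4, size=(300, 1000)).astype(np.int8)
        eff, _ = assign_qtl_effects(1000, 80, MixturePrior(), 2.5, seed=4,
                                    dosages_h=dos)
        assert abs((dos @ eff).var() - 2.5) < 1e-9

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            assign_qtl_effects(10, 2, MixturePrior(), 0.0, seed=0)


class TestSimulateDrp:
    def test_huge_daughter_count_recovers_tbv(self):
        cfg = cg.SimConfig(seed=21, n_snp=300, n_qtl=30,
                           group_sizes={"H_bull": 50, "H_cow": 2, "J_cow": 2,
                                        "J_bull": 2, "75H25J_cow": 2,
                                        "50H50J_cow": 2, "25H75J_cow": 2},
                           daughters_range=(10 ** 6, 10 ** 6))
        pop = cg.simulate_population(cfg)
        drp = cg.simulate_drp(pop, cfg, seed=22)
        bulls = pop.sex == "bull"
        noise = drp.y[bulls] - pop.tbv[bulls] - cfg.sex_effect \
            - cfg.j_mean_shift * pop.breed_fractions_true[bulls, 1]
        assert noise.std() < 0.01 * np.sqrt(cfg.sigma2_g)

    def test_cow_reliability_formula_single_record(self):
        params = cg.WeightParams(0.33, 0.56, 0.2)
        assert cg.cow_reliability(params, 1) == pytest.approx(0.33)
        # implied noise variance sigma2_g * (1 - r2) / r2
        assert (1 - 0.33) / 0.33 == pytest.approx(0.67 / 0.33)

    def test_drp_unbiased_for_tbv(self):
        cfg = cg.SimConfig(seed=23, n_snp=400, n_qtl=40,
                           group_sizes={"H_cow": 5000})
        pop = cg.simulate_population(cfg)
        drp = cg.simulate_drp(pop, cfg, seed=24)
        slope = np.cov(drp.y, pop.tbv)[0, 1] / pop.tbv.var(ddof=1)
        assert abs(slope - 1.0) < 0.05

    @pytest.mark.parametrize("n_records", [1, 6])
    def test_noise_variance_matches_reliability_stratum(self, n_records):
        cfg = cg.SimConfig(seed=25 + n_records, n_snp=300, n_qtl=30,
                           group_sizes={"H_cow": 800},
                           records_range=(n_records, n_records))
        pop = cg.simulate_population(cfg)
        drp = cg.simulate_drp(pop, cfg, seed=26 + n_records)
        r2 = cg.cow_reliability(cfg.weight_params, n_records)
        target = cfg.sigma2_g * (1 - r2) / r2
        observed = (drp.y - pop.tbv).var()
        assert abs(observed - target) / target < 0.10

    def test_same_seed_bit_identical(self, small_config):
        a = cg.simulate_population(small_config)
        b = cg.simulate_population(small_config)
        assert np.array_equal(a.genotypes.dosages, b.genotypes.dosages)
        assert np.array_equal(a.tbv, b.tbv)
        da = cg.simulate_drp(a, small_config, seed=9)
        db = cg.simulate_drp(b, small_config, seed=9)
        assert np.array_equal(da.y, db.y) and np.array_equal(da.weight, db.weight)

    def test_traits_share_weights_not_noise(self, small_population, small_config):
        milk, fat, protein = cg.simulate_drp_traits(
            small_population, small_config, seed=31)
        assert np.array_equal(milk.weight, fat.weight)
        assert np.array_equal(milk.n_eff, protein.n_eff)
        assert not np.array_equal(milk.y, fat.y)


class TestReferenceDesigns:
    def test_ref3_is_union_of_ref1_and_ref2(self, small_designs):
        designs, _ = small_designs
        by = {d.name: d for d in designs}
        assert set(by["Ref3"].reference_ids) == (
            set(by["Ref1"].reference_ids) | set(by["Ref2"].reference_ids))

    def test_ref6_and_ref7_same_total_size(self, small_designs):
        designs, _ = small_designs
        by = {d.name: d for d in designs}
        assert len(by["Ref6"].reference_ids) == len(by["Ref7"].reference_ids)

    def test_ref8_unions_ref6_and_ref7(self, small_designs):
        designs, _ = small_designs
        by = {d.name: d for d in designs}
        assert set(by["Ref8"].reference_ids) == (
            set(by["Ref6"].reference_ids) | set(by["Ref7"].reference_ids))

    def test_validation_disjoint_from_every_reference(self, small_designs):
        designs, validation = small_designs
        val = set(np.concatenate(list(validation.values())))
        for d in designs:
            assert not (val & set(d.reference_ids)), d.name

    def test_validation_covers_all_five_groups(self, small_designs):
        _, validation = small_designs
        assert set(validation) == set(cg.BREED_GROUPS)
        assert all(len(v) >= 2 for v in validation.values())

    def test_missing_group_raises(self):
        cfg = cg.SimConfig(seed=41, n_snp=200, n_qtl=10,
                           group_sizes={"H_cow": 30, "J_cow": 30})
        pop = cg.simulate_population(cfg)
        with pytest.raises(ValueError, match="no cows available|no bulls"):
            cg.build_reference_designs(pop, seed=42)


class TestSimConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"fst": 0.7}, {"h2": 1.2}, {"t": 0.1}, {"n_qtl": 10, "n_snp": 5},
        {"ancestral_freq_range": (0.0, 0.9)},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            cg.SimConfig(seed=0, **kwargs)
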