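"""Lattice statistics: transfer matrix vs enumeration, distributions, MCMC."""

import numpy as np
import pytest
from scipy.stats import binom

from fibrilbind import isotherms as iso
from fibrilbind.lattice import (
    EMPTY,
    INHIBITOR,
    LIGAND,
    FibrilConfig,
    LatticeModel,
    MCMCSettings,
    enumerate_oracle,
    finite_occupancy,
    infinite_occupancy,
    mcmc_sample,
    occupancy_distribution,
    saturating_limit_check,
)

from conftest import random_model


class TestModelValidation:
    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            LatticeModel({LIGAND: -1.0})

    def test_empty_pair_factor_must_be_one(self):
        with pytest.raises(ValueError):
            LatticeModel({LIGAND: 1.0}, {(EMPTY, LIGAND): 2.0})

    def test_bad_boundary_rejected(self):
        with pytest.raises(ValueError):
            FibrilConfig(5, boundary="helical")

    def test_nonpositive_sites_rejected(self):
        with pytest.raises(ValueError):
            FibrilConfig(0)


class TestInfiniteLattice:
    def test_langmuir_case(self):
        occ = infinite_occupancy(LatticeModel.two_state(1.0, 1.0))
        assert occ.fraction(LIGAND) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("log_c", np.linspace(-3, 3, 7))
    @pytest.mark.parametrize("alpha", [0.2, 1.0, 10.0, 100.0])
    def test_matches_closed_form(self, log_c, alpha):
        c = 10.0**log_c
        occ = infinite_occupancy(LatticeModel.two_state(c, alpha))
        assert occ.fraction(LIGAND) == pytest.approx(
            iso.saturation_fraction(c, alpha), abs=1e-10
        )

    def test_fractions_and_pairs_sum_to_one(self, rng):
        for _ in range(20):
            occ = infinite_occupancy(random_model(rng))
            assert sum(occ.mean_fraction.values()) == pytest.approx(1.0, abs=1e-10)
            assert sum(occ.pair_fraction.values()) == pytest.approx(1.0, abs=1e-10)

    def test_symmetric_saturating_three_state(self):
        model = LatticeModel.three_state(1e8, 1e8, 1.0, 1.0, 1.0)
        occ = infinite_occupancy(model)
        assert occ.fraction(LIGAND) == pytest.approx(0.5, abs=1e-6)

    def test_all_zero_weights_are_empty_lattice(self):
        occ = infinite_occupancy(LatticeModel.two_state(0.0, 5.0))
        assert occ.fraction(EMPTY) == pytest.approx(1.0)

    def test_large_beta_alternation(self):
        # chi = 10 with unit self-factors: beta = 100; saturated midpoint
        model = LatticeModel.three_state(1e6, 1e6, 1.0, 1.0, 10.0)
        occ = infinite_occupancy(model)
        assert occ.pair_fraction[(INHIBITOR, LIGAND)] > 0.9


class TestFiniteLattice:
    def test_single_site_has_no_cooperativity(self):
        occ = finite_occupancy(LatticeModel.two_state(1.0, 50.0), FibrilConfig(1))
        assert occ.fraction(LIGAND) == pytest.approx(0.5, abs=1e-12)
        assert occ.pair_fraction is None

    def test_two_sites_hand_enumeration(self):
        # Z = 1 + 2c + alpha c^2 = 13 at c=1, alpha=10; <n> = 2(c + alpha c^2)/Z
        occ = finite_occupancy(LatticeModel.two_state(1.0, 10.0), FibrilConfig(2))
        assert occ.fraction(LIGAND) == pytest.approx(11.0 / 13.0, abs=1e-12)

    def test_oracle_equivalence_random_models(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 9))
            boundary = str(rng.choice(["free", "periodic"]))
            model = random_model(rng)
            cfg = FibrilConfig(n, boundary)
            got = finite_occupancy(model, cfg)
            ref = enumerate_oracle(model, cfg)
            for sp in model.species:
                assert got.mean_fraction[sp] == pytest.approx(
                    ref.mean_fraction[sp], abs=1e-12
                )
            if got.pair_fraction is not None:
                for key, val in got.pair_fraction.items():
                    assert val == pytest.approx(ref.pair_fraction[key], abs=1e-12)

    def test_converges_to_infinite_lattice(self):
        model = LatticeModel.two_state(0.1, 10.0)
        target = infinite_occupancy(model).fraction(LIGAND)
        errs = [
            abs(finite_occupancy(model, FibrilConfig(n)).fraction(LIGAND) - target)
            for n in (100, 1000, 10000)
        ]
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-3
        # edge effects at N = 1000 scale like 1/N: ~1.1e-3 at the midpoint here
        assert abs(finite_occupancy(model, FibrilConfig(1000)).fraction(LIGAND) - 0.5) < 2e-3

    def test_large_weights_do_not_overflow(self):
        model = LatticeModel.two_state(1e3, 100.0)
        occ = finite_occupancy(model, FibrilConfig(5000))
        assert 0.99 < occ.fraction(LIGAND) <= 1.0

    def test_enumeration_guard(self):
        with pytest.raises(ValueError, match="finite_occupancy"):
            enumerate_oracle(LatticeModel.two_state(1.0, 1.0), FibrilConfig(30))


class TestCountDistribution:
    def test_noncooperative_is_binomial(self):
        dist = occupancy_distribution(LatticeModel.two_state(1.0, 1.0), FibrilConfig(10))
        expected = binom.pmf(np.arange(11), 10, 0.5)
        assert np.max(np.abs(dist - expected)) < 1e-10

    def test_two_site_hand_values(self):
        dist = occupancy_distribution(LatticeModel.two_state(1.0, 10.0), FibrilConfig(2))
        assert dist == pytest.approx([1 / 13, 2 / 13, 10 / 13], abs=1e-12)

    def test_matches_oracle_and_mean_consistency(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 8))
            boundary = str(rng.choice(["free", "periodic"]))
            model = random_model(rng)
            cfg = FibrilConfig(n, boundary)
            dist = occupancy_distribution(model, cfg, LIGAND)
            ref = enumerate_oracle(model, cfg, count_species=LIGAND)
            assert np.max(np.abs(dist - ref.count_distribution)) < 1e-12
            assert dist.sum() == pytest.approx(1.0, abs=1e-10)
            mean = np.arange(n + 1) @ dist
            assert mean / n == pytest.approx(
                finite_occupancy(model, cfg).fraction(LIGAND), abs=1e-10
            )


class TestMCMC:
    def test_langmuir_mean_within_three_se(self):
        model = LatticeModel.two_state(1.0, 1.0)
        res = mcmc_sample(model, FibrilConfig(1000),
                          MCMCSettings(sweeps=2000, burn_in=400, thinning=5, seed=11))
        assert abs(res.mean_fraction[LIGAND] - 0.5) < 3 * res.stderr[LIGAND]

    def test_cooperative_mean_matches_exact(self):
        model = LatticeModel.two_state(1.0, 10.0)
        cfg = FibrilConfig(1000)
        exact = finite_occupancy(model, cfg).fraction(LIGAND)
        res = mcmc_sample(model, cfg,
                          MCMCSettings(sweeps=3000, burn_in=600, thinning=5, seed=12))
        assert abs(res.mean_fraction[LIGAND] - exact) < 3 * res.stderr[LIGAND]

    def test_deterministic_given_seed(self):
        model = LatticeModel.two_state(0.5, 3.0)
        cfg = FibrilConfig(200)
        settings = MCMCSettings(sweeps=300, burn_in=100, thinning=2, seed=42)
        a = mcmc_sample(model, cfg, settings)
        b = mcmc_sample(model, cfg, settings)
        assert np.array_equal(a.trace[LIGAND], b.trace[LIGAND])

    def test_calibration_over_random_cases(self, rng):
        """Batch-means intervals: estimate within 4 SE of the exact value in
        nearly all seeded cases."""
        hits = total = 0
        for case in range(100):
            model = random_model(rng, weight_range=(0.1, 5.0), factor_range=(0.2, 10.0))
            cfg = FibrilConfig(int(rng.integers(30, 80)))
            exact = finite_occupancy(model, cfg)
            res = mcmc_sample(model, cfg,
                              MCMCSettings(sweeps=1500, burn_in=300, thinning=5,
                                           seed=int(rng.integers(2**31))))
            for sp in (LIGAND,):
                se = res.stderr[sp]
                if not np.isfinite(se) or se == 0:
                    continue
                total += 1
                hits += abs(res.mean_fraction[sp] - exact.mean_fraction[sp]) < 4 * se
        assert total >= 90
        assert hits / total >= 0.95

    def test_alternating_pairs_at_large_beta(self):
        model = LatticeModel.three_state(1e6, 1e6, 1.0, 1.0, 10.0)
        res = mcmc_sample(model, FibrilConfig(1000),
                          MCMCSettings(sweeps=1500, burn_in=300, thinning=5, seed=5))
        assert res.pair_fraction[(INHIBITOR, LIGAND)] > 0.9

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            MCMCSettings(sweeps=100, burn_in=100)
        with pytest.raises(ValueError):
            MCMCSettings(seed="abc")


class TestSaturatedReduction:
    @pytest.mark.parametrize(
        "x, beta, expected",
        [(10.0, 1.0, 1.0 / 11.0), (1.0, 100.0, 0.5)],
    )
    def test_limit_values(self, x, beta, expected):
        assert saturating_limit_check(x, beta, scale=1e6) == pytest.approx(
            expected, abs=1e-5
        )

    @pytest.mark.parametrize("x, beta", [(3.0, 0.5), (0.3, 10.0), (5.0, 2.0)])
    def test_monotone_convergence_to_closed_form(self, x, beta):
        target = iso.competition_fraction(x, beta)
        errs = [abs(saturating_limit_check(x, beta, s) - target)
                for s in (1e2, 1e4, 1e6)]
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-4
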