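"""Partition evidence: exact noiseless form, approximate noisy form,
posterior normalization, and the Monte-Carlo oracle."""

import numpy as np
import pytest
from scipy import integrate

from bmselect.conjugate import (
    BetaPrior,
    GroupStats,
    WishartParams,
    log_beta_bernoulli,
    log_knw,
    log_kw,
    nw_posterior,
)
from bmselect.data import Dataset, Partition, all_partitions
from bmselect.evidence import (
    EvidenceEngine,
    ModelPriors,
    log_evidence_noiseless,
    log_evidence_noisy,
    noisy_sigma_blocks,
    posterior_over_partitions,
)
from bmselect.oracle import mc_evidence_oracle
from bmselect.priors import MomentSpec, PriorConfig
from bmselect.simulate import SimConfig, simulate_dataset

from conftest import GENTLE_MOMENTS, GENTLE_NOISE, make_instance


class TestNoiselessEvidence:
    def test_engine_matches_direct_formula(self, gentle_config):
        for seed in range(6):
            _, _, clean, _ = make_instance(seed)
            engine = EvidenceEngine(clean, gentle_config)
            for part in all_partitions(clean.n_proteins):
                direct = log_evidence_noiseless(
                    clean, part,
                    ModelPriors.for_partition(gentle_config, part),
                )
                assert engine.log_evidence(part) == pytest.approx(
                    direct, rel=1e-10, abs=1e-8
                )

    def test_matches_mc_oracle_on_toy_cohort(self, gentle_config, toy_dataset):
        part = Partition([True])
        priors = ModelPriors.for_partition(gentle_config, part)
        closed = log_evidence_noiseless(toy_dataset, part, priors)
        est, se = mc_evidence_oracle(
            toy_dataset, part, priors, "noiseless", 200_000, seed=7
        )
        assert abs(closed - est) <= 3.0 * se

    def test_empty_cohort_gives_equal_evidence(self, gentle_config):
        ds = Dataset(np.zeros((3, 0)), np.array([], dtype=str))
        vals = [
            log_evidence_noiseless(
                ds, p, ModelPriors.for_partition(gentle_config, p)
            )
            for p in all_partitions(3)
        ]
        np.testing.assert_allclose(vals, vals[0], atol=1e-9)

    def test_permutation_equivariance(self, gentle_config):
        _, _, clean, _ = make_instance(3, p_range=(3, 4))
        order = [2, 0, 1]
        permuted = clean.permute_proteins(order)
        for part in all_partitions(3):
            pp = Partition(part.mask[order])
            a = log_evidence_noiseless(
                clean, part, ModelPriors.for_partition(gentle_config, part)
            )
            b = log_evidence_noiseless(
                permuted, pp, ModelPriors.for_partition(gentle_config, pp)
            )
            assert a == pytest.approx(b, rel=1e-10)

    def test_status_relabel_symmetry_with_equal_group_priors(
        self, gentle_config
    ):
        _, _, clean, _ = make_instance(5, p_range=(2, 3))
        flipped = Dataset(
            clean.concentrations,
            np.where(clean.statuses == "P", "H", "P"),
            clean.protein_names,
        )
        for part in all_partitions(clean.n_proteins):
            pri = ModelPriors.for_partition(gentle_config, part)
            assert log_evidence_noiseless(clean, part, pri) == pytest.approx(
                log_evidence_noiseless(flipped, part, pri), rel=1e-10
            )

    def test_degenerate_single_status_cohort_is_finite(self, gentle_config):
        ds = Dataset(np.array([[0.1, 0.2, 0.3]]), np.array(["P", "P", "P"]))
        for part in all_partitions(1):
            val = log_evidence_noiseless(
                ds, part, ModelPriors.for_partition(gentle_config, part)
            )
            assert np.isfinite(val)


class TestPosteriorOverPartitions:
    def test_empty_cohort_posterior_is_uniform(self, gentle_config):
        ds = Dataset(np.zeros((3, 0)), np.array([], dtype=str))
        table = posterior_over_partitions(ds, all_partitions(3), gentle_config)
        np.testing.assert_allclose(table.posterior, 1.0 / 8.0, atol=1e-12)

    def test_probabilities_sum_to_one(self, gentle_config):
        for seed in range(4):
            _, _, clean, _ = make_instance(seed + 20)
            table = posterior_over_partitions(
                clean, all_partitions(clean.n_proteins), gentle_config
            )
            assert table.posterior.sum() == pytest.approx(1.0, abs=1e-12)

    def test_strong_biomarker_is_map(self):
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 1000
            is_path = rng.random(n) < rng.beta(1, 1)
            x = rng.normal(1000.0, 0.03, size=(2, n))
            x[0, is_path] += 300.0  # separation >> group spread
            ds = Dataset(x, np.where(is_path, "P", "H"))
            table = posterior_over_partitions(
                ds, all_partitions(2), PriorConfig()
            )
            hits += table.map_partition.bitmask == 1
        assert hits >= int(0.99 * n_seeds)

    def test_nonuniform_partition_prior(self, gentle_config):
        ds = Dataset(np.zeros((2, 0)), np.array([], dtype=str))
        weights = [1.0, 2.0, 3.0, 4.0]
        table = posterior_over_partitions(
            ds, all_partitions(2), gentle_config, partition_prior=weights
        )
        np.testing.assert_allclose(
            table.posterior, np.asarray(weights) / 10.0, atol=1e-12
        )

    def test_empty_partition_list_rejected(self, gentle_config):
        ds = Dataset(np.zeros((1, 0)), np.array([], dtype=str))
        with pytest.raises(ValueError, match="candidate"):
            posterior_over_partitions(ds, [], gentle_config)

    def test_duplication_dominance_plausibility(self, gentle_config):
        # Duplicating the cohort usually sharpens the already-favored
        # partition.  This is a plausibility check, not a theorem;
        # occasional violations are documented in the methods note.
        holds = 0
        seeds = range(12)
        for seed in seeds:
            _, _, clean, _ = make_instance(seed + 40, p_range=(2, 3),
                                           n_range=(20, 41))
            parts = all_partitions(clean.n_proteins)
            t1 = posterior_over_partitions(clean, parts, gentle_config)
            doubled = Dataset(
                np.hstack([clean.concentrations] * 2),
                np.concatenate([clean.statuses] * 2),
            )
            t2 = posterior_over_partitions(doubled, parts, gentle_config)
            holds += t2.posterior[t1.map_index] >= t1.posterior[t1.map_index]
        assert holds > len(seeds) / 2


class TestNoisySigmaBlocks:
    def test_hand_assembled_two_by_two(self):
        part = Partition([True, False])
        nw_plus = ModelPriors.for_partition(
            PriorConfig(GENTLE_MOMENTS), part
        )
        noise = WishartParams(10.0, 0.5 * np.eye(2))
        priors = ModelPriors(
            nw_plus.nw_path, nw_plus.nw_healthy, nw_plus.nw_common,
            BetaPrior(), noise,
        )
        pi = np.array([[2.0]])
        blocks = noisy_sigma_blocks(part, priors, pi, pi, np.array([[3.0]]))
        q_eps = 10.0 + 1 - 2
        base = np.linalg.inv(0.5 * np.eye(2)) / q_eps
        nu = priors.nw_path.nu
        expect = base + np.diag([2.0 / (nu + 1 - 1), 3.0 / (nu + 1 - 1)])
        np.testing.assert_allclose(blocks.sigma_path, expect, rtol=1e-12)
        np.testing.assert_allclose(blocks.sigma_healthy, expect, rtol=1e-12)

    def test_all_discriminant_has_single_block(self):
        part = Partition([True, True])
        cfg = PriorConfig(GENTLE_MOMENTS)
        priors = ModelPriors(
            cfg.nw(2), cfg.nw(2), None, BetaPrior(),
            WishartParams(10.0, np.eye(2)),
        )
        pi = np.array([[2.0, 0.3], [0.3, 1.0]])
        blocks = noisy_sigma_blocks(part, priors, pi, pi, None)
        expect = np.eye(2) / 9.0 + pi / (cfg.nw(2).nu + 1 - 2)
        np.testing.assert_allclose(blocks.sigma_path, expect, rtol=1e-12)

    def test_block_scatter_respects_protein_order(self):
        # discriminant coordinate is the SECOND protein: its Pi block must
        # land on index 1 after un-permuting from partition order.
        part = Partition([False, True])
        cfg = PriorConfig(GENTLE_MOMENTS)
        priors = ModelPriors(
            cfg.nw(1), cfg.nw(1), cfg.nw(1), BetaPrior(),
            WishartParams(10.0, np.eye(2)),
        )
        blocks = noisy_sigma_blocks(
            part, priors, np.array([[5.0]]), np.array([[5.0]]),
            np.array([[7.0]]),
        )
        q = cfg.nw(1).nu + 1 - 1
        assert blocks.sigma_path[1, 1] == pytest.approx(1 / 9.0 + 5.0 / q)
        assert blocks.sigma_path[0, 0] == pytest.approx(1 / 9.0 + 7.0 / q)

    def test_missing_noise_prior_rejected(self):
        # (the degrees-of-freedom guards inside the noisy path are
        # unreachable for valid Wishart parameters, since nu > d - 1
        # already implies nu + 1 - d > 0; infeasible moment settings are
        # rejected earlier, in moment_match_wishart)
        part = Partition([True, True])
        cfg = PriorConfig(GENTLE_MOMENTS)
        priors = ModelPriors(cfg.nw(2), cfg.nw(2), None, BetaPrior(), None)
        with pytest.raises(ValueError, match="noise"):
            noisy_sigma_blocks(part, priors, np.eye(2), np.eye(2), None)


class TestNoisyEvidence:
    def test_engine_matches_direct_formula(self, gentle_config):
        for seed in range(4):
            _, _, _, noisy = make_instance(seed + 60, noise=GENTLE_NOISE)
            engine = EvidenceEngine(noisy, gentle_config, noisy=True)
            for part in all_partitions(noisy.n_proteins):
                direct = log_evidence_noisy(
                    noisy, part,
                    ModelPriors.for_partition(
                        gentle_config, part, with_noise=True
                    ),
                )
                assert engine.log_evidence(part) == pytest.approx(
                    direct, rel=1e-10, abs=1e-8
                )

    def test_exact_quadrature_gold_standard(self):
        """On a P=1, N=2 cohort the noisy evidence is an exact 2-D
        integral of closed-form Wishart/Normal-Wishart ratios.  The MC
        oracle must agree with the quadrature; the Gaussian-approximated
        closed form carries a small documented bias from substituting the
        measured group means for the latent ones."""
        mom = MomentSpec(mean_of_gamma=500.0, var_of_gamma=50.0,
                         mean_of_m=0.0, var_of_m=0.02)
        noise_mom = MomentSpec(mean_of_gamma=5e3, var_of_gamma=5e3)
        pc = PriorConfig(mom, BetaPrior(1, 1), noise_mom)
        y = np.array([[0.21, -0.05]])
        ds = Dataset(y, np.array(["P", "H"]))
        part = Partition([True])
        pri = ModelPriors.for_partition(pc, part, with_noise=True)
        wish = pc.noise_wishart(1)
        lkw_pri = log_kw(wish)
        lknw_pri = log_knw(pri.nw_path)

        def integrand(x1, x2):
            x = np.array([x1, x2])
            lam_inv = 1.0 / wish.lam_eps[0, 0] + np.sum((y[0] - x) ** 2)
            le = (
                log_kw(WishartParams(wish.nu_eps + 2, [[1.0 / lam_inv]]))
                - lkw_pri - np.log(2 * np.pi)
            )
            for xi in (x1, x2):
                st = GroupStats(1, [xi], [[0.0]])
                le += (
                    log_knw(nw_posterior(pri.nw_path, st))
                    - lknw_pri - 0.5 * np.log(2 * np.pi)
                )
            return np.exp(le)

        val, quad_err = integrate.dblquad(
            integrand, -2, 2, -2, 2, epsabs=1e-12, epsrel=1e-9
        )
        exact = np.log(val) + log_beta_bernoulli(pc.beta, 1, 1)
        mc, se = mc_evidence_oracle(ds, part, pri, "noisy", 300_000, seed=5)
        assert abs(mc - exact) <= 4.0 * se  # oracle is unbiased
        closed = log_evidence_noisy(ds, part, pri)
        assert abs(closed - exact) < 0.3  # small approximation bias only

    def test_log_evidence_differences_match_mc_oracle(self):
        # Decision-relevant contract: differences across partitions agree
        # with brute-force marginalization (shared approximation bias
        # cancels) under the approximation's premises.
        mom = MomentSpec(mean_of_gamma=500.0, var_of_gamma=50.0,
                         mean_of_m=0.0, var_of_m=0.02)
        noise_mom = MomentSpec(mean_of_gamma=5e3, var_of_gamma=5e3)
        pc = PriorConfig(mom, BetaPrior(1, 1), noise_mom)
        _, _, _, noisy = make_instance(101, noise=noise_mom, moments=mom,
                                       p_range=(1, 2))
        parts = all_partitions(noisy.n_proteins)
        mc, se, cf = [], [], []
        for i, part in enumerate(parts):
            pri = ModelPriors.for_partition(pc, part, with_noise=True)
            cf.append(log_evidence_noisy(noisy, part, pri))
            m, s = mc_evidence_oracle(
                noisy, part, pri, "noisy", 250_000, seed=500 + i
            )
            mc.append(m)
            se.append(s)
        for i in range(1, len(parts)):
            dd = (cf[i] - cf[0]) - (mc[i] - mc[0])
            assert abs(dd) <= 3.0 * np.hypot(se[i], se[0]) + 0.05

    def test_noiseless_limit_recovers_exact_evidence(self, gentle_config):
        # As the noise precision grows, the noisy evidence converges to
        # the exact noiseless evidence of the measured data.
        tight_noise = MomentSpec(mean_of_gamma=1e8, var_of_gamma=1e8)
        pc = PriorConfig(GENTLE_MOMENTS, BetaPrior(1, 1), tight_noise)
        _, _, _, noisy = make_instance(71, noise=tight_noise)
        for part in all_partitions(noisy.n_proteins):
            approx = log_evidence_noisy(
                noisy, part, ModelPriors.for_partition(pc, part, True)
            )
            exact = log_evidence_noiseless(
                noisy, part, ModelPriors.for_partition(pc, part)
            )
            assert approx == pytest.approx(exact, abs=0.15)

    def test_map_decisions_converge_to_noiseless_at_high_precision(self):
        # Weak-noise regime of the benchmark protocol: the noisy selector
        # agrees with the exact noiseless selector on the same data.
        noise_mom = MomentSpec(mean_of_gamma=1e4, var_of_gamma=1e-5)
        agree = 0
        for seed in range(8):
            rng = np.random.default_rng(seed)
            cfg = SimConfig(
                n_proteins=2, n_individuals=300, n_reps=1,
                noise_moments=noise_mom, seed=seed,
            )
            truth = Partition.from_bitmask(seed % 4, 2)
            _, noisy = simulate_dataset(truth, cfg, rng)
            pc = cfg.prior_config
            parts = all_partitions(2)
            noisy_map = posterior_over_partitions(
                noisy, parts, pc, model="noisy"
            ).map_index
            clean_map = posterior_over_partitions(
                noisy, parts, pc, model="noiseless"
            ).map_index
            agree += noisy_map == clean_map
        assert agree >= 7

    def test_permutation_equivariance(self):
        noise_mom = GENTLE_NOISE
        pc = PriorConfig(GENTLE_MOMENTS, BetaPrior(1, 1), noise_mom)
        _, _, _, noisy = make_instance(81, noise=noise_mom, p_range=(3, 4))
        order = [1, 2, 0]
        permuted = noisy.permute_proteins(order)
        for part in all_partitions(3):
            pp = Partition(part.mask[order])
            a = log_evidence_noisy(
                noisy, part, ModelPriors.for_partition(pc, part, True)
            )
            b = log_evidence_noisy(
                permuted, pp, ModelPriors.for_partition(pc, pp, True)
            )
            assert a == pytest.approx(b, rel=1e-10)


class TestMCOracle:
    def test_empty_cohort_estimate_is_exactly_zero(self, gentle_config):
        ds = Dataset(np.zeros((1, 0)), np.array([], dtype=str))
        part = Partition([True])
        est, _ = mc_evidence_oracle(
            ds, part, ModelPriors.for_partition(gentle_config, part),
            "noiseless", 1000, seed=0,
        )
        assert est == 0.0

    def test_standard_error_scales_with_sample_size(self, gentle_config,
                                                    toy_dataset):
        part = Partition([True])
        pri = ModelPriors.for_partition(gentle_config, part)
        reps = 12
        se_small = np.mean([
            mc_evidence_oracle(toy_dataset, part, pri, "noiseless",
                               4000, seed=s)[1]
            for s in range(reps)
        ])
        se_big = np.mean([
            mc_evidence_oracle(toy_dataset, part, pri, "noiseless",
                               16000, seed=100 + s)[1]
            for s in range(reps)
        ])
        assert se_small / se_big == pytest.approx(2.0, rel=0.35)
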