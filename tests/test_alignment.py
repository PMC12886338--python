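"""Alignment objectives: MMD family, contrastive family, Gaussian-KL
invariance, counterfactual consistency, domain confusion, total objective."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurofact import alignment as al
from neurofact.alignment import ClassStats
from neurofact.autodiff import Tensor
from neurofact.errors import ValidationError
from neurofact.losses import LossWeights

rng = np.random.default_rng(1)


# --------------------------------------------------------------------- MMD

class TestMedianBandwidth:
    def test_single_pair(self):
        assert al.median_bandwidth(np.array([[0.0], [2.0]])) == 2.0

    def test_three_point_enumeration(self):
        pts = np.array([[0.0], [1.0], [3.0]])  # pairwise {1, 2, 3}
        assert al.median_bandwidth(pts) == 2.0

    def test_homogeneous_scaling(self):
        pts = rng.normal(size=(10, 3))
        assert al.median_bandwidth(5 * pts) == pytest.approx(
            5 * al.median_bandwidth(pts))

    def test_coincident_points_fall_back(self):
        assert al.median_bandwidth(np.zeros((4, 2))) == 1.0


class TestMMD2:
    def test_identical_samples_is_zero(self):
        p = rng.normal(size=(6, 3))
        assert al.mmd2(p, p, 1.0).item() == pytest.approx(0.0, abs=1e-12)

    def test_singleton_closed_form(self):
        u, v = np.array([[0.0, 0.0]]), np.array([[1.0, 1.0]])
        h = 0.7
        expect = 2 - 2 * np.exp(-2.0 / (2 * h ** 2))
        assert al.mmd2(u, v, h).item() == pytest.approx(expect)

    def test_symmetry(self):
        p, q = rng.normal(size=(5, 2)), rng.normal(size=(7, 2))
        assert al.mmd2(p, q, 1.3).item() == pytest.approx(
            al.mmd2(q, p, 1.3).item(), abs=1e-12)

    def test_linear_kernel_is_mean_difference(self):
        p, q = rng.normal(size=(5, 2)), rng.normal(size=(7, 2))
        expect = np.sum((p.mean(0) - q.mean(0)) ** 2)
        assert al.mmd2(p, q, 1.0, kernel="linear").item() == \
            pytest.approx(expect)

    def test_unbiased_estimator_centers_on_zero(self):
        vals = []
        for s in range(200):
            r = np.random.default_rng(s)
            vals.append(al.mmd2(r.normal(size=(20, 2)),
                                r.normal(size=(20, 2)), 1.0,
                                unbiased=True).item())
        assert abs(np.mean(vals)) < 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            al.mmd2(np.zeros((0, 2)), np.zeros((3, 2)), 1.0)


class TestStratifiedMMD:
    def test_single_stratum_skips_to_zero(self):
        z = rng.normal(size=(8, 2))
        assert al.loss_mmd_strata(z, np.zeros(8, dtype=int)).item() == 0.0

    def test_three_strata_match_pairwise_oracle(self):
        z = rng.normal(size=(18, 3))
        s = np.repeat([0, 1, 2], 6)
        h = al.median_bandwidth(z)
        oracle = 0.0
        for a in range(3):
            for b in range(a + 1, 3):
                w = (2 * 6 * 6 / 12) / 18
                oracle += w * al.mmd2(z[s == a], z[s == b], h).item()
        assert al.loss_mmd_strata(z, s).item() == pytest.approx(oracle)

    def test_conditional_reduces_to_marginal_for_one_class(self):
        z = rng.normal(size=(12, 2))
        s = np.repeat([0, 1], 6)
        y = np.zeros(12, dtype=int)
        assert al.loss_cond_align(z, y, s).item() == pytest.approx(
            al.loss_mmd_strata(z, s).item())

    def test_conditional_matches_double_loop_oracle(self):
        z = rng.normal(size=(24, 3))
        y = np.repeat([0, 1], 12)
        s = np.tile(np.repeat([0, 1], 6), 2)
        h = al.median_bandwidth(z)
        oracle = 0.0
        for k in (0, 1):
            ia = np.flatnonzero((y == k) & (s == 0))
            ib = np.flatnonzero((y == k) & (s == 1))
            w = (2 * len(ia) * len(ib) / (len(ia) + len(ib))) / 24
            oracle += w * al.mmd2(z[ia], z[ib], h).item()
        assert al.loss_cond_align(z, y, s).item() == pytest.approx(oracle)

    def test_identical_subgroup_samples_give_zero(self):
        block = rng.normal(size=(5, 2))
        z = np.vstack([block, block])
        s = np.repeat([0, 1], 5)
        assert al.loss_mmd_strata(z, s).item() == pytest.approx(0, abs=1e-12)


# -------------------------------------------------------------- contrastive

class TestSupCon:
    def test_worked_three_point_example(self):
        z = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([0, 1, 0])
        val = al.loss_supcon(z, y, tau=1.0).item()
        assert val == pytest.approx(np.log(1 + np.e) - 1, abs=1e-9)

    def test_two_identical_same_class_is_zero(self):
        z = np.array([[0.6, 0.8], [0.6, 0.8]])
        assert al.loss_supcon(z, np.array([1, 1]), 1.0).item() == \
            pytest.approx(0.0, abs=1e-9)

    def test_scale_invariance(self):
        z = rng.normal(size=(10, 4))
        y = rng.integers(0, 3, size=10)
        assert al.loss_supcon(z, y, 0.5).item() == pytest.approx(
            al.loss_supcon(5 * z, y, 0.5).item(), abs=1e-9)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_explicit_double_loop(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 16))
        z = r.normal(size=(n, 5))
        y = r.integers(0, 3, size=n)
        zn = z / np.linalg.norm(z, axis=1, keepdims=True)
        sim = zn @ zn.T
        tau = 0.8
        total, pairs = 0.0, 0
        for i in range(n):
            denom = sum(np.exp(sim[i, k] / tau) for k in range(n) if k != i)
            for j in range(n):
                if j != i and y[j] == y[i]:
                    total += -np.log(np.exp(sim[i, j] / tau) / denom)
                    pairs += 1
        if pairs:
            assert al.loss_supcon(z, y, tau).item() == pytest.approx(
                total / pairs, abs=1e-6)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValidationError):
            al.loss_supcon(rng.normal(size=(3, 2)), np.zeros(3, int), 0.0)


class TestStability:
    def test_zero_sigma_is_zero(self):
        assert al.loss_stability(rng.normal(size=(5, 8)), 0.0).item() == 0.0

    def test_chi_square_moment(self):
        z = np.zeros((10_000, 8))
        val = al.loss_stability(z, 0.1, seed=0).item()
        assert val == pytest.approx(0.08, rel=0.05)

    def test_deterministic_given_seed(self):
        z = rng.normal(size=(6, 4))
        assert al.loss_stability(z, 0.2, seed=5).item() == \
            al.loss_stability(z, 0.2, seed=5).item()


class TestHardContrastive:
    def test_identical_positive_orthogonal_negative(self):
        z = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        y = np.array([0, 0, 1])
        # both class-0 anchors: positive sim 1, negative sim 0, tau=1
        expect = -np.log(np.e / (np.e + 1))
        assert al.loss_hard_contrastive(z, y, 1.0, 5).item() == \
            pytest.approx(expect, abs=1e-9)

    def test_separable_limit_vanishes_at_small_tau(self):
        z = np.array([[1.0, 0.0], [1.0, 0.0], [-1.0, 0.0]])
        y = np.array([0, 0, 1])
        assert al.loss_hard_contrastive(z, y, 0.01, 5).item() == \
            pytest.approx(0.0, abs=1e-12)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_hard_k_all_matches_brute_force(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 12))
        z = r.normal(size=(n, 3))
        y = r.integers(0, 2, size=n)
        zn = z / np.linalg.norm(z, axis=1, keepdims=True)
        sim = zn @ zn.T
        tau = 0.5
        vals = []
        for i in range(n):
            pos = [j for j in range(n) if j != i and y[j] == y[i]]
            neg = [j for j in range(n) if y[j] != y[i]]
            if not pos or not neg:
                continue
            j_star = pos[int(np.argmin([sim[i, j] for j in pos]))]
            num = np.exp(sim[i, j_star] / tau)
            den = num + sum(np.exp(sim[i, k] / tau) for k in neg)
            vals.append(-np.log(num / den))
        if vals:
            got = al.loss_hard_contrastive(z, y, tau, hard_k=n).item()
            assert got == pytest.approx(np.mean(vals), abs=1e-6)


class TestCentersAndStats:
    def test_center_loss_zero_at_centers(self):
        stats = ClassStats(2, 2, 3)
        stats.centers[:] = [[1, 0, 0], [0, 1, 0]]
        stats.center_init[:] = True
        z = stats.centers[np.array([0, 1, 0])]
        assert al.loss_center(z, [0, 1, 0], stats).item() == 0.0

    def test_zero_decay_tracks_batch_means(self):
        stats = ClassStats(2, 2, 2, ema_decay=0.0)
        stats.center_init[:] = True
        z = rng.normal(size=(8, 2))
        y = np.repeat([0, 1], 4)
        al.update_centers(z, y, stats)
        assert np.allclose(stats.centers[0], z[:4].mean(axis=0))
        assert np.allclose(stats.centers[1], z[4:].mean(axis=0))

    def test_center_ema_matches_hand_rolled_sequence(self):
        stats = ClassStats(1, 2, 2, ema_decay=0.9)
        mu = None
        for s in range(5):
            z = np.random.default_rng(s).normal(size=(6, 2))
            al.update_centers(z, np.zeros(6, int), stats)
            m = z.mean(axis=0)
            mu = m if mu is None else 0.9 * mu + 0.1 * m
        assert np.allclose(stats.centers[0], mu, atol=1e-10)

    def test_full_shrinkage_gives_isotropic_covariance(self):
        stats = ClassStats(1, 1, 3, shrink_alpha=1.0)
        z = rng.normal(size=(20, 3))
        al.update_gaussian_stats(z, np.zeros(20, int), np.zeros(20, int),
                                 stats)
        cov = stats.class_cov[0]
        off = cov - np.diag(np.diag(cov))
        assert np.allclose(off, 0)
        assert np.allclose(np.diag(cov), cov[0, 0])

    def test_shrunk_covariances_stay_positive_definite(self):
        stats = ClassStats(2, 2, 4, shrink_alpha=0.1)
        for s in range(5):
            r = np.random.default_rng(s)
            z = r.normal(size=(30, 4)) * r.uniform(0.01, 2.0)
            y = r.integers(0, 2, size=30)
            st_ = r.integers(0, 2, size=30)
            al.update_gaussian_stats(z, y, st_, stats)
        for k in range(2):
            np.linalg.cholesky(stats.class_cov[k])
            for s_ in range(2):
                if stats.cell_count[k, s_] > 0:
                    np.linalg.cholesky(stats.cell_cov[k, s_])

    def test_constant_embeddings_reach_identity_floor(self):
        stats = ClassStats(1, 1, 2, shrink_alpha=0.1, ema_decay=0.5)
        z = np.tile([[1.0, 2.0]], (10, 1))
        for _ in range(50):
            al.update_gaussian_stats(z, np.zeros(10, int), np.zeros(10, int),
                                     stats)
        assert np.allclose(stats.class_mean[0], [1.0, 2.0])
        cov = stats.class_cov[0]
        assert np.allclose(cov, cov[0, 0] * np.eye(2))  # isotropic floor


class TestInvariance:
    def _warm_stats(self, d=2):
        stats = ClassStats(2, 2, d)
        stats.class_count[:] = 100
        stats.cell_count[:] = 50
        for k in range(2):
            stats.class_cov[k] = np.eye(d)
            for s in range(2):
                stats.cell_cov[k, s] = np.eye(d)
                stats.cell_mean[k, s] = stats.class_mean[k]
        return stats

    def test_matching_cells_give_zero(self):
        assert al.loss_invariance(self._warm_stats()) == pytest.approx(0.0)

    def test_unit_mean_shift_closed_form(self):
        stats = self._warm_stats(d=1)
        stats.cell_mean[0, 0] = [1.0]   # KL(N(1,1)||N(0,1)) = 0.5
        assert al.loss_invariance(stats) == pytest.approx(0.5)

    def test_closed_form_matches_monte_carlo(self):
        m0, c0 = np.array([0.5, -0.2]), np.array([[0.8, 0.1], [0.1, 1.2]])
        m1, c1 = np.zeros(2), np.eye(2)
        closed = al._gauss_kl(m0, c0, m1, c1)
        r = np.random.default_rng(0)
        z = r.multivariate_normal(m0, c0, size=200_000)
        from scipy.stats import multivariate_normal
        mc = np.mean(multivariate_normal.logpdf(z, m0, c0)
                     - multivariate_normal.logpdf(z, m1, c1))
        assert closed == pytest.approx(mc, rel=0.02)

    def test_invariant_to_stratum_relabeling(self):
        stats = self._warm_stats()
        stats.cell_mean[0, 0] = [0.3, 0.0]
        stats.cell_mean[0, 1] = [0.0, -0.4]
        base = al.loss_invariance(stats)
        stats.cell_mean[0] = stats.cell_mean[0][::-1].copy()
        stats.cell_cov[0] = stats.cell_cov[0][::-1].copy()
        assert al.loss_invariance(stats) == pytest.approx(base)

    def test_batch_variant_agrees_with_closed_form(self):
        stats = ClassStats(1, 2, 2, shrink_alpha=0.1)
        stats.class_count[0] = 100
        stats.class_mean[0] = np.zeros(2)
        stats.class_cov[0] = np.eye(2)
        r = np.random.default_rng(2)
        z = r.normal(size=(40, 2))
        y = np.zeros(40, int)
        s = np.repeat([0, 1], 20)
        got = al.loss_invariance_batch(z, y, s, stats).item()
        oracle = 0.0
        for st_ in (0, 1):
            zc = z[s == st_]
            m = zc.mean(axis=0)
            c = (zc - m).T @ (zc - m) / len(zc)
            c = 0.9 * c + 0.1 * (np.trace(c) / 2 + al.COV_FLOOR) * np.eye(2)
            oracle += al._gauss_kl(m, c, np.zeros(2), np.eye(2))
        assert got == pytest.approx(oracle, abs=1e-9)


class TestCounterfactualLoss:
    def test_min_enumeration(self):
        cf = np.zeros((1, 4))
        targets = np.stack([np.full(4, 1.0), np.full(4, 1.5)])  # d2: 4, 9
        assert al.loss_counterfactual(cf, targets).item() == pytest.approx(4.0)

    def test_identical_target_contributes_zero(self):
        cf = rng.normal(size=(1, 6))
        targets = np.vstack([cf, rng.normal(size=(1, 6))])
        assert al.loss_counterfactual(cf, targets).item() == \
            pytest.approx(0.0, abs=1e-12)

    def test_extra_far_target_never_increases(self):
        cf = rng.normal(size=(3, 5))
        tgt = rng.normal(size=(4, 5))
        base = al.loss_counterfactual(cf, tgt).item()
        more = np.vstack([tgt, np.full((1, 5), 100.0)])
        assert al.loss_counterfactual(cf, more).item() <= base + 1e-12


class TestDomainConfusion:
    def _head(self):
        from neurofact.nn import Linear
        return Linear(4, 2, np.random.default_rng(0))

    def test_disabled_branch_rejected(self):
        with pytest.raises(ValidationError):
            al.domain_confusion_loss(None, rng.normal(size=(4, 4)),
                                     np.zeros(4, int), 1.0)

    def test_uniform_predictions_give_log2(self):
        head = self._head()
        head.W.data[:] = 0
        head.b.data[:] = 0
        z = rng.normal(size=(8, 4))
        s = np.repeat([0, 1], 4)
        assert al.domain_confusion_loss(head, z, s, 1.0).item() == \
            pytest.approx(np.log(2))

    def test_zero_strength_blocks_encoder_gradient(self):
        head = self._head()
        z = Tensor(rng.normal(size=(6, 4)), requires_grad=True)
        al.domain_confusion_loss(head, z, np.zeros(6, int), 0.0).backward()
        assert z.grad is None or np.allclose(z.grad, 0)

    def test_encoder_gradient_is_negated_and_scaled(self):
        head = self._head()
        s = np.array([0, 1, 0, 1])
        z0 = rng.normal(size=(4, 4))
        za = Tensor(z0, requires_grad=True)
        al.domain_confusion_loss(head, za, s, 1.0).backward()
        zb = Tensor(z0, requires_grad=True)
        al.domain_confusion_loss(head, zb, s, 2.5).backward()
        assert np.allclose(zb.grad, 2.5 * za.grad)


class TestTotal:
    def test_zero_lambdas_reduce_to_task(self):
        w = LossWeights(lambda1=0, lambda2=0, lambda3=0, lambda4=0, lambda5=0)
        terms = {"task": 3.2, "mmd": 9.0, "cond": 9.0, "contrastive": 9.0,
                 "inv": 9.0, "cf": 9.0}
        assert al.total_cdaa(terms, w).item() == pytest.approx(3.2)

    def test_weighted_sum_matches_spreadsheet_oracle(self):
        w = LossWeights()
        vals = dict(zip(["task", "mmd", "cond", "contrastive", "inv", "cf"],
                        rng.uniform(0.1, 3.0, size=6)))
        expect = (vals["task"]
                  + w.lambda1 * w.lambda_m * vals["mmd"]
                  + w.lambda2 * w.lambda_c * vals["cond"]
                  + w.lambda3 * vals["contrastive"]
                  + w.lambda4 * vals["inv"]
                  + w.lambda5 * vals["cf"])
        assert al.total_cdaa(vals, w).item() == pytest.approx(expect,
                                                              abs=1e-12)

    def test_missing_term_is_named(self):
        with pytest.raises(ValidationError, match="inv"):
            al.total_cdaa({"task": 1.0, "mmd": 0, "cond": 0,
                           "contrastive": 0, "cf": 0}, LossWeights())
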