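"""Fairer multiplicative-updates scheme: weights, stacking, steps, fits."""

import dataclasses

import numpy as np
import pytest

from fairnmf import (
    FairerMUState,
    Factorization,
    FitConfig,
    GroupedMatrix,
    build_stacked,
    compute_metrics,
    fit_fairer_mu,
    fit_standard,
    mu_step,
    mu_update_h,
    select_worst_group,
    update_c,
)


def _grouped(rng, m=24, n=6, L=2):
    labels = np.repeat(np.arange(L), m // L)
    return GroupedMatrix(rng.uniform(size=(labels.size, n)), labels).normalized()


class TestWorstGroupSelection:
    def _with_losses(self, rng, losses):
        G = _grouped(rng, L=len(losses))
        F = Factorization(rng.uniform(size=(G.m, 2)), rng.uniform(size=(2, G.n)))
        errs = np.array(
            [np.linalg.norm(G.block(l) - F.W[G.group_indices[l]] @ F.H) for l in range(G.L)]
        )
        E = errs - np.asarray(losses) * G.group_norms
        E = np.maximum(E, 0)  # keep valid baselines
        return G, F, E

    def test_examples(self, rng):
        G, F, E = self._with_losses(rng, [0.2, 0.5])
        assert select_worst_group(G, F, E) == 1

    def test_exact_tie_breaks_to_lowest_index(self, rng):
        # two bit-identical group blocks and factors -> exactly equal losses
        block = rng.uniform(size=(6, 5))
        Wb = rng.uniform(size=(6, 2))
        G = GroupedMatrix(np.vstack([block, block]), np.repeat(["a", "b"], 6))
        F = Factorization(np.vstack([Wb, Wb]), rng.uniform(size=(2, 5)))
        assert select_worst_group(G, F, [0.1, 0.1]) == 0

    def test_agrees_with_metrics_argmax(self, rng):
        for _ in range(20):
            L = int(rng.integers(2, 5))
            G, F, E = self._with_losses(rng, rng.uniform(0.05, 0.6, size=L))
            assert select_worst_group(G, F, E) == compute_metrics(G, F, E).worst_group


class TestWeightUpdate:
    def test_first_step_is_vertex(self):
        s = update_c(FairerMUState.initial(3), 0)
        np.testing.assert_array_equal(s.c, [1, 0, 0])
        assert s.k == 1 and s.worst_history == (0,)

    def test_unnormalized_matches_normalized_rule(self):
        # c=(1,0), worst=2 -> (1,1); normalized (0.5,0.5) equals
        # (k-1)/k*(1,0) + 1/k*e2 at k=2
        s = update_c(FairerMUState(c=np.array([1.0, 0.0]), k=1), 1)
        np.testing.assert_array_equal(s.c, [1, 1])
        np.testing.assert_allclose(s.c / s.c.sum(), [0.5, 0.5])

    def test_mass_counts_iterations(self, rng):
        s = FairerMUState.initial(4)
        for _ in range(13):
            s = update_c(s, int(rng.integers(4)))
        assert s.c.sum() == 13 and s.k == 13

    def test_invalid_index_raises(self):
        with pytest.raises(IndexError):
            update_c(FairerMUState.initial(2), 5)


class TestStackedPair:
    def test_zero_weight_zero_block(self, rng):
        G = _grouped(rng)
        F = Factorization(rng.uniform(size=(G.m, 2)), rng.uniform(size=(2, G.n)))
        sp = build_stacked(G, F, [1.0, 0.0])
        np.testing.assert_array_equal(sp.X_tilde[G.group_indices[1]], 0.0)
        np.testing.assert_array_equal(sp.W_tilde[G.group_indices[1]], 0.0)

    def test_linear_in_c(self, rng):
        G = _grouped(rng)
        F = Factorization(rng.uniform(size=(G.m, 2)), rng.uniform(size=(2, G.n)))
        a = build_stacked(G, F, [1.0, 2.0])
        b = build_stacked(G, F, [7.0, 14.0])
        np.testing.assert_allclose(b.X_tilde, 7 * a.X_tilde)
        np.testing.assert_allclose(b.W_tilde, 7 * a.W_tilde)

    def test_single_group_is_normalized_matrix(self, rng):
        G = GroupedMatrix(rng.uniform(size=(8, 4)), np.zeros(8))
        F = Factorization(rng.uniform(size=(8, 2)), rng.uniform(size=(2, 4)))
        sp = build_stacked(G, F, [1.0])
        np.testing.assert_allclose(sp.X_tilde, G.X / np.linalg.norm(G.X))

    def test_all_zero_weights_rejected(self, rng):
        G = _grouped(rng)
        F = Factorization(rng.uniform(size=(G.m, 2)), rng.uniform(size=(2, G.n)))
        with pytest.raises(ValueError, match="all zero"):
            build_stacked(G, F, [0.0, 0.0])


class TestScaleInvariance:
    def test_h_update_invariant_under_c_rescaling(self, rng):
        """Positive rescaling of the group weights leaves the stacked H
        update unchanged to 1e-12 relative — the identity licensing the
        unnormalized accumulation rule."""
        G = _grouped(rng, L=3, m=30)
        F = Factorization(rng.uniform(size=(G.m, 3)), rng.uniform(size=(3, G.n)))
        c = np.array([3.0, 1.0, 2.0])
        for alpha in (10.0, 0.125, 1e3):
            a = build_stacked(G, F, c)
            b = build_stacked(G, F, alpha * c)
            Ha = mu_update_h(a.X_tilde, a.W_tilde, F.H)
            Hb = mu_update_h(b.X_tilde, b.W_tilde, F.H)
            np.testing.assert_allclose(Ha, Hb, rtol=1e-12)


class TestMUStep:
    def test_single_group_reduces_to_standard_update(self, rng):
        """At L=1 the stacked update is the standard MU update on X/‖X‖,
        which equals the update on (X, W) by scale cancellation."""
        G = GroupedMatrix(rng.uniform(size=(10, 5)), np.zeros(10))
        F = Factorization(rng.uniform(size=(10, 2)), rng.uniform(size=(2, 5)))
        state = FairerMUState.initial(1)
        F2, _ = mu_step(G, F, state, [0.0])
        H_std = mu_update_h(G.X, F.W, F.H)
        np.testing.assert_allclose(F2.H, H_std, rtol=1e-12)

    def test_zero_entries_of_h_remain_zero_for_interior_weights(self, rng):
        """Once every group carries weight, the update is multiplicative and
        preserves exact zeros of H."""
        G = _grouped(rng)
        H = rng.uniform(size=(2, G.n))
        H[1, 3] = 0.0
        F = Factorization(rng.uniform(size=(G.m, 2)), H)
        state = FairerMUState(c=np.array([2.0, 1.0]), k=3)
        F2, _ = mu_step(G, F, state, [0.0, 0.0])
        assert F2.H[1, 3] == 0.0

    def test_records_worst_history(self, rng):
        G = _grouped(rng)
        F = Factorization(rng.uniform(size=(G.m, 2)), rng.uniform(size=(2, G.n)))
        state = FairerMUState.initial(2)
        E = np.zeros(2)
        w0 = select_worst_group(G, F, E)
        F, state = mu_step(G, F, state, E)
        assert state.worst_history == (w0,)
        assert state.c.sum() == 1


class TestFitFairerMU:
    def test_single_group_reduction(self, rng):
        G = GroupedMatrix(rng.uniform(size=(40, 8)), np.zeros(40)).normalized()
        cfg = FitConfig(rank=3, max_iter=300, seed=23)
        e_fair = fit_fairer_mu(G, [0.0], cfg).metrics.relative_errors[0]
        e_std = fit_standard(G, cfg).error_trace[-1, 0]
        assert abs(e_fair - e_std) < 0.01

    def test_c_history_replayable(self, dataset1, dataset1_baseline_r6):
        cfg = FitConfig(rank=6, max_iter=30, seed=2)
        res = fit_fairer_mu(dataset1, dataset1_baseline_r6, cfg)
        ct = res.extras["c_trace"]
        hist = res.extras["worst_history"]
        assert ct.shape[0] == res.n_iter + 1
        # each recorded worst index is where c gained its unit of mass
        for k, w in enumerate(hist):
            gained = ct[k + 1] - ct[k]
            assert gained[w] == 1.0 and gained.sum() == 1.0

    def test_exact_c_mode_fails_to_find_low_loss(self, dataset1, dataset1_baseline_r6):
        """Jumping to the vertex weights every step destroys the unweighted
        group's dictionary; the decreasing-step rule finds a far lower
        max-loss on the same data and seed."""
        cfg = FitConfig(rank=6, max_iter=300, error_floor_pct=0.1, seed=4)
        f_dec = fit_fairer_mu(dataset1, dataset1_baseline_r6, cfg).metrics.f
        f_exact = fit_fairer_mu(
            dataset1, dataset1_baseline_r6, dataclasses.replace(cfg, c_rule="exact")
        ).metrics.f
        assert f_exact > f_dec + 0.2

    def test_improves_worst_group_over_standard_on_average(self, dataset1):
        """The min-max MU scheme typically finds a lower max-loss than
        standard NMF on the complexity-imbalanced benchmark."""
        from fairnmf import derive_seed, estimate_all_baselines

        f_mu, f_std = [], []
        for trial in range(5):
            cfg = FitConfig(
                rank=6, max_iter=500, error_floor_pct=0.1,
                seed=derive_seed(0, "fit", 6, trial),
            )
            E = estimate_all_baselines(
                dataset1, cfg, T=5, seed=derive_seed(0, "baseline", 6, trial)
            )
            f_mu.append(fit_fairer_mu(dataset1, E, cfg).metrics.f)
            f_std.append(fit_standard(dataset1, cfg, E.E).metrics.f)
        assert np.mean(f_mu) < np.mean(f_std)
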