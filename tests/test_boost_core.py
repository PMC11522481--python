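"""Boosting core: working responses, closed forms, selection, fitting loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genoboost.boost_core import (
    DegenerateVariantError,
    HyperParams,
    NoSelectableVariantError,
    SampleState,
    SufficientStats,
    accumulate_stats,
    boost_fit,
    compute_sample_state,
    learner_loss,
    predict_genetic_score,
    select_variant,
    solve_additive,
    solve_nonadditive,
    training_log_loss,
)
from genoboost.covariate_model import linear_predictor
from genoboost.evaluate import auc
from genoboost.geno_io import MISSING, PhenotypeTable

from conftest import make_matrix, make_pheno


class TestSampleState:
    @pytest.mark.parametrize("F,y,p,z,w", [
        (0.0, 1, 0.5, 2.0, 0.25),
        (0.0, -1, 0.5, -2.0, 0.25),
        (np.log(3), 1, 0.75, 4 / 3, 0.1875),
    ])
    def test_newton_step_quantities(self, F, y, p, z, w):
        s = compute_sample_state(np.array([F]), np.array([y]))
        assert s.p[0] == pytest.approx(p)
        assert s.z[0] == pytest.approx(z)
        assert s.w[0] == pytest.approx(w)

    def test_response_clipped_and_weight_floored(self):
        s = compute_sample_state(np.array([-20.0]), np.array([1]), z_max=4.0,
                                 w_floor=1e-10)
        assert s.z[0] == 4.0
        assert s.w[0] >= 1e-10

    def test_sign_of_z_matches_label(self):
        rng = np.random.default_rng(0)
        F = rng.normal(size=50)
        y = rng.choice([-1, 1], size=50)
        s = compute_sample_state(F, y)
        assert (np.sign(s.z) == y).all()

    def test_nonfinite_predictor_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            compute_sample_state(np.array([np.inf]), np.array([1]))


def state_from(w, z):
    w = np.asarray(w, dtype=float)
    z = np.asarray(z, dtype=float)
    return SampleState(F=np.zeros_like(w), p=np.full_like(w, 0.5), z=z, w=w)


class TestAccumulateStats:
    def test_one_sample_per_class(self):
        s = accumulate_stats(np.array([0, 1, 2]), state_from([1, 1, 1], [0, 1, 2]))
        np.testing.assert_allclose(s.W, [1, 1, 1])
        np.testing.assert_allclose(s.U, [0, 1, 2])
        np.testing.assert_allclose(s.Q, [0, 1, 4])

    def test_missing_excluded(self):
        s = accumulate_stats(np.array([0, 0, MISSING]),
                             state_from([2, 3, 9], [1, -1, 5]))
        np.testing.assert_allclose(s.W, [5, 0, 0])
        np.testing.assert_allclose(s.U, [-1, 0, 0])

    def test_all_missing_gives_zeros(self):
        s = accumulate_stats(np.full(3, MISSING), state_from([1, 1, 1], [1, 1, 1]))
        assert s.W.sum() == 0 and s.U.sum() == 0

    def test_class_sums_bounded_by_total_weight(self):
        rng = np.random.default_rng(2)
        col = rng.choice([0, 1, 2, MISSING], size=100)
        w = rng.random(100)
        s = accumulate_stats(col, state_from(w, rng.normal(size=100)))
        assert s.W.sum() <= w.sum() + 1e-12


class TestSolveAdditive:
    @pytest.mark.parametrize("W,U,expected", [
        ((1, 1, 1), (0, 1, 2), (0.0, 1.0)),
        ((1, 1, 1), (0, 1, 0), (1 / 3, 0.0)),
        ((4, 2, 0), (0, 2, 0), (0.0, 1.0)),
    ])
    def test_closed_form_examples(self, W, U, expected):
        stats = SufficientStats(W=np.array(W, float), U=np.array(U, float))
        c, alpha = solve_additive(stats)
        assert c == pytest.approx(expected[0])
        assert alpha == pytest.approx(expected[1])

    def test_degenerate_single_class(self):
        stats = SufficientStats(W=np.array([5.0, 0, 0]), U=np.array([1.0, 0, 0]))
        with pytest.raises(DegenerateVariantError):
            solve_additive(stats)

    def test_matches_numerical_weighted_least_squares(self):
        """Closed form equals the 2x2 weighted normal-equations solve."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            W = rng.random(3) * 10
            zbar = rng.normal(size=3) * 4
            U = W * zbar
            stats = SufficientStats(W=W, U=U)
            c, alpha = solve_additive(stats)
            # direct normal equations for min sum_k W_k (c + alpha*k - zbar_k)^2
            g = np.array([0.0, 1.0, 2.0])
            A = np.array([[W.sum(), (W * g).sum()],
                          [(W * g).sum(), (W * g * g).sum()]])
            b = np.array([U.sum(), (U * g).sum()])
            ref = np.linalg.solve(A, b)
            assert abs(c - ref[0]) <= 1e-8 * max(1, abs(ref[0]))
            assert abs(alpha - ref[1]) <= 1e-8 * max(1, abs(ref[1]))


class TestSolveNonadditive:
    def test_elementwise_ratio(self):
        stats = SufficientStats(W=np.array([2.0, 4, 1]), U=np.array([1.0, 2, 3]))
        assert solve_nonadditive(stats) == pytest.approx((0.5, 0.5, 3.0))

    def test_s2_clamped_toward_baseline(self):
        stats = SufficientStats(W=np.array([2.0, 4, 1]), U=np.array([1.0, 2, 3]))
        assert solve_nonadditive(stats, s2_clip=1.0) == pytest.approx((0.5, 0.5, 1.5))

    def test_empty_homozygote_class_imputed_from_het(self):
        stats = SufficientStats(W=np.array([2.0, 4, 0]), U=np.array([1.0, 2, 0]))
        assert solve_nonadditive(stats) == pytest.approx((0.5, 0.5, 0.5))

    def test_empty_het_class_imputed_to_midpoint(self):
        stats = SufficientStats(W=np.array([2.0, 0, 2]), U=np.array([0.0, 0, 4]))
        assert solve_nonadditive(stats) == pytest.approx((0.0, 1.0, 2.0))

    def test_scores_are_weighted_class_means(self):
        rng = np.random.default_rng(3)
        col = rng.choice([0, 1, 2], size=200)
        w = rng.random(200)
        z = rng.normal(size=200)
        stats = accumulate_stats(col, state_from(w, z))
        s = solve_nonadditive(stats)
        for k in range(3):
            sel = col == k
            assert s[k] == pytest.approx(np.average(z[sel], weights=w[sel]))


class TestLearnerLoss:
    def test_exact_fit_has_zero_loss(self):
        stats = SufficientStats(W=np.ones(3), U=np.array([0.0, 1, 2]),
                                Q=np.array([0.0, 1, 4]))
        assert learner_loss(stats, (0, 1, 2)) == pytest.approx(0.0)

    def test_constant_scores_classwise_formula(self):
        stats = SufficientStats(W=np.ones(3), U=np.array([0.0, 1, 2]),
                                Q=np.array([0.0, 1, 4]))
        assert learner_loss(stats, (1, 1, 1)) == pytest.approx(2.0)

    def test_empty_stats_zero(self):
        assert learner_loss(SufficientStats(W=np.zeros(3), U=np.zeros(3)),
                            (1, 2, 3)) == 0.0

    def test_equals_sample_level_sum(self):
        rng = np.random.default_rng(5)
        col = rng.choice([0, 1, 2, MISSING], size=300)
        w = rng.random(300)
        z = rng.normal(size=300)
        stats = accumulate_stats(col, state_from(w, z))
        f = (0.3, -0.1, 0.8)
        direct = sum(w[i] * (f[col[i]] - z[i]) ** 2
                     for i in range(300) if col[i] != MISSING)
        assert learner_loss(stats, f) == pytest.approx(direct)

    def test_nesting_nonadditive_additive_constant(self):
        """Freeing the heterozygote can only lower the weighted loss."""
        rng = np.random.default_rng(8)
        for _ in range(50):
            col = rng.choice([0, 1, 2], size=120)
            w = rng.random(120) + 0.01
            z = rng.normal(size=120)
            stats = accumulate_stats(col, state_from(w, z))
            s = solve_nonadditive(stats)
            c, alpha = solve_additive(stats)
            const = stats.U.sum() / stats.W.sum()
            l_non = learner_loss(stats, s)
            l_add = learner_loss(stats, (c, c + alpha, c + 2 * alpha))
            l_const = learner_loss(stats, (const, const, const))
            assert l_non <= l_add + 1e-9
            assert l_add <= l_const + 1e-9


class TestSelectVariant:
    def test_argmin(self):
        assert select_variant(np.array([3.0, 1.0, 2.0])) == 1

    def test_tie_breaks_to_smallest_index(self):
        assert select_variant(np.array([1.0, 1.0])) == 0

    def test_all_degenerate_errors(self):
        with pytest.raises(NoSelectableVariantError):
            select_variant(np.array([np.inf, np.inf]))


class TestBoostFit:
    def test_zero_iterations_is_covariate_only(self, small_cohort):
        G, pheno, _ = small_cohort
        model = boost_fit(G, pheno, HyperParams(gamma=0.1, T=0))
        assert model.learners == []
        assert predict_genetic_score(model, G).tolist() == [0.0] * G.n_samples

    def test_separating_variant_reaches_training_auc_one(self):
        # genotype 2 <=> case: one variant separates classes perfectly
        col = np.array([0] * 10 + [2] * 10, dtype=np.int8)
        G = make_matrix(col[:, None])
        pheno = make_pheno([-1] * 10 + [1] * 10)
        model = boost_fit(G, pheno, HyperParams(gamma=1.0, T=25), "nonadditive")
        pgs = predict_genetic_score(model, G)
        assert auc(pgs, pheno.y) == 1.0

    def test_first_selection_is_brute_force_loss_minimizer(self, causal_vs_null_cohort):
        G, pheno, truth = causal_vs_null_cohort
        model = boost_fit(G, pheno, HyperParams(gamma=0.1, T=1), "nonadditive")
        first = model.learners[0][0].variant_index

        # independent brute force: loss of every variant at iteration 0
        F0 = linear_predictor(model.covariate_fit, pheno.covariates)
        state = compute_sample_state(F0, pheno.y)
        losses = []
        for j in range(G.n_variants):
            stats = accumulate_stats(G.dosages[:, j], state)
            if (stats.W > 0).sum() < 2:
                losses.append(np.inf)
                continue
            losses.append(learner_loss(stats, solve_nonadditive(stats)))
        assert first == int(np.argmin(losses))
        assert first == truth.causal_indices[0]

    def test_training_log_loss_nonincreasing(self, small_cohort):
        G, pheno, _ = small_cohort
        losses = []

        def trace(t, learner, F):
            losses.append(training_log_loss(F, pheno.y))

        boost_fit(G, pheno, HyperParams(gamma=0.1, T=200), "nonadditive",
                  trace_callback=trace)
        diffs = np.diff(losses)
        assert (diffs <= 1e-12).all()

    def test_collapse_matches_learner_list_predictions(self, small_cohort):
        G, pheno, _ = small_cohort
        model = boost_fit(G, pheno, HyperParams(gamma=0.5, T=40), "nonadditive")
        # learner-by-learner accumulation
        F = np.zeros(G.n_samples)
        for learner, gamma in model.learners:
            col = G.dosages[:, learner.variant_index]
            for k in range(3):
                F[col == k] += gamma * learner.scores[k]
        np.testing.assert_allclose(F, predict_genetic_score(model, G), atol=1e-12)
        # repeat selections must have occurred for this to be a real check
        assert len(model.learners) > model.n_selected()

    def test_additive_mode_scores_lie_on_a_line(self, small_cohort):
        G, pheno, _ = small_cohort
        model = boost_fit(G, pheno, HyperParams(gamma=0.1, T=30), "additive")
        for learner, _ in model.learners:
            f0, f1, f2 = learner.scores
            assert f1 - f0 == pytest.approx(f2 - f1, abs=1e-12)
            assert f0 == pytest.approx(learner.c)
            assert f1 - f0 == pytest.approx(learner.alpha)

    def test_batch_screening_restricts_between_full_scans(self, small_cohort):
        """With batching forced on, selections between full scans stay in
        the batch retained from the last full scan."""
        import genoboost.boost_core as bc
        G, pheno, _ = small_cohort
        old = bc.FULL_SCAN_MAX_VARIANTS
        bc.FULL_SCAN_MAX_VARIANTS = 5  # force the batch path for this panel
        try:
            hp = HyperParams(gamma=0.2, T=12, m_batch=6)
            model = boost_fit(G, pheno, hp, "nonadditive")
        finally:
            bc.FULL_SCAN_MAX_VARIANTS = old
        full = boost_fit(G, pheno, HyperParams(gamma=0.2, T=12, m_batch=6),
                         "nonadditive")
        # batch run selects from a restricted pool but stays a valid model
        assert len(model.learners) == 12
        # first selection (full scan) agrees with the unbatched run
        assert model.learners[0][0].variant_index == full.learners[0][0].variant_index

    def test_single_class_labels_rejected(self, small_cohort):
        G, _, _ = small_cohort
        pheno = PhenotypeTable(list(G.samples), np.ones(G.n_samples, dtype=int),
                               np.empty((G.n_samples, 0)))
        with pytest.raises(ValueError, match="class"):
            boost_fit(G, pheno, HyperParams(T=1))


class TestPredictGeneticScore:
    def test_triplet_lookup_with_missing_zero(self):
        from genoboost.boost_core import GenoBoostModel, WeakLearner
        from genoboost.covariate_model import LogisticFit
        G = make_matrix(np.array([[0], [1], [2], [MISSING]]))
        fit = LogisticFit(0.0, np.empty(0), -1.0, True)
        learner = WeakLearner(variant_index=0, mode="nonadditive",
                              scores=(0.0, 0.3, 0.9))
        model = GenoBoostModel(fit, [(learner, 1.0)], "nonadditive",
                               G.variant_ids(), list(G.variants))
        np.testing.assert_allclose(predict_genetic_score(model, G),
                                   [0.0, 0.3, 0.9, 0.0])

    def test_absent_variant_errors_with_id(self, small_cohort):
        G, pheno, _ = small_cohort
        model = boost_fit(G, pheno, HyperParams(gamma=0.1, T=5))
        G2 = G.subset_variants(np.zeros(G.n_variants, dtype=bool))
        with pytest.raises(KeyError, match="absent"):
            predict_genetic_score(model, G2)

    def test_flipped_alleles_reoriented_at_prediction(self, small_cohort):
        from dataclasses import replace
        G, pheno, _ = small_cohort
        model = boost_fit(G, pheno, HyperParams(gamma=0.1, T=10))
        ref = predict_genetic_score(model, G)
        flipped = G.dosages.copy()
        obs = flipped != MISSING
        flipped[obs] = 2 - flipped[obs]
        variants = [replace(v, allele_ref=v.allele_alt, allele_alt=v.allele_ref)
                    for v in G.variants]
        G_flip = type(G)(flipped, variants, list(G.samples))
        np.testing.assert_allclose(predict_genetic_score(model, G_flip), ref,
                                   atol=1e-12)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=10, deadline=None)
def test_intercept_shift_invariance(seed):
    """Shifting F by a constant changes z/w bookkeeping but the shifted
    predictor yields the same probabilities when the shift is kept in F."""
    rng = np.random.default_rng(seed)
    F = rng.normal(size=30)
    y = rng.choice([-1, 1], size=30)
    shift = 0.7
    s0 = compute_sample_state(F, y, z_max=100.0)
    s1 = compute_sample_state(F + shift, y, z_max=100.0)
    p0 = 1 / (1 + np.exp(-(s0.F + shift)))
    np.testing.assert_allclose(p0, s1.p, atol=1e-12)
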