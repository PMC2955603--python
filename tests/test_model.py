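"""Units for the priors, the phase design builder and the marginal likelihood."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln
from scipy.stats import poisson

from oracles import log_marginal_quadrature
from tvdbn.model import (
    ChangepointConfiguration,
    ExpressionDataset,
    Hyperparameters,
    PhaseDesign,
    PhaseModel,
    build_phase_design,
    changepoint_position_log_prior,
    gene_log_posterior_score,
    log_marginal_phase,
    parent_set_log_prior,
    truncated_poisson_pmf,
)


class TestTruncatedPoisson:
    def test_outside_truncation_is_zero(self):
        assert truncated_poisson_pmf(3, mean=1.0, kmax=2) == 0.0

    def test_normalized_value(self):
        # e^-1 * 1^k/k! over {0,1,2} -> 1/(1+1+0.5)
        assert truncated_poisson_pmf(0, mean=1.0, kmax=2) == pytest.approx(0.4)

    @given(mean=st.floats(0.05, 20.0), kmax=st.integers(0, 15))
    @settings(max_examples=40, deadline=None)
    def test_sums_to_one_over_support(self, mean, kmax):
        total = sum(truncated_poisson_pmf(k, mean, kmax) for k in range(kmax + 1))
        assert total == pytest.approx(1.0, rel=1e-12)

    @given(mean=st.floats(0.05, 20.0), kmax=st.integers(1, 12),
           k=st.integers(0, 11))
    @settings(max_examples=40, deadline=None)
    def test_successive_ratio_is_untruncated(self, mean, kmax, k):
        if k + 1 > kmax:
            return
        ratio = (truncated_poisson_pmf(k + 1, mean, kmax)
                 / truncated_poisson_pmf(k, mean, kmax))
        assert ratio == pytest.approx(mean / (k + 1), rel=1e-10)

    @pytest.mark.parametrize("bad_k", [-1, 0.5])
    def test_invalid_k_raises(self, bad_k):
        with pytest.raises(ValueError):
            truncated_poisson_pmf(bad_k, mean=1.0, kmax=3)


class TestStructurePriors:
    def test_no_changepoints_has_log_prior_zero(self):
        cfg = ChangepointConfiguration.from_interior([], n=12)
        assert changepoint_position_log_prior(cfg, 12) == 0.0

    @pytest.mark.parametrize("k", [1, 2])
    def test_matches_enumeration(self, k):
        # enumerate all strictly increasing interior vectors over {3..12}
        n = 12
        count = sum(1 for _ in itertools.combinations(range(3, n + 1), k))
        cfg = ChangepointConfiguration.from_interior(list(range(3, 3 + k)), n)
        assert changepoint_position_log_prior(cfg, n) == pytest.approx(-math.log(count))

    def test_invalid_configuration_rejected(self):
        with pytest.raises(ValueError):
            ChangepointConfiguration.from_interior([2], n=12)   # below support
        with pytest.raises(ValueError):
            ChangepointConfiguration.from_interior([5, 5], n=12)
        with pytest.raises(ValueError):
            ChangepointConfiguration(xi=(3, 13)).validate(12)   # wrong bound

    @pytest.mark.parametrize("s,q,expected", [
        (0, 5, 0.0),
        (1, 5, -math.log(5)),
        (2, 5, -math.log(len(list(itertools.combinations(range(5), 2))))),
    ])
    def test_parent_set_prior(self, s, q, expected):
        assert parent_set_log_prior(s, q) == pytest.approx(expected)

    def test_parent_set_prior_domain_error(self):
        with pytest.raises(ValueError):
            parent_set_log_prior(6, 5)


class TestDomainTypes:
    def test_dataset_needs_three_timepoints(self, rng):
        with pytest.raises(ValueError):
            ExpressionDataset(gene_ids=["a"], values=rng.normal(size=(1, 2, 1)))

    def test_dataset_rejects_hidden_nonfinite(self, rng):
        vals = rng.normal(size=(1, 4, 1))
        vals[0, 1, 0] = np.nan
        with pytest.raises(ValueError):
            ExpressionDataset(gene_ids=["a"], values=vals)
        # but masked non-finite cells are fine
        mask = np.zeros_like(vals, dtype=bool)
        mask[0, 1, 0] = True
        ExpressionDataset(gene_ids=["a"], values=vals, missing_mask=mask)

    def test_phase_model_invariants(self):
        with pytest.raises(ValueError):
            PhaseModel(parents={0, 1}, coeffs=[1.0, 0.0])
        with pytest.raises(ValueError):
            PhaseModel(parents={0}, coeffs=[1.0], sigma2=-1.0)

    def test_hyperparameters_validation(self):
        with pytest.raises(ValueError):
            Hyperparameters(c=0.3).validate()
        with pytest.raises(ValueError):
            Hyperparameters(chi=0.5, zeta=0.5, rho=0.5).validate()
        Hyperparameters().validate(n=12, n_candidates=5)


class TestBuildPhaseDesign:
    def test_direct_construction(self, rng):
        vals = rng.normal(size=(2, 4, 1))
        data = ExpressionDataset(gene_ids=["i", "j"], values=vals)
        design = build_phase_design(data, "i", ["j"], (2, 4))
        assert design.D.shape == (2, 2)
        np.testing.assert_allclose(design.D[:, 0], 1.0)
        np.testing.assert_allclose(design.D[:, 1], vals[1, 0:2, 0])
        np.testing.assert_allclose(design.y, vals[0, 1:3, 0])

    def test_shape_with_replicates(self, small_dataset):
        design = build_phase_design(small_dataset, "g0", ["g1", "g2"], (3, 6))
        assert design.D.shape == (2 * 3, 3)

    def test_intercept_only(self, small_dataset):
        design = build_phase_design(small_dataset, "g0", [], (2, 4))
        assert design.D.shape == (4, 1)
        assert np.all(design.D == 1.0)

    def test_empty_phase_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            build_phase_design(small_dataset, "g0", [], (4, 4))

    def test_missing_rows_dropped_and_all_missing_raises(self, rng):
        vals = rng.normal(size=(2, 4, 2))
        mask = np.zeros_like(vals, dtype=bool)
        mask[0, 1, 0] = True                     # target missing at t=2, rep 0
        data = ExpressionDataset(gene_ids=["i", "j"], values=vals, missing_mask=mask)
        design = build_phase_design(data, "i", ["j"], (2, 4))
        assert design.D.shape[0] == 3            # one of four rows dropped
        mask[0, 1, 1] = True
        mask[0, 2, :] = True
        data = ExpressionDataset(gene_ids=["i", "j"], values=vals, missing_mask=mask)
        with pytest.raises(ValueError, match="i"):
            build_phase_design(data, "i", ["j"], (2, 4))

    @given(st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_rows_pair_response_with_lagged_predictors(self, seed):
        rng = np.random.default_rng(seed)
        n, m = 6, 3
        vals = rng.normal(size=(2, n, m))
        data = ExpressionDataset(gene_ids=["i", "j"], values=vals)
        a, b = 3, 6
        design = build_phase_design(data, "i", ["j"], (a, b))
        r = 0
        for t in range(a, b):
            for l in range(m):
                assert design.y[r] == vals[0, t - 1, l]
                assert design.D[r, 1] == vals[1, t - 2, l]
                r += 1


class TestLogMarginalPhase:
    def test_matches_quadrature_oracle(self, hyper, rng):
        instances = []
        for _ in range(11):
            s = int(rng.integers(0, 3))
            N = int(rng.integers(s + 2, 7))
            delta2 = float(rng.uniform(0.2, 8.0))
            D = np.column_stack([np.ones(N)]
                                + [rng.normal(size=N) for _ in range(s)])
            y = rng.normal(size=N)
            instances.append((D, y, delta2))
        for D, y, delta2 in instances:
            closed = log_marginal_phase(PhaseDesign(D, y), hyper, delta2=delta2)
            oracle = log_marginal_quadrature(D, y, delta2=delta2, n_theta=32)
            assert closed == pytest.approx(oracle, rel=1e-5)

    def test_spec_intercept_example(self, hyper):
        D = np.array([[1.0], [1.0]])
        y = np.array([0.3, -0.1])
        closed = log_marginal_phase(PhaseDesign(D, y), hyper, delta2=10.0)
        oracle = log_marginal_quadrature(D, y, delta2=10.0)
        assert closed == pytest.approx(oracle, rel=1e-6)

    def test_row_permutation_invariance(self, hyper, rng):
        D = np.column_stack([np.ones(5), rng.normal(size=5)])
        y = rng.normal(size=5)
        perm = rng.permutation(5)
        a = log_marginal_phase(PhaseDesign(D, y), hyper)
        b = log_marginal_phase(PhaseDesign(D[perm], y[perm]), hyper)
        assert a == pytest.approx(b, rel=1e-12)

    def test_exact_fit_beats_equal_norm_misfit(self, hyper, rng):
        """Zero-residual response scores above any same-norm response with a
        larger residual sum of squares (same design)."""
        for _ in range(3):
            D = np.column_stack([np.ones(6), rng.normal(size=6)])
            theta = rng.normal(size=2)
            y_exact = D @ theta
            # rotate part of y out of the column span, keeping ||y|| fixed
            resid_dir = rng.normal(size=6)
            resid_dir -= D @ np.linalg.lstsq(D, resid_dir, rcond=None)[0]
            resid_dir /= np.linalg.norm(resid_dir)
            for frac in (0.3, 0.9):
                y_bad = (math.sqrt(1 - frac ** 2) * y_exact
                         + frac * np.linalg.norm(y_exact) * resid_dir)
                assert np.linalg.norm(y_bad) == pytest.approx(
                    np.linalg.norm(y_exact))
                assert (log_marginal_phase(PhaseDesign(D, y_exact), hyper)
                        > log_marginal_phase(PhaseDesign(D, y_bad), hyper))

    def test_singular_gram_warns_not_crashes(self, hyper, rng):
        col = rng.normal(size=4)
        D = np.column_stack([np.ones(4), col, col])     # duplicated parent
        y = rng.normal(size=4)
        with pytest.warns(RuntimeWarning, match="ridge"):
            val = log_marginal_phase(PhaseDesign(D, y), hyper)
        assert np.isfinite(val)


class TestGeneLogPosteriorScore:
    def _manual_score(self, data, target, interior, parents, hyper, candidates):
        """Independent reassembly with scipy priors + the oracle-pinned marginal."""
        n = data.n
        k = len(interior)
        kmax = hyper.effective_k_max(n)
        smax = min(hyper.s_max, len(candidates))
        score = math.log(poisson.pmf(k, hyper.lambda_cp)
                         / poisson.cdf(kmax, hyper.lambda_cp))
        score -= math.log(math.comb(n - 2, k))
        bounds = (2, *interior, n + 1)
        for h in range(k + 1):
            pa = parents[h]
            score += math.log(poisson.pmf(len(pa), hyper.Lambda_par)
                              / poisson.cdf(smax, hyper.Lambda_par))
            score -= math.log(math.comb(len(candidates), len(pa)))
            genes = [candidates[j] for j in pa]
            design = build_phase_design(data, target, genes,
                                        (bounds[h], bounds[h + 1]))
            score += log_marginal_phase(design, hyper)
        return score

    def test_matches_independent_assembly(self, toy_dataset, hyper):
        candidates = ["c0", "c1"]
        hyper = Hyperparameters(s_max=2)
        for interior, parents in [
            ((), [(0,)]),
            ((4,), [(), (0, 1)]),
            ((3, 5), [(1,), (0,), ()]),
        ]:
            cfg = ChangepointConfiguration.from_interior(interior, toy_dataset.n)
            got = gene_log_posterior_score(toy_dataset, "target", cfg,
                                           [frozenset(p) for p in parents],
                                           hyper, candidates)
            want = self._manual_score(toy_dataset, "target", interior,
                                      parents, hyper, candidates)
            assert got == pytest.approx(want, rel=1e-10)

    def test_additive_over_phases(self, toy_dataset, hyper):
        """Changing one phase's parent set changes only that phase's term."""
        cfg = ChangepointConfiguration.from_interior((4,), toy_dataset.n)
        cands = ["c0", "c1"]
        s_a = gene_log_posterior_score(toy_dataset, "target", cfg,
                                       [frozenset(), frozenset({0})], hyper, cands)
        s_b = gene_log_posterior_score(toy_dataset, "target", cfg,
                                       [frozenset(), frozenset({1})], hyper, cands)
        s_c = gene_log_posterior_score(toy_dataset, "target", cfg,
                                       [frozenset({0}), frozenset({0})], hyper, cands)
        s_d = gene_log_posterior_score(toy_dataset, "target", cfg,
                                       [frozenset({0}), frozenset({1})], hyper, cands)
        assert s_a - s_b == pytest.approx(s_c - s_d, rel=1e-9)

    def test_invariant_to_candidate_relabeling(self, toy_dataset, hyper):
        cfg = ChangepointConfiguration.from_interior((4,), toy_dataset.n)
        orig = gene_log_posterior_score(toy_dataset, "target", cfg,
                                        [frozenset({0}), frozenset({1})],
                                        hyper, ["c0", "c1"])
        flipped = gene_log_posterior_score(toy_dataset, "target", cfg,
                                           [frozenset({1}), frozenset({0})],
                                           hyper, ["c1", "c0"])
        assert orig == pytest.approx(flipped, rel=1e-12)

    def test_factorizes_over_targets(self, toy_dataset, hyper):
        """Scores for one gene ignore edits to other targets' expression."""
        cfg = ChangepointConfiguration.from_interior((4,), toy_dataset.n)
        before = gene_log_posterior_score(toy_dataset, "c1", cfg,
                                          [frozenset({0}), frozenset()],
                                          hyper, ["c0"])
        edited = ExpressionDataset(gene_ids=list(toy_dataset.gene_ids),
                                   values=toy_dataset.values.copy())
        edited.values[0] += 5.0                 # another target gene
        after = gene_log_posterior_score(edited, "c1", cfg,
                                         [frozenset({0}), frozenset()],
                                         hyper, ["c0"])
        assert before == after
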