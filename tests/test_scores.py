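"""Penalized membership scores and the full log-posterior objective."""

import math

import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import norm

from probic.matrix import ExpressionMatrix
from probic.model import (
    Assignment,
    BackgroundModel,
    BiclusterParams,
    PriorSpec,
    array_log_score,
    gene_log_score,
    log_posterior,
    map_update_params,
)


def neutral_prior(n_arrays, n_genes=None, **kw):
    base = dict(
        mu0=np.zeros(n_arrays),
        kappa0=1.0,
        nu0=1.0,
        sigma0=np.ones(n_arrays),
        f_bcl=1.0,
        log_penalty=0.0,
        p_gene=0.5,
        sigma_floor=1e-9,
    )
    base.update(kw)
    return PriorSpec(**base)


def flat_background(n_arrays, mu=0.0, sigma=1.0):
    return BackgroundModel(
        np.full(n_arrays, mu), np.full(n_arrays, sigma), sigma_floor=1e-9
    )


def manual_params(mu_rows, sigma_rows):
    mu = np.asarray(mu_rows, float).reshape(-1, 1)
    sigma = np.asarray(sigma_rows, float).reshape(-1, 1)
    return BiclusterParams(mu=mu, sigma=sigma, n_present=np.ones_like(mu, dtype=int))


class TestGeneLogScore:
    def test_worked_log_ratio(self):
        # one member array, x = 2.0, bicluster N(2.0, 0.5), background N(0, 1),
        # no penalty, neutral membership prior: score = -log(0.5) + 2
        values = np.array([[2.0, 0.0], [0.0, 0.0]])
        m = ExpressionMatrix(["g0", "g1"], ["a0", "a1"], values)
        assignment = Assignment(
            np.array([[True], [False]]), np.array([[True], [False]])
        )
        score = gene_log_score(
            "g0", 0, m, manual_params([2.0, 0.0], [0.5, 1.0]), assignment,
            flat_background(2), neutral_prior(2),
        )
        assert score == pytest.approx(-math.log(0.5) + 2.0, abs=1e-12)

    def test_zero_when_bicluster_equals_background(self):
        rng = np.random.default_rng(0)
        m = ExpressionMatrix(
            ["g0", "g1", "g2"], ["a0", "a1"], rng.normal(size=(3, 2))
        )
        assignment = Assignment(
            np.array([[True], [True], [False]]), np.array([[True], [True]])
        )
        score = gene_log_score(
            "g2", 0, m, manual_params([0.0, 0.0], [1.0, 1.0]), assignment,
            flat_background(2), neutral_prior(2),
        )
        assert score == pytest.approx(0.0, abs=1e-12)

    def test_background_favoured_array_decreases_score(self):
        # x is at the background mode and 3 sigma from the bicluster mean
        values = np.array([[2.0, 0.0], [0.0, 0.0]])
        m = ExpressionMatrix(["g0", "g1"], ["a0", "a1"], values)
        params = manual_params([2.0, 3.0], [0.5, 1.0])
        one = Assignment(np.array([[True], [False]]), np.array([[True], [False]]))
        both = Assignment(np.array([[True], [False]]), np.array([[True], [True]]))
        args = (m, params, one, flat_background(2), neutral_prior(2))
        s_one = gene_log_score("g0", 0, *args)
        s_both = gene_log_score(
            "g0", 0, m, params, both, flat_background(2), neutral_prior(2)
        )
        assert s_both < s_one

    def test_empty_array_set_reduces_to_prior_terms(self):
        values = np.zeros((2, 2))
        values[0, 0] = 1.0
        m = ExpressionMatrix(["g0", "g1"], ["a0", "a1"], values)
        assignment = Assignment(
            np.array([[True], [False]]), np.array([[False], [False]])
        )
        prior = neutral_prior(2, p_gene=0.2)
        score = gene_log_score(
            "g0", 0, m, manual_params([0, 0], [1, 1]), assignment,
            flat_background(2), prior,
        )
        assert score == pytest.approx(math.log(0.2 / 0.8), abs=1e-12)

    def test_penalty_and_bias_terms(self):
        values = np.array([[2.0, 2.0], [0.0, 0.0]])
        m = ExpressionMatrix(["g0", "g1"], ["a0", "a1"], values)
        assignment = Assignment(
            np.array([[True], [False]]), np.array([[True], [True]])
        )
        bias = np.array([0.7, 0.0])
        base = gene_log_score(
            "g0", 0, m, manual_params([2, 2], [0.5, 0.5]), assignment,
            flat_background(2), neutral_prior(2),
        )
        shifted = gene_log_score(
            "g0", 0, m, manual_params([2, 2], [0.5, 0.5]), assignment,
            flat_background(2),
            neutral_prior(2, log_penalty=math.log(2.0), gene_bias=bias),
        )
        # two member arrays pay 2 log 2; the bias adds back 0.7
        assert shifted == pytest.approx(base - 2 * math.log(2.0) + 0.7, abs=1e-12)


class TestArrayLogScore:
    def test_displaced_tight_genes_score_positive(self):
        rng = np.random.default_rng(1)
        values = rng.normal(0.0, 1.0, size=(12, 3))
        values[:8, 0] = rng.normal(3.0, 0.2, size=8)  # 3 background sigmas away
        m = ExpressionMatrix(
            [f"g{i}" for i in range(12)], ["a0", "a1", "a2"], values
        )
        gm = np.zeros((12, 1), bool)
        gm[:8] = True
        assignment = Assignment(gm, np.ones((3, 1), bool))
        prior = neutral_prior(
            3, mu0=np.array([3.0, 0.0, 0.0]), log_penalty=math.log(2.0),
            sigma0=np.full(3, 0.5),
        )
        score = array_log_score("a0", 0, m, assignment, flat_background(3), prior)
        assert score > 0

    def test_background_matching_values_bounded_by_penalty_terms(self):
        # member values at the background mean, query profile on the
        # background mean, near-rigid prior: the fit reduces to the
        # background and the log-ratio terms vanish
        values = np.zeros((6, 2))
        values[:, 1] = np.linspace(-1, 1, 6)
        m = ExpressionMatrix([f"g{i}" for i in range(6)], ["a0", "a1"], values)
        assignment = Assignment(np.ones((6, 1), bool), np.ones((2, 1), bool))
        pen = math.log(2.0)
        prior = neutral_prior(2, nu0=1e9, kappa0=1e9, log_penalty=pen)
        score = array_log_score("a0", 0, m, assignment, flat_background(2), prior)
        assert score <= 6 * pen + prior.array_bias[0]
        assert score == pytest.approx(-6 * pen, abs=1e-3)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(8, 2))
        perm = rng.permutation(8)
        members = {f"g{i}" for i in range(5)}
        prior = neutral_prior(2)
        scores = []
        for ids, vals in (
            ([f"g{i}" for i in range(8)], values),
            ([f"g{i}" for i in perm], values[perm]),
        ):
            m = ExpressionMatrix(ids, ["a0", "a1"], vals)
            gm = np.array([[g in members] for g in m.gene_ids])
            scores.append(
                array_log_score(
                    "a0", 0, m, Assignment(gm, np.ones((2, 1), bool)),
                    flat_background(2), prior,
                )
            )
        assert scores[0] == pytest.approx(scores[1], abs=1e-12)

    def test_no_member_genes_is_an_error(self):
        m = ExpressionMatrix(["g0", "g1"], ["a0", "a1"], np.zeros((2, 2)))
        assignment = Assignment(np.zeros((2, 1), bool), np.ones((2, 1), bool))
        with pytest.raises(ValueError, match="no member genes"):
            array_log_score("a0", 0, m, assignment, flat_background(2),
                            neutral_prior(2))


def naive_log_posterior(matrix, assignment, params, background, prior):
    """Independent cell-by-cell re-summation of the objective."""

    def log_normal(x, mu, sigma):
        return float(norm.logpdf(x, loc=mu, scale=sigma))

    def log_nix(mu, s2, mu0, kappa0, nu0, s0sq):
        half = nu0 / 2.0
        inv_chi2 = (
            half * math.log(half * s0sq)
            - float(gammaln(half))
            - (half + 1.0) * math.log(s2)
            - half * s0sq / s2
        )
        return inv_chi2 + log_normal(mu, mu0, math.sqrt(s2 / kappa0))

    G, A = matrix.values.shape
    B = assignment.n_biclusters
    total = 0.0
    for i in range(G):
        for j in range(A):
            if not matrix.mask[i, j]:
                continue
            owners = [
                b
                for b in range(B)
                if assignment.gene_membership[i, b]
                and assignment.array_membership[j, b]
            ]
            if owners:
                dens = max(
                    log_normal(
                        matrix.values[i, j], params.mu[j, b], params.sigma[j, b]
                    )
                    for b in owners
                )
                total += dens - prior.log_penalty
            else:
                total += log_normal(
                    matrix.values[i, j], background.mu_bgr[j], background.sigma_bgr[j]
                )
    mode_s2 = prior.nu0 * prior.sigma0**2 / (prior.nu0 + 3.0)
    mode_sigma = np.maximum(np.sqrt(mode_s2), prior.sigma_floor)
    for b in range(B):
        for i in range(G):
            if assignment.gene_membership[i, b]:
                total += math.log(prior.p_gene) + prior.gene_bias_for(G)[i]
            else:
                total += math.log(1.0 - prior.p_gene)
        for j in range(A):
            if assignment.array_membership[j, b]:
                total += prior.array_bias[j]
                total += log_nix(
                    params.mu[j, b], params.sigma[j, b] ** 2,
                    prior.mu0[j], prior.kappa0, prior.nu0, prior.sigma0[j] ** 2,
                )
            else:
                total += log_nix(
                    prior.mu0[j], mode_sigma[j] ** 2,
                    prior.mu0[j], prior.kappa0, prior.nu0, prior.sigma0[j] ** 2,
                )
    return total


class TestLogPosterior:
    def test_matches_naive_resummation(self, tiny_matrix):
        gm = np.array([[True], [True], [False], [True], [False], [False]])
        am = np.array([[True], [False], [True], [False]])
        assignment = Assignment(gm, am)
        prior = neutral_prior(
            4, log_penalty=math.log(2.0), p_gene=0.1,
            gene_bias=np.linspace(-0.2, 0.3, 6), array_bias=np.linspace(0, 0.1, 4),
        )
        bg = flat_background(4, mu=0.1, sigma=1.2)
        params = map_update_params(tiny_matrix, assignment, prior)
        got = log_posterior(tiny_matrix, assignment, params, bg, prior)
        want = naive_log_posterior(tiny_matrix, assignment, params, bg, prior)
        assert got == pytest.approx(want, abs=1e-9)

    def test_two_overlapping_biclusters_match_naive(self, tiny_matrix):
        gm = np.array(
            [[True, False], [True, True], [False, True],
             [True, False], [False, True], [False, False]]
        )
        am = np.array([[True, True], [False, True], [True, False], [False, True]])
        assignment = Assignment(gm, am)
        prior = neutral_prior(4, log_penalty=0.3, p_gene=0.05)
        bg = flat_background(4)
        params = map_update_params(tiny_matrix, assignment, prior)
        got = log_posterior(tiny_matrix, assignment, params, bg, prior)
        want = naive_log_posterior(tiny_matrix, assignment, params, bg, prior)
        assert got == pytest.approx(want, abs=1e-9)

    def test_empty_assignment_is_background_plus_prior_mode(self, tiny_matrix):
        assignment = Assignment(np.zeros((6, 1), bool), np.zeros((4, 1), bool))
        prior = neutral_prior(4, p_gene=0.5)
        bg = flat_background(4)
        params = map_update_params(tiny_matrix, assignment, prior)
        got = log_posterior(tiny_matrix, assignment, params, bg, prior)
        x = tiny_matrix.values[tiny_matrix.mask]
        bg_ll = float(norm.logpdf(x, 0.0, 1.0).sum())
        want = naive_log_posterior(tiny_matrix, assignment, params, bg, prior)
        assert got == pytest.approx(want, abs=1e-9)
        # background likelihood dominates; membership and theta-prior terms
        # are the constant remainder
        assert got - bg_ll == pytest.approx(want - bg_ll, abs=1e-9)

    def test_outlying_bicluster_cell_decreases_objective(self, tiny_matrix):
        gm = np.array([[True], [True], [False], [False], [False], [False]])
        am = np.array([[True], [True], [False], [False]])
        assignment = Assignment(gm, am)
        prior = neutral_prior(4)
        bg = flat_background(4)
        params = map_update_params(tiny_matrix, assignment, prior)
        base = log_posterior(tiny_matrix, assignment, params, bg, prior)
        moved = ExpressionMatrix(
            tiny_matrix.gene_ids, tiny_matrix.array_ids,
            tiny_matrix.values.copy(), tiny_matrix.mask.copy(),
        )
        moved.values[0, 0] = 40.0  # far from bicluster and background means
        worse = log_posterior(moved, assignment, params, bg, prior)
        assert worse < base
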