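"""Probabilistic model and hard-assignment EM for query-based biclustering.

The generative picture: every expression value x_ga either belongs to a
bicluster b -- in which case it is drawn from a per-array Normal
N(mu_ab, sigma_ab) shared by all member genes of b on array a -- or to the
array's background Normal N(mu_a_bgr, sigma_a_bgr).  Background parameters
are estimated robustly up front and held fixed.  Each bicluster-array Normal
carries a conjugate Normal-Inverse-chi-squared (NIX) prior with
hyperparameters (mu0[a], kappa0, nu0, sigma0[a]^2); the prior mean profile
mu0 is the average expression of the seed (query) genes, which is what makes
the search query-based.  Gene and array memberships are the hidden
variables; learning alternates MAP parameter updates with deterministic
reassignment by penalized log-odds scores (hard EM), so the log-posterior
trace is non-decreasing.

Scoring conventions
-------------------
``log_penalty`` stores log(pi_bicl/pi_bgr) as a *positive threshold*: each
present bicluster cell pays ``-log_penalty`` in the objective, i.e. a cell
must be that many times more likely under the bicluster distribution than
under the background before it pays for itself.  The parameter set theta has
fixed dimension: every (array, bicluster) pair owns a Normal whose NIX prior
is always paid, with non-member arrays held at the prior joint mode.  The EM
engine therefore scores E-step moves against the parameters frozen at the
last M-step, which makes every reassignment an exact ascent step of
:func:`log_posterior` and the trace provably non-decreasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, ndtri
from scipy.stats import norm

from probic.matrix import ExpressionMatrix

_LOG_2PI = math.log(2.0 * math.pi)


class DegenerateArrayError(ValueError):
    """An array has too few usable values for background estimation."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class BackgroundModel:
    """Per-array background Normal parameters (mu_a_bgr, sigma_a_bgr)."""

    mu_bgr: np.ndarray
    sigma_bgr: np.ndarray
    sigma_floor: float

    def __post_init__(self) -> None:
        self.mu_bgr = np.asarray(self.mu_bgr, dtype=float)
        self.sigma_bgr = np.asarray(self.sigma_bgr, dtype=float)
        if self.mu_bgr.shape != self.sigma_bgr.shape:
            raise ValueError("mu_bgr and sigma_bgr must have equal length")
        if self.sigma_floor <= 0:
            raise ValueError("sigma_floor must be positive")
        if np.any(self.sigma_bgr < self.sigma_floor):
            raise ValueError("sigma_bgr below sigma_floor")


@dataclass
class PriorSpec:
    """Hyperparameters of the bicluster model.

    mu0[a] is the query mean profile; sigma0[a] = f_bcl * sigma_a_bgr is the
    prior bicluster spread; kappa0 weights the prior mean against the data
    (large kappa0 anchors the bicluster on the query profile); nu0 weights
    the prior variance.  log_penalty is the per-cell complexity threshold,
    p_gene the Bernoulli prior that a gene belongs to a bicluster, and
    gene_bias / array_bias optional per-object log-prior offsets for
    specific membership knowledge.
    """

    mu0: np.ndarray
    kappa0: float
    nu0: float
    sigma0: np.ndarray
    f_bcl: float
    log_penalty: float
    p_gene: float
    gene_bias: np.ndarray | None = None
    array_bias: np.ndarray | None = None
    sigma_floor: float = 1e-9

    def __post_init__(self) -> None:
        self.mu0 = np.asarray(self.mu0, dtype=float)
        self.sigma0 = np.asarray(self.sigma0, dtype=float)
        if self.kappa0 <= 0 or self.nu0 <= 0:
            raise ValueError("kappa0 and nu0 must be positive")
        if not 0.0 < self.p_gene < 1.0:
            raise ValueError("p_gene must lie in the open interval (0, 1)")
        if not 0.0 < self.f_bcl <= 1.0:
            raise ValueError("f_bcl must lie in (0, 1]")
        if np.any(self.sigma0 <= 0):
            raise ValueError("sigma0 must be strictly positive for every array")
        if self.array_bias is None:
            self.array_bias = np.zeros_like(self.mu0)
        else:
            self.array_bias = np.asarray(self.array_bias, dtype=float)

    def gene_bias_for(self, n_genes: int) -> np.ndarray:
        if self.gene_bias is None:
            return np.zeros(n_genes)
        return np.asarray(self.gene_bias, dtype=float)


@dataclass
class Assignment:
    """Boolean gene- and array-to-bicluster memberships (hidden variables)."""

    gene_membership: np.ndarray
    array_membership: np.ndarray

    def __post_init__(self) -> None:
        self.gene_membership = np.atleast_2d(np.asarray(self.gene_membership, bool))
        self.array_membership = np.atleast_2d(np.asarray(self.array_membership, bool))
        if self.gene_membership.shape[1] != self.array_membership.shape[1]:
            raise ValueError("gene and array membership disagree on bicluster count")

    @property
    def n_biclusters(self) -> int:
        return self.gene_membership.shape[1]

    def copy(self) -> "Assignment":
        return Assignment(self.gene_membership.copy(), self.array_membership.copy())


@dataclass
class BiclusterParams:
    """Per-(array, bicluster) Normal parameters, the theta of the model.

    Columns hold the candidate MAP fit for *every* array (the fit an array
    would receive were it a member); restriction to member arrays gives the
    parameters that actually generate cells.  ``n_present`` counts the
    member-gene values each fit was computed from.
    """

    mu: np.ndarray  # (n_arrays, n_biclusters)
    sigma: np.ndarray
    n_present: np.ndarray  # (n_arrays, n_biclusters) ints


@dataclass
class BiclusterResult:
    """Outcome of one EM run: memberships, parameters, and diagnostics."""

    genes: list[str]
    arrays: list[str]
    mu: np.ndarray  # per member array, in `arrays` order
    sigma: np.ndarray
    log_posterior_trace: list[float]
    n_iterations: int
    converged: bool

    @property
    def is_empty(self) -> bool:
        return len(self.genes) == 0

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "arrays": list(self.arrays),
            "mu": [float(v) for v in self.mu],
            "sigma": [float(v) for v in self.sigma],
            "log_posterior_trace": [float(v) for v in self.log_posterior_trace],
            "n_iterations": int(self.n_iterations),
            "converged": bool(self.converged),
        }


# ---------------------------------------------------------------------------
# background estimation
# ---------------------------------------------------------------------------


def trim_consistency_factor(trim_fraction: float) -> float:
    """Variance-consistency factor for symmetric two-sided trimming.

    Removing the outer ``trim_fraction`` of each tail of a Normal sample
    leaves a truncated Normal whose standard deviation understates sigma by
    sqrt(1 - 2 z phi(z) / (1 - 2 alpha)) with z the (1 - alpha) quantile.
    Dividing by that factor makes the trimmed estimator consistent for an
    uncontaminated Normal.
    """
    if trim_fraction == 0.0:
        return 1.0
    z = ndtri(1.0 - trim_fraction)
    retained = 1.0 - 2.0 * trim_fraction
    trunc_var = 1.0 - 2.0 * z * norm.pdf(z) / retained
    return 1.0 / math.sqrt(trunc_var)


def estimate_background(
    matrix: ExpressionMatrix,
    trim_fraction: float = 0.1,
    sigma_floor: float | None = None,
) -> BackgroundModel:
    """Robust per-array background Normal via symmetric trimming.

    For each array independently, the lowest and highest ``trim_fraction``
    of present values are discarded; the mean and (consistency-corrected)
    standard deviation of the rest give (mu_a_bgr, sigma_a_bgr).  Trimming
    filters out the most over- and under-expressed genes per condition, so a
    modest fraction of genuinely regulated genes does not inflate the
    background spread.  Parameters are fixed; EM never re-estimates them.
    """
    if not 0.0 <= trim_fraction <= 0.45:
        raise ValueError("trim_fraction must lie in [0, 0.45]")
    factor = trim_consistency_factor(trim_fraction)
    mus = np.empty(matrix.n_arrays)
    sigmas = np.empty(matrix.n_arrays)
    for j in range(matrix.n_arrays):
        col = matrix.values[:, j][matrix.mask[:, j]]
        k = int(math.floor(col.size * trim_fraction))
        kept = np.sort(col)[k : col.size - k] if k else np.sort(col)
        if kept.size < 3:
            raise DegenerateArrayError(
                f"array {matrix.array_ids[j]!r}: only {kept.size} values retained "
                f"after trimming; need at least 3"
            )
        mus[j] = kept.mean()
        sigmas[j] = kept.std(ddof=1) * factor
    if sigma_floor is None:
        med = float(np.median(sigmas))
        sigma_floor = 1e-3 * med if med > 0 else 1e-9
    if sigma_floor <= 0:
        raise ValueError("sigma_floor must be positive")
    return BackgroundModel(
        mu_bgr=mus,
        sigma_bgr=np.maximum(sigmas, sigma_floor),
        sigma_floor=float(sigma_floor),
    )


# ---------------------------------------------------------------------------
# prior construction and initialization
# ---------------------------------------------------------------------------


def build_prior(
    matrix: ExpressionMatrix,
    seed_genes: Iterable[str],
    background: BackgroundModel,
    f_bcl: float = 0.5,
    kappa0: float | None = None,
    nu0: float = 10.0,
    log_penalty: float = math.log(2.0),
    p_gene: float = 0.01,
) -> PriorSpec:
    """Derive the NIX prior from the seed genes.

    mu0[a] is the mean of the present seed values on array a (the query
    profile) and sigma0[a] = f_bcl * sigma_a_bgr, i.e. the prior expects a
    bicluster tighter than background by the factor f_bcl.  kappa0 defaults
    to 10x the number of genes in the matrix, keeping the bicluster mean
    anchored on the query profile.
    """
    seeds = list(seed_genes)
    if not seeds:
        raise ValueError("seed set is empty")
    idx = matrix.gene_index(seeds)
    vals = matrix.values[idx]
    present = matrix.mask[idx]
    counts = present.sum(axis=0)
    if np.any(counts == 0):
        bad = [str(a) for a in matrix.array_ids[counts == 0]]
        raise ValueError(f"all seed values missing on array(s): {bad}")
    mu0 = np.where(present, vals, 0.0).sum(axis=0) / counts
    if kappa0 is None:
        kappa0 = 10.0 * matrix.n_genes
    return PriorSpec(
        mu0=mu0,
        kappa0=float(kappa0),
        nu0=float(nu0),
        sigma0=f_bcl * background.sigma_bgr,
        f_bcl=float(f_bcl),
        log_penalty=float(log_penalty),
        p_gene=float(p_gene),
        sigma_floor=background.sigma_floor,
    )


def init_assignments(
    matrix: ExpressionMatrix, seed_genes: Iterable[str]
) -> Assignment:
    """Seed initialization of the hidden variables for one bicluster.

    Seed genes start as the only members; every array starts as a member so
    the first M-step fits all arrays to the seed profile and the first
    E-step prunes arrays by their penalized score.  Deterministic.
    """
    seeds = list(seed_genes)
    if not seeds:
        raise ValueError("seed set is empty")
    idx = matrix.gene_index(seeds)
    genes = np.zeros((matrix.n_genes, 1), dtype=bool)
    genes[idx, 0] = True
    arrays = np.ones((matrix.n_arrays, 1), dtype=bool)
    return Assignment(genes, arrays)


# ---------------------------------------------------------------------------
# conjugate MAP update
# ---------------------------------------------------------------------------


def _norm_logpdf(x: np.ndarray, mu, sigma) -> np.ndarray:
    z = (x - mu) / sigma
    return -0.5 * _LOG_2PI - np.log(sigma) - 0.5 * z * z


def _nix_logpdf(mu, sigma2, mu0, kappa0: float, nu0: float, sigma0sq):
    """Log density of the Normal-Inverse-chi^2 prior at (mu, sigma^2)."""
    half_nu = 0.5 * nu0
    inv_chi2 = (
        half_nu * np.log(half_nu * sigma0sq)
        - gammaln(half_nu)
        - (half_nu + 1.0) * np.log(sigma2)
        - half_nu * sigma0sq / sigma2
    )
    normal = (
        -0.5 * _LOG_2PI
        - 0.5 * np.log(sigma2 / kappa0)
        - 0.5 * kappa0 * (mu - mu0) ** 2 / sigma2
    )
    return inv_chi2 + normal


def _prior_mode_sigma(prior: PriorSpec) -> np.ndarray:
    """Joint-mode sigma of the NIX prior, floor-clamped (per array)."""
    mode_var = prior.nu0 * prior.sigma0**2 / (prior.nu0 + 3.0)
    return np.maximum(np.sqrt(mode_var), prior.sigma_floor)


def _fit_arrays(
    matrix: ExpressionMatrix, gene_members: np.ndarray, prior: PriorSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Candidate MAP fit (mu, sigma, n_present) for every array at once.

    Standard conjugate update: kappa_n = kappa0 + n, mu_n = (kappa0 mu0 +
    n xbar)/kappa_n, nu_n = nu0 + n, nu_n sigma_n^2 = nu0 sigma0^2 + S +
    (kappa0 n / kappa_n)(xbar - mu0)^2; the returned values are the joint
    mode of the posterior NIX, sigma^2 = nu_n sigma_n^2 / (nu_n + 3).
    Arrays with no present member value fall back to (mu0, sigma0).
    """
    vals = matrix.values[gene_members]
    present = matrix.mask[gene_members]
    n = present.sum(axis=0).astype(float)
    safe = np.where(present, vals, 0.0)
    total = safe.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        xbar = np.where(n > 0, total / np.maximum(n, 1.0), 0.0)
        sq = np.where(present, (safe - xbar) ** 2, 0.0).sum(axis=0)
    kappa_n = prior.kappa0 + n
    mu_n = (prior.kappa0 * prior.mu0 + n * xbar) / kappa_n
    nu_n = prior.nu0 + n
    nssq = (
        prior.nu0 * prior.sigma0**2
        + sq
        + (prior.kappa0 * n / kappa_n) * (xbar - prior.mu0) ** 2
    )
    sigma = np.maximum(np.sqrt(nssq / (nu_n + 3.0)), prior.sigma_floor)
    empty = n == 0
    mu_n = np.where(empty, prior.mu0, mu_n)
    sigma = np.where(empty, prior.sigma0, sigma)
    return mu_n, sigma, present.sum(axis=0)


def map_update_params(
    matrix: ExpressionMatrix,
    assignment: Assignment,
    prior: PriorSpec | Sequence[PriorSpec],
) -> BiclusterParams:
    """Maximization step: MAP Normal parameters for every (array, bicluster).

    Member genes with present values on an array determine its posterior
    NIX; the joint posterior mode is returned, sigma clamped at
    ``prior.sigma_floor``.  With no data the prior values (mu0, sigma0)
    come back unchanged.  Fits are produced for all arrays (the member
    restriction is taken by the caller) because the E-step needs candidate
    fits for non-member arrays too.
    """
    B = assignment.n_biclusters
    priors = _as_prior_list(prior, B)
    mu = np.empty((matrix.n_arrays, B))
    sigma = np.empty((matrix.n_arrays, B))
    n_present = np.empty((matrix.n_arrays, B), dtype=int)
    for b in range(B):
        mu[:, b], sigma[:, b], n_present[:, b] = _fit_arrays(
            matrix, assignment.gene_membership[:, b], priors[b]
        )
    return BiclusterParams(mu=mu, sigma=sigma, n_present=n_present)


# ---------------------------------------------------------------------------
# penalized assignment scores
# ---------------------------------------------------------------------------


def _gene_scores_vec(
    matrix: ExpressionMatrix,
    array_members: np.ndarray,
    mu_b: np.ndarray,
    sigma_b: np.ndarray,
    background: BackgroundModel,
    prior: PriorSpec,
) -> np.ndarray:
    """Penalized log-odds of membership for every gene simultaneously."""
    base = math.log(prior.p_gene / (1.0 - prior.p_gene)) + prior.gene_bias_for(
        matrix.n_genes
    )
    cols = np.flatnonzero(array_members)
    if cols.size == 0:
        return base.copy() if isinstance(base, np.ndarray) else base
    x = np.where(matrix.mask[:, cols], matrix.values[:, cols], 0.0)
    lr = _norm_logpdf(x, mu_b[cols], sigma_b[cols]) - _norm_logpdf(
        x, background.mu_bgr[cols], background.sigma_bgr[cols]
    )
    lr = np.where(matrix.mask[:, cols], lr, 0.0)
    n_present = matrix.mask[:, cols].sum(axis=1)
    return lr.sum(axis=1) - n_present * prior.log_penalty + base


def gene_log_score(
    gene: str,
    bicluster: int,
    matrix: ExpressionMatrix,
    params: BiclusterParams,
    assignment: Assignment,
    background: BackgroundModel,
    prior: PriorSpec,
) -> float:
    """Score deciding gene membership: positive means assign.

    Sum over the bicluster's member arrays (present values only) of the
    bicluster-vs-background log-density ratio, minus the complexity
    threshold per present cell, plus the Bernoulli membership log-odds
    log(p_gene/(1-p_gene)) and any per-gene bias.  Over an empty array set
    only the prior terms remain.
    """
    g = matrix.gene_index([gene])[0]
    scores = _gene_scores_vec(
        matrix,
        assignment.array_membership[:, bicluster],
        params.mu[:, bicluster],
        params.sigma[:, bicluster],
        background,
        prior,
    )
    return float(np.atleast_1d(scores)[g])


def _array_scores_vec(
    matrix: ExpressionMatrix,
    gene_members: np.ndarray,
    background: BackgroundModel,
    prior: PriorSpec,
    theta_mu: np.ndarray | None = None,
    theta_sigma: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scores for every array given the current member genes.

    The log-density ratio summed over member genes (present values only),
    minus the per-cell threshold, plus the array bias.  By default each
    array is evaluated with its candidate MAP fit; the EM engine instead
    passes the parameters frozen at the last M-step (``theta_mu`` /
    ``theta_sigma``), which hold non-member arrays at the prior mode.
    Arrays whose member-gene values are all missing score -inf (never
    members).  Returns (scores, candidate mu, candidate sigma).
    """
    mu_n, sigma_n, n_present = _fit_arrays(matrix, gene_members, prior)
    mu_eval = mu_n if theta_mu is None else theta_mu
    sigma_eval = sigma_n if theta_sigma is None else theta_sigma
    x = np.where(
        matrix.mask[gene_members], matrix.values[gene_members], 0.0
    )
    lr = _norm_logpdf(x, mu_eval, sigma_eval) - _norm_logpdf(
        x, background.mu_bgr, background.sigma_bgr
    )
    lr = np.where(matrix.mask[gene_members], lr, 0.0)
    scores = lr.sum(axis=0) - n_present * prior.log_penalty + prior.array_bias
    scores = np.where(n_present == 0, -np.inf, scores)
    return scores, mu_n, sigma_n


def array_log_score(
    array: str,
    bicluster: int,
    matrix: ExpressionMatrix,
    assignment: Assignment,
    background: BackgroundModel,
    prior: PriorSpec,
) -> float:
    """Score deciding array membership: positive means assign.

    Evaluates this array with the candidate MAP fit of
    :func:`map_update_params` under the bicluster's current member genes.
    Undefined (raises) when the bicluster has no member genes.
    """
    gene_members = assignment.gene_membership[:, bicluster]
    if not gene_members.any():
        raise ValueError("array score undefined for a bicluster with no member genes")
    a = matrix.array_index([array])[0]
    scores, _, _ = _array_scores_vec(matrix, gene_members, background, prior)
    return float(scores[a])


# ---------------------------------------------------------------------------
# full objective
# ---------------------------------------------------------------------------


def _as_prior_list(
    prior: PriorSpec | Sequence[PriorSpec], n_biclusters: int
) -> list[PriorSpec]:
    if isinstance(prior, PriorSpec):
        return [prior] * n_biclusters
    priors = list(prior)
    if len(priors) != n_biclusters:
        raise ValueError("need one prior per bicluster")
    return priors


def log_posterior(
    matrix: ExpressionMatrix,
    assignment: Assignment,
    params: BiclusterParams,
    background: BackgroundModel,
    prior: PriorSpec | Sequence[PriorSpec],
) -> float:
    """The full log-posterior the EM ascends.

    Sum over present cells of the log-density under the owning distribution
    (background, or the maximum-density owning bicluster for covered cells,
    each covered cell paying -log_penalty), plus the Bernoulli gene
    membership prior and array bias terms, plus the NIX prior density of
    theta.  The theta prior runs over all (array, bicluster) pairs with
    non-member arrays held at the prior joint mode, so membership moves are
    comparable under one objective of fixed dimension.
    """
    B = assignment.n_biclusters
    priors = _as_prior_list(prior, B)
    mask = matrix.mask
    x = np.where(mask, matrix.values, 0.0)
    cell = _norm_logpdf(x, background.mu_bgr, background.sigma_bgr)
    best = np.full(matrix.values.shape, -np.inf)
    covered = np.zeros(matrix.values.shape, dtype=bool)
    penalty = np.zeros(matrix.values.shape)
    for b in range(B):
        gm = assignment.gene_membership[:, b]
        am = assignment.array_membership[:, b]
        if not gm.any() or not am.any():
            continue
        block = np.outer(gm, am)
        dens = _norm_logpdf(x, params.mu[:, b], params.sigma[:, b])
        improved = block & (dens > best)
        best = np.where(improved, dens, best)
        penalty = np.where(improved, priors[b].log_penalty, penalty)
        covered |= block
    cell = np.where(covered, best - penalty, cell)
    total = float(np.where(mask, cell, 0.0).sum())

    for b in range(B):
        pb = priors[b]
        gm = assignment.gene_membership[:, b]
        am = assignment.array_membership[:, b]
        gene_bias = pb.gene_bias_for(matrix.n_genes)
        log_p = math.log(pb.p_gene)
        log_q = math.log(1.0 - pb.p_gene)
        total += float(np.where(gm, log_p + gene_bias, log_q).sum())
        total += float(pb.array_bias[am].sum())
        mode_sigma = _prior_mode_sigma(pb)
        mode_lp = _nix_logpdf(
            pb.mu0, mode_sigma**2, pb.mu0, pb.kappa0, pb.nu0, pb.sigma0**2
        )
        theta_lp = _nix_logpdf(
            params.mu[:, b],
            params.sigma[:, b] ** 2,
            pb.mu0,
            pb.kappa0,
            pb.nu0,
            pb.sigma0**2,
        )
        total += float(np.where(am, theta_lp, mode_lp).sum())
    return total


# ---------------------------------------------------------------------------
# hard-assignment EM
# ---------------------------------------------------------------------------


def run_em(
    matrix: ExpressionMatrix,
    seed_genes: Iterable[str],
    background: BackgroundModel,
    prior: PriorSpec,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> BiclusterResult:
    """Learn one bicluster from a seed set by hard-assignment EM.

    Alternates MAP parameter updates (M) with full sweeps of array then gene
    reassignment by penalized score (E), starting from the seed
    initialization, until assignments stabilize, the log-posterior change
    drops below ``tol``, or ``max_iter`` is reached.  Seed genes are free to
    be dropped -- this is what makes the method robust to noisy seeds.  A
    bicluster that loses all genes comes back as an empty, converged result.
    """
    return run_em_multi(matrix, [seed_genes], background, prior, max_iter, tol)[0]


def run_em_multi(
    matrix: ExpressionMatrix,
    seed_sets: Sequence[Iterable[str]],
    background: BackgroundModel,
    prior: PriorSpec | Sequence[PriorSpec],
    max_iter: int = 100,
    tol: float = 1e-6,
) -> list[BiclusterResult]:
    """Joint hard EM over one or more biclusters, one seed set each.

    ``prior`` may be one PriorSpec shared by all biclusters or one per seed
    set.  Biclusters share the matrix and background but are scored
    independently; overlapping cells are owned by the maximum-density
    bicluster inside :func:`log_posterior`.  The default experimental usage
    is a single seed set per run.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    B = len(seed_sets)
    if B == 0:
        raise ValueError("need at least one seed set")
    priors = _as_prior_list(prior, B)
    inits = [init_assignments(matrix, s) for s in seed_sets]
    assignment = Assignment(
        np.hstack([a.gene_membership for a in inits]),
        np.hstack([a.array_membership for a in inits]),
    )
    alive = np.ones(B, dtype=bool)  # biclusters that have not emptied out
    trace: list[float] = []
    converged = False
    n_iter = 0
    params = map_update_params(matrix, assignment, priors)
    for n_iter in range(1, max_iter + 1):
        trace.append(log_posterior(matrix, assignment, params, background, priors))
        new = assignment.copy()
        for b in range(B):
            if not alive[b]:
                new.gene_membership[:, b] = False
                new.array_membership[:, b] = False
                continue
            pb = priors[b]
            gm = assignment.gene_membership[:, b]
            am = assignment.array_membership[:, b]
            # theta frozen at the last M-step: fits for member arrays,
            # prior joint mode elsewhere
            theta_mu = np.where(am, params.mu[:, b], pb.mu0)
            theta_sigma = np.where(am, params.sigma[:, b], _prior_mode_sigma(pb))
            scores, _, _ = _array_scores_vec(
                matrix, gm, background, pb, theta_mu, theta_sigma
            )
            am_new = scores > 0.0
            new.array_membership[:, b] = am_new
            gscores = _gene_scores_vec(
                matrix, am_new, theta_mu, theta_sigma, background, pb
            )
            gm_new = np.atleast_1d(gscores) > 0.0
            new.gene_membership[:, b] = gm_new
            if not gm_new.any():
                alive[b] = False
                new.array_membership[:, b] = False
        unchanged = np.array_equal(
            new.gene_membership, assignment.gene_membership
        ) and np.array_equal(new.array_membership, assignment.array_membership)
        assignment = new
        params = map_update_params(matrix, assignment, priors)
        if unchanged:
            converged = True
            break
        final = log_posterior(matrix, assignment, params, background, priors)
        if len(trace) >= 1 and abs(final - trace[-1]) < tol:
            trace.append(final)
            converged = True
            break
    else:
        trace.append(log_posterior(matrix, assignment, params, background, priors))

    results = []
    for b in range(B):
        gm = assignment.gene_membership[:, b]
        am = assignment.array_membership[:, b]
        results.append(
            BiclusterResult(
                genes=[str(g) for g in matrix.gene_ids[gm]],
                arrays=[str(a) for a in matrix.array_ids[am]],
                mu=params.mu[am, b].copy(),
                sigma=params.sigma[am, b].copy(),
                log_posterior_trace=list(trace),
                n_iterations=n_iter,
                converged=converged or not alive[b],
            )
        )
    return results
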