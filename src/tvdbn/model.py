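"""Piecewise-constant autoregressive network model and its marginal likelihood.

A target gene's expression is modelled, within each regulatory phase, as a
lag-1 linear regression on the expression of its parent genes:

    X_i(t) = sum_{j in Pa_h} a_hj * X_j(t-1) + b_h + e(t),   e(t) ~ N(0, sigma_h^2)

for t in the half-open phase [xi_{h-1}, xi_h).  Phases are delimited by an
unknown set of changepoints; the compulsory bounds are xi_0 = 2 (first-order
Markov model) and xi_{k+1} = n + 1.  Interior changepoints live in {3, ..., n}.

Priors: the changepoint count k and each phase's parent count s follow
truncated Poisson distributions (means lambda and Lambda, maxima k_max and
s_max); positions and parent sets are uniform given the counts; the noise
variance is inverse-Gamma; regression coefficients carry a Zellner g-prior
N(0, sigma^2 delta^2 (D'D)^{-1}) whose scale delta^2 is the expected
signal-to-noise ratio.  With these conjugate choices the regression
coefficients and noise variance integrate out analytically, leaving a
multivariate-t-type phase marginal with shrinkage factor delta^2/(1+delta^2);
the sampler only ever scores the discrete structure (k, xi, parent sets).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "ExpressionDataset",
    "ChangepointConfiguration",
    "PhaseModel",
    "Hyperparameters",
    "PhaseDesign",
    "truncated_poisson_pmf",
    "truncated_poisson_log_pmf",
    "truncated_poisson_log_pmf_vector",
    "changepoint_position_log_prior",
    "parent_set_log_prior",
    "build_phase_design",
    "log_marginal_phase",
    "log_marginal_from_stats",
    "gene_log_posterior_score",
    "GeneScorer",
]

RIDGE_SCALE = 1e-8


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """Replicated multi-gene time series.

    Parameters
    ----------
    gene_ids
        One identifier per gene (unique).
    values
        Real array of shape ``(p, n, m)`` — gene x time-point x replicate —
        in log-expression units.
    missing_mask
        Optional boolean array of the same shape; ``True`` marks a missing
        measurement.  Masked cells may hold any float.
    strains
        Optional per-replicate strain labels (knock-out designs fold the
        genetic contexts into the replicate axis); length ``m``.
    """

    gene_ids: list
    values: np.ndarray
    missing_mask: np.ndarray | None = None
    strains: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must have shape (genes, time, replicates)")
        p, n, m = self.values.shape
        if len(self.gene_ids) != p:
            raise ValueError("gene_ids length does not match values")
        if len(set(self.gene_ids)) != p:
            raise ValueError("duplicate gene ids")
        if n < 3:
            raise ValueError("need at least 3 time-points (one lag-1 transition "
                             "inside the compulsory bounds)")
        if m < 1:
            raise ValueError("need at least one replicate")
        if self.missing_mask is None:
            self.missing_mask = np.zeros_like(self.values, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise ValueError("missing_mask shape mismatch")
        if not np.all(np.isfinite(self.values[~self.missing_mask])):
            raise ValueError("non-finite value outside the missing mask")
        if self.strains is not None and len(self.strains) != m:
            raise ValueError("strains length must equal replicate count")

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def m(self) -> int:
        return self.values.shape[2]

    @property
    def p(self) -> int:
        return self.values.shape[0]

    def gene_index(self, gene) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene id {gene!r}") from None


@dataclass(frozen=True)
class ChangepointConfiguration:
    """Changepoint vector (xi_0, ..., xi_{k+1}) with xi_0 = 2, xi_{k+1} = n+1."""

    xi: tuple

    @classmethod
    def from_interior(cls, positions, n: int) -> "ChangepointConfiguration":
        cfg = cls(xi=(2, *sorted(positions), n + 1))
        cfg.validate(n)
        return cfg

    @property
    def k(self) -> int:
        return len(self.xi) - 2

    @property
    def interior(self) -> tuple:
        return self.xi[1:-1]

    def phases(self):
        """Half-open phase intervals [xi_{h-1}, xi_h)."""
        return [(self.xi[h], self.xi[h + 1]) for h in range(len(self.xi) - 1)]

    def validate(self, n: int) -> None:
        if self.xi[0] != 2 or self.xi[-1] != n + 1:
            raise ValueError(f"compulsory bounds are xi_0=2, xi_k+1={n + 1}; got {self.xi}")
        inner = self.interior
        if any(not (3 <= p <= n) for p in inner):
            raise ValueError(f"interior changepoints must lie in {{3..{n}}}; got {inner}")
        if any(b <= a for a, b in zip(self.xi, self.xi[1:])):
            raise ValueError(f"changepoints must be strictly increasing; got {self.xi}")


@dataclass
class PhaseModel:
    """Parent set and regression parameters for one phase (parameters optional:
    the sampler works with the marginalized model)."""

    parents: frozenset
    coeffs: np.ndarray | None = None
    intercept: float | None = None
    sigma2: float | None = None

    def __post_init__(self):
        self.parents = frozenset(self.parents)
        if self.sigma2 is not None and self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.coeffs is not None:
            self.coeffs = np.asarray(self.coeffs, dtype=float)
            if len(self.coeffs) != len(self.parents):
                raise ValueError("one coefficient per parent")
            if np.any(self.coeffs == 0.0):
                raise ValueError("parents must have non-zero coefficients")

    @property
    def s(self) -> int:
        return len(self.parents)


@dataclass
class Hyperparameters:
    """Prior and sampler constants.

    ``lambda_cp`` / ``Lambda_par`` are the expected changepoint / parent
    counts; both carry a Gamma(alpha, beta) hyperprior (shape/scale) and are
    resampled with the chain, so the values here are initial states only.
    ``delta2`` is the signal-to-noise ratio of the coefficient g-prior with an
    inverse-Gamma(alpha_delta, beta_delta) hyperprior.  ``c`` scales the
    changepoint birth/death proposal probabilities and must stay below 1/4 so
    shifts and regression updates dominate; ``chi``/``zeta``/``rho`` split the
    regression update into edge birth / edge death / edge exchange.
    """

    lambda_cp: float = 0.5
    Lambda_par: float = 0.5
    alpha: float = 1.0
    beta: float = 0.5
    k_max: int | None = None   # defaults to n - 2 at run time
    s_max: int = 5
    upsilon0: float = 1.0
    gamma0: float = 0.1
    delta2: float = 1.0
    alpha_delta: float = 2.0
    beta_delta: float = 0.2
    c: float = 0.2
    chi: float = 0.4
    zeta: float = 0.4
    rho: float = 0.2
    v_frac: float = 0.5

    def validate(self, n: int | None = None, n_candidates: int | None = None) -> None:
        if not self.c < 0.25:
            raise ValueError("move constant c must be smaller than 1/4")
        if abs(self.chi + self.zeta + self.rho - 1.0) > 1e-12:
            raise ValueError("chi + zeta + rho must equal 1")
        for name in ("lambda_cp", "Lambda_par", "alpha", "beta", "upsilon0",
                     "gamma0", "delta2", "alpha_delta", "beta_delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.v_frac <= 1.0:
            raise ValueError("v_frac must lie in [0, 1]")
        if n is not None and self.k_max is not None and self.k_max > n - 2:
            raise ValueError("k_max cannot exceed n - 2")
        if n_candidates is not None and self.s_max > n_candidates:
            raise ValueError("s_max cannot exceed the number of candidate parents")

    def effective_k_max(self, n: int) -> int:
        return n - 2 if self.k_max is None else self.k_max


@dataclass
class PhaseDesign:
    """Design matrix and response for one phase.

    ``D`` has ``m * (phase length)`` rows (minus any rows dropped for missing
    values) and ``s + 1`` columns, the first of which is all ones; row r pairs
    ``y[r]`` = target value at time t with parent values at time t - 1 in the
    same replicate.
    """

    D: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.D = np.atleast_2d(np.asarray(self.D, dtype=float))
        self.y = np.asarray(self.y, dtype=float)
        if self.D.shape[0] != self.y.shape[0]:
            raise ValueError("row count mismatch between D and y")


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

def truncated_poisson_log_pmf_vector(mean: float, kmax: int) -> np.ndarray:
    """Log-pmf of a Poisson(mean) truncated to {0, ..., kmax}."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    if kmax < 0:
        raise ValueError("kmax must be non-negative")
    ks = np.arange(kmax + 1)
    logp = -mean + ks * math.log(mean) - gammaln(ks + 1.0)
    norm = logsumexp_1d(logp)
    return logp - norm


def logsumexp_1d(a: np.ndarray) -> float:
    amax = np.max(a)
    return float(amax + np.log(np.sum(np.exp(a - amax))))


def truncated_poisson_log_pmf(k: int, mean: float, kmax: int) -> float:
    if not float(k).is_integer() or k < 0:
        raise ValueError("k must be a non-negative integer")
    k = int(k)
    if k > kmax:
        return -math.inf
    return float(truncated_poisson_log_pmf_vector(mean, kmax)[k])


def truncated_poisson_pmf(k: int, mean: float, kmax: int) -> float:
    """Pmf of a Poisson(mean) truncated to {0, ..., kmax}; 0 outside."""
    lp = truncated_poisson_log_pmf(k, mean, kmax)
    return 0.0 if lp == -math.inf else math.exp(lp)


def changepoint_position_log_prior(cfg: ChangepointConfiguration, n: int) -> float:
    """Uniform prior over the C(n-2, k) interior changepoint subsets of {3..n}."""
    cfg.validate(n)
    return -math.lgamma(n - 1) + math.lgamma(cfg.k + 1) + math.lgamma(n - 1 - cfg.k)


def parent_set_log_prior(s: int, n_candidates: int) -> float:
    """Uniform prior over the C(q, s) parent sets of size s."""
    if s < 0 or s > n_candidates:
        raise ValueError(f"parent count s={s} outside [0, {n_candidates}]")
    return -(math.lgamma(n_candidates + 1) - math.lgamma(s + 1)
             - math.lgamma(n_candidates - s + 1))


# ---------------------------------------------------------------------------
# Phase design and marginal likelihood
# ---------------------------------------------------------------------------

def build_phase_design(data: ExpressionDataset, target, parents, phase) -> PhaseDesign:
    """Assemble (D, y) for one phase of one target gene.

    ``phase`` is the half-open interval ``(a, b)`` in changepoint coordinates:
    response times t = a..b-1 (1-based), predictors at t-1.  Rows with a
    missing value in any used cell (target at t or a parent at t-1) are
    dropped; the phase must retain at least one row.
    """
    a, b = phase
    n, m = data.n, data.m
    if not (2 <= a < b <= n + 1):
        raise ValueError(f"phase [{a}, {b}) outside the admissible range [2, {n + 1})")
    ti = data.gene_index(target) if not isinstance(target, (int, np.integer)) else int(target)
    pidx = [data.gene_index(g) if not isinstance(g, (int, np.integer)) else int(g)
            for g in parents]

    rows_D, rows_y = [], []
    for t in range(a, b):            # 1-based target time
        for l in range(m):
            if data.missing_mask[ti, t - 1, l]:
                continue
            pred = data.values[pidx, t - 2, l] if pidx else np.empty(0)
            if pidx and np.any(data.missing_mask[pidx, t - 2, l]):
                continue
            rows_D.append(np.concatenate(([1.0], pred)))
            rows_y.append(data.values[ti, t - 1, l])
    if not rows_y:
        raise ValueError(
            f"phase [{a}, {b}) of gene {data.gene_ids[ti]!r} has no usable rows "
            "(all dropped for missing values)")
    return PhaseDesign(D=np.array(rows_D), y=np.array(rows_y))


def _fit_statistic(DtD: np.ndarray, u: np.ndarray) -> float:
    """u' (D'D)^{-1} u with a small ridge fallback for singular Gram matrices."""
    d = DtD.shape[0]
    try:
        c, low = _cho_factor(DtD)
        sol = _cho_solve((c, low), u)
    except np.linalg.LinAlgError:
        ridge = RIDGE_SCALE * np.trace(DtD) / d
        if ridge <= 0:
            ridge = RIDGE_SCALE
        warnings.warn("singular D'D; adding ridge %.3g to the g-prior precision" % ridge,
                      RuntimeWarning, stacklevel=2)
        sol = np.linalg.solve(DtD + ridge * np.eye(d), u)
    return float(u @ sol)


def _cho_factor(a):
    return np.linalg.cholesky(a), True


def _cho_solve(cl, b):
    c, _ = cl
    y = np.linalg.solve(c, b)
    return np.linalg.solve(c.T, y)


def log_marginal_from_stats(N: int, d: int, yty: float, fit: float,
                            hyper: Hyperparameters, delta2: float | None = None) -> float:
    """Closed-form log marginal likelihood from sufficient statistics.

    ``N`` rows, ``d = s+1`` columns, ``yty = y'y``, ``fit = y'D(D'D)^{-1}D'y``.
    Marginalizing the coefficients (g-prior) and the noise variance
    (inverse-Gamma(upsilon0/2, gamma0/2)) gives

        (2pi)^{-N/2} (1+delta2)^{-d/2} * (g0/2)^{u0/2} Gamma(u0/2 + N/2)
        / [ Gamma(u0/2) * (g0/2 + Q/2)^{u0/2 + N/2} ]

    with residual quadratic form Q = y'y - delta2/(1+delta2) * fit.
    """
    if delta2 is None:
        delta2 = hyper.delta2
    a0 = 0.5 * hyper.upsilon0
    b0 = 0.5 * hyper.gamma0
    shrink = delta2 / (1.0 + delta2)
    Q = yty - shrink * fit
    if Q < 0:  # numerical round-off on perfectly fit data
        Q = 0.0
    key = (N, a0, b0)
    const = _MARGINAL_CONSTANTS.get(key)
    if const is None:
        const = (-0.5 * N * math.log(2.0 * math.pi)
                 + a0 * math.log(b0) - math.lgamma(a0)
                 + math.lgamma(a0 + 0.5 * N))
        _MARGINAL_CONSTANTS[key] = const
    return (const - 0.5 * d * math.log1p(delta2)
            - (a0 + 0.5 * N) * math.log(b0 + 0.5 * Q))


_MARGINAL_CONSTANTS: dict = {}


def log_marginal_phase(design: PhaseDesign, hyper: Hyperparameters,
                       delta2: float | None = None) -> float:
    """Log marginal likelihood of one phase (coefficients and variance integrated out)."""
    D, y = design.D, design.y
    N, d = D.shape
    DtD = D.T @ D
    u = D.T @ y
    fit = _fit_statistic(DtD, u)
    return log_marginal_from_stats(N, d, float(y @ y), fit, hyper, delta2)


def gene_log_posterior_score(data: ExpressionDataset, target, cfg: ChangepointConfiguration,
                             parents_per_phase, hyper: Hyperparameters, candidates,
                             delta2: float | None = None,
                             lambda_cp: float | None = None,
                             Lambda_par: float | None = None) -> float:
    """Unnormalized log posterior of one gene's structure (Pr(x(1)) omitted).

    Sum of the truncated-Poisson prior on k, the uniform position prior, and —
    per phase — the truncated-Poisson prior on s, the uniform parent-set prior
    and the marginal phase likelihood.  The candidate list fixes the parent-set
    prior's universe.
    """
    n = data.n
    cfg.validate(n)
    if len(parents_per_phase) != cfg.k + 1:
        raise ValueError("need one parent set per phase")
    q = len(candidates)
    kmax = hyper.effective_k_max(n)
    smax = min(hyper.s_max, q)
    lam = hyper.lambda_cp if lambda_cp is None else lambda_cp
    Lam = hyper.Lambda_par if Lambda_par is None else Lambda_par

    score = truncated_poisson_log_pmf(cfg.k, lam, kmax)
    score += changepoint_position_log_prior(cfg, n)
    candidates = list(candidates)
    for (a, b), parents in zip(cfg.phases(), parents_per_phase):
        s = len(parents)
        if s > smax:
            raise ValueError(f"parent set of size {s} exceeds s_max={smax}")
        genes = [candidates[int(g)] if isinstance(g, (int, np.integer)) else g
                 for g in parents]
        design = build_phase_design(data, target, genes, (a, b))
        score += truncated_poisson_log_pmf(s, Lam, smax)
        score += parent_set_log_prior(s, q)
        score += log_marginal_phase(design, hyper, delta2)
    return score


# ---------------------------------------------------------------------------
# Fast scoring path for the sampler
# ---------------------------------------------------------------------------

class GeneScorer:
    """Cached phase-marginal evaluator for one target gene.

    Precomputes cumulative cross-products of the lag-1 candidate design so a
    phase's Gram matrix is two array subtractions, and caches the
    delta2-independent pieces (N, d, y'y, y'Py) per (phase, parent-set) key —
    the marginal for any delta2 is then a handful of scalar operations.

    Rows with a missing value in the target at t or in *any* candidate at t-1
    are dropped wholesale here (the reference path ``build_phase_design`` drops
    per used cells only); on complete data the two paths agree exactly.
    """

    def __init__(self, data: ExpressionDataset, target, candidates,
                 hyper: Hyperparameters):
        self.data = data
        self.hyper = hyper
        self.n = data.n
        ti = data.gene_index(target) if not isinstance(target, (int, np.integer)) else int(target)
        cidx = np.array([data.gene_index(g) if not isinstance(g, (int, np.integer)) else int(g)
                         for g in candidates], dtype=int)
        self.target_index = ti
        self.candidate_indices = cidx
        self.q = len(cidx)

        n, m = data.n, data.m
        q1 = self.q + 1
        # per target-time t (=2..n) sufficient statistics, summed over kept replicates
        G = np.zeros((n + 2, q1, q1))
        U = np.zeros((n + 2, q1))
        YY = np.zeros(n + 2)
        NR = np.zeros(n + 2)
        vals = data.values
        miss = data.missing_mask
        for t in range(2, n + 1):
            keep = ~(miss[ti, t - 1, :] | miss[cidx, t - 2, :].any(axis=0))
            if not np.any(keep):
                continue
            Z = np.empty((int(keep.sum()), q1))
            Z[:, 0] = 1.0
            Z[:, 1:] = vals[cidx][:, t - 2, keep].T
            yv = vals[ti, t - 1, keep]
            G[t] = Z.T @ Z
            U[t] = Z.T @ yv
            YY[t] = float(yv @ yv)
            NR[t] = len(yv)
        self._cumG = np.cumsum(G, axis=0)
        self._cumU = np.cumsum(U, axis=0)
        self._cumYY = np.cumsum(YY)
        self._cumN = np.cumsum(NR)
        self._pieces: dict = {}

    def phase_row_count(self, a: int, b: int) -> int:
        return int(self._cumN[b - 1] - self._cumN[a - 1])

    def pieces(self, a: int, b: int, parents: frozenset):
        """(N, d, y'y, y'Py) for phase [a, b) with the given candidate-index set."""
        key = (a, b, parents)
        out = self._pieces.get(key)
        if out is not None:
            return out
        idx = np.fromiter((0, *(1 + j for j in sorted(parents))), dtype=int)
        S = self._cumG[b - 1] - self._cumG[a - 1]
        u = (self._cumU[b - 1] - self._cumU[a - 1])[idx]
        A = S[np.ix_(idx, idx)]
        yty = float(self._cumYY[b - 1] - self._cumYY[a - 1])
        N = int(self._cumN[b - 1] - self._cumN[a - 1])
        if N == 0:
            raise ValueError(f"phase [{a}, {b}) has no usable rows")
        fit = _fit_statistic(A, u)
        out = (N, len(idx), yty, fit)
        self._pieces[key] = out
        return out

    def log_marginal(self, a: int, b: int, parents: frozenset, delta2: float) -> float:
        N, d, yty, fit = self.pieces(a, b, parents)
        return log_marginal_from_stats(N, d, yty, fit, self.hyper, delta2)

    def phase_log_score(self, a: int, b: int, parents: frozenset,
                        Lambda_par: float, delta2: float) -> float:
        """Parent-count prior + parent-set prior + marginal likelihood of a phase."""
        s = len(parents)
        smax = min(self.hyper.s_max, self.q)
        return (truncated_poisson_log_pmf(s, Lambda_par, smax)
                + parent_set_log_prior(s, self.q)
                + self.log_marginal(a, b, parents, delta2))
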