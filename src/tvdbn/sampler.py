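"""Reversible-jump MCMC over changepoint configurations and parent sets.

One iteration proposes a single structural move — changepoint birth, death or
shift, or a within-phase regression-model update (edge birth / death /
exchange) — accepts it by a Metropolis-Hastings ratio on the marginalized
posterior score, and then resamples the hyperparameters (lambda, Lambda by
conjugate-proposal MH with exact truncation correction; delta2 by a random
walk on the log scale).

Because regression coefficients and noise variances are integrated out
analytically, the state space is discrete (plus the three scalar
hyperparameters) and Green's trans-dimensional acceptance ratio reduces to an
ordinary MH ratio with explicit forward/reverse proposal probabilities.  At a
changepoint birth the two sub-phases' parent sets are re-proposed from a
mixture of (i) a copy of the split phase's set and (ii) the parent-set prior;
the death move mirrors this, so both densities are available in closed form.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .model import (
    ExpressionDataset,
    GeneScorer,
    Hyperparameters,
    parent_set_log_prior,
)

__all__ = [
    "MoveSchedule",
    "SamplerState",
    "SamplerTrace",
    "TraceRecord",
    "move_probabilities",
    "propose_birth",
    "propose_death",
    "propose_shift",
    "update_regression",
    "resample_hyperparameters",
    "run_sampler",
]

logger = logging.getLogger(__name__)

BIRTH, DEATH, SHIFT, REGRESSION, NULL = "B", "D", "S", "R", "0"


# ---------------------------------------------------------------------------
# Scalar prior helpers (hot path: plain math, no array allocation)
# ---------------------------------------------------------------------------

def _pois_weights(mean: float, kmax: int):
    """Unnormalized Poisson weights mean^j / j! for j = 0..kmax."""
    w = [1.0]
    term = 1.0
    for j in range(1, kmax + 1):
        term *= mean / j
        w.append(term)
    return w


def _tp_logpmf(s: int, mean: float, smax: int) -> float:
    """Truncated-Poisson log pmf on {0..smax} (normalizer by direct summation)."""
    if s < 0 or s > smax:
        return -math.inf
    w = _pois_weights(mean, smax)
    return math.log(w[s] / sum(w))


def _pois_log_cdf(mean: float, kmax: int) -> float:
    """log Pr(Poisson(mean) <= kmax)."""
    return -mean + math.log(sum(_pois_weights(mean, kmax)))


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def _set_prior_logpmf(pa: frozenset, q: int, Lambda: float, smax: int) -> float:
    """Prior pmf of a parent set: truncated Poisson on its size, uniform given size."""
    s = len(pa)
    if s > min(smax, q):
        return -math.inf
    return _tp_logpmf(s, Lambda, min(smax, q)) - _log_comb(q, s)


def _sample_prior_set(rng, q: int, Lambda: float, smax: int) -> frozenset:
    smax_eff = min(smax, q)
    w = _pois_weights(Lambda, smax_eff)
    u = rng.random() * sum(w)
    s = 0
    acc = w[0]
    while u > acc and s < smax_eff:
        s += 1
        acc += w[s]
    if s == 0:
        return frozenset()
    return frozenset(int(j) for j in rng.choice(q, size=s, replace=False))


_LOG_HALF = math.log(0.5)


def _mix_logpdf(pa: frozenset, base: frozenset, q: int, Lambda: float, smax: int) -> float:
    """Density of the copy/prior mixture used to re-propose a phase's parents."""
    lp = _LOG_HALF + _set_prior_logpmf(pa, q, Lambda, smax)
    if pa == base:
        lp = np.logaddexp(_LOG_HALF, lp)
    return float(lp)


def _mix_sample(rng, base: frozenset, q: int, Lambda: float, smax: int) -> frozenset:
    if rng.random() < 0.5:
        return base
    return _sample_prior_set(rng, q, Lambda, smax)


def _merge_logpdf(pa: frozenset, left: frozenset, right: frozenset,
                  q: int, Lambda: float, smax: int) -> float:
    """Density of the merged-phase proposal: 1/2 copy (uniform source), 1/2 prior."""
    copy_mass = 0.5 * ((pa == left) + (pa == right))
    lp = _LOG_HALF + _set_prior_logpmf(pa, q, Lambda, smax)
    if copy_mass > 0:
        lp = np.logaddexp(_LOG_HALF + math.log(copy_mass), lp)
    return float(lp)


def _merge_sample(rng, left: frozenset, right: frozenset,
                  q: int, Lambda: float, smax: int) -> frozenset:
    if rng.random() < 0.5:
        return left if rng.random() < 0.5 else right
    return _sample_prior_set(rng, q, Lambda, smax)


# ---------------------------------------------------------------------------
# Move schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MoveSchedule:
    """Probabilities of changepoint Birth / Death / Shift and Regression update."""

    b: float
    d: float
    v: float
    w: float

    def __post_init__(self):
        if abs(self.b + self.d + self.v + self.w - 1.0) > 1e-12:
            raise ValueError("move probabilities must sum to 1")


def move_probabilities(k: int, hyper: Hyperparameters, kmax: int,
                       lambda_cp: float | None = None) -> MoveSchedule:
    """b_k = c min(1, Pr(k+1)/Pr(k)), d_k = c min(1, Pr(k-1)/Pr(k)) under the
    truncated Poisson prior (the truncation constant cancels in the ratio);
    d_0 = v_0 = 0 and b_kmax = 0; the remaining mass is split between shift
    (fraction ``v_frac``, when k >= 1) and regression update."""
    if not hyper.c < 0.25:
        raise ValueError("move constant c must be smaller than 1/4")
    if not 0 <= k <= kmax:
        raise ValueError(f"k={k} outside [0, {kmax}]")
    lam = hyper.lambda_cp if lambda_cp is None else lambda_cp
    b = hyper.c * min(1.0, lam / (k + 1)) if k < kmax else 0.0
    d = hyper.c * min(1.0, k / lam) if k >= 1 else 0.0
    rest = 1.0 - b - d
    v = hyper.v_frac * rest if k >= 1 else 0.0
    return MoveSchedule(b=b, d=d, v=v, w=rest - v)


# ---------------------------------------------------------------------------
# Sampler state and trace
# ---------------------------------------------------------------------------

@dataclass
class SamplerState:
    """Current structure (changepoints + per-phase parent sets) and hyperparameters."""

    xi: tuple
    parents: tuple          # one frozenset of candidate indices per phase
    lambda_cp: float
    Lambda_par: float
    delta2: float

    def __post_init__(self):
        if len(self.parents) != len(self.xi) - 1:
            raise ValueError("need exactly one parent set per phase")

    @property
    def k(self) -> int:
        return len(self.xi) - 2

    @property
    def interior(self) -> tuple:
        return self.xi[1:-1]


@dataclass(frozen=True)
class TraceRecord:
    k: int
    xi: tuple
    parents: tuple
    move: str
    accepted: bool


@dataclass
class SamplerTrace:
    """Per-iteration structural samples plus hyperparameter paths."""

    records: list
    burn_in: int
    seed: int | None
    n: int
    target: object
    candidates: list
    lambda_cp: np.ndarray = field(default=None)
    Lambda_par: np.ndarray = field(default=None)
    delta2: np.ndarray = field(default=None)
    acceptance_rates: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.records)

    def post_burn_in(self):
        return self.records[self.burn_in:]


# ---------------------------------------------------------------------------
# Moves
# ---------------------------------------------------------------------------

def _phase_prior(pa: frozenset, q: int, Lam: float, smax: int) -> float:
    return _tp_logpmf(len(pa), Lam, min(smax, q)) + parent_set_log_prior(len(pa), q)


class _Scorer:
    """Bundles the marginal-likelihood evaluator with the structural priors;
    with ``use_likelihood=False`` the likelihood term is constant (prior-only
    chain, used to validate the sampler against the prior hierarchy)."""

    def __init__(self, gene_scorer: GeneScorer | None, q: int, hyper: Hyperparameters,
                 use_likelihood: bool = True):
        self.gs = gene_scorer
        self.q = q
        self.hyper = hyper
        self.use_likelihood = use_likelihood and gene_scorer is not None

    def marginal(self, a: int, b: int, pa: frozenset, delta2: float) -> float:
        if not self.use_likelihood:
            return 0.0
        return self.gs.log_marginal(a, b, pa, delta2)

    def phase(self, a: int, b: int, pa: frozenset, Lam: float, delta2: float) -> float:
        return _phase_prior(pa, self.q, Lam, self.hyper.s_max) + self.marginal(a, b, pa, delta2)


def _k_prior_ratio(k_new: int, k_old: int, lam: float) -> float:
    """log Pr(k_new)/Pr(k_old) under the truncated Poisson (normalizer cancels)."""
    return ((k_new - k_old) * math.log(lam)
            - math.lgamma(k_new + 1) + math.lgamma(k_old + 1))


def _position_prior_ratio(k_new: int, k_old: int, n: int) -> float:
    return _log_comb(n - 2, k_old) - _log_comb(n - 2, k_new)


def propose_birth(state: SamplerState, rng, scorer: _Scorer, hyper: Hyperparameters,
                  n: int, kmax: int):
    """Insert a changepoint at a uniformly chosen free position; re-propose the
    two sub-phases' parent sets from the copy/prior mixture.  Returns
    ``(proposed_state, log_acceptance)``; impossible proposals return
    ``(None, -inf)`` and count as rejected."""
    k = state.k
    free = [p for p in range(3, n + 1) if p not in state.xi]
    if k >= kmax or not free:
        return None, -math.inf
    q, Lam, smax = scorer.q, state.Lambda_par, hyper.s_max
    p = int(free[rng.integers(len(free))])
    h = int(np.searchsorted(state.xi, p)) - 1
    a, b = state.xi[h], state.xi[h + 1]
    pa0 = state.parents[h]
    pa1 = _mix_sample(rng, pa0, q, Lam, smax)
    pa2 = _mix_sample(rng, pa0, q, Lam, smax)

    try:
        dscore = (scorer.phase(a, p, pa1, Lam, state.delta2)
                  + scorer.phase(p, b, pa2, Lam, state.delta2)
                  - scorer.phase(a, b, pa0, Lam, state.delta2))
    except ValueError:
        return None, -math.inf
    dscore += _k_prior_ratio(k + 1, k, state.lambda_cp)
    dscore += _position_prior_ratio(k + 1, k, n)

    sched = move_probabilities(k, hyper, kmax, state.lambda_cp)
    sched_new = move_probabilities(k + 1, hyper, kmax, state.lambda_cp)
    log_fwd = (math.log(sched.b) - math.log(len(free))
               + _mix_logpdf(pa1, pa0, q, Lam, smax)
               + _mix_logpdf(pa2, pa0, q, Lam, smax))
    log_rev = (math.log(sched_new.d) - math.log(k + 1)
               + _merge_logpdf(pa0, pa1, pa2, q, Lam, smax))

    new_xi = tuple(sorted((*state.xi, p)))
    new_parents = state.parents[:h] + (pa1, pa2) + state.parents[h + 1:]
    new_state = SamplerState(new_xi, new_parents, state.lambda_cp,
                             state.Lambda_par, state.delta2)
    return new_state, dscore + log_rev - log_fwd


def propose_death(state: SamplerState, rng, scorer: _Scorer, hyper: Hyperparameters,
                  n: int, kmax: int):
    """Remove a uniformly chosen changepoint; re-propose the merged phase's
    parent set (copy-of-either-side / prior mixture)."""
    k = state.k
    if k < 1:
        return None, -math.inf
    q, Lam, smax = scorer.q, state.Lambda_par, hyper.s_max
    i = int(rng.integers(k)) + 1          # index into xi
    p = state.xi[i]
    a, b = state.xi[i - 1], state.xi[i + 1]
    pa1, pa2 = state.parents[i - 1], state.parents[i]
    pam = _merge_sample(rng, pa1, pa2, q, Lam, smax)

    try:
        dscore = (scorer.phase(a, b, pam, Lam, state.delta2)
                  - scorer.phase(a, p, pa1, Lam, state.delta2)
                  - scorer.phase(p, b, pa2, Lam, state.delta2))
    except ValueError:
        return None, -math.inf
    dscore += _k_prior_ratio(k - 1, k, state.lambda_cp)
    dscore += _position_prior_ratio(k - 1, k, n)

    sched = move_probabilities(k, hyper, kmax, state.lambda_cp)
    sched_new = move_probabilities(k - 1, hyper, kmax, state.lambda_cp)
    n_free_after = (n - 2) - (k - 1)
    log_fwd = (math.log(sched.d) - math.log(k)
               + _merge_logpdf(pam, pa1, pa2, q, Lam, smax))
    log_rev = (math.log(sched_new.b) - math.log(n_free_after)
               + _mix_logpdf(pa1, pam, q, Lam, smax)
               + _mix_logpdf(pa2, pam, q, Lam, smax))

    new_xi = state.xi[:i] + state.xi[i + 1:]
    new_parents = state.parents[:i - 1] + (pam,) + state.parents[i + 1:]
    new_state = SamplerState(new_xi, new_parents, state.lambda_cp,
                             state.Lambda_par, state.delta2)
    return new_state, dscore + log_rev - log_fwd


def propose_shift(state: SamplerState, rng, scorer: _Scorer, hyper: Hyperparameters,
                  n: int, kmax: int):
    """Move one changepoint to a uniformly chosen feasible position between its
    flanking changepoints (symmetric proposal; parent sets kept)."""
    k = state.k
    if k < 1:
        return None, -math.inf
    i = int(rng.integers(k)) + 1
    p = state.xi[i]
    left, right = state.xi[i - 1], state.xi[i + 1]
    feasible = [x for x in range(left + 1, right) if x != p]
    if not feasible:
        return None, -math.inf
    p_new = int(feasible[rng.integers(len(feasible))])
    Lam, d2 = state.Lambda_par, state.delta2
    pa1, pa2 = state.parents[i - 1], state.parents[i]
    try:
        dscore = (scorer.marginal(left, p_new, pa1, d2)
                  + scorer.marginal(p_new, right, pa2, d2)
                  - scorer.marginal(left, p, pa1, d2)
                  - scorer.marginal(p, right, pa2, d2))
    except ValueError:
        return None, -math.inf
    new_xi = state.xi[:i] + (p_new,) + state.xi[i + 1:]
    new_state = SamplerState(new_xi, state.parents, state.lambda_cp,
                             state.Lambda_par, state.delta2)
    return new_state, dscore


def _submove_probs(s: int, q: int, smax: int, hyper: Hyperparameters):
    """Effective (add, remove, exchange) probabilities: an impossible sub-move's
    mass is folded into the exchange move when available, otherwise the
    remaining moves are renormalized (null move if nothing is possible)."""
    smax_eff = min(smax, q)
    add_ok = s < smax_eff
    del_ok = s >= 1
    exch_ok = 1 <= s < q
    p_add = hyper.chi if add_ok else 0.0
    p_del = hyper.zeta if del_ok else 0.0
    p_exch = hyper.rho if exch_ok else 0.0
    total = p_add + p_del + p_exch
    if total == 0.0:
        return None
    lost = 1.0 - total
    if exch_ok:
        p_exch += lost
    else:
        p_add, p_del, p_exch = p_add / total, p_del / total, p_exch / total
    return p_add, p_del, p_exch


def update_regression(state: SamplerState, rng, scorer: _Scorer, hyper: Hyperparameters,
                      phase_index: int | None = None):
    """Edge birth / death / exchange in one phase (second RJ-MCMC level).

    The acceptance ratio combines the marginalized score ratio, the
    truncated-Poisson prior ratio on the parent count, the uniform-set prior
    ratio and the proposal probabilities."""
    q, smax = scorer.q, hyper.s_max
    h = int(rng.integers(len(state.parents))) if phase_index is None else phase_index
    a, b = state.xi[h], state.xi[h + 1]
    pa = state.parents[h]
    s = len(pa)
    Lam, d2 = state.Lambda_par, state.delta2
    probs = _submove_probs(s, q, smax, hyper)
    if probs is None:
        return None, -math.inf
    p_add, p_del, p_exch = probs
    u = rng.random()
    try:
        if u < p_add:
            non_parents = [j for j in range(q) if j not in pa]
            j = int(non_parents[rng.integers(len(non_parents))])
            pa_new = pa | {j}
            rev = _submove_probs(s + 1, q, smax, hyper)
            log_fwd = math.log(p_add) - math.log(q - s)
            log_rev = math.log(rev[1]) - math.log(s + 1)
        elif u < p_add + p_del:
            members = sorted(pa)
            j = int(members[rng.integers(s)])
            pa_new = pa - {j}
            rev = _submove_probs(s - 1, q, smax, hyper)
            log_fwd = math.log(p_del) - math.log(s)
            log_rev = math.log(rev[0]) - math.log(q - (s - 1))
        else:
            members = sorted(pa)
            non_parents = [j for j in range(q) if j not in pa]
            j_out = int(members[rng.integers(s)])
            j_in = int(non_parents[rng.integers(len(non_parents))])
            pa_new = (pa - {j_out}) | {j_in}
            log_fwd = log_rev = 0.0     # symmetric in counts
        dscore = (scorer.phase(a, b, pa_new, Lam, d2)
                  - scorer.phase(a, b, pa, Lam, d2))
    except ValueError:
        return None, -math.inf
    new_parents = state.parents[:h] + (pa_new,) + state.parents[h + 1:]
    new_state = SamplerState(state.xi, new_parents, state.lambda_cp,
                             state.Lambda_par, state.delta2)
    return new_state, dscore + log_rev - log_fwd


# ---------------------------------------------------------------------------
# Hyperparameter resampling
# ---------------------------------------------------------------------------

def resample_hyperparameters(state: SamplerState, rng, scorer: _Scorer,
                             hyper: Hyperparameters, n: int, kmax: int,
                             delta_step: float = 0.7) -> SamplerState:
    """Refresh (lambda, Lambda, delta2); never alters the structure.

    lambda | k and Lambda | (s_1..s_{k+1}) use the untruncated conjugate Gamma
    as an independence MH proposal with the exact truncation correction (a
    Poisson-cdf ratio); delta2 uses a log-scale random walk against the
    inverse-Gamma prior times the marginalized likelihood.
    """
    k = state.k
    # lambda | k
    shape = hyper.alpha + k
    scale = hyper.beta / (1.0 + hyper.beta)
    lam_new = float(rng.gamma(shape, scale))
    if lam_new > 0:
        log_acc = _pois_log_cdf(state.lambda_cp, kmax) - _pois_log_cdf(lam_new, kmax)
        if math.log(rng.random()) < log_acc:
            state = SamplerState(state.xi, state.parents, lam_new,
                                 state.Lambda_par, state.delta2)

    # Lambda | parent counts
    q = scorer.q
    smax_eff = min(hyper.s_max, q)
    s_tot = sum(len(pa) for pa in state.parents)
    n_phases = k + 1
    shape = hyper.alpha + s_tot
    scale = hyper.beta / (1.0 + n_phases * hyper.beta)
    Lam_new = float(rng.gamma(shape, scale))
    if Lam_new > 0:
        log_acc = n_phases * (_pois_log_cdf(state.Lambda_par, smax_eff)
                              - _pois_log_cdf(Lam_new, smax_eff))
        if math.log(rng.random()) < log_acc:
            state = SamplerState(state.xi, state.parents, state.lambda_cp,
                                 Lam_new, state.delta2)

    # delta2 | structure, data
    d2 = state.delta2
    d2_new = d2 * math.exp(delta_step * rng.normal())
    a_d, b_d = hyper.alpha_delta, hyper.beta_delta

    def _log_target(d2v: float) -> float:
        lp = -(a_d + 1.0) * math.log(d2v) - b_d / d2v
        if scorer.use_likelihood:
            for (a, b), pa in zip(zip(state.xi, state.xi[1:]), state.parents):
                lp += scorer.marginal(a, b, pa, d2v)
        return lp

    log_acc = (_log_target(d2_new) - _log_target(d2)
               + math.log(d2_new) - math.log(d2))   # log-RW Jacobian
    if math.log(rng.random()) < log_acc:
        state = SamplerState(state.xi, state.parents, state.lambda_cp,
                             state.Lambda_par, d2_new)
    return state


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def run_sampler(data: ExpressionDataset | None, target, candidates,
                iterations: int = 50000, seed: int | None = None,
                hyper: Hyperparameters | None = None,
                burn_in: float = 0.25, self_loops: bool = False,
                use_likelihood: bool = True, n: int | None = None,
                log_every: int = 1000, resample_hypers: bool = True) -> SamplerTrace:
    """Run the RJ-MCMC chain for one target gene and return its trace.

    ``candidates`` lists the allowed parent genes (ids or indices into
    ``data``); the target may appear among them only with ``self_loops=True``.
    With ``use_likelihood=False`` the chain samples the structural prior
    hierarchy (``data`` may then be None if ``n`` is given).  Reproducible
    given ``seed``.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    hyper = hyper or Hyperparameters()
    candidates = list(candidates)
    if data is not None:
        n = data.n
        if not self_loops and any(
                (data.gene_index(g) if not isinstance(g, (int, np.integer)) else int(g))
                == (data.gene_index(target) if not isinstance(target, (int, np.integer))
                    else int(target))
                for g in candidates):
            raise ValueError("target among candidates requires self_loops=True")
    if n is None:
        raise ValueError("n must be given when data is None")
    q = len(candidates)
    hyper.validate(n=n)   # s_max is clamped to min(s_max, q) throughout
    kmax = min(hyper.effective_k_max(n), n - 2)

    gene_scorer = GeneScorer(data, target, candidates, hyper) if (
        data is not None and use_likelihood) else None
    scorer = _Scorer(gene_scorer, q, hyper, use_likelihood)
    rng = np.random.default_rng(seed)

    state = SamplerState(xi=(2, n + 1), parents=(frozenset(),),
                         lambda_cp=hyper.lambda_cp, Lambda_par=hyper.Lambda_par,
                         delta2=hyper.delta2)

    movers = {BIRTH: propose_birth, DEATH: propose_death, SHIFT: propose_shift}
    proposed = {m: 0 for m in (BIRTH, DEATH, SHIFT, REGRESSION)}
    accepted = {m: 0 for m in (BIRTH, DEATH, SHIFT, REGRESSION)}
    records = []
    lam_path = np.empty(iterations)
    Lam_path = np.empty(iterations)
    d2_path = np.empty(iterations)

    for it in range(iterations):
        sched = move_probabilities(state.k, hyper, kmax, state.lambda_cp)
        u = rng.random()
        if u < sched.b:
            move = BIRTH
        elif u < sched.b + sched.d:
            move = DEATH
        elif u < sched.b + sched.d + sched.v:
            move = SHIFT
        else:
            move = REGRESSION
        proposed[move] += 1
        if move == REGRESSION:
            new_state, log_acc = update_regression(state, rng, scorer, hyper)
        else:
            new_state, log_acc = movers[move](state, rng, scorer, hyper, n, kmax)
        ok = new_state is not None and (log_acc >= 0 or math.log(rng.random()) < log_acc)
        if ok:
            state = new_state
            accepted[move] += 1

        if resample_hypers:
            state = resample_hyperparameters(state, rng, scorer, hyper, n, kmax)
        records.append(TraceRecord(state.k, state.xi, state.parents, move, ok))
        lam_path[it] = state.lambda_cp
        Lam_path[it] = state.Lambda_par
        d2_path[it] = state.delta2

        if log_every and (it + 1) % log_every == 0:
            rates = {m: (accepted[m] / proposed[m] if proposed[m] else float("nan"))
                     for m in proposed}
            logger.info("iter %d: k=%d acceptance rates %s", it + 1, state.k,
                        {m: round(r, 3) for m, r in rates.items()})

    n_burn = int(round(burn_in * iterations))
    trace = SamplerTrace(records=records, burn_in=n_burn, seed=seed, n=n,
                         target=target, candidates=candidates,
                         lambda_cp=lam_path, Lambda_par=Lam_path, delta2=d2_path)
    trace.acceptance_rates = {
        m: (accepted[m] / proposed[m] if proposed[m] else float("nan"))
        for m in proposed}
    return trace
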