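"""Posterior summaries, Bayes factors and network selection from a trace.

The Bayes factor of an event E is its posterior odds divided by its prior
odds.  Posterior probabilities are empirical frequencies over the post-burn-in
trace; prior probabilities come from direct Monte-Carlo simulation of the
prior hierarchy (lambda, Lambda ~ Gamma; counts truncated Poisson; positions
and parent sets uniform).  Support bands follow Kass & Raftery: below 3 "not
supported", 3-20 "positive", above 20 "strong".

Selection is three-staged: pick the changepoint count k with the largest
Bayes factor, then the k positions with the largest Bayes factors, then — for
each resulting phase — the parent genes whose Bayes factor exceeds the
threshold (3 by default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import (
    ExpressionDataset,
    Hyperparameters,
    build_phase_design,
)
from .sampler import SamplerTrace

__all__ = [
    "BayesFactorReport",
    "SelectedNetwork",
    "SelectedPhase",
    "posterior_probability",
    "bayes_factor",
    "support_label",
    "prior_event_probability",
    "select_network",
    "attach_coefficients",
]


def support_label(bf: float) -> str:
    """Kass-Raftery support band for a Bayes factor."""
    if bf < 3:
        return "not supported"
    if bf <= 20:
        return "positive"
    return "strong"


@dataclass
class BayesFactorReport:
    """Bayes factors for changepoint counts, positions (given the selected
    count) and per-(phase, candidate) parent inclusion."""

    k_bf: dict
    position_bf: dict
    parent_bf: dict          # (phase_index, candidate_index) -> BF
    prior_note: str = ("prior odds estimated by Monte-Carlo simulation of the "
                       "hyperprior-marginalized prior hierarchy")

    def labels(self) -> dict:
        out = {}
        for name, d in (("k", self.k_bf), ("position", self.position_bf),
                        ("parent", self.parent_bf)):
            out[name] = {key: support_label(bf) for key, bf in d.items()}
        return out


@dataclass
class SelectedPhase:
    start: int
    end: int
    parents: list            # candidate indices
    parent_bf: dict          # candidate index -> BF (selected parents only)
    coefficients: dict = field(default_factory=dict)   # candidate -> posterior mean
    intercept: float | None = None


@dataclass
class SelectedNetwork:
    """One gene's selected time-varying model: changepoints + per-phase parents."""

    target: object
    k: int
    positions: tuple
    phases: list             # of SelectedPhase
    candidates: list
    report: BayesFactorReport | None = None


# ---------------------------------------------------------------------------
# Posterior / prior event probabilities
# ---------------------------------------------------------------------------

def _phase_covering(xi: tuple, t: float) -> int:
    """Index of the phase [xi_{h-1}, xi_h) containing time t."""
    for h in range(len(xi) - 1):
        if xi[h] <= t < xi[h + 1]:
            return h
    raise ValueError(f"time {t} outside [{xi[0]}, {xi[-1]})")


def _event_indicator(rec, event) -> bool:
    kind = event[0]
    if kind == "k":
        return rec.k == event[1]
    if kind == "position":
        return event[1] in rec.xi[1:-1]
    if kind == "parent":
        _, j, t = event
        return j in rec.parents[_phase_covering(rec.xi, t)]
    raise ValueError(f"unknown event kind {kind!r}")


def posterior_probability(trace: SamplerTrace, event) -> float:
    """Empirical post-burn-in frequency of an event.

    Events: ``("k", kappa)``, ``("position", p)``, or ``("parent", j, t)`` —
    candidate j is a parent in the phase covering time t.
    """
    records = trace.post_burn_in()
    if not records:
        raise ValueError("empty post-burn-in trace")
    hits = sum(_event_indicator(r, event) for r in records)
    return hits / len(records)


def bayes_factor(posterior_p: float, prior_p: float) -> float:
    """Posterior odds over prior odds."""
    if not 0.0 < prior_p < 1.0:
        raise ValueError(f"prior probability {prior_p} makes the prior odds improper")
    if posterior_p >= 1.0:
        warnings.warn("posterior probability 1: Bayes factor reported as +inf",
                      RuntimeWarning, stacklevel=2)
        return math.inf
    post_odds = posterior_p / (1.0 - posterior_p)
    prior_odds = prior_p / (1.0 - prior_p)
    return post_odds / prior_odds


def _sample_prior_hierarchy(hyper: Hyperparameters, n: int, n_candidates: int,
                            n_draws: int, rng):
    """Vectorized draws of (k, s of a typical phase) from the prior hierarchy."""
    kmax = min(hyper.effective_k_max(n), n - 2)
    smax = min(hyper.s_max, n_candidates)
    lam = rng.gamma(hyper.alpha, hyper.beta, size=n_draws)
    Lam = rng.gamma(hyper.alpha, hyper.beta, size=n_draws)

    def trunc_pois(means, mmax):
        js = np.arange(mmax + 1)
        logp = (-means[:, None] + js[None, :] * np.log(means[:, None])
                - [math.lgamma(j + 1) for j in js])
        p = np.exp(logp - logp.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        cum = np.cumsum(p, axis=1)
        u = rng.random(len(means))[:, None]
        return (u > cum).sum(axis=1)

    k = trunc_pois(lam, kmax)
    s = trunc_pois(Lam, smax)      # parent count of one (exchangeable) phase
    return k, s


def prior_event_probability(event, hyper: Hyperparameters, n: int,
                            n_candidates: int, n_draws: int = 50000,
                            seed: int | None = None) -> float:
    """Monte-Carlo prior probability of an event under the prior hierarchy.

    Position and parent events are collapsed by exchangeability: given k
    changepoints each position in {3..n} is included with probability
    k/(n-2), and given a phase parent count s each candidate is a parent with
    probability s/q — the estimator averages these over the hierarchy draws.
    """
    rng = np.random.default_rng(seed)
    k, s = _sample_prior_hierarchy(hyper, n, n_candidates, n_draws, rng)
    kind = event[0]
    if kind == "k":
        return float(np.mean(k == event[1]))
    if kind == "position":
        return float(np.mean(k / (n - 2)))
    if kind == "parent":
        return float(np.mean(s / n_candidates))
    raise ValueError(f"unknown event kind {kind!r}")


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def select_network(trace: SamplerTrace, hyper: Hyperparameters | None = None,
                   bf_threshold: float = 3.0, n_prior_draws: int = 50000,
                   prior_seed: int = 0) -> SelectedNetwork:
    """Three-stage Bayes-factor selection of one gene's time-varying network.

    Ties in the k or position Bayes factors resolve to the smaller k / the
    earlier position.  A sample contributes to a selected phase's parent
    statistics through its own phase covering the selected phase's midpoint,
    which keeps the statistics robust to one-off changepoint jitter.
    """
    hyper = hyper or Hyperparameters()
    records = trace.post_burn_in()
    if not records:
        raise ValueError("empty post-burn-in trace")
    n, q = trace.n, len(trace.candidates)
    n_rec = len(records)
    kmax = min(hyper.effective_k_max(n), n - 2)
    rng = np.random.default_rng(prior_seed)
    k_draws, s_draws = _sample_prior_hierarchy(hyper, n, q, n_prior_draws, rng)
    floor = 1.0 / (n_prior_draws + 1.0)       # guard against zero MC mass

    def _bf(post_p, prior_p):
        prior_p = min(max(prior_p, floor), 1.0 - floor)
        if post_p >= 1.0:
            return math.inf
        return (post_p / (1.0 - post_p)) / (prior_p / (1.0 - prior_p))

    # --- stage 1: changepoint count
    k_counts = np.bincount([r.k for r in records], minlength=kmax + 1)
    k_bf = {}
    for kappa in range(kmax + 1):
        post_p = k_counts[kappa] / n_rec
        prior_p = float(np.mean(k_draws == kappa))
        k_bf[kappa] = _bf(post_p, prior_p)
    k_sel = max(range(kmax + 1), key=lambda kappa: (k_bf[kappa], -kappa))

    # --- stage 2: positions
    prior_incl = float(np.mean(k_draws / (n - 2)))
    pos_bf = {}
    pos_counts = {p: 0 for p in range(3, n + 1)}
    for r in records:
        for p in r.xi[1:-1]:
            pos_counts[p] += 1
    for p in range(3, n + 1):
        pos_bf[p] = _bf(pos_counts[p] / n_rec, prior_incl)
    ranked = sorted(pos_bf, key=lambda p: (-pos_bf[p], p))
    positions = tuple(sorted(ranked[:k_sel]))

    # --- stage 3: parents per phase
    bounds = (2, *positions, n + 1)
    prior_parent = float(np.mean(s_draws / q)) if q else 0.0
    phases = []
    parent_bf_all = {}
    for h in range(len(bounds) - 1):
        a, b = bounds[h], bounds[h + 1]
        mid = 0.5 * (a + b)
        counts = np.zeros(q)
        for r in records:
            pa = r.parents[_phase_covering(r.xi, mid)]
            for j in pa:
                counts[j] += 1
        sel_parents, sel_bf = [], {}
        for j in range(q):
            bf = _bf(counts[j] / n_rec, prior_parent)
            parent_bf_all[(h, j)] = bf
            if bf > bf_threshold:
                sel_parents.append(j)
                sel_bf[j] = bf
        phases.append(SelectedPhase(start=a, end=b, parents=sel_parents,
                                    parent_bf=sel_bf))

    report = BayesFactorReport(k_bf=k_bf, position_bf=pos_bf, parent_bf=parent_bf_all)
    return SelectedNetwork(target=trace.target, k=k_sel, positions=positions,
                           phases=phases, candidates=list(trace.candidates),
                           report=report)


def attach_coefficients(network: SelectedNetwork, data: ExpressionDataset,
                        hyper: Hyperparameters | None = None,
                        delta2: float | None = None) -> SelectedNetwork:
    """Fill in posterior-mean regression coefficients for the selected model.

    Under the g-prior the conditional posterior mean of the coefficients is
    the least-squares solution shrunk by delta2/(1+delta2); ``delta2``
    defaults to the hyperparameter value (pass the trace's posterior mean for
    a data-driven shrinkage).
    """
    hyper = hyper or Hyperparameters()
    d2 = hyper.delta2 if delta2 is None else delta2
    shrink = d2 / (1.0 + d2)
    for phase in network.phases:
        genes = [network.candidates[j] for j in phase.parents]
        design = build_phase_design(data, network.target, genes,
                                    (phase.start, phase.end))
        DtD = design.D.T @ design.D
        theta = shrink * np.linalg.lstsq(DtD, design.D.T @ design.y, rcond=None)[0]
        phase.intercept = float(theta[0])
        phase.coefficients = {j: float(c) for j, c in zip(phase.parents, theta[1:])}
    return network
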