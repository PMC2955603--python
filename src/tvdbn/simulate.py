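"""Synthetic time-varying regulatory networks and the recovery benchmark.

The generator emulates a piecewise-constant lag-1 autoregressive target: a
random network structure (changepoints + per-phase parent sets and
coefficients) is drawn first, parent expression values are sampled uniformly
from [-2, -0.1] U [0.1, 2] and the target is computed from the autoregressive
model plus Gaussian noise.  Two designs are produced:

* WT — one multi-gene time series with replicated measurements (8 replicates
  by default); the sampler must find the parents among the candidate genes.
* KO — each replicate contains one block per genetic context (wild type plus
  one deletion strain per candidate regulator); in the block where regulator
  j is deleted its expression is identically zero, so its contribution to the
  target disappears (4 replicates by default).

Recovery is scored by positive predictive value and sensitivity, separately
for changepoints (exact integer position match by default) and for
(parent, phase) edges; edge scores are computed only on genes whose
changepoint segmentation was recovered exactly.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ExpressionDataset, Hyperparameters
from .sampler import run_sampler
from .selection import SelectedNetwork, select_network

__all__ = [
    "TrueNetwork",
    "BenchmarkCondition",
    "BenchmarkResult",
    "simulate_structure",
    "simulate_wt",
    "simulate_ko",
    "evaluate_changepoints",
    "evaluate_edges",
    "run_benchmark",
]

logger = logging.getLogger(__name__)

COEF_LOW, COEF_HIGH = 0.1, 2.0


@dataclass
class TrueNetwork:
    """Ground-truth time-varying structure for one simulated target gene."""

    n: int
    changepoints: tuple                  # interior positions, strictly increasing
    parents: list                        # per phase: tuple of candidate indices
    coeffs: list                         # per phase: dict candidate -> coefficient
    intercepts: list                     # per phase: float
    noise_sd: float
    mode: str                            # "WT" or "KO"
    n_candidates: int

    def __post_init__(self):
        if self.mode not in ("WT", "KO"):
            raise ValueError("mode must be 'WT' or 'KO'")
        for cd in self.coeffs:
            for v in cd.values():
                if not (COEF_LOW <= abs(v) <= COEF_HIGH):
                    raise ValueError("coefficients must lie in [-2,-0.1] U [0.1,2]")
        if any(len(p) > 5 for p in self.parents):
            raise ValueError("at most 5 parents per phase")

    @property
    def phases(self):
        bounds = (2, *self.changepoints, self.n + 1)
        return [(bounds[h], bounds[h + 1]) for h in range(len(bounds) - 1)]

    def phase_of(self, t: int) -> int:
        bounds = (2, *self.changepoints, self.n + 1)
        for h in range(len(bounds) - 1):
            if bounds[h] <= t < bounds[h + 1]:
                return h
        raise ValueError(f"time {t} outside [2, {self.n + 1})")


def _draw_coefficient(rng) -> float:
    """Uniform on [-2, -0.1] U [0.1, 2]."""
    mag = rng.uniform(COEF_LOW, COEF_HIGH)
    return float(mag if rng.random() < 0.5 else -mag)


def _draw_signal(rng, size):
    mag = rng.uniform(COEF_LOW, COEF_HIGH, size=size)
    sign = np.where(rng.random(size=size) < 0.5, 1.0, -1.0)
    return mag * sign


def simulate_structure(rng, n: int = 12, n_candidates: int = 5,
                       phase_size: int = 4, max_edges: int = 5,
                       mode: str = "WT", noise_sd: float = 0.5) -> TrueNetwork:
    """Draw a ground-truth structure with regularly spaced changepoints.

    Changepoints sit at 2 + j*phase_size for j = 1, 2, ... while they stay in
    the admissible range {3..n}; the last phase absorbs any remainder (so
    phase_size >= n - 1 yields a single phase and no changepoint).  Per phase
    the parent count is uniform on {1..min(max_edges, n_candidates)}, parents
    are drawn without replacement and their coefficients come from
    [-2,-0.1] U [0.1,2]; the baseline term is zero (the protocol draws
    regulator coefficients only, so phases differ through their parent sets
    and coefficients, not through mean shifts).

    A changepoint marks a change in the regulatory inputs, so consecutive
    phases are constrained to differ in their parent sets (when more than one
    set is possible); independently drawn identical adjacent sets would
    create changepoints that are unidentifiable in principle.
    """
    if phase_size < 1:
        raise ValueError("phase_size must be >= 1")
    if n < 3:
        raise ValueError("need n >= 3")
    cps = tuple(p for p in range(2 + phase_size, n + 1, phase_size))
    smax = min(max_edges, n_candidates)
    parents, coeffs, intercepts = [], [], []
    for _ in range(len(cps) + 1):
        while True:
            s = int(rng.integers(1, smax + 1))
            pa = tuple(sorted(int(j) for j in rng.choice(n_candidates, size=s,
                                                         replace=False)))
            if not parents or pa != parents[-1] or n_candidates == 1:
                break
        parents.append(pa)
        coeffs.append({j: _draw_coefficient(rng) for j in pa})
        intercepts.append(0.0)
    return TrueNetwork(n=n, changepoints=cps, parents=parents, coeffs=coeffs,
                       intercepts=intercepts, noise_sd=noise_sd, mode=mode,
                       n_candidates=n_candidates)


def _target_ids(q: int):
    return ["target"] + [f"P{j + 1}" for j in range(q)]


def _fill_target(vals, truth, rng, cols):
    """Compute the target row from the autoregressive model; cols selects replicates."""
    n = truth.n
    sd = truth.noise_sd
    vals[0, 0, cols] = _draw_signal(rng, size=len(cols))
    for t in range(2, n + 1):
        h = truth.phase_of(t)
        x = np.full(len(cols), truth.intercepts[h])
        for j, a in truth.coeffs[h].items():
            x += a * vals[1 + j, t - 2, cols]
        if sd > 0:
            x += rng.normal(0.0, sd, size=len(cols))
        vals[0, t - 1, cols] = x


def simulate_wt(structure: TrueNetwork, replicates: int = 8,
                rng=None) -> ExpressionDataset:
    """Wild-type design: parent values i.i.d. on the two-interval set per
    (time, replicate); the target follows the autoregressive model with
    N(0, noise_sd^2) noise."""
    if structure.mode != "WT":
        raise ValueError("structure.mode must be 'WT'")
    rng = np.random.default_rng() if rng is None else rng
    q, n = structure.n_candidates, structure.n
    vals = np.empty((1 + q, n, replicates))
    vals[1:] = _draw_signal(rng, size=(q, n, replicates))
    _fill_target(vals, structure, rng, np.arange(replicates))
    return ExpressionDataset(gene_ids=_target_ids(q), values=vals)


def simulate_ko(structure: TrueNetwork, replicates: int = 4,
                rng=None) -> ExpressionDataset:
    """Knock-out design: each replicate holds one block per genetic context
    (WT plus one deletion strain per candidate regulator); the deleted
    regulator's expression is zero throughout its block."""
    if structure.mode != "KO":
        raise ValueError("structure.mode must be 'KO'")
    rng = np.random.default_rng() if rng is None else rng
    q, n = structure.n_candidates, structure.n
    n_blocks = q + 1                       # WT + one deletion per regulator
    m = replicates * n_blocks
    vals = np.empty((1 + q, n, m))
    strains = []
    ids = _target_ids(q)
    for l in range(replicates):
        for blk in range(n_blocks):
            col = l * n_blocks + blk
            vals[1:, :, col] = _draw_signal(rng, size=(q, n))
            if blk > 0:
                vals[blk, :, col] = 0.0    # deleted regulator (gene row blk)
                strains.append(ids[blk])
            else:
                strains.append("WT")
    _fill_target(vals, structure, rng, np.arange(m))
    return ExpressionDataset(gene_ids=ids, values=vals, strains=strains)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def evaluate_changepoints(truth, selected, tolerance: int = 0):
    """(sensitivity %, PPV %) of changepoint recovery; exact integer match by
    default (``tolerance`` enables one-to-one matching within +/- tolerance).
    Undefined rates (no truth / no predictions) are returned as None.
    """
    true_pos = sorted(truth.changepoints if isinstance(truth, TrueNetwork) else truth)
    inf_pos = sorted(selected.positions if isinstance(selected, SelectedNetwork)
                     else selected)
    if tolerance == 0:
        tp = len(set(true_pos) & set(inf_pos))
    else:
        used = [False] * len(inf_pos)
        tp = 0
        for p in true_pos:
            for idx, pp in enumerate(inf_pos):
                if not used[idx] and abs(pp - p) <= tolerance:
                    used[idx] = True
                    tp += 1
                    break
    sens = 100.0 * tp / len(true_pos) if true_pos else None
    ppv = 100.0 * tp / len(inf_pos) if inf_pos else None
    return sens, ppv


def evaluate_edges(truth: TrueNetwork, selected: SelectedNetwork):
    """(sensitivity %, PPV %) over (parent, phase) edges, defined only when the
    changepoint segmentation was recovered exactly; otherwise (None, None)."""
    if tuple(sorted(selected.positions)) != tuple(truth.changepoints):
        return None, None
    true_edges = {(h, j) for h, pa in enumerate(truth.parents) for j in pa}
    sel_edges = {(h, j) for h, ph in enumerate(selected.phases) for j in ph.parents}
    tp = len(true_edges & sel_edges)
    sens = 100.0 * tp / len(true_edges) if true_edges else None
    ppv = 100.0 * tp / len(sel_edges) if sel_edges else None
    return sens, ppv


# ---------------------------------------------------------------------------
# Benchmark
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BenchmarkCondition:
    """One cell of the simulation grid."""

    mode: str = "WT"
    noise_sd: float = 0.5
    phase_size: int = 4
    n_candidates: int = 5
    replicates: int | None = None        # defaults: 8 (WT) / 4 (KO)
    n: int = 12
    max_edges: int = 5

    def effective_replicates(self) -> int:
        if self.replicates is not None:
            return self.replicates
        return 8 if self.mode == "WT" else 4


@dataclass
class BenchmarkResult:
    """Aggregated recovery rates per condition (percent scale)."""

    table: pd.DataFrame
    n_series: int
    iterations: int
    seed: int | None

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def run_single_series(condition: BenchmarkCondition, seed: int,
                      iterations: int = 15000, hyper: Hyperparameters | None = None,
                      burn_in: float = 0.25):
    """Simulate one target, run inference and selection, return raw counts.

    Returns a dict with changepoint TP/FP/FN, whether segmentation was exact,
    and — if it was — edge TP/FP/FN.
    """
    rng = np.random.default_rng(seed)
    truth = simulate_structure(rng, n=condition.n, n_candidates=condition.n_candidates,
                               phase_size=condition.phase_size,
                               max_edges=condition.max_edges, mode=condition.mode,
                               noise_sd=condition.noise_sd)
    reps = condition.effective_replicates()
    data = (simulate_wt(truth, replicates=reps, rng=rng) if condition.mode == "WT"
            else simulate_ko(truth, replicates=reps, rng=rng))
    candidates = data.gene_ids[1:]
    sub_seed = int(rng.integers(2 ** 31))
    trace = run_sampler(data, "target", candidates, iterations=iterations,
                        seed=sub_seed, hyper=hyper, burn_in=burn_in, log_every=0)
    selected = select_network(trace, hyper=hyper, prior_seed=sub_seed)

    true_cp = set(truth.changepoints)
    inf_cp = set(selected.positions)
    out = {
        "cp_tp": len(true_cp & inf_cp),
        "cp_fp": len(inf_cp - true_cp),
        "cp_fn": len(true_cp - inf_cp),
        "segmented": tuple(sorted(inf_cp)) == tuple(truth.changepoints),
        "edge_tp": 0, "edge_fp": 0, "edge_fn": 0,
    }
    if out["segmented"]:
        true_edges = {(h, j) for h, pa in enumerate(truth.parents) for j in pa}
        sel_edges = {(h, j) for h, ph in enumerate(selected.phases)
                     for j in ph.parents}
        out["edge_tp"] = len(true_edges & sel_edges)
        out["edge_fp"] = len(sel_edges - true_edges)
        out["edge_fn"] = len(true_edges - sel_edges)
    return out


def _rate(num: int, den: int):
    return 100.0 * num / den if den else None


def run_benchmark(conditions, n_series: int = 200, seed: int | None = None,
                  iterations: int = 15000, hyper: Hyperparameters | None = None,
                  burn_in: float = 0.25) -> BenchmarkResult:
    """Run the recovery benchmark over a grid of conditions.

    For each condition ``n_series`` independent target genes are simulated,
    inferred and selected; true/false positive counts are pooled over the
    series before forming rates.  Fully reproducible given ``seed``.
    """
    rows = []
    master = np.random.default_rng(seed)
    for cond in conditions:
        seeds = master.integers(2 ** 31, size=n_series)
        tallies = {k: 0 for k in ("cp_tp", "cp_fp", "cp_fn",
                                  "edge_tp", "edge_fp", "edge_fn")}
        n_seg = 0
        t0 = time.time()
        for s in seeds:
            res = run_single_series(cond, int(s), iterations=iterations,
                                    hyper=hyper, burn_in=burn_in)
            for key in tallies:
                tallies[key] += res[key]
            n_seg += res["segmented"]
        rows.append({
            "mode": cond.mode, "noise_sd": cond.noise_sd,
            "phase_size": cond.phase_size, "n_candidates": cond.n_candidates,
            "replicates": cond.effective_replicates(), "n_series": n_series,
            "n_segmented": n_seg,
            "cp_sensitivity": _rate(tallies["cp_tp"],
                                    tallies["cp_tp"] + tallies["cp_fn"]),
            "cp_ppv": _rate(tallies["cp_tp"], tallies["cp_tp"] + tallies["cp_fp"]),
            "edge_sensitivity": _rate(tallies["edge_tp"],
                                      tallies["edge_tp"] + tallies["edge_fn"]),
            "edge_ppv": _rate(tallies["edge_tp"],
                              tallies["edge_tp"] + tallies["edge_fp"]),
        })
        logger.info("condition %s: %d series in %.1fs", cond, n_series,
                    time.time() - t0)
    return BenchmarkResult(table=pd.DataFrame(rows), n_series=n_series,
                           iterations=iterations, seed=seed)
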