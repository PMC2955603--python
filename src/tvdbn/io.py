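"""Tab-delimited expression matrices, candidate pre-selection and result tables.

Expression matrix dialect: first column holds gene identifiers; every other
header cell is ``time:replicate`` or ``time:replicate:strain`` (1-based
integers; the strain field marks knock-out designs, where each replicate
comprises one block per genetic context).  Cells are floats; empty cells or
``NA`` are missing values.
"""

from __future__ import annotations

import json
import math
import warnings

import numpy as np

from .model import ExpressionDataset
from .sampler import SamplerTrace, TraceRecord
from .selection import SelectedNetwork, SelectedPhase, support_label

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "apply_ko_encoding",
    "preselect_parents",
    "write_results",
    "read_results",
    "save_trace",
    "load_trace",
    "write_dot",
]

MISSING_TOKENS = {"", "NA", "NaN", "nan"}
MAX_MISSING_FRACTION = 0.2


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def _parse_header_cell(cell: str, col: int):
    parts = cell.strip().split(":")
    if len(parts) not in (2, 3):
        raise ValueError(f"header column {col}: expected 'time:replicate[:strain]', "
                         f"got {cell!r}")
    try:
        t, r = int(parts[0]), int(parts[1])
    except ValueError:
        raise ValueError(f"header column {col}: non-integer time/replicate in "
                         f"{cell!r}") from None
    strain = parts[2] if len(parts) == 3 else None
    if t < 1 or r < 1:
        raise ValueError(f"header column {col}: time and replicate are 1-based")
    return t, r, strain


def read_expression_matrix(path, drop_missing_genes: bool = True) -> ExpressionDataset:
    """Read a tab-delimited expression matrix.

    Genes with more than 20% missing cells are dropped with a warning (set
    ``drop_missing_genes=False`` to keep them).  Raises on ragged rows,
    duplicate gene ids and malformed headers, naming the offending line.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    ncol = len(header)
    if ncol < 2:
        raise ValueError(f"{path}: line 1: header needs a gene column plus data columns")
    cols = [_parse_header_cell(c, i + 1) for i, c in enumerate(header[1:])]

    times = sorted({t for t, _, _ in cols})
    if times != list(range(1, len(times) + 1)):
        raise ValueError(f"{path}: time-points must cover 1..n; got {times}")
    n = len(times)
    rep_keys = []                       # distinct (replicate, strain) in first-seen order
    for _, r, s in cols:
        if (r, s) not in rep_keys:
            rep_keys.append((r, s))
    m = len(rep_keys)
    seen = set()
    for t, r, s in cols:
        if (t, r, s) in seen:
            raise ValueError(f"{path}: duplicate column for time {t}, replicate {r}"
                             + (f", strain {s}" if s else ""))
        seen.add((t, r, s))
    if len(cols) != n * m:
        raise ValueError(f"{path}: incomplete design: {len(cols)} columns for "
                         f"{n} time-points x {m} replicate blocks")

    gene_ids, rows, masks = [], [], []
    for ln_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != ncol:
            raise ValueError(f"{path}: line {ln_no}: expected {ncol} fields, "
                             f"got {len(fields)}")
        gene = fields[0].strip()
        if gene in gene_ids:
            raise ValueError(f"{path}: line {ln_no}: duplicate gene id {gene!r}")
        vals = np.zeros((n, m))
        mask = np.zeros((n, m), dtype=bool)
        for (t, r, s), cell in zip(cols, fields[1:]):
            j = rep_keys.index((r, s))
            if cell.strip() in MISSING_TOKENS:
                mask[t - 1, j] = True
            else:
                try:
                    vals[t - 1, j] = float(cell)
                except ValueError:
                    raise ValueError(f"{path}: line {ln_no}: bad value {cell!r}") from None
        gene_ids.append(gene)
        rows.append(vals)
        masks.append(mask)

    values = np.stack(rows)
    missing = np.stack(masks)
    if drop_missing_genes:
        frac = missing.reshape(len(gene_ids), -1).mean(axis=1)
        keep = frac <= MAX_MISSING_FRACTION
        for g, f in zip(gene_ids, frac):
            if f > MAX_MISSING_FRACTION:
                warnings.warn(f"gene {g!r} dropped: {100 * f:.0f}% missing values",
                              UserWarning, stacklevel=2)
        gene_ids = [g for g, k in zip(gene_ids, keep) if k]
        values, missing = values[keep], missing[keep]
    strains = [s if s is not None else "WT" for _, s in rep_keys] \
        if any(s is not None for _, s in rep_keys) else None
    return ExpressionDataset(gene_ids=gene_ids, values=values,
                             missing_mask=missing, strains=strains)


def write_expression_matrix(data: ExpressionDataset, path) -> None:
    """Inverse of :func:`read_expression_matrix` (lossless for valid data)."""
    n, m = data.n, data.m
    with open(path, "w") as fh:
        cells = []
        for t in range(1, n + 1):
            for j in range(m):
                cell = f"{t}:{j + 1}"
                if data.strains is not None:
                    cell += f":{data.strains[j]}"
                cells.append(cell)
        fh.write("gene\t" + "\t".join(cells) + "\n")
        for i, g in enumerate(data.gene_ids):
            row = []
            for t in range(n):
                for j in range(m):
                    row.append("NA" if data.missing_mask[i, t, j]
                               else repr(float(data.values[i, t, j])))
            fh.write(str(g) + "\t" + "\t".join(row) + "\n")


def apply_ko_encoding(data: ExpressionDataset) -> ExpressionDataset:
    """Zero a regulator's expression inside its own deletion block.

    Strain labels equal to a gene id mark that gene's deletion strain; its
    measured values there are replaced by the functional-status encoding 0,
    so its covariate (and hence any regression on it) carries no signal in
    the context where it is absent.
    """
    if data.strains is None:
        raise ValueError("dataset has no strain labels")
    values = data.values.copy()
    mask = data.missing_mask.copy()
    for j, strain in enumerate(data.strains):
        if strain in data.gene_ids:
            gi = data.gene_index(strain)
            values[gi, :, j] = 0.0
            mask[gi, :, j] = False
    return ExpressionDataset(gene_ids=list(data.gene_ids), values=values,
                             missing_mask=mask, strains=list(data.strains))


# ---------------------------------------------------------------------------
# Candidate pre-selection
# ---------------------------------------------------------------------------

def _profile(data: ExpressionDataset, gene) -> np.ndarray:
    i = data.gene_index(gene)
    vals = np.where(data.missing_mask[i], np.nan, data.values[i])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(vals, axis=1)


def _window_correlation(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def preselect_parents(data: ExpressionDataset, target, candidates,
                      window: int = 10, top: int = 10, lag: int = 0):
    """Rank candidate parents by sliding-window profile correlation.

    A candidate's score is the maximum over all ``window``-long stretches of
    |Pearson r| between its (replicate-averaged) profile and the target's.
    With ``lag=1`` the candidate's profile is shifted one step earlier, the
    alignment the lag-1 regression model actually uses.  Returns the ``top``
    highest-scoring candidates, best first.
    """
    n = data.n
    if n < window:
        raise ValueError(f"need at least window={window} time-points (have {n})")
    ty = _profile(data, target)
    scored = []
    for cand in candidates:
        cx = _profile(data, cand)
        best = 0.0
        seen_valid = False
        for start in range(0, n - window + 1):
            sl = slice(start, start + window)
            if lag == 0:
                r = _window_correlation(cx[sl], ty[sl])
            else:
                if start + window + lag > n:
                    continue
                r = _window_correlation(cx[sl], ty[start + lag:start + window + lag])
            if not math.isnan(r):
                seen_valid = True
                best = max(best, abs(r))
        if not seen_valid:
            warnings.warn(f"candidate {cand!r}: constant profile in every window; "
                          "scored 0", UserWarning, stacklevel=2)
        scored.append((cand, best))
    scored.sort(key=lambda cs: -cs[1])
    return [c for c, _ in scored[:top]]


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def _fmt_bf(bf: float) -> str:
    return "inf" if math.isinf(bf) else f"{bf:.6g}"


def write_results(networks, prefix, dot: bool = False) -> None:
    """Write selection results as TSV tables (plus an optional DOT graph).

    ``<prefix>.changepoints.tsv`` — gene, position, BF, support label;
    ``<prefix>.edges.tsv`` — target, parent, phase bounds, BF, coefficient
    sign, support label; ``<prefix>.summary.tsv`` — one line per gene with its
    changepoint count and total parent count (genes with neither appear here
    only).
    """
    if isinstance(networks, SelectedNetwork):
        networks = [networks]
    with open(f"{prefix}.changepoints.tsv", "w") as fh:
        fh.write("gene\tposition\tbf\tsupport\n")
        for net in networks:
            for p in net.positions:
                bf = net.report.position_bf[p] if net.report else math.inf
                fh.write(f"{net.target}\t{p}\t{_fmt_bf(bf)}\t{support_label(bf)}\n")
    with open(f"{prefix}.edges.tsv", "w") as fh:
        fh.write("target\tparent\tphase_start\tphase_end\tbf\tsign\tsupport\n")
        for net in networks:
            for phase in net.phases:
                for j in phase.parents:
                    bf = phase.parent_bf.get(j, math.inf)
                    coef = phase.coefficients.get(j)
                    sign = "" if coef is None else ("+" if coef > 0 else "-")
                    fh.write(f"{net.target}\t{net.candidates[j]}\t{phase.start}\t"
                             f"{phase.end}\t{_fmt_bf(bf)}\t{sign}\t{support_label(bf)}\n")
    with open(f"{prefix}.summary.tsv", "w") as fh:
        fh.write("gene\tk\tlast_bound\tn_parents\tcandidates\n")
        for net in networks:
            n_par = sum(len(ph.parents) for ph in net.phases)
            last = net.phases[-1].end if net.phases else 0
            fh.write(f"{net.target}\t{net.k}\t{last}\t{n_par}\t"
                     + ",".join(str(c) for c in net.candidates) + "\n")
    if dot:
        write_dot(networks, f"{prefix}.dot")


def read_results(prefix) -> list:
    """Re-read result tables into SelectedNetwork objects (lossless for the
    selected structure and Bayes factors of selected items)."""
    nets, last_bounds = {}, {}
    with open(f"{prefix}.summary.tsv") as fh:
        next(fh)
        for line in fh:
            gene, k, last, _, cands = line.rstrip("\n").split("\t")
            nets[gene] = SelectedNetwork(target=gene, k=int(k), positions=(),
                                         phases=[], candidates=cands.split(","))
            last_bounds[gene] = int(last)
    positions = {g: [] for g in nets}
    with open(f"{prefix}.changepoints.tsv") as fh:
        next(fh)
        for line in fh:
            gene, p, bf, _ = line.rstrip("\n").split("\t")
            positions[gene].append(int(p))
    edges = {g: {} for g in nets}
    with open(f"{prefix}.edges.tsv") as fh:
        next(fh)
        for line in fh:
            gene, parent, a, b, bf, sign, _ = line.rstrip("\n").split("\t")
            edges[gene].setdefault((int(a), int(b)), []).append(
                (parent, float(bf)))
    out = []
    for gene, net in nets.items():
        net.positions = tuple(sorted(positions[gene]))
        last = last_bounds[gene]
        bounds = (2, *net.positions, last) if last else (2,)
        for a, b in zip(bounds, bounds[1:]):
            plist = edges[gene].get((a, b), [])
            idx = [net.candidates.index(p) for p, _ in plist]
            net.phases.append(SelectedPhase(
                start=a, end=b, parents=idx,
                parent_bf={i: bf for i, (_, bf) in zip(idx, plist)}))
        out.append(net)
    return out


def write_dot(networks, path) -> None:
    """Export the selected time-varying network as a Graphviz DOT file, one
    edge per (parent, phase), colour-coded by phase."""
    palette = ["#1b9e77", "#d95f02", "#7570b3", "#e7298a", "#66a61e",
               "#e6ab02", "#a6761d", "#666666"]
    with open(path, "w") as fh:
        fh.write("digraph time_varying_network {\n")
        for net in networks:
            for h, phase in enumerate(net.phases):
                color = palette[h % len(palette)]
                for j in phase.parents:
                    fh.write(f'  "{net.candidates[j]}" -> "{net.target}" '
                             f'[label="[{phase.start},{phase.end})" color="{color}"];\n')
        fh.write("}\n")


# ---------------------------------------------------------------------------
# Trace persistence
# ---------------------------------------------------------------------------

def save_trace(trace: SamplerTrace, path) -> None:
    """Serialize a sampler trace to JSON lines (header record first)."""
    with open(path, "w") as fh:
        header = {"burn_in": trace.burn_in, "seed": trace.seed, "n": trace.n,
                  "target": trace.target,
                  "candidates": [str(c) for c in trace.candidates]}
        fh.write(json.dumps(header) + "\n")
        for rec in trace.records:
            fh.write(json.dumps([rec.k, list(rec.xi),
                                 [sorted(p) for p in rec.parents],
                                 rec.move, int(rec.accepted)]) + "\n")


def load_trace(path) -> SamplerTrace:
    with open(path) as fh:
        header = json.loads(fh.readline())
        records = []
        for line in fh:
            k, xi, parents, move, acc = json.loads(line)
            records.append(TraceRecord(k=k, xi=tuple(xi),
                                       parents=tuple(frozenset(p) for p in parents),
                                       move=move, accepted=bool(acc)))
    return SamplerTrace(records=records, burn_in=header["burn_in"],
                        seed=header["seed"], n=header["n"],
                        target=header["target"], candidates=header["candidates"])
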