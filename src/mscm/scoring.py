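"""Evidence scores and their combination.

Three per-species channels support a gene's membership in a bicluster:

* expression — the decrease in the bicluster's residual when the gene is
  included.  The residual is the mean-absolute deviation from an additive
  gene + condition model, normalized by the submatrix value range; lower
  means tighter co-expression.
* motif — the gene's mean best-hit log p-value over the bicluster's
  discovered motifs (negated, so larger is stronger).
* network — the number of association-network edges between the gene and
  the current members.

Each raw channel value is standardized against an empirical null built
from seeded random gene draws on the same dataset, which makes the
channels commensurable; the single-species membership score is the
weighted sum of the three z-scores, and the two-species joint score of an
ortholog pair combines the two members' scores (sum by default, min as a
conservative option).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from mscm.model import Motif, OrthologPair, SpeciesDataset
from mscm.motifs import PwmScanner

RESIDUAL_RANGE_FLOOR = 1e-12
COHESION_CAP = 300.0


@dataclass
class ScoreWeights:
    """Channel weights plus the activation thresholds of the optimizer
    objective.

    ``gene_penalty`` / ``cond_penalty`` are subtracted from each member
    gene's / condition's standardized score in the bicluster total: a
    member must be supported beyond roughly the upper tail of the chance
    distribution to contribute positively, which keeps biclusters from
    accreting chance-level members during annealing.
    """

    w_expr: float = 1.0
    w_motif: float = 0.5
    w_net: float = 0.5
    gene_penalty: float = 2.0
    cond_penalty: float = 0.5

    def __post_init__(self) -> None:
        if self.w_expr < 0 or self.w_motif < 0 or self.w_net < 0:
            raise ValueError("weights must be non-negative")
        if self.w_expr + self.w_motif + self.w_net <= 0:
            raise ValueError("at least one weight must be positive")


# ---------------------------------------------------------------------------
# raw channel statistics
# ---------------------------------------------------------------------------

def residual_matrix(X: np.ndarray) -> float:
    """Range-normalized mean-absolute residual of a submatrix.

    residual = mean_ij |x_ij - m_i. - m_.j + m_..| / (max - min), over
    non-missing cells; the denominator is floored at 1e-12.  All-missing
    input returns +inf (worst possible).
    """
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return float("inf")
    finite = np.isfinite(X)
    n = int(finite.sum())
    if n == 0:
        return float("inf")
    Xf = np.where(finite, X, 0.0)
    row_n = finite.sum(axis=1)
    col_n = finite.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        row_mean = Xf.sum(axis=1) / row_n
        col_mean = Xf.sum(axis=0) / col_n
    grand = Xf.sum() / n
    dev = np.abs(X - row_mean[:, None] - col_mean[None, :] + grand)
    num = np.where(finite, dev, 0.0).sum() / n
    value_range = float(np.max(np.where(finite, X, -np.inf))
                        - np.min(np.where(finite, X, np.inf)))
    return float(num / max(value_range, RESIDUAL_RANGE_FLOOR))


def expression_residual(expr: pd.DataFrame, genes: Sequence[str],
                        conditions: Sequence[str]) -> float:
    """Residual of the bicluster submatrix ``expr[genes, conditions]``."""
    if len(genes) < 1 or len(conditions) < 1:
        raise ValueError("need at least one gene and one condition")
    sub = expr.loc[list(genes), list(conditions)]
    return residual_matrix(sub.to_numpy())


def _loo_residuals(X: np.ndarray, axis: int) -> np.ndarray:
    """Residual of ``X`` with each slice along ``axis`` left out, in one
    vectorized pass (identical values to deleting the slice and calling
    :func:`residual_matrix`)."""
    X = np.asarray(X, dtype=float)
    if axis == 1:
        X = X.T
    g, c = X.shape
    if g <= 1:
        return np.full(g, np.inf)
    finite = np.isfinite(X)
    Xf = np.where(finite, X, 0.0)
    row_n = finite.sum(axis=1)
    col_n = finite.sum(axis=0)
    row_sum = Xf.sum(axis=1)
    col_sum = Xf.sum(axis=0)
    n_tot, s_tot = row_n.sum(), row_sum.sum()
    n_ex = n_tot - row_n                       # (g,) finite cells left
    with np.errstate(invalid="ignore", divide="ignore"):
        grand_ex = (s_tot - row_sum) / n_ex
        colmean_ex = (col_sum[None, :] - Xf) / (col_n[None, :] - finite)  # (g, c)
        row_mean = row_sum / row_n
    D = X - row_mean[:, None]                  # nan where X is nan
    A = np.abs(D[None, :, :] - colmean_ex[:, None, :] + grand_ex[:, None, None])
    M = np.broadcast_to(finite[None, :, :], A.shape).copy()
    idx = np.arange(g)
    M[idx, idx, :] = False
    num = np.where(M, A, 0.0).sum(axis=(1, 2))
    # value range with each row excluded, from the two extreme rows
    rmax = np.max(np.where(finite, X, -np.inf), axis=1)
    rmin = np.min(np.where(finite, X, np.inf), axis=1)
    max1 = rmax.argmax()
    max2 = np.max(np.delete(rmax, max1)) if g > 1 else -np.inf
    min1 = rmin.argmin()
    min2 = np.min(np.delete(rmin, min1)) if g > 1 else np.inf
    hi = np.where(idx == max1, max2, rmax[max1])
    lo = np.where(idx == min1, min2, rmin[min1])
    den = np.maximum(hi - lo, RESIDUAL_RANGE_FLOOR)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / n_ex / den
    out[n_ex == 0] = np.inf
    return out


def loo_row_residuals(X: np.ndarray) -> np.ndarray:
    """Residual of ``X`` with each row (gene) left out in turn."""
    return _loo_residuals(X, axis=0)


def profile_misfit(X: np.ndarray, member_rows: np.ndarray,
                   cols: np.ndarray, query_rows: np.ndarray) -> np.ndarray:
    """How badly each query gene's profile fits the bicluster.

    For the member submatrix, compute the condition profile (column means
    relative to the grand mean) and the value range; a query gene's
    misfit is the mean absolute deviation of its (row-centered) values
    from that profile, normalized by the member range.  Lower = better
    fit; this is the expression channel's raw statistic (negated).
    """
    Xs = X[np.ix_(member_rows, cols)]
    finite = np.isfinite(Xs)
    n = finite.sum()
    if n == 0:
        return np.full(query_rows.size, np.inf)
    Xf = np.where(finite, Xs, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        col_mean = Xf.sum(axis=0) / finite.sum(axis=0)
    grand = Xf.sum() / n
    profile = np.nan_to_num(col_mean - grand, nan=0.0)
    rng_val = float(np.max(np.where(finite, Xs, -np.inf))
                    - np.min(np.where(finite, Xs, np.inf)))
    denom = max(rng_val, RESIDUAL_RANGE_FLOOR)
    Xq = X[np.ix_(query_rows, cols)]
    qf = np.isfinite(Xq)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(qf, Xq, 0.0).sum(axis=1) / qf.sum(axis=1)
    dev = np.abs(Xq - alpha[:, None] - profile[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(qf, dev, 0.0).sum(axis=1) / qf.sum(axis=1) / denom
    d[qf.sum(axis=1) == 0] = np.inf
    return d


def loo_col_residuals(X: np.ndarray) -> np.ndarray:
    """Residual of ``X`` with each column (condition) left out in turn."""
    return _loo_residuals(X, axis=1)


def network_cohesion_score(network: nx.Graph, genes: Sequence[str]) -> float:
    """-log10 hypergeometric upper-tail probability of the induced edge
    count, capped at 300.

    Universe: the C(N, 2) possible edges over the network's N nodes, of
    which M exist (edge types pooled); draw C(|genes|, 2); observe the
    number of induced edges.  Fewer than 2 genes scores 0.
    """
    gene_set = set(genes)
    if len(gene_set) < 2:
        return 0.0
    N = network.number_of_nodes()
    M = network.number_of_edges()
    if N < 2 or M == 0:
        return 0.0
    present = [g for g in gene_set if g in network]
    k = nx.induced_subgraph(network, present).number_of_edges()
    total = N * (N - 1) // 2
    draws = min(len(gene_set) * (len(gene_set) - 1) // 2, total)
    p = float(stats.hypergeom.sf(k - 1, total, M, draws))
    return float(min(-np.log10(max(p, 10.0 ** (-COHESION_CAP))), COHESION_CAP))


def motif_component_score(motifs: Sequence[Motif], gene: str) -> float:
    """Mean over motifs of the gene's best-hit natural-log p-value;
    a missing promoter/hit contributes 0 (no evidence) for that motif."""
    if not motifs:
        return 0.0
    values = []
    for motif in motifs:
        hit = motif.hits.get(gene)
        values.append(hit.logp if hit is not None else 0.0)
    return float(np.mean(values))


def bicluster_motif_mean(motifs: Sequence[Motif], genes: Sequence[str]) -> float:
    if not genes:
        return 0.0
    return float(np.mean([motif_component_score(motifs, g) for g in genes]))


# ---------------------------------------------------------------------------
# dataset context and empirical nulls
# ---------------------------------------------------------------------------

def _size_grid(limit: int, lo: int) -> np.ndarray:
    """Roughly geometric grid of set sizes from ``lo`` to ``limit``."""
    if limit <= lo:
        return np.array([max(limit, 1)])
    sizes = [lo]
    while sizes[-1] < limit:
        nxt = max(sizes[-1] + 1, int(round(sizes[-1] * 1.5)))
        sizes.append(min(nxt, limit))
    return np.array(sorted(set(sizes)))


class ChannelNulls:
    """Empirical per-channel nulls on a grid of bicluster shapes.

    The distribution of every raw channel statistic depends strongly on
    the member-set and condition-set sizes (small random submatrices have
    far noisier residuals), so the null mean/sd is estimated by seeded
    random draws at each grid shape and interpolated bilinearly in
    between.  Queries are clipped to the grid boundary.
    """

    def __init__(self, X: np.ndarray, A: np.ndarray, seed: int, n_draws: int):
        rng = np.random.default_rng(seed)
        n, c = X.shape
        self.gene_sizes = _size_grid(min(n - 1, 45), 3)
        self.cond_sizes = _size_grid(c, 2)
        G, C = len(self.gene_sizes), len(self.cond_sizes)
        self.expr_mean = np.zeros((G, C)); self.expr_sd = np.ones((G, C))
        self.cond_mean = np.zeros((G, C)); self.cond_sd = np.ones((G, C))
        self.net_mean = np.zeros(G); self.net_sd = np.ones(G)
        self.resid_mean = np.zeros((G, C)); self.resid_sd = np.ones((G, C))
        self.resid_samples: Dict[Tuple[int, int], np.ndarray] = {}
        for gi, k in enumerate(self.gene_sizes):
            net_vals = np.empty(n_draws)
            for ci, kc in enumerate(self.cond_sizes):
                expr_vals = np.empty(n_draws)
                cond_vals = np.empty(n_draws)
                resid_vals = np.empty(n_draws)
                for d in range(n_draws):
                    rows = rng.choice(n, size=min(k + 1, n), replace=False)
                    members, extra = rows[:k], rows[-1]
                    cols = rng.choice(c, size=min(kc + 1, c), replace=False)
                    use_cols = cols[:kc]
                    r0 = residual_matrix(X[np.ix_(members, use_cols)])
                    resid_vals[d] = r0
                    # expression channel: negative profile misfit of a
                    # random gene against a random member set
                    expr_vals[d] = -float(
                        profile_misfit(X, members, use_cols, np.array([extra]))[0]
                    )
                    if kc < c:
                        cond_vals[d] = r0 - residual_matrix(X[np.ix_(members, cols)])
                    else:
                        cond_vals[d] = 0.0
                    if ci == 0:
                        net_vals[d] = float(A[extra, members].sum()) / k
                self.expr_mean[gi, ci], self.expr_sd[gi, ci] = _mean_sd(expr_vals)
                self.cond_mean[gi, ci], self.cond_sd[gi, ci] = _mean_sd(cond_vals)
                self.resid_mean[gi, ci], self.resid_sd[gi, ci] = _mean_sd(resid_vals)
                self.resid_samples[(int(k), int(kc))] = resid_vals
            self.net_mean[gi], self.net_sd[gi] = _mean_sd(net_vals)

    # -- interpolation helpers ------------------------------------------------
    def _axis_weights(self, sizes: np.ndarray, value: float):
        value = float(np.clip(value, sizes[0], sizes[-1]))
        hi = int(np.searchsorted(sizes, value, side="left"))
        if hi == 0:
            return 0, 0, 0.0
        lo = hi - 1
        if sizes[hi] == sizes[lo]:
            return lo, hi, 0.0
        return lo, hi, (value - sizes[lo]) / (sizes[hi] - sizes[lo])

    def _interp2(self, mean: np.ndarray, sd: np.ndarray, k: float, kc: float):
        g0, g1, wg = self._axis_weights(self.gene_sizes, k)
        c0, c1, wc = self._axis_weights(self.cond_sizes, kc)
        def blend(M):
            top = (1 - wc) * M[g0, c0] + wc * M[g0, c1]
            bot = (1 - wc) * M[g1, c0] + wc * M[g1, c1]
            return (1 - wg) * top + wg * bot
        return float(blend(mean)), float(max(blend(sd), 1e-9))

    def expr_stats(self, n_members: int, n_conds: int):
        return self._interp2(self.expr_mean, self.expr_sd, n_members, n_conds)

    def cond_stats(self, n_members: int, n_conds: int):
        return self._interp2(self.cond_mean, self.cond_sd, n_members, n_conds)

    def net_stats(self, n_members: int):
        g0, g1, wg = self._axis_weights(self.gene_sizes, n_members)
        mean = (1 - wg) * self.net_mean[g0] + wg * self.net_mean[g1]
        sd = (1 - wg) * self.net_sd[g0] + wg * self.net_sd[g1]
        return float(mean), float(max(sd, 1e-9))

    def residual_null(self, n_genes: int, n_conds: int) -> np.ndarray:
        """Null residual samples at the grid shape nearest the query."""
        k = int(self.gene_sizes[np.argmin(np.abs(self.gene_sizes - n_genes))])
        kc = int(self.cond_sizes[np.argmin(np.abs(self.cond_sizes - n_conds))])
        return self.resid_samples[(k, kc)]


def _mean_sd(values: np.ndarray) -> Tuple[float, float]:
    return float(np.mean(values)), float(max(np.std(values), 1e-9))


class SpeciesContext:
    """Array view of one dataset plus its channel nulls.

    Built once per dataset; shared by the scorer and the optimizer.
    ``n_draws`` random draws per grid shape parameterize the nulls.
    """

    def __init__(self, dataset: SpeciesDataset, seed: int = 0,
                 n_draws: int = 300):
        self.dataset = dataset
        self.genes: List[str] = list(dataset.expression.index)
        self.gene_index = {g: i for i, g in enumerate(self.genes)}
        self.conditions: List[str] = list(dataset.expression.columns)
        self.cond_index = {c: j for j, c in enumerate(self.conditions)}
        self.X = dataset.expression.to_numpy(dtype=float)
        n = len(self.genes)
        self.A = np.zeros((n, n), dtype=bool)
        for u, v in dataset.network.edges():
            iu, iv = self.gene_index.get(u), self.gene_index.get(v)
            if iu is not None and iv is not None:
                self.A[iu, iv] = self.A[iv, iu] = True
        self.nulls = ChannelNulls(self.X, self.A, seed, n_draws)

    def rows(self, genes: Sequence[str]) -> np.ndarray:
        return np.array([self.gene_index[g] for g in genes], dtype=int)

    def cols(self, conditions: Sequence[str]) -> np.ndarray:
        return np.array([self.cond_index[c] for c in conditions], dtype=int)


@dataclass
class SpeciesState:
    """The per-species view of one bicluster while it is being scored:
    current members, conditions and the motif evidence vector."""

    ctx: SpeciesContext
    members: List[str]
    conditions: List[str]
    #: per-dataset-gene mean best-hit natural-log p over current motifs
    motif_logp: Optional[np.ndarray] = None
    motif_mean: float = 0.0
    motif_sd: float = 1.0

    def motif_z(self, row: int) -> float:
        if self.motif_logp is None:
            return 0.0
        raw = -self.motif_logp[row]
        return (raw - self.motif_mean) / self.motif_sd

    def motif_z_vector(self, rows: np.ndarray) -> np.ndarray:
        if self.motif_logp is None:
            return np.zeros(rows.size)
        raw = -self.motif_logp[rows]
        return (raw - self.motif_mean) / self.motif_sd


def motif_logp_vector(ctx: SpeciesContext, motifs: Sequence[Motif],
                      step_bits: float = 0.01) -> np.ndarray:
    """Scan every promoter of the dataset with the bicluster's motifs and
    return the per-gene mean best-hit log p (0 where no promoter)."""
    out = np.zeros(len(ctx.genes))
    if not motifs:
        return out
    scanners = [PwmScanner(m.pwm, step_bits=step_bits) for m in motifs]
    from mscm.motifs import encode

    for i, gene in enumerate(ctx.genes):
        seq = ctx.dataset.promoters.get(gene)
        if not seq:
            continue
        enc = encode(seq)
        logps = []
        for sc in scanners:
            res = sc.scan(enc)
            logps.append(res.best.logp if res.best is not None else 0.0)
        out[i] = float(np.mean(logps))
    return out


def attach_motifs(state: SpeciesState, motifs: Sequence[Motif],
                  step_bits: float = 0.01) -> None:
    """Set the state's motif channel from freshly discovered motifs,
    standardizing against the whole-dataset distribution."""
    if not motifs:
        state.motif_logp = None
        return
    vec = motif_logp_vector(state.ctx, motifs, step_bits=step_bits)
    state.motif_logp = vec
    raw = -vec
    state.motif_mean = float(raw.mean())
    state.motif_sd = float(max(raw.std(), 1e-9))


# ---------------------------------------------------------------------------
# membership scores
# ---------------------------------------------------------------------------

def member_gene_scores(state: SpeciesState, weights: ScoreWeights) -> np.ndarray:
    """Membership score of every current member (vectorized)."""
    ctx = state.ctx
    rows = ctx.rows(state.members)
    cols = ctx.cols(state.conditions)
    # a member gene is scored against the null of one gene queried
    # against a member set of the remaining |members| - 1
    raw_expr = -profile_misfit(ctx.X, rows, cols, rows)
    em, es = ctx.nulls.expr_stats(rows.size - 1, cols.size)
    z_expr = (raw_expr - em) / es
    n_other = max(rows.size - 1, 1)
    deg = ctx.A[np.ix_(rows, rows)].sum(axis=1).astype(float) / n_other
    nm, ns = ctx.nulls.net_stats(n_other)
    z_net = (deg - nm) / ns
    z_mot = state.motif_z_vector(rows)
    return weights.w_expr * z_expr + weights.w_net * z_net + weights.w_motif * z_mot


def candidate_gene_score(gene: str, state: SpeciesState, weights: ScoreWeights) -> float:
    """Membership score of a gene not currently in the member set."""
    ctx = state.ctx
    row = ctx.gene_index[gene]
    rows = ctx.rows(state.members)
    cols = ctx.cols(state.conditions)
    raw_expr = -float(profile_misfit(ctx.X, rows, cols, np.array([row]))[0])
    em, es = ctx.nulls.expr_stats(rows.size, cols.size)
    z_expr = (raw_expr - em) / es
    deg = float(ctx.A[row, rows].sum()) / max(rows.size, 1)
    nm, ns = ctx.nulls.net_stats(max(rows.size, 1))
    z_net = (deg - nm) / ns
    z_mot = state.motif_z(row)
    return float(weights.w_expr * z_expr + weights.w_net * z_net + weights.w_motif * z_mot)


def gene_membership_score(gene: str, state: SpeciesState, weights: ScoreWeights) -> float:
    """Single-species membership score of ``gene`` under the current
    bicluster state; larger = stronger membership.

    A gene unknown to every channel scores 0 with a warning.
    """
    ctx = state.ctx
    if gene not in ctx.gene_index:
        known = gene in ctx.dataset.promoters or gene in ctx.dataset.network
        if not known:
            warnings.warn(f"gene {gene!r} unknown to every evidence channel; score 0")
            return 0.0
        # expression is the indexing backbone; a gene without expression
        # cannot be scored against the member submatrix
        warnings.warn(f"gene {gene!r} has no expression profile; score 0")
        return 0.0
    if gene in state.members:
        idx = state.members.index(gene)
        return float(member_gene_scores(state, weights)[idx])
    return candidate_gene_score(gene, state, weights)


def member_condition_scores(state: SpeciesState, weights: ScoreWeights) -> np.ndarray:
    """Condition membership score: the standardized decrease in the
    species' residual when the condition is included (expression only)."""
    ctx = state.ctx
    rows = ctx.rows(state.members)
    cols = ctx.cols(state.conditions)
    Xs = ctx.X[np.ix_(rows, cols)]
    base = residual_matrix(Xs)
    loo = loo_col_residuals(Xs)
    raw = loo - base
    cm, cs = ctx.nulls.cond_stats(rows.size, cols.size - 1)
    z = (raw - cm) / cs
    return weights.w_expr * z


def candidate_condition_score(cond: str, state: SpeciesState, weights: ScoreWeights) -> float:
    ctx = state.ctx
    rows = ctx.rows(state.members)
    cols = ctx.cols(state.conditions)
    j = ctx.cond_index[cond]
    r0 = residual_matrix(ctx.X[np.ix_(rows, cols)])
    r1 = residual_matrix(ctx.X[np.ix_(rows, np.append(cols, j))])
    cm, cs = ctx.nulls.cond_stats(rows.size, cols.size)
    z = ((r0 - r1) - cm) / cs
    return float(weights.w_expr * z)


def side_total_score(state: SpeciesState, weights: ScoreWeights) -> float:
    """Total single-species score: member gene terms plus condition
    terms, each offset by its activation threshold.

    Condition terms are Stouffer-normalized (divided by sqrt of the
    condition count): they are strongly mutually correlated once a
    coherent gene set is in place, so summing them raw would let the
    condition subset dominate the gene evidence.
    """
    if not state.members or not state.conditions:
        return float("-inf")
    gene_part = (member_gene_scores(state, weights) - weights.gene_penalty).sum()
    cond_terms = member_condition_scores(state, weights) - weights.cond_penalty
    cond_part = cond_terms.sum() / math.sqrt(len(state.conditions))
    return float(gene_part + cond_part)


def multispecies_pair_score(pair: OrthologPair, state_a: SpeciesState,
                            state_b: SpeciesState, weights: ScoreWeights,
                            rule: str = "sum") -> float:
    """Joint two-species membership score of an ortholog pair.

    ``rule`` is the combination contract: "sum" (default) or "min"
    (conservative).
    """
    sa = gene_membership_score(pair.gene_a, state_a, weights)
    sb = gene_membership_score(pair.gene_b, state_b, weights)
    if rule == "sum":
        return sa + sb
    if rule == "min":
        return min(sa, sb)
    raise ValueError(f"unknown combination rule {rule!r}")


def empirical_residual_p(ctx: SpeciesContext, observed: float,
                         n_genes: int = 10, n_conds: int = 10) -> float:
    """One-sided empirical p of an observed residual against random
    draws at the nearest null grid shape (smaller residual = better)."""
    samples = ctx.nulls.residual_null(n_genes, n_conds)
    if samples.size == 0:
        return 1.0
    return float((1 + np.sum(samples <= observed)) / (samples.size + 1))
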