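"""Community structure of the signed, weighted, directed synapse matrix.

Quality function. For a directed weighted layer with weights ``w_ij`` and
total weight ``m``, modularity at resolution ``gamma_res`` is

    Q = (1/m) * sum_ij [ w_ij - gamma_res * s_out_i * s_in_j / m ] * delta(sigma_i, sigma_j)

(the directed configuration null). Signed matrices are split into a
positive and a negative layer and combined as

    Q = Q+ - (m- / (m+ + m-)) * Q-

so that dense positive blocks raise quality while dense negative blocks
lower it (the standard signed extension).

Maximisation uses a Louvain-style greedy label-moving heuristic with node
aggregation, run many times from random orders. Robust partitions come from
consensus clustering: an association (co-assignment) matrix over the
ensemble is thresholded by the maximum of a column-permuted null
association matrix and re-clustered until the ensemble is unanimous.

Statistical significance of modular structure is assessed against null
matrices produced by degree-preserving rewiring that exactly conserves
every node's in-degree and out-degree (weights travel with their source
edge).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as _stats


class ConsensusError(RuntimeError):
    pass


@dataclass
class ModularityParams:
    """Knobs for partition ensembles and consensus."""

    gamma_res: float = 1.0
    n_runs: int = 100
    n_null: int = 10            # rewired nulls per significance comparison
    seed: int = 0
    max_consensus_iter: int = 50
    sweep_runs: int = 5         # maximizer restarts per gamma during sweeps

    def __post_init__(self) -> None:
        if self.gamma_res <= 0:
            raise ValueError("gamma_res must be > 0")
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")


@dataclass
class CommunityPartition:
    """Node -> module labels (contiguous from 0) with quality Q."""

    labels: np.ndarray
    q: float
    gamma_res: float

    @property
    def n_modules(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels)


def _split_layers(W) -> tuple[np.ndarray, np.ndarray]:
    A = W.toarray() if sp.issparse(W) else np.asarray(W, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrix must be square")
    return np.where(A > 0, A, 0.0), np.where(A < 0, -A, 0.0)


def canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel modules contiguously from 0 in order of first appearance."""
    labels = np.asarray(labels)
    _, first = np.unique(labels, return_index=True)
    order = labels[np.sort(first)]
    lut = {int(l): i for i, l in enumerate(order)}
    return np.array([lut[int(l)] for l in labels], dtype=np.int64)


def _layer_q(A: np.ndarray, labels: np.ndarray, gamma: float) -> float:
    m = A.sum()
    if m == 0:
        return 0.0
    k = int(labels.max()) + 1
    ind = np.zeros((A.shape[0], k))
    ind[np.arange(A.shape[0]), labels] = 1.0
    within = float(np.einsum("ic,ij,jc->", ind, A, ind))
    s_out = A.sum(axis=1) @ ind
    s_in = A.sum(axis=0) @ ind
    return (within - gamma * float(s_out @ s_in) / m) / m


def modularity_q(W, labels: np.ndarray, gamma_res: float = 1.0) -> float:
    """Signed, weighted, directed modularity of a partition."""
    Ap, An = _split_layers(W)
    labels = np.asarray(labels, dtype=np.int64)
    if labels.shape[0] != Ap.shape[0]:
        raise ValueError("partition does not cover all nodes")
    labels = canonical_labels(labels)
    mp, mn = Ap.sum(), An.sum()
    if mp + mn == 0:
        return 0.0
    qp = _layer_q(Ap, labels, gamma_res)
    qn = _layer_q(An, labels, gamma_res)
    return qp - (mn / (mp + mn)) * qn


# -- Louvain-style maximizer ----------------------------------------------

def _local_move(Ap: np.ndarray, An: np.ndarray, gamma: float,
                rng: np.random.Generator, labels: np.ndarray) -> bool:
    """One round of greedy label moves; returns True if anything moved."""
    n = Ap.shape[0]
    mp, mn = Ap.sum(), An.sum()
    coef_n = mn / (mp + mn) if (mp + mn) > 0 else 0.0
    sout_p, sin_p = Ap.sum(axis=1), Ap.sum(axis=0)
    sout_n, sin_n = An.sum(axis=1), An.sum(axis=0)
    k = int(labels.max()) + 1
    Sout_p = np.bincount(labels, weights=sout_p, minlength=k)
    Sin_p = np.bincount(labels, weights=sin_p, minlength=k)
    Sout_n = np.bincount(labels, weights=sout_n, minlength=k)
    Sin_n = np.bincount(labels, weights=sin_n, minlength=k)

    improved = False
    for _pass in range(20):
        moved = 0
        for i in rng.permutation(n):
            ci = labels[i]
            Sout_p[ci] -= sout_p[i]
            Sin_p[ci] -= sin_p[i]
            Sout_n[ci] -= sout_n[i]
            Sin_n[ci] -= sin_n[i]

            row_p = Ap[i, :] + Ap[:, i]
            row_n = An[i, :] + An[:, i]
            lp = np.bincount(labels, weights=row_p, minlength=k)
            ln = np.bincount(labels, weights=row_n, minlength=k)
            self_p, self_n = row_p[i], row_n[i]
            lp[ci] -= self_p  # exclude the node's own contribution
            ln[ci] -= self_n

            gain = np.zeros(k)
            if mp > 0:
                gain += lp / mp - gamma * (sout_p[i] * Sin_p
                                           + sin_p[i] * Sout_p) / mp ** 2
            if mn > 0:
                gain -= coef_n * (ln / mn - gamma * (sout_n[i] * Sin_n
                                                     + sin_n[i] * Sout_n) / mn ** 2)
            best = int(np.argmax(gain))
            if gain[best] <= gain[ci] + 1e-12:
                best = ci
            labels[i] = best
            Sout_p[best] += sout_p[i]
            Sin_p[best] += sin_p[i]
            Sout_n[best] += sout_n[i]
            Sin_n[best] += sin_n[i]
            if best != ci:
                moved += 1
        if moved == 0:
            break
        improved = True
    return improved


def _aggregate(A: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    ind = np.zeros((A.shape[0], k))
    ind[np.arange(A.shape[0]), labels] = 1.0
    return ind.T @ A @ ind


def louvain_signed(W, gamma_res: float = 1.0, seed: int = 0) -> CommunityPartition:
    """Greedy multi-level maximisation of signed directed modularity.

    Runs start either from singletons or from a random coarse labelling
    (seed-dependent), aggregate communities level by level, and finish with
    a node-level refinement pass on the original matrix; Q never decreases
    during refinement.
    """
    Ap, An = _split_layers(W)
    n = Ap.shape[0]
    rng = np.random.default_rng(seed)
    inits = [np.arange(n, dtype=np.int64)]
    if 2 < n <= 12:
        # tiny graphs are riddled with local optima: try many random starts
        for _ in range(12):
            k0 = int(rng.integers(2, n + 1))
            inits.append(canonical_labels(rng.integers(0, k0, n)))
    best = None
    for init in inits:
        node_labels = _louvain_once(Ap, An, gamma_res, rng, init)
        q = modularity_q(W, node_labels, gamma_res)
        if best is None or q > best[1] + 1e-15:
            best = (node_labels, q)
    return CommunityPartition(best[0], best[1], gamma_res)


def _louvain_once(Ap, An, gamma_res, rng, init_labels) -> np.ndarray:
    n = Ap.shape[0]
    node_labels = np.arange(n, dtype=np.int64)
    cur_p, cur_n = Ap, An
    level_labels = init_labels.copy()
    first = True
    while True:
        improved = _local_move(cur_p, cur_n, gamma_res, rng, level_labels)
        level_labels = canonical_labels(level_labels)
        node_labels = level_labels[node_labels]
        k = int(level_labels.max()) + 1
        if (not improved and not first) or k == cur_p.shape[0]:
            break
        first = False
        cur_p = _aggregate(cur_p, level_labels, k)
        cur_n = _aggregate(cur_n, level_labels, k)
        level_labels = np.arange(k, dtype=np.int64)
    # flat refinement on the original matrix
    node_labels = canonical_labels(node_labels)
    _local_move(Ap, An, gamma_res, rng, node_labels)
    return canonical_labels(node_labels)


# -- rewired null ----------------------------------------------------------

def rewire_null(W, seed: int = 0, swap_factor: int = 10) -> sp.csr_matrix:
    """Degree-preserving rewiring of a directed (signed, weighted) matrix.

    Performs ``swap_factor * n_edges`` attempted double-edge swaps
    (a->b, c->d) => (a->d, c->b), rejecting swaps that would create
    self-loops or duplicate edges. Every node's in-degree and out-degree
    are exactly preserved; each edge's weight stays with its source, so
    sign consistency by source neuron is preserved too.
    """
    coo = sp.coo_matrix(W)
    src, tgt, wts = coo.row.copy(), coo.col.copy(), coo.data.copy()
    n_edges = src.size
    if n_edges < 2:
        raise ValueError("need at least 2 edges to rewire")
    existing = set(zip(src.tolist(), tgt.tolist()))
    rng = np.random.default_rng(seed)
    n_attempts = swap_factor * n_edges
    pairs = rng.integers(0, n_edges, size=(n_attempts, 2))
    for e1, e2 in pairs:
        if e1 == e2:
            continue
        a, b_ = int(src[e1]), int(tgt[e1])
        c, d_ = int(src[e2]), int(tgt[e2])
        if a == c or b_ == d_ or a == d_ or c == b_:
            continue
        if (a, d_) in existing or (c, b_) in existing:
            continue
        existing.discard((a, b_))
        existing.discard((c, d_))
        existing.add((a, d_))
        existing.add((c, b_))
        tgt[e1], tgt[e2] = d_, b_
    return sp.coo_matrix((wts, (src, tgt)), shape=coo.shape).tocsr()


# -- gamma optimization ----------------------------------------------------

def best_partition(W, gamma_res: float, n_restarts: int, seed: int
                   ) -> CommunityPartition:
    """Best-of-``n_restarts`` greedy maximisation."""
    best = None
    for r in range(n_restarts):
        part = louvain_signed(W, gamma_res, seed=seed + r)
        if best is None or part.q > best.q:
            best = part
    return best


def optimize_gamma(W, sweep, params: ModularityParams | None = None,
                   ) -> tuple[float, pd.DataFrame]:
    """Pick the resolution maximising Q_empirical - Q_null over a sweep.

    Null matrices are generated once by degree-preserving rewiring and
    scored at every resolution. Returns the selected gamma_res and the
    sweep table (gamma_res, q_emp, q_null, q_diff, degenerate flag).
    """
    sweep = np.asarray(list(sweep), dtype=float)
    if sweep.size == 0:
        raise ValueError("gamma sweep must be non-empty")
    params = params or ModularityParams()
    nulls = [rewire_null(W, seed=params.seed + 7919 * (i + 1))
             for i in range(max(1, params.n_null))]
    rows = []
    for g in sweep:
        q_emp = best_partition(W, g, params.sweep_runs, params.seed).q
        q_null = float(np.mean([
            best_partition(Wn, g, params.sweep_runs, params.seed).q
            for Wn in nulls]))
        rows.append((g, q_emp, q_null, q_emp - q_null))
    df = pd.DataFrame(rows, columns=["gamma_res", "q_emp", "q_null", "q_diff"])
    df["degenerate"] = df["q_diff"].max() < 1e-3
    return float(df.loc[df["q_diff"].idxmax(), "gamma_res"]), df


# -- consensus clustering --------------------------------------------------

def _association(ensemble: np.ndarray) -> np.ndarray:
    """Co-assignment frequency matrix from an (n_runs, n_nodes) ensemble."""
    n_runs, n = ensemble.shape
    A = np.zeros((n, n))
    for run in ensemble:
        A += (run[:, None] == run[None, :])
    return A / n_runs


def consensus_communities(W, gamma_res: float,
                          params: ModularityParams | None = None
                          ) -> CommunityPartition:
    """Consensus partition from an ensemble of greedy maximisations.

    The association matrix over ``params.n_runs`` partitions is thresholded
    at the maximum off-diagonal value of a null association matrix built by
    permuting each partition (column of the node x run ensemble) across
    nodes, then re-clustered; the cycle repeats until the ensemble is
    unanimous. Raises :class:`ConsensusError` if it fails to converge.
    """
    params = params or ModularityParams()
    n = W.shape[0]
    rng = np.random.default_rng(params.seed)
    ensemble = np.stack([
        louvain_signed(W, gamma_res, seed=params.seed + i).labels
        for i in range(params.n_runs)])

    for iteration in range(params.max_consensus_iter):
        if all(np.array_equal(ensemble[0], row) for row in ensemble[1:]):
            labels = canonical_labels(ensemble[0])
            return CommunityPartition(labels, modularity_q(W, labels, gamma_res),
                                      gamma_res)
        A = _association(ensemble)
        null_ens = np.stack([rng.permutation(run) for run in ensemble])
        A_null = _association(null_ens)
        np.fill_diagonal(A_null, 0.0)
        thr = A_null.max()
        A_thr = np.where(A > thr, A, 0.0)
        np.fill_diagonal(A_thr, 0.0)
        if A_thr.sum() == 0:  # nothing survives: all-singleton consensus
            labels = np.arange(n, dtype=np.int64)
            return CommunityPartition(labels, modularity_q(W, labels, gamma_res),
                                      gamma_res)
        ensemble = np.stack([
            louvain_signed(A_thr, 1.0, seed=params.seed + 31 * iteration + i).labels
            for i in range(params.n_runs)])
    raise ConsensusError(
        f"consensus failed to converge in {params.max_consensus_iter} iterations")


class ConsensusCommunities:
    """Clusterer-style wrapper: ``fit`` stores ``labels_``, ``q_``."""

    def __init__(self, gamma_res: float = 1.0, n_runs: int = 100, seed: int = 0):
        self.gamma_res = gamma_res
        self.n_runs = n_runs
        self.seed = seed

    def fit(self, W):
        params = ModularityParams(gamma_res=self.gamma_res, n_runs=self.n_runs,
                                  seed=self.seed)
        part = consensus_communities(W, self.gamma_res, params)
        self.labels_ = part.labels
        self.q_ = part.q
        self.partition_ = part
        return self

    def fit_predict(self, W):
        return self.fit(W).labels_

    def get_params(self, deep: bool = True):
        return {"gamma_res": self.gamma_res, "n_runs": self.n_runs,
                "seed": self.seed}

    def set_params(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)
        return self


# -- module composition ----------------------------------------------------

def module_report(partition: CommunityPartition | np.ndarray,
                  meta: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-module size and composition, plus network-level summaries.

    ``meta`` must carry one row per node with ``region`` and ``excitatory``
    columns. Percentages are over module membership; for CA3-CA1 analyses
    pct_ca3 + pct_ca1 = 100.
    """
    labels = partition.labels if isinstance(partition, CommunityPartition) \
        else np.asarray(partition)
    if len(meta) != labels.shape[0]:
        raise ValueError("metadata does not cover all nodes")
    rows = []
    for mod in range(int(labels.max()) + 1):
        m = labels == mod
        size = int(m.sum())
        reg = meta.loc[m, "region"]
        rows.append({
            "module": mod,
            "size": size,
            "pct_ca3": 100.0 * (reg == "CA3").mean(),
            "pct_ca1": 100.0 * (reg == "CA1").mean(),
            "pct_inhibitory": 100.0 * (~meta.loc[m, "excitatory"]).mean(),
        })
    df = pd.DataFrame(rows)
    summary = {
        "n_modules": len(df),
        "size_range": int(df["size"].max() - df["size"].min()),
        "sizes": df["size"].tolist(),
    }
    return df, summary


def composition_regression(table: pd.DataFrame, x: str = "pct_inhibitory",
                           y: str = "pct_ca1") -> dict:
    """OLS of one composition percentage on another across modules."""
    if len(table) < 3:
        raise ValueError("need at least 3 modules for a regression")
    xv = table[x].to_numpy(dtype=float)
    yv = table[y].to_numpy(dtype=float)
    if np.allclose(xv.var(), 0.0):
        raise ValueError(f"degenerate regression: {x} has zero variance")
    res = _stats.linregress(xv, yv)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r2": float(res.rvalue ** 2), "p_value": float(res.pvalue),
            "x": x, "y": y}


# -- dynamic community metrics ---------------------------------------------

def align_partitions(partitions: list[np.ndarray]) -> list[np.ndarray]:
    """Match module labels across timepoints by maximal Jaccard overlap.

    Modules of each timepoint are matched to the previous (aligned)
    timepoint's modules greedily, processing larger modules first;
    unmatched modules receive fresh labels.
    """
    if len(partitions) < 2:
        raise ValueError("need at least 2 timepoints")
    aligned = [canonical_labels(partitions[0])]
    next_label = int(aligned[0].max()) + 1
    for t in range(1, len(partitions)):
        prev = aligned[-1]
        cur = canonical_labels(partitions[t])
        prev_sets = {l: set(np.flatnonzero(prev == l))
                     for l in np.unique(prev)}
        out = np.full_like(cur, -1)
        used = set()
        order = sorted(np.unique(cur),
                       key=lambda l: -int((cur == l).sum()))
        for l in order:
            members = set(np.flatnonzero(cur == l))
            best_j, best_lab = 0.0, None
            for pl, pset in prev_sets.items():
                if pl in used:
                    continue
                j = len(members & pset) / len(members | pset)
                if j > best_j:
                    best_j, best_lab = j, pl
            if best_lab is None:
                best_lab = next_label
                next_label += 1
            else:
                used.add(best_lab)
            out[cur == l] = best_lab
        aligned.append(out)
    return aligned


def flexibility(partitions: list[np.ndarray]) -> np.ndarray:
    """Fraction of consecutive transitions at which a node switches module."""
    aligned = align_partitions(partitions)
    stack = np.stack(aligned)
    changes = stack[1:] != stack[:-1]
    return changes.mean(axis=0)


def promiscuity(partitions: list[np.ndarray]) -> np.ndarray:
    """Fraction of all communities in the sequence a node ever joins."""
    aligned = align_partitions(partitions)
    stack = np.stack(aligned)
    total = len(np.unique(stack))
    return np.array([len(np.unique(stack[:, i])) / total
                     for i in range(stack.shape[1])])


def quintile_profile(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Per-group occupancy of the pooled distribution's quintiles.

    Boundaries come from the pooled values; each group's occupancy
    fractions sum to 1. Returns a table indexed by group with columns
    q1..q5.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.size < 5:
        raise ValueError("need at least 5 nodes for quintiles")
    bounds = np.quantile(values, [0.2, 0.4, 0.6, 0.8])
    bins = np.searchsorted(bounds, values, side="left")
    rows = {}
    for g in np.unique(groups):
        m = groups == g
        occ = np.bincount(bins[m], minlength=5) / m.sum()
        rows[g] = occ
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"q{i}" for i in range(1, 6)])
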