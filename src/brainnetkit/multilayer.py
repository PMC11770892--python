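"""Sliding-window dynamic functional connectivity, multilayer modularity,
and node switching rates.

A subject's regional BOLD series is cut into overlapping windows (length W
TRs, fractional step realized by rounding window onsets to integer
volumes); each window yields a Pearson correlation matrix with negative
entries zeroed, forming the layers of a temporal multilayer network.  A
generalized Louvain optimizer maximizes the multislice modularity

    Q = (1/2mu) sum_{ijs} [A_ijs - gamma k_is k_js / (2 m_s)] delta(g_is, g_js)
      + (1/2mu) 2 omega sum_{is} delta(g_is, g_{i,s+1})

with ordinal (adjacent-layer) interlayer coupling omega and resolution
gamma, where 2mu = sum_s 2 m_s + 2 omega N (L-1).  The switching rate of a
node is the fraction of adjacent-layer transitions at which its module
assignment changes.  Because the Louvain heuristic is stochastic, each
subject is optimized repeatedly with independent visit orders and the
statistics are averaged over repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .stats import TestResult, fdr_bh, welch_t

__all__ = [
    "LayerStack",
    "MultilayerPartition",
    "make_windows",
    "dynamic_fc",
    "multilayer_modularity",
    "louvain_multilayer",
    "switching_rate",
    "run_switching_analysis",
    "group_compare_switching",
    "DEFAULT_OMEGAS",
    "DEFAULT_GAMMAS",
]

DEFAULT_WINDOW_TR = 20
DEFAULT_STEP_TR = 0.95
DEFAULT_OMEGAS = (0.5, 0.75, 1.0)
DEFAULT_GAMMAS = (0.9, 1.0, 1.1)
DEFAULT_N_REPEATS = 50


@dataclass
class LayerStack:
    """Ordered per-window connectivity matrices forming a multilayer network."""

    matrices: np.ndarray  # (L, N, N) symmetric, nonnegative, zero diagonal
    window_starts: np.ndarray | None = None
    window_length: int | None = None
    step: float | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrices, dtype=float)
        if m.ndim != 3 or m.shape[1] != m.shape[2]:
            raise ValueError("matrices must be (L, N, N)")
        if np.any(m < 0):
            raise ValueError("layer weights must be nonnegative")
        if not np.allclose(m, np.transpose(m, (0, 2, 1))):
            raise ValueError("layer matrices must be symmetric")
        if np.any(np.abs(np.diagonal(m, axis1=1, axis2=2)) > 1e-12):
            raise ValueError("layer diagonals must be zero")
        self.matrices = np.ascontiguousarray(m)

    @property
    def n_layers(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.matrices.shape[1]


@dataclass
class MultilayerPartition:
    """Module assignment per (layer, node) with its modularity Q."""

    assignment: np.ndarray  # (L, N) positive integer module ids
    Q: float
    gamma: float
    omega: float

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment)
        if a.ndim != 2 or np.any(a < 1):
            raise ValueError("assignment must be (L, N) with positive module ids")
        self.assignment = a.astype(np.int64)


def make_windows(n_volumes: int, window_length: int, step: float) -> np.ndarray:
    """Window onset indices: round(i*step) while the window fits.

    Fractional steps are realized by rounding onsets to integer volumes
    (half rounds up), e.g. 210 volumes with W=20 and step 0.95 gives 201
    windows.
    """
    if window_length > n_volumes:
        raise ValueError("window longer than the series")
    if step <= 0:
        raise ValueError("step must be > 0")
    starts = []
    i = 0
    while True:
        s = int(np.floor(i * step + 0.5))
        if s + window_length > n_volumes:
            break
        starts.append(s)
        i += 1
    return np.array(starts, dtype=int)


def dynamic_fc(series, window_starts: np.ndarray, window_length: int,
               step: float | None = None) -> LayerStack:
    """Windowed Pearson correlation layers; negatives zeroed, diagonal zero."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 2:
        raise ValueError("series must be 2-D (time x node)")
    n_time, n_nodes = x.shape
    if len(window_starts) == 0 or window_starts[-1] + window_length > n_time:
        raise ValueError("windows do not fit the series")
    layers = np.zeros((len(window_starts), n_nodes, n_nodes))
    for w, s in enumerate(window_starts):
        seg = x[s:s + window_length]
        sd = seg.std(axis=0)
        dead = sd == 0
        if np.any(dead):
            warnings.warn(f"zero-variance node(s) {np.nonzero(dead)[0].tolist()} in window {w}")
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(seg, rowvar=False)
        r[dead, :] = 0.0
        r[:, dead] = 0.0
        np.fill_diagonal(r, 0.0)
        layers[w] = np.clip(r, 0.0, None)
    return LayerStack(layers, window_starts=np.asarray(window_starts),
                      window_length=window_length, step=step)


# ---------------------------------------------------------------------------
# Multislice modularity and generalized Louvain
# ---------------------------------------------------------------------------

def _stack_arrays(stack: LayerStack):
    a = stack.matrices
    k = a.sum(axis=2)
    twom = k.sum(axis=1)
    return a, k, twom


def multilayer_modularity(stack: LayerStack, assignment: np.ndarray,
                          gamma: float, omega: float) -> float:
    """Evaluate the multislice quality Q of a given (L, N) assignment."""
    a, k, twom = _stack_arrays(stack)
    L, N = k.shape
    g = np.asarray(assignment)
    if g.shape != (L, N):
        raise ValueError("assignment must cover all (layer, node) pairs")
    two_mu = twom.sum() + 2.0 * omega * N * max(L - 1, 0)
    if two_mu == 0:
        return 0.0
    total = 0.0
    for s in range(L):
        same = g[s][:, None] == g[s][None, :]
        total += a[s][same].sum()
        if twom[s] > 0:
            # community degree sums; includes the i == j null term as in the
            # single-layer Newman-Girvan form
            ksums = np.bincount(g[s] - g[s].min(), weights=k[s])
            total -= gamma * (ksums**2).sum() / twom[s]
    if L > 1:
        total += 2.0 * omega * np.sum(g[:-1] == g[1:])
    return float(total / two_mu)


@njit(cache=True)
def _louvain_sweep(a, k, twom, labels, order, gamma, omega, scores, seen, touched):
    L, N = k.shape
    n_moves = 0
    for t in range(order.shape[0]):
        idx = order[t]
        s = idx // N
        i = idx % N
        cur = labels[s, i]
        coef = gamma * k[s, i] / twom[s] if twom[s] > 0 else 0.0
        nt = 0
        for j in range(N):
            if j == i:
                continue
            c = labels[s, j]
            if not seen[c]:
                seen[c] = True
                scores[c] = 0.0
                touched[nt] = c
                nt += 1
            scores[c] += a[s, i, j] - coef * k[s, j]
        if s > 0:
            c = labels[s - 1, i]
            if not seen[c]:
                seen[c] = True
                scores[c] = 0.0
                touched[nt] = c
                nt += 1
            scores[c] += omega
        if s < L - 1:
            c = labels[s + 1, i]
            if not seen[c]:
                seen[c] = True
                scores[c] = 0.0
                touched[nt] = c
                nt += 1
            scores[c] += omega
        base = scores[cur] if seen[cur] else 0.0
        best_c = cur
        best = base
        for q in range(nt):
            c = touched[q]
            if scores[c] > best + 1e-12:
                best = scores[c]
                best_c = c
        for q in range(nt):
            seen[touched[q]] = False
        if best_c != cur:
            labels[s, i] = best_c
            n_moves += 1
    return n_moves


def _aggregate_matrix(a, k, twom, labels, gamma, omega):
    """Community-by-community aggregated modularity mass, sparse CSR.

    Entry (c, d) is the total modularity mass (intralayer weight minus the
    gamma-scaled null term, plus omega couplings) between communities c and
    d, so merging communities sums masses exactly.
    """
    from scipy.sparse import coo_array

    L, N = k.shape
    uniq, compact = np.unique(labels, return_inverse=True)
    compact = compact.reshape(L, N)
    C = len(uniq)
    rows, cols, vals = [], [], []
    for s in range(L):
        loc, inv = np.unique(compact[s], return_inverse=True)
        m = np.zeros((N, len(loc)))
        m[np.arange(N), inv] = 1.0
        block = m.T @ a[s] @ m
        if twom[s] > 0:
            kc = m.T @ k[s]
            block -= gamma * np.outer(kc, kc) / twom[s]
        rr, cc = np.meshgrid(loc, loc, indexing="ij")
        rows.append(rr.ravel())
        cols.append(cc.ravel())
        vals.append(block.ravel())
    if L > 1:
        c1 = compact[:-1].ravel()
        c2 = compact[1:].ravel()
        rows.append(np.concatenate([c1, c2]))
        cols.append(np.concatenate([c2, c1]))
        vals.append(np.full(2 * c1.size, omega))
    bagg = coo_array(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(C, C),
    ).tocsr()
    return bagg, compact


@njit(cache=True)
def _merge_sweep(indptr, indices, data, comm, order, scores, seen, touched):
    n_moves = 0
    for t in range(order.shape[0]):
        u = order[t]
        cur = comm[u]
        nt = 0
        for p in range(indptr[u], indptr[u + 1]):
            v = indices[p]
            if v == u:
                continue
            c = comm[v]
            if not seen[c]:
                seen[c] = True
                scores[c] = 0.0
                touched[nt] = c
                nt += 1
            scores[c] += data[p]
        base = scores[cur] if seen[cur] else 0.0
        best = base
        best_c = cur
        for q in range(nt):
            c = touched[q]
            if scores[c] > best + 1e-12:
                best = scores[c]
                best_c = c
        for q in range(nt):
            seen[touched[q]] = False
        if best_c != cur:
            comm[u] = best_c
            n_moves += 1
    return n_moves


def _greedy_merge(bagg, rng, max_sweeps=50):
    """Louvain-style merging of supernodes on the aggregated mass matrix."""
    C = bagg.shape[0]
    comm = np.arange(C, dtype=np.int64)
    scores = np.zeros(C)
    seen = np.zeros(C, dtype=np.bool_)
    touched = np.zeros(C, dtype=np.int64)
    for _ in range(max_sweeps):
        order = rng.permutation(C).astype(np.int64)
        if _merge_sweep(bagg.indptr, bagg.indices, bagg.data, comm, order,
                        scores, seen, touched) == 0:
            break
    return comm


def louvain_multilayer(
    stack: LayerStack,
    gamma: float = 1.0,
    omega: float = 1.0,
    n_repeats: int = 1,
    seed: int = 0,
    max_sweeps: int = 50,
) -> tuple[MultilayerPartition, list[MultilayerPartition]]:
    """Generalized Louvain on the temporal supra-graph.

    Runs ``n_repeats`` independent optimizations with random node visiting
    orders (greedy local moves, then community aggregation, iterated until Q
    stops increasing) and returns (best partition, all repeats).
    """
    if stack.n_layers == 0 or stack.n_nodes == 0:
        raise ValueError("empty layer stack")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    a, k, twom = _stack_arrays(stack)
    L, N = k.shape
    maxc = L * N
    scores = np.zeros(maxc)
    seen = np.zeros(maxc, dtype=np.bool_)
    touched = np.zeros(maxc, dtype=np.int64)
    rng = np.random.default_rng(seed)
    repeats = []
    for _ in range(n_repeats):
        labels = np.arange(maxc, dtype=np.int64).reshape(L, N)
        for _phase in range(20):
            total_moves = 0
            for _sweep in range(max_sweeps):
                order = rng.permutation(maxc).astype(np.int64)
                moves = _louvain_sweep(a, k, twom, labels, order, gamma, omega,
                                       scores, seen, touched)
                total_moves += moves
                if moves == 0:
                    break
            bagg, compact = _aggregate_matrix(a, k, twom, labels, gamma, omega)
            merge = _greedy_merge(bagg, rng)
            n_before = bagg.shape[0]
            labels = merge[compact]
            if total_moves == 0 and len(np.unique(merge)) == n_before:
                break
        # canonical relabeling: module ids 1..C in order of first appearance
        _, inv = np.unique(labels, return_inverse=True)
        flat = inv.reshape(L, N).ravel()
        first = {}
        relabeled = np.empty_like(flat)
        for pos, c in enumerate(flat):
            if c not in first:
                first[c] = len(first) + 1
            relabeled[pos] = first[c]
        part = MultilayerPartition(relabeled.reshape(L, N),
                                   Q=multilayer_modularity(stack, relabeled.reshape(L, N), gamma, omega),
                                   gamma=gamma, omega=omega)
        repeats.append(part)
    best = max(repeats, key=lambda p: p.Q)
    return best, repeats


def switching_rate(partition: MultilayerPartition) -> np.ndarray:
    """Per-node fraction of adjacent-layer transitions that change module."""
    g = partition.assignment
    if g.shape[0] < 2:
        raise ValueError("switching rate needs at least 2 layers")
    return (g[1:] != g[:-1]).mean(axis=0)


# ---------------------------------------------------------------------------
# Subject-level pipeline and group comparison
# ---------------------------------------------------------------------------

def run_switching_analysis(
    subject_series: list,
    omegas=DEFAULT_OMEGAS,
    gammas=DEFAULT_GAMMAS,
    window_length: int = DEFAULT_WINDOW_TR,
    step: float = DEFAULT_STEP_TR,
    n_repeats: int = DEFAULT_N_REPEATS,
    seed: int = 0,
) -> dict:
    """Dynamic FC + repeated multilayer community detection per subject.

    For every subject and every (omega, gamma) setting, switching rates and
    Q are averaged over ``n_repeats`` Louvain repeats.  Returns a dict with
    ``rates`` (n_subjects, n_settings, n_nodes), ``q`` (n_subjects,
    n_settings) and the ``settings`` list of (omega, gamma) pairs.
    """
    if len(subject_series) == 0:
        raise ValueError("at least one subject required")
    settings = [(w, g) for w in omegas for g in gammas]
    first = np.asarray(subject_series[0], dtype=float)
    n_nodes = first.shape[1]
    rates = np.zeros((len(subject_series), len(settings), n_nodes))
    qvals = np.zeros((len(subject_series), len(settings)))
    for si, series in enumerate(subject_series):
        x = np.asarray(series, dtype=float)
        starts = make_windows(x.shape[0], window_length, step)
        stack = dynamic_fc(x, starts, window_length, step=step)
        for gi, (om, ga) in enumerate(settings):
            sub_seed = (seed * 1_000_003 + si * 1009 + gi * 101) % (2**31 - 1)
            _, reps = louvain_multilayer(stack, gamma=ga, omega=om,
                                         n_repeats=n_repeats, seed=sub_seed)
            rates[si, gi] = np.mean([switching_rate(p) for p in reps], axis=0)
            qvals[si, gi] = np.mean([p.Q for p in reps])
    return {"rates": rates, "q": qvals, "settings": settings}


def switching_rates_frame(result: dict, subjects: list[str] | None = None) -> pd.DataFrame:
    """Tidy (subject, setting, node, rate) view of a switching analysis."""
    rates = result["rates"]
    n_subj, n_set, n_nodes = rates.shape
    if subjects is None:
        subjects = [f"S{i + 1:04d}" for i in range(n_subj)]
    rows = []
    for si in range(n_subj):
        for gi, (om, ga) in enumerate(result["settings"]):
            for node in range(n_nodes):
                rows.append((subjects[si], f"omega={om},gamma={ga}", node, rates[si, gi, node]))
    return pd.DataFrame(rows, columns=["subject", "setting", "node", "rate"])


def group_compare_switching(rates_g1: np.ndarray, rates_g2: np.ndarray,
                            q: float = 0.05) -> dict:
    """Per-node two-sample t-tests on switching rates with BH-FDR.

    ``rates_g*`` are (n_subjects, n_nodes) for a single (omega, gamma)
    setting.  Nodes with zero variance in both groups are skipped with a
    warning and get p = 1.
    """
    r1 = np.atleast_2d(np.asarray(rates_g1, dtype=float))
    r2 = np.atleast_2d(np.asarray(rates_g2, dtype=float))
    if r1.shape[0] < 2 or r2.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group")
    if r1.shape[1] != r2.shape[1]:
        raise ValueError("node count mismatch between groups")
    n_nodes = r1.shape[1]
    tstats = np.zeros(n_nodes)
    pvals = np.ones(n_nodes)
    for node in range(n_nodes):
        if r1[:, node].std() == 0 and r2[:, node].std() == 0:
            warnings.warn(f"node {node} has degenerate variance; skipped")
            continue
        res: TestResult = welch_t(r1[:, node], r2[:, node])
        tstats[node] = res.statistic
        pvals[node] = res.p
    p_adj, mask = fdr_bh(pvals, q=q)
    return {"t": tstats, "p": pvals, "p_fdr": p_adj, "significant": mask}
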