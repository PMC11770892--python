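"""Structural covariance networks (SCN) and permutation group comparison.

Regional gray-matter volumes are first residualized against age and sex by
ordinary least squares (both groups pooled, so nuisance fits cannot inject
group differences).  For each group, the SCN is the region-by-region
Pearson correlation of residualized volumes across that group's subjects.
Metric curves are computed over a sparsity grid and summarised by AUC; the
two groups are compared by permuting group labels, recomputing both
networks and their AUCs, and scoring the observed AUC difference against
the permutation null with a two-tailed add-one p-value.  Nodal p-values
are Benjamini-Hochberg corrected across regions within each metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import graphs
from .graphs import (
    BinaryGraph,
    GlobalMetrics,
    NodalMetrics,
    auc_over_sparsity,
    threshold_by_sparsity,
)
from .stats import fdr_bh

__all__ = [
    "CovarianceNetwork",
    "ScnComparison",
    "residualize_covariates",
    "build_group_scn",
    "scn_metric_curves",
    "compare_groups_permutation",
]

ALL_GLOBAL = ("Cp", "Lp", "Gamma", "Lambda", "Sigma", "Eglobal", "Elocal")
ALL_NODAL = ("degree", "betweenness", "efficiency")
#: Global metrics computable without random-network nulls.
FAST_GLOBAL = ("Cp", "Lp", "Eglobal", "Elocal")


@dataclass
class CovarianceNetwork:
    """Group-level region x region Pearson correlation matrix."""

    group: object
    n_subjects: int
    matrix: np.ndarray
    region_names: list[str] | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("covariance network must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("covariance network must have unit diagonal")
        if np.any(np.abs(m) > 1 + 1e-10):
            raise ValueError("correlations must lie in [-1, 1]")
        self.matrix = m


@dataclass
class ScnComparison:
    """Observed AUC differences, permutation p-values and nodal FDR masks."""

    global_diff: dict[str, float]
    global_p: dict[str, float]
    nodal_diff: dict[str, np.ndarray]
    nodal_p: dict[str, np.ndarray]
    nodal_p_fdr: dict[str, np.ndarray]
    nodal_significant: dict[str, np.ndarray]
    n_perm: int


def _region_columns(table: pd.DataFrame) -> list[str]:
    meta = {"subject", "group", "age", "sex"}
    return [c for c in table.columns if c not in meta]


def residualize_covariates(table: pd.DataFrame) -> pd.DataFrame:
    """Regress age and sex out of every region, pooling both groups.

    Each region's values are replaced by the OLS residual plus the grand
    mean, so the operation is idempotent up to numerical tolerance.
    """
    for col in ("age", "sex"):
        if col not in table.columns:
            raise ValueError(f"covariate column '{col}' missing")
        if np.std(table[col].to_numpy(dtype=float)) == 0:
            raise ValueError(f"covariate '{col}' is constant; regression ill-posed")
    regions = _region_columns(table)
    x = np.column_stack([
        np.ones(len(table)),
        table["age"].to_numpy(dtype=float),
        table["sex"].to_numpy(dtype=float),
    ])
    y = table[regions].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    out = table.copy()
    out[regions] = resid + y.mean(axis=0)
    return out


def build_group_scn(table: pd.DataFrame, group) -> CovarianceNetwork:
    """Pearson correlation of every region pair across one group's subjects."""
    sub = table[table["group"] == group]
    if len(sub) < 3:
        raise ValueError(f"group {group!r} has fewer than 3 subjects")
    regions = _region_columns(table)
    y = sub[regions].to_numpy(dtype=float)
    sd = y.std(axis=0)
    dead = sd == 0
    if np.any(dead):
        warnings.warn(f"zero-variance region(s) {list(np.array(regions)[dead])}; entries set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(y, rowvar=False)
    r[dead, :] = 0.0
    r[:, dead] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return CovarianceNetwork(group=group, n_subjects=len(sub), matrix=r,
                             region_names=regions)


def _metrics_at_sparsity(
    g: BinaryGraph,
    global_metrics: tuple,
    nodal_metrics: tuple,
    n_random: int,
    rng: np.random.Generator,
) -> tuple[dict, dict]:
    gvals: dict[str, float] = {}
    need_null = any(m in global_metrics for m in ("Gamma", "Lambda", "Sigma"))
    if "Cp" in global_metrics or need_null:
        _, cp = graphs.clustering_coefficient(g)
        if "Cp" in global_metrics:
            gvals["Cp"] = cp
    if "Lp" in global_metrics or need_null:
        lp = graphs.characteristic_path_length(g)
        if "Lp" in global_metrics:
            gvals["Lp"] = lp
    if "Eglobal" in global_metrics:
        gvals["Eglobal"] = graphs.global_efficiency(g)
    if "Elocal" in global_metrics:
        gvals["Elocal"] = graphs.local_efficiency(g)
    if need_null:
        gamma, lam, sigma = graphs.small_world_indices(g, n_random=n_random, seed=rng)
        if "Gamma" in global_metrics:
            gvals["Gamma"] = gamma
        if "Lambda" in global_metrics:
            gvals["Lambda"] = lam
        if "Sigma" in global_metrics:
            gvals["Sigma"] = sigma
    nvals: dict[str, np.ndarray] = {}
    if "degree" in nodal_metrics:
        nvals["degree"] = graphs.degree(g).astype(float)
    if "betweenness" in nodal_metrics:
        nvals["betweenness"] = graphs.betweenness(g)
    if "efficiency" in nodal_metrics:
        nvals["efficiency"] = graphs.nodal_efficiency(g)
    return gvals, nvals


def scn_metric_curves(
    net: CovarianceNetwork,
    grid=None,
    n_random: int = 100,
    seed: int | np.random.Generator = 0,
    global_metrics: tuple = ALL_GLOBAL,
    nodal_metrics: tuple = ALL_NODAL,
) -> tuple[GlobalMetrics, NodalMetrics]:
    """Threshold at every sparsity, compute metrics, and summarise by AUC."""
    grid = graphs.default_sparsity_grid() if grid is None else np.asarray(grid, dtype=float)
    if np.any((grid <= 0) | (grid > 1)):
        raise ValueError("sparsity grid must lie in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = net.matrix.shape[0]
    gcurves = {m: np.zeros(len(grid)) for m in global_metrics}
    ncurves = {m: np.zeros((len(grid), n)) for m in nodal_metrics}
    for si, sp in enumerate(grid):
        g = threshold_by_sparsity(net.matrix, sp)
        gvals, nvals = _metrics_at_sparsity(g, global_metrics, nodal_metrics, n_random, rng)
        for m, v in gvals.items():
            gcurves[m][si] = v
        for m, v in nvals.items():
            ncurves[m][si] = v
    return GlobalMetrics(grid, gcurves), NodalMetrics(grid, ncurves)


def _auc_stats(table, regions, groups, grid, n_random, rng, global_metrics, nodal_metrics):
    gaucs = {}
    naucs = {}
    for grp in groups:
        net = build_group_scn(table, grp)
        gm, nm = scn_metric_curves(net, grid, n_random, rng,
                                   global_metrics=global_metrics,
                                   nodal_metrics=nodal_metrics)
        gaucs[grp] = gm.auc
        naucs[grp] = nm.auc
    g1, g2 = groups
    gdiff = {m: gaucs[g1][m] - gaucs[g2][m] for m in global_metrics}
    ndiff = {m: naucs[g1][m] - naucs[g2][m] for m in nodal_metrics}
    return gdiff, ndiff


def compare_groups_permutation(
    table: pd.DataFrame,
    n_perm: int = 1000,
    grid=None,
    n_random: int = 100,
    seed: int = 0,
    global_metrics: tuple = ALL_GLOBAL,
    nodal_metrics: tuple = ALL_NODAL,
    fdr_q: float = 0.05,
) -> ScnComparison:
    """Nonparametric permutation test on AUC differences between two groups.

    The observed statistic per metric (and per node for nodal metrics) is
    AUC(group1) - AUC(group2).  The null shuffles group labels, recomputes
    both covariance networks and their AUCs, and p = (1 + #{|null| >=
    |obs|}) / (1 + n_perm), two-tailed.  Nodal p-values are BH-FDR adjusted
    across regions within each metric.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    groups = sorted(pd.unique(table["group"]))
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    sizes = table["group"].value_counts()
    if sizes.min() < 3:
        raise ValueError("each group needs at least 3 subjects")
    grid = graphs.default_sparsity_grid() if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    regions = _region_columns(table)

    obs_g, obs_n = _auc_stats(table, regions, groups, grid, n_random, rng,
                              global_metrics, nodal_metrics)

    count_g = {m: 0 for m in global_metrics}
    count_n = {m: np.zeros(len(regions)) for m in nodal_metrics}
    labels = table["group"].to_numpy()
    perm_table = table.copy()
    for _ in range(n_perm):
        perm_table["group"] = rng.permutation(labels)
        pg, pn = _auc_stats(perm_table, regions, groups, grid, n_random, rng,
                            global_metrics, nodal_metrics)
        for m in global_metrics:
            if abs(pg[m]) >= abs(obs_g[m]):
                count_g[m] += 1
        for m in nodal_metrics:
            count_n[m] += np.abs(pn[m]) >= np.abs(obs_n[m])

    global_p = {m: (1 + count_g[m]) / (1 + n_perm) for m in global_metrics}
    nodal_p = {m: (1 + count_n[m]) / (1 + n_perm) for m in nodal_metrics}
    nodal_p_fdr = {}
    nodal_sig = {}
    for m in nodal_metrics:
        p_adj, mask = fdr_bh(nodal_p[m], q=fdr_q)
        nodal_p_fdr[m] = p_adj
        nodal_sig[m] = mask
    return ScnComparison(
        global_diff=obs_g, global_p=global_p,
        nodal_diff=obs_n, nodal_p=nodal_p,
        nodal_p_fdr=nodal_p_fdr, nodal_significant=nodal_sig,
        n_perm=n_perm,
    )
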