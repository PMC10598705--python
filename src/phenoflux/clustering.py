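"""Metric screening, Z-scoring, bootstrap clustering and phenotype calling.

Samples are clustered into light-response phenotypes in four steps:

1. *Screen*: keep the metrics that differ significantly (p < 0.05) across
   dominant symbiont types — one-way ANOVA when the residuals pass a
   Shapiro-Wilk normality check, Kruskal-Wallis otherwise. The screen is
   univariate and uncorrected by design: it is a filter, not inference.
2. *Z-score*: standardize each kept metric to mean 0, SD 1 (missing values
   are ignored in the moments and retained as missing).
3. *Cluster*: hierarchical agglomerative clustering of samples with
   distance 1 - Pearson correlation between sample metric vectors and
   average linkage; node support from multiscale bootstrap over metric
   resampling (scale factors 0.5-1.4), yielding approximately-unbiased
   (AU) and raw bootstrap-probability (BP) values per internal node.
4. *Cut*: the dendrogram is cut so exactly k (default 4) groups remain;
   labels are ordered by cluster size descending.

Driver metrics separating the phenotypes are ranked by their one-way
F-statistic on the Z-scored values, aggregated over wavelength/timepoint
into metric families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "ScreenResult",
    "ClusterResult",
    "PhenotypeAssignment",
    "screen_metrics",
    "zscore_matrix",
    "bootstrap_cluster",
    "cut_phenotypes",
    "rank_driver_metrics",
    "to_newick",
]

_ALPHA = 0.05
_MAX_MISSING_FRACTION = 0.20
_DEFAULT_SCALES = np.round(np.linspace(0.5, 1.4, 10), 2)


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenResult:
    metric: str
    test: str  # "anova" | "kruskal" | "skipped"
    p_value: float
    kept: bool
    reason: str = ""


def screen_metrics(
    wide: pd.DataFrame,
    groups: pd.Series,
    alpha: float = _ALPHA,
    normality_alpha: float = _ALPHA,
) -> list[ScreenResult]:
    """Screen metric columns for differences across symbiont-type groups.

    ``wide`` is a samples x metrics table; ``groups`` maps sample id to its
    dominant type. Per metric, residuals about group means are tested with
    Shapiro-Wilk: one-way ANOVA if normality is not rejected, otherwise
    Kruskal-Wallis. A metric is kept iff p < alpha. Constant metrics and
    metrics leaving fewer than two groups with >= 2 samples are skipped.
    """
    groups = groups.reindex(wide.index)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    level_counts = groups.value_counts()
    if (level_counts >= 3).sum() < 2:
        raise ValueError("screening requires >= 2 groups with >= 3 samples")

    results: list[ScreenResult] = []
    garr = groups.to_numpy()
    for col in wide.columns:
        x = wide[col].to_numpy(dtype=float)
        ok = np.isfinite(x)
        xv, gv = x[ok], garr[ok]
        if len(xv) == 0 or np.ptp(xv) == 0:
            results.append(ScreenResult(col, "skipped", np.nan, False, "constant"))
            continue
        samples = [xv[gv == g] for g in np.unique(gv)]
        samples = [s for s in samples if len(s) >= 2]
        if len(samples) < 2:
            warnings.warn(f"metric {col}: <2 usable groups, skipped", stacklevel=2)
            results.append(ScreenResult(col, "skipped", np.nan, False, "too few groups"))
            continue
        resid = np.concatenate([s - s.mean() for s in samples])
        if np.ptp(resid) == 0:
            normal = True  # zero residuals: ANOVA degenerate but harmless
        else:
            normal = stats.shapiro(resid).pvalue >= normality_alpha
        if normal:
            test, p = "anova", stats.f_oneway(*samples).pvalue
        else:
            test, p = "kruskal", stats.kruskal(*samples).pvalue
        p = float(p) if np.isfinite(p) else 1.0
        results.append(ScreenResult(col, test, p, bool(p < alpha)))
    return results


def kept_metrics(results: Sequence[ScreenResult]) -> list[str]:
    return [r.metric for r in results if r.kept]


# ---------------------------------------------------------------------------
# Z-scoring
# ---------------------------------------------------------------------------


def zscore_matrix(wide: pd.DataFrame) -> pd.DataFrame:
    """Standardize each metric column to mean 0, SD 1 (missing-aware)."""
    mu = wide.mean(axis=0, skipna=True)
    sd = wide.std(axis=0, ddof=0, skipna=True)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance metrics (should have been screened): {zero[:5]}")
    return (wide - mu) / sd


# ---------------------------------------------------------------------------
# Bootstrap clustering
# ---------------------------------------------------------------------------


def _correlation_distance(X: np.ndarray) -> np.ndarray:
    """1 - Pearson between sample rows, pairwise-complete on missing."""
    if np.isfinite(X).all():
        corr = np.corrcoef(X)
    else:
        corr = pd.DataFrame(X.T).corr(min_periods=3).to_numpy()
    corr = np.clip(corr, -1.0, 1.0)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def _node_leafsets(Z: np.ndarray, n: int) -> list[frozenset]:
    """Leaf index set of every internal node of a scipy linkage."""
    sets: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    out = []
    for i, (a, b) in enumerate(Z[:, :2].astype(int)):
        s = sets[a] | sets[b]
        sets[n + i] = s
        out.append(s)
    return out


@dataclass
class ClusterResult:
    """Sample dendrogram with multiscale bootstrap node support."""

    sample_ids: list[str]
    linkage: np.ndarray
    support: pd.DataFrame  # per internal node: au, bp, n_leaves
    n_boot: int
    scales: np.ndarray
    excluded: list[str] = field(default_factory=list)


def _au_from_counts(
    bp_by_scale: np.ndarray, scales: np.ndarray, n_per_scale: int
) -> tuple[float, float]:
    """pvclust-style AU/BP from per-scale bootstrap probabilities.

    Fits  qnorm(1 - BP_r) = v * sqrt(r) + c / sqrt(r)  by weighted least
    squares over scale factors r; AU = 1 - Phi(v - c), the bias-corrected
    probability at r -> the unbiased limit, and BP = 1 - Phi(v + c) the
    smoothed ordinary bootstrap probability.
    """
    eps = 1.0 / (2.0 * n_per_scale)
    bp = np.clip(bp_by_scale, eps, 1.0 - eps)
    if np.all(bp_by_scale >= 1.0 - 1e-12):
        return 1.0, 1.0
    if np.all(bp_by_scale <= 1e-12):
        return 0.0, 0.0
    z = stats.norm.ppf(1.0 - bp)
    sr = np.sqrt(scales)
    X = np.column_stack([sr, 1.0 / sr])
    # binomial delta-method weights
    var = bp * (1.0 - bp) / (n_per_scale * stats.norm.pdf(z) ** 2)
    w = 1.0 / np.maximum(var, 1e-12)
    WX = X * w[:, None]
    try:
        beta = np.linalg.solve(X.T @ WX, WX.T @ z)
    except np.linalg.LinAlgError:
        return float(np.mean(1.0 - bp)), float(np.mean(1.0 - bp))
    v, c = beta
    au = float(1.0 - stats.norm.cdf(v - c))
    bp_fit = float(1.0 - stats.norm.cdf(v + c))
    return au, bp_fit


def bootstrap_cluster(
    z_matrix: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    scales: Optional[np.ndarray] = None,
    max_missing: float = _MAX_MISSING_FRACTION,
) -> ClusterResult:
    """Cluster samples with multiscale-bootstrap node support.

    ``z_matrix`` is samples x metrics (Z-scored). Distance between samples
    is 1 - Pearson correlation of their metric vectors; average linkage.
    ``n_boot`` total bootstrap replicates are split evenly over the scale
    factors (default 0.5-1.4); each replicate resamples metrics with
    replacement at size round(r * n_metrics). Deterministic given ``seed``.
    Samples with more than ``max_missing`` missing metrics are excluded.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    frac_missing = z_matrix.isna().mean(axis=1)
    excluded = list(z_matrix.index[frac_missing > max_missing])
    if excluded:
        warnings.warn(f"excluding missing-dominated samples: {excluded}", stacklevel=2)
        z_matrix = z_matrix.drop(index=excluded)
    n = len(z_matrix)
    if n < 3:
        raise ValueError("need >= 3 samples to cluster")
    # sample-order invariance: canonicalize row order
    z_matrix = z_matrix.sort_index()
    X = z_matrix.to_numpy(dtype=float)
    m = X.shape[1]
    scales = _DEFAULT_SCALES if scales is None else np.asarray(scales, float)

    Z = hierarchy.linkage(squareform(_correlation_distance(X), checks=False), "average")
    ref_sets = _node_leafsets(Z, n)

    rng = np.random.default_rng(seed)
    n_per_scale = max(int(round(n_boot / len(scales))), 1)
    counts = np.zeros((len(scales), len(ref_sets)), dtype=float)
    ref_index = {s: i for i, s in enumerate(ref_sets)}
    for si, r in enumerate(scales):
        m_r = max(int(round(r * m)), 2)
        for _ in range(n_per_scale):
            cols = rng.integers(0, m, size=m_r)
            Xb = X[:, cols]
            Db = _correlation_distance(Xb)
            Zb = hierarchy.linkage(squareform(Db, checks=False), "average")
            for s in _node_leafsets(Zb, n):
                j = ref_index.get(s)
                if j is not None:
                    counts[si, j] += 1.0
    bp_by_scale = counts / n_per_scale

    au = np.empty(len(ref_sets))
    bp = np.empty(len(ref_sets))
    for j in range(len(ref_sets)):
        au[j], bp[j] = _au_from_counts(bp_by_scale[:, j], scales, n_per_scale)
    support = pd.DataFrame({
        "node": np.arange(len(ref_sets)),
        "au": au,
        "bp": bp,
        "bp_raw_r1": bp_by_scale[np.argmin(np.abs(scales - 1.0))],
        "n_leaves": [len(s) for s in ref_sets],
    })
    return ClusterResult(
        sample_ids=list(z_matrix.index), linkage=Z, support=support,
        n_boot=n_per_scale * len(scales), scales=scales, excluded=excluded,
    )


# ---------------------------------------------------------------------------
# Phenotype cut
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeAssignment:
    """Sample -> phenotype labels (1..k, ordered by cluster size desc)."""

    labels: pd.Series
    k: int
    cluster_result: Optional[ClusterResult] = None

    def __post_init__(self) -> None:
        got = sorted(self.labels.unique())
        if got != list(range(1, self.k + 1)):
            raise ValueError(f"labels must be contiguous 1..{self.k}, got {got}")


def cut_phenotypes(result: ClusterResult, k: int = 4) -> PhenotypeAssignment:
    """Cut the dendrogram so exactly k groups remain.

    Labels are renumbered by cluster size descending; ties broken by the
    first sample id in the cluster.
    """
    n = len(result.sample_ids)
    if k > n:
        raise ValueError(f"k={k} exceeds {n} leaves")
    raw = hierarchy.fcluster(result.linkage, t=k, criterion="maxclust")
    ids = pd.Index(result.sample_ids, name="sample_id")
    order = sorted(
        np.unique(raw),
        key=lambda lab: (-int(np.sum(raw == lab)), min(ids[raw == lab])),
    )
    remap = {lab: i + 1 for i, lab in enumerate(order)}
    labels = pd.Series([remap[v] for v in raw], index=ids, name="phenotype")
    return PhenotypeAssignment(labels=labels, k=len(order), cluster_result=result)


# ---------------------------------------------------------------------------
# Driver metrics
# ---------------------------------------------------------------------------


def rank_driver_metrics(
    z_matrix: pd.DataFrame, assignment: PhenotypeAssignment
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank metrics by how strongly they separate the phenotypes.

    Scores each metric with the one-way F-statistic of its Z-scored values
    across phenotype labels, then aggregates over wavelength/timepoint into
    metric families (the leading token of the metric_wavelength_timepoint
    key). Returns (per-metric table, per-family table), both sorted by
    score. The family table carries an ``informative`` flag: False when no
    metric reaches p < 0.05 (e.g. identical phenotypes).
    """
    labels = assignment.labels.reindex(z_matrix.index)
    if labels.isna().any():
        raise ValueError("assignment missing labels for some samples")
    if labels.nunique() < 2:
        raise ValueError("need >= 2 phenotypes to rank driver metrics")
    garr = labels.to_numpy()
    f_vals, p_vals = [], []
    for col in z_matrix.columns:
        x = z_matrix[col].to_numpy(dtype=float)
        ok = np.isfinite(x)
        samples = [x[ok & (garr == g)] for g in np.unique(garr)]
        samples = [s for s in samples if len(s) >= 2]
        if len(samples) < 2 or all(np.ptp(s) == 0 for s in samples):
            f, p = np.nan, np.nan
        else:
            res = stats.f_oneway(*samples)
            f, p = float(res.statistic), float(res.pvalue)
        f_vals.append(f)
        p_vals.append(p)
    per_metric = pd.DataFrame({
        "metric": z_matrix.columns,
        "family": [c.split("_")[0] for c in z_matrix.columns],
        "f_stat": f_vals,
        "p_value": p_vals,
    }).sort_values("f_stat", ascending=False, ignore_index=True)
    fam = (
        per_metric.groupby("family")
        .agg(mean_f=("f_stat", "mean"), max_f=("f_stat", "max"),
             n_metrics=("f_stat", "size"),
             n_significant=("p_value", lambda p: int((p < _ALPHA).sum())))
        .sort_values("mean_f", ascending=False)
        .reset_index()
    )
    fam["informative"] = fam["n_significant"] > 0
    return per_metric, fam


# ---------------------------------------------------------------------------
# Newick export
# ---------------------------------------------------------------------------


def to_newick(result: ClusterResult, support: str = "au") -> str:
    """Serialize the dendrogram to Newick with node support labels."""
    tree = hierarchy.to_tree(result.linkage)
    sup = result.support.set_index("node")[support]
    n = len(result.sample_ids)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0) if parent_height is not None else 0.0
        if node.is_leaf():
            return f"{result.sample_ids[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        label = f"{sup.loc[node.id - n]:.3f}"
        return f"({left},{right}){label}:{length:.6g}"

    # root branch length 0
    return rec(tree, tree.dist) + ";"
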