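"""Mass-univariate maps with cluster-based Monte-Carlo permutation correction.

A FeatureMap holds one value per (subject, channel, feature) where the feature
axis is MSE scales, frequency bins, or PAC band pairs.  Per pixel, the group
contrast uses the classical equal-variance two-sample t statistic and the
score association uses the Spearman correlation (converted to a t value for
thresholding).  Pixels with two-tailed P < 0.05 are pooled into clusters under
the combined adjacency — spatial sensor neighborhood within a feature, plus
consecutive scales/frequency bins within a channel (PAC pairs are clustered
spatially only) — and each cluster is summarized by its mass (sum of t).  The
Monte-Carlo null is the per-permutation maximum cluster mass per sign;
cluster P values are doubled within-tail probabilities capped at 1 (FieldTrip
two-tailed convention), with p = (b + 1)/(n_perm + 1).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .core import InvalidArgumentError, NeighborhoodGraph

__all__ = [
    "FeatureMap",
    "StatMap",
    "Cluster",
    "ClusterResult",
    "group_tmap",
    "score_rmap",
    "find_clusters",
    "permutation_test",
    "report_clusters",
]


@dataclass
class FeatureMap:
    """(n_subjects, n_channels, n_features) array plus axis metadata."""

    data: np.ndarray
    channel_names: tuple[str, ...]
    feature_labels: tuple
    feature_kind: str = "scale"  # scale | frequency | pair

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise InvalidArgumentError("FeatureMap data must be 3-D")
        if self.data.shape[1] != len(self.channel_names):
            raise InvalidArgumentError("channel axis mismatch")
        if self.data.shape[2] != len(self.feature_labels):
            raise InvalidArgumentError("feature axis mismatch")
        if self.feature_kind not in ("scale", "frequency", "pair"):
            raise InvalidArgumentError(f"unknown feature_kind {self.feature_kind!r}")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self):
        return self.data.shape[1:]

    def features_adjacent(self) -> bool:
        """Consecutive scales/frequencies are adjacent; PAC pairs are not."""
        return self.feature_kind in ("scale", "frequency")


@dataclass
class StatMap:
    stat: np.ndarray  # (n_channels, n_features) t values
    df: int
    pos_mask: np.ndarray
    neg_mask: np.ndarray
    threshold_p: float = 0.05
    kind: str = "t"  # t | spearman_t
    rho: np.ndarray | None = None  # raw Spearman rho for correlation maps


@dataclass
class Cluster:
    pixels: list  # [(channel index, feature index), ...]
    sign: int  # +1 or -1
    mass: float  # sum of t over pixels
    tvals: list = field(default_factory=list)  # per-pixel t, same order
    p_mc: float | None = None

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    @property
    def channels(self) -> list:
        return sorted({c for c, _ in self.pixels})


@dataclass
class ClusterResult:
    clusters: list  # of Cluster, observed, both signs
    n_permutations: int
    seed: int | None
    null_max_pos: np.ndarray = field(default_factory=lambda: np.empty(0))
    null_max_neg: np.ndarray = field(default_factory=lambda: np.empty(0))
    exact: bool = False

    def significant(self, alpha: float = 0.05) -> list:
        return [c for c in self.clusters if c.p_mc is not None and c.p_mc < alpha]


# ---------------------------------------------------------------------------
# Statistic maps

def group_tmap(fm: FeatureMap, labels, threshold_p: float = 0.05) -> StatMap:
    """Pixelwise equal-variance two-sample t map (group A minus group B).

    ``labels`` is a boolean or two-level array per subject; True/first level is
    the first group.  Missing values (NaN) are excluded pairwise per pixel.
    """
    g = _as_group_bool(labels, fm.n_subjects)
    n1, n2 = int(g.sum()), int((~g).sum())
    if n1 < 2 or n2 < 2:
        raise InvalidArgumentError("both groups need at least 2 subjects")
    x = fm.data.reshape(fm.n_subjects, -1)
    t, df = _welchfree_t(x[g], x[~g])
    tcrit = stats.t.ppf(1 - threshold_p / 2, df)
    shape = fm.shape
    tmap = t.reshape(shape)
    return StatMap(tmap, df, tmap > tcrit, tmap < -tcrit, threshold_p, "t")


def _as_group_bool(labels, n: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.shape[0] != n:
        raise InvalidArgumentError("labels length must equal subject count")
    if labels.dtype == bool:
        return labels
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise InvalidArgumentError(f"expected 2 group levels, got {list(levels)}")
    return labels == levels[0]


def _welchfree_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, int]:
    """Classical pooled-variance t per column, NaN-aware."""
    n1 = np.sum(~np.isnan(a), axis=0)
    n2 = np.sum(~np.isnan(b), axis=0)
    m1 = np.nanmean(a, axis=0)
    m2 = np.nanmean(b, axis=0)
    v1 = np.nanvar(a, axis=0, ddof=1)
    v2 = np.nanvar(b, axis=0, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = np.where(sp2 == 0, 0.0, t)
    return t, int(np.max(df))


def _rank(x: np.ndarray, axis: int = 0) -> np.ndarray:
    return stats.rankdata(x, axis=axis)


def score_rmap(fm: FeatureMap, scores, threshold_p: float = 0.05) -> StatMap:
    """Pixelwise Spearman correlation with per-subject scores.

    The map carries the t-transform t = ρ√((n−2)/(1−ρ²)) so that cluster mass
    is commensurable with the group t maps; the threshold is the two-tailed
    P < ``threshold_p`` cut on that t.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != fm.n_subjects:
        raise InvalidArgumentError("scores length must equal subject count")
    if fm.n_subjects < 5:
        raise InvalidArgumentError("need ≥ 5 subjects for a correlation map")
    if not np.all(np.isfinite(scores)):
        raise InvalidArgumentError("scores must be finite")
    if np.ptp(scores) == 0:
        raise InvalidArgumentError("scores are constant")
    n = fm.n_subjects
    x = fm.data.reshape(n, -1)
    rx = _rank(x)
    rs = _rank(scores)
    zx = (rx - rx.mean(axis=0)) / rx.std(axis=0)
    zs = (rs - rs.mean()) / rs.std()
    rho = zs @ zx / n
    rho = np.clip(rho, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt(df / (1 - rho**2))
    t = np.where(np.abs(rho) >= 1.0, np.sign(rho) * 1e6, t)
    tcrit = stats.t.ppf(1 - threshold_p / 2, df)
    tmap = t.reshape(fm.shape)
    return StatMap(tmap, df, tmap > tcrit, tmap < -tcrit, threshold_p, "spearman_t",
                   rho=rho.reshape(fm.shape))


# ---------------------------------------------------------------------------
# Clustering

def _pixel_neighbors(graph: NeighborhoodGraph, n_feat: int,
                     features_adjacent: bool) -> list:
    """Adjacency list over flattened (channel, feature) pixels."""
    n_ch = graph.n_channels
    nbrs = [[] for _ in range(n_ch * n_feat)]
    ch_nbrs = [list(np.flatnonzero(graph.adjacency[c])) for c in range(n_ch)]
    for c in range(n_ch):
        for f in range(n_feat):
            p = c * n_feat + f
            for c2 in ch_nbrs[c]:
                nbrs[p].append(c2 * n_feat + f)
            if features_adjacent:
                if f > 0:
                    nbrs[p].append(p - 1)
                if f < n_feat - 1:
                    nbrs[p].append(p + 1)
    return nbrs


def _mask_clusters(mask_flat: np.ndarray, stat_flat: np.ndarray,
                   nbrs: list) -> list:
    """Connected suprathreshold components: list of (pixel list, mass)."""
    seen = np.zeros(mask_flat.shape[0], dtype=bool)
    out = []
    idx = np.flatnonzero(mask_flat)
    for start in idx:
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            p = stack.pop()
            comp.append(p)
            for q in nbrs[p]:
                if mask_flat[q] and not seen[q]:
                    seen[q] = True
                    stack.append(q)
        out.append((comp, float(stat_flat[comp].sum())))
    return out


def find_clusters(sm: StatMap, graph: NeighborhoodGraph,
                  features_adjacent: bool = True) -> list:
    """Observed clusters per sign, sorted by |mass| descending."""
    n_ch, n_feat = sm.stat.shape
    if graph.n_channels != n_ch:
        raise InvalidArgumentError("graph does not match stat map channels")
    nbrs = _pixel_neighbors(graph, n_feat, features_adjacent)
    stat_flat = sm.stat.ravel()
    clusters = []
    for sign, mask in ((1, sm.pos_mask), (-1, sm.neg_mask)):
        for comp, mass in _mask_clusters(mask.ravel(), stat_flat, nbrs):
            pixels = [(p // n_feat, p % n_feat) for p in comp]
            clusters.append(Cluster(pixels, sign, mass,
                                    [float(stat_flat[p]) for p in comp]))
    clusters.sort(key=lambda c: -abs(c.mass))
    return clusters


# ---------------------------------------------------------------------------
# Permutation inference

def _group_t_perms(x: np.ndarray, g_mat: np.ndarray) -> np.ndarray:
    """t maps for many label assignments.  x: (n, p); g_mat: (B, n) bool."""
    n, p = x.shape
    n1 = g_mat[0].sum()
    n2 = n - n1
    gf = g_mat.astype(float)
    s1 = gf @ x
    s2 = x.sum(axis=0) - s1
    q1 = gf @ (x**2)
    q2 = (x**2).sum(axis=0) - q1
    m1 = s1 / n1
    m2 = s2 / n2
    v1 = (q1 - n1 * m1**2) / (n1 - 1)
    v2 = (q2 - n2 * m2**2) / (n2 - 1)
    df = n - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return np.where(sp2 <= 0, 0.0, t)


def _score_t_perms(x: np.ndarray, scores: np.ndarray,
                   perm_idx: np.ndarray) -> np.ndarray:
    """Spearman-t maps for many score orderings.  perm_idx: (B, n) int."""
    n, p = x.shape
    rx = _rank(x)
    zx = (rx - rx.mean(axis=0)) / rx.std(axis=0)
    rs = _rank(scores)
    zs = (rs - rs.mean()) / rs.std()
    zs_perm = zs[perm_idx]  # (B, n)
    rho = np.clip(zs_perm @ zx / n, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt(df / (1 - rho**2))
    return np.where(np.abs(rho) >= 1.0, np.sign(rho) * 1e6, t)


def permutation_test(
    fm: FeatureMap,
    design,
    graph: NeighborhoodGraph,
    n_perm: int = 10000,
    seed: int = 0,
    threshold_p: float = 0.05,
    statistic: str = "mass",
) -> ClusterResult:
    """Cluster-based Monte-Carlo permutation test over a FeatureMap.

    ``design`` is a group label vector (group contrast; labels are shuffled)
    or a dict ``{"scores": values}`` (Spearman association; scores are
    shuffled).  ``statistic`` is "mass" (sum of t, the default) or "size"
    (pixel count, signed).  When fewer distinct group splits than ``n_perm``
    exist, the test falls back to complete enumeration.
    """
    if n_perm < 100:
        raise InvalidArgumentError("n_perm must be ≥ 100")
    n = fm.n_subjects
    x = fm.data.reshape(n, -1)
    n_ch, n_feat = fm.shape
    nbrs = _pixel_neighbors(graph, n_feat, fm.features_adjacent())
    rng = np.random.default_rng(seed)

    is_score = isinstance(design, dict)
    if is_score:
        scores = np.asarray(design["scores"], dtype=float)
        sm = score_rmap(fm, scores, threshold_p)
        df = sm.df
        exact = False
        perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)])
        t_null = _score_t_perms(x, scores, perm_idx)
    else:
        g = _as_group_bool(design, n)
        sm = group_tmap(fm, g, threshold_p)
        df = sm.df
        n1 = int(g.sum())
        n_distinct = comb(n, n1)
        exact = n_distinct <= n_perm
        if exact:
            warnings.warn(
                f"only {n_distinct} distinct label splits; using complete enumeration",
                stacklevel=2,
            )
            g_mat = np.zeros((n_distinct, n), dtype=bool)
            for bi, pick in enumerate(itertools.combinations(range(n), n1)):
                g_mat[bi, list(pick)] = True
        else:
            g_mat = np.zeros((n_perm, n), dtype=bool)
            for bi in range(n_perm):
                g_mat[bi, rng.choice(n, n1, replace=False)] = True
        t_null = _group_t_perms(x, g_mat)

    tcrit = stats.t.ppf(1 - threshold_p / 2, df)
    clusters = find_clusters(sm, graph, fm.features_adjacent())

    b_total = t_null.shape[0]
    null_pos = np.zeros(b_total)
    null_neg = np.zeros(b_total)
    for bi in range(b_total):
        row = t_null[bi]
        pos = row > tcrit
        if pos.any():
            comps = _mask_clusters(pos, row, nbrs)
            null_pos[bi] = max(
                (len(c) if statistic == "size" else m) for c, m in comps
            )
        neg = row < -tcrit
        if neg.any():
            comps = _mask_clusters(neg, -row, nbrs)
            null_neg[bi] = max(
                (len(c) if statistic == "size" else m) for c, m in comps
            )

    denom = b_total if exact else b_total + 1
    for cl in clusters:
        obs = cl.n_pixels if statistic == "size" else abs(cl.mass)
        null = null_pos if cl.sign > 0 else null_neg
        # tolerance so the identity permutation ties with the observed mass
        b = int(np.sum(null >= obs - 1e-8 * max(1.0, obs)))
        p_tail = (b if exact else b + 1) / denom
        cl.p_mc = min(1.0, 2 * p_tail)

    return ClusterResult(clusters, b_total, seed, null_pos, null_neg, exact)


def report_clusters(cr: ClusterResult, channel_names,
                    feature_labels) -> pd.DataFrame:
    """Tabular cluster report (one row per cluster); empty frame when none."""
    rows = []
    for ci, cl in enumerate(cr.clusters):
        feats = sorted({f for _, f in cl.pixels})
        chans = [channel_names[c] for c in cl.channels]
        rows.append(
            dict(
                cluster_id=ci + 1,
                sign=cl.sign,
                p_mc=cl.p_mc,
                mass=cl.mass,
                n_pixels=cl.n_pixels,
                channels=";".join(chans),
                feature_min=feature_labels[feats[0]],
                feature_max=feature_labels[feats[-1]],
                t_min=min(cl.tvals) if cl.tvals else np.nan,
                t_max=max(cl.tvals) if cl.tvals else np.nan,
            )
        )
    cols = ["cluster_id", "sign", "p_mc", "mass", "n_pixels", "channels",
            "feature_min", "feature_max", "t_min", "t_max"]
    return pd.DataFrame(rows, columns=cols)
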