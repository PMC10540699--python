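"""Within-subject ANOVA maps and permutation cluster-mass inference.

Familywise error over channels(×time) is controlled by the permutation
max-cluster-mass distribution: statistic maps are thresholded at the
cluster-forming level (p < 0.001 by default), suprathreshold points are
grouped by channel adjacency plus temporal contiguity, and each observed
cluster's mass is compared against the null distribution of the largest
cluster mass under exchangeability (condition-label permutations for ANOVA
maps, sign flips for one-sample contrast maps).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats


# ---------------------------------------------------------------------------
# repeated-measures F statistics (vectorized over trailing map dimensions)

def rm_anova_1way(values: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    """One-way within-subject F. ``values``: (n_subjects, k, ...)."""
    x = np.asarray(values, dtype=np.float64)
    n, k = x.shape[:2]
    if n < 2 or k < 2:
        raise ValueError("need >=2 subjects and >=2 conditions")
    gm = x.mean(axis=(0, 1))
    m_s = x.mean(axis=1)
    m_c = x.mean(axis=0)
    ss_cond = n * ((m_c - gm) ** 2).sum(axis=0)
    resid = x - m_s[:, None] - m_c[None] + gm
    ss_err = (resid ** 2).sum(axis=(0, 1))
    df1, df2 = k - 1, (n - 1) * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_cond / df1) / np.maximum(ss_err / df2, 1e-300)
    # identical conditions leave only float dust in both sums: report F = 0
    tiny = 1e-12 * (x.var(axis=(0, 1)) + 1e-300)
    return np.where(ss_cond < tiny, 0.0, np.nan_to_num(f)), (df1, df2)


def rm_anova_2way(values: np.ndarray) -> dict[str, tuple[np.ndarray, tuple[int, int]]]:
    """Two-way within-subject F maps. ``values``: (n, a, b, ...).

    Returns F and dfs for effects 'A', 'B' and 'AxB', each tested against
    its own effect-by-subject interaction error term.
    """
    x = np.asarray(values, dtype=np.float64)
    n, a, b = x.shape[:3]
    gm = x.mean(axis=(0, 1, 2))
    m_s = x.mean(axis=(1, 2))
    m_a = x.mean(axis=(0, 2))
    m_b = x.mean(axis=(0, 1))
    m_ab = x.mean(axis=0)
    m_sa = x.mean(axis=2)
    m_sb = x.mean(axis=1)

    out = {}

    tiny = 1e-12 * (x.var(axis=(0, 1, 2)) + 1e-300)

    def eff(ss_eff, ss_err, df1, df2, name):
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss_eff / df1) / np.maximum(ss_err / df2, 1e-300)
        out[name] = (np.where(ss_eff < tiny, 0.0, np.nan_to_num(f)),
                     (df1, df2))

    ss_a = n * b * ((m_a - gm) ** 2).sum(axis=0)
    ss_as = b * ((m_sa - m_s[:, None] - m_a[None] + gm) ** 2).sum(axis=(0, 1))
    eff(ss_a, ss_as, a - 1, (a - 1) * (n - 1), "A")

    ss_b = n * a * ((m_b - gm) ** 2).sum(axis=0)
    ss_bs = a * ((m_sb - m_s[:, None] - m_b[None] + gm) ** 2).sum(axis=(0, 1))
    eff(ss_b, ss_bs, b - 1, (b - 1) * (n - 1), "B")

    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None] + gm) ** 2).sum(axis=(0, 1))
    resid = (x - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None]
             + m_a[None, :, None] + m_b[None, None, :] + m_s[:, None, None] - gm)
    ss_abs = (resid ** 2).sum(axis=(0, 1, 2))
    eff(ss_ab, ss_abs, (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1), "AxB")
    return out


def one_sample_t(maps: np.ndarray) -> tuple[np.ndarray, int]:
    """One-sample t against zero. ``maps``: (n_subjects, ...)."""
    x = np.asarray(maps, dtype=np.float64)
    n = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.maximum(sd / np.sqrt(n), 1e-300)
    return np.nan_to_num(t), n - 1


# ---------------------------------------------------------------------------
# clustering

@dataclass
class Cluster:
    channels: np.ndarray                 # channel indices in the cluster
    time_indices: Optional[np.ndarray]   # None for channel-only maps
    mass: float
    p_fwe: float = np.nan

    def time_window_s(self, times: np.ndarray) -> tuple[float, float]:
        if self.time_indices is None:
            raise ValueError("channel-only cluster has no time window")
        return float(times[self.time_indices.min()]), \
            float(times[self.time_indices.max()])


@dataclass
class ClusterResult:
    clusters: list[Cluster] = field(default_factory=list)
    forming_threshold: float = np.nan
    forming_p: float = 1e-3
    n_permutations: int = 0

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_fwe < alpha]


def find_clusters(stat: np.ndarray, threshold: float,
                  adjacency: np.ndarray, two_sided: bool = False
                  ) -> list[Cluster]:
    """Connected suprathreshold clusters of a (ch,) or (ch, T) statistic map.

    Connectivity: channel adjacency at the same time point plus temporal
    contiguity within a channel.  For two-sided statistics clusters are
    formed on |stat| (positive and negative points may merge only through
    suprathreshold paths, which cannot happen for contiguous smooth maps of
    opposite sign at the same location).
    """
    values = np.abs(stat) if two_sided else stat
    chan_only = values.ndim == 1
    grid = values[:, None] if chan_only else values
    exceed = grid > threshold
    n_ch, n_t = grid.shape
    visited = np.zeros_like(exceed)
    neighbors_of = [np.flatnonzero(adjacency[c]) for c in range(n_ch)]
    clusters = []
    for c0, t0 in zip(*np.nonzero(exceed)):
        if visited[c0, t0]:
            continue
        stack, members = [(c0, t0)], []
        visited[c0, t0] = True
        while stack:
            c, t = stack.pop()
            members.append((c, t))
            for t2 in (t - 1, t + 1):
                if 0 <= t2 < n_t and exceed[c, t2] and not visited[c, t2]:
                    visited[c, t2] = True
                    stack.append((c, t2))
            for c2 in neighbors_of[c]:
                if exceed[c2, t] and not visited[c2, t]:
                    visited[c2, t] = True
                    stack.append((c2, t))
        ch = np.unique([m[0] for m in members])
        ti = None if chan_only else np.unique([m[1] for m in members])
        mass = float(sum(grid[c, t] for c, t in members))
        clusters.append(Cluster(channels=ch, time_indices=ti, mass=mass))
    clusters.sort(key=lambda c: -c.mass)
    return clusters


def max_cluster_mass(stat: np.ndarray, threshold: float,
                     adjacency: np.ndarray, two_sided: bool = False) -> float:
    cl = find_clusters(stat, threshold, adjacency, two_sided)
    return cl[0].mass if cl else 0.0


def attach_pvalues(clusters: list[Cluster], null_masses: np.ndarray
                   ) -> list[Cluster]:
    null_masses = np.asarray(null_masses)
    for c in clusters:
        c.p_fwe = float((1 + np.sum(null_masses >= c.mass))
                        / (1 + len(null_masses)))
    return clusters


# ---------------------------------------------------------------------------
# permutation schemes

def sign_flip_t_maps(contrasts: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t-maps of sign-flipped subject contrasts, vectorized over flips.

    ``contrasts``: (n, ...); ``signs``: (n_perm, n).  Uses the identity that
    the second moment is flip-invariant.
    """
    n = contrasts.shape[0]
    flat = contrasts.reshape(n, -1)
    sq = (flat ** 2).sum(axis=0)
    mean = signs @ flat / n                       # (n_perm, p)
    var = (sq[None] - n * mean ** 2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.maximum(np.sqrt(var / n), 1e-300)
    return np.nan_to_num(t).reshape(signs.shape[0], *contrasts.shape[1:])


def cluster_test_1samp(contrasts: np.ndarray, adjacency: np.ndarray,
                       n_perm: int = 500, forming_p: float = 1e-3,
                       seed: int = 0) -> tuple[np.ndarray, ClusterResult]:
    """One-sample cluster-mass test of subject contrast maps against zero.

    Cluster-forming threshold: two-sided t at ``forming_p``; null from
    random sign flips of whole subjects.
    """
    n = contrasts.shape[0]
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    t_obs, df = one_sample_t(contrasts)
    thr = float(stats.t.isf(forming_p / 2, df))
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    t_null = sign_flip_t_maps(contrasts, signs)
    null = np.array([max_cluster_mass(t_null[i], thr, adjacency, True)
                     for i in range(n_perm)])
    clusters = attach_pvalues(find_clusters(t_obs, thr, adjacency, True), null)
    result = ClusterResult(clusters=clusters, forming_threshold=thr,
                           forming_p=forming_p, n_permutations=n_perm)
    return t_obs, result


def cluster_test_rm1way(values: np.ndarray, adjacency: np.ndarray,
                        n_perm: int = 500, forming_p: float = 1e-3,
                        seed: int = 0) -> tuple[np.ndarray, ClusterResult]:
    """One-way within-subject F cluster-mass test.

    ``values``: (n_subjects, k, channels[, time]).  Null: condition labels
    permuted independently within each subject.
    """
    n, k = values.shape[:2]
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    f_obs, (df1, df2) = rm_anova_1way(values)
    thr = float(stats.f.isf(forming_p, df1, df2))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = np.stack([values[s][rng.permutation(k)] for s in range(n)])
        f_p, _ = rm_anova_1way(perm)
        null[i] = max_cluster_mass(f_p, thr, adjacency)
    clusters = attach_pvalues(find_clusters(f_obs, thr, adjacency), null)
    result = ClusterResult(clusters=clusters, forming_threshold=thr,
                           forming_p=forming_p, n_permutations=n_perm)
    return f_obs, result
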