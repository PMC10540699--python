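"""Condition-wise ERPs and the univariate channel x time statistics.

Subject-level condition ERPs (robust trial averages) enter a 3 x 3
within-subject ANOVA — Contents (standard, deviant ID, deviant BD) x Time
(isochronous, interval-based, beat-based) — plus a planned 2 x 2 congruence
contrast: Contents (deviant ID, deviant BD) x Time (interval-based,
beat-based) with weights (+1, -1, -1, +1), which is nonzero exactly when the
deviant-type effect depends on the timing regime.  Maps are spatially
smoothed, and familywise error over channels x time is controlled by
permutation max-cluster-mass inference (cluster-forming p < 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cluster_stats import (ClusterResult, cluster_test_1samp, one_sample_t,
                            rm_anova_2way)
from .containers import EpochsSet
from .montage import channel_adjacency, gaussian_channel_smoother
from .preprocess import robust_average

CONTENTS = ("standard", "deviant_ID", "deviant_BD")
TIMES = ("isochronous", "interval_based", "beat_based")
CONGRUENCE_TIMES = ("interval_based", "beat_based")


@dataclass
class ConditionERP:
    """All 9 Contents x Time cell waveforms for one subject."""

    waveforms: np.ndarray            # (3 contents, 3 times, channels, time)
    times: np.ndarray
    channel_names: list[str]
    channel_positions: np.ndarray
    subject: int | None = None
    #: designated standards split by position type, for the standards-only
    #: control: (2 [ID, BD], 3 times, channels, time)
    standards_by_position: np.ndarray | None = None


def build_condition_erps(epochs: EpochsSet, robust: bool = True
                         ) -> ConditionERP:
    """Robust-average every Contents x Time cell (standards pool both
    designated positions; the split is kept for the control analysis)."""
    n_ch, n_t = epochs.data.shape[1:]
    waves = np.zeros((3, 3, n_ch, n_t))
    by_pos = np.zeros((2, 3, n_ch, n_t))
    avg = (lambda d: robust_average(d, fs=epochs.sample_rate_hz)) if robust \
        else (lambda d: d.mean(axis=0))
    for i, content in enumerate(CONTENTS):
        for j, time in enumerate(TIMES):
            cell = epochs.select(content=content, condition=time)
            if cell.data.shape[0] < 2:
                raise ValueError(f"cell {content} x {time} has "
                                 f"{cell.data.shape[0]} trials (<2)")
            waves[i, j] = avg(cell.data)
            if content == "standard":
                for k, pos in enumerate(("ID", "BD")):
                    sub = cell.select(position_type=pos)
                    if sub.data.shape[0] >= 2:
                        by_pos[k, j] = avg(sub.data)
    return ConditionERP(waveforms=waves, times=epochs.times,
                        channel_names=list(epochs.channel_names),
                        channel_positions=epochs.channel_positions,
                        subject=epochs.subject,
                        standards_by_position=by_pos)


def stack_cohort(erps: list[ConditionERP]) -> np.ndarray:
    """(n_subjects, 3, 3, channels, time) cell array from subject ERPs."""
    return np.stack([e.waveforms for e in erps])


# ---------------------------------------------------------------------------
# smoothing

def smooth_topo_time(maps: np.ndarray, pos2d: np.ndarray,
                     fwhm_mm: float = 5.0) -> np.ndarray:
    """Spatial Gaussian smoothing across the channel axis (axis -2); the
    time axis is left untouched.  The smoothing matrix is doubly stochastic,
    so constant maps are unchanged and total mass is conserved."""
    w = gaussian_channel_smoother(pos2d, fwhm_mm)
    return np.einsum("cd,...dt->...ct", w, maps)


def _smooth_cells(cells: np.ndarray, pos2d: np.ndarray, fwhm_mm: float
                  ) -> np.ndarray:
    if cells.ndim == 4:   # subjects x k x ch x t
        return smooth_topo_time(cells, pos2d, fwhm_mm)
    return smooth_topo_time(cells.reshape(-1, *cells.shape[-2:]), pos2d,
                            fwhm_mm).reshape(cells.shape)


# ---------------------------------------------------------------------------
# ANOVA maps and contrasts

def anova_map(cells: np.ndarray, pos2d: np.ndarray, fwhm_mm: float = 5.0
              ) -> dict[str, tuple[np.ndarray, tuple[int, int]]]:
    """Within-subject F maps of the 3 x 3 design.

    ``cells``: (n_subjects, 3 contents, 3 times, channels, time).  Returns
    F maps and dfs for 'contents', 'time' and 'interaction'.
    """
    if cells.ndim != 5 or cells.shape[1:3] != (3, 3):
        raise ValueError("expected (n, 3, 3, channels, time) cell array")
    sm = _smooth_cells(cells, pos2d, fwhm_mm)
    res = rm_anova_2way(sm)
    return {"contents": res["A"], "time": res["B"], "interaction": res["AxB"]}


def mismatch_contrast_maps(cells: np.ndarray) -> np.ndarray:
    """Subject-level deviant-minus-standard maps, pooled over deviant types
    and timing conditions.  ``cells``: (n, 3, 3, ch, t)."""
    deviants = cells[:, 1:, :, :, :].mean(axis=(1, 2))
    standards = cells[:, 0, :, :, :].mean(axis=1)
    return deviants - standards


def congruence_contrast_maps(deviant_cells: np.ndarray) -> np.ndarray:
    """Subject-level 2 x 2 interaction maps with weights (+1, -1, -1, +1).

    ``deviant_cells``: (n, 2 contents [ID, BD], 2 times [interval, beat],
    channels, time).  Zero whenever the cell means are additive.
    """
    if deviant_cells.shape[1:3] != (2, 2):
        raise ValueError("expected (n, 2, 2, channels, time)")
    return (deviant_cells[:, 0, 0] - deviant_cells[:, 0, 1]
            - deviant_cells[:, 1, 0] + deviant_cells[:, 1, 1])


def extract_deviant_cells(cells: np.ndarray) -> np.ndarray:
    """(n, 2, 2, ch, t) deviant cells in (ID, BD) x (interval, beat) order
    from the full (n, 3, 3, ch, t) array."""
    return cells[:, 1:3][:, :, 1:3]


def mismatch_test(cells: np.ndarray, pos2d: np.ndarray,
                  adjacency: np.ndarray | None = None, n_perm: int = 500,
                  fwhm_mm: float = 5.0, forming_p: float = 1e-3,
                  seed: int = 0) -> tuple[np.ndarray, ClusterResult]:
    """Cluster test of the deviant-vs-standard difference (sign flips)."""
    if adjacency is None:
        adjacency = channel_adjacency(pos2d)
    maps = smooth_topo_time(mismatch_contrast_maps(cells), pos2d, fwhm_mm)
    return cluster_test_1samp(maps, adjacency, n_perm=n_perm,
                              forming_p=forming_p, seed=seed)


def congruence_test(cells: np.ndarray, pos2d: np.ndarray,
                    adjacency: np.ndarray | None = None, n_perm: int = 500,
                    fwhm_mm: float = 5.0, forming_p: float = 1e-3,
                    seed: int = 0) -> tuple[np.ndarray, ClusterResult]:
    """Cluster test of the planned 2 x 2 congruence interaction."""
    if adjacency is None:
        adjacency = channel_adjacency(pos2d)
    maps = smooth_topo_time(congruence_contrast_maps(extract_deviant_cells(cells)),
                            pos2d, fwhm_mm)
    return cluster_test_1samp(maps, adjacency, n_perm=n_perm,
                              forming_p=forming_p, seed=seed)


def standards_control(erps: list[ConditionERP], pos2d: np.ndarray,
                      adjacency: np.ndarray | None = None, n_perm: int = 500,
                      fwhm_mm: float = 5.0, forming_p: float = 1e-3,
                      seed: int = 0) -> tuple[np.ndarray, ClusterResult]:
    """Congruence machinery applied to designated standards instead of
    deviants: standard_ID/standard_BD x interval/beat."""
    for e in erps:
        if e.standards_by_position is None:
            raise ValueError("standards not separable by position type")
    cells = np.stack([e.standards_by_position[:, 1:3] for e in erps])
    if adjacency is None:
        adjacency = channel_adjacency(pos2d)
    maps = smooth_topo_time(congruence_contrast_maps(cells), pos2d, fwhm_mm)
    return cluster_test_1samp(maps, adjacency, n_perm=n_perm,
                              forming_p=forming_p, seed=seed)


# ---------------------------------------------------------------------------
# post-hocs and subject indices

def posthoc_pairwise(cell_values: np.ndarray, pairs: list[tuple[int, int]],
                     n_comparisons: int | None = None) -> list[dict]:
    """Paired t-tests on cluster-averaged amplitudes, Bonferroni-corrected.

    ``cell_values``: (n_subjects, n_cells)."""
    n_comparisons = n_comparisons or len(pairs)
    out = []
    for i, j in pairs:
        t, p = stats.ttest_rel(cell_values[:, i], cell_values[:, j])
        out.append({"pair": (i, j), "t": float(t), "p": float(p),
                    "p_bonferroni": float(min(1.0, p * n_comparisons))})
    return out


def cluster_mean(maps: np.ndarray, cluster) -> np.ndarray:
    """Average a (…, channels, time) map over a cluster's channel x time
    extent."""
    sub = maps[..., cluster.channels, :]
    if cluster.time_indices is not None:
        sub = sub[..., cluster.time_indices]
    return sub.mean(axis=(-2, -1))


def subject_indices(cells: np.ndarray, mismatch_cluster,
                    congruence_cluster) -> dict[str, np.ndarray]:
    """Per-subject mismatch and congruence indices over the group cluster
    masks.

    mismatch_index: |deviant| - |standard| cluster-averaged amplitude,
    pooled over deviant types and timing conditions.  congruence_index:
    congruent-deviant minus incongruent-deviant cluster-averaged amplitude.
    """
    dev = cluster_mean(cells[:, 1:, :, :, :].mean(axis=(1, 2)),
                       mismatch_cluster)
    std = cluster_mean(cells[:, 0, :, :, :].mean(axis=1), mismatch_cluster)
    mismatch = np.abs(dev) - np.abs(std)
    d = extract_deviant_cells(cells)
    congruent = (d[:, 0, 0] + d[:, 1, 1]) / 2.0     # ID x interval, BD x beat
    incongruent = (d[:, 1, 0] + d[:, 0, 1]) / 2.0
    congruence = cluster_mean(congruent - incongruent, congruence_cluster)
    return {"mismatch_index": mismatch, "congruence_index": congruence}
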