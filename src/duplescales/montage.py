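"""64-channel sensor layout (10-10 names) with a 2-D scalp projection.

Coordinates come from the bundled standard 10-05 montage; the azimuthal
equidistant projection is scaled so the scalp disc has a 20 mm radius, which
puts the median inter-channel spacing near 5 mm — the scale on which the
5 mm FWHM topography smoothing operates.
"""

from __future__ import annotations

import functools
import re
import warnings

import numpy as np
from scipy.spatial import Delaunay

#: ANT-style 64-channel 10-10 cap; Fpz is required by the blink machinery.
CHANNELS_64 = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2", "Iz",
)

PROJECTION_RADIUS_MM = 20.0


@functools.lru_cache(maxsize=None)
def _positions_3d() -> np.ndarray:
    import mne
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        monty = mne.channels.make_standard_montage("standard_1005")
    pos = monty.get_positions()["ch_pos"]
    return np.array([pos[name] for name in CHANNELS_64])


def positions_2d(names=CHANNELS_64) -> np.ndarray:
    """Azimuthal-equidistant projection (mm on the projection scale)."""
    xyz = _positions_3d()
    xyz = xyz - xyz.mean(axis=0) * np.array([1.0, 1.0, 0.0])  # recentre x/y
    r = np.linalg.norm(xyz, axis=1)
    unit = xyz / r[:, None]
    theta = np.arccos(np.clip(unit[:, 2], -1, 1))   # polar angle from vertex
    phi = np.arctan2(unit[:, 1], unit[:, 0])
    rho = theta / theta.max() * PROJECTION_RADIUS_MM
    out = np.column_stack([rho * np.cos(phi), rho * np.sin(phi)])
    idx = [CHANNELS_64.index(n) for n in names]
    return out[idx]


def mirror_pairs(names=CHANNELS_64) -> dict[str, str]:
    """Left-right homologue map (F3<->F4, T7<->T8, ...); midline maps to itself.

    Numbering follows the 10-10 convention: odd = left, even = right,
    homologues are (2k-1, 2k).
    """
    out = {}
    for name in names:
        m = re.fullmatch(r"([A-Za-z]+?)(z|\d+)", name)
        if m is None:
            raise ValueError(f"cannot parse channel name {name!r}")
        prefix, num = m.groups()
        if num == "z":
            out[name] = name
            continue
        n = int(num)
        partner = f"{prefix}{n + 1 if n % 2 else n - 1}"
        if partner not in names:
            raise ValueError(f"channel {name} has no mirror partner in layout")
        out[name] = partner
    return out


def gaussian_channel_smoother(pos2d: np.ndarray, fwhm_mm: float = 5.0,
                              n_sinkhorn: int = 50, tol: float = 1e-10
                              ) -> np.ndarray:
    """Doubly-stochastic Gaussian smoothing matrix over channels.

    Built from a symmetric Gaussian kernel on the projected inter-channel
    distances and balanced by Sinkhorn iterations, so a constant map is left
    unchanged (rows sum to 1) and total mass is conserved (columns sum to 1).
    FWHM -> 0 reduces to the identity.
    """
    if fwhm_mm <= 0:
        return np.eye(len(pos2d))
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    d2 = np.sum((pos2d[:, None, :] - pos2d[None, :, :]) ** 2, axis=-1)
    k = np.exp(-0.5 * d2 / sigma ** 2)
    for _ in range(n_sinkhorn):
        # symmetric scaling keeps K symmetric; at convergence it is doubly
        # stochastic
        scale = 1.0 / np.sqrt(k.sum(axis=1))
        k = k * scale[:, None] * scale[None, :]
        if abs(k.sum(axis=1) - 1.0).max() < tol:
            break
    return k


def channel_adjacency(pos2d: np.ndarray, prune_factor: float = 1.5) -> np.ndarray:
    """Boolean channel adjacency from a Delaunay triangulation of the 2-D
    positions, pruning edges longer than ``prune_factor`` x median edge."""
    tri = Delaunay(pos2d)
    n = len(pos2d)
    adj = np.zeros((n, n), dtype=bool)
    edges = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = sorted((simplex[i], simplex[(i + 1) % 3]))
            edges.add((a, b))
    lengths = {e: np.linalg.norm(pos2d[e[0]] - pos2d[e[1]]) for e in edges}
    cutoff = prune_factor * np.median(list(lengths.values()))
    for (a, b), d in lengths.items():
        if d <= cutoff:
            adj[a, b] = adj[b, a] = True
    return adj
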