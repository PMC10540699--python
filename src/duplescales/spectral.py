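"""Inter-trial phase coherence (ITPC) over whole-sequence epochs.

For each trial (one full 56-tone sequence), the Fourier phase at the exact
analysis frequencies is taken by an explicit single-frequency DFT (the trials
differ slightly in duration across timing regimes, so no common FFT bin grid
exists).  Phase consistency across the N trials of a condition is

    ITPC_f = ([sum cos phi_f]^2 + [sum sin phi_f]^2) / N,

which ranges from ~1 under uniform phases (its expectation) to N at perfect
coherence.  A conventional normalized variant (resultant length in [0, 1])
is available; condition contrasts are unaffected at fixed N because the two
scales are monotonically related.

The analysis frequencies are the element rate (4.048 Hz), the pair rate
(2.024 Hz) and their flanking neighbor frequencies used by the peak tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .cluster_stats import ClusterResult, cluster_test_rm1way, rm_anova_1way
from .montage import gaussian_channel_smoother, mirror_pairs
from .paradigm import Schedule, TimingCondition, synthesize_audio


@dataclass(frozen=True)
class RateSpec:
    element_rate: float = 4.048
    pair_rate: float = 2.024
    element_neighbors: tuple[float, float] = (3.974, 4.124)
    pair_neighbors: tuple[float, float] = (1.949, 2.099)

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([*self.pair_neighbors[:1], self.pair_rate,
                         self.pair_neighbors[1], self.element_neighbors[0],
                         self.element_rate, self.element_neighbors[1]])

    def target_and_neighbors(self, which: str) -> tuple[float, tuple[float, float]]:
        if which == "element":
            return self.element_rate, self.element_neighbors
        if which == "pair":
            return self.pair_rate, self.pair_neighbors
        raise ValueError(f"unknown rate {which!r}")


DEFAULT_RATES = RateSpec()


@dataclass
class ITPCSpectrum:
    values: np.ndarray          # channels x frequencies, in [0, n_trials]
    frequencies_hz: np.ndarray
    n_trials: int
    condition: str
    half: str = "all"

    def at(self, freq_hz: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.frequencies_hz - freq_hz)))
        if abs(self.frequencies_hz[i] - freq_hz) > 1e-6:
            raise KeyError(f"frequency {freq_hz} Hz not in spectrum")
        return self.values[:, i]


# ---------------------------------------------------------------------------
# single-frequency DFT

def exact_dft(x: np.ndarray, fs: float, freqs_hz) -> np.ndarray:
    """Complex inner product with e^(-i 2 pi f t) at exact frequencies.

    ``x``: (..., n_samples); returns (..., n_freqs).  cos(2 pi f t) yields
    phase 0, sin(2 pi f t) yields phase -pi/2.
    """
    freqs = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    if np.any(freqs > fs / 2):
        raise ValueError("requested frequency above Nyquist")
    t = np.arange(x.shape[-1]) / fs
    basis = np.exp(-2j * np.pi * freqs[:, None] * t[None, :])
    return x @ basis.T


def sequence_phase(segment: np.ndarray, fs: float, freqs_hz) -> np.ndarray:
    """Fourier phase (rad) of a trial segment at the exact frequencies."""
    return np.angle(exact_dft(segment, fs, freqs_hz))


def itpc(phases: np.ndarray, axis: int = 0, normalized: bool = False
         ) -> np.ndarray:
    """Inter-trial phase coherence across the trial axis.

    As printed: (sum cos)^2 + (sum sin)^2 over N; ``normalized`` instead
    returns the mean resultant length |sum e^(i phi)| / N in [0, 1].
    """
    phases = np.asarray(phases)
    n = phases.shape[axis]
    if n < 1:
        raise ValueError("ITPC needs at least one trial")
    c = np.cos(phases).sum(axis=axis)
    s = np.sin(phases).sum(axis=axis)
    r2 = c ** 2 + s ** 2
    return np.sqrt(r2) / n if normalized else r2 / n


def onset_train_peak_hz(onsets_s, f_min_hz: float = 3.0,
                        f_max_hz: float = 5.0, df_hz: float = 0.001) -> float:
    """Frequency of the spectral maximum of a unit impulse train at the given
    onset times, searched on a dense grid within [f_min, f_max]."""
    onsets = np.asarray(onsets_s, dtype=float)
    freqs = np.arange(f_min_hz, f_max_hz + df_hz / 2, df_hz)
    mag = np.abs(np.exp(-2j * np.pi * freqs[:, None] * onsets[None, :]).sum(axis=1))
    return float(freqs[int(np.argmax(mag))])


# ---------------------------------------------------------------------------
# spectra from trial segments

def itpc_spectra(segments: Iterable[tuple[object, np.ndarray]], fs: float,
                 rates: RateSpec = DEFAULT_RATES,
                 halves: Optional[dict[int, str]] = None,
                 ) -> dict[tuple[str, str], ITPCSpectrum]:
    """ITPC per (condition, half) from an iterable of (trial, channels x time).

    Phases are computed per trial over its own full duration.  Keys are
    (condition, 'all') plus, when ``halves`` maps trial_index -> half,
    (condition, 'first'/'second').
    """
    freqs = rates.frequencies
    bucket: dict[tuple[str, str], list[np.ndarray]] = {}
    for trial, seg in segments:
        ph = sequence_phase(seg, fs, freqs)
        cond = trial.condition.value
        bucket.setdefault((cond, "all"), []).append(ph)
        if halves is not None:
            bucket.setdefault((cond, halves[trial.trial_index]), []).append(ph)
    out = {}
    for (cond, half), phs in bucket.items():
        arr = np.stack(phs)              # trials x channels x freqs
        out[(cond, half)] = ITPCSpectrum(values=itpc(arr, axis=0),
                                         frequencies_hz=freqs,
                                         n_trials=arr.shape[0],
                                         condition=cond, half=half)
    return out


# ---------------------------------------------------------------------------
# statistics

def peak_test(subject_spectra: np.ndarray, freqs_hz: np.ndarray,
              rates: RateSpec = DEFAULT_RATES, which: str = "element"
              ) -> dict[str, float]:
    """Paired t-test of channel-averaged ITPC at the target rate vs the mean
    of its neighbor frequencies, across subjects.

    ``subject_spectra``: (n_subjects, n_freqs), already channel-averaged.
    Positive t means target exceeds neighbors.
    """
    x = np.asarray(subject_spectra, dtype=np.float64)
    if x.shape[0] < 2:
        raise ValueError("peak test needs at least 2 subjects")
    target, nb = rates.target_and_neighbors(which)
    idx = lambda f: int(np.argmin(np.abs(freqs_hz - f)))
    tgt = x[:, idx(target)]
    ngb = (x[:, idx(nb[0])] + x[:, idx(nb[1])]) / 2.0
    diff = tgt - ngb
    if np.allclose(diff, 0.0, atol=1e-12 * max(1.0, np.abs(x).max())):
        t, p = 0.0, 1.0          # degenerate: target equals neighbors
    else:
        t, p = stats.ttest_rel(tgt, ngb)
    return {"t": float(t), "p": float(p), "df": x.shape[0] - 1,
            "mean_target": float(tgt.mean()), "mean_neighbors": float(ngb.mean())}


def condition_anova_topo(maps: np.ndarray, pos2d: np.ndarray,
                         adjacency: np.ndarray, n_perm: int = 500,
                         fwhm_mm: float = 5.0, forming_p: float = 1e-3,
                         seed: int = 0) -> dict:
    """Channel-wise within-subject ANOVA of ITPC topographies over the three
    timing conditions, with permutation cluster-mass correction.

    ``maps``: (n_subjects, 3, n_channels) single-rate ITPC values, condition
    order (isochronous, interval_based, beat_based).  Maps are spatially
    smoothed first.  Post-hoc pairwise t-tests on cluster-averaged values are
    Bonferroni-corrected over the 3 comparisons.
    """
    w = gaussian_channel_smoother(pos2d, fwhm_mm)
    smoothed = maps @ w.T
    f_map, result = cluster_test_rm1way(smoothed, adjacency, n_perm=n_perm,
                                        forming_p=forming_p, seed=seed)
    posthoc = {}
    if result.significant():
        mask = result.significant()[0].channels
        cell = smoothed[:, :, mask].mean(axis=2)      # subjects x 3
        pairs = [(0, 1, "isochronous_vs_interval"),
                 (0, 2, "isochronous_vs_beat"),
                 (1, 2, "interval_vs_beat")]
        for i, j, name in pairs:
            t, p = stats.ttest_rel(cell[:, i], cell[:, j])
            posthoc[name] = {"t": float(t), "p": float(p),
                             "p_bonferroni": float(min(1.0, p * 3))}
    return {"f_map": f_map, "clusters": result, "posthoc": posthoc,
            "smoothed_maps": smoothed}


def split_half_anova(subject_rate_itpc: np.ndarray) -> pd.DataFrame:
    """Per-half one-way rm-ANOVAs of channel-averaged ITPC at the two rates.

    ``subject_rate_itpc``: (n_subjects, 2 rates [pair, element], 3 conditions,
    2 halves).  Returns one row per (rate, half) with F, p, and
    Benjamini-Hochberg q over the 4 tests.
    """
    from statsmodels.stats.multitest import multipletests
    x = np.asarray(subject_rate_itpc, dtype=np.float64)
    rows = []
    for r, rate in enumerate(("pair", "element")):
        for h, half in enumerate(("first", "second")):
            f, (df1, df2) = rm_anova_1way(x[:, r, :, h])
            p = float(stats.f.sf(f, df1, df2))
            rows.append({"rate": rate, "half": half, "F": float(f),
                         "df1": df1, "df2": df2, "p": p})
    df = pd.DataFrame(rows)
    df["p_fdr"] = multipletests(df["p"], alpha=0.05, method="fdr_bh")[1]
    df["significant_fdr"] = multipletests(df["p"], alpha=0.05,
                                          method="fdr_bh")[0]
    return df


def flip_lr(topography: np.ndarray, names) -> np.ndarray:
    """Swap values between left-right mirror-paired channels (midline fixed)."""
    pairs = mirror_pairs(tuple(names))
    names = list(names)
    idx = np.array([names.index(pairs[n]) for n in names])
    return np.asarray(topography)[..., idx]


# ---------------------------------------------------------------------------
# stimulus spectrum

def stimulus_itpc(schedule: Schedule, fs: float = 16000.0,
                  rates: RateSpec = DEFAULT_RATES,
                  max_trials_per_condition: Optional[int] = None,
                  ) -> dict[str, ITPCSpectrum]:
    """ITPC of the stimulus itself: Hilbert amplitude envelopes of the
    synthesized trial audio run through the same phase/ITPC machinery."""
    from scipy.signal import hilbert
    freqs = rates.frequencies
    bucket: dict[str, list[np.ndarray]] = {}
    counts: dict[str, int] = {}
    for trial in schedule.trials:
        cond = trial.condition.value
        if (max_trials_per_condition is not None
                and counts.get(cond, 0) >= max_trials_per_condition):
            continue
        counts[cond] = counts.get(cond, 0) + 1
        wave = synthesize_audio(trial, fs)
        env = np.abs(hilbert(wave))
        bucket.setdefault(cond, []).append(sequence_phase(env, fs, freqs))
    return {cond: ITPCSpectrum(values=itpc(np.stack(phs), axis=0)[None, :],
                               frequencies_hz=freqs, n_trials=len(phs),
                               condition=cond)
            for cond, phs in bucket.items()}
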