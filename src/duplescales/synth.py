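"""Synthetic EEG and behavior with the statistical structure the analysis assumes.

The generator emulates a 64-channel, 1024 Hz recording of the duple-scale
experiment:

* 1/f background noise (spectrally shaped white noise, mild spatial mixing),
* tone-evoked responses (an N1-like kernel per tone, scaled with tone level),
* condition-gated entrainment: sinusoids at the element rate (1/0.247 s) and
  pair rate (1/0.494 s) whose trial-to-trial phase offsets are von-Mises
  distributed with concentration kappa — kappa and amplitude control the
  measurable inter-trial phase coherence directly,
* a mismatch kernel on deviant tones peaking near 198 ms (inside the
  173-223 ms mismatch-response window) with an anterior-posterior topography,
* a congruence kernel near 155 ms (inside 130-180 ms) with a left
  central-posterior topography, applied only to temporally congruent deviants
  (ID deviants in interval-based trials, BD deviants in beat-based trials),
* eyeblinks (biphasic 400 ms template, Poisson arrivals, frontal-polar
  topography) in the continuous path,
* per-condition behavioral hit probabilities and log-normal reaction times,
  with pair-rate phase locking and beat-condition RTs improving only in the
  second half of the experiment.

Two generation paths share the same kernels and topographies: a full
continuous path (``synth_recording``, used with the preprocessing chain) and
fast paths that draw epochs or whole-sequence segments directly at the
analysis sampling rate (``synth_epochs``, ``synth_sequence_segments``),
which is how the statistical calibration studies are run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from . import paradigm
from .containers import EpochsSet, Recording
from .montage import CHANNELS_64, positions_2d
from .paradigm import (Role, Schedule, TimingCondition, condition_halves,
                       trial_start_times)

ELEMENT_RATE_HZ = 1.0 / paradigm.ELEMENT_SOA_S   # ~4.049 Hz
PAIR_RATE_HZ = 1.0 / paradigm.PAIR_SOA_S         # ~2.024 Hz

EPOCH_TMIN_S = -0.050
EPOCH_TMAX_S = 0.247
BASELINE_S = (-0.025, 0.025)

#: deviant type congruent with each timing regime
CONGRUENT_DEVIANT = {
    TimingCondition.interval_based.value: Role.deviant_ID.value,
    TimingCondition.beat_based.value: Role.deviant_BD.value,
}


@dataclass
class SynthEEGParams:
    """Generative parameters; amplitudes in µV, concentrations unitless."""

    n_channels: int = 64
    sample_rate_hz: float = 1024.0
    noise_1f_exponent: float = 1.0
    noise_scale: float = 10.0            # µV RMS per channel, broadband
    noise_spatial_sigma_mm: float = 4.0  # on the 2-D projection scale
    entrain_amp: dict = field(default_factory=lambda: {
        ("element", "isochronous"): 1.2,
        ("element", "beat_based"): 1.2,
        ("element", "interval_based"): 0.3,
        ("pair", "isochronous"): 0.0,
        ("pair", "beat_based"): 1.2,
        ("pair", "interval_based"): 0.0,
    })
    #: phase concentration per (rate, condition, half); pair-rate locking in
    #: the beat-based regime emerges with experience, hence the half gating
    entrain_kappa: dict = field(default_factory=lambda: {
        ("pair", "beat_based", "first"): 0.0,
        ("pair", "beat_based", "second"): 6.0,
    })
    entrain_kappa_default: float = 6.0
    erp_amp: float = 0.5
    mismatch_amp: float = 3.0
    congruence_amp: float = 5.0
    congruence_on_standards: bool = False   # negative-control switch
    blink_rate_hz: float = 0.10
    blink_amp_uv: float = 120.0
    subject_sigma: float = 0.3              # log-normal SD of subject effects

    def kappa(self, rate: str, condition: str, half: str) -> float:
        return float(self.entrain_kappa.get((rate, condition, half),
                                            self.entrain_kappa_default))

    def amp(self, rate: str, condition: str) -> float:
        return float(self.entrain_amp.get((rate, condition), 0.0))


@dataclass
class SynthBehaviorParams:
    hit_prob: dict = field(default_factory=lambda: {
        "isochronous": 0.6775, "interval_based": 0.6912, "beat_based": 0.6388,
    })
    #: median RT (s) per (condition, half); beat-based speeds up with practice
    rt_median_s: dict = field(default_factory=lambda: {
        ("isochronous", "first"): 0.511, ("isochronous", "second"): 0.511,
        ("interval_based", "first"): 0.649, ("interval_based", "second"): 0.649,
        ("beat_based", "first"): 0.720, ("beat_based", "second"): 0.590,
    })
    rt_sigma_log: float = 0.35
    lapse_prob: float = 0.02


@dataclass
class SubjectSim:
    """One simulated participant: perturbed parameters plus a private seed."""
    subject: int
    eeg: SynthEEGParams
    behavior: SynthBehaviorParams
    seed: int


# ---------------------------------------------------------------------------
# kernels and topographies

def erp_kernel(t: np.ndarray) -> np.ndarray:
    """Unit-peak N1-like deflection (peak 100 ms)."""
    return np.exp(-0.5 * ((t - 0.100) / 0.018) ** 2)


def mismatch_kernel(t: np.ndarray) -> np.ndarray:
    """Unit-peak mismatch deflection (peak 198 ms, mass within 173-223 ms)."""
    return np.exp(-0.5 * ((t - 0.198) / 0.012) ** 2)


def congruence_kernel(t: np.ndarray) -> np.ndarray:
    """Unit-peak congruence deflection (peak 155 ms, mass within 130-180 ms)."""
    return np.exp(-0.5 * ((t - 0.155) / 0.012) ** 2)


def blink_template(t: np.ndarray) -> np.ndarray:
    """Biphasic ~400 ms blink waveform, unit positive peak."""
    return (np.exp(-0.5 * ((t - 0.120) / 0.050) ** 2)
            - 0.35 * np.exp(-0.5 * ((t - 0.260) / 0.070) ** 2))


def _gauss_topo(pos2d: np.ndarray, names, center: str, sigma_mm: float
                ) -> np.ndarray:
    c = pos2d[list(names).index(center)]
    d2 = np.sum((pos2d - c) ** 2, axis=1)
    return np.exp(-0.5 * d2 / sigma_mm ** 2)


def topographies(pos2d: np.ndarray, names=CHANNELS_64) -> dict[str, np.ndarray]:
    """Signed, unit-max spatial patterns for every generative component."""
    g = lambda center, s: _gauss_topo(pos2d, names, center, s)
    return {
        # fronto-central negativity for the tone-evoked N1
        "erp": -g("FCz", 10.0),
        # anterior-negative / posterior-positive mismatch pattern
        "mismatch": -g("Fz", 8.0) + 0.8 * g("POz", 8.0),
        # left central-posterior congruence pattern (negative polarity)
        "congruence": -g("CP3", 6.0),
        "entrain_element": g("Cz", 12.0),
        "entrain_pair": g("C6", 8.0),        # right-lateral
        "blink": g("Fpz", 8.0),
    }


# ---------------------------------------------------------------------------
# noise

def one_over_f_noise(rng: np.random.Generator, shape: tuple[int, ...],
                     sample_rate_hz: float, exponent: float = 1.0,
                     scale: float = 1.0, f_floor_hz: float = 0.5) -> np.ndarray:
    """1/f^exponent noise along the last axis, RMS-normalized to ``scale``.

    Spectral shaping of white noise; the amplitude profile is flattened below
    ``f_floor_hz`` so the variance stays finite.
    """
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate_hz)
    profile = 1.0 / np.maximum(freqs, f_floor_hz) ** (exponent / 2.0)
    profile[0] = 0.0   # zero-mean
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1) * profile
    x = np.fft.irfft(spec, n=n, axis=-1)
    rms = np.sqrt(np.mean(x ** 2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms * scale


def _spatial_mixer(pos2d: np.ndarray, sigma_mm: float) -> np.ndarray:
    """Row-normalized Gaussian mixing matrix giving noise a realistic
    inter-channel correlation while preserving per-channel RMS."""
    d2 = np.sum((pos2d[:, None, :] - pos2d[None, :, :]) ** 2, axis=-1)
    k = np.exp(-0.5 * d2 / sigma_mm ** 2)
    return k / np.sqrt((k ** 2).sum(axis=1, keepdims=True))


def _channel_noise(rng, n_channels, n_samples, fs, params: SynthEEGParams,
                   mixer: np.ndarray | None) -> np.ndarray:
    x = one_over_f_noise(rng, (n_channels, n_samples), fs,
                         params.noise_1f_exponent, params.noise_scale)
    if mixer is not None:
        x = mixer @ x
    return x


# ---------------------------------------------------------------------------
# subject-level random effects

def subject_eeg_params(params: SynthEEGParams, rng: np.random.Generator
                       ) -> SynthEEGParams:
    """Multiplicative log-normal perturbation of all effect amplitudes."""
    s = params.subject_sigma
    ln = lambda: float(np.exp(rng.normal(0.0, s)))
    return replace(
        params,
        erp_amp=params.erp_amp * ln(),
        mismatch_amp=params.mismatch_amp * ln(),
        congruence_amp=params.congruence_amp * ln(),
        entrain_amp={k: v * ln() for k, v in params.entrain_amp.items()},
    )


def subject_behavior_params(params: SynthBehaviorParams,
                            rng: np.random.Generator) -> SynthBehaviorParams:
    hp = {k: float(np.clip(v + rng.normal(0.0, 0.05), 0.05, 0.98))
          for k, v in params.hit_prob.items()}
    rt = {k: v * float(np.exp(rng.normal(0.0, 0.10)))
          for k, v in params.rt_median_s.items()}
    return replace(params, hit_prob=hp, rt_median_s=rt)


def synth_cohort(n_subjects: int, eeg_params: SynthEEGParams | None = None,
                 behavior_params: SynthBehaviorParams | None = None,
                 seed: int = 0) -> list[SubjectSim]:
    """Independent per-subject parameter draws and private seeds."""
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    eeg_params = eeg_params or SynthEEGParams()
    behavior_params = behavior_params or SynthBehaviorParams()
    master = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(master.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        out.append(SubjectSim(
            subject=i,
            eeg=subject_eeg_params(eeg_params, rng),
            behavior=subject_behavior_params(behavior_params, rng),
            seed=int(rng.integers(2 ** 31)),
        ))
    return out


# ---------------------------------------------------------------------------
# helpers

def _trial_phase_offsets(schedule: Schedule, params: SynthEEGParams,
                         rng: np.random.Generator) -> dict[int, dict[str, float]]:
    halves = condition_halves(schedule)
    offsets: dict[int, dict[str, float]] = {}
    for trial in schedule.trials:
        cond, half = trial.condition.value, halves[trial.trial_index]
        offsets[trial.trial_index] = {
            rate: float(rng.vonmises(0.0, params.kappa(rate, cond, half)))
            for rate in ("element", "pair")
        }
    return offsets


def _kernel_events(trial, params: SynthEEGParams):
    """(onset_s, kernel_fn, component_key, gain) contributions of one trial."""
    congruent = CONGRUENT_DEVIANT.get(trial.condition.value)
    out = []
    for tone in trial.tones:
        gain = params.erp_amp * 10.0 ** (tone.level_db / 20.0)
        out.append((tone.onset_s, erp_kernel, "erp", gain))
        role = tone.role.value
        if role in (Role.deviant_ID.value, Role.deviant_BD.value):
            out.append((tone.onset_s, mismatch_kernel, "mismatch",
                        params.mismatch_amp))
            if role == congruent and params.congruence_amp:
                out.append((tone.onset_s, congruence_kernel, "congruence",
                            params.congruence_amp))
        if params.congruence_on_standards and params.congruence_amp:
            cong_std = {Role.deviant_ID.value: Role.designated_standard_ID.value,
                        Role.deviant_BD.value: Role.designated_standard_BD.value
                        }.get(congruent or "", None)
            if role == cong_std:
                out.append((tone.onset_s, congruence_kernel, "congruence",
                            params.congruence_amp))
    return out


def _render_trial_signal(trial, params: SynthEEGParams, topo: dict,
                         fs: float, n_samples: int,
                         phase_offsets: dict[str, float]) -> np.ndarray:
    """Deterministic (noise-free) multichannel signal of one trial,
    t=0 at trial onset."""
    t = np.arange(n_samples) / fs
    sig = np.zeros((len(topo["erp"]), n_samples))
    for rate, f in (("element", ELEMENT_RATE_HZ), ("pair", PAIR_RATE_HZ)):
        a = params.amp(rate, trial.condition.value)
        if a:
            wave = a * np.cos(2 * np.pi * f * t + phase_offsets[rate])
            sig += topo[f"entrain_{rate}"][:, None] * wave[None, :]
    for onset, kernel, key, gain in _kernel_events(trial, params):
        i0 = int(round(onset * fs))
        if i0 >= n_samples:
            continue
        seg = kernel(np.arange(n_samples - i0) / fs)
        sig[:, i0:] += gain * topo[key][:, None] * seg[None, :]
    return sig


# ---------------------------------------------------------------------------
# generation paths

def synth_recording(schedule: Schedule, params: SynthEEGParams | None = None,
                    seed: int = 0) -> Recording:
    """Continuous full-fidelity recording (1/f noise + signal + blinks)."""
    params = params or SynthEEGParams()
    names = list(CHANNELS_64[:params.n_channels])
    if "Fpz" not in names:
        raise ValueError("layout must include the frontal-polar channel Fpz")
    pos = positions_2d(names)
    topo = {k: v[:params.n_channels] for k, v in topographies(positions_2d(),
                                                              CHANNELS_64).items()}
    fs = params.sample_rate_hz
    rng = np.random.default_rng(seed)
    starts = trial_start_times(schedule)
    total_s = starts[-1] + schedule.trials[-1].duration_s + \
        schedule.inter_trial_interval_s
    n = int(round(total_s * fs))
    mixer = _spatial_mixer(pos, params.noise_spatial_sigma_mm)
    data = _channel_noise(rng, len(names), n, fs, params, mixer)
    offsets = _trial_phase_offsets(schedule, params, rng)
    spans = []
    for trial in schedule.trials:
        i0 = int(round(starts[trial.trial_index] * fs))
        n_trial = int(round(trial.duration_s * fs))
        n_trial = min(n_trial, n - i0)
        data[:, i0:i0 + n_trial] += _render_trial_signal(
            trial, params, topo, fs, n_trial, offsets[trial.trial_index])
        spans.append({"trial_index": trial.trial_index, "start": i0,
                      "stop": i0 + n_trial})
    # blinks: Poisson arrivals over the whole recording
    if params.blink_rate_hz > 0:
        n_blinks = rng.poisson(params.blink_rate_hz * total_s)
        tmpl_t = np.arange(int(round(0.4 * fs))) / fs
        tmpl = blink_template(tmpl_t)
        for onset in np.sort(rng.uniform(0, total_s - 0.5, size=n_blinks)):
            i0 = int(round(onset * fs))
            amp = params.blink_amp_uv * rng.uniform(0.7, 1.3)
            data[:, i0:i0 + len(tmpl)] += amp * topo["blink"][:, None] * tmpl[None, :]
    events = paradigm.events_dataframe(schedule)
    events = events.rename(columns={"trial_type": "role"}) \
        if "trial_type" in events and "role" not in events else events
    events = events.assign(sample=np.round(events["onset"] * fs).astype(int))
    return Recording(
        data=data.astype(np.float32), sample_rate_hz=fs, channel_names=names,
        channel_positions=pos,
        events=events[list(dict.fromkeys(["sample", *events.columns]))],
        trial_spans=pd.DataFrame(spans),
    )


def synth_epochs(schedule: Schedule, params: SynthEEGParams | None = None,
                 seed: int = 0, fs: float = 300.0,
                 n_per_cell: int | None = None) -> EpochsSet:
    """Fast path: draw deviant/standard epochs directly at the analysis rate.

    Epochs are -50..247 ms around each target tone, built from spatially
    mixed 1/f noise plus the same kernels the continuous path uses (previous
    and next tone ERPs included; entrainment, whose epoch-scale contribution
    is negligible, and blinks are left to the continuous path).  Baseline
    corrected over ±25 ms.  ``n_per_cell`` optionally subsamples each
    content x condition cell.
    """
    params = params or SynthEEGParams()
    names = list(CHANNELS_64[:params.n_channels])
    pos = positions_2d(names)
    topo = {k: v[:params.n_channels]
            for k, v in topographies(positions_2d(), CHANNELS_64).items()}
    rng = np.random.default_rng(seed)
    mixer = _spatial_mixer(pos, params.noise_spatial_sigma_mm)
    halves = condition_halves(schedule)

    i0 = int(round(EPOCH_TMIN_S * fs))
    i1 = int(round(EPOCH_TMAX_S * fs))
    times = np.arange(i0, i1 + 1) / fs          # inclusive end: 90 samples
    n_t = len(times)

    rows, chunks = [], []
    for trial in schedule.trials:
        events = _kernel_events(trial, params)
        targets = [(k, tone) for k, tone in enumerate(trial.tones)
                   if tone.role in paradigm.TARGET_ROLES]
        for k, tone in targets:
            sig = np.zeros((len(names), n_t))
            for onset, kernel, key, gain in events:
                rel = times + tone.onset_s - onset
                if rel[-1] < 0 or rel[0] > 0.4:
                    continue
                w = np.where(rel >= 0, kernel(np.clip(rel, 0, None)), 0.0)
                sig += gain * topo[key][:, None] * w[None, :]
            role = tone.role.value
            content = ("standard" if role.startswith("designated") else role)
            rows.append({
                "content": content,
                "position_type": "ID" if role.endswith("ID") else "BD",
                "condition": trial.condition.value,
                "half": halves[trial.trial_index],
                "trial_index": trial.trial_index,
                "role": role,
            })
            chunks.append(sig)
    labels = pd.DataFrame(rows)
    data = np.stack(chunks)
    if n_per_cell is not None:
        keep = np.zeros(len(labels), dtype=bool)
        for _, idx in labels.groupby(["content", "condition"]).groups.items():
            idx = np.asarray(idx)
            sel = idx if len(idx) <= n_per_cell else \
                np.sort(rng.choice(idx, n_per_cell, replace=False))
            keep[sel] = True
        data, labels = data[keep], labels.loc[keep].reset_index(drop=True)
    noise = _channel_noise(rng, data.shape[0] * len(names), n_t, fs, params,
                           None).reshape(data.shape[0], len(names), n_t)
    data = data + np.einsum("ij,njt->nit", mixer, noise)
    base = np.abs(times) <= BASELINE_S[1] + 1e-9
    data -= data[:, :, base].mean(axis=2, keepdims=True)
    return EpochsSet(data=data, times=times, labels=labels,
                     sample_rate_hz=fs, channel_names=names,
                     channel_positions=pos)


def synth_sequence_segments(schedule: Schedule,
                            params: SynthEEGParams | None = None,
                            seed: int = 0, fs: float = 300.0
                            ) -> Iterator[tuple[object, np.ndarray]]:
    """Fast path for the spectral analysis: yield (trial, channels x time)
    segments spanning each full sequence (onset to offset), noise included,
    blink/filtering-free."""
    params = params or SynthEEGParams()
    names = list(CHANNELS_64[:params.n_channels])
    pos = positions_2d(names)
    topo = {k: v[:params.n_channels]
            for k, v in topographies(positions_2d(), CHANNELS_64).items()}
    rng = np.random.default_rng(seed)
    mixer = _spatial_mixer(pos, params.noise_spatial_sigma_mm)
    offsets = _trial_phase_offsets(schedule, params, rng)
    for trial in schedule.trials:
        n_samples = int(round(trial.duration_s * fs))
        sig = _render_trial_signal(trial, params, topo, fs, n_samples,
                                   offsets[trial.trial_index])
        sig += _channel_noise(rng, len(names), n_samples, fs, params, mixer)
        yield trial, sig


def synth_subject_indices(n_subjects: int, r_congruence_itpc: float = 0.65,
                          seed: int = 0) -> pd.DataFrame:
    """Subject-level index table with a controlled congruence <-> ITPC
    correlation, for exercising the across-subject correlation analysis.

    Scales mimic pipeline outputs: itpc_index (pair-rate interval-beat ITPC
    difference, second half) mean -0.4, SD 0.3; congruence_index mean -2 µV,
    SD 1.2; mismatch_index mean 1 µV, SD 0.8 (independent); behavioral
    accuracy index mean 5%, SD 4% (independent of the neural indices).
    """
    rng = np.random.default_rng(seed)
    z1, z2 = rng.standard_normal((2, n_subjects))
    r = r_congruence_itpc
    itpc_index = -0.4 + 0.3 * z1
    congruence = -2.0 + 1.2 * (r * z1 + np.sqrt(1 - r ** 2) * z2)
    return pd.DataFrame({
        "behavioral_index": 5.0 + 4.0 * rng.standard_normal(n_subjects),
        "itpc_index": itpc_index,
        "congruence_index": congruence,
        "mismatch_index": 1.0 + 0.8 * rng.standard_normal(n_subjects),
    })


def synth_behavior(schedule: Schedule,
                   params: SynthBehaviorParams | None = None,
                   seed: int = 0, subject: int | None = None) -> pd.DataFrame:
    """Simulated responses for every repetition (decoy) trial."""
    params = params or SynthBehaviorParams()
    rng = np.random.default_rng(seed)
    halves = condition_halves(schedule)
    rows = []
    for trial in schedule.trials:
        if trial.repetition_scale is None:
            continue
        cond, half = trial.condition.value, halves[trial.trial_index]
        p_hit = (1.0 - params.lapse_prob) * params.hit_prob[cond]
        hit = bool(rng.random() < p_hit)
        rt = float(rng.lognormal(np.log(params.rt_median_s[(cond, half)]),
                                 params.rt_sigma_log)) if hit else np.nan
        rows.append({"subject": subject, "trial_index": trial.trial_index,
                     "condition": cond, "half": half, "hit": hit, "rt_s": rt})
    return pd.DataFrame(rows)
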