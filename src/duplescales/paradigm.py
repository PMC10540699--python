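"""Generative model of the auditory duple-scale experiment.

The paradigm presents sequences ("trials") of seven ascending or descending
musical scales, eight tones each (56 tones per trial).  Tones form duples:
pair-initial ("stressed") tones at full level, pair-final tones 10 dB quieter.
Three timing regimes manipulate *when* predictions:

* ``isochronous`` — every onset asynchrony fixed at 247 ms (element rate
  1/0.247 s ~= 4.048 Hz),
* ``beat_based`` — pair-initial onsets on a fixed 494 ms grid (pair rate
  1/0.494 s ~= 2.024 Hz), within-pair gap jittered,
* ``interval_based`` — within-pair gap fixed at 247 ms, pair-initial onsets
  jittered around the 494 ms grid.

*What* predictions are manipulated by frequency-outlier deviants: an
interval-defining (ID) deviant replaces a scale-final (pair-final) tone and a
beat-defining (BD) deviant replaces a scale-penultimate (pair-initial) tone.
Designated standards mark the same two within-scale positions in unaltered
scales and serve as the ERP comparison tones.  A repetition decoy (immediate
tone repetition) appears in half of the trials and defines the behavioral
task.  The gap preceding every deviant and designated standard is forced to
exactly 247 ms so that evoked-response baselines are timing-matched across
regimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

TONE_DURATION_S = 0.166
ELEMENT_SOA_S = 0.247
PAIR_SOA_S = 0.494
INTER_TRIAL_INTERVAL_S = 1.0
JITTER_MULTIPLIERS = (0.667, 0.834, 1.166, 1.333)
#: additive shifts (s) applied to pair-initial onsets in the interval_based regime
JITTER_DELTAS = tuple(ELEMENT_SOA_S * (m - 1.0) for m in JITTER_MULTIPLIERS)

N_SCALES = 7
TONES_PER_SCALE = 8
TONES_PER_TRIAL = N_SCALES * TONES_PER_SCALE
N_TRIALS_DEFAULT = 240
N_BLOCKS_DEFAULT = 12
TRIALS_PER_BLOCK_DEFAULT = 20

F0_MIN_HZ = 300.0
F0_MAX_HZ = 600.0
OUTLIER_FACTOR = 0.2

#: scales eligible for deviants / repetitions / designated standards (0-based)
ALTERABLE_SCALES = (2, 3, 4, 5, 6)

ID_POSITION = 7   # scale-final, pair-final tone (0-based position in scale)
BD_POSITION = 6   # scale-penultimate, pair-initial tone


class TimingCondition(str, Enum):
    isochronous = "isochronous"
    interval_based = "interval_based"
    beat_based = "beat_based"


CONDITIONS = (
    TimingCondition.isochronous,
    TimingCondition.interval_based,
    TimingCondition.beat_based,
)


class Role(str, Enum):
    plain = "plain"
    designated_standard_ID = "designated_standard_ID"
    designated_standard_BD = "designated_standard_BD"
    deviant_ID = "deviant_ID"
    deviant_BD = "deviant_BD"
    repetition = "repetition"


TARGET_ROLES = (
    Role.deviant_ID,
    Role.deviant_BD,
    Role.designated_standard_ID,
    Role.designated_standard_BD,
)


@dataclass
class ToneEvent:
    trial_index: int
    scale_index: int
    position_in_scale: int
    onset_s: float
    f0_hz: float
    level_db: float
    role: Role = Role.plain
    duration_s: float = TONE_DURATION_S

    @property
    def is_pair_initial(self) -> bool:
        return self.position_in_scale % 2 == 0


@dataclass
class TrialSpec:
    trial_index: int
    direction: str                      # "ascending" | "descending"
    condition: TimingCondition
    scale_start_f0s: np.ndarray         # (7,) Hz
    tones: list[ToneEvent] = field(default_factory=list)
    deviant_scales: tuple[int, int] = (-1, -1)          # (ID scale, BD scale)
    repetition_scale: Optional[int] = None
    repetition_position: Optional[int] = None
    designated_standard_scales: tuple[int, int] = (-1, -1)

    @property
    def duration_s(self) -> float:
        last = self.tones[-1]
        return last.onset_s + last.duration_s

    def tones_in_scale(self, scale: int) -> list[ToneEvent]:
        return self.tones[scale * TONES_PER_SCALE:(scale + 1) * TONES_PER_SCALE]


@dataclass
class Schedule:
    trials: list[TrialSpec]
    blocks: list[list[int]]
    block_conditions: list[TimingCondition]
    seed: int
    inter_trial_interval_s: float = INTER_TRIAL_INTERVAL_S

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def trials_for(self, condition: TimingCondition) -> list[TrialSpec]:
        return [t for t in self.trials if t.condition == condition]


# ---------------------------------------------------------------------------
# scale construction

def build_scale(start_f0: float, direction: str) -> np.ndarray:
    """Eight F0 values spanning one octave in equal log steps (ratio 2^(1/7)).

    Ascending scales run from ``start_f0`` to ``2*start_f0``; descending to
    ``start_f0/2``.
    """
    if not (F0_MIN_HZ <= start_f0 <= F0_MAX_HZ):
        raise ValueError(
            f"start_f0 {start_f0} Hz outside the {F0_MIN_HZ}-{F0_MAX_HZ} Hz range"
        )
    if direction not in ("ascending", "descending"):
        raise ValueError(f"unknown direction {direction!r}")
    sign = 1.0 if direction == "ascending" else -1.0
    steps = np.arange(TONES_PER_SCALE)
    return start_f0 * 2.0 ** (sign * steps / (TONES_PER_SCALE - 1))


def outlier_f0(scale_f0s: np.ndarray, rng: np.random.Generator) -> float:
    """Frequency outlier 20% above the scale maximum or 20% below its minimum.

    The direction is chosen uniformly at random.
    """
    scale_f0s = np.asarray(scale_f0s, dtype=float)
    if rng.random() < 0.5:
        return float(scale_f0s.min() * (1.0 - OUTLIER_FACTOR))
    return float(scale_f0s.max() * (1.0 + OUTLIER_FACTOR))


# ---------------------------------------------------------------------------
# onset assignment

def assign_onsets(condition: TimingCondition, rng: np.random.Generator,
                  n_tones: int = TONES_PER_TRIAL) -> np.ndarray:
    """Onset times (s from trial start) for one trial under a timing regime.

    Onset asynchronies are onset-to-onset (SOA): the 247 ms element interval
    with 166 ms tones yields the 4.048 Hz element rate and the 494 ms pair
    interval the 2.024 Hz pair rate.
    """
    condition = TimingCondition(condition)
    if n_tones % 2:
        raise ValueError("n_tones must be even (duple structure)")
    n_pairs = n_tones // 2
    onsets = np.empty(n_tones)
    if condition is TimingCondition.isochronous:
        return np.arange(n_tones) * ELEMENT_SOA_S
    if condition is TimingCondition.beat_based:
        initial = np.arange(n_pairs) * PAIR_SOA_S
        gaps = ELEMENT_SOA_S * rng.choice(JITTER_MULTIPLIERS, size=n_pairs)
        onsets[0::2] = initial
        onsets[1::2] = initial + gaps
        return onsets
    # interval_based: pair-initial onsets drift around the 494 ms grid, each
    # shifted relative to the previous pair-initial tone's actual onset.
    deltas = rng.choice(JITTER_DELTAS, size=n_pairs)
    initial = np.empty(n_pairs)
    initial[0] = 0.0
    for p in range(1, n_pairs):
        initial[p] = initial[p - 1] + PAIR_SOA_S + deltas[p]
    onsets[0::2] = initial
    onsets[1::2] = initial + ELEMENT_SOA_S
    return onsets


# ---------------------------------------------------------------------------
# trial construction

def _base_trial(trial_index: int, condition: TimingCondition,
                rng: np.random.Generator) -> TrialSpec:
    direction = "ascending" if rng.random() < 0.5 else "descending"
    starts = rng.uniform(F0_MIN_HZ, F0_MAX_HZ, size=N_SCALES)
    onsets = assign_onsets(condition, rng)
    tones = []
    for k in range(TONES_PER_TRIAL):
        scale, pos = divmod(k, TONES_PER_SCALE)
        f0 = build_scale(starts[scale], direction)[pos]
        level = -10.0 if pos % 2 else 0.0
        tones.append(ToneEvent(trial_index, scale, pos, float(onsets[k]),
                               float(f0), level))
    return TrialSpec(trial_index, direction, condition, starts, tones)


def place_deviants(trial: TrialSpec, rng: np.random.Generator) -> TrialSpec:
    """Insert one ID deviant (scale-final) and one BD deviant (penultimate)
    into two distinct alterable scales."""
    if len(ALTERABLE_SCALES) < 2:
        raise RuntimeError("need at least two eligible scales for deviants")
    id_scale, bd_scale = rng.choice(ALTERABLE_SCALES, size=2, replace=False)
    for scale, pos, role in ((int(id_scale), ID_POSITION, Role.deviant_ID),
                             (int(bd_scale), BD_POSITION, Role.deviant_BD)):
        scale_f0s = np.array([t.f0_hz for t in trial.tones_in_scale(scale)])
        tone = trial.tones[scale * TONES_PER_SCALE + pos]
        tone.f0_hz = outlier_f0(scale_f0s, rng)
        tone.role = role
    trial.deviant_scales = (int(id_scale), int(bd_scale))
    return trial


def place_repetition(trial: TrialSpec, rng: np.random.Generator,
                     include: bool) -> TrialSpec:
    """Optionally turn one tone of an unaltered scale into an immediate
    repetition of its predecessor (the behavioral target)."""
    if not include:
        return trial
    candidates = [s for s in ALTERABLE_SCALES if s not in trial.deviant_scales]
    if not candidates:
        raise RuntimeError("no eligible scale left for the repetition decoy")
    scale = int(rng.choice(candidates))
    pos = int(rng.integers(1, TONES_PER_SCALE))
    base = scale * TONES_PER_SCALE
    trial.tones[base + pos].f0_hz = trial.tones[base + pos - 1].f0_hz
    trial.tones[base + pos].role = Role.repetition
    trial.repetition_scale = scale
    trial.repetition_position = pos
    return trial


def designate_standards(trial: TrialSpec, rng: np.random.Generator) -> TrialSpec:
    """Mark the ERP comparison tones: the final tone of one unaltered scale
    (ID standard) and the penultimate tone of another (BD standard)."""
    used = set(trial.deviant_scales)
    if trial.repetition_scale is not None:
        used.add(trial.repetition_scale)
    candidates = [s for s in ALTERABLE_SCALES if s not in used]
    if len(candidates) < 2:
        raise RuntimeError("fewer than two unaltered scales for standards")
    id_scale, bd_scale = rng.choice(candidates, size=2, replace=False)
    trial.tones[int(id_scale) * TONES_PER_SCALE + ID_POSITION].role = \
        Role.designated_standard_ID
    trial.tones[int(bd_scale) * TONES_PER_SCALE + BD_POSITION].role = \
        Role.designated_standard_BD
    trial.designated_standard_scales = (int(id_scale), int(bd_scale))
    return trial


def fix_pretarget_isis(trial: TrialSpec) -> TrialSpec:
    """Force the onset asynchrony preceding every deviant and designated
    standard to exactly 247 ms.

    The adjusted tone's shift propagates to all later tones, so each regime's
    generative rule is preserved locally elsewhere in the trial.
    """
    onsets = np.array([t.onset_s for t in trial.tones])
    for k, tone in enumerate(trial.tones):
        if tone.role in TARGET_ROLES and k > 0:
            delta = (onsets[k - 1] + ELEMENT_SOA_S) - onsets[k]
            onsets[k:] += delta
    for t, onset in zip(trial.tones, onsets):
        t.onset_s = float(onset)
    return trial


def build_trial(trial_index: int, condition: TimingCondition,
                rng: np.random.Generator, include_repetition: bool) -> TrialSpec:
    trial = _base_trial(trial_index, condition, rng)
    trial = place_deviants(trial, rng)
    trial = place_repetition(trial, rng, include_repetition)
    trial = designate_standards(trial, rng)
    trial = fix_pretarget_isis(trial)
    return trial


# ---------------------------------------------------------------------------
# schedule construction

def _block_condition_order(n_blocks: int, rng: np.random.Generator
                           ) -> list[TimingCondition]:
    """Pseudo-random block order, balanced over conditions, no immediate
    repeats (rejection sampling)."""
    if n_blocks % len(CONDITIONS):
        raise ValueError("n_blocks must be a multiple of 3")
    pool = list(CONDITIONS) * (n_blocks // len(CONDITIONS))
    for _ in range(10_000):
        order = [pool[i] for i in rng.permutation(len(pool))]
        if all(a != b for a, b in zip(order, order[1:])):
            return order
    raise RuntimeError("failed to draw a block order without repeats")


def build_schedule(seed: int, n_blocks: int = N_BLOCKS_DEFAULT,
                   trials_per_block: int = TRIALS_PER_BLOCK_DEFAULT) -> Schedule:
    """Full experiment plan: ``n_blocks`` blocks of ``trials_per_block``
    trials, balanced over the three timing conditions, half of the trials
    carrying a repetition decoy.  Bit-reproducible given ``seed``."""
    rng = np.random.default_rng(seed)
    block_conditions = _block_condition_order(n_blocks, rng)
    n_trials = n_blocks * trials_per_block
    # exactly 50% repetition trials, balanced within block
    rep_flags = np.zeros(n_trials, dtype=bool)
    for b in range(n_blocks):
        flags = np.zeros(trials_per_block, dtype=bool)
        flags[:int(round(trials_per_block / 2))] = True
        rep_flags[b * trials_per_block:(b + 1) * trials_per_block] = \
            flags[rng.permutation(trials_per_block)]
    trials, blocks = [], []
    for b, condition in enumerate(block_conditions):
        block_idx = []
        for j in range(trials_per_block):
            idx = b * trials_per_block + j
            trials.append(build_trial(idx, condition, rng, bool(rep_flags[idx])))
            block_idx.append(idx)
        blocks.append(block_idx)
    return Schedule(trials, blocks, block_conditions, seed)


def condition_halves(schedule: Schedule) -> dict[int, str]:
    """Map trial index -> experiment half ('first'/'second'), defined per
    condition by chronological order (first vs last half of that condition's
    trials)."""
    halves: dict[int, str] = {}
    for condition in CONDITIONS:
        idx = [t.trial_index for t in schedule.trials_for(condition)]
        cut = len(idx) // 2
        for i in idx[:cut]:
            halves[i] = "first"
        for i in idx[cut:]:
            halves[i] = "second"
    return halves


# ---------------------------------------------------------------------------
# event table

def trial_start_times(schedule: Schedule) -> np.ndarray:
    """Global start time (s) of each trial, separated by the fixed 1 s
    inter-trial interval measured offset-to-onset."""
    starts = np.empty(schedule.n_trials)
    t = 0.0
    for i, trial in enumerate(schedule.trials):
        starts[i] = t
        t += trial.duration_s + schedule.inter_trial_interval_s
    return starts


def events_dataframe(schedule: Schedule) -> pd.DataFrame:
    """Flatten a schedule into a BIDS-events-style table (onsets global, s)."""
    starts = trial_start_times(schedule)
    halves = condition_halves(schedule)
    trial_block = {i: b for b, idx in enumerate(schedule.blocks) for i in idx}
    rows = []
    for trial in schedule.trials:
        t0 = starts[trial.trial_index]
        for tone in trial.tones:
            rows.append({
                "onset": t0 + tone.onset_s,
                "duration": tone.duration_s,
                "trial_type": tone.role.value,
                "trial_index": trial.trial_index,
                "block": trial_block[trial.trial_index],
                "condition": trial.condition.value,
                "half": halves[trial.trial_index],
                "scale_index": tone.scale_index,
                "position": tone.position_in_scale,
                "f0_hz": tone.f0_hz,
                "level_db": tone.level_db,
                "role": tone.role.value,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# audio

def synthesize_audio(trial: TrialSpec, sample_rate: float,
                     n_harmonics: int = 5, ramp_s: float = 0.010) -> np.ndarray:
    """Render a trial as a waveform of harmonic complexes.

    Each tone is a ``n_harmonics``-partial complex (amplitudes 1/k) with
    10 ms raised-cosine on/off ramps; −10 dB tones are scaled by 10^(−10/20).
    An empty trial renders as inter-trial-interval silence.
    """
    if sample_rate < 8000:
        raise ValueError("sample_rate must be at least 8 kHz")
    if not trial.tones:
        return np.zeros(int(round(INTER_TRIAL_INTERVAL_S * sample_rate)))
    n = int(round(trial.duration_s * sample_rate))
    wave = np.zeros(n)
    n_tone = int(round(TONE_DURATION_S * sample_rate))
    t = np.arange(n_tone) / sample_rate
    n_ramp = int(round(ramp_s * sample_rate))
    env = np.ones(n_tone)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    env[:n_ramp] = ramp
    env[-n_ramp:] = ramp[::-1]
    for tone in trial.tones:
        x = np.zeros(n_tone)
        for k in range(1, n_harmonics + 1):
            if k * tone.f0_hz < sample_rate / 2:
                x += np.sin(2 * np.pi * k * tone.f0_hz * t) / k
        x *= env * 10.0 ** (tone.level_db / 20.0)
        i0 = int(round(tone.onset_s * sample_rate))
        wave[i0:i0 + n_tone] += x[:max(0, n - i0)]
    peak = np.abs(wave).max()
    return wave / peak * 0.95 if peak > 0 else wave


def pair_initial_soas(trial: TrialSpec, exclude_fixed: bool = True) -> np.ndarray:
    """Onset asynchronies between consecutive pair-initial tones.

    With ``exclude_fixed``, gaps whose flanking pairs contain a deviant or
    designated standard (where the pre-target override perturbs the grid) are
    dropped — in the beat_based regime the remaining values are exactly 0.494 s.
    """
    initial = [t for t in trial.tones if t.is_pair_initial]
    onsets = np.array([t.onset_s for t in initial])
    soas = np.diff(onsets)
    if not exclude_fixed:
        return soas
    # pair p covers tones 2p, 2p+1; gap g joins pair-initial tones g and g+1
    target_pairs = {k // 2 for k, t in enumerate(trial.tones)
                    if t.role in TARGET_ROLES}
    keep = [g for g in range(len(soas))
            if not ({g, g + 1} & target_pairs)]
    return soas[keep]
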