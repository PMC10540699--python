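# Methods

## The paradigm generator

A trial is seven scales of eight tones (56 tones), all ascending or all
descending, each scale one octave in equal log steps (ratio 2^(1/7)) from a
start F0 drawn uniformly from 300–600 Hz.  Tones last 166 ms; even positions
(0-based odd indices) are −10 dB, forming duples.  "ISI" throughout means
onset-to-onset asynchrony (SOA): only this reading makes 247 ms spacing with
166 ms tones produce the 4.049 Hz element rate.

Timing regimes:

* isochronous — onsets k·0.247 s;
* beat-based — pair-initial onsets on the 0.494 s grid; within-pair gap
  0.247 s × m, m drawn i.i.d. from {0.667, 0.834, 1.166, 1.333};
* interval-based — within-pair gap fixed at 0.247 s; each pair-initial onset
  is the previous pair-initial onset + 0.494 s + 0.247·(m−1).  Shifts are
  anchored to the previous pair's *actual* onset, so timing drifts
  cumulatively — an accepted property of this regime.

Per trial: one ID deviant (scale-final tone) and one BD deviant
(scale-penultimate) in two distinct scales among scales 2–6; deviant F0 is
min(scale)×0.8 or max(scale)×1.2 (direction uniform at random).  Half of the
trials carry a repetition decoy: in a third, distinct scale, one tone's F0
(uniform position 1–7) is replaced by its predecessor's — replacement keeps
56 tones/trial, which the printed totals require.  Designated standards (the
ERP comparison tones) mark the final and penultimate tones of two further
unaltered scales, one tone per scale.  The gap before every deviant and
designated standard is then forced to exactly 0.247 s; the adjusted tone's
shift propagates to all later onsets so each regime's generative rule stays
intact elsewhere.  Consequences tested exactly: scale categories
64.3/14.3/14.3/7.1%, deviant probability 2/56 = 3.57%, 80 deviants and 80
designated standards per type per condition, and (excluding gaps adjacent to
the overrides) a unique 494 ms pair-initial SOA in beat-based trials.

Blocks: 12 × 20 trials, 4 blocks per regime, pseudo-random order with no
immediate repeats (rejection sampling).  Block count and size are
parameters; scaled-down schedules (e.g. 6 × 12) keep every invariant except
the absolute counts.  Generation is bit-reproducible from the seed.

Audio (used for the stimulus-spectrum analysis) renders each tone as a
5-harmonic complex (amplitudes 1/k) with 10 ms raised-cosine ramps; −10 dB
tones are scaled by 10^(−10/20).  This is a parametric stand-in for the
vocoded harp timbre of a live experiment; its amplitude envelope, not its
timbre, is what the analysis consumes.

## The synthetic EEG generator

64 channels (10-10 names, coordinates from the bundled standard montage),
default 1024 Hz continuous or 300 Hz in the direct-epoch/segment fast paths.
Components, all sharing one set of kernels and topographies:

* **Noise** — 1/f^1 spectrally shaped white noise, 10 µV RMS per channel,
  mildly spatially mixed (Gaussian kernel, σ = 4 mm on the projection
  scale); amplitude profile flattened below 0.5 Hz.
* **Entrainment** — sinusoids at exactly 1/0.247 and 1/0.494 Hz with
  trial-wise von-Mises phase offsets of concentration κ.  This gives direct
  analytic control of ITPC: amplitude sets detectability, κ sets phase
  consistency.  Defaults (µV): element 1.2/0.3/1.2 for
  isochronous/interval/beat (central topography); pair 0/0/1.2
  (right-lateral topography).  κ = 6 everywhere except pair-rate beat-based,
  which is gated by experiment half: κ = 0 (first) → 6 (second), so
  pair-rate coherence *emerges* with exposure.
* **Tone-evoked kernels** — an N1-like Gaussian (peak 100 ms, σ 18 ms,
  fronto-central negative topography), amplitude 0.5 µV scaled by tone level.
  0.5 µV keeps the evoked duple train from itself producing condition
  differences in pair-rate coherence (the split-half pattern must be carried
  by the κ gating) and from breaking the isochronous ≈ beat equality at the
  element rate (pair-final jitter degrades evoked element coherence only in
  the beat regime).
* **Mismatch kernel** — Gaussian peak 198 ms, σ 12 ms (mass within
  173–223 ms), anterior-negative/posterior-positive topography, 3 µV, on
  every deviant.
* **Congruence kernel** — Gaussian peak 155 ms, σ 12 ms (mass within
  130–180 ms), left central-posterior negative topography, 5 µV, only on
  temporally congruent deviants (ID × interval-based, BD × beat-based).  A
  switch applies it to designated standards instead, as the negative control
  of the standards-only control analysis.
* **Blinks** (continuous path only) — biphasic 400 ms template, Poisson
  arrivals at 0.1 Hz, ~120 µV peak at Fpz decaying with distance.

The mismatch/congruence amplitudes are calibrated — the emulated study
reports statistics, not generative µV — to make every injected effect
recoverable at desk-scale cohorts while the null calibration stays exact;
they are deliberately generous relative to real mismatch responses
(~0.2 µV differences at 20 subjects × 80 trials) because the test cohorts
are an order of magnitude smaller.

Subjects differ by multiplicative log-normal factors (σ = 0.3) on all
effect amplitudes, plus jittered behavioral parameters.  Behavioral
responses: hits ~ Bernoulli((1−lapse)·p_cond) with p = 0.6775/0.6912/0.6388
(isochronous/interval/beat); RTs log-normal (σ_log = 0.35) with medians
0.511/0.649 s constant across halves and 0.72 → 0.59 s for beat-based, so
RTs improve with exposure only where the beat is predictable.  RTs beyond
2 s occur naturally and exercise the scoring filter.

What the generator does *not* emulate: biophysical forward models (lead
fields), non-stationary or heavy-tailed noise, channel artifacts other than
blinks, evoked-latency jitter, false alarms in the decoy task.  Passing
tests therefore demonstrate correctness and calibration of the *analysis*
under the stated generative assumptions, not performance on real EEG.

## Preprocessing

High-pass 0.1 Hz → band-stop 48–52 Hz → polyphase resample to 300 Hz → low-
pass 90 Hz, all 5th-order zero-phase (forward-backward) Butterworth;
filtfilt padding spans three periods of the lowest cutoff so the 0.1 Hz
stage settles.  Blink removal: Fpz band-passed 1–10 Hz, peaks > 5 robust
(MAD-scaled) SDs above the median with 500 ms refractoriness (blinks reach
z ≈ 30 on Fpz; a lower threshold would false-alarm on background noise and
modify blink-free recordings); blink-locked
epochs (−200…600 ms) are averaged and the top-2 spatial principal
components of that average are projected out of all channels.  Average
reference.  Epochs: −50…247 ms around deviants and designated standards
with the inclusive-end convention (90 samples at 300 Hz; the half-open
alternative would drop the 247 ms endpoint), baseline ±25 ms.  DSS keeps 8
components ranked by evoked/total power after whitening on the single-trial
covariance (ridge 1e-9 × trace).  Robust averaging: bisquare weights
(tuning 4.685) on residuals standardized by the across-trial MAD, ≤10
iterations, 1e-6 relative tolerance, then 48 Hz low-pass.

## Statistics

ITPC is computed per channel first and averaged afterwards (the two
operations do not commute).  The unnormalized form ([Σcos]² + [Σsin]²)/N is
primary; a normalized resultant-length variant is exposed, and condition
contrasts are equivalent under either at fixed N.

Topography smoothing uses a Gaussian on 2-D azimuthal-equidistant channel
coordinates scaled to a 20 mm scalp disc (median inter-channel spacing
≈ 5 mm), FWHM 5 mm, balanced to doubly stochastic by symmetric Sinkhorn
scaling so constants are preserved and mass is conserved.  Channel adjacency
is the Delaunay triangulation pruned at 1.5× the median edge.

Within-subject F maps (one-way and 3 × 3 two-way, each effect against its
effect-by-subject error) are computed in closed form and cross-checked
against an independent rm-ANOVA implementation in the tests.  Cluster
inference replaces parametric random-field correction with permutation
max-cluster-mass: threshold at the cluster-forming level (p < 0.001),
cluster suprathreshold points by channel adjacency + temporal contiguity,
and compare observed masses against the permutation distribution of the
maximum mass (sign flips of subject contrast maps for one-sample contrasts;
within-subject condition-label permutations for ANOVAs).  p_FWE uses the
add-one estimator.  Degenerate identical-condition inputs report F = 0.

Behavior: accuracy counts all hits; the 2 s cutoff filters RTs only (mean of
correct trials, log-transformed).  One-way rm-ANOVA over regimes with
FDR-corrected (Benjamini–Hochberg, q = 0.05) paired post-hocs; Wilcoxon
signed-rank across halves (exact for n ≤ 25, zero differences dropped).
Brain–behavior: OLS of the behavioral index on the three neural indices,
exclusion at Cook's distance > 5× mean, Pearson correlations among all
pairs, Bonferroni over the tested pairs.

## Problem sizes and design choices

Test and acceptance cohorts are scaled-down study conditions, chosen as the
smallest sizes at which each question is answerable: null calibration of
the cluster tests uses 100 replicates of 8 subjects × 24 trials; ERP effect
recovery 25 replicates of 12 subjects × 72 trials (24 per cell); ITPC
pattern recovery 25 replicates of 8 subjects × 72 trials at 150 Hz (the
analysis band ends at 4.124 Hz); correlation recovery 50 replicates of
n = 18 index tables.  The split-half machinery accepts any even split with
at least two trials per half; the full-scale experiment gives 40 + 40.

Open choices resolved here: one designated tone per standard scale (the
printed standard counts match this reading); the two deviants never share a
scale; the 3 × 3 "standard" cell pools both designated positions, with the
position-resolved split kept for the standards-only control; outlier
direction and repetition position are uniform at random; jitter draws are
i.i.d. with replacement.

Known limitations: the congruence/mismatch effect sizes are generative
conveniences, not measured physiology; the interval-based regime's
cumulative drift means its trials differ slightly in duration (the
single-frequency DFT over each trial's own span handles this); stimulus
ITPC of a deterministic isochronous envelope saturates at N for every
frequency with nonzero energy, so stimulus-spectrum comparisons are only
informative across jittered conditions.
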