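# Methods

This note documents the models, numerical choices and limitations behind
`megeeg`.  It covers the synthetic-data generator, each analysis stage,
the statistical tests, and the problem sizes used by the test suite and
the acceptance script.

## Synthetic paired sessions

The generator exists so that every analysis stage can be verified against
known ground truth.  It emulates paired recordings, not physics:

**Geometry.** 63 scalp electrodes use 10-10 names with positions from the
MNE `standard_1005` montage projected to a 0.09 m sphere; a 64th channel
carries the ECG.  64 OPM sites sit on a golden-spiral spherical cap of a
0.10 m sphere, each with a radial and a tangential sensitive axis
(128 channels).  Reduced channel counts (used in tests) take evenly spaced
subsets.

**Sources and mixing.** One band-limited cortical source per task: a
13–30 Hz source under C3 (motor) or an 8–13 Hz source under Oz (alpha).
The carrier is Gaussian narrowband noise normalised so its mean Hilbert
envelope is exactly 1, which makes planted amplitude modulation directly
recoverable from the mean envelope.  A source mixes into channel *c* with
weight `exp(−d²/2σ²)`, *d* the great-circle scalp distance from source to
channel.  This is a channel-statistical stand-in for volume conduction and
field spread — deliberately not a lead field, because the analyses under
test are channel-level and a kernel width gives controllable ground truth.
Defaults `sigma_eeg = 0.045 m > sigma_meg = 0.025 m` encode that EEG
signals are spatially broader; the spread-fraction ordering between
modalities follows from this and is verified, not assumed.

**Task structure (defaults are the study conditions).** Motor: 50 trials
of 5 s; movement occupies the second before each movement-offset event;
beta amplitude drops by `erd_depth = 0.3` during movement and rebounds as
a 1 s raised-cosine bump of peak `pmbr_gain = 0.2` starting 0.5 s after
offset.  Alpha: 5 cycles of 30 s eyes-closed / 30 s eyes-open with
instruction events; occipital amplitude is `alpha_gain = 3` during closed
halves (power contrast 9).  EEG is sampled at 1000 Hz, MEG at 1200 Hz,
motion at 120 Hz.  Signals are synthesised at 6 kHz (the least common
multiple) and decimated by slicing — safe because every component is
band-limited far below the decimated Nyquist rates.

**Artifacts** (amplitudes in signal units, baseline beta envelope = 1):

* mains: 50 Hz + 0.4×100 Hz sinusoids, common phase, per-channel gain
  jitter; default amplitude 0.5;
* cardiac: a stylised PQRST template repeated at 72 bpm with 5 %
  inter-beat jitter, random per-channel weights (default 0.3); the ECG
  channel carries a clean, large copy;
* muscle: 60–130 Hz noise bursts gated by a 0.5 s raised cosine at each
  head-movement time, 20× weaker on MEG than EEG (default 1.0 on EEG) —
  muscle artifacts are the classic EEG-dominant contamination;
* MEG movement artifact: the exact forward model `n_i(t)·(B0 + G·x_i(t))`
  evaluated along the rigid-body helmet motion through a remnant static
  field (default ~0.6 nT uniform + ~2 nT/m gradient, the post-nulling
  scale), interpolated from the 120 Hz motion base.  This produces the
  large low-frequency (< 5 Hz) artifact characteristic of OPMs moving in
  a non-zero field.
* background: 1/f-amplitude noise per channel (default RMS 0.3),
  synthesised directly in the frequency domain.

**Helmet motion.** A slow sub-threshold sway (2 mm) plus `n_motion_bursts`
out-and-back raised-cosine displacements (0.03 m over 0.5 s, peak speed
~0.19 m/s) with small rotations; default 6 bursts per session, matching
the handful of spontaneous movements seen in a cooperative adult.

**Determinism.** One integer seed drives named sub-generators (source,
motion, cardiac, per-modality noise/artifacts), so the EEG stream is
bit-identical whether or not MEG is generated alongside it, and identical
seeds give identical sessions.

What the generator does **not** emulate: realistic lead fields, eye
blinks, electrode impedance drift, inter-subject anatomy, non-stationary
noise, or nonlinear (high-spatial-order) room fields.  Passing tests
therefore show the pipeline recovers what it is designed to measure under
controlled conditions — not that it is robust to everything real data
contains.

## Preprocessing

Zero-phase (forward–backward) filtering throughout: a 4th-order
Butterworth band-pass (1–150 Hz) cascaded with 4th-order band-stop
notches of ±2 Hz around 50 and 100 Hz, applied as a single SOS cascade;
then per-channel mean and best-fit-line removal.  Zero-phase filtering is
chosen so envelope timing relative to movement offset is not lag-biased.

Epoch windows are half-open `[t_min, t_max)` against 0-based sample
indices; trials whose window leaves the recording are kept as zero rows
with `retained = False` so trial indexing stays aligned with events.

**Trial/channel rejection** replaces visual inspection with a
deterministic rule: per trial, the median (across channels) log-variance
is converted to a robust z (median/MAD, scale 1.4826); trials with z > 5
are dropped.  Channels are marked bad when their median log-variance
across trials is both a z > 5 outlier **and** exceeds 10× the median
channel variance.  The ratio guard matters: on clean data the
across-channel variance spread is tiny, so a pure z-rule would cull the
signal-carrying channels near the source — topography is not an artifact.
At these defaults, artifact-free synthetic sessions retain ≥ 90 % of
trials, and sessions with default artifacts retain ~85–95 % (motion-burst
trials are the ones removed), mirroring the near-complete retention a
conservative visual pass produces.

**Re-referencing** (EEG): `average` subtracts the instantaneous mean of
good scalp channels (motor task); `average_excluding` computes the
reference without the occipital set (Pz, POz, Oz, P1–P8, PO3/4, PO7–10,
O1, O2) but subtracts it from all channels (alpha task — the signal of
interest must not sit in the reference); `CRR` keeps the common recording
reference (identity).  **Homogeneous field correction** (MEG) projects
each time sample onto the complement of the sensor-orientation matrix
`N`: `s ← (I − N N⁺) s`, removing the spatially uniform field.  The
projector is idempotent and time-invariant, so its order relative to
temporal filtering is immaterial (asserted by a test); it is applied
after epoching.

## Spectral analysis

Time-frequency spectrograms use a filterbank of 18 overlapping bands of
3rd-order zero-phase Butterworth filters; per band the Hilbert envelope is
averaged over retained trials, then expressed as relative change against
the mean amplitude in the baseline window (3–4 s after movement offset
for the motor task; −2 to −1 s before the marker for motion trials).
Published work rarely lists filterbank edges; here the defaults are
centres linearly spaced 2–40 Hz (motor) or 4–124 Hz (motion/wide-band),
half-width `max(2 Hz, 0.3 × centre)` — ≥ 50 % overlap across the plotted
range, fully configurable.  Envelopes are averaged **before** baseline
division (the average-then-normalise order), and the first/last 0.3 s of
each epoch are flagged as edge-contaminated in TFS metadata rather than
trimmed, since all analysis windows avoid the edges anyway.

PSDs are raw rectangular-window periodograms (no detrending or
windowing), trial-averaged within condition; the one-sided normalisation
satisfies Parseval (`Σ P·Δf` = mean square), verified against a direct
DFT oracle.

## Metrics and statistics

* Beta SNR per the formula in the README, on the trial-averaged envelope;
  zero MRBD standard deviation is an error (degenerate envelope).
* Best channel: argmax SNR (or contrast); ties break lexicographically so
  runs are reproducible.
* Spread fraction: envelopes concatenated across retained trials
  (unaveraged), one Pearson r per channel against the peak, threshold
  r > 0.3; the peak channel is excluded from numerator and denominator
  (including it would add a guaranteed r = 1 self-count).
* Alpha contrast: in-band (8–13 Hz inclusive on the discrete grid) power
  ratio, eyes closed / eyes open.
* Rank-sum test: two-sided; when both groups have ≤ 12 observations the
  exact permutation null is computed by dynamic programming over
  integer-doubled mid-ranks (ties handled exactly), otherwise the
  tie-corrected normal approximation with continuity correction.  Study
  group sizes (9 and 12) always take the exact branch.
* Pearson correlation: `scipy.stats.pearsonr` (t-based two-sided p).

## Field nulling

The remnant field model is `B(r) = B0 + G·r` with `G` symmetric and
traceless — the five physical degrees of freedom a static source-free
field permits (∇·B = 0, ∇×B ≈ 0 inside the helmet volume); a fit with all
9 gradient components would be partly unidentifiable physics.  Fitting is
linear least squares over the 8 parameters on motion-synchronised OPM
data; identifiability requires the motion to excite at least two rotation
axes (a static head reduces to a `B0`-only fit, returned with a warning).
RMS over a sphere (radius 0.25 m, centred on the helmet-volume centroid)
has the closed form `sqrt(|B0 + G·c|² + R²‖G‖²_F/3)`, validated against a
10⁶-point Monte-Carlo surface average.

Nulling solves least-squares coil currents against an 8×n coil
calibration matrix (27 coils by default; condition number > 1e8 is
refused), applies them through an optionally *miscalibrated* true
response, and iterates fit → solve → apply with a fresh simulated field
map each iteration — the fit–null–fit–null–map protocol.  With 5 %
coil miscalibration each iteration cuts the residual by roughly the
miscalibration factor, so two iterations reduce a ~4.6 nT remnant field
by well over an order of magnitude (median ≥ 5× is asserted; the
simulation converges further than a real room, where unmodelled
higher-order fields dominate the floor — a known limitation).

## Head motion

Helmet speed is the Euclidean norm of the centrally-differenced position
trace (one-sided at the edges).  Markers are placed at upward crossings
of 0.1 m/s; crossings within a 5 s refractory period (one trial length)
are suppressed so sustained movement does not spawn a trial per sample.
Markers map to each recording's time base by nearest sample via the
shared start trigger, without interpolating the 120 Hz speed series.
Motion trials span −2 to +3 s with a −2 to −1 s baseline, analysed with
the wide-band filterbank.

## Pipeline and cardiac handling

Cardiac artifacts in the alpha task are removed by ECG-locked template
subtraction: R-peaks from the ECG channel (peak picking with a 0.4 s
minimum separation), a per-channel beat-locked average as template,
subtracted at every beat.  This is deterministic and directly testable
against the generator's template-based cardiac model; a
decomposition-based cleaner can be plugged in through the
`cardiac_cleaner` hook.  MEG streams (no ECG of their own) reuse beat
times from the simultaneous EEG, rescaled between sampling rates;
MEG-only sessions skip cardiac removal.

Group reports are emitted as TSV (tables) + JSON (statistics), with an
optional matplotlib bar-chart helper; plots are conveniences and never
test surfaces.

## Problem sizes in tests and the acceptance script

The generator's defaults are full study scale; tests and the acceptance
script pass reduced sizes explicitly, chosen as the smallest sessions in
which every planted effect remains comfortably recoverable:

* replicate (100×) group experiments: motor 9 participants × 8 trials ×
  12 EEG channels; alpha 12 participants × 4 cycles of 6 s × 12 channels;
  nulling 12 sessions × 2 conditions with 5 s field maps;
* recovery tests: 50 trials (study scale) × 12 channels, averaged over
  3 seeds, tolerance ≈ 3 standard errors of that mean; alpha gain
  recovery over 8–12 seeds at 31 channels;
* modality contrasts: 31 EEG channels vs 32 MEG sites so the focal MEG
  kernel still lands on a sensor near the source.

## Known limitations

* The Gaussian mixing kernel cannot produce the dipolar field sign
  structure of real MEG; spread is therefore tested as an ordering, not
  an absolute level.
* The exact rank-sum DP assumes mid-ranks double to integers (true for
  any real-valued input).
* Template subtraction removes only the beat-locked cardiac component;
  beat-shape variability would leave a residual that the generator does
  not model.
* Simulated nulling has no hardware imperfections beyond the calibration
  error, so post-nulling residuals are optimistic relative to a physical
  room.
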