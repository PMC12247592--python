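# megeeg

Channel-level analysis of simultaneous EEG and wearable OPM-MEG
(optically-pumped-magnetometer magnetoencephalography) recordings.

## The problem

EEG and MEG measure the same neural currents through different physics, and
recording them together is recommended clinical practice in epilepsy.
Wearable OPM-MEG makes a combined wearable system possible — but does
strapping a 128-channel magnetometer helmet over an EEG cap degrade either
signal?  Answering that requires a channel-level comparison pipeline:

* **beta SNR** for a motor task.  Per channel, on the trial-averaged
  13–30 Hz Hilbert envelope,

  `SNR = (mean_PMBR − mean_MRBD) / std_MRBD`

  where the MRBD window (movement-related beta decrease) is −1–0 s and the
  PMBR window (post-movement beta rebound) 0.5–1.5 s relative to movement
  offset.  Group comparisons (modality alone vs simultaneous) use the
  two-sided Wilcoxon rank-sum test, exact at study group sizes.
* **channel spread** — the fraction of channels whose unaveraged beta
  envelope has Pearson r > 0.3 with the best-SNR channel: a proxy for
  volume conduction (EEG) vs magnetic field spread (MEG).
* **alpha contrast** for an eyes-open/closed task: 8–13 Hz periodogram
  power, eyes closed over eyes open, at the best channel.
* **background-field nulling**: the remnant static field in the shielded
  room is modelled as a uniform vector `B0` plus a symmetric traceless
  first-order gradient `G` (8 parameters), fitted by least squares from
  motion-synchronised OPM data `b_i(t) = n_i(t)·(B0 + G·x_i(t))`, and
  cancelled by wall-coil currents.  Efficacy is the RMS of `|B0 + G·r|`
  over a 0.25 m sphere: `sqrt(|B0|² + R²·‖G‖²_F / 3)`.
* **head-motion artifacts**: helmet speed from a 120 Hz motion trace,
  motion trials at 0.1 m/s threshold crossings, and a 1–130 Hz
  filterbank-Hilbert spectrogram around each event, separating the
  EEG-dominant high-frequency muscle artifact from the MEG-dominant
  low-frequency movement-through-field artifact.

Because real paired recordings are not shipped with the package, a
first-class synthetic generator produces paired sessions (63+1-channel EEG
at 1000 Hz, 128-channel dual-axis MEG at 1200 Hz, shared motion trace and
cardiac/mains/muscle artifacts) with planted, recoverable effect sizes.

## Worked example

```python
from megeeg import SyntheticGroundTruth, generate_session
from megeeg.pipeline import analyse_motor_session

truth = SyntheticGroundTruth(seed=1)   # ERD depth 0.3, rebound gain 0.2
eeg, meg, _ = generate_session("motor", truth, n_trials=50, n_eeg=63,
                               modalities=("eeg",))
res = analyse_motor_session(eeg, "eeg")
print(f"best channel   {res['best_channel']}")
print(f"beta SNR       {res['snr_best']:.1f}")
print(f"spread         {res['spread_fraction']:.2f}")
print(f"trials kept    {res['n_trials_retained']}/50")
```

prints

```
best channel   CP3
beta SNR       6.3
spread         0.79
trials kept    43/50
```

The planted beta source sits under C3; `CP3` is its immediate neighbour, a
beta SNR of ~6 at 50 trials is in the range expected for a strong motor
response, and 0.79 of the other channels correlate with the peak above
r = 0.3 — the broad spatial spread characteristic of EEG (the same session
analysed as MEG gives ~0.2).

A thin CLI wraps the same calls:

```bash
megeeg simulate --task motor --seed 1 --out session.h5
megeeg run --in session.h5 --task motor --out results/
megeeg fieldnull --iterations 2 --seed 1 --out nulling.json
```

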