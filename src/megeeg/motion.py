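"""Helmet-speed computation, motion-event detection and motion-locked TFS.

Head motion affects the two modalities differently: EEG picks up broadband
muscle activity (dominant above ~60 Hz), while OPM-MEG picks up a
low-frequency (< 5 Hz) artifact from the sensors moving through the
remnant static field.  Motion "trials" are defined wherever helmet speed
exceeds a threshold (default 0.1 m/s), and a wide-band (1-130 Hz)
relative-change spectrogram is computed around each marker with a
pre-movement baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_bundle import MotionTrace, Recording
from .spectral import TFS, BandSpec, filterbank_tfs
from .preprocess import epoch

SPEED_THRESHOLD = 0.1  # m/s
MOTION_WINDOW = (-2.0, 3.0)  # s around each marker
MOTION_BASELINE = (-2.0, -1.0)  # s


@dataclass
class MotionEventSet:
    """Suprathreshold-motion markers in the motion-trace time base."""

    marker_samples: np.ndarray  # indices into the motion trace
    fs_motion: float
    threshold: float
    refractory: float
    window: tuple[float, float] = MOTION_WINDOW

    def __post_init__(self) -> None:
        self.marker_samples = np.asarray(self.marker_samples, dtype=int)
        if self.marker_samples.size > 1:
            if np.any(np.diff(self.marker_samples) <= 0):
                raise ValueError("markers must be strictly increasing")

    @property
    def marker_times(self) -> np.ndarray:
        return self.marker_samples / self.fs_motion

    def to_recording_samples(self, fs: float) -> np.ndarray:
        """Nearest-sample mapping into a recording sharing the start trigger."""
        return np.round(self.marker_times * fs).astype(int)


def helmet_speed(m: MotionTrace) -> np.ndarray:
    """Speed of helmet translation (m/s) from the position trace.

    Central differences in the interior, one-sided at the edges; the
    Euclidean magnitude of the velocity vector, one value per sample.
    """
    if m.n_samples < 2:
        raise ValueError("need at least 2 motion samples")
    vel = np.gradient(m.position, 1.0 / m.fs_motion, axis=0)
    return np.linalg.norm(vel, axis=1)


def detect_motion_events(
    speed: np.ndarray,
    fs_motion: float,
    threshold: float = SPEED_THRESHOLD,
    refractory: float = 5.0,
) -> MotionEventSet:
    """Mark upward threshold crossings of the speed series.

    Crossings within the refractory period (default 5 s, one motion-trial
    length) after a marker are suppressed so trials do not self-overlap.
    An empty event set is allowed.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    speed = np.asarray(speed, dtype=float)
    above = speed > threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above.size and above[0]:
        crossings = np.concatenate([[0], crossings])
    markers: list[int] = []
    refractory_samples = int(round(refractory * fs_motion))
    last = -np.inf
    for c in crossings:
        if c - last >= refractory_samples:
            markers.append(int(c))
            last = c
    return MotionEventSet(
        marker_samples=np.array(markers, dtype=int),
        fs_motion=fs_motion,
        threshold=threshold,
        refractory=refractory,
    )


def motion_tfs(
    rec: Recording,
    ev: MotionEventSet,
    bands: BandSpec | None = None,
    window: tuple[float, float] = MOTION_WINDOW,
    baseline: tuple[float, float] = MOTION_BASELINE,
) -> TFS:
    """Motion-locked relative-change spectrogram (1-130 Hz by default).

    Epochs ``window`` around each marker (mapped into the recording's time
    base via the shared start trigger) and computes the filterbank TFS with
    a pre-movement baseline.
    """
    if ev.marker_samples.size == 0:
        raise ValueError("no motion trials")
    if bands is None:
        bands = BandSpec.default_motion()
    samples = ev.to_recording_samples(rec.fs)
    tagged = rec.copy()
    tagged.events = list(rec.events) + [
        ("motion", int(s)) for s in samples if 0 <= s < rec.n_samples
    ]
    ep = epoch(tagged, "motion", window[0], window[1])
    return filterbank_tfs(ep, bands, baseline)


def band_mean_change(
    tfs: TFS,
    freq_min: float,
    freq_max: float | None = None,
    t_min: float = 0.0,
    t_max: float | None = None,
    good_only: bool = True,
) -> float:
    """Mean relative change over bands with centres in [freq_min, freq_max]
    and times in [t_min, t_max] — e.g. post-marker high-band power for the
    muscle-artifact contrast."""
    centres = tfs.band_spec.centres
    bmask = centres >= freq_min
    if freq_max is not None:
        bmask &= centres <= freq_max
    if not bmask.any():
        raise ValueError("no bands in requested frequency range")
    tmask = tfs.times >= t_min
    if t_max is not None:
        tmask &= tfs.times <= t_max
    ch = (
        [i for i, c in enumerate(tfs.channels) if c.is_good]
        if good_only
        else list(range(len(tfs.channels)))
    )
    return float(tfs.values[np.ix_(ch, np.flatnonzero(bmask),
                                   np.flatnonzero(tmask))].mean())
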