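"""Filterbank-Hilbert time-frequency analysis and periodogram PSDs.

The time-frequency spectrogram (TFS) is built the classic way: the data
are band-pass filtered into overlapping frequency bands (3rd-order
Butterworth, zero-phase), the Hilbert transform gives the analytic signal,
and its magnitude the oscillatory amplitude envelope.  Envelopes are
averaged across trials, then expressed as relative change against the mean
amplitude in a baseline window: ``(a - a_base) / a_base``.  Relative
change is dimensionless and invariant to any positive rescaling of the
input, which makes EEG (volts) and MEG (tesla) directly comparable.

PSDs use the raw rectangular-window periodogram so that the integral of
power over frequency equals the signal's mean square (Parseval).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io_bundle import ChannelInfo, EpochSet


@dataclass
class BandSpec:
    """Ordered overlapping band edges for the filterbank."""

    bands: list[tuple[float, float]]
    order: int = 3
    nominal_centres: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("need at least one band")
        for low, high in self.bands:
            if not 0 < low < high:
                raise ValueError(f"invalid band ({low}, {high})")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")

    def validate(self, fs: float) -> None:
        for low, high in self.bands:
            if high >= fs / 2:
                raise ValueError(f"band edge {high} Hz >= Nyquist ({fs / 2} Hz)")

    @property
    def centres(self) -> np.ndarray:
        if self.nominal_centres is not None:
            return np.asarray(self.nominal_centres, dtype=float)
        return np.array([(lo + hi) / 2.0 for lo, hi in self.bands])

    @classmethod
    def from_centres(
        cls, centres: np.ndarray, order: int = 3, min_halfwidth: float = 2.0,
        rel_halfwidth: float = 0.3,
    ) -> "BandSpec":
        """Bands of half-width max(min_halfwidth, rel_halfwidth * centre);
        low edges are floored at 0.25 Hz."""
        centres = np.asarray(centres, dtype=float)
        bands = []
        for c in centres:
            hw = max(min_halfwidth, rel_halfwidth * c)
            bands.append((max(c - hw, 0.25), c + hw))
        return cls(bands=bands, order=order, nominal_centres=centres)

    @classmethod
    def default_motor(cls, n_bands: int = 18) -> "BandSpec":
        """18 overlapping bands with centres linearly spaced 2-40 Hz."""
        return cls.from_centres(np.linspace(2.0, 40.0, n_bands))

    @classmethod
    def default_motion(cls, n_bands: int = 18) -> "BandSpec":
        """18 overlapping bands spanning the 1-130 Hz range (centres 4-124)."""
        return cls.from_centres(np.linspace(4.0, 124.0, n_bands))


@dataclass
class EnvelopeSet:
    """Per-trial amplitude envelopes: trials x channels x samples (>= 0)."""

    data: np.ndarray
    fs: float
    band: tuple[float, float]
    window: tuple[float, float]
    channels: list[ChannelInfo]
    retained: np.ndarray

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.data.shape[2]) / self.fs

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def trial_average(self) -> np.ndarray:
        """Mean envelope over retained trials: channels x samples."""
        return self.data[self.retained].mean(axis=0)


@dataclass
class TFS:
    """Baseline-relative time-frequency amplitude: channels x bands x samples."""

    values: np.ndarray
    band_spec: BandSpec
    times: np.ndarray
    baseline: tuple[float, float]
    channels: list[ChannelInfo]
    edge_duration: float = 0.3  # s at each end flagged as edge-contaminated

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def edge_mask(self) -> np.ndarray:
        """True where samples are within the edge-contaminated margins."""
        t0, t1 = self.times[0], self.times[-1]
        return (self.times < t0 + self.edge_duration) | (
            self.times > t1 - self.edge_duration
        )


@dataclass
class PSDSet:
    """Trial-averaged periodogram power per condition, common frequency grid."""

    frequencies: np.ndarray
    power: dict[str, np.ndarray]  # condition -> channels x frequencies
    channels: list[ChannelInfo] = field(default_factory=list)

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]


# ---------------------------------------------------------------------------


def band_envelope(
    ep: EpochSet, band: tuple[float, float], order: int = 3
) -> EnvelopeSet:
    """Per-trial, per-channel amplitude envelope in one band.

    Zero-phase Butterworth band-pass, analytic signal via the Hilbert
    transform, magnitude.  No trial averaging.
    """
    low, high = band
    if high >= ep.fs / 2:
        raise ValueError(f"band edge {high} Hz >= Nyquist ({ep.fs / 2} Hz)")
    sos = signal.butter(order, band, btype="bandpass", fs=ep.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, ep.data, axis=2)
    env = np.abs(signal.hilbert(filtered, axis=2))
    return EnvelopeSet(
        data=env,
        fs=ep.fs,
        band=(float(low), float(high)),
        window=ep.window,
        channels=list(ep.channels),
        retained=ep.retained.copy(),
    )


def filterbank_tfs(
    ep: EpochSet,
    spec: BandSpec,
    baseline: tuple[float, float],
) -> TFS:
    """Trial-averaged relative-change spectrogram over a filterbank.

    Per band: envelope, average across retained trials, subtract the mean
    amplitude in the baseline window and divide by it.  The baseline window
    must lie inside the epoch window.
    """
    spec.validate(ep.fs)
    t = ep.times
    b0, b1 = baseline
    if b0 < ep.window[0] - 1e-9 or b1 > ep.window[1] + 1e-9:
        raise ValueError(
            f"baseline {baseline} outside epoch window {ep.window}"
        )
    base_mask = (t >= b0) & (t < b1)
    if not base_mask.any():
        raise ValueError("baseline window contains no samples")
    n_ch = ep.data.shape[1]
    values = np.empty((n_ch, len(spec.bands), ep.data.shape[2]))
    for k, band in enumerate(spec.bands):
        env = band_envelope(ep, band, order=spec.order)
        mean_env = env.trial_average()  # channels x samples
        base = mean_env[:, base_mask].mean(axis=1, keepdims=True)
        if np.any(base <= 0):
            raise ValueError(
                f"non-positive baseline amplitude in band {band}; cannot normalise"
            )
        values[:, k, :] = (mean_env - base) / base
    return TFS(
        values=values,
        band_spec=spec,
        times=t,
        baseline=(float(b0), float(b1)),
        channels=list(ep.channels),
    )


def psd_periodogram(ep: EpochSet, conditions: list[str] | None = None) -> PSDSet:
    """Raw rectangular-window periodogram, trial-averaged within condition.

    Trials are grouped by their event label (e.g. ``eyes_open`` /
    ``eyes_closed``).  Frequency resolution is fs/N for N-sample trials and
    the power integrates to the mean-square signal (Parseval).
    """
    if ep.labels is None:
        raise ValueError("EpochSet has no trial labels to group by")
    if conditions is None:
        seen = []
        for lbl in ep.labels:
            if lbl not in seen:
                seen.append(lbl)
        conditions = seen
    freqs = None
    power: dict[str, np.ndarray] = {}
    for cond in conditions:
        sel = [
            k for k, lbl in enumerate(ep.labels) if lbl == cond and ep.retained[k]
        ]
        if not sel:
            raise ValueError(f"no retained trials for condition {cond!r}")
        f, pxx = signal.periodogram(
            ep.data[sel], fs=ep.fs, window="boxcar", detrend=False, axis=2
        )
        freqs = f
        power[cond] = pxx.mean(axis=0)
    return PSDSet(frequencies=freqs, power=power, channels=list(ep.channels))
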