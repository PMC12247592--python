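"""Continuous-data conditioning, epoching, trial rejection and referencing.

The conditioning chain mirrors a standard sensor-level pipeline: zero-phase
4th-order Butterworth band-pass (1-150 Hz by default), zero-phase notches
at 50 and 100 Hz, per-channel mean and linear-trend removal.  Trials are
then cut around events, outlier trials/channels are removed with a
deterministic robust-z rule (a reproducible surrogate for visual
inspection), EEG is re-referenced, and MEG gets homogeneous field
correction — a rank-3 projector that removes the spatially uniform field
component using the sensor orientation geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io_bundle import EpochSet, Modality, Recording

DEFAULT_Z_THRESH = 5.0
#: a channel is only marked bad if, besides its robust z, its variance also
#: exceeds this multiple of the median channel variance — a smooth
#: topography (signal-carrying channels have genuinely higher variance)
#: must not be culled, only grossly deviant sensors.
CHANNEL_VAR_RATIO = 10.0


@dataclass
class FilterSpec:
    """Band-pass + notch specification for continuous conditioning."""

    band: tuple[float, float] = (1.0, 150.0)
    order: int = 4
    notches: list[float] = field(default_factory=lambda: [50.0, 100.0])
    notch_halfwidth: float = 2.0

    def validate(self, fs: float) -> None:
        low, high = self.band
        if not 0 < low < high:
            raise ValueError(f"invalid band {self.band}")
        if high >= fs / 2:
            raise ValueError(f"band edge {high} Hz >= Nyquist ({fs / 2} Hz)")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        for f0 in self.notches:
            if f0 + self.notch_halfwidth >= fs / 2:
                raise ValueError(f"notch at {f0} Hz too close to Nyquist")


@dataclass
class RejectionReport:
    """Outcome of robust-z trial/channel rejection."""

    trial_variance: np.ndarray  # trials x channels
    trial_z: np.ndarray
    channel_z: np.ndarray
    removed_trials: list[int]
    removed_channels: list[str]
    threshold: float


def preprocess_continuous(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Zero-phase band-pass + notch filter, demean, linear detrend.

    Events, channel metadata and the motion trace pass through untouched.
    """
    if spec is None:
        spec = FilterSpec()
    spec.validate(rec.fs)
    if not np.all(np.isfinite(rec.data)):
        bad = [
            rec.channels[i].name
            for i in np.unique(np.nonzero(~np.isfinite(rec.data))[0])
        ]
        raise ValueError(f"non-finite samples in channels: {bad}")
    # one zero-phase pass through the band-pass + notch cascade
    stages = [
        signal.butter(spec.order, spec.band, btype="bandpass", fs=rec.fs,
                      output="sos")
    ]
    for f0 in spec.notches:
        stop = (f0 - spec.notch_halfwidth, f0 + spec.notch_halfwidth)
        stages.append(
            signal.butter(spec.order, stop, btype="bandstop", fs=rec.fs,
                          output="sos")
        )
    data = signal.sosfiltfilt(np.vstack(stages), rec.data, axis=1)
    # vectorised linear detrend (removes per-channel mean and best-fit line)
    n = data.shape[1]
    t = np.arange(n) - (n - 1) / 2.0
    slope = (data @ t) / (t @ t)
    data = data - data.mean(axis=1, keepdims=True) - slope[:, None] * t
    out = rec.copy()
    out.data = data
    return out


def epoch(
    rec: Recording,
    label: str | list[str],
    t_min: float,
    t_max: float,
) -> EpochSet:
    """Cut trials around events with the given label(s).

    The window is half-open [t_min, t_max) relative to each event sample.
    Trials whose window falls outside the recording are kept as zero-filled
    rows with ``retained = False`` (and a warning), so trial indexing stays
    aligned with the event list.
    """
    labels = [label] if isinstance(label, str) else list(label)
    matches = [(lbl, s) for lbl, s in rec.events if lbl in labels]
    if not matches:
        raise ValueError(f"no events with label(s) {labels}")
    n_samp = int(round((t_max - t_min) * rec.fs))
    n_ch = rec.data.shape[0]
    data = np.zeros((len(matches), n_ch, n_samp))
    retained = np.ones(len(matches), dtype=bool)
    trial_labels = []
    for k, (lbl, s) in enumerate(matches):
        trial_labels.append(lbl)
        i0 = s + int(round(t_min * rec.fs))
        i1 = i0 + n_samp
        if i0 < 0 or i1 > rec.n_samples:
            warnings.warn(
                f"trial {k} ({lbl!r} at sample {s}) window outside data; dropped",
                stacklevel=2,
            )
            retained[k] = False
            continue
        data[k] = rec.data[:, i0:i1]
    return EpochSet(
        data=data,
        fs=rec.fs,
        window=(t_min, t_max),
        channels=[c for c in rec.channels],
        retained=retained,
        labels=trial_labels,
    )


def _robust_z(values: np.ndarray) -> np.ndarray:
    """Median/MAD z-scores; exactly-median values get z = 0 even at MAD 0."""
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    dev = values - med
    if mad == 0:
        z = np.where(dev == 0, 0.0, np.inf * np.sign(dev))
        return z
    return dev / (1.4826 * mad)


def reject_outliers(
    ep: EpochSet, z_thresh: float = DEFAULT_Z_THRESH
) -> tuple[EpochSet, RejectionReport]:
    """Remove high-variance trials and channels by robust z-score.

    Per trial: the median (across channels) log-variance is converted to a
    robust z via median/MAD over retained trials; trials with z > z_thresh
    are dropped.  Channels whose median log-variance across trials is a
    z > z_thresh outlier are marked bad.  Deterministic; conservative at
    the default threshold so clean sessions keep nearly all trials.
    """
    if ep.retained.sum() < 4:
        raise ValueError("need at least 4 retained trials for rejection")
    good_ch = ep.good_channel_indices()
    var = ep.data.var(axis=2)  # trials x channels
    with np.errstate(divide="ignore"):
        logvar = np.log(np.where(var > 0, var, np.nan))

    trial_stat = np.nanmedian(logvar[:, good_ch], axis=1)
    idx = np.flatnonzero(ep.retained)
    trial_z = np.full(ep.n_trials, -np.inf)
    trial_z[idx] = _robust_z(trial_stat[idx])
    removed_trials = [int(i) for i in idx[trial_z[idx] > z_thresh]]

    chan_stat = np.nanmedian(logvar[ep.retained][:, good_ch], axis=0)
    chan_z_good = _robust_z(chan_stat)
    channel_z = np.zeros(len(ep.channels))
    channel_z[good_ch] = chan_z_good
    ratio_ok = chan_stat - np.median(chan_stat) > np.log(CHANNEL_VAR_RATIO)
    removed_channels = [
        ep.channels[good_ch[i]].name
        for i in np.flatnonzero((chan_z_good > z_thresh) & ratio_ok)
    ]

    out = ep.copy()
    out.retained[removed_trials] = False
    if out.retained.sum() == 0:
        raise ValueError("rejection removed all trials")
    for ch in out.channels:
        if ch.name in removed_channels:
            ch.is_good = False
    report = RejectionReport(
        trial_variance=var,
        trial_z=trial_z,
        channel_z=channel_z,
        removed_trials=removed_trials,
        removed_channels=removed_channels,
        threshold=z_thresh,
    )
    return out, report


def rereference(
    ep: EpochSet,
    scheme: str = "average",
    exclude: list[str] | tuple[str, ...] = (),
) -> EpochSet:
    """Re-reference EEG epochs.

    ``average``: subtract the instantaneous mean of all good scalp channels
    from every scalp channel.  ``average_excluding``: the reference is
    computed without the excluded channels (e.g. occipital channels in the
    alpha task, so the signal of interest does not leak into the
    reference) but subtracted from all scalp channels.  ``CRR``: identity
    — data stay referenced to the recording reference electrode.
    """
    if scheme not in ("average", "average_excluding", "CRR"):
        raise ValueError(f"unknown referencing scheme {scheme!r}")
    eeg_idx = [
        i for i, c in enumerate(ep.channels) if c.modality is Modality.EEG
    ]
    if not eeg_idx:
        raise ValueError("re-referencing applies to EEG data only")
    if any(c.modality is Modality.MEG for c in ep.channels):
        raise ValueError("re-referencing applies to EEG data only, not MEG")
    if scheme == "CRR":
        return ep.copy()
    names = set(exclude)
    missing = names - {ep.channels[i].name for i in eeg_idx}
    if scheme == "average_excluding" and missing:
        raise ValueError(f"excluded channels not present: {sorted(missing)}")
    ref_idx = [
        i
        for i in eeg_idx
        if ep.channels[i].is_good
        and (scheme == "average" or ep.channels[i].name not in names)
    ]
    if not ref_idx:
        raise ValueError("no channels available to form the reference")
    out = ep.copy()
    ref = out.data[:, ref_idx, :].mean(axis=1, keepdims=True)
    out.data[:, eeg_idx, :] -= ref
    return out


def homogeneous_field_correction(ep: EpochSet) -> EpochSet:
    """Project out the spatially uniform field from MEG epochs.

    With N the (good channels) x 3 matrix of sensor orientations, each time
    sample s is replaced by (I - N N^+) s, the least-squares residual after
    removing the best-fitting uniform field.  The projector is idempotent
    and time-invariant, so ordering with temporal filtering is immaterial.
    """
    meg_idx = [
        i for i, c in enumerate(ep.channels)
        if c.modality is Modality.MEG and c.is_good
    ]
    if len(meg_idx) < 4:
        raise ValueError("homogeneous field correction needs >= 4 good MEG channels")
    N = np.stack([ep.channels[i].orientation for i in meg_idx])
    if np.linalg.matrix_rank(N) < 3:
        raise ValueError("orientations do not span 3D")
    projector = np.eye(len(meg_idx)) - N @ np.linalg.pinv(N)
    out = ep.copy()
    block = out.data[:, meg_idx, :]
    out.data[:, meg_idx, :] = np.einsum("ij,tjs->tis", projector, block)
    return out
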