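"""Synthetic paired EEG / OPM-MEG sessions with known ground truth.

Every analysis stage in this package is exercised against simulated
sessions whose effect sizes are planted and therefore recoverable:

* a **motor task** (default 50 trials of 5 s) with a beta-band (13-30 Hz)
  source under the left motor cortex whose amplitude drops by ``erd_depth``
  during movement and rebounds by ``pmbr_gain`` (1 s raised-cosine bump
  starting 0.5 s after movement offset);
* an **alpha task** (default 5 cycles of 30 s eyes-closed / 30 s eyes-open)
  with an occipital 8-13 Hz source whose amplitude is ``alpha_gain`` times
  larger with eyes closed;
* artifacts: 50/100 Hz mains, a jittered cardiac template (clean copy on
  the ECG channel), high-frequency muscle bursts coincident with head
  movement (EEG-dominant), and a low-frequency MEG artifact from rigid-body
  motion of the sensor array through the remnant static field.

Sources mix into channels through a scalp-distance Gaussian kernel
``w = exp(-d^2 / 2 sigma^2)`` — a channel-statistical stand-in for volume
conduction (EEG, broad ``sigma_eeg``) and magnetic field spread (MEG,
focal ``sigma_meg``), not a physical lead field.

Neural signals are generated in dimensionless "signal units" in which the
baseline beta envelope is 1, then scaled to SI units per modality
(2 uV for EEG, 300 fT for MEG).  One integer seed drives named
sub-generators, so the EEG stream is bit-identical whether or not the MEG
stream is generated alongside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from functools import lru_cache

import numpy as np
from scipy import signal
from scipy.spatial.transform import Rotation

from .fieldnull import FieldModel, forward_field, rigid_transform_geometry
from .io_bundle import AxisTag, ChannelInfo, Modality, MotionTrace, Recording

GENERATOR_NAME = "megeeg-synth"
GENERATOR_VERSION = 1

HEAD_RADIUS = 0.09  # m, EEG scalp sphere
HELMET_RADIUS = 0.10  # m, OPM sensor shell
EEG_SCALE = 2e-6  # V per signal unit
MEG_SCALE = 3e-13  # T per signal unit
ECG_SCALE = 1e-4  # V per signal unit on the ECG channel

MASTER_FS = 6000.0  # Hz; common multiple of 1000 and 1200

#: 63 scalp labels: BrainProducts-style 64-electrode 10-10 set minus FT10
#: (FCz is the recording reference, AFz the ground).
EEG_CHANNEL_NAMES = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8", "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10", "AF7",
    "AF3", "AF4", "AF8", "F5", "F1", "F2", "F6", "FT9", "FT7", "FC3", "FC4",
    "FT8", "C5", "C1", "C2", "C6", "TP7", "CP3", "CPz", "CP4", "TP8", "P5",
    "P1", "P2", "P6", "PO7", "PO3", "POz", "PO4", "PO8",
]

#: occipital / parieto-occipital channels excluded from the alpha reference
OCCIPITAL_CHANNELS = [
    "Pz", "POz", "Oz", "P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8",
    "PO3", "PO4", "PO7", "PO8", "PO9", "PO10", "O1", "O2",
]


def default_residual_field() -> FieldModel:
    """Post-nulling remnant field used for the MEG motion artifact (~0.6 nT)."""
    return FieldModel.from_params([0.3, 0.15, 0.4, 0.8, -0.5, 0.3, 1.2, 0.6])


def default_remnant_field() -> FieldModel:
    """Pre-nulling remnant field (~4.6 nT RMS on the 0.25 m sphere)."""
    return FieldModel.from_params([2.8, -1.9, 3.0, 3.0, -2.0, 1.5, 4.0, 2.5])


@dataclass
class SyntheticGroundTruth:
    """Planted effect sizes and artifact amplitudes for one session.

    Artifact amplitudes are in signal units (baseline beta envelope = 1).
    """

    erd_depth: float = 0.3
    pmbr_gain: float = 0.2
    alpha_gain: float = 3.0
    sigma_eeg: float = 0.045
    sigma_meg: float = 0.025
    mains_amp: float = 0.5
    cardiac_amp: float = 0.3
    muscle_amp: float = 1.0
    noise_amp: float = 0.3
    field: FieldModel = dc_field(default_factory=default_residual_field)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_depth < 1.0:
            raise ValueError("erd_depth must be in [0, 1)")
        if self.alpha_gain < 1.0:
            raise ValueError("alpha_gain must be >= 1")
        if self.sigma_eeg <= 0 or self.sigma_meg <= 0:
            raise ValueError("mixing widths must be positive")
        for name in ("mains_amp", "cardiac_amp", "muscle_amp", "noise_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def quiet(cls, seed: int = 0, **kwargs) -> "SyntheticGroundTruth":
        """Artifact-free, effect-free truth (null-session baseline)."""
        defaults = dict(
            erd_depth=0.0,
            pmbr_gain=0.0,
            alpha_gain=1.0,
            mains_amp=0.0,
            cardiac_amp=0.0,
            muscle_amp=0.0,
            field=FieldModel(),
            seed=seed,
        )
        defaults.update(kwargs)
        return cls(**defaults)


# ---------------------------------------------------------------------------
# sensor geometry
# ---------------------------------------------------------------------------


@lru_cache(maxsize=1)
def _montage_positions() -> dict[str, np.ndarray]:
    import mne

    mne.set_log_level("ERROR")
    montage = mne.channels.make_standard_montage("standard_1005")
    return {k: np.asarray(v) for k, v in montage.get_positions()["ch_pos"].items()}


def eeg_layout(n_channels: int = 63, include_ecg: bool = True) -> list[ChannelInfo]:
    """EEG channel set on a 0.09 m scalp sphere (10-10 names, MNE positions).

    Reduced channel counts take an evenly spaced subset of the full list.
    """
    if not 1 <= n_channels <= len(EEG_CHANNEL_NAMES):
        raise ValueError(f"n_channels must be in [1, {len(EEG_CHANNEL_NAMES)}]")
    idx = np.unique(
        np.round(np.linspace(0, len(EEG_CHANNEL_NAMES) - 1, n_channels)).astype(int)
    )
    pos = _montage_positions()
    channels = []
    for i in idx:
        name = EEG_CHANNEL_NAMES[i]
        p = pos[name]
        p = p / np.linalg.norm(p) * HEAD_RADIUS
        channels.append(ChannelInfo(name=name, modality=Modality.EEG, position=p))
    if include_ecg:
        channels.append(ChannelInfo(name="ECG", modality=Modality.ECG))
    return channels


def meg_layout(n_sites: int = 64) -> list[ChannelInfo]:
    """Dual-axis OPM sites on a golden-spiral spherical cap (radius 0.10 m).

    Each site contributes a radial and a tangential channel, so the channel
    count is ``2 * n_sites`` (128 by default).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z_min, z_max = -0.25, 0.995
    channels = []
    for i in range(n_sites):
        z = z_max - (z_max - z_min) * (i + 0.5) / n_sites
        r_xy = np.sqrt(max(0.0, 1.0 - z * z))
        phi = i * golden
        u = np.array([r_xy * np.cos(phi), r_xy * np.sin(phi), z])
        pos = HELMET_RADIUS * u
        tang = np.cross([0.0, 0.0, 1.0], u)
        norm = np.linalg.norm(tang)
        tang = np.array([1.0, 0.0, 0.0]) if norm < 1e-6 else tang / norm
        site = f"S{i + 1:03d}"
        channels.append(
            ChannelInfo(
                name=f"{site}-RAD",
                modality=Modality.MEG,
                position=pos,
                orientation=u,
                axis_tag=AxisTag.RADIAL,
            )
        )
        channels.append(
            ChannelInfo(
                name=f"{site}-TAN",
                modality=Modality.MEG,
                position=pos,
                orientation=tang,
                axis_tag=AxisTag.TANGENTIAL,
            )
        )
    return channels


def _scalp_distance(source_unit: np.ndarray, channels: list[ChannelInfo]) -> np.ndarray:
    """Great-circle distance (m, on the 0.09 m head sphere) source -> channel."""
    d = np.zeros(len(channels))
    for i, ch in enumerate(channels):
        norm = np.linalg.norm(ch.position)
        if norm < 1e-12:  # ECG: no scalp position, no neural pickup
            d[i] = np.inf
            continue
        u = ch.position / norm
        d[i] = HEAD_RADIUS * np.arccos(np.clip(np.dot(source_unit, u), -1.0, 1.0))
    return d


def mixing_weights(
    source_unit: np.ndarray, channels: list[ChannelInfo], sigma: float
) -> np.ndarray:
    d = _scalp_distance(source_unit, channels)
    with np.errstate(over="ignore"):
        w = np.exp(-(d**2) / (2.0 * sigma**2))
    w[~np.isfinite(d)] = 0.0
    return w


# ---------------------------------------------------------------------------
# signal building blocks
# ---------------------------------------------------------------------------


def pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
               fs: float, rms: float) -> np.ndarray:
    """1/f-amplitude noise, flat below 1 Hz, normalised to the given RMS."""
    if rms == 0.0:
        return np.zeros((n_channels, n_samples))
    n_freq = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    # synthesise directly in the frequency domain: one inverse FFT per channel
    spec = (
        rng.standard_normal((n_channels, n_freq))
        + 1j * rng.standard_normal((n_channels, n_freq))
    ) * shaping
    out = np.fft.irfft(spec, n=n_samples, axis=1)
    scale = out.std(axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    return out / scale * rms


def narrowband_carrier(
    rng: np.random.Generator, n_samples: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Gaussian narrowband noise whose Hilbert envelope has mean 1.

    A Gaussian narrowband process with standard deviation s has mean
    envelope s * sqrt(pi/2); normalising by that makes the planted
    amplitude modulation directly recoverable from the mean envelope.
    """
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n_samples))
    s = x.std()
    if s == 0:
        return x
    return x / (s * np.sqrt(np.pi / 2.0))


def cardiac_template(fs: float, duration: float = 0.6) -> np.ndarray:
    """Stylised PQRST pulse (unit R-peak) sampled at ``fs``."""
    t = np.arange(int(round(duration * fs))) / fs
    r = np.exp(-((t - 0.20) ** 2) / (2 * 0.012**2))
    q = -0.15 * np.exp(-((t - 0.17) ** 2) / (2 * 0.008**2))
    s = -0.20 * np.exp(-((t - 0.23) ** 2) / (2 * 0.008**2))
    tw = 0.25 * np.exp(-((t - 0.45) ** 2) / (2 * 0.04**2))
    return r + q + s + tw


def cardiac_beat_times(
    rng: np.random.Generator, duration: float, bpm: float = 72.0,
    jitter: float = 0.05,
) -> np.ndarray:
    """Beat onset times with fractional inter-beat-interval jitter."""
    ibi = 60.0 / bpm
    times = []
    t = 0.3
    while t < duration - 0.7:
        times.append(t)
        t += ibi * (1.0 + jitter * rng.standard_normal())
    return np.array(times)


def _add_pulses(out: np.ndarray, template: np.ndarray, times: np.ndarray,
                weights: np.ndarray, fs: float) -> None:
    """Add ``weights[c] * template`` at each onset time, in place."""
    n = out.shape[1]
    for t0 in times:
        i0 = int(round(t0 * fs))
        i1 = min(i0 + template.size, n)
        if i0 >= n:
            break
        out[:, i0:i1] += weights[:, None] * template[: i1 - i0]


def _raised_cosine(t: np.ndarray, t0: float, width: float) -> np.ndarray:
    """0.5*(1 - cos) bump on [t0, t0+width), zero elsewhere; unit peak."""
    x = (t - t0) / width
    bump = 0.5 * (1.0 - np.cos(2.0 * np.pi * x))
    bump[(x < 0) | (x >= 1)] = 0.0
    return bump


def _add_bump(out: np.ndarray, fs: float, t0: float, width: float,
              amp: float) -> None:
    """Add amp * raised-cosine on [t0, t0+width) in place (slice-local)."""
    n = out.shape[-1]
    i0 = max(int(np.ceil(t0 * fs)), 0)
    i1 = min(int(np.ceil((t0 + width) * fs)), n)
    if i1 <= i0:
        return
    x = (np.arange(i0, i1) / fs - t0) / width
    out[..., i0:i1] += amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * x))


# ---------------------------------------------------------------------------
# task envelopes
# ---------------------------------------------------------------------------


def motor_offset_times(n_trials: int, trial_duration: float = 5.0) -> np.ndarray:
    """Movement-offset times: first offset at 2 s, one per trial."""
    return 2.0 + trial_duration * np.arange(n_trials)


def beta_envelope_profile(
    t_rel: np.ndarray, erd_depth: float, pmbr_gain: float
) -> np.ndarray:
    """Planted beta amplitude vs time relative to movement offset.

    1 at baseline; (1 - erd_depth) during movement [-1, 0); plus a 1 s
    raised-cosine rebound of peak ``pmbr_gain`` on [0.5, 1.5).  This is the
    analytic oracle for envelope-recovery tests.
    """
    a = np.ones_like(t_rel, dtype=float)
    a[(t_rel >= -1.0) & (t_rel < 0.0)] -= erd_depth
    a += pmbr_gain * _raised_cosine(t_rel, 0.5, 1.0)
    return a


def _motor_amplitude(t: np.ndarray, offsets: np.ndarray, truth) -> np.ndarray:
    a = np.ones_like(t)
    fs = 1.0 / (t[1] - t[0])
    n = t.size
    for off in offsets:
        i0 = max(int(np.ceil((off - 1.0) * fs)), 0)
        i1 = min(int(np.ceil(off * fs)), n)
        a[i0:i1] -= truth.erd_depth
        _add_bump(a, fs, off + 0.5, 1.0, truth.pmbr_gain)
    return a


def alpha_instruction_times(
    n_cycles: int, cycle_duration: float = 30.0, start: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """(eyes-closed, eyes-open) instruction times for alternating cycles."""
    closed = start + 2.0 * cycle_duration * np.arange(n_cycles)
    opened = closed + cycle_duration
    return closed, opened


def _alpha_amplitude(
    t: np.ndarray, closed: np.ndarray, opened: np.ndarray, gain: float
) -> np.ndarray:
    a = np.ones_like(t)
    for c, o in zip(closed, opened):
        a[(t >= c) & (t < o)] = gain
    return a


# ---------------------------------------------------------------------------
# helmet motion
# ---------------------------------------------------------------------------


def _motion_burst_times(
    rng: np.random.Generator, n_bursts: int, duration: float, margin: float = 4.0
) -> np.ndarray:
    if n_bursts == 0 or duration <= 2 * margin:
        return np.array([])
    centres = np.linspace(margin, duration - margin, n_bursts)
    jitter = (duration - 2 * margin) / max(n_bursts, 1) * 0.2
    return np.sort(centres + jitter * rng.uniform(-1, 1, size=n_bursts))


def generate_helmet_motion(
    rng: np.random.Generator,
    duration: float,
    fs_motion: float = 120.0,
    n_bursts: int = 6,
    burst_displacement: float = 0.03,
    burst_rotation: float = 0.08,
    burst_width: float = 0.5,
    baseline_sway: float = 0.002,
) -> tuple[MotionTrace, np.ndarray]:
    """Helmet motion: slow sub-threshold sway plus discrete movement bursts.

    Each burst is an out-and-back raised-cosine displacement (~0.03 m over
    0.5 s, peak speed ~0.19 m/s, above the 0.1 m/s detection threshold)
    with an accompanying small rotation.  Returns the trace and the burst
    centre times.
    """
    n = int(round(duration * fs_motion))
    t = np.arange(n) / fs_motion
    sos = signal.butter(2, 0.2, btype="lowpass", fs=fs_motion, output="sos")
    sway = signal.sosfiltfilt(sos, rng.standard_normal((3, n)), axis=1)
    sway = sway / np.maximum(sway.std(axis=1, keepdims=True), 1e-12) * baseline_sway
    position = sway.T.copy()
    rotvec = np.zeros((n, 3))
    bursts = _motion_burst_times(rng, n_bursts, duration)
    for t0 in bursts:
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        bump = _raised_cosine(t, t0 - burst_width / 2.0, burst_width)
        position += burst_displacement * bump[:, None] * direction
        rotvec += burst_rotation * bump[:, None] * axis
    quat = Rotation.from_rotvec(rotvec).as_quat()
    quat /= np.linalg.norm(quat, axis=1, keepdims=True)
    return MotionTrace(fs_motion=fs_motion, position=position, rotation=quat), bursts


def motion_field_artifact(
    field_model: FieldModel,
    motion: MotionTrace,
    channels: list[ChannelInfo],
    chunk: int = 2000,
) -> np.ndarray:
    """Per-channel nT reading from rigid-body motion through the static field.

    Returns channels x motion-samples, referenced to the rest pose (first
    sample) so that a still helmet reads zero.  Computed in sample chunks to
    bound memory at full array sizes.
    """
    positions = np.stack([c.position for c in channels])
    orientations = np.stack([c.orientation for c in channels])
    n = motion.n_samples
    out = np.empty((len(channels), n))
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        sub = MotionTrace(
            fs_motion=motion.fs_motion,
            position=motion.position[sl],
            rotation=None if motion.rotation is None else motion.rotation[sl],
        )
        x_room, n_room = rigid_transform_geometry(sub, positions, orientations)
        out[:, sl] = forward_field(field_model, x_room, n_room).T
    rest = forward_field(
        field_model, positions[None, :, :], orientations[None, :, :]
    ).T
    return out - rest


# ---------------------------------------------------------------------------
# session generation
# ---------------------------------------------------------------------------


def _named_rngs(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


_RNG_NAMES = (
    "source", "motion", "cardiac", "eeg_noise", "meg_noise",
    "eeg_artifact", "meg_artifact", "mains",
)


def _source_unit_vector(name: str) -> np.ndarray:
    p = _montage_positions()[name]
    return p / np.linalg.norm(p)


def generate_session(
    task: str,
    truth: SyntheticGroundTruth,
    *,
    n_trials: int = 50,
    trial_duration: float = 5.0,
    n_cycles: int = 5,
    cycle_duration: float = 30.0,
    n_eeg: int = 63,
    n_meg_sites: int = 64,
    modalities: tuple[str, ...] = ("eeg", "meg"),
    fs_eeg: float = 1000.0,
    fs_meg: float = 1200.0,
    fs_motion: float = 120.0,
    n_motion_bursts: int = 6,
) -> tuple[Recording | None, Recording | None, SyntheticGroundTruth]:
    """Generate one paired session for the motor or alpha task.

    Returns ``(eeg, meg, truth)``; a modality not listed in ``modalities``
    comes back as ``None``.  Identical seeds give bit-identical output, and
    the EEG stream does not depend on whether MEG is generated (named
    sub-generators per component).
    """
    if task not in ("motor", "alpha"):
        raise ValueError(f"unknown task {task!r}")
    rngs = _named_rngs(truth.seed, _RNG_NAMES)

    if task == "motor":
        offsets = motor_offset_times(n_trials, trial_duration)
        duration = offsets[-1] + 4.0 + 1.0
        source_unit = _source_unit_vector("C3")
        band = (13.0, 30.0)
    else:
        closed, opened = alpha_instruction_times(n_cycles, cycle_duration)
        duration = opened[-1] + cycle_duration + 0.5
        source_unit = _source_unit_vector("Oz")
        band = (8.0, 13.0)

    n_master = int(round(duration * MASTER_FS))
    t_master = np.arange(n_master) / MASTER_FS
    carrier = narrowband_carrier(rngs["source"], n_master, MASTER_FS, band)
    if task == "motor":
        amp = _motor_amplitude(t_master, offsets, truth)
    else:
        amp = _alpha_amplitude(t_master, closed, opened, truth.alpha_gain)
    source_master = amp * carrier

    motion, burst_times = generate_helmet_motion(
        rngs["motion"], duration, fs_motion=fs_motion, n_bursts=n_motion_bursts
    )
    beats = cardiac_beat_times(rngs["cardiac"], duration)

    def events_for(fs: float) -> list[tuple[str, int]]:
        ev = [("sync", 0)]
        if task == "motor":
            for off in offsets:
                ev.append(("cue", int(round((off - 2.0) * fs))))
                ev.append(("move_offset", int(round(off * fs))))
        else:
            for tc in closed:
                ev.append(("eyes_closed", int(round(tc * fs))))
            for to in opened:
                ev.append(("eyes_open", int(round(to * fs))))
        ev.sort(key=lambda e: e[1])
        return ev

    def build_modality(which: str) -> Recording:
        if which == "eeg":
            fs = fs_eeg
            channels = eeg_layout(n_eeg, include_ecg=True)
            sigma = truth.sigma_eeg
            rng_noise, rng_art = rngs["eeg_noise"], rngs["eeg_artifact"]
            muscle_amp = truth.muscle_amp
        else:
            fs = fs_meg
            channels = meg_layout(n_meg_sites)
            sigma = truth.sigma_meg
            rng_noise, rng_art = rngs["meg_noise"], rngs["meg_artifact"]
            muscle_amp = truth.muscle_amp / 20.0  # MEG barely sees muscle
        step = int(round(MASTER_FS / fs))
        source = source_master[::step]
        n = source.size
        t = np.arange(n) / fs
        weights = mixing_weights(source_unit, channels, sigma)
        data = weights[:, None] * source[None, :]
        data += pink_noise(rng_noise, len(channels), n, fs, truth.noise_amp)
        if truth.mains_amp > 0:
            ph1, ph2 = rngs["mains"].uniform(0, 2 * np.pi, size=2)
            gains = 1.0 + 0.2 * rng_art.standard_normal(len(channels))
            mains = truth.mains_amp * (
                np.sin(2 * np.pi * 50.0 * t + ph1)
                + 0.4 * np.sin(2 * np.pi * 100.0 * t + ph2)
            )
            data += gains[:, None] * mains[None, :]
        if truth.cardiac_amp > 0 and beats.size:
            template = cardiac_template(fs)
            w = truth.cardiac_amp * (0.5 + rng_art.random(len(channels)))
            _add_pulses(data, template, beats, w, fs)
        if muscle_amp > 0 and burst_times.size:
            sos = signal.butter(
                4, (60.0, min(130.0, fs / 2 - 10)), btype="bandpass",
                fs=fs, output="sos",
            )
            hf = signal.sosfiltfilt(sos, rng_art.standard_normal(n))
            hf /= max(hf.std(), 1e-12)
            env = np.zeros(n)
            for t0 in burst_times:
                _add_bump(env, fs, t0 - 0.25, 0.5, 1.0)
            w = muscle_amp * (0.3 + rng_art.random(len(channels)))
            data += w[:, None] * (hf * env)[None, :]
        if which == "eeg":
            # ECG channel: clean cardiac template train, replaces neural mix
            ecg_idx = [i for i, c in enumerate(channels)
                       if c.modality is Modality.ECG]
            if ecg_idx and beats.size:
                i = ecg_idx[0]
                data[i] = 0.01 * rng_noise.standard_normal(n)
                _add_pulses(
                    data[i:i + 1], cardiac_template(fs), beats,
                    np.array([ECG_SCALE / EEG_SCALE]), fs,
                )
            data *= EEG_SCALE
        else:
            if np.any(np.abs(truth.field.to_params()) > 0):
                art_nT = motion_field_artifact(truth.field, motion, channels)
                t_motion = motion.times
                art = np.empty((len(channels), n))
                for c in range(len(channels)):
                    art[c] = np.interp(t, t_motion, art_nT[c])
                data += art * (1e-9 / MEG_SCALE)
            data *= MEG_SCALE
        return Recording(
            fs=fs, data=data, channels=channels, events=events_for(fs),
            motion=motion,
        )

    rec_eeg = build_modality("eeg") if "eeg" in modalities else None
    rec_meg = build_modality("meg") if "meg" in modalities else None
    return rec_eeg, rec_meg, truth


# ---------------------------------------------------------------------------
# field-mapping sessions
# ---------------------------------------------------------------------------


def generate_fieldmap_session(
    field_model: FieldModel,
    *,
    geometry: list[ChannelInfo] | None = None,
    movement_amplitude: tuple[float, float] = (0.03, 0.2),
    duration: float = 60.0,
    noise: float = 0.01,
    fs: float = 120.0,
    seed: int = 0,
) -> tuple[np.ndarray, MotionTrace]:
    """Simulate a head-movement field-mapping run.

    The helmet executes smooth multi-axis translations (RMS
    ``movement_amplitude[0]`` metres) and rotations (RMS
    ``movement_amplitude[1]`` radians); channel ``i`` at sample ``t`` reads
    ``n_i(t) . (B0 + G x_i(t)) + noise`` in nT, sampled on the motion time
    base.  ``noise`` is the additive white noise RMS in nT.
    """
    import warnings as _warnings

    if duration <= 0:
        raise ValueError("duration must be positive")
    if geometry is None:
        geometry = meg_layout(64)
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    trans_amp, rot_amp = movement_amplitude
    if trans_amp == 0 and rot_amp == 0 and np.any(np.abs(field_model.G) > 0):
        _warnings.warn("gradient unidentifiable without movement", stacklevel=2)

    def smooth_multiaxis(amp: float) -> np.ndarray:
        out = np.zeros((n, 3))
        if amp == 0:
            return out
        for axis in range(3):
            for _ in range(2):
                f = rng.uniform(0.08, 0.45)
                ph = rng.uniform(0, 2 * np.pi)
                out[:, axis] += np.sin(2 * np.pi * f * t + ph)
        rms = out.std(axis=0, keepdims=True)
        rms[rms == 0] = 1.0
        return out / rms * amp

    position = smooth_multiaxis(trans_amp)
    rotvec = smooth_multiaxis(rot_amp)
    quat = Rotation.from_rotvec(rotvec).as_quat()
    norms = np.linalg.norm(quat, axis=1, keepdims=True)
    motion = MotionTrace(fs_motion=fs, position=position, rotation=quat / norms)

    positions = np.stack([c.position for c in geometry])
    orientations = np.stack([c.orientation for c in geometry])
    x_room, n_room = rigid_transform_geometry(motion, positions, orientations)
    opm = forward_field(field_model, x_room, n_room).T
    if noise > 0:
        opm = opm + noise * rng.standard_normal(opm.shape)
    return opm, motion
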