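"""Data model and on-disk persistence for paired EEG / OPM-MEG sessions.

The in-memory containers (:class:`Recording`, :class:`EpochSet`,
:class:`MotionTrace`, :class:`Session`) are the universal currency of the
package: the synthetic generator produces them, the preprocessing and
analysis stages consume and return them.  On disk, a session is a single
HDF5 "bundle" with groups ``/eeg``, ``/meg``, ``/motion`` and ``/meta`` so
that one file carries both modalities at their native sampling rates.

Units are SI throughout: volts (EEG), tesla (MEG), metres, seconds.
Sample indices are 0-based and epoch windows are half-open
``[t_min, t_max)`` in seconds relative to the event sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

BUNDLE_VERSION = 1

#: unit converters for display (SI -> conventional)
V_TO_UV = 1e6
T_TO_FT = 1e15
T_TO_NT = 1e9


class Modality(str, Enum):
    EEG = "EEG"
    MEG = "MEG"
    ECG = "ECG"
    TRIGGER = "TRIGGER"


class AxisTag(str, Enum):
    RADIAL = "radial"
    TANGENTIAL = "tangential"
    NONE = "none"


class BundleFormatError(ValueError):
    """Raised when an on-disk bundle is missing mandatory content."""


@dataclass
class ChannelInfo:
    """One sensor channel: label, modality and head-frame geometry.

    ``position`` is in metres in a head-fixed frame; ``orientation`` is the
    unit sensitive-axis vector for MEG channels (dual-axis magnetometers
    contribute two channels per site, tagged radial / tangential) and is
    meaningless for EEG.
    """

    name: str
    modality: Modality
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray | None = None
    axis_tag: AxisTag = AxisTag.NONE
    is_good: bool = True

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        self.axis_tag = AxisTag(self.axis_tag)
        self.position = np.asarray(self.position, dtype=float)
        if self.orientation is not None:
            self.orientation = np.asarray(self.orientation, dtype=float)
        if self.modality is Modality.MEG:
            if self.orientation is None:
                raise ValueError(f"MEG channel {self.name!r} needs an orientation")
            n = float(np.linalg.norm(self.orientation))
            if abs(n - 1.0) > 1e-9:
                raise ValueError(
                    f"MEG channel {self.name!r} orientation norm {n} != 1"
                )


@dataclass
class MotionTrace:
    """Rigid-body helmet motion: position (m) and optional unit quaternion."""

    fs_motion: float
    position: np.ndarray
    rotation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.position = np.atleast_2d(np.asarray(self.position, dtype=float))
        if self.position.shape[1] != 3:
            raise ValueError("motion position must be samples x 3")
        if self.rotation is not None:
            self.rotation = np.asarray(self.rotation, dtype=float)
            if self.rotation.shape != (self.position.shape[0], 4):
                raise ValueError("rotation must be samples x 4 quaternions")
            norms = np.linalg.norm(self.rotation, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("quaternions must have unit norm")

    @property
    def n_samples(self) -> int:
        return self.position.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_motion


@dataclass
class Recording:
    """Continuous multichannel data with channel metadata and events.

    ``data`` is channels x samples, ``events`` a list of ``(label, sample)``
    with 0-based sample indices into the recording.
    """

    fs: float
    data: np.ndarray
    channels: list[ChannelInfo]
    events: list[tuple[str, int]] = field(default_factory=list)
    motion: MotionTrace | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channels)} channels"
            )
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        n = self.data.shape[1]
        for label, s in self.events:
            if not 0 <= int(s) < n:
                raise ValueError(f"event {label!r} at sample {s} outside [0, {n})")
        self.events = [(str(lbl), int(s)) for lbl, s in self.events]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def picks(self, modality: Modality | str) -> np.ndarray:
        m = Modality(modality)
        return np.array(
            [i for i, c in enumerate(self.channels) if c.modality is m], dtype=int
        )

    def copy(self) -> "Recording":
        return Recording(
            fs=self.fs,
            data=self.data.copy(),
            channels=[replace(c) for c in self.channels],
            events=list(self.events),
            motion=self.motion,
        )


@dataclass
class EpochSet:
    """Trials cut around events: trials x channels x samples.

    ``window`` is the half-open epoch window in seconds relative to the
    event; ``retained`` marks trials that survived cutting / rejection;
    ``labels`` carries the originating event label per trial (used to group
    eyes-open vs eyes-closed conditions).
    """

    data: np.ndarray
    fs: float
    window: tuple[float, float]
    channels: list[ChannelInfo]
    retained: np.ndarray | None = None
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("EpochSet data must be trials x channels x samples")
        n_trials = self.data.shape[0]
        expected = int(round((self.window[1] - self.window[0]) * self.fs))
        if self.data.shape[2] != expected:
            raise ValueError(
                f"window {self.window} at fs {self.fs} implies {expected} "
                f"samples, got {self.data.shape[2]}"
            )
        if self.retained is None:
            self.retained = np.ones(n_trials, dtype=bool)
        self.retained = np.asarray(self.retained, dtype=bool)
        if self.retained.shape != (n_trials,):
            raise ValueError("retained mask length must equal trial count")
        if self.labels is not None and len(self.labels) != n_trials:
            raise ValueError("labels length must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.data.shape[2]) / self.fs

    def retained_data(self) -> np.ndarray:
        return self.data[self.retained]

    def good_channel_indices(self) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(self.channels) if c.is_good], dtype=int
        )

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            fs=self.fs,
            window=self.window,
            channels=[replace(c) for c in self.channels],
            retained=self.retained.copy(),
            labels=None if self.labels is None else list(self.labels),
        )


@dataclass
class Session:
    """One experimental session: EEG and/or MEG streams plus shared motion."""

    eeg: Recording | None = None
    meg: Recording | None = None
    motion: MotionTrace | None = None
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# HDF5 bundle persistence
# ---------------------------------------------------------------------------


def _write_channels(grp: h5py.Group, channels: Sequence[ChannelInfo]) -> None:
    grp.create_dataset(
        "names", data=np.array([c.name for c in channels], dtype="S64")
    )
    grp.create_dataset(
        "modality", data=np.array([c.modality.value for c in channels], dtype="S8")
    )
    grp.create_dataset(
        "axis_tag", data=np.array([c.axis_tag.value for c in channels], dtype="S16")
    )
    grp.create_dataset("position", data=np.stack([c.position for c in channels]))
    ori = np.stack(
        [
            c.orientation if c.orientation is not None else np.full(3, np.nan)
            for c in channels
        ]
    )
    grp.create_dataset("orientation", data=ori)
    grp.create_dataset(
        "is_good", data=np.array([c.is_good for c in channels], dtype=bool)
    )


def _read_channels(grp: h5py.Group) -> list[ChannelInfo]:
    names = [n.decode() for n in grp["names"][()]]
    mods = [m.decode() for m in grp["modality"][()]]
    tags = [t.decode() for t in grp["axis_tag"][()]]
    pos = grp["position"][()]
    ori = grp["orientation"][()]
    good = grp["is_good"][()]
    out = []
    for i, name in enumerate(names):
        o = None if np.any(np.isnan(ori[i])) else ori[i]
        out.append(
            ChannelInfo(
                name=name,
                modality=Modality(mods[i]),
                position=pos[i],
                orientation=o,
                axis_tag=AxisTag(tags[i]),
                is_good=bool(good[i]),
            )
        )
    return out


def _write_recording(grp: h5py.Group, rec: Recording) -> None:
    grp.create_dataset("data", data=rec.data)
    grp.attrs["fs"] = rec.fs
    _write_channels(grp.create_group("channels"), rec.channels)
    ev = grp.create_group("events")
    ev.create_dataset(
        "labels", data=np.array([e[0] for e in rec.events], dtype="S64")
    )
    ev.create_dataset(
        "samples", data=np.array([e[1] for e in rec.events], dtype=np.int64)
    )


def _read_recording(grp: h5py.Group) -> Recording:
    for needed in ("data", "channels", "events"):
        if needed not in grp:
            raise BundleFormatError(
                f"bundle group {grp.name!r} missing mandatory dataset {needed!r}"
            )
    ev = grp["events"]
    events = [
        (lbl.decode(), int(s))
        for lbl, s in zip(ev["labels"][()], ev["samples"][()])
    ]
    return Recording(
        fs=float(grp.attrs["fs"]),
        data=grp["data"][()],
        channels=_read_channels(grp["channels"]),
        events=events,
    )


def _write_motion(grp: h5py.Group, motion: MotionTrace) -> None:
    grp.attrs["fs_motion"] = motion.fs_motion
    grp.create_dataset("position", data=motion.position)
    if motion.rotation is not None:
        grp.create_dataset("rotation", data=motion.rotation)


def _read_motion(grp: h5py.Group) -> MotionTrace:
    return MotionTrace(
        fs_motion=float(grp.attrs["fs_motion"]),
        position=grp["position"][()],
        rotation=grp["rotation"][()] if "rotation" in grp else None,
    )


def write_bundle(obj: Session | Recording, path: str | Path) -> None:
    """Write a session (or a single recording) to an HDF5 bundle.

    A bare :class:`Recording` is stored under ``/eeg`` or ``/meg`` depending
    on whether it contains any MEG channels.
    """
    if isinstance(obj, Recording):
        has_meg = any(c.modality is Modality.MEG for c in obj.channels)
        obj = Session(meg=obj) if has_meg else Session(eeg=obj)
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["bundle_version"] = BUNDLE_VERSION
        for key, val in obj.meta.items():
            meta.attrs[str(key)] = val
        if obj.eeg is not None:
            _write_recording(f.create_group("eeg"), obj.eeg)
            if obj.eeg.motion is not None and obj.motion is None:
                obj = replace(obj, motion=obj.eeg.motion)
        if obj.meg is not None:
            _write_recording(f.create_group("meg"), obj.meg)
            if obj.meg.motion is not None and obj.motion is None:
                obj = replace(obj, motion=obj.meg.motion)
        if obj.motion is not None:
            _write_motion(f.create_group("motion"), obj.motion)


def read_bundle(path: str | Path) -> Session:
    """Read an HDF5 bundle back into a :class:`Session` (lossless)."""
    with h5py.File(path, "r") as f:
        if "meta" not in f:
            raise BundleFormatError("bundle missing mandatory group 'meta'")
        version = int(f["meta"].attrs.get("bundle_version", -1))
        if version != BUNDLE_VERSION:
            raise BundleFormatError(
                f"bundle version {version} not supported "
                f"(expected {BUNDLE_VERSION})"
            )
        if "eeg" not in f and "meg" not in f:
            raise BundleFormatError("bundle contains neither 'eeg' nor 'meg' group")
        sess = Session(
            eeg=_read_recording(f["eeg"]) if "eeg" in f else None,
            meg=_read_recording(f["meg"]) if "meg" in f else None,
            motion=_read_motion(f["motion"]) if "motion" in f else None,
            meta={k: f["meta"].attrs[k] for k in f["meta"].attrs
                  if k != "bundle_version"},
        )
    if sess.motion is not None:
        for rec in (sess.eeg, sess.meg):
            if rec is not None:
                rec.motion = sess.motion
    return sess


def read_motion_csv(path: str | Path, fs_motion: float = 120.0) -> MotionTrace:
    """Read a motion trace from CSV.

    Expected columns: ``x, y, z`` (metres) and optionally ``qx, qy, qz,
    qw`` (unit quaternion).  The sample rate is not stored in the file and
    must be supplied (default 120 Hz).
    """
    import csv

    with open(path, newline="") as f:
        rows = list(csv.DictReader(f))
    if not rows:
        raise ValueError(f"empty motion CSV: {path}")
    for col in ("x", "y", "z"):
        if col not in rows[0]:
            raise ValueError(f"motion CSV missing column {col!r}")
    position = np.array(
        [[float(r["x"]), float(r["y"]), float(r["z"])] for r in rows]
    )
    rotation = None
    if all(c in rows[0] for c in ("qx", "qy", "qz", "qw")):
        rotation = np.array(
            [[float(r["qx"]), float(r["qy"]), float(r["qz"]), float(r["qw"])]
             for r in rows]
        )
    return MotionTrace(fs_motion=fs_motion, position=position,
                       rotation=rotation)


# ---------------------------------------------------------------------------
# BrainVision import
# ---------------------------------------------------------------------------


def import_brainvision(header_path: str | Path, ecg_channel: str = "ECG") -> Recording:
    """Import a BrainVision vhdr/vmrk/eeg triplet as a :class:`Recording`.

    Scalp channels get modality EEG; the channel named ``ecg_channel`` (if
    present) is tagged ECG.  Markers become events with their description as
    the label.  Fails on empty data; a missing marker file yields an empty
    event list with a warning (MNE warns; we re-raise as events=[]).
    """
    import mne

    header_path = Path(header_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_brainvision(header_path, preload=True, verbose="ERROR")
    data = raw.get_data()
    if data.size == 0 or data.shape[1] == 0:
        raise ValueError("empty data in BrainVision file")
    channels = []
    for name in raw.ch_names:
        mod = Modality.ECG if name == ecg_channel else Modality.EEG
        channels.append(ChannelInfo(name=name, modality=mod))
    events = []
    for ann in raw.annotations:
        sample = int(round(ann["onset"] * raw.info["sfreq"]))
        if 0 <= sample < data.shape[1]:
            events.append((str(ann["description"]), sample))
    if not events:
        warnings.warn(f"no markers found for {header_path.name}", stacklevel=2)
    return Recording(
        fs=float(raw.info["sfreq"]), data=data, channels=channels, events=events
    )
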