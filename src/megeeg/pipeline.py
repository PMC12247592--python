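"""Study-level orchestration: per-session analyses, group tables, reports.

A study is a manifest of sessions — each a (participant, condition, task)
triple with its data — where condition is ``eeg_only``, ``meg_only`` or
``simultaneous``.  The motor analysis chain per session and modality is
preprocess -> epoch (-1, 4) s around movement offset -> robust trial
rejection -> (average re-reference | homogeneous field correction) ->
beta envelopes -> SNR -> best channel -> spread fraction.  The alpha chain
is preprocess -> cardiac template subtraction -> epoch (1, 6) s per
instruction -> (occipital-excluded average reference | HFC) -> periodogram
PSD per condition -> alpha contrast -> best channel.  Group comparisons
(with vs without the other modality) use the two-sided rank-sum test.

Cardiac removal is a deterministic ECG-locked template subtraction: beats
are detected on the ECG channel, a per-channel beat-locked average is
formed and subtracted at each beat.  An alternative decomposition-based
cleaner can be plugged in via the ``cardiac_cleaner`` hook.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .fieldnull import CoilCalibration, FieldModel, nulling_cycle
from .io_bundle import EpochSet, Modality, Recording, Session, read_bundle
from .metrics import (
    SnrConfig,
    alpha_contrast,
    best_channel,
    pearson_corr,
    rank_sum_test,
    snr_beta,
    spread_fraction,
)
from .preprocess import (
    FilterSpec,
    epoch,
    homogeneous_field_correction,
    preprocess_continuous,
    reject_outliers,
    rereference,
)
from .spectral import band_envelope, psd_periodogram
from .synthetic import (
    OCCIPITAL_CHANNELS,
    SyntheticGroundTruth,
    generate_session,
)

#: reduced session sizes used for replicate (many-seed) experiments; the
#: generator defaults stay at full study scale.
REPLICATE_MOTOR_KW = dict(n_trials=8, n_eeg=12, n_meg_sites=8, n_motion_bursts=2)
REPLICATE_ALPHA_KW = dict(
    n_cycles=4, cycle_duration=6.0, n_eeg=12, n_meg_sites=8, n_motion_bursts=2
)


@dataclass
class SessionEntry:
    """One manifest row: who, which condition, which task, and the data.

    ``session`` may be an in-memory :class:`Session`, a bundle path, or —
    for field-nulling studies — a :class:`FieldModel`.
    """

    participant: str
    condition: str
    task: str
    session: Session | FieldModel | str | Path

    def load(self) -> Session | FieldModel:
        if isinstance(self.session, (str, Path)):
            return read_bundle(self.session)
        return self.session


@dataclass
class StudyManifest:
    entries: list[SessionEntry]

    def __post_init__(self) -> None:
        keys = [(e.participant, e.condition, e.task) for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("(participant, condition, task) must be unique")
        if not self.entries:
            raise ValueError("empty manifest")


@dataclass
class AnalysisConfig:
    """Defaults mirror the sensor-level analysis choices throughout."""

    filter: FilterSpec = field(default_factory=FilterSpec)
    z_thresh: float = 5.0
    snr: SnrConfig = field(default_factory=SnrConfig)
    motor_window: tuple[float, float] = (-1.0, 4.0)
    motor_baseline: tuple[float, float] = (3.0, 4.0)
    alpha_window: tuple[float, float] = (1.0, 6.0)
    alpha_band: tuple[float, float] = (8.0, 13.0)
    envelope_order: int = 3
    r_thresh: float = 0.3
    occipital_exclude: tuple[str, ...] = tuple(OCCIPITAL_CHANNELS)
    eeg_motor_reference: str = "average"
    eeg_alpha_reference: str = "average_excluding"


def _drop_modality(ep: EpochSet, modality: Modality) -> EpochSet:
    keep = [i for i, c in enumerate(ep.channels) if c.modality is not modality]
    return EpochSet(
        data=ep.data[:, keep, :],
        fs=ep.fs,
        window=ep.window,
        channels=[ep.channels[i] for i in keep],
        retained=ep.retained.copy(),
        labels=None if ep.labels is None else list(ep.labels),
    )


# ---------------------------------------------------------------------------
# cardiac template subtraction
# ---------------------------------------------------------------------------


def detect_heartbeats(rec: Recording) -> np.ndarray:
    """R-peak sample indices from the ECG channel (peak picking)."""
    ecg_idx = [i for i, c in enumerate(rec.channels) if c.modality is Modality.ECG]
    if not ecg_idx:
        raise ValueError("recording has no ECG channel")
    ecg = rec.data[ecg_idx[0]]
    ecg = ecg * np.sign(np.abs(ecg.max()) - np.abs(ecg.min()) or 1.0)
    height = 0.5 * ecg.max()
    peaks, _ = sp_signal.find_peaks(
        ecg, height=height, distance=int(0.4 * rec.fs)
    )
    return peaks


def subtract_cardiac(
    rec: Recording,
    beat_samples: np.ndarray | None = None,
    window: tuple[float, float] = (-0.25, 0.45),
) -> tuple[Recording, np.ndarray]:
    """Remove the cardiac artifact by beat-locked template subtraction.

    A per-channel average around each beat (the template) is subtracted at
    every beat.  Beats are detected on the ECG channel unless sample
    indices are supplied (e.g. mapped from a simultaneous EEG stream for a
    MEG recording without its own ECG).
    """
    if beat_samples is None:
        beat_samples = detect_heartbeats(rec)
    beat_samples = np.asarray(beat_samples, dtype=int)
    out = rec.copy()
    if beat_samples.size < 3:
        warnings.warn("fewer than 3 beats found; cardiac subtraction skipped",
                      stacklevel=2)
        return out, beat_samples
    i_lo = int(round(window[0] * rec.fs))
    i_hi = int(round(window[1] * rec.fs))
    width = i_hi - i_lo
    usable = beat_samples[
        (beat_samples + i_lo >= 0) & (beat_samples + i_hi <= rec.n_samples)
    ]
    segments = np.stack([out.data[:, b + i_lo:b + i_lo + width] for b in usable])
    template = segments.mean(axis=0)
    for b in usable:
        out.data[:, b + i_lo:b + i_lo + width] -= template
    return out, beat_samples


# ---------------------------------------------------------------------------
# per-session analyses
# ---------------------------------------------------------------------------


def analyse_motor_session(
    rec: Recording, modality: str, config: AnalysisConfig | None = None
) -> dict:
    """Full motor-task chain for one recording; returns the channel metrics."""
    if config is None:
        config = AnalysisConfig()
    rec = preprocess_continuous(rec, config.filter)
    ep = epoch(rec, "move_offset", *config.motor_window)
    ep, report = reject_outliers(ep, config.z_thresh)
    if modality == "eeg":
        ep = rereference(ep, config.eeg_motor_reference)
        ep = _drop_modality(ep, Modality.ECG)
    else:
        ep = homogeneous_field_correction(ep)
    env = band_envelope(ep, config.snr.beta_band, order=config.envelope_order)
    snr = snr_beta(env, config.snr)
    best = best_channel(snr)
    spread = spread_fraction(env, best, config.r_thresh)
    return {
        "snr": snr,
        "best_channel": best,
        "snr_best": snr[best],
        "spread_fraction": spread,
        "n_trials_retained": int(ep.retained.sum()),
        "rejection": report,
    }


def analyse_alpha_session(
    rec: Recording,
    modality: str,
    config: AnalysisConfig | None = None,
    beat_samples: np.ndarray | None = None,
    cardiac_cleaner: Callable[[Recording], Recording] | None = None,
) -> dict:
    """Full alpha-task chain for one recording; returns contrast metrics."""
    if config is None:
        config = AnalysisConfig()
    rec = preprocess_continuous(rec, config.filter)
    if cardiac_cleaner is not None:
        rec = cardiac_cleaner(rec)
    else:
        has_ecg = any(c.modality is Modality.ECG for c in rec.channels)
        if has_ecg or beat_samples is not None:
            rec, beat_samples = subtract_cardiac(rec, beat_samples)
    ep = epoch(rec, ["eyes_closed", "eyes_open"], *config.alpha_window)
    ep, report = reject_outliers(ep, config.z_thresh)
    if modality == "eeg":
        present = [
            n for n in config.occipital_exclude if n in ep.channel_names
        ]
        ep = rereference(ep, config.eeg_alpha_reference, exclude=present)
        ep = _drop_modality(ep, Modality.ECG)
    else:
        ep = homogeneous_field_correction(ep)
    psd = psd_periodogram(ep, conditions=["eyes_closed", "eyes_open"])
    contrast = alpha_contrast(psd, band=config.alpha_band)
    best = max(contrast, key=lambda k: (contrast[k], k))
    return {
        "contrast": contrast,
        "best_channel": best,
        "contrast_best": contrast[best],
        "psd": psd,
        "n_trials_retained": int(ep.retained.sum()),
        "rejection": report,
        "beat_samples": beat_samples,
    }


# ---------------------------------------------------------------------------
# group analyses
# ---------------------------------------------------------------------------

_MOD_CONDITIONS = {
    "eeg": ("eeg_only", "simultaneous"),
    "meg": ("meg_only", "simultaneous"),
}


def _sessions_for(entry: SessionEntry) -> list[tuple[str, Recording]]:
    sess = entry.load()
    if not isinstance(sess, Session):
        raise TypeError("manifest entry does not hold a Session")
    out = []
    if sess.eeg is not None and entry.condition in ("eeg_only", "simultaneous"):
        out.append(("eeg", sess.eeg))
    if sess.meg is not None and entry.condition in ("meg_only", "simultaneous"):
        out.append(("meg", sess.meg))
    return out


def _group_stats(table: pd.DataFrame, value: str) -> dict:
    """Alone-vs-simultaneous comparison per modality + cross-modality r."""
    report: dict = {"conditions": {}, "comparisons": {}}
    for modality, (alone, simul) in _MOD_CONDITIONS.items():
        sub = table[table.modality == modality]
        vals = {}
        for cond in (alone, simul):
            v = sub[sub.condition == cond][value].to_numpy(dtype=float)
            if v.size:
                vals[cond] = v
                report["conditions"][f"{modality}:{cond}"] = {
                    "mean": float(v.mean()),
                    "std": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                    "n": int(v.size),
                }
            else:
                report["conditions"][f"{modality}:{cond}"] = {"missing": True}
        if len(vals) == 2 and all(v.size >= 3 for v in vals.values()):
            stat, p = rank_sum_test(vals[alone], vals[simul])
            report["comparisons"][modality] = {"statistic": stat, "p": p}
    simul = table[table.condition == "simultaneous"]
    eeg = simul[simul.modality == "eeg"].set_index("participant")[value]
    meg = simul[simul.modality == "meg"].set_index("participant")[value]
    shared = sorted(set(eeg.index) & set(meg.index))
    if len(shared) >= 3:
        r, p = pearson_corr(eeg.loc[shared].to_numpy(), meg.loc[shared].to_numpy())
        report["cross_modality_pearson"] = {"r": r, "p": p, "n": len(shared)}
    return report


def run_motor_analysis(
    manifest: StudyManifest, config: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Per-session motor metrics plus the group comparison report."""
    if config is None:
        config = AnalysisConfig()
    rows = []
    for entry in manifest.entries:
        if entry.task != "motor":
            continue
        for modality, rec in _sessions_for(entry):
            res = analyse_motor_session(rec, modality, config)
            rows.append(
                dict(
                    participant=entry.participant,
                    condition=entry.condition,
                    modality=modality,
                    snr=res["snr_best"],
                    best_channel=res["best_channel"],
                    spread_fraction=res["spread_fraction"],
                    n_trials=res["n_trials_retained"],
                )
            )
    if not rows:
        raise ValueError("manifest contains no motor sessions")
    table = pd.DataFrame(rows)
    report = _group_stats(table, "snr")
    spread = {}
    for modality in ("eeg", "meg"):
        v = table[table.modality == modality]["spread_fraction"]
        if len(v):
            spread[modality] = {"mean": float(v.mean()), "n": int(len(v))}
    eeg_s = table[table.modality == "eeg"]["spread_fraction"].to_numpy()
    meg_s = table[table.modality == "meg"]["spread_fraction"].to_numpy()
    if eeg_s.size >= 3 and meg_s.size >= 3:
        stat, p = rank_sum_test(eeg_s, meg_s)
        spread["eeg_vs_meg"] = {"statistic": stat, "p": p}
    report["spread"] = spread
    return table, report


def run_alpha_analysis(
    manifest: StudyManifest, config: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Per-session alpha contrast plus the group comparison report."""
    if config is None:
        config = AnalysisConfig()
    rows = []
    for entry in manifest.entries:
        if entry.task != "alpha":
            continue
        sess = entry.load()
        beat_map = None
        needs_meg = (
            isinstance(sess, Session)
            and sess.meg is not None
            and entry.condition in ("meg_only", "simultaneous")
        )
        if needs_meg and sess.eeg is not None:
            try:
                beat_map = detect_heartbeats(sess.eeg)
            except ValueError:
                beat_map = None
        for modality, rec in _sessions_for(entry):
            beats = None
            if modality == "meg" and beat_map is not None:
                beats = np.round(beat_map * rec.fs / sess.eeg.fs).astype(int)
            res = analyse_alpha_session(rec, modality, config, beat_samples=beats)
            rows.append(
                dict(
                    participant=entry.participant,
                    condition=entry.condition,
                    modality=modality,
                    contrast=res["contrast_best"],
                    best_channel=res["best_channel"],
                    n_trials=res["n_trials_retained"],
                )
            )
    if not rows:
        raise ValueError("manifest contains no alpha sessions")
    table = pd.DataFrame(rows)
    report = _group_stats(table, "contrast")
    return table, report


def run_field_nulling(
    manifest: StudyManifest,
    cal: CoilCalibration | None = None,
    true_cal: CoilCalibration | None = None,
    iterations: int = 2,
    config: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Nulling-cycle report per session and the condition comparison.

    Each entry's ``session`` must be a :class:`FieldModel` (the remnant
    field for that session); entries holding anything else are skipped
    with a warning.
    """
    from .synthetic import meg_layout

    if cal is None:
        cal = CoilCalibration.window_coils()
    config = config or {}
    geometry = config.get("geometry") or meg_layout(config.get("n_sites", 8))
    rows = []
    for k, entry in enumerate(manifest.entries):
        model = entry.load()
        if not isinstance(model, FieldModel):
            warnings.warn(
                f"entry {entry.participant}/{entry.condition} has no field map; "
                "skipped", stacklevel=2,
            )
            continue
        steps = nulling_cycle(
            model,
            geometry,
            cal,
            iterations=iterations,
            true_cal=true_cal,
            seed=config.get("seed", 0) + 7919 * k,
            duration=config.get("duration", 20.0),
            noise=config.get("noise", 0.01),
        )
        rows.append(
            dict(
                participant=entry.participant,
                condition=entry.condition,
                rms_before=steps[0].rms_before,
                rms_after=steps[-1].rms_after,
                reduction_factor=steps[0].rms_before / max(steps[-1].rms_after,
                                                           1e-30),
            )
        )
    if not rows:
        raise ValueError("no field maps in manifest")
    table = pd.DataFrame(rows)
    report = {"conditions": {}, "comparisons": {}}
    conds = sorted(table.condition.unique())
    for cond in conds:
        for col in ("rms_before", "rms_after"):
            v = table[table.condition == cond][col].to_numpy(dtype=float)
            report["conditions"][f"{cond}:{col}"] = {
                "mean": float(v.mean()),
                "std": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                "n": int(v.size),
            }
    if len(conds) == 2:
        a = table[table.condition == conds[0]]["rms_after"].to_numpy(dtype=float)
        b = table[table.condition == conds[1]]["rms_after"].to_numpy(dtype=float)
        if a.size >= 3 and b.size >= 3:
            stat, p = rank_sum_test(a, b)
            report["comparisons"]["rms_after"] = {"statistic": stat, "p": p}
    return table, report


# ---------------------------------------------------------------------------
# synthetic study construction
# ---------------------------------------------------------------------------


def generate_study(
    task: str,
    n_participants: int,
    base_seed: int = 0,
    conditions: tuple[str, ...] = ("eeg_only", "simultaneous"),
    effect_scale: dict[str, float] | None = None,
    truth_kwargs: dict | None = None,
    session_kwargs: dict | None = None,
) -> StudyManifest:
    """Build a manifest of synthetic sessions for replicate experiments.

    Per participant, the planted effect sizes are jittered (same jitter in
    every condition — the participant's "physiology"), while session noise
    differs per condition.  ``effect_scale`` maps a condition name to a
    multiplicative degradation of the planted effects (e.g. ``{"simultaneous":
    0.5}`` halves them there), used to verify the power of the group test.
    """
    effect_scale = effect_scale or {}
    truth_kwargs = dict(truth_kwargs or {})
    session_kwargs = dict(session_kwargs or {})
    modalities = session_kwargs.pop(
        "modalities", ("eeg",) if conditions == ("eeg_only", "simultaneous")
        else ("eeg", "meg")
    )
    root = np.random.SeedSequence(base_seed)
    part_rng = np.random.default_rng(root.spawn(1)[0])
    entries = []
    for p in range(n_participants):
        jitter = part_rng.uniform(0.7, 1.3)
        for ci, cond in enumerate(conditions):
            scale = effect_scale.get(cond, 1.0) * jitter
            seed = int(
                np.random.default_rng(
                    np.random.SeedSequence([base_seed, p, ci])
                ).integers(2**31 - 1)
            )
            base = SyntheticGroundTruth(seed=seed, **truth_kwargs)
            truth = replace(
                base,
                erd_depth=min(base.erd_depth * scale, 0.95),
                pmbr_gain=base.pmbr_gain * scale,
                alpha_gain=1.0 + (base.alpha_gain - 1.0) * scale,
                seed=seed,
            )
            eeg, meg, _ = generate_session(
                task, truth, modalities=modalities, **session_kwargs
            )
            entries.append(
                SessionEntry(
                    participant=f"P{p + 1:02d}",
                    condition=cond,
                    task=task,
                    session=Session(eeg=eeg, meg=meg,
                                    motion=(eeg or meg).motion),
                )
            )
    return StudyManifest(entries=entries)


# ---------------------------------------------------------------------------
# report output
# ---------------------------------------------------------------------------


def write_report(
    out_dir: str | Path, name: str, table: pd.DataFrame, report: dict
) -> None:
    """Emit the metric table as TSV and the group report as JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_dir / f"{name}_metrics.tsv", sep="\t", index=False)
    with open(out_dir / f"{name}_report.json", "w") as f:
        json.dump(report, f, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def save_report_figures(out_dir: str | Path, table: pd.DataFrame,
                        value: str = "snr") -> None:
    """Convenience bar chart of per-condition group means (never a test
    surface)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    groups = table.groupby(["modality", "condition"])[value]
    means = groups.mean()
    stds = groups.std()
    labels = [f"{m}\n{c}" for m, c in means.index]
    ax.bar(range(len(means)), means.to_numpy(),
           yerr=np.nan_to_num(stds.to_numpy()), capsize=3)
    ax.set_xticks(range(len(means)), labels, fontsize=8)
    ax.set_ylabel(value)
    fig.tight_layout()
    fig.savefig(out_dir / f"{value}_by_condition.png", dpi=120)
    plt.close(fig)
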