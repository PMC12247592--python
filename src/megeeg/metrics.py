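"""Channel-level summary statistics for the EEG / OPM-MEG comparison.

The headline quantities:

* **beta SNR** — on the trial-averaged 13-30 Hz envelope, the difference in
  mean amplitude between the post-movement rebound window (0.5-1.5 s) and
  the movement-related desynchronisation window (-1-0 s), divided by the
  standard deviation within the desynchronisation window;
* **spread fraction** — the proportion of other good channels whose
  (trial-concatenated, unaveraged) beta envelope has Pearson r > 0.3 with
  the best-SNR channel: a channel-statistical proxy for volume conduction
  (EEG) and magnetic field spread (MEG);
* **alpha contrast** — 8-13 Hz power with eyes closed divided by eyes open;
* group comparisons via the two-sided Wilcoxon rank-sum test (exact
  permutation null at study-scale group sizes) and Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spectral import EnvelopeSet, PSDSet

#: exact rank-sum branch is used when both groups are at most this size
EXACT_RANKSUM_MAX_N = 12


@dataclass
class SnrConfig:
    """Windows (s, relative to movement offset) and band for beta SNR."""

    mrbd_window: tuple[float, float] = (-1.0, 0.0)
    pmbr_window: tuple[float, float] = (0.5, 1.5)
    beta_band: tuple[float, float] = (13.0, 30.0)

    def __post_init__(self) -> None:
        a0, a1 = self.mrbd_window
        b0, b1 = self.pmbr_window
        if not (a0 < a1 and b0 < b1):
            raise ValueError("windows must be increasing")
        if a1 > b0 and b1 > a0:
            raise ValueError("MRBD and PMBR windows must be disjoint")


def snr_beta(
    env: EnvelopeSet, cfg: SnrConfig | None = None, good_only: bool = True
) -> dict[str, float]:
    """Per-channel beta SNR on the trial-averaged envelope.

    SNR_c = (mean over PMBR window - mean over MRBD window) /
    std over MRBD window; positive when the rebound exceeds the
    desynchronised level.
    """
    if cfg is None:
        cfg = SnrConfig()
    t = env.times
    mrbd = (t >= cfg.mrbd_window[0]) & (t < cfg.mrbd_window[1])
    pmbr = (t >= cfg.pmbr_window[0]) & (t < cfg.pmbr_window[1])
    if not mrbd.any() or not pmbr.any():
        raise ValueError("SNR windows fall outside the epoch")
    avg = env.trial_average()  # channels x samples
    out: dict[str, float] = {}
    for i, ch in enumerate(env.channels):
        if good_only and not ch.is_good:
            continue
        base = avg[i, mrbd]
        sd = base.std()
        if sd == 0:
            raise ValueError(f"degenerate envelope (zero MRBD std) on {ch.name}")
        out[ch.name] = float((avg[i, pmbr].mean() - base.mean()) / sd)
    return out


def best_channel(snr: dict[str, float]) -> str:
    """Channel with the highest SNR; ties break lexicographically."""
    finite = {k: v for k, v in snr.items() if np.isfinite(v)}
    if not finite:
        raise ValueError("no finite SNR values")
    top = max(finite.values())
    return min(name for name, v in finite.items() if v == top)


def spread_fraction(
    env: EnvelopeSet, peak: str, r_thresh: float = 0.3
) -> float:
    """Fraction of other good channels correlated (r > r_thresh) with the peak.

    Envelopes are concatenated across retained trials along time before
    correlating (one r per channel pair, zero temporal lag); the peak
    channel is excluded from both numerator and denominator.
    """
    names = env.channel_names
    if peak not in names:
        raise ValueError(f"peak channel {peak!r} not found")
    good = [i for i, c in enumerate(env.channels) if c.is_good]
    if len(good) < 2:
        raise ValueError("need at least 2 good channels")
    peak_idx = names.index(peak)
    if not env.channels[peak_idx].is_good:
        raise ValueError(f"peak channel {peak!r} is marked bad")
    concat = env.data[env.retained]  # trials x channels x samples
    concat = np.moveaxis(concat, 1, 0).reshape(len(names), -1)
    peak_sig = concat[peak_idx]
    n_hit = 0
    n_other = 0
    for i in good:
        if i == peak_idx:
            continue
        n_other += 1
        r = np.corrcoef(peak_sig, concat[i])[0, 1]
        if r > r_thresh:
            n_hit += 1
    return n_hit / n_other


def alpha_contrast(
    psd: PSDSet,
    band: tuple[float, float] = (8.0, 13.0),
    closed: str = "eyes_closed",
    opened: str = "eyes_open",
    good_only: bool = True,
) -> dict[str, float]:
    """Per-channel in-band power ratio, eyes closed over eyes open.

    Band edges are inclusive on the discrete frequency grid.
    """
    for cond in (closed, opened):
        if cond not in psd.power:
            raise ValueError(f"condition {cond!r} missing from PSD set")
    mask = (psd.frequencies >= band[0]) & (psd.frequencies <= band[1])
    if not mask.any():
        raise ValueError("alpha band contains no frequency bins")
    p_closed = psd.power[closed][:, mask].sum(axis=1)
    p_open = psd.power[opened][:, mask].sum(axis=1)
    out: dict[str, float] = {}
    for i, ch in enumerate(psd.channels):
        if good_only and not ch.is_good:
            continue
        if p_open[i] <= 0:
            raise ValueError(f"zero eyes-open band power on {ch.name}")
        out[ch.name] = float(p_closed[i] / p_open[i])
    return out


# ---------------------------------------------------------------------------
# statistical tests
# ---------------------------------------------------------------------------


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact permutation p for the rank-sum statistic of x.

    Enumerates the permutation distribution of the rank-sum of a group of
    size n1 drawn from the pooled mid-ranks (ties handled by mid-ranks) via
    dynamic programming over integer-doubled ranks.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    # doubled mid-ranks are integers
    r2 = np.round(2 * ranks).astype(int)
    # dp[k] maps achievable doubled-rank-sums -> count, choosing k items
    dp: list[dict[int, int]] = [dict() for _ in range(n1 + 1)]
    dp[0][0] = 1
    for r in r2:
        for k in range(min(n1, len(r2)) - 1, -1, -1):
            if not dp[k]:
                continue
            tgt = dp[k + 1]
            for s, c in dp[k].items():
                tgt[s + r] = tgt.get(s + r, 0) + c
    total = sum(dp[n1].values())
    mean2 = n1 * (len(pooled) + 1)  # doubled expected rank-sum
    obs_dev = abs(round(2 * w_obs) - mean2)
    extreme = sum(
        c for s, c in dp[n1].items() if abs(s - mean2) >= obs_dev
    )
    p = extreme / total
    return float(w_obs), float(min(p, 1.0))


def rank_sum_test(
    x, y, method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    ``method='auto'`` uses the exact permutation null when both groups have
    at most 12 observations (covering study-scale group comparisons), and
    the tie-corrected normal approximation otherwise.  Returns (rank-sum
    statistic of x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    if x.size < 3 or y.size < 3:
        raise ValueError("each sample must have at least 3 observations")
    if method == "auto":
        method = (
            "exact"
            if max(x.size, y.size) <= EXACT_RANKSUM_MAX_N
            else "approx"
        )
    if method == "exact":
        return _exact_ranksum_p(x, y)
    if method == "approx":
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic",
            use_continuity=True,
        )
        w = stats.rankdata(np.concatenate([x, y]))[: x.size].sum()
        return float(w), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")


def pearson_corr(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with t-based two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("samples must have equal length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance sample")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
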