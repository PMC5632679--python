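"""Univariate class-discriminability analysis.

The central statistic is the *signed r²*: the squared point-biserial
correlation between a feature (one channel at one time point or frequency
bin) and the binary class indicator, carrying the sign of the class-mean
difference.  It is computed as a map over (channel × time) for ERP analysis
and over (channel × frequency) for spectral analysis, and drives the
heuristic selection of up to five maximally discriminative temporal
intervals used for spatio-temporal features.

ERD/ERS curves show the stimulus-locked modulation of a band's oscillatory
amplitude: band-pass per trial, analytic-signal (Hilbert) envelope, average
per class, and subtraction of the class's mean over a 200 ms pre-stimulus
baseline so positive values are synchronization and negative values
desynchronization, in μV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .containers import EpochSet, InvalidConfigurationError, MissingClassError


@dataclass
class DiscriminabilityMap:
    """Signed r² over (channel × axis), axis being time (ms) or frequency (Hz).

    Sign convention: positive where class A's mean exceeds class B's.
    """

    values: np.ndarray
    axis: np.ndarray
    axis_kind: str  # "time" or "frequency"
    channel_labels: list[str]
    class_pair: tuple[str, str]

    def __post_init__(self) -> None:
        if np.any(np.abs(self.values) > 1.0 + 1e-12):
            raise InvalidConfigurationError("signed r² values must lie in [−1, 1]")


@dataclass
class IntervalSet:
    """Up to five disjoint, ordered (start ms, end ms) discriminative windows."""

    intervals: list[tuple[float, float]]
    scores: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        for (a0, a1) in self.intervals:
            if a1 <= a0:
                raise InvalidConfigurationError("interval end must exceed start")
        for (_, a1), (b0, _) in zip(self.intervals, self.intervals[1:]):
            if b0 < a1:
                raise InvalidConfigurationError("intervals must be disjoint and ordered")

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class ERDCurve:
    """Per-class baseline-referenced envelope time courses for one band (μV)."""

    band: tuple[float, float]
    times: np.ndarray
    values: dict[str, np.ndarray]
    baseline: tuple[float, float] = (-200.0, 0.0)


def _split_classes(
    epochs: EpochSet, class_pair: tuple[str, str], min_per_class: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    a, b = class_pair
    xa = epochs.data[epochs.labels == a]
    xb = epochs.data[epochs.labels == b]
    if len(xa) < min_per_class or len(xb) < min_per_class:
        raise MissingClassError(
            f"need ≥ {min_per_class} trials per class, got {len(xa)} {a!r} / {len(xb)} {b!r}"
        )
    return xa, xb


def signed_r_squared(
    epochs: EpochSet, class_pair: tuple[str, str]
) -> DiscriminabilityMap:
    """Signed squared point-biserial correlation at every (channel, sample).

    At each point, ``r`` is the Pearson correlation between the amplitude
    across trials and the binary class indicator; the map value is
    ``sign(mean_A − mean_B) · r²``.  Points with zero pooled variance map
    to 0.
    """
    xa, xb = _split_classes(epochs, class_pair)
    na, nb = len(xa), len(xb)
    mean_a, mean_b = xa.mean(axis=0), xb.mean(axis=0)
    diff = mean_a - mean_b
    pooled = np.concatenate([xa, xb], axis=0)
    var = pooled.var(axis=0)  # biased (ddof=0), matching the Pearson formula
    with np.errstate(divide="ignore", invalid="ignore"):
        r = diff * np.sqrt(na * nb) / ((na + nb) * np.sqrt(var))
    r = np.nan_to_num(r, nan=0.0, posinf=0.0, neginf=0.0)
    values = np.sign(diff) * r**2
    return DiscriminabilityMap(
        values=values,
        axis=epochs.times.copy(),
        axis_kind="time",
        channel_labels=list(epochs.channel_labels),
        class_pair=class_pair,
    )


# ---------------------------------------------------------------------------
# Heuristic interval selection


def select_intervals(
    dmap: DiscriminabilityMap,
    n_max: int = 5,
    pattern_corr_threshold: float = 0.8,
    smooth_ms: float = 50.0,
    min_score_fraction: float = 0.05,
    min_seed_fraction: float = 0.25,
    max_width_ms: float = 150.0,
) -> IntervalSet:
    """Pick up to ``n_max`` disjoint temporal windows of high discriminability
    with a stable spatial pattern.

    Scoring: |r²| is summed over the channels whose sign matches each time
    point's dominant sign, and lightly smoothed in time.  The best time point
    seeds an interval that grows outward while the spatial r² pattern
    (time-smoothed) stays correlated ≥ ``pattern_corr_threshold`` with the
    seed pattern; the interval is then zeroed out and the search repeats.
    Points below ``min_score_fraction`` of the global peak never extend an
    interval and points below ``min_seed_fraction`` never start one, so a
    discriminability-free map yields an empty set (with a warning).  Growth
    stops at ``max_width_ms``, so a sustained component contributes several
    adjacent windows (mean amplitude over a narrow window tracks the
    component's time course; one long window would average it away).
    """
    if dmap.axis_kind != "time":
        raise InvalidConfigurationError("interval selection needs a (channel × time) map")
    times = dmap.axis
    n_t = len(times)
    dt = float(np.median(np.diff(times))) if n_t > 1 else 1.0

    # time-smoothed copy stabilizes both the score and the spatial patterns
    w = max(1, int(round(smooth_ms / dt)))
    if w > 1:
        kernel = np.ones(w) / w
        vals = np.apply_along_axis(
            lambda v: np.convolve(v, kernel, mode="same"), -1, dmap.values
        )
    else:
        vals = dmap.values

    dominant = np.sign(vals.sum(axis=0))
    mask = (np.sign(vals) == dominant) & (dominant != 0)
    score = np.where(mask, np.abs(vals), 0.0).sum(axis=0)

    peak0 = score.max()
    if peak0 <= 0:
        warnings.warn("no discriminability found; returning empty interval set", stacklevel=2)
        return IntervalSet(intervals=[])
    floor = min_score_fraction * peak0
    seed_floor = min_seed_fraction * peak0

    def pattern_corr(p: np.ndarray, q: np.ndarray) -> float:
        p = p - p.mean()
        q = q - q.mean()
        denom = np.linalg.norm(p) * np.linalg.norm(q)
        return float(p @ q / denom) if denom > 0 else 0.0

    work = score.copy()
    picks: list[tuple[int, int, float]] = []  # (lo, hi inclusive, score)
    for _ in range(n_max):
        t0 = int(np.argmax(work))
        if work[t0] <= seed_floor:
            break
        seed_pattern = vals[:, t0]
        lo = hi = t0
        max_pts = max(1, int(round(max_width_ms / dt)))
        while (
            hi - lo + 1 < max_pts
            and lo - 1 >= 0
            and work[lo - 1] > floor
            and pattern_corr(seed_pattern, vals[:, lo - 1]) >= pattern_corr_threshold
        ):
            lo -= 1
        while (
            hi - lo + 1 < max_pts
            and hi + 1 < n_t
            and work[hi + 1] > floor
            and pattern_corr(seed_pattern, vals[:, hi + 1]) >= pattern_corr_threshold
        ):
            hi += 1
        picks.append((lo, hi, float(score[lo : hi + 1].sum())))
        work[lo : hi + 1] = 0.0

    picks.sort(key=lambda p: p[0])
    intervals = [(float(times[lo]), float(times[hi] + dt)) for lo, hi, _ in picks]
    scores = [s for _, _, s in picks]
    return IntervalSet(intervals=intervals, scores=scores)


def exhaustive_best_interval(
    dmap: DiscriminabilityMap, max_len: int | None = None
) -> tuple[float, float]:
    """Brute-force oracle: the contiguous window maximizing summed |r²|
    (density-normalized), for cross-checking the heuristic on simple maps."""
    vals = np.abs(dmap.values).sum(axis=0)
    times = dmap.axis
    n = len(times)
    dt = float(np.median(np.diff(times)))
    max_len = max_len or n
    best, best_score = (0, 0), -np.inf
    cum = np.concatenate([[0.0], np.cumsum(vals)])
    for lo in range(n):
        for hi in range(lo, min(lo + max_len, n)):
            s = (cum[hi + 1] - cum[lo]) / np.sqrt(hi - lo + 1)
            if s > best_score:
                best_score, best = s, (lo, hi)
    return float(times[best[0]]), float(times[best[1]] + dt)


# ---------------------------------------------------------------------------
# Spectra


def band_spectrum_discriminability(
    epochs: EpochSet,
    class_pair: tuple[str, str],
    freq_range: tuple[float, float] = (3.0, 40.0),
    window: tuple[float, float] = (0.0, 2000.0),
    welch_window_s: float = 1.0,
    welch_overlap: float = 0.5,
) -> DiscriminabilityMap:
    """Signed r² of per-trial Welch band power over (channel × frequency).

    Power is estimated per trial over ``window`` (the full trial by default)
    with ``welch_window_s`` segments at ``welch_overlap`` fractional overlap,
    then log-transformed before the correlation — power is lognormal-ish and
    the correlation is better behaved on the log scale.
    """
    if freq_range[1] > epochs.fs / 2:
        raise InvalidConfigurationError(
            f"frequency range {freq_range} exceeds Nyquist ({epochs.fs / 2} Hz)"
        )
    mask = epochs.time_mask(*window)
    seg = epochs.data[:, :, mask]
    nperseg = min(int(round(welch_window_s * epochs.fs)), seg.shape[-1])
    noverlap = int(round(welch_overlap * nperseg))
    freqs, psd = signal.welch(
        seg, fs=epochs.fs, nperseg=nperseg, noverlap=noverlap, axis=-1
    )
    fmask = (freqs >= freq_range[0]) & (freqs <= freq_range[1])
    logp = np.log(np.maximum(psd[:, :, fmask], 1e-300))

    power_epochs = EpochSet(
        data=logp,
        labels=epochs.labels,
        times=freqs[fmask],  # reuse the container; "times" carries Hz here
        fs=epochs.fs,
        channel_labels=list(epochs.channel_labels),
    )
    dmap = signed_r_squared(power_epochs, class_pair)
    dmap.axis_kind = "frequency"
    return dmap


# ---------------------------------------------------------------------------
# ERD/ERS curves


def erd_curves(
    epochs: EpochSet,
    band: tuple[float, float],
    baseline: tuple[float, float] = (-200.0, 0.0),
    classes: tuple[str, ...] | None = None,
) -> ERDCurve:
    """Per-class band-envelope time courses referenced to pre-stimulus baseline.

    Each trial is band-pass filtered (Butterworth order 4, zero-phase), the
    instantaneous amplitude taken as the Hilbert-envelope magnitude, averaged
    across trials per class, and each class curve shifted so its mean over
    the baseline window is exactly zero.  Negative values are ERD, positive
    ERS, in μV.
    """
    if band[1] >= epochs.fs / 2:
        raise InvalidConfigurationError(f"band {band} exceeds Nyquist")
    bmask = epochs.time_mask(*baseline)
    if not bmask.any():
        raise InvalidConfigurationError(f"baseline {baseline} outside epoch window")
    classes = classes or tuple(dict.fromkeys(epochs.labels.tolist()))
    sos = signal.butter(4, band, btype="bandpass", fs=epochs.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    envelope = np.abs(signal.hilbert(filtered, axis=-1))

    values: dict[str, np.ndarray] = {}
    for c in classes:
        sel = envelope[epochs.labels == c]
        if len(sel) < 2:
            raise MissingClassError(f"need ≥ 2 trials for class {c!r}")
        curve = sel.mean(axis=0)  # channels × samples
        curve = curve - curve[:, bmask].mean(axis=-1, keepdims=True)
        values[c] = curve
    return ERDCurve(band=band, times=epochs.times.copy(), values=values, baseline=baseline)
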