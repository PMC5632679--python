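"""Filtering, downsampling, epoching and epoch/channel cleaning.

Default pipeline, in order: anti-alias low-pass (Chebyshev type II, order 10,
42 Hz pass-band edge, 3 dB ripple, 50 dB attenuation from 49 Hz), decimation
to 100 Hz, drift-removal high-pass (least-squares FIR of order 3× the target
rate, 1 Hz, applied forward-backward for zero phase), segmentation into
−200…2000 ms epochs, then three rejection rules evaluated on a 5–40 Hz
band-passed copy of the data:

* channels whose per-trial variance falls below 0.5 μV² in more than 10% of
  trials are dropped (dead electrodes);
* epochs whose per-channel variance is excessive (variance > median + 5·MAD
  across epochs, per channel) in more than 20% of channels are dropped
  (muscle artifacts);
* epochs with more than 150 μV max−min range in any of F9, F10, AF3, AF4
  are dropped (strong eye movements);

and finally trial-wise baseline correction on the 100 ms pre-stimulus mean.
Rejection never modifies surviving signal values; only the filters and the
baseline correction do.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import (
    DegenerateDataError,
    EpochSet,
    InvalidConfigurationError,
    Recording,
)


class FilterDesignError(ValueError):
    """The requested filter cannot be realized at the given sampling rate."""


class EmptyEpochsError(ValueError):
    """Segmentation found no events / no surviving epochs."""


# ---------------------------------------------------------------------------
# Filtering and resampling


@dataclass(frozen=True)
class FilterSpec:
    """Declarative filter description.

    ``lowpass-cheby2`` uses ``order``, ``edge_hz`` (pass-band edge),
    ``stop_hz``, ``ripple_db`` (max pass-band ripple) and ``atten_db``
    (min stop-band attenuation).  ``highpass-fir`` uses ``order`` (taps − 1),
    ``edge_hz`` (pass-band start) and ``stop_hz`` (upper edge of the fully
    rejected band); it is designed by least squares and is linear-phase.
    """

    kind: str
    order: int
    edge_hz: float
    stop_hz: float
    ripple_db: float = 3.0
    atten_db: float = 50.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass-cheby2", "highpass-fir"):
            raise InvalidConfigurationError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise InvalidConfigurationError("filter order must be ≥ 1")
        if self.kind == "lowpass-cheby2" and not self.edge_hz < self.stop_hz:
            raise InvalidConfigurationError("low-pass needs edge < stop")
        if self.kind == "highpass-fir" and not self.stop_hz < self.edge_hz:
            raise InvalidConfigurationError("high-pass needs stop < edge")


def default_lowpass() -> FilterSpec:
    """Anti-aliasing low-pass: Chebyshev II, order 10, 42 Hz edge, 49 Hz stop."""
    return FilterSpec(
        kind="lowpass-cheby2", order=10, edge_hz=42.0, stop_hz=49.0,
        ripple_db=3.0, atten_db=50.0, zero_phase=True,
    )


def default_highpass(fs: float = 100.0) -> FilterSpec:
    """Drift-removal FIR high-pass: 1 Hz, order 3×fs, zero-phase."""
    return FilterSpec(
        kind="highpass-fir", order=int(3 * fs), edge_hz=1.0, stop_hz=0.5,
        zero_phase=True,
    )


def design_filter(spec: FilterSpec, fs: float):
    """Realize a FilterSpec at sampling rate ``fs``.

    Returns ``("sos", sos)`` or ``("fir", taps)``.  Raises
    :class:`FilterDesignError` when the band edges do not fit below Nyquist.
    """
    nyq = fs / 2.0
    if spec.kind == "lowpass-cheby2":
        if spec.stop_hz >= nyq:
            raise FilterDesignError(
                f"stop band {spec.stop_hz} Hz not below Nyquist ({nyq} Hz)"
            )
        # Each pass of a zero-phase (forward-backward) application only needs
        # half the dB specs; the critical frequency comes from cheb2ord so the
        # pass-band edge actually meets the ripple bound.
        gpass = spec.ripple_db / (2.0 if spec.zero_phase else 1.0)
        gstop = spec.atten_db / (2.0 if spec.zero_phase else 1.0)
        try:
            needed, wn = signal.cheb2ord(spec.edge_hz, spec.stop_hz, gpass, gstop, fs=fs)
        except Exception as exc:
            raise FilterDesignError(f"cannot design low-pass: {exc}") from exc
        if needed > spec.order:
            raise FilterDesignError(
                f"order {spec.order} cannot reach {gstop:g} dB at {spec.stop_hz} Hz "
                f"with ≤ {gpass:g} dB ripple at {spec.edge_hz} Hz (needs {needed})"
            )
        sos = signal.cheby2(spec.order, gstop, wn, btype="lowpass", fs=fs, output="sos")
        return "sos", sos
    if spec.edge_hz >= nyq:
        raise FilterDesignError(f"edge {spec.edge_hz} Hz not below Nyquist ({nyq} Hz)")
    numtaps = spec.order + 1
    if numtaps % 2 == 0:  # firls needs an odd tap count (type-I linear phase)
        numtaps += 1
    taps = signal.firls(
        numtaps,
        [0.0, spec.stop_hz, spec.edge_hz, nyq],
        [0.0, 0.0, 1.0, 1.0],
        fs=fs,
    )
    return "fir", taps


def _filter_array(x: np.ndarray, realized, zero_phase: bool) -> np.ndarray:
    kind, coef = realized
    if kind == "sos":
        return signal.sosfiltfilt(coef, x, axis=-1) if zero_phase else signal.sosfilt(
            coef, x, axis=-1
        )
    if zero_phase:
        return signal.filtfilt(coef, [1.0], x, axis=-1, padlen=min(3 * len(coef), x.shape[-1] - 1))
    return signal.lfilter(coef, [1.0], x, axis=-1)


def apply_filter(recording: Recording, spec: FilterSpec) -> Recording:
    """Filter a continuous recording; events and metadata are preserved."""
    realized = design_filter(spec, recording.fs)
    out = recording.copy()
    out.data = _filter_array(out.data, realized, spec.zero_phase)
    return out


def resample(recording: Recording, target_fs: float) -> Recording:
    """Anti-aliased polyphase resampling with event-index remapping."""
    if target_fs > recording.fs:
        raise InvalidConfigurationError(
            f"target rate {target_fs} Hz above source rate {recording.fs} Hz"
        )
    if target_fs == recording.fs:
        return recording.copy()
    frac = Fraction(target_fs / recording.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(recording.data, up, down, axis=-1)
    ratio = target_fs / recording.fs
    n_new = data.shape[1]
    events = [
        (min(int(round(idx * ratio)), n_new - 1), lab) for idx, lab in recording.events
    ]
    return Recording(
        data=data,
        channel_labels=list(recording.channel_labels),
        fs=target_fs,
        events=events,
        annotations=[dict(a) for a in recording.annotations],
    )


# ---------------------------------------------------------------------------
# Epoching


def segment_epochs(
    recording: Recording, window: tuple[float, float] = (-200.0, 2000.0)
) -> EpochSet:
    """Cut one epoch per event over the half-open window [start, end) ms.

    Epochs that would extend past the recording bounds are dropped and
    logged.  At 100 Hz the default window yields 220 samples per epoch.
    """
    if not recording.events:
        raise EmptyEpochsError("recording has no events to segment")
    fs = recording.fs
    start_ms, end_ms = window
    offsets = np.arange(
        int(round(start_ms * fs / 1000.0)), int(round(end_ms * fs / 1000.0))
    )
    times = offsets * 1000.0 / fs

    kept, labels, dropped = [], [], []
    n = recording.n_samples
    for i, (ev, lab) in enumerate(recording.events):
        lo, hi = ev + offsets[0], ev + offsets[-1]
        if lo < 0 or hi >= n:
            dropped.append(i)
            continue
        kept.append(recording.data[:, ev + offsets])
        labels.append(lab)
    if not kept:
        raise EmptyEpochsError("every epoch fell outside the recording bounds")
    log = []
    if dropped:
        log.append(
            {
                "step": "segment_epochs",
                "kind": "epoch",
                "removed": dropped,
                "reason": "window outside recording bounds",
            }
        )
    return EpochSet(
        data=np.stack(kept),
        labels=np.array(labels),
        times=times,
        fs=fs,
        channel_labels=list(recording.channel_labels),
        rejection_log=log,
    )


# ---------------------------------------------------------------------------
# Rejection rules (evaluated on a band-passed copy; data returned unfiltered)


def _bandpassed_copy(epochs: EpochSet, band: tuple[float, float]) -> np.ndarray:
    low, high = band
    high = min(high, 0.49 * epochs.fs)
    sos = signal.butter(4, [low, high], btype="bandpass", fs=epochs.fs, output="sos")
    return signal.sosfiltfilt(sos, epochs.data, axis=-1)


def reject_flat_channels(
    epochs: EpochSet,
    band: tuple[float, float] = (5.0, 40.0),
    var_threshold: float = 0.5,
    trial_fraction: float = 0.10,
) -> EpochSet:
    """Drop channels whose band-passed variance is below ``var_threshold``
    μV² in more than ``trial_fraction`` of trials."""
    bp = _bandpassed_copy(epochs, band)
    trial_var = bp.var(axis=-1)  # trials × channels
    flat_frac = (trial_var < var_threshold).mean(axis=0)
    bad = np.flatnonzero(flat_frac > trial_fraction)
    if len(bad) == epochs.n_channels:
        raise DegenerateDataError("flat-channel rule would remove every channel")
    keep = np.setdiff1d(np.arange(epochs.n_channels), bad)
    log = list(epochs.rejection_log)
    log.append(
        {
            "step": "reject_flat_channels",
            "kind": "channel",
            "removed": [epochs.channel_labels[i] for i in bad],
            "reason": f"band-passed variance < {var_threshold} μV² in "
            f"> {trial_fraction:.0%} of trials",
        }
    )
    return replace(
        epochs,
        data=epochs.data[:, keep, :],
        channel_labels=[epochs.channel_labels[i] for i in keep],
        rejection_log=log,
    )


def reject_highvariance_epochs(
    epochs: EpochSet,
    band: tuple[float, float] = (5.0, 40.0),
    channel_fraction: float = 0.20,
    mad_factor: float = 5.0,
) -> EpochSet:
    """Drop epochs with excessive variance in more than ``channel_fraction``
    of channels.

    "Excessive" for a channel means the epoch's band-passed variance exceeds
    the channel's median + ``mad_factor``·MAD across epochs — a robust rule;
    the factor is configurable.
    """
    if epochs.n_trials < 2:
        raise InvalidConfigurationError("need at least 2 epochs")
    bp = _bandpassed_copy(epochs, band)
    trial_var = bp.var(axis=-1)  # trials × channels
    med = np.median(trial_var, axis=0)
    mad = np.median(np.abs(trial_var - med), axis=0)
    excess = trial_var > med + mad_factor * mad
    bad = np.flatnonzero(excess.mean(axis=1) > channel_fraction)
    if len(bad) == epochs.n_trials:
        raise DegenerateDataError("variance rule would remove every epoch")
    keep = np.setdiff1d(np.arange(epochs.n_trials), bad)
    log = list(epochs.rejection_log)
    log.append(
        {
            "step": "reject_highvariance_epochs",
            "kind": "epoch",
            "removed": bad.tolist(),
            "reason": f"variance > median + {mad_factor}·MAD in "
            f"> {channel_fraction:.0%} of channels",
        }
    )
    return replace(
        epochs, data=epochs.data[keep], labels=epochs.labels[keep], rejection_log=log
    )


EYE_CHANNELS = ("F9", "F10", "AF3", "AF4")


def reject_minmax_epochs(
    epochs: EpochSet,
    channels: tuple[str, ...] = EYE_CHANNELS,
    range_threshold: float = 150.0,
) -> EpochSet:
    """Drop epochs whose max−min range on any named fronto-polar channel
    exceeds ``range_threshold`` μV (strong eye movements)."""
    present = [c for c in channels if c in epochs.channel_labels]
    if not present:
        raise InvalidConfigurationError(
            f"none of the eye-movement channels {channels} are present"
        )
    idx = [epochs.channel_index(c) for c in present]
    rng_ = epochs.data[:, idx, :].max(axis=-1) - epochs.data[:, idx, :].min(axis=-1)
    bad = np.flatnonzero((rng_ > range_threshold).any(axis=1))
    if len(bad) == epochs.n_trials:
        raise DegenerateDataError("min-max rule would remove every epoch")
    keep = np.setdiff1d(np.arange(epochs.n_trials), bad)
    log = list(epochs.rejection_log)
    log.append(
        {
            "step": "reject_minmax_epochs",
            "kind": "epoch",
            "removed": bad.tolist(),
            "reason": f"max−min > {range_threshold} μV on {present}",
        }
    )
    return replace(
        epochs, data=epochs.data[keep], labels=epochs.labels[keep], rejection_log=log
    )


def baseline_correct(
    epochs: EpochSet, baseline: tuple[float, float] = (-100.0, 0.0)
) -> EpochSet:
    """Subtract each trial's and channel's mean over the baseline window."""
    mask = epochs.time_mask(*baseline)
    if not mask.any():
        raise InvalidConfigurationError(
            f"baseline window {baseline} outside epoch window"
        )
    means = epochs.data[:, :, mask].mean(axis=-1, keepdims=True)
    return replace(epochs, data=epochs.data - means, rejection_log=list(epochs.rejection_log))


# ---------------------------------------------------------------------------
# Convenience chain


def preprocess(
    recording: Recording,
    target_fs: float = 100.0,
    epoch_window: tuple[float, float] = (-200.0, 2000.0),
    baseline: tuple[float, float] = (-100.0, 0.0),
    var_threshold: float = 0.5,
    flat_trial_fraction: float = 0.10,
    excess_channel_fraction: float = 0.20,
    mad_factor: float = 5.0,
    minmax_threshold: float = 150.0,
    minmax_channels: tuple[str, ...] = EYE_CHANNELS,
) -> EpochSet:
    """Run the full default chain: low-pass → downsample → high-pass →
    epoch → channel rejection → epoch rejection → baseline correction."""
    rec = apply_filter(recording, default_lowpass())
    rec = resample(rec, target_fs)
    rec = apply_filter(rec, default_highpass(target_fs))
    epochs = segment_epochs(rec, epoch_window)
    epochs = reject_flat_channels(
        epochs, var_threshold=var_threshold, trial_fraction=flat_trial_fraction
    )
    epochs = reject_highvariance_epochs(
        epochs, channel_fraction=excess_channel_fraction, mad_factor=mad_factor
    )
    epochs = reject_minmax_epochs(
        epochs, channels=minmax_channels, range_threshold=minmax_threshold
    )
    return baseline_correct(epochs, baseline)
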