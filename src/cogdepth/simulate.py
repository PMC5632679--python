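"""Synthetic 64-channel EEG for the NT/ST/DT paradigm.

The generator emulates the structure the downstream analysis assumes:

* a stimulus-locked ERP source with two components — a bump near 250 ms
  (σ ≈ 40 ms) and a broader centro-parietal positivity near 400 ms
  (σ ≈ 80 ms) — whose amplitudes grade with the processing level;
* α (8–14 Hz) and β (16–20 Hz) oscillatory sources, stationary narrowband
  Gaussian noise whose envelope dips after each stimulus (event-related
  desynchronization): a trapezoidal drop starting 300 ms post-stimulus with
  class-specific depth and duration, deeper/longer for deeper processing;
* broadband 1/f background sources and white sensor noise;
* a fixed per-seed linear mixing into channels, with a centro-parietal
  weighting template for the ERP/ERD sources (no volume-conduction head
  model — a documented simplification).

The rendered recording decomposes *exactly* as ``background + Σ per-event
contributions``: the ERD is implemented subtractively,
``(1 − dip(t))·osc(t) = osc(t) − dip(t)·osc(t)``, so each event contributes
the mixed ERP kernel minus the dip-windowed oscillation segment.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import signal

from .containers import CLASSES, InvalidConfigurationError, Recording
from .paradigm import StimulusSequence, TimingConfig

# ---------------------------------------------------------------------------
# Channel geometry

#: 63 scalp electrodes (10-20 extended) plus one infra-ocular EOG channel.
CHANNEL_LABELS_64 = [
    "Fp1", "Fp2", "AF7", "AF3", "AF4", "AF8", "F9", "F7", "F5", "F3",
    "F1", "Fz", "F2", "F4", "F6", "F8", "F10", "FT7", "FC5", "FC3",
    "FC1", "FCz", "FC2", "FC4", "FC6", "FT8", "T7", "C5", "C3", "C1",
    "Cz", "C2", "C4", "C6", "T8", "TP7", "CP5", "CP3", "CP1", "CPz",
    "CP2", "CP4", "CP6", "TP8", "P7", "P5", "P3", "P1", "Pz", "P2",
    "P4", "P6", "P8", "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz",
    "O2", "PO9", "PO10", "EOG",
]

_ROW_GAIN = {
    "Fp": 0.05, "AF": 0.08, "F": 0.15, "FT": 0.25, "FC": 0.40,
    "T": 0.25, "C": 0.70, "TP": 0.45, "CP": 0.95, "P": 1.00,
    "PO": 0.60, "O": 0.35,
}


#: order in which electrodes are added to reduced montages: scalp coverage
#: first, then the channels the cleaning and EOG-control rules depend on
_REDUCED_PRIORITY = [
    "Cz", "Pz", "EOG", "F9", "F10", "AF3", "AF4", "Fp1", "CPz", "Fz",
    "C3", "C4", "P3", "P4", "Oz", "FCz", "CP1", "CP2", "F3", "F4",
    "P7", "P8", "PO3", "PO4", "T7", "T8", "Fp2", "POz", "CP5", "CP6",
    "C1", "C2", "F7", "F8", "O1", "O2",
]


def default_channel_labels(n_channels: int = 64) -> list[str]:
    """A montage of ``n_channels`` electrodes in canonical order, EOG last.

    Reduced montages keep scalp coverage (centro-parietal plus the frontal
    channels the artifact rules and the EOG-control mode rely on) instead of
    truncating the full list.
    """
    if n_channels < 2 or n_channels > len(CHANNEL_LABELS_64):
        raise InvalidConfigurationError(
            f"n_channels must be in [2, {len(CHANNEL_LABELS_64)}]"
        )
    if n_channels == len(CHANNEL_LABELS_64):
        return list(CHANNEL_LABELS_64)
    chosen: list[str] = []
    for lab in _REDUCED_PRIORITY + CHANNEL_LABELS_64:
        if lab not in chosen:
            chosen.append(lab)
        if len(chosen) == n_channels:
            break
    scalp = sorted(
        (c for c in chosen if c != "EOG"), key=CHANNEL_LABELS_64.index
    )
    return scalp + ["EOG"] if "EOG" in chosen else scalp


def centro_parietal_template(channel_labels: list[str]) -> np.ndarray:
    """Forward-mixing weights of a centro-parietal source, max entry 1 (≈Pz).

    Weights follow the electrode row (frontal → occipital) with a lateral
    Gaussian falloff; the EOG channel gets zero cortical gain.
    """
    weights = np.zeros(len(channel_labels))
    for i, lab in enumerate(channel_labels):
        if lab == "EOG":
            continue
        m = re.match(r"([A-Za-z]+?)(z|\d+)$", lab)
        if not m:
            continue
        row, pos = m.group(1), m.group(2)
        gain = _ROW_GAIN.get(row, 0.1)
        lateral = 0 if pos == "z" else (int(pos) + 1) // 2
        weights[i] = gain * np.exp(-(lateral**2) / 8.0)
    peak = weights.max()
    return weights / peak if peak > 0 else weights


# ---------------------------------------------------------------------------
# Effect specification

#: (low, high) Hz of the two oscillatory bands carrying the ERD effect.
DEFAULT_BANDS = {"alpha": (8.0, 14.0), "beta": (16.0, 20.0)}


@dataclass(frozen=True)
class ErdSpec:
    """Trapezoidal envelope drop of one band for one class.

    ``depth`` is the fractional amplitude drop in [0, 1]; ``duration_ms`` is
    the plateau length.  The dip ramps up over 100 ms from 300 ms
    post-stimulus (so the envelope minimum sits near 500 ms) and ramps back
    over 100 ms.
    """

    depth: float = 0.0
    duration_ms: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth <= 1.0:
            raise InvalidConfigurationError("ERD depth must be in [0, 1]")
        if self.duration_ms < 0:
            raise InvalidConfigurationError("ERD duration must be non-negative")


def _default_erd() -> dict[str, dict[str, ErdSpec]]:
    return {
        "alpha": {
            "NT": ErdSpec(0.05, 200.0),
            "ST": ErdSpec(0.30, 400.0),
            "DT": ErdSpec(0.45, 800.0),
        },
        "beta": {
            "NT": ErdSpec(0.02, 200.0),
            "ST": ErdSpec(0.15, 300.0),
            "DT": ErdSpec(0.25, 600.0),
        },
    }


@dataclass
class EffectSpec:
    """Amplitudes, ERD geometry and noise levels of the synthetic session.

    Defaults emulate the qualitative picture of the paradigm: the 400 ms
    positivity grades NT < ST < DT; the 250 ms component separates
    processing from no-processing; α/β desynchronization is deeper and more
    sustained for deeper processing (DT duration ≥ ST duration).
    """

    erp_peak1_amp: dict[str, float] = field(
        default_factory=lambda: {"NT": 1.0, "ST": 2.0, "DT": 2.2}
    )
    erp_peak2_amp: dict[str, float] = field(
        default_factory=lambda: {"NT": 1.0, "ST": 2.5, "DT": 4.0}
    )
    erd: dict[str, dict[str, ErdSpec]] = field(default_factory=_default_erd)
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    osc_amp: dict[str, float] = field(
        default_factory=lambda: {"alpha": 2.0, "beta": 1.0}
    )
    noise_sigma: float = 1.5
    background_1f_exponent: float = 1.0
    n_background_sources: int = 8
    background_rms: float = 3.0
    mixing_seed: int | None = None

    def __post_init__(self) -> None:
        for amps in (self.erp_peak1_amp, self.erp_peak2_amp):
            for c in CLASSES:
                if c not in amps:
                    raise InvalidConfigurationError(f"missing ERP amplitude for {c}")
                if not np.isfinite(amps[c]):
                    raise InvalidConfigurationError("ERP amplitudes must be finite")
        for band, per_class in self.erd.items():
            if band not in self.bands:
                raise InvalidConfigurationError(f"ERD band {band!r} has no band edges")
            for c in CLASSES:
                if c not in per_class:
                    raise InvalidConfigurationError(f"missing ERD spec for {c} in {band}")

    @classmethod
    def null(cls) -> "EffectSpec":
        """No class-dependent effects: flat ERPs and no ERD anywhere."""
        zero_erd = {
            band: {c: ErdSpec(0.0, 0.0) for c in CLASSES} for band in DEFAULT_BANDS
        }
        return cls(
            erp_peak1_amp={c: 0.0 for c in CLASSES},
            erp_peak2_amp={c: 0.0 for c in CLASSES},
            erd=zero_erd,
        )


# ---------------------------------------------------------------------------
# Waveform primitives

ERP_PEAK1_MS = 250.0
ERP_PEAK1_SIGMA_MS = 40.0
ERP_PEAK2_MS = 400.0
ERP_PEAK2_SIGMA_MS = 80.0
#: post-stimulus support of the ERP kernel (both bumps decayed to ~0)
ERP_KERNEL_MS = 1000.0
ERD_ONSET_MS = 300.0
ERD_RAMP_MS = 100.0


def erp_kernel(t_ms: np.ndarray, amp1: float, amp2: float) -> np.ndarray:
    """Two Gaussian bumps at 250 ms (σ 40) and 400 ms (σ 80), in μV."""
    t = np.asarray(t_ms, dtype=float)
    k = amp1 * np.exp(-0.5 * ((t - ERP_PEAK1_MS) / ERP_PEAK1_SIGMA_MS) ** 2)
    k += amp2 * np.exp(-0.5 * ((t - ERP_PEAK2_MS) / ERP_PEAK2_SIGMA_MS) ** 2)
    return np.where(t >= 0, k, 0.0)


def erd_dip(
    t_ms: np.ndarray,
    depth: float,
    duration_ms: float,
    onset_ms: float = ERD_ONSET_MS,
    ramp_ms: float = ERD_RAMP_MS,
) -> np.ndarray:
    """Trapezoidal envelope-drop window in [0, depth] over post-stimulus time."""
    t = np.asarray(t_ms, dtype=float)
    if depth == 0.0 or duration_ms == 0.0:
        return np.zeros_like(t)
    up = np.clip((t - onset_ms) / ramp_ms, 0.0, 1.0)
    down = np.clip((onset_ms + ramp_ms + duration_ms + ramp_ms - t) / ramp_ms, 0.0, 1.0)
    return depth * np.minimum(up, down)


def _one_over_f_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-RMS noise with amplitude spectrum ∝ f^(−exponent/2)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0
    out = np.fft.irfft(spec * shaping, n)
    return out / out.std()


def _narrowband_noise(
    rng: np.random.Generator, n: int, band: tuple[float, float], fs: float
) -> np.ndarray:
    """Unit-RMS stationary Gaussian noise band-passed to ``band``."""
    low, high = band
    if high >= fs / 2:
        raise InvalidConfigurationError(f"band {band} exceeds Nyquist at fs={fs}")
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


# ---------------------------------------------------------------------------
# Session rendering


def simulate_background(
    n_channels: int,
    n_samples: int,
    fs: float,
    effects: EffectSpec,
    seed: int | None = None,
) -> tuple[np.ndarray, dict[str, Any]]:
    """Render the event-free part of a session.

    Returns the background channel data (1/f sources + stationary α/β
    oscillations + sensor noise, in μV) and a ``sources`` dict holding the
    oscillation source time courses and all mixing vectors — exactly what
    :func:`event_contributions` needs to render the stimulus-locked part.
    """
    rng = np.random.default_rng(seed)
    mix_rng = (
        np.random.default_rng(effects.mixing_seed)
        if effects.mixing_seed is not None
        else rng
    )
    labels = default_channel_labels(n_channels)
    template = centro_parietal_template(labels)

    nb = effects.n_background_sources
    bg_mix = mix_rng.standard_normal((n_channels, nb)) / np.sqrt(nb)
    # smooth mixing across the channel ordering (neighbouring electrodes see
    # correlated background) — crude stand-in for volume conduction
    kernel = np.array([0.25, 0.5, 1.0, 0.5, 0.25])
    kernel /= kernel.sum()
    for j in range(nb):
        bg_mix[:, j] = np.convolve(bg_mix[:, j], kernel, mode="same")

    data = np.zeros((n_channels, n_samples))
    for j in range(nb):
        src = _one_over_f_noise(rng, n_samples, effects.background_1f_exponent)
        data += effects.background_rms * np.outer(bg_mix[:, j], src)

    osc_sources: dict[str, np.ndarray] = {}
    for band_name, edges in effects.bands.items():
        amp = effects.osc_amp.get(band_name, 0.0)
        src = amp * _narrowband_noise(rng, n_samples, edges, fs)
        osc_sources[band_name] = src
        data += np.outer(template, src)

    data += effects.noise_sigma * rng.standard_normal((n_channels, n_samples))

    sources = {
        "labels": labels,
        "template": template,
        "osc": osc_sources,
        "bg_mixing": bg_mix,
    }
    return data, sources


def event_contributions(
    sequence: StimulusSequence,
    timing: TimingConfig,
    effects: EffectSpec,
    sources: dict[str, Any],
    n_samples: int,
    event_samples: list[int],
) -> np.ndarray:
    """Stimulus-locked additive terms: mixed ERP kernels minus dip-windowed
    oscillation segments, one per event.  Linear superposition throughout."""
    fs = timing.sampling_rate_hz
    template = sources["template"]
    n_channels = len(template)
    out = np.zeros((n_channels, n_samples))

    k_len = int(round(ERP_KERNEL_MS * fs / 1000.0))
    t_kernel = np.arange(k_len) * 1000.0 / fs

    labels = sequence.flat_labels()
    for ev, lab in zip(event_samples, labels):
        stop = min(ev + k_len, n_samples)
        seg = slice(ev, stop)
        n_seg = stop - ev
        kern = erp_kernel(
            t_kernel[:n_seg], effects.erp_peak1_amp[lab], effects.erp_peak2_amp[lab]
        )
        out[:, seg] += np.outer(template, kern)
        t_rel = t_kernel  # reuse grid; dips may extend past the ERP kernel
        for band_name, per_class in effects.erd.items():
            spec = per_class[lab]
            if spec.depth == 0.0 or spec.duration_ms == 0.0:
                continue
            dip_len_ms = ERD_ONSET_MS + 2 * ERD_RAMP_MS + spec.duration_ms
            d_len = int(round(dip_len_ms * fs / 1000.0))
            d_stop = min(ev + d_len, n_samples)
            t_d = np.arange(d_stop - ev) * 1000.0 / fs
            dip = erd_dip(t_d, spec.depth, spec.duration_ms)
            osc = sources["osc"][band_name][ev:d_stop]
            out[:, ev:d_stop] -= np.outer(template, dip * osc)
    return out


def generate_continuous_eeg(
    sequence: StimulusSequence,
    timing: TimingConfig | None = None,
    effects: EffectSpec | None = None,
    n_channels: int = 64,
    seed: int | None = None,
    pad_s: float = 2.0,
    return_parts: bool = False,
):
    """Render a full continuous session for a stimulus sequence.

    One event marker is placed at every stimulus onset (``pad + i·ISI +
    fixation``).  Same seed ⇒ bit-identical output.  With
    ``return_parts=True`` also returns ``{'background', 'contributions',
    'sources', 'event_samples'}`` for invariance checks and source-level
    oracles.
    """
    timing = timing or TimingConfig()
    effects = effects or EffectSpec()
    if n_channels < 2:
        raise InvalidConfigurationError("need at least 2 channels")

    fs = timing.sampling_rate_hz
    isi = timing.isi_samples
    if isi * 1000.0 / fs < ERP_KERNEL_MS:
        warnings.warn(
            "inter-stimulus interval shorter than the ERP kernel support; "
            "overlapping kernels are summed linearly",
            stacklevel=2,
        )
    pad = int(round(pad_s * fs))
    n_trials = sequence.n_trials
    n_samples = 2 * pad + n_trials * isi
    fix = int(round(timing.fixation_ms * fs / 1000.0))
    event_samples = [pad + i * isi + fix for i in range(n_trials)]

    background, sources = simulate_background(n_channels, n_samples, fs, effects, seed)
    contrib = event_contributions(
        sequence, timing, effects, sources, n_samples, event_samples
    )
    data = background + contrib

    labels = sequence.flat_labels()
    recording = Recording(
        data=data,
        channel_labels=sources["labels"],
        fs=fs,
        events=[(ev, lab) for ev, lab in zip(event_samples, labels)],
    )
    if return_parts:
        parts = {
            "background": background,
            "contributions": contrib,
            "sources": sources,
            "event_samples": event_samples,
        }
        return recording, parts
    return recording


# ---------------------------------------------------------------------------
# Artifact injection

ARTIFACT_KINDS = ("flat-channel", "muscle-burst", "eye-step")


@dataclass(frozen=True)
class ArtifactSpec:
    """One injected artifact: kind, target channels, placement, magnitude.

    Placement is either ``trial`` (an event index; the artifact covers
    −200…2000 ms around that stimulus onset) or ``span_s`` (absolute start /
    end in seconds); with neither, the whole recording is affected.
    """

    kind: str
    channels: tuple[str, ...]
    trial: int | None = None
    span_s: tuple[float, float] | None = None
    magnitude: float = 100.0

    def __post_init__(self) -> None:
        if self.kind not in ARTIFACT_KINDS:
            raise InvalidConfigurationError(
                f"unknown artifact kind {self.kind!r}; expected one of {ARTIFACT_KINDS}"
            )


def _artifact_span(rec: Recording, spec: ArtifactSpec) -> tuple[int, int]:
    n = rec.n_samples
    if spec.trial is not None:
        # from stimulus onset to trial end, so the onset edge lies inside the
        # −200…2000 ms epoch window
        ev = rec.events[spec.trial][0]
        start = ev
        stop = ev + int(round(2.0 * rec.fs))
    elif spec.span_s is not None:
        start = int(round(spec.span_s[0] * rec.fs))
        stop = int(round(spec.span_s[1] * rec.fs))
    else:
        start, stop = 0, n
    return max(start, 0), min(stop, n)


def inject_artifacts(
    recording: Recording,
    specs: list[ArtifactSpec],
    seed: int | None = None,
) -> Recording:
    """Superpose artifacts on a copy of the recording.

    ``flat-channel`` zeroes the channel (dead electrode); ``muscle-burst``
    adds 30 Hz–Nyquist filtered noise at the given RMS magnitude;
    ``eye-step`` adds a DC step of the given magnitude over the span.  The
    ground truth is appended to ``annotations`` for test assertions.  An
    empty spec list returns an identical copy.
    """
    out = recording.copy()
    rng = np.random.default_rng(seed)
    for spec in specs:
        start, stop = _artifact_span(out, spec)
        idx = [out.channel_index(c) for c in spec.channels]
        seg = slice(start, stop)
        n_seg = stop - start
        if spec.kind == "flat-channel":
            out.data[idx, seg] = 0.0
        elif spec.kind == "eye-step":
            out.data[idx, seg] += spec.magnitude
        elif spec.kind == "muscle-burst":
            high = min(45.0, 0.45 * out.fs)
            sos = signal.butter(4, [30.0, high], btype="bandpass", fs=out.fs, output="sos")
            for i in idx:
                burst = signal.sosfiltfilt(sos, rng.standard_normal(n_seg))
                out.data[i, seg] += spec.magnitude * burst / burst.std()
        out.annotations.append(
            {
                "artifact": spec.kind,
                "channels": list(spec.channels),
                "span": (start, stop),
                "trial": spec.trial,
                "magnitude": spec.magnitude,
            }
        )
    return out
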