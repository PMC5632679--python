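"""Spatial filtering: spatio-spectral decomposition (SSD) and common
spatial patterns (CSP).

Both are generalized eigenvalue problems over channel covariances:

* SSD maximizes band power in a signal band relative to the power in two
  flanking noise bands, ``W = argmax (wᵀ C_signal w) / (wᵀ C_flank w)`` —
  used on *continuous* data (filter-edge artifacts are avoided that way) as
  a denoising projection before CSP;
* CSP jointly diagonalizes the two class-average covariances of
  band-filtered epochs; each component's eigenvalue λ is its class-A
  variance fraction in [0, 1], so components with λ far from 0.5 are the
  discriminative ones.  Up to three filters per class are kept, ranked by
  max(λ, 1−λ) with a median-variance consistency check.

Filters (columns of W) extract components; patterns (columns of A,
``A = C·W·(WᵀC·W)⁻¹``) describe their scalp projection.  Each filter is
scaled so its largest-magnitude pattern entry is positive (the sign is
otherwise indeterminate).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg, signal

from .containers import (
    EpochSet,
    InvalidConfigurationError,
    MissingClassError,
    Recording,
)

logger = logging.getLogger(__name__)

#: generalized eigenvalues below this fraction of the largest are discarded
SSD_EIGENVALUE_TRUNCATION = 1e-6


@dataclass(frozen=True)
class BandSpec:
    """Signal band plus flanker geometry for SSD.

    Two flanking noise bands of ``flanker_hz`` width sit ``gap_hz`` below and
    above the signal band.
    """

    low: float
    high: float
    flanker_hz: float = 2.0
    gap_hz: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise InvalidConfigurationError("need 0 < low < high")
        if self.flanker_hz <= 0 or self.gap_hz < 0:
            raise InvalidConfigurationError("flanker width must be positive, gap ≥ 0")
        if self.low - self.gap_hz - self.flanker_hz <= 0:
            raise InvalidConfigurationError("lower flanker extends to or below 0 Hz")

    @property
    def signal_band(self) -> tuple[float, float]:
        return (self.low, self.high)

    @property
    def flanker_bands(self) -> tuple[tuple[float, float], tuple[float, float]]:
        return (
            (self.low - self.gap_hz - self.flanker_hz, self.low - self.gap_hz),
            (self.high + self.gap_hz, self.high + self.gap_hz + self.flanker_hz),
        )


@dataclass
class SpatialFilterBank:
    """Demixing filters W, mixing patterns A and eigenvalues λ.

    Components are ordered by descending λ for SSD (band-to-flanker power
    ratio) and by descending max(λ, 1−λ) for CSP (λ = class-A variance
    fraction).
    """

    W: np.ndarray  # channels × components
    A: np.ndarray  # channels × components
    eigenvalues: np.ndarray
    method: str  # "SSD" | "CSP"
    band: tuple[float, float]
    channel_labels: list[str]
    class_pair: tuple[str, str] | None = None

    @property
    def n_components(self) -> int:
        return self.W.shape[1]


def _bandpass(data: np.ndarray, band: tuple[float, float], fs: float) -> np.ndarray:
    low, high = band
    if high >= fs / 2:
        raise InvalidConfigurationError(f"band {band} exceeds Nyquist at fs={fs}")
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def _fix_signs(W: np.ndarray, A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    for j in range(A.shape[1]):
        k = int(np.argmax(np.abs(A[:, j])))
        if A[k, j] < 0:
            A[:, j] = -A[:, j]
            W[:, j] = -W[:, j]
    return W, A


def _patterns(cov: np.ndarray, W: np.ndarray) -> np.ndarray:
    # A = C W (Wᵀ C W)⁻¹ — the unique patterns consistent with the filters
    m = W.T @ cov @ W
    return cov @ W @ np.linalg.pinv(m)


def ssd_fit(
    recording: Recording,
    band: BandSpec,
    truncation: float = SSD_EIGENVALUE_TRUNCATION,
) -> SpatialFilterBank:
    """Fit SSD filters on continuous data.

    Solves the generalized eigenproblem of (signal-band covariance,
    flanker-band covariance) after a whitening/rank-reduction step that
    discards signal-covariance eigendirections below ``truncation`` times
    the largest (low-rank factorization).  λ are the band-to-flanker power
    ratios, sorted descending.
    """
    x_sig = _bandpass(recording.data, band.signal_band, recording.fs)
    lo_band, hi_band = band.flanker_bands
    x_noise = _bandpass(recording.data, lo_band, recording.fs) + _bandpass(
        recording.data, hi_band, recording.fs
    )
    c_sig = np.cov(x_sig)
    c_noise = np.cov(x_noise)
    return _ssd_from_covariances(
        c_sig, c_noise, band, list(recording.channel_labels), truncation
    )


def ssd_fit_epochs(
    epochs: EpochSet, band: BandSpec, truncation: float = SSD_EIGENVALUE_TRUNCATION
) -> SpatialFilterBank:
    """SSD from *broadband* epoched data (concatenated trials) — used when
    fitting must stay inside a cross-validation fold and no continuous data
    is at hand.  Filter-edge effects at trial boundaries are accepted."""
    flat = np.concatenate(list(epochs.data), axis=-1)
    rec = Recording(
        data=flat, channel_labels=list(epochs.channel_labels), fs=epochs.fs
    )
    return ssd_fit(rec, band, truncation)


def trial_covariances(data: np.ndarray) -> np.ndarray:
    """Per-trial sample covariances of a (trials × channels × samples) array."""
    centered = data - data.mean(axis=-1, keepdims=True)
    return centered @ centered.transpose(0, 2, 1) / (data.shape[-1] - 1)


def ssd_fit_covariances(
    c_signal: np.ndarray,
    c_noise: np.ndarray,
    band: BandSpec,
    channel_labels: list[str],
    truncation: float = SSD_EIGENVALUE_TRUNCATION,
) -> SpatialFilterBank:
    """SSD from precomputed signal-band and flanker-band covariances.

    Lets callers filter once and refit on trial subsets (e.g. inside
    cross-validation folds) without re-filtering."""
    return _ssd_from_covariances(c_signal, c_noise, band, channel_labels, truncation)


def _ssd_from_covariances(
    c_sig: np.ndarray,
    c_noise: np.ndarray,
    band: BandSpec,
    channel_labels: list[str],
    truncation: float,
) -> SpatialFilterBank:
    evals, evecs = linalg.eigh(c_sig)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > truncation * evals[0]
    rank = int(keep.sum())
    if rank < c_sig.shape[0]:
        logger.info("SSD rank reduction: %d → %d dimensions", c_sig.shape[0], rank)
    white = evecs[:, :rank] / np.sqrt(evals[:rank])  # channels × rank

    cs_w = white.T @ c_sig @ white
    cn_w = white.T @ c_noise @ white
    # noise covariance can be rank-deficient on synthetic data; ridge if so
    ridge = 0.0
    try:
        lam, vecs = linalg.eigh(cs_w, cn_w)
    except linalg.LinAlgError:
        ridge = 1e-9 * np.trace(cn_w) / rank
        logger.info("SSD: flanker covariance singular, ridge %.3e added", ridge)
        lam, vecs = linalg.eigh(cs_w, cn_w + ridge * np.eye(rank))
    order = np.argsort(lam)[::-1]
    lam, vecs = lam[order], vecs[:, order]

    W = white @ vecs
    A = _patterns(c_sig, W)
    W, A = _fix_signs(W, A)
    return SpatialFilterBank(
        W=W,
        A=A,
        eigenvalues=lam,
        method="SSD",
        band=band.signal_band,
        channel_labels=channel_labels,
    )


def select_ssd_components(
    bank: SpatialFilterBank,
    ratio_threshold: float = 1.2,
    min_keep: int = 1,
    max_keep: int | None = None,
) -> SpatialFilterBank:
    """Keep the genuinely oscillatory SSD subspace.

    Broadband (1/f or white) noise has a roughly constant band-to-flanker
    power ratio, so its eigenvalues cluster around a common baseline;
    oscillatory sources stand above it.  Components with
    λ > ``ratio_threshold`` × median(λ) are kept (at least ``min_keep``,
    at most ``max_keep``).  Projecting onto this subspace before CSP is what
    makes SSD act as a denoiser — an invertible (full) SSD rotation would
    leave CSP unchanged.
    """
    if bank.method != "SSD":
        raise InvalidConfigurationError("component selection applies to SSD banks")
    lam = bank.eigenvalues
    baseline = np.median(lam)
    keep = int(max((lam > ratio_threshold * baseline).sum(), min_keep))
    if max_keep is not None:
        keep = min(keep, max_keep)
    # λ is sorted descending, so the top-`keep` slice is the kept subspace
    return replace(
        bank, W=bank.W[:, :keep], A=bank.A[:, :keep], eigenvalues=lam[:keep]
    )


# ---------------------------------------------------------------------------
# CSP


def _class_covariance(x: np.ndarray) -> np.ndarray:
    """Average of per-trial sample covariances (trials × channels × samples)."""
    n = x.shape[-1]
    centered = x - x.mean(axis=-1, keepdims=True)
    covs = centered @ centered.transpose(0, 2, 1) / (n - 1)
    return covs.mean(axis=0)


def csp_fit(
    epochs: EpochSet,
    class_pair: tuple[str, str],
    band: tuple[float, float] | None = None,
) -> SpatialFilterBank:
    """Fit CSP filters for a class pair on (already band-filtered) epochs.

    W jointly diagonalizes the class-average covariances: λ_i is component
    i's class-A variance fraction, ``wᵀC_A w / wᵀ(C_A + C_B) w``, in [0, 1];
    λ_A + λ_B = 1 per component by construction.  Components are ordered by
    descending max(λ, 1−λ).
    """
    xa, xb = _split_classes_data(epochs, class_pair)
    c_a = _class_covariance(xa)
    c_b = _class_covariance(xb)
    comp = c_a + c_b
    ridge = 0.0
    try:
        lam, W = linalg.eigh(c_a, comp)
    except linalg.LinAlgError:
        ridge = 1e-9 * np.trace(comp) / comp.shape[0]
        logger.info("CSP: composite covariance singular, ridge %.3e added", ridge)
        lam, W = linalg.eigh(c_a, comp + ridge * np.eye(comp.shape[0]))
    lam = np.clip(lam, 0.0, 1.0)
    order = np.argsort(np.maximum(lam, 1 - lam))[::-1]
    lam, W = lam[order], W[:, order]
    A = _patterns(comp, W)
    W, A = _fix_signs(W, A)
    return SpatialFilterBank(
        W=W,
        A=A,
        eigenvalues=lam,
        method="CSP",
        band=band or (np.nan, np.nan),
        channel_labels=list(epochs.channel_labels),
        class_pair=class_pair,
    )


def _split_classes_data(
    epochs: EpochSet, class_pair: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    a, b = class_pair
    xa = epochs.data[epochs.labels == a]
    xb = epochs.data[epochs.labels == b]
    if len(xa) < 2 or len(xb) < 2:
        raise MissingClassError(
            f"need ≥ 2 trials per class, got {len(xa)} {a!r} / {len(xb)} {b!r}"
        )
    return xa, xb


def select_csp_components(
    bank: SpatialFilterBank,
    epochs: EpochSet | None = None,
    max_per_class: int = 3,
    margin: float = 0.01,
    median_ratio_margin: float = 1.05,
) -> SpatialFilterBank:
    """Keep up to ``max_per_class`` components from each eigenvalue extreme.

    A component qualifies only if |λ − 0.5| > ``margin`` and — when training
    epochs are supplied — its median per-trial variance ordering across the
    two classes agrees with the side of 0.5 its λ sits on by at least
    ``median_ratio_margin`` (consistency check against outlier-driven
    eigenvalues; the mean covariance is outlier-sensitive, the median is
    not).  May return fewer components; returns zero with a warning when
    nothing is discriminative.
    """
    if bank.method != "CSP":
        raise InvalidConfigurationError("component selection applies to CSP banks")
    lam = bank.eigenvalues
    consistent = np.ones(len(lam), dtype=bool)
    if epochs is not None and bank.class_pair is not None:
        xa, xb = _split_classes_data(epochs, bank.class_pair)
        va = np.einsum("ic,tcs->tis", bank.W.T, xa).var(axis=-1)
        vb = np.einsum("ic,tcs->tis", bank.W.T, xb).var(axis=-1)
        med_a, med_b = np.median(va, axis=0), np.median(vb, axis=0)
        consistent = np.where(
            lam > 0.5,
            med_a > median_ratio_margin * med_b,
            med_b > median_ratio_margin * med_a,
        )

    high = [i for i in np.argsort(lam)[::-1] if lam[i] > 0.5 + margin and consistent[i]]
    low = [i for i in np.argsort(lam) if lam[i] < 0.5 - margin and consistent[i]]
    chosen = sorted(
        set(high[:max_per_class]) | set(low[:max_per_class]),
        key=lambda i: np.maximum(lam[i], 1 - lam[i]),
        reverse=True,
    )
    if not chosen:
        warnings.warn("no discriminative CSP components found", stacklevel=2)
    return replace(
        bank,
        W=bank.W[:, chosen],
        A=bank.A[:, chosen],
        eigenvalues=lam[list(chosen)] if chosen else np.empty(0),
    )


def apply_filters(bank: SpatialFilterBank, epochs: EpochSet) -> EpochSet:
    """Project epochs into component space (each trial left-multiplied by Wᵀ)."""
    if bank.W.shape[0] != epochs.n_channels:
        raise InvalidConfigurationError(
            f"bank has {bank.W.shape[0]} channels, epochs have {epochs.n_channels}"
        )
    if bank.channel_labels != epochs.channel_labels:
        raise InvalidConfigurationError("channel label sets differ between bank and epochs")
    data = np.einsum("ck,tcs->tks", bank.W, epochs.data)
    labels = [f"{bank.method}{j}" for j in range(bank.n_components)]
    return replace(
        epochs,
        data=data,
        channel_labels=labels,
        rejection_log=list(epochs.rejection_log),
    )
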