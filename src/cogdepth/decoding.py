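"""Multimodal feature fusion and shrinkage-LDA classification.

Features per trial:

* spatio-temporal (ERP): mean amplitude per channel over each selected
  discriminative interval;
* spatio-spectral (mCSP): log-variance of each retained CSP component in
  the α and β bands over a 350–2000 ms post-stimulus window (the cognitive
  process is assumed under way from the P300 peak onward).

Feature tables are concatenated (optionally z-scored with training-set
statistics) and classified by linear discriminant analysis whose pooled
covariance is shrunk toward a scaled identity with the analytic Ledoit-Wolf
intensity.  Performance is the area under the ROC curve (equivalently the
normalized Mann-Whitney U statistic), evaluated by stratified 10-fold
cross-validation repeated 10 times.

By default every data-driven step — interval selection, SSD, CSP, scaling,
LDA — is fitted inside each training fold (fully nested validation).
``nested=False`` instead fits SSD and the interval selection once on the
whole dataset, a partially nested variant with a small known optimism, kept
for comparison.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.covariance import ledoit_wolf

from .containers import (
    EpochSet,
    InvalidConfigurationError,
    MissingClassError,
)
from .spatial import (
    BandSpec,
    SpatialFilterBank,
    apply_filters,
    csp_fit,
    select_csp_components,
    select_ssd_components,
    ssd_fit_covariances,
    trial_covariances,
)
from .univariate import IntervalSet, select_intervals, signed_r_squared

logger = logging.getLogger(__name__)

MODALITIES = ("erp", "csp-alpha", "csp-beta")


@dataclass
class FeatureTable:
    """Trials × features matrix with per-column provenance.

    Each provenance entry records the modality plus the channel/component
    and interval/band the column came from.
    """

    matrix: np.ndarray
    provenance: list[dict]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise InvalidConfigurationError("feature matrix must be 2-D")
        if len(self.provenance) != self.matrix.shape[1]:
            raise InvalidConfigurationError("provenance must cover every column exactly once")
        if len(self.labels) != self.matrix.shape[0]:
            raise InvalidConfigurationError("labels must cover every trial")
        if not np.all(np.isfinite(self.matrix)):
            raise InvalidConfigurationError("features contain non-finite values")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


class EmptyFeatureError(ValueError):
    """No features could be extracted (e.g. empty interval set)."""


def erp_features(epochs: EpochSet, intervals: IntervalSet) -> FeatureTable:
    """Mean amplitude per (channel, interval): channels × intervals columns."""
    if len(intervals) == 0:
        raise EmptyFeatureError("empty interval set")
    cols, prov = [], []
    for (t0, t1) in intervals.intervals:
        mask = epochs.time_mask(t0, t1)
        if not mask.any():
            raise InvalidConfigurationError(f"interval ({t0}, {t1}) outside epoch window")
        means = epochs.data[:, :, mask].mean(axis=-1)  # trials × channels
        for c, lab in enumerate(epochs.channel_labels):
            cols.append(means[:, c])
            prov.append({"modality": "erp", "channel": lab, "interval": (t0, t1)})
    return FeatureTable(np.column_stack(cols), prov, epochs.labels.copy())


def logvar_features(
    component_epochs: EpochSet,
    window: tuple[float, float] = (350.0, 2000.0),
    band_name: str = "",
    epsilon: float = 1e-12,
) -> FeatureTable:
    """Natural log of per-component variance over the post-stimulus window."""
    mask = component_epochs.time_mask(*window)
    if not mask.any():
        raise InvalidConfigurationError(f"window {window} outside epoch window")
    var = component_epochs.data[:, :, mask].var(axis=-1)
    if np.any(var <= 0):
        logger.info("log-variance: %d zero-variance entries floored", int((var <= 0).sum()))
        var = np.maximum(var, epsilon)
    prov = [
        {"modality": f"csp-{band_name}" if band_name else "csp", "component": lab,
         "window": window}
        for lab in component_epochs.channel_labels
    ]
    return FeatureTable(np.log(var), prov, component_epochs.labels.copy())


@dataclass
class FeatureScaler:
    """Per-column standardization fitted on training data only."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, matrix: np.ndarray) -> "FeatureScaler":
        std = matrix.std(axis=0, ddof=0)
        return cls(mean=matrix.mean(axis=0), std=np.where(std > 0, std, 1.0))

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        return (matrix - self.mean) / self.std


def fuse_features(tables: list[FeatureTable], zscore: bool = False) -> FeatureTable:
    """Column-wise concatenation (training-set z-scoring is applied later,
    inside the fold, via :class:`FeatureScaler`)."""
    if not tables:
        raise EmptyFeatureError("nothing to fuse")
    first = tables[0]
    for t in tables[1:]:
        if t.matrix.shape[0] != first.matrix.shape[0] or not np.array_equal(
            t.labels, first.labels
        ):
            raise InvalidConfigurationError("feature tables disagree on trials")
    fused = FeatureTable(
        np.concatenate([t.matrix for t in tables], axis=1),
        [dict(p) for t in tables for p in t.provenance],
        first.labels.copy(),
    )
    if zscore:
        scaler = FeatureScaler.fit(fused.matrix)
        fused = replace(fused, matrix=scaler.transform(fused.matrix))
    return fused


# ---------------------------------------------------------------------------
# Shrinkage LDA


@dataclass
class LDAModel:
    """Linear discriminant: score(x) = wᵀx + b, positive ⇒ class B.

    The pooled within-class covariance is shrunk toward a scaled identity,
    ``Σ_γ = (1−γ)Σ + γ·(tr Σ / d)·I``, with analytically chosen γ.
    """

    weights: np.ndarray
    bias: float
    shrinkage: float
    class_pair: tuple[str, str]
    means: dict[str, np.ndarray]

    def decision_values(self, matrix: np.ndarray) -> np.ndarray:
        return matrix @ self.weights + self.bias


def lda_train(
    features: FeatureTable,
    class_pair: tuple[str, str],
    shrinkage: float | None = None,
) -> LDAModel:
    """Train shrinkage-regularized LDA for one class pair.

    γ defaults to the Ledoit-Wolf analytic estimate on the pooled
    class-centered data; pass ``shrinkage`` to force a value (γ=1 yields the
    scaled-identity / mean-difference classifier).  ``w = Σ_γ⁻¹(μ_B − μ_A)``
    and the bias centers the decision value midway between the class means.
    """
    a, b = class_pair
    xa = features.matrix[features.labels == a]
    xb = features.matrix[features.labels == b]
    if len(xa) < 2 or len(xb) < 2:
        raise MissingClassError(f"need ≥ 2 trials per class for {class_pair}")
    mu_a, mu_b = xa.mean(axis=0), xb.mean(axis=0)
    centered = np.concatenate([xa - mu_a, xb - mu_b], axis=0)
    d = centered.shape[1]
    emp = centered.T @ centered / len(centered)
    if shrinkage is None:
        _, gamma = ledoit_wolf(centered, assume_centered=True)
    else:
        gamma = float(shrinkage)
    target = np.trace(emp) / d if d else 1.0
    sigma = (1.0 - gamma) * emp + gamma * target * np.eye(d)
    w = np.linalg.solve(sigma, mu_b - mu_a)
    bias = -0.5 * float(w @ (mu_a + mu_b))
    return LDAModel(
        weights=w, bias=bias, shrinkage=float(gamma), class_pair=class_pair,
        means={a: mu_a, b: mu_b},
    )


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the normalized Mann-Whitney U statistic.

    ``labels`` is boolean (True = positive class); ties count one half.
    Equals P(score⁺ > score⁻) + ½·P(score⁺ = score⁻).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise MissingClassError("AUC needs both classes present")
    from scipy.stats import rankdata

    ranks = rankdata(scores)  # midranks handle ties as ½ automatically
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc_permutation_pvalue(
    scores: np.ndarray,
    labels: np.ndarray,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> float:
    """Permutation p-value for AUC ≠ 0.5 under label exchangeability.

    Labels are permuted against the fixed scores; the p-value is the
    fraction of permutations whose |AUC − 0.5| reaches the observed one
    (with the +1 correction).
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=bool)
    observed = abs(auc(scores, labels) - 0.5)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if abs(auc(scores, perm) - 0.5) >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


# ---------------------------------------------------------------------------
# Cross-validated decoding


@dataclass
class DecodingConfig:
    """What to fuse and how to validate.

    ``modalities`` ⊆ {"erp", "csp-alpha", "csp-beta"}; bands are the α and β
    edges; ``csp_window`` is the log-variance window; ``nested=False``
    reproduces the partially nested variant (SSD + interval selection fitted
    on the whole dataset).
    """

    modalities: tuple[str, ...] = MODALITIES
    n_folds: int = 10
    n_repetitions: int = 10
    zscore: bool = False
    nested: bool = True
    use_ssd: bool = True
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"alpha": (8.0, 14.0), "beta": (16.0, 20.0)}
    )
    band_specs: dict[str, BandSpec] = field(default_factory=dict)
    csp_window: tuple[float, float] = (350.0, 2000.0)
    max_csp_per_class: int = 3
    n_intervals: int = 5
    #: SSD components with λ above this multiple of the median λ are kept
    ssd_ratio_threshold: float = 1.2
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.modalities:
            raise InvalidConfigurationError("at least one modality must be enabled")
        for m in self.modalities:
            if m not in MODALITIES:
                raise InvalidConfigurationError(f"unknown modality {m!r}")
        for name, edges in self.bands.items():
            self.band_specs.setdefault(name, BandSpec(*edges))

    def fingerprint(self) -> str:
        blob = repr(
            (
                sorted(self.modalities), self.n_folds, self.n_repetitions,
                self.zscore, self.nested, self.use_ssd, sorted(self.bands.items()),
                self.csp_window, self.max_csp_per_class, self.n_intervals, self.seed,
            )
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class CVReport:
    """Per-repetition × per-fold AUCs for one class pair."""

    aucs: np.ndarray  # repetitions × folds
    class_pair: tuple[str, str]
    seed: int | None
    config_fingerprint: str
    mode: str = "default"
    trial_scores: np.ndarray | None = None
    trial_labels: np.ndarray | None = None

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())

    @property
    def std_auc(self) -> float:
        return float(self.aucs.std())


def _stratified_folds(
    labels: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Random stratified partition: test-index arrays covering all trials."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < n_folds:
            raise InvalidConfigurationError(
                f"class {cls!r} has {len(idx)} trials, fewer than {n_folds} folds"
            )
        idx = rng.permutation(idx)
        for f, chunk in enumerate(np.array_split(idx, n_folds)):
            folds[f].extend(chunk.tolist())
    return [np.sort(np.array(f)) for f in folds]


def _band_filtered_cache(
    epochs: EpochSet, config: DecodingConfig
) -> dict[str, dict]:
    """Filter each enabled band once (label-independent, so outside folds).

    Per band: the signal-band filtered epochs, plus — when SSD is on — the
    per-trial signal and flanker covariances SSD refits from inside folds.
    """
    from .spatial import _bandpass

    cache: dict[str, dict] = {}
    for name in config.bands:
        if f"csp-{name}" not in config.modalities:
            continue
        spec = config.band_specs[name]
        sig = _bandpass(epochs.data, spec.signal_band, epochs.fs)
        entry: dict = {
            "epochs": replace(
                epochs, data=sig, rejection_log=list(epochs.rejection_log)
            )
        }
        if config.use_ssd:
            lo, hi = spec.flanker_bands
            flank = _bandpass(epochs.data, lo, epochs.fs) + _bandpass(
                epochs.data, hi, epochs.fs
            )
            entry["sig_covs"] = trial_covariances(sig)
            entry["flank_covs"] = trial_covariances(flank)
        cache[name] = entry
    return cache


def _subset(epochs: EpochSet, idx: np.ndarray) -> EpochSet:
    return replace(
        epochs, data=epochs.data[idx], labels=epochs.labels[idx],
        rejection_log=list(epochs.rejection_log),
    )


def _fold_features(
    train: EpochSet,
    test: EpochSet,
    band_cache: dict[str, dict],
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    class_pair: tuple[str, str],
    config: DecodingConfig,
    fixed_intervals: IntervalSet | None,
    fixed_ssd: dict[str, SpatialFilterBank],
) -> tuple[FeatureTable, FeatureTable]:
    """Fit all estimators on the training split, apply to both splits."""
    train_tables, test_tables = [], []

    if "erp" in config.modalities:
        intervals = fixed_intervals
        if intervals is None:
            dmap = signed_r_squared(train, class_pair)
            intervals = select_intervals(dmap, n_max=config.n_intervals)
        if len(intervals) == 0:  # discriminability-free training fold
            mid = 0.5 * (train.times[0] + train.times[-1])
            intervals = IntervalSet(intervals=[(mid, train.times[-1])])
        train_tables.append(erp_features(train, intervals))
        test_tables.append(erp_features(test, intervals))

    for name in config.bands:
        if f"csp-{name}" not in config.modalities:
            continue
        entry = band_cache[name]
        btrain = _subset(entry["epochs"], train_idx)
        btest = _subset(entry["epochs"], test_idx)
        if config.use_ssd:
            ssd = fixed_ssd.get(name)
            if ssd is None:
                ssd = ssd_fit_covariances(
                    entry["sig_covs"][train_idx].mean(axis=0),
                    entry["flank_covs"][train_idx].mean(axis=0),
                    config.band_specs[name],
                    list(btrain.channel_labels),
                )
                ssd = select_ssd_components(
                    ssd, ratio_threshold=config.ssd_ratio_threshold
                )
            btrain = apply_filters(ssd, btrain)
            btest = apply_filters(ssd, btest)
        csp = csp_fit(btrain, class_pair, band=config.bands[name])
        with warnings.catch_warnings():
            # a fold without discriminative components is routine, not a
            # user-facing anomaly; the band is simply skipped
            warnings.simplefilter("ignore", UserWarning)
            csp = select_csp_components(
                csp, btrain, max_per_class=config.max_csp_per_class
            )
        if csp.n_components == 0:
            continue
        train_tables.append(
            logvar_features(apply_filters(csp, btrain), config.csp_window, name)
        )
        test_tables.append(
            logvar_features(apply_filters(csp, btest), config.csp_window, name)
        )

    if not train_tables:
        raise EmptyFeatureError("no features produced in this fold")
    return fuse_features(train_tables), fuse_features(test_tables)


def crossvalidate(
    epochs: EpochSet,
    class_pair: tuple[str, str],
    config: DecodingConfig | None = None,
    mode: str = "default",
) -> CVReport:
    """Stratified k-fold × r-repetition decoding of one class pair.

    Every repetition draws a fresh stratified partition from the seeded RNG;
    per fold, features are fitted on the training trials only (see
    :func:`_fold_features`) and the held-out trials are scored by the
    trained LDA.  The report carries the per-fold AUC matrix and the
    cross-validated decision value of every trial (averaged over
    repetitions' test assignments).
    """
    config = config or DecodingConfig()
    pair_epochs = epochs.select_classes(class_pair)
    labels = pair_epochs.labels
    if len(np.unique(labels)) < 2:
        raise MissingClassError(f"both classes of {class_pair} must be present")
    rng = np.random.default_rng(config.seed)

    band_cache = _band_filtered_cache(pair_epochs, config)

    fixed_intervals: IntervalSet | None = None
    fixed_ssd: dict[str, SpatialFilterBank] = {}
    if not config.nested:
        # partially nested variant: SSD and interval selection on all data
        if "erp" in config.modalities:
            fixed_intervals = select_intervals(
                signed_r_squared(pair_epochs, class_pair), n_max=config.n_intervals
            )
        if config.use_ssd:
            for name, entry in band_cache.items():
                fixed_ssd[name] = select_ssd_components(
                    ssd_fit_covariances(
                        entry["sig_covs"].mean(axis=0),
                        entry["flank_covs"].mean(axis=0),
                        config.band_specs[name],
                        list(pair_epochs.channel_labels),
                    ),
                    ratio_threshold=config.ssd_ratio_threshold,
                )

    n_trials = len(labels)
    aucs = np.zeros((config.n_repetitions, config.n_folds))
    score_sum = np.zeros(n_trials)
    score_count = np.zeros(n_trials)
    positive = class_pair[1]

    for rep in range(config.n_repetitions):
        folds = _stratified_folds(labels, config.n_folds, rng)
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(n_trials), test_idx)
            train = _subset(pair_epochs, train_idx)
            test = _subset(pair_epochs, test_idx)
            ftrain, ftest = _fold_features(
                train, test, band_cache, train_idx, test_idx,
                class_pair, config, fixed_intervals, fixed_ssd,
            )
            scaler = FeatureScaler.fit(ftrain.matrix) if config.zscore else None
            if scaler is not None:
                ftrain = replace(ftrain, matrix=scaler.transform(ftrain.matrix))
                ftest = replace(ftest, matrix=scaler.transform(ftest.matrix))
            model = lda_train(ftrain, class_pair)
            scores = model.decision_values(ftest.matrix)
            aucs[rep, f] = auc(scores, ftest.labels == positive)
            score_sum[test_idx] += scores
            score_count[test_idx] += 1

    return CVReport(
        aucs=aucs,
        class_pair=class_pair,
        seed=config.seed,
        config_fingerprint=config.fingerprint(),
        mode=mode,
        trial_scores=score_sum / np.maximum(score_count, 1),
        trial_labels=labels == positive,
    )


# ---------------------------------------------------------------------------
# EOG-only control decoding

EOG_DERIVATIONS = (("EOG", "Fp1"), ("F10", "F9"))


def channel_subset_control(
    epochs: EpochSet,
    class_pair: tuple[str, str],
    config: DecodingConfig | None = None,
    derivations: tuple[tuple[str, str], ...] = EOG_DERIVATIONS,
) -> CVReport:
    """Decode from ocular derivations only (contamination control).

    Builds the vertical (EOG − Fp1) and horizontal (F10 − F9) bipolar
    derivations and runs the standard pipeline on those two channels alone.
    AUC near 0.5 indicates the full-montage decoding is not driven by eye
    movements.  The report is marked ``mode="EOG-control"``.
    """
    for pair in derivations:
        for ch in pair:
            if ch not in epochs.channel_labels:
                raise InvalidConfigurationError(f"channel {ch!r} not present")
    rows = []
    names = []
    for pos, neg in derivations:
        rows.append(
            epochs.data[:, epochs.channel_index(pos), :]
            - epochs.data[:, epochs.channel_index(neg), :]
        )
        names.append(f"{pos}-{neg}")
    sub = replace(
        epochs,
        data=np.stack(rows, axis=1),
        channel_labels=names,
        rejection_log=list(epochs.rejection_log),
    )
    config = config or DecodingConfig()
    report = crossvalidate(sub, class_pair, config, mode="EOG-control")
    return report
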