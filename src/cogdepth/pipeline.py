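"""The end-to-end analysis chain.

``run_pipeline`` chains simulate/read → preprocess → univariate maps →
spatial filtering → decoding for all three class pairs, and writes a run
manifest (configuration, seed, rejection logs, per-fold AUCs), CSV tables
and optional figures into the output directory.  A run is fully
reconstructable from its manifest: same config + seed ⇒ same numbers.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .containers import EpochSet, Recording
from .decoding import CVReport, DecodingConfig, channel_subset_control, crossvalidate
from .io import PipelineConfig, read_brainvision, save_epochs
from .paradigm import TimingConfig, generate_stimulus_sequence
from .preprocessing import preprocess
from .simulate import EffectSpec, generate_continuous_eeg
from .univariate import erd_curves, signed_r_squared

logger = logging.getLogger(__name__)

CLASS_PAIRS = (("NT", "ST"), ("NT", "DT"), ("ST", "DT"))


class PipelineError(RuntimeError):
    """Wraps a stage failure with the stage's identity."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        return wrapper

    return deco


@_stage("simulate")
def acquire(config: PipelineConfig) -> Recording:
    """Read the configured BrainVision file, or simulate a session."""
    if config.input_vhdr:
        return read_brainvision(config.input_vhdr)
    sequence = generate_stimulus_sequence(
        n_runs=config.n_runs,
        n_total=config.n_total,
        ratios=tuple(config.ratios),
        tolerance=config.ratio_tolerance,
        seed=config.seed,
    )
    timing = TimingConfig(sampling_rate_hz=config.sampling_rate_hz)
    effects = EffectSpec.null() if config.effects == "null" else EffectSpec()
    return generate_continuous_eeg(
        sequence, timing, effects, n_channels=config.n_channels, seed=config.seed
    )


@_stage("preprocess")
def preprocess_stage(recording: Recording, config: PipelineConfig) -> EpochSet:
    epochs = preprocess(
        recording,
        target_fs=config.target_fs,
        epoch_window=tuple(config.epoch_window),
        baseline=tuple(config.erp_baseline),
        var_threshold=config.flat_var_threshold,
        flat_trial_fraction=config.flat_trial_fraction,
        excess_channel_fraction=config.excess_channel_fraction,
        mad_factor=config.excess_mad_factor,
        minmax_threshold=config.minmax_threshold,
    )
    for entry in epochs.rejection_log:
        logger.info(
            "%s removed %d %s(s)", entry["step"], len(entry["removed"]), entry["kind"]
        )
    return epochs


@_stage("analyze")
def univariate_stage(epochs: EpochSet, config: PipelineConfig) -> dict:
    maps = {f"{a}-{b}": signed_r_squared(epochs, (a, b)) for a, b in CLASS_PAIRS}
    erds = {
        name: erd_curves(epochs, tuple(edges), baseline=tuple(config.erd_baseline))
        for name, edges in config.bands.items()
    }
    return {"r2_maps": maps, "erd_curves": erds}


@_stage("decode")
def decode_stage(epochs: EpochSet, config: PipelineConfig) -> dict[str, CVReport]:
    dec = DecodingConfig(
        modalities=tuple(config.modalities),
        n_folds=config.n_folds,
        n_repetitions=config.n_repetitions,
        zscore=config.zscore,
        nested=config.nested,
        use_ssd=config.use_ssd,
        bands={k: tuple(v) for k, v in config.bands.items()},
        csp_window=tuple(config.csp_window),
        max_csp_per_class=config.max_csp_per_class,
        n_intervals=config.n_intervals,
        seed=config.seed,
    )
    reports = {}
    for a, b in CLASS_PAIRS:
        if config.eog_control:
            reports[f"{a}-{b}"] = channel_subset_control(epochs, (a, b), dec)
        else:
            reports[f"{a}-{b}"] = crossvalidate(epochs, (a, b), dec)
        logger.info("decoded %s-%s: mean AUC %.3f", a, b, reports[f"{a}-{b}"].mean_auc)
    return reports


@_stage("report")
def report_stage(
    out_dir: Path,
    config: PipelineConfig,
    epochs: EpochSet,
    analysis: dict,
    reports: dict[str, CVReport],
) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(vars(config), default=list)),
        "n_trials": int(epochs.n_trials),
        "n_channels": int(epochs.n_channels),
        "rejection_log": epochs.rejection_log,
        "reports": {
            pair: {
                "mean_auc": rep.mean_auc,
                "std_auc": rep.std_auc,
                "mode": rep.mode,
                "config_fingerprint": rep.config_fingerprint,
            }
            for pair, rep in reports.items()
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    import csv

    with open(out_dir / "fold_aucs.csv", "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(["pair", "repetition", "fold", "auc"])
        for pair, rep in reports.items():
            for r in range(rep.aucs.shape[0]):
                for k in range(rep.aucs.shape[1]):
                    writer.writerow([pair, r, k, f"{rep.aucs[r, k]:.6f}"])

    if config.make_figures:
        _write_figures(out_dir, epochs, analysis)
    return manifest


def _write_figures(out_dir: Path, epochs: EpochSet, analysis: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for pair, dmap in analysis["r2_maps"].items():
        fig, ax = plt.subplots(figsize=(8, 5))
        vmax = max(np.abs(dmap.values).max(), 1e-6)
        im = ax.imshow(
            dmap.values,
            aspect="auto",
            origin="lower",
            extent=[dmap.axis[0], dmap.axis[-1], 0, dmap.values.shape[0]],
            cmap="RdBu_r",
            vmin=-vmax,
            vmax=vmax,
        )
        ax.set(xlabel="time (ms)", ylabel="channel", title=f"signed r²  {pair}")
        fig.colorbar(im, ax=ax, label="signed r²")
        fig.savefig(out_dir / f"r2_{pair}.png", dpi=100)
        plt.close(fig)

    pz = epochs.channel_labels.index("Pz") if "Pz" in epochs.channel_labels else 0
    for name, curve in analysis["erd_curves"].items():
        fig, ax = plt.subplots(figsize=(8, 4))
        for cls, vals in curve.values.items():
            ax.plot(curve.times, vals[pz], label=cls)
        ax.axvline(0, color="k", lw=0.5)
        ax.set(
            xlabel="time (ms)",
            ylabel="envelope change (μV)",
            title=f"ERD/ERS {curve.band[0]:g}–{curve.band[1]:g} Hz at "
            f"{epochs.channel_labels[pz]}",
        )
        ax.legend()
        fig.savefig(out_dir / f"erd_{name}.png", dpi=100)
        plt.close(fig)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain and return the manifest dict."""
    if not config.modalities:
        from .containers import InvalidConfigurationError

        raise InvalidConfigurationError("no modalities enabled")
    out_dir = Path(config.out_dir)
    recording = acquire(config)
    epochs = preprocess_stage(recording, config)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_epochs(epochs, out_dir / "epochs.h5")
    analysis = univariate_stage(epochs, config)
    reports = decode_stage(epochs, config)
    return report_stage(out_dir, config, epochs, analysis, reports)
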