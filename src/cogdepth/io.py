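"""Readers, writers and configuration.

Interchange format is the BrainVision triplet (.vhdr/.vmrk/.eeg) the
acquisition hardware family writes: an INI-style text header, a text marker
file, and multiplexed IEEE float32 binary data.  Stimulus classes map to
marker codes ``NT→S 1, ST→S 2, DT→S 3``.  Reading goes through MNE;
the writer is this package's own (float dialect, stated in the header).

Intermediate results are cached in an HDF5 container with a flat schema:
``data``, ``fs``, ``channel_labels``, and either ``events``/``event_labels``
(Recording) or ``labels``/``times``/``rejection_log`` (EpochSet, log stored
as JSON).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .containers import EpochSet, InvalidConfigurationError, Recording

MARKER_CODES = {"NT": "S  1", "ST": "S  2", "DT": "S  3"}
CODE_TO_LABEL = {"S  1": "NT", "S  2": "ST", "S  3": "DT",
                 "S 1": "NT", "S 2": "ST", "S 3": "DT",
                 "S1": "NT", "S2": "ST", "S3": "DT"}


class FileFormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


# ---------------------------------------------------------------------------
# BrainVision


def write_brainvision(recording: Recording, vhdr_path: str | Path) -> Path:
    """Write a Recording as a BrainVision triplet (IEEE float32, multiplexed).

    ``vhdr_path`` names the header; the ``.vmrk`` and ``.eeg`` siblings are
    written next to it.  Returns the header path.
    """
    vhdr = Path(vhdr_path).with_suffix(".vhdr")
    vmrk = vhdr.with_suffix(".vmrk")
    eeg = vhdr.with_suffix(".eeg")

    n_ch = recording.n_channels
    header = [
        "BrainVision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={1e6 / recording.fs:.6f}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, lab in enumerate(recording.channel_labels, start=1):
        header.append(f"Ch{i}={lab},,1,µV")
    vhdr.write_text("\n".join(header) + "\n", encoding="utf-8")

    markers = [
        "BrainVision Data Exchange Marker File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,0",
    ]
    for k, (idx, lab) in enumerate(recording.events, start=2):
        code = MARKER_CODES.get(lab)
        if code is None:
            raise InvalidConfigurationError(f"no marker code for label {lab!r}")
        markers.append(f"Mk{k}=Stimulus,{code},{idx + 1},1,0")
    vmrk.write_text("\n".join(markers) + "\n", encoding="utf-8")

    recording.data.T.astype("<f4").tofile(eeg)
    return vhdr


def read_brainvision(vhdr_path: str | Path) -> Recording:
    """Read a BrainVision triplet into a Recording (via MNE).

    Stimulus markers S1/S2/S3 become NT/ST/DT events; other markers are
    ignored.  Missing sibling files or malformed headers raise
    :class:`FileFormatError`.
    """
    import mne

    vhdr = Path(vhdr_path)
    if not vhdr.exists():
        raise FileFormatError(f"header file {vhdr} not found")
    try:
        raw = mne.io.read_raw_brainvision(vhdr, preload=True, verbose="error")
    except Exception as exc:  # mne raises various types for format problems
        raise FileFormatError(f"cannot read {vhdr}: {exc}") from exc

    data = raw.get_data() * 1e6  # mne holds volts; we keep μV
    events = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        code = desc.split("/")[-1].strip()
        label = CODE_TO_LABEL.get(code)
        if label is not None:
            events.append((int(round(onset * raw.info["sfreq"])), label))
    return Recording(
        data=data,
        channel_labels=list(raw.ch_names),
        fs=float(raw.info["sfreq"]),
        events=events,
    )


# ---------------------------------------------------------------------------
# HDF5 container


def save_recording(recording: Recording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data, compression="gzip")
        f.attrs["fs"] = recording.fs
        f.attrs["kind"] = "recording"
        f.create_dataset(
            "channel_labels",
            data=np.array(recording.channel_labels, dtype=h5py.string_dtype()),
        )
        if recording.events:
            f.create_dataset("events", data=np.array([e[0] for e in recording.events]))
            f.create_dataset(
                "event_labels",
                data=np.array([e[1] for e in recording.events], dtype=h5py.string_dtype()),
            )
        f.attrs["annotations"] = json.dumps(recording.annotations)


def load_recording(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "recording":
            raise FileFormatError(f"{path} does not hold a recording")
        events = []
        if "events" in f:
            events = [
                (int(i), lab.decode() if isinstance(lab, bytes) else str(lab))
                for i, lab in zip(f["events"][()], f["event_labels"][()])
            ]
        return Recording(
            data=f["data"][()],
            channel_labels=[
                s.decode() if isinstance(s, bytes) else str(s)
                for s in f["channel_labels"][()]
            ],
            fs=float(f.attrs["fs"]),
            events=events,
            annotations=json.loads(f.attrs.get("annotations", "[]")),
        )


def save_epochs(epochs: EpochSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip")
        f.create_dataset("labels", data=np.array(epochs.labels, dtype=h5py.string_dtype()))
        f.create_dataset("times", data=epochs.times)
        f.attrs["fs"] = epochs.fs
        f.attrs["kind"] = "epochs"
        f.create_dataset(
            "channel_labels",
            data=np.array(epochs.channel_labels, dtype=h5py.string_dtype()),
        )
        f.attrs["rejection_log"] = json.dumps(epochs.rejection_log)


def load_epochs(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "epochs":
            raise FileFormatError(f"{path} does not hold an epoch set")
        return EpochSet(
            data=f["data"][()],
            labels=np.array(
                [s.decode() if isinstance(s, bytes) else str(s) for s in f["labels"][()]]
            ),
            times=f["times"][()],
            fs=float(f.attrs["fs"]),
            channel_labels=[
                s.decode() if isinstance(s, bytes) else str(s)
                for s in f["channel_labels"][()]
            ],
            rejection_log=json.loads(f.attrs.get("rejection_log", "[]")),
        )


# ---------------------------------------------------------------------------
# Pipeline configuration


@dataclass
class PipelineConfig:
    """Every knob of the full pipeline, serializable to YAML.

    All thresholds default to the published analysis values; simulation
    settings control the synthetic session when no input file is given.
    """

    # input
    input_vhdr: str | None = None
    seed: int = 0
    # simulation
    n_runs: int = 5
    n_total: int = 600
    ratios: tuple[float, float, float] = (0.75, 0.125, 0.125)
    ratio_tolerance: float = 0.02
    n_channels: int = 64
    sampling_rate_hz: float = 1000.0
    effects: str = "default"  # "default" | "null"
    # preprocessing
    target_fs: float = 100.0
    epoch_window: tuple[float, float] = (-200.0, 2000.0)
    erp_baseline: tuple[float, float] = (-100.0, 0.0)
    erd_baseline: tuple[float, float] = (-200.0, 0.0)
    flat_var_threshold: float = 0.5
    flat_trial_fraction: float = 0.10
    excess_channel_fraction: float = 0.20
    excess_mad_factor: float = 5.0
    minmax_threshold: float = 150.0
    # bands
    bands: dict = field(default_factory=lambda: {"alpha": [8.0, 14.0], "beta": [16.0, 20.0]})
    # decoding
    modalities: tuple[str, ...] = ("erp", "csp-alpha", "csp-beta")
    eog_control: bool = False
    n_folds: int = 10
    n_repetitions: int = 10
    zscore: bool = False
    nested: bool = True
    use_ssd: bool = True
    csp_window: tuple[float, float] = (350.0, 2000.0)
    max_csp_per_class: int = 3
    n_intervals: int = 5
    # output
    out_dir: str = "cogdepth_out"
    make_figures: bool = True

    def save(self, path: str | Path) -> None:
        def plain(obj):
            if isinstance(obj, tuple):
                return [plain(x) for x in obj]
            if isinstance(obj, list):
                return [plain(x) for x in obj]
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            return obj

        Path(path).write_text(yaml.safe_dump(plain(asdict(self))), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        cfg = cls(**raw)
        # YAML round-trips tuples as lists; normalize back
        for name in ("ratios", "epoch_window", "erp_baseline", "erd_baseline",
                     "csp_window", "modalities"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg
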