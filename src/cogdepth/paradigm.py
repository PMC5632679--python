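"""The three-level visual paradigm: stimulus sequences and behavioural counts.

Trials come in three classes — non-target (NT, no processing), shallow
target (ST, colour match: silently count +1) and deep target (DT, colour and
category match: count +1, evaluate the cognitive task and count a further
+10 on a positive answer).  Class ratios default to 75% / 12.5% / 12.5%,
presented in 5 runs of 120 stimuli (600 total) with a 2.5 s inter-stimulus
interval (500 ms fixation, 1250 ms stimulus, 750 ms relaxation).

Sequences are constructed with exact multinomial rounding and then shuffled
within runs, so the configured ratio tolerance (±2% by default) holds
structurally for every seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import CLASSES, InvalidConfigurationError

#: Default NT / ST / DT proportions.
DEFAULT_RATIOS = (0.75, 0.125, 0.125)
DEFAULT_TOLERANCE = 0.02
DEFAULT_N_RUNS = 5
DEFAULT_N_TOTAL = 600


class UndefinedRatioError(ZeroDivisionError):
    """The answers ratio is undefined when the correct count is zero."""


@dataclass(frozen=True)
class TimingConfig:
    """Trial timing in milliseconds and the acquisition sampling rate."""

    fixation_ms: float = 500.0
    stimulus_ms: float = 1250.0
    relax_ms: float = 750.0
    sampling_rate_hz: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("fixation_ms", "stimulus_ms", "relax_ms", "sampling_rate_hz"):
            if getattr(self, name) <= 0:
                raise InvalidConfigurationError(f"{name} must be positive")

    @property
    def isi_ms(self) -> float:
        """Inter-stimulus interval: fixation + stimulus + relaxation."""
        return self.fixation_ms + self.stimulus_ms + self.relax_ms

    @property
    def isi_samples(self) -> int:
        return int(round(self.isi_ms * self.sampling_rate_hz / 1000.0))


@dataclass
class StimulusSequence:
    """Ordered trial labels per run plus the DT task answers.

    ``dt_answers`` maps the global trial index of every DT trial to the
    boolean outcome of its yes/no cognitive task (positive → the participant
    counts a further +10).
    """

    runs: list[list[str]]
    dt_answers: dict[int, bool] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        flat = self.flat_labels()
        for lab in flat:
            if lab not in CLASSES:
                raise InvalidConfigurationError(f"unknown trial label {lab!r}")
        dt_idx = {i for i, lab in enumerate(flat) if lab == "DT"}
        if set(self.dt_answers) != dt_idx:
            raise InvalidConfigurationError("every DT trial needs exactly one answer flag")

    def flat_labels(self) -> list[str]:
        return [lab for run in self.runs for lab in run]

    @property
    def n_trials(self) -> int:
        return sum(len(run) for run in self.runs)

    def class_counts(self) -> dict[str, int]:
        flat = self.flat_labels()
        return {c: flat.count(c) for c in CLASSES}

    def class_proportions(self) -> dict[str, float]:
        n = self.n_trials
        return {c: k / n for c, k in self.class_counts().items()}


def _exact_counts(n_total: int, ratios: tuple[float, float, float]) -> list[int]:
    """Multinomial rounding: floor targets, then distribute the remainder by
    largest fractional part (ties by class order)."""
    raw = [n_total * r for r in ratios]
    counts = [int(np.floor(x)) for x in raw]
    remainder = n_total - sum(counts)
    frac_order = sorted(range(3), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in frac_order[:remainder]:
        counts[i] += 1
    return counts


def generate_stimulus_sequence(
    n_runs: int = DEFAULT_N_RUNS,
    n_total: int = DEFAULT_N_TOTAL,
    ratios: tuple[float, float, float] = DEFAULT_RATIOS,
    tolerance: float = DEFAULT_TOLERANCE,
    seed: int | None = None,
) -> StimulusSequence:
    """Generate a randomly ordered NT/ST/DT sequence with exact class counts.

    Counts are fixed by multinomial rounding of ``n_total * ratios`` and
    shuffled across the whole session before being split into ``n_runs``
    near-equal runs, so realized proportions deviate from the targets by at
    most one trial in ``n_total`` — always within the paradigm's ±2% band for
    the default 600-trial session.  DT answer flags are drawn Bernoulli(0.5).
    """
    if n_total < 1:
        raise InvalidConfigurationError("n_total must be at least 1")
    if n_runs < 1:
        raise InvalidConfigurationError("n_runs must be at least 1")
    if tolerance < 0:
        raise InvalidConfigurationError("tolerance must be non-negative")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise InvalidConfigurationError(f"ratios must sum to 1, got {sum(ratios)}")

    rng = np.random.default_rng(seed)
    counts = _exact_counts(n_total, tuple(ratios))
    for c, k, r in zip(CLASSES, counts, ratios):
        if abs(k / n_total - r) > tolerance + 1e-12:
            raise InvalidConfigurationError(
                f"{c} count {k}/{n_total} cannot meet ratio {r} within ±{tolerance}"
            )

    labels = np.repeat(np.array(CLASSES), counts)
    rng.shuffle(labels)

    # Split into runs of near-equal length (first runs take the extra trial).
    base, extra = divmod(n_total, n_runs)
    runs: list[list[str]] = []
    pos = 0
    for r in range(n_runs):
        size = base + (1 if r < extra else 0)
        runs.append([str(x) for x in labels[pos : pos + size]])
        pos += size

    flat = [lab for run in runs for lab in run]
    dt_answers = {i: bool(rng.integers(0, 2)) for i, lab in enumerate(flat) if lab == "DT"}
    return StimulusSequence(runs=runs, dt_answers=dt_answers, seed=seed)


def compute_correct_count(sequence: StimulusSequence) -> int:
    """The correct silent count for a sequence.

    Every ST or DT trial contributes +1 (colour match); a DT trial whose task
    answer is positive contributes a further +10. NT trials contribute 0.
    """
    total = 0
    for i, lab in enumerate(sequence.flat_labels()):
        if lab in ("ST", "DT"):
            total += 1
        if lab == "DT" and sequence.dt_answers[i]:
            total += 10
    return total


def answers_ratio(response: int, correct: int) -> float:
    """Behavioural error: |correct − response| / correct (0 = perfect)."""
    if correct <= 0:
        raise UndefinedRatioError("answers ratio undefined for correct count 0")
    return abs(correct - response) / correct
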