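"""Simulate a session of the three-level paradigm.

Builds a 600-stimulus sequence (75% non-targets, 12.5% shallow and deep
targets each), derives the correct silent count a perfect participant would
report, and renders 16-channel synthetic EEG with graded ERPs and α/β
desynchronization.
"""

import cogdepth as cd

seq = cd.generate_stimulus_sequence(n_runs=5, n_total=600, seed=1)
counts = seq.class_counts()
print(f"trials per class: {counts}")
print(f"class percentages: "
      f"{ {c: round(100 * k / seq.n_trials, 1) for c, k in counts.items()} }")

correct = cd.compute_correct_count(seq)
print(f"correct silent count for the session: {correct}")
print(f"answers ratio for a response of {correct - 12}: "
      f"{cd.answers_ratio(correct - 12, correct):.3f}  (0 = perfect)")

timing = cd.TimingConfig(sampling_rate_hz=200.0)
recording = cd.generate_continuous_eeg(seq, timing, n_channels=16, seed=1)
print(f"rendered {recording.n_channels} channels × {recording.n_samples} samples "
      f"({recording.duration_s:.0f} s at {recording.fs:g} Hz), "
      f"{len(recording.events)} stimulus markers")
# The recording can be exported for other toolboxes:
#   cd.write_brainvision(recording, "session.vhdr")
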