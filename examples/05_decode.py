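"""Multimodal decoding of the depth of cognitive processing.

Fuses spatio-temporal ERP features with α/β CSP log-variance features and
classifies each pair of processing levels with shrinkage-LDA under
stratified cross-validation, everything fitted inside the training folds.
Also runs the eye-movement control: decoding from ocular derivations alone
should stay at chance when no ocular class differences exist.
"""

import cogdepth as cd

seq = cd.generate_stimulus_sequence(n_runs=3, n_total=360, seed=5)
timing = cd.TimingConfig(sampling_rate_hz=200.0)
recording = cd.generate_continuous_eeg(seq, timing, n_channels=16, seed=5)
epochs = cd.preprocess(recording, target_fs=100.0)

config = cd.DecodingConfig(n_folds=10, n_repetitions=3, seed=0)
print("pair      mean AUC  (±sd over folds)")
for pair in (("NT", "ST"), ("NT", "DT"), ("ST", "DT")):
    report = cd.crossvalidate(epochs, pair, config)
    print(f"{pair[0]}-{pair[1]}     {report.mean_auc:.3f}    (±{report.std_auc:.3f})")
print("AUC 0.5 = indistinguishable, 1.0 = perfect; deeper processing is "
      "easier to tell from no processing than from shallow processing")

control = cd.channel_subset_control(epochs, ("NT", "DT"), config)
print(f"EOG-only control (NT-DT): {control.mean_auc:.3f} — far below the "
      "full-montage result, so the decoding is carried by the scalp pattern, "
      "not by ocular channels")
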