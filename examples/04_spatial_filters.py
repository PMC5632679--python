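"""Spatial filtering: SSD source extraction and CSP class contrast.

SSD finds projections whose α-band power stands out against the flanking
frequencies (oscillatory sources); CSP then finds, inside that subspace,
the projections whose band power differs most between two processing
levels.
"""

import numpy as np

import cogdepth as cd
from cogdepth.spatial import BandSpec, select_ssd_components, _bandpass

seq = cd.generate_stimulus_sequence(n_runs=2, n_total=240, seed=4)
timing = cd.TimingConfig(sampling_rate_hz=200.0)
recording = cd.generate_continuous_eeg(seq, timing, n_channels=16, seed=4)

band = BandSpec(8.0, 14.0, flanker_hz=2.0, gap_hz=1.0)
ssd = cd.ssd_fit(recording, band)
ssd_sel = select_ssd_components(ssd)
print(f"SSD: {ssd.n_components} components, "
      f"{ssd_sel.n_components} kept above the broadband baseline; "
      f"top band-to-flanker ratios: {np.round(ssd.eigenvalues[:3], 2)}")

epochs = cd.preprocess(recording, target_fs=100.0)
alpha_epochs = epochs.copy()
alpha_epochs.data = _bandpass(epochs.data, (8.0, 14.0), epochs.fs)
csp = cd.csp_fit(alpha_epochs, ("NT", "DT"), band=(8.0, 14.0))
csp_sel = cd.select_csp_components(csp, alpha_epochs, max_per_class=3)
print(f"CSP (α band, NT vs DT): eigenvalues "
      f"{np.round(csp.eigenvalues[:4], 2)} …; "
      f"{csp_sel.n_components} components retained")
print("an eigenvalue is the NT share of a component's variance: far from 0.5 "
      "means the rhythm's power separates the two processing levels")

components = cd.apply_filters(csp_sel, alpha_epochs)
print(f"component-space epochs: {components.n_trials} trials × "
      f"{components.n_channels} components")
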