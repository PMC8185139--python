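"""Extract the seven EEG node features from one 4 s segment.

Simulates one subject per group and compares the feature values of their
first segments: the less regular, noisier group should score higher on the
complexity entropies and lower on synchronization.
"""

import gazegraph as gg

spec_asd, spec_td = gg.default_group_specs()
for spec in (spec_asd, spec_td):
    rec = gg.simulate_eeg(spec, n_channels=8, duration_s=8.0, rate_hz=256.0, seed=3)
    seg = gg.segment_recording(rec, window_s=4.0)[0]
    feats = gg.extract_eeg_features(seg)
    print(f"\n{spec.label}:")
    for name, value in feats.as_dict().items():
        print(f"  {name:>12s} = {value: .4f}")

print(
    "\nmean_value tracks the DC offset knob; appr_en/samp_en/perm_en rise with"
    "\nthe broadband noise share; pcc_sync rises with the shared-driver"
    "\ncoupling; stft/wavelet entropies reflect how oscillation and noise"
    "\nshare the time-frequency plane."
)
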