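"""Compute SpO2 from a dual-wavelength (red/IR) PPG pair.

The generator builds two channels sharing beat times whose per-beat
ratio-of-ratios equals 0.6. With identity calibration (A=1, B=0) the median
SpO2 estimate recovers that ratio; with a realistic calibration line
(here A=-25, B=110) the same ratio maps to a saturation percentage.
"""

import ppgwave as pw

config = pw.SyntheticConfig(duration=60.0, hr_mean=72.0, noise_sd=0.005, seed=9)
red, ir, peaks = pw.generate_dual_channel(config, ratio=0.6)

features_red = pw.pulse_features(red, peaks)
features_ir = pw.pulse_features(ir, peaks)

identity = pw.compute_spo2(features_red, features_ir, pw.SpO2Params(A=1.0, B=0.0))
print(f"median ratio-of-ratios: {identity.median:.3f} (configured 0.600)")

calibrated = pw.compute_spo2(features_red, features_ir, pw.SpO2Params(A=-25.0, B=110.0))
print(f"median SpO2 with A=-25, B=110: {calibrated.median:.1f}% "
      f"over {len(calibrated.per_beat)} beats")
print("Each beat contributes R = (dI/I)_red / (dI/I)_ir from its "
      "peak-to-trough excursion and peak value; SpO2 = A*R + B.")
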