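"""Localize a simulated dipole with the scalar LCMV beamformer.

A band-limited source at a known voxel drives a radial-magnetometer helmet
through the Sarvas single-sphere forward model.  The beamformer scans a
7-voxel mini-grid; noise-normalized output power should peak at the true
voxel, and the reconstructed time-course should match the injected signal.
"""

from megbeta import experiments

res = experiments.beamformer_inverse_crime(seed=0)

print(f"true voxel index:      {res['true_voxel']}")
print(f"localized voxel index: {res['localized_voxel']}")
print(f"voxel time-course correlation with injected source: "
      f"{res['timecourse_correlation']:.6f}")
print(f"network (map-weighted, sign-aligned) correlation:   "
      f"{res['network_correlation']:.6f}")
print("correlation > 0.99 = the unit-gain spatial filter reconstructs the "
      "source up to scale")
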