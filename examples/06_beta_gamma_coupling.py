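"""Correlate an integrative beta curve with coupled visual gamma envelopes.

If the late integrative beta component coordinates remote processing, it
should co-vary with gamma amplitude in a sensory network.  Gamma envelopes
are simulated at a known coupling level; the analysis computes Pearson r
per gamma band over the 900 post-stimulus samples and Fisher-transforms it.
"""

import numpy as np

from megbeta import coupling, task, weibull

target_r = 0.4
curve = weibull.weibull_pdf(weibull.sample_times_ms(), 900.0, 3.0)
centers = [30.0, 35.0, 47.5, 55.0, 60.0, 65.0]

zs = []
for subject in range(24):
    gamma = task.simulate_coupled_gamma(curve, target_r, len(centers),
                                        seed=subject)
    recs = coupling.beta_gamma_correlation(curve, gamma, centers,
                                           subject=f"s{subject:02d}")
    zs.extend(r.z for r in recs)

print(f"target coupling r = {target_r}  ->  Fisher z = {np.arctanh(target_r):.4f}")
print(f"mean recovered z over {len(zs)} records: {np.mean(zs):.4f}")
print(f"recovered r (back-transformed): {np.tanh(np.mean(zs)):.4f}")
print("agreement within ~0.05 in z = the coupling estimator is unbiased")
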