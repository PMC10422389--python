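"""Simulate one synthetic walking trial and look at what the devices saw.

Builds the default gait model (71 kg adult, 0.26 m foot, 0.7 s stance,
double-hump GRF), samples the continuous pressure field on the platform and
insole grids, and prints the basic sanity quantities: the vertical-force
peak against the configured profile, and the heel-to-toe CoP progression.
"""

import numpy as np

import footkinetics as fk

model = fk.default_model(noise_sd=2.0, seed=7)
trial, gt = fk.simulate_trial(model)

platform_force = (trial.platform.frames.sum(axis=(1, 2))
                  * trial.platform.geometry.cell_area * 1000.0)
print(f"configured GRF peak : {gt.peak_force:7.1f} N "
      f"({model.profile.peak_bw():.3f} body weights)")
print(f"platform-sampled peak: {platform_force.max():7.1f} N "
      f"(grid discretization + sensor noise)")

cop = gt.total_cop_foot
print(f"CoP progression along the foot axis: {cop[0, 1] * 100:.1f} cm (heel) "
      f"-> {cop[-1, 1] * 100:.1f} cm (toe) over {model.stance_duration:.2f} s")
print(f"saturated sensel samples: platform {int(trial.platform.saturated.sum())}, "
      f"insole {int(trial.insole.saturated.sum())}")
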