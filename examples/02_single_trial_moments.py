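"""Process one trial into joint-moment curves and compare with ground truth.

Runs the full pipeline on a noiseless synthetic trial — stance detection,
marker filtering, cell segmentation by joint-center location, cross-product
moments, body-mass normalization, resampling to % stance — and prints each
joint's peak dorsiflexion moment next to the continuous-field truth.
"""

import numpy as np

import footkinetics as fk

model = fk.default_model(noise_sd=0.0)
trial, gt = fk.simulate_trial(model)
tc = fk.process_trial(trial, "platform")

onset, offset = tc.stance
print(f"stance: frames {onset}..{offset} "
      f"({(offset - onset + 1) / model.rate:.2f} s)\n")
print(f"{'joint':6s} {'peak DF (N·m/kg)':>18s} {'truth':>8s} {'TMax %':>7s} {'truth':>6s}")
for joint in ("ankle", "MT", "MP"):
    got = tc.moments[joint].dfpf
    ref = gt.moment_curves[joint].dfpf
    print(f"{joint:6s} {got.max():18.3f} {ref.max():8.3f} "
          f"{np.argmax(got):7d} {np.argmax(ref):6d}")
print("\nThe pipeline works from 1 cm pressure cells; the truth from the")
print("continuous field. Peak values agree to a fraction of a percent and")
print("peak timing to a couple of %-stance points.")
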