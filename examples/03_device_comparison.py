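"""Compare platform- and insole-derived moments on the same simulated walk.

An in-shoe insole captures only part of the foot's contact load; scaling
its field by 0.9 emulates that incomplete capture.  The pipeline then sees
a ~10 % lower ankle peak moment from the insole — the kind of systematic
device difference a paired-device study is designed to quantify.
"""

import footkinetics as fk

model = fk.default_model(noise_sd=0.0)

for bias in (1.0, 0.9):
    tp, ti = fk.make_device_pair(model, insole_bias=bias)
    peak_p = fk.process_trial(tp, "platform").moments["ankle"].dfpf.max()
    peak_i = fk.process_trial(ti, "insole").moments["ankle"].dfpf.max()
    print(f"insole bias {bias:.1f}: platform {peak_p:.3f} N·m/kg, "
          f"insole {peak_i:.3f} N·m/kg "
          f"-> difference {100 * (peak_p - peak_i) / peak_p:+.1f} %")
print("\nWith no bias the two grids sample one field and differ only by")
print("discretization; a 0.9 field scale surfaces as a ~10 % peak deficit.")
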