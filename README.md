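# footkinetics

Multisegment in-shoe foot kinetics from plantar-pressure grids.

Clinical gait labs want joint moments not just at the ankle but at the
midtarsal (MT) and metatarsophalangeal (MP) joints, and they want them for
*shod* walking, where orthoses and footwear act. Force plates only give the
total ground reaction at one center of pressure (CoP), so they cannot split
load between foot segments. Pressure grids can: every sensel has a known
location, so each cell's load can be assigned to the segment it acts on.
`footkinetics` implements that pipeline for two complementary sensors — a
ground pressure platform (fixed in the lab frame) and an in-shoe instrumented
insole (fixed in the foot frame) — and the statistics needed to ask whether
the two devices are interchangeable.

## What it computes

For each stance phase, with pressure `p_i` (kPa) on cells of area `A_i` at
locations `r_i`:

- **Resultant and CoP** per frame: `F = Σ p_i A_i`, `cop = Σ p_i A_i r_i / F`
  (normal component only — grids do not sense friction).
- **Segmented forces**: each active cell is assigned to hindfoot, forefoot
  or hallux by comparing its coordinate along the foot's anteroposterior
  axis (markers C1→H2) with the ankle, MT and MP joint-center coordinates,
  re-evaluated every frame. Cells distal to a joint load that joint.
- **Insole registration**: the insole grid is placed into the lab frame by
  one rigid transform — rotation from the foot progression angle,
  translation matching the insole and platform CoPs 0.1 s after initial
  contact.
- **External joint moments**: `M = (cop − jc) × F` with `F = (0, 0, ΣpA)`,
  expressed in the proximal segment's frame (segment weight and inertia
  neglected), zero-phase Butterworth filtered, divided by body mass
  (N·m/kg) and resampled to 101 points over 0–100 % stance.
- **Curve descriptors and reliability**: MaxVal/TMax (and MinVal/TMin) per
  curve; mean ± 95 % CI group curves; a long-format parameter table (one
  row per subject × shoe × device × trial per descriptor); and two-way
  mixed-effects, mean-rating intraclass correlations, both consistency
  ICC(3,k) and absolute agreement ICC(2,k).

A synthetic generator (`footkinetics.synthetic`) builds complete trials —
markers plus both pressure streams sampled from one continuous pressure
field — with exact 1 mm-quadrature ground truth for every stage, so the
whole pipeline is testable without laboratory data.

## Worked example

```python
import footkinetics as fk

model = fk.default_model(noise_sd=0.0)        # 71 kg, 0.26 m foot, 0.7 s stance
trial, gt = fk.simulate_trial(model)          # markers + platform + insole
tc = fk.process_trial(trial, "platform")      # full kinetics pipeline
for joint in ("ankle", "MT", "MP"):
    print(joint, round(tc.moments[joint].dfpf.max(), 3),
          round(gt.moment_curves[joint].dfpf.max(), 3))
```

prints

```
ankle 1.376 1.375
MT 0.839 0.84
MP 0.163 0.163
```

— the peak dorsiflexion moment per joint (N·m/kg) recovered from 1 cm
pressure cells next to the continuous-field truth: ankle loads hardest,
the MP joint least, with agreement to a fraction of a percent. The scripts
in `examples/` walk through simulation, single-trial processing, the
device-bias experiment (a 0.9 insole field scale surfaces as a ~10 % ankle
peak deficit) and a full repeated-measures design with ICC tables; each
prints what its numbers mean. A thin CLI (`footkinetics simulate/process/
compare/icc`) wraps the same functions for directory-level batch runs.

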