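# Methods

## The measurement problem

A multisegment foot model needs, at every instant of stance, the external
load acting *distal* to each joint. Force plates cannot provide this: they
report one resultant at one center of pressure. A pressure grid can,
because every sensel has a known position, so its load can be attributed to
the hindfoot, forefoot or hallux. Two grid types are supported and
deliberately treated symmetrically:

- a **ground platform** (default 1 sensel/cm², 4–1000 kPa), fixed in the
  laboratory frame, measuring shoe-sole-to-ground contact;
- an **in-shoe insole** (default ≈3.9 sensels/cm² at 5.06 mm pitch,
  4–862 kPa), fixed in the foot frame, measuring foot-to-shoe contact.

Both sense only the normal pressure component. All friction-related terms
are therefore outside the model (see Limitations).

## Pipeline model and assumptions

**Frames and conventions.** The laboratory frame has +Y anterior, +X
lateral-medial, +Z up, origin at the platform center. Segment frames are
right-handed with local y along the segment long axis, z up, x the
flexion axis; they are built from configurable marker recipes (hindfoot
from C1→H2 with the MC/LC malleolar pair; forefoot from the metatarsal
base/head pairs; hallux from the MP line toward HX with global-up
reference; shank from four shank markers). Joint centers are midpoints of
medial/lateral marker pairs: ankle = (MC, LC), MT = (NV, CU),
MP = (H1, H3). All recipes are swappable per lab because multisegment
marker sets vary; the defaults are conventional for this model family.

**Kinematics.** Joint angles are intrinsic Cardan angles of the distal
relative to the proximal segment in the order dorsiflexion/plantarflexion
→ abduction/adduction → inversion/eversion (x–z–y), computed with
`scipy.spatial.transform.Rotation` and zeroed at the upright static
reference. Gimbal proximity (|second angle| within 1e-6° of 90°) is
flagged with the third angle conventionally 0. Marker trajectories are
low-pass filtered at 10 Hz before any frame construction.

**Stance and segmentation.** Stance is the longest run of total force
above max(10 N, 1.5 % body weight) lasting ≥ 3 frames; stances shorter
than 0.2 s reject the trial. Cells are segmented by their scalar
coordinate along the foot's anteroposterior axis — the ground-plane
C1→H2 direction, not global Y, so the rule is invariant to toe-out; a
`global_y` fallback is configurable. Joint-center coordinates are
projected onto that axis at every frame. Intervals are half-open with the
boundary cell assigned to the distal segment, which makes the partition
deterministic and exhaustive: distal(MP) = hallux cells,
distal(MT) = hallux + forefoot, distal(ankle) = all.

**Registration.** The insole grid is mapped into the laboratory frame by a
single planar rigid transform: rotation = the foot progression angle at
the matching instant (so the grid's long axis lands on the foot axis),
translation chosen so the insole CoP coincides with the platform CoP at
that instant. The matching instant is onset + round(0.1 s × rate). The
transform is held constant over stance: the stance foot is quasi-static on
the ground, and re-registering after heel-off would require a reference
the platform no longer provides once load moves to the toes.

**Moments.** With only normal forces available, the external moment about
a joint center jc is `M = (cop₃ − jc) × (0, 0, F)` with the CoP lifted to
the ground plane z = 0, expressed in the proximal segment frame
(`Rᵀ M_global`). Segment weight, inertia and angular acceleration are
neglected — at the foot these terms are small against the contact moment.
Shoe-sole thickness is *not* added to the moment arm for either device:
one common geometric treatment keeps the devices comparable, at the cost
of treating the insole as if it sensed at ground level (a documented
comparability caveat, not an oversight). Both devices therefore differ
only in what they sense, not in how they are processed.

**Normalization.** Moments are divided by body mass (N·m/kg — the unit
convention of this literature; "body-weight normalization" here means
mass, not weight in newtons) and linearly resampled to 101 stations over
0–100 % stance, endpoints exact.

**Filtering.** All filters are fourth-order Butterworth applied
forward-backward (`sosfiltfilt`, even-reflective padding of 3 × order).
Zero phase matters: a causal filter would shift peak times, and peak
timing (TMax/TMin) is a primary outcome. The double pass squares the
magnitude response, so the gain at the nominal cutoff is 0.5. The kinetic
cutoff defaults to 50 Hz; at a 100 Hz sampling rate that sits exactly at
Nyquist, where a digital Butterworth is undefined, so the cutoff is
clipped to 0.95 × Nyquist (47.5 Hz) with a logged warning. At these
sampling rates the clipped filter is effectively transparent for smooth
gait signals; the cutoff is configurable for higher-rate recordings.

**Curve statistics.** Each 101-point curve is summarized by MaxVal/TMax
and MinVal/TMin (first occurrence on ties; curves are smoothed, so ties
are practically measure-zero). Group curves average trials within subject
first, then subjects, with a t-based 95 % CI (`mean ± t₍ₙ₋₁₎ sd/√n`) —
subjects are the sampling unit and n = 10 is small, so a normal quantile
would understate the ribbon. Sagittal curves are compared on MaxVal/TMax,
frontal curves on MinVal/TMin (the eversion peak is a minimum);
transverse (ab/adduction) moments are computed but excluded from
comparison reports because their amplitudes are negligible throughout
stance.

**ICC.** Intraclass correlations come from the two-way ANOVA mean
squares: consistency ICC(3,k) = (MS_R − MS_E)/MS_R and absolute agreement
ICC(2,k) = (MS_R − MS_E)/(MS_R + (MS_C − MS_E)/n), with
F = MS_R/MS_E on (n−1, (n−1)(k−1)) df for significance. Two rating
layouts are exposed, because "a rating" is genuinely ambiguous in a
paired-device repeated-trials design: the default device-agreement report
uses the k = 2 devices as raters on subject × shoe × trial targets; the
test-retest report uses the k = 5 repeated trials as ratings per
subject × shoe target within one device. The implementation is
cross-checked in the test suite against longhand sums-of-squares and
against `pingouin.intraclass_corr`.

## The synthetic generator

`synthetic.GaitModel` defines one continuous plantar-pressure field

    p(x, y, t) = F(t) · Σₖ wₖ(t) · φₖ(x, y)

- `F(t)`: a double-hump vertical GRF — peaks 1.10 and 1.05 body weights at
  25 % and 75 % stance with a ≈0.8 BW valley, smooth compact-support edge
  ramps — the standard walking shape; stance 0.7 s at 100 Hz.
- `φₖ`: unit-mass 2-D Gaussian blobs under the heel, metatarsal heads and
  hallux, **truncated at 3σ and renormalized**. Truncation gives compact
  support (a blob strictly posterior to a joint line contributes exactly
  zero distal force — needed for exact construction guarantees) and is
  symmetric, so each blob's centroid stays at its center and the total
  continuous CoP is closed-form: Σₖ wₖ μₖ. That closed form is what the
  registration tests use as the "noiseless continuous CoP".
- `wₖ(t)`: clamped-smoothstep ramps shifting load heel → metatarsals →
  hallux, exactly 0/1 outside their transition windows (same
  compact-support rationale); normalized to sum to 1.
- Markers sit on a rigid planted foot (0.26 m, joint lines at 0.25/0.45/
  0.75 of foot length — standard adult proportions) posed by a planar
  rigid transform (progression angle ≈7°, position on the platform); the
  shank pitches −10°→+20° over stance to emulate tibial progression.
  Subject draws for design simulation follow the study cohort (mass
  71 ± 12 kg) with smaller within-subject trial jitter.
- Both grids sample the same field; the insole field can be scaled by a
  multiplicative `insole_bias` to emulate the insole's incomplete capture
  of contact forces. Additive Gaussian sensor noise (default 2 kPa) is
  applied to loaded sensels, then range conditioning (clip at p_max with
  saturation flags, zero below the 4 kPa sensing floor). All randomness
  flows from one integer seed; output is bitwise reproducible.

**Ground truth** integrates the field by quadrature on a 1 mm grid
(per-blob region masses precomputed once, since blobs are static in the
foot frame), then applies the *same* marker-derived frames, conventions,
normalization and resampling as the pipeline. Ground truth is therefore
independent in what the pipeline is being tested on — grid sampling,
range conditioning, stance detection, segmentation, registration — while
sharing the coordinate conventions, which is exactly the comparison one
wants.

**What passing tests do and do not show.** The generator emulates a rigid
planted foot, a smooth three-blob pressure field and ideal
synchronization. Real data add soft-tissue and shoe-deformation marker
artifact, non-rigid foot segments, pressure patterns with more structure
(individual metatarsal heads, lateral arch), insole slippage and
crosstalk, and imperfect device synchronization. Recovery of ground truth
here validates the *algorithms* (segmentation, registration, moments,
statistics), not the measurement fidelity of any physical sensor.

## Numerical choices

- Degenerate inputs: all-zero pressure frames yield zero force with a
  flagged (NaN) CoP; empty distal cell sets yield zero moment; coincident
  joint-center markers warn and return the common point; collinear frame
  markers raise a degenerate-geometry error.
- Missing marker samples are NaN-flagged, never silently interpolated;
  linear gap filling is available explicitly (`gap_fill`, max 10 frames).
- Resampling endpoints are reproduced exactly; curve peak ties resolve to
  first occurrence.
- Round-trips through the native CSV/JSON formats preserve floats to
  better than 1e-12 relative (`%.17g` formatting).
- Simulated problem sizes: the shipped study design is 10 × 2 × 2 × 5
  (200 walks, 400 device trials) on the 1 cm/5.06 mm default grids, which
  processes in a few seconds; ground-truth quadrature uses a 1 mm step.

## Known limitations

- Friction forces and free torque are not measured by either device and
  are excluded from the moments; sagittal peaks are consequently lower
  than force-plate-based values.
- The insole registration is a single rigid transform per stance; foot
  deformation after heel-off is not re-tracked.
- Segment inertia and weight are neglected (external contact moments
  only).
- The generator's foot is rigid: joint-angle outputs on synthetic data
  exercise the math, not physiological ranges of motion.
- C3D reading requires the optional `ezc3d` dependency; TRC/CSV are the
  native formats.
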