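# Methods

This note documents the model, the numerical choices, and what the
synthetic cohorts do and do not establish.

## Model and assumptions

The pipeline models the implanted electrode array as a time-varying
weighted network and assumes that epileptogenic tissue is distinguished
by a *transient rise in network centrality* spanning the seizure: EZ
electrodes are unremarkable before onset, become the most central nodes
mid-seizure as they recruit other regions, and recede after offset.
Everything downstream of the raw voltages is built to expose exactly
this signature:

- Connectivity is the **magnitude cross-power restricted to the gamma
  band (30–90 Hz)**, the band with the strongest seizure-related power
  modulation. No phase, coherence normalization, or directionality is
  used; consequently the adjacency is symmetric and nonnegative by
  construction, and eigenvector centrality is well defined with a
  nonnegative Perron vector.
- Ranking the EVC within each window discards amplitude information on
  purpose: only the *ordering* of electrodes is assumed comparable
  across windows, seizures, and patients.
- The normalization chain (500-point time base, divide by electrode
  count, divide by area) turns each rank trajectory into a density on
  [0, 1], so recordings with different durations and electrode counts
  live in one feature space. The decile feature vector is a coarse,
  monotone summary of where that density's mass sits in normalized
  time; an ictal centrality arch shifts interior deciles toward the
  middle of the clip.
- The likelihood surface assumes EZ-like signatures form one cluster
  in the 2D PC space, modeled as a single origin with per-quadrant
  Gaussian falloff. This is deliberately low-capacity: four 2×2
  covariances and one origin, trainable from tens of patients.

## Parameters

| Parameter | Default | Units | Notes |
|---|---|---|---|
| notch stop band | 59.5–60.5 | Hz | order-4 Butterworth, forward–backward; configurable for 50 Hz mains |
| clip padding | 60 | s | analysis clip is onset − 60 s … offset + 60 s, truncated with a warning at record edges |
| band | 30–90 | Hz | inclusive DFT-bin range; rectangular (no taper) window |
| window / hop | 2.5 / 1.0 | s | one network per second |
| signature length | 500 | samples | fixed normalized time base |
| features | 10 | — | decile locations, nondecreasing in [0, 1] |
| decay α₁..α₄ | 1.0 | — | per-quadrant exponential decay; no principled prior value exists, so they default to 1 and are configurable |
| origin grid | 100 × 100 | — | candidate origins at cell centers of the training scores' bounding box expanded by 10% |
| likelihood threshold α | 0.9 | — | 0.3/0.6/0.9 supported; separation between outcome groups grows with α |

Any global scaling of the adjacency (spectral normalization constants,
taper energy) cancels in the EVC ranking, which is verified by a scale
invariance test.

## Numerical choices

- **Cross-power quadrature**: the band integral is a bin sum times the
  bin width, endpoints inclusive. The diagonal (self-power) is zeroed
  before centrality — self-power carries no inter-electrode
  information — with a flag to retain it.
- **Eigenvector sign and degeneracy**: the leading eigenvector's
  largest-magnitude entry is made positive; eigensolver noise below
  zero is clipped and the vector renormalized. An all-zero adjacency
  (flat segment) maps to the uniform vector with eigenvalue 0 rather
  than propagating NaNs.
- **Rank ties** are broken by ascending channel index, so ranks are
  always a permutation and runs are bit-reproducible.
- **Resampling**: stretching uses linear interpolation; shrinking uses
  `round(linspace)` index decimation without anti-aliasing, matching a
  plain downsampling of the rank sequence.
- **Integrals** use the trapezoid rule on the uniform 500-point grid
  (exact for piecewise-linear signals); decile locations are
  interpolated linearly inside a grid cell rather than snapped to the
  grid, removing a 1/500 quantization artifact.
- **Quadrant boundaries**: membership on a boundary goes to the
  smallest-index quadrant (counterclockwise from upper-right); the
  convention is measure-zero but fixed for determinism.
- **Covariance degeneracy**: quadrants with fewer than 3 training
  points fall back to the pooled covariance; a ridge of 1e-6 × mean
  variance (escalated tenfold until positive-definite) guards the
  inverse.
- **Origin search** is a deterministic argmax over the grid in
  row-major order (first maximum wins); per-candidate covariances are
  re-fit on the training fold only. The search objective is the mean
  per-seizure held-out DOA under leave-one-patient-out folds, computed
  with closed-form 2×2 algebra for speed and checked in tests against
  the public covariance/weight routines.
- **Rank-sum test**: exact null when the combined sample is ≤ 20 and
  tie-free, otherwise the tie- and continuity-corrected normal
  approximation.
- **Degenerate min–max scaling** (a center with all-equal values) maps
  to 0.

## Design decisions that were genuinely open

- **Full-clip vs. ictal-only signatures.** The normalization can be
  read as applying to the seizure epoch alone or to the whole padded
  clip; the arch signature as described spans pre-ictal, ictal and
  post-ictal phases, so the default normalizes the full clip and
  records the onset/offset positions on the normalized axis. An
  `ictal` mode exists; models refuse to mix modes between training and
  inference.
- **One shared origin.** The four quadrant means are tied to a single
  trained origin rather than optimized independently; the quadrant
  picture is of one peak with direction-dependent falloff, and a
  four-fold origin search would square the search space for marginal
  capacity.
- **Fold aggregation.** The leave-one-patient-out objective averages
  per-seizure DOA across all held-out seizures (each patient
  contributes equally when seizure counts are equal, as in the
  synthetic cohorts).
- **CAR over retained channels only.** Artifact channels are excluded
  from the reference average as well as from analysis, since a bad
  channel inside the reference would leak its artifact into every
  channel.
- **EDF writing.** Recordings are persisted as plain 16-bit EDF with
  1-second records via a minimal writer in this package; reading goes
  through MNE, which also serves as the independent reader in the
  round-trip test. Quantization to the per-channel 16-bit range is the
  usual EDF precision loss.

## Synthetic cohorts: what they emulate and what they don't

`synthetic_data` emulates the *structure* the method keys on, at the
study's scale: ~76–92 channels at 1 kHz, 60 s pre-ictal, 120 s ictal,
60 s post-ictal, planted EZ sizes of 5–12 electrodes, two seizures per
patient, and outcome labeling where successful cases annotate the truly
seizing channels and failed cases annotate a disjoint set
(mislocalization) or carry no planted source at all (no coverage).
Channels carry independent unit-RMS 1/f noise; a single shared
bandpassed (30–90 Hz) gamma source is injected into EZ channels with a
raised-cosine envelope peaking mid-ictal at 6× the noise RMS, and into
the remaining channels at 0.5× (ictal recruitment). The smooth envelope
produces the gradual rank rise/fall of the arch without switching
artifacts, and equal-power noise keeps pre-ictal ranks exchangeable.

Not emulated: biophysical seizure dynamics (neural mass models),
electrode geometry and volume conduction, multiple independent seizure
foci, inter-center hardware differences, high-frequency oscillations,
artifacts and bad channels, or annotation noise on onset/offset. A
passing recovery experiment therefore shows that the pipeline detects
transient shared-source centralization against 1/f background at
realistic channel counts and SNR — not that it localizes clinical EZ
in real patients.

## Problem sizes used in the shipped experiments

The packaged recovery experiment uses a 16-patient cohort (8 success,
8 failure; two seizures each; seed 7), trains the origin on 8 patients
with the full 100 × 100 grid and evaluates the held-out 8, all at the
default window, band and threshold settings. Unit tests exercising the
generator's rank-shift behavior use 16-channel, 35-s clips over 20
seeds, since the injection mechanism is size-free.

## Known limitations

- The origin search optimizes agreement with annotations that are
  themselves wrong for failed patients; it works because successes
  dominate the gradient of the objective, but a cohort of mostly
  failures would mistrain the surface.
- With the low-capacity surface and α = 0.9, held-out success DOA is
  modest and some seizures yield an empty prediction (scored 0); this
  mirrors the intended conservative reading of a high threshold.
- Decile features are invariant to the *amplitude* of the arch beyond
  its effect on mass placement; two channels with differently sized but
  identically timed arches are indistinguishable.
- The exact rank-sum null is only used for small tie-free samples;
  heavily tied small samples fall back to the corrected normal
  approximation.
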