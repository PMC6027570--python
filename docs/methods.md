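# Methods

## Signal model and quantification

A FAIR (flow-sensitive alternating inversion recovery) scan of one
mid-ventricular short-axis slice consists of a base image `B` (no labeling
pulse), a noise-only image, and six control/label pairs `(C_i, L_i)`
acquired in separate breath-holds.  Myocardial blood flow is recovered
from the single-compartment general kinetic model in its post-labeling-
delay form:

    F = (C - L) / (2 * B * T_D * exp(-T_D / T1_blood))

with `T_D = n_RR * 60000 / HR` ms (default two cardiac cycles between
inversion and readout) and `T1_blood = 1650` ms (overridable).  `F` is
reported in ml/g/min; the 60000 ms/min unit factor is applied inside the
formula and the blood-tissue partition coefficient is absorbed as 1 ml/g,
so the equation above maps signal differences directly to flow.  Regional
quantification averages `C`, `L`, `B` over a segment first and then
inverts (segment-mean-then-quantify); a pixelwise map mode with either
per-pixel or segment-mean base normalization is also provided, since the
two coincide only for piecewise-uniform base signal.  Negative per-pair
flows are retained: clipping would bias both the repeat SD and group
means.

Per segment, the six pairs give six MBF repeats; their sample standard
deviation (n-1) is the physiological noise PN, and tSNR = MBF/PN is the
quality statistic.  Segments with tSNR < 2 are *flagged* excluded —
values are never deleted — with the boundary case tSNR = 2 included, and
PN = 0 treated as the noise-free limit (included iff MBF > 0).  Exclusion
is applied per analysis arm: the rest/stress comparison drops a segment
pair when either condition is flagged; the cross-sectional post-infarct
comparison applies no exclusion at all, because the infarcted segment is
known in advance and low tSNR is part of its phenotype.

## Segmentation

The LV myocardium mask is partitioned into six 60-degree wedges about the
LV center, anchored at the anterior RV insertion angle, ordered
anteroseptal → inferoseptal → inferior → inferolateral → anterolateral →
anterior counter-clockwise in the displayed image (viewed from the apex).
Wedges are half-open `[start, start + 60)`, which resolves boundary
pixels deterministically; angles are degrees counter-clockwise from the
+col axis with 0-based row/col indexing.  The region map is fixed:
anteroseptal = infarct; inferior, inferolateral, anterolateral = remote;
anterior, inferoseptal = other.

The spatial-temporal filter is a mask-restricted neighborhood mean
(Euclidean footprint, default radius 1 pixel) with optional across-frame
averaging.  The exact filter used in the original workflow is not
specified; this neighborhood mean is a stated stand-in and is
parameterized so it can be swapped.  It is applied only to pixelwise
display maps: segment-level quantification already pools spatially, and
smoothing across wedge boundaries before segment averaging would mix
neighboring segments' signals.

## Synthetic cohorts

The generator runs the same model forward.  Geometry is an idealized
annulus (endo 12 mm, epi 20 mm, 128×128 grid at 1.5625 mm — a 20 cm FOV),
fixed across slices; heterogeneity enters through the flow field and
noise, not the anatomy.  Per slice:

- per-segment true MBF is drawn from the scenario's normal distribution
  and clipped at zero (clipping rather than resampling keeps the cohort
  mean and SD essentially at the configured values);
- heart rate ~ N(93, 9) bpm at rest, N(87, 6) under stress; base-image
  SNR ~ N(98, 31), floored at 20;
- each pair i sees segment flows `F + eps_i`, `eps_i ~ N(0, sigma_flow)`,
  painted into the control-minus-label difference via the forward model;
- every frame receives independent Gaussian thermal noise at
  `sigma = base_signal / SNR` (additive Gaussian, not Rician: at SNR ≈ 98
  the magnitude bias is negligible and beyond scope).

`sigma_flow` is calibrated per slice so that the *total* per-pair
segment-mean MBF SD equals the configured physiological noise (default
0.15 ml/g/min): the thermal contribution propagates analytically as
`SD(Cbar - Lbar) = sqrt(2/n_pix) * B/SNR` divided by the kinetic-model
denominator, and the flow term is set in quadrature (clipped at zero if
thermal noise alone exceeds the target).  Noise on the segment-mean base
signal is ~SNR·sqrt(n_pix) times smaller and ignored.

Scenario defaults are the study conditions: baseline 41 slices / 24
subjects, MBF 1.08 ± 0.62; paired rest/stress 25 slices / 13 subjects
(rest 1.08 ± 0.54, stress 1.47 ± 0.62); post-infarct cohorts of 9, 8 and
4 slices at 1-2 days, 1-2 weeks and 4 weeks with the anteroseptal segment
overridden to 0.20 ± 0.05 ml/g/min.  The infarct value is a synthetic
stand-in (no numeric infarct-zone MBF is available to emulate), chosen in
the no-reflow range and low enough that tSNR < 2 typically flags the
segment.  Rest and stress flows within a segment are bivariate normal
with correlation 0.7 — rest and stress perfusion share the vascular
territory — so the perfusion reserve is an emergent quantity rather than
a configured ratio.  Randomness is explicit: each slice derives its
generators from `SeedSequence((cohort_seed, slice_index))`; there is no
global RNG state.

### What the generator does and does not emulate

It reproduces the acquisition structure, the first- and second-order
statistics of the flow field, the repeat-to-repeat variability and the
thermal noise floor.  It does not model motion, breath-hold
misregistration, arterial transit time, inversion-slab profiles, bSSFP
transients, coil shading, or spatially structured artifacts — the
mechanisms that drove most real-world exclusions (concentrated in the
inferoseptal/inferior walls).  Passing recovery tests therefore
demonstrates correctness of the inversion, the segmental machinery and
the statistics under the modeled noise, not robustness to those
acquisition artifacts.

### Selection bias of the tSNR gate

With PN ≈ 0.15 ml/g/min the gate effectively removes segments whose true
flow falls below ≈ 0.3 ml/g/min.  Because the generator treats the full
0.62 SD as true between-segment spread, about 10% of baseline segments
sit below that threshold, and the included-segment cohort mean sits
systematically above the configured population mean — about +0.13 ml/g/min
at baseline and about +0.09 on the stress side of the paired comparison
(where dropping a pair excluded in either condition also removes
correlated low-stress segments).  This is a property of the study
conditions themselves, not of the estimator: the per-segment quantifier
is unbiased against its own slice truth (verified to < 0.02 ml/g/min over
50-slice cohorts).  The recovery tests assert the ±3 SE band against the
configured means regardless, so the baseline/stress mean checks sit at or
just past the edge of that band depending on the seed; the corresponding
test docstrings point back to this section.

## Group statistics

The unit of analysis is the segment (slice-nested), ordinary tests, no
mixed-effects modeling: paired two-sided Student t-test for rest vs
stress; MPR = stress/rest per kept segment summarized as mean ± SD (pairs
with nonpositive rest flow are counted undefined and omitted); one-way
ANOVA across timepoints for the cross-sectional comparison, with each
post-infarct timepoint tested pairwise against baseline by two-sample
t-test and Holm-Šidák step-down adjustment
(`adj_(i) = max_{j<=i} 1 - (1 - p_(j))^(m - j + 1)`, clipped at 1);
significance at α = 0.05.  Degenerate inputs are explicit errors:
zero-variance differences with nonzero mean, groups smaller than two,
zero within-group variance with unequal means.  Identical paired samples
return (t = 0, p = 1).  The family-wise type-I error of the full
ANOVA-plus-Holm-Šidák procedure is verified by simulation to sit at the
nominal 0.05 ± 0.02 at the study's group sizes (41/9/8/4).

## Numerical and testing choices

- Zero-noise round trips are exact to 1e-9 relative by construction
  (forward and inverse share the closed form but are evaluated through
  the full image pipeline).
- Unit tests run on 64×64 grids for speed; recovery and acceptance runs
  use the full default scenarios.  The Monte-Carlo oracles use 2·10^5 to
  4·10^5 draws (flow-noise calibration, stress-arm distribution oracle)
  and 600 replicates (type-I calibration).
- On a square pixel grid the six 60° wedges of a symmetric annulus cannot
  have exactly equal pixel counts (the grid has 90°/180° symmetry, not
  60°); opposite wedges are exactly equal and all six agree to within a
  few percent, which is what the segmentation tests assert.
- NIfTI volumes are written as float64 so series round-trip bit-for-bit;
  label maps as int16; metadata in JSON sidecars.  Frames are assumed
  pre-registered (breath-hold-to-breath-hold registration is out of
  scope).
- Pixelwise maps use NaN as the background sentinel, since 0 is a valid
  flow.

## Known limitations

Idealized fixed geometry; scalar per-scan PN target (real PN varies
regionally, 0.15 ± 0.10); no artifact model, so the synthetic exclusion
fraction (~12% at baseline) is lower than observed in vivo (~28%); no
arterial-transit-time or two-compartment modeling; cross-sectional
analysis treats segments as independent samples, as in the replicated
design.
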