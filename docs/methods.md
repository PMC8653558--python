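# Methods

This note documents the models, numerical choices and assumptions behind
`discdegen`: what each measurement computes, what the synthetic generator
emulates (and does not), and where the design was genuinely open.

## Study layout

The encoded design is a five-level rabbit lumbar experiment: within each
animal, L1–L2 receives a 10 µl contrast-agent (CA) injection, L2–L3/L3–L4/
L4–L5 receive 0.01/0.1/1.0 mg of monosodium iodoacetate (MIA) in 10 µl CA,
and L5–L6 is left untouched as the non-injected (NI) normalisation
reference. Cohorts of six animals reach endpoints at 2, 4, 8 and 12 weeks;
within each cohort three animals are assigned to micro-CT and three to MRI
(a deterministic convention — animals 1–6 are the week-2 cohort, the first
three of each cohort the micro-CT arm), with all discs available to
histology afterwards. Radiographs run biweekly from the pre-injection
baseline. The NI reference level and arm assignment are fields of
`StudyDesign`, not constants, so alternative layouts are configurable.

## Radiographic disc height

Heights enter as measured lengths (pixels or mm); there is no landmark
detection. Calibration is per image against the 10-mm marker, because
projection magnification varies between sessions; %DHI is consequently
invariant to any per-image rescaling (verified by test). The baseline for
%DHI is the week-0 (pre-injection) DHI. Missing timepoints are flagged
`absent` and never interpolated — interpolation would invent data.

## Directed least-distance 3D disc height

The 3D-DH is the mean over all inferior-endplate points of the minimum
Euclidean distance to the superior cloud. The measure is directed
(inferior→superior), not symmetrised; a `symmetric=True` flag exists for
sensitivity checks. Nearest-neighbour search uses a KD-tree and equals
O(n²) brute force exactly (tested); ties in the nearest neighbour leave
the distance value unchanged.

**Zone geometry.** The disc frame is a least-squares mid-plane through the
pooled clouds (smallest principal axis = normal, oriented toward the
superior plate), with the in-plane anterior axis from an anatomical hint.
The footprint ellipse is a principal-axis fit (for a uniform ellipse the
semi-axis is twice the per-axis standard deviation). Points inside the
co-axial ellipse shrunk by `np_fraction` (default 0.5 per semi-axis, hence
25 % of the footprint area) are NP; annulus points are assigned by azimuth
from the anterior axis with boundaries at ±45° and ±135°. The NP extent
and the quadrant construction are assumptions — the underlying anatomy
defines AF and NP footprints only "ideally" — and both are configurable.

**Normalisation and binning.** Per-zone 3D-DHI divides by the *matched*
zone of the same animal's NI disc (`mode="whole_disc"` divides by the
reference's whole-disc 3D-DH instead, since either reading is defensible).
Bins are half-open and lower-inclusive exactly as reported: a value of
70.0 falls in 70–<80, a value of 90.0 in ≥90. Empty zones propagate NaN
("undefined"), never 0, so they cannot silently bias means.

## T2 relaxometry

Voxel decay follows S(TE) = S0·exp(−TE/T2) on 20 echoes equally spaced
20–400 ms (the protocol's echo list is read as an arithmetic progression;
the spacing is configurable), TR 2500 ms. The default fit is weighted
log-linear regression of ln S on TE with S² weights, followed by **one
refit with weights from the fitted curve**: measured-signal weights are
noisy at low SNR and produce a percent-level T2 bias that the single
model-weight pass removes (recovery error at 2 % Gaussian noise drops from
≈2.6 % to ≈0.5 %). A Levenberg–Marquardt refinement seeded by the
log-linear result is available (`method="nonlinear"`); the two agree
within 1 % at ≤2 % noise. Echoes at or below the noise floor (default 3×
the background standard deviation estimated from the last echo) get zero
weight; voxels with fewer than 3 usable echoes, non-positive or
ceiling-clipped T2 (t2_max = 1000 ms) are invalid and excluded from every
ROI summary. A first-echo exclusion flag (stimulated-echo mitigation)
exists but is off by default since the protocol uses all 20 echoes.
Colour maps use a fixed black→blue→…→red palette (high T2 red, low T2
blue/black); rendering then re-classifying recovers the bin index exactly.

## Histology and cell censuses

Scores are consumed as tables; no image analysis. Category ranges are
configuration (default 0–2 per category, total 0–14) — the grading system
is cited, not printed, in the source material, so the range ships as a
documented assumption. Surviving-cell percentages use field-summed counts
(not means of per-field percentages), which is robust to unequal field
densities; the denominator is the matched-timepoint CA control.

## Statistics

The two-way repeated-measures ANOVA is computed from the balanced
sum-of-squares decomposition with each effect tested against its
interaction with subjects (no sphericity correction by default; none is
assumed in the emulated design). It is vectorised so the 1000-replicate
null calibration runs in seconds, and it matches `pingouin.rm_anova` to
machine precision (tested). Degenerate inputs are flagged: zero
between-cell variance yields F = 0, p = 1; a real effect with zero error
variance saturates at F = ∞, p = 0. Kruskal–Wallis and Friedman use
tie-corrected statistics with χ² p-values by default and exact permutation
p-values on demand (full enumeration up to a configurable assignment
count, seeded Monte Carlo beyond); both match independent enumeration
oracles on small instances. Bonferroni multiplies raw pairwise p by the
number of comparisons (capped at 1); Tukey HSD uses the studentized-range
distribution. Correlation defaults to Spearman because histology grades
are ordinal; Pearson is always reported alongside. Significance is fixed
at 0.05. Under null simulations (8 subjects × 4×4 within for the ANOVA,
4×15 groups for Kruskal–Wallis, 12×5 blocks for Friedman, n = 20 pairs for
correlation — sizes chosen so the asymptotic approximations are adequate)
every test's rejection rate lies in [0.03, 0.07].

## The synthetic generator

The generator is the package's data source (no raw data accompany the
emulated study) and its defaults *are* the study conditions. A preset
table (`data/default_presets.yaml`) fixes, per treatment × week, the true
zone gap scales, radiographic %DHI trajectory, T2 scale, histology
category means, cell survival fraction and clone probability. Printed
group means are encoded exactly (e.g. posterior-zone scale 0.688→0.382 for
MIA 0.1 mg, survival 40.6/19.1/2.5 % at week 12); intermediate weeks,
anterior/lateral scales and all control trajectories are monotone
interpolations or flat assumptions, marked as such in the file. A single
`severity` scalar per cell drives T2 decline (t2_scale = 1 − 0.5·severity)
and histology means (category weight × severity, the endplate weakly
coupled), which is what produces the strong negative T2–histology
correlation as an emergent property rather than a planted one.

**Endplate phantoms.** Points are uniform on an elliptical footprint
(semi-axes 7.5 × 5 mm); the local gap above each position is
base_gap × zone scale, blended across zone boundaries by smoothstep over
0.5 mm of physical distance, plus independent Gaussian surface roughness
(0.05 mm) on each plate. The two plates share lateral sample positions
("congruent sampling", as if exported from one segmentation lattice);
without this the nearest-neighbour distance on finite random clouds
carries an O(spacing²/gap) bias and the noiseless pipeline could never
equal the generator truth exactly. The default gap is **1.2 mm**, the
physiologic rabbit lumbar disc height. This matters: the directed least
distance to a non-uniform surface takes the slant path (g/√(1+s²) under
local slope s, and direct shortcuts of lateral radius √(g_hi²−g_lo²)
across zone boundaries), so the measurement–truth coupling shrinks roughly
quadratically with the gap-to-footprint ratio. At a 4 mm gap the lateral
and NP zone recoveries would be biased by several percentage points; at
1.2 mm all zonal recoveries are within 0.7 points of truth. For the same
geometric reason the machine-precision generator/pipeline consistency
check is run on spatially uniform gap fields (where the directed distance
is exactly the gap); non-uniform fields are validated at the 2-point
recovery level instead.

**Other modalities.** Radiograph triplets scale a fixed baseline
(3.8/4.2/3.6 mm — radiographic projections, deliberately not tied to the
micro-CT gap) by the trajectory, add i.i.d. Gaussian measurement noise
(0.05 mm, small enough for 2-point recovery at n = 6, large enough to
exercise the statistics), and are emitted in pixels against an exact
10-mm/200-px marker. Echo stacks use a two-compartment disc phantom
(NP 120 ms / AF 40 ms baselines — absolute T2 is an assumption; only
relative change is calibrated) with 2 % Gaussian noise (Rician available)
and a 5 % per-disc biological T2 jitter. Histology scores are binomial on
the category range around the preset mean; alive counts are Poisson around
120 cells/field × survival fraction; clones are Bernoulli.

Everything is deterministic given one master seed (independent spawned
child streams per animal × modality); identical seeds give bit-identical
studies, different seeds share the truth table and differ only in noise.

## What passing tests do and do not show

The generator reproduces the *statistical structure* the pipeline assumes:
smooth endplates, monoexponential decay, Poisson censuses, exact marker
calibration. Real data add segmentation error, endplate sclerosis and
osteophytes, B1/stimulated-echo effects, reader variability in Ha/Hm/Hp
placement and ROI tracing, and inter-animal covariance — none of which are
modelled. Recovery of the calibrated truths therefore validates the
measurement chain's correctness and calibration, not its robustness to
those real-world artefacts. Census-based quantities carry irreducible
Poisson noise (≈1.6 percentage points s.d. for a six-animal survival
estimate at 120 cells/field), so individual six-animal replications can
miss a 2-point band even though the estimator is unbiased.

## Problem sizes

Default desk-scale sizes: 2000 points per endplate (3 phantom seeds per
cell), 32×32×20 echo stacks, 24 animals × 5 levels, 1000-replicate null
calibrations. A full emulated study runs in ≈1 s; the entire validation
suite in well under a minute.
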