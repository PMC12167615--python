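# Methods

## SUV conversion

PET voxels hold activity concentration `Ac` in kBq/mL. The standardized
uptake value is `SUV = Ac / (Ai'/w)` with `Ai'` the administered activity
decay-corrected forward to the start of imaging,
`Ai' = Ai · 2^(−Δt/T½)`, `Δt` the uptake time in minutes and
`T½ = 109.77` min for F-18. Decay during the acquisition itself is ignored
(scanners decay-correct frames to scan start). Internally everything is in
mm, kBq, g and minutes: `Ai'` in kBq divided by body mass in g gives the
concentration corresponding to SUV = 1, assuming tissue density 1 g/cm³.
Converters (MBq, kg, ISO-8601 timestamps) live at the I/O boundary.

## Spherical kernels on voxel grids

All spherical VOIs are discretized by the voxel-centre rule: a voxel belongs
to a sphere when its centre lies within the radius (no partial-volume
weighting). The SUVpeak kernel is the sphere of exactly 1 cm³
(d = 2·(3·1000/4π)^⅓ ≈ 12.407 mm). At 2 mm isotropic spacing this kernel
contains 123 voxels (984 mm³); the lattice-count fluctuation keeps the
discretized volume within about 2% of 1 cm³ for spacings ≤ 2 mm but the
error is *not* bounded by one voxel volume and becomes large (>10%) at
2.5–3 mm spacing, so the working resolution of the phantoms is 2 mm.
SUVpeak at a mask voxel is the mean of the SUV image (not restricted to the
organ) over the kernel; kernel voxels outside the image grid are excluded
from the mean (only relevant for organs near the image border — the
placement margin makes this moot for measurement spheres).

## Automatic sphere placement

For each organ at risk (kidneys, liver, parotid glands, spleen; measurement
sphere 30 mm for liver, 15 mm otherwise):

1. SUVpeak for every organ voxel;
2. candidate centres: organ voxels where the Euclidean distance transform of
   the mask (sampled in world mm) is ≥ sphere radius + 5 mm — exact for the
   continuous sphere, cheap and deterministic;
3. per-candidate score: maximum + standard deviation of the in-mask SUVpeak
   values inside the measurement sphere. SD is the *population* SD
   (divide by N) — a fixed convention, documented because either choice is
   defensible;
4. the chosen centre minimizes |score − median(score)|; the even-count
   median is the mean of the two central scores; ties are broken by the
   lexicographically smallest (i, j, k) voxel index so results are
   bit-reproducible across platforms.

The organ SUVmean is then the mean of the SUV image (not of the SUVpeak
map) over the measurement sphere. Scoring uses only in-mask SUVpeak values
because SUVpeak is defined on the organ; an empty candidate set raises
"organ too small" (a 24 mm spherical organ cannot host a 15 mm sphere with
the 5 mm margin). Bilateral organs (kidneys, parotid glands) are pooled
into one mask and receive a single sphere by default; a per-component mode
places one sphere per connected component and averages the SUVmeans. A
placement whose sphere max exceeds a configurable multiple (default 2×) of
the organ median SUV is flagged for review — an automated stand-in for the
manual check one would perform in high-burden patients.

## Burden metrics

TLV is the voxel-count volume of all lesion segmentations (cm³). TLU is
TLV times the SUVmean over the pooled lesion voxels (one global mean over
the union, not per-lesion averaging), algebraically equal to the voxelwise
integral of SUV. TLU carries SUV·cm³; because SUV·volume/body-mass is an
activity fraction under density 1 g/cm³, the percentage of injected
activity in tumour is `100 · TLU / (w_kg · 1000)` — a mass balance the
tests verify against the direct voxel sum of activity.

## Cohort statistics

Spearman rho is the Pearson correlation of average ranks (tie-corrected);
significance uses the two-tailed t-approximation
`t = rho·√((n−2)/(1−rho²))`, which matches standard software at cohort
scale; an exact permutation p is provided for n ≤ 8 and used as a testing
oracle. Patients with TLV = 0 are included in the correlations by default
(their ties are handled by average ranks); a flag restricts to TLV > 0.
Missing organs are removed pairwise per correlation. Quartiles use linear
interpolation (type 7), recorded in the report metadata. TLV strata are
0, (0,25], (25,189], (189,532], (532,1355], (1355,∞) cm³ — half-open on
the left so a value at a cut-off belongs to the lower group. The
`log10(x+1)` transform of TLV/TLU is for scatter plots only; rank
correlations are invariant under it (asserted to 1e-12). No between-group
hypothesis tests are run: the upper strata are intentionally sparse.

## Synthetic data

**Patient phantoms** place ellipsoidal organs (kidneys and parotids as
bilateral pairs) and spherical lesions on a 96×96×72 grid at 2 mm spacing,
fill uniform per-organ SUV over a 0.5 SUV background, optionally smooth
(Gaussian, FWHM in mm) and add voxel noise with SD proportional to the
local noise-free value (default 5% where used). The SUV image is converted
to activity concentration through the inverse SUV formula so the pipeline's
conversion round-trips exactly. Organ disjointness is asserted; lesions may
overlap organs only when a fixture flag is set. The truth record stores the
noise-free organ means, TLV, TLU and % injected.

**Cohorts** are drawn image-free: weight ~ N(87, 14²) kg clipped to
[48, 146], injected activity ~ N(4.0, 0.2²) MBq/kg clipped to [2.8, 6.0];
TLV is zero with probability 157/1086 and otherwise lognormal with median
3.8 cm³ and log-SD 2.0 (right tail reaching ~2000 cm³ at n ≈ 1000); lesion
SUVmean is lognormal with median 8 (so median TLU ≈ 31 SUV·cm³ and median
% injected ≈ 0.04% among tumour-bearing patients). Organ uptake is
`SUV_o = B_o · (1 − β·TLU/(TLU+K)) · ε_o` with baselines
B = {kidneys 13.1, liver 11.8, parotids 18.6, spleen 11.3} and lognormal
`ε_o` whose log-SD is solved from the target IQRs
({4.6, 4.4, 6.8, 5.8}) via `IQR/median = 2·sinh(z₇₅·σ)`. The saturating
(Michaelis–Menten-like) coupling is a modelling choice — no mechanistic
form is established for the sink effect — chosen because with large K the
depression only becomes visible at very high burden and because (β, K) are
identifiable. β = 0 is the null model; the test-bench uses β = 0.6,
K = 500 SUV·cm³ as the "coupling present" condition.

What the phantoms deliberately do **not** model: real anatomy, scanner
physics (PSF, attenuation, reconstruction), Poisson-like or spatially
correlated noise (the Gaussian voxel noise is a desk-scale stand-in and is
non-physical), partial-volume effects, or lesion-segmentation uncertainty.
Passing tests therefore demonstrate the correctness and robustness of the
algorithms under the stated model, not clinical performance on real scans.

## Problem sizes and numerics

The test-bench uses one-organ phantoms on 36³–48³ grids for brute-force
oracle comparison (20 seeds), the full four-organ phantom for recovery
(50 noisy seeds; a 15 mm sphere at 2 mm spacing averages ~220 voxels, so 5%
voxel noise leaves ~0.3% SD on the sphere mean), 20 lesion-avoidance seeds,
and 20 cohort replicates of n = 500 for the null and coupled correlation
checks. Floating-point conventions: population SD everywhere in scoring;
kernel means accumulate in float64; placement is deterministic bit-for-bit
for fixed inputs (lexicographic tie-break, single seeded generator per
phantom/cohort, seeds recorded in outputs).

## Known limitations

* Organ baselines enter the phantom as uniform values; real organs have
  internal texture, so the (max + SD) score distribution on real data is
  wider than on phantoms.
* The sink coupling acts through TLU only; renal function and other
  covariates that modulate kidney uptake are out of scope.
* The EDT-based edge rule treats the voxelized mask boundary as the organ
  edge; sub-voxel boundary positions are not modelled.
* At spacings coarser than ~2 mm the discretized 1 cm³ SUVpeak kernel is
  volumetrically biased (see above); resample first if that matters.
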