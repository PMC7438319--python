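# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `synapcount`.  Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Synthetic spinning-disk fields (`synthgen.PunctaFieldSpec`)

A field emulates a two-channel 16-bit SDM frame: 43.008 × 43.008 µm at
84 nm/pixel (512 × 512).  Labeled entities are of three kinds — channel-1
only, channel-2 only, both.  Given per-channel densities d₁, d₂ (puncta per
100 µm²) and colocalization fraction c, the three Poisson rates are
λ_both = c·(d₁+d₂)/(1+c), λ₁ = d₁−λ_both, λ₂ = d₂−λ_both, so each channel's
marginal count is Poisson with mean density × area and the entity-level
colocalized fraction is c.  A c incompatible with the marginals (negative
λᵢ) is rejected.

Entity positions are hard-core: pairwise separation ≥ 250 nm (≈ 3 px),
placed by rejection sampling with a bounded retry budget.  The hard core is
the package's own choice of a realistic condition: postsynaptic densities
of distinct synapses do not interpenetrate, and typical punctum diameters
are ~300 nm.  It also keeps the detection problem well-posed — at the
reference densities (1.4–2.2 entities/µm²) a looser core would place a
non-negligible fraction of distinct puncta inside one another, making the
density and colocalization ground truths themselves ambiguous.

Each punctum is rendered as a rotated anisotropic Gaussian spot.  The
ground-truth "size" of a punctum is the area of its 10%-of-peak isocontour,
A = 2π σₓσᵧ ln 10, so the segmentation rule used downstream has an exact
analytic target; areas are drawn log-normal with (µ = 11.21, σ = 0.46) on
the log-nm² scale, the measured PSD95-punctum size distribution.  Spot
amplitudes are uniform in [500, 3000] counts over a background of 500 with
additive Gaussian noise (σ = 30): the source study does not state punctum
intensity distributions, so the amplitude range is a free parameter chosen
to span dim-but-detectable through bright puncta.  Colocalized entities are
rendered in both channels at the same location with independent ≤ 0.5 px
sub-pixel jitter per channel, and with independent per-channel areas and
amplitudes (the two proteins label the same synapse but need not produce
identical spots).

## Punctum detection and measurement (`puncta`)

Feature stack: a multi-resolution, multi-orientation second-order nonlocal
derivative.  For scale s and orientation θ, f = S − ½(S₊d + S₋d), where S is
the image smoothed at σ = s/2 and d = s(cos θ, sin θ); scales (1, 1.5, 2.5,
4) px and 4 orientations by default.  The blob response is max over scales
of min over orientations (the orientation minimum suppresses edges and
ridges).  Candidates are 3×3 local maxima of each per-scale map above a low
threshold (default 1 intensity unit — deliberately high recall), merged
across scales, then greedily de-duplicated at 2 px keeping the stronger
peak.  Per-scale peak finding matters: close pairs that merge at a coarse
scale remain separate at a finer one.

A seeded random forest on the candidate feature vectors (all scale ×
orientation responses, the combined response, and the median-subtracted
local intensity) separates true puncta from noise.  It is trained on
synthetic fields, labeling candidates within 2 px of a ground-truth punctum
as positive.  The contract is behavioral, not architectural: held-out ROC
AUC ≥ 0.95 and ≤ 2% acceptance on pure-noise fields, both asserted in the
tests.

Segmentation re-implements the 10%-of-maximum rule: after subtracting the
field median (a robust background estimate; the rule is ill-posed on a
nonzero baseline), the mask is the connected component, containing the
peak, of pixels ≥ 0.10 × the peak value — scale-invariant by construction.
When neighboring masks swallow each other's peaks, pixels are reassigned to
their nearest accepted peak and the component containing the own peak is
kept; without this split, one merged mask can only pair with one channel-2
punctum and the colocalization index is biased low at high c.

The six descriptors: mean background-subtracted intensity over the mask;
size = |mask| × pixel area (7,056 nm² at 84 nm pixels); skewness and
kurtosis as standardized 3rd/4th moments of within-mask intensities
(kurtosis non-excess, normal → 3); circularity 4πA/P² with the Crofton
perimeter; aspect ratio from the intensity-weighted second-moment ellipse.

Colocalization is object-based with one-to-one pairing: two puncta are the
same entity iff their masks overlap by ≥ 25% of the smaller mask, matched
greedily by decreasing overlap (ties by centroid distance);
c = paired / (n₁ + n₂ − paired).  The 25% floor (configurable;
0 restores a literal ≥ 1 pixel rule) exists because at realistic densities
single-pixel contact between adjacent *distinct* puncta otherwise
produces a false-colocalization floor of ~0.04 even when c = 0.  A
centroid-distance mode (≤ 200 nm) is available as an alternative.  Measured
recovery across c ∈ {0, 0.5, 0.66, 1}: within ±0.02.

## Synthetic EM volumes (`synthgen.EmVolumeSpec`)

Labeled volumes use the acquisition geometry (5 × 5 nm pixels, 20 nm
sections); the default block is 5.12 × 3.84 × 1.6 µm — acquisition-scale
stacks (10.24 × 7.68 µm × hundreds of sections) are representable
(`EmVolumeSpec.acquisition_field()`) but too large for routine desk runs, so all
defaults are desk-scale and the methods below are size-independent.

A synapse is a pair of curved plates: the SAS midsurface is a spherical cap
of area exactly A (cap height h = A/(2πR), sphere radius R = 2.5 × the
equivalent disc radius), with the PSD plate on the convex side and the
presynaptic plate on the concave side separated by a 20 nm cleft.  Both
plates share one lateral footprint (the rim cylinder), which keeps plate
volume proportional to thickness on either side of the curved cleft —
matching the observation that active zone and PSD have similar extents.
Plate thicknesses encode the type: PSD 40 nm (AS) vs 20 nm (SS) against a
15 nm presynaptic plate.  SAS areas are log-normal per type (AS: µ = 10.54,
σ = 0.64; SS: µ = 10.70, σ = 0.69, log-nm²).  Voxelization includes a voxel
when the radial interval it spans intersects the plate shell, so plates
thinner than one 20 nm section stay watertight.  Placement is hard-core on
bounding radii; counts are Poisson (drawn before placement, so the voxel
grid never distorts them); AS:SS mixture defaults to ≈ 95.6 : 4.4.

## Counting, shrinkage, classification, SAS (`emstack`)

**Brick rule.**  A counting frame is an axis-aligned box with one inclusion
and one exclusion face per axis (default: low faces include, high faces
exclude).  An object — via its voxelized extent's bounding box — is counted
iff it intersects the frame and touches no exclusion face; for the default
convention this reduces to "the object's max corner lies in the frame",
which makes the unique-association property transparent: tiling a volume
with frames counts every object exactly once (asserted exactly in tests),
and E[count] = density × frame volume for random placements (mean bias
< 1% over 250 frames in the tests, bound 2%).

**Shrinkage.**  Processing shrinks tissue by linear factor 0.9508 (area
0.9040, volume 0.8595).  The correction direction is: measured volumes are
divided by the volume factor (the in-vivo tissue is larger), so corrected
densities are lower; the raw mode is available
(`synapse_density(..., correct=False)`), and synthetic tissue uses factor
1.0 since it never shrank.

**AS/SS.**  In the source workflow the distinction is expert judgment
("prominent" vs "thin" PSD).  Here it is a thickness-ratio rule: AS iff the
PSD plate is ≥ 1.5 × thicker than the presynaptic plate (threshold
configurable).  Since both plates share the apposition area, the thickness
ratio equals the volume ratio, which is what is computed — no surface
measurement is needed, and the rule is deterministic.  On generator
synapses at 40/15 vs 20/15 nm the rule is essentially error-free, so
mixture recovery is limited only by sampling.

**SAS area.**  The apposition surface is measured as a normal-weighted
voxel-face staircase.  For each boundary face of one component behind which
the partner lies within 60 nm along the face axis (marching voxel by voxel,
stopping if the component itself intervenes), the face contributes its
geometric area × |n_a|, the matching component of the local interface
normal, taken from the gradient of the smoothed signed distance field
EDT(pre) − EDT(post).  Summing |n_a|-weighted faces converges to ∫dA
because the axis-a staircase area is ∫|n_a|dA and Σ n_a² = 1; this removes
the up-to-41% staircase overestimate a plain face count suffers on tilted
interfaces.  The SAS area is the mean of the pre-side and post-side sums
(the surface halfway across the cleft).  The partner is dilated by one
voxel along the fine in-plane axes before the march to bridge sub-voxel rim
quantization.  Accuracy on closed-form oracles: flat apposition −0.04%,
30°-tilted plane +2.4%, random spherical caps −3.7% ± 3% (tolerance 10%);
below ~10⁴ nm² — smaller than real synapses and < 2% of the reference size
distribution — voxel quantization pushes individual errors past 10%, so the
per-object oracle applies to the distribution's bulk.
A plain marching-cubes level set was rejected: its equidistant surface
extends laterally past the plate rim and overestimates small caps by tens
of percent regardless of distance-band filtering.

## Density algebra and calibration (`densify`, `pipeline`)

dTotal = (dPSD95 + dSAP102)/(1+c) is evaluated **per section/field first**,
then averaged (the reference table's own construction; the printed total for
a layer is not the formula applied to the printed means).  The conversion
factor k is the quotient of layer-mean AS density and layer-mean dTotal; the
brain-wide factor is the **mean of the three layer factors** (0.0162 on the
reference table; the pooled quotient of all-layer means gives 0.0163 and is
available as `mode="pooled"`).  Region estimates k·dTotal are always flagged
"minimum estimate".  Log-normal fits are closed-form MLE (µ = mean of logs,
σ = population SD of logs) with a descriptive one-sample KS test; degenerate
samples (n < 2, nonpositive values, zero variance) raise.

`pipeline.run_calibration` ties everything together per layer: SDM fields →
detected densities and c → dTotal; EM stacks → brick counts → AS density;
k per layer and averaged.  Defaults: 3 layers at the reference CA1
magnitudes, 2 full-size SDM fields and five 5.12 × 3.84 × 2.4 µm EM stacks
per layer (≈ 340 counted AS per layer, statistical error ≈ 3% on the
averaged factor).  Every stage seed is derived from the global seed and the
stage name (CRC32-mixed `SeedSequence`), so a config reruns bit-identically;
reports carry the config hash and seed.  End-to-end recovery of a known k*
is asserted within 10%.

## Group comparisons (`statcmp`)

The gate: ANOVA iff every group passes Shapiro–Wilk and the set passes
Levene at α = 0.05; otherwise Kruskal–Wallis, with Holm-adjusted Dunn
pairwise comparisons for ≥ 3 groups or the exact Mann–Whitney U test for
two (verified against brute-force enumeration at n = 4+4).  Constant groups
route to the nonparametric branch.  Neither gate test is named in the
source description; Shapiro–Wilk/Levene are the conventional pair.  Under a
Gaussian null the full gated procedure's type-I rate stays within
[0.03, 0.07] (1,000-simulation check).

## Problem sizes and limitations

Test and acceptance runs use desk-scale sizes chosen once: half- or
full-size SDM fields, EM blocks of tens of µm³, 20-seed recovery loops,
5,000-synapse classification samples, 350-synapse SAS-distribution
samples.  At these sizes every tolerance asserted is dominated by the
documented statistical error, not by the implementation.

What the generators do not emulate: optical PSF depth effects, bleaching,
mosaic seams, uneven background, EM milling artifacts, membrane
reconstruction, perforated PSDs, or clustered (non-hard-core) synapse
arrangements.  Passing tests therefore demonstrate correctness of the
measurement chain under the stated geometric/noise model, not robustness to
every real-microscope artifact.  The colocalization definition (mask
overlap ≥ 25% of the smaller mask) and the AS/SS thickness-ratio rule are
documented package choices standing in for undocumented or expert-manual
steps of the source workflow; both are configurable, and the conversion
factors derived from the reference summary table do not depend on them.
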