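# Methods

This note documents the models, numerical choices and known limitations of
`mtlumen`. It is written for someone who wants to judge what the package's
passing tests do and do not demonstrate about real tomographic data.

## Helical geometry (`helix`)

A filament is modelled as a 1-start helix parameterized by a signed
per-subunit twist (degrees) and rise (Å); all filaments handled here are
left-handed, so twist ∈ (−360°, 0°). Orientations are intrinsic Z-Y-Z Euler
triplets (rot, tilt, psi) with tilt normalized to [0°, 180°] and rot/psi to
(−180°, 180°]. The polarity flip composes the particle rotation with a 180°
rotation about the Y axis and re-extracts a canonical triplet from the
matrix, which keeps the operation well defined at the gimbal poles
(tie-break: rot carries the full in-plane angle, psi = 0). Angles are
degrees everywhere; radians exist only inside trigonometric calls.

The closed-form cross-over relation
*c* = rise · 180/(180 − |twist|), valid for 90° < |twist| < 180°, is the
package's internal oracle: every Fourier-space measurement is checked
against it. It gives 281.9 Å for cofilactin (−161.8°/28.5 Å) and 380.8 Å
for bare F-actin (−167°/27.5 Å) — cofilin decoration shortens the
cross-over by reducing the twist magnitude.

## Synthetic data (`synth`)

The generator emulates the three inputs the pipeline consumes.

**Density volumes.** Filaments are sums of isotropic Gaussian blobs placed
on subunit lattices. Microtubules: N ∈ {12…15} protofilaments at center
radius N·s/2π with lateral spacing s = 50 Å, monomer spacing 40.95 Å and a
3-start axial stagger of 3·40.95/N Å; no seam. Luminal filaments: actin
blobs at 25 Å radius on the helical lattice, plus outer cofilin blobs at
45 Å radius on the same azimuth when decorated (this widens the filament,
the visually dominant effect of decoration). Polarity is physical: each
subunit carries a lighter marker blob offset 12 Å along the lattice plus
direction, and a "minus" filament has its whole local lattice rotated 180°
about a perpendicular axis (a proper rotation, preserving handedness).

Blob widths are tubulin 16 Å, actin 12 Å, cofilin 9 Å (σ). The widths must
be small relative to the ~28 Å rise: with σ comparable to the rise the
axial density modulation washes out and a twist/rise search degenerates to
a surface that is flat in rise. The chosen values keep individual subunits
visible at bin4 sampling (11.81 Å/voxel) while preserving the filaments'
relative diameters.

**Corruption model.** Additive white Gaussian noise (σ expressed as a
fraction of the signal peak) is applied in real space, then a missing wedge
is imposed in Fourier space: with the tilt axis along y and a ±60° tilt
range, all frequencies whose (k_x, k_z) component makes an angle greater
than 60° with the x–y plane are zeroed. The mask depends only on |k_x|,
|k_z|, hence is Hermitian-symmetric and the corrupted volume remains real.
No CTF, no dose weighting, no reconstruction round-trip: passing tests
therefore say nothing about CTF-related artifacts.

**Vote tables.** Each simulated filament draws a true
(protofilament-number, polarity) class from a configurable distribution;
each of its particles votes for the true class with probability
`p_correct` (default 0.85) and otherwise uniformly among the remaining
classes. CC scores are class-conditional normals truncated at zero —
N(0.15, 0.03) for correct votes, N(0.10, 0.03) for wrong ones, a
calibration that straddles the 0.13 assignment threshold without emulating
any particular alignment package's score scale. Whole filaments share a
half-set tag, mirroring the practice of keeping a filament's particles in
one resolution subset.

**Morphology particles.** 2D side-view projections of short filament
segments (projecting an isotropic 3D Gaussian gives a 2D Gaussian of the
same σ, so images are rendered directly from lattice (y, z) coordinates):
cofilactin (−161.8°/28.5 Å, decorated), bare F-actin (−167°/27.5 Å, bare),
and "other" (a featureless rod). The helical phase of each particle is
uniform-random; noise σ = peak/SNR. Default box 64 px at 5.9 Å — about
378 Å of filament, 1.3 cofilactin cross-overs.

All generators are deterministic given the integer seed in their spec.

## Traces and host mapping (`trace`)

Traces are polylines in nm. Resampling places particles at arc-length
multiples of the spacing (8 nm for microtubules, 6 nm for luminal
filaments) and transports an orthonormal frame along the trace by minimal
rotation (parallel transport). Frenet frames were rejected because they are
undefined on straight segments and flip at inflections. A trace shorter
than the spacing yields one particle at its midpoint.

A luminal filament is assigned to the microtubule whose axis minimizes the
mean point-to-polyline distance, accepted only if that mean is ≤ 8 nm. The
8 nm cut is a design choice (the lumen is ~15 nm wide and containment was
judged visually in practice); it is exposed in the configuration.

## Vote caller (`votes`)

Cleaning retains the top ⌈0.8·n⌉ particles by CC, globally across the table
(per-filament cleaning is available as an option). Ties at the retention
boundary drop the lowest particle ids first. A filament is assigned to its
modal class if the modal fraction ≥ 0.65, or ≥ 0.50 with the filament's
overall CC ≥ 0.13; "overall CC" is interpreted as the mean CC of the
filament's retained particles (median available), computed after cleaning —
the order of operations follows the cleaning-then-calling sequence. Exact
modal ties are undetermined (neither criterion can distinguish the tied
classes), as are filaments whose every particle was cleaned away.
Undetermined filaments are excluded from every downstream statistic.
Polarity unification applies the Y-axis 180° flip to the original Euler
angles of minus-called filaments.

Protrusion summaries exclude protrusions with fewer than two assigned
microtubules; orientation is "uniform" iff all assigned microtubules share
polarity. Protofilament distributions are computed per replicate and
summarized as mean ± sample s.d. (n−1).

## Fourier analysis (`fourier`)

**Cross-over measurement.** The volume is masked with a soft cylinder
(value 1 inside r₀ = diameter/2, Gaussian falloff with σ = r₀/4), projected
perpendicular to the filament axis, apodized with a Tukey window (sharp
support edges otherwise ring sinc sidelobes into the low-frequency band),
embedded in a 512-pixel box, and the power spectrum is 2×2-binned to 256.
The profile along the axial frequency is averaged over the two half-planes
and over ±40 binned pixels either side of the meridian — the cross-over
layer line carries a Bessel-order-2 term whose intensity peaks tens of
pixels off the meridian, so a narrow near-meridian band would miss it. The
layer line is the **first** local maximum walking out from the equator that
stands ≥ 3× above its local background (median of the ±6 px neighborhood,
peak ±1 excluded); the first-peak rule matters because the 1-start pitch
line (~59–63 Å) is far stronger than the cross-over line and would win a
global-maximum pick. L is read at whole-pixel resolution — matching a
manual line measurement on a spectrum image, which quantizes the result
(L = 11 → 27.49 nm at 11.81 Å sampling against the 28.19 nm closed form);
parabolic sub-pixel refinement is available (`subpixel=True`, giving
28.2 nm). The conversion *c* = B·p/L uses B = 256 and the original
real-space pixel size p: 2×2 binning of the Fourier image halves L while
the frequency step per binned pixel becomes 1/(256·p), so the formula is
exact under this and only this reading.

**Symmetry search.** The score of (twist, rise) is the Pearson correlation,
over the cylinder support of the outer diameter (default 120 Å), between
the map and the map rotated by twist about z and translated by rise along
z (trilinear interpolation; voxels translated past the z extent are
excluded). The search is coarse (1°, 0.5 Å over −200…−100° × 1…40 Å) then
fine (0.1°, 0.1 Å in a ±1.5-step window); an exhaustive fine scan is not
needed because the coarse surface is unimodal in the scanned window for
blob-lattice maps. Degeneracy (featureless or cylindrically smooth maps,
where every transform scores alike) is flagged when the best score exceeds
the worst scanned-or-probed score by less than 0.05; the probes evaluate
rises far from the optimum so that a deliberately narrow scan window is not
mistaken for a flat surface. An optional Gaussian prefilter (σ in Å)
suppresses noise before scoring; it commutes with the symmetry transform
and therefore does not move a clean map's optimum (verified: the noiseless
optimum is unchanged at σ = 9 Å, while a map with noise at 50 % of the
signal peak recovers twist/rise within 0.3°/0.3 Å).

On the 64³, 5.9 Å/voxel test maps the recovered rise is 28.45 Å against
the generating 28.5 Å — a one-fine-step bias from interpolation smoothing —
and the twist is exact to the fine step.

**FSC.** Standard per-shell normalized cross-correlation of Fourier
coefficients; resolution is 1/frequency at the first crossing below the
threshold (default 0.143, configurable), linearly interpolated between
shells, and undefined (None) when the curve never crosses. No mask-
correction or phase randomization is applied.

## Luminal statistics (`luminal`)

Occupancy is the percentage of microtubules hosting ≥ 1 filament (a
microtubule with several counts once). Coverage is Σ filament lengths /
microtubule length, clamped to 1 with a warning when the sum exceeds the
microtubule by more than 5 % (a tracing inconsistency; whether overlapping
filaments can legitimately exceed 1 is unresolved, so the clamp is
explicit). Orientation concordance is the fraction of filaments whose
barbed end points towards the host's plus end, among records with both
polarities resolved. Morphology length fractions sum per-segment lengths,
so filaments that transition between morphologies contribute to both
classes. Technical replicates are pooled before percentages; biological
replicates are summarized as mean ± sample s.d., with the s.d. reported as
undefined for a single replicate.

## Morphology consensus (`morph`)

The iterative 3D classification of the experimental pipeline is replaced by
a template-correlation surrogate on projection images. Per-particle
classification correlates each image against phase banks (12 phases) of the
three noise-free reference projections and takes the best match. Each of
the nine runs (class counts 5/10/20 × reference twists −162/−165/−167°)
clusters the particles by k-means — on log power spectra, which are
invariant to the helical phase, so clusters collect morphologies rather
than phases — and maps each cluster to a morphology by the majority of its
members' template labels. (Mapping by correlating the *class average*
against the templates is available but unreliable for phase-mixed classes,
whose averages smear.) The run's reference twist enters through the
clustering seed; once particles are pre-aligned it has no other observable
role in the surrogate, so run-to-run scatter here is smaller than in a real
expectation-maximization classification. At high SNR the surrogate's
confusion matrix is the identity on {cofilactin, f-actin}; this is a
statement about the synthetic images' separability (width + cross-over
pattern), not about real class averages.

## I/O and configuration (`io`, `cli`)

Volumes are MRC mode-2 with the voxel size in the cell header; particle
tables are STAR (one loop, named columns) or TSV; traces are plain-text
"id x y z" lines; configuration is flat key=value text with unknown keys
rejected. STAR/CIF and MRC parsing is delegated to gemmi. Lengths in
tables are nm, map-level quantities (rise, diameters, resolution) are Å,
and column names carry their unit suffix to keep the two scales apart.
Indexing is 0-based throughout. Every CLI subcommand takes `--seed`,
produces byte-identical primary outputs for a fixed seed, and logs the
config hash, seed and version to stderr.

## Problem sizes and limitations

The shipped tests and the acceptance script run at desk scale: 64³ maps
(apix ≈ 5.9 Å) for symmetry searches, a 512³ box (apix 11.81 Å, ~600 nm of
filament) for the cross-over measurement, 544 simulated microtubules × 40
particles for vote calling, and 2,000 particles for the morphology
consensus. These sizes make each stage's statistics well conditioned
(binomial s.e. ≈ 1 % for the vote recovery) while the whole suite runs in
a couple of minutes.

What passing tests do **not** show: robustness to CTF and reconstruction
artifacts (not simulated); correctness of cell-scale occupancy percentages
(they depend on real tomogram content, which the generator does not
emulate); performance of the morphology surrogate on genuinely ambiguous
intermediate-decoration filaments (the generator draws from three discrete
morphologies); and behavior on multi-start helices or lattices with seams,
which are out of scope.
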