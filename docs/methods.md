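# Methods

This note documents the models behind `oligoscope`, the defaults they
use, and the limits of what the synthetic test suite can show.

## Hard-sphere topograph simulation

The sample is a union of hard spheres: one sphere per heavy atom, with
united-atom-like radii (C 0.17, N 0.155, O 0.152, S 0.18, P 0.18 nm;
0.17 nm for anything else) that absorb the hydrogens crystal structures
do not resolve. A uniform radius can be substituted
(`assign_radii(st, "uniform:0.15")`) since the appropriate choice for a
given tip calibration is an open modelling question. The support plane
z = 0 stands in for the membrane surface: the structure is grounded so
its lowest sphere is tangent to the plane, and simulated heights are
clipped at zero. Nothing below the plane is removed, so features that
would in reality be buried in the bilayer (for example a C-terminal tag
flipped to the far side) still occupy space under the ring — they affect
grounding but not the visible topography.

The probe is a cone of half angle α (default 5°) blended with a
spherical apex of radius R (default 0.5 nm). Its surface height above
the apex is

    s(x) = R − sqrt(R² − x²)                    for x ≤ R·cos α
    s(x) = R(1 − sin α) + (x − R·cos α)·cot α   beyond the blend circle

continuous and once-differentiable at the blend.

The topograph records, per pixel, the lowest apex height at which the
rigid tip touches the sample — exactly the grayscale dilation of the
union-of-spheres top surface by the reflected tip. Per atom (radius r,
centre height z_a, lateral distance d) the touching height has two
branches:

    apex-sphere contact  h = z_a − R + sqrt((R + r)² − d²),   d ≤ (R + r)·cos α
    cone-flank contact   h = z_a + [r − (d − R·cos α)·cos α]/sin α − R(1 − sin α)

The flank branch keeps the blend offset `R(1 − sin α)/sin α`; dropping
it (a common small-angle shortcut) breaks the dilation identity. A
deliberately independent oracle (`oligoscope.oracles`) re-derives every
pixel by numerically maximising `S(q) − s(|q − p|)` over contact points
with `scipy.optimize.minimize_scalar`; the two agree to ~1e-15 nm on
random scenes, and that agreement is part of the test suite.

Default grid: 0.1 nm pixels. Coarser grids work; a warning is issued
when the pixel exceeds the structure extent.

### Resolution filter

Real topographs are limited to roughly 2 nm lateral resolution, so
simulated maps are low-pass filtered at a 2 nm cut-off wavelength. The
kernel shape is a modelling choice: the default Gaussian
(attenuation 1/2 at the cut-off) avoids the ringing an ideal brick-wall
kernel adds to hard simulated edges; `ideal` and `butterworth:<order>`
are available, and the ideal kernel is what the passband/stopband unit
tests use. Mirror padding of one cut-off wavelength suppresses
wrap-around; the mean height (DC) is restored exactly after cropping.

## Ring analysis

**Peaks.** Subunit apices are local maxima with topographic prominence
≥ `min_prominence`, computed exactly by a persistence sweep (union-find
over pixels sorted by height, 8-connectivity; a peak's prominence is its
height above the key saddle where its component merges into a higher
one). Default `min_prominence` = 0.05 nm: ~2.5× the prominence that
pixel noise of σ = 0.05 nm retains after the 2 nm smoothing, and small
enough to keep subunit peaks whose saddles ride on a central His-tag
dome. Peaks closer than `min_separation` (default 0.8 nm) are greedily
suppressed in height order; survivors are refined to sub-pixel positions
with a 3×3 quadratic fit, because the ring diameters of interest
(2.8–4.9 nm) span only tens of pixels. Noisy maps should be smoothed
with the same 2 nm filter before detection (`presmooth=FilterSpec(2.0)`)
so experimental-style and simulated maps are treated identically.

**Symmetry.** The order n ∈ {2..8} is the argmax of the rotational
autocorrelation C(n): the Pearson correlation between a polar resampling
of an annulus around the centre and its copy rotated by 2π/n (840
angular samples, divisible by every candidate order, bilinear
interpolation). Because a C6 map also correlates under C3, a candidate
that is a multiple of the raw winner and scores within 0.05 of it is
preferred (finest consistent order). Confidence is the winner's score
margin over non-divisor rivals, clipped to [0, 1] at a margin of 0.2; a
rotationally uniform map (score spread < 1e-4, the bilinear resampling
ripple) is flagged degenerate with confidence 0.

**Diameters.** Two conventions are reported side by side because
experimental reports mix them. The *peak-circle diameter* is from the
algebraic (Kåsa) least-squares circle through the subunit peaks —
collinear peaks are a degeneracy error. The *outer diameter* is where
the azimuthally averaged radial profile falls to half the ring-crest
height above background (background = median of the outermost 10% of
the profile), beyond the crest; it is NaN when the profile never
crosses half height inside the map. Comparisons to reported pentamer
"ring diameters" should use the peak-circle value and comparisons to
trimer "outer diameters" the half-height value; that pairing is this
package's interpretation, not a claim about any particular lab's
protocol. With ≥ 4 detected peaks, any peak much closer to the peak
centroid than the ring radius (< 0.5× the median peak radius) is treated
as a central protrusion and excluded from the circle fit.

**Central feature and face.** `central_feature` = height at the ring
centre minus the mean height on the peak circle. Above
+`protrusion_threshold` (default 0.2 nm, ≈ 4× the synthetic noise floor)
the map is called C-side (pooled C-terminal His-tags form a rigid
central bump); below −threshold, N-side (open pore); otherwise the face
is unknown. Face assignment by height difference between the two trimer
populations seen in 2D packing is deliberately not implemented — the
height offset is not quantified well enough to contract.

**Aggregation.** Per-patch counts use the sample s.d. (n−1); a single
patch reports s.d. 0 and is flagged. Class fractions are over all calls.

## Exciton-coupled CD

Each protomer contributes one retinal transition dipole: origin at the
polyene-chain midpoint (mean of atoms C5..C15), direction from the
Schiff-base end (C15, the "tail") to the β-ionone end (C5, the "head").
Site energies are reduced wavenumbers 1/λ (nm⁻¹) and are equal within an
oligomer (degenerate exciton model — one λ_max per protein). Couplings
use the point-dipole form V_ij = μ² κ_ij / d³ with
κ = û_i·û_j − 3(û_i·R̂)(û_j·R̂); a 0.3 nm distance guard flags
geometries too tight for the point-dipole picture (extended-dipole
refinements are out of scope). The default reduced dipole strength 0.03
puts nearest-neighbour couplings at a few 1e-5 nm⁻¹ for ~2 nm rings,
i.e. exciton splittings of tens of nm around a 524 nm band — the scale
retinal proteins show.

Diagonalising the Hamiltonian gives state energies E_k and rotational
strengths

    R_k = −(π/λ̄) Σ_{i<j} c_ik c_jk [R_ij · (μ_i × μ_j)]

which sum to zero for any geometry (orthonormality of the eigenvectors;
enforced as a post-check at 1e-9 and tested at 1e-12). Spectra are sums
of unit-area Gaussians (default 40 nm FWHM — visible retinal bands are
broad) weighted by R_k, plus one intrinsic band of the same shape at
λ_max representing the monomer CD. Units are reduced throughout: only
signs, orderings and peak positions are meaningful.

**Couplet classification.** A spectrum with both a positive and a
negative extremum above tolerance is a couplet; the lobe at shorter
wavelength is the blue lobe. (+ blue, − red) is a *normal* couplet — the
trimer signature — and (− blue, + red) an *inverted* couplet — the
pentamer signature. Lobes are ordered relative to each other rather than
relative to the monomer λ_max, because the coupled manifold can sit
entirely to one side of λ_max (the tangential trimer geometry puts both
bands red of a 524 nm site band) and pinning lobe signs to λ_max would
then misclassify a clean couplet. Single-signed spectra are "single
peak", red-shifted when the extremum lies more than bandwidth/4 red of
λ_max. This captures the diagnostic that matters in practice: a weak
inverted couplet under a dominant positive intrinsic band never crosses
zero, but drags the single apparent peak measurably red of λ_max, and
the shift grows with coupling strength until the lobes separate.

## Synthetic generator

The generator emulates the study geometry at desk scale: Cₙ rings
(n = 3, 5, 6) of cylinder-like protomers (vertical stacks of overlapping
spheres whose centres span [r, height − r], so stack top = protomer
height exactly), ring diameters 2.8–4.9 nm, protomer height 3.5 nm, and
an auto protomer radius of 0.95·ring_radius·sin(π/n) capped at 1.25 nm
(a seven-transmembrane-bundle radius). Recovery sweeps draw diameters
per class — trimers 2.8–4.8 nm, pentamers 4.1–4.9 nm, hexamers
4.5–4.9 nm — matching how the two measures co-vary in real rings; a
2.8 nm hexamer would have sub-resolution subunit spacing and is not a
condition the generator claims to represent.

The central feature is either `none`, a guaranteed-empty `pore`, or a
`protrusion:<height>` — a 0.35 nm-sphere stack seated *on the C-terminal
face*, mimicking pooled His-tags. Because it is a surface bump rather
than a full-height column, flipping the ring to the N-side view leaves
it hanging below the ring, and the tip sees an open pore — the two-face
phenomenology without any membrane model.

Dipole azimuth modes: `head_to_tail` points every head along the
clockwise tangent (each head toward the neighbouring tail);
`tail_to_tail` points heads radially outward with a fixed 30° clockwise
cant. The cant is essential physics, not decoration: an exactly radial
arrangement has σᵥ mirror symmetry, hence zero rotational strength and
no couplet at all. The handedness pair was fixed once so that
head-to-tail yields the normal (trimer-type) couplet and tail-to-tail
the inverted (pentamer-type) one; the *flip* property — reversing the
azimuth mode reverses the couplet label — holds across all n and tilt
angles and is the generator-level statement of the packing-determines-
couplet claim. Tilt above the membrane plane defaults to 20°, a typical
retinal inclination.

Noise is pixelwise Gaussian (default σ = 0.05 nm, a quiet liquid-cell
topograph) plus optional per-scanline offsets; negative pixels are
allowed. Randomness: a ring's only stochastic field is its azimuthal
phase, drawn from the spec seed; patch scenes derive one RNG stream per
ring from (scene seed, index), so scenes are reproducible item by item.

PDB fixtures store sphere radii in the B-factor column (the PDB format
has no radius field) and carry two-atom pseudo-retinals (C15/C5) so the
chromophore path round-trips through the file format.

**What passing synthetic tests does not show.** Protomers are smooth
cylinders: real protomers have corrugated tops, so real subunit peaks
are broader and prominence thresholds may need retuning on experimental
maps. There is no lipid background, no tip contamination or double-tip
artifacts, no drift, and no elastic deformation; the noise model is
white, whereas instrument noise is correlated. CD amplitudes are
reduced-unit and say nothing about measured Δε magnitudes; only sign
patterns and shift directions transfer.

## Pipeline

`run_pipeline` validates a declarative YAML/JSON config (unknown keys
are errors), then per structure: orient (each requested face), simulate,
filter, analyse, and — when retinals are present — solve the exciton
system and classify the couplet. Stage errors are recorded per structure
without aborting the rest; the JSON report echoes the config verbatim,
carries every warning, and references only files that exist. Outputs
contain no timestamps, so identical configs rewrite outputs
bit-identically. Problem sizes in the shipped checks (101×101 maps at
0.1 nm pixels, 100-ring recovery sweeps, 1000-geometry sum-rule scans)
were chosen to exercise the full parameter ranges while keeping a
complete run in the minutes range on one core.

## Known limitations

- Assemblies must already contain the oligomer; crystallographic
  symmetry operators are not expanded.
- Only model 1 of multi-model files is read.
- Trimer face assignment by absolute height is not implemented.
- The exciton model is point-dipole, degenerate-site, single-band; no
  vibronic structure, no environmental shifts, no absolute intensities.
- The tip never deforms the sample; tapping dynamics and feedback
  artifacts are out of scope (the noise generator adds scan-line offsets
  only).
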