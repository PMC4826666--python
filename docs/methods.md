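# Methods

`plaquemech` implements a hybrid experimental–numerical framework for
estimating the mechanical properties of atherosclerotic plaque components
from vessel inflation tests imaged with high-frequency ultrasound. Because
no public RF recordings of such experiments exist, the package pairs the
estimation machinery with a fully synthetic experiment generator whose
ground truth is known, so every stage can be validated quantitatively.
This note documents the models, the numerical choices, and what the
synthetic studies do and do not demonstrate.

## The mechanical model

A plaque cross-section is idealized in 2D plane strain: the vessel is held
at fixed longitudinal stretch during inflation, axial motion is negligible,
and the cross-section deforms in its own plane. Three tissue regions are
distinguished — the thickened intima, the media+adventitia fused into a
single "wall", and optional calcifications — each an incompressible
Neo-Hookean solid with strain energy

    W = C (I₁ − 3),

where `C` is the shear-modulus-like stiffness parameter (the infinitesimal
shear modulus is `2C`) and `I₁` the first invariant of the left
Cauchy–Green tensor (out-of-plane stretch 1). Calcium is effectively rigid
(three orders of magnitude stiffer than tissue). Reported Young's moduli
use the incompressible relation `E = 6C`.

The luminal pressure is a follower load (normal to the deformed lumen
surface): at 120 mmHg the geometry changes enough that dead loads would
misdirect the traction. To suppress rigid-body motion without constraining
the vessel, a very soft compressible buffer ring (Poisson ratio 0,
thickness 2 mm) surrounds the adventitia and its outer rim is clamped.
Lumen displacements change by well under 0.5% when the buffer stiffness is
moved across two orders of magnitude (tested).

The FE reference configuration is the geometry imaged at the first
protocol pressure (10 mmHg), assumed stress-free; the residual stress and
the small 10 mmHg preload are neglected, and loads are pressure increases
above that baseline. Incremental stiffness is assessed by fitting each
pressure step (10→80, 80→100, 100→120 mmHg) independently with its own
Neo-Hookean parameters.

## Finite elements

Quadratic (6-node) triangles on a structured radial mesh: the contours are
star-shaped about the lumen centroid, so tissue and buffer are meshed as
stacked radial rings of quads split into triangles and elevated to P2 with
straight edges. Calcium inclusions relabel elements by majority
intersection area with the calcium polygon. Default tissue edge length is
0.15 mm (≈2.5×10³ elements); lumen displacements change <1% on halving it
(tested). This is one order below the element counts a production
contact-rich model would use, chosen because the inverse loop multiplies
solve counts; the convergence test justifies it for smooth layered
cross-sections.

Incompressibility is handled two ways, agreeing within 1% (tested):

* **mixed** (default): element-wise constant pressure, statically
  condensed (perturbed Lagrangian with bulk modulus `κ = 10⁴ C`); the
  P2/P0 pair is inf-sup stable in 2D and keeps the global system
  displacement-only;
* **penalty**: compressible Neo-Hookean
  `W = C(I₁−3) − 2C ln J + κ/2 (ln J)²` with the same `κ`.

The buffer always uses the compressible form with zero second Lamé
parameter. Newton–Raphson with the exact consistent tangent (including the
nonsymmetric follower-load stiffness) converges to a relative residual of
10⁻⁸; load steps bisect automatically on divergence (depth ≤ 8, with a
total iteration budget so pathological parameter combinations fail fast
instead of stalling).

**Verification oracle.** For a homogeneous tube, incompressibility fixes
the kinematics (`r² = R² + a² − A²`) and radial equilibrium reduces to a
1D quadrature `P = ∫ 2C(λ² − λ⁻²)/r dr`; root-finding for the deformed
inner radius gives an independent solution. FE inner-radius *expansions*
match it within 1% across P ∈ {2,6,10,16} kPa and C ∈ {20,100,400} kPa.
(Expansions, not radii: the 96-vertex polygonal contour carries a ~0.4 µm
static radius offset that is not a property of the solution but would
dominate the smallest expansion, ~2.4 µm.)

An exact identity of the model is used heavily: scaling every modulus by
`k` and the pressure by `1/k` leaves the displacement field unchanged. The
inverse operator therefore solves one canonical problem (`C_wall = 1`) per
intima/wall stiffness ratio and serves all lattice candidates from a
shared ascending pressure ladder of cached Newton states. This requires
buffer and calcium stiffness to be specified relative to the wall
(buffer 10⁻⁴ C_wall, calcium 10³ C_wall, i.e. the conventional 10⁵ kPa at
C_wall = 100 kPa); both choices are far outside the range where they
influence tissue displacements. Candidates whose canonical pressure
`P/C_wall` exceeds 8 kPa (inner stretch beyond ≈3) are excluded from the
search as non-converged — they lie far outside the physiological branch.

## Synthetic ultrasound acquisition

RF frames are simulated with a convolutional point-spread-function model:
each line is a sum over scatterers of reflectivity × lateral Gaussian beam
weight × Gaussian-modulated cosine pulse at the scatterer depth. This
produces fully developed speckle (Rayleigh envelope, tested by KS) and
realistic decorrelation under deformation, which is what displacement
tracking needs; it does **not** model beamforming, attenuation, phase
aberration, reverberation or nonlinear propagation, so tracking accuracy
measured here is an upper bound relative to a physical scanner.

Scatterers (default 3000/mm², ≥10 per resolution cell) fill the tissue
between lumen and outer wall; the lumen and bath are anechoic. Default
transducer: 40 MHz carrier, 50% fractional bandwidth, 45 µm lateral beam
sigma, 154 MHz sampling, 11 µm line pitch. The sampling rate and pitch
were chosen so that the physical kernel sizes of the tracking schedule
quantize exactly: the depth step is `c/(2f_s)` = 5 µm, making 60 µm
kernels exactly 12 samples and the final axial grid step exactly 15 µm,
and 715/935 µm lateral kernels exactly 65/85 lines with the lateral step
quantizing to 5 lines = 55 µm. Additive white noise is specified as SNR in
dB relative to the frame RMS (default 30 dB).

The inflation is acquired quasi-statically: frames are recorded along a
geometric pressure ladder (interframe pressure ratio ≤ 1.15 by default)
passing through every step boundary. This matters: tracking a full
pressure step in one frame pair fails below the lumen, where the coarse
3.85 mm templates straddle the anechoic lumen and blend opposite-signed
motion while the fine pass only searches ±30 µm. Small interframe motion
keeps every pair within range, and the incremental maps are accumulated by
material trajectory following onto the base (10 mmHg) grid.

## Displacement tracking

Three-iteration coarse-to-fine zero-mean normalized cross-correlation of
RF data: iteration 1 uses 3850×715 µm templates in 7700×935 µm search
windows (50% axial / 92% lateral overlap, FFT-based correlation);
iterations 2 and 3 use 60×715 µm in 120×935 µm (75%/92%, direct
correlation, compiled). Iteration 3 locally aligns the post frame by
bilinear re-sampling at the current estimate and refines the peak with
3-point parabolic interpolation, `δ = (c₋ − c₊)/(2(c₋ − 2c₀ + c₊))`. A
5×5 median filter cleans each iteration's map. Physical kernel sizes are
converted to samples by flooring to even counts (≥8); template-grid steps
round to whole samples/lines, giving the 15 µm axial / 55 µm lateral final
grid.

Design choices where the standard scheme is silent:

* **Validity gating.** Anechoic regions produce noise-only estimates once
  additive noise is present. A node is kept only if its template RF
  standard deviation exceeds 10% of the grid's strong-signal level (95th
  percentile) and its correlation peak reaches 0.15; gated nodes are NaN,
  and search-offset propagation between iterations fills them from the
  nearest valid node. Without this, junk estimates from the lumen and
  bath leak into valid tissue through the offset interpolation.
* **Median windows never exceed the map.** On the coarse map (typically
  4–5 rows spanning the whole depth) a 5-row median would mix regions
  millimetres apart — it destroyed below-lumen estimates in development —
  so an axis shorter than the window is left unfiltered.
* **Iterated alignment.** The parabolic interpolator on an RF correlation
  (carrier wavelength 3.85 samples) is biased by up to ~0.05 samples at
  quarter-sample offsets. Nodes whose residual estimate is substantially
  fractional are re-aligned at the fractional estimate, where the
  interpolator is unbiased; near-integer residuals skip the extra pass
  (re-sampling noise would dominate). Integer shifts are recovered to
  <0.1 µm and 0.3-sample shifts to <0.05 samples RMSE at 30 dB SNR
  (tested).
* **Sequential prior.** When tracking a quasi-static sequence, each
  pair may supply the previous increment's map as a second offset
  hypothesis for the fine pass; the better correlation peak wins per
  node. Coarse templates that are mostly anechoic occasionally lose
  their weak tissue peak to a noise peak in a particular realization,
  and the prior recovers exactly those nodes.
* Tie-breaking between equal correlation maxima prefers the
  smallest-magnitude lag; only the axial displacement component feeds the
  inverse problem (lateral estimates are markedly noisier and are kept
  for reporting only).

## Histology-to-ultrasound registration

Component contours drawn on histology are mapped onto the ultrasound frame
using only the lumen and outer-wall contours, which an operator can draw
on both modalities: landmarks are paired by matched arc-length
parameterization anchored at the point of maximum wall thickness (a
reproducible, anatomy-driven rotational anchor), and a 2D thin-plate
spline is fitted to the pairs (zero smoothing reproduces affine maps
exactly; a small bending-energy weight absorbs histology shrinkage noise).
Limitations: arc-length pairing gives exact correspondences only for
similarity transforms; strongly anisotropic distortions are absorbed only
approximately, and intensity information is not used at all.

## Inverse estimation

Measured and computed axial displacements are averaged over a measurement
grid of 100 µm square cells forming a single column through the plaque
thickness at the lumen-center lateral position — the central band where
the beam direction coincides with the radial direction. A single column is
what reproduces the expected 30–50 cells over plaques a few millimetres
thick. Cells are fixed in the reference (10 mmHg) configuration; measured
values are material (trajectory-accumulated) displacements at the cell's
grid nodes, computed values are 4×4-point cell averages of the FE
increment at the same material positions, so the two sides are compared
like for like at every step.

Per step, the objective `F = Σⱼ (uⱼᶜᵒᵐᵖ − uⱼᵐᵉᵃˢ)²` is minimized by
exhaustive search over (C_wall, C_intima) ∈ [1, 400] kPa. The default
lattice is two-stage — a 20×20 log-spaced coarse pass followed by a 9×9
linear refinement spanning the coarse winner's neighbor interval — with a
literal single-stage constant-step lattice available by configuration.
Ties prefer the softer wall, then the softer intima. Goodness of fit is
`Δu_rel = (√F / n) · (u_mean)⁻¹ × 100%` with `u_mean` the mean absolute
measured cell displacement of the step (an RMS-style alternative exists
behind a flag but is never the default).

**Identifiability.** Incompressible layers in series contribute luminal
pressure roughly in proportion to stiffness × thickness, so when the
intima is much thinner than the measurement cells a change of C_intima is
compensated by a small change of C_wall with almost no change in the
displacement field. The objective then has a flat valley: profiling F over
C_wall at each fixed C_intima, the profile stays below 1% on the Δu_rel
scale across the entire 1–400 kPa intima axis for a 0.1 mm intima
(measured ≤0.08%). Note the *raw* field sensitivity along the intima axis
is necessarily large at the stiff end (C·t of even a thin stiff layer
rivals the wall's), which is why the flat direction is a property of the
minimization, not of the field.

## Synthetic phantoms and what the studies show

Phantoms are layered cross-sections: circular lumen, cosine-modulated
intimal thickness (eccentricity 0 = concentric, 1 = fully one-sided, thick
pole toward the transducer), uniform wall, optional elliptical calcium
centered on the intima–media interface. Defaults (lumen radius 1.5 mm,
wall 0.5 mm, peak intima 2.0 mm, eccentricity 0.6) give 30–50 measurement
cells. Contours are stored as explicit polylines so traced and synthetic
geometries share one code path.

The end-to-end study — phantom → FE truth → scatterer displacement → RF at
30 dB SNR → tracking → grid averaging → grid search — recovers the truth
moduli within one lattice step at every pressure step with Δu_rel well
under the 2% goodness threshold. Because the truth is generated by the
same constitutive model the inverse assumes (and, at matched mesh, the
same discretization), this validates the *chain* — displacement
estimation, averaging, and minimization — not the constitutive adequacy of
the Neo-Hookean model for real tissue, nor robustness to acquisition
physics the RF simulator omits. Those require real recordings.

Study problem sizes (validation module and tests): tube oracle at 0.15 mm
mesh edge; self-consistency on a concentric phantom at 0.3 mm edge with an
8×8+5×5 lattice and 20 noise replicates of 1 µm; end-to-end at 0.25 mm
edge, 8×8+5×5 lattice, ±2.2 mm field of view and interframe ratio 1.2.
These are the package's desk-scale reference conditions; all are
configurable upward.

## Known limitations

* 2D plane strain; no anisotropy, viscoelasticity, residual stress, or
  longitudinal prestretch mechanics.
* Star-shaped contours only (structured radial meshing); strongly
  non-convex lumens would need a general conforming mesher.
* The RF model omits beamforming and attenuation; lateral displacement
  accuracy is poor by construction (no spatial compounding).
* The incremental-step fit treats each step as an independent
  Neo-Hookean problem loading from the imaged reference; the start-state
  pre-deformation is recomputed with the candidate moduli.
* Quadrilateral elements are not implemented; triangles handle arbitrary
  star-shaped contours.
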