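# Methods

`stagecal` models and compensates the three systematic positioning errors of
a vision-guided micromanipulation platform: nonlinear imaging distortion of
the microscope optics, the in-plane deflection angle between the camera and
the motorized X-Y stage, and the direction-dependent mechanical displacement
error of the stage itself. This note records the model, the estimation
procedures, the synthetic rig used to validate them, and the numerical and
design choices a maintainer would want to know.

## Error model

**Imaging.** A point `P = (X, Y, 0)` on the (fronto-parallel) stage plane
projects to image pixel `p = (u, v)` through a planar homography
`λ p̃ = H P̃ = A [R₁₂ | t] P̃`, with internal matrix
`A = [[fx, 0, u0], [0, fy, v0], [0, 0, 1]]` (focal scales in px/µm). Lens
distortion displaces observed points radially; the second-order model maps
an observed point to its theoretical position by

    u_theo = u + k (u − u0) r²,   v_theo = v + k (v − v0) r²,
    r² = (u − u0)² + (v − v0)²

with distortion factor `k` (px⁻²) and principal point `(u0, v0)`. The actual
magnification is `M = (fx·Lu + fy·Lv)/2` for sensor pixel pitches `Lu, Lv`
(µm/px), and `M′ = M / M_nominal` is the ratio to the objective's rated
magnification.

**Camera mounting.** The screw-mounted camera sits rotated by a small
deflection angle `θ` about the optical axis relative to the stage axes. The
first-order installation transform uses conversion factors
`εx = −εy = sin θ`; both are exposed separately so a non-orthogonality term
can be injected in tests.

**Stage mechanics.** Commanded travel is scaled by `(1 + Δ)` with a signed
relative error per axis and direction (`Δx±`, `Δy±`; backlash makes the two
directions differ). The errors are stored dimensionless because the
mechanical error grows linearly with commanded distance.

The combined error transform is
`T = M′ · [[1, εy, Δx], [εx, 1, Δy], [0, 0, 1]] · [R₂ | t̂]`, assembled as a
3×3 homogeneous 2-D map.

**Coordinate convention.** Image coordinates are 0-based `(u, v) =
(column, row)`, origin top-left. Stage coordinates share the image
handedness: +X rightward, +Y along image `v`. This single-handedness
convention is what makes the deflection angle measured from stitching
(`θ = arctan(dy/dx)` on an X series, in image coordinates) directly the
angle by which commands must be counter-rotated (`rotate(−θ)`); with a
y-up physical frame the two angles would differ in sign. Angles are stored
in degrees at API boundaries and radians internally; files store degrees.

## Estimation procedures

**Plumb-line distortion calibration.** Images of straight grid lines must be
straight after correction. Subpixel centerline points are extracted by
scanning perpendicular to each line family (intensity-weighted centroids in
a ±2·linewidth window; samples near line crossings are rejected when the
window edges are still dark; tracks are grown by nearest-prediction
association so tilted and curved lines are followed). The objective

    F(k, u0, v0, {αᵢ, φᵢ}) = Σᵢ Σⱼ (ûᵢⱼ cos αᵢ + v̂ᵢⱼ sin αᵢ + φᵢ)²

is minimized by Levenberg–Marquardt with an analytic Jacobian, where
`(û, v̂)` are the observed points pushed through the radial correction.
Lines are parameterized in Hessian normal form `(cos α, sin α, φ)` with
`α ∈ (−π/2, π/2]`; the printed objective without a unit-normal constraint
would admit the trivial zero solution, which the angle parameterization
excludes. Per-line `(αᵢ, φᵢ)` initialize from total-least-squares fits,
`(u0, v0)` from the raster center, `k = 0`. Several rasters can be fit
jointly with shared `(k, u0, v0)`. Requires both line families: a single
pencil leaves the principal point unconstrained along the line direction.

**Homography and decomposition.** Line points undistorted with the fitted
intrinsics are refit as straight lines; their crossings give point pairs and
the lines themselves line pairs against the known 50 µm grid. The direct
linear transform stacks `p × (H P) = 0` and `L × (Hᵀ l) = 0` constraints
(world→image convention with its contravariant line map), Hartley-normalizes
both frames and solves by SVD. Degeneracy is flagged when the nullspace
dimension exceeds one, ill-conditioning when the two smallest singular
values are within a factor of ten. A single fronto-parallel plane cannot
separate focal length from plane distance (the two Zhang-style
orthonormality constraints degenerate to `fx = fy`), so `fx, fy` are taken
as the column norms of the upper 2×2 of `H` normalized to `H[2,2] = 1` —
the metric pixel scale provided by the grid pitch. With known intrinsics
(`estimate_focal=False`) the conventional `[r1 r2 t] = A⁻¹H/λ`, `‖r1‖ = 1`
decomposition is used instead and also recovers the plane offset. The
rotation is projected to the nearest proper rotation; `t̂ = Lu·t` applies
the pixel-pitch correction; `(δx, δy)` are the translation components of
the first two rows of `[R | t̂]`.

**Deflection by stitching.** The stage steps half a frame along one axis;
consecutive frames are registered and `θ = arctan(dy/dx)` per pair (X
series; transposed with a sign flip for Y series so both estimate the same
mounting angle), averaged arithmetically over pairs. Frames are first
resampled into distortion-free coordinates — the distortion gradient across
a half-frame shift otherwise biases offsets by several pixels.

**Mechanical errors.** For each of +X, −X, +Y, −Y the stage steps n times;
each consecutive pair's measured offset (after distortion compensation and
rotation by −θ onto the motion axis) is compared with the nominal step in
pixels; `Δ` is the mean error divided by the step. X series step half the
frame width, Y series half the frame height. For an arbitrary motion
direction `β`, the applicable `(Δx, Δy)` pair is selected by the quadrant
of `β` with half-open bounds `[0°,90°), [90°,180°), [180°,270°),
[270°,360°)`.

**Registration.** The default backend is FFT cross-power correlation with
three accuracy safeguards: (1) a Hann window and soft whitening
`R/(|R| + 0.5·mean|R|)` — full whitening weights the noise-only frequencies
between the grid harmonics as strongly as the signal and smears the peak
along the line-direction ridges; (2) a peak search restricted to a window
around the expected (commanded) offset, because a periodic grid target
correlates at every lattice offset; a shift and its frame-period complement
are also indistinguishable in the FFT, so the result is reported as the
representative nearest the expectation; (3) after the first estimate, the
offset is re-measured on the overlap crop only, which removes the ~0.1 px
bias the non-shared image regions leave in the full-frame correlation.
Subpixel refinement evaluates the cross-power inverse DFT on a local
upsampled grid (final resolution 2.5·10⁻³ px). Multi-pair estimators run a
consensus second pass around the median pair offset, because a step that is
a whole number of grid pitches lets a grid-rich pair lock onto the lattice
alias. A SIFT feature backend (1-px translation consensus over match
displacement vectors, ≥8 inliers, phase-correlation fallback) is provided
as an independent cross-check (`backend="cross-check"` raises on
disagreement beyond half a grid period) but is not the default: it is an
order of magnitude slower on full frames and adds no accuracy on these
images.

**Compensation.** The model keeps the five coefficients `M′, δx, δy, θ` and
the `Δ` set. In the default *coherent* mode a desired displacement
(measured on the image at nominal magnification) maps to the stage command

    command = diag(1/(1+Δx_sel), 1/(1+Δy_sel)) · rotate(−θ) · desired / M′

with the `Δ` pair selected by the post-rotation motion quadrant; this
exactly inverts the forward stage model when the calibration equals the
truth. The distortion offsets `δ` are a constant recentering term applied
once per absolute positioning (flag `apply_delta`), never per unit step —
a per-step multiplicative δ would command zero motion for a perfect system
whose theoretical δ is 0. A *paper_literal* mode evaluates the closed-form
update `X1 = X0 + M′·δx·μ·s·cos θ` (sine analog for Y) with the scalar
quadrant gain `μ(β) = (1+Δx_sel)|cos β| + (1+Δy_sel)|sin β|` verbatim, for
auditability; it is not invertible (at zero error and β = 45° the scalar
gain is √2, not 1) and is not used by the closed-loop evaluations.

## Synthetic rig

The generator renders the calibration target through the forward model:
world grid → stage offset → rotation θ → magnification → radial distortion
(closed form: the observed→theoretical map *is* the model, so the renderer
inverse-maps each observed pixel) → additive Gaussian noise → 8-bit
quantization. Grid lines have a Gaussian cross-section (σ = half the line
width) so centroid extraction reaches subpixel accuracy; intensities are
background 200, line cores 50, noise clipped to [0, 255].

Defaults are the worked example's conditions: 20×20 squares of 50 µm,
1200×900 px rasters, M_nominal 20, M_true 19.843 (M′ = 0.99215), pixel
pitch Lu = Lv = 20 µm (≈ 0.992 px/µm, consistent with a 600 µm step being
half the 1200 px frame), θ = −5.578°, Δx± = −0.87 %/−0.97 %,
Δy± = −0.95 %/−0.87 % (the tabulated per-600-px mean offsets divided by the
step), image noise σ = 2 intensity units. The distortion factor defaults to
k = 5·10⁻⁸ px⁻² — a printed value of 0.0122 px⁻² is physically impossible
for the r² form (it would displace points by thousands of pixels at
r = 100) and is treated as a typographical artifact; fixtures stay in the
realistic ≤ 10⁻⁷ px⁻² range.

Beyond the engraved grid, the substrate carries a fixed field of
pseudo-random dark speckle marks (dust and engraving defects; 120 000 marks
over ±10 mm, ≈ 330 per field of view, Gaussian cores of 1.5–4 px, excluded
from the grid square plus one pitch of margin). They are not decoration:
a purely periodic target is self-similar under lattice translation, so
stitching would be ill-posed on the synthetic rig exactly as it would be on
a real scale without surrounding features. Each mark is projected through
the full forward model so its subpixel observed position is exactly
consistent with the grid. Displacement series are run on the blank
substrate beside the scale (start offset 1600 µm): the 600 µm step is 12
grid pitches, so grid-rich frames would correlate at the nominal offset and
bias the measured error toward zero — the real procedure has the same
constraint.

What the rig does **not** emulate: microscope PSF and defocus, illumination
gradients and drift, shot noise, stage vibration, backlash hysteresis
beyond the sign-dependent Δ, and thermal drift. Passing recovery tests
therefore demonstrates the estimators' correctness and their noise behavior
under additive Gaussian noise, not robustness to optical artifacts of a
physical instrument.

## Numerical choices

- Inverse distortion (theoretical→observed) is a damped Newton iteration on
  the radial cubic `r + k r³ = r_theo` (tolerance 10⁻¹² px², ≤ 50
  iterations, monotone-radius guard `|3 k r²| < 1`). Whole-image
  undistortion solves the same equation vectorized once per raster geometry
  and resamples with cubic splines.
- The LM fit runs with analytic Jacobian, `xtol = ftol = gtol = 10⁻¹⁴`;
  MINPACK's internal column scaling handles the ~10 orders of magnitude
  between `k` and the intercepts.
- Homography normalization: Frobenius norm 1, largest-magnitude entry
  positive.
- Quadrant boundaries are half-open with the positive-direction error
  applying at 0° and the θ-rotated command direction (not the raw desired
  direction) selecting the quadrant in compensation.
- Trial problem sizes: calibration uses one grid raster and four 10-step
  series; closed-loop suites use 50 single-shot targets and the five
  rectangle classes (5–21 frames, 600 µm steps) with first-vs-last frame
  stitching as the cumulative-error measure. The rectangle classes walk
  1–5 steps per side (the published class table's image counts imply k
  steps per side for class k; its "total step length" column is internally
  inconsistent with those counts and the path length used for the
  linearity analysis is derived from the image counts).

## Known limitations

- `fx`/`fy` (hence M′) inherit any systematic centroid bias of the rendered
  line profile; end-to-end recovery is ~0.05 % on the synthetic rig, well
  inside the 2 % acceptance band but not at the 10⁻⁴ level of the other
  parameters.
- The deflection and mechanical estimates assume pure translation between
  frames; rotation within a series (stage yaw) is out of scope.
- The scalar paper-literal gain is reported for audit only; composing it
  with a displacement magnitude cannot reproduce independent per-axis
  correction.
- Registration accuracy degrades when the expected-offset window is wrong
  by more than half a grid period; all drivers pass the commanded step as
  the expectation.
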