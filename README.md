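# stagecal

Positioning-error calibration and compensation for vision-guided
micromanipulation platforms: an inverted microscope, a camera, and a
motorized X-Y stage. When such a system converts a clicked image position
into a stage command, three systematic errors corrupt the move — nonlinear
(radial) imaging distortion of the optics, the deflection angle between the
camera mounting and the stage axes, and the direction-dependent mechanical
displacement error of the stage. At micromanipulation scales (cell
injection, nucleus transfer) these errors reach micrometres and matter.

`stagecal` estimates each error from calibration imagery of a square grid
target, combines them into one compensation model, and corrects stage
commands with it. A synthetic rig renders the whole acquisition chain with
known ground truth, so every estimator ships with a closed-loop recovery
test.

## The model

Observed pixels relate to theoretical (pinhole) positions by a second-order
radial distortion about the principal point `(u0, v0)`:

    u_theo = u + k (u − u0) r²,   r² = (u − u0)² + (v − v0)²

The plane-to-image map is `λ p̃ = A [R₁₂ | t] P̃`; its decomposition gives the
actual magnification `M = (fx·Lu + fy·Lv)/2` and the ratio `M′ = M/M_nom`.
Stitching stage-stepped frames gives the mounting deflection
`θ = arctan(dy/dx)`, and per-axis stepping experiments give the relative
displacement errors `Δx±, Δy±`. The combined error transform is

    T = M′ · [[1, εy, Δx], [εx, 1, Δy], [0, 0, 1]] · [R | t̂],   εx = −εy = sin θ

and a desired displacement `d` (µm, measured on the image at nominal
magnification) becomes the stage command
`diag(1/(1+Δx), 1/(1+Δy)) · rotate(−θ) · d / M′`, with the `Δ` pair chosen
by the motion quadrant. See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
import stagecal as sc

# a rig with realistic errors: M' = 0.99215, theta = -5.578 deg,
# k = 5e-8 /px^2, per-axis displacement errors ~ -0.9 %
truth = sc.GroundTruth(seed=1)

# calibrate the full model from rendered fixtures
result = sc.calibrate_synthetic(truth)
model = result.model
print(f"M'    = {model.M_prime:.5f}")
print(f"theta = {model.theta_deg:.4f} deg")
print(f"k     = {model.intr.k:.3e} /px^2")

# single-shot test: bring a clicked point to the image centre
rng = np.random.default_rng(2024)
residuals = [
    sc.single_shot_trial(model, truth, rng.uniform([100, 100], [1100, 800]),
                         seed=i).residual_norm
    for i in range(50)
]
print(f"max residual    = {max(residuals):.4f} um")
print(f"median residual = {np.median(residuals):.4f} um")
```

prints (exact k and residuals vary slightly with the noise seed):

```
M'    = 0.99171
theta = -5.5777 deg
k     = 4.996e-08 /px^2
max residual    = 0.0145 um
median residual = 0.0045 um
```

The calibration recovers the injected deflection to well under 0.01° and
the distortion factor to ~0.1 %; with compensation, 50 random positioning
moves land within 0.015 µm of their targets, against a ~32 µm median error
for the uncompensated rig (the mounting rotation dominates).

The same machinery is scriptable from the shell:

```
stagecal simulate --out series/ --axis x --n-steps 10 --seed 1
stagecal deflection --series series/ --axis x --step-px 595
stagecal calibrate --config rig.yaml --out calibration.json
stagecal build-model --calibration calibration.json --out model.json
stagecal compensate --model model.json --dx-um 100 --dy-um 0
```

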