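# Methods

This note records the models implemented in `mcascreen`, their
assumptions, the defaults that matter, and the choices made where the
design was genuinely open. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Optical forward model and its inversion

A multicellular aggregate is modelled as a prolate ellipsoid with
in-plane semi-axes `a ≥ b` (µm) and out-of-plane semi-axis equal to `b`.
The camera sees a 2-D projection, so the out-of-plane extent is not
observable; setting it to `b` makes the center chord of a sphere exactly
its diameter `D`, which is the assumption behind calibrating the
attenuation length against `D`. A cyst carries a concentric shell of
uniform thickness `t`; its lumen is treated as perfectly transparent, so
the optical path is the outer-ellipsoid chord minus the inner-ellipsoid
chord (clamped at zero). Transmitted intensity follows the Beer–Lambert
law `I = I₀ e^(−L/h₀)` per pixel, with optional additive Gaussian noise
(`noise_sd`, relative to `I₀`, default 0 — the camera noise of a real
instrument is not specified, so noise is a configurable robustness knob
rather than a calibrated model). Diffraction, defocus and the refractive
effects of the hydrogel capsule are not rendered; an optional faint dark
ring outside the outline is available for robustness experiments only.

Thickness estimation inverts the same law: `h = h₀ ln(I₀/I) ≥ 0`. The
sign convention is chosen so that thickness is non-negative for an
absorbing tissue (a formulation with `ln(I/I₀)` would be negative).

Defaults: `h₀ = 140 µm` (HEK-like tissue), `I₀ = 1`, 3 µm px⁻¹,
256 × 256 px frames.

## Synthetic populations

Equivalent diameters are drawn from a normal with mean 330 µm and SD
60 µm, truncated below at 50 µm (the lower end of the MCA size range).
Apparent eccentricities are drawn from a Beta distribution with mean
0.57; the Beta concentration (α+β = 5) gives a realistic ~0.2 spread and
support on [0, 1), clipped at 0.95. The in-plane axes solve
`D = 2√(ab)` and `e² = 1 − b²/a²` simultaneously.

Cysts get a monolayer of thickness `t = D/3.24`, so the center chord is
`2t = D/1.62` — the implemented scaling of monolayer thickness with
cyst size. Two constraints follow:

- The concentric shell must fit inside the minor axis (`t < b`), which
  fails for `e ≳ 0.79` at this thickness ratio.
- The bright-center signature that separates cysts from spheroids is
  only guaranteed for thin shells (`t < b/2`). At the default ratio the
  shell is thick (`t ≈ 0.62 b` for a sphere), and for strongly
  elongated cysts (`e ≳ 0.6`) the thin bright rim of the inner region
  genuinely outweighs the center spot, defeating the classifier.

Cyst eccentricities are therefore capped at 0.5 by default
(`cyst_eccentricity_max`). This is a modelling statement, not merely a
numerical convenience: cysts are near-spherical epithelial monolayers,
whereas the 0.57 apparent-eccentricity statistic describes plain
spheroid populations, whose shape is set by the hydrogel capsules they
conform to. Spheroid sampling is unaffected by the cap.

What passing tests on these synthetics do and do not show: they
demonstrate that the pipeline's measurements and calibrations are
self-consistent under the stated optical model, and that the classifier
separates the two phenotypes whenever the lumen produces a real
transmission excess. They do not capture lumen-filled cysts,
non-concentric shells, textured tissue, or optical artefacts, all of
which degrade a real instrument's recall.

## Screening pipeline

Frames are normalised by an object-free background (floor 10⁻⁶ against
division by zero). The mask is the set of pixels below 0.90× background
— the threshold is user-set in practice; 0.90 is the package default and
is configurable. Only the largest connected component is analysed;
frames whose largest component is below 200 px are discarded; a
multi-object flag is raised when more than one component passes the
cutoff (this feeds the sorter's co-detection logic). The Inner region is
a 6-px Euclidean-disk erosion of the mask, the Border the set
difference, and the Center a disk of 11 px diameter about the mask
centroid (rounded to the nearest pixel; one source describes the same
region as an 11-px radius disk — the diameter reading is the default
and the size is configurable).

The perimeter `P` is the Border pixel count, which is what the
instrument logs for the `A^0.5 ∝ P` population plot; because that
border is 6 px thick, a separate single-pixel contour perimeter
(4-direction Crofton estimate) backs the isoperimetric ratio
`circ = 4πA/P_geom²`, which is ≈1 for disks. A note on the `A–P`
scaling constant: for a perfect circle `P_geom = √(4π)·√A`, i.e. the
proportionality constant between `√A` and perimeter is `1/√(4π)`; the
package reports `circ`, from which either convention follows.

The ellipse fit uses the normalised second central moments of the
binary mask (standard region-ellipse estimator). The local background
`I₀` entering the thickness estimate is computed per frame (mean
intensity outside the dilated mask) rather than globally, since
illumination drifts between frames in practice.

Calibration fits are through-origin least squares:
`−ln(I_center/I₀) = D/h₀` over a spheroid series (the reported
attenuation length is the reciprocal slope), and `h = D/k` over a cyst
series using the spheroid-calibrated `h₀`. The through-origin model is
flagged as inadequate when an affine fit halves the residual RMS *and*
the residual exceeds 5% of the mean thickness — the second condition
keeps the small systematic bias of center-disk averaging (a few µm,
strongest for small cysts) from raising false alarms.

## Encapsulation and sorting

Drop loading is Poissonian: `P(Nₛ) = e^(−λ) λ^Nₛ/Nₛ!` with
`λ = C·V_d`. The default `λ = 0.26` corresponds to the practical
operating point (≈5 MCAs mL⁻¹ at 50 µL drops); `λ = 0.1` is the
low-co-encapsulation regime (90% empty drops, <0.5% co-encapsulation).
Drops detach at 3.8 Hz (`T_d = 0.26 s`); on a positive detection the
field is activated for `1.5 T_d` starting one detection lead
(default 10 ms) after the trigger, and overlapping windows merge.

Decision logic: empty drops are never deflected; a single detected
target is; a drop containing any detected waste object is not. For
all-target multi-occupancy drops two policies exist — `strict` (never
deflect multi-occupancy) and `lenient` (deflect if all contents are
targets, the default): the two published descriptions of the rule
differ, so both are implemented and neither is asserted as ground
truth.

Multi-step sorting re-sorts the waste vial: an aggregate is selected if
it is marked target once within `n_steps` attempts, which recovers the
yield lost to co-encapsulation vetoes. Purity is
`n_targets/(n_targets+n_waste)` over the pooled sorted vial (the
alternative reading `n_c/n_s` is inconsistent with a 432/1001 mixture
starting at 43%); yield is the recovered fraction of initial true
targets. Pooled purity is non-decreasing across steps exactly when each
step's additions are purer than the pool — guaranteed in the
recall-limited regime (no false positives), which is how the seeded
property runs are configured. Quartiles use linear interpolation (no
specific estimator is mandated by the source material; the choice is
logged in CLI reports).

Size gating compares the measured diameter with `[D_min, D_max]`
(inclusive by default). Between steps the measured diameter is re-drawn
from the orientation-projection model: a prolate aggregate viewed along
a uniformly random direction projects to an ellipse with semi-axes
`(√(a² sin²ψ + b² cos²ψ), b)`, so the apparent `D` varies between `2b`
and `2√(ab)`. Post-sort distribution summaries are evaluated on
re-measured diameters — the physical re-screening of the sorted vial —
because gate acceptance conditions on the measurement, biasing the
*true*-diameter distribution of accepted objects upward.

## Acoustic field

Each cap holds 36 piston transducers on a sphere of 86 mm curvature
radius centered on the common focus, in rings of 6/12/18. Every
transducer contributes a spherical wave `(drive/r)·Dir(θ)·e^{ikr}` with
the far-field circular-piston directivity `2J₁(ka sinθ)/(ka sinθ)`
(piston radius 4.5 mm, `Dir(0)=1`); the exact directivity correction of
the original device is not published, so this standard form is used and
the aperture is configurable. With in-phase caps the superposition is a
standing wave along the cap axis; the field is linear in the drive, and
node spacing is drive-invariant.

Ring polar angles are not published either; the default is the compact
layout 4°/8°/12°. This choice is deliberate: converging waves at polar
angle θ contribute an axial wavenumber `k cosθ`, so wide layouts
stretch the axial fringe spacing by `1/⟨cosθ⟩` (e.g. ≈4.55 mm for
rings at 8°/16°/24°), while the compact layout reproduces the device's
documented half-wavelength node spacing (λ_a/2 = 4.29 mm at 40 kHz in
air, c₀ = 343 m s⁻¹, ρ₀ = 1.2 kg m⁻³). The simulator places point
piston sources and does not model transducer housing footprints, so
ring compactness carries no packing constraint.

The simulation grid follows the instrument's convention: extents of
4λ_a per axis, steps λ_a/25 along the optical (x) axis and λ_a/50 along
y and z, peak-to-peak amplitudes sampled at 40 instants per period.
Nodes are located as local minima of the peak-to-peak axis profile with
parabolic sub-grid refinement, averaged within ±1.5λ_a of the focus.

Schlieren contrast is modelled as the x-projected pressure gradient
along y (centered differences); shadowgraph contrast as the x-projected
Laplacian, which for sinusoidal fields is proportional to the pressure
itself (∇²p = −k²p) — both are forward models of the optical
observables up to a scale factor, not simulations of the optical bench.

## Radiation force and drop kinematics

The small-drop radiation force is
`F_a = 2π² Φ R_d³ p_a² / (λ_a ρ₀ c₀²)` with contrast factor Φ = 5/6,
valid for `R_d/λ_a < 0.3`; a warning flags evaluations beyond that. The
default 50 µL drop has `R_d = 2.29 mm` and `R_d/λ_a ≈ 0.27` — inside
the validity range (the package computes this ratio rather than
asserting a rounded value). The inversion
`p_a = √(F_a λ_a ρ₀ c₀² / (2π² Φ R_d³))` is exact.

Deflection kinematics are two-phase: constant axial force `F_a`
(default 2.5 × 10⁻⁴ N) for an actuation time `Δt_a` from rest, then
ballistic flight, with gravity throughout, so `z(t) = gt²/2` and the
exit speed is `v₀ = F_a Δt_a/m` with `m = ρ_w V_d = 5 × 10⁻⁵ kg`. The
trajectory is evaluated in closed form — the model is piecewise
constant, so no ODE integrator (and no integrator error) is involved.
`Δt_a` defaults to 0.03 s, a transit time consistent with a strong
(tens of degrees) initial deflection at the default force; the axial
extent of the actuation zone is not published, so `Δt_a` is a free
parameter, not a claimed constant. Air drag, drop-shape oscillation,
acoustic streaming and the position dependence of the force along the
node lines are neglected, consistent with the constant-force reading of
the deflection data. The force is recovered from a sampled trajectory
by registering the time origin on `z(t)` and solving the linear least
squares problem for `F_a` (plus an axial offset); only the pendant-drop
gravity detachment radius `√(γ/ρg)` is computed among the detachment
criteria — the published surface-tension/ARF balance expression is
dimensionally inconsistent as printed and is not reproduced.

## Problem sizes and numerical conventions

Calibration fits use 50 noiseless renders spanning 150–550 µm; the
classifier regression benchmark uses 500 cysts + 500 spheroids at
`noise_sd = 0.02` with fixed seeds; Monte-Carlo occupancy checks use
10⁵ drops; sorting property runs use 600–1200 aggregates over 3 steps.
These sizes make every statistic stable at the asserted tolerances
while keeping the whole suite fast on a single CPU. All random draws go
through seeded `numpy` generators; identical configuration and seed
give bit-identical outputs. Degenerate inputs (empty masks, all-equal
regressors, empty populations, fewer than two field nodes) raise typed
errors rather than returning silent defaults; ties in the phenotype
criterion resolve to "spheroid".

## Known limitations

- The optical model omits scattering anisotropy, diffraction and
  defocus: the attenuation length acts as an effective parameter.
- The shell of the hydrogel capsule is not rendered by default, so
  capsule-touching artefacts of real images are unmodelled.
- Multi-frame tracking (velocity/rotation histograms) is out of scope;
  arrival streams are memoryless by construction.
- The acoustic model is linear superposition of point pistons: no
  transducer electro-mechanics, no scattering by the capillary, no
  streaming.
- Sample-dependent published outcomes (post-sort purity/yield values,
  per-step population counts) are not reproduced numerically; the
  corresponding behaviour is verified as distributional properties on
  synthetic populations.
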