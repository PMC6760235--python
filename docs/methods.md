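# Methods

This note documents the physical model, the synthetic-data generator,
the numerical design of the solvers, and what the tests do and do not
demonstrate.

## Sensor model

The coded wavefront sensor is an intensity sensor with a random binary
phase mask (features of 12.9 µm, phase 0 or π at the nominal
wavelength) a distance *z* in front of it. Under collimated
illumination the mask produces a diffraction speckle pattern *I*₀ on
the sensor. A thin sample conjugated to the mask plane with complex
transmission *A*(**r**)·exp[jφ(**r**)] modifies the measurement to

    I(r + (λz/2π)∇φ) = |A(r)|² (1 − (λz/2π)∇²φ) I₀(r)

— the speckle translates with the wavefront slope and dims/brightens
with the wavefront curvature (caustic factor). A first-order Taylor
expansion of the left side recovers the transport-of-intensity
equation, which the package implements both as a predictor
(`tie_predict`, lagged fixed point) and as the classical two-step
Poisson inversion (`tie_solve`).

All lengths are micrometres. Phase and OPD are related by
φ = 2π·OPD/λ at the nominal wavelength λ = 0.5328 µm; every model
quantity depends on OPD only (λ cancels in the shift (λz/2π)∇φ =
z∇OPD and in the caustic factor), which is why a single nominal
wavelength faithfully stands in for broadband illumination of a weakly
dispersive sample.

Default geometry: *z* = 1430 µm (the calibrated mean), sensor pitch
6.45 µm, mask pitch 12.9 µm. The theoretical wavefront-curvature limit
of the model is |∇²OPD| ≪ 1/z (≈ 700 m⁻¹ here); expressed for a
sinusoidal OPD = H·cos(ωx) it bounds the amplitude by H ≪ 1/(zω²).

## Wave-optics simulator (the study conditions)

The simulator is the ground truth against which every reconstruction is
scored; it emulates:

- **Mask**: i.i.d. uniform binary features, seeded and reproducible,
  upsampled to the simulation grid by nearest neighbour. The rendered
  phase profile is smoothed with a Gaussian of σ = 3–4 µm (default 4)
  to model the band-limiting effects of the real acquisition chain —
  broadband illumination averaging out fine interference structure,
  optical and sensor MTF, and fabrication edge rounding — which a
  strictly monochromatic, sharp-edged simulation omits. The design
  point was chosen so the speckle spectrum satisfies the sensor's
  sampling design premise: ≲ 4% of the speckle intensity power lies
  beyond the pixel Nyquist frequency (a perfectly sharp monochromatic
  mask would put ~34% there, and that aliased power acts as
  displacement-independent noise that biases every flow estimator).
- **Propagation**: exact scalar angular-spectrum transfer function,
  evanescent components removed, plus the standard anti-aliasing band
  limit for long throws. Energy in the retained band is conserved to
  1e−6.
- **Sensing**: 4× lateral oversampling of the sensor pitch, area
  integration (box average) over each pixel, and a 32-pixel guard
  border, cropped from outputs, that absorbs the spectral method's
  periodic wrap-around. Sample fields are tapered to unity over the
  guard band (raised cosine) for the same reason.
- **Noise**: optional Poisson shot noise and Gaussian read noise
  (`add_sensor_noise`); all accuracy tests run noise-free, so the
  quoted recovery errors measure model + algorithm fidelity, not
  photon statistics.

What the simulator does **not** model: spectrally integrated
(polychromatic) speckle, partial spatial coherence, sensor nonlinearity
and fixed-pattern noise, and real microscope aberrations. Passing tests
therefore demonstrate correctness of the model and solver under ideal
collimated, monochromatic-equivalent conditions; absolute accuracies on
laboratory data will be lower.

## Phantoms

Every phantom stores the analytic parameters it was built from, so
recovery errors are computed against exact truth:

- **Microlens array**: plano-convex spherical caps, radius of curvature
  R = f(n−1) (thin-lens; the design back focal length 6.7 mm and
  fused-silica n = 1.46 at the nominal wavelength are the defaults),
  tiled at 150 µm. An optional `magnification` images the array at ×M:
  lateral coordinates stretch, OPD is unchanged, so slopes fall by M
  and curvatures by M². Recovery tests use M = 6, which puts one
  lenslet across the 128² test sensor with ≤ 0.6 px speckle shifts and
  a caustic factor ≥ 0.98 — inside the model's validity region, as a
  lenslet imaged at high magnification is in the laboratory.
- **Sinusoid** OPD = H·cos(ωx) for transfer-function measurements
  (peak curvature Hω²).
- **Constant curvature** OPD = (c/4)(x²+y²) with exactly constant
  discrete Laplacian.
- **Torus cell**: difference of two concentric Gaussians (ring maximum,
  bowl-like central indentation, peak OPD 0.4 µm by default) with an
  optional central transmission dip — the absorption/refraction-tangle
  fixture. Its parameters are test fixtures chosen to resemble red
  blood cell images at high magnification, not measured values.

## Joint reconstruction

Variables: phase φ (radians at the nominal wavelength) and modulated
intensity m = |Ã|² = |A|²(1 − (λz/2π)∇²φ). Images are normalized to
0–255; the default tradeoff weights α = 0.1, β = 0.1, γ = 100, τ = 5
assume that scale. Discrete operators are forward differences with
replicate boundary and the matching 5-point Laplacian, chosen so the
gradient/divergence pair is exactly adjoint (this also makes the DCT
Poisson solver an exact inverse for slope integration).

The minimization alternates (3 outer iterations by default):

1. **Phase step.** The warped data term is linearized around the
   current φ (Gauss–Newton, 3 relinearizations; Jacobian from the
   warped measurement's own gradients — the inverse-compositional
   choice). Each linearized subproblem is solved by a scaled-form ADMM
   that splits off the ℓ₁ gradient prior (soft thresholding) and
   solves the coupled quadratic by conjugate gradients with a
   DCT-diagonal preconditioner. Because the Jacobian is a directional
   derivative along the local speckle gradient, the subproblem is
   nearly singular along speckle iso-contours at the printed prior
   weights; a Levenberg–Marquardt trust region on the *displacement
   step*, μ‖∇(φ−φ₀)‖² with μ proportional to the mean squared speckle
   gradient, regularizes the step without suppressing low-frequency
   wavefront components (an identity damping would). Steps are
   accepted only if the true objective decreases; otherwise the
   damping grows.
2. **Intensity step.** Per-pixel least squares in m with the ℓ₁
   gradient/Laplacian priors handled by the same ADMM machinery. The
   ADMM penalty is scaled to the mean per-pixel data curvature
   ⟨I₀²⟩ (≈ 10⁴ for 0–255 images) so the splitting constraint binds
   within a few iterations. The candidate is kept only if it lowers
   the full objective. The phase step runs first in each alternation:
   letting the intensity update absorb unexplained *displacement*
   residual stalls the phase recovery.

**Initialization.** φ starts from one cheap pass of windowed subpixel
speckle tracking (16-px windows) integrated by the curl-free Poisson
solver, and m from 1. This registers the image pair to well under a
pixel, keeps the Gauss–Newton refinement inside its basin for shifts of
several pixels (no coarse-to-fine pyramid is needed — box-downsampled
speckle loses its trackable grain, which is why a pyramid was rejected),
and leaves residuals small enough that the intensity step cannot absorb
displacement signal.

**Data-term support.** The warped residual is tapered to zero over a
4-pixel border (raised cosine): where **r** + **u** leaves the frame
the model is undefined, and boundary replication artifacts would
otherwise dominate the fit. Priors remain global.

**Outputs.** The objective trace is non-increasing by construction
(accept/reject); the returned wavefront is tilt-removed (least-squares
affine plane) and zero-mean, matching the post-processing used on
laboratory data; the amplitude is caustic-corrected via
A = Ã·√(1 + (λz/2π)∇²φ) with the radicand clamped at 10⁻³ (clamp
count reported in the diagnostics). For the model-evaluation Laplacian
(caustic factor, amplitude correction) boundary pixels use one-sided
second differences so a pure tilt carries zero curvature; the solver's
adjoint-consistent operator pair is unchanged.

**Baselines.** `track_and_integrate` is classical windowed
cross-correlation slope tracking (textureless windows flagged and
inpainted from neighbours) followed by least-squares curl-free
integration; `curl_free_flow` is the joint machinery with the
amplitude frozen at one (displacement parameterized directly as a
phase gradient). Both ignore the amplitude/caustic coupling, which is
what the joint solver's advantage on absorbing samples demonstrates.

## Refocusing and calibration

The recovered (amplitude, OPD) pair defines a complex field at the
nominal wavelength that can be propagated to any defocus by the angular
spectrum method. The best-focus search sweeps Δf, measures the
half-energy beam radius at each plane, and fits the geometric V-shape
r = c·|Δf − z_f| to its wings, excluding the diffraction-rounded
vertex. This estimates the *geometric* focus, which is what a
manufacturer's back focal length specifies. The conventional
peak-intensity metric is offered as an alternative, but for a lenslet
of Fresnel number a²/(λf) ≈ 1.6 the axial intensity peak sits ~11%
short of the geometric focus (the classical focal-shift effect), so it
cannot reproduce the design focal length; the phase cross-sections
likewise flatten at the shifted beam waist, not at f.

Distance calibration inverts the shift law per applied tilt
(z = shift·pitch·(2π/λ)/slope) and averages. The closed-loop synthetic
experiment (simulate at a known z, apply tilts spanning 0.5–3 px,
track, invert) recovers z to well within 2%; shifts below ~0.3 px are
avoided because subpixel correlation bias grows sharply there.

The phase transfer function is measured empirically: sinusoid phantoms
over an (H, ω) grid are pushed through the wave simulator and
reconstructed; the score is valid = clip(1 − relative RMS error, 0, 1).
Degradation is monotone in the peak curvature Hω², and recovery
collapses as Hω² approaches the 1/z bound — the empirical failure
onset sits well below the theoretical bound, consistent with reading
"≪" as an order of magnitude.

## Numerical sizes used in the tests

Accuracy tests run on 128² sensor pixels (simulation grids 768² at
1.6125 µm pitch), refocusing on 512² field grids at 1.2 µm, and the
calibration loop on 192²–256² images; these sizes put every quoted
statistic at a few seconds to tens of seconds per case while leaving
speckle statistics (≈ 40 grains across the field) representative.
Quoted recovery errors: ≤ 5% of the OPD range for microlens, constant
curvature, and torus phantoms through the full wave-optics pipeline at
speckle shifts up to ~3 px; the joint solver is at least as accurate as
both sequential baselines on the absorbing torus.

## Known limitations

- The ~9% of speckle power that a sharp monochromatic mask would alias
  is suppressed by the mask-smoothing model rather than by an explicit
  spectral integration; simulations of dispersion-related effects are
  out of scope.
- The amplitude/caustic decomposition is ill-conditioned where
  wavefront curvature approaches 1/z; the solver clamps rather than
  fails, and the recovered bright-field image inherits the ambiguity
  (as it does in the laboratory instrument).
- Recovery accuracy degrades for OPD structure whose period approaches
  the tracking window (16 px) at small amplitudes — visible as
  validity < 1 in the transfer function even inside the curvature
  bound.
- The solver's printed runtimes are CPU-bound Python/NumPy; no GPU
  path is provided.
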