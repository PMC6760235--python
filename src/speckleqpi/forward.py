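"""Geometric (ray-optics) forward model of the coded sensor and its TIE limit.

The sensor encodes a wavefront ``phi`` into speckle motion:
``I(r + (lambda z / 2 pi) grad(phi)) = |A|^2 (1 - (lambda z / 2 pi) lap(phi)) I0(r)``.
The displacement term is the tilt->shift law; the parenthesised factor is
the caustic (local focusing) intensity modulation.  First-order Taylor
expansion of the warped intensity recovers the transport-of-intensity
equation, implemented here both as a predictor and as the classical
two-Poisson-solve inversion.

Because ``(lambda/2pi) grad(phi) = grad(OPD)``, everything below is
wavelength-invariant at fixed OPD; phases are formed at the nominal
wavelength purely for bookkeeping.
"""

from __future__ import annotations

import warnings

import numpy as np

from ._operators import (div, grad, image_gradient_centered, laplacian,
                         poisson_solve_neumann, warp_image)
from .fields import IntensityImage, WavefrontMap
from .geometry import SensorGeometry
from .phantoms import SamplePhantom


class ModelValidityError(RuntimeError):
    """The small-curvature ray model does not hold for this input."""


#: Displacement (sensor pixels) above which the warp model is suspect.
MAX_TRUSTED_DISPLACEMENT_PX = 10.0

#: Curvature factor below which the linearised caustic term is suspect.
MIN_TRUSTED_FACTOR = 0.5


def opd_laplacian_per_um(wavefront: WavefrontMap) -> np.ndarray:
    """``lap(OPD)`` in 1/um.

    Interior pixels see the standard 5-point stencil (composed central
    differences); boundary pixels use one-sided differences so that a
    pure tilt carries zero curvature everywhere instead of a spurious
    caustic ring at the frame edge.
    """
    def second_diff(u: np.ndarray, axis: int) -> np.ndarray:
        u = np.moveaxis(u, axis, 0)
        d = np.empty_like(u)
        d[1:-1] = u[2:] - 2.0 * u[1:-1] + u[:-2]
        d[0] = u[2] - 2.0 * u[1] + u[0]
        d[-1] = u[-3] - 2.0 * u[-2] + u[-1]
        return np.moveaxis(d, 0, axis)

    opd = wavefront.opd_um
    return (second_diff(opd, 1) + second_diff(opd, 0)) / wavefront.pitch_um**2


def curvature_factor(wavefront: WavefrontMap, geometry: SensorGeometry) -> np.ndarray:
    """The caustic factor ``1 - (lambda z / 2 pi) lap(phi) = 1 - z lap(OPD)``.

    Raises :class:`ModelValidityError` where the factor is nonpositive
    (ray crossing: the linearised model has no meaning there) and warns
    when it strays below 0.5.
    """
    factor = 1.0 - geometry.z_um * opd_laplacian_per_um(wavefront)
    if np.any(factor <= 0.0):
        raise ModelValidityError(
            "curvature factor is nonpositive somewhere: wavefront curvature "
            "exceeds the 1/z caustic limit of the ray model"
        )
    if factor.min() < MIN_TRUSTED_FACTOR:
        warnings.warn(
            f"curvature factor dips to {factor.min():.3f}; the small-curvature "
            "expansion is unreliable below 0.5",
            stacklevel=2,
        )
    return factor


def displacement_px(wavefront: WavefrontMap, geometry: SensorGeometry
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Speckle displacement ``(lambda z / 2 pi) grad(phi)`` in sensor pixels.

    Forward differences, Neumann boundary; equals ``z grad(OPD) / pitch``.
    """
    gx, gy = grad(wavefront.opd_um)
    scale = geometry.z_um / wavefront.pitch_um**2
    return gx * scale, gy * scale


def geometric_forward(I0: IntensityImage, sample: SamplePhantom,
                      geometry: SensorGeometry) -> IntensityImage:
    """Model-consistent measurement image from a reference and a sample.

    Implements the warped ray model by inverse-map resampling: the output
    at pixel ``x`` is ``|A|^2 (1 - z lap(OPD)) I0`` sampled at
    ``x - u(x)`` with cubic interpolation, where ``u`` is the speckle
    displacement.  Away from boundaries the flux of ``|A|^2 I0`` is
    preserved to within the interpolation error.
    """
    if I0.shape != sample.shape:
        raise ValueError(f"grids differ: I0 {I0.shape} vs sample {sample.shape}")
    wf = sample.wavefront
    ux, uy = displacement_px(wf, geometry)
    dmax = float(np.hypot(ux, uy).max())
    if dmax > MAX_TRUSTED_DISPLACEMENT_PX:
        warnings.warn(
            f"max speckle displacement {dmax:.1f} px exceeds the trusted range "
            f"({MAX_TRUSTED_DISPLACEMENT_PX:.0f} px) of the first-order warp",
            stacklevel=2,
        )
    source = sample.amplitude**2 * curvature_factor(wf, geometry) * I0.data
    warped = warp_image(source, -ux, -uy, order=3)
    return IntensityImage(data=np.clip(warped, 0.0, None), pitch_um=I0.pitch_um)


def tie_predict(I1: IntensityImage, wavefront: WavefrontMap,
                z_um: float, wavelength_um: float,
                max_iters: int = 50, tol: float = 1e-10) -> IntensityImage:
    """Defocused image ``I2`` from the TIE, by lagged fixed-point iteration.

    Solves ``grad(I2) . grad(phi) + I1 lap(phi) = (k/z)(I1 - I2)`` for
    ``I2``, evaluating the ``grad(I2)`` term at the previous iterate
    (starting from ``I2 = I1``).
    """
    if I1.shape != wavefront.shape:
        raise ValueError("I1 and wavefront grids must be congruent")
    k = 2.0 * np.pi / wavelength_um
    pitch = I1.pitch_um
    phi = 2.0 * np.pi * wavefront.opd_um / wavelength_um
    gpx, gpy = grad(phi)
    gpx, gpy = gpx / pitch, gpy / pitch
    lap_phi = laplacian(phi) / pitch**2
    I2 = I1.data.copy()
    scale = z_um / k
    ref = max(float(np.abs(I1.data).max()), 1e-30)
    for _ in range(max_iters):
        g2x, g2y = image_gradient_centered(I2)
        new = I1.data - scale * ((g2x / pitch) * gpx + (g2y / pitch) * gpy
                                 + I1.data * lap_phi)
        step = float(np.abs(new - I2).max())
        I2 = new
        if step < tol * ref:
            break
    else:
        raise RuntimeError("TIE fixed point did not converge within "
                           f"{max_iters} iterations")
    return IntensityImage(data=np.clip(I2, 0.0, None), pitch_um=pitch)


def tie_solve(I1: IntensityImage, I2: IntensityImage,
              z_um: float, wavelength_um: float) -> WavefrontMap:
    """Classical two-step TIE inversion (two Neumann Poisson solves).

    Solves ``div(I1 grad(phi)) = (k/z)(I1 - I2)`` by first solving
    ``lap(psi) = (k/z)(I1 - I2)``, dividing ``grad(psi)`` by ``I1``, and
    solving a second Poisson equation for the zero-mean ``phi``.
    The mask-free TIE setting assumes unit sample amplitude.
    """
    if I1.shape != I2.shape:
        raise ValueError("I1 and I2 must be congruent")
    if np.any(I1.data <= 0):
        raise ValueError("I1 must be strictly positive for TIE inversion")
    k = 2.0 * np.pi / wavelength_um
    pitch = I1.pitch_um
    rhs = (k / z_um) * (I1.data - I2.data)
    psi = poisson_solve_neumann(rhs * pitch**2)
    gx, gy = grad(psi)
    gx, gy = gx / I1.data, gy / I1.data
    phi = poisson_solve_neumann(div(gx, gy))
    phi -= phi.mean()
    return WavefrontMap.from_phase(phi, pitch_um=pitch, wavelength_um=wavelength_um)
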