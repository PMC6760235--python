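"""Synthetic sample fields (amplitude + OPD) with analytic ground truth.

Each generator returns a :class:`SamplePhantom` carrying the exact
parameters it was built from, so downstream recovery errors can be
computed against stored truth without re-derivation.  Phantoms are
analytic in the pixel-centred coordinates, so the same phantom can be
evaluated consistently on the sensor grid and on the finer simulation
grid.

An optional ``magnification`` models imaging the object through a
microscope at x``M``: lateral coordinates stretch by ``M`` while the OPD
profile is unchanged (phase is conserved along rays), which divides
wavefront slopes by ``M`` and curvatures by ``M^2`` at the sensor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fields import ComplexField, WavefrontMap, pixel_coords
from .geometry import NOMINAL_WAVELENGTH_UM


@dataclass
class SamplePhantom:
    """A synthetic sample: nonnegative amplitude ``A`` and OPD wavefront."""

    amplitude: np.ndarray
    wavefront: WavefrontMap
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.amplitude.shape != self.wavefront.shape:
            raise ValueError("amplitude and wavefront grids must be congruent")
        if np.any(self.amplitude < 0) or np.any(self.amplitude > 1.0 + 1e-12):
            raise ValueError("amplitude must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.amplitude.shape

    def to_field(self) -> ComplexField:
        """The sample's complex transmission at the nominal wavelength."""
        return ComplexField(amplitude=self.amplitude,
                            phase_rad=self.wavefront.phase_rad,
                            pitch_um=self.wavefront.pitch_um,
                            wavelength_um=self.wavefront.wavelength_um)


def microlens_phantom(pitch_um: float, focal_mm: float, n: float,
                      grid: tuple[int, int], sample_pitch_um: float,
                      magnification: float = 1.0,
                      wavelength_um: float = NOMINAL_WAVELENGTH_UM) -> SamplePhantom:
    """Square-grid plano-convex microlens array.

    Lenslets are spherical caps with radius of curvature
    ``R = f (n - 1)`` (thin lens), tiled at ``pitch_um``.  The OPD is
    ``(n - 1)`` times the local glass thickness, normalized to zero at
    the thinnest point (cell corners); unit amplitude.
    """
    if focal_mm <= 0:
        raise ValueError("focal_mm must be positive")
    if not 1.0 < n < 2.0:
        raise ValueError("refractive index must lie in (1, 2)")
    if magnification <= 0:
        raise ValueError("magnification must be positive")
    p = pitch_um * magnification
    if p < 2 * sample_pitch_um:
        raise ValueError("lenslet pitch must span at least 2 grid samples")
    focal_um = focal_mm * 1000.0
    X, Y = pixel_coords(grid, sample_pitch_um)
    if np.isinf(focal_um):
        opd = np.zeros(grid)
        R = np.inf
        edge_drop = 0.0
    else:
        R = focal_um * (n - 1.0)  # object-side radius of curvature, um
        r_corner = (pitch_um / 2.0) * np.sqrt(2.0)
        if r_corner > R:
            raise ValueError(
                f"lenslet corner radius {r_corner:.1f} um exceeds the surface "
                f"radius of curvature {R:.1f} um; such a lens cannot be cut"
            )
        # fold into one cell, object-plane radial coordinate
        Xl = ((X + p / 2.0) % p - p / 2.0) / magnification
        Yl = ((Y + p / 2.0) % p - p / 2.0) / magnification
        sag = R - np.sqrt(R**2 - Xl**2 - Yl**2)
        sag_corner = R - np.sqrt(R**2 - r_corner**2)
        opd = (n - 1.0) * (sag_corner - sag)
        a = pitch_um / 2.0
        edge_drop = (n - 1.0) * (R - np.sqrt(R**2 - a**2))
    wf = WavefrontMap(opd_um=opd, pitch_um=sample_pitch_um, wavelength_um=wavelength_um)
    truth = {
        "kind": "microlens",
        "pitch_um": pitch_um,
        "focal_um": focal_um,
        "n": n,
        "radius_of_curvature_um": R,
        "magnification": magnification,
        "center_to_edge_drop_um": edge_drop,
    }
    return SamplePhantom(amplitude=np.ones(grid), wavefront=wf, truth=truth)


def sinusoid_phantom(H_um: float, omega_rad_per_um: float,
                     grid: tuple[int, int], sample_pitch_um: float,
                     wavelength_um: float = NOMINAL_WAVELENGTH_UM) -> SamplePhantom:
    """One-dimensional cosine OPD, ``OPD(x, y) = H cos(omega x)``.

    The largest OPD curvature is ``H omega^2``, stored in the truth
    metadata; it is the quantity the wavefront-resolution bound
    ``H << 1/(z omega^2)`` constrains.
    """
    nyquist = np.pi / sample_pitch_um
    if omega_rad_per_um < 0:
        raise ValueError("omega must be nonnegative")
    if omega_rad_per_um > nyquist:
        raise ValueError(
            f"omega {omega_rad_per_um} rad/um exceeds the grid Nyquist {nyquist:.3f}"
        )
    X, _ = pixel_coords(grid, sample_pitch_um)
    opd = H_um * np.cos(omega_rad_per_um * X)
    wf = WavefrontMap(opd_um=opd, pitch_um=sample_pitch_um, wavelength_um=wavelength_um)
    truth = {
        "kind": "sinusoid",
        "H_um": H_um,
        "omega_rad_per_um": omega_rad_per_um,
        "max_curvature_per_um": H_um * omega_rad_per_um**2,
    }
    return SamplePhantom(amplitude=np.ones(grid), wavefront=wf, truth=truth)


def curvature_phantom(curvature_per_m: float, grid: tuple[int, int],
                      sample_pitch_um: float,
                      wavelength_um: float = NOMINAL_WAVELENGTH_UM) -> SamplePhantom:
    """Constant-curvature (defocus) OPD with ``laplacian(OPD) = c`` everywhere."""
    if not np.isfinite(curvature_per_m):
        raise ValueError("curvature must be finite")
    c_per_um = curvature_per_m * 1e-6  # 1/m -> 1/um
    X, Y = pixel_coords(grid, sample_pitch_um)
    opd = (c_per_um / 4.0) * (X**2 + Y**2)
    wf = WavefrontMap(opd_um=opd, pitch_um=sample_pitch_um, wavelength_um=wavelength_um)
    truth = {"kind": "curvature", "curvature_per_m": curvature_per_m}
    return SamplePhantom(amplitude=np.ones(grid), wavefront=wf, truth=truth)


def cell_phantom(kind: str, params: dict | None, grid: tuple[int, int],
                 sample_pitch_um: float,
                 wavelength_um: float = NOMINAL_WAVELENGTH_UM) -> SamplePhantom:
    """Parametric cell-like OPD phantoms.

    ``torus``: a difference of two concentric Gaussians giving a ring
    maximum with a bowl-like central indentation (a red-blood-cell-like
    profile); an optional amplitude dip inside the cell couples
    absorption with refraction.  ``blob``: a single Gaussian mound.

    Parameters (``params`` keys, all optional): ``radius_um`` outer
    Gaussian sigma (default 150), ``dip_fraction`` relative depth of the
    inner Gaussian (torus only, default 0.5), ``peak_opd_um`` maximum OPD
    (default 0.4), ``amplitude_dip`` central transmission drop in [0, 1)
    (default 0), ``center_um`` (x, y) offset.
    """
    if kind not in ("torus", "blob"):
        raise ValueError(f"unknown cell phantom kind {kind!r}")
    p = dict(params or {})
    radius = float(p.pop("radius_um", 150.0))
    dip = float(p.pop("dip_fraction", 0.5))
    peak = float(p.pop("peak_opd_um", 0.4))
    amp_dip = float(p.pop("amplitude_dip", 0.0))
    cx, cy = p.pop("center_um", (0.0, 0.0))
    if p:
        raise ValueError(f"unknown cell phantom parameters: {sorted(p)}")
    if not 0.0 <= amp_dip < 1.0:
        raise ValueError("amplitude_dip must lie in [0, 1)")
    X, Y = pixel_coords(grid, sample_pitch_um)
    r_sq = (X - cx) ** 2 + (Y - cy) ** 2
    outer = np.exp(-r_sq / (2.0 * radius**2))
    if kind == "torus":
        inner = np.exp(-r_sq / (2.0 * (radius / 2.0) ** 2))
        profile = outer - dip * inner
    else:
        profile = outer
    top = profile.max()
    opd = peak * profile / top if top > 0 else np.zeros(grid)
    amplitude = 1.0 - amp_dip * outer
    wf = WavefrontMap(opd_um=opd, pitch_um=sample_pitch_um, wavelength_um=wavelength_um)
    truth = {
        "kind": kind,
        "radius_um": radius,
        "dip_fraction": dip if kind == "torus" else 0.0,
        "peak_opd_um": peak,
        "amplitude_dip": amp_dip,
        "center_um": (cx, cy),
    }
    return SamplePhantom(amplitude=amplitude, wavefront=wf, truth=truth)
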