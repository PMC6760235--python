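"""In-memory containers for images, wavefronts and sampled complex fields.

All lengths are micrometres.  Grids are row-major 2-D arrays with the
pixel-centred convention: the coordinate origin sits at the grid centre,
``x`` runs along columns (axis 1) and ``y`` along rows (axis 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import NOMINAL_WAVELENGTH_UM, SensorGeometry


def pixel_coords(shape: tuple[int, int], pitch_um: float) -> tuple[np.ndarray, np.ndarray]:
    """Return meshgrid ``(X, Y)`` in um, origin at the grid centre."""
    ny, nx = shape
    x = (np.arange(nx) - (nx - 1) / 2.0) * pitch_um
    y = (np.arange(ny) - (ny - 1) / 2.0) * pitch_um
    return np.meshgrid(x, y)


def _as_2d_float(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2:
        raise ValueError(f"{name} must be a 2-D array, got shape {a.shape}")
    return a


@dataclass
class IntensityImage:
    """Nonnegative irradiance map on a pixel grid (reference I0, measurement I, ...)."""

    data: np.ndarray
    pitch_um: float

    def __post_init__(self) -> None:
        self.data = _as_2d_float(self.data, "data")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensity contains non-finite values")
        if np.any(self.data < 0):
            raise ValueError("intensity must be nonnegative")
        if self.pitch_um <= 0:
            raise ValueError("pitch_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class WavefrontMap:
    """Scalar optical path difference field, in micrometres.

    OPD relates to phase at the nominal wavelength by
    ``phi = 2 pi * OPD / lambda`` (exactly, both ways).
    """

    opd_um: np.ndarray
    pitch_um: float
    wavelength_um: float = NOMINAL_WAVELENGTH_UM

    def __post_init__(self) -> None:
        self.opd_um = _as_2d_float(self.opd_um, "opd_um")
        if not np.all(np.isfinite(self.opd_um)):
            raise ValueError("OPD contains non-finite values")
        if self.pitch_um <= 0 or self.wavelength_um <= 0:
            raise ValueError("pitch_um and wavelength_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.opd_um.shape

    @property
    def phase_rad(self) -> np.ndarray:
        return 2.0 * np.pi * self.opd_um / self.wavelength_um

    @classmethod
    def from_phase(
        cls, phase_rad: np.ndarray, pitch_um: float, wavelength_um: float = NOMINAL_WAVELENGTH_UM
    ) -> "WavefrontMap":
        phase_rad = np.asarray(phase_rad, dtype=float)
        return cls(opd_um=wavelength_um * phase_rad / (2.0 * np.pi),
                   pitch_um=pitch_um, wavelength_um=wavelength_um)


@dataclass
class ComplexField:
    """Sampled scalar field ``A(r) * exp(j phi(r))`` with grid metadata."""

    amplitude: np.ndarray
    phase_rad: np.ndarray
    pitch_um: float
    wavelength_um: float = NOMINAL_WAVELENGTH_UM

    def __post_init__(self) -> None:
        self.amplitude = _as_2d_float(self.amplitude, "amplitude")
        self.phase_rad = _as_2d_float(self.phase_rad, "phase_rad")
        if self.amplitude.shape != self.phase_rad.shape:
            raise ValueError("amplitude and phase grids must be congruent")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be nonnegative")
        if self.wavelength_um <= 0:
            raise ValueError("wavelength_um must be positive")
        if self.pitch_um <= 0:
            raise ValueError("pitch_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.amplitude.shape

    @property
    def values(self) -> np.ndarray:
        """The complex samples ``A * exp(j phi)``."""
        return self.amplitude * np.exp(1j * self.phase_rad)

    @classmethod
    def from_values(
        cls, values: np.ndarray, pitch_um: float, wavelength_um: float = NOMINAL_WAVELENGTH_UM
    ) -> "ComplexField":
        values = np.asarray(values, dtype=complex)
        return cls(amplitude=np.abs(values), phase_rad=np.angle(values),
                   pitch_um=pitch_um, wavelength_um=wavelength_um)

    def energy(self) -> float:
        return float(np.sum(self.amplitude**2))


@dataclass
class SlopeField:
    """Speckle displacement field in sensor pixels.

    ``dx_px``/``dy_px`` are the optically encoded shifts
    ``(lambda z / 2 pi) grad(phi) / pitch`` along x (columns) and y (rows).
    """

    dx_px: np.ndarray
    dy_px: np.ndarray
    geometry: SensorGeometry
    valid: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.dx_px = _as_2d_float(self.dx_px, "dx_px")
        self.dy_px = _as_2d_float(self.dy_px, "dy_px")
        if self.dx_px.shape != self.dy_px.shape:
            raise ValueError("dx_px and dy_px must be congruent")
        if not (np.all(np.isfinite(self.dx_px)) and np.all(np.isfinite(self.dy_px))):
            raise ValueError("slope field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dx_px.shape

    def wavefront_slopes_rad_per_um(self) -> tuple[np.ndarray, np.ndarray]:
        """Wavefront slopes ``theta = (lambda/2pi) grad(phi)`` in radians."""
        s = self.geometry.sensor_pitch_um / self.geometry.z_um
        return self.dx_px * s, self.dy_px * s
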