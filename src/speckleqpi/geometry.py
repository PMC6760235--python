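"""Sensor geometry of the coded wavefront sensor.

The sensor is an ordinary intensity sensor with a random binary (0/pi)
phase mask mounted a short distance ``z`` in front of it.  A wavefront
with local slope ``grad(phi)`` translates the mask's diffraction speckle
pattern on the sensor by ``(lambda * z / 2 pi) * grad(phi)``; all
reconstruction and calibration code derives its pixel/slope scaling from
this object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Nominal wavelength in micrometres used throughout for OPD <-> phase
#: conversion under broadband illumination.
NOMINAL_WAVELENGTH_UM = 0.5328

#: Default calibrated mask-to-sensor distance in micrometres.
DEFAULT_Z_UM = 1430.0

#: Default sensor pixel pitch in micrometres.
DEFAULT_SENSOR_PITCH_UM = 6.45

#: Default mask feature pitch in micrometres.
DEFAULT_MASK_PIXEL_UM = 12.9


@dataclass(frozen=True)
class SensorGeometry:
    """Geometry of the mask + sensor assembly.

    Parameters
    ----------
    z_um : float
        Mask-to-sensor distance in micrometres (calibrated; default the
        calibrated mean 1.43 mm).
    wavelength_um : float
        Nominal wavelength in micrometres.
    sensor_pitch_um : float
        Sensor pixel pitch in micrometres.
    mask_pixel_um : float
        Mask feature pitch in micrometres.
    """

    z_um: float = DEFAULT_Z_UM
    wavelength_um: float = NOMINAL_WAVELENGTH_UM
    sensor_pitch_um: float = DEFAULT_SENSOR_PITCH_UM
    mask_pixel_um: float = DEFAULT_MASK_PIXEL_UM

    def __post_init__(self) -> None:
        for name in ("z_um", "wavelength_um", "sensor_pitch_um", "mask_pixel_um"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v!r}")

    @property
    def k_um(self) -> float:
        """Wavenumber ``2 pi / lambda`` in rad/um (derived, never stored)."""
        return 2.0 * np.pi / self.wavelength_um

    @property
    def shift_scale_um(self) -> float:
        """``lambda * z / 2 pi`` in um^2: phase slope (rad/um) -> lateral shift (um)."""
        return self.wavelength_um * self.z_um / (2.0 * np.pi)

    @property
    def phase_to_shift_px(self) -> float:
        """Displacement in sensor pixels per unit per-pixel phase difference (rad).

        A per-pixel forward difference of the phase map equals
        ``grad(phi) * pitch``; the optical shift in pixels is then
        ``(lambda z / 2 pi) * grad(phi) / pitch``, i.e. this factor times
        the per-pixel difference.
        """
        return self.shift_scale_um / self.sensor_pitch_um**2

    def with_z(self, z_um: float) -> "SensorGeometry":
        return SensorGeometry(
            z_um=z_um,
            wavelength_um=self.wavelength_um,
            sensor_pitch_um=self.sensor_pitch_um,
            mask_pixel_um=self.mask_pixel_um,
        )
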