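"""Sensor calibration and wavefront-resolution analysis.

The mask-to-sensor distance ``z`` sets the scale between wavefront
slopes and speckle shifts (``shift = (lambda z / 2 pi) grad(phi)``), so
it is calibrated by applying known tilts, tracking the speckle shift and
inverting the scaling; the mean over tilts is the calibrated ``z``.

The same geometry bounds the recoverable wavefronts: the ray model needs
``|lap(OPD)| << 1/z``, which for a sinusoidal OPD of amplitude ``H`` and
frequency ``omega`` means ``H << 1/(z omega^2)``.  The phase transfer
function is measured empirically by sweeping ``(H, omega)`` sinusoid
phantoms through the wave-optics simulator and scoring the recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from skimage.registration import phase_cross_correlation

from .fields import ComplexField, IntensityImage, WavefrontMap, pixel_coords
from .geometry import SensorGeometry
from .optics import (DEFAULT_GUARD_PX, DEFAULT_OVERSAMPLE, make_mask,
                     mask_feature_samples, simulate_measurement,
                     simulate_reference, simulation_grid)
from .phantoms import sinusoid_phantom
from .reconstruct import SolverParams, remove_tilt, solve_joint


@dataclass(frozen=True)
class CalibrationRecord:
    """One tilt measurement: applied phase slope vs tracked speckle shift."""

    applied_slope_rad_per_um: float
    measured_shift_px: float
    sensor_pitch_um: float
    wavelength_um: float

    @property
    def implied_z_um(self) -> float:
        """``z = shift * pitch * (2 pi / lambda) / slope``."""
        return (self.measured_shift_px * self.sensor_pitch_um
                * (2.0 * np.pi / self.wavelength_um)
                / self.applied_slope_rad_per_um)


def calibrate_z(records: Sequence[CalibrationRecord]) -> float:
    """Mean implied mask-to-sensor distance over the calibration records."""
    usable = [r for r in records if abs(r.applied_slope_rad_per_um) > 0]
    if not usable:
        raise ValueError("calibration requires at least one record with a "
                         "nonzero applied slope")
    return float(np.mean([r.implied_z_um for r in usable]))


def calibration_experiment(geometry: SensorGeometry,
                           target_shifts_px: Sequence[float] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0),
                           shape: tuple[int, int] = (256, 256),
                           mask_seed: int = 0,
                           oversample: int = DEFAULT_OVERSAMPLE,
                           guard_px: int = DEFAULT_GUARD_PX
                           ) -> list[CalibrationRecord]:
    """Closed-loop synthetic calibration run.

    Simulates the coded sensor at ``geometry.z_um``, applies pure-tilt
    wavefronts whose predicted speckle shifts are ``target_shifts_px``,
    tracks each shift by global subpixel cross-correlation against the
    reference, and returns one record per tilt.  ``calibrate_z`` on the
    result recovers the simulated distance.
    """
    sim_shape, sim_pitch = simulation_grid(geometry, shape, oversample, guard_px)
    need = int(np.ceil(max(sim_shape) / mask_feature_samples(geometry.mask_pixel_um, sim_pitch)))
    mask = make_mask(mask_seed, (need, need), geometry)
    I0 = simulate_reference(mask, geometry, shape, oversample, guard_px)
    X, _ = pixel_coords(sim_shape, sim_pitch)
    records = []
    for shift_px in target_shifts_px:
        slope = shift_px * geometry.sensor_pitch_um / geometry.shift_scale_um
        tilt = ComplexField(amplitude=np.ones(sim_shape), phase_rad=slope * X,
                            pitch_um=sim_pitch, wavelength_um=geometry.wavelength_um)
        I = simulate_measurement(mask, geometry, tilt, oversample, guard_px)
        sh, _, _ = phase_cross_correlation(I0.data, I.data, upsample_factor=100)
        records.append(CalibrationRecord(
            applied_slope_rad_per_um=slope,
            measured_shift_px=float(-sh[1]),
            sensor_pitch_um=geometry.sensor_pitch_um,
            wavelength_um=geometry.wavelength_um,
        ))
    return records


def curvature_upper_bound(z_um: float) -> float:
    """Theoretical wavefront-curvature bound ``1/z``, in 1/m."""
    if z_um <= 0:
        raise ValueError("z must be positive")
    return 1e6 / z_um


def h_upper_bound(z_um: float, omega_rad_per_um: float) -> float:
    """Sinusoid-amplitude bound ``1/(z omega^2)`` in um."""
    if z_um <= 0 or omega_rad_per_um <= 0:
        raise ValueError("z and omega must be positive")
    return 1.0 / (z_um * omega_rad_per_um**2)


def rayleigh_resolution(magnification: float, NA: float,
                        wavelength_um: float) -> float:
    """Image-plane Rayleigh resolution ``M * 0.61 lambda / NA`` in um."""
    if not 0.0 < NA <= 1.0:
        raise ValueError("NA must lie in (0, 1]")
    if magnification < 1.0:
        raise ValueError("magnification must be at least 1")
    return magnification * 0.61 * wavelength_um / NA


def cutoff_omega(length_um: float) -> float:
    """Angular cutoff frequency ``pi / length`` in rad/um.

    The half-period convention: a feature of size ``L`` corresponds to a
    sinusoid of period ``2 L``.  It reproduces both the objective cutoff
    (46.4 um -> 0.07 rad/um) and the pixel cutoff (6.45 um -> 0.49 rad/um).
    """
    if length_um <= 0:
        raise ValueError("length must be positive")
    return np.pi / length_um


@dataclass(frozen=True)
class TransferPoint:
    """Recovery score of one sinusoidal OPD ``H cos(omega x)``."""

    H_um: float
    omega_rad_per_um: float
    recovery_error: float    # relative RMS of recovered vs true OPD
    valid: float             # 1 - clipped error, in [0, 1]


def default_transfer_solver(I0: IntensityImage, I: IntensityImage,
                            geometry: SensorGeometry) -> WavefrontMap:
    return solve_joint(I0, I, geometry, SolverParams()).wavefront


def measure_phase_transfer(solver: Callable[[IntensityImage, IntensityImage, SensorGeometry], WavefrontMap] | None,
                           geometry: SensorGeometry,
                           H_grid: Sequence[float],
                           omega_grid: Sequence[float],
                           shape: tuple[int, int] = (128, 128),
                           mask_seed: int = 0,
                           oversample: int = DEFAULT_OVERSAMPLE,
                           guard_px: int = DEFAULT_GUARD_PX
                           ) -> list[TransferPoint]:
    """Empirical phase transfer function over an ``(H, omega)`` grid.

    For each pair a sinusoid phantom is pushed through the wave-optics
    simulator, reconstructed with ``solver`` (the joint solver by
    default), and scored as ``valid = clip(1 - relative RMS error, 0, 1)``.
    Recovery failures score zero instead of raising.  Degradation is
    expected to be monotone in the peak curvature ``H omega^2`` with
    onset below the ``1/z`` bound.
    """
    solver = solver or default_transfer_solver
    sim_shape, sim_pitch = simulation_grid(geometry, shape, oversample, guard_px)
    nyq = np.pi / sim_pitch
    need = int(np.ceil(max(sim_shape) / mask_feature_samples(geometry.mask_pixel_um, sim_pitch)))
    mask = make_mask(mask_seed, (need, need), geometry)
    I0 = simulate_reference(mask, geometry, shape, oversample, guard_px)
    points: list[TransferPoint] = []
    for H in H_grid:
        for omega in omega_grid:
            if omega > nyq:
                raise ValueError(f"omega {omega} above simulation Nyquist {nyq:.3f}")
            sample = sinusoid_phantom(H, omega, sim_shape, sim_pitch,
                                      wavelength_um=geometry.wavelength_um)
            truth = sinusoid_phantom(H, omega, shape, geometry.sensor_pitch_um,
                                     wavelength_um=geometry.wavelength_um)
            try:
                I = simulate_measurement(mask, geometry, sample.to_field(),
                                         oversample, guard_px)
                recovered = solver(I0, I, geometry)
                rec = remove_tilt(recovered).opd_um
                rec = rec - rec.mean()
                ref = truth.wavefront.opd_um - truth.wavefront.opd_um.mean()
                denom = np.sqrt(np.mean(ref**2))
                err = float(np.sqrt(np.mean((rec - ref) ** 2)) / denom) if denom > 0 else 0.0
            except Exception:
                err = np.inf
            points.append(TransferPoint(H_um=H, omega_rad_per_um=omega,
                                        recovery_error=err,
                                        valid=float(np.clip(1.0 - err, 0.0, 1.0))))
    return points
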