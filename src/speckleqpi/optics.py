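"""Physical-optics simulator of the coded wavefront sensor.

A random binary 0/pi phase mask sits a distance ``z`` (~1.5 mm) in front
of an intensity sensor.  Collimated illumination diffracts off the mask
into a high-contrast speckle pattern (the reference image ``I0``); a
sample field conjugated to the mask plane tilts the local wavefront and
translates the speckle in proportion to its slopes (the measurement
image ``I``).  The simulation is monochromatic at the nominal wavelength;
for OPD-level quantities this stands in for the broadband illumination
because a weakly dispersive sample shifts the speckle identically at
every wavelength.

Simulation grids oversample the sensor pitch by an integer factor
(default 4x) so that mask features and diffraction fringes are resolved;
the sensor model is area integration (box average) over each pixel, and a
guard border (default 32 sensor pixels) absorbs the periodic wrap-around
of the spectral propagator and is cropped from all outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from scipy.ndimage import gaussian_filter

from ._operators import block_average
from .fields import ComplexField, IntensityImage
from .geometry import SensorGeometry

DEFAULT_OVERSAMPLE = 4
DEFAULT_GUARD_PX = 32


@dataclass(frozen=True)
class MaskPattern:
    """Random binary phase mask at mask-pixel resolution.

    ``values`` holds 0/1 per mask feature; the optical phase of feature
    ``v`` is ``phase_levels[v]`` (0 or pi for the fabricated mask).
    """

    values: np.ndarray
    mask_pixel_um: float
    phase_levels: tuple[float, float] = (0.0, np.pi)
    seed: int | None = None
    edge_smoothing_um: float = 4.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("mask values must be 2-D")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("mask values must be strictly binary (0 or 1)")
        if self.mask_pixel_um <= 0:
            raise ValueError("mask_pixel_um must be positive")
        object.__setattr__(self, "values", v.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def phase(self) -> np.ndarray:
        """Phase in radians per mask feature."""
        lo, hi = self.phase_levels
        return np.where(self.values == 0, lo, hi).astype(float)


def make_mask(seed: int, shape: tuple[int, int], geometry: SensorGeometry) -> MaskPattern:
    """Draw an i.i.d. uniform binary mask of ``shape`` mask pixels.

    Deterministic given ``seed``; each feature is 0 or 1 with probability
    one half, mimicking the laser-written photolithographic pattern.
    """
    ny, nx = shape
    if ny <= 0 or nx <= 0:
        raise ValueError(f"mask shape must be positive, got {shape}")
    rng = np.random.default_rng(seed)
    values = rng.integers(0, 2, size=(ny, nx), dtype=np.uint8)
    return MaskPattern(values=values, mask_pixel_um=geometry.mask_pixel_um, seed=seed)


def mask_feature_samples(mask_pixel_um: float, sim_pitch_um: float) -> int:
    """Simulation samples per mask feature (nearest-neighbour upsampling block)."""
    return int(np.ceil(mask_pixel_um / sim_pitch_um))


def render_mask_field(mask: MaskPattern, sim_pitch_um: float,
                      sim_shape: tuple[int, int],
                      wavelength_um: float) -> ComplexField:
    """Upsample the mask to the simulation grid as a unit-amplitude phase field."""
    block = mask_feature_samples(mask.mask_pixel_um, sim_pitch_um)
    need_y = int(np.ceil(sim_shape[0] / block))
    need_x = int(np.ceil(sim_shape[1] / block))
    if mask.shape[0] < need_y or mask.shape[1] < need_x:
        raise ValueError(
            f"mask of {mask.shape} features cannot cover a {sim_shape} grid at "
            f"{sim_pitch_um} um pitch (needs {(need_y, need_x)} features)"
        )
    phase = np.kron(mask.phase(), np.ones((block, block)))[: sim_shape[0], : sim_shape[1]]
    if mask.edge_smoothing_um > 0:
        phase = gaussian_filter(phase, mask.edge_smoothing_um / sim_pitch_um)
    return ComplexField(amplitude=np.ones(sim_shape), phase_rad=phase,
                        pitch_um=sim_pitch_um, wavelength_um=wavelength_um)


def angular_spectrum_propagate(field: ComplexField, distance_um: float) -> ComplexField:
    """Exact scalar angular-spectrum propagation over ``distance_um``.

    The transfer function ``exp(j z sqrt(k^2 - kx^2 - ky^2))`` is applied
    in the spatial-frequency domain; evanescent components (and, for long
    throws, spatial frequencies whose fringes would alias on this grid,
    after Matsushima's band limit) are zeroed.  Negative distances
    back-propagate; energy in the kept band is conserved exactly.
    """
    if field.wavelength_um <= 0:
        raise ValueError("wavelength must be positive")
    if distance_um == 0.0:
        return ComplexField(amplitude=field.amplitude.copy(),
                            phase_rad=field.phase_rad.copy(),
                            pitch_um=field.pitch_um,
                            wavelength_um=field.wavelength_um)
    ny, nx = field.shape
    dx = field.pitch_um
    k = 2.0 * np.pi / field.wavelength_um
    kx = 2.0 * np.pi * np.fft.fftfreq(nx, dx)
    ky = 2.0 * np.pi * np.fft.fftfreq(ny, dx)
    KX, KY = np.meshgrid(kx, ky)
    kz_sq = k**2 - KX**2 - KY**2
    keep = kz_sq > 0.0
    # Matsushima band limit: drop frequencies whose transfer-function
    # fringes are undersampled by the grid's frequency step.
    z = abs(distance_um)
    fx_lim = 1.0 / (np.sqrt((2.0 * z / (nx * dx)) ** 2 + 1.0) * field.wavelength_um)
    fy_lim = 1.0 / (np.sqrt((2.0 * z / (ny * dx)) ** 2 + 1.0) * field.wavelength_um)
    keep &= np.abs(KX) <= 2.0 * np.pi * fx_lim
    keep &= np.abs(KY) <= 2.0 * np.pi * fy_lim
    H = np.zeros((ny, nx), dtype=complex)
    H[keep] = np.exp(1j * distance_um * np.sqrt(kz_sq[keep]))
    out = np.fft.ifft2(np.fft.fft2(field.values) * H)
    return ComplexField.from_values(out, pitch_um=dx, wavelength_um=field.wavelength_um)


def simulation_grid(geometry: SensorGeometry, shape: tuple[int, int],
                    oversample: int = DEFAULT_OVERSAMPLE,
                    guard_px: int = DEFAULT_GUARD_PX) -> tuple[tuple[int, int], float]:
    """Simulation grid (shape, pitch) covering ``shape`` sensor pixels plus guard."""
    ny, nx = shape
    if ny <= 0 or nx <= 0:
        raise ValueError(f"sensor shape must be positive, got {shape}")
    sim_shape = ((ny + 2 * guard_px) * oversample, (nx + 2 * guard_px) * oversample)
    return sim_shape, geometry.sensor_pitch_um / oversample


def apodize_guard(sample: ComplexField, guard_sim_px: int) -> ComplexField:
    """Taper a sample field to unit amplitude / zero phase over the guard band.

    A separable raised-cosine window keeps the interior untouched and
    makes the field compatible with the propagator's periodic boundary.
    """
    if guard_sim_px <= 0:
        return sample

    def window(n: int) -> np.ndarray:
        w = np.ones(n)
        g = min(guard_sim_px, n // 2)
        ramp = 0.5 - 0.5 * np.cos(np.pi * (np.arange(g) + 0.5) / g)
        w[:g] = ramp
        w[n - g:] = ramp[::-1]
        return w

    w2 = np.outer(window(sample.shape[0]), window(sample.shape[1]))
    return ComplexField(amplitude=1.0 + w2 * (sample.amplitude - 1.0),
                        phase_rad=w2 * sample.phase_rad,
                        pitch_um=sample.pitch_um,
                        wavelength_um=sample.wavelength_um)


def _sense(field: ComplexField, geometry: SensorGeometry, shape: tuple[int, int],
           oversample: int, guard_px: int) -> IntensityImage:
    """Propagate to the sensor, area-integrate to pixels, crop the guard."""
    out = angular_spectrum_propagate(field, geometry.z_um)
    intensity = out.amplitude**2
    pixels = block_average(intensity, oversample)
    if guard_px > 0:
        pixels = pixels[guard_px:-guard_px, guard_px:-guard_px]
    if pixels.shape != shape:
        raise ValueError(f"sensed image {pixels.shape} does not match requested {shape}")
    return IntensityImage(data=pixels, pitch_um=geometry.sensor_pitch_um)


def simulate_reference(mask: MaskPattern, geometry: SensorGeometry,
                       shape: tuple[int, int],
                       oversample: int = DEFAULT_OVERSAMPLE,
                       guard_px: int = DEFAULT_GUARD_PX) -> IntensityImage:
    """Reference speckle image ``I0``: the mask's diffraction pattern.

    Collimated unit-amplitude illumination is assumed; the returned image
    is the squared modulus of the mask field propagated by ``z``,
    area-integrated onto sensor pixels.
    """
    sim_shape, sim_pitch = simulation_grid(geometry, shape, oversample, guard_px)
    field = render_mask_field(mask, sim_pitch, sim_shape, geometry.wavelength_um)
    return _sense(field, geometry, shape, oversample, guard_px)


def simulate_measurement(mask: MaskPattern, geometry: SensorGeometry,
                         sample: ComplexField,
                         oversample: int = DEFAULT_OVERSAMPLE,
                         guard_px: int = DEFAULT_GUARD_PX,
                         apodize: bool = True) -> IntensityImage:
    """Measurement speckle image ``I`` for a sample conjugated to the mask plane.

    ``sample`` must live on the full simulation grid returned by
    :func:`simulation_grid` for the requested output shape.  With a flat
    sample the output equals :func:`simulate_reference` exactly.
    """
    ny, nx = sample.shape
    if ny % oversample or nx % oversample:
        raise ValueError("sample grid is not an integer multiple of the oversampling")
    shape = (ny // oversample - 2 * guard_px, nx // oversample - 2 * guard_px)
    if shape[0] <= 0 or shape[1] <= 0:
        raise ValueError("sample grid smaller than twice the guard border")
    sim_shape, sim_pitch = simulation_grid(geometry, shape, oversample, guard_px)
    if not np.isclose(sample.pitch_um, sim_pitch):
        raise ValueError(
            f"sample pitch {sample.pitch_um} um does not match the simulation "
            f"pitch {sim_pitch} um for this geometry/oversampling"
        )
    if apodize:
        sample = apodize_guard(sample, guard_px * oversample)
    maskf = render_mask_field(mask, sim_pitch, sim_shape, geometry.wavelength_um)
    field = ComplexField(amplitude=sample.amplitude * maskf.amplitude,
                         phase_rad=sample.phase_rad + maskf.phase_rad,
                         pitch_um=sim_pitch, wavelength_um=geometry.wavelength_um)
    return _sense(field, geometry, shape, oversample, guard_px)


def simulate_phantom_pair(make_sample, mask_seed: int, geometry: SensorGeometry,
                          shape: tuple[int, int],
                          oversample: int = DEFAULT_OVERSAMPLE,
                          guard_px: int = DEFAULT_GUARD_PX):
    """Reference/measurement pair plus sensor-grid truth for a phantom.

    ``make_sample(grid, pitch_um)`` must return a phantom (anything with
    ``to_field()``) or a :class:`ComplexField`; it is evaluated once on
    the fine simulation grid for the wave-optics run and once on the
    sensor grid for ground truth.  Returns ``(I0, I, truth_phantom)``.
    """
    sim_shape, sim_pitch = simulation_grid(geometry, shape, oversample, guard_px)
    feat = mask_feature_samples(geometry.mask_pixel_um, sim_pitch)
    need = int(np.ceil(max(sim_shape) / feat))
    mask = make_mask(mask_seed, (need, need), geometry)
    I0 = simulate_reference(mask, geometry, shape, oversample, guard_px)
    sample = make_sample(sim_shape, sim_pitch)
    sample_field = sample.to_field() if hasattr(sample, "to_field") else sample
    I = simulate_measurement(mask, geometry, sample_field, oversample, guard_px)
    truth = make_sample(shape, geometry.sensor_pitch_um)
    return I0, I, truth


def add_sensor_noise(image: IntensityImage, rng: np.random.Generator,
                     photon_count: float | None = None,
                     gaussian_sigma: float = 0.0) -> IntensityImage:
    """Optional shot (Poisson, at ``photon_count`` photons per unit mean
    intensity) and additive Gaussian read noise."""
    data = image.data.copy()
    if photon_count is not None:
        scale = photon_count / max(data.mean(), 1e-30)
        data = rng.poisson(data * scale) / scale
    if gaussian_sigma > 0:
        data = data + rng.normal(0.0, gaussian_sigma, size=data.shape)
    return IntensityImage(data=np.clip(data, 0.0, None), pitch_um=image.pitch_um)
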