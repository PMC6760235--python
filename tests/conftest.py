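"""Shared fixtures: one simulated sensor shared across the suite.

Wave-optics simulation and joint reconstruction are the expensive steps,
so the default-geometry mask, reference image and phantom measurement
pairs are built once per session and memoized by phantom name.
"""

from __future__ import annotations

import numpy as np
import pytest

import speckleqpi as sq
from speckleqpi import optics as op

SHAPE = (128, 128)


@pytest.fixture(scope="session")
def geometry() -> sq.SensorGeometry:
    return sq.SensorGeometry()


def _phantom_factories():
    return {
        "microlens": lambda grid, pitch: sq.microlens_phantom(
            150.0, 6.7, 1.46, grid, pitch, magnification=6.0),
        "curvature": lambda grid, pitch: sq.curvature_phantom(35.0, grid, pitch),
        "gentle_curvature": lambda grid, pitch: sq.curvature_phantom(2.0, grid, pitch),
        "torus": lambda grid, pitch: sq.cell_phantom(
            "torus", {"radius_um": 250.0, "peak_opd_um": 0.4}, grid, pitch),
        "torus_dip": lambda grid, pitch: sq.cell_phantom(
            "torus", {"radius_um": 250.0, "peak_opd_um": 0.4, "amplitude_dip": 0.3},
            grid, pitch),
    }


class SensorBench:
    """Session-lived simulated bench: geometry, mask, reference, pair cache."""

    def __init__(self, geometry: sq.SensorGeometry):
        self.geometry = geometry
        self.shape = SHAPE
        sim_shape, sim_pitch = op.simulation_grid(geometry, SHAPE)
        self.sim_shape = sim_shape
        self.sim_pitch = sim_pitch
        feat = op.mask_feature_samples(geometry.mask_pixel_um, sim_pitch)
        need = int(np.ceil(max(sim_shape) / feat))
        self.mask = op.make_mask(0, (need, need), geometry)
        self.reference = op.simulate_reference(self.mask, geometry, SHAPE)
        self._pairs: dict[str, tuple] = {}
        self._factories = _phantom_factories()

    def pair(self, name: str):
        """(I0, I, truth_phantom) for a named phantom, cached."""
        if name not in self._pairs:
            factory = self._factories[name]
            sample = factory(self.sim_shape, self.sim_pitch)
            I = op.simulate_measurement(self.mask, self.geometry, sample.to_field())
            truth = factory(self.shape, self.geometry.sensor_pitch_um)
            self._pairs[name] = (self.reference, I, truth)
        return self._pairs[name]

    def truth_opd(self, name: str) -> np.ndarray:
        """Tilt-removed zero-mean truth OPD, the solver's output convention."""
        truth = self.pair(name)[2]
        ref = sq.remove_tilt(truth.wavefront).opd_um
        return ref - ref.mean()


@pytest.fixture(scope="session")
def bench(geometry) -> SensorBench:
    return SensorBench(geometry)


@pytest.fixture(scope="session")
def joint_results(bench):
    """Joint reconstructions for the recovery phantoms, computed once."""
    out = {}
    for name in ("microlens", "curvature", "torus"):
        I0, I, _ = bench.pair(name)
        out[name] = sq.solve_joint(I0, I, bench.geometry)
    return out


def rel_rms(recovered: np.ndarray, truth: np.ndarray) -> float:
    """RMS error relative to the truth's peak-to-valley range."""
    return float(np.sqrt(np.mean((recovered - truth) ** 2))
                 / (truth.max() - truth.min()))
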