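"""Discrete differential operators and small numerical utilities.

The gradient is the forward difference with replicate (Neumann) boundary,
its divergence is the exact negative adjoint, and the Laplacian is the
5-point stencil ``div(grad)``.  This exact adjoint pairing is what makes
the DCT Poisson solver an exact discrete inverse of slope integration and
keeps the reconstruction subproblems consistent.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.fft import dctn, idctn


def grad(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward-difference gradient ``(du/dx, du/dy)`` in per-pixel units.

    Neumann boundary: the difference past the last sample is zero.
    """
    gx = np.zeros_like(u)
    gy = np.zeros_like(u)
    gx[:, :-1] = u[:, 1:] - u[:, :-1]
    gy[:-1, :] = u[1:, :] - u[:-1, :]
    return gx, gy


def div(px: np.ndarray, py: np.ndarray) -> np.ndarray:
    """Divergence, the negative adjoint of :func:`grad` (``div = -grad^T``)."""
    d = np.zeros_like(px)
    d[:, 0] = px[:, 0]
    d[:, 1:-1] = px[:, 1:-1] - px[:, :-2]
    d[:, -1] = -px[:, -2]
    dy = np.zeros_like(py)
    dy[0, :] = py[0, :]
    dy[1:-1, :] = py[1:-1, :] - py[:-2, :]
    dy[-1, :] = -py[-2, :]
    return d + dy


def laplacian(u: np.ndarray) -> np.ndarray:
    """5-point Laplacian with Neumann boundary, ``div(grad(u))``."""
    return div(*grad(u))


def neumann_laplacian_eigenvalues(shape: tuple[int, int]) -> np.ndarray:
    """Eigenvalues of ``-laplacian`` (i.e. ``grad^T grad``) in the DCT-II basis."""
    ny, nx = shape
    wx = 4.0 * np.sin(np.pi * np.arange(nx) / (2.0 * nx)) ** 2
    wy = 4.0 * np.sin(np.pi * np.arange(ny) / (2.0 * ny)) ** 2
    return wy[:, None] + wx[None, :]


def poisson_solve_neumann(rhs: np.ndarray) -> np.ndarray:
    """Solve ``laplacian(u) = rhs`` with Neumann boundary, zero-mean solution.

    Diagonalizes the 5-point Neumann Laplacian by the type-II DCT; the
    incompatible mean of ``rhs`` (Neumann problems require a zero-mean
    source) is projected out, as is the solution's arbitrary constant.
    """
    lam = neumann_laplacian_eigenvalues(rhs.shape)
    spec = dctn(rhs, type=2, norm="ortho")
    spec[0, 0] = 0.0
    lam[0, 0] = 1.0
    u = idctn(-spec / lam, type=2, norm="ortho")
    return u - u.mean()


def integrate_gradient(gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    """Least-squares curl-free integration of a per-pixel gradient field.

    Solves ``grad^T grad u = grad^T g`` exactly (DCT), so applying it to
    ``grad(u)`` of any field returns ``u`` up to its mean.
    """
    return poisson_solve_neumann(div(gx, gy))


def warp_image(image: np.ndarray, dx_px: np.ndarray, dy_px: np.ndarray,
               order: int = 3) -> np.ndarray:
    """Sample ``image`` at ``(x + dx, y + dy)`` with spline interpolation.

    Replicate boundary; displacements in pixels on the image's own grid.
    """
    ny, nx = image.shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    return ndimage.map_coordinates(image, [yy + dy_px, xx + dx_px],
                                   order=order, mode="nearest")


def image_gradient_centered(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centred per-pixel gradient (np.gradient convention) for warp Jacobians."""
    gy, gx = np.gradient(u)
    return gx, gy


def fit_affine_plane(u: np.ndarray) -> np.ndarray:
    """Least-squares affine plane ``a + b x + c y`` fitted to ``u`` (pixel coords)."""
    ny, nx = u.shape
    x = np.arange(nx) - (nx - 1) / 2.0
    y = np.arange(ny) - (ny - 1) / 2.0
    X, Y = np.meshgrid(x, y)
    # centred coordinates make the normal equations diagonal
    a = u.mean()
    b = (u * X).sum() / (X**2).sum()
    c = (u * Y).sum() / (Y**2).sum()
    return a + b * X + c * Y


def soft_threshold(v: np.ndarray, t: float) -> np.ndarray:
    """Proximal operator of ``t * ||.||_1`` (elementwise shrinkage)."""
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def block_average(a: np.ndarray, factor: int) -> np.ndarray:
    """Area-integrating downsample by an integer factor (box average)."""
    ny, nx = a.shape
    if ny % factor or nx % factor:
        raise ValueError(f"shape {a.shape} not divisible by factor {factor}")
    return a.reshape(ny // factor, factor, nx // factor, factor).mean(axis=(1, 3))
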