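"""Reconstruction of sample amplitude and phase from one speckle image pair.

The central solver jointly estimates the wavefront ``phi`` and the
modulated intensity ``|A~|^2 = |A|^2 (1 - (lambda z/2pi) lap(phi))`` by
minimizing

    || I(r + (lambda z/2pi) grad(phi)) - |A~|^2 I0 ||_2^2
        + alpha ||grad(phi)||_1 + beta (||grad(phi)||_2^2 + ||lap(phi)||_2^2)
        + gamma (||grad(|A~|^2)||_1 + ||lap(|A~|^2)||_1)
        + tau   (||grad(|A~|^2)||_2^2 + ||lap(|A~|^2)||_2^2)

in an alternating fashion: a Gauss-Newton relinearization of the warped
data term in ``phi`` and a per-pixel-diagonal data fit in ``|A~|^2``,
each handled by a scaled-form ADMM inner loop (soft-thresholding for the
l1 pieces, conjugate gradients for the coupled quadratics).  Images are
normalized to the 0-255 grayscale range internally, which is the scale
the default tradeoff weights assume.

Classical baselines (windowed subpixel speckle tracking with curl-free
Poisson integration, and curl-free optical flow, i.e. the same machinery
with the amplitude frozen at one) are provided for comparison; on
absorbing samples their phase estimates are biased because their models
ignore the amplitude/caustic coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.fft import dctn, idctn
from scipy.sparse.linalg import LinearOperator, cg
from skimage.registration import phase_cross_correlation

from ._operators import (div, fit_affine_plane, grad, image_gradient_centered,
                         integrate_gradient, laplacian,
                         neumann_laplacian_eigenvalues, soft_threshold,
                         warp_image)
from .fields import IntensityImage, SlopeField, WavefrontMap
from .geometry import SensorGeometry

GRAY_SCALE = 255.0


@dataclass(frozen=True)
class SolverParams:
    """Tradeoff weights and iteration counts of the joint solver.

    The default weights are the typical values for grayscale images
    normalized to 0-255: ``alpha=0.1, beta=0.1, gamma=100, tau=5``.
    """

    alpha: float = 0.1
    beta: float = 0.1
    gamma: float = 100.0
    tau: float = 5.0
    outer_iters: int = 3
    inner_iters: int = 8
    warp_linearizations: int = 3
    tol: float = 1e-4
    rho: float = 1.0
    damping: float = 0.05
    border_margin_px: int = 4
    cg_iters: int = 80
    cg_tol: float = 1e-8
    init_from_tracking: bool = True
    track_window_px: int = 16
    interp_order: int = 3

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "tau"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("outer_iters", "inner_iters", "warp_linearizations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")
        if self.rho <= 0:
            raise ValueError("rho must be positive")


@dataclass
class ReconResult:
    """Joint reconstruction output.

    ``wavefront`` is the tilt-removed, zero-mean OPD map; ``amplitude``
    is the caustic-corrected sample amplitude ``A``; ``objective_trace``
    holds the objective at start and after each alternating step
    (non-increasing by construction).
    """

    wavefront: WavefrontMap
    modulated_intensity: np.ndarray
    amplitude: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)


def remove_tilt(wavefront: WavefrontMap) -> WavefrontMap:
    """Subtract the least-squares affine plane ``a + b x + c y`` from the OPD.

    The output is orthogonal to ``{1, x, y}``; applying it twice is the
    same as applying it once.
    """
    opd = wavefront.opd_um - fit_affine_plane(wavefront.opd_um)
    return WavefrontMap(opd_um=opd, pitch_um=wavefront.pitch_um,
                        wavelength_um=wavefront.wavelength_um)


def correct_amplitude(result: ReconResult, geometry: SensorGeometry,
                      eps: float = 1e-3) -> np.ndarray:
    """Caustic-corrected sample amplitude ``A = A~ sqrt(1 + (lambda z/2pi) lap(phi))``.

    The radicand is clamped at ``eps`` where wavefront curvature pushes
    it nonpositive; the clamp count lands in ``result.diagnostics``.
    """
    A, clamped = _amplitude_from(result.modulated_intensity, result.wavefront, geometry, eps)
    result.diagnostics["amplitude_clamp_count"] = clamped
    return A


def _amplitude_from(modulated: np.ndarray, wavefront: WavefrontMap,
                    geometry: SensorGeometry, eps: float = 1e-3
                    ) -> tuple[np.ndarray, int]:
    from .forward import opd_laplacian_per_um

    lap_opd = opd_laplacian_per_um(wavefront)
    radicand = 1.0 + geometry.z_um * lap_opd
    clamped = int(np.count_nonzero(radicand < eps))
    radicand = np.maximum(radicand, eps)
    return np.sqrt(np.clip(modulated, 0.0, None) * radicand), clamped


def _phase_displacement_px(phi: np.ndarray, kappa: float) -> tuple[np.ndarray, np.ndarray]:
    gx, gy = grad(phi)
    return kappa * gx, kappa * gy


def _border_weight(shape: tuple[int, int], margin: int) -> np.ndarray:
    """Raised-cosine taper to zero over a border band of ``margin`` pixels.

    The warped data term is undefined where ``r + u`` leaves the frame;
    weighting the residual to zero there keeps boundary replication
    artifacts out of the fit (the priors still extend the solution to
    the edge).
    """
    if margin <= 0:
        return np.ones(shape)

    def ramp(n: int) -> np.ndarray:
        w = np.ones(n)
        g = min(margin, n // 2)
        edge = 0.5 - 0.5 * np.cos(np.pi * (np.arange(g) + 0.5) / g)
        w[:g] = edge
        w[n - g:] = edge[::-1]
        return w

    return np.outer(ramp(shape[0]), ramp(shape[1]))


def eval_objective(wavefront: WavefrontMap, intensity_sq: np.ndarray,
                   I0: IntensityImage, I: IntensityImage,
                   geometry: SensorGeometry, params: SolverParams) -> float:
    """The joint objective at ``(phi, |A~|^2)`` on already-normalized images.

    Images are taken as given (the solver normalizes to 0-255 before
    calling this); constant phase offsets do not change the value.
    """
    for name, arr in (("wavefront", wavefront.opd_um), ("intensity_sq", intensity_sq),
                      ("I0", I0.data), ("I", I.data)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} contains non-finite values")
    phi = wavefront.phase_rad
    kappa = geometry.phase_to_shift_px
    ux, uy = _phase_displacement_px(phi, kappa)
    warped = warp_image(I.data, ux, uy, order=params.interp_order)
    wt = _border_weight(I0.shape, params.border_margin_px)
    data = float(np.sum((wt * (warped - intensity_sq * I0.data)) ** 2))
    gpx, gpy = grad(phi)
    lp = laplacian(phi)
    gmx, gmy = grad(intensity_sq)
    lm = laplacian(intensity_sq)
    reg_phi = (params.alpha * (np.abs(gpx).sum() + np.abs(gpy).sum())
               + params.beta * (np.sum(gpx**2 + gpy**2) + np.sum(lp**2)))
    reg_m = (params.gamma * (np.abs(gmx).sum() + np.abs(gmy).sum() + np.abs(lm).sum())
             + params.tau * (np.sum(gmx**2 + gmy**2) + np.sum(lm**2)))
    return data + float(reg_phi) + float(reg_m)


def _cg_solve(matvec, rhs: np.ndarray, x0: np.ndarray, params: SolverParams,
              precond_diag: np.ndarray | None = None) -> np.ndarray:
    """Conjugate-gradient solve with an optional DCT-diagonal preconditioner.

    Both subproblem operators are dominated by constant-coefficient
    gradient/biharmonic terms, which are diagonal in the Neumann DCT
    basis; preconditioning with that diagonal makes CG converge in a few
    tens of iterations where the raw fourth-order system crawls.
    """
    shape = rhs.shape
    op = LinearOperator(
        (rhs.size, rhs.size),
        matvec=lambda v: matvec(v.reshape(shape)).ravel(),
        dtype=float,
    )
    M = None
    if precond_diag is not None:
        safe = np.maximum(precond_diag, 1e-12 * precond_diag.max())

        def apply_precond(v: np.ndarray) -> np.ndarray:
            spec = dctn(v.reshape(shape), type=2, norm="ortho")
            return idctn(spec / safe, type=2, norm="ortho").ravel()

        M = LinearOperator((rhs.size, rhs.size), matvec=apply_precond, dtype=float)
    x, _ = cg(op, rhs.ravel(), x0=x0.ravel(), rtol=params.cg_tol,
              maxiter=params.cg_iters, M=M)
    return x.reshape(shape)


def _phi_admm(phi0: np.ndarray, m: np.ndarray, A0: np.ndarray, B: np.ndarray,
              kappa: float, params: SolverParams, damping: float = 0.0) -> np.ndarray:
    """One Gauss-Newton linearization of the warped data term, solved by ADMM.

    Linearizes ``W(phi) = B(r + kappa grad(phi))`` around ``phi0`` using
    the warped image's own gradients (inverse-compositional Jacobian) and
    minimizes over ``phi`` with the l1 gradient prior split off.

    ``damping`` adds a Levenberg-style trust region on the displacement
    step, ``mu ||grad(phi - phi0)||^2`` with ``mu`` scaled to the mean
    squared speckle gradient: the Jacobian is a directional derivative
    along the local speckle gradient, so it leaves phase components
    along speckle iso-contours unconstrained and the (deliberately weak)
    printed prior weights cannot tame them by themselves.  A gradient
    (not identity) penalty keeps the trust region spectrally matched to
    ``J^T J`` and does not suppress the smooth low-frequency wavefront.
    """
    ux, uy = _phase_displacement_px(phi0, kappa)
    W0 = warp_image(B, ux, uy, order=params.interp_order)
    wt = _border_weight(B.shape, params.border_margin_px)
    Gx, Gy = image_gradient_centered(W0)
    Gx = wt * Gx
    Gy = wt * Gy

    def J(p: np.ndarray) -> np.ndarray:
        gx, gy = grad(p)
        return kappa * (Gx * gx + Gy * gy)

    def Jt(r: np.ndarray) -> np.ndarray:
        return -kappa * div(Gx * r, Gy * r)

    r0 = wt * (W0 - m * A0)
    b0 = J(phi0) - r0
    beta, rho, alpha = params.beta, params.rho, params.alpha
    data_curv = kappa**2 * float(np.mean(Gx**2 + Gy**2))
    mu = damping * data_curv

    def matvec(p: np.ndarray) -> np.ndarray:
        return (Jt(J(p)) - (mu + beta + rho / 2.0) * laplacian(p)
                + beta * laplacian(laplacian(p)))

    lam = neumann_laplacian_eigenvalues(phi0.shape)
    precond = (0.5 * data_curv + mu + beta + rho / 2.0) * lam + beta * lam**2
    precond[0, 0] = 0.5 * data_curv + mu + beta  # keep the mean mode solvable

    phi = phi0.copy()
    vx, vy = grad(phi)
    wx = np.zeros_like(phi)
    wy = np.zeros_like(phi)
    Jtb = Jt(b0) - mu * laplacian(phi0)
    for _ in range(params.inner_iters):
        rhs = Jtb - (rho / 2.0) * div(vx - wx, vy - wy)
        phi = _cg_solve(matvec, rhs, phi, params, precond)
        gx, gy = grad(phi)
        vx = soft_threshold(gx + wx, alpha / rho)
        vy = soft_threshold(gy + wy, alpha / rho)
        wx += gx - vx
        wy += gy - vy
    return phi


def _m_admm(m0: np.ndarray, W: np.ndarray, A0: np.ndarray,
            params: SolverParams) -> np.ndarray:
    """Modulated-intensity update: per-pixel data fit with l1/l2 priors by ADMM."""
    tau, gamma = params.tau, params.gamma
    wt_sq = _border_weight(m0.shape, params.border_margin_px) ** 2
    A0sq = wt_sq * A0**2
    # The ADMM penalty must live on the scale of the per-pixel data
    # curvature |I0|^2 (~1e4 for 0-255 images) for the splitting
    # constraint to bind in a few iterations; params.rho is the penalty
    # relative to that scale.
    rho = params.rho * float(A0sq.mean())

    def matvec(x: np.ndarray) -> np.ndarray:
        return (A0sq * x - (tau + rho / 2.0) * laplacian(x)
                + (tau + rho / 2.0) * laplacian(laplacian(x)))

    lam = neumann_laplacian_eigenvalues(m0.shape)
    precond = (float(A0sq.mean()) + (tau + rho / 2.0) * lam
               + (tau + rho / 2.0) * lam**2)

    m = m0.copy()
    px, py = grad(m)
    q = laplacian(m)
    wpx = np.zeros_like(m)
    wpy = np.zeros_like(m)
    wq = np.zeros_like(m)
    base_rhs = wt_sq * A0 * W
    for _ in range(params.inner_iters):
        rhs = (base_rhs - (rho / 2.0) * div(px - wpx, py - wpy)
               + (rho / 2.0) * laplacian(q - wq))
        m = _cg_solve(matvec, rhs, m, params, precond)
        gx, gy = grad(m)
        lm = laplacian(m)
        px = soft_threshold(gx + wpx, gamma / rho)
        py = soft_threshold(gy + wpy, gamma / rho)
        q = soft_threshold(lm + wq, gamma / rho)
        wpx += gx - px
        wpy += gy - py
        wq += lm - q
    return m


def _solve(I0: IntensityImage, I: IntensityImage, geometry: SensorGeometry,
           params: SolverParams, update_amplitude: bool) -> ReconResult:
    if I0.shape != I.shape:
        raise ValueError(f"reference {I0.shape} and measurement {I.shape} differ")
    if not np.any(I0.data > 0):
        raise ValueError("reference image is identically zero")
    if I0.pitch_um != geometry.sensor_pitch_um:
        geometry = SensorGeometry(z_um=geometry.z_um,
                                  wavelength_um=geometry.wavelength_um,
                                  sensor_pitch_um=I0.pitch_um,
                                  mask_pixel_um=geometry.mask_pixel_um)
    scale = GRAY_SCALE / I0.data.max()
    A0 = I0.data * scale
    B = I.data * scale

    kappa = geometry.phase_to_shift_px
    I0_n = IntensityImage(data=A0, pitch_um=geometry.sensor_pitch_um)
    I_n = IntensityImage(data=B, pitch_um=geometry.sensor_pitch_um)

    def objective(p: np.ndarray, mm: np.ndarray) -> float:
        wf = WavefrontMap.from_phase(p, geometry.sensor_pitch_um,
                                     geometry.wavelength_um)
        return eval_objective(wf, mm, I0_n, I_n, geometry, params)

    def m_update(phi_cur: np.ndarray, m_cur: np.ndarray) -> np.ndarray:
        ux, uy = _phase_displacement_px(phi_cur, kappa)
        W = warp_image(B, ux, uy, order=params.interp_order)
        cand = _m_admm(m_cur, W, A0, params)
        # the m-subproblem is convex but the inner loop is truncated:
        # keep the candidate only if it lowers the full objective
        return cand if objective(phi_cur, cand) <= objective(phi_cur, m_cur) else m_cur

    # Initialization: a coarse windowed-tracking pass followed by curl-free
    # integration registers the pair to well under a pixel, which keeps the
    # Gauss-Newton refinement in its basin and leaves residuals small
    # enough that the intensity update cannot absorb displacement signal.
    phi = np.zeros_like(A0)
    m = np.ones_like(A0)
    if params.init_from_tracking and min(A0.shape) >= 3 * params.track_window_px:
        try:
            wf0 = track_and_integrate(I0_n, I_n, geometry,
                                      window_px=params.track_window_px,
                                      stride=params.track_window_px // 2)
            phi0 = 2.0 * np.pi * wf0.opd_um / geometry.wavelength_um
            if objective(phi0, m) <= objective(phi, m):
                phi = phi0
        except ValueError:
            pass  # textureless reference: keep the zero start

    energy = objective(phi, m)
    trace: list[float] = [energy]
    converged = False
    for _ in range(params.outer_iters):
        e_prev = energy
        damping = params.damping
        for _ in range(params.warp_linearizations):
            # Levenberg-Marquardt trust region per relinearization: grow
            # the damping until the step decreases the true objective,
            # relax it again after accepted steps.
            accepted = False
            for _ in range(6):
                cand = _phi_admm(phi, m, A0, B, kappa, params, damping)
                e_cand = objective(cand, m)
                if e_cand <= energy:
                    phi, energy = cand, e_cand
                    damping = max(damping / 2.0, params.damping)
                    accepted = True
                    break
                damping *= 4.0
            if not accepted:
                break
        if update_amplitude:
            m = m_update(phi, m)
            energy = objective(phi, m)
        trace.append(energy)
        if e_prev - energy <= params.tol * max(e_prev, 1e-30):
            converged = True
            break

    wf = WavefrontMap.from_phase(phi, geometry.sensor_pitch_um, geometry.wavelength_um)
    wf = remove_tilt(wf)
    wf.opd_um -= wf.opd_um.mean()
    ux, uy = _phase_displacement_px(phi, geometry.phase_to_shift_px)
    warped = warp_image(B, ux, uy, order=params.interp_order)
    residual = float(np.linalg.norm(warped - m * A0))
    from .forward import opd_laplacian_per_um

    factor = 1.0 - geometry.z_um * opd_laplacian_per_um(wf)
    result = ReconResult(
        wavefront=wf,
        modulated_intensity=np.clip(m, 0.0, None),
        amplitude=np.ones_like(m),
        objective_trace=trace,
        diagnostics={
            "residual_norm": residual,
            "curvature_factor_min": float(factor.min()),
            "curvature_factor_max": float(factor.max()),
            "converged": converged,
            "max_displacement_px": float(np.hypot(ux, uy).max()),
        },
    )
    result.amplitude = correct_amplitude(result, geometry)
    return result


def solve_joint(I0: IntensityImage, I: IntensityImage, geometry: SensorGeometry,
                params: SolverParams | None = None) -> ReconResult:
    """Jointly reconstruct wavefront and modulated intensity from one pair.

    Alternates Gauss-Newton phase updates with per-pixel intensity
    updates (both ADMM-regularized), backtracking so the objective trace
    never increases; the returned wavefront is tilt-removed and
    zero-mean and the amplitude is caustic-corrected.
    """
    return _solve(I0, I, geometry, params or SolverParams(), update_amplitude=True)


def curl_free_flow(I0: IntensityImage, I: IntensityImage, geometry: SensorGeometry,
                   params: SolverParams | None = None) -> WavefrontMap:
    """Curl-free optical flow baseline: the displacement is parameterized
    as a phase gradient and optimized with the phase priors only, with the
    sample amplitude frozen at one (no caustic/amplitude coupling)."""
    result = _solve(I0, I, geometry, params or SolverParams(), update_amplitude=False)
    return result.wavefront


def track_slopes(I0: IntensityImage, I: IntensityImage,
                 window_px: int = 32, stride: int | None = None,
                 upsample_factor: int = 20,
                 texture_rel_std: float = 1e-3) -> SlopeField:
    """Windowed subpixel cross-correlation speckle tracking.

    Each window's displacement is the subpixel phase-correlation peak of
    measurement against reference; textureless windows are flagged and
    inpainted from their nearest valid neighbours, and the window-grid
    field is bilinearly upsampled to the full pixel grid.
    """
    if window_px < 8:
        raise ValueError("window must be at least 8 px")
    if I0.shape != I.shape:
        raise ValueError("reference and measurement must be congruent")
    stride = stride or window_px // 2
    ny, nx = I0.shape
    ys = np.arange(0, ny - window_px + 1, stride)
    xs = np.arange(0, nx - window_px + 1, stride)
    if len(ys) < 2 or len(xs) < 2:
        raise ValueError("image too small for the requested window/stride")
    dx = np.full((len(ys), len(xs)), np.nan)
    dy = np.full((len(ys), len(xs)), np.nan)
    for i, y0 in enumerate(ys):
        for j, x0 in enumerate(xs):
            sl = (slice(y0, y0 + window_px), slice(x0, x0 + window_px))
            ref = I0.data[sl]
            if ref.std() <= texture_rel_std * max(ref.mean(), 1e-30):
                continue  # textureless: leave invalid
            shift, _, _ = phase_cross_correlation(ref, I.data[sl],
                                                  upsample_factor=upsample_factor)
            # the speckle moved by -shift (shift registers I back onto I0)
            dy[i, j], dx[i, j] = -shift[0], -shift[1]
    valid = np.isfinite(dx)
    if not valid.any():
        raise ValueError("no window had trackable speckle texture")
    if not valid.all():
        idx = ndimage.distance_transform_edt(~valid, return_distances=False,
                                             return_indices=True)
        dx = dx[tuple(idx)]
        dy = dy[tuple(idx)]
    centers_y = ys + (window_px - 1) / 2.0
    centers_x = xs + (window_px - 1) / 2.0
    full = np.mgrid[0:ny, 0:nx]
    iy = np.clip(np.interp(full[0][:, 0], centers_y, np.arange(len(ys))), 0, len(ys) - 1)
    ix = np.clip(np.interp(full[1][0, :], centers_x, np.arange(len(xs))), 0, len(xs) - 1)
    coords = np.meshgrid(iy, ix, indexing="ij")
    dx_full = ndimage.map_coordinates(dx, coords, order=1, mode="nearest")
    dy_full = ndimage.map_coordinates(dy, coords, order=1, mode="nearest")
    geometry = SensorGeometry(sensor_pitch_um=I0.pitch_um)
    return SlopeField(dx_px=dx_full, dy_px=dy_full, geometry=geometry,
                      valid=valid)


def integrate_slopes(slopes: SlopeField, geometry: SensorGeometry | None = None
                     ) -> WavefrontMap:
    """Least-squares curl-free integration of a tracked displacement field.

    The displacement in pixels divided by the geometry's
    phase-to-shift factor gives per-pixel phase differences; a Neumann
    Poisson solve (exact discrete inverse of the forward-difference
    gradient) returns the zero-mean wavefront.  A slope field with a curl
    component integrates to the potential of its curl-free part.
    """
    geometry = geometry or slopes.geometry
    kappa = geometry.phase_to_shift_px
    phi = integrate_gradient(slopes.dx_px / kappa, slopes.dy_px / kappa)
    return WavefrontMap.from_phase(phi, pitch_um=geometry.sensor_pitch_um,
                                   wavelength_um=geometry.wavelength_um)


def track_and_integrate(I0: IntensityImage, I: IntensityImage,
                        geometry: SensorGeometry, window_px: int = 32,
                        stride: int | None = None) -> WavefrontMap:
    """Classical slope-tracking baseline: track windows, then integrate."""
    slopes = track_slopes(I0, I, window_px=window_px, stride=stride)
    slopes = SlopeField(dx_px=slopes.dx_px, dy_px=slopes.dy_px,
                        geometry=geometry, valid=slopes.valid)
    wf = integrate_slopes(slopes, geometry)
    wf = remove_tilt(wf)
    wf.opd_um -= wf.opd_um.mean()
    return wf
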