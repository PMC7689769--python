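"""Target-field gradient coil design for a transverse-B0 Halbach magnet.

In a dipolar Halbach array the main field B0 points *across* the bore (z in
this package's convention) while the coil formers are cylinders around the
bore axis (x). The imaging gradients are therefore the spatial derivatives of
Bz - not of the axial component as in a conventional superconducting magnet -
and off-the-shelf coil layouts do not apply. The y- and z-gradient coils come
out quadrupole-like, while the x-gradient (gradient along the bore) is a
distinct longitudinal pattern with field nulls and reversal points just
beyond the former ends.

Design method
-------------
A divergence-free surface current on the cylindrical former is represented by
a stream function psi(phi, x) expanded in azimuthal harmonics times axial
sine modes (so no current crosses the former ends). The current density is
K = grad(psi) x n, and Bz produced at a set of target points inside the
former is linear in the expansion coefficients. The coefficients solve a
Tikhonov-regularized least-squares problem matching Bz = G * u (u the
coordinate of the requested axis) on the target points, with the surface
current power as the penalty. The continuous solution is then discretized
into wire loops by contouring psi at equally spaced levels: each contour is a
closed wire carrying the level spacing delta-psi as its current.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
import numpy as np

from .fieldcore import (
    DSVRegion,
    FieldMap,
    PointGrid,
    WireSet,
    biot_savart,
)

__all__ = [
    "CylindricalFormer",
    "StreamFunction",
    "GradientPerformance",
    "design_stream_function",
    "stream_function_residual",
    "contour_wires",
    "design_gradient_coil",
    "gradient_performance",
    "encoding_field_map",
    "wireset_to_csv",
    "wireset_from_csv",
]

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class CylindricalFormer:
    """Cylindrical coil former around the bore axis (x)."""

    radius: float = 0.125
    length: float = 0.35

    def __post_init__(self):
        if not 0 < self.radius < 0.135:
            raise ValueError("former radius must be positive and fit the 0.135 m bore")
        if self.length <= 0:
            raise ValueError("former length must be positive")


@dataclass(frozen=True)
class StreamFunction:
    """Stream function on a cylindrical former, psi(phi, x) in amperes.

    ``coeffs`` has one entry per basis function; the basis is the outer
    product of azimuthal functions {1, cos(m phi), sin(m phi); m = 1..m_max}
    and axial modes sin(n pi (x + L/2) / L), n = 1..n_axial. Contours of psi
    are current paths; the reconstructed surface current is divergence-free
    by construction.
    """

    former: CylindricalFormer
    coeffs: np.ndarray
    m_max: int = 4
    n_axial: int = 12
    regularization: float = 0.0

    def __post_init__(self):
        c = np.asarray(self.coeffs, dtype=float)
        if not np.all(np.isfinite(c)):
            raise ValueError("coefficients must be finite")
        if len(c) != (2 * self.m_max + 1) * self.n_axial:
            raise ValueError("coefficient count does not match the basis")
        object.__setattr__(self, "coeffs", c)

    # -- basis evaluation ---------------------------------------------------

    def _angular(self, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Angular functions and their d/dphi, shape (npts, 2*m_max+1)."""
        cols = [np.ones_like(phi)]
        dcols = [np.zeros_like(phi)]
        for m in range(1, self.m_max + 1):
            cols += [np.cos(m * phi), np.sin(m * phi)]
            dcols += [-m * np.sin(m * phi), m * np.cos(m * phi)]
        return np.stack(cols, axis=-1), np.stack(dcols, axis=-1)

    def _axial(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Axial modes and their d/dx, shape (npts, n_axial)."""
        L = self.former.length
        n = np.arange(1, self.n_axial + 1)
        arg = np.pi * n * (x[..., None] + L / 2) / L
        return np.sin(arg), (np.pi * n / L) * np.cos(arg)

    def basis_matrix(self, phi: np.ndarray, x: np.ndarray) -> np.ndarray:
        """psi basis values at (phi, x) pairs, shape (npts, n_basis)."""
        ang, _ = self._angular(phi)
        ax, _ = self._axial(x)
        return (ang[:, :, None] * ax[:, None, :]).reshape(len(phi), -1)

    def psi(self, phi: np.ndarray, x: np.ndarray) -> np.ndarray:
        return self.basis_matrix(phi, x) @ self.coeffs

    def psi_grid(self, phi: np.ndarray, x: np.ndarray) -> np.ndarray:
        """psi on the outer product of 1-D phi and x axes, shape (nphi, nx).

        Uses the separability of the basis: psi = Ang(phi) C Ax(x)^T with C
        the (angular, axial) coefficient matrix.
        """
        ang, _ = self._angular(np.asarray(phi, dtype=float))
        ax, _ = self._axial(np.asarray(x, dtype=float))
        C = self.coeffs.reshape(2 * self.m_max + 1, self.n_axial)
        return ang @ C @ ax.T

    def surface_current_basis(
        self, phi: np.ndarray, x: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-basis K components at (phi, x): (Kx, Kphi), each (npts, n_basis).

        K = grad_s(psi) x n with n the outward radial normal:
        Kx = -(1/a) dpsi/dphi,  Kphi = dpsi/dx.
        """
        a = self.former.radius
        ang, dang = self._angular(phi)
        ax, dax = self._axial(x)
        Kx = -(dang[:, :, None] * ax[:, None, :]).reshape(len(phi), -1) / a
        Kphi = (ang[:, :, None] * dax[:, None, :]).reshape(len(phi), -1)
        return Kx, Kphi

    # -- field of the continuous current ------------------------------------

    def field(
        self, grid: PointGrid, n_phi: int = 72, n_x: int = 60, chunk: int = 256
    ) -> FieldMap:
        """Field of the continuous surface current (patch-discretized)."""
        a, L = self.former.radius, self.former.length
        phi = (np.arange(n_phi) + 0.5) * 2 * np.pi / n_phi
        x = -L / 2 + (np.arange(n_x) + 0.5) * L / n_x
        PHI, X = np.meshgrid(phi, x, indexing="ij")
        phi_f, x_f = PHI.ravel(), X.ravel()
        dA = a * (2 * np.pi / n_phi) * (L / n_x)
        Kx, Kphi = self.surface_current_basis(phi_f, x_f)
        kx = Kx @ self.coeffs
        kphi = Kphi @ self.coeffs
        Kc = np.stack(
            [kx, kphi * np.cos(phi_f), -kphi * np.sin(phi_f)], axis=1
        )  # (npatch, 3)
        patch_pos = np.stack([x_f, a * np.sin(phi_f), a * np.cos(phi_f)], axis=1)
        pts = grid.points
        B = np.empty((len(pts), 3))
        for lo in range(0, len(pts), chunk):
            d = pts[lo : lo + chunk, None, :] - patch_pos[None, :, :]
            inv_r3 = np.linalg.norm(d, axis=2) ** (-3.0)
            B[lo : lo + chunk] = (
                1e-7 * dA * np.einsum("psk,ps->pk", np.cross(Kc[None, :, :], d), inv_r3)
            )
        return FieldMap(grid=grid, B=B)


@dataclass(frozen=True)
class GradientPerformance:
    """Efficiency and linearity figures of a gradient coil."""

    efficiency: float  # mT/m/A at the magnet centre
    nonlinearity_max: float  # % over the stated FOV
    field_map: FieldMap
    fov: float
    axis: str
    resistance_estimate: float | None = None

    def __post_init__(self):
        if self.nonlinearity_max < 0:
            raise ValueError("nonlinearity must be non-negative")


# ---------------------------------------------------------------------------
# Design matrix assembly
# ---------------------------------------------------------------------------


def _assembly_matrices(
    former: CylindricalFormer,
    targets: np.ndarray,
    m_max: int,
    n_axial: int,
    n_phi: int,
    n_x: int,
):
    """Bz design matrix A (ntargets, nbasis) and current-power matrix R."""
    a, L = former.radius, former.length
    phi = (np.arange(n_phi) + 0.5) * 2 * np.pi / n_phi
    x = -L / 2 + (np.arange(n_x) + 0.5) * L / n_x
    PHI, X = np.meshgrid(phi, x, indexing="ij")
    phi_f, x_f = PHI.ravel(), X.ravel()
    dA = a * (2 * np.pi / n_phi) * (L / n_x)

    sf = StreamFunction(
        former=former,
        coeffs=np.zeros((2 * m_max + 1) * n_axial),
        m_max=m_max,
        n_axial=n_axial,
    )
    Kx, Kphi = sf.surface_current_basis(phi_f, x_f)  # (npatch, nbasis)
    # Cartesian current components on the surface: position (x, a sin, a cos)
    # with phi measured from the B0 (z) axis; phi-hat = (0, cos phi, -sin phi).
    Ky = Kphi * np.cos(phi_f)[:, None]
    Kz = -Kphi * np.sin(phi_f)[:, None]
    patch_pos = np.stack([x_f, a * np.sin(phi_f), a * np.cos(phi_f)], axis=1)

    d = targets[:, None, :] - patch_pos[None, :, :]  # (T, P, 3)
    inv_r3 = np.linalg.norm(d, axis=2) ** (-3.0)
    # (K x d)_z = Kx*dy - Ky*dx
    Wy = 1e-7 * dA * d[:, :, 1] * inv_r3  # multiplies Kx
    Wx = 1e-7 * dA * d[:, :, 0] * inv_r3  # multiplies Ky
    A = Wy @ Kx - Wx @ Ky
    del Kz

    Kmat = np.vstack([Kx, Kphi])
    R = dA * (Kmat.T @ Kmat)
    return A, R


def _lcurve_lambda(
    A: np.ndarray, R: np.ndarray, b: np.ndarray, n_lambda: int = 25
) -> float:
    """Pick the Tikhonov weight at the corner of the L-curve."""
    AtA, Atb = A.T @ A, A.T @ b
    scale = np.trace(AtA) / max(np.trace(R), 1e-300)
    lams = scale * np.logspace(-9, 1, n_lambda)
    res, sem = [], []
    for lam in lams:
        c = np.linalg.solve(AtA + lam * R, Atb)
        res.append(np.linalg.norm(A @ c - b))
        sem.append(np.sqrt(max(c @ R @ c, 1e-300)))
    lr, ls = np.log(np.asarray(res)), np.log(np.asarray(sem))
    # discrete curvature of the L-curve
    d1r, d1s = np.gradient(lr), np.gradient(ls)
    d2r, d2s = np.gradient(d1r), np.gradient(d1s)
    kappa = (d1r * d2s - d1s * d2r) / (d1r**2 + d1s**2) ** 1.5
    return float(lams[int(np.argmax(kappa))])


def design_stream_function(
    axis: str,
    former: CylindricalFormer,
    target_gradient: float,
    target_region: DSVRegion,
    *,
    m_max: int = 4,
    n_axial: int = 12,
    reg_weight: float | None = None,
    n_phi: int = 72,
    n_x: int = 60,
) -> StreamFunction:
    """Solve the regularized target-field problem on the former surface.

    Parameters
    ----------
    axis : {'x', 'y', 'z'}
        Gradient axis: the target is Bz = G * (coordinate of this axis).
    target_gradient : float
        Requested gradient strength, mT/m.
    target_region : DSVRegion
        Points on which the target field is imposed; must fit inside the
        former with at least 1 cm radial margin.
    reg_weight : float, optional
        Tikhonov weight on the surface-current power. Default: chosen by an
        L-curve corner search.
    """
    ax = _AXIS_INDEX[axis]
    pts = target_region.sample_points.points
    rho = np.linalg.norm(pts[:, 1:], axis=1)
    if np.any(rho > former.radius - 0.01) or np.any(
        np.abs(pts[:, 0]) > former.length / 2
    ):
        raise ValueError("target region must fit inside the former with 1 cm margin")
    b = (target_gradient * 1e-3) * pts[:, ax]  # tesla
    A, R = _assembly_matrices(former, pts, m_max, n_axial, n_phi, n_x)
    lam = _lcurve_lambda(A, R, b) if reg_weight is None else reg_weight
    M = A.T @ A + lam * R
    try:
        c = np.linalg.solve(M, A.T @ b)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "target-field system is singular; increase the regularization weight"
        ) from e
    cond = np.linalg.cond(M)
    if cond > 1e14:
        raise np.linalg.LinAlgError(
            f"target-field system is ill-conditioned (cond={cond:.2e}); "
            "increase the regularization weight"
        )
    return StreamFunction(
        former=former, coeffs=c, m_max=m_max, n_axial=n_axial, regularization=lam
    )


def stream_function_residual(
    sf: StreamFunction,
    axis: str,
    target_gradient: float,
    target_region: DSVRegion,
    n_phi: int = 72,
    n_x: int = 60,
) -> float:
    """Relative RMS error of the continuous solution on the target points."""
    ax = _AXIS_INDEX[axis]
    pts = target_region.sample_points.points
    b = (target_gradient * 1e-3) * pts[:, ax]
    A, _ = _assembly_matrices(sf.former, pts, sf.m_max, sf.n_axial, n_phi, n_x)
    resid = A @ sf.coeffs - b
    return float(np.sqrt(np.mean(resid**2)) / np.sqrt(np.mean(b**2)))


# ---------------------------------------------------------------------------
# Contour discretization
# ---------------------------------------------------------------------------


def _crop_wrap_contour(c: np.ndarray, n_phi_2pi: float) -> np.ndarray | None:
    """Reduce a contour spanning >= 2 pi of azimuth to one period (a hoop).

    ``c`` is in (row=phi index, col=x index) coordinates. Points with phi
    index in [pi, 3 pi) are kept; the ends then map to the same point on the
    cylinder, so the cropped curve closes around the azimuth.
    """
    span = c[:, 0].max() - c[:, 0].min()
    if span < n_phi_2pi * 0.98:
        return None
    mask = (c[:, 0] >= n_phi_2pi / 2) & (c[:, 0] < 3 * n_phi_2pi / 2)
    if mask.sum() < 4:
        return None
    return c[mask]


def contour_wires(
    sf: StreamFunction,
    n_contours: int = 12,
    *,
    grid_phi: int = 720,
    grid_x: int = 361,
    max_segment: float = 0.004,
) -> WireSet:
    """Discretize a stream function into closed wire loops.

    psi is contoured at levels +-(k - 1/2) * dpsi, k = 1..n_contours, with
    dpsi = max|psi| / n_contours; every loop carries dpsi amperes when the
    (series-connected) coil is driven with dpsi, i.e. the WireSet current is
    dpsi. Contours are extracted on a doubly-unrolled azimuthal domain so
    loops crossing the phi = 0 seam and full hoops are both handled.
    """
    from skimage import measure

    a, L = sf.former.radius, sf.former.length
    phi = np.linspace(0, 4 * np.pi, 2 * grid_phi - 1)
    x = np.linspace(-L / 2, L / 2, grid_x)
    psi = sf.psi_grid(phi, x)
    dphi = phi[1] - phi[0]
    dx = x[1] - x[0]
    n_phi_2pi = 2 * np.pi / dphi

    psi_max = np.abs(psi).max()
    if psi_max <= 0:
        raise ValueError("stream function is identically zero")
    dpsi = psi_max / n_contours
    levels = [(k + 0.5) * dpsi * s for k in range(n_contours) for s in (1, -1)]

    loops: list[tuple[np.ndarray, bool]] = []  # ((phi, x) polyline, is_hoop)
    for level in levels:
        if abs(level) >= psi_max:
            continue
        for c in measure.find_contours(psi, level, positive_orientation="high"):
            is_hoop = False
            if not np.allclose(c[0], c[-1]):
                cc = _crop_wrap_contour(c, n_phi_2pi)
                if cc is None:
                    continue  # clipped duplicate of a loop seen at another unroll
                c, is_hoop = cc, True
            else:
                mean_phi = c[:, 0].mean() * dphi
                if not (np.pi <= mean_phi < 3 * np.pi):
                    continue  # keep exactly one unrolled copy of each loop
            loops.append(
                (np.stack([c[:, 0] * dphi, -L / 2 + c[:, 1] * dx], axis=1), is_hoop)
            )

    if not loops:
        raise ValueError("no closed contours found; increase n_contours")

    paths = []
    for lp, is_hoop in loops:
        p3 = np.stack([lp[:, 1], a * np.sin(lp[:, 0]), a * np.cos(lp[:, 0])], axis=1)
        if is_hoop:
            p3 = np.vstack([p3, p3[:1]])  # phi and phi + 2 pi meet on the cylinder
        paths.append(_resample_closed(p3, max_segment))
    return WireSet(paths=tuple(paths), current=dpsi, wire_diameter=0.0015)


def _resample_closed(path: np.ndarray, max_segment: float) -> np.ndarray:
    """Resample a closed polyline to roughly uniform segment length."""
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(np.ceil(total / max_segment)), 8)
    si = np.linspace(0.0, total, n + 1)
    out = np.stack([np.interp(si, s, path[:, k]) for k in range(3)], axis=1)
    out[-1] = out[0]
    return out


def design_gradient_coil(
    axis: str,
    former: CylindricalFormer,
    target_gradient: float,
    target_region: DSVRegion,
    n_contours: int = 12,
    **kwargs,
) -> WireSet:
    """Design a discrete-wire gradient coil: target-field solve + contouring.

    The returned WireSet's polarity is normalized so that the central
    gradient has the sign of ``target_gradient``.
    """
    sf = design_stream_function(
        axis, former, target_gradient, target_region, **kwargs
    )
    wires = contour_wires(sf, n_contours)
    g0 = _central_gradient(wires, axis)
    if g0 * target_gradient < 0:
        wires = dataclasses.replace(wires, current=-wires.current)
    return wires


# ---------------------------------------------------------------------------
# Performance metrics
# ---------------------------------------------------------------------------


def _central_gradient(wires: WireSet, axis: str, step: float = 0.002) -> float:
    """dBz/du at the magnet centre (T/m) via central finite difference."""
    ax = _AXIS_INDEX[axis]
    pts = np.zeros((2, 3))
    pts[0, ax] = -step
    pts[1, ax] = +step
    bz = biot_savart(wires, PointGrid(points=pts)).b0_component
    return float((bz[1] - bz[0]) / (2 * step))


def gradient_performance(
    wires: WireSet,
    fov: float,
    grid_spacing: float,
    axis: str,
    *,
    region: str = "sphere",
    current: float | None = None,
) -> GradientPerformance:
    """Efficiency (mT/m/A) and maximum nonlinearity (%) over a FOV.

    Nonlinearity at a point r is |Bz(r) - G0*u| / (G0 * fov/2) * 100 with G0
    the central gradient and u the coordinate along the gradient axis; the
    maximum is taken over a cubic lattice of the given spacing restricted to
    the inscribed sphere of diameter ``fov`` (``region='cube'`` uses the full
    cube).
    """
    if current is not None:
        wires = wires.scaled(current)
    if wires.current == 0:
        raise ValueError("wire current must be nonzero")
    ax = _AXIS_INDEX[axis]
    n = int(round(fov / grid_spacing)) + 1
    grid = PointGrid.from_lattice((n, n, n), grid_spacing)
    pts = grid.points
    if region == "sphere":
        keep = np.linalg.norm(pts, axis=1) <= fov / 2 + 1e-12
    elif region == "cube":
        keep = np.ones(len(pts), dtype=bool)
    else:
        raise ValueError("region must be 'sphere' or 'cube'")
    eval_grid = PointGrid(points=pts[keep])
    fmap = biot_savart(wires, eval_grid)
    g0 = _central_gradient(wires, axis)
    if g0 == 0:
        raise ValueError("central gradient is zero; cannot normalize")
    u = eval_grid.points[:, ax]
    dev = np.abs(fmap.b0_component - g0 * u) / (abs(g0) * fov / 2) * 100.0
    return GradientPerformance(
        efficiency=abs(g0) / abs(wires.current) * 1e3,
        nonlinearity_max=float(dev.max()),
        field_map=fmap,
        fov=fov,
        axis=axis,
        resistance_estimate=wires.resistance_estimate(),
    )


def encoding_field_map(
    wires: WireSet, grid: PointGrid, axis: str
) -> np.ndarray:
    """Per-point effective coordinate (m) of a gradient coil: Bz(r) / G0.

    Equals the true coordinate wherever the coil is perfectly linear; this is
    the quantity the conjugate-phase reconstruction consumes.
    """
    g0 = _central_gradient(wires, axis)
    if g0 == 0:
        raise ValueError("central gradient is zero; cannot normalize")
    bz = biot_savart(wires, grid).b0_component
    return bz / g0


# ---------------------------------------------------------------------------
# Wire I/O
# ---------------------------------------------------------------------------


def wireset_to_csv(wires: WireSet, csv_path, manifest_path=None) -> None:
    """CSV rows (path_id, x, y, z) plus an optional JSON manifest."""
    rows = []
    for i, p in enumerate(wires.paths):
        ids = np.full((len(p), 1), i, dtype=float)
        rows.append(np.hstack([ids, p]))
    np.savetxt(
        csv_path,
        np.vstack(rows),
        delimiter=",",
        header="path_id,x,y,z",
        comments="",
    )
    if manifest_path is not None:
        with open(manifest_path, "w") as f:
            json.dump(
                {
                    "current": wires.current,
                    "wire_diameter": wires.wire_diameter,
                    "n_paths": wires.n_paths,
                },
                f,
            )


def wireset_from_csv(csv_path, manifest_path=None) -> WireSet:
    data = np.atleast_2d(np.loadtxt(csv_path, delimiter=",", skiprows=1))
    current, wd = 1.0, 0.0015
    if manifest_path is not None:
        with open(manifest_path) as f:
            m = json.load(f)
        current, wd = m["current"], m["wire_diameter"]
    paths = tuple(
        data[data[:, 0] == pid, 1:4] for pid in np.unique(data[:, 0])
    )
    return WireSet(paths=paths, current=current, wire_diameter=wd)
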