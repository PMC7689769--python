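"""Elementary magnetostatics and scalar utilities for low-field MRI design.

This module provides the building blocks everything else rests on: point-dipole
field sums for permanent-magnet arrays, finite-segment Biot-Savart for wire
coils, field-homogeneity metrics over a spherical target volume, and the small
set of scalar formulas (Larmor frequency, thermal drift sensitivity, Johnson
noise density) used when reasoning about a ~50 mT permanent-magnet scanner.

Coordinate convention used throughout the package
-------------------------------------------------
* ``x`` (index 0) is the bore axis of the cylindrical magnet.
* ``z`` (index 2) is the main-field (B0) direction, *transverse* to the bore,
  as is characteristic of a dipolar (k = 1) Halbach array.
* ``y`` (index 1) completes the right-handed frame.

All positions are in metres and all fields in tesla unless stated otherwise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as _field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MU0",
    "GAMMA_BAR_HZ_PER_T",
    "K_BOLTZMANN",
    "T_ROOM_K",
    "NDFEB_TEMPCO_PER_C",
    "REMANENCE_T",
    "BORE_AXIS",
    "B0_AXIS",
    "MagnetElement",
    "PointGrid",
    "FieldMap",
    "DSVRegion",
    "WireSet",
    "SingularFieldError",
    "dipole_field",
    "biot_savart",
    "homogeneity_ppm",
    "larmor_frequency",
    "thermal_drift_sensitivity",
    "johnson_noise_density",
]

# ---------------------------------------------------------------------------
# Physical constants and package-wide configuration
# ---------------------------------------------------------------------------

MU0 = 4e-7 * np.pi  # vacuum permeability, T*m/A

#: Proton gyromagnetic ratio over 2*pi, Hz/T.
GAMMA_BAR_HZ_PER_T = 42.5774785e6

K_BOLTZMANN = 1.380649e-23  # J/K
T_ROOM_K = 290.0

#: Fractional change of NdFeB remanence per degree Celsius (magnitude).
#: Vendor data sheets quote 0.10-0.12 %/degC for sintered N-grades.
NDFEB_TEMPCO_PER_C = 0.0012

#: Typical remanence of common sintered NdFeB grades, tesla.
REMANENCE_T = {"N48": 1.42, "N45": 1.35}

BORE_AXIS = np.array([1.0, 0.0, 0.0])
B0_AXIS = np.array([0.0, 0.0, 1.0])


class SingularFieldError(ValueError):
    """Raised when a field is requested at (or too close to) a source."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MagnetElement:
    """A single permanent magnet modelled as a point dipole.

    Parameters
    ----------
    center : (3,) array
        Position of the magnet centre, m.
    moment_dir : (3,) array
        Unit vector along the magnetization.
    remanence : float
        Remanent flux density Br of the material, T.
    volume : float
        Magnet volume, m^3. The dipole moment is ``Br * V / mu0``.
    """

    center: np.ndarray
    moment_dir: np.ndarray
    remanence: float
    volume: float

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        d = np.asarray(self.moment_dir, dtype=float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"moment_dir must be a unit vector, |d| = {n!r}")
        object.__setattr__(self, "moment_dir", d)
        if not self.volume > 0:
            raise ValueError("volume must be positive")
        if not self.remanence > 0:
            raise ValueError("remanence must be positive")

    @property
    def moment(self) -> np.ndarray:
        """Dipole moment vector m = Br*V/mu0 * moment_dir, A*m^2."""
        return (self.remanence * self.volume / MU0) * self.moment_dir

    @property
    def size(self) -> float:
        """Edge length of the equivalent cube, m (used for singularity checks)."""
        return float(self.volume ** (1.0 / 3.0))


@dataclass(frozen=True)
class PointGrid:
    """A named set of evaluation points, optionally on a regular lattice."""

    points: np.ndarray
    shape: tuple | None = None
    spacing: float | tuple | None = None

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.shape[-1] != 3:
            raise ValueError("points must be (N, 3)")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points must be finite")
        if self.shape is not None and int(np.prod(self.shape)) != len(pts):
            raise ValueError("len(points) must equal product(shape)")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    @classmethod
    def from_lattice(
        cls,
        shape: Sequence[int],
        spacing: float | Sequence[float],
        center: Sequence[float] = (0.0, 0.0, 0.0),
    ) -> "PointGrid":
        """Centred rectangular lattice. ``spacing`` may be scalar or per-axis."""
        shape = tuple(int(s) for s in shape)
        sp = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
        axes = [
            (np.arange(n) - (n - 1) / 2.0) * d + c
            for n, d, c in zip(shape, sp, center)
        ]
        g = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([a.ravel() for a in g], axis=1)
        return cls(points=pts, shape=shape, spacing=tuple(sp))


@dataclass(frozen=True)
class FieldMap:
    """Vector magnetic field sampled on a :class:`PointGrid`.

    ``b0_axis`` defines the direction onto which ``b0_component`` projects;
    it defaults to the package-wide transverse B0 axis (z).
    """

    grid: PointGrid
    B: np.ndarray
    b0_axis: np.ndarray = _field(default_factory=lambda: B0_AXIS.copy())

    def __post_init__(self):
        B = np.atleast_2d(np.asarray(self.B, dtype=float))
        if B.shape != (len(self.grid), 3):
            raise ValueError(f"B must be ({len(self.grid)}, 3), got {B.shape}")
        ax = np.asarray(self.b0_axis, dtype=float)
        ax = ax / np.linalg.norm(ax)
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "b0_axis", ax)

    @property
    def b0_component(self) -> np.ndarray:
        """Projection of B on the B0 axis, per point (T)."""
        return self.B @ self.b0_axis

    def __add__(self, other: "FieldMap") -> "FieldMap":
        if len(other.grid) != len(self.grid) or not np.allclose(
            other.grid.points, self.grid.points
        ):
            raise ValueError("cannot add field maps on different grids")
        return FieldMap(grid=self.grid, B=self.B + other.B, b0_axis=self.b0_axis)

    # -- serialization ------------------------------------------------------

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("points", data=self.grid.points)
            f.create_dataset("B", data=self.B)
            f.attrs["b0_axis"] = self.b0_axis
            f.attrs["units"] = "SI: points in m, B in T"
            f.attrs["axis_convention"] = "x = bore axis, z = B0 (transverse)"
            if self.grid.shape is not None:
                f.attrs["grid_shape"] = self.grid.shape

    @classmethod
    def from_hdf5(cls, path) -> "FieldMap":
        import h5py

        with h5py.File(path, "r") as f:
            pts = f["points"][()]
            B = f["B"][()]
            ax = f.attrs.get("b0_axis", B0_AXIS)
            shape = f.attrs.get("grid_shape", None)
            shape = tuple(int(s) for s in shape) if shape is not None else None
        return cls(grid=PointGrid(points=pts, shape=shape), B=B, b0_axis=np.asarray(ax))

    def to_csv(self, path) -> None:
        """Flat CSV: x,y,z,Bx,By,Bz in SI units."""
        data = np.hstack([self.grid.points, self.B])
        header = "x,y,z,Bx,By,Bz"
        np.savetxt(path, data, delimiter=",", header=header, comments="")

    @classmethod
    def from_csv(cls, path) -> "FieldMap":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        data = np.atleast_2d(data)
        return cls(grid=PointGrid(points=data[:, :3]), B=data[:, 3:6])


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors via the golden-angle spiral."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    cos_t = 1.0 - 2.0 * i / n
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    return np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=1)


@dataclass(frozen=True)
class DSVRegion:
    """Spherical target volume (diameter of spherical volume, DSV).

    Homogeneity of the main field is specified over this region. The sample
    points are carried explicitly so that a field evaluated once on them can
    be re-used by optimizers.
    """

    diameter: float
    center: np.ndarray
    sample_points: PointGrid

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        r = np.linalg.norm(self.sample_points.points - self.center, axis=1)
        if np.any(r > self.diameter / 2 + 1e-12):
            raise ValueError("sample point outside the spherical region")

    @classmethod
    def fibonacci(
        cls,
        diameter: float = 0.20,
        center: Sequence[float] = (0.0, 0.0, 0.0),
        n_shells: int = 11,
        points_per_shell: int = 100,
    ) -> "DSVRegion":
        """Centre point plus ``n_shells`` concentric golden-angle shells.

        The default (11 x 100 + 1 = 1101 points) is a cheap rotation-fair
        sample of a 20-cm DSV.
        """
        center = np.asarray(center, dtype=float)
        radii = np.linspace(diameter / 2 / n_shells, diameter / 2, n_shells)
        pts = [center[None, :]]
        for r in radii:
            pts.append(center + r * _fibonacci_sphere(points_per_shell))
        return cls(
            diameter=diameter,
            center=center,
            sample_points=PointGrid(points=np.vstack(pts)),
        )


@dataclass(frozen=True)
class WireSet:
    """Ordered 3-D wire paths sharing a common (series) drive current.

    Each path is an (N, 3) polyline in metres. Closed loops have first point
    equal to last point; paths that are not closed must be listed in
    ``open_paths`` (leads). Current is in amperes; positive current flows in
    the direction of increasing point index.
    """

    paths: tuple
    current: float = 1.0
    wire_diameter: float = 0.0015
    open_paths: frozenset = frozenset()

    def __post_init__(self):
        paths = tuple(np.asarray(p, dtype=float) for p in self.paths)
        for i, p in enumerate(paths):
            if p.ndim != 2 or p.shape[1] != 3 or len(p) < 2:
                raise ValueError(f"path {i} must be an (N>=2, 3) polyline")
            if i not in self.open_paths and not np.allclose(p[0], p[-1], atol=1e-9):
                raise ValueError(
                    f"path {i} is not closed; mark it in open_paths if it is a lead"
                )
        object.__setattr__(self, "paths", paths)
        if not np.isfinite(self.current):
            raise ValueError("current must be finite")

    @property
    def n_paths(self) -> int:
        return len(self.paths)

    def total_length(self) -> float:
        return float(
            sum(np.linalg.norm(np.diff(p, axis=0), axis=1).sum() for p in self.paths)
        )

    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        """All segment start/end points stacked over paths: (S,3), (S,3)."""
        a = np.vstack([p[:-1] for p in self.paths])
        b = np.vstack([p[1:] for p in self.paths])
        return a, b

    def scaled(self, current: float) -> "WireSet":
        return dataclasses.replace(self, current=current)

    def resistance_estimate(self, resistivity: float = 1.68e-8) -> float:
        """Ohmic resistance of the full series winding (copper default)."""
        area = np.pi * (self.wire_diameter / 2.0) ** 2
        return resistivity * self.total_length() / area


# ---------------------------------------------------------------------------
# Field computations
# ---------------------------------------------------------------------------


def dipole_field(
    elements: Iterable[MagnetElement],
    grid: PointGrid,
    *,
    b0_axis: np.ndarray | None = None,
    chunk: int = 2048,
) -> FieldMap:
    """Superposed point-dipole field of a set of permanent magnets.

    B(r) = sum over elements of (mu0 / 4 pi) [3 (m . r^) r^ - m] / |r|^3,
    with m = Br * V / mu0 * moment_dir. The sum is linear both in the element
    list (superposition) and in each remanence.

    Raises
    ------
    SingularFieldError
        If any evaluation point lies within half an element size of that
        element's centre (point-dipole model invalid there).
    """
    elements = list(elements)
    pts = grid.points
    B = np.zeros((len(pts), 3))
    if elements:
        centers = np.stack([e.center for e in elements])  # (E, 3)
        moments = np.stack([e.moment for e in elements])  # (E, 3)
        min_dist = np.array([e.size / 2.0 for e in elements])  # (E,)
        for lo in range(0, len(pts), chunk):
            p = pts[lo : lo + chunk]  # (P, 3)
            d = p[:, None, :] - centers[None, :, :]  # (P, E, 3)
            r2 = np.einsum("pek,pek->pe", d, d)
            bad = r2 <= min_dist[None, :] ** 2
            if np.any(bad):
                ip, ie = np.argwhere(bad)[0]
                raise SingularFieldError(
                    f"evaluation point {lo + ip} at {p[ip]} lies inside/too near "
                    f"magnet element {ie} at {centers[ie]}"
                )
            inv_r3 = r2 ** (-1.5)
            m_dot_d = np.einsum("ek,pek->pe", moments, d)
            B[lo : lo + chunk] = 1e-7 * (
                np.einsum("pe,pek->pk", 3.0 * m_dot_d / r2 * inv_r3, d)
                - inv_r3 @ moments
            )
    kwargs = {} if b0_axis is None else {"b0_axis": b0_axis}
    return FieldMap(grid=grid, B=B, **kwargs)


def biot_savart(
    wires: WireSet,
    grid: PointGrid,
    *,
    b0_axis: np.ndarray | None = None,
    chunk: int = 512,
) -> FieldMap:
    """Magnetic field of polyline currents via finite-segment Biot-Savart.

    Uses the exact closed form for a straight segment carrying current I
    from a to b evaluated at p (Hanson & Hirshman form):

        B = (mu0 I / 4 pi) * (r1 x r2) (|r1| + |r2|)
            / ( |r1| |r2| ( |r1| |r2| + r1 . r2 ) )

    with r1 = p - a, r2 = p - b. Converges to the smooth-curve field as the
    discretization is refined.
    """
    a, b = wires.segments()
    pts = grid.points
    B = np.zeros((len(pts), 3))
    pref = 1e-7 * wires.current
    for lo in range(0, len(pts), chunk):
        p = pts[lo : lo + chunk]
        r1 = p[:, None, :] - a[None, :, :]  # (P, S, 3)
        r2 = p[:, None, :] - b[None, :, :]
        n1 = np.linalg.norm(r1, axis=2)
        n2 = np.linalg.norm(r2, axis=2)
        denom = n1 * n2 * (n1 * n2 + np.einsum("psk,psk->ps", r1, r2))
        if np.any(denom <= 1e-30):
            ip, isg = np.argwhere(denom <= 1e-30)[0]
            raise SingularFieldError(
                f"evaluation point {lo + ip} at {p[ip]} lies on wire segment {isg}"
            )
        cross = np.cross(r1, r2)
        B[lo : lo + chunk] = pref * np.einsum(
            "psk,ps->pk", cross, (n1 + n2) / denom
        )
    kwargs = {} if b0_axis is None else {"b0_axis": b0_axis}
    return FieldMap(grid=grid, B=B, **kwargs)


# ---------------------------------------------------------------------------
# Homogeneity metrics and scalar formulas
# ---------------------------------------------------------------------------


def _region_values(field: FieldMap, region: DSVRegion | None) -> np.ndarray:
    """b0 samples of ``field`` restricted to ``region`` (matched by position)."""
    if region is None:
        return field.b0_component
    rpts = region.sample_points.points
    fpts = field.grid.points
    if len(rpts) == len(fpts) and np.allclose(rpts, fpts, atol=1e-12):
        return field.b0_component
    from scipy.spatial import cKDTree

    dist, idx = cKDTree(fpts).query(rpts)
    if np.any(dist > 1e-9):
        raise ValueError(
            "DSV sample points are not covered by the field map grid; "
            "evaluate the field on region.sample_points first"
        )
    return field.b0_component[idx]


def homogeneity_ppm(
    field: FieldMap,
    region: DSVRegion | None = None,
    *,
    metric: str = "p2p",
) -> float:
    """Field inhomogeneity over a spherical region, in ppm.

    The default (and the convention used for all quoted numbers in this
    package) is peak-to-peak over mean:

        ppm = (max - min) / mean * 1e6

    ``metric='rms'`` instead returns std/mean * 1e6.
    """
    vals = _region_values(field, region)
    if len(vals) < 2:
        raise ValueError("need at least 2 sample points in the region")
    mean = vals.mean()
    if mean <= 0:
        raise ValueError(
            "mean b0 component is non-positive; is the B0 axis configured correctly?"
        )
    if metric == "p2p":
        return float((vals.max() - vals.min()) / mean * 1e6)
    if metric == "rms":
        return float(vals.std() / mean * 1e6)
    raise ValueError(f"unknown metric {metric!r}")


def larmor_frequency(b0: float) -> float:
    """Proton Larmor frequency f = gamma-bar * B0, Hz. (~2.13 MHz at 50 mT)."""
    if b0 < 0:
        raise ValueError("B0 must be non-negative")
    return GAMMA_BAR_HZ_PER_T * b0


def thermal_drift_sensitivity(
    b0: float, tempco: float = NDFEB_TEMPCO_PER_C
) -> float:
    """Resonance-frequency sensitivity to magnet temperature, Hz per degC.

    The remanence of NdFeB falls by ~0.1-0.12% per degree Celsius, so the
    Larmor frequency drifts proportionally: f * |tempco|. At 50 mT this is
    roughly 2.5 kHz/degC.
    """
    if abs(tempco) >= 0.01:
        raise ValueError("tempco magnitude must be < 0.01 per degC")
    return larmor_frequency(b0) * abs(tempco)


def johnson_noise_density(resistance: float, temperature: float = T_ROOM_K) -> float:
    """Thermal (Johnson) voltage noise density sqrt(4 kB T R), in nV/sqrt(Hz)."""
    if resistance < 0:
        raise ValueError("resistance must be non-negative")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return float(np.sqrt(4.0 * K_BOLTZMANN * temperature * resistance) * 1e9)
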