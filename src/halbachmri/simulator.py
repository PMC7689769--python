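"""Digital phantoms and Cartesian k-space acquisition simulation.

The forward model is the discrete encoding sum

    s(kx, ky, kz) = sum_r rho(r) w(r)
                    exp(-i 2 pi [kx Gx~(r) + ky Gy~(r) + kz Gz~(r)])
                    exp(-i 2 pi dB0(r) t(kx))
                    [exp(-t_echo(ky,kz) / T2(r))]  (optional)
                    exp(-i 2 pi df(t_shot) t(kx))  (optional drift)
                    + complex white noise,

where Gu~ are the *effective coordinate* maps of the gradient coils (equal to
the true coordinates for perfectly linear coils, in which case the sum is the
plain DFT of the weighted phantom), t(kx) is the readout time measured from
the echo centre, and w(r) the steady-state contrast weighting of the chosen
sequence. The matching inverse operation lives in :mod:`halbachmri.recon`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence import DriftModel, EncodeSchedule, TSEParams, echo_train_schedule

__all__ = [
    "Phantom",
    "EncodingMaps",
    "AcqSimConfig",
    "KSpaceData",
    "tube_grid_phantom",
    "tissue_phantom",
    "contrast_weighting",
    "simulate_acquisition",
    "BRAIN_TISSUE",
    "KNEE_TISSUE",
]

#: Relaxation times (T1, T2) in ms estimated at ~50 mT.
BRAIN_TISSUE = {"brain": (500.0, 250.0), "csf": (1750.0, 0.9 * 1750.0)}
KNEE_TISSUE = {"muscle": (200.0, 47.0), "fat": (140.0, 84.0), "cartilage": (70.0, 20.0)}


@dataclass(frozen=True)
class Phantom:
    """Proton-density and relaxation maps on a voxel grid.

    ``rho`` is arbitrary units (>= 0); ``t1``/``t2`` in ms (positive wherever
    rho > 0); ``spacing``/``origin`` in mm. Arrays may be 2-D or 3-D.
    """

    rho: np.ndarray
    t1: np.ndarray
    t2: np.ndarray
    spacing: tuple
    origin: tuple | None = None

    def __post_init__(self):
        rho = np.asarray(self.rho, dtype=float)
        t1 = np.asarray(self.t1, dtype=float)
        t2 = np.asarray(self.t2, dtype=float)
        if t1.shape != rho.shape or t2.shape != rho.shape:
            raise ValueError("rho, t1, t2 grids must be congruent")
        if np.any(rho < 0):
            raise ValueError("rho must be non-negative")
        sup = rho > 0
        if np.any(t1[sup] <= 0) or np.any(t2[sup] <= 0):
            raise ValueError("t1 and t2 must be positive where rho > 0")
        spacing = tuple(float(s) for s in np.broadcast_to(self.spacing, (rho.ndim,)))
        origin = self.origin
        if origin is None:
            origin = (0.0,) * rho.ndim
        object.__setattr__(self, "rho", rho)
        object.__setattr__(self, "t1", t1)
        object.__setattr__(self, "t2", t2)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in origin))

    @property
    def shape(self) -> tuple:
        return self.rho.shape

    def coordinates_m(self) -> list[np.ndarray]:
        """Per-axis voxel-centre coordinates in metres (centred convention)."""
        out = []
        for n, d, o in zip(self.shape, self.spacing, self.origin):
            out.append(((np.arange(n) - n // 2) * d + o) * 1e-3)
        return out

    def coordinate_grids_m(self) -> list[np.ndarray]:
        axes = self.coordinates_m()
        return list(np.meshgrid(*axes, indexing="ij"))

    def to_nifti(self, path) -> None:
        import nibabel as nib

        arr = self.rho if self.rho.ndim == 3 else self.rho[..., None]
        affine = np.diag(list(self.spacing) + [1.0] * (4 - len(self.spacing)))
        nib.save(nib.Nifti1Image(arr.astype(np.float32), affine), str(path))


@dataclass(frozen=True)
class EncodingMaps:
    """Effective-coordinate maps of the three gradient coils plus dB0.

    gx, gy, gz are in metres on the image voxel grid and equal the physical
    coordinates in the perfectly linear limit; delta_b0 is in Hz.
    """

    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray | None = None
    delta_b0: np.ndarray | None = None

    def __post_init__(self):
        gx = np.asarray(self.gx, dtype=float)
        gy = np.asarray(self.gy, dtype=float)
        if gy.shape != gx.shape:
            raise ValueError("map grids must be congruent")
        gz = self.gz
        if gz is not None:
            gz = np.asarray(gz, dtype=float)
            if gz.shape != gx.shape:
                raise ValueError("map grids must be congruent")
        db0 = self.delta_b0
        if db0 is not None:
            db0 = np.asarray(db0, dtype=float)
            if db0.shape != gx.shape:
                raise ValueError("map grids must be congruent")
        object.__setattr__(self, "gx", gx)
        object.__setattr__(self, "gy", gy)
        object.__setattr__(self, "gz", gz)
        object.__setattr__(self, "delta_b0", db0)

    @classmethod
    def identity(cls, phantom: Phantom) -> "EncodingMaps":
        """Maps of perfectly linear coils on the phantom grid."""
        grids = phantom.coordinate_grids_m()
        gz = grids[2] if phantom.rho.ndim == 3 else None
        return cls(gx=grids[0], gy=grids[1], gz=gz)


@dataclass(frozen=True)
class AcqSimConfig:
    """Noise / drift / decay switches for the forward simulation."""

    noise_sd: float = 0.0
    seed: int = 0
    drift: DriftModel | None = None
    include_t2_in_train: bool = False
    #: evaluate the drift offset at each line's echo time (True) or once per
    #: shot at the excitation time (False)
    drift_per_echo: bool = True

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class KSpaceData:
    """Complex k-space samples on a full Cartesian array (zeros off-mask)."""

    samples: np.ndarray
    dwell: float
    schedule: EncodeSchedule | None
    mask: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=complex)
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != s.shape[1:]:
            raise ValueError("mask must match the phase-encode dims of samples")
        if np.any(s[:, ~mask] != 0):
            raise ValueError("unmasked entries must be exactly zero")
        object.__setattr__(self, "samples", s)
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple:
        return self.samples.shape

    def readout_times(self) -> np.ndarray:
        """Per-readout-sample time from the echo centre, s."""
        n = self.shape[0]
        return (np.arange(n) - n // 2) * self.dwell

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("samples", data=self.samples)
            f.create_dataset("mask", data=self.mask)
            f.attrs["dwell"] = self.dwell
            if self.schedule is not None:
                rows = np.array(
                    [
                        [e.ky, e.kz, e.shot, e.echo, e.time_s]
                        for e in self.schedule.entries
                    ]
                )
                f.create_dataset("schedule", data=rows)
                f.attrs["shots"] = self.schedule.shots
                f.attrs["etl"] = self.schedule.etl
                f.attrs["effective_te"] = self.schedule.effective_te


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------


def tube_grid_phantom(
    tube_diameter_mm: float = 8.0,
    tube_length_mm: float = 35.0,
    grid_pitch_mm: float = 17.0,
    voxel_mm: float = 1.0,
    grid_shape: tuple = (7, 7),
    fov_mm: tuple | None = None,
    plane: str = "yz",
    t1_ms: float = 3000.0,
    t2_ms: float = 2500.0,
) -> tuple[Phantom, np.ndarray]:
    """Water-tube resolution phantom: a rectangular grid of cylinders.

    The default builds 45 water tubes (8 mm diameter, 35 mm long) on a 7 x 7
    grid with 17 mm pitch and the four corner positions left empty. Tubes run
    along the axis perpendicular to ``plane`` ('yz' -> along x, the bore).

    Returns the phantom and the (n_tubes, 3) array of tube-centre positions
    in mm (centred coordinates), for use as distortion-metric references.
    """
    if grid_pitch_mm <= tube_diameter_mm:
        raise ValueError("tubes overlap: grid pitch must exceed the tube diameter")
    if voxel_mm > tube_diameter_mm / 4:
        raise ValueError("voxel size must be <= tube_diameter / 4")
    n1, n2 = grid_shape
    extent_u = (n1 - 1) * grid_pitch_mm + tube_diameter_mm
    extent_v = (n2 - 1) * grid_pitch_mm + tube_diameter_mm
    if fov_mm is None:
        fov_mm = (
            tube_length_mm + 2 * voxel_mm,
            extent_u + 4 * voxel_mm,
            extent_v + 4 * voxel_mm,
        )
    shape = tuple(max(int(np.ceil(f / voxel_mm)), 4) for f in fov_mm)

    ax = [(np.arange(n) - n // 2) * voxel_mm for n in shape]

    centers_u = (np.arange(n1) - (n1 - 1) / 2) * grid_pitch_mm
    centers_v = (np.arange(n2) - (n2 - 1) / 2) * grid_pitch_mm
    corners = {(0, 0), (0, n2 - 1), (n1 - 1, 0), (n1 - 1, n2 - 1)}
    rho = np.zeros(shape)
    centers = []
    # partial-volume rasterization: 5^3 staggered subsamples per voxel inside
    # a per-tube bounding box (staggering avoids lattice-commensurate bias)
    ss = ((np.arange(5) + 0.5) / 5.0 - 0.5) * voxel_mm
    dX, dU, dV = np.meshgrid(ss, ss, ss, indexing="ij")
    dX, dU, dV = dX.ravel(), dU.ravel(), dV.ravel()
    r_t = tube_diameter_mm / 2
    for i, cu in enumerate(centers_u):
        for j, cv in enumerate(centers_v):
            if (i, j) in corners:
                continue
            su = slice(
                np.searchsorted(ax[1], cu - r_t - voxel_mm),
                np.searchsorted(ax[1], cu + r_t + voxel_mm),
            )
            sv = slice(
                np.searchsorted(ax[2], cv - r_t - voxel_mm),
                np.searchsorted(ax[2], cv + r_t + voxel_mm),
            )
            Xb, Ub, Vb = np.meshgrid(ax[0], ax[1][su], ax[2][sv], indexing="ij")
            frac = np.zeros(Xb.shape)
            for dx, du, dv in zip(dX, dU, dV):
                frac += (
                    ((Ub + du - cu) ** 2 + (Vb + dv - cv) ** 2 <= r_t**2)
                    & (np.abs(Xb + dx) <= tube_length_mm / 2)
                )
            rho[:, su, sv] = np.maximum(rho[:, su, sv], frac / len(dX))
            centers.append((0.0, cu, cv))

    if plane == "xy":  # tubes along z instead of x
        rho = np.transpose(rho, (2, 1, 0))
        centers = [(c[2], c[1], c[0]) for c in centers]
    elif plane != "yz":
        raise ValueError("plane must be 'yz' or 'xy'")

    ph = Phantom(
        rho=rho,
        t1=np.full(rho.shape, t1_ms),
        t2=np.full(rho.shape, t2_ms),
        spacing=(voxel_mm,) * 3,
    )
    return ph, np.asarray(centers)


def tissue_phantom(
    kind: str,
    shape: tuple = (64, 64, 64),
    voxel_mm: float = 4.0,
) -> Phantom:
    """Simple geometric tissue phantoms with low-field relaxation times.

    'brain': an ellipsoid of brain tissue (T1/T2 = 500/250 ms) containing two
    CSF ventricle compartments (T1 = 1750 ms, T2 = 0.9 T1).
    'knee': concentric cylinders of muscle, fat and cartilage with
    (T1, T2) = (200, 47), (140, 84), (70, 20) ms.
    """
    ax = [(np.arange(n) - n // 2) * voxel_mm for n in shape]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    rho = np.zeros(shape)
    t1 = np.ones(shape)
    t2 = np.ones(shape)
    half = np.array([n // 2 * voxel_mm for n in shape])

    if kind == "brain":
        a, b, c = 0.72 * half
        body = (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0
        rho[body] = 0.8
        t1[body], t2[body] = BRAIN_TISSUE["brain"]
        vr = 0.22 * min(a, b, c)
        for side in (-1.0, 1.0):
            vent = (
                (X / 2.2) ** 2 + (Y - side * 0.3 * b) ** 2 + (Z / 1.5) ** 2
            ) <= vr**2
            rho[vent] = 1.0
            t1[vent], t2[vent] = BRAIN_TISSUE["csf"]
    elif kind == "knee":
        R = np.hypot(Y, Z)
        rmax = 0.8 * min(half[1], half[2])
        within_x = np.abs(X) <= 0.8 * half[0]
        muscle = (R <= rmax) & within_x
        fat = (R <= 0.55 * rmax) & within_x
        cart = (R <= 0.25 * rmax) & within_x
        for region, (t1v, t2v), dens in (
            (muscle, KNEE_TISSUE["muscle"], 0.9),
            (fat, KNEE_TISSUE["fat"], 1.0),
            (cart, KNEE_TISSUE["cartilage"], 0.7),
        ):
            rho[region] = dens
            t1[region], t2[region] = t1v, t2v
    else:
        raise ValueError("kind must be 'brain' or 'knee'")
    return Phantom(rho=rho, t1=t1, t2=t2, spacing=(voxel_mm,) * 3)


# ---------------------------------------------------------------------------
# Contrast and the forward model
# ---------------------------------------------------------------------------


def contrast_weighting(
    t1: float | np.ndarray,
    t2: float | np.ndarray,
    p: TSEParams,
    mode: str | None = None,
) -> np.ndarray:
    """Steady-state signal weighting of a TSE protocol, in [0, 1+].

    saturation_recovery:  (1 - exp(-TR/T1)) * exp(-TEeff/T2)
    inversion_recovery:   |1 - 2 exp(-TI/T1) + exp(-TR/T1)| * exp(-TEeff/T2)

    The mode defaults to inversion recovery when the protocol carries a TI.
    """
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if np.any(t1 <= 0) or np.any(t2 <= 0):
        raise ValueError("relaxation times must be positive")
    if mode is None:
        mode = "inversion_recovery" if p.ti is not None else "saturation_recovery"
    te_eff = echo_train_schedule_effective_te(p)
    decay = np.exp(-te_eff / t2)
    if mode == "saturation_recovery":
        return (1.0 - np.exp(-p.tr / t1)) * decay
    if mode == "inversion_recovery":
        if p.ti is None:
            raise ValueError("inversion recovery needs a TI")
        return np.abs(1.0 - 2.0 * np.exp(-p.ti / t1) + np.exp(-p.tr / t1)) * decay
    raise ValueError(f"unknown mode {mode!r}")


def echo_train_schedule_effective_te(p: TSEParams) -> float:
    """Effective TE (ms) implied by the protocol ordering."""
    if p.ordering == "center_out":
        return p.te
    return (p.etl + 1) / 2.0 * p.te


def _k_axes(p: TSEParams, shape: tuple) -> list[np.ndarray]:
    """Centred k-space coordinates (cycles/m) per dimension."""
    out = []
    for n, fov in zip(shape, p.fov):
        out.append((np.arange(n) - n // 2) / (fov * 1e-3))
    return out


def simulate_acquisition(
    ph: Phantom,
    maps: EncodingMaps,
    schedule: EncodeSchedule,
    p: TSEParams,
    cfg: AcqSimConfig = AcqSimConfig(),
    *,
    chunk_voxels: int = 4096,
) -> KSpaceData:
    """Forward-encode a phantom through (possibly nonlinear) gradient maps.

    With identity maps, no dB0, no drift and no noise this reduces to the
    discrete Fourier transform of the contrast-weighted phantom on the
    package's centred index convention.
    """
    is3d = ph.rho.ndim == 3
    if maps.gx.shape != ph.shape:
        raise ValueError("encoding maps must live on the phantom voxel grid")
    if is3d and maps.gz is None:
        raise ValueError("3-D phantom needs a gz map")
    shape = tuple(p.matrix) if is3d else (p.matrix[0], p.matrix[1])
    kx, *kphase = _k_axes(p, shape)
    nro = shape[0]
    t_ro = (np.arange(nro) - nro // 2) * p.dwell  # readout time from echo centre

    w = contrast_weighting(ph.t1, ph.t2, p)
    rho_w = (ph.rho * w).ravel()
    keep = rho_w != 0
    rho_w = rho_w[keep]
    gx = maps.gx.ravel()[keep]
    gy = maps.gy.ravel()[keep]
    gz = maps.gz.ravel()[keep] if is3d else None
    db0 = maps.delta_b0.ravel()[keep] if maps.delta_b0 is not None else None
    t2v = ph.t2.ravel()[keep]

    mask = np.zeros(shape[1:], dtype=bool)
    line_index: dict[tuple[int, int], object] = {}
    n1 = shape[1]
    n2 = shape[2] if is3d else 1
    for e in schedule.entries:
        mask[(e.ky + n1 // 2, e.kz + n2 // 2) if is3d else (e.ky + n1 // 2,)] = True
        line_index[(e.ky, e.kz)] = e

    s = np.zeros(shape, dtype=complex)
    ky = kphase[0]
    kz = kphase[1] if is3d else None

    if is3d:
        # cap the intermediate (n1, n2, chunk) array at ~64 MB
        chunk_voxels = min(chunk_voxels, max(4_000_000 // (n1 * n2), 64))

    if not cfg.include_t2_in_train:
        # separable fast path: s = sum_v rho_w * Ex (x) Ey (x) Ez
        for lo in range(0, len(rho_w), chunk_voxels):
            sl = slice(lo, lo + chunk_voxels)
            phase_x = np.outer(kx, gx[sl])
            if db0 is not None:
                phase_x = phase_x + np.outer(t_ro, db0[sl])
            Ex = np.exp(-2j * np.pi * phase_x)  # (nx, V)
            Ey = np.exp(-2j * np.pi * np.outer(ky, gy[sl]))  # (n1, V)
            A = Ex * rho_w[sl]
            if is3d:
                Ez = np.exp(-2j * np.pi * np.outer(kz, gz[sl]))
                T = np.einsum("yv,zv->yzv", Ey, Ez)
                s += np.einsum("xv,yzv->xyz", A, T)
            else:
                s += np.einsum("xv,yv->xy", A, Ey)
    else:
        # per-line loop with voxel-wise T2 decay across the train
        for e in line_index.values():
            decay = np.exp(-(e.echo * p.te) / t2v)
            for lo in range(0, len(rho_w), chunk_voxels):
                sl = slice(lo, lo + chunk_voxels)
                phase_x = np.outer(kx, gx[sl])
                if db0 is not None:
                    phase_x = phase_x + np.outer(t_ro, db0[sl])
                Ex = np.exp(-2j * np.pi * phase_x)
                ph_y = ky[e.ky + n1 // 2] * gy[sl]
                if is3d:
                    ph_y = ph_y + kz[e.kz + n2 // 2] * gz[sl]
                amp = rho_w[sl] * decay[sl] * np.exp(-2j * np.pi * ph_y)
                col = Ex @ amp
                if is3d:
                    s[:, e.ky + n1 // 2, e.kz + n2 // 2] += col
                else:
                    s[:, e.ky + n1 // 2] += col

    # drift: a frequency offset evaluated at the line's echo time (or once
    # per shot), applied as a phase ramp across the readout samples
    if cfg.drift is not None:
        for e in line_index.values():
            t_eval = e.time_s if cfg.drift_per_echo else e.shot * p.tr / 1000.0
            df = float(cfg.drift.offset_hz(t_eval))
            ramp = np.exp(-2j * np.pi * df * t_ro)
            if is3d:
                s[:, e.ky + n1 // 2, e.kz + n2 // 2] *= ramp
            else:
                s[:, e.ky + n1 // 2] *= ramp

    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        noise = rng.normal(0, cfg.noise_sd, s.shape) + 1j * rng.normal(
            0, cfg.noise_sd, s.shape
        )
        s = s + noise

    # enforce exact zeros off-mask
    s[:, ~mask] = 0.0
    return KSpaceData(samples=s, dwell=p.dwell, schedule=schedule, mask=mask)
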