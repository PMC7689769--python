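"""Discretized Halbach-array construction and genetic-algorithm optimization.

Two optimization problems are covered, matching how a ~50 mT permanent-magnet
scanner is actually designed and then corrected:

1. *Ring-diameter optimization*: the main magnet is a stack of 23 rings, each
   with two layers of 12-mm N48 cubes in the k = 1 (dipolar) Halbach
   orientation. The per-ring layer radii are free parameters (mirror-symmetric
   about the midplane) chosen by a genetic algorithm to minimize the
   peak-to-peak field inhomogeneity over a 20-cm spherical volume.

2. *Shim-grid optimization*: after the main magnet is built (and measured),
   a cylindrical grid of 15 rings x 60 positions for small 3-mm N45 cubes is
   filled by a ternary genetic algorithm - each position is empty, aligned
   with the local k = 1 orientation, or flipped 180 degrees - to cancel the
   residual inhomogeneity.

Both optimizers are deterministic given a seed and use elitism, so the
best-so-far fitness is monotone non-increasing across generations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as _field
from typing import Callable, Sequence

import numpy as np

from .fieldcore import (
    B0_AXIS,
    REMANENCE_T,
    DSVRegion,
    FieldMap,
    MagnetElement,
    PointGrid,
    dipole_field,
    homogeneity_ppm,
)

__all__ = [
    "AZIMUTHAL_CLEARANCE",
    "ABSENT",
    "ALIGNED",
    "FLIPPED",
    "RingSpec",
    "HalbachMagnetDesign",
    "ShimGrid",
    "GAConfig",
    "GeometryError",
    "OptimizationResult",
    "default_magnets_per_layer",
    "build_halbach_elements",
    "build_shim_elements",
    "optimize_ring_diameters",
    "optimize_shim",
]

#: Default azimuthal clearance between neighbouring cubes on a layer, m.
#: Chosen (together with the ring-radius window below) so that the nominal
#: 23-ring geometry operates near 50 mT with the magnets held in printed
#: trays; see docs/methods.md for the packaging rationale.
AZIMUTHAL_CLEARANCE = 0.007

#: Default search window for the first-layer ring radius, m.
RING_RADIUS_WINDOW = (0.185, 0.215)

#: Radial clearance between the two layers of a ring, m.
LAYER_CLEARANCE = 0.001

BORE_RADIUS = 0.135

ABSENT, ALIGNED, FLIPPED = 0, 1, 2


class GeometryError(ValueError):
    """Raised when a magnet geometry is physically infeasible."""


def default_magnets_per_layer(
    radius: float,
    magnet_size: float = 0.012,
    clearance: float = AZIMUTHAL_CLEARANCE,
) -> int:
    """Number of cubes that fit on a layer with the given clearance."""
    return int(2 * np.pi * radius // (magnet_size + clearance))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RingSpec:
    """One ring of the Halbach stack: two concentric layers of cubes."""

    axial_position: float
    layer_radii: tuple
    magnets_per_layer: tuple
    magnet_size: float = 0.012
    remanence: float = REMANENCE_T["N48"]
    #: azimuthal offset of the first magnet from the B0 axis, rad
    phi0: float = 0.0

    def __post_init__(self):
        radii = tuple(float(r) for r in self.layer_radii)
        counts = tuple(int(n) for n in self.magnets_per_layer)
        if len(radii) != 2 or len(counts) != 2:
            raise ValueError("exactly two layers per ring")
        for r in radii:
            if r <= BORE_RADIUS:
                raise GeometryError(
                    f"layer radius {r} must exceed the bore radius {BORE_RADIUS}"
                )
        for n in counts:
            if n < 8:
                raise GeometryError("need at least 8 magnets per layer")
        for r, n in zip(radii, counts):
            if 2 * np.pi * r / n <= self.magnet_size:
                raise GeometryError(
                    f"magnets overlap on layer r={r}: arc spacing "
                    f"{2 * np.pi * r / n:.4f} <= magnet size {self.magnet_size}"
                )
        object.__setattr__(self, "layer_radii", radii)
        object.__setattr__(self, "magnets_per_layer", counts)


@dataclass(frozen=True)
class HalbachMagnetDesign:
    """A full Halbach magnet: a stack of rings, sorted along the bore axis."""

    rings: tuple
    bore_diameter: float = 0.27
    length: float = 0.50
    b0_axis: np.ndarray = _field(default_factory=lambda: B0_AXIS.copy())

    def __post_init__(self):
        rings = tuple(self.rings)
        pos = [r.axial_position for r in rings]
        if any(b < a for a, b in zip(pos, pos[1:])):
            raise ValueError("rings must be sorted by axial position")
        if abs((pos[-1] - pos[0]) - self.length) > 1e-9:
            raise ValueError("outer ring separation must match the stated length")
        object.__setattr__(self, "rings", rings)
        object.__setattr__(
            self, "b0_axis", np.asarray(self.b0_axis, dtype=float)
        )

    @property
    def n_rings(self) -> int:
        return len(self.rings)

    @classmethod
    def reference(
        cls,
        n_rings: int = 23,
        length: float = 0.50,
        layer1_radius: float | Sequence[float] = 0.20,
        magnet_size: float = 0.012,
        remanence: float = REMANENCE_T["N48"],
        clearance: float = AZIMUTHAL_CLEARANCE,
    ) -> "HalbachMagnetDesign":
        """The 23-ring, two-layer template geometry (radii may vary per ring)."""
        radii = np.broadcast_to(np.asarray(layer1_radius, dtype=float), (n_rings,))
        rings = []
        for x, r1 in zip(np.linspace(-length / 2, length / 2, n_rings), radii):
            r2 = r1 + magnet_size + LAYER_CLEARANCE
            rings.append(
                RingSpec(
                    axial_position=float(x),
                    layer_radii=(float(r1), float(r2)),
                    magnets_per_layer=(
                        default_magnets_per_layer(r1, magnet_size, clearance),
                        default_magnets_per_layer(r2, magnet_size, clearance),
                    ),
                    magnet_size=magnet_size,
                    remanence=remanence,
                )
            )
        return cls(rings=tuple(rings), length=length)

    def to_json(self, path) -> None:
        table = [
            {
                "axial_position": r.axial_position,
                "layer_radii": list(r.layer_radii),
                "magnets_per_layer": list(r.magnets_per_layer),
                "magnet_size": r.magnet_size,
                "remanence": r.remanence,
            }
            for r in self.rings
        ]
        with open(path, "w") as f:
            json.dump(
                {
                    "bore_diameter": self.bore_diameter,
                    "length": self.length,
                    "rings": table,
                },
                f,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "HalbachMagnetDesign":
        with open(path) as f:
            d = json.load(f)
        rings = tuple(
            RingSpec(
                axial_position=r["axial_position"],
                layer_radii=tuple(r["layer_radii"]),
                magnets_per_layer=tuple(r["magnets_per_layer"]),
                magnet_size=r["magnet_size"],
                remanence=r["remanence"],
            )
            for r in d["rings"]
        )
        return cls(rings=rings, bore_diameter=d["bore_diameter"], length=d["length"])


@dataclass(frozen=True)
class ShimGrid:
    """Ternary shim-magnet grid on a cylindrical former.

    ``state`` is a flat (n_rings * positions_per_ring,) integer vector with
    values ABSENT (0), ALIGNED (1) or FLIPPED (2), stored ring-major: entry
    ``i * positions_per_ring + j`` is ring i (ring 0 at -length/2), azimuthal
    position j (position 0 on the B0 axis).
    """

    radius: float = 0.1625
    length: float = 0.28
    n_rings: int = 15
    positions_per_ring: int = 60
    state: np.ndarray | None = None
    magnet_size: float = 0.003
    remanence: float = REMANENCE_T["N45"]

    def __post_init__(self):
        n = self.n_rings * self.positions_per_ring
        state = self.state
        if state is None:
            state = np.zeros(n, dtype=np.int8)
        state = np.asarray(state, dtype=np.int8).ravel()
        if len(state) != n:
            raise ValueError(f"state must have {n} entries")
        if not np.all(np.isin(state, (ABSENT, ALIGNED, FLIPPED))):
            raise ValueError("state entries must be ABSENT/ALIGNED/FLIPPED")
        object.__setattr__(self, "state", state)

    @property
    def n_positions(self) -> int:
        return self.n_rings * self.positions_per_ring

    def positions_and_orientations(self) -> tuple[np.ndarray, np.ndarray]:
        """Centres (N,3) and ALIGNED moment directions (N,3) of every slot."""
        xs = np.linspace(-self.length / 2, self.length / 2, self.n_rings)
        phi = np.arange(self.positions_per_ring) * 2 * np.pi / self.positions_per_ring
        X, PHI = np.meshgrid(xs, phi, indexing="ij")
        centers = np.stack(
            [X, self.radius * np.sin(PHI), self.radius * np.cos(PHI)], axis=-1
        ).reshape(-1, 3)
        orient = np.stack(
            [np.zeros_like(PHI), np.sin(2 * PHI), np.cos(2 * PHI)], axis=-1
        ).reshape(-1, 3)
        return centers, orient

    def state_matrix(self) -> np.ndarray:
        return self.state.reshape(self.n_rings, self.positions_per_ring)

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(
                {
                    "radius": self.radius,
                    "length": self.length,
                    "magnet_size": self.magnet_size,
                    "remanence": self.remanence,
                    "state": self.state_matrix().tolist(),
                },
                f,
            )

    @classmethod
    def from_json(cls, path) -> "ShimGrid":
        with open(path) as f:
            d = json.load(f)
        state = np.asarray(d["state"], dtype=np.int8)
        return cls(
            radius=d["radius"],
            length=d["length"],
            n_rings=state.shape[0],
            positions_per_ring=state.shape[1],
            state=state.ravel(),
            magnet_size=d["magnet_size"],
            remanence=d["remanence"],
        )


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings. Identical config + seed => identical run."""

    population_size: int = 100
    generations: int = 200
    crossover_rate: float = 0.8
    mutation_rate: float = 0.02
    tournament_size: int = 3
    elitism: int = 1
    seed: int = 0

    def __post_init__(self):
        if min(self.population_size, self.generations, self.tournament_size) <= 0:
            raise ValueError("population, generations and tournament must be positive")
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class OptimizationResult:
    """Outcome of a GA run: best individual plus its trajectory."""

    best: object
    fitness: float
    history: np.ndarray  # best-so-far fitness per generation (monotone)
    evaluations: int


# ---------------------------------------------------------------------------
# Element construction
# ---------------------------------------------------------------------------


def _ring_elements(ring: RingSpec) -> list[MagnetElement]:
    out = []
    vol = ring.magnet_size**3
    for r, n in zip(ring.layer_radii, ring.magnets_per_layer):
        phi = ring.phi0 + np.arange(n) * 2 * np.pi / n
        for p in phi:
            out.append(
                MagnetElement(
                    center=np.array(
                        [ring.axial_position, r * np.sin(p), r * np.cos(p)]
                    ),
                    moment_dir=np.array([0.0, np.sin(2 * p), np.cos(2 * p)]),
                    remanence=ring.remanence,
                    volume=vol,
                )
            )
    return out


def build_halbach_elements(design: HalbachMagnetDesign) -> list[MagnetElement]:
    """Expand a ring-stack design into individual point-dipole elements.

    A cube at azimuth phi (measured from the B0 axis in the transverse plane)
    carries a moment rotated by 2*phi - the k = 1 Halbach rule - so the net
    interior field points along the B0 axis.
    """
    elements: list[MagnetElement] = []
    for i, ring in enumerate(design.rings):
        try:
            elements.extend(_ring_elements(ring))
        except GeometryError as e:  # pragma: no cover - RingSpec validates first
            raise GeometryError(f"ring {i}: {e}") from e
    return elements


def build_shim_elements(grid: ShimGrid) -> list[MagnetElement]:
    """Expand the occupied slots of a shim grid into dipole elements."""
    centers, orient = grid.positions_and_orientations()
    vol = grid.magnet_size**3
    out = []
    for c, o, s in zip(centers, orient, grid.state):
        if s == ABSENT:
            continue
        if s == FLIPPED:
            o = -o
        out.append(
            MagnetElement(center=c, moment_dir=o, remanence=grid.remanence, volume=vol)
        )
    return out


# ---------------------------------------------------------------------------
# Generic GA engine
# ---------------------------------------------------------------------------


def _ga_minimize(
    evaluate: Callable[[np.ndarray], np.ndarray],
    init_population: np.ndarray,
    crossover: Callable,
    mutate: Callable,
    cfg: GAConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, np.ndarray, int]:
    """Tournament-selection GA with elitism; minimizes ``evaluate``.

    ``evaluate`` maps a (P, G) population to (P,) fitness values.
    Returns (best genome, best fitness, best-so-far history, n evaluations).
    """
    pop = init_population.copy()
    P = len(pop)
    fit = evaluate(pop)
    n_eval = P
    order = np.argsort(fit)
    best_x, best_f = pop[order[0]].copy(), float(fit[order[0]])
    history = [best_f]
    for _ in range(cfg.generations):
        # tournament selection of parents
        idx = rng.integers(0, P, size=(2 * P, cfg.tournament_size))
        winners = idx[np.arange(2 * P), np.argmin(fit[idx], axis=1)]
        parents = pop[winners]
        children = np.empty_like(pop)
        for i in range(0, P - cfg.elitism, 1):
            a, b = parents[2 * i], parents[2 * i + 1]
            if rng.random() < cfg.crossover_rate:
                c = crossover(a, b, rng)
            else:
                c = a.copy()
            children[i] = mutate(c, rng)
        # elitism: carry over the best individuals unchanged
        elite = pop[np.argsort(fit)[: cfg.elitism]]
        children[P - cfg.elitism :] = elite
        pop = children
        fit = evaluate(pop)
        n_eval += P
        i = int(np.argmin(fit))
        if fit[i] < best_f:
            best_f = float(fit[i])
            best_x = pop[i].copy()
        history.append(best_f)
    return best_x, best_f, np.asarray(history), n_eval


# ---------------------------------------------------------------------------
# Ring-diameter optimization
# ---------------------------------------------------------------------------


def _mirror_genes(genes: np.ndarray, n_rings: int) -> np.ndarray:
    """Expand the unique half of a mirror-symmetric radius vector."""
    n_half = (n_rings + 1) // 2
    assert len(genes) == n_half
    return np.concatenate([genes, genes[: n_rings - n_half][::-1]])


def _design_with_radii(
    template: HalbachMagnetDesign, radii: np.ndarray
) -> HalbachMagnetDesign:
    rings = []
    for ring, r1 in zip(template.rings, radii):
        r2 = r1 + ring.magnet_size + LAYER_CLEARANCE
        rings.append(
            dataclasses.replace(
                ring,
                layer_radii=(float(r1), float(r2)),
                magnets_per_layer=(
                    default_magnets_per_layer(r1, ring.magnet_size),
                    default_magnets_per_layer(r2, ring.magnet_size),
                ),
            )
        )
    return dataclasses.replace(template, rings=tuple(rings))


class _RingFieldCache:
    """b0/B contributions of one mirror-symmetric ring pair, memoized.

    Uniform crossover re-uses parent gene values, so most (ring, radius)
    pairs encountered during a GA run repeat; caching makes the fitness
    evaluation cost proportional to the number of *new* gene values.
    """

    def __init__(self, template: HalbachMagnetDesign, points: np.ndarray):
        self.template = template
        self.points = points
        self._cache: dict[tuple[int, int], np.ndarray] = {}
        grid = PointGrid(points=points)
        self._grid = grid

    def contribution(self, ring_index: int, radius: float) -> np.ndarray:
        """(npts, 3) field of ring ``ring_index`` and its mirror twin."""
        key = (ring_index, int(round(radius * 1e7)))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        n = self.template.n_rings
        indices = {ring_index, n - 1 - ring_index}
        B = np.zeros((len(self.points), 3))
        for i in indices:
            ring = self.template.rings[i]
            design_ring = dataclasses.replace(
                ring,
                layer_radii=(radius, radius + ring.magnet_size + LAYER_CLEARANCE),
                magnets_per_layer=(
                    default_magnets_per_layer(radius, ring.magnet_size),
                    default_magnets_per_layer(
                        radius + ring.magnet_size + LAYER_CLEARANCE, ring.magnet_size
                    ),
                ),
            )
            B += dipole_field(_ring_elements(design_ring), self._grid).B
        self._cache[key] = B
        return B


def optimize_ring_diameters(
    template: HalbachMagnetDesign,
    ga: GAConfig,
    dsv: DSVRegion,
    *,
    bounds: tuple[float, float] = RING_RADIUS_WINDOW,
    candidates: Sequence[Sequence[float]] | None = None,
) -> tuple[HalbachMagnetDesign, OptimizationResult]:
    """Optimize per-ring layer radii for B0 homogeneity over the DSV.

    The genome is the first-layer radius of each ring in the front half of
    the magnet (mirror symmetry about the midplane is enforced). Fitness is
    the peak-to-peak homogeneity in ppm over ``dsv``.

    Parameters
    ----------
    bounds : (lo, hi)
        Radius window for real-coded genes (uniform crossover + Gaussian
        mutation). Checked for bore clearance before the GA starts.
    candidates : list of per-ring candidate radii, optional
        If given, the search is over these discrete values only (one list per
        half-ring gene); useful for small exhaustively checkable problems.
    """
    n_rings = template.n_rings
    n_half = (n_rings + 1) // 2
    lo, hi = bounds
    if lo <= BORE_RADIUS:
        raise GeometryError(
            f"radius lower bound {lo} must clear the bore radius {BORE_RADIUS}"
        )
    rng = np.random.default_rng(ga.seed)
    cache = _RingFieldCache(template, dsv.sample_points.points)
    axis = template.b0_axis / np.linalg.norm(template.b0_axis)

    def genes_to_radii(genes: np.ndarray) -> np.ndarray:
        if candidates is not None:
            vals = np.array(
                [candidates[i][int(g)] for i, g in enumerate(genes)], dtype=float
            )
        else:
            vals = np.asarray(genes, dtype=float)
        return _mirror_genes(vals, n_rings)

    def evaluate(pop: np.ndarray) -> np.ndarray:
        out = np.empty(len(pop))
        for k, genes in enumerate(pop):
            radii = genes_to_radii(genes)
            b0 = np.zeros(len(dsv.sample_points))
            for i in range(n_half):
                b0 += cache.contribution(i, float(radii[i])) @ axis
            mean = b0.mean()
            out[k] = (b0.max() - b0.min()) / mean * 1e6 if mean > 0 else np.inf
        return out

    if candidates is not None:
        if len(candidates) != n_half:
            raise ValueError(f"need {n_half} candidate lists")
        sizes = np.array([len(c) for c in candidates])
        init = rng.integers(0, sizes, size=(ga.population_size, n_half))

        def mutate(c, rng):
            m = rng.random(n_half) < ga.mutation_rate
            c = c.copy()
            c[m] = rng.integers(0, sizes[m])
            return c

    else:
        init = rng.uniform(lo, hi, size=(ga.population_size, n_half))
        sigma = 0.1 * (hi - lo)

        def mutate(c, rng):
            m = rng.random(n_half) < ga.mutation_rate
            c = c.copy()
            c[m] = np.clip(c[m] + rng.normal(0, sigma, m.sum()), lo, hi)
            return c

    def crossover(a, b, rng):
        take = rng.random(n_half) < 0.5
        return np.where(take, a, b)

    best, fbest, history, n_eval = _ga_minimize(
        evaluate, init, crossover, mutate, ga, rng
    )
    design = _design_with_radii(template, genes_to_radii(best))
    return design, OptimizationResult(
        best=design, fitness=fbest, history=history, evaluations=n_eval
    )


# ---------------------------------------------------------------------------
# Shim-grid optimization
# ---------------------------------------------------------------------------


def _shim_basis(grid: ShimGrid, points: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """(n_positions, npts) b0 contribution of an ALIGNED magnet in each slot."""
    centers, orient = grid.positions_and_orientations()
    vol = grid.magnet_size**3
    pg = PointGrid(points=points)
    basis = np.empty((grid.n_positions, len(points)))
    for i in range(grid.n_positions):
        el = MagnetElement(
            center=centers[i],
            moment_dir=orient[i],
            remanence=grid.remanence,
            volume=vol,
        )
        basis[i] = dipole_field([el], pg).B @ axis
    return basis


def _interp_to_points(field: FieldMap, points: np.ndarray) -> np.ndarray:
    """b0 component of ``field`` at ``points`` (exact match or interpolation)."""
    fpts = field.grid.points
    if len(fpts) == len(points) and np.allclose(fpts, points, atol=1e-12):
        return field.b0_component
    from scipy.interpolate import LinearNDInterpolator

    interp = LinearNDInterpolator(fpts, field.b0_component)
    vals = interp(points)
    if np.any(np.isnan(vals)):
        raise ValueError("DSV extends outside the base field map coverage")
    return vals


def optimize_shim(
    base_field: FieldMap,
    grid: ShimGrid,
    ga: GAConfig,
    dsv: DSVRegion,
) -> tuple[ShimGrid, OptimizationResult]:
    """Fill the ternary shim grid to minimize inhomogeneity of base + shims.

    The base field is interpolated onto the DSV sample points if needed. The
    all-ABSENT configuration is seeded into the initial population and elitism
    preserves it unless improved upon, so the returned grid is never worse
    than leaving every slot empty.
    """
    points = dsv.sample_points.points
    axis = base_field.b0_axis
    base = _interp_to_points(base_field, points)
    basis = _shim_basis(grid, points, axis)  # (900, npts)
    n = grid.n_positions
    rng = np.random.default_rng(ga.seed)

    signs = np.array([0.0, 1.0, -1.0])  # ABSENT, ALIGNED, FLIPPED

    def evaluate(pop: np.ndarray) -> np.ndarray:
        S = signs[pop]  # (P, n)
        fields = base[None, :] + S @ basis  # (P, npts)
        mean = fields.mean(axis=1)
        ptp = fields.max(axis=1) - fields.min(axis=1)
        out = np.where(mean > 0, ptp / np.where(mean > 0, mean, 1.0) * 1e6, np.inf)
        return out

    init = rng.integers(0, 3, size=(ga.population_size, n)).astype(np.int8)
    init[0] = ABSENT  # guarantee the do-nothing baseline is present

    def crossover(a, b, rng):
        take = rng.random(n) < 0.5
        return np.where(take, a, b).astype(np.int8)

    def mutate(c, rng):
        m = rng.random(n) < ga.mutation_rate
        c = c.copy()
        c[m] = rng.integers(0, 3, size=m.sum())
        return c

    best, fbest, history, n_eval = _ga_minimize(
        evaluate, init, crossover, mutate, ga, rng
    )
    out = dataclasses.replace(grid, state=best.astype(np.int8))
    return out, OptimizationResult(
        best=out, fitness=fbest, history=history, evaluations=n_eval
    )
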