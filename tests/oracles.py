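"""Independent closed-form / brute-force oracles used by the test suite.

These deliberately do not share code paths with the package: the cuboid field
uses the charged-face closed form, the loop field the elliptic-integral
closed form, and the enumeration helpers plain Python loops.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ellipe, ellipk

MU0 = 4e-7 * np.pi


def _charged_rectangle_H(x, y, z, x1, x2, y1, y2, sigma):
    """H field of a uniformly (magnetically) charged rectangle at z' = 0.

    Rectangle spans [x1, x2] x [y1, y2] in its own plane; evaluation point in
    the same frame at height z.
    """
    H = np.zeros(3)
    for i, xi in enumerate((x1, x2)):
        for j, yj in enumerate((y1, y2)):
            s = (-1) ** (i + j)
            X, Y = x - xi, y - yj
            r = np.sqrt(X * X + Y * Y + z * z)
            H[0] -= s * np.log(Y + r)
            H[1] -= s * np.log(X + r)
            H[2] += s * np.arctan2(X * Y, z * r)
    return sigma / (4 * np.pi) * H


def cuboid_field_exact(point, center, dims, magnetization):
    """B field (T) of a uniformly magnetized cuboid via face charges.

    ``magnetization`` is the vector M in A/m (for NdFeB, Br / mu0). Exact for
    any outside point. The field of an arbitrary M is the superposition of
    the three axis-aligned magnetization components.
    """
    p = np.asarray(point, float) - np.asarray(center, float)
    d = np.asarray(dims, float) / 2.0
    M = np.asarray(magnetization, float)
    B = np.zeros(3)
    # component of M along each axis -> two charged faces normal to that axis
    for axis in range(3):
        if M[axis] == 0:
            continue
        others = [a for a in range(3) if a != axis]
        # work in a frame where the charged faces are normal to 'z'
        x, y, z = p[others[0]], p[others[1]], p[axis]
        Hl = np.zeros(3)
        for zface, sigma in ((d[axis], M[axis]), (-d[axis], -M[axis])):
            Hl += _charged_rectangle_H(
                x, y, z - zface, -d[others[0]], d[others[0]],
                -d[others[1]], d[others[1]], sigma,
            )
        B[others[0]] += MU0 * Hl[0]
        B[others[1]] += MU0 * Hl[1]
        B[axis] += MU0 * Hl[2]
    return B


def cuboid_field_subdivided(point, center, dims, magnetization, n=12):
    """Same field by dividing the cuboid into n^3 point dipoles (brute force)."""
    p = np.asarray(point, float)
    c = np.asarray(center, float)
    d = np.asarray(dims, float)
    M = np.asarray(magnetization, float)
    ax = [c[k] - d[k] / 2 + (np.arange(n) + 0.5) * d[k] / n for k in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    centers = np.stack([X.ravel(), Y.ravel(), Z.ravel()], 1)
    m = M * np.prod(d) / n**3  # dipole moment per cell
    r = p[None, :] - centers
    rn = np.linalg.norm(r, axis=1, keepdims=True)
    rhat = r / rn
    B = 1e-7 * (3 * (rhat @ m)[:, None] * rhat - m) / rn**3
    return B.sum(0)


def loop_field_offaxis(R, I, rho, z):
    """(B_rho, B_z) of a circular loop (radius R, current I) at (rho, z).

    Elliptic-integral closed form (loop in the z = 0 plane, centred on the
    z axis).
    """
    if rho == 0:
        return 0.0, MU0 * I * R**2 / (2 * (R**2 + z**2) ** 1.5)
    k2 = 4 * R * rho / ((R + rho) ** 2 + z**2)
    K, E = ellipk(k2), ellipe(k2)
    pref = MU0 * I / (2 * np.pi * np.sqrt((R + rho) ** 2 + z**2))
    Bz = pref * (K + (R**2 - rho**2 - z**2) / ((R - rho) ** 2 + z**2) * E)
    Brho = (
        MU0
        * I
        * z
        / (2 * np.pi * rho * np.sqrt((R + rho) ** 2 + z**2))
        * (-K + (R**2 + rho**2 + z**2) / ((R - rho) ** 2 + z**2) * E)
    )
    return Brho, Bz


def circular_loop(R, n_segments, z=0.0):
    """Polyline approximation of a circular loop in the z-plane (around z)."""
    t = np.linspace(0, 2 * np.pi, n_segments + 1)
    return np.stack([R * np.cos(t), R * np.sin(t), np.full_like(t, z)], axis=1)


def brute_force_assignment_rms(detected, reference):
    """Exhaustive minimum-RMS matching of detected blobs to references."""
    from itertools import permutations

    detected = np.asarray(detected, float)
    reference = np.asarray(reference, float)
    n = min(len(detected), len(reference))
    best = np.inf
    for perm in permutations(range(len(reference)), n):
        errs = np.linalg.norm(detected[:n] - reference[list(perm)], axis=1)
        rms = np.sqrt(np.mean(errs**2))
        best = min(best, rms)
    return best


def elliptical_count_bruteforce(n1, n2):
    """Direct enumeration of the centred-index ellipse inclusion rule."""
    count = 0
    for i in range(-(n1 // 2), n1 - n1 // 2):
        for j in range(-(n2 // 2), n2 - n2 // 2):
            if (i / (n1 / 2)) ** 2 + (j / (n2 / 2)) ** 2 <= 1 + 1e-12:
                count += 1
    return count


def dft_bruteforce(rho_w, coords_m, fovs_mm):
    """Plain triple-sum DFT of a weighted phantom (centred conventions)."""
    shape = rho_w.shape
    kax = [
        (np.arange(n) - n // 2) / (f * 1e-3) for n, f in zip(shape, fovs_mm)
    ]
    kgrids = np.meshgrid(*kax, indexing="ij")
    kflat = np.stack([k.ravel() for k in kgrids], 1)
    rflat = np.stack([c.ravel() for c in coords_m], 1)
    phase = kflat @ rflat.T
    return (np.exp(-2j * np.pi * phase) @ rho_w.ravel()).reshape(shape)
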