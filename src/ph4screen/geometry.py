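"""Small rigid-geometry helpers used throughout the package.

Coordinates are right-handed Cartesian angstroms everywhere; a rigid motion is
a proper rotation ``R`` (3x3, det +1) followed by a translation ``t``.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

Point = tuple[float, float, float]


def as_points(coords) -> np.ndarray:
    """Coerce an (n, 3) array-like of coordinates to a float ndarray."""
    arr = np.asarray(coords, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(1, 3)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"expected (n, 3) coordinates, got shape {arr.shape}")
    return arr


def apply_rigid(coords, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    """Apply ``x -> R x + t`` to each row of ``coords``."""
    pts = as_points(coords)
    return pts @ np.asarray(rotation, dtype=float).T + np.asarray(translation, dtype=float)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A rotation matrix drawn uniformly (Haar) from SO(3)."""
    return Rotation.random(random_state=rng).as_matrix()


def angle_deg(a, b, c) -> float:
    """Angle A-B-C at vertex ``b`` in degrees, in [0, 180]."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    u, v = a - b, c - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("degenerate angle: coincident points")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("cannot normalise the zero vector")
    return v / n


def fibonacci_sphere(n: int, radius: float, center) -> np.ndarray:
    """``n`` near-uniform points on a sphere (deterministic golden-angle lattice)."""
    center = np.asarray(center, dtype=float)
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return center + radius * pts
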