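"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: superposition goes
through scipy's ``Rotation.align_vectors`` (not the package's Kabsch), and
mapping enumeration is brute force over all kind-compatible permutations
with no distance prefilter.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.spatial.transform import Rotation

from ph4screen.featperc import FeatureSet
from ph4screen.ph4core import Pharmacophore


def superpose_rmsd(P, Q) -> float:
    """Optimal proper-rotation RMSD of P onto Q via scipy align_vectors."""
    P, Q = np.asarray(P, float), np.asarray(Q, float)
    Pc, Qc = P - P.mean(axis=0), Q - Q.mean(axis=0)
    _rot, rssd = Rotation.align_vectors(Qc, Pc)
    return float(rssd / math.sqrt(len(P)))


def grid_min_rmsd(P, Q, n_samples: int = 20000, seed: int = 0) -> float:
    """Minimum RMSD over a dense random sample of proper rotations."""
    P, Q = np.asarray(P, float), np.asarray(Q, float)
    Pc, Qc = P - P.mean(axis=0), Q - Q.mean(axis=0)
    rots = Rotation.random(n_samples, random_state=np.random.default_rng(seed)).as_matrix()
    best = math.inf
    for R in rots:
        rmsd = math.sqrt(np.mean(np.sum((Pc @ R.T - Qc) ** 2, axis=1)))
        best = min(best, rmsd)
    return best


def enumerate_mappings(query: Pharmacophore, fs: FeatureSet):
    """All kind-compatible injective full mappings, no distance filtering.

    Yields tuples of molecule feature indices ordered like query.required.
    """
    req = query.required
    by_kind: dict = {}
    for i, f in enumerate(fs.features):
        by_kind.setdefault(f.kind, []).append(i)
    slots = [by_kind.get(f.kind, []) for f in req]
    for combo in itertools.product(*slots):
        if len(set(combo)) == len(combo):
            yield combo


def exhaustive_best_rmsd(query: Pharmacophore, fs: FeatureSet) -> tuple[float, tuple | None]:
    """Best RMSD over every kind-compatible permutation (no prefilter)."""
    req = query.required
    Q = np.array([f.center for f in req], float)
    mol = fs.centers()
    best, best_map = math.inf, None
    for combo in enumerate_mappings(query, fs):
        rmsd = superpose_rmsd(mol[list(combo)], Q)
        if rmsd < best:
            best, best_map = rmsd, combo
    return best, best_map


def accepted_mappings(query: Pharmacophore, fs: FeatureSet, threshold: float):
    """Oracle hit mappings: permutations whose optimal RMSD <= threshold."""
    req = query.required
    Q = np.array([f.center for f in req], float)
    mol = fs.centers()
    out = []
    for combo in enumerate_mappings(query, fs):
        if superpose_rmsd(mol[list(combo)], Q) <= threshold:
            out.append(combo)
    return out


def _aligned_deviations(P, Q) -> np.ndarray:
    """Per-point residual norms at the optimal proper-rotation superposition."""
    P, Q = np.asarray(P, float), np.asarray(Q, float)
    Pc, Qc = P - P.mean(axis=0), Q - Q.mean(axis=0)
    rot, _rssd = Rotation.align_vectors(Qc, Pc)
    return np.linalg.norm(Pc @ rot.as_matrix().T - Qc, axis=1)


def mappings_within_radii(query: Pharmacophore, fs: FeatureSet):
    """Permutations whose optimally aligned per-feature deviations each fit
    inside the corresponding query tolerance sphere."""
    req = query.required
    Q = np.array([f.center for f in req], float)
    radii = np.array([f.radius for f in req], float)
    mol = fs.centers()
    out = []
    for combo in enumerate_mappings(query, fs):
        if (_aligned_deviations(mol[list(combo)], Q) <= radii).all():
            out.append(combo)
    return out
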