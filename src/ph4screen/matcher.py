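"""Pharmacophore screening engine.

Screening proceeds in two stages, mirroring the usual search strategy of
pharmacophore engines:

1. a cheap *distance prefilter* enumerates kind-compatible injective
   assignments of molecule features to query features whose pairwise
   inter-feature distances agree within the summed tolerance radii, and
2. for each surviving assignment, a closed-form least-squares rigid
   superposition (Kabsch, proper rotations only) of the mapped molecule
   feature centers onto the query feature centers; the assignment with the
   smallest RMSD wins.

A conformer is a hit when its best RMSD is at or below the threshold and no
atom of the aligned conformer penetrates an excluded volume. The prefilter is
admissible: its distance slack (sum of the two query radii per pair) can never
reject an assignment whose aligned per-feature deviations all fit inside the
feature tolerance spheres.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import AlignmentError, PerceptionError
from .featperc import (
    ConformerRecord,
    FeatureSet,
    PerceptionRules,
    default_rules,
    perceive_and_project,
)
from .ph4core import ExcludedVolume, Feature, Pharmacophore

logger = logging.getLogger(__name__)

__all__ = [
    "Mapping",
    "MatchResult",
    "ScreenReport",
    "kabsch_superpose",
    "distance_prefilter",
    "check_excluded_volumes",
    "match_conformer",
    "screen_library",
    "screen_feature_sets",
    "DEFAULT_RMSD_THRESHOLD",
    "DEFAULT_ATOM_RADIUS",
]

#: Default acceptance threshold on the feature-center RMSD (angstrom).
DEFAULT_RMSD_THRESHOLD = 1.0
#: Generic heavy-atom radius used in excluded-volume clash tests (angstrom).
DEFAULT_ATOM_RADIUS = 1.0


@dataclass(frozen=True)
class Mapping:
    """Injective assignment query-feature-id -> molecule feature index."""

    pairs: tuple[tuple[str, int], ...]

    def __post_init__(self):
        idxs = [i for _fid, i in self.pairs]
        if len(set(idxs)) != len(idxs):
            raise ValueError("mapping must be injective")

    def molecule_indices(self) -> tuple[int, ...]:
        return tuple(i for _fid, i in self.pairs)

    def query_ids(self) -> tuple[str, ...]:
        return tuple(fid for fid, _i in self.pairs)


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one conformer against one query model.

    ``rmsd`` is +inf when no mapping survived the prefilter. ``hit`` holds
    exactly when a mapping exists, rmsd <= threshold, and no clash.
    """

    molecule_id: str
    conformer_index: int
    mapping: Mapping | None
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    clash: bool
    hit: bool


@dataclass
class ScreenReport:
    """Per-molecule best results of screening one library with one query."""

    query_name: str
    results: dict[str, MatchResult]  # molecule_id -> best MatchResult
    n_skipped: int = 0

    @property
    def n_screened(self) -> int:
        return len(self.results)

    @property
    def hits(self) -> list[MatchResult]:
        """Hit list sorted ascending by rmsd (ties by molecule id)."""
        hs = [r for r in self.results.values() if r.hit]
        return sorted(hs, key=lambda r: (r.rmsd, r.molecule_id))

    @property
    def n_hits(self) -> int:
        return sum(1 for r in self.results.values() if r.hit)

    def hit_ids(self) -> set[str]:
        return {r.molecule_id for r in self.results.values() if r.hit}


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------


def kabsch_superpose(P, Q) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of points ``P`` onto points ``Q``.

    Returns ``(R, t, rmsd)`` with ``R`` a proper rotation (det +1, reflections
    disallowed) and ``t`` a translation such that ``R @ p + t`` best matches
    ``q`` in the least-squares sense; ``rmsd`` is the root-mean-square residual
    at the optimum.

    Degenerate input where all points of either set coincide yields the
    identity rotation and the centroid-to-centroid translation.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise AlignmentError(f"point sets must share shape (n, 3); got {P.shape} vs {Q.shape}")
    if len(P) < 3:
        raise AlignmentError("kabsch_superpose needs at least 3 point pairs")
    if not (np.isfinite(P).all() and np.isfinite(Q).all()):
        raise AlignmentError("non-finite coordinates")

    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq
    H = Pc.T @ Qc
    if np.allclose(H, 0.0):
        # all points coincident in at least one set: rotation is arbitrary
        R = np.eye(3)
        t = cq - cp
        rmsd = float(np.sqrt(np.mean(np.sum((Pc - Qc) ** 2, axis=1))))
        return R, t, rmsd
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    resid = Pc @ R.T - Qc
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return R, t, rmsd


# ---------------------------------------------------------------------------
# Distance prefilter
# ---------------------------------------------------------------------------


def distance_prefilter(query: Pharmacophore, fs: FeatureSet) -> list[Mapping]:
    """Enumerate kind-compatible injective mappings passing the distance check.

    For every pair of already-assigned query features (i, j) the molecule's
    inter-feature distance must satisfy
    ``|d_mol(i, j) - d_query(i, j)| <= radius_i + radius_j``.
    Mappings cover exactly the query's required features, in query feature
    order, so the returned list is in lexicographic mapping order.
    """
    req = query.required
    if not req:
        return []
    mol_centers = fs.centers() if fs.features else np.zeros((0, 3))
    mol_kinds = [f.kind for f in fs.features]
    q_centers = np.array([f.center for f in req], dtype=float)
    q_radii = [f.radius for f in req]
    n_req = len(req)

    candidates: list[list[int]] = [
        [i for i, k in enumerate(mol_kinds) if k == f.kind] for f in req
    ]
    if any(not c for c in candidates):
        return []

    out: list[Mapping] = []
    assign: list[int] = []

    def backtrack(pos: int) -> None:
        if pos == n_req:
            out.append(Mapping(tuple((req[k].id, assign[k]) for k in range(n_req))))
            return
        for idx in candidates[pos]:
            if idx in assign:
                continue
            ok = True
            for prev in range(pos):
                d_mol = float(np.linalg.norm(mol_centers[assign[prev]] - mol_centers[idx]))
                d_q = float(np.linalg.norm(q_centers[prev] - q_centers[pos]))
                if abs(d_mol - d_q) > q_radii[prev] + q_radii[pos]:
                    ok = False
                    break
            if ok:
                assign.append(idx)
                backtrack(pos + 1)
                assign.pop()

    backtrack(0)
    return out


# ---------------------------------------------------------------------------
# Clash test and conformer matching
# ---------------------------------------------------------------------------


def check_excluded_volumes(
    conf_atoms,
    volumes: Sequence[ExcludedVolume],
    atom_radius: float = DEFAULT_ATOM_RADIUS,
) -> bool:
    """True iff any atom center is *strictly* closer than volume.radius +
    atom_radius to an excluded-volume center (touching exactly is no clash)."""
    if not volumes:
        return False
    atoms = np.asarray(conf_atoms, dtype=float)
    if atoms.size == 0:
        return False
    centers = np.array([v.center for v in volumes], dtype=float)
    radii = np.array([v.radius for v in volumes], dtype=float)
    dists = cdist(atoms, centers)
    return bool((dists < radii[None, :] + atom_radius).any())


def _no_match(fs: FeatureSet) -> MatchResult:
    return MatchResult(
        molecule_id=fs.molecule_id,
        conformer_index=fs.conformer_index,
        mapping=None,
        rotation=np.eye(3),
        translation=np.zeros(3),
        rmsd=math.inf,
        clash=False,
        hit=False,
    )


def match_conformer(
    fs: FeatureSet,
    conf: ConformerRecord | None,
    query: Pharmacophore,
    rmsd_threshold: float = DEFAULT_RMSD_THRESHOLD,
    atom_radius: float = DEFAULT_ATOM_RADIUS,
) -> MatchResult:
    """Best rigid match of one conformer's features onto the query.

    All prefiltered mappings are superposed; the minimum-RMSD mapping wins
    (ties resolved by lexicographic mapping order, i.e. first enumerated).
    The winning transform is applied to all conformer atoms for the
    excluded-volume clash test. ``conf`` may be None when the caller has no
    atoms to clash-test (feature-only screening).
    """
    mappings = distance_prefilter(query, fs)
    if not mappings:
        return _no_match(fs)

    req = query.required
    q_centers = np.array([f.center for f in req], dtype=float)
    mol_centers = fs.centers()

    best: tuple[float, int] | None = None
    best_Rt: tuple[np.ndarray, np.ndarray] | None = None
    for m_idx, mapping in enumerate(mappings):
        P = mol_centers[list(mapping.molecule_indices())]
        R, t, rmsd = kabsch_superpose(P, q_centers)
        if best is None or rmsd < best[0] - 1e-15:
            best = (rmsd, m_idx)
            best_Rt = (R, t)
    rmsd, m_idx = best
    R, t = best_Rt
    mapping = mappings[m_idx]

    clash = False
    if conf is not None and query.excluded_volumes:
        moved = conf.coords @ R.T + t
        clash = check_excluded_volumes(moved, query.excluded_volumes, atom_radius)
    hit = (rmsd <= rmsd_threshold) and not clash
    return MatchResult(
        molecule_id=fs.molecule_id,
        conformer_index=fs.conformer_index,
        mapping=mapping,
        rotation=R,
        translation=t,
        rmsd=rmsd,
        clash=clash,
        hit=hit,
    )


# ---------------------------------------------------------------------------
# Library screening
# ---------------------------------------------------------------------------


def _better(a: MatchResult, b: MatchResult) -> MatchResult:
    """Prefer lower rmsd; ties go to the lower conformer index."""
    ka = (a.rmsd, a.conformer_index)
    kb = (b.rmsd, b.conformer_index)
    return a if ka <= kb else b


def _merge_best(results: dict[str, MatchResult], res: MatchResult) -> None:
    prev = results.get(res.molecule_id)
    if prev is None:
        results[res.molecule_id] = res
        return
    best = _better(prev, res)
    # a molecule is a hit if any conformer hits, even if the best-RMSD
    # conformer clashes; keep the hit flag sticky on the stored best
    if (prev.hit or res.hit) and not best.hit:
        alt = res if best is prev else prev
        if alt.hit:
            best = alt
    results[res.molecule_id] = best


def screen_library(
    library: Iterable[ConformerRecord],
    query: Pharmacophore,
    rules: PerceptionRules | None = None,
    rmsd_threshold: float = DEFAULT_RMSD_THRESHOLD,
    atom_radius: float = DEFAULT_ATOM_RADIUS,
) -> ScreenReport:
    """Screen a conformer library; one best MatchResult per molecule.

    A molecule is a hit iff at least one of its conformers is a hit; its
    reported result is the minimum-RMSD hit when one exists, otherwise the
    minimum-RMSD conformer overall (ties broken by lowest conformer index).
    Records failing perception are skipped with a warning and counted.
    """
    rules = rules or default_rules()
    results: dict[str, MatchResult] = {}
    n_skipped = 0
    for conf in library:
        try:
            fs = perceive_and_project(conf, rules)
        except PerceptionError as exc:
            logger.warning("skipping %s[%d]: %s", conf.molecule_id, conf.conformer_index, exc)
            n_skipped += 1
            continue
        res = match_conformer(fs, conf, query, rmsd_threshold, atom_radius)
        _merge_best(results, res)
    return ScreenReport(query_name=query.name, results=results, n_skipped=n_skipped)


def screen_feature_sets(
    pairs: Iterable[tuple[FeatureSet, ConformerRecord | None]],
    query: Pharmacophore,
    rmsd_threshold: float = DEFAULT_RMSD_THRESHOLD,
    atom_radius: float = DEFAULT_ATOM_RADIUS,
) -> ScreenReport:
    """Screen pre-perceived feature sets (fast path bypassing perception)."""
    results: dict[str, MatchResult] = {}
    for fs, conf in pairs:
        res = match_conformer(fs, conf, query, rmsd_threshold, atom_radius)
        _merge_best(results, res)
    return ScreenReport(query_name=query.name, results=results, n_skipped=0)
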