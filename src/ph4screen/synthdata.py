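"""Synthetic inputs with analytically guaranteed structure.

Real pharmacophore validation sets (DUD-E / DEKOIS-style actives and decoys)
cannot be bundled, so this module *plants* them: molecules are assembled from
minimal chemically valid fragments — a carbonyl for an acceptor, a hydroxyl
for a donor, a short alkyl cluster for a hydrophobe — whose perceived features
land exactly at prescribed positions. Planted matchers place every required
feature at the query position plus bounded jitter under a random rigid motion
(guaranteed hits); planted non-matchers either lack one required feature kind
entirely or have all inter-feature distances scaled x2 (guaranteed to fail the
distance prefilter, verified against the prefilter at build time). Screening
such a library therefore reproduces a prescribed confusion matrix exactly.

The default test-set composition mirrors a per-kinase active/decoy benchmark
with a decoys/actives ratio of about 30. All generators are pure functions of
their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd

from .errors import GenerationError, InvariantError
from .featperc import ConformerRecord, FeatureSet
from .geometry import apply_rigid, fibonacci_sphere, random_rotation, unit
from .matcher import DEFAULT_RMSD_THRESHOLD, distance_prefilter
from .ph4core import (
    DEFAULT_MAIN_RADIUS,
    DEFAULT_PROJ_RADIUS,
    ExcludedVolume,
    Feature,
    FeatureKind,
    Pharmacophore,
)
from .rbuilder import ComplexRecord, ProteinAtom, transform_complex

__all__ = [
    "TargetPlant",
    "PlantSpec",
    "ToyComplexSpec",
    "default_query",
    "default_plant_spec",
    "plant_matched_library",
    "plant_matched_feature_sets",
    "make_toy_complex",
    "random_rigid_transform",
]

# fragment bond lengths (angstrom)
_CO_DOUBLE = 1.23
_CO_SINGLE = 1.43
_OH = 0.96


def default_query(name: str = "Ph4-4-like", n_volumes: int = 30) -> Pharmacophore:
    """A seven-feature multi-kinase-style query with excluded volumes.

    Geometry emulates a type II kinase inhibitor pharmacophore: a hinge-region
    acceptor, an alphaC-helix-glutamate donor, a DFG-aspartate acceptor (each
    with a projected site point 3 A out) and a broad allosteric-back-pocket
    hydrophobe. Excluded volumes sit on a 12 A shell around the features,
    marking receptor-occupied space without touching planted matchers.
    """
    f1 = (0.0, 0.0, 0.0)
    f5 = (-2.598076, 1.5, 0.0)  # 3 A from f1
    f2 = (5.0, 1.0, 0.0)
    f6 = (6.5, 3.598076, 0.0)  # 3 A from f2
    f3 = (8.0, -1.5, 1.0)
    f7 = (8.0, -4.5, 1.0)  # 3 A from f3
    f4 = (11.5, 0.5, -0.5)
    features = (
        Feature("F1", FeatureKind.ACC, f1, DEFAULT_MAIN_RADIUS),
        Feature("F2", FeatureKind.DON, f2, DEFAULT_MAIN_RADIUS),
        Feature("F3", FeatureKind.ACC, f3, DEFAULT_MAIN_RADIUS),
        Feature("F4", FeatureKind.HYD, f4, 1.5),
        Feature("F5", FeatureKind.ACC_PROJ, f5, DEFAULT_PROJ_RADIUS, parent_id="F1"),
        Feature("F6", FeatureKind.DON_PROJ, f6, DEFAULT_PROJ_RADIUS, parent_id="F2"),
        Feature("F7", FeatureKind.ACC_PROJ, f7, DEFAULT_PROJ_RADIUS, parent_id="F3"),
    )
    centroid = np.array([f.center for f in features]).mean(axis=0)
    volumes = tuple(
        ExcludedVolume(tuple(float(x) for x in p), 1.0)
        for p in fibonacci_sphere(n_volumes, 12.0, centroid)
    )
    return Pharmacophore(name=name, features=features, excluded_volumes=volumes)


@dataclass(frozen=True)
class TargetPlant:
    """Planted composition for one target: set sizes and true/false positives."""

    actives: int
    decoys: int
    tp: int
    fp: int

    def __post_init__(self):
        if min(self.actives, self.decoys, self.tp, self.fp) < 0:
            raise InvariantError("counts must be non-negative")
        if self.tp > self.actives or self.fp > self.decoys:
            raise InvariantError("tp <= actives and fp <= decoys required")


@dataclass(frozen=True)
class PlantSpec:
    query: Pharmacophore
    per_target: dict[str, TargetPlant]
    jitter_sigma: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.jitter_sigma < 0:
            raise InvariantError("jitter_sigma must be >= 0")
        if not self.per_target:
            raise InvariantError("per_target must be non-empty")


def default_plant_spec(seed: int = 0, query: Pharmacophore | None = None) -> PlantSpec:
    """The benchmark-mimicking scenario: 73 actives / 2314 decoys over three
    kinases (ratio ~30), planted so screening yields 55 true and 91 false
    positives — i.e. 146 hits out of 2387 compounds."""
    rng = np.random.default_rng(seed)
    composition = {"VEGFR2": (26, 801), "FGFR1": (20, 600), "BRAF": (27, 913)}
    tp_split = _random_partition(rng, 55, [26, 20, 27])
    fp_split = _random_partition(rng, 91, [801, 600, 913])
    per_target = {
        t: TargetPlant(a, d, tp_split[i], fp_split[i])
        for i, (t, (a, d)) in enumerate(composition.items())
    }
    return PlantSpec(
        query=query or default_query(),
        per_target=per_target,
        jitter_sigma=0.15,
        seed=seed,
    )


def _random_partition(rng: np.random.Generator, total: int, caps: list[int]) -> list[int]:
    """Split ``total`` uniformly at random over bins with capacities ``caps``."""
    if total > sum(caps):
        raise InvariantError("partition total exceeds capacity")
    counts = [0] * len(caps)
    open_bins = [i for i in range(len(caps)) if caps[i] > 0]
    for _ in range(total):
        i = int(rng.choice(open_bins))
        counts[i] += 1
        if counts[i] == caps[i]:
            open_bins.remove(i)
    return counts


# ---------------------------------------------------------------------------
# Fragment geometry
# ---------------------------------------------------------------------------


def _main_features(query: Pharmacophore) -> list[tuple[Feature, Feature | None]]:
    """Required main features paired with their projection (if any)."""
    proj_of = {f.parent_id: f for f in query.required if f.kind.is_projected}
    return [(f, proj_of.get(f.id)) for f in query.required if not f.kind.is_projected]


def _direction(main: Feature, proj: Feature | None) -> np.ndarray:
    if proj is None:
        return np.array([1.0, 0.0, 0.0])
    return unit(np.asarray(proj.center) - np.asarray(main.center))


@dataclass(frozen=True)
class _Fragment:
    kind: FeatureKind
    anchor: np.ndarray  # feature position
    direction: np.ndarray  # hydrogen-bond direction (toward projection)
    proj_distance: float


def _fragment_atoms(frag: _Fragment) -> tuple[list[tuple[str, tuple, int]], list[tuple[int, int, int]]]:
    """Atoms/bonds of the minimal fragment realizing one main feature."""
    p, u = frag.anchor, frag.direction
    if frag.kind == FeatureKind.ACC:
        # carbonyl: O at the anchor, C opposite the projection direction
        atoms = [("O", tuple(p), 0), ("C", tuple(p - _CO_DOUBLE * u), 0)]
        bonds = [(0, 1, 2)]
    elif frag.kind == FeatureKind.DON:
        # hydroxyl: O at the anchor, H toward the projection, C opposite
        atoms = [
            ("O", tuple(p), 0),
            ("H", tuple(p + _OH * u), 0),
            ("C", tuple(p - _CO_SINGLE * u), 0),
        ]
        bonds = [(0, 1, 1), (0, 2, 1)]
    elif frag.kind == FeatureKind.HYD:
        # propane whose carbon centroid is exactly the anchor
        offsets = np.array([[-1.26, 0.25, 0.0], [0.0, -0.5, 0.0], [1.26, 0.25, 0.0]])
        atoms = [("C", tuple(p + o), 0) for o in offsets]
        bonds = [(0, 1, 1), (1, 2, 1)]
    else:  # pragma: no cover - projections never get fragments
        raise GenerationError(f"no fragment for kind {frag.kind}")
    return atoms, bonds


def _fragment_features(frag: _Fragment) -> list[Feature]:
    """Exactly the features perception finds on this fragment (ids arbitrary)."""
    p, u, d = frag.anchor, frag.direction, frag.proj_distance
    proj = tuple(p + d * u)
    if frag.kind == FeatureKind.ACC:
        return [
            Feature("a", FeatureKind.ACC, tuple(p), DEFAULT_MAIN_RADIUS),
            Feature("ap", FeatureKind.ACC_PROJ, proj, DEFAULT_PROJ_RADIUS, parent_id="a"),
        ]
    if frag.kind == FeatureKind.DON:
        # the hydroxyl oxygen is both donor and acceptor; both project along u
        return [
            Feature("d", FeatureKind.DON, tuple(p), DEFAULT_MAIN_RADIUS),
            Feature("dp", FeatureKind.DON_PROJ, proj, DEFAULT_PROJ_RADIUS, parent_id="d"),
            Feature("da", FeatureKind.ACC, tuple(p), DEFAULT_MAIN_RADIUS),
            Feature("dap", FeatureKind.ACC_PROJ, proj, DEFAULT_PROJ_RADIUS, parent_id="da"),
        ]
    return [Feature("h", FeatureKind.HYD, tuple(p), DEFAULT_MAIN_RADIUS)]


def _renumber(features: list[Feature]) -> tuple[Feature, ...]:
    """Give concatenated fragment features unique ids (M1, M2, ...), rewiring
    each projection to the nearest preceding feature with its old parent id
    (the parent always precedes its projection within a fragment)."""
    new_ids = [f"M{i}" for i in range(1, len(features) + 1)]
    renamed = []
    for i, f in enumerate(features):
        pid = None
        if f.parent_id is not None:
            j = next(k for k in range(i - 1, -1, -1) if features[k].id == f.parent_id)
            pid = new_ids[j]
        renamed.append(replace(f, id=new_ids[i], parent_id=pid))
    return tuple(renamed)


def _plan_molecule(
    query: Pharmacophore,
    rng: np.random.Generator,
    role: Literal["hit", "drop", "scaled"],
    jitter_sigma: float,
    max_jitter: float,
) -> list[_Fragment]:
    mains = _main_features(query)
    centroid = np.array([m.center for m, _p in mains]).mean(axis=0)
    proj_d = 3.0
    for m, pr in mains:
        if pr is not None:
            proj_d = float(np.linalg.norm(np.asarray(pr.center) - np.asarray(m.center)))
            break

    drop_kind = None
    if role == "drop":
        kinds = [m.kind for m, _p in mains]
        drop_kind = FeatureKind.HYD if FeatureKind.HYD in kinds else kinds[0]

    frags = []
    for main, proj in mains:
        if drop_kind is not None and main.kind == drop_kind:
            continue
        anchor = np.asarray(main.center, dtype=float)
        if role == "scaled":
            anchor = centroid + 2.0 * (anchor - centroid)
        jit = rng.normal(0.0, jitter_sigma, size=3)
        norm = float(np.linalg.norm(jit))
        if norm > max_jitter:
            jit *= (max_jitter * 0.999) / norm
        frags.append(
            _Fragment(
                kind=main.kind,
                anchor=anchor + jit,
                direction=_direction(main, proj),
                proj_distance=proj_d,
            )
        )
    return frags


def _fragments_to_conformer(
    frags: list[_Fragment], molecule_id: str, rng: np.random.Generator
) -> ConformerRecord:
    atoms: list[tuple[str, tuple, int]] = []
    bonds: list[tuple[int, int, int]] = []
    for frag in frags:
        base = len(atoms)
        fa, fb = _fragment_atoms(frag)
        atoms.extend(fa)
        bonds.extend((i + base, j + base, o) for i, j, o in fb)
    R = random_rotation(rng)
    t = rng.uniform(-10.0, 10.0, size=3)
    xyz = apply_rigid([a[1] for a in atoms], R, t)
    atoms = [(el, tuple(float(x) for x in xyz[i]), q) for i, (el, _p, q) in enumerate(atoms)]
    return ConformerRecord(molecule_id, 0, tuple(atoms), tuple(bonds))


def _fragments_to_feature_set(
    frags: list[_Fragment], molecule_id: str, rng: np.random.Generator
) -> FeatureSet:
    feats: list[Feature] = []
    for frag in frags:
        feats.extend(_fragment_features(frag))
    feats = list(_renumber(feats))
    R = random_rotation(rng)
    t = rng.uniform(-10.0, 10.0, size=3)
    moved = [f.moved_to(apply_rigid(f.center, R, t)[0]) for f in feats]
    owners = tuple((0,) for _ in moved)
    return FeatureSet(molecule_id, 0, tuple(moved), owners)


def _static_feature_set(frags: list[_Fragment], molecule_id: str) -> FeatureSet:
    feats = list(_renumber([f for frag in frags for f in _fragment_features(frag)]))
    return FeatureSet(molecule_id, 0, tuple(feats), tuple((0,) for _ in feats))


def _nonhit_fragments(
    query: Pharmacophore,
    rng: np.random.Generator,
    jitter_sigma: float,
    max_jitter: float,
    mol_id: str,
) -> list[_Fragment]:
    """A non-matcher: scaled x2 when that provably fails the prefilter,
    otherwise with one required feature kind dropped."""
    role = "scaled" if rng.random() < 0.5 else "drop"
    frags = _plan_molecule(query, rng, role, jitter_sigma, max_jitter)
    if role == "scaled":
        fs = _static_feature_set(frags, mol_id)
        if distance_prefilter(query, fs):
            # geometry too forgiving for the x2 trick; drop a kind instead
            frags = _plan_molecule(query, rng, "drop", jitter_sigma, max_jitter)
    return frags


def plant_matched_library(
    spec: PlantSpec,
    rmsd_threshold: float = DEFAULT_RMSD_THRESHOLD,
) -> tuple[list[ConformerRecord], pd.DataFrame]:
    """Build the planted conformer library plus its labels table.

    Returns one conformer per compound and a frame with columns
    ``compound_id, target, label``. Exactly ``tp`` actives and ``fp`` decoys
    per target are hits by construction; every other compound fails the
    distance prefilter. Deterministic given ``spec.seed``.
    """
    max_jitter = rmsd_threshold / 2.0
    if spec.jitter_sigma > max_jitter:
        raise GenerationError(
            f"jitter_sigma={spec.jitter_sigma} cannot guarantee hits: per-feature "
            f"displacement must stay below rmsd_threshold/2 = {max_jitter}"
        )
    _check_query_scalable(spec.query)
    rng = np.random.default_rng(spec.seed)
    records: list[ConformerRecord] = []
    rows = []
    for target in spec.per_target:  # insertion order: deterministic
        plant = spec.per_target[target]
        for i in range(plant.actives):
            mol_id = f"{target}-A{i + 1:04d}"
            role_hit = i < plant.tp
            frags = (
                _plan_molecule(spec.query, rng, "hit", spec.jitter_sigma, max_jitter)
                if role_hit
                else _nonhit_fragments(spec.query, rng, spec.jitter_sigma, max_jitter, mol_id)
            )
            records.append(_fragments_to_conformer(frags, mol_id, rng))
            rows.append((mol_id, target, "ACTIVE"))
        for i in range(plant.decoys):
            mol_id = f"{target}-D{i + 1:04d}"
            role_hit = i < plant.fp
            frags = (
                _plan_molecule(spec.query, rng, "hit", spec.jitter_sigma, max_jitter)
                if role_hit
                else _nonhit_fragments(spec.query, rng, spec.jitter_sigma, max_jitter, mol_id)
            )
            records.append(_fragments_to_conformer(frags, mol_id, rng))
            rows.append((mol_id, target, "DECOY"))
    labels = pd.DataFrame(rows, columns=["compound_id", "target", "label"])
    return records, labels


def plant_matched_feature_sets(
    spec: PlantSpec,
    rmsd_threshold: float = DEFAULT_RMSD_THRESHOLD,
) -> tuple[list[tuple[FeatureSet, None]], pd.DataFrame]:
    """Fast path: the same planted library as bare feature sets (no molecules)."""
    max_jitter = rmsd_threshold / 2.0
    if spec.jitter_sigma > max_jitter:
        raise GenerationError(
            f"jitter_sigma={spec.jitter_sigma} cannot guarantee hits: per-feature "
            f"displacement must stay below rmsd_threshold/2 = {max_jitter}"
        )
    _check_query_scalable(spec.query)
    rng = np.random.default_rng(spec.seed)
    out: list[tuple[FeatureSet, None]] = []
    rows = []
    for target in spec.per_target:
        plant = spec.per_target[target]
        for label, count, n_hits, tag in (
            ("ACTIVE", plant.actives, plant.tp, "A"),
            ("DECOY", plant.decoys, plant.fp, "D"),
        ):
            for i in range(count):
                mol_id = f"{target}-{tag}{i + 1:04d}"
                frags = (
                    _plan_molecule(spec.query, rng, "hit", spec.jitter_sigma, max_jitter)
                    if i < n_hits
                    else _nonhit_fragments(
                        spec.query, rng, spec.jitter_sigma, max_jitter, mol_id
                    )
                )
                out.append((_fragments_to_feature_set(frags, mol_id, rng), None))
                rows.append((mol_id, target, label))
    labels = pd.DataFrame(rows, columns=["compound_id", "target", "label"])
    return out, labels


def _check_query_scalable(query: Pharmacophore) -> None:
    """Planting needs every required feature pair farther apart than its slack."""
    req = query.required
    for i in range(len(req)):
        for j in range(i + 1, len(req)):
            d = float(np.linalg.norm(np.asarray(req[i].center) - np.asarray(req[j].center)))
            if d <= req[i].radius + req[j].radius:
                raise GenerationError(
                    f"query features {req[i].id}/{req[j].id} closer ({d:.2f} A) than "
                    "their summed radii; planted non-hits cannot be guaranteed"
                )


# ---------------------------------------------------------------------------
# Toy complexes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyComplexSpec:
    """A minimal complex with a prescribed number of clean interactions."""

    n_hbonds: int = 1
    n_hydrophobes: int = 1
    hbond_distance: float = 2.9  # donor heavy atom ... acceptor, A
    hbond_angle: float = 160.0  # D-H...A, degrees
    seed: int = 0

    def __post_init__(self):
        if self.n_hbonds < 0 or self.n_hydrophobes < 0:
            raise InvariantError("counts must be >= 0")
        if not (0.0 < self.hbond_angle <= 180.0):
            raise InvariantError("hbond_angle must lie in (0, 180]")
        if self.hbond_distance <= _OH:
            raise GenerationError("hbond_distance too short to place the hydrogen")


def _acceptor_position(D: np.ndarray, H: np.ndarray, distance: float, angle: float) -> np.ndarray:
    """Place A so |D-A| = distance and the D-H...A angle equals ``angle``."""
    phi = np.radians(180.0 - angle)
    u = np.array([np.cos(phi), np.sin(phi), 0.0])
    dh = float(np.linalg.norm(H - D))
    # |H + r u - D|^2 = distance^2 with H - D along +x
    b = 2.0 * dh * u[0]
    c = dh * dh - distance * distance
    r = (-b + np.sqrt(b * b - 4 * c)) / 2.0
    if r <= 0:
        raise GenerationError("infeasible hydrogen-bond geometry")
    return H + r * u


def make_toy_complex(spec: ToyComplexSpec, complex_id: str = "toy") -> ComplexRecord:
    """A complex whose default-criteria interactions are exactly as requested.

    Each hydrogen bond is a ligand hydroxyl donating to a lone protein
    carbonyl oxygen at the requested distance/angle; each hydrophobic contact
    is a ligand propane ringed by three apolar protein carbons. Interaction
    sites are spaced 14 A apart so they cannot cross-talk. The whole complex
    is posed by a seed-dependent rigid motion.
    """
    lig_atoms: list[tuple[str, tuple, int]] = []
    lig_bonds: list[tuple[int, int, int]] = []
    prot: list[ProteinAtom] = []

    res_no = 100
    for i in range(spec.n_hbonds):
        base = np.array([14.0 * i, 0.0, 0.0])
        D = base
        H = base + np.array([_OH, 0.0, 0.0])
        C = base - np.array([_CO_SINGLE, 0.0, 0.0])
        k = len(lig_atoms)
        lig_atoms += [("O", tuple(D), 0), ("H", tuple(H), 0), ("C", tuple(C), 0)]
        lig_bonds += [(k, k + 1, 1), (k, k + 2, 1)]
        A = _acceptor_position(D - base, H - base, spec.hbond_distance, spec.hbond_angle) + base
        prot.append(ProteinAtom("A", res_no, "SER", "O", "O", tuple(float(x) for x in A)))
        res_no += 1

    for j in range(spec.n_hydrophobes):
        base = np.array([14.0 * j, 20.0, 0.0])
        offsets = np.array([[-1.26, 0.25, 0.0], [0.0, -0.5, 0.0], [1.26, 0.25, 0.0]])
        k = len(lig_atoms)
        lig_atoms += [("C", tuple(base + o), 0) for o in offsets]
        lig_bonds += [(k, k + 1, 1), (k + 1, k + 2, 1)]
        for m in range(3):
            theta = 2.0 * np.pi * m / 3.0
            pos = base + 4.0 * np.array([np.cos(theta), np.sin(theta), 0.2])
            prot.append(
                ProteinAtom("A", res_no, "LEU", f"CD{m + 1}", "C", tuple(float(x) for x in pos))
            )
        res_no += 1

    if not lig_atoms:  # featureless ligand so the record stays valid
        lig_atoms = [("C", (0.0, -20.0, 0.0), 0)]

    # three non-collinear alpha carbons anchor the alignment
    for n, ca in enumerate([(-20.0, -10.0, 0.0), (-12.0, -10.0, 6.0), (-20.0, -2.0, 8.0)]):
        prot.append(ProteinAtom("A", n + 1, "GLY", "CA", "C", ca))

    cx = ComplexRecord(
        complex_id,
        tuple(prot),
        ConformerRecord(f"{complex_id}:lig", 0, tuple(lig_atoms), tuple(lig_bonds)),
        tuple(i for i, a in enumerate(prot) if a.atom_name == "CA"),
    )
    rng = np.random.default_rng(spec.seed)
    return transform_complex(cx, random_rotation(rng), rng.uniform(-5.0, 5.0, size=3))


def random_rigid_transform(conf: ConformerRecord, seed: int) -> ConformerRecord:
    """Re-pose a conformer by a uniform random rotation plus a translation
    drawn from a +-10 A box; all interatomic distances are preserved."""
    rng = np.random.default_rng(seed)
    return conf.transformed(random_rotation(rng), rng.uniform(-10.0, 10.0, size=3))
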