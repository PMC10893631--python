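"""Receptor-based pharmacophore construction from protein-ligand complexes.

The route mirrors how structure-based pharmacophores are built for a family
of kinase complexes sharing a binding mode:

1. rigidly align every complex onto a reference using paired alpha-carbon
   coordinates (closed-form Kabsch superposition),
2. detect ligand-protein interactions per complex — hydrogen bonds by a
   donor...acceptor distance plus D-H...A angle rule, hydrophobic contacts by
   proximity of a ligand hydrophobe centroid to a group of apolar protein
   atoms,
3. single-linkage cluster like-kind interaction points across complexes;
   clusters supported by enough distinct complexes become common features,
4. place excluded volumes on binding-site protein atoms (greedy maximin
   selection, away from feature centers), and
5. enumerate named feature-combination hypotheses into query pharmacophores.

Complexes are read from standard PDB files; the ligand is selected by residue
name and its bonds are inferred from interatomic distances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import AlignmentError, InvariantError, MalformedFileError, SchemaViolationError
from .featperc import ConformerRecord, FeatureSet
from .geometry import Point, angle_deg, apply_rigid
from .matcher import kabsch_superpose
from .ph4core import DEFAULT_MAIN_RADIUS, ExcludedVolume, Feature, FeatureKind, Pharmacophore

__all__ = [
    "ProteinAtom",
    "ComplexRecord",
    "InteractionKind",
    "InteractionRecord",
    "InteractionCriteria",
    "Hypothesis",
    "HypothesisSpec",
    "align_complexes",
    "detect_interactions",
    "cluster_common_features",
    "place_excluded_volumes",
    "enumerate_hypotheses",
    "load_complex_pdb",
    "write_complex_pdb",
    "transform_complex",
]

_APOLAR_ELEMENTS = {"C", "S"}
_POLAR_ELEMENTS = {"N", "O"}
#: Maximum covalent N/O-H distance when attaching protein hydrogens to donors.
_DONOR_H_MAX = 1.25


@dataclass(frozen=True)
class ProteinAtom:
    chain_id: str
    res_number: int
    res_name: str
    atom_name: str
    element: str
    center: Point

    @property
    def residue_id(self) -> str:
        return f"{self.chain_id}:{self.res_name}{self.res_number}"


@dataclass(frozen=True)
class ComplexRecord:
    """One aligned or alignable protein-ligand complex."""

    complex_id: str
    protein_atoms: tuple[ProteinAtom, ...]
    ligand: ConformerRecord
    alpha_carbons: tuple[int, ...]

    def __post_init__(self):
        if not self.alpha_carbons:
            raise InvariantError(f"{self.complex_id}: alpha_carbons must be non-empty")
        n = len(self.protein_atoms)
        if any(not (0 <= i < n) for i in self.alpha_carbons):
            raise InvariantError(f"{self.complex_id}: alpha-carbon index out of range")

    def protein_coords(self) -> np.ndarray:
        return np.array([a.center for a in self.protein_atoms], dtype=float)

    def alpha_carbon_by_residue(self) -> dict[str, int]:
        return {self.protein_atoms[i].residue_id: i for i in self.alpha_carbons}


class InteractionKind(str, Enum):
    HBOND_LIG_DON = "HBOND_LIG_DON"  # ligand donates the hydrogen
    HBOND_LIG_ACC = "HBOND_LIG_ACC"  # ligand accepts the hydrogen
    HYDROPHOBIC = "HYDROPHOBIC"


_KIND_TO_FEATURE = {
    InteractionKind.HBOND_LIG_ACC: FeatureKind.ACC,
    InteractionKind.HBOND_LIG_DON: FeatureKind.DON,
    InteractionKind.HYDROPHOBIC: FeatureKind.HYD,
}


@dataclass(frozen=True)
class InteractionRecord:
    complex_id: str
    kind: InteractionKind
    ligand_point: Point
    partner_residue: str
    partner_atom: str
    distance: float
    angle: float | None  # degrees; absent for hydrophobic contacts

    def __post_init__(self):
        if self.distance <= 0:
            raise InvariantError("interaction distance must be > 0")
        if self.angle is not None and not (0.0 <= self.angle <= 180.0):
            raise InvariantError("interaction angle must lie in [0, 180]")


@dataclass(frozen=True)
class InteractionCriteria:
    """Geometric cutoffs for interaction detection (field-conventional)."""

    hbond_max_da: float = 3.5  # donor-heavy to acceptor distance, A
    hbond_min_angle: float = 120.0  # D-H...A angle, degrees
    hydrophobic_max_dist: float = 4.5  # centroid to apolar protein atom, A
    hydrophobic_min_group: int = 3  # apolar atoms needed for a contact

    def __post_init__(self):
        if min(self.hbond_max_da, self.hbond_min_angle, self.hydrophobic_max_dist) <= 0:
            raise InvariantError("criteria must be positive")
        if self.hydrophobic_min_group <= 0:
            raise InvariantError("hydrophobic_min_group must be positive")
        if self.hbond_min_angle > 180.0:
            raise InvariantError("hbond_min_angle must be <= 180")


@dataclass(frozen=True)
class Hypothesis:
    name: str
    feature_ids: tuple[str, ...]
    radius_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))


@dataclass(frozen=True)
class HypothesisSpec:
    """Named feature subsets (plus radius overrides) defining candidate models."""

    combinations: tuple[Hypothesis, ...]

    @classmethod
    def from_json(cls, path) -> "HypothesisSpec":
        try:
            doc = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise MalformedFileError(f"{path}: not valid JSON: {exc}") from exc
        combos = doc.get("combinations")
        if not isinstance(combos, list):
            raise SchemaViolationError(f"{path}: 'combinations' must be a list")
        out = []
        for i, c in enumerate(combos):
            if not isinstance(c, dict) or "name" not in c or "features" not in c:
                raise SchemaViolationError(
                    f"{path}: combinations[{i}] needs 'name' and 'features'"
                )
            out.append(
                Hypothesis(
                    name=str(c["name"]),
                    feature_ids=tuple(c["features"]),
                    radius_overrides={k: float(v) for k, v in c.get("radii", {}).items()},
                )
            )
        return cls(combinations=tuple(out))


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


def transform_complex(cx: ComplexRecord, rotation, translation) -> ComplexRecord:
    """Apply one rigid motion to every protein atom and the ligand."""
    coords = apply_rigid(cx.protein_coords(), rotation, translation)
    prot = tuple(
        replace(a, center=tuple(float(x) for x in coords[i]))
        for i, a in enumerate(cx.protein_atoms)
    )
    return replace(cx, protein_atoms=prot, ligand=cx.ligand.transformed(rotation, translation))


def _paired_alpha_coords(
    ref: ComplexRecord, other: ComplexRecord, pairs: list[tuple[str, str]]
) -> tuple[np.ndarray, np.ndarray]:
    ref_ca = ref.alpha_carbon_by_residue()
    oth_ca = other.alpha_carbon_by_residue()
    P, Q = [], []
    for ref_res, oth_res in pairs:
        if ref_res not in ref_ca:
            raise AlignmentError(f"{ref.complex_id}: no alpha carbon for residue {ref_res!r}")
        if oth_res not in oth_ca:
            raise AlignmentError(f"{other.complex_id}: no alpha carbon for residue {oth_res!r}")
        Q.append(ref.protein_atoms[ref_ca[ref_res]].center)
        P.append(other.protein_atoms[oth_ca[oth_res]].center)
    return np.array(P, dtype=float), np.array(Q, dtype=float)


def identity_correspondence(
    complexes: list[ComplexRecord], reference: str
) -> dict[str, list[tuple[str, str]]]:
    """Pair alpha carbons by identical residue ids with the reference."""
    ref = next(c for c in complexes if c.complex_id == reference)
    ref_res = set(ref.alpha_carbon_by_residue())
    out = {}
    for cx in complexes:
        if cx.complex_id == reference:
            continue
        shared = sorted(ref_res & set(cx.alpha_carbon_by_residue()))
        out[cx.complex_id] = [(r, r) for r in shared]
    return out


def align_complexes(
    complexes: list[ComplexRecord],
    reference: str,
    correspondence: dict[str, list[tuple[str, str]]] | None = None,
) -> list[ComplexRecord]:
    """Rigidly superpose every complex onto the reference via paired alpha carbons.

    ``correspondence`` maps each non-reference complex id to residue-id pairs
    (reference residue, that complex's residue); by default residues sharing
    an id are paired. Each complex needs >= 3 non-collinear pairs. The same
    proper rotation + translation is applied to protein and ligand alike.
    """
    ids = [c.complex_id for c in complexes]
    if reference not in ids:
        raise AlignmentError(f"reference complex {reference!r} not among {ids}")
    ref = complexes[ids.index(reference)]
    if correspondence is None:
        correspondence = identity_correspondence(complexes, reference)

    out = []
    for cx in complexes:
        if cx.complex_id == reference:
            out.append(cx)
            continue
        pairs = correspondence.get(cx.complex_id, [])
        if len(pairs) < 3:
            raise AlignmentError(
                f"{cx.complex_id}: need >= 3 alpha-carbon pairs, got {len(pairs)}"
            )
        P, Q = _paired_alpha_coords(ref, cx, pairs)
        # collinear alpha carbons leave the rotation under-determined
        s = np.linalg.svd(P - P.mean(axis=0), compute_uv=False)
        if s[1] < 1e-8 * max(s[0], 1.0):
            raise AlignmentError(f"{cx.complex_id}: degenerate (collinear) alpha-carbon set")
        R, t, _rmsd = kabsch_superpose(P, Q)
        out.append(transform_complex(cx, R, t))
    return out


# ---------------------------------------------------------------------------
# Interaction detection
# ---------------------------------------------------------------------------


def _protein_donor_hydrogens(cx: ComplexRecord) -> dict[int, list[int]]:
    """Map protein N/O atom index -> indices of covalently attached hydrogens."""
    h_idx = [i for i, a in enumerate(cx.protein_atoms) if a.element == "H"]
    polar_idx = [i for i, a in enumerate(cx.protein_atoms) if a.element in _POLAR_ELEMENTS]
    out: dict[int, list[int]] = {}
    if not h_idx or not polar_idx:
        return out
    coords = cx.protein_coords()
    d = cdist(coords[h_idx], coords[polar_idx])
    for hi, row in zip(h_idx, d):
        j = int(np.argmin(row))
        if row[j] <= _DONOR_H_MAX:
            out.setdefault(polar_idx[j], []).append(hi)
    return out


def detect_interactions(
    cx: ComplexRecord,
    fs: FeatureSet,
    criteria: InteractionCriteria | None = None,
) -> list[InteractionRecord]:
    """Ligand-protein interactions of one complex, given the ligand's features.

    A hydrogen bond is reported iff the donor-heavy-atom...acceptor distance
    is <= ``hbond_max_da`` and the D-H...A angle is >= ``hbond_min_angle``
    (the best hydrogen is used when several are bonded). Ligand donors pair
    with protein N/O acceptors; ligand acceptors pair with protein N/O atoms
    bearing an explicit hydrogen. A hydrophobic contact is reported iff a
    ligand hydrophobe centroid lies within ``hydrophobic_max_dist`` of at
    least ``hydrophobic_min_group`` apolar (C/S) protein atoms.
    """
    criteria = criteria or InteractionCriteria()
    lig_coords = cx.ligand.coords
    prot = cx.protein_atoms
    prot_coords = cx.protein_coords()
    donor_hs = _protein_donor_hydrogens(cx)
    out: list[InteractionRecord] = []

    for fi, feat in enumerate(fs.features):
        if feat.kind == FeatureKind.DON:
            d_idx = fs.owners[fi][0]
            h_idxs = [j for j in cx.ligand.neighbors(d_idx) if cx.ligand.element(j) == "H"]
            if not h_idxs:
                continue
            for pi, atom in enumerate(prot):
                if atom.element not in _POLAR_ELEMENTS:
                    continue
                dist = float(np.linalg.norm(lig_coords[d_idx] - prot_coords[pi]))
                if dist > criteria.hbond_max_da:
                    continue
                best = max(
                    angle_deg(lig_coords[d_idx], lig_coords[h], prot_coords[pi])
                    for h in h_idxs
                )
                if best >= criteria.hbond_min_angle:
                    out.append(
                        InteractionRecord(
                            cx.complex_id,
                            InteractionKind.HBOND_LIG_DON,
                            feat.center,
                            atom.residue_id,
                            atom.atom_name,
                            dist,
                            best,
                        )
                    )
        elif feat.kind == FeatureKind.ACC:
            a_idx = fs.owners[fi][0]
            for pi, hs in sorted(donor_hs.items()):
                dist = float(np.linalg.norm(prot_coords[pi] - lig_coords[a_idx]))
                if dist > criteria.hbond_max_da:
                    continue
                best = max(
                    angle_deg(prot_coords[pi], prot_coords[h], lig_coords[a_idx]) for h in hs
                )
                if best >= criteria.hbond_min_angle:
                    atom = prot[pi]
                    out.append(
                        InteractionRecord(
                            cx.complex_id,
                            InteractionKind.HBOND_LIG_ACC,
                            feat.center,
                            atom.residue_id,
                            atom.atom_name,
                            dist,
                            best,
                        )
                    )
        elif feat.kind == FeatureKind.HYD:
            centroid = np.asarray(feat.center)
            apolar = [
                (pi, float(np.linalg.norm(prot_coords[pi] - centroid)))
                for pi, a in enumerate(prot)
                if a.element in _APOLAR_ELEMENTS
            ]
            close = [(pi, d) for pi, d in apolar if d <= criteria.hydrophobic_max_dist]
            if len(close) >= criteria.hydrophobic_min_group:
                pi, dist = min(close, key=lambda pd: pd[1])
                atom = prot[pi]
                out.append(
                    InteractionRecord(
                        cx.complex_id,
                        InteractionKind.HYDROPHOBIC,
                        feat.center,
                        atom.residue_id,
                        atom.atom_name,
                        dist,
                        None,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Common-feature clustering
# ---------------------------------------------------------------------------

_FEATURE_KIND_ORDER = {FeatureKind.ACC: 0, FeatureKind.DON: 1, FeatureKind.HYD: 2}


def cluster_common_features(
    per_complex: list[list[InteractionRecord]],
    tolerance: float = 1.5,
    min_support: int | None = None,
) -> list[Feature]:
    """Single-linkage cluster like-kind interaction points across complexes.

    Clusters with link distance <= ``tolerance`` supported by at least
    ``min_support`` distinct complexes (default: all complexes, i.e. features
    common to every complex) become features at the cluster centroid. The
    result is canonically ordered (kind, centroid) and independent of the
    input complex order; ids are F1, F2, ...
    """
    if tolerance <= 0:
        raise InvariantError("tolerance must be > 0")
    records = [r for recs in per_complex for r in recs]
    if min_support is None:
        min_support = len(per_complex)

    pooled: list[tuple[FeatureKind, np.ndarray, set[str]]] = []
    for kind in (FeatureKind.ACC, FeatureKind.DON, FeatureKind.HYD):
        pts = [
            (np.asarray(r.ligand_point, dtype=float), r.complex_id)
            for r in records
            if _KIND_TO_FEATURE[r.kind] == kind
        ]
        if not pts:
            continue
        X = np.array([p for p, _c in pts])
        if len(pts) == 1:
            assignments = np.array([1])
        else:
            assignments = fcluster(linkage(X, method="single"), t=tolerance, criterion="distance")
        for label in np.unique(assignments):
            members = np.flatnonzero(assignments == label)
            support = {pts[i][1] for i in members}
            if len(support) >= min_support:
                pooled.append((kind, X[members].mean(axis=0), support))

    pooled.sort(key=lambda kcs: (_FEATURE_KIND_ORDER[kcs[0]], tuple(np.round(kcs[1], 9))))
    return [
        Feature(f"F{i}", kind, tuple(float(x) for x in centroid), DEFAULT_MAIN_RADIUS)
        for i, (kind, centroid, _s) in enumerate(pooled, start=1)
    ]


# ---------------------------------------------------------------------------
# Excluded volumes
# ---------------------------------------------------------------------------


def place_excluded_volumes(
    complexes: list[ComplexRecord],
    feature_pool: list[Feature],
    shell: float = 5.0,
    keepout: float = 2.0,
    volume_radius: float = 1.0,
    max_count: int = 30,
) -> list[ExcludedVolume]:
    """Greedy maximin placement of excluded volumes on binding-site atoms.

    Candidates are protein heavy atoms within ``shell`` of any ligand atom of
    their complex; candidates within ``keepout`` of any feature center are
    discarded. Up to ``max_count`` candidates are kept, greedily maximizing
    the pairwise minimum distance; ties break on (residue id, atom name,
    complex id), so placement is deterministic.
    """
    feats = np.array([f.center for f in feature_pool], dtype=float) if feature_pool else None
    candidates: list[tuple[tuple[str, str, str], np.ndarray]] = []
    for cx in complexes:
        lig = cx.ligand.coords
        prot = cx.protein_coords()
        heavy = [i for i, a in enumerate(cx.protein_atoms) if a.element != "H"]
        if not heavy:
            continue
        near = cdist(prot[heavy], lig).min(axis=1) <= shell
        for local, keep in zip(heavy, near):
            if not keep:
                continue
            atom = cx.protein_atoms[local]
            pos = prot[local]
            if feats is not None and np.linalg.norm(feats - pos, axis=1).min() <= keepout:
                continue
            candidates.append(((atom.residue_id, atom.atom_name, cx.complex_id), pos))

    if not candidates:
        return []
    candidates.sort(key=lambda kp: kp[0])
    pos = np.array([p for _k, p in candidates])

    if feats is not None:
        first = int(np.argmax(np.linalg.norm(pos[:, None, :] - feats[None], axis=2).min(axis=1)))
    else:
        first = 0
    selected = [first]
    while len(selected) < min(max_count, len(candidates)):
        dmin = cdist(pos, pos[selected]).min(axis=1)
        dmin[selected] = -1.0
        selected.append(int(np.argmax(dmin)))

    volumes = [
        ExcludedVolume(tuple(float(x) for x in pos[i]), volume_radius) for i in sorted(selected)
    ]
    if feats is not None:
        for v in volumes:  # contract: never inside the keepout of a feature
            assert np.linalg.norm(feats - np.asarray(v.center), axis=1).min() > keepout
    return volumes


# ---------------------------------------------------------------------------
# Hypothesis enumeration
# ---------------------------------------------------------------------------


def enumerate_hypotheses(
    feature_pool: list[Feature],
    spec: HypothesisSpec,
    volumes: list[ExcludedVolume],
) -> list[Pharmacophore]:
    """One query pharmacophore per named feature combination (shared volumes)."""
    by_id = {f.id: f for f in feature_pool}
    out = []
    for combo in spec.combinations:
        missing = [fid for fid in combo.feature_ids if fid not in by_id]
        if missing:
            raise InvariantError(f"hypothesis {combo.name!r}: unknown features {missing}")
        feats = []
        for f in feature_pool:
            if f.id in combo.feature_ids:
                r = combo.radius_overrides.get(f.id, f.radius)
                feats.append(replace(f, radius=r))
        out.append(
            Pharmacophore(
                name=combo.name,
                features=tuple(feats),
                excluded_volumes=tuple(volumes),
                required_feature_ids=(),
            )
        )
    return out


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------


def load_complex_pdb(path, ligand_res: str, complex_id: str | None = None) -> ComplexRecord:
    """Read a protein-ligand complex from PDB; ligand chosen by residue name.

    Ligand bonds are inferred from interatomic distances (no CONECT needed);
    formal charges default to zero.
    """
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=1)
    is_lig = arr.res_name == ligand_res
    if not is_lig.any():
        raise SchemaViolationError(f"{path}: no atoms with residue name {ligand_res!r}")
    lig = arr[is_lig]
    prot = arr[~is_lig]
    if len(prot) == 0:
        raise SchemaViolationError(f"{path}: no protein atoms")

    bonds = struc.connect_via_distances(lig)
    bond_list = [(int(i), int(j), 1) for i, j, _t in bonds.as_array()]
    atoms = tuple(
        (str(el).capitalize(), tuple(float(x) for x in xyz), 0)
        for el, xyz in zip(lig.element, lig.coord)
    )
    name = complex_id or Path(path).stem
    ligand = ConformerRecord(name + ":lig", 0, atoms, tuple(bond_list))

    protein_atoms = tuple(
        ProteinAtom(
            chain_id=str(c),
            res_number=int(r),
            res_name=str(rn),
            atom_name=str(an),
            element=str(el).capitalize(),
            center=tuple(float(x) for x in xyz),
        )
        for c, r, rn, an, el, xyz in zip(
            prot.chain_id, prot.res_id, prot.res_name, prot.atom_name, prot.element, prot.coord
        )
    )
    alpha = tuple(i for i, a in enumerate(protein_atoms) if a.atom_name == "CA")
    return ComplexRecord(name, protein_atoms, ligand, alpha)


def write_complex_pdb(cx: ComplexRecord, path, ligand_res: str = "LIG") -> None:
    """Write a complex as a PDB file (ligand as HETATM under ``ligand_res``)."""
    n_prot = len(cx.protein_atoms)
    n_lig = len(cx.ligand.atoms)
    arr = struc.AtomArray(n_prot + n_lig)
    coords = np.zeros((n_prot + n_lig, 3))
    elem_counts: dict[str, int] = {}
    for i, a in enumerate(cx.protein_atoms):
        arr.chain_id[i] = a.chain_id
        arr.res_id[i] = a.res_number
        arr.res_name[i] = a.res_name
        arr.atom_name[i] = a.atom_name
        arr.element[i] = a.element.upper()
        arr.hetero[i] = False
        coords[i] = a.center
    lig_res_id = max((a.res_number for a in cx.protein_atoms), default=0) + 1
    for k, (el, xyz, _q) in enumerate(cx.ligand.atoms):
        i = n_prot + k
        elem_counts[el] = elem_counts.get(el, 0) + 1
        arr.chain_id[i] = "L"
        arr.res_id[i] = lig_res_id
        arr.res_name[i] = ligand_res
        arr.atom_name[i] = f"{el.upper()}{elem_counts[el]}"
        arr.element[i] = el.upper()
        arr.hetero[i] = True
        coords[i] = xyz
    arr.coord = coords
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))
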