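"""Pharmacophoric feature perception on 3D small-molecule conformers.

Perceives hydrogen-bond donors and acceptors (SMARTS-driven, RDKit matching)
and hydrophobic centroids (all-carbon rings and acyclic carbon chains), then
places projected site points that encode hydrogen-bond directionality:

* a donor projection lies along the donor heavy-atom -> hydrogen unit vector,
* an acceptor projection lies opposite the mean unit vector to the acceptor's
  bonded heavy neighbours (a lone-pair direction proxy),

both at a configurable projection distance (default 3.0 A, a typical
donor...acceptor separation).

Conformers are exchanged as multi-record V2000 SDF; each record is one
conformer. Explicit hydrogens are required for donor projections; the SDF
reader adds any missing hydrogens with generated coordinates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .errors import InvariantError, MalformedFileError, PerceptionError
from .geometry import Point, apply_rigid, unit
from .ph4core import DEFAULT_MAIN_RADIUS, DEFAULT_PROJ_RADIUS, Feature, FeatureKind

logger = logging.getLogger(__name__)

__all__ = [
    "ConformerRecord",
    "FeatureSet",
    "PerceptionRules",
    "default_rules",
    "perceive_features",
    "project_site_points",
    "perceive_and_project",
    "read_sdf",
    "write_sdf",
]

#: Minimum size for an all-carbon ring to count as one hydrophobic group.
RING_MIN_ATOMS = 5

_KIND_ORDER = {
    FeatureKind.ACC: 0,
    FeatureKind.DON: 1,
    FeatureKind.HYD: 2,
    FeatureKind.ACC_PROJ: 3,
    FeatureKind.DON_PROJ: 4,
}

_BOND_TYPES = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
    4: Chem.BondType.AROMATIC,
}


@dataclass(frozen=True)
class ConformerRecord:
    """One 3D conformer: elements, coordinates (A), charges and bonds."""

    molecule_id: str
    conformer_index: int
    atoms: tuple[tuple[str, Point, int], ...]  # (element, xyz, formal charge)
    bonds: tuple[tuple[int, int, int], ...]  # (i, j, order; 4 = aromatic)

    def __post_init__(self):
        if self.conformer_index < 0:
            raise InvariantError("conformer_index must be >= 0")
        if not self.atoms:
            raise InvariantError(f"{self.molecule_id}: conformer needs at least 1 atom")
        n = len(self.atoms)
        for el, xyz, _q in self.atoms:
            if len(xyz) != 3 or not all(np.isfinite(xyz)):
                raise InvariantError(f"{self.molecule_id}: non-finite coordinates")
        for i, j, _o in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise InvariantError(f"{self.molecule_id}: bond ({i},{j}) out of range")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a[1] for a in self.atoms], dtype=float)

    def element(self, i: int) -> str:
        return self.atoms[i][0]

    def neighbors(self, i: int) -> list[int]:
        out = [j if a == i else a for a, j, _o in self.bonds if i in (a, j)]
        return sorted(out)

    def transformed(self, rotation, translation) -> "ConformerRecord":
        new_xyz = apply_rigid(self.coords, rotation, translation)
        atoms = tuple(
            (el, tuple(float(x) for x in new_xyz[i]), q)
            for i, (el, _xyz, q) in enumerate(self.atoms)
        )
        return ConformerRecord(self.molecule_id, self.conformer_index, atoms, self.bonds)

    def to_rdkit(self) -> Chem.Mol:
        """Build a sanitized RDKit molecule (implicit hydrogens allowed)."""
        rw = Chem.RWMol()
        for el, _xyz, q in self.atoms:
            atom = Chem.Atom(el)
            atom.SetFormalCharge(q)
            rw.AddAtom(atom)
        for i, j, order in self.bonds:
            bt = _BOND_TYPES.get(order)
            if bt is None:
                raise PerceptionError(f"{self.molecule_id}: unsupported bond order {order}")
            rw.AddBond(i, j, bt)
        mol = rw.GetMol()
        try:
            Chem.SanitizeMol(mol)
        except Exception as exc:  # rdkit raises various sanitization errors
            raise PerceptionError(f"{self.molecule_id}: unsanitizable molecule: {exc}") from exc
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i, (_el, xyz, _q) in enumerate(self.atoms):
            conf.SetAtomPosition(i, tuple(map(float, xyz)))
        mol.AddConformer(conf, assignId=True)
        mol.SetProp("_Name", self.molecule_id)
        return mol

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, molecule_id: str, conformer_index: int) -> "ConformerRecord":
        if mol.GetNumConformers() == 0:
            raise PerceptionError(f"{molecule_id}: molecule has no coordinates")
        conf = mol.GetConformer()
        atoms = tuple(
            (
                atom.GetSymbol(),
                tuple(float(x) for x in conf.GetAtomPosition(atom.GetIdx())),
                atom.GetFormalCharge(),
            )
            for atom in mol.GetAtoms()
        )
        bonds = []
        for b in mol.GetBonds():
            if b.GetBondType() == Chem.BondType.AROMATIC:
                order = 4
            else:
                order = int(round(b.GetBondTypeAsDouble()))
            bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
        return cls(molecule_id, conformer_index, atoms, tuple(bonds))


@dataclass(frozen=True)
class FeatureSet:
    """Perceived features of one conformer, with owning atom indices.

    ``owners[k]`` lists the atom indices that define ``features[k]`` (the
    heavy atom for ACC/DON, the group atoms for HYD, parent heavy atom plus
    hydrogen for DON_PROJ).
    """

    molecule_id: str
    conformer_index: int
    features: tuple[Feature, ...]
    owners: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        if len(self.features) != len(self.owners):
            raise InvariantError("features and owners must be parallel")
        ids = {f.id for f in self.features}
        for f in self.features:
            if f.kind.is_projected and f.parent_id not in ids:
                raise InvariantError(f"projection {f.id} references unknown parent")

    def centers(self) -> np.ndarray:
        return np.array([f.center for f in self.features], dtype=float)

    def by_kind(self, kind: FeatureKind) -> list[int]:
        return [i for i, f in enumerate(self.features) if f.kind == kind]


@dataclass(frozen=True)
class PerceptionRules:
    """SMARTS-driven typing rules.

    The first atom of each donor/acceptor SMARTS match is taken as the
    feature atom. Hydrophobe patterns select candidate atoms; all-carbon
    rings of >= 5 selected atoms and acyclic connected groups of
    >= ``hydrophobe_min_atoms`` selected atoms become centroid features.
    """

    donor_patterns: tuple[str, ...] = ("[#7;!H0]", "[#8;!H0]")
    acceptor_patterns: tuple[str, ...] = (
        "[#7;!$([#7+]);!$([NX3][CX3]=[OX1])]",
        "[#8;!$([#8+])]",
    )
    hydrophobe_patterns: tuple[str, ...] = ("[#6]",)
    projection_distance: float = 3.0
    hydrophobe_min_atoms: int = 3

    def __post_init__(self):
        if self.projection_distance <= 0:
            raise InvariantError("projection_distance must be > 0")
        for name in ("donor_patterns", "acceptor_patterns", "hydrophobe_patterns"):
            if not getattr(self, name):
                raise InvariantError(f"{name} must be non-empty")

    def compiled(self, patterns: tuple[str, ...]) -> list[Chem.Mol]:
        out = []
        for smarts in patterns:
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise PerceptionError(f"unparsable SMARTS pattern: {smarts!r}")
            out.append(patt)
        return out

    @classmethod
    def from_json(cls, path) -> "PerceptionRules":
        try:
            doc = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise MalformedFileError(f"{path}: not valid JSON: {exc}") from exc
        kwargs = {}
        for key in (
            "donor_patterns",
            "acceptor_patterns",
            "hydrophobe_patterns",
        ):
            if key in doc:
                kwargs[key] = tuple(doc[key])
        for key in ("projection_distance", "hydrophobe_min_atoms"):
            if key in doc:
                kwargs[key] = doc[key]
        return cls(**kwargs)


def default_rules() -> PerceptionRules:
    return PerceptionRules()


def _matched_atoms(mol: Chem.Mol, patterns: list[Chem.Mol]) -> list[int]:
    hits: set[int] = set()
    for patt in patterns:
        for match in mol.GetSubstructMatches(patt):
            hits.add(match[0])
    return sorted(hits)


def _hydrophobe_groups(mol: Chem.Mol, selected: set[int], min_atoms: int) -> list[tuple[int, ...]]:
    """All-carbon rings (>= RING_MIN_ATOMS) and acyclic selected components."""
    groups: list[tuple[int, ...]] = []
    ring_atoms: set[int] = set()
    for ring in mol.GetRingInfo().AtomRings():
        if set(ring) <= selected and len(ring) >= RING_MIN_ATOMS:
            groups.append(tuple(sorted(ring)))
        ring_atoms.update(ring)
    acyclic = {i for i in selected if i not in ring_atoms}
    seen: set[int] = set()
    for start in sorted(acyclic):
        if start in seen:
            continue
        comp, stack = [], [start]
        seen.add(start)
        while stack:
            cur = stack.pop()
            comp.append(cur)
            for nb in mol.GetAtomWithIdx(cur).GetNeighbors():
                j = nb.GetIdx()
                if j in acyclic and j not in seen:
                    seen.add(j)
                    stack.append(j)
        if len(comp) >= min_atoms:
            groups.append(tuple(sorted(comp)))
    return sorted(groups, key=lambda g: g[0])


def perceive_features(conf: ConformerRecord, rules: PerceptionRules | None = None) -> FeatureSet:
    """Perceive ACC / DON / HYD features on one conformer.

    Deterministic: features are ordered by kind (ACC, DON, HYD) then by
    lowest owning atom index; ids are ``ACC1, ACC2, ..., DON1, ..., HYD1, ...``.
    """
    rules = rules or default_rules()
    mol = conf.to_rdkit()
    coords = conf.coords

    donors = _matched_atoms(mol, rules.compiled(rules.donor_patterns))
    acceptors = _matched_atoms(mol, rules.compiled(rules.acceptor_patterns))
    hyd_sel = set(_matched_atoms(mol, rules.compiled(rules.hydrophobe_patterns)))
    groups = _hydrophobe_groups(mol, hyd_sel, rules.hydrophobe_min_atoms)

    features: list[Feature] = []
    owners: list[tuple[int, ...]] = []
    for n, idx in enumerate(acceptors, start=1):
        features.append(
            Feature(f"ACC{n}", FeatureKind.ACC, tuple(coords[idx]), DEFAULT_MAIN_RADIUS)
        )
        owners.append((idx,))
    for n, idx in enumerate(donors, start=1):
        features.append(
            Feature(f"DON{n}", FeatureKind.DON, tuple(coords[idx]), DEFAULT_MAIN_RADIUS)
        )
        owners.append((idx,))
    for n, group in enumerate(groups, start=1):
        centroid = coords[list(group)].mean(axis=0)
        features.append(Feature(f"HYD{n}", FeatureKind.HYD, tuple(centroid), DEFAULT_MAIN_RADIUS))
        owners.append(group)
    return FeatureSet(conf.molecule_id, conf.conformer_index, tuple(features), tuple(owners))


def _explicit_hydrogens(conf: ConformerRecord, heavy: int) -> list[int]:
    return [j for j in conf.neighbors(heavy) if conf.element(j) == "H"]


def _heavy_neighbors(conf: ConformerRecord, atom: int) -> list[int]:
    return [j for j in conf.neighbors(atom) if conf.element(j) != "H"]


def project_site_points(
    fs: FeatureSet, conf: ConformerRecord, rules: PerceptionRules | None = None
) -> FeatureSet:
    """Append DON_PROJ / ACC_PROJ site points to a perceived feature set.

    Donor projections run along the heavy-atom -> hydrogen unit vector (the
    lowest-index hydrogen when several are bonded); acceptor projections run
    opposite the mean unit vector to bonded heavy neighbours. Acceptors with
    no heavy neighbour (isolated water-like oxygens) receive no projection.
    Every projected point sits exactly ``projection_distance`` from its parent.
    """
    rules = rules or default_rules()
    coords = conf.coords
    d = rules.projection_distance

    features = list(fs.features)
    owners = list(fs.owners)
    for i, feat in enumerate(fs.features):
        if feat.kind == FeatureKind.DON:
            heavy = fs.owners[i][0]
            hydrogens = _explicit_hydrogens(conf, heavy)
            if not hydrogens:
                raise InvariantError(
                    f"{conf.molecule_id}: donor {feat.id} has no explicit hydrogen"
                )
            h = hydrogens[0]
            direction = unit(coords[h] - coords[heavy])
            point = coords[heavy] + d * direction
            features.append(
                Feature(
                    f"{feat.id}_P",
                    FeatureKind.DON_PROJ,
                    tuple(point),
                    DEFAULT_PROJ_RADIUS,
                    parent_id=feat.id,
                )
            )
            owners.append((heavy, h))
        elif feat.kind == FeatureKind.ACC:
            acc = fs.owners[i][0]
            heavies = _heavy_neighbors(conf, acc)
            if not heavies:
                continue  # no defined lone-pair direction
            mean_vec = np.mean([unit(coords[j] - coords[acc]) for j in heavies], axis=0)
            if np.linalg.norm(mean_vec) < 1e-9:
                continue  # symmetric environment, direction undefined
            direction = -unit(mean_vec)
            point = coords[acc] + d * direction
            features.append(
                Feature(
                    f"{feat.id}_P",
                    FeatureKind.ACC_PROJ,
                    tuple(point),
                    DEFAULT_PROJ_RADIUS,
                    parent_id=feat.id,
                )
            )
            owners.append(tuple(fs.owners[i]))
    return FeatureSet(fs.molecule_id, fs.conformer_index, tuple(features), tuple(owners))


def perceive_and_project(
    conf: ConformerRecord, rules: PerceptionRules | None = None
) -> FeatureSet:
    rules = rules or default_rules()
    return project_site_points(perceive_features(conf, rules), conf, rules)


# ---------------------------------------------------------------------------
# SDF I/O
# ---------------------------------------------------------------------------


def read_sdf(path, id_prop: str | None = None, add_hs: bool = True) -> Iterator[ConformerRecord]:
    """Iterate conformer records from a multi-record V2000 SDF file.

    ``molecule_id`` comes from the record title, or from property ``id_prop``
    when given. Consecutive records sharing an id become conformers 0, 1, ...
    of one molecule (a ``conformer_index`` property overrides). Unreadable
    records are skipped with a warning.
    """
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    counters: dict[str, int] = {}
    for rec_no, mol in enumerate(supplier):
        if mol is None:
            logger.warning("%s: skipping unreadable SDF record %d", path, rec_no)
            continue
        if id_prop is not None and mol.HasProp(id_prop):
            mol_id = mol.GetProp(id_prop)
        else:
            mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        if not mol_id:
            mol_id = f"record{rec_no}"
        if mol.HasProp("conformer_index"):
            conf_idx = int(mol.GetProp("conformer_index"))
        else:
            conf_idx = counters.get(mol_id, 0)
        counters[mol_id] = conf_idx + 1
        if add_hs:
            mol = Chem.AddHs(mol, addCoords=True)
        yield ConformerRecord.from_rdkit(mol, mol_id, conf_idx)


def write_sdf(records: Iterable[ConformerRecord], path) -> None:
    """Write conformer records to a V2000 SDF file (deterministic output)."""
    writer = Chem.SDWriter(str(path))
    writer.SetForceV3000(False)
    for rec in records:
        mol = rec.to_rdkit()
        mol.SetProp("conformer_index", str(rec.conformer_index))
        writer.write(mol)
    writer.close()
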