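"""Pharmacophore data model, JSON serialization and geometric bookkeeping.

A pharmacophore is a named, ordered set of typed 3D features — hydrogen-bond
acceptors (ACC), donors (DON) and hydrophobic centroids (HYD), optionally with
projected site points (ACC_PROJ / DON_PROJ) marking the direction of the
hydrogen bond toward the putative receptor partner — plus a set of excluded
volumes describing receptor-occupied space that ligand atoms must not enter.

Coordinates are Cartesian angstroms. Every feature carries a tolerance-sphere
radius; the radii double as the admissible slack in the screening prefilter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import (
    DanglingParentError,
    InvariantError,
    MalformedFileError,
    SchemaViolationError,
)
from .geometry import Point

__all__ = [
    "FeatureKind",
    "Feature",
    "ExcludedVolume",
    "Pharmacophore",
    "load_pharmacophore",
    "save_pharmacophore",
    "interfeature_distances",
    "DEFAULT_MAIN_RADIUS",
    "DEFAULT_PROJ_RADIUS",
]

#: Default tolerance-sphere radii (angstrom) when the input omits them.
DEFAULT_MAIN_RADIUS = 1.0
DEFAULT_PROJ_RADIUS = 1.5


class FeatureKind(str, Enum):
    ACC = "ACC"
    DON = "DON"
    HYD = "HYD"
    ACC_PROJ = "ACC_PROJ"
    DON_PROJ = "DON_PROJ"

    @property
    def is_projected(self) -> bool:
        return self in (FeatureKind.ACC_PROJ, FeatureKind.DON_PROJ)

    @property
    def parent_kind(self) -> "FeatureKind | None":
        """For projected kinds, the main kind they must hang off."""
        return {
            FeatureKind.ACC_PROJ: FeatureKind.ACC,
            FeatureKind.DON_PROJ: FeatureKind.DON,
        }.get(self)


@dataclass(frozen=True)
class Feature:
    """One typed pharmacophoric point with a tolerance sphere.

    ``parent_id`` is set exactly for projected kinds and names the main
    feature whose hydrogen-bond direction the projection encodes.
    """

    id: str
    kind: FeatureKind
    center: Point
    radius: float
    parent_id: str | None = None

    def __post_init__(self):
        if not self.id:
            raise InvariantError("feature id must be non-empty")
        if self.radius <= 0:
            raise InvariantError(f"feature {self.id}: radius must be > 0")
        if len(self.center) != 3 or not all(np.isfinite(self.center)):
            raise InvariantError(f"feature {self.id}: center must be a finite 3D point")
        if self.kind.is_projected and self.parent_id is None:
            raise InvariantError(f"projected feature {self.id} must carry a parent_id")
        if not self.kind.is_projected and self.parent_id is not None:
            raise InvariantError(f"main feature {self.id} must not carry a parent_id")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)

    def moved_to(self, center) -> "Feature":
        return replace(self, center=tuple(float(x) for x in center))


@dataclass(frozen=True)
class ExcludedVolume:
    """A receptor-occupied sphere; any ligand atom entering it kills a match."""

    center: Point
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise InvariantError("excluded volume radius must be > 0")
        if len(self.center) != 3 or not all(np.isfinite(self.center)):
            raise InvariantError("excluded volume center must be a finite 3D point")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)


@dataclass(frozen=True)
class Pharmacophore:
    """A named query model: ordered features, excluded volumes, required ids.

    ``required_feature_ids`` lists the feature ids every hit must map; an
    empty tuple means "all features are required" (full-match screening).
    """

    name: str
    features: tuple[Feature, ...]
    excluded_volumes: tuple[ExcludedVolume, ...] = ()
    required_feature_ids: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "features", tuple(self.features))
        object.__setattr__(self, "excluded_volumes", tuple(self.excluded_volumes))
        object.__setattr__(self, "required_feature_ids", tuple(self.required_feature_ids))
        ids = [f.id for f in self.features]
        if len(set(ids)) != len(ids):
            raise InvariantError(f"model {self.name}: duplicate feature ids")
        if not any(not f.kind.is_projected for f in self.features):
            raise InvariantError(f"model {self.name}: needs at least one main feature")
        by_id = {f.id: f for f in self.features}
        for f in self.features:
            if f.kind.is_projected:
                parent = by_id.get(f.parent_id)
                if parent is None:
                    raise DanglingParentError(
                        f"model {self.name}: feature {f.id} references missing parent "
                        f"{f.parent_id!r}"
                    )
                if parent.kind != f.kind.parent_kind:
                    raise InvariantError(
                        f"model {self.name}: projection {f.id} must hang off a "
                        f"{f.kind.parent_kind.value} feature"
                    )
        unknown = set(self.required_feature_ids) - set(ids)
        if unknown:
            raise InvariantError(
                f"model {self.name}: required_feature_ids not in model: {sorted(unknown)}"
            )

    @property
    def feature_ids(self) -> tuple[str, ...]:
        return tuple(f.id for f in self.features)

    @property
    def required(self) -> tuple[Feature, ...]:
        """Features that must all be mapped; defaults to every feature."""
        if not self.required_feature_ids:
            return self.features
        wanted = set(self.required_feature_ids)
        return tuple(f for f in self.features if f.id in wanted)

    def feature(self, fid: str) -> Feature:
        for f in self.features:
            if f.id == fid:
                return f
        raise KeyError(fid)

    def centers(self) -> np.ndarray:
        return np.array([f.center for f in self.features], dtype=float)


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

_NDIGITS = 6  # fixed float precision for byte-stable files


def _r(x: float) -> float:
    return round(float(x), _NDIGITS)


def _feature_to_json(f: Feature) -> dict:
    d = {
        "id": f.id,
        "kind": f.kind.value,
        "center": [_r(c) for c in f.center],
        "radius": _r(f.radius),
    }
    if f.parent_id is not None:
        d["parent_id"] = f.parent_id
    return d


def save_pharmacophore(model: Pharmacophore, path) -> None:
    """Write ``model`` as canonical JSON (sorted keys, 6-decimal floats).

    Two saves of the same model produce byte-identical files. Coordinates are
    rounded to 6 decimals, so save->load is the exact identity on models whose
    floats already carry at most 6 decimals.
    """
    doc = {
        "name": model.name,
        "features": [_feature_to_json(f) for f in model.features],
        "excluded_volumes": [
            {"center": [_r(c) for c in v.center], "radius": _r(v.radius)}
            for v in model.excluded_volumes
        ],
        "required_feature_ids": list(model.required_feature_ids),
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1) + "\n")


def _parse_point(obj, what: str) -> Point:
    if (
        not isinstance(obj, (list, tuple))
        or len(obj) != 3
        or not all(isinstance(x, (int, float)) and not isinstance(x, bool) for x in obj)
    ):
        raise SchemaViolationError(f"{what}: 'center' must be a list of 3 numbers")
    return tuple(float(x) for x in obj)


def load_pharmacophore(path) -> Pharmacophore:
    """Load a pharmacophore from its JSON file, validating every invariant."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise MalformedFileError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaViolationError(f"{path}: top level must be a JSON object")
    name = doc.get("name")
    if not isinstance(name, str) or not name:
        raise SchemaViolationError(f"{path}: 'name' must be a non-empty string")
    raw_feats = doc.get("features")
    if not isinstance(raw_feats, list) or not raw_feats:
        raise SchemaViolationError(f"{path}: 'features' must be a non-empty list")

    features = []
    for i, rf in enumerate(raw_feats):
        if not isinstance(rf, dict):
            raise SchemaViolationError(f"{path}: features[{i}] must be an object")
        try:
            kind = FeatureKind(rf.get("kind"))
        except ValueError:
            raise SchemaViolationError(
                f"{path}: features[{i}]: unknown kind {rf.get('kind')!r}"
            ) from None
        fid = rf.get("id")
        if not isinstance(fid, str) or not fid:
            raise SchemaViolationError(f"{path}: features[{i}]: 'id' must be a string")
        radius = rf.get("radius")
        if radius is None:
            radius = DEFAULT_PROJ_RADIUS if kind.is_projected else DEFAULT_MAIN_RADIUS
        if not isinstance(radius, (int, float)) or isinstance(radius, bool):
            raise SchemaViolationError(f"{path}: features[{i}]: 'radius' must be a number")
        parent = rf.get("parent_id")
        if parent is not None and not isinstance(parent, str):
            raise SchemaViolationError(f"{path}: features[{i}]: 'parent_id' must be a string")
        try:
            features.append(
                Feature(
                    id=fid,
                    kind=kind,
                    center=_parse_point(rf.get("center"), f"features[{i}]"),
                    radius=float(radius),
                    parent_id=parent,
                )
            )
        except InvariantError as exc:
            raise SchemaViolationError(f"{path}: {exc}") from exc

    volumes = []
    raw_vols = doc.get("excluded_volumes", [])
    if not isinstance(raw_vols, list):
        raise SchemaViolationError(f"{path}: 'excluded_volumes' must be a list")
    for i, rv in enumerate(raw_vols):
        if not isinstance(rv, dict):
            raise SchemaViolationError(f"{path}: excluded_volumes[{i}] must be an object")
        radius = rv.get("radius")
        if not isinstance(radius, (int, float)) or isinstance(radius, bool):
            raise SchemaViolationError(
                f"{path}: excluded_volumes[{i}]: 'radius' must be a number"
            )
        try:
            volumes.append(
                ExcludedVolume(
                    center=_parse_point(rv.get("center"), f"excluded_volumes[{i}]"),
                    radius=float(radius),
                )
            )
        except InvariantError as exc:
            raise SchemaViolationError(f"{path}: {exc}") from exc

    req = doc.get("required_feature_ids", [])
    if not isinstance(req, list) or not all(isinstance(x, str) for x in req):
        raise SchemaViolationError(f"{path}: 'required_feature_ids' must be a list of strings")

    try:
        return Pharmacophore(
            name=name,
            features=tuple(features),
            excluded_volumes=tuple(volumes),
            required_feature_ids=tuple(req),
        )
    except DanglingParentError:
        raise
    except InvariantError as exc:
        raise SchemaViolationError(f"{path}: {exc}") from exc


def interfeature_distances(model: Pharmacophore) -> np.ndarray:
    """Symmetric matrix of pairwise Euclidean feature-center distances (angstrom).

    Row/column order follows the model's feature order.
    """
    if len(model.features) < 2:
        raise InvariantError("interfeature_distances needs at least 2 features")
    return squareform(pdist(model.centers()))
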