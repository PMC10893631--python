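import numpy as np
import pytest

from ph4screen.featperc import ConformerRecord
from ph4screen.ph4core import ExcludedVolume, Feature, FeatureKind, Pharmacophore
from ph4screen.synthdata import default_query


@pytest.fixture
def query() -> Pharmacophore:
    """The seven-feature kinase-style query with 30 excluded volumes."""
    return default_query()


@pytest.fixture
def simple_query() -> Pharmacophore:
    """A minimal three-feature query without volumes (one of each main kind)."""
    return Pharmacophore(
        name="simple",
        features=(
            Feature("A", FeatureKind.ACC, (0.0, 0.0, 0.0), 1.0),
            Feature("D", FeatureKind.DON, (4.0, 0.0, 0.0), 1.0),
            Feature("H", FeatureKind.HYD, (0.0, 5.0, 0.0), 1.0),
        ),
    )


def make_methanol(origin=(0.0, 0.0, 0.0)) -> ConformerRecord:
    """Explicit-hydrogen methanol posed with the O-H bond along +x."""
    o = np.asarray(origin, dtype=float)
    atoms = (
        ("O", tuple(o), 0),
        ("H", tuple(o + [0.96, 0.0, 0.0]), 0),
        ("C", tuple(o + [-1.43, 0.0, 0.0]), 0),
    )
    return ConformerRecord("methanol", 0, atoms, ((0, 1, 1), (0, 2, 1)))


def make_benzene() -> ConformerRecord:
    """An ideal benzene hexagon (C-C 1.39 A) centered at the origin."""
    atoms = []
    for k in range(6):
        th = np.pi * k / 3.0
        atoms.append(("C", (1.39 * np.cos(th), 1.39 * np.sin(th), 0.0), 0))
    bonds = tuple((k, (k + 1) % 6, 2 if k % 2 == 0 else 1) for k in range(6))
    return ConformerRecord("benzene", 0, tuple(atoms), bonds)


def make_ethane() -> ConformerRecord:
    atoms = (("C", (0.0, 0.0, 0.0), 0), ("C", (1.54, 0.0, 0.0), 0))
    return ConformerRecord("ethane", 0, atoms, ((0, 1, 1),))
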