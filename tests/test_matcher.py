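import math

import numpy as np
import pytest

from oracle_utils import (
    accepted_mappings,
    exhaustive_best_rmsd,
    grid_min_rmsd,
    superpose_rmsd,
)
from ph4screen.errors import AlignmentError
from ph4screen.featperc import FeatureSet
from ph4screen.geometry import apply_rigid, random_rotation
from ph4screen.matcher import (
    check_excluded_volumes,
    distance_prefilter,
    kabsch_superpose,
    match_conformer,
    screen_feature_sets,
)
from ph4screen.ph4core import ExcludedVolume, Feature, FeatureKind, Pharmacophore


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------


def test_kabsch_identity_on_equal_sets():
    P = np.random.default_rng(0).normal(size=(6, 3))
    R, t, rmsd = kabsch_superpose(P, P)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(R, np.eye(3), atol=1e-9)
    assert np.allclose(t, 0.0, atol=1e-9)


def test_kabsch_recovers_rigid_motion():
    rng = np.random.default_rng(1)
    P = rng.normal(size=(5, 3))
    Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    Q = P @ Rz.T + np.array([1.0, 2.0, 3.0])
    R, t, rmsd = kabsch_superpose(P, Q)
    assert rmsd < 1e-9
    assert np.allclose(R, Rz, atol=1e-9)
    assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)


def test_kabsch_mirror_matches_rotation_grid_oracle():
    """Reflections are disallowed: a mirrored set keeps a strictly positive
    RMSD matching a dense proper-rotation search."""
    P = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    Q = P * np.array([1.0, 1.0, -1.0])
    _R, _t, rmsd = kabsch_superpose(P, Q)
    assert rmsd > 0.0
    grid = grid_min_rmsd(P, Q, n_samples=20000, seed=0)
    assert rmsd <= grid + 1e-9  # closed form is optimal
    assert grid - rmsd < 0.02  # and the grid gets close at this resolution


@pytest.mark.parametrize("seed", range(5))
def test_kabsch_agrees_with_scipy_align_vectors(seed):
    rng = np.random.default_rng(seed)
    P, Q = rng.normal(size=(7, 3)), rng.normal(size=(7, 3))
    _R, _t, rmsd = kabsch_superpose(P, Q)
    assert rmsd == pytest.approx(superpose_rmsd(P, Q), abs=1e-9)


def test_kabsch_input_validation():
    P = np.zeros((2, 3))
    with pytest.raises(AlignmentError):
        kabsch_superpose(P, P)
    with pytest.raises(AlignmentError):
        kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


def test_kabsch_coincident_points_degenerate_contract():
    P = np.zeros((4, 3))
    Q = np.ones((4, 3))
    R, t, rmsd = kabsch_superpose(P, Q)
    assert np.allclose(R, np.eye(3))
    assert np.allclose(t, [1.0, 1.0, 1.0])
    assert rmsd == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# Distance prefilter
# ---------------------------------------------------------------------------


def _fs(feature_list, mol_id="mol"):
    """Build a bare FeatureSet; projected kinds attach to the latest main of
    their parent kind."""
    feats = []
    last_main = {}
    for i, (kind, ctr) in enumerate(feature_list):
        parent = None
        if kind.is_projected:
            parent = last_main[kind.parent_kind]
        f = Feature(f"m{i}", kind, tuple(map(float, ctr)), 1.0, parent_id=parent)
        if not kind.is_projected:
            last_main[kind] = f.id
        feats.append(f)
    return FeatureSet(mol_id, 0, tuple(feats), tuple((0,) for _ in feats))


def test_prefilter_unique_mapping(simple_query):
    fs = _fs(
        [
            (FeatureKind.ACC, (0, 0, 0)),
            (FeatureKind.DON, (4, 0, 0)),
            (FeatureKind.HYD, (0, 5, 0)),
        ]
    )
    maps = distance_prefilter(simple_query, fs)
    assert len(maps) == 1
    assert maps[0].pairs == (("A", 0), ("D", 1), ("H", 2))


def test_prefilter_two_compatible_acceptors_give_two_mappings(simple_query):
    fs = _fs(
        [
            (FeatureKind.ACC, (0, 0, 0)),
            (FeatureKind.ACC, (0.5, 0, 0)),
            (FeatureKind.DON, (4, 0, 0)),
            (FeatureKind.HYD, (0, 5, 0)),
        ]
    )
    maps = distance_prefilter(simple_query, fs)
    assert len(maps) == 2
    assert {m.pairs[0][1] for m in maps} == {0, 1}


def test_prefilter_rejects_distance_beyond_slack(simple_query):
    # query ACC-DON distance 4.0, slack 2.0 -> molecule distance 6.5 fails
    fs = _fs(
        [
            (FeatureKind.ACC, (0, 0, 0)),
            (FeatureKind.DON, (6.5, 0, 0)),
            (FeatureKind.HYD, (0, 5, 0)),
        ]
    )
    assert distance_prefilter(simple_query, fs) == []


def test_prefilter_requires_every_kind(simple_query):
    fs = _fs([(FeatureKind.ACC, (0, 0, 0)), (FeatureKind.DON, (4, 0, 0))])
    assert distance_prefilter(simple_query, fs) == []


# ---------------------------------------------------------------------------
# Excluded volumes
# ---------------------------------------------------------------------------


def test_clash_rules_at_boundary():
    vols = [ExcludedVolume((0.0, 0.0, 0.0), 1.0)]
    assert check_excluded_volumes([(0.0, 0.0, 0.0)], vols, atom_radius=1.0)
    assert not check_excluded_volumes([(2.1, 0.0, 0.0)], vols, atom_radius=1.0)
    # exactly at radius + atom_radius: strict inequality means no clash
    assert not check_excluded_volumes([(2.0, 0.0, 0.0)], vols, atom_radius=1.0)


# ---------------------------------------------------------------------------
# Conformer matching
# ---------------------------------------------------------------------------


def test_exact_feature_placement_is_perfect_hit(simple_query):
    fs = _fs([(k.kind, k.center) for k in simple_query.features])
    res = match_conformer(fs, None, simple_query)
    assert res.hit and res.rmsd == pytest.approx(0.0, abs=1e-12)
    assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)


def test_common_translation_is_absorbed(simple_query):
    fs = _fs([(f.kind, np.asarray(f.center) + [0.5, 0.0, 0.0]) for f in simple_query.features])
    res = match_conformer(fs, None, simple_query)
    assert res.hit and res.rmsd < 1e-9


def test_no_mapping_yields_absent_mapping_no_hit(simple_query):
    fs = _fs([(FeatureKind.ACC, (0, 0, 0))])
    res = match_conformer(fs, None, simple_query)
    assert res.mapping is None and not res.hit and math.isinf(res.rmsd)


@pytest.mark.parametrize("seed", range(10))
def test_jittered_match_equals_exhaustive_oracle(query, seed):
    rng = np.random.default_rng(seed)
    feats = []
    for f in query.features:
        feats.append((f.kind, np.asarray(f.center) + rng.normal(0, 0.2, 3)))
    fs = _fs(feats)
    res = match_conformer(fs, None, query)
    oracle_rmsd, _ = exhaustive_best_rmsd(query, fs)
    assert res.rmsd == pytest.approx(oracle_rmsd, abs=1e-9)


def test_prefilter_admissibility_on_jittered_instances(query):
    """No oracle-accepted mapping at the hit threshold is ever prefiltered out."""
    for seed in range(20):
        rng = np.random.default_rng(seed)
        fs = _fs(
            [(f.kind, np.asarray(f.center) + rng.normal(0, 0.25, 3)) for f in query.features]
        )
        kept = {m.molecule_indices() for m in distance_prefilter(query, fs)}
        for combo in accepted_mappings(query, fs, threshold=1.0):
            assert combo in kept


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------


def test_screen_empty_library(simple_query):
    rep = screen_feature_sets([], simple_query)
    assert rep.n_screened == 0 and rep.n_hits == 0 and rep.hits == []


def test_screen_rigid_copies_all_hit(query):
    pairs = []
    for seed in range(12):
        rng = np.random.default_rng(seed)
        R, t = random_rotation(rng), rng.uniform(-10, 10, 3)
        fs = _fs(
            [(f.kind, apply_rigid(f.center, R, t)[0]) for f in query.features],
            mol_id=f"mol{seed}",
        )
        pairs.append((fs, None))
    rep = screen_feature_sets(pairs, query)
    assert rep.n_hits == 12
    assert all(r.rmsd < 1e-9 for r in rep.hits)
    # hit list sorted ascending by rmsd
    rmsds = [r.rmsd for r in rep.hits]
    assert rmsds == sorted(rmsds)


def test_hit_count_monotone_in_threshold(query):
    rng = np.random.default_rng(3)
    pairs = []
    for i in range(30):
        fs = _fs(
            [(f.kind, np.asarray(f.center) + rng.normal(0, 0.4, 3)) for f in query.features],
            mol_id=f"m{i}",
        )
        pairs.append((fs, None))
    counts = [
        screen_feature_sets(pairs, query, rmsd_threshold=th).n_hits
        for th in (0.2, 0.5, 1.0, 2.0)
    ]
    assert counts == sorted(counts)


def test_adding_excluded_volume_never_increases_hits(query, simple_query):
    from ph4screen.featperc import ConformerRecord

    fs = _fs([(f.kind, f.center) for f in simple_query.features])
    conf = ConformerRecord(
        "mol",
        0,
        tuple(("C", tuple(map(float, f.center)), 0) for f in simple_query.features),
        (),
    )
    base = match_conformer(fs, conf, simple_query)
    assert base.hit
    blocked = Pharmacophore(
        name="blocked",
        features=simple_query.features,
        excluded_volumes=(ExcludedVolume((0.0, 0.0, 0.0), 1.0),),
    )
    res = match_conformer(fs, conf, blocked)
    assert res.clash and not res.hit
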