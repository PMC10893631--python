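import numpy as np
import pytest

from oracle_utils import superpose_rmsd
from ph4screen.errors import AlignmentError, InvariantError
from ph4screen.featperc import ConformerRecord, perceive_features
from ph4screen.geometry import apply_rigid, random_rotation
from ph4screen.ph4core import Feature, FeatureKind
from ph4screen.rbuilder import (
    ComplexRecord,
    Hypothesis,
    HypothesisSpec,
    InteractionCriteria,
    InteractionKind,
    InteractionRecord,
    ProteinAtom,
    align_complexes,
    cluster_common_features,
    detect_interactions,
    enumerate_hypotheses,
    place_excluded_volumes,
    transform_complex,
)
from ph4screen.synthdata import ToyComplexSpec, make_toy_complex


def _random_complex(seed=0, n_res=100):
    """A synthetic protein backbone (CA only) with a tiny ethanol-like ligand."""
    rng = np.random.default_rng(seed)
    prot = tuple(
        ProteinAtom("A", i + 1, "GLY", "CA", "C", tuple(rng.uniform(-20, 20, 3)))
        for i in range(n_res)
    )
    lig = ConformerRecord(
        "lig",
        0,
        (("C", (0.0, 0.0, 0.0), 0), ("C", (1.5, 0.0, 0.0), 0), ("O", (2.2, 1.2, 0.0), 0)),
        ((0, 1, 1), (1, 2, 1)),
    )
    return ComplexRecord(f"cx{seed}", prot, lig, tuple(range(n_res)))


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


def test_align_recovers_rigid_copy_exactly():
    ref = _random_complex(0)
    rng = np.random.default_rng(7)
    moved = transform_complex(ref, random_rotation(rng), rng.uniform(-15, 15, 3))
    moved = ComplexRecord("copy", moved.protein_atoms, moved.ligand, moved.alpha_carbons)
    aligned = align_complexes([ref, moved], reference="cx0")
    ca_ref = ref.protein_coords()[list(ref.alpha_carbons)]
    ca_new = aligned[1].protein_coords()[list(aligned[1].alpha_carbons)]
    rmsd = np.sqrt(np.mean(np.sum((ca_ref - ca_new) ** 2, axis=1)))
    assert rmsd < 1e-6
    # the ligand was carried along by the same motion
    assert np.abs(aligned[1].ligand.coords - ref.ligand.coords).max() < 1e-6


def test_align_transform_matches_kabsch_oracle():
    ref = _random_complex(1)
    rng = np.random.default_rng(8)
    moved = transform_complex(ref, random_rotation(rng), rng.uniform(-15, 15, 3))
    moved = ComplexRecord("copy", moved.protein_atoms, moved.ligand, moved.alpha_carbons)
    noisy = ComplexRecord(
        "noisy",
        tuple(
            a if a.atom_name != "CA" else
            ProteinAtom(a.chain_id, a.res_number, a.res_name, a.atom_name, a.element,
                        tuple(np.asarray(a.center) + np.random.default_rng(a.res_number).normal(0, 0.3, 3)))
            for a in moved.protein_atoms
        ),
        moved.ligand,
        moved.alpha_carbons,
    )
    aligned = align_complexes([ref, noisy], reference="cx1")
    P = noisy.protein_coords()[list(noisy.alpha_carbons)]
    Q = ref.protein_coords()[list(ref.alpha_carbons)]
    achieved = np.sqrt(
        np.mean(
            np.sum(
                (aligned[1].protein_coords()[list(aligned[1].alpha_carbons)] - Q) ** 2, axis=1
            )
        )
    )
    assert achieved == pytest.approx(superpose_rmsd(P, Q), abs=1e-9)


def test_align_rejects_two_pairs():
    a, b = _random_complex(0), _random_complex(2)
    b = ComplexRecord("b", b.protein_atoms, b.ligand, b.alpha_carbons)
    pairs = [("A:GLY1", "A:GLY1"), ("A:GLY2", "A:GLY2")]
    with pytest.raises(AlignmentError):
        align_complexes([a, b], "cx0", {"b": pairs})


def test_align_rejects_collinear_alpha_carbons():
    prot = tuple(
        ProteinAtom("A", i + 1, "GLY", "CA", "C", (float(i), 0.0, 0.0)) for i in range(5)
    )
    lig = ConformerRecord("lig", 0, (("C", (0.0, 0.0, 0.0), 0),), ())
    line = ComplexRecord("line", prot, lig, tuple(range(5)))
    ref = ComplexRecord("ref", prot, lig, tuple(range(5)))
    with pytest.raises(AlignmentError):
        align_complexes([ref, line], "ref")


def test_align_is_idempotent():
    ref = _random_complex(0)
    rng = np.random.default_rng(9)
    moved = transform_complex(ref, random_rotation(rng), rng.uniform(-15, 15, 3))
    moved = ComplexRecord("copy", moved.protein_atoms, moved.ligand, moved.alpha_carbons)
    once = align_complexes([ref, moved], "cx0")
    twice = align_complexes(once, "cx0")
    for c1, c2 in zip(once, twice):
        assert np.abs(c1.protein_coords() - c2.protein_coords()).max() < 1e-9


# ---------------------------------------------------------------------------
# Interaction detection
# ---------------------------------------------------------------------------


def _donor_complex(n_o_dist: float, angle: float):
    """Ligand N-H donor aimed at a single protein oxygen, exact geometry."""
    from ph4screen.synthdata import _acceptor_position

    D = np.zeros(3)
    H = np.array([1.01, 0.0, 0.0])
    A = _acceptor_position(D, H, n_o_dist, angle)
    lig = ConformerRecord(
        "lig",
        0,
        (("N", tuple(D), 0), ("H", tuple(H), 0), ("C", (-1.4, 0.3, 0.0), 0)),
        ((0, 1, 1), (0, 2, 1)),
    )
    prot = (
        ProteinAtom("A", 50, "SER", "O", "O", tuple(A)),
        ProteinAtom("A", 1, "GLY", "CA", "C", (-15.0, 0.0, 0.0)),
        ProteinAtom("A", 2, "GLY", "CA", "C", (-15.0, 5.0, 0.0)),
        ProteinAtom("A", 3, "GLY", "CA", "C", (-12.0, 0.0, 5.0)),
    )
    return ComplexRecord("hb", prot, lig, (1, 2, 3))


@pytest.mark.parametrize(
    "dist, angle, expected",
    [
        (2.9, 160.0, 1),  # inside both cutoffs
        (4.0, 160.0, 0),  # beyond the distance cutoff
        (2.9, 90.0, 0),  # below the angular cutoff
    ],
)
def test_hbond_detection_rules(dist, angle, expected):
    cx = _donor_complex(dist, angle)
    fs = perceive_features(cx.ligand)
    ints = [
        i
        for i in detect_interactions(cx, fs)
        if i.kind == InteractionKind.HBOND_LIG_DON
    ]
    assert len(ints) == expected
    if expected:
        assert ints[0].distance == pytest.approx(dist, abs=1e-9)
        assert ints[0].angle == pytest.approx(angle, abs=1e-6)
        assert ints[0].partner_atom == "O"


def test_detection_invariant_under_joint_rigid_motion():
    cx = _donor_complex(2.9, 160.0)
    rng = np.random.default_rng(4)
    moved = transform_complex(cx, random_rotation(rng), rng.uniform(-10, 10, 3))
    a = detect_interactions(cx, perceive_features(cx.ligand))
    b = detect_interactions(moved, perceive_features(moved.ligand))
    assert len(a) == len(b) == 1
    assert a[0].distance == pytest.approx(b[0].distance, abs=1e-9)
    assert a[0].angle == pytest.approx(b[0].angle, abs=1e-6)


def test_toy_complex_produces_requested_interactions():
    cx = make_toy_complex(ToyComplexSpec(n_hbonds=2, n_hydrophobes=1, seed=5))
    ints = detect_interactions(cx, perceive_features(cx.ligand))
    kinds = sorted(i.kind.value for i in ints)
    assert kinds == ["HBOND_LIG_DON", "HBOND_LIG_DON", "HYDROPHOBIC"]


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def _acc(cx_id, point):
    return [
        InteractionRecord(
            cx_id, InteractionKind.HBOND_LIG_ACC, tuple(point), "A:SER50", "O", 2.9, 160.0
        )
    ]


def test_cluster_close_points_merge_at_midpoint():
    per = [_acc("a", (0.0, 0.0, 0.0)), _acc("b", (0.5, 0.0, 0.0))]
    pool = cluster_common_features(per, tolerance=1.5, min_support=2)
    assert len(pool) == 1
    assert pool[0].kind == FeatureKind.ACC
    assert np.allclose(pool[0].center, (0.25, 0.0, 0.0))


def test_cluster_far_points_have_no_common_feature():
    per = [_acc("a", (0.0, 0.0, 0.0)), _acc("b", (3.0, 0.0, 0.0))]
    assert cluster_common_features(per, tolerance=1.5, min_support=2) == []


def test_cluster_min_support_one_passes_everything_through():
    per = [_acc("a", (0.0, 0.0, 0.0)), _acc("b", (3.0, 0.0, 0.0))]
    pool = cluster_common_features(per, tolerance=1.5, min_support=1)
    assert len(pool) == 2


def test_cluster_output_independent_of_complex_order():
    per = [_acc("a", (0.0, 0.0, 0.0)), _acc("b", (0.5, 0.0, 0.0)), _acc("c", (9.0, 0.0, 0.0))]
    fwd = cluster_common_features(per, tolerance=1.5, min_support=1)
    rev = cluster_common_features(list(reversed(per)), tolerance=1.5, min_support=1)
    assert fwd == rev


def test_cluster_rejects_nonpositive_tolerance():
    with pytest.raises(InvariantError):
        cluster_common_features([], tolerance=0.0)


# ---------------------------------------------------------------------------
# Excluded volumes
# ---------------------------------------------------------------------------


def _shell_complex(n_near: int, seed=0):
    """Ligand carbon at origin with ``n_near`` protein atoms on a 4 A shell."""
    rng = np.random.default_rng(seed)
    atoms = []
    for i in range(n_near):
        v = rng.normal(size=3)
        v = 4.0 * v / np.linalg.norm(v)
        atoms.append(ProteinAtom("A", i + 10, "LEU", f"C{i}", "C", tuple(v)))
    atoms.append(ProteinAtom("A", 1, "GLY", "CA", "C", (50.0, 0.0, 0.0)))
    lig = ConformerRecord("lig", 0, (("C", (0.0, 0.0, 0.0), 0),), ())
    return ComplexRecord("sh", tuple(atoms), lig, (len(atoms) - 1,))


def test_no_protein_atom_in_shell_gives_no_volumes():
    cx = _shell_complex(0)
    assert place_excluded_volumes([cx], [], shell=5.0) == []


def test_forty_candidates_capped_at_thirty():
    cx = _shell_complex(40)
    vols = place_excluded_volumes([cx], [], shell=5.0, max_count=30)
    assert len(vols) == 30


def test_candidate_at_feature_center_is_always_discarded():
    cx = _shell_complex(10, seed=1)
    # plant a feature exactly on one candidate atom
    target = cx.protein_atoms[0].center
    pool = [Feature("F1", FeatureKind.ACC, target, 1.0)]
    vols = place_excluded_volumes([cx], pool, shell=5.0, keepout=2.0, max_count=30)
    assert all(np.linalg.norm(np.asarray(v.center) - np.asarray(target)) > 2.0 for v in vols)


def test_volume_placement_is_deterministic():
    cx = _shell_complex(25, seed=2)
    v1 = place_excluded_volumes([cx], [], max_count=10)
    v2 = place_excluded_volumes([cx], [], max_count=10)
    assert v1 == v2


# ---------------------------------------------------------------------------
# Hypothesis enumeration
# ---------------------------------------------------------------------------


def _pool():
    return [
        Feature("F1", FeatureKind.ACC, (0.0, 0.0, 0.0), 1.0),
        Feature("F2", FeatureKind.DON, (5.0, 0.0, 0.0), 1.0),
        Feature("F3", FeatureKind.HYD, (0.0, 5.0, 0.0), 1.0),
    ]


def test_seventeen_named_combinations_give_seventeen_models():
    combos = tuple(
        Hypothesis(f"Ph4-{i + 1}", ("F1", "F2", "F3")[: 2 + i % 2]) for i in range(17)
    )
    models = enumerate_hypotheses(_pool(), HypothesisSpec(combos), [])
    assert len(models) == 17
    assert [m.name for m in models] == [f"Ph4-{i + 1}" for i in range(17)]


def test_powerset_toggle_spec_gives_two_to_the_k():
    import itertools

    pool = _pool()
    combos = []
    for r in range(1, 4):
        for subset in itertools.combinations([f.id for f in pool], r):
            combos.append(Hypothesis("+".join(subset), subset))
    models = enumerate_hypotheses(pool, HypothesisSpec(tuple(combos)), [])
    assert len(models) == 2 ** 3 - 1  # nonempty subsets (a model needs a feature)


def test_empty_spec_gives_no_models():
    assert enumerate_hypotheses(_pool(), HypothesisSpec(()), []) == []


def test_dangling_feature_reference_raises():
    with pytest.raises(InvariantError):
        enumerate_hypotheses(_pool(), HypothesisSpec((Hypothesis("x", ("NOPE",)),)), [])


def test_radius_override_applies():
    spec = HypothesisSpec((Hypothesis("m", ("F1", "F2"), {"F1": 2.5}),))
    (model,) = enumerate_hypotheses(_pool(), spec, [])
    assert model.feature("F1").radius == 2.5
    assert model.feature("F2").radius == 1.0
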