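import numpy as np
import pytest

from pdzscreen import (
    DetectedFeature,
    FeatureKind,
    MatchError,
    PharmacophoreModel,
    Query,
    fitness_score,
    kabsch_superpose,
    match_pose,
)

from conftest import brute_force_match, random_instance, random_rotation


def features_at_queries(model, skip=(), kind_override=None):
    feats = []
    for q in model.queries:
        if q.id in skip:
            continue
        kind = kind_override.get(q.id, q.kind) if kind_override else q.kind
        feats.append(DetectedFeature(kind, q.position.copy(), [0]))
    return feats


class TestKabsch:
    def test_identity_on_equal_sets(self):
        rng = np.random.default_rng(0)
        P = rng.normal(size=(5, 3))
        R, t, rmsd = kabsch_superpose(P, P)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(R, np.eye(3), atol=1e-9)
        assert np.allclose(t, 0.0, atol=1e-9)

    def test_exact_recovery_of_rigid_relation(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [0, 2, 0], [0.5, 0.5, 1.5]])
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        Q = P @ Rz.T + np.array([1.0, 2.0, 3.0])
        R, t, rmsd = kabsch_superpose(P, Q)
        assert rmsd <= 1e-9
        assert np.allclose(R, Rz, atol=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_one_dimensional_closed_form(self):
        # segments of length 2 and 4: optimal translation centres both,
        # leaving residuals of +-1 at the endpoints -> RMSD exactly 1
        P = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        Q = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        _, _, rmsd = kabsch_superpose(P, Q)
        assert rmsd == pytest.approx(1.0, abs=1e-9)

    def test_rotation_always_proper(self):
        # a reflection-prone configuration must still yield det +1
        P = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
        Q = np.array([[-1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
        R, _, _ = kabsch_superpose(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_errors(self):
        with pytest.raises(MatchError):
            kabsch_superpose(np.zeros((0, 3)), np.zeros((0, 3)))
        with pytest.raises(MatchError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((3, 3)))


class TestMatchPose:
    def test_perfect_pose_matches_all_queries(self, dvl1_model):
        result = match_pose(features_at_queries(dvl1_model), dvl1_model)
        assert result.n_matched == 7
        assert result.rmsd_matched == pytest.approx(0.0, abs=1e-12)
        assert result.fitness == pytest.approx(7.0)
        assert result.accepted

    def test_missing_required_feature_rejects_despite_high_count(self, dvl1_model):
        feats = features_at_queries(dvl1_model, skip={"hyd_subpocket"})
        result = match_pose(feats, dvl1_model)
        assert result.n_matched == 6
        assert not result.accepted

    def test_tolerance_boundary_polar_vs_hydrophobic(self, dvl1_model):
        """A 2.2 Å offset overruns a donor query (2.0 Å) but not a
        hydrophobic one (2.5 Å)."""
        donor_q = next(q for q in dvl1_model.queries if q.kind is FeatureKind.DONOR)
        hyd_q = next(q for q in dvl1_model.queries if q.id == "hyd_subpocket")
        offset = np.array([0.0, 0.0, 2.2])
        donor_feat = [DetectedFeature(FeatureKind.DONOR, donor_q.position + offset, [0])]
        r = match_pose(donor_feat, dvl1_model)
        assert r.n_matched == 0
        hyd_feat = [DetectedFeature(FeatureKind.HYDROPHOBIC, hyd_q.position + offset, [0])]
        r = match_pose(hyd_feat, dvl1_model)
        assert r.n_matched == 1
        assert "hyd_subpocket" in r.assignment

    def test_aromatic_hydrophobic_interchangeable_polar_not(self, dvl1_model):
        # swap aromatic <-> hydrophobic kinds on the apolar queries: still 7
        override = {}
        for q in dvl1_model.queries:
            if q.kind is FeatureKind.AROMATIC:
                override[q.id] = FeatureKind.HYDROPHOBIC
            elif q.kind is FeatureKind.HYDROPHOBIC:
                override[q.id] = FeatureKind.AROMATIC
        feats = features_at_queries(dvl1_model, kind_override=override)
        assert match_pose(feats, dvl1_model).n_matched == 7
        # a donor feature on the acceptor query never matches it
        acc_q = next(q for q in dvl1_model.queries if q.kind is FeatureKind.ACCEPTOR)
        feats = [DetectedFeature(FeatureKind.DONOR, acc_q.position.copy(), [0])]
        assert match_pose(feats, dvl1_model).n_matched == 0

    def test_assignment_is_injective_and_within_tolerance(self, dvl1_model):
        rng = np.random.default_rng(5)
        feats = [
            DetectedFeature(q.kind, q.position + rng.normal(0, 0.8, 3), [0])
            for q in dvl1_model.queries
        ] + [
            DetectedFeature(FeatureKind.AROMATIC, rng.uniform(-4, 8, 3), [0])
            for _ in range(3)
        ]
        result = match_pose(feats, dvl1_model)
        assert len(set(result.assignment.values())) == len(result.assignment)
        tol = {q.id: q.tolerance for q in dvl1_model.queries}
        pos = {q.id: q.position for q in dvl1_model.queries}
        for qid, fi in result.assignment.items():
            assert np.linalg.norm(feats[fi].centroid - pos[qid]) <= tol[qid] + 1e-12

    def test_empty_model_rejected(self):
        with pytest.raises(MatchError):
            match_pose([], None)

    def test_no_features_yields_empty_rejected_result(self, dvl1_model):
        result = match_pose([], dvl1_model)
        assert result.n_matched == 0
        assert not result.accepted
        assert result.fitness == 0.0


class TestOracleEquivalence:
    @pytest.mark.parametrize("batch", range(5))
    def test_matches_exhaustive_enumeration(self, batch):
        """The assignment matcher reproduces brute-force enumeration of all
        injective kind-compatible assignments on random small instances."""
        for k in range(100):
            features, model = random_instance(seed=20_000 + batch * 100 + k)
            result = match_pose(features, model)
            n_expected, accepted_expected = brute_force_match(features, model)
            assert result.n_matched == n_expected
            assert result.accepted == accepted_expected


class TestFitness:
    def test_perfect_seven_feature_match_scores_seven(self, dvl1_model):
        result = match_pose(features_at_queries(dvl1_model), dvl1_model)
        assert fitness_score(result, dvl1_model) == pytest.approx(7.0)

    def test_five_matches_at_half_tolerance_scores_four_and_a_half(self):
        queries = tuple(
            Query(f"q{i}", FeatureKind.AROMATIC, np.array([8.0 * i, 0, 0]), 2.5)
            for i in range(5)
        )
        model = PharmacophoreModel("five", queries, min_match=5)
        feats = [
            DetectedFeature(FeatureKind.AROMATIC,
                            q.position + np.array([0, 1.25, 0]), [0])
            for q in model.queries
        ]
        result = match_pose(feats, model)
        assert result.n_matched == 5
        assert result.fitness == pytest.approx(4.5)
        assert fitness_score(result, model) == pytest.approx(4.5)

    def test_match_count_dominates_residuals(self, dvl1_model):
        """Any 6-match outscores any 5-match: worst 6-match fitness > 5."""
        rng = np.random.default_rng(9)
        six = [
            DetectedFeature(q.kind, q.position + _offset(rng, q.tolerance * 0.999), [0])
            for q in dvl1_model.queries[:6]
        ]
        five = [
            DetectedFeature(q.kind, q.position.copy(), [0])
            for q in dvl1_model.queries[:5]
        ]
        r6 = match_pose(six, dvl1_model)
        r5 = match_pose(five, dvl1_model)
        assert r6.n_matched == 6 and r5.n_matched == 5
        assert r6.fitness > r5.fitness
        assert 5.0 < r6.fitness <= 6.0


def _offset(rng, radius):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v) * radius


class TestAlignMode:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_fitness_invariant_under_rigid_transform(self, dvl1_model, seed):
        rng = np.random.default_rng(seed)
        feats = [
            DetectedFeature(q.kind, q.position + rng.normal(0, 0.3, 3), [0])
            for q in dvl1_model.queries
        ]
        base = match_pose(feats, dvl1_model, mode="align")
        R = random_rotation(rng)
        t = rng.normal(0, 25, 3)
        moved = [
            DetectedFeature(f.kind, R @ f.centroid + t, f.atom_indices)
            for f in feats
        ]
        res = match_pose(moved, dvl1_model, mode="align")
        assert res.fitness == pytest.approx(base.fitness, abs=1e-6)
        assert res.n_matched == base.n_matched
        # pre-aligned matching, by contrast, is frame-dependent
        assert match_pose(moved, dvl1_model, mode="prealigned").n_matched == 0

    def test_align_recovers_perfect_pose_from_any_frame(self, dvl1_model):
        rng = np.random.default_rng(17)
        R = random_rotation(rng)
        t = rng.normal(0, 30, 3)
        feats = [
            DetectedFeature(q.kind, R @ q.position + t, [0])
            for q in dvl1_model.queries
        ]
        result = match_pose(feats, dvl1_model, mode="align")
        assert result.n_matched == 7
        assert result.rmsd_matched <= 1e-6
        assert result.accepted


class TestMonotonicity:
    @pytest.mark.parametrize("seed", [3, 4, 5, 6])
    def test_enlarging_tolerances_never_decreases_matches(self, seed):
        features, model = random_instance(seed=seed)
        base = match_pose(features, model).n_matched
        for scale in (1.5, 2.0, 4.0):
            grown = PharmacophoreModel(
                model.name,
                tuple(
                    Query(q.id, q.kind, q.position, q.tolerance * scale, q.required)
                    for q in model.queries
                ),
                min_match=model.min_match,
            )
            assert match_pose(features, grown).n_matched >= base

    @pytest.mark.parametrize("seed", [7, 8, 9])
    def test_acceptance_monotone_in_min_match_threshold(self, seed, dvl1_model):
        rng = np.random.default_rng(seed)
        feats = [
            DetectedFeature(q.kind, q.position + rng.normal(0, 1.2, 3), [0])
            for q in dvl1_model.queries
        ]
        for lower, higher in [(4, 5), (5, 6), (6, 7)]:
            strict = PharmacophoreModel(
                "strict", dvl1_model.queries, min_match=higher
            )
            lax = PharmacophoreModel("lax", dvl1_model.queries, min_match=lower)
            if match_pose(feats, strict).accepted:
                assert match_pose(feats, lax).accepted
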