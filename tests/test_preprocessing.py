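import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphpro import (
    CaTrace,
    RigidTransform,
    alignment_score,
    global_align,
    kabsch_superpose,
    preprocess_pair,
    restrict_to_aligned,
    rmsd,
)
from morphpro.synthetic import ChainSpec, make_morph_pair


def _random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestGlobalAlign:
    def test_identical_sequences_align_without_gaps(self):
        assert global_align("ACD", "ACD") == [(0, 0), (1, 1), (2, 2)]

    def test_deletion_gaps_the_unmatched_residue(self):
        # All five possible global alignments of ACD vs AD score worse than
        # gapping the C (A:A + D:D = 10 with one gap opening).
        columns = global_align("ACD", "AD")
        assert (1, None) in columns
        assert (0, 0) in columns and (2, 1) in columns

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACD")

    def test_score_is_symmetric(self):
        rng = np.random.default_rng(5)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(10):
            a = "".join(rng.choice(aa, size=rng.integers(5, 20)))
            b = "".join(rng.choice(aa, size=rng.integers(5, 20)))
            assert alignment_score(a, b) == pytest.approx(alignment_score(b, a))


class TestRestrictToAligned:
    def test_identity_alignment_has_no_breaks(self, valid_chain):
        alignment = [(i, i) for i in range(valid_chain.n)]
        pair = restrict_to_aligned(valid_chain, valid_chain, alignment)
        assert pair.n == valid_chain.n
        assert not pair.broken_edge.any()
        assert pair.broken_angle[0] and pair.broken_angle[-1]
        assert not pair.broken_angle[1:-1].any()

    def test_alignment_skip_marks_broken_edge(self, valid_chain):
        alignment = [(i, i) for i in range(valid_chain.n) if i != 5]
        pair = restrict_to_aligned(valid_chain, valid_chain, alignment)
        expected = np.zeros(valid_chain.n - 2, bool)
        expected[4] = True  # between restricted positions 4 and 5
        np.testing.assert_array_equal(pair.broken_edge, expected)
        assert pair.broken_angle[4] and pair.broken_angle[5]

    def test_residue_number_gap_marks_broken_edge(self):
        coords = np.array([[0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0], [0, 3.8, 0]], float)
        ids = [("A", 1, ""), ("A", 2, ""), ("A", 10, ""), ("A", 11, "")]
        trace = CaTrace(coords, ids, "ACDE")
        pair = restrict_to_aligned(trace, trace, [(i, i) for i in range(4)])
        assert pair.broken_edge.tolist() == [False, True, False]

    def test_too_few_matches_rejected(self, valid_chain):
        with pytest.raises(ValueError, match="aligned columns"):
            restrict_to_aligned(valid_chain, valid_chain, [(0, 0)])


class TestKabsch:
    def test_identical_point_sets(self):
        pts = np.random.default_rng(1).normal(size=(8, 3))
        transform, fit = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(transform.translation, 0.0, atol=1e-9)
        assert fit == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_rigid_transform(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(12, 3)) * 5
        rot90 = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], float)
        known = RigidTransform(rot90, np.array([4.0, -2.0, 7.0]))
        transform, fit = kabsch_superpose(known.apply(pts), pts)
        assert fit == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(transform.rotation @ known.rotation, np.eye(3), atol=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))

    @given(seed=st.integers(0, 10 ** 6))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_superposition_never_increases_rmsd(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(10, 3)) * 4
        b = rng.normal(size=(10, 3)) * 4
        _, fit = kabsch_superpose(a, b)
        assert fit <= rmsd(a, b) + 1e-12

    @given(seed=st.integers(0, 10 ** 6))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_invariant_to_rigid_pretransform(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(10, 3)) * 4
        b = rng.normal(size=(10, 3)) * 4
        _, fit = kabsch_superpose(a, b)
        pre = RigidTransform(_random_rotation(rng), rng.normal(size=3) * 10)
        _, fit_pre = kabsch_superpose(pre.apply(a), b)
        assert fit_pre == pytest.approx(fit, abs=1e-9)


class TestRmsd:
    def test_identical_is_zero(self, valid_chain):
        assert rmsd(valid_chain.coords, valid_chain.coords) == 0.0

    def test_uniform_offset(self):
        a = np.zeros((2, 3))
        b = a + np.array([1.0, 0.0, 0.0])
        assert rmsd(a, b) == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(10, 3)), rng.normal(size=(10, 3))
        expected = np.sqrt(sum(np.sum((p - q) ** 2) for p, q in zip(a, b)) / 10)
        assert rmsd(a, b) == pytest.approx(expected, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


class TestPreprocessPair:
    def test_full_pipeline_superposes_end_onto_start(self):
        start, end = make_morph_pair(ChainSpec(n=20, seed=5), hinge_angle_deg=15)
        pair, transform, fit = preprocess_pair(start, end)
        assert pair.n == 20
        # superposition can only reduce the coordinate RMSD
        assert fit <= rmsd(start.coords, end.coords) + 1e-12
        assert fit == pytest.approx(rmsd(pair.start.coords, pair.end.coords), abs=1e-12)
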