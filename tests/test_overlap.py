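"""Pairwise overlap values and displacement estimates."""

import numpy as np
import pytest

import specklekin as sk
from specklekin.overlap import (
    displacement_estimate,
    overlap_value,
    pairwise_overlaps,
    records_to_table,
)
from specklekin.preprocess import separate

from conftest import truth_displacements


def _gauss(shape, sigma, centre):
    yy = (np.arange(shape[0])[:, None] - centre[0]) ** 2
    xx = (np.arange(shape[1])[None, :] - centre[1]) ** 2
    return np.exp(-(yy + xx) / (2 * sigma**2))


class TestOverlapValue:
    def test_self_overlap_is_positive_sum_of_squares(self):
        rng = np.random.default_rng(0)
        s = 1.0 + 0.1 * rng.standard_normal((32, 32))
        mask = np.ones_like(s, dtype=bool)
        v = overlap_value(s, s, mask)
        sc = s[mask] - s[mask].mean()
        assert v == pytest.approx(np.sum(sc**2))
        assert v > 0

    def test_symmetry_exact(self):
        rng = np.random.default_rng(1)
        a = rng.random((16, 16))
        b = rng.random((16, 16))
        mask = rng.random((16, 16)) > 0.2
        assert overlap_value(a, b, mask) == overlap_value(b, a, mask)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            overlap_value(np.ones((4, 4)), np.ones((5, 5)), np.ones((4, 4), bool))
        with pytest.raises(ValueError):
            overlap_value(np.ones((4, 4)), np.ones((4, 4)), np.zeros((4, 4), bool))

    def test_disjoint_sources_give_null_overlap(self):
        """Speckles of non-overlapping source sets pass a permutation null."""
        med = sk.make_medium(5, (128, 128), 4, 10, 0.5, 1)
        obj = sk.ObjectMask(np.ones((8, 8)))
        f1 = sk.render_frame(med, obj, offset=(-10, -10))
        f2 = sk.render_frame(med, obj, offset=(10, 10))
        cutoff = sk.default_cutoff(128, 10)
        _, s1 = separate(f1, cutoff)
        _, s2 = separate(f2, cutoff)
        mask = s1.valid & s2.valid
        v = overlap_value(s1.values, s2.values, mask)
        rng = np.random.default_rng(0)
        b = s2.values[mask]
        null = [
            overlap_value(s1.values[mask], rng.permutation(b), np.ones(b.shape, bool))
            for _ in range(200)
        ]
        assert abs(v) < 3 * np.std(null) + abs(np.mean(null))

    @pytest.mark.parametrize("shared", [0.25, 0.5, 0.75])
    def test_overlap_tracks_shared_source_fraction(self, shared):
        """C_ij / C_ii approximates the shared-source fraction."""
        h = 16  # bar of 16 rows x 8 cols; shift rows to control the overlap
        obj = sk.ObjectMask(np.ones((h, 8)))
        shift = int(round(h * (1 - shared)))
        ratios = []
        for seed in (0, 1, 2):
            med = sk.make_medium(seed, (128, 128), 4, 10, 0.5, 1)
            f1 = sk.render_frame(med, obj, offset=(0, 0))
            f2 = sk.render_frame(med, obj, offset=(shift, 0))
            recs = pairwise_overlaps(
                sk.SpeckleStack(np.stack([f1, f2])), sk.default_cutoff(128, 10)
            )
            by = {(r.i, r.j): r.overlap_value for r in recs}
            ratios.append(by[(0, 1)] / np.sqrt(by[(0, 0)] * by[(1, 1)]))
        assert np.mean(ratios) == pytest.approx(shared, abs=0.1 * shared + 0.03)


class TestDisplacementEstimate:
    def test_identical_envelopes_give_zero(self):
        e = 1.0 + _gauss((64, 64), 8, (30, 34))
        d, q = displacement_estimate(e, e)
        assert d == (0, 0)
        assert q > 0.3

    def test_integer_shift_recovered_exactly(self):
        e1 = 1.0 + _gauss((64, 64), 8, (28, 30))
        e2 = 1.0 + _gauss((64, 64), 8, (31, 35))  # shifted by (3, 5)
        d, _ = displacement_estimate(e1, e2)
        assert d == (3, 5)

    def test_antisymmetry(self):
        e1 = 1.0 + _gauss((64, 64), 8, (28, 30))
        e2 = 1.0 + _gauss((64, 64), 8, (35, 26))
        d12, _ = displacement_estimate(e1, e2)
        d21, _ = displacement_estimate(e2, e1)
        assert d12 == (-d21[0], -d21[1])

    def test_flat_envelope_rejected(self):
        with pytest.raises(ValueError):
            displacement_estimate(np.ones((32, 32)), np.ones((32, 32)))


class TestPairwiseOverlaps:
    def test_two_frames_give_four_records(self, small_medium):
        obj = sk.ObjectMask(np.ones((6, 6)))
        f = [sk.render_frame(small_medium, obj, offset=o) for o in [(0, 0), (2, 1)]]
        recs = pairwise_overlaps(sk.SpeckleStack(np.stack(f)), 8)
        assert len(recs) == 4
        selfs = {(r.i, r.j) for r in recs if r.i == r.j}
        assert selfs == {(0, 0), (1, 1)}
        for r in recs:
            if r.i == r.j:
                assert r.displacement == (0, 0)

    def test_order_invariance(self, small_medium):
        """Shuffled frame order yields the same records up to relabeling."""
        obj = sk.ObjectMask(np.ones((6, 6)))
        traj = [(0, 0), (3, 0), (0, 4), (-2, -2)]
        stack = sk.render_sequence(small_medium, obj, None, traj)
        perm = [2, 0, 3, 1]
        shuffled = sk.SpeckleStack(stack.frames[perm])
        r1 = pairwise_overlaps(stack, 8)
        r2 = pairwise_overlaps(shuffled, 8)
        key = lambda recs: sorted(
            (round(r.overlap_value, 6), r.displacement) for r in recs
        )
        assert key(r1) == key(r2)

    def test_displacements_match_simulation_metadata(self, small_medium):
        obj = sk.ObjectMask(np.ones((6, 6)))
        traj = [(0, 0), (3, 0), (3, 3), (0, 3)]
        stack = sk.render_sequence(small_medium, obj, None, traj)
        recs = pairwise_overlaps(stack, 8)
        truth = truth_displacements(stack)
        assert all(r.displacement == truth[(r.i, r.j)] for r in recs)

    def test_max_pairs_subsampling_deterministic(self, small_medium):
        obj = sk.ObjectMask(np.ones((6, 6)))
        traj = [(0, 0), (2, 0), (0, 2), (2, 2)]
        stack = sk.render_sequence(small_medium, obj, None, traj)
        a = pairwise_overlaps(stack, 8, max_pairs=3, subsample_seed=5)
        b = pairwise_overlaps(stack, 8, max_pairs=3, subsample_seed=5)
        assert [(r.i, r.j) for r in a] == [(r.i, r.j) for r in b]
        assert len(a) == 4 + 2 * 3  # self records + both orders of 3 pairs

    def test_single_frame_rejected(self, small_medium):
        obj = sk.ObjectMask(np.ones((6, 6)))
        f = sk.render_frame(small_medium, obj)
        with pytest.raises(ValueError):
            pairwise_overlaps(sk.SpeckleStack(f[None]), 8)

    def test_table_serialization(self, small_medium):
        obj = sk.ObjectMask(np.ones((6, 6)))
        stack = sk.render_sequence(small_medium, obj, None, [(0, 0), (1, 1)])
        recs = pairwise_overlaps(stack, 8)
        df = records_to_table(recs)
        assert list(df.columns) == ["i", "j", "dy", "dx", "value", "quality"]
        assert len(df) == len(recs)
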