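"""Dice, pixel accuracy and centroid-based detection vs brute-force oracles."""

import numpy as np
import pytest

from fiberseg.evaluation import (DetectionCounts, detect_axons, dice,
                                 evaluate, pixel_accuracy)


# ---------------------------------------------------------------- oracles --

def brute_force_dice(a, b):
    inter = n_a = n_b = 0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            n_a += bool(a[i, j])
            n_b += bool(b[i, j])
            inter += bool(a[i, j]) and bool(b[i, j])
    return 1.0 if n_a + n_b == 0 else 2 * inter / (n_a + n_b)


def brute_force_accuracy(p, t):
    same = 0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            same += p[i, j] == t[i, j]
    return same / p.size


def brute_force_detection(pred, truth):
    """Flood-fill components, centroid containment matching."""
    def components(mask):
        seen = np.zeros_like(mask, dtype=bool)
        comps = []
        for i in range(mask.shape[0]):
            for j in range(mask.shape[1]):
                if mask[i, j] and not seen[i, j]:
                    stack, px = [(i, j)], []
                    seen[i, j] = True
                    while stack:
                        r, c = stack.pop()
                        px.append((r, c))
                        for dr in (-1, 0, 1):
                            for dc in (-1, 0, 1):
                                rr, cc = r + dr, c + dc
                                if (0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]
                                        and mask[rr, cc] and not seen[rr, cc]):
                                    seen[rr, cc] = True
                                    stack.append((rr, cc))
                    comps.append(px)
        return comps

    truth_comps = components(truth == 2)
    owner = -np.ones(truth.shape, dtype=int)
    for idx, px in enumerate(truth_comps):
        for r, c in px:
            owner[r, c] = idx
    hits = [0] * len(truth_comps)
    fp = 0
    for px in components(pred == 2):
        r = int(round(sum(p[0] for p in px) / len(px)))
        c = int(round(sum(p[1] for p in px) / len(px)))
        o = owner[min(r, truth.shape[0] - 1), min(c, truth.shape[1] - 1)]
        if o < 0:
            fp += 1
        else:
            hits[o] += 1
    tp = sum(h > 0 for h in hits)
    fp += sum(h - 1 for h in hits if h > 1)
    return tp, fp, len(truth_comps) - tp


# ------------------------------------------------------------------ tests --

class TestDice:
    def test_identical_nonempty(self, rng):
        a = rng.random((8, 8)) > 0.5
        assert dice(a, a) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = b[3, 3] = True
        assert dice(a, b) == 0.0

    def test_block_worked_example(self):
        # 2x2 block inside a 2x4 block: 2*4/(4+8) = 2/3
        a = np.zeros((6, 6), bool)
        b = np.zeros((6, 6), bool)
        a[2:4, 2:4] = True
        b[2:4, 1:5] = True
        assert dice(a, b) == pytest.approx(2 / 3)

    def test_both_empty_is_one(self):
        assert dice(np.zeros((3, 3)), np.zeros((3, 3))) == 1.0

    def test_symmetric_and_permutation_invariant(self, rng):
        a = rng.random((10, 10)) > 0.6
        b = rng.random((10, 10)) > 0.6
        assert dice(a, b) == dice(b, a)
        perm = rng.permutation(100)
        ap = a.ravel()[perm].reshape(10, 10)
        bp = b.ravel()[perm].reshape(10, 10)
        assert dice(ap, bp) == pytest.approx(dice(a, b))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice(np.zeros((3, 3)), np.zeros((4, 4)))


class TestPixelAccuracy:
    def test_identical(self, rng):
        m = rng.integers(0, 3, size=(5, 5))
        assert pixel_accuracy(m, m) == 1.0

    def test_all_wrong(self):
        assert pixel_accuracy(np.zeros((4, 4)), np.ones((4, 4))) == 0.0

    def test_partial(self):
        t = np.zeros((3, 3), int)
        p = t.copy()
        p[0, 0] = p[1, 1] = p[2, 2] = 1
        assert pixel_accuracy(p, t) == pytest.approx(6 / 9)


class TestDetection:
    @staticmethod
    def _mask_with_disks(centers, radius=3, shape=(32, 32)):
        m = np.zeros(shape, np.uint8)
        rr, cc = np.meshgrid(range(shape[0]), range(shape[1]), indexing="ij")
        for r0, c0 in centers:
            m[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2] = 2
        return m

    def test_perfect_prediction(self):
        truth = self._mask_with_disks([(8, 8), (8, 24), (24, 16)])
        counts = detect_axons(truth, truth)
        assert (counts.tp, counts.fp, counts.fn) == (3, 0, 0)

    def test_one_spurious_object(self):
        truth = self._mask_with_disks([(8, 8), (8, 24), (24, 16)])
        pred = self._mask_with_disks([(8, 8), (8, 24), (24, 16), (24, 28)], radius=2)
        counts = detect_axons(pred, truth)
        assert counts.sensitivity == 1.0
        assert counts.precision == pytest.approx(0.75)

    def test_empty_prediction_flagged(self):
        truth = self._mask_with_disks([(8, 8), (24, 24)])
        counts = detect_axons(np.zeros_like(truth), truth)
        assert (counts.tp, counts.fn) == (0, 2)
        assert counts.precision == 0.0
        assert counts.undefined_precision

    def test_oversegmentation_counts_surplus_as_fp(self):
        truth = np.zeros((16, 16), np.uint8)
        truth[4:12, 4:12] = 2          # one big object
        pred = np.zeros((16, 16), np.uint8)
        pred[5:7, 5:7] = 2             # two fragments inside it
        pred[9:11, 9:11] = 2
        counts = detect_axons(pred, truth)
        assert (counts.tp, counts.fp, counts.fn) == (1, 1, 0)


class TestAgainstBruteForce:
    def test_random_mask_pairs_match_oracle_exactly(self, rng):
        for _ in range(25):
            pred = rng.integers(0, 3, size=(32, 32)).astype(np.uint8)
            truth = rng.integers(0, 3, size=(32, 32)).astype(np.uint8)
            assert dice(pred == 2, truth == 2) == brute_force_dice(pred == 2, truth == 2)
            assert pixel_accuracy(pred, truth) == brute_force_accuracy(pred, truth)
            counts = detect_axons(pred, truth)
            assert (counts.tp, counts.fp, counts.fn) == brute_force_detection(pred, truth)


class TestEvaluate:
    def test_perfect_prediction_all_ones(self):
        m = TestDetection._mask_with_disks([(8, 8), (8, 24), (24, 16)])
        m[0:4, 12:20] = 1  # some myelin so its Dice is defined by overlap
        report = evaluate(m, m)
        assert report.axon_dice == report.myelin_dice == 1.0
        assert report.pixel_accuracy == report.sensitivity == report.precision == 1.0

    def test_all_background_prediction(self):
        truth = np.zeros((10, 10), np.uint8)
        truth[2:5, 2:5] = 2
        truth[6:9, 6:9] = 1
        report = evaluate(np.zeros_like(truth), truth)
        assert report.axon_dice == 0.0
        assert report.myelin_dice == 0.0
        assert report.pixel_accuracy == pytest.approx(1 - 18 / 100)
        assert report.sensitivity == 0.0
        assert any("precision" in f for f in report.flags)

    def test_counts_invariants(self):
        counts = DetectionCounts(tp=3, fp=1, fn=2)
        assert counts.sensitivity == pytest.approx(0.6)
        assert counts.precision == pytest.approx(0.75)


class TestProperties:
    """Randomized invariants (hypothesis, derandomized)."""

    from hypothesis import given, settings, strategies as st

    @given(seed=st.integers(0, 10 ** 6), threshold=st.floats(0.1, 0.9))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_dice_bounds_and_symmetry(self, seed, threshold):
        r = np.random.default_rng(seed)
        a = r.random((12, 12)) > threshold
        b = r.random((12, 12)) > threshold
        d = dice(a, b)
        assert 0.0 <= d <= 1.0
        assert d == dice(b, a)
        assert dice(a, a) == 1.0

    @given(seed=st.integers(0, 10 ** 6))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_detection_counts_consistent(self, seed):
        r = np.random.default_rng(seed)
        pred = r.integers(0, 3, size=(20, 20)).astype(np.uint8)
        truth = r.integers(0, 3, size=(20, 20)).astype(np.uint8)
        c = detect_axons(pred, truth)
        assert c.tp >= 0 and c.fp >= 0 and c.fn >= 0
        assert 0.0 <= c.sensitivity <= 1.0
        assert 0.0 <= c.precision <= 1.0
        from skimage.measure import label
        _, n_truth = label(truth == 2, connectivity=2, return_num=True)
        assert c.tp + c.fn == n_truth
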