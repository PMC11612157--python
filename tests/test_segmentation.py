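"""Extremal-region segmentation: max-tree, features, SVM, antichain selection."""

import numpy as np
import pytest
from antichain_oracle import (
    StubNode as _StubNode,
    StubTree as _StubTree,
    brute_force_antichain_optimum,
    dp_selected_value,
)

from optopattern import calibration as cal
from optopattern import fixtures as fx
from optopattern import projection as proj
from optopattern import segmentation as seg


def two_disk_image(shape=(96, 96), r=10):
    yy, xx = np.mgrid[0: shape[0], 0: shape[1]].astype(float)
    img = np.zeros(shape)
    img[(yy - 25) ** 2 + (xx - 25) ** 2 <= r**2] = 1.0
    img[(yy - 70) ** 2 + (xx - 65) ** 2 <= r**2] = 0.8
    return img


class TestComponentTree:
    def test_constant_image_single_root(self):
        tree = seg.build_component_tree(np.full((32, 32), 3.7))
        assert len(tree.nodes) == 1
        assert tree.nodes[0].parent == -1
        assert tree.nodes[0].area == 32 * 32

    def test_two_disks_two_candidate_lineages(self):
        img = two_disk_image()
        # Oracle: brute-force threshold sweep, counting area-gated components
        # at every level.
        from scipy.ndimage import label as cc_label

        best = 0
        for t in np.unique(img)[:-1]:
            lab, n = cc_label(img > t)
            areas = np.bincount(lab.ravel())[1:]
            best = max(best, int(((areas >= 20) & (areas <= 10_000)).sum()))
        assert best == 2

        tree = seg.build_component_tree(img)
        elig = set(tree.eligible_nodes())

        def has_eligible_ancestor(nid):
            p = tree.nodes[nid].parent
            while p != -1:
                if p in elig:
                    return True
                p = tree.nodes[p].parent
            return False

        maximal = [n for n in elig if not has_eligible_ancestor(n)]
        assert len(maximal) == best == 2

    def test_nesting_invariant_random_image(self, rng):
        img = rng.uniform(0, 1, (40, 40))
        tree = seg.build_component_tree(img)
        for nid, node in enumerate(tree.nodes):
            if node.parent == -1:
                continue
            child_px = set(tree.node_pixels(nid).tolist())
            parent_px = set(tree.node_pixels(node.parent).tolist())
            assert child_px < parent_px

    def test_dark_on_bright_polarity(self):
        img = 1.0 - two_disk_image()
        tree = seg.build_component_tree(img, polarity="dark_on_bright")
        assert len(tree.eligible_nodes()) > 0

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            seg.build_component_tree(np.zeros((4, 4, 3)))


class TestRegionFeatures:
    def test_feature_vector_length_and_finiteness(self):
        tree = seg.build_component_tree(two_disk_image())
        for nid in tree.eligible_nodes():
            f = seg.region_features(tree, nid)
            assert f.shape == (seg.N_FEATURES,) == (9,)
            assert np.all(np.isfinite(f))

    def test_disk_geometry_features(self):
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        img = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 12**2).astype(float)
        tree = seg.build_component_tree(img)
        nid = max(tree.eligible_nodes(), key=lambda n: tree.nodes[n].level)
        f = seg.region_features(tree, nid)
        named = dict(zip(seg.FEATURE_NAMES, f))
        assert 0.85 <= named["compactness"] <= 1.0
        # π/4 in the continuum; rasterization (bbox width 2r+1) lowers it.
        r = 12
        expected = np.pi * r**2 / (2 * r + 1) ** 2
        assert named["bbox_fill"] == pytest.approx(expected, rel=0.03)
        assert abs(named["bbox_fill"] - np.pi / 4) < 0.1
        assert named["axis_ratio"] == pytest.approx(1.0, abs=0.05)

    def test_shape_features_invariant_to_intensity_offset(self):
        img = two_disk_image()
        t1 = seg.build_component_tree(img)
        t2 = seg.build_component_tree(img + 0.1)
        shape_idx = [0, 1, 2, 3, 4]
        for n1, n2 in zip(t1.eligible_nodes(), t2.eligible_nodes()):
            f1, f2 = seg.region_features(t1, n1), seg.region_features(t2, n2)
            assert np.allclose(f1[shape_idx], f2[shape_idx])
            # Mean intensity shifts by exactly the added constant.
            assert f2[5] - f1[5] == pytest.approx(0.1, abs=1e-9)


class TestClassifier:
    def test_separable_fixture_accuracy(self, trained_classifier):
        pos, neg = [], []
        for s in (11, 12):
            img, gt = fx.disk_fixture(n_disks=20, n_distractors=12, seed=s,
                                      shape=(320, 320))
            p, n = seg.harvest_training_regions(img, gt)
            pos.extend(p)
            neg.extend(n)
        X = np.array(pos + neg)
        y = np.array([1] * len(pos) + [0] * len(neg))
        pred = trained_classifier.likelihood(X) >= 0.5
        assert (pred == y).mean() >= 0.95

    def test_insufficient_examples_rejected(self):
        # No true cells at all: zero positive example regions.
        img, gt = fx.disk_fixture(n_disks=0, n_distractors=5, shape=(224, 224),
                                  seed=1)
        with pytest.raises(seg.InsufficientTrainingDataError):
            seg.train_region_classifier([(img, gt)], seed=0)

    def test_deterministic_for_fixed_seed(self):
        train = [fx.disk_fixture(n_disks=20, n_distractors=12, seed=11,
                                 shape=(320, 320))]
        a = seg.train_region_classifier(train, seed=3)
        b = seg.train_region_classifier(train, seed=3)
        assert np.array_equal(a.weights, b.weights)
        assert a.bias == b.bias and a.platt_a == b.platt_a

    def test_duplication_invariance(self):
        fixture = fx.disk_fixture(n_disks=20, n_distractors=12, seed=11,
                                  shape=(320, 320))
        a = seg.train_region_classifier([fixture], seed=0)
        b = seg.train_region_classifier([fixture, fixture], seed=0)
        assert np.allclose(a.weights, b.weights, atol=1e-6)
        assert a.bias == pytest.approx(b.bias, abs=1e-6)


class TestAntichainSelection:
    def test_all_below_threshold_gives_empty_mask(self):
        tree = seg.build_component_tree(two_disk_image())
        liks = {n: 0.1 for n in tree.eligible_nodes()}
        assert seg.select_nonoverlapping(tree, liks, 0.5).max() == 0

    def test_nested_chain_prefers_higher_score(self, rng):
        tree = _StubTree(1, rng)
        tree.nodes.append(_StubNode(0))
        tree.nodes[0].children.append(1)
        tree.nodes.append(_StubNode(1))
        tree.nodes[1].children.append(2)
        tree._direct = [np.array([0]), np.array([1]), np.array([2])]
        tree.shape = (2, 2)
        scores = {1: 0.6, 2: 0.9}
        assert brute_force_antichain_optimum(tree, scores, 0.5) == pytest.approx(0.4)
        mask = seg.select_nonoverlapping(tree, scores, 0.5)
        # Node 2 (score 0.9) selected alone: exactly its pixel set labeled.
        assert set(np.nonzero(mask.ravel())[0]) == {2}

    def test_dp_matches_brute_force_on_random_trees(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(4, 13))
            tree = _StubTree(n, rng)
            scores = {i: float(rng.uniform(0, 1)) for i in range(1, n)}
            thr = 0.5
            assert dp_selected_value(tree, scores, thr) == pytest.approx(
                brute_force_antichain_optimum(tree, scores, thr)
            )

    def test_monotone_threshold_property(self, rng):
        tree = _StubTree(12, rng)
        scores = {i: float(rng.uniform(0, 1)) for i in range(1, 12)}
        counts = []
        for thr in (0.2, 0.4, 0.6, 0.8):
            mask = seg.select_nonoverlapping(tree, scores, thr)
            counts.append(len(np.unique(mask)) - 1)
        assert all(a >= b for a, b in zip(counts, counts[1:]))


def object_prf(mask, gt, iou_thr=0.7):
    """Object-level matching by IoU between predicted and true labels."""
    matched_gt, matched_pred = set(), set()
    for p in np.unique(mask)[1:]:
        pm = mask == p
        for g in np.unique(gt)[1:]:
            if g in matched_gt:
                continue
            gm = gt == g
            iou = np.logical_and(pm, gm).sum() / np.logical_or(pm, gm).sum()
            if iou >= iou_thr:
                matched_gt.add(g)
                matched_pred.add(p)
                break
    n_pred = mask.max()
    n_gt = gt.max()
    return len(matched_pred) / max(n_pred, 1), len(matched_gt) / max(n_gt, 1)


class TestSegmentPipeline:
    def test_blank_image_empty_mask(self, trained_classifier):
        mask = seg.segment(np.zeros((64, 64)), trained_classifier)
        assert mask.max() == 0

    def test_thirty_disk_fixture_perfect_precision_recall(
        self, trained_classifier, eval_fixture
    ):
        img, gt = eval_fixture
        mask = seg.segment(img, trained_classifier)
        precision, recall = object_prf(mask, gt)
        assert precision == 1.0
        assert recall == 1.0

    def test_selected_regions_pairwise_disjoint(self, trained_classifier, rng):
        img = rng.uniform(0, 1, (96, 96))
        mask = seg.segment(img, trained_classifier)
        # Disjointness is structural: one label per pixel; labels contiguous.
        labels = np.unique(mask)
        assert labels[0] == 0 or mask.min() > 0
        assert list(labels[labels > 0]) == list(range(1, mask.max() + 1))

    def test_mask_to_projection_round_trip(self, trained_classifier, eval_fixture):
        img, _ = eval_fixture
        mask = (seg.segment(img, trained_classifier) > 0).astype(float)
        h = cal.Homography(np.array([[1.05, 0.02, 5.0], [-0.02, 0.95, -3.0],
                                     [0, 0, 1.0]]))
        pattern = cal.correct_pattern(mask, h, (400, 400))
        rec = proj.render_irradiance(pattern, h, 1.0, mask.shape).irradiance
        covered = (rec > 0.5) & (mask > 0.5)
        assert covered.sum() / mask.sum() >= 0.95
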