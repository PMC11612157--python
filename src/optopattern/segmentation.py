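"""Extremal-region cell segmentation.

The engine follows the fast extremal-region recipe: build a max-tree (the
nested family of connected components obtained by thresholding the image at
every gray level), describe each candidate region with 9 shape and texture
features, score candidates with a linear support-vector machine calibrated to
[0, 1] likelihoods, and finally select the best antichain of the tree — a set
of regions none of which contains another — as the cell mask.

Feature set (fixed, length 9): area, perimeter, compactness 4πA/P²,
bounding-box fill ratio, major/minor axis ratio, mean interior intensity,
interior intensity variance, boundary contrast (|interior mean − immediate
exterior mean|), and the node's normalized gray level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import perimeter as _mask_perimeter
from skimage.morphology import max_tree

N_FEATURES = 9

FEATURE_NAMES = (
    "area",
    "perimeter",
    "compactness",
    "bbox_fill",
    "axis_ratio",
    "mean_intensity",
    "intensity_variance",
    "boundary_contrast",
    "gray_level",
)


class InsufficientTrainingDataError(ValueError):
    """A class has fewer labeled example regions than required for training."""


@dataclass
class TreeNode:
    """One extremal region (canonical max-tree node)."""

    index: int                 # canonical flat pixel index
    level: int                 # quantized gray level (0..255)
    area: int                  # pixels in the region (node + all descendants)
    parent: int                # index into the node list; -1 for root
    children: list[int] = field(default_factory=list)
    eligible: bool = True      # inside the [min_area, max_area] gate


class ComponentTree:
    """Max-tree of a grayscale image quantized to 256 levels, 4-connectivity.

    ``polarity='dark_on_bright'`` inverts the image first so that dark objects
    become maxima.  Nodes outside the area gates are kept (they carry the
    nesting structure) but flagged ineligible for selection.
    """

    def __init__(
        self,
        image: np.ndarray,
        polarity: str = "bright_on_dark",
        min_area: int = 20,
        max_area: int = 10_000,
    ):
        image = np.asarray(image, dtype=float)
        if image.ndim != 2:
            raise ValueError("component tree requires a single-channel 2D image")
        if polarity == "dark_on_bright":
            work = image.max() - image
        elif polarity == "bright_on_dark":
            work = image
        else:
            raise ValueError(f"unknown polarity: {polarity!r}")
        self.image = image
        self.polarity = polarity
        lo, hi = work.min(), work.max()
        if hi > lo:
            quant = np.round((work - lo) / (hi - lo) * 255).astype(np.int32)
        else:
            quant = np.zeros(work.shape, dtype=np.int32)
        self.quantized = quant
        self.shape = image.shape
        self.min_area, self.max_area = min_area, max_area
        self._build()

    def _build(self) -> None:
        parent_px, traverser = max_tree(self.quantized, connectivity=1)
        flat = self.quantized.ravel()
        parent_flat = parent_px.ravel()
        root = traverser[0]
        # Canonical pixels: root, plus any pixel whose level differs from its
        # parent pixel's level.
        canonical = flat != flat[parent_flat]
        canonical[root] = True
        # Map every pixel to its canonical representative (parents precede
        # children in traverser order, so one pass suffices).
        canon_of = np.empty(flat.size, dtype=np.int64)
        canon_of[root] = root
        for p in traverser[1:]:
            canon_of[p] = p if canonical[p] else canon_of[parent_flat[p]]
        self._canon_of_pixel = canon_of

        canon_idx = traverser[canonical[traverser]]  # root-first order
        node_id = {int(c): i for i, c in enumerate(canon_idx)}
        # Subtree areas: accumulate leaf-to-root.
        areas = np.zeros(flat.size, dtype=np.int64)
        np.add.at(areas, canon_of, 1)
        for c in canon_idx[:0:-1]:
            areas[canon_of[parent_flat[c]]] += areas[c]

        self.nodes: list[TreeNode] = []
        for c in canon_idx:
            c = int(c)
            pid = -1 if c == root else node_id[int(canon_of[parent_flat[c]])]
            node = TreeNode(
                index=c,
                level=int(flat[c]),
                area=int(areas[c]),
                parent=pid,
                eligible=self.min_area <= areas[c] <= self.max_area,
            )
            self.nodes.append(node)
            if pid >= 0:
                self.nodes[pid].children.append(len(self.nodes) - 1)
        self.root = 0
        # The root is the full support, never a cell candidate.
        self.nodes[0].eligible = False

        # Direct-member pixel lists per node (pixels at exactly this node's
        # component, excluding descendants at higher levels).
        order = np.argsort(canon_of, kind="stable")
        sorted_canon = canon_of[order]
        seg_lo = np.searchsorted(sorted_canon, canon_idx, side="left")
        seg_hi = np.searchsorted(sorted_canon, canon_idx, side="right")
        direct = [order[lo:hi] for lo, hi in zip(seg_lo, seg_hi)]

        # Euler-tour layout: a DFS orders all pixels so every node's subtree
        # occupies one contiguous slice — node_pixels is then O(area).
        n_nodes = len(self.nodes)
        self._span = np.zeros((n_nodes, 2), dtype=np.int64)
        self._pixel_order = np.empty(flat.size, dtype=np.int64)
        cursor = 0
        stack: list[tuple[int, bool]] = [(0, False)]
        while stack:
            nid, done = stack.pop()
            if done:
                self._span[nid, 1] = cursor
                continue
            self._span[nid, 0] = cursor
            d = direct[nid]
            self._pixel_order[cursor: cursor + len(d)] = d
            cursor += len(d)
            stack.append((nid, True))
            for c in reversed(self.nodes[nid].children):
                stack.append((c, False))
        assert cursor == flat.size

    def __len__(self) -> int:
        return len(self.nodes)

    def node_pixels(self, node_id: int) -> np.ndarray:
        """Flat pixel indices of the full region (node plus descendants)."""
        lo, hi = self._span[node_id]
        return self._pixel_order[lo:hi]

    def node_mask(self, node_id: int) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        mask.ravel()[self.node_pixels(node_id)] = True
        return mask

    def eligible_nodes(self) -> list[int]:
        return [i for i, n in enumerate(self.nodes) if n.eligible]


def build_component_tree(
    image: np.ndarray,
    polarity: str = "bright_on_dark",
    min_area: int = 20,
    max_area: int = 10_000,
) -> ComponentTree:
    """Convenience constructor for :class:`ComponentTree`."""
    return ComponentTree(image, polarity, min_area, max_area)


def region_features(tree: ComponentTree, node_id: int) -> np.ndarray:
    """The 9-dimensional shape/texture descriptor of one extremal region."""
    px = tree.node_pixels(node_id)
    ncols = tree.shape[1]
    ys, xs = px // ncols, px % ncols
    area = float(len(px))
    # Work on a 1-px-padded bounding-box crop: all mask operations are local.
    y0, y1 = ys.min(), ys.max()
    x0, x1 = xs.min(), xs.max()
    mask = np.zeros((y1 - y0 + 3, x1 - x0 + 3), dtype=bool)
    mask[ys - y0 + 1, xs - x0 + 1] = True
    per = max(_mask_perimeter(mask, neighborhood=4), 1.0)
    compact = 4.0 * np.pi * area / per**2
    bbox_fill = area / float((y1 - y0 + 1) * (x1 - x0 + 1))

    mu_y, mu_x = ys.mean(), xs.mean()
    cyy = np.mean((ys - mu_y) ** 2) + 1 / 12.0
    cxx = np.mean((xs - mu_x) ** 2) + 1 / 12.0
    cxy = np.mean((ys - mu_y) * (xs - mu_x))
    tr, det = cyy + cxx, cyy * cxx - cxy**2
    disc = max(tr**2 / 4 - det, 0.0)
    lam1 = tr / 2 + np.sqrt(disc)
    lam2 = max(tr / 2 - np.sqrt(disc), 1e-9)
    axis_ratio = float(np.sqrt(lam1 / lam2))

    vals = tree.image.ravel()[px]
    mean_int = float(vals.mean())
    var_int = float(vals.var())
    ring = ndimage.binary_dilation(mask, structure=np.ones((3, 3))) & ~mask
    ry, rx = np.nonzero(ring)
    ry, rx = ry + y0 - 1, rx + x0 - 1
    inside = (ry >= 0) & (ry < tree.shape[0]) & (rx >= 0) & (rx < ncols)
    exterior = tree.image[ry[inside], rx[inside]]
    contrast = abs(mean_int - float(exterior.mean())) if exterior.size else 0.0
    gray = tree.nodes[node_id].level / 255.0

    feats = np.array(
        [area, per, compact, bbox_fill, axis_ratio, mean_int, var_int, contrast, gray]
    )
    assert feats.shape == (N_FEATURES,) and np.all(np.isfinite(feats))
    return feats


@dataclass
class RegionClassifier:
    """Linear SVM region scorer with logistic likelihood calibration."""

    weights: np.ndarray        # (9,)
    bias: float
    feat_mean: np.ndarray      # standardization statistics
    feat_std: np.ndarray
    platt_a: float             # likelihood = sigmoid(a * decision + b)
    platt_b: float

    def decision(self, features: np.ndarray) -> np.ndarray:
        f = (np.atleast_2d(features) - self.feat_mean) / self.feat_std
        return f @ self.weights + self.bias

    def likelihood(self, features: np.ndarray) -> np.ndarray:
        d = self.decision(features)
        return 1.0 / (1.0 + np.exp(-(self.platt_a * d + self.platt_b)))

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "weights": self.weights.tolist(),
                "bias": self.bias,
                "feat_mean": self.feat_mean.tolist(),
                "feat_std": self.feat_std.tolist(),
                "platt_a": self.platt_a,
                "platt_b": self.platt_b,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "RegionClassifier":
        import json

        d = json.loads(text)
        return cls(
            np.array(d["weights"]),
            d["bias"],
            np.array(d["feat_mean"]),
            np.array(d["feat_std"]),
            d["platt_a"],
            d["platt_b"],
        )


def _iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    inter = np.logical_and(mask_a, mask_b).sum()
    union = np.logical_or(mask_a, mask_b).sum()
    return inter / union if union else 0.0


def harvest_training_regions(
    image: np.ndarray,
    gt_labels: np.ndarray,
    polarity: str = "bright_on_dark",
    pos_iou: float = 0.7,
    neg_iou: float = 0.5,
    min_area: int = 20,
    max_area: int = 10_000,
):
    """Candidate regions from one labeled fixture, split by ground-truth IoU.

    Returns ``(pos_features, neg_features)`` lists: positives overlap a
    ground-truth cell with IoU ≥ ``pos_iou``, negatives with IoU ≤ ``neg_iou``.
    The negative band deliberately includes loose-fitting ancestors of true
    cells (IoU up to 0.5): they are what the selection stage must learn to
    rank below a tight fit.
    """
    tree = build_component_tree(image, polarity, min_area, max_area)
    gt_flat = np.asarray(gt_labels).ravel()
    gt_sizes = np.bincount(gt_flat)
    pos, neg = [], []
    for nid in tree.eligible_nodes():
        px = tree.node_pixels(nid)
        overlap = np.bincount(gt_flat[px], minlength=len(gt_sizes))
        best = 0.0
        for g in np.nonzero(overlap)[0]:
            if g == 0:
                continue
            inter = overlap[g]
            union = len(px) + gt_sizes[g] - inter
            best = max(best, inter / union)
        if best >= pos_iou:
            pos.append(region_features(tree, nid))
        elif best <= neg_iou:
            neg.append(region_features(tree, nid))
    return pos, neg


def train_region_classifier(
    fixtures,
    seed: int = 0,
    polarity: str = "bright_on_dark",
    min_examples: int = 20,
    min_area: int = 20,
    max_area: int = 10_000,
) -> RegionClassifier:
    """Fit the region SVM from labeled fixtures ``[(image, gt_label_mask), ...]``.

    Features are standardized, a linear max-margin classifier is fitted with a
    per-sample-averaged hinge objective (so the boundary is invariant to
    duplicating the training set), and decision values are calibrated to
    likelihoods with a logistic (Platt) fit.  Deterministic for a fixed seed.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.svm import LinearSVC

    pos, neg = [], []
    for image, gt in fixtures:
        p, n = harvest_training_regions(
            image, gt, polarity, min_area=min_area, max_area=max_area
        )
        pos.extend(p)
        neg.extend(n)
    if len(pos) < min_examples or len(neg) < min_examples:
        raise InsufficientTrainingDataError(
            f"need >= {min_examples} examples per class, "
            f"got {len(pos)} positive / {len(neg)} negative"
        )
    X = np.array(pos + neg)
    y = np.array([1] * len(pos) + [0] * len(neg))
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std < 1e-12] = 1.0
    Xs = (X - mean) / std

    svc = LinearSVC(C=100.0 / len(y), dual=False, tol=1e-8, random_state=seed,
                    max_iter=20_000)
    svc.fit(Xs, y)
    w, b = svc.coef_[0].copy(), float(svc.intercept_[0])
    dec = Xs @ w + b
    platt = LogisticRegression(C=np.inf, tol=1e-8, max_iter=10_000)
    platt.fit(dec[:, None], y)
    return RegionClassifier(
        weights=w,
        bias=b,
        feat_mean=mean,
        feat_std=std,
        platt_a=float(platt.coef_[0, 0]),
        platt_b=float(platt.intercept_[0]),
    )


def select_nonoverlapping(
    tree: ComponentTree,
    likelihoods: dict[int, float],
    min_likelihood: float = 0.5,
) -> np.ndarray:
    """Optimal antichain of the component tree, rendered as a label mask.

    Maximizes the sum of (likelihood − ``min_likelihood``) over selected
    regions subject to the non-overlap (antichain) constraint, by bottom-up
    dynamic programming: a node's value is the better of its own score and the
    sum of its children's values.  Nodes without a likelihood (or below the
    threshold) can only contribute through their descendants.
    """
    n = len(tree.nodes)
    value = np.zeros(n)
    take = np.zeros(n, dtype=bool)
    # Children precede parents when iterating node ids in reverse (root is 0
    # and ids were assigned root-first).
    for nid in range(n - 1, -1, -1):
        node = tree.nodes[nid]
        child_sum = sum(value[c] for c in node.children)
        own = likelihoods.get(nid, -np.inf) - min_likelihood
        if node.eligible and own > 0 and own > child_sum:
            value[nid] = own
            take[nid] = True
        else:
            value[nid] = child_sum

    mask = np.zeros(tree.shape, dtype=np.int32)
    label_id = 0
    stack = [tree.root]
    while stack:
        nid = stack.pop()
        if take[nid]:
            label_id += 1
            mask.ravel()[tree.node_pixels(nid)] = label_id
        else:
            stack.extend(sorted(tree.nodes[nid].children, reverse=True))
    return mask


def segment(
    image: np.ndarray,
    classifier: RegionClassifier,
    polarity: str = "bright_on_dark",
    min_likelihood: float = 0.5,
    min_area: int = 20,
    max_area: int = 10_000,
) -> np.ndarray:
    """Full pipeline: component tree → features → SVM likelihoods → antichain."""
    tree = build_component_tree(image, polarity, min_area, max_area)
    elig = tree.eligible_nodes()
    if not elig:
        return np.zeros(tree.shape, dtype=np.int32)
    feats = np.array([region_features(tree, nid) for nid in elig])
    liks = classifier.likelihood(feats)
    return select_nonoverlapping(tree, dict(zip(elig, liks)), min_likelihood)
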