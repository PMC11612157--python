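"""Projector–camera geometric calibration.

The optical train maps DMD pixel coordinates into camera pixel coordinates.
We model that mapping as an 8-degree-of-freedom planar projective transform
(homography), estimated from fiducial spot correspondences by the normalized
direct linear transform.  Once estimated, target shapes drawn in camera space
are pre-corrected (inverse-warped) into DMD space so that the projected
pattern lands where intended on the sample.

Conventions: 0-based pixel coordinates, ``x`` = column, ``y`` = row.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.transform import ProjectiveTransform, warp

logger = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    """Point configuration cannot fix a homography (too few / collinear)."""


class DetectionFailureError(RuntimeError):
    """Fiducial detection found an unexpected number of spots."""

    def __init__(self, message: str, observed_count: int):
        super().__init__(message)
        self.observed_count = observed_count


@dataclass
class Homography:
    """Invertible 3×3 projective map between DMD and camera pixel space.

    ``matrix`` is normalized so element (3, 3) = 1.  ``residual_rms`` is the
    root-mean-square reprojection error (camera pixels) of the fit that
    produced it (0 for exact constructions).
    """

    matrix: np.ndarray
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("homography matrix must be 3x3")
        if abs(np.linalg.det(m)) < 1e-15:
            raise DegenerateInputError("homography matrix is singular")
        if m[2, 2] != 0:
            m = m / m[2, 2]
        self.matrix = m

    @classmethod
    def identity(cls) -> "Homography":
        return cls(np.eye(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 2) points (x, y) through the homography."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        homog = np.hstack([pts, np.ones((len(pts), 1))])
        mapped = homog @ self.matrix.T
        return mapped[:, :2] / mapped[:, 2:3]

    # Alias so a Homography can be handed to skimage.transform.warp as an
    # inverse_map (warp calls it with (col, row) coordinate arrays).
    def transform(self, coords: np.ndarray) -> np.ndarray:
        return self.apply(coords)

    __call__ = transform

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix), residual_rms=self.residual_rms)

    def to_json(self) -> str:
        return json.dumps(
            {"matrix": self.matrix.ravel().tolist(), "residual_rms": self.residual_rms}
        )

    @classmethod
    def from_json(cls, text: str) -> "Homography":
        d = json.loads(text)
        return cls(np.array(d["matrix"], dtype=float).reshape(3, 3), d.get("residual_rms", 0.0))


@dataclass
class FiducialSet:
    """Paired DMD-space and camera-space fiducial coordinates (index-matched)."""

    dmd_points: np.ndarray
    camera_points: np.ndarray

    def __post_init__(self) -> None:
        self.dmd_points = np.atleast_2d(np.asarray(self.dmd_points, dtype=float))
        self.camera_points = np.atleast_2d(np.asarray(self.camera_points, dtype=float))
        if self.dmd_points.shape != self.camera_points.shape:
            raise ValueError("dmd and camera point lists must have equal shape")
        if self.dmd_points.shape[1] != 2:
            raise ValueError("points must be (N, 2) arrays of (x, y)")
        d = self.dmd_points
        if len(np.unique(d, axis=0)) != len(d):
            raise ValueError("dmd fiducial points must be distinct")


def _collinear(points: np.ndarray, tol: float = 1e-6) -> bool:
    pts = points - points.mean(axis=0)
    s = np.linalg.svd(pts, compute_uv=False)
    return len(s) < 2 or s[1] <= tol * max(s[0], 1.0)


def generate_fiducial_pattern(
    rows: int,
    cols: int,
    spot_radius: float,
    margin: float,
    dmd_shape: tuple[int, int] = (1080, 1920),
):
    """Regular grid of full-on disks for calibration, plus their known centres.

    One corner spot (grid index 0, 0) is enlarged to 1.5× radius to break the
    180° rotational ambiguity of a symmetric grid.  Returns ``(pattern,
    centers)`` where ``centers`` is an (rows·cols, 2) array of (x, y) DMD
    coordinates in row-major grid order.
    """
    from .projection import DMDPattern  # local import to avoid a cycle

    if rows < 2 or cols < 2:
        raise DegenerateInputError(
            "fiducial grid needs at least 2 rows and 2 columns: collinear spot "
            "centres cannot fix a projective mapping"
        )
    big_r = 1.5 * spot_radius
    h, w = dmd_shape
    margin_y, margin_x = (margin, margin) if np.isscalar(margin) else margin
    if 2 * (margin_y + big_r) >= h or 2 * (margin_x + big_r) >= w:
        raise ValueError("fiducial spots do not fit inside the DMD array")
    xs = np.linspace(margin_x + big_r, w - 1 - margin_x - big_r, cols)
    ys = np.linspace(margin_y + big_r, h - 1 - margin_y - big_r, rows)
    centers = np.array([(x, y) for y in ys for x in xs])
    # Grid spacing must keep disks disjoint so detection can count them.
    min_pitch = min(np.diff(xs).min() if cols > 1 else np.inf,
                    np.diff(ys).min() if rows > 1 else np.inf)
    if min_pitch <= 2 * big_r:
        raise ValueError("fiducial spots overlap; reduce radius or grid size")
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    duties = np.zeros(dmd_shape)
    for i, (cx, cy) in enumerate(centers):
        r = big_r if i == 0 else spot_radius
        duties[(xx - cx) ** 2 + (yy - cy) ** 2 <= r**2] = 1.0
    return DMDPattern(duties), centers


def detect_fiducial_centroids(
    frame: np.ndarray,
    expected_count: int,
    grid_shape: tuple[int, int] | None = None,
    min_spot_px: int = 5,
) -> np.ndarray:
    """Locate fiducial spot centroids in a camera frame, in grid order.

    The frame is Otsu-thresholded, connected components smaller than
    ``min_spot_px`` pixels are discarded, and intensity-weighted centroids are
    returned row-major after orientation disambiguation: the enlarged corner
    spot (largest area) is rotated to grid index (0, 0).  ``grid_shape``
    defaults to a square grid of ``expected_count`` spots.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be a single-channel 2D image")
    if grid_shape is None:
        side = int(round(np.sqrt(expected_count)))
        if side * side != expected_count:
            raise ValueError("grid_shape required for non-square fiducial grids")
        grid_shape = (side, side)
    if grid_shape[0] * grid_shape[1] != expected_count:
        raise ValueError("grid_shape inconsistent with expected_count")

    if frame.max() <= frame.min():
        raise DetectionFailureError("frame has no contrast; no fiducials found", 0)
    thresh = threshold_otsu(frame)
    labels = label(frame > thresh, connectivity=2)
    props = [p for p in regionprops(labels, intensity_image=frame) if p.area >= min_spot_px]
    if len(props) != expected_count:
        raise DetectionFailureError(
            f"expected {expected_count} fiducial spots, found {len(props)}", len(props)
        )
    # centroid_weighted is (row, col); store as (x, y).
    cents = np.array([(p.centroid_weighted[1], p.centroid_weighted[0]) for p in props])
    areas = np.array([p.area for p in props])

    nrows, ncols = grid_shape
    order = np.argsort(cents[:, 1], kind="stable")  # by y, then chunk into rows
    ordered = []
    for r in range(nrows):
        row_idx = order[r * ncols: (r + 1) * ncols]
        row_idx = row_idx[np.argsort(cents[row_idx, 0], kind="stable")]
        ordered.extend(row_idx.tolist())
    ordered = np.array(ordered)
    # The enlarged marker spot must sit at grid index 0; if it landed at the
    # opposite corner the grid is seen rotated by 180°.
    marker = int(np.argmax(areas))
    pos = int(np.where(ordered == marker)[0][0])
    if pos == len(ordered) - 1:
        ordered = ordered[::-1]
    elif pos != 0:
        raise DetectionFailureError(
            "enlarged corner spot not found at a grid corner; cannot orient grid",
            len(props),
        )
    return cents[ordered]


def estimate_homography(fiducials: FiducialSet) -> Homography:
    """Least-squares projective fit (normalized DLT) of camera = H · dmd.

    Requires ≥ 4 non-collinear correspondences.  ``residual_rms`` is reported
    in camera pixels.
    """
    src, dst = fiducials.dmd_points, fiducials.camera_points
    if len(src) < 4:
        raise DegenerateInputError("homography estimation needs >= 4 point pairs")
    if _collinear(src) or _collinear(dst):
        raise DegenerateInputError("collinear points cannot fix a homography")
    tform = ProjectiveTransform.from_estimate(src, dst)
    if not tform:
        raise DegenerateInputError("projective fit failed (degenerate configuration)")
    h = Homography(tform.params)
    resid = np.sqrt(np.mean(np.sum((h.apply(src) - dst) ** 2, axis=1)))
    h.residual_rms = float(resid)
    return h


def correct_pattern(target: np.ndarray, h: Homography, dmd_shape: tuple[int, int]):
    """Pre-correct a camera-space target image into a DMD duty-cycle pattern.

    Inverse-warps the target into DMD space with bilinear interpolation (for
    each DMD pixel, sample the target at its forward-projected camera
    location); regions mapping outside the target get duty 0.  Forward
    projection of the result through ``h`` then reproduces the target.
    """
    from .projection import DMDPattern

    target = np.asarray(target, dtype=float)
    out = warp(
        target,
        inverse_map=h.transform,
        output_shape=dmd_shape,
        order=1,
        cval=0.0,
        preserve_range=True,
    )
    out = np.clip(out, 0.0, 1.0)
    if target.max() > 0 and out.max() == 0:
        logger.warning(
            "camera-space target lies entirely outside the mapped DMD footprint; "
            "corrected pattern is all-zero"
        )
    return DMDPattern(out)
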