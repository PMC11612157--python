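"""Frame-to-frame cell tracking over time-lapse segmentation masks.

Identities are propagated by optimal bipartite assignment (Hungarian method)
on centroid distances, gated by a maximum physical displacement.  Unmatched
detections open new tracks; unmatched tracks survive a configurable number of
frames (``lost_patience``) before closing.  Ties are broken deterministically
by lowest (track id, label).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy import ndimage

_GATE_COST = 1e9


@dataclass
class Track:
    """One cell identity: (frame, label, centroid) observations over time."""

    track_id: int
    observations: list[tuple[int, int, float, float]] = field(default_factory=list)
    status: str = "active"        # active | lost
    missed: int = 0

    def add(self, frame: int, label: int, x: float, y: float) -> None:
        if self.observations and frame <= self.observations[-1][0]:
            raise ValueError("frame indices must be strictly increasing")
        self.observations.append((frame, label, x, y))
        self.missed = 0

    @property
    def last_position(self) -> tuple[float, float]:
        return self.observations[-1][2], self.observations[-1][3]


def _centroids(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.unique(mask)
    labels = labels[labels != 0]
    if len(labels) == 0:
        return labels, np.zeros((0, 2))
    cents = ndimage.center_of_mass(np.ones_like(mask), mask, labels)
    # center_of_mass returns (row, col); store (x, y).
    return labels, np.array([(c, r) for r, c in cents])


def link_masks(
    masks,
    max_displacement_um: float = 20.0,
    lost_patience: int = 0,
    pixel_size_um: float = 1.083,
) -> list[Track]:
    """Link an ordered sequence of label masks into tracks.

    ``max_displacement_um`` gates candidate matches (centroid distance in
    physical units); ``lost_patience`` is how many frames a track may go
    undetected before it closes.
    """
    masks = list(masks)
    if not masks:
        return []
    shape = masks[0].shape
    tracks: list[Track] = []
    open_tracks: list[Track] = []
    next_id = 1
    for f, mask in enumerate(masks):
        if mask.shape != shape:
            raise ValueError("all masks must share dimensions")
        labels, cents = _centroids(mask)
        cents_um = cents * pixel_size_um
        # Deterministic candidate ordering.
        open_tracks.sort(key=lambda t: t.track_id)
        order = np.argsort(labels, kind="stable")
        labels, cents, cents_um = labels[order], cents[order], cents_um[order]

        matched_det = np.zeros(len(labels), dtype=bool)
        if open_tracks and len(labels):
            prev = np.array([t.last_position for t in open_tracks]) * pixel_size_um
            dist = np.linalg.norm(prev[:, None, :] - cents_um[None, :, :], axis=2)
            cost = np.where(dist <= max_displacement_um, dist, _GATE_COST)
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                if cost[r, c] >= _GATE_COST:
                    continue
                open_tracks[r].add(f, int(labels[c]), float(cents[c, 0]), float(cents[c, 1]))
                matched_det[c] = True
        # Age unmatched open tracks.
        still_open = []
        for t in open_tracks:
            if t.observations and t.observations[-1][0] == f:
                still_open.append(t)
            else:
                t.missed += 1
                if t.missed > lost_patience:
                    t.status = "lost"
                else:
                    still_open.append(t)
        open_tracks = still_open
        # New tracks for unmatched detections.
        for c in np.nonzero(~matched_det)[0]:
            t = Track(track_id=next_id)
            next_id += 1
            t.add(f, int(labels[c]), float(cents[c, 0]), float(cents[c, 1]))
            tracks.append(t)
            open_tracks.append(t)
    return tracks


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Long-form table (track_id, frame, label, x, y) for CSV export."""
    rows = [
        {"track_id": t.track_id, "frame": f, "label": lbl, "x": x, "y": y}
        for t in tracks
        for (f, lbl, x, y) in t.observations
    ]
    return pd.DataFrame(rows, columns=["track_id", "frame", "label", "x", "y"])
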