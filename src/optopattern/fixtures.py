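"""Synthetic labeled microscopy fixtures for segmentation and tracking.

These generators produce images with exact ground truth: Gaussian-blurred
disks standing in for fluorescent cell bodies, optional non-cell distractor
structures (dim elongated bars) for classifier training, and drifting-disk
mask sequences for tracking.  All randomness is seeded.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter


def disk_fixture(
    n_disks: int = 30,
    shape: tuple[int, int] = (256, 256),
    radius: float = 8.0,
    snr: float = 6.0,
    blur_sigma: float = 1.5,
    n_distractors: int = 0,
    seed: int = 0,
):
    """Well-separated bright disks on a dark noisy background, with labels.

    Disks of unit amplitude are placed on a jittered grid (centre spacing
    ≥ 4·radius), blurred, and corrupted with Gaussian noise of standard
    deviation 1/``snr``.  Optional distractors are dim thin bars — real image
    structure that is not a cell.  Returns ``(image, gt_labels)`` where
    ``gt_labels`` marks the unblurred disk supports 1..n.
    """
    rng = np.random.default_rng(seed)
    rows, cols = shape
    # Grid placement with jitter keeps disks well separated.
    pitch = 4.0 * radius
    gy = np.arange(pitch, rows - pitch, pitch)
    gx = np.arange(pitch, cols - pitch, pitch)
    sites = [(y, x) for y in gy for x in gx]
    if len(sites) < n_disks + n_distractors:
        raise ValueError("field too small for the requested object count")
    rng.shuffle(sites)
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    clean = np.zeros(shape)
    labels = np.zeros(shape, dtype=np.int32)
    for i in range(n_disks):
        cy, cx = sites[i]
        cy += rng.uniform(-radius / 2, radius / 2)
        cx += rng.uniform(-radius / 2, radius / 2)
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        clean[disk] = 1.0
        labels[disk] = i + 1
    for j in range(n_distractors):
        cy, cx = sites[n_disks + j]
        horizontal = rng.random() < 0.5
        half_len, half_w = 1.8 * radius, 1.5
        if horizontal:
            bar = (np.abs(yy - cy) <= half_w) & (np.abs(xx - cx) <= half_len)
        else:
            bar = (np.abs(xx - cx) <= half_w) & (np.abs(yy - cy) <= half_len)
        clean[bar] = np.maximum(clean[bar], 0.4)
    image = gaussian_filter(clean, blur_sigma)
    # Noise is blurred by the same optics as the signal, then rescaled so the
    # image-level SNR (peak amplitude / noise std) is exactly as requested.
    noise = gaussian_filter(rng.normal(0.0, 1.0, shape), blur_sigma)
    image += noise * (1.0 / snr) / noise.std()
    return image, labels


def drifting_disks(
    n_frames: int = 10,
    n_objects: int = 1,
    shape: tuple[int, int] = (128, 128),
    radius: float = 6.0,
    starts=None,
    velocities=None,
    skip=(),
):
    """Label-mask sequence of disks moving at constant velocity.

    ``starts``/``velocities``: per-object (x, y) tuples in pixels (defaults:
    spread across the field, 2 px/frame drift).  ``skip``: set of
    ``(frame, object)`` pairs to omit (simulated detection dropouts).
    Returns ``(masks, truth)`` with ``truth[frame][label] = object index``.
    """
    rows, cols = shape
    if starts is None:
        starts = [(20.0 + 25.0 * i, 20.0 + 10.0 * i) for i in range(n_objects)]
    if velocities is None:
        velocities = [(2.0, 1.0)] * n_objects
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    masks, truth = [], []
    for f in range(n_frames):
        mask = np.zeros(shape, dtype=np.int32)
        ids = {}
        label = 0
        for o in range(n_objects):
            if (f, o) in skip:
                continue
            x = starts[o][0] + velocities[o][0] * f
            y = starts[o][1] + velocities[o][1] * f
            label += 1
            mask[(yy - y) ** 2 + (xx - x) ** 2 <= radius**2] = label
            ids[label] = o
        masks.append(mask)
        truth.append(ids)
    return masks, truth
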