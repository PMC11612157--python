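"""Digital micromirror device (DMD) pattern model and irradiance rendering.

A DMD is a binary spatial light modulator: each micromirror flips between an
ON and an OFF tilt state under fast pulse-width modulation (PWM), so the
time-averaged light it forwards is linear in its duty cycle.  A pattern is
therefore a 2D array of duty-cycle fractions in [0, 1].  Projecting a pattern
through the optical train maps DMD pixel space into camera pixel space via a
projective transform (see :mod:`optopattern.calibration`) and scales duty to
irradiance with a single scalar calibration (``max_irradiance``, μW/cm²).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import warp

from .calibration import Homography

#: Default DMD array: 1080p micromirror grid (rows, cols).
DEFAULT_DMD_SHAPE: tuple[int, int] = (1080, 1920)


@dataclass
class DMDPattern:
    """Per-micromirror PWM duty-cycle map in DMD pixel coordinates."""

    duties: np.ndarray

    def __post_init__(self) -> None:
        self.duties = np.asarray(self.duties, dtype=float)
        if self.duties.ndim != 2:
            raise ValueError("duty map must be 2D (rows x cols)")
        if np.any(self.duties < 0) or np.any(self.duties > 1):
            raise ValueError("duty cycles must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.duties.shape  # type: ignore[return-value]


@dataclass
class IrradianceField:
    """Sample-plane irradiance in camera pixel space, units μW/cm²."""

    irradiance: np.ndarray
    max_irradiance: float
    timestamp_h: float = 0.0
    pixel_size_um: float = 1.083

    def __post_init__(self) -> None:
        self.irradiance = np.asarray(self.irradiance, dtype=float)
        if np.any(self.irradiance < -1e-6):
            raise ValueError("irradiance must be non-negative")
        if np.any(self.irradiance > self.max_irradiance + 1e-6 * max(1.0, self.max_irradiance)):
            raise ValueError("irradiance exceeds max_irradiance")

    def sample(self, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
        """Nearest-pixel irradiance at physical positions (μm from the frame origin)."""
        rows, cols = self.irradiance.shape
        c = np.clip(np.round(np.asarray(x_um) / self.pixel_size_um).astype(int), 0, cols - 1)
        r = np.clip(np.round(np.asarray(y_um) / self.pixel_size_um).astype(int), 0, rows - 1)
        return self.irradiance[r, c]


def mirror_count(pattern: DMDPattern) -> int:
    """Number of micromirrors addressed by the pattern (rows · cols)."""
    return int(pattern.duties.shape[0] * pattern.duties.shape[1])


def _check_inside(shape: tuple[int, int], ys: np.ndarray, xs: np.ndarray) -> None:
    if np.any(ys < 0) or np.any(ys >= shape[0]) or np.any(xs < 0) or np.any(xs >= shape[1]):
        raise ValueError("shape geometry falls outside the DMD array")


def compose_shape(
    kind: str,
    dmd_shape: tuple[int, int] = DEFAULT_DMD_SHAPE,
    *,
    center: tuple[float, float] | None = None,
    outer_radius: float | None = None,
    stroke: float | None = None,
    arm_length: float | None = None,
    n_fingers: int = 4,
    finger_width: float | None = None,
    axis: str = "x",
    polarity: str = "light_on_dark",
) -> DMDPattern:
    """Render a named illumination shape as a duty-cycle pattern.

    Kinds
    -----
    ``full_on`` / ``full_off``
        Uniform duty 1 / 0.
    ``circle``
        Annulus ring: ``outer_radius`` and ``stroke`` (ring width), centred at
        ``center`` (x, y) (defaults to the array centre).
    ``cross``
        Two orthogonal bars of half-length ``arm_length`` and width ``stroke``.
    ``finger_stripes``
        ``n_fingers`` dark rectangular fingers of width ``finger_width`` on a
        lit background (the experimental convention: dark regions are spared,
        the surround is illuminated).
    ``linear_gradient``
        Duty ramp 0 → 1 along ``axis`` ('x' across columns or 'y' across rows).

    ``polarity='dark_on_light'`` inverts the pattern.
    """
    rows, cols = dmd_shape
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    if center is None:
        center = ((cols - 1) / 2.0, (rows - 1) / 2.0)
    cx, cy = center

    if kind == "full_on":
        duties = np.ones(dmd_shape)
    elif kind == "full_off":
        duties = np.zeros(dmd_shape)
    elif kind == "circle":
        if outer_radius is None or stroke is None:
            raise ValueError("circle requires outer_radius and stroke")
        if stroke <= 0 or stroke > outer_radius:
            raise ValueError("stroke must lie in (0, outer_radius]")
        _check_inside(dmd_shape, np.array([cy - outer_radius, cy + outer_radius]),
                      np.array([cx - outer_radius, cx + outer_radius]))
        rr = np.hypot(xx - cx, yy - cy)
        duties = ((rr <= outer_radius) & (rr >= outer_radius - stroke)).astype(float)
    elif kind == "cross":
        if arm_length is None or stroke is None:
            raise ValueError("cross requires arm_length and stroke")
        _check_inside(dmd_shape, np.array([cy - arm_length, cy + arm_length]),
                      np.array([cx - arm_length, cx + arm_length]))
        half = stroke / 2.0
        horiz = (np.abs(yy - cy) <= half) & (np.abs(xx - cx) <= arm_length)
        vert = (np.abs(xx - cx) <= half) & (np.abs(yy - cy) <= arm_length)
        duties = (horiz | vert).astype(float)
    elif kind == "finger_stripes":
        if finger_width is None:
            finger_width = cols / (2 * n_fingers + 1)
        if n_fingers < 1 or finger_width <= 0 or n_fingers * finger_width >= cols:
            raise ValueError("finger geometry does not fit the array")
        duties = np.ones(dmd_shape)
        # Fingers evenly spaced along x, spanning the full height.
        gap = (cols - n_fingers * finger_width) / (n_fingers + 1)
        for i in range(n_fingers):
            x0 = gap + i * (finger_width + gap)
            duties[:, int(round(x0)): int(round(x0 + finger_width))] = 0.0
    elif kind == "linear_gradient":
        if axis == "x":
            duties = np.broadcast_to((np.arange(cols) / (cols - 1)), dmd_shape).copy()
        elif axis == "y":
            duties = np.broadcast_to((np.arange(rows) / (rows - 1))[:, None], dmd_shape).copy()
        else:
            raise ValueError("axis must be 'x' or 'y'")
    else:
        raise ValueError(f"unknown shape kind: {kind!r}")

    if polarity == "dark_on_light":
        duties = 1.0 - duties
    elif polarity != "light_on_dark":
        raise ValueError(f"unknown polarity: {polarity!r}")
    return DMDPattern(duties)


def render_irradiance(
    pattern: DMDPattern,
    h: Homography,
    max_irradiance: float,
    camera_shape: tuple[int, int],
    *,
    blur_sigma_px: float = 0.0,
    pixel_size_um: float = 1.083,
    timestamp_h: float = 0.0,
) -> IrradianceField:
    """Forward-project a duty-cycle pattern into camera space.

    The duty map is warped DMD → camera through ``h`` (bilinear interpolation,
    zero outside the DMD footprint) and scaled by ``max_irradiance``;
    irradiance is exactly linear in duty cycle (time-division PWM).  An
    optional Gaussian blur models illumination bleed-through between
    neighbouring regions (off by default).
    """
    if max_irradiance <= 0:
        raise ValueError("max_irradiance must be positive")
    warped = warp(
        pattern.duties,
        inverse_map=h.inverse().transform,
        output_shape=camera_shape,
        order=1,
        cval=0.0,
        preserve_range=True,
    )
    if blur_sigma_px > 0:
        from scipy.ndimage import gaussian_filter

        warped = gaussian_filter(warped, blur_sigma_px)
    warped = np.clip(warped, 0.0, 1.0)
    return IrradianceField(
        irradiance=warped * max_irradiance,
        max_irradiance=max_irradiance,
        timestamp_h=timestamp_h,
        pixel_size_um=pixel_size_um,
    )
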