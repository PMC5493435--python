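"""Cortical intensity profile extraction along a closed cell outline.

Mirrors the manual ImageJ workflow used for crescent quantification: trace
the cell outline, straighten it, take a plot profile of grey values along
it, correct for background, and divide by the mean.  Here the tracing is
replaced by sub-pixel iso-contouring of a binary mask, and the straightened
plot profile by arc-length-equidistant bilinear sampling with an averaging
band of configurable width normal to the outline.

Conventions: image coordinates are 0-based with y increasing downward;
outlines are traversed clockwise in the viewer's frame; the first profile
sample sits where the outline crosses the ray from the cell centroid along
the anterior-posterior axis (+x by default), giving every profile the same
geometric phase origin regardless of vertex list order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

__all__ = [
    "CellOutline",
    "IntensityProfile",
    "DegenerateProfileError",
    "extract_outline",
    "sample_profile",
    "background_correct",
    "normalize_profile",
    "estimate_background",
]


class DegenerateProfileError(ValueError):
    """Raised when a profile carries no signal (all zero) and cannot be normalized."""


@dataclass(frozen=True)
class CellOutline:
    """Closed polygon tracing a cell boundary.

    ``vertices`` is an (n, 2) array of subpixel (x, y) coordinates, 0-based,
    y down, traversed clockwise in the viewer's frame; the edge from the last
    vertex back to the first is implicit.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("outline needs an (n>=3, 2) vertex array")
        # drop an explicit closing vertex if present
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        if v.shape[0] < 3:
            raise ValueError("outline needs at least 3 distinct vertices")
        if abs(_signed_area(v)) <= 0:
            raise ValueError("outline encloses zero area")
        object.__setattr__(self, "vertices", v)

    @property
    def is_clockwise(self) -> bool:
        # in a y-down frame, positive shoelace area = clockwise on screen
        return _signed_area(self.vertices) > 0

    def oriented_clockwise(self) -> "CellOutline":
        if self.is_clockwise:
            return self
        return CellOutline(self.vertices[::-1].copy())

    @property
    def area(self) -> float:
        return abs(_signed_area(self.vertices))

    @property
    def perimeter(self) -> float:
        v = self.vertices
        d = np.diff(np.vstack([v, v[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    @property
    def centroid(self) -> np.ndarray:
        v = self.vertices
        x, y = v[:, 0], v[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        a = cross.sum() / 2.0
        cx = ((x + xn) * cross).sum() / (6.0 * a)
        cy = ((y + yn) * cross).sum() / (6.0 * a)
        return np.array([cx, cy])


def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return float((x * yn - xn * y).sum() / 2.0)


@dataclass(frozen=True)
class IntensityProfile:
    """Grey values sampled at N positions along a closed cortical outline."""

    values: np.ndarray
    arc_positions: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        arcs = np.asarray(self.arc_positions, dtype=float)
        if vals.ndim != 1 or vals.size < 3:
            raise ValueError("profile needs at least 3 samples")
        if arcs.shape != vals.shape:
            raise ValueError("arc_positions must match values in length")
        if np.any(vals < 0):
            raise ValueError("grey values must be nonnegative")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "arc_positions", arcs)

    @property
    def n(self) -> int:
        return int(self.values.size)


# ---------------------------------------------------------------------------
# outline extraction
# ---------------------------------------------------------------------------

def extract_outline(mask: np.ndarray, smooth_sigma: float = 1.0) -> CellOutline:
    """Trace the closed boundary of a single-component binary mask.

    The boundary is the 0.5 iso-contour (subpixel) of the mask indicator
    after a light Gaussian blur (``smooth_sigma`` px), which removes the
    one-pixel staircase of the rasterized boundary — the analogue of a
    smooth freehand trace; pass ``smooth_sigma=0`` for the raw contour.
    Returned clockwise in image coordinates. Raises ``ValueError`` for an
    empty mask, more than one connected component, or a component smaller
    than 9 px.
    """
    m = np.asarray(mask).astype(bool)
    labels, n_comp = measure.label(m, return_num=True, connectivity=1)
    if n_comp == 0:
        raise ValueError("empty mask: no foreground component to outline")
    if n_comp > 1:
        raise ValueError(f"mask has {n_comp} connected components; expected exactly 1")
    if m.sum() < 9:
        raise ValueError("foreground component smaller than 9 px")

    pad = max(2, int(np.ceil(3 * smooth_sigma)) + 1)
    padded = np.pad(m.astype(float), pad)
    if smooth_sigma > 0:
        padded = ndimage.gaussian_filter(padded, smooth_sigma)
    contours = measure.find_contours(padded, 0.5)
    # the outer boundary is the longest contour
    contour = max(contours, key=lambda c: c.shape[0])
    # find_contours yields (row, col) = (y, x); shift off the padding
    xy = np.column_stack([contour[:, 1], contour[:, 0]]) - pad
    return CellOutline(xy).oriented_clockwise()


# ---------------------------------------------------------------------------
# profile sampling
# ---------------------------------------------------------------------------

def _resample_closed_points(vertices: np.ndarray, arc_targets: np.ndarray) -> np.ndarray:
    """Points at given arc lengths along the closed polygon (linear interpolation)."""
    v = np.vstack([vertices, vertices[:1]])
    seg = np.diff(v, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    t = np.mod(arc_targets, total)
    idx = np.clip(np.searchsorted(cum, t, side="right") - 1, 0, len(seg_len) - 1)
    denom = np.where(seg_len[idx] > 0, seg_len[idx], 1.0)
    frac = (t - cum[idx]) / denom
    return v[idx] + frac[:, None] * seg[idx]


def _phase_origin_arc(outline: CellOutline, ap_axis: np.ndarray) -> float:
    """Arc length at which the outline crosses the centroid ray along ap_axis.

    Coarse scan over a dense arc grid, then bisection refinement of the
    zero crossing of the signed angle, so the origin is a property of the
    curve geometry, not of the vertex-list parameterization.
    """
    c = outline.centroid
    total = outline.perimeter
    ax = np.asarray(ap_axis, dtype=float)
    ax = ax / np.hypot(*ax)

    def signed_angle(t):
        pts = _resample_closed_points(outline.vertices, np.atleast_1d(t))
        rel = pts - c
        # signed angle from the A-P axis to each boundary point, y-down frame
        return np.arctan2(ax[0] * rel[:, 1] - ax[1] * rel[:, 0], rel @ ax)

    dense = max(4096, 16 * outline.vertices.shape[0])
    t = np.linspace(0.0, total, dense, endpoint=False)
    ang = signed_angle(t)
    i = int(np.argmin(np.abs(ang)))
    lo, hi = t[i] - total / dense, t[i] + total / dense
    a_lo, a_hi = float(signed_angle(lo)[0]), float(signed_angle(hi)[0])
    if a_lo == 0.0:
        return float(np.mod(lo, total))
    if a_lo * a_hi < 0 and abs(a_lo) < np.pi / 2 and abs(a_hi) < np.pi / 2:
        for _ in range(60):  # bisection to ~1e-12 of an arc unit
            mid = 0.5 * (lo + hi)
            a_mid = float(signed_angle(mid)[0])
            if a_mid == 0.0:
                return float(np.mod(mid, total))
            if a_lo * a_mid < 0:
                hi, a_hi = mid, a_mid
            else:
                lo, a_lo = mid, a_mid
        return float(np.mod(0.5 * (lo + hi), total))
    return float(t[i])


def sample_profile(
    image: np.ndarray,
    outline: CellOutline,
    n_samples: int = 100,
    line_width: float = 3.0,
    ap_axis: tuple[float, float] = (1.0, 0.0),
    pixel_scale: float | None = None,
) -> IntensityProfile:
    """Mean grey value in a band of ``line_width`` px normal to the outline,
    at ``n_samples`` arc-length-equidistant positions.

    Sampling uses bilinear interpolation; the band is averaged over sub-pixel
    offsets spanning line_width centered on the outline. The first sample is
    the outline point in the ``ap_axis`` direction from the centroid, so the
    profile phase is geometric and independent of vertex list order.
    ``arc_positions`` are in px, or microns when ``pixel_scale`` (um/px) is
    given.
    """
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3")
    if line_width <= 0:
        raise ValueError("line_width must be positive")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be a single-channel 2-D array")

    outline = outline.oriented_clockwise()
    total = outline.perimeter
    t0 = _phase_origin_arc(outline, np.asarray(ap_axis, dtype=float))
    # sample k (1-based) sits at arc fraction k/N from the phase origin,
    # matching theta_k = 2*pi*k/N in the harmonic statistics
    arcs = t0 + total * np.arange(1, n_samples + 1) / n_samples
    pts = _resample_closed_points(outline.vertices, arcs)

    # tangent by central differences of neighbouring resample points
    eps = total / (8.0 * n_samples)
    ahead = _resample_closed_points(outline.vertices, arcs + eps)
    behind = _resample_closed_points(outline.vertices, arcs - eps)
    tang = ahead - behind
    tnorm = np.hypot(tang[:, 0], tang[:, 1])
    tnorm[tnorm == 0] = 1.0
    tang /= tnorm[:, None]
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])

    n_off = max(3, int(np.ceil(line_width / 0.5)) | 1)  # odd count, ~0.5 px spacing
    offsets = np.linspace(-line_width / 2.0, line_width / 2.0, n_off)
    # coordinates (n_samples, n_off, 2)
    coords = pts[:, None, :] + offsets[None, :, None] * normal[:, None, :]
    xs = coords[..., 0]
    ys = coords[..., 1]
    h, w = img.shape
    if xs.min() < 0 or ys.min() < 0 or xs.max() > w - 1 or ys.max() > h - 1:
        raise ValueError("sampling band exits the image bounds")
    sampled = ndimage.map_coordinates(img, [ys.ravel(), xs.ravel()], order=1, mode="nearest")
    values = sampled.reshape(n_samples, n_off).mean(axis=1)
    values = np.clip(values, 0.0, None)

    arc_pos = total * np.arange(1, n_samples + 1) / n_samples
    if pixel_scale is not None:
        arc_pos = arc_pos * pixel_scale
    return IntensityProfile(values=values, arc_positions=arc_pos, normalized=False)


# ---------------------------------------------------------------------------
# correction and normalization
# ---------------------------------------------------------------------------

def background_correct(profile: IntensityProfile, background: float) -> IntensityProfile:
    """Subtract a background grey value, flooring at zero."""
    if background < 0:
        raise ValueError("background must be >= 0")
    return replace(profile, values=np.clip(profile.values - background, 0.0, None))


def normalize_profile(profile: IntensityProfile) -> IntensityProfile:
    """Divide by the mean grey value (I_k = grey value k / mean of grey values)."""
    m = profile.values.mean()
    if m <= 0:
        raise DegenerateProfileError("all-zero profile: polarity undefined")
    return replace(profile, values=profile.values / m, normalized=True)


def estimate_background(image: np.ndarray, mask: np.ndarray) -> float:
    """Median grey value outside a 3-px dilation of the cell mask."""
    img = np.asarray(image, dtype=float)
    m = np.asarray(mask).astype(bool)
    if img.shape != m.shape:
        raise ValueError("image and mask shapes differ")
    dilated = morphology.dilation(m, morphology.disk(3))
    exterior = img[~dilated]
    if exterior.size == 0:
        raise ValueError("no exterior pixels to estimate background from")
    return float(np.median(exterior))
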