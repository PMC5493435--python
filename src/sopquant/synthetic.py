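"""Synthetic fluorescence data with the statistical structure the analysis assumes.

Real inputs to this pipeline are single-channel micrographs of mitotic
sensory organ precursor (SOP) cells, manually traced outlines, and per-fly
bristle-defect tallies.  None of these ship with the package, so this module
generates stand-ins with controllable ground truth:

* an elliptical cell with a cortical intensity ring modulated by a unimodal
  crescent of adjustable angular concentration (``generate_cell_image``),
* cortical intensity profiles drawn directly from the same crescent law,
  bypassing imaging (``generate_profile``),
* populations of asymmetric division events with wrapped-normal division
  angles and Beta-distributed daughter-intensity asymmetry
  (``generate_division_population``),
* genotype x defect-category count tables from multinomial draws
  (``generate_contingency``).

The crescent law is a von-Mises-shaped bump normalized to its peak:

    I(theta) = baseline + amplitude * exp(kappa * (cos(theta - mu) - 1))

so ``kappa = 0`` gives an angularly uniform ring (the null for the
polarization coefficient) and large ``kappa`` a tight crescent at ``mu``.
Angles are measured from the anterior-posterior axis, positive clockwise in
the viewer's frame (y-down image coordinates), matching the division-angle
convention used throughout the package.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SyntheticCellSpec",
    "DivisionPopulationSpec",
    "GeometryError",
    "crescent_law",
    "generate_cell_image",
    "generate_profile",
    "generate_division_population",
    "generate_population_profiles",
    "generate_contingency",
]


class GeometryError(ValueError):
    """Raised when a cell geometry cannot be rasterized inside its image."""


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"{name} must be >= 0, got {value!r}")


@dataclass(frozen=True)
class SyntheticCellSpec:
    """Full parameterization of one synthetic SOP cell image.

    Grey values are in arbitrary camera units; geometry in pixels. Defaults
    emulate a ~60 px diameter mitotic cell imaged at 16 bit with a bright
    cortical ring over dimmer cytoplasm and dark background.
    """

    image_size: tuple[int, int] = (128, 128)  # (height, width)
    center: tuple[float, float] = (64.0, 64.0)  # (x, y), subpixel
    semi_axes: tuple[float, float] = (32.0, 26.0)  # (major, minor), px
    ring_width: float = 6.0  # wide enough that a 3 px sampling band stays on the ring
    crescent_center_angle: float = 0.0  # degrees in (-180, 180]
    crescent_kappa: float = 0.0  # angular concentration, >= 0
    crescent_amplitude: float = 0.0
    cortex_baseline: float = 300.0
    cytoplasm_level: float = 100.0
    background_level: float = 20.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 4 or w < 4:
            raise ValueError("image_size must be at least 4x4 pixels")
        a, b = self.semi_axes
        if a <= 0 or b <= 0 or self.ring_width <= 0:
            raise ValueError("semi_axes and ring_width must be positive")
        if min(a, b) < 2.0 * self.ring_width:
            raise ValueError(
                "both semi_axes must be >= 2*ring_width "
                f"(got semi_axes={self.semi_axes}, ring_width={self.ring_width})"
            )
        if not (-180.0 < self.crescent_center_angle <= 180.0):
            raise ValueError("crescent_center_angle must lie in (-180, 180]")
        for name in (
            "crescent_kappa",
            "crescent_amplitude",
            "cortex_baseline",
            "cytoplasm_level",
            "background_level",
            "noise_sd",
        ):
            _check_nonneg(name, getattr(self, name))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class DivisionPopulationSpec:
    """Parameters of a synthetic population of asymmetric divisions.

    Defaults mirror the study conditions of the wild-type group: n = 60
    divisions per genotype, division angles wrapped-normal around the
    anterior-posterior axis with SD ~35 degrees, strongly asymmetric
    daughter-intensity segregation, and a tight cortical crescent
    (``polarization_kappa``) for the companion profile generator.

    ``segregation_shape`` are the (alpha, beta) parameters of the Beta
    distribution of the min/max daughter intensity ratio; its mean is
    alpha / (alpha + beta).
    """

    n_cells: int = 60
    angle_mean: float = 0.0
    angle_sd: float = 35.0  # wrapped-normal dispersion, degrees
    segregation_shape: tuple[float, float] = (2.0, 8.0)
    polarization_kappa: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.angle_sd < 0:
            raise ValueError("angle_sd must be >= 0")
        a, b = self.segregation_shape
        if a <= 0 or b <= 0:
            raise ValueError("segregation_shape parameters must be positive")
        if self.polarization_kappa < 0:
            raise ValueError("polarization_kappa must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def crescent_law(
    theta: np.ndarray,
    kappa: float,
    amplitude: float,
    baseline: float,
    center_angle_deg: float = 0.0,
) -> np.ndarray:
    """Expected cortical intensity at angular position ``theta`` (radians).

    ``baseline + amplitude * exp(kappa*(cos(theta - mu) - 1))``: a von-Mises
    bump normalized to peak at ``baseline + amplitude``; kappa = 0 is the
    uniform limit ``baseline + amplitude`` everywhere.
    """
    mu = np.deg2rad(center_angle_deg)
    return baseline + amplitude * np.exp(kappa * (np.cos(theta - mu) - 1.0))


# ---------------------------------------------------------------------------
# image generation
# ---------------------------------------------------------------------------

def generate_cell_image(spec: SyntheticCellSpec) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize one elliptical cell with a crescent-modulated cortical ring.

    Returns ``(image, mask)``: a float64 grey-value image and a boolean mask
    of the cell region (interior of the ellipse centerline of the ring).

    The ring is drawn by first-order signed-distance thresholding with a
    one-pixel linear anti-aliased edge, which keeps the ring centerline
    intensity within interpolation tolerance of the closed-form crescent law.
    Noise is additive Gaussian (sd = ``noise_sd``) clipped at zero.
    """
    h, w = spec.image_size
    cx, cy = spec.center
    A, B = spec.semi_axes
    half = spec.ring_width / 2.0

    # reject rings that leave the image (including the anti-alias margin)
    margin = half + 1.0
    if (
        cx - A - margin < 0
        or cx + A + margin > w - 1
        or cy - B - margin < 0
        or cy + B + margin > h - 1
    ):
        raise GeometryError(
            "cortical ring extends outside the image: "
            f"center={spec.center}, semi_axes={spec.semi_axes}, "
            f"ring_width={spec.ring_width}, image_size={spec.image_size}"
        )

    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - cx
    dy = yy - cy
    # first-order signed distance to the ellipse: (r_norm - 1) / |grad r_norm|
    r = np.sqrt((dx / A) ** 2 + (dy / B) ** 2)
    grad = np.sqrt((dx / A**2) ** 2 + (dy / B**2) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        sdist = np.where(grad > 0, (r - 1.0) / grad, -min(A, B))

    theta = np.arctan2(dy, dx)  # y-down frame: positive = clockwise on screen
    ring_value = crescent_law(
        theta,
        spec.crescent_kappa,
        spec.crescent_amplitude,
        spec.cortex_baseline,
        spec.crescent_center_angle,
    )

    # linear anti-aliasing over 1 px at each of the three region boundaries
    def smooth_step(d: np.ndarray) -> np.ndarray:
        # 0 where d <= -0.5, 1 where d >= 0.5, linear in between
        return np.clip(d + 0.5, 0.0, 1.0)

    w_out = smooth_step(sdist - half)          # 1 outside the ring's outer edge
    w_in = smooth_step(-(sdist + half))        # 1 inside the ring's inner edge
    w_ring = np.clip(1.0 - w_out - w_in, 0.0, 1.0)

    image = (
        w_in * spec.cytoplasm_level
        + w_ring * ring_value
        + w_out * spec.background_level
    )

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, None)

    mask = sdist <= 0.0
    return image, mask


# ---------------------------------------------------------------------------
# direct profile generation
# ---------------------------------------------------------------------------

def generate_profile(
    n_samples: int,
    crescent_kappa: float,
    crescent_amplitude: float,
    baseline: float,
    noise_sd: float,
    seed: int,
    crescent_center_angle: float = 0.0,
):
    """Draw one cortical intensity profile from the crescent law plus noise.

    Samples sit at theta_k = 2*pi*k/n_samples for k = 1..n_samples, matching
    the angular convention of the harmonic statistics. Returns an
    unnormalized :class:`~sopquant.profiles.IntensityProfile`.
    """
    from .profiles import IntensityProfile

    if n_samples < 3:
        raise ValueError("n_samples must be >= 3 (harmonics undefined below)")
    _check_nonneg("crescent_kappa", crescent_kappa)
    _check_nonneg("crescent_amplitude", crescent_amplitude)
    _check_nonneg("baseline", baseline)
    _check_nonneg("noise_sd", noise_sd)

    k = np.arange(1, n_samples + 1)
    theta = 2.0 * np.pi * k / n_samples
    values = crescent_law(
        theta, crescent_kappa, crescent_amplitude, baseline, crescent_center_angle
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=n_samples)
    values = np.clip(values, 0.0, None)
    return IntensityProfile(values=values, arc_positions=theta.copy(), normalized=False)


# ---------------------------------------------------------------------------
# division populations
# ---------------------------------------------------------------------------

def _wrap_degrees(angles: np.ndarray) -> np.ndarray:
    """Map degrees into (-180, 180]."""
    wrapped = np.mod(-np.asarray(angles, dtype=float) + 180.0, 360.0)
    return 180.0 - wrapped


def generate_division_population(spec: DivisionPopulationSpec):
    """Draw ``n_cells`` asymmetric division records.

    Division angles are wrapped-normal(angle_mean, angle_sd) mapped into
    (-180, 180]. Daughter intensities are built from a Beta-distributed
    min/max ratio: the brighter daughter's intensity is drawn around 100
    grey values (10% lognormal scatter) and the dimmer one is ratio times
    that. Records carry the daughter displacement axis realizing the drawn
    angle against the reference A-P axis (1, 0).
    """
    from .divisions import DivisionRecord

    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    angles = _wrap_degrees(rng.normal(spec.angle_mean, spec.angle_sd, size=n))
    a, b = spec.segregation_shape
    ratios = rng.beta(a, b, size=n)
    # avoid the measure-zero both-zero degenerate record
    bright = 100.0 * np.exp(rng.normal(0.0, 0.1, size=n))
    dim = ratios * bright

    records = []
    for i in range(n):
        ang = np.deg2rad(angles[i])
        # y-down frame: clockwise-positive angle from (1, 0) has +sin on y
        axis = (float(np.cos(ang)), float(np.sin(ang)))
        records.append(
            DivisionRecord(
                cell_id=f"cell{i:04d}",
                intensity_a=float(bright[i]),
                intensity_b=float(dim[i]),
                daughter_axis=axis,
                ap_axis=(1.0, 0.0),
            )
        )
    return records


def generate_population_profiles(
    spec: DivisionPopulationSpec,
    n_samples: int = 100,
    crescent_amplitude: float = 1000.0,
    baseline: float = 100.0,
    noise_sd: float = 30.0,
):
    """Per-cell cortical profiles for a division population.

    Uses ``spec.polarization_kappa`` as the crescent concentration of every
    cell; the crescent center angle is tied to each record's division angle
    in spirit but drawn independently here (the harmonic magnitudes are
    phase-invariant, so the center does not affect P). Noise defaults to
    30% of the cytoplasmic baseline, a realistic live-imaging level.
    """
    rng = np.random.default_rng(spec.seed + 1)
    profiles = []
    for _ in range(spec.n_cells):
        center = float(rng.uniform(-180.0, 180.0))
        profiles.append(
            generate_profile(
                n_samples,
                spec.polarization_kappa,
                crescent_amplitude,
                baseline,
                noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
                crescent_center_angle=center,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------

def generate_contingency(
    category_probs,
    n_per_group,
    seed: int = 0,
    row_labels=None,
    col_labels=None,
):
    """Multinomial defect-category counts per genotype, assembled row-wise.

    ``category_probs`` is a sequence of probability vectors (one per group,
    each summing to 1); ``n_per_group`` the number of scored individuals per
    group (e.g. 100 wings per genotype).
    """
    from .group_stats import ContingencyTable

    probs = [np.asarray(p, dtype=float) for p in category_probs]
    ns = np.asarray(n_per_group, dtype=int)
    if len(probs) != len(ns):
        raise ValueError("category_probs and n_per_group must have equal length")
    c = len(probs[0])
    for p in probs:
        if len(p) != c:
            raise ValueError("all probability vectors must have equal length")
        if np.any(p < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("each probability vector must sum to 1")
    if np.any(ns < 0):
        raise ValueError("counts must be nonnegative")

    rng = np.random.default_rng(seed)
    rows = [rng.multinomial(int(n), p) for n, p in zip(ns, probs)]
    counts = np.vstack(rows).astype(int)
    if row_labels is None:
        row_labels = [f"group{i}" for i in range(len(probs))]
    if col_labels is None:
        col_labels = [f"cat{j}" for j in range(c)]
    return ContingencyTable(counts=counts, row_labels=list(row_labels), col_labels=list(col_labels))
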