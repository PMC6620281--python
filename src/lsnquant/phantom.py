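"""Synthetic abdominal-slice phantoms with a controllable surface nodularity.

A phantom is a bright, star-convex "liver" on a darker background, modulated
by a smooth multiplicative bias field and additive Gaussian noise.  The
boundary radius is

    r(theta) = r0(theta) + A * sum_k bump(theta; theta_k, width)

where ``r0`` is a low-order Fourier perturbation of a circle and the bumps
are wrapped Gaussians whose centres are drawn from a seeded generator.  The
amplitude ``A`` (in pixels) is the single ground-truth nodularity knob: all
dose-response tests downstream vary only ``A``.

Everything is a pure function of :class:`PhantomSpec`; the same spec yields
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import polygon2mask

from .errors import DomainError

__all__ = [
    "PhantomSpec",
    "PhantomData",
    "generate_boundary",
    "make_bias_field",
    "generate_phantom",
]

#: number of angular samples used when tracing the analytic boundary
N_ANGLES = 1024

#: documented constant c in the planar-ramp max/min ratio (1+beta)/(1-beta*c)
PLANAR_RAMP_C = 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic slice; hashable and immutable."""

    image_height: int = 128
    image_width: int = 128
    pixel_spacing: float = 1.0
    center: tuple[float, float] = (64.0, 64.0)  # (row, col), pixels
    base_radius: float = 40.0
    fourier_coeffs: tuple[float, ...] = ()  # pairs (a1, b1, a2, b2, ...), order <= 4
    nodularity_amplitude: float = 0.0  # A, pixels
    nodule_count: int = 12
    nodule_width: float = 0.15  # radians
    liver_intensity: float = 180.0
    background_intensity: float = 70.0
    bias_contrast: float = 0.0  # beta >= 0
    bias_kind: str = "none"  # planar_ramp | gaussian_bump | none
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_radius <= 0:
            raise DomainError("base_radius must be positive")
        if self.nodularity_amplitude < 0:
            raise DomainError("nodularity_amplitude must be >= 0")
        if self.liver_intensity == self.background_intensity:
            raise DomainError("liver_intensity must differ from background_intensity")
        if self.bias_contrast < 0:
            raise DomainError("bias_contrast must be >= 0")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")
        if self.bias_kind not in ("planar_ramp", "gaussian_bump", "none"):
            raise DomainError(f"unknown bias_kind {self.bias_kind!r}")
        if len(self.fourier_coeffs) > 8:
            raise DomainError("fourier_coeffs limited to order 4 (8 values)")


@dataclass
class PhantomData:
    """A generated phantom together with every piece of ground truth."""

    image: np.ndarray
    true_mask: np.ndarray
    true_boundary: np.ndarray  # (n, 2) array of sub-pixel (row, col), cyclic
    true_bias: np.ndarray
    spec: PhantomSpec = field(repr=False)


def _radius_profile(spec: PhantomSpec, theta: np.ndarray) -> np.ndarray:
    """Evaluate r(theta) = r0(theta) + A * bumps(theta)."""
    r0 = np.ones_like(theta)
    coeffs = spec.fourier_coeffs
    for k in range(0, len(coeffs), 2):
        order = k // 2 + 1
        a = coeffs[k]
        b = coeffs[k + 1] if k + 1 < len(coeffs) else 0.0
        r0 += a * np.cos(order * theta) + b * np.sin(order * theta)
    r = spec.base_radius * r0

    if spec.nodularity_amplitude > 0 and spec.nodule_count > 0:
        rng = np.random.default_rng(spec.seed)
        centers = rng.uniform(0.0, 2.0 * np.pi, size=spec.nodule_count)
        w = spec.nodule_width
        bumps = np.zeros_like(theta)
        for tk in centers:
            # wrap the Gaussian bump around the circle
            for m in (-2.0 * np.pi, 0.0, 2.0 * np.pi):
                bumps += np.exp(-0.5 * ((theta - tk + m) / w) ** 2)
        r = r + spec.nodularity_amplitude * bumps
    return r


def base_radius_profile(spec: PhantomSpec, theta: np.ndarray) -> np.ndarray:
    """The smooth (A = 0) radius profile, for ground-truth comparisons."""
    return _radius_profile(replace(spec, nodularity_amplitude=0.0), theta)


def generate_boundary(spec: PhantomSpec, n_angles: int = N_ANGLES) -> np.ndarray:
    """Sample the closed, positively oriented boundary polygon.

    Returns an ``(n_angles, 2)`` array of sub-pixel ``(row, col)`` points.
    The polyline is cyclic: the last point connects back to the first.
    Orientation is counter-clockwise in the sense of a positive shoelace
    area in ``(col, row)`` coordinates, matching the surface tracer.
    """
    if spec.base_radius < 5:
        raise DomainError("base_radius must be >= 5 pixels")
    theta = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    r = _radius_profile(spec, theta)
    if np.any(r <= 0):
        raise DomainError("radius profile collapsed to zero; reduce coefficients")
    cr, cc = spec.center
    rows = cr + r * np.sin(theta)
    cols = cc + r * np.cos(theta)

    margin = 2.0
    if rows.min() < margin:
        raise DomainError(f"boundary violates top margin: min row {rows.min():.2f} < {margin}")
    if rows.max() > spec.image_height - 1 - margin:
        raise DomainError(
            f"boundary violates bottom margin: max row {rows.max():.2f} > "
            f"{spec.image_height - 1 - margin}")
    if cols.min() < margin:
        raise DomainError(f"boundary violates left margin: min col {cols.min():.2f} < {margin}")
    if cols.max() > spec.image_width - 1 - margin:
        raise DomainError(
            f"boundary violates right margin: max col {cols.max():.2f} > "
            f"{spec.image_width - 1 - margin}")
    return np.column_stack([rows, cols])


def make_bias_field(spec: PhantomSpec) -> np.ndarray:
    """Smooth positive multiplicative field, rescaled to mean 1 over the image.

    planar_ramp : linear in the column index, raw range [1-beta, 1+beta]
                  (so max/min = (1+beta)/(1-beta), i.e. c = 1).
    gaussian_bump : 1 + beta * exp(-d^2 / (2 s^2)) centred on ``spec.center``
                  with s = min(H, W) / 4.
    none : all ones.
    """
    h, w = spec.image_height, spec.image_width
    beta = spec.bias_contrast
    if spec.bias_kind == "none" or beta == 0.0:
        return np.ones((h, w))
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    if spec.bias_kind == "planar_ramp":
        raw = 1.0 + beta * (2.0 * cols / (w - 1) - 1.0)
    elif spec.bias_kind == "gaussian_bump":
        cr, cc = spec.center
        s = min(h, w) / 4.0
        raw = 1.0 + beta * np.exp(-((rows - cr) ** 2 + (cols - cc) ** 2) / (2.0 * s * s))
    else:  # pragma: no cover - guarded in PhantomSpec
        raise DomainError(f"unknown bias_kind {spec.bias_kind!r}")
    if np.any(raw <= 0):
        raise DomainError(f"bias_contrast {beta} produces non-positive field values")
    return raw / raw.mean()


def gaussian_bump_bias_closed_form(spec: PhantomSpec, row: float, col: float) -> float:
    """Pointwise analytic value of the gaussian_bump field before normalisation."""
    cr, cc = spec.center
    s = min(spec.image_height, spec.image_width) / 4.0
    return 1.0 + spec.bias_contrast * np.exp(
        -((row - cr) ** 2 + (col - cc) ** 2) / (2.0 * s * s))


def generate_phantom(spec: PhantomSpec) -> PhantomData:
    """Rasterise the boundary and compose bias x piecewise-constant + noise.

    The noise stream is drawn from a generator seeded with ``spec.seed + 1``
    so that it is independent of the bump-centre stream.
    """
    boundary = generate_boundary(spec)
    shape = (spec.image_height, spec.image_width)
    mask = polygon2mask(shape, boundary)
    bias = make_bias_field(spec)
    truth = np.where(mask, spec.liver_intensity, spec.background_intensity)
    image = bias * truth
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed + 1)
        image = image + rng.normal(0.0, spec.noise_sd, size=shape)
    return PhantomData(image=image, true_mask=mask, true_boundary=boundary,
                       true_bias=bias, spec=spec)
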