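"""Augmentations that act jointly and consistently on (IT, phi, r).

3D-PLI parameter maps are derived quantities of an underlying sinusoidal
intensity profile, so they cannot be transformed independently like ordinary
image channels:

* Photometric changes are modeled physically, by scaling the attenuation
  coefficient (``IT' = I0 (IT/I0)**gamma_a``) or the birefringent thickness
  (``r' = |sin(gamma_t arcsin r)|`` together with the matching transmittance
  change).
* Spatial resampling of a weighted pixel neighborhood is performed on the
  Fourier representation of the profile: the transmittance averages linearly,
  while retardation and direction average as the transmittance-weighted
  complex field ``r * IT * exp(i 2 phi)``, whose magnitude and half-phase give
  the resampled (r', phi').
* Any transform that changes pixel geometry additionally requires a direction
  correction: unit direction vectors are pushed through the (constant, for
  affine maps) Jacobian and re-expressed modulo pi, *before* the pixel grid is
  warped.

All operations are pure functions of (input, parameters, rng).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .physics import ParameterMaps, wrap_direction

__all__ = [
    "AugmentationPolicy",
    "scale_attenuation",
    "scale_thickness",
    "resample",
    "correct_direction",
    "rotate_direction",
    "affine_matrix",
    "affine_augment",
    "flip_augment",
    "gaussian_blur",
    "center_crop",
    "random_policy_apply",
]


# ---------------------------------------------------------------------------
# Photometric (signal-parameter) augmentations
# ---------------------------------------------------------------------------

def scale_attenuation(maps: ParameterMaps, gamma_a: float, incident_intensity: float = 1.0) -> ParameterMaps:
    """Scale the attenuation coefficient by ``gamma_a``.

    Under the Bouguer-Lambert law, ``mu -> gamma_a * mu`` maps the
    transmittance to ``IT' = I0 * (IT/I0)**gamma_a``; direction and
    retardation are untouched.
    """
    if gamma_a <= 0:
        raise ValueError("gamma_a must be positive")
    it = incident_intensity * (maps.transmittance / incident_intensity) ** gamma_a
    return ParameterMaps(it, maps.direction, maps.retardation, maps.pixel_size_um)


def scale_thickness(maps: ParameterMaps, gamma_t: float, incident_intensity: float = 1.0) -> ParameterMaps:
    """Scale the birefringent section thickness by ``gamma_t``.

    Thickness enters the phase linearly (delta' = gamma_t * delta), so
    ``r' = |sin(gamma_t * arcsin(r))|``; the magnitude keeps r in [0, 1] when
    the scaled phase leaves the principal branch, consistent with retardation
    being the magnitude |sin delta|.  The transmittance scales like an
    attenuation change with the same exponent.
    """
    if gamma_t <= 0:
        raise ValueError("gamma_t must be positive")
    r = np.abs(np.sin(gamma_t * np.arcsin(np.clip(maps.retardation, 0.0, 1.0))))
    it = incident_intensity * (maps.transmittance / incident_intensity) ** gamma_t
    return ParameterMaps(it, maps.direction, r, maps.pixel_size_um)


# ---------------------------------------------------------------------------
# Resampling on the Fourier representation
# ---------------------------------------------------------------------------

def _complex_field(maps: ParameterMaps) -> np.ndarray:
    """Transmittance-weighted orientation field r * IT * exp(i 2 phi)."""
    return maps.retardation * maps.transmittance * np.exp(2j * maps.direction)


def _decompose(it: np.ndarray, field: np.ndarray, pixel_size_um: float) -> ParameterMaps:
    """Recover (r, phi) from a resampled complex field and transmittance."""
    zero = it <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(zero, 0.0, np.abs(field) / np.where(zero, 1.0, it))
    phi = np.where(zero | (np.abs(field) == 0), 0.0, wrap_direction(0.5 * np.angle(field)))
    return ParameterMaps(np.where(zero, 0.0, it), phi, np.clip(r, 0.0, 1.0), pixel_size_um)


def resample(maps: ParameterMaps, weights: np.ndarray) -> ParameterMaps:
    """Resample parameter maps with explicit per-target weight stencils.

    ``weights`` has shape ``(n_out, n_src)`` where ``n_src`` equals the number
    of pixels of the input maps (flattened in C order); each row must be
    non-negative and sum to 1.  Output maps are 1-D with ``n_out`` pixels:
    transmittance is the weighted mean, and (r, phi) come from the weighted
    complex average normalized by the output transmittance.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 2 or weights.shape[1] != maps.transmittance.size:
        raise ValueError("weights must have shape (n_out, n_source_pixels)")
    if np.any(weights < 0) or not np.allclose(weights.sum(axis=1), 1.0):
        raise ValueError("each stencil must be non-negative and sum to 1")
    it = weights @ maps.transmittance.ravel()
    field = weights @ _complex_field(maps).ravel()
    return _decompose(it, field, maps.pixel_size_um)


# ---------------------------------------------------------------------------
# Direction correction
# ---------------------------------------------------------------------------

def correct_direction(phi: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Push direction angles through the Jacobian of an in-plane affine map.

    Directions are converted to unit vectors ``d = (cos phi, sin phi)`` in the
    (x, y) frame, mapped as ``d' = A d`` and re-expressed modulo pi.  For a
    pure rotation this reduces to ``phi' = phi + theta``; for a reflection
    ``diag(-1, 1)`` it gives ``phi' = -phi (mod pi)``.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (2, 2):
        raise ValueError("expected a 2x2 Jacobian matrix")
    if abs(np.linalg.det(matrix)) < 1e-12:
        raise ValueError("singular Jacobian")
    dx = np.cos(phi)
    dy = np.sin(phi)
    dxp = matrix[0, 0] * dx + matrix[0, 1] * dy
    dyp = matrix[1, 0] * dx + matrix[1, 1] * dy
    return wrap_direction(np.arctan2(dyp, dxp))


def rotate_direction(phi: np.ndarray, theta: float) -> np.ndarray:
    """Closed form of the direction correction for a rotation by ``theta``."""
    return wrap_direction(phi + theta)


# ---------------------------------------------------------------------------
# Geometric transforms and blur
# ---------------------------------------------------------------------------

def affine_matrix(
    scale: tuple[float, float] = (1.0, 1.0),
    rotation: float = 0.0,
    shear: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Compose a 2x2 affine matrix ``R(rotation) @ Shear @ diag(scale)``.

    Angles in radians; scale/shear are per (x, y) axis, shear entries are the
    angles whose tangents fill the off-diagonals.
    """
    sx, sy = scale
    shx, shy = shear
    c, s = np.cos(rotation), np.sin(rotation)
    rot = np.array([[c, -s], [s, c]])
    sh = np.array([[1.0, np.tan(shx)], [np.tan(shy), 1.0]])
    return rot @ sh @ np.diag([sx, sy])


def _xy_to_rc(matrix: np.ndarray) -> np.ndarray:
    """Re-express a matrix acting on (x, y) vectors in (row, col) order."""
    swap = np.array([[0.0, 1.0], [1.0, 0.0]])
    return swap @ matrix @ swap


def _warp(arr: np.ndarray, matrix: np.ndarray, offset: np.ndarray) -> np.ndarray:
    return ndimage.affine_transform(arr, matrix, offset=offset, order=1, mode="constant", cval=0.0)


def affine_augment(maps: ParameterMaps, matrix: np.ndarray, translation: tuple[float, float] = (0.0, 0.0)) -> ParameterMaps:
    """Apply an in-plane affine transform ``p -> A (p - c) + c + t``.

    The transform is taken about the image center ``c`` with ``p = (x, y)``
    pixel coordinates and translation ``t`` in pixels.  Directions are
    corrected through the Jacobian ``A`` before the grid is warped; pixel
    values are resampled with bilinear stencils on (IT, r IT e^{i 2 phi}),
    zero-padded outside the field (callers crop away padding).
    """
    matrix = np.asarray(matrix, dtype=float)
    if abs(np.linalg.det(matrix)) < 1e-12:
        raise ValueError("degenerate affine matrix")
    phi_corr = correct_direction(maps.direction, matrix)
    corrected = ParameterMaps(maps.transmittance, phi_corr, maps.retardation, maps.pixel_size_um)

    h, w = maps.shape
    center_xy = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    inv_xy = np.linalg.inv(matrix)
    # scipy's affine_transform computes input_index = M @ output_index + offset
    m_rc = _xy_to_rc(inv_xy)
    t_xy = np.asarray(translation, dtype=float)
    offset_xy = center_xy - inv_xy @ (center_xy + t_xy)
    offset_rc = offset_xy[::-1]

    it = _warp(corrected.transmittance, m_rc, offset_rc)
    field = _complex_field(corrected)
    field_w = _warp(field.real, m_rc, offset_rc) + 1j * _warp(field.imag, m_rc, offset_rc)
    return _decompose(np.maximum(it, 0.0), field_w, maps.pixel_size_um)


def flip_augment(maps: ParameterMaps, axis: int) -> ParameterMaps:
    """Mirror the maps along image axis 0 (rows/y) or 1 (cols/x).

    Pixel flipping is exact (no interpolation); the direction correction is
    the Jacobian push-through for the corresponding reflection matrix, which
    for either axis amounts to ``phi -> -phi (mod pi)``.
    """
    if axis not in (0, 1):
        raise ValueError("axis must be 0 (vertical) or 1 (horizontal)")
    reflection = np.diag([-1.0, 1.0]) if axis == 1 else np.diag([1.0, -1.0])
    phi = correct_direction(maps.direction, reflection)
    return ParameterMaps(
        np.flip(maps.transmittance, axis=axis).copy(),
        np.flip(phi, axis=axis).copy(),
        np.flip(maps.retardation, axis=axis).copy(),
        maps.pixel_size_um,
    )


def gaussian_blur(maps: ParameterMaps, sigma: float, truncate: float = 4.0) -> ParameterMaps:
    """Gaussian blur with stencil weights that sum to one (reflect boundary).

    Blurring is a resampling with Gaussian stencils, applied to the
    transmittance and the complex orientation field; constant fields are exact
    fixed points and sigma = 0 is the identity.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return maps.copy()
    blur = lambda a: ndimage.gaussian_filter(a, sigma, mode="reflect", truncate=truncate)
    it = blur(maps.transmittance)
    field = _complex_field(maps)
    field_b = blur(field.real) + 1j * blur(field.imag)
    return _decompose(it, field_b, maps.pixel_size_um)


def center_crop(maps: ParameterMaps, crop_px: int) -> ParameterMaps:
    h, w = maps.shape
    if crop_px > h or crop_px > w:
        raise ValueError("crop larger than image")
    y0 = (h - crop_px) // 2
    x0 = (w - crop_px) // 2
    sl = (slice(y0, y0 + crop_px), slice(x0, x0 + crop_px))
    return ParameterMaps(
        maps.transmittance[sl].copy(),
        maps.direction[sl].copy(),
        maps.retardation[sl].copy(),
        maps.pixel_size_um,
    )


# ---------------------------------------------------------------------------
# Random policy
# ---------------------------------------------------------------------------

@dataclass
class AugmentationPolicy:
    """Ranges of the randomized training augmentation pipeline.

    The photometric exponents are drawn log-uniformly with base 2
    (``gamma = 2**u`` with ``u ~ U(range)``); affine parameters are drawn
    uniformly per axis.  Defaults follow the training protocol for
    contrastive learning on 3D-PLI patches.
    """

    gamma_a_log2_range: tuple[float, float] = (-1.0, 1.0)
    gamma_t_log2_range: tuple[float, float] = (-1.0, 1.0)
    scale_range: tuple[float, float] = (0.9, 1.3)
    rotation_range_deg: tuple[float, float] = (-180.0, 180.0)
    shear_range_deg: tuple[float, float] = (-20.0, 20.0)
    flip_prob: float = 0.5
    blur_prob: float = 0.5
    blur_sigma_range: tuple[float, float] = (0.0, 2.0)
    crop_px: int = 128
    incident_intensity: float = 1.0

    def __post_init__(self) -> None:
        for lo, hi in (
            self.gamma_a_log2_range,
            self.gamma_t_log2_range,
            self.scale_range,
            self.rotation_range_deg,
            self.shear_range_deg,
            self.blur_sigma_range,
        ):
            if lo > hi:
                raise ValueError("range endpoints must be ordered")
        if not (0.0 <= self.flip_prob <= 1.0 and 0.0 <= self.blur_prob <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.crop_px <= 0:
            raise ValueError("crop_px must be positive")

    @classmethod
    def identity(cls, crop_px: int = 128) -> "AugmentationPolicy":
        """Degenerate policy whose only effect is the center crop."""
        return cls(
            gamma_a_log2_range=(0.0, 0.0),
            gamma_t_log2_range=(0.0, 0.0),
            scale_range=(1.0, 1.0),
            rotation_range_deg=(0.0, 0.0),
            shear_range_deg=(0.0, 0.0),
            flip_prob=0.0,
            blur_prob=0.0,
            blur_sigma_range=(0.0, 0.0),
            crop_px=crop_px,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AugmentationPolicy":
        raw = yaml.safe_load(Path(path).read_text())
        tuple_keys = {
            "gamma_a_log2_range",
            "gamma_t_log2_range",
            "scale_range",
            "rotation_range_deg",
            "shear_range_deg",
            "blur_sigma_range",
        }
        return cls(**{k: tuple(v) if k in tuple_keys else v for k, v in raw.items()})


def random_policy_apply(maps: ParameterMaps, policy: AugmentationPolicy, rng: np.random.Generator) -> ParameterMaps:
    """Draw one augmentation per policy entry and apply the full pipeline.

    Order: random affine (bilinear resampling) -> center crop (discarding
    padding) -> random flips -> thickness scaling -> attenuation scaling ->
    Gaussian blur with probability ``blur_prob``.
    """
    scale = tuple(rng.uniform(*policy.scale_range, size=2))
    rotation = np.deg2rad(rng.uniform(*policy.rotation_range_deg))
    shear = tuple(np.deg2rad(rng.uniform(*policy.shear_range_deg, size=2)))
    matrix = affine_matrix(scale=scale, rotation=rotation, shear=shear)
    out = affine_augment(maps, matrix)
    out = center_crop(out, policy.crop_px)
    for axis in (0, 1):
        if rng.uniform() < policy.flip_prob:
            out = flip_augment(out, axis)
    gamma_t = 2.0 ** rng.uniform(*policy.gamma_t_log2_range)
    out = scale_thickness(out, gamma_t, policy.incident_intensity)
    gamma_a = 2.0 ** rng.uniform(*policy.gamma_a_log2_range)
    out = scale_attenuation(out, gamma_a, policy.incident_intensity)
    if rng.uniform() < policy.blur_prob:
        out = gaussian_blur(out, rng.uniform(*policy.blur_sigma_range))
    return out
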