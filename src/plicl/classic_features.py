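"""Classical texture descriptors on (IT, |sin delta|, phi-hat) tiles.

Because the raw direction map encodes *absolute* in-plane orientation, it is
first converted to an orientation-gradient magnitude ``phi_hat``: direction
angles are doubled and written as unit complex numbers
``z = cos(2 phi) + i sin(2 phi)``, both Sobel kernels are applied to the
complex field, and the response is aggregated as ``|Gx + Gy| / 12``, where 12
(the sum of |Kx + Ky| entries) normalizes the output to [0, 1].  Constant
direction fields give exactly zero.

On each tile, three descriptor families are computed for the three maps
(transmittance normalized to [0, 1], retardation, phi_hat):

* histogram statistics (128 bins): mean, population variance, skewness,
  excess kurtosis, Shannon entropy in nats — 15 features;
* rotation-invariant uniform local binary patterns, 8 sampling points at
  radii 1, 2, 3, 10-bin normalized histograms — 90 features;
* normalized symmetric gray-level co-occurrence matrices over 32 levels at
  distances 1, 2, 4 and four angles (averaged over angles): contrast,
  correlation, energy, homogeneity — 36 features.

Their concatenation (histogram | LBP | GLCM) yields the 141-feature combined
baseline.  The tiling interface matches the learned-feature inference grid
(tile 128, stride 64), so classical and learned feature maps are directly
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import graycomatrix, graycoprops, local_binary_pattern

from .contrastive import FeatureMap
from .physics import ParameterMaps

__all__ = [
    "SOBEL_KX",
    "SOBEL_KY",
    "SOBEL_NORMALIZER",
    "TextureFeatureVector",
    "sobel_direction",
    "histogram_features",
    "lbp_features",
    "glcm_features",
    "combined_features",
    "classic_feature_map",
]

#: 3x3 Sobel kernel responding to horizontal gradients (d/dx).
SOBEL_KX = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
#: 3x3 Sobel kernel responding to vertical gradients (d/dy).
SOBEL_KY = SOBEL_KX.T
#: sum(|Kx + Ky|) — the tight bound on |Gx + Gy| for unit complex inputs.
SOBEL_NORMALIZER = float(np.abs(SOBEL_KX + SOBEL_KY).sum())

_MAP_NAMES = ("transmittance", "retardation", "direction_gradient")
_HIST_STATS = ("mean", "variance", "skewness", "kurtosis", "entropy")
_LBP_RADII = (1, 2, 3)
_LBP_POINTS = 8
_LBP_BINS = 10
_GLCM_LEVELS = 32
_GLCM_DISTANCES = (1, 2, 4)
_GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
_GLCM_PROPS = ("contrast", "correlation", "energy", "homogeneity")
_HIST_BINS = 128


@dataclass(frozen=True)
class TextureFeatureVector:
    """Fixed-length feature vector with a (map, descriptor, parameter) schema."""

    values: np.ndarray
    schema: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.schema):
            raise ValueError("schema and values disagree in length")

    def __len__(self) -> int:
        return len(self.values)


def sobel_direction(phi: np.ndarray) -> np.ndarray:
    """Circular-safe Sobel gradient magnitude of a direction map, in [0, 1]."""
    z = np.exp(2j * np.asarray(phi, dtype=float))
    conv = lambda k: (
        ndimage.convolve(z.real, k, mode="reflect") + 1j * ndimage.convolve(z.imag, k, mode="reflect")
    )
    gx = conv(SOBEL_KX)
    gy = conv(SOBEL_KY)
    return np.abs(gx + gy) / SOBEL_NORMALIZER


def _tile_maps(tile: ParameterMaps, incident_intensity: float) -> dict[str, np.ndarray]:
    return {
        "transmittance": np.clip(tile.transmittance / incident_intensity, 0.0, 1.0),
        "retardation": tile.retardation,
        "direction_gradient": sobel_direction(tile.direction),
    }


def histogram_features(tile: ParameterMaps, incident_intensity: float = 1.0) -> TextureFeatureVector:
    """15 first-order statistics from 128-bin normalized histograms."""
    values: list[float] = []
    schema: list[tuple[str, str, str]] = []
    for name, img in _tile_maps(tile, incident_intensity).items():
        if img.size == 0:
            raise ValueError("empty tile")
        hist, edges = np.histogram(img, bins=_HIST_BINS, range=(0.0, 1.0))
        p = hist / hist.sum()
        centers = 0.5 * (edges[:-1] + edges[1:])
        mean = float((p * centers).sum())
        var = float((p * (centers - mean) ** 2).sum())
        if var > 0:
            skew = float((p * (centers - mean) ** 3).sum() / var**1.5)
            kurt = float((p * (centers - mean) ** 4).sum() / var**2 - 3.0)
        else:
            skew, kurt = 0.0, 0.0
        nz = p[p > 0]
        entropy = float(-(nz * np.log(nz)).sum())
        values.extend([mean, var, skew, kurt, entropy])
        schema.extend((name, "histogram", stat) for stat in _HIST_STATS)
    return TextureFeatureVector(np.array(values), tuple(schema))


def lbp_features(tile: ParameterMaps, incident_intensity: float = 1.0) -> TextureFeatureVector:
    """90 rotation-invariant uniform LBP histogram features (radii 1, 2, 3)."""
    h, w = tile.shape
    if min(h, w) <= 2 * max(_LBP_RADII):
        raise ValueError("tile too small for the largest LBP radius")
    values: list[float] = []
    schema: list[tuple[str, str, str]] = []
    for name, img in _tile_maps(tile, incident_intensity).items():
        # 8-bit quantization: LBP thresholds neighbors against the center, so
        # float interpolation noise on near-constant tiles would scatter codes
        quantized = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
        for radius in _LBP_RADII:
            codes = local_binary_pattern(quantized, _LBP_POINTS, radius, method="uniform")
            interior = codes[radius:-radius, radius:-radius]  # drop boundary artifacts
            hist, _ = np.histogram(interior, bins=_LBP_BINS, range=(0, _LBP_BINS))
            values.extend(hist / hist.sum())
            schema.extend((name, "lbp", f"r{radius}_code{c}") for c in range(_LBP_BINS))
    return TextureFeatureVector(np.array(values), tuple(schema))


def glcm_features(tile: ParameterMaps, incident_intensity: float = 1.0) -> TextureFeatureVector:
    """36 angle-averaged co-occurrence features (distances 1, 2, 4).

    Maps are quantized to 32 equal bins over [0, 1]; matrices are symmetric
    and normalized.  For degenerate single-level tiles the correlation is
    defined as 0.
    """
    values: list[float] = []
    schema: list[tuple[str, str, str]] = []
    for name, img in _tile_maps(tile, incident_intensity).items():
        levels = np.clip((img * _GLCM_LEVELS).astype(int), 0, _GLCM_LEVELS - 1).astype(np.uint8)
        glcm = graycomatrix(
            levels,
            distances=_GLCM_DISTANCES,
            angles=_GLCM_ANGLES,
            levels=_GLCM_LEVELS,
            symmetric=True,
            normed=True,
        )
        degenerate = levels.min() == levels.max()
        for prop in _GLCM_PROPS:
            per_angle = graycoprops(glcm, prop)  # (n_distances, n_angles)
            if prop == "correlation" and degenerate:
                per_angle = np.zeros_like(per_angle)
            avg = per_angle.mean(axis=1)
            for dist, val in zip(_GLCM_DISTANCES, avg):
                values.append(float(val))
                schema.append((name, "glcm", f"d{dist}_{prop}"))
    return TextureFeatureVector(np.array(values), tuple(schema))


def combined_features(tile: ParameterMaps, incident_intensity: float = 1.0) -> TextureFeatureVector:
    """Concatenation histogram | LBP | GLCM (141 features, stable order)."""
    parts = [
        histogram_features(tile, incident_intensity),
        lbp_features(tile, incident_intensity),
        glcm_features(tile, incident_intensity),
    ]
    return TextureFeatureVector(
        np.concatenate([p.values for p in parts]),
        tuple(s for p in parts for s in p.schema),
    )


def classic_feature_map(
    maps: ParameterMaps,
    extractor=combined_features,
    tile_px: int = 128,
    stride_px: int | None = None,
    mask: np.ndarray | None = None,
    section: int = 0,
) -> FeatureMap:
    """Tile a section and extract classical features on the inference grid.

    Uses the same tiling geometry as learned-feature inference so classical
    and learned feature maps share grid coordinates.
    """
    h, w = maps.shape
    stride = stride_px if stride_px is not None else tile_px // 2
    if tile_px > h or tile_px > w:
        raise ValueError("section smaller than tile")
    hh = (h - tile_px) // stride + 1
    ww = (w - tile_px) // stride + 1
    rows = []
    labels = np.zeros((hh, ww), dtype=np.int8) if mask is not None else None
    for iy in range(hh):
        row = []
        for ix in range(ww):
            sl = (slice(iy * stride, iy * stride + tile_px), slice(ix * stride, ix * stride + tile_px))
            tile = ParameterMaps(
                maps.transmittance[sl], maps.direction[sl], maps.retardation[sl], maps.pixel_size_um
            )
            row.append(extractor(tile).values)
            if labels is not None:
                labels[iy, ix] = np.argmax(np.bincount(mask[sl].ravel().astype(int)))
        rows.append(row)
    return FeatureMap(
        features=np.asarray(rows),
        tile_px=tile_px,
        stride_px=stride,
        section=section,
        pixel_size_um=maps.pixel_size_um,
        tile_labels=labels,
    )
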