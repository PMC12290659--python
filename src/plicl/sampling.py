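"""Positive-pair sampling by spatial context over a section stack.

A positive pair consists of an *anchor* patch at a random foreground location
and a *positive* patch taken from its spatial neighborhood in the undistorted
3D reference frame.  Four sampling modes are supported:

* ``SAME``  — the anchor is reused as its own positive (no context).
* ``CL2D``  — the positive lies on an in-plane circle of radius r (um) around
  the anchor, in the same section.
* ``CL3D``  — the displacement is drawn uniformly on the surface of a sphere
  of radius r (um); the z component (in um) is divided by the section spacing
  and the positive lands on the nearest section *other than* the anchor's.
* ``NN``    — the positive sits at the same in-plane reference coordinates in
  a random adjacent section (the r = 0 limit of CL3D).

In-plane voxels (1.3 um) and section spacing (60 um) are strongly
anisotropic, so all context geometry is computed in physical micrometers
before snapping z to sections.  Patches are always extracted from the
original (unwarped) section maps: the per-section frames supply natural
orientation variation between the members of a pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .physics import ParameterMaps
from .synthdata import SectionStack

__all__ = ["SamplingMode", "PairSpec", "sample_anchor", "sample_positive", "extract_pair", "pair_stream", "pairs_to_frame"]


class SamplingMode(str, Enum):
    SAME = "same"
    CL2D = "cl2d"
    CL3D = "cl3d"
    NN = "nn"


@dataclass(frozen=True)
class PairSpec:
    """Anchor/positive locations ((section, y, x) in section pixels)."""

    mode: SamplingMode
    radius_um: float
    anchor: tuple[int, int, int]
    positive: tuple[int, int, int]
    anchor_patch_px: int = 192


def _foreground_coords(stack: SectionStack, margin_px: int) -> np.ndarray:
    """(section, y, x) of all foreground pixels whose patch fits the section."""
    h, w = stack.shape
    fg = stack.masks > 0
    if margin_px > 0:
        valid = np.zeros_like(fg)
        lo = margin_px
        valid[:, lo : h - margin_px, lo : w - margin_px] = True
        fg = fg & valid
    coords = np.argwhere(fg)
    if coords.size == 0:
        raise ValueError("no foreground pixels available for anchor sampling")
    return coords


def sample_anchor(
    stack: SectionStack,
    rng: np.random.Generator,
    patch_px: int = 192,
    sections: list[int] | None = None,
) -> tuple[int, int, int]:
    """Uniform random foreground location whose patch footprint fits.

    Only pixels with visible tissue (GM or WM) are eligible as patch centers.
    """
    coords = _foreground_coords(stack, margin_px=(patch_px + 1) // 2)
    if sections is not None:
        keep = np.isin(coords[:, 0], sections)
        coords = coords[keep]
        if coords.size == 0:
            raise ValueError("no foreground pixels in the requested sections")
    s, y, x = coords[rng.integers(len(coords))]
    return int(s), int(y), int(x)


def sample_positive(
    stack: SectionStack,
    anchor: tuple[int, int, int],
    mode: SamplingMode,
    radius_um: float,
    rng: np.random.Generator,
    max_retries: int = 64,
) -> tuple[int, int, int]:
    """Draw the positive location for an anchor under the given context mode.

    The anchor is first mapped into the reference frame through its section
    transform; the displacement is drawn there and the result is mapped back
    into the target section's pixel frame through that section's inverse
    transform.  Displacements whose z coordinate falls outside the stack are
    redrawn (bounded retries).
    """
    mode = SamplingMode(mode)
    if radius_um < 0:
        raise ValueError("radius must be non-negative")
    s_a, y_a, x_a = anchor
    if mode is SamplingMode.SAME:
        return anchor
    if mode is SamplingMode.NN:
        candidates = [s for s in (s_a - 1, s_a + 1) if 0 <= s < stack.n_sections]
        if not candidates:
            raise ValueError("NN sampling requires at least two sections")
        s_p = int(candidates[rng.integers(len(candidates))])
        ref = stack.section_to_reference(s_a, np.array([x_a, y_a], dtype=float))
        x_p, y_p = stack.reference_to_section(s_p, ref)
        return s_p, int(round(y_p)), int(round(x_p))

    px = stack.pixel_size_um
    ref = stack.section_to_reference(s_a, np.array([x_a, y_a], dtype=float))
    if mode is SamplingMode.CL2D:
        ang = rng.uniform(0.0, 2.0 * np.pi)
        dxy_um = radius_um * np.array([np.cos(ang), np.sin(ang)])
        x_p, y_p = stack.reference_to_section(s_a, ref + dxy_um / px)
        return s_a, int(round(y_p)), int(round(x_p))

    # CL3D: uniform on the sphere surface, z handled in physical um
    spacing = stack.section_spacing_um
    for _ in range(max_retries):
        vec = rng.standard_normal(3)
        norm = np.linalg.norm(vec)
        if norm == 0:
            continue
        vec = vec / norm * radius_um
        z_frac = vec[2] / spacing
        z_float = s_a + z_frac
        others = np.array([s for s in range(stack.n_sections) if s != s_a])
        if others.size == 0:
            raise ValueError("CL3D sampling requires at least two sections")
        dist = np.abs(others - z_float)
        best = dist.min()
        if z_float < -0.5 or z_float > stack.n_sections - 0.5:
            continue  # beyond the first/last section: redraw the displacement
        tied = others[np.isclose(dist, best)]
        s_p = int(tied[rng.integers(len(tied))])
        x_p, y_p = stack.reference_to_section(s_p, ref + vec[:2] / px)
        return s_p, int(round(y_p)), int(round(x_p))
    raise RuntimeError("exhausted retries drawing a CL3D displacement inside the stack")


def _crop(maps: ParameterMaps, y: int, x: int, patch_px: int) -> ParameterMaps | None:
    h, w = maps.shape
    half = patch_px // 2
    y0, x0 = y - half, x - half
    if y0 < 0 or x0 < 0 or y0 + patch_px > h or x0 + patch_px > w:
        return None
    sl = (slice(y0, y0 + patch_px), slice(x0, x0 + patch_px))
    return ParameterMaps(
        maps.transmittance[sl].copy(),
        maps.direction[sl].copy(),
        maps.retardation[sl].copy(),
        maps.pixel_size_um,
    )


def extract_pair(stack: SectionStack, spec: PairSpec) -> tuple[ParameterMaps, ParameterMaps]:
    """Cut the anchor/positive patches from the original (unwarped) sections."""
    s_a, y_a, x_a = spec.anchor
    s_p, y_p, x_p = spec.positive
    a = _crop(stack.sections[s_a], y_a, x_a, spec.anchor_patch_px)
    p = _crop(stack.sections[s_p], y_p, x_p, spec.anchor_patch_px)
    if a is None or p is None:
        raise ValueError("patch footprint out of bounds")
    return a, p


def pair_stream(
    stack: SectionStack,
    mode: SamplingMode,
    radius_um: float,
    rng: np.random.Generator,
    patch_px: int = 192,
    sections: list[int] | None = None,
    max_retries: int = 64,
):
    """Endless generator of valid :class:`PairSpec` draws (seeded by ``rng``).

    The foreground coordinate list is computed once up front, so streaming is
    much cheaper than repeated :func:`sample_anchor` calls.
    """
    coords = _foreground_coords(stack, margin_px=(patch_px + 1) // 2)
    if sections is not None:
        coords = coords[np.isin(coords[:, 0], sections)]
        if coords.size == 0:
            raise ValueError("no foreground pixels in the requested sections")
    while True:
        for _ in range(max_retries):
            s, y, x = coords[rng.integers(len(coords))]
            anchor = (int(s), int(y), int(x))
            positive = sample_positive(stack, anchor, mode, radius_um, rng)
            spec = PairSpec(SamplingMode(mode), radius_um, anchor, positive, patch_px)
            s_p, y_p, x_p = positive
            if _crop(stack.sections[s_p], y_p, x_p, patch_px) is not None:
                break
        else:
            raise RuntimeError("could not place a valid pair")
        yield spec


def pairs_to_frame(specs: list[PairSpec]) -> pd.DataFrame:
    """Tabulate pair draws for audit (one row per pair)."""
    return pd.DataFrame(
        {
            "mode": [s.mode.value for s in specs],
            "radius_um": [s.radius_um for s in specs],
            "anchor_section": [s.anchor[0] for s in specs],
            "anchor_y": [s.anchor[1] for s in specs],
            "anchor_x": [s.anchor[2] for s in specs],
            "positive_section": [s.positive[0] for s in specs],
            "positive_y": [s.positive[1] for s in specs],
            "positive_x": [s.positive[2] for s in specs],
            "patch_px": [s.anchor_patch_px for s in specs],
        }
    )
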