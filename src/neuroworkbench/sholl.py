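"""Sholl morphometry of cultured neurons.

Nuclei give the circle centres; a neuriteness-filtered brightfield image
gives a skeletonised cell mask; intersection counts with concentric circles
(20 um start, 10 um spacing) quantify arbour complexity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import meijering, threshold_otsu, threshold_triangle
from skimage.morphology import binary_dilation, disk, remove_small_objects, skeletonize

__all__ = [
    "ShollProfile",
    "segment_nuclei",
    "neurite_mask_bf",
    "sholl_count",
    "default_radii_um",
]

MIN_NUCLEUS_PX2 = 1000
MIN_SPECKLE_PX2 = 50


@dataclass
class ShollProfile:
    """Per-cell intersection counts at concentric radii."""

    cell_id: int
    radii_um: np.ndarray
    intersections: np.ndarray
    excluded: bool = False
    exclusion_reason: str = ""


def default_radii_um(max_um: float = 150.0) -> np.ndarray:
    """Sholl radii starting at 20 um with 10 um spacing."""
    return np.arange(20.0, max_um + 1e-9, 10.0)


def segment_nuclei(nucleus_channel: np.ndarray) -> list[tuple[float, float]]:
    """Otsu-thresholded nuclei, objects under 1000 px^2 discarded.

    Returns centroid (row, col) per nucleus.
    """
    img = np.asarray(nucleus_channel, dtype=float)
    if not np.any(img != img.flat[0]):
        return []
    mask = img > threshold_otsu(img)
    mask = remove_small_objects(mask, min_size=MIN_NUCLEUS_PX2)
    labels, n = ndimage.label(mask)
    return [tuple(c) for c in ndimage.center_of_mass(mask, labels, range(1, n + 1))]


def neurite_mask_bf(brightfield: np.ndarray, sigmas=(2, 3, 4)) -> np.ndarray:
    """Skeletonised cell mask from a brightfield image.

    Meijering neuriteness filter (dark ridges on bright background) with
    sigmas 2/3/4, triangle-algorithm threshold, removal of speckles smaller
    than 50 px^2, then skeletonisation to a 1-px-wide mask.
    """
    img = np.asarray(brightfield, dtype=float)
    if not np.any(img != img.flat[0]):
        return np.zeros(img.shape, dtype=bool)
    ridges = meijering(img, sigmas=sigmas, black_ridges=True)
    mask = ridges > threshold_triangle(ridges)
    mask = remove_small_objects(mask, min_size=MIN_SPECKLE_PX2)
    return skeletonize(mask)


def sholl_count(
    skeleton: np.ndarray,
    centre: tuple[float, float],
    radii_um: np.ndarray,
    pixel_um: float,
) -> ShollProfile:
    """Count skeleton intersections with each Sholl circle.

    For a radius r: skeleton pixels whose distance (in um) to the centre is
    within +-1 pixel of r are selected, dilated with a disk of radius 2 px to
    close small gaps, and the 8-connected components give the intersection
    count.
    """
    if pixel_um <= 0:
        raise ValueError("pixel_um must be positive")
    skeleton = np.asarray(skeleton, dtype=bool)
    r0, c0 = centre
    if not (0 <= r0 < skeleton.shape[0] and 0 <= c0 < skeleton.shape[1]):
        raise ValueError("centre lies outside the image")
    rows, cols = np.indices(skeleton.shape)
    dist_um = np.hypot(rows - r0, cols - c0) * pixel_um
    counts = []
    struct = np.ones((3, 3), dtype=bool)
    for r in np.asarray(radii_um, dtype=float):
        annulus = skeleton & (np.abs(dist_um - r) <= pixel_um)
        if not annulus.any():
            counts.append(0)
            continue
        closed = binary_dilation(annulus, footprint=disk(2))
        _, n = ndimage.label(closed, structure=struct)
        counts.append(int(n))
    return ShollProfile(
        cell_id=0,
        radii_um=np.asarray(radii_um, dtype=float),
        intersections=np.asarray(counts, dtype=int),
    )


def flag_exclusions(
    skeleton: np.ndarray, centres: list[tuple[float, float]], border_px: int = 5
) -> list[str]:
    """Rule-based stand-ins for the manual quality exclusions.

    A cell is flagged if its skeleton touches the image border (truncated
    arbour) -- with several nuclei in one field every cell shares the mask,
    so overlap flags are raised when two centres fall within 40 px.
    """
    reasons = []
    touches = (
        skeleton[:border_px].any()
        or skeleton[-border_px:].any()
        or skeleton[:, :border_px].any()
        or skeleton[:, -border_px:].any()
    )
    pts = np.asarray(centres, dtype=float)
    for i, c in enumerate(centres):
        reason = ""
        if touches:
            reason = "touches_border"
        elif len(pts) > 1:
            d = np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1])
            d[i] = np.inf
            if d.min() < 40:
                reason = "overlaps_neighbour"
        reasons.append(reason)
    return reasons
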