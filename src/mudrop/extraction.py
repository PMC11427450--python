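"""From label masks to per-droplet observations.

Region growing aggregates connected same-class pixels of a predicted (or
ground-truth) mask into discrete droplet regions; each region then becomes a
:class:`DropletObservation` carrying the droplet state, centroid, pixel count
(the volume proxy) and nearest electrode.  The controller consumes only these
observations — never simulator internals — so the same code drives a real
camera + segmentation stack.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import ElectrodeGrid
from .states import DropletState

#: minimum region size in pixels at the 512-px working resolution; scaled
#: with resolution by :func:`default_min_size`.
MIN_SIZE_AT_512 = 20

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def default_min_size(resolution: int) -> int:
    """Speckle threshold scaled to the mask resolution (area scaling)."""
    return max(1, round(MIN_SIZE_AT_512 * (resolution / 512) ** 2))


def grid_min_size(grid: ElectrodeGrid) -> int:
    """Speckle threshold tied to the chip geometry: 5% of one electrode
    footprint.  The smallest controllable droplet is comparable to an
    electrode, so anything this small is segmentation noise."""
    return max(4, round(0.05 * grid.footprint_area()))


@dataclass
class Region:
    """One maximal connected same-class component of the mask."""

    class_id: int
    pixels: np.ndarray        # (n, 2) array of (row, col) coordinates
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]   # (top, left, bottom, right), half-open
    pixel_count: int


@dataclass
class DropletObservation:
    """What the controller knows about one droplet in one frame."""

    state: DropletState
    centroid: tuple[float, float]
    pixel_count: int
    electrode_id: int
    bbox: tuple[int, int, int, int]


def grow_regions(mask: np.ndarray, connectivity: int = 4,
                 min_size: int = 20) -> list[Region]:
    """Group connected same-class nonzero pixels into regions.

    Components are grown per class under the chosen pixel connectivity
    (4-neighborhood by default — the conservative choice that keeps
    near-touching droplets separate, matching the split-state definition);
    components smaller than ``min_size`` are dropped as segmentation speckle.
    Regions are returned in row-major order of their first (seed) pixel.
    """
    mask = np.asarray(mask)
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    if mask.size and (mask.min() < 0 or mask.max() > 4):
        raise ValueError("mask values must lie in {0..4}")
    regions: list[Region] = []
    for c in np.unique(mask):
        if c == 0:
            continue
        labeled, n = ndimage.label(mask == c, structure=_STRUCTURES[connectivity])
        for k in range(1, n + 1):
            rows, cols = np.nonzero(labeled == k)
            if rows.size < min_size:
                continue
            regions.append(Region(
                class_id=int(c),
                pixels=np.column_stack([rows, cols]),
                centroid=(float(rows.mean()), float(cols.mean())),
                bbox=(int(rows.min()), int(cols.min()),
                      int(rows.max()) + 1, int(cols.max()) + 1),
                pixel_count=int(rows.size),
            ))
    # row-major seed order across classes
    regions.sort(key=lambda r: (int(r.pixels[0, 0]), int(r.pixels[0, 1])))
    return regions


def majority_vote_refine(mask: np.ndarray, connectivity: int = 4) -> np.ndarray:
    """Relabel every connected foreground component with its majority class.

    A physical droplet is one connected silhouette; stray class fragments
    inside it (a lobe of an hourglass read as split, a patch of a droplet
    read as merging) are segmentation noise.  Touching droplets always share
    a class (contact makes both merging), so a whole-component majority vote
    cleans fragments without ever mixing distinct droplets.
    """
    mask = np.asarray(mask)
    labeled, n = ndimage.label(mask > 0, structure=_STRUCTURES[connectivity])
    if n == 0:
        return mask.copy()
    out = mask.copy()
    for k in range(1, n + 1):
        sel = labeled == k
        counts = np.bincount(mask[sel], minlength=5)
        out[sel] = counts[1:].argmax() + 1
    return out


def to_observations(regions: list[Region],
                    grid: ElectrodeGrid) -> list[DropletObservation]:
    """Attach each region to the electrode whose footprint contains its
    centroid (lowest index on a boundary tie; nearest footprint center when
    the centroid falls in a gap or margin)."""
    return [DropletObservation(
        state=DropletState(r.class_id),
        centroid=r.centroid,
        pixel_count=r.pixel_count,
        electrode_id=grid.electrode_at(r.centroid),
        bbox=r.bbox,
    ) for r in regions]


def observe_mask(mask: np.ndarray, grid: ElectrodeGrid,
                 connectivity: int = 4,
                 min_size: int | None = None,
                 refine: bool = True) -> list[DropletObservation]:
    """Full extraction pipeline: majority-vote refinement, region growing,
    then electrode assignment."""
    if min_size is None:
        min_size = grid_min_size(grid)
    if refine:
        mask = majority_vote_refine(mask, connectivity)
    return to_observations(grow_regions(mask, connectivity, min_size), grid)


def covers_electrodes(observation: DropletObservation, mask: np.ndarray,
                      targets: list[int], grid: ElectrodeGrid) -> bool:
    """True iff every pixel of every target electrode footprint carries the
    observation's droplet class — the dispensing coverage condition."""
    cls = int(observation.state)
    for e in targets:
        t, l, b, r = grid.footprint(e)
        if not np.all(mask[t:b, l:r] == cls):
            return False
    return True


def volume_error(pixel_counts: tuple[float, float]) -> float:
    """Relative volume imbalance ``|a - b| / (a + b)`` of a split pair (also
    used for a dispensed volume against its target area)."""
    a, b = pixel_counts
    if a <= 0 or b <= 0:
        raise ValueError("lost droplet: pixel counts must be > 0")
    return abs(a - b) / (a + b)


def observations_to_frame(observations: list[DropletObservation],
                          frame_index: int = 0) -> pd.DataFrame:
    """Observation log rows (the data behind per-frame state/position plots)."""
    return pd.DataFrame([
        {"frame_index": frame_index, "droplet_id": i,
         "state": o.state.name.lower(), "centroid_row": o.centroid[0],
         "centroid_col": o.centroid[1], "pixel_count": o.pixel_count,
         "electrode_id": o.electrode_id}
        for i, o in enumerate(observations)])
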