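"""Virtual DMF device: droplet scene renderer and toy electrowetting physics.

This module stands in for the chip + camera of a real electrowetting platform.
It renders droplet scenes together with exact ground-truth class masks, and
advances droplets under an actuation pattern with a discrete physics update
that injects the failure modes a feedback controller must correct: a movement
step that silently fails, and a split during which the droplet is pulled
entirely to one side by the first activated electrode.

The physics is deliberately a discrete toy model (no contact-angle
hydrodynamics): one update per camera frame, droplets snap to electrode
centers, and volumes are tracked in pixel-area units so that the rendered
pixel count of a droplet is an unbiased measurement of its volume.

Randomness: a root seed in :class:`PhysicsParams` is split into two child
streams (physics, rendering noise) via ``np.random.SeedSequence(seed).spawn(2)``
so the two noise sources are independently reproducible.  Physics draws happen
in a documented order (reservoir updates, then splitting resolutions, then
moves, each in ascending droplet-id order) so trajectories can be replayed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grid import ElectrodeGrid
from .states import BACKGROUND, DROPLET_COLORS, DropletState

BACKGROUND_RGB = 205.0     # uniform chip background level
OUTLINE_RGB = 172.0        # faint electrode outline level
RIM_PX = 2                 # dark rim width, the main edge cue
TRANSPARENT_FILL = 0.93    # transparent droplets: background x this
TRANSPARENT_RIM = 0.62


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class VirtualDroplet:
    """One droplet tracked by the simulator.

    ``volume`` is in pixel-area units; the renderer draws the droplet with
    that many pixels (up to rasterization error).  A reservoir droplet uses
    ``shape="reservoir"`` and covers the electrode footprints in ``extent``.
    """

    droplet_id: int
    volume: float
    centroid: tuple[float, float]
    state: DropletState = DropletState.UNSPLIT
    color: str = "blue"
    shape: str = "circle"
    partner: int | None = None
    neck_px: float = 4.0
    lobe_axis: str = "h"            # "h" or "v": axis of the splitting hourglass
    lobe_span: float | None = None  # center-to-lobe distance while SPLITTING
    extent: tuple[int, ...] | None = None   # reservoir only
    neck_at: int | None = None              # reservoir only: necking electrode

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("droplet volume must be > 0")
        self.state = DropletState(self.state)

    @property
    def radius(self) -> float:
        """Equivalent circular radius in pixels."""
        return math.sqrt(self.volume / math.pi)


@dataclass
class PhysicsParams:
    """Failure-mode magnitudes of the virtual device.

    Defaults are chosen so failures occur often enough to exercise the
    feedback loops: a movement step fails 5% of the time, a split is pulled
    entirely to one side 10% of the time, and the signed volume imbalance
    ``delta`` of a successful split (halves ``V*(1/2 +- delta)``) is drawn
    from N(0, 0.04).
    """

    move_success_prob: float = 0.95
    split_pull_prob: float = 0.1
    split_asymmetry_sd: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.move_success_prob, self.split_pull_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.split_asymmetry_sd < 0:
            raise ValueError("split_asymmetry_sd must be >= 0")


@dataclass
class SceneFrame:
    """An RGB camera frame plus its ground-truth 5-class label mask."""

    image: np.ndarray   # (H, W, 3) uint8
    mask: np.ndarray    # (H, W) uint8, values in {0..4}
    frame_index: int = 0

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask shapes disagree")


@dataclass(frozen=True)
class ActuationPattern:
    """Set of energized electrodes held for ``hold_frames`` camera frames."""

    active: frozenset[int]
    hold_frames: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "active", frozenset(self.active))
        if self.hold_frames < 1:
            raise ValueError("hold_frames must be >= 1")

    def validate(self, grid: ElectrodeGrid) -> None:
        for e in self.active:
            if not 0 <= e < grid.n_electrodes:
                raise ValueError(f"pattern references nonexistent electrode {e}")


# ---------------------------------------------------------------------------
# brightness
# ---------------------------------------------------------------------------

def adjust_brightness(image: np.ndarray, factor: float) -> np.ndarray:
    """Scale every channel value by ``factor``: ``clip(round(v * factor))``.

    Emulates a linear change of the luminous environment.
    """
    if factor <= 0:
        raise ValueError("brightness factor must be > 0")
    out = np.rint(image.astype(np.float64) * factor)
    return np.clip(out, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# shape rasterization
# ---------------------------------------------------------------------------

def _shape_mask(shape: str, area: float, center: tuple[float, float],
                hw: tuple[int, int]) -> np.ndarray:
    """Boolean raster of one droplet silhouette with the requested area."""
    h, w = hw
    rr, cc = np.ogrid[:h, :w]
    cr, ccol = center
    if shape == "circle":
        r = math.sqrt(area / math.pi)
        return (rr - cr) ** 2 + (cc - ccol) ** 2 <= r * r
    if shape == "rectangle":
        rw = math.sqrt(area * 1.4)
        rh = area / rw
        return (np.abs(rr - cr) <= rh / 2) & (np.abs(cc - ccol) <= rw / 2)
    if shape == "l_shape":
        s = math.sqrt(area / 0.75)
        sq = (np.abs(rr - cr) <= s / 2) & (np.abs(cc - ccol) <= s / 2)
        notch = (rr < cr) & (cc > ccol)
        return sq & ~notch
    if shape == "triangle":
        base = math.sqrt(area / 0.45)     # height = 0.9 * base
        ht = 0.9 * base
        y = rr - (cr - ht / 2)            # distance below apex
        half = (base / 2) * np.clip(y / ht, 0, None)
        return (y >= 0) & (y <= ht) & (np.abs(cc - ccol) <= half)
    raise ValueError(f"unknown droplet shape {shape!r}")


def shape_halfspan(shape: str, area: float) -> float:
    """Conservative half-extent of a silhouette, for canvas placement."""
    if shape == "circle":
        return math.sqrt(area / math.pi)
    if shape == "rectangle":
        return math.sqrt(area * 1.4) / 2
    if shape == "l_shape":
        return math.sqrt(area / 0.75) / 2 * math.sqrt(2)
    if shape == "triangle":
        return math.sqrt(area / 0.45) / 2 * 1.1
    if shape == "reservoir":
        return float("inf")
    raise ValueError(f"unknown droplet shape {shape!r}")


def _hourglass_mask(volume: float, center: tuple[float, float], span: float,
                    neck_px: float, axis: str, hw: tuple[int, int]) -> np.ndarray:
    """Two circular lobes joined by a thin neck — the splitting silhouette.

    ``span`` is the distance from the hourglass center to each lobe center;
    the neck is a ``neck_px``-wide band joining the lobes along ``axis``.
    """
    h, w = hw
    rr, cc = np.ogrid[:h, :w]
    cr, ccol = center
    r = math.sqrt((volume / 2) / math.pi)
    if axis == "h":
        c1, c2 = (cr, ccol - span), (cr, ccol + span)
        neck = ((rr >= cr - neck_px / 2) & (rr < cr + neck_px / 2)
                & (np.abs(cc - ccol) <= span))
    else:
        c1, c2 = (cr - span, ccol), (cr + span, ccol)
        neck = ((cc >= ccol - neck_px / 2) & (cc < ccol + neck_px / 2)
                & (np.abs(rr - cr) <= span))
    lobe1 = (rr - c1[0]) ** 2 + (cc - c1[1]) ** 2 <= r * r
    lobe2 = (rr - c2[0]) ** 2 + (cc - c2[1]) ** 2 <= r * r
    return lobe1 | lobe2 | neck


def _reservoir_mask(droplet: VirtualDroplet, grid: ElectrodeGrid,
                    hw: tuple[int, int]) -> np.ndarray:
    """Reservoir silhouette: padded union of covered electrode footprints;
    while necking, the electrode at ``neck_at`` is drawn as a thin band."""
    m = np.zeros(hw, dtype=bool)
    pad = 3
    for e in droplet.extent or ():
        t, l, b, r = grid.footprint(e)
        if droplet.neck_at is not None and e == droplet.neck_at:
            mid = (t + b) // 2
            half = max(2, int(droplet.neck_px) // 2)
            m[mid - half:mid + half, max(l - pad, 0):r + pad] = True
        else:
            m[max(t - pad, 0):b + pad, max(l - pad, 0):r + pad] = True
    return m


def droplet_silhouette(droplet: VirtualDroplet, grid: ElectrodeGrid,
                       hw: tuple[int, int]) -> np.ndarray:
    if droplet.shape == "reservoir":
        return _reservoir_mask(droplet, grid, hw)
    if droplet.state is DropletState.SPLITTING:
        span = droplet.lobe_span if droplet.lobe_span is not None else grid.pitch / 2
        return _hourglass_mask(droplet.volume, droplet.centroid, span,
                               droplet.neck_px, droplet.lobe_axis, hw)
    return _shape_mask(droplet.shape, droplet.volume, droplet.centroid, hw)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_frame(
    droplets: list[VirtualDroplet],
    grid: ElectrodeGrid,
    brightness_factor: float = 1.0,
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.0,
    frame_index: int = 0,
    canvas_shape: tuple[int, int] | None = None,
) -> SceneFrame:
    """Render a scene and its exact ground-truth mask.

    The image shows each droplet per its shape and color on a uniform chip
    background with faint electrode outlines; transparent droplets are drawn
    as a background-colored fill with a darker refraction rim.  The mask
    labels every droplet pixel with the class id of its state.  Overlapping
    droplets of different states make the ground truth ambiguous and are
    rejected.
    """
    if brightness_factor <= 0:
        raise ValueError("brightness factor must be > 0")
    hw = canvas_shape if canvas_shape is not None else grid.canvas_shape()
    img = np.full(hw + (3,), BACKGROUND_RGB, dtype=np.float64)
    mask = np.zeros(hw, dtype=np.uint8)

    for e in range(grid.n_electrodes):
        t, l, b, r = grid.footprint(e)
        img[t:b, [l, r - 1]] = OUTLINE_RGB
        img[[t, b - 1], l:r] = OUTLINE_RGB

    for d in sorted(droplets, key=lambda d: d.droplet_id):
        sil = droplet_silhouette(d, grid, hw)
        if not sil.any():
            raise ValueError(f"droplet {d.droplet_id} rasterized to zero pixels")
        if d.shape != "reservoir":
            rows, cols = np.nonzero(sil)
            if (rows.min() == 0 or cols.min() == 0
                    or rows.max() == hw[0] - 1 or cols.max() == hw[1] - 1):
                raise ValueError(f"droplet {d.droplet_id} does not fit the canvas")
        clash = sil & (mask != 0) & (mask != int(d.state))
        if clash.any():
            raise ValueError(
                "overlapping droplets with incompatible states make the "
                "ground-truth mask ambiguous")
        fill = DROPLET_COLORS.get(d.color, None) if d.color != "transparent" else None
        if d.color not in DROPLET_COLORS:
            raise ValueError(f"unknown droplet color {d.color!r}")
        interior = ndimage.binary_erosion(sil, iterations=RIM_PX, border_value=0)
        rim = sil & ~interior
        if fill is None:  # transparent liquid: refraction cue only
            img[interior] = BACKGROUND_RGB * TRANSPARENT_FILL
            img[rim] = BACKGROUND_RGB * TRANSPARENT_RIM
        else:
            img[interior] = np.asarray(fill, dtype=np.float64)
            img[rim] = np.asarray(fill, dtype=np.float64) * 0.55
        mask[sil] = int(d.state)

    if rng is not None and noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img8 = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    if brightness_factor != 1.0:
        img8 = adjust_brightness(img8, brightness_factor)
    return SceneFrame(image=img8, mask=mask, frame_index=frame_index)


# ---------------------------------------------------------------------------
# physics
# ---------------------------------------------------------------------------

def _flanks(grid: ElectrodeGrid, e: int) -> list[tuple[int, int, str]]:
    """Opposing electrode pairs around ``e``: [(left, right, axis), ...]."""
    r, c = grid.rc(e)
    out = []
    if 0 <= c - 1 and c + 1 < grid.cols:
        out.append((grid.index(r, c - 1), grid.index(r, c + 1), "h"))
    if 0 <= r - 1 and r + 1 < grid.rows:
        out.append((grid.index(r - 1, c), grid.index(r + 1, c), "v"))
    return out


#: droplets whose silhouette edges come within this fraction of an electrode
#: width are in contact: the equivalent-circle footprint underestimates how
#: far an electrowetting droplet spreads over its energized electrode
CONTACT_BAND = 0.35


def _contact_gap(grid: ElectrodeGrid) -> float:
    return CONTACT_BAND * grid.electrode_px


def _edge_gap(a: VirtualDroplet, b: VirtualDroplet) -> float:
    d = math.dist(a.centroid, b.centroid)
    return d - a.radius - b.radius


def _reservoir_gap(d: VirtualDroplet, res: VirtualDroplet,
                   grid: ElectrodeGrid) -> float:
    """Distance from a droplet's edge to the reservoir silhouette edge."""
    pad = 3 + grid.electrode_px / 2
    return min(math.dist(d.centroid, grid.center(e)) for e in res.extent
               ) - pad - d.radius


def step_physics(
    droplets: list[VirtualDroplet],
    pattern: ActuationPattern,
    grid: ElectrodeGrid,
    params: PhysicsParams,
    rng: np.random.Generator,
) -> list[VirtualDroplet]:
    """Advance the droplet configuration by one frame under ``pattern``.

    Update rules, applied in this order (draws in ascending droplet id):

    1. reservoir droplets: neck resolution (pull-back with probability
       ``split_pull_prob``, else break-off with relative volume noise
       ``split_asymmetry_sd``), necking trigger, or extension by one
       electrode with probability ``move_success_prob``;
    2. splitting droplets resolve: pulled to one side with probability
       ``split_pull_prob`` (side drawn uniformly), else two SPLIT halves of
       volumes ``V*(1/2 + delta)`` and ``V*(1/2 - delta)``;
    3. an unsplit droplet with both flanking electrodes active and its own
       inactive starts SPLITTING (hourglass);
    4. a droplet adjacent to exactly one active electrode moves one electrode
       toward it with probability ``move_success_prob``;
    5. touching droplets become MERGING, and a MERGING pair coalesces into
       one UNSPLIT droplet of summed volume;
    6. SPLIT partners drifting farther than ~1.6 electrode pitches apart
       revert to UNSPLIT.

    Total volume is conserved exactly by move, split and merge.
    """
    pattern.validate(grid)
    active = pattern.active
    ds = {d.droplet_id: replace(d) for d in droplets}
    next_id = max(ds, default=-1) + 1

    # -- 1. reservoirs ------------------------------------------------------
    for i in sorted(ds):
        d = ds[i]
        if d.shape != "reservoir":
            continue
        if d.state is DropletState.SPLITTING and d.neck_at is not None:
            u = rng.uniform()
            cut = tuple(e for e in d.extent if e < d.neck_at)
            if u < params.split_pull_prob or not cut:
                d.extent = tuple(e for e in d.extent if e >= d.neck_at)
                d.state = DropletState.UNSPLIT
                d.neck_at = None
            else:
                eps = rng.normal(0.0, params.split_asymmetry_sd)
                vol = max(1.0, len(cut) * grid.footprint_area() * (1.0 + eps))
                centers = np.array([grid.center(e) for e in cut])
                new = VirtualDroplet(
                    droplet_id=next_id, volume=vol,
                    centroid=tuple(centers.mean(axis=0)),
                    state=DropletState.SPLIT, color=d.color, shape="circle",
                    partner=d.droplet_id)
                next_id += 1
                d.volume -= vol
                d.extent = tuple(e for e in d.extent if e > d.neck_at)
                d.state = DropletState.SPLIT
                d.partner = new.droplet_id
                d.neck_at = None
                ds[new.droplet_id] = new
            continue
        # necking trigger: an inactive extent electrode separating covered
        # electrodes from the (active) reservoir -> neck forms there
        res_active = any(e in active for e in d.extent if e in grid.reservoir_ids)
        inner = [e for e in d.extent
                 if e not in active and e not in grid.reservoir_ids
                 and any(x < e for x in d.extent) and any(x > e for x in d.extent)]
        if res_active and inner:
            d.neck_at = max(inner)
            d.state = DropletState.SPLITTING
            continue
        # extension toward lower indices (dispense layout: reservoir on the right)
        frontier = min(d.extent) - 1
        if frontier >= 0 and frontier in active:
            if rng.uniform() < params.move_success_prob:
                d.extent = (frontier,) + tuple(d.extent)
        if d.state is DropletState.SPLIT and d.partner is not None:
            if d.partner not in ds:
                d.state = DropletState.UNSPLIT
                d.partner = None

    # -- 2. splitting droplets resolve --------------------------------------
    for i in sorted(ds):
        d = ds[i]
        if d.shape == "reservoir" or d.state is not DropletState.SPLITTING:
            continue
        e = grid.electrode_at(d.centroid)
        flank = next(((a, b, ax) for a, b, ax in _flanks(grid, e)
                      if a in active and b in active and e not in active), None)
        if flank is None:  # actuation released: droplet relaxes back
            d.state = DropletState.UNSPLIT
            d.lobe_span = None
            continue
        a, b, _ax = flank
        u = rng.uniform()
        if u < params.split_pull_prob:
            side = int(rng.integers(2))
            d.state = DropletState.UNSPLIT
            d.centroid = grid.center(a if side == 0 else b)
            d.lobe_span = None
        else:
            delta = rng.normal(0.0, params.split_asymmetry_sd)
            v1 = d.volume * (0.5 + delta)
            v2 = d.volume - v1
            d.volume = v1
            d.centroid = grid.center(a)
            d.state = DropletState.SPLIT
            d.shape = "circle"
            d.lobe_span = None
            d.partner = next_id
            half = VirtualDroplet(
                droplet_id=next_id, volume=v2, centroid=grid.center(b),
                state=DropletState.SPLIT, color=d.color, shape="circle",
                partner=d.droplet_id)
            next_id += 1
            ds[half.droplet_id] = half

    # -- 3. split trigger ----------------------------------------------------
    for i in sorted(ds):
        d = ds[i]
        if d.shape == "reservoir" or d.state is not DropletState.UNSPLIT:
            continue
        e = grid.electrode_at(d.centroid)
        if e in active:
            continue
        flank = next(((a, b, ax) for a, b, ax in _flanks(grid, e)
                      if a in active and b in active), None)
        if flank is not None:
            d.state = DropletState.SPLITTING
            d.centroid = grid.center(e)
            d.lobe_axis = flank[2]
            d.lobe_span = grid.pitch / 2.0
            d.shape = "circle"

    # -- 4. moves ------------------------------------------------------------
    for i in sorted(ds):
        d = ds[i]
        if d.shape == "reservoir" or d.state is DropletState.SPLITTING:
            continue
        e = grid.electrode_at(d.centroid)
        if e in active:
            d.centroid = grid.center(e)  # held in place, centered
            continue
        targets = [n for n in grid.neighbors(e) if n in active]
        if len(targets) == 1:
            if rng.uniform() < params.move_success_prob:
                dest = grid.center(targets[0])
                # an approach toward another droplet stops at contact (the
                # liquid fronts meet before the centers align)
                for j in sorted(ds):
                    o = ds[j]
                    if j == i or o.shape == "reservoir":
                        continue
                    sep = math.dist(dest, o.centroid)
                    if sep < d.radius + o.radius + _contact_gap(grid):
                        back = d.radius + o.radius - 2.0
                        if sep > 1e-6:
                            ur = (dest[0] - o.centroid[0]) / sep
                            uc = (dest[1] - o.centroid[1]) / sep
                        else:
                            cr, cc = d.centroid
                            n0 = math.dist(d.centroid, o.centroid) or 1.0
                            ur = (cr - o.centroid[0]) / n0
                            uc = (cc - o.centroid[1]) / n0
                        dest = (o.centroid[0] + back * ur,
                                o.centroid[1] + back * uc)
                        break
                d.centroid = dest

    # -- 5a. re-absorption into a reservoir ----------------------------------
    reservoirs = [i for i in sorted(ds) if ds[i].shape == "reservoir"]
    for i in sorted(ds):
        if i not in ds or ds[i].shape == "reservoir":
            continue
        d = ds[i]
        if d.state is DropletState.SPLITTING:
            continue
        for ri in reservoirs:
            if _reservoir_gap(d, ds[ri], grid) <= 1.0:
                ds[ri].volume += d.volume
                if ds[ri].partner == i:
                    ds[ri].partner = None
                    ds[ri].state = DropletState.UNSPLIT
                del ds[i]
                break

    # -- 5b. merging ---------------------------------------------------------
    ids = sorted(ds)
    for ii, i in enumerate(ids):
        if i not in ds:
            continue
        a = ds[i]
        if a.shape == "reservoir":
            continue
        for j in ids[ii + 1:]:
            if j not in ds or i not in ds:
                break
            b = ds[j]
            if b.shape == "reservoir":
                continue
            if _edge_gap(a, b) <= _contact_gap(grid):
                # states follow appearance: a pair that no longer shows two
                # lobes (deep overlap) has merged; a visible contact doublet
                # is MERGING until it coalesces on the next step
                deep_overlap = (math.dist(a.centroid, b.centroid)
                                < 0.6 * max(a.radius, b.radius))
                was_merging = (a.state is DropletState.MERGING
                               and a.partner == j
                               and b.state is DropletState.MERGING
                               and b.partner == i)
                if was_merging or deep_overlap:
                    v = a.volume + b.volume
                    wa, wb = a.volume / v, b.volume / v
                    a.volume = v
                    a.centroid = (wa * a.centroid[0] + wb * b.centroid[0],
                                  wa * a.centroid[1] + wb * b.centroid[1])
                    a.state = DropletState.UNSPLIT
                    a.shape = "circle"
                    a.partner = None
                    del ds[j]
                else:
                    a.state = b.state = DropletState.MERGING
                    a.partner, b.partner = j, i
                    # snap into firm contact so the rendered silhouettes
                    # share a boundary (one connected merging region)
                    gap = _edge_gap(a, b)
                    d = math.dist(a.centroid, b.centroid)
                    if d > 0 and gap > -2.0:
                        shift = (gap + 2.0) / 2.0
                        ur = (b.centroid[0] - a.centroid[0]) / d
                        uc = (b.centroid[1] - a.centroid[1]) / d
                        a.centroid = (a.centroid[0] + shift * ur,
                                      a.centroid[1] + shift * uc)
                        b.centroid = (b.centroid[0] - shift * ur,
                                      b.centroid[1] - shift * uc)

    # -- 6. pair states follow geometry as partners drift -------------------
    # a merging doublet pulled out of contact reads as a split pair
    for i in sorted(ds):
        d = ds[i]
        if d.state is not DropletState.MERGING:
            continue
        p = ds.get(d.partner) if d.partner is not None else None
        if p is None:
            d.state = DropletState.UNSPLIT
            d.partner = None
        elif d.shape != "reservoir" and p.shape != "reservoir" \
                and _edge_gap(d, p) > _contact_gap(grid):
            d.state = p.state = DropletState.SPLIT

    for i in sorted(ds):
        d = ds[i]
        if d.state is not DropletState.SPLIT:
            continue
        p = ds.get(d.partner) if d.partner is not None else None
        if p is None:
            d.state = DropletState.UNSPLIT
            d.partner = None
            continue
        if d.shape == "reservoir":
            apart = _reservoir_gap(p, d, grid) > 1.6 * grid.pitch
        elif p.shape == "reservoir":
            apart = _reservoir_gap(d, p, grid) > 1.6 * grid.pitch
        else:
            apart = _edge_gap(d, p) > 1.6 * grid.pitch
        if apart:
            d.state = DropletState.UNSPLIT
            d.partner = None

    return [ds[i] for i in sorted(ds)]


# ---------------------------------------------------------------------------
# device
# ---------------------------------------------------------------------------

class VirtualDevice:
    """Chip + camera stand-in: holds droplets, applies actuation patterns and
    captures frames.  Controllers talk to it only through ``actuate`` and
    ``capture``, the same contract a hardware driver would expose.
    """

    def __init__(
        self,
        droplets: list[VirtualDroplet],
        grid: ElectrodeGrid,
        params: PhysicsParams | None = None,
        noise_sd: float = 1.5,
        brightness: float = 1.0,
        record: bool = False,
    ) -> None:
        self.grid = grid
        self.params = params if params is not None else PhysicsParams()
        self.droplets = [replace(d) for d in droplets]
        phys_ss, rend_ss = np.random.SeedSequence(self.params.seed).spawn(2)
        self.physics_rng = np.random.default_rng(phys_ss)
        self.render_rng = np.random.default_rng(rend_ss)
        self.noise_sd = noise_sd
        self.brightness = brightness
        self.frame_count = 0
        self.record = record
        self.frames: list[SceneFrame] = []
        self.truth_log: list[tuple[int, ...]] = []   # state multiset per recorded frame

    def actuate(self, active, frames: int = 1) -> None:
        """Hold ``active`` energized for ``frames`` camera frames."""
        pattern = ActuationPattern(active=frozenset(active), hold_frames=frames)
        for _ in range(frames):
            self.droplets = step_physics(
                self.droplets, pattern, self.grid, self.params, self.physics_rng)
            self.frame_count += 1
            if self.record:
                self.frames.append(self.capture())
                self.truth_log.append(self.state_multiset())

    def capture(self) -> SceneFrame:
        return render_frame(
            self.droplets, self.grid, brightness_factor=self.brightness,
            rng=self.render_rng, noise_sd=self.noise_sd,
            frame_index=self.frame_count)

    def state_multiset(self) -> tuple[int, ...]:
        return tuple(sorted(int(d.state) for d in self.droplets))

    def total_volume(self) -> float:
        return sum(d.volume for d in self.droplets)
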