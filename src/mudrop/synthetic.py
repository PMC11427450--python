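"""Synthetic droplet scenes: the training distribution of the virtual chip.

Scenes emulate the camera view of droplets on an electrode array in all four
states, across the five liquid colors (red, yellow, blue, black, transparent)
and four silhouettes (circle, rectangle, L-shape, triangle), with linear
brightness perturbation and mild sensor noise.  Geometry follows the state
definitions: a split pair sits roughly one electrode width apart, a merging
pair shares a boundary, a splitting droplet is an hourglass.  Lone droplets
of *different* groups are kept at least two electrode widths apart so the
pair states stay geometrically unambiguous.

Defaults: 3x3 grid with 32-px electrodes (128x128 canvas), droplet areas of
0.7–1.4 electrode areas for lone droplets (an electrowetting droplet spans
its electrode) and 0.35–0.7 per pair half, brightness factor drawn
uniformly from [0.5, 1.5] (the lab illumination variability the generator
emulates), and Gaussian sensor noise with sd 1.5 grey levels.
"""
from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from .control import ControlPolicy, run_merge, run_move, run_split
from .grid import ElectrodeGrid, default_grid, make_grid
from .observers import GroundTruthObserver
from .simulator import (PhysicsParams, SceneFrame, VirtualDevice,
                        VirtualDroplet, render_frame, shape_halfspan)
from .states import DROPLET_COLORS, DROPLET_SHAPES, DropletState

BRIGHTNESS_JITTER = (0.5, 1.5)
NOISE_SD = 1.5
#: split-pair edge gap in electrode widths, spanning the separations the
#: chip itself realizes (halves parked on flanking electrodes two pitches
#: apart); unrelated droplets stay >= 2.0 electrode widths apart
SPLIT_GAP = (0.85, 1.5)
UNRELATED_GAP = 2.0


def _group_radius(droplets: list[VirtualDroplet]) -> tuple[tuple[float, float], float]:
    """Bounding circle (center, radius) of one droplet group."""
    pts = np.array([d.centroid for d in droplets])
    center = pts.mean(axis=0)
    r = max(math.dist(center, d.centroid) + d.radius for d in droplets)
    return (float(center[0]), float(center[1])), r


def _sample_group(rng: np.random.Generator, grid: ElectrodeGrid,
                  state: DropletState, first_id: int,
                  hw: tuple[int, int]) -> list[VirtualDroplet]:
    h, w = hw
    color = str(rng.choice(list(DROPLET_COLORS)))
    shape = str(rng.choice(DROPLET_SHAPES))
    ep = grid.electrode_px

    def place(margin: float) -> tuple[float, float]:
        m = margin + 3
        return (float(rng.uniform(m, h - m)), float(rng.uniform(m, w - m)))

    if state is DropletState.UNSPLIT:
        area = float(rng.uniform(0.7, 1.4)) * ep * ep
        return [VirtualDroplet(first_id, area,
                               place(shape_halfspan(shape, area) + 2), state,
                               color, shape)]
    if state is DropletState.SPLITTING:
        area = float(rng.uniform(0.7, 1.4)) * ep * ep
        span = float(rng.uniform(0.45, 0.6)) * grid.pitch
        neck = float(rng.uniform(3.5, 6.0))
        r = math.sqrt(area / 2 / math.pi)
        axis = "h" if rng.uniform() < 0.5 else "v"
        d = VirtualDroplet(first_id, area, place(span + r + 2), state,
                           color, "circle", neck_px=neck, lobe_axis=axis,
                           lobe_span=span)
        return [d]
    # pair states
    a1 = float(rng.uniform(0.35, 0.7)) * ep * ep
    a2 = float(rng.uniform(0.35, 0.7)) * ep * ep
    if state is DropletState.MERGING:
        # droplets round off on contact; overlap slightly so the pair is one
        # connected merging region
        shape = "circle"
        h1 = math.sqrt(a1 / math.pi)
        h2 = math.sqrt(a2 / math.pi)
        dist = h1 + h2 - 2.0
    else:
        h1, h2 = shape_halfspan(shape, a1), shape_halfspan(shape, a2)
        dist = h1 + h2 + float(rng.uniform(*SPLIT_GAP)) * ep
        # wide pairs of chunky silhouettes must still fit the canvas
        dist_max = 2 * (min(hw) / 2.0 - max(h1, h2) - 5)
        dist = min(dist, max(dist_max, h1 + h2 + SPLIT_GAP[0] * ep))
    theta = float(rng.choice([0.0, math.pi / 2]))
    dr, dc = math.sin(theta) * dist / 2, math.cos(theta) * dist / 2
    c = place(dist / 2 + max(h1, h2) + 2)
    d1 = VirtualDroplet(first_id, a1, (c[0] - dr, c[1] - dc), state,
                        color, shape, partner=first_id + 1)
    d2 = VirtualDroplet(first_id + 1, a2, (c[0] + dr, c[1] + dc), state,
                        color, shape, partner=first_id)
    return [d1, d2]


def sample_scene(rng: np.random.Generator, grid: ElectrodeGrid | None = None,
                 primary_state: DropletState | None = None,
                 ) -> tuple[list[VirtualDroplet], float]:
    """Draw one scene: droplet groups plus its brightness factor."""
    grid = grid if grid is not None else default_grid()
    hw = grid.canvas_shape()
    state = (primary_state if primary_state is not None
             else DropletState(int(rng.integers(1, 5))))
    droplets = _sample_group(rng, grid, state, 0, hw)
    if rng.uniform() < 0.3:
        # second, unrelated group: a small lone droplet far enough from the
        # first group that it cannot be confused with a split partner
        c0, r0 = _group_radius(droplets)
        h, w = hw
        for _ in range(60):
            area = float(rng.uniform(0.22, 0.4)) * grid.electrode_px ** 2
            shape = str(rng.choice(DROPLET_SHAPES))
            half = shape_halfspan(shape, area) + 2
            pos = (float(rng.uniform(half + 3, h - half - 3)),
                   float(rng.uniform(half + 3, w - half - 3)))
            r1 = shape_halfspan(shape, area)
            if math.dist(c0, pos) - r0 - r1 >= UNRELATED_GAP * grid.electrode_px:
                droplets.append(VirtualDroplet(
                    max(d.droplet_id for d in droplets) + 1, area, pos,
                    DropletState.UNSPLIT,
                    str(rng.choice(list(DROPLET_COLORS))), shape))
                break
    brightness = float(rng.uniform(*BRIGHTNESS_JITTER))
    return droplets, brightness


def make_frames(n: int, seed: int, grid: ElectrodeGrid | None = None,
                brightness: bool = True) -> list[SceneFrame]:
    """Render ``n`` seeded scenes cycling the primary state so all four
    droplet states are evenly covered."""
    grid = grid if grid is not None else default_grid()
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n):
        state = DropletState(1 + i % 4)
        droplets, bf = sample_scene(rng, grid, primary_state=state)
        frames.append(render_frame(
            droplets, grid, brightness_factor=bf if brightness else 1.0,
            rng=rng, noise_sd=NOISE_SD, frame_index=i))
    return frames


def make_arrays(n: int, seed: int, grid: ElectrodeGrid | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """``n`` frames as stacked arrays: uint8 images (N,H,W,3), masks (N,H,W)."""
    frames = make_frames(n, seed, grid)
    images = np.stack([f.image for f in frames])
    masks = np.stack([f.mask for f in frames])
    return images, masks


def make_scenarios(n_scenarios: int, frames_per: int, seed: int,
                   grid: ElectrodeGrid | None = None) -> list[list[SceneFrame]]:
    """Independent short scene sequences for the brightness robustness sweep
    (rendered at reference brightness 1.0; the sweep perturbs them)."""
    grid = grid if grid is not None else default_grid()
    ss = np.random.SeedSequence(seed).spawn(n_scenarios)
    out = []
    for child in ss:
        rng = np.random.default_rng(child)
        frames = []
        for i in range(frames_per):
            state = DropletState(1 + i % 4)
            droplets, _ = sample_scene(rng, grid, primary_state=state)
            frames.append(render_frame(droplets, grid, brightness_factor=1.0,
                                       rng=rng, noise_sd=NOISE_SD,
                                       frame_index=i))
        out.append(frames)
    return out


# ---------------------------------------------------------------------------
# scripted control sessions (continuous recognition footage)
# ---------------------------------------------------------------------------

def dispense_grid(electrode_px: int = 32) -> ElectrodeGrid:
    """The 7-electrode dispensing strip: electrode 6 is the reservoir,
    5 the dispensing electrode, 2–4 the driving electrodes."""
    return make_grid(1, 7, electrode_px, reservoir_ids=[6], margin_px=20)


def split_strip(electrode_px: int = 32) -> ElectrodeGrid:
    """A 1x5 strip used for the splitting-CV experiments."""
    return make_grid(1, 5, electrode_px, margin_px=20)


def simulate_control_video(seed: int, n_frames: int = 2000,
                           grid: ElectrodeGrid | None = None,
                           params: PhysicsParams | None = None,
                           policy: ControlPolicy | None = None
                           ) -> list[SceneFrame]:
    """Record a long continuous control session on the virtual chip.

    Repeated sub-sessions (one per color x shape combination, cycling) run a
    scripted move / split / re-merge sequence with ground-truth feedback
    while every camera frame is recorded, until ``n_frames`` frames exist.
    The footage covers all four states plus the failure-recovery transients.
    """
    grid = grid if grid is not None else default_grid()
    policy = policy or ControlPolicy()
    base = params if params is not None else PhysicsParams()
    colors = list(DROPLET_COLORS)
    frames: list[SceneFrame] = []
    session = 0
    center = grid.index(grid.rows // 2, grid.cols // 2)
    while len(frames) < n_frames:
        child = int(np.random.SeedSequence([seed, session]).generate_state(1)[0]
                    % (2 ** 31))
        p = replace(base, seed=child)
        rng = np.random.default_rng(child)
        color = colors[session % len(colors)]
        shape = DROPLET_SHAPES[session % len(DROPLET_SHAPES)]
        area = float(rng.uniform(1.1, 1.4)) * grid.electrode_px ** 2
        droplet = VirtualDroplet(0, area, grid.center(center), color=color,
                                 shape=shape)
        device = VirtualDevice([droplet], grid, p, noise_sd=NOISE_SD,
                               record=True)
        observer = GroundTruthObserver(grid)
        try:
            run_move(device, observer, center, center - 1, policy)
            run_move(device, observer, center - 1, center, policy)
            out = run_split(device, observer, center, policy)
            if out.success:
                halves = sorted(o.electrode_id for o in out.final_observations)
                run_merge(device, observer, halves[0], halves[-1],
                          center, policy)
        except ValueError:
            pass   # a failed sub-session still contributed frames
        frames.extend(device.frames)
        session += 1
    return frames[:n_frames]
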