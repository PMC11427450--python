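"""Observation-driven droplet control: move, split, merge, dispense.

Each manipulation is a small state machine.  The controller issues an
actuation pattern, waits a predefined settle delay (observing every camera
frame), classifies what it sees, and corrects failures: a movement failure
re-activates the electrode; a split pulled to one side is moved back and
re-attempted; a splitting droplet that does not reach the split state within
the timeout (one second of frames at the camera rate) restarts the attempt.
``closed_loop_split`` adds the volume feedback: after every successful split
the pixel-count volume error of the pair is measured, and a pair exceeding
the tolerance (3% by default) is re-merged, moved to another electrode and
re-split, so every accepted pair is within tolerance by construction.

The controller is observation-only: it consumes :class:`DropletObservation`
lists from an observer callable and issues patterns to a device exposing
``actuate``/``capture`` — the same contract a hardware driver and a real
camera + segmentation stack would satisfy.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .extraction import DropletObservation, covers_electrodes, volume_error
from .grid import ElectrodeGrid
from .states import DropletState

U, SP, S, M = 1, 2, 3, 4  # class ids, for the legality table


@dataclass
class ControlPolicy:
    """Timing and feedback thresholds shared by all manipulations."""

    settle_frames: int = 3        # predefined post-actuation delay
    timeout_frames: int = 30      # the 1-s limit at 30 frames per second
    max_retries: int = 5
    restart_budget: int = 3       # dispensing restarts
    volume_tolerance: float = 0.03

    def __post_init__(self) -> None:
        if min(self.settle_frames, self.timeout_frames, self.max_retries,
               self.restart_budget) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0.0 < self.volume_tolerance < 1.0:
            raise ValueError("volume_tolerance must lie in (0, 1)")


@dataclass
class TraceEntry:
    active: frozenset[int]
    states: tuple[int, ...]       # sorted state multiset observed
    inferred: bool = False        # True when frames were skipped between looks


@dataclass
class ControlOutcome:
    success: bool
    retries: int
    frames_elapsed: int
    final_observations: list[DropletObservation]
    trace: list[TraceEntry] = field(default_factory=list)
    note: str = ""


class _Session:
    """Bookkeeping shared by the manipulation loops."""

    def __init__(self, device, observer, policy: ControlPolicy) -> None:
        self.device = device
        self.observer = observer
        self.policy = policy
        self.frames = 0
        self.retries = 0
        self.trace: list[TraceEntry] = []
        self.obs: list[DropletObservation] = []

    def look(self, active=frozenset()) -> list[DropletObservation]:
        self.obs = self.observer(self.device.capture())
        self.trace.append(TraceEntry(frozenset(active), _multiset(self.obs)))
        return self.obs

    def hold(self, active, frames: int) -> list[DropletObservation]:
        """Energize ``active`` for ``frames`` frames, observing each one."""
        active = frozenset(active)
        for _ in range(frames):
            self.device.actuate(active, 1)
            self.frames += 1
            self.look(active)
        return self.obs

    def outcome(self, success: bool, note: str = "") -> ControlOutcome:
        return ControlOutcome(success=success, retries=self.retries,
                              frames_elapsed=self.frames,
                              final_observations=self.obs,
                              trace=self.trace, note=note)


def _multiset(obs: list[DropletObservation]) -> tuple[int, ...]:
    return tuple(sorted(int(o.state) for o in obs))


def _at(obs, electrode: int, state: DropletState | None = None):
    return [o for o in obs
            if o.electrode_id == electrode
            and (state is None or o.state is state)]


# ---------------------------------------------------------------------------
# movement
# ---------------------------------------------------------------------------

def plan_move(src: int, dst: int, grid: ElectrodeGrid) -> list[frozenset[int]]:
    """Single-electrode activation sequence along a shortest Manhattan path,
    row moves before column moves."""
    if src == dst:
        raise ValueError("src and dst must differ")
    r0, c0 = grid.rc(src)
    r1, c1 = grid.rc(dst)
    path = []
    r, c = r0, c0
    while r != r1:
        r += 1 if r1 > r else -1
        path.append(frozenset({grid.index(r, c)}))
    while c != c1:
        c += 1 if c1 > c else -1
        path.append(frozenset({grid.index(r, c)}))
    return path


def run_move(device, observer, src: int, dst: int,
             policy: ControlPolicy | None = None,
             grid: ElectrodeGrid | None = None,
             _session: _Session | None = None) -> ControlOutcome:
    """Drive the droplet at ``src`` to ``dst``, re-activating the electrode
    whenever a step is observed to have failed."""
    policy = policy or ControlPolicy()
    grid = grid if grid is not None else device.grid
    s = _session or _Session(device, observer, policy)
    if _session is None:
        obs = s.look()
        if len(_at(obs, src, DropletState.UNSPLIT)) != 1:
            raise ValueError(f"expected exactly one unsplit droplet at {src}")
    for target in plan_move(src, dst, grid):
        (e,) = target
        attempts = 0
        while True:
            obs = s.hold(target, policy.settle_frames)
            if not obs:
                return s.outcome(False, note="droplet vanished")
            if _at(obs, e):
                break
            attempts += 1
            s.retries += 1
            if attempts > policy.max_retries:
                return s.outcome(False, note=f"stuck short of electrode {e}")
    ok = bool(_at(s.obs, dst))
    return s.outcome(ok)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def _split_flanks(at: int, grid: ElectrodeGrid) -> tuple[int, int]:
    r, c = grid.rc(at)
    if not (c - 1 >= 0 and c + 1 < grid.cols):
        raise ValueError(f"electrode {at} lacks free flanking electrodes")
    return grid.index(r, c - 1), grid.index(r, c + 1)


def run_split(device, observer, at: int,
              policy: ControlPolicy | None = None,
              grid: ElectrodeGrid | None = None,
              _session: _Session | None = None) -> ControlOutcome:
    """Split the droplet at ``at`` by energizing both flanking electrodes.

    Observed unsplit-on-one-side (the droplet pulled to the first electrode)
    reverts the droplet to its initial electrode and re-splits; a splitting
    state that does not resolve within the timeout also counts as a retry.
    """
    policy = policy or ControlPolicy()
    grid = grid if grid is not None else device.grid
    left, right = _split_flanks(at, grid)
    s = _session or _Session(device, observer, policy)
    if _session is None:
        obs = s.look()
        if len(_at(obs, at, DropletState.UNSPLIT)) != 1:
            raise ValueError(f"expected exactly one unsplit droplet at {at}")
    attempts = 0
    while attempts <= policy.max_retries:
        resolved = False
        for _ in range(policy.timeout_frames):
            obs = s.hold({left, right}, 1)
            if not obs:
                return s.outcome(False, note="droplet vanished")
            split_obs = [o for o in obs if o.state is DropletState.SPLIT]
            if len(split_obs) >= 2:
                return s.outcome(True)
            pulled = (_at(obs, left, DropletState.UNSPLIT)
                      or _at(obs, right, DropletState.UNSPLIT))
            if pulled:
                side = pulled[0].electrode_id
                sub = run_move(device, observer, side, at, policy, grid,
                               _session=s)
                if not sub.success:
                    return s.outcome(False, note="recovery move failed")
                resolved = True
                break
        attempts += 1
        s.retries += 1
        if not resolved:
            # timeout: relax the droplet back onto the center electrode
            s.hold({at}, policy.settle_frames)
    return s.outcome(False, note="split retries exhausted")


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def run_merge(device, observer, a: int, b: int, meet: int,
              policy: ControlPolicy | None = None,
              grid: ElectrodeGrid | None = None,
              _session: _Session | None = None) -> ControlOutcome:
    """Route the droplet at ``a`` into the one at ``b``; once contact is
    observed (merging state) wait for coalescence, then park the merged
    droplet at ``meet``."""
    if a == b:
        raise ValueError("a and b must differ")
    policy = policy or ControlPolicy()
    grid = grid if grid is not None else device.grid
    s = _session or _Session(device, observer, policy)
    if _session is None:
        obs = s.look()
        if not (_at(obs, a) and _at(obs, b)):
            raise ValueError("expected droplets at both a and b")

    path = plan_move(a, b, grid)
    merging_seen = False
    for target in path:
        (e,) = target
        # keep the stationary droplet pinned on its own electrode while the
        # other one is routed toward it
        pattern = target | {b}
        attempts = 0
        while True:
            obs = s.hold(pattern, policy.settle_frames)
            if any(o.state is DropletState.MERGING for o in obs) or \
                    (len(obs) == 1 and obs[0].state is DropletState.UNSPLIT):
                merging_seen = True
                break
            if _at(obs, e):
                break
            attempts += 1
            s.retries += 1
            if attempts > policy.max_retries:
                return s.outcome(False, note="approach move failed")
        if merging_seen:
            break

    # wait for coalescence into a single unsplit droplet
    for _ in range(policy.timeout_frames):
        if len(s.obs) == 1 and s.obs[0].state is DropletState.UNSPLIT:
            break
        s.hold({b}, 1)
    if not (len(s.obs) == 1 and s.obs[0].state is DropletState.UNSPLIT):
        return s.outcome(False, note="droplets failed to coalesce")

    here = s.obs[0].electrode_id
    if here != meet:
        sub = run_move(device, observer, here, meet, policy, grid, _session=s)
        if not sub.success:
            return s.outcome(False, note="post-merge parking failed")
    return s.outcome(True)


# ---------------------------------------------------------------------------
# dispensing
# ---------------------------------------------------------------------------

def run_dispense(device, observer, grid: ElectrodeGrid | None = None,
                 policy: ControlPolicy | None = None) -> ControlOutcome:
    """Dispense one unit droplet from the reservoir.

    Phase 1 energizes the driving + dispensing electrodes until the liquid
    finger is observed to cover the target electrodes; phase 2 re-energizes
    the reservoir with the dispensing electrode off and waits (within the
    timeout) for the splitting -> split transition; phase 3 accepts the
    droplet if its pixel-count volume error against the target electrode
    area is within tolerance, otherwise the process restarts.
    """
    policy = policy or ControlPolicy()
    grid = grid if grid is not None else device.grid
    if not grid.reservoir_ids:
        raise ValueError("grid has no reservoir electrode")
    reservoir = max(grid.reservoir_ids)
    dispensing = reservoir - 1
    targets = [reservoir - 3, reservoir - 2]
    target_area = len(targets) * grid.footprint_area()
    s = _Session(device, observer, policy)
    obs = s.look()
    if not obs:
        raise ValueError("no reservoir droplet observed")

    for restart in range(policy.restart_budget + 1):
        # phase 1: pull the liquid finger out until it covers the targets
        covered = False
        for _ in range(policy.timeout_frames):
            s.hold({*targets, dispensing}, 1)
            frame_mask = s.device.capture().mask
            res_obs = max(s.obs, key=lambda o: o.pixel_count, default=None)
            if res_obs and covers_electrodes(res_obs, frame_mask, targets, grid):
                covered = True
                break
        if not covered:
            s.retries += 1
            continue
        # phase 2: reservoir on, dispensing electrode off -> neck and break
        dispensed = None
        for _ in range(policy.timeout_frames):
            obs = s.hold({reservoir}, 1)
            small = [o for o in obs
                     if o.state is DropletState.SPLIT
                     and o.electrode_id in targets]
            if small:
                dispensed = min(small, key=lambda o: o.pixel_count)
                break
        if dispensed is None:   # timeout event: restart the process
            s.retries += 1
            continue
        # phase 3: volume feedback
        err = volume_error((dispensed.pixel_count, target_area))
        if err <= policy.volume_tolerance:
            return s.outcome(True)
        # off-spec volume: drive the droplet back into the reservoir and retry
        s.retries += 1
        here = dispensed.electrode_id
        for e in range(here + 1, reservoir):
            s.hold({e}, policy.settle_frames)
            if len(s.obs) <= 1:
                break
        s.hold({reservoir, dispensing}, policy.settle_frames)
    return s.outcome(False, note="dispense restart budget exhausted")


# ---------------------------------------------------------------------------
# closed-loop splitting
# ---------------------------------------------------------------------------

def closed_loop_split(device, observer, at: int,
                      policy: ControlPolicy | None = None,
                      grid: ElectrodeGrid | None = None
                      ) -> tuple[tuple[int, int] | None, ControlOutcome]:
    """Split with pixel-count volume feedback.

    After each successful split the volume error ``|a-b|/(a+b)`` of the pair
    is computed from pixel counts; a pair exceeding the tolerance is
    re-merged, moved one electrode over (back and forth at a grid edge), and
    re-split.  Every accepted pair satisfies the tolerance by construction;
    when retries run out the last pair is returned flagged unaccepted.
    """
    policy = policy or ControlPolicy()
    grid = grid if grid is not None else device.grid
    s = _Session(device, observer, policy)
    obs = s.look()
    if len(_at(obs, at, DropletState.UNSPLIT)) != 1:
        raise ValueError(f"expected exactly one unsplit droplet at {at}")

    cur = at
    pair = None
    for attempt in range(policy.max_retries + 1):
        out = run_split(device, observer, cur, policy, grid, _session=s)
        if not out.success:
            return pair, s.outcome(False, note="split failed")
        halves = sorted((o for o in s.obs if o.state is DropletState.SPLIT),
                        key=lambda o: o.electrode_id)
        pair = (halves[0].pixel_count, halves[1].pixel_count)
        if volume_error(pair) <= policy.volume_tolerance:
            return pair, s.outcome(True)
        if attempt == policy.max_retries:
            break
        s.retries += 1
        # re-merge the rejected halves, park at a neighboring electrode
        left, right = _split_flanks(cur, grid)
        r, c = grid.rc(cur)
        new = grid.index(r, c - 1) if c - 1 >= 1 else grid.index(r, c + 1)
        sub = run_merge(device, observer, halves[0].electrode_id,
                        halves[1].electrode_id, new, policy, grid, _session=s)
        if not sub.success:
            return pair, s.outcome(False, note="re-merge failed")
        cur = new
    return pair, s.outcome(False, note="volume tolerance not met within retries")


def coefficient_of_variation(volumes) -> float:
    """Sample CV in percent: ``100 * sd / mean`` with the n-1 denominator."""
    v = np.asarray(list(volumes), dtype=np.float64)
    if v.size < 2:
        raise ValueError("CV needs at least two values")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("CV needs a positive mean")
    return float(100.0 * v.std(ddof=1) / mean)


# ---------------------------------------------------------------------------
# trace legality
# ---------------------------------------------------------------------------

def _successors(states: tuple[int, ...]) -> set[tuple[int, ...]]:
    """One-frame successors of an observed state multiset under the control
    state machines (identity included)."""
    out = {states}
    ms = list(states)

    def with_swap(remove, add):
        rest = list(ms)
        for x in remove:
            rest.remove(x)
        out.add(tuple(sorted(rest + list(add))))

    for x in set(ms):
        if x == U:
            with_swap([U], [SP])                # unsplit -> splitting
        if x == SP:
            with_swap([SP], [S, S])             # splitting -> split pair
            with_swap([SP], [U])                # pulled to one side
        if x == M:
            with_swap([M], [U])                 # coalescence
            with_swap([M], [M, M])              # contact-point flicker
            with_swap([M], [S, S])              # doublet pulled apart
    # two droplets coming into contact usually read as ONE connected merging
    # region, but the rasterized contact may flicker between one and two
    for a, b in ((U, U), (U, S), (S, S)):
        if (ms.count(a) >= 2 if a == b else ms.count(a) >= 1 and ms.count(b) >= 1):
            with_swap([a, b], [M])
            with_swap([a, b], [M, M])
    if ms.count(S) >= 2:
        with_swap([S, S], [U, U])               # pair drifts apart
    if ms.count(U) >= 2:
        with_swap([U, U], [U])                  # absorbed into a reservoir
    if ms.count(M) >= 2:
        with_swap([M, M], [U])                  # coalescence of a flickering pair
        with_swap([M, M], [M])
    return out


def validate_trace(trace: list[TraceEntry]) -> bool:
    """Check that consecutive observed state multisets only make transitions
    the state machines permit; an entry flagged ``inferred`` (frames skipped
    between observations) may take two elementary transitions at once."""
    for prev, cur in zip(trace, trace[1:]):
        succ = _successors(prev.states)
        if cur.inferred:
            succ = set().union(*(_successors(x) for x in succ))
        if cur.states not in succ:
            return False
    return True
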