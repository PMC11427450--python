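"""Observers: frame -> droplet observations.

Both observers share the extraction pipeline (region growing over a label
mask, then electrode assignment); they differ only in where the mask comes
from — the ground truth of the virtual device, or the segmentation network.
"""
from __future__ import annotations

from .extraction import DropletObservation, observe_mask
from .grid import ElectrodeGrid
from .segmentation import predict
from .simulator import SceneFrame


class GroundTruthObserver:
    """Reads the simulator's ground-truth mask — the ideal-camera baseline."""

    def __init__(self, grid: ElectrodeGrid, connectivity: int = 4,
                 min_size: int | None = None) -> None:
        self.grid = grid
        self.connectivity = connectivity
        self.min_size = min_size

    def __call__(self, frame: SceneFrame) -> list[DropletObservation]:
        return observe_mask(frame.mask, self.grid, self.connectivity,
                            self.min_size)


class ModelObserver:
    """Runs the trained segmentation network on the camera image."""

    def __init__(self, net, grid: ElectrodeGrid, working_resolution: int = 512,
                 connectivity: int = 4, min_size: int | None = None) -> None:
        self.net = net
        self.grid = grid
        self.working_resolution = working_resolution
        self.connectivity = connectivity
        self.min_size = min_size

    def __call__(self, frame: SceneFrame) -> list[DropletObservation]:
        mask = predict(self.net, frame.image, self.working_resolution)
        return observe_mask(mask, self.grid, self.connectivity, self.min_size)
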