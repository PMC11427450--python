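"""Droplet state vocabulary and the fixed mask class encoding.

On an electrowetting chip a droplet is observed in one of four morphological
states: a lone droplet (*unsplit*), an hourglass-necked droplet mid-division
(*splitting*), a freshly divided pair separated by roughly one electrode width
(*split*), or two droplets in contact (*merging*).  Segmentation masks use a
fixed 5-class integer encoding with background = 0.
"""
from __future__ import annotations

from enum import IntEnum


class DropletState(IntEnum):
    """Morphological droplet state; the value is the mask class id."""

    UNSPLIT = 1
    SPLITTING = 2
    SPLIT = 3
    MERGING = 4


BACKGROUND = 0
NUM_CLASSES = 5
FOREGROUND_CLASSES = (1, 2, 3, 4)

#: LabelMe polygon label -> class id
STATE_NAMES = {
    "unsplit": DropletState.UNSPLIT,
    "splitting": DropletState.SPLITTING,
    "split": DropletState.SPLIT,
    "merging": DropletState.MERGING,
}

#: class id -> display color for indexed-PNG masks (background, then the four
#: states in the conventional overlay colors: red, green, yellow, blue).
MASK_PALETTE = {
    0: (0, 0, 0),
    1: (220, 40, 40),
    2: (40, 200, 60),
    3: (230, 210, 40),
    4: (50, 90, 220),
}

#: named droplet liquids available to the renderer; ``None`` marks a
#: transparent droplet (rendered as a refraction rim over the background).
DROPLET_COLORS = {
    "red": (200, 45, 45),
    "yellow": (225, 195, 60),
    "blue": (55, 85, 200),
    "black": (35, 35, 35),
    "transparent": None,
}

DROPLET_SHAPES = ("circle", "rectangle", "l_shape", "triangle")
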