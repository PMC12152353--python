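"""Workspace geometry: pads, start key, and the camera's pixel grid.

The physical setup is a table filmed from above: a picking pad on the
participant's right where bricks are presented, a placing pad on the left,
and a start key on the midline close to the participant. All analysis
regions are expressed in a single "image-cm" frame: the camera's pixel
frame scaled by ``pixel_scale`` (cm per pixel), origin at the top-left
corner, y increasing toward the participant (downward in the image).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# physical constants of the apparatus (cm)
PAD_WIDTH = 22.0      # short side, facing the participant
PAD_DEPTH = 30.0
PAD_GAP = 16.0        # lateral gap between the two pads
PAD_EDGE_OFFSET = 5.5   # table edge to pad front edge
KEY_EDGE_OFFSET = 3.5   # table edge to key front edge
KEY_SIZE = 3.0


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in image-cm coordinates."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(f"degenerate rectangle: {self}")

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x0 + self.x1), 0.5 * (self.y0 + self.y1))

    def contains(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.x0) & (x <= self.x1) & (y >= self.y0) & (y <= self.y1)

    def distance_outside(self, x, y):
        """Euclidean distance to the rectangle boundary; 0 inside."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        dx = np.maximum(np.maximum(self.x0 - x, x - self.x1), 0.0)
        dy = np.maximum(np.maximum(self.y0 - y, y - self.y1), 0.0)
        return np.hypot(dx, dy)

    def quadrants(self) -> dict[int, "Rect"]:
        """Split into four equal quadrants.

        Ids follow the convention used for the spatial-preference analysis:
        1 = far-left, 2 = far-right, 3 = near-left, 4 = near-right, where
        "near" is the half closer to the participant (larger y).
        """
        cx, cy = self.center
        return {
            1: Rect(self.x0, self.y0, cx, cy),
            2: Rect(cx, self.y0, self.x1, cy),
            3: Rect(self.x0, cy, cx, self.y1),
            4: Rect(cx, cy, self.x1, self.y1),
        }


@dataclass(frozen=True)
class WorkspaceLayout:
    """Positions of pads and start key plus camera calibration.

    ``pixel_scale`` is cm per pixel (default 0.042, i.e. the 4.73-pixel
    tracking error corresponds to about 0.2 cm); ``image_size`` is
    (width, height) in pixels. The default layout places the apparatus in a
    1440 x 1080 frame with the participant along the bottom edge.
    """

    picking_pad: Rect
    placing_pad: Rect
    start_key: tuple[float, float]
    key_region: Rect
    pixel_scale: float = 0.042
    image_size: tuple[int, int] = (1440, 1080)

    def __post_init__(self) -> None:
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")
        # pads must not overlap
        a, b = self.picking_pad, self.placing_pad
        if not (a.x0 >= b.x1 or b.x0 >= a.x1 or a.y0 >= b.y1 or b.y0 >= a.y1):
            raise ValueError("picking and placing pads overlap")

    @classmethod
    def default(cls, pixel_scale: float = 0.042,
                image_size: tuple[int, int] = (1440, 1080)) -> "WorkspaceLayout":
        w_cm = image_size[0] * pixel_scale
        h_cm = image_size[1] * pixel_scale
        cx = w_cm / 2.0
        bottom = h_cm  # participant edge
        y1 = bottom - PAD_EDGE_OFFSET
        y0 = y1 - PAD_DEPTH
        picking = Rect(cx + PAD_GAP / 2.0, y0, cx + PAD_GAP / 2.0 + PAD_WIDTH, y1)
        placing = Rect(cx - PAD_GAP / 2.0 - PAD_WIDTH, y0, cx - PAD_GAP / 2.0, y1)
        key_y = bottom - KEY_EDGE_OFFSET - KEY_SIZE / 2.0
        key = (cx, key_y)
        key_rect = Rect(cx - KEY_SIZE / 2.0, key_y - KEY_SIZE / 2.0,
                        cx + KEY_SIZE / 2.0, key_y + KEY_SIZE / 2.0)
        return cls(picking_pad=picking, placing_pad=placing, start_key=key,
                   key_region=key_rect, pixel_scale=pixel_scale,
                   image_size=image_size)

    # -- coordinate transforms -------------------------------------------
    def cm_to_px(self, x_cm, y_cm):
        return (np.asarray(x_cm) / self.pixel_scale,
                np.asarray(y_cm) / self.pixel_scale)

    def px_to_cm(self, x_px, y_px):
        return (np.asarray(x_px) * self.pixel_scale,
                np.asarray(y_px) * self.pixel_scale)

    def pad(self, area: str) -> Rect:
        if area == "picking":
            return self.picking_pad
        if area == "placing":
            return self.placing_pad
        raise ValueError(f"unknown area {area!r} (expected 'picking' or 'placing')")

    def pad_px(self, area: str) -> tuple[int, int, int, int]:
        """Pad crop rectangle in integer pixel coordinates (left, top, right, bottom)."""
        r = self.pad(area)
        return (int(round(r.x0 / self.pixel_scale)),
                int(round(r.y0 / self.pixel_scale)),
                int(round(r.x1 / self.pixel_scale)),
                int(round(r.y1 / self.pixel_scale)))
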