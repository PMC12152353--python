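"""Difference-image quantification of picking and placing activity.

Start and end scene photographs of a trial differ exactly where objects
were taken or put down. Each image is cropped to the relevant pad,
binarized in HSV space (saturation and value both above 50 mark a colored
brick against the gray pad), blurred (Gaussian radius 5), and the absolute
difference of the two blurred masks is normalized, blurred, floored at 150
to remove small lighting/jitter artifacts, blurred once more, and rescaled
to a 0-100% activation map. Mean activation per pad quadrant localizes
where picking/placing happened (quadrant ids: 1 far-left, 2 far-right,
3 near-left, 4 near-right).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageFilter

from .layout import WorkspaceLayout

ARTIFACT_FLOOR = 150  # on the 0-255 normalized difference scale
BLUR_RADIUS = 5.0


@dataclass
class ActivationMap:
    area: str                       # "picking" or "placing"
    values: np.ndarray              # per-pixel activation, 0-100 scale
    quadrant_means: tuple[float, float, float, float]
    crop_rect: tuple[int, int, int, int]  # pixels (left, top, right, bottom)


def _require_rgb(image: Image.Image) -> Image.Image:
    if not isinstance(image, Image.Image):
        raise TypeError("expected a PIL image")
    if image.mode != "RGB":
        raise ValueError(f"expected an RGB image, got mode {image.mode!r}")
    return image


def binarize_scene(image: Image.Image, s_threshold: int = 50,
                   v_threshold: int = 50) -> np.ndarray:
    """Saturation/value mask: 255 where a colored object is, 0 on gray background."""
    image = _require_rgb(image)
    hsv = np.asarray(image.convert("HSV"))
    mask = (hsv[..., 1] > s_threshold) & (hsv[..., 2] > v_threshold)
    return np.where(mask, 255, 0).astype(np.uint8)


def _blur(arr: np.ndarray, radius: float = BLUR_RADIUS) -> np.ndarray:
    img = Image.fromarray(arr.astype(np.uint8), mode="L")
    return np.asarray(img.filter(ImageFilter.GaussianBlur(radius)), dtype=float)


def quadrant_means(values: np.ndarray) -> tuple[float, float, float, float]:
    """Mean activation in the four equal quadrants (1 far-left ... 4 near-right).

    With odd dimensions the extra pixel row/column goes to the near/right
    quadrants.
    """
    values = np.asarray(values, dtype=float)
    h, w = values.shape
    cy, cx = h // 2, w // 2
    return (float(values[:cy, :cx].mean()),   # 1 far-left
            float(values[:cy, cx:].mean()),   # 2 far-right
            float(values[cy:, :cx].mean()),   # 3 near-left
            float(values[cy:, cx:].mean()))   # 4 near-right


def activation_map(start_image: Image.Image, end_image: Image.Image,
                   area: str, layout: WorkspaceLayout | None = None,
                   crop_rect: tuple[int, int, int, int] | None = None
                   ) -> ActivationMap:
    """Activation map over one pad from a trial's start/end scene pair.

    ``crop_rect`` (left, top, right, bottom in pixels) overrides the pad
    rectangle derived from ``layout``. The result is symmetric in the image
    order (absolute difference) and all-zero for identical images.
    """
    start_image = _require_rgb(start_image)
    end_image = _require_rgb(end_image)
    if start_image.size != end_image.size:
        raise ValueError("start and end images must have the same size")
    if crop_rect is None:
        layout = layout or WorkspaceLayout.default()
        left, top, right, bottom = layout.pad_px(area)
        # rescale the pad rectangle if the photograph resolution differs
        sx = start_image.size[0] / layout.image_size[0]
        sy = start_image.size[1] / layout.image_size[1]
        crop_rect = (int(round(left * sx)), int(round(top * sy)),
                     int(round(right * sx)), int(round(bottom * sy)))
    a = binarize_scene(start_image.crop(crop_rect))
    b = binarize_scene(end_image.crop(crop_rect))
    diff = np.abs(_blur(a) - _blur(b))
    peak = diff.max()
    if peak > 0:
        diff = diff * (255.0 / peak)
    diff = _blur(diff)
    diff[diff < ARTIFACT_FLOOR] = 0.0
    diff = _blur(diff)
    values = diff * (100.0 / 255.0)
    return ActivationMap(area=area, values=values,
                         quadrant_means=quadrant_means(values),
                         crop_rect=tuple(crop_rect))
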