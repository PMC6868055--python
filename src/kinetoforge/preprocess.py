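"""Image-processing chain from z-stack to analysis-ready 50x50 RGB images.

The canonical order is: center crop to 50x50 -> maximum intensity
projection over z -> per-channel 16-bit normalization -> duplication into
the 8 dihedral (D4) orientations -> background subtraction -> 2D adaptive
Wiener denoising. The same chain applies to simulated and user-supplied
stacks; its output is the fixed input contract of the feature extractor
and the CNN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .microscope_sim import ImageStack

__all__ = ["ProcessedImage", "max_project", "normalize_16bit",
           "augment_orientations", "subtract_background", "wiener_denoise",
           "process_stack", "CHANNEL_TO_RGB"]

# fluorescent channel -> RGB slot; blue is unused by the two-color assays
CHANNEL_TO_RGB = {"red": 0, "green": 1, "blue": 2}

UINT16_MAX = 65535


@dataclass
class ProcessedImage:
    """A 50x50x3 16-bit RGB image with orientation and provenance tags."""

    pixels: np.ndarray
    orientation: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("processed image must be (rows, cols, 3)")
        if self.pixels.dtype != np.uint16:
            if self.pixels.min() < 0 or self.pixels.max() > UINT16_MAX:
                raise ValueError("pixel values outside the 16-bit range")
            self.pixels = self.pixels.astype(np.uint16)


def max_project(stack: ImageStack) -> np.ndarray:
    """Per-channel, per-pixel maximum over z. Returns (channels, rows, cols)."""
    if stack.voxels.shape[1] < 1:
        raise ValueError("stack has no z planes")
    return stack.voxels.max(axis=1)


def normalize_16bit(image: np.ndarray) -> np.ndarray:
    """Linearly rescale each channel of a (rows, cols, C) image to [0, 65535].

    A constant channel carries no usable signal and maps to all zeros.
    """
    image = np.asarray(image, dtype=float)
    out = np.zeros_like(image)
    for c in range(image.shape[2]):
        ch = image[..., c]
        lo, hi = ch.min(), ch.max()
        if hi > lo:
            out[..., c] = (ch - lo) / (hi - lo) * UINT16_MAX
    return np.rint(out).astype(np.uint16)


def augment_orientations(image: np.ndarray) -> list[np.ndarray]:
    """The 8 dihedral-group orientations of a square image, original first.

    Order: rotations by 0/90/180/270 degrees, then the left-right flip of
    each. 90-degree rotations are lossless on square images, which is why
    arbitrary-angle rotations are not offered.
    """
    image = np.asarray(image)
    if image.shape[0] != image.shape[1]:
        raise ValueError("dihedral augmentation requires a square image")
    rots = [np.rot90(image, k, axes=(0, 1)) for k in range(4)]
    flips = [np.flip(r, axis=1) for r in rots]
    return [np.ascontiguousarray(a) for a in rots + flips]


def subtract_background(image: np.ndarray, method: str = "median") -> np.ndarray:
    """Subtract a per-channel background estimate, clipping at zero."""
    image = np.asarray(image, dtype=float)
    if method == "median":
        bg = np.median(image, axis=(0, 1), keepdims=True)
    elif method == "min":
        bg = image.min(axis=(0, 1), keepdims=True)
    else:
        raise ValueError(f"unknown background method {method!r}")
    return np.clip(image - bg, 0.0, None)


def wiener_denoise(image: np.ndarray, window: tuple = (3, 3)) -> np.ndarray:
    """Local-adaptive 2D Wiener filter per channel.

    Classic formulation: local means/variances over the window, noise power
    estimated as the mean of the local variances.
    """
    image = np.asarray(image, dtype=float)
    if window[0] > image.shape[0] or window[1] > image.shape[1]:
        raise ValueError("Wiener window larger than image")
    out = np.empty_like(image)
    for c in range(image.shape[2]):
        ch = image[..., c]
        if np.ptp(ch) == 0:
            out[..., c] = ch
        else:
            # flat local windows yield 0/0 inside scipy's estimator; those
            # pixels fall back to the local mean, so the warnings are moot
            with np.errstate(divide="ignore", invalid="ignore"):
                out[..., c] = scipy.signal.wiener(ch, mysize=window)
    return out


def _center_crop(channels_first: np.ndarray, size: tuple = (50, 50)) -> np.ndarray:
    c, ny, nx = channels_first.shape
    ty, tx = size
    if ny < ty or nx < tx:
        raise ValueError(f"stack field {ny}x{nx} smaller than crop {ty}x{tx}")
    y0 = (ny - ty) // 2
    x0 = (nx - tx) // 2
    return channels_first[:, y0:y0 + ty, x0:x0 + tx]


def process_stack(stack: ImageStack, crop: tuple = (50, 50),
                  background: str = "median",
                  wiener_window: tuple = (3, 3),
                  source_id: str = "") -> list[ProcessedImage]:
    """Run the full chain on one stack; returns 8 oriented ProcessedImages.

    Channels are routed into RGB slots via :data:`CHANNEL_TO_RGB`; slots
    without a source channel stay zero.
    """
    proj = _center_crop(max_project(stack), crop)
    ny, nx = proj.shape[1:]
    rgb = np.zeros((ny, nx, 3), dtype=float)
    for name, arr in zip(stack.channel_map, proj):
        slot = CHANNEL_TO_RGB.get(name)
        if slot is None:
            raise ValueError(f"channel {name!r} has no RGB slot")
        rgb[..., slot] = arr
    norm = normalize_16bit(rgb)
    outputs = []
    for k, oriented in enumerate(augment_orientations(norm)):
        sub = subtract_background(oriented, method=background)
        den = wiener_denoise(sub, window=wiener_window)
        final = np.clip(np.rint(den), 0, UINT16_MAX).astype(np.uint16)
        outputs.append(ProcessedImage(
            final, orientation=k,
            provenance={"source": source_id, "orientation": k,
                        "steps": ["crop", "max_project", "normalize",
                                  "orient", "background", "wiener"]}))
    return outputs
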