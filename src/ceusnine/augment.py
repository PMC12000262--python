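"""Synchronized geometric augmentation of nine-slice pseudo-RGB stacks.

One concrete transform (zoom, flips, shifts, rotation) is sampled per
training example and then applied identically to every one of the nine
grayscale slices, so the lesion stays co-registered across phases.  Areas
moved in from outside the frame are filled with constant black.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from .assembly import PseudoRGBStack


@dataclass(frozen=True)
class AugmentParams:
    """Sampling ranges: zoom U[0.8,1.2], flips Bernoulli(0.5), shifts within
    +/-10% of the side, rotation within +/-15 degrees."""

    zoom_range: tuple[float, float] = (0.8, 1.2)
    horizontal_flip: bool = True
    vertical_flip: bool = True
    height_shift: float = 0.1
    width_shift: float = 0.1
    rotation: float = 15.0
    fill_mode: str = "constant"

    def __post_init__(self) -> None:
        lo, hi = self.zoom_range
        if lo <= 0 or hi < lo:
            raise ValueError("zoom bounds must be positive with min <= max")
        if not (0 <= self.height_shift < 1 and 0 <= self.width_shift < 1):
            raise ValueError("shift fractions must lie in [0, 1)")
        if self.rotation < 0:
            raise ValueError("rotation range must be >= 0")
        if self.fill_mode != "constant":
            raise ValueError("only constant (black) fill is supported")


@dataclass(frozen=True)
class TransformSpec:
    """One concrete sampled transform; shifts are fractions of the side."""

    zoom: float = 1.0
    hflip: bool = False
    vflip: bool = False
    shift_rows: float = 0.0
    shift_cols: float = 0.0
    angle_deg: float = 0.0

    def is_identity(self) -> bool:
        return (self.zoom == 1.0 and not self.hflip and not self.vflip
                and self.shift_rows == 0.0 and self.shift_cols == 0.0
                and self.angle_deg == 0.0)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TransformSpec":
        return cls(**json.loads(text))


def sample_transform(params: AugmentParams,
                     rng: np.random.Generator | int) -> TransformSpec:
    """Sample one concrete transform; deterministic for a fixed rng state."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    lo, hi = params.zoom_range
    return TransformSpec(
        zoom=float(rng.uniform(lo, hi)),
        hflip=bool(params.horizontal_flip and rng.random() < 0.5),
        vflip=bool(params.vertical_flip and rng.random() < 0.5),
        shift_rows=float(rng.uniform(-params.height_shift, params.height_shift)),
        shift_cols=float(rng.uniform(-params.width_shift, params.width_shift)),
        angle_deg=float(rng.uniform(-params.rotation, params.rotation)),
    )


def _affine(t: TransformSpec, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Inverse map (matrix, offset) for scipy affine_transform.

    Forward map: flip about center, zoom, rotate, then shift; the inverse is
    what the resampler consumes.
    """
    h, w = shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    theta = math.radians(t.angle_deg)
    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])
    flip = np.diag([-1.0 if t.vflip else 1.0, -1.0 if t.hflip else 1.0])
    fwd = rot @ (t.zoom * flip)
    inv = np.linalg.inv(fwd)
    shift = np.array([t.shift_rows * h, t.shift_cols * w])
    offset = center - inv @ (center + shift)
    return inv, offset


def apply_transform(image: np.ndarray, t: TransformSpec) -> np.ndarray:
    """Apply one transform to a single 2-D grayscale slice (bilinear,
    constant-black fill)."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale slice")
    if t.is_identity():
        return img.copy()
    matrix, offset = _affine(t, img.shape)
    return ndimage.affine_transform(img, matrix, offset=offset, order=1,
                                    mode="constant", cval=0.0)


def transform_stack_array(data: np.ndarray, t: TransformSpec) -> np.ndarray:
    """Apply one transform to every slice of a raw (3, H, W, 3) stack array."""
    data = np.asarray(data)
    if data.ndim != 4 or data.shape[0] != 3 or data.shape[3] != 3:
        raise ValueError(f"expected a (3, H, W, 3) stack, got {data.shape}")
    out = np.empty(data.shape, dtype=np.float64)
    for k in range(3):
        for c in range(3):
            out[k, :, :, c] = apply_transform(data[k, :, :, c], t)
    return out


def apply_synchronized(stack: PseudoRGBStack, t: TransformSpec) -> PseudoRGBStack:
    """Apply the same transform to all nine slices of a stack."""
    return PseudoRGBStack(data=transform_stack_array(stack.data, t),
                          slots=stack.slots)
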