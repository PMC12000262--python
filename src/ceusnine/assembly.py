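"""From per-case phase frames to the nine-slot model input.

Covers the square ROI contract (side ~50% larger than the lesion diameter,
constant within a case), the rules that pick exactly nine of the eleven phase
datasets for a given examination time limit, pseudo-RGB packing (nine
grayscale slices as three 3-channel images), bilinear resizing to the model
input side, and stratified case-level train/validation/test splitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize
from sklearn.model_selection import StratifiedKFold, train_test_split

from .phantom import PHASE_IDS

#: Examination time limits, shortest first.  "B" is the degenerate
#: B-mode-only condition used by the single-input reference model.
TIME_LIMITS = ("B", "B-AF", "B-1m", "B-2m", "B-5m", "B-10m")

_AF_IDS = tuple(f"AF{i}" for i in range(1, 7))

#: Phases available under each limit, in nominal time order.
_AVAILABLE = {
    "B": ("B",),
    "B-AF": ("B",) + _AF_IDS,
    "B-1m": ("B",) + _AF_IDS + ("1m",),
    "B-2m": ("B",) + _AF_IDS + ("1m", "2m"),
    "B-5m": ("B",) + _AF_IDS + ("1m", "2m", "5m"),
    "B-10m": ("B",) + _AF_IDS + ("1m", "2m", "5m", "10m"),
}

#: Rank of each phase id in nominal time order (duplicates share a rank).
PHASE_ORDER = {p: i for i, p in enumerate(PHASE_IDS)}


# ---------------------------------------------------------------------------
# ROI extraction
# ---------------------------------------------------------------------------

def roi_side(lesion_diameter: float, margin_factor: float = 1.5) -> int:
    """Square ROI side: the lesion diameter enlarged by the margin factor."""
    if lesion_diameter <= 0:
        raise ValueError("lesion_diameter must be positive")
    if margin_factor <= 1:
        raise ValueError("margin_factor must exceed 1")
    return int(round(margin_factor * lesion_diameter))


def extract_roi(image: np.ndarray, lesion_center: tuple[float, float],
                lesion_diameter: float, margin_factor: float = 1.5) -> np.ndarray:
    """Crop the square lesion ROI from one frame.

    The window is centered on the lesion; near an image edge it is shifted
    (never zero-padded) so the crop stays inside the frame.  The same side
    must be reused for every phase of a case.
    """
    side = roi_side(lesion_diameter, margin_factor)
    h, w = image.shape[:2]
    if side > h or side > w:
        raise ValueError(f"ROI side {side} exceeds image shape {(h, w)}")
    r0 = int(round(lesion_center[0] - side / 2.0))
    c0 = int(round(lesion_center[1] - side / 2.0))
    r0 = min(max(r0, 0), h - side)
    c0 = min(max(c0, 0), w - side)
    return image[r0:r0 + side, c0:c0 + side]


# ---------------------------------------------------------------------------
# phase selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseSelection:
    """Nine ordered phase slots for one time limit (duplicates allowed)."""

    time_limit: str
    slots: tuple[str, ...]
    excluded: tuple[str, ...]
    rule_seed: int

    def __post_init__(self) -> None:
        if len(self.slots) != 9:
            raise ValueError("a selection has exactly nine slots")
        ranks = [PHASE_ORDER[p] for p in self.slots]
        if any(b < a for a, b in zip(ranks, ranks[1:])):
            raise ValueError("slots must be ordered by non-decreasing phase time")


def select_phases(available: tuple[str, ...] | list[str], time_limit: str,
                  rule_seed: int = 0) -> PhaseSelection:
    """Pick the nine phase slots for one examination time limit.

    B-2m uses all nine available datasets; B-1m duplicates B-mode; B (the
    degenerate single-phase condition) and B-AF pad with further B-mode
    copies; B-5m/B-10m drop one/two AF frames uniformly at random (seeded).
    """
    if time_limit not in _AVAILABLE:
        raise ValueError(f"unknown time_limit {time_limit!r}; expected one of {TIME_LIMITS}")
    need = _AVAILABLE[time_limit]
    missing = [p for p in need if p not in set(available)]
    if missing:
        raise ValueError(f"phases {missing} required for {time_limit} are unavailable")

    rng = np.random.default_rng(rule_seed)
    excluded: tuple[str, ...] = ()
    if time_limit == "B":
        slots = ("B",) * 9
    elif time_limit == "B-AF":
        slots = ("B", "B", "B") + _AF_IDS
    elif time_limit == "B-1m":
        slots = ("B", "B") + _AF_IDS + ("1m",)
    elif time_limit == "B-2m":
        slots = need
    else:
        n_drop = 1 if time_limit == "B-5m" else 2
        dropped = rng.choice(6, size=n_drop, replace=False)
        excluded = tuple(_AF_IDS[i] for i in sorted(dropped))
        slots = tuple(p for p in need if p not in excluded)
    return PhaseSelection(time_limit=time_limit, slots=tuple(slots),
                          excluded=excluded, rule_seed=rule_seed)


# ---------------------------------------------------------------------------
# pseudo-RGB packing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PseudoRGBStack:
    """Nine grayscale slices grouped as three 3-channel images.

    ``data`` has shape (3, H, W, 3): triplet k holds slots 3k..3k+2 in its
    channel axis, so the whole stack can be transformed as one 4-D image.
    """

    data: np.ndarray
    slots: tuple[str, ...]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


def pack_stack(selection: PhaseSelection, images: dict[str, np.ndarray]) -> PseudoRGBStack:
    """Pack one image per selection slot into a pseudo-RGB stack."""
    slices = []
    shape = None
    for slot in selection.slots:
        img = np.asarray(images[slot])
        if img.ndim != 2:
            raise ValueError(f"slot {slot}: expected a 2-D grayscale image")
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError(f"slot {slot}: shape {img.shape} != {shape}")
        slices.append(img)
    h, w = shape
    data = np.empty((3, h, w, 3), dtype=np.result_type(*[s.dtype for s in slices]))
    for j, img in enumerate(slices):
        data[j // 3, :, :, j % 3] = img
    return PseudoRGBStack(data=data, slots=selection.slots)


def unpack_stack(stack: PseudoRGBStack | np.ndarray) -> list[np.ndarray]:
    """Return the nine grayscale slices in slot order (round-trip of pack)."""
    data = stack.data if isinstance(stack, PseudoRGBStack) else np.asarray(stack)
    if data.ndim != 4 or data.shape[0] != 3 or data.shape[3] != 3:
        raise ValueError(f"expected a (3, H, W, 3) stack, got {data.shape}")
    return [data[j // 3, :, :, j % 3] for j in range(9)]


# ---------------------------------------------------------------------------
# resizing
# ---------------------------------------------------------------------------

def resize_to_input(image: np.ndarray, side: int = 244) -> np.ndarray:
    """Bilinear resize to ``side x side`` (the model input size).

    The default follows the source protocol's printed 244 rather than the
    conventional 224.  An image already at the target size is returned
    unchanged (as a copy).
    """
    if side <= 0:
        raise ValueError("side must be positive")
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("image is empty")
    if img.shape[:2] == (side, side):
        return img.astype(np.float64, copy=True)
    return _sk_resize(img.astype(np.float64), (side, side), order=1,
                      preserve_range=True, anti_aliasing=False)


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Stratified 10-fold cross-validation with an 8:2 train/val sub-split."""

    folds: int = 10
    val_fraction: float = 0.2
    seed: int = 0


def split_dataset(manifest: pd.DataFrame, spec: SplitSpec = SplitSpec()) -> pd.DataFrame:
    """Assign every case a role per fold: stratified, case-level, seeded.

    ``manifest`` needs ``case_id`` and ``label`` columns.  Returns a long
    frame with columns ``case_id, fold, role`` where role is train/val/test;
    across folds the test sets partition the cohort.
    """
    case_ids = manifest["case_id"].to_numpy()
    labels = manifest["label"].to_numpy()
    counts = pd.Series(labels).value_counts()
    too_small = counts[counts < spec.folds]
    if not too_small.empty:
        name = too_small.index[0]
        raise ValueError(
            f"class {name!r} has {too_small.iloc[0]} cases, fewer than {spec.folds} folds")

    skf = StratifiedKFold(n_splits=spec.folds, shuffle=True, random_state=spec.seed)
    rows = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(case_ids, labels)):
        fold_seed = int(np.random.SeedSequence([spec.seed, fold]).generate_state(1)[0] % 2**31)
        # stratify the 8:2 sub-split when the validation part can hold at
        # least one case of every class; otherwise split plainly
        n_val = int(np.ceil(spec.val_fraction * len(train_idx)))
        stratify = labels[train_idx] if n_val >= len(counts) else None
        tr, val = train_test_split(train_idx, test_size=spec.val_fraction,
                                   stratify=stratify, random_state=fold_seed)
        for idx, role in ((tr, "train"), (val, "val"), (test_idx, "test")):
            for i in idx:
                rows.append((case_ids[i], fold, role))
    out = pd.DataFrame(rows, columns=["case_id", "fold", "role"])
    return out.sort_values(["fold", "role", "case_id"]).reset_index(drop=True)
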