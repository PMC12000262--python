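"""Synthetic multi-phase contrast-enhanced ultrasound (CEUS) lesion phantoms.

A Sonazoid CEUS examination of a focal liver lesion is summarized here by
eleven still frames: a pre-injection B-mode frame, six arterial-flow (AF)
frames taken 20-40 s after bolus injection, and single frames at 1, 2, 5 and
10 min (the 10-min frame being the post-vascular "Kupffer" phase).  The three
diagnostic classes differ almost entirely in their washout kinetics:

* benign nodules sustain their enhancement (no washout),
* hepatocellular carcinoma (HCC) washes out mildly, starting around 2 min,
* non-HCC malignancies (metastases, ICC) wash out markedly within 1 min.

The generator draws class-conditional kinetic parameters, evaluates a minimal
time-intensity model for lesion and liver parenchyma, and renders each phase
as a speckled, log-compressed 8-bit grayscale frame with a circular lesion on
a uniform parenchyma background.

Time-intensity model
--------------------
Parenchyma follows a saturating wash-in to a sustained plateau::

    P(t) = Pb + Ap * (1 - exp(-(t - ta) / tau_p)),   t >= ta

The lesion follows a (faster) wash-in multiplied by a washout factor that is
1 before ``washout_onset`` and afterwards decays exponentially to a floor set
by the Kupffer-phase enhancement defect::

    L(t) = Lb + A * w(t) * d(t) + artifact_gain
    w(t) = 1 - exp(-(t - ta) / tau_in)
    d(t) = 1                                          t < onset
         = f + (1 - f) * exp(-(t - onset) / tau_out)  t >= onset,  f = 1 - kupffer_defect

``artifact_gain`` models the residual tissue-harmonic brightness of nodules
that are hyperechoic before injection; it adds to the lesion at every phase,
including pre-injection, and pushes late washout scores back toward iso/hyper.

A small fraction of HCC phantoms draw metastasis-like fast-washout kinetics:
clinically these are the atypical HCCs that wash out within 1 min and would
be scored LR-M; they make the class boundaries realistically imperfect.
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd

#: Sentinel time for the pre-injection B-mode frame.
PRE_INJECTION = -1.0

#: The six AF frames are spread evenly over the 20-40 s window.
AF_WINDOW = (20.0, 40.0)

PHASE_IDS = ("B", "AF1", "AF2", "AF3", "AF4", "AF5", "AF6", "1m", "2m", "5m", "10m")
LATE_PHASE_TIMES = {"1m": 60.0, "2m": 120.0, "5m": 300.0, "10m": 600.0}

CLASS_LABELS = ("benign", "HCC", "non-HCC-malignant")
_CLASS_SHORT = {"benign": "ben", "HCC": "hcc", "non-HCC-malignant": "met"}

#: +/-20% multiplicative jitter, implemented as lognormal with sigma=ln(1.2).
LOG_JITTER_SIGMA = math.log(1.2)

MANIFEST_COLUMNS = (
    "case_id",
    "label",
    "seed",
    "lesion_diameter_px",
    "washout_onset_s",
    "washout_tau_s",
    "kupffer_defect",
    "artifact_gain",
)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseSchedule:
    """The eleven acquisition slots of one examination.

    ``af_times`` are the six AF frame times in seconds after injection; the
    late phases are fixed at their nominal 1/2/5/10-min marks and B-mode is
    the pre-injection sentinel.
    """

    af_times: tuple[float, ...] = (20.0, 24.0, 28.0, 32.0, 36.0, 40.0)

    def __post_init__(self) -> None:
        if len(self.af_times) != 6:
            raise ValueError("a schedule has exactly six AF frames")
        lo, hi = AF_WINDOW
        if not all(lo <= t <= hi for t in self.af_times):
            raise ValueError(f"AF times must lie within {AF_WINDOW}")
        times = list(self.af_times) + sorted(LATE_PHASE_TIMES.values())
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("phase times must be strictly increasing after B-mode")

    def times(self) -> dict[str, float]:
        """Map each phase id to its time (B-mode maps to the sentinel)."""
        out = {"B": PRE_INJECTION}
        for i, t in enumerate(self.af_times, start=1):
            out[f"AF{i}"] = t
        out.update(LATE_PHASE_TIMES)
        return out


@dataclass(frozen=True)
class KineticParams:
    """Kinetic parameters of one lesion, in linear (pre-log) intensity units."""

    baseline_lesion: float = 24.0
    baseline_parenchyma: float = 30.0
    arrival_time: float = 15.0
    wash_in_tau: float = 5.0
    peak_amplitude: float = 116.0
    parenchyma_amplitude: float = 110.0
    parenchyma_tau: float = 15.0
    washout_onset: float = math.inf
    washout_tau: float = 300.0
    kupffer_defect: float = 0.0
    artifact_gain: float = 0.0

    def __post_init__(self) -> None:
        if self.wash_in_tau <= 0 or self.parenchyma_tau <= 0 or self.washout_tau <= 0:
            raise ValueError("all time constants must be positive")
        if self.washout_onset < self.arrival_time:
            raise ValueError("washout cannot begin before contrast arrival")
        if not 0.0 <= self.kupffer_defect <= 1.0:
            raise ValueError("kupffer_defect must lie in [0, 1]")
        if self.artifact_gain < 0:
            raise ValueError("artifact_gain must be >= 0")
        if self.baseline_lesion < 0 or self.baseline_parenchyma < 0:
            raise ValueError("baselines must be >= 0")


@dataclass(frozen=True)
class PhantomGeometry:
    image_side: int = 128
    lesion_center: tuple[float, float] = (64.0, 64.0)
    lesion_diameter: float = 32.0
    roi_margin_factor: float = 1.5

    def __post_init__(self) -> None:
        if self.lesion_diameter <= 0:
            raise ValueError("lesion_diameter must be positive")
        if self.roi_margin_factor <= 1:
            raise ValueError("roi_margin_factor must exceed 1")
        r = self.lesion_diameter / 2.0
        for c in self.lesion_center:
            if c - r < 0 or c + r > self.image_side:
                raise ValueError("lesion must fit inside the image")


@dataclass(frozen=True)
class NoiseParams:
    """Speckle and display-mapping parameters.

    ``speckle_scale`` interpolates between a noise-free render (0) and fully
    developed speckle (1, unit-mean Rayleigh amplitude).  The display maps
    ``log_dynamic_range`` dB below ``full_scale`` onto the quantized range.
    """

    speckle_scale: float = 1.0
    log_dynamic_range: float = 63.0
    bit_depth: int = 8
    full_scale: float = 200.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.speckle_scale < 0:
            raise ValueError("speckle_scale must be >= 0")
        if self.log_dynamic_range <= 0:
            raise ValueError("log_dynamic_range must be positive")
        if self.bit_depth < 1:
            raise ValueError("bit_depth must be >= 1")


# ---------------------------------------------------------------------------
# time-intensity model
# ---------------------------------------------------------------------------

def time_intensity(params: KineticParams, t: float) -> tuple[float, float]:
    """Lesion and parenchyma linear intensity at time ``t`` seconds.

    ``t`` may be :data:`PRE_INJECTION` for the B-mode frame; any other
    negative time is rejected.  Returns ``(lesion, parenchyma)``.
    """
    p = params
    if t == PRE_INJECTION:
        return p.baseline_lesion + p.artifact_gain, p.baseline_parenchyma
    if t < 0:
        raise ValueError(f"time must be >= 0 or the pre-injection sentinel, got {t}")

    dt = t - p.arrival_time
    if dt <= 0:
        return p.baseline_lesion + p.artifact_gain, p.baseline_parenchyma

    wash_in = 1.0 - math.exp(-dt / p.wash_in_tau)
    paren_in = 1.0 - math.exp(-dt / p.parenchyma_tau)

    if math.isinf(p.washout_onset) or t < p.washout_onset:
        decay = 1.0
    else:
        floor = 1.0 - p.kupffer_defect
        decay = floor + (1.0 - floor) * math.exp(-(t - p.washout_onset) / p.washout_tau)

    lesion = p.baseline_lesion + p.peak_amplitude * wash_in * decay + p.artifact_gain
    paren = p.baseline_parenchyma + p.parenchyma_amplitude * paren_in
    return lesion, paren


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def disk_mask(side: int, center: tuple[float, float], diameter: float,
              scale: float = 1.0) -> np.ndarray:
    """Boolean mask of the lesion disk, optionally shrunk/grown by ``scale``."""
    rr, cc = np.ogrid[:side, :side]
    radius = scale * diameter / 2.0
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def log_compress(amplitude: np.ndarray, noise: NoiseParams) -> np.ndarray:
    """Map linear amplitudes onto the quantized log-compressed display range."""
    levels = 2**noise.bit_depth - 1
    a = np.maximum(np.asarray(amplitude, dtype=np.float64), 1e-12)
    db = 20.0 * np.log10(a / noise.full_scale)
    frac = np.clip(1.0 + db / noise.log_dynamic_range, 0.0, 1.0)
    return np.rint(frac * levels).astype(np.uint8 if noise.bit_depth <= 8 else np.uint16)


def pixel_to_linear(pixels: np.ndarray, noise: NoiseParams) -> np.ndarray:
    """Invert :func:`log_compress` (up to quantization and clipping)."""
    levels = 2**noise.bit_depth - 1
    frac = np.asarray(pixels, dtype=np.float64) / levels
    return noise.full_scale * 10.0 ** ((frac - 1.0) * noise.log_dynamic_range / 20.0)


def render_phase(geometry: PhantomGeometry, noise: NoiseParams,
                 lesion_i: float, paren_i: float,
                 rng: np.random.Generator | int) -> np.ndarray:
    """Render one phase as a quantized grayscale frame.

    A lesion disk of ``geometry.lesion_diameter`` sits on a uniform parenchyma
    background; unit-mean Rayleigh speckle multiplies the linear field before
    log compression.  Deterministic for a given rng state.
    """
    if lesion_i < 0 or paren_i < 0:
        raise ValueError("intensities must be >= 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    side = geometry.image_side
    fld = np.full((side, side), float(paren_i))
    fld[disk_mask(side, geometry.lesion_center, geometry.lesion_diameter)] = float(lesion_i)
    if noise.speckle_scale > 0:
        # unit-mean Rayleigh amplitude: scale sqrt(2/pi) gives E[R] = 1
        r = rng.rayleigh(scale=math.sqrt(2.0 / math.pi), size=fld.shape)
        s = np.maximum(1.0 + noise.speckle_scale * (r - 1.0), 0.0)
        fld = fld * s
    return log_compress(fld, noise)


# ---------------------------------------------------------------------------
# class-conditional priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WashoutPrior:
    washout_onset: float
    washout_tau: float
    kupffer_defect: float


@dataclass(frozen=True)
class ClassPrior:
    """Prior over washout kinetics for one diagnostic class.

    ``atypical`` (drawn with probability ``atypical_fraction``) models cases
    whose kinetics mimic another class, e.g. the ~14% of HCCs that wash out
    within 1 min and would be scored LR-M.
    """

    typical: WashoutPrior
    atypical: WashoutPrior | None = None
    atypical_fraction: float = 0.0
    jitter_sigma: float = LOG_JITTER_SIGMA


DEFAULT_PRIORS: dict[str, ClassPrior] = {
    "benign": ClassPrior(WashoutPrior(math.inf, 300.0, 0.0)),
    "HCC": ClassPrior(
        WashoutPrior(120.0, 300.0, 0.6),
        atypical=WashoutPrior(40.0, 60.0, 0.8),
        atypical_fraction=0.15,
    ),
    "non-HCC-malignant": ClassPrior(WashoutPrior(40.0, 60.0, 0.9)),
}


@dataclass(frozen=True)
class CaseRecord:
    """One synthetic lesion case: its truth and its eleven rendered frames."""

    case_id: str
    label: str
    params: KineticParams
    geometry: PhantomGeometry
    noise: NoiseParams
    schedule: PhaseSchedule
    images: dict[str, np.ndarray] = field(repr=False)
    rng_seed: int = 0


def _jitter(rng: np.random.Generator, value: float, sigma: float) -> float:
    return value * math.exp(rng.normal(0.0, sigma))


def sample_kinetics(prior: ClassPrior, rng: np.random.Generator,
                    artifact_gain: float = 0.0) -> KineticParams:
    """Draw one lesion's kinetic parameters from a class prior."""
    wp = prior.typical
    if prior.atypical is not None and rng.random() < prior.atypical_fraction:
        wp = prior.atypical
    sig = prior.jitter_sigma
    base = KineticParams()

    # one global gain factor keeps lesion and parenchyma enhancement
    # correlated (dose/system gain); the lesion gets a small extra factor,
    # kept at 2% so a benign lesion stays safely iso at late phases
    gain = math.exp(rng.normal(0.0, sig))
    lesion_extra = math.exp(rng.normal(0.0, math.log(1.02)))
    wash_in_tau = _jitter(rng, base.wash_in_tau, sig)

    onset = wp.washout_onset
    if math.isfinite(onset):
        onset = max(base.arrival_time, _jitter(rng, onset, sig))
    defect = min(1.0, max(0.0, _jitter(rng, wp.kupffer_defect, sig))) if wp.kupffer_defect else 0.0

    return KineticParams(
        wash_in_tau=wash_in_tau,
        parenchyma_tau=3.0 * wash_in_tau,
        peak_amplitude=base.peak_amplitude * gain * lesion_extra,
        parenchyma_amplitude=base.parenchyma_amplitude * gain,
        washout_onset=onset,
        washout_tau=_jitter(rng, wp.washout_tau, sig),
        kupffer_defect=defect,
        artifact_gain=artifact_gain,
    )


def sample_case(class_label: str,
                class_prior_params: dict[str, ClassPrior] | None = None,
                rng_seed: int = 0,
                *,
                image_side: int = 128,
                speckle_scale: float = 1.0,
                artifact_gain: float = 0.0,
                case_id: str | None = None) -> CaseRecord:
    """Draw one labelled case and render all eleven phase frames.

    Deterministic for a fixed ``rng_seed``; the returned record keeps the true
    kinetic parameters so downstream scores can be checked against the
    generating truth.
    """
    if class_label not in CLASS_LABELS:
        raise ValueError(f"unknown class label {class_label!r}; expected one of {CLASS_LABELS}")
    priors = class_prior_params if class_prior_params is not None else DEFAULT_PRIORS
    rng = np.random.default_rng(rng_seed)

    params = sample_kinetics(priors[class_label], rng, artifact_gain)

    side = image_side
    diameter = float(np.round(rng.uniform(0.19, 0.38) * side))
    r = diameter / 2.0
    jit = 0.05 * side
    center = tuple(
        float(np.clip(side / 2.0 + rng.uniform(-jit, jit), r + 1, side - r - 1))
        for _ in range(2)
    )
    geometry = PhantomGeometry(image_side=side, lesion_center=center,
                               lesion_diameter=diameter)
    noise = NoiseParams(speckle_scale=speckle_scale, rng_seed=rng_seed)
    schedule = PhaseSchedule()

    images = {}
    for phase, t in schedule.times().items():
        lesion_i, paren_i = time_intensity(params, t)
        images[phase] = render_phase(geometry, noise, lesion_i, paren_i, rng)

    cid = case_id if case_id is not None else f"{_CLASS_SHORT[class_label]}{rng_seed % 10**6:06d}"
    return CaseRecord(case_id=cid, label=class_label, params=params,
                      geometry=geometry, noise=noise, schedule=schedule,
                      images=images, rng_seed=rng_seed)


def sample_cohort(n_per_class: int, seed: int,
                  class_prior_params: dict[str, ClassPrior] | None = None,
                  *,
                  image_side: int = 128,
                  speckle_scale: float = 1.0,
                  artifact_rate: float = 0.0,
                  artifact_gain_mean: float = 60.0) -> list[CaseRecord]:
    """Draw a balanced labelled cohort (``n_per_class`` cases per class)."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    master = np.random.default_rng(seed)
    cases = []
    for label in CLASS_LABELS:
        for i in range(n_per_class):
            case_seed = int(master.integers(2**31))
            gain = 0.0
            if artifact_rate > 0 and master.random() < artifact_rate:
                gain = _jitter(master, artifact_gain_mean, LOG_JITTER_SIGMA)
            cases.append(sample_case(
                label, class_prior_params, case_seed,
                image_side=image_side, speckle_scale=speckle_scale,
                artifact_gain=gain,
                case_id=f"{_CLASS_SHORT[label]}{i:04d}",
            ))
    return cases


# ---------------------------------------------------------------------------
# on-disk cohorts
# ---------------------------------------------------------------------------

def _fmt(value: float) -> str:
    if math.isinf(value):
        return "inf"
    return f"{value:.6g}"


def write_cohort(cases: list[CaseRecord], out_dir: str | os.PathLike) -> pd.DataFrame:
    """Write rendered cases to ``out_dir``: 11 PNGs per case plus
    ``manifest.csv`` (naming ``<case_id>_<phase>.png``)."""
    out = str(out_dir)
    try:
        os.makedirs(out, exist_ok=True)
        probe = os.path.join(out, ".write_probe")
        with open(probe, "w"):
            pass
        os.remove(probe)
    except OSError as exc:
        raise OSError(f"output directory {out!r} is not writable: {exc}") from exc

    rows = []
    for case in cases:
        for phase in PHASE_IDS:
            iio.imwrite(os.path.join(out, f"{case.case_id}_{phase}.png"),
                        case.images[phase])
        rows.append({
            "case_id": case.case_id,
            "label": case.label,
            "seed": case.rng_seed,
            "lesion_diameter_px": _fmt(case.geometry.lesion_diameter),
            "washout_onset_s": _fmt(case.params.washout_onset),
            "washout_tau_s": _fmt(case.params.washout_tau),
            "kupffer_defect": _fmt(case.params.kupffer_defect),
            "artifact_gain": _fmt(case.params.artifact_gain),
        })

    manifest_path = os.path.join(out, "manifest.csv")
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(MANIFEST_COLUMNS))
        writer.writeheader()
        writer.writerows(rows)
    return pd.read_csv(manifest_path)


def generate_cohort(n_per_class: int, seed: int, out_dir: str | os.PathLike,
                    **cohort_kwargs) -> pd.DataFrame:
    """Sample a cohort and write it to disk (see :func:`write_cohort`).

    Re-running with the same seed produces byte-identical manifests and
    images.
    """
    return write_cohort(sample_cohort(n_per_class, seed, **cohort_kwargs), out_dir)


def load_cohort_images(manifest_path: str | os.PathLike) -> list[dict]:
    """Load a written cohort back as dicts of phase images plus metadata.

    The manifest does not record the lesion center; written phantoms keep the
    lesion near the frame center, so downstream ROI extraction uses the image
    center together with the manifest diameter.
    """
    manifest = pd.read_csv(manifest_path)
    base = os.path.dirname(str(manifest_path))
    out = []
    for _, row in manifest.iterrows():
        images = {
            phase: iio.imread(os.path.join(base, f"{row.case_id}_{phase}.png"))
            for phase in PHASE_IDS
        }
        out.append({
            "case_id": row.case_id,
            "label": row.label,
            "lesion_diameter": float(row.lesion_diameter_px),
            "images": images,
        })
    return out
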