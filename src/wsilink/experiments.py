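"""Experiment designs over a spatiotemporal slide hierarchy.

The designs mirror how serial sections and rescans of formalin-fixed
paraffin-embedded (FFPE) blocks are released in practice:

* ``E1``   — rescan pairs: each patient has the same slide digitised twice
  (different scanners); one scan goes to background knowledge B, the other
  to the probe set P, by a fair coin.
* ``E2a``  — directly consecutive section pairs, split the same way.
* ``E2b``  — distance thresholding: one random *pivot* slide per patient
  enters B; every slide of that patient strictly farther than ``l`` mm from
  the pivot becomes a probe (possibly none).
* ``cE2a`` / ``cE2b`` — cropped variants: both slides are reduced to an
  interior tissue window; in ``cE2a`` the probe window is additionally
  displaced by a fixed shift in a random direction per pair.
* ``sweep_patients`` / ``sweep_probes`` — cohort-size and probes-per-patient
  sweeps.

Each run re-randomises the split per repeat from per-repeat child seeds, so
a master seed reproduces the full result set bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .attack import BackgroundItem, RsResult, evaluate_attack, validate_ground_truth
from .features import DEFAULT_EXTRACTOR, ImageThumb

__all__ = [
    "SlideRecord",
    "Manifest",
    "SetSplit",
    "ExperimentConfig",
    "DESIGNS",
    "split_pairs",
    "build_distance_threshold_sets",
    "sweep_patients",
    "sweep_probes",
    "overlap_fraction",
    "crop_with_shift",
    "tissue_centroid",
    "run_experiment",
]

HIERARCHY_CLASSES = ("H1", "H2_consecutive", "H2_distant", "H3", "H4", "H5")

DESIGNS = ("E1", "E2a", "E2b", "cE2a", "cE2b", "sweep_patients", "sweep_probes")


@dataclass(frozen=True)
class SlideRecord:
    """One slide of one patient.

    ``section_position_mm`` is the cumulative depth of the cut within the
    tissue block (rescans of the same slide share a position).
    """

    patient_id: str
    slide_id: str
    section_position_mm: float
    acquisition_tag: str = "scanner-0"
    hierarchy_class: str = "H2_consecutive"
    image_path: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.patient_id or not self.slide_id:
            raise ValueError("patient_id and slide_id must be non-empty")
        if self.section_position_mm < 0:
            raise ValueError(f"negative section position for slide {self.slide_id!r}")
        if self.hierarchy_class not in HIERARCHY_CLASSES:
            raise ValueError(
                f"unknown hierarchy class {self.hierarchy_class!r} for slide {self.slide_id!r}"
            )


@dataclass
class Manifest:
    """An ordered cohort of slide records; file order drives tie-breaking."""

    records: List[SlideRecord]
    cohort: str = "cohort"

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("manifest has no records")
        seen = set()
        for rec in self.records:
            if rec.slide_id in seen:
                raise ValueError(f"duplicate slide_id {rec.slide_id!r}")
            seen.add(rec.slide_id)

    @property
    def patients(self) -> List[str]:
        """Patient ids in first-appearance order."""
        out: List[str] = []
        seen = set()
        for rec in self.records:
            if rec.patient_id not in seen:
                seen.add(rec.patient_id)
                out.append(rec.patient_id)
        return out

    def slides_of(self, patient_id: str) -> List[SlideRecord]:
        return [r for r in self.records if r.patient_id == patient_id]

    def mean_slides_per_patient(self) -> float:
        return len(self.records) / len(self.patients)


@dataclass
class SetSplit:
    """One realised background/probe split with its ground truth."""

    background: Tuple[BackgroundItem, ...]
    truth: Dict[str, frozenset]
    probe_ids: Tuple[str, ...]
    repeat_index: int = 0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        bg_ids = {item.item_id for item in self.background}
        patients = [item.patient_id for item in self.background]
        if len(set(patients)) != len(patients):
            raise ValueError("background must hold exactly one slide per patient")
        overlap = bg_ids & set(self.probe_ids)
        if overlap:
            raise ValueError(f"slides in both background and probes: {sorted(overlap)}")
        validate_ground_truth(self.truth)
        claimed = set().union(*self.truth.values()) if self.truth else set()
        if claimed != set(self.probe_ids):
            raise ValueError("ground truth does not partition the probe set")


@dataclass(frozen=True)
class ExperimentConfig:
    design: str
    repeats: int = 40
    seed: int = 0
    distance_threshold_mm: Optional[float] = None  # E2b / cE2b
    n_patients: Optional[int] = None  # sweep_patients
    probes_per_patient: Optional[int] = None  # sweep_probes
    crop_side: int = 224
    shift_px: float = 0.0
    extractor: str = DEFAULT_EXTRACTOR
    measure: str = "cosine"
    exclude_probeless: bool = False

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}; use one of {DESIGNS}")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.design in ("E2b", "cE2b") and self.distance_threshold_mm is None:
            raise ValueError(f"design {self.design} requires distance_threshold_mm")
        if self.design == "sweep_patients" and self.n_patients is None:
            raise ValueError("sweep_patients requires n_patients")
        if self.design == "sweep_probes" and self.probes_per_patient is None:
            raise ValueError("sweep_probes requires probes_per_patient")
        if self.design == "cE2b" and self.shift_px != 0.0:
            raise ValueError("crop shifts are not supported for non-consecutive designs")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Split construction
# ---------------------------------------------------------------------------

def split_pairs(manifest: Manifest, seed) -> SetSplit:
    """Fair-coin split of two-slide patients into background and probe sets."""
    rng = _rng(seed)
    background: List[BackgroundItem] = []
    truth: Dict[str, frozenset] = {}
    probes: List[str] = []
    for patient in manifest.patients:
        slides = manifest.slides_of(patient)
        if len(slides) != 2:
            raise ValueError(
                f"pair split needs exactly 2 slides per patient; {patient!r} has {len(slides)}"
            )
        flip = int(rng.integers(2))
        bg, probe = (slides[flip], slides[1 - flip])
        background.append(BackgroundItem(patient, bg.slide_id))
        truth[patient] = frozenset({probe.slide_id})
        probes.append(probe.slide_id)
    return SetSplit(tuple(background), truth, tuple(probes))


def build_distance_threshold_sets(manifest: Manifest, l: float, seed) -> SetSplit:
    """Pivot-based split: probes are the slides strictly farther than ``l`` mm
    from the per-patient random pivot; empty probe sets are retained."""
    if l < 0:
        raise ValueError("distance threshold l must be >= 0")
    rng = _rng(seed)
    background: List[BackgroundItem] = []
    truth: Dict[str, frozenset] = {}
    probes: List[str] = []
    for patient in manifest.patients:
        slides = manifest.slides_of(patient)
        pivot = slides[int(rng.integers(len(slides)))]
        background.append(BackgroundItem(patient, pivot.slide_id))
        far = [
            s.slide_id
            for s in slides
            if s.slide_id != pivot.slide_id
            and abs(s.section_position_mm - pivot.section_position_mm) > l
        ]
        truth[patient] = frozenset(far)
        probes.extend(far)
    return SetSplit(tuple(background), truth, tuple(probes))


def sweep_patients(manifest: Manifest, n: int, seed) -> SetSplit:
    """Random ``n``-patient sub-cohort; one random slide per patient goes to
    background, all their remaining slides become probes."""
    all_patients = manifest.patients
    if not (1 <= n <= len(all_patients)):
        raise ValueError(f"n_patients must be in [1, {len(all_patients)}], got {n}")
    rng = _rng(seed)
    chosen_idx = sorted(rng.choice(len(all_patients), size=n, replace=False))
    background: List[BackgroundItem] = []
    truth: Dict[str, frozenset] = {}
    probes: List[str] = []
    for i in chosen_idx:
        patient = all_patients[i]
        slides = manifest.slides_of(patient)
        keep = int(rng.integers(len(slides)))
        background.append(BackgroundItem(patient, slides[keep].slide_id))
        rest = [s.slide_id for j, s in enumerate(slides) if j != keep]
        truth[patient] = frozenset(rest)
        probes.extend(rest)
    return SetSplit(tuple(background), truth, tuple(probes))


def sweep_probes(manifest: Manifest, p: int, seed) -> SetSplit:
    """Fixed probes-per-patient split over patients with at least p+1 slides:
    sample p+1 slides, send one to background and p to the probe set."""
    if p < 1:
        raise ValueError("probes_per_patient must be >= 1")
    rng = _rng(seed)
    background: List[BackgroundItem] = []
    truth: Dict[str, frozenset] = {}
    probes: List[str] = []
    for patient in manifest.patients:
        slides = manifest.slides_of(patient)
        if len(slides) < p + 1:
            continue
        subset = rng.choice(len(slides), size=p + 1, replace=False)
        keep = subset[0]
        background.append(BackgroundItem(patient, slides[keep].slide_id))
        rest = [slides[j].slide_id for j in subset[1:]]
        truth[patient] = frozenset(rest)
        probes.extend(rest)
    if not background:
        raise ValueError(f"no patient has the {p + 1} slides needed for p={p}")
    return SetSplit(tuple(background), truth, tuple(probes))


# ---------------------------------------------------------------------------
# Crop-overlap geometry
# ---------------------------------------------------------------------------

def overlap_fraction(shift_px: float, direction_deg: float, window_px: int) -> float:
    """Shared-area fraction of two square windows displaced by a fixed vector.

    With displacement (dx, dy) = shift * (cos t, sin t) and window side W the
    intersection is (W - |dx|)(W - |dy|), i.e. a fraction
    (1 - |dx|/W)(1 - |dy|/W), clipped at 0 for disjoint windows.  Maximal for
    axis-aligned directions, minimal at 45 degrees.
    """
    if shift_px < 0:
        raise ValueError("shift_px must be >= 0")
    if window_px <= 0:
        raise ValueError("window_px must be positive")
    t = math.radians(direction_deg)
    dx = abs(shift_px * math.cos(t))
    dy = abs(shift_px * math.sin(t))
    return max(0.0, 1.0 - dx / window_px) * max(0.0, 1.0 - dy / window_px)


def tissue_centroid(image: ImageThumb) -> Tuple[float, float]:
    """Intensity-weighted centroid (row, col) of tissue, assuming stained
    tissue is darker than the background glass."""
    gray = image.pixels @ np.array([0.299, 0.587, 0.114])
    weight = 1.0 - gray
    total = float(weight.sum())
    if total <= 0:
        h, w = gray.shape
        return (h / 2.0, w / 2.0)
    rows = np.arange(gray.shape[0], dtype=float)
    cols = np.arange(gray.shape[1], dtype=float)
    return (
        float((weight.sum(axis=1) * rows).sum() / total),
        float((weight.sum(axis=0) * cols).sum() / total),
    )


def crop_with_shift(
    image_bg: ImageThumb,
    image_probe: ImageThumb,
    crop_side: int,
    shift_px: float,
    seed,
) -> Tuple[ImageThumb, ImageThumb, float]:
    """Cut interior windows from a registered slide pair.

    The background window is centred on the tissue centroid (clamped so that
    both windows fit); the probe window is displaced by ``shift_px`` in one
    uniformly random direction drawn per pair.  Returns both crops and the
    analytic overlap fraction of the two windows.
    """
    if crop_side < 8:
        raise ValueError("crop_side must be >= 8")
    if shift_px < 0:
        raise ValueError("shift_px must be >= 0")
    rng = _rng(seed)
    theta = float(rng.uniform(0.0, 360.0))
    dx = shift_px * math.cos(math.radians(theta))
    dy = shift_px * math.sin(math.radians(theta))

    h, w = image_bg.height, image_bg.width
    if crop_side > h or crop_side > w:
        raise ValueError(f"crop side {crop_side} exceeds image size {h}x{w}")
    cy, cx = tissue_centroid(image_bg)
    top = int(round(cy - crop_side / 2.0))
    left = int(round(cx - crop_side / 2.0))
    # Clamp so both the background window and the shifted probe window fit.
    top = min(max(top, max(0, -int(round(dy)))), min(h - crop_side, h - crop_side - int(round(dy))))
    left = min(max(left, max(0, -int(round(dx)))), min(w - crop_side, w - crop_side - int(round(dx))))
    p_top = top + int(round(dy))
    p_left = left + int(round(dx))
    if top < 0 or left < 0 or p_top < 0 or p_left < 0 or (
        p_top + crop_side > image_probe.height or p_left + crop_side > image_probe.width
    ):
        raise ValueError(
            f"shift {shift_px} px pushes the {crop_side} px crop outside the {h}x{w} frame"
        )

    crop_bg = ImageThumb(
        image_bg.pixels[top : top + crop_side, left : left + crop_side, :],
        slide_id=image_bg.slide_id,
        provenance="cropped",
    )
    crop_probe = ImageThumb(
        image_probe.pixels[p_top : p_top + crop_side, p_left : p_left + crop_side, :],
        slide_id=image_probe.slide_id,
        provenance="cropped",
    )
    return crop_bg, crop_probe, overlap_fraction(shift_px, theta, crop_side)


# ---------------------------------------------------------------------------
# Experiment runner
# ---------------------------------------------------------------------------

def _build_split(config: ExperimentConfig, manifest: Manifest, rng) -> SetSplit:
    if config.design in ("E1", "E2a", "cE2a"):
        return split_pairs(manifest, rng)
    if config.design in ("E2b", "cE2b"):
        return build_distance_threshold_sets(manifest, config.distance_threshold_mm, rng)
    if config.design == "sweep_patients":
        return sweep_patients(manifest, config.n_patients, rng)
    return sweep_probes(manifest, config.probes_per_patient, rng)


def _validate_compat(config: ExperimentConfig, manifest: Manifest) -> None:
    """Fail before any repeat runs if the manifest cannot serve the design."""
    if config.design in ("E1", "E2a", "cE2a"):
        for patient in manifest.patients:
            n = len(manifest.slides_of(patient))
            if n != 2:
                raise ValueError(
                    f"design {config.design} needs slide pairs; patient {patient!r} has {n}"
                )
    if config.design == "sweep_patients" and not (
        1 <= config.n_patients <= len(manifest.patients)
    ):
        raise ValueError(
            f"n_patients={config.n_patients} out of range for a "
            f"{len(manifest.patients)}-patient cohort"
        )
    if config.design == "sweep_probes":
        p = config.probes_per_patient
        if not any(len(manifest.slides_of(h)) >= p + 1 for h in manifest.patients):
            raise ValueError(f"no patient has >= {p + 1} slides for p={p}")


def _cropped_images(
    split: SetSplit, images, config: ExperimentConfig, rng
) -> Dict[str, ImageThumb]:
    """Crop every background/probe pair (one random shift direction per pair)."""
    get = images if callable(images) else images.__getitem__
    out: Dict[str, ImageThumb] = {}
    probes_of = {item.patient_id: sorted(split.truth[item.patient_id]) for item in split.background}
    for item in split.background:
        bg_img = get(item.item_id)
        for probe_id in probes_of[item.patient_id]:
            crop_bg, crop_probe, _ = crop_with_shift(
                bg_img, get(probe_id), config.crop_side, config.shift_px, rng
            )
            out.setdefault(item.item_id, crop_bg)
            out[probe_id] = crop_probe
        if item.item_id not in out:  # probeless patient: still crop its background
            crop_bg, _, _ = crop_with_shift(bg_img, bg_img, config.crop_side, 0.0, rng)
            out[item.item_id] = crop_bg
    return out


def run_experiment(
    config: ExperimentConfig,
    manifest: Manifest,
    images,
    *,
    feature_cache: Optional[Dict] = None,
) -> List[RsResult]:
    """Run one experiment design: ``config.repeats`` re-randomised splits,
    each evaluated with the similarity attack.

    Child seeds are spawned from the master seed, so the full result list is
    reproducible bit-for-bit.  For non-crop designs a ``feature_cache`` dict
    may be supplied to memoise per-slide features across repeats (and across
    configs sharing the same manifest); crop designs re-extract per repeat
    because the windows move.
    """
    _validate_compat(config, manifest)
    cropped = config.design in ("cE2a", "cE2b")
    if cropped:
        feature_cache = None  # windows differ per repeat; caching would alias them
    results: List[RsResult] = []
    for repeat, child in enumerate(np.random.SeedSequence(config.seed).spawn(config.repeats)):
        rng = np.random.default_rng(child)
        split = _build_split(config, manifest, rng)
        split = replace(split, repeat_index=repeat, seed=config.seed)
        repeat_images = _cropped_images(split, images, config, rng) if cropped else images
        results.append(
            evaluate_attack(
                split,
                repeat_images,
                extractor=config.extractor,
                measure=config.measure,
                feature_cache=feature_cache,
                exclude_probeless=config.exclude_probeless,
            )
        )
    return results
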