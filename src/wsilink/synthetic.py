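"""Synthetic tissue-phantom cohorts with the slide hierarchy the attacks assume.

Real WSI collections are access-restricted, so the experiment harness runs on
generated pseudo-slides that reproduce the *structure* the linkage attacks
exploit, not histological detail:

* a per-patient base texture — a smoothed Gaussian random field thresholded
  into blob-like "tissue" on a light glass background, colourised in a
  hematoxylin–eosin-like palette;
* rescans (hierarchy H-1): the same geometry re-digitised with colour-channel
  gain/gamma jitter, sub-pixel resampling and sensor noise;
* serial sections (hierarchy H-2): elastic deformation plus content turnover
  (blob birth/death), both growing linearly with the cutting distance in mm,
  so image divergence increases with physical distance in the block.

Every operation is deterministic per seed; zero-amplitude parameters give the
exact identity, which the tests rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, zoom

from .experiments import Manifest, SlideRecord
from .features import ImageThumb

__all__ = [
    "TissuePhantomParams",
    "SlideFamily",
    "generate_patient_texture",
    "derive_rescan",
    "derive_section",
    "generate_slide_family",
    "generate_cohort_manifest",
]

_HEMATOXYLIN = np.array([0.42, 0.28, 0.58])
_EOSIN = np.array([0.88, 0.60, 0.70])
_GLASS = np.array([0.96, 0.95, 0.97])


@dataclass(frozen=True)
class TissuePhantomParams:
    """Knobs of the phantom generator.

    ``turnover_per_mm`` is the fraction of tissue content replaced per mm of
    cutting distance (capped at 1); ``deform_px_per_mm`` the elastic
    displacement amplitude per mm.  Defaults are calibrated to reproduce the
    qualitative orderings expected of serial sections — rescans nearly
    identical, divergence growing with distance — not any real collection.
    """

    side: int = 512
    texture_corr_px: float = 24.0
    rescan_jitter: float = 0.04
    deform_px_per_mm: float = 1.5
    turnover_per_mm: float = 0.05
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.side < 64:
            raise ValueError("side must be >= 64 (too small for grid features)")
        for name in ("texture_corr_px", "rescan_jitter", "deform_px_per_mm", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.turnover_per_mm <= 1.0):
            raise ValueError("turnover_per_mm must lie in [0, 1]")


@dataclass
class SlideFamily:
    """All slides generated for one patient, in section order."""

    patient_id: str
    images: List[ImageThumb]
    positions_mm: List[float]
    acquisition_tags: List[str]
    hierarchy_classes: List[str]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _smooth_field(rng: np.random.Generator, side: int, sigma: float) -> np.ndarray:
    """Zero-mean unit-variance Gaussian random field with correlation ~sigma px.

    Large-sigma fields are synthesised at reduced resolution and upsampled,
    which changes nothing statistically but keeps generation fast.
    """
    factor = 4 if sigma >= 8 else 1
    small = max(16, math.ceil(side / factor) + 2)
    f = gaussian_filter(rng.standard_normal((small, small)), sigma / factor, mode="reflect")
    if factor > 1:
        f = zoom(f, (side + 2 * factor) / small, order=1)[:side, :side]
    else:
        f = f[:side, :side]
    f = f - f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_patient_texture(params: TissuePhantomParams, patient_seed) -> ImageThumb:
    """Render one patient's base tissue texture, deterministic per seed.

    Each patient draws individual morphology offsets — tissue fraction, stain
    balance and staining intensity — on top of an independent random field, so
    different patients are separable in feature space the way different tissue
    blocks are, while derived rescans/sections of the same patient stay close.
    """
    rng = np.random.default_rng(patient_seed)
    side = params.side
    tissue_bias = float(rng.uniform(-0.35, 0.35))  # per-patient tissue fraction
    stain_bias = float(rng.uniform(-0.8, 0.8))  # hematoxylin/eosin balance
    density_scale = float(rng.uniform(0.82, 1.0))  # overall staining intensity
    shape_field = _smooth_field(rng, side, params.texture_corr_px)
    stain_field = _smooth_field(rng, side, params.texture_corr_px * 1.5)
    fine_field = _smooth_field(rng, side, 3.0)

    tissue = _sigmoid((shape_field + tissue_bias) / 0.35)  # soft blob mask in [0,1]
    stain = _sigmoid((stain_field + stain_bias) / 0.5)[..., None]
    colour = _HEMATOXYLIN * stain + _EOSIN * (1.0 - stain)
    # darker, finely textured interior where the field is strong
    density = (
        density_scale * (0.8 + 0.2 * _sigmoid(-shape_field)) + 0.08 * fine_field
    )[..., None]
    pixels = _GLASS + tissue[..., None] * (colour * density - _GLASS)
    return ImageThumb(np.clip(pixels, 0.0, 1.0))


def derive_rescan(base: ImageThumb, params: TissuePhantomParams, seed) -> ImageThumb:
    """Re-digitise a slide: colour gain/gamma jitter, sub-pixel resampling and
    sensor noise; the tissue geometry is unchanged."""
    rng = np.random.default_rng(seed)
    out = base.pixels.copy()
    a = params.rescan_jitter
    if a > 0:
        gamma = np.exp(rng.normal(0.0, a, size=3))
        gains = 1.0 + rng.normal(0.0, a, size=3)
        out = np.clip(out, 0.0, 1.0) ** gamma[None, None, :]
        out = out * gains[None, None, :]
        dy, dx = rng.uniform(-0.75, 0.75, size=2)
        rows = np.arange(out.shape[0], dtype=float)[:, None] + dy
        cols = np.arange(out.shape[1], dtype=float)[None, :] + dx
        grid_r = np.broadcast_to(rows, out.shape[:2])
        grid_c = np.broadcast_to(cols, out.shape[:2])
        out = np.stack(
            [
                map_coordinates(out[:, :, c], [grid_r, grid_c], order=1, mode="reflect")
                for c in range(3)
            ],
            axis=2,
        )
    if params.noise_sd > 0:
        out = out + rng.normal(0.0, params.noise_sd, size=out.shape)
    return ImageThumb(np.clip(out, 0.0, 1.0), slide_id=base.slide_id, provenance=base.provenance)


def derive_section(
    base: ImageThumb, distance_mm: float, params: TissuePhantomParams, seed
) -> ImageThumb:
    """Emulate a section cut ``distance_mm`` away in the block.

    Elastic deformation (smoothed random displacement field, amplitude
    ``deform_px_per_mm * distance``) models tissue warping between cuts;
    content turnover replaces a fraction ``min(turnover_per_mm * distance, 1)``
    of the frame with fresh texture, modelling structures appearing and
    vanishing through the block.  Distance 0 is the identity transform.
    """
    if distance_mm < 0:
        raise ValueError("distance_mm must be >= 0")
    rng = np.random.default_rng(seed)
    side = base.pixels.shape[0]
    out = base.pixels

    amp = params.deform_px_per_mm * distance_mm
    if amp > 0:
        u = _smooth_field(rng, side, params.texture_corr_px * 2) * amp
        v = _smooth_field(rng, side, params.texture_corr_px * 2) * amp
        rows = np.arange(out.shape[0], dtype=float)[:, None] + u
        cols = np.arange(out.shape[1], dtype=float)[None, :] + v
        grid_r = np.broadcast_to(rows, out.shape[:2]) if rows.shape != out.shape[:2] else rows
        grid_c = np.broadcast_to(cols, out.shape[:2]) if cols.shape != out.shape[:2] else cols
        out = np.stack(
            [
                map_coordinates(out[:, :, c], [grid_r, grid_c], order=1, mode="reflect")
                for c in range(3)
            ],
            axis=2,
        )

    turnover = min(params.turnover_per_mm * distance_mm, 1.0)
    if turnover > 0:
        fresh = generate_patient_texture(params, int(rng.integers(2**31))).pixels
        mask_field = _smooth_field(rng, side, params.texture_corr_px)
        threshold = float(np.quantile(mask_field, 1.0 - turnover))
        mask = _sigmoid((mask_field - threshold) / 0.08)[..., None]
        out = out * (1.0 - mask) + fresh * mask

    if params.noise_sd > 0:
        out = out + rng.normal(0.0, params.noise_sd, size=out.shape)
    return ImageThumb(np.clip(out, 0.0, 1.0), slide_id=base.slide_id, provenance=base.provenance)


def generate_slide_family(
    patient_id: str,
    n_sections: int,
    spacing_mm: Tuple[float, float],
    params: TissuePhantomParams,
    seed,
    *,
    rescans_per_slide: int = 0,
) -> SlideFamily:
    """Generate one patient: a base slide, serial sections at random spacings,
    and optional rescans of the base slide.

    Sections are evolved cut by cut (each derived from the previous one at the
    drawn spacing), so divergence between two sections grows with their
    separation in the block, as it does through a real FFPE block.
    """
    low, high = spacing_mm
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    if not (0 < low <= high):
        raise ValueError("spacing bounds must satisfy 0 < low <= high")
    rng = np.random.default_rng(seed)
    base = generate_patient_texture(params, int(rng.integers(2**31)))

    images = [base]
    positions = [0.0]
    tags = ["scanner-A"]
    classes = ["H1"]
    for i in range(1, n_sections):
        spacing = float(rng.uniform(low, high))
        images.append(derive_section(images[-1], spacing, params, int(rng.integers(2**31))))
        positions.append(positions[-1] + spacing)
        tags.append("scanner-A")
        classes.append("H2_consecutive" if i == 1 else "H2_distant")
    for j in range(rescans_per_slide):
        images.append(derive_rescan(base, params, int(rng.integers(2**31))))
        positions.append(0.0)  # rescans share the base slide's position
        tags.append(f"scanner-{chr(ord('B') + j)}")
        classes.append("H1")
    return SlideFamily(patient_id, images, positions, tags, classes)


def generate_cohort_manifest(
    n_patients: int,
    slides_per_patient: Union[int, Sequence[int]],
    spacing_mm: Tuple[float, float] = (3.0, 5.0),
    params: TissuePhantomParams = TissuePhantomParams(),
    seed: int = 0,
    out_dir: Optional[Union[str, Path]] = None,
    *,
    rescans_per_slide: int = 0,
    cohort: str = "synthetic",
) -> Tuple[Manifest, Dict[str, ImageThumb]]:
    """Generate a whole cohort: manifest plus in-memory images.

    ``slides_per_patient`` may be a single count or one count per patient
    (useful to shape uneven cohorts).  With ``out_dir`` set, PNG images and
    the manifest CSV are also written to disk; regeneration with the same
    seed reproduces identical files.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if isinstance(slides_per_patient, int):
        counts = [slides_per_patient] * n_patients
    else:
        counts = list(slides_per_patient)
        if len(counts) != n_patients:
            raise ValueError("slides_per_patient list must have one entry per patient")
    if any(c < 1 for c in counts):
        raise ValueError("every patient needs at least 1 slide")

    master = np.random.SeedSequence(seed)
    records: List[SlideRecord] = []
    images: Dict[str, ImageThumb] = {}
    for idx, child in enumerate(master.spawn(n_patients)):
        patient_id = f"P{idx:03d}"
        family = generate_slide_family(
            patient_id, counts[idx], spacing_mm, params, child,
            rescans_per_slide=rescans_per_slide,
        )
        for s, (img, pos, tag, cls) in enumerate(
            zip(family.images, family.positions_mm, family.acquisition_tags, family.hierarchy_classes)
        ):
            slide_id = f"{patient_id}-S{s:02d}"
            records.append(
                SlideRecord(
                    patient_id=patient_id,
                    slide_id=slide_id,
                    section_position_mm=pos,
                    acquisition_tag=tag,
                    hierarchy_class=cls,
                    image_path=f"{slide_id}.png" if out_dir is not None else None,
                )
            )
            img.slide_id = slide_id
            images[slide_id] = img

    manifest = Manifest(records=records, cohort=cohort)
    if out_dir is not None:
        from .io import save_image, write_manifest

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec in records:
            save_image(images[rec.slide_id], out / rec.image_path)
        write_manifest(manifest, out / "manifest.csv")
    return manifest, images
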