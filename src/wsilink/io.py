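"""Manifest, image and run-configuration I/O."""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import yaml
from PIL import Image

from .experiments import ExperimentConfig, Manifest, SlideRecord
from .features import ImageThumb

__all__ = [
    "MANIFEST_COLUMNS",
    "read_manifest",
    "write_manifest",
    "load_image",
    "save_image",
    "DirectoryImages",
    "RunConfig",
    "load_run_config",
]

log = logging.getLogger("wsilink")

MANIFEST_COLUMNS = [
    "patient_id", "slide_id", "section_position_mm",
    "acquisition_tag", "hierarchy_class", "image_path",
]


def read_manifest(path: Union[str, Path], cohort: Optional[str] = None) -> Manifest:
    """Read and validate a cohort manifest CSV, preserving row order.

    Errors (missing column, duplicate slide id, negative position, malformed
    value) name the offending data row, counting from 1.
    """
    path = Path(path)
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in MANIFEST_COLUMNS if c != "image_path" and c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"{path}: missing manifest column(s): {', '.join(missing)}")
        seen = set()
        for row_no, row in enumerate(reader, start=1):
            try:
                rec = SlideRecord(
                    patient_id=row["patient_id"].strip(),
                    slide_id=row["slide_id"].strip(),
                    section_position_mm=float(row["section_position_mm"]),
                    acquisition_tag=(row.get("acquisition_tag") or "scanner-0").strip(),
                    hierarchy_class=(row.get("hierarchy_class") or "H2_consecutive").strip(),
                    image_path=(row.get("image_path") or None),
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: row {row_no}: {exc}") from None
            if rec.slide_id in seen:
                raise ValueError(f"{path}: row {row_no}: duplicate slide_id {rec.slide_id!r}")
            seen.add(rec.slide_id)
            records.append(rec)
    if not records:
        raise ValueError(f"{path}: manifest has no data rows")
    return Manifest(records=records, cohort=cohort or path.stem)


def write_manifest(manifest: Manifest, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=MANIFEST_COLUMNS)
        writer.writeheader()
        for rec in manifest.records:
            writer.writerow(
                {
                    "patient_id": rec.patient_id,
                    "slide_id": rec.slide_id,
                    "section_position_mm": f"{rec.section_position_mm:.6g}",
                    "acquisition_tag": rec.acquisition_tag,
                    "hierarchy_class": rec.hierarchy_class,
                    "image_path": rec.image_path or "",
                }
            )
    return path


def load_image(path: Union[str, Path], slide_id: str = "") -> ImageThumb:
    """Load an 8-bit RGB PNG/TIFF thumbnail as float pixels in [0, 1]."""
    with Image.open(path) as im:
        rgb = im.convert("RGB")
        pixels = np.asarray(rgb, dtype=np.float64) / 255.0
    return ImageThumb(pixels=pixels, slide_id=slide_id or Path(path).stem)


def save_image(image: ImageThumb, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.clip(np.round(image.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)
    return path


class DirectoryImages:
    """Lazy slide-id -> image lookup over a manifest's image files."""

    def __init__(self, manifest: Manifest, image_root: Union[str, Path]):
        self.root = Path(image_root)
        self._paths: Dict[str, Path] = {}
        for rec in manifest.records:
            if rec.image_path is None:
                raise ValueError(f"slide {rec.slide_id!r} has no image_path in the manifest")
            self._paths[rec.slide_id] = self.root / rec.image_path
        self._cache: Dict[str, ImageThumb] = {}

    def __getitem__(self, slide_id: str) -> ImageThumb:
        if slide_id not in self._paths:
            raise KeyError(f"no image available for slide {slide_id!r}")
        if slide_id not in self._cache:
            p = self._paths[slide_id]
            if not p.exists():
                raise FileNotFoundError(f"image file for slide {slide_id!r} not found: {p}")
            self._cache[slide_id] = load_image(p, slide_id)
        return self._cache[slide_id]


@dataclass
class RunConfig:
    """A persisted run description: experiment block plus paths."""

    experiment: ExperimentConfig
    manifest_path: str
    image_root: str = "."
    out_dir: str = "results"
    log_level: str = "INFO"


def load_run_config(path: Union[str, Path]) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    exp = ExperimentConfig(**raw["experiment"])
    paths = raw.get("paths", {})
    return RunConfig(
        experiment=exp,
        manifest_path=paths.get("manifest", "manifest.csv"),
        image_root=paths.get("image_root", "."),
        out_dir=paths.get("out_dir", "results"),
        log_level=raw.get("logging", {}).get("level", "INFO"),
    )
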