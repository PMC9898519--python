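"""Case / mass / image records and their CSV/JSON manifest round-trip.

The clinical unit is one mass per breast side; a case may contribute one mass
per side (bilateral cases contribute two).  Each mass carries 1–8 ultrasound
images.  Manifests are flat CSV files with one row per image:

    case_id, age, side, disease, max_diameter_mm, image_path [, image_id, mass_id]

A JSON equivalent (list of row objects) is accepted and produced as well.
Images may live on disk (``path``) or in memory (``pixels``) — the synthetic
cohort generator supports both so tests can run without touching the
filesystem.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .taxonomy import Taxonomy

SIDES = ("left", "right")

MANIFEST_COLUMNS = [
    "case_id",
    "age",
    "side",
    "disease",
    "max_diameter_mm",
    "image_path",
    "image_id",
    "mass_id",
]


class ManifestError(ValueError):
    """Malformed manifest content; message names the offending row."""


@dataclass
class ImageRecord:
    image_id: str
    mass_id: str
    path: str | None = None
    width: int | None = None
    height: int | None = None
    pixels: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.path is None and self.pixels is None:
            raise ManifestError(f"image {self.image_id}: neither path nor pixels")
        if self.pixels is not None and self.pixels.ndim != 2:
            raise ManifestError(f"image {self.image_id}: pixels must be 2-D grayscale")


@dataclass
class MassRecord:
    mass_id: str
    case_id: str
    side: str
    disease: str
    max_diameter: float | None = None  # mm
    images: list[ImageRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ManifestError(f"mass {self.mass_id}: side must be left/right")

    @property
    def n_images(self) -> int:
        return len(self.images)


@dataclass
class CaseRecord:
    case_id: str
    age: float | None = None
    masses: list[MassRecord] = field(default_factory=list)
    pathology_confirmed: bool = True


def validate_case(case: CaseRecord, taxonomy: Taxonomy) -> None:
    """Check label resolution and per-mass image presence; raise on failure."""
    for mass in case.masses:
        taxonomy.resolve(mass.disease)
        if not mass.images:
            raise ManifestError(f"mass {mass.mass_id}: no images")


# ---------------------------------------------------------------------------
# manifest round-trip


def cases_to_frame(cases: Sequence[CaseRecord]) -> pd.DataFrame:
    rows = []
    for case in cases:
        for mass in case.masses:
            for img in mass.images:
                rows.append(
                    {
                        "case_id": case.case_id,
                        "age": case.age,
                        "side": mass.side,
                        "disease": mass.disease,
                        "max_diameter_mm": mass.max_diameter,
                        "image_path": img.path,
                        "image_id": img.image_id,
                        "mass_id": mass.mass_id,
                    }
                )
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def frame_to_cases(df: pd.DataFrame, taxonomy: Taxonomy | None = None) -> list[CaseRecord]:
    required = {"case_id", "side", "disease", "image_path"}
    missing = required - set(df.columns)
    if missing:
        raise ManifestError(f"manifest missing columns: {sorted(missing)}")

    cases: dict[str, CaseRecord] = {}
    masses: dict[tuple[str, str, str], MassRecord] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        case_id = str(d["case_id"])
        disease = str(d["disease"])
        if taxonomy is not None and disease not in taxonomy:
            raise ManifestError(f"row {i}: unknown disease {disease!r}")
        side = str(d["side"])
        if side not in SIDES:
            raise ManifestError(f"row {i}: bad side {side!r}")
        mass_id = str(d.get("mass_id") or f"{case_id}-{side}-{disease}")
        key = (case_id, side, mass_id)
        case = cases.get(case_id)
        if case is None:
            age = d.get("age")
            case = cases[case_id] = CaseRecord(
                case_id=case_id, age=None if pd.isna(age) else float(age)
            )
        mass = masses.get(key)
        if mass is None:
            diam = d.get("max_diameter_mm")
            mass = masses[key] = MassRecord(
                mass_id=mass_id,
                case_id=case_id,
                side=side,
                disease=disease,
                max_diameter=None if diam is None or pd.isna(diam) else float(diam),
            )
            case.masses.append(mass)
        image_id = str(d.get("image_id") or f"{mass_id}-img{mass.n_images + 1}")
        img_path = d["image_path"]
        if img_path is None or (isinstance(img_path, float) and pd.isna(img_path)):
            raise ManifestError(f"row {i}: missing image_path")
        mass.images.append(ImageRecord(image_id=image_id, mass_id=mass_id, path=str(img_path)))
    return list(cases.values())


def read_manifest(path: str | Path, taxonomy: Taxonomy | None = None) -> list[CaseRecord]:
    """Load a case manifest (CSV, or JSON list of row objects)."""
    path = Path(path)
    if path.suffix == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path)
    return frame_to_cases(df, taxonomy)


def write_manifest(cases: Sequence[CaseRecord], path: str | Path) -> None:
    path = Path(path)
    df = cases_to_frame(cases)
    if path.suffix == ".json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=1))
    else:
        df.to_csv(path, index=False)


def all_masses(cases: Iterable[CaseRecord]) -> list[MassRecord]:
    return [m for c in cases for m in c.masses]


def all_images(cases: Iterable[CaseRecord]) -> list[ImageRecord]:
    return [img for m in all_masses(cases) for img in m.images]
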