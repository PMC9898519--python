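"""Ensemble diagnosis: one case-level report from the three task models.

The benign/malignant model scores every provided image of the mass; the image
with the highest malignant probability is selected, and the type and disease
models run on that single image to produce top-3 candidate lists.  The three
results are produced independently — a benign-looking case may still carry a
malignant top disease; such inconsistencies are reported verbatim with a
warning flag so a physician can adjudicate, never silently reconciled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .records import ImageRecord
from .selector import ModelTriple
from .taxonomy import MALIGNANT, Taxonomy
from .trainer import TrainConfig, preprocess


class DiagnosisError(ValueError):
    pass


def top_k(probabilities: Mapping[str, float], k: int = 3) -> list[tuple[str, float]]:
    """The k most probable classes, descending; ties break lexicographically."""
    for name, p in probabilities.items():
        if p < 0:
            raise DiagnosisError(f"negative probability for {name!r}")
    ranked = sorted(probabilities.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


@dataclass
class Diagnosis:
    case_id: str
    per_image_malignant_prob: dict[str, float]
    case_malignant_prob: float
    selected_image: str
    type_top3: list[tuple[str, float]]
    disease_top3: list[tuple[str, float]]
    inconsistent: bool = False   # benign call but malignant top disease (or vice versa)

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "per_image_malignant_prob": self.per_image_malignant_prob,
            "case_malignant_prob": self.case_malignant_prob,
            "selected_image": self.selected_image,
            "type_top3": self.type_top3,
            "disease_top3": self.disease_top3,
            "inconsistent": self.inconsistent,
        }


def _malignant_prob(triple: ModelTriple, X: np.ndarray) -> np.ndarray:
    probs = triple.bm.predict_proba(X)
    classes = list(triple.bm.classes)
    if MALIGNANT not in classes:
        raise DiagnosisError("BM model does not know the malignant class")
    return probs[:, classes.index(MALIGNANT)]


def diagnose_case(
    images: Sequence[ImageRecord],
    models: ModelTriple,
    config: TrainConfig,
    case_id: str = "",
    taxonomy: Taxonomy | None = None,
    aggregate: str = "max",
) -> Diagnosis:
    """Produce the three-part report for one mass from its images.

    The case-level malignancy score is the max over per-image malignant
    probabilities by default (``aggregate="mean"`` averages instead); the
    type/disease models only see the highest-scoring image.
    """
    if not images:
        raise DiagnosisError("no images provided")
    if aggregate not in ("max", "mean"):
        raise DiagnosisError(f"unknown aggregate {aggregate!r}")

    X = np.stack([preprocess(img, config).ravel() for img in images])
    mal = _malignant_prob(models, X)
    per_image = {img.image_id: float(p) for img, p in zip(images, mal)}
    sel_idx = int(np.argmax(mal))
    selected = images[sel_idx]
    case_prob = float(mal.max() if aggregate == "max" else mal.mean())

    x_sel = X[sel_idx : sel_idx + 1]
    pt_probs = dict(zip(models.pt.classes, models.pt.predict_proba(x_sel)[0]))
    pd_probs = dict(zip(models.pd.classes, models.pd.predict_proba(x_sel)[0]))
    type3 = [(n, float(p)) for n, p in top_k(pt_probs)]
    disease3 = [(n, float(p)) for n, p in top_k(pd_probs)]

    inconsistent = False
    if taxonomy is not None and disease3:
        top_disease_mal = taxonomy.malignancy_of(disease3[0][0]) == MALIGNANT
        case_mal = case_prob >= 0.5
        inconsistent = top_disease_mal != case_mal

    return Diagnosis(
        case_id=case_id,
        per_image_malignant_prob=per_image,
        case_malignant_prob=case_prob,
        selected_image=selected.image_id,
        type_top3=type3,
        disease_top3=disease3,
        inconsistent=inconsistent,
    )
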