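"""Staged training-set construction: per-side mass selection, benign/malignant
balancing, cross-stage accumulation, task datasets and frozen test sets.

The pipeline trains in stages on an accumulating pool of pathology-confirmed
cases.  At each stage:

1. candidate masses are reduced to one mass per (case, side) —
   malignant beats benign, highest malignancy grade among malignant,
   largest diameter among benign (:func:`select_mass_per_side`);
2. all prior stages' cases are merged with the new arrivals
   (:func:`accumulate`);
3. benign cases are down-sampled so benign roughly matches malignant in both
   case count and image count (:func:`balance_stage`) — excluded benign cases
   are recorded, not discarded silently;
4. three task datasets (BM / PT / PD) are built with a per-class inclusion
   threshold and a seeded 8:2 image-level train/validation split
   (:func:`build_task_datasets`).

Frozen binary test sets for checkpoint selection are built once from held-out
cases (:func:`build_fixed_testset`) and never enter training.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np

from .records import CaseRecord, ImageRecord, MassRecord, all_masses
from .taxonomy import BENIGN, MALIGNANT, Taxonomy

Task = Literal["BM", "PT", "PD"]
TASKS: tuple[Task, ...] = ("BM", "PT", "PD")


class DatasetError(ValueError):
    pass


@dataclass
class LabeledImage:
    """One image with the class label it carries for a given task."""

    image: ImageRecord
    label: str
    mass_id: str
    disease: str


@dataclass
class TaskDataset:
    task: Task
    classes: dict[str, list[LabeledImage]]
    train: list[LabeledImage]
    val: list[LabeledImage]
    stage: int
    seed: int

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(sorted(self.classes))

    def summary(self) -> dict:
        return {
            "task": self.task,
            "stage": self.stage,
            "classes": {c: len(v) for c, v in sorted(self.classes.items())},
            "n_train": len(self.train),
            "n_val": len(self.val),
        }


@dataclass
class StagePlan:
    stage: int
    new_cases: list[CaseRecord]
    accumulated_cases: list[CaseRecord]
    balanced_cases: list[CaseRecord]
    excluded_benign: list[CaseRecord]
    seed: int
    # bookkeeping for the balancing ambiguity: both case and image counts
    case_counts: dict[str, int] = field(default_factory=dict)
    image_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "stage": self.stage,
                "seed": self.seed,
                "new_cases": [c.case_id for c in self.new_cases],
                "accumulated_cases": [c.case_id for c in self.accumulated_cases],
                "balanced_cases": [c.case_id for c in self.balanced_cases],
                "excluded_benign": [c.case_id for c in self.excluded_benign],
                "case_counts": self.case_counts,
                "image_counts": self.image_counts,
            },
            indent=1,
        )


# ---------------------------------------------------------------------------
# per-side mass selection


def case_malignancy(case: CaseRecord, taxonomy: Taxonomy) -> str:
    """A case is malignant iff any of its (selected) masses is malignant."""
    mals = {taxonomy.malignancy_of(m.disease) for m in case.masses}
    return MALIGNANT if MALIGNANT in mals else BENIGN


def select_mass_per_side(
    candidates: Sequence[MassRecord], taxonomy: Taxonomy
) -> MassRecord:
    """Pick the single representative mass for one case-side.

    Any malignant candidate beats all benign ones.  Among malignant masses the
    highest malignancy grade wins (tie or missing grade: first by mass_id,
    with a warning).  Among benign masses the largest ``max_diameter`` wins;
    missing diameters fall back to image count, then mass_id.
    """
    if not candidates:
        raise DatasetError("no candidate masses")
    ids = {(m.case_id, m.side) for m in candidates}
    if len(ids) != 1:
        raise DatasetError(f"candidates span several case-sides: {sorted(ids)}")

    malignant = [m for m in candidates if taxonomy.malignancy_of(m.disease) == MALIGNANT]
    if malignant:
        graded = [(taxonomy.grade_of(m.disease), m) for m in malignant]
        if len(malignant) > 1 and any(g is None for g, _ in graded):
            warnings.warn(
                f"case {malignant[0].case_id} {malignant[0].side}: malignant tie "
                "without grades; resolving by mass_id",
                stacklevel=2,
            )
            return min(malignant, key=lambda m: m.mass_id)
        best_grade = max(g for g, _ in graded) if graded[0][0] is not None else None
        top = [m for g, m in graded if g == best_grade] if best_grade is not None else malignant
        if len(top) > 1:
            warnings.warn(
                f"case {top[0].case_id} {top[0].side}: equal malignancy grade; "
                "resolving by mass_id",
                stacklevel=2,
            )
        return min(top, key=lambda m: m.mass_id)

    # benign only: largest diameter, then most images, then mass_id
    def benign_key(m: MassRecord):
        diam = m.max_diameter if m.max_diameter is not None else -1.0
        return (-diam, -m.n_images, m.mass_id)

    return min(candidates, key=benign_key)


def select_cases(cases: Sequence[CaseRecord], taxonomy: Taxonomy) -> list[CaseRecord]:
    """Apply per-side selection and the pathology-confirmation filter."""
    out = []
    for case in cases:
        if not case.pathology_confirmed:
            continue
        by_side: dict[str, list[MassRecord]] = {}
        for m in case.masses:
            by_side.setdefault(m.side, []).append(m)
        selected = [
            select_mass_per_side(group, taxonomy) for _, group in sorted(by_side.items())
        ]
        out.append(
            CaseRecord(
                case_id=case.case_id,
                age=case.age,
                masses=selected,
                pathology_confirmed=True,
            )
        )
    return out


# ---------------------------------------------------------------------------
# accumulation and balancing


def accumulate(
    previous: StagePlan | None, new_cases: Sequence[CaseRecord]
) -> list[CaseRecord]:
    """Union of all prior accumulated cases with the new arrivals.

    Duplicate (case_id, side) pairs or mass ids across stages are an error —
    a case examined once must not re-enter the stream.
    """
    pool: list[CaseRecord] = list(previous.accumulated_cases) if previous else []
    seen_sides = {(m.case_id, m.side) for c in pool for m in c.masses}
    seen_masses = {m.mass_id for c in pool for m in c.masses}
    for case in new_cases:
        for m in case.masses:
            if (m.case_id, m.side) in seen_sides:
                raise DatasetError(f"duplicate case-side ({m.case_id}, {m.side})")
            if m.mass_id in seen_masses:
                raise DatasetError(f"duplicate mass_id {m.mass_id}")
            seen_sides.add((m.case_id, m.side))
            seen_masses.add(m.mass_id)
        pool.append(case)
    return pool


def _image_count(cases: Sequence[CaseRecord]) -> int:
    return sum(m.n_images for c in cases for m in c.masses)


def balance_stage(
    cases: Sequence[CaseRecord],
    taxonomy: Taxonomy,
    seed: int,
    stage: int = 0,
    new_cases: Sequence[CaseRecord] | None = None,
    case_surplus_tolerance: int = 2,
) -> StagePlan:
    """Down-sample benign cases to approximate benign/malignant parity.

    All malignant cases are kept.  Benign cases are drawn without replacement
    in a seeded random order until the benign case count reaches the malignant
    case count; after parity, up to ``case_surplus_tolerance`` extra benign
    cases are admitted while each one strictly shrinks the benign-vs-malignant
    *image* count gap.  Remaining benign cases are listed as
    ``excluded_benign`` (available again at later stages).
    """
    rng = np.random.default_rng(seed)
    malignant = [c for c in cases if case_malignancy(c, taxonomy) == MALIGNANT]
    benign = [c for c in cases if case_malignancy(c, taxonomy) == BENIGN]
    order = rng.permutation(len(benign))
    shuffled = [benign[i] for i in order]

    n_mal = len(malignant)
    mal_images = _image_count(malignant)
    chosen: list[CaseRecord] = []
    if len(shuffled) <= n_mal:
        chosen = shuffled
        rest: list[CaseRecord] = []
    else:
        chosen = shuffled[:n_mal]
        rest = shuffled[n_mal:]
        surplus = 0
        while rest and surplus < case_surplus_tolerance:
            gap = abs(_image_count(chosen) - mal_images)
            new_gap = abs(_image_count(chosen + rest[:1]) - mal_images)
            if new_gap < gap:
                chosen.append(rest.pop(0))
                surplus += 1
            else:
                break

    balanced = malignant + chosen
    return StagePlan(
        stage=stage,
        new_cases=list(new_cases if new_cases is not None else cases),
        accumulated_cases=list(cases),
        balanced_cases=balanced,
        excluded_benign=rest if len(shuffled) > n_mal else [],
        seed=seed,
        case_counts={BENIGN: len(chosen), MALIGNANT: n_mal},
        image_counts={BENIGN: _image_count(chosen), MALIGNANT: mal_images},
    )


# ---------------------------------------------------------------------------
# task datasets


def _label_fn(task: Task, taxonomy: Taxonomy) -> Callable[[MassRecord], str]:
    if task == "BM":
        return lambda m: taxonomy.malignancy_of(m.disease)
    if task == "PT":
        return lambda m: taxonomy.ptype_of(m.disease)
    return lambda m: m.disease


def _split_class(
    items: list[LabeledImage], split: float, rng: np.random.Generator
) -> tuple[list[LabeledImage], list[LabeledImage]]:
    n = len(items)
    # round half up on the validation share
    n_val = max(1, int(np.floor((1 - split) * n + 0.5)))
    order = rng.permutation(n)
    val_idx = set(order[:n_val].tolist())
    train = [it for i, it in enumerate(items) if i not in val_idx]
    val = [it for i, it in enumerate(items) if i in val_idx]
    return train, val


def build_task_datasets(
    cases: Sequence[CaseRecord],
    taxonomy: Taxonomy,
    min_images: int = 10,
    split: float = 0.8,
    seed: int = 0,
    stage: int = 0,
) -> dict[Task, TaskDataset]:
    """Build the BM / PT / PD datasets from a balanced case pool.

    PT/PD classes with fewer than ``min_images`` images are excluded from
    their task (their images still contribute to BM through their malignancy
    class).  Each class is split 8:2 into train/validation at the image level
    with ``val = max(1, round(0.2 n))``; the BM task must retain both classes
    at or above the threshold or the pool is too early to train.
    """
    if not 0 < split < 1:
        raise DatasetError("split must be in (0,1)")
    masses = all_masses(cases)
    out: dict[Task, TaskDataset] = {}
    for t_i, task in enumerate(TASKS):
        label_of = _label_fn(task, taxonomy)
        classes: dict[str, list[LabeledImage]] = {}
        for m in masses:
            lab = label_of(m)
            for img in m.images:
                classes.setdefault(lab, []).append(
                    LabeledImage(image=img, label=lab, mass_id=m.mass_id, disease=m.disease)
                )
        if task == "BM":
            for cls in (BENIGN, MALIGNANT):
                if len(classes.get(cls, [])) < min_images:
                    raise DatasetError(
                        f"BM class {cls!r} has {len(classes.get(cls, []))} images "
                        f"(< {min_images}): too early to train"
                    )
        else:
            classes = {c: v for c, v in classes.items() if len(v) >= min_images}

        rng = np.random.default_rng((seed, stage, t_i))
        train: list[LabeledImage] = []
        val: list[LabeledImage] = []
        for cls in sorted(classes):
            tr, va = _split_class(classes[cls], split, rng)
            train.extend(tr)
            val.extend(va)
        out[task] = TaskDataset(
            task=task, classes=classes, train=train, val=val, stage=stage, seed=seed
        )
    return out


# ---------------------------------------------------------------------------
# frozen selection test sets


@dataclass
class FixedTestSet:
    """Frozen binary test set used only for checkpoint selection."""

    task: Task
    positive_class: str
    items: list[LabeledImage]  # label is "positive" / "negative"
    seed: int
    testset_id: str

    @property
    def image_ids(self) -> set[str]:
        return {it.image.image_id for it in self.items}

    def manifest(self) -> str:
        return json.dumps(
            {
                "task": self.task,
                "positive_class": self.positive_class,
                "seed": self.seed,
                "testset_id": self.testset_id,
                "items": [
                    {"image_id": it.image.image_id, "label": it.label} for it in self.items
                ],
            },
            indent=1,
        )


def build_fixed_testset(
    cases: Sequence[CaseRecord],
    taxonomy: Taxonomy,
    task: Task,
    positive_class: str,
    n_pos: int,
    n_neg: int,
    seed: int,
) -> FixedTestSet:
    """Draw a seeded positive/negative image test set for one task.

    Positives are images whose task label equals ``positive_class``;
    negatives are drawn from all other images of the pool.
    """
    label_of = _label_fn(task, taxonomy)
    pos, neg = [], []
    for m in all_masses(cases):
        bucket = pos if label_of(m) == positive_class else neg
        for img in m.images:
            bucket.append(
                LabeledImage(image=img, label=label_of(m), mass_id=m.mass_id, disease=m.disease)
            )
    if len(pos) < n_pos or len(neg) < n_neg:
        raise DatasetError(
            f"insufficient images for {task} test set: "
            f"{len(pos)} positives (need {n_pos}), {len(neg)} negatives (need {n_neg})"
        )
    rng = np.random.default_rng(seed)
    chosen_pos = [pos[i] for i in rng.choice(len(pos), n_pos, replace=False)]
    chosen_neg = [neg[i] for i in rng.choice(len(neg), n_neg, replace=False)]
    items = [
        LabeledImage(it.image, "positive", it.mass_id, it.disease) for it in chosen_pos
    ] + [LabeledImage(it.image, "negative", it.mass_id, it.disease) for it in chosen_neg]
    return FixedTestSet(
        task=task,
        positive_class=positive_class,
        items=items,
        seed=seed,
        testset_id=f"{task}-{positive_class}-{n_pos}+{n_neg}-s{seed}",
    )
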