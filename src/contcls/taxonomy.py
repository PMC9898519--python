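"""Pathology label taxonomy shared by dataset construction, diagnosis and scoring.

Every mass carries a *disease* label confirmed by pathology.  Diseases are
grouped into *pathological types* (ptype), and every ptype is either benign or
malignant.  The three classification tasks the pipeline trains — benign vs
malignant (BM), pathological type (PT) and pathological disease (PD) — are all
derived from this single hierarchy, so the taxonomy is loaded once and passed
everywhere a label has to be resolved.

The taxonomy is user-configurable (YAML/JSON mapping
``disease -> {ptype, malignancy, grade?}``); a default covering common breast
mass pathologies ships with the package (:func:`default_taxonomy`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

BENIGN = "benign"
MALIGNANT = "malignant"
_MALIGNANCIES = (BENIGN, MALIGNANT)


class TaxonomyError(ValueError):
    """Raised for malformed taxonomy configs or unresolvable labels."""


@dataclass(frozen=True)
class PathLabel:
    """One disease with its pathological type and malignancy class."""

    disease: str
    ptype: str
    malignancy: str
    grade: int | None = None  # degree of malignancy; malignant diseases only

    def __post_init__(self) -> None:
        if not self.disease:
            raise TaxonomyError("disease name must be nonempty")
        if not self.ptype:
            raise TaxonomyError(f"{self.disease!r}: ptype must be nonempty")
        if self.malignancy not in _MALIGNANCIES:
            raise TaxonomyError(
                f"{self.disease!r}: malignancy must be one of {_MALIGNANCIES}, "
                f"got {self.malignancy!r}"
            )


@dataclass(frozen=True)
class Taxonomy:
    """Validated set of :class:`PathLabel`, closed under lookup.

    Any disease referenced by a manifest must resolve here; unknown names
    raise :class:`TaxonomyError` rather than silently passing through.
    """

    labels: tuple[PathLabel, ...]
    _by_disease: Mapping[str, PathLabel] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        by_disease: dict[str, PathLabel] = {}
        ptype_mal: dict[str, str] = {}
        for lab in self.labels:
            if lab.disease in by_disease:
                raise TaxonomyError(f"duplicate disease {lab.disease!r}")
            by_disease[lab.disease] = lab
            prev = ptype_mal.setdefault(lab.ptype, lab.malignancy)
            if prev != lab.malignancy:
                raise TaxonomyError(
                    f"ptype {lab.ptype!r} maps to both malignancy classes"
                )
        object.__setattr__(self, "_by_disease", by_disease)

    # -- lookup ------------------------------------------------------------

    def resolve(self, disease: str) -> PathLabel:
        try:
            return self._by_disease[disease]
        except KeyError:
            raise TaxonomyError(f"unknown disease {disease!r}") from None

    def malignancy_of(self, disease: str) -> str:
        return self.resolve(disease).malignancy

    def ptype_of(self, disease: str) -> str:
        return self.resolve(disease).ptype

    def grade_of(self, disease: str) -> int | None:
        return self.resolve(disease).grade

    # -- views -------------------------------------------------------------

    @property
    def diseases(self) -> tuple[str, ...]:
        return tuple(lab.disease for lab in self.labels)

    @property
    def ptypes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab.ptype)
        return tuple(seen)

    def diseases_of_malignancy(self, malignancy: str) -> tuple[str, ...]:
        if malignancy not in _MALIGNANCIES:
            raise TaxonomyError(f"unknown malignancy class {malignancy!r}")
        return tuple(l.disease for l in self.labels if l.malignancy == malignancy)

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, disease: object) -> bool:
        return disease in self._by_disease


def load_taxonomy(source: str | Path | Mapping) -> Taxonomy:
    """Build a :class:`Taxonomy` from a mapping or a YAML/JSON file.

    The config maps disease name to ``{ptype, malignancy, grade?}``.  Every
    malignant disease must either declare an integer ``grade`` or none of
    them may (grades are optional as a block, but mass selection needs them
    to break ties between malignant masses on one side).

    Raises
    ------
    TaxonomyError
        On duplicate diseases, a missing/invalid ``malignancy`` field, or a
        ptype straddling both malignancy classes.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        raw = yaml.safe_load(text) if not str(source).endswith(".json") else json.loads(text)
    else:
        raw = source
    if not isinstance(raw, Mapping) or not raw:
        raise TaxonomyError("taxonomy config must be a nonempty mapping")

    labels = []
    for disease, spec in raw.items():
        if not isinstance(spec, Mapping):
            raise TaxonomyError(f"{disease!r}: entry must be a mapping")
        if "malignancy" not in spec:
            raise TaxonomyError(f"{disease!r}: missing malignancy")
        if "ptype" not in spec:
            raise TaxonomyError(f"{disease!r}: missing ptype")
        grade = spec.get("grade")
        if grade is not None and not isinstance(grade, int):
            raise TaxonomyError(f"{disease!r}: grade must be an integer")
        labels.append(
            PathLabel(
                disease=str(disease),
                ptype=str(spec["ptype"]),
                malignancy=str(spec["malignancy"]),
                grade=grade,
            )
        )
    return Taxonomy(tuple(labels))


def default_taxonomy() -> Taxonomy:
    """The breast-mass taxonomy bundled with the package (24 diseases)."""
    with resources.as_file(
        resources.files("contcls.data").joinpath("default_taxonomy.yaml")
    ) as p:
        return load_taxonomy(p)


def malignancy_of(taxonomy: Taxonomy, disease: str) -> str:
    """Module-level convenience mirroring :meth:`Taxonomy.malignancy_of`."""
    return taxonomy.malignancy_of(disease)


def partition(taxonomy: Taxonomy) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """(benign diseases, malignant diseases) — disjoint, union = all."""
    return (
        taxonomy.diseases_of_malignancy(BENIGN),
        taxonomy.diseases_of_malignancy(MALIGNANT),
    )
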