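"""Synthetic cohorts: ultrasound-like lesion phantoms, case manifests and
simulated physician readers.

The image model is a deliberately minimal 4-parameter lesion phantom — an
ellipse with configurable aspect ratio, boundary irregularity (radial noise),
interior echogenicity and posterior acoustic shadow, embedded in speckle
background.  Benign-looking defaults are wide, smooth, bright and shadow-free;
malignant-looking defaults are tall, irregular, hypoechoic and shadowed, with
per-disease echogenicity offsets so the fine-grained disease task is learnable
too.  This is a test harness for the pipeline, not a claim about sonographic
physics.

Cohort shape defaults emulate a realistic breast-mass stream: benign cases
outnumber malignant (~73%), fibroadenoma / adenosis / invasive ductal
carcinoma dominate, ~12% of cases are bilateral, and each mass carries 1–8
images.

Simulated readers answer the same three questions the pipeline does, with a
single ``skill`` knob controlling how often they are right and how far down
their top-3 list the truth lands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from PIL import Image

from .evaluate import MassEval
from .records import CaseRecord, ImageRecord, MassRecord, write_manifest
from .taxonomy import BENIGN, MALIGNANT, Taxonomy, default_taxonomy


class SynthError(ValueError):
    pass


# realistic relative frequencies for the default breast-mass taxonomy
DEFAULT_PREVALENCE: dict[str, float] = {
    # benign
    "Fibroadenoma of breast": 187,
    "Breast adenopathy": 191,
    "Breast abscess": 24,
    "Breast cyst": 20,
    "Intraductal papilloma of the breast": 16,
    "Mammary plasma cell mastitis": 12,
    "Granulomatous lobular mastitis": 3,
    "Fibroepithelial tumor of the breast": 3,
    "Breast lipoma": 2,
    "Acute suppurative mastitis": 1,
    "Benign phyllodes tumor of the breast": 1,
    "Mammary hemangioma": 1,
    "Radial sclerosing lesions of the breast": 1,
    # malignant
    "Invasive ductal carcinoma of the breast": 138,
    "Ductal carcinoma in situ of the breast": 10,
    "Intraductal papillary carcinoma of the breast": 5,
    "Invasive lobular carcinoma of the breast": 4,
    "Medullary breast cancer": 3,
    "Mucinous breast cancer": 2,
    "Breast neuroendocrine carcinoma": 2,
    "Borderline phyllodes tumor of the breast": 1,
    "Intracystic papillary carcinoma": 1,
    "Malignant mesenchymal tumor of the breast": 1,
    "Adenoid cystic carcinoma of the breast": 1,
}


@dataclass(frozen=True)
class Appearance:
    aspect_ratio: float      # width / height of the lesion ellipse
    margin_noise: float      # radial boundary perturbation amplitude (0 = smooth)
    echogenicity: float      # mean interior gray level, 0-255
    shadow_strength: float   # 0 = none, 1 = full posterior shadow


def default_appearance(taxonomy: Taxonomy) -> dict[str, Appearance]:
    """Deterministic per-disease phantom parameters.

    Benign diseases: wide, smooth, bright, unshadowed; malignant: tall,
    irregular, dark, shadowed.  Echogenicity is spread across the diseases of
    each malignancy class (benign 140–230, malignant 20–110) so diseases are
    separable by interior intensity.
    """
    out: dict[str, Appearance] = {}
    for malignancy, (lo, hi) in ((BENIGN, (120.0, 200.0)), (MALIGNANT, (50.0, 130.0))):
        names = sorted(taxonomy.diseases_of_malignancy(malignancy))
        for i, name in enumerate(names):
            frac = i / max(1, len(names) - 1)
            echo = lo + frac * (hi - lo)
            if malignancy == BENIGN:
                out[name] = Appearance(
                    aspect_ratio=1.5 + 0.3 * frac,
                    margin_noise=0.10,
                    echogenicity=echo,
                    shadow_strength=0.10,
                )
            else:
                out[name] = Appearance(
                    aspect_ratio=1.0 + 0.2 * frac,
                    margin_noise=0.25,
                    echogenicity=echo,
                    shadow_strength=0.40,
                )
    return out


@dataclass
class SynthConfig:
    n_cases: int = 300
    benign_fraction: float = 0.73
    disease_prevalence: Mapping[str, float] | None = None  # default: DEFAULT_PREVALENCE
    images_per_mass: tuple[int, int] = (1, 8)
    bilateral_rate: float = 0.12
    image_size: int = 64
    class_appearance: Mapping[str, Appearance] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.benign_fraction < 1.0:
            raise SynthError("benign_fraction must be in (0,1)")
        lo, hi = self.images_per_mass
        if lo < 1 or hi < lo:
            raise SynthError("images_per_mass must be a nonempty 1-based range")


# ---------------------------------------------------------------------------
# image rendering


def render_image(params: Appearance, size: int, seed: int) -> np.ndarray:
    """Render one grayscale lesion phantom (uint8, shape (size, size)).

    One ellipse-like lesion at image center: half-axes set by ``aspect_ratio``,
    boundary perturbed radially by a smooth low-order harmonic field scaled by
    ``margin_noise``, interior at ``echogenicity`` with speckle, and a
    posterior shadow column darkened by ``shadow_strength``.  Background is
    speckle around mid-gray.  Same seed, same pixels.
    """
    if size < 16:
        raise SynthError("size must be >= 16")
    rng = np.random.default_rng(seed)

    img = rng.normal(150.0, 28.0, size=(size, size))

    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = (size - 1) / 2.0
    base = size * 0.21
    a = base * np.sqrt(params.aspect_ratio)   # horizontal half-axis
    b = base / np.sqrt(params.aspect_ratio)   # vertical half-axis

    dx, dy = (xx - cx) / a, (yy - cy) / b
    r = np.sqrt(dx**2 + dy**2)
    theta = np.arctan2(dy, dx)
    boundary = np.ones_like(theta)
    for k in (2, 3, 5):
        amp, phase = rng.normal(0.0, 1.0), rng.uniform(0, 2 * np.pi)
        boundary += params.margin_noise * amp / 2.0 * np.cos(k * theta + phase)
    inside = r <= boundary

    interior = rng.normal(params.echogenicity, 14.0, size=(size, size))
    img[inside] = interior[inside]

    # posterior shadow: darken below the lesion within its horizontal extent
    cols = np.abs(xx - cx) <= a * 0.8
    below = yy > cy + b
    shadow = cols & below & ~inside
    img[shadow] *= 1.0 - 0.75 * params.shadow_strength

    return np.clip(img, 0, 255).astype(np.uint8)


def _jitter_appearance(app: Appearance, rng: np.random.Generator) -> Appearance:
    """Per-mass biological variability around the disease's nominal phantom.

    Masses of one disease are not identical: interior echogenicity, shape and
    shadowing all vary between patients.  The jitter makes the benign and
    malignant intensity distributions overlap, so the malignancy task is
    learnable but not trivially separable.
    """
    return Appearance(
        aspect_ratio=float(app.aspect_ratio * np.exp(rng.normal(0.0, 0.15))),
        margin_noise=float(np.clip(app.margin_noise * rng.uniform(0.5, 1.5), 0.0, 1.0)),
        echogenicity=float(np.clip(app.echogenicity + rng.normal(0.0, 45.0), 5.0, 250.0)),
        shadow_strength=float(np.clip(app.shadow_strength + rng.normal(0.0, 0.15), 0.0, 1.0)),
    )


def _acquisition_jitter(pixels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-image gain/offset variation, as left by operator-dependent scanner
    settings: absolute gray level is an unreliable cue across acquisitions."""
    gain = rng.normal(1.0, 0.18)
    offset = rng.normal(0.0, 18.0)
    return np.clip(pixels.astype(np.float64) * gain + offset, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# cohort generation


def _split_prevalence(
    prevalence: Mapping[str, float], taxonomy: Taxonomy
) -> dict[str, dict[str, float]]:
    split: dict[str, dict[str, float]] = {BENIGN: {}, MALIGNANT: {}}
    for disease, w in prevalence.items():
        if w <= 0:
            raise SynthError(f"nonpositive prevalence for {disease!r}")
        split[taxonomy.malignancy_of(disease)][disease] = float(w)
    for mal, d in split.items():
        if not d:
            raise SynthError(f"no {mal} disease has positive prevalence")
    return split


def generate_cohort(
    config: SynthConfig,
    taxonomy: Taxonomy | None = None,
    out_dir: str | Path | None = None,
    id_prefix: str = "",
) -> list[CaseRecord]:
    """Generate a seeded, reproducible cohort of cases with rendered images.

    Case ids are zero-padded in generation order, which doubles as the
    chronological examination order used for staging.  With ``out_dir`` set,
    PNGs and a CSV manifest are written; otherwise images stay in memory on
    the :class:`ImageRecord` objects.
    """
    taxonomy = taxonomy or default_taxonomy()
    prevalence = config.disease_prevalence or DEFAULT_PREVALENCE
    by_class = _split_prevalence(prevalence, taxonomy)
    appearance = dict(config.class_appearance or default_appearance(taxonomy))
    for disease in set(by_class[BENIGN]) | set(by_class[MALIGNANT]):
        if disease not in appearance:
            raise SynthError(f"no appearance parameters for {disease!r}")

    rng = np.random.default_rng(config.seed)
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        (out_path / "images").mkdir(parents=True, exist_ok=True)

    cases: list[CaseRecord] = []
    for i in range(config.n_cases):
        case_id = f"{id_prefix}case{i:05d}"
        age = float(rng.integers(18, 85))
        bilateral = rng.random() < config.bilateral_rate
        sides = ["left", "right"] if bilateral else [str(rng.choice(["left", "right"]))]
        masses = []
        for side in sides:
            mal = MALIGNANT if rng.random() >= config.benign_fraction else BENIGN
            pool = by_class[mal]
            names = sorted(pool)
            weights = np.array([pool[n] for n in names])
            disease = names[rng.choice(len(names), p=weights / weights.sum())]
            mass_id = f"{case_id}-{side[0]}"
            n_img = int(rng.integers(config.images_per_mass[0], config.images_per_mass[1] + 1))
            diameter = float(np.round(rng.uniform(6, 35) if mal == BENIGN else rng.uniform(8, 45), 1))
            mass_app = _jitter_appearance(appearance[disease], rng)
            images = []
            for j in range(n_img):
                img_seed = int(rng.integers(0, 2**31 - 1))
                pixels = _acquisition_jitter(
                    render_image(mass_app, config.image_size, img_seed), rng
                )
                image_id = f"{mass_id}-img{j + 1}"
                path = None
                if out_path is not None:
                    path = str(out_path / "images" / f"{image_id}.png")
                    Image.fromarray(pixels, mode="L").save(path)
                images.append(
                    ImageRecord(
                        image_id=image_id,
                        mass_id=mass_id,
                        path=path,
                        width=config.image_size,
                        height=config.image_size,
                        pixels=pixels,
                    )
                )
            masses.append(
                MassRecord(
                    mass_id=mass_id,
                    case_id=case_id,
                    side=side,
                    disease=disease,
                    max_diameter=diameter,
                    images=images,
                )
            )
        cases.append(CaseRecord(case_id=case_id, age=age, masses=masses))

    if out_path is not None:
        write_manifest(cases, out_path / "manifest.csv")
    return cases


# ---------------------------------------------------------------------------
# simulated readers


@dataclass(frozen=True)
class ReaderProfile:
    name: str
    working_years: float
    skill: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.skill <= 1.0:
            raise SynthError("skill must be in [0,1]")


def _confusions(
    truth: str, pool: Sequence[str], same_class: Sequence[str],
    n: int, rng: np.random.Generator,
) -> list[str]:
    """Draw n distinct wrong answers, preferring the truth's malignancy class."""
    same = [c for c in same_class if c != truth]
    other = [c for c in pool if c != truth and c not in same]
    out: list[str] = []
    while len(out) < n and (same or other):
        use_same = same and (not other or rng.random() < 0.8)
        src = same if use_same else other
        pick = src.pop(int(rng.integers(len(src))))
        out.append(pick)
    return out


def _top3_for(
    truth: str, pool: Sequence[str], same_class: Sequence[str],
    skill: float, rng: np.random.Generator,
) -> list[str]:
    u = rng.random()
    if u < skill:
        rank = 1
    elif u < skill + (1 - skill) / 2:
        rank = 2
    elif u < skill + 3 * (1 - skill) / 4:
        rank = 3
    else:
        rank = 0  # truth absent from the three diagnoses
    n_conf = 3 if rank == 0 else 2
    conf = _confusions(truth, pool, same_class, n_conf, rng)
    if rank == 0:
        return conf
    top3 = conf[: rank - 1] + [truth] + conf[rank - 1 :]
    return top3[:3]


def simulate_reader(
    truths: Sequence[tuple[str, str]],
    profile: ReaderProfile,
    taxonomy: Taxonomy | None = None,
) -> list[MassEval]:
    """Simulate one reader's answers over ``(mass_id, truth_disease)`` pairs.

    The malignancy call is correct with probability ``0.5 + 0.5·skill`` (a
    skill-0 reader guesses at chance); the true type/disease lands at top-1
    with probability ``skill``, at rank 2 with ``(1−skill)/2``, rank 3 with
    ``(1−skill)/4`` and is absent with ``(1−skill)/4``.  Wrong answers are
    drawn preferentially (80%) from the truth's own malignancy class.
    """
    if not truths:
        raise SynthError("empty cohort")
    taxonomy = taxonomy or default_taxonomy()
    rng = np.random.default_rng(profile.seed)
    diseases = list(taxonomy.diseases)
    ptypes = list(taxonomy.ptypes)

    evals: list[MassEval] = []
    for mass_id, disease in truths:
        label = taxonomy.resolve(disease)
        truly_malignant = label.malignancy == MALIGNANT
        correct = rng.random() < 0.5 + 0.5 * profile.skill
        says_malignant = truly_malignant if correct else not truly_malignant
        same_diseases = list(taxonomy.diseases_of_malignancy(label.malignancy))
        same_ptypes = sorted(
            {taxonomy.ptype_of(d) for d in same_diseases}
        )
        evals.append(
            MassEval(
                mass_id=mass_id,
                truth_disease=disease,
                malignant_score=1.0 if says_malignant else 0.0,
                type_top3=_top3_for(label.ptype, ptypes, same_ptypes, profile.skill, rng),
                disease_top3=_top3_for(disease, diseases, same_diseases, profile.skill, rng),
            )
        )
    return evals
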