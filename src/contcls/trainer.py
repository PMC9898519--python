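"""Stage-wise training with trigger threshold, warm start and checkpoint retention.

Training for a stage starts only once enough new labeled images of *both*
malignancy classes have accumulated (:func:`should_trigger`, default 125 per
class).  A training run makes one pass ("round") over the training split per
round and snapshots the model after every round; only the last
``retain_last`` checkpoints (default 8) are kept in a ring buffer, and the
checkpoint of the final round is the run's terminal model.

The classifier backbone is pluggable behind :class:`ClassifierBackbone`.  The
default, :class:`SGDBackbone`, is a multinomial logistic regression trained by
seeded SGD on flattened preprocessed pixels — small, CPU-friendly and exactly
reproducible, which is what the orchestration logic needs; heavier
convolutional backbones can be registered without touching the pipeline.
"""

from __future__ import annotations

import copy
import time
from dataclasses import dataclass, field, replace
from typing import Mapping, Protocol, Sequence

import numpy as np
from PIL import Image
from sklearn.linear_model import SGDClassifier

from .datasets import LabeledImage, TaskDataset
from .records import ImageRecord


class TrainerError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    trigger_images: int = 125     # per-class new-image threshold to start a run
    max_rounds: int = 25          # passes over the training split
    retain_last: int = 8          # checkpoint ring-buffer size
    backbone: str = "sgd"
    warm_start: bool = True       # chain from the previous stage's model
    seed: int = 0
    input_size: int = 64          # images resized to input_size x input_size
    crop_margins: bool = False    # trim annotation border before resize
    crop_fraction: float = 0.10   # border share removed when crop_margins is on

    def __post_init__(self) -> None:
        if self.retain_last < 1:
            raise ValueError("retain_last must be >= 1")
        if self.trigger_images < 1:
            raise ValueError("trigger_images must be >= 1")


def should_trigger(
    new_image_count_by_class: Mapping[str, int], config: TrainConfig
) -> bool:
    """True iff every malignancy class has accumulated enough new images.

    The run starts when the *smaller* of the benign / malignant new-image
    counts reaches ``trigger_images``; counts reset after a completed run.
    """
    counts = list(new_image_count_by_class.values())
    if any(c < 0 for c in counts):
        raise TrainerError("image counts must be nonnegative")
    if len(counts) < 2:
        return False
    return min(counts) >= config.trigger_images


# ---------------------------------------------------------------------------
# preprocessing


def preprocess(image: ImageRecord, config: TrainConfig) -> np.ndarray:
    """Decode one image to a float array in [0, 1] of shape (input_size, input_size).

    Color inputs are collapsed to grayscale; peripheral annotation margins are
    trimmed only when ``crop_margins`` is on.
    """
    if image.pixels is not None:
        arr = np.asarray(image.pixels, dtype=np.float64)
        if arr.max() > 1.0:
            arr = arr / 255.0
        pil = Image.fromarray((arr * 255).astype(np.uint8), mode="L")
    else:
        try:
            pil = Image.open(image.path).convert("L")
        except OSError as e:
            raise TrainerError(f"unreadable image {image.path}: {e}") from e
    if config.crop_margins:
        w, h = pil.size
        dx, dy = int(w * config.crop_fraction), int(h * config.crop_fraction)
        pil = pil.crop((dx, dy, w - dx, h - dy))
    pil = pil.resize((config.input_size, config.input_size), Image.BILINEAR)
    return np.asarray(pil, dtype=np.float64) / 255.0


def _features(items: Sequence[LabeledImage], config: TrainConfig) -> np.ndarray:
    return np.stack([preprocess(it.image, config).ravel() for it in items])


# ---------------------------------------------------------------------------
# checkpoints


@dataclass
class Checkpoint:
    round: int
    task: str
    model_ref: object          # opaque handle owned by the backbone
    train_accuracy: float
    created_at: float = field(default_factory=time.time)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model_ref.predict_proba(X)

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.model_ref.classes)


@dataclass
class CheckpointSet:
    task: str
    stage: int
    checkpoints: list[Checkpoint]   # ascending round order, last retain_last only
    terminal_round: int
    config: TrainConfig
    train_image_ids: set[str] = field(default_factory=set)
    train_accuracies: dict[int, float] = field(default_factory=dict)

    @property
    def terminal(self) -> Checkpoint:
        return self.checkpoints[-1]

    def by_round(self, rnd: int) -> Checkpoint:
        for ck in self.checkpoints:
            if ck.round == rnd:
                return ck
        raise KeyError(rnd)


# ---------------------------------------------------------------------------
# backbones


class ClassifierBackbone(Protocol):
    """Contract a backbone must satisfy.

    ``fit`` runs ``rounds`` passes over (X, y) and emits one model snapshot per
    round via the returned list; snapshots expose ``predict_proba`` rows that
    sum to 1 and a ``classes`` tuple.  Same seed + data must give identical
    probabilities.
    """

    def fit(
        self,
        X: np.ndarray,
        y: Sequence[str],
        rounds: int,
        seed: int,
        init: "FrozenLinearModel | None" = None,
    ) -> list["FrozenLinearModel"]: ...


@dataclass
class FrozenLinearModel:
    """Immutable snapshot of a linear softmax classifier."""

    coef: np.ndarray
    intercept: np.ndarray
    classes: tuple[str, ...]

    def decision(self, X: np.ndarray) -> np.ndarray:
        z = X @ self.coef.T + self.intercept
        if z.ndim == 1 or z.shape[1] == 1:
            z = np.column_stack([-z.ravel(), z.ravel()])
        return z

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = self.decision(np.asarray(X, dtype=np.float64))
        z = z - z.max(axis=1, keepdims=True)
        p = np.exp(z)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.classes)[np.argmax(self.predict_proba(X), axis=1)]


class SGDBackbone:
    """Multinomial logistic regression trained with per-round partial fits.

    One "round" is a full shuffled pass over the training matrix.  Weights for
    classes present in a warm-start snapshot are copied over; new classes get
    zero-initialised rows, which is how the output layer is re-dimensioned
    when the PT/PD class sets grow between stages.
    """

    def __init__(self, alpha: float = 1e-4, eta0: float = 0.3):
        self.alpha = alpha
        self.eta0 = eta0

    def fit(
        self,
        X: np.ndarray,
        y: Sequence[str],
        rounds: int,
        seed: int,
        init: FrozenLinearModel | None = None,
    ) -> list[FrozenLinearModel]:
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=object)
        classes = np.array(sorted(set(y.tolist())), dtype=object)
        clf = SGDClassifier(
            loss="log_loss",
            alpha=self.alpha,
            learning_rate="constant",
            eta0=self.eta0,
            random_state=seed,
            shuffle=False,
        )
        rng = np.random.default_rng(seed)
        # one dummy call fixes the class set and allocates coef_
        clf.partial_fit(X[:1], y[:1], classes=classes)
        clf.coef_[:] = 0.0
        clf.intercept_[:] = 0.0
        if init is not None:
            self._copy_weights(clf, classes, init)
        snapshots: list[FrozenLinearModel] = []
        for _ in range(rounds):
            order = rng.permutation(len(y))
            clf.partial_fit(X[order], y[order])
            snapshots.append(
                FrozenLinearModel(
                    coef=clf.coef_.copy(),
                    intercept=clf.intercept_.copy(),
                    classes=tuple(classes.tolist()),
                )
            )
        return snapshots

    @staticmethod
    def _copy_weights(
        clf: SGDClassifier, classes: np.ndarray, init: FrozenLinearModel
    ) -> None:
        if clf.coef_.shape[1] != init.coef.shape[1]:
            raise TrainerError("warm start with mismatched feature dimension")
        old_index = {c: i for i, c in enumerate(init.classes)}
        if len(classes) == 2 and len(init.classes) == 2 and clf.coef_.shape[0] == 1:
            if tuple(classes.tolist()) == init.classes:
                clf.coef_[0] = init.coef[0]
                clf.intercept_[0] = init.intercept[0]
            return
        if clf.coef_.shape[0] == len(classes) and init.coef.shape[0] == len(init.classes):
            for row, c in enumerate(classes.tolist()):
                if c in old_index:
                    clf.coef_[row] = init.coef[old_index[c]]
                    clf.intercept_[row] = init.intercept[old_index[c]]


_BACKBONES: dict[str, ClassifierBackbone] = {}


def register_backbone(name: str, backbone: ClassifierBackbone) -> None:
    _BACKBONES[name] = backbone


def get_backbone(name: str) -> ClassifierBackbone:
    try:
        return _BACKBONES[name]
    except KeyError:
        raise TrainerError(f"unknown backbone {name!r}") from None


register_backbone("sgd", SGDBackbone())


# ---------------------------------------------------------------------------
# training


def train_task(
    dataset: TaskDataset,
    config: TrainConfig,
    init: Checkpoint | None = None,
) -> CheckpointSet:
    """Train one task for ``max_rounds`` rounds, keeping the last ``retain_last``
    checkpoints.

    Per-round training accuracy is recorded for every round (including the
    ones whose snapshots rotate out of the ring buffer).  ``init`` warm-starts
    from a prior stage's checkpoint.
    """
    if len(dataset.train) < 2 or len(dataset.classes) < 2:
        raise TrainerError(
            f"{dataset.task} dataset below trainable size "
            f"({len(dataset.train)} images, {len(dataset.classes)} classes)"
        )
    backbone = get_backbone(config.backbone)
    X = _features(dataset.train, config)
    y = [it.label for it in dataset.train]
    init_model = init.model_ref if (init is not None and config.warm_start) else None
    try:
        snapshots = backbone.fit(X, y, rounds=config.max_rounds, seed=config.seed, init=init_model)
    except TrainerError:
        raise
    except Exception as e:  # surface backbone failures with the round index
        raise TrainerError(f"backbone {config.backbone!r} failed: {e}") from e

    accuracies: dict[int, float] = {}
    checkpoints: list[Checkpoint] = []
    y_arr = np.asarray(y, dtype=object)
    for rnd, snap in enumerate(snapshots, start=1):
        acc = float(np.mean(snap.predict(X) == y_arr))
        accuracies[rnd] = acc
        checkpoints.append(
            Checkpoint(round=rnd, task=dataset.task, model_ref=snap, train_accuracy=acc)
        )
        if len(checkpoints) > config.retain_last:
            checkpoints.pop(0)
    return CheckpointSet(
        task=dataset.task,
        stage=dataset.stage,
        checkpoints=checkpoints,
        terminal_round=len(snapshots),
        config=config,
        train_image_ids={it.image.image_id for it in dataset.train},
        train_accuracies=accuracies,
    )
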