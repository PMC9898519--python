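"""Checkpoint supervision: pick the optimization model (OM) and keep the
terminal non-optimal model (NOM), then decide promotion of the new stage.

After each stage's training run, every retained checkpoint is evaluated on a
frozen binary test set.  The checkpoint with the highest one-vs-rest AUC is
designated the *optimization model* (OM); the checkpoint of the final round —
the model trained until accuracy stopped improving — is the *non-optimal
model* (NOM).  Since the NOM is itself in the candidate set, OM AUC ≥ NOM AUC
by construction.

Promotion compares the freshly selected model trio with the incumbent on the
same internal test set using the full nine-index scorecard total; the new
trio is deployed only if its total does not fall below the incumbent's, so
the deployed score never decreases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import FixedTestSet
from .evaluate import ScoreCard, roc_auc
from .trainer import Checkpoint, CheckpointSet, TrainConfig, _features


class SelectionError(ValueError):
    pass


@dataclass
class SelectionRecord:
    task: str
    stage: int
    candidate_aucs: dict[int, float]   # round -> AUC on the frozen test set
    om_round: int
    nom_round: int
    testset_id: str

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "stage": self.stage,
            "candidate_aucs": {str(k): v for k, v in sorted(self.candidate_aucs.items())},
            "om_round": self.om_round,
            "nom_round": self.nom_round,
            "testset_id": self.testset_id,
        }


@dataclass
class ModelTriple:
    """The deployed {BM, PT, PD} trio, all of one variant (OM or NOM)."""

    bm: Checkpoint
    pt: Checkpoint
    pd: Checkpoint
    variant: str   # "OM" | "NOM"
    stage: int

    def __post_init__(self) -> None:
        if self.variant not in ("OM", "NOM"):
            raise SelectionError("variant must be OM or NOM")


def _positive_probs(ck: Checkpoint, X: np.ndarray, positive_class: str) -> np.ndarray:
    """One-vs-rest positive-class probability for each test image.

    For the PT/PD multi-class heads this is the probability mass the model
    puts on the designated positive class; a class the checkpoint has never
    seen scores 0 everywhere.
    """
    probs = ck.predict_proba(X)
    classes = list(ck.classes)
    if positive_class not in classes:
        return np.zeros(len(X))
    return probs[:, classes.index(positive_class)]


def select_optimal(
    checkpoints: CheckpointSet,
    testset: FixedTestSet,
    positive_class: str | None = None,
) -> SelectionRecord:
    """Evaluate every retained checkpoint on the frozen test set; pick the OM.

    ``om_round`` is the argmax of one-vs-rest AUC (ties go to the *later*
    round); ``nom_round`` is the terminal round.  Test images overlapping the
    run's training images are a hard error (leakage guard).
    """
    if not checkpoints.checkpoints:
        raise SelectionError("no checkpoints to select from")
    if not testset.items:
        raise SelectionError("empty test set")
    overlap = checkpoints.train_image_ids & testset.image_ids
    if overlap:
        raise SelectionError(
            f"test set leaks {len(overlap)} training image(s), e.g. {sorted(overlap)[:3]}"
        )
    if positive_class is None:
        positive_class = testset.positive_class

    X = _features([it for it in testset.items], checkpoints.config)
    labels = [1 if it.label == "positive" else 0 for it in testset.items]
    aucs: dict[int, float] = {}
    for ck in checkpoints.checkpoints:
        scores = _positive_probs(ck, X, positive_class)
        if np.all(scores == scores[0]):
            aucs[ck.round] = 0.5  # uninformative head: all ties
        else:
            aucs[ck.round] = roc_auc(scores, labels)[0]
    om_round = max(aucs, key=lambda r: (aucs[r], r))
    return SelectionRecord(
        task=checkpoints.task,
        stage=checkpoints.stage,
        candidate_aucs=aucs,
        om_round=om_round,
        nom_round=checkpoints.terminal_round,
        testset_id=testset.testset_id,
    )


@dataclass
class EvaluatedTriple:
    """A model trio with its scorecard on a named test set."""

    triple: ModelTriple
    scorecard: ScoreCard
    testset_id: str


def promote(new: EvaluatedTriple, incumbent: EvaluatedTriple | None) -> bool:
    """True iff the new trio's total score is at least the incumbent's.

    An equal total promotes the fresher model.  Scorecards must come from the
    same frozen test set or the comparison is meaningless.
    """
    if incumbent is None:
        return True
    if new.testset_id != incumbent.testset_id:
        raise SelectionError(
            f"scorecards from different test sets: {new.testset_id} vs {incumbent.testset_id}"
        )
    return new.scorecard.total >= incumbent.scorecard.total
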