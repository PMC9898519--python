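"""The simulated prospective study: stage, train, select, evaluate, promote.

Ties every module together into the staged loop the pipeline is built for:

    for each stage:
        accumulate new cases → balance benign vs malignant →
        build BM/PT/PD datasets → (trigger check) → train three tasks →
        select OM / NOM per task on frozen binary test sets →
        evaluate both trios on every configured evaluation set →
        score → promote if the internal-test total did not drop

Case ids double as examination order: the internal evaluation set is a seeded
random hold-out, the remaining stream is split chronologically into stages.
The frozen selection test sets are drawn from the internal hold-out pool, so
no selection or evaluation image can ever appear in training (audited at the
end of the run).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import datasets as ds
from .datasets import FixedTestSet, StagePlan, TASKS
from .ensemble import diagnose_case
from .evaluate import (
    IndexResult,
    MassEval,
    ScoreCard,
    compute_indices,
    rank_entries,
    score_indices,
)
from .records import CaseRecord, all_masses
from .selector import (
    EvaluatedTriple,
    ModelTriple,
    SelectionRecord,
    promote,
    select_optimal,
)
from .synth import SynthConfig, generate_cohort
from .taxonomy import BENIGN, MALIGNANT, Taxonomy, default_taxonomy
from .trainer import Checkpoint, CheckpointSet, TrainConfig, should_trigger, train_task


class StudyError(RuntimeError):
    pass


@dataclass
class StudyConfig:
    n_stages: int = 6
    synth: SynthConfig = field(default_factory=SynthConfig)
    train: TrainConfig = field(default_factory=lambda: TrainConfig(trigger_images=30, max_rounds=20))
    taxonomy: Taxonomy | None = None
    internal_test_fraction: float = 0.2
    selection_pos_neg: tuple[int, int] = (80, 80)
    min_images: int = 10
    external_synth: SynthConfig | None = None   # optional second-site cohort
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stages < 1:
            raise StudyError("n_stages must be >= 1")


@dataclass
class StageOutcome:
    stage: int
    trained: bool
    plan: StagePlan | None
    selection: dict[str, SelectionRecord] = field(default_factory=dict)
    results: dict[tuple[str, str], IndexResult] = field(default_factory=dict)   # (testset, variant)
    scorecards: dict[tuple[str, str], ScoreCard] = field(default_factory=dict)
    promoted: bool = False
    deployed_total: float = float("nan")


@dataclass
class StudyReport:
    config: StudyConfig
    stages: list[StageOutcome]
    deployed_totals: list[float]
    seed: int

    def mean_total(self, variant: str, testset: str = "internal") -> float:
        vals = [
            s.scorecards[(testset, variant)].total
            for s in self.stages
            if (testset, variant) in s.scorecards
        ]
        return float(np.mean(vals))

    def table(self) -> pd.DataFrame:
        """Long-form report: one row per stage × test set × variant."""
        rows = []
        for st in self.stages:
            for (testset, variant), ix in st.results.items():
                card = st.scorecards[(testset, variant)]
                row = {
                    "stage": st.stage,
                    "testset": testset,
                    "variant": variant,
                    "auc": round(ix.auc, 3),
                    "auc_ci": f"({ix.auc_ci_low:.3f}-{ix.auc_ci_high:.3f})",
                }
                for name in IndexResult.PERCENT_FIELDS:
                    row[name] = round(getattr(ix, name), 1)
                row["total_score"] = round(card.total, 2)
                rows.append(row)
        return pd.DataFrame(rows)

    def rank_table(self, readers: Sequence[tuple[str, float, dict]] = ()) -> pd.DataFrame:
        """Rank deployed per-stage OM internal totals against reader entries."""
        entries = list(readers)
        for st in self.stages:
            key = ("internal", "OM")
            if key in st.scorecards:
                entries.append((f"CLS_{st.stage}", st.scorecards[key].total, {}))
        table = rank_entries(entries)
        return pd.DataFrame(table.to_rows())

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "deployed_totals": self.deployed_totals,
                "stages": [
                    {
                        "stage": st.stage,
                        "trained": st.trained,
                        "promoted": st.promoted,
                        "deployed_total": st.deployed_total,
                        "selection": {t: r.to_dict() for t, r in st.selection.items()},
                        "totals": {
                            f"{ts}/{var}": card.total
                            for (ts, var), card in st.scorecards.items()
                        },
                    }
                    for st in self.stages
                ],
            },
            indent=1,
        )


# ---------------------------------------------------------------------------


def _positive_classes(
    cases: Sequence[CaseRecord], taxonomy: Taxonomy
) -> dict[str, str]:
    """Designated positive class per task: BM → malignant; PT/PD → the most
    frequent malignant type / disease in the pool (ties by name)."""
    masses = all_masses(cases)
    mal = [m for m in masses if taxonomy.malignancy_of(m.disease) == MALIGNANT]
    if not mal:
        raise StudyError("no malignant masses in the pool")

    def most_frequent(labels: list[str]) -> str:
        counts: dict[str, int] = {}
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
        return min(counts, key=lambda c: (-counts[c], c))

    return {
        "BM": MALIGNANT,
        "PT": most_frequent([taxonomy.ptype_of(m.disease) for m in mal]),
        "PD": most_frequent([m.disease for m in mal]),
    }


def _evaluate_triple(
    triple: ModelTriple,
    eval_cases: Sequence[CaseRecord],
    taxonomy: Taxonomy,
    config: TrainConfig,
) -> tuple[IndexResult, ScoreCard]:
    evals = []
    for mass in all_masses(eval_cases):
        diag = diagnose_case(
            mass.images, triple, config, case_id=mass.case_id, taxonomy=taxonomy
        )
        evals.append(
            MassEval(
                mass_id=mass.mass_id,
                truth_disease=mass.disease,
                malignant_score=diag.case_malignant_prob,
                type_top3=[n for n, _ in diag.type_top3],
                disease_top3=[n for n, _ in diag.disease_top3],
            )
        )
    ix = compute_indices(evals, taxonomy)
    return ix, score_indices(ix)


def _stage_chunks(
    cases: list[CaseRecord], n_stages: int, taxonomy: Taxonomy
) -> list[list[CaseRecord]]:
    """Chronological stage cuts placed to even out the malignant image load.

    The stream is kept in examination order but cut where the cumulative
    malignant image count crosses k/n_stages of the total, so every stage
    carries roughly the same amount of new malignant material (the quantity
    the trigger and the benign balancing both key on).
    """
    cases = sorted(cases, key=lambda c: c.case_id)   # chronological order
    mal_images = [
        sum(
            m.n_images
            for m in c.masses
            if taxonomy.malignancy_of(m.disease) == MALIGNANT
        )
        for c in cases
    ]
    total = sum(mal_images)
    if total == 0:
        bounds = np.linspace(0, len(cases), n_stages + 1).astype(int)
        return [cases[bounds[i] : bounds[i + 1]] for i in range(n_stages)]
    cum = np.cumsum(mal_images)
    chunks: list[list[CaseRecord]] = []
    start = 0
    for k in range(1, n_stages):
        cut = int(np.searchsorted(cum, total * k / n_stages, side="left")) + 1
        cut = max(cut, start + 1)
        chunks.append(cases[start:cut])
        start = cut
    chunks.append(cases[start:])
    return chunks


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full staged study on a synthetic cohort; see module docstring."""
    taxonomy = config.taxonomy or default_taxonomy()
    rng = np.random.default_rng(config.seed)

    synth_cfg = replace(config.synth, seed=int(rng.integers(0, 2**31 - 1)))
    cohort = generate_cohort(synth_cfg, taxonomy)
    cases = ds.select_cases(cohort, taxonomy)

    # hold out the internal evaluation pool
    n_test = max(2, int(round(config.internal_test_fraction * len(cases))))
    test_idx = set(rng.choice(len(cases), n_test, replace=False).tolist())
    internal = [c for i, c in enumerate(cases) if i in test_idx]
    stream = [c for i, c in enumerate(cases) if i not in test_idx]

    eval_sets: dict[str, list[CaseRecord]] = {"internal": internal}
    if config.external_synth is not None:
        ext_cfg = replace(config.external_synth, seed=int(rng.integers(0, 2**31 - 1)))
        # the id prefix keeps every external case/mass/image id distinct
        ext = ds.select_cases(
            generate_cohort(ext_cfg, taxonomy, id_prefix="ext-"), taxonomy
        )
        eval_sets["external"] = ext

    # frozen selection test sets from the internal pool
    positives = _positive_classes(internal, taxonomy)
    testsets: dict[str, FixedTestSet] = {}
    for t_i, task in enumerate(TASKS):
        label_of = ds._label_fn(task, taxonomy)
        n_pos_avail = sum(
            m.n_images for m in all_masses(internal) if label_of(m) == positives[task]
        )
        n_neg_avail = sum(
            m.n_images for m in all_masses(internal) if label_of(m) != positives[task]
        )
        n_pos = min(config.selection_pos_neg[0], n_pos_avail)
        n_neg = min(config.selection_pos_neg[1], n_neg_avail)
        if n_pos < 5 or n_neg < 5:
            raise StudyError(f"internal pool too small for a {task} selection test set")
        testsets[task] = ds.build_fixed_testset(
            internal, taxonomy, task, positives[task], n_pos, n_neg,
            seed=int(rng.integers(0, 2**31 - 1)),
        )

    chunks = _stage_chunks(stream, config.n_stages, taxonomy)
    stages: list[StageOutcome] = []
    deployed_totals: list[float] = []
    prev_plan: StagePlan | None = None
    prev_om: dict[str, Checkpoint] = {}
    incumbent: EvaluatedTriple | None = None
    pending: dict[str, int] = {BENIGN: 0, MALIGNANT: 0}
    train_image_ids: set[str] = set()

    for stage_no, chunk in enumerate(chunks, start=1):
        accumulated = ds.accumulate(prev_plan, chunk)
        stage_seed = int(rng.integers(0, 2**31 - 1))
        plan = ds.balance_stage(
            accumulated, taxonomy, seed=stage_seed, stage=stage_no, new_cases=chunk
        )
        prev_plan = plan
        outcome = StageOutcome(stage=stage_no, trained=False, plan=plan)

        for case in chunk:
            for m in case.masses:
                pending[taxonomy.malignancy_of(m.disease)] += m.n_images
        if not should_trigger(pending, config.train):
            # not enough new material: stage carries over, deployment unchanged
            outcome.deployed_total = deployed_totals[-1] if deployed_totals else float("nan")
            deployed_totals.append(outcome.deployed_total)
            stages.append(outcome)
            continue
        pending = {BENIGN: 0, MALIGNANT: 0}

        task_cfg = replace(config.train, seed=int(rng.integers(0, 2**31 - 1)))
        task_sets = ds.build_task_datasets(
            plan.balanced_cases,
            taxonomy,
            min_images=config.min_images,
            seed=task_cfg.seed,
            stage=stage_no,
        )
        runs: dict[str, CheckpointSet] = {}
        om: dict[str, Checkpoint] = {}
        nom: dict[str, Checkpoint] = {}
        for task in TASKS:
            run = train_task(task_sets[task], task_cfg, init=prev_om.get(task))
            rec = select_optimal(run, testsets[task])
            runs[task] = run
            outcome.selection[task] = rec
            om[task] = run.by_round(rec.om_round)
            nom[task] = run.by_round(rec.nom_round)
            train_image_ids |= run.train_image_ids
        outcome.trained = True
        prev_om = om

        om_triple = ModelTriple(om["BM"], om["PT"], om["PD"], "OM", stage_no)
        nom_triple = ModelTriple(nom["BM"], nom["PT"], nom["PD"], "NOM", stage_no)
        for ts_name, ts_cases in eval_sets.items():
            for variant, triple in (("OM", om_triple), ("NOM", nom_triple)):
                ix, card = _evaluate_triple(triple, ts_cases, taxonomy, task_cfg)
                outcome.results[(ts_name, variant)] = ix
                outcome.scorecards[(ts_name, variant)] = card

        new_eval = EvaluatedTriple(
            om_triple, outcome.scorecards[("internal", "OM")], "internal"
        )
        outcome.promoted = promote(new_eval, incumbent)
        if outcome.promoted:
            incumbent = new_eval
        outcome.deployed_total = incumbent.scorecard.total
        deployed_totals.append(outcome.deployed_total)
        stages.append(outcome)

    # global leakage audit: no evaluation/selection image in any training split
    eval_ids = {
        img.image_id for cases_ in eval_sets.values() for m in all_masses(cases_) for img in m.images
    }
    for ts in testsets.values():
        eval_ids |= ts.image_ids
    leaked = eval_ids & train_image_ids
    if leaked:
        raise StudyError(f"leakage audit failed: {len(leaked)} images in both pools")

    return StudyReport(
        config=config, stages=stages, deployed_totals=deployed_totals, seed=config.seed
    )
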