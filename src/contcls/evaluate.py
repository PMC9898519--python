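"""Nine-index diagnostic evaluation, 100-point weighted scoring and ranking.

A diagnostic report for a mass is judged on three levels:

* benign/malignant — a continuous malignancy score, evaluated threshold-free
  by ROC AUC (pairwise concordance, ties ½) with a DeLong 95% CI, plus the
  sensitivity/specificity pair at the Youden-index operating point;
* pathological type — a top-3 list of type names, evaluated by top-1 accuracy
  (DAPT), rank-weighted 3/2/1/0 identification accuracy (APTI) and the rate
  of the true type missing from the top-3 (MDRPT);
* disease — the same three indices over the disease top-3
  (DAPD / ADPD / MDRPD).

The nine indices are folded into a 100-point total: the AUC contributes
``20·AUC``; each percent index contributes ``value/10`` if higher is better
or ``(100−value)/10`` for the two missed-diagnosis rates.  A perfect system
scores exactly 100.  Totals are ranked across systems and human readers on a
common table, and reader experience (working years) can be correlated with
the totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .taxonomy import MALIGNANT, Taxonomy


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# ROC


def _check_binary(labels: np.ndarray) -> None:
    u = np.unique(labels)
    if u.size != 2 or not np.array_equal(u, [0, 1]):
        raise EvaluationError("labels must contain both classes, coded 0/1")


def _midranks(x: np.ndarray) -> np.ndarray:
    # midranks as used by DeLong's fast algorithm
    return stats.rankdata(x, method="average")


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, float, float]:
    """AUC by pairwise concordance (ties count ½) with a DeLong 95% CI.

    Equivalent to the Mann–Whitney U statistic normalised by the number of
    positive–negative pairs.  The CI is AUC ± 1.96·SE with SE from DeLong's
    structural-component variance, clipped to [0, 1]; a degenerate variance
    (perfect separation) collapses the CI onto the AUC.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.shape != labels.shape:
        raise EvaluationError("scores and labels must have equal length")
    _check_binary(labels)

    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)

    # concordance via midranks (O(N log N), exactly the all-pairs count)
    allr = _midranks(np.concatenate([pos, neg]))
    auc = (allr[:m].sum() - m * (m + 1) / 2) / (m * n)

    # DeLong structural components
    v10 = (_midranks(np.concatenate([pos, neg]))[:m] - _midranks(pos)) / n
    v01 = 1.0 - (_midranks(np.concatenate([neg, pos]))[:n] - _midranks(neg)) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    z = stats.norm.ppf(0.975)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    return float(auc), float(lo), float(hi)


def youden_point(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, float]:
    """(sensitivity %, specificity %) at the Youden-optimal threshold.

    Scans every distinct score as a candidate threshold (call positive when
    ``score >= t``), plus the all-negative rule, maximising J = sens + spec − 1.
    Ties prefer the higher sensitivity, then the higher threshold.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    _check_binary(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    thresholds = np.concatenate([np.unique(scores), [np.inf]])
    best = None
    for t in thresholds:
        sens = np.mean(pos >= t)
        spec = np.mean(neg < t)
        key = (sens + spec - 1.0, sens, t)
        if best is None or key > best[0]:
            best = (key, (float(sens * 100), float(spec * 100)))
    return best[1]


# ---------------------------------------------------------------------------
# top-3 rank indices


def rank_points(truth_name: str, top3: Sequence[str]) -> int:
    """3/2/1 points for the truth at rank 1/2/3 of the top-3 list, else 0."""
    if len(top3) > 3:
        raise EvaluationError("top3 longer than 3")
    if len(set(top3)) != len(top3):
        raise EvaluationError(f"duplicate names in top3: {list(top3)}")
    for pos, name in enumerate(top3, start=1):
        if name == truth_name:
            return 4 - pos
    return 0


@dataclass
class MassEval:
    """One mass's ground truth and the report under evaluation."""

    mass_id: str
    truth_disease: str
    malignant_score: float
    type_top3: list[str] = field(default_factory=list)
    disease_top3: list[str] = field(default_factory=list)


@dataclass
class IndexResult:
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    sensitivity: float
    specificity: float
    dapt: float
    apti: float
    mdrpt: float
    dapd: float
    adpd: float
    mdrpd: float

    PERCENT_FIELDS = (
        "sensitivity",
        "specificity",
        "dapt",
        "apti",
        "mdrpt",
        "dapd",
        "adpd",
        "mdrpd",
    )

    def validate(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise EvaluationError("auc out of [0,1]")
        for name in self.PERCENT_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise EvaluationError(f"{name} out of [0,100]: {v}")


def _rank_counts(evals: Sequence[MassEval], truth_of, top3_of) -> tuple[int, int, int, int]:
    n1 = n2 = n3 = n0 = 0
    for ev in evals:
        pts = rank_points(truth_of(ev), top3_of(ev))
        if pts == 3:
            n1 += 1
        elif pts == 2:
            n2 += 1
        elif pts == 1:
            n3 += 1
        else:
            n0 += 1
    return n1, n2, n3, n0


def compute_indices(evals: Sequence[MassEval], taxonomy: Taxonomy) -> IndexResult:
    """Compute the nine indices over a set of evaluated masses.

    AUC / sensitivity / specificity come from ``malignant_score`` against the
    malignancy of the true disease.  With n1, n2, n3, n0 the counts of masses
    whose true type sits at top-3 rank 1, 2, 3 or nowhere:

        DAPT  = 100·n1/N
        APTI  = 100·(3n1 + 2n2 + n3) / (3N)
        MDRPT = 100·n0/N

    and identically for the disease list (DAPD / ADPD / MDRPD).
    """
    if not evals:
        raise EvaluationError("no masses to evaluate")
    labels = [1 if taxonomy.malignancy_of(ev.truth_disease) == MALIGNANT else 0 for ev in evals]
    scores = [ev.malignant_score for ev in evals]
    auc, lo, hi = roc_auc(scores, labels)
    sens, spec = youden_point(scores, labels)

    N = len(evals)
    t1, t2, t3, t0 = _rank_counts(
        evals, lambda ev: taxonomy.ptype_of(ev.truth_disease), lambda ev: ev.type_top3
    )
    d1, d2, d3, d0 = _rank_counts(
        evals, lambda ev: ev.truth_disease, lambda ev: ev.disease_top3
    )
    res = IndexResult(
        auc=auc,
        auc_ci_low=lo,
        auc_ci_high=hi,
        sensitivity=sens,
        specificity=spec,
        dapt=100.0 * t1 / N,
        apti=100.0 * (3 * t1 + 2 * t2 + t3) / (3 * N),
        mdrpt=100.0 * t0 / N,
        dapd=100.0 * d1 / N,
        adpd=100.0 * (3 * d1 + 2 * d2 + d3) / (3 * N),
        mdrpd=100.0 * d0 / N,
    )
    res.validate()
    return res


# ---------------------------------------------------------------------------
# 100-point weighted score


HIGHER_BETTER = ("sensitivity", "specificity", "dapt", "apti", "dapd", "adpd")
MISSED_RATES = ("mdrpt", "mdrpd")


@dataclass
class ScoreCard:
    component_scores: dict[str, float]
    total: float

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        out = {k: round(v, ndigits) for k, v in self.component_scores.items()}
        out["total"] = round(self.total, ndigits)
        return out


def score_indices(ix: IndexResult) -> ScoreCard:
    """Fold the nine indices into the 100-point weighted total.

    AUC is worth up to 20 points (``20·AUC``); each of the other eight
    indices up to 10 — ``value/10`` for higher-is-better indices and
    ``(100−value)/10`` for the two missed-diagnosis rates.  Components are
    computed unrounded; round only for display.
    """
    ix.validate()
    comps: dict[str, float] = {"auc": 20.0 * ix.auc}
    for name in HIGHER_BETTER:
        comps[name] = getattr(ix, name) / 10.0
    for name in MISSED_RATES:
        comps[name] = (100.0 - getattr(ix, name)) / 10.0
    return ScoreCard(component_scores=comps, total=float(sum(comps.values())))


# ---------------------------------------------------------------------------
# ranking and correlation


@dataclass
class RankEntry:
    name: str
    total: float
    rank: int
    metadata: dict = field(default_factory=dict)


@dataclass
class RankTable:
    entries: list[RankEntry]

    def rank_of(self, name: str) -> int:
        for e in self.entries:
            if e.name == name:
                return e.rank
        raise KeyError(name)

    def to_rows(self) -> list[dict]:
        return [
            {"name": e.name, "total": e.total, "rank": e.rank, **e.metadata}
            for e in self.entries
        ]


def rank_entries(
    entries: Sequence[tuple[str, float] | tuple[str, float, dict]]
) -> RankTable:
    """Rank by descending total; rank 1 is best.

    Equal totals receive consecutive ranks, ordered by name.
    """
    if not entries:
        raise EvaluationError("no entries to rank")
    norm = [(e[0], float(e[1]), e[2] if len(e) > 2 else {}) for e in entries]
    norm.sort(key=lambda e: (-e[1], e[0]))
    return RankTable(
        entries=[
            RankEntry(name=n, total=t, rank=i, metadata=md)
            for i, (n, t, md) in enumerate(norm, start=1)
        ]
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation, reported to 2 decimals."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or len(x) < 3:
        raise EvaluationError("need equal-length sequences of length >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise EvaluationError("zero variance")
    return round(float(stats.pearsonr(x, y).statistic), 2)
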