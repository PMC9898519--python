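# contcls

A continual-learning pipeline for ultrasound mass classification, built
around the supervision problem that makes continual learning hard to deploy
clinically: as new pathology-confirmed cases stream in and the model is
retrained, nothing guarantees the new model is better than the one already in
use. `contcls` implements a staged retrain–select–promote loop for a
three-task breast-mass classifier, together with the evaluation machinery to
score it against human readers — and a synthetic cohort generator so the
whole pipeline runs and is tested end to end without any clinical data.

## What it does

**Three tasks, one taxonomy.** Every mass carries a pathology-confirmed
*disease* label; diseases roll up into *pathological types*, and each type is
benign or malignant. From one labeled stream the pipeline derives three
classification tasks: benign vs malignant (BM), pathological type (PT) and
disease (PD).

**Staged dataset construction.** Cases accumulate across stages (stage *k*
contains everything from stages 1..*k*). Per breast side, one representative
mass is kept (malignant beats benign; highest malignancy grade among
malignant; largest diameter among benign). Benign cases are down-sampled to
approximate benign/malignant parity in cases and images; PT/PD classes enter
only once they have accumulated ≥ 10 images; each class is split 8:2 into
train/validation.

**Checkpoint supervision (OM/NOM).** Training starts when enough new images
of both malignancy classes have arrived (the trigger preset). One checkpoint
is saved per round; the last 8 are retained. Each retained checkpoint is
evaluated on a frozen binary test set; the checkpoint with the highest AUC
becomes the *optimization model* (OM), the final checkpoint is the
*non-optimal model* (NOM). A freshly selected OM trio {BM, PT, PD} replaces
the deployed trio only if its scorecard total on the frozen internal test set
does not drop — so deployed performance never decreases.

**Ensemble diagnosis.** The BM model scores every image of a mass; the
highest-malignant-probability image is passed to the PT and PD models, which
return top-3 candidate lists. The three outputs are independent; conflicts
are flagged, not reconciled.

**Nine-index scoring.** A prediction set is judged by AUC (with DeLong 95%
CI), sensitivity and specificity at the Youden point, and six top-3 indices —
top-1 type accuracy (DAPT), rank-weighted 3/2/1/0 type identification
accuracy (APTI), type missed-diagnosis rate (MDRPT), and the disease
analogues (DAPD/ADPD/MDRPD). These fold into a 100-point total:

    total = 20·AUC + Σ value/10 (higher-better indices)
                   + Σ (100 − value)/10 (missed-diagnosis rates)

A perfect system scores exactly 100. Totals rank systems and human readers
on a common table.

## Worked example

```python
from contcls import StudyConfig, run_study

report = run_study(StudyConfig(seed=5))   # 6 stages, ~300 synthetic cases
print(report.table()[["stage", "variant", "auc", "sensitivity",
                      "dapt", "mdrpd", "total_score"]].to_string(index=False))
print([round(t, 2) for t in report.deployed_totals])
```

prints (seed 5) one row per stage × {OM, NOM} on the internal test set:

```
 stage variant   auc  sensitivity  dapt  mdrpd  total_score
     1      OM 0.850         81.0  47.1   11.8        75.83
     1     NOM 0.850         81.0  51.5   11.8        76.66
     2      OM 0.925         90.5  42.6   13.2        73.13
     2     NOM 0.925         90.5  45.6   16.2        76.08
     3      OM 0.938         90.5  45.6   13.2        77.52
     3     NOM 0.938         90.5  39.7   13.2        76.59
     4      OM 0.942         90.5  51.5   38.2        74.74
     4     NOM 0.931         90.5  44.1   25.0        72.54
     5      OM 0.935         90.5  51.5   13.2        79.63
     5     NOM 0.832         95.2  50.0   13.2        75.34
     6      OM 0.954         95.2  51.5    8.8        79.84
     6     NOM 0.954         95.2  48.5   23.5        73.76
[75.83, 75.83, 77.52, 77.52, 79.63, 79.84]
```

The deployed total (last line) never decreases: at stages 2 and 4 the new
OM scored below the incumbent, so the incumbent stayed deployed. AUC and
the total climb as the case pool accumulates, and the OM outscores the NOM
at the later stages — the selection step doing its job.

Scoring a reader (or any prediction manifest) works the same way:

```python
from contcls import (ReaderProfile, compute_indices, default_taxonomy,
                     score_indices, simulate_reader)
tax = default_taxonomy()
truths = [("m1", "Breast cyst"), ("m2", "Invasive ductal carcinoma of the breast")]
evals = simulate_reader(truths * 20, ReaderProfile("reader", 5, skill=1.0), tax)
print(score_indices(compute_indices(evals, tax)).total)   # 100.0
```

A `contcls` command-line tool exposes the same steps
(`simulate`, `build-dataset`, `evaluate`, `rank`, `run-study`,
`simulate-readers`); see `contcls --help`.

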