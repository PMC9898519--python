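# Methods

This note documents the models, rules and numerical choices behind
`contcls`, the parameters that matter, what the synthetic generator does and
does not emulate, and where the design was genuinely open.

## The continual-learning loop

The pipeline models a clinical deployment in which pathology-confirmed
ultrasound images arrive as a stream and a three-task classifier
(benign/malignant BM, pathological type PT, disease PD) is retrained in
stages. The core safety mechanism is *supervised promotion*: a retrained
model is measured on a frozen internal test set with a nine-index scorecard,
and replaces the deployed model only if its total does not drop. The
deployed score is therefore non-decreasing by construction; the pipeline
asserts this at run time.

### Dataset construction rules

* **One mass per case-side.** Among candidate masses on one breast side: any
  malignant mass beats all benign ones; among malignant masses the highest
  malignancy *grade* (an integer per malignant disease in the taxonomy
  config) wins; among benign masses the largest `max_diameter` wins. Ties:
  malignant ties with no grades resolve to the lowest `mass_id` and emit a
  warning; benign masses without diameters fall back to image count, then
  `mass_id`. The tie rules are this package's choices; the selection
  *ordering* (malignant > grade > size) is the modeled clinical rule.
* **Accumulation.** Stage *k*'s pool is the union of all earlier pools and
  the new arrivals; duplicate case-sides or mass ids across stages are an
  error, since a case examined once must not re-enter the stream.
* **Benign balancing.** All malignant cases are kept. Benign cases are drawn
  in a seeded random order until case parity, then up to 2 more are admitted
  while each strictly shrinks the benign-vs-malignant *image* gap. "Parity
  in cases first, image proximity second" is one concrete reading of
  balancing "number and images"; both resulting counts are recorded in the
  stage plan for audit.
* **Inclusion threshold and split.** PT/PD classes need ≥ 10 accumulated
  images to enter their task (their images still count for BM); each class
  is split 8:2 at image level with `val = max(1, round(0.2·n))`, ties
  rounding half up. Image-level splitting lets two images of one mass fall
  on both sides of the split; `split_unit="mass"` would be safer but the
  image-level rule is the modeled behaviour, so it is the default. The BM
  task must hold both classes at or above the threshold or the pool is "too
  early to train".

### Training and checkpoint retention

Training for a stage starts only when the smaller of the benign/malignant
*new*-image counts reaches the trigger preset (`trigger_images`; 125 by
default, the value a mid-size clinical stream accumulates per stage — the
bundled synthetic study uses 30, scaled to its smaller stages). Counts reset
after a completed run. One checkpoint is saved per round (one full pass over
the training split); only the last 8 are retained (`retain_last`), and the
final round's checkpoint is the run's terminal model.

The default backbone is a multinomial logistic regression trained by seeded
SGD on flattened 64×64 grayscale pixels, with a **constant** learning rate
(0.3) and weak L2 (1e-4). Two properties motivated this choice over a
convolutional network: it is exactly reproducible and CPU-cheap, and the
constant learning rate keeps successive checkpoints genuinely different —
the regime in which selecting among retained checkpoints is meaningful at
all. With a decaying rate the terminal checkpoint is almost always the best
and the OM/NOM distinction collapses. Heavier backbones can be registered
behind the same `fit → snapshots` contract; warm starting across stages
copies weight rows for known classes and zero-fills rows for classes that
appeared since the previous stage.

### Selection and promotion

Every retained checkpoint is evaluated on a frozen binary test set (drawn
once from the held-out internal pool, never from training data — overlap is
a hard error). BM uses malignant-vs-benign images; PT and PD are multi-class
models, but selection uses one-vs-rest AUC against a designated positive
class (the most frequent malignant type/disease in the pool), mirroring the
binary construction of the selection sets. The argmax is the OM (ties go to
the later round); the terminal checkpoint is the NOM. Since the NOM is in
the candidate set, OM AUC ≥ NOM AUC always.

Promotion compares full nine-index scorecard totals on the same frozen
internal test set, not selection AUC alone — whether the original decision
used the total or per-task AUC is not recoverable, and the total is the
quantity the deployment guarantee is stated in. An equal total promotes the
fresher model.

### Ensemble diagnosis

The BM model scores every image of a mass; the case-level malignancy score
is the **max** over per-image malignant probabilities (an
`aggregate="mean"` option exists). The max is consistent with the rule that
the highest-malignant-probability image — the most suspicious view — is the
one passed to the PT and PD models for the top-3 lists. The three outputs
are produced independently; a benign-scored case with a malignant top
disease is flagged `inconsistent`, never silently reconciled. Binary calls,
when needed, can use either a 0.5 threshold or the Youden operating point;
the evaluation itself is threshold-free (ROC) plus the Youden pair.

## The nine indices and the 100-point score

With `n1, n2, n3, n0` the counts of masses whose true type sits at rank
1, 2, 3 of the top-3 list or is absent, over `N` masses:

    DAPT  = 100·n1/N
    APTI  = 100·(3·n1 + 2·n2 + n3)/(3·N)
    MDRPT = 100·n0/N

and identically for DAPD/ADPD/MDRPD over the disease list. APTI's `3N`
denominator normalises the 3/2/1/0 rank points so a perfect reader scores
100; this normalisation, and the `(100−value)/10` treatment of the two
missed-rates in the total, are reconstructions locked by regression tests
against the bundled reference score tables (every printed component equals
`value/10`, `(100−value)/10` or `20·AUC` to the printed precision; one
reference row prints a specificity inconsistent with its own component score
and is tested against its printed components instead).

AUC is pairwise concordance (ties ½), computed via midranks —
identical to the Mann–Whitney statistic. The 95% CI uses DeLong's
structural-component variance, hand-implemented and verified against R
`pROC::ci.auc(method="delong")` to 9 decimals on a frozen instance; a
degenerate variance (perfect separation) collapses the CI onto the AUC. The
Youden operating point scans every distinct score as a `>=` threshold plus
the all-negative rule; ties prefer higher sensitivity, then the higher
threshold. Readers who give binary calls instead of probabilities get the
same code path; their "ROC" is the two-point curve, so their AUC behaves
like balanced accuracy.

Ranking sorts totals descending; equal totals take consecutive ranks in name
order. The experience correlation is the plain product-moment r, reported to
2 decimals.

## The synthetic cohort generator

The generator exists so every stage of the pipeline is exercised end to end
with known ground truth. It emulates the *shape* of a breast-mass stream,
not sonographic physics:

* **Cohort shape.** Defaults: 73% benign, ~12% bilateral cases, 1–8 images
  per mass, disease frequencies matching a realistic clinic mix (adenosis
  and fibroadenoma dominate benign; invasive ductal carcinoma dominates
  malignant). Case ids are generation-ordered and double as examination
  order for staging.
* **Image model.** A 4-parameter lesion phantom: an ellipse with aspect
  ratio (benign wide, malignant tall), radial boundary noise (malignant
  irregular), interior echogenicity (benign bright 120–200, malignant dark
  50–130, spread per disease so the fine-grained tasks are learnable) and a
  posterior shadow column, in speckle background. Per-mass jitter
  (echogenicity sd 45, shape and shadow noise) models biological
  variability; per-image gain/offset jitter (sd 0.18 / 18 gray levels)
  models operator-dependent scanner settings. Together these make the
  malignancy task land in a realistic AUC regime (~0.85–0.98 across stages)
  instead of being trivially separable — without class overlap, checkpoint
  selection has nothing to select.
* **Readers.** A single `skill ∈ [0,1]` knob: the malignancy call is correct
  with probability `0.5 + 0.5·skill`; the true type/disease lands at rank 1
  with probability `skill`, rank 2 with `(1−skill)/2`, rank 3 with
  `(1−skill)/4`, and is absent with `(1−skill)/4`, so missed-rate indices
  are exercised at every skill level and a skill-1 reader scores exactly
  100.00. Wrong answers are drawn preferentially (80%) from the truth's own
  malignancy class, which keeps the missed-rate indices realistic.

What passing tests on this generator shows: the orchestration, selection,
promotion and scoring logic behave as specified under a learnable,
class-imbalanced, staged stream. What it does not show: performance on real
ultrasound — the phantom has none of the anatomy, artifacts or label noise
of clinical images, and absolute index values on it do not transfer.

## The bundled reference experiment

The default study (`StudyConfig()`): ~300 synthetic cases, 64×64 phantoms,
20% held out as the frozen internal pool (which also supplies the ~80+80
image selection test sets), six chronological stages cut to even out the
malignant image load, trigger 30, 20 rounds per stage, warm start on. Ten
seeds run in under two minutes on one CPU; the problem sizes were chosen so
the full suite stays interactive while the staged effects (accumulation,
promotion, OM-vs-NOM) are measurable. Across seeds the average OM total
exceeds the average NOM total in most runs (the per-seed probability is
roughly 0.8–0.9; the mean OM−NOM gap is robustly positive at ≈ +1 to +2.5
points) and the deployed score is non-decreasing in every run.

## Numerical choices and degenerate inputs

* All randomness flows from explicit integer seeds (`numpy` Generators);
  replaying a config + seed reproduces reports byte-identically.
* Probability rows from any backbone must sum to 1; binary heads are
  represented as a single coefficient row expanded by softmax.
* An uninformative selection head (constant scores) is assigned AUC 0.5
  rather than raising inside the selection loop.
* Scorecard components are computed unrounded and rounded only for display
  (2 decimals; percent indices print at 1 decimal).
* Single-class evaluation sets, empty top-3 lists, zero-variance correlation
  inputs, sub-16-pixel renders and unreadable images all raise typed errors
  early rather than propagating NaNs.

## Known limitations

* The pathological-type grouping in the bundled taxonomy is a working
  grouping of common breast pathologies, not an authoritative ontology;
  sites should supply their own config.
* Image-level splitting (the default, matching the modeled system) leaks
  mass identity between train and validation; validation metrics are
  optimistic. The frozen test sets are case-held-out, so selection and
  promotion are unaffected.
* The linear backbone cannot represent texture beyond raw pixels; it is a
  vehicle for the orchestration logic, not a competitive image classifier.
* Reader simulation treats each mass independently; real readers drift,
  fatigue and correlate errors across similar cases.
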