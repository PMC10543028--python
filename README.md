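# slide2rx

Predicting a cancer patient's response to targeted therapy usually requires
tumor sequencing, which is slow and expensive. `slide2rx` implements an
indirect, two-step alternative that needs only a routine H&E-stained slide:

1. **Impute bulk expression from the slide.** Tissue tiles (512×512 px at
   20×, Sobel-gradient filtered, colour-normalized, resized to 224×224) are
   embedded as 2,048-d feature vectors, compressed to 512-d by an
   autoencoder, and mapped to genome-wide expression by multi-task MLPs —
   one per *tranche* of 4,096 genes with similar median expression, with a
   shared 512-node hidden layer. Tile predictions are averaged to slides and
   patients; evaluation uses patient-level 5×5 nested cross-validation
   (25 member models).

2. **Score drug match from the imputed expression.** For a drug with known
   synthetic-lethal (SL) and synthetic-rescue (SR) partner genes, the
   matching score is the fraction of favourable partner states over
   cohort-rank-normalized expression,

   EMS = [#{SL: rank ≤ 1/3} + #{SR: rank < 2/3}] / (#SL + #SR present),

   and a patient is *matched* when EMS ≥ 0.54 (a fixed, pre-established
   threshold). No response labels are needed for training, so the approach
   extends to any drug with a partner network.

The package is aimed at computational-pathology and precision-oncology
researchers who want a tested, fully seeded reference implementation of this
pipeline — including its evaluation statistics (per-gene Holm–Šídák
significance, hallmark enrichment, signature/survival association, odds
ratio with Woolf CI, Fisher exact, average precision, coverage curves,
permutation tests) and a synthetic-cohort generator so every stage runs
without downloads. See `docs/methods.md` for the model details and design
choices.

## Worked example

The clinical headline of this approach is an aggregate "basket" analysis of
234 patients (78 responders) across five cohorts and four drugs. From the
published summary statistics alone, the underlying 2×2 table is uniquely
recoverable by exhaustive enumeration:

```bash
$ slide2rx reconstruct-table --n 234 --responders 78 \
      --constraints '{"or": 2.44, "precision_pct": 47.8}'
1 table(s); unique: True
(a,b,c,d)=(33,36,45,120)  OR=2.444 CI=[1.36,4.38]  precision=47.8%  ORR=33.3%  increase=43.5%  Fisher p=0.003659
```

Reading: of 69 EMS-matched patients, 33 responded (precision 47.8%) versus
an overall response rate of 33.3% — a 43.5% relative gain — and the odds of
response among matched patients are 2.44× those of unmatched patients, with
a Woolf 95% CI of [1.36, 4.38] excluding 1.

A fully synthetic end-to-end run (generate → tile → feature → impute →
score → evaluate) on a 300-patient cohort:

```python
import pandas as pd
from slide2rx import *
from slide2rx.ems import score_cohort

spec = SyntheticCohortSpec(n_patients=300, slide_dims=(128, 128),
                           tile_edge=128, blank_border=False,
                           n_genes=120, n_driven_genes=40, seed=5)
cohort = generate_cohort(spec)
network = generate_gi_network(cohort, n_sl=10, n_sr=5, seed=5)
labels = generate_response(cohort.truth["true_ems"], slope=4.0, intercept=-2.0, seed=5)

dataset = cohort_to_dataset(cohort)
cfg = TrainingConfig(learning_rate=3e-3, max_epochs=40, patience=8, seed=5)
ae_cfg = TrainingConfig(learning_rate=1e-3, max_epochs=10, patience=3, seed=5)
imputed = crossfit_impute(dataset, cfg, ae_config=ae_cfg, n_folds=2, seed=5)

ems = pd.Series({r.patient_id: r.ems for r in score_cohort(imputed.T, network)})
report = evaluate_response(ems, labels, threshold=0.54)
print(round(report["odds_ratio"], 2), round(report["precision"], 3), round(report["orr"], 3))
```

prints `5.83 0.753 0.47`: patients called matched from *imputed* expression
respond at 75% versus a 47% cohort-wide rate, an odds ratio of 5.8 — the
planted image→expression→response signal survives the whole pipeline.

## Command line

`slide2rx simulate | tile | prep-expr | ems | eval-expr | eval-response |
reconstruct-table` — thin wrappers over the library; run any subcommand with
`--help`. Training and nested cross-validation are driven through the
library API (`make_fold_plan`, `nested_cv_train`, `ensemble_predict`,
`crossfit_impute`, `loocv_direct`).

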