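# ppglucose

Non-invasive blood-glucose estimation from single-channel in-ear
photoplethysmography (PPG), implemented as a tested, reusable pipeline:

1. **Synthetic cohort generation** — glucose trajectories (fasting +
   postprandial, four diabetic phenotypes), glucometer readings and
   glucose-modulated PPG recordings. Cycle amplitude falls and pulse width
   grows with glucose; recordings carry baseline wander, sensor noise and
   motion-corrupted cycles. Fully seeded.
2. **Pre-processing** — zero-phase Butterworth filtering (DC: order 10,
   0.01 Hz low-pass; AC: order 8, 0.3–10 Hz band-pass), linear-interpolation
   upsampling, lower-envelope (cubic-spline) baseline removal, peak/trough
   detection.
3. **Cycle processing** — trough-to-trough segmentation around each
   systolic peak, matched-filter quality control against the mean of the
   middle ten cycles (cycles with r < 0.90 rejected), and 18 features per
   valid cycle (timing, amplitude, widths, area, optical density, and
   Teager–Kaiser energy statistics).
4. **High/low-glucose statistics** — split at the subject's mean fasting
   glucose, pointwise Welch t-tests on ensemble cycles, per-feature
   percentage-difference ranking.
5. **Modelling** — per-subject day-wise split (days 1–7 train, 8–9 test),
   seeded randomized hyperparameter search over bagged trees and
   least-squares gradient boosting (5-fold CV grouped by recording),
   per-cycle prediction and per-recording aggregation.
6. **Clinical evaluation** — Clarke error grid (canonical 1987 region
   inequalities), RMSE, MARD, Pearson r, least-squares regression report
   with 95% CIs, and glucometer tolerance-band compliance.

## Quick start (library)

```python
import ppglucose as pg

result = pg.run_pipeline(pg.PipelineConfig(seed=0))
for subject, res in result.subjects.items():
    print(subject, res.report.as_dict())
```

## Command line

```bash
# generate a synthetic cohort on disk (DSV traces + metadata + manifest)
ppglucose simulate --out cohort/ --seed 0

# per-cycle feature extraction + QC tables for an on-disk cohort
ppglucose features --cohort cohort/ --out features/

# full pipeline (simulates the default cohort when --cohort is omitted)
ppglucose run-all --out results/ --seed 0 --dump-intermediate

# show all tunables (filter orders/cutoffs, r_min, split days, ...)
ppglucose config show
```

Configuration is a flat YAML file mirroring `PipelineConfig`; defaults
reproduce the published analysis parameters (low-pass order 10 at 0.01 Hz,
band-pass order 8 at 0.3–10 Hz, r_min 0.90, 5 CV folds, train days 1–7).

## Tests

```bash
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests, and
`tests/test_acceptance.py` with one test (group) per acceptance criterion.
The two end-to-end criteria share one session-scoped run of the default
four-subject cohort (~10 minutes on one CPU); the rest of the suite runs
in a few minutes.

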