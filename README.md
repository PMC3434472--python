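# cresstex

Texture evaluation of CuCl₂ biocrystallograms from a blinded cress-seedling
bioassay — with a seeded synthetic-study generator so the entire pipeline is
testable without laboratory images.

## The scientific problem

In the biocrystallisation assay, a cress-seedling extract is mixed with
copper-chloride solution and left to crystallise on a glass plate.  The
resulting dendritic pattern (the *biocrystallogram*) is sensitive to the
biological state of the extract, and the assay asks whether two
indistinguishable-by-chemistry preparations — a homeopathic *Stannum
metallicum* 30x ("verum") and an identically processed water 30x ("control")
applied to the seedlings — leave systematically different crystallisation
textures.

Because any effect would be subtle, the experimental design carries the
weight: two laboratories, repeated experimental days, both preparations in
triplicate ("internal replicates"), six plate replicates per extract,
randomized coded labels (blinding) with a separate code holder, reference
plates, and discard rules.  Evaluation is computerised texture analysis:
plates are scanned at 256 grey levels, Gaussian-normalised, divided into
concentric annular regions of interest (0–50, 50–70, 70–90, 90–100 % of the
plate radius), and each region is summarised by 15 second-order texture
variables of the grey-level co-occurrence matrix (GLCM).  The statistics
layer runs full factorial ANOVA F-tests (day × treatment × internal
replicate, all interactions), Holm multiple-testing correction over the
whole table, variable-correlation grouping, evaporation-time correlations,
and a processing-order (batch-drift) diagnostic with linear detrending.

This package implements that pipeline end to end:

| module | contents |
| --- | --- |
| `cresstex.design` | crossed blinded design, coding/decoding, discards, potency arithmetic |
| `cresstex.synthesis` | seeded synthetic crystallogram renderer, evaporation times, seedling weights |
| `cresstex.imageprep` | grey conversion, Gaussian normalisation, centre detection, annular ROI masks |
| `cresstex.texture` | masked symmetric GLCMs and the 15 second-order variables |
| `cresstex.evaluation` | factorial ANOVA, t/LSD, Holm, grouping, order diagnostic and correction |
| `cresstex.pipeline` / `cresstex.cli` | generate → analyze → decode orchestration and the `cresstex` command |
| `cresstex.calibration` | simulation experiments: type-I error, effect recovery, order power, grouping |

No laboratory images from the original assay are publicly available, so the
synthetic generator plays the role of nature: it renders stylised dendritic
plates carrying the statistical structure the analysis is built to detect
(day effects, a two-component treatment signal, evaporation-linked
roughness, processing-order drift, peripheral crystallisations at long
evaporation times), and every downstream claim is validated against that
known ground truth.

## Worked example

Generate a six-day two-lab study (2 plate replicates, reduced 128-px
geometry, injected treatment effect 0.4), extract features while still
blinded, then decode.  `config.yaml` overrides a handful of the
`RunConfig` defaults:

```yaml
days_per_lab: [3, 3]
n_plate_reps: 2
n_reference: 2
geometry: {size: 128, plate_diameter_px: 116}
effects: {treatment_effect: 0.4, day_by_treatment_sd: 0.2}
cooc: {levels: 64}
seed: 42
```

```
$ cresstex generate --config config.yaml --out study
study written to study
$ cresstex analyze --config config.yaml --study study
report written to study/report
$ cresstex decode --report study/report --key study/coding_key.json
decoded report at study/report
```

The analyze stage is blinded: `study/metadata.csv` and
`report/features.csv` carry only the coded labels "1"–"6"; truth labels
appear nowhere on disk until `decode` is run with the code holder's key
(and a tampered or missing key is refused).

Evaporation times reproduce the two labs' operating ranges
(`report/evaporation_by_day.csv`):

```
 lab  day  mean  std  count
BRAD    4 19.54 0.14     12
BRAD    5 17.42 0.13     12
BRAD    6 17.71 0.21     12
 LBI    1 14.03 0.15     12
 LBI    2 13.75 0.19     12
 LBI    3 14.81 0.14     12
```

The decoded per-ROI ANOVA (`report/anova_by_roi.csv`) localises the two
components of the injected treatment signal — the centre-zone asymmetry
picked up by `diagonal_moment`/`cluster_shade` in the inner regions, and
the contrast gain picked up by the roughness variables in the annuli:

```
                 treatment 0-50%  treatment 50-70%  treatment 70-90%  treatment 90-100%
cluster_shade             0.1077            0.0553            0.9721             0.6241
diagonal_moment           0.0032            0.0187            0.1011             0.5543
inertia                   0.0000            0.0000            0.0000             0.0000
entropy                   0.0000            0.0000            0.0000             0.0000
```

(Whole-plate tests in `anova_main_effects.csv` are deliberately harder: the
global grey normalisation makes the full-disc statistics conservative, so
single small studies rarely reject there — the localised table and the
pooled calibration experiments below are where the signal lives.)

The same report directory also contains the Holm-corrected flags
(`holm_flags.csv`), the variable grouping with evaporation correlations
(`variable_groups.csv`, `variable_correlations.csv`) and the
processing-order diagnostic (`processing_order_p.csv`).

Everything is also available in memory:

```python
from cresstex import build_design, randomize_and_code, simulate_evaporation
from cresstex.pipeline import study_feature_table, texture_reports

d = build_design(days_per_lab=(3, 3), n_plate_reps=2, n_reference=0)
randomize_and_code(d, seed=42)
simulate_evaporation(d, seed=42)
feats = study_feature_table(d, seed=42)       # renders plates, one row per (plate, ROI)
reports = texture_reports(feats)              # table1/table2/holm/groups/order tables
```

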