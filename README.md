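# oligofish

Automated 1p/19q FISH polysomy calling and cohort statistics for
oligodendroglioma.

## The problem

Oligodendrogliomas (OGs) are IDH-mutant gliomas defined by whole-arm
1p/19q codeletion. A subset of codeleted tumours additionally carries
*polysomy* of the retained control arms — three or more copies of 1q
and/or 19p — which marks chromosomal instability and worse prognosis,
especially in grade-3 (O3) disease. Dual-colour FISH scores this
per nucleus: a red target probe (1p36, 19q13 or CDKN2A/9p21) against a
green control probe (1q25, 19p13 or CEP9), giving each nucleus an
"R/G" signature such as `1/2` (plain codeletion) or `2/4` (codeletion
with a control-arm gain).

`oligofish` implements the full interpretation pipeline for
neuropathology/cytogenetics labs and methods researchers:

- **Per-cell classification.** Each nucleus is binned by its exact
  rational ratio R/G: deletion (R/G < 0.75), instability
  (0.75 ≤ R/G < 1), normal (R/G = 1) or polysomy-without-deletion
  (R/G > 1); G = 0 is uninterpretable. Deleted nuclei with G ≥ 3 fall
  into four categories — homozygous (R/G = 0), hemizygous
  (R/G < 0.5), polyploid pattern (R/G = 0.5, excluding `1/2`) and
  instability pattern (0.5 < R/G < 0.75).
- **Sample-level calling.** Deletion when ≥ 55% of interpretable
  nuclei are deleted; polysomy when ≥ 30% show G ≥ 3; CDKN2A
  hemizygous/homozygous deletion at 40%/30% with a mean + 3 SD
  calibration on non-neoplastic controls. Two-assay combination gives
  the codeletion status, the polysomy subgroup (1p and 19q / 1p alone /
  19q alone) and a ploidy extrapolation (identical `2/4` patterns on
  both chromosomes → tetraploid, `3/6` → hexaploid, `1/2` on one with a
  gain on the other → polysomic).
- **Signature profiling.** Empirical R/G signature, band and category
  distributions per sample and per cohort, including the seven
  predominant polysomy signatures `0/3, 0/4, 1/3, 1/4, 2/5, 2/4, 2/3`.
- **Concordance.** An emulated 100-nucleus manual rater against the
  full automated counts, with Cohen's κ = (p_o − p_e)/(1 − p_e) and
  percent agreement on the binary polysomy calls.
- **Cohort statistics.** Pearson chi-square associations, Kaplan–Meier
  curves with median survival and 1/5/10/15/20-year horizons, log-rank
  tests, and univariate/multivariate Cox proportional-hazards models
  (multivariate entry for covariates with univariate log-rank p < 0.05).
- **Synthetic cohorts.** A generator that emulates FFPE FISH data —
  latent tumour states per nucleus, truncation/split/background noise,
  clinical covariates and Weibull proportional-hazards survival — so
  the entire pipeline is testable end to end without patient data.
- **Image simulation.** A small two-channel renderer plus spot detector
  standing in for the acquisition platform, with exact round-trip
  recovery on clean fields.

## Worked example

Simulate a 35-patient cohort, run the full pipeline and read the report:

```python
import json
from oligofish import io_formats
from oligofish.pipeline import PipelineConfig, run_pipeline
from oligofish.synthetic_cohort import SimulationConfig, simulate_cohort

cfg = SimulationConfig(n_samples_per_grade={"O2": 20, "O3": 15}, seed=1)
cells, records, truth = simulate_cohort(cfg)
io_formats.write_cell_table(cells, "cells.tsv")
io_formats.write_patient_table(records, "patients.csv")

report = run_pipeline(PipelineConfig(
    cells_path="cells.tsv", patients_path="patients.csv",
    out_dir="results", seed=1,
))
print(json.dumps(report["calls"]["P001"]["CHR1"]))
```

prints

```json
{"sample_id": "P001", "assay": "CHR1", "n_cells_total": 1333,
 "n_cells_interpretable": 1327, "fraction_deleted": 0.818,
 "fraction_control_polysomy": 0.209,
 "deletion_called": true, "polysomy_called": false}
```

P001 is codeleted (82% of its 1327 interpretable nuclei deleted, above
the 55% cut-off) but not polysomic (21% of nuclei with G ≥ 3, below
30%). Across the cohort, 16 of 35 samples are called polysomic —
matching the generating truth exactly — the emulated 100-cell manual
rater agrees with the automated call on every sample (κ = 1.0), and the
survival block shows the polysomy effect the generator planted: median
overall survival 82 months in called-polysomic patients versus
not-reached in the rest (log-rank p = 0.010).

The same pipeline is available from the shell:

```bash
oligofish simulate --seed 1 --out-dir demo/
oligofish report demo/cells.tsv --patients demo/patients.csv --out-dir demo/results
oligofish concord demo/cells.tsv --manual-n 100
```

## Layout

| module | contents |
| --- | --- |
| `oligofish.io_formats` | typed records; cells.tsv / patients.csv / report.json I/O |
| `oligofish.cell_classifier` | per-nucleus band, polysomy flag, category |
| `oligofish.sample_caller` | cut-off calls, CDKN2A, assay combination, ploidy |
| `oligofish.signature_profile` | R/G signature distributions and cohort summaries |
| `oligofish.concordance` | manual-rater emulation, Cohen's κ, percent agreement |
| `oligofish.cohort_stats` | chi-square, Kaplan–Meier, log-rank, Cox |
| `oligofish.synthetic_cohort` | FFPE FISH cohort generator with survival model |
| `oligofish.fish_image_sim` | two-channel field rendering and spot detection |
| `oligofish.pipeline`, `oligofish.cli` | orchestration and the `oligofish` CLI |

See `docs/methods.md` for the model details, parameter defaults and
known limitations.
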