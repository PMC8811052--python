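# lungfate

Longitudinal fate analysis of disseminated tumor cells (DTCs) in the lung,
built around serial imaging through an implantable lung window, plus the
spatial statistics that connect DTC phenotype back to TMEM doorways in the
primary tumor.

## The problem

When tumor cells reach the lung vasculature, three questions decide whether
they can seed metastases: are they **retained** in the lung or cleared back
into circulation; do they **extravasate** across the endothelium into the
parenchyma; and once extravasated, do they **die**, **survive as dormant
single cells**, or **grow** into micrometastases?  With a lung imaging
window the same microvascular field can be re-imaged every 8 hours, so each
cell's fate is observed on a session grid: events are known only up to the
8-h interval in which they happened (interval censoring).

In the primary tumor, the complementary question is spatial: are
marker-positive tumor cells (e.g. dormancy marker NR2F1, or NR2F1+/MenaINV+
double positives) enriched near **TMEM doorways** — the tumor
cell/macrophage/endothelial-cell triplets through which cells intravasate —
relative to the bulk nuclei population?

`lungfate` implements the full computational side of this workflow as a
tested, seedable pipeline, together with a synthetic-data generator so every
stage can be exercised and validated without in-vivo imaging data:

* **`lungfate.synthetic`** — ground-truthed generators: longitudinal
  lung-window cohorts driven by a discrete-time fate chain, primary-tumor
  point patterns with distance-dependent marker positivity, rendered
  fluorescence fields and negative controls, and migration time-lapses.
* **`lungfate.registration`** — phase-correlation translation registration:
  relocating the same field across sessions, drift removal within
  time-lapse stacks, and temporal-median suppression of flowing-erythrocyte
  signal.
* **`lungfate.detection`** — segmentation (threshold + watershed),
  negative-control and top-fraction marker thresholding, macrophage
  counting with the >19 um² area filter, per-nucleus intensity profiles,
  and metastatic-foci (>5 cells) counting.
* **`lungfate.tracking`** — mutual-nearest-neighbour linking across
  sessions, intravascular/extravascular compartment calls by vessel-mask
  overlap, and the fate rule table (disappearance, death-by-debris, growth).
* **`lungfate.fatestats`** — Kaplan–Meier retention curves with log-rank
  comparison, extravasation kinetics (interval midpoint convention),
  outcome fractions, motility projections, and normality-screened group
  tests (t / Mann–Whitney, ANOVA+Sidak / Kruskal–Wallis+Dunn).
* **`lungfate.spatial`** — landmark affine alignment of serial sections and
  the reference-normalized nearest-structure distance statistic (doorways,
  TMEM-free vessels, macrophages) with permutation nulls.
* **`lungfate.pipeline` / `lungfate` CLI** — config-driven orchestration
  with end-to-end determinism.

## The statistics at the core

**Retention.** Each cell contributes a time-to-event observation measured
from its own arrival; the event is disappearance from the field (or death),
censoring occurs at the end of follow-up or when a field cannot be
relocated.  Retention is the product-limit estimator
S(t) = prod over event times t_i <= t of (1 - d_i / n_i) on the 8-h grid,
with groups compared by the log-rank (Mantel–Cox) test.

**Extravasation timing.** An extravasation observed first at session k+1
happened in interval (8k, 8(k+1)] and is assigned the midpoint 8k + 4 h;
the per-cohort summary is the percentage extravasated by 64 h and the
mean ± SEM of the midpoint times.

**Fold enrichment.** For query cells (marker-positive) and reference nuclei,
distances to the nearest dilated doorway ROI (dilation 60 um; inside = 0)
are binned on [0, 200] um in 40-um bins.  Each bin's query relative
frequency is divided by the reference relative frequency, and the headline
scalar is

    fold = [f_q(0-80) / f_r(0-80)] / [f_q(160-200) / f_r(160-200)]

which is ~1 under no association.  Group-level estimates average the
normalized frequencies across replicate tissues before taking the ratio;
uncertainty comes from a marker-label permutation null.

**Synthetic fate chain.** Cohorts are generated by a first-order Markov
chain over 8-h intervals with hazards indexed by time since arrival:
intravascular cells disappear (p_dis[k]) or extravasate (p_ext[k]);
extravasated cells die (p_die[k]) or begin growth (p_grow[k]).  Closed-form
endpoint probabilities (`markov_endpoints`) make the generator its own
oracle, and shipped calibration profiles (`profiles.sm_fate_params`,
`profiles.em_fate_params`) reproduce the characteristic endpoint patterns
of spontaneous vs experimental metastasis models.

## Worked example

```python
from lungfate.profiles import sm_fate_params, default_geometry
from lungfate.synthetic import simulate_cohort, markov_endpoints
from lungfate.evaluate import analyze_cohort
from lungfate.fatestats import summarize_group

params = sm_fate_params()                      # spontaneous-metastasis profile
cohort = simulate_cohort(params, default_geometry(), seed=42)
tracks = analyze_cohort(cohort)                # link + fate-classify detections
summary = summarize_group(tracks, "SM")

print(f"cells tracked:        {summary.n_tracks}")
print(f"retained at 64 h:     {100 * summary.km_curve['survival'].iloc[-1]:.1f}%")
print(f"extravasated by 64 h: {summary.pct_extravasated:.1f}%")
print(f"mean time to extravasation: {summary.mean_extravasation_time_h:.1f} "
      f"+/- {summary.sem_extravasation_time_h:.1f} h")
```

prints

```
cells tracked:        69
retained at 64 h:     73.9%
extravasated by 64 h: 65.2%
mean time to extravasation: 12.2 +/- 1.4 h
```

One simulated animal yields ~70 analyzable cells; the pipeline's estimates
(73.9% retained, 65.2% extravasated, 12.2 h mean) recover the profile's
generative truth (70%, 64%, 11.6 h) within this cohort's sampling noise —
`lungfate.evaluate.recovery_benchmark` quantifies exactly this agreement
over many random hazard configurations.

The same run from the shell, as a two-arm study with a spatial stage:

```sh
lungfate run --seed 42 --outdir results/demo \
    --set groups.SM.n_animals=4 --set groups.EM.n_animals=4
```

writes per-animal detections, track tables, KM curves, enrichment
histograms and a `report.json` holding the per-group summaries, the
log-rank comparison, and the tissue fold-enrichment estimates.  Rerunning
the same command reproduces the report byte for byte.

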