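# Methods

This note documents the models behind `lungfate`, the choices made where
the design was genuinely open, and what the synthetic validation studies do
and do not demonstrate about real imaging data.

## Observation scheme

A lung-window experiment images the same microvascular field at 8-h
sessions.  A "Pre" session (at -8 h relative to the analysis origin)
identifies cells already present, whose arrival times are unknown; such
cells are excluded from all statistics.  Each cell is followed for a
64-h horizon measured from its own arrival session, so event times are
interval-censored on the session grid.  The package treats this grid as
primitive: no continuous-time imputation is performed anywhere except the
midpoint convention for extravasation times (below).

## The fate chain

Cohorts are simulated by a first-order Markov chain over observation
intervals, with hazards indexed by intervals since arrival:

| state | transition | hazard | default (SM / EM profile) |
|---|---|---|---|
| intravascular | disappeared (cleared/recirculated) | `p_disappear[k]` | 0.0708 / 0.3157 |
| intravascular | extravasated | `p_extravasate[k]` | ramp, see below |
| extravasated single | dead (debris) | `p_die[k]` | 0.0232 / 0.4372 |
| extravasated single | growing (micrometastasis) | `p_grow[k]` | 0.0054 / 0.1093 |

Disappeared, dead, and growing are absorbing.  Constraints
`p_disappear + p_extravasate <= 1` and `p_die + p_grow <= 1` are enforced
per interval.  Arrivals are Poisson per interval (`arrival_rate`); the EM
profile uses a single bolus arrival interval (tail-vein injection), the SM
profile spreads arrivals over the experiment with a few pre-existing cells.

`markov_endpoints` computes the exact endpoint distribution of this chain
by forward recursion; it is the oracle for every recovery study and the
target of calibration.  The shipped profiles were fit once, by least
squares on those closed-form endpoints, to the endpoint pattern
characteristic of each model (SM: ~70% retained at 64 h, 64% extravasated
with mean time ~11.6 h and ~half within the first interval, 84/13/3%
survived/died/grew; EM: ~5% retained, 16% extravasated with mean ~28 h and
none in the first interval, 10/72/18%).  The extravasation hazard is a
logistic ramp in k — decreasing for SM (fast crossers), increasing for EM —
because a single constant hazard cannot produce both the late EM mean time
and the heavy EM clearance.  The profiles are calibration inputs for
synthetic scenarios, not measurements.

Geometry: cells arrest on vessel centerlines (persistent-random-walk
capillary layouts, dilated to a configurable area fraction, default 15%),
at least 30 um apart.  On extravasation a cell steps just past the vessel
wall — one cell radius clear of the lumen — which keeps its ground-truth
compartment unambiguous while keeping the inter-session displacement
(~16-18 um) below the 20-um linking gate.  Death is rendered as 2-3 debris
objects (each ~20 um², below the 50-um² debris ceiling and the 19-um²
macrophage filter); growth as an area increase to 2.5x the single-cell
area, safely above the 2x growth threshold and the ~5% session-to-session
area noise.

Censoring: a cell whose observations simply stop is observationally
identical to a disappearance, so per-cell censoring cannot be inferred from
the detections alone.  In the experiment, losses to follow-up are *known*
(a session's field could not be relocated; the experiment ended), so the
simulator emits a censoring log (cell, time, last position) alongside the
detections, and the tracker censors tracks whose end matches a log entry.
The default profiles use `censor_prob = 0`; relocation failure is the
mechanism that produces censoring in image-space runs.

## Tracking and fate rules

Linking is greedy mutual-nearest-neighbour between consecutive sessions
within a 20-um gate — appropriate because observed DTCs are nearly
immobile (projected to need >> 64 h to cross a 256-um half-field), so
inter-session displacement is dominated by registration jitter and the
extravasation step.  Debris-sized objects (< 50 um²) neither seed nor
extend tracks.  Tracks seeded within the gate of a Pre-session detection
are discarded.

Compartment: overlap fraction of the cell footprint with the vessel mask;
>= 0.5 intravascular, exactly 0 extravasated, otherwise "uncertain" and
excluded from extravasation statistics rather than forced to a call.

Absence rule table, applied when a track ends before its horizon:

* intravascular, no debris -> **disappeared** (event);
* extravascular, >= 2 sub-cellular objects within the gate of the last
  position -> **died** (event);
* extravascular, no debris -> anomalous (extravasated cells cannot
  recirculate) -> censored.

Growth: any observed area > 2x the single-cell area (or a multi-cell
cluster).  The 2x threshold tolerates transient ~10% area fluctuations.

## Cohort statistics

Retention uses the product-limit estimator (lifelines) on the interval
grid, with the event timed at the first session the cell was absent, and
log-rank for two-group comparison.  Extravasation times use the interval
midpoint ((k + 0.5) * 8 h), which is unbiased if crossings are uniform
within an interval; means ± SEM are over extravasated cells, and
percentages are aggregated per animal first (mean ± SEM across animals) to
avoid pseudo-replication.  The denominator of "% extravasated" includes
cells that disappeared without extravasating.

Group comparisons follow a Shapiro–Wilk screen at alpha = 0.05: two groups
get a t-test when both pass, otherwise a two-tailed Mann–Whitney; more
groups get one-way ANOVA with Sidak-adjusted pairwise t-tests, otherwise
Kruskal–Wallis with Dunn's rank-based pairwise z-tests (Bonferroni-style
adjustment, tie-corrected; implemented in-package since no installed
library provides Dunn's procedure).  Groups with n < 3 skip the screen and
use the nonparametric branch.

## Tissue model and the enrichment statistic

Tissues are homogeneous Poisson nuclei (default 2000 / mm²) with uniformly
placed doorway ROIs (discs, default radius 5 um) and macrophages (uniform,
plus one at each doorway, since a doorway contains a macrophage).  Marker
positivity is Bernoulli with

    p(d) = b * (1 + (E - 1) * exp(-d / tau)),

where d is the *same* dilated-doorway distance the estimator measures
(d = max(0, distance to ROI - 60 um)), b is the far-field positive
fraction (default 0.10, the in-vitro baseline of NR2F1 positivity), E the
amplitude at the doorway, and tau = 40 um the decay length (matching the
bin width; chosen so enrichment is concentrated in the first one or two
bins as in observed curves).  Default field: 1.7 x 1.7 mm (within the
1–3 mm² ROI range used for this kind of section analysis) with 10 doorways
(~3.5 / mm²).

For recovery studies, E is solved per tissue in closed form so that the
realized-nuclei true near/far positivity ratio equals a requested target
exactly; the generative truth is then not subject to layout noise.

Distances: doorway distances are analytic (point-to-disc minus dilation,
floored at 0); mask distances (TMEM-free vessels) use exact
point-to-pixel-center KD-tree queries, so they agree with brute-force
all-pairs computation to machine precision.  Vessel components intersecting
a doorway ROI are deleted before the TMEM-free variant.

Binning: half-open 40-um bins on [0, 200) um; points at >= 200 um are
tallied in an overflow bin excluded from relative frequencies (the
within-range normalization; the near/far fold ratio is invariant to this
choice).  A reference-empty bin makes that bin's ratio undefined (NaN,
flagged); an empty far query window makes the per-tissue fold undefined —
reported as NaN with a warning, never silently 0 or infinity.

Two fold estimators are provided deliberately:

* `fold_enrichment` — the per-tissue ratio of combined-window normalized
  frequencies.  At realistic counts (~100 positive cells, of which ~10 fall
  in the far window) this ratio is noticeably biased upward (E[1/X]
  convexity, roughly +1/E[q_far]); it is kept as the per-tissue statistic
  and for the CSR calibration study, where full-size default tissues make
  the bias small.
* `combined_fold_enrichment` — the group estimator: normalized window
  frequencies are averaged across replicate tissues *before* the ratio,
  mirroring how replicate ROI curves are averaged and then read off.  Its
  denominator is a mean over ~80 far-window cells, so the residual bias is
  ~1-3%.  Recovery studies and pipeline reports use this estimator.

The permutation null redraws the marker-positive set as a uniform subset of
the nuclei (size fixed at the observed count) and recomputes the fold;
p = (1 + #{null >= observed}) / (1 + n_perm).  Under the null, p is
uniform up to the 1/(n_perm+1) discretization and rare exact ties (ties
count toward the null, making p conservative by construction).

No edge correction is applied to the distance histograms: the reference
normalization cancels most boundary effects, and the statistic is a ratio
of frequencies over the same field.  This is a known limitation for fields
whose doorways sit very close to a border.

## Registration

Translation-only (phase correlation, integer pixel): the fixtured window
constrains inter-session motion to x-y shifts, and downstream decisions are
mask overlaps at >= 1-um scale, so subpixel refinement adds nothing.
Match quality is the normalized cross-correlation after applying the shift,
clipped to [0, 1]; relocation picks the best-scoring candidate on the
vasculature channel and fails below `min_score = 0.5` (the downstream
pipeline then censors tracks at that session).  Flat images are a
degenerate-input error, not a zero-score match.  The blood-averaging step
is a per-pixel temporal median over >= 3 registered frames.

## Detection and thresholding

"Just above background" is fixed as the 99.9th percentile of
negative-control pixels: deterministic and robust to isolated hot pixels.
High-marker calibration takes the (1 - f) quantile of reference-cell mean
intensities (f = 0.05 by default) with *strict* inequality for positivity,
so ties default to negative and discreteness cannot push the positive
fraction above f; the resulting ThresholdSpec is reused unchanged on other
tissues.  Per-cell positivity uses the mean intensity above threshold; a
fraction-of-pixels-above-threshold variant would be a reasonable
alternative but is not implemented.

Watershed seeds are local maxima of the lightly smoothed distance
transform (sigma 1 px, min separation 4 px); the smoothing prevents
plateau artifacts in near-symmetric objects.  Macrophages are counted
after the watershed with a strict > 19 um² area filter.  Metastatic foci
are single-linkage clusters at a 30-um contact distance (a config knob)
with >= 6 cells (i.e. "more than 5"), normalized to tissue area.

## Validation studies: problem sizes and what they show

* KM oracle: 240+ enumerated fixtures of <= 10 cells, exact agreement with
  a textbook product-limit computation.
* Fate recovery: 20 random constant-hazard configurations, ~500 cells each
  on a 2-mm field, full detections -> tracks -> statistics path; each
  configuration's six endpoint estimates must fall in a joint 99% sampling
  region of the closed-form truth (Sidak-split exact binomial bands;
  normal band for the mean time), with >= 19/20 configurations passing.
* Spatial null: 200 default tissues at E = 1 (mean per-tissue fold within
  [0.95, 1.05]) and 100 permutation runs (KS uniformity of p).
* Enrichment recovery: targets 1.5 / 2.2 / 3.2 at ~2000 nuclei and ~100
  positive cells per tissue (b = 0.05, 1 mm², 6 doorways), 6 replicates of
  8 tissues; the replicate-mean combined estimate within 15% of truth.
* Registration: exact recovery of +/-50 px shifts, <= 1 px at SNR 3 over
  50 trials, relocation among 5 decoys >= 95%.
* Counting rules: exact on constructed fixtures.
* Determinism: the full two-group pipeline report is byte-identical across
  reruns of the same seed.

These studies validate the *pipeline logic* under the generator's
assumptions.  They do not capture real-data failure modes: breathing
deformation beyond x-y drift, photobleaching and illumination drift,
segmentation of touching or dim cells at realistic SNR, pathologist
variability in doorway annotation, or marker thresholds on non-Gaussian
backgrounds.  Passing them shows the analysis is correct and calibrated,
not that acquisition artifacts are handled.

## Known limitations

* The fate chain has no intravascular proliferation and no re-entry of
  disappeared cells; growth is absorbing.
* Hazards are indexed by time since arrival only (no frailty across cells
  or animals beyond Poisson arrivals).
* The tissue model places doorways uniformly, independent of the vessel
  layout used for the TMEM-free variant.
* Per-tissue fold enrichment is biased upward at small far-window counts;
  use the combined estimator for group summaries (both are reported).
* Relocation assumes the candidate set contains at most one true match and
  uses no stage coordinates.
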