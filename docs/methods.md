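# Methods

## Model and assumptions

The screen compares two annotated LC-MS/MS feature tables of the same
fermented medium: one filter-sterilized (0.22 µm; heat-labile compounds
intact) and one autoclaved (121 °C; heat-labile compounds degraded,
degradation products formed). The design has no replicates; the only
statistic is the ratio of within-table relative abundances, and all
conclusions are of the screening kind — candidate sets to be narrowed
further, not hypothesis tests.

Assumptions baked into the procedure:

* **Identity matching.** The two tables are annotated against the same
  spectral libraries, so the annotation name (case-folded, trimmed,
  whitespace-collapsed) is the cross-treatment key. No m/z–retention-time
  tolerance matching is attempted; distinct keys are never merged.
* **One abundance per compound.** When a compound appears several times
  within one table (both ion modes, several adducts), the largest-area
  record is retained — the conventional quantifier choice. Positive- and
  negative-mode compounds are pooled into a single table *before*
  normalization, because the screen needs a single Rf and Ra per compound
  and per-treatment totals are reported without a per-mode breakdown.
* **Unannotated features are excluded.** Rows with an empty name are
  rejected with a warning; the screen counts identified compounds only.

## Relative abundance and the stability ratio

With areas *a₁…a\_N* in one table, `RAᵢ = aᵢ/Σaⱼ × N` — the area over the
mean area. The statistic is dimensionless, sums to N, averages 1, and is
invariant under rescaling of all areas, which makes it comparable between
two tables of different size and total ion signal. Its cost is a
*composition effect*: RA is relative to the table it sits in, so removing
368 compounds' worth of heat-degraded mass and adding 1141 products shifts
every compound's ratio multiplicatively by
(mean area of autoclaved table)⁻¹ · (mean area of filter table)⁻¹-type
factors even when the compound's own area is unchanged. This is inherent
to the normalization, not a bug; the classification windows absorb a mild
shift, and the synthetic tests verify by an independent oracle that the
shift stays inside the window for the parameter sets they assert on.

Shared compounds get `ratio = Rf/Ra` and a strict-open-window call:
`low < ratio < high` → anti-aging candidate, `ratio > inhibitor` →
growth-inhibiting candidate, else unclassified. Defaults are
`(low, high, inhibitor) = (0.75, 1.5, 9)`. Two notes on the defaults:

* The inhibitor cutoff 9 is the operational rendering of "more than 90 %
  reduction of relative abundance". Taken literally a 90 % reduction is a
  ratio of 10; the stated operational cutoff 9 is implemented as given and
  exposed in config rather than silently "corrected".
* Boundary behaviour beyond the printed inequalities is unspecified, so
  the windows are implemented literally as open intervals: a ratio of
  exactly 0.75, 1.5 or 9 receives no call.

Compounds absent from one treatment never receive a ratio (no ratio = ∞
convention); disappearance is reported through the partition counts.

## Tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| anti_aging_low / high | 0.75 / 1.5 | ratio | heat-stable window |
| inhibitor_ratio | 9 | ratio | depletion cutoff |
| delimiter, name/area columns | tab, `name`/`area` | — | input dialect |
| n_stable / n_sensitive / n_degraded / n_products | 89 / 13 / 368 / 1141 | compounds | generator class sizes |
| area_log_mean / area_log_sd | ln 10⁶ / 0.6 | ln(detector units) | base-area log-normal |
| noise_log_sd | 0.05 | ln scale | multiplicative measurement noise per table |
| retention_min / max | 0.02 / 0.05 | fraction | area surviving autoclaving for sensitive compounds |
| detection_threshold | 0 | detector units | observed areas below it are dropped per table |

## The synthetic-data generator

The generator plants four compound classes — stable (both tables, same
underlying area), sensitive (autoclaved area × retention ∈ [0.02, 0.05],
i.e. 95–98 % destroyed), degraded (pre-autoclave only) and product
(post-autoclave only) — with log-normal base areas, independent
multiplicative log-normal noise per table, and a detection threshold. The
default class sizes mirror a real fermented-medium screen: 470 compounds
before autoclaving, 1243 after, 102 shared. All randomness descends from
one root seed through named sub-streams (separate streams per class and
per table), so enlarging one class never perturbs another class's areas or
noise — a property the tests assert.

Numerical/design choices:

* `area_log_sd = 0.6` (≈ 10-fold 95 % range). A moderate spread keeps the
  total-area normalization stable at the simulated compound counts so the
  between-table composition shift (log-SD ≈ 0.06 at the recovery preset)
  stays well inside the anti-aging window, which the recovery and
  noise-monotonicity properties require by design and the tests confirm
  by oracle. Real LC-MS areas are heavier-tailed (several orders of
  magnitude); with a heavy-tailed area distribution the mean-area ratio
  between tables is dominated by a few large compounds and can carry *all*
  stable compounds outside the window at once. That regime is a genuine
  feature of real data that the generator deliberately does not emulate —
  see limitations.
* `noise_log_sd = 0.05` (≈ 5 % CV): a typical well-behaved LC-MS peak-area
  repeatability figure.
* Retention 2–5 %: comfortably past the nine-fold depletion cutoff even
  after composition correction.
* Ties in dedup keep the first-read record; rendered tables and all
  outputs are sorted by compound key, so identical inputs give
  byte-identical outputs.

What passing synthetic tests do and do not show: they demonstrate the
pipeline computes the statistic, partition and windows correctly and
recovers planted classes under multiplicative noise and composition shift.
They do not demonstrate robustness to annotation error, adduct splitting
across treatments, retention-time drift, heavy-tailed abundance
distributions, or real biological scatter — on real data most shared
compounds may legitimately fall outside both windows (in the motivating
screen only 17 of 102 shared compounds were in the anti-aging window,
versus ~89 of 102 in the cleaner synthetic preset).

## Degenerate inputs and error handling

Empty tables, tables whose rows are all invalid, missing files and missing
required columns are hard errors naming the cause. Zero or negative areas
are rejected per row (never silently kept); a non-positive Rf or Ra inside
the classifier raises, since it can only mean a matching bug upstream.
Threshold configurations violating `0 < low < high ≤ inhibitor` are
rejected before any input is read. A failed CLI run leaves no partial
output directory (results are staged and moved on success).

## Problem sizes used in the checks

The test suite exercises random tables up to 30 compounds (1000 tables for
the normalization identities), random pairs up to 10 compounds against a
straight-line brute-force oracle (300 pairs), a 370-compound recovery
preset (100 stable / 20 sensitive / 50 degraded / 200 products) across 20
seeds × 4 noise levels, and one full-scale 1611-compound CLI run. These
sizes give stable statistics for every property asserted while keeping the
whole suite in the seconds range.

## Known limitations

* Identity matching inherits every flaw of upstream annotation: the same
  molecule annotated under different names in the two tables is counted as
  degraded + product rather than shared.
* The relative-abundance statistic is compositional; ratios shift with the
  table composition even for truly unchanged compounds. With the magnitude
  of compound turnover the screen targets (hundreds lost, a thousand
  gained) a mild window around 1 absorbs this only when no small set of
  compounds dominates total signal.
* No uncertainty is attached to any call (single-run design, no
  replicates); the windows are screening heuristics, not tests.
* The superclass summary treats the taxonomy label as an opaque string.
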