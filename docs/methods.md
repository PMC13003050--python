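# Methods

## The problem

Hospitals on busy streets receive traffic exhaust through infiltration
and natural ventilation, so nitrogen dioxide (NO₂) — the most
health-relevant nitrogen oxide — becomes an occupational hazard for
staff who spend most of a shift in one room. `no2risk` implements the
complete occupational risk-assessment workflow for such a setting: a
four-hospital, two-season indoor NO₂ campaign (hospitals classed by the
traffic congestion of their main street: heavy HTH, moderate MTH, low
LTH, and an on-sea road OSH), scored through a 3×3 risk matrix and
analysed with a conventional parametric battery. Because no per-sample
data are deposited anywhere, the package also contains a synthetic
campaign generator calibrated to the published per-cell summary
statistics, so every analysis runs end to end without external data.

## Risk matrix

Each sampled location gets two ordinal scores:

* **Likelihood L ∈ {1,2,3}** from the fraction of the work shift staff
  spend at the location: L=1 below 25%, L=2 from 25% to 75%
  (inclusive), L=3 above 75%. The sampling window (08:00–14:00, the
  morning shift) is taken as the denominator: the study design reports
  a 6-hour sampling shift and no separate shift length.
* **Severity S ∈ {1,2,3}** from the NO₂ concentration: S=1 below
  500 µg/m³ (minor effects), S=2 from 500 to 2000 µg/m³ inclusive
  (acute respiratory symptoms, reduced FEV₁), S=3 above 2000 µg/m³
  (bronchitis, reduced FVC/FEV₁).

The outer bands are strict inequalities, so each middle band is closed
on both ends and the bands partition their domains; the band edges and
category map are shipped as data (`data/no2_matrix.yaml`) and the
engine accepts any N×M profile with contiguous bands. The risk factor
is RF = L×S, reachable values {1,2,3,4,6,9}, categorized low (1–2,
green), moderate (3–4, yellow), high (6, bright red), very high (9,
deep red). "Medium" is accepted as an input alias of "moderate". RF is
monotone in each input, and the category is a function of RF alone.

Literature studies that report only a mean concentration are converted
to an RF pair by assuming the exposure time was either 25–75% of the
shift (L=2) or above 75% (L=3) — `external_study_rf`.

## Measurement model and QC

A measurement is one location-shift: hospital, traffic category,
season, location label, occupancy fraction, concentration (µg/m³) and
an optional staff count. Concentrations may instead arrive as raw
active-sampling records (collected mass µg, pump flow L/min, duration
min); the concentration is mass divided by the pumped volume
(flow × duration / 1000 m³). Flow rates outside the bubbler method's
0.2–1.0 L/min envelope are QC rejections. No desorption or
collection-efficiency factor is applied — the wet-chemistry constants
of the analytic method are instrument-specific and not part of this
package's scope; concentrations are treated as final.

CSV I/O is strict about the schema, reports invalid rows with their row
number and reason (JSON-lines QC report), and round-trips bit-exactly.

## Synthetic campaign generator

The published record of the campaign is, per (hospital, season) cell:
n ∈ {7, 9, 11}, mean, SD, min and max (76 measurements total: 22 HTH,
18 MTH, 14 OSH, 22 LTH). The generator models each cell as a
**truncated normal on [min, max]** — normality of the concentrations
was not rejected in the original campaign, and the printed extremes act
as hard bounds — with the *parent* parameters (µ, σ) solved numerically
(two-equation root find, 1e-6 relative tolerance) so the realized
moments of the truncated distribution match the printed mean and SD.
Naive truncation of an N(mean, SD) parent would bias the realized
moments; for the HTH hot cell the bias on the mean is about +5 µg/m³.

**Feasibility caveat.** For seven of the eight cells the printed sample
SD exceeds the largest SD any truncated normal can attain on the
printed [min, max] (the family's supremum approaches the uniform /
exponential-tilt limit; e.g. on [360, 370] no member reaches SD 5.0).
This is a property of small-sample statistics — a sample SD from n=9
routinely exceeds the population value — not of the implementation.
`calibrate_truncated_normal` therefore raises a `CalibrationError` for
such targets, and the generator falls back to the closest attainable
family member: the mean is matched exactly (always feasible, via a
monotone 1-D solve for µ at fixed σ) and σ is chosen to minimize the
gap to the printed SD. Replicate-averaged sample means are therefore
unbiased for every cell, while realized SDs sit at the interval's
supremum for the infeasible cells; the SD-recovery test is run only on
the jointly feasible HTH hot cell.

Seeding: one integer seed per campaign; each cell draws from an
independent substream derived from (seed, hospital, season), so row
order never affects the draws and a fixed seed reproduces the campaign
bit-exactly.

Occupancy is attached by label: continuous-care areas (clinics, patient
rooms, emergency rooms, ICUs, operation rooms) get 0.9 of the shift,
administrative/support areas (offices, pharmacies, laboratories) 0.5.

## Risk fixtures (reconstruction, not data)

The per-location risk tables of the original campaign were published
only as figure images; what is desk-checkable is the category shares
(high: 72.7% HTH hot, 63.6% HTH cold; moderate: 77.8% MTH, 57.1% OSH,
54.5% LTH, identical in both seasons) and the RF ranges (4–6 at HTH,
2–3 elsewhere). `build_risk_fixture` ships deterministic location
tables — concentrations evenly spaced across each cell's scoring band,
occupancy by the label rule above, with exactly the number of
continuous-care locations needed — that reproduce those shares exactly
when scored. The same tables are packaged as CSVs under
`data/fixtures/` (the suite asserts CSV == builder output). They are
labelled reconstructions throughout: the occupancy assignments are
constrained only by the published shares and ranges.

One internal inconsistency had to be resolved: the HTH cold sample
minimum is 490 µg/m³, which bands to severity 1 and cannot yield RF ≥ 4,
yet the reported HTH RF range is 4–6 in both seasons with a 63.6% high
share. The fixture uses concentrations in [500, 600] so both reported
results hold; the campaign generator, whose job is moment fidelity,
honours the printed minimum of 490.

## Statistical battery

* Per-cell summaries: arithmetic mean, sample SD (n−1), min, max.
* Kolmogorov–Smirnov normality per cell against a normal with the
  sample's own moments. With estimated parameters the classical KS
  p-value is conservative (a Lilliefors correction would be sharper);
  that suits its screening role here, and the caveat is documented.
* One-way ANOVA across hospitals (seasons pooled), then Fisher LSD
  pairwise comparisons using the ANOVA pooled mean-square error with
  N−k degrees of freedom, uncorrected by definition.
* Independent two-sample t-tests, Student's pooled-variance form by
  default (the published seasonal comparisons assume equal variances);
  Welch behind `equal_var=False`. A summary-statistics entry point
  allows testing published tables directly.
* Spearman rank correlation with average ranks for ties, two-sided p.
* α = 0.05 throughout, significance as p ≤ α; no multiple-testing
  correction anywhere, mirroring the original battery.

Congestion enters the correlations as an ordinal code HT=3, MT=2,
LT=1, OS=1 — the on-sea road carries low congestion despite its
seafront location. The coding is an assumption (no published ordinal
values exist) and can be overridden per call.

## Problem sizes and tolerances

Replicated checks use 1,000 campaigns for moment recovery (each cell's
replicate-averaged sample mean within 3 standard errors of its design
mean; every draw inside [min, max]), 500 campaigns for the
concentration-vs-congestion Spearman average, and 100 campaigns for the
replicate-majority battery checks; the unit suite uses 200 replicates
for the in-suite recovery checks. Calibration results are cached per
cell. Percentages are rounded half-away-from-zero to one decimal
(8/11 → 72.7, 7/9 → 77.8).

## Limitations

* The generator reproduces per-cell marginal distributions only: no
  within-day traffic dynamics, no room-to-room spatial structure, no
  outdoor/indoor coupling, no correlation between location label and
  concentration within a cell. Passing tests show the scoring and the
  battery behave correctly under the published summary conditions, not
  that they would reproduce unpublished raw data.
* Fixture occupancy fractions are reconstructions; the RF-vs-congestion
  correlation on fixtures is therefore checked qualitatively (strong,
  positive) rather than against the published coefficient.
* KS p-values with estimated parameters are approximate (conservative).
* No dose-response or health-effect modelling: severity band
  descriptions are carried as text only.
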