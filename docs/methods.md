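# Methods

## Model

The package operationalises a FMECA-style comparison between what a
preparation process *should* tolerate and what monitoring *finds*.

**Hazard groups.** Marketed AD products are assigned to eight groups by
predicates on catalog attributes: powdered form, liquid form, corrosive,
marketed in a single presentation, unstable (immediate-use only), no
external holder casing, high average therapeutic concentration, poorly
soluble. Membership is per product and overlapping: cyclophosphamide,
for instance, is simultaneously powdered, without holder casing, highly
concentrated and poorly soluble, and contributes monitoring records to
all four strata. The single-presentation predicate counts distinct
marketed vial strengths when they are known (the packaged catalog
carries them) and falls back to distinct mg/mL concentration values
otherwise — nominal concentration alone cannot discriminate the group,
since many multi-strength products reconstitute to one nominal
concentration.

**Catalog provenance.** The packaged catalog (29 products) transcribes
the drug-characteristics table of a four-hospital Italian FMECA study,
with group-defining flags seeded from the published group membership
lists where the free-text characteristics are ambiguous or conflicting
(e.g. vincristine's stability is listed as "no information" yet the
drug sits in the unstable group; the doxorubicin entry is the
immediate-use liposomal product). Three products appear in the
published group lists but not in the characteristics table; their rows
use standard formulary strengths and are supplementary. The corrosive
list's "TX" token is read as PTX (paclitaxel), consistent with the
companion monitoring table and the surrounding discussion of busulfan
and paclitaxel micro-spills. The published tables also disagree with
each other on the unstable-group membership; both lists are kept
verbatim in `adrisk.reference` (`GROUP_MEMBERS` vs
`ALT_UNSTABLE_MEMBERS`), and the catalog follows the ARL-side list.

**ARL.** An 8 × 2 × 5 matrix of ordinal scores (1–5), complete by
construction; the ARL of a (group, mode) cell is the column sum, hence
in [5, 25]. ARLs are always derived, never stored, so matrix and ARL
cannot disagree. The packaged default matrix is the consensus of the
study's multidisciplinary panel and reproduces all sixteen published
column sums exactly. Config overrides merge cell-wise over the
defaults so a unit can re-rate single failure modes.

**MRL.** Five band mappings turn a stratum's monitoring summary into
RPNs. The printed rubric has gaps and overlaps ("<3 %" then "4–6 %";
"6–8 %" then "8–10 %"; "50–99" then ">100"; "4–5" then ">6"); a scoring
function must be total, so bands are contiguous half-open intervals on
the printed edges, upper-edge-inclusive on the lower band. Two values
need an explicit convention: a count of exactly 6 detected ADs maps to
band 5 (the "≥6" reading — the 4–5 band excludes it), and a surface
spread of exactly 100 pg/cm² maps to band 5 (the "50–99" band excludes
it). Resolved band tables are echoed in every report for audit.

**Glove bands and AGVs.** Glove spread is binned against Alert Glove
Values: `<LOQ → 1`, `[LOQ, AGV90/10] → 2`, `(AGV90/10, AGV90] → 3`,
`(AGV90, AGV95/10] → 4`, `> AGV95/10 → 5` (so a value at the AGV 95th
percentile scores 5). The printed band order implies
`LOQ < AGV90/10 < AGV90 < AGV95/10 < AGV95`, which requires
`AGV95 > 10·AGV90`; configurations violating this are rejected at
validation rather than reordered — the rubric defines an order, not a
fallback. AGVs are per-drug config inputs with a global default; when
a stratum's glove spread aggregates several analytes, the AGV of the
analyte attaining the spread quantile is used (smallest positive load
at or above the interpolated quantile, ties broken lexicographically).
The packaged defaults (p90 = 10, p95 = 150, LOQ = 0.1 pg/cm²) are
synthetic placeholders, labelled non-authoritative: real alert values
must come from a laboratory's own reference glove-monitoring
distribution.

**Summaries.** Percentages are per-record: 100 × positives / records
per medium. "Spread" is not defined numerically in the source
framework; the package uses the 90th percentile (linear interpolation)
of positive-record loads, configurable to median/p90/p95/max — an
upper-level summary consistent with the percentile framing of the
glove alert values. Detected ADs are distinct analytes with ≥ 1
positive record in either medium. Start- and end-of-shift records are
pooled by default (a single RPN per stratum implies pooling); a
`shift_phase` argument stratifies. A stratum with no records raises an
explicit empty-stratum error and is reported as skipped; a stratum with
records but no positives scores all-minimum (MRL 5).

**Classification.** `Δ = MRL − ARL`; `Δ ≤ 0` under control (the strip
defines no band below equality, so better-than-acceptable is simply
under control), `+1` moderate, `+2` severe, `> +2` high.

## Published reference profiles

`adrisk.reference` packages the published sixteen-cell assessment
(component RPNs, printed MRLs, printed labels) as input data for
regression tests. Two published columns (corrosive/manual,
one-concentration/manual) print an MRL that is not the sum of their own
components (15 vs 13, 18 vs 16), and five cells print "moderate" where
the strip rule applied to the printed MRL/ARL yields "under control".
Both kinds of inconsistency are surfaced by
`component_sum_discrepancies()` and `label_discrepancies()`; the
implementation follows the arithmetic and the strip rule, and flags the
divergent cells rather than guessing intent.

## Synthetic campaigns

Each wipe or glove sample is assayed for every analyte on the campaign
panel, as a multi-analyte LC-MS/MS method would; each (sample, analyte)
result is positive with probability `detection_prob` and positive loads
are lognormal(`log_mean`, `log_sd`) on the natural-log scale,
left-censored at the LOQ. Loads are drawn for every flagged result
regardless of the LOQ, so raising the LOQ only censors more records —
it never reshuffles the stream, which makes censoring-monotonicity
properties exactly testable. Detection probability and log-mean accept
per-medium values because surfaces and gloves are binned separately.
Records alternate start/end shift phases and cycle over a small fixed
set of locations and hospitals; an optional per-location lognormal
random effect exists (`location_sd`, default 0: per-record
independence, the simplest model that exercises the rubric).

Generic defaults emulate a moderately contaminated unit: detection
probability 0.2 per analyte-record, load median ≈ 20 pg/cm² with
geometric standard deviation e ≈ 2.7, LOQ 0.1 pg/cm².

**Rubric inversion.** `spec_for_target_rpns` maps a five-RPN target to
a spec: the count target fixes the number of active analytes (1, 2, 3,
4, 6 — a top-band count needs a panel of at least six); percentage
targets set the detection probability to the band midpoint (open top
bands span `lo..1.5·lo`, capped at 100 %); spread targets set the
log-mean so the spread quantile sits at the geometric band midpoint,
`μ = ln(mid) − z₀.₉·σ` with a deliberately tight σ = 0.3 so the realised
quantile stays inside the band. A below-LOQ glove-spread target is
only satisfiable together with a bottom-band glove percentage (a
positive glove implies a quantifiable load) and is otherwise rejected;
the all-ones target is generated with zero detection. Default campaign
size for targeting is 1000 samples per medium; the recovery tests run
at 500. With those sizes the binding uncertainty is the binomial width
of the percentage estimators against the 3-point-wide middle bands,
and band-interior targets are recovered with frequency well above 0.9
per parameter and band.

## Problem sizes in the test and acceptance runs

Golden reproductions of the published tables are exact and instant.
The stochastic checks use: recovery sweeps over all five parameters ×
five bands at 500 samples per medium (25–100 seeded replicates per
band, more for the percentage parameters whose bands are narrowest),
and a 200-replicate Monte-Carlo of the powder/manual target profile at
1000 samples per medium, which must reproduce MRL 20 and the *high*
classification in ≥ 95 % of replicates (observed: 99–100 % across
seeds).

## Known limitations

* The single-score RPN is taken as given data; the package does not
  model how severity, frequency and avoidability were combined, nor the
  classical S×O×D factorisation.
* Percentages are per-record; per-location aggregation before counting
  would change them and is not implemented.
* The synthetic model is independent Bernoulli/lognormal per record: no
  spatial carry-over between surfaces and gloves, no temporal dynamics,
  no inter-hospital heterogeneity beyond labels. Passing recovery tests
  show the scoring machinery is calibrated, not that real campaigns
  match the generator's distributional assumptions.
* Analytical-chemistry concerns (recovery/desorption correction,
  inter-laboratory harmonisation) are out of scope; loads are taken as
  reported.
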