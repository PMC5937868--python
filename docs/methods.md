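# Methods

This note records how the package computes each stage of the HeLM lake
assessment, the defaults it ships, and the choices made where the procedure
left room for interpretation.

## Survey data model

A survey is a set of plot observations — (lake, transect, year, depth zone,
plot, taxon, DAFOR category) — plus one measured maximum colonization depth
(C_max, m) per transect and year. Sampling zones are the five standard depth
bands 0–1, 1–2, 2–4, 4–8 and >8 m. Taxa are matched by exact identifier;
there is no fuzzy name resolution, by design — determinism beats
convenience in a regulatory pipeline. CSV is the only exchange format
(comma or semicolon separated, auto-detected; decimal point mandatory).

## Trophic index (TIHeLM)

Plot records are first collapsed to one DAFOR category per taxon and
transect. The procedure defines "relative abundance within the transect"
without fixing the plot-to-transect aggregation; the default here is the
**maximum** category the taxon attains in any plot of any zone (a
presence-dominance reading, conservative for patchy stands), with a modal
rule available behind the `rule` parameter. Categories map to percent cover
(87.5 / 50 / 17.5 / 5.5 / 0.5), covers are raised to the power 0.2, and the
transect value is the weighted mean of taxon LTR scores with those weights.
Because the weights are normalized within the transect, a common rescaling
of all covers cancels exactly — a property the test suite enforces.

Taxa without an LTR but with an Ellenberg nutrient value N (1–9) are scored
through LTR = 1.395 N − 0.6276. The regression exceeds the 10-rank scale at
N = 9 (11.93); imputed values are clamped into (0, 10] with a warning — LTR
is a 10-rank-scale analogue and the published worst-case lake sits near 9.
Unscoreable taxa (no LTR, no N — typically mosses and filamentous algae
absent from the calibration lists) are excluded and counted in a
per-transect diagnostics record; a transect with no scoreable taxon yields
an explicitly undefined index, never zero. The lake value is the unweighted
mean of its defined transect values.

## Colonization depth (C_max)

The annual lake value defaults to the **maximum** transect C_max of that
lake-year (the field protocol deliberately revisits the deepest transects,
so the maximum is the intended reading; a 95th-percentile rule is available
for robustness against recording errors). The lake metric is the arithmetic
mean of the annual values over the years actually surveyed; missing years
are absent from the mean, never imputed as zero. Values are reported at
2 decimals, matching the published precision.

## Reference screening and boundary setting

Screening applies seven pressure criteria conjunctively with **strict**
inequalities (TP < limit, CHLA < limit, SD > limit, ALU < limit, IA <
limit, NASN > limit, PD < limit); a missing indicator renders its criterion
"not evaluable" and blocks the pass. The limits per lake type are the
published ones (deep lakes: 12 µg/L TP, 2 µg/L CHLA, 6 m SD; shallow: 15,
5, 2; both: 4 % artificial land, 25 % intensive agriculture, 70 % natural
cover, 30 inhabitants/km²).

The second filtering step — disqualifying reference sites whose vegetation
is limited by natural substrate or slope rather than pressure — is not
given an explicit rule in the source procedure; this package uses Tukey
fences (outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR], multiplier configurable) on
the per-transect metric values, with fewer than four values or a zero IQR
treated as "nothing flagged".

Boundaries are derived per metric from per-transect values ("sites" are
transects; a lake-level derivation is a one-line change in the calling
code). Percentiles are linearly interpolated order statistics (the common
type-7 estimator) and are always read in the **direction of degradation**:
for the lower-is-better trophic index P90/P75 are the upper-tail 90th/75th
percentiles, for the higher-is-better depth metric they are the lower-tail
10th/25th — the published deep-lake High/Good raw boundary (10.86 m) lying
below the reference median (12.2 m) admits no other reading. The reference
value is the median of reference-site values; High/Good comes from the
reference distribution, Good/Moderate from sites in the 20–50 µg/L TP band,
and the EQR range from the Good/Moderate boundary down to the lower anchor
is divided into three equal classes.

The lower anchor is 0 for the depth metric (a vegetation-free lake). The
trophic index needs a finite positive anchor for normalization; the
derivation uses the worst (minimum) EQR observed across the supplied sites,
and the shipped published set uses 0.675 — the value implied by continuing
the published equal trisection below the printed Poor/Bad boundary
(0.90 − 3·(0.90 − 0.75)/2). The published Moderate/Poor and Poor/Bad steps
(0.08, 0.07) are unequal, which indicates intermediate rounding in the
published table; the builtin set therefore carries the printed two-decimal
values verbatim so published classifications reproduce exactly, while
freshly derived sets keep full precision.

## EQR, normalization, classification

EQR = reference/observed for the trophic index (observed 0 clamps to 1 with
a warning) and observed/reference for depth, capped into [0, 1] — the cap
is required: lakes colonized deeper than the reference median (e.g. the two
deep reference lakes) must score exactly 1. Normalization is piecewise
linear through the knots (lower anchor → 0), (P/B → 0.2), (M/P → 0.4),
(G/M → 0.6), (H/G → 0.8), (1 → 1); values below the anchor clamp to 0. The
final score is the equal-weight mean of the two normalized EQRs; a lake
with only one computable metric is reported with that metric and no final
score. A score exactly on a class boundary belongs to the **upper** class
(the published table is ambiguous here and no published lake sits on a
boundary). Reported precision: 3 decimals for the trophic index and all
(n)EQR/final values, 2 for raw C_max.

Re-deriving the published table from its raw metric values reproduces all
16 status labels and all normalized EQRs and final scores to within
±0.002; the residual (≤ 0.001) is the published table's own intermediate
rounding (e.g. one lake's trophic-index nEQR prints 0.687 where
full-precision computation gives 0.688).

## Pressure-response evaluation

Simple fits are ordinary least squares of the transformed response on one
log10-transformed pressure indicator: trophic index log10-transformed,
depth square-root-transformed, final score untransformed (these transforms
are the published ones; logarithms are base 10 throughout). Reported
statistics: R², Pearson r signed like the slope, and the F-test p-value;
a metric counts as well-performing at R² > 0.30, |r| > 0.55, p < 0.05.
Lakes with non-positive pressure values are excluded from log fits with a
warning. The multivariate fit regresses the untransformed final score on
log10 TP, CHLA and SD together and reports the positive multiple
correlation √R²; predictors collinear to machine precision raise an error
naming the pair. Life-form relative abundances are per-lake sums of
DAFOR-transformed, transect-aggregated covers normalized to 1; turnover
trends are least-squares polynomials (default degree 2, configurable) of
the square-root-transformed shares on a score axis.

## Synthetic gradient generator

The generator emulates the study design the method assumes: a set of
natural Mediterranean lakes (default 16, half deep, half shallow,
interleaved) log-spaced along a 5–150 µg/L total-phosphorus gradient, each
with 12 transects surveyed in three consecutive years across the five depth
zones, scored against a 24-taxon pool spanning all six life-forms in which
every second taxon carries only an Ellenberg N value (so the imputation
path is exercised on realistic data).

Structure built in, and what it is for:

* Secchi depth falls and chlorophyll rises with TP through smooth power
  laws (SD = 35.5·TP^−0.8 m; CHLA = 0.073·TP^1.45 µg/L), chosen so lakes
  below the screening TP limits also satisfy the clarity and chlorophyll
  criteria — low-TP lakes are reference-grade by construction.
* The depth limit follows clarity through √C_max = 1.23 + 2.43·log10(SD),
  truncated at 0 and capped at the 8 m basin depth for shallow lakes. The
  slope is steeper than field calibrations so that the emulated gradient
  reaches vegetation-free hypereutrophic conditions within the default TP
  range and the end-to-end pipeline exhibits all five status classes.
* Community turnover is implemented as monotone, per-taxon DAFOR category
  shifts on the fixed pool: clear-water forms (elodeids, charids; LTR
  4–6.5) fade with the trophic position, helophytes and lemnids (LTR
  8.8–10) rise, intermediate forms (ceratophyllids, nymphaeids; LTR
  6.8–7.4) hold steady and then fade toward hypereutrophy. Taxon-specific
  staggering spreads the category shifts along the gradient. Keeping the
  shifts monotone per taxon makes the noiseless pipeline provably ordered.
* Noise is multiplicative lognormal on the water-quality relations and
  Gaussian on per-transect C_max (default σ = 0.1); with σ = 0 every
  relation is deterministic, and the final score is strictly decreasing in
  TP within the deep-lake type (shallow lakes plateau where the basin-depth
  cap binds — a real feature of shallow basins, asserted non-strictly).

What the generator does **not** emulate: biogeography and species identity,
depth-zone-resolved light limitation, seasonal dynamics, inter-annual
regime shifts, and observer error in DAFOR scoring. Tests passing on
synthetic bundles therefore demonstrate the pipeline's arithmetic,
orderings and error handling — not field validity of the index, which
rests on the published calibration.

## Numerical conventions

* Percentiles/quantiles: numpy's default linear interpolation (type 7).
* Ties at class boundaries resolve upward; EQRs cap at 1; nEQRs clamp at 0
  below the lower anchor.
* Boundary records validate the strict ordering 1 ≥ H/G > G/M > M/P > P/B >
  anchor ≥ 0 at construction; derivation raises a configuration error when
  the data imply H/G ≤ G/M (reference sites not better than TP-group
  sites).
* Problem sizes in the shipped tests and the acceptance script are the
  study-scale defaults: 16 lakes, 12 transects × 3 years, n = 200 for noisy
  regression recovery, 1000 transects for quantile-convergence checks.

## Known limitations

* The published per-transect raw data and the full LTR taxa list are not
  distributed; the builtin taxa table is empty and all survey-level tests
  run on synthetic taxa. Published-value reproduction therefore starts from
  the published per-lake raw metrics.
* The exact outlier rule and plot-to-transect aggregation of the original
  procedure are unstated; the defaults here (Tukey fences, maximum DAFOR)
  are documented choices, not claims about the original computation.
* The multivariate "R" is reported as the positive multiple correlation;
  sign conventions for multiple regression differ across software.
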