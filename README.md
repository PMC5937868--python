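# helm-assess

Ecological status assessment of natural lakes from aquatic macrophyte
transect surveys, implementing the HeLM method (Hellenic Lake Macrophyte
assessment) used for Water Framework Directive (WFD) monitoring of Greek
natural lakes.

## Who this is for

Freshwater ecologists and monitoring agencies who hold plot-level macrophyte
survey data (DAFOR abundance records along depth-zoned shore transects plus
the maximum colonization depth per transect) and per-lake eutrophication
pressure indicators, and who need the full chain from raw surveys to a
five-class WFD status call — including reference-site screening, class
boundary derivation, and pressure-response validation of the method itself.

## The method

HeLM combines one taxonomic-composition metric and one abundance metric,
each expressed as an ecological quality ratio (EQR) against type-specific
reference conditions:

* **TIHeLM** — a cover-weighted mean of taxon trophic scores per transect,
  averaged over a lake's transects:

      TIHeLM_transect = Σᵢ LTRᵢ · wᵢ / Σᵢ wᵢ,   wᵢ = (% coverᵢ)^0.2

  DAFOR categories map to percent cover (dominant 87.5, abundant 50,
  frequent 17.5, occasional 5.5, rare 0.5); the 0.2 exponent keeps dominant
  stands from swamping the index. Taxa lacking a lake trophic rank (LTR) but
  carrying an Ellenberg nutrient value N are scored through the calibration
  regression LTR = 1.395 N − 0.6276. Lower TIHeLM = better.

* **C_max** — the maximum colonization depth of aquatic vegetation (m):
  deepest transect value per lake-year, averaged over the survey years.
  Deeper = better.

Raw values become EQRs (reference/observed for TIHeLM, observed/reference
for C_max, capped at 1), are rescaled by piecewise-linear interpolation so
the High/Good, Good/Moderate, Moderate/Poor and Poor/Bad class boundaries
sit at 0.8/0.6/0.4/0.2 for both metrics, and the final HeLM score is their
equal-weight mean; the status class follows from the 0.8/0.6/0.4/0.2
anchors.

Reference lakes are screened by seven conjunctive pressure criteria (total
phosphorus, chlorophyll a, Secchi depth, artificial land use, intensive
agriculture, natural land cover, population density). Boundaries follow the
percentile scheme: reference value = median of reference-site transect
values, High/Good = degradation-direction 90th percentile of the reference
distribution, Good/Moderate = 75th degradation-direction percentile among
sites in the 20–50 µg/L TP band, and the EQR range below Good/Moderate is
divided into three equal classes. The boundary set published for the Greek
national lake types (deep GR-DNL, shallow GR-SNL) ships as
`builtin:helm2018`.

## Worked example

Assess a lake from already-aggregated metric values against the published
boundary set:

```python
from helm_assess import assess_from_raw, builtin_boundaries_helm2018
from helm_assess.core import LakeMeta, LakeType
from helm_assess.classification import round_assessment

meta = LakeMeta("Yliki", "Yliki", LakeType.GR_DNL)
a = assess_from_raw("Yliki", meta, tihelm_raw=7.439, cmax_raw_m=3.80,
                    boundaries=builtin_boundaries_helm2018())
print(round_assessment(a))
```

prints

```
{'lake_id': 'Yliki', 'lake_type': 'GR-DNL', 'tihelm_raw': 7.439,
 'neqr_tihelm': 0.866, 'cmax_raw_m': 3.8, 'neqr_cmax': 0.519,
 'helm': 0.693, 'status': 'Good'}
```

i.e. lake Yliki's trophic index EQR of 7.141/7.439 = 0.96 normalizes to
0.866 (High band), its colonization depth of 3.80 m against the 12.2 m deep
-lake reference normalizes to 0.519 (Moderate band), and their mean 0.693
classifies the lake as Good — matching the published assessment.

The same pipeline runs from CSV files via the CLI, here on a synthetic
bundle produced by the built-in gradient simulator:

```bash
helm simulate --seed 7 --out bundle
helm assess --surveys bundle/surveys.csv --taxa bundle/taxa.csv \
            --meta bundle/meta.csv --boundaries builtin:helm2018 \
            --out results.csv
head -4 results.csv
```

```
lake_id,lake_type,tihelm_raw,neqr_tihelm,cmax_raw_m,neqr_cmax,helm,status
L01,GR-DNL,6.138,1.0,14.29,1.0,1.0,High
L02,GR-SNL,6.214,1.0,8.0,1.0,1.0,High
L03,GR-DNL,6.602,1.0,11.9,0.956,0.978,High
```

Further subcommands: `helm screen` (reference screening), `helm boundaries`
(derive a boundary set from surveys + pressures), `helm evaluate`
(pressure-response regressions of the metrics and final scores).

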