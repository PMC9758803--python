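# ecolink

Does sampling health facilities bias effective-coverage estimates produced by
ecologically linking household surveys to facility assessments?  `ecolink` is
a simulation framework for answering that question.  It is aimed at
researchers in health-systems measurement who combine household care-seeking
data (MICS/DHS-style cluster surveys) with facility quality data (SPA/SARA-
style assessments) to estimate input- and quality-adjusted coverage of
sick-child and childbirth care, and who need to know how much error the
facility sampling design — as opposed to the linking method itself —
introduces.

## The estimation chain

Effective coverage over an in-need population is the weighted ratio mean

```
EC = Σᵢ wᵢ·sᵢ·qᵢ / Σᵢ wᵢ
```

where `sᵢ` indicates care-seeking from a skilled (facility-based) provider
and `qᵢ` is the quality score of individual *i*'s linked provider:
structural (readiness) quality for **input-adjusted** coverage, process
(provision-of-care) quality for **quality-adjusted** coverage, and `qᵢ ≡ 1`
for **crude** coverage.  Three linking rules assign `qᵢ`:

* **exact match** — the specific provider the respondent stated (truth
  reference, always against the full facility census);
* **Euclidean nearest** — the closest facility, as the crow flies, within the
  reported provider category (managing authority × level of care);
* **administrative unit** — the caseload-weighted mean score of all
  facilities of the reported category in the respondent's district.

Individuals who cannot be linked (unrecalled provider, or category absent
from the facility set) receive the average score of their reported category;
unskilled sources (pharmacies, community health workers) count as no skilled
care.  Standard errors treat survey clusters as PSUs (single-stratum Taylor
linearization of the ratio mean); facility-side error is ignored.

On top of this chain the package implements SPA-style facility sampling
(census of referral facilities plus stratified random samples of first-level
facilities at sizes 65/90/130, 20 draws each) and two quality perturbations
(uniform-random re-scoring; a preferential-care-seeking shift of ±15
percentage points driven by facility utilization, distance to the nearest
cluster, and the category median).  A synthetic-region generator reproduces
the study conditions — 44 clusters, 392 delivery and 183 sick-child episodes,
a census of 194 facilities, calibrated care-source mix and between-cluster
care-seeking heterogeneity — so the whole experiment runs end to end without
access to the underlying (non-public) survey data.

## Worked example

```python
from ecolink import GeneratorConfig, generate_region, run_scenario
from ecolink.sampling_quality import SampleDesign
from ecolink.study_runner import outlier_margins

region = generate_region(GeneratorConfig(seed=1))
result = run_scenario(region, "original", SampleDesign(seed=1))

exact = result.reference("exact", "delivery", "input_adjusted")
print(f"exact-match input-adjusted delivery coverage: "
      f"{100*exact.point:.1f}% (95% CI {100*exact.ci_low:.1f}-{100*exact.ci_high:.1f})")
```

Output:

```
exact-match input-adjusted delivery coverage: 39.1% (95% CI 33.0-45.3)
census admin     link: 39.1% (95% CI 33.0-45.3)
census euclidean link: 39.1% (95% CI 33.1-45.1)
n=65 admin     median [IQR] over 20 draws: 39.0 [38.5-39.4]
n=65 euclidean median [IQR] over 20 draws: 39.2 [38.5-39.6]
sampled estimates outside the exact-match CI: 0/480
```

Read: with realistic (low-variance) quality scores, both ecological methods
reproduce the exact-match estimate almost perfectly, and none of the 480
sample-derived estimates (3 sizes × 20 draws × 2 methods × 2 service areas ×
2 indicators) leaves the truth reference's confidence band — facility
sampling adds spread, not bias.  Under the preferential-care-seeking scenario
the picture changes: ecological linking systematically underestimates the
exact-match coverage, and outliers concentrate in the smallest sample size
and the Euclidean method.

## Command line

```
ecolink generate --seed 1 --out region/          # synthetic region (CSV + GeoJSON)
ecolink link --method euclidean --region region/ --out links.csv
ecolink coverage --links links.csv --region region/ --out estimates.csv
ecolink sample --region region/ --sizes 65,90,130 --draws 20 --seed 1 --out samples/
ecolink simulate-quality --mode preferential --region region/ --out region_pref/
ecolink run --region region/ --scenario original --seed 1 --out results/
```

`run` writes `estimates.csv` (every estimate with CI), `outliers.csv`
(counts against the exact-match and census references, with per-size and
per-method denominators), `summary.csv` (median [IQR] per grid cell) and
strip plots per service area.

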