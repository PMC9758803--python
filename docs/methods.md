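# Methods

This note documents the models, conventions and design choices behind
`ecolink`: what is computed, under which assumptions, and which parts are
calibrated emulation versus first-principles estimation.

## Data model and file layout

A *region* is a facility census, a set of household-survey clusters, and a
set of care episodes.  Provider categories are the cross of managing
authority (`public | private | religious | ngo`) and level of care
(`first_level | referral`); this pair is the key that restricts every linking
operation.  Coordinates are WGS84 decimal degrees (longitude, latitude),
stored at full precision; no cluster displacement is applied.

Column dictionary (CSV, UTF-8, header row; unknown extra columns are
preserved but ignored):

* `facilities.csv` — `facility_id, authority, level, district, longitude,
  latitude, skilled, caseload_sick_child, caseload_delivery,
  structural_sick_child, structural_delivery, process_sick_child,
  process_delivery`.  Scores lie in [0, 1]; caseloads are annual volumes ≥ 0.
* `clusters.csv` — `cluster_id, longitude, latitude, district, weight`
  (survey weight > 0; any response-rate adjustment is assumed already
  embodied in the weights).
* `episodes.csv` — `episode_id, cluster_id, service_area, weight, sources`.
  `sources` packs the reported sources of care into one cell:
  `authority|level|facility_id` tokens joined by `;`, with an empty facility
  id when the specific provider is unknown, `unskilled||` for a
  pharmacy/community-health-worker source, and an empty cell for no care
  sought.  Delivery episodes carry at most one source; sick-child episodes
  may carry several.

Writes additionally emit an RFC 7946 GeoJSON point layer of facilities and
clusters.  Floats are printed with shortest round-trip formatting and parsed
back with round-trip precision, so write → read is the identity.  A stated
facility id absent from the census is retained and *flagged* unresolvable
rather than dropped, because the exact-match fallback rule consumes it.

## Linking

Distance is the great-circle (haversine) distance with mean Earth radius
6371.0088 km — the appropriate "as the crow flies" metric at regional scale,
with the constant fixed for reproducibility.  Episode location is the cluster
centroid, matching how cluster surveys release coordinates.

* **Exact match** runs against the full census even in sampled scenarios
  (the truth reference comes from the one-time full assessment).  A skilled
  source with a resolvable stated id receives that facility's scores;
  otherwise the category fallback applies.
* **Euclidean nearest** selects, per skilled source, the facility of the
  reported category minimizing centroid distance over whichever facility set
  (census or sample) the scenario dictates.  Equidistant candidates are
  broken by smallest facility id — the source data are silent on ties and
  determinism is required.
* **Administrative unit** assigns the caseload-weighted mean score of the
  district × category facility set, `Σ caseload_f·score_f / Σ caseload_f`;
  zero total caseload degrades to the unweighted mean.

The **fallback** (unlinkable source, or category absent from the district or
the sampled set) is the caseload-weighted category mean over the facility set
in use, degrading to the census-wide category mean when the category is
entirely absent from a sample.  Caseload weighting keeps the fallback
consistent with the administrative method; an unweighted variant is
available.  Episodes with several skilled sources receive the unweighted mean
of per-source scores; unskilled sources are excluded, and an episode with
only unskilled sources counts as receiving no skilled care.  Score
aggregation sums facilities in id order so that results are invariant to the
ordering of a facility set — a sample that happens to equal the census
reproduces census results bit for bit.

## Coverage estimation

Crude, input-adjusted and quality-adjusted coverage are weighted ratio means
over in-need episodes (see README).  Variance is the single-stratum Taylor
linearization of the ratio estimator with clusters as with-replacement PSUs:

```
var(r) = n/(n−1) · Σ_c u_c² / W²,   u_c = Σ_{i∈c} w_i (v_i − r)
```

with `n` clusters and total weight `W`.  The 95% CI is the symmetric normal
approximation clipped to [0, 1].  This is the standard design-based default;
the published CIs this emulates do not state their construction, so the
normal approximation is a documented convention, not a reproduction claim.
Facility-side measurement error is excluded by design (the facility data are
a census).  Estimates are only meaningful at the survey's sample domain
level; the package computes none below it.

## Facility sampling

`draw_facility_sample` keeps every referral facility and draws the nominal
`n` among first-level facilities without replacement, by default allocated
proportionally across two authority strata (public vs private/religious/NGO)
with largest-remainder rounding; an unstratified switch exists.  The nominal
sizes (default 65, 90, 130 with 20 draws each) are configuration inputs.
`spa_sample_size` implements the margin-of-error formula with finite-
population correction, `n = ⌈n₀ / (1 + (n₀−1)/N)⌉`, `n₀ = z²p(1−p)/e²`; at
`N = 187, e = 0.10` it yields 64, so the conventional 65 is treated as a
design choice of the emulated assessments, and the formula is a utility
rather than the source of the defaults.  Each (size, draw) cell uses an
independent stream seeded from (master seed, size, draw), so any single draw
is reproducible in isolation.

## Quality simulations

* **random** — every structural and process score is redrawn
  Uniform[0, 1], independently per facility, service area and indicator;
  locations, categories, caseloads and care-seeking stay fixed.  This widens
  within-category score spread far beyond realistic data and stresses the
  ecological methods.
* **preferential** — per service area and indicator, scores shift by
  ±delta (default 0.15): up if the facility was used by at least the
  utilization threshold (1 sick-child or 2 delivery respondents, counted
  from resolvable stated sources); down if underused and within 10 km of a
  household cluster; for underused facilities farther than 10 km, up when the
  pre-shift score is at or above the category median and down when below
  (ties shift up — a documented, configurable convention).  Medians are
  computed per category × indicator on pre-shift scores; results clamp to
  [0, 1].  The runner reports the up/down tally since the rules were designed
  to roughly balance the two.

For the random and preferential scenarios the exact-match reference is
recomputed on the re-scored census, so "truth" moves with the simulated
quality landscape.

## Synthetic regions

The generator emulates the study conditions, not any particular geography:

* **Census and survey sizes** — 144 public first-level, 22 private and 21
  religious first-level (together 43), 5 public and 2 private referral
  facilities; 44 clusters; 392 delivery and 183 sick-child episodes.
* **Care-source mix** — delivery: 65.2% facility care of which 46.0% public
  first-level; sick child: 43.2% care-seeking with 27.0% public first-level
  and 8.2% pharmacy (unskilled).  The residual facility mass is split
  11.0/5.0/3.2% (delivery: public referral / private / religious first-level)
  and 3.0/3.0/2.0% (sick child: public referral / private / religious
  first-level), following the observed ordering; these splits are generator
  conventions.  7% of care-seeking episodes have their stated facility id
  blanked, matching the published exact-match assignment rates (92–94%).
* **Geography** — clusters uniform over a 150 km square; facilities
  scattered around six town centres (Gaussian, 8 km scale, one quarter fully
  dispersed) so nearest-facility linking is non-trivial; districts are a
  3 × 3 spatial grid partition, giving every facility exactly one district.
* **Quality scores** — Beta distributions reparameterized by (mean, sd) per
  category (first-level means 0.55–0.60, referral 0.78, sd 0.07 so the
  within-category IQR stays under 20 percentage points), with structural and
  process scores coupled by a Gaussian copula (ρ = 0.6).  Setting sd = 0
  collapses each category to its mean exactly.
* **Caseloads** — log-normal (median 250, σ_log 0.8); an optional
  coefficient couples caseload to process quality, needed when emulating a
  volume–quality link.
* **Care-seeking heterogeneity** — the probability of seeking any care
  varies between clusters with intra-class correlation 0.55, back-solved
  from the published regional CIs (crude delivery 65.2%, CI 53.2–75.5%
  implies a design effect near 5.6 at ~9 births per cluster).  Cluster
  propensities follow the Beta quantile profile evaluated at fixed
  mid-quantiles and randomly permuted over clusters, which pins the
  region-wide rate at its configured value — so large-sample calibration
  holds exactly while the survey design effect is realistic.
* **Provider choice** — a gravity model: probability ∝ caseload ·
  exp(−d/15 km) · exp(quality_preference · process score).  The emulated
  study observed behaviour rather than modelling it, so this model is an
  artifact convention; `quality_preference = 0` (default) makes choice
  independent of quality, and positive values (4.0 in the preferential
  replicates, together with caseload–quality coupling 3.0) produce the
  bypassing behaviour that scenario requires.

What the generator does **not** emulate: real spatial facility density and
road access, survey weighting (weights default to 1), seasonality or
recall error in care-seeking, and the construction of quality indices from
inventory items (scores are taken as given in [0, 1]).  Passing tests
therefore demonstrate properties of the estimation chain under controlled,
realistic-scale conditions — not agreement with any particular country's
field data.

## Numerical and testing choices

* IQR and median use linear-interpolation percentiles; exports also report
  percentages rounded to one decimal.
* Outlier = sampled point strictly outside a reference 95% CI; boundary
  points do not count.
* Degenerate inputs: < 2 clusters is an error for variance; an empty
  district × category set falls back rather than erroring; a category absent
  from both sample and census is an error.
* Test problem sizes: oracle comparisons run 50 regions of ≤ 200 facilities
  against exhaustive scans; CI calibration uses 1 000 replicates of a
  44-cluster survey; directional replication uses 50 preference-generated
  replicates; generator calibration inflates to 50 000 episodes.  These sizes
  put Monte-Carlo noise well inside the asserted tolerances while keeping the
  default suite around half a minute.

## Known limitations

* The normal-approximation CI slightly undercovers at 44 clusters compared
  with a t-based interval; the calibration test budget (95% ± 2 pp) reflects
  this.
* Outlier percentages under the random and preferential scenarios are
  sensitive to the within-category score variance and the care-seeking
  design effect; the synthetic defaults reproduce the qualitative pattern
  (outliers concentrate at n = 65 and under Euclidean linking; none fall
  outside census bounds under the original scenario) rather than exact
  published percentages, which depend on the non-public source data.
* Travel-time or road-network distance linking and cluster-coordinate
  displacement are out of scope.
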