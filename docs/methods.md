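# Methods

This note documents the models and procedures implemented in
`sealrange`, the defaults chosen where the methodology leaves a choice
open, and what the synthetic-data experiments do and do not demonstrate.

## Data model and preprocessing

A *track* is one animal's time-ordered table of GPS fixes (UTC
timestamp, lon/lat, satellite count, residual error) plus deployment
metadata (sex, masses, dates). Duplicate timestamps are collapsed to the
first occurrence and logged.

**Projection.** All geometry runs in a local planar frame under an
azimuthal-equidistant projection centred on the colony (spherical earth,
mean radius 6371.0088 km). For a central-place forager this minimises
distance distortion where it matters: distances from the centre are
exact, and pairwise distances within 500 km are accurate to < 0.5 %.
The forward/inverse formulas are closed-form and invert each other to
well under a metre at study scale.

**Quality filter.** A fix is removed when it has fewer than 5
satellites, a residual error above 30, or an implied travel speed above
10 km/h. The speed rule runs as a single forward pass against the last
*retained* fix, so one teleporting outlier cannot cascade-delete the
rest of a track; the pass is idempotent, and each removed fix is
attributed to the first rule that fired (satellites → residual → speed),
so the per-rule counts partition the removals.

**Seasons.** Summer is 1 June–30 September and fall 1 October–4
December, both inclusive; other dates are *excluded* (animals are at the
breeding colony and foraging is essentially arrested), not an error.

**Bathymetry.** Depth grids use the plain-text ESRI ASCII raster
dialect with bilinear interpolation; queries outside the extent raise.

## Movement-state HMM

Travel rate between consecutive fixes is modelled with a 2-state hidden
Markov model: a slow state (area-restricted search, ARS) and a fast
state (directed travel), gamma emission in each state (the standard
positive-support family for speeds). Tracks are split into *bursts*
wherever the inter-fix gap exceeds 2 h (eight missed 15-min fixes —
typically GPS suspension while hauled out), and the forward recursion
restarts at each burst so haul-outs contribute no spurious speeds.

Fitting is Baum–Welch EM: scaled forward–backward E-step (compiled with
numba), weighted gamma maximum likelihood M-step (Newton on the shape
equation). Zero speeds are nudged to half the smallest positive speed.
Initialisation is deterministic: 2-means on speeds seeded at the
25th/75th percentiles, transition persistence 0.9. Convergence is a
log-likelihood change below 1e-6 (cap 500 iterations); the likelihood is
checked non-decreasing. States are reordered slow-first after fitting,
eliminating label switching. The deliverable per fix is p(ARS), the
smoothed posterior of the slow state; a Viterbi decoder is provided for
cross-checks.

## T-LoCoH home ranges and core areas

The time-scaled distance between fixes i and j is

    TSD = sqrt(Δx² + Δy² + (s · v_max · Δt)²),

with Δt in hours: temporal separation becomes a third Euclidean axis
scaled by the dimensionless parameter `s` and the animal's maximum
theoretical velocity `v_max`. With `s = 0` the method reduces to the
classical space-only local hull model. `v_max` defaults to the 99.9th
percentile of observed filtered speeds, capped at 10 km/h to match the
quality filter.

Neighbour selection is either the `k` nearest fixes by TSD (fixed
method) or the adaptive `a`-method: neighbours accumulate nearest-first
while the running sum of their TSDs stays within a budget `a` (derived,
when unset, as the median cumulative distance realised at k = 15). The
adaptive method gives more detail where the animal lingers and is the
configuration used for final isopleths; both methods are verified
against brute-force oracles. Each parent point's neighbour set becomes a
convex hull; sets with fewer than three distinct non-collinear points
are flagged degenerate and excluded from isopleth accounting.

**Parameter diagnostics.** A hull is *time selected* when its neighbour
set under `s` differs from its set under `s = 0`; `s` is chosen as the
smallest candidate putting 40–80 % of hulls in that state. For `k` (or
`a`), curves of 95 %-isopleth area and edge:area across candidates are
produced, and the recommendation is the first candidate whose relative
area change from the previous one drops below 10 % — an explicit,
testable version of choosing the visually stabilised value. On the
noiseless synthetic tracks the time-selected band is reached at much
smaller `s` (~1e-5–1e-3) than on field data, because without measurement
noise even a tiny time axis reorders near-co-located neighbours; the
acceptance script therefore sweeps a log-spaced grid.

**Isopleths.** Hulls are sorted descending by a use metric — enclosed
fixes per km² (*point density*) or separate visits (*visit frequency*) —
with ties broken by smaller area, then earlier parent; they are merged
until the union encloses the requested fraction of all retained fixes,
counted uniquely across the union. The 95 % density-sorted isopleth is
the home range; the 30 % visitation-sorted isopleth is the core area.
Both are computed per season, and an animal-season with fewer than 100
fixes is flagged insufficient rather than estimated. The core is not
asserted to nest inside the home range: the two sort metrics differ.

## Hull metrics and behaviour classification

Enclosed points (boundary inclusive, so a hull's own members always
count) drive the revisitation metrics: `nsv`, the number of separate
visits, where a new visit starts after an absence *strictly* longer than
12 h (an exact identity, nsv = 1 + #gaps > 12 h, is tested exhaustively);
`mnlv`, total enclosed fixes per visit. Both are normalised by hull area
(km⁻²). Eccentricity is `sqrt(1 − (b/a)²)` of the minimum-area
(Löwner–John) ellipse enclosing the hull vertices, computed by a
numba-compiled Khachiyan iteration (step tolerance 1e-7, capped at 1000
iterations — beyond the cap the axis ratio is accurate to well under a
percent, ample for a shape index); degenerate hulls take e = 1. Mean
p(ARS) averages the HMM posterior over enclosed fixes.

Classification pools hulls across the population (matching the single
set of published thresholds rather than per-animal quantiles), after
excluding hulls parented within 15 km of the colony, where short
movements around the haul-out would swamp the revisitation signal.
Linear-interpolation quartiles of nsv km⁻² define three visitation bands
(infrequent < q1 < frequent < q3 < very frequent); each band splits at
its own median of mnlv km⁻², ties to the lower-duration category. The
time budget treats each classified parent fix as one sampling interval
(15-min sampling is near-uniform after filtering), giving per
animal × season category proportions summarised by medians and raw
median absolute deviations.

## Mass accounting and multimodel inference

Mass gain is expressed as percent of initial mass per day,
`100·(final − initial)/(initial·days)`. Females weighed postpartum are
corrected back to parturition mass at 4.1 kg day⁻¹ of lactation loss.

Model comparison uses the small-sample criterion
`AICc = −2LL + 2K + 2K(K+1)/(n−K−1)`, ΔAICc, Akaike weights and
evidence ratios `ER = exp(Δ/2)` (reported against the runner-up unless a
pair is named). Mixed models are fitted by full maximum likelihood — not
REML — so likelihoods are comparable across fixed-effect structures;
`K` counts fixed coefficients plus the residual variance plus (when
present) the random-intercept variance. Marginal R² is the fixed-effect
variance share of (fixed + random-intercept + residual) variance;
conditional R² adds the random intercept. `mad` is reported raw, with no
1.4826 consistency factor. Fitting is a pluggable backend (statsmodels
MixedLM/OLS by default, with an optimizer fallback); everything
downstream consumes only (LL, K, n, variance components), and a failed
fit flags that model without aborting the set. The standard candidate
set spans body mass, season, sex and their pairwise interactions (13
models).

## Synthetic forager generator

The generator emulates the statistical structure the analysis assumes —
not any particular dataset. An animal alternates haul-outs at the colony
(gamma-distributed, mean 16 h; a single fix is emitted at haul-out start
and the GPS then stays silent, creating the gaps the burst logic
expects) with foraging trips: directed outbound travel to a chosen
patch's core (gamma speeds, mean 4.5 km/h; von Mises heading
concentration 20), area-restricted search inside the patch (mean
0.8 km/h, near-uniform turning, mild attraction toward the patch centre
so use is densest where the patch is most profitable), and directed
return. Patch choice is proportional to attractiveness × per-animal
Dirichlet preference, with the just-visited patch down-weighted
(depletion needs recovery time). Dwell follows a patch-independent
budget tied to the mean round-trip travel time of the available patch
set, fixing the at-sea forage:travel split at 60/40 on average.

Defaults are realistic for a large temperate pinniped: fixes every
15 min over a 1 June–4 December window; patches 30–90 km (females) or
60–150 km (males) from the colony, the two nearest staying available in
fall (late-season contraction); synthetic bathymetry with 50–75 m banks
at patch sites; deployment masses ~209/164 kg and gain rates ~0.30/0.22
% day⁻¹ (males/females); defect rates of 3 % low-satellite, 2.5 %
high-residual and 2.2 % teleport fixes (~7.7 % total). All randomness
derives from one integer seed; identical seeds give bit-identical
tracks.

What the generator does **not** emulate: GPS position noise (fixes are
exact, which shifts the time-selection `s` band downward, see above),
depth-dependent behaviour, drift haul-outs at sea, tide or weather
effects, or inter-annual variation. Passing tests therefore demonstrate
that the pipeline recovers structure *of the kind assumed*, at synthetic
scale (populations of ~6 animals over 90–186 days), not field-data
performance; published medians from real populations are not
reproduction targets.

## Pipeline

`sealrange all --outdir out --seed 1` (or stage-by-stage) runs
simulate → filter → hmm → hulls → isopleths → classify → budgets →
stats. Every stage writes text outputs (CSV, GeoJSON, YAML/JSON) plus a
manifest entry recording a parameter hash, input-file hashes, the seed
and a timestamp; a stage whose inputs and parameters are unchanged is
skipped, and identical configurations yield byte-identical CSVs. Hull
sets for the final isopleths use the adaptive method; the fixed-`k`
method remains available for diagnostics and oracle tests.

## Numerical and design choices

- Duplicate fix timestamps: keep first, log the count.
- Speed filter: single forward pass (not iterated); deterministic.
- On-edge points count as enclosed, avoiding floating-point exclusion of
  hull members.
- Isopleth tie-breaks: smaller hull area first, then earlier parent
  timestamp; deterministic output ordering throughout.
- Point density uses *enclosed* fixes (not member points) per km².
- Degenerate (zero-area) hulls contribute no isopleth coverage.
- The ~4-animal minimum for classification quartiles and the ≥ 50-speed
  minimum for HMM fitting are hard preconditions, not silent defaults.
- Problem sizes in the test and acceptance runs (6-animal populations,
  90–186-day windows, 20 HMM replicates, 50 model-selection replicates)
  were chosen as the smallest scales at which the recovered structure is
  stable run-to-run.

## Known limitations

- The HMM assumes gamma speeds and exactly two states; multimodal
  within-state speed distributions would be absorbed, not flagged.
- Eccentricity beyond the iteration cap is approximate (≪ 1 % error in
  the axis ratio) for very asymmetric vertex sets.
- MixedLM variance components near zero can make marginal and
  conditional R² coincide; this is reported as computed.
- Isopleth polygons are unions of many small hulls and may contain
  holes; containment queries on exact points are sensitive to this at
  the sub-kilometre scale, which is why final isopleths use the
  adaptive neighbour method.
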