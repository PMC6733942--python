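# Methods

This note documents the models behind the package, the assumptions they
make, the defaults and why, and what the synthetic-data experiments do and
do not demonstrate.

## Data model

A campaign is a set of watersheds, each a rooted tree of sampling sites: an
edge points from a site to the next site downstream, the outlet is the root,
and every site carries its cumulative drainage area `A_i` (km²) and a
concentration per season × solute. From the cumulative areas the package
derives the **incremental area** `a_i = A_i − Σ A_children` — the part of a
site's catchment not already drained by an upstream site. The incremental
areas are non-negative by the nesting invariant and form a disjoint
partition of the watershed (`Σ a_i = A_outlet`), which is what the leverage
conservation identity is stated on.

Concentrations below detection may be recorded as `<LOD` sentinels; they are
substituted with LOD/2 and flagged rather than dropped, keeping the site
count of the design intact while staying auditable. Units are per-solute
metadata: every metric is unit-invariant by construction (z-scores, ratios
to the outlet, ranks).

## Variance collapse

Within one watershed × season × solute, concentrations are z-scored
(`(C − mean)/sd`, sample sd) and ordered by drainage area, ties broken by
site id. The working model is a single change point in *variance* along the
area axis: for a split after `k` sites,

    LR(k) = n log σ̂²_all − k log σ̂²_1..k − (n−k) log σ̂²_k+1..n ,

with maximum-likelihood (ddof = 0) variances about each segment's own mean.
`k` ranges over `[min_segment, n − min_segment]` (default 5, preventing
degenerate end splits) and the maximising split is the candidate change
point; ties go to the smallest `k`. Segment variances are floored at 1e−12
so the log stays finite for constant segments — any true collapse to zero
variance then produces an enormous LR rather than an overflow.

Significance is a permutation test: the z-values are re-ordered uniformly at
random `n_perm` times (default 999, seeded) and the max-LR statistic is
recomputed; `p = (1 + #{LR_perm ≥ LR_obs}) / (n_perm + 1)`. Under the no-
change null the z-series is exchangeable, so the test is exact up to
Monte-Carlo error — the type-I experiment below confirms the calibration.
When `p > α` no change point is reported (the spatial drivers are then
either larger than the watershed or erased by in-stream processing).

The reported **threshold area** is the geometric mean of the two drainage
areas bracketing the split: areas span orders of magnitude, so the log
midpoint is the natural interpolant. A sliding-window variance profile
(window 10, sample variance, geometric-mean window area) is attached to each
result for inspection; detection itself always operates on the z-series.

Scaling is per watershed × season × solute by default. Pooling seasons
before scaling is a caller-side choice (scale the pooled values and pass the
series in); the per-slice default keeps seasons comparable when their means
differ.

## Subcatchment leverage

    L_i = 100 · ((C_i − C_out)/C_out) · (A_i/A_out)   [%]

Leverage weights a site's concentration deviation from the outlet by its
relative drainage area: a small headwater twice as concentrated as the
outlet moves outlet chemistry far less than a mainstem site with the same
deviation. Since per-site discharge is unmeasured in synoptic campaigns, the
area weight assumes **uniform specific discharge** (runoff proportional to
drainage area); this assumption is used consistently in the generator's
routing, so conservation tests close exactly. The outlet's own leverage is
identically zero, and positive *mean* leverage means headwaters carry more
solute than reaches the outlet — net in-network removal; negative means net
production.

Two partition modes:

* `all` (default) — every non-outlet site with its cumulative area; this is
  the per-site map / box-plot quantity. Nested sites overlap, so the
  zero-mean property under conservative mixing holds only approximately.
* `incremental` — sites weighted by incremental area, with the
  concentration of each site's *own* water de-mixed by mass balance:

      Ĉ_i = (A_i C_i − Σ_children A_c C_c) / a_i .

  Under conservative area-proportional routing `Σ a_i Ĉ_i = A_out C_out`
  telescopes over the tree, so the mean leverage over this partition is zero
  to machine precision on *any* conservative network — the conservation
  contract the test suite closes at 1e−9. For unmixed headwater sites
  Ĉ_i = C_i. De-mixing needs complete concentrations below each site, so
  missing cells are an error in this mode (they are silently dropped in
  `all` mode). Pure junction sites (a_i = 0) have no water of their own and
  are excluded.

Summaries report mean, median, type-7 (linear-interpolation) quartiles,
whiskers at the most extreme points within 1.5 × IQR, and the points beyond
— the quantile convention is stated because box-plot statistics differ
across conventions.

## Spatial stability

Spearman rank correlation of paired early/late concentrations across sites
(average ranks for ties), with a two-sided p-value from the
t-approximation `t = r_s √((n−2)/(1−r_s²))` for n > 10 and from exact
enumeration of all n! rank pairings for 3 ≤ n ≤ 10 (vectorised in chunks;
at n = 10 this is 3.6 M pairings and runs in seconds). Significance is
assessed at α = 0.05 by default. `r_s` is invariant under strictly monotone
transforms of either season, so calibration or unit changes between
campaigns do not affect it.

## Synthetic generator

The generator emulates the structure of a nested synoptic design while
keeping every planted parameter recoverable:

* **Topology** — `n_headwaters` leaf reaches joined pairwise uniformly at
  random until one root remains: a random binary merge tree with `2n − 1`
  reaches, outlet at the root.
* **Areas** — every reach (junctions included) draws an incremental area
  from LogNormal(μ = 0.47, σ = 0.8) km² (median 1.6, mean ≈ 2.2 km²), so a
  default 21-headwater watershed drains ≈ 90 km² — the scale of a mid-sized
  Arctic study catchment, with reach areas spanning roughly two orders of
  magnitude.
* **Sources** — reaches are grouped into contiguous patches of ≈
  `patch_area_km2` by greedy post-order aggregation (close a patch when the
  accumulated incremental area first reaches the target; overshoot is
  bounded by the largest merged chunk). Patch means are
  `baseline + patch_sd·u_p`, local sources add `local_sd·e_i`, truncated at
  zero. Defaults `baseline = 5`, `patch_sd = 1`, `local_sd = 0.25`
  (arbitrary concentration units): patch-to-patch contrast four times the
  within-patch noise, strong enough that the patch scale — not the noise
  floor — sets the variance structure. Truncated-Gaussian rather than
  lognormal sources keep `patch_sd`/`local_sd` directly interpretable; with
  the default baseline the truncation is negligible (≈ 5σ events).
* **Seasons** — the standard-normal draws behind both seasons are tied by a
  Gaussian copula with correlation `rho_season`; each site's (early, late)
  pair is then bivariate normal with correlation ρ even after routing
  (routing is the same linear mixing in both seasons), inducing a Spearman
  correlation of `(6/π) arcsin(ρ/2)`.
* **Routing** — post-order area-weighted mixing
  `C = (Σ A_c C_c + a·c_local)/A`, then `C ← C e^{−k_r}` per reach:
  `k_r = 0` is exactly conservative (the outlet equals the area-weighted
  mean of all local sources — checked against a flatten-the-tree oracle at
  1e−12), `k_r > 0` is net removal, `k_r < 0` net production.
* **Sampling** — a seeded subset of reaches (outlet always included) is
  exported; topology is contracted to nearest sampled ancestors, so the
  sampled network remains a valid nested tree and the conservation identity
  still telescopes.

The bundled `study_design()` mimics a three-watershed Arctic campaign
(42/41/31 sites, two seasons, three solutes) with per-watershed × solute
patch scales in the 3–30 km² range, weak net DOC production everywhere,
nitrate uptake in the tundra watershed, and seasonal persistence high for
DOC in the tundra/alpine watersheds but low in the lake-dominated one.
Lakes are represented only implicitly (small patches + low `rho_season`);
there is no residence-time or hydrograph model, no thermokarst event model,
no measurement error, and no spatial correlation beyond the patch
structure. Passing recovery tests therefore demonstrates that the metrics
recover planted structure under the package's own mixing assumptions — not
that real watersheds satisfy those assumptions.

## Recovery experiments and problem sizes

* **Patch-scale recovery** uses a *scale-matched* window: 79 reaches with
  mean incremental area ≈ `A_p/10`, watershed total ≈ 8 patches. The patch
  area is the only length scale in the problem, so each condition is tested
  with the same dimensionless geometry; a fixed watershed would confound the
  patch scale with window effects (too few patches above it, or a decay
  spanning the whole window). The single-split estimator is biased toward
  the geometric middle of the variance decay — with this window the median
  detected threshold sits at ≈ 1.7–2.2 × `A_p`, within the factor-of-3 band
  the experiment checks, and roughly a quarter to a third of seeds yield a
  significant detection (the median is taken over detected runs).
* **Sign recovery** uses 39-site watersheds, `k_r = ±0.1`, 50 seeds per
  sign.
* **Stability recovery** uses a fine-grained design (119 sites, 3 km²
  patches): nested sites share upstream sources, so coarse patches would
  leave only a handful of effectively independent observations and a noisy
  `r_s`; the fine-grained field isolates the copula parameter. Medians over
  20 seeds land within ±0.15 of the induced value.
* **Type-I calibration** uses 200 seeds of i.i.d. noise at n = 40 with 999
  permutations each (vectorised; runs in under a second).

These sizes keep the full test suite under ~10 s while leaving comfortable
statistical margins.

## Numerical choices and degenerate inputs

Variance floor 1e−12 in the LR; smallest-`k` tie-break; area-nesting checks
at 1e−9 relative tolerance; zero-variance series, < 2 sites, missing or
zero outlet concentrations, < 3 stability pairs, and zero-variance seasons
are explicit typed errors rather than NaNs. The pipeline derives one
independent permutation seed per watershed × season × solute from the run
seed via seed-sequence spawning, writes tables at 6 significant digits with
SHA-256 checksums in a manifest, stages output atomically (no partial
reports), and refuses to overwrite a non-empty directory unless forced —
and then only if it looks like a previous report.

## Known limitations

* One change point in variance only — no multiple-segment models, no
  change-in-mean detection, no variograms.
* The threshold estimator's mid-decay bias (above) means detected scales are
  comparative rather than sharp estimates; interpret within ~×2–3.
* Leverage is concentration-based; with no discharge data it cannot be
  turned into fluxes, and the uniform-runoff assumption is untested in any
  given field watershed.
* The `<LOD` policy (LOD/2, flagged, included) is one defensible choice;
  sensitivity to it should be checked on real data with heavy censoring.
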