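# synoptic

Metrics for **repeated synoptic sampling of watershed chemistry**: given a
near-simultaneous snapshot of solute concentrations (e.g. DOC, NO₃⁻, SRP) at
tens of nested subcatchments within a stream network, repeated across
seasons, the package quantifies

1. **Variance collapse** — the drainage-area scale at which among-site
   variance in scaled concentration drops toward zero, an estimate of the
   characteristic *patch size* of the landscape sources and sinks feeding
   the network;
2. **Subcatchment leverage** — each site's percent influence on outlet
   chemistry,

   `L_i = 100 · ((C_i − C_out)/C_out) · (A_i/A_out)  [%]`,

   whose mean is zero under conservative mixing, positive under net
   in-network removal and negative under net production;
3. **Spatial stability** — the Spearman rank correlation `r_s` of paired
   early- vs late-season concentrations across sites, i.e. whether the
   spatial pattern of sources and sinks persists between campaigns.

It is aimed at watershed biogeochemists and spatial ecologists designing or
analysing synoptic campaigns (Arctic river networks are the motivating
setting), and at anyone who needs a tested, scriptable implementation of
these three metrics with honest significance tests.

Because real synoptic datasets are rarely deposited, the package ships a
first-class **synthetic stream-network generator** (random binary drainage
trees, patch-structured source fields of controllable characteristic area,
area-proportional conservative routing with optional first-order reaction,
and a Gaussian copula controlling cross-season persistence). Every metric is
validated by *parameter recovery* against the truth the generator planted —
see `docs/methods.md` for the model and its assumptions.

## Worked example

```python
import synoptic as sp

# a three-watershed study design (Tundra 42, Lake 41, Alpine 31 sites;
# two seasons; DOC, NO3, SRP), simulated with known truth
configs, params = sp.study_design(seed=42)
dataset, truth = sp.simulate_dataset(configs, solute_params=params)

net = dataset.network("Tundra")
values, ids = [], []
for sid in sorted(net.sites):
    values.append((net.area(sid), net.concentration(sid, "early", "NO3")))
    ids.append(sid)
series = sp.scale_concentrations(values, site_ids=ids,
                                 watershed_id="Tundra", season="early",
                                 solute="NO3")
print(sp.VarianceCollapseModel(series).fit(seed=42).summary())
print(sp.SubcatchmentLeverage(net, "early", "NO3").fit().summary())
print(sp.SpatialStability(net, "NO3", "early", "late").fit().summary())
```

prints

```
Variance collapse change point
==============================
series            Tundra early NO3
n sites           42
max LR statistic  13.22
permutation p     0.031  (999 permutations)
split index       37
threshold area    46.72 km2

Subcatchment leverage
=====================
series          Tundra early NO3
partition       all
n sites         41
mean leverage   +4.569 %  (net removal)
median          +1.684 %
quartiles       [+0.9871, +5.799] %
whiskers        [+0.1839, +12.51] %
points beyond   4

Spatial stability (Spearman)
============================
series      Tundra NO3 (early vs late)
n pairs     42
r_s         0.102
p value     0.5203  [t-approximation]
alpha       0.05
no significant rank correlation (spatial reorganisation)
```

Reading it: ordered by drainage area, the 42 scaled nitrate concentrations
show a statistically significant variance collapse (permutation p = 0.031),
with the split bracketing ~47 km²; the positive mean leverage (+4.6%) says
headwaters carry more nitrate than reaches the outlet — net in-network
uptake (this design plants `k_r = +0.10` for Tundra NO₃⁻, so the sign is
recovered); and the low, non-significant `r_s` reflects the weak seasonal
persistence (ρ = 0.25) planted for this solute: the spatial pattern
reorganised between seasons.

## Command line

```bash
synoptic simulate --seed 1 --out sim/            # chemistry.csv, network.csv, truth.csv
synoptic metrics --chemistry sim/chemistry.csv \
                 --network sim/network.csv --out report/ --seed 1
synoptic all --seed 1 --out run/                 # simulate + metrics
synoptic recover --seed 1 --out recovery/        # parameter-recovery experiments
```

`metrics` accepts any long-format chemistry table
(`site_id, watershed_id, drainage_area_km2, season, solute, concentration`,
with `<LOD` sentinels honoured) plus a two-column `site_id, downstream_id`
edge list, so real field campaigns drop in directly. Reports are delimited
tables plus a checksummed manifest; reruns under the same seed are
byte-identical.

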