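"""Synthetic stream networks with known patch scale, reactivity and stability.

Field synoptic campaigns are expensive and rarely deposited, so every metric
in this package is validated by *parameter recovery* on simulated watersheds
in which the truth is known by construction:

* a random binary drainage network (uniform random pairwise joining of
  subtree roots) whose reaches carry lognormal incremental areas;
* a patch-structured solute source field: contiguous groups of reaches with
  total area ~ ``patch_area_km2`` share a patch mean, plus local noise —
  the characteristic patch scale the variance-collapse detector must find;
* conservative area-proportional routing with optional first-order
  in-network reaction ``k_r`` per reach (+ removal, - production) — the sign
  the mean subcatchment leverage must recover;
* a Gaussian copula with correlation ``rho_season`` tying the two seasons'
  source fields together — the spatial stability the Spearman metric must
  recover.

Everything is deterministic under the config seed.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io import Dataset, SiteRecord, WatershedNetwork

SEASONS = ("early", "late")
SOLUTES = ("DOC", "NO3", "SRP")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic watershed.

    Defaults describe a mid-sized Arctic-style study watershed: ~41 reaches
    (21 headwaters), mean incremental reach area ~2.2 km2 (lognormal with
    mu = 0.47, sigma = 0.8, i.e. median 1.6 km2), total area ~90 km2, source
    patches of 10 km2, patch-to-patch concentration sd four times the
    within-patch sd, and strongly persistent seasonal sources.
    """

    watershed_id: str = "synthetic"
    n_headwaters: int = 21
    area_lognormal_mu: float = 0.47
    area_lognormal_sigma: float = 0.8
    patch_area_km2: float = 10.0
    patch_sd: float = 1.0
    local_sd: float = 0.25
    baseline_concentration: float = 5.0
    k_r: float = 0.0
    rho_season: float = 0.8
    seed: int = 0
    n_sites_sampled: int | None = None

    def validate(self) -> None:
        if self.n_headwaters < 2:
            raise ConfigError("n_headwaters must be >= 2")
        if self.patch_area_km2 <= 0:
            raise ConfigError("patch_area_km2 must be > 0")
        if self.patch_sd < 0 or self.local_sd < 0:
            raise ConfigError("patch_sd and local_sd must be >= 0")
        if self.baseline_concentration <= 0:
            raise ConfigError("baseline_concentration must be > 0")
        if not -1.0 <= self.rho_season <= 1.0:
            raise ConfigError("rho_season must lie in [-1, 1]")
        n_reaches = 2 * self.n_headwaters - 1
        if self.n_sites_sampled is not None and not (
            1 < self.n_sites_sampled <= n_reaches
        ):
            raise ConfigError(
                f"n_sites_sampled must be in (1, {n_reaches}] "
                f"(got {self.n_sites_sampled})"
            )


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_network(config: SimConfig) -> WatershedNetwork:
    """Random binary drainage tree with lognormal incremental reach areas.

    ``n_headwaters`` leaf reaches are joined pairwise (uniformly at random)
    under new junction reaches until a single root — the outlet — remains:
    2n - 1 reaches, every junction binary.  Each reach (junctions included)
    receives its own lognormal incremental drainage area; cumulative areas
    accumulate downstream.
    """
    config.validate()
    rng = _child_rngs(config.seed, 1)[0]
    ws = config.watershed_id
    n = config.n_headwaters

    leaf_ids = [f"{ws}-h{i:03d}" for i in range(1, n + 1)]
    children: dict[str, list[str]] = {sid: [] for sid in leaf_ids}
    roots = list(leaf_ids)
    j = 0
    while len(roots) > 1:
        j += 1
        i1, i2 = sorted(rng.choice(len(roots), size=2, replace=False))
        right = roots.pop(int(i2))
        left = roots.pop(int(i1))
        new = f"{ws}-j{j:03d}"
        children[new] = [left, right]
        roots.append(new)
    outlet = roots[0]

    downstream: dict[str, str | None] = {outlet: None}
    for parent, kids in children.items():
        for k in kids:
            downstream[k] = parent

    order = sorted(children)  # deterministic id order for area draws
    inc = dict(zip(order, rng.lognormal(
        config.area_lognormal_mu, config.area_lognormal_sigma, size=len(order)
    )))

    # cumulative areas by upstream-first accumulation
    cum: dict[str, float] = {}

    def _post(sid: str) -> float:
        total = inc[sid] + sum(_post(c) for c in children[sid])
        cum[sid] = total
        return total

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 4 * len(order) + 100))
    try:
        _post(outlet)
    finally:
        sys.setrecursionlimit(old_limit)

    sites = {
        sid: SiteRecord(
            site_id=sid,
            watershed_id=ws,
            drainage_area_km2=float(cum[sid]),
            downstream_id=downstream[sid],
        )
        for sid in order
    }
    return WatershedNetwork(ws, sites)


def partition_patches(
    network: WatershedNetwork, patch_area_km2: float
) -> dict[str, int]:
    """Group reaches into contiguous source patches of ~``patch_area_km2``.

    Greedy post-order aggregation: climbing down from the leaves, open
    reaches accumulate (one tributary at a time at junctions) and a patch is
    closed as soon as the accumulated incremental area first reaches the
    target; open reaches remaining at the outlet close as a final (possibly
    undersized) patch.  Every reach belongs to exactly one patch, and every
    patch except possibly the last has area in ``[patch_area_km2,
    patch_area_km2 + max(patch_area_km2, max incremental area))`` — the
    overshoot is bounded by the largest indivisible chunk merged in (an
    almost-full tributary or a single large reach).
    """
    if patch_area_km2 <= 0:
        raise ConfigError("patch_area_km2 must be > 0")
    if patch_area_km2 >= network.total_area_km2:
        _warnings.warn(
            f"patch_area_km2={patch_area_km2} >= watershed area "
            f"{network.total_area_km2:.3g}; the whole watershed is one patch",
            stacklevel=2,
        )
    patch_of: dict[str, int] = {}
    next_id = 0
    open_reaches: dict[str, list[str]] = {}  # per-site open set from its subtree
    open_area: dict[str, float] = {}
    for sid in network.postorder():
        reaches: list[str] = []
        area = 0.0
        chunks = [
            (open_reaches.pop(c), open_area.pop(c)) for c in network.children[sid]
        ]
        chunks.append(([sid], network.incremental_area[sid]))
        for chunk_reaches, chunk_area in chunks:
            reaches.extend(chunk_reaches)
            area += chunk_area
            if area >= patch_area_km2:
                for r in reaches:
                    patch_of[r] = next_id
                next_id += 1
                reaches, area = [], 0.0
        open_reaches[sid] = reaches
        open_area[sid] = area
    leftovers = open_reaches[network.outlet_id]
    if leftovers:
        for r in leftovers:
            patch_of[r] = next_id
    return patch_of


def generate_source_field(
    network: WatershedNetwork,
    patches: Mapping[str, int],
    config: SimConfig,
    patch_noise: np.ndarray,
    local_noise: np.ndarray,
) -> dict[str, float]:
    """Local source concentration per reach from explicit standard-normal draws.

    Patch means are ``baseline + patch_sd * u_p`` (one draw per patch id in
    sorted order); each reach adds ``local_sd * e_i`` (draws in sorted site
    order) and is truncated at zero — solute concentrations cannot be
    negative.
    """
    patch_ids = sorted(set(patches.values()))
    if len(patch_noise) != len(patch_ids):
        raise ConfigError(
            f"need {len(patch_ids)} patch draws (got {len(patch_noise)})"
        )
    site_ids = sorted(network.sites)
    if len(local_noise) != len(site_ids):
        raise ConfigError(
            f"need {len(site_ids)} local draws (got {len(local_noise)})"
        )
    mean_of = {
        p: config.baseline_concentration + config.patch_sd * float(u)
        for p, u in zip(patch_ids, patch_noise)
    }
    return {
        sid: max(0.0, mean_of[patches[sid]] + config.local_sd * float(e))
        for sid, e in zip(site_ids, local_noise)
    }


def generate_source_fields(
    network: WatershedNetwork,
    patches: Mapping[str, int],
    config: SimConfig,
    rng: np.random.Generator,
    seasons: Sequence[str] = SEASONS,
) -> dict[str, dict[str, float]]:
    """Per-season source fields sharing draws through a Gaussian copula.

    Season 1 uses fresh standard-normal draws; each later season mixes them
    with independent innovations at correlation ``rho_season``, so the
    underlying (patch, local) fields are jointly Gaussian across seasons with
    the configured correlation.
    """
    n_p = len(set(patches.values()))
    n_s = len(network.sites)
    rho = config.rho_season
    u0 = rng.standard_normal(n_p)
    e0 = rng.standard_normal(n_s)
    fields: dict[str, dict[str, float]] = {}
    for i, season in enumerate(seasons):
        if i == 0:
            u, e = u0, e0
        else:
            u = rho * u0 + np.sqrt(1 - rho**2) * rng.standard_normal(n_p)
            e = rho * e0 + np.sqrt(1 - rho**2) * rng.standard_normal(n_s)
        fields[season] = generate_source_field(network, patches, config, u, e)
    return fields


def route_and_mix(
    network: WatershedNetwork,
    sources: Mapping[str, float],
    k_r: float = 0.0,
) -> dict[str, float]:
    """Area-proportional conservative mixing with first-order reaction.

    Post-order traversal: each reach mixes its tributaries' exports with its
    own incremental water (all weighted by drainage area, i.e. uniform
    specific discharge), then applies ``exp(-k_r)`` — removal for positive
    ``k_r``, production for negative.  With ``k_r = 0`` every concentration
    is exactly the area-weighted mean of the upstream local sources.
    """
    conc: dict[str, float] = {}
    for sid in network.postorder():
        mass = network.incremental_area[sid] * sources[sid]
        for c in network.children[sid]:
            mass += network.area(c) * conc[c]
        conc[sid] = (mass / network.area(sid)) * np.exp(-k_r)
    return conc


def simulate_dataset(
    configs: Sequence[SimConfig],
    seasons: Sequence[str] = SEASONS,
    solutes: Sequence[str] = SOLUTES,
    solute_params: Mapping | None = None,
) -> tuple[Dataset, pd.DataFrame]:
    """Simulate a complete multi-watershed synoptic Dataset plus its truth.

    ``solute_params`` optionally overrides per-solute parameters, keyed by
    ``solute`` or ``(watershed_id, solute)`` (the latter wins), each value a
    dict of :class:`SimConfig` field overrides (e.g. ``{"k_r": 0.1}``).
    Returns the Dataset (sampled sites only, outlet always included, topology
    attached) and a truth table with one row per watershed x solute.
    """
    solute_params = solute_params or {}
    sites: dict[str, dict[str, SiteRecord]] = {}
    networks: dict[str, WatershedNetwork] = {}
    truth_rows = []
    for config in configs:
        config.validate()
        if config.n_headwaters < 8:
            raise ConfigError(
                "simulate_dataset requires n_headwaters >= 8 per watershed "
                "(metrics need network structure to be meaningful)"
            )
        ws = config.watershed_id
        if ws in sites:
            raise ConfigError(f"duplicate watershed_id {ws!r}")
        full = generate_network(config)
        rngs = _child_rngs(config.seed, len(solutes) + 1)
        sample_rng = rngs[0]

        # sample the synoptic site subset once per watershed
        all_ids = sorted(full.sites)
        n_sample = config.n_sites_sampled or len(all_ids)
        non_outlet = [s for s in all_ids if s != full.outlet_id]
        chosen = sample_rng.choice(
            len(non_outlet), size=n_sample - 1, replace=False
        )
        sampled = sorted([non_outlet[int(i)] for i in chosen] + [full.outlet_id])
        sampled_set = set(sampled)

        # contract topology onto the sampled sites: nearest sampled ancestor
        def _sampled_downstream(sid: str) -> str | None:
            cur = full.sites[sid].downstream_id
            while cur is not None and cur not in sampled_set:
                cur = full.sites[cur].downstream_id
            return cur

        ws_records = {
            sid: SiteRecord(
                site_id=sid,
                watershed_id=ws,
                drainage_area_km2=full.area(sid),
                downstream_id=_sampled_downstream(sid),
            )
            for sid in sampled
        }

        for solute, rng in zip(solutes, rngs[1:]):
            overrides = dict(solute_params.get(solute, {}))
            overrides.update(solute_params.get((ws, solute), {}))
            cfg = replace(config, **overrides) if overrides else config
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                patches = partition_patches(full, cfg.patch_area_km2)
            fields = generate_source_fields(full, patches, cfg, rng, seasons)
            for season in seasons:
                routed = route_and_mix(full, fields[season], cfg.k_r)
                for sid in sampled:
                    ws_records[sid].concentrations[(season, solute)] = float(
                        routed[sid]
                    )
            truth_rows.append(
                {
                    "watershed_id": ws,
                    "solute": solute,
                    "patch_area_km2": cfg.patch_area_km2,
                    "k_r": cfg.k_r,
                    "rho_season": cfg.rho_season,
                    "n_patches": len(set(patches.values())),
                    "n_sites": len(sampled),
                    "total_area_km2": full.total_area_km2,
                    "seed": config.seed,
                }
            )
        sites[ws] = ws_records
        networks[ws] = WatershedNetwork(ws, ws_records)

    dataset = Dataset(
        sites=sites,
        seasons=list(seasons),
        solutes=list(solutes),
        networks=networks,
        provenance="synthetic",
    )
    return dataset, pd.DataFrame(truth_rows)


def study_design(seed: int = 0) -> tuple[list[SimConfig], dict]:
    """Three-watershed design emulating an Arctic repeated-synoptic study.

    Alpine (31 sites), Lake (41) and Tundra (42; one reach left unsampled),
    two seasons, three solutes — 114 sampled sites in total.  Per-solute
    patch scales span the 3-30 km2 range; DOC is a weak net producer
    everywhere, nitrate is taken up in the tundra watershed, and seasonal
    persistence is high for DOC in the tundra/alpine watersheds but low in
    the lake-dominated one.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    configs = [
        SimConfig(watershed_id="Tundra", n_headwaters=22, n_sites_sampled=42,
                  seed=seeds[0]),
        SimConfig(watershed_id="Lake", n_headwaters=21, n_sites_sampled=41,
                  seed=seeds[1]),
        SimConfig(watershed_id="Alpine", n_headwaters=16, n_sites_sampled=31,
                  seed=seeds[2]),
    ]
    solute_params = {
        ("Tundra", "DOC"): {"patch_area_km2": 19.0, "k_r": -0.02, "rho_season": 0.85},
        ("Tundra", "NO3"): {"patch_area_km2": 20.0, "k_r": 0.10, "rho_season": 0.25},
        ("Tundra", "SRP"): {"patch_area_km2": 28.0, "k_r": -0.05, "rho_season": 0.30},
        ("Lake", "DOC"): {"patch_area_km2": 8.0, "k_r": -0.03, "rho_season": 0.10},
        ("Lake", "NO3"): {"patch_area_km2": 6.0, "k_r": 0.02, "rho_season": 0.35},
        ("Lake", "SRP"): {"patch_area_km2": 10.0, "k_r": 0.05, "rho_season": 0.55},
        ("Alpine", "DOC"): {"patch_area_km2": 10.0, "k_r": -0.005, "rho_season": 0.65},
        ("Alpine", "NO3"): {"patch_area_km2": 4.0, "k_r": 0.005, "rho_season": 0.45},
        ("Alpine", "SRP"): {"patch_area_km2": 12.0, "k_r": -0.04, "rho_season": 0.30},
    }
    return configs, solute_params
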