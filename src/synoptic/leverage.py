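"""Subcatchment leverage and seasonal spatial stability.

**Leverage** quantifies each subcatchment's percent influence on outlet
chemistry: the site's concentration deviation from the outlet weighted by its
drainage area relative to the outlet,

    L_i = 100 * ((C_i - C_out) / C_out) * (A_i / A_out)   [%]

Under conservative mixing with area-proportional runoff (uniform specific
discharge — the only discharge model used here, since per-site discharge is
unmeasured in synoptic campaigns) the area-weighted deviations cancel, so
leverage averages to zero over a disjoint partition of the watershed.  A
positive *mean* leverage means headwaters carry more solute than reaches the
outlet — net in-network removal/uptake; a negative mean means net in-network
production.

Two partition modes are provided:

* ``"all"`` (default) — every non-outlet site with its *cumulative* drainage
  area, the form behind the per-site maps and box plots.  Nested mainstem
  sites overlap, so the zero-mean contract holds only approximately.
* ``"incremental"`` — every site weighted by its *incremental* area, with the
  concentration of the site's own incremental water recovered by mass
  balance from its upstream neighbours,

      Chat_i = (A_i C_i - sum_children A_c C_c) / a_i .

  The incremental areas partition the watershed exactly, and under
  conservative routing ``sum_i a_i Chat_i = A_out C_out`` telescopes, so the
  mean leverage over this partition is zero to machine precision — the
  conservation contract the test-suite closes.  For unmixed headwater sites
  ``Chat_i = C_i``.

**Spatial stability** asks whether the spatial pattern of concentrations
persists between sampling campaigns: the Spearman rank correlation of paired
early- vs late-season concentrations across sites.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import (
    InsufficientDataError,
    MissingOutletError,
    UndefinedCorrelationError,
)
from .io import WatershedNetwork


# ---------------------------------------------------------------------------
# leverage
# ---------------------------------------------------------------------------


@dataclass
class LeverageSummary:
    """Box-plot statistics of per-site leverage (type-7 quantiles)."""

    n: int
    mean: float
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[float]


@dataclass
class LeverageResult:
    """Per-site leverage plus the watershed-season summary."""

    watershed_id: str
    season: str
    solute: str
    partition: str
    site_ids: list[str]
    areas_km2: list[float]
    leverage_pct: list[float]
    summary_stats: LeverageSummary = field(default=None)  # set in fit()

    def summary(self) -> str:
        s = self.summary_stats
        return "\n".join(
            [
                "Subcatchment leverage",
                "=====================",
                f"series          {self.watershed_id} {self.season} {self.solute}",
                f"partition       {self.partition}",
                f"n sites         {s.n}",
                f"mean leverage   {s.mean:+.4g} %"
                + ("  (net removal)" if s.mean > 0 else "  (net production)" if s.mean < 0 else ""),
                f"median          {s.median:+.4g} %",
                f"quartiles       [{s.q1:+.4g}, {s.q3:+.4g}] %",
                f"whiskers        [{s.whisker_low:+.4g}, {s.whisker_high:+.4g}] %",
                f"points beyond   {len(s.outliers)}",
            ]
        )


def mean_leverage_summary(leverage_pct) -> LeverageSummary:
    """Mean, median, quartiles and 1.5 x IQR whiskers of leverage values.

    Quartiles use linear interpolation (type 7); whiskers are the most
    extreme observations within 1.5 x IQR of the quartiles, and values beyond
    them are returned explicitly.
    """
    v = np.asarray(list(leverage_pct), dtype=float)
    if v.size == 0:
        raise InsufficientDataError("no leverage values to summarise")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = sorted(v[(v < lo_fence) | (v > hi_fence)].tolist())
    return LeverageSummary(
        n=int(v.size),
        mean=float(v.mean()),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=outliers,
    )


class SubcatchmentLeverage:
    """Leverage model for one watershed x season x solute.

    Parameters
    ----------
    network
        Validated :class:`~synoptic.io.WatershedNetwork` with concentrations.
    season, solute
        Which concentration cells to analyse.
    partition
        ``"all"`` (nested, cumulative areas; outlet excluded from the
        summary) or ``"incremental"`` (disjoint partition for the
        conservation contract; requires complete concentrations).
    """

    def __init__(
        self,
        network: WatershedNetwork,
        season: str,
        solute: str,
        partition: str = "all",
    ):
        if partition not in {"all", "incremental"}:
            raise ValueError(f"unknown partition mode {partition!r}")
        self.network = network
        self.season = season
        self.solute = solute
        self.partition = partition

    def fit(self) -> LeverageResult:
        net, season, solute = self.network, self.season, self.solute
        c_out = net.concentration(net.outlet_id, season, solute)
        if c_out is None:
            raise MissingOutletError(
                f"watershed {net.watershed_id!r}: outlet {net.outlet_id!r} has no "
                f"{season}/{solute} concentration"
            )
        if c_out <= 0:
            raise MissingOutletError(
                f"watershed {net.watershed_id!r}: outlet {season}/{solute} "
                f"concentration is {c_out}; leverage (relative to the outlet) "
                "is undefined"
            )
        a_out = net.total_area_km2

        site_ids: list[str] = []
        areas: list[float] = []
        lev: list[float] = []
        if self.partition == "all":
            for sid in sorted(net.sites):
                c = net.concentration(sid, season, solute)
                if c is None:
                    continue
                a = net.area(sid)
                site_ids.append(sid)
                areas.append(a)
                lev.append(100.0 * ((c - c_out) / c_out) * (a / a_out))
            summary_vals = [
                l for sid, l in zip(site_ids, lev) if sid != net.outlet_id
            ]
        else:
            # de-mix each site's own incremental water by mass balance; the
            # identity needs every site's concentration, so missing cells are
            # an error here rather than silently dropped
            for sid in sorted(net.sites):
                if net.concentration(sid, season, solute) is None:
                    raise MissingOutletError(
                        f"watershed {net.watershed_id!r}: site {sid!r} has no "
                        f"{season}/{solute} concentration; the incremental "
                        "partition requires complete data"
                    )
            for sid in sorted(net.sites):
                a_inc = net.incremental_area[sid]
                if a_inc <= 0:
                    continue  # pure junction: no incremental water of its own
                c = net.concentration(sid, season, solute)
                mass = net.area(sid) * c
                for child in net.children[sid]:
                    mass -= net.area(child) * net.concentration(child, season, solute)
                c_hat = mass / a_inc
                site_ids.append(sid)
                areas.append(a_inc)
                lev.append(100.0 * ((c_hat - c_out) / c_out) * (a_inc / a_out))
            summary_vals = lev
        if not summary_vals:
            raise InsufficientDataError(
                f"watershed {net.watershed_id!r}: no non-outlet sites with "
                f"{season}/{solute} concentrations"
            )
        result = LeverageResult(
            watershed_id=net.watershed_id,
            season=season,
            solute=solute,
            partition=self.partition,
            site_ids=site_ids,
            areas_km2=areas,
            leverage_pct=lev,
        )
        result.summary_stats = mean_leverage_summary(summary_vals)
        return result


def subcatchment_leverage(
    network: WatershedNetwork,
    season: str,
    solute: str,
    partition: str = "all",
) -> LeverageResult:
    """Functional wrapper: fit :class:`SubcatchmentLeverage`."""
    return SubcatchmentLeverage(network, season, solute, partition).fit()


# ---------------------------------------------------------------------------
# spatial stability
# ---------------------------------------------------------------------------


@dataclass
class StabilityResult:
    """Spearman rank stability of the spatial concentration pattern."""

    watershed_id: str
    solute: str
    season_a: str
    season_b: str
    n_pairs: int
    r_s: float
    p_value: float
    significant: bool
    alpha: float
    method: str  # "t-approximation" or "exact permutation"
    pairs: list[tuple[str, float, float]] = field(default_factory=list)

    def summary(self) -> str:
        verdict = (
            "stable spatial pattern"
            if self.significant and self.r_s > 0
            else "no significant rank correlation (spatial reorganisation)"
            if not self.significant
            else "significant pattern reversal"
        )
        return "\n".join(
            [
                "Spatial stability (Spearman)",
                "============================",
                f"series      {self.watershed_id} {self.solute} "
                f"({self.season_a} vs {self.season_b})",
                f"n pairs     {self.n_pairs}",
                f"r_s         {self.r_s:.3f}",
                f"p value     {self.p_value:.4g}  [{self.method}]",
                f"alpha       {self.alpha}",
                verdict,
            ]
        )


def _exact_spearman_p(x_rank: np.ndarray, y_rank: np.ndarray) -> float:
    """Two-sided exact permutation p-value for Spearman r (n <= 10).

    Enumerates all pairings of the (possibly tied, average) ranks in chunks;
    the statistic is the Pearson correlation of the rank vectors, which
    reduces to a single dot product because the permuted vector's mean and
    variance are permutation-invariant.
    """
    n = len(x_rank)
    xc = x_rank - x_rank.mean()
    yc = y_rank - y_rank.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    r_obs = float(xc @ yc) / denom
    count = 0
    total = 0
    chunk: list[tuple[int, ...]] = []
    chunk_size = 200_000
    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == chunk_size:
            r = (yc[np.array(chunk)] @ xc) / denom
            count += int(np.count_nonzero(np.abs(r) >= abs(r_obs) - 1e-12))
            total += len(chunk)
            chunk = []
    if chunk:
        r = (yc[np.array(chunk)] @ xc) / denom
        count += int(np.count_nonzero(np.abs(r) >= abs(r_obs) - 1e-12))
        total += len(chunk)
    return count / total


class SpatialStability:
    """Rank-correlation stability model for one watershed x solute."""

    def __init__(
        self,
        network: WatershedNetwork,
        solute: str,
        season_a: str,
        season_b: str,
        alpha: float = 0.05,
    ):
        self.network = network
        self.solute = solute
        self.season_a = season_a
        self.season_b = season_b
        self.alpha = alpha

    def fit(self) -> StabilityResult:
        net = self.network
        pairs = []
        for sid in sorted(net.sites):
            ca = net.concentration(sid, self.season_a, self.solute)
            cb = net.concentration(sid, self.season_b, self.solute)
            if ca is not None and cb is not None:
                pairs.append((sid, float(ca), float(cb)))
        n = len(pairs)
        if n < 3:
            raise InsufficientDataError(
                f"watershed {net.watershed_id!r}: only {n} paired sites for "
                f"{self.solute} ({self.season_a} vs {self.season_b}); need >= 3"
            )
        x = np.array([p[1] for p in pairs])
        y = np.array([p[2] for p in pairs])
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise UndefinedCorrelationError(
                f"watershed {net.watershed_id!r}: zero variance in one season "
                f"for {self.solute}; rank correlation undefined"
            )
        rx = stats.rankdata(x)  # average ranks for ties
        ry = stats.rankdata(y)
        r_s = float(np.corrcoef(rx, ry)[0, 1])
        if n > 10:
            # two-sided t-approximation, t = r sqrt((n-2)/(1-r^2))
            _, p = stats.spearmanr(x, y)
            p = float(p)
            method = "t-approximation"
        else:
            p = _exact_spearman_p(rx, ry)
            method = "exact permutation"
        return StabilityResult(
            watershed_id=net.watershed_id,
            solute=self.solute,
            season_a=self.season_a,
            season_b=self.season_b,
            n_pairs=n,
            r_s=r_s,
            p_value=p,
            significant=bool(p <= self.alpha),
            alpha=self.alpha,
            method=method,
            pairs=pairs,
        )


def spatial_stability(
    network: WatershedNetwork,
    solute: str,
    season_a: str,
    season_b: str,
    alpha: float = 0.05,
) -> StabilityResult:
    """Functional wrapper: fit :class:`SpatialStability`."""
    return SpatialStability(network, solute, season_a, season_b, alpha).fit()
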