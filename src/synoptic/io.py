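"""Data model and delimited-table IO for synoptic watershed-chemistry datasets.

A dataset couples two plain-text tables:

* a **chemistry table** in long format — one row per (site, season, solute)
  with the site's watershed and cumulative drainage area repeated on each row;
* a **network table** — a two-column edge list (``site_id, downstream_id``)
  linking every site to the next site downstream; an empty ``downstream_id``
  marks the watershed outlet.

Concentrations below the detection limit may be recorded as ``<LOD`` sentinels
(e.g. ``<0.5``); they are substituted with LOD/2 and flagged so that every
site keeps its full complement of cells while remaining auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .exceptions import (
    DuplicateMeasurementError,
    NestingError,
    SchemaError,
    TopologyError,
    ValidationError,
)

CHEMISTRY_COLUMNS = (
    "site_id",
    "watershed_id",
    "drainage_area_km2",
    "season",
    "solute",
    "concentration",
)
NETWORK_COLUMNS = ("site_id", "downstream_id")

#: relative tolerance for the area-accounting identity
AREA_RTOL = 1e-9


@dataclass
class SiteRecord:
    """One sampling location within a watershed.

    ``drainage_area_km2`` is the cumulative (total upstream) area at the site.
    ``downstream_id`` is ``None`` for the watershed outlet. ``concentrations``
    maps ``(season, solute)`` to a non-negative value; keys absent from the
    mapping are explicitly missing cells. ``below_lod`` records cells whose
    stored value is LOD/2, substituted from a ``<LOD`` sentinel.
    """

    site_id: str
    watershed_id: str
    drainage_area_km2: float
    downstream_id: str | None = None
    concentrations: dict[tuple[str, str], float] = field(default_factory=dict)
    below_lod: set[tuple[str, str]] = field(default_factory=set)

    def concentration(self, season: str, solute: str) -> float | None:
        return self.concentrations.get((season, solute))


class WatershedNetwork:
    """A rooted tree of nested sampling sites; the outlet is the root.

    Stores both the cumulative drainage area of every site (as sampled) and
    the *incremental* area ``a_i = A_i - sum(A_children)`` — the portion of a
    site's catchment not already drained by an upstream site.  The incremental
    areas form a disjoint partition of the watershed, which is what the
    conservation contract of subcatchment leverage is tested on.
    """

    def __init__(self, watershed_id: str, sites: Mapping[str, SiteRecord]):
        self.watershed_id = watershed_id
        self.sites: dict[str, SiteRecord] = dict(sites)
        self._validate_and_index()

    # -- construction -----------------------------------------------------

    def _validate_and_index(self) -> None:
        ws = self.watershed_id
        roots = [s for s in self.sites.values() if s.downstream_id is None]
        if len(roots) != 1:
            raise TopologyError(
                f"watershed {ws!r} must have exactly one outlet "
                f"(found {len(roots)}: {sorted(s.site_id for s in roots)})"
            )
        self.outlet_id = roots[0].site_id

        g = nx.DiGraph()
        g.add_nodes_from(self.sites)
        for s in self.sites.values():
            if s.downstream_id is not None:
                if s.downstream_id not in self.sites:
                    raise TopologyError(
                        f"watershed {ws!r}: site {s.site_id!r} drains to unknown "
                        f"site {s.downstream_id!r}"
                    )
                g.add_edge(s.site_id, s.downstream_id)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            raise TopologyError(f"watershed {ws!r}: cycle in network: {cycle}")
        if not nx.is_weakly_connected(g):
            raise TopologyError(f"watershed {ws!r}: network is not connected")

        self.children: dict[str, list[str]] = {sid: [] for sid in self.sites}
        for s in self.sites.values():
            if s.downstream_id is not None:
                self.children[s.downstream_id].append(s.site_id)
        for kids in self.children.values():
            kids.sort()

        self.incremental_area: dict[str, float] = {}
        for sid, rec in self.sites.items():
            down = rec.downstream_id
            if down is not None and rec.drainage_area_km2 > self.sites[down].drainage_area_km2 * (1 + AREA_RTOL):
                raise NestingError(
                    f"watershed {ws!r}: site {sid!r} area {rec.drainage_area_km2} "
                    f"exceeds downstream site {down!r} area "
                    f"{self.sites[down].drainage_area_km2}"
                )
            child_sum = sum(self.sites[c].drainage_area_km2 for c in self.children[sid])
            inc = rec.drainage_area_km2 - child_sum
            if inc < -AREA_RTOL * max(rec.drainage_area_km2, 1.0):
                raise NestingError(
                    f"watershed {ws!r}: children of {sid!r} drain {child_sum} km2, "
                    f"more than the site's own {rec.drainage_area_km2} km2"
                )
            self.incremental_area[sid] = max(inc, 0.0)

    # -- accessors --------------------------------------------------------

    def area(self, site_id: str) -> float:
        return self.sites[site_id].drainage_area_km2

    @property
    def total_area_km2(self) -> float:
        return self.area(self.outlet_id)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def leaves(self) -> list[str]:
        return sorted(sid for sid, kids in self.children.items() if not kids)

    def postorder(self) -> list[str]:
        """Site ids with every site preceded by all of its upstream sites."""
        order: list[str] = []
        stack: list[tuple[str, bool]] = [(self.outlet_id, False)]
        while stack:
            sid, expanded = stack.pop()
            if expanded:
                order.append(sid)
            else:
                stack.append((sid, True))
                for c in reversed(self.children[sid]):
                    stack.append((c, False))
        return order

    def concentration(self, site_id: str, season: str, solute: str) -> float | None:
        return self.sites[site_id].concentration(season, solute)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<WatershedNetwork {self.watershed_id!r}: {self.n_sites} sites, "
            f"{self.total_area_km2:.3g} km2, outlet {self.outlet_id!r}>"
        )


@dataclass
class Dataset:
    """All watersheds of one study: site records plus (optional) topology.

    ``sites`` maps watershed id -> site id -> :class:`SiteRecord`.  Until
    :func:`read_network` attaches topology, ``networks`` is empty.
    """

    sites: dict[str, dict[str, SiteRecord]]
    seasons: list[str]
    solutes: list[str]
    networks: dict[str, WatershedNetwork] = field(default_factory=dict)
    provenance: str = ""

    @property
    def watershed_ids(self) -> list[str]:
        return sorted(self.sites)

    def network(self, watershed_id: str) -> WatershedNetwork:
        try:
            return self.networks[watershed_id]
        except KeyError:
            raise TopologyError(
                f"no network attached for watershed {watershed_id!r}; "
                "call read_network first"
            ) from None

    def n_cells(self) -> int:
        return sum(
            len(rec.concentrations)
            for ws in self.sites.values()
            for rec in ws.values()
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _parse_concentration(raw) -> tuple[float | None, bool]:
    """Return (value, below_lod). '<x' sentinels become (x/2, True)."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None, False
    s = str(raw).strip()
    if s == "" or s.lower() in {"na", "nan"}:
        return None, False
    if s.startswith("<"):
        lod = float(s[1:])
        if lod <= 0:
            raise ValidationError(f"non-positive detection limit in {raw!r}")
        return lod / 2.0, True
    return float(s), False


def read_chemistry_table(path, sep: str = ",") -> Dataset:
    """Read a long-format chemistry table into a (topology-less) Dataset.

    Required columns: ``site_id, watershed_id, drainage_area_km2, season,
    solute, concentration``.  Duplicate (site, season, solute) rows are an
    error; empty concentration cells are recorded as missing, never as zero.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in CHEMISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"chemistry table {path} is missing required column(s): "
            + ", ".join(missing)
        )

    sites: dict[str, dict[str, SiteRecord]] = {}
    seasons: list[str] = []
    solutes: list[str] = []
    seen: set[tuple[str, str, str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        ws = row.watershed_id.strip()
        sid = row.site_id.strip()
        season = row.season.strip()
        solute = row.solute.strip()
        if not ws or not sid:
            raise ValidationError(f"row {i}: empty site_id or watershed_id")
        try:
            area = float(row.drainage_area_km2)
        except ValueError as exc:
            raise ValidationError(
                f"row {i}: unreadable drainage_area_km2 {row.drainage_area_km2!r}"
            ) from exc
        if not area > 0:
            raise ValidationError(
                f"row {i}: drainage_area_km2 must be > 0 for site {sid!r} "
                f"(got {area})"
            )
        key = (ws, sid, season, solute)
        if key in seen:
            raise DuplicateMeasurementError(
                f"row {i}: duplicate measurement for site {sid!r}, "
                f"season {season!r}, solute {solute!r} in watershed {ws!r}"
            )
        seen.add(key)

        rec = sites.setdefault(ws, {}).get(sid)
        if rec is None:
            rec = SiteRecord(site_id=sid, watershed_id=ws, drainage_area_km2=area)
            sites[ws][sid] = rec
        elif not math.isclose(rec.drainage_area_km2, area, rel_tol=AREA_RTOL):
            raise ValidationError(
                f"row {i}: site {sid!r} has inconsistent drainage areas "
                f"({rec.drainage_area_km2} vs {area})"
            )
        value, flagged = _parse_concentration(row.concentration)
        if value is not None:
            if value < 0:
                raise ValidationError(
                    f"row {i}: negative concentration {value} for site {sid!r}"
                )
            rec.concentrations[(season, solute)] = value
            if flagged:
                rec.below_lod.add((season, solute))
        if season not in seasons:
            seasons.append(season)
        if solute not in solutes:
            solutes.append(solute)

    return Dataset(sites=sites, seasons=seasons, solutes=solutes, provenance=str(path))


def read_network(path, dataset: Dataset, sep: str = ",") -> Dataset:
    """Attach validated rooted-tree topology from an edge-list table.

    The table has columns ``site_id, downstream_id``; an empty downstream id
    marks the outlet.  Every site of the chemistry table must appear.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in NETWORK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"network table {path} is missing required column(s): "
            + ", ".join(missing)
        )

    downstream: dict[str, str | None] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        sid = row.site_id.strip()
        down = row.downstream_id.strip() or None
        if sid in downstream:
            raise TopologyError(f"row {i}: site {sid!r} listed twice in edge table")
        downstream[sid] = down

    networks: dict[str, WatershedNetwork] = {}
    for ws in dataset.watershed_ids:
        ws_sites = dataset.sites[ws]
        absent = sorted(set(ws_sites) - set(downstream))
        if absent:
            raise TopologyError(
                f"watershed {ws!r}: sites missing from network table: {absent}"
            )
        for sid, rec in ws_sites.items():
            rec.downstream_id = downstream[sid]
        networks[ws] = WatershedNetwork(ws, ws_sites)
    dataset.networks = networks
    return dataset


def validate_dataset(dataset: Dataset, min_sites: int = 10) -> list[str]:
    """Return data-quality warnings (never raises).

    Flags watershed × season × solute slices with fewer than ``min_sites``
    measured sites (change-point power), watersheds with > 20% missing cells,
    and zero-variance slices (a solute constant across all sites).
    """
    warnings: list[str] = []
    for ws in dataset.watershed_ids:
        recs = list(dataset.sites[ws].values())
        n_sites = len(recs)
        n_possible = n_sites * len(dataset.seasons) * len(dataset.solutes)
        n_present = sum(len(r.concentrations) for r in recs)
        if n_possible and (n_possible - n_present) / n_possible > 0.20:
            warnings.append(
                f"watershed {ws!r}: {n_possible - n_present}/{n_possible} "
                "concentration cells missing (>20%)"
            )
        for season in dataset.seasons:
            for solute in dataset.solutes:
                vals = [
                    r.concentration(season, solute)
                    for r in recs
                    if r.concentration(season, solute) is not None
                ]
                if len(vals) < min_sites:
                    warnings.append(
                        f"watershed {ws!r}, {season}/{solute}: only {len(vals)} "
                        f"measured sites (< {min_sites}); change-point power is low"
                    )
                elif len(set(vals)) == 1:
                    warnings.append(
                        f"watershed {ws!r}, {season}/{solute}: concentration is "
                        "constant across sites (zero variance)"
                    )
    return warnings


# ---------------------------------------------------------------------------
# writers (canonical ordering so write -> read -> write is byte-stable)
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    # shortest representation that round-trips the float exactly
    return repr(float(x))


def write_chemistry_table(dataset: Dataset, path, sep: str = ",") -> None:
    """Write the chemistry table in canonical row order (UTF-8, header row)."""
    rows = []
    for ws in dataset.watershed_ids:
        for sid in sorted(dataset.sites[ws]):
            rec = dataset.sites[ws][sid]
            for season in dataset.seasons:
                for solute in dataset.solutes:
                    key = (season, solute)
                    if key in rec.concentrations:
                        v = rec.concentrations[key]
                        cell = "<" + _fmt(2 * v) if key in rec.below_lod else _fmt(v)
                    else:
                        cell = ""
                    rows.append(
                        (sid, ws, _fmt(rec.drainage_area_km2), season, solute, cell)
                    )
    pd.DataFrame(rows, columns=list(CHEMISTRY_COLUMNS)).to_csv(
        path, sep=sep, index=False
    )


def write_network(dataset: Dataset, path, sep: str = ",") -> None:
    """Write the edge list (outlets get an empty downstream cell)."""
    rows = []
    for ws in dataset.watershed_ids:
        for sid in sorted(dataset.sites[ws]):
            rec = dataset.sites[ws][sid]
            rows.append((sid, rec.downstream_id or ""))
    pd.DataFrame(rows, columns=list(NETWORK_COLUMNS)).to_csv(path, sep=sep, index=False)
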