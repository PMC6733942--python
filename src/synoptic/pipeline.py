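"""Orchestration: run all three metrics over a dataset and write a report.

The report is a set of delimited tables (stable column order, 6 significant
digits) plus a JSON manifest recording the configuration, library versions,
data-quality warnings and a SHA-256 checksum of every file — reruns with the
same configuration and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
import shutil
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .changepoint import VarianceCollapseModel, scale_concentrations
from .exceptions import ConfigError, SynopticError
from .io import (
    Dataset,
    read_chemistry_table,
    read_network,
    validate_dataset,
    write_chemistry_table,
    write_network,
)
from .leverage import SpatialStability, SubcatchmentLeverage
from .simulate import simulate_dataset, study_design

MANIFEST_NAME = "manifest.json"
FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Configuration of one metrics run (CLI flags mirror these one-to-one)."""

    chemistry_path: str | None = None
    network_path: str | None = None
    output_dir: str = "synoptic-out"
    simulate: bool = False
    alpha: float = 0.05
    n_perm: int = 999
    window: int = 10
    min_segment: int = 5
    seed: int = 0
    partition: str = "all"
    force: bool = False

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_perm < 99:
            raise ConfigError(f"n_perm must be >= 99, got {self.n_perm}")
        if self.partition not in {"all", "incremental"}:
            raise ConfigError(f"unknown partition mode {self.partition!r}")
        if not self.simulate and (
            self.chemistry_path is None or self.network_path is None
        ):
            raise ConfigError(
                "either set simulate=True or provide chemistry_path and "
                "network_path"
            )


@dataclass
class MetricsResults:
    """Result bundle of one pipeline run: four tidy tables plus warnings."""

    collapse: pd.DataFrame
    leverage_summary: pd.DataFrame
    leverage_sites: pd.DataFrame
    stability: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> str:
        n_sig = (
            int(self.collapse["threshold_area_km2"].notna().sum())
            if not self.collapse.empty
            else 0
        )
        n_stab = (
            int(self.stability["significant"].sum())
            if not self.stability.empty
            else 0
        )
        lines = [
            "Synoptic metrics results",
            "========================",
            f"collapse rows          {len(self.collapse)} "
            f"({n_sig} significant variance collapses)",
            f"leverage summaries     {len(self.leverage_summary)}",
            f"per-site leverage rows {len(self.leverage_sites)}",
            f"stability rows         {len(self.stability)} "
            f"({n_stab} significant)",
            f"warnings               {len(self.warnings)}",
        ]
        return "\n".join(lines)


def compute_metrics(dataset: Dataset, config: RunConfig) -> MetricsResults:
    """Variance collapse, leverage and stability for every slice of ``dataset``.

    One collapse row and one leverage summary per watershed x season x
    solute; one stability row per watershed x solute (first vs last season).
    Any module error aborts the run.
    """
    config.validate()
    if len(dataset.seasons) < 2:
        raise ConfigError(
            "spatial stability needs at least two seasons "
            f"(dataset has {dataset.seasons})"
        )
    warnings = validate_dataset(dataset)

    tasks = [
        (ws, season, solute)
        for ws in dataset.watershed_ids
        for season in dataset.seasons
        for solute in dataset.solutes
    ]
    seeds = {
        task: int(s.generate_state(1)[0] % (2**31))
        for task, s in zip(tasks, np.random.SeedSequence(config.seed).spawn(len(tasks)))
    }

    collapse_rows, summary_rows, site_rows, stability_rows = [], [], [], []
    for ws, season, solute in tasks:
        net = dataset.network(ws)
        values, site_ids = [], []
        for sid in sorted(net.sites):
            c = net.concentration(sid, season, solute)
            if c is not None:
                values.append((net.area(sid), c))
                site_ids.append(sid)
        series = scale_concentrations(
            values, site_ids=site_ids,
            watershed_id=ws, season=season, solute=solute,
        )
        cp = VarianceCollapseModel(series).fit(
            alpha=config.alpha,
            n_perm=config.n_perm,
            min_segment=config.min_segment,
            seed=seeds[(ws, season, solute)],
            window=config.window,
        )
        collapse_rows.append(
            {
                "watershed_id": ws,
                "season": season,
                "solute": solute,
                "n": cp.n,
                "lr_statistic": cp.lr_statistic,
                "p_value": cp.p_value,
                "threshold_area_km2": cp.threshold_area_km2,
            }
        )

        lev = SubcatchmentLeverage(net, season, solute, config.partition).fit()
        s = lev.summary_stats
        summary_rows.append(
            {
                "watershed_id": ws,
                "season": season,
                "solute": solute,
                "n": s.n,
                "mean": s.mean,
                "median": s.median,
                "q1": s.q1,
                "q3": s.q3,
                "whisker_low": s.whisker_low,
                "whisker_high": s.whisker_high,
                "n_beyond_whiskers": len(s.outliers),
            }
        )
        for sid, area, l in zip(lev.site_ids, lev.areas_km2, lev.leverage_pct):
            site_rows.append(
                {
                    "watershed_id": ws,
                    "season": season,
                    "solute": solute,
                    "site_id": sid,
                    "drainage_area_km2": area,
                    "leverage_pct": l,
                }
            )

    season_a, season_b = dataset.seasons[0], dataset.seasons[-1]
    for ws in dataset.watershed_ids:
        for solute in dataset.solutes:
            st = SpatialStability(
                dataset.network(ws), solute, season_a, season_b, config.alpha
            ).fit()
            stability_rows.append(
                {
                    "watershed_id": ws,
                    "solute": solute,
                    "season_a": season_a,
                    "season_b": season_b,
                    "n_pairs": st.n_pairs,
                    "r_s": st.r_s,
                    "p_value": st.p_value,
                    "significant": st.significant,
                }
            )

    return MetricsResults(
        collapse=pd.DataFrame(collapse_rows),
        leverage_summary=pd.DataFrame(summary_rows),
        leverage_sites=pd.DataFrame(site_rows),
        stability=pd.DataFrame(stability_rows),
        warnings=warnings,
    )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def write_report(
    results: MetricsResults, output_dir: str, config: RunConfig | None = None,
    force: bool = False,
) -> dict:
    """Write result tables + manifest atomically; return the manifest.

    Tables are written to a scratch sibling directory first and moved into
    place only when complete, so a failed run leaves no partial outputs.
    An existing non-empty output directory is refused unless ``force`` is set
    and the directory looks like a previous report (contains a manifest).
    """
    output_dir = os.path.abspath(output_dir)
    if os.path.isdir(output_dir) and os.listdir(output_dir):
        if not force:
            raise FileExistsError(
                f"output directory {output_dir} is not empty; use force=True "
                "(--force) to overwrite"
            )
        if not os.path.exists(os.path.join(output_dir, MANIFEST_NAME)):
            raise FileExistsError(
                f"refusing to overwrite {output_dir}: it does not look like a "
                f"previous report (no {MANIFEST_NAME})"
            )

    staging = output_dir + f".partial-{os.getpid()}"
    if os.path.exists(staging):
        shutil.rmtree(staging)
    os.makedirs(staging)
    try:
        tables = {
            "collapse.csv": results.collapse,
            "leverage_summary.csv": results.leverage_summary,
            "leverage_sites.csv": results.leverage_sites,
            "stability.csv": results.stability,
        }
        files = {}
        for name, df in tables.items():
            if df.empty:
                continue
            path = os.path.join(staging, name)
            df.to_csv(path, index=False, float_format=FLOAT_FMT)
            files[name] = _sha256(path)
        manifest = {
            "synoptic_version": __version__,
            "config": asdict(config) if config is not None else None,
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "warnings": results.warnings,
            "files": files,
        }
        with open(os.path.join(staging, MANIFEST_NAME), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except BaseException:
        shutil.rmtree(staging, ignore_errors=True)
        raise
    if os.path.isdir(output_dir):
        shutil.rmtree(output_dir)
    os.replace(staging, output_dir)
    return manifest


def run_metrics_pipeline(config: RunConfig) -> MetricsResults:
    """Load (or simulate) a dataset, compute all metrics, write the report."""
    config.validate()
    if config.simulate:
        configs, solute_params = study_design(config.seed)
        dataset, _ = simulate_dataset(configs, solute_params=solute_params)
    else:
        dataset = read_chemistry_table(config.chemistry_path)
        dataset = read_network(config.network_path, dataset)
    results = compute_metrics(dataset, config)
    write_report(results, config.output_dir, config=config, force=config.force)
    return results


def write_simulated_inputs(
    dataset: Dataset, truth: pd.DataFrame, output_dir: str, force: bool = False
) -> dict[str, str]:
    """Write chemistry/network/truth tables for a simulated dataset."""
    os.makedirs(output_dir, exist_ok=True)
    paths = {
        "chemistry": os.path.join(output_dir, "chemistry.csv"),
        "network": os.path.join(output_dir, "network.csv"),
        "truth": os.path.join(output_dir, "truth.csv"),
    }
    for p in paths.values():
        if os.path.exists(p) and not force:
            raise FileExistsError(f"{p} exists; use force=True (--force)")
    write_chemistry_table(dataset, paths["chemistry"])
    write_network(dataset, paths["network"])
    truth.to_csv(paths["truth"], index=False)
    return paths
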