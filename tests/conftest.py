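import numpy as np
import pytest

from synoptic.io import SiteRecord, WatershedNetwork


def make_chain_network(areas, watershed_id="W", concentrations=None):
    """Chain s0 -> s1 -> ... -> outlet with the given cumulative areas.

    ``concentrations`` optionally maps (season, solute) -> list of values in
    site order.
    """
    n = len(areas)
    sites = {}
    for i, a in enumerate(areas):
        sid = f"s{i}"
        conc = {}
        if concentrations:
            conc = {key: float(vals[i]) for key, vals in concentrations.items()}
        sites[sid] = SiteRecord(
            site_id=sid,
            watershed_id=watershed_id,
            drainage_area_km2=float(a),
            downstream_id=None if i == n - 1 else f"s{i + 1}",
            concentrations=conc,
        )
    return WatershedNetwork(watershed_id, sites)


def make_paired_network(pairs, season_a="early", season_b="late", solute="X"):
    """Chain network whose site i carries the i-th (early, late) pair."""
    a_vals = [p[0] for p in pairs]
    b_vals = [p[1] for p in pairs]
    return make_chain_network(
        list(range(1, len(pairs) + 1)),
        concentrations={(season_a, solute): a_vals, (season_b, solute): b_vals},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
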