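import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_chain_network, make_paired_network
from synoptic.exceptions import (
    InsufficientDataError,
    MissingOutletError,
    UndefinedCorrelationError,
)
from synoptic.io import SiteRecord, WatershedNetwork
from synoptic.leverage import (
    SpatialStability,
    SubcatchmentLeverage,
    mean_leverage_summary,
    spatial_stability,
    subcatchment_leverage,
)
from synoptic.recovery import simulate_watershed
from synoptic.simulate import SimConfig


def two_leaf_network(c1=3.0, c2=1.0, a1=20.0, a2=80.0):
    """Two headwater leaves mixing conservatively into a zero-increment outlet."""
    c_out = (a1 * c1 + a2 * c2) / (a1 + a2)
    sites = {
        "h1": SiteRecord("h1", "W", a1, "out", {("early", "X"): c1}),
        "h2": SiteRecord("h2", "W", a2, "out", {("early", "X"): c2}),
        "out": SiteRecord("out", "W", a1 + a2, None, {("early", "X"): c_out}),
    }
    return WatershedNetwork("W", sites)


class TestLeverage:
    def test_arithmetic_example(self):
        # C_i=2, C_out=1, A_i=10, A_out=100 -> +10%
        net = make_chain_network(
            [10, 100], concentrations={("early", "X"): [2.0, 1.0]}
        )
        res = subcatchment_leverage(net, "early", "X")
        lev = dict(zip(res.site_ids, res.leverage_pct))
        assert lev["s0"] == pytest.approx(10.0)

    def test_outlet_leverage_is_exactly_zero(self):
        net = make_chain_network(
            [1, 5, 10], concentrations={("early", "X"): [4.0, 2.0, 3.0]}
        )
        res = subcatchment_leverage(net, "early", "X")
        assert dict(zip(res.site_ids, res.leverage_pct))["s2"] == 0.0
        # outlet excluded from the summary
        assert res.summary_stats.n == 2

    def test_disjoint_headwater_partition_balances_exactly(self):
        net = two_leaf_network()
        res = subcatchment_leverage(net, "early", "X", partition="incremental")
        lev = dict(zip(res.site_ids, res.leverage_pct))
        assert lev["h1"] == pytest.approx(100 * (3 - 1.4) / 1.4 * 0.2)  # +22.857%
        assert lev["h2"] == pytest.approx(-lev["h1"])
        assert res.summary_stats.mean == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_conservative_watershed_mean_incremental_leverage_zero(self, seed):
        """Area-proportional conservative mixing => zero-mean leverage over
        the disjoint incremental partition, on any network."""
        cfg = SimConfig(watershed_id="W", n_headwaters=25, k_r=0.0, seed=seed)
        net = simulate_watershed(cfg, seasons=("early",))
        res = subcatchment_leverage(net, "early", "X", partition="incremental")
        assert res.summary_stats.mean == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_reaction_sign_and_magnitude(self, seed):
        """Net removal (k_r>0) gives positive mean leverage, production
        negative, and the magnitude grows with |k_r|."""
        means = {}
        for k_r in (-0.2, -0.1, -0.05, 0.05, 0.1, 0.2):
            cfg = SimConfig(watershed_id="W", n_headwaters=20, k_r=k_r, seed=seed)
            net = simulate_watershed(cfg, seasons=("early",))
            means[k_r] = subcatchment_leverage(net, "early", "X").summary_stats.mean
        for k_r, m in means.items():
            assert np.sign(m) == np.sign(k_r)
        assert means[0.05] < means[0.1] < means[0.2]
        assert means[-0.05] > means[-0.1] > means[-0.2]

    @given(st.floats(0.01, 100.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_invariance(self, c):
        base = [4.0, 2.0, 1.0, 3.0]
        net1 = make_chain_network([1, 2, 5, 10],
                                  concentrations={("early", "X"): base})
        net2 = make_chain_network([1, 2, 5, 10],
                                  concentrations={("early", "X"): [c * v for v in base]})
        r1 = subcatchment_leverage(net1, "early", "X")
        r2 = subcatchment_leverage(net2, "early", "X")
        assert np.allclose(r1.leverage_pct, r2.leverage_pct, rtol=1e-9)

    def test_missing_outlet_concentration_errors(self):
        net = make_chain_network([1, 10], concentrations={("early", "X"): [2.0, 1.0]})
        del net.sites["s1"].concentrations[("early", "X")]
        with pytest.raises(MissingOutletError, match="outlet"):
            subcatchment_leverage(net, "early", "X")

    def test_zero_outlet_concentration_errors(self):
        net = make_chain_network([1, 10], concentrations={("early", "X"): [2.0, 0.0]})
        with pytest.raises(MissingOutletError, match="undefined"):
            subcatchment_leverage(net, "early", "X")

    def test_incremental_mode_requires_complete_data(self):
        net = make_chain_network(
            [1, 5, 10], concentrations={("early", "X"): [4.0, 2.0, 3.0]}
        )
        del net.sites["s0"].concentrations[("early", "X")]
        with pytest.raises(MissingOutletError, match="complete"):
            SubcatchmentLeverage(net, "early", "X", partition="incremental").fit()


class TestLeverageSummary:
    def test_symmetric_values(self):
        s = mean_leverage_summary([-10.0, 0.0, 10.0])
        assert s.mean == 0.0 and s.median == 0.0
        assert s.outliers == []

    def test_far_point_flagged_beyond_upper_whisker(self):
        s = mean_leverage_summary([1.0, 2.0, 3.0, 4.0, 100.0])
        assert s.q1 == 2.0 and s.q3 == 4.0  # type-7 quantiles
        assert s.whisker_high == 4.0
        assert s.outliers == [100.0]

    def test_single_value(self):
        s = mean_leverage_summary([7.5])
        assert s.mean == s.median == 7.5

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            mean_leverage_summary([])


class TestSpatialStability:
    def test_perfect_monotone(self):
        st_ = spatial_stability(
            make_paired_network([(1, 2), (2, 4), (3, 6), (4, 8)]), "X", "early", "late"
        )
        assert st_.r_s == pytest.approx(1.0)
        assert st_.method == "exact permutation"

    def test_perfect_reversal(self):
        st_ = spatial_stability(
            make_paired_network([(1, 8), (2, 6), (3, 4), (4, 2)]), "X", "early", "late"
        )
        assert st_.r_s == pytest.approx(-1.0)

    def test_rank_formula_oracle(self):
        # ranks d^2 = (0,1,1,0,0): 1 - 6*2/(5*24) = 0.9
        st_ = spatial_stability(
            make_paired_network([(1, 1), (2, 3), (3, 2), (4, 4), (5, 5)]),
            "X", "early", "late",
        )
        assert st_.r_s == pytest.approx(0.9)

    def test_exact_p_value_small_n(self):
        # n=4 perfect monotone: 2 of 4! = 24 pairings reach |r|=1
        st_ = spatial_stability(
            make_paired_network([(1, 2), (2, 4), (3, 6), (4, 8)]), "X", "early", "late"
        )
        assert st_.p_value == pytest.approx(2 / 24)
        assert not st_.significant

    def test_t_approximation_matches_scipy_for_large_n(self, rng):
        from scipy import stats as sps

        pairs = [(float(a), float(b)) for a, b in rng.random((15, 2))]
        st_ = spatial_stability(make_paired_network(pairs), "X", "early", "late")
        r_ref, p_ref = sps.spearmanr([a for a, _ in pairs], [b for _, b in pairs])
        assert st_.method == "t-approximation"
        assert st_.r_s == pytest.approx(r_ref, rel=1e-12)
        assert st_.p_value == pytest.approx(p_ref, rel=1e-12)

    @pytest.mark.parametrize(
        "transform", [np.exp, lambda v: v**3, lambda v: np.log(v + 10.0)]
    )
    def test_invariant_under_monotone_transforms(self, rng, transform):
        pairs = rng.random((12, 2)) * 5
        st1 = spatial_stability(
            make_paired_network([tuple(p) for p in pairs]), "X", "early", "late"
        )
        st2 = spatial_stability(
            make_paired_network(
                [(p[0], float(transform(np.asarray(p[1])))) for p in pairs]
            ),
            "X", "early", "late",
        )
        assert st1.r_s == pytest.approx(st2.r_s, rel=1e-12)
        assert st1.p_value == pytest.approx(st2.p_value, rel=1e-9)

    def test_only_paired_sites_used(self):
        net = make_paired_network([(1, 2), (2, 4), (3, 6), (4, 8)])
        del net.sites["s1"].concentrations[("late", "X")]
        st_ = spatial_stability(net, "X", "early", "late")
        assert st_.n_pairs == 3

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            spatial_stability(make_paired_network([(1, 2), (2, 4)]), "X", "early", "late")

    def test_zero_variance_season_rejected(self):
        net = make_paired_network([(1, 2), (1, 4), (1, 6)])
        with pytest.raises(UndefinedCorrelationError):
            spatial_stability(net, "X", "early", "late")

    def test_ties_use_average_ranks(self):
        from scipy import stats as sps

        pairs = [(1, 1), (2, 1), (2, 3), (4, 3), (5, 5), (5, 6), (7, 7), (8, 8),
                 (9, 9), (10, 10), (11, 11), (12, 13)]
        st_ = spatial_stability(make_paired_network(pairs), "X", "early", "late")
        r_ref, _ = sps.spearmanr([a for a, _ in pairs], [b for _, b in pairs])
        assert st_.r_s == pytest.approx(r_ref, rel=1e-12)
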