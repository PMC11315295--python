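import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from phagequant import (
    CoverageError,
    GrowthCurve,
    SimulationConfig,
    aggregate_replicates,
    find_peak_valley,
    percent_lysogens,
    quantify_lysogeny,
    simulate_mixture,
)
from phagequant.lysogeny import BRANCH_NO_NET_LYSIS, BRANCH_SCALED, LysogenyEstimate


def _brute_force_peak_valley(times, od, boundary):
    """Independent oracle: plain-python max/min over the half-open split."""
    before = [(t, o) for t, o in zip(times, od) if t <= boundary]
    after = [(t, o) for t, o in zip(times, od) if t > boundary]
    od_p = max(o for _, o in before)
    t_p = min(t for t, o in before if o == od_p)
    od_v = min(o for _, o in after)
    t_v = min(t for t, o in after if o == od_v)
    return od_p, t_p, od_v, t_v


class TestFindPeakValley:
    def test_worked_example(self):
        curve = GrowthCurve("w", [0, 2, 4, 6, 8], [0.10, 0.30, 0.50, 0.20, 0.40])
        pv = find_peak_valley(curve, 4.0)
        assert (pv.od_p, pv.t_p) == (0.50, 4.0)
        assert (pv.od_v, pv.t_v) == (0.20, 6.0)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0.01, 2.0), min_size=6, max_size=40), st.randoms())
    def test_matches_brute_force_oracle(self, ods, rnd):
        times = np.arange(len(ods), dtype=float)
        boundary = rnd.uniform(0.5, len(ods) - 1.5)
        curve = GrowthCurve("h", times, ods)
        pv = find_peak_valley(curve, boundary)
        assert (pv.od_p, pv.t_p, pv.od_v, pv.t_v) == _brute_force_peak_valley(
            times, ods, boundary
        )

    def test_monotone_curve_extremes_hug_the_boundary(self):
        t = np.arange(0, 9.0, 1.0)
        curve = GrowthCurve("m", t, 0.1 + 0.05 * t)
        pv = find_peak_valley(curve, 4.0)
        assert pv.t_p == 4.0  # last point at or before the boundary
        assert pv.t_v == 5.0  # first point after it

    def test_tie_takes_earliest_time(self):
        curve = GrowthCurve("t", [0, 1, 2, 5, 6], [0.3, 0.3, 0.1, 0.2, 0.2])
        pv = find_peak_valley(curve, 4.0)
        assert pv.t_p == 0.0
        assert pv.t_v == 5.0

    def test_no_points_after_boundary(self):
        curve = GrowthCurve("c", [0, 1, 2, 3], [0.1, 0.2, 0.3, 0.4])
        with pytest.raises(CoverageError):
            find_peak_valley(curve, 10.0)


class TestPercentLysogens:
    def test_equal_ratios_give_zero(self):
        res = percent_lysogens(0.5, 0.25, 0.5, 0.25)
        assert res.branch == BRANCH_NO_NET_LYSIS
        assert res.percent_lysogens_raw == pytest.approx(0.0, abs=1e-12)

    def test_scaled_branch_worked_example(self):
        # E = 0.8/0.5 + (0.8/0.2 - 1) = 4.6; %L frozen from exact arithmetic
        res = percent_lysogens(0.6, 0.2, 0.5, 0.8)
        assert res.branch == BRANCH_SCALED
        assert res.expansion_factor == pytest.approx(4.6, abs=1e-12)
        assert res.percent_lysogens_raw == pytest.approx(92.7536231884058, abs=0.01)

    def test_vanishing_valley_approaches_total_conversion(self):
        res = percent_lysogens(0.6, 1e-9, 0.5, 0.8)
        assert res.percent_lysogens == pytest.approx(100.0, abs=1e-3)

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError):
            percent_lysogens(0.6, 0.0, 0.5, 0.8)

    @settings(max_examples=500, deadline=None)
    @given(
        od_p=st.floats(0.01, 10.0),
        n_tp=st.floats(0.01, 10.0),
        n_tv=st.floats(0.01, 10.0),
        s=st.floats(1.0, 100.0),
    )
    def test_branch_theorem(self, od_p, n_tp, n_tv, s):
        """Whenever N_tV/N_tP <= OD_V/OD_P the raw %L cannot be positive."""
        od_v = s * od_p * n_tv / n_tp
        assume(n_tv / n_tp <= od_v / od_p)  # float rounding can flip the edge
        res = percent_lysogens(od_p, od_v, n_tp, n_tv)
        assert res.branch == BRANCH_NO_NET_LYSIS
        assert res.percent_lysogens_raw <= 1e-9
        assert res.percent_lysogens <= 1e-9  # clamp floor, up to float rounding

    def test_branch_theorem_dense_random_sample(self):
        """10^4 random positive quadruples in the no-net-lysis region."""
        rng = np.random.default_rng(7)
        q = rng.uniform(0.01, 10.0, size=(10_000, 3))
        scale = rng.uniform(1.0, 50.0, size=10_000)
        bad = 0
        for (od_p, n_tp, n_tv), s in zip(q, scale):
            od_v = s * od_p * n_tv / n_tp
            if n_tv / n_tp > od_v / od_p:  # rounding flipped the condition
                continue
            if percent_lysogens(od_p, od_v, n_tp, n_tv).percent_lysogens_raw > 1e-9:
                bad += 1
        assert bad == 0

    def test_monotone_nonincreasing_in_valley_od(self):
        vals = [
            percent_lysogens(0.6, odv, 0.5, 0.8).percent_lysogens
            for odv in np.linspace(0.01, 0.5, 50)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_common_rescaling_of_all_inputs_is_invariant(self):
        # both branches depend on the inputs only through ratios
        for quad in [(0.5, 0.6, 0.5, 0.55), (0.6, 0.2, 0.5, 0.8)]:
            a = percent_lysogens(*quad)
            b = percent_lysogens(*(10.0 * v for v in quad))
            assert a.branch == b.branch
            assert a.percent_lysogens_raw == pytest.approx(b.percent_lysogens_raw)

    def test_scaled_branch_depends_on_infected_od_scale(self):
        """Rescaling only the infected-culture ODs changes the scaled branch.

        The additive (N_tV/OD_V - 1) term compares the infected valley to
        the control directly, so the scaled branch is not invariant to a
        calibration factor applied to the infected readings alone; the
        no-net-lysis branch, a pure ratio of ratios, is.
        """
        a = percent_lysogens(0.6, 0.2, 0.5, 0.8)
        b = percent_lysogens(0.6 * 1.5, 0.2 * 1.5, 0.5, 0.8)
        assert a.branch == b.branch == BRANCH_SCALED
        assert abs(a.percent_lysogens_raw - b.percent_lysogens_raw) > 0.5
        c = percent_lysogens(0.5, 0.6, 0.5, 0.55)
        d = percent_lysogens(0.5 * 1.5, 0.6 * 1.5, 0.5, 0.55)
        assert c.branch == d.branch == BRANCH_NO_NET_LYSIS
        assert c.percent_lysogens_raw == pytest.approx(d.percent_lysogens_raw)


class TestQuantifyLysogeny:
    def test_no_lysogens_reads_near_zero(self):
        cfg = SimulationConfig(lysogen_fraction=0.0, noise_sd=0.005, seed=11)
        curves = simulate_mixture(cfg)
        est = quantify_lysogeny(curves["induced_phagelike"], curves["buffer_control"])
        assert est.percent_lysogens == pytest.approx(0.0, abs=2.0)

    def test_fully_lysogenized_reads_near_total(self):
        cfg = SimulationConfig(lysogen_fraction=1.0, noise_sd=0.005, seed=12)
        curves = simulate_mixture(cfg)
        est = quantify_lysogeny(curves["induced_phagelike"], curves["buffer_control"])
        assert est.percent_lysogens >= 95.0

    def test_surface_condition_uses_5h_boundary(self):
        cfg = SimulationConfig(
            lysogen_fraction=0.5, seed=13, condition="surface", induction_time=4.0
        )
        curves = simulate_mixture(cfg)
        est = quantify_lysogeny(curves["induced_phagelike"], curves["buffer_control"])
        assert est.peakvalley.boundary == 5.0
        assert est.peakvalley.t_p <= 5.0 < est.peakvalley.t_v

    def test_boundary_override_beyond_curve_is_coverage_error(self):
        cfg = SimulationConfig(seed=14)
        curves = simulate_mixture(cfg)
        with pytest.raises(CoverageError):
            quantify_lysogeny(
                curves["induced_phagelike"],
                curves["buffer_control"],
                boundary_override=100.0,
            )

    def test_mismatched_metadata_rejected(self):
        cfg = SimulationConfig(seed=15)
        curves = simulate_mixture(cfg)
        other = curves["buffer_control"].with_metadata(strain="other")
        with pytest.raises(ValueError, match="strain"):
            quantify_lysogeny(curves["induced_phagelike"], other)


def _estimate(pct):
    from phagequant import PeakValley

    pv = PeakValley(od_p=0.5, t_p=3.0, od_v=0.2, t_v=6.0, boundary=4.0)
    return LysogenyEstimate(
        percent_lysogens_raw=pct, percent_lysogens=pct, expansion_factor=2.0,
        branch=BRANCH_SCALED, peakvalley=pv, n_tp=0.5, n_tv=0.9,
    )


class TestAggregateReplicates:
    def test_mean_and_sd(self):
        s = aggregate_replicates([_estimate(50.0), _estimate(60.0), _estimate(70.0)])
        assert s.mean_percent == pytest.approx(60.0)
        assert s.sd_percent == pytest.approx(10.0)
        assert s.n == 3 and s.sd_defined

    def test_single_estimate_sd_flagged(self):
        s = aggregate_replicates([_estimate(42.0)])
        assert s.mean_percent == 42.0
        assert s.sd_percent == 0.0
        assert not s.sd_defined

    def test_order_invariance(self):
        a = aggregate_replicates([_estimate(10.0), _estimate(30.0), _estimate(20.0)])
        b = aggregate_replicates([_estimate(30.0), _estimate(20.0), _estimate(10.0)])
        assert (a.mean_percent, a.sd_percent) == (b.mean_percent, b.sd_percent)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_replicates([])
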