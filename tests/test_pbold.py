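import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pboldqa import (
    FCMatrix,
    SimConfig,
    chord_distance,
    edge_geometry,
    enumerate_quadruples,
    quadruple_pbold,
    scan_pbold,
    simulate_fluctuations,
    synthesize_roi_spc,
)
from pboldqa.io_model import ROITimeseriesSet
from pboldqa.pbold import EdgeGeometry, QuadrupleConfig

TES = [13.9, 31.7, 49.5]


def brute_force_edges(vx, vy, m, delta):
    """Scalar per-edge reference implementation of the geometry scoring."""
    n = vx.shape[0]
    out = []
    for a in range(n):
        for b in range(a + 1, n):
            x = vx[a, b]
            y = vy[a, b]
            d_so = abs(x - y) / math.sqrt(2)
            d_bold = abs(m * x - y) / math.sqrt(m * m + 1)
            if d_so - d_bold > delta:
                pref = 1.0
            elif d_bold - d_so > delta:
                pref = 0.0
            else:
                pref = 0.5
            w = math.sqrt(x * x + y * y)
            out.append((a, b, x, y, d_so, d_bold, pref, w))
    return out


def fc_pair(vx, vy, pair_x=(13.9, 13.9), pair_y=(49.5, 49.5)):
    quad = QuadrupleConfig(pair_x=pair_x, pair_y=pair_y,
                           echo_idx_x=(0, 0), echo_idx_y=(2, 2))
    fx = FCMatrix(values=vx, estimator="covariance", te_pair=pair_x, n_t=10)
    fy = FCMatrix(values=vy, estimator="covariance", te_pair=pair_y, n_t=10)
    return fx, fy, quad


def point_edge(x, y, m=2.0, delta=1e-3):
    """Score a single point (x, y) against lines of slope 1 and m."""
    vx = np.array([[0.0, x], [0.0, 0.0]])
    vy = np.array([[0.0, y], [0.0, 0.0]])
    quad = QuadrupleConfig(pair_x=(1.0, 1.0), pair_y=(1.0, m),
                           echo_idx_x=(0, 0), echo_idx_y=(0, 1), delta=delta)
    fx = FCMatrix(values=vx, estimator="covariance", te_pair=(1.0, 1.0), n_t=10)
    fy = FCMatrix(values=vy, estimator="covariance", te_pair=(1.0, m), n_t=10)
    return edge_geometry(fx, fy, quad)[0]


class TestEnumerateQuadruples:
    def test_three_echoes_give_fifteen(self):
        assert len(enumerate_quadruples(TES)) == 15

    def test_two_echoes_give_three(self):
        # 3 pairs {(1,1),(1,2),(2,2)} -> 3 * 2 / 2 = 3 quadruples
        assert len(enumerate_quadruples([14.0, 30.0])) == 3

    @pytest.mark.parametrize("n_echoes,expected", [(2, 3), (3, 15), (4, 45),
                                                   (5, 105)])
    def test_count_formula(self, n_echoes, expected):
        tes = list(np.linspace(10, 60, n_echoes))
        p = n_echoes * (n_echoes + 1) // 2
        assert expected == p * (p - 1) // 2
        assert len(enumerate_quadruples(tes)) == expected

    def test_extreme_pair_slope(self):
        # [(TE1,TE1),(TE3,TE3)] with TEs 13.9/49.5: m = 49.5^2 / 13.9^2
        quads = enumerate_quadruples(TES)
        match = [q for q in quads
                 if q.pair_x == (13.9, 13.9) and q.pair_y == (49.5, 49.5)]
        assert len(match) == 1
        assert match[0].slope == pytest.approx(49.5**2 / 13.9**2)
        assert match[0].slope == pytest.approx(12.6818, abs=5e-4)

    def test_canonical_slope_at_least_one(self):
        assert all(q.slope >= 1.0 for q in enumerate_quadruples(TES))

    def test_single_echo_rejected(self):
        with pytest.raises(ValueError, match=">=2 echoes"):
            enumerate_quadruples([30.0])

    def test_chord_zero_iff_unit_slope(self):
        # TEs 10/20/40: pairs (10,40) and (20,20) share the product 400
        quads = enumerate_quadruples([10.0, 20.0, 40.0])
        degenerate = [q for q in quads if q.slope == 1.0]
        assert len(degenerate) == 1
        assert degenerate[0].chord == 0.0
        assert all(q.chord > 0 for q in quads if q.slope != 1.0)


class TestChordDistance:
    def test_zero_angle(self):
        assert chord_distance(0.0) == 0.0

    def test_diameter(self):
        assert chord_distance(math.pi, 0.5) == pytest.approx(1.0)

    def test_quarter_turn(self):
        assert chord_distance(math.pi / 4, 0.5) == pytest.approx(
            2 * 0.5 * math.sin(math.pi / 8)
        )
        assert chord_distance(math.pi / 4, 0.5) == pytest.approx(0.38268,
                                                                 abs=1e-5)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            chord_distance(-0.1)
        with pytest.raises(ValueError):
            chord_distance(math.pi + 0.1)


class TestEdgeGeometry:
    def test_point_on_identity_line(self):
        edge = point_edge(0.2, 0.2, m=3.0)
        assert edge.d_so == 0.0
        assert edge.pref == 0.0

    def test_point_on_bold_line(self):
        m = 3.0
        edge = point_edge(0.1, 0.1 * m, m=m)
        assert edge.d_bold == pytest.approx(0.0, abs=1e-15)
        assert edge.pref == 1.0

    def test_hand_checked_distances(self):
        edge = point_edge(1.0, 0.0, m=2.0)
        assert edge.d_so == pytest.approx(1 / math.sqrt(2))
        assert edge.d_so == pytest.approx(0.70711, abs=1e-5)
        assert edge.d_bold == pytest.approx(2 / math.sqrt(5))
        assert edge.d_bold == pytest.approx(0.89443, abs=1e-5)
        assert edge.pref == 0.0
        assert edge.weight == pytest.approx(1.0)

    def test_three_four_five_weight(self):
        edge = point_edge(0.3, 0.4)
        assert edge.weight == pytest.approx(0.5)

    def test_tie_band_gives_half(self):
        # equidistant from both lines -> |d_bold - d_so| <= delta -> 0.5
        m = 3.0
        # the bisector direction between slopes 1 and m
        ang = (math.atan(1.0) + math.atan(m)) / 2
        edge = point_edge(0.5 * math.cos(ang), 0.5 * math.sin(ang), m=m)
        assert edge.pref == 0.5

    def test_matches_brute_force(self, rng):
        for _ in range(100):
            vx = rng.normal(0, 0.5, size=(10, 10))
            vy = rng.normal(0, 0.5, size=(10, 10))
            m = float(rng.uniform(1.0, 13.0))
            quad = QuadrupleConfig(pair_x=(1.0, 1.0), pair_y=(1.0, m),
                                   echo_idx_x=(0, 0), echo_idx_y=(0, 1))
            fx = FCMatrix(values=vx, estimator="covariance",
                          te_pair=(1.0, 1.0), n_t=10)
            fy = FCMatrix(values=vy, estimator="covariance",
                          te_pair=(1.0, m), n_t=10)
            edges = edge_geometry(fx, fy, quad)
            expected = brute_force_edges(vx, vy, m, quad.delta)
            assert len(edges) == len(expected) == 45
            for edge, (a, b, x, y, d_so, d_bold, pref, w) in zip(edges,
                                                                 expected):
                assert (edge.roi_a, edge.roi_b) == (a, b)
                assert edge.fc_x == x and edge.fc_y == y
                assert edge.d_so == d_so
                assert edge.d_bold == d_bold
                assert edge.pref == pref
                assert edge.weight == w

    def test_literal_pref_is_reversed(self):
        # the as-printed rule labels the edge *farther* from the BOLD line 1
        fx, fy, quad = fc_pair(np.array([[0, 0.2], [0, 0]]),
                               np.array([[0, 0.2], [0, 0]]))
        assert edge_geometry(fx, fy, quad)[0].pref == 0.0
        assert edge_geometry(fx, fy, quad, literal_pref=True)[0].pref == 1.0

    def test_symmetrize_flag(self):
        vx = np.array([[0.0, 1.0], [3.0, 0.0]])
        vy = np.zeros((2, 2))
        fx, fy, quad = fc_pair(vx, vy)
        assert edge_geometry(fx, fy, quad)[0].fc_x == 1.0
        assert edge_geometry(fx, fy, quad, symmetrize=True)[0].fc_x == 2.0

    def test_roi_count_mismatch(self):
        fx = FCMatrix(values=np.zeros((3, 3)), estimator="covariance",
                      te_pair=(1.0, 1.0), n_t=10)
        fy = FCMatrix(values=np.zeros((4, 4)), estimator="covariance",
                      te_pair=(1.0, 2.0), n_t=10)
        quad = QuadrupleConfig(pair_x=(1.0, 1.0), pair_y=(1.0, 2.0),
                               echo_idx_x=(0, 0), echo_idx_y=(0, 1))
        with pytest.raises(ValueError, match="mismatch"):
            edge_geometry(fx, fy, quad)

    def test_pearson_matrix_rejected(self):
        fx = FCMatrix(values=np.eye(3), estimator="pearson",
                      te_pair=(1.0, 1.0), n_t=10)
        fy = FCMatrix(values=np.eye(3), estimator="covariance",
                      te_pair=(1.0, 2.0), n_t=10)
        quad = QuadrupleConfig(pair_x=(1.0, 1.0), pair_y=(1.0, 2.0),
                               echo_idx_x=(0, 0), echo_idx_y=(0, 1))
        with pytest.raises(ValueError, match="covariance"):
            edge_geometry(fx, fy, quad)


def make_edge(pref, weight):
    return EdgeGeometry(roi_a=0, roi_b=1, fc_x=0.0, fc_y=0.0, d_so=0.0,
                        d_bold=0.0, pref=pref, weight=weight)


class TestQuadruplePbold:
    def test_all_prefer_bold(self):
        assert quadruple_pbold([make_edge(1.0, 0.3)] * 4) == 1.0

    def test_even_split(self):
        assert quadruple_pbold([make_edge(1.0, 1.0),
                                make_edge(0.0, 1.0)]) == 0.5

    def test_weighted_mean(self):
        assert quadruple_pbold([make_edge(1.0, 3.0),
                                make_edge(0.0, 1.0)]) == 0.75

    def test_all_zero_weights_undefined(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="pboldqa.pbold"):
            value = quadruple_pbold([make_edge(1.0, 0.0), make_edge(0.0, 0.0)])
        assert math.isnan(value)
        assert any("undefined" in rec.message for rec in caplog.records)

    def test_no_edges_raises(self):
        with pytest.raises(ValueError, match="no edges"):
            quadruple_pbold([])


def regime_ts(bold_fraction, seed=1, n_rois=50, n_t=500):
    cfg = SimConfig(n_rois=n_rois, n_t=n_t, echo_times=tuple(TES),
                    bold_fraction=bold_fraction, seed=seed)
    return synthesize_roi_spc(simulate_fluctuations(cfg), TES)


class TestScanPbold:
    def test_pure_so_low(self):
        assert scan_pbold(regime_ts(0.0)).p_bold <= 0.05

    def test_pure_bold_high(self):
        assert scan_pbold(regime_ts(1.0)).p_bold >= 0.95

    def test_identical_echo_series_give_zero(self, rng):
        # a literal net-magnetization-only signal: same series at every echo.
        # A strong shared component keeps every edge covariance well outside
        # the delta tie band around the origin, so every edge scores 0.
        shared = rng.normal(0, 0.5, size=80)
        row = shared[None, :] + rng.normal(0, 0.05, size=(6, 80))
        row -= row.mean(axis=1, keepdims=True)
        ts = ROITimeseriesSet(values=np.stack([row] * 3), echo_times=TES,
                              units="spc")
        result = scan_pbold(ts)
        assert all(e.d_so == 0.0 for q in result.per_quadruple
                   for e in q.edges)
        assert result.p_bold == 0.0

    def test_result_invariants(self):
        result = scan_pbold(regime_ts(0.5))
        assert 0.0 <= result.p_bold <= 1.0
        assert len(result.per_quadruple) == 15
        num = sum(e.quad.chord * e.p_bold for e in result.per_quadruple
                  if not math.isnan(e.p_bold) and e.quad.chord > 0)
        den = sum(e.quad.chord for e in result.per_quadruple
                  if not math.isnan(e.p_bold) and e.quad.chord > 0)
        assert result.p_bold == pytest.approx(num / den, abs=1e-12)

    def test_monotone_in_bold_fraction(self):
        values = [scan_pbold(regime_ts(f)).p_bold
                  for f in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_axis_swap_invariance(self):
        ts = regime_ts(0.5, n_rois=15, n_t=200)
        from pboldqa.fc import covariance_fc
        from pboldqa.pbold import quadruple_pbold as qp

        for quad in enumerate_quadruples(TES):
            swapped = quad.swapped()
            edges = edge_geometry(covariance_fc(ts, *quad.echo_idx_x),
                                  covariance_fc(ts, *quad.echo_idx_y), quad)
            edges_sw = edge_geometry(covariance_fc(ts, *swapped.echo_idx_x),
                                     covariance_fc(ts, *swapped.echo_idx_y),
                                     swapped)
            for e, es in zip(edges, edges_sw):
                assert e.d_so == pytest.approx(es.d_so, abs=1e-12)
                assert e.d_bold == pytest.approx(es.d_bold, abs=1e-12)
                assert e.pref == es.pref
                assert e.weight == pytest.approx(es.weight, abs=1e-12)
            assert qp(edges) == pytest.approx(qp(edges_sw), abs=1e-12)

    def test_degenerate_quadruple_safe(self):
        # TEs 10/20/40 contain an m = 1 quadruple (chord 0); the scan value
        # must remain defined and in range
        tes = [10.0, 20.0, 40.0]
        cfg = SimConfig(n_rois=10, n_t=100, echo_times=tuple(tes), seed=2,
                        bold_fraction=0.7)
        ts = synthesize_roi_spc(simulate_fluctuations(cfg), tes)
        result = scan_pbold(ts)
        assert 0.0 <= result.p_bold <= 1.0
        degenerate = [e for e in result.per_quadruple if e.quad.chord == 0.0]
        assert len(degenerate) == 1

    def test_literal_pref_inverts_regimes(self):
        assert scan_pbold(regime_ts(0.0), literal_pref=True).p_bold >= 0.95
        assert scan_pbold(regime_ts(1.0), literal_pref=True).p_bold <= 0.05

    def test_requires_spc(self, rng):
        raw = ROITimeseriesSet(values=rng.random((3, 4, 20)) + 1,
                               echo_times=TES, units="raw")
        with pytest.raises(ValueError, match="spc"):
            scan_pbold(raw)

    @given(seed=st.integers(0, 2**31 - 1),
           f=st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=15, deadline=None)
    def test_range_property(self, seed, f):
        ts = regime_ts(f, seed=seed, n_rois=8, n_t=60)
        assert 0.0 <= scan_pbold(ts, keep_edges=False).p_bold <= 1.0
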