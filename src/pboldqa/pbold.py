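"""The p_BOLD metric.

For every quadruple of echo-time pairs, each edge (pair of ROIs) becomes a
point whose coordinates are its across-echo covariances under the two pairs.
Echo-time-independent (net magnetization, "S_o") fluctuations put edges on
the identity line; echo-time-dependent (BOLD) fluctuations put them on a
line through the origin with slope equal to the ratio of the echo-time
products. Each edge votes for the line it sits closer to, weighted by its
distance from the origin; quadruple scores are then averaged, weighted by
the chord distance separating the two lines (a measure of how discriminative
that quadruple is). The result is a scan-level score in [0, 1]: high means
BOLD-dominated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations, combinations_with_replacement

import numpy as np

from pboldqa.fc import FCMatrix, covariance_fc
from pboldqa.io_model import ROITimeseriesSet

logger = logging.getLogger("pboldqa.pbold")

__all__ = [
    "QuadrupleConfig",
    "EdgeGeometry",
    "QuadrupleResult",
    "PBOLDResult",
    "enumerate_quadruples",
    "edge_geometry",
    "quadruple_pbold",
    "chord_distance",
    "scan_pbold",
]

DEFAULT_DELTA = 1e-3
DEFAULT_CHORD_RADIUS = 0.5


def chord_distance(theta: float, radius: float = DEFAULT_CHORD_RADIUS) -> float:
    """Chord length subtended by angle ``theta`` on a circle of ``radius``:
    2 * R * sin(theta / 2)."""
    if not 0.0 <= theta <= math.pi:
        raise ValueError(f"theta must be in [0, pi], got {theta}")
    return 2.0 * radius * math.sin(theta / 2.0)


@dataclass(frozen=True)
class QuadrupleConfig:
    """One quadruple of echo-time pairs and its derived line geometry.

    ``pair_x`` indexes the abscissa covariance matrix, ``pair_y`` the
    ordinate one. ``slope`` is (TE_k*TE_l)/(TE_i*TE_j); ``theta`` the angle
    between the slope line and the identity line; ``chord`` the separation of
    the two lines at ``radius``.
    """

    pair_x: tuple[float, float]
    pair_y: tuple[float, float]
    echo_idx_x: tuple[int, int]
    echo_idx_y: tuple[int, int]
    delta: float = DEFAULT_DELTA
    radius: float = DEFAULT_CHORD_RADIUS
    slope: float = field(init=False)
    theta: float = field(init=False)
    chord: float = field(init=False)

    def __post_init__(self) -> None:
        prod_x = self.pair_x[0] * self.pair_x[1]
        prod_y = self.pair_y[0] * self.pair_y[1]
        if prod_x <= 0 or prod_y <= 0:
            raise ValueError("echo times must be positive")
        m = prod_y / prod_x
        # |arctan(m) - pi/4|: angle to the identity line, valid for any m > 0
        theta = abs(math.atan(m) - math.pi / 4.0)
        object.__setattr__(self, "slope", m)
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "chord", chord_distance(theta, self.radius))

    def swapped(self) -> "QuadrupleConfig":
        """The same quadruple with x/y axes exchanged (slope -> 1/slope)."""
        return QuadrupleConfig(
            pair_x=self.pair_y,
            pair_y=self.pair_x,
            echo_idx_x=self.echo_idx_y,
            echo_idx_y=self.echo_idx_x,
            delta=self.delta,
            radius=self.radius,
        )


def enumerate_quadruples(
    echo_times,
    delta: float = DEFAULT_DELTA,
    radius: float = DEFAULT_CHORD_RADIUS,
) -> list[QuadrupleConfig]:
    """All unordered combinations of two distinct echo-time pairs.

    With Ne echoes there are P = Ne*(Ne+1)/2 unordered pairs (with
    repetition) and P*(P-1)/2 quadruples — 15 for a 3-echo scan. Within each
    quadruple the pair with the smaller TE product is mapped to the x-axis so
    the slope is >= 1; axis choice does not affect any edge quantity (point
    and lines reflect together across the identity).
    """
    echo_times = np.asarray(echo_times, dtype=float)
    if echo_times.size < 2:
        raise ValueError("p_BOLD requires >=2 echoes")
    pairs = list(combinations_with_replacement(range(echo_times.size), 2))
    quads = []
    for (i, j), (k, l) in combinations(pairs, 2):
        prod_a = echo_times[i] * echo_times[j]
        prod_b = echo_times[k] * echo_times[l]
        if prod_b >= prod_a:
            idx_x, idx_y = (i, j), (k, l)
        else:
            idx_x, idx_y = (k, l), (i, j)
        quads.append(
            QuadrupleConfig(
                pair_x=(echo_times[idx_x[0]], echo_times[idx_x[1]]),
                pair_y=(echo_times[idx_y[0]], echo_times[idx_y[1]]),
                echo_idx_x=idx_x,
                echo_idx_y=idx_y,
                delta=delta,
                radius=radius,
            )
        )
    return quads


@dataclass
class EdgeGeometry:
    """Scatter coordinates and line distances for one edge in one quadruple."""

    roi_a: int
    roi_b: int
    fc_x: float
    fc_y: float
    d_so: float
    d_bold: float
    pref: float  # 0, 0.5 or 1
    weight: float


def _edge_arrays(
    x: np.ndarray, y: np.ndarray, m: float, delta: float, literal_pref: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized distances/labels for points (x, y) against lines y=x and y=m*x."""
    d_so = np.abs(x - y) / math.sqrt(2.0)
    d_bold = np.abs(m * x - y) / math.sqrt(m * m + 1.0)
    if literal_pref:
        # as-printed label rule (see README): 1 if d_bold > d_so + delta,
        # 0 if d_bold < d_so + delta, 0.5 on the boundary
        pref = np.where(
            d_bold > d_so + delta, 1.0, np.where(d_bold < d_so + delta, 0.0, 0.5)
        )
    else:
        # closer-line-wins: the edge prefers the BOLD line when it is closer
        diff = d_so - d_bold
        pref = np.where(diff > delta, 1.0, np.where(diff < -delta, 0.0, 0.5))
    weight = np.sqrt(x * x + y * y)
    return d_so, d_bold, pref, weight


def edge_geometry(
    fcm_x: FCMatrix,
    fcm_y: FCMatrix,
    quad: QuadrupleConfig,
    literal_pref: bool = False,
    symmetrize: bool = False,
) -> list[EdgeGeometry]:
    """Map each edge (strict upper triangle) into the 2D covariance plane and
    score it against the identity (S_o) and slope (BOLD) lines.

    ``symmetrize`` averages each cross-echo covariance matrix with its
    transpose before the triangle is taken.
    """
    for fcm, name in ((fcm_x, "x"), (fcm_y, "y")):
        if fcm.estimator != "covariance":
            raise ValueError(f"{name}-axis matrix must use the covariance estimator")
    if fcm_x.n_rois != fcm_y.n_rois:
        raise ValueError(
            f"ROI count mismatch: {fcm_x.n_rois} (x) vs {fcm_y.n_rois} (y)"
        )
    vx = fcm_x.values
    vy = fcm_y.values
    if symmetrize:
        vx = 0.5 * (vx + vx.T)
        vy = 0.5 * (vy + vy.T)
    iu = np.triu_indices(fcm_x.n_rois, k=1)
    x = vx[iu]
    y = vy[iu]
    d_so, d_bold, pref, weight = _edge_arrays(
        x, y, quad.slope, quad.delta, literal_pref
    )
    return [
        EdgeGeometry(
            roi_a=int(a),
            roi_b=int(b),
            fc_x=float(x[n]),
            fc_y=float(y[n]),
            d_so=float(d_so[n]),
            d_bold=float(d_bold[n]),
            pref=float(pref[n]),
            weight=float(weight[n]),
        )
        for n, (a, b) in enumerate(zip(iu[0], iu[1]))
    ]


def quadruple_pbold(edges: list[EdgeGeometry]) -> float:
    """Weighted mean of edge preferences; NaN if every weight is zero."""
    if not edges:
        raise ValueError("no edges given")
    weights = np.array([e.weight for e in edges])
    prefs = np.array([e.pref for e in edges])
    total = weights.sum()
    if total == 0:
        logger.warning("all edge weights are zero; quadruple p_BOLD undefined")
        return float("nan")
    return float((weights * prefs).sum() / total)


@dataclass
class QuadrupleResult:
    quad: QuadrupleConfig
    p_bold: float
    n_edges: int
    edges: list[EdgeGeometry] | None = None


@dataclass
class PBOLDResult:
    """Scan-level p_BOLD with its per-quadruple breakdown."""

    p_bold: float
    per_quadruple: list[QuadrupleResult]
    n_rois: int
    te_list: list[float]


def scan_pbold(
    ts: ROITimeseriesSet,
    delta: float = DEFAULT_DELTA,
    radius: float = DEFAULT_CHORD_RADIUS,
    literal_pref: bool = False,
    symmetrize: bool = False,
    keep_edges: bool = True,
) -> PBOLDResult:
    """Compute scan-level p_BOLD from spc-unit ROI timeseries.

    Runs the per-quadruple edge scoring over every echo-time quadruple, then
    averages the per-quadruple values weighted by chord distance. Quadruples
    with undefined scores (all-zero edge weights) or zero chord (coincident
    lines, no discriminative power) are excluded from the average.
    """
    if ts.units != "spc":
        raise ValueError("scan_pbold expects spc-unit input; call to_spc first")
    if ts.n_rois < 2:
        raise ValueError("p_BOLD requires at least 2 ROIs")
    if ts.n_t < 2:
        raise ValueError("p_BOLD requires at least 2 timepoints")

    quads = enumerate_quadruples(ts.echo_times, delta=delta, radius=radius)

    fc_cache: dict[tuple[int, int], FCMatrix] = {}

    def fc_for(idx: tuple[int, int]) -> FCMatrix:
        if idx not in fc_cache:
            fc_cache[idx] = covariance_fc(ts, idx[0], idx[1])
        return fc_cache[idx]

    per_quadruple: list[QuadrupleResult] = []
    num = 0.0
    den = 0.0
    for quad in quads:
        edges = edge_geometry(
            fc_for(quad.echo_idx_x),
            fc_for(quad.echo_idx_y),
            quad,
            literal_pref=literal_pref,
            symmetrize=symmetrize,
        )
        p_q = quadruple_pbold(edges)
        per_quadruple.append(
            QuadrupleResult(
                quad=quad,
                p_bold=p_q,
                n_edges=len(edges),
                edges=edges if keep_edges else None,
            )
        )
        if not math.isnan(p_q) and quad.chord > 0:
            num += quad.chord * p_q
            den += quad.chord
    if den == 0:
        raise ValueError(
            "p_BOLD undefined: every quadruple has zero chord weight or undefined score"
        )
    return PBOLDResult(
        p_bold=num / den,
        per_quadruple=per_quadruple,
        n_rois=ts.n_rois,
        te_list=[float(t) for t in ts.echo_times],
    )
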