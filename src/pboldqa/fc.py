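"""Signal-percent-change conversion and across-echo connectivity matrices.

Across-echo connectivity pairs the signal of ROI x observed at one echo time
with the signal of ROI y observed at another. Covariance matrices use the
sample (Nt-1) denominator and are generally asymmetric for distinct echoes;
``covariance_fc(a, b)`` is the transpose of ``covariance_fc(b, a)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from pboldqa.io_model import ROITimeseriesSet

logger = logging.getLogger("pboldqa.fc")

__all__ = ["FCMatrix", "to_spc", "covariance_fc", "pearson_fc"]


@dataclass
class FCMatrix:
    """An across-echo functional-connectivity matrix.

    Entry ``(x, y)`` relates ROI x measured at ``te_pair[0]`` to ROI y
    measured at ``te_pair[1]``.
    """

    values: np.ndarray
    estimator: str  # "pearson" | "covariance"
    te_pair: tuple[float, float]
    n_t: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("FC matrix must be square")
        if self.estimator not in ("pearson", "covariance"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        self.te_pair = (float(self.te_pair[0]), float(self.te_pair[1]))

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        """Dense TSV with a two-line comment header recording provenance."""
        header = (
            f"# estimator={self.estimator}\n"
            f"# te_pair_ms={self.te_pair[0]:g},{self.te_pair[1]:g} n_t={self.n_t}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.values, delimiter="\t", fmt="%.17g")


def to_spc(ts: ROITimeseriesSet) -> ROITimeseriesSet:
    """Convert raw ROI series to fractional signal change, (S - mean) / mean.

    Every row must have a strictly positive temporal mean; offending ROIs are
    reported by label and echo index (1-based).
    """
    if ts.units != "raw":
        raise ValueError("to_spc expects raw-unit input")
    means = ts.values.mean(axis=2, keepdims=True)
    bad = np.argwhere(means[:, :, 0] <= 0)
    if bad.size:
        e, r = bad[0]
        raise ValueError(
            f"ROI {ts.roi_ids[r]} at echo {e + 1} has non-positive temporal mean "
            f"({means[e, r, 0]:g}); cannot convert to signal percent change"
        )
    values = (ts.values - means) / means
    # the subtraction leaves tiny float residue in the row means; remove it
    values -= values.mean(axis=2, keepdims=True)
    return ROITimeseriesSet(
        values=values, echo_times=ts.echo_times, units="spc", roi_ids=list(ts.roi_ids)
    )


def _rows(ts: ROITimeseriesSet, echo: int) -> np.ndarray:
    if ts.units != "spc":
        raise ValueError("FC estimators expect spc-unit input; call to_spc first")
    if not 0 <= echo < ts.n_echoes:
        raise IndexError(f"echo index {echo} out of range for {ts.n_echoes} echoes")
    return ts.values[echo]


def covariance_fc(ts: ROITimeseriesSet, echo_a: int, echo_b: int) -> FCMatrix:
    """Across-echo covariance: entry (x, y) = cov(S_x at TE_a, S_y at TE_b).

    Uses the sample denominator (Nt - 1). Temporal means are re-removed even
    though spc rows are nominally zero-mean, to bound floating-point drift.
    """
    if ts.n_t < 2:
        raise ValueError("covariance requires at least 2 timepoints")
    a = _rows(ts, echo_a)
    b = _rows(ts, echo_b)
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    values = (a @ b.T) / (ts.n_t - 1)
    return FCMatrix(
        values=values,
        estimator="covariance",
        te_pair=(ts.echo_times[echo_a], ts.echo_times[echo_b]),
        n_t=ts.n_t,
    )


def pearson_fc(ts: ROITimeseriesSet, echo_a: int, echo_b: int) -> FCMatrix:
    """Across-echo Pearson correlation between ROI series at two echoes.

    Rows with zero temporal variance produce NaN entries and a warning; they
    are never silently coerced to 0.
    """
    if ts.n_t < 2:
        raise ValueError("correlation requires at least 2 timepoints")
    a = _rows(ts, echo_a)
    b = _rows(ts, echo_b)
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    norm_a = np.sqrt((a**2).sum(axis=1))
    norm_b = np.sqrt((b**2).sum(axis=1))
    zero_a = norm_a == 0
    zero_b = norm_b == 0
    if zero_a.any() or zero_b.any():
        n_zero = int(zero_a.sum() + zero_b.sum())
        logger.warning(
            "%d zero-variance ROI series; their correlations are set to NaN", n_zero
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        values = (a @ b.T) / np.outer(norm_a, norm_b)
    values[zero_a, :] = np.nan
    values[:, zero_b] = np.nan
    return FCMatrix(
        values=values,
        estimator="pearson",
        te_pair=(ts.echo_times[echo_a], ts.echo_times[echo_b]),
        n_t=ts.n_t,
    )
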