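"""Synthetic multi-echo data generation.

Two fluctuation sources drive the signal: echo-time-independent changes in
net magnetization (relative amplitude ``delta_rho``) and echo-time-dependent
changes in the transverse relaxation rate (``delta_r2s``, units 1/ms). The
``bold_fraction`` mixing parameter fixes, per ROI, the share of fractional
signal-change variance carried by the relaxation term at the reference echo
(the second echo time). ``bold_fraction=0`` gives a pure net-magnetization
regime, ``bold_fraction=1`` a pure BOLD regime.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from pboldqa.io_model import MEScan, ROITimeseriesSet

logger = logging.getLogger("pboldqa.simulator")

__all__ = [
    "FluctuationSeries",
    "DecayBaseline",
    "SimConfig",
    "default_network_covariance",
    "simulate_fluctuations",
    "synthesize_roi_spc",
    "synthesize_voxel_scan",
    "apply_tr_jitter",
    "saturation_offsets",
    "generate_background_fixture",
    "build_voxel_phantom",
]


@dataclass
class FluctuationSeries:
    """Zero-mean fluctuation matrices, one row per ROI.

    ``delta_r2s`` is the relaxation-rate fluctuation in 1/ms; ``delta_rho``
    is the dimensionless relative net-magnetization fluctuation.
    """

    delta_r2s: np.ndarray
    delta_rho: np.ndarray

    def __post_init__(self) -> None:
        self.delta_r2s = np.asarray(self.delta_r2s, dtype=float)
        self.delta_rho = np.asarray(self.delta_rho, dtype=float)
        if self.delta_r2s.shape != self.delta_rho.shape:
            raise ValueError("delta_r2s and delta_rho must share shape")
        if self.delta_r2s.ndim != 2:
            raise ValueError("fluctuations must be (n_rois, n_t)")

    @property
    def n_rois(self) -> int:
        return self.delta_r2s.shape[0]

    @property
    def n_t(self) -> int:
        return self.delta_r2s.shape[1]


@dataclass
class DecayBaseline:
    """Baseline net magnetization and relaxation-rate grids.

    ``s0_bar`` >= 0 (0 outside the object); ``r2s_bar`` in 1/ms, positive
    inside the object. Gray-matter-like defaults correspond to T2* of 30-50
    ms, i.e. r2s_bar of 0.02-0.033 /ms.
    """

    s0_bar: np.ndarray
    r2s_bar: np.ndarray

    def __post_init__(self) -> None:
        self.s0_bar = np.asarray(self.s0_bar, dtype=float)
        self.r2s_bar = np.asarray(self.r2s_bar, dtype=float)
        if self.s0_bar.shape != self.r2s_bar.shape:
            raise ValueError("s0_bar and r2s_bar must share shape")
        if np.any(self.s0_bar < 0):
            raise ValueError("s0_bar must be non-negative")
        if np.any(self.r2s_bar[self.s0_bar > 0] <= 0):
            raise ValueError("r2s_bar must be positive inside the object")


def default_network_covariance(
    n_rois: int, sigma: float = 1.0, n_blocks: int = 5, within: float = 0.8
) -> np.ndarray:
    """Block-diagonal inter-ROI covariance: ``n_blocks`` near-equal blocks
    with within-block covariance ``within * sigma**2``, variance ``sigma**2``
    on the diagonal, and zero covariance between blocks."""
    cov = np.zeros((n_rois, n_rois))
    bounds = np.linspace(0, n_rois, n_blocks + 1).astype(int)
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        cov[b0:b1, b0:b1] = within * sigma**2
    np.fill_diagonal(cov, sigma**2)
    return cov


@dataclass
class SimConfig:
    """Configuration for ROI-level fluctuation simulation.

    ``bold_fraction`` is the share of signal-change variance carried by the
    relaxation term at the reference echo (second entry of ``echo_times``).
    ``network_covariance`` is the target inter-ROI covariance of the total
    fractional signal change at the reference echo; its diagonal sets the
    fluctuation amplitude.
    """

    n_rois: int = 50
    n_t: int = 500
    echo_times: tuple[float, ...] = (13.9, 31.7, 49.5)
    bold_fraction: float = 0.5
    network_covariance: np.ndarray | None = None
    thermal_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.bold_fraction <= 1.0:
            raise ValueError("bold_fraction must be in [0, 1]")
        if self.thermal_sigma < 0:
            raise ValueError("thermal_sigma must be >= 0")
        if len(self.echo_times) < 2:
            raise ValueError("need >=2 echo times")
        if self.network_covariance is None:
            self.network_covariance = default_network_covariance(self.n_rois)
        self.network_covariance = np.asarray(self.network_covariance, dtype=float)
        if self.network_covariance.shape != (self.n_rois, self.n_rois):
            raise ValueError("network_covariance must be (n_rois, n_rois)")
        if not np.allclose(self.network_covariance, self.network_covariance.T):
            raise ValueError("network_covariance must be symmetric")

    @property
    def te_ref(self) -> float:
        """Reference echo time (the second echo), in ms."""
        return float(self.echo_times[1])


def _psd_factor(cov: np.ndarray) -> np.ndarray:
    """Square-root factor of a PSD matrix; raises on negative eigenvalues."""
    vals, vecs = np.linalg.eigh(cov)
    tol = -1e-10 * max(1.0, float(np.abs(vals).max()))
    if vals.min() < tol:
        raise ValueError(
            f"network covariance is not positive semidefinite "
            f"(min eigenvalue {vals.min():g})"
        )
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def simulate_fluctuations(config: SimConfig) -> FluctuationSeries:
    """Draw the two fluctuation sources as independent zero-mean Gaussian
    processes with inter-ROI covariance proportional to the configured
    network covariance.

    At the reference echo, the variance split between the relaxation term
    (``delta_r2s * te_ref``) and the net-magnetization term is exactly
    ``bold_fraction`` : ``1 - bold_fraction``. Rows are demeaned so the
    zero-mean invariant holds exactly at finite n_t.
    """
    rng = np.random.default_rng(config.seed)
    factor = _psd_factor(config.network_covariance)
    z_rho = rng.standard_normal((config.n_rois, config.n_t))
    z_r2s = rng.standard_normal((config.n_rois, config.n_t))
    f = config.bold_fraction
    delta_rho = np.sqrt(1.0 - f) * (factor @ z_rho)
    delta_r2s = (np.sqrt(f) / config.te_ref) * (factor @ z_r2s)
    delta_rho -= delta_rho.mean(axis=1, keepdims=True)
    delta_r2s -= delta_r2s.mean(axis=1, keepdims=True)
    return FluctuationSeries(delta_r2s=delta_r2s, delta_rho=delta_rho)


def synthesize_roi_spc(fluct: FluctuationSeries, echo_times) -> ROITimeseriesSet:
    """Linearized fractional signal change per echo:
    S_x,i(t) = delta_rho_x(t) - delta_r2s_x(t) * TE_i (no noise term)."""
    echo_times = np.asarray(echo_times, dtype=float)
    values = (
        fluct.delta_rho[None, :, :]
        - fluct.delta_r2s[None, :, :] * echo_times[:, None, None]
    )
    return ROITimeseriesSet(values=values, echo_times=echo_times, units="spc")


def synthesize_voxel_scan(
    baseline: DecayBaseline,
    fluct: FluctuationSeries,
    voxel_labels: np.ndarray,
    echo_times,
    thermal_sigma: float = 0.0,
    seed: int = 0,
    tr: float | None = None,
) -> MEScan:
    """Full nonlinear multi-echo signal on a voxel grid.

    ``voxel_labels`` maps each voxel to a fluctuation row (integer labels
    1..n_rois; 0 = background carrying only baseline decay and noise).
    The signal is ``s0_bar * (1 + delta_rho) * exp(-(r2s_bar + delta_r2s) * TE)``
    plus i.i.d. Gaussian noise of sd ``thermal_sigma`` everywhere, including
    outside the object. Raises if any fluctuation drives the relaxation rate
    non-positive.
    """
    echo_times = np.asarray(echo_times, dtype=float)
    labels = np.asarray(voxel_labels)
    if labels.shape != baseline.s0_bar.shape:
        raise ValueError("voxel_labels grid must match the baseline grid")
    if labels.max() > fluct.n_rois:
        raise ValueError(
            f"label {labels.max()} exceeds number of fluctuation rows {fluct.n_rois}"
        )
    n_t = fluct.n_t
    shape = labels.shape

    # per-voxel fluctuation series; background voxels get zeros (row 0)
    rho = np.vstack([np.zeros((1, n_t)), fluct.delta_rho])
    r2s = np.vstack([np.zeros((1, n_t)), fluct.delta_r2s])
    vox_rho = rho[labels.ravel()]  # (n_vox, n_t)
    vox_r2s = r2s[labels.ravel()]

    r2s_total = baseline.r2s_bar.ravel()[:, None] + vox_r2s
    in_object = baseline.s0_bar.ravel() > 0
    bad = (r2s_total[in_object] <= 0).nonzero()
    if bad[0].size:
        vox_flat = np.flatnonzero(in_object)[bad[0][0]]
        vox_idx = np.unravel_index(vox_flat, shape)
        raise ValueError(
            f"fluctuation drives R2* non-positive at voxel {tuple(int(v) for v in vox_idx)}, "
            f"timepoint {int(bad[1][0])}"
        )

    rng = np.random.default_rng(seed)
    data = []
    s0 = baseline.s0_bar.ravel()[:, None] * (1.0 + vox_rho)
    for te in echo_times:
        signal = s0 * np.exp(-r2s_total * te)
        if thermal_sigma > 0:
            signal = signal + rng.normal(0.0, thermal_sigma, size=signal.shape)
        data.append(signal.reshape(*shape, n_t))
    mask = in_object.reshape(shape)
    return MEScan(data=data, echo_times=echo_times, tr=tr, mask=mask)


def saturation_offsets(
    tr_actual: np.ndarray, t1: float, nominal_tr: float
) -> np.ndarray:
    """Relative steady-state longitudinal magnetization change for per-volume
    repetition times ``tr_actual`` against the nominal TR:
    (1 - exp(-TR_t/T1)) / (1 - exp(-TR_nom/T1)) - 1."""
    if t1 <= 0:
        raise ValueError("T1 must be positive")
    if nominal_tr <= 0:
        raise ValueError("nominal TR must be positive")
    tr_actual = np.asarray(tr_actual, dtype=float)
    if np.any(tr_actual <= 0):
        raise ValueError("per-volume TR must be positive")
    denom = 1.0 - np.exp(-nominal_tr / t1)
    return (1.0 - np.exp(-tr_actual / t1)) / denom - 1.0


def apply_tr_jitter(
    fluct: FluctuationSeries,
    tr_offsets: np.ndarray,
    t1: float,
    nominal_tr: float,
) -> FluctuationSeries:
    """Emulate irregular-TR saturation effects as an added net-magnetization
    fluctuation, identical across ROIs and echoes.

    This uses a single-compartment T1 steady-state model; the per-timepoint
    term is demeaned before being added so the fluctuation rows stay
    zero-mean (a constant saturation offset belongs to the baseline, not the
    fluctuation).
    """
    tr_offsets = np.asarray(tr_offsets, dtype=float)
    if tr_offsets.shape != (fluct.n_t,):
        raise ValueError(
            f"tr_offsets must have length n_t={fluct.n_t}, got {tr_offsets.shape}"
        )
    term = saturation_offsets(nominal_tr + tr_offsets, t1, nominal_tr)
    term = term - term.mean()
    return FluctuationSeries(
        delta_r2s=fluct.delta_r2s.copy(),
        delta_rho=fluct.delta_rho + term[None, :],
    )


def generate_background_fixture(
    grid_shape: tuple[int, int, int],
    n_t: int,
    sigma: float,
    zero_fraction: float = 0.0,
    seed: int = 0,
    echo_times=(13.9, 31.7, 49.5),
    folded: bool = True,
) -> MEScan:
    """Object-free scan for exercising the thermal-noise estimator.

    Voxel values are ``|N(0, sigma)|`` (magnitude-image style) or signed
    ``N(0, sigma)`` when ``folded=False``; a ``zero_fraction`` of timepoints
    per voxel is forced to exactly zero (uniformly at random) to test the
    zero-count exclusion rule.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if not 0.0 <= zero_fraction <= 1.0:
        raise ValueError("zero_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    data = []
    for _ in echo_times:
        vol = rng.normal(0.0, sigma, size=(*grid_shape, n_t))
        if folded:
            vol = np.abs(vol)
        if zero_fraction > 0:
            zeros = rng.random(size=vol.shape) < zero_fraction
            vol[zeros] = 0.0
        data.append(vol)
    return MEScan(data=data, echo_times=np.asarray(echo_times, dtype=float))


def build_voxel_phantom(
    n_rois: int,
    voxels_per_roi: int = 8,
    margin: int = 2,
    s0: float = 1000.0,
    r2s: float = 0.025,
) -> tuple[DecayBaseline, np.ndarray]:
    """A compact cubic phantom: ``n_rois`` contiguous blocks of
    ``voxels_per_roi`` voxels inside a background shell of ``margin`` voxels.

    Returns the decay baseline and the integer label volume (0 = background).
    """
    n_obj = n_rois * voxels_per_roi
    side = int(np.ceil(n_obj ** (1.0 / 3.0)))
    shape = (side + 2 * margin, side + 2 * margin, side + 2 * margin)
    labels = np.zeros(shape, dtype=int)
    inner = np.zeros((side, side, side), dtype=int)
    flat = inner.ravel()
    for r in range(n_rois):
        flat[r * voxels_per_roi : (r + 1) * voxels_per_roi] = r + 1
    labels[margin : margin + side, margin : margin + side, margin : margin + side] = (
        flat.reshape(side, side, side)
    )
    s0_bar = np.where(labels > 0, s0, 0.0)
    r2s_bar = np.where(labels > 0, r2s, 1.0)  # positive placeholder outside object
    return DecayBaseline(s0_bar=s0_bar, r2s_bar=r2s_bar), labels
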