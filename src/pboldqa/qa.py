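"""Companion QA metrics: TSNR and background thermal-noise estimation."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from pboldqa.io_model import MEScan

logger = logging.getLogger("pboldqa.qa")

__all__ = ["TSNRSummary", "ThermalNoiseEstimate", "tsnr", "estimate_thermal_noise"]


@dataclass
class TSNRSummary:
    """Voxelwise TSNR map for one echo, plus the in-mask median."""

    tsnr_map: np.ndarray  # 3D, NaN where undefined (zero temporal sd)
    median: float
    n_undefined: int
    mask_provenance: str


@dataclass
class ThermalNoiseEstimate:
    """Per-echo thermal-noise sigma estimated from background voxels."""

    sigma: np.ndarray  # one value per echo, scanner units
    n_background: int
    n_excluded_mean: int
    n_excluded_zeros: int


def tsnr(
    data: np.ndarray,
    mask: np.ndarray | None = None,
    mean_to_reintroduce: np.ndarray | None = None,
) -> TSNRSummary:
    """Temporal SNR map: temporal mean / temporal sd (sample sd, Nt-1).

    When the input is a residual timeseries (detrended data with its mean
    removed), pass the original mean image as ``mean_to_reintroduce``; it is
    added back before the ratio is formed. Voxels with zero temporal sd get
    NaN and are excluded from the median, with a logged count.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D (x,y,z,t) grid, got {data.ndim}D")
    if data.shape[3] < 2:
        raise ValueError("TSNR requires at least 2 timepoints")
    if mean_to_reintroduce is not None:
        mean_to_reintroduce = np.asarray(mean_to_reintroduce, dtype=float)
        if mean_to_reintroduce.shape != data.shape[:3]:
            raise ValueError("mean image shape must match the spatial grid")
        data = data + mean_to_reintroduce[..., None]

    mean = data.mean(axis=3)
    sd = data.std(axis=3, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tsnr_map = mean / sd
    tsnr_map[sd == 0] = np.nan

    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
        provenance = "whole-grid"
    else:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != data.shape[:3]:
            raise ValueError("mask shape must match the spatial grid")
        provenance = "user-supplied"

    in_mask = tsnr_map[mask]
    n_undefined = int(np.isnan(in_mask).sum())
    if n_undefined:
        logger.warning(
            "%d in-mask voxels with zero temporal variance excluded from the "
            "TSNR median",
            n_undefined,
        )
    finite = in_mask[~np.isnan(in_mask)]
    median = float(np.median(finite)) if finite.size else float("nan")
    return TSNRSummary(
        tsnr_map=tsnr_map,
        median=median,
        n_undefined=n_undefined,
        mask_provenance=provenance,
    )


def estimate_thermal_noise(
    scan: MEScan,
    bg_mean_max: float = 2.0,
    max_zero_count: int = 20,
) -> ThermalNoiseEstimate:
    """Thermal-noise sigma per echo from object- and ghosting-free voxels.

    Background voxels are those with temporal mean <= ``bg_mean_max`` in
    every echo AND at most ``max_zero_count`` exactly-zero timepoints (in
    every echo). Per echo, sigma is the spatial standard deviation across
    background voxels computed per volume, averaged over timepoints; the
    per-volume form is robust to slow drifts. Intended for raw (unprocessed)
    data.

    Note the defaults are scanner-unit and run-length dependent: the mean
    threshold assumes raw scanner units, and the zero-count threshold is an
    absolute count, not a fraction of the number of timepoints.
    """
    stacked = np.stack([d.reshape(-1, scan.n_t) for d in scan.data])  # (e, v, t)
    means = stacked.mean(axis=2)  # (e, v)
    zero_counts = (stacked == 0).sum(axis=2)  # (e, v)

    low_mean = (means <= bg_mean_max).all(axis=0)
    few_zeros = (zero_counts <= max_zero_count).all(axis=0)
    background = low_mean & few_zeros

    n_excluded_mean = int((~low_mean).sum())
    n_excluded_zeros = int((low_mean & ~few_zeros).sum())
    n_background = int(background.sum())
    if n_background == 0:
        raise ValueError(
            "no object-free voxels; is this a skull-stripped or masked image?"
        )
    if n_background < 2:
        raise ValueError("need at least 2 background voxels for a spatial sd")

    bg = stacked[:, background, :]  # (e, n_bg, t)
    sigma = bg.std(axis=1, ddof=1).mean(axis=1)  # spatial sd per volume, then mean
    return ThermalNoiseEstimate(
        sigma=sigma,
        n_background=n_background,
        n_excluded_mean=n_excluded_mean,
        n_excluded_zeros=n_excluded_zeros,
    )
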