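"""Input/output layer: multi-echo NIfTI loading, parcellations, ROI extraction.

Volumes are NIfTI-1/2 files read through nibabel, one 4D file per echo.
Parcellations come either as an integer-labeled atlas on the scan grid or as
a TSV of spheres (label, x_mm, y_mm, z_mm, radius_mm) rasterized through the
scan affine. All voxel indices are 0-based; world coordinates go through the
NIfTI affine.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("pboldqa.io")

__all__ = [
    "MEScan",
    "Parcellation",
    "ROITimeseriesSet",
    "load_me_scan",
    "load_parcellation",
    "filter_rois_by_coverage",
    "extract_roi_timeseries",
    "write_report",
]


@dataclass
class MEScan:
    """A multi-echo scan: one 4D intensity grid per echo plus echo times.

    Parameters
    ----------
    data : list of ndarray
        One ``(x, y, z, t)`` array per echo, in scanner units.
    echo_times : ndarray
        Echo times in milliseconds, strictly increasing.
    tr : float, optional
        Nominal repetition time in seconds.
    mask : ndarray, optional
        3D boolean array of in-brain voxels.
    affine : ndarray
        4x4 voxel-to-world affine (identity if unknown).
    """

    data: list[np.ndarray]
    echo_times: np.ndarray
    tr: float | None = None
    mask: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if len(self.data) != self.echo_times.size:
            raise ValueError(
                f"{len(self.data)} data grids but {self.echo_times.size} echo times"
            )
        if len(self.data) < 2:
            raise ValueError("p_BOLD requires >=2 echoes")
        if np.any(self.echo_times <= 0):
            raise ValueError("echo times must be positive")
        if np.any(np.diff(self.echo_times) <= 0):
            raise ValueError("echo times must be strictly increasing")
        shapes = {d.shape for d in self.data}
        if len(shapes) != 1:
            raise ValueError(f"echo grids have inconsistent shapes: {sorted(shapes)}")
        shape = self.data[0].shape
        if len(shape) != 4:
            raise ValueError(f"expected 4D (x,y,z,t) grids, got shape {shape}")
        if shape[3] < 2:
            raise ValueError("need at least 2 timepoints")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != shape[:3]:
                raise ValueError(
                    f"mask shape {self.mask.shape} != spatial grid {shape[:3]}"
                )

    @property
    def n_echoes(self) -> int:
        return len(self.data)

    @property
    def n_t(self) -> int:
        return self.data[0].shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data[0].shape[:3]


@dataclass
class Parcellation:
    """Mapping from integer ROI labels to voxel index sets on a scan grid.

    ``roi_voxel_sets[label]`` is an ``(n, 3)`` integer array of voxel indices;
    ``coverage[label]`` is the fraction of the ROI's voxels inside the mask
    used at construction/filter time (1.0 if no mask has been applied).
    """

    roi_ids: list[int]
    roi_voxel_sets: dict[int, np.ndarray]
    coverage: dict[int, float] = field(default_factory=dict)
    grid_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if len(set(self.roi_ids)) != len(self.roi_ids):
            raise ValueError("ROI labels must be unique")
        for label in self.roi_ids:
            vox = np.asarray(self.roi_voxel_sets[label], dtype=int).reshape(-1, 3)
            self.roi_voxel_sets[label] = vox
            if self.grid_shape is not None and vox.size:
                if np.any(vox < 0) or np.any(vox >= np.array(self.grid_shape)):
                    raise ValueError(f"ROI {label} has voxel indices off the grid")
            cov = self.coverage.setdefault(label, 1.0)
            if not 0.0 <= cov <= 1.0:
                raise ValueError(f"coverage for ROI {label} outside [0, 1]: {cov}")

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)


@dataclass
class ROITimeseriesSet:
    """Per-echo matrices of ROI timeseries, shape ``(n_echoes, n_rois, n_t)``.

    ``units`` is ``"raw"`` (scanner units) or ``"spc"`` (fractional signal
    change). In spc units every row is expected to have (near-)zero temporal
    mean; :meth:`validate_spc` checks this explicitly, it is not enforced at
    construction so that model-generated series remain representable.
    """

    values: np.ndarray
    echo_times: np.ndarray
    units: str
    roi_ids: list[int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (n_echoes, n_rois, n_t)")
        if self.values.shape[0] != self.echo_times.size:
            raise ValueError("first axis of values must match number of echo times")
        if self.units not in ("raw", "spc"):
            raise ValueError(f"units must be 'raw' or 'spc', got {self.units!r}")
        if self.roi_ids is None:
            self.roi_ids = list(range(1, self.values.shape[1] + 1))
        elif len(self.roi_ids) != self.values.shape[1]:
            raise ValueError("roi_ids length must match second axis of values")

    @property
    def n_echoes(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    @property
    def n_t(self) -> int:
        return self.values.shape[2]

    def validate_spc(self, rtol: float = 1e-10) -> None:
        """Assert every row has temporal mean 0 within ``rtol`` of its scale."""
        if self.units != "spc":
            raise ValueError("validate_spc only applies to spc-unit sets")
        means = self.values.mean(axis=2)
        scale = np.abs(self.values).max(axis=2)
        scale[scale == 0] = 1.0
        if np.any(np.abs(means) > rtol * scale):
            raise ValueError("spc rows do not have zero temporal mean")


def load_me_scan(
    paths: Sequence[str | os.PathLike],
    echo_times: Sequence[float],
    mask_path: str | os.PathLike | None = None,
) -> MEScan:
    """Load one 4D NIfTI per echo into an :class:`MEScan`.

    Echoes given out of TE order are sorted ascending with a warning. Shape
    mismatches, non-4D inputs, and fewer than 2 echoes are hard errors.
    """
    paths = list(paths)
    echo_times = np.asarray(echo_times, dtype=float)
    if len(paths) != echo_times.size:
        raise ValueError(
            f"{len(paths)} echo files but {echo_times.size} echo times given"
        )
    if len(paths) < 2:
        raise ValueError("p_BOLD requires >=2 echoes")

    order = np.argsort(echo_times, kind="stable")
    if not np.array_equal(order, np.arange(len(paths))):
        logger.warning(
            "echo files were not given in ascending TE order; reordering to %s",
            echo_times[order].tolist(),
        )
        paths = [paths[i] for i in order]
        echo_times = echo_times[order]

    data = []
    affine = None
    ref_shape = None
    for path, te in zip(paths, echo_times):
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj, dtype=float)
        if arr.ndim != 4:
            raise ValueError(f"{path}: expected a 4D NIfTI, got {arr.ndim}D")
        if ref_shape is None:
            ref_shape = arr.shape
            affine = img.affine
        elif arr.shape != ref_shape:
            raise ValueError(
                f"{path}: shape {arr.shape} does not match first echo {ref_shape}"
            )
        data.append(arr)

    mask = None
    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        mask = np.asarray(mimg.dataobj) > 0
        if mask.shape != ref_shape[:3]:
            raise ValueError(
                f"{mask_path}: mask shape {mask.shape} != scan grid {ref_shape[:3]}"
            )

    return MEScan(data=data, echo_times=echo_times, mask=mask, affine=affine)


def _rasterize_spheres(
    table: pd.DataFrame, grid_shape: tuple[int, int, int], affine: np.ndarray
) -> dict[int, np.ndarray]:
    """Rasterize spheres: a voxel belongs to a sphere iff its world-space
    center lies within ``radius_mm`` of the sphere center."""
    idx = np.indices(grid_shape).reshape(3, -1).T  # (n_vox, 3), 0-based
    homog = np.c_[idx, np.ones(len(idx))]
    world = homog @ affine.T  # (n_vox, 4)
    world = world[:, :3]
    sets: dict[int, np.ndarray] = {}
    for row in table.itertuples(index=False):
        center = np.array([row.x_mm, row.y_mm, row.z_mm], dtype=float)
        dist = np.linalg.norm(world - center, axis=1)
        inside = dist <= float(row.radius_mm)
        label = int(row.label)
        sets[label] = idx[inside]
        if not inside.any():
            logger.warning(
                "ROI %d: sphere at %s (r=%.1f mm) contains no voxel center",
                label,
                center.tolist(),
                row.radius_mm,
            )
    return sets


def load_parcellation(
    source: str | os.PathLike | pd.DataFrame,
    grid_shape: tuple[int, int, int] | None = None,
    affine: np.ndarray | None = None,
) -> Parcellation:
    """Load a parcellation from a labeled atlas NIfTI or a sphere table.

    Parameters
    ----------
    source
        Path to an integer-labeled NIfTI atlas, a path to a sphere TSV with
        columns ``label, x_mm, y_mm, z_mm, radius_mm``, or an equivalent
        DataFrame.
    grid_shape, affine
        Scan geometry; required for sphere tables, used for grid validation
        with atlases.
    """
    if isinstance(source, pd.DataFrame) or str(source).endswith((".tsv", ".csv", ".txt")):
        if isinstance(source, pd.DataFrame):
            table = source
        else:
            table = pd.read_csv(source, sep=None, engine="python")
        required = {"label", "x_mm", "y_mm", "z_mm", "radius_mm"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"sphere table missing columns: {sorted(missing)}")
        if grid_shape is None or affine is None:
            raise ValueError("sphere tables require the scan grid shape and affine")
        sets = _rasterize_spheres(table, grid_shape, affine)
        labels = [int(x) for x in table["label"]]
        return Parcellation(roi_ids=labels, roi_voxel_sets=sets, grid_shape=grid_shape)

    img = nib.load(str(source))
    atlas = np.asarray(img.dataobj)
    if atlas.ndim == 4 and atlas.shape[3] == 1:
        atlas = atlas[..., 0]
    if atlas.ndim != 3:
        raise ValueError(f"atlas must be 3D, got {atlas.ndim}D")
    if grid_shape is not None and atlas.shape != tuple(grid_shape):
        raise ValueError(
            f"atlas grid {atlas.shape} does not match scan grid {tuple(grid_shape)}"
        )
    atlas = np.rint(atlas).astype(int)
    labels = sorted(int(v) for v in np.unique(atlas) if v != 0)
    sets = {
        label: np.argwhere(atlas == label) for label in labels
    }
    return Parcellation(roi_ids=labels, roi_voxel_sets=sets, grid_shape=atlas.shape)


def filter_rois_by_coverage(
    parcellation: Parcellation, mask: np.ndarray, threshold: float = 0.95
) -> Parcellation:
    """Keep only ROIs with at least ``threshold`` of their voxels inside ``mask``.

    The boundary is inclusive: coverage exactly equal to the threshold is
    retained. Raises if no ROI survives.
    """
    mask = np.asarray(mask).astype(bool)
    if parcellation.grid_shape is not None and mask.shape != parcellation.grid_shape:
        raise ValueError(
            f"mask shape {mask.shape} != parcellation grid {parcellation.grid_shape}"
        )
    kept_ids: list[int] = []
    kept_sets: dict[int, np.ndarray] = {}
    coverage: dict[int, float] = {}
    dropped: list[int] = []
    for label in parcellation.roi_ids:
        vox = parcellation.roi_voxel_sets[label]
        if vox.size == 0:
            dropped.append(label)
            continue
        inside = mask[vox[:, 0], vox[:, 1], vox[:, 2]]
        cov = float(inside.mean())
        if cov >= threshold:
            kept_ids.append(label)
            kept_sets[label] = vox
            coverage[label] = cov
        else:
            dropped.append(label)
    if dropped:
        logger.warning(
            "coverage filter (threshold=%.2f) dropped %d ROI(s): %s",
            threshold,
            len(dropped),
            dropped,
        )
    if not kept_ids:
        raise ValueError("no ROI survives coverage filter")
    return Parcellation(
        roi_ids=kept_ids,
        roi_voxel_sets=kept_sets,
        coverage=coverage,
        grid_shape=parcellation.grid_shape,
    )


def extract_roi_timeseries(
    scan: MEScan, parcellation: Parcellation
) -> ROITimeseriesSet:
    """Unweighted spatial mean over each ROI's voxels, per echo and timepoint."""
    n_r = parcellation.n_rois
    values = np.empty((scan.n_echoes, n_r, scan.n_t), dtype=float)
    for r, label in enumerate(parcellation.roi_ids):
        vox = parcellation.roi_voxel_sets[label]
        if vox.size == 0:
            raise ValueError(f"ROI {label} has no voxels; run the coverage filter first")
        for e in range(scan.n_echoes):
            block = scan.data[e][vox[:, 0], vox[:, 1], vox[:, 2], :]  # (n_vox, n_t)
            values[e, r, :] = block.mean(axis=0)
    return ROITimeseriesSet(
        values=values,
        echo_times=scan.echo_times,
        units="raw",
        roi_ids=list(parcellation.roi_ids),
    )


def write_report(result, aux: Mapping | None, out_dir: str | os.PathLike) -> dict:
    """Write the scan-level QA summary (JSON + TSV mirror) and the per-quadruple
    edge table (TSV).

    ``result`` is a :class:`pboldqa.pbold.PBOLDResult`; ``aux`` may carry
    ``tsnr_median`` (per-echo list), ``thermal_sigma`` (per-echo list),
    ``seed``, ``config`` and warning counters, all copied verbatim into the
    summary. Returns the paths written.
    """
    from pboldqa import __version__

    if not str(out_dir):
        raise ValueError("output directory must be a non-empty path")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    summary: dict = {
        "tool": "pbold-qa",
        "version": __version__,
        "p_bold": result.p_bold,
        "n_rois": result.n_rois,
        "n_quadruples": len(result.per_quadruple),
        "te_list_ms": [float(t) for t in result.te_list],
        "per_quadruple": [
            {
                "quadruple_id": q_id,
                "te_pair_x": list(entry.quad.pair_x),
                "te_pair_y": list(entry.quad.pair_y),
                "slope": entry.quad.slope,
                "theta": entry.quad.theta,
                "chord": entry.quad.chord,
                "p_bold": None if np.isnan(entry.p_bold) else entry.p_bold,
                "n_edges": entry.n_edges,
            }
            for q_id, entry in enumerate(result.per_quadruple)
        ],
    }
    if aux:
        for key, val in aux.items():
            summary[key] = val

    json_path = out / "summary.json"
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2)

    flat = {
        "p_bold": result.p_bold,
        "n_rois": result.n_rois,
        "n_quadruples": len(result.per_quadruple),
    }
    if aux:
        for key, val in aux.items():
            if isinstance(val, (list, tuple)):
                for i, v in enumerate(val):
                    flat[f"{key}_{i + 1}"] = v
            elif np.isscalar(val):
                flat[key] = val
    tsv_path = out / "summary.tsv"
    pd.DataFrame([flat]).to_csv(tsv_path, sep="\t", index=False)

    edge_rows = []
    for q_id, entry in enumerate(result.per_quadruple):
        if entry.edges is None:
            continue
        for edge in entry.edges:
            edge_rows.append(
                {
                    "quadruple_id": q_id,
                    "te_pair_x": f"{entry.quad.pair_x[0]:g}x{entry.quad.pair_x[1]:g}",
                    "te_pair_y": f"{entry.quad.pair_y[0]:g}x{entry.quad.pair_y[1]:g}",
                    "roi_a": edge.roi_a,
                    "roi_b": edge.roi_b,
                    "fc_x": edge.fc_x,
                    "fc_y": edge.fc_y,
                    "d_so": edge.d_so,
                    "d_bold": edge.d_bold,
                    "pref": edge.pref,
                    "weight": edge.weight,
                }
            )
    edges_path = out / "edges.tsv"
    pd.DataFrame(
        edge_rows,
        columns=[
            "quadruple_id",
            "te_pair_x",
            "te_pair_y",
            "roi_a",
            "roi_b",
            "fc_x",
            "fc_y",
            "d_so",
            "d_bold",
            "pref",
            "weight",
        ],
    ).to_csv(edges_path, sep="\t", index=False)

    return {"summary_json": str(json_path), "summary_tsv": str(tsv_path), "edges_tsv": str(edges_path)}
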