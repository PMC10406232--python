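"""Target time-series extraction: atlas-ROI means and spatial regression.

A decoding target y(t) is either the unweighted mean series over an
anatomical ROI mask, or a network time series obtained by *spatial
regression* (stage 1 of dual regression): at every time point the in-brain
voxel intensities are regressed on all network template maps jointly (plus an
intercept), and the coefficient of template k over time is network k's
series. Templates are z-scored within the brain mask before regression so
coefficient scales are comparable across networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import BoldRun, InputError, VolumeGrid

__all__ = [
    "TargetSeries",
    "TemplateSet",
    "roi_mean_series",
    "spatial_regression_series",
    "zscore_series",
]


@dataclass
class TargetSeries:
    """A named label signal y(t) for one network or region."""

    name: str
    values: np.ndarray
    kind: str = "roi-mean"  # or "spatial-regression"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.values)):
            raise InputError(f"target series {self.name!r} contains non-finite values")
        if self.kind not in ("roi-mean", "spatial-regression"):
            raise InputError(f"unknown target kind {self.kind!r}")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class TemplateSet:
    """K spatial template maps plus the brain mask they live in."""

    names: list[str]
    maps: list[VolumeGrid]
    brain_mask: VolumeGrid

    def __post_init__(self) -> None:
        if len(self.names) != len(self.maps) or not self.maps:
            raise InputError("TemplateSet needs >= 1 named template")
        mask = np.asarray(self.brain_mask.data, dtype=bool)
        if not mask.any():
            raise InputError("brain mask is empty")
        shapes = {m.shape for m in self.maps} | {self.brain_mask.shape}
        if len(shapes) != 1:
            raise InputError("templates and mask must share one grid")
        for name, m in zip(self.names, self.maps):
            if not np.any(np.asarray(m.data)[mask] != 0):
                raise InputError(f"template {name!r} has no support inside the mask")

    @property
    def K(self) -> int:
        return len(self.maps)


def zscore_series(values: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance rescaling (population sd); constant -> zeros."""
    v = np.asarray(values, dtype=np.float64)
    sd = v.std()
    if sd == 0:
        return v - v.mean()
    return (v - v.mean()) / sd


def roi_mean_series(run: BoldRun, roi_mask: VolumeGrid, name: str = "roi") -> TargetSeries:
    """Unweighted mean of the run over the ROI voxels, per time point."""
    m = np.asarray(roi_mask.data, dtype=bool)
    if m.shape != run.grid_shape:
        raise InputError("ROI mask shape does not match the run grid")
    if not m.any():
        raise InputError("ROI mask is empty")
    return TargetSeries(name, run.data[m].mean(axis=0), kind="roi-mean")


def spatial_regression_series(
    run: BoldRun, templates: TemplateSet
) -> list[TargetSeries]:
    """Stage-1 dual regression of the run on all templates jointly.

    For each time point, OLS of the in-mask intensities on the K z-scored
    templates plus an intercept; template k's coefficient over time is
    series k. A global per-time-point additive shift is absorbed by the
    intercept and leaves every series unchanged.
    """
    mask = np.asarray(templates.brain_mask.data, dtype=bool)
    if mask.shape != run.grid_shape:
        raise InputError("template grid does not match the run grid")
    V = int(mask.sum())
    design = np.empty((V, templates.K + 1))
    design[:, 0] = 1.0
    for k, tmap in enumerate(templates.maps):
        col = np.asarray(tmap.data, dtype=np.float64)[mask]
        sd = col.std()
        design[:, k + 1] = (col - col.mean()) / sd if sd > 0 else col - col.mean()

    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name the most collinear template pair for the error message
        sub = design[:, 1:]
        cc = np.corrcoef(sub.T)
        np.fill_diagonal(cc, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(cc)), cc.shape)
        raise InputError(
            "rank-deficient template matrix; most collinear pair: "
            f"{templates.names[i]!r} and {templates.names[j]!r}"
        )

    Y = run.data[mask]  # V x T
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)  # (K+1) x T
    return [
        TargetSeries(templates.names[k], beta[k + 1], kind="spatial-regression")
        for k in range(templates.K)
    ]
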