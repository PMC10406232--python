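"""Nuisance variable regression and spatial smoothing.

Each run is cleaned by regressing out, voxelwise, a nuisance design made of
the white-matter and CSF mean time series, the six motion parameters, and an
orthogonal polynomial drift basis up to order 4; the residuals are then
smoothed with a 6 mm FWHM Gaussian kernel. The regression is ordinary least
squares per voxel, so residuals are orthogonal to every retained design
column.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import ndimage

from .core_io import BoldRun, InputError, VolumeGrid

__all__ = [
    "NuisanceDesign",
    "ConfoundRegressor",
    "orthogonal_polynomial_basis",
    "build_nuisance_design",
    "regress_out",
    "smooth",
    "preprocess_run",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class NuisanceDesign:
    """A T x K nuisance design matrix with column labels.

    Columns are standardized (except the intercept) and rank-reduced: any
    column that does not increase the rank of the design is dropped with a
    warning, so the retained design has full column rank.
    """

    matrix: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.labels):
            raise InputError("design matrix / label mismatch")

    @property
    def T(self) -> int:
        return self.matrix.shape[0]

    @property
    def K(self) -> int:
        return self.matrix.shape[1]


def orthogonal_polynomial_basis(n_points: int, order: int) -> np.ndarray:
    """Discretely orthonormal polynomial columns of degree 0..order.

    Gram-Schmidt (QR) orthogonalization of the Vandermonde columns
    {1, t, t^2, ...} on ``n_points`` equispaced points in [-1, 1]; spans the
    same space as raw powers but is perfectly conditioned. Column d is signed
    so its leading (degree-d) coefficient is positive. Returns an
    (n_points, order+1) array with orthonormal columns.
    """
    if n_points < order + 1:
        raise InputError(f"need at least {order + 1} time points for order {order}")
    t = np.linspace(-1.0, 1.0, n_points)
    V = np.vander(t, N=order + 1, increasing=True)
    Q, R = np.linalg.qr(V)
    return Q * np.sign(np.diag(R))


def _mean_series(run: BoldRun, mask: VolumeGrid | None) -> np.ndarray | None:
    if mask is None:
        return None
    m = np.asarray(mask.data, dtype=bool)
    if m.shape != run.grid_shape:
        raise InputError("mask shape does not match the run grid")
    if not m.any():
        return None
    return run.data[m].mean(axis=0)


def build_nuisance_design(
    run: BoldRun,
    wm_mask: VolumeGrid | None = None,
    csf_mask: VolumeGrid | None = None,
    motion: np.ndarray | None = None,
    poly_order: int = 4,
) -> NuisanceDesign:
    """Assemble the nuisance design for one run.

    Columns, in order: WM mean series, CSF mean series, 6 motion parameters,
    orthogonal polynomials of degree 0..poly_order (degree 0 is the
    intercept). Empty masks drop their column with a warning; columns
    collinear with the ones before them (e.g. a constant motion trace vs the
    intercept) are dropped with a warning.
    """
    T = run.T
    columns: list[np.ndarray] = []
    labels: list[str] = []

    wm = _mean_series(run, wm_mask)
    if wm_mask is not None and wm is None:
        warnings.warn("empty WM mask: column omitted", stacklevel=2)
    if wm is not None:
        columns.append(wm)
        labels.append("wm")
    csf = _mean_series(run, csf_mask)
    if csf_mask is not None and csf is None:
        warnings.warn("empty CSF mask: column omitted", stacklevel=2)
    if csf is not None:
        columns.append(csf)
        labels.append("csf")

    if motion is not None:
        motion = np.asarray(motion, dtype=np.float64)
        if motion.shape != (T, 6):
            raise InputError(f"motion table must be ({T}, 6), got {motion.shape}")
        for j in range(6):
            columns.append(motion[:, j])
            labels.append(f"motion{j + 1}")

    poly = orthogonal_polynomial_basis(T, poly_order)
    for d in range(poly_order + 1):
        columns.append(poly[:, d])
        labels.append(f"poly{d}")

    # standardize non-constant columns for conditioning; the span is unchanged
    std_cols = []
    for col, lab in zip(columns, labels):
        sd = col.std()
        if sd > 0 and lab != "poly0":
            col = (col - col.mean()) / sd if lab.startswith(("wm", "csf", "motion")) else col / np.abs(col).max()
        std_cols.append(col)

    kept: list[np.ndarray] = []
    kept_labels: list[str] = []
    # poly0 (intercept) is seeded first so constant nuisance traces are the
    # ones flagged as redundant, then columns re-enter in their stated order
    order = sorted(range(len(std_cols)), key=lambda i: labels[i] != "poly0")
    basis: np.ndarray | None = None
    dropped: list[str] = []
    keep_flags = [False] * len(std_cols)
    for i in order:
        col = std_cols[i]
        if basis is None:
            cand = col[:, None]
        else:
            cand = np.column_stack([basis, col])
        if np.linalg.matrix_rank(cand) > (0 if basis is None else basis.shape[1]):
            basis = cand
            keep_flags[i] = True
        else:
            dropped.append(labels[i])
    if dropped:
        warnings.warn(f"dropped collinear nuisance columns: {dropped}", stacklevel=2)
    for flag, col, lab in zip(keep_flags, std_cols, labels):
        if flag:
            kept.append(col)
            kept_labels.append(lab)
    return NuisanceDesign(np.column_stack(kept), kept_labels)


class ConfoundRegressor:
    """OLS confound removal over a T x V data matrix (sklearn-style transformer).

    ``fit`` stores the design's pseudoinverse; ``transform`` returns the
    least-squares residual of every column of the data against the design.
    """

    def __init__(self, design: NuisanceDesign):
        self.design = design

    def fit(self, X: np.ndarray | None = None, y=None) -> "ConfoundRegressor":
        D = self.design.matrix
        self.pinv_ = np.linalg.pinv(D)
        self.design_ = D
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.shape[0] != self.design_.shape[0]:
            raise InputError("data rows do not match design rows")
        beta = self.pinv_ @ X
        return X - self.design_ @ beta

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).transform(X)


def regress_out(run: BoldRun, design: NuisanceDesign) -> BoldRun:
    """Replace each voxel series by its OLS residual against the design."""
    if design.T != run.T:
        raise InputError(f"design has {design.T} rows, run has {run.T}")
    flat = run.data.reshape(-1, run.T).T  # T x V
    resid = ConfoundRegressor(design).fit_transform(flat)
    data = resid.T.reshape(run.data.shape)
    return BoldRun(data, run.voxel_size_mm, run.tr_s)


def smooth(run: BoldRun, fwhm_mm: float = 6.0) -> BoldRun:
    """Per-volume Gaussian smoothing with the kernel width given as FWHM in mm.

    sigma per axis is ``fwhm / (2 sqrt(2 ln 2))`` divided by the voxel size;
    reflective boundaries preserve the volume-wide mean. ``fwhm_mm = 0`` is
    the identity.
    """
    if fwhm_mm < 0:
        raise InputError(f"FWHM must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return run
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / v for v in run.voxel_size_mm]
    out = ndimage.gaussian_filter(
        run.data, sigma=sigma_vox + [0.0], mode="reflect"
    )
    return BoldRun(out, run.voxel_size_mm, run.tr_s)


def preprocess_run(
    run: BoldRun,
    wm_mask: VolumeGrid | None = None,
    csf_mask: VolumeGrid | None = None,
    motion: np.ndarray | None = None,
    poly_order: int = 4,
    fwhm_mm: float = 6.0,
    smooth_first: bool = False,
) -> BoldRun:
    """Nuisance regression followed by smoothing (order configurable)."""
    design = build_nuisance_design(run, wm_mask, csf_mask, motion, poly_order)
    if smooth_first:
        return regress_out(smooth(run, fwhm_mm), design)
    return smooth(regress_out(run, design), fwhm_mm)
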