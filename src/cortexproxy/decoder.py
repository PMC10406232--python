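"""Linear epsilon-insensitive support vector regression from surface features.

The decoder relates the surface feature vector x(t) (one column per surface
voxel, or per volumetric subdivision) to a target series y(t) via a linear
SVR model w, b: y_hat(t) = w . x(t) + b. Accuracy is estimated by split-half
cross-validation across a subject's two runs and summarized as the Pearson
correlation r between predicted and observed target series on the held-out
run.

:class:`SurfaceDecoder` is a scikit-learn estimator (fit/predict,
``coef_``/``intercept_``); the module-level functions (``train_svr``,
``predict``, ``crossvalidate``) are thin wrappers that additionally track
feature provenance so a model can never be applied to a mismatched voxel set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import warnings

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted, validate_data

from .core_io import BoldRun, InputError, VolumeGrid
from .targets import TargetSeries

__all__ = [
    "FeatureMatrix",
    "SvrConfig",
    "LinearSvrModel",
    "AccuracyResult",
    "SurfaceDecoder",
    "svmlight_default_C",
    "primal_objective",
    "extract_features",
    "train_svr",
    "predict",
    "crossvalidate",
    "residual_diagnostics",
    "safe_pearson_r",
    "save_model",
    "load_model",
    "weights_to_volume",
]


def svmlight_default_C(X: np.ndarray) -> float:
    """The SVM-light default cost: 1 / mean_i ||x_i||^2 over training rows."""
    X = np.asarray(X, dtype=np.float64)
    avg_sq = float(np.mean(np.sum(X**2, axis=1)))
    if avg_sq <= 0:
        raise InputError("cannot derive default C from all-zero features")
    return 1.0 / avg_sq


def primal_objective(
    w: np.ndarray, b: float, X: np.ndarray, y: np.ndarray, C: float, epsilon: float
) -> float:
    """Primal SVR objective: 0.5 ||w||^2 + C * sum_t max(0, |y - w.x - b| - eps)."""
    w = np.asarray(w, dtype=np.float64)
    resid = np.abs(np.asarray(y) - (np.asarray(X) @ w + b))
    return 0.5 * float(w @ w) + C * float(np.maximum(0.0, resid - epsilon).sum())


class SurfaceDecoder(RegressorMixin, BaseEstimator):
    """Linear epsilon-SVR decoder (scikit-learn estimator).

    Parameters
    ----------
    C : float or "auto", default=100.0
        Regularization cost. ``"auto"`` uses the SVM-light default,
        ``1 / mean ||x||^2`` over the training rows, recomputed at each fit
        (used for the sparse subdivision models).
    epsilon : float, default=0.1
        Half-width of the insensitivity tube.
    tol : float, default=1e-6
        Solver stopping tolerance (duality-gap based; deterministic SMO).
    max_iter : int, default=1_000_000
        Hard cap on SMO iterations; bounds the worst case on targets that are
        far outside the feature span (surrogate labels can be such targets).

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Primal weight vector w.
    intercept_ : float
        Bias b.
    C_ : float
        The cost actually used (resolved from "auto" if applicable).
    """

    def __init__(
        self,
        C: float | str = 100.0,
        epsilon: float = 0.1,
        tol: float = 1e-6,
        max_iter: int = 1_000_000,
    ):
        self.C = C
        self.epsilon = epsilon
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y) -> "SurfaceDecoder":
        X, y = validate_data(self, X, y, y_numeric=True, dtype=np.float64)
        if X.shape[0] < 2:
            raise InputError("need at least 2 training rows")
        if float(np.std(y)) == 0.0:
            raise InputError("degenerate target: zero variance")
        if self.epsilon < 0:
            raise InputError("epsilon must be >= 0")
        if self.C == "auto":
            self.C_ = svmlight_default_C(X)
        else:
            self.C_ = float(self.C)
            if self.C_ <= 0:
                raise InputError("C must be positive")
        svr = SVR(
            kernel="linear", C=self.C_, epsilon=self.epsilon, tol=self.tol,
            max_iter=self.max_iter,
        )
        svr.fit(X, y)
        self.coef_ = np.asarray(svr.coef_, dtype=np.float64).ravel()
        self.intercept_ = float(np.ravel(svr.intercept_)[0])
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = validate_data(self, X, reset=False, dtype=np.float64)
        return X @ self.coef_ + self.intercept_


@dataclass
class FeatureMatrix:
    """T x F feature matrix plus per-column provenance.

    Provenance entries are hashable identifiers: a voxel coordinate tuple in
    voxel mode, or ``("sub", i)`` in subdivision mode; they cover columns
    bijectively and are compared exactly before any prediction.
    """

    data: np.ndarray
    provenance: tuple

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.provenance = tuple(self.provenance)
        if self.data.ndim != 2:
            raise InputError("feature matrix must be 2-D (time x features)")
        if self.data.shape[1] != len(self.provenance):
            raise InputError("provenance does not cover all feature columns")
        if len(set(self.provenance)) != len(self.provenance):
            raise InputError("provenance entries must be unique")

    @property
    def T(self) -> int:
        return self.data.shape[0]

    @property
    def F(self) -> int:
        return self.data.shape[1]


@dataclass
class SvrConfig:
    """Hyperparameters: C (100 for full-surface models, "auto" = SVM-light
    default for subdivision models), epsilon (0.1), linear kernel only."""

    C_reg: float | str = 100.0
    epsilon: float = 0.1
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.C_reg != "auto" and float(self.C_reg) <= 0:
            raise InputError("C must be positive or 'auto'")
        if self.epsilon < 0:
            raise InputError("epsilon must be >= 0")


@dataclass
class LinearSvrModel:
    """A trained linear SVR: weights w, bias b, config, feature provenance."""

    weights: np.ndarray
    bias: float
    config: SvrConfig
    provenance: tuple
    C_used: float = 0.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.weights)) or not np.isfinite(self.bias):
            raise InputError("non-finite model parameters")
        if len(self.provenance) != self.weights.shape[0]:
            raise InputError("provenance does not match the weight vector")


@dataclass
class AccuracyResult:
    """Split-half cross-validation outcome for one (subject, target)."""

    r_per_direction: tuple[float, float]
    mean_r: float
    predicted: list[np.ndarray]
    observed: list[np.ndarray]
    residuals: list[np.ndarray] = field(default_factory=list)
    zero_variance_flags: tuple[bool, bool] = (False, False)


def extract_features(run: BoldRun, mask_or_subdivisions) -> FeatureMatrix:
    """Build the T x F feature matrix for one run.

    Voxel mode (``mask_or_subdivisions`` is a :class:`VolumeGrid` mask): one
    column per mask voxel in lexicographic index order. Subdivision mode (a
    ``SubdivisionSet``): one column per subdivision, the unweighted mean of
    its member voxels.
    """
    if isinstance(mask_or_subdivisions, VolumeGrid):
        m = np.asarray(mask_or_subdivisions.data, dtype=bool)
        if m.shape != run.grid_shape:
            raise InputError("feature mask shape does not match the run grid")
        if not m.any():
            raise InputError("feature mask is empty")
        coords = np.argwhere(m)  # lexicographic (C-order) by construction
        X = run.data[m].T  # T x F, same C-order as argwhere
        prov = tuple(tuple(int(c) for c in row) for row in coords)
        return FeatureMatrix(X, prov)
    # subdivision mode (duck-typed to avoid an import cycle)
    subs = mask_or_subdivisions
    if len(subs.subdivisions) == 0:
        raise InputError("subdivision set is empty")
    cols = []
    prov = []
    for i, sub in enumerate(subs.subdivisions):
        vox = np.asarray(sub.voxels)
        if (vox < 0).any() or (vox >= np.array(run.grid_shape)).any():
            raise InputError("subdivision voxel outside the run grid")
        cols.append(run.data[vox[:, 0], vox[:, 1], vox[:, 2], :].mean(axis=0))
        prov.append(("sub", i))
    return FeatureMatrix(np.column_stack(cols), tuple(prov))


def train_svr(X: FeatureMatrix, y: TargetSeries | np.ndarray, cfg: SvrConfig | None = None) -> LinearSvrModel:
    """Fit the linear SVR and return the primal model with provenance."""
    cfg = cfg or SvrConfig()
    yv = y.values if isinstance(y, TargetSeries) else np.asarray(y, dtype=np.float64)
    if X.T != yv.shape[0]:
        raise InputError(f"feature rows ({X.T}) != target length ({yv.shape[0]})")
    if X.T < 8:
        raise InputError("need at least 8 time points to train")
    if not np.all(np.isfinite(X.data)):
        raise InputError("non-finite feature values")
    est = SurfaceDecoder(C=cfg.C_reg, epsilon=cfg.epsilon, tol=cfg.tol).fit(X.data, yv)
    return LinearSvrModel(est.coef_, est.intercept_, cfg, X.provenance, C_used=est.C_)


def predict(model: LinearSvrModel, X: FeatureMatrix) -> TargetSeries:
    """Apply w . x + b; refuses mismatched provenance rather than reordering."""
    if X.provenance != model.provenance:
        raise InputError("feature provenance does not match the trained model")
    return TargetSeries("prediction", X.data @ model.weights + model.bias)


def safe_pearson_r(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    """Pearson r; a (numerically) zero-variance input yields (0.0, flag=True)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    for v in (a, b):
        if v.std() <= 1e-12 * max(1.0, float(np.abs(v).max())):
            return 0.0, True
    r = float(stats.pearsonr(a, b).statistic)
    if not np.isfinite(r):
        return 0.0, True
    return r, False


def crossvalidate(
    run_a: tuple[FeatureMatrix, TargetSeries | np.ndarray],
    run_b: tuple[FeatureMatrix, TargetSeries | np.ndarray],
    cfg: SvrConfig | None = None,
) -> AccuracyResult:
    """Split-half cross-validation over a subject's two runs.

    Trains on run A, tests on run B, then vice versa; each direction's
    accuracy is Pearson r(y_hat_test, y_test) and the summary is the
    arithmetic mean of the two. A zero-variance prediction is recorded as
    r = 0 with a warning flag.
    """
    cfg = cfg or SvrConfig()
    rs: list[float] = []
    preds: list[np.ndarray] = []
    obs: list[np.ndarray] = []
    resid: list[np.ndarray] = []
    flags: list[bool] = []
    for (Xtr, ytr), (Xte, yte) in ((run_a, run_b), (run_b, run_a)):
        model = train_svr(Xtr, ytr, cfg)
        yhat = predict(model, Xte).values
        ytev = yte.values if isinstance(yte, TargetSeries) else np.asarray(yte, float)
        r, flag = safe_pearson_r(yhat, ytev)
        if flag:
            warnings.warn("zero-variance prediction: r recorded as 0", stacklevel=2)
        rs.append(r)
        flags.append(flag)
        preds.append(yhat)
        obs.append(ytev)
        resid.append(ytev - yhat)
    return AccuracyResult(
        r_per_direction=(rs[0], rs[1]),
        mean_r=float(np.mean(rs)),
        predicted=preds,
        observed=obs,
        residuals=resid,
        zero_variance_flags=(flags[0], flags[1]),
    )


def mean_r_fisher(r_values) -> float:
    """Fisher-z combination of correlations (optional alternative to the mean)."""
    z = np.arctanh(np.clip(np.asarray(r_values, float), -1 + 1e-12, 1 - 1e-12))
    return float(np.tanh(z.mean()))


def residual_diagnostics(res: AccuracyResult) -> dict:
    """Moments of the prediction residuals plus r(residual, predicted).

    Residuals of a well-specified decoder should look like white noise:
    near-zero mean/skew/excess kurtosis and no correlation with the
    prediction.
    """
    resid = np.concatenate(res.residuals)
    pred = np.concatenate(res.predicted)
    r_rp, flag = safe_pearson_r(resid, pred)
    sd = float(resid.std())
    return {
        "mean": float(resid.mean()),
        "sd": sd,
        "skewness": float(stats.skew(resid)) if sd > 0 else 0.0,
        "excess_kurtosis": float(stats.kurtosis(resid)) if sd > 0 else 0.0,
        "r_residual_predicted": r_rp,
        "degenerate": flag,
    }


def save_model(model: LinearSvrModel, path) -> None:
    """Persist as a TSV weight table with a JSON header line."""
    header = {
        "bias": model.bias,
        "C_reg": model.config.C_reg,
        "epsilon": model.config.epsilon,
        "C_used": model.C_used,
    }
    with open(path, "w") as fh:
        fh.write("#" + json.dumps(header) + "\n")
        fh.write("provenance\tweight\n")
        for prov, w in zip(model.provenance, model.weights):
            fh.write(f"{json.dumps(list(prov) if isinstance(prov, tuple) else prov)}\t{float(w)!r}\n")


def load_model(path) -> LinearSvrModel:
    with open(path) as fh:
        header = json.loads(fh.readline().lstrip("#"))
        fh.readline()  # column names
        prov = []
        weights = []
        for line in fh:
            p, w = line.rstrip("\n").split("\t")
            entry = json.loads(p)
            prov.append(tuple(entry) if isinstance(entry, list) else entry)
        # re-parse weights exactly
            weights.append(float(w))
    prov = tuple(tuple(x) if isinstance(x, list) else x for x in prov)
    cfg = SvrConfig(C_reg=header["C_reg"], epsilon=header["epsilon"])
    return LinearSvrModel(np.array(weights), header["bias"], cfg, tuple(prov), header["C_used"])


def weights_to_volume(model: LinearSvrModel, mask: VolumeGrid) -> VolumeGrid:
    """Scatter a voxel-mode weight vector back onto its feature mask."""
    m = np.asarray(mask.data, dtype=bool)
    coords = np.argwhere(m)
    prov = tuple(tuple(int(c) for c in row) for row in coords)
    if prov != model.provenance:
        raise InputError("mask does not match the model's feature provenance")
    out = np.zeros(m.shape, dtype=np.float64)
    out[m] = model.weights
    return VolumeGrid(out, mask.voxel_size_mm)
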