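"""Estimating morpho-physiological traits from spectral indices.

Three estimation routes, mirroring how breeders actually use canopy spectra:

* **Univariate calibration** — ordinary least squares of a trait on a single
  index, linear or quadratic. The literal "pick the higher R2" rule always
  prefers the quadratic (nested models), so :func:`best_univariate` keeps the
  quadratic only when it beats the linear fit by a ΔR2 margin or its
  curvature term is significant; a zero margin recovers the literal rule.
* **PLSR** — partial least squares regression of one trait on all indices at
  once, with the latent-factor count chosen by leave-one-out cross-validation
  (minimum PRESS) and accuracy reported over repeated random
  calibration/validation splits (default 10 repeats of 75/25).
* **Correlation-matrix PCA** — eigendecomposition of the trait+index
  correlation matrix for the usual two-component biplot summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from .exceptions import ConfigurationError, SaltspecError


@dataclass(frozen=True)
class FitResult:
    """One univariate calibration: form, coefficients (ascending power), R2."""

    form: str  # 'linear' | 'quadratic'
    coefficients: tuple[float, ...]  # (intercept, slope[, curvature])
    r2: float
    residual_sd: float
    n: int

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x) + self.coefficients[0]
        for power, c in enumerate(self.coefficients[1:], start=1):
            out = out + c * x ** power
        return out


def fit_univariate(x, y, form: str = "linear") -> FitResult:
    """Least-squares fit of ``y`` on ``x`` (or on ``x, x^2`` for quadratic)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    degree = {"linear": 1, "quadratic": 2}.get(form)
    if degree is None:
        raise ConfigurationError(f"unknown form {form!r}")
    if x.size != y.size:
        raise SaltspecError("x and y lengths differ")
    if x.size < degree + 2:
        raise SaltspecError(f"need at least {degree + 2} points for a {form} fit")
    if np.ptp(x) == 0:
        raise SaltspecError("x is constant; cannot calibrate")
    design = np.vander(x, degree + 1, increasing=True)
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    sse = float(np.sum((y - fitted) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        warnings.warn("constant response; R2 reported as 0", RuntimeWarning,
                      stacklevel=2)
        r2 = 0.0
    else:
        r2 = max(0.0, 1.0 - sse / sst)
    df_resid = x.size - (degree + 1)
    residual_sd = float(np.sqrt(sse / df_resid)) if df_resid > 0 else float("nan")
    return FitResult(form, tuple(float(c) for c in coef), r2, residual_sd, int(x.size))


def best_univariate(x, y, delta_r2_threshold: float = 0.02,
                    curvature_alpha: float = 0.05) -> FitResult:
    """Linear vs quadratic calibration with an overfitting guard.

    The quadratic wins only if its R2 exceeds the linear R2 by more than
    ``delta_r2_threshold`` or its curvature coefficient is significant at
    ``curvature_alpha``. A threshold of 0 with ``curvature_alpha=0`` is the
    literal highest-R2 rule (quadratic always).
    """
    linear = fit_univariate(x, y, "linear")
    quadratic = fit_univariate(x, y, "quadratic")
    if quadratic.r2 - linear.r2 > delta_r2_threshold:
        return quadratic
    if curvature_alpha > 0:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        df_resid = x.size - 3
        if df_resid > 0:
            design = np.vander(x, 3, increasing=True)
            xtx_inv = np.linalg.pinv(design.T @ design)
            sse = (1 - quadratic.r2) * np.sum((y - y.mean()) ** 2)
            se = np.sqrt(max(sse / df_resid, 0) * xtx_inv[2, 2])
            if se > 0:
                t = abs(quadratic.coefficients[2]) / se
                if 2 * stats.t.sf(t, df_resid) < curvature_alpha:
                    return quadratic
    return linear


def calibration_table(sri: pd.DataFrame, traits: pd.DataFrame,
                      index_names: list[str], trait_names: list[str],
                      delta_r2_threshold: float = 0.02) -> pd.DataFrame:
    """Best univariate fit of every trait on every index (long table)."""
    rows = []
    for idx_name in index_names:
        for trait in trait_names:
            mask = sri[idx_name].notna() & traits[trait].notna()
            fit = best_univariate(sri.loc[mask, idx_name], traits.loc[mask, trait],
                                  delta_r2_threshold)
            coef = dict(zip(("intercept", "slope", "curvature"), fit.coefficients))
            rows.append({"index": idx_name, "trait": trait, "form": fit.form,
                         **coef, "r2": fit.r2, "n": fit.n})
    return pd.DataFrame(rows)


class PLSRModel:
    """Partial least squares regression of one trait on an index matrix.

    Thin wrapper (column-standardized X, centred/scaled y) exposing the fitted
    latent factors; ``n_factors`` must not exceed min(n_samples - 1,
    n_predictors). Zero-variance predictor columns are dropped with a warning.
    """

    def __init__(self, n_factors: int):
        if n_factors < 1:
            raise ConfigurationError("n_factors must be >= 1")
        self.n_factors = n_factors
        self._pls: PLSRegression | None = None
        self.columns_: list[str] | None = None

    def fit(self, X: pd.DataFrame, y) -> "PLSRModel":
        X = pd.DataFrame(X)
        if X.isna().any().any():
            raise SaltspecError("predictor matrix contains missing cells")
        sd = X.std(ddof=1)
        constant = sd.index[(sd == 0) | sd.isna()].tolist()
        if constant:
            warnings.warn(f"zero-variance predictor(s) dropped: {constant}",
                          RuntimeWarning, stacklevel=2)
            X = X.drop(columns=constant)
        cap = min(len(X) - 1, X.shape[1])
        if self.n_factors > cap:
            raise ConfigurationError(
                f"n_factors={self.n_factors} exceeds bound {cap}")
        self.columns_ = list(X.columns)
        self._pls = PLSRegression(n_components=self.n_factors, scale=True)
        self._pls.fit(X.to_numpy(float), np.asarray(y, dtype=float))
        return self

    @property
    def x_scores_(self) -> np.ndarray:
        return self._pls.x_scores_

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if self._pls is None:
            raise SaltspecError("model is not fitted")
        X = pd.DataFrame(X)[self.columns_]
        return self._pls.predict(X.to_numpy(float)).ravel()


def plsr_train(X: pd.DataFrame, y, n_factors: int) -> PLSRModel:
    """Fit a PLSR model with a fixed latent-factor count."""
    return PLSRModel(n_factors).fit(X, y)


def select_factors_loocv(X: pd.DataFrame, y, max_factors: int | None = None
                         ) -> tuple[int, np.ndarray]:
    """Latent-factor count minimizing the leave-one-out PRESS.

    Returns ``(chosen, press)`` where ``press[f-1]`` is the predicted residual
    error sum of squares with ``f`` factors; ties go to the smaller count.
    """
    X = pd.DataFrame(X).reset_index(drop=True)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise SaltspecError("need at least 3 samples for LOOCV")
    cap = min(n - 2, X.shape[1])  # n-2: one sample held out, one df for centring
    if max_factors is None:
        max_factors = cap
    max_factors = min(max_factors, cap)
    press = np.zeros(max_factors)
    for i in range(n):
        train = np.arange(n) != i
        Xt, yt = X.loc[train], y[train]
        for f in range(1, max_factors + 1):
            model = PLSRModel(f).fit(Xt, yt)
            pred = model.predict(X.loc[[i]])[0]
            press[f - 1] += (y[i] - pred) ** 2
    chosen = int(np.argmin(press)) + 1
    return chosen, press


@dataclass
class CVReport:
    """Repeated-split PLSR accuracy: calibration vs validation R2 and RMSE."""

    r2_cal: float
    rmse_cal: float
    r2_val: float
    rmse_val: float
    n_repeats: int
    val_fraction: float
    seed: int | None
    chosen_factors: list[int] = field(default_factory=list)
    press_curves: list[np.ndarray] = field(default_factory=list)
    per_repeat: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {"r2_cal": self.r2_cal, "rmse_cal": self.rmse_cal,
                "r2_val": self.r2_val, "rmse_val": self.rmse_val,
                "n_repeats": self.n_repeats, "val_fraction": self.val_fraction,
                "chosen_factors": list(self.chosen_factors)}


def _score(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    sst = np.sum((y_true - y_true.mean()) ** 2)
    sse = np.sum((y_true - y_pred) ** 2)
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    return float(r2), float(np.sqrt(sse / len(y_true)))


def plsr_evaluate(
    X: pd.DataFrame,
    y,
    val_fraction: float = 0.25,
    n_repeats: int = 10,
    seed: int | None = None,
    max_factors: int | None = None,
) -> CVReport:
    """Repeated random-split evaluation of PLSR on one trait.

    For every repeat: draw a random calibration/validation split, choose the
    factor count by LOOCV on the calibration part only, refit, and score both
    parts. Reported R2 and RMSE are means over repeats.
    """
    X = pd.DataFrame(X).reset_index(drop=True)
    y = np.asarray(y, dtype=float)
    n = len(y)
    n_val = int(round(n * val_fraction))
    if n_val < 3 or n - n_val < 4:
        raise SaltspecError(f"split of {n} samples at {val_fraction} is degenerate")
    rng = np.random.default_rng(seed)
    rows, chosen_all, curves = [], [], []
    for rep in range(n_repeats):
        perm = rng.permutation(n)
        val_idx, cal_idx = perm[:n_val], perm[n_val:]
        chosen, press = select_factors_loocv(X.loc[cal_idx], y[cal_idx], max_factors)
        model = PLSRModel(chosen).fit(X.loc[cal_idx], y[cal_idx])
        r2_cal, rmse_cal = _score(y[cal_idx], model.predict(X.loc[cal_idx]))
        r2_val, rmse_val = _score(y[val_idx], model.predict(X.loc[val_idx]))
        rows.append({"repeat": rep, "factors": chosen, "r2_cal": r2_cal,
                     "rmse_cal": rmse_cal, "r2_val": r2_val, "rmse_val": rmse_val})
        chosen_all.append(chosen)
        curves.append(press)
    per_repeat = pd.DataFrame(rows)
    return CVReport(
        r2_cal=float(per_repeat["r2_cal"].mean()),
        rmse_cal=float(per_repeat["rmse_cal"].mean()),
        r2_val=float(per_repeat["r2_val"].mean()),
        rmse_val=float(per_repeat["rmse_val"].mean()),
        n_repeats=n_repeats, val_fraction=val_fraction, seed=seed,
        chosen_factors=chosen_all, press_curves=curves, per_repeat=per_repeat)


@dataclass
class PCAResult:
    """Correlation-matrix PCA: explained fractions, loadings, scores."""

    explained: np.ndarray  # fractions, descending, summing to 1
    loadings: pd.DataFrame  # variables x components
    scores: pd.DataFrame  # samples x components


def pca_correlation(features: pd.DataFrame) -> PCAResult:
    """PCA of the correlation matrix of the numeric feature columns.

    Constant columns are dropped with a warning. Scores are the z-scored data
    projected on the (orthonormal) eigenvectors; eigenvalues are normalized to
    explained-variance fractions.
    """
    numeric = features.select_dtypes("number")
    sd = numeric.std(ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()].tolist()
    if constant:
        warnings.warn(f"constant column(s) dropped: {constant}", RuntimeWarning,
                      stacklevel=2)
        numeric = numeric.drop(columns=constant)
    if numeric.shape[1] < 2:
        raise SaltspecError("need at least two non-constant columns")
    z = (numeric - numeric.mean()) / numeric.std(ddof=1)
    corr = np.corrcoef(numeric.to_numpy(float), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0, None), eigvec[:, order]
    # sign convention: largest-magnitude loading positive per component
    for j in range(eigvec.shape[1]):
        lead = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[lead, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    comps = [f"PC{i + 1}" for i in range(len(eigval))]
    return PCAResult(
        explained=eigval / eigval.sum(),
        loadings=pd.DataFrame(eigvec, index=numeric.columns, columns=comps),
        scores=pd.DataFrame(z.to_numpy() @ eigvec, index=features.index,
                            columns=comps),
    )
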