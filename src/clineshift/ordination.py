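"""Constrained ordination (RDA / CCA) and AMOVA derived from it.

Redundancy analysis is multivariate least squares of a response matrix on
explanatory variables followed by a PCA (SVD) of the fitted values.  It
preserves Euclidean distances, which is why it carries the same
sums-of-squares bookkeeping as an analysis of molecular variance: with
population indicators as the constraints, the constrained sum of squares is
the among-population SS and the residual the within-population SS, from
which the usual variance components and Phi_ST follow.

Canonical correspondence analysis is the chi-square analogue -- weighted
least squares of the standardized residual profiles -- provided as an
alternative protocol for count prediction; unlike the RDA + binomial-smooth
pipeline it can hand back negative expected counts, which is flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator

from .io import IndividualAlleleTable

__all__ = [
    "RedundancyAnalysis",
    "CanonicalCorrespondenceAnalysis",
    "AmovaTable",
    "fit_rda",
    "predict_rda",
    "fit_predict_cca",
    "amova_rda",
]


def _matrix(x, name: str) -> tuple[np.ndarray, list | None, list | None]:
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), list(x.index), list(x.columns)
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional")
    return arr, None, None


def _dependent_columns(xc: np.ndarray, names: list | None) -> list:
    """Identify columns beyond the numerical rank via pivoted QR."""
    r = np.linalg.matrix_rank(xc)
    _, _, piv = linalg.qr(xc, mode="economic", pivoting=True)
    dep = sorted(piv[r:])
    if names is not None:
        return [names[j] for j in dep]
    return list(dep)


class RedundancyAnalysis(BaseEstimator):
    """Redundancy analysis: PCA of the least-squares fit of Y on X.

    Both matrices are centered columnwise; the coefficient matrix ``coef_``
    solves the centered least-squares problem, the SVD of the fitted values
    supplies the constrained axes, and inertias use the variance convention
    (sums of squares divided by n - 1).  With an empty explanatory matrix
    the analysis degenerates to PCA of the centered response.

    Fitted attributes
    -----------------
    x_mean_, y_mean_ : column means used for centering
    coef_ : (p, m) coefficient matrix
    singular_values_, axes_ : SVD of the centered fitted matrix
    total_inertia_, constrained_inertia_, residual_inertia_ : variance split
    """

    def fit(self, X, Y) -> "RedundancyAnalysis":
        x, x_rows, x_cols = _matrix(X, "X") if X is not None else (None, None, None)
        y, y_rows, y_cols = _matrix(Y, "Y")
        n = y.shape[0]
        if n < 2:
            raise ValueError("need at least 2 rows")
        if x is None:
            x = np.empty((n, 0))
        if x.shape[0] != n:
            raise ValueError("X and Y must have aligned rows")
        self.x_mean_ = x.mean(axis=0) if x.shape[1] else np.empty(0)
        self.y_mean_ = y.mean(axis=0)
        xc = x - self.x_mean_
        yc = y - self.y_mean_
        if x.shape[1]:
            if np.linalg.matrix_rank(xc) < xc.shape[1]:
                dep = _dependent_columns(xc, x_cols)
                raise ValueError(f"explanatory matrix is rank deficient; dependent columns: {dep}")
            self.coef_, *_ = np.linalg.lstsq(xc, yc, rcond=None)
            fitted = xc @ self.coef_
        else:
            # no constraints: RDA degenerates to PCA of the centered response
            self.coef_ = np.empty((0, y.shape[1]))
            fitted = yc
        u, s, vt = np.linalg.svd(fitted, full_matrices=False)
        keep = s > s[0] * 1e-12 if s.size and s[0] > 0 else np.zeros(s.shape, bool)
        self.singular_values_ = s[keep]
        self.axes_ = vt[keep]  # right singular vectors (response loadings)
        self.site_scores_ = u[:, keep] * s[keep]
        self.rank_ = int(keep.sum())
        self.fitted_ = fitted
        self.residual_ = yc - fitted
        denom = n - 1
        self.total_inertia_ = float(np.sum(yc**2)) / denom
        self.constrained_inertia_ = float(np.sum(fitted**2)) / denom
        self.residual_inertia_ = float(np.sum(self.residual_**2)) / denom
        self.n_samples_ = n
        self.feature_names_in_ = x_cols
        self.response_names_ = y_cols
        self.row_ids_ = y_rows
        return self

    def predict(self, X_new, rank: int | str = "full"):
        """Predict responses for new explanatory rows.

        Yhat = (X_new - x_mean) @ coef + y_mean, optionally projected onto
        the top-``rank`` constrained axes before un-centering.
        """
        x, rows, cols = _matrix(X_new, "X_new")
        if self.feature_names_in_ is not None and cols is not None:
            if cols != self.feature_names_in_:
                raise ValueError(
                    f"explanatory variables {cols} do not match the model's "
                    f"{self.feature_names_in_}"
                )
        if x.shape[1] != len(self.x_mean_):
            raise ValueError("wrong number of explanatory variables")
        fitted = (x - self.x_mean_) @ self.coef_
        if rank != "full":
            r = int(rank)
            v = self.axes_[:r]
            fitted = fitted @ v.T @ v
        out = fitted + self.y_mean_
        if self.response_names_ is not None:
            return pd.DataFrame(out, index=rows, columns=self.response_names_)
        return out


class CanonicalCorrespondenceAnalysis(BaseEstimator):
    """CCA-style calibration/prediction for nonnegative count matrices.

    The count matrix is converted to chi-square-standardized residual
    profiles Q = (P - r c^T)/sqrt(r c^T); Q is regressed on the
    (mass-weighted) standardized explanatory variables by weighted least
    squares with row weights r.  Prediction back-transforms the fitted
    profiles to expected counts at the calibration row and column masses;
    negative expected counts are possible and flagged.
    """

    def fit(self, X, Y) -> "CanonicalCorrespondenceAnalysis":
        x, _, x_cols = _matrix(X, "X")
        y, y_rows, y_cols = _matrix(Y, "Y")
        if np.any(y < 0):
            raise ValueError("CCA requires nonnegative counts")
        r_sum = y.sum(axis=1)
        c_sum = y.sum(axis=0)
        if np.any(r_sum <= 0) or np.any(c_sum <= 0):
            raise ValueError("CCA requires positive row and column sums")
        self.grand_total_ = float(y.sum())
        p = y / self.grand_total_
        self.r_ = p.sum(axis=1)
        self.c_ = p.sum(axis=0)
        expected = np.outer(self.r_, self.c_)
        self.sqrt_rc_ = np.sqrt(expected)
        q = (p - expected) / self.sqrt_rc_
        # weighted standardization of X by the row masses
        self.x_wmean_ = self.r_ @ x
        xc = x - self.x_wmean_
        self.x_wsd_ = np.sqrt(self.r_ @ xc**2)
        if np.any(self.x_wsd_ == 0):
            raise ValueError("explanatory variable with zero weighted variance")
        xs = xc / self.x_wsd_
        w = np.sqrt(self.r_)[:, None]
        design = np.column_stack([np.ones(len(q)), xs])
        self.coef_, *_ = np.linalg.lstsq(design * w, q * w, rcond=None)
        self.feature_names_in_ = x_cols
        self.response_names_ = y_cols
        self.row_ids_ = y_rows
        return self

    def predict(self, X_new):
        """Expected counts for new explanatory rows.

        Returns ``(counts, negative_flag)``; the flag is True when any
        predicted count is negative (the pathology the binomial-smooth
        correction step exists to repair).
        """
        x, rows, cols = _matrix(X_new, "X_new")
        if self.feature_names_in_ is not None and cols is not None and cols != self.feature_names_in_:
            raise ValueError("explanatory variables do not match the fitted model")
        xs = (x - self.x_wmean_) / self.x_wsd_
        design = np.column_stack([np.ones(len(xs)), xs])
        q_hat = design @ self.coef_
        p_hat = q_hat * self.sqrt_rc_ + np.outer(self.r_, self.c_)
        counts = p_hat * self.grand_total_
        flag = bool(np.any(counts < 0))
        if flag:
            warnings.warn("CCA predicted negative expected counts", UserWarning, stacklevel=2)
        if self.response_names_ is not None:
            counts = pd.DataFrame(counts, index=rows, columns=self.response_names_)
        return counts, flag


# thin functional wrappers -------------------------------------------------


def fit_rda(Y, X) -> RedundancyAnalysis:
    """Calibrate a redundancy analysis of response Y on explanatory X."""
    return RedundancyAnalysis().fit(X, Y)


def predict_rda(model: RedundancyAnalysis, X_new, rank: int | str = "full"):
    return model.predict(X_new, rank=rank)


def fit_predict_cca(Y, X, X_new):
    """Calibrate the CCA variant on (Y, X) and predict counts at X_new."""
    return CanonicalCorrespondenceAnalysis().fit(X, Y).predict(X_new)


# ---------------------------------------------------------------------------
# AMOVA


@dataclass
class AmovaTable:
    """Two-level AMOVA report (among / within populations).

    ``sigma2_among``/``sigma2_within`` are the variance components, ``n0``
    the weighted average sample size, ``phi_st`` the fraction of variance
    among populations (NaN when there is no variance at all).
    """

    df_among: int
    df_within: int
    df_total: int
    ss_among: float
    ss_within: float
    ss_total: float
    ms_among: float
    ms_within: float
    sigma2_among: float
    sigma2_within: float
    n0: float
    phi_st: float

    def to_frame(self) -> pd.DataFrame:
        sig_tot = self.sigma2_among + self.sigma2_within
        pct = (
            [100 * self.sigma2_among / sig_tot, 100 * self.sigma2_within / sig_tot, 100.0]
            if sig_tot > 0
            else [np.nan, np.nan, np.nan]
        )
        return pd.DataFrame(
            {
                "df": [self.df_among, self.df_within, self.df_total],
                "SS": [self.ss_among, self.ss_within, self.ss_total],
                "MS": [self.ms_among, self.ms_within, np.nan],
                "sigma2": [self.sigma2_among, self.sigma2_within, sig_tot],
                "pct": pct,
            },
            index=["among populations", "within populations", "total"],
        )

    def write(self, path) -> None:
        frame = self.to_frame()
        frame.loc["Phi_ST", "sigma2"] = self.phi_st
        frame.to_csv(path, index_label="source")


def amova_rda(individuals: IndividualAlleleTable) -> AmovaTable:
    """AMOVA computed from an RDA with population-indicator constraints.

    The individual x allele dosage matrix is regressed on population
    indicators (one level dropped; the split is coding-invariant): the
    constrained sum of squares is the among-population SS and the residual
    the within-population SS.  Variance components use the standard
    weighted average sample size n0 = (N - sum(n_i^2)/N)/(g-1).
    """
    y = individuals.allele_matrix()
    pops = individuals.population_of
    labels = list(dict.fromkeys(pops))
    g = len(labels)
    n = len(y)
    if g < 2:
        raise ValueError("AMOVA needs at least 2 populations")
    if n <= g:
        raise ValueError("AMOVA needs more individuals than populations")
    indicators = pd.get_dummies(pops, drop_first=True).astype(float)
    model = RedundancyAnalysis().fit(indicators, y)
    denom = n - 1
    ss_among = model.constrained_inertia_ * denom
    ss_within = model.residual_inertia_ * denom
    ss_total = ss_among + ss_within
    df_among = g - 1
    df_within = n - g
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    sizes = pops.value_counts()
    n0 = (n - float((sizes**2).sum()) / n) / df_among
    sigma2_within = ms_within
    sigma2_among = (ms_among - ms_within) / n0
    total_var = sigma2_among + sigma2_within
    if ss_total == 0:
        warnings.warn("all individuals identical; Phi_ST undefined", UserWarning, stacklevel=2)
        phi = float("nan")
    else:
        phi = sigma2_among / total_var
    return AmovaTable(
        df_among=df_among,
        df_within=df_within,
        df_total=n - 1,
        ss_among=ss_among,
        ss_within=ss_within,
        ss_total=ss_total,
        ms_among=ms_among,
        ms_within=ms_within,
        sigma2_among=sigma2_among,
        sigma2_within=sigma2_within,
        n0=n0,
        phi_st=phi,
    )
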