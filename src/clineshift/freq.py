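"""Second calibration step: binomial smooth correction of predicted counts.

The ordination step is linear and can predict allele counts below zero or
above the sample size.  Per locus, a binomial-family smooth (logit link,
natural cubic regression spline of the predicted baseline count of the
minor allele, observations weighted by N) is calibrated against the
observed baseline frequencies; pushing changed-climate predicted counts
through the inverse link then guarantees frequencies inside [0, 1] with
matching confidence limits.  The spline basis extrapolates linearly on the
link scale, so counts outside the calibration range map to tail
frequencies rather than failing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import build_design_matrices, dmatrix
from scipy.special import expit
from sklearn.base import BaseEstimator

from .count import CountPrediction
from .io import AlleleCountTable, counts_to_frequencies, minor_alleles

__all__ = [
    "PredictionTable",
    "FrequencyModel",
    "freq_model",
    "freq_pred",
    "freq_scatter_data",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile

#: column order of the assembled per-population x locus output table
TABLE_COLUMNS = [
    "N",
    "Allele.freq",
    "A",
    "B",
    "Ap",
    "Bp",
    "N.e1",
    "Freq.e1",
    "Freq.e2",
    "LCL",
    "UCL",
    "increasing",
]


@dataclass
class PredictionTable:
    """Long-format table of observed and predicted minor-allele frequencies.

    One row per population x locus with columns ``N`` (alleles sampled),
    ``Allele.freq`` (observed baseline minor-allele frequency), ``A``/``B``
    (baseline minor/major counts), ``Ap``/``Bp`` (predicted minor/major
    counts), ``N.e1`` (= Ap + Bp = N), ``Freq.e1`` (= Ap/N.e1, unbounded),
    ``Freq.e2`` (smooth-corrected frequency in [0, 1]), ``LCL``/``UCL``
    (95% limits) and ``increasing`` (Freq.e2 > Allele.freq).
    """

    data: pd.DataFrame
    climate_tag: str = "changed"

    def __post_init__(self) -> None:
        need = ["population", "locus", *TABLE_COLUMNS]
        missing = [c for c in need if c not in self.data.columns]
        if missing:
            raise ValueError(f"prediction table lacks columns {missing}")
        self.data = self.data[need].reset_index(drop=True)

    def write(self, path) -> None:
        """Write as delimited text, frequencies rendered at 3 decimals."""
        out = self.data.copy()
        for col in ("Allele.freq", "Ap", "Bp", "Freq.e1", "Freq.e2", "LCL", "UCL"):
            out[col] = out[col].map(lambda v: f"{v:.3f}")
        sep = "\t" if str(path).endswith((".tsv", ".txt", ".tab")) else ","
        out.to_csv(path, sep=sep, index=False)


class _LocusSmooth:
    """Fitted binomial smooth for one locus.

    kind: "spline" (cr basis), "linear" (intercept + slope) or "constant"
    (boundary or zero-spread fallback).
    """

    def __init__(self, kind, params=None, cov=None, design_info=None, value=None):
        self.kind = kind
        self.params = params
        self.cov = cov
        self.design_info = design_info
        self.value = value  # constant frequency for kind == "constant"

    def _design(self, t: np.ndarray) -> np.ndarray:
        if self.kind == "spline":
            (mat,) = build_design_matrices([self.design_info], {"t": t})
            return np.asarray(mat)
        return np.column_stack([np.ones(len(t)), t])

    def predict(self, t: np.ndarray):
        """Return (freq, lcl, ucl) on the response scale for counts ``t``."""
        t = np.asarray(t, dtype=float)
        if self.kind == "constant":
            f = np.full(t.shape, self.value)
            return f, f.copy(), f.copy()
        z = self._design(t)
        eta = z @ self.params
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", z, self.cov, z), 0.0))
        return expit(eta), expit(eta - _Z95 * se), expit(eta + _Z95 * se)


class FrequencyModel(BaseEstimator):
    """Per-locus binomial smooth mapping predicted counts onto frequencies.

    Parameters
    ----------
    basis_dim : int or None
        Dimension of the natural cubic regression spline basis on the link
        scale; ``None`` uses min(4, populations - 1).  Values below 3 fall
        back to an ordinary (linear-in-link) weighted logistic regression.

    Fit with the *baseline* count predictions so the smooth learns the map
    from the linear model's output back to observed frequencies.
    """

    def __init__(self, basis_dim: int | None = None):
        self.basis_dim = basis_dim

    def fit(self, X: CountPrediction, Y: AlleleCountTable) -> "FrequencyModel":
        if X.climate_tag != "baseline":
            warnings.warn(
                "frequency model should be calibrated on baseline predictions; "
                f"got climate_tag={X.climate_tag!r}",
                UserWarning,
                stacklevel=2,
            )
        if list(X.population_ids) != list(Y.population_ids):
            raise ValueError("count prediction and counts tables are misaligned")
        g = len(Y.population_ids)
        k = self.basis_dim if self.basis_dim is not None else min(4, g - 1)
        if k > g - 1:
            warnings.warn(
                f"basis_dim {k} exceeds populations - 1; reduced to {g - 1}",
                UserWarning,
                stacklevel=2,
            )
            k = g - 1
        self.minor_ = dict(minor_alleles(Y))
        freqs = counts_to_frequencies(Y, which="minor")
        n_weights = Y.N.to_numpy(dtype=float)
        self.smooths_: dict[str, _LocusSmooth] = {}
        for locus in Y.locus_ids:
            minor = self.minor_[locus]
            t = (X.ap if minor == "A" else X.bp)[locus].to_numpy(dtype=float)
            f_obs = freqs[locus].to_numpy(dtype=float)
            self.smooths_[locus] = self._fit_locus(locus, t, f_obs, n_weights, k)
        self.basis_dim_ = k
        return self

    @staticmethod
    def _fit_locus(locus, t, f_obs, n_weights, k) -> _LocusSmooth:
        if np.ptp(f_obs) == 0:
            f0 = float(f_obs[0])
            if f0 in (0.0, 1.0):
                warnings.warn(
                    f"locus {locus!r}: observed frequencies all {f0:g}; degenerate "
                    "constant fit",
                    UserWarning,
                    stacklevel=3,
                )
                return _LocusSmooth("constant", value=f0)
            # intercept-only logistic fit: exact constant with a proper CI
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(f_obs, np.ones((len(t), 1)), family=sm.families.Binomial(), var_weights=n_weights).fit()
            sm0 = _LocusSmooth("linear", params=np.array([res.params[0], 0.0]), cov=np.zeros((2, 2)))
            sm0.cov[0, 0] = res.cov_params().iloc[0, 0] if hasattr(res.cov_params(), "iloc") else res.cov_params()[0, 0]
            return sm0
        if np.ptp(t) == 0:
            warnings.warn(
                f"locus {locus!r}: predicted baseline counts constant; constant fit",
                UserWarning,
                stacklevel=3,
            )
            mean_f = float(np.average(f_obs, weights=n_weights))
            return _LocusSmooth("constant", value=mean_f)
        k_eff = min(k, len(np.unique(t)) - 1)
        if k_eff >= 3:
            dm = dmatrix(f"cr(t, df={k_eff}) - 1", {"t": t})
            design_info = dm.design_info
            z = np.asarray(dm)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(f_obs, z, family=sm.families.Binomial(), var_weights=n_weights).fit()
            return _LocusSmooth(
                "spline",
                params=np.asarray(res.params),
                cov=np.asarray(res.cov_params()),
                design_info=design_info,
            )
        z = np.column_stack([np.ones(len(t)), t])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(f_obs, z, family=sm.families.Binomial(), var_weights=n_weights).fit()
        return _LocusSmooth("linear", params=np.asarray(res.params), cov=np.asarray(res.cov_params()))

    def predict(
        self,
        pred: CountPrediction,
        baseline_counts: AlleleCountTable,
        climate_tag: str | None = None,
    ) -> PredictionTable:
        """Assemble the full observed/predicted frequency table."""
        if list(pred.population_ids) != list(baseline_counts.population_ids):
            raise ValueError("count prediction and baseline counts are misaligned")
        missing = [l for l in pred.locus_ids if l not in self.smooths_]
        if missing:
            raise KeyError(f"loci absent from the fitted frequency model: {missing}")
        tag = climate_tag if climate_tag is not None else pred.climate_tag
        freqs = counts_to_frequencies(baseline_counts, which="minor")
        n = baseline_counts.N
        rows = []
        for locus in pred.locus_ids:
            minor = self.minor_[locus]
            major = "B" if minor == "A" else "A"
            a_obs = baseline_counts.allele_counts(locus, minor)
            b_obs = baseline_counts.allele_counts(locus, major)
            ap = (pred.ap if minor == "A" else pred.bp)[locus]
            bp = (pred.bp if minor == "A" else pred.ap)[locus]
            f2, lcl, ucl = self.smooths_[locus].predict(ap.to_numpy(dtype=float))
            for i, pop in enumerate(pred.population_ids):
                n_e1 = float(pred.n_e1[pop])
                freq_e1 = float(ap[pop]) / n_e1
                rows.append(
                    {
                        "population": pop,
                        "locus": locus,
                        "N": int(n[pop]),
                        "Allele.freq": float(freqs.loc[pop, locus]),
                        "A": int(a_obs[pop]),
                        "B": int(b_obs[pop]),
                        "Ap": float(ap[pop]),
                        "Bp": float(bp[pop]),
                        "N.e1": n_e1,
                        "Freq.e1": freq_e1,
                        "Freq.e2": float(f2[i]),
                        "LCL": float(lcl[i]),
                        "UCL": float(ucl[i]),
                        "increasing": bool(f2[i] > freqs.loc[pop, locus]),
                    }
                )
        return PredictionTable(pd.DataFrame(rows), climate_tag=tag)


def freq_model(
    counts: AlleleCountTable, baseline_pred: CountPrediction, basis_dim: int | None = None
) -> FrequencyModel:
    """Calibrate the binomial smooth on baseline predictions and counts."""
    return FrequencyModel(basis_dim=basis_dim).fit(baseline_pred, counts)


def freq_pred(
    fm: FrequencyModel,
    pred: CountPrediction,
    baseline_counts: AlleleCountTable,
    climate_tag: str | None = None,
) -> PredictionTable:
    """Predict corrected frequencies for baseline or changed climates."""
    return fm.predict(pred, baseline_counts, climate_tag=climate_tag)


def freq_scatter_data(table: PredictionTable, r2_split: float = 0.5) -> pd.DataFrame:
    """Per-population goodness of fit of predicted vs observed frequencies.

    For each population, R^2 of the least-squares regression of the
    observed baseline frequency on the corrected prediction across loci;
    populations split into "high"/"low" groups at ``r2_split`` for
    observed-vs-predicted plotting (1:1, 1:1.05 and 1:0.95 reference
    lines).  Populations with fewer than 3 loci go to the low group.
    """
    out = []
    for pop, sub in table.data.groupby("population", sort=False):
        obs = sub["Allele.freq"].to_numpy(dtype=float)
        prd = sub["Freq.e2"].to_numpy(dtype=float)
        if len(sub) < 3:
            warnings.warn(
                f"population {pop!r} has fewer than 3 loci; R^2 undefined, "
                "placed in the low group",
                UserWarning,
                stacklevel=2,
            )
            r2 = np.nan
            group = "low"
        else:
            if np.ptp(prd) == 0 or np.ptp(obs) == 0:
                r2 = 0.0
            else:
                r2 = float(np.corrcoef(obs, prd)[0, 1] ** 2)
            group = "high" if r2 > r2_split else "low"
        out.append({"population": pop, "r2": r2, "group": group})
    return pd.DataFrame(out)
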