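"""Explanatory-variable reduction and climate-novelty screening.

Collinear climate variables inflate the variance of the ordination
coefficients and make transfer to new climates unstable, so before
calibration the variable set is reduced until every variance inflation
factor (VIF) falls below a threshold (20 by default, the usual rule of
thumb in regression and distribution modelling).  Separately, populations
whose changed-climate values fall outside the baseline calibration range
are flagged as environmentally novel, with a normal tail probability
quantifying how far outside they sit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .io import EnvTable

__all__ = [
    "VifReport",
    "NoveltyRecord",
    "NoveltyReport",
    "VIFSelector",
    "compute_vif",
    "vif_subset",
    "environmental_novel",
]

#: R^2 at or above which a variable is treated as perfectly collinear.
_R2_COLLINEAR = 1.0 - 1e-12


def _as_frame(env) -> pd.DataFrame:
    if isinstance(env, EnvTable):
        return env.values
    return pd.DataFrame(env).astype(float)


def _vif_series(frame: pd.DataFrame) -> pd.Series:
    """VIF_j = 1/(1-R^2_j), R^2_j from OLS of column j on the others
    (with intercept).  Perfect collinearity -> +inf."""
    x = frame.to_numpy(dtype=float)
    n, p = x.shape
    if n < 2:
        raise ValueError("VIF needs at least 2 populations")
    sds = x.std(axis=0)
    if np.any(sds == 0):
        bad = frame.columns[np.nonzero(sds == 0)[0][0]]
        raise ValueError(f"variable {bad!r} has zero variance")
    out = {}
    for j, name in enumerate(frame.columns):
        if p == 1:
            out[name] = 1.0
            continue
        y = x[:, j]
        others = np.column_stack([np.ones(n), np.delete(x, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / sst
        out[name] = np.inf if r2 >= _R2_COLLINEAR else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def compute_vif(env) -> pd.Series:
    """Variance inflation factor of every variable in the table."""
    return _vif_series(_as_frame(env))


@dataclass
class VifReport:
    """Outcome of stepwise VIF reduction."""

    retained: list[str]
    dropped: list[tuple[str, float]]  # (variable, VIF or |r| at removal)
    final_vifs: pd.Series
    threshold: float
    keep: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert not (set(self.retained) & {v for v, _ in self.dropped})


class VIFSelector(BaseEstimator, TransformerMixin):
    """Stepwise variance-inflation-factor variable selector.

    Step 1 removes every non-``keep`` variable whose absolute Pearson
    correlation with any ``keep`` variable exceeds ``cor_cut``.  Step 2
    iteratively removes the non-``keep`` variable with the largest VIF
    until all non-``keep`` VIFs are at or below ``threshold`` (ties broken
    by column order; first column wins removal).  ``keep`` variables are
    always retained, with a warning if they are mutually collinear.

    Parameters
    ----------
    threshold : float, default 20.0
        Maximum tolerated VIF for non-kept variables.
    keep : sequence of str, default ()
        Variables forced into the retained set.
    cor_cut : float, default 0.9
        Absolute-correlation cut against kept variables in step 1.
    """

    def __init__(self, threshold: float = 20.0, keep: tuple = (), cor_cut: float = 0.9):
        self.threshold = threshold
        self.keep = keep
        self.cor_cut = cor_cut

    def fit(self, X, y=None) -> "VIFSelector":
        frame = _as_frame(X)
        keep = list(self.keep)
        unknown = [k for k in keep if k not in frame.columns]
        if unknown:
            raise ValueError(f"keep variables not in table: {unknown}")
        current = list(frame.columns)
        dropped: list[tuple[str, float]] = []

        if keep:
            corr = frame.corr().abs()
            for var in list(current):
                if var in keep:
                    continue
                worst = corr.loc[var, keep].max()
                if worst > self.cor_cut:
                    current.remove(var)
                    dropped.append((var, float(worst)))
            if len(keep) > 1:
                keep_vifs = _vif_series(frame[keep])
                if np.isinf(keep_vifs).any():
                    warnings.warn(
                        "forced-keep variables are mutually collinear; retained regardless",
                        UserWarning,
                        stacklevel=2,
                    )

        while True:
            vifs = _vif_series(frame[current])
            candidates = [v for v in current if v not in keep and vifs[v] > self.threshold]
            if not candidates:
                break
            worst = max(candidates, key=lambda v: (vifs[v], -current.index(v)))
            # ties broken by column order: first column wins removal
            top = [v for v in candidates if vifs[v] == vifs[worst]]
            worst = min(top, key=current.index)
            current.remove(worst)
            dropped.append((worst, float(vifs[worst])))

        self.report_ = VifReport(
            retained=current,
            dropped=dropped,
            final_vifs=_vif_series(frame[current]),
            threshold=self.threshold,
            keep=keep,
        )
        self.feature_names_in_ = np.asarray(frame.columns)
        return self

    def transform(self, X):
        frame = _as_frame(X)
        return frame[self.report_.retained]

    def get_support(self) -> list[str]:
        return list(self.report_.retained)


def vif_subset(env, threshold: float = 20.0, keep: tuple = (), cor_cut: float = 0.9) -> VifReport:
    """Reduce an environmental table to a low-collinearity subset."""
    return VIFSelector(threshold=threshold, keep=keep, cor_cut=cor_cut).fit(env).report_


# ---------------------------------------------------------------------------
# environmental novelty


@dataclass
class NoveltyRecord:
    variable: str
    changed_value: float
    baseline_min: float
    baseline_max: float
    tail_probability: float


@dataclass
class NoveltyReport:
    """Populations whose changed climate leaves the baseline range.

    ``per_population`` lists, for each flagged population, the variables
    strictly outside the baseline range with one-sided normal tail
    probabilities from the baseline mean and sample standard deviation;
    ``novelty_p`` is the smallest of those probabilities.
    """

    per_population: dict = field(default_factory=dict)
    novelty_p: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pop, records in self.per_population.items():
            for r in records:
                rows.append(
                    {
                        "population": pop,
                        "variable": r.variable,
                        "changed_value": r.changed_value,
                        "baseline_min": r.baseline_min,
                        "baseline_max": r.baseline_max,
                        "tail_probability": r.tail_probability,
                    }
                )
        return pd.DataFrame(rows)


def environmental_novel(baseline: EnvTable, changed: EnvTable) -> NoveltyReport:
    """Flag populations facing climates outside the calibration range.

    For each population x variable with changed value strictly outside the
    inclusive baseline [min, max], the one-sided tail probability on the
    violated side is computed from the baseline column mean and sample
    (n-1) standard deviation.  Populations with no flagged variable are
    absent from the report.
    """
    base = baseline.values
    chg = changed.values
    if list(base.columns) != list(chg.columns):
        raise ValueError("baseline and changed tables must share variables in order")
    if list(base.index) != list(chg.index):
        raise ValueError("baseline and changed tables must share populations in order")
    mins = base.min(axis=0)
    maxs = base.max(axis=0)
    mus = base.mean(axis=0)
    sds = base.std(axis=0, ddof=1)
    report = NoveltyReport()
    for pop in chg.index:
        records = []
        for var in chg.columns:
            x = float(chg.loc[pop, var])
            lo, hi = float(mins[var]), float(maxs[var])
            if lo <= x <= hi:
                continue
            sd = float(sds[var])
            if sd == 0:
                warnings.warn(
                    f"variable {var!r} has zero baseline spread; tail probability "
                    "degenerate for population "
                    f"{pop!r}",
                    UserWarning,
                    stacklevel=2,
                )
                p = 0.0
            else:
                z = (x - float(mus[var])) / sd
                p = float(stats.norm.sf(z)) if x > hi else float(stats.norm.cdf(z))
            records.append(NoveltyRecord(var, x, lo, hi, p))
        if records:
            report.per_population[pop] = records
            report.novelty_p[pop] = min(r.tail_probability for r in records)
    return report
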