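"""First calibration step: predict allele counts from climate via RDA/CCA.

The baseline population x allele-count matrix is the ordination response
and the baseline climate the constraint.  Prediction at a new climate gives
raw per-allele counts which, per locus, are rescaled proportionally so the
pair sums to the population's observed sample size N; negative predicted
counts are deliberately kept (the binomial-smooth correction, not this
step, is responsible for mapping onto valid frequencies).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import AlleleCountTable, EnvTable, check_datasets
from .ordination import CanonicalCorrespondenceAnalysis, RedundancyAnalysis

__all__ = ["CountPrediction", "CountModel", "count_model", "count_pred"]


@dataclass
class CountPrediction:
    """Per population x locus predicted allele-count pairs.

    ``ap``/``bp`` are population x locus frames of predicted counts of the
    locus's A and B alleles (real-valued, possibly negative); after
    rescaling ``ap + bp`` equals the observed N exactly (``n_e1``).
    """

    ap: pd.DataFrame
    bp: pd.DataFrame
    n_e1: pd.Series
    climate_tag: str = "baseline"
    negative_flag: bool = False

    @property
    def locus_ids(self) -> list[str]:
        return list(self.ap.columns)

    @property
    def population_ids(self) -> list:
        return list(self.ap.index)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pop in self.ap.index:
            for locus in self.ap.columns:
                rows.append(
                    {
                        "population": pop,
                        "locus": locus,
                        "Ap": self.ap.loc[pop, locus],
                        "Bp": self.bp.loc[pop, locus],
                        "N.e1": self.n_e1[pop],
                        "climate": self.climate_tag,
                    }
                )
        return pd.DataFrame(rows)


class CountModel(BaseEstimator):
    """Climate -> allele-count calibration (RDA by default, CCA optional).

    Parameters
    ----------
    use_cca : bool, default False
        Use the chi-square (correspondence-analysis) protocol instead of
        redundancy analysis.
    rank : int or "full", default "full"
        Number of constrained axes used at prediction (RDA only).
    """

    def __init__(self, use_cca: bool = False, rank: int | str = "full"):
        self.use_cca = use_cca
        self.rank = rank

    def fit(self, X: EnvTable, Y: AlleleCountTable) -> "CountModel":
        check_datasets(Y, X).raise_if_failed()
        self.loci_ = Y.locus_ids
        self.N_ = Y.N.copy()
        self.columns_ = list(Y.counts.columns)
        if self.use_cca:
            self.ordination_ = CanonicalCorrespondenceAnalysis().fit(X.values, Y.counts)
        else:
            self.ordination_ = RedundancyAnalysis().fit(X.values, Y.counts)
        return self

    def predict(self, X: EnvTable) -> CountPrediction:
        """Predict rescaled allele-count pairs under the given climate."""
        if list(X.population_ids) != list(self.N_.index):
            raise ValueError("environmental table populations differ from calibration")
        if self.use_cca:
            raw, neg = self.ordination_.predict(X.values)
        else:
            raw = self.ordination_.predict(X.values, rank=self.rank)
            neg = bool((raw.to_numpy() < 0).any())
        ap = {}
        bp = {}
        n = self.N_.to_numpy(dtype=float)
        for locus in self.loci_:
            a_raw = raw[f"{locus}.A"].to_numpy(dtype=float)
            b_raw = raw[f"{locus}.B"].to_numpy(dtype=float)
            s = a_raw + b_raw
            if np.any(s <= 0):
                bad = np.nonzero(s <= 0)[0][0]
                pop = self.N_.index[bad]
                raise ValueError(
                    f"raw predicted counts for population {pop!r}, locus {locus!r} "
                    f"sum to {s[bad]:.6g} <= 0; proportional rescaling to N undefined"
                )
            ap[locus] = a_raw * n / s
            bp[locus] = b_raw * n / s
        index = self.N_.index
        return CountPrediction(
            ap=pd.DataFrame(ap, index=index),
            bp=pd.DataFrame(bp, index=index),
            n_e1=self.N_.astype(float),
            climate_tag=X.climate_tag,
            negative_flag=neg,
        )


def count_model(counts: AlleleCountTable, env_baseline: EnvTable, use_cca: bool = False) -> CountModel:
    """Calibrate the count model on baseline counts and climate."""
    return CountModel(use_cca=use_cca).fit(env_baseline, counts)


def count_pred(model: CountModel, env: EnvTable, counts_baseline: AlleleCountTable | None = None) -> CountPrediction:
    """Predict allele counts under ``env`` (baseline check or changed climate)."""
    if counts_baseline is not None and list(counts_baseline.population_ids) != list(model.N_.index):
        raise ValueError("baseline counts do not match the calibrated model")
    return model.predict(env)
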