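"""Synthetic populations sampled along climate gradients with known truth.

Each locus carries a logistic allele-frequency cline on a single driver
climate variable: the true frequency of the A allele in population p is
``expit(b0 + b1 * x_p)``.  Observed counts are binomial draws of N alleles
at that frequency (or deterministic rounding with noise off), so every
stage of the prediction pipeline can be checked against the closed-form
truth under both the baseline climate and a uniformly shifted one.
Nuisance climate variables correlated with the driver are included to
exercise variable selection realistically.

Random streams are keyed per (seed, population, locus), so enlarging the
scenario never perturbs the columns already generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import AlleleCountTable, EnvTable, GeoTable

__all__ = ["ClineScenario", "SyntheticDataset", "generate_dataset"]


@dataclass
class ClineScenario:
    """Parameters of a logistic-cline simulation.

    ``intercepts``/``slopes`` give the per-locus logistic coefficients
    (defaults spread intercepts so loci cover a range of frequencies);
    ``delta`` is the uniform shift of the driver variable in the changed
    climate; ``nuisance_cor`` the correlation of each nuisance variable
    with the driver.
    """

    n_populations: int = 20
    n_alleles: int = 100  # alleles sampled per population (N)
    n_loci: int = 4
    intercepts: tuple = ()
    slopes: tuple = ()
    driver_range: tuple = (-2.0, 2.0)
    delta: float = 0.5
    noise: bool = True
    n_nuisance: int = 3
    nuisance_cor: float = 0.7
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_populations < 3:
            raise ValueError("need at least 3 populations")
        if self.n_alleles < 1:
            raise ValueError("need at least 1 allele sampled per population")
        if self.n_loci < 1:
            raise ValueError("need at least 1 locus")
        if not self.intercepts:
            self.intercepts = tuple(np.linspace(-1.0, 1.0, self.n_loci))
        if not self.slopes:
            self.slopes = tuple(1.0 + 0.25 * (i % 3) for i in range(self.n_loci))
        if len(self.intercepts) != self.n_loci or len(self.slopes) != self.n_loci:
            raise ValueError("intercepts/slopes must have one entry per locus")


@dataclass
class SyntheticDataset:
    counts: AlleleCountTable
    env_baseline: EnvTable
    env_changed: EnvTable
    geo: GeoTable
    true_freq_baseline: pd.DataFrame  # A-allele frequency, population x locus
    true_freq_changed: pd.DataFrame
    scenario: ClineScenario = field(repr=False, default=None)


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(key)))


def generate_dataset(s: ClineScenario) -> SyntheticDataset:
    """Generate aligned genetic, climate and geographic tables plus truth."""
    g, L, N = s.n_populations, s.n_loci, s.n_alleles
    pops = [f"P{i + 1:02d}" for i in range(g)]
    loci = [f"L{j + 1:02d}" for j in range(L)]
    x = np.linspace(*s.driver_range, g)

    env_cols = {"driver": x}
    rho = float(s.nuisance_cor)
    x_std = (x - x.mean()) / x.std()
    for j in range(s.n_nuisance):
        z = _rng(s.seed, 1_000_000 + j).standard_normal(g)
        z = (z - z.mean()) / z.std()
        env_cols[f"nuis{j + 1}"] = rho * x_std + np.sqrt(1 - rho**2) * z
    env_base = pd.DataFrame(env_cols, index=pops)
    env_chg = env_base.copy()
    env_chg["driver"] = env_chg["driver"] + s.delta

    true_b = {}
    true_c = {}
    count_cols = {}
    for l, locus in enumerate(loci):
        b0, b1 = s.intercepts[l], s.slopes[l]
        fb = expit(b0 + b1 * x)
        fc = expit(b0 + b1 * (x + s.delta))
        true_b[locus] = fb
        true_c[locus] = fc
        if s.noise:
            a = np.array([_rng(s.seed, p, l).binomial(N, fb[p]) for p in range(g)])
        else:
            a = np.round(N * fb).astype(np.int64)
        count_cols[f"{locus}.A"] = a
        count_cols[f"{locus}.B"] = N - a

    lat = np.linspace(40.0, 55.0, g) + _rng(s.seed, 2_000_000).normal(0, 0.3, g)
    lon = np.full(g, -122.0) + _rng(s.seed, 2_000_001).normal(0, 1.0, g)
    geo = GeoTable(pd.DataFrame({"longitude": lon, "latitude": lat}, index=pops))

    return SyntheticDataset(
        counts=AlleleCountTable(pd.DataFrame(count_cols, index=pops)),
        env_baseline=EnvTable(env_base, climate_tag="baseline"),
        env_changed=EnvTable(env_chg, climate_tag="changed"),
        geo=geo,
        true_freq_baseline=pd.DataFrame(true_b, index=pops),
        true_freq_changed=pd.DataFrame(true_c, index=pops),
        scenario=s,
    )
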