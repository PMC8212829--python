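import numpy as np
import pandas as pd
import pytest

from clineshift import AlleleCountTable, ClineScenario, EnvTable, generate_dataset
from clineshift.count import count_model, count_pred
from clineshift.freq import freq_model, freq_pred


@pytest.fixture(scope="session")
def noisefree_data():
    """Deterministic logistic clines, 20 populations, no sampling noise."""
    return generate_dataset(ClineScenario(noise=False, seed=7))


@pytest.fixture(scope="session")
def noisy_data():
    """Same clines with binomial sampling of 100 alleles per population."""
    return generate_dataset(ClineScenario(noise=True, seed=7))


@pytest.fixture(scope="session")
def changed_table(noisy_data):
    """Full pipeline output: changed-climate prediction table."""
    d = noisy_data
    model = count_model(d.counts, d.env_baseline)
    base_pred = count_pred(model, d.env_baseline, d.counts)
    fm = freq_model(d.counts, base_pred)
    return freq_pred(fm, count_pred(model, d.env_changed, d.counts), d.counts)


@pytest.fixture
def tiny_counts():
    """Three populations, two loci, hand-sized counts."""
    return AlleleCountTable(
        pd.DataFrame(
            {
                "L1.A": [2, 5, 8],
                "L1.B": [8, 5, 2],
                "L2.A": [1, 4, 9],
                "L2.B": [9, 6, 1],
            },
            index=["P1", "P2", "P3"],
        )
    )


@pytest.fixture
def tiny_env():
    return EnvTable(
        pd.DataFrame({"temp": [10.0, 15.0, 20.0], "prec": [800.0, 650.0, 400.0]}, index=["P1", "P2", "P3"]),
        climate_tag="baseline",
    )


def pipeline_mae(dataset, basis_dim=None):
    """Mean |predicted - true| changed-climate minor-allele frequency."""
    from clineshift.io import minor_alleles

    model = count_model(dataset.counts, dataset.env_baseline)
    base_pred = count_pred(model, dataset.env_baseline, dataset.counts)
    fm = freq_model(dataset.counts, base_pred, basis_dim=basis_dim)
    table = freq_pred(fm, count_pred(model, dataset.env_changed, dataset.counts), dataset.counts)
    minors = minor_alleles(dataset.counts)
    errs = []
    for locus in dataset.counts.locus_ids:
        truth = dataset.true_freq_changed[locus]
        if minors[locus] == "B":
            truth = 1.0 - truth
        sub = table.data[table.data["locus"] == locus].set_index("population")
        errs.append(np.abs(sub["Freq.e2"] - truth).to_numpy())
    return float(np.mean(np.concatenate(errs)))
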