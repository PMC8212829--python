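"""Binomial smooth correction: calibration, prediction table, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from clineshift.count import CountPrediction, count_model, count_pred
from clineshift.freq import (
    FrequencyModel,
    PredictionTable,
    freq_model,
    freq_pred,
    freq_scatter_data,
)
from clineshift.io import AlleleCountTable, EnvTable
from clineshift.synthetic import ClineScenario, generate_dataset


def _baseline_pred(counts, env):
    model = count_model(counts, env)
    return model, count_pred(model, env, counts)


def test_noise_free_logistic_relation_is_recovered():
    # single driver so the predicted count determines the true frequency
    d = generate_dataset(ClineScenario(noise=False, n_nuisance=0, seed=7))
    _, base_pred = _baseline_pred(d.counts, d.env_baseline)
    fm = freq_model(d.counts, base_pred)
    table = freq_pred(fm, base_pred, d.counts, climate_tag="baseline")
    err = (table.data["Freq.e2"] - table.data["Allele.freq"]).abs()
    assert err.max() < 0.01


def _irls_logistic(t, f, w):
    """Unpenalized weighted logistic regression by hand-rolled IRLS."""
    z = np.column_stack([np.ones(len(t)), t])
    beta = np.zeros(2)
    for _ in range(200):
        mu = expit(z @ beta)
        wt = w * mu * (1 - mu)
        grad = z.T @ (w * (f - mu))
        hess = z.T @ (z * wt[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < 1e-12:
            break
    return beta


def test_linear_in_link_fit_matches_irls_oracle():
    rng = np.random.default_rng(19)
    g = 15
    t = np.linspace(5, 60, g)
    f_true = expit(-3 + 0.08 * t)
    n = np.full(g, 80)
    a = rng.binomial(80, f_true)
    counts = AlleleCountTable(
        pd.DataFrame({"L1.A": a, "L1.B": 80 - a}, index=[f"P{i}" for i in range(g)])
    )
    # minor allele may be A or B; make A clearly minor
    assert a.sum() < (80 * g - a.sum())
    pred = CountPrediction(
        ap=pd.DataFrame({"L1": t}, index=counts.population_ids),
        bp=pd.DataFrame({"L1": 80 - t}, index=counts.population_ids),
        n_e1=pd.Series(80.0, index=counts.population_ids),
        climate_tag="baseline",
    )
    fm = FrequencyModel(basis_dim=2).fit(pred, counts)
    smooth = fm.smooths_["L1"]
    assert smooth.kind == "linear"
    oracle = _irls_logistic(t, a / 80.0, n.astype(float))
    np.testing.assert_allclose(smooth.params, oracle, rtol=1e-6)


def test_constant_frequency_yields_constant_fit():
    g = 8
    counts = AlleleCountTable(
        pd.DataFrame({"L1.A": [5] * g, "L1.B": [5] * g}, index=[f"P{i}" for i in range(g)])
    )
    pred = CountPrediction(
        ap=pd.DataFrame({"L1": np.linspace(2, 8, g)}, index=counts.population_ids),
        bp=pd.DataFrame({"L1": 10 - np.linspace(2, 8, g)}, index=counts.population_ids),
        n_e1=pd.Series(10.0, index=counts.population_ids),
        climate_tag="baseline",
    )
    fm = FrequencyModel().fit(pred, counts)
    table = fm.predict(pred, counts)
    np.testing.assert_allclose(table.data["Freq.e2"], 0.5, atol=1e-8)


def test_all_zero_frequencies_degenerate_warning():
    g = 6
    counts = AlleleCountTable(
        pd.DataFrame({"L1.A": [0] * g, "L1.B": [10] * g}, index=[f"P{i}" for i in range(g)])
    )
    pred = CountPrediction(
        ap=pd.DataFrame({"L1": np.linspace(0, 3, g)}, index=counts.population_ids),
        bp=pd.DataFrame({"L1": 10 - np.linspace(0, 3, g)}, index=counts.population_ids),
        n_e1=pd.Series(10.0, index=counts.population_ids),
        climate_tag="baseline",
    )
    with pytest.warns(UserWarning, match="degenerate"):
        fm = FrequencyModel().fit(pred, counts)
    table = fm.predict(pred, counts)
    assert (table.data["Freq.e2"] == 0.0).all()
    assert (table.data["LCL"] == 0.0).all() and (table.data["UCL"] == 0.0).all()


def test_basis_reduction_warns_with_few_populations():
    g = 4
    counts = AlleleCountTable(
        pd.DataFrame({"L1.A": [1, 3, 5, 7], "L1.B": [9, 7, 5, 3]}, index=[f"P{i}" for i in range(g)])
    )
    pred = CountPrediction(
        ap=pd.DataFrame({"L1": [1.0, 3.0, 5.0, 7.0]}, index=counts.population_ids),
        bp=pd.DataFrame({"L1": [9.0, 7.0, 5.0, 3.0]}, index=counts.population_ids),
        n_e1=pd.Series(10.0, index=counts.population_ids),
        climate_tag="baseline",
    )
    with pytest.warns(UserWarning, match="reduced"):
        FrequencyModel(basis_dim=6).fit(pred, counts)


def test_prediction_table_fields_and_ranges(changed_table):
    d = changed_table.data
    np.testing.assert_allclose(d["Freq.e1"], d["Ap"] / d["N.e1"], rtol=1e-12)
    assert ((d["Freq.e2"] >= 0) & (d["Freq.e2"] <= 1)).all()
    assert ((d["LCL"] >= 0) & (d["UCL"] <= 1)).all()
    assert ((d["LCL"] <= d["Freq.e2"]) & (d["Freq.e2"] <= d["UCL"])).all()
    assert (d["increasing"] == (d["Freq.e2"] > d["Allele.freq"])).all()
    assert (d["Ap"] + d["Bp"]).to_numpy() == pytest.approx(d["N.e1"].to_numpy())


def test_negative_rda_frequency_is_mapped_into_unit_interval():
    """Scenario engineered so the first step predicts a negative frequency;
    the smooth correction must still land in [0, 1]."""
    s = ClineScenario(
        n_populations=15,
        n_loci=1,
        intercepts=(-3.0,),
        slopes=(1.6,),
        delta=-2.0,
        noise=False,
        seed=5,
    )
    d = generate_dataset(s)
    model = count_model(d.counts, d.env_baseline)
    base_pred = count_pred(model, d.env_baseline, d.counts)
    chg_pred = count_pred(model, d.env_changed, d.counts)
    fm = freq_model(d.counts, base_pred)
    table = freq_pred(fm, chg_pred, d.counts)
    assert (table.data["Freq.e1"] < 0).any()  # the pathology is present
    assert ((table.data["Freq.e2"] >= 0) & (table.data["Freq.e2"] <= 1)).all()
    assert ((table.data["LCL"] >= 0) & (table.data["UCL"] <= 1)).all()


def test_monotone_smooth_is_monotone_in_predicted_count(noisefree_data):
    d = noisefree_data
    _, base_pred = _baseline_pred(d.counts, d.env_baseline)
    fm = freq_model(d.counts, base_pred)
    smooth = fm.smooths_["L01"]
    grid = np.linspace(-20, 120, 200)
    f, _, _ = smooth.predict(grid)
    diffs = np.diff(f)
    if (diffs >= -1e-12).all() or (diffs <= 1e-12).all():
        # the fitted smooth is monotone: larger Ap never reverses Freq.e2
        assert (np.diff(np.sort(f)) >= -1e-12).all()


def test_missing_locus_raises(changed_table, noisy_data):
    d = noisy_data
    model = count_model(d.counts, d.env_baseline)
    base_pred = count_pred(model, d.env_baseline, d.counts)
    fm = freq_model(d.counts, base_pred)
    chg = count_pred(model, d.env_changed, d.counts)
    chg.ap.columns = ["X" + c for c in chg.ap.columns]
    chg.bp.columns = ["X" + c for c in chg.bp.columns]
    with pytest.raises(KeyError, match="absent"):
        freq_pred(fm, chg, d.counts)


def test_scatter_groups_and_r2_oracle():
    rows = []
    obs = {"P1": [0.1, 0.2, 0.3, 0.4], "P2": [0.3, 0.3, 0.1, 0.4]}
    prd = {"P1": [0.1, 0.2, 0.3, 0.4], "P2": [0.2, 0.4, 0.4, 0.2]}
    for pop in ("P1", "P2"):
        for i in range(4):
            rows.append(
                {
                    "population": pop,
                    "locus": f"L{i}",
                    "N": 10,
                    "Allele.freq": obs[pop][i],
                    "A": 1,
                    "B": 9,
                    "Ap": 1.0,
                    "Bp": 9.0,
                    "N.e1": 10.0,
                    "Freq.e1": 0.1,
                    "Freq.e2": prd[pop][i],
                    "LCL": 0.0,
                    "UCL": 1.0,
                    "increasing": False,
                }
            )
    table = PredictionTable(pd.DataFrame(rows), climate_tag="baseline")
    out = freq_scatter_data(table).set_index("population")
    assert out.loc["P1", "group"] == "high"
    assert out.loc["P1", "r2"] == pytest.approx(1.0)
    r_oracle = np.corrcoef(obs["P2"], prd["P2"])[0, 1] ** 2
    assert out.loc["P2", "r2"] == pytest.approx(r_oracle)


def test_scatter_few_loci_goes_low_with_warning():
    rows = [
        {
            "population": "P1",
            "locus": "L1",
            "N": 10,
            "Allele.freq": 0.2,
            "A": 2,
            "B": 8,
            "Ap": 2.0,
            "Bp": 8.0,
            "N.e1": 10.0,
            "Freq.e1": 0.2,
            "Freq.e2": 0.2,
            "LCL": 0.1,
            "UCL": 0.3,
            "increasing": False,
        }
    ]
    table = PredictionTable(pd.DataFrame(rows), climate_tag="baseline")
    with pytest.warns(UserWarning, match="fewer than 3 loci"):
        out = freq_scatter_data(table)
    assert out.iloc[0]["group"] == "low"


def test_table_write_renders_three_decimals(tmp_path, changed_table):
    path = tmp_path / "t.csv"
    changed_table.write(path)
    first = pd.read_csv(path)
    assert f"{changed_table.data['Freq.e2'][0]:.3f}" == f"{first['Freq.e2'][0]:.3f}"
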