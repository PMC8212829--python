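"""Redundancy analysis, the CCA variant, and AMOVA from the ordination."""

import numpy as np
import pandas as pd
import pytest

from clineshift.io import IndividualAlleleTable
from clineshift.ordination import (
    CanonicalCorrespondenceAnalysis,
    RedundancyAnalysis,
    amova_rda,
    fit_predict_cca,
    fit_rda,
    predict_rda,
)


def test_perfect_linear_dependence_saturates_inertia():
    x = np.array([[1.0], [2.0], [3.0], [4.0]])
    y = 2.0 * x
    model = fit_rda(y, x)
    assert model.constrained_inertia_ == pytest.approx(model.total_inertia_)
    np.testing.assert_allclose(model.fitted_, y - y.mean(axis=0), atol=1e-12)


def test_orthogonal_response_gives_zero_constrained_inertia():
    x = np.array([[1.0], [-1.0], [1.0], [-1.0]])
    y = np.array([[1.0], [1.0], [-1.0], [-1.0]])
    model = fit_rda(y, x)
    np.testing.assert_allclose(model.coef_, 0.0, atol=1e-12)
    assert model.constrained_inertia_ == pytest.approx(0.0, abs=1e-12)


def test_coefficients_match_normal_equations_oracle():
    rng = np.random.default_rng(21)
    x = rng.standard_normal((6, 2))
    y = rng.standard_normal((6, 3))
    model = fit_rda(y, x)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    oracle = np.linalg.solve(xc.T @ xc, xc.T @ yc)
    np.testing.assert_allclose(model.coef_, oracle, rtol=1e-10)
    assert model.constrained_inertia_ == pytest.approx(
        float(np.sum(model.singular_values_**2)) / 5
    )


def test_variance_conservation():
    rng = np.random.default_rng(8)
    x = rng.standard_normal((10, 3))
    y = rng.standard_normal((10, 4))
    model = fit_rda(y, x)
    assert model.constrained_inertia_ + model.residual_inertia_ == pytest.approx(
        model.total_inertia_
    )


def test_predict_identity_on_calibration_data():
    rng = np.random.default_rng(13)
    x = rng.standard_normal((7, 2))
    y = rng.standard_normal((7, 3))
    model = fit_rda(y, x)
    np.testing.assert_allclose(predict_rda(model, x), model.fitted_ + model.y_mean_, atol=1e-12)


def test_centroid_maps_to_centroid():
    rng = np.random.default_rng(14)
    x = rng.standard_normal((5, 2))
    y = rng.standard_normal((5, 2))
    model = fit_rda(y, x)
    np.testing.assert_allclose(
        predict_rda(model, x.mean(axis=0)[None, :])[0], model.y_mean_, atol=1e-12
    )


def test_scalar_prediction_matches_slope_intercept():
    x = np.array([[0.0], [1.0], [2.0]])
    y = np.array([[1.0], [3.0], [4.0]])
    model = fit_rda(y, x)
    slope = np.polyfit(x[:, 0], y[:, 0], 1)[0]
    intercept = np.polyfit(x[:, 0], y[:, 0], 1)[1]
    x_new = np.array([[5.0]])
    assert predict_rda(model, x_new)[0, 0] == pytest.approx(slope * 5 + intercept)


def test_rank_deficient_explanatory_names_columns():
    x = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0]})
    y = np.random.default_rng(0).standard_normal((4, 2))
    with pytest.raises(ValueError, match="rank deficient"):
        fit_rda(y, x)


def test_no_constraints_degenerates_to_pca():
    rng = np.random.default_rng(30)
    y = rng.standard_normal((8, 4))
    model = RedundancyAnalysis().fit(None, y)
    yc = y - y.mean(axis=0)
    _, s, vt = np.linalg.svd(yc, full_matrices=False)
    np.testing.assert_allclose(model.singular_values_, s, rtol=1e-10)
    assert model.constrained_inertia_ == pytest.approx(model.total_inertia_)
    # axes agree up to sign
    for k in range(vt.shape[0]):
        assert abs(np.dot(model.axes_[k], vt[k])) == pytest.approx(1.0)


def test_predict_rejects_wrong_variables():
    x = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
    y = np.array([[1.0], [2.0], [2.5]])
    model = fit_rda(y, x)
    with pytest.raises(ValueError, match="do not match"):
        model.predict(pd.DataFrame({"z": [1.0]}))


def test_rank_truncated_prediction_projects_onto_axes():
    rng = np.random.default_rng(17)
    x = rng.standard_normal((9, 3))
    y = rng.standard_normal((9, 4))
    model = fit_rda(y, x)
    full = model.predict(x, rank="full") - model.y_mean_
    r1 = model.predict(x, rank=1) - model.y_mean_
    v1 = model.axes_[0]
    np.testing.assert_allclose(r1, (full @ v1)[:, None] * v1[None, :], atol=1e-10)


# --------------------------------------------------------------------------
# CCA


def test_cca_saturated_indicators_reproduce_counts():
    y = np.array([[10.0, 5.0, 1.0], [2.0, 8.0, 4.0], [6.0, 6.0, 6.0], [1.0, 2.0, 9.0]])
    x = np.eye(4)[:, :3]  # full population indicators (one dropped)
    counts, flag = fit_predict_cca(y, x, x)
    np.testing.assert_allclose(counts, y, atol=1e-8)
    assert flag is False


def test_cca_fitted_matches_weighted_regression_oracle():
    """Calibration-data predictions equal an independently coded
    chi-square-profile weighted regression."""
    rng = np.random.default_rng(2)
    y = rng.integers(1, 20, size=(4, 3)).astype(float)
    x = rng.standard_normal((4, 2))
    counts, _ = fit_predict_cca(y, x, x)

    total = y.sum()
    p = y / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    q = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    xw = x - r @ x
    xs = xw / np.sqrt(r @ xw**2)
    d = np.column_stack([np.ones(4), xs])
    rw = np.diag(r)
    beta = np.linalg.solve(d.T @ rw @ d, d.T @ rw @ q)
    q_hat = d @ beta
    oracle = (q_hat * np.sqrt(np.outer(r, c)) + np.outer(r, c)) * total
    np.testing.assert_allclose(counts, oracle, rtol=1e-8)


def test_cca_flags_negative_predictions():
    y = np.array([[10.0, 1.0], [8.0, 3.0], [6.0, 5.0], [1.0, 12.0]])
    x = np.arange(4.0)[:, None]
    model = CanonicalCorrespondenceAnalysis().fit(x, y)
    with pytest.warns(UserWarning, match="negative"):
        _, flag = model.predict(np.array([[25.0]]))
    assert flag is True


def test_cca_rejects_zero_margins():
    y = np.array([[0.0, 0.0], [1.0, 2.0]])
    with pytest.raises(ValueError, match="positive row and column sums"):
        CanonicalCorrespondenceAnalysis().fit(np.arange(2.0)[:, None], y)


# --------------------------------------------------------------------------
# AMOVA


def _random_individuals(rng, g, n_per, loci):
    dosages = {}
    for l in range(loci):
        a = rng.integers(0, 3, size=g * n_per)
        dosages[f"L{l}.A"] = a
        dosages[f"L{l}.B"] = 2 - a
    idx = [f"i{k}" for k in range(g * n_per)]
    pops = pd.Series(np.repeat([f"P{j}" for j in range(g)], n_per), index=idx)
    return IndividualAlleleTable(pd.DataFrame(dosages, index=idx), pops)


def _pairwise_ss(mat):
    d2 = ((mat[:, None, :] - mat[None, :, :]) ** 2).sum(axis=2)
    return d2[np.triu_indices(len(mat), 1)].sum() / len(mat)


def test_amova_matches_pairwise_distance_oracle():
    rng = np.random.default_rng(42)
    ind = _random_individuals(rng, 2, 3, 4)
    table = amova_rda(ind)
    mat = ind.allele_matrix().to_numpy(float)
    ss_total = _pairwise_ss(mat)
    ss_within = sum(
        ((mat[sl][:, None, :] - mat[sl][None, :, :]) ** 2).sum(axis=2)[
            np.triu_indices(3, 1)
        ].sum()
        / 3
        for sl in (slice(0, 3), slice(3, 6))
    )
    assert table.ss_total == pytest.approx(ss_total, rel=1e-10)
    assert table.ss_within == pytest.approx(ss_within, rel=1e-10)
    assert table.ss_among == pytest.approx(ss_total - ss_within, rel=1e-9)


def test_amova_identical_individuals_has_undefined_phi():
    dosages = pd.DataFrame({"L1.A": [1, 1, 1, 1], "L1.B": [1, 1, 1, 1]}, index=list("abcd"))
    pops = pd.Series(["P1", "P1", "P2", "P2"], index=dosages.index)
    with pytest.warns(UserWarning, match="identical"):
        table = amova_rda(IndividualAlleleTable(dosages, pops))
    assert table.ss_total == 0
    assert np.isnan(table.phi_st)


def test_amova_fixation_gives_phi_one():
    dosages = pd.DataFrame(
        {"L1.A": [2, 2, 2, 0, 0, 0], "L1.B": [0, 0, 0, 2, 2, 2]},
        index=[f"i{k}" for k in range(6)],
    )
    pops = pd.Series(["P1"] * 3 + ["P2"] * 3, index=dosages.index)
    table = amova_rda(IndividualAlleleTable(dosages, pops))
    assert table.ss_within == pytest.approx(0.0, abs=1e-10)
    assert table.phi_st == pytest.approx(1.0)


def test_amova_requires_two_populations():
    dosages = pd.DataFrame({"L1.A": [1, 2], "L1.B": [1, 0]}, index=["a", "b"])
    pops = pd.Series(["P1", "P1"], index=dosages.index)
    with pytest.raises(ValueError, match="2 populations"):
        amova_rda(IndividualAlleleTable(dosages, pops))


def test_amova_invariant_to_population_label_order():
    rng = np.random.default_rng(5)
    ind = _random_individuals(rng, 3, 4, 3)
    t1 = amova_rda(ind)
    # reverse row order (changes which indicator level is dropped)
    rev = IndividualAlleleTable(ind.dosages.iloc[::-1], ind.population_of.iloc[::-1])
    t2 = amova_rda(rev)
    assert t1.ss_among == pytest.approx(t2.ss_among, rel=1e-10)
    assert t1.phi_st == pytest.approx(t2.phi_st, rel=1e-10)


def test_amova_degrees_of_freedom():
    rng = np.random.default_rng(6)
    ind = _random_individuals(rng, 3, 5, 2)
    table = amova_rda(ind)
    assert (table.df_among, table.df_within, table.df_total) == (2, 12, 14)
    assert table.ss_among + table.ss_within == pytest.approx(table.ss_total)
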