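"""Likelihood correctness, optimizer behavior, identifiability tooling."""
import numpy as np
import pandas as pd
import pytest

from bcellqsp import (
    CalibrationProblem,
    build_parameters,
    fit,
    fit_vmax_per_study,
    multistart,
    profile_ci,
    uncertainty_bands,
)
from bcellqsp.calibration import (
    _fd_hessian,
    _nearest_psd,
    multistart_dispersion,
)
from bcellqsp.parameters import FITTED_NAMES

from conftest import FAST_FIT, LOOP_TOL

DAYS = (7.0, 14.0, 28.0, 60.0, 200.0)
TISSUES = ("spleen", "lymph_nodes", "bone_marrow", "blood")


def _table(values_by_tissue):
    rows = []
    for tissue, vals in values_by_tissue.items():
        for d, v in zip(DAYS, vals):
            rows.append(
                {
                    "study": "s",
                    "tissue": tissue,
                    "day": d,
                    "value": v,
                    "error": np.nan,
                    "scaled": True,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def truth_values(params_sc):
    return np.array([getattr(params_sc, n) for n in FITTED_NAMES])


@pytest.fixture(scope="module")
def noiseless_predictions(params_sc, schedule, truth_values):
    """Model predictions at truth, via the same pathway the likelihood uses."""
    seed_table = _table({t: [1.0] * len(DAYS) for t in TISSUES})
    problem = CalibrationProblem(seed_table, params_sc, schedule, **LOOP_TOL)
    pred = problem.predict(truth_values)
    out = {}
    for tissue in TISSUES:
        idx = problem.data["tissue"] == tissue
        sub = problem.data[idx].sort_values("day")
        out[tissue] = pred[idx.to_numpy()][np.argsort(sub["day"].to_numpy())]
    return out


def test_neg2ll_closed_form_for_constant_residuals(
    params_sc, schedule, truth_values, noiseless_predictions
):
    # observations chosen so every log10(value+1) residual equals exactly c;
    # the profiled-variance objective collapses to n*(1 + log(2*pi*c^2))
    c = 0.1
    shifted = {
        t: (np.asarray(v) + 1.0) * 10.0**c - 1.0
        for t, v in noiseless_predictions.items()
    }
    problem = CalibrationProblem(_table(shifted), params_sc, schedule, **LOOP_TOL)
    n = len(problem.data)
    expected = n * (1.0 + np.log(2.0 * np.pi * c**2))
    assert problem.neg2ll(truth_values) == pytest.approx(expected, rel=1e-9)


def test_neg2ll_additive_over_variable_groups(
    params_sc, schedule, truth_values, noiseless_predictions
):
    rng = np.random.default_rng(3)
    noisy = {
        t: np.asarray(v) * rng.lognormal(0.0, 0.3, size=len(DAYS))
        for t, v in noiseless_predictions.items()
    }
    total = CalibrationProblem(
        _table(noisy), params_sc, schedule, **LOOP_TOL
    ).neg2ll(truth_values)
    parts = sum(
        CalibrationProblem(
            _table({t: noisy[t]}), params_sc, schedule, **LOOP_TOL
        ).neg2ll(truth_values)
        for t in TISSUES
    )
    assert total == pytest.approx(parts, rel=1e-9)


def test_sigmas_are_rms_residuals(params_sc, schedule, truth_values, fitted):
    problem, _, _ = fitted
    res = problem.residuals_by_group(truth_values)
    sig = problem.sigmas(truth_values)
    for tissue, r in res.items():
        assert sig[tissue] == pytest.approx(float(np.sqrt(np.mean(r**2))))


def test_problem_validation(params_sc, schedule):
    with pytest.raises(ValueError):
        CalibrationProblem(pd.DataFrame(columns=["day"]), params_sc, schedule)
    with pytest.raises(ValueError):
        CalibrationProblem(
            _table({"spleen": [1] * 5}), params_sc, schedule, scale="bogus"
        )


def test_fd_hessian_quadratic_oracle():
    A = np.array([[2.0, 0.5, 0.0], [0.5, 1.0, -0.3], [0.0, -0.3, 3.0]])

    def f(x):
        return float(x @ A @ x)

    H = _fd_hessian(f, np.array([0.4, -1.2, 2.0]), h=0.01)
    np.testing.assert_allclose(H, 2.0 * A, atol=1e-7)


def test_nearest_psd():
    good = np.array([[2.0, 0.1], [0.1, 1.0]])
    np.testing.assert_allclose(_nearest_psd(good), good)
    bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
    with pytest.warns(UserWarning):
        repaired = _nearest_psd(bad)
    assert np.all(np.linalg.eigvalsh(repaired) > 0)


def test_fit_requires_positive_init(fitted):
    problem, _, _ = fitted
    with pytest.raises(ValueError):
        fit(problem, init={"Vmax": -5.0}, **FAST_FIT)


def test_fit_with_all_parameters_fixed_evaluates_objective(fitted):
    problem, _, _ = fitted
    pinned = {n: getattr(problem.base_params, n) for n in FITTED_NAMES}
    r = fit(problem, fixed=pinned)
    assert r.converged and r.n_iter == 0
    assert r.minus2ll == pytest.approx(
        problem.neg2ll(np.array([pinned[n] for n in FITTED_NAMES])), rel=1e-12
    )


def test_one_dimensional_fit_recovers_vmax(fitted):
    problem, _, truth = fitted
    true_vmax = truth["parameters"]["Vmax"]
    pinned = {
        n: truth["parameters"][n] for n in FITTED_NAMES if n != "Vmax"
    }
    r = fit(problem, init={"Vmax": true_vmax * 2.0}, fixed=pinned, **FAST_FIT)
    # only noise separates the estimate from truth in the 1-D problem
    assert r.estimates["Vmax"] == pytest.approx(true_vmax, rel=0.25)
    assert 0.0 < r.rse["Vmax"] < 25.0


def test_fit_result_serializes(fitted):
    _, result, _ = fitted
    d = result.to_dict()
    assert set(d) >= {"estimates", "minus2ll", "sigma", "rse_percent"}
    assert set(d["estimates"]) == set(FITTED_NAMES)


def test_profile_ci_brackets_the_estimate(fitted):
    problem, result, _ = fitted
    lo, hi = profile_ci(
        problem, result, "kmat_3",
        fatol=1e-3, xatol=1e-2, restart=False, maxiter=150, xtol_log=0.03,
    )
    est = result.estimates["kmat_3"]
    assert lo < est < hi
    # profile CI and Wald CI should be the same order of width
    wald = est * result.rse["kmat_3"] / 100.0 * 1.96
    assert (hi - lo) == pytest.approx(2.0 * wald, rel=0.6)


def test_multistart_validation_and_dispersion(fitted):
    problem, _, _ = fitted
    with pytest.raises(ValueError):
        multistart(problem, n_starts=1)
    results = multistart(problem, n_starts=3, seed=5, **FAST_FIT)
    assert len(results) == 3
    assert results[0].minus2ll <= results[-1].minus2ll
    disp = multistart_dispersion(results)
    assert set(disp) == set(FITTED_NAMES)
    assert all(v >= 0.0 for v in disp.values())


def test_uncertainty_bands_are_ordered(fitted):
    problem, result, _ = fitted
    bands = uncertainty_bands(
        problem, result, n_samples=25, seed=0, t_end=100.0, dt_out=10.0
    )
    for state in ("ASCBone", "ASCSpleen"):
        b = bands[state]
        assert np.all(b["lower"] <= b["median"] + 1e-9)
        assert np.all(b["median"] <= b["upper"] + 1e-9)


def test_fit_vmax_per_study_validation(params_sc, schedule):
    no_bone = _table({"spleen": [1.0] * 5})
    with pytest.raises(ValueError, match="bone-marrow"):
        fit_vmax_per_study([no_bone], params_sc, schedule)
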