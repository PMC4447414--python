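"""Error statistics, empirical p-values, and submission analytics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wcbench import scoring as sc
from wcbench import toycell as tc

positive = st.floats(min_value=1e-3, max_value=1e3)


# ---------------------------------------------------------------------------
# parameter error (mean squared log10 ratio)


def test_param_error_values():
    assert sc.param_error([2.0, 3.0], [2.0, 3.0]) == 0.0
    assert abs(sc.param_error([10.0], [1.0]) - 1.0) < 1e-12
    est = np.ones(30)
    true = np.ones(30)
    est[0] = 10.0
    assert abs(sc.param_error(est, true) - 1.0 / 30.0) < 1e-12


def test_param_error_domain_and_contract():
    with pytest.raises(sc.DomainError):
        sc.param_error([-1.0], [1.0])
    with pytest.raises(tc.ContractError):
        sc.param_error([1.0, 2.0], [1.0])


@given(st.lists(st.tuples(positive, positive), min_size=1, max_size=20))
def test_param_error_permutation_and_reciprocal_invariance(pairs):
    est = np.array([p[0] for p in pairs])
    true = np.array([p[1] for p in pairs])
    e = sc.param_error(est, true)
    perm = np.random.default_rng(0).permutation(len(pairs))
    assert math.isclose(e, sc.param_error(est[perm], true[perm]), rel_tol=1e-9)
    assert math.isclose(e, sc.param_error(1 / est, 1 / true), rel_tol=1e-9)


# ---------------------------------------------------------------------------
# prediction error (variance-normalized least squares)


def test_prediction_error_values():
    assert sc.prediction_error([1.0], [1.0], [1.0]) == 0.0
    assert abs(sc.prediction_error([3.0], [1.0], [1.0]) - 4.0) < 1e-12
    # deviations of 1 and 3 sigma -> (1 + 9) / 2
    e = sc.prediction_error([1.0, 3.0], [0.0, 0.0], [1.0, 1.0])
    assert abs(e - 5.0) < 1e-12


def test_prediction_error_scaling():
    rng = np.random.default_rng(1)
    true = rng.normal(size=20)
    sig = rng.uniform(0.5, 2.0, size=20) ** 2
    dev = rng.normal(size=20)
    e1 = sc.prediction_error(true + dev, true, sig)
    e3 = sc.prediction_error(true + 3 * dev, true, sig)
    assert math.isclose(e3, 9 * e1, rel_tol=1e-9)


def test_prediction_error_variance_floor():
    e, detail, n_excl = sc.prediction_error(
        [1.0, 5.0], [0.0, 4.0], [0.0, 1.0], return_detail=True
    )
    assert n_excl == 1 and abs(e - 1.0) < 1e-12
    assert np.isnan(detail[0])
    with pytest.raises(sc.EstimationUndefinedError):
        sc.prediction_error([1.0], [0.0], [0.0])


# ---------------------------------------------------------------------------
# empirical p-values and combined score


def test_empirical_pvalue_extremes():
    pool = np.array([[1.0, 2.0], [3.0, 4.0], [2.0, 9.0]])
    err_fn = lambda v: float(np.sum(v))
    n_meta = 100
    p_low = sc.empirical_pvalue(-1e9, pool, err_fn, n_meta=n_meta, seed=0)
    assert p_low == 1.0 / (n_meta + 1)
    p_high = sc.empirical_pvalue(1e9, pool, err_fn, n_meta=n_meta, seed=0)
    assert p_high == 1.0


def test_empirical_pvalue_degenerate_pool():
    pool = np.ones((3, 4))
    assert sc.empirical_pvalue(0.5, pool, lambda v: 1.0, n_meta=10, seed=0) == 1.0


def test_empirical_pvalue_enumeration_oracle():
    """Two one-coordinate submissions: meta errors are an equal coin flip
    between the two submission errors, so the p-value matches the exact
    enumeration probability."""
    pool = np.array([[1.0], [10.0]])
    err_fn = lambda v: sc.param_error(v, np.array([1.0]))  # errors 0 or 1
    n_meta = 4000
    p = sc.empirical_pvalue(0.0, pool, err_fn, n_meta=n_meta, seed=3)
    assert abs(p - 0.5) < 0.04  # (1 + n/2) / (n + 1)
    p_all = sc.empirical_pvalue(1.0, pool, err_fn, n_meta=n_meta, seed=3)
    assert p_all == 1.0


def test_empirical_pvalue_monotone():
    rng = np.random.default_rng(7)
    pool = rng.lognormal(size=(5, 6))
    err_fn = lambda v: float(np.mean(v**2))
    observed = sorted(rng.uniform(0.1, 10.0, size=8))
    ps = [
        sc.empirical_pvalue(o, pool, err_fn, n_meta=300, seed=9) for o in observed
    ]
    assert all(a <= b for a, b in zip(ps, ps[1:]))


def test_overall_score():
    assert sc.overall_score(1.0, 1.0) == 0.0
    assert abs(sc.overall_score(math.exp(-2), math.exp(-3)) - 5.0) < 1e-12
    assert abs(sc.overall_score(0.5, 0.5) - 2 * math.log(2)) < 1e-12
    with pytest.raises(sc.DomainError):
        sc.overall_score(0.0, 0.5)


def test_score_decomposition_identity():
    """s equals -ln p_param - ln p_predict to machine precision."""
    for pp, pq in [(0.3, 0.7), (1e-4, 0.2), (1.0, 1.0)]:
        assert math.isclose(
            sc.overall_score(pp, pq),
            -math.log(pp) - math.log(pq),
            rel_tol=0,
            abs_tol=1e-12,
        )


# ---------------------------------------------------------------------------
# analytics


def _truth(names):
    return tc.ParameterSet(
        tuple(names), ("rna_half_life",) * len(names), np.ones(len(names))
    )


def test_per_parameter_errors():
    names = ("a", "b")
    truth = _truth(names)
    exact = sc.Submission(values={"a": 1.0, "b": 1.0})
    off = sc.Submission(values={"a": 10.0, "b": 1.0})
    out = sc.per_parameter_errors([exact, exact], truth, names, top_k=2)
    assert np.allclose(out["mean_sq_log10_error"], 0.0)
    out = sc.per_parameter_errors([exact, off], truth, names, top_k=1)
    assert np.allclose(out["mean_sq_log10_error"], [0.0, 0.0])
    out = sc.per_parameter_errors([exact, off], truth, names, top_k=2)
    assert np.allclose(out["mean_sq_log10_error"], [0.5, 0.0])
    out = sc.per_parameter_errors([exact], truth, names, top_k=5)
    assert out.attrs["truncated"]


def test_coefficient_of_variation():
    cells = np.array([[1.0, 1.0, 0.0], [3.0, 1.0, 0.0]])
    out = sc.coefficient_of_variation(cells)
    assert abs(out["cv"][0] - math.sqrt(2) / 2) < 1e-12
    assert out["cv"][1] == 0.0
    assert out["zero_mean"][2] and np.isnan(out["cv"][2])
    with pytest.raises(tc.ContractError):
        sc.coefficient_of_variation(cells[:1])


def test_bundle_cv_by_class(pkg):
    table = sc.bundle_cv_by_class(pkg.mutant_bundle)
    assert set(table.index) <= set(tc.DATA_CLASSES)
    assert (table["median_cv"] >= 0).all()


def test_parameter_error_correlation_signal():
    names = ("a", "b")
    rng = np.random.default_rng(5)
    subs = []
    for _ in range(50):
        va = rng.uniform(0.5, 2.0)
        sub = sc.Submission(values={"a": va, "b": 1.3})
        sub.prediction_error = va  # strictly increasing in a
        subs.append(sub)
    out = sc.parameter_error_correlation(subs, names).set_index("name")
    assert out.loc["a", "rho"] == pytest.approx(1.0)
    assert not out.loc["b", "defined"]  # constant column flagged


def test_parameter_error_correlation_null():
    """Independent shuffled columns stay near zero correlation."""
    rng = np.random.default_rng(8)
    names = tuple(f"p{i}" for i in range(10))
    subs = []
    for _ in range(200):
        sub = sc.Submission(
            values={n: rng.lognormal() for n in names}
        )
        sub.prediction_error = rng.lognormal()
        subs.append(sub)
    out = sc.parameter_error_correlation(subs, names)
    assert (np.abs(out["rho"]) < 0.2).mean() >= 0.95


def test_parameter_error_correlation_undefined():
    subs = [
        sc.Submission(values={"a": 1.0}, prediction_error=1.0),
        sc.Submission(values={"a": 2.0}, prediction_error=2.0),
    ]
    out = sc.parameter_error_correlation(subs, ("a",))
    assert out.attrs["undefined"]


# ---------------------------------------------------------------------------
# batch scoring round trip


def test_score_submissions_leaderboard(pkg):
    truth = pkg.reveal_truth()
    names = pkg.unknowns.names
    rng = np.random.default_rng(2)
    subs = []
    for k, spread in enumerate((0.0, 0.1, 0.5)):
        values = {
            n: truth.value(n) * math.exp(rng.normal(0, spread)) for n in names
        }
        sub = sc.Submission(values=values, team=f"team{k}")
        sub.predicted_means = pkg.mutant_bundle.means * (
            1 + rng.normal(0, 0.01 * (k + spread), size=pkg.mutant_bundle.M)
        )
        subs.append(sub)
    reports = sc.score_submissions(
        subs, truth, names, bundle_true=pkg.mutant_bundle, n_meta=300, seed=4
    )
    board = sc.leaderboard(reports)
    assert list(board.columns) == [
        "team", "e_param", "e_predict", "p_param", "p_predict", "s",
    ]
    exact = next(r for r in reports if r.team == "team0")
    assert exact.e_param == 0.0
    assert all(0 < r.p_param <= 1 for r in reports)
    for r in reports:
        assert math.isclose(
            r.s, -math.log(r.p_param) - math.log(r.p_predict), abs_tol=1e-12
        )
    # the exact submission cannot rank below a heavily-spread one on e_param
    assert exact.e_param <= min(r.e_param for r in reports)
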