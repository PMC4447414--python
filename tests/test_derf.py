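"""DE mutation, median acceptance, PCA basis, forests, and the full search."""

import numpy as np
import pytest

from wcbench import derf
from wcbench import toycell as tc

LO, HI = derf.DEFAULT_BOUNDS


def _evaluated(x, err, birth=0, provenance="init"):
    ind = derf.Individual(np.asarray(x, dtype=float), provenance, birth=birth)
    ind.set_error(err)
    return ind


class _StubRng:
    """Fixes the p/q/r draw order and F for hand-arithmetic checks."""

    def __init__(self, order, f):
        self.order = order
        self.f = f

    def choice(self, n, size, replace):
        return np.array(self.order)

    def uniform(self, lo, hi):
        return self.f


def test_init_population_size_bounds_determinism():
    config = derf.DEConfig(seed=0)
    pop = derf.init_population(config, n_dims=7)
    assert len(pop) == 200
    for ind in pop:
        assert np.all(ind.x >= LO) and np.all(ind.x <= HI)
        assert ind.provenance == "init" and not ind.evaluated
    again = derf.init_population(config, n_dims=7)
    assert all(np.array_equal(a.x, b.x) for a, b in zip(pop, again))


def test_de_propose_hand_arithmetic():
    pop = [
        _evaluated([1.0, 1.0], 0.5),
        _evaluated([1.5, 1.0], 0.1),
        _evaluated([0.5, 1.0], 0.9),
    ]
    config = derf.DEConfig(f_range=(0.5, 0.5))
    cand = derf.de_propose(pop, _StubRng([0, 1, 2], 0.5), config)
    # x_q (err 0.1) minus x_r (err 0.9): (1,1) + 0.5 * ((1.5,1) - (0.5,1))
    assert np.allclose(cand.x, [1.5, 1.0])
    assert cand.provenance == "de"
    # q/r swap when the lower-error individual was drawn second
    cand = derf.de_propose(pop, _StubRng([0, 2, 1], 0.5), config)
    assert np.allclose(cand.x, [1.5, 1.0])


def test_de_propose_zero_difference_and_clamp():
    same = [_evaluated([0.8, 0.3], 0.1 * i) for i in range(3)]
    config = derf.DEConfig(f_range=(0.2, 1.0))
    cand = derf.de_propose(same, np.random.default_rng(0), config)
    assert np.allclose(cand.x, [0.8, 0.3])
    pop = [
        _evaluated([1.9, 0.07], 0.5),
        _evaluated([1.9, 0.07], 0.1),
        _evaluated([0.1, 1.9], 0.9),
    ]
    cand = derf.de_propose(pop, _StubRng([0, 1, 2], 1.0), config)
    assert cand.x[0] == HI and cand.x[1] == LO  # exact clamp at the bounds
    with pytest.raises(tc.ContractError):
        derf.de_propose(same[:2], np.random.default_rng(0), config)


def test_error_immutable():
    ind = _evaluated([1.0], 0.5)
    with pytest.raises(tc.ContractError):
        ind.set_error(0.1)


def test_accept_median_rule():
    config = derf.DEConfig(population_cap=4)
    pop = [_evaluated([1.0], e, birth=i) for i, e in enumerate((0.1, 0.2, 0.3, 0.4))]
    median = derf.population_median(pop)  # 0.25

    above = derf.Individual(np.array([1.1]), "de")
    ok, err = derf.accept(pop, above, lambda x: 0.5, config)
    assert not ok and len(pop) == 4

    exactly = derf.Individual(np.array([1.2]), "de")
    ok, _ = derf.accept(pop, exactly, lambda x: median, config)
    assert not ok  # strict inequality

    below = derf.Individual(np.array([1.3]), "de")
    ok, _ = derf.accept(pop, below, lambda x: 0.05, config)
    assert ok and len(pop) == 4  # cap held: worst (0.4) evicted
    assert max(ind.error for ind in pop) == 0.3


def test_accept_eval_failure_discards():
    config = derf.DEConfig()
    pop = [_evaluated([1.0], e) for e in (0.1, 0.2, 0.3)]
    trace = []

    def broken(x):
        raise RuntimeError("boom")

    ok, err = derf.accept(pop, derf.Individual(np.array([1.0]), "de"), broken,
                          config, trace)
    assert not ok and np.isnan(err) and len(pop) == 3
    assert "boom" in trace[0]["note"]


def test_feature_basis_rank_one():
    rng = np.random.default_rng(0)
    direction = rng.normal(size=6)
    X = np.outer(rng.normal(size=30), direction) + 5.0
    config = derf.DEConfig(pca_min_components=1, pca_standardize=False)
    basis = derf.fit_feature_basis(X, config)
    assert basis.n_components == 1
    assert basis.explained_fractions[0] == pytest.approx(1.0)


def test_feature_basis_isotropic_component_count():
    """Isotropic data: the retained count at the 40% target matches an
    independent eigenvalue-spectrum computation (sample eigenvalues of
    isotropic noise are inflated at the top, so the count falls below the
    naive 0.4 * d)."""
    rng = np.random.default_rng(1)
    X = rng.normal(size=(500, 50))
    config = derf.DEConfig(pca_min_components=1, pca_standardize=False)
    basis = derf.fit_feature_basis(X, config)
    # oracle: eigendecompose the sample covariance directly
    Xc = X - X.mean(axis=0)
    eig = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
    frac = np.cumsum(eig) / eig.sum()
    expected = int(np.searchsorted(frac, 0.40) + 1)
    assert abs(basis.n_components - expected) <= 2
    assert expected < 20  # top-eigenvalue inflation is real at n=500, d=50


def test_feature_basis_projection_roundtrip():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(40, 8))
    config = derf.DEConfig(pca_min_components=8, pca_max_components=8)
    basis = derf.fit_feature_basis(X, config)
    v = X[3]
    back = basis.reconstruct(basis.project(v))[0]
    assert np.allclose(back, v, atol=1e-8)


def test_feature_basis_degenerate():
    with pytest.raises(derf.DegenerateBasisError):
        derf.fit_feature_basis(np.ones((5, 3)), derf.DEConfig())


def test_train_rf_constant_targets():
    rng = np.random.default_rng(3)
    F = rng.normal(size=(30, 4))
    Y = np.full((30, 2), 0.7)
    state = derf.train_rf(F, Y, derf.DEConfig(), seed=0)
    pred = state.predict(rng.normal(size=4))
    assert np.allclose(pred, 0.7)


def test_train_rf_linear_signal_vs_permuted_null():
    rng = np.random.default_rng(4)
    F = rng.normal(size=(500, 5))
    y = F @ np.array([1.0, -2.0, 0.5, 0.0, 3.0])
    config = derf.DEConfig(rf_trees=50)
    state = derf.train_rf(F, y[:, None], config, seed=0)
    assert state.oob_r2[0] >= 0.8
    null = derf.train_rf(F, rng.permutation(y)[:, None], config, seed=0)
    assert null.oob_r2[0] <= 0.1


def test_train_rf_too_few_rows():
    with pytest.raises(tc.ContractError):
        derf.train_rf(np.ones((4, 2)), np.ones((4, 1)), derf.DEConfig())


class _ConstantForest:
    def __init__(self, value):
        self.value = value

    def predict(self, Z):
        return np.full(len(Z), self.value)


def test_rf_propose_fixed_point_and_clamp():
    best = _evaluated([0.8, 1.2], 0.1)
    best.phenotype = np.array([1.0, 2.0, 3.0])
    pop = [best, _evaluated([1.0, 1.0], 0.5), _evaluated([1.1, 1.0], 0.7)]
    basis = derf.FeatureBasis(
        center=np.zeros(3),
        scale=np.ones(3),
        axes=np.eye(3)[:2],
        explained_fractions=np.array([0.5, 0.3]),
        n_components=2,
        target_met=True,
    )
    config = derf.DEConfig()
    state = derf.RFEnsembleState(
        forests=[_ConstantForest(0.8), _ConstantForest(1.2)],
        n_rows=10,
        oob_r2=np.ones(2),
    )
    cand = derf.rf_propose(state, pop, basis, config)
    assert np.allclose(cand.x, best.x)  # forests reproducing best: fixed point
    assert cand.provenance == "rf"

    wild = derf.RFEnsembleState(
        forests=[_ConstantForest(5.0), _ConstantForest(0.001)],
        n_rows=10,
        oob_r2=np.ones(2),
    )
    cand = derf.rf_propose(wild, pop, basis, config)
    assert cand.x[0] == HI and cand.x[1] == LO


def test_run_sphere_convergence_single_seed():
    target = np.full(5, 0.9)
    cost = lambda x: float(np.sum((x - target) ** 2))
    result = derf.run(cost, derf.DEConfig(budget=4000, seed=0), n_dims=5)
    assert result.best.error <= 1e-2
    assert result.n_evaluations == 4000
    # best-ever error is non-increasing along the trace
    errors = result.trace["error"].to_numpy()
    running = np.fmin.accumulate(errors)
    assert result.best.error == running[-1]
    assert np.all(np.diff(running) <= 0 + 1e-15)


def test_run_without_phenotypes_is_pure_de():
    cost = lambda x: float(np.sum(x**2))
    config = derf.DEConfig(budget=400, seed=1, rf_period=10**9)
    result = derf.run(cost, config, n_dims=3)
    assert not (result.trace["provenance"] == "rf").any()


def test_run_budget_contract():
    with pytest.raises(derf.BudgetError):
        derf.run(lambda x: 0.0, derf.DEConfig(budget=100), n_dims=2)


def test_run_rf_epochs_with_phenotypes():
    """A cost that exposes phenotypes triggers RF epochs, and every accepted
    candidate was strictly below the median at proposal time."""
    rng = np.random.default_rng(0)
    W = rng.normal(size=(12, 4))
    target = np.full(4, 0.9)

    def cost(x):
        phenotype = W @ x
        return float(np.sum((x - target) ** 2)), phenotype

    config = derf.DEConfig(budget=800, seed=2, rf_period=200, rf_proposals=3,
                           pca_min_components=4)
    result = derf.run(cost, config, n_dims=4)
    assert (result.trace["provenance"] == "rf").sum() > 0
    post_init = result.trace[np.isfinite(result.trace["median"])]
    accepted = post_init[post_init["accepted"]]
    assert (accepted["error"] < accepted["median"]).all()
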