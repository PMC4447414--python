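"""Hybrid differential-evolution / random-forest parameter search.

Individuals are multiplicative fold-change vectors over the unknown
parameters, bounded coordinate-wise to [0.066, 1.906].  The search
alternates two moves:

* **exploration** -- DE mutation without crossover: draw three distinct
  evaluated individuals, order the difference pair so the lower-error one is
  ``x_q``, and propose ``x_new = x_p + F (x_q - x_r)`` with ``F`` uniform in
  [0.2, 1]; the proposal is clamped to the bounds and accepted only if its
  prediction error is strictly below the current population median;

* **exploitation** -- periodically, all evaluated phenotype vectors are
  reduced by PCA to the leading components covering ~40% of the variance, a
  regression forest per unknown parameter is trained to map reduced
  phenotype -> fold change, and a proposal is built by rewriting the current
  best individual coordinate-by-coordinate with the forests' predictions.
  The proposal passes through the same median-acceptance gate.

The population would grow without bound under pure insertion, so a cap with
worst-error eviction is imposed.  All randomness flows from one seed through
named substreams so traces are replayable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor

from .toycell import ContractError, as_seed_sequence

DEFAULT_BOUNDS = (0.066, 1.906)
DEFAULT_F_RANGE = (0.2, 1.0)


class DegenerateBasisError(RuntimeError):
    """The phenotype matrix is constant; no principal axes exist."""


class BudgetError(RuntimeError):
    """The evaluation budget cannot cover the initial population."""


@dataclass(frozen=True)
class DEConfig:
    population_size: int = 200
    f_range: tuple = DEFAULT_F_RANGE
    bounds: tuple = DEFAULT_BOUNDS
    budget: int = 5000
    population_cap: int = 80
    rf_period: int = 300          # evaluations between RF injection epochs
    rf_proposals: int = 5
    pca_variance_target: float = 0.40
    pca_min_components: int = 24  # keep "several dozen" axes even when the
    pca_max_components: int = 50  # variance target is met by very few
    pca_standardize: bool = True
    rf_trees: int = 25
    rf_min_rows: int = 10
    rf_max_rows: int = 600        # train on the lowest-error rows only
    keep_rejected: bool = True    # rejected phenotypes still train the forests
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 4:
            raise ContractError("population size must be >= 4 (DE needs p,q,r)")
        lo, hi = self.bounds
        if not (0 < lo < hi):
            raise ContractError("bounds must satisfy 0 < low < high")
        flo, fhi = self.f_range
        if not (0 < flo <= fhi):
            raise ContractError("F range must be positive and ordered")


class Individual:
    """A bounded fold-change vector with an immutable, late-bound error."""

    __slots__ = ("x", "_error", "provenance", "birth", "phenotype")

    def __init__(self, x, provenance: str, birth: int = 0):
        self.x = np.asarray(x, dtype=float)
        self._error = None
        self.provenance = provenance
        self.birth = birth
        self.phenotype = None

    @property
    def error(self):
        return self._error

    def set_error(self, value: float):
        if self._error is not None:
            raise ContractError("individual error is immutable once set")
        self._error = float(value)

    @property
    def evaluated(self) -> bool:
        return self._error is not None

    def __repr__(self):
        return (
            f"Individual({self.provenance}, err={self._error}, "
            f"x={np.array2string(self.x, precision=3)})"
        )


def clamp(x: np.ndarray, bounds) -> np.ndarray:
    return np.clip(x, bounds[0], bounds[1])


def init_population(config: DEConfig, n_dims: int, seed=None) -> list:
    """Population of log-uniform draws over the bounds, tagged ``init``."""
    rng = np.random.default_rng(
        as_seed_sequence(config.seed if seed is None else seed)
    )
    lo, hi = np.log(config.bounds[0]), np.log(config.bounds[1])
    return [
        Individual(np.exp(rng.uniform(lo, hi, size=n_dims)), "init", birth=i)
        for i in range(config.population_size)
    ]


def de_propose(pop, rng: np.random.Generator, config: DEConfig) -> Individual:
    """One DE mutation: ``x_new = x_p + F (x_q - x_r)`` with
    ``error(x_q) < error(x_r)`` (ties keep the draw order), no crossover,
    coordinates clamped to the bounds."""
    evaluated = [ind for ind in pop if ind.evaluated]
    if len(evaluated) < 3:
        raise ContractError("DE mutation needs >= 3 evaluated individuals")
    i_p, i_q, i_r = rng.choice(len(evaluated), size=3, replace=False)
    x_p, x_q, x_r = evaluated[i_p], evaluated[i_q], evaluated[i_r]
    if x_r.error < x_q.error:
        x_q, x_r = x_r, x_q
    F = rng.uniform(*config.f_range)
    return Individual(clamp(x_p.x + F * (x_q.x - x_r.x), config.bounds), "de")


def population_median(pop) -> float:
    errors = [ind.error for ind in pop if ind.evaluated]
    if not errors:
        raise ContractError("population has no evaluated individuals")
    return float(np.median(errors))


def accept(pop, candidate: Individual, eval_fn, config: DEConfig, trace=None):
    """Evaluate the candidate once and insert it iff its error is strictly
    below the current population median; evict the worst member (ties ->
    oldest) when the cap is exceeded.  Returns (accepted, error)."""
    if candidate.evaluated:
        raise ContractError("candidate must be unevaluated")
    median = population_median(pop)
    try:
        result = eval_fn(candidate.x)
    except Exception as exc:  # evaluation failure: discard, budget spent
        if trace is not None:
            trace.append(
                {
                    "error": math.nan,
                    "provenance": candidate.provenance,
                    "accepted": False,
                    "median": median,
                    "note": f"eval failed: {exc}",
                }
            )
        return False, math.nan
    if isinstance(result, tuple):
        err, phenotype = result
        if phenotype is not None:
            candidate.phenotype = np.asarray(phenotype, dtype=float)
    else:
        err = result
    candidate.set_error(err)
    accepted = err < median
    if accepted:
        pop.append(candidate)
        while len(pop) > config.population_cap:
            worst = max(pop, key=lambda ind: (ind.error, -ind.birth))
            pop.remove(worst)
    if trace is not None:
        trace.append(
            {
                "error": err,
                "provenance": candidate.provenance,
                "accepted": accepted,
                "median": median,
                "note": "",
            }
        )
    return accepted, err


# ---------------------------------------------------------------------------
# random-forest exploitation


@dataclass
class FeatureBasis:
    """Centered (optionally column-standardized) orthonormal principal axes
    of the phenotype measurements."""

    center: np.ndarray
    scale: np.ndarray                # per-column divisor (1s when unscaled)
    axes: np.ndarray                 # (n_components, n_features)
    explained_fractions: np.ndarray
    n_components: int
    target_met: bool

    def project(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return ((X - self.center) / self.scale) @ self.axes.T

    def reconstruct(self, Z) -> np.ndarray:
        return (np.atleast_2d(Z) @ self.axes) * self.scale + self.center


def fit_feature_basis(phenotypes: np.ndarray, config: DEConfig) -> FeatureBasis:
    """Leading principal axes until cumulative explained variance reaches the
    target (default 40%) or the component cap, whichever comes first.

    Measurement columns mix very different natural scales (molecule counts,
    masses, event times), so with ``config.pca_standardize`` (the default)
    columns are divided by their standard deviation first -- otherwise the
    basis would be dominated by the largest-count data classes.
    """
    X = np.asarray(phenotypes, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ContractError("need at least two phenotype rows")
    if np.allclose(X, X[0]):
        raise DegenerateBasisError("constant phenotype matrix")
    if config.pca_standardize:
        sd = X.std(axis=0)
        scale = np.where(sd > 0, sd, 1.0)
    else:
        scale = np.ones(X.shape[1])
    center = X.mean(axis=0)
    Xs = (X - center) / scale
    max_comp = min(config.pca_max_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=max_comp, svd_solver="full")
    pca.fit(Xs)
    frac = pca.explained_variance_ratio_
    cum = np.cumsum(frac)
    k = int(np.searchsorted(cum, config.pca_variance_target) + 1)
    k = min(max(k, config.pca_min_components), max_comp)
    return FeatureBasis(
        center=center,
        scale=scale,
        axes=pca.components_[:k],
        explained_fractions=frac[:k],
        n_components=k,
        target_met=bool(cum[k - 1] >= config.pca_variance_target),
    )


@dataclass
class RFEnsembleState:
    """One regression forest per unknown parameter, reduced phenotype ->
    fold change, with out-of-bag scores."""

    forests: list
    n_rows: int
    oob_r2: np.ndarray

    @property
    def n_params(self):
        return len(self.forests)

    def predict(self, features: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(features)
        return np.array([f.predict(Z)[0] for f in self.forests])


def train_rf(
    features: np.ndarray, targets: np.ndarray, config: DEConfig, seed=0
) -> RFEnsembleState:
    """Train per-parameter regression forests on (reduced phenotype, fold
    change) rows, recording out-of-bag R^2 per parameter."""
    F = np.asarray(features, dtype=float)
    Y = np.atleast_2d(np.asarray(targets, dtype=float))
    if F.shape[0] != Y.shape[0]:
        raise ContractError("feature/target row mismatch")
    if F.shape[0] < config.rf_min_rows:
        raise ContractError(
            f"need >= {config.rf_min_rows} training rows, got {F.shape[0]}"
        )
    rng = np.random.default_rng(as_seed_sequence(seed))
    forests = []
    oob = []
    for j in range(Y.shape[1]):
        y = Y[:, j]
        forest = RandomForestRegressor(
            n_estimators=config.rf_trees,
            oob_score=True,
            bootstrap=True,
            random_state=int(rng.integers(0, 2**31)),
            n_jobs=1,
        )
        with warnings.catch_warnings():
            # few-row fits can leave some samples without OOB predictions
            warnings.simplefilter("ignore")
            forest.fit(F, y)
            oob.append(forest.oob_score_ if np.ptp(y) > 0 else 1.0)
        forests.append(forest)
    return RFEnsembleState(forests=forests, n_rows=F.shape[0], oob_r2=np.array(oob))


def rf_propose(
    state: RFEnsembleState,
    pop,
    basis: FeatureBasis,
    config: DEConfig,
    at_phenotype: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> Individual:
    """Rewrite the best individual coordinate-by-coordinate with the forests'
    predictions, clamped to the bounds.

    The forests are evaluated at the reduced ``at_phenotype`` when given
    (typically the observed target phenotype, turning the ensemble into a
    direct inverse estimator); otherwise at the best individual's own
    reduced phenotype.  With ``rng`` the per-coordinate prediction is drawn
    from a single random tree instead of the forest mean, so repeated calls
    seed the population with distinct draws from the estimate's spread.
    """
    if state is None or not state.forests:
        raise ContractError("untrained RF state")
    evaluated = [ind for ind in pop if ind.evaluated]
    if not evaluated:
        raise ContractError("population has no evaluated individuals")
    best = min(evaluated, key=lambda ind: ind.error)
    if at_phenotype is None:
        if best.phenotype is None:
            raise ContractError("best individual carries no phenotype")
        at_phenotype = best.phenotype
    z = basis.project(at_phenotype)[0]
    x = best.x.copy()
    for j in range(state.n_params):  # fixed coordinate order
        if rng is None:
            x[j] = state.forests[j].predict(z[None, :])[0]
        else:
            # sample one tree per coordinate: a draw from the forest's
            # prediction spread, giving distinct population seeds
            trees = state.forests[j].estimators_
            x[j] = trees[rng.integers(len(trees))].predict(z[None, :])[0]
    return Individual(clamp(x, config.bounds), "rf")


# ---------------------------------------------------------------------------
# the full search


@dataclass
class RunResult:
    best: Individual
    trace: pd.DataFrame
    population: list
    n_evaluations: int


def run(
    eval_fn,
    config: DEConfig,
    n_dims: int = 30,
    target_phenotype: np.ndarray | None = None,
) -> RunResult:
    """Run the full DE-RF search under an evaluation budget.

    ``eval_fn(x)`` returns either a scalar error or ``(error, phenotype)``;
    without phenotypes the RF epochs are skipped and the search reduces to
    pure DE.  When ``target_phenotype`` (e.g. the mutant bundle means) is
    given, RF proposals are the forests' predictions at the observed
    phenotype; otherwise at the best individual's phenotype.  The trace
    records one row per evaluation (error, provenance, acceptance,
    population median at proposal time).
    """
    if config.budget < config.population_size:
        raise BudgetError("budget cannot cover the initial population")
    ss = as_seed_sequence(config.seed)
    s_init, s_de, s_rf, s_pca = ss.spawn(4)
    rng_de = np.random.default_rng(s_de)
    rng_rf = np.random.default_rng(s_pca)

    pop = init_population(config, n_dims, seed=s_init)

    trace = []
    archive = []  # every evaluated individual (for RF training)
    n_eval = 0
    best = None

    def evaluate_initial(ind):
        nonlocal n_eval, best
        result = eval_fn(ind.x)
        if isinstance(result, tuple):
            err, phenotype = result
            if phenotype is not None:
                ind.phenotype = np.asarray(phenotype, dtype=float)
        else:
            err = result
        ind.set_error(err)
        n_eval += 1
        archive.append(ind)
        if best is None or err < best.error:
            best = ind
        trace.append(
            {
                "error": err,
                "provenance": ind.provenance,
                "accepted": True,
                "median": math.nan,
                "note": "",
            }
        )

    for ind in pop:
        evaluate_initial(ind)

    state = None
    basis = None
    next_rf = config.population_size + config.rf_period
    while n_eval < config.budget:
        do_rf = (
            n_eval >= next_rf
            and any(ind.phenotype is not None for ind in archive)
        )
        if do_rf:
            next_rf += config.rf_period
            rows = [
                ind
                for ind in (archive if config.keep_rejected else pop)
                if ind.phenotype is not None and ind.evaluated
            ]
            if len(rows) > config.rf_max_rows:
                rows = sorted(rows, key=lambda ind: ind.error)[: config.rf_max_rows]
            if len(rows) >= config.rf_min_rows:
                X = np.stack([ind.phenotype for ind in rows])
                try:
                    basis = fit_feature_basis(X, config)
                except DegenerateBasisError:
                    basis = None
                if basis is not None:
                    F = basis.project(X)
                    Y = np.stack([ind.x for ind in rows])
                    state = train_rf(F, Y, config, seed=s_rf)
                    for k in range(config.rf_proposals):
                        if n_eval >= config.budget:
                            break
                        cand = rf_propose(
                            state,
                            pop,
                            basis,
                            config,
                            at_phenotype=target_phenotype,
                            rng=None if k == 0 else rng_rf,
                        )
                        accepted, err = accept(pop, cand, eval_fn, config, trace)
                        n_eval += 1
                        if cand.evaluated:
                            archive.append(cand)
                            if err < best.error:
                                best = cand
                    continue
        cand = de_propose(pop, rng_de, config)
        accepted, err = accept(pop, cand, eval_fn, config, trace)
        n_eval += 1
        if cand.evaluated:
            archive.append(cand)
            if err < best.error:
                best = cand

    trace_df = pd.DataFrame(trace)
    trace_df.index.name = "evaluation"
    return RunResult(best=best, trace=trace_df, population=pop, n_evaluations=n_eval)
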