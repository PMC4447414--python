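"""Self-contained correctness checks over the whole pipeline.

Each ``check_*`` function recomputes a structural or statistical property of
the package from scratch and returns a plain dict with a ``passed`` flag and
the measured values, so the same logic backs the test suite, the
``wcbench acceptance`` subcommand, and the reproduction script.
"""

from __future__ import annotations

import math

import numpy as np

from . import challenge as ch
from . import derf
from . import reduced as rd
from . import scoring as sc
from . import toycell as tc

DEFAULT_PACKAGE_SEED = 11


def check_compounding(
    per_step_increase: float = 0.019, n_steps: int = 15
) -> dict:
    """The per-step doubling-time increase compounds over the default step
    count to the headline overall increase (rounds to 33%)."""
    total = (1.0 + per_step_increase) ** n_steps - 1.0
    percent = 100.0 * total
    return {
        "passed": round(percent) == 33,
        "per_step_percent": 100.0 * per_step_increase,
        "n_steps": n_steps,
        "total_percent": percent,
    }


def build_default_package(seed: int = DEFAULT_PACKAGE_SEED) -> ch.ChallengePackage:
    return ch.generate_challenge(tc.default_spec(), seed=seed)


def check_challenge_structure(pkg: ch.ChallengePackage) -> dict:
    """Default package counts: 15 modified parameters, 30 unknowns, 8 mutant
    data sets, 480 perturbation data sets, and a budget that rejects the
    51st distinct request."""
    truth = pkg.reveal_truth()
    n_modified = sum(
        1
        for n in truth.names
        if truth.value(n) != pkg.wildtype.value(n)
    )
    n_flagged = sum(pkg.unknowns.truth_flags().values())

    # spend the budget on distinct data sets, then check the hard stop
    # (on a fresh library view so the package itself is left untouched)
    library = ch.PerturbationLibrary(
        bundles=pkg.perturbations.bundles, budget=pkg.perturbations.budget
    )
    requests = [
        (cond, cls)
        for cond in library.conditions
        for cls in tc.DATA_CLASSES
    ]
    budget_before = library.budget
    for cond, cls in requests[:budget_before]:
        library.request(cond, cls)
    over_budget_rejected = False
    try:
        library.request(*requests[budget_before])
    except ch.BudgetExhaustedError:
        over_budget_rejected = True
    # duplicate requests stay free
    library.request(*requests[0])
    duplicate_free = library.budget == 0

    result = {
        "n_modified": n_modified,
        "n_modified_flagged": n_flagged,
        "n_unknowns": len(pkg.unknowns),
        "n_mutant_data_sets": pkg.N_MUTANT_DATA_SETS,
        "n_perturbation_data_sets": pkg.perturbations.n_data_sets,
        "budget": budget_before,
        "over_budget_rejected": over_budget_rejected,
        "duplicate_free": duplicate_free,
    }
    result["passed"] = (
        n_modified == 15
        and n_flagged == 15
        and result["n_unknowns"] == 30
        and result["n_mutant_data_sets"] == 8
        and result["n_perturbation_data_sets"] == 480
        and budget_before == 50
        and over_budget_rejected
        and duplicate_free
    )
    return result


def check_scoring_identities(seed: int = 0) -> dict:
    """Closed-form identities of the scoring statistics, plus p-value
    monotonicity and agreement with exhaustive enumeration on a tiny pool."""
    checks = {}
    checks["eq1_truth_zero"] = sc.param_error([2.0, 3.0], [2.0, 3.0]) == 0.0
    checks["eq1_tenfold_one"] = abs(sc.param_error([10.0], [1.0]) - 1.0) < 1e-12
    checks["eq2_two_sigma_four"] = (
        abs(sc.prediction_error([3.0], [1.0], [1.0]) - 4.0) < 1e-12
    )
    checks["eq3_unit_zero"] = sc.overall_score(1.0, 1.0) == 0.0
    checks["eq3_exp_five"] = (
        abs(sc.overall_score(math.exp(-2.0), math.exp(-3.0)) - 5.0) < 1e-12
    )

    # monotonicity on a shared pool
    rng = np.random.default_rng(seed)
    pool = rng.lognormal(0.0, 0.5, size=(6, 4))
    truth = np.ones(4)
    err_fn = lambda v: sc.param_error(v, truth)
    errors = sorted(err_fn(pool[i]) for i in range(6))
    ps = [
        sc.empirical_pvalue(e, pool, err_fn, n_meta=500, seed=seed)
        for e in errors
    ]
    checks["pvalue_monotone"] = all(a <= b for a, b in zip(ps, ps[1:]))

    # exhaustive enumeration: 2 one-coordinate submissions -> 2 meta vectors
    pool2 = np.array([[1.0], [10.0]])
    err_fn2 = lambda v: sc.param_error(v, np.array([1.0]))
    p_lo = sc.empirical_pvalue(0.0, pool2, err_fn2, n_meta=2000, seed=seed)
    # enumeration: meta errors are {0, 1} equally likely; e.g. observed=0
    # catches all meta errors <= 0, expected fraction 1/2
    expected = (1 + 2000 * 0.5) / (2000 + 1)
    checks["pvalue_enumeration"] = abs(p_lo - expected) < 0.05
    return {"passed": all(checks.values()), **checks}


def sphere_reference_run(seed: int, budget: int = 5000, n_dims: int = 5):
    """One DE run on a sphere cost centred at a seeded in-bounds point,
    with bound accounting on every evaluated candidate."""
    lo, hi = derf.DEFAULT_BOUNDS
    rng = np.random.default_rng(10_000 + seed)
    target = np.exp(rng.uniform(np.log(lo), np.log(hi), n_dims))
    violations = 0

    def cost(x):
        nonlocal violations
        if np.any(x < lo - 1e-12) or np.any(x > hi + 1e-12):
            violations += 1
        return float(np.sum((x - target) ** 2))

    config = derf.DEConfig(budget=budget, seed=seed)
    result = derf.run(cost, config, n_dims=n_dims)
    return result, violations


def check_derf_properties(base_seed: int = 0, n_seeds: int = 10) -> dict:
    """Bound invariance, strict below-median acceptance replayed from the
    trace, and sphere convergence (best error <= 1e-2 in >= 9/10 seeds)."""
    converged = 0
    total_violations = 0
    median_ok = True
    rf_free_ok = True
    for k in range(n_seeds):
        result, violations = sphere_reference_run(base_seed + k)
        total_violations += violations
        if result.best.error <= 1e-2:
            converged += 1
        trace = result.trace
        post_init = trace[np.isfinite(trace["median"])]
        accepted = post_init[post_init["accepted"]]
        if not (accepted["error"] < accepted["median"]).all():
            median_ok = False
        if (trace["provenance"] == "rf").any():
            rf_free_ok = False  # scalar cost: no phenotypes, no RF epochs
    return {
        "passed": (
            converged >= 9
            and total_violations == 0
            and median_ok
            and rf_free_ok
        ),
        "converged": converged,
        "n_seeds": n_seeds,
        "bound_violations": total_violations,
        "median_acceptance_replayed": median_ok,
        "no_rf_without_phenotypes": rf_free_ok,
    }


def check_reduced_recovery(pkg: ch.ChallengePackage) -> dict:
    """Noise-free identifiability (all 30 unknowns within 1% relative from a
    deterministic-mode bundle) and stochastic accuracy (median relative
    error <= 15% from the released 32-cell bundle)."""
    truth = pkg.reveal_truth()
    det_bundle = tc.simulate_population(
        pkg.spec, truth, n_cells=2, mode="deterministic"
    )
    _, det_sub = rd.fit_reduced(pkg, bundle=det_bundle)
    det_errors = np.array(
        [
            abs(det_sub.values[n] / truth.value(n) - 1.0)
            for n in pkg.unknowns.names
        ]
    )
    _, stoch_sub = rd.fit_reduced(pkg)
    stoch_errors = np.array(
        [
            abs(stoch_sub.values[n] / truth.value(n) - 1.0)
            for n in pkg.unknowns.names
        ]
    )
    return {
        "passed": (
            float(det_errors.max()) <= 0.01
            and float(np.median(stoch_errors)) <= 0.15
        ),
        "deterministic_max_rel_error": float(det_errors.max()),
        "stochastic_median_rel_error": float(np.median(stoch_errors)),
        "n_unknowns": len(pkg.unknowns),
    }


def derf_direction_run(pkg: ch.ChallengePackage, seed: int, budget: int = 3000):
    """One DE-RF run on the deterministic toy challenge; returns the number
    of modified parameters whose estimated log-fold-change sign matches the
    truth."""
    truth = pkg.reveal_truth()
    names = pkg.unknowns.names
    true_folds = np.array(
        [truth.value(n) / pkg.wildtype.value(n) for n in names]
    )
    flags = pkg.unknowns.truth_flags()
    modified = [i for i, n in enumerate(names) if flags[n]]
    evaluator = ch.PredictionEvaluator(pkg, mode="deterministic")
    config = derf.DEConfig(budget=budget, seed=seed)
    result = derf.run(
        evaluator,
        config,
        n_dims=len(names),
        target_phenotype=pkg.mutant_bundle.means,
    )
    est = result.best.x
    n_correct = sum(
        1
        for i in modified
        if np.sign(np.log(est[i])) == np.sign(np.log(true_folds[i]))
    )
    return n_correct, len(modified), result


def check_derf_direction_recovery(
    pkg: ch.ChallengePackage, n_seeds: int = 10, base_seed: int = 0
) -> dict:
    """Direction recovery: >= 12 of 15 modified parameters get the right
    sign in >= 7 of 10 seeds."""
    per_seed = []
    for k in range(n_seeds):
        n_correct, n_modified, _ = derf_direction_run(pkg, base_seed + k)
        per_seed.append(n_correct)
    n_pass = sum(1 for s in per_seed if s >= 12)
    return {
        "passed": n_pass >= 7,
        "per_seed_correct": per_seed,
        "n_modified": n_modified,
        "seeds_passing": n_pass,
        "n_seeds": n_seeds,
    }


def run_all(seed: int = DEFAULT_PACKAGE_SEED, quick: bool = False) -> dict:
    """Run every check; ``quick`` trims the multi-seed suites to 3 seeds
    (exploratory use -- the full suite is the reference)."""
    pkg = build_default_package(seed)
    n_seeds = 3 if quick else 10
    report = {
        "compounding": check_compounding(),
        "challenge_structure": check_challenge_structure(pkg),
        "scoring_identities": check_scoring_identities(),
        "derf_properties": check_derf_properties(n_seeds=n_seeds),
        "reduced_recovery": check_reduced_recovery(pkg),
        "derf_direction_recovery": check_derf_direction_recovery(
            pkg, n_seeds=n_seeds
        ),
    }
    report["passed"] = all(v["passed"] for v in report.values() if isinstance(v, dict))
    return report
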