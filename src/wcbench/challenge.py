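"""Challenge construction: sensitivity-weighted mutant building, unknown-set
selection, perturbation-library generation, and budgeted data release.

The mutant strain is built iteratively: at each step the sensitivity of the
doubling time to every eligible parameter is estimated, the fold change each
parameter would need to lengthen the doubling time by a fixed per-step
fraction (default 1.9%) is planned, and one not-yet-modified parameter is
drawn with probability proportional to the magnitude of its planned log fold
change.  Compounding the per-step target over the default 15 steps yields the
overall ~33% doubling-time increase the challenge asks estimators to explain.

The resulting package discloses the wild-type parameters, a 32-cell mutant
data bundle, and the identities (not values) of 30 unknown parameters; the
mutant truth is sealed away from the estimator-facing interface.  A library
of 2-fold up/down perturbation bundles (8 cells each) is released one
(condition, data class) data set at a time under a 50-request budget.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import toycell as tc
from .toycell import (
    ContractError,
    DataSetBundle,
    ModelSpec,
    ParameterSet,
    PARAM_CLASSES,
)

LN2 = math.log(2.0)

DIRECTIONS = ("up", "down")
PERTURBATION_FOLD = 2.0


class SensitivityUndefinedError(RuntimeError):
    """A finite-difference endpoint failed to divide."""


class NoCandidateError(RuntimeError):
    """Every sensitivity fell below the floor; no step can be planned."""


class SelectionError(RuntimeError):
    """An unknown-set class pool is too small (strict mode)."""


class BudgetExhaustedError(RuntimeError):
    """The perturbation request budget has run out."""


class PerturbationLookupError(KeyError):
    """Requested condition or data class does not exist in the library."""


# ---------------------------------------------------------------------------
# sensitivity and step planning


def _doubling_time_at(spec, params, n_cells, seeds, mode):
    if mode == "deterministic":
        traj = tc.simulate_cell(spec, params, mode="deterministic")
        if not traj.divided:
            return None
        return traj.t_div
    times = []
    for s in seeds:
        traj = tc.simulate_cell(spec, params, seed=s, mode="stochastic")
        if traj.divided:
            times.append(traj.t_div)
    if not times:
        return None
    return float(np.mean(times))


def estimate_sensitivity(
    spec: ModelSpec,
    params: ParameterSet,
    name: str,
    n_cells: int = 8,
    rel_step: float = 0.05,
    seed=0,
    mode: str = "stochastic",
) -> float:
    """Central finite difference of ln(doubling time) w.r.t. ln(value).

    Both endpoints reuse the same per-cell seeds (common random numbers) so
    the stochastic estimate is a paired difference.  Binding probabilities
    are clipped at 1 on the upper endpoint and the log step adjusted
    accordingly, so the returned quantity is always a proper two-sided
    logarithmic derivative.
    """
    if name not in params:
        raise ContractError(f"unknown parameter {name!r}")
    if not (0.0 < rel_step <= 0.5):
        raise ContractError("rel_step must lie in (0, 0.5]")
    v = params.value(name)
    delta = math.log1p(rel_step)
    v_up = v * math.exp(delta)
    if params.pclass(name) == "binding_probability":
        v_up = min(v_up, 1.0)
    v_dn = v * math.exp(-delta)
    d_up = math.log(v_up / v)
    d_dn = delta
    if d_up <= 0:
        # parameter pinned at its upper bound: one-sided difference
        d_up = 0.0

    seeds = tc.as_seed_sequence(seed).spawn(n_cells)
    results = {}
    for label, val in (("up", v_up), ("down", v_dn)):
        t = _doubling_time_at(spec, params.with_value(name, val), n_cells, seeds, mode)
        if t is None:
            raise SensitivityUndefinedError(
                f"{label} endpoint of {name} failed to divide"
            )
        results[label] = t
    return math.log(results["up"] / results["down"]) / (d_up + d_dn)


def plan_step(
    sensitivities: dict,
    per_step_increase: float,
    floor: float = 1e-3,
    max_abs_log_fold: float = math.log(10.0),
) -> dict:
    """Fold change per parameter that would lengthen the doubling time by
    ``per_step_increase``, from first-order sensitivities.

    Parameters with |sensitivity| below ``floor`` are excluded (their planned
    fold change would be astronomically large); log fold changes are clipped
    to ``max_abs_log_fold``.
    """
    if per_step_increase <= 0:
        raise ContractError("per_step_increase must be positive")
    target = math.log1p(per_step_increase)
    plan = {}
    for name, s in sensitivities.items():
        if abs(s) < floor:
            continue
        logfold = float(np.clip(target / s, -max_abs_log_fold, max_abs_log_fold))
        plan[name] = math.exp(logfold)
    if not plan:
        raise NoCandidateError("all sensitivities below the floor")
    return plan


# ---------------------------------------------------------------------------
# mutant construction


@dataclass
class MutantStrain:
    """The built mutant: parameter set, modification list, and step log."""

    mutant: ParameterSet
    wildtype: ParameterSet
    modifications: list          # of (name, wt value, mutant value, fold)
    step_log: list               # of per-step dicts
    early_stop: bool = False

    @property
    def modified_names(self):
        return tuple(m[0] for m in self.modifications)

    def modification_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.modifications, columns=["name", "wildtype", "mutant", "fold"]
        )


def build_mutant(
    spec: ModelSpec,
    wildtype: ParameterSet | None = None,
    n_steps: int = 15,
    per_step_increase: float = 0.019,
    seed=0,
    sensitivity_mode: str = "deterministic",
    sensitivity_cells: int = 8,
    rel_step: float = 0.05,
    weighting: str = "fold",
    sensitivity_floor: float = 1e-3,
    max_abs_log_fold: float = math.log(10.0),
) -> MutantStrain:
    """Iteratively modify ``n_steps`` distinct parameters, each step drawn
    with probability proportional to |planned log fold change| (``weighting=
    'fold'``; ``'inverse'`` uses the reciprocal weights).

    Stops early only if the achieved doubling-time ratio already exceeds the
    compounded target ``(1 + per_step_increase) ** n_steps``.
    """
    if wildtype is None:
        wildtype = spec.wildtype
    if weighting not in ("fold", "inverse"):
        raise ContractError(f"unknown weighting {weighting!r}")
    ss = tc.as_seed_sequence(seed)
    pick_rng = np.random.default_rng(ss.spawn(1)[0])
    sens_seeds = ss.spawn(max(n_steps, 1))

    params = wildtype
    t_wt = tc.doubling_time(tc.simulate_cell(spec, wildtype, mode="deterministic"))
    target_ratio = (1.0 + per_step_increase) ** n_steps
    modifications = []
    step_log = []
    early_stop = False
    modified = set()

    for step in range(n_steps):
        eligible = [n for n in params.names if n not in modified]
        if n_steps > len(eligible) + len(modified):
            raise ContractError("n_steps exceeds the number of parameters")
        sens = {}
        for nm in eligible:
            try:
                sens[nm] = estimate_sensitivity(
                    spec,
                    params,
                    nm,
                    n_cells=sensitivity_cells,
                    rel_step=rel_step,
                    seed=sens_seeds[step],
                    mode=sensitivity_mode,
                )
            except SensitivityUndefinedError:
                continue
        try:
            plan = plan_step(
                sens,
                per_step_increase,
                floor=sensitivity_floor,
                max_abs_log_fold=max_abs_log_fold,
            )
        except NoCandidateError:
            if not modifications:
                raise
            raise NoCandidateError(
                f"eligible pool exhausted after {len(modifications)} steps"
            )

        # binding probabilities cannot exceed 1: clip the planned value and
        # drop parameters left with no room to move
        feasible = {}
        for nm, fold in plan.items():
            new_val = params.value(nm) * fold
            if params.pclass(nm) == "binding_probability":
                new_val = min(new_val, 1.0)
            eff_fold = new_val / params.value(nm)
            if abs(math.log(eff_fold)) > 1e-9:
                feasible[nm] = eff_fold
        if not feasible:
            raise NoCandidateError("no feasible candidate after clipping")

        names = sorted(feasible)
        w = np.array([abs(math.log(feasible[nm])) for nm in names])
        if weighting == "inverse":
            w = 1.0 / w
        chosen = names[pick_rng.choice(len(names), p=w / w.sum())]
        fold = feasible[chosen]
        old_val = params.value(chosen)
        new_val = old_val * fold
        params = params.with_value(chosen, new_val)
        modified.add(chosen)
        modifications.append((chosen, old_val, new_val, fold))

        t_now = tc.doubling_time(
            tc.simulate_cell(spec, params, mode="deterministic")
        )
        step_log.append(
            {
                "step": step,
                "chosen": chosen,
                "fold": fold,
                "sensitivity": sens.get(chosen),
                "weights": {nm: float(x) for nm, x in zip(names, w)},
                "doubling_time": t_now,
                "ratio": t_now / t_wt,
            }
        )
        if t_now / t_wt > target_ratio:
            early_stop = step < n_steps - 1
            break

    return MutantStrain(
        mutant=params,
        wildtype=wildtype,
        modifications=modifications,
        step_log=step_log,
        early_stop=early_stop,
    )


# ---------------------------------------------------------------------------
# unknown-set selection


@dataclass
class UnknownSet:
    """The parameter identities released to estimators: every modified name
    plus unmodified decoys of the same three classes.  Truth flags (modified
    yes/no) are held privately and only surfaced through ``truth_flags``,
    which scoring and analytics use; estimator-facing code sees names and
    classes only."""

    names: tuple
    classes: dict                     # name -> class
    _modified: frozenset = field(repr=False)
    redistributed: bool = False

    def __len__(self):
        return len(self.names)

    def truth_flags(self) -> dict:
        """Modified yes/no per name (scoring/analytics only)."""
        return {n: (n in self._modified) for n in self.names}

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"name": self.names, "class": [self.classes[n] for n in self.names]}
        )


def _proportional_counts(targets: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` over ``targets``."""
    if targets.sum() == 0:
        return np.zeros_like(targets, dtype=int)
    quota = targets / targets.sum() * total
    counts = np.floor(quota).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(quota - counts))
    for i in range(remainder):
        counts[order[i % len(order)]] += 1
    return counts


def select_unknowns(
    strain: MutantStrain,
    wildtype: ParameterSet | None = None,
    n_extra: int = 15,
    seed=0,
    strict: bool = False,
    reserve_binding: int = 1,
) -> UnknownSet:
    """Unknown set = modified names + ``n_extra`` unmodified names sampled to
    match the modified class proportions (largest-remainder rounding).

    ``reserve_binding`` binding probabilities are kept out of the unknown
    set as disclosed calibration anchors (the ChIP-seq inversion needs at
    least one).  When a class has fewer unmodified parameters than its
    proportional share, the shortfall is redistributed to classes with spare
    pool and the set is flagged ``redistributed``; ``strict=True`` raises
    instead.
    """
    if wildtype is None:
        wildtype = strain.wildtype
    modified = list(strain.modified_names)
    mod_counts = np.array(
        [
            sum(1 for n in modified if wildtype.pclass(n) == cls)
            for cls in PARAM_CLASSES
        ]
    )
    pools = {
        cls: sorted(
            n for n in wildtype.names_of_class(cls) if n not in set(modified)
        )
        for cls in PARAM_CLASSES
    }
    avail = np.array(
        [
            max(
                0,
                len(pools[cls])
                - (reserve_binding if cls == "binding_probability" else 0),
            )
            for cls in PARAM_CLASSES
        ]
    )
    if avail.sum() < n_extra:
        raise SelectionError(
            "not enough unmodified parameters to draw the extra set"
        )
    counts = _proportional_counts(mod_counts.astype(float), n_extra)
    short = counts - avail
    if np.any(short > 0):
        if strict:
            cls = PARAM_CLASSES[int(np.argmax(short))]
            raise SelectionError(
                f"class pool too small for proportional extras: {cls}"
            )
        deficit = int(np.clip(short, 0, None).sum())
        counts = np.minimum(counts, avail)
        spare = avail - counts
        # redistribute by largest spare, then class order
        while deficit > 0:
            j = int(np.argmax(spare))
            if spare[j] <= 0:
                raise SelectionError("no spare pool left during redistribution")
            counts[j] += 1
            spare[j] -= 1
            deficit -= 1
        redistributed = True
    else:
        redistributed = False

    rng = np.random.default_rng(tc.as_seed_sequence(seed))
    extras = []
    for cls, k in zip(PARAM_CLASSES, counts):
        pool = pools[cls]
        if k > 0:
            idx = rng.choice(len(pool), size=int(k), replace=False)
            extras.extend(pool[i] for i in sorted(idx))
    names = tuple(modified + extras)
    classes = {n: wildtype.pclass(n) for n in names}
    return UnknownSet(
        names=names,
        classes=classes,
        _modified=frozenset(modified),
        redistributed=redistributed,
    )


# ---------------------------------------------------------------------------
# perturbation library and package


@dataclass
class PerturbationLibrary:
    """2-fold up/down perturbation bundles for every unknown parameter,
    released one (condition, data class) data set at a time under a budget.

    Repeated requests for an already-released data set are free."""

    bundles: dict                     # (name, direction) -> DataSetBundle
    budget: int
    released: set = field(default_factory=set)

    @property
    def n_data_sets(self) -> int:
        return len(self.bundles) * len(tc.DATA_CLASSES)

    @property
    def conditions(self):
        return tuple(sorted(self.bundles))

    def request(self, condition, data_class: str) -> pd.DataFrame:
        name, direction = condition
        if (name, direction) not in self.bundles:
            raise PerturbationLookupError(
                f"no perturbation condition {(name, direction)!r}"
            )
        if data_class not in tc.DATA_CLASSES:
            raise PerturbationLookupError(f"unknown data class {data_class!r}")
        key = (name, direction, data_class)
        if key not in self.released:
            if self.budget <= 0:
                raise BudgetExhaustedError(
                    "perturbation request budget exhausted"
                )
            self.budget -= 1
            self.released.add(key)
        return self.bundles[(name, direction)].class_frame(data_class)


@dataclass
class ChallengePackage:
    """Everything the challenge releases, plus the sealed truth.

    Estimator-facing: ``spec`` (model structure and constants), disclosed
    ``wildtype`` values, the 32-cell ``mutant_bundle``, the ``unknowns``
    identities, and the budgeted ``perturbations`` library.  The sealed
    mutant parameter values are only reachable through ``reveal_truth()``,
    which scoring and analytics call.
    """

    spec: ModelSpec
    wildtype: ParameterSet
    mutant_bundle: DataSetBundle
    unknowns: UnknownSet
    perturbations: PerturbationLibrary
    master_seed: int
    _truth: ParameterSet = field(repr=False)

    N_MUTANT_DATA_SETS = len(tc.DATA_CLASSES)

    def reveal_truth(self) -> ParameterSet:
        """Sealed mutant parameter values (scoring/analytics only)."""
        if self._truth is None:
            raise ContractError(
                "package was loaded without the sealed truth "
                "(ChallengePackage.load(..., with_truth=True))"
            )
        return self._truth

    def request_perturbation(self, condition, data_class):
        return self.perturbations.request(condition, data_class)

    def checksum(self) -> str:
        h = hashlib.md5()
        h.update(self.wildtype.values.tobytes())
        h.update(",".join(self.unknowns.names).encode())
        h.update(self.mutant_bundle.checksum().encode())
        for cond in self.perturbations.conditions:
            h.update(self.perturbations.bundles[cond].checksum().encode())
        return h.hexdigest()

    # -- directory serialization --------------------------------------------

    def save(self, path):
        if self._truth is None:
            raise ContractError("cannot save a package loaded without truth")
        os.makedirs(path, exist_ok=True)
        self.spec.save(os.path.join(path, "model_spec.json"))
        self.wildtype.to_tsv(os.path.join(path, "wildtype.tsv"))
        self.unknowns.as_frame().to_csv(
            os.path.join(path, "unknowns.tsv"), sep="\t", index=False
        )
        self.mutant_bundle.to_dir(os.path.join(path, "mutant"), write_cells=True)
        for (name, direction), bundle in sorted(self.perturbations.bundles.items()):
            bundle.to_dir(
                os.path.join(path, "perturbations", f"{name}_{direction}")
            )
        truth = self._truth.as_frame()
        truth["modified"] = [
            self.unknowns.truth_flags().get(n, False) for n in truth["name"]
        ]
        truth.to_csv(os.path.join(path, "truth.tsv.sealed"), sep="\t", index=False)
        manifest = {
            "master_seed": self.master_seed,
            "budget": self.perturbations.budget,
            "released": sorted(list(k) for k in self.perturbations.released),
            "checksum": self.checksum(),
            "n_perturbation_data_sets": self.perturbations.n_data_sets,
        }
        with open(os.path.join(path, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def load(cls, path, with_truth: bool = False) -> "ChallengePackage":
        """Load a package directory.

        ``with_truth=False`` (the estimator-facing default) never opens
        ``truth.tsv.sealed``; scoring and analytics pass ``with_truth=True``.
        """
        spec = ModelSpec.load(os.path.join(path, "model_spec.json"))
        wildtype = ParameterSet.from_tsv(os.path.join(path, "wildtype.tsv"))
        unk_df = pd.read_csv(os.path.join(path, "unknowns.tsv"), sep="\t")
        mutant_bundle = DataSetBundle.from_dir(os.path.join(path, "mutant"))
        with open(os.path.join(path, "manifest.json")) as fh:
            manifest = json.load(fh)
        bundles = {}
        pert_root = os.path.join(path, "perturbations")
        for entry in sorted(os.listdir(pert_root)):
            name, direction = entry.rsplit("_", 1)
            bundles[(name, direction)] = DataSetBundle.from_dir(
                os.path.join(pert_root, entry)
            )
        library = PerturbationLibrary(
            bundles=bundles,
            budget=int(manifest["budget"]),
            released={tuple(k) for k in manifest.get("released", [])},
        )
        if with_truth:
            truth_df = pd.read_csv(
                os.path.join(path, "truth.tsv.sealed"), sep="\t"
            )
            truth = ParameterSet.from_frame(truth_df)
            modified = frozenset(truth_df.loc[truth_df["modified"], "name"])
        else:
            truth = None  # estimator-facing load: reveal_truth() will refuse
            modified = frozenset()
        unknowns = UnknownSet(
            names=tuple(unk_df["name"]),
            classes=dict(zip(unk_df["name"], unk_df["class"])),
            _modified=modified
            if with_truth
            else frozenset(),
        )
        return cls(
            spec=spec,
            wildtype=wildtype,
            mutant_bundle=mutant_bundle,
            unknowns=unknowns,
            perturbations=library,
            master_seed=int(manifest["master_seed"]),
            _truth=truth,
        )


def _derived_seed(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1)[0] % (2**31))


def generate_challenge(
    spec: ModelSpec,
    seed: int = 0,
    n_steps: int = 15,
    per_step_increase: float = 0.019,
    n_extra_unknowns: int = 15,
    n_mutant_cells: int = 32,
    n_perturbation_cells: int = 8,
    budget: int = 50,
    **build_kwargs,
) -> ChallengePackage:
    """Build the full challenge from (spec, master seed): mutant strain,
    32-cell mutant bundle, unknown set, and the complete perturbation
    library (every unknown x 2-fold up/down x eight data classes)."""
    ss = tc.as_seed_sequence(seed)
    s_build, s_unknowns, s_mutant, s_pert = ss.spawn(4)

    strain = build_mutant(
        spec,
        spec.wildtype,
        n_steps=n_steps,
        per_step_increase=per_step_increase,
        seed=s_build,
        **build_kwargs,
    )
    unknowns = select_unknowns(
        strain, spec.wildtype, n_extra=n_extra_unknowns, seed=s_unknowns
    )
    mutant_bundle = tc.simulate_population(
        spec, strain.mutant, n_mutant_cells, seed=_derived_seed(s_mutant)
    )

    bundles = {}
    pert_seeds = s_pert.spawn(len(unknowns.names) * 2)
    k = 0
    for name in unknowns.names:
        for direction in DIRECTIONS:
            fold = PERTURBATION_FOLD if direction == "up" else 1.0 / PERTURBATION_FOLD
            value = strain.mutant.value(name) * fold
            if unknowns.classes[name] == "binding_probability":
                value = min(value, 1.0)
            pert_params = strain.mutant.with_value(name, value)
            bundles[(name, direction)] = tc.simulate_population(
                spec,
                pert_params,
                n_perturbation_cells,
                seed=_derived_seed(pert_seeds[k]),
                keep_cells=False,
            )
            k += 1

    library = PerturbationLibrary(bundles=bundles, budget=budget)
    return ChallengePackage(
        spec=spec,
        wildtype=spec.wildtype,
        mutant_bundle=mutant_bundle,
        unknowns=unknowns,
        perturbations=library,
        master_seed=seed if isinstance(seed, (int, np.integer)) else -1,
        _truth=strain.mutant,
    )


# ---------------------------------------------------------------------------
# estimator-facing prediction evaluator


class PredictionEvaluator:
    """Maps a fold-change vector over the unknown names to the least-squares
    prediction error against the mutant bundle.

    Candidate phenotypes are simulated with the unknown parameters set to
    ``wildtype * fold``; everything else stays at the disclosed wild-type
    values (true for all non-unknown parameters by construction).  Uses only
    estimator-facing package content.  Returns ``(error, phenotype_means)``
    so surrogate-assisted optimizers can exploit the full measurement vector.
    """

    def __init__(
        self,
        pkg: ChallengePackage,
        mode: str = "deterministic",
        n_cells: int = 2,
        seed: int = 0,
        variance_floor: float = 1e-12,
    ):
        from .scoring import prediction_error  # local import: no cycle at load

        self._prediction_error = prediction_error
        self.pkg = pkg
        self.mode = mode
        self.n_cells = n_cells
        self.seed = seed
        self.variance_floor = variance_floor
        self.names = pkg.unknowns.names
        self.n_evaluations = 0

    def params_from_folds(self, folds) -> ParameterSet:
        folds = np.asarray(folds, dtype=float)
        if folds.size != len(self.names):
            raise ContractError("fold vector length != number of unknowns")
        updates = {}
        for name, f in zip(self.names, folds):
            value = self.pkg.wildtype.value(name) * float(f)
            if self.pkg.unknowns.classes[name] == "binding_probability":
                value = min(value, 1.0)
            updates[name] = value
        return self.pkg.wildtype.with_values(updates)

    def phenotype(self, folds) -> np.ndarray:
        params = self.params_from_folds(folds)
        spec = self.pkg.spec
        if self.mode == "deterministic":
            traj = tc.simulate_cell(spec, params, mode="deterministic")
            if not traj.divided:
                return None  # cell never divided: no phenotype
            registry = self.pkg.mutant_bundle.registry
            return tc.cell_measurements(spec, traj, registry, rng=None)
        bundle = tc.simulate_population(
            spec, params, self.n_cells, seed=self.seed, keep_cells=False
        )
        return bundle.means

    def __call__(self, folds):
        means = self.phenotype(folds)
        if means is None:
            # a candidate whose cell never divides is infinitely far from
            # the mutant phenotype
            self.n_evaluations += 1
            return math.inf, None
        err = self._prediction_error(
            means,
            self.pkg.mutant_bundle.means,
            self.pkg.mutant_bundle.variances,
            variance_floor=self.variance_floor,
        )
        self.n_evaluations += 1
        return err, means
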