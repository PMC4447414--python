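"""Reduced physical-model estimators: read parameters directly off the data.

The surrogate's steady-state relations are invertible from the released data
classes, which is exactly the identifiability structure the data bundle was
designed around:

* **binding probabilities** from ChIP-seq initiation counts, corrected for
  the replication-driven DNA copy-number gradient read from DNA-seq, with a
  single proportionality constant fit on calibration genes whose binding
  probabilities are disclosed (not in the unknown set);
* **RNA half-lives** by inverting the birth-death balance: with per-copy
  synthesis rate ``a = p * k_txn`` known from the previous step and the cell
  cycle reconstructed from DNA-seq (fork-passage time) and the mean division
  time, the time-averaged RNA level is an explicit monotone function of the
  decay rate, solved by bracketing;
* **turnover numbers** by inverting the flux law
  ``v = kcat * e * S / (K + S)`` with time-averaged enzyme concentration,
  metabolite pool, and flux;
* an optional **refinement** pass: cyclic coordinate search over
  multiplicative steps that keeps a move only when the prediction error
  against the mutant bundle decreases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import toycell as tc
from .challenge import ChallengePackage, PredictionEvaluator
from .toycell import ContractError, LN2

POSITIVE_FLOOR = 1e-9


class CalibrationError(RuntimeError):
    """No calibration gene with a disclosed binding probability."""


class DataError(ValueError):
    """Measured data violate a physical constraint (e.g. zero copy number)."""


@dataclass
class ReducedEstimate:
    """Per-parameter point estimates with method tags and flags."""

    estimates: dict = field(default_factory=dict)     # name -> value
    standard_errors: dict = field(default_factory=dict)
    methods: dict = field(default_factory=dict)       # name -> method tag
    inestimable: dict = field(default_factory=dict)   # name -> reason
    calibration: dict = field(default_factory=dict)

    def merge(self, other: "ReducedEstimate") -> "ReducedEstimate":
        out = ReducedEstimate(
            estimates={**self.estimates, **other.estimates},
            standard_errors={**self.standard_errors, **other.standard_errors},
            methods={**self.methods, **other.methods},
            inestimable={**self.inestimable, **other.inestimable},
            calibration={**self.calibration, **other.calibration},
        )
        return out

    def value(self, name):
        return self.estimates[name]

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for name, v in self.estimates.items():
            rows.append(
                {
                    "name": name,
                    "value": v,
                    "method": self.methods.get(name, ""),
                    "flag": self.inestimable.get(name, ""),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# copy-number profile helpers


def interpolate_copy_number(
    bin_distances: np.ndarray, bin_means: np.ndarray, at: np.ndarray
) -> np.ndarray:
    """Piecewise-linear interpolation of the DNA-seq profile with linear
    edge extrapolation (the profile is linear in arm distance wherever the
    forks completed, so clamping at the outermost bins would bias genes
    nearer oriC or terC than any bin midpoint)."""
    at = np.atleast_1d(np.asarray(at, dtype=float))
    out = np.interp(at, bin_distances, bin_means)
    lo_slope = (bin_means[1] - bin_means[0]) / (bin_distances[1] - bin_distances[0])
    hi_slope = (bin_means[-1] - bin_means[-2]) / (
        bin_distances[-1] - bin_distances[-2]
    )
    below = at < bin_distances[0]
    above = at > bin_distances[-1]
    out[below] = bin_means[0] + lo_slope * (at[below] - bin_distances[0])
    out[above] = bin_means[-1] + hi_slope * (at[above] - bin_distances[-1])
    return out


# ---------------------------------------------------------------------------
# the three class estimators


def estimate_bind_probs(
    chip_counts: np.ndarray,
    copy_numbers: np.ndarray,
    calibration: dict,
    gene_names,
) -> ReducedEstimate:
    """Binding probabilities from ChIP-seq counts corrected by DNA copy
    number: ``p_hat_g = alpha * chip_g / copy_g`` with ``alpha`` fit by least
    squares through the origin on the calibration genes.
    """
    chip_counts = np.asarray(chip_counts, dtype=float)
    copy_numbers = np.asarray(copy_numbers, dtype=float)
    gene_names = list(gene_names)
    if np.any(copy_numbers <= 0):
        raise DataError("non-positive DNA copy number")
    if not calibration:
        raise CalibrationError("no calibration genes with known binding probability")
    ratio = chip_counts / copy_numbers
    idx = {g: i for i, g in enumerate(gene_names)}
    x = np.array([ratio[idx[g]] for g in calibration])
    y = np.array([calibration[g] for g in calibration])
    denom = float(np.sum(x * x))
    if denom == 0:
        raise CalibrationError("calibration genes carry no ChIP signal")
    alpha = float(np.sum(x * y) / denom)

    out = ReducedEstimate(calibration={"alpha": alpha})
    for g in gene_names:
        name = f"pb_{g}"
        raw = alpha * ratio[idx[g]]
        if chip_counts[idx[g]] <= 0:
            out.estimates[name] = POSITIVE_FLOOR
            out.inestimable[name] = "zero ChIP signal"
        else:
            out.estimates[name] = float(np.clip(raw, POSITIVE_FLOOR, 1.0))
        out.methods[name] = "chip_copy"
    return out


def _mean_rna_model(a: float, d: float, t_pass: float, t_div: float) -> float:
    """Time-averaged RNA of the deterministic birth-death cycle: steady at
    copy 1 until the fork passage, then relaxing to the copy-2 steady state.
    """
    t_pass = float(np.clip(t_pass, 0.0, t_div))
    rest = t_div - t_pass
    integral = (a / d) * t_pass + (2 * a / d) * rest - (a / d**2) * (
        1.0 - math.exp(-d * rest)
    )
    return integral / t_div


def estimate_half_lives(
    rna_levels: np.ndarray,
    synthesis_rates: np.ndarray,
    gene_names,
    t_div: float,
    t_pass: np.ndarray | None = None,
    copy_numbers: np.ndarray | None = None,
) -> ReducedEstimate:
    """RNA half-lives from time-averaged expression and known synthesis.

    With neither ``t_pass`` nor ``copy_numbers`` the plain steady state
    ``t_half = ln2 * RNA / synthesis`` is used; given the cycle geometry the
    copy-number step is accounted for exactly (``t_pass_g = t_div *
    (2 - mean_copy_g)`` reconstructs the fork passage from DNA-seq).
    """
    rna_levels = np.asarray(rna_levels, dtype=float)
    synthesis_rates = np.asarray(synthesis_rates, dtype=float)
    gene_names = list(gene_names)
    if t_pass is None and copy_numbers is not None:
        t_pass = t_div * (2.0 - np.asarray(copy_numbers, dtype=float))
    out = ReducedEstimate()
    for i, g in enumerate(gene_names):
        name = f"hl_{g}"
        out.methods[name] = "halflife_ss"
        a = synthesis_rates[i]
        if a <= 0 or rna_levels[i] <= 0:
            out.estimates[name] = POSITIVE_FLOOR
            out.inestimable[name] = "zero synthesis or expression"
            continue
        if t_pass is None:
            d = a / rna_levels[i]  # <RNA> = a/d at constant copy 1
        else:
            tp = float(np.clip(t_pass[i], 0.0, t_div))
            target = rna_levels[i]

            def f(d):
                return _mean_rna_model(a, d, tp, t_div) - target

            lo, hi = 1e-4, 1e4
            if f(lo) < 0:  # expression above any attainable mean
                d = lo
                out.inestimable[name] = "expression above model range"
            elif f(hi) > 0:
                d = hi
                out.inestimable[name] = "expression below model range"
            else:
                d = brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)
        out.estimates[name] = LN2 / d
    return out


def estimate_kcats(
    fluxes: np.ndarray,
    enzyme_concentrations: np.ndarray,
    metabolite_pools: np.ndarray,
    K: float,
    reaction_names,
    reaction_metabolite: np.ndarray,
) -> ReducedEstimate:
    """Turnover numbers by inverting the saturation flux law per reaction."""
    fluxes = np.asarray(fluxes, dtype=float)
    enzyme_concentrations = np.asarray(enzyme_concentrations, dtype=float)
    metabolite_pools = np.asarray(metabolite_pools, dtype=float)
    out = ReducedEstimate()
    for r, rname in enumerate(reaction_names):
        name = f"kcat_{rname}"
        out.methods[name] = "kcat_flux"
        e = enzyme_concentrations[r]
        v = fluxes[r]
        s = metabolite_pools[reaction_metabolite[r]]
        if e <= 0 or v <= 0:
            out.estimates[name] = POSITIVE_FLOOR
            out.inestimable[name] = "zero enzyme or flux"
            continue
        sat = s / (K + s)
        out.estimates[name] = float(v / (e * sat))
    return out


# ---------------------------------------------------------------------------
# refinement by flux/phenotype matching


def refine_by_matching(
    initial: ReducedEstimate,
    eval_fn,
    unknown_names,
    wildtype_values: dict,
    budget: int,
    step: float = 1.1,
    shrink: float = 0.5,
    bounds=(0.066, 1.906),
) -> tuple:
    """Cyclic coordinate search over multiplicative steps; a move is kept
    only if the prediction error decreases.  Returns (refined estimate,
    final error, evaluations used)."""
    unknown_names = tuple(unknown_names)
    missing = [n for n in unknown_names if n not in initial.estimates]
    if missing:
        raise ContractError(f"initial estimate missing: {missing}")
    if budget < len(unknown_names):
        raise ContractError("budget must cover at least one pass")

    folds = np.array(
        [
            np.clip(
                initial.estimates[n] / wildtype_values[n], bounds[0], bounds[1]
            )
            for n in unknown_names
        ]
    )

    def error_of(f):
        res = eval_fn(f)
        return res[0] if isinstance(res, tuple) else res

    current = error_of(folds)
    used = 1
    log_step = math.log(step)
    while used < budget and log_step > 1e-4:
        improved = False
        for j in range(len(unknown_names)):
            if used + 2 > budget:
                break
            for direction in (+1, -1):
                # line search: keep stepping while the move helps
                while used < budget:
                    trial = folds.copy()
                    trial[j] = float(
                        np.clip(
                            trial[j] * math.exp(direction * log_step),
                            bounds[0],
                            bounds[1],
                        )
                    )
                    if trial[j] == folds[j]:
                        break
                    try:
                        e = error_of(trial)
                    except Exception:
                        break  # skip the coordinate on evaluation failure
                    used += 1
                    if e < current:
                        current = e
                        folds = trial
                        improved = True
                    else:
                        break
        if not improved:
            log_step *= shrink
    refined = ReducedEstimate(
        estimates={
            n: folds[j] * wildtype_values[n] for j, n in enumerate(unknown_names)
        },
        methods={n: "refined" for n in unknown_names},
        calibration=dict(initial.calibration),
    )
    return refined, current, used


# ---------------------------------------------------------------------------
# package-level orchestration


def fit_reduced(
    pkg: ChallengePackage,
    bundle: tc.DataSetBundle | None = None,
    refine_budget: int = 0,
):
    """Run the three class estimators on a mutant bundle and assemble a
    submission covering every unknown name.

    Uses only estimator-facing package content: the bundle means, the model
    structure/constants, and the disclosed wild-type values of parameters
    outside the unknown set.  Returns (ReducedEstimate, Submission).
    """
    from .scoring import Submission

    spec = pkg.spec
    if bundle is None:
        bundle = pkg.mutant_bundle
    c = spec.constants
    genes = list(spec.gene_names)
    unknown = set(pkg.unknowns.names)

    chip = bundle.class_means("chipseq", genes)
    dnaseq = bundle.class_means("dnaseq")
    rna = bundle.class_means("rna_array", genes)
    prot_conc = bundle.class_means("protein_array", genes)
    flux = bundle.class_means("reaction_fluxes", spec.reaction_names)
    pools = bundle.class_means(
        "metabolite_concentrations",
        [f"M{m + 1}" for m in range(spec.n_metabolites)],
    )
    t_div = bundle.scalar("single_cell", "t_div")

    copy_at_genes = interpolate_copy_number(
        spec.dna_bin_distances, dnaseq, spec.arm_distances
    )
    calibration = {
        g: pkg.wildtype.value(f"pb_{g}")
        for g in genes
        if f"pb_{g}" not in unknown
    }
    est_p = estimate_bind_probs(chip, copy_at_genes * t_div, calibration, genes)

    # synthesis per copy a = p * k_txn, with disclosed values where known
    p_hat = np.array(
        [
            pkg.wildtype.value(f"pb_{g}")
            if f"pb_{g}" not in unknown
            else est_p.estimates[f"pb_{g}"]
            for g in genes
        ]
    )
    est_h = estimate_half_lives(
        rna,
        p_hat * c.k_txn,
        genes,
        t_div=t_div,
        copy_numbers=copy_at_genes,
    )
    est_k = estimate_kcats(
        flux,
        prot_conc[spec.reaction_gene],
        pools,
        c.K,
        spec.reaction_names,
        spec.reaction_metabolite,
    )

    estimate = est_p.merge(est_h).merge(est_k)
    if refine_budget > 0:
        evaluator = PredictionEvaluator(pkg, mode="deterministic")
        wt = {n: pkg.wildtype.value(n) for n in pkg.unknowns.names}
        estimate, _, _ = refine_by_matching(
            estimate, evaluator, pkg.unknowns.names, wt, budget=refine_budget
        )

    submission = Submission(
        values={n: float(estimate.estimates[n]) for n in pkg.unknowns.names},
        team="reduced-model",
    )
    return estimate, submission
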