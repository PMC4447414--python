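"""Stochastic surrogate cell model and in-silico data generation.

The surrogate stands in for a full mechanistic whole-cell model at a cost of
milliseconds per cell instead of core-days.  It keeps the identifiability
structure a parameter-estimation challenge needs: three parameter classes
(RNA-polymerase promoter binding probabilities, RNA half-lives, metabolic
turnover numbers), stochastic cell-to-cell variation, a replication-driven
DNA copy-number gradient from oriC to terC, and a doubling-time phenotype
that responds to all three classes through a metabolic growth coupling.

State per cell: per-gene RNA and protein counts, per-metabolite pools, mass,
and a pair of bidirectional replication forks.  Per time step ``dt``:

* DNA copy number ``c_g`` is 2 once a fork has passed gene ``g``, else 1
  (fractional within the step containing the passage, so time averages are
  free of grid staircase artifacts).
* RNA synthesis events per gene have mean ``c_g * p_g * k_txn * dt``;
  RNA decays first-order with half-life ``t_half_g``.  Deterministic mode
  uses the exact exponential integrator of the birth-death step.
* Protein synthesis has mean ``k_tl * RNA_g * dt``; no active decay.
* Reaction flux ``v_r = kcat_r * (E_r / mass) * S / (K + S)``; each
  metabolite pool relaxes toward a homeostatic set point minus consumption.
* Growth rate ``mu = mu0 * geomean_r(clip(v_r / v_ref_r, floor, cap))`` with
  ``v_ref_r`` the wild-type balanced-growth flux; mass grows by
  ``(1 + mu * dt)`` per step.
* Replication initiates at a mass threshold; forks progress symmetrically;
  the cell divides (cytokinesis) once replication is complete AND mass has
  doubled.

Eight data classes are assembled per population: single-cell time courses
and event times, metabolite concentrations, DNA-seq, RNA-seq, ChIP-seq
(lifetime transcription-initiation counts), RNA array, protein array
(concentrations), and reaction fluxes.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

LN2 = math.log(2.0)


def as_seed_sequence(seed) -> np.random.SeedSequence:
    """Accept an int or an existing SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


PARAM_CLASSES = ("binding_probability", "rna_half_life", "turnover_number")

DATA_CLASSES = (
    "single_cell",
    "metabolite_concentrations",
    "dnaseq",
    "rnaseq",
    "chipseq",
    "rna_array",
    "protein_array",
    "reaction_fluxes",
)

#: cycle fractions at which single-cell time courses are registered
CYCLE_FRACTIONS = (0.1, 0.3, 0.5, 0.7, 0.9)


class InvalidParameterError(ValueError):
    """A parameter value violates its domain (non-positive, binding prob > 1)."""


class ContractError(ValueError):
    """A precondition of an operation was violated."""


class EstimationImpossibleError(RuntimeError):
    """No divided cells: the requested phenotype cannot be computed."""


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class ParameterSet:
    """Ordered, named positive parameters of the three challenge classes.

    ``names``/``classes``/``values`` are parallel tuples/arrays.  Binding
    probabilities are dimensionless in (0, 1], half-lives carry time units,
    turnover numbers are per unit time.
    """

    names: tuple
    classes: tuple
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.names) != len(set(self.names)):
            raise InvalidParameterError("parameter names must be unique")
        if len(self.names) != len(self.classes) or len(self.names) != self.values.size:
            raise InvalidParameterError("names/classes/values length mismatch")
        for cls in self.classes:
            if cls not in PARAM_CLASSES:
                raise InvalidParameterError(f"unknown parameter class {cls!r}")
        self.validate()
        object.__setattr__(
            self, "_index", {n: i for i, n in enumerate(self.names)}
        )

    def validate(self):
        if np.any(~np.isfinite(self.values)) or np.any(self.values <= 0):
            raise InvalidParameterError("all parameter values must be positive")
        for cls, v in zip(self.classes, self.values):
            if cls == "binding_probability" and v > 1.0:
                raise InvalidParameterError(
                    f"binding probability {v} exceeds 1"
                )

    def __len__(self):
        return len(self.names)

    def __contains__(self, name):
        return name in self._index

    def value(self, name):
        return float(self.values[self._index[name]])

    def pclass(self, name):
        return self.classes[self._index[name]]

    def names_of_class(self, cls):
        return tuple(n for n, c in zip(self.names, self.classes) if c == cls)

    def with_value(self, name, value) -> "ParameterSet":
        vals = self.values.copy()
        vals[self._index[name]] = value
        return ParameterSet(self.names, self.classes, vals)

    def with_values(self, updates: dict) -> "ParameterSet":
        vals = self.values.copy()
        for name, value in updates.items():
            vals[self._index[name]] = value
        return ParameterSet(self.names, self.classes, vals)

    def subset(self, names) -> "ParameterSet":
        idx = [self._index[n] for n in names]
        return ParameterSet(
            tuple(names),
            tuple(self.classes[i] for i in idx),
            self.values[idx],
        )

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"name": self.names, "class": self.classes, "value": self.values}
        )

    def to_tsv(self, path):
        self.as_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ParameterSet":
        return cls(
            tuple(df["name"]), tuple(df["class"]), df["value"].to_numpy(float)
        )

    @classmethod
    def from_tsv(cls, path) -> "ParameterSet":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class Constants:
    """Kinetic and growth constants of the surrogate (arbitrary units; the
    time unit is calibrated so the wild-type doubling time is near 1)."""

    initial_mass: float = 1.0
    replication_mass_threshold: float = 1.25
    fork_speed: float = 1.25          # chromosome fraction per unit time
    k_txn: float = 200.0              # initiations / time / copy / unit prob.
    k_tl: float = 10.0                # proteins / RNA / time
    K: float = 0.5                    # metabolite saturation constant
    mu0: float = LN2                  # baseline growth rate
    s_setpoint: float = 1.0           # homeostatic metabolite set point
    s_relax: float = 20.0             # metabolite relaxation rate
    s_consumption: float = 0.5        # flux -> pool drain coefficient
    ratio_floor: float = 0.25         # growth-coupling clip floor
    ratio_cap: float = 2.0            # growth-coupling clip cap
    dt: float = 0.01
    t_max: float = 6.0

    def validate(self):
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ContractError(f"constant {name} must be strictly positive")


@dataclass(frozen=True)
class ModelSpec:
    """Wiring of the toy cell: genes, gene->reaction map, wild-type
    parameters, and kinetic constants.

    ``gene_positions`` are chromosome fractions in [0, 1) with oriC at 0 and
    terC at 0.5; replication forks travel both arms symmetrically.
    ``reaction_gene[r]`` is the index of the single enzyme gene of reaction
    ``r``; ``reaction_metabolite[r]`` the index of its substrate pool.
    """

    gene_names: tuple
    gene_positions: np.ndarray
    reaction_names: tuple
    reaction_gene: np.ndarray
    reaction_metabolite: np.ndarray
    n_metabolites: int
    wildtype: ParameterSet
    constants: Constants = field(default_factory=Constants)
    n_dna_bins: int = 8

    def __post_init__(self):
        object.__setattr__(
            self, "gene_positions", np.asarray(self.gene_positions, dtype=float)
        )
        object.__setattr__(
            self, "reaction_gene", np.asarray(self.reaction_gene, dtype=int)
        )
        object.__setattr__(
            self,
            "reaction_metabolite",
            np.asarray(self.reaction_metabolite, dtype=int),
        )
        if self.n_genes < 2 or self.n_reactions < 1:
            raise ContractError("need n_genes >= 2 and at least one reaction")
        if len(set(np.round(self.gene_positions, 12))) != self.n_genes:
            raise ContractError("gene positions must be unique")
        if np.any(self.gene_positions < 0) or np.any(self.gene_positions >= 1):
            raise ContractError("gene positions must lie in [0, 1)")
        if len(set(self.reaction_gene.tolist())) != self.n_reactions:
            raise ContractError("each reaction needs its own enzyme gene")
        self.constants.validate()
        self._check_wildtype(self.wildtype)

    # -- structural accessors ------------------------------------------------

    @property
    def n_genes(self):
        return len(self.gene_names)

    @property
    def n_reactions(self):
        return len(self.reaction_names)

    @property
    def arm_distances(self) -> np.ndarray:
        """Distance of each gene from oriC along its replication arm."""
        pos = self.gene_positions
        return np.minimum(pos, 1.0 - pos)

    @property
    def dna_bin_distances(self) -> np.ndarray:
        """Arm-distance midpoints of the DNA-seq bins (oriC -> terC)."""
        edges = np.linspace(0.0, 0.5, self.n_dna_bins + 1)
        return 0.5 * (edges[:-1] + edges[1:])

    @property
    def metabolic_gene_indices(self) -> np.ndarray:
        return self.reaction_gene

    def binding_name(self, g):
        return f"pb_{self.gene_names[g]}"

    def halflife_name(self, g):
        return f"hl_{self.gene_names[g]}"

    def kcat_name(self, r):
        return f"kcat_{self.reaction_names[r]}"

    def _check_wildtype(self, params: ParameterSet):
        expected = (
            [self.binding_name(g) for g in range(self.n_genes)]
            + [self.halflife_name(g) for g in range(self.n_genes)]
            + [self.kcat_name(r) for r in range(self.n_reactions)]
        )
        if set(expected) != set(params.names):
            raise InvalidParameterError(
                "parameter names do not match the model layout"
            )

    def param_arrays(self, params: ParameterSet):
        """Return (binding probs per gene, half-lives per gene, kcats per
        reaction) as arrays aligned with the spec layout."""
        self._check_wildtype(params)
        p = np.array([params.value(self.binding_name(g)) for g in range(self.n_genes)])
        th = np.array([params.value(self.halflife_name(g)) for g in range(self.n_genes)])
        kc = np.array([params.value(self.kcat_name(r)) for r in range(self.n_reactions)])
        return p, th, kc

    # -- balanced-growth reference -------------------------------------------

    def balanced_state(self, params: ParameterSet):
        """Expected birth state (RNA counts, protein counts, metabolite
        pools) for a strain with the given parameters at copy number 1."""
        c = self.constants
        p, th, kc = self.param_arrays(params)
        rna = p * c.k_txn * th / LN2
        protein = c.k_tl * rna / c.mu0
        e_conc = protein[self.reaction_gene] / c.initial_mass
        pools = _quasi_steady_pools(self, kc, e_conc)
        return rna, protein, pools

    @property
    def reference_fluxes(self) -> np.ndarray:
        """Wild-type balanced-growth fluxes v_ref (growth normalization)."""
        cached = self.__dict__.get("_reference_fluxes")
        if cached is not None:
            return cached
        c = self.constants
        _, _, kc = self.param_arrays(self.wildtype)
        rna, protein, pools = self.balanced_state(self.wildtype)
        e_conc = protein[self.reaction_gene] / c.initial_mass
        sat = pools[self.reaction_metabolite] / (c.K + pools[self.reaction_metabolite])
        v_ref = kc * e_conc * sat
        object.__setattr__(self, "_reference_fluxes", v_ref)
        return v_ref

    # -- serialization -------------------------------------------------------

    def to_json(self) -> dict:
        return {
            "gene_names": list(self.gene_names),
            "gene_positions": self.gene_positions.tolist(),
            "reaction_names": list(self.reaction_names),
            "reaction_gene": self.reaction_gene.tolist(),
            "reaction_metabolite": self.reaction_metabolite.tolist(),
            "n_metabolites": self.n_metabolites,
            "n_dna_bins": self.n_dna_bins,
            "constants": {
                k: getattr(self.constants, k)
                for k in self.constants.__dataclass_fields__
            },
            "wildtype": self.wildtype.as_frame().to_dict(orient="list"),
        }

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=1)

    @classmethod
    def from_json(cls, doc: dict) -> "ModelSpec":
        return cls(
            gene_names=tuple(doc["gene_names"]),
            gene_positions=np.asarray(doc["gene_positions"]),
            reaction_names=tuple(doc["reaction_names"]),
            reaction_gene=np.asarray(doc["reaction_gene"]),
            reaction_metabolite=np.asarray(doc["reaction_metabolite"]),
            n_metabolites=int(doc["n_metabolites"]),
            wildtype=ParameterSet.from_frame(pd.DataFrame(doc["wildtype"])),
            constants=Constants(**doc["constants"]),
            n_dna_bins=int(doc["n_dna_bins"]),
        )

    @classmethod
    def load(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_json(json.load(fh))


def _quasi_steady_pools(spec: ModelSpec, kcats, e_conc) -> np.ndarray:
    """Solve the scalar homeostatic balance per metabolite pool:
    relax * (set - S) = drain * sum_r kcat_r e_r S/(K+S)."""
    c = spec.constants
    pools = np.empty(spec.n_metabolites)
    for m in range(spec.n_metabolites):
        mask = spec.reaction_metabolite == m
        capacity = float(np.sum(kcats[mask] * e_conc[mask]))
        if capacity == 0.0:
            pools[m] = c.s_setpoint
            continue

        def f(s):
            return c.s_relax * (c.s_setpoint - s) - c.s_consumption * capacity * s / (
                c.K + s
            )

        pools[m] = brentq(f, 1e-12, c.s_setpoint)
    return pools


def default_spec() -> ModelSpec:
    """The default toy cell: 12 genes (9 metabolic), 9 reactions coupled to
    3 metabolite pools, one enzyme gene per reaction.

    33 parameters total (12 binding probabilities, 12 half-lives, 9 turnover
    numbers), enough to host the 30-unknown challenge composition.
    """
    n_genes, n_reactions, n_metab = 12, 9, 3
    gene_names = tuple(f"G{i + 1:02d}" for i in range(n_genes))
    reaction_names = tuple(f"R{i + 1}" for i in range(n_reactions))
    positions = np.array(
        [0.02, 0.10, 0.18, 0.26, 0.34, 0.42, 0.48, 0.56, 0.64, 0.72, 0.83, 0.93]
    )
    reaction_gene = np.arange(n_reactions)  # G01..G09 are the enzymes
    reaction_metabolite = np.arange(n_reactions) % n_metab

    # mildly varied wild-type values (fixed, not tunable at run time)
    pb = np.array(
        [0.45, 0.30, 0.55, 0.25, 0.40, 0.60, 0.35, 0.50, 0.28, 0.33, 0.22, 0.38]
    )
    hl = np.array(
        [0.20, 0.15, 0.25, 0.18, 0.22, 0.16, 0.28, 0.14, 0.24, 0.19, 0.17, 0.21]
    )
    kcat = np.array([0.030, 0.045, 0.025, 0.050, 0.035, 0.040, 0.028, 0.055, 0.032])

    names = (
        [f"pb_{g}" for g in gene_names]
        + [f"hl_{g}" for g in gene_names]
        + [f"kcat_{r}" for r in reaction_names]
    )
    classes = (
        ["binding_probability"] * n_genes
        + ["rna_half_life"] * n_genes
        + ["turnover_number"] * n_reactions
    )
    wildtype = ParameterSet(tuple(names), tuple(classes), np.r_[pb, hl, kcat])
    return ModelSpec(
        gene_names=gene_names,
        gene_positions=positions,
        reaction_names=reaction_names,
        reaction_gene=reaction_gene,
        reaction_metabolite=reaction_metabolite,
        n_metabolites=n_metab,
        wildtype=wildtype,
    )


# ---------------------------------------------------------------------------
# measurement registry


def build_registry(spec: ModelSpec) -> pd.DataFrame:
    """Flat measurement index i = 0..M-1 -> (data_class, entity, time)."""
    rows = []
    for f in CYCLE_FRACTIONS:
        for what in ("mass", "volume", "growth_rate"):
            rows.append(("single_cell", what, f))
    for ev in ("t_init", "t_repl", "t_div"):
        rows.append(("single_cell", ev, np.nan))
    for m in range(spec.n_metabolites):
        rows.append(("metabolite_concentrations", f"M{m + 1}", np.nan))
    for b in range(spec.n_dna_bins):
        rows.append(("dnaseq", f"bin{b + 1:02d}", np.nan))
    for cls in ("rnaseq", "chipseq", "rna_array", "protein_array"):
        for g in spec.gene_names:
            rows.append((cls, g, np.nan))
    for r in spec.reaction_names:
        rows.append(("reaction_fluxes", r, np.nan))
    df = pd.DataFrame(rows, columns=["data_class", "entity", "time"])
    df.index.name = "index"
    return df


def registry_checksum(registry: pd.DataFrame) -> str:
    payload = registry.to_csv().encode()
    return hashlib.md5(payload).hexdigest()


# ---------------------------------------------------------------------------
# single-cell simulation


@dataclass
class CellTrajectory:
    """Full single-cell record over one life cycle.

    Arrays are aligned with ``times``; row ``i`` is the state at ``times[i]``.
    ``status`` is 'divided' or 'timeout' (max simulated time reached without
    cytokinesis -- never a silent truncation).
    """

    times: np.ndarray
    mass: np.ndarray
    volume: np.ndarray
    growth_rate: np.ndarray
    rna: np.ndarray              # (T, n_genes)
    protein: np.ndarray          # (T, n_genes)
    copy_number: np.ndarray      # (T, n_genes), values in {1, 2}
    fluxes: np.ndarray           # (T, n_reactions)
    metabolites: np.ndarray      # (T, n_metabolites)
    chip_counts: np.ndarray      # per-gene lifetime initiation events
    t_init: float
    t_repl: float
    t_div: float
    status: str
    avg_rna: np.ndarray
    avg_protein_conc: np.ndarray
    avg_flux: np.ndarray
    avg_metabolites: np.ndarray
    avg_copy_bins: np.ndarray
    daughter_rna: np.ndarray | None = None
    daughter_protein: np.ndarray | None = None

    @property
    def divided(self) -> bool:
        return self.status == "divided"


def _passage_times(spec: ModelSpec, t_init: float) -> np.ndarray:
    return t_init + spec.arm_distances / spec.constants.fork_speed


def _fractional_copy(t0, t1, passage):
    """Mean copy number over [t0, t1] for fork-passage times `passage`."""
    frac_two = (t1 - passage) / (t1 - t0)
    np.clip(frac_two, 0.0, 1.0, out=frac_two)
    return 1.0 + frac_two


def simulate_cell(
    spec: ModelSpec,
    params: ParameterSet,
    seed=0,
    mode: str = "stochastic",
) -> CellTrajectory:
    """Simulate a single cell from birth to cytokinesis (or ``t_max``).

    ``mode='deterministic'`` propagates expectations (real-valued counts,
    ``seed`` ignored); ``mode='stochastic'`` draws Poisson synthesis events,
    binomial RNA survival, and Poisson initial counts.
    """
    if mode not in ("stochastic", "deterministic"):
        raise ContractError(f"unknown mode {mode!r}")
    params.validate()
    spec._check_wildtype(params)
    c = spec.constants
    dt = c.dt
    stochastic = mode == "stochastic"
    rng = np.random.default_rng(seed) if stochastic else None

    p, th, kc = spec.param_arrays(params)
    a = p * c.k_txn                      # initiations / time / copy
    d = LN2 / th                         # decay rates
    decay = np.exp(-d * dt)
    gain = (1.0 - decay) / d             # exact birth-death integrator weight
    rgene = spec.reaction_gene
    rmet = spec.reaction_metabolite
    v_ref = spec.reference_fluxes
    bin_dist = spec.dna_bin_distances
    arm = spec.arm_distances

    rna0, prot0, pools0 = spec.balanced_state(params)
    if stochastic:
        rna = rng.poisson(rna0).astype(float)
        protein = rng.poisson(prot0).astype(float)
    else:
        rna = rna0.copy()
        protein = prot0.copy()
    pools = pools0.copy()
    mass = c.initial_mass

    n_max = int(round(c.t_max / dt))
    G, R, M = spec.n_genes, spec.n_reactions, spec.n_metabolites
    times = np.empty(n_max + 1)
    mass_tr = np.empty(n_max + 1)
    mu_tr = np.empty(n_max + 1)
    rna_tr = np.empty((n_max + 1, G))
    prot_tr = np.empty((n_max + 1, G))
    copy_tr = np.empty((n_max + 1, G), dtype=int)
    flux_tr = np.empty((n_max + 1, R))
    met_tr = np.empty((n_max + 1, M))
    chip = np.zeros(G)

    # time-average accumulators (trapezoid for smooth state variables)
    acc_rna = np.zeros(G)
    acc_conc = np.zeros(G)
    acc_flux = np.zeros(R)
    acc_met = np.zeros(M)
    acc_bins = np.zeros(spec.n_dna_bins)

    t_init = math.nan
    t_repl = math.nan
    t_div = math.nan
    passage = None      # per-gene fork passage times once initiated
    bin_pass = None

    inv_vref = 1.0 / v_ref
    inv_nr = 1.0 / R
    floor, cap = c.ratio_floor, c.ratio_cap

    def fluxes_now(prot_, pools_, mass_):
        s = pools_[rmet]
        return kc * (prot_[rgene] / mass_) * (s / (c.K + s))

    def growth_rate_of(v_):
        ratio = v_ * inv_vref
        np.clip(ratio, floor, cap, out=ratio)
        return c.mu0 * math.exp(float(np.log(ratio).sum()) * inv_nr)

    v = fluxes_now(protein, pools, mass)
    times[0] = 0.0
    mass_tr[0] = mass
    rna_tr[0] = rna
    prot_tr[0] = protein
    copy_tr[0] = 1
    flux_tr[0] = v
    met_tr[0] = pools
    mu_tr[0] = growth_rate_of(v)

    step = 0
    status = "timeout"
    for step in range(1, n_max + 1):
        t0 = (step - 1) * dt
        t1 = step * dt

        if passage is None:
            c_gene = np.ones(G)
            c_bins = np.ones(spec.n_dna_bins)
        else:
            c_gene = _fractional_copy(t0, t1, passage)
            c_bins = _fractional_copy(t0, t1, bin_pass)

        synth_mean = a * c_gene * dt
        rna_prev = rna
        if stochastic:
            births = rng.poisson(synth_mean)
            survivors = rng.binomial(rna.astype(int), decay)
            rna = survivors + births
            chip += births
            protein = protein + rng.poisson(c.k_tl * rna_prev * dt)
        else:
            rna = rna * decay + a * c_gene * gain
            chip += synth_mean
            protein = protein + c.k_tl * rna_prev * dt

        v = fluxes_now(protein, pools, mass)
        drain = np.bincount(rmet, weights=v, minlength=M)
        pools = pools + dt * (
            c.s_relax * (c.s_setpoint - pools) - c.s_consumption * drain
        )
        np.maximum(pools, 1e-12, out=pools)

        mu = growth_rate_of(v)
        mass = mass * (1.0 + mu * dt)

        # accumulate time averages over [t0, t1]
        acc_rna += 0.5 * (rna_prev + rna) * dt
        acc_conc += protein * (dt / mass)
        acc_flux += v * dt
        acc_met += pools * dt
        acc_bins += c_bins * dt

        # replication bookkeeping
        if passage is None and mass >= c.replication_mass_threshold:
            t_init = t1
            passage = _passage_times(spec, t_init)
            bin_pass = t_init + bin_dist / c.fork_speed
        if math.isnan(t_repl) and passage is not None:
            t_done = t_init + 0.5 / c.fork_speed
            if t1 >= t_done:
                t_repl = t_done

        times[step] = t1
        mass_tr[step] = mass
        mu_tr[step] = mu
        rna_tr[step] = rna
        prot_tr[step] = protein
        copy_tr[step] = 1 if passage is None else (t1 >= passage).astype(int) + 1
        flux_tr[step] = v
        met_tr[step] = pools

        if not math.isnan(t_repl) and mass >= 2.0 * c.initial_mass:
            # cytokinesis time: the mass-doubling crossing is interpolated
            # within the step (mass is linear over one step), so the doubling
            # time responds continuously to parameter changes instead of
            # being quantized to the dt grid
            m_prev = mass_tr[step - 1]
            if m_prev < 2.0 * c.initial_mass:
                frac = (2.0 * c.initial_mass - m_prev) / (mass - m_prev)
                t_cross = t0 + frac * dt
            else:
                t_cross = t0
            t_div = max(t_cross, t_repl)
            status = "divided"
            break

    n = step + 1
    total_t = times[step] if times[step] > 0 else dt
    daughter_rna = daughter_prot = None
    if status == "divided" and stochastic:
        daughter_rna = rng.binomial(rna.astype(int), 0.5).astype(float)
        daughter_prot = rng.binomial(protein.astype(int), 0.5).astype(float)
    elif status == "divided":
        daughter_rna = rna / 2.0
        daughter_prot = protein / 2.0

    return CellTrajectory(
        times=times[:n].copy(),
        mass=mass_tr[:n].copy(),
        volume=mass_tr[:n].copy(),  # unit density: volume proportional to mass
        growth_rate=mu_tr[:n].copy(),
        rna=rna_tr[:n].copy(),
        protein=prot_tr[:n].copy(),
        copy_number=copy_tr[:n].copy(),
        fluxes=flux_tr[:n].copy(),
        metabolites=met_tr[:n].copy(),
        chip_counts=chip,
        t_init=t_init,
        t_repl=t_repl,
        t_div=t_div,
        status=status,
        avg_rna=acc_rna / total_t,
        avg_protein_conc=acc_conc / total_t,
        avg_flux=acc_flux / total_t,
        avg_metabolites=acc_met / total_t,
        avg_copy_bins=acc_bins / total_t,
        daughter_rna=daughter_rna,
        daughter_protein=daughter_prot,
    )


# ---------------------------------------------------------------------------
# population bundles


@dataclass
class DataSetBundle:
    """Per-measurement means and unbiased variances across a population of
    cells, with the flat measurement registry.

    ``cell_values`` keeps the (n_divided, M) per-cell table so downstream
    analytics (coefficients of variation) do not need to re-simulate.  The
    stored variance is the sample variance across cells; whether the original
    challenge used a sample or a known model variance is not recorded there,
    and the ``variance_kind`` flag documents the assumption.
    """

    registry: pd.DataFrame
    means: np.ndarray
    variances: np.ndarray
    n_cells: int
    seed: int | None = None
    cell_values: np.ndarray | None = None
    n_undivided: int = 0
    variance_kind: str = "sample"

    def __post_init__(self):
        M = len(self.registry)
        if self.means.size != M or self.variances.size != M:
            raise ContractError("means/variances must match registry length")
        if np.any(self.variances < -1e-12):
            raise ContractError("variances must be non-negative")
        if self.n_cells <= 0:
            raise ContractError("n_cells must be positive")
        missing = set(DATA_CLASSES) - set(self.registry["data_class"])
        if missing:
            raise ContractError(f"bundle missing data classes: {sorted(missing)}")

    @property
    def M(self) -> int:
        return len(self.registry)

    def class_mask(self, data_class: str) -> np.ndarray:
        return (self.registry["data_class"] == data_class).to_numpy()

    def class_frame(self, data_class: str) -> pd.DataFrame:
        mask = self.class_mask(data_class)
        df = self.registry.loc[mask].copy()
        df["mean"] = self.means[mask]
        df["variance"] = self.variances[mask]
        return df

    def class_means(self, data_class: str, entities=None) -> np.ndarray:
        df = self.class_frame(data_class)
        if entities is not None:
            df = df.set_index("entity").loc[list(entities)].reset_index()
        return df["mean"].to_numpy()

    def scalar(self, data_class: str, entity: str) -> float:
        df = self.class_frame(data_class)
        return float(df.loc[df["entity"] == entity, "mean"].iloc[0])

    def checksum(self) -> str:
        h = hashlib.md5()
        h.update(self.means.tobytes())
        h.update(self.variances.tobytes())
        h.update(str(self.n_cells).encode())
        return h.hexdigest()

    # -- serialization: one TSV per data class + JSON manifest ---------------

    def to_dir(self, path, write_cells: bool = False):
        os.makedirs(path, exist_ok=True)
        for cls in DATA_CLASSES:
            df = self.class_frame(cls).reset_index()
            df.to_csv(
                os.path.join(path, f"{cls}.tsv"),
                sep="\t",
                index=False,
                float_format="%.17g",  # bit-exact round trip
                columns=["index", "data_class", "entity", "time", "mean", "variance"],
            )
        if write_cells and self.cell_values is not None:
            pd.DataFrame(self.cell_values).to_csv(
                os.path.join(path, "cells.tsv"),
                sep="\t",
                index=False,
                float_format="%.17g",
            )
        manifest = {
            "n_cells": self.n_cells,
            "n_undivided": self.n_undivided,
            "seed": self.seed,
            "M": self.M,
            "variance_kind": self.variance_kind,
            "registry_checksum": registry_checksum(self.registry),
            "checksum": self.checksum(),
        }
        with open(os.path.join(path, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def from_dir(cls, path) -> "DataSetBundle":
        with open(os.path.join(path, "manifest.json")) as fh:
            manifest = json.load(fh)
        frames = []
        for data_class in DATA_CLASSES:
            df = pd.read_csv(
                os.path.join(path, f"{data_class}.tsv"),
                sep="\t",
                float_precision="round_trip",
            )
            frames.append(df)
        full = pd.concat(frames).sort_values("index").set_index("index")
        registry = full[["data_class", "entity", "time"]]
        cell_values = None
        cells_path = os.path.join(path, "cells.tsv")
        if os.path.exists(cells_path):
            cell_values = pd.read_csv(
                cells_path, sep="\t", float_precision="round_trip"
            ).to_numpy(float)
        return cls(
            registry=registry,
            means=full["mean"].to_numpy(float),
            variances=full["variance"].to_numpy(float),
            n_cells=int(manifest["n_cells"]),
            seed=manifest.get("seed"),
            cell_values=cell_values,
            n_undivided=int(manifest.get("n_undivided", 0)),
            variance_kind=manifest.get("variance_kind", "sample"),
        )


def cell_measurements(
    spec: ModelSpec,
    traj: CellTrajectory,
    registry: pd.DataFrame,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Flatten one divided cell's trajectory into the measurement vector.

    ``rng`` applies the measurement dialects: the RNA array re-reads the
    latent time-averaged RNA signal through a multiplicative lognormal layer,
    RNA-seq re-reads it through count sampling at a fixed depth.  With
    ``rng=None`` (deterministic populations) both equal the latent signal.
    """
    if not traj.divided:
        raise ContractError("cannot register measurements for an undivided cell")
    out = np.empty(len(registry))
    i = 0
    for f in CYCLE_FRACTIONS:
        t = f * traj.t_div
        out[i] = np.interp(t, traj.times, traj.mass)
        out[i + 1] = np.interp(t, traj.times, traj.volume)
        out[i + 2] = np.interp(t, traj.times, traj.growth_rate)
        i += 3
    out[i : i + 3] = (traj.t_init, traj.t_repl, traj.t_div)
    i += 3
    out[i : i + spec.n_metabolites] = traj.avg_metabolites
    i += spec.n_metabolites
    out[i : i + spec.n_dna_bins] = traj.avg_copy_bins
    i += spec.n_dna_bins
    G = spec.n_genes
    latent = traj.avg_rna
    if rng is None:
        rnaseq = latent
        rna_array = latent
    else:
        depth = 10.0
        rnaseq = rng.poisson(latent * depth) / depth
        rna_array = latent * rng.lognormal(0.0, 0.1, size=G)
    out[i : i + G] = rnaseq
    i += G
    out[i : i + G] = traj.chip_counts
    i += G
    out[i : i + G] = rna_array
    i += G
    out[i : i + G] = traj.avg_protein_conc
    i += G
    out[i : i + spec.n_reactions] = traj.avg_flux
    i += spec.n_reactions
    assert i == len(registry)
    return out


def simulate_population(
    spec: ModelSpec,
    params: ParameterSet,
    n_cells: int,
    seed=0,
    mode: str = "stochastic",
    keep_cells: bool = True,
) -> DataSetBundle:
    """Simulate ``n_cells`` independent cells and assemble the eight-class
    data bundle (per-measurement mean and unbiased variance across cells)."""
    if n_cells < 2:
        raise ContractError("n_cells must be >= 2 for variances to be defined")
    registry = build_registry(spec)
    ss = as_seed_sequence(seed)
    cell_seeds = ss.spawn(n_cells)
    noise_rng = np.random.default_rng(ss.spawn(1)[0])

    rows = []
    n_undivided = 0
    for k in range(n_cells):
        traj = simulate_cell(spec, params, seed=cell_seeds[k], mode=mode)
        if not traj.divided:
            n_undivided += 1
            continue
        rng = noise_rng if mode == "stochastic" else None
        rows.append(cell_measurements(spec, traj, registry, rng))
    if len(rows) < 2:
        raise EstimationImpossibleError(
            f"only {len(rows)} of {n_cells} cells divided; bundle undefined"
        )
    table = np.asarray(rows)
    means = table.mean(axis=0)
    variances = table.var(axis=0, ddof=1)
    return DataSetBundle(
        registry=registry,
        means=means,
        variances=variances,
        n_cells=n_cells,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        cell_values=table if keep_cells else None,
        n_undivided=n_undivided,
    )


def doubling_time(source) -> float:
    """Mean cytokinesis time.

    Accepts a single trajectory, an iterable of trajectories (undivided cells
    are excluded and counted -- see ``doubling_time_report``), or a
    ``DataSetBundle`` (reads the registered mean division time).
    """
    return doubling_time_report(source)[0]


def doubling_time_report(source):
    if isinstance(source, DataSetBundle):
        return source.scalar("single_cell", "t_div"), 0
    if isinstance(source, CellTrajectory):
        source = [source]
    divided = [tr.t_div for tr in source if tr.divided]
    n_undivided = sum(1 for tr in source if not tr.divided)
    if not divided:
        raise EstimationImpossibleError("no divided cells")
    return float(np.mean(divided)), n_undivided
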