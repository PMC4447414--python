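"""Single-cell dynamics, population bundles, and their invariants."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from wcbench import toycell as tc

LN2 = np.log(2.0)


def test_no_transcription_limit(spec):
    """Silencing every promoter empties RNA and metabolic protein pools and
    pins growth at the clipped floor."""
    params = spec.wildtype.with_values(
        {spec.binding_name(g): 1e-12 for g in range(spec.n_genes)}
    )
    traj = tc.simulate_cell(spec, params, seed=1, mode="stochastic")
    assert np.all(traj.rna == 0)
    metabolic = spec.metabolic_gene_indices
    assert np.all(traj.protein[:, metabolic] == 0)
    mu_floor = spec.constants.mu0 * spec.constants.ratio_floor
    assert np.allclose(traj.growth_rate, mu_floor)


def test_no_decay_limit(spec):
    """With effectively infinite half-lives, deterministic RNA counts never
    decrease."""
    params = spec.wildtype.with_values(
        {spec.halflife_name(g): 1e9 for g in range(spec.n_genes)}
    )
    traj = tc.simulate_cell(spec, params, mode="deterministic")
    assert np.all(np.diff(traj.rna, axis=0) >= -1e-9)


def test_steady_state_rna_matches_ode_oracle(spec):
    """Pre-replication deterministic RNA sits at the birth-death steady
    state c * p * k_txn * t_half / ln2, cross-checked against an independent
    scipy ODE integration."""
    traj = tc.simulate_cell(spec, spec.wildtype, mode="deterministic")
    p, th, _ = spec.param_arrays(spec.wildtype)
    expected = p * spec.constants.k_txn * th / LN2
    i = np.searchsorted(traj.times, 0.2)  # burn-in, before initiation
    assert traj.times[i] < traj.t_init
    assert np.allclose(traj.rna[i], expected, rtol=0.01)

    # independent oracle: integrate dR/dt = a - ln2/t_half * R per gene
    a = p * spec.constants.k_txn
    sol = solve_ivp(
        lambda t, r: a - (LN2 / th) * r,
        (0.0, traj.times[i]),
        expected,  # start at the analytic steady state, as the cell does
        rtol=1e-10,
        atol=1e-12,
    )
    assert np.allclose(traj.rna[i], sol.y[:, -1], rtol=0.01)


def test_trajectory_invariants(spec):
    traj = tc.simulate_cell(spec, spec.wildtype, seed=5, mode="stochastic")
    assert traj.status == "divided"
    assert np.all(traj.mass > 0)
    assert np.all(np.diff(traj.mass) >= 0)
    assert set(np.unique(traj.copy_number)) <= {1, 2}
    assert np.all(np.diff(traj.copy_number, axis=0) >= 0)
    assert traj.t_init <= traj.t_repl <= traj.t_div + 1e-12
    assert np.all(traj.rna >= 0) and np.all(traj.protein >= 0)
    assert np.all(traj.rna == np.round(traj.rna))  # integer counts


def test_mass_log_identity(spec):
    """Growth bookkeeping: log mass increments equal sum log(1 + mu dt)."""
    traj = tc.simulate_cell(spec, spec.wildtype, seed=2, mode="stochastic")
    dt = spec.constants.dt
    lhs = np.log(traj.mass[-1] / traj.mass[0])
    rhs = np.sum(np.log1p(traj.growth_rate[1:] * dt))
    assert abs(lhs - rhs) < 1e-9


@pytest.mark.parametrize("which", ["kcat", "binding"])
def test_monotone_parameter_response(spec, which):
    """Deterministic mode: less enzyme activity never shortens the cycle,
    more transcription of a metabolic gene never lengthens it."""
    t_wt = tc.simulate_cell(spec, spec.wildtype, mode="deterministic").t_div
    for idx in (0, 4):
        if which == "kcat":
            name = spec.kcat_name(idx)
            params = spec.wildtype.with_value(
                name, spec.wildtype.value(name) * 0.7
            )
            t_mut = tc.simulate_cell(spec, params, mode="deterministic").t_div
            assert t_mut >= t_wt - 1e-9
        else:
            g = spec.metabolic_gene_indices[idx]
            name = spec.binding_name(g)
            params = spec.wildtype.with_value(
                name, min(spec.wildtype.value(name) * 1.3, 1.0)
            )
            t_mut = tc.simulate_cell(spec, params, mode="deterministic").t_div
            assert t_mut <= t_wt + 1e-9


def test_population_determinism(spec):
    b1 = tc.simulate_population(spec, spec.wildtype, 8, seed=42)
    b2 = tc.simulate_population(spec, spec.wildtype, 8, seed=42)
    assert b1.checksum() == b2.checksum()
    assert np.array_equal(b1.cell_values, b2.cell_values)


def test_deterministic_population_zero_variance(spec):
    b = tc.simulate_population(spec, spec.wildtype, 4, mode="deterministic")
    assert np.allclose(b.variances, 0.0)


def test_population_contract_errors(spec):
    with pytest.raises(tc.ContractError):
        tc.simulate_population(spec, spec.wildtype, 1, seed=0)


def test_dnaseq_gradient_and_bookkeeping_oracle(spec, pkg):
    """The DNA-seq profile decreases from oriC to terC, and the simulated
    per-bin time averages match the analytic fork-geometry bookkeeping."""
    means = pkg.mutant_bundle.class_means("dnaseq")
    assert np.all(np.diff(means) <= 1e-9)

    traj = tc.simulate_cell(spec, spec.wildtype, mode="deterministic")
    t_pass = traj.t_init + spec.dna_bin_distances / spec.constants.fork_speed
    expected = 1.0 + np.clip(traj.t_div - t_pass, 0.0, None) / traj.t_div
    assert np.allclose(traj.avg_copy_bins, expected, atol=2 * spec.constants.dt)


def test_seed_independence_of_population_means(spec):
    """Means from two independent 32-cell populations agree within four
    standard errors."""
    b1 = tc.simulate_population(spec, spec.wildtype, 32, seed=101)
    b2 = tc.simulate_population(spec, spec.wildtype, 32, seed=202)
    se = np.sqrt((b1.variances + b2.variances) / 32)
    ok = se > 0
    z = np.abs(b1.means[ok] - b2.means[ok]) / se[ok]
    assert np.all(z < 4.0)


def test_doubling_time():
    make = lambda t, status="divided": tc.CellTrajectory(
        times=np.array([0.0, t]),
        mass=np.array([1.0, 2.0]),
        volume=np.array([1.0, 2.0]),
        growth_rate=np.zeros(2),
        rna=np.zeros((2, 1)),
        protein=np.zeros((2, 1)),
        copy_number=np.ones((2, 1), dtype=int),
        fluxes=np.zeros((2, 1)),
        metabolites=np.zeros((2, 1)),
        chip_counts=np.zeros(1),
        t_init=0.1,
        t_repl=0.5,
        t_div=t if status == "divided" else np.nan,
        status=status,
        avg_rna=np.zeros(1),
        avg_protein_conc=np.zeros(1),
        avg_flux=np.zeros(1),
        avg_metabolites=np.zeros(1),
        avg_copy_bins=np.zeros(1),
    )
    assert tc.doubling_time(make(2.0)) == 2.0
    assert tc.doubling_time([make(1.0), make(3.0)]) == 2.0
    mean, n_undiv = tc.doubling_time_report([make(1.0), make(3.0, "timeout")])
    assert mean == 1.0 and n_undiv == 1
    with pytest.raises(tc.EstimationImpossibleError):
        tc.doubling_time([make(1.0, "timeout")])


def test_doubling_time_against_division_rule_oracle(spec):
    """Re-apply the division condition (replication complete and mass
    doubled) to the recorded trajectory, independently of the simulator's
    own bookkeeping."""
    traj = tc.simulate_cell(spec, spec.wildtype, mode="deterministic")
    crossed = traj.mass >= 2.0 * spec.constants.initial_mass
    t_mass = traj.times[np.argmax(crossed)]
    oracle = max(t_mass, traj.t_repl)
    assert abs(traj.t_div - oracle) <= spec.constants.dt + 1e-12


def test_invalid_parameters(spec):
    with pytest.raises(tc.InvalidParameterError):
        tc.ParameterSet(("a",), ("rna_half_life",), np.array([-1.0]))
    with pytest.raises(tc.InvalidParameterError):
        tc.ParameterSet(("a",), ("binding_probability",), np.array([1.5]))
    with pytest.raises(tc.InvalidParameterError):
        tc.ParameterSet(("a", "a"), ("rna_half_life",) * 2, np.ones(2))


def test_bundle_roundtrip(spec, tmp_path):
    bundle = tc.simulate_population(spec, spec.wildtype, 4, seed=9)
    bundle.to_dir(tmp_path / "b", write_cells=True)
    back = tc.DataSetBundle.from_dir(tmp_path / "b")
    assert np.allclose(back.means, bundle.means)
    assert np.allclose(back.variances, bundle.variances)
    assert back.n_cells == bundle.n_cells
    assert np.allclose(back.cell_values, bundle.cell_values)
    assert back.checksum() == bundle.checksum()


def test_spec_roundtrip(spec, tmp_path):
    spec.save(tmp_path / "spec.json")
    back = tc.ModelSpec.load(tmp_path / "spec.json")
    assert back.gene_names == spec.gene_names
    assert np.allclose(back.gene_positions, spec.gene_positions)
    assert np.allclose(back.wildtype.values, spec.wildtype.values)
    assert back.constants == spec.constants
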