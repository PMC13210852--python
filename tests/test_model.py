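"""Core model: spatial operators, conservation structure, integration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

import enzfilm as ez
from enzfilm.model import _deinterleave, _interleave, _rhs_interleaved

from conftest import random_state


def uniform_state(N, **kw):
    fields = {s: np.full(N, kw.get(s, 0.0)) for s in ("E", "C", "A", "EC", "EA", "P")}
    return ez.StateField(**fields)


# ---------------------------------------------------------------------------
# porosity and diffusivity
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("C,A,phi", [
    (0.302, 0.698, 0.0),   # pristine film: dense polymer
    (0.0, 0.0, 1.0),       # fully degraded limit
    (0.1, 0.4, 0.5),
])
def test_porosity_values(C, A, phi):
    state = uniform_state(5, C=C, A=A)
    assert np.allclose(ez.porosity(state), phi)


def test_porosity_clipped_to_unit_interval():
    state = uniform_state(3, C=0.7, A=0.6)  # overshoot: C+A>1
    assert np.all(ez.porosity(state) == 0.0)


@pytest.mark.parametrize("phi,De0,alpha,expected", [
    (0.0, 1.66, 1.0, 1.66),   # dense-polymer limit
    (1.0, 1.0, 1.0, 2.0),
    (0.5, 1.66, 1.0, 2.49),
])
def test_effective_diffusivity(phi, De0, alpha, expected):
    tr = ez.TransportParameters(De0=De0, alpha_e=alpha)
    got = ez.effective_diffusivity(np.array([phi]), tr)
    assert got[0] == pytest.approx(expected, rel=1e-12)


@given(phi1=st.floats(0, 1), phi2=st.floats(0, 1))
@settings(max_examples=50, deadline=None)
def test_effective_diffusivity_monotone(phi1, phi2):
    tr = ez.TransportParameters(De0=1.66, alpha_e=1.0)
    lo, hi = sorted([phi1, phi2])
    d = ez.effective_diffusivity(np.array([lo, hi]), tr)
    assert d[0] <= d[1]


# ---------------------------------------------------------------------------
# reaction structure
# ---------------------------------------------------------------------------

def test_reaction_rates_zero_without_enzyme(case_config):
    state = uniform_state(7, C=0.302, A=0.698)
    rates = ez.reaction_rates(state, case_config.kinetics)
    for v in rates.values():
        assert np.all(v == 0.0)


def test_reaction_conservation_random_states(case_config, rng):
    """Polymer and enzyme totals are conserved algebraically by the scheme."""
    kin = case_config.kinetics
    for _ in range(20):
        state = random_state(rng)
        r = ez.reaction_rates(state, kin)
        polymer = r["C"] + r["A"] + r["EC"] + r["EA"] + r["P"]
        enzyme = r["E"] + r["EC"] + r["EA"]
        assert np.allclose(polymer, 0.0, atol=1e-14)
        assert np.allclose(enzyme, 0.0, atol=1e-14)


def test_rhs_diffusion_only_in_enzyme_block(case_config, rng):
    cfg = case_config
    geom = ez.Geometry(L=0.25, N=9)
    state = random_state(rng, N=9)
    full = ez.assemble_rhs(state, cfg.kinetics, cfg.transport, geom)
    r = ez.reaction_rates(state, cfg.kinetics)
    react = np.concatenate([r[s] for s in ("E", "C", "A", "EC", "EA", "P")])
    diff = full - react
    N = 9
    assert np.any(diff[:N] != 0.0)       # E block carries the operator
    assert np.all(diff[N:] == 0.0)       # immobile species, products removed


def test_rhs_zero_gradient_no_diffusion(case_config):
    geom = ez.Geometry(L=0.25, N=9)
    state = uniform_state(9, E=0.7, C=0.3, A=0.3)
    full = ez.assemble_rhs(state, case_config.kinetics, case_config.transport, geom)
    r = ez.reaction_rates(state, case_config.kinetics)
    # interior nodes: no diffusive contribution for a flat E field
    assert np.allclose(full[1:9], r["E"][1:], atol=1e-12)


def test_rhs_fickian_inflow_sign(case_config):
    geom = ez.Geometry(L=0.25, N=9)
    state = uniform_state(9, C=0.302, A=0.698)
    state.E[0] = 1.0
    full = ez.assemble_rhs(state, case_config.kinetics, case_config.transport, geom)
    assert full[1] > 0.0  # node next to the surface receives inflow


def test_compiled_kernel_matches_reference(case_config, rng):
    """The interleaved compiled RHS equals the numpy reference operator."""
    cfg = case_config
    geom = ez.Geometry(L=0.25, N=11)
    for _ in range(5):
        state = random_state(rng, N=11)
        ref = ez.assemble_rhs(state, cfg.kinetics, cfg.transport, geom)
        y = _interleave(state.to_vector(), 11)
        k = cfg.kinetics
        got = _rhs_interleaved(y, 11, 1.0 / geom.dx ** 2, k.k1, k.k_m1, k.k3,
                               k.k_m3, k.k_conv, k.k_deg_C, k.k_deg_A,
                               cfg.transport.De0, cfg.transport.alpha_e)
        # reference keeps reaction terms at the pinned node out as well
        assert np.allclose(_deinterleave(got, 11), ref, atol=1e-13)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def test_parameter_validation():
    with pytest.raises(ValueError):
        ez.KineticParameters(-1, 0, 0, 0, 0, 0, 0)
    with pytest.raises(ValueError):
        ez.TransportParameters(De0=0.0)
    with pytest.raises(ValueError):
        ez.Geometry(L=0.25, N=2)
    with pytest.raises(ValueError):
        ez.InitialComposition(C0=0.5, A0=0.4)
    with pytest.raises(ValueError):
        ez.SolverSettings(rtol=-1)
    with pytest.raises(ValueError):
        ez.SolverSettings(output_times=(5.0, 1.0))


def test_geometry_grid():
    g = ez.Geometry(L=0.25, N=25)
    assert g.dx * (g.N - 1) == pytest.approx(g.L, abs=0)
    assert np.allclose(np.diff(g.x), g.dx)
    assert ez.grid_points_for(0.25) == 25
    # thicker films keep at least the case-study resolution
    assert ez.grid_points_for(4.0) >= 4.0 / ez.CASE_STUDY_DX


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def test_inert_film_pure_diffusion(case_config):
    """With all rate constants zero the enzyme just fills the film."""
    kin = ez.KineticParameters(0, 0, 0, 0, 0, 0, 0)
    cfg = case_config
    traj = ez.simulate(kin, cfg.transport, cfg.geometry, cfg.initial,
                       ez.SolverSettings(t_end=10.0, output_times=(0.0, 10.0)))
    final = traj.states[-1]
    assert np.allclose(final.E, 1.0, atol=1e-5)
    assert np.allclose(final.C, 0.302, atol=1e-9)
    assert np.allclose(final.A, 0.698, atol=1e-9)
    assert np.allclose(final.P, 0.0, atol=1e-9)


def test_polymer_mass_conserved_case_study(case_trajectory, case_config):
    atol = case_config.solver.atol
    for s in case_trajectory.states:
        assert np.max(np.abs(s.polymer_total() - 1.0)) < 10 * atol


def test_trajectory_initial_state(case_trajectory):
    s0 = case_trajectory.states[0]
    assert s0.E[0] == 1.0 and np.all(s0.E[1:] == 0.0)
    assert np.all(s0.C == 0.302) and np.all(s0.EC == 0.0)


def test_state_bounds_along_trajectory(case_trajectory):
    for s in case_trajectory.states:
        for name in ("C", "A", "EC", "EA", "P"):
            assert getattr(s, name).min() > -1e-6
        # E may overshoot the bath value by the solver tolerance scale
        assert s.E.min() > -1e-6 and s.E.max() < 1.0 + 1e-4


def test_lsoda_and_bdf_paths_agree(case_config):
    cfgL = ez.case_study_config(method="LSODA")
    tB = ez.simulate(case_config.kinetics, case_config.transport,
                     case_config.geometry, case_config.initial,
                     case_config.solver)
    tL = ez.simulate(cfgL.kinetics, cfgL.transport, cfgL.geometry,
                     cfgL.initial, cfgL.solver)
    d = max(np.max(np.abs(a.to_vector() - b.to_vector()))
            for a, b in zip(tB.states, tL.states))
    assert d < 1e-5


def test_grid_convergence_weight_loss():
    """N=25/50/100 agree to well under half a percentage point."""
    wl = {}
    for N in (25, 50, 100):
        cfg = ez.case_study_config(N=N, method="LSODA")
        traj = ez.simulate(cfg.kinetics, cfg.transport, cfg.geometry,
                           cfg.initial, cfg.solver)
        s = ez.observable_series(traj, cfg.geometry, cfg.initial)
        wl[N] = s.weight_loss_pct
    assert np.max(np.abs(wl[25] - wl[100])) < 0.5
    assert np.max(np.abs(wl[50] - wl[100])) < 0.5


def test_explicit_euler_oracle_small_instance(case_config):
    """Independent fixed-step explicit Euler on the reference operator
    reproduces the stiff solution of a small instance to 1e-4."""
    cfg = case_config
    geom = ez.Geometry(L=0.05, N=6)
    t_end = 1.0
    traj = ez.simulate(cfg.kinetics, cfg.transport, geom, cfg.initial,
                       ez.SolverSettings(t_end=t_end, output_times=(0.0, t_end)))

    De_max = cfg.transport.De0 * (1 + cfg.transport.alpha_e)
    dt_stab = geom.dx ** 2 / (2 * De_max)
    dt = 0.2 * dt_stab
    n_steps = int(np.ceil(t_end / dt))
    dt = t_end / n_steps
    state = ez.StateField.initial(geom, cfg.initial)
    y = state.to_vector()
    for _ in range(n_steps):
        y = y + dt * ez.assemble_rhs(ez.StateField.from_vector(y),
                                     cfg.kinetics, cfg.transport, geom)
    final = traj.states[-1].to_vector()
    assert np.max(np.abs(y - final)) < 1e-4


def test_well_mixed_limit_matrix_exponential(case_config):
    """As De0 -> inf, the polymer subsystem follows the E=1 linear system."""
    k = case_config.kinetics
    M = np.array([
        [-k.k1, 0, k.k_m1, 0, 0],
        [0, -k.k3, k.k_conv, k.k_m3, 0],
        [k.k1, 0, -(k.k_m1 + k.k_conv + k.k_deg_C), 0, 0],
        [0, k.k3, 0, -(k.k_m3 + k.k_deg_A), 0],
        [0, 0, k.k_deg_C, k.k_deg_A, 0]])
    y0 = np.array([0.302, 0.698, 0, 0, 0])
    big = ez.TransportParameters(De0=1e6, alpha_e=1.0)
    traj = ez.simulate(k, big, case_config.geometry, case_config.initial,
                       case_config.solver)
    for t, s in zip(traj.times, traj.states):
        ref = expm(M * t) @ y0
        num = np.array([s.C.mean(), s.A.mean(), s.EC.mean(),
                        s.EA.mean(), s.P.mean()])
        assert np.max(np.abs(num - ref)) < 1e-4


def test_enzyme_balance_against_boundary_flux(dense_trajectory, case_config):
    bal = ez.enzyme_balance(dense_trajectory, case_config.transport,
                            case_config.geometry, t_min=2.0)
    assert bal["relative_mismatch"] < 0.01


def test_alpha_e_robustness(case_config):
    """Observable curves barely move over alpha_e in [0.5, 5]."""
    curves = {}
    for ae in (0.5, 1.0, 5.0):
        tr = ez.TransportParameters(De0=1.66, alpha_e=ae)
        cfg = ez.case_study_config(method="LSODA")
        traj = ez.simulate(cfg.kinetics, tr, cfg.geometry, cfg.initial,
                           cfg.solver)
        s = ez.observable_series(traj, cfg.geometry, cfg.initial)
        curves[ae] = (s.weight_loss_pct, s.crystallinity_pct)
    for ae in (0.5, 5.0):
        assert np.max(np.abs(curves[ae][0] - curves[1.0][0])) < 1.0
        assert np.max(np.abs(curves[ae][1] - curves[1.0][1])) < 1.0


def test_simulation_failure_reports_time():
    exc = ez.SimulationError("boom", t_reached=3.5)
    assert exc.t_reached == 3.5


def test_trajectory_frame_layout(case_trajectory, case_config):
    df = ez.trajectory_frame(case_trajectory, case_config.geometry)
    assert list(df.columns) == ["time_h", "x_mm", "E", "C", "A", "EC", "EA", "P"]
    assert len(df) == len(case_trajectory.times) * case_config.geometry.N
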