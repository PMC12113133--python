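"""ODE assembly, closed-form motifs, conservation and steady-state logic."""

import numpy as np
import pytest
from scipy.linalg import expm

from plk1net import (
    InitialConditionPolicy,
    NetworkModel,
    ParameterSource,
    Reaction,
    ReactionType,
    SimulationSettings,
    Species,
    SpeciesKind,
    assemble_odes,
    assign_parameters,
    build_rate_law,
    detect_steady_state,
    parameters_from_model,
    phenotype_mask_for,
    simulate,
)
from plk1net.mass_action_engine import ParameterError, initial_state
from plk1net.synthetic_data import (
    NetworkGenSpec,
    ParamGenSpec,
    generate_network,
    generate_parameters,
)
from plk1net.network_construction import build_network

from conftest import central_dogma_motif, closed_association_motif, decay_motif


class TestAssignParameters:
    def test_all_defaults(self, motif):
        table = assign_parameters(motif)
        assert len(table) == 4
        assert all(src is ParameterSource.DEFAULT_BY_TYPE
                   for _, src in table.entries.values())

    def test_curated_wins(self, motif):
        table = assign_parameters(motif, curated={"deg_p_X": 0.3})
        assert table.entries["deg_p_X"] == (0.3, ParameterSource.CURATED)
        assert table.n_curated() == 1

    def test_nonpositive_curated_rejected(self, motif):
        with pytest.raises(ParameterError, match="deg_p_X"):
            assign_parameters(motif, curated={"deg_p_X": 0.0})


class TestRateLaw:
    def test_degradation(self):
        rx = Reaction("d", ReactionType.DEGRADATION, reactants=(("S", 1),))
        assert build_rate_law(rx, 1.0)({"S": 5.0}) == pytest.approx(5.0)

    def test_transcription_zero_order_with_modifier(self):
        rx = Reaction("t", ReactionType.TRANSCRIPTION,
                      products=(("m", 1),), modifiers=("G",))
        assert build_rate_law(rx, 2.0)({"G": 1.0, "m": 7.0}) == pytest.approx(2.0)

    def test_association_hand_product(self):
        rx = Reaction("a", ReactionType.ASSOCIATION,
                      reactants=(("A", 1), ("B", 1)), products=(("C", 1),))
        assert build_rate_law(rx, 0.1)({"A": 2.0, "B": 3.0}) == pytest.approx(0.6)


class TestAssembleOdes:
    def test_central_dogma_textbook_form(self, motif):
        rhs, sids = assemble_odes(motif, parameters_from_model(motif))
        i = {s: j for j, s in enumerate(sids)}
        y = np.zeros(3)
        y[i["g_X"]], y[i["m_X"]], y[i["p_X"]] = 1.0, 0.5, 0.25
        dy = rhs(0.0, y)
        # d[m]/dt = k_tr*G - d_m*m ; d[p]/dt = k_tl*m - d_p*p
        assert dy[i["m_X"]] == pytest.approx(2.0 * 1.0 - 1.0 * 0.5)
        assert dy[i["p_X"]] == pytest.approx(3.0 * 0.5 - 2.0 * 0.25)
        assert dy[i["g_X"]] == 0.0

    def test_rhs_matches_naive_accumulation_on_random_models(self, rng):
        """Brute-force per-reaction accumulation oracle, many random models."""
        for s in range(20):
            records, _d, _t = generate_network(
                NetworkGenSpec(n_proteins=10, n_processes=2, seed=s))
            model = build_network(records)
            params = generate_parameters(model, ParamGenSpec(seed=s))
            rhs, sids = assemble_odes(model, params)
            for _ in range(5):
                y = rng.random(len(sids)) * 3.0
                conc = dict(zip(sids, y))
                naive = {sid: 0.0 for sid in sids}
                for rx in model.reactions.values():
                    v = build_rate_law(rx, params.k(rx.id))(conc)
                    for sid, n in rx.reactants:
                        naive[sid] -= n * v
                    for sid, n in rx.products:
                        naive[sid] += n * v
                for sid in sids:
                    if model.species[sid].kind is SpeciesKind.GENE:
                        naive[sid] = 0.0
                expected = np.array([naive[sid] for sid in sids])
                got = rhs(0.0, y)
                scale = np.maximum(np.abs(expected), 1.0)
                assert np.all(np.abs(got - expected) / scale < 1e-12)

    def test_phenotype_derivative_nonnegative(self):
        model = decay_motif(with_phenotype=True)
        rhs, sids = assemble_odes(model, parameters_from_model(model))
        for y in (np.array([0.0, 0.0]), np.array([2.0, 1.0])):
            dy = rhs(0.0, y)
            assert dy[sids.index("ph_OUT")] >= 0.0


class TestSimulate:
    def test_pure_decay_closed_form(self):
        model = decay_motif(k=1.0)
        policy = InitialConditionPolicy()  # free-form protein starts at 5 µM
        settings = SimulationSettings(n_intervals=150, interval_hours=0.28)
        traj = simulate(model, parameters_from_model(model), policy, settings)
        expected = 5.0 * np.exp(-traj.times)
        got = traj.series("p_S")
        mask = expected > 1e-6
        assert np.allclose(got[mask], expected[mask], rtol=1e-5)
        assert got[1] == pytest.approx(5.0 * np.exp(-0.28), rel=1e-5)

    def test_central_dogma_unit_steady_state(self):
        motif = central_dogma_motif(k_tr=1, d_m=1, k_tl=1, d_p=1)
        traj = simulate(motif, parameters_from_model(motif),
                        InitialConditionPolicy(),
                        SimulationSettings(n_intervals=150))
        assert traj.series("m_X")[-1] == pytest.approx(1.0, rel=1e-4)
        assert traj.series("p_X")[-1] == pytest.approx(1.0, rel=1e-4)

    def test_central_dogma_parameterised_steady_state(self, motif):
        # k_tr=2, d_m=1, k_tl=3, d_p=2 -> m* = 2, p* = 3
        traj = simulate(motif, parameters_from_model(motif))
        assert traj.series("m_X")[-1] == pytest.approx(2.0, rel=1e-4)
        assert traj.series("p_X")[-1] == pytest.approx(3.0, rel=1e-4)

    def test_moiety_conservation_in_closed_association(self):
        model = closed_association_motif(k=0.3)
        policy = InitialConditionPolicy(overrides={"p_A": 4.0, "p_B": 2.0,
                                                   "cx_C": 0.0})
        traj = simulate(model, parameters_from_model(model), policy,
                        SimulationSettings(n_intervals=150))
        total_a = traj.series("p_A") + traj.series("cx_C")
        total_b = traj.series("p_B") + traj.series("cx_C")
        assert np.all(np.abs(total_a - 4.0) / 4.0 < 1e-8)
        assert np.all(np.abs(total_b - 2.0) / 2.0 < 1e-8)

    def test_gene_trajectories_exactly_constant(self, motif):
        traj = simulate(motif, parameters_from_model(motif))
        assert np.all(traj.series("g_X") == traj.series("g_X")[0])

    def test_concentrations_nonnegative(self):
        records, _d, _t = generate_network(NetworkGenSpec(seed=13))
        model = build_network(records)
        traj = simulate(model, parameters_from_model(model))
        assert traj.concentrations.min() >= 0.0

    def test_phenotype_trajectories_nondecreasing(self):
        model = decay_motif(with_phenotype=True)
        traj = simulate(model, parameters_from_model(model))
        ph = traj.series("ph_OUT")
        assert np.all(np.diff(ph) >= -1e-9)

    def test_linear_subsystem_matches_matrix_exponential(self):
        # A -> B -> C chain with degradation everywhere: dy/dt = M y
        model = NetworkModel(
            species=[Species(f"p_{n}", n, SpeciesKind.PROTEIN, free_form=True)
                     for n in "ABC"],
            reactions=[
                Reaction("ab", ReactionType.STATE_TRANSITION,
                         reactants=(("p_A", 1),), products=(("p_B", 1),), k=1.2),
                Reaction("bc", ReactionType.STATE_TRANSITION,
                         reactants=(("p_B", 1),), products=(("p_C", 1),), k=0.7),
                Reaction("da", ReactionType.DEGRADATION,
                         reactants=(("p_A", 1),), k=0.2),
                Reaction("dc", ReactionType.DEGRADATION,
                         reactants=(("p_C", 1),), k=0.4),
            ],
        )
        M = np.array([[-1.4, 0.0, 0.0],
                      [1.2, -0.7, 0.0],
                      [0.0, 0.7, -0.4]])
        y0 = np.array([5.0, 5.0, 5.0])
        settings = SimulationSettings(n_intervals=100)
        traj = simulate(model, parameters_from_model(model),
                        InitialConditionPolicy(), settings)
        expected = expm(M * settings.horizon_hours) @ y0
        got = traj.concentrations[-1]
        assert np.allclose(got, expected, rtol=1e-6, atol=1e-9)


class TestSteadyStateDetection:
    def test_constant_trajectory_reached_at_first_interval(self, motif):
        params = parameters_from_model(motif)
        rhs, sids = assemble_odes(motif, params)
        from plk1net import Trajectory

        times = np.linspace(0, 2.8, 11)
        y = np.tile([1.0, 2.0, 3.0], (11, 1))  # m*=2, p*=3 exactly
        traj = Trajectory(times=times, concentrations=y, species_ids=sids)
        rep = detect_steady_state(traj, rhs)
        assert rep.reached and rep.first_interval == 1

    def test_decay_crossing_matches_analytic_solve(self):
        # C(t) = C0 e^{-kt}; below the floor the residual is k·C/floor, so the
        # criterion ε first holds when C < ε·floor/k: t* = ln(C0·k/(ε·floor))/k
        model = decay_motif(k=1.0)
        params = parameters_from_model(model)
        settings = SimulationSettings(n_intervals=150)
        traj = simulate(model, params, InitialConditionPolicy(), settings)
        rhs, sids = assemble_odes(model, params)
        rep = detect_steady_state(traj, rhs, criterion=0.1, floor=1e-2)
        t_star = np.log(5.0 / (0.1 * 1e-2)) / 1.0
        expected_interval = int(np.ceil(t_star / settings.interval_hours))
        assert rep.reached
        assert abs(rep.first_interval - expected_interval) <= 1

    def test_too_short_trajectory_rejected(self, motif):
        from plk1net import Plk1NetError, Trajectory

        rhs, sids = assemble_odes(motif, parameters_from_model(motif))
        traj = Trajectory(times=np.array([0.0, 0.28]),
                          concentrations=np.zeros((2, 3)), species_ids=sids)
        with pytest.raises(Plk1NetError):
            detect_steady_state(traj, rhs)


def test_initial_condition_policy_rules(motif):
    policy = InitialConditionPolicy(overrides={"m_X": 0.7})
    y0 = initial_state(motif, policy)
    sids = list(motif.species)
    assert y0[sids.index("g_X")] == 1.0
    assert y0[sids.index("m_X")] == 0.7
    assert y0[sids.index("p_X")] == 0.0
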