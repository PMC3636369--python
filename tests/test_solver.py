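import numpy as np
import pytest
from scipy.linalg import expm

from ldfkit import fixtures as fx
from ldfkit.landscape import LandscapeSystem
from ldfkit.nuclides import ValidationError
from ldfkit.object_model import RL
from ldfkit.solver import (
    ReleaseScenario,
    bateman_solution,
    integrate,
    mass_balance_audit,
    propagate,
    steady_state,
)


def scalar_system(k, s):
    """One compartment with loss rate k and constant source s."""
    return (lambda t: np.array([[-k]])), (lambda t: np.array([s]))


class TestPropagate:
    def test_zero_release_stays_zero(self, decay_graph, chain_library):
        system = LandscapeSystem(decay_graph, chain_library, "Syn1")
        scn = ReleaseScenario(
            mode="constant", nuclide="Syn1", target_objects={"obj1": 1.0},
            rate=0.0, start=0.0,
        )
        sol = integrate(system, scn, (0.0, 100.0))
        assert np.all(sol.states == 0.0)

    def test_single_compartment_closed_form(self):
        # A(t) = (S/k)(1 - exp(-k t))
        k, s = 0.35, 2.0
        mat, src = scalar_system(k, s)
        grid = np.linspace(0.0, 30.0, 61)
        out = propagate(mat, src, np.zeros(1), grid, grid)
        expected = (s / k) * (1.0 - np.exp(-k * grid))
        assert np.allclose(out[:, 0], expected, rtol=1e-10)

    def test_linearity_in_source(self, decay_graph, chain_library):
        system = LandscapeSystem(decay_graph, chain_library, "Syn1")
        grid = np.linspace(0.0, 500.0, 11)

        def run(rate):
            scn = ReleaseScenario(
                mode="constant", nuclide="Syn1", target_objects={"obj1": 1.0},
                rate=rate, start=0.0,
            )
            return integrate(system, scn, (0.0, 500.0), output_grid=grid).states

        a, b = run(1.0), run(2.0)
        assert np.allclose(2.0 * a, b, rtol=1e-12, atol=1e-300)

    def test_pulse_response_is_time_invariant_shift(self, decay_graph, chain_library):
        """Superposition basis: shifting the pulse shifts the response."""
        system = LandscapeSystem(decay_graph, chain_library, "Syn1")
        shift = 50.0

        def run(start, grid):
            scn = ReleaseScenario(
                mode="pulse", nuclide="Syn1", target_objects={"obj1": 1.0},
                amount=1.0, start=start, duration=1.0,
            )
            return integrate(system, scn, (0.0, 600.0), output_grid=grid).states

        grid = np.linspace(100.0, 500.0, 21)
        early = run(0.0, grid)
        late = run(shift, grid + shift)
        assert np.allclose(early, late, rtol=1e-10, atol=1e-300)

    def test_negative_span_rejected(self, decay_graph, chain_library):
        system = LandscapeSystem(decay_graph, chain_library, "Syn1")
        scn = ReleaseScenario(
            mode="constant", nuclide="Syn1", target_objects={"obj1": 1.0}
        )
        with pytest.raises(ValidationError):
            integrate(system, scn, (10.0, 0.0))


class TestBateman:
    def test_single_member_exponential(self):
        lam = np.array([0.01])
        t = np.linspace(0.0, 500.0, 50)
        got = bateman_solution(lam, np.array([2.0]), t)
        assert np.allclose(got[:, 0], 2.0 * np.exp(-0.01 * t), rtol=1e-12)

    def test_two_member_chain_vs_matrix_exponential(self):
        lam = np.array([0.02, 0.005])
        D = np.array([[-lam[0], 0.0], [lam[1], -lam[1]]])
        a0 = np.array([3.0, 0.5])
        t = np.linspace(0.0, 1000.0, 101)
        ref = np.array([expm(D * ti) @ a0 for ti in t])
        got = bateman_solution(lam, a0, t)
        assert np.max(np.abs(got - ref) / np.maximum(ref, 1e-300)) < 1e-10

    def test_fast_daughter_reaches_secular_equilibrium(self):
        lam = np.array([1e-4, 10.0])
        t = np.array([5.0])  # many daughter half-lives, parent barely decayed
        got = bateman_solution(lam, np.array([1.0, 0.0]), t)
        parent = got[0, 0]
        assert got[0, 1] == pytest.approx(parent, rel=1e-3)

    def test_near_equal_constants_are_stable(self):
        lam = np.array([0.01, 0.01])
        got = bateman_solution(lam, np.array([1.0, 0.0]), np.array([100.0]))
        assert np.isfinite(got).all()
        # limit solution: daughter activity = lam * t * exp(-lam t) * A0
        assert got[0, 1] == pytest.approx(0.01 * 100.0 * np.exp(-1.0), rel=1e-4)


class TestChainIntegration:
    def test_three_member_pulse_matches_bateman(self, decay_graph, chain_library):
        system = LandscapeSystem(decay_graph, chain_library, "Syn1")
        dur = 1e-6
        scn = ReleaseScenario(
            mode="pulse", nuclide="Syn1", target_objects={"obj1": 1.0},
            amount=1.0, start=0.0, duration=dur,
        )
        grid = np.linspace(1.0, 10_000.0, 101)
        sol = integrate(system, scn, (0.0, 10_000.0), output_grid=grid)
        lams = np.array([s.decay_constant for s in system.chain])
        ref = bateman_solution(lams, np.array([1.0, 0.0, 0.0]), grid - dur / 2.0)
        got = np.stack([sol.total_inventory(s.name) for s in system.chain], axis=1)
        rel = np.abs(got - ref) / np.maximum(np.abs(ref), 1e-300)
        assert rel.max() < 1e-6

    def test_daughters_accumulate_in_release_compartment(
        self, decay_graph, chain_library
    ):
        system = LandscapeSystem(decay_graph, chain_library, "Syn1")
        scn = ReleaseScenario(
            mode="constant", nuclide="Syn1", target_objects={"obj1": 1.0},
            rate=1.0, start=0.0,
        )
        sol = integrate(system, scn, (0.0, 2000.0), output_grid=np.array([2000.0]))
        inv = sol.inventories()  # (nt, n_obj, n_comp, n_mem)
        assert inv[0, 0, RL, 1] > 0.0 and inv[0, 0, RL, 2] > 0.0


class TestSteadyState:
    def test_single_compartment(self):
        assert steady_state(np.array([[-0.1]]), np.array([1.0]))[0] == pytest.approx(
            10.0
        )

    def test_zero_source_zero_state(self):
        A = steady_state(-0.3 * np.eye(4), np.zeros(4))
        assert np.all(A == 0.0)

    def test_singular_matrix_names_trap_compartments(self):
        K = np.zeros((2, 2))
        K[0, 0] = -1.0
        K[1, 0] = 1.0  # compartment 1 has inflow but no loss
        with pytest.raises(ValidationError, match="no loss path"):
            steady_state(K, np.array([1.0, 0.0]))

    def test_long_integration_converges_to_steady_state(self, graph1, library):
        system = LandscapeSystem(graph1, library, "Ra226syn")
        t_frozen = 9000.0  # succession complete: parameters constant here
        M_full = system.matrix_at(t_frozen)
        S_full = np.zeros(system.n_tot)
        S_full[system.idx_inv(0, 0, RL)] = 1.0
        grid = np.array([0.0, 120_000.0])
        out = propagate(
            lambda t: M_full, lambda t: S_full, np.zeros(system.n_tot), grid, grid
        )
        K = M_full[: system.n_inv, : system.n_inv]
        A_star = steady_state(K, S_full[: system.n_inv])
        active = A_star > 0.0
        rel = np.abs(out[-1, : system.n_inv][active] - A_star[active]) / A_star[active]
        assert rel.max() < 1e-3


class TestMassBalance:
    def test_closed_pulse_of_stable_nuclide_stays_put(self, decay_graph):
        lib = fx.synthetic_chain(half_lives=(1e15,))
        system = LandscapeSystem(decay_graph, lib, "Syn1")
        scn = ReleaseScenario(
            mode="pulse", nuclide="Syn1", target_objects={"obj1": 1.0},
            amount=1.0, start=0.0, duration=1.0,
        )
        sol = integrate(system, scn, (0.0, 1000.0))
        totals = sol.total_inventory("Syn1")
        assert totals[-1] == pytest.approx(1.0, rel=1e-9)
        assert mass_balance_audit(sol) < 1e-9

    def test_pure_decay_ledger_approaches_injected(self, decay_graph):
        lib = fx.synthetic_chain(half_lives=(10.0,))
        system = LandscapeSystem(decay_graph, lib, "Syn1")
        scn = ReleaseScenario(
            mode="pulse", nuclide="Syn1", target_objects={"obj1": 1.0},
            amount=1.0, start=0.0, duration=1.0,
        )
        sol = integrate(system, scn, (0.0, 500.0))
        assert sol.ledger("decayed", "Syn1")[-1] == pytest.approx(1.0, rel=1e-9)

    def test_audit_across_isolation_window(self, graph1, library):
        sched = graph1.schedules["obj1"]
        span = (sched.isolation_start - 100.0, sched.isolation_end + 100.0)
        grid = np.linspace(*span, 141)
        system = LandscapeSystem(graph1, library, "Ra226syn")
        scn = ReleaseScenario(
            mode="constant", nuclide="Ra226syn", target_objects={"obj1": 1.0},
            rate=1.0, start=span[0],
        )
        sol = integrate(system, scn, span, output_grid=grid)
        assert mass_balance_audit(sol) < 1e-6
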