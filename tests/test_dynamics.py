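import numpy as np
import pytest

import afferentsim as af
from afferentsim.classify import detect_spikes
from afferentsim.dynamics import (
    BifurcationDiagram1D,
    find_equilibria,
    find_hopf,
    hopf_bearing,
    stationary_current_curve,
    tipping_map,
    _set_na_k,
)
from afferentsim.experiments import local_boundary_gNa
from afferentsim.model_core import steady_state
from afferentsim.simulate import StimulusProtocol, integrate


def _spikes_from_perturbed_equilibrium(
    model, I_stim, dV=0.5, T=4000.0
) -> int:
    """Spike count after nudging the equilibrium at constant I_stim."""
    eqs = find_equilibria(model, I_stim)
    s0 = steady_state(model, eqs[0].V)
    s0.V += dV
    tr = integrate(
        model, StimulusProtocol(T_total=T, I_hold=I_stim), initial_state=s0
    )
    return len(detect_spikes(tr))


class TestEquilibria:
    def test_single_stable_rest_state_matches_scan_oracle(self, base_model):
        eqs = find_equilibria(base_model, 0.0)
        assert len(eqs) == 1 and eqs[0].is_stable
        # brute-force 1-D scan of the stationary current balance
        V = np.arange(-90.0, 0.0, 0.001)
        f = -stationary_current_curve(base_model, V)
        k = np.argmin(np.abs(f))
        assert eqs[0].V == pytest.approx(V[k], abs=0.01)

    def test_equilibrium_is_rhs_root(self, neuropathic_model):
        for eq in find_equilibria(neuropathic_model, 30.0):
            dy = af.rhs(eq.state, neuropathic_model, eq.I_stim)
            assert np.linalg.norm(dy) < 1e-9

    def test_eigenvalue_count_matches_dimension(self, neuropathic_model):
        eq = find_equilibria(neuropathic_model, 0.0)[0]
        assert len(eq.eigenvalues) == neuropathic_model.dim

    def test_zero_conductance_channel_leaves_equilibrium_unchanged(self, base_model):
        extended = base_model.with_channel(af.sodium_channel(0.0, label="silent"))
        eq0 = find_equilibria(base_model, 5.0)[0]
        eq1 = find_equilibria(extended, 5.0)[0]
        assert eq1.V == pytest.approx(eq0.V, abs=1e-9)
        # original eigenvalues are preserved among the extended set
        for lam in eq0.eigenvalues:
            assert np.min(np.abs(eq1.eigenvalues - lam)) < 1e-6

    def test_no_root_in_bracket_returns_empty(self, base_model):
        assert find_equilibria(base_model, 0.0, V_range=(-50.0, -40.0)) == []


class TestScanIstim:
    def test_neuropathic_cell_has_subcritical_hopf_with_bistable_window(
        self, neuropathic_diagram
    ):
        d = neuropathic_diagram
        assert d.has_hopf
        assert d.hopf_type == "subcritical"
        lo, hi = d.bistable_interval
        assert lo < hi == pytest.approx(d.hopf_I_star)

    def test_normal_cell_has_no_hopf_in_range(self, normal_model):
        from afferentsim.dynamics import scan_Istim

        d = scan_Istim(normal_model, n_samples=15, simulate_cycles=False)
        assert not d.has_hopf
        assert d.bistable_interval is None

    def test_limit_cycle_extends_through_bistable_window(self, neuropathic_diagram):
        d = neuropathic_diagram
        assert len(d.lc_I) > 0
        assert d.lc_I.min() < d.hopf_I_star  # coexists with the stable rest state
        assert np.all(d.lc_V_max > 0.0)  # overshooting spikes
        assert np.all(d.lc_V_min < -60.0)

    def test_bistability_requires_hopf(self):
        with pytest.raises(ValueError):
            BifurcationDiagram1D(
                I_samples=np.arange(3.0),
                V_eq=np.zeros(3),
                eq_stable=np.ones(3, bool),
                hopf_I_star=None,
                bistable_interval=(1.0, 2.0),
            )

    def test_subthreshold_multistart_converges_to_unique_rest(
        self, neuropathic_model, neuropathic_diagram, rng
    ):
        I_quiet = neuropathic_diagram.bistable_interval[0] - 10.0
        eq = find_equilibria(neuropathic_model, I_quiet)
        target = [e for e in eq if e.is_stable][0].V
        finals = []
        for _ in range(12):
            V0 = rng.uniform(-80.0, -30.0)
            s0 = steady_state(neuropathic_model, V0)
            tr = integrate(
                neuropathic_model,
                StimulusProtocol(T_total=3000.0, I_hold=I_quiet, record_dt=1.0),
                initial_state=s0,
            )
            finals.append(tr.V[-1])
        assert np.allclose(finals, target, atol=0.05)

    def test_hopf_agrees_with_simulated_spiking_onset(self, neuropathic_model):
        # smallest constant stimulus at which a slightly perturbed
        # equilibrium escapes into sustained spiking
        I_star = find_hopf(neuropathic_model)
        lo, hi = I_star - 3.0, I_star + 3.0
        while hi - lo > 0.1:
            mid = 0.5 * (lo + hi)
            if _spikes_from_perturbed_equilibrium(neuropathic_model, mid) >= 3:
                hi = mid
            else:
                lo = mid
        assert hi == pytest.approx(I_star, abs=0.5)

    def test_step_from_rest_latches_inside_bistable_window(
        self, neuropathic_model, neuropathic_diagram
    ):
        # hard excitation: the step-onset transient crosses the
        # quasi-separatrix, so sustained spiking already appears below I*
        I = neuropathic_diagram.hopf_I_star - 2.0
        assert I > neuropathic_diagram.bistable_interval[0]
        proto = StimulusProtocol.step(I, onset=50.0, duration=1000.0, tail=10.0)
        n = len(detect_spikes(integrate(neuropathic_model, proto)))
        assert n >= 3


@pytest.fixture(scope="module")
def small_map(normal_model):
    gNa = np.linspace(0.0, 4.0, 9)
    gK = np.linspace(0.0, 3.0, 7)
    return tipping_map(normal_model, gNa, gK)


class TestTippingMap:
    def test_origin_is_not_hopf_bearing(self, small_map):
        assert not small_map.hopf_bearing[0, 0]

    def test_boundary_monotone_in_gK(self, small_map):
        assert small_map.check_boundary_monotone()

    def test_reference_points_fall_on_expected_sides(self, small_map):
        gNa, gK = small_map.gNa_grid, small_map.gK_grid
        i_kl, i_kh = np.searchsorted(gK, 2.0), np.searchsorted(gK, 2.5)
        j_nl, j_nh = np.searchsorted(gNa, 2.0), np.searchsorted(gNa, 2.5)
        assert small_map.hopf_bearing[i_kl, j_nh]  # neuropathic (2.5, 2.0)
        assert not small_map.hopf_bearing[i_kh, j_nl]  # normal (2.0, 2.5)

    def test_istar_decreases_with_gNa_inside_bearing_region(self, small_map):
        row = small_map.I_star[2]  # gK = 1.0
        # cells whose Hopf lies below the scanned range saturate at the
        # bottom of the range; the decrease applies to in-range crossings
        vals = row[np.isfinite(row) & (row > np.nanmin(small_map.I_star))]
        assert len(vals) >= 3
        assert np.all(np.diff(vals) < 0)

    def test_leak_increase_moves_boundary_to_larger_gNa(self, normal_model):
        b_low = local_boundary_gNa(normal_model, 1.5)
        from afferentsim.dynamics import apply_context

        stiffer = apply_context(normal_model, g_leak=3.0)
        b_high = local_boundary_gNa(stiffer, 1.5)
        assert b_high > b_low

    def test_empty_grid_rejected(self, normal_model):
        with pytest.raises(ValueError):
            tipping_map(normal_model, [], [1.0])

    def test_refined_boundary_matches_bisection(self, normal_model):
        gNa = np.linspace(0.0, 3.0, 7)
        tm = tipping_map(
            normal_model, gNa, np.array([1.0]), refine_boundary=True,
            boundary_tol=0.01,
        )
        direct = local_boundary_gNa(normal_model, 1.0, tol=0.01)
        assert tm.boundary[0] == pytest.approx(direct, abs=0.02)


class TestHopfBearing:
    def test_found_hopf_implies_bearing(self, neuropathic_model):
        assert find_hopf(neuropathic_model) is not None
        assert hopf_bearing(neuropathic_model)

    def test_base_and_normal_cells_are_not_bearing(self, base_model, normal_model):
        assert not hopf_bearing(base_model)
        assert not hopf_bearing(normal_model)

    def test_far_past_boundary_is_bearing_without_in_range_crossing(self, base_model):
        hot = _set_na_k(base_model, 6.0, 0.0)  # Hopf lies below I = 0
        assert find_hopf(hot) is None
        assert hopf_bearing(hot)
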