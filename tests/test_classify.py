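import numpy as np
import pytest

import afferentsim as af
from afferentsim.classify import (
    ExcitabilityLabel,
    classify_excitability,
    detect_bursts,
    detect_mpo,
    detect_spikes,
    titrate_to_tipping,
)
from afferentsim.experiments import local_boundary_gNa
from afferentsim.model_core import AHPParams
from afferentsim.simulate import Trace


def synthetic_trace(t, V):
    n = len(t)
    return Trace(
        t=t,
        V=V,
        w=np.zeros(n),
        m=np.zeros((n, 0)),
        z=np.zeros(n),
        I_applied=np.zeros(n),
    )


def spike_waveform_trace(spike_times, T=1000.0, dt=0.05, width=1.0):
    """Flat -65 mV trace with gaussian spike bumps peaking at +30 mV."""
    t = np.arange(0.0, T, dt)
    V = np.full_like(t, -65.0)
    for ts in spike_times:
        V += 95.0 * np.exp(-0.5 * ((t - ts) / width) ** 2)
    return synthetic_trace(t, V)


class TestDetectSpikes:
    def test_flat_subthreshold_trace_has_no_spikes(self):
        tr = spike_waveform_trace([])
        assert len(detect_spikes(tr)) == 0

    def test_five_injected_waveforms_detected_at_known_times(self):
        times = [100.0, 250.0, 400.0, 550.0, 700.0]
        tr = spike_waveform_trace(times)
        found = detect_spikes(tr)
        assert len(found) == 5
        # threshold crossing happens on the rising flank, within ~1 ms
        assert np.allclose(found, times, atol=1.5)

    def test_count_invariant_to_upsampling(self):
        times = [100.0, 300.0, 500.0]
        tr = spike_waveform_trace(times, dt=0.1)
        t2 = np.arange(0.0, tr.t[-1], 0.05)
        tr2 = synthetic_trace(t2, np.interp(t2, tr.t, tr.V))
        assert len(detect_spikes(tr)) == len(detect_spikes(tr2)) == 3

    def test_refractory_merges_double_crossings(self):
        t = np.arange(0.0, 20.0, 0.05)
        V = np.full_like(t, -65.0)
        for ts in (10.0, 10.8):  # closer than the 2 ms refractory gap
            V += 95.0 * np.exp(-0.5 * ((t - ts) / 0.3) ** 2)
        assert len(detect_spikes(synthetic_trace(t, V))) == 1

    def test_coarse_sampling_rejected(self):
        t = np.arange(0.0, 100.0, 1.0)
        with pytest.raises(ValueError):
            detect_spikes(synthetic_trace(t, np.zeros_like(t)))


class TestClassifyExcitability:
    def test_base_cell_is_onset_only_at_all_rungs(self, base_model):
        lab = classify_excitability(base_model)
        assert lab.pattern == "onset-only"
        assert 1 <= lab.spike_count < 3

    def test_hopf_bearing_cell_is_repetitive(self, neuropathic_model):
        lab = classify_excitability(neuropathic_model)
        assert lab.is_repetitive
        assert lab.spike_count >= 3

    def test_normal_cell_is_onset_only(self, normal_model):
        assert classify_excitability(normal_model).pattern == "onset-only"

    def test_two_spikes_is_still_onset_only(self):
        # the printed rule: repetitive requires at least three spikes
        lab = ExcitabilityLabel(pattern="onset-only", spike_count=2)
        assert not lab.is_repetitive
        with pytest.raises(ValueError):
            ExcitabilityLabel(pattern="repetitive", spike_count=2)

    def test_short_steps_rejected(self, base_model):
        with pytest.raises(ValueError):
            classify_excitability(base_model, duration=200.0)


class TestDetectMPO:
    def test_noise_free_equilibrium_trace_is_flat(self, neuropathic_model):
        r = detect_mpo(neuropathic_model.with_noise(None), I_stim=20.0, T=5000.0)
        assert not r.present

    def test_sinusoid_in_noise_recovers_frequency(self, rng):
        dt = 0.5  # ms
        t = np.arange(0.0, 10000.0, dt)
        f0 = 35.0  # Hz
        V = -65.0 + 1.0 * np.sin(2 * np.pi * f0 * t / 1000.0)
        V += 0.3 * rng.standard_normal(len(t))
        r = detect_mpo(af.CellModel(), I_stim=0.0, trace=synthetic_trace(t, V))
        assert r.present
        assert r.peak_freq == pytest.approx(f0, abs=1.5)

    def test_peak_grows_approaching_the_hopf(self, neuropathic_model):
        noisy = neuropathic_model.with_noise(af.NoiseSpec(sigma=0.3))
        far = detect_mpo(noisy, I_stim=20.0, seed=3, T=10000.0)
        near = detect_mpo(noisy, I_stim=50.0, seed=3, T=10000.0)
        assert near.peak_to_background > far.peak_to_background
        assert near.present and not far.present

    def test_short_segment_rejected(self, neuropathic_model):
        with pytest.raises(ValueError):
            detect_mpo(neuropathic_model, I_stim=0.0, T=1000.0)


class TestDetectBursts:
    def test_regular_tonic_train_is_not_bursting(self):
        assert not detect_bursts(np.arange(0.0, 1000.0, 20.0)).present

    def test_three_groups_of_four(self):
        times = np.concatenate(
            [start + 10.0 * np.arange(4) for start in (0.0, 500.0, 1000.0)]
        )
        r = detect_bursts(times)
        assert r.present
        assert [b[2] for b in r.bursts] == [4, 4, 4]

    def test_fewer_than_six_spikes_never_bursting(self):
        assert not detect_bursts(np.array([0.0, 5.0, 300.0, 305.0])).present

    def test_bursting_needs_bistability_and_adaptation(
        self, neuropathic_model, normal_model, neuropathic_diagram
    ):
        I = neuropathic_diagram.hopf_I_star + 2.0
        proto = af.StimulusProtocol.step(I, onset=100.0, duration=8000.0, tail=100.0)

        with_ahp = neuropathic_model.with_ahp(AHPParams())
        spikes = detect_spikes(af.integrate(with_ahp, proto))
        assert detect_bursts(spikes).present

        spikes = detect_spikes(af.integrate(neuropathic_model, proto))
        assert len(spikes) >= 6 and not detect_bursts(spikes).present

        # no bistable window: adaptation alone cannot produce bursts
        spikes = detect_spikes(af.integrate(normal_model.with_ahp(AHPParams()), proto))
        assert not detect_bursts(spikes).present


class TestTitration:
    def test_already_repetitive_cell_needs_nothing(self, neuropathic_model):
        r = titrate_to_tipping(neuropathic_model, "add-Na", classifier="hopf")
        assert r.converged and r.minimal_density == 0.0

    def test_matches_boundary_distance_along_gNa(self, normal_model):
        r = titrate_to_tipping(normal_model, "add-Na", classifier="hopf")
        boundary = local_boundary_gNa(normal_model, 2.5)
        native = normal_model.channel("Na").gbar
        assert r.converged
        assert r.minimal_density == pytest.approx(boundary - native, abs=0.02)

    def test_nS_per_pF_uses_capacitance_convention(self, normal_model):
        r = titrate_to_tipping(normal_model, "add-Na", classifier="hopf")
        assert r.minimal_density_nS_per_pF == pytest.approx(
            r.minimal_density / normal_model.core.C
        )

    def test_K_blockade_moves_cell_toward_tipping(self, normal_model):
        r0 = titrate_to_tipping(normal_model, "add-Na", classifier="hopf")
        blocked = normal_model.scale_channel("K", 0.5)  # 4-AP-like
        r1 = titrate_to_tipping(blocked, "add-Na", classifier="hopf")
        assert r1.minimal_density < r0.minimal_density

    def test_no_flip_within_limit_reports_unconverged(self, normal_model):
        r = titrate_to_tipping(
            normal_model, "add-Na", g_max=0.1, classifier="hopf"
        )
        assert not r.converged
        assert r.bracket == (0.1, float("inf"))

    def test_simulation_titration_flips_at_or_before_hopf_boundary(
        self, normal_model
    ):
        # the step protocol can recruit the spiking attractor through
        # hard excitation once the bistable window dips into the tested
        # stimulus range, i.e. slightly before the Hopf itself does
        fast = titrate_to_tipping(normal_model, "add-Na", classifier="hopf")
        slow = titrate_to_tipping(
            normal_model, "add-Na", classifier="simulate", tolerance=0.02
        )
        assert slow.converged
        assert slow.minimal_density <= fast.minimal_density + 0.02
        assert fast.minimal_density - slow.minimal_density < 0.6

    def test_conversion_then_reversal_restores_classification(self, normal_model):
        r = titrate_to_tipping(normal_model, "add-Na", classifier="hopf")
        converted = normal_model.with_channel(
            af.sodium_channel(r.minimal_density + 0.05, label="virtual-Na")
        )
        from afferentsim.dynamics import hopf_bearing

        assert hopf_bearing(converted)
        back = titrate_to_tipping(converted, "add-K", classifier="hopf")
        assert back.converged and back.minimal_density > 0.0
        silenced = converted.with_channel(
            af.potassium_channel(back.minimal_density + 0.05, label="virtual-K")
        )
        assert not hopf_bearing(silenced)

    def test_unknown_direction_rejected(self, normal_model):
        with pytest.raises(ValueError):
            titrate_to_tipping(normal_model, "add-Cl")
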