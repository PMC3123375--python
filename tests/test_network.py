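"""Population drives, connectome sampling, synaptic kinetics."""

import math

import numpy as np
import pytest

from hstheta.channels import ConfigurationError
from hstheta.network import (
    Connectome,
    DualExpGating,
    PopulationSpec,
    Projection,
    SynapseSpec,
    draw_heterogeneous_drive,
    dual_exp_norm,
    dual_exp_peak_time,
    export_edge_list,
    import_edge_list,
    nmda_unblock,
    populations_from_params,
    projections_from_params,
    sample_connectome,
    synaptic_current,
    synaptic_gating_step,
)


class TestHeterogeneousDrive:
    def test_zero_sigma_gives_identical_drives(self):
        spec = PopulationSpec("basket", 50, 1.2, 0.0)
        assert np.all(draw_heterogeneous_drive(spec, 3) == 1.2)

    def test_seed_determinism(self):
        spec = PopulationSpec("pyramidal", 10, 15.0, 0.1)
        a = draw_heterogeneous_drive(spec, 42)
        b = draw_heterogeneous_drive(spec, 42)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, draw_heterogeneous_drive(spec, 43))

    def test_sample_mean_obeys_clt_bound(self):
        spec = PopulationSpec("basket", 10_000, 1.0, 0.1)
        drives = draw_heterogeneous_drive(spec, 5)
        assert abs(drives.mean() - 1.0) < 3 * 0.1 / math.sqrt(10_000)


class TestConnectome:
    def _proj(self, in_degree, source="basket", target="pyramidal"):
        syn = SynapseSpec("gaba_a", 0.1, -75.0, 0.5, 8.0)
        return Projection(source, target, syn, in_degree)

    def test_zero_in_degree_empty_adjacency(self):
        c = sample_connectome([self._proj(0)], {"basket": 100, "pyramidal": 10}, 1)
        assert c.pre[0].shape == (10, 0)

    def test_full_in_degree_is_all_to_all(self):
        c = sample_connectome([self._proj(100)], {"basket": 100, "pyramidal": 10}, 1)
        for row in c.pre[0]:
            assert sorted(row) == list(range(100))

    def test_excessive_in_degree_rejected(self):
        with pytest.raises(ConfigurationError):
            sample_connectome([self._proj(101)], {"basket": 100, "pyramidal": 10}, 1)

    def test_source_selection_is_uniform(self):
        """Each of 100 sources is chosen with frequency 5/100 over many
        realizations (binomial 3-sigma bound)."""
        n_real = 4000
        counts = np.zeros(100)
        for seed in range(n_real):
            c = sample_connectome(
                [self._proj(5)], {"basket": 100, "pyramidal": 1}, seed
            )
            counts[c.pre[0][0]] += 1
        p = 0.05
        sigma = math.sqrt(n_real * p * (1 - p))
        assert np.all(np.abs(counts - n_real * p) < 4.5 * sigma)
        # and globally unbiased at 3 sigma for the mean count
        assert abs(counts.mean() - n_real * p) < 3 * sigma / 10

    def test_audit_passes_for_default_wiring(self, params):
        projs = projections_from_params(params)
        sizes = {k: v.n for k, v in populations_from_params(params).items()}
        c = sample_connectome(projs, sizes, 9)
        c.audit(sizes)

    def test_reseeding_changes_adjacency_preserves_degrees(self, params):
        projs = projections_from_params(params)
        sizes = {k: v.n for k, v in populations_from_params(params).items()}
        c1 = sample_connectome(projs, sizes, 1)
        c2 = sample_connectome(projs, sizes, 2)
        assert any(not np.array_equal(a, b) for a, b in zip(c1.pre, c2.pre))
        for proj, pre in zip(c2.projections, c2.pre):
            assert pre.shape[1] == proj.in_degree

    def test_transmitter_rules_enforced(self):
        syn = SynapseSpec("gaba_a", 0.1, -75.0, 0.5, 8.0)
        with pytest.raises(ConfigurationError):
            Projection("pyramidal", "basket", syn, 5)  # pyr output must be AMPA
        ampa = SynapseSpec("ampa", 0.1, 0.0, 0.5, 3.0)
        with pytest.raises(ConfigurationError):
            Projection("basket", "pyramidal", ampa, 5)  # interneurons are GABAergic

    def test_edge_list_roundtrip(self, params, tmp_path):
        projs = projections_from_params(params)
        sizes = {k: v.n for k, v in populations_from_params(params).items()}
        c = sample_connectome(projs, sizes, 5)
        path = tmp_path / "edges.tsv"
        export_edge_list(c, path)
        c2 = import_edge_list(path, projs, sizes)
        for a, b in zip(c.pre, c2.pre):
            np.testing.assert_array_equal(np.sort(a, axis=1), np.sort(b, axis=1))


class TestSynapticKinetics:
    def _spec(self, tr=0.5, td=8.0, tx="gaba_a", e=-75.0, vdep=False):
        return SynapseSpec(tx, 0.1, e, tr, td, voltage_dependence=vdep)

    def test_decay_without_spikes_is_exponential(self):
        # in the tau_rise -> 0 limit, s decays as exp(-t/tau_decay)
        spec = self._spec(tr=1e-4, td=8.0)
        g = DualExpGating(spec, u=1.0, v=0.0)
        s0 = g.s
        for _ in range(100):
            g = synaptic_gating_step(g, 0, 0.1)
        assert g.s / s0 == pytest.approx(math.exp(-10.0 / 8.0), rel=1e-3)

    def test_single_spike_peaks_at_analytic_time(self):
        spec = self._spec(tr=0.5, td=8.0)
        g = DualExpGating(spec)
        g = synaptic_gating_step(g, 1, 1e-9)
        dt = 0.01
        trace = []
        for _ in range(2000):
            trace.append(g.s)
            g = synaptic_gating_step(g, 0, dt)
        t_peak = np.argmax(trace) * dt
        assert t_peak == pytest.approx(dual_exp_peak_time(0.5, 8.0), abs=2 * dt)
        assert max(trace) == pytest.approx(1.0, rel=1e-3)  # unit-peak normalization

    def test_nmda_blocked_at_hyperpolarized_potentials(self):
        spec = self._spec(tr=5.0, td=100.0, tx="nmda", e=0.0, vdep=True)
        i = synaptic_current(1.0, spec, -90.0)
        i_no_block = spec.g_max * 1.0 * (-90.0 - spec.e_rev)
        # magnesium block removes >95% of the current at -90 mV
        assert abs(i) < 0.05 * abs(i_no_block)
        assert nmda_unblock(-90.0) < 0.05

    def test_zero_gating_zero_current(self):
        assert synaptic_current(0.0, self._spec(), -55.0) == 0.0

    def test_zero_driving_force(self):
        assert synaptic_current(1.0, self._spec(e=-75.0), -75.0) == 0.0

    def test_inhibitory_current_is_outward_above_reversal(self):
        # g_max*s = 0.1, V - E = 20 mV -> +2 uA/cm2 outward
        spec = SynapseSpec("gaba_a", 0.1, -75.0, 0.5, 8.0)
        assert synaptic_current(1.0, spec, -55.0) == pytest.approx(2.0)

    def test_invalid_time_constants_rejected(self):
        with pytest.raises(ConfigurationError):
            SynapseSpec("gaba_a", 0.1, -75.0, 8.0, 0.5)
        with pytest.raises(ConfigurationError):
            SynapseSpec("gaba_a", 0.1, -40.0, 0.5, 8.0)  # reversal too high
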