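"""Generator statistics: OU physics, detachment kinetics, determinism."""
import numpy as np
import pytest
from scipy import stats

from trapforge import (GroundTruth, SimConfig, simulate_bead_only,
                       simulate_ensemble_trace, simulate_event_metrics,
                       thermal_energy)
from trapforge.simulate import _detach_hazard


class TestBeadOnlyOU:
    def test_stationary_variance_matches_equipartition(self):
        # 10^6 samples -> within 2% of kT/k
        cfg = SimConfig(k_trap=0.04, duration_s=200.0, seed=5)
        trace = simulate_bead_only(cfg)
        expected = cfg.kT / cfg.k_trap  # 102.9 nm^2
        assert trace.positions.var(ddof=1) == pytest.approx(expected, rel=0.02)

    def test_lag1_autocorrelation(self):
        cfg = SimConfig(k_trap=0.06, duration_s=200.0, seed=6)
        x = simulate_bead_only(cfg).positions
        expected = np.exp(-cfg.k_trap * cfg.dt / cfg.gamma)
        observed = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert observed == pytest.approx(expected, rel=0.02)

    def test_stiffer_trap_narrower_well(self):
        v = {}
        for k in (0.04, 0.10):
            cfg = SimConfig(k_trap=k, duration_s=10.0, seed=7)
            v[k] = simulate_bead_only(cfg).positions.var(ddof=1)
        assert v[0.10] < v[0.04]
        assert v[0.04] == pytest.approx(102.9, rel=0.05)
        assert v[0.10] == pytest.approx(41.2, rel=0.05)

    def test_small_gamma_limit_uncorrelated(self):
        # gamma -> 0: correlation time << dt, successive samples independent
        cfg = SimConfig(k_trap=0.04, duration_s=20.0, seed=8, gamma=1e-9)
        x = simulate_bead_only(cfg).positions
        assert x.var(ddof=1) == pytest.approx(cfg.kT / 0.04, rel=0.03)
        assert abs(np.corrcoef(x[:-1], x[1:])[0, 1]) < 0.01

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(k_trap=-0.04, duration_s=1.0, seed=0)
        with pytest.raises(ValueError):
            SimConfig(k_trap=0.04, duration_s=1.0, seed=0, sample_rate_hz=0)


class TestEnsembleKinetics:
    def test_detachment_times_exponential_at_frozen_load(self):
        """Single head at fixed load detaches as a Poisson process with
        rate h(F); KS agreement with the closed-form exponential."""
        cfg = SimConfig(k_trap=0.06, duration_s=1.0, seed=0, pi_mM=30.0,
                        k_adp0=4.0)
        F = 1.5
        rate = _detach_hazard(F, cfg, cfg.kT)
        rng = np.random.default_rng(99)
        draws = rng.exponential(1.0 / rate, 10_000)
        ks = stats.kstest(draws, "expon", args=(0, 1.0 / rate))
        assert ks.pvalue > 0.01
        # and the hazard itself is the sum of the two Bell pathways
        kT = cfg.kT
        expected = (cfg.k_adp0 * np.exp(-F * cfg.d_adp / kT)
                    + cfg.pi_mM * cfg.k_pi0_per_mM * np.exp(F * cfg.d_pi / kT))
        assert rate == pytest.approx(expected, rel=1e-12)

    def test_phosphate_shortens_lifetimes(self):
        """More Pi at fixed load -> faster detachment, shorter events."""
        means = []
        for pi in (0.0, 30.0):
            cfg = SimConfig(k_trap=0.06, duration_s=1.0, seed=1, pi_mM=pi)
            df = simulate_event_metrics(cfg, 500, seed=21)
            means.append(df.t_on.mean())
        assert means[1] < means[0]

    def test_stiffness_lengthens_lifetimes_without_pi(self):
        """Catch pathway (d_adp > 0, no Pi): load slows detachment."""
        means = []
        for k in (0.04, 0.10):
            cfg = SimConfig(k_trap=k, duration_s=1.0, seed=1, pi_mM=0.0)
            df = simulate_event_metrics(cfg, 500, seed=22)
            means.append(df.t_on.mean())
        assert means[1] > means[0]

    def test_stiffness_shortens_lifetimes_with_pi(self):
        means = []
        for k in (0.04, 0.10):
            cfg = SimConfig(k_trap=k, duration_s=1.0, seed=1, pi_mM=30.0,
                            k_adp0=0.0)
            df = simulate_event_metrics(cfg, 500, seed=23)
            means.append(df.t_on.mean())
        assert means[1] < means[0]

    def test_no_attachment_means_no_events(self):
        cfg = SimConfig(k_trap=0.04, duration_s=5.0, seed=2, k_init=0.0,
                        k_attach=0.0)
        trace, truth = simulate_ensemble_trace(cfg)
        assert truth.n_events == 0
        assert trace.positions.var(ddof=1) == pytest.approx(cfg.kT / 0.04,
                                                            rel=0.1)

    def test_zero_heads_is_bead_only(self):
        cfg = SimConfig(k_trap=0.04, duration_s=2.0, seed=3, n_heads=0)
        trace, truth = simulate_ensemble_trace(cfg)
        ref = simulate_bead_only(cfg)
        assert truth.n_events == 0
        np.testing.assert_array_equal(trace.positions, ref.positions)

    def test_determinism_same_seed_same_trace(self):
        cfg = SimConfig(k_trap=0.06, duration_s=5.0, seed=42, pi_mM=30.0)
        t1, g1 = simulate_ensemble_trace(cfg)
        t2, g2 = simulate_ensemble_trace(cfg)
        np.testing.assert_array_equal(t1.positions, t2.positions)
        assert [(e.start_sample, e.end_sample) for e in g1.events] == \
               [(e.start_sample, e.end_sample) for e in g2.events]

    def test_truth_events_sorted_nonoverlapping(self, ensemble_sim):
        _, trace, truth = ensemble_sim
        prev = 0
        for ev in truth.events:
            assert ev.start_sample >= prev
            assert ev.end_sample > ev.start_sample
            assert ev.end_sample <= trace.n_samples
            prev = ev.end_sample

    def test_variance_drops_while_bound(self, ensemble_sim):
        cfg, trace, truth = ensemble_sim
        ev = max(truth.events, key=lambda e: e.n_samples)
        inside = trace.positions[ev.start_sample + 50:ev.end_sample - 50]
        assert inside.var(ddof=1) < 0.5 * (cfg.kT / cfg.k_trap)

    def test_hazard_overflow_clipped_with_warning(self):
        cfg = SimConfig(k_trap=0.06, duration_s=1.0, seed=0, pi_mM=30.0)
        with pytest.warns(RuntimeWarning, match="clipped"):
            h = _detach_hazard(1e6, cfg, cfg.kT)
        assert np.isfinite(h)


def test_thermal_energy_reference_value():
    assert thermal_energy(298.15) == pytest.approx(4.116, abs=5e-4)
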