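"""Exactness, reproducibility, and protocol handling of the Gillespie engine."""

import numpy as np
import pytest
from scipy import stats

import selectorswitch as sw
from selectorswitch.network import Protocol, build_network
from selectorswitch.parameters import ParameterSet
from selectorswitch.presets import UNSTABLE_4B

from conftest import batch_se


def birth_death_network(f: float, b: float):
    """Pure birth-death process on the mRNA species: 0 -> M at f, M -> 0 at b.

    Realized by switching off every other channel of the non-cooperative
    network and driving basal transcription.
    """
    p = ParameterSet(fO=0.0, bO=1.0, bT=1.0, fM=0.0, bM=b, fC=0.0, bC=0.0,
                     NT=1, fM0=f)
    return build_network("noncoop", p)


class TestExactness:
    def test_birth_death_stationary_poisson(self):
        """Long-run occupancy of a birth-death process is Poisson(f/b)."""
        f, b = 2.0, 0.2            # stationary mean 10
        net = birth_death_network(f, b)
        init = net.initial_state(M=10, C=0)
        traj = sw.gillespie_run(net, init, 60000.0, seed=11, sample_dt=10.0)
        m = traj.column("M")[100:]  # discard burn-in
        mean = m.mean()
        assert abs(mean - f / b) < 3 * batch_se(m)
        # chi-square against the Poisson pmf on pooled tail bins
        kmax = int(m.max())
        observed = np.bincount(m, minlength=kmax + 1).astype(float)
        expected = stats.poisson.pmf(np.arange(kmax + 1), f / b) * len(m)
        keep = expected > 5
        observed = np.append(observed[keep], observed[~keep].sum())
        expected = np.append(expected[keep], expected[~keep].sum())
        # samples are autocorrelated (correlation time 1/b = 5 samples);
        # thin by 10 sampling intervals for an approximately iid test
        thin = m[::10]
        observed = np.bincount(thin, minlength=kmax + 1).astype(float)
        expected = stats.poisson.pmf(np.arange(kmax + 1), f / b) * len(thin)
        keep = expected > 5
        o = np.append(observed[keep], observed[~keep].sum())
        e = np.append(expected[keep], expected[~keep].sum())
        chi2 = ((o - e) ** 2 / e).sum()
        pval = stats.chi2.sf(chi2, df=len(o) - 1)
        assert pval > 0.01

    def test_promoter_occupancy_matches_detailed_balance(self):
        """Clamped-protein promoter binding equilibrates to fO*C/(fO*C+bO)."""
        p = ParameterSet(fO=0.03, bO=30.0, bT=30.0, fM=0.0, bM=1.0,
                         fC=0.0, bC=0.0, NT=1)
        net = build_network("noncoop", p)
        init = net.initial_state(M=0, C=1000)   # no production or decay:
        traj = sw.gillespie_run(net, init, 20000.0, seed=4, sample_dt=1.0)
        occ = traj.column("OC")[1000:]
        theta = 0.03 * 1000 / (0.03 * 1000 + 30.0)
        assert abs(occ.mean() - theta) < 3 * batch_se(occ)

    def test_unstable_switch_mrna_mean_matches_table(self):
        """Time-averaged che-1 mRNA at the unstable-switch parameters is ~7."""
        net = build_network("noncoop", UNSTABLE_4B)
        init = sw.on_initial_state(UNSTABLE_4B, "noncoop", network=net)
        traj = sw.gillespie_run(net, init, 10000.0, seed=21, sample_dt=5.0)
        m = traj.column("M")[200:]
        prot = traj.total_protein(net)
        assert prot.min() > 0, "switched OFF during the sampling window"
        assert abs(m.mean() - 7.0) < max(3 * batch_se(m), 0.7)


class TestContracts:
    def test_absorbing_state_stays_constant(self):
        net = build_network("noncoop", UNSTABLE_4B)
        init = net.initial_state(M=0, C=0)
        traj = sw.gillespie_run(net, init, 1000.0, seed=0, sample_dt=10.0)
        assert np.all(traj.states == init)

    def test_same_seed_same_trajectory(self):
        net = build_network("noncoop", UNSTABLE_4B)
        init = sw.on_initial_state(UNSTABLE_4B, "noncoop", network=net)
        t1 = sw.gillespie_run(net, init, 300.0, seed=9, sample_dt=5.0)
        t2 = sw.gillespie_run(net, init, 300.0, seed=9, sample_dt=5.0)
        assert np.array_equal(t1.states, t2.states)
        t3 = sw.gillespie_run(net, init, 300.0, seed=10, sample_dt=5.0)
        assert not np.array_equal(t1.states, t3.states)

    def test_empty_protocol_bitwise_identical(self):
        net = build_network("noncoop", UNSTABLE_4B)
        init = sw.on_initial_state(UNSTABLE_4B, "noncoop", network=net)
        t1 = sw.gillespie_run(net, init, 300.0, seed=9, sample_dt=5.0)
        t2 = sw.gillespie_run(net, init, 300.0, seed=9, sample_dt=5.0,
                              protocol=Protocol())
        assert np.array_equal(t1.states, t2.states)

    def test_rejects_invalid_initial_state(self):
        net = build_network("noncoop", UNSTABLE_4B)
        bad = net.initial_state(M=1, C=1).copy()
        bad[net.index["OT"]] += 1   # breaks target-promoter conservation
        with pytest.raises(ValueError):
            sw.gillespie_run(net, bad, 10.0, seed=0)

    def test_depletion_protocol_lowers_protein(self):
        """A strong depletion window visibly pulls total CHE-1 down."""
        prot = Protocol.depletion(2000.0, 6000.0, UNSTABLE_4B.bC * 50)
        traj = sw.run_protocol(UNSTABLE_4B, "noncoop", prot, 8000.0, seed=3,
                               sample_dt=50.0)
        net = build_network("noncoop", UNSTABLE_4B)
        c = traj.total_protein(net)
        before = c[(traj.times > 500) & (traj.times < 2000)].mean()
        during = c[(traj.times > 4000) & (traj.times < 8000)].mean()
        assert during < before / 4


class TestFirstPassage:
    def test_already_off_returns_zero(self):
        net = build_network("noncoop", UNSTABLE_4B)
        init = net.initial_state(M=0, C=0)
        assert sw.first_passage_to_off(UNSTABLE_4B, "noncoop", seed=1,
                                       t_max=100.0, init=init,
                                       network=net) == 0.0

    def test_stable_short_window_censored(self):
        from selectorswitch.presets import STABLE_4B
        assert sw.first_passage_to_off(STABLE_4B, "noncoop", seed=1,
                                       t_max=200.0) is None

    def test_scaled_fixture_switches(self, scaled_unstable):
        fpt = sw.first_passage_to_off(scaled_unstable, "noncoop", seed=2,
                                      t_max=3e6)
        assert fpt is not None and fpt > 0


class TestRecoveryFraction:
    def test_zero_duration_always_recovers(self, scaled_unstable):
        res = sw.recovery_fraction(scaled_unstable, "noncoop", 0.0,
                                   scaled_unstable.bC * 50, n_runs=4, seed=1,
                                   observation_window=600.0)
        assert res["fraction"] == 1.0

    def test_overwhelming_depletion_prevents_recovery(self, scaled_unstable):
        """Depletion long and strong enough to extinguish every molecule."""
        res = sw.recovery_fraction(scaled_unstable, "noncoop", 2e5,
                                   scaled_unstable.bC * 500, n_runs=4, seed=1,
                                   observation_window=3600.0)
        assert res["fraction"] == 0.0

    def test_requires_runs(self, scaled_unstable):
        with pytest.raises(ValueError):
            sw.recovery_fraction(scaled_unstable, "noncoop", 0.0, 1.0,
                                 n_runs=0, seed=1)


class TestEnsembleAgainstODE:
    def test_ensemble_mean_tracks_deterministic_solution(self):
        """The SSA ensemble mean follows the mass-action ODE at high copies."""
        from selectorswitch.deterministic import integrate, on_initial_state
        net = build_network("noncoop", UNSTABLE_4B)
        init = on_initial_state(UNSTABLE_4B, "noncoop", network=net)
        # perturb away from the fixed point so there is relaxation to track
        pert = init.copy()
        pert[net.index["C"]] = int(init[net.index["C"]] * 0.5)
        n_runs, t_end = 16, 1500.0
        ens = np.zeros((n_runs, 4))
        t_check = np.array([300.0, 600.0, 1000.0, 1500.0])
        for r in range(n_runs):
            traj = sw.gillespie_run(net, pert, t_end, seed=100 + r,
                                    sample_dt=10.0)
            c = traj.total_protein(net)
            idx = np.searchsorted(traj.times, t_check)
            ens[r] = c[idx]
        t_ode, states = integrate(UNSTABLE_4B, "noncoop",
                                  pert.astype(float), (0.0, t_end),
                                  n_eval=601)
        w = net.protein_weights
        ode_c = states @ w
        ode_at = np.interp(t_check, t_ode, ode_c)
        mean = ens.mean(axis=0)
        se = ens.std(axis=0, ddof=1) / np.sqrt(n_runs)
        assert np.all(np.abs(mean - ode_at) < 3.5 * se + 0.01 * ode_at)
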