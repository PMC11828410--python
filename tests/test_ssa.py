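"""Stochastic sampler: determinism, conservation, analytic agreement."""

import numpy as np
import pytest

from conjkin import (
    GrowthParams,
    KineticParams,
    SimConfig,
    SimState,
    build_network,
    ensemble_td,
    growth_deficit_scan,
    normalized_error,
    simulate,
    simulate_reference,
    td_mobilization,
)


class TestDeterminism:
    def test_same_seed_same_path(self, pkm101):
        cfg = SimConfig(1e5, 1.0, record_times=np.linspace(0, 1, 11), seed=42)
        net = build_network(pkm101, None, cfg)
        a = simulate(net, SimState(D=100, R=5000), cfg)
        b = simulate(net, SimState(D=100, R=5000), cfg)
        assert np.array_equal(a.states, b.states)

    def test_different_seed_different_path(self, pkm101):
        net = build_network(pkm101, None, area_or_volume=1e5)
        paths = []
        for seed in (1, 2):
            cfg = SimConfig(1e5, 1.0, record_times=(0.5, 1.0), seed=seed)
            paths.append(simulate(net, SimState(D=100, R=5000), cfg).states)
        assert not np.array_equal(*paths)


class TestConservation:
    def test_no_recipients_no_transconjugants(self, pkm101):
        cfg = SimConfig(1e4, 2.0, record_times=(1.0, 2.0), seed=0)
        net = build_network(pkm101, None, cfg)
        traj = simulate(net, SimState(D=200, R=0), cfg)
        assert np.all(traj.counts("T") == 0)
        assert np.all(traj.td_ratio == 0)

    @pytest.mark.parametrize("mode, koff", [("mobilization", 1.0), ("conjugation", 2.0)])
    def test_pathwise_conservation_without_growth(self, mode, koff):
        # event-resolved reference path: invariants hold after every jump
        p = KineticParams(k_on=200.0, tau=0.2, k_off=koff, mode=mode)
        cfg = SimConfig(1e3, 1.0, seed=5)
        net = build_network(p, None, cfg)
        traj = simulate_reference(net, SimState(D=20, R=100), cfg)
        D, R, C, T, C2 = (traj.counts(s) for s in ("D", "R", "C", "T", "C2"))
        assert np.all(D + C == 20)  # donor side
        if mode == "mobilization":
            assert np.all(R + C + T == 100)  # recipient side
        assert np.all(D + R + T + 2 * C + 2 * C2 == 120)  # total cells

    def test_compiled_kernel_agrees_with_reference_sampler(self):
        # dual route: the numba kernel and the event-resolved python
        # sampler must draw from the same law
        p = KineticParams(k_on=50.0, tau=0.5, mode="mobilization")
        n = 300
        t = 0.5
        ref = np.empty(n)
        fast = np.empty(n)
        net = build_network(p, None, area_or_volume=100.0)
        for i in range(n):
            cfg = SimConfig(100.0, t, record_times=(t,), seed=i)
            fast[i] = simulate(net, SimState(D=5, R=50), cfg).counts("T")[-1]
            ref_traj = simulate_reference(net, SimState(D=5, R=50), cfg)
            ref[i] = ref_traj.counts("T")[-1]
        se = np.sqrt(ref.var(ddof=1) / n + fast.var(ddof=1) / n)
        assert abs(ref.mean() - fast.mean()) < 4 * se


class TestAnalyticAgreement:
    def test_mobilization_matches_type2_mean(self, pkm101):
        # short mating (t = tau) with excess recipients: the ensemble
        # mean must sit on the closed-form curve within Monte-Carlo error
        p = KineticParams(pkm101.k_on, pkm101.tau, mode="mobilization")
        A, t = 4e5, p.tau
        cfg = SimConfig(A, t, record_times=(t,), seed=7)
        net = build_network(p, None, cfg, scheme="effective")
        ens = ensemble_td(net, SimState(D=200, R=20000), cfg, n_reps=400)
        pred = td_mobilization(20000 / A, p, t)
        assert abs(ens.mean_td[-1] - pred) < 3 * ens.se_td[-1] + 0.01 * pred

    def test_density_invariance_under_thinning(self):
        # doubling area and all counts leaves the expected T/D unchanged
        p = KineticParams(160.0, 0.25, mode="mobilization")
        means = []
        ses = []
        for scale in (1, 2):
            cfg = SimConfig(1e5 * scale, 0.25, record_times=(0.25,), seed=11 * scale)
            net = build_network(p, None, cfg, scheme="effective")
            ens = ensemble_td(
                net, SimState(D=100 * scale, R=5000 * scale), cfg, n_reps=300
            )
            means.append(ens.mean_td[-1])
            ses.append(ens.se_td[-1])
        assert abs(means[0] - means[1]) < 3 * np.hypot(*ses)


class TestNormalizedError:
    @pytest.mark.parametrize(
        "a, b, expected", [(4, 4, 0.0), (3, 1, 1.0), (1.1, 1.0, 0.095238), (0, 0, 0.0)]
    )
    def test_values(self, a, b, expected):
        assert normalized_error(a, b) == pytest.approx(expected, abs=1e-6)
        assert normalized_error(b, a) == pytest.approx(expected, abs=1e-6)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            normalized_error(-1.0, 1.0)


class TestGrowthDeficitScan:
    def test_deviation_grows_with_deficit(self, pkm101):
        cfg = SimConfig(2e5, 1.0, record_times=(1.0,), seed=3, n_replicates=60)
        scan = growth_deficit_scan(
            pkm101, [0.0, 0.4, 0.8], cfg, initial=SimState(D=100, R=10000)
        )
        err = scan["norm_error"].to_numpy()
        assert err[2] > err[0]
        assert np.all(np.diff(err) > -0.03)  # monotone within Monte-Carlo slack

    def test_invalid_deficit(self, pkm101):
        cfg = SimConfig(1e5, 1.0, seed=0)
        with pytest.raises(ValueError):
            growth_deficit_scan(pkm101, [1.2], cfg)
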