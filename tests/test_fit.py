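"""Estimator: exactness, identifiability, bootstrap, group comparison."""

import math

import numpy as np
import pandas as pd
import pytest

from conjkin import (
    DilutionDesign,
    InsufficientDesignError,
    KineticParams,
    NoiseModel,
    ObservationTable,
    bootstrap_ci,
    compare_log_td,
    fit_type2,
    generate_dilution_experiment,
    prediction_band,
)
from conjkin.observations import COLUMNS


def noiseless(params, **kw):
    return generate_dilution_experiment(
        params, noise=NoiseModel(sigma_log=0.0), seed=0, **kw
    )


def table_from_rows(rows):
    return ObservationTable(pd.DataFrame(rows, columns=COLUMNS))


def manual_rows(densities, td_fn, mode="conjugation", t=1.0, area=1e6, reps=3):
    rows = []
    for i, R in enumerate(densities):
        for rep in range(reps):
            rows.append(
                dict(
                    experiment_id=f"d{i}",
                    plasmid_label="syn",
                    mode=mode,
                    time_h=t,
                    geometry="surface",
                    area_or_volume=area,
                    donor_count=1e4,
                    recipient_count=R * area,
                    transconjugant_count=td_fn(R) * 1e4,
                    replicate_index=rep,
                )
            )
    return rows


class TestRoundTrip:
    @pytest.mark.parametrize("mode", ["conjugation", "mobilization"])
    def test_exact_recovery_on_noiseless_data(self, mode):
        p = KineticParams(160.0, 0.25, mode=mode)
        fit = fit_type2(noiseless(p))
        assert fit.converged
        assert fit.k_on == pytest.approx(160.0, rel=1e-6)
        assert fit.tau == pytest.approx(0.25, rel=1e-6)
        assert not any(fit.flags.values())

    def test_row_order_invariance(self):
        p = KineticParams(215.0, 0.13)
        obs = generate_dilution_experiment(p, noise=NoiseModel(sigma_log=0.3), seed=3)
        shuffled = ObservationTable(
            obs.raw.sample(frac=1.0, random_state=9).reset_index(drop=True)
        )
        f1, f2 = fit_type2(obs), fit_type2(shuffled)
        assert f1.k_on == pytest.approx(f2.k_on, rel=1e-8)
        assert f1.tau == pytest.approx(f2.tau, rel=1e-8)

    def test_unit_rescaling_invariance(self):
        # shrinking all densities by 10x (same counts, 10x area) must
        # inflate k_on by 10x and leave tau untouched
        p = KineticParams(215.0, 0.13)
        obs = generate_dilution_experiment(p, noise=NoiseModel(sigma_log=0.2), seed=4)
        df = obs.raw
        df2 = df.assign(area_or_volume=df["area_or_volume"] * 10.0)
        f1, f2 = fit_type2(obs), fit_type2(ObservationTable(df2))
        assert f2.k_on == pytest.approx(10 * f1.k_on, rel=1e-5)
        assert f2.tau == pytest.approx(f1.tau, rel=1e-5)


class TestIdentifiability:
    def test_too_few_densities(self):
        p = KineticParams(160.0, 0.25)
        obs = noiseless(p, design=DilutionDesign(dilution_exponents=(0, -1, -2)))
        with pytest.raises(InsufficientDesignError):
            fit_type2(obs)

    def test_constant_td_pins_tau_only(self):
        # a flat titration carries no information on k_on; tau follows
        # from the plateau: tau = t / ln(1 + T/D)
        obs = table_from_rows(manual_rows([1e-3, 1e-2, 1e-1, 1.0], lambda R: 5.0))
        fit = fit_type2(obs)
        assert fit.flags["k_on_unidentifiable"]
        assert math.isinf(fit.k_on_ci[1])
        assert fit.tau == pytest.approx(1.0 / math.log(6.0), rel=1e-2)

    def test_deep_ddt_leaves_tau_unidentified(self):
        # all densities far below half-saturation: the response is the
        # straight line R k_on t and tau rests on pure extrapolation
        p = KineticParams(215.0, 0.13)
        design = DilutionDesign(base_density=1e-5, dilution_exponents=(1, 0.5, 0, -0.5, -1))
        obs = generate_dilution_experiment(p, design, NoiseModel(sigma_log=0.0), seed=8)
        fit = fit_type2(obs)
        assert fit.k_on == pytest.approx(215.0, rel=1e-3)
        assert fit.flags["tau_unidentifiable"]
        assert math.isinf(fit.tau_ci[1])


class TestBootstrap:
    def test_seeded_reproducibility_and_point_inside(self):
        p = KineticParams(215.0, 0.13)
        obs = generate_dilution_experiment(p, noise=NoiseModel(sigma_log=0.3), seed=5)
        fit = fit_type2(obs)
        b1 = bootstrap_ci(obs, fit, n_boot=200, seed=11)
        b2 = bootstrap_ci(obs, fit, n_boot=200, seed=11)
        assert b1.k_on_ci == b2.k_on_ci and b1.tau_ci == b2.tau_ci
        assert b1.k_on_ci[0] <= b1.k_on <= b1.k_on_ci[1]
        assert b1.tau_ci[0] <= b1.tau <= b1.tau_ci[1]

    def test_interval_width_shrinks_with_noise(self):
        p = KineticParams(215.0, 0.13)
        widths = []
        for sigma in (0.4, 0.1, 0.02):
            obs = generate_dilution_experiment(
                p, noise=NoiseModel(sigma_log=sigma), seed=6
            )
            b = bootstrap_ci(obs, fit_type2(obs), n_boot=200, seed=1)
            widths.append(b.k_on_ci[1] - b.k_on_ci[0])
        assert widths[0] > widths[1] > widths[2]

    def test_prediction_band_contains_point_curve_and_collapses_at_zero(self):
        p = KineticParams(215.0, 0.13)
        obs = generate_dilution_experiment(p, noise=NoiseModel(sigma_log=0.3), seed=7)
        b = bootstrap_ci(obs, fit_type2(obs), n_boot=200, seed=2)
        dens = np.geomspace(1e-6, 1.0, 20)
        band = prediction_band(b, dens)
        assert np.all(band["td_lo"] <= band["td_point"] + 1e-12)
        assert np.all(band["td_point"] <= band["td_hi"] + 1e-12)
        assert band["td_hi"].iloc[0] < 1e-3  # band pinched toward 0 at R -> 0


class TestCompareLogTd:
    def test_identical_groups(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = compare_log_td(a, a)
        assert res.diff_log_means == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_tenfold_shift(self):
        a = np.array([0.5, 1.0, 2.0, 4.0])
        res = compare_log_td(10 * a, a)
        assert res.diff_log_means == pytest.approx(math.log(10.0))

    def test_zeros_excluded_and_counted(self):
        res = compare_log_td([1.0, 2.0, 0.0], [0.5, 1.0, -1.0])
        assert res.n_excluded == 2
        assert res.n_a == 2 and res.n_b == 2

    def test_type_i_error_rate_near_nominal(self):
        # simulated null: both groups from one log-normal
        rng = np.random.default_rng(12345)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            x = np.exp(rng.normal(0.0, 0.5, size=8))
            y = np.exp(rng.normal(0.0, 0.5, size=8))
            if compare_log_td(x, y).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sim <= 0.07
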