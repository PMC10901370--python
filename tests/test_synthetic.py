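"""Generator and emulator: determinism, invariants, mass balance, mechanism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from cleans.anomaly import compute_anomalies
from cleans.config import ClimateConfig, EmulatorParams, WorldConfig
from cleans.synthetic import (
    Scenario,
    generate_climate,
    generate_world,
    make_future_scenario,
    simulate_agroecosystem,
    simulate_records,
    world_to_frame,
)


def _profile(**kw):
    base = dict(
        fpu_id="X",
        cropland_area=1000.0,
        mean_precip=800.0,
        sd_precip=160.0,
        mean_temp=15.0,
        bd=1.3,
        cf=10.0,
        sdc=40.0,
        stc=30.0,
        baseline_nin=150.0,
        irrigated=False,
    )
    base.update(kw)
    from cleans.synthetic import FPUProfile

    return FPUProfile(**base)


class TestWorld:
    def test_minimal_world_satisfies_invariants(self):
        (p,) = generate_world(1, seed=1)
        assert 0 <= p.cf <= 100 and 0 <= p.sdc <= 100 and 0 <= p.stc <= 100
        assert p.sdc + p.stc <= 100
        assert 0 <= p.sd_precip < p.mean_precip
        assert p.cropland_area > 0 and p.baseline_nin >= 0

    def test_seed_determinism_and_sensitivity(self):
        w1 = world_to_frame(generate_world(200, seed=7))
        w2 = world_to_frame(generate_world(200, seed=7))
        w3 = world_to_frame(generate_world(200, seed=8))
        pd.testing.assert_frame_equal(w1, w2)
        assert not np.array_equal(w1["mean_precip"], w3["mean_precip"])

    def test_world_spans_gradient_and_irrigation_mix(self):
        w = world_to_frame(generate_world(200, seed=7))
        assert w["mean_precip"].min() < 500 and w["mean_precip"].max() > 1500
        assert 0.3 < w["irrigated"].mean() < 0.7

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ValueError):
            generate_world(0, seed=1)


class TestClimate:
    def test_degenerate_variance_gives_constant_series(self):
        clim = generate_climate(_profile(sd_precip=0.0), 10, seed=3)
        assert np.allclose(clim.apr, clim.apr[0])

    def test_sample_mean_matches_profile_moments(self):
        p = _profile()
        clim = generate_climate(p, 30, seed=3)
        se = p.sd_precip / np.sqrt(30)
        assert abs(clim.apr.mean() - p.mean_precip) < 3 * se

    def test_precipitation_ordering_invariant(self):
        for seed in range(5):
            clim = generate_climate(_profile(), 40, seed=seed)
            assert np.all(clim.ferpr <= clim.gspr + 1e-9)
            assert np.all(clim.gspr <= clim.apr + 1e-9)
            assert np.all(clim.apr >= 0)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            generate_climate(_profile(), 1, seed=0)


class TestEmulator:
    def test_empty_nitrogen_system_is_inert(self):
        p = _profile(baseline_nin=0.0)
        clim = generate_climate(p, 10, seed=1)
        params = EmulatorParams(deposition=0.0, initial_residual=0.0)
        rec = simulate_agroecosystem(p, clim, np.zeros(10), params, seed=2)
        assert np.allclose(rec["nw"], 0) and np.allclose(rec["yield"], 0)

    def test_mass_balance_closes(self):
        p = _profile()
        clim = generate_climate(p, 20, seed=1)
        nin = np.full(20, p.baseline_nin)
        for noise in (0.0, 0.1):
            params = EmulatorParams(noise_sd_nw=noise, noise_sd_yield=noise)
            rec = simulate_agroecosystem(p, clim, nin, params, seed=2)
            pool = np.empty(20)
            pool[0] = params.initial_residual + nin[0] + params.deposition
            pool[1:] = rec["residual_n"].to_numpy()[:-1] + nin[1:] + params.deposition
            out = rec[["nw", "uptake", "residual_n", "gaseous_n"]].sum(axis=1)
            assert np.allclose(pool, out, rtol=1e-9)

    def test_loss_components_sum_to_total(self, world200):
        rec = world200["records"]
        total = rec["nws"] + rec["nwr"] + rec["nwl"]
        assert np.allclose(total, rec["nw"], rtol=1e-12)
        assert (rec[["nw", "nws", "nwr", "nwl", "uptake", "residual_n"]] >= 0).all().all()

    def test_wetness_slope_amplifies_wet_year_loss(self):
        p = _profile()
        clim = generate_climate(p, 20, seed=1)
        nin = np.full(20, p.baseline_nin)
        recs = {}
        for b in (1.5, 3.5):
            params = EmulatorParams(
                loss_logistic_b=b, noise_sd_nw=0.0, noise_sd_yield=0.0
            )
            recs[b] = simulate_agroecosystem(p, clim, nin, params, seed=2)
        wettest = int(np.argmax(clim.apr))
        assert recs[3.5]["nw"].iloc[wettest] > recs[1.5]["nw"].iloc[wettest]

    def test_negative_input_rejected(self):
        p = _profile()
        clim = generate_climate(p, 5, seed=1)
        with pytest.raises(ValueError):
            simulate_agroecosystem(p, clim, [-1, 0, 0, 0, 0], EmulatorParams(), seed=0)

    def test_table_level_determinism(self):
        profiles = generate_world(5, seed=1)
        args = (profiles, 10, ("maize", "wheat"), EmulatorParams(), 2, 3)
        r1, _ = simulate_records(*args)
        r2, _ = simulate_records(*args)
        assert r1.to_csv(index=False) == r2.to_csv(index=False)

    def test_anomaly_sign_structure_of_losses(self, world200):
        """Dry years lose less than average, very wet years much more."""
        rec = world200["records"].merge(
            world200["anomalies"][["fpu_id", "year", "sa"]], on=["fpu_id", "year"]
        )
        means = rec.groupby(["fpu_id", "crop"])["nw"].transform("mean")
        relative = rec["nw"] / means
        assert relative[rec["sa"] < -1].mean() < 1.0
        assert relative[rec["sa"] > 2].mean() > 1.0


class TestFutureScenario:
    def test_identity_scenario_reproduces_historical(self):
        profiles = generate_world(5, seed=1)
        params = EmulatorParams()
        hist, _ = simulate_records(profiles, 10, ("maize",), params, 2, 3)
        fut, _ = make_future_scenario(
            profiles, 10, ("maize",), params, Scenario("id"), 2, 3, start_year=1981
        )
        pd.testing.assert_frame_equal(hist, fut)

    def test_nin_multiplier_scales_input(self):
        profiles = generate_world(5, seed=1)
        params = EmulatorParams()
        fut, _ = make_future_scenario(
            profiles, 10, ("maize",), params, Scenario("n13", nin_mult=1.3), 2, 3
        )
        hist, _ = simulate_records(profiles, 10, ("maize",), params, 2, 3)
        assert np.isclose(fut["nin"].mean(), 1.3 * hist["nin"].mean())

    def test_wider_precip_distribution_raises_ewy_frequency(self):
        """Future EWYs classified against historical baselines become more
        frequent when the precipitation SD grows."""
        profiles = generate_world(100, seed=11)
        params = EmulatorParams(noise_sd_nw=0.0, noise_sd_yield=0.0)
        hist, _ = simulate_records(profiles, 30, ("maize",), params, 2, 3)
        hist_anom = compute_anomalies(hist)
        baselines = {
            fpu: (g["baseline_mean"].iloc[0], g["baseline_sd"].iloc[0])
            for fpu, g in hist_anom.groupby("fpu_id")
        }
        fut, _ = make_future_scenario(
            profiles,
            30,
            ("maize",),
            params,
            Scenario("wet", precip_sd_mult=1.5),
            22,
            23,
        )
        fut_anom = compute_anomalies(fut, baselines=baselines)
        assert fut_anom["ewy"].mean() > hist_anom["ewy"].mean()

    def test_nonpositive_multiplier_rejected(self):
        with pytest.raises(ValueError):
            Scenario("bad", precip_sd_mult=0.0)
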