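"""Synthetic generators: determinism, closed-form noise statistics, round trips."""

import numpy as np
import pandas as pd
import pytest

import ch4hyst
from ch4hyst.errors import StabilityError
from ch4hyst import synthetic as syn
from ch4hyst.synthetic import (
    MechanisticParams,
    SynthSiteConfig,
    gen_covariates,
    gen_flux_mechanistic,
    gen_flux_parametric,
    gen_network,
    gen_site,
    gen_temperature,
    write_network,
)


def cfg(**kw):
    base = dict(site_id="S1", ecosystem_type="fen", latitude=55.0, years=1, seed=0)
    base.update(kw)
    return SynthSiteConfig(**base)


class TestTemperature:
    def test_noise_free_sinusoid_peaks_midyear(self):
        t = gen_temperature(cfg(t_noise_sd=0.0))
        peak_doy = t.idxmax().dayofyear
        assert abs(peak_doy - 182) <= 1
        assert t.max() == pytest.approx(cfg().t_mean + cfg().t_amplitude, rel=1e-3)

    def test_same_seed_identical(self):
        a = gen_temperature(cfg(seed=9))
        b = gen_temperature(cfg(seed=9))
        pd.testing.assert_series_equal(a, b)

    def test_southern_phase_flip(self):
        t = gen_temperature(cfg(latitude=-40.0, t_noise_sd=0.0))
        assert t.idxmax().month in (12, 1)

    def test_ar1_stationary_sd_closed_form(self):
        c = cfg(years=28, t_noise_sd=2.0, t_ar1=0.7)  # ~1e4 days
        t = gen_temperature(c)
        clean = gen_temperature(SynthSiteConfig(**{**c.__dict__, "t_noise_sd": 0.0}))
        noise = (t - clean).to_numpy()
        expected = 2.0 / np.sqrt(1 - 0.7**2)
        assert np.std(noise) == pytest.approx(expected, rel=0.05)


class TestCovariates:
    def test_gpp_vanishes_below_freezing(self):
        c = cfg(t_mean=-20.0, t_amplitude=10.0, t_noise_sd=0.0)
        t = gen_temperature(c)
        cov = gen_covariates(c, t)
        assert (cov["gpp"] == 0.0).all()

    def test_dry_series_monotone_drawdown(self):
        c = cfg(precip_prob=0.0)
        t = gen_temperature(c)
        cov = gen_covariates(c, t)
        assert (cov["precip"] == 0.0).all()
        wtd = cov["wtd"].to_numpy()
        assert (np.diff(wtd) <= 0).all()
        assert wtd[-1] == pytest.approx(c.wtd_floor)

    def test_precip_mean_closed_form(self):
        c = cfg(years=28, precip_prob=0.3, precip_gamma_shape=1.2, precip_gamma_scale=5.0)
        t = gen_temperature(c)
        cov = gen_covariates(c, t)
        expected = 0.3 * 1.2 * 5.0
        assert cov["precip"].mean() == pytest.approx(expected, rel=0.05)


class TestParametricFlux:
    def test_no_hysteresis_closed_loop(self):
        c = cfg(a_early=0.2, a_late=0.2, flux_noise_cv=0.0, years=2)
        series, truth = gen_site(c)
        results, _, _ = ch4hyst.analyze_dataset({c.site_id: series})
        for r in results:
            assert abs(r.h_area) <= 1e-9

    def test_positive_injection_detected(self):
        c = cfg(a_early=0.5, a_late=-0.5, flux_noise_cv=0.0, years=2)
        series, _ = gen_site(c)
        results, _, _ = ch4hyst.analyze_dataset({c.site_id: series})
        assert results and all(r.h_area > 0 for r in results)

    def test_noise_free_round_trip_recovers_parameters(self):
        """analyze(generate(theta)) returns theta's branch parameters to <= 1e-9."""
        c = cfg(a_early=0.37, a_late=-0.11, flux_noise_cv=0.0, years=3, seed=12)
        series, truth = gen_site(c)
        results, _, _ = ch4hyst.analyze_dataset({c.site_id: series})
        assert len(results) >= 2
        for r in results:
            assert r.fit_earlier.a_hys == pytest.approx(0.37, abs=1e-9)
            assert r.fit_later.a_hys == pytest.approx(-0.11, abs=1e-9)

    def test_subzero_days_emit_small_positive_floor(self):
        c = cfg(t_mean=5.0, t_amplitude=15.0, flux_noise_cv=0.0, seed=2)
        series, _ = gen_site(c)
        frozen = series.data[series.data["t_air"] <= 0]["f_ch4"]
        assert len(frozen) > 10
        assert (frozen >= 0).all()
        assert frozen.mean() < 2.0


class TestMechanisticFlux:
    def test_no_substrate_no_flux(self):
        t = gen_temperature(cfg(t_noise_sd=0.0))
        gpp = pd.Series(0.0, index=t.index)
        f = gen_flux_mechanistic(t, gpp, MechanisticParams(), flux_noise_cv=0.0, s0=0.0)
        assert (f == 0.0).all()

    def test_mass_balance(self):
        c = cfg(years=2, seed=5)
        t = gen_temperature(c)
        cov = gen_covariates(c, t)
        p = MechanisticParams(gpp_to_substrate=0.1, substrate_lag=20)
        f = gen_flux_mechanistic(t, cov["gpp"], p, flux_noise_cv=0.0, s0=1.0)
        emitted_gC = f.sum() / p.unit_scale
        supplied = p.gpp_to_substrate * cov["gpp"].sum() + 1.0
        assert emitted_gC <= supplied + 1e-9

    def test_lagged_substrate_gives_positive_hysteresis(self):
        """Substrate accumulated past the temperature peak sustains later emission."""
        c = cfg(years=2, seed=3, t_mean=8.0, t_amplitude=14.0, t_noise_sd=0.5)
        t = gen_temperature(c)
        cov = gen_covariates(c, t)
        p = MechanisticParams(substrate_lag=20, q10=2.5)
        f = gen_flux_mechanistic(t, cov["gpp"], p, flux_noise_cv=0.0, s0=5.0)
        df = pd.DataFrame({"t_air": t, "f_ch4": f, "gpp": cov["gpp"]})
        from ch4hyst.datamodel import DailySeries, SiteMeta

        series = DailySeries("MECH", df, SiteMeta("MECH", "fen", 55.0, 0.0))
        results, _, _ = ch4hyst.analyze_dataset({"MECH": series})
        assert results
        assert np.mean([r.h_area for r in results]) > 0

    def test_divergence_detected(self):
        t = gen_temperature(cfg(t_noise_sd=0.0))
        gpp = pd.Series(10.0, index=t.index)
        bad = MechanisticParams(gpp_to_substrate=1e7, decay_rate=1e-9, q10=1.1)
        with pytest.raises(StabilityError):
            gen_flux_mechanistic(t, gpp, bad, flux_noise_cv=0.0)

    def test_predominantly_positive_over_parameter_hypercube(self):
        """Across plausible mechanistic parameters, positive loops dominate."""
        from scipy.stats import qmc

        sampler = qmc.LatinHypercube(d=3, seed=1)
        draws = sampler.random(50)
        lags = (5 + draws[:, 0] * 40).astype(int)       # 5..45 days
        q10s = 1.5 + draws[:, 1] * 2.0                  # 1.5..3.5
        decays = 0.005 + draws[:, 2] * 0.045            # 0.005..0.05 1/d
        signs = []
        for i in range(50):
            c = cfg(years=1, seed=100 + i, t_noise_sd=0.5)
            t = gen_temperature(c)
            cov = gen_covariates(c, t)
            p = MechanisticParams(substrate_lag=int(lags[i]), q10=float(q10s[i]),
                                  decay_rate=float(decays[i]))
            f = gen_flux_mechanistic(t, cov["gpp"], p, flux_noise_cv=0.0, s0=5.0)
            df = pd.DataFrame({"t_air": t, "f_ch4": f})
            from ch4hyst.datamodel import DailySeries, SiteMeta

            series = DailySeries("M", df, SiteMeta("M", "fen", 55.0, 0.0))
            results, _, _ = ch4hyst.analyze_dataset({"M": series})
            if results:
                signs.append(results[0].h_area > 0)
        assert len(signs) >= 40
        assert np.mean(signs) > 0.5


class TestNetwork:
    def test_ground_truth_bookkeeping(self, small_network):
        years_total = sum(c.years for c in small_network.configs)
        assert len(small_network.truth) == years_total
        assert set(small_network.dataset) == set(small_network.truth["site_id"])

    def test_constructed_positive_fraction_exact(self, small_network):
        n = len(small_network.truth)
        n_pos = (small_network.truth["a_early"] > small_network.truth["a_late"]).sum()
        assert n_pos == round(0.75 * n)

    def test_same_seed_byte_identical_csvs(self, tmp_path):
        a_dir, b_dir = tmp_path / "a", tmp_path / "b"
        write_network(gen_network(n_sites=3, seed=17), a_dir)
        write_network(gen_network(n_sites=3, seed=17), b_dir)
        for f in sorted(a_dir.iterdir()):
            assert f.read_bytes() == (b_dir / f.name).read_bytes()

    def test_written_network_reads_back(self, tmp_path):
        net = gen_network(n_sites=3, seed=17)
        write_network(net, tmp_path)
        loaded = syn.read_network(tmp_path)
        assert set(loaded) == set(net.dataset)
        s = loaded[sorted(loaded)[0]]
        orig = net.dataset[s.site_id]
        np.testing.assert_allclose(
            s.data["f_ch4"].to_numpy(), orig.data["f_ch4"].round(6).to_numpy()
        )
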