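"""Synthetic experiment generator: determinism, trends, invertibility."""

import numpy as np
import pytest

from phaeotox.growth import log_logistic_inhibition
from phaeotox.multivariate import spearman_dose
from phaeotox.pigments import default_library, fit_pigments
from phaeotox.synthetic import (
    DEFAULT_EFFECT_SIGNS,
    ExperimentConfig,
    generate_bundle,
    generate_growth,
    generate_spectrum,
    generate_transient,
)


class TestConfig:
    def test_doses_sorted_and_validated(self):
        cfg = ExperimentConfig(doses=(80.0, 0.0, 20.0))
        assert cfg.doses == (0.0, 20.0, 80.0)
        with pytest.raises(ValueError):
            ExperimentConfig(doses=(-1.0, 5.0))
        with pytest.raises(ValueError):
            ExperimentConfig(true_ic50=0.0)
        with pytest.raises(ValueError):
            ExperimentConfig(noise_cv=-0.1)

    def test_default_design_matches_bioassay_protocol(self):
        cfg = ExperimentConfig()
        assert cfg.doses == (0.0, 0.3, 0.6, 20.0, 40.0, 80.0)
        assert cfg.n_replicates == 3
        assert cfg.initial_density == pytest.approx(2.7e5)

    def test_unknown_effect_sign_rejected(self):
        with pytest.raises(ValueError):
            ExperimentConfig(effect_signs={"nonsense_endpoint": 1})

    def test_default_inhibition_near_printed_points(self):
        # hill slope calibrated so the noiseless curve passes near the
        # 39%/83% inhibition observed at 40 and 80 ug/L
        cfg = ExperimentConfig()
        assert cfg.inhibition(40.0) == pytest.approx(39.0, abs=5.0)
        assert cfg.inhibition(80.0) == pytest.approx(83.0, abs=7.0)


class TestGenerateGrowth:
    def test_control_grows_exponentially_noiseless(self):
        cfg = ExperimentConfig(noise_cv=0.0)
        s = generate_growth(cfg)[(0.0, 0)]
        logs = np.log(s.densities)
        rates = np.diff(logs) / np.diff(s.times)
        assert np.allclose(rates, rates[0])
        assert s.densities[0] == pytest.approx(cfg.initial_density)

    def test_density_reduction_at_ic50_is_half(self):
        cfg = ExperimentConfig(doses=(0.0, 47.3), true_ic50=47.3,
                               noise_cv=0.0)
        g = generate_growth(cfg)
        ratio = g[(47.3, 0)].density_at(96.0) / g[(0.0, 0)].density_at(96.0)
        assert ratio == pytest.approx(0.5)

    def test_inhibition_follows_log_logistic_curve(self):
        cfg = ExperimentConfig(noise_cv=0.0)
        g = generate_growth(cfg)
        control = g[(0.0, 0)].density_at(96.0)
        for dose in cfg.doses[1:]:
            expected = float(log_logistic_inhibition(
                np.array([dose]), cfg.true_ic50, cfg.hill_slope)[0])
            got = (1 - g[(dose, 0)].density_at(96.0) / control) * 100
            assert got == pytest.approx(expected, abs=1e-9)

    def test_same_seed_identical_replicate_order_independent(self):
        a = generate_growth(ExperimentConfig(seed=3))
        b = generate_growth(ExperimentConfig(seed=3))
        for key in a:
            np.testing.assert_array_equal(a[key].densities, b[key].densities)

    def test_noise_scales_with_cv(self):
        lo = generate_growth(ExperimentConfig(noise_cv=0.01, seed=5))
        hi = generate_growth(ExperimentConfig(noise_cv=0.3, seed=5))
        clean = generate_growth(ExperimentConfig(noise_cv=0.0, seed=5))
        dev = lambda g: np.mean([  # noqa: E731
            np.abs(np.log(g[k].densities / clean[k].densities)).mean()
            for k in clean])
        assert dev(hi) > 5 * dev(lo) > 0


class TestGenerateTransient:
    def test_passes_through_cardinal_construction_points(self):
        tr = generate_transient({"f0": 500, "fm": 2500, "vj": 0.5,
                                 "vi": 0.85})
        assert tr.at(2e-3) == pytest.approx(1500.0, rel=1e-9)
        assert tr.at(50e-6) == pytest.approx(500.0, rel=1e-9)
        assert tr.fluorescence[-1] == pytest.approx(2500.0, rel=1e-9)

    def test_monotone_non_decreasing_noiseless(self):
        tr = generate_transient({"f0": 400, "fm": 2100, "vj": 0.42,
                                 "vi": 0.9})
        assert np.all(np.diff(tr.fluorescence) >= -1e-6)

    def test_invalid_vj_vi_ordering_rejected(self):
        with pytest.raises(ValueError):
            generate_transient({"f0": 500, "fm": 2500, "vj": 0.9,
                                "vi": 0.5})
        with pytest.raises(ValueError):
            generate_transient({"f0": 500, "fm": 400, "vj": 0.5,
                                "vi": 0.8})

    def test_same_seed_identical_noise(self):
        p = {"f0": 500, "fm": 2500, "vj": 0.5, "vi": 0.85}
        a = generate_transient(p, noise_sd=10.0, seed=9)
        b = generate_transient(p, noise_sd=10.0, seed=9)
        np.testing.assert_array_equal(a.fluorescence, b.fluorescence)


class TestGenerateSpectrum:
    def test_zero_everything_is_zero(self):
        sp = generate_spectrum({"chl_a": 0.0})
        assert np.all(sp.absorbance == 0)

    def test_doubling_concentrations_doubles_spectrum(self):
        c = {"chl_a": 0.5, "fucoxanthin": 0.3}
        a = generate_spectrum(c)
        b = generate_spectrum({k: 2 * v for k, v in c.items()})
        np.testing.assert_allclose(b.absorbance, 2 * a.absorbance)

    def test_unknown_pigment_rejected(self):
        with pytest.raises(KeyError):
            generate_spectrum({"violaxanthin": 1.0})

    def test_noiseless_mixture_inverts_through_fit(self):
        lib = default_library()
        truth = {"chl_a": 0.8, "fucoxanthin": 0.5}
        sp = generate_spectrum(truth, lib)
        fit = fit_pigments(sp, lib)
        for p, c in truth.items():
            assert fit[p] == pytest.approx(c, rel=0.01)
        for p in set(lib.pigments) - set(truth):
            assert fit[p] == pytest.approx(0.0, abs=1e-6)


class TestGenerateBundle:
    def test_fixed_seed_bundle_is_identical(self):
        cfg = ExperimentConfig(seed=21)
        a, b = generate_bundle(cfg), generate_bundle(cfg)
        for key in a.growth:
            np.testing.assert_array_equal(a.growth[key].densities,
                                          b.growth[key].densities)
            np.testing.assert_array_equal(a.transients[key].fluorescence,
                                          b.transients[key].fluorescence)
            np.testing.assert_array_equal(a.spectra[key].absorbance,
                                          b.spectra[key].absorbance)
            assert a.fa_tables[key].equals(b.fa_tables[key])
            assert a.assays[key]["a532"] == b.assays[key]["a532"]
            assert a.biochem[key] == b.biochem[key]

    def test_ground_truth_recorded_for_all_replicates(self,
                                                      noiseless_bundle):
        truth = noiseless_bundle.ground_truth
        assert set(truth["per_replicate"]) == set(noiseless_bundle.growth)
        assert truth["ic50"] == noiseless_bundle.config.true_ic50

    def test_trending_endpoints_have_exact_spearman_sign(
            self, noiseless_config, noiseless_bundle):
        cfg = noiseless_config
        doses = np.array(cfg.doses)
        endpoints = noiseless_bundle.ground_truth["endpoints"]
        for name, sign in DEFAULT_EFFECT_SIGNS.items():
            vals = np.array([endpoints[name][d] for d in doses])
            if sign == 0:
                assert np.ptp(vals) == 0
            else:
                res = spearman_dose(vals, doses)
                assert res.rho == pytest.approx(float(sign)), name

    def test_measured_fa_trends_match_signs(self, noiseless_config,
                                            noiseless_bundle):
        cfg = noiseless_config
        doses = np.array(cfg.doses)
        rel = noiseless_bundle.ground_truth["fa_relative_pct"]
        for fa, sign in DEFAULT_EFFECT_SIGNS.items():
            if not fa.startswith("C") or sign == 0:
                continue
            vals = np.array([rel[d][fa] for d in doses])
            assert spearman_dose(vals, doses).rho == pytest.approx(
                float(sign)), fa

    def test_flat_signs_give_identical_treatments(self):
        cfg = ExperimentConfig(
            noise_cv=0.0, seed=2,
            effect_signs={k: 0 for k in DEFAULT_EFFECT_SIGNS})
        bundle = generate_bundle(cfg)
        ref = bundle.transients[(0.0, 0)].fluorescence
        for (dose, r), tr in bundle.transients.items():
            np.testing.assert_allclose(tr.fluorescence, ref)
        pig = bundle.ground_truth["per_replicate"][(0.0, 0)]["pigments"]
        for key in bundle.spectra:
            assert bundle.ground_truth["per_replicate"][key]["pigments"] \
                == pig
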