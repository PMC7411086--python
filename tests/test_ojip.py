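"""OJIP cardinal points and JIP-test parameter derivation."""

import numpy as np
import pytest

from phaeotox.ojip import (
    CardinalPoints,
    FluorescenceTransient,
    aoec_fraction,
    compute_jip,
    extract_cardinal_points,
    grouping_probability,
)
from phaeotox.synthetic import generate_transient


def _transient(f0=500.0, fm=2500.0, vj=0.5, vi=0.85, times=None, **kw):
    return generate_transient({"f0": f0, "fm": fm, "vj": vj, "vi": vi, **kw},
                              times=times)


class TestCardinalPoints:
    def test_construction_points_recovered(self):
        tr = _transient()
        cp = extract_cardinal_points(tr)
        assert cp.F0 == pytest.approx(500.0, rel=5e-3)
        assert cp.FM == pytest.approx(2500.0, rel=5e-3)
        assert cp.FJ == pytest.approx(500 + 0.5 * 2000, rel=5e-3)
        assert cp.FI == pytest.approx(500 + 0.85 * 2000, rel=5e-3)
        assert not cp.degenerate

    def test_flat_transient_degenerate(self):
        t = np.geomspace(1e-5, 1.0, 50)
        tr = FluorescenceTransient(times=t, fluorescence=np.full_like(t, 700.0))
        cp = extract_cardinal_points(tr)
        assert cp.degenerate
        assert cp.F0 == cp.FJ == cp.FI == cp.FM == 700.0

    def test_interpolation_matches_dense_grid_oracle(self):
        # on a very dense grid the nearest sample is the oracle
        tr_dense = _transient(times=np.geomspace(1e-5, 2.0, 20000))
        cp = extract_cardinal_points(tr_dense)
        for t_card, val in ((50e-6, cp.F0), (2e-3, cp.FJ), (30e-3, cp.FI)):
            nearest = tr_dense.fluorescence[
                np.argmin(np.abs(tr_dense.times - t_card))]
            assert val == pytest.approx(nearest, rel=1e-3)

    def test_out_of_range_time_rejected(self):
        tr = _transient()
        with pytest.raises(ValueError):
            tr.at(1e-7)


class TestComputeJip:
    def test_quantum_yield_arithmetic(self):
        tr = _transient()
        jp = compute_jip(extract_cardinal_points(tr), tr)
        assert jp.phi_P0 == pytest.approx(0.8, rel=5e-3)
        assert jp.tr0_di0 == pytest.approx(4.0, rel=2e-2)
        assert jp.VJ == pytest.approx(0.5, rel=5e-3)
        assert jp.psi_E0 == pytest.approx(0.5, rel=5e-3)
        assert jp.psi_ratio == pytest.approx(1.0, rel=2e-2)

    def test_area_matches_trapezoid_oracle(self):
        tr = _transient()
        cp = extract_cardinal_points(tr)
        jp = compute_jip(cp, tr)
        t, f = tr.times, tr.fluorescence
        i_fm = int(np.argmax(f))
        oracle = np.trapezoid(cp.FM - f[: i_fm + 1], t[: i_fm + 1])
        assert jp.area == pytest.approx(oracle, rel=5e-3)

    def test_energy_conservation_to_machine_precision(self):
        tr = _transient()
        jp = compute_jip(extract_cardinal_points(tr), tr)
        assert jp.abs_cs == jp.tr_cs + jp.di_cs  # exact float identity

    def test_degenerate_when_fm_not_above_f0(self):
        t = np.geomspace(1e-5, 1.0, 50)
        tr = FluorescenceTransient(times=t, fluorescence=np.full_like(t, 5.0))
        jp = compute_jip(extract_cardinal_points(tr), tr)
        assert jp.degenerate
        assert np.isnan(jp.VJ)

    def test_abs_cs_proxy_switch(self):
        tr = _transient()
        cp = extract_cardinal_points(tr)
        jp0 = compute_jip(cp, tr, abs_cs_proxy="F0")
        jpm = compute_jip(cp, tr, abs_cs_proxy="FM")
        assert jp0.abs_cs == cp.F0
        assert jpm.abs_cs == cp.FM
        assert jp0.phi_P0 == jpm.phi_P0


class TestJipInvariants:
    @pytest.mark.parametrize("k", [0.5, 2.0, 17.0])
    def test_scale_invariance(self, k):
        tr = _transient(vj=0.45, vi=0.8)
        scaled = FluorescenceTransient(times=tr.times,
                                       fluorescence=tr.fluorescence * k)
        a = compute_jip(extract_cardinal_points(tr), tr)
        b = compute_jip(extract_cardinal_points(scaled), scaled)
        for attr in ("VJ", "VI", "phi_P0", "psi_E0", "delta_R0", "N",
                     "tr0_di0", "M0"):
            assert getattr(b, attr) == pytest.approx(getattr(a, attr),
                                                     rel=1e-9)
        for attr in ("abs_cs", "tr_cs", "et_cs", "di_cs"):
            assert getattr(b, attr) == pytest.approx(k * getattr(a, attr),
                                                     rel=1e-9)

    def test_lowering_fm_lowers_phi_p0_and_tr0_di0(self):
        values = []
        for fm in (2500.0, 2000.0, 1500.0):
            tr = _transient(fm=fm)
            jp = compute_jip(extract_cardinal_points(tr), tr)
            values.append((jp.phi_P0, jp.tr0_di0))
        assert values[0] > values[1] > values[2]

    def test_roundtrip_recovery_within_half_percent(self, rng):
        for _ in range(25):
            f0 = rng.uniform(300, 800)
            fm = f0 * rng.uniform(3, 6)
            vj = rng.uniform(0.3, 0.6)
            vi = rng.uniform(vj + 0.05, 0.95)
            tr = _transient(f0=f0, fm=fm, vj=vj, vi=vi)
            jp = compute_jip(extract_cardinal_points(tr), tr)
            assert jp.F0 == pytest.approx(f0, rel=5e-3)
            assert jp.FM == pytest.approx(fm, rel=5e-3)
            assert jp.VJ == pytest.approx(vj, rel=5e-3)
            assert jp.VI == pytest.approx(vi, rel=5e-3)


class TestAoecAndGrouping:
    def test_sample_equal_control_gives_one(self):
        tr = _transient()
        jp = compute_jip(extract_cardinal_points(tr), tr)
        assert aoec_fraction(jp, jp) == pytest.approx(1.0)

    def test_k_step_rising_to_j_drives_aoec_to_zero(self):
        import dataclasses
        tr_c = _transient()
        control = compute_jip(extract_cardinal_points(tr_c), tr_c)
        # limit of the formula as the K band rises to the J step
        for ratio, bound in ((0.9, 0.25), (0.99, 0.03), (0.9999, 3e-4)):
            sample = dataclasses.replace(control, VK=control.VJ * ratio)
            assert aoec_fraction(sample, control) < bound
        exact = dataclasses.replace(control, VK=control.VJ)
        assert aoec_fraction(exact, control) == pytest.approx(0.0)

    def test_matches_hand_computation(self):
        tr_c = _transient(vk=0.25, vj=0.5)
        tr_s = _transient(vk=0.30, vj=0.5)
        control = compute_jip(extract_cardinal_points(tr_c), tr_c)
        sample = compute_jip(extract_cardinal_points(tr_s), tr_s)
        expected = (1 - sample.VK / sample.VJ) / (1 - control.VK / control.VJ)
        assert aoec_fraction(sample, control) == pytest.approx(expected)
        # analytic oracle from the generating ratios: (1-.6)/(1-.5) = 0.8
        assert aoec_fraction(sample, control) == pytest.approx(0.8, rel=2e-2)

    def test_grouping_probability_zero_for_identical_transients(self):
        tr = _transient()
        assert grouping_probability(tr, tr) == pytest.approx(0.0, abs=1e-9)
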