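"""Estimator algebra, invariances, recovery in the noiseless limit, bootstrap."""

import numpy as np
import pytest

import lesionbypass as lb
from conftest import make_band_table, recovery_tables


class TestIncorporationEfficiency:
    def test_equal_intensities_give_unity(self, decode_g):
        bands = make_band_table({"G14": 1.0}, decode_g)
        assert lb.incorporation_efficiency(bands, "G14") == pytest.approx(1.0)

    def test_absent_band_reads_zero(self, decode_g):
        bands = make_band_table({"G14": 1.0}, decode_g)
        assert lb.incorporation_efficiency(bands, "G13") == 0.0

    def test_direct_ratio(self, decode_g):
        bands = make_band_table({"G13": 0.078}, decode_g)
        assert lb.incorporation_efficiency(bands, "G13") == pytest.approx(0.078)

    def test_unequal_loading_corrected_by_normalization(self, decode_g):
        bands = make_band_table({"G13": 0.5}, decode_g)
        # double the G13 lane loading: both its bands scale together
        for protocol, length in ((lb.PROTOCOL_EH, 24), (lb.PROTOCOL_PH, 20)):
            sel = (bands["sample"] == "G13") & (bands["length_nt"] == length)
            bands.loc[sel, "intensity"] *= 2
        assert lb.incorporation_efficiency(bands, "G13") == pytest.approx(0.5)
        assert lb.incorporation_efficiency(
            bands, "G13", normalize=False
        ) == pytest.approx(1.0)

    def test_missing_24mer_is_data_error(self, decode_g):
        bands = make_band_table({"G13": 0.5}, decode_g)
        bands = bands[~((bands["sample"] == "G13") & (bands["length_nt"] == 24))]
        with pytest.raises(lb.DataError, match="construction"):
            lb.incorporation_efficiency(bands, "G13")

    def test_missing_control_20mer_is_control_error(self, decode_g):
        bands = make_band_table({"G13": 0.5}, decode_g)
        bands = bands[~((bands["sample"] == "STD") & (bands["length_nt"] == 20))]
        with pytest.raises(lb.ControlError):
            lb.incorporation_efficiency(bands, "G13")


class TestQuantify:
    def test_single_outcome_full_rbe(self, decode_g):
        bands = make_band_table({"G13": 1.0}, decode_g)
        res = lb.quantify(bands, decode_g)
        assert res.rbe_pct == pytest.approx(100.0)
        assert res.f_pct["G13"] == pytest.approx(100.0)

    def test_vent_ldg_worked_example(self, decode_g):
        # 0.078 + 0.042 = 0.120; 0.078/0.120 = 0.65
        bands = make_band_table({"G13": 0.078, "G14": 0.042}, decode_g)
        res = lb.quantify(bands, decode_g)
        assert res.rbe_pct == pytest.approx(12.0)
        assert res.f_pct["G13"] == pytest.approx(65.0)
        assert res.f_pct["G14"] == pytest.approx(35.0)
        assert res.labels["G13"] == "l-dG → T"

    def test_taq_lda_worked_example(self):
        decode_a = lb.decode_table("A")
        bands = make_band_table({"A16": 0.1008, "A13": 0.0592}, decode_a)
        res = lb.quantify(bands, decode_a)
        assert res.rbe_pct == pytest.approx(16.0)
        assert res.f_pct["A16"] == pytest.approx(63.0)
        assert res.f_pct["A13"] == pytest.approx(37.0)

    def test_scale_invariance(self, decode_g):
        a = lb.quantify(make_band_table({"G13": 0.3, "G15": 0.1}, decode_g), decode_g)
        b = lb.quantify(
            make_band_table({"G13": 0.3, "G15": 0.1}, decode_g, scale=137.5), decode_g
        )
        assert a.rbe == pytest.approx(b.rbe, rel=1e-12)
        for k in a.f:
            assert a.f[k] == pytest.approx(b.f[k], rel=1e-12)

    def test_frequencies_sum_to_one(self, decode_g):
        res = lb.quantify(
            make_band_table({"G13": 0.2, "G14": 0.05, "G16": 0.01}, decode_g), decode_g
        )
        assert sum(res.f.values()) == pytest.approx(1.0, abs=1e-15)

    def test_zero_rbe_flags_undefined_frequencies(self, decode_g):
        res = lb.quantify(make_band_table({}, decode_g), decode_g)
        assert res.rbe == 0.0
        assert not res.mf_defined
        assert res.f is None and res.f_pct is None  # flagged, not NaN

    def test_monotonicity_in_band_intensity(self, decode_g):
        lo = lb.quantify(make_band_table({"G13": 0.2, "G14": 0.1}, decode_g), decode_g)
        hi = lb.quantify(make_band_table({"G13": 0.3, "G14": 0.1}, decode_g), decode_g)
        assert hi.e["G13"] > lo.e["G13"]
        assert hi.rbe > lo.rbe
        assert hi.f["G13"] > lo.f["G13"]

    def test_missing_sample_is_data_error(self, decode_g):
        bands = make_band_table({"G13": 0.5}, decode_g)
        bands = bands[bands["sample"] != "G15"]
        with pytest.raises(lb.DataError, match="G15"):
            lb.quantify(bands, decode_g)

    def test_missing_control_is_control_error(self, decode_g):
        bands = make_band_table({"G13": 0.5}, decode_g)
        bands = bands[bands["sample"] != "STD"]
        with pytest.raises(lb.ControlError):
            lb.quantify(bands, decode_g)


class TestNoiselessRecovery:
    def test_expected_pool_zero_noise_recovery_is_exact(self):
        tables, decode = recovery_tables(
            "G", 0.12, {"A": 0.65, "C": 0.35}, sigma=0.0, seeds=(1,), expected=True
        )
        res = lb.quantify(tables[0], decode)
        assert abs(res.rbe - 0.12) < 1e-9
        assert abs(res.f["G13"] - 0.65) < 1e-9
        assert abs(res.f["G14"] - 0.35) < 1e-9

    def test_global_gain_cancels_end_to_end(self):
        tables, decode = recovery_tables(
            "C", 0.39, {"G": 1.0}, sigma=0.05, seeds=(4,), n_templates=20_000
        )
        base = lb.quantify(tables[0], decode)
        scaled = tables[0].copy()
        scaled["intensity"] *= 3.7e4
        res = lb.quantify(scaled, decode)
        assert res.rbe == pytest.approx(base.rbe, rel=1e-12)


class TestBootstrap:
    def test_zero_noise_gives_zero_width_interval(self):
        tables, decode = recovery_tables(
            "G", 0.12, {"A": 0.65, "C": 0.35}, sigma=0.0, seeds=(1, 2, 3), expected=True
        )
        ci = lb.bootstrap_ci(tables, decode, n_boot=50, seed=0)
        assert ci.rbe[0] == pytest.approx(ci.rbe[1], abs=1e-12)
        assert ci.rbe[0] == pytest.approx(0.12, abs=1e-9)

    def test_requires_two_replicates(self, decode_g):
        bands = make_band_table({"G13": 0.5}, decode_g)
        with pytest.raises(lb.DataError, match="2 replicate"):
            lb.bootstrap_ci([bands], decode_g)

    def test_single_resample_degenerate(self):
        tables, decode = recovery_tables(
            "G", 0.3, {"A": 1.0}, sigma=0.05, seeds=(5, 6), n_templates=5000
        )
        ci = lb.bootstrap_ci(tables, decode, n_boot=1, seed=1)
        assert ci.rbe[0] == pytest.approx(ci.rbe[1], abs=1e-15)

    def test_seeded_bootstrap_reproducible(self):
        tables, decode = recovery_tables(
            "G", 0.3, {"A": 1.0}, sigma=0.05, seeds=(5, 6, 7), n_templates=5000
        )
        a = lb.bootstrap_ci(tables, decode, n_boot=200, seed=11)
        b = lb.bootstrap_ci(tables, decode, n_boot=200, seed=11)
        assert a.rbe == b.rbe and a.f == b.f
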