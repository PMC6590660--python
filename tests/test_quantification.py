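import numpy as np
import pytest

from mp2rageme import (bland_altman, build_lookup, resample_b1, roi_medians,
                       steady_state_uni, t1_from_uni, t2star_fit)
from mp2rageme.quantification import NonMonotoneLookupError


class TestLookupTable:
    @pytest.mark.parametrize("proto", ["me_lut", "mp_lut"])
    def test_monotone_branch_covers_physiological_range(self, proto, request):
        # the long-T1 end of the branch recedes for strongly reduced transmit
        # (fold-over near 4.5 s at b1 = 0.6) but spans the full tissue range
        # throughout the physiological field window
        lut = request.getfixturevalue(proto)
        for j in range(len(lut.b1_grid)):
            assert lut.t1_grid[lut.branch_lo[j]] <= 0.5
            assert lut.t1_grid[lut.branch_hi[j]] >= 4.4
            if 0.75 <= lut.b1_grid[j] <= 1.25:
                assert lut.t1_grid[lut.branch_hi[j]] >= 5.0
            col = lut.uni_values[lut.branch_lo[j]:lut.branch_hi[j] + 1, j]
            assert np.all(np.diff(col) < 0)

    def test_single_b1_reduces_to_classic_lookup(self, me_protocol):
        lut = build_lookup(me_protocol, b1_grid=None)
        lut1 = build_lookup(me_protocol,
                            t1_grid=lut.t1_grid, b1_grid=np.array([1.0]))
        j = np.where(lut.b1_grid == 1.0)[0][0]
        np.testing.assert_allclose(lut1.uni_values[:, 0], lut.uni_values[:, j])

    @pytest.mark.parametrize("t1", [0.7003, 1.1502, 1.8497, 3.0001, 4.4999])
    @pytest.mark.parametrize("b1", [0.8, 1.0, 1.2])
    def test_encode_decode_identity(self, me_lut, me_protocol, t1, b1):
        u = float(steady_state_uni(me_protocol, t1, b1))
        t1_hat, valid = me_lut.invert(u, b1=b1)
        assert valid
        assert t1_hat == pytest.approx(t1, abs=1e-3)

    def test_out_of_branch_uni_clamps_and_flags(self, me_lut):
        t1_hat, valid = me_lut.invert(-0.499, b1=1.0)
        assert not np.all(valid)
        assert me_lut.t1_grid[0] <= t1_hat <= me_lut.t1_grid[-1]

    def test_grids_must_increase(self, me_protocol):
        with pytest.raises(ValueError):
            build_lookup(me_protocol, t1_grid=np.array([1.0, 0.5, 2.0]))

    def test_non_monotone_column_raises(self, me_protocol, monkeypatch):
        import mp2rageme.quantification as q

        def wiggly(p, t1, b1):
            t = np.broadcast_to(np.asarray(t1), np.broadcast_shapes(
                np.shape(t1), np.shape(b1))).astype(float)
            return -t + 0.3 * np.sin(20 * t)   # folds over repeatedly

        monkeypatch.setattr(q, "steady_state_uni", wiggly)
        with pytest.raises(NonMonotoneLookupError, match="fold-over"):
            build_lookup(me_protocol, t1_grid=np.linspace(0.5, 5.0, 200),
                         b1_grid=np.array([1.0]))


class TestT1FromUni:
    def test_volume_round_trip_noiseless(self, me_lut, me_protocol, rng):
        t1_true = rng.uniform(0.6, 4.5, size=(9, 8, 7))
        b1_true = rng.uniform(0.8, 1.2, size=t1_true.shape)
        uni = steady_state_uni(me_protocol, t1_true, b1_true)
        t1_hat, valid = t1_from_uni(uni, b1_true, me_lut)
        assert valid.all()
        assert np.max(np.abs(t1_hat - t1_true)) <= 2e-3

    def test_decode_at_wrong_b1_is_biased(self, me_lut, me_protocol):
        # encoded at B1=1.2 but decoded at nominal: apparent T1 is biased low
        u = float(steady_state_uni(me_protocol, 1.15, 1.2))
        biased, _ = t1_from_uni(np.full((2, 2), u), np.ones((2, 2)), me_lut)
        exact, _ = t1_from_uni(np.full((2, 2), u), np.full((2, 2), 1.2), me_lut)
        assert np.allclose(exact, 1.15, atol=2e-3)
        assert np.all(biased < 1.15 - 0.05)

    def test_b1_outside_grid_is_clamped_with_warning(self, me_lut, me_protocol,
                                                     caplog):
        uni = np.full((3, 3), float(steady_state_uni(me_protocol, 1.15, 1.4)))
        b1 = np.full((3, 3), 1.6)
        with caplog.at_level("WARNING"):
            t1_hat, valid = t1_from_uni(uni, b1, me_lut)
        assert "clamped" in caplog.text
        assert np.allclose(t1_hat, 1.15, atol=2e-3)  # clamps to grid edge 1.4

    def test_shape_mismatch_rejected(self, me_lut):
        with pytest.raises(ValueError):
            t1_from_uni(np.zeros((4, 4)), np.ones((2, 2)), me_lut)


class TestT2StarFit:
    TES = np.array([3.0, 11.5, 20.0, 28.5])

    @pytest.mark.parametrize("t2s", [5.0, 12.0, 26.7, 55.0, 100.0])
    def test_exact_on_noiseless_decay(self, t2s):
        s0 = 1.7
        echoes = [np.full((4, 3), s0 * np.exp(-te / t2s)) for te in self.TES]
        t2_hat, s0_hat, valid = t2star_fit(echoes, self.TES)
        assert valid.all()
        np.testing.assert_allclose(t2_hat, t2s, rtol=1e-9)
        np.testing.assert_allclose(s0_hat, s0, rtol=1e-9)

    def test_constant_signal_flagged_invalid(self):
        echoes = [np.ones((2, 2))] * 4
        _, _, valid = t2star_fit(echoes, self.TES)
        assert not valid.any()

    def test_all_zero_voxel_invalid_not_raised(self):
        echoes = [np.zeros(5) for _ in self.TES]
        t2_hat, _, valid = t2star_fit(echoes, self.TES)
        assert not valid.any()
        assert np.isnan(t2_hat).all()

    def test_rician_noise_median_bias_small(self, rng):
        # 10,000 voxels at magnitude SNR 30: median estimate within 5%
        t2s, s0, snr = 26.7, 1.0, 30.0
        clean = s0 * np.exp(-self.TES / t2s)
        n = 10_000
        echoes = [np.abs(c + rng.normal(0, s0 / snr, n)
                         + 1j * rng.normal(0, s0 / snr, n)) for c in clean]
        t2_hat, _, valid = t2star_fit(echoes, self.TES)
        assert valid.mean() > 0.99
        assert abs(np.median(t2_hat[valid]) / t2s - 1.0) <= 0.05

    def test_noise_floor_exclusion_keeps_two_echoes(self):
        # last echoes buried in the floor are dropped, fit still valid
        t2s = 8.0
        clean = np.exp(-self.TES / t2s)          # last echo ~0.03
        echoes = [np.full(3, c) for c in clean]
        t2_hat, _, valid = t2star_fit(echoes, self.TES, noise_sd=0.05)
        assert valid.all()
        assert np.allclose(t2_hat, t2s, rtol=1e-6)

    def test_nonlinear_refinement_matches_on_clean_data(self):
        clean = [np.full(2, 0.9 * np.exp(-te / 30.0)) for te in self.TES]
        lin, _, _ = t2star_fit(clean, self.TES)
        nl, _, _ = t2star_fit(clean, self.TES, nonlinear=True)
        np.testing.assert_allclose(nl, lin, rtol=1e-5)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            t2star_fit([np.ones(3)], [3.0])
        with pytest.raises(ValueError):
            t2star_fit([np.ones(3)] * 2, [3.0, 2.0])


class TestRoiMedians:
    def test_constant_map(self):
        labels = np.array([[1, 1, 2], [2, 2, 0]])
        table = roi_medians(np.full((2, 3), 7.5), labels)
        assert (table["median"] == 7.5).all()
        assert table.set_index("label").loc[2, "n"] == 3

    def test_empty_label_flagged(self):
        labels = np.array([1, 1, 1])
        table = roi_medians(np.array([1.0, 2.0, 3.0]), labels,
                            names={1: "wm", 4: "ghost"})
        ghost = table.set_index("label").loc[4]
        assert ghost["n"] == 0 and np.isnan(ghost["median"])

    def test_median_and_iqr(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        table = roi_medians(vals, np.ones(5, dtype=int))
        assert table.loc[0, "median"] == 3.0
        assert table.loc[0, "iqr"] == pytest.approx(2.0)

    def test_misaligned_labels_rejected(self):
        with pytest.raises(ValueError):
            roi_medians(np.zeros((2, 2)), np.zeros((3, 3), dtype=int))


class TestBlandAltman:
    def test_identical_measurements(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        stats = bland_altman(x, x)
        assert stats.mean_diff == 0.0 and stats.rpc == 0.0 and stats.cv == 0.0
        assert stats.r2 == pytest.approx(1.0)
        assert np.isnan(stats.ks_p)

    def test_rpc_recovers_normal_sd(self, rng):
        base = rng.uniform(10, 20, 10_000)
        d = rng.normal(0.0, 1.0, 10_000)
        stats = bland_altman(base + d, base)
        assert stats.rpc == pytest.approx(1.96, rel=0.03)
        assert stats.ks_p > 0.01  # differences are Gaussian

    def test_r2_is_of_the_pair_not_of_differences(self):
        x = np.linspace(0, 1, 20)
        stats = bland_altman(x, 2.0 - x)     # perfectly anti-correlated
        assert stats.r2 == pytest.approx(1.0)
        assert stats.mean_diff != 0.0

    def test_requires_paired_samples(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0, 3.0], [1.0, 2.0])


def test_resample_b1_preserves_constant_and_shape():
    out = resample_b1(np.full((4, 4, 4), 1.05), (12, 11, 10))
    assert out.shape == (12, 11, 10)
    np.testing.assert_allclose(out, 1.05)
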