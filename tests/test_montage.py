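import numpy as np
import pytest

import megmontage as mm
from megmontage.forward import LeadField
from megmontage.montage import (
    MontageOperator,
    SourceWaveforms,
    build_whitener,
    principal_mode,
)


def _random_leadfield(rng, M=20, P=8):
    return LeadField(
        matrix=rng.standard_normal((M, P)) * 1e-12,
        row_channels=[f"c{i}" for i in range(M)],
        col_components=[(f"s{j // 2}", ["theta", "phi"][j % 2]) for j in range(P)],
    )


class TestWhitener:
    def test_diagonal_default_magnetometer_scale(self, helmet, noise):
        W = build_whitener(noise)
        mag_rows = [i for i, c in enumerate(helmet.channels) if c.kind == "magnetometer"]
        assert np.allclose(W[mag_rows], 1.0 / 2e-13)

    def test_identity_covariance(self):
        n = mm.NoiseModel(kind="full", covariance=np.eye(5))
        assert np.allclose(build_whitener(n), np.eye(5))

    def test_full_covariance_whitens(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((6, 6))
        C = A @ A.T + 6 * np.eye(6)
        W = build_whitener(mm.NoiseModel(kind="full", covariance=C))
        assert np.allclose(W @ C @ W.T, np.eye(6), atol=1e-10)

    def test_non_positive_definite_rejected(self):
        C = np.diag([1.0, -1.0, 2.0])
        with pytest.raises(ValueError):
            build_whitener(mm.NoiseModel(kind="full", covariance=C))

    def test_bad_sds_rejected(self):
        with pytest.raises(ValueError):
            mm.NoiseModel(sds=[1e-13, 0.0])


class TestBuildMontage:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_unit_diagonal_gram(self, seed):
        """diag(Ln' Ln) = 1 for random lead fields and noise models."""
        rng = np.random.default_rng(seed)
        lf = _random_leadfield(rng)
        noise = mm.NoiseModel(sds=rng.uniform(0.5, 2.0, 20) * 1e-13)
        lam = rng.uniform(0, 0.05)
        op = mm.build_montage(lf, noise, lam)
        assert np.allclose(np.diag(op.gram) - lam, 1.0, atol=1e-12)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_unit_gram_full_covariance(self, seed):
        rng = np.random.default_rng(seed)
        lf = _random_leadfield(rng)
        A = rng.standard_normal((20, 20)) * 1e-13
        noise = mm.NoiseModel(kind="full", covariance=A @ A.T + 20e-26 * np.eye(20))
        op = mm.build_montage(lf, noise, 0.01)
        assert np.allclose(np.diag(op.gram) - 0.01, 1.0, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_recovery_at_zero_lambda(self, seed):
        """lambda=0, noiseless b = L s recovers s to 1e-10 relative error."""
        rng = np.random.default_rng(seed)
        lf = _random_leadfield(rng, M=30, P=10)
        noise = mm.NoiseModel(sds=rng.uniform(0.5, 2.0, 30) * 1e-13)
        op = mm.build_montage(lf, noise, 0.0)
        s = rng.standard_normal((10, 7)) * 1e-8
        shat = op.transform @ (lf.matrix @ s)
        assert np.linalg.norm(shat - s) < 1e-10 * np.linalg.norm(s)

    def test_amplitude_shrinks_monotonically_with_lambda(self, leadfield, noise):
        """Reconstructed amplitude at a montage location decreases as the
        regularization grows (noiseless limit)."""
        s = np.zeros(58)
        s[14] = 1e-7
        b = leadfield.matrix @ s
        amps = []
        for lam in (0.0, 0.005, 0.01, 0.02, 0.03, 0.04, 0.05):
            op = mm.build_montage(leadfield, noise, lam)
            amps.append(np.linalg.norm((op.transform @ b)[14:16]))
        assert all(a > b_ for a, b_ in zip(amps, amps[1:]))
        assert amps[0] == pytest.approx(1e-7, rel=1e-9)

    def test_large_lambda_drives_output_to_zero(self, tiny_leadfield, tiny_helmet):
        noise = mm.NoiseModel.from_array(tiny_helmet)
        b = tiny_leadfield.matrix @ (1e-7 * np.ones(8))
        big = mm.build_montage(tiny_leadfield, noise, 1e4)
        assert np.linalg.norm(big.transform @ b) < 1e-3 * 1e-7

    def test_silent_component_named_in_error(self, tiny_helmet):
        lf = _random_leadfield(np.random.default_rng(0), M=24, P=4)
        lf.matrix[:, 2] = 0.0
        with pytest.raises(ValueError, match="s1"):
            mm.build_montage(lf, mm.NoiseModel.from_array(tiny_helmet), 0.01)

    def test_negative_lambda_rejected(self, tiny_leadfield, tiny_helmet):
        with pytest.raises(ValueError):
            mm.build_montage(tiny_leadfield, mm.NoiseModel.from_array(tiny_helmet), -0.1)

    def test_save_load_round_trip(self, tiny_leadfield, tiny_helmet, tmp_path):
        op = mm.build_montage(tiny_leadfield, mm.NoiseModel.from_array(tiny_helmet), 0.02)
        path = tmp_path / "montage.json"
        op.save(path)
        again = MontageOperator.load(path)
        assert np.allclose(again.transform, op.transform)
        assert again.lambda_frac == 0.02
        assert again.channel_order == op.channel_order
        assert again.component_order == op.component_order


class TestApplyMontage:
    @pytest.fixture(scope="class")
    def tiny_op(self, tiny_leadfield, tiny_helmet):
        return mm.build_montage(tiny_leadfield, mm.NoiseModel.from_array(tiny_helmet), 0.01)

    def test_zero_in_zero_out_and_linearity(self, tiny_op, tiny_helmet):
        z = mm.Recording(data=np.zeros((24, 50)), fs=1000.0, array=tiny_helmet)
        assert np.all(tiny_op.apply(z).data == 0)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((24, 50)) * 1e-12
        y = rng.standard_normal((24, 50)) * 1e-12
        rx = mm.Recording(data=x, fs=1000.0, array=tiny_helmet)
        ry = mm.Recording(data=y, fs=1000.0, array=tiny_helmet)
        rxy = mm.Recording(data=2 * x + 3 * y, fs=1000.0, array=tiny_helmet)
        assert np.allclose(
            tiny_op.apply(rxy).data,
            2 * tiny_op.apply(rx).data + 3 * tiny_op.apply(ry).data,
        )

    def test_channel_mismatch_raises(self, tiny_op, helmet):
        rec = mm.Recording(data=np.zeros((306, 10)), fs=1000.0, array=helmet)
        with pytest.raises(ValueError, match="channel order"):
            tiny_op.apply(rec)

    def test_reorder_then_apply_matches(self, tiny_op, tiny_helmet):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((24, 30)) * 1e-12
        rec = mm.Recording(data=x, fs=1000.0, array=tiny_helmet)
        perm = list(np.random.default_rng(3).permutation(24))
        shuffled = rec.reorder([tiny_helmet.names[i] for i in perm])
        back = shuffled.reorder(tiny_op.channel_order)
        assert np.allclose(tiny_op.apply(back).data, tiny_op.apply(rec).data)


class TestDisplayModes:
    def _components(self, data):
        P = data.shape[0]
        labels = [(f"s{j // 2}", ["theta", "phi"][j % 2]) for j in range(P)]
        return SourceWaveforms(data=data, fs=1000.0, labels=labels)

    def test_rms_arithmetic(self):
        w = self._components(np.array([[3.0], [4.0]]))
        out = mm.rms_mode(w)
        assert out.data[0, 0] == pytest.approx(np.sqrt((9 + 16) / 2))
        assert out.mode == "rms"

    def test_rms_single_component(self):
        w = self._components(np.array([[5.0], [0.0]]))
        assert mm.rms_mode(w).data[0, 0] == pytest.approx(5.0 / np.sqrt(2))

    def test_rms_row_count_for_br29(self, leadfield, noise, helmet):
        op = mm.build_montage(leadfield, noise, 0.02)
        rec = mm.Recording(
            data=np.random.default_rng(0).standard_normal((306, 40)) * 1e-12,
            fs=1000.0,
            array=helmet,
        )
        out = mm.rms_mode(op.apply(rec))
        assert out.data.shape[0] == 29

    def test_principal_fixed_orientation_captures_all_variance(self):
        t = np.linspace(0, 1, 200)
        src = np.sin(2 * np.pi * 5 * t)
        u = np.array([0.6, 0.8])
        w = self._components(np.outer(u, src))
        out, est = principal_mode(w)
        assert est[0].eigenvalues[1] == pytest.approx(0.0, abs=1e-12 * est[0].eigenvalues[0])
        assert abs(est[0].principal @ u) == pytest.approx(1.0)
        # projection reconstructs the scalar waveform up to sign convention
        assert np.allclose(np.abs(out.data[0]), np.abs(src), atol=1e-12)

    def test_principal_matches_svd_oracle(self):
        rng = np.random.default_rng(7)
        S = rng.standard_normal((2, 300))
        w = self._components(S)
        out, est = principal_mode(w)
        U, sv, _ = np.linalg.svd(S, full_matrices=False)
        assert np.allclose(np.sort(est[0].eigenvalues), np.sort(sv**2), rtol=1e-10)
        assert abs(est[0].principal @ U[:, 0]) == pytest.approx(1.0, rel=1e-10)

    def test_degenerate_tie_break_deterministic(self):
        """Two equal-power orthogonal components: the e_theta-dominant
        eigenvector is chosen, and repeated calls agree."""
        t = np.arange(400)
        S = np.vstack([np.cos(2 * np.pi * t / 100), np.sin(2 * np.pi * t / 100)])
        w = self._components(S)
        out1, est1 = principal_mode(w)
        out2, est2 = principal_mode(w)
        assert np.array_equal(out1.data, out2.data)
        assert abs(est1[0].principal[0]) >= abs(est1[0].principal[1])

    def test_zero_window_flags_undefined(self):
        w = self._components(np.zeros((2, 50)))
        out, est = principal_mode(w)
        assert not est[0].defined
        assert np.all(out.data == 0)

    def test_windowed_orientation(self):
        """Orientation is estimated on the window but projected over the
        full trace."""
        S = np.zeros((2, 100))
        S[0, :50] = 1.0  # theta-only in the first half
        S[1, 50:] = 2.0  # phi-only in the second half
        w = self._components(S)
        out, est = principal_mode(w, window=slice(0, 50))
        assert np.allclose(np.abs(est[0].principal), [1.0, 0.0], atol=1e-12)
        assert np.allclose(out.data[0, 50:], 0.0, atol=1e-12)


class TestConditionNumber:
    def _op_with_gram(self, G):
        P = G.shape[0]
        return MontageOperator(
            transform=np.zeros((P, 4)),
            lambda_frac=0.0,
            whitener=np.ones(4),
            depth_weights=np.ones(P),
            gram=G,
            channel_order=[f"c{i}" for i in range(4)],
            component_order=[(f"s{i}", "theta") for i in range(P)],
        )

    def test_identity_and_diag(self):
        assert mm.condition_number(self._op_with_gram(np.eye(3))) == pytest.approx(1.0)
        assert mm.condition_number(self._op_with_gram(np.diag([4.0, 1.0]))) == pytest.approx(4.0)

    def test_strictly_decreasing_in_lambda(self, leadfield, noise):
        conds = [
            mm.condition_number(mm.build_montage(leadfield, noise, lam))
            for lam in (0.0, 0.005, 0.01, 0.02, 0.03, 0.04, 0.05)
        ]
        assert all(a > b for a, b in zip(conds, conds[1:]))


class TestOrientationRecovery:
    def test_within_5_degrees_at_high_snr(self, leadfield, noise, helmet, br29):
        """A fixed-orientation tangential dipole at high SNR yields a
        principal orientation within 5 degrees of the truth."""
        import megmontage.simulate as sim
        from megmontage.forward import DipoleSource

        # lambda = 0: the pseudoinverse is orientation-unbiased, so the
        # residual error isolates the noise sensitivity of the principal
        # extraction
        op = mm.build_montage(leadfield, noise, 0.0)
        loc = br29["FC6R"]
        angle_true = np.deg2rad(30.0)
        direction = np.cos(angle_true) * loc.e_theta + np.sin(angle_true) * loc.e_phi
        wf = sim.make_burst_waveform(sim.BurstSpec(), 1000.0, 4.0)
        bg = sim.synth_background(helmet, 1000.0, 4.0, seed=10)
        rec = sim.simulate_recording(
            DipoleSource(loc.position, direction), wf, bg, br29.sphere
        )
        windows = mm.SnrWindows.default(1000.0, 4.0)
        comp = op.apply(rec)
        pr, est = principal_mode(comp, window=windows.signal_mask(rec.n_samples))
        j = pr.labels.index("FC6R")
        snr2 = mm.snr_db_channels(pr.data, windows)[j]
        assert snr2 >= 30.0
        err = abs(est[j].angle - angle_true)
        err = min(err, np.pi - err)
        assert np.rad2deg(err) <= 5.0
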