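"""Time-frequency distribution, PLV, dPAC, and network construction."""

import numpy as np
import pytest

from multifreq import (
    BandSpec,
    TrialEpochs,
    amplitude_envelope,
    build_network,
    dpac,
    intra_layer_weights,
    inter_layer_weights,
    low_freq_phase,
    plv,
    rid_rihaczek,
    tf_phase_difference,
)

FS, N = 256.0, 256
T = np.arange(N) / FS


class TestRidRihaczek:
    def test_sinusoid_energy_concentrates_on_ridge(self):
        tfd = rid_rihaczek(np.cos(2 * np.pi * 40 * T), FS)
        bin40 = int(40 * N / FS)
        ridge = np.argmax(np.abs(tfd.values[20:-20]), axis=1)
        assert np.all(ridge == bin40)

    def test_zero_signal_gives_zero_tfd(self):
        tfd = rid_rihaczek(np.zeros(N), FS)
        assert np.allclose(tfd.values, 0.0)

    def test_kernel_reduces_cross_term_ripple(self):
        # two tones: interference makes |C| at a component bin ripple at the
        # difference frequency; the reduced-interference kernel suppresses it
        x = np.cos(2 * np.pi * 20 * T) + np.cos(2 * np.pi * 100 * T)
        bin20 = int(20 * N / FS)
        rid = np.abs(rid_rihaczek(x, FS).values[20:-20, bin20])
        plain = np.abs(rid_rihaczek(x, FS, kernel_param=1e6).values[20:-20, bin20])
        cv = lambda v: v.std() / v.mean()
        assert cv(rid) < 0.1
        assert cv(rid) < 0.2 * cv(plain)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            rid_rihaczek(np.zeros(16), FS, kernel_param=0.0)
        with pytest.raises(ValueError):
            rid_rihaczek(np.full(16, np.nan), FS)
        with pytest.raises(ValueError):
            rid_rihaczek(np.zeros((4, 4)), FS)


class TestPhaseDifference:
    def test_identical_channels_zero_phase(self):
        tfd = rid_rihaczek(np.cos(2 * np.pi * 10 * T), FS)
        phi = tf_phase_difference(tfd, tfd)
        assert np.allclose(phi.compressed(), 0.0, atol=1e-9)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a = rid_rihaczek(rng.normal(size=N), FS)
        b = rid_rihaczek(rng.normal(size=N), FS)
        ab, ba = tf_phase_difference(a, b), tf_phase_difference(b, a)
        # -pi/pi boundary aside, phases negate
        z = np.exp(1j * ab.filled(0)) * np.exp(1j * ba.filled(0))
        assert np.allclose(np.angle(z), 0.0, atol=1e-9)

    def test_delayed_sinusoid_phase_at_carrier(self):
        # weak kernel keeps the spectral delay phase intact; magnitude-weighted
        # circular mean at the carrier bin equals -2 pi f0 dt
        f0, dt = 8.0, 0.02
        Cu = rid_rihaczek(np.cos(2 * np.pi * f0 * T), FS, kernel_param=1.0)
        Cv = rid_rihaczek(np.cos(2 * np.pi * f0 * (T - dt)), FS, kernel_param=1.0)
        phi = tf_phase_difference(Cu, Cv)
        b = int(round(f0 * N / FS))
        w = (np.abs(Cu.values[:, b]) * np.abs(Cv.values[:, b]))[20:-20]
        z = np.sum(w * np.exp(1j * phi[20:-20, b].filled(0))) / w.sum()
        assert abs(np.angle(z)) == pytest.approx(2 * np.pi * f0 * dt, abs=0.1)

    def test_mismatched_axes_rejected(self):
        a = rid_rihaczek(np.zeros(N), FS)
        b = rid_rihaczek(np.zeros(N // 2), FS)
        with pytest.raises(ValueError):
            tf_phase_difference(a, b)


class TestPlv:
    def test_identical_phases_give_one(self):
        phi = np.tile(np.linspace(-3, 3, 50), (8, 1))
        assert np.allclose(plv(phi), 1.0)

    def test_balanced_opposite_phases_cancel(self):
        phi = np.array([[0.0], [np.pi], [0.0], [np.pi]])
        assert plv(phi)[0] == pytest.approx(0.0, abs=1e-12)

    def test_uniform_random_phases_match_rayleigh_expectation(self):
        # E[PLV] for i.i.d. uniform phases ~ sqrt(pi / (4K))
        rng = np.random.default_rng(7)
        K = 50
        values = plv(rng.uniform(-np.pi, np.pi, size=(K, 1000)))
        assert values.mean() == pytest.approx(np.sqrt(np.pi / (4 * K)), abs=0.01)

    def test_requires_two_trials(self):
        with pytest.raises(ValueError):
            plv(np.zeros((1, 4)))


class TestIntraLayerWeights:
    def test_identical_channels_weight_one(self):
        x = np.cos(2 * np.pi * 10 * T)
        data = np.stack([x, x])[:, :, None] * np.ones((2, N, 5))
        w = intra_layer_weights(TrialEpochs(data, FS), (8.0, 12.0), (0.1, 0.6))
        assert w[0, 1] == pytest.approx(1.0, abs=1e-9)
        assert w[0, 0] == 0.0

    def test_independent_noise_near_rayleigh_floor(self):
        rng = np.random.default_rng(1)
        K = 40
        data = rng.normal(size=(2, N, K))
        w = intra_layer_weights(TrialEpochs(data, FS), (8.0, 12.0), (0.1, 0.6))
        assert w[0, 1] < 2.0 * np.sqrt(np.pi / (4 * K))

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(4, N, 6))
        w = intra_layer_weights(TrialEpochs(data, FS), (8.0, 12.0), (0.1, 0.6))
        assert np.allclose(w, w.T)
        assert np.all((w >= 0) & (w <= 1))

    def test_empty_band_rejected(self):
        data = np.zeros((2, N, 3))
        with pytest.raises(ValueError):
            intra_layer_weights(TrialEpochs(data, FS), (8.2, 8.8), (0.1, 0.6))


class TestEnvelopeAndPhase:
    def test_am_envelope_tracks_modulator(self):
        mod = 1 + 0.8 * np.cos(2 * np.pi * 6 * T)
        tfd = rid_rihaczek(mod * np.cos(2 * np.pi * 40 * T), FS)
        env = amplitude_envelope(tfd, (31.0, 100.0))
        r = np.corrcoef(env[20:-20], mod[20:-20])[0, 1]
        assert r > 0.8

    def test_unmodulated_carrier_envelope_flat(self):
        tfd = rid_rihaczek(np.cos(2 * np.pi * 40 * T), FS)
        env = amplitude_envelope(tfd, (31.0, 100.0))
        inner = env[20:-20]
        assert inner.std() / inner.mean() < 0.2

    def test_zero_signal_zero_envelope(self):
        tfd = rid_rihaczek(np.zeros(N), FS)
        assert np.allclose(amplitude_envelope(tfd, (31.0, 100.0)), 0.0)

    def test_phase_advances_at_carrier_rate(self):
        tfd = rid_rihaczek(np.cos(2 * np.pi * 6 * T + 1.0), FS)
        phi = np.unwrap(np.asarray(low_freq_phase(tfd, 6.0)))
        slope = np.polyfit(T, phi, 1)[0]
        assert slope == pytest.approx(2 * np.pi * 6, rel=0.05)

    def test_phase_of_negated_signal_shifts_by_pi(self):
        x = np.cos(2 * np.pi * 6 * T)
        p1 = low_freq_phase(rid_rihaczek(x, FS), 6.0)
        p2 = low_freq_phase(rid_rihaczek(-x, FS), 6.0)
        diff = np.angle(np.exp(1j * (np.asarray(p2) - np.asarray(p1))))
        assert np.allclose(np.abs(diff), np.pi, atol=1e-9)

    def test_empty_band_rejected(self):
        tfd = rid_rihaczek(np.cos(2 * np.pi * 6 * T), FS)
        with pytest.raises(ValueError):
            amplitude_envelope(tfd, (40.0, 40.0))


class TestDpac:
    def test_cauchy_schwarz_equality_case(self):
        K = 20
        a = np.full((K, 4), 2.5)
        phi = np.tile(np.linspace(0, 1, 4), (K, 1))
        assert np.allclose(dpac(a, phi), 1.0)

    def test_bounded_by_one(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 5, (30, 50))
        phi = rng.uniform(-np.pi, np.pi, (30, 50))
        assert np.all(dpac(a, phi) <= 1.0 + 1e-12)

    def test_uncoupled_floor_shrinks_with_trials(self):
        rng = np.random.default_rng(4)
        K = 100
        a = rng.uniform(0.5, 1.5, (K, 1000))
        phi = rng.uniform(-np.pi, np.pi, (K, 1000))
        assert dpac(a, phi).mean() < 0.15

    def test_planted_coupling_exceeds_uncoupled(self):
        rng = np.random.default_rng(5)
        K = 60
        phi = rng.uniform(-np.pi, np.pi, (K, 500))
        coupled = dpac(1 + 0.9 * np.cos(phi), phi)
        uncoupled = dpac(1 + 0.9 * np.cos(rng.uniform(-np.pi, np.pi, phi.shape)), phi)
        assert coupled.mean() > 2 * uncoupled.mean()

    def test_zero_amplitudes_give_zero(self):
        assert dpac(np.zeros((5, 3)), np.ones((5, 3)))[0] == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dpac(np.zeros((5, 3)), np.zeros((5, 4)))


class TestInterLayerWeights:
    def _epochs(self, coupled, seed=0, K=40):
        rng = np.random.default_rng(seed)
        data = rng.normal(0, 0.3, size=(4, N, K))
        for k in range(K):
            phi0 = rng.uniform(0, 2 * np.pi)
            data[0, :, k] += np.cos(2 * np.pi * 6 * T + phi0)
            env = 1 + 0.9 * np.cos(2 * np.pi * 6 * T + phi0) if coupled else 1.0
            psi = rng.uniform(0, 2 * np.pi)
            data[1, :, k] += env * np.cos(2 * np.pi * 40 * T + psi)
            data[2, :, k] += np.cos(2 * np.pi * 6 * T + rng.uniform(0, 2 * np.pi))
            data[3, :, k] += np.cos(2 * np.pi * 40 * T + rng.uniform(0, 2 * np.pi))
        return TrialEpochs(data, FS)

    def test_planted_link_is_largest_block_entry(self):
        w = inter_layer_weights(
            self._epochs(coupled=True), (4.0, 8.0), (35.0, 46.0), (0.1, 0.6)
        )
        off_diag = w.copy()
        assert off_diag[0, 1] == off_diag.max()

    def test_uncoupled_block_stays_near_floor(self):
        w = inter_layer_weights(
            self._epochs(coupled=False), (4.0, 8.0), (35.0, 46.0), (0.1, 0.6)
        )
        assert w.max() < 0.35

    def test_band_order_enforced(self):
        with pytest.raises(ValueError):
            inter_layer_weights(
                self._epochs(True, K=3), (35.0, 46.0), (4.0, 8.0), (0.1, 0.6)
            )
        with pytest.raises(ValueError):
            inter_layer_weights(
                self._epochs(True, K=3), (4.0, 8.0), (35.0, 46.0), (0.1, 0.6),
                pac_direction="sideways",
            )


class TestBuildNetwork:
    def test_network_valid_and_deterministic(self):
        rng = np.random.default_rng(6)
        data = rng.normal(size=(3, N, 6))
        epochs = TrialEpochs(data, FS)
        bands = BandSpec(bands={"theta": (4.0, 8.0), "gamma": (31.0, 49.0)},
                         window=(0.1, 0.4))
        net = build_network(epochs, bands)
        assert net.layers == ["theta", "gamma"]
        assert net.n_nodes == [3, 3]
        for h in range(2):
            blk = net.intra_block(h)
            assert np.allclose(blk, blk.T)
            assert blk.min() >= 0 and blk.max() <= 1
        assert net.inter_block(0, 1).max() <= 1
        net2 = build_network(TrialEpochs(data, FS), bands)
        assert net2 == net

    def test_all_noise_input_gives_uniform_weak_weights(self):
        rng = np.random.default_rng(8)
        epochs = TrialEpochs(rng.normal(size=(4, N, 30)), FS)
        bands = BandSpec(bands={"theta": (4.0, 8.0), "gamma": (31.0, 49.0)},
                         window=(0.1, 0.4))
        net = build_network(epochs, bands)
        iu = np.triu_indices(4, 1)
        assert net.intra_block(0)[iu].max() < 0.5
        assert net.inter_block(0, 1).max() < 0.4

    def test_epochs_file_round_trip(self, tmp_path):
        from multifreq import load_epochs, save_epochs

        rng = np.random.default_rng(9)
        epochs = TrialEpochs(rng.normal(size=(3, 32, 4)), FS, t0=0.1,
                             channel_names=["Fz", "Cz", "Pz"])
        save_epochs(epochs, str(tmp_path / "ep"))
        back = load_epochs(str(tmp_path / "ep"))
        assert np.array_equal(back.data, epochs.data)
        assert back.fs == epochs.fs and back.t0 == epochs.t0
        assert back.channel_names == ["Fz", "Cz", "Pz"]

    def test_epoch_validation(self):
        with pytest.raises(ValueError):
            TrialEpochs(np.zeros((2, 16, 1)), FS)  # single trial
        with pytest.raises(ValueError):
            TrialEpochs(np.zeros((2, 16, 4)), -1.0)
        with pytest.raises(ValueError):
            BandSpec(bands={"a": (8.0, 4.0)})
        with pytest.raises(ValueError):
            BandSpec(bands={"a": (4.0, 8.0), "b": (6.0, 12.0)})
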