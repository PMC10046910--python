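"""Network behaviour: kernel algebra, oracle equivalence, gradients, training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from kcsfcnet.model import (KCSFCnet, connectivity_block, count_parameters,
                            extract_connectivity, gaussian_kernel, pair_indices)
from kcsfcnet.synthetic import Coupling, SyntheticSpec, generate_subject


class TestGaussianKernel:
    def test_zero_distance_gives_one(self):
        z = np.arange(5.0)
        assert gaussian_kernel(z, z, sigma=2.0) == 1.0

    def test_analytic_value_at_two_sigma_squared(self):
        z = np.zeros(2)
        zp = np.array([np.sqrt(2.0) * 1.5, 0.0])  # d^2 = 2 sigma^2 at sigma=1.5
        assert gaussian_kernel(z, zp, sigma=1.5) == pytest.approx(np.exp(-1), abs=1e-12)

    def test_matches_independent_expression(self, rng):
        z, zp = rng.standard_normal((2, 32))
        expected = np.exp(-np.sum((z - zp) ** 2) / (2 * 1.5**2))
        assert gaussian_kernel(z, zp, sigma=1.5) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("sigma", [0.0, -1.0])
    def test_nonpositive_sigma_rejected(self, sigma):
        with pytest.raises(ValueError, match="sigma"):
            gaussian_kernel(np.zeros(3), np.ones(3), sigma)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            gaussian_kernel(np.zeros(3), np.zeros(4), 1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(arrays(float, 8, elements=st.floats(-5, 5)),
           arrays(float, 8, elements=st.floats(-5, 5)),
           st.floats(0.1, 10))
    def test_range_and_symmetry(self, z, zp, sigma):
        k = gaussian_kernel(z, zp, sigma)
        assert 0.0 <= k <= 1.0  # mathematically (0,1]; 0.0 only by underflow
        assert k == gaussian_kernel(zp, z, sigma)


class TestConnectivityBlock:
    def test_identical_channels_give_ones(self):
        filt = np.tile(np.random.default_rng(0).standard_normal((1, 1, 10)), (1, 4, 1))
        assert np.allclose(connectivity_block(filt, sigma=1.0), 1.0)

    def test_pair_enumeration_for_four_channels(self):
        i, j = pair_indices(4)
        assert list(zip(i.tolist(), j.tolist())) == [
            (0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        out = connectivity_block(np.random.default_rng(1).standard_normal((2, 4, 10)), 1.0)
        assert out.shape == (2, 6)

    def test_brute_force_oracle(self, rng):
        filt = rng.standard_normal((2, 8, 49))
        got = connectivity_block(filt, sigma=2.0)
        i, j = pair_indices(8)
        for f in range(2):
            for p, (a, b) in enumerate(zip(i, j)):
                expected = gaussian_kernel(filt[f, a], filt[f, b], 2.0)
                assert abs(got[f, p] - expected) < 1e-5

    def test_nonfinite_rejected(self):
        bad = np.zeros((1, 3, 5))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            connectivity_block(bad, 1.0)


def straight_line_forward(X, W, sigma, V, b):
    """Independent composition: convolve -> ELU -> pairwise kernels ->
    filter mean -> ELU -> linear -> softmax (no normalisation, no dropout)."""
    B, nc, nt = X.shape
    nf, dt = W.shape
    T = nt - dt + 1

    def elu(v):
        return np.where(v > 0, v, np.exp(v) - 1)

    probs = np.zeros((B, V.shape[1]))
    conns = []
    for r in range(B):
        feat = np.zeros((nf, nc, T))
        for f in range(nf):
            for c in range(nc):
                for t in range(T):
                    feat[f, c, t] = np.dot(X[r, c, t:t + dt], W[f])
        feat = elu(feat)
        i, j = pair_indices(nc)
        kmat = np.zeros((nf, len(i)))
        for f in range(nf):
            for p, (a, c2) in enumerate(zip(i, j)):
                kmat[f, p] = np.exp(-np.sum((feat[f, a] - feat[f, c2]) ** 2)
                                    / (2 * sigma**2))
        conn = kmat.mean(axis=0)
        conns.append(conn)
        z = elu(conn) @ V + b
        e = np.exp(z - z.max())
        probs[r] = e / e.sum()
    return probs, np.array(conns)


class TestForward:
    def test_matches_straight_line_oracle(self, rng):
        X = rng.standard_normal((1, 3, 16))
        y = np.array([0])  # single trial; fit() needs both classes, so build by hand
        m = KCSFCnet(n_filters=1, kernel_length=4, n_epochs=0, dropout_rate=0.0,
                     batch_norm=False, sigma_init="fixed", sigma_value=1.3,
                     dtype="float64", random_state=5)
        Xfit = rng.standard_normal((4, 3, 16))
        m.fit(Xfit, np.array([0, 1, 0, 1]))
        probs, conn = m.forward(X.astype(np.float64))
        W = m.conv_filters_
        exp_probs, exp_conn = straight_line_forward(
            X, W, m.sigma_, m.readout_weights_, m.intercept_)
        assert np.abs(probs - exp_probs).max() < 1e-6
        assert np.abs(conn - exp_conn).max() < 1e-6

    def test_probabilities_normalised(self, fitted_small, small_planted):
        probs = fitted_small.predict_proba(small_planted.data)
        assert np.all(probs >= 0) and np.all(probs <= 1)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_readout_gives_uniform(self, tiny_trials):
        m = KCSFCnet(n_filters=1, kernel_length=4, n_epochs=0, dropout_rate=0.0,
                     random_state=0)
        m.fit(tiny_trials.data, tiny_trials.labels)
        m._params["V"][:] = 0.0
        m._params["c"][:] = 0.0
        probs, _ = m.forward(tiny_trials.data)
        assert np.allclose(probs, 0.5, atol=1e-12)

    def test_shape_mismatch_named(self, fitted_small):
        with pytest.raises(ValueError, match="expected"):
            fitted_small.predict(np.zeros((2, 3, 50)))


class TestInitialisation:
    def test_median_heuristic_halves_median_distance(self, tiny_trials):
        m = KCSFCnet(n_filters=2, kernel_length=8, n_epochs=0, dropout_rate=0.0,
                     dtype="float64", random_state=1)
        m.fit(tiny_trials.data, tiny_trials.labels)
        X = m._validate_X(tiny_trials.data)
        cache = m._forward(m._params, X, training=True)
        med = np.median(cache["D2"])  # sigma^2 = median/2  =>  median kernel e^-1
        assert m.sigma_ == pytest.approx(np.sqrt(med / 2.0), rel=1e-6)
        # median of a monotone transform: exact up to even-count interpolation
        med_kernel = np.median(np.exp(-cache["D2"] / (2 * m.sigma_**2)))
        assert med_kernel == pytest.approx(np.exp(-1), rel=1e-3)

    def test_fixed_policy(self, tiny_trials):
        m = KCSFCnet(sigma_init="fixed", sigma_value=1.0, kernel_length=8,
                     n_epochs=0, random_state=0)
        m.fit(tiny_trials.data, tiny_trials.labels)
        assert m.sigma_ == 1.0

    def test_degenerate_batch_falls_back_with_warning(self):
        X = np.zeros((4, 3, 16))
        y = np.array([0, 1, 0, 1])
        m = KCSFCnet(n_filters=1, kernel_length=4, n_epochs=0, batch_norm=False,
                     random_state=0)
        with pytest.warns(UserWarning, match="sigma=1"):
            m.fit(X, y)
        assert m.sigma_ == 1.0

    def test_same_seed_identical_params(self, tiny_trials):
        a = KCSFCnet(kernel_length=8, n_epochs=5, random_state=3)
        b = KCSFCnet(kernel_length=8, n_epochs=5, random_state=3)
        a.fit(tiny_trials.data, tiny_trials.labels)
        b.fit(tiny_trials.data, tiny_trials.labels)
        for k in a._params:
            assert np.array_equal(a._params[k], b._params[k])


class TestCountParameters:
    @pytest.mark.parametrize("nc,nf,dt,ny,expected", [
        (64, 4, 64, 2, 4301),
        (64, 2, 64, 2, 4169),
        (2, 1, 2, 2, 11),
    ])
    def test_closed_form(self, nc, nf, dt, ny, expected):
        assert count_parameters(nc, nf, dt, ny) == expected

    def test_matches_live_model(self, fitted_small):
        live = sum(np.asarray(v).size for v in fitted_small._params.values())
        assert fitted_small.n_parameters_ == live
        assert fitted_small.n_parameters_ == count_parameters(8, 2, 32, 2)


class TestGradients:
    def test_backprop_matches_finite_differences(self, tiny_trials):
        m = KCSFCnet(n_filters=2, kernel_length=8, n_epochs=1, dropout_rate=0.0,
                     dtype="float64", random_state=0)
        m.fit(tiny_trials.data, tiny_trials.labels)
        X = m._validate_X(tiny_trials.data)
        P = {k: np.asarray(v).copy() for k, v in m._params.items()}
        Y = np.eye(2)[tiny_trials.labels]

        def loss_at(params):
            return m._loss(m._forward(params, X, training=True)["probs"], Y)

        grads = m._backward(P, m._forward(P, X, training=True), Y)
        eps = 1e-6
        for key, idx in [("rho", ()), ("W", (0, 3)), ("W", (1, 5)),
                         ("V", (2, 1)), ("g1", (0,)), ("g2", ()), ("c", (1,))]:
            pp = {k: np.asarray(v).copy() for k, v in P.items()}
            pm = {k: np.asarray(v).copy() for k, v in P.items()}
            pp[key][idx] += eps
            pm[key][idx] -= eps
            fd = (loss_at(pp) - loss_at(pm)) / (2 * eps)
            an = np.asarray(grads[key])[idx]
            rel = abs(fd - an) / max(abs(fd), abs(an), 1e-12)
            assert rel < 1e-4, f"gradient mismatch for {key}{idx}: {rel:.2e}"


class TestTraining:
    def test_learns_planted_coupling(self, fitted_small, small_planted):
        acc = (fitted_small.predict(small_planted.data) == small_planted.labels).mean()
        assert acc >= 0.9

    def test_single_class_rejected(self, tiny_trials):
        with pytest.raises(ValueError, match="single class"):
            KCSFCnet(kernel_length=8).fit(tiny_trials.data,
                                          np.zeros(tiny_trials.n_trials))

    def test_constraints_hold_after_training(self, fitted_small):
        assert fitted_small.sigma_ > 0
        conv_norms = np.linalg.norm(fitted_small.conv_filters_, axis=1)
        dense_norms = np.linalg.norm(fitted_small.readout_weights_, axis=0)
        assert np.all(conv_norms <= 2.0 + 1e-6)
        assert np.all(dense_norms <= 0.5 + 1e-6)

    def test_loss_trend_non_increasing_at_the_end(self, fitted_small):
        curve = np.array(fitted_small.loss_curve_)
        tail = len(curve) // 10
        assert curve[-tail:].mean() <= curve[-2 * tail:-tail].mean() + 1e-3

    def test_kernel_length_must_fit(self, tiny_trials):
        with pytest.raises(ValueError, match="kernel_length"):
            KCSFCnet(kernel_length=64).fit(tiny_trials.data, tiny_trials.labels)

    def test_a_learned_filter_tunes_to_planted_band(self):
        # batch norm makes the network scale-invariant to filter amplitude,
        # so untuned filters keep arbitrary spectral peaks; recovery of the
        # planted band shows up as (at least) one filter peaking inside it
        spec = SyntheticSpec(n_trials=40, n_channels=8, fs=128.0, duration=2.0,
                             couplings=(Coupling((0, 1), 8.0, 13.0, 1),),
                             snr=2.0, seed=5)
        ts = generate_subject(spec)
        m = KCSFCnet(n_filters=2, kernel_length=32, n_epochs=300, random_state=0)
        m.fit(ts.data, ts.labels)
        freqs = np.fft.rfftfreq(512, d=1 / 128.0)
        spect = np.abs(np.fft.rfft(m.conv_filters_, n=512, axis=1)) ** 2
        peaks = freqs[np.argmax(spect, axis=1)]
        assert any(8.0 <= p <= 13.0 for p in peaks), peaks


class TestConnectivityExtraction:
    def test_values_in_unit_interval(self, fitted_small, small_planted):
        conn = extract_connectivity(fitted_small, small_planted.data)
        assert conn.values.min() >= 0.0
        assert conn.values.max() <= 1.0
        assert conn.values.shape == (small_planted.n_trials, 28)

    def test_identical_channels_give_all_ones(self, fitted_small):
        one = np.random.default_rng(0).standard_normal((1, 1, 256))
        X = np.tile(one, (1, 8, 1))
        conn = fitted_small.connectivity(X)
        assert np.allclose(conn.values, 1.0)

    def test_inference_is_deterministic(self, fitted_small, small_planted):
        a = fitted_small.connectivity(small_planted.data).values
        b = fitted_small.connectivity(small_planted.data).values
        assert np.array_equal(a, b)

    def test_symmetric_matrix_reconstruction(self, fitted_small, small_planted):
        conn = fitted_small.connectivity(small_planted.data)
        mat = conn.to_matrix()
        assert np.allclose(mat, mat.transpose(0, 2, 1))
        assert np.allclose(np.diagonal(mat, axis1=1, axis2=2), 1.0)
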