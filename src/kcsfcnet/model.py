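"""KCS-FCnet: kernel cross-spectral functional connectivity network.

A shallow end-to-end classifier for two-class motor-imagery EEG.  Per trial
``X ∈ R^{Nc×Nt}`` the architecture is

    1-D temporal convolution (Nf bias-free filters w_f of length Δt)
    → batch normalisation → ELU
    → Gaussian-kernel pairwise connectivity per filter,
      κ_G(z_c, z_c') = exp(−‖z_c − z_c'‖² / 2σ²)
    → average over the Nf filter maps (the expectation over filters)
    → batch normalisation → ELU → flatten → dropout
    → dense softmax readout on the Nc(Nc−1)/2 upper-triangle pairs.

The learnable parameter set is Θ = {w_f, σ, batch-norm scale/shift, v, b};
σ is stored as log σ so positivity is unconditional.  Training minimises
mean categorical cross-entropy with full-batch Adam and re-projects the
max-norm constraints (conv filters ≤ 2.0, dense columns ≤ 0.5) after every
update.  The averaged pre-readout connectivity vector lies in [0,1] and is
the model's interpretable functional-connectivity feature map.

Everything, including back-propagation through the kernel and the batch
normalisations, is implemented directly on numpy arrays; a finite-difference
check in the test suite pins the analytic gradients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "gaussian_kernel",
    "pair_indices",
    "connectivity_block",
    "count_parameters",
    "ConnectivityTensor",
    "KCSFCnet",
    "extract_connectivity",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


# ---------------------------------------------------------------------------
# functional primitives
# ---------------------------------------------------------------------------

def gaussian_kernel(z: np.ndarray, z_prime: np.ndarray, sigma: float) -> float:
    """Gaussian (RBF) similarity exp(−‖z−z′‖² / 2σ²) between two vectors."""
    z = np.asarray(z, dtype=float)
    z_prime = np.asarray(z_prime, dtype=float)
    if z.shape != z_prime.shape:
        raise ValueError(f"length mismatch: {z.shape} vs {z_prime.shape}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    d2 = float(np.sum((z - z_prime) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma**2)))


def pair_indices(n_channels: int) -> tuple[np.ndarray, np.ndarray]:
    """Strict upper-triangle channel pairs (c, c′), c < c′, lexicographic."""
    i, j = np.triu_indices(n_channels, k=1)
    return i, j


def connectivity_block(filtered: np.ndarray, sigma: float) -> np.ndarray:
    """Pairwise Gaussian-kernel connectivity of filtered channel signals.

    ``filtered`` has shape (Nf, Nc, T); the result is (Nf, M) with
    M = Nc(Nc−1)/2, entry (f, p) = κ_G(filtered[f, c_p], filtered[f, c′_p]).
    """
    filtered = np.asarray(filtered, dtype=float)
    if filtered.ndim != 3:
        raise ValueError(f"expected (Nf, Nc, T), got shape {filtered.shape}")
    if not np.all(np.isfinite(filtered)):
        raise ValueError("non-finite values in filtered input")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    i, j = pair_indices(filtered.shape[1])
    diff = filtered[:, i, :] - filtered[:, j, :]
    d2 = np.einsum("fpt,fpt->fp", diff, diff)
    return np.exp(-d2 / (2.0 * sigma**2))


def count_parameters(n_channels: int, n_filters: int, kernel_length: int,
                     n_classes: int = 2, batch_norm: bool = True) -> int:
    """Trainable-parameter count of the architecture.

    Conv Nf·Δt (bias-free) + 2·Nf + 2 batch-norm scale/shift (if enabled)
    + dense M·Ny + Ny + the single kernel scale σ, M = Nc(Nc−1)/2.
    """
    m = n_channels * (n_channels - 1) // 2
    total = n_filters * kernel_length + m * n_classes + n_classes + 1
    if batch_norm:
        total += 2 * n_filters + 2
    return total


@dataclass
class ConnectivityTensor:
    """Trial-wise averaged connectivity, vectorised strict upper triangle.

    ``values`` is (R, M) in [0, 1]; ``pair_index`` lists the (c, c′) channel
    pairs, c < c′, in lexicographic order.
    """

    values: np.ndarray
    pair_index: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be (trials, pairs)")
        if not self.pair_index:
            # infer Nc from M = Nc(Nc-1)/2
            m = self.values.shape[1]
            nc = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
            if nc * (nc - 1) // 2 != m:
                raise ValueError(f"{m} pairs is not a triangular number")
            i, j = pair_indices(nc)
            self.pair_index = list(zip(i.tolist(), j.tolist()))
        if len(self.pair_index) != self.values.shape[1]:
            raise ValueError("pair_index length does not match values")

    @property
    def n_channels(self) -> int:
        return max(max(p) for p in self.pair_index) + 1

    def to_matrix(self) -> np.ndarray:
        """Symmetric (R, Nc, Nc) matrices with unit diagonal."""
        nc = self.n_channels
        out = np.zeros((self.values.shape[0], nc, nc))
        i = np.array([p[0] for p in self.pair_index])
        j = np.array([p[1] for p in self.pair_index])
        out[:, i, j] = self.values
        out[:, j, i] = self.values
        out[:, np.arange(nc), np.arange(nc)] = 1.0
        return out


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _elu(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0, z, np.expm1(z))


def _elu_grad(z: np.ndarray, a: np.ndarray) -> np.ndarray:
    # a = elu(z); derivative is 1 for z>0 and exp(z) = a+1 otherwise
    return np.where(z > 0, 1.0, a + 1.0)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sliding(X: np.ndarray, dt: int) -> np.ndarray:
    # (B, Nc, Nt) -> (B, Nc, T, dt) windows, T = Nt - dt + 1
    return np.lib.stride_tricks.sliding_window_view(X, dt, axis=-1)


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class KCSFCnet(ClassifierMixin, BaseEstimator):
    """Kernel cross-spectral functional connectivity classifier.

    Parameters
    ----------
    n_filters : int, default=4
        Number Nf of temporal convolution filters (the study grid is {2,3,4}).
    kernel_length : int, default=64
        Filter length Δt in samples; the default is half the 128 Hz target
        sampling rate, following the convention of tying kernel length to fs.
        Must be smaller than the trial length Nt.
    n_epochs : int, default=500
        Full-batch Adam epochs.
    learning_rate : float, default=1e-3
    dropout_rate : float, default=0.5
        Dropout on the flattened connectivity vector during training.
    conv_max_norm : float, default=2.0
        Per-filter Euclidean max-norm, re-projected after every update.
    dense_max_norm : float, default=0.5
        Per-output-column max-norm of the readout weights.
    sigma_init : {"median_heuristic", "fixed"}, default="median_heuristic"
        Kernel-scale initialisation: the median heuristic sets
        σ² = ½·median‖z_c − z_c′‖² over the initial filtered features of the
        training batch; "fixed" uses ``sigma_value``.
    sigma_value : float, default=1.0
    batch_norm : bool, default=True
        Enable the two batch-normalisation stages.  Disabling them yields the
        bare function composition (useful for analytic checks).
    dtype : {"float32", "float64"}, default="float32"
        Training precision.  float64 is used by the gradient tests.
    random_state : int or None
        Seeds filter initialisation, shuffling-free here, and dropout masks.

    Attributes
    ----------
    conv_filters_ : ndarray (n_filters, kernel_length)
        Learned temporal filters w_f.
    sigma_ : float
        Learned kernel scale σ.
    readout_weights_ : ndarray (M, 2); intercept_ : ndarray (2,)
        Dense softmax readout v, b over the M channel pairs.
    loss_curve_ : list of float
        Training cross-entropy per epoch.
    """

    def __init__(self, n_filters: int = 4, kernel_length: int = 64,
                 n_epochs: int = 500, learning_rate: float = 1e-3,
                 dropout_rate: float = 0.5, conv_max_norm: float = 2.0,
                 dense_max_norm: float = 0.5, sigma_init: str = "median_heuristic",
                 sigma_value: float = 1.0, batch_norm: bool = True,
                 dtype: str = "float32", random_state: int | None = None,
                 verbose: int = 0):
        self.n_filters = n_filters
        self.kernel_length = kernel_length
        self.n_epochs = n_epochs
        self.learning_rate = learning_rate
        self.dropout_rate = dropout_rate
        self.conv_max_norm = conv_max_norm
        self.dense_max_norm = dense_max_norm
        self.sigma_init = sigma_init
        self.sigma_value = sigma_value
        self.batch_norm = batch_norm
        self.dtype = dtype
        self.random_state = random_state
        self.verbose = verbose

    # -- validation --------------------------------------------------------

    def _validate_X(self, X: np.ndarray, fitted: bool = False) -> np.ndarray:
        X = np.asarray(X, dtype=self.dtype)
        if X.ndim != 3:
            raise ValueError(
                f"expected X of shape (trials, channels, samples), got {X.shape}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in X")
        if fitted:
            exp = (self._nc, self._nt)
            if X.shape[1:] != exp:
                raise ValueError(
                    f"shape mismatch: expected (*, {exp[0]}, {exp[1]}), got {X.shape}"
                )
        return X

    # -- forward / backward ------------------------------------------------

    def _forward(self, P: dict, X: np.ndarray, training: bool,
                 rng: np.random.Generator | None = None,
                 Xflat: np.ndarray | None = None) -> dict:
        """Full forward pass; returns a cache of every intermediate needed
        by :meth:`_backward`.  ``training`` selects batch statistics and
        dropout; inference uses the stored running statistics.  ``Xflat``
        lets the training loop reuse the windowed input across epochs.
        """
        dt = self.kernel_length
        use_bn = self.batch_norm
        B, nc = X.shape[0], X.shape[1]
        T = X.shape[2] - dt + 1
        if Xflat is None:
            Xflat = np.ascontiguousarray(_sliding(X, dt)).reshape(-1, dt)
        Z0 = np.ascontiguousarray(
            (Xflat @ P["W"].T).reshape(B, nc, T, -1).transpose(0, 3, 1, 2)
        )
        cache = {"Xflat": Xflat, "Z0": Z0, "shape": (B, nc, T)}

        if use_bn:
            if training:
                mu1 = Z0.mean(axis=(0, 2, 3))
                var1 = Z0.var(axis=(0, 2, 3))
                self._run_mu1 = (1 - _BN_MOMENTUM) * self._run_mu1 + _BN_MOMENTUM * mu1
                self._run_var1 = (1 - _BN_MOMENTUM) * self._run_var1 + _BN_MOMENTUM * var1
            else:
                mu1, var1 = self._run_mu1, self._run_var1
            std1 = np.sqrt(var1 + _BN_EPS)
            xhat1 = (Z0 - mu1[None, :, None, None]) / std1[None, :, None, None]
            Z1 = P["g1"][None, :, None, None] * xhat1 + P["b1"][None, :, None, None]
            cache.update(xhat1=xhat1, std1=std1)
        else:
            Z1 = Z0
        A1 = _elu(Z1)
        cache.update(Z1=Z1, A1=A1)

        # pair differences via the signed incidence matrix (BLAS batched matmul)
        diff = np.matmul(self._incidence.T, A1)   # (B, Nf, M, T)
        D2 = np.einsum("bfpt,bfpt->bfp", diff, diff)
        sigma = float(np.exp(P["rho"]))
        K = np.exp(-D2 / (2.0 * sigma**2))
        Pconn = K.mean(axis=1)                    # (B, M): avg over filters
        cache.update(diff=diff, D2=D2, K=K, sigma=sigma, Pconn=Pconn)

        if use_bn:
            if training:
                mu2 = Pconn.mean()
                var2 = Pconn.var()
                self._run_mu2 = (1 - _BN_MOMENTUM) * self._run_mu2 + _BN_MOMENTUM * mu2
                self._run_var2 = (1 - _BN_MOMENTUM) * self._run_var2 + _BN_MOMENTUM * var2
            else:
                mu2, var2 = self._run_mu2, self._run_var2
            std2 = np.sqrt(var2 + _BN_EPS)
            xhat2 = (Pconn - mu2) / std2
            Z2 = P["g2"] * xhat2 + P["b2"]
            cache.update(xhat2=xhat2, std2=std2)
        else:
            Z2 = Pconn
        A2 = _elu(Z2)
        cache.update(Z2=Z2, A2=A2)

        if training and self.dropout_rate > 0 and rng is not None:
            keep = 1.0 - self.dropout_rate
            mask = ((rng.random(A2.shape) < keep) / keep).astype(A2.dtype)
            A2d = A2 * mask
            cache["mask"] = mask
        else:
            A2d = A2
        logits = A2d @ P["V"] + P["c"]
        probs = _softmax(logits)
        cache.update(A2d=A2d, probs=probs)
        return cache

    def _backward(self, P: dict, cache: dict, Y: np.ndarray) -> dict:
        """Gradients of mean cross-entropy w.r.t. every parameter in ``P``.

        ``Y`` is the one-hot label matrix.  Batch-norm gradients use the
        standard whitening backward pass (batch statistics are functions of
        the input, so their dependence is included).
        """
        B = Y.shape[0]
        use_bn = self.batch_norm
        g = {}

        dlogits = (cache["probs"] - Y) / B
        g["V"] = cache["A2d"].T @ dlogits
        g["c"] = dlogits.sum(axis=0)
        dA2d = dlogits @ P["V"].T
        dA2 = dA2d * cache["mask"] if "mask" in cache else dA2d
        dZ2 = dA2 * _elu_grad(cache["Z2"], cache["A2"])

        if use_bn:
            xhat2, std2 = cache["xhat2"], cache["std2"]
            g["g2"] = np.array(np.sum(dZ2 * xhat2))
            g["b2"] = np.array(np.sum(dZ2))
            dxhat2 = dZ2 * P["g2"]
            n2 = dZ2.size
            dP = (dxhat2 - dxhat2.mean() - xhat2 * np.mean(dxhat2 * xhat2)) / std2
            del n2
        else:
            dP = dZ2

        nf = self.n_filters
        K, D2, sigma = cache["K"], cache["D2"], cache["sigma"]
        dK = dP[:, None, :] / nf
        # σ through ρ = log σ:  dκ/dρ = κ · D2 / σ²
        g["rho"] = np.array(np.sum(dK * K * D2) / sigma**2)
        dD2 = dK * K * (-1.0 / (2.0 * sigma**2))
        G = (2.0 * dD2)[..., None] * cache["diff"]          # (B, Nf, M, T)
        dA1 = np.matmul(self._incidence, G)                 # (B, Nf, Nc, T)

        dZ1 = dA1 * _elu_grad(cache["Z1"], cache["A1"])
        if use_bn:
            xhat1, std1 = cache["xhat1"], cache["std1"]
            g["g1"] = np.sum(dZ1 * xhat1, axis=(0, 2, 3))
            g["b1"] = np.sum(dZ1, axis=(0, 2, 3))
            dxhat1 = dZ1 * P["g1"][None, :, None, None]
            m1 = dxhat1.mean(axis=(0, 2, 3))
            mx1 = np.mean(dxhat1 * xhat1, axis=(0, 2, 3))
            dZ0 = (dxhat1 - m1[None, :, None, None]
                   - xhat1 * mx1[None, :, None, None]) / std1[None, :, None, None]
        else:
            dZ0 = dZ1

        # conv weights: correlate upstream gradient with input windows
        dZ0f = dZ0.transpose(1, 0, 2, 3).reshape(self.n_filters, -1)
        g["W"] = dZ0f @ cache["Xflat"]
        return g

    @staticmethod
    def _loss(probs: np.ndarray, Y: np.ndarray) -> float:
        p = np.clip(np.sum(probs * Y, axis=1), 1e-12, None)
        return float(-np.mean(np.log(p)))

    # -- initialisation ----------------------------------------------------

    def _init_params(self, X: np.ndarray, rng: np.random.Generator) -> dict:
        dt, nf, m, ny = self.kernel_length, self.n_filters, self._m, 2
        ftype = np.float64 if self.dtype == "float64" else np.float32
        P = {
            "W": (rng.standard_normal((nf, dt)) / np.sqrt(dt)).astype(ftype),
            "V": (rng.uniform(-1, 1, (m, ny)) * np.sqrt(6.0 / (m + ny))).astype(ftype),
            "c": np.zeros(ny, dtype=ftype),
            "rho": np.array(0.0, dtype=ftype),
        }
        if self.batch_norm:
            P["g1"] = np.ones(nf, dtype=ftype)
            P["b1"] = np.zeros(nf, dtype=ftype)
            P["g2"] = np.array(1.0, dtype=ftype)
            P["b2"] = np.array(0.0, dtype=ftype)
            self._run_mu1 = np.zeros(nf, dtype=ftype)
            self._run_var1 = np.ones(nf, dtype=ftype)
            self._run_mu2 = ftype(0.0)
            self._run_var2 = ftype(1.0)

        if self.sigma_init == "median_heuristic":
            sigma = self._median_heuristic(P, X)
        elif self.sigma_init == "fixed":
            sigma = float(self.sigma_value)
        else:
            raise ValueError(f"unknown sigma_init {self.sigma_init!r}")
        if sigma <= 0:
            raise ValueError("sigma must initialise positive")
        P["rho"] = np.array(np.log(sigma), dtype=ftype)
        return P

    def _median_heuristic(self, P: dict, X: np.ndarray) -> float:
        """σ² = ½ · median over trials, filters and pairs of ‖z_c − z_c′‖²,
        with z the initial filtered (batch-normalised, ELU) features."""
        cache = self._forward({**P, "rho": np.array(0.0)}, X, training=True)
        if self.batch_norm:  # undo the running-stat update of this probe pass
            nf = self.n_filters
            self._run_mu1 = np.zeros(nf, dtype=self._run_mu1.dtype)
            self._run_var1 = np.ones(nf, dtype=self._run_var1.dtype)
            self._run_mu2, self._run_var2 = type(self._run_mu2)(0.0), type(self._run_var2)(1.0)
        med = float(np.median(cache["D2"]))
        if med <= 0:
            warnings.warn("degenerate (all-equal) features: falling back to sigma=1")
            return 1.0
        return float(np.sqrt(med / 2.0))

    # -- constraints -------------------------------------------------------

    def _project(self, P: dict) -> None:
        wn = np.linalg.norm(P["W"], axis=1, keepdims=True)
        np.divide(P["W"], np.maximum(wn / self.conv_max_norm, 1.0), out=P["W"])
        vn = np.linalg.norm(P["V"], axis=0, keepdims=True)
        np.divide(P["V"], np.maximum(vn / self.dense_max_norm, 1.0), out=P["V"])

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        X = self._validate_X(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training set contains a single class")
        if len(self.classes_) > 2:
            raise ValueError("binary classification only")
        yi = np.searchsorted(self.classes_, y)

        B, nc, nt = X.shape
        if self.kernel_length >= nt:
            raise ValueError(
                f"kernel_length ({self.kernel_length}) must be < trial length ({nt})"
            )
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        self._nc, self._nt = nc, nt
        self._m = nc * (nc - 1) // 2
        self._pair_i, self._pair_j = pair_indices(nc)
        ftype = np.float64 if self.dtype == "float64" else np.float32
        S = np.zeros((nc, self._m), dtype=ftype)
        S[self._pair_i, np.arange(self._m)] = 1.0
        S[self._pair_j, np.arange(self._m)] = -1.0
        self._incidence = S

        rng = np.random.default_rng(self.random_state)
        P = self._init_params(X, rng)
        Y = np.eye(2, dtype=X.dtype)[yi]

        mstate = {k: np.zeros_like(v) for k, v in P.items()}
        vstate = {k: np.zeros_like(v) for k, v in P.items()}
        b1m, b2m, eps = 0.9, 0.999, 1e-8
        Xflat = np.ascontiguousarray(_sliding(X, self.kernel_length)).reshape(
            -1, self.kernel_length
        )
        self.loss_curve_ = []
        for epoch in range(self.n_epochs):
            cache = self._forward(P, X, training=True, rng=rng, Xflat=Xflat)
            loss = self._loss(cache["probs"], Y)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss} "
                    f"(sigma={cache['sigma']:.3g}, lr={self.learning_rate})"
                )
            self.loss_curve_.append(loss)
            grads = self._backward(P, cache, Y)
            t = epoch + 1
            for k in P:
                gk = grads[k].astype(P[k].dtype, copy=False)
                mstate[k] = b1m * mstate[k] + (1 - b1m) * gk
                vstate[k] = b2m * vstate[k] + (1 - b2m) * gk**2
                mhat = mstate[k] / (1 - b1m**t)
                vhat = vstate[k] / (1 - b2m**t)
                P[k] = np.asarray(P[k] - self.learning_rate * mhat / (np.sqrt(vhat) + eps))
            self._project(P)
            if self.verbose and (epoch % 50 == 0 or epoch == self.n_epochs - 1):
                print(f"epoch {epoch:4d}  loss {loss:.4f}")

        self._params = P
        self.conv_filters_ = np.asarray(P["W"], dtype=float)
        self.sigma_ = float(np.exp(P["rho"]))
        self.readout_weights_ = np.asarray(P["V"], dtype=float)
        self.intercept_ = np.asarray(P["c"], dtype=float)
        self.n_features_in_ = nc
        self.n_parameters_ = count_parameters(
            nc, self.n_filters, self.kernel_length, 2, self.batch_norm
        )
        assert self.n_parameters_ == sum(v.size for v in P.values())
        return self

    def forward(self, X):
        """Probabilities and averaged connectivity for a batch of trials
        (inference mode: running batch-norm statistics, dropout disabled)."""
        check_is_fitted(self, "conv_filters_")
        X = self._validate_X(X, fitted=True)
        cache = self._forward(self._params, X, training=False)
        return cache["probs"], cache["Pconn"]

    def predict_proba(self, X) -> np.ndarray:
        probs, _ = self.forward(X)
        return np.asarray(probs, dtype=float)

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        # argmax with lowest index on exact ties
        return self.classes_[np.argmax(probs, axis=1)]

    def connectivity(self, X) -> ConnectivityTensor:
        """Trial-wise averaged Gaussian-kernel connectivity (inference mode)."""
        _, conn = self.forward(X)
        return ConnectivityTensor(
            values=np.asarray(conn, dtype=float),
            pair_index=list(zip(self._pair_i.tolist(), self._pair_j.tolist())),
        )

    def aggregate_frequency_response(self, fs: float, n_fft: int = 512):
        """Σ_f |FFT(w_f)|² of the learned temporal filters, with the freq axis.

        The peak location indicates which band the filters have tuned to.
        """
        check_is_fitted(self, "conv_filters_")
        spec = np.abs(np.fft.rfft(self.conv_filters_, n=n_fft, axis=1)) ** 2
        freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
        return freqs, spec.sum(axis=0)


def extract_connectivity(model: KCSFCnet, X: np.ndarray) -> ConnectivityTensor:
    """Functional alias for :meth:`KCSFCnet.connectivity`."""
    return model.connectivity(X)
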