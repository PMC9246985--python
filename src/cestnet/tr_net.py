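"""The transformation network: anti-phase -> in-phase CEST profiles.

Maps the packed time-domain representation of an anti-phase CEST profile
(two 130-vectors: zero-filled real-FT coefficients and the matching time
axis) to the decoupled, upsampled 128-point in-phase profile.  The
architecture is a stack of dilated gated convolution blocks (the spectral
decoupling building block) followed by a bidirectional recurrent module and
a dense head.  Two heads are available:

- ``head="time"`` (default): the head emits 65 complex time-domain points
  (130 reals) that a frozen inverse real-FT maps to the 128-point profile;
- ``head="freq"``: the head emits the 128 frequency-domain points directly.

Training minimizes the mean-squared error between the transformed profile
and the clean in-phase target, with ADAM and a loss-coupled learning-rate
decay lr = base_lr * loss^(3/4), clipped to [lr_min, base_lr].
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .processing import N_UPSAMPLED, PACKED_SIZE, pack_input, pack_profile, upsampled_grid
from .profiles import CESTProfile
from .scenarios import ValidationError

__all__ = ["TransformationNetwork", "build_dnn_tr", "train_dnn_tr", "transform"]

_TIME_SCALE = 100.0  # time-axis channel rescale (s -> units of 10 ms)


def _irfft_matrix() -> np.ndarray:
    """Frozen linear map from 130 packed reals to the 128-point profile."""
    M = np.empty((2 * PACKED_SIZE, N_UPSAMPLED))
    for j in range(2 * PACKED_SIZE):
        v = np.zeros(2 * PACKED_SIZE)
        v[j] = 1.0
        c = v[:PACKED_SIZE] + 1j * v[PACKED_SIZE:]
        M[j] = np.fft.irfft(c, n=N_UPSAMPLED, norm="forward")
    return M


class TransformationNetwork(BaseEstimator):
    """Anti-phase to in-phase CEST transformation, sklearn-style.

    Parameters
    ----------
    channels, kernel, dilations, rnn_units : architecture knobs; the default
        configuration is deliberately small (CPU-trainable in minutes).
    head : "time" or "freq" output domain.
    base_lr, lr_min : learning-rate schedule bounds.
    batch_size, epochs, seed : training controls; one seed fixes weight
        initialization and data order.
    """

    def __init__(
        self,
        channels: int = 24,
        kernel: int = 7,
        dilations: tuple = (1, 2, 4),
        rnn_units: int = 24,
        head: str = "time",
        base_lr: float = 4e-4,
        lr_min: float = 1e-6,
        batch_size: int = 256,
        epochs: int = 10,
        clip_norm: float = 10.0,
        seed: int = 0,
    ):
        self.channels = channels
        self.kernel = kernel
        self.dilations = dilations
        self.rnn_units = rnn_units
        self.head = head
        self.base_lr = base_lr
        self.lr_min = lr_min
        self.batch_size = batch_size
        self.epochs = epochs
        self.clip_norm = clip_norm
        self.seed = seed

    # -- model construction -------------------------------------------------
    def _build(self) -> nn.Sequential:
        if self.head not in ("time", "freq"):
            raise ValidationError(f"unknown head {self.head!r}")
        rng = np.random.default_rng(self.seed)
        layers = [nn.Conv1D(3, self.channels, 5, 1, "tanh", rng)]
        for d in self.dilations:
            layers.append(nn.GatedConvBlock(self.channels, self.kernel, d, rng))
        layers.append(nn.BiRNN(self.channels, self.rnn_units, rng))
        layers.append(nn.Flatten())
        n_flat = PACKED_SIZE * 2 * self.rnn_units
        if self.head == "time":
            head = nn.Dense(n_flat, 2 * PACKED_SIZE, None, rng)
            layers += [head, nn.FixedLinear(_irfft_matrix())]
        else:
            head = nn.Dense(n_flat, N_UPSAMPLED, None, rng)
            layers.append(head)
        # small-output head initialization: the head predicts coefficients
        # of order 0.1, far below the glorot output scale
        head.W *= 0.05
        return nn.Sequential(layers)

    @staticmethod
    def _prepare(X: np.ndarray) -> np.ndarray:
        """(n, 260) packed input -> (n, 65, 3) channels (re, im, scaled t)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 4 * PACKED_SIZE:
            raise ValidationError(f"expected (n, 260) packed input, got {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValidationError("non-finite values in network input")
        re = X[:, :PACKED_SIZE]
        im = X[:, PACKED_SIZE : 2 * PACKED_SIZE]
        t = X[:, 2 * PACKED_SIZE : 3 * PACKED_SIZE] * _TIME_SCALE
        return np.stack([re, im, t], axis=-1)

    # -- training -----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "TransformationNetwork":
        """Train on packed inputs X (n, 260) and clean IP targets y (n, 128)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.model_ = self._build()
        self.n_params_ = self.model_.n_params
        rng = np.random.default_rng(self.seed + 1)
        opt = nn.Adam(self.model_.params)
        history = {"mse": [], "mae": [], "lr": []}
        loss_ema = None
        checkpoint = self.model_.get_weights()
        n = X.shape[0]
        for _ in range(self.epochs):
            order = rng.permutation(n)
            ep_se, ep_ae, ep_n, lr = 0.0, 0.0, 0, self.base_lr
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb = self._prepare(X[idx])
                yb = y[idx]
                out = self.model_.forward(xb)
                err = out - yb
                mse = float(np.mean(err**2))
                if not np.isfinite(mse):
                    self.model_.set_weights(checkpoint)
                    raise FloatingPointError("NaN loss; restored last checkpoint")
                loss_ema = mse if loss_ema is None else 0.9 * loss_ema + 0.1 * mse
                lr = float(np.clip(self.base_lr * loss_ema**0.75, self.lr_min, self.base_lr))
                self.model_.backward(2.0 * err / err.size)
                opt.step(self.model_.grads, lr, clip_norm=self.clip_norm)
                ep_se += mse * idx.size
                ep_ae += float(np.mean(np.abs(err))) * idx.size
                ep_n += idx.size
            history["mse"].append(ep_se / ep_n)
            history["mae"].append(ep_ae / ep_n)
            history["lr"].append(lr)
            checkpoint = self.model_.get_weights()
        self.history_ = history
        return self

    # -- inference ----------------------------------------------------------
    def transform(self, X: np.ndarray) -> np.ndarray:
        """128-point in-phase profiles for packed inputs X (n, 260)."""
        if not hasattr(self, "model_"):
            raise ValidationError("network is not fitted")
        X = np.asarray(X, dtype=float)
        # chunked inference: the layers cache activations for backprop
        out = [
            self.model_.forward(self._prepare(X[i : i + 512]))
            for i in range(0, X.shape[0], 512)
        ]
        return np.concatenate(out, axis=0)

    def transform_profile(self, profile: CESTProfile, larmor_mhz: float | None = None) -> CESTProfile:
        """Full chain: dip -> rFFT -> zero-fill -> network -> IP profile."""
        import warnings

        if larmor_mhz is None:
            from .scenarios import larmor_MHz

            if "b0" not in profile.meta:
                raise ValidationError("profile lacks b0 metadata; pass larmor_mhz")
            larmor_mhz = larmor_MHz(profile.meta["b0"])
        if not 50 <= profile.n_offsets <= 128:
            warnings.warn(
                f"{profile.n_offsets} offsets is outside the 50-128 training range"
            )
        ptd = pack_profile(profile, larmor_mhz)
        vec, tvec = pack_input(ptd)
        ip = self.transform(np.concatenate([vec, tvec])[None, :])[0]
        offsets = upsampled_grid(profile.offset_min, profile.span, profile.n_offsets)
        return CESTProfile(
            offsets, ip, phase="ip", provenance=profile.provenance,
            noise=profile.noise, meta=dict(profile.meta),
        )


# -- thin functional wrappers ----------------------------------------------
def build_dnn_tr(**cfg) -> TransformationNetwork:
    return TransformationNetwork(**cfg)


def train_dnn_tr(model: TransformationNetwork, X, y) -> TransformationNetwork:
    return model.fit(X, y)


def transform(model: TransformationNetwork, ap_profile: CESTProfile, **kw) -> CESTProfile:
    return model.transform_profile(ap_profile, **kw)
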