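"""The chemical-shift network: shifts and calibrated uncertainties.

Maps a 128-point in-phase CEST profile to a 3 x 2 output of normalized
chemical shifts f_pred in (0, 1) and confidences c_pred in (0, 1) through a
densely connected 1-D convolutional network with a sigmoidal last layer.
A predicted uncertainty follows from the confidence as

    sigma_pred = k * (1 / c_pred - 1),

spanning (0, inf) as c_pred goes from 1 to 0.  Training uses a two-part loss
that mirrors a least-squares cost:

    L_freq  = sum_i (f_pred_i - f_true_i)^2 / sigma_pred_i^2      (chi^2-like)
    L_uncer = 1e-4 * sum_i 1_i * sqrt(sigma_pred_i)

with the indicator 1 = {1,1,1} for three-state input and {1,1,0} for
two-state input, so absent states may keep large uncertainties.  The constant
k is 1 during training and is afterwards rescaled to
k = (max offsets - min offsets) * sqrt(L_freq_final), which gives L_freq an
expectation value of 1 and makes sigma_pred report the expected shift error
in ppm.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .processing import N_UPSAMPLED
from .scenarios import ValidationError

__all__ = [
    "ChemicalShiftNetwork",
    "ShiftPrediction",
    "loss_freq",
    "loss_uncer",
    "calibrate_k",
    "map_shift",
    "sigma_from_confidence",
    "confidence_from_sigma",
    "build_dnn_cs",
    "train_dnn_cs",
]

C_EPS = 1e-6  # confidence clamp, keeps sigma finite and positive
UNCER_WEIGHT = 1e-4


def sigma_from_confidence(c, k: float = 1.0):
    """sigma = k (1/c - 1); bijective (0, 1) -> (0, inf)."""
    c = np.clip(np.asarray(c, dtype=float), C_EPS, 1.0 - C_EPS)
    return k * (1.0 / c - 1.0)


def confidence_from_sigma(sigma, k: float = 1.0):
    """Inverse mapping c = 1 / (1 + sigma/k)."""
    return 1.0 / (1.0 + np.asarray(sigma, dtype=float) / k)


def loss_freq(f_pred, f_true, sigma_pred) -> float:
    """Chi-square-like shift loss, summed over the three state slots."""
    f_pred, f_true = np.asarray(f_pred, float), np.asarray(f_true, float)
    sigma = np.asarray(sigma_pred, dtype=float)
    if np.any(sigma <= 0):
        raise ValidationError("sigma_pred must be positive")
    return float(np.sum((f_pred - f_true) ** 2 / sigma**2, axis=-1).mean())

def loss_uncer(sigma_pred, indicator) -> float:
    """Confidence-forcing loss: 1e-4 * sum_i 1_i sqrt(sigma_i)."""
    sigma = np.asarray(sigma_pred, dtype=float)
    ind = np.asarray(indicator, dtype=float)
    return float(np.sum(ind * UNCER_WEIGHT * np.sqrt(sigma), axis=-1).mean())


def calibrate_k(offset_span: float, l_freq_final: float) -> float:
    """k = (max offsets - min offsets) * sqrt(L_freq), in ppm."""
    if offset_span <= 0 or l_freq_final <= 0:
        raise ValidationError("span and L_freq must be positive")
    return offset_span * np.sqrt(l_freq_final)


def map_shift(f_pred, offset_min: float, span: float):
    """Linear map from normalized shift to ppm: delta = span * f + offset_min."""
    f = np.asarray(f_pred, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValidationError("normalized shifts must lie in [0, 1]")
    return span * f + offset_min


class ShiftPrediction:
    """Up to three chemical shifts with confidences and ppm uncertainties."""

    def __init__(self, f_pred, c_pred, offset_min, span, k_unitless):
        self.f_pred = np.asarray(f_pred, dtype=float)
        self.c_pred = np.asarray(c_pred, dtype=float)
        self.delta = map_shift(self.f_pred, offset_min, span)
        self.k = span * k_unitless  # ppm
        self.sigma = sigma_from_confidence(self.c_pred, self.k)
        self.offset_min, self.span = offset_min, span

    def passes(self, threshold: float = 0.4) -> np.ndarray:
        return self.c_pred >= threshold


class ShiftReadout(nn.Layer):
    """Soft-argmax readout of per-slot position heatmaps plus pooled features.

    Input (B, L, 3 + K): the first three channels are position-logit maps,
    one per state slot; the rest are confidence features.  Output
    (B, 12 + 2K): the logit of each slot's soft-argmax position (so a
    downstream sigmoid can reproduce the position exactly), the peakiness
    (participation ratio sum s^2) and maximum of each heatmap (both collapse
    when a map is multimodal, i.e. the input is ambiguous), the pairwise
    distances between slot positions (overlapping states drive low
    confidence), and the confidence channels pooled by mean and by max
    (max pooling preserves localized evidence such as a deep secondary dip).
    """

    def __init__(self):
        super().__init__()

    def forward(self, x):
        B, L, C = x.shape
        self._x_shape = x.shape
        h = x[..., :3]
        h = h - h.max(axis=1, keepdims=True)
        e = np.exp(h)
        self._s = e / e.sum(axis=1, keepdims=True)  # (B, L, 3)
        self._pos = (np.arange(L) + 0.5) / L
        self._p = np.einsum("l,bls->bs", self._pos, self._s)
        self._p = np.clip(self._p, 1e-6, 1 - 1e-6)
        logit_p = np.log(self._p / (1.0 - self._p))
        peak = np.sum(self._s**2, axis=1)
        self._amax = np.argmax(self._s, axis=1)  # (B, 3)
        smax = np.take_along_axis(self._s, self._amax[:, None, :], axis=1)[:, 0, :]
        p = self._p
        self._dsign = np.stack(
            [np.sign(p[:, 0] - p[:, 1]), np.sign(p[:, 0] - p[:, 2]), np.sign(p[:, 1] - p[:, 2])],
            axis=1,
        )
        dists = np.stack(
            [np.abs(p[:, 0] - p[:, 1]), np.abs(p[:, 0] - p[:, 2]), np.abs(p[:, 1] - p[:, 2])],
            axis=1,
        )
        g = x[..., 3:].mean(axis=1)
        self._gmax_idx = np.argmax(x[..., 3:], axis=1)  # (B, K)
        gmax = np.take_along_axis(x[..., 3:], self._gmax_idx[:, None, :], axis=1)[:, 0, :]
        return np.concatenate([logit_p, peak, smax, dists, g, gmax], axis=-1)

    def backward(self, grad):
        B, L, C = self._x_shape
        K = C - 3
        g_logit, g_peak, g_smax = grad[:, :3], grad[:, 3:6], grad[:, 6:9]
        g_dist, g_feat, g_gmax = grad[:, 9:12], grad[:, 12 : 12 + K], grad[:, 12 + K :]
        gp = g_logit / (self._p * (1.0 - self._p))  # through the logit map
        # pairwise-distance contributions to dL/dp
        s = self._dsign
        gp = gp + np.stack(
            [
                g_dist[:, 0] * s[:, 0] + g_dist[:, 1] * s[:, 1],
                -g_dist[:, 0] * s[:, 0] + g_dist[:, 2] * s[:, 2],
                -g_dist[:, 1] * s[:, 1] - g_dist[:, 2] * s[:, 2],
            ],
            axis=1,
        )
        # dL/ds from the position expectation, the peakiness and the map maximum
        gs = gp[:, None, :] * self._pos[None, :, None] + g_peak[:, None, :] * 2.0 * self._s
        np.put_along_axis(
            gs,
            self._amax[:, None, :],
            np.take_along_axis(gs, self._amax[:, None, :], axis=1) + g_smax[:, None, :],
            axis=1,
        )
        inner = np.sum(gs * self._s, axis=1, keepdims=True)
        gh = self._s * (gs - inner)
        gx = np.zeros(self._x_shape)
        gx[..., :3] = gh
        gx[..., 3:] = g_feat[:, None, :] / L
        np.put_along_axis(
            gx[..., 3:],
            self._gmax_idx[:, None, :],
            np.take_along_axis(gx[..., 3:], self._gmax_idx[:, None, :], axis=1)
            + g_gmax[:, None, :],
            axis=1,
        )
        return gx


class ChemicalShiftNetwork(BaseEstimator):
    """DenseNet-style shift/confidence regressor, sklearn-style.

    ``fit(X, y)`` takes 128-point in-phase profiles X (n, 128) and targets
    y (n, 6) = [f_true (3) | indicator (3)].  After training ``k_unitless_``
    holds sqrt(mean L_freq) of the final epoch; multiplied by the offset span
    it is the paper-convention calibration constant in ppm.
    """

    def __init__(
        self,
        channels0: int = 16,
        growth: int = 12,
        block_depth: int = 3,
        n_blocks: int = 2,
        kernel: int = 5,
        lr: float = 3.3e-4,
        batch_size: int = 128,
        epochs: int = 15,
        clip_norm: float = 50.0,
        conf_bias: float = 2.0,
        warmup_epochs: int = 0,
        heatmap_weight: float = 1.0,
        seed: int = 0,
    ):
        self.channels0 = channels0
        self.growth = growth
        self.block_depth = block_depth
        self.n_blocks = n_blocks
        self.kernel = kernel
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.clip_norm = clip_norm
        self.conf_bias = conf_bias
        self.warmup_epochs = warmup_epochs
        self.heatmap_weight = heatmap_weight
        self.seed = seed

    def _build(self) -> nn.Sequential:
        rng = np.random.default_rng(self.seed)
        layers = [nn.Conv1D(1, self.channels0, 9, 1, "relu", rng)]
        ch = self.channels0
        for b in range(self.n_blocks):
            for _ in range(self.block_depth):
                layers.append(nn.DenseConv(ch, self.growth, self.kernel, rng))
                ch += self.growth
            if b < self.n_blocks - 1:
                # transition: 1x1 compression + pooling
                layers.append(nn.Conv1D(ch, self.channels0, 1, 1, "relu", rng))
                ch = self.channels0
                layers.append(nn.AvgPool1D(2))
        # heads: 3 position-logit maps + pooled confidence features, read out
        # by a soft-argmax; the sigmoidal last layer sees the position logits
        # so it can pass positions through unchanged
        n_feat = 8
        layers.append(nn.Conv1D(ch, 3 + n_feat, 1, 1, None, rng))
        layers.append(ShiftReadout())
        out = nn.Dense(12 + 2 * n_feat, 6, None, rng)
        out.W *= 0.1
        for i in range(3):  # identity mapping position logit -> f at init
            out.W[i, :] = 0.0
            out.W[i, 2 * i] = 1.0
        # start confident: with c near 0, L_freq provides no gradient on the
        # shifts (a low-confidence local minimum); biasing the confidence
        # logits positive lets the shift error drive learning from the start
        out.b[1::2] = self.conf_bias
        layers += [out, nn.Activation("sigmoid"), nn.Reshape((3, 2))]
        return nn.Sequential(layers)

    @staticmethod
    def _loss_and_grad(
        out: np.ndarray,
        f_true: np.ndarray,
        ind: np.ndarray,
        sigma_fixed: float | None = None,
    ):
        """Batch loss (L_freq, L_uncer) and gradient wrt the (B, 3, 2) output.

        With ``sigma_fixed`` the uncertainty is held constant and receives no
        gradient (the warm-up mode); otherwise the full two-part loss applies.
        """
        B = out.shape[0]
        f = out[..., 0]
        c = np.clip(out[..., 1], C_EPS, 1.0 - C_EPS)
        sigma = np.full_like(c, sigma_fixed) if sigma_fixed is not None else 1.0 / c - 1.0
        err = f - f_true
        lf = np.sum(err**2 / sigma**2, axis=1)
        lu = np.sum(ind * UNCER_WEIGHT * np.sqrt(sigma), axis=1)
        g = np.zeros_like(out)
        g[..., 0] = 2.0 * err / sigma**2 / B
        if sigma_fixed is None:
            dl_dsigma = -2.0 * err**2 / sigma**3 + ind * UNCER_WEIGHT / (2.0 * np.sqrt(sigma))
            g[..., 1] = dl_dsigma * (-1.0 / c**2) / B
        return float(lf.mean()), float(lu.mean()), g

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ChemicalShiftNetwork":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != N_UPSAMPLED:
            raise ValidationError(f"expected (n, 128) profiles, got {X.shape}")
        f_true, ind = y[:, :3], y[:, 3:]
        self.model_ = self._build()
        self.n_params_ = self.model_.n_params
        # split at the readout so the warm-up can supervise the heatmaps
        split = next(
            i for i, l in enumerate(self.model_.layers) if isinstance(l, ShiftReadout)
        )
        body = nn.Sequential(self.model_.layers[:split])
        head = nn.Sequential(self.model_.layers[split:])
        rng = np.random.default_rng(self.seed + 1)
        opt = nn.Adam(self.model_.params)
        history = {"l_freq": [], "l_uncer": []}
        checkpoint = self.model_.get_weights()
        n = X.shape[0]
        # sigma held at its initialization value during warm-up epochs
        sigma0 = float(sigma_from_confidence(1.0 / (1.0 + np.exp(-self.conf_bias))))
        for epoch in range(self.epochs):
            warm = epoch < self.warmup_epochs
            order = rng.permutation(n)
            ep_lf, ep_lu, ep_n = 0.0, 0.0, 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                z = body.forward(X[idx, :, None])
                out = head.forward(z)
                lf, lu, g = self._loss_and_grad(
                    out, f_true[idx], ind[idx], sigma_fixed=sigma0 if warm else None
                )
                if not np.isfinite(lf + lu):
                    self.model_.set_weights(checkpoint)
                    raise FloatingPointError("NaN loss; restored last checkpoint")
                gz = head.backward(g)
                if warm:
                    # auxiliary heatmap supervision: cross-entropy against the
                    # true position bin keeps the position maps unimodal, so
                    # the soft-argmax cannot average over ambiguous modes
                    L = z.shape[1]
                    s = head.layers[0]._s  # softmax maps cached by the readout
                    bins = np.clip((f_true[idx] * L).astype(int), 0, L - 1)
                    g_ce = s.copy()
                    batch_rows = np.arange(idx.size)
                    for slot in range(3):
                        g_ce[batch_rows, bins[:, slot], slot] -= 1.0
                    gz[..., :3] += self.heatmap_weight * g_ce / idx.size
                body.backward(gz)
                opt.step(self.model_.grads, self.lr, clip_norm=self.clip_norm)
                ep_lf += lf * idx.size
                ep_lu += lu * idx.size
                ep_n += idx.size
            history["l_freq"].append(ep_lf / ep_n)
            history["l_uncer"].append(ep_lu / ep_n)
            checkpoint = self.model_.get_weights()
        self.history_ = history
        # k rescale: during training k = 1; afterwards sqrt of the final
        # mean L_freq, so that L_freq has expectation 1 in sigma units
        self.k_unitless_ = float(np.sqrt(history["l_freq"][-1])) if history["l_freq"] else 1.0
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """(n, 3, 2) tensor of [f_pred, c_pred] per state slot."""
        if not hasattr(self, "model_"):
            raise ValidationError("network is not fitted")
        X = np.asarray(X, dtype=float)
        out = [
            self.model_.forward(X[i : i + 512, :, None])
            for i in range(0, X.shape[0], 512)
        ]
        return np.concatenate(out, axis=0)

    def predict_shifts(self, X: np.ndarray, offset_min: float, span: float) -> list[ShiftPrediction]:
        out = self.predict(X)
        return [
            ShiftPrediction(out[i, :, 0], out[i, :, 1], offset_min, span, self.k_unitless_)
            for i in range(out.shape[0])
        ]


def build_dnn_cs(**cfg) -> ChemicalShiftNetwork:
    return ChemicalShiftNetwork(**cfg)


def train_dnn_cs(model: ChemicalShiftNetwork, X, y) -> ChemicalShiftNetwork:
    return model.fit(X, y)
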