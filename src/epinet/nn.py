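"""Minimal dense regression network with hand-rolled reverse-mode gradients.

Architecture: four fully connected layers of shape d x fd, fd x fd, fd x d,
d x 1, with batch normalization and leaky-ReLU activations after the first
three layers, Xavier-uniform initialization and an Adam optimizer.  The
network exposes ``forward``/``backward`` so that arbitrary scalar losses of
the predictions (including spectral penalties evaluated on a separately
enumerated batch) can drive the parameter updates.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

__all__ = ["DenseNet", "Adam", "build_dnn"]

_LEAK = 0.01
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


def _xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class DenseNet:
    """Four-layer MLP; deterministic given its seed."""

    def __init__(self, d: int, expansion: int = 10, seed: int = 0):
        if d < 1 or expansion < 1:
            raise ValueError("d and expansion must be >= 1")
        self.d = d
        self.expansion = expansion
        self.seed = seed
        rng = np.random.default_rng(seed)
        fd = d * expansion
        dims = [(d, fd), (fd, fd), (fd, d), (d, 1)]
        self.params: dict[str, np.ndarray] = {}
        for i, (a, b) in enumerate(dims):
            self.params[f"W{i}"] = _xavier_uniform(rng, a, b)
            self.params[f"b{i}"] = np.zeros(b)
        for i, (_, b) in enumerate(dims[:3]):
            self.params[f"g{i}"] = np.ones(b)      # batchnorm gamma
            self.params[f"be{i}"] = np.zeros(b)    # batchnorm beta
        self.running_mean = [np.zeros(b) for _, b in dims[:3]]
        self.running_var = [np.ones(b) for _, b in dims[:3]]
        self._cache = None

    # -- persistence --------------------------------------------------------

    def state_dict(self) -> dict:
        return {
            "params": {k: v.copy() for k, v in self.params.items()},
            "running_mean": [m.copy() for m in self.running_mean],
            "running_var": [v.copy() for v in self.running_var],
        }

    def load_state_dict(self, state: dict) -> None:
        self.params = {k: v.copy() for k, v in state["params"].items()}
        self.running_mean = [m.copy() for m in state["running_mean"]]
        self.running_var = [v.copy() for v in state["running_var"]]

    def clone(self) -> "DenseNet":
        other = DenseNet(self.d, self.expansion, self.seed)
        other.load_state_dict(self.state_dict())
        return other

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        cache = {"x": x, "training": training, "layers": []}
        h = x
        for i in range(3):
            z = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            if training and z.shape[0] > 1:
                mu = z.mean(axis=0)
                var = z.var(axis=0)
                self.running_mean[i] = ((1 - _BN_MOMENTUM) * self.running_mean[i]
                                        + _BN_MOMENTUM * mu)
                self.running_var[i] = ((1 - _BN_MOMENTUM) * self.running_var[i]
                                       + _BN_MOMENTUM * var)
            else:
                mu = self.running_mean[i]
                var = self.running_var[i]
            ivstd = 1.0 / np.sqrt(var + _BN_EPS)
            zhat = (z - mu) * ivstd
            a = self.params[f"g{i}"] * zhat + self.params[f"be{i}"]
            out = np.where(a > 0, a, _LEAK * a)
            cache["layers"].append(
                {"h_in": h, "z": z, "mu": mu, "ivstd": ivstd, "zhat": zhat,
                 "a": a, "batch_stats": training and z.shape[0] > 1})
            h = out
        y = h @ self.params["W3"] + self.params["b3"]
        cache["h_last"] = h
        self._cache = cache
        return y[:, 0]

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode predictions (running batchnorm statistics)."""
        return self.forward(x, training=False)

    def backward(self, dout: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of sum(dout * output) w.r.t. all parameters."""
        cache = self._cache
        if cache is None:
            raise RuntimeError("backward called before forward")
        grads = {}
        dy = np.asarray(dout, dtype=float)[:, None]
        grads["W3"] = cache["h_last"].T @ dy
        grads["b3"] = dy.sum(axis=0)
        dh = dy @ self.params["W3"].T
        for i in reversed(range(3)):
            layer = cache["layers"][i]
            a = layer["a"]
            da = dh * np.where(a > 0, 1.0, _LEAK)
            grads[f"g{i}"] = (da * layer["zhat"]).sum(axis=0)
            grads[f"be{i}"] = da.sum(axis=0)
            dzhat = da * self.params[f"g{i}"]
            if layer["batch_stats"]:
                n = dzhat.shape[0]
                zc = layer["z"] - layer["mu"]
                ivstd = layer["ivstd"]
                dvar = np.sum(dzhat * zc, axis=0) * (-0.5) * ivstd ** 3
                dmu = (-np.sum(dzhat, axis=0) * ivstd
                       + dvar * (-2.0) * zc.mean(axis=0))
                dz = dzhat * ivstd + dvar * 2.0 * zc / n + dmu / n
            else:
                dz = dzhat * layer["ivstd"]
            grads[f"W{i}"] = layer["h_in"].T @ dz
            grads[f"b{i}"] = dz.sum(axis=0)
            dh = dz @ self.params[f"W{i}"].T
        return grads


def build_dnn(d: int, expansion: int = 10, seed: int = 0) -> DenseNet:
    """Model factory; identical seeds yield identical initial parameters."""
    return DenseNet(d=d, expansion=expansion, seed=seed)


@dataclass
class Adam:
    """Adaptive-moment optimizer over a DenseNet's parameter dict."""

    lr: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self):
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}
        self._t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self._t += 1
        t = self._t
        for key, g in grads.items():
            if key not in self._m:
                self._m[key] = np.zeros_like(params[key])
                self._v[key] = np.zeros_like(params[key])
            g = g.reshape(params[key].shape)
            self._m[key] = self.beta1 * self._m[key] + (1 - self.beta1) * g
            self._v[key] = self.beta2 * self._v[key] + (1 - self.beta2) * g * g
            mhat = self._m[key] / (1 - self.beta1 ** t)
            vhat = self._v[key] / (1 - self.beta2 ** t)
            params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
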