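"""Scalable spectral regularization via ADMM decoupling.

The exact spectral penalty is split with an auxiliary sparse spectrum ``u``
and a scaled dual vector ``gamma`` living on a fixed set of subsampled
query points ``X_T`` chosen to induce a sparse-graph code:

* theta-step: SGD on ``sum (y_i - g(x_i))**2 + (rho/2)||g(X_T) - H_T u + gamma||**2``
* u-step: peeling-based sparse WH recovery of ``g(X_T) + gamma``, followed
  by the hard-threshold prox of the l0 penalty (keep ``u_S**2 >= 2*alpha/rho``)
* dual update: ``gamma += g(X_T) - H_T u``

``H_T u`` is computed on the fly from the sparse support; no object of size
2**d is ever allocated, so any ``d`` is admissible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, DenseNet
from .sparse import (QuerySet, SamplingPlan, compute_observations, design_plan,
                     peel, points_to_pm1, sample_points)
from .spectral import MULTILINEAR, UNITARY, WHSpectrum, mask_order

__all__ = ["ENSConfig", "ADMMState", "ht_times_u", "theta_step", "u_step",
           "dual_step", "train_ens", "order_histogram", "soft_threshold"]


@dataclass
class ENSConfig:
    alpha: float = 1.0
    rho: float = 0.01
    outer_iterations: int = 20
    epochs_per_step: int = 50
    warmup_epochs: int = 200
    patience: int = 20
    batch_size: int = 64
    lr: float = 0.01
    C: int = 3
    b: int | None = None
    k_estimate: int = 16
    plan_seed: int = 0
    seed: int = 0
    accept_partial_peeling: bool = True

    def __post_init__(self):
        if self.rho <= 0:
            raise ValueError("rho must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


@dataclass
class ADMMState:
    """One EN-S iterate: sparse spectrum, dual vector, diagnostics."""

    u: WHSpectrum
    gamma: np.ndarray
    primal_residual: float
    iteration: int
    peeling_converged: bool = True


def ht_times_u(points_pm1: np.ndarray, u: WHSpectrum) -> np.ndarray:
    """Rows of the unitary WH matrix times a sparse spectrum.

    Entry for a ±1 row ``x`` is ``sum_S u_S * 2**(-d/2) * prod_{i in S} x_i``
    (for a unitary-scale ``u``); cost O(|T| * |supp(u)|).
    """
    x = np.atleast_2d(np.asarray(points_pm1, dtype=float))
    n, d = x.shape
    if u.d != d:
        raise ValueError(f"spectrum d={u.d} != row width {d}")
    out = np.zeros(n)
    scale = 2.0 ** (-d / 2.0) if u.scale == UNITARY else 1.0
    for mask, coef in u.coefficients.items():
        if mask == 0:
            out += coef * scale
            continue
        sites = [i for i in range(d) if (mask >> i) & 1]
        out += coef * scale * np.prod(x[:, sites], axis=1)
    return out


def soft_threshold(w: np.ndarray, threshold: float) -> np.ndarray:
    """Prox of ``t*||u||_1 + (1/2)||w - u||**2``: shrink toward zero by t.

    Reference utility only; the EN-S main path uses peeling plus the l0
    hard threshold instead.
    """
    w = np.asarray(w, dtype=float)
    return np.sign(w) * np.maximum(np.abs(w) - threshold, 0.0)


def _composite_epoch(model: DenseNet, opt: Adam, rng: np.random.Generator,
                     X_tr, y_tr, X_T, target, rho: float, batch_size: int) -> None:
    n = X_tr.shape[0]
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        idx = order[start:start + batch_size]
        pred = model.forward(X_tr[idx], training=True)
        grads = model.backward(2.0 * (pred - y_tr[idx]))
        if rho > 0 and X_T is not None:
            g_T = model.forward(X_T, training=True)
            pen_grads = model.backward(rho * (g_T - target))
            for k in grads:
                grads[k] = grads[k] + pen_grads[k]
        opt.step(model.params, grads)


def theta_step(model: DenseNet, train_set, X_T: np.ndarray,
               u: WHSpectrum, gamma: np.ndarray, rho: float,
               epochs: int = 50, lr: float = 0.01, batch_size: int = 64,
               seed: int = 0, opt: Adam | None = None) -> DenseNet:
    """Gradient descent on the MSE plus the quadratic ADMM coupling term."""
    X_tr = np.asarray(train_set[0], float)
    y_tr = np.asarray(train_set[1], float)
    hu = ht_times_u(X_T, u) if X_T is not None else None
    target = (hu - gamma) if X_T is not None else None
    if opt is None:
        opt = Adam(lr=lr)
    rng = np.random.default_rng(seed)
    for _ in range(epochs):
        _composite_epoch(model, opt, rng, X_tr, y_tr, X_T, target, rho,
                         batch_size)
        pred = model.predict(X_tr)
        if not np.all(np.isfinite(pred)):
            raise FloatingPointError("non-finite predictions in theta-step")
    return model


def u_step(values_T: np.ndarray, gamma: np.ndarray, queries: QuerySet,
           alpha: float, rho: float, previous: WHSpectrum | None = None,
           accept_partial: bool = True,
           noise_threshold: float | None = None) -> tuple[WHSpectrum, bool]:
    """Sparse spectral projection of ``g(X_T) + gamma`` via peeling.

    Recovered coefficients are converted to the unitary scale and passed
    through the exact l0 prox: keep ``u_S`` only if ``u_S**2 >= 2*alpha/rho``.
    """
    w = np.asarray(values_T, float) + np.asarray(gamma, float)
    plan = queries.plan
    observations = compute_observations(w, queries)
    result = peel(observations, plan, noise_threshold=noise_threshold)
    if not result.converged and not accept_partial:
        if previous is None:
            raise RuntimeError("peeling failed to converge and no previous u")
        return previous, False
    unitary = result.spectrum.to_scale(UNITARY)
    cutoff = np.sqrt(2.0 * alpha / rho) if alpha > 0 else 0.0
    kept = {m: c for m, c in unitary.coefficients.items() if abs(c) >= cutoff}
    return WHSpectrum(d=plan.d, coefficients=kept, scale=UNITARY), result.converged


def dual_step(gamma: np.ndarray, values_T: np.ndarray,
              hu: np.ndarray) -> np.ndarray:
    """gamma + (g(X_T) - H_T u): exact addition of the primal residual."""
    return np.asarray(gamma, float) + (np.asarray(values_T, float)
                                       - np.asarray(hu, float))


def train_ens(model: DenseNet, train_set, val_set,
              config: ENSConfig) -> tuple[DenseNet, list[ADMMState]]:
    """Full EN-S loop: warmup MSE training, then ADMM alternation.

    With ``outer_iterations == 0`` this returns the plain MSE-trained
    model.  The subsampling plan is drawn once and the same query set is
    reused (and cached) across all iterations.  The returned model carries
    the best validation MSE seen anywhere in the run.
    """
    X_tr = np.asarray(train_set[0], float)
    y_tr = np.asarray(train_set[1], float)
    X_val = np.asarray(val_set[0], float)
    y_val = np.asarray(val_set[1], float)
    d = model.d

    plan = design_plan(d, config.k_estimate, C=config.C, b=config.b,
                       seed=config.plan_seed, strict=False)
    queries = sample_points(plan)
    X_T = points_to_pm1(queries.points, d).astype(float)

    rng = np.random.default_rng(config.seed)
    opt = Adam(lr=config.lr)
    best_val = np.inf
    best_state = model.state_dict()

    def check_val():
        nonlocal best_val, best_state
        val_mse = float(np.mean((y_val - model.predict(X_val)) ** 2))
        if val_mse < best_val:
            best_val = val_mse
            best_state = model.state_dict()
        return val_mse

    # warmup: plain MSE training with early stopping on validation MSE
    since_best = 0
    for _ in range(config.warmup_epochs):
        _composite_epoch(model, opt, rng, X_tr, y_tr, None, None, 0.0,
                         config.batch_size)
        before = best_val
        check_val()
        since_best = 0 if best_val < before else since_best + 1
        if since_best >= config.patience:
            break

    u = WHSpectrum(d=d, coefficients={}, scale=UNITARY)
    gamma = np.zeros(queries.n_unique)
    trace: list[ADMMState] = []

    if config.outer_iterations > 0:
        # seed u from the warm model: a first theta-step against u=0 would
        # only shrink the landscape toward zero on X_T
        u, _ = u_step(model.predict(X_T), gamma, queries, config.alpha,
                      config.rho, previous=u,
                      accept_partial=config.accept_partial_peeling)

    for t in range(config.outer_iterations):
        theta_step(model, (X_tr, y_tr), X_T, u, gamma, config.rho,
                   epochs=config.epochs_per_step, lr=config.lr,
                   batch_size=config.batch_size,
                   seed=config.seed + 1000 + t, opt=opt)
        check_val()
        g_T = model.predict(X_T)
        u, converged = u_step(g_T, gamma, queries, config.alpha, config.rho,
                              previous=u,
                              accept_partial=config.accept_partial_peeling)
        hu = ht_times_u(X_T, u)
        gamma = dual_step(gamma, g_T, hu)
        trace.append(ADMMState(
            u=u, gamma=gamma.copy(),
            primal_residual=float(np.linalg.norm(g_T - hu)),
            iteration=t, peeling_converged=converged))

    model.load_state_dict(best_state)
    return model, trace


def order_histogram(u_history) -> dict[int, int]:
    """Counts of interaction order |S| over all coefficients in a history
    of sparse spectra (or ADMMState objects)."""
    counts: dict[int, int] = {}
    for entry in u_history:
        spectrum = entry.u if isinstance(entry, ADMMState) else entry
        for mask in spectrum.coefficients:
            order = mask_order(mask)
            counts[order] = counts.get(order, 0) + 1
    return counts
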