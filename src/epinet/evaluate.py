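"""Metrics, the Lasso-over-WH-features baseline, and benchmark orchestration."""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .spectral import (MULTILINEAR, Landscape, PseudoBooleanFunction,
                       WHSpectrum, enumerate_inputs, fwht)

__all__ = ["EvaluationReport", "r_squared", "spectrum_nmse",
           "lasso_wh_baseline", "monomial_features", "run_benchmark"]

# default lambda grid: 50 log-spaced values on [1e-7, 1]
LASSO_LAMBDA_GRID = np.logspace(-7, 0, 50)
TOP_M_GRID = (1, 2, 5, 10, 20, 50, None)   # None = all nonzero (plain Lasso)


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.size != y_pred.size or y_true.size < 2:
        raise ValueError("need equal-length vectors with >= 2 entries")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero variance in y_true")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


def spectrum_nmse(estimated: WHSpectrum, truth: WHSpectrum) -> float:
    """||est - truth||^2 / ||truth||^2 over the union of supports."""
    if estimated.d != truth.d:
        raise ValueError("spectra differ in d")
    if estimated.scale != truth.scale:
        estimated = estimated.to_scale(truth.scale)
    denom = truth.energy()
    if denom == 0:
        raise ValueError("zero-energy reference spectrum")
    num = 0.0
    for m in set(estimated.coefficients) | set(truth.coefficients):
        diff = estimated.coefficients.get(m, 0.0) - truth.coefficients.get(m, 0.0)
        num += diff * diff
    return num / denom


def monomial_features(x: np.ndarray, max_order: int
                      ) -> tuple[np.ndarray, list[int]]:
    """WH monomial design matrix for all subsets of order 1..max_order."""
    x = np.atleast_2d(np.asarray(x, float))
    d = x.shape[1]
    masks: list[int] = []
    cols: list[np.ndarray] = []
    for order in range(1, max_order + 1):
        for sites in combinations(range(d), order):
            mask = 0
            for s in sites:
                mask |= 1 << s
            masks.append(mask)
            cols.append(np.prod(x[:, list(sites)], axis=1))
    F = np.column_stack(cols) if cols else np.empty((x.shape[0], 0))
    return F, masks


def lasso_wh_baseline(train_set, max_order: int, val_set,
                      lambda_grid: np.ndarray = LASSO_LAMBDA_GRID,
                      top_m_grid=TOP_M_GRID
                      ) -> tuple[PseudoBooleanFunction, dict]:
    """l1-penalized fit over WH monomials with OLS support debiasing.

    For each lambda on the grid, the Lasso support is ranked by coefficient
    magnitude; each candidate top-m subset is refit by ordinary least
    squares and the (lambda, m) pair with the lowest validation MSE wins.
    The plain Lasso is recovered when all nonzero coefficients are kept.
    """
    from sklearn.linear_model import Lasso

    X_tr, y_tr = np.asarray(train_set[0], float), np.asarray(train_set[1], float)
    X_val, y_val = np.asarray(val_set[0], float), np.asarray(val_set[1], float)
    d = X_tr.shape[1]
    F_tr, masks = monomial_features(X_tr, max_order)
    F_val, _ = monomial_features(X_val, max_order)

    best = {"val_mse": np.inf, "lambda": None, "m": None,
            "support": [], "coefs": [], "intercept": float(np.mean(y_tr))}
    for lam in lambda_grid:
        model = Lasso(alpha=float(lam), fit_intercept=True, max_iter=5000,
                      tol=1e-6)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(F_tr, y_tr)
        nz = np.flatnonzero(model.coef_)
        if nz.size == 0:
            mean_mse = float(np.mean((y_val - np.mean(y_tr)) ** 2))
            if mean_mse < best["val_mse"]:
                best.update(val_mse=mean_mse, **{"lambda": float(lam)}, m=0,
                            support=[], coefs=[])
            continue
        ranked = nz[np.argsort(-np.abs(model.coef_[nz]))]
        for m in top_m_grid:
            take = ranked if m is None else ranked[:m]
            if take.size == 0:
                continue
            A = np.column_stack([np.ones(len(y_tr)), F_tr[:, take]])
            beta, *_ = np.linalg.lstsq(A, y_tr, rcond=None)
            pred_val = beta[0] + F_val[:, take] @ beta[1:]
            val_mse = float(np.mean((y_val - pred_val) ** 2))
            if val_mse < best["val_mse"]:
                best.update(val_mse=val_mse, m=(None if m is None else int(m)),
                            support=[masks[t] for t in take],
                            coefs=list(map(float, beta[1:])),
                            intercept=float(beta[0]))
                best["lambda"] = float(lam)
    terms = [(0, best["intercept"])] if best["intercept"] != 0 else []
    terms += [(m, c) for m, c in zip(best["support"], best["coefs"]) if c != 0]
    pbf = PseudoBooleanFunction(d=d, terms=terms)
    report = {"lambda": best["lambda"], "top_m": best["m"],
              "val_mse": best["val_mse"], "n_features": len(masks),
              "support_size": len(best["support"])}
    if not best["support"]:
        report["warning"] = "empty support at all lambdas; mean-only model"
    return pbf, report


@dataclass
class EvaluationReport:
    method: str
    seed: int
    r2: float
    nmse: float | None = None
    extra: dict = field(default_factory=dict)


def run_benchmark(config: dict) -> dict:
    """Simulate -> split -> train each method -> aggregate R2/NMSE.

    The same landscape, split and model initialization seed are shared by
    all methods within a seed (paired design), so per-seed deltas isolate
    the effect of regularization.  Returns per-seed reports plus mean and
    SEM aggregates; the output is deterministic given the config.
    """
    from .en import ENConfig, train_en
    from .ens import ENSConfig, train_ens
    from .landscapes import (SyntheticSpec, generate_sparse_landscape,
                             sample_dataset, split_dataset)
    from .nn import build_dnn
    from .spectral import Landscape as _L

    d = config["d"]
    methods = list(config.get("methods", ["dnn", "dnn+en"]))
    seeds = list(config.get("seeds", [0]))
    n_train = config.get("n_train", 60)
    n_val = config.get("n_val", n_train)
    n_test = config.get("n_test", 2000)
    sigma_frac = config.get("sigma_frac", 0.05)
    expansion = config.get("expansion", 2)
    max_order = config.get("lasso_max_order", 2)

    large_orders = config.get("large_orders", (1, 3))
    small_orders = config.get("small_orders")

    rows: list[EvaluationReport] = []
    for seed in seeds:
        spec0 = SyntheticSpec(d=d, k_large=config.get("k_large", 5),
                              k_small=config.get("k_small", 20),
                              large_orders=large_orders,
                              small_orders=small_orders, seed=seed)
        truth, _ = generate_sparse_landscape(spec0)
        signal_sd = float(np.sqrt(sum(c * c for m, c in truth.terms if m != 0)))
        spec = SyntheticSpec(d=d, k_large=spec0.k_large, k_small=spec0.k_small,
                             large_orders=large_orders,
                             small_orders=small_orders,
                             sigma=sigma_frac * signal_sd, seed=seed)
        truth, sampler = generate_sparse_landscape(spec)
        n_total = n_train + n_val + n_test
        X, y = sample_dataset(sampler, d, n_total, seed=seed + 17)
        split = split_dataset(n_total, n_train, n_val, n_test, seed=seed + 31)
        # standardize targets on the training set; predictions are mapped
        # back before any spectrum comparison
        mu = float(np.mean(y[split.train]))
        sd = float(np.std(y[split.train])) or 1.0
        ys = (y - mu) / sd
        tr = (X[split.train].astype(float), ys[split.train])
        va = (X[split.val].astype(float), ys[split.val])
        te = (X[split.test].astype(float), ys[split.test])
        truth_spec = truth.spectrum()

        for method in methods:
            nmse = None
            if method == "lasso":
                pbf, _rep = lasso_wh_baseline(tr, max_order, va)
                pred = pbf(te[0])
                est = WHSpectrum(
                    d=d,
                    coefficients={m: c * sd + (mu if m == 0 else 0.0)
                                  for m, c in pbf.spectrum().coefficients.items()},
                    scale=MULTILINEAR)
                nmse = spectrum_nmse(est, truth_spec)
            elif method in ("dnn", "dnn+en"):
                alpha = 0.0 if method == "dnn" else config.get("alpha", 0.1)
                lr = 0.001 if method == "dnn" else config.get("lr", 0.01)
                model = build_dnn(d, expansion=expansion, seed=seed)
                cfg = ENConfig(alpha=alpha, lr=lr,
                               epochs=config.get("epochs", 1000),
                               patience=config.get("patience", 20), seed=seed)
                model, _log = train_en(model, tr, va, cfg)
                pred = model.predict(te[0])
                if d <= 16:
                    full = model.predict(enumerate_inputs(d).astype(float)) * sd + mu
                    est = fwht(_L(d=d, values=full), MULTILINEAR)
                    nmse = spectrum_nmse(est, truth_spec)
            elif method == "dnn+ens":
                model = build_dnn(d, expansion=expansion, seed=seed)
                cfg = ENSConfig(alpha=config.get("ens_alpha", 1.0),
                                rho=config.get("rho", 0.01),
                                outer_iterations=config.get("outer_iterations", 10),
                                epochs_per_step=config.get("epochs_per_step", 50),
                                k_estimate=config.get("k_estimate", 16),
                                b=config.get("b"), C=config.get("C", 3),
                                lr=config.get("lr", 0.01),
                                patience=config.get("patience", 20),
                                plan_seed=seed, seed=seed)
                model, _trace = train_ens(model, tr, va, cfg)
                pred = model.predict(te[0])
                if d <= 16:
                    full = model.predict(enumerate_inputs(d).astype(float)) * sd + mu
                    est = fwht(_L(d=d, values=full), MULTILINEAR)
                    nmse = spectrum_nmse(est, truth_spec)
            else:
                raise ValueError(f"unknown method {method!r}")
            rows.append(EvaluationReport(method=method, seed=seed,
                                         r2=r_squared(te[1], pred), nmse=nmse))

    out = {"per_seed": [vars(r) for r in rows], "aggregate": {}}
    for method in methods:
        r2s = np.array([r.r2 for r in rows if r.method == method])
        nmses = [r.nmse for r in rows if r.method == method and r.nmse is not None]
        agg = {"r2_mean": float(r2s.mean()),
               "r2_sem": float(r2s.std(ddof=1) / np.sqrt(len(r2s)))
               if len(r2s) > 1 else 0.0}
        if nmses:
            nm = np.array(nmses)
            agg["nmse_mean"] = float(nm.mean())
            agg["nmse_sem"] = (float(nm.std(ddof=1) / np.sqrt(len(nm)))
                               if len(nm) > 1 else 0.0)
        out["aggregate"][method] = agg
    return out
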