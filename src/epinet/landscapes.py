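"""Synthetic sparse-epistasis landscapes, dataset sampling and preprocessing.

The generator emulates the assumed structure of measured fitness functions:
a handful of large-magnitude spectral coefficients plus a larger band of
small ones, observed under additive zero-mean Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .spectral import PseudoBooleanFunction, eval_pbf

__all__ = ["SyntheticSpec", "DataSplit", "generate_sparse_landscape",
           "NoisySampler", "sample_dataset", "split_dataset",
           "boxcox_preprocess", "boxcox_inverse", "index_to_pm1"]


@dataclass(frozen=True)
class SyntheticSpec:
    d: int
    k_large: int = 5
    k_small: int = 20
    order_low: int = 1
    order_high: int | None = None    # defaults to min(5, d)
    large_range: tuple[float, float] = (8.0, 16.0)
    small_range: tuple[float, float] = (0.1, 1.0)
    # optional per-band order ranges; measured landscapes typically carry
    # their large coefficients at low order, so benchmarks may set e.g.
    # large_orders=(1, 3) while small terms roam the full default range
    large_orders: tuple[int, int] | None = None
    small_orders: tuple[int, int] | None = None
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.order_high is None:
            object.__setattr__(self, "order_high", min(5, self.d))
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.k_large + self.k_small > (1 << self.d):
            raise ValueError("more terms requested than 2**d masks")
        for lo, hi in ((self.order_low, self.order_high),
                       self.large_orders or (1, 1),
                       self.small_orders or (1, 1)):
            if not (1 <= lo <= hi <= self.d):
                raise ValueError("invalid order range")


class NoisySampler:
    """Callable returning noisy observations of a fixed ground truth.

    Noise is applied to observations only; the stored polynomial is exact.
    The noise stream is deterministic given the spec seed.
    """

    def __init__(self, pbf: PseudoBooleanFunction, sigma: float, seed: int):
        self.pbf = pbf
        self.sigma = sigma
        self._rng = np.random.default_rng(seed)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        clean = eval_pbf(self.pbf, x)
        if self.sigma == 0:
            return clean
        return clean + self._rng.normal(0.0, self.sigma, size=clean.shape)


def _draw_masks(rng: np.random.Generator, spec: SyntheticSpec,
                count: int, taken: set[int],
                orders: tuple[int, int] | None = None) -> list[int]:
    lo, hi = orders if orders is not None else (spec.order_low, spec.order_high)
    masks = []
    while len(masks) < count:
        order = int(rng.integers(lo, hi + 1))
        sites = rng.choice(spec.d, size=order, replace=False)
        mask = 0
        for s in sites:
            mask |= 1 << int(s)
        if mask in taken:
            continue
        taken.add(mask)
        masks.append(mask)
    return masks


def generate_sparse_landscape(spec: SyntheticSpec
                              ) -> tuple[PseudoBooleanFunction, NoisySampler]:
    """Ground-truth sparse polynomial plus its noisy observation sampler.

    Orders are drawn uniformly in [order_low, order_high], then a mask of
    that order uniformly, without replacement across terms.  Large-band
    magnitudes are uniform in ``large_range``, small-band in
    ``small_range``, with random signs.
    """
    rng = np.random.default_rng(spec.seed)
    taken: set[int] = set()
    terms: list[tuple[int, float]] = []
    for count, (lo, hi), orders in (
            (spec.k_large, spec.large_range, spec.large_orders),
            (spec.k_small, spec.small_range, spec.small_orders)):
        for mask in _draw_masks(rng, spec, count, taken, orders):
            magnitude = rng.uniform(lo, hi)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            terms.append((mask, sign * magnitude))
    pbf = PseudoBooleanFunction(d=spec.d, terms=terms)
    sampler = NoisySampler(pbf, spec.sigma, seed=spec.seed + 1)
    return pbf, sampler


def index_to_pm1(indices: np.ndarray, d: int) -> np.ndarray:
    """±1 rows for canonical enumeration indices (bit set -> -1)."""
    idx = np.asarray(indices, dtype=np.int64)
    bits = (idx[:, None] >> np.arange(d)) & 1
    return (1 - 2 * bits).astype(np.int8)


def sample_dataset(sampler, d: int, n: int, seed: int = 0
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Uniform without-replacement sample of the combinatorial space.

    ``sampler`` is any callable on ±1 matrices (a :class:`NoisySampler`, a
    model, or a plain function).  For d beyond enumeration range, distinct
    random indices are drawn by rejection instead of a dense permutation.
    """
    rng = np.random.default_rng(seed)
    if d <= 48:
        total = 1 << d
        if n > total:
            raise ValueError(f"cannot draw {n} distinct points from 2**{d}")
        indices = rng.choice(total, size=n, replace=False)
    else:
        seen: set[int] = set()
        while len(seen) < n:
            for chunk in rng.integers(0, 1 << 62, size=n, dtype=np.int64):
                seen.add(int(chunk) & ((1 << d) - 1))
                if len(seen) == n:
                    break
        indices = np.array(sorted(seen))
        rng.shuffle(indices)
    x = index_to_pm1(indices, d)
    y = np.asarray(sampler(x), dtype=float)
    return x, y


@dataclass
class DataSplit:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    seed: int

    def __post_init__(self):
        sets = [set(self.train), set(self.val), set(self.test)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("split index sets overlap")


def split_dataset(n_samples: int, train_n: int, val_n: int, test_n: int,
                  seed: int = 0) -> DataSplit:
    """Disjoint random train/validation/test index sets."""
    if train_n + val_n + test_n > n_samples:
        raise ValueError(
            f"split sizes {train_n}+{val_n}+{test_n} exceed {n_samples}")
    perm = np.random.default_rng(seed).permutation(n_samples)
    return DataSplit(
        train=perm[:train_n],
        val=perm[train_n:train_n + val_n],
        test=perm[train_n + val_n:train_n + val_n + test_n],
        seed=seed,
    )


_BC_GRID = np.linspace(-2.0, 2.0, 101)


def boxcox_preprocess(y: np.ndarray, strict: bool = False,
                      grid: np.ndarray = _BC_GRID
                      ) -> tuple[np.ndarray, float, float]:
    """Box-Cox power transform with profile-likelihood lambda selection.

    Nonpositive values are shifted to positivity (unless ``strict``).
    Returns (transformed values, chosen lambda, shift applied).
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("values must be finite")
    if np.ptp(y) == 0:
        raise ValueError("degenerate (constant) input")
    shift = 0.0
    if y.min() <= 0:
        if strict:
            raise ValueError("nonpositive values with strict=True")
        shift = -y.min() + 1e-3 * np.ptp(y)
    z = y + shift
    lls = np.array([stats.boxcox_llf(lam, z) for lam in grid])
    lam = float(grid[int(np.argmax(lls))])
    return special.boxcox(z, lam), lam, shift


def boxcox_inverse(t: np.ndarray, lam: float, shift: float) -> np.ndarray:
    return special.inv_boxcox(np.asarray(t, dtype=float), lam) - shift
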