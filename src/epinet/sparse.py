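"""Sublinear sparse WH recovery via sparse-graph-code subsampling and peeling.

The query design hashes each WH coefficient ``alpha_S`` into one bin per
subsampling group; a coefficient with subset mask ``S`` lands in bin
``M_c^T S`` (mod 2) of group ``c``.  Observing each bin under ``d+1`` delay
offsets (zero plus every unit coordinate vector) exposes both the location
and the value of a coefficient that is alone in its bin: the amplitude is
constant across delays while the sign flips under delay ``e_i`` exactly when
``i in S``.  Peeling repeatedly extracts such singletons and subtracts their
contribution from every group until the bin graph is empty.

All sequence points are carried as Python integers (bit ``i`` set means
site ``i`` mutated, i.e. ``x_i = -1``), so arbitrary ``d`` is supported
without ever allocating a 2**d object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .spectral import MULTILINEAR, WHSpectrum, fwht_vector, mask_to_bitstring, bitstring_to_mask

__all__ = [
    "SamplingPlan",
    "ObservationSet",
    "BinState",
    "RecoveryResult",
    "design_plan",
    "sample_points",
    "points_to_pm1",
    "compute_observations",
    "detect_bin",
    "peel",
    "recover_sparse_wht",
]


def _parity(x: int) -> int:
    return int(x).bit_count() & 1


# ---------------------------------------------------------------------------
# Plan
# ---------------------------------------------------------------------------


@dataclass
class SamplingPlan:
    """Sparse-graph-code subsampling design.

    ``columns[c]`` holds the ``b`` columns of the group-``c`` subsampling
    matrix ``M_c`` (each column a d-bit integer).  ``delays`` is the offset
    set ``{0, e_1, ..., e_d}``.
    """

    d: int
    C: int
    b: int
    columns: list[list[int]]
    seed: int

    @property
    def n_bins(self) -> int:
        return 1 << self.b

    @property
    def delays(self) -> list[int]:
        return [0] + [1 << i for i in range(self.d)]

    @property
    def n_delays(self) -> int:
        return self.d + 1

    @property
    def query_budget(self) -> int:
        """Number of plan query slots |T| (before deduplication)."""
        return self.C * (self.d + 1) * (1 << self.b)

    def hash_mask(self, mask: int, group: int) -> int:
        """Bin index M_c^T S of coefficient mask S in the given group."""
        j = 0
        for t, col in enumerate(self.columns[group]):
            j |= _parity(mask & col) << t
        return j

    def bin_point(self, group: int, ell: int) -> int:
        """Sequence point M_c @ ell (no delay), as a d-bit integer."""
        m = 0
        for t, col in enumerate(self.columns[group]):
            if (ell >> t) & 1:
                m ^= col
        return m

    def to_json(self, path) -> None:
        payload = {
            "d": self.d, "C": self.C, "b": self.b, "seed": self.seed,
            "columns": [[mask_to_bitstring(col, self.d) for col in group]
                        for group in self.columns],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SamplingPlan":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            d=payload["d"], C=payload["C"], b=payload["b"],
            seed=payload["seed"],
            columns=[[bitstring_to_mask(col) for col in group]
                     for group in payload["columns"]],
        )


def _gf2_rank(columns: list[int]) -> int:
    rank = 0
    rows = list(columns)
    for _ in range(len(rows)):
        pivot = next((r for r in rows if r), 0)
        if not pivot:
            break
        rank += 1
        low = pivot & -pivot
        rows = [r ^ pivot if r & low else r for r in rows if r != pivot]
    return rank


def design_plan(d: int, k_estimate: int, C: int = 3, b: int | None = None,
                seed: int = 0, strict: bool = True) -> SamplingPlan:
    """Draw a random full-rank subsampling plan.

    ``b`` defaults to ``ceil(log2 k) + 1`` so that ``2**b >= 2k``, the
    regime in which peeling succeeds with high probability.
    """
    if C < 2:
        raise ValueError("need at least C=2 subsampling groups")
    if b is None:
        b = max(1, int(np.ceil(np.log2(max(k_estimate, 1)))) + 1)
    if b > d:
        raise ValueError(f"b={b} cannot exceed d={d}")
    if (1 << b) <= k_estimate:
        msg = (f"2**b={1 << b} bins <= k_estimate={k_estimate}: "
               "peeling is unlikely to converge")
        if strict:
            raise ValueError(msg)
        import warnings
        warnings.warn(msg, stacklevel=2)
    rng = np.random.default_rng(seed)
    columns: list[list[int]] = []
    for _ in range(C):
        while True:
            cols = []
            for _ in range(b):
                bits = rng.integers(0, 2, size=d)
                cols.append(int("".join(map(str, bits[::-1])), 2))
            if _gf2_rank(cols) == b:
                columns.append(cols)
                break
    return SamplingPlan(d=d, C=C, b=b, columns=columns, seed=seed)


# ---------------------------------------------------------------------------
# Query points and observations
# ---------------------------------------------------------------------------


@dataclass
class QuerySet:
    """Deduplicated query points plus the map back to plan slots."""

    plan: SamplingPlan
    points: list[int]                 # unique d-bit points
    slot_index: np.ndarray            # shape (C, d+1, 2**b) -> row in points

    @property
    def n_unique(self) -> int:
        return len(self.points)


def sample_points(plan: SamplingPlan) -> QuerySet:
    """Enumerate all plan query points, deduplicated with an index map."""
    lookup: dict[int, int] = {}
    points: list[int] = []
    B = plan.n_bins
    slot_index = np.empty((plan.C, plan.n_delays, B), dtype=np.int64)
    delays = plan.delays
    for c in range(plan.C):
        base = [plan.bin_point(c, ell) for ell in range(B)]
        for t, delta in enumerate(delays):
            for ell in range(B):
                m = base[ell] ^ delta
                row = lookup.get(m)
                if row is None:
                    row = len(points)
                    lookup[m] = row
                    points.append(m)
                slot_index[c, t, ell] = row
    return QuerySet(plan=plan, points=points, slot_index=slot_index)


def points_to_pm1(points: list[int], d: int) -> np.ndarray:
    """±1 matrix for integer-coded points (bit set -> -1)."""
    out = np.ones((len(points), d), dtype=np.int8)
    for r, m in enumerate(points):
        mm = m
        while mm:
            low = mm & -mm
            out[r, low.bit_length() - 1] = -1
            mm ^= low
    return out


@dataclass
class ObservationSet:
    """Per-group, per-delay bin observations (small WH transforms)."""

    plan: SamplingPlan
    bins: np.ndarray        # shape (C, d+1, 2**b)
    noise_scale: float = 0.0

    def copy(self) -> "ObservationSet":
        return ObservationSet(plan=self.plan, bins=self.bins.copy(),
                              noise_scale=self.noise_scale)

    def total_energy(self) -> float:
        return float(np.sum(self.bins ** 2))


def compute_observations(values: np.ndarray, queries: QuerySet) -> ObservationSet:
    """Hash subsampled function values into bins.

    For each (group, delay) the length-2**b vector of values over bin
    indices is WH-transformed and scaled by 1/2**b, so that a lone
    coefficient ``alpha_S`` shows up in bin ``hash(S)`` with amplitude
    ``alpha_S * (-1)**<S, delta>``.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size != queries.n_unique:
        raise ValueError(
            f"expected {queries.n_unique} values aligned with the query set, "
            f"got {values.size}")
    plan = queries.plan
    B = plan.n_bins
    bins = np.empty((plan.C, plan.n_delays, B))
    for c in range(plan.C):
        for t in range(plan.n_delays):
            v = values[queries.slot_index[c, t]]
            bins[c, t] = fwht_vector(v) / B
    # median-based noise scale: with 2**b >= 2k most bins are empty, so the
    # median bin magnitude tracks the noise floor
    noise = float(np.median(np.abs(bins)))
    return ObservationSet(plan=plan, bins=bins, noise_scale=noise)


# ---------------------------------------------------------------------------
# Bin classification
# ---------------------------------------------------------------------------


@dataclass
class BinState:
    kind: str                      # "zero-ton" | "singleton" | "multi-ton"
    mask: int = -1
    value: float = 0.0
    confidence: float = 0.0


def detect_bin(observations: np.ndarray, noise_threshold: float,
               plan: SamplingPlan | None = None, group: int = 0,
               bin_index: int = 0, ratio_tol: float = 0.2,
               ratio_frac: float = 0.8) -> BinState:
    """Classify one bin from its d+1 delayed observations.

    A singleton must (a) carry energy above the threshold, (b) have a
    consistent amplitude across delays (ratio test: at least ``ratio_frac``
    of the |observations| within ``ratio_tol`` relative distance of the
    median amplitude), and (c) hash back to its own bin under the plan.
    Anything ambiguous is conservatively labelled multi-ton.
    """
    obs = np.asarray(observations, dtype=float)
    d = obs.size - 1
    rms = float(np.sqrt(np.mean(obs ** 2)))
    if rms <= noise_threshold:
        return BinState(kind="zero-ton", confidence=1.0)
    amps = np.abs(obs)
    modal = float(np.median(amps))
    if modal <= 0:
        return BinState(kind="multi-ton")
    frac_ok = float(np.mean(np.abs(amps - modal) <= ratio_tol * modal))
    if frac_ok < ratio_frac:
        return BinState(kind="multi-ton", confidence=frac_ok)
    ref = obs[0]
    if abs(ref) <= ratio_tol * modal:
        return BinState(kind="multi-ton", confidence=frac_ok)
    mask = 0
    for i in range(d):
        if obs[i + 1] * ref < 0:
            mask |= 1 << i
    if plan is not None and plan.hash_mask(mask, group) != bin_index:
        return BinState(kind="multi-ton", confidence=frac_ok)
    signs = np.ones(d + 1)
    mm = mask
    while mm:
        low = mm & -mm
        signs[low.bit_length()] = -1.0   # delay index i+1 for site i
        mm ^= low
    value = float(np.mean(obs * signs))
    if value == 0.0:
        return BinState(kind="multi-ton", confidence=frac_ok)
    return BinState(kind="singleton", mask=mask, value=value,
                    confidence=frac_ok)


# ---------------------------------------------------------------------------
# Peeling
# ---------------------------------------------------------------------------


@dataclass
class RecoveryResult:
    spectrum: WHSpectrum
    iterations: int
    residual_energy: float
    unresolved_bins: int
    converged: bool
    queries_planned: int = 0
    queries_unique: int = 0
    plan: SamplingPlan | None = None
    history: list[dict[int, float]] = field(default_factory=list)


def _delay_signs(mask: int, d: int) -> np.ndarray:
    signs = np.ones(d + 1)
    mm = mask
    while mm:
        low = mm & -mm
        signs[low.bit_length()] = -1.0
        mm ^= low
    return signs


def peel(observations: ObservationSet, plan: SamplingPlan,
         max_iterations: int | None = None,
         noise_threshold: float | None = None) -> RecoveryResult:
    """Iterative peeling decoder over the bin graph.

    Each sweep scans all bins; every singleton found is immediately
    subtracted from all groups (re-hashed per group).  Stops when a sweep
    finds no singleton or the iteration budget runs out.
    """
    obs = observations.copy()
    d = plan.d
    B = plan.n_bins
    if noise_threshold is None:
        peak = float(np.max(np.abs(obs.bins))) if obs.bins.size else 0.0
        noise_threshold = max(4.0 * obs.noise_scale, 1e-9 * peak, 1e-12)
    if max_iterations is None:
        max_iterations = 2 * B + 10

    recovered: dict[int, float] = {}
    iterations = 0
    converged = False
    sweep_log: list[dict[int, float]] = []
    for _ in range(max_iterations):
        found = 0
        for c in range(plan.C):
            for j in range(B):
                state = detect_bin(obs.bins[c, :, j], noise_threshold,
                                   plan=plan, group=c, bin_index=j)
                if state.kind != "singleton":
                    continue
                mask, value = state.mask, state.value
                recovered[mask] = recovered.get(mask, 0.0) + value
                if recovered[mask] == 0.0:
                    del recovered[mask]
                signs = _delay_signs(mask, d)
                for cc in range(plan.C):
                    jj = plan.hash_mask(mask, cc)
                    obs.bins[cc, :, jj] -= value * signs
                found += 1
        if found == 0:
            break
        iterations += 1
        sweep_log.append(dict(recovered))

    unresolved = 0
    for c in range(plan.C):
        for j in range(B):
            rms = float(np.sqrt(np.mean(obs.bins[c, :, j] ** 2)))
            if rms > noise_threshold:
                unresolved += 1
    converged = unresolved == 0
    spectrum = WHSpectrum(d=d, coefficients=dict(recovered), scale=MULTILINEAR)
    return RecoveryResult(
        spectrum=spectrum,
        iterations=iterations,
        residual_energy=obs.total_energy(),
        unresolved_bins=unresolved,
        converged=converged,
        plan=plan,
        history=sweep_log,
    )


# ---------------------------------------------------------------------------
# End-to-end recovery from a black-box oracle
# ---------------------------------------------------------------------------


class CountingOracle:
    """Wraps a callable on ±1 matrices; counts evaluations and caches them."""

    def __init__(self, fn):
        self.fn = fn
        self.n_evaluated = 0
        self._cache: dict[int, float] = {}

    def query(self, points: list[int], d: int) -> np.ndarray:
        missing = [m for m in points if m not in self._cache]
        if missing:
            x = points_to_pm1(missing, d)
            vals = np.asarray(self.fn(x), dtype=float).reshape(-1)
            if vals.size != len(missing):
                raise ValueError("oracle returned wrong number of values")
            self.n_evaluated += len(missing)
            for m, v in zip(missing, vals):
                self._cache[m] = float(v)
        return np.array([self._cache[m] for m in points])


def recover_sparse_wht(oracle, d: int, k_estimate: int, C: int = 3,
                       b: int | None = None, seed: int = 0,
                       noise_threshold: float | None = None,
                       max_iterations: int | None = None) -> RecoveryResult:
    """design_plan -> sample_points -> oracle -> compute_observations -> peel.

    ``oracle`` maps a ±1 matrix of shape (n, d) to n real values.  The
    total number of distinct oracle evaluations is at most the plan budget
    C*(d+1)*2**b; nothing of size 2**d is ever allocated.
    """
    plan = design_plan(d, k_estimate, C=C, b=b, seed=seed)
    queries = sample_points(plan)
    counting = oracle if isinstance(oracle, CountingOracle) else CountingOracle(oracle)
    values = counting.query(queries.points, d)
    observations = compute_observations(values, queries)
    result = peel(observations, plan, max_iterations=max_iterations,
                  noise_threshold=noise_threshold)
    result.queries_planned = plan.query_budget
    result.queries_unique = counting.n_evaluated
    return result
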