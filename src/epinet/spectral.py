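"""Walsh-Hadamard spectral core for pseudo-Boolean fitness functions.

A fitness function over ``d`` binary sites is represented as a multilinear
polynomial ``f(x) = sum_S alpha_S prod_{i in S} x_i`` with ``x in {-1,+1}^d``.
The coefficients ``alpha_S`` are the epistatic interaction coefficients; they
are obtained from the full table of function values by the Walsh-Hadamard
(WH) transform.

Conventions (fixed once, used everywhere):

* Subset masks are integers; bit ``i`` of a mask means site ``i`` (0-based)
  is a member of the subset.
* Enumeration: entry ``j`` of a :class:`Landscape` holds the value at the
  ±1 vector whose coordinate ``i`` is ``+1`` iff bit ``i`` of ``j`` is 0,
  i.e. ``x_i = (-1)**bit_i(j)``.  The reference (no-mutation) state maps
  to ``+1``.
* Two coefficient scales are supported.  ``multilinear`` stores the literal
  polynomial coefficients ``alpha_S``; ``unitary`` stores the coefficients
  of the norm-preserving transform, which differ by a factor ``2**(d/2)``:
  ``unitary = multilinear * 2**(d/2)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SiteEncoding",
    "Landscape",
    "WHSpectrum",
    "PseudoBooleanFunction",
    "enumerate_inputs",
    "fwht",
    "inverse_wht",
    "fwht_vector",
    "eval_pbf",
    "variance_explained_curve",
    "encode_sequences",
    "decode_matrix",
    "mask_order",
    "mask_to_bitstring",
    "bitstring_to_mask",
    "D_MAX",
]

D_MAX = 25

MULTILINEAR = "multilinear"
UNITARY = "unitary"
_SCALES = (MULTILINEAR, UNITARY)


def mask_order(mask: int) -> int:
    """Number of sites in the subset encoded by ``mask``."""
    return int(mask).bit_count()


def mask_to_bitstring(mask: int, d: int) -> str:
    """Render a subset mask as a string of d chars, site 0 first."""
    return "".join("1" if (mask >> i) & 1 else "0" for i in range(d))


def bitstring_to_mask(bits: str) -> int:
    mask = 0
    for i, ch in enumerate(bits):
        if ch == "1":
            mask |= 1 << i
        elif ch != "0":
            raise ValueError(f"invalid bit character {ch!r}")
    return mask


# ---------------------------------------------------------------------------
# Encodings
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteEncoding:
    """Mapping from raw sequence strings to ±1 vectors of width ``d``.

    ``binary-site`` interprets each raw character as mutation absence ('0',
    mapped to +1) or presence ('1', mapped to -1), one feature per site.
    ``one-hot-block`` expands each site over its alphabet: within a site's
    block exactly one feature (the observed letter) is set to -1 and all
    others are +1.
    """

    scheme: str
    alphabets: tuple[str, ...] = ()
    n_sites: int = 0

    def __post_init__(self):
        if self.scheme not in ("binary-site", "one-hot-block"):
            raise ValueError(f"unknown encoding scheme {self.scheme!r}")
        if self.scheme == "one-hot-block" and not self.alphabets:
            raise ValueError("one-hot-block encoding requires per-site alphabets")

    @classmethod
    def binary(cls, n_sites: int) -> "SiteEncoding":
        return cls(scheme="binary-site", n_sites=n_sites)

    @classmethod
    def one_hot(cls, alphabets: Sequence[str]) -> "SiteEncoding":
        return cls(scheme="one-hot-block", alphabets=tuple(alphabets),
                   n_sites=len(alphabets))

    @property
    def d(self) -> int:
        """Total width of the binary feature space."""
        if self.scheme == "binary-site":
            return self.n_sites
        return sum(len(a) for a in self.alphabets)

    def encode_one(self, seq: str) -> np.ndarray:
        if len(seq) != self.n_sites:
            raise ValueError(
                f"sequence length {len(seq)} != expected {self.n_sites}")
        if self.scheme == "binary-site":
            out = np.empty(self.n_sites, dtype=np.int8)
            for i, ch in enumerate(seq):
                if ch == "0":
                    out[i] = 1
                elif ch == "1":
                    out[i] = -1
                else:
                    raise ValueError(f"unknown symbol {ch!r} at site {i}")
            return out
        out = np.ones(self.d, dtype=np.int8)
        off = 0
        for i, (ch, alphabet) in enumerate(zip(seq, self.alphabets)):
            pos = alphabet.find(ch)
            if pos < 0:
                raise ValueError(f"unknown symbol {ch!r} at site {i}")
            out[off + pos] = -1
            off += len(alphabet)
        return out

    def decode_one(self, x: np.ndarray) -> str:
        if len(x) != self.d:
            raise ValueError(f"vector width {len(x)} != d={self.d}")
        if self.scheme == "binary-site":
            return "".join("1" if v < 0 else "0" for v in x)
        chars = []
        off = 0
        for alphabet in self.alphabets:
            block = x[off:off + len(alphabet)]
            hits = np.flatnonzero(block < 0)
            if len(hits) != 1:
                raise ValueError("one-hot block does not contain exactly one set bit")
            chars.append(alphabet[hits[0]])
            off += len(alphabet)
        return "".join(chars)


def encode_sequences(sequences: Iterable[str], encoding: SiteEncoding) -> np.ndarray:
    """Encode raw sequences into a ±1 matrix of shape (n, encoding.d)."""
    rows = [encoding.encode_one(s) for s in sequences]
    if not rows:
        return np.empty((0, encoding.d), dtype=np.int8)
    return np.stack(rows)


def decode_matrix(x: np.ndarray, encoding: SiteEncoding) -> list[str]:
    return [encoding.decode_one(row) for row in np.atleast_2d(x)]


# ---------------------------------------------------------------------------
# Landscape and spectrum containers
# ---------------------------------------------------------------------------


@dataclass
class Landscape:
    """Full table of function values over all 2**d inputs.

    ``values[j]`` is the function value at the ±1 vector with
    ``x_i = (-1)**bit_i(j)``.
    """

    d: int
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != 1 << self.d:
            raise ValueError(
                f"landscape must have 2**d = {1 << self.d} values, "
                f"got {self.values.size}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("landscape values must be finite")

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"index": np.arange(self.values.size),
                      "value": self.values}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, d: int) -> "Landscape":
        import pandas as pd
        df = pd.read_csv(path).sort_values("index")
        return cls(d=d, values=df["value"].to_numpy())


@dataclass
class WHSpectrum:
    """Sparse WH coefficient map with an explicit scale tag."""

    d: int
    coefficients: dict[int, float]
    scale: str = MULTILINEAR

    def __post_init__(self):
        if self.scale not in _SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if len(self.coefficients) > (1 << self.d):
            raise ValueError("more coefficients than 2**d")
        for mask in self.coefficients:
            if not (0 <= mask < (1 << self.d)):
                raise ValueError(f"mask {mask} out of range for d={self.d}")

    def to_scale(self, scale: str) -> "WHSpectrum":
        if scale not in _SCALES:
            raise ValueError(f"unknown scale {scale!r}")
        if scale == self.scale:
            return self
        factor = 2.0 ** (self.d / 2.0)
        if scale == MULTILINEAR:
            factor = 1.0 / factor
        return WHSpectrum(
            d=self.d,
            coefficients={m: c * factor for m, c in self.coefficients.items()},
            scale=scale,
        )

    def support(self) -> list[int]:
        return sorted(self.coefficients)

    def l1(self) -> float:
        return float(sum(abs(c) for c in self.coefficients.values()))

    def energy(self) -> float:
        return float(sum(c * c for c in self.coefficients.values()))

    def dense(self) -> np.ndarray:
        out = np.zeros(1 << self.d)
        for m, c in self.coefficients.items():
            out[m] = c
        return out

    def prune(self, tol: float = 0.0) -> "WHSpectrum":
        return WHSpectrum(
            d=self.d,
            coefficients={m: c for m, c in self.coefficients.items()
                          if abs(c) > tol},
            scale=self.scale,
        )

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("mask\torder\tcoefficient\tscale\n")
            for m in sorted(self.coefficients):
                fh.write(f"{mask_to_bitstring(m, self.d)}\t{mask_order(m)}\t"
                         f"{self.coefficients[m]!r}\t{self.scale}\n")

    @classmethod
    def from_tsv(cls, path) -> "WHSpectrum":
        coeffs: dict[int, float] = {}
        scale = MULTILINEAR
        d = None
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("mask"):
                raise ValueError("missing spectrum TSV header")
            for line in fh:
                bits, _order, coef, scale = line.rstrip("\n").split("\t")
                d = len(bits)
                coeffs[bitstring_to_mask(bits)] = float(coef)
        if d is None:
            raise ValueError("empty spectrum file")
        return cls(d=d, coefficients=coeffs, scale=scale)

    def to_json(self, path) -> None:
        payload = {
            "d": self.d,
            "scale": self.scale,
            "coefficients": {mask_to_bitstring(m, self.d): c
                             for m, c in sorted(self.coefficients.items())},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "WHSpectrum":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            d=payload["d"],
            coefficients={bitstring_to_mask(b): float(c)
                          for b, c in payload["coefficients"].items()},
            scale=payload["scale"],
        )


@dataclass
class PseudoBooleanFunction:
    """Sparse multilinear polynomial over ±1 inputs."""

    d: int
    terms: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self):
        masks = [m for m, _ in self.terms]
        if len(set(masks)) != len(masks):
            raise ValueError("duplicate masks in term list")
        for m, c in self.terms:
            if not (0 <= m < (1 << self.d)):
                raise ValueError(f"mask {m} out of range for d={self.d}")
            if c == 0:
                raise ValueError("zero coefficient in term list")

    @property
    def k(self) -> int:
        return len(self.terms)

    def spectrum(self) -> WHSpectrum:
        return WHSpectrum(d=self.d, coefficients=dict(self.terms),
                          scale=MULTILINEAR)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return eval_pbf(self, x)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------


def enumerate_inputs(d: int, d_max: int = D_MAX) -> np.ndarray:
    """All 2**d ±1 rows in canonical enumeration order.

    Row ``j`` has ``x_i = +1`` iff bit ``i`` of ``j`` is 0.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    if d > d_max:
        raise ValueError(
            f"d={d} exceeds the dense enumeration limit d_max={d_max}; "
            "use the sparse (EN-S) pathway instead")
    j = np.arange(1 << d, dtype=np.int64)
    bits = (j[:, None] >> np.arange(d)) & 1
    return (1 - 2 * bits).astype(np.int8)


def fwht_vector(v: np.ndarray) -> np.ndarray:
    """Unnormalized fast WH transform (Sylvester ordering), O(p log p).

    Returns ``H @ v`` with ``H[j,k] = (-1)**popcount(j & k)``.  Applying it
    twice returns ``2**d * v``.
    """
    v = np.array(v, dtype=float)
    n = v.size
    if n == 0 or (n & (n - 1)) != 0:
        raise ValueError(f"length {n} is not a power of two")
    h = 1
    while h < n:
        v = v.reshape(-1, 2, h)
        a = v[:, 0, :].copy()
        b = v[:, 1, :].copy()
        v[:, 0, :] = a + b
        v[:, 1, :] = a - b
        v = v.reshape(n)
        h *= 2
    return v


def fwht(landscape: Landscape, scale: str = MULTILINEAR,
         tol: float = 0.0) -> WHSpectrum:
    """WH transform of a full landscape, returned sparsely.

    In the multilinear scale the output coefficients are exactly the
    ``alpha_S`` of the polynomial representation.
    """
    if scale not in _SCALES:
        raise ValueError(f"unknown scale {scale!r}")
    coeffs = fwht_vector(landscape.values)
    if scale == MULTILINEAR:
        coeffs /= float(1 << landscape.d)
    else:
        coeffs /= 2.0 ** (landscape.d / 2.0)
    nz = np.flatnonzero(np.abs(coeffs) > tol)
    return WHSpectrum(d=landscape.d,
                      coefficients={int(m): float(coeffs[m]) for m in nz},
                      scale=scale)


def inverse_wht(spectrum: WHSpectrum) -> Landscape:
    """Reconstruct the full landscape from a (sparse) spectrum."""
    dense = spectrum.dense()
    values = fwht_vector(dense)
    if spectrum.scale == MULTILINEAR:
        pass  # H @ alpha is already the value table
    elif spectrum.scale == UNITARY:
        values /= 2.0 ** (spectrum.d / 2.0)
    else:  # pragma: no cover - guarded in constructor
        raise ValueError(f"unknown scale {spectrum.scale!r}")
    return Landscape(d=spectrum.d, values=values)


def eval_pbf(pbf: PseudoBooleanFunction, inputs: np.ndarray) -> np.ndarray:
    """Evaluate the multilinear polynomial at ±1 rows."""
    x = np.atleast_2d(np.asarray(inputs))
    if x.shape[1] != pbf.d:
        raise ValueError(f"input width {x.shape[1]} != d={pbf.d}")
    out = np.zeros(x.shape[0])
    for mask, coef in pbf.terms:
        if mask >> pbf.d:
            raise ValueError(f"mask {mask} references site >= d={pbf.d}")
        if mask == 0:
            out += coef
            continue
        sites = [i for i in range(pbf.d) if (mask >> i) & 1]
        out += coef * np.prod(x[:, sites], axis=1)
    return out


def variance_explained_curve(spectrum: WHSpectrum,
                             up_to: int | None = None) -> np.ndarray:
    """Fraction of (non-constant) spectral energy in the top-k coefficients.

    The constant term (mask 0) is excluded from numerator and denominator.
    Ties in magnitude are broken by ascending mask value.
    """
    items = [(m, c) for m, c in spectrum.coefficients.items() if m != 0]
    total = sum(c * c for _, c in items)
    if total <= 0:
        raise ValueError("degenerate landscape: zero non-constant variance")
    items.sort(key=lambda mc: (-(mc[1] * mc[1]), mc[0]))
    if up_to is None:
        up_to = len(items)
    sq = np.array([c * c for _, c in items[:up_to]])
    fractions = np.cumsum(sq) / total
    if up_to > len(items):
        fractions = np.concatenate(
            [fractions, np.full(up_to - len(items), fractions[-1] if len(fractions) else 1.0)])
    return fractions
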