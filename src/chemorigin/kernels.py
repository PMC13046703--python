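"""Kernel engine: the five SVM kernel families and Gram-matrix construction.

Families (x1, x2 are row vectors; · the dot product):

* linear      k = x1·x2′
* polynomial  k = (c1 · x1·x2′ + c2)^c3
* gaussian    k = exp(−‖x1 − x2‖² / σ²)   (σ² divides the squared distance
  directly — no factor 2)
* sigmoid     k = tanh(a · x1·x2′ + c)
* hybrid      k = m·linear + n·polynomial + q·gaussian with m + n + q = 1,
  a convex combination of Mercer kernels (hence itself Mercer); the sigmoid,
  which is not positive semi-definite in general, is excluded from the mix.

Non-integer exponents c3 are permitted; the polynomial base is floored at 0
before exponentiation so the kernel stays real.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

__all__ = ["KernelSpec", "gram", "check_psd"]

FAMILIES = ("linear", "polynomial", "gaussian", "sigmoid", "hybrid")
_SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus all named parameters (unused ones are ignored)."""

    family: str = "linear"
    c1: float = 0.0125      # polynomial scale
    c2: float = 1.0         # polynomial shift
    c3: float = 2.0         # polynomial exponent
    sigma2: float = 20.0    # gaussian width σ²
    a: float = 0.01         # sigmoid slope
    c: float = 0.0          # sigmoid shift
    m: float = 1.0          # hybrid weight on linear
    n: float = 0.0          # hybrid weight on polynomial
    q: float = 0.0          # hybrid weight on gaussian

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family in ("gaussian", "hybrid") and not self.sigma2 > 0:
            raise ValueError("sigma2 must be positive")
        if self.family in ("polynomial", "hybrid") and self.c3 < 1:
            raise ValueError("polynomial exponent c3 must be >= 1")
        if self.family == "hybrid":
            for name, w in (("m", self.m), ("n", self.n), ("q", self.q)):
                if not 0.0 <= w <= 1.0:
                    raise ValueError(f"hybrid weight {name} must lie in [0, 1]")
            if abs(self.m + self.n + self.q - 1.0) > _SIMPLEX_TOL:
                raise ValueError("hybrid weights must satisfy m + n + q = 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, mapping: dict) -> "KernelSpec":
        return cls(**mapping)


def _linear(X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    return X1 @ X2.T


def _polynomial(X1: np.ndarray, X2: np.ndarray, c1: float, c2: float, c3: float) -> np.ndarray:
    base = np.maximum(c1 * (X1 @ X2.T) + c2, 0.0)
    return base ** c3


def _gaussian(X1: np.ndarray, X2: np.ndarray, sigma2: float) -> np.ndarray:
    sq = (
        np.sum(X1 ** 2, axis=1)[:, None]
        + np.sum(X2 ** 2, axis=1)[None, :]
        - 2.0 * (X1 @ X2.T)
    )
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-sq / sigma2)


def gram(X1: np.ndarray, X2: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Gram matrix G[i, j] = k(X1[i], X2[j]) under ``spec``."""
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    if X1.ndim != 2 or X2.ndim != 2:
        raise ValueError("inputs must be 2-D sample matrices")
    if X1.shape[1] != X2.shape[1]:
        raise ValueError(f"feature-count mismatch: {X1.shape[1]} vs {X2.shape[1]}")
    if spec.family == "linear":
        return _linear(X1, X2)
    if spec.family == "polynomial":
        return _polynomial(X1, X2, spec.c1, spec.c2, spec.c3)
    if spec.family == "gaussian":
        return _gaussian(X1, X2, spec.sigma2)
    if spec.family == "sigmoid":
        return np.tanh(spec.a * (X1 @ X2.T) + spec.c)
    # hybrid
    return (
        spec.m * _linear(X1, X2)
        + spec.n * _polynomial(X1, X2, spec.c1, spec.c2, spec.c3)
        + spec.q * _gaussian(X1, X2, spec.sigma2)
    )


def check_psd(G: np.ndarray, tolerance: float = 1e-8) -> tuple[bool, float]:
    """Mercer-validity guard: is the smallest eigenvalue ≥ −tolerance?

    Returns ``(is_psd, smallest_eigenvalue)``.  An indefinite Gram matrix
    (possible for the sigmoid family) raises no error — the flag is the
    caller's signal.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("Gram matrix must be square")
    if not np.allclose(G, G.T, atol=max(tolerance, 1e-8)):
        raise ValueError("Gram matrix is asymmetric beyond tolerance")
    w_min = float(np.linalg.eigvalsh((G + G.T) / 2.0)[0])
    return w_min >= -tolerance, w_min
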