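"""SVD of time-resolved data: decomposition, singular-value weighting, rank.

A delay×channel matrix D factorises as D = U·S·Vᵀ with the left singular
vectors U carrying the time-domain traces and the right singular vectors V the
spectral shapes.  The largest singular values carry the signal; fitting the
first few (optionally singular-value-weighted) left singular vectors is a
noise-reduced alternative to fitting the full matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["SVDResult", "svd_decompose", "weight_left_vectors", "significant_rank"]


@dataclass
class SVDResult:
    """U, S, V of a data matrix; vectors are columns, values non-increasing."""

    left_vectors: np.ndarray    # (m, r) time-domain
    singular_values: np.ndarray  # (r,)
    right_vectors: np.ndarray   # (n, r) spectral-domain

    @property
    def rank(self) -> int:
        return int(self.singular_values.size)

    def reconstruct(self) -> np.ndarray:
        return (self.left_vectors * self.singular_values) @ self.right_vectors.T


def svd_decompose(data) -> SVDResult:
    """Full (thin) SVD with a deterministic sign convention.

    The sign of each component pair is fixed by making the largest-magnitude
    element of the right singular vector positive — the sign itself carries no
    physical meaning.
    """
    values = np.asarray(data.values if hasattr(data, "values") else data, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("data contains non-finite entries")
    U, s, Vt = np.linalg.svd(values, full_matrices=False)
    V = Vt.T
    for j in range(s.size):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
            U[:, j] = -U[:, j]
    return SVDResult(U, s, V)


def weight_left_vectors(svd: SVDResult, n_keep: int) -> np.ndarray:
    """First ``n_keep`` left singular vectors scaled column-wise by their singular values."""
    if not 1 <= n_keep <= svd.rank:
        raise ValueError(f"n_keep must be in [1, {svd.rank}]")
    return svd.left_vectors[:, :n_keep] * svd.singular_values[:n_keep]


def significant_rank(svd: SVDResult, gap_factor: float = 10.0) -> int:
    """Number of singular values standing clearly above the noise floor.

    Returns the smallest r with s_r / s_{r+1} ≥ ``gap_factor`` whose tail
    s_{r+1}, s_{r+2}, … continues a flat/slow noise trend (no further gap of
    that size) — a gap inside the signal values does not qualify.  When no
    gap exists anywhere (e.g. pure white noise) the result is 0, with a
    warning: structureless spectra give no objective component count and the
    scree plot must be inspected by eye.
    """
    if not gap_factor > 1:
        raise ValueError("gap_factor must be > 1")
    s = svd.singular_values
    if s.size == 1:
        return 1 if s[0] > 0 else 0
    # Values at the numerical floor are indistinguishable: clamp before ratios
    # so junk-level fluctuations cannot masquerade as gaps.
    floor = np.finfo(float).eps * max(s[0], 1.0) if s.size else 0.0
    sc = np.maximum(s, floor)
    ratios = [sc[r] / sc[r + 1] for r in range(s.size - 1)]
    gaps = [r for r, q in enumerate(ratios) if q >= gap_factor]
    for r in gaps:
        if all(q < gap_factor for q in ratios[r + 1 :]):
            return r + 1
    warnings.warn("no singular-value gap found; rank undetermined (returning 0)")
    return 0
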