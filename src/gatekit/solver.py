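"""Spectral solution of the master equation.

For a generator Q the occupancy row vector obeys dP/dt = P Q.  Writing
the eigendecomposition Q = V L V^-1 gives the relaxation

    P(t) = P(0) sum_i A_i exp(lambda_i t),   A_i = V[:, i] V^-1[i, :],

and the equilibrium occupancy is the projection onto the (unique)
zero-eigenvalue mode, P(inf) = P(0) A_0.  All routines here use the
row-vector convention: occupancies left-multiply the propagator.

Complex eigenpairs, possible for schemes that violate detailed balance,
are kept throughout the algebra; results are cast to real only after the
imaginary residue is verified to be negligible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidArgumentError, NumericalFailureError, ReducibilityError
from .mechanism import MechanismSpec, RateMatrix

__all__ = [
    "SpectralDecomposition",
    "OccupancyVector",
    "spectral_decompose",
    "equilibrium",
    "occupancy_timecourse",
    "open_probability",
]

_ZERO_EIG_TOL = 1e-9
_IMAG_TOL = 1e-9
_RECON_TOL = 1e-8


@dataclass(frozen=True)
class OccupancyVector:
    """State probabilities at one time point (``time=inf`` for equilibrium)."""

    values: np.ndarray
    time: float = np.inf

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise InvalidArgumentError("occupancy must be a 1-D vector")
        if np.any(v < -1e-9) or np.any(v > 1 + 1e-9):
            raise InvalidArgumentError("occupancies must lie in [0, 1]")
        if abs(v.sum() - 1.0) > 1e-9:
            raise InvalidArgumentError("occupancies must sum to 1")
        object.__setattr__(self, "values", v)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


@dataclass(frozen=True)
class SpectralDecomposition:
    """Eigendecomposition of a generator with the zero mode identified."""

    eigenvalues: np.ndarray
    right_vectors: np.ndarray
    inverse_vectors: np.ndarray
    zero_index: int


def _as_matrix(Q: RateMatrix | np.ndarray) -> np.ndarray:
    return np.asarray(Q, dtype=float)


def spectral_decompose(Q: RateMatrix | np.ndarray) -> SpectralDecomposition:
    """Eigendecompose a generator and identify its stationary mode.

    Exactly one eigenvalue must be zero within
    ``1e-9 * max(1, max|lambda|)``; several near-zero eigenvalues mean
    the chain is reducible and a :class:`ReducibilityError` is raised.
    The decomposition is verified by reconstructing Q to a relative
    Frobenius error below 1e-8.
    """
    q = _as_matrix(Q)
    lam, vec = np.linalg.eig(q)
    try:
        vec_inv = np.linalg.inv(vec)
    except np.linalg.LinAlgError as exc:
        raise NumericalFailureError("eigenvector matrix is singular") from exc
    recon = vec @ np.diag(lam) @ vec_inv
    denom = max(np.linalg.norm(q), 1e-300)
    if np.linalg.norm(recon - q) / denom > _RECON_TOL:
        raise NumericalFailureError(
            "eigendecomposition does not reconstruct Q (defective matrix?)"
        )
    tol = _ZERO_EIG_TOL * max(1.0, float(np.abs(lam).max()))
    near_zero = np.flatnonzero(np.abs(lam) < tol)
    if near_zero.size == 0:
        raise NumericalFailureError("no zero eigenvalue found in generator spectrum")
    if near_zero.size > 1:
        raise ReducibilityError(
            f"{near_zero.size} near-zero eigenvalues: the chain is reducible"
        )
    return SpectralDecomposition(
        eigenvalues=lam,
        right_vectors=vec,
        inverse_vectors=vec_inv,
        zero_index=int(near_zero[0]),
    )


def _to_real(values: np.ndarray) -> np.ndarray:
    if np.abs(values.imag).max(initial=0.0) > _IMAG_TOL:
        raise NumericalFailureError(
            "imaginary residue above tolerance after spectral summation"
        )
    return values.real


def _clean_probability(p: np.ndarray, time: float) -> OccupancyVector:
    p = np.where((p < 0) & (p > -1e-9), 0.0, p)
    return OccupancyVector(values=p / p.sum(), time=time)


def equilibrium(
    Q: RateMatrix | np.ndarray, p0: OccupancyVector | Sequence[float] | None = None
) -> OccupancyVector:
    """Stationary occupancy via the rank-1 projector of the zero mode.

    The result is independent of the initial occupancy ``p0`` (any point
    on the simplex projects to the same stationary vector); ``p0``
    defaults to the uniform distribution.
    """
    q = _as_matrix(Q)
    if p0 is None:
        p0 = np.full(q.shape[0], 1.0 / q.shape[0])
    p0 = np.asarray(p0, dtype=float)
    if abs(p0.sum() - 1.0) > 1e-9:
        raise InvalidArgumentError("initial occupancy must sum to 1")
    dec = spectral_decompose(q)
    k = dec.zero_index
    projector = np.outer(dec.right_vectors[:, k], dec.inverse_vectors[k, :])
    p_inf = _to_real(p0 @ projector)
    return _clean_probability(p_inf, np.inf)


def occupancy_timecourse(
    Q: RateMatrix | np.ndarray,
    p0: OccupancyVector | Sequence[float],
    times: Sequence[float],
) -> list[OccupancyVector]:
    """Relaxation P(t) = P(0) V exp(L t) V^-1 at the requested times."""
    q = _as_matrix(Q)
    p0 = np.asarray(p0, dtype=float)
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise InvalidArgumentError("times must be >= 0")
    dec = spectral_decompose(q)
    coeff = p0 @ dec.right_vectors  # modal coordinates of P(0)
    out = []
    for t in times:
        p_t = _to_real((coeff * np.exp(dec.eigenvalues * t)) @ dec.inverse_vectors)
        out.append(_clean_probability(p_t, float(t)))
    return out


def open_probability(
    p: OccupancyVector | Sequence[float], spec: MechanismSpec
) -> float:
    """Probability mass on the conducting states of the mechanism."""
    values = np.asarray(p, dtype=float)
    return float(values[sorted(spec.conducting_states)].sum())
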