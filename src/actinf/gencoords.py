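"""Generalized coordinates of motion and generalized (block) precisions.

A variable in generalized coordinates is the vector of its value and
temporal derivatives ``(u, u', u'', ...)`` up to some embedding order
``n``.  Random fluctuations are assumed analytic, with a Gaussian
autocorrelation function of width ``s`` (the *roughness*, in time-bin
units); this induces a fixed covariance among derivative orders of a
unit-variance process, from which block precisions over generalized
states are built.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: log precisions are clamped to +/- this value before exponentiation
LOG_PRECISION_CAP = 32.0


@dataclass
class RoughnessModel:
    """Smoothness of random fluctuations.

    ``s`` is the width (standard deviation, in time bins) of the Gaussian
    autocorrelation function rho(h) = exp(-h^2 / (2 s^2)) assumed for all
    noise processes.
    """

    s: float = 0.5

    def __post_init__(self) -> None:
        if not self.s > 0:
            raise ValueError(f"roughness s must be positive, got {self.s}")


@dataclass
class GeneralizedVector:
    """A variable and its temporal derivatives to embedding order ``order``.

    ``values[c, k]`` holds the k-th temporal derivative of component c.
    """

    values: np.ndarray = field()

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ValueError("GeneralizedVector values must be 2-D (dim, order)")
        if self.values.shape[1] < 1:
            raise ValueError("embedding order must be >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("GeneralizedVector entries must be finite")

    @property
    def dim(self) -> int:
        return self.values.shape[0]

    @property
    def order(self) -> int:
        return self.values.shape[1]

    def flat(self) -> np.ndarray:
        """Flatten order-major: all components at order 0, then order 1, ..."""
        return self.values.T.ravel()

    @classmethod
    def from_flat(cls, flat: np.ndarray, dim: int, order: int) -> "GeneralizedVector":
        return cls(np.asarray(flat, float).reshape(order, dim).T)


def shift(values: np.ndarray) -> np.ndarray:
    """Apply the derivative operator D: move each order down one slot.

    Output order k equals input order k+1; the top order becomes zero.
    Accepts a (dim, order) array and returns one of the same shape.
    """
    values = np.atleast_2d(values)
    out = np.zeros_like(values, dtype=float)
    out[:, :-1] = values[:, 1:]
    return out


def shift_gv(gv: GeneralizedVector) -> GeneralizedVector:
    return GeneralizedVector(shift(gv.values))


def _gaussian_acf_derivatives(max_order: int, s: float) -> np.ndarray:
    """Derivatives rho^(k)(0) of rho(h) = exp(-h^2/(2 s^2)) at zero lag.

    rho^(2k)(0) = (-1)^k (2k-1)!! / s^(2k); odd derivatives vanish.
    """
    d = np.zeros(max_order + 1)
    d[0] = 1.0
    dfact = 1.0  # (2k-1)!!
    for k in range(1, max_order // 2 + 1):
        dfact *= 2 * k - 1
        d[2 * k] = (-1) ** k * dfact / s ** (2 * k)
    return d


def derivative_covariance(order: int, roughness: RoughnessModel) -> np.ndarray:
    """Covariance among derivative orders of a unit-variance smooth process.

    For a stationary process z with autocorrelation rho,
    ``Cov(z^(i), z^(j)) = (-1)^i rho^(i+j)(0)``; entries with odd ``i+j``
    vanish.  Raises if the result is not positive definite (an invalid
    roughness setting for this order).
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    rho = _gaussian_acf_derivatives(2 * (order - 1), roughness.s)
    V = np.empty((order, order))
    for i in range(order):
        for j in range(order):
            V[i, j] = (-1) ** i * rho[i + j]
    # symmetrize against float noise
    V = 0.5 * (V + V.T)
    if np.min(np.linalg.eigvalsh(V)) <= 0:
        raise ValueError(
            f"derivative covariance not positive definite for order={order}, "
            f"s={roughness.s}"
        )
    return V


_SINV_CACHE: dict[tuple[int, float], np.ndarray] = {}


def derivative_precision(order: int, roughness: RoughnessModel) -> np.ndarray:
    """Inverse of :func:`derivative_covariance` (cached)."""
    key = (order, roughness.s)
    if key not in _SINV_CACHE:
        V = derivative_covariance(order, roughness)
        _SINV_CACHE[key] = np.linalg.inv(V)
    return _SINV_CACHE[key]


def clamp_log_precision(pi) -> np.ndarray:
    return np.clip(np.asarray(pi, dtype=float), -LOG_PRECISION_CAP, LOG_PRECISION_CAP)


def generalized_precision(
    log_precision, order: int, roughness: RoughnessModel
) -> np.ndarray:
    """Block precision over ``dim x order`` generalized entries.

    ``log_precision`` may be a scalar or a per-component vector pi; the
    result is kron(inv(V), diag(exp(pi))) acting on order-major flattened
    generalized vectors.  For ``order == 1`` this is exactly diag(exp(pi)).
    """
    pi = clamp_log_precision(np.atleast_1d(log_precision))
    Sinv = derivative_precision(order, roughness)
    return np.kron(Sinv, np.diag(np.exp(pi)))


def generalized_log_det(log_precision, order: int, roughness: RoughnessModel) -> float:
    """log |Pi~| for the block precision of :func:`generalized_precision`."""
    pi = clamp_log_precision(np.atleast_1d(log_precision))
    dim = pi.size
    V = derivative_covariance(order, roughness)
    sign, logdetV = np.linalg.slogdet(V)
    return float(order * np.sum(pi) - dim * logdetV)


def smooth_noise(
    rng: np.random.Generator | int,
    length: int,
    log_precision: float,
    roughness: RoughnessModel,
    dim: int = 1,
) -> np.ndarray:
    """Seeded, temporally smooth Gaussian noise.

    Returns a ``(dim, length)`` array with marginal variance exp(-pi) and
    Gaussian autocorrelation of width ``s`` (the same kernel assumed by
    :func:`derivative_covariance`).  Synthesis: white noise convolved with
    a Gaussian kernel of width s/sqrt(2) (so the *autocorrelation* has
    width s), rescaled to the target variance.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pi = float(clamp_log_precision(log_precision))
    sd = np.exp(-pi / 2.0)
    if pi >= LOG_PRECISION_CAP:
        return np.zeros((dim, length))
    # synthesize on an upsampled grid so the kernel is well resolved even
    # for sub-bin smoothness, then decimate back to the bin grid
    up = max(1, int(np.ceil(4.0 / roughness.s)))
    sk = roughness.s * up / np.sqrt(2.0)
    half = max(1, int(np.ceil(4 * sk)))
    t = np.arange(-half, half + 1)
    kernel = np.exp(-(t**2) / (2 * sk**2))
    kernel /= np.sqrt(np.sum(kernel**2))  # unit output variance
    pad = kernel.size
    n_fine = length * up + 2 * pad
    white = rng.standard_normal((dim, n_fine))
    out = np.empty((dim, length))
    for c in range(dim):
        full = np.convolve(white[c], kernel, mode="same")
        out[c] = full[pad : pad + length * up : up]
    return sd * out
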