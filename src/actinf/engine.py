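"""Generic active-inference engine: generalized Bayesian filtering plus action.

The agent's generative model is a stack of levels

    v(i-1) = g(i)(x(i), v(i)) + noise,   x'(i) = f(i)(x(i), v(i)) + noise

with log precisions pi that may depend on the level's own states and
causes.  Perception integrates a generalized gradient descent on
variational free energy in generalized coordinates of motion,

    d(mu~)/dt = D mu~ - dF/d(mu~),

and action descends the same free energy through the true sensory
sensitivity to action,

    da/dt = -(ds~/da)' xi_v(1).

The descent correction is assembled from precision-weighted prediction
errors (the message-passing form), with Jacobians of the generalized
maps obtained by central finite differences so that the assembled flow
agrees with the finite-difference gradient of the scalar free energy --
including the precision-gradient and trace terms that appear when log
precisions are state dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.stats import norm as _norm

from .gencoords import (
    RoughnessModel,
    clamp_log_precision,
    derivative_precision,
    generalized_log_det,
    generalized_precision,
    shift,
    smooth_noise,
)

__all__ = [
    "LevelSpec",
    "HierarchicalModel",
    "GenerativeProcess",
    "PosteriorState",
    "PredictionErrors",
    "SimulationRecord",
    "PriorSchedule",
    "constant_prior",
    "DivergenceError",
    "free_energy_gradient",
    "compute_errors",
    "free_energy",
    "recognition_flow",
    "action_flow",
    "step",
    "run_closed_loop",
    "relax_posterior",
    "posterior_interval",
    "laplace_stddev",
]


class DivergenceError(RuntimeError):
    """Raised when the descent produces non-finite quantities."""

    def __init__(self, msg: str, time_bin: int | None = None):
        super().__init__(msg + ("" if time_bin is None else f" (time bin {time_bin})"))
        self.time_bin = time_bin


# --------------------------------------------------------------------------
# model specification
# --------------------------------------------------------------------------


@dataclass
class LevelSpec:
    """One level of the hierarchical generative model.

    ``output`` predicts the cause of the level below (sensations at the
    lowest level) and ``flow`` gives the motion of this level's hidden
    states.  ``log_precision_x`` weights the state error Dx~ - f~ of this
    level; ``log_precision_v`` weights the *output* error (the level
    below's cause, or the sensations, minus g~).  Either may be a constant
    (scalar / per-component vector) or a callable ``pi(x0, v0)`` of the
    level's own order-0 states and causes.
    """

    n_x: int
    n_v: int
    out_dim: int
    flow: Optional[Callable] = None  # f(x, v) -> dx/dt
    output: Optional[Callable] = None  # g(x, v) -> prediction of below
    log_precision_x: object = 0.0
    log_precision_v: object = 0.0
    # optional analytic Jacobians: fx, fv, gx, gv of shape (out, in)
    jac: dict = field(default_factory=dict)
    # optional analytic gradient of a state-dependent log precision:
    # dpi_x / dpi_v : (x0, v0) -> (group_dim, n_x + n_v) array
    dpi_x: Optional[Callable] = None
    dpi_v: Optional[Callable] = None

    def pi_x(self, x0, v0) -> np.ndarray:
        return self._pi(self.log_precision_x, self.n_x, x0, v0)

    def pi_v(self, x0, v0) -> np.ndarray:
        return self._pi(self.log_precision_v, self.out_dim, x0, v0)

    @staticmethod
    def _pi(spec, dim, x0, v0) -> np.ndarray:
        if callable(spec):
            val = np.atleast_1d(np.asarray(spec(x0, v0), float))
        else:
            val = np.atleast_1d(np.asarray(spec, float))
        if val.size == 1:
            val = np.full(dim, float(val[0]))
        return clamp_log_precision(val)


@dataclass
class PriorSchedule:
    """Top-level prior expectation eta(t) with its log precision."""

    value: Callable  # t -> (n_v_top,) array
    log_precision: float = 0.0
    derivative: Optional[Callable] = None  # t -> (n_v_top,) array

    def tilde(self, t: float, order: int, dim: int) -> np.ndarray:
        out = np.zeros((dim, order))
        out[:, 0] = np.atleast_1d(self.value(t))
        if order > 1 and self.derivative is not None:
            out[:, 1] = np.atleast_1d(self.derivative(t))
        return out


def constant_prior(value, log_precision: float = 0.0) -> PriorSchedule:
    arr = np.atleast_1d(np.asarray(value, float))
    return PriorSchedule(value=lambda t: arr, log_precision=log_precision)


@dataclass
class HierarchicalModel:
    """Ordered stack of levels (levels[0] is the sensory level)."""

    levels: Sequence[LevelSpec]
    n_orders: int = 4  # embedding order for hidden states
    d_orders: int = 2  # embedding order for causes and sensations
    roughness: RoughnessModel = field(default_factory=RoughnessModel)
    prior: Optional[PriorSchedule] = None

    def __post_init__(self) -> None:
        for i in range(1, len(self.levels)):
            if self.levels[i].out_dim != self.levels[i - 1].n_v:
                raise ValueError(
                    f"level {i} output dim {self.levels[i].out_dim} does not match "
                    f"level {i - 1} cause dim {self.levels[i - 1].n_v}"
                )
        if self.levels[-1].n_v > 0 and self.prior is None:
            raise ValueError("top level has causes but no prior schedule")

    # -- flat posterior layout: per level [x block (order-major), v block] --
    def block_slices(self) -> list[tuple[slice, slice]]:
        out, pos = [], 0
        for lv in self.levels:
            nx = lv.n_x * self.n_orders
            nv = lv.n_v * self.d_orders
            out.append((slice(pos, pos + nx), slice(pos + nx, pos + nx + nv)))
            pos += nx + nv
        return out

    @property
    def n_flat(self) -> int:
        return sum(
            lv.n_x * self.n_orders + lv.n_v * self.d_orders for lv in self.levels
        )

    def shift_operator(self) -> np.ndarray:
        """Block-diagonal derivative operator D on the flat posterior."""
        D = np.zeros((self.n_flat, self.n_flat))
        for (slx, slv), lv in zip(self.block_slices(), self.levels):
            if lv.n_x:
                D[slx, slx] = _shift_matrix(self.n_orders, lv.n_x)
            if lv.n_v:
                D[slv, slv] = _shift_matrix(self.d_orders, lv.n_v)
        return D

    def order0_labels(self) -> list[tuple[int, str, int]]:
        """(level, 'x'|'v', component) for each order-0 entry, in flat order."""
        out = []
        for i, lv in enumerate(self.levels):
            out += [(i, "x", c) for c in range(lv.n_x)]
            out += [(i, "v", c) for c in range(lv.n_v)]
        return out


def _shift_matrix(order: int, dim: int) -> np.ndarray:
    N = np.zeros((order, order))
    for k in range(order - 1):
        N[k, k + 1] = 1.0
    return np.kron(N, np.eye(dim))


# --------------------------------------------------------------------------
# posterior state and prediction errors
# --------------------------------------------------------------------------


@dataclass
class PosteriorState:
    """Posterior expectations mu~ for every level, as one flat vector."""

    model: HierarchicalModel
    flat: np.ndarray

    @classmethod
    def zeros(cls, model: HierarchicalModel) -> "PosteriorState":
        return cls(model, np.zeros(model.n_flat))

    def mu_x(self, level: int) -> np.ndarray:
        slx, _ = self.model.block_slices()[level]
        lv = self.model.levels[level]
        return self.flat[slx].reshape(self.model.n_orders, lv.n_x).T

    def mu_v(self, level: int) -> np.ndarray:
        _, slv = self.model.block_slices()[level]
        lv = self.model.levels[level]
        return self.flat[slv].reshape(self.model.d_orders, lv.n_v).T

    def set_mu_x(self, level: int, values: np.ndarray) -> None:
        slx, _ = self.model.block_slices()[level]
        self.flat[slx] = np.asarray(values, float).T.ravel()

    def set_mu_v(self, level: int, values: np.ndarray) -> None:
        _, slv = self.model.block_slices()[level]
        self.flat[slv] = np.asarray(values, float).T.ravel()


@dataclass
class ErrorGroup:
    """One error group: raw generalized error, its precision and weights."""

    level: int
    kind: str  # 'x', 'v' or 'eta'
    eps: np.ndarray  # flat, order-major
    pi: np.ndarray  # per-component log precision (order-0)
    order: int
    dim: int
    Pi: np.ndarray  # generalized block precision

    @property
    def xi(self) -> np.ndarray:
        return self.Pi @ self.eps

    def eps_matrix(self) -> np.ndarray:
        return self.eps.reshape(self.order, self.dim).T


@dataclass
class PredictionErrors:
    groups: list[ErrorGroup]

    def get(self, level: int, kind: str) -> ErrorGroup:
        for g in self.groups:
            if g.level == level and g.kind == kind:
                return g
        raise KeyError(f"no error group level={level} kind={kind}")

    def xi_v(self, level: int) -> np.ndarray:
        return self.get(level, "v").xi


# --------------------------------------------------------------------------
# generalized application of level functions
# --------------------------------------------------------------------------


def _level_jacobians(lv: LevelSpec, x0: np.ndarray, v0: np.ndarray):
    """Order-0 Jacobians of f and g (analytic if provided, else FD)."""

    def fd(func, out_dim, wrt):
        args = {"x": x0.copy(), "v": v0.copy()}
        base = args[wrt]
        J = np.zeros((out_dim, base.size))
        for j in range(base.size):
            h = 1e-6 * max(1.0, abs(base[j]))
            up, dn = base.copy(), base.copy()
            up[j] += h
            dn[j] -= h
            a1 = {**args, wrt: up}
            a0 = {**args, wrt: dn}
            J[:, j] = (
                np.atleast_1d(func(a1["x"], a1["v"]))
                - np.atleast_1d(func(a0["x"], a0["v"]))
            ) / (2 * h)
        return J

    jac = lv.jac
    fx = fv = gx = gv = None
    if lv.n_x and lv.flow is not None:
        fx = jac["fx"](x0, v0) if "fx" in jac else fd(lv.flow, lv.n_x, "x")
        fv = (
            (jac["fv"](x0, v0) if "fv" in jac else fd(lv.flow, lv.n_x, "v"))
            if lv.n_v
            else np.zeros((lv.n_x, 0))
        )
    if lv.output is not None:
        gx = (
            (jac["gx"](x0, v0) if "gx" in jac else fd(lv.output, lv.out_dim, "x"))
            if lv.n_x
            else np.zeros((lv.out_dim, 0))
        )
        gv = (
            (jac["gv"](x0, v0) if "gv" in jac else fd(lv.output, lv.out_dim, "v"))
            if lv.n_v
            else np.zeros((lv.out_dim, 0))
        )
    return fx, fv, gx, gv


def _gen_apply(lv: LevelSpec, mu_x: np.ndarray, mu_v: np.ndarray, n: int, d: int):
    """Generalized f~ (orders 0..n-1) and g~ (orders 0..d-1).

    Order 0 applies the nonlinear map; higher orders apply the chain rule
    at order 0 (first-order expansion, the usual generalized-filtering
    convention).
    """
    x0 = mu_x[:, 0] if lv.n_x else np.zeros(0)
    v0 = mu_v[:, 0] if lv.n_v else np.zeros(0)
    fx, fv, gx, gv = _level_jacobians(lv, x0, v0)

    f_tilde = None
    if lv.n_x and lv.flow is not None:
        f_tilde = np.zeros((lv.n_x, n))
        f_tilde[:, 0] = np.atleast_1d(lv.flow(x0, v0))
        for k in range(1, n):
            val = fx @ mu_x[:, k]
            if lv.n_v and k < d:
                val = val + fv @ mu_v[:, k]
            f_tilde[:, k] = val
    g_tilde = np.zeros((lv.out_dim, d))
    g_tilde[:, 0] = np.atleast_1d(lv.output(x0, v0))
    for k in range(1, d):
        val = np.zeros(lv.out_dim)
        if lv.n_x and k < n:
            val = val + gx @ mu_x[:, k]
        if lv.n_v:
            val = val + gv @ mu_v[:, k]
        g_tilde[:, k] = val
    return f_tilde, g_tilde


def _gen_map_flat(lv: LevelSpec, z: np.ndarray, n: int, d: int) -> np.ndarray:
    """Stacked [f~; g~] (order-major flat) as a function of the level's
    flattened (mu_x, mu_v)."""
    nx = lv.n_x * n
    mu_x = z[:nx].reshape(n, lv.n_x).T if lv.n_x else np.zeros((0, n))
    mu_v = z[nx:].reshape(d, lv.n_v).T if lv.n_v else np.zeros((0, d))
    f_t, g_t = _gen_apply(lv, mu_x, mu_v, n, d)
    parts = []
    if f_t is not None:
        parts.append(f_t.T.ravel())
    parts.append(g_t.T.ravel())
    return np.concatenate(parts)


def _gen_map_jacobian(lv: LevelSpec, z: np.ndarray, n: int, d: int) -> np.ndarray:
    """Jacobian of the stacked generalized map, by central differences.

    This is exact to FD accuracy, so it includes the curvature terms that
    arise because the order-0 Jacobians are themselves functions of the
    order-0 expectations.
    """
    base = _gen_map_flat(lv, z, n, d)
    J = np.zeros((base.size, z.size))
    for j in range(z.size):
        h = 1e-6 * max(1.0, abs(z[j]))
        up, dn = z.copy(), z.copy()
        up[j] += h
        dn[j] -= h
        J[:, j] = (_gen_map_flat(lv, up, n, d) - _gen_map_flat(lv, dn, n, d)) / (2 * h)
    return J


# --------------------------------------------------------------------------
# errors, free energy and its gradient
# --------------------------------------------------------------------------


def _build_groups(
    model: HierarchicalModel,
    posterior: PosteriorState,
    sensations: np.ndarray,
    t: float = 0.0,
) -> tuple[PredictionErrors, list]:
    """Assemble all error groups plus cached per-level generalized maps."""
    n, d, rough = model.n_orders, model.d_orders, model.roughness
    s = np.atleast_2d(np.asarray(sensations, float))
    if s.shape[0] != model.levels[0].out_dim:
        raise ValueError(
            f"sensations dim {s.shape[0]} != level-1 output dim "
            f"{model.levels[0].out_dim}"
        )
    if s.shape[1] < d:
        s = np.hstack([s, np.zeros((s.shape[0], d - s.shape[1]))])
    groups: list[ErrorGroup] = []
    cache = []
    for i, lv in enumerate(model.levels):
        mu_x, mu_v = posterior.mu_x(i), posterior.mu_v(i)
        x0 = mu_x[:, 0] if lv.n_x else np.zeros(0)
        v0 = mu_v[:, 0] if lv.n_v else np.zeros(0)
        f_t, g_t = _gen_apply(lv, mu_x, mu_v, n, d)
        cache.append((f_t, g_t))
        if lv.n_x and lv.flow is not None:
            eps_x = shift(mu_x) - f_t
            pi_x = lv.pi_x(x0, v0)
            groups.append(
                ErrorGroup(
                    i, "x", eps_x.T.ravel(), pi_x, n, lv.n_x,
                    generalized_precision(pi_x, n, rough),
                )
            )
        below = s[:, :d] if i == 0 else posterior.mu_v(i - 1)
        eps_v = below - g_t
        pi_v = lv.pi_v(x0, v0)
        groups.append(
            ErrorGroup(
                i, "v", eps_v.T.ravel(), pi_v, d, lv.out_dim,
                generalized_precision(pi_v, d, rough),
            )
        )
    top = model.levels[-1]
    if top.n_v and model.prior is not None:
        eta = model.prior.tilde(t, d, top.n_v)
        eps = posterior.mu_v(len(model.levels) - 1) - eta
        pi = np.broadcast_to(
            np.atleast_1d(np.asarray(model.prior.log_precision, float)),
            (top.n_v,),
        ).copy()
        groups.append(
            ErrorGroup(
                len(model.levels) - 1, "eta", eps.T.ravel(), pi, d, top.n_v,
                generalized_precision(pi, d, rough),
            )
        )
    return PredictionErrors(groups), cache


def compute_errors(
    model: HierarchicalModel,
    posterior: PosteriorState,
    sensations: np.ndarray,
    t: float = 0.0,
) -> PredictionErrors:
    """Raw and precision-weighted prediction errors for every level.

    ``sensations`` is a (n_s, d) array in generalized coordinates (extra
    orders are zero-padded).  The top level's cause error is taken against
    the prior schedule eta(t).
    """
    return _build_groups(model, posterior, sensations, t)[0]


def free_energy(
    model: HierarchicalModel,
    posterior: PosteriorState,
    sensations: np.ndarray,
    t: float = 0.0,
) -> float:
    """F = 1/2 sum over groups of (eps' Pi eps - log|Pi|).

    State-independent normalization constants are dropped; the -log|Pi|
    term is retained because it carries the state dependence of precision.
    """
    errors = compute_errors(model, posterior, sensations, t)
    F = 0.0
    for g in errors.groups:
        F += 0.5 * (
            g.eps @ g.Pi @ g.eps
            - generalized_log_det(g.pi, g.order, model.roughness)
        )
    if not np.isfinite(F):
        raise DivergenceError("free energy is not finite")
    return float(F)


def _pi_gradient(lv: LevelSpec, which: str, x0: np.ndarray, v0: np.ndarray):
    """d pi / d(x0, v0) for a state-dependent log precision, or None."""
    spec = lv.log_precision_x if which == "x" else lv.log_precision_v
    if not callable(spec):
        return None
    analytic = lv.dpi_x if which == "x" else lv.dpi_v
    if analytic is not None:
        return np.atleast_2d(np.asarray(analytic(x0, v0), float))
    dim = lv.n_x if which == "x" else lv.out_dim
    nin = x0.size + v0.size
    J = np.zeros((dim, nin))
    z = np.concatenate([x0, v0])
    for j in range(nin):
        h = 1e-6 * max(1.0, abs(z[j]))
        up, dn = z.copy(), z.copy()
        up[j] += h
        dn[j] -= h
        pu = lv._pi(spec, dim, up[: x0.size], up[x0.size :])
        pd = lv._pi(spec, dim, dn[: x0.size], dn[x0.size :])
        J[:, j] = (pu - pd) / (2 * h)
    return J


@dataclass
class _GradAux:
    """Curvature information produced alongside the gradient.

    ``hessian_gn`` is the Gauss-Newton approximation sum_g Je' Pi Je of
    the free-energy Hessian (used to build the local-linearization
    propagator); ``dgrad_ds`` maps perturbations of the flattened
    generalized sensations into gradient perturbations.
    """

    hessian_gn: np.ndarray
    dgrad_ds: np.ndarray
    jac_sensory: np.ndarray | None = None  # d(eps_v1)/d(mu~)


def _gradient_core(
    model: HierarchicalModel,
    posterior: PosteriorState,
    sensations: np.ndarray,
    t: float = 0.0,
    want_aux: bool = False,
):
    n, d, rough = model.n_orders, model.d_orders, model.roughness
    errors, _ = _build_groups(model, posterior, sensations, t)
    slices = model.block_slices()
    nf = model.n_flat
    grad = np.zeros(nf)
    n_s = model.levels[0].out_dim
    H = np.zeros((nf, nf)) if want_aux else None
    dgrad_ds = np.zeros((nf, n_s * d)) if want_aux else None
    jac_sensory = None

    # Jacobians of the stacked generalized maps, per level
    jac_maps = []
    for i, lv in enumerate(model.levels):
        slx, slv = slices[i]
        z = np.concatenate([posterior.flat[slx], posterior.flat[slv]])
        jac_maps.append(_gen_map_jacobian(lv, z, n, d))

    for g in errors.groups:
        lv = model.levels[g.level]
        slx, slv = slices[g.level]
        xi = g.xi
        # full Jacobian of this group's error w.r.t. the flat posterior
        Je = np.zeros((g.eps.size, nf))
        if g.kind == "eta":
            Je[:, slv] = np.eye(g.eps.size)
        else:
            J = jac_maps[g.level]
            nfx = lv.n_x * n if (lv.n_x and lv.flow is not None) else 0
            nin_x = lv.n_x * n
            if g.kind == "x":
                Je[:, slx] = _shift_matrix(n, lv.n_x)
                Jf = J[:nfx, :]
                Je[:, slx] -= Jf[:, :nin_x]
                if lv.n_v:
                    Je[:, slv] -= Jf[:, nin_x:]
            else:  # 'v'
                if g.level > 0:
                    _, slv_below = slices[g.level - 1]
                    Je[:, slv_below] = np.eye(g.eps.size)
                Jg = J[nfx:, :]
                Je[:, slx] -= Jg[:, :nin_x]
                if lv.n_v:
                    Je[:, slv] -= Jg[:, nin_x:]
        grad += Je.T @ xi
        if want_aux:
            PiJe = g.Pi @ Je
            H += Je.T @ PiJe
            if g.level == 0 and g.kind == "v":
                dgrad_ds += Je.T @ g.Pi
                jac_sensory = Je

        # state-dependent precision: quadratic and trace (log-det) terms
        if g.kind != "eta":
            x0 = posterior.mu_x(g.level)[:, 0] if lv.n_x else np.zeros(0)
            v0 = posterior.mu_v(g.level)[:, 0] if lv.n_v else np.zeros(0)
            dpi = _pi_gradient(lv, g.kind, x0, v0)
            if dpi is not None:
                Sinv = derivative_precision(g.order, rough)
                E = g.eps_matrix()  # (dim, order)
                q = np.einsum("co,op,cp->c", E, Sinv, E)
                w = 0.5 * (np.exp(g.pi) * q - g.order)
                contrib = dpi.T @ w  # (n_x + n_v,)
                grad[slx.start : slx.start + lv.n_x] += contrib[: lv.n_x]
                if lv.n_v:
                    grad[slv.start : slv.start + lv.n_v] += contrib[lv.n_x :]
    if want_aux:
        return grad, errors, _GradAux(H, dgrad_ds, jac_sensory)
    return grad, errors, None


def free_energy_gradient(
    model: HierarchicalModel,
    posterior: PosteriorState,
    sensations: np.ndarray,
    t: float = 0.0,
) -> np.ndarray:
    """dF/d(mu~), assembled from precision-weighted errors (Eq. 3 form)."""
    return _gradient_core(model, posterior, sensations, t)[0]


def recognition_flow(
    model: HierarchicalModel,
    posterior: PosteriorState,
    sensations: np.ndarray,
    t: float = 0.0,
    rate: float = 1.0,
) -> np.ndarray:
    """d(mu~)/dt = D mu~ - dF/d(mu~) (Eq. 1/3), on the flat posterior."""
    D = model.shift_operator()
    flow = D @ posterior.flat - rate * free_energy_gradient(
        model, posterior, sensations, t
    )
    if not np.all(np.isfinite(flow)):
        bad = [
            model.order0_labels()[min(j, len(model.order0_labels()) - 1)]
            for j in np.where(~np.isfinite(flow))[0][:1]
        ]
        raise DivergenceError(f"non-finite recognition flow near {bad}")
    return flow


# --------------------------------------------------------------------------
# generative process (the "real world") and action
# --------------------------------------------------------------------------


@dataclass
class GenerativeProcess:
    """True dynamics: flow/output also take action a and exogenous cause v(t)."""

    n_x: int
    n_s: int
    n_a: int = 0
    flow: Optional[Callable] = None  # f(x, v, a) -> dx/dt
    output: Optional[Callable] = None  # g(x, v, a) -> sensations (n_s,)
    cause: Callable = lambda t: np.zeros(0)
    n_v: int = 0
    noise_log_precision_x: float = 32.0
    noise_log_precision_s: float = 32.0
    roughness: RoughnessModel = field(default_factory=RoughnessModel)
    jac: dict = field(default_factory=dict)

    def cause_derivative(self, t: float, h: float = 1e-4) -> np.ndarray:
        if self.n_v == 0:
            return np.zeros(0)
        return (np.atleast_1d(self.cause(t + h)) - np.atleast_1d(self.cause(t - h))) / (
            2 * h
        )

    def _jac(self, name: str, func, out_dim, x, v, a):
        if name in self.jac:
            return self.jac[name](x, v, a)
        sizes = {"x": x, "v": v, "a": a}[name[1]]
        J = np.zeros((out_dim, np.size(sizes)))
        args = {"x": np.asarray(x, float), "v": np.asarray(v, float),
                "a": np.atleast_1d(np.asarray(a, float))}
        base = args[name[1]]
        for j in range(base.size):
            h = 1e-6 * max(1.0, abs(base[j]))
            up, dn = base.copy(), base.copy()
            up[j] += h
            dn[j] -= h
            hi = {**args, name[1]: up}
            lo = {**args, name[1]: dn}
            J[:, j] = (
                np.atleast_1d(func(hi["x"], hi["v"], hi["a"]))
                - np.atleast_1d(func(lo["x"], lo["v"], lo["a"]))
            ) / (2 * h)
        return J

    def sensations_tilde(
        self,
        x: np.ndarray,
        v: np.ndarray,
        a: np.ndarray,
        d: int,
        noise_s: np.ndarray | None = None,
        noise_x: np.ndarray | None = None,
        vdot: np.ndarray | None = None,
    ) -> np.ndarray:
        """Generalized sensations (n_s, d): value plus chain-rule derivatives.

        ``noise_s`` may carry derivative columns (n_s, k); ``noise_x`` is the
        order-0 state fluctuation entering the flow.
        """
        x = np.asarray(x, float)
        v = np.atleast_1d(np.asarray(v, float))
        a = np.atleast_1d(np.asarray(a, float))
        s = np.zeros((self.n_s, d))
        s[:, 0] = np.atleast_1d(self.output(x, v, a))
        if d > 1 and self.n_x:
            xdot = np.atleast_1d(self.flow(x, v, a))
            if noise_x is not None:
                xdot = xdot + noise_x
            Gx = self._jac("gx", self.output, self.n_s, x, v, a)
            Fx = self._jac("fx", self.flow, self.n_x, x, v, a)
            cur = xdot
            for k in range(1, d):
                s[:, k] = Gx @ cur
                cur = Fx @ cur
            if self.n_v:
                Gv = self._jac("gv", self.output, self.n_s, x, v, a)
                s[:, 1] += Gv @ (vdot if vdot is not None else np.zeros(self.n_v))
        if noise_s is not None:
            ns = np.atleast_2d(noise_s)
            k = min(d, ns.shape[1])
            s[:, :k] += ns[:, :k]
        return s

    def sensory_state_sensitivity(
        self, x: np.ndarray, v: np.ndarray, a: np.ndarray, d: int
    ) -> np.ndarray:
        """ds~/dx (first-order chain), shape (n_s * d, n_x)."""
        if self.n_x == 0:
            return np.zeros((self.n_s * d, 0))
        Gx = self._jac("gx", self.output, self.n_s, x, v, a)
        Fx = self._jac("fx", self.flow, self.n_x, x, v, a)
        out = np.zeros((d, self.n_s, self.n_x))
        cur = Gx
        for k in range(d):
            out[k] = cur
            cur = cur @ Fx
        return out.reshape(d * self.n_s, self.n_x)

    def sensory_action_sensitivity(
        self, x: np.ndarray, v: np.ndarray, a: np.ndarray, d: int
    ) -> np.ndarray:
        """ds~/da, shape (n_s * d, n_a), order-major rows."""
        if self.n_a == 0:
            return np.zeros((self.n_s * d, 0))
        Ga = self._jac("ga", self.output, self.n_s, x, v, a)
        out = np.zeros((d, self.n_s, self.n_a))
        out[0] = Ga
        if d > 1 and self.n_x:
            Gx = self._jac("gx", self.output, self.n_s, x, v, a)
            Fx = self._jac("fx", self.flow, self.n_x, x, v, a)
            Fa = self._jac("fa", self.flow, self.n_x, x, v, a)
            cur = Fa
            for k in range(1, d):
                out[k] = Gx @ cur
                cur = Fx @ cur
        return out.reshape(d * self.n_s, self.n_a)


def action_flow(
    process: GenerativeProcess,
    errors: PredictionErrors,
    x: np.ndarray,
    v: np.ndarray,
    a: np.ndarray,
    d: int,
    rate: float = 1.0,
    reflex_precision: np.ndarray | None = None,
) -> np.ndarray:
    """da/dt = -(ds~/da)' xi_v(1): the classical reflex arc.

    By default the sensory errors are weighted by the model's (possibly
    state-dependent) sensory precision, the exact free-energy gradient.
    With ``reflex_precision`` given, the raw proprioceptive errors are
    weighted by that fixed block precision instead -- a constant spinal
    reflex gain, decoupled from descending precision control.
    """
    if process.n_a == 0:
        return np.zeros(0)
    dsda = process.sensory_action_sensitivity(x, v, a, d)
    g = errors.get(0, "v")
    xi = g.xi if reflex_precision is None else reflex_precision @ g.eps
    return -rate * dsda.T @ xi


# --------------------------------------------------------------------------
# integration
# --------------------------------------------------------------------------


def _ll_advance(u: np.ndarray, f: np.ndarray, J: np.ndarray, dt: float) -> np.ndarray:
    """Local-linearization update Delta u = (expm(J dt) - I) J^+ f, computed
    through the augmented matrix exponential (robust to singular J)."""
    nu = u.size
    M = np.zeros((nu + 1, nu + 1))
    M[:nu, :nu] = J * dt
    M[:nu, nu] = f * dt
    E = expm(M)
    return u + E[:nu, nu]


def _ll_step(flow_fn, u: np.ndarray, dt: float, J: np.ndarray) -> np.ndarray:
    return _ll_advance(u, flow_fn(u), J, dt)


def _flow_jacobian(flow_fn, u: np.ndarray, f0: np.ndarray | None = None) -> np.ndarray:
    if f0 is None:
        f0 = flow_fn(u)
    J = np.zeros((u.size, u.size))
    for j in range(u.size):
        h = 1e-4 * max(1.0, abs(u[j]))
        up = u.copy()
        up[j] += h
        J[:, j] = (flow_fn(up) - f0) / h
    return J


def step(
    flow_fn: Callable,
    u: np.ndarray,
    dt: float,
    n_sub: int = 1,
    max_retries: int = 8,
) -> np.ndarray:
    """Advance a combined flow by one bin with local linearization.

    The Jacobian is refreshed at each sub-step; on non-finite output the
    sub-step is halved up to ``max_retries`` times.
    """
    h = dt / n_sub
    cur = u
    remaining = dt
    retries = 0
    while remaining > 1e-12:
        hh = min(h, remaining)
        J = _flow_jacobian(flow_fn, cur)
        nxt = _ll_step(flow_fn, cur, hh, J)
        if not np.all(np.isfinite(nxt)):
            retries += 1
            if retries > max_retries:
                raise DivergenceError("integration step failed to converge")
            h = hh / 2.0
            continue
        cur = nxt
        remaining -= hh
    return cur


# --------------------------------------------------------------------------
# closed loop
# --------------------------------------------------------------------------


@dataclass
class SimulationRecord:
    """Aligned per-bin series from a closed-loop run."""

    model: HierarchicalModel
    time: np.ndarray  # bin index * dt
    sensations: np.ndarray  # (T, n_s) order-0 sensory input
    true_states: np.ndarray  # (T, n_x_process)
    true_cause: np.ndarray  # (T, n_v_process)
    posterior: np.ndarray  # (T, n_flat)
    action: np.ndarray  # (T, n_a)
    free_energy: np.ndarray  # (T,)
    xi: dict  # (level, kind) -> (T, dim*order)
    sigma0: Optional[np.ndarray] = None  # (T, n order-0 vars) Laplace std
    metadata: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return self.time.size

    def posterior_at(self, t_index: int) -> PosteriorState:
        return PosteriorState(self.model, self.posterior[t_index].copy())

    def mu_x0(self, level: int, component: int = 0) -> np.ndarray:
        """Order-0 posterior expectation series for one hidden state."""
        slx, _ = self.model.block_slices()[level]
        return self.posterior[:, slx.start + component]

    def mu_v0(self, level: int, component: int = 0) -> np.ndarray:
        _, slv = self.model.block_slices()[level]
        return self.posterior[:, slv.start + component]

    def sigma0_for(self, level: int, kind: str, component: int = 0) -> np.ndarray:
        if self.sigma0 is None:
            raise ValueError("run was recorded without Laplace covariance")
        labels = self.model.order0_labels()
        idx = labels.index((level, kind, component))
        return self.sigma0[:, idx]

    def to_frame(self):
        """Long-format table: one row per bin per recorded variable."""
        import pandas as pd

        rows = []
        labels = self.model.order0_labels()
        for name, arr in [("sensation", self.sensations),
                          ("true_state", self.true_states),
                          ("true_cause", self.true_cause),
                          ("action", self.action)]:
            for c in range(arr.shape[1]):
                rows.append(
                    pd.DataFrame(
                        {"time": self.time, "variable": f"{name}[{c}]",
                         "value": arr[:, c]}
                    )
                )
        for j, (lvl, kind, comp) in enumerate(labels):
            col = [i for i, lab in enumerate(labels) if lab == (lvl, kind, comp)][0]
            series = (
                self.mu_x0(lvl, comp) if kind == "x" else self.mu_v0(lvl, comp)
            )
            rows.append(
                pd.DataFrame(
                    {"time": self.time,
                     "variable": f"mu_{kind}[{lvl + 1},{comp}]",
                     "value": series}
                )
            )
            if self.sigma0 is not None:
                rows.append(
                    pd.DataFrame(
                        {"time": self.time,
                         "variable": f"sigma_{kind}[{lvl + 1},{comp}]",
                         "value": self.sigma0[:, col]}
                    )
                )
        for (lvl, kind), arr in self.xi.items():
            for c in range(arr.shape[1]):
                rows.append(
                    pd.DataFrame(
                        {"time": self.time,
                         "variable": f"xi_{kind}[{lvl + 1},{c}]",
                         "value": arr[:, c]}
                    )
                )
        rows.append(
            pd.DataFrame(
                {"time": self.time, "variable": "free_energy",
                 "value": self.free_energy}
            )
        )
        return pd.concat(rows, ignore_index=True)


def laplace_stddev(
    model: HierarchicalModel,
    posterior: PosteriorState,
    sensations: np.ndarray,
    t: float = 0.0,
    h: float = 1e-4,
) -> np.ndarray:
    """Posterior std of order-0 variables from the curvature of F (Laplace).

    The Hessian of F at the current expectations is computed by finite
    differences of the assembled gradient; its pseudo-inverse gives the
    Laplace covariance, and the marginal order-0 standard deviations are
    returned in flat-label order.
    """
    nf = model.n_flat
    H = np.zeros((nf, nf))
    base = posterior.flat.copy()
    for j in range(nf):
        hj = h * max(1.0, abs(base[j]))
        up = PosteriorState(model, base.copy())
        dn = PosteriorState(model, base.copy())
        up.flat[j] += hj
        dn.flat[j] -= hj
        H[:, j] = (
            free_energy_gradient(model, up, sensations, t)
            - free_energy_gradient(model, dn, sensations, t)
        ) / (2 * hj)
    H = 0.5 * (H + H.T)
    cov = np.linalg.pinv(H, rcond=1e-12, hermitian=True)
    var = np.clip(np.diag(cov), 0.0, None)
    idx = []
    pos = 0
    for lv in model.levels:
        idx += list(range(pos, pos + lv.n_x))  # order-0 states
        pos += lv.n_x * model.n_orders
        idx += list(range(pos, pos + lv.n_v))  # order-0 causes
        pos += lv.n_v * model.d_orders
    return np.sqrt(var[idx])


def posterior_interval(
    record: SimulationRecord,
    level: int,
    kind: str,
    component: int,
    coverage: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided credible band mu +/- z(coverage) sigma from the Laplace
    covariance; z(0.9) = 1.6449."""
    if not 0 <= coverage < 1:
        raise ValueError("coverage must be in [0, 1)")
    z = _norm.ppf(0.5 + coverage / 2.0)
    sigma = record.sigma0_for(level, kind, component)
    mu = (
        record.mu_x0(level, component)
        if kind == "x"
        else record.mu_v0(level, component)
    )
    return mu - z * sigma, mu + z * sigma


def relax_posterior(
    model: HierarchicalModel,
    sensations: np.ndarray,
    mu0: np.ndarray | None = None,
    t: float = 0.0,
    n_iter: int = 64,
    dt: float = 1.0,
    rate: float = 1.0,
) -> PosteriorState:
    """Integrate recognition dynamics to (near) fixed point under frozen
    sensations.  Used for static models and posterior initialization."""
    mu = np.zeros(model.n_flat) if mu0 is None else np.asarray(mu0, float).copy()

    def flow(u):
        return recognition_flow(model, PosteriorState(model, u), sensations, t, rate)

    for _ in range(n_iter):
        mu = step(flow, mu, dt)
    return PosteriorState(model, mu)


def run_closed_loop(
    process: GenerativeProcess,
    model: HierarchicalModel,
    duration: int,
    rng_seed: int = 0,
    dt: float = 1.0,
    rate: float = 1.0,
    action_rate: float = 1.0,
    n_sub: int = 2,
    mu0: np.ndarray | None = None,
    x0: np.ndarray | None = None,
    a0: np.ndarray | None = None,
    store_covariance: bool = False,
    action_schedule: Optional[Callable] = None,
    reflex_log_precision: float | None = None,
    metadata: dict | None = None,
) -> SimulationRecord:
    """Integrate the coupled perception-action loop for ``duration`` bins.

    The combined state (true process states, posterior expectations,
    action) is advanced bin by bin with local linearization; sensations
    are generated by the process with temporally smooth noise and embedded
    in generalized coordinates.  With ``action_schedule`` given, action
    follows that open-loop schedule instead of the reflex-arc dynamics
    (used for plant characterization); with ``n_a = 0`` the run is
    perception only.

    Deterministic for a fixed ``rng_seed``.
    """
    if duration < 1:
        raise ValueError("duration must be >= 1")
    d = model.d_orders
    ss = np.random.SeedSequence(rng_seed)
    seed_x, seed_s = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    w_x = smooth_noise(
        seed_x, duration + 1, process.noise_log_precision_x, process.roughness,
        dim=max(process.n_x, 1),
    )[: process.n_x]
    w_s = smooth_noise(
        seed_s, duration + 1, process.noise_log_precision_s, process.roughness,
        dim=process.n_s,
    )
    # derivative stack of the sensory noise, orders 0..d-1
    w_s_stack = [w_s]
    for _ in range(d - 1):
        w_s_stack.append(
            np.gradient(w_s_stack[-1], dt, axis=1)
            if duration > 1
            else np.zeros_like(w_s)
        )
    w_s_stack = np.stack(w_s_stack, axis=-1)  # (n_s, T+1, d)

    n_xp, n_a = process.n_x, process.n_a
    nf = model.n_flat
    x = np.zeros(n_xp) if x0 is None else np.asarray(x0, float).copy()
    mu = np.zeros(nf) if mu0 is None else np.asarray(mu0, float).copy()
    a = np.zeros(n_a) if a0 is None else np.atleast_1d(np.asarray(a0, float)).copy()
    active = n_a > 0 and action_schedule is None

    T = duration
    rec_s = np.zeros((T, process.n_s))
    rec_x = np.zeros((T, n_xp))
    rec_v = np.zeros((T, process.n_v))
    rec_mu = np.zeros((T, nf))
    rec_a = np.zeros((T, n_a))
    rec_F = np.zeros(T)
    rec_sigma = np.zeros((T, len(model.order0_labels()))) if store_covariance else None
    probe = compute_errors(model, PosteriorState(model, mu),
                           np.zeros((model.levels[0].out_dim, d)))
    rec_xi = {
        (g.level, g.kind): np.zeros((T, g.dim * g.order)) for g in probe.groups
    }

    D = model.shift_operator()
    Pi_reflex = None
    if reflex_log_precision is not None:
        Pi_reflex = generalized_precision(
            np.full(process.n_s, float(reflex_log_precision)), d, model.roughness
        )

    for t_i in range(T):
        t_time = t_i * dt
        v = np.atleast_1d(process.cause(t_time)) if process.n_v else np.zeros(0)
        vdot = process.cause_derivative(t_time) if process.n_v else np.zeros(0)
        ns = w_s_stack[:, t_i, :]
        nx_noise = w_x[:, t_i] if n_xp else None
        if action_schedule is not None:
            a = np.atleast_1d(np.asarray(action_schedule(t_time), float))

        n_comb = n_xp + nf + (n_a if active else 0)

        def flow_and_jac(u, t_time=t_time, v=v, vdot=vdot, ns=ns,
                        nx_noise=nx_noise):
            """Combined flow and its (Gauss-Newton) Jacobian."""
            xp = u[:n_xp]
            mu_f = u[n_xp : n_xp + nf]
            aa = u[n_xp + nf :] if active else a
            s_t = process.sensations_tilde(
                xp, v, aa, d, noise_s=ns, noise_x=nx_noise, vdot=vdot
            )
            post = PosteriorState(model, mu_f)
            grad, errs, aux = _gradient_core(model, post, s_t, t_time, True)
            mu_dot = D @ mu_f - rate * grad
            flow_parts, J = [], np.zeros((n_comb, n_comb))
            sl_x = slice(0, n_xp)
            sl_m = slice(n_xp, n_xp + nf)
            sl_a = slice(n_xp + nf, n_comb)
            if n_xp:
                xdot = np.atleast_1d(process.flow(xp, v, aa))
                if nx_noise is not None:
                    xdot = xdot + nx_noise
                flow_parts.append(xdot)
                J[sl_x, sl_x] = process._jac("fx", process.flow, n_xp, xp, v, aa)
                dsdx = process.sensory_state_sensitivity(xp, v, aa, d)
                J[sl_m, sl_x] = -rate * aux.dgrad_ds @ dsdx
            flow_parts.append(mu_dot)
            J[sl_m, sl_m] = D - rate * aux.hessian_gn
            if n_a and active:
                dsda = process.sensory_action_sensitivity(xp, v, aa, d)
                g_s = errs.get(0, "v")
                Pi_a = g_s.Pi if Pi_reflex is None else Pi_reflex
                xi1 = Pi_a @ g_s.eps
                flow_parts.append(-action_rate * dsda.T @ xi1)
                J[sl_x, sl_a] = process._jac("fa", process.flow, n_xp, xp, v, aa)
                J[sl_m, sl_a] = -rate * aux.dgrad_ds @ dsda
                # d(adot)/d(mu, x, a) with dsda held locally constant
                J[sl_a, sl_m] = -action_rate * dsda.T @ Pi_a @ aux.jac_sensory
                J[sl_a, sl_x] = (
                    -action_rate
                    * dsda.T
                    @ Pi_a
                    @ (dsdx if n_xp else np.zeros((dsda.shape[0], 0)))
                )
                J[sl_a, sl_a] = -action_rate * dsda.T @ Pi_a @ dsda
            return np.concatenate(flow_parts), J

        rec_v[t_i] = v

        u = np.concatenate([x, mu] + ([a] if active else []))
        remaining, h, retries = dt, dt / n_sub, 0
        while remaining > 1e-12:
            hh = min(h, remaining)
            f_u, J_u = flow_and_jac(u)
            nxt = _ll_advance(u, f_u, J_u, hh)
            if not np.all(np.isfinite(nxt)):
                retries += 1
                if retries > 10:
                    raise DivergenceError(
                        "integration step failed to converge", time_bin=t_i
                    )
                h = hh / 2.0
                continue
            u = nxt
            remaining -= hh
        x = u[:n_xp]
        mu = u[n_xp : n_xp + nf]
        if active:
            a = u[n_xp + nf :]

        # one contemporaneous snapshot per bin: end-of-bin true states,
        # action, sensations and the posterior that has assimilated them
        s_now = process.sensations_tilde(
            x, v, a, d, noise_s=ns, noise_x=nx_noise, vdot=vdot
        )
        rec_s[t_i] = s_now[:, 0]
        rec_x[t_i] = x
        rec_a[t_i] = a
        post_now = PosteriorState(model, mu)
        errs_now = _build_groups(model, post_now, s_now, t_time)[0]
        rec_mu[t_i] = mu
        for g in errs_now.groups:
            key = (g.level, g.kind)
            if key in rec_xi:
                rec_xi[key][t_i] = g.xi
        F = 0.0
        for g in errs_now.groups:
            F += 0.5 * (
                g.eps @ g.Pi @ g.eps
                - generalized_log_det(g.pi, g.order, model.roughness)
            )
        if not np.isfinite(F):
            raise DivergenceError("free energy diverged", time_bin=t_i)
        rec_F[t_i] = F
        if store_covariance:
            rec_sigma[t_i] = laplace_stddev(model, post_now, s_now, t_time)

    meta = {"seed": rng_seed, "dt": dt, "duration": duration, "rate": rate,
            "n_orders": model.n_orders, "d_orders": model.d_orders,
            "reflex_log_precision": reflex_log_precision}
    meta.update(metadata or {})
    return SimulationRecord(
        model=model, time=np.arange(T) * dt, sensations=rec_s, true_states=rec_x,
        true_cause=rec_v, posterior=rec_mu, action=rec_a, free_energy=rec_F,
        xi=rec_xi, sigma0=rec_sigma, metadata=meta,
    )
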