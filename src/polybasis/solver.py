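"""Primal-dual solvers for the constrained basis-region reconstruction.

Two closely related algorithms are implemented:

* ``pd`` -- a diagonally preconditioned Chambolle-Pock-type primal-dual
  algorithm for the CONVEXIFIED program, in which the linearization point
  (hence the Jacobian H) and the nonlinearity offset are held fixed;
* ``dncpd`` -- the dynamic non-convex variant that, after every primal
  update, relinearizes the data model at the new iterate: it recomputes the
  nonlinearity residual Delta g and the effective weights of H, and
  refreshes the data-dual step sizes Sigma_u and the primal steps T from the
  new |H| row/column sums.  All other dual step sizes stay those computed at
  the zero expansion point.

The optimization program: minimize 1/2 || (g - Delta g) - H b' ||^2 subject
to TV(f'_m1) <= gamma_m1, TV(f'_m2) <= gamma_m2, per-pixel volume
conservation in the designated two-material regions, and b' >= 0.

Diagonal preconditioning follows the absolute row/column sums of the stacked
constraint operator K = [H; a1 grad U_m1; a2 grad U_m2; nu I; {b_lc V_lc}]
with a balance parameter rho_pc: dual steps sigma = rho_pc / (|K| 1), primal
steps tau = 1 / (rho_pc |K^T| 1); rows/columns with zero sums get zero steps.
For the gradient-domain duals the per-pixel step is rho_pc divided by the
SUM of the two component-row sums, shared by both components, so that the
l1-ball projection of the per-pixel gradient magnitudes is well defined;
this is never larger than the per-component rule, so the preconditioner
condition still holds.

With a monochromatic spectrum the data model is exactly linear, Delta g
vanishes identically, and ``dncpd`` reproduces ``pd`` iterate for iterate.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward_model import PolyForwardModel
from .geometry import operator_norm
from .regions import assemble_basis_images, compute_vmi, vc_residual
from .tv import grad, grad_adjoint, grad_magnitude, grad_abs_col_sums, isotropic_tv

__all__ = [
    "SolverConfig",
    "PreconditionerSet",
    "SolverState",
    "MetricsRecord",
    "pol1b",
    "neg",
    "init_scaling",
    "init_state",
    "tv_dual_step",
    "iterate",
    "convergence_metrics",
    "solve",
]

_EPS = 1e-30

DEFAULT_TOLERANCES = {
    "data": 1e-6,
    "tv1": 1e-6,
    "tv2": 1e-6,
    "vc": 1e-6,
    "nonneg": 1e-6,
    "primal_change": 1e-6,
}


@dataclass
class SolverConfig:
    """Solver settings.

    ``rho_pc`` is the preconditioning balance parameter (dimensionless,
    distinct from the material densities); ``m1``/``m2`` are energy-bin
    indices of the two TV-constrained VMIs; ``tolerances`` lists the enabled
    convergence metrics and their thresholds -- iteration stops when every
    enabled metric is below its threshold, or at ``max_iters``.
    """

    gamma_m1: float
    gamma_m2: float
    m1: int
    m2: int
    algorithm: str = "dncpd"
    rho_pc: float = 1.0
    max_iters: int = 5000
    tolerances: dict = field(default_factory=lambda: dict(DEFAULT_TOLERANCES))
    norm_iters: int = 100
    norm_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("pd", "dncpd"):
            raise ValueError("algorithm must be 'pd' or 'dncpd'")
        if self.gamma_m1 < 0 or self.gamma_m2 < 0:
            raise ValueError("TV bounds must be nonnegative")
        if self.rho_pc <= 0:
            raise ValueError("rho_pc must be positive")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")


@dataclass
class PreconditionerSet:
    """Balancing scalars and diagonal step arrays of the stacked operator."""

    nu: float
    alpha1: float
    alpha2: float
    beta: dict  # lc -> scalar
    norm_H0: float
    sigma_u: np.ndarray          # (J,)
    sigma_v: np.ndarray          # (ny, nx) per-pixel, shared by components
    sigma_w: np.ndarray
    sigma_p: np.ndarray          # (N_b,)
    sigma_q: dict                # lc -> (I_lc,)
    tau: np.ndarray              # (N_b,)
    static_colsums: np.ndarray   # (N_b,) non-H part of |K^T| 1


@dataclass
class SolverState:
    """Mutable per-iteration state of the PD/dNCPD loop."""

    n: int
    b: np.ndarray
    b_prev: np.ndarray
    btilde: np.ndarray
    t_b: np.ndarray         # path lengths of b (J x K)
    t_btilde: np.ndarray
    u: np.ndarray
    v: np.ndarray           # (2, ny, nx)
    w: np.ndarray
    p: np.ndarray
    q: dict                 # lc -> (I_lc,)
    dg: np.ndarray
    weights: np.ndarray     # current effective weights of H (J x K)
    sigma_u: np.ndarray
    tau: np.ndarray


@dataclass
class MetricsRecord:
    """Per-iteration convergence metrics (all nonnegative)."""

    n: int
    data: float
    tv1: float
    tv2: float
    vc: dict
    nonneg: float
    primal_change: float
    nrmse: float | None = None

    def max_vc(self) -> float:
        return max(self.vc.values()) if self.vc else 0.0

    def enabled_values(self, names) -> dict:
        vals = {
            "data": self.data,
            "tv1": self.tv1,
            "tv2": self.tv2,
            "vc": self.max_vc(),
            "nonneg": self.nonneg,
            "primal_change": self.primal_change,
        }
        return {k: vals[k] for k in names if k in vals}


# ---------------------------------------------------------------------------
# prox operators

def pol1b(x: np.ndarray, r: float) -> np.ndarray:
    """Euclidean projection of a nonnegative vector onto {y >= 0, sum y <= r}.

    Returns ``x`` unchanged when it is already inside the ball; otherwise the
    sort-and-threshold simplex projection (ties resolved by the cumulative-sum
    rule).
    """
    x = np.asarray(x, dtype=float)
    if r < 0:
        raise ValueError("radius must be nonnegative")
    if np.any(x < 0):
        raise ValueError("pol1b expects a nonnegative input")
    if r == 0:
        return np.zeros_like(x)
    if x.sum() <= r:
        return x.copy()
    u = np.sort(x)[::-1]
    css = np.cumsum(u)
    idx = np.arange(1, x.size + 1)
    cond = u - (css - r) / idx > 0
    if not cond.any():  # only reachable through roundoff at vanishing radius
        return np.zeros_like(x)
    k = idx[cond][-1]
    theta = (css[k - 1] - r) / k
    return np.maximum(x - theta, 0.0)


def neg(x: np.ndarray) -> np.ndarray:
    """Elementwise min(x, 0): projection onto the nonpositive orthant."""
    return np.minimum(x, 0.0)


def _clip_threshold(a: np.ndarray, w: np.ndarray, r: float) -> float:
    """Threshold t >= 0 solving sum_i w_i * max(a_i - t, 0) = r.

    ``a`` are nonnegative magnitudes, ``w`` positive weights.  Returns 0 when
    sum w_i a_i <= r (the constraint is slack).  Piecewise-linear root found
    by the sort-and-cumulate rule; for uniform weights this reduces to the
    simplex-projection threshold of :func:`pol1b`.
    """
    if a.size == 0 or np.dot(w, a) <= r:
        return 0.0
    order = np.argsort(a)[::-1]
    a_s = a[order]
    w_s = w[order]
    S = np.cumsum(a_s * w_s)
    W = np.cumsum(w_s)
    t_cand = (S - r) / W
    k = np.nonzero(a_s - t_cand > 0)[0][-1]
    return float(max(t_cand[k], 0.0))


def tv_dual_step(
    v: np.ndarray,
    d: np.ndarray,
    sigma: np.ndarray,
    alpha: float,
    gamma: float,
) -> np.ndarray:
    """One gradient-domain (TV-constraint) dual update.

    ``d`` is the gradient field of the extrapolated VMI, ``sigma`` the
    per-pixel dual step (shared by both components).  The step evaluates the
    prox (in the Sigma-weighted metric) of the conjugate of the TV-ball
    indicator: the ascent v' = v + Sigma alpha d followed by clipping the
    per-pixel gradient magnitudes |v'| to a water-filling threshold t with
    sum_i (|v'_i| - t)_+ / sigma_i = alpha * gamma.  Via Moreau decomposition
    this equals v' - Sigma z* with z* the Sigma^-1-metric projection of
    Sigma^-1 v' onto the l1-ball of magnitudes; for uniform sigma it is
    exactly the POL1B (l1-ball projection) form.  Pixels with zero
    dual step (zero stacked-operator rows) are left untouched; 0/0 := 0.
    """
    vp = v + sigma[np.newaxis] * alpha * d
    mag = grad_magnitude(vp)
    active = sigma > 0
    a = mag[active].ravel()
    w = 1.0 / sigma[active].ravel()
    t = _clip_threshold(a, w, alpha * gamma)
    if t == 0.0:
        out = np.where(active[np.newaxis], 0.0, vp)
        return out
    scale = np.ones_like(mag)
    hit = active & (mag > t)
    scale[hit] = t / mag[hit]
    return vp * scale[np.newaxis]


# ---------------------------------------------------------------------------
# linear sub-operators on the congregated vector

def _vmi_grad_apply(model: PolyForwardModel, m: int, x: np.ndarray) -> np.ndarray:
    """grad U_m x: gradient field of the VMI of x at bin m."""
    return grad(compute_vmi(x, model.partition, model.mus, m))


def _vmi_grad_adjoint(model: PolyForwardModel, m: int, g: np.ndarray) -> np.ndarray:
    """U_m^T grad^T g as a congregated vector."""
    img = grad_adjoint(g).ravel()
    part = model.partition
    out = np.empty(part.N_b)
    for l, k, sl in part.blocks():
        out[sl] = model.mus.mu[k, m] * img[part.region_pixels[l]]
    return out


def _vc_apply(model: PolyForwardModel, lc: int, x: np.ndarray) -> np.ndarray:
    """V_lc x = sum_{k in Phi_lc} x_lc,k / rho_k (I_lc,)."""
    part = model.partition
    rho = model.mus.densities
    out = np.zeros(part.I_l(lc))
    for k in part.phi[lc]:
        out += x[part.block(lc, k)] / rho[k]
    return out


def _vc_adjoint_add(model: PolyForwardModel, lc: int, qv: np.ndarray, beta: float, out: np.ndarray) -> None:
    part = model.partition
    rho = model.mus.densities
    for k in part.phi[lc]:
        out[part.block(lc, k)] += beta * qv / rho[k]


def _pixel_mu_image(model: PolyForwardModel, m: int) -> np.ndarray:
    """Per-pixel sum of mu_km over the materials of the pixel's region."""
    part = model.partition
    out = np.zeros(part.n_pixels)
    for l, k, _ in part.blocks():
        out[part.region_pixels[l]] += model.mus.mu[k, m]
    return out.reshape(part.shape)


# ---------------------------------------------------------------------------
# initialization

def init_scaling(model: PolyForwardModel, config: SolverConfig) -> PreconditionerSet:
    """Balancing scalars and diagonal steps at the zero expansion point."""
    part = model.partition
    ny, nx = part.shape
    rho_pc = config.rho_pc
    w0 = model.weights_from_t(np.zeros((model.J, model.K)))  # spectrum-averaged mu

    norm_H = operator_norm(
        lambda x: model.H_apply(x, w0),
        lambda y: model.H_adjoint(y, w0),
        (model.J, part.N_b),
        iters=config.norm_iters,
        tol=config.norm_tol,
        seed=config.seed,
    )
    if norm_H == 0:
        raise ValueError("H(0) has zero norm; check inputs")
    norms_grad = []
    for m in (config.m1, config.m2):
        norms_grad.append(
            operator_norm(
                lambda x, m=m: _vmi_grad_apply(model, m, x),
                lambda g, m=m: _vmi_grad_adjoint(model, m, g.reshape(2, ny, nx)),
                (2 * part.n_pixels, part.N_b),
                iters=config.norm_iters,
                tol=config.norm_tol,
                seed=config.seed + 1,
            )
        )
    rho_mat = model.mus.densities
    # V_lc rows are disjoint two-entry rows, so the norm is closed-form
    beta = {
        lc: norm_H / float(np.sqrt(sum(1.0 / rho_mat[k] ** 2 for k in part.phi[lc])))
        for lc in part.psi_vc
    }
    nu = norm_H / 1.0
    alpha1 = norm_H / norms_grad[0]
    alpha2 = norm_H / norms_grad[1]

    def _safe_inv(x, scale):
        return np.where(x > 0, scale / np.where(x > 0, x, 1.0), 0.0)

    sigma_u = _safe_inv(model.h_row_sums(w0), rho_pc)

    sigma_vw = []
    for m, alpha in ((config.m1, alpha1), (config.m2, alpha2)):
        omega = _pixel_mu_image(model, m)
        rs = np.zeros((ny, nx))
        rs[:-1, :] += alpha * (omega[:-1, :] + omega[1:, :])   # y-difference rows
        rs[:, :-1] += alpha * (omega[:, :-1] + omega[:, 1:])   # x-difference rows
        sigma_vw.append(_safe_inv(rs, rho_pc))

    sigma_p = np.full(part.N_b, rho_pc / nu)
    sigma_q = {
        lc: np.full(
            part.I_l(lc),
            rho_pc / (beta[lc] * sum(1.0 / rho_mat[k] for k in part.phi[lc])),
        )
        for lc in part.psi_vc
    }

    # static (non-H) part of the stacked-operator column sums
    static = np.full(part.N_b, nu)
    cstencil = grad_abs_col_sums(ny, nx).ravel()
    for m, alpha in ((config.m1, alpha1), (config.m2, alpha2)):
        for l, k, sl in part.blocks():
            static[sl] += alpha * model.mus.mu[k, m] * cstencil[part.region_pixels[l]]
    for lc in part.psi_vc:
        for k in part.phi[lc]:
            static[part.block(lc, k)] += beta[lc] / rho_mat[k]

    tau = 1.0 / (rho_pc * (model.h_col_sums(w0) + static))

    return PreconditionerSet(
        nu=nu,
        alpha1=alpha1,
        alpha2=alpha2,
        beta=beta,
        norm_H0=norm_H,
        sigma_u=sigma_u,
        sigma_v=sigma_vw[0],
        sigma_w=sigma_vw[1],
        sigma_p=sigma_p,
        sigma_q=sigma_q,
        tau=tau,
        static_colsums=static,
    )


def init_state(model: PolyForwardModel, precond: PreconditionerSet) -> SolverState:
    """All-zeros initialization (primal, extrapolation, and every dual)."""
    part = model.partition
    ny, nx = part.shape
    zeros_b = np.zeros(part.N_b)
    t0 = np.zeros((model.J, model.K))
    w0 = model.weights_from_t(t0)
    return SolverState(
        n=0,
        b=zeros_b.copy(),
        b_prev=zeros_b.copy(),
        btilde=zeros_b.copy(),
        t_b=t0.copy(),
        t_btilde=t0.copy(),
        u=np.zeros(model.J),
        v=np.zeros((2, ny, nx)),
        w=np.zeros((2, ny, nx)),
        p=np.zeros(part.N_b),
        q={lc: np.zeros(part.I_l(lc)) for lc in part.psi_vc},
        dg=np.zeros(model.J),
        weights=w0,
        sigma_u=precond.sigma_u.copy(),
        tau=precond.tau.copy(),
    )


# ---------------------------------------------------------------------------
# iteration

def iterate(
    state: SolverState,
    data: np.ndarray,
    precond: PreconditionerSet,
    model: PolyForwardModel,
    config: SolverConfig,
) -> SolverState:
    """One PD/dNCPD iteration (updates ``state`` in place and returns it)."""
    part = model.partition
    su = state.sigma_u

    # data-fidelity dual ascent with its resolvent
    Hbt = model.H_apply_t(state.t_btilde, state.weights)
    resid = (data - state.dg) - Hbt
    state.u = (state.u - su * resid) / (1.0 + su)

    # TV-constraint duals
    d1 = _vmi_grad_apply(model, config.m1, state.btilde)
    state.v = tv_dual_step(state.v, d1, precond.sigma_v, precond.alpha1, config.gamma_m1)
    d2 = _vmi_grad_apply(model, config.m2, state.btilde)
    state.w = tv_dual_step(state.w, d2, precond.sigma_w, precond.alpha2, config.gamma_m2)

    # nonnegativity dual
    state.p = neg(state.p + precond.sigma_p * precond.nu * state.btilde)

    # volume-conservation duals
    for lc in part.psi_vc:
        state.q[lc] = state.q[lc] + precond.sigma_q[lc] * precond.beta[lc] * (
            _vc_apply(model, lc, state.btilde) - 1.0
        )

    # primal descent through the stacked adjoints
    ascent = model.H_adjoint(state.u, state.weights)
    ascent = ascent + precond.alpha1 * _vmi_grad_adjoint(model, config.m1, state.v)
    ascent = ascent + precond.alpha2 * _vmi_grad_adjoint(model, config.m2, state.w)
    ascent = ascent + precond.nu * state.p
    for lc in part.psi_vc:
        _vc_adjoint_add(model, lc, state.q[lc], precond.beta[lc], ascent)
    b_new = state.b - state.tau * ascent

    # over-relaxed extrapolation; its path lengths follow by linearity
    t_new = model.path_lengths(b_new)
    state.btilde = 2.0 * b_new - state.b
    state.t_btilde = 2.0 * t_new - state.t_b
    state.b_prev = state.b
    state.b = b_new

    if config.algorithm == "dncpd":
        # relinearize: Delta g at the OLD expansion point,
        # then refresh the weights and the H-dependent step sizes
        state.dg = model.delta_g_from_t(t_new, state.weights)
        state.weights = model.weights_from_t(t_new)
        rowsums = model.h_row_sums(state.weights)
        state.sigma_u = np.where(
            rowsums > 0, config.rho_pc / np.where(rowsums > 0, rowsums, 1.0), 0.0
        )
        state.tau = 1.0 / (
            config.rho_pc * (model.h_col_sums(state.weights) + precond.static_colsums)
        )
    state.t_b = t_new

    state.n += 1
    if not (np.all(np.isfinite(state.b)) and np.all(np.isfinite(state.u))):
        raise FloatingPointError(f"non-finite iterate at n = {state.n}")
    return state


def convergence_metrics(
    state: SolverState,
    data: np.ndarray,
    model: PolyForwardModel,
    config: SolverConfig,
    truth_bprime: np.ndarray | None = None,
) -> MetricsRecord:
    """Normalized residual-and-feasibility metrics of the current iterate."""
    part = model.partition
    Hb = model.H_apply_t(state.t_b, state.weights)
    d_data = float(
        np.linalg.norm((data - state.dg) - Hb) / max(np.linalg.norm(data), _EPS)
    )
    gaps = []
    for m, gamma in ((config.m1, config.gamma_m1), (config.m2, config.gamma_m2)):
        tv = isotropic_tv(compute_vmi(state.b, part, model.mus, m))
        gaps.append(max(0.0, tv - gamma) / max(gamma, _EPS))
    vc = {}
    for lc in part.psi_vc:
        r = vc_residual(state.b, part, lc, model.mus.densities)
        vc[lc] = float(np.linalg.norm(r) / np.sqrt(part.I_l(lc)))
    nb = np.linalg.norm(state.b)
    nonneg = float(np.linalg.norm(np.minimum(state.b, 0.0)) / max(nb, _EPS))
    change = float(np.linalg.norm(state.b - state.b_prev) / max(nb, _EPS))
    nrmse = None
    if truth_bprime is not None:
        bt = assemble_basis_images(truth_bprime, part)
        bb = assemble_basis_images(state.b, part)
        nrmse = float(np.linalg.norm(bb - bt) / np.linalg.norm(bt))
    return MetricsRecord(
        n=state.n,
        data=d_data,
        tv1=gaps[0],
        tv2=gaps[1],
        vc=vc,
        nonneg=nonneg,
        primal_change=change,
        nrmse=nrmse,
    )


def solve(
    data: np.ndarray,
    system,
    partition,
    spectrum,
    mus,
    config: SolverConfig,
    truth_bprime: np.ndarray | None = None,
    callback=None,
    metrics_every: int = 1,
) -> tuple:
    """Run the configured algorithm to convergence or ``max_iters``.

    Returns ``(bprime_star, history)`` with one :class:`MetricsRecord` per
    recorded iteration.  Deterministic for a fixed configuration.
    """
    data = np.asarray(data, dtype=float).ravel()
    model = PolyForwardModel(system, partition, spectrum, mus)
    if data.size != model.J:
        raise ValueError(f"data length {data.size} != J = {model.J}")
    precond = init_scaling(model, config)
    state = init_state(model, precond)
    history = []
    tols = config.tolerances
    for _ in range(config.max_iters):
        state = iterate(state, data, precond, model, config)
        if state.n % metrics_every == 0 or state.n == config.max_iters:
            rec = convergence_metrics(state, data, model, config, truth_bprime)
            history.append(rec)
            if callback is not None:
                callback(rec)
            vals = rec.enabled_values(tols)
            if vals and all(vals[k] < tols[k] for k in vals):
                break
    return state.b, history
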