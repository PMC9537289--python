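"""Bifurcation sets of the Wilson-Cowan model: closed-form single-node curves
and network-level linear stability maps.

Single node
-----------
Fixed points of the uncoupled (``eps = 0``) node satisfy ``u* = f(c1 u* - c2
v* + P)`` and ``v* = f(c3 u* - c4 v* + Q)``.  Parameterising by the fixed
point ``(u*, v*) in (0, 1)^2`` and inverting the sigmoid
(``f^{-1}(y) = ln(y / (1 - y))``) gives

    P = f^{-1}(u*) - c1 u* + c2 v*,    Q = f^{-1}(v*) - c3 u* + c4 v*.

With the sigmoid slopes ``phi_u = u*(1 - u*)`` and ``phi_v = v*(1 - v*)`` the
single-node Jacobian is

    J = [[-1 + c1 phi_u,  -c2 phi_u],
         [ c3 phi_v,      -1 - c4 phi_v]].

The Hopf set is the trace-zero locus with positive determinant and the
saddle-node set is the determinant-zero locus; both conditions are linear in
``phi_v`` given ``phi_u``, so the curves are swept in closed form over a grid
of ``u*`` values.

Network
-------
For coupled networks the uniform-steady-state destabilisation is mapped by
root-solving the ``2N``-dimensional right-hand side at each ``(P, Q)`` cell
(warm-started by continuation from the neighbouring cell) and classifying the
eigenvalues of the analytic ``2N x 2N`` Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import root

from .dynamics import WCParameters, firing_rate
from .netmodel import LayerMatrix

EIG_TOL = 1e-8  # |Re| / |Im| threshold for classification and curve residuals
RESIDUAL_TOL = 1e-10

CLASS_STABLE_NODE = "stable-node"
CLASS_STABLE_FOCUS = "stable-focus"
CLASS_UNSTABLE = "unstable"
CLASS_NO_FP = "no-fixed-point-found"


@dataclass
class BifurcationSet:
    """Sampled (P, Q) bifurcation loci of the single-node model."""

    curve_points: np.ndarray  # (n, 2) of (P, Q)
    labels: list[str]  # per point: 'hopf' or 'saddle-node'
    parameterisation: np.ndarray  # (n, 2) of the generating fixed point (u*, v*)

    def points(self, label: str) -> np.ndarray:
        mask = np.array([lab == label for lab in self.labels])
        return self.curve_points[mask] if mask.any() else np.empty((0, 2))


@dataclass
class FixedPointResult:
    """Outcome of a 2N-dimensional fixed-point solve."""

    x: np.ndarray
    residual: float
    converged: bool


@dataclass
class StabilityMap:
    """Linear-stability classification of the tracked steady state on a grid."""

    P_grid: np.ndarray
    Q_grid: np.ndarray
    classification: np.ndarray  # (nP, nQ) of str, indexed [pi, qi]
    leading_eigenvalue: np.ndarray  # (nP, nQ) complex
    fixed_points: np.ndarray = field(default=None, repr=False)  # (nP, nQ, 2N)

    @property
    def unstable_mask(self) -> np.ndarray:
        return self.classification == CLASS_UNSTABLE

    def boundary_mask(self) -> np.ndarray:
        """Cells with a 4-neighbour on the other side of the stability boundary."""
        unstable = self.unstable_mask
        out = np.zeros_like(unstable, dtype=bool)
        for shift, axis in ((1, 0), (-1, 0), (1, 1), (-1, 1)):
            rolled = np.roll(unstable, shift, axis=axis)
            # roll wraps; invalidate the wrapped edge
            edge = np.zeros_like(unstable, dtype=bool)
            if axis == 0:
                idx = 0 if shift == 1 else -1
                edge[idx, :] = True
            else:
                idx = 0 if shift == 1 else -1
                edge[:, idx] = True
            differs = (rolled != unstable) & ~edge
            out |= differs
        return out


def _phi(y: np.ndarray) -> np.ndarray:
    return y * (1.0 - y)


def _logit(y: np.ndarray) -> np.ndarray:
    return np.log(y / (1.0 - y))


def _pq_from_fixed_point(u, v, params: WCParameters):
    p = _logit(u) - params.c1 * u + params.c2 * v
    q = _logit(v) - params.c3 * u + params.c4 * v
    return p, q


def single_node_jacobian(u: float, v: float, params: WCParameters) -> np.ndarray:
    """Jacobian of the uncoupled node evaluated at a fixed point ``(u, v)``."""
    pu, pv = _phi(u), _phi(v)
    return np.array(
        [
            [-1.0 + params.c1 * pu, -params.c2 * pu],
            [params.c3 * pv, -1.0 - params.c4 * pv],
        ]
    )


def single_node_bifurcation_sets(
    params: WCParameters | None = None, n_samples: int = 2000
) -> BifurcationSet:
    """Closed-form Hopf and saddle-node sets of the uncoupled node.

    Sweeps ``u*`` over a uniform grid in (0, 1); for each value the defining
    condition (trace = 0 with det > 0 for Hopf, det = 0 for saddle-node) is a
    linear equation in ``phi_v = v*(1 - v*)``, yielding up to two ``v*``
    branches and hence up to two curve points per locus.
    """
    params = params or WCParameters()
    c1, c2, c3, c4 = params.c1, params.c2, params.c3, params.c4
    us = np.linspace(1e-4, 1.0 - 1e-4, n_samples)
    pts: list[tuple[float, float]] = []
    labels: list[str] = []
    fps: list[tuple[float, float]] = []

    def emit(u, phi_v, label):
        if not (0.0 < phi_v <= 0.25):
            return
        disc = np.sqrt(max(1.0 - 4.0 * phi_v, 0.0))
        for v in ((1.0 - disc) / 2.0, (1.0 + disc) / 2.0):
            if not (0.0 < v < 1.0):
                continue
            jac = single_node_jacobian(u, v, params)
            tr = jac[0, 0] + jac[1, 1]
            det = jac[0, 0] * jac[1, 1] - jac[0, 1] * jac[1, 0]
            if label == "hopf" and (abs(tr) > EIG_TOL or det <= 0.0):
                continue
            if label == "saddle-node" and abs(det) > EIG_TOL:
                continue
            p, q = _pq_from_fixed_point(u, v, params)
            pts.append((float(p), float(q)))
            labels.append(label)
            fps.append((float(u), float(v)))

    for u in us:
        phi_u = _phi(u)
        if c4 != 0.0:
            emit(u, (c1 * phi_u - 2.0) / c4, "hopf")
        den = c4 + phi_u * (c2 * c3 - c1 * c4)
        if abs(den) > 1e-14:
            emit(u, (c1 * phi_u - 1.0) / den, "saddle-node")

    if not pts:
        raise ValueError("no bifurcation locus exists in (0,1)^2 for these parameters")
    return BifurcationSet(np.array(pts), labels, np.array(fps))


# ---------------------------------------------------------------------------
# network-level machinery
# ---------------------------------------------------------------------------


def network_rhs(state: np.ndarray, b: np.ndarray, params: WCParameters) -> np.ndarray:
    """Right-hand side of the 2N Wilson-Cowan ODE system (drift only)."""
    n = b.shape[0]
    u, v = state[:n], state[n:]
    xu = params.c1 * u - params.c2 * v + params.P + params.epsilon * (b @ u)
    xv = params.c3 * u - params.c4 * v + params.Q
    return np.concatenate((-u + firing_rate(xu), -v + firing_rate(xv)))


def network_jacobian(state: np.ndarray, b: np.ndarray, params: WCParameters) -> np.ndarray:
    """Analytic 2N x 2N Jacobian of :func:`network_rhs`."""
    n = b.shape[0]
    u, v = state[:n], state[n:]
    xu = params.c1 * u - params.c2 * v + params.P + params.epsilon * (b @ u)
    xv = params.c3 * u - params.c4 * v + params.Q
    fu = firing_rate(xu)
    fv = firing_rate(xv)
    phi_u = fu * (1.0 - fu)
    phi_v = fv * (1.0 - fv)
    eye = np.eye(n)
    j11 = -eye + phi_u[:, None] * (params.c1 * eye + params.epsilon * b)
    j12 = np.diag(-params.c2 * phi_u)
    j21 = np.diag(params.c3 * phi_v)
    j22 = -eye - np.diag(params.c4 * phi_v)
    return np.block([[j11, j12], [j21, j22]])


def network_fixed_point(
    connectivity: LayerMatrix | np.ndarray,
    params: WCParameters,
    guess: np.ndarray,
    multistart: bool = True,
) -> FixedPointResult:
    """Root-solve the 2N system from ``guess`` with the analytic Jacobian.

    With ``multistart`` (default), a failed solve falls back to a fixed set
    of structured uniform starting states (hybr can stall on the sigmoid's
    plateaus, where ``||F||`` has spurious local minima).  The best result is
    returned either way; ``converged`` reports whether the residual
    infinity-norm is below ``1e-10``.
    """
    b = connectivity.weights if isinstance(connectivity, LayerMatrix) else np.asarray(
        connectivity, dtype=float
    )
    best = _solve_once(b, params, np.asarray(guess, dtype=float))
    if best.converged or not multistart:
        return best
    n = b.shape[0]
    for u0, v0 in ((0.05, 0.05), (0.95, 0.95), (0.25, 0.75), (0.75, 0.25),
                   (0.05, 0.95), (0.95, 0.05), (0.5, 0.5)):
        res = _solve_once(
            b, params, np.concatenate((np.full(n, u0), np.full(n, v0)))
        )
        if res.converged:
            return res
        if res.residual < best.residual:
            best = res
    return best


def _solve_once(
    b: np.ndarray, params: WCParameters, guess: np.ndarray
) -> FixedPointResult:
    sol = root(
        network_rhs,
        guess,
        args=(b, params),
        jac=network_jacobian,
        method="hybr",
    )
    x = sol.x
    residual = float(np.abs(network_rhs(x, b, params)).max())
    # damped-Newton polish: hybr can stall short of tolerance near folds (and
    # occasionally on plateaus of the sigmoid) while a root remains reachable
    for _ in range(100):
        if residual < RESIDUAL_TOL:
            break
        f = network_rhs(x, b, params)
        try:
            step = np.linalg.solve(network_jacobian(x, b, params), f)
        except np.linalg.LinAlgError:
            break
        alpha = 1.0
        improved = False
        for _ in range(12):
            x_new = x - alpha * step
            new_res = float(np.abs(network_rhs(x_new, b, params)).max())
            if np.isfinite(new_res) and new_res < residual:
                x, residual = x_new, new_res
                improved = True
                break
            alpha *= 0.5
        if not improved:
            break
    return FixedPointResult(x, residual, residual < RESIDUAL_TOL)


def network_stability_map(
    connectivity: LayerMatrix | np.ndarray,
    params: WCParameters,
    P_range: tuple[float, float] = (-6.0, 2.0),
    Q_range: tuple[float, float] = (-12.0, 0.0),
    resolution: int = 30,
    keep_fixed_points: bool = False,
    rng_seed: int = 12345,
) -> StabilityMap:
    """Classify steady-state stability over a (P, Q) grid.

    Sweeps column-major in ``P`` with warm starts (continuation from the
    previous cell), falling back to five random restarts when the solve
    fails; failed cells are marked ``no-fixed-point-found``, never
    interpolated.  Classification uses the leading eigenvalue of the analytic
    Jacobian: positive real part means the steady state is destabilised
    (oscillatory onset when the leading pair is complex — Hopf type; real
    leading eigenvalue — saddle-node type).
    """
    b = connectivity.weights if isinstance(connectivity, LayerMatrix) else np.asarray(
        connectivity, dtype=float
    )
    n = b.shape[0]
    p_vals = np.linspace(*P_range, resolution)
    q_vals = np.linspace(*Q_range, resolution)
    classification = np.empty((resolution, resolution), dtype=object)
    leading = np.zeros((resolution, resolution), dtype=complex)
    fps = np.zeros((resolution, resolution, 2 * n)) if keep_fixed_points else None
    rng = np.random.default_rng(rng_seed)

    col_start = np.full(2 * n, 0.5)
    for pi, p in enumerate(p_vals):
        guess = col_start.copy()
        for qi, q in enumerate(q_vals):
            cell = params.replace(P=float(p), Q=float(q))
            res = network_fixed_point(b, cell, guess)
            if not res.converged:
                # last-resort random multistart (structured restarts already
                # happen inside network_fixed_point)
                for _ in range(5):
                    res = network_fixed_point(b, cell, rng.random(2 * n))
                    if res.converged:
                        break
            if not res.converged:
                classification[pi, qi] = CLASS_NO_FP
                leading[pi, qi] = np.nan
                continue
            guess = res.x
            if qi == 0:
                col_start = res.x
            eigs = np.linalg.eigvals(network_jacobian(res.x, b, cell))
            lead = eigs[np.argmax(eigs.real)]
            leading[pi, qi] = lead
            if fps is not None:
                fps[pi, qi] = res.x
            if lead.real > EIG_TOL:
                classification[pi, qi] = CLASS_UNSTABLE
            elif abs(lead.imag) > EIG_TOL:
                classification[pi, qi] = CLASS_STABLE_FOCUS
            else:
                classification[pi, qi] = CLASS_STABLE_NODE
    return StabilityMap(p_vals, q_vals, classification, leading, fps)
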