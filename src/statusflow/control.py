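"""Iterative compensatory-perturbation control of the status dynamics.

Given a state stranded in the diseased basin (or on an escaping orbit), the
controller designs a sequence of small admissible state perturbations that
drive the orbit into the basin of a target attractor, following the
closest-approach linearization scheme of network control:

1. integrate the orbit and find its time of closest approach t_c to the
   target state x*;
2. integrate the variational equation dM/dt = DF(x(t)) M, M(t_0) = I, to
   obtain the sensitivity of x(t_c) to the initial state;
3. solve the constrained linearized program

       min |x* - (x(t_c) + M delta)|
       s.t. component admissibility (frozen coordinates, sign/box bounds),
            eps0 <= |delta| <= eps1,
            delta . delta_prev >= 0   (no backtracking),

4. apply delta to the initial state and repeat until the perturbed orbit
   relaxes into the target basin.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize

from .dynamics import EquilibriumSet, ForceField, Orbit, find_equilibria, integrate_orbit

__all__ = [
    "ControlProblem",
    "PerturbationStep",
    "RescueResult",
    "variational_matrix",
    "closest_approach",
    "solve_perturbation_nlp",
    "iterative_rescue",
]


@dataclass(frozen=True)
class ControlProblem:
    """Constraint set and target of the rescue controller.

    ``eligible`` marks which state components may be perturbed (the equality
    constraints freeze the rest); ``eps0``/``eps1`` bound the perturbation
    magnitude per iteration; ``component_bounds`` optionally boxes each
    component of delta (the admissibility inequalities).
    """

    target: np.ndarray
    eligible: tuple[bool, ...] = (True, True)
    eps0: float = 1e-4
    eps1: float = 0.3
    component_bounds: tuple[tuple[float, float], ...] | None = None
    max_iterations: int = 100
    settle_tol: float = 1e-6

    def __post_init__(self):
        t = np.asarray(self.target, dtype=float)
        if not np.all(np.isfinite(t)):
            raise ValueError("target must be finite")
        if not 0 <= self.eps0 <= self.eps1:
            raise ValueError("need 0 <= eps0 <= eps1")
        if len(self.eligible) != t.size:
            raise ValueError("eligible mask must match the state dimension")


@dataclass
class PerturbationStep:
    delta: np.ndarray
    delta_prev: np.ndarray | None
    t_c: float
    closest_distance: float
    M: np.ndarray
    nlp_status: str


@dataclass
class RescueResult:
    """Trace of the iterative rescue."""

    steps: list[PerturbationStep]
    success: bool
    final_state: np.ndarray
    final_distance: float
    initial_state: np.ndarray
    target: np.ndarray

    @property
    def total_perturbation(self) -> np.ndarray:
        """The full compensatory perturbation (sum of the accepted steps)."""
        if not self.steps:
            return np.zeros_like(self.target)
        return np.sum([s.delta for s in self.steps], axis=0)

    @property
    def n_iterations(self) -> int:
        return len(self.steps)

    def summary(self) -> str:
        lines = [
            "Compensatory-perturbation rescue",
            "================================",
            f"initial state: {np.array2string(self.initial_state, precision=4)}",
            f"target:        {np.array2string(self.target, precision=4)}",
            f"success:       {self.success} in {self.n_iterations} iterations",
            f"final distance to target: {self.final_distance:.3e}",
            f"total perturbation: {np.array2string(self.total_perturbation, precision=4)}",
        ]
        return "\n".join(lines)

    def to_json(self, path) -> None:
        payload = {
            "success": self.success,
            "initial_state": self.initial_state.tolist(),
            "target": self.target.tolist(),
            "final_distance": self.final_distance,
            "total_perturbation": self.total_perturbation.tolist(),
            "steps": [
                {
                    "delta": s.delta.tolist(),
                    "t_c": s.t_c,
                    "closest_distance": s.closest_distance,
                    "nlp_status": s.nlp_status,
                }
                for s in self.steps
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def variational_matrix(
    field: ForceField,
    y0,
    t_grid: np.ndarray,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Solve dM/dt = DF(x(t)) M jointly with the orbit; M(t_0) = identity.

    Returns M with shape (len(t_grid), n, n), where n is the state dimension.
    """
    y0 = np.asarray(y0, dtype=float)
    n = y0.size
    t_grid = np.asarray(t_grid, dtype=float)

    def rhs(t, z):
        y = z[:n]
        M = z[n:].reshape(n, n)
        J = field.jacobian(y[0])
        dy = np.array([y[1], field.force(y[0], y[1])])
        return np.concatenate([dy, (J @ M).ravel()])

    z0 = np.concatenate([y0, np.eye(n).ravel()])
    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), z0, t_eval=t_grid,
                    rtol=rtol, atol=atol, method="RK45")
    if not sol.success:
        raise RuntimeError(f"variational integration failed: {sol.message}")
    return sol.y[n:].T.reshape(len(t_grid), n, n)


def closest_approach(orbit: Orbit, target) -> tuple[float, float]:
    """Time and distance of the orbit's minimum distance to the target state.

    The discrete minimum is refined by quadratic interpolation of the
    squared-distance time series (or by evaluating the dense solution when
    the orbit carries one).
    """
    target = np.asarray(target, dtype=float)
    d2 = np.sum((orbit.states - target) ** 2, axis=1)
    k = int(np.argmin(d2))
    if 0 < k < len(d2) - 1:
        t0, t1, t2 = orbit.times[k - 1 : k + 2]
        f0, f1, f2 = d2[k - 1 : k + 2]
        denom = (f0 - 2 * f1 + f2)
        if denom > 0:
            # vertex of the parabola through the three samples
            dt = 0.5 * (f0 - f2) / denom * (t2 - t0) / 2
            t_star = float(np.clip(t1 + dt, t0, t2))
        else:
            t_star = float(t1)
        if orbit.dense is not None:
            y = orbit.dense(t_star)
            return t_star, float(np.linalg.norm(y - target))
        f_star = min(f1, np.interp(t_star, orbit.times, d2))
        return t_star, float(np.sqrt(f_star))
    return float(orbit.times[k]), float(np.sqrt(d2[k]))


def solve_perturbation_nlp(
    problem: ControlProblem,
    x_tc: np.ndarray,
    M: np.ndarray,
    delta_prev: np.ndarray | None = None,
) -> tuple[np.ndarray, str]:
    """Constrained linearized step: minimize |x* - (x(t_c) + M delta)|.

    Constraints: frozen components are exactly zero, eps0 <= |delta| <= eps1,
    optional per-component boxes, and non-backtracking
    delta . delta_prev >= 0. Solved by SLSQP on the free components; returns
    ``(delta, status)`` with status ``optimal``, ``feasible`` (best point
    found but not reported optimal) or ``infeasible``.
    """
    target = np.asarray(problem.target, dtype=float)
    x_tc = np.asarray(x_tc, dtype=float)
    n = target.size
    free = np.asarray(problem.eligible, dtype=bool)
    if not free.any():
        return np.zeros(n), "infeasible"
    Mf = M[:, free]
    residual0 = target - x_tc

    if problem.eps0 == 0.0 and np.linalg.norm(residual0) == 0.0:
        return np.zeros(n), "optimal"

    def objective(u):
        r = residual0 - Mf @ u
        return float(r @ r)

    def jac(u):
        r = residual0 - Mf @ u
        return -2.0 * (Mf.T @ r)

    cons = [
        {"type": "ineq", "fun": lambda u: problem.eps1**2 - u @ u,
         "jac": lambda u: -2.0 * u},
    ]
    if problem.eps0 > 0:
        cons.append(
            {"type": "ineq", "fun": lambda u: u @ u - problem.eps0**2,
             "jac": lambda u: 2.0 * u}
        )
    if delta_prev is not None:
        dp = np.asarray(delta_prev, dtype=float)[free]
        if np.linalg.norm(dp) > 0:
            cons.append(
                {"type": "ineq", "fun": lambda u: u @ dp, "jac": lambda u: dp}
            )
    bounds = None
    if problem.component_bounds is not None:
        bounds = [problem.component_bounds[i] for i in range(n) if free[i]]

    # start from the clipped unconstrained least-squares step
    u0, *_ = np.linalg.lstsq(Mf, residual0, rcond=None)
    nrm = np.linalg.norm(u0)
    if nrm > problem.eps1:
        u0 = u0 * (problem.eps1 / nrm)
    elif nrm < problem.eps0:
        direction = u0 / nrm if nrm > 0 else np.ones(free.sum()) / np.sqrt(free.sum())
        u0 = direction * problem.eps0
    if delta_prev is not None:
        dp = np.asarray(delta_prev, dtype=float)[free]
        if np.linalg.norm(dp) > 0 and u0 @ dp < 0:
            u0 = u0 - dp * (u0 @ dp) / (dp @ dp)
            if np.linalg.norm(u0) < problem.eps0:
                u0 = dp / np.linalg.norm(dp) * max(problem.eps0, 1e-12)

    res = minimize(objective, u0, jac=jac, method="SLSQP", bounds=bounds,
                   constraints=cons, options={"maxiter": 200, "ftol": 1e-14})
    u = res.x
    mag = np.linalg.norm(u)
    feasible = problem.eps0 - 1e-9 <= mag <= problem.eps1 + 1e-9
    if delta_prev is not None:
        dp = np.asarray(delta_prev, dtype=float)[free]
        if np.linalg.norm(dp) > 0:
            feasible = feasible and (u @ dp >= -1e-12)
    if not feasible:
        return np.zeros(n), "infeasible"
    # project tiny violations back onto the annulus
    if mag > problem.eps1:
        u = u * (problem.eps1 / mag)
    elif 0 < mag < problem.eps0:
        u = u * (problem.eps0 / mag)
    delta = np.zeros(n)
    delta[free] = u
    return delta, "optimal" if res.success else "feasible"


def _settles_to(
    field: ForceField,
    y0: np.ndarray,
    target: np.ndarray,
    horizon: float,
    tol: float,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> tuple[bool, float]:
    """Integrate the unperturbed continuation and report the closest approach
    to the target over its tail."""
    orbit = integrate_orbit(field, y0, (0.0, horizon), rtol=rtol, atol=atol,
                            dense_output=True)
    d_end = float(np.linalg.norm(orbit.states[-1] - target))
    _, d_min = closest_approach(orbit, target)
    return d_end <= tol, min(d_end, d_min) if d_end <= tol else d_end


def iterative_rescue(
    field: ForceField,
    initial_state,
    problem: ControlProblem,
    orbit_horizon: float = 80.0,
    settle_horizon: float = 800.0,
    equilibria: EquilibriumSet | None = None,
) -> RescueResult:
    """Drive ``initial_state`` into the basin of the target attractor.

    Iterates integrate -> closest approach -> variational matrix ->
    constrained linearized perturbation, with reject-and-halve backtracking
    when a step fails to reduce the closest-approach distance. Success is
    declared when the *unperturbed* continuation of the current state relaxes
    to the target within ``problem.settle_tol``; the reported final distance
    is the continuation's closest approach to the target.
    """
    y = np.asarray(initial_state, dtype=float).copy()
    target = np.asarray(problem.target, dtype=float)
    if equilibria is None:
        equilibria = find_equilibria(field)
    steps: list[PerturbationStep] = []
    delta_prev: np.ndarray | None = None

    settled, dist = _settles_to(field, y, target, settle_horizon, problem.settle_tol)
    if settled:
        return RescueResult(steps=[], success=True, final_state=y,
                            final_distance=dist,
                            initial_state=np.asarray(initial_state, float),
                            target=target)

    best_distance = np.inf
    for _ in range(problem.max_iterations):
        orbit = integrate_orbit(field, y, (0.0, orbit_horizon),
                                t_eval=np.linspace(0, orbit_horizon, 2000),
                                dense_output=True)
        t_c, d_c = closest_approach(orbit, target)
        t_c = max(t_c, 1e-6)
        M_path = variational_matrix(field, y, np.array([0.0, t_c]))
        M = M_path[-1]
        x_tc = orbit.dense(t_c)
        delta, status = solve_perturbation_nlp(problem, x_tc, M, delta_prev)
        if status == "infeasible":
            break
        # reject-and-shrink: require the new orbit's closest approach to improve
        accepted = False
        trial = delta.copy()
        for _halving in range(6):
            y_try = y + trial
            orbit_try = integrate_orbit(
                field, y_try, (0.0, orbit_horizon),
                t_eval=np.linspace(0, orbit_horizon, 2000), dense_output=True,
            )
            _, d_try = closest_approach(orbit_try, target)
            if d_try <= d_c * (1.0 + 1e-12):
                accepted = True
                break
            nxt = trial / 2.0
            if np.linalg.norm(nxt) < problem.eps0:
                break  # cannot shrink further without violating eps0
            trial = nxt
        if not accepted or not np.any(trial):
            break
        y = y + trial
        best_distance = min(best_distance, d_c)
        steps.append(
            PerturbationStep(delta=trial, delta_prev=delta_prev, t_c=t_c,
                             closest_distance=d_c, M=M, nlp_status=status)
        )
        delta_prev = trial
        settled, dist = _settles_to(field, y, target, settle_horizon,
                                    problem.settle_tol)
        if settled:
            return RescueResult(steps=steps, success=True, final_state=y,
                                final_distance=dist,
                                initial_state=np.asarray(initial_state, float),
                                target=target)
    settled, dist = _settles_to(field, y, target, settle_horizon, problem.settle_tol)
    if not settled:
        warnings.warn("rescue did not reach the target basin", stacklevel=2)
    return RescueResult(steps=steps, success=settled, final_state=y,
                        final_distance=dist,
                        initial_state=np.asarray(initial_state, float),
                        target=target)
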