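"""Bistable status dynamics.

The 1-D reaction coordinate x (position along the disease/control axis of
the manifold embedding) obeys a damped Newtonian system

    dx/dt = v
    dv/dt = F(x, v),   F(x, v) = (1/sqrt(h)) sum_s C_s (x - mu_s) e^{-(x - mu_s)^2} - eta v,

one gaussian-localized force term per status manifold plus a linear
dissipation -eta v. The potential is P(x) = -int F(x, 0) dx (closed form),
so mechanical energy E = v^2/2 + P(x) satisfies dE/dt = -eta v^2.

The default calibrated field places the wells at mu = -0.75 (disease) and
mu = +0.75 (control-like) with amplitudes C = -1 and C = -rho*, where rho*
is chosen so the interior unstable equilibrium -- the boundary between the
two basins of attraction -- sits exactly at x = -0.08, with dissipation
eta = 0.1. This reproduces the bistable phase portrait of disease status:
a diseased attractor x_D < 0, a control attractor x_C > 0, and the basin
boundary at -0.08.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "ForceField",
    "Orbit",
    "Equilibrium",
    "EquilibriumSet",
    "BasinMap",
    "force",
    "find_equilibria",
    "integrate_orbit",
    "basin_map",
    "DissipationModel",
    "DissipationResults",
    "fit_eta_bootstrap",
]

#: basin boundary of the default calibrated field
BOUNDARY_X = -0.08


@dataclass(frozen=True)
class ForceField:
    """Superposition of gaussian-localized wells with linear dissipation.

    ``wells`` is a list of ``(center mu_s, amplitude C_s)``; negative
    amplitudes make attracting wells.
    """

    wells: tuple[tuple[float, float], ...] = ((-0.75, -1.0), (0.75, -1.0))
    eta: float = 0.1
    h: float = 1.0

    def __post_init__(self):
        if not self.wells:
            raise ValueError("need at least one well")
        if self.eta < 0:
            raise ValueError("dissipation eta must be >= 0")
        if self.h <= 0:
            raise ValueError("bandwidth h must be > 0")

    @classmethod
    def default_calibrated(
        cls,
        eta: float = 0.1,
        h: float = 1.0,
        mu_disease: float = -0.75,
        mu_control: float = 0.75,
        boundary: float = BOUNDARY_X,
        amplitude_scale: float = 1.0,
    ) -> "ForceField":
        """Two-well field whose interior unstable root sits at ``boundary``.

        The control-well amplitude ratio rho* solves F(boundary, 0) = 0 by
        root bracketing (rho* ~ 1.0263 at the defaults). Scaling both
        amplitudes by ``amplitude_scale`` (e.g. a fitted |C|) leaves every
        equilibrium in place.
        """

        def residual(rho: float) -> float:
            f = cls(wells=((mu_disease, -1.0), (mu_control, -rho)), eta=eta, h=h)
            return f.force(boundary, 0.0)

        rho_star = brentq(residual, 1e-6, 1e3, xtol=1e-14)
        s = amplitude_scale
        return cls(
            wells=((mu_disease, -1.0 * s), (mu_control, -rho_star * s)),
            eta=eta,
            h=h,
        )

    def conservative_force(self, x):
        """F(x, 0): the position-dependent part of the force."""
        x = np.asarray(x, dtype=float)
        total = np.zeros_like(x)
        for mu, C in self.wells:
            dx = x - mu
            total = total + C * dx * np.exp(-(dx**2))
        out = total / np.sqrt(self.h)
        return float(out) if out.ndim == 0 else out

    def force(self, x, v):
        """Full force F(x, v) = F(x, 0) - eta v."""
        return self.conservative_force(x) - self.eta * np.asarray(v, dtype=float)

    def potential(self, x):
        """P(x) = -int_0^x F(u, 0) du, in closed form."""
        x = np.asarray(x, dtype=float)
        total = np.zeros_like(x)
        for mu, C in self.wells:
            total = total + 0.5 * C * (np.exp(-((x - mu) ** 2)) - np.exp(-(mu**2)))
        out = total / np.sqrt(self.h)
        return float(out) if out.ndim == 0 else out

    def force_gradient(self, x) -> float:
        """dF/dx at (x, 0), for Jacobians and stability analysis."""
        x = float(x)
        total = 0.0
        for mu, C in self.wells:
            dx = x - mu
            total += C * (1.0 - 2.0 * dx**2) * np.exp(-(dx**2))
        return total / np.sqrt(self.h)

    def jacobian(self, x: float) -> np.ndarray:
        """State Jacobian DF of (dx/dt, dv/dt) = (v, F(x, v))."""
        return np.array([[0.0, 1.0], [self.force_gradient(x), -self.eta]])

    def energy(self, x, v):
        return 0.5 * np.asarray(v, dtype=float) ** 2 + self.potential(x)

    def escape_bound(self, tol: float = 1e-6) -> float:
        """|x| beyond which the conservative force is below ``tol`` outward:
        practical 'unbounded orbit' bound for basin classification."""
        centers = [abs(mu) for mu, _ in self.wells]
        b = max(centers) + 1.0
        while abs(self.conservative_force(b)) > tol or abs(
            self.conservative_force(-b)
        ) > tol:
            b += 0.5
            if b > 100:
                break
        return b

    def replace(self, **kwargs) -> "ForceField":
        return replace(self, **kwargs)


def force(field: ForceField, x, v):
    return field.force(x, v)


@dataclass
class Orbit:
    """Integrated trajectory of the second-order system, states = (x, v)."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, 2)
    rtol: float
    atol: float
    dense: object = None  # scipy OdeSolution, when requested

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("orbit times must be strictly increasing")

    @property
    def x(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def v(self) -> np.ndarray:
        return self.states[:, 1]


def integrate_orbit(
    field: ForceField,
    y0,
    t_span: tuple[float, float],
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    dense_output: bool = False,
    events=None,
) -> Orbit:
    """Adaptively integrate dx/dt = v, dv/dt = F(x, v)."""
    y0 = np.asarray(y0, dtype=float)
    if not np.all(np.isfinite(y0)):
        raise ValueError("initial state must be finite")

    def rhs(t, y):
        return [y[1], field.force(y[0], y[1])]

    sol = solve_ivp(
        rhs, t_span, y0, t_eval=t_eval, rtol=rtol, atol=atol,
        dense_output=dense_output, events=events, method="RK45",
    )
    if not sol.success and sol.status < 0:
        raise RuntimeError(f"orbit integration failed: {sol.message}")
    return Orbit(times=sol.t, states=sol.y.T, rtol=rtol, atol=atol,
                 dense=sol.sol if dense_output else None)


# ---------------------------------------------------------------------------
# equilibria
# ---------------------------------------------------------------------------


@dataclass
class Equilibrium:
    x: float
    stability: str  # stable / unstable / saddle
    eigenvalues: np.ndarray

    @property
    def state(self) -> np.ndarray:
        return np.array([self.x, 0.0])


@dataclass
class EquilibriumSet:
    equilibria: list[Equilibrium]
    field: ForceField

    @property
    def stable(self) -> list[Equilibrium]:
        return [e for e in self.equilibria if e.stability == "stable"]

    @property
    def unstable(self) -> list[Equilibrium]:
        return [e for e in self.equilibria if e.stability != "stable"]

    @property
    def x_D(self) -> float:
        """Diseased attractor: the stable point at x < 0."""
        neg = [e.x for e in self.stable if e.x < 0]
        if not neg:
            raise ValueError("no stable equilibrium at x < 0")
        return max(neg)

    @property
    def x_C(self) -> float:
        """Control attractor: the stable point at x > 0."""
        pos = [e.x for e in self.stable if e.x > 0]
        if not pos:
            raise ValueError("no stable equilibrium at x > 0")
        return min(pos)

    @property
    def y_D(self) -> np.ndarray:
        return np.array([self.x_D, 0.0])

    @property
    def y_C(self) -> np.ndarray:
        return np.array([self.x_C, 0.0])

    @property
    def basin_boundary(self) -> float:
        """Interior unstable root separating the two basins on the v = 0 axis."""
        inner = [e for e in self.unstable if min(e.x for e in self.stable)
                 < e.x < max(e.x for e in self.stable)]
        if not inner:
            raise ValueError("no interior unstable equilibrium")
        return inner[0].x

    def summary(self) -> str:
        lines = [
            "Equilibria of the status force field",
            "====================================",
            f"eta = {self.field.eta:g}, h = {self.field.h:g}",
            "",
            "x*          stability  Re(eigenvalues)",
        ]
        for e in sorted(self.equilibria, key=lambda e: e.x):
            re = ", ".join(f"{ev.real:+.4f}" for ev in e.eigenvalues)
            lines.append(f"{e.x:+.6f}   {e.stability:9s}  {re}")
        return "\n".join(lines)


def find_equilibria(
    field: ForceField,
    interval: tuple[float, float] = (-3.0, 3.0),
    n_grid: int = 10_000,
) -> EquilibriumSet:
    """All roots of F(x, 0) on the interval by sign-change bracketing plus
    bisection, classified by the eigenvalues of the state Jacobian
    [[0, 1], [dF/dx, -eta]]."""
    xs = np.linspace(interval[0], interval[1], n_grid)
    fs = field.conservative_force(xs)
    roots = []
    for i in range(len(xs) - 1):
        if fs[i] == 0.0:
            roots.append(xs[i])
        elif fs[i] * fs[i + 1] < 0:
            roots.append(brentq(field.conservative_force, xs[i], xs[i + 1],
                                xtol=1e-12))
    if fs[-1] == 0.0:
        roots.append(xs[-1])
    out = []
    for x_star in roots:
        ev = np.linalg.eigvals(field.jacobian(x_star))
        re = np.sort(ev.real)
        if np.all(re < 0):
            stability = "stable"
        elif re[0] < 0 < re[1]:
            stability = "saddle" if np.all(np.isreal(ev)) else "unstable"
        else:
            stability = "unstable"
        out.append(Equilibrium(x=float(x_star), stability=stability,
                               eigenvalues=ev))
    if not out:
        import warnings

        warnings.warn("no equilibria found on the interval", stacklevel=2)
    return EquilibriumSet(equilibria=out, field=field)


# ---------------------------------------------------------------------------
# basins
# ---------------------------------------------------------------------------


@dataclass
class BasinMap:
    """Grid classification of initial conditions over the (x, v) plane."""

    x_grid: np.ndarray
    v_grid: np.ndarray
    labels: np.ndarray  # strings: basin:<x*>, escaped, undecided
    equilibria: EquilibriumSet

    def label_at(self, x: float, v: float) -> str:
        i = int(np.argmin(np.abs(self.v_grid - v)))
        j = int(np.argmin(np.abs(self.x_grid - x)))
        return str(self.labels[i, j])

    @property
    def undecided_fraction(self) -> float:
        return float((self.labels == "undecided").mean())

    def to_tsv(self, path) -> None:
        import pandas as pd

        rows = []
        for i, v in enumerate(self.v_grid):
            for j, x in enumerate(self.x_grid):
                rows.append({"x": x, "v": v, "label": self.labels[i, j]})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def classify_initial_state(
    field: ForceField,
    y0,
    equilibria: EquilibriumSet,
    horizon: float = 400.0,
    ball_radius: float = 0.02,
    escape_tol: float = 1e-6,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> str:
    """Integrate one initial condition until it settles in a stable point's
    ball (with small velocity) or leaves the practical escape bound."""
    stable_x = [e.x for e in equilibria.stable]
    bound = field.escape_bound(escape_tol)

    def reach_event(t, y):
        d = min(abs(y[0] - xs) for xs in stable_x)
        return max(d, abs(y[1]) / 2) - ball_radius

    reach_event.terminal = True

    def escape_event(t, y):
        return abs(y[0]) - bound

    escape_event.terminal = True
    escape_event.direction = 1.0

    orbit = integrate_orbit(
        field, y0, (0.0, horizon), rtol=rtol, atol=atol,
        events=[reach_event, escape_event],
    )
    xf, vf = orbit.states[-1]
    if abs(xf) >= bound - 1e-9 and xf * vf > 0:
        return "escaped"
    d = [abs(xf - xs) for xs in stable_x]
    k = int(np.argmin(d))
    if d[k] <= ball_radius * 1.5 and abs(vf) <= ball_radius * 3:
        return f"basin:{stable_x[k]:+.6f}"
    return "undecided"


def basin_map(
    field: ForceField,
    x_range: tuple[float, float] = (-2.0, 2.0),
    v_range: tuple[float, float] = (-1.0, 1.0),
    n_x: int = 41,
    n_v: int = 21,
    horizon: float = 400.0,
    ball_radius: float = 0.02,
) -> BasinMap:
    """Classify a grid of initial conditions into basins of attraction.

    Cells whose orbit neither settles nor escapes within the horizon are
    labelled ``undecided``.
    """
    eq = find_equilibria(field)
    if not eq.stable:
        raise ValueError("field has no stable equilibria to attract orbits")
    xs = np.linspace(*x_range, n_x)
    vs = np.linspace(*v_range, n_v)
    labels = np.empty((n_v, n_x), dtype=object)
    for i, v in enumerate(vs):
        for j, x in enumerate(xs):
            labels[i, j] = classify_initial_state(
                field, (x, v), eq, horizon=horizon, ball_radius=ball_radius
            )
    return BasinMap(x_grid=xs, v_grid=vs, labels=labels, equilibria=eq)


# ---------------------------------------------------------------------------
# dissipation fitting
# ---------------------------------------------------------------------------


@dataclass
class DissipationResults:
    """Bootstrap estimate of the dissipation parameter eta."""

    eta: float
    bootstrap_sd: float
    ci_low: float
    ci_high: float
    n_boot: int
    bootstrap_estimates: np.ndarray

    def summary(self) -> str:
        return (
            "Dissipation fit (trajectory least squares, bootstrap)\n"
            "=====================================================\n"
            f"eta:          {self.eta:.6f}\n"
            f"bootstrap sd: {self.bootstrap_sd:.6f}\n"
            f"95% CI:       [{self.ci_low:.6f}, {self.ci_high:.6f}]\n"
            f"n_boot:       {self.n_boot}"
        )


class DissipationModel:
    """Least-squares fit of eta from observed orbits of a known well system.

    For a candidate eta the orbits are re-integrated from each trajectory's
    initial state and compared to the observations; the SSE is minimized by
    bounded scalar search. Bootstrap over trajectories gives the sd and a
    percentile confidence interval.
    """

    def __init__(
        self,
        trajectories: list[Orbit],
        field_template: ForceField,
        fit_rtol: float = 1e-8,
        fit_atol: float = 1e-10,
    ):
        if len(trajectories) < 2:
            raise ValueError("need at least 2 trajectories")
        spans = [np.ptp(o.states, axis=0).max() for o in trajectories]
        if max(spans) == 0:
            raise ValueError("all trajectories are constant; eta is unidentifiable")
        self.trajectories = trajectories
        self.field_template = field_template
        self.fit_rtol = fit_rtol
        self.fit_atol = fit_atol

    def _sse(self, eta: float, subset: list[Orbit]) -> float:
        trial = self.field_template.replace(eta=eta)
        total = 0.0
        for obs in subset:
            sim = integrate_orbit(
                trial, obs.states[0], (obs.times[0], obs.times[-1]),
                t_eval=obs.times, rtol=self.fit_rtol, atol=self.fit_atol,
            )
            total += float(np.sum((sim.states - obs.states) ** 2))
        return total

    def _fit_subset(self, subset: list[Orbit], xatol: float) -> float:
        res = minimize_scalar(
            lambda e: self._sse(e, subset), bounds=(0.0, 1.0),
            method="bounded", options={"xatol": xatol},
        )
        return float(res.x)

    def fit(self, n_boot: int = 100, seed: int = 0) -> DissipationResults:
        if n_boot < 10:
            raise ValueError("n_boot must be >= 10")
        rng = np.random.default_rng(seed)
        point = self._fit_subset(self.trajectories, xatol=1e-9)
        boots = np.empty(n_boot)
        n = len(self.trajectories)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            boots[b] = self._fit_subset([self.trajectories[i] for i in idx],
                                        xatol=1e-6)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        return DissipationResults(
            eta=point, bootstrap_sd=float(boots.std(ddof=1)),
            ci_low=float(lo), ci_high=float(hi), n_boot=n_boot,
            bootstrap_estimates=boots,
        )


def fit_eta_bootstrap(
    trajectories: list[Orbit],
    field_template: ForceField,
    n_boot: int = 100,
    seed: int = 0,
) -> DissipationResults:
    """Functional wrapper over :class:`DissipationModel`."""
    return DissipationModel(trajectories, field_template).fit(n_boot=n_boot, seed=seed)
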