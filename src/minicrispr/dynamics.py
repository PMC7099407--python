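"""Numerical replicator and replicator-mutator dynamics.

The state is (x_A, x_B): the fractions of each strain carrying a
cross-targeting spacer.  With no spacer loss the dynamics are the
two-strain replicator equations

    dx_A/dt = x_A (f_A1(x_B) - phi_A),    phi_A = x_A f_A1 + (1-x_A) f_A2

which reduce to the separable form

    dx_A/dt = x_A (1 - x_A) (a + b x_B)
    dx_B/dt = x_B (1 - x_B) (a' + b' x_A).

With a per-generation spacer-loss rate d the targeting class's growth
term acquires a factor (1 - d), giving a replicator-mutator system.

Because the cyclic regime is a *center* (a continuum of closed orbits,
not a limit cycle), convergence detection must not "converge away" the
oscillation: cycling is declared via Poincare-section returns, and the
first integral

    H = a' ln x_A - (a'+b') ln(1-x_A) - a ln x_B + (a+b) ln(1-x_B)

is exposed to verify orbit closure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.integrate import solve_ivp

from .game_core import (
    PairConfig,
    ReducedCoefficients,
    fitness_components,
    reduced_coefficients,
)
from .regimes import classify_regime

__all__ = [
    "SolverSettings",
    "Trajectory",
    "IntegrationError",
    "replicator_rhs",
    "reduced_rhs",
    "simulate_replicator",
    "conserved_quantity",
    "find_equilibria",
    "basin_classify",
]

#: Euclidean radius for a Poincare-section return to count as a cycle.
POINCARE_TOL = 1e-3
#: Distance within which a converged state is matched to an equilibrium.
EQUILIBRIUM_TOL = 1e-6
#: Boundary clamping tolerance (only round-off excursions are clamped).
CLAMP_TOL = 1e-12


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the failing time."""


@dataclass(frozen=True)
class SolverSettings:
    """Numerical settings for the replicator integrator.

    ``t_max`` is the integration horizon in generations (the cyclic
    orbit period at moderate coefficients is O(10^2), so the default
    1e4 spans many periods).  ``convergence_eps`` is the vector-field
    norm below which a state counts as an equilibrium, and
    ``cycle_window`` the chunk length between convergence/cycle checks.
    """

    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    t_max: float = 1e4
    convergence_eps: float = 1e-9
    cycle_window: float = 500.0
    method: str = "LSODA"

    def __post_init__(self) -> None:
        for name in ("rel_tol", "abs_tol", "t_max", "convergence_eps",
                     "cycle_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Trajectory:
    """Time series of the spacer-carrier fractions."""

    t: np.ndarray
    x_A: np.ndarray
    x_B: np.ndarray
    terminal_state: str  # converged | cycling | max_time

    def final_state(self) -> np.ndarray:
        return np.array([self.x_A[-1], self.x_B[-1]])

    def to_tsv(self, path: Union[str, Path]) -> None:
        """Write as TSV with full round-trip floating precision."""
        data = np.column_stack([self.t, self.x_A, self.x_B])
        header = "t\tx_A\tx_B"
        np.savetxt(path, data, fmt="%.17g", delimiter="\t", header=header,
                   comments="")
        with open(path, "a") as fh:
            fh.write(f"# terminal_state={self.terminal_state}\n")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "Trajectory":
        terminal = "max_time"
        rows = []
        with open(path) as fh:
            header = fh.readline()
            if header.strip().split("\t") != ["t", "x_A", "x_B"]:
                raise ValueError(f"unexpected trajectory header: {header!r}")
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    if "terminal_state=" in line:
                        terminal = line.split("terminal_state=")[1].strip()
                    continue
                if line:
                    rows.append([float(v) for v in line.split("\t")])
        arr = np.array(rows)
        return cls(t=arr[:, 0], x_A=arr[:, 1], x_B=arr[:, 2],
                   terminal_state=terminal)


# ---------------------------------------------------------------------------
# Vector fields
# ---------------------------------------------------------------------------

def replicator_rhs(pair: PairConfig, x: Sequence[float]) -> np.ndarray:
    """Full replicator(-mutator) right-hand side from the fitness terms.

    dx/dt = x ((1-d) f1(x_other) - phi);  with d = 0 this is the plain
    replicator equation built directly from the payoff mixtures, which
    serves as an independent cross-check of the reduced form.
    """
    # solver trial steps may overshoot [0,1] by round-off; evaluate the
    # (polynomial) fitness terms at the clipped state
    x_A = min(max(float(x[0]), 0.0), 1.0)
    x_B = min(max(float(x[1]), 0.0), 1.0)
    out = np.empty(2)
    for i, (name, own, other) in enumerate((("A", x_A, x_B),
                                            ("B", x_B, x_A))):
        params, p = pair.focal(name)
        f1, f2 = fitness_components(params, p, other,
                                    pair.effective_variant(name))
        phi = own * f1 + (1.0 - own) * f2
        out[i] = own * ((1.0 - params.d) * f1 - phi)
    return out


def reduced_rhs(coeffs: ReducedCoefficients, x: Sequence[float]) -> np.ndarray:
    """Reduced (loss-free) right-hand side x(1-x)(a + b x_other)."""
    x_A, x_B = float(x[0]), float(x[1])
    return np.array([
        x_A * (1.0 - x_A) * (coeffs.a + coeffs.b * x_B),
        x_B * (1.0 - x_B) * (coeffs.a_prime + coeffs.b_prime * x_A),
    ])


def conserved_quantity(coeffs: ReducedCoefficients,
                       x: Sequence[float]) -> float:
    """First integral H of the reduced replicator system.

    H = a' ln x_A - (a'+b') ln(1-x_A) - a ln x_B + (a+b) ln(1-x_B)
    is constant along exact loss-free trajectories, so its numerical
    drift measures integration error and tests orbit closure in the
    cyclic regime.  Requires a strictly interior state.
    """
    x_A, x_B = float(x[0]), float(x[1])
    if not (0.0 < x_A < 1.0 and 0.0 < x_B < 1.0):
        raise ValueError(
            f"conserved_quantity needs an interior state, got ({x_A}, {x_B})")
    a, b = coeffs.a, coeffs.b
    ap, bp = coeffs.a_prime, coeffs.b_prime
    return (ap * math.log(x_A) - (ap + bp) * math.log(1.0 - x_A)
            - a * math.log(x_B) + (a + b) * math.log(1.0 - x_B))


# ---------------------------------------------------------------------------
# Equilibria
# ---------------------------------------------------------------------------

def _corner_eigenvalues(coeffs: ReducedCoefficients,
                        corner: Tuple[int, int]) -> Tuple[float, float]:
    """Eigenvalues of the (diagonal) Jacobian of the reduced system."""
    a, b, ap, bp = coeffs.a, coeffs.b, coeffs.a_prime, coeffs.b_prime
    x_A, x_B = corner
    lam_A = (1 - 2 * x_A) * (a + b * x_B)
    lam_B = (1 - 2 * x_B) * (ap + bp * x_A)
    return lam_A, lam_B


def _tag(eigs: Sequence[float]) -> str:
    if any(e == 0.0 for e in eigs):
        return "neutral"
    if all(e < 0.0 for e in eigs):
        return "stable"
    return "unstable"


def find_equilibria(pair: PairConfig
                    ) -> List[Tuple[Tuple[float, float], str]]:
    """All rest points of the loss-free dynamics with stability tags.

    Returns the four corners and, when it exists inside (0,1)^2, the
    interior equilibrium (-a'/b', -a/b).  Tags come from the linearised
    eigenvalues: ``stable`` (all negative), ``unstable`` (a positive
    eigenvalue; saddles included), or ``neutral`` (zero or purely
    imaginary eigenvalues -- the cyclic regime's center).  Interior-edge
    equilibria only arise on degenerate (boundary) parameter sets, where
    an entire edge consists of rest points; those continua are not
    enumerated.
    """
    if pair.strain_A.d != 0.0 or pair.strain_B.d != 0.0:
        raise ValueError("find_equilibria requires d_A = d_B = 0")
    coeffs = reduced_coefficients(pair)
    out: List[Tuple[Tuple[float, float], str]] = []
    for corner in ((0, 0), (1, 0), (0, 1), (1, 1)):
        eigs = _corner_eigenvalues(coeffs, corner)
        out.append(((float(corner[0]), float(corner[1])), _tag(eigs)))
    if coeffs.b != 0.0 and coeffs.b_prime != 0.0:
        x_B = -coeffs.a / coeffs.b
        x_A = -coeffs.a_prime / coeffs.b_prime
        if 0.0 < x_A < 1.0 and 0.0 < x_B < 1.0:
            # Jacobian is anti-diagonal at the interior point:
            # eigenvalues +-sqrt(k) with k = xA(1-xA) b * xB(1-xB) b'.
            k = (x_A * (1 - x_A) * coeffs.b) * (x_B * (1 - x_B) * coeffs.b_prime)
            tag = "neutral" if k <= 0.0 else "unstable"
            out.append(((x_A, x_B), tag))
    return out


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def _clamp(x: np.ndarray) -> np.ndarray:
    """Clamp round-off boundary excursions (within CLAMP_TOL) only."""
    y = x.copy()
    y[(y < 0.0) & (y > -CLAMP_TOL)] = 0.0
    y[(y > 1.0) & (y < 1.0 + CLAMP_TOL)] = 1.0
    return y


def _expit(u: np.ndarray) -> np.ndarray:
    from scipy.special import expit
    return expit(u)


def _logit(x: float) -> float:
    from scipy.special import logit
    return float(logit(x))


#: |logit(x)| beyond which x is numerically indistinguishable from 0/1
#: well past EQUILIBRIUM_TOL.
_U_CORNER = 16.0


def simulate_replicator(pair: PairConfig,
                        x0: Sequence[float],
                        settings: Optional[SolverSettings] = None
                        ) -> Trajectory:
    """Integrate the replicator (or replicator-mutator) dynamics.

    With d_A = d_B = 0 the reduced form is integrated in logit
    coordinates u = ln(x/(1-x)), where du/dt = a + b x_other is smooth
    and bounded: this removes the x(1-x) boundary degeneracy, which
    otherwise underflows on large-amplitude cyclic orbits that creep
    exponentially close to the faces of the unit square.  Components
    started exactly on an invariant face (x = 0, or x = 1 with no loss)
    are held there exactly.  With spacer loss the full fitness-based
    mutator form is integrated in the original coordinates (its
    attractors are interior, away from the degeneracy).

    Integration proceeds in chunks of ``settings.cycle_window``; after
    each chunk the state is tested for convergence (replicator
    vector-field norm below ``convergence_eps`` close to an equilibrium
    that is stable, or lies on the frozen face the orbit started on)
    and for cycling (a Poincare-section return within POINCARE_TOL of a
    previous crossing while the transformed flow stays bounded away
    from equilibrium over the window).
    """
    settings = settings or SolverSettings()
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (2,) or np.any(x0 < 0.0) or np.any(x0 > 1.0):
        raise ValueError(f"x0 must be two fractions in [0,1], got {x0}")

    loss_free = pair.strain_A.d == 0.0 and pair.strain_B.d == 0.0
    if loss_free:
        return _simulate_reduced_logit(pair, x0, settings)
    return _simulate_mutator(pair, x0, settings)


def _simulate_reduced_logit(pair: PairConfig, x0: np.ndarray,
                            settings: SolverSettings) -> Trajectory:
    coeffs = reduced_coefficients(pair)
    equilibria = find_equilibria(pair)
    frozen = [x0[i] in (0.0, 1.0) for i in range(2)]

    ab = np.array([[coeffs.a, coeffs.b],
                   [coeffs.a_prime, coeffs.b_prime]])

    def rhs_u(t: float, u: np.ndarray) -> np.ndarray:
        x = _expit(u)
        for i in range(2):
            if frozen[i]:
                x[i] = x0[i]
        du = np.array([ab[0, 0] + ab[0, 1] * x[1],
                       ab[1, 0] + ab[1, 1] * x[0]])
        for i in range(2):
            if frozen[i]:
                du[i] = 0.0
        return du

    u0 = np.array([_logit(x0[i]) if not frozen[i] else 0.0 for i in range(2)])

    # Poincare section through the interior equilibrium (if any).
    interior = next((pt for pt, tag in equilibria
                     if 0.0 < pt[0] < 1.0 and 0.0 < pt[1] < 1.0), None)
    events = None
    if interior is not None and not any(frozen):
        u_section = _logit(interior[1])

        def crossing(t, u):
            return u[1] - u_section
        crossing.direction = 1.0
        events = [crossing]

    stable_targets = [np.asarray(pt) for pt, tag in equilibria
                      if tag == "stable"]
    if any(frozen):
        # on an invariant face any corner of that face can attract
        stable_targets = [np.asarray(pt) for pt, _ in equilibria
                          if all(pt[i] == x0[i] for i in range(2) if frozen[i])
                          and all(v in (0.0, 1.0) for v in pt)]

    ts = [np.array([0.0])]
    us = [u0.reshape(2, 1)]
    crossings: List[np.ndarray] = []
    state = u0.copy()
    t = 0.0
    terminal = "max_time"

    while t < settings.t_max - 1e-12:
        t_next = min(t + settings.cycle_window, settings.t_max)
        sol = solve_ivp(rhs_u, (t, t_next), state, method=settings.method,
                        rtol=settings.rel_tol, atol=settings.abs_tol,
                        events=events, dense_output=False)
        if not sol.success:
            raise IntegrationError(
                f"ODE solver failed at t={sol.t[-1]:.6g}: {sol.message}")
        if sol.t.size > 1:
            ts.append(sol.t[1:])
            us.append(sol.y[:, 1:])
        state = sol.y[:, -1].copy()
        t = t_next

        # -- convergence: small replicator field near a stable target
        x = _expit(state)
        du = rhs_u(t, state)
        fnorm = float(np.linalg.norm(x * (1 - x) * du))
        if fnorm < settings.convergence_eps and any(
                np.linalg.norm(x - tgt) < EQUILIBRIUM_TOL
                for tgt in stable_targets):
            terminal = "converged"
            break

        # -- cycling: a section return while du stays away from zero
        if events is not None and sol.y_events and sol.y_events[0].size:
            for ev in np.atleast_2d(sol.y_events[0]):
                ev_x = _expit(ev)
                if any(np.linalg.norm(ev_x - prev) < POINCARE_TOL
                       for prev in crossings):
                    window = us[-1]
                    cols = range(0, window.shape[1],
                                 max(1, window.shape[1] // 50))
                    norms = [np.linalg.norm(rhs_u(0.0, window[:, j]))
                             for j in cols]
                    if not norms or min(norms) > settings.convergence_eps:
                        terminal = "cycling"
                        break
                crossings.append(ev_x.copy())
            if terminal == "cycling":
                break

    t_arr = np.concatenate(ts)
    x_arr = _expit(np.concatenate(us, axis=1))
    for i in range(2):
        if frozen[i]:
            x_arr[i, :] = x0[i]
    return Trajectory(t=t_arr, x_A=x_arr[0], x_B=x_arr[1],
                      terminal_state=terminal)


def _simulate_mutator(pair: PairConfig, x0: np.ndarray,
                      settings: SolverSettings) -> Trajectory:
    rhs = lambda t, y: replicator_rhs(pair, y)

    ts = [np.array([0.0])]
    xs = [x0.reshape(2, 1)]
    state = x0.copy()
    t = 0.0
    terminal = "max_time"
    while t < settings.t_max - 1e-12:
        t_next = min(t + settings.cycle_window, settings.t_max)
        sol = solve_ivp(rhs, (t, t_next), state, method=settings.method,
                        rtol=settings.rel_tol, atol=settings.abs_tol,
                        dense_output=False)
        if not sol.success:
            raise IntegrationError(
                f"ODE solver failed at t={sol.t[-1]:.6g}: {sol.message}")
        if sol.t.size > 1:
            ts.append(sol.t[1:])
            xs.append(_clamp(sol.y[:, 1:]))
        state = _clamp(sol.y[:, -1].copy())
        t = t_next
        # the mutator flow contracts onto isolated equilibria located by
        # the solver itself; a vanishing field is sufficient
        if float(np.linalg.norm(rhs(t, state))) < settings.convergence_eps:
            terminal = "converged"
            break

    t_arr = np.concatenate(ts)
    x_arr = np.concatenate(xs, axis=1)
    for i in range(2):
        if x0[i] == 0.0:  # x = 0 is invariant even under loss
            x_arr[i, :] = 0.0
    return Trajectory(t=t_arr, x_A=x_arr[0], x_B=x_arr[1],
                      terminal_state=terminal)


# ---------------------------------------------------------------------------
# Empirical basin classification
# ---------------------------------------------------------------------------

_ATTRACTOR_LABELS = {
    frozenset({(0, 0)}): "no_targeting",
    frozenset({(1, 0)}): "A_targets_B",
    frozenset({(0, 1)}): "B_targets_A",
    frozenset({(1, 1)}): "mutual_targeting",
    frozenset({(1, 0), (0, 1)}): "bistable_unidirectional",
    frozenset({(0, 0), (1, 1)}): "bistable_mutual_or_none",
    frozenset({"cycle"}): "cyclic",
}


def basin_classify(pair: PairConfig, n_starts: int = 12, seed: int = 0,
                   settings: Optional[SolverSettings] = None) -> str:
    """Empirical regime label from seeded interior initial conditions.

    Integrates from ``n_starts`` interior starts -- four deterministic
    probes near the corners (so that every basin of a bistable system is
    sampled) plus seeded random starts -- and maps the set of reached
    attractors (corners, or persistent cycling) onto the same label
    vocabulary as :func:`minicrispr.regimes.classify_regime`.  Purely a
    numerical cross-check; returns ``"undetermined"`` when the attractor
    set matches no known pattern.
    """
    rng = np.random.default_rng(seed)
    settings = settings or SolverSettings()
    probes = [np.array(p) for p in
              ((0.05, 0.05), (0.95, 0.05), (0.05, 0.95), (0.95, 0.95))]
    attractors = set()
    for k in range(n_starts):
        x0 = probes[k] if k < len(probes) else rng.uniform(0.05, 0.95, size=2)
        traj = simulate_replicator(pair, x0, settings)
        final = traj.final_state()
        if traj.terminal_state == "cycling":
            attractors.add("cycle")
            continue
        corner = (int(round(final[0])), int(round(final[1])))
        if (traj.terminal_state == "converged"
                and np.linalg.norm(final - np.array(corner)) < 1e-3):
            attractors.add(corner)
        elif np.linalg.norm(final - np.array(corner)) < 1e-6:
            # ran out of time but effectively at a corner
            attractors.add(corner)
        else:
            attractors.add("undetermined")
    return _ATTRACTOR_LABELS.get(frozenset(attractors), "undetermined")
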