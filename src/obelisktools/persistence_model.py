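"""Selection / segregational-loss dynamics of a high-copy extrachromosomal element.

The model follows two subpopulations of host cells: Type 1 cells carry ``N``
copies of the element (here, a viroid-like Obelisk RNA) and grow at rate
``r1``; Type 2 cells carry none and grow at rate ``r2``.  Each copy imposes a
linear fitness cost ``alpha = r2 / Nstar`` where ``Nstar`` (the element's
*capacity*) is the copy number at which the host growth rate reaches zero, so

    r1 = r2 * (1 - N / Nstar),        0 <= N < Nstar.

At division, copies are partitioned at random between the two daughters, so a
daughter inherits zero copies with probability

    mu = (1/2) ** N,

and Type 2 cells arise from Type 1 births at rate ``r1 * mu``.  Type 2 cells
never regain the element.  The abundances x = (x1, x2) obey the linear system

    dx/dt = A x,    A = [[r1 (1 - mu), 0], [r1 mu, r2]],

whose eigenvalues are the diagonal entries.  From the initial condition
x(0) = (1, 0), the closed-form *response time* t* — the first time the
element-free subpopulation equals the carrier subpopulation — is

    t* = log(1 + (r2 - r1 (1 - mu)) / (r1 mu)) / (r2 - r1 (1 - mu)).

Because ``mu`` decays geometrically in ``N``, it underflows to exactly 0.0 in
64-bit binary floating point once N reaches ``stability_threshold()`` (1075
under IEEE 754 double precision with gradual underflow), at which point the
source term vanishes and carrier cells are evolutionarily stable despite
their fitness burden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "SegregationParams",
    "PopulationState",
    "Trajectory",
    "AnalyticSolution",
    "IntegrationError",
    "DegenerateEigenvaluesError",
    "loss_probability",
    "type1_growth_rate",
    "dynamics_matrix",
    "simulate",
    "analytic_solution",
    "analytic_state",
    "analytic_states",
    "response_time",
    "crossing_time",
    "stability_threshold",
    "sweep_response_time",
    "SWEEP_COLUMNS",
]


class IntegrationError(RuntimeError):
    """The ODE solver failed; the message carries the solver diagnostic."""


class DegenerateEigenvaluesError(ValueError):
    """The two eigenvalues coincide (r2 == r1*(1-mu)); the closed form with
    distinct exponentials does not apply.  This cannot happen for valid
    parameters with N >= 1 (then r1*(1-mu) < r1 < r2) but is guarded for
    defensive use with exotic inputs."""


def _as_count(value, name: str) -> int:
    """Coerce a copy-number-like argument to a non-negative int."""
    if isinstance(value, bool):
        raise TypeError(f"{name} must be an integer, got bool")
    if isinstance(value, float):
        if not value.is_integer():
            raise ValueError(f"{name} must be an integer, got {value!r}")
        value = int(value)
    if not isinstance(value, (int, np.integer)):
        raise TypeError(f"{name} must be an integer, got {type(value).__name__}")
    value = int(value)
    if value < 0:
        raise ValueError(f"{name} must be >= 0, got {value}")
    return value


def loss_probability(N) -> float:
    """Probability (1/2)**N that a daughter cell inherits zero of N copies.

    Evaluated in 64-bit binary floating point with gradual underflow: the
    result is the smallest positive subnormal (5e-324) at N = 1074 and
    exactly 0.0 from N = 1075 on.
    """
    N = _as_count(N, "N")
    # ldexp scales by an exact power of two, so every representable value
    # (normal or subnormal) of (1/2)**N is hit exactly before underflow.
    return math.ldexp(1.0, -N)


def type1_growth_rate(r2: float, N, Nstar) -> float:
    """Growth rate r1 = r2 * (1 - N/Nstar) of element-carrying cells.

    Accepts the closed boundary N == Nstar (where r1 == 0 by the definition
    of capacity), which lies outside the open parameter range of
    :class:`SegregationParams`.
    """
    N = _as_count(N, "N")
    Nstar = _as_count(Nstar, "Nstar")
    if Nstar < 1:
        raise ValueError(f"Nstar must be >= 1, got {Nstar}")
    if N > Nstar:
        raise ValueError(f"N must be <= Nstar, got N={N}, Nstar={Nstar}")
    if not (math.isfinite(r2) and r2 > 0):
        raise ValueError(f"r2 must be positive and finite, got {r2!r}")
    return r2 * (1.0 - N / Nstar)


@dataclass(frozen=True)
class SegregationParams:
    """Free parameters of the model and their derived rates.

    Parameters
    ----------
    N : int
        Element copy number per carrier cell, ``0 <= N < Nstar``.
    Nstar : int
        Element capacity: the copy number at which the carrier growth rate
        reaches zero.  Sets the per-copy burden ``alpha = r2 / Nstar``.
    r2 : float, default 1
        Growth rate of element-free cells.  With ``r2 = 1`` all times are in
        units of the element-free exponential timescale.
    """

    N: int
    Nstar: int
    r2: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "N", _as_count(self.N, "N"))
        object.__setattr__(self, "Nstar", _as_count(self.Nstar, "Nstar"))
        if self.Nstar < 1:
            raise ValueError(f"Nstar must be >= 1, got {self.Nstar}")
        if not self.N < self.Nstar:
            raise ValueError(
                f"model requires 0 <= N < Nstar, got N={self.N}, Nstar={self.Nstar}"
            )
        r2 = float(self.r2)
        if not (math.isfinite(r2) and r2 > 0):
            raise ValueError(f"r2 must be positive and finite, got {self.r2!r}")
        object.__setattr__(self, "r2", r2)

    @property
    def mu(self) -> float:
        """Segregational loss probability (1/2)**N."""
        return loss_probability(self.N)

    @property
    def alpha(self) -> float:
        """Per-copy fitness burden r2 / Nstar."""
        return self.r2 / self.Nstar

    @property
    def r1(self) -> float:
        """Growth rate of carrier cells, r2 * (1 - N/Nstar)."""
        return type1_growth_rate(self.r2, self.N, self.Nstar)


@dataclass(frozen=True)
class PopulationState:
    """Abundances of the two subpopulations at one time point."""

    x1: float
    x2: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.x1 < 0 or self.x2 < 0:
            raise ValueError(f"abundances must be >= 0, got ({self.x1}, {self.x2})")
        if self.t < 0:
            raise ValueError(f"time must be >= 0, got {self.t}")

    @property
    def total(self) -> float:
        return self.x1 + self.x2

    @property
    def frequencies(self) -> tuple[float, float]:
        X = self.total
        if X <= 0:
            raise ValueError("frequencies undefined for an empty population")
        return (self.x1 / X, self.x2 / X)


def dynamics_matrix(params: SegregationParams) -> np.ndarray:
    """Rate matrix A = [[r1(1-mu), 0], [r1*mu, r2]].

    The first column sums to r1 exactly: every Type 1 birth yields either a
    carrier daughter (rate r1*(1-mu)) or an element-free daughter (rate
    r1*mu).  Entry (0, 1) is zero because Type 2 cells never regain copies.
    """
    r1, mu = params.r1, params.mu
    return np.array([[r1 * (1.0 - mu), 0.0], [r1 * mu, params.r2]])


@dataclass(frozen=True)
class Trajectory:
    """Time series of subpopulation abundances from one simulation."""

    params: SegregationParams
    times: np.ndarray
    states: np.ndarray  # shape (n_points, 2): columns x1, x2

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        states = np.asarray(self.states, dtype=float)
        if times.ndim != 1 or states.shape != (times.size, 2):
            raise ValueError(
                f"states must be (n, 2) aligned with times, got {states.shape}"
            )
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)

    @property
    def x1(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def x2(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def totals(self) -> np.ndarray:
        return self.states.sum(axis=1)

    @property
    def frequencies(self) -> np.ndarray:
        """Per-time fractions x_i / X; rows sum to 1."""
        return self.states / self.totals[:, None]

    def state_at(self, i: int) -> PopulationState:
        return PopulationState(
            x1=self.states[i, 0], x2=self.states[i, 1], t=self.times[i]
        )

    def to_frame(self) -> pd.DataFrame:
        freq = self.frequencies
        return pd.DataFrame(
            {
                "time": self.times,
                "x1": self.x1,
                "x2": self.x2,
                "freq1": freq[:, 0],
                "freq2": freq[:, 1],
            }
        )


def simulate(
    params: SegregationParams,
    x0: Sequence[float] = (1.0, 0.0),
    t_end: float = 50.0,
    n_points: int = 501,
    *,
    rtol: float = 1e-9,
    atol=1e-12,
    method: str = "LSODA",
    t_grid=None,
) -> Trajectory:
    """Integrate dx/dt = A x on an even time grid [0, t_end].

    Uses an adaptive, stiff-capable solver (LSODA by default) at tight
    tolerances because the eigenvalue gap ``r2 - r1(1-mu)`` can span many
    orders of magnitude when ``mu`` is tiny.  ``atol`` may be a scalar or a
    per-component pair; pass a small second component to resolve the early
    phase where x2 is orders of magnitude below x1.  ``t_grid`` overrides
    the even grid with an arbitrary strictly increasing set of output times
    (e.g. log-spaced), in which case ``t_end``/``n_points`` are ignored.
    """
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (2,) or np.any(x0 < 0) or not np.any(x0 > 0):
        raise ValueError(f"x0 must be two non-negative abundances, not both zero: {x0}")
    if t_grid is not None:
        t_eval = np.asarray(t_grid, dtype=float)
        if t_eval.ndim != 1 or t_eval.size < 1 or np.any(np.diff(t_eval) <= 0):
            raise ValueError("t_grid must be strictly increasing")
        if t_eval[0] < 0:
            raise ValueError("t_grid times must be >= 0")
        t_end = float(t_eval[-1])
    else:
        if not (t_end > 0):
            raise ValueError(f"t_end must be > 0, got {t_end}")
        if n_points < 2:
            raise ValueError(f"n_points must be >= 2, got {n_points}")
        t_eval = np.linspace(0.0, float(t_end), int(n_points))
    A = dynamics_matrix(params)
    sol = solve_ivp(
        lambda t, x: A @ x,
        (0.0, float(t_end)),
        x0,
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        jac=lambda t, x: A,
    )
    if not sol.success:
        raise IntegrationError(
            f"ODE integration failed for {params}: {sol.message}"
        )
    return Trajectory(params=params, times=sol.t, states=sol.y.T)


def analytic_solution(params: SegregationParams) -> "AnalyticSolution":
    """Eigen-decomposition constants for the initial condition x(0) = (1, 0)."""
    r1, r2, mu = params.r1, params.r2, params.mu
    eigen1 = r1 * (1.0 - mu)
    denom = r2 - eigen1
    if denom == 0.0:
        raise DegenerateEigenvaluesError(
            f"eigenvalues coincide (r2 == r1*(1-mu) == {r2}); no closed form"
        )
    return AnalyticSolution(
        params=params, eigen1=eigen1, eigen2=r2, c1=-1.0, c2=r1 * mu / denom
    )


@dataclass(frozen=True)
class AnalyticSolution:
    """Closed-form solution x(t) = c1*v1*exp(eigen1*t) + c2*v2*exp(eigen2*t)
    specialised to the initial condition x(0) = (1, 0), where c1 = -1 and
    c2 = r1*mu / (r2 - r1*(1-mu))."""

    params: SegregationParams
    eigen1: float
    eigen2: float
    c1: float
    c2: float

    def __call__(self, t) -> np.ndarray:
        """Evaluate (x1, x2) at scalar or array times t >= 0."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("times must be >= 0")
        e1 = np.exp(self.eigen1 * t)
        e2 = np.exp(self.eigen2 * t)
        x1 = e1
        x2 = self.c2 * (e2 - e1)
        return np.stack([x1, x2], axis=-1)


def analytic_state(params: SegregationParams, t: float) -> PopulationState:
    """Closed-form state at time t from the initial condition x(0) = (1, 0)."""
    x1, x2 = analytic_solution(params)(float(t))
    # Subtractive cancellation in c2*(e2 - e1) can produce a tiny negative x2
    # at very small t; clamp at zero.
    return PopulationState(x1=float(x1), x2=float(max(x2, 0.0)), t=float(t))


def analytic_states(params: SegregationParams, times) -> np.ndarray:
    """Closed-form states on an array of times; shape (n, 2)."""
    states = analytic_solution(params)(np.asarray(times, dtype=float))
    states[..., 1] = np.maximum(states[..., 1], 0.0)
    return states


def response_time(params: SegregationParams) -> float:
    """Closed-form time t* at which x2 first equals x1 from x(0) = (1, 0).

    Returns ``math.inf`` when the loss source term ``r1*mu`` underflows to
    zero (the carrier state is then numerically stable; tables use a
    'stable' sentinel instead, see :func:`sweep_response_time`).

    Raises
    ------
    ValueError
        If N == 0: then every Type 1 birth is element-free (mu == 1) and the
        printed formula degenerates.
    """
    if params.N == 0:
        raise ValueError(
            "response_time requires N >= 1; at N == 0 every division loses "
            "the element (mu == 1) and the crossing formula degenerates"
        )
    r1, mu = params.r1, params.mu
    source = r1 * mu
    if source == 0.0:
        return math.inf
    delta = params.r2 - r1 * (1.0 - mu)
    ratio = delta / source
    if math.isinf(ratio):
        # subnormal source: the ratio overflows but its log does not, and
        # log1p(x) == log(x) to double precision for such enormous x
        return (math.log(delta) - math.log(source)) / delta
    return math.log1p(ratio) / delta


def crossing_time(trajectory: Trajectory) -> float | None:
    """First time x2 >= x1 in a simulated trajectory, or None if not reached.

    Intended as a purely numerical oracle for :func:`response_time`: the
    trajectory must start from x0 = (1, 0).  The crossing is located by
    linear interpolation of x2 - x1 between the bracketing samples.
    """
    diff = trajectory.x2 - trajectory.x1
    hits = np.nonzero(diff >= 0.0)[0]
    if hits.size == 0:
        return None
    i = int(hits[0])
    if i == 0 or diff[i] == 0.0:
        return float(trajectory.times[i])
    t0, t1 = trajectory.times[i - 1], trajectory.times[i]
    d0, d1 = diff[i - 1], diff[i]
    return float(t0 + (t1 - t0) * (-d0) / (d1 - d0))


def stability_threshold() -> int:
    """Smallest copy number N with loss_probability(N) == 0.0 exactly.

    Defined relative to the 64-bit binary floating-point contract with
    gradual underflow, under which (1/2)**1074 is the smallest positive
    subnormal and (1/2)**1075 underflows to zero; the returned value is
    found by direct scan, not assumed.
    """
    N = 0
    while loss_probability(N) > 0.0:
        N += 1
    return N


SWEEP_COLUMNS = ["N", "Nstar", "r1", "mu", "t_star", "stable", "error"]


def sweep_response_time(
    N_grid: Iterable[int], Nstar_grid: Iterable[int], r2: float = 1.0
) -> pd.DataFrame:
    """Closed-form t* over the product of copy-number and capacity grids.

    Returns one row per (N, Nstar) pair with columns ``N Nstar r1 mu t_star
    stable error``.  Rows where mu has underflowed (or the source term
    ``r1*mu`` has) carry ``stable=True`` and a NaN ``t_star``.  Invalid
    pairs (N < 1 or N >= Nstar) are recorded in the ``error`` column and the
    sweep continues.
    """
    rows = []
    for N in N_grid:
        for Nstar in Nstar_grid:
            row = {
                "N": N,
                "Nstar": Nstar,
                "r1": math.nan,
                "mu": math.nan,
                "t_star": math.nan,
                "stable": False,
                "error": "",
            }
            try:
                params = SegregationParams(N=N, Nstar=Nstar, r2=r2)
                if params.N < 1:
                    raise ValueError("response time requires N >= 1")
                row["r1"], row["mu"] = params.r1, params.mu
                t_star = response_time(params)
                if math.isinf(t_star):
                    row["stable"] = True
                else:
                    row["t_star"] = t_star
            except (ValueError, TypeError) as exc:
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)
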