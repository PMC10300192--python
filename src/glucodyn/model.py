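"""Core ODE model of glucose-accessibility-limited tumour cell growth.

The model tracks live cells ``N(t)``, dead cells ``D(t)`` and extracellular
glucose ``G_total(t)`` in one culture well over a four-day experiment:

.. math::

    dN/dt &= k_p N (1 - N/\\theta) S_p - k_d N S_d - k_{bys} N D/(D+N) \\\\
    dD/dt &= k_d N S_d + k_{bys} N D/(D+N) \\\\
    dG_{total}/dt &= -v N \\, G_{acs}/(G_{acs} + G^*)

Proliferation is logistic, scaled by the state function
``S_p = 1 - S_d``; starvation death is scaled by
``S_d = (1 - G_acs/(G_acs + G_min)) tanh(t)``, which ramps in over roughly
the first two days and saturates when accessible glucose is exhausted.
The bystander term models death of live cells driven by factors released
by accumulated dead cells, proportional to the dead-cell fraction.

A glucose-uptake inhibitor (Cytochalasin B, a competitive GLUT1 blocker)
enters through a single dose-dependent inhibition constant ``G_in`` that
reduces the glucose *accessible* to the cells,

.. math:: G_{acs} = G_{total} / (1 + G_{in} N),

so an untreated well (``G_in = 0``) reduces exactly to the baseline,
treatment-free model.

Units: time in days (``t = 0`` at the medium change), glucose in mM, cells
as counts; measured confluence (percent of well area covered) converts to
cells through the carrying capacity ``theta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "GlobalParams",
    "BystanderRelation",
    "InhibitionParams",
    "ModelState",
    "Well",
    "TimeCourse",
    "SimulationResult",
    "IntegrationError",
    "default_time_grid",
    "state_functions",
    "accessible_glucose",
    "bystander_rate",
    "rhs",
    "simulate_forward",
    "simulate_batch",
    "confluence_to_cells",
    "cells_to_confluence",
]


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails to meet its tolerances."""


def default_time_grid() -> np.ndarray:
    """Sampling grid of the experiments: every 3 h for 4 days (33 points)."""
    return np.arange(33) * 0.125


@dataclass(frozen=True)
class GlobalParams:
    """Cell-line-level rates and constants.

    Defaults are the literature/previously-calibrated values for the
    MDA-MB-231 line.

    k_p : proliferation rate, 1/day
    k_d : starvation (glucose-depletion) death rate, 1/day
    v : glucose consumption rate, mM/(cell day)
    theta : carrying capacity of one well, cells
    G_star : Michaelis-Menten constant of consumption, mM
    G_min : minimum glucose level for uptake/proliferation, mM
    """

    k_p: float = 0.14
    k_d: float = 0.041
    v: float = 4.48e-5
    theta: float = 8e4
    G_star: float = 0.5
    G_min: float = 0.01

    def __post_init__(self) -> None:
        for name in ("k_p", "k_d", "v", "theta", "G_star", "G_min"):
            val = getattr(self, name)
            if not (np.isfinite(val) and val > 0):
                raise ValueError(f"GlobalParams.{name} must be finite and > 0, got {val!r}")


@dataclass(frozen=True)
class BystanderRelation:
    """Exponential-decay law for the bystander death rate.

    ``k_bys(G0) = k_bys_0 * exp(-alpha * G0) + beta`` where ``G0`` is the
    initial (accessible) glucose level of the well.  ``k_bys_0`` is the
    maximum rate under glucose scarcity, ``alpha`` the glucose dependence
    (1/mM) and ``beta`` a baseline offset (1/day).
    """

    k_bys_0: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("k_bys_0", "alpha", "beta"):
            val = getattr(self, name)
            if not (np.isfinite(val) and val >= 0):
                raise ValueError(f"BystanderRelation.{name} must be finite and >= 0, got {val!r}")

    def rate(self, G0):
        """Evaluate k_bys at initial glucose ``G0`` (scalar or array, mM)."""
        G0 = np.asarray(G0, dtype=float)
        if np.any(G0 < 0):
            raise ValueError("initial glucose must be >= 0")
        out = self.k_bys_0 * np.exp(-self.alpha * G0) + self.beta
        return float(out) if out.ndim == 0 else out


def bystander_rate(G0, rel: BystanderRelation):
    """Bystander death rate at initial glucose ``G0`` (1/day)."""
    return rel.rate(G0)


@dataclass(frozen=True)
class InhibitionParams:
    """Map from inhibitor dose (uM) to the inhibition constant G_in (1/cell).

    Dose 0 must map to G_in = 0: no treatment means accessible glucose
    equals total glucose.
    """

    g_in: Mapping[float, float] = field(default_factory=lambda: {0.0: 0.0})

    def __post_init__(self) -> None:
        clean = {}
        for dose, gin in self.g_in.items():
            dose = float(dose)
            gin = float(gin)
            if dose < 0 or gin < 0 or not np.isfinite(gin):
                raise ValueError(f"invalid inhibition entry dose={dose}, G_in={gin}")
            if dose == 0.0 and gin != 0.0:
                raise ValueError("dose 0 must map to G_in = 0")
            clean[dose] = gin
        object.__setattr__(self, "g_in", clean)

    @classmethod
    def default(cls) -> "InhibitionParams":
        """Point estimates for Cytochalasin B at 0 / 2 / 10 uM."""
        return cls({0.0: 0.0, 2.0: 3.02e-4, 10.0: 4.55e-4})

    def for_dose(self, dose: float) -> float:
        dose = float(dose)
        if dose == 0.0:
            return 0.0
        if dose not in self.g_in:
            raise KeyError(f"no inhibition constant for dose {dose} uM; known doses: {sorted(self.g_in)}")
        return self.g_in[dose]

    @property
    def doses(self) -> tuple:
        return tuple(sorted(self.g_in))


@dataclass(frozen=True)
class ModelState:
    """Instantaneous state of one well: live cells, dead cells, glucose, time."""

    N: float
    D: float
    G_total: float
    t: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.N, self.D, self.G_total, self.t)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"non-finite model state {vals}")
        if self.N < 0 or self.D < 0 or self.G_total < 0 or self.t < 0:
            raise ValueError(f"model state components must be >= 0, got {vals}")


@dataclass(frozen=True)
class Well:
    """One culture well's design point.

    ``initial_confluence`` and ``initial_dead_confluence`` are area
    fractions in [0, 1]; ``G0`` is the initial glucose in mM and ``dose``
    the Cytochalasin B dose in uM.
    """

    well_id: str
    initial_confluence: float
    G0: float
    dose: float = 0.0
    replicate: int = 1
    dataset_tag: str = "A"
    initial_dead_confluence: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.initial_confluence <= 1.0:
            raise ValueError(f"initial_confluence must be in [0, 1], got {self.initial_confluence}")
        if not 0.0 <= self.initial_dead_confluence <= 1.0:
            raise ValueError("initial_dead_confluence must be in [0, 1]")
        if self.G0 < 0:
            raise ValueError("G0 must be >= 0")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")


@dataclass
class TimeCourse:
    """Paired live/dead confluence trajectories (percent) on a shared grid."""

    times: np.ndarray
    live: np.ndarray
    dead: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.live = np.asarray(self.live, dtype=float)
        self.dead = np.asarray(self.dead, dtype=float)
        if not (self.times.shape == self.live.shape == self.dead.shape):
            raise ValueError("times, live and dead must have equal lengths")
        if self.times.size < 1 or self.times[0] < 0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing and start at >= 0")
        eps = 1e-6
        if np.any(self.live < -eps) or np.any(self.dead < -eps):
            raise ValueError("confluence values must be >= 0")
        if np.any(self.live > 100 + eps):
            raise ValueError("live confluence cannot exceed 100%")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class SimulationResult:
    """Forward simulation output: confluence course plus glucose trajectories."""

    course: TimeCourse
    n_cells: np.ndarray
    d_cells: np.ndarray
    g_total: np.ndarray
    g_acs: np.ndarray


# ---------------------------------------------------------------------------
# elementary model functions
# ---------------------------------------------------------------------------

def state_functions(G_acs, t, G_min: float):
    """Complementary proliferation/death scalings ``(S_p, S_d)``.

    ``S_d = (1 - G_acs/(G_acs + G_min)) * tanh(t)`` and ``S_p = 1 - S_d``.
    Both lie in [0, 1]; time is in days.
    """
    G_acs = np.asarray(G_acs, dtype=float)
    t = np.asarray(t, dtype=float)
    if G_min <= 0:
        raise ValueError("G_min must be > 0")
    if np.any(G_acs < 0) or np.any(t < 0):
        raise ValueError("G_acs and t must be >= 0")
    s_d = (1.0 - G_acs / (G_acs + G_min)) * np.tanh(t)
    s_p = 1.0 - s_d
    if s_d.ndim == 0:
        return float(s_p), float(s_d)
    return s_p, s_d


def accessible_glucose(G_total, N, G_in):
    """Glucose accessible to cells under uptake inhibition (mM).

    ``G_acs = G_total / (1 + G_in * N)``; equals ``G_total`` iff
    ``G_in * N == 0``.
    """
    G_total = np.asarray(G_total, dtype=float)
    N = np.asarray(N, dtype=float)
    G_in = np.asarray(G_in, dtype=float)
    if np.any(G_total < 0) or np.any(N < 0) or np.any(G_in < 0):
        raise ValueError("G_total, N and G_in must all be >= 0")
    out = G_total / (1.0 + G_in * N)
    return float(out) if out.ndim == 0 else out


def confluence_to_cells(confluence_pct, theta: float):
    """Convert confluence (percent of well area) to a cell count."""
    confluence_pct = np.asarray(confluence_pct, dtype=float)
    if np.any(confluence_pct < 0) or np.any(confluence_pct > 100):
        raise ValueError("confluence must be in [0, 100] percent")
    out = confluence_pct / 100.0 * theta
    return float(out) if out.ndim == 0 else out


def cells_to_confluence(cells, theta: float):
    """Convert a cell count to confluence (percent of well area)."""
    cells = np.asarray(cells, dtype=float)
    if np.any(cells < 0) or np.any(cells > theta * (1 + 1e-12)):
        raise ValueError("cell count must be in [0, theta]")
    out = 100.0 * cells / theta
    return float(out) if out.ndim == 0 else out


def rhs(state: ModelState, params: GlobalParams, k_bys: float, G_in: float):
    """Right-hand side ``(dN/dt, dD/dt, dG_total/dt)`` at one state.

    The bystander fraction ``D/(D+N)`` is defined as 0 when ``D + N == 0``
    (no cells, no bystander death).
    """
    if k_bys < 0 or G_in < 0:
        raise ValueError("k_bys and G_in must be >= 0")
    dN, dD, dG = _derivatives(
        np.asarray(state.N, float), np.asarray(state.D, float),
        np.asarray(state.G_total, float), state.t,
        params, np.asarray(k_bys, float), np.asarray(G_in, float),
    )
    return float(dN), float(dD), float(dG)


def _derivatives(N, D, G, t, params: GlobalParams, k_bys, G_in):
    """Vectorized model derivatives; negative state components are clamped
    to 0 inside the rate laws so adaptive steps cannot produce NaNs."""
    N = np.maximum(N, 0.0)
    D = np.maximum(D, 0.0)
    G = np.maximum(G, 0.0)
    g_acs = G / (1.0 + G_in * N)
    s_d = (1.0 - g_acs / (g_acs + params.G_min)) * math.tanh(t)
    s_p = 1.0 - s_d
    total = N + D
    bys_frac = np.divide(D, total, out=np.zeros_like(np.asarray(total, float)), where=total > 0)
    death = params.k_d * N * s_d + k_bys * N * bys_frac
    dN = params.k_p * N * (1.0 - N / params.theta) * s_p - death
    dD = death
    dG = -params.v * N * g_acs / (g_acs + params.G_star)
    return dN, dD, dG


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

# Post-integration clipping tolerances: excursions below zero larger than
# these indicate solver failure rather than roundoff.
_CLIP_TOL_CELLS = 1.0      # cells (= 1.25e-3 confluence points at theta 8e4)
_CLIP_TOL_GLUCOSE = 1e-5   # mM


def _clip_nonnegative(arr: np.ndarray, tol: float, what: str) -> np.ndarray:
    low = arr.min() if arr.size else 0.0
    if low < -tol:
        raise IntegrationError(f"{what} reached {low:.3g}, beyond the clipping tolerance {tol:g}")
    return np.maximum(arr, 0.0)


def simulate_batch(
    n0: np.ndarray,
    d0: np.ndarray,
    g0: np.ndarray,
    k_bys: np.ndarray,
    g_in: np.ndarray,
    params: GlobalParams,
    time_grid: np.ndarray | None = None,
    *,
    rtol: float = 1e-6,
    method: str = "RK45",
):
    """Integrate many independent wells at once.

    All per-well arguments are broadcast to a common length ``m``; the
    stacked system (3 m states) is handed to one adaptive solver call with
    a fully vectorized right-hand side, which is what makes the nested
    calibration loops affordable.  Returns ``(N, D, G)`` arrays of shape
    ``(m, len(time_grid))`` in cells / mM.
    """
    if time_grid is None:
        time_grid = default_time_grid()
    time_grid = np.asarray(time_grid, dtype=float)
    n0, d0, g0, k_bys, g_in = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(a, dtype=float)) for a in (n0, d0, g0, k_bys, g_in))
    )
    m = n0.size
    if np.any(k_bys < 0) or np.any(g_in < 0):
        raise ValueError("k_bys and G_in must be >= 0")
    y0 = np.concatenate([n0, d0, g0]).astype(float)

    def fun(t, y):
        N = y[:m]
        D = y[m : 2 * m]
        G = y[2 * m :]
        dN, dD, dG = _derivatives(N, D, G, t, params, k_bys, g_in)
        return np.concatenate([dN, dD, dG])

    atol = np.concatenate([
        np.full(m, 1e-6),   # cells
        np.full(m, 1e-6),   # cells
        np.full(m, 1e-9),   # mM
    ])
    t_span = (float(time_grid[0]), float(time_grid[-1]))
    if time_grid.size == 1:
        return n0.reshape(-1, 1), d0.reshape(-1, 1), g0.reshape(-1, 1)
    sol = solve_ivp(fun, t_span, y0, method=method, t_eval=time_grid, rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    y = sol.y
    N = _clip_nonnegative(y[:m], _CLIP_TOL_CELLS, "live cell count")
    D = _clip_nonnegative(y[m : 2 * m], _CLIP_TOL_CELLS, "dead cell count")
    G = _clip_nonnegative(y[2 * m :], _CLIP_TOL_GLUCOSE, "glucose")
    return N, D, G


def simulate_forward(
    well: Well,
    params: GlobalParams,
    k_bys: float,
    g_in: float,
    time_grid: np.ndarray | None = None,
    *,
    rtol: float = 1e-8,
    method: str = "LSODA",
) -> SimulationResult:
    """Simulate one well forward from its initial conditions.

    ``N(0) = initial_confluence * theta``, ``D(0)`` from the well's initial
    dead confluence (default 0), ``G_total(0) = G0``.  Returns confluence
    time courses (percent) along with the cell-count and glucose
    (total and accessible) trajectories.
    """
    if time_grid is None:
        time_grid = default_time_grid()
    n0 = well.initial_confluence * params.theta
    d0 = well.initial_dead_confluence * params.theta
    N, D, G = simulate_batch(
        np.array([n0]), np.array([d0]), np.array([well.G0]),
        np.array([float(k_bys)]), np.array([float(g_in)]),
        params, time_grid, rtol=rtol, method=method,
    )
    N, D, G = N[0], D[0], G[0]
    g_acs = G / (1.0 + float(g_in) * N)
    course = TimeCourse(
        times=np.asarray(time_grid, dtype=float),
        live=100.0 * N / params.theta,
        dead=100.0 * D / params.theta,
    )
    return SimulationResult(course=course, n_cells=N, d_cells=D, g_total=G, g_acs=g_acs)
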