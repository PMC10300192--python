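"""Multi-stage calibration of the growth model.

The workflow proceeds in seven stages:

1. Fit the cell-line globals (k_p, k_d, v) jointly to the untreated
   dataset, with one free bystander rate k_bys per well.
2. Fit the exponential-decay relation k_bys(G0) to the per-well rates.
3. Express k_bys as a function of the inhibition constant G_in through the
   accessible initial glucose of each treated well.
4. With k_bys pinned by step 3, estimate one G_in per nonzero dose from the
   treated dataset, with confidence intervals.
5. Re-fit the treated dataset with k_bys free per well and G_in constrained
   inside its step-4 interval.
6. Check that the free k_bys estimates still decay with accessible initial
   glucose (they should correlate more strongly with accessible than with
   total glucose) and, if so, refit the relation on the accessible scale.
7. Predict unseen wells from initial conditions alone.

All residuals are unweighted confluence differences (percent points),
pooled over live and dead channels, wells and time points.  The
globals-plus-locals problems are solved nested: for any trial global
vector, each well's scalar k_bys is optimized independently by a
vectorized bracketing grid refinement (all wells x candidates integrated
in a single batched ODE solve); the outer bound-constrained least-squares
then works on the concentrated objective.  At the inner optimum the
partial Jacobian with the local rates held fixed yields the exact
gradient of the concentrated objective (envelope argument), so the outer
solver sees consistent derivatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .datasets import Dataset
from .model import (
    BystanderRelation,
    GlobalParams,
    InhibitionParams,
    SimulationResult,
    Well,
    accessible_glucose,
    simulate_batch,
    simulate_forward,
)

__all__ = [
    "CalibrationResult",
    "RelationFit",
    "GinFit",
    "AccessibleRefit",
    "IdentifiabilityError",
    "fit_dataset_a",
    "fit_kbys_relation",
    "kbys_as_function_of_gin",
    "fit_gin_constrained",
    "fit_gin_and_local_kbys",
    "refit_relation_accessible",
    "predict",
    "linearized_intervals",
    "bootstrap_intervals",
    "confidence_intervals",
]

GLOBAL_BOUNDS = {"k_p": (0.0, 5.0), "k_d": (0.0, 5.0), "v": (0.0, 1e-3)}
KBYS_BOUNDS = (0.0, 5.0)
GIN_BOUNDS = (0.0, 1e-2)


class IdentifiabilityError(RuntimeError):
    """Raised when the data cannot constrain the requested parameter."""


@dataclass
class CalibrationResult:
    """Estimates, intervals and diagnostics from one calibration stage."""

    stage: str
    globals_: dict[str, float] = field(default_factory=dict)
    global_ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    local_kbys: dict[str, float] = field(default_factory=dict)
    local_kbys_ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    objective: float = np.nan
    per_well_sse: dict[str, float] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (lo, hi) in {**self.global_ci, **self.local_kbys_ci}.items():
            est = self.globals_.get(name, self.local_kbys.get(name))
            if est is not None and not (lo - 1e-12 <= est <= hi + 1e-12):
                raise ValueError(f"interval for {name} does not contain its estimate")


@dataclass
class RelationFit:
    """Fitted bystander decay law with 95% intervals."""

    relation: BystanderRelation
    ci: dict[str, tuple[float, float]]
    cov: np.ndarray
    diagnostics: dict = field(default_factory=dict)


@dataclass
class GinFit:
    """Per-dose inhibition-constant estimate with a 95% interval."""

    dose: float
    value: float
    ci: tuple[float, float]
    diagnostics: dict = field(default_factory=dict)


@dataclass
class AccessibleRefit:
    """Outcome of the accessible-glucose consistency check (step 6)."""

    corr_total: float
    corr_accessible: float
    trend_rho: float
    trend_p: float
    pattern_confirmed: bool
    relation: BystanderRelation
    relation_fit: RelationFit | None = None


# ---------------------------------------------------------------------------
# batched data blocks and the nested local optimizer
# ---------------------------------------------------------------------------

@dataclass
class _WellBlock:
    ids: list[str]
    n0: np.ndarray
    d0: np.ndarray
    g0: np.ndarray
    obs_live: np.ndarray   # (m, T) confluence %
    obs_dead: np.ndarray
    time_grid: np.ndarray

    @property
    def m(self) -> int:
        return len(self.ids)


def _block(dataset: Dataset, theta: float, wells: Sequence[Well] | None = None) -> _WellBlock:
    wells = list(wells) if wells is not None else list(dataset.wells)
    ids = [w.well_id for w in wells]
    tcs = [dataset.courses[i] for i in ids]
    return _WellBlock(
        ids=ids,
        n0=np.array([w.initial_confluence * theta for w in wells]),
        d0=np.array([w.initial_dead_confluence * theta for w in wells]),
        g0=np.array([w.G0 for w in wells]),
        obs_live=np.stack([tc.live for tc in tcs]),
        obs_dead=np.stack([tc.dead for tc in tcs]),
        time_grid=dataset.time_grid,
    )


def _residual_matrix(block: _WellBlock, params: GlobalParams, kbys: np.ndarray,
                     gin: np.ndarray, rtol: float) -> np.ndarray:
    """Signed residuals (simulated - observed), shape (m, 2T) in confluence %."""
    N, D, _ = simulate_batch(block.n0, block.d0, block.g0, kbys, gin, params,
                             block.time_grid, rtol=rtol)
    scale = 100.0 / params.theta
    return np.concatenate([N * scale - block.obs_live, D * scale - block.obs_dead], axis=1)


def _best_kbys(block: _WellBlock, params: GlobalParams, gin: np.ndarray, *,
               bounds: tuple[float, float] = KBYS_BOUNDS, n_grid: int = 12,
               passes: int = 7, rtol: float = 1e-6) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Per-well scalar k_bys by vectorized bracketing grid refinement.

    Every pass evaluates ``n_grid`` candidates for all wells in one batched
    solve and shrinks each well's bracket around its best candidate; the
    final precision is ``(hi-lo) * (2/(n_grid-1))**passes`` (~3e-5 on the
    default bounds).  Returns (k, per-well SSE, per-pass pooled SSE trace).
    """
    m = block.m
    T = block.time_grid.size
    lo = np.full(m, float(bounds[0]))
    hi = np.full(m, float(bounds[1]))
    gin = np.broadcast_to(np.asarray(gin, float), (m,))
    frac = np.linspace(0.0, 1.0, n_grid)
    best_k = np.full(m, np.nan)
    best_sse = np.full(m, np.inf)
    trace: list[float] = []
    rep = lambda a: np.repeat(a, n_grid)
    for _ in range(passes):
        cand = lo[:, None] + (hi - lo)[:, None] * frac[None, :]
        N, D, _ = simulate_batch(rep(block.n0), rep(block.d0), rep(block.g0),
                                 cand.ravel(), rep(gin), params, block.time_grid, rtol=rtol)
        scale = 100.0 / params.theta
        res_live = N.reshape(m, n_grid, T) * scale - block.obs_live[:, None, :]
        res_dead = D.reshape(m, n_grid, T) * scale - block.obs_dead[:, None, :]
        sse = (res_live**2).sum(axis=2) + (res_dead**2).sum(axis=2)  # (m, n_grid)
        idx = sse.argmin(axis=1)
        best_sse = sse[np.arange(m), idx]
        best_k = cand[np.arange(m), idx]
        trace.append(float(best_sse.sum()))
        lo = cand[np.arange(m), np.maximum(idx - 1, 0)]
        hi = cand[np.arange(m), np.minimum(idx + 1, n_grid - 1)]
    return best_k, best_sse, trace


# ---------------------------------------------------------------------------
# confidence intervals
# ---------------------------------------------------------------------------

def linearized_intervals(estimates: np.ndarray, jac: np.ndarray, residuals: np.ndarray,
                         level: float = 0.95) -> np.ndarray:
    """95% (default) intervals from the linearized residual covariance.

    ``cov = s^2 (J^T J)^{-1}`` with ``s^2 = SSR / (n - p)``.  Zero
    residuals give zero-width intervals.  Raises ``LinAlgError`` when the
    Jacobian is singular (callers may fall back to the bootstrap).
    """
    residuals = np.asarray(residuals, float).ravel()
    jac = np.asarray(jac, float)
    n, p = jac.shape
    dof = max(n - p, 1)
    s2 = float(residuals @ residuals) / dof
    jtj = jac.T @ jac
    cond = np.linalg.cond(jtj)
    if not np.isfinite(cond) or cond > 1e14:
        raise np.linalg.LinAlgError("singular residual Jacobian")
    cov = s2 * np.linalg.inv(jtj)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    tcrit = stats.t.ppf(0.5 + level / 2.0, dof)
    est = np.asarray(estimates, float)
    return np.column_stack([est - tcrit * se, est + tcrit * se])


def bootstrap_intervals(refit: Callable[[Sequence], np.ndarray], units: Sequence,
                        n_boot: int = 200, seed: int = 0, level: float = 0.95) -> np.ndarray:
    """Non-parametric bootstrap over resampling units (wells).

    ``refit`` maps a resampled list of units to a parameter vector.
    Refuses fewer than two units.
    """
    units = list(units)
    if len(units) < 2:
        raise ValueError("bootstrap needs at least 2 resampling units")
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_boot):
        sample = [units[i] for i in rng.integers(0, len(units), len(units))]
        draws.append(np.asarray(refit(sample), float))
    draws = np.stack(draws)
    lo = np.percentile(draws, 100 * (0.5 - level / 2), axis=0)
    hi = np.percentile(draws, 100 * (0.5 + level / 2), axis=0)
    return np.column_stack([lo, hi])


def confidence_intervals(estimates, jac=None, residuals=None, *, method: str = "linearized",
                         refit=None, units=None, n_boot: int = 200, seed: int = 0,
                         level: float = 0.95) -> np.ndarray:
    """Dispatch to linearized (default) or bootstrap intervals.

    A singular Jacobian triggers a bootstrap fallback (with a warning)
    when ``refit``/``units`` are supplied.
    """
    if method == "linearized":
        try:
            return linearized_intervals(estimates, jac, residuals, level)
        except np.linalg.LinAlgError:
            if refit is None or units is None:
                raise
            warnings.warn("singular Jacobian; falling back to well bootstrap", stacklevel=2)
            return bootstrap_intervals(refit, units, n_boot, seed, level)
    if method == "bootstrap":
        return bootstrap_intervals(refit, units, n_boot, seed, level)
    raise ValueError(f"unknown CI method {method!r}")


# ---------------------------------------------------------------------------
# step 1: globals + per-well k_bys on the untreated dataset
# ---------------------------------------------------------------------------

def fit_dataset_a(
    dataset: Dataset,
    *,
    base: GlobalParams | None = None,
    x0: Sequence[float] | None = None,
    n_starts: int = 1,
    seed: int = 0,
    rtol: float = 1e-6,
    kbys_bounds: tuple[float, float] = KBYS_BOUNDS,
    compute_ci: bool = True,
) -> CalibrationResult:
    """Step 1: shared (k_p, k_d, v) plus one k_bys per untreated well.

    ``base`` carries the fixed constants (theta, G_star, G_min); its rate
    entries also serve as the default initial guess (the literature values
    for this cell line).  ``n_starts > 1`` adds log-uniform restarts drawn
    with ``seed``.
    """
    base = base or GlobalParams()
    if any(w.dose != 0 for w in dataset.wells):
        raise ValueError("step-1 calibration expects an untreated (dose 0) dataset")
    if len(dataset.wells) == 0:
        raise ValueError("empty dataset")
    if len(dataset.wells) == 1:
        warnings.warn("single-well dataset: global rates are weakly identifiable", stacklevel=2)

    block = _block(dataset, base.theta)
    gin = np.zeros(block.m)
    lb = np.array([GLOBAL_BOUNDS[k][0] for k in ("k_p", "k_d", "v")])
    ub = np.array([GLOBAL_BOUNDS[k][1] for k in ("k_p", "k_d", "v")])
    cache: dict[tuple, tuple[np.ndarray, np.ndarray, list[float]]] = {}
    nfev = [0]
    inner_traces: list[list[float]] = []

    def params_of(g):
        return GlobalParams(k_p=max(g[0], 1e-12), k_d=max(g[1], 1e-12), v=max(g[2], 1e-15),
                            theta=base.theta, G_star=base.G_star, G_min=base.G_min)

    def inner(g):
        key = tuple(np.round(np.asarray(g, float), 15))
        if key not in cache:
            k, sse, trace = _best_kbys(block, params_of(g), gin, bounds=kbys_bounds, rtol=rtol)
            cache[key] = (k, sse, trace)
            inner_traces.append(trace)
            nfev[0] += 1
        return cache[key]

    def residual(g):
        k, _, _ = inner(g)
        return _residual_matrix(block, params_of(g), k, gin, rtol).ravel()

    def jac(g):
        # envelope: hold the inner-optimal k fixed while differencing globals
        k, _, _ = inner(g)
        g = np.asarray(g, float)
        base_res = _residual_matrix(block, params_of(g), k, gin, rtol).ravel()
        cols = []
        for j in range(3):
            # FD step must clear the ODE-tolerance noise floor of the residuals
            step = max(1e-4 * abs(g[j]), 1e-8)
            gp = g.copy()
            gp[j] = min(g[j] + step, ub[j])
            res_p = _residual_matrix(block, params_of(gp), k, gin, rtol).ravel()
            cols.append((res_p - base_res) / (gp[j] - g[j]))
        return np.column_stack(cols)

    starts = [np.array([base.k_p, base.k_d, base.v]) if x0 is None else np.asarray(x0, float)]
    if n_starts > 1:
        rng = np.random.default_rng(seed)
        lo_log = np.log([1e-3, 1e-3, 1e-7])
        hi_log = np.log([ub[0], ub[1], ub[2]])
        for _ in range(n_starts - 1):
            starts.append(np.exp(rng.uniform(lo_log, hi_log)))

    best = None
    for s in starts:
        res = optimize.least_squares(
            residual, np.clip(s, lb + 1e-12, ub), jac=jac, bounds=(lb, ub),
            x_scale=np.array([0.1, 0.05, 1e-5]), method="trf",
            ftol=1e-8, xtol=1e-8, max_nfev=30,
        )
        if best is None or res.cost < best.cost:
            best = res

    # Joint Gauss-Newton polish over (globals, every k_bys).  The nested
    # phase tracks the k_d <-> k_bys valley only approximately (its
    # concentrated Jacobian ignores the local-rate coupling); the joint
    # problem's full-but-cheap Jacobian restores quadratic convergence.
    k_start, _, _ = inner(best.x)
    m = block.m

    def joint_residual(x):
        return _residual_matrix(block, params_of(x[:3]), x[3:], gin, rtol).ravel()

    def joint_jac(x):
        g, k = x[:3], x[3:]
        base_res = _residual_matrix(block, params_of(g), k, gin, rtol)
        gcols = []
        for j in range(3):
            step = max(1e-4 * abs(g[j]), 1e-8)
            gp = g.copy()
            gp[j] = min(g[j] + step, ub[j])
            res_p = _residual_matrix(block, params_of(gp), k, gin, rtol)
            gcols.append(((res_p - base_res) / (gp[j] - g[j])).ravel())
        return _full_jacobian(block, params_of(g), k, gin, base_res.ravel(), rtol,
                              globals_cols=np.column_stack(gcols))

    x0_joint = np.concatenate([best.x, k_start])
    lb_joint = np.concatenate([lb, np.full(m, kbys_bounds[0])])
    ub_joint = np.concatenate([ub, np.full(m, kbys_bounds[1])])
    joint = optimize.least_squares(
        joint_residual, np.clip(x0_joint, lb_joint, ub_joint), jac=joint_jac,
        bounds=(lb_joint, ub_joint),
        x_scale=np.concatenate([[0.1, 0.05, 1e-5], np.full(m, 0.05)]),
        method="trf", ftol=1e-10, xtol=1e-10, max_nfev=40,
    )
    g_hat = joint.x[:3]
    k_hat = joint.x[3:]
    params_hat = params_of(g_hat)
    resid = _residual_matrix(block, params_hat, k_hat, gin, rtol)
    per_sse = (resid**2).sum(axis=1)
    objective = float(per_sse.sum())
    best = joint

    result = CalibrationResult(
        stage="dataset_A_globals",
        globals_={"k_p": float(g_hat[0]), "k_d": float(g_hat[1]), "v": float(g_hat[2])},
        local_kbys={i: float(k) for i, k in zip(block.ids, k_hat)},
        objective=objective,
        per_well_sse={i: float(s) for i, s in zip(block.ids, per_sse)},
        diagnostics={
            "success": bool(best.success),
            "message": best.message,
            "n_outer_evals": nfev[0],
            "initial_cost_trace": inner_traces[0] if inner_traces else [],
            "n_starts": len(starts),
        },
    )
    if not best.success:
        warnings.warn(f"step-1 optimizer did not converge: {best.message}", stacklevel=2)

    if compute_ci:
        full_jac = joint_jac(joint.x)
        ci = linearized_intervals(np.concatenate([g_hat, k_hat]), full_jac, resid.ravel())
        result.global_ci = {name: (float(ci[j, 0]), float(ci[j, 1]))
                            for j, name in enumerate(("k_p", "k_d", "v"))}
        result.local_kbys_ci = {i: (float(ci[3 + j, 0]), float(ci[3 + j, 1]))
                                for j, i in enumerate(block.ids)}
    return result


def _full_jacobian(block: _WellBlock, params: GlobalParams, kbys: np.ndarray,
                   gin: np.ndarray, base_res: np.ndarray, rtol: float,
                   globals_cols: np.ndarray | None = None) -> np.ndarray:
    """Residual Jacobian over (globals..., k_bys per well).

    Exploits the block structure: one perturbed batch solve with all local
    rates shifted at once fills every k column, because each well's
    residual rows depend only on its own rate.
    """
    m = block.m
    T = block.time_grid.size
    n_res = 2 * T * m
    n_glob = 0 if globals_cols is None else globals_cols.shape[1]
    J = np.zeros((n_res, n_glob + m))
    if globals_cols is not None:
        J[:, :n_glob] = globals_cols
    step = np.maximum(1e-6 * np.abs(kbys), 1e-8)
    res_p = _residual_matrix(block, params, kbys + step, gin, rtol)  # (m, 2T)
    base_mat = base_res.reshape(m, 2 * T)
    dcol = (res_p - base_mat) / step[:, None]
    for i in range(m):  # rows of well i in the raveled (m, 2T) layout
        J[i * 2 * T : (i + 1) * 2 * T, n_glob + i] = dcol[i]
    return J


# ---------------------------------------------------------------------------
# step 2 (and 6): the bystander decay law
# ---------------------------------------------------------------------------

def fit_kbys_relation(
    g0: Sequence[float],
    kbys: Sequence[float],
    *,
    level: float = 0.95,
) -> RelationFit:
    """Fit ``k_bys = k_bys_0 exp(-alpha G0) + beta`` by bounded NLS.

    Requires at least 4 pairs spanning at least 2 distinct glucose levels.
    All three coefficients are bounded below by 0, so the fitted curve is
    non-increasing by construction.
    """
    g0 = np.asarray(g0, float)
    kbys = np.asarray(kbys, float)
    if g0.size != kbys.size or g0.size < 4:
        raise ValueError("need at least 4 (G0, k_bys) pairs")
    if np.unique(g0).size < 2:
        raise ValueError("degenerate design: k_bys relation needs >= 2 distinct glucose levels")

    span = float(g0.max() - g0.min())
    k_lo, k_hi = float(kbys.min()), float(kbys.max())
    p0 = [max(k_hi - k_lo, 1e-6), 1.0 / max(span, 1e-6), max(k_lo, 1e-8)]

    def f(g, k0, a, b):
        return k0 * np.exp(-a * g) + b

    popt, pcov = optimize.curve_fit(f, g0, kbys, p0=p0, bounds=(0.0, np.inf), maxfev=20000)
    rel = BystanderRelation(*[float(p) for p in popt])
    resid = kbys - f(g0, *popt)
    dof = max(g0.size - 3, 1)
    tcrit = stats.t.ppf(0.5 + level / 2.0, dof)
    se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    names = ("k_bys_0", "alpha", "beta")
    ci = {n: (float(p - tcrit * s), float(p + tcrit * s)) for n, p, s in zip(names, popt, se)}
    return RelationFit(relation=rel, ci=ci, cov=pcov,
                       diagnostics={"sse": float(resid @ resid), "n": int(g0.size)})


def kbys_as_function_of_gin(well: Well, params: GlobalParams,
                            rel: BystanderRelation) -> Callable[[float], float]:
    """Step 3: k_bys as a function of G_in for one well.

    ``k_bys(G_in) = k_bys_0 exp(-alpha G_acs0(G_in)) + beta`` with
    ``G_acs0 = G0 / (1 + G_in N0)``; non-decreasing in G_in because
    stronger inhibition lowers accessible glucose.
    """
    n0 = well.initial_confluence * params.theta

    def k_of_gin(g_in: float) -> float:
        return float(rel.rate(accessible_glucose(well.G0, n0, g_in)))

    return k_of_gin


# ---------------------------------------------------------------------------
# step 4: per-dose G_in with k_bys pinned by the relation
# ---------------------------------------------------------------------------

def fit_gin_constrained(
    dataset: Dataset,
    globals_: GlobalParams,
    rel: BystanderRelation,
    *,
    gin_bounds: tuple[float, float] = GIN_BOUNDS,
    rtol: float = 1e-6,
    level: float = 0.95,
) -> dict[float, GinFit]:
    """Step 4: one G_in per nonzero dose, k_bys assigned from the relation.

    Untreated wells are pinned at G_in = 0 and do not enter the fit.
    """
    doses = sorted({w.dose for w in dataset.wells if w.dose > 0})
    if not doses:
        raise ValueError("dataset contains no treated wells")
    out: dict[float, GinFit] = {}
    for dose in doses:
        wells = [w for w in dataset.wells if w.dose == dose]
        block = _block(dataset, globals_.theta, wells)
        if np.all(block.g0 == 0):
            raise IdentifiabilityError(f"dose {dose}: all wells at glucose 0, G_in unidentifiable")

        def residual(gin: float) -> np.ndarray:
            kb = rel.rate(block.g0 / (1.0 + gin * block.n0))
            return _residual_matrix(block, globals_, kb, np.full(block.m, gin), rtol).ravel()

        def sse(gin: float) -> float:
            r = residual(gin)
            return float(r @ r)

        # derivative-free search: a coarse log-spaced scan seeds a bounded
        # Brent refinement (FD gradients at the 1e-4 parameter scale would
        # drown in ODE tolerance noise)
        lo_b, hi_b = gin_bounds
        grid = np.concatenate([[lo_b], np.geomspace(max(lo_b, 1e-7), hi_b, 24)])
        vals = np.array([sse(g) for g in grid])
        if vals.max() - vals.min() <= 1e-9 * max(vals.max(), 1.0):
            raise IdentifiabilityError(f"dose {dose}: flat objective, G_in unidentifiable")
        i = int(vals.argmin())
        bracket = (grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)])
        opt = optimize.minimize_scalar(sse, bounds=bracket, method="bounded",
                                       options={"xatol": 1e-10})
        gin_hat = float(opt.x)
        res_hat = residual(gin_hat)
        h = max(1e-3 * gin_hat, 1e-7)
        jac = ((residual(gin_hat + h) - res_hat) / h).reshape(-1, 1)
        ci = linearized_intervals(np.array([gin_hat]), jac, res_hat, level)
        lo = max(float(ci[0, 0]), lo_b)
        hi = min(float(ci[0, 1]), hi_b)
        out[dose] = GinFit(dose=dose, value=gin_hat, ci=(lo, hi),
                           diagnostics={"success": True, "sse": float(opt.fun),
                                        "n_wells": block.m})
    return out


# ---------------------------------------------------------------------------
# step 5: joint G_in (bounded by step 4) + free local k_bys
# ---------------------------------------------------------------------------

def fit_gin_and_local_kbys(
    dataset: Dataset,
    globals_: GlobalParams,
    gin_bounds: Mapping[float, tuple[float, float]],
    *,
    kbys_bounds: tuple[float, float] = KBYS_BOUNDS,
    rtol: float = 1e-6,
    compute_ci: bool = True,
) -> CalibrationResult:
    """Step 5: per-dose G_in inside its step-4 interval, free k_bys per well.

    Treated doses are independent given the globals, so each dose is
    concentrated separately: a bounded scalar search over G_in with the
    per-well rates re-optimized at every trial value.
    """
    theta = globals_.theta
    gin_est: dict[float, float] = {0.0: 0.0}
    bound_flags: dict[float, bool] = {}
    kbys: dict[str, float] = {}
    kbys_ci: dict[str, tuple[float, float]] = {}
    per_sse: dict[str, float] = {}
    objective = 0.0
    doses = sorted({w.dose for w in dataset.wells})
    for dose in doses:
        wells = [w for w in dataset.wells if w.dose == dose]
        block = _block(dataset, theta, wells)
        if dose == 0.0:
            gin_hat = 0.0
        else:
            if dose not in gin_bounds:
                raise KeyError(f"no step-4 G_in bounds for dose {dose}")
            lo, hi = gin_bounds[dose]
            if hi - lo < 1e-15:
                gin_hat = float(lo)
            else:
                def F(g):
                    _, sse, _ = _best_kbys(block, globals_, np.full(block.m, g),
                                           bounds=kbys_bounds, rtol=rtol, passes=6)
                    return float(sse.sum())

                opt = optimize.minimize_scalar(F, bounds=(lo, hi), method="bounded",
                                               options={"xatol": max((hi - lo) * 1e-4, 1e-12)})
                gin_hat = float(opt.x)
            bound_flags[dose] = bool(
                hi - lo > 1e-15 and min(gin_hat - lo, hi - gin_hat) < 1e-3 * (hi - lo)
            )
        gin_est[dose] = gin_hat
        k_hat, sse, _ = _best_kbys(block, globals_, np.full(block.m, gin_hat),
                                   bounds=kbys_bounds, rtol=rtol, passes=8)
        objective += float(sse.sum())
        for i, wid in enumerate(block.ids):
            kbys[wid] = float(k_hat[i])
            per_sse[wid] = float(sse[i])
        if compute_ci:
            resid = _residual_matrix(block, globals_, k_hat, np.full(block.m, gin_hat), rtol)
            J = _full_jacobian(block, globals_, k_hat, np.full(block.m, gin_hat),
                               resid.ravel(), rtol)
            try:
                ci = linearized_intervals(k_hat, J, resid.ravel())
                for j, wid in enumerate(block.ids):
                    kbys_ci[wid] = (float(ci[j, 0]), float(ci[j, 1]))
            except np.linalg.LinAlgError:
                warnings.warn(f"singular Jacobian for dose {dose} local rates; no intervals",
                              stacklevel=2)

    return CalibrationResult(
        stage="dataset_B_joint",
        globals_={f"G_in[{d:g}uM]": g for d, g in gin_est.items() if d > 0},
        local_kbys=kbys,
        local_kbys_ci=kbys_ci,
        objective=objective,
        per_well_sse=per_sse,
        diagnostics={"gin": gin_est, "gin_at_bound": bound_flags},
    )


# ---------------------------------------------------------------------------
# step 6: accessible-glucose consistency check and relation refit
# ---------------------------------------------------------------------------

def refit_relation_accessible(
    kbys: Mapping[str, float],
    g_total0: Mapping[str, float],
    g_acs0: Mapping[str, float],
    prior: BystanderRelation,
    *,
    trend_alpha: float = 0.05,
) -> AccessibleRefit:
    """Step 6: compare free k_bys against total vs accessible glucose.

    Reports Pearson correlations of k_bys with G_total(0) and G_acs(0), runs
    a monotone-trend check (Spearman) on the accessible scale, and refits
    the decay law against G_acs(0) only if a significant decreasing trend
    is present; otherwise returns the prior relation with the pattern flag
    down.
    """
    ids = sorted(kbys)
    k = np.array([kbys[i] for i in ids])
    gt = np.array([g_total0[i] for i in ids])
    ga = np.array([g_acs0[i] for i in ids])
    if k.size < 4:
        raise ValueError("need at least 4 wells")

    def _safe_pearson(x, y):
        if np.std(x) == 0 or np.std(y) == 0:
            return 0.0
        return float(stats.pearsonr(x, y)[0])

    corr_total = _safe_pearson(gt, k)
    corr_acs = _safe_pearson(ga, k)
    if np.std(k) == 0:
        rho, p = 0.0, 1.0
    else:
        rho, p = stats.spearmanr(ga, k)
        rho, p = float(rho), float(p)
    confirmed = rho < 0 and p < trend_alpha
    if not confirmed:
        return AccessibleRefit(corr_total=corr_total, corr_accessible=corr_acs,
                               trend_rho=rho, trend_p=p, pattern_confirmed=False,
                               relation=prior)
    fit = fit_kbys_relation(ga, k)
    return AccessibleRefit(corr_total=corr_total, corr_accessible=corr_acs,
                           trend_rho=rho, trend_p=p, pattern_confirmed=True,
                           relation=fit.relation, relation_fit=fit)


def accessible_initial_glucose(dataset: Dataset, globals_: GlobalParams,
                               gin_by_dose: Mapping[float, float]) -> dict[str, float]:
    """Per-well accessible initial glucose under fitted inhibition."""
    out = {}
    for w in dataset.wells:
        gin = gin_by_dose.get(w.dose, 0.0) if w.dose > 0 else 0.0
        out[w.well_id] = float(accessible_glucose(w.G0, w.initial_confluence * globals_.theta, gin))
    return out


# ---------------------------------------------------------------------------
# step 7: prediction from initial conditions only
# ---------------------------------------------------------------------------

def predict(
    well: Well,
    globals_: GlobalParams,
    rel: BystanderRelation,
    inhibition: InhibitionParams,
    time_grid: np.ndarray | None = None,
    *,
    rtol: float = 1e-8,
) -> SimulationResult:
    """Step 7: forward prediction with no per-well fitting.

    Computes the accessible initial glucose from the dose's inhibition
    constant, evaluates the bystander rate from the decay law at that
    level, and simulates forward.
    """
    g_in = inhibition.for_dose(well.dose)
    n0 = well.initial_confluence * globals_.theta
    g_acs0 = accessible_glucose(well.G0, n0, g_in)
    kbys = float(rel.rate(g_acs0))
    return simulate_forward(well, globals_, kbys, g_in, time_grid, rtol=rtol)
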