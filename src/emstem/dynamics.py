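"""ODE dynamics, steady-state enumeration, and multistability classification.

Every node ``i`` obeys a production--decay equation

    dp_i/dt = g_i * prod_j HS(p_j; mu_ji, lam_ji, n_ji) - k_i * p_i

where the product runs over incoming edges and ``HS`` is the shifted Hill
function: 1 with no regulator, approaching the fold change ``lam`` at
saturation (``lam > 1`` activation, ``lam < 1`` inhibition).

Steady states for one parameter set are found by integrating many random
initial conditions to convergence, polishing each converged endpoint with a
Newton root solve, discarding endpoints whose Jacobian has an eigenvalue with
positive real part (saddles reached by numerical accident), and merging
duplicates whose node levels agree within a log2-space tolerance.  The count
of distinct stable states classifies the parameter set as monostable,
bistable, tristable, or >=4-stable.

The trajectory integrator is an exponential (production--decay) Euler scheme
compiled with numba: with production frozen over a step the decay part is
integrated exactly, which keeps levels positive and is unconditionally stable
for the linear part; a per-step cap on the relative state change handles the
steep Hill-threshold regions.  Converged endpoints are always re-solved with
Newton iteration in log space to the residual criterion below, so the
integrator only needs to deliver basins, not precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numba import njit
from scipy import optimize

from .sampler import (
    ModelParams,
    Perturbation,
    SamplingRanges,
    model_rng,
    sample_initial_conditions,
    sample_parameter_set,
    threshold_medians,
)
from .topology import ACTIVATION, NetworkTopology

logger = logging.getLogger(__name__)

MULTISTABILITY_LABELS = {1: "monostable", 2: "bistable", 3: "tristable"}


def classify_multistability(n_states: int | "ParameterSetResult") -> str:
    """Label a parameter set by its number of distinct stable states."""
    if hasattr(n_states, "n_states"):
        n_states = n_states.n_states
    if n_states < 1:
        raise ValueError("no distinct states: degenerate parameter set cannot be classified")
    return MULTISTABILITY_LABELS.get(n_states, ">=4-stable")


@dataclass(frozen=True)
class SolverConfig:
    """Numerical knobs for steady-state enumeration.

    ``t_max_factor / min(k)`` bounds the integration horizon; ``rel_tol`` is
    the scale-free convergence criterion ``max_i |dp_i/dt| / (k_i p_i)``;
    ``dedup_log2_tol`` merges states whose levels agree node-wise within that
    many log2 units; endpoints with a Jacobian eigenvalue real part above
    ``stability_tol`` are discarded as saddles.
    """

    t_max_factor: float = 200.0
    rel_tol: float = 1e-6
    rel_step_cap: float = 0.2
    dt_min: float = 1e-3
    dt_max: float = 5.0
    max_steps: int = 30000
    dedup_log2_tol: float = 0.05
    stability_tol: float = 1e-8
    polish_rel_tol: float = 1e-8
    floor: float = 1e-12


DEFAULT_SOLVER = SolverConfig()


def shifted_hill(p: float | np.ndarray, mu: float, lam: float, n: int) -> float | np.ndarray:
    """Shifted Hill regulatory factor ``mu^n/(mu^n+p^n) + lam*p^n/(mu^n+p^n)``.

    Equals 1 at ``p = 0``, ``(1+lam)/2`` at ``p = mu``, and tends to ``lam``
    as ``p -> inf``; bounded between ``min(1, lam)`` and ``max(1, lam)`` and
    monotone in ``p``.
    """
    if mu <= 0:
        raise ValueError(f"threshold mu must be positive, got {mu}")
    if lam <= 0:
        raise ValueError(f"fold change lam must be positive, got {lam}")
    if n < 1:
        raise ValueError(f"Hill coefficient n must be >= 1, got {n}")
    p = np.asarray(p, dtype=float)
    ratio = (p / mu) ** n
    return (1.0 + lam * ratio) / (1.0 + ratio)


def _hill_derivative(p: float, mu: float, lam: float, n: int) -> float:
    """d(HS)/dp = (lam-1) * n * mu^n * p^(n-1) / (mu^n + p^n)^2."""
    mun = mu ** n
    pn = p ** n
    return (lam - 1.0) * n * mun * (p ** (n - 1)) / (mun + pn) ** 2


def rhs(s: np.ndarray, m: ModelParams, t: NetworkTopology) -> np.ndarray:
    """Time derivative of the state vector ``s`` (topology node order)."""
    s = np.asarray(s, dtype=float)
    if s.shape != (t.n_nodes,):
        raise ValueError(f"state vector has shape {s.shape}, expected ({t.n_nodes},)")
    src, dst, _ = t.edge_arrays()
    production = m.g.copy()
    for e in range(t.n_edges):
        production[dst[e]] *= shifted_hill(s[src[e]], m.mu[e], m.lam[e], int(m.n[e]))
    return production - m.k * s


def jacobian(s: np.ndarray, m: ModelParams, t: NetworkTopology) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs` at state ``s``."""
    s = np.asarray(s, dtype=float)
    src, dst, _ = t.edge_arrays()
    E, N = t.n_edges, t.n_nodes
    h = np.array([shifted_hill(s[src[e]], m.mu[e], m.lam[e], int(m.n[e])) for e in range(E)])
    production = m.g.copy()
    for e in range(E):
        production[dst[e]] *= h[e]
    J = -np.diag(m.k.astype(float))
    for e in range(E):
        i, j = dst[e], src[e]
        dh = _hill_derivative(s[j], m.mu[e], m.lam[e], int(m.n[e]))
        # product over the other edges into i, times dH/dp_j
        J[i, j] += (production[i] / h[e]) * dh
    return J


@njit(cache=True)
def _integrate_batch(ics, g, k, src, dst, lam, mun, nh,
                     t_max, rel_tol, step_cap, dt_min, dt_max, max_steps, floor):
    """Integrate each initial condition to the convergence criterion.

    Returns (endpoints, converged) where endpoints has the same shape as
    ``ics`` and converged marks trajectories meeting the residual criterion
    within the time/step budget.
    """
    n_ic, nn = ics.shape
    ne = src.shape[0]
    out = np.empty_like(ics)
    ok = np.zeros(n_ic, np.bool_)
    P = np.empty(nn)
    for m in range(n_ic):
        p = ics[m].copy()
        t = 0.0
        dt_cap = dt_max
        prev_resid = 1e300
        for _step in range(max_steps):
            for i in range(nn):
                P[i] = g[i]
            for e in range(ne):
                x = p[src[e]]
                xn = 1.0
                for _ in range(nh[e]):
                    xn *= x
                P[dst[e]] *= (mun[e] + lam[e] * xn) / (mun[e] + xn)
            resid = 0.0
            dt = dt_cap
            for i in range(nn):
                target = P[i] / k[i]
                denom = p[i] if p[i] > floor else floor
                r = abs(target - p[i]) / denom
                if r > resid:
                    resid = r
                if r > step_cap:
                    f = step_cap / r
                    dti = -np.log(1.0 - f) / k[i]
                    if dti < dt:
                        dt = dti
            if resid < rel_tol:
                ok[m] = True
                break
            # damp the step when the residual grows (cobweb oscillation of
            # the frozen-production map around a steep nullcline); recover
            # slowly while it shrinks again
            if resid > prev_resid:
                dt_cap *= 0.7
                if dt_cap < dt_min:
                    dt_cap = dt_min
            elif dt_cap < dt_max:
                dt_cap *= 1.02
                if dt_cap > dt_max:
                    dt_cap = dt_max
            prev_resid = resid
            if dt > dt_cap:
                dt = dt_cap
            if dt < dt_min:
                dt = dt_min
            for i in range(nn):
                target = P[i] / k[i]
                a = np.exp(-k[i] * dt)
                p[i] = target + (p[i] - target) * a
                if p[i] < floor:
                    p[i] = floor
            t += dt
            if t >= t_max:
                break
        out[m] = p
    return out, ok


def _dedup_log2(states: np.ndarray, tol: float) -> np.ndarray:
    """Greedy merge of rows whose levels agree node-wise within ``tol`` log2 units."""
    kept: List[np.ndarray] = []
    for row in states:
        lrow = np.log2(row)
        if not any(np.max(np.abs(lrow - np.log2(s))) < tol for s in kept):
            kept.append(row)
    return np.array(kept) if kept else np.empty((0, states.shape[1]))


def _polish_root(x0: np.ndarray, m: ModelParams, t: NetworkTopology) -> Optional[np.ndarray]:
    """Newton-polish a candidate steady state in log space; None on failure."""

    def fun(u: np.ndarray) -> np.ndarray:
        return rhs(np.exp(u), m, t)

    def jac(u: np.ndarray) -> np.ndarray:
        p = np.exp(u)
        return jacobian(p, m, t) * p[np.newaxis, :]

    sol = optimize.root(fun, np.log(x0), jac=jac, method="hybr")
    if not sol.success:
        return None
    p = np.exp(sol.x)
    if not np.all(np.isfinite(p)) or not np.all(p > 0):
        return None
    return p


@dataclass
class ParameterSetResult:
    """Distinct stable steady states found for one parameter set."""

    params: ModelParams
    states: np.ndarray            # (n_states, n_nodes), raw levels
    frac_converged: float         # fraction of initial conditions converged

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def degenerate(self) -> bool:
        """True when no trajectory yielded a valid stable state."""
        return self.n_states == 0


def find_steady_states(
    m: ModelParams,
    t: NetworkTopology,
    ics: np.ndarray,
    config: SolverConfig = DEFAULT_SOLVER,
) -> ParameterSetResult:
    """Enumerate distinct stable steady states reachable from ``ics``.

    Trajectories are integrated to the scale-free residual criterion,
    endpoints are merged in log2 space, each representative is Newton-polished
    on ``rhs = 0``, re-checked against the residual criterion, filtered for
    linear stability, and deduplicated once more.
    """
    ics = np.atleast_2d(np.asarray(ics, dtype=float))
    if ics.shape[0] < 1:
        raise ValueError("at least one initial condition is required")
    src, dst, _ = t.edge_arrays()
    mun = m.mu.astype(float) ** m.n.astype(float)
    t_max = config.t_max_factor / float(np.min(m.k))
    endpoints, converged = _integrate_batch(
        ics, m.g.astype(float), m.k.astype(float), src, dst,
        m.lam.astype(float), mun, m.n.astype(np.int64),
        t_max, config.rel_tol, config.rel_step_cap,
        config.dt_min, config.dt_max, config.max_steps, config.floor,
    )
    frac = float(np.mean(converged))
    candidates = _dedup_log2(endpoints[converged], config.dedup_log2_tol)

    accepted: List[np.ndarray] = []
    for cand in candidates:
        p = _polish_root(cand, m, t)
        if p is None:
            continue
        resid = np.max(np.abs(rhs(p, m, t)) / (m.k * p))
        if resid > config.polish_rel_tol:
            continue
        eig = np.linalg.eigvals(jacobian(p, m, t))
        if np.max(eig.real) > config.stability_tol:
            continue  # saddle reached by numerical accident
        accepted.append(p)
    states = _dedup_log2(np.array(accepted), config.dedup_log2_tol) if accepted \
        else np.empty((0, t.n_nodes))
    return ParameterSetResult(params=m, states=states, frac_converged=frac)


@dataclass
class EnsembleResult:
    """All parameter-set results for one replicate of one circuit."""

    topology: NetworkTopology
    seed: int
    replicate: int
    perturbations: Tuple[Perturbation, ...]
    results: List[ParameterSetResult]
    n_failed: int = 0

    @property
    def n_models(self) -> int:
        return len(self.results) + self.n_failed

    def multistability_fractions(self) -> pd.Series:
        """Fraction of non-degenerate parameter sets per stability class."""
        counts = {"monostable": 0, "bistable": 0, "tristable": 0, ">=4-stable": 0}
        total = 0
        for r in self.results:
            if r.degenerate:
                continue
            counts[classify_multistability(r.n_states)] += 1
            total += 1
        if total == 0:
            raise ValueError("ensemble has no non-degenerate parameter sets")
        return pd.Series({k: v / total for k, v in counts.items()})

    def solutions_frame(self) -> pd.DataFrame:
        """Tidy table of raw steady-state levels, one row per solution."""
        rows = []
        for r in self.results:
            for s in r.states:
                rows.append(
                    {"replicate": self.replicate, "param_set": r.params.param_set_id,
                     "n_states": r.n_states, **dict(zip(self.topology.nodes, s))}
                )
        return pd.DataFrame(rows, columns=["replicate", "param_set", "n_states", *self.topology.nodes])


def run_ensemble(
    t: NetworkTopology,
    r: SamplingRanges | None = None,
    n_models: int = 1000,
    n_inits: int = 100,
    perturbations: Sequence[Perturbation] = (),
    seed: int = 0,
    replicate: int = 0,
    config: SolverConfig = DEFAULT_SOLVER,
) -> EnsembleResult:
    """Sample, solve, and classify ``n_models`` random parameterizations.

    Deterministic given ``(seed, replicate)``: each parameter set uses an
    independent substream derived from the pair plus its index.  Per-set
    sampler or solver failures are logged and counted, not propagated.
    """
    if n_models < 1:
        raise ValueError(f"n_models must be >= 1, got {n_models}")
    if n_inits < 1:
        raise ValueError(f"n_inits must be >= 1, got {n_inits}")
    ranges = r if r is not None else SamplingRanges()
    medians = threshold_medians(t, ranges)  # once per ensemble
    results: List[ParameterSetResult] = []
    n_failed = 0
    for i in range(n_models):
        rng = model_rng(seed, replicate, i)
        try:
            m = sample_parameter_set(
                t, ranges, perturbations, rng, param_set_id=i, replicate=replicate,
                medians=medians,
            )
            m.seed = seed
            ics = sample_initial_conditions(m, t, n_inits, rng)
            res = find_steady_states(m, t, ics, config)
        except Exception:  # pragma: no cover - defensive per-set isolation
            logger.exception("parameter set %d failed; skipping", i)
            n_failed += 1
            continue
        if res.degenerate:
            logger.warning("parameter set %d: no converged stable state", i)
        results.append(res)
    return EnsembleResult(
        topology=t, seed=seed, replicate=replicate,
        perturbations=tuple(perturbations), results=results, n_failed=n_failed,
    )
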