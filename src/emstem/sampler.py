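"""Random kinetic parameterizations for circuit ensembles.

This module is the analysis's synthetic-data generator: no experimental data
enter the pipeline anywhere.  Each "model" of an ensemble is one uniform
random draw of kinetic parameters for a fixed topology — maximal production
rate G and degradation rate k per node, and a fold-change λ, threshold μ and
integer Hill coefficient n per edge — mimicking cell-to-cell variability in
kinetic rates across a population.

Conventions
-----------
* ``G`` is the *maximal* production rate, reached when all incoming
  activations are saturated and all inhibitions are off.  The basal rate is
  derived as ``g = G / ∏ λ⁺`` over incoming activating edges.
* Activating edges draw ``λ > 1`` uniformly from the fold-change range;
  inhibiting edges draw the *reciprocal* fold uniformly, i.e. ``λ = 1/U``.
* Thresholds ``μ`` for an edge ``j → i`` are drawn uniformly from
  ``[0.02·M_j, 1.98·M_j]`` where ``M_j`` estimates the median level of the
  source node ``j`` across the ensemble — the *half-functional rule*, which
  keeps each link functional with roughly even odds (see
  :func:`threshold_medians`).  ``M_j`` always uses the *unperturbed*
  reference ranges, so an over/down-expression perturbation shifts only
  production, not thresholds.
* Over-expression or knock-down of a node by ``fold`` scales both endpoints
  of that node's G sampling range by ``fold`` (``fold=10`` is "oe10",
  ``fold=0.1`` is "de10").
* Initial conditions are drawn log-uniformly between the smallest possible
  steady level (all activators off, all inhibitors maximally active) and the
  largest (``G/k``) per node.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np

from .topology import ACTIVATION, INHIBITION, NetworkTopology, TopologyError


class SamplingError(ValueError):
    """Invalid sampling ranges or perturbations."""


@dataclass(frozen=True)
class Perturbation:
    """Scale one node's maximal-production sampling range by ``fold``."""

    node: str
    fold: float

    def __post_init__(self) -> None:
        if not self.fold > 0:
            raise SamplingError(f"perturbation fold must be positive, got {self.fold}")


@dataclass(frozen=True)
class SamplingRanges:
    """Uniform sampling ranges for every kinetic parameter class.

    ``production_overrides`` maps node names to per-node ``(lo, hi)`` G
    ranges; nodes not listed use ``production``.  All other ranges are
    shared across nodes/edges.
    """

    production: Tuple[float, float] = (1.0, 100.0)
    degradation: Tuple[float, float] = (0.1, 1.0)
    hill_coefficients: Tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    fold_change: Tuple[float, float] = (1.0, 100.0)
    threshold_window: Tuple[float, float] = (0.02, 1.98)
    threshold_rule: str = "half-functional"
    production_overrides: Mapping[str, Tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, (lo, hi) in (
            ("production", self.production),
            ("degradation", self.degradation),
            ("fold_change", self.fold_change),
            ("threshold_window", self.threshold_window),
        ):
            if not (lo > 0 and hi >= lo):
                raise SamplingError(f"{label} range must satisfy 0 < min <= max, got ({lo}, {hi})")
        for node, (lo, hi) in self.production_overrides.items():
            if not (lo > 0 and hi >= lo):
                raise SamplingError(
                    f"production override for {node!r} must satisfy 0 < min <= max, got ({lo}, {hi})"
                )
        if not self.hill_coefficients or any(
            (int(n) != n or n < 1) for n in self.hill_coefficients
        ):
            raise SamplingError("hill_coefficients must be a non-empty set of integers >= 1")
        if self.threshold_rule not in ("half-functional", "unregulated"):
            raise SamplingError(
                f"threshold_rule must be 'half-functional' or 'unregulated', got {self.threshold_rule!r}"
            )

    def production_range(self, node: str) -> Tuple[float, float]:
        return tuple(self.production_overrides.get(node, self.production))

    def threshold_scale(self, node: str) -> float:
        """``M`` for the half-functional threshold rule: mid(G range)/mid(k range)."""
        lo, hi = self.production_range(node)
        klo, khi = self.degradation
        return (0.5 * (lo + hi)) / (0.5 * (klo + khi))


#: Internal seed of the threshold-calibration Monte Carlo.  Fixed: the
#: calibration is part of the model definition, not of the sampled ensemble.
_CALIBRATION_SEED = 777

_median_cache: Dict[tuple, Dict[str, float]] = {}


def _ranges_key(t: NetworkTopology, r: SamplingRanges, n_samples: int) -> tuple:
    return (
        t.name, t.nodes, t.edges, r.production, r.degradation,
        r.hill_coefficients, r.fold_change, r.threshold_window, r.threshold_rule,
        tuple(sorted(r.production_overrides.items())), n_samples,
    )


def threshold_medians(
    t: NetworkTopology, r: SamplingRanges, n_samples: int = 20000
) -> Dict[str, float]:
    """Per-node median-level estimates ``M`` for the threshold calibration.

    Thresholds of outgoing edges of node ``s`` are drawn uniformly from
    ``[w_lo·M_s, w_hi·M_s]`` (default ``[0.02·M_s, 1.98·M_s]``), so each link
    is functional with roughly even odds — the half-functional rule.

    ``rule='half-functional'`` (default) estimates ``M_s`` by Monte Carlo as
    the median of ``s``'s level *including its own incoming regulation*, one
    level deep: ``G/k`` times each incoming shifted-Hill factor with the
    regulator's level drawn from its unregulated ``G/k`` distribution and
    the inner threshold drawn around the regulator's unregulated median.
    ``rule='unregulated'`` is the crude stand-in ``mid(G range)/mid(k
    range)``; it systematically overestimates the levels of repressed nodes
    and hence under-activates their outgoing links.

    The estimate uses an internal fixed seed and is cached, so it is a pure
    function of topology and ranges; it always uses the *unperturbed*
    reference ranges.
    """
    key = _ranges_key(t, r, n_samples)
    if key in _median_cache:
        return _median_cache[key]
    klo, khi = r.degradation
    if r.threshold_rule == "unregulated":
        M = {node: r.threshold_scale(node) for node in t.nodes}
        _median_cache[key] = M
        return M
    rng = np.random.default_rng(_CALIBRATION_SEED)

    def unregulated(node: str, size: int) -> np.ndarray:
        lo, hi = r.production_range(node)
        return rng.uniform(lo, hi, size) / rng.uniform(klo, khi, size)

    m0 = {node: float(np.median(unregulated(node, n_samples))) for node in t.nodes}
    hill = np.asarray(r.hill_coefficients, dtype=float)
    wlo, whi = r.threshold_window
    M: Dict[str, float] = {}
    for node in t.nodes:
        level = unregulated(node, n_samples)
        for e in t.incoming(node):
            x = unregulated(e.source, n_samples)
            lam = rng.uniform(*r.fold_change, n_samples)
            n = hill[rng.integers(0, len(hill), n_samples)]
            mu = rng.uniform(wlo * m0[e.source], whi * m0[e.source], n_samples)
            ratio = (x / mu) ** n
            if e.sign == ACTIVATION:
                # HS/lam: basal production is G/lam, saturating to G
                level *= (1.0 + lam * ratio) / (1.0 + ratio) / lam
            else:
                lam_i = 1.0 / lam
                level *= (1.0 + lam_i * ratio) / (1.0 + ratio)
        M[node] = float(np.median(level))
    _median_cache[key] = M
    return M


def apply_fold_change(r: SamplingRanges, pert: Perturbation, topology: Optional[NetworkTopology] = None) -> SamplingRanges:
    """Return a copy of ``r`` with ``pert.node``'s G range scaled by ``pert.fold``.

    If a topology is given, the node must belong to it.
    """
    if topology is not None and pert.node not in topology.nodes:
        raise TopologyError(f"perturbation names unknown node {pert.node!r}")
    lo, hi = r.production_range(pert.node)
    overrides = dict(r.production_overrides)
    overrides[pert.node] = (lo * pert.fold, hi * pert.fold)
    return replace(r, production_overrides=overrides)


@dataclass
class ModelParams:
    """One sampled kinetic parameterization of a topology.

    Node arrays follow the topology's node order; edge arrays follow its
    edge-list order.  Satisfies ``G = g · ∏ λ⁺`` (incoming activators) for
    every node, to machine precision.
    """

    topology_name: str
    nodes: Tuple[str, ...]
    G: np.ndarray        # maximal production, per node
    g: np.ndarray        # basal production, per node
    k: np.ndarray        # degradation, per node
    lam: np.ndarray      # fold change, per edge (>1 activation, <1 inhibition)
    mu: np.ndarray       # threshold, per edge
    n: np.ndarray        # Hill coefficient, per edge (int)
    param_set_id: int = 0
    replicate: int = 0
    seed: Optional[int] = None


def _incoming_lambda_products(
    t: NetworkTopology, lam: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-node products of incoming activating λ and incoming inhibiting λ."""
    src, dst, sign = t.edge_arrays()
    act = np.ones(t.n_nodes)
    inh = np.ones(t.n_nodes)
    for e in range(t.n_edges):
        if sign[e] == ACTIVATION:
            act[dst[e]] *= lam[e]
        else:
            inh[dst[e]] *= lam[e]
    return act, inh


def sample_parameter_set(
    t: NetworkTopology,
    r: SamplingRanges,
    perturbations: Sequence[Perturbation] = (),
    rng: np.random.Generator | int | None = None,
    param_set_id: int = 0,
    replicate: int = 0,
    medians: Optional[Mapping[str, float]] = None,
) -> ModelParams:
    """Draw one random parameter set for topology ``t``.

    Perturbations scale the G sampling range of the named nodes; thresholds
    are calibrated against the unperturbed reference ranges in ``r``.
    Draw order is fixed (per node: G then k; per edge: n, λ, μ), so a seeded
    generator reproduces the set bit-for-bit.
    """
    rng = np.random.default_rng(rng)
    if medians is None:
        medians = threshold_medians(t, r)
    perturbed = r
    for p in perturbations:
        perturbed = apply_fold_change(perturbed, p, topology=t)

    N, E = t.n_nodes, t.n_edges
    G = np.empty(N)
    k = np.empty(N)
    for i, node in enumerate(t.nodes):
        lo, hi = perturbed.production_range(node)
        G[i] = rng.uniform(lo, hi)
        k[i] = rng.uniform(*r.degradation)

    lam = np.empty(E)
    mu = np.empty(E)
    n = np.empty(E, dtype=np.int64)
    hill = np.asarray(r.hill_coefficients, dtype=np.int64)
    wlo, whi = r.threshold_window
    for e, edge in enumerate(t.edges):
        n[e] = hill[rng.integers(0, len(hill))]
        fold = rng.uniform(*r.fold_change)
        lam[e] = fold if edge.sign == ACTIVATION else 1.0 / fold
        M = medians[edge.source]  # from unperturbed reference ranges
        mu[e] = rng.uniform(wlo * M, whi * M)

    act_prod, _ = _incoming_lambda_products(t, lam)
    g = G / act_prod
    return ModelParams(
        topology_name=t.name, nodes=t.nodes, G=G, g=g, k=k, lam=lam, mu=mu, n=n,
        param_set_id=param_set_id, replicate=replicate,
    )


def initial_condition_bounds(p: ModelParams, t: NetworkTopology) -> Tuple[np.ndarray, np.ndarray]:
    """Per-node ``(L, U)`` bounds for random initial conditions.

    ``U = G/k`` (all activators saturated, inhibitors off); ``L`` is the
    opposite extreme, ``(G/∏λ⁺)·∏λ⁻/k``.  Nodes with no incoming edges have
    ``L = U = G/k``.
    """
    act_prod, inh_prod = _incoming_lambda_products(t, p.lam)
    U = p.G / p.k
    L = (p.G / act_prod) * inh_prod / p.k
    return L, U


def sample_initial_conditions(
    p: ModelParams,
    t: NetworkTopology,
    count: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw ``count`` state vectors log-uniformly within the reachable box.

    Returns an array of shape ``(count, n_nodes)``.  Input-less nodes get the
    degenerate value ``G/k`` exactly.
    """
    if count < 1:
        raise SamplingError(f"count must be >= 1, got {count}")
    rng = np.random.default_rng(rng)
    L, U = initial_condition_bounds(p, t)
    logL, logU = np.log(L), np.log(U)
    u = rng.uniform(size=(count, t.n_nodes))
    return np.exp(logL + u * (logU - logL))


def model_rng(seed: int, replicate: int, param_set_id: int) -> np.random.Generator:
    """Deterministic per-model substream: independent across (replicate, id)."""
    return np.random.default_rng([seed, replicate, param_set_id])
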