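"""Parameter-level metrics of regulatory-link potency.

The strength of a link is defined from its sampled kinetic parameters alone,
independent of expression at steady state:

    l = lam_eff * (G_s / k_s) / mu,   lam_eff = lam (activation) or 1/lam (inhibition)

where ``G_s/k_s`` — the maximum possible steady level of the *source* node —
normalizes the threshold ``mu`` (the threshold gates the source's level, so
the source's scale is the dimensionally coherent normalizer; switchable via
``normalize_by``).  A neutral link (``lam_eff = 1``, ``mu = G_s/k_s``) has
``l = 1``.

For two links of a feedback loop, ``asymmetry = log2(l1/l2)`` (antisymmetric
under swap) and ``coupling = log2(l1) + log2(l2)`` (symmetric); together they
determine ``(log2 l1, log2 l2)`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .sampler import ModelParams
from .topology import ACTIVATION, Edge, NetworkTopology


@dataclass(frozen=True)
class LinkStrength:
    """Effective strength of one edge under one parameter set."""

    source: str
    target: str
    l: float

    @property
    def log2_l(self) -> float:
        return float(np.log2(self.l))


def link_strength(
    m: ModelParams,
    t: NetworkTopology,
    e: Edge | Tuple[str, str],
    normalize_by: str = "source",
) -> LinkStrength:
    """Strength of edge ``e`` under parameter set ``m``."""
    if not isinstance(e, Edge):
        found = t.find_edge(*e)
        if found is None:
            raise ValueError(f"no edge {e[0]}->{e[1]} in circuit {t.name!r}")
        e = found
    ei = t.edge_index(e.source, e.target)
    mu = float(m.mu[ei])
    if mu <= 0:
        raise ValueError(f"threshold must be positive, got {mu}")
    lam = float(m.lam[ei])
    lam_eff = lam if e.sign == ACTIVATION else 1.0 / lam
    ref = e.source if normalize_by == "source" else e.target
    ni = t.node_index(ref)
    scale = float(m.G[ni] / m.k[ni])
    return LinkStrength(source=e.source, target=e.target, l=lam_eff * scale / mu)


def loop_asymmetry(l1: LinkStrength | float, l2: LinkStrength | float) -> float:
    """Signed log-ratio ``log2(l1/l2)``; antisymmetric under swap."""
    a = l1.l if isinstance(l1, LinkStrength) else float(l1)
    b = l2.l if isinstance(l2, LinkStrength) else float(l2)
    if not (a > 0 and b > 0):
        raise ValueError("link strengths must be positive")
    return float(np.log2(a / b))


def coupling_strength(l1: LinkStrength | float, l2: LinkStrength | float) -> float:
    """Combined strength ``log2(l1) + log2(l2)``; symmetric under swap."""
    a = l1.l if isinstance(l1, LinkStrength) else float(l1)
    b = l2.l if isinstance(l2, LinkStrength) else float(l2)
    if not (a > 0 and b > 0):
        raise ValueError("link strengths must be positive")
    return float(np.log2(a) + np.log2(b))


def strength_series(
    params: Sequence[ModelParams],
    t: NetworkTopology,
    edge: Tuple[str, str],
    normalize_by: str = "source",
) -> pd.Series:
    """Vectorized link strength over an ensemble, indexed by parameter-set id."""
    ei = t.edge_index(*edge)
    e = t.edges[ei]
    ni = t.node_index(e.source if normalize_by == "source" else e.target)
    ids, vals = [], []
    for m in params:
        lam = float(m.lam[ei])
        lam_eff = lam if e.sign == ACTIVATION else 1.0 / lam
        vals.append(lam_eff * float(m.G[ni] / m.k[ni]) / float(m.mu[ei]))
        ids.append(m.param_set_id)
    return pd.Series(vals, index=pd.Index(ids, name="param_set"), name=f"{edge[0]}->{edge[1]}")


def strength_by_phenotype(
    params: Sequence[ModelParams],
    t: NetworkTopology,
    labeled: pd.DataFrame,
    edge_pair: Tuple[Tuple[str, str], Tuple[str, str]],
    metric: str = "coupling",
    normalize_by: str = "source",
) -> Tuple[Dict[str, np.ndarray], pd.DataFrame]:
    """Distribution of a pair metric per phenotype, plus pairwise tests.

    The metric (``coupling``, ``asymmetry``, or ``strength`` of the first
    edge) is a parameter-set-level quantity; every solution of a parameter
    set inherits its value, so a set appearing in several phenotypes
    contributes to each.  Pairwise two-sided rank-sum tests between
    phenotype groups are Holm-adjusted; empty groups are omitted.
    """
    s1 = strength_series(params, t, edge_pair[0], normalize_by)
    s2 = strength_series(params, t, edge_pair[1], normalize_by)
    if metric == "coupling":
        values = np.log2(s1) + np.log2(s2)
    elif metric == "asymmetry":
        values = np.log2(s1 / s2)
    elif metric == "strength":
        values = s1.astype(float)
    else:
        raise ValueError(f"unknown metric {metric!r}")

    groups: Dict[str, np.ndarray] = {}
    for c, grp in labeled.groupby("phenotype"):
        v = values.reindex(grp["param_set"]).to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if len(v):
            groups[str(c)] = v

    from .pipeline import holm_adjust, rank_sum_test

    names = sorted(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = rank_sum_test(groups[a], groups[b])
            rows.append({"group_a": a, "group_b": b, "statistic": res.statistic,
                         "p_value": res.p_value,
                         "median_a": float(np.median(groups[a])),
                         "median_b": float(np.median(groups[b]))})
    tests = pd.DataFrame(rows)
    if not tests.empty:
        tests["p_holm"] = holm_adjust(tests["p_value"].tolist())
    return groups, tests
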