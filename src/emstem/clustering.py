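"""Normalization, phenotype clustering, and phase labeling of pooled solutions.

Raw steady-state levels are pooled across parameter sets, log2-transformed,
and normalized gene-wise against a *reference* ensemble (the same circuit with
no perturbation): ``z = (log2 p - mean(log2 p_ref)) / sd(log2 p_ref)``.

Phenotypes are assigned by k-means on the four core nodes only (miR-200, ZEB,
LIN28, let-7); SNAIL, NF-kB and any PSF node are excluded as features because
they are not regulated by the core toggles.  At k = 4 the clusters are named
by ascending median ZEB: epithelial (e) < hybrid epithelial (he) < hybrid
mesenchymal (hm) < mesenchymal (m), with descending median miR-200 breaking
ties.  The multiset of labels of one parameter set's coexisting states is its
*phase*, e.g. ``{e,m}`` for an epithelial/mesenchymal bistable set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .topology import BASE_NODES, CORE_NODES

PROVENANCE_COLUMNS = ("replicate", "param_set", "n_states")
PHENOTYPE_ORDER = ("e", "he", "hm", "m")


class NormalizationError(ValueError):
    """Degenerate reference statistics (e.g. zero variance for a node)."""


def reference_stats(reference: pd.DataFrame, nodes: Sequence[str]) -> pd.DataFrame:
    """Gene-wise mean and SD of log2 levels of the unperturbed reference run.

    Returns a DataFrame indexed by node with columns ``mean`` and ``sd``.
    """
    if reference.empty:
        raise NormalizationError("reference table is empty")
    stats = {}
    for node in nodes:
        logp = np.log2(reference[node].to_numpy(dtype=float))
        sd = float(np.std(logp))
        if sd == 0.0:
            raise NormalizationError(f"zero reference variance for node {node!r}")
        stats[node] = (float(np.mean(logp)), sd)
    return pd.DataFrame(stats, index=["mean", "sd"]).T


def normalize(
    solutions: pd.DataFrame,
    reference: pd.DataFrame,
    nodes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Gene-wise normalization of raw levels against a reference ensemble.

    ``reference`` is either a raw solution table of the unperturbed circuit
    or a precomputed :func:`reference_stats` frame.  Provenance columns are
    carried through unchanged; node columns become z-scores of log2 levels.
    """
    if nodes is None:
        nodes = [c for c in solutions.columns if c not in PROVENANCE_COLUMNS]
    if set(reference.columns) >= {"mean", "sd"} and reference.index.isin(nodes).any():
        stats = reference
    else:
        stats = reference_stats(reference, nodes)
    out = solutions.loc[:, [c for c in PROVENANCE_COLUMNS if c in solutions.columns]].copy()
    for node in nodes:
        mean, sd = stats.loc[node, "mean"], stats.loc[node, "sd"]
        out[node] = (np.log2(solutions[node].to_numpy(dtype=float)) - mean) / sd
    return out


@dataclass
class PhenotypeAssignment:
    """Cluster membership per solution plus per-parameter-set phase labels."""

    labels: pd.Series                 # per-solution phenotype, aligned to the table index
    centers: pd.DataFrame             # cluster centers in z-space, indexed by phenotype
    feature_nodes: Tuple[str, ...]
    inertia: float

    def with_labels(self, tbl: pd.DataFrame) -> pd.DataFrame:
        out = tbl.copy()
        out["phenotype"] = self.labels
        return out


def _order_clusters(tbl: pd.DataFrame, raw_labels: np.ndarray, k: int) -> List[int]:
    """Cluster ids ordered by ascending median ZEB, descending median miR-200."""
    keys = []
    for c in range(k):
        mask = raw_labels == c
        keys.append((float(tbl.loc[mask, "ZEB"].median()),
                     -float(tbl.loc[mask, "miR200"].median()), c))
    return [c for _, _, c in sorted(keys)]


def kmeans_phenotypes(
    tbl: pd.DataFrame,
    k: int = 4,
    restarts: int = 10,
    seed: int = 0,
    feature_nodes: Sequence[str] = CORE_NODES,
) -> PhenotypeAssignment:
    """Partition normalized solutions into phenotypes with k-means.

    Best of ``restarts`` initializations by inertia.  At ``k = 4`` clusters
    are named e/he/hm/m by ascending median ZEB; other k get rank names
    ``c1..ck`` in the same ordering.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    X = tbl.loc[:, list(feature_nodes)].to_numpy(dtype=float)
    if k > len(np.unique(X, axis=0)):
        raise ValueError(f"k={k} exceeds the number of distinct rows")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    raw = km.fit_predict(X)
    order = _order_clusters(tbl, raw, k)
    names = list(PHENOTYPE_ORDER) if k == 4 else [f"c{i + 1}" for i in range(k)]
    mapping = {cluster: names[rank] for rank, cluster in enumerate(order)}
    labels = pd.Series([mapping[c] for c in raw], index=tbl.index, name="phenotype")
    centers = pd.DataFrame(km.cluster_centers_, columns=list(feature_nodes))
    centers.index = pd.Index([mapping[c] for c in range(k)], name="phenotype")
    centers = centers.loc[names]
    return PhenotypeAssignment(
        labels=labels, centers=centers, feature_nodes=tuple(feature_nodes),
        inertia=float(km.inertia_),
    )


def cluster_quality_sweep(
    tbl: pd.DataFrame,
    k_range: Sequence[int] = range(2, 9),
    restarts: int = 10,
    seed: int = 0,
    feature_nodes: Sequence[str] = CORE_NODES,
    silhouette_cap: int = 20000,
) -> pd.DataFrame:
    """Silhouette, Calinski-Harabasz, Davies-Bouldin and inertia per k.

    Silhouette is computed on a seeded subsample when the table exceeds
    ``silhouette_cap`` rows; the subsample size used is recorded.
    """
    X = tbl.loc[:, list(feature_nodes)].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    if len(X) > silhouette_cap:
        sub_idx = rng.choice(len(X), size=silhouette_cap, replace=False)
    else:
        sub_idx = np.arange(len(X))
    records = []
    for k in k_range:
        if k < 2:
            raise ValueError(f"k must be >= 2, got {k}")
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
        labels = km.fit_predict(X)
        records.append({
            "k": k,
            "silhouette": float(silhouette_score(X[sub_idx], labels[sub_idx])),
            "calinski_harabasz": float(calinski_harabasz_score(X, labels)),
            "davies_bouldin": float(davies_bouldin_score(X, labels)),
            "inertia": float(km.inertia_),
            "silhouette_n": int(len(sub_idx)),
        })
    return pd.DataFrame.from_records(records).set_index("k")


@dataclass
class PCASummary:
    """Variance fractions and loadings of the pooled normalized solutions."""

    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # components x nodes, orthonormal rows

    @property
    def pc1_fraction(self) -> float:
        return float(self.explained_variance_ratio[0])

    @property
    def pc2_fraction(self) -> float:
        return float(self.explained_variance_ratio[1])


def pca_summary(tbl: pd.DataFrame, nodes: Sequence[str] = BASE_NODES) -> PCASummary:
    """PCA of the normalized solutions over the base-circuit nodes.

    Loadings are orthonormal; variance fractions sum to 1.  PC1 is oriented
    so its ZEB loading is negative (epithelial states score positive), and
    each further component so its largest-magnitude loading is positive.
    """
    X = tbl.loc[:, list(nodes)].to_numpy(dtype=float)
    if len(X) < 2:
        raise ValueError("PCA needs at least 2 rows")
    pca = PCA(n_components=len(nodes))
    pca.fit(X)
    comps = pca.components_.copy()
    zeb = list(nodes).index("ZEB") if "ZEB" in nodes else None
    for c in range(comps.shape[0]):
        if c == 0 and zeb is not None:
            if comps[0, zeb] > 0:
                comps[0] = -comps[0]
        elif comps[c, np.argmax(np.abs(comps[c]))] < 0:
            comps[c] = -comps[c]
    loadings = pd.DataFrame(comps, columns=list(nodes),
                            index=[f"PC{i + 1}" for i in range(comps.shape[0])])
    return PCASummary(explained_variance_ratio=pca.explained_variance_ratio_.copy(),
                      loadings=loadings)


def phase_label(labels: Iterable[str]) -> str:
    """Canonical phase string for a multiset of phenotype labels, e.g. ``{e,m}``."""
    order = {name: i for i, name in enumerate(PHENOTYPE_ORDER)}
    parts = sorted(labels, key=lambda s: (order.get(s, len(order)), s))
    return "{" + ",".join(parts) + "}"


def label_phases(labeled: pd.DataFrame) -> pd.DataFrame:
    """Phase frequency table by multistability class, per replicate.

    ``labeled`` must carry ``replicate``, ``param_set``, ``n_states`` and a
    ``phenotype`` column covering every solution of each parameter set.
    Returns a tidy frame with columns ``replicate, stability, phase,
    frequency`` where frequencies sum to 1 within each (replicate,
    stability) group.
    """
    if labeled["phenotype"].isna().any():
        raise ValueError("parameter set with unlabeled solution")
    from .dynamics import classify_multistability

    phases = (
        labeled.groupby(["replicate", "param_set"])
        .agg(n_states=("n_states", "first"), n_rows=("phenotype", "size"),
             phase=("phenotype", phase_label))
        .reset_index()
    )
    bad = phases[phases["n_states"] != phases["n_rows"]]
    if not bad.empty:
        raise ValueError(
            f"{len(bad)} parameter sets have solutions missing from the labeled table"
        )
    phases["stability"] = phases["n_states"].map(classify_multistability)
    freq = (
        phases.groupby(["replicate", "stability"])["phase"]
        .value_counts(normalize=True)
        .rename("frequency")
        .reset_index()
    )
    return freq


@dataclass
class WardResult:
    """Ward-linkage summary on (a subsample of) the normalized solutions."""

    linkage: np.ndarray
    row_indices: np.ndarray            # positions into the input table
    four_group_labels: np.ndarray      # cluster ids (1..4) at the 4-group cut


def ward_dendrogram(
    tbl: pd.DataFrame,
    max_rows: int = 5000,
    seed: int = 0,
    feature_nodes: Sequence[str] = CORE_NODES,
) -> WardResult:
    """Agglomerative clustering with Ward's minimum-variance criterion.

    Rows are subsampled (seeded) beyond ``max_rows``.  The 4-group cut is
    returned for cross-checking against the k-means partition.
    """
    X = tbl.loc[:, list(feature_nodes)].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    if len(X) > max_rows:
        idx = np.sort(rng.choice(len(X), size=max_rows, replace=False))
    else:
        idx = np.arange(len(X))
    Z = linkage(X[idx], method="ward")
    labels = fcluster(Z, t=4, criterion="maxclust")
    return WardResult(linkage=Z, row_indices=idx, four_group_labels=labels)


def label_agreement(a: Sequence, b: Sequence) -> float:
    """Best-permutation agreement between two partitions of the same rows."""
    from itertools import permutations

    a = np.asarray(a)
    b = np.asarray(b)
    ua, ub = np.unique(a), np.unique(b)
    best = 0.0
    for perm in permutations(ub, len(ua)):
        mapping = dict(zip(ua, perm))
        best = max(best, float(np.mean([mapping[x] for x in a] == b)))
    return best


def cluster_centers_plane(
    labeled: pd.DataFrame, x: str = "ZEB", y: str = "LIN28"
) -> pd.DataFrame:
    """Cluster centers (means) in a 2-D normalized-expression plane."""
    return labeled.groupby("phenotype")[[x, y]].mean()


def corner_geometry(centers: pd.DataFrame, x: str = "ZEB", y: str = "LIN28") -> pd.DataFrame:
    """Assign four cluster centers to quadrant corners and measure rectangle misfit.

    Corners are defined by the median split of the four centers.  For each
    off-diagonal corner the *predicted* rectangle position takes its x from
    the on-diagonal corner sharing its x-side and its y from the one sharing
    its y-side; ``misfit`` is the Chebyshev distance to that prediction.
    Returns a frame indexed by corner: ``low_low, low_high, high_low,
    high_high`` with center coordinates and misfit (NaN for the two
    on-diagonal anchors).
    """
    if len(centers) != 4:
        raise ValueError(f"expected 4 cluster centers, got {len(centers)}")
    cx, cy = centers[x].median(), centers[y].median()
    corners = {}
    for name, row in centers.iterrows():
        key = ("low" if row[x] < cx else "high") + "_" + ("low" if row[y] < cy else "high")
        if key in corners:
            raise ValueError("cluster centers do not occupy distinct quadrants")
        corners[key] = (float(row[x]), float(row[y]))
    if set(corners) != {"low_low", "low_high", "high_low", "high_high"}:
        raise ValueError("cluster centers do not occupy distinct quadrants")
    ll, hh = corners["low_low"], corners["high_high"]
    pred = {"low_high": (ll[0], hh[1]), "high_low": (hh[0], ll[1])}
    rows = []
    for key in ("low_low", "low_high", "high_low", "high_high"):
        px, py = corners[key]
        misfit = np.nan
        if key in pred:
            misfit = max(abs(px - pred[key][0]), abs(py - pred[key][1]))
        rows.append({"corner": key, x: px, y: py, "misfit": misfit})
    return pd.DataFrame(rows).set_index("corner")
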