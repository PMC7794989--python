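"""End-to-end orchestration: replicates, circuits, perturbation sweeps, stats.

A *run* simulates ``n_replicates`` independent ensembles of a circuit (each
analogous to a biological replicate), then, per replicate: normalizes pooled
solutions against the unperturbed reference, clusters them into phenotypes,
labels multistable phases, builds the stemness window, and computes the
p1/p2 enrichment probabilities; cross-replicate quantities are reported as
mean ± SD.  Perturbation sweeps rerun the ensemble with a node's production
range scaled by each fold, normalizing every perturbed run against the
*unperturbed* reference statistics of the same replicate and reusing the
unperturbed stemness window.

Significance testing follows the comparison type: distributions within one
replicate use the two-sided Mann-Whitney U test, cross-replicate proportions
use Welch's t-test, and each result table is Holm-adjusted as one family.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from . import __version__
from .clustering import (
    PhenotypeAssignment,
    cluster_quality_sweep,
    kmeans_phenotypes,
    label_phases,
    normalize,
    pca_summary,
    reference_stats,
)
from .dynamics import DEFAULT_SOLVER, EnsembleResult, SolverConfig, run_ensemble
from .sampler import Perturbation, SamplingRanges
from .stemness import (
    EnrichmentProbs,
    StemnessWindow,
    conditional_probabilities,
    lin28_stats,
    stemness_window,
    window_sensitivity,
)
from .topology import BASE_NODES, NetworkTopology, builtin_circuit, load_topology

logger = logging.getLogger(__name__)

PRESETS = {
    "paper": dict(n_replicates=5, n_models=10000, n_inits=100),
    "desk": dict(n_replicates=5, n_models=1000, n_inits=50),
    "mini": dict(n_replicates=2, n_models=600, n_inits=30),
}


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StatTest:
    statistic: float
    p_value: float
    median_ratio: float
    median_diff: float
    flag: Optional[str] = None


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> StatTest:
    """Two-sided Mann-Whitney U test with median-based effect sizes."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    ma, mb = float(np.median(a)), float(np.median(b))
    ratio = ma / mb if mb != 0 else np.inf
    if np.all(a == a[0]) and np.all(b == a[0]):
        return StatTest(statistic=len(a) * len(b) / 2.0, p_value=1.0,
                        median_ratio=ratio, median_diff=ma - mb, flag="all values tied")
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    return StatTest(statistic=float(u), p_value=float(p),
                    median_ratio=ratio, median_diff=ma - mb)


def welch_test(a: Sequence[float], b: Sequence[float]) -> StatTest:
    """Welch's unequal-variance t-test for cross-replicate proportions."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 replicates")
    ma, mb = float(np.mean(a)), float(np.mean(b))
    ratio = ma / mb if mb != 0 else np.inf
    if np.var(a) == 0 and np.var(b) == 0:
        if ma == mb:
            return StatTest(statistic=0.0, p_value=1.0, median_ratio=ratio,
                            median_diff=ma - mb, flag="zero variance, equal means")
        return StatTest(statistic=np.inf, p_value=0.0, median_ratio=ratio,
                        median_diff=ma - mb, flag="zero variance")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return StatTest(statistic=float(t), p_value=float(p),
                    median_ratio=ratio, median_diff=ma - mb)


def holm_adjust(pvals: Sequence[float]) -> List[float]:
    """Step-down Holm-Bonferroni adjustment, input order preserved."""
    p = np.asarray(list(pvals), dtype=float)
    if len(p) == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1].tolist()


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything needed to reproduce a run; outputs are a pure function of it."""

    circuit: str = "base"                # builtin name or path to a .topo file
    n_models: int = 1000
    n_inits: int = 50
    n_replicates: int = 5
    seed: int = 0
    k: int = 4
    restarts: int = 10
    window_fraction: float = 0.30
    quality_sweep: bool = False
    quality_k_range: Tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    perturbation_node: Optional[str] = None
    folds: Tuple[float, ...] = (0.1, 1.0, 10.0)
    outdir: Optional[str] = None
    ranges: SamplingRanges = field(default_factory=SamplingRanges)
    solver: SolverConfig = field(default_factory=SolverConfig)

    def __post_init__(self) -> None:
        for name in ("n_models", "n_inits", "n_replicates", "restarts"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if any(f <= 0 for f in self.folds):
            raise ValueError("perturbation folds must be positive")
        if not 0 < self.window_fraction <= 1:
            raise ValueError("window_fraction must be in (0, 1]")

    @classmethod
    def preset(cls, name: str, **overrides) -> "RunConfig":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; valid: {sorted(PRESETS)}")
        return cls(**{**PRESETS[name], **overrides})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        preset = raw.pop("preset", None)
        if "ranges" in raw:
            coerced = {k: tuple(v) if isinstance(v, list) else v
                       for k, v in raw["ranges"].items()}
            raw["ranges"] = SamplingRanges(**coerced)
        if "solver" in raw:
            raw["solver"] = SolverConfig(**raw["solver"])
        if "folds" in raw:
            raw["folds"] = tuple(raw["folds"])
        return cls.preset(preset, **raw) if preset else cls(**raw)

    def resolve_topology(self) -> NetworkTopology:
        if Path(self.circuit).suffix == ".topo":
            return load_topology(self.circuit)
        return builtin_circuit(self.circuit)

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["ranges"]["production_overrides"] = dict(d["ranges"]["production_overrides"])
        return d


# ---------------------------------------------------------------------------
# analysis bundles
# ---------------------------------------------------------------------------

@dataclass
class CircuitAnalysis:
    """All per-replicate and summary products for one circuit/perturbation."""

    config: RunConfig
    topology: NetworkTopology
    perturbations: Tuple[Perturbation, ...]
    ensembles: List[EnsembleResult]
    ref_stats: Dict[int, pd.DataFrame]           # per-replicate normalization stats
    assignments: Dict[int, PhenotypeAssignment]
    labeled: pd.DataFrame                        # z-scores + phenotype, all replicates
    multistability: pd.DataFrame                 # per replicate, classes as columns
    phases: pd.DataFrame                         # tidy phase frequencies
    window: StemnessWindow
    probs: EnrichmentProbs
    pca_ratios: pd.DataFrame                     # per replicate, PC1..PCn fractions
    quality: Dict[int, pd.DataFrame] = field(default_factory=dict)

    def multistability_summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.multistability.mean(axis=0),
                             "sd": self.multistability.std(axis=0)})

    def composition(self, stability: Optional[str] = None) -> pd.DataFrame:
        """Phenotype proportions (mean ± SD across replicates).

        ``stability='monostable'`` restricts to solutions of monostable
        parameter sets; None pools all solutions.
        """
        tbl = self.labeled
        if stability == "monostable":
            tbl = tbl[tbl["n_states"] == 1]
        elif stability is not None:
            raise ValueError(f"unsupported stability filter {stability!r}")
        per_rep = (
            tbl.groupby("replicate")["phenotype"].value_counts(normalize=True)
            .rename("proportion").reset_index()
            .pivot(index="replicate", columns="phenotype", values="proportion")
            .fillna(0.0)
        )
        return pd.DataFrame({"mean": per_rep.mean(axis=0), "sd": per_rep.std(axis=0)})

    def phase_summary(self, stability: str) -> pd.DataFrame:
        """Mean ± SD phase frequencies for one multistability class."""
        sub = self.phases[self.phases["stability"] == stability]
        per_rep = sub.pivot(index="replicate", columns="phase", values="frequency").fillna(0.0)
        return pd.DataFrame({"mean": per_rep.mean(axis=0), "sd": per_rep.std(axis=0)})

    def pca_mean(self) -> pd.Series:
        return self.pca_ratios.mean(axis=0)

    def sensitivity(self, f_list: Sequence[float]) -> pd.DataFrame:
        return window_sensitivity(self.labeled, lin28_stats(self.labeled), f_list)

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.labeled.to_csv(out / "solutions_labeled.csv", index=False)
        self.multistability.to_csv(out / "multistability_per_replicate.csv")
        self.multistability_summary().to_csv(out / "multistability_summary.csv")
        self.phases.to_csv(out / "phase_frequencies.csv", index=False)
        self.probs.per_replicate.to_csv(out / "enrichment_per_replicate.csv", index=False)
        self.probs.summary.to_csv(out / "enrichment_summary.csv")
        self.pca_ratios.to_csv(out / "pca_variance_fractions.csv")
        for rep, q in self.quality.items():
            q.to_csv(out / f"cluster_quality_rep{rep}.csv")
        manifest = {
            "package_version": __version__,
            "config": self.config.to_manifest(),
            "circuit": self.topology.name,
            "perturbations": [dataclasses.asdict(p) for p in self.perturbations],
            "window": dataclasses.asdict(self.window),
            "n_models_per_replicate": self.config.n_models,
            "n_failed": {e.replicate: e.n_failed for e in self.ensembles},
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2)


def _simulate_replicates(
    topo: NetworkTopology,
    cfg: RunConfig,
    perturbations: Sequence[Perturbation],
) -> List[EnsembleResult]:
    out = []
    for rep in range(cfg.n_replicates):
        logger.info("simulating %s replicate %d/%d (%d models x %d inits)",
                    topo.name, rep + 1, cfg.n_replicates, cfg.n_models, cfg.n_inits)
        out.append(run_ensemble(
            topo, cfg.ranges, n_models=cfg.n_models, n_inits=cfg.n_inits,
            perturbations=perturbations, seed=cfg.seed, replicate=rep,
            config=cfg.solver,
        ))
    return out


def analyze_ensembles(
    ensembles: List[EnsembleResult],
    cfg: RunConfig,
    ref_stats: Optional[Dict[int, pd.DataFrame]] = None,
    window: Optional[StemnessWindow] = None,
) -> CircuitAnalysis:
    """Normalize, cluster, phase-label and window one simulated circuit.

    ``ref_stats``/``window`` default to self-derived (unperturbed run); a
    perturbed run passes the unperturbed circuit's statistics instead.
    """
    topo = ensembles[0].topology
    stats_by_rep: Dict[int, pd.DataFrame] = {}
    assignments: Dict[int, PhenotypeAssignment] = {}
    labeled_parts: List[pd.DataFrame] = []
    multi_rows = {}
    pca_rows = {}
    quality: Dict[int, pd.DataFrame] = {}
    pca_nodes = [n for n in BASE_NODES if n in topo.nodes]

    for ens in ensembles:
        rep = ens.replicate
        raw = ens.solutions_frame()
        if raw.empty:
            raise ValueError(f"replicate {rep} produced no solutions")
        st = ref_stats[rep] if ref_stats is not None else reference_stats(raw, topo.nodes)
        stats_by_rep[rep] = st
        z = normalize(raw, st, topo.nodes)
        assign = kmeans_phenotypes(z, k=cfg.k, restarts=cfg.restarts, seed=cfg.seed + rep)
        assignments[rep] = assign
        labeled_parts.append(assign.with_labels(z))
        multi_rows[rep] = ens.multistability_fractions()
        pca = pca_summary(z, nodes=pca_nodes)
        pca_rows[rep] = pd.Series(
            pca.explained_variance_ratio,
            index=[f"PC{i + 1}" for i in range(len(pca.explained_variance_ratio))],
        )
        if cfg.quality_sweep:
            quality[rep] = cluster_quality_sweep(
                z, k_range=cfg.quality_k_range, restarts=cfg.restarts, seed=cfg.seed + rep
            )

    labeled = pd.concat(labeled_parts, ignore_index=True)
    phases = label_phases(labeled)
    if window is None:
        window = stemness_window(lin28_stats(labeled), f=cfg.window_fraction)
    probs = conditional_probabilities(labeled, window)
    return CircuitAnalysis(
        config=cfg, topology=topo, perturbations=ensembles[0].perturbations,
        ensembles=ensembles, ref_stats=stats_by_rep, assignments=assignments,
        labeled=labeled, multistability=pd.DataFrame(multi_rows).T,
        phases=phases, window=window, probs=probs,
        pca_ratios=pd.DataFrame(pca_rows).T, quality=quality,
    )


def run_full_analysis(cfg: RunConfig) -> CircuitAnalysis:
    """Simulate and analyze the unperturbed circuit end to end.

    Deterministic given the config; persists tables and a manifest when
    ``cfg.outdir`` is set.
    """
    topo = cfg.resolve_topology()
    ensembles = _simulate_replicates(topo, cfg, ())
    analysis = analyze_ensembles(ensembles, cfg)
    if cfg.outdir:
        analysis.save(cfg.outdir)
    return analysis


@dataclass
class SweepResult:
    """Reference run plus one analysis per perturbation fold."""

    node: str
    reference: CircuitAnalysis
    by_fold: Dict[float, CircuitAnalysis]

    def p2_table(self) -> pd.DataFrame:
        rows = []
        for fold, a in sorted(self.by_fold.items()):
            for c, r in a.probs.summary.iterrows():
                rows.append({"fold": fold, "phenotype": c,
                             "p1": r["p1_mean"], "p1_sd": r["p1_sd"],
                             "p2": r["p2_mean"], "p2_sd": r["p2_sd"]})
        return pd.DataFrame(rows)


def perturbation_sweep(
    cfg: RunConfig,
    node: Optional[str] = None,
    folds: Optional[Sequence[float]] = None,
    reference: Optional[CircuitAnalysis] = None,
) -> SweepResult:
    """Run the circuit at each fold of a node's production range.

    Every fold is a separate ensemble; normalization statistics and the
    stemness window come from the unperturbed reference of the same
    replicate, so perturbed z-scores live on the reference scale.
    ``fold = 1`` reuses the reference run itself.
    """
    node = node or cfg.perturbation_node
    if node is None:
        raise ValueError("no perturbation node given")
    folds = tuple(folds if folds is not None else cfg.folds)
    topo = cfg.resolve_topology()
    if node not in topo.nodes:
        raise ValueError(f"perturbation node {node!r} not in circuit {topo.name!r}")
    if reference is None:
        reference = run_full_analysis(replace(cfg, outdir=None))
    by_fold: Dict[float, CircuitAnalysis] = {}
    for fold in folds:
        if fold == 1.0:
            by_fold[fold] = reference
            continue
        ensembles = _simulate_replicates(topo, cfg, (Perturbation(node, fold),))
        by_fold[fold] = analyze_ensembles(
            ensembles, cfg, ref_stats=reference.ref_stats, window=reference.window
        )
    result = SweepResult(node=node, reference=reference, by_fold=by_fold)
    if cfg.outdir:
        out = Path(cfg.outdir)
        for fold, a in by_fold.items():
            a.save(out / f"fold_{fold:g}")
        result.p2_table().to_csv(out / "sweep_enrichment.csv", index=False)
    return result


def enrichment_tests(analysis: CircuitAnalysis) -> pd.DataFrame:
    """Welch tests on cross-replicate p1/p2: hybrids vs non-hybrids, Holm-adjusted."""
    per = analysis.probs.per_replicate
    rows = []
    for quantity in ("p1", "p2"):
        wide = per.pivot(index="replicate", columns="phenotype", values=quantity)
        hybrid = wide.get("he", 0) + wide.get("hm", 0)
        nonhyb = wide.get("e", 0) + wide.get("m", 0)
        res = welch_test(hybrid.to_numpy(), nonhyb.to_numpy())
        rows.append({"comparison": f"{quantity}: hybrid vs non-hybrid",
                     "statistic": res.statistic, "p_value": res.p_value,
                     "mean_diff": res.median_diff, "flag": res.flag})
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_value"].tolist())
    return out


def plot_summary(analysis: CircuitAnalysis, outdir) -> List[str]:
    """Write basic diagnostic figures (phenotype proportions, p1/p2, PCA)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    comp = analysis.composition(stability="monostable")
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(comp.index, comp["mean"], yerr=comp["sd"], color="tab:blue")
    ax.set_ylabel("proportion of monostable solutions")
    fig.tight_layout()
    path = out / "monostable_composition.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    written.append(str(path))

    s = analysis.probs.summary
    fig, axes = plt.subplots(1, 2, figsize=(7, 3), sharex=True)
    for ax, q in zip(axes, ("p1", "p2")):
        ax.bar(s.index, s[f"{q}_mean"], yerr=s[f"{q}_sd"], color="tab:green")
        ax.set_title(q)
    fig.tight_layout()
    path = out / "enrichment.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    written.append(str(path))

    rep0 = analysis.labeled[analysis.labeled["replicate"] == analysis.labeled["replicate"].min()]
    nodes = [n for n in BASE_NODES if n in rep0.columns]
    pca = pca_summary(rep0, nodes=nodes)
    scores = rep0[nodes].to_numpy() @ pca.loadings.to_numpy().T
    fig, ax = plt.subplots(figsize=(4, 4))
    for c, grp in rep0.assign(pc1=scores[:, 0], pc2=scores[:, 1]).groupby("phenotype"):
        ax.scatter(grp["pc1"], grp["pc2"], s=3, label=str(c), alpha=0.4)
    ax.set_xlabel(f"PC1 ({pca.pc1_fraction:.0%})")
    ax.set_ylabel(f"PC2 ({pca.pc2_fraction:.0%})")
    ax.legend(markerscale=3)
    fig.tight_layout()
    path = out / "pca_scatter.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    written.append(str(path))
    return written
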