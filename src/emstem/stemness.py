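"""Stemness-window definition and phenotype-enrichment probabilities.

LIN28 is the stemness readout: its direct target OCT4 confers maximal
stemness at intermediate levels, so solutions whose LIN28 falls in a band
around the population median are deemed stem-like.  The *biological range*
is the median ± one interquartile range of the pooled LIN28 distribution
(median and IQR computed per replicate on the normalized scale, then
averaged across replicates); the *stemness window* is the middle fraction
``f`` of that range, symmetric about the median — default ``f = 0.30``,
i.e. ``[median - 0.3·IQR, median + 0.3·IQR]``.

Two conditional probabilities quantify enrichment:

* ``p1(c)`` — probability of lying in the window given phenotype ``c``;
* ``p2(c)`` — probability of phenotype ``c`` given lying in the window
  (so ``Σ_c p2(c) = 1`` whenever the window is occupied).

Both are computed per replicate and summarized as mean ± SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

HYBRID_PHENOTYPES = ("he", "hm")
NONHYBRID_PHENOTYPES = ("e", "m")


@dataclass(frozen=True)
class StemnessWindow:
    """Closed LIN28 interval deemed stem-like, with its provenance."""

    lower: float
    upper: float
    median: float
    iqr: float
    fraction: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"degenerate window [{self.lower}, {self.upper}]")

    def contains(self, values: np.ndarray | pd.Series) -> np.ndarray:
        """Boundary values count as inside (closed interval)."""
        v = np.asarray(values, dtype=float)
        return (v >= self.lower) & (v <= self.upper)


def lin28_stats(tbl: pd.DataFrame, node: str = "LIN28") -> pd.DataFrame:
    """Per-replicate median and IQR of the pooled LIN28 distribution."""
    def _iqr(x: pd.Series) -> float:
        q75, q25 = np.percentile(x.to_numpy(dtype=float), [75, 25])
        return float(q75 - q25)

    return tbl.groupby("replicate")[node].agg(median="median", iqr=_iqr)


def stemness_window(
    lin28_by_replicate: pd.DataFrame | pd.Series,
    f: float = 0.30,
) -> StemnessWindow:
    """Build the window from per-replicate median/IQR statistics.

    Accepts the output of :func:`lin28_stats` (columns ``median``/``iqr``)
    or a full solution table carrying ``replicate`` and ``LIN28`` columns.
    Statistics are averaged across replicates before the window is formed.
    """
    if not 0 < f <= 1:
        raise ValueError(f"window fraction must be in (0, 1], got {f}")
    if isinstance(lin28_by_replicate, pd.DataFrame) and "LIN28" in lin28_by_replicate.columns:
        stats = lin28_stats(lin28_by_replicate)
    else:
        stats = lin28_by_replicate
    m = float(stats["median"].mean())
    q = float(stats["iqr"].mean())
    if q <= 0:
        raise ValueError("degenerate LIN28 distribution: interquartile range is zero")
    return StemnessWindow(lower=m - f * q, upper=m + f * q, median=m, iqr=q, fraction=f)


@dataclass
class EnrichmentProbs:
    """p1/p2 per phenotype per replicate, with cross-replicate summaries."""

    per_replicate: pd.DataFrame   # columns: replicate, phenotype, p1, p2, n, n_window
    summary: pd.DataFrame         # index: phenotype; p1_mean, p1_sd, p2_mean, p2_sd
    window: StemnessWindow
    empty_window_replicates: tuple = ()

    def hybrid_sums(self) -> pd.DataFrame:
        """Mean p1/p2 summed over hybrid vs non-hybrid phenotypes."""
        s = self.summary
        rows = {}
        for name, group in (("hybrid", HYBRID_PHENOTYPES), ("nonhybrid", NONHYBRID_PHENOTYPES)):
            present = [p for p in group if p in s.index]
            rows[name] = {
                "p1": float(s.loc[present, "p1_mean"].sum()),
                "p2": float(s.loc[present, "p2_mean"].sum()),
            }
        return pd.DataFrame(rows).T


def conditional_probabilities(
    labeled: pd.DataFrame,
    w: StemnessWindow,
    node: str = "LIN28",
) -> EnrichmentProbs:
    """Compute p1 and p2 per phenotype, per replicate, then summarize.

    ``labeled`` must carry ``replicate``, ``phenotype`` and the LIN28 column
    on the same normalized scale the window was built on.
    """
    if labeled["phenotype"].isna().any():
        raise ValueError("every solution must carry a phenotype label")
    records = []
    empty = []
    phenotypes = sorted(labeled["phenotype"].unique())
    for rep, grp in labeled.groupby("replicate"):
        inside = w.contains(grp[node])
        n_window = int(inside.sum())
        if n_window == 0:
            empty.append(rep)
        for c in phenotypes:
            mask = (grp["phenotype"] == c).to_numpy()
            n_c = int(mask.sum())
            both = int((mask & inside).sum())
            records.append({
                "replicate": rep, "phenotype": c,
                "p1": both / n_c if n_c else np.nan,
                "p2": both / n_window if n_window else np.nan,
                "n": n_c, "n_window": n_window,
            })
    per_rep = pd.DataFrame.from_records(records)
    summary = per_rep.groupby("phenotype").agg(
        p1_mean=("p1", "mean"), p1_sd=("p1", "std"),
        p2_mean=("p2", "mean"), p2_sd=("p2", "std"),
    )
    return EnrichmentProbs(per_replicate=per_rep, summary=summary, window=w,
                           empty_window_replicates=tuple(empty))


def window_sensitivity(
    labeled: pd.DataFrame,
    stats: pd.DataFrame,
    f_list: Sequence[float],
    node: str = "LIN28",
) -> pd.DataFrame:
    """Window composition as the window fraction grows.

    For each ``f``: the window bounds, pooled in-window count, and the
    pooled share of each phenotype among in-window solutions (p2 computed on
    all replicates' solutions together, for stability at small f).
    """
    phenotypes = sorted(labeled["phenotype"].unique())
    rows = []
    for f in f_list:
        w = stemness_window(stats, f=f)
        inside = w.contains(labeled[node])
        n_in = int(inside.sum())
        row = {"f": f, "lower": w.lower, "upper": w.upper, "n_window": n_in}
        for c in phenotypes:
            both = int(((labeled["phenotype"] == c).to_numpy() & inside).sum())
            row[f"p2_{c}"] = both / n_in if n_in else np.nan
        rows.append(row)
    out = pd.DataFrame(rows).set_index("f")
    hybrid_cols = [f"p2_{c}" for c in HYBRID_PHENOTYPES if f"p2_{c}" in out.columns]
    out["hybrid_share"] = out[hybrid_cols].sum(axis=1)
    return out
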