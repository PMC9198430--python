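"""Enrichment-guided temporal clustering and ordering of pathway events.

Dynamic features' fold-change profiles are z-transformed across time
points and clustered with k-means over a sweep of k.  Each candidate
clustering is scored by annotation enrichment: the sum over clusters of
-log10(Fisher p) for terms significant after BH within the cluster.  The
k maximising this score is the reported optimum — clusterings that line
up with known pathway structure win.  Cluster mean profiles are then
reduced to up/down events timed at the half-amplitude crossing, giving
an ordered event table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans

from .stats import bh_adjust

__all__ = [
    "ClusterResult",
    "ztransform_profiles",
    "fisher_enrichment",
    "cluster_sweep",
    "event_times",
]


@dataclass
class ClusterResult:
    """Outcome of the enrichment-guided k sweep."""

    k_tried: list[int]
    memberships: dict[int, pd.Series]  # k -> feature -> cluster id
    enrichment_score: dict[int, float]  # k -> E(k)
    k_star: int
    enriched_terms: pd.DataFrame  # at k_star: cluster, term, odds_ratio, p, q
    no_enrichment: bool = False

    @property
    def labels(self) -> pd.Series:
        return self.memberships[self.k_star]


def ztransform_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """z-score each feature's fold-change profile across time points.

    Zero-variance (flat) features are dropped with a warning; the
    transform is idempotent on its own output.
    """
    if profiles.shape[1] < 3:
        raise ValueError("need at least 3 time points")
    X = profiles.to_numpy(dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel() | ~np.isfinite(sd).ravel()
    if flat.any():
        warnings.warn(
            f"dropping {int(flat.sum())} flat profile(s) with zero variance",
            UserWarning,
        )
    Z = (X[~flat] - mean[~flat]) / sd[~flat]
    return pd.DataFrame(Z, index=profiles.index[~flat], columns=profiles.columns)


def fisher_enrichment(
    members: set | Sequence, term: set | Sequence, universe: set | Sequence
) -> tuple[float, float]:
    """One-sided Fisher's exact test for term enrichment in a cluster.

    Returns (odds ratio, p) from the 2x2 table of cluster membership vs
    term membership over the universe; the odds ratio uses the Haldane
    0.5 correction when a cell is zero.
    """
    members, term, universe = set(members), set(term), set(universe)
    if not members <= universe or not term <= universe:
        raise ValueError("members and term must be subsets of the universe")
    a = len(members & term)
    b = len(members - term)
    c = len(term - members)
    d = len(universe - members - term)
    # hypergeometric upper tail: P(X >= a)
    p = float(sps.hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))
    if min(a, b, c, d) == 0:
        a_, b_, c_, d_ = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a_, b_, c_, d_ = a, b, c, d
    odds = (a_ * d_) / (b_ * c_)
    return float(odds), p


def _enrichment_at_k(
    labels: pd.Series, terms: Mapping[str, set], alpha: float
) -> tuple[float, pd.DataFrame]:
    universe = set(labels.index)
    rows = []
    for cid in sorted(labels.unique()):
        members = set(labels.index[labels == cid])
        cluster_rows = []
        for term_name, term_set in sorted(terms.items()):
            term_in = set(term_set) & universe
            if not term_in:
                continue
            odds, p = fisher_enrichment(members, term_in, universe)
            cluster_rows.append(
                {"cluster": cid, "term": term_name, "odds_ratio": odds, "p": p}
            )
        if cluster_rows:
            q = bh_adjust([r["p"] for r in cluster_rows])
            for r, qv in zip(cluster_rows, q):
                r["q"] = qv
            rows.extend(cluster_rows)
    table = pd.DataFrame(rows, columns=["cluster", "term", "odds_ratio", "p", "q"])
    if table.empty:
        return 0.0, table
    sig = table[table["q"] <= alpha]
    score = float(-np.log10(np.clip(sig["p"], 1e-300, None)).sum()) if len(sig) else 0.0
    return score, table


def cluster_sweep(
    zprofiles: pd.DataFrame,
    k_range: Sequence[int],
    terms: Mapping[str, set],
    n_starts: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> ClusterResult:
    """k-means over a range of k, scored by per-cluster term enrichment.

    E(k) sums -log10(Fisher p) of terms with BH q <= alpha within each
    cluster; k* maximises E(k) with ties broken toward smaller k.  When
    no term is enriched at any k, k* is still reported but flagged
    (``no_enrichment``) with a warning.
    """
    if not terms:
        raise ValueError("empty term annotation")
    k_range = sorted(set(int(k) for k in k_range))
    if min(k_range) < 2:
        raise ValueError("k must be at least 2")
    if max(k_range) > len(zprofiles) // 5:
        raise ValueError("largest k exceeds n_features / 5")
    X = zprofiles.to_numpy(dtype=float)
    memberships: dict[int, pd.Series] = {}
    scores: dict[int, float] = {}
    tables: dict[int, pd.DataFrame] = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed)
        labels = pd.Series(km.fit_predict(X), index=zprofiles.index, name="cluster")
        memberships[k] = labels
        scores[k], tables[k] = _enrichment_at_k(labels, terms, alpha)
    best = max(scores.values())
    k_star = min(k for k in k_range if scores[k] == best)
    no_enrichment = best == 0.0
    if no_enrichment:
        warnings.warn("no enriched terms at any k; optimal k is unguided", UserWarning)
    return ClusterResult(
        k_tried=k_range,
        memberships=memberships,
        enrichment_score=scores,
        k_star=k_star,
        enriched_terms=tables[k_star],
        no_enrichment=no_enrichment,
    )


def event_times(
    mean_profiles: pd.DataFrame, time_coords: Sequence[float]
) -> pd.DataFrame:
    """Reduce cluster mean profiles to ordered up/down events.

    Direction is *up* when the profile's maximum occurs after its
    minimum, *down* otherwise.  The event time is the first crossing of
    the half-amplitude level (midpoint of min and max), linearly
    interpolated between adjacent time points.  Flat profiles are
    excluded with a warning.  Ranks order events by time (ties by
    cluster id).
    """
    times = np.asarray(time_coords, dtype=float)
    if mean_profiles.shape[1] != times.size:
        raise ValueError("profile length must match the number of time coordinates")
    rows = []
    for cid, row in mean_profiles.iterrows():
        y = row.to_numpy(dtype=float)
        lo, hi = float(y.min()), float(y.max())
        if hi - lo < 1e-12:
            warnings.warn(f"cluster {cid!r} has a flat mean profile; excluded", UserWarning)
            continue
        direction = "up" if int(np.argmax(y)) > int(np.argmin(y)) else "down"
        mid = 0.5 * (lo + hi)
        event_t = times[-1]
        if direction == "up":
            crossed = y >= mid
        else:
            crossed = y <= mid
        for i in range(1, y.size):
            if not crossed[i - 1] and crossed[i]:
                frac = (mid - y[i - 1]) / (y[i] - y[i - 1])
                event_t = times[i - 1] + frac * (times[i] - times[i - 1])
                break
        else:
            if crossed[0]:
                event_t = times[0]
        rows.append({"cluster": cid, "direction": direction, "event_time": float(event_t)})
    table = pd.DataFrame(rows, columns=["cluster", "direction", "event_time"])
    if not table.empty:
        table = table.sort_values(
            ["event_time", "cluster"], kind="mergesort"
        ).reset_index(drop=True)
        table["rank"] = np.arange(1, len(table) + 1)
    else:
        table["rank"] = pd.Series(dtype=int)
    return table
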