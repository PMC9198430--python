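"""Kinase-substrate scoring from motif and temporal-profile evidence.

For each kinase with enough annotated (known) substrates, two evidence
streams are scored for every quantified site:

* **motif score** — how well the site's +/-7 flanking window matches a
  position-specific scoring matrix (PSSM) learned from the known
  substrates' windows, min-max normalised into [0, 1];
* **profile score** — Pearson correlation between the site's standardized
  temporal profile and the centroid profile of the known substrates,
  mapped to [0, 1] via (r + 1) / 2.

The combined score is their weighted geometric mean.  On top of the
score table sit the signalome network (kinases linked by shared
predicted substrate proteins) and the inhibitor-profile dissection that
splits high-scoring candidates between two kinase groups (e.g. MAPK1/3
vs MAPK8/9) by which inhibitor suppresses them more.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .kinact import ContrastMatrix
from .synth import AMINO_ACIDS, PAD

__all__ = [
    "PSSM",
    "build_pssm",
    "motif_score",
    "profile_score",
    "combined_score",
    "score_all",
    "build_signalome",
    "dissect_specificity",
]


@dataclass
class PSSM:
    """Position x residue probability table with pseudocount alpha."""

    kinase_id: str
    probs: pd.DataFrame  # positions x 20 residues
    alpha: float
    n_sequences: int

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("pseudocount alpha must be > 0")
        sums = self.probs.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("PSSM rows must sum to 1")


def build_pssm(
    kinase_id: str, windows: Sequence[str], alpha: float = 0.01, min_known: int = 5
) -> PSSM:
    """Learn a PSSM from a kinase's known-substrate windows.

    Probability at (position, residue) = (count + alpha) / (n_p + 20*alpha)
    where n_p counts non-padding residues at that position; padding
    symbols at protein termini contribute nothing.
    """
    windows = list(windows)
    if len(windows) < min_known:
        raise ValueError(
            f"kinase {kinase_id}: only {len(windows)} windows (min_known={min_known})"
        )
    lengths = {len(w) for w in windows}
    if len(lengths) != 1:
        raise ValueError("windows must share one length")
    (L,) = lengths
    counts = np.zeros((L, len(AMINO_ACIDS)))
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    for w in windows:
        for p, ch in enumerate(w):
            if ch == PAD:
                continue
            if ch not in aa_index:
                raise ValueError(f"unknown residue {ch!r} in window {w!r}")
            counts[p, aa_index[ch]] += 1
    n_p = counts.sum(axis=1, keepdims=True)
    probs = (counts + alpha) / (n_p + len(AMINO_ACIDS) * alpha)
    center = L // 2
    table = pd.DataFrame(probs, index=range(-center, L - center), columns=list(AMINO_ACIDS))
    return PSSM(kinase_id=kinase_id, probs=table, alpha=alpha, n_sequences=len(windows))


def motif_score(pssm: PSSM, window: str) -> float:
    """Score a window against a PSSM, min-max normalised into [0, 1].

    The raw score is the mean log-probability over non-padding positions;
    it is rescaled by the best/worst achievable raw scores under the PSSM
    (per-position max/min log-probability over the same positions).  A
    fully degenerate (uniform) PSSM scores every window 0.5 by
    convention.
    """
    L = pssm.probs.shape[0]
    if len(window) != L:
        raise ValueError(f"window length {len(window)} != PSSM length {L}")
    logp = np.log(pssm.probs.to_numpy())
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    raws, maxs, mins = [], [], []
    for p, ch in enumerate(window):
        if ch == PAD:
            continue
        if ch not in aa_index:
            raise ValueError(f"unknown residue {ch!r} in window {window!r}")
        raws.append(logp[p, aa_index[ch]])
        maxs.append(logp[p].max())
        mins.append(logp[p].min())
    if not raws:
        raise ValueError("all-padding window cannot be scored")
    raw, raw_max, raw_min = np.mean(raws), np.mean(maxs), np.mean(mins)
    if raw_max - raw_min < 1e-12:
        return 0.5
    return float((raw - raw_min) / (raw_max - raw_min))


def profile_score(
    site_profile: np.ndarray | pd.Series, centroid: np.ndarray | pd.Series
) -> float | None:
    """Pearson correlation with the known-substrate centroid, mapped to [0, 1].

    Returns None (recorded as missing) for zero-variance profiles.
    """
    x = np.asarray(site_profile, dtype=float)
    y = np.asarray(centroid, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("profiles must share a length of at least 2")
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    r = float(np.corrcoef(x, y)[0, 1])
    return (r + 1.0) / 2.0


def combined_score(s_motif: float, s_profile: float, w: float = 0.5) -> float:
    """Weighted geometric mean of motif and profile scores: S_m^w * S_p^(1-w)."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must be in [0, 1]")
    return float(s_motif ** w * s_profile ** (1.0 - w))


def score_all(
    windows: Mapping[str, str],
    profiles: pd.DataFrame,
    annotation: Mapping[str, Sequence[str]],
    min_known: int = 5,
    w: float = 0.5,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Score every quantified site against every eligible kinase.

    Parameters
    ----------
    windows
        site id -> flanking window (sites without windows are skipped).
    profiles
        sites x contrasts standardized temporal profiles.
    annotation
        kinase -> known substrate site ids (the training sets).

    Returns a long table (site, kinase, S_motif, S_profile, S_combined,
    known) covering |sites| x |eligible kinases| rows; kinases with
    fewer than ``min_known`` known substrates present in the data are
    skipped and listed in ``table.attrs['skipped_kinases']``.
    """
    if not annotation:
        raise ValueError("empty kinase-substrate annotation")
    sites = [s for s in profiles.index if s in windows]
    rows = []
    skipped = []
    for kinase in sorted(annotation):
        known = [s for s in annotation[kinase] if s in windows and s in profiles.index]
        if len(known) < min_known:
            skipped.append(kinase)
            continue
        pssm = build_pssm(kinase, [windows[s] for s in known], alpha=alpha, min_known=min_known)
        centroid = profiles.loc[known].mean(axis=0).to_numpy()
        known_set = set(known)
        for site in sites:
            s_m = motif_score(pssm, windows[site])
            s_p = profile_score(profiles.loc[site].to_numpy(), centroid)
            s_c = combined_score(s_m, s_p, w) if s_p is not None else np.nan
            rows.append(
                {
                    "site": site,
                    "kinase": kinase,
                    "S_motif": s_m,
                    "S_profile": np.nan if s_p is None else s_p,
                    "S_combined": s_c,
                    "known": site in known_set,
                }
            )
    table = pd.DataFrame(
        rows, columns=["site", "kinase", "S_motif", "S_profile", "S_combined", "known"]
    )
    table.attrs["skipped_kinases"] = skipped
    table.attrs["w"] = w
    return table


def build_signalome(
    table: pd.DataFrame,
    site_to_protein: Mapping[str, str],
    assign_threshold: float = 0.5,
) -> tuple[dict[str, str], nx.Graph]:
    """Assign sites to kinases and link kinases by shared substrate proteins.

    Each site goes to its argmax-scoring kinase when that combined score
    reaches ``assign_threshold`` (ties break lexicographically).  An
    undirected edge between two kinases weighs the number of distinct
    proteins carrying at least one assigned site that scores at or above
    the threshold for *both* kinases.
    """
    wide = table.pivot(index="site", columns="kinase", values="S_combined")
    assignments: dict[str, str] = {}
    for site, row in wide.iterrows():
        scores = row.dropna()
        if scores.empty:
            continue
        best = scores.max()
        if best >= assign_threshold:
            # lexicographic tie-break over equally scoring kinases
            winners = sorted(scores.index[scores == best])
            assignments[site] = winners[0]
    graph = nx.Graph()
    graph.add_nodes_from(sorted(wide.columns))
    shared: dict[tuple[str, str], set[str]] = {}
    for site in assignments:
        prot = site_to_protein.get(site)
        if prot is None:
            continue
        above = sorted(wide.columns[(wide.loc[site] >= assign_threshold).fillna(False)])
        for i, k1 in enumerate(above):
            for k2 in above[i + 1 :]:
                shared.setdefault((k1, k2), set()).add(prot)
    for (k1, k2), prots in shared.items():
        graph.add_edge(k1, k2, weight=len(prots))
    return assignments, graph


def dissect_specificity(
    table: pd.DataFrame,
    zmat_inhibition: ContrastMatrix,
    kinase_groups: Mapping[str, Sequence[str]],
    score_threshold: float = 0.7,
    axes: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Split high-scoring candidate substrates between two kinase groups.

    Candidates are sites whose best combined score within either group
    exceeds ``score_threshold``.  A candidate belongs to the first group
    when it is more inhibited under the first group's inhibitor contrast
    (z_first < z_second) and vice versa; ties stay unassigned
    (``group = None``).  Candidates missing an inhibition value are
    excluded and listed in ``result.attrs['excluded']``.
    """
    if len(kinase_groups) != 2:
        raise ValueError("exactly two kinase groups are required")
    if axes is None:
        axes = tuple(zmat_inhibition.contrasts[:2])
    g1, g2 = list(kinase_groups)
    wide = table.pivot(index="site", columns="kinase", values="S_combined")
    group_scores = {}
    for g, members in kinase_groups.items():
        present = [k for k in members if k in wide.columns]
        if not present:
            raise ValueError(f"no scored kinases for group {g!r}")
        group_scores[g] = wide[present].max(axis=1)
    best = pd.DataFrame(group_scores)
    candidates = best.index[(best > score_threshold).any(axis=1)]
    rows, excluded = [], []
    z = zmat_inhibition.z
    for site in candidates:
        if site not in z.index or z.loc[site, list(axes)].isna().any():
            excluded.append(site)
            continue
        z1 = float(z.at[site, axes[0]])
        z2 = float(z.at[site, axes[1]])
        if z1 < z2:
            group = g1
        elif z2 < z1:
            group = g2
        else:
            group = None
        rows.append(
            {
                "site": site,
                "group": group,
                "S_combined": float(best.loc[site].max()),
                f"z_{axes[0]}": z1,
                f"z_{axes[1]}": z2,
            }
        )
    result = pd.DataFrame(
        rows, columns=["site", "group", "S_combined", f"z_{axes[0]}", f"z_{axes[1]}"]
    )
    result.attrs["excluded"] = excluded
    return result
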