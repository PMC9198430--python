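"""Cross-omics concordance and morphology-index arithmetic.

Compares a bulk proteome time course against single-cell transcriptomes:
cells are gated on marker genes, sparse genes dropped, the top highly
variable genes selected, and each cell correlated with each proteome
time point over the shared gene set.  Also computes the standard
image-derived myogenesis indices (differentiation index, percentage of
MHC-positive cells, fusion index) from nuclei counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GateRule",
    "CountSummary",
    "gate_cells",
    "filter_sparse_genes",
    "top_hvg",
    "correlate_cells_to_timepoints",
    "morphology_indices",
]


@dataclass(frozen=True)
class GateRule:
    """Marker gate: (any positive marker expressed) AND (all negative absent)."""

    positive: tuple[str, ...] = ("Myf5", "Myod1")
    negative: tuple[str, ...] = ("Myog",)
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if set(self.positive) & set(self.negative):
            raise ValueError("positive and negative marker sets overlap")


@dataclass(frozen=True)
class CountSummary:
    """Image-derived nuclei counts from stained wells."""

    total_nuclei: int
    nuclei_in_mhc_pos: int
    mhc_pos_cells: int
    nuclei_in_myotubes: int  # within multinucleated (>=4 nuclei) myotubes

    def __post_init__(self) -> None:
        counts = (
            self.total_nuclei,
            self.nuclei_in_mhc_pos,
            self.mhc_pos_cells,
            self.nuclei_in_myotubes,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if max(counts[1:]) > self.total_nuclei:
            raise ValueError("component counts cannot exceed total nuclei")


def gate_cells(expr: pd.DataFrame, rule: GateRule = GateRule()) -> list[str]:
    """Select cells passing the marker gate from a cells x genes matrix."""
    for g in (*rule.positive, *rule.negative):
        if g not in expr.columns:
            raise ValueError(f"marker gene {g!r} absent from expression matrix")
    pos = (expr[list(rule.positive)] > rule.threshold).any(axis=1)
    neg = (expr[list(rule.negative)] <= rule.threshold).all(axis=1)
    return list(expr.index[pos & neg])


def filter_sparse_genes(expr: pd.DataFrame, max_zero_fraction: float = 0.95) -> list[str]:
    """Keep genes whose zero fraction is at most ``max_zero_fraction``."""
    zero_frac = (expr == 0).mean(axis=0)
    return list(expr.columns[zero_frac <= max_zero_fraction])


def top_hvg(expr: pd.DataFrame, n: int = 100) -> list[str]:
    """Top ``n`` highly variable genes by variance of log1p expression.

    Ties break by gene id order; ``n`` larger than the gene count
    returns every gene.
    """
    logged = np.log1p(expr)
    var = logged.var(axis=0, ddof=1)
    ranked = pd.DataFrame({"var": var, "gene": var.index.astype(str)})
    ranked = ranked.sort_values(["var", "gene"], ascending=[False, True], kind="mergesort")
    return list(ranked.index[: min(n, len(ranked))])


def correlate_cells_to_timepoints(
    expr: pd.DataFrame, proteome: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r between each cell and each proteome time point over shared genes.

    ``expr`` is cells x genes (restricted to HVGs beforehand), ``proteome``
    is genes x time points of log2 ratios; gene matching is by exact
    identifier.  Pairs with missing values are dropped pairwise.
    """
    shared = [g for g in expr.columns if g in proteome.index]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need at least 3")
    out = pd.DataFrame(index=expr.index, columns=proteome.columns, dtype=float)
    E = expr[shared]
    P = proteome.loc[shared]
    for tp in proteome.columns:
        y = P[tp]
        for cell in expr.index:
            x = E.loc[cell]
            ok = x.notna() & y.notna()
            if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
                out.at[cell, tp] = np.nan
                continue
            out.at[cell, tp] = float(np.corrcoef(x[ok], y[ok])[0, 1])
    return out


def morphology_indices(c: CountSummary) -> tuple[float, float, float]:
    """(differentiation index, fraction MHC+, fusion index) from nuclei counts.

    differentiation index = nuclei within MHC+ cells / total nuclei;
    fraction MHC+ = MHC+ cell count / total nuclei;
    fusion index = nuclei within multinucleated (>=4) myotubes / total nuclei.
    """
    if c.total_nuclei == 0:
        raise ValueError("total nuclei count is zero")
    total = float(c.total_nuclei)
    return (
        c.nuclei_in_mhc_pos / total,
        c.mhc_pos_cells / total,
        c.nuclei_in_myotubes / total,
    )
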