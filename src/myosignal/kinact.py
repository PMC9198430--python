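"""Substrate-set kinase-activity inference on standardized contrasts.

A kinase's activity at a contrast (e.g. 30m-vs-0h) is summarised by the
Stouffer combination of its known substrates' standardized phosphorylation
changes: Z = sum(z_i) / sqrt(n).  For paired inhibitor experiments the
same statistic is evaluated along unit directions in the plane of the two
inhibitor contrasts ("rotated z-space"), attributing inhibition to one
treatment, the other, or both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import QuantMatrix
from .stats import bh_adjust

__all__ = [
    "ContrastMatrix",
    "Direction",
    "standardize",
    "stouffer_set_test",
    "project",
    "canonical_inhibition_directions",
    "kinase_direction_analysis",
    "kinase_activity_timecourse",
]


@dataclass
class ContrastMatrix:
    """Features x contrasts standardized scores (each column: mean 0, sd 1)."""

    z: pd.DataFrame

    @property
    def features(self) -> pd.Index:
        return self.z.index

    @property
    def contrasts(self) -> list[str]:
        return list(self.z.columns)


@dataclass(frozen=True)
class Direction:
    """A unit direction in contrast space with a human-readable label."""

    vector: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        norm = float(np.linalg.norm(self.vector))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"direction {self.label or self.vector} is not unit norm")


def standardize(
    ratios: QuantMatrix,
    contrasts: Mapping[str, str] | Sequence[str] | None = None,
) -> ContrastMatrix:
    """Collapse replicate ratios to per-contrast means and z-standardize columns.

    ``contrasts`` maps contrast label -> condition (whose mean log2 ratio
    versus the built-in reference is the raw score).  By default every
    non-reference condition becomes a contrast named ``{cond}-vs-{ref}``.
    Columns are centred and scaled by the sample standard deviation
    (ddof=1); a zero-variance column is an error.
    """
    if ratios.scale != "ratio":
        raise ValueError("standardize expects a ratio-scale matrix")
    conds = list(ratios.condition_order)
    if contrasts is None:
        contrasts = {f"{c}-vs-{conds[0]}": c for c in conds[1:]}
    elif not isinstance(contrasts, Mapping):
        contrasts = {c: c for c in contrasts}
    cols = {}
    for label, cond in contrasts.items():
        if cond not in conds:
            raise ValueError(f"contrast {label!r}: condition {cond!r} not in design")
        cols[label] = ratios.values[ratios.samples_of(cond)].mean(axis=1)
    raw = pd.DataFrame(cols)
    sd = raw.std(axis=0, ddof=1)
    if (sd == 0).any() or sd.isna().any():
        bad = list(sd.index[(sd == 0) | sd.isna()])
        raise ValueError(f"zero-variance contrast column(s): {bad}")
    z = (raw - raw.mean(axis=0)) / sd
    return ContrastMatrix(z=z)


def stouffer_set_test(z: pd.Series, members: Iterable[str]) -> tuple[float, float]:
    """Stouffer combination over a feature set: Z = sum(z_i)/sqrt(n), two-sided p."""
    members = list(members)
    if not members:
        raise ValueError("empty member set")
    absent = [mb for mb in members if mb not in z.index]
    if absent:
        raise ValueError(f"members absent from score vector: {absent[:5]}")
    vals = z.loc[members].to_numpy(dtype=float)
    Z = float(vals.sum() / np.sqrt(len(vals)))
    p = float(2.0 * sps.norm.sf(abs(Z)))
    return Z, p


def project(zmat: ContrastMatrix, direction: Direction) -> pd.Series:
    """Project each feature's contrast scores onto a unit direction.

    Under independent standard-normal columns the projected scores are
    again standard normal, so the Stouffer set test applies unchanged.
    """
    vec = np.asarray(direction.vector, dtype=float)
    if vec.shape[0] != zmat.z.shape[1]:
        raise ValueError(
            f"direction has {vec.shape[0]} axes but matrix has {zmat.z.shape[1]} contrasts"
        )
    scores = zmat.z.to_numpy(dtype=float) @ vec
    return pd.Series(scores, index=zmat.features, name=direction.label or "projected")


def canonical_inhibition_directions(
    axes: tuple[str, str] = ("PD", "SP")
) -> list[Direction]:
    """The 8 unit directions at 45-degree steps in the two-inhibitor plane.

    Treatment contrasts are log2(treated/control), so inhibition is
    negative: "inhibited by PD only" = (-1, 0), "by SP only" = (0, -1),
    "by both" = (-1/sqrt(2), -1/sqrt(2)).
    """
    a, b = axes
    s = 1.0 / np.sqrt(2.0)
    spec = [
        ((1.0, 0.0), f"up in {a} only"),
        ((s, s), f"up in both {a} and {b}"),
        ((0.0, 1.0), f"up in {b} only"),
        ((-s, s), f"inhibited by {a}, up in {b}"),
        ((-1.0, 0.0), f"inhibited by {a} only"),
        ((-s, -s), f"inhibited by both {a} and {b}"),
        ((0.0, -1.0), f"inhibited by {b} only"),
        ((s, -s), f"up in {a}, inhibited by {b}"),
    ]
    return [Direction(vector=v, label=lab) for v, lab in spec]


def _set_test_table(
    score_columns: Mapping[str, pd.Series],
    annotation: Mapping[str, Sequence[str]],
    min_substrates: int,
    axis_name: str,
) -> pd.DataFrame:
    rows = []
    skipped: list[str] = []
    for kinase in sorted(annotation):
        for axis, scores in score_columns.items():
            members = [s for s in annotation[kinase] if s in scores.index]
            if len(members) < min_substrates:
                skipped.append(kinase)
                break
            Z, p = stouffer_set_test(scores, members)
            rows.append(
                {"kinase": kinase, axis_name: axis, "n": len(members), "Z": Z, "p": p}
            )
    table = pd.DataFrame(rows, columns=["kinase", axis_name, "n", "Z", "p"])
    if not table.empty:
        table["q"] = np.nan
        for axis in table[axis_name].unique():
            mask = table[axis_name] == axis
            table.loc[mask, "q"] = bh_adjust(table.loc[mask, "p"].to_numpy())
    else:
        table["q"] = pd.Series(dtype=float)
    table.attrs["skipped_kinases"] = sorted(set(skipped))
    return table


def kinase_direction_analysis(
    zmat: ContrastMatrix,
    annotation: Mapping[str, Sequence[str]],
    directions: Sequence[Direction] | None = None,
    min_substrates: int = 3,
) -> pd.DataFrame:
    """Direction-based integrative kinase test over paired inhibitor contrasts.

    For each (kinase, direction) the substrate z-scores are projected
    onto the direction and combined with the Stouffer statistic; BH
    adjustment runs across kinases within each direction.  Kinases with
    fewer than ``min_substrates`` quantified substrates are excluded and
    recorded in ``table.attrs['skipped_kinases']``.
    """
    if directions is None:
        directions = canonical_inhibition_directions(tuple(zmat.contrasts[:2]))
    cols = {d.label: project(zmat, d) for d in directions}
    return _set_test_table(cols, annotation, min_substrates, "direction")


def kinase_activity_timecourse(
    zmat: ContrastMatrix,
    annotation: Mapping[str, Sequence[str]],
    min_substrates: int = 3,
) -> pd.DataFrame:
    """Signed kinase activity (Stouffer Z) per time contrast.

    Substrates annotated to a kinase but absent from the matrix are
    skipped; the reported ``n`` is the number actually used.
    """
    cols = {c: zmat.z[c] for c in zmat.contrasts}
    return _set_test_table(cols, annotation, min_substrates, "contrast")
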