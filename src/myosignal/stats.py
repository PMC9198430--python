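"""Differential and dynamic-regulation statistics.

Implements the moderated t-test with empirical-Bayes variance shrinkage
(the limma-style squeezing of per-feature sample variances toward a
common prior estimated by the method of moments on log variances),
classical one-way ANOVA for dynamic-regulation calls, and
Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "anova_oneway",
    "dynamic_call",
    "eb_moderate",
    "moderated_t",
    "two_group_moderated",
    "contrast_vs_reference_de",
]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def anova_oneway(groups) -> tuple[float, float]:
    """Classical one-way ANOVA F and p over replicate groups.

    Degenerate case of zero within-group variance with unequal means is
    reported as (inf, 0.0).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[~np.isnan(g)] for g in groups]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two non-empty groups")
    within_ss = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    means = [g.mean() for g in groups]
    if within_ss == 0.0:
        if np.allclose(means, means[0]):
            return 0.0, 1.0
        return float("inf"), 0.0
    F, p = sps.f_oneway(*groups)
    return float(F), float(p)


# ---------------------------------------------------------------------------
# Empirical-Bayes variance moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return float("inf")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def eb_moderate(s2, d: float) -> tuple[float, float]:
    """Estimate the prior variance s0^2 and prior df d0 from sample variances.

    Method of moments on log sample variances: with s^2 ~ s0^2 * F(d, d0),
    the mean and variance of log s^2 identify (s0^2, d0) through digamma /
    trigamma relations.  When the empirical variance of log s^2 is at or
    below the trigamma(d/2) floor, the prior is effectively exact and
    d0 = inf with s0^2 the (geometric-mean) common variance.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 10:
        raise ValueError("need at least 10 positive sample variances")
    if d <= 0:
        raise ValueError("residual df must be positive")
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    if e_var < 1e-15:
        # literally identical variances: no chi-square sampling spread, so the
        # log-scale bias correction does not apply; the prior is that value
        return float(s2[0]), float("inf")
    excess = e_var - float(special.polygamma(1, d / 2.0))
    if excess <= 0:
        return float(np.exp(e_mean)), float("inf")
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return s0_2, d0


@dataclass
class ModeratedTestResult:
    """Per-feature moderated-t output plus the shared prior."""

    table: pd.DataFrame  # feature, log2FC, s2, s2_post, t, df_total, p, q, de
    s0_2: float
    d0: float


def moderated_t(
    log2fc,
    s2,
    n1: int,
    n2: int,
    s0_2: float,
    d0: float,
    features=None,
    fc_threshold: float = 1.0,
    fdr: float = 0.05,
) -> ModeratedTestResult:
    """Moderated two-group t-test from per-feature effects and pooled variances.

    The posterior variance blends the feature's pooled variance s^2
    (with d = n1 + n2 - 2 df) and the prior s0^2 (d0 df):

        s2_post = (d0 * s0^2 + d * s^2) / (d0 + d)
        t = log2FC / sqrt(s2_post * (1/n1 + 1/n2)),  df = d + d0.

    d0 = 0 reproduces the classical pooled t exactly; d0 = inf uses the
    prior variance alone with normal reference.  A feature is called DE
    when |log2FC| >= fc_threshold and q < fdr (fold-change threshold
    inclusive, FDR threshold strict).
    """
    log2fc = np.asarray(log2fc, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    d = n1 + n2 - 2
    if d <= 0:
        raise ValueError("need at least 3 samples across the two groups")
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2.copy()
        df_total = float(d)
    else:
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        df_total = float(d + d0)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / se
    if np.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df=df_total)
    q = bh_adjust(p)
    de = (np.abs(log2fc) >= fc_threshold) & (q < fdr)
    if features is None:
        features = pd.RangeIndex(len(log2fc))
    table = pd.DataFrame(
        {
            "log2FC": log2fc,
            "s2": s2,
            "s2_post": s2_post,
            "t": t,
            "df_total": df_total,
            "p": p,
            "q": q,
            "de": de,
        },
        index=pd.Index(features, name="feature"),
    )
    return ModeratedTestResult(table=table, s0_2=s0_2, d0=d0)


def two_group_moderated(
    group1: pd.DataFrame,
    group2: pd.DataFrame,
    d0: float | None = None,
    s0_2: float | None = None,
    fc_threshold: float = 1.0,
    fdr: float = 0.05,
) -> ModeratedTestResult:
    """Moderated t between two features x replicates matrices.

    Estimates (s0^2, d0) by :func:`eb_moderate` unless given explicitly
    (pass ``d0=0`` for the classical unmoderated test).
    """
    if not group1.index.equals(group2.index):
        raise ValueError("the two groups must share the same feature index")
    x1 = group1.to_numpy(dtype=float)
    x2 = group2.to_numpy(dtype=float)
    n1, n2 = x1.shape[1], x2.shape[1]
    d = n1 + n2 - 2
    fc = x1.mean(axis=1) - x2.mean(axis=1)
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / d
    if d0 is None or s0_2 is None:
        est_s0_2, est_d0 = eb_moderate(s2, d)
        s0_2 = est_s0_2 if s0_2 is None else s0_2
        d0 = est_d0 if d0 is None else d0
    return moderated_t(
        fc, s2, n1, n2, s0_2, d0,
        features=group1.index, fc_threshold=fc_threshold, fdr=fdr,
    )


# ---------------------------------------------------------------------------
# Dynamic-regulation calls
# ---------------------------------------------------------------------------

def dynamic_call(
    ratios,
    fc_threshold: float = 1.0,
    min_timepoints: int = 2,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Call dynamically regulated features over a ratio-scale time course.

    A feature is dynamic when its absolute log2 fold change (condition
    mean relative to the reference) exceeds ``fc_threshold`` at
    ``min_timepoints`` or more time points AND the BH-adjusted one-way
    ANOVA p over all time points is at or below ``fdr``.

    ``ratios`` is a :class:`~myosignal.preprocess.QuantMatrix` on the
    ratio scale (reference condition included, at 0 by construction).
    """
    if ratios.scale != "ratio":
        raise ValueError("dynamic_call expects a ratio-scale matrix")
    conds = list(ratios.condition_order)
    reference = conds[0]
    nonref = conds[1:]
    cond_means = pd.DataFrame(
        {c: ratios.values[ratios.samples_of(c)].mean(axis=1) for c in nonref}
    )
    n_big = (cond_means.abs() > fc_threshold).sum(axis=1)
    max_fc = cond_means.abs().max(axis=1)
    F = np.empty(len(ratios.features))
    p = np.empty(len(ratios.features))
    groups_cols = [ratios.samples_of(c) for c in conds]
    vals = ratios.values
    for i, feat in enumerate(ratios.features):
        groups = [vals.loc[feat, cols].to_numpy(dtype=float) for cols in groups_cols]
        F[i], p[i] = anova_oneway(groups)
    q = bh_adjust(p)
    dynamic = (n_big.to_numpy() >= min_timepoints) & (q <= fdr)
    return pd.DataFrame(
        {
            "max_abs_log2FC": max_fc,
            "n_timepoints_above": n_big,
            "F": F,
            "p": p,
            "q": q,
            "dynamic": dynamic,
        },
        index=ratios.features,
    )


# ---------------------------------------------------------------------------
# Two-stage contrast against a shared reference
# ---------------------------------------------------------------------------

def contrast_vs_reference_de(
    treatment: pd.DataFrame,
    mutant: pd.DataFrame,
    reference: pd.DataFrame,
    fc_threshold: float = 1.0,
    fdr: float = 0.05,
) -> ModeratedTestResult:
    """Two-stage differential expression against a shared reference.

    Both comparison groups (features x replicates, log2 intensities) are
    first converted to ratios against the reference group's per-feature
    mean; the two normalised ratio sets are then compared with the
    moderated t-test.  Swapping the two groups negates every log2FC.
    """
    for m in (treatment, mutant):
        if not m.index.equals(reference.index):
            raise ValueError("all three groups must share the same feature index")
    ref_mean = reference.mean(axis=1)
    r1 = treatment.sub(ref_mean, axis=0)
    r2 = mutant.sub(ref_mean, axis=0)
    return two_group_moderated(r1, r2, fc_threshold=fc_threshold, fdr=fdr)
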