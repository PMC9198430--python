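"""Filtering, imputation, ratio conversion and normalisation of quantification matrices.

The input is a features x samples table of log2 label-free quantification
(LFQ) intensities with explicit missing cells, plus a per-sample design
(condition, replicate, batch).  The operations here mirror the standard
phosphoproteomics preprocessing chain:

1. presence filtering (minimum numbers of quantified values overall and
   within conditions, optionally requiring adjacent time points),
2. two-stage imputation: condition-specific draws where a condition has
   enough observed replicates, then a down-shifted-normal "random tail"
   draw per sample for the left-censored remainder,
3. conversion to log2 ratios against a reference condition,
4. additive batch correction,
5. removal of unwanted variation (RUV) against negative-control features,
6. correction of phosphosite ratios by the host protein's ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QuantMatrix",
    "FilterRule",
    "read_quant_matrix",
    "write_quant_matrix",
    "filter_features",
    "impute_condition_specific",
    "impute_random_tail",
    "to_ratios",
    "correct_batch",
    "select_stable_features",
    "ruv_normalize",
    "proteome_correct",
]

DESIGN_COLUMNS = ("condition", "replicate", "batch")


@dataclass
class QuantMatrix:
    """A features x samples log2 quantification matrix with sample design.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample;
        missing cells are NaN.
    design
        DataFrame indexed by sample id with columns ``condition``,
        ``replicate`` and ``batch``; one row per sample, in the same
        order as the value columns.
    scale
        ``"intensity"`` for log2 intensities, ``"ratio"`` for log2 ratios
        relative to a reference condition.
    condition_order
        Time/condition order used wherever adjacency matters.  Defaults
        to order of first appearance in the design.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    scale: str = "intensity"
    condition_order: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated feature ids: {dups}")
        missing_cols = [c for c in DESIGN_COLUMNS if c not in self.design.columns]
        if missing_cols:
            raise ValueError(f"design lacks columns: {missing_cols}")
        data_samples = list(self.values.columns)
        design_samples = list(self.design.index)
        if set(data_samples) != set(design_samples):
            only_data = sorted(set(data_samples) - set(design_samples))
            only_design = sorted(set(design_samples) - set(data_samples))
            raise ValueError(
                "sample ids in data and design do not match; "
                f"only in data: {only_data}; only in design: {only_design}"
            )
        # align design row order to the data columns
        self.design = self.design.loc[data_samples]
        if not self.condition_order:
            seen: list[str] = []
            for c in self.design["condition"]:
                if c not in seen:
                    seen.append(c)
            self.condition_order = tuple(seen)
        if self.scale not in ("intensity", "ratio"):
            raise ValueError(f"unknown scale {self.scale!r}")

    # -- conveniences -------------------------------------------------
    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def conditions(self) -> tuple[str, ...]:
        return self.condition_order

    @property
    def batches(self) -> list:
        out = []
        for b in self.design["batch"]:
            if b not in out:
                out.append(b)
        return out

    def samples_of(self, condition: str, batch=None) -> list[str]:
        mask = self.design["condition"] == condition
        if batch is not None:
            mask &= self.design["batch"] == batch
        return list(self.design.index[mask])

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def copy(self) -> "QuantMatrix":
        return replace(self, values=self.values.copy(), design=self.design.copy())


@dataclass(frozen=True)
class FilterRule:
    """Presence-filter thresholds.

    A feature is retained iff its total number of quantified values is at
    least ``min_total_quantified`` AND there exist at least
    ``min_conditions`` conditions (consecutive in the declared condition
    order when ``adjacency_required``) each holding at least
    ``min_reps_within_condition`` quantified replicates.
    """

    min_total_quantified: int = 0
    min_reps_within_condition: int = 1
    min_conditions: int = 1
    adjacency_required: bool = False

    # canonical rule sets used by the study designs ------------------
    @classmethod
    def phospho_timecourse(cls) -> "FilterRule":
        """>=4 of 16 quantified overall and >=3 of 4 replicates in >=1 time point."""
        return cls(4, 3, 1, False)

    @classmethod
    def phospho_inhibition(cls) -> "FilterRule":
        """>=3 of 12 quantified overall and >=3 of 4 replicates in >=1 condition."""
        return cls(3, 3, 1, False)

    @classmethod
    def proteome_timecourse(cls) -> "FilterRule":
        """>=2 of 4 replicates quantified in >=2 adjacent time points."""
        return cls(0, 2, 2, True)

    @classmethod
    def proteome_inhibition(cls) -> "FilterRule":
        """>=4 of 15 quantified overall and >=3 of 4 replicates in >=1 condition."""
        return cls(4, 3, 1, False)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_quant_matrix(path, design_path, scale: str = "intensity") -> QuantMatrix:
    """Read a tab-delimited quantification matrix plus its sample design.

    The matrix file has feature ids in the first column and one column
    per sample; empty fields are missing values.  Malformed numeric
    cells raise a ``ValueError`` naming the offending row and column.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col].replace("", np.nan), errors="coerce")
        bad = converted.isna() & (raw[col] != "") & raw[col].notna()
        if bad.any():
            row = raw.index[bad.to_numpy()][0]
            raise ValueError(
                f"malformed numeric value {raw.loc[row, col]!r} at row {row!r}, column {col!r}"
            )
        values[col] = converted
    values.index.name = None
    values.columns.name = None
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    return QuantMatrix(values=values, design=design, scale=scale)


def write_quant_matrix(m: QuantMatrix, path, design_path=None) -> None:
    """Write the matrix (and optionally the design) as TSV; NaN -> empty field."""
    out = m.values.copy()
    out.index.name = out.index.name or "feature"
    out.to_csv(path, sep="\t", na_rep="")
    if design_path is not None:
        d = m.design.copy()
        d.index.name = d.index.name or "sample"
        d.to_csv(design_path, sep="\t")


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_features(m: QuantMatrix, rule: FilterRule) -> QuantMatrix:
    """Apply a presence :class:`FilterRule`; returns a matrix of retained features."""
    conds = list(m.condition_order)
    reps_per_cond = m.design.groupby("condition").size()
    if rule.min_reps_within_condition > int(reps_per_cond.max()):
        raise ValueError(
            "min_reps_within_condition exceeds the replicate count of every condition"
        )
    observed = m.values.notna()
    total = observed.sum(axis=1)
    # quantified replicate count per (feature, condition)
    cond_counts = pd.DataFrame(
        {c: observed[m.samples_of(c)].sum(axis=1) for c in conds}
    )
    qualifies = cond_counts >= rule.min_reps_within_condition

    if rule.adjacency_required:
        if rule.min_conditions > 1:
            run = np.zeros(len(m.features), dtype=int)
            best = np.zeros(len(m.features), dtype=int)
            for c in conds:
                q = qualifies[c].to_numpy()
                run = np.where(q, run + 1, 0)
                best = np.maximum(best, run)
            cond_ok = best >= rule.min_conditions
        else:
            cond_ok = qualifies.any(axis=1).to_numpy()
    else:
        cond_ok = (qualifies.sum(axis=1) >= rule.min_conditions).to_numpy()

    keep = (total >= rule.min_total_quantified).to_numpy() & cond_ok
    return replace(m, values=m.values.loc[keep].copy(), design=m.design.copy())


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def impute_condition_specific(
    m: QuantMatrix,
    min_observed: int = 3,
    seed: int | None = 0,
    mode: str = "draw",
) -> QuantMatrix:
    """First-stage imputation from observed replicates of the same condition.

    For each (feature, condition) cell group with at least ``min_observed``
    observed replicates, every missing cell is replaced by a draw from
    N(mean_observed, sd_observed) (``mode="draw"``, seeded) or by the
    observed mean (``mode="mean"``).  Conditions with fewer observed
    replicates are left untouched for the second-stage tail imputation.
    """
    if m.scale != "intensity":
        raise ValueError("condition-specific imputation expects an intensity-scale matrix")
    if mode not in ("draw", "mean"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    values = m.values.copy()
    for cond in m.condition_order:
        cols = m.samples_of(cond)
        block = values[cols]
        obs_count = block.notna().sum(axis=1)
        target = obs_count[(obs_count >= min_observed) & (obs_count < len(cols))].index
        for feat in target:
            row = block.loc[feat]
            obs = row.dropna()
            mu = float(obs.mean())
            sd = float(obs.std(ddof=1))
            for col in cols:
                if pd.isna(values.at[feat, col]):
                    if mode == "draw":
                        values.at[feat, col] = rng.normal(mu, sd)
                    else:
                        values.at[feat, col] = mu
    return replace(m, values=values, design=m.design.copy())


def impute_random_tail(
    m: QuantMatrix,
    shift: float = 1.8,
    width: float = 0.3,
    per_sample: bool = True,
    seed: int | None = 0,
) -> QuantMatrix:
    """Down-shifted-normal imputation of all remaining missing cells.

    Missing cells in sample ``s`` are drawn from
    N(mean_s - shift * sd_s, (width * sd_s)^2) where the moments are over
    the observed cells of ``s`` (or of the whole matrix when
    ``per_sample`` is false).  This emulates values at the detection
    limit for left-censored LFQ data.
    """
    if m.scale != "intensity":
        raise ValueError("random-tail imputation expects an intensity-scale matrix")
    rng = np.random.default_rng(seed)
    values = m.values.copy()
    if not per_sample:
        flat = values.to_numpy().ravel()
        obs = flat[~np.isnan(flat)]
        if obs.size < 2:
            raise ValueError("fewer than 2 observed values in the matrix")
        mu, sd = float(np.mean(obs)), float(np.std(obs, ddof=1))
    for col in values.columns:
        colvals = values[col]
        miss = colvals.isna()
        if not miss.any():
            continue
        if per_sample:
            obs = colvals.dropna().to_numpy()
            if obs.size < 2:
                raise ValueError(
                    f"sample {col!r} has fewer than 2 observed values; sd undefined"
                )
            mu, sd = float(np.mean(obs)), float(np.std(obs, ddof=1))
        draws = rng.normal(mu - shift * sd, width * sd, size=int(miss.sum()))
        values.loc[miss, col] = draws
    return replace(m, values=values, design=m.design.copy())


# ---------------------------------------------------------------------------
# Ratios, batch correction, RUV
# ---------------------------------------------------------------------------

def to_ratios(m: QuantMatrix, reference_condition: str) -> QuantMatrix:
    """Convert a fully imputed intensity matrix to log2 ratios vs a reference.

    The reference mean is computed per feature within each batch (so the
    reference itself cannot re-introduce batch structure); every sample of
    that batch is then centred on it.
    """
    if m.scale != "intensity":
        raise ValueError("to_ratios expects an intensity-scale matrix")
    if m.n_missing():
        raise ValueError("to_ratios requires a fully imputed matrix")
    if reference_condition not in m.condition_order:
        raise ValueError(f"reference condition {reference_condition!r} not in design")
    values = m.values.copy()
    for batch in m.batches:
        ref_cols = m.samples_of(reference_condition, batch=batch)
        if not ref_cols:
            raise ValueError(
                f"batch {batch!r} has no samples of reference condition "
                f"{reference_condition!r}"
            )
        batch_cols = list(m.design.index[m.design["batch"] == batch])
        ref_mean = values[ref_cols].mean(axis=1)
        values[batch_cols] = values[batch_cols].sub(ref_mean, axis=0)
    return replace(m, values=values, design=m.design.copy(), scale="ratio")


def correct_batch(m: QuantMatrix, method: str = "center") -> QuantMatrix:
    """Remove additive per-(feature, batch) location shifts.

    ``center`` subtracts each feature's batch-mean deviation from its
    grand mean.  ``eb_location`` shrinks those deviations toward zero
    with an empirical-Bayes weight n_b*tau^2 / (n_b*tau^2 + sigma^2),
    where tau^2 is a method-of-moments estimate of the between-batch
    variance shared across features and sigma^2 the feature's
    within-batch residual variance.
    """
    if method not in ("center", "eb_location"):
        raise ValueError(f"unknown batch-correction method {method!r}")
    batches = m.batches
    if len(batches) < 2:
        warnings.warn("single batch: batch correction is a no-op", UserWarning)
        return m.copy()
    X = m.values.to_numpy(dtype=float)
    grand = np.nanmean(X, axis=1, keepdims=True)
    batch_cols = {b: [m.samples.get_loc(s) for s in m.design.index[m.design["batch"] == b]]
                  for b in batches}
    dev = {}
    for b, cols in batch_cols.items():
        dev[b] = np.nanmean(X[:, cols], axis=1, keepdims=True) - grand

    if method == "eb_location":
        # pooled within-batch residual variance per feature
        resid_ss = np.zeros(X.shape[0])
        resid_df = np.zeros(X.shape[0])
        for b, cols in batch_cols.items():
            sub = X[:, cols]
            bm = np.nanmean(sub, axis=1, keepdims=True)
            resid_ss += np.nansum((sub - bm) ** 2, axis=1)
            resid_df += np.sum(~np.isnan(sub), axis=1) - 1
        sigma2 = resid_ss / np.maximum(resid_df, 1)
        # method of moments for tau^2 across all (feature, batch) deviations
        n_b = {b: len(cols) for b, cols in batch_cols.items()}
        d2 = np.concatenate([dev[b].ravel() ** 2 - sigma2 / n_b[b] for b in batches])
        tau2 = max(float(np.mean(d2)), 0.0)
        out = X.copy()
        for b, cols in batch_cols.items():
            w = n_b[b] * tau2 / (n_b[b] * tau2 + np.maximum(sigma2, 1e-12))
            out[:, cols] = out[:, cols] - (w[:, None] * dev[b])
    else:
        out = X.copy()
        for b, cols in batch_cols.items():
            out[:, cols] = out[:, cols] - dev[b]

    values = pd.DataFrame(out, index=m.features, columns=m.samples)
    return replace(m, values=values, design=m.design.copy())


def select_stable_features(m: QuantMatrix, n: int) -> list[str]:
    """Pick the ``n`` features whose condition means vary least.

    These serve as negative controls for RUV: features assumed unaffected
    by the biology.  Ties break by total variance, then by feature id.
    """
    cond_means = pd.DataFrame(
        {c: m.values[m.samples_of(c)].mean(axis=1) for c in m.condition_order}
    )
    crit = pd.DataFrame(
        {
            "cond_var": cond_means.var(axis=1, ddof=1),
            "total_var": m.values.var(axis=1, ddof=1),
        },
        index=m.features,
    )
    crit["fid"] = crit.index.astype(str)
    ranked = crit.sort_values(["cond_var", "total_var", "fid"], kind="mergesort")
    return list(ranked.index[: min(n, len(ranked))])


def ruv_normalize(m: QuantMatrix, controls: Sequence[str], k: int) -> QuantMatrix:
    """Remove unwanted variation estimated from negative-control features.

    The top-``k`` sample-space singular vectors of the (feature-centred)
    control submatrix define unwanted factors W; every feature is
    regressed on W and the fitted component removed.
    """
    controls = list(controls)
    missing = [c for c in controls if c not in m.features]
    if missing:
        raise ValueError(f"control features absent from matrix: {missing[:5]}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= len(m.samples):
        raise ValueError("k must be smaller than the number of samples")
    if m.n_missing():
        raise ValueError("ruv_normalize requires a complete matrix")
    Xc = m.values.loc[controls].to_numpy(dtype=float)
    Xc = Xc - Xc.mean(axis=1, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # scale-aware tolerance: a controls submatrix that is numerically zero
    # relative to the data carries no estimable unwanted factor, so there is
    # nothing to remove (this also makes the correction idempotent)
    Y = m.values.to_numpy(dtype=float)
    data_scale = float(np.sqrt(np.mean(Y**2)))
    tol = 1e-9 * max(data_scale, 1.0)
    rank = int((S > tol).sum())
    if rank == 0:
        warnings.warn(
            "control submatrix is numerically zero; no unwanted factor removed",
            UserWarning,
        )
        return m.copy()
    if k > rank:
        raise ValueError(f"k={k} exceeds the rank ({rank}) of the control submatrix")
    W = Vt[:k].T  # samples x k, orthonormal columns
    row_mean = Y.mean(axis=1, keepdims=True)
    Yc = Y - row_mean
    corrected = Y - (Yc @ W) @ W.T
    values = pd.DataFrame(corrected, index=m.features, columns=m.samples)
    return replace(m, values=values, design=m.design.copy())


# ---------------------------------------------------------------------------
# Proteome correction of phosphosite ratios
# ---------------------------------------------------------------------------

def proteome_correct(
    phospho: QuantMatrix,
    protein: QuantMatrix,
    site_to_protein: Mapping[str, str],
    conditions: Iterable[str] | None = None,
) -> tuple[QuantMatrix, list[str]]:
    """Subtract the host protein's condition-mean ratio from each site ratio.

    Removes the component of a phosphosite's change that merely tracks
    protein abundance.  Sites whose protein is unmapped or unquantified
    pass through unchanged and are returned in the flag list.
    """
    if phospho.scale != "ratio" or protein.scale != "ratio":
        raise ValueError("proteome_correct expects ratio-scale matrices")
    target_conditions = list(conditions) if conditions is not None else list(
        phospho.condition_order
    )
    for c in target_conditions:
        if c not in protein.condition_order:
            raise ValueError(f"condition {c!r} absent from protein data")
    prot_means = pd.DataFrame(
        {c: protein.values[protein.samples_of(c)].mean(axis=1) for c in target_conditions}
    )
    values = phospho.values.copy()
    unmapped: list[str] = []
    sample_cond = phospho.design["condition"]
    for site in phospho.features:
        prot = site_to_protein.get(site)
        if prot is None or prot not in prot_means.index:
            unmapped.append(site)
            continue
        for col in phospho.samples:
            cond = sample_cond[col]
            if cond in target_conditions:
                values.at[site, col] -= prot_means.at[prot, cond]
    corrected = replace(phospho, values=values, design=phospho.design.copy())
    return corrected, unmapped
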