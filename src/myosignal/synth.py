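"""Synthetic phosphoproteome/proteome/expression data with planted ground truth.

Every downstream stage of the pipeline (filtering, imputation, kinase
activity inference, substrate prediction, clustering, differential
statistics, cross-omics concordance) is verifiable against the ground
truth these generators emit: which kinase drives which site, the true
per-condition kinase activities, the motif each kinase recognises, the
pathway/cluster membership of each protein, the planted batch shifts,
and the latent (pre-missingness) intensity matrix.

The generative model is deliberately the simplest one consistent with
log2-scale LFQ data: a substrate site's log2 intensity at condition c is

    baseline + activity_kinase[c] + batch_shift + N(0, noise_sd)

with flanking sequence windows drawn from the kinase's position-specific
scoring matrix (PSSM).  Missingness is intensity-dependent (cells below
a per-sample quantile of the latent matrix, emulating left-censoring)
plus a random completely-at-random component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import QuantMatrix

__all__ = [
    "AMINO_ACIDS",
    "PAD",
    "KinaseModel",
    "GroundTruth",
    "KinaseSubstrateAnnotation",
    "make_design",
    "make_kinase_models",
    "sample_window",
    "simulate_phospho",
    "simulate_proteome",
    "subset_known_substrates",
    "simulate_expression",
    "timecourse_design",
    "proteome_design",
    "inhibition_design",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: padding symbol for windows truncated at protein termini
PAD = "_"


@dataclass
class KinaseModel:
    """A planted kinase: its recognition motif and per-condition activity."""

    kinase_id: str
    pssm: pd.DataFrame  # window positions x 20 residues, rows sum to 1
    activity: dict[str, float]  # condition -> log2 activity vs reference
    n_true_substrates: int = 0

    def __post_init__(self) -> None:
        sums = self.pssm.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"PSSM rows of {self.kinase_id} do not sum to 1")


@dataclass
class GroundTruth:
    """Everything the generators planted, for recovery tests downstream."""

    site_to_kinase: dict[str, str | None] = field(default_factory=dict)
    substrates: dict[str, list[str]] = field(default_factory=dict)
    activities: dict[str, dict[str, float]] = field(default_factory=dict)
    pathways: dict[str, set[str]] = field(default_factory=dict)
    cluster_ids: dict[str, int] = field(default_factory=dict)
    batch_shifts: pd.DataFrame | None = None
    dynamic_flags: dict[str, bool] = field(default_factory=dict)
    latent: pd.DataFrame | None = None
    missing_mask: pd.DataFrame | None = None


@dataclass
class KinaseSubstrateAnnotation:
    """Known (annotated) substrates per kinase plus the held-out remainder."""

    known: dict[str, list[str]]
    held_out: dict[str, list[str]]

    def __post_init__(self) -> None:
        for k in self.known:
            overlap = set(self.known[k]) & set(self.held_out.get(k, []))
            if overlap:
                raise ValueError(f"kinase {k}: known and held-out sets overlap")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"kinase": k, "site": s}
            for k, sites in sorted(self.known.items())
            for s in sites
        ]
        return pd.DataFrame(rows, columns=["kinase", "site"])


# ---------------------------------------------------------------------------
# Designs
# ---------------------------------------------------------------------------

def make_design(
    conditions: Sequence[str], n_replicates: int, n_batches: int = 1
) -> pd.DataFrame:
    """Build a sample design table: conditions x replicates, replicates split
    evenly over batches."""
    rows = []
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            batch = f"b{(rep - 1) * n_batches // n_replicates + 1}"
            rows.append(
                {
                    "sample": f"{cond}_r{rep}",
                    "condition": cond,
                    "replicate": rep,
                    "batch": batch,
                }
            )
    return pd.DataFrame(rows).set_index("sample")


def timecourse_design() -> pd.DataFrame:
    """The myogenic-differentiation phospho design: 4 time points x 4 replicates,
    replicates split over 2 batches (16 samples)."""
    return make_design(["0h", "30m", "24h", "d5"], 4, n_batches=2)


def proteome_design() -> pd.DataFrame:
    """The 8-time-point proteome design, 4 replicates over 2 batches."""
    return make_design(["0h", "1h", "6h", "12h", "24h", "d2", "d3", "d5"], 4, n_batches=2)


def inhibition_design() -> pd.DataFrame:
    """Control vs MAPK1/3 inhibitor (PD) vs MAPK8/9 inhibitor (SP), 4 replicates."""
    return make_design(["ctrl", "PD", "SP"], 4, n_batches=1)


# ---------------------------------------------------------------------------
# Kinase models
# ---------------------------------------------------------------------------

def make_kinase_models(
    n_kinases: int,
    window_len: int = 15,
    motif_informativeness: float = 0.5,
    conditions: Sequence[str] = ("0h", "30m", "24h", "d5"),
    activity_sd: float = 1.5,
    activities: Sequence[Mapping[str, float]] | None = None,
    seed: int = 0,
) -> list[KinaseModel]:
    """Create ``n_kinases`` kinase models with random motifs and activities.

    ``motif_informativeness`` in [0, 1] interpolates each non-centre PSSM
    row between the uniform distribution (0) and a point mass on one
    preferred residue (1); the mean per-position KL divergence from
    uniform therefore grows monotonically with it.  The centre position
    is fixed to the phosphoacceptor (S/T at equal probability).
    Activities are log2 effects per condition with the first condition as
    reference (0), drawn N(0, activity_sd) unless given explicitly.
    """
    if n_kinases < 1:
        raise ValueError("n_kinases must be >= 1")
    if window_len % 2 == 0:
        raise ValueError("window_len must be odd")
    if not 0.0 <= motif_informativeness <= 1.0:
        raise ValueError("motif_informativeness must be in [0, 1]")
    rng = np.random.default_rng(seed)
    center = window_len // 2
    n_aa = len(AMINO_ACIDS)
    models: list[KinaseModel] = []
    for i in range(n_kinases):
        pssm = np.full((window_len, n_aa), 1.0 / n_aa)
        preferred = rng.integers(0, n_aa, size=window_len)
        for p in range(window_len):
            if p == center:
                continue
            row = np.full(n_aa, (1.0 - motif_informativeness) / n_aa)
            row[preferred[p]] += motif_informativeness
            pssm[p] = row
        # phosphoacceptor: S and T at equal probability
        pssm[center] = 0.0
        pssm[center, AMINO_ACIDS.index("S")] = 0.5
        pssm[center, AMINO_ACIDS.index("T")] = 0.5
        table = pd.DataFrame(
            pssm,
            index=range(-center, center + 1),
            columns=list(AMINO_ACIDS),
        )
        if activities is not None:
            act = dict(activities[i])
        else:
            act = {c: 0.0 for c in conditions}
            for c in conditions[1:]:
                act[c] = float(rng.normal(0.0, activity_sd))
        models.append(KinaseModel(kinase_id=f"kin_{i:02d}", pssm=table, activity=act))
    return models


def sample_window(pssm: pd.DataFrame, rng: np.random.Generator) -> str:
    """Draw one flanking window from a PSSM, position-independently."""
    residues = list(pssm.columns)
    probs = pssm.to_numpy()
    idx = [rng.choice(len(residues), p=probs[p]) for p in range(probs.shape[0])]
    return "".join(residues[i] for i in idx)


def _uniform_window(window_len: int, rng: np.random.Generator) -> str:
    center = window_len // 2
    chars = [AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), size=window_len)]
    chars[center] = "S" if rng.random() < 0.5 else "T"
    return "".join(chars)


# ---------------------------------------------------------------------------
# Phosphoproteome simulation
# ---------------------------------------------------------------------------

def simulate_phospho(
    models: Sequence[KinaseModel],
    n_sites_per_kinase: int,
    n_background: int,
    design: pd.DataFrame,
    noise_sd: float = 0.5,
    batch_sd: float = 0.3,
    mnar_quantile: float = 0.1,
    mcar_rate: float = 0.05,
    baseline_mean: float = 21.0,
    baseline_sd: float = 1.5,
    seed: int = 0,
) -> tuple[QuantMatrix, pd.DataFrame, GroundTruth]:
    """Simulate a phosphosite log2-intensity matrix with planted kinase signal.

    Returns the observed matrix (with missingness applied), a windows
    table (site, protein, position, window) and the :class:`GroundTruth`
    carrying assignments, activities, batch shifts, the latent complete
    matrix and the missingness mask.
    """
    if n_sites_per_kinase > 0 and len(models) == 0:
        raise ValueError("no kinase models supplied but n_sites_per_kinase > 0")
    for r in (mnar_quantile, mcar_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("missingness rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    design = design.copy()
    conditions = list(dict.fromkeys(design["condition"]))
    reference = conditions[0]
    samples = list(design.index)
    batches = list(dict.fromkeys(design["batch"]))

    site_ids: list[str] = []
    windows: list[dict] = []
    site_to_kinase: dict[str, str | None] = {}
    substrates: dict[str, list[str]] = {m.kinase_id: [] for m in models}
    effects: dict[str, dict[str, float]] = {}

    idx = 0
    for model in models:
        window_len = model.pssm.shape[0]
        for _ in range(n_sites_per_kinase):
            sid = f"site_{idx:05d}"
            idx += 1
            site_ids.append(sid)
            site_to_kinase[sid] = model.kinase_id
            substrates[model.kinase_id].append(sid)
            effects[sid] = dict(model.activity)
            windows.append(
                {
                    "site": sid,
                    "protein": f"prot_{sid}",
                    "position": int(rng.integers(8, 500)),
                    "window": sample_window(model.pssm, rng),
                }
            )
        model.n_true_substrates = n_sites_per_kinase
    window_len = models[0].pssm.shape[0] if models else 15
    for _ in range(n_background):
        sid = f"site_{idx:05d}"
        idx += 1
        site_ids.append(sid)
        site_to_kinase[sid] = None
        effects[sid] = {c: 0.0 for c in conditions}
        windows.append(
            {
                "site": sid,
                "protein": f"prot_{sid}",
                "position": int(rng.integers(8, 500)),
                "window": _uniform_window(window_len, rng),
            }
        )

    n_sites = len(site_ids)
    baseline = rng.normal(baseline_mean, baseline_sd, size=n_sites)
    shift = pd.DataFrame(
        rng.normal(0.0, batch_sd, size=(n_sites, len(batches))),
        index=site_ids,
        columns=batches,
    )
    latent = np.empty((n_sites, len(samples)))
    for j, s in enumerate(samples):
        cond = design.at[s, "condition"]
        batch = design.at[s, "batch"]
        eff = np.array([effects[sid].get(cond, 0.0) for sid in site_ids])
        latent[:, j] = (
            baseline
            + eff
            + shift[batch].to_numpy()
            + rng.normal(0.0, noise_sd, size=n_sites)
        )
    latent_df = pd.DataFrame(latent, index=site_ids, columns=samples)

    observed = latent_df.copy()
    if mnar_quantile > 0:
        for s in samples:
            thr = observed[s].quantile(mnar_quantile)
            observed.loc[observed[s] < thr, s] = np.nan
    if mcar_rate > 0:
        mask = rng.random(observed.shape) < mcar_rate
        observed = observed.mask(mask & observed.notna().to_numpy())

    gt = GroundTruth(
        site_to_kinase=site_to_kinase,
        substrates=substrates,
        activities={m.kinase_id: dict(m.activity) for m in models},
        batch_shifts=shift,
        latent=latent_df,
        missing_mask=observed.isna(),
    )
    qm = QuantMatrix(
        values=observed,
        design=design,
        scale="intensity",
        condition_order=tuple(conditions),
    )
    windows_df = pd.DataFrame(windows, columns=["site", "protein", "position", "window"])
    return qm, windows_df, gt


# ---------------------------------------------------------------------------
# Proteome simulation
# ---------------------------------------------------------------------------

def simulate_proteome(
    design: pd.DataFrame,
    n_proteins: int,
    coupling_to_phospho: float = 0.0,
    phospho_trends: Mapping[str, Mapping[str, float]] | None = None,
    n_clusters: int = 0,
    cluster_size: int = 25,
    cluster_amplitude: float = 2.0,
    noise_sd: float = 0.3,
    batch_sd: float = 0.3,
    mnar_quantile: float = 0.05,
    mcar_rate: float = 0.02,
    baseline_mean: float = 24.0,
    baseline_sd: float = 1.5,
    seed: int = 0,
) -> tuple[QuantMatrix, GroundTruth]:
    """Simulate a protein log2-intensity matrix.

    Dynamics come from two optional sources: *planted temporal clusters*
    (step-like up/down profiles with staggered onset times, amplitude
    ``cluster_amplitude``, one pathway term per cluster) and *coupling to
    phospho trends* (``coupling_to_phospho`` in [0, 1] scales a supplied
    per-protein condition trend, used to test proteome correction).
    Remaining proteins are flat background.
    """
    if not 0.0 <= coupling_to_phospho <= 1.0:
        raise ValueError("coupling_to_phospho must be in [0, 1]")
    rng = np.random.default_rng(seed)
    design = design.copy()
    conditions = list(dict.fromkeys(design["condition"]))
    samples = list(design.index)
    batches = list(dict.fromkeys(design["batch"]))
    n_cond = len(conditions)

    coupled_ids = list(phospho_trends) if phospho_trends else []
    prot_ids = coupled_ids + [f"prot_{i:05d}" for i in range(n_proteins - len(coupled_ids))]
    if len(prot_ids) != n_proteins:
        raise ValueError("n_proteins smaller than the number of coupled proteins")

    effects = {p: {c: 0.0 for c in conditions} for p in prot_ids}
    cluster_ids: dict[str, int] = {}
    pathways: dict[str, set[str]] = {}
    dynamic_flags = {p: False for p in prot_ids}

    for p in coupled_ids:
        for c in conditions:
            effects[p][c] = coupling_to_phospho * float(phospho_trends[p].get(c, 0.0))
        if any(abs(v) > 0 for v in effects[p].values()):
            dynamic_flags[p] = True

    free = [p for p in prot_ids if p not in coupled_ids]
    if n_clusters > 0:
        if n_clusters * cluster_size > len(free):
            raise ValueError("not enough proteins for the requested clusters")
        # staggered onset: cluster j switches at interior time index 1+j
        for j in range(n_clusters):
            members = free[j * cluster_size : (j + 1) * cluster_size]
            onset = 1 + j % max(n_cond - 1, 1)
            sign = 1.0 if j % 2 == 0 else -1.0
            term = f"term_cluster_{j}"
            pathways[term] = set(members)
            for p in members:
                cluster_ids[p] = j
                dynamic_flags[p] = True
                for ci, c in enumerate(conditions):
                    effects[p][c] = sign * cluster_amplitude if ci >= onset else 0.0
        # a couple of uninformative terms over random background proteins
        bg = free[n_clusters * cluster_size :]
        if len(bg) >= 10:
            for t in range(2):
                pick = rng.choice(bg, size=min(10, len(bg)), replace=False)
                pathways[f"term_noise_{t}"] = set(pick)

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_proteins)
    shift = pd.DataFrame(
        rng.normal(0.0, batch_sd, size=(n_proteins, len(batches))),
        index=prot_ids,
        columns=batches,
    )
    latent = np.empty((n_proteins, len(samples)))
    for j, s in enumerate(samples):
        cond = design.at[s, "condition"]
        batch = design.at[s, "batch"]
        eff = np.array([effects[p][cond] for p in prot_ids])
        latent[:, j] = (
            baseline
            + eff
            + shift[batch].to_numpy()
            + rng.normal(0.0, noise_sd, size=n_proteins)
        )
    latent_df = pd.DataFrame(latent, index=prot_ids, columns=samples)
    observed = latent_df.copy()
    if mnar_quantile > 0:
        for s in samples:
            thr = observed[s].quantile(mnar_quantile)
            observed.loc[observed[s] < thr, s] = np.nan
    if mcar_rate > 0:
        mask = rng.random(observed.shape) < mcar_rate
        observed = observed.mask(mask & observed.notna().to_numpy())

    gt = GroundTruth(
        activities={p: effects[p] for p in prot_ids},
        pathways=pathways,
        cluster_ids=cluster_ids,
        batch_shifts=shift,
        dynamic_flags=dynamic_flags,
        latent=latent_df,
        missing_mask=observed.isna(),
    )
    qm = QuantMatrix(
        values=observed,
        design=design,
        scale="intensity",
        condition_order=tuple(conditions),
    )
    return qm, gt


# ---------------------------------------------------------------------------
# Annotation subsetting
# ---------------------------------------------------------------------------

def subset_known_substrates(
    gt: GroundTruth,
    known_fraction: float = 0.5,
    min_known: int = 3,
    seed: int = 0,
) -> KinaseSubstrateAnnotation:
    """Flag a fraction of each kinase's true substrates as 'known' annotation.

    The remainder is withheld as held-out positives for recovery tests,
    emulating an incomplete kinase-substrate database.
    """
    if not 0.0 < known_fraction <= 1.0:
        raise ValueError("known_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    known: dict[str, list[str]] = {}
    held_out: dict[str, list[str]] = {}
    for kinase, subs in sorted(gt.substrates.items()):
        n_true = len(subs)
        if n_true < min_known:
            raise ValueError(
                f"kinase {kinase} has only {n_true} true substrates "
                f"(min_known={min_known})"
            )
        n_known = max(min_known, int(np.floor(known_fraction * n_true)))
        n_known = min(n_known, n_true)
        order = rng.permutation(n_true)
        known[kinase] = sorted(subs[i] for i in order[:n_known])
        held_out[kinase] = sorted(subs[i] for i in order[n_known:])
    return KinaseSubstrateAnnotation(known=known, held_out=held_out)


# ---------------------------------------------------------------------------
# Single-cell expression simulation
# ---------------------------------------------------------------------------

def simulate_expression(
    n_cells: int,
    n_genes: int = 200,
    markers: Sequence[str] = ("Myf5", "Myod1", "Myog"),
    frac_target: float = 0.5,
    mean_count: float = 3.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a cells x genes count matrix with marker-gated cell types.

    'Target' cells express at least one of the progenitor markers
    (Myf5/Myod1) and none of the differentiation marker (Myog);
    non-target cells do the opposite.  Returns the count matrix and the
    generator's cell labels for gate-recall checks.
    """
    if len(markers) != 3:
        raise ValueError("expected exactly three markers: two positive, one negative")
    rng = np.random.default_rng(seed)
    pos1, pos2, neg = markers
    other = [f"gene_{i:04d}" for i in range(n_genes - 3)]
    genes = [pos1, pos2, neg] + other
    cells = [f"cell_{i:04d}" for i in range(n_cells)]
    counts = rng.poisson(mean_count, size=(n_cells, n_genes)).astype(float)
    gi = {g: j for j, g in enumerate(genes)}
    labels = []
    for i in range(n_cells):
        is_target = rng.random() < frac_target
        labels.append("target" if is_target else "other")
        if is_target:
            # at least one positive marker on, negative marker off
            counts[i, gi[neg]] = 0.0
            if rng.random() < 0.5:
                counts[i, gi[pos1]] = rng.poisson(mean_count) + 1.0
                counts[i, gi[pos2]] = rng.poisson(mean_count) * (rng.random() < 0.5)
            else:
                counts[i, gi[pos2]] = rng.poisson(mean_count) + 1.0
                counts[i, gi[pos1]] = rng.poisson(mean_count) * (rng.random() < 0.5)
        else:
            counts[i, gi[neg]] = rng.poisson(mean_count) + 1.0
    expr = pd.DataFrame(counts, index=cells, columns=genes)
    return expr, pd.Series(labels, index=cells, name="label")
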