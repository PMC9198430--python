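# Methods

## Scope and data model

`myosignal` analyses features × samples matrices of log2-scale label-free
quantification (LFQ) intensities — phosphosites or proteins — with a
per-sample design (condition/time point, replicate, batch) and explicit
missing cells. All inference happens on log2 ratios against a reference
condition (time 0 or vehicle control) and, downstream, on per-contrast
z-standardized scores.

## Synthetic data generator

The generator is the package's verification backbone: it plants a known
signal and emits it alongside the data so every stage can be scored
against truth.

**Generative model.** A substrate site of kinase k has log2 intensity

    y_{i,s} = b_i + a_k(c_s) + δ_{i,batch(s)} + ε_{i,s}

with baseline b_i ~ N(21, 1.5²) (typical log2 LFQ magnitude), planted
activity a_k(c) per condition (reference fixed at 0, others N(0, 1.5²)
unless supplied), additive batch shifts δ ~ N(0, batch_sd²) per
(feature, batch), and noise ε ~ N(0, noise_sd²). Background sites have
a ≡ 0. Flanking ±7-residue windows of substrates are drawn
position-independently from the kinase's PSSM (centre fixed to S/T at
0.5/0.5); background windows are uniform over the 20 residues. Motif
sharpness is controlled by `motif_informativeness` m ∈ [0, 1]: each
non-centre PSSM row is (1−m)/20 + m·1{preferred residue}, so the mean
per-position KL divergence from uniform grows monotonically with m.

**Missingness.** Left-censoring is emulated by deleting, per sample, all
cells below the `mnar_quantile` of the latent (complete) column, then
deleting an `mcar_rate` fraction of the remainder at random. The latent
matrix and the missingness mask are kept in the ground truth so tests
can verify the mechanism (observed values stochastically dominate the
missing ones).

**Default study conditions.** The phospho time course is 4 time points
(0h, 30m, 24h, d5) × 4 replicates with replicates split over 2 batches
(16 samples); the proteome uses 8 time points (0h, 1h, 6h, 12h, 24h,
d2, d3, d5); the inhibition design is control/PD/SP × 4 replicates.
Defaults: 10 kinases × 20 substrates + 300 background sites,
noise_sd = 0.5 (a typical log2 replicate sd for LFQ), batch_sd = 0.3,
mnar_quantile = 0.1, mcar_rate = 0.05. Activity-recovery benchmarks are
run at noise_sd = 1 — a deliberately pessimistic replicate noise.

**What the generator does not emulate.** Peptide-to-site rollup,
correlated (pathway-structured) background, non-additive batch effects,
intensity-dependent noise, realistic protein sequence composition, and
annotation errors. Recovery results on this generator therefore bound
what the methods can do when their model assumptions hold; they do not
certify performance on real spectra-derived data.

## Preprocessing chain

1. **Presence filtering.** A feature is retained iff its total quantified
   count reaches `min_total_quantified` and at least `min_conditions`
   conditions (consecutive in declared time order when
   `adjacency_required`) each hold ≥ `min_reps_within_condition`
   quantified replicates. The four canonical rule sets (phospho
   time course 4-of-16 + 3-of-4; phospho inhibition 3-of-12 + 3-of-4;
   proteome 2-of-4 in ≥2 adjacent time points; inhibition proteome
   4-of-15 + 3-of-4) ship as `FilterRule` classmethods. "More than two
   quantified" is read strictly as ≥3.
2. **Condition-specific imputation.** Where a (feature, condition) group
   has ≥3 observed replicates, missing cells are drawn from
   N(μ̂, σ̂²) of the observed ones (seeded; a deterministic mean mode is
   available). This preserves within-condition variance rather than
   collapsing it.
3. **Random-tail imputation.** Remaining missing cells in sample s are
   drawn from N(μ_s − shift·σ_s, (width·σ_s)²) with the standard
   down-shifted-normal defaults shift = 1.8, width = 0.3, per sample —
   emulating values at the detection limit.
4. **Ratios.** Each value minus the feature's reference-condition mean,
   computed within batch so the reference cannot re-introduce batch
   structure; reference columns average to zero by construction.
5. **Batch correction.** Location-only: `center` removes each feature's
   per-batch mean deviation; `eb_location` shrinks the deviations with
   weight n_b·τ²/(n_b·τ² + σ²) where τ² is a method-of-moments
   between-batch variance shared across features. A scale adjustment is
   deliberately out of scope — the simulated (and typical log2 LFQ)
   batch effects are additive.
6. **RUV.** Negative controls are the n features with the smallest
   variance of condition means (ties: total variance, then id). The
   top-k sample-space singular vectors of the centred controls submatrix
   define unwanted factors W; every feature's projection onto W is
   removed. A numerically zero controls submatrix (relative tolerance
   1e-9 of the data scale) means no estimable factor: the matrix is
   returned unchanged with a warning, which also makes the correction
   idempotent; k exceeding the numerical rank is an error.
7. **Proteome correction.** Site ratio minus the host protein's
   condition-mean ratio (condition-matched; replicate-matched protein
   values are deliberately not used, as proteome and phospho replicates
   are not paired). Unmapped sites pass through and are flagged.

## Kinase activity and direction analysis

Per contrast, replicate ratios collapse to condition means and each
column is centred and scaled by its sample sd (ddof = 1; the convention
chosen so a column of means {−1, 0, 1} standardizes to itself). The
substrate-set statistic is Stouffer's Z = Σz_i/√n with two-sided normal
p; it is exact under the null when the z columns are standard normal and
satisfies the union identity Z_∪ = (√n₁Z₁ + √n₂Z₂)/√(n₁+n₂) for
disjoint sets. Annotated substrates absent from the matrix are skipped
(and not counted in n); kinases below `min_substrates = 3` are excluded.

For two inhibitor contrasts, scores are projected onto unit directions
(dot product); under independent standard-normal columns the projection
is again standard normal, so the same set test applies. The canonical
set is 8 directions at 45° steps; treated/control ratios make
"inhibited" negative, so "inhibited by PD only" = (−1, 0) and "by both"
= (−1/√2, −1/√2). BH runs across kinases within each direction. Signed
Z is reported as the activity; p-values are two-sided.

## Substrate scoring, signalome, specificity dissection

PSSMs are learned from a kinase's known-substrate windows with
pseudocount α = 0.01: p(pos, aa) = (count + α)/(n_pos + 20α), padding
symbols excluded position-wise (kinases with fewer than `min_known = 5`
windows are skipped). The motif score min-max normalises the mean
log-probability of a window by the best/worst achievable under the PSSM,
yielding [0, 1]; a fully degenerate PSSM scores 0.5 by convention. The
profile score is (r + 1)/2 against the centroid of known substrates'
standardized profiles; zero-variance profiles are recorded as missing.
The combined score is the weighted geometric mean S_m^w·S_p^(1−w) with
w = 0.5 — the simplest combination that is zero when either evidence
stream is contradicted and lies between the components for w ∈ (0, 1).
Recovery benchmarks exclude each kinase's training (known) substrates
from its evaluation set; negatives are pure background sites.

Sites are assigned to their argmax-scoring kinase when that score
reaches 0.5 (ties: lexicographic). A signalome edge between two kinases
counts the distinct proteins carrying at least one assigned site scoring
≥ threshold for both kinases — shared predicted substrates as a proxy
for co-regulation.

Specificity dissection takes candidates with combined score > 0.7 for
either kinase group (group score = max over members, treating e.g.
MAPK1 and MAPK3 as one inhibitable unit) and classifies them by
inhibition profile: z_PD < z_SP ⇒ first group's substrate, the reverse
⇒ second group's; exact ties stay unassigned. The 0.7 threshold applies
to the combined score.

## Temporal clustering and event ordering

Fold-change profiles of dynamic proteins are z-scored across time
points (flat profiles dropped). For each k in the sweep, k-means runs
with `n_starts` seeded restarts; the clustering score is
E(k) = Σ_clusters Σ_terms −log10 p over terms with BH q ≤ 0.05 within
the cluster (one-sided Fisher/hypergeometric p against the clustered
universe; Haldane 0.5 correction for odds ratios with zero cells).
k* maximises E(k), ties toward smaller k; when nothing is enriched at
any k the result is flagged rather than trusted. Event detection is
deliberately simple: direction is up when the cluster mean's maximum
follows its minimum; the event time is the first half-amplitude
crossing, linearly interpolated between adjacent time points. On
monotone step-like profiles this reproduces the ordering of model-based
event detectors with far fewer knobs; on non-monotone profiles only the
first transition is reported.

## Differential statistics

`eb_moderate` implements the method of moments on log sample variances:
with s² ~ s₀²·F(d, d₀), e = log s² − ψ(d/2) + log(d/2) has mean
log s₀² − ψ(d₀/2) + log(d₀/2) (sign convention folded in) and variance
ψ′(d/2) + ψ′(d₀/2); matching empirical moments and inverting the
trigamma by Newton iteration gives (s₀², d₀). When the empirical
variance of e is at or below the ψ′(d/2) floor, d₀ = ∞ and
s₀² = exp(mean(e)) (bias-corrected); literally identical variances are
treated as noiseless and return the common value exactly. The moderated
statistic is t = log2FC/√(s²_post(1/n₁+1/n₂)) with
s²_post = (d₀s₀² + d·s²)/(d₀+d) on d + d₀ df (normal reference at
d₀ = ∞); d₀ = 0 reproduces the classical pooled t exactly. The
implementation agrees with R limma's `lmFit`/`eBayes` to machine
precision on a shared fixture (tested). DE calls use |log2FC| ≥ 1
(inclusive) and q < 0.05 (strict); dynamic-regulation calls use
|log2FC| > 1 (strict) at ≥2 time points and ANOVA q ≤ 0.05, each
threshold following its source wording, all configurable. The two-stage
contrast (two overexpression arms vs a shared reference, then moderated
t between the normalised ratio arms) is antisymmetric under arm swap by
construction.

## Concordance and morphology

Cells pass the marker gate when any positive marker exceeds the
threshold (default: > 0 counts) and every negative marker does not —
"(Myf5+ or Myod1+) and Myog−" under the default markers, implemented
exactly as parenthesised even though it reads like a progenitor gate;
the rule is configurable. Genes with > 95% zeros are dropped (boundary
kept); HVGs rank by variance of log1p expression (scale-robust; a CV
criterion would weight low-expression genes more). Pearson correlations
are computed per (cell, time point) over shared gene symbols with
pairwise deletion. Morphology indices are pure count arithmetic:
differentiation index = nuclei in MHC+ cells / total nuclei, %MHC+ =
MHC+ cells / total nuclei, fusion index = nuclei in multinucleated (≥4)
myotubes / total nuclei; tubes with ≤3 nuclei contribute nothing to the
fusion numerator by the definition of the input count.

## Numerical and design choices

- Ties break lexicographically by feature/kinase id everywhere, for
  determinism; all randomness flows through explicit integer seeds.
- Sample sd (ddof = 1) is used for standardization and imputation
  moments.
- Problem sizes in the shipped benchmarks (500 phospho sites, 500
  proteins, 1000-replicate null calibrations, 5000-feature prior
  recovery) are chosen so the full suite verifies every stage on one
  CPU in well under a minute per scenario while keeping Monte-Carlo
  error comfortably inside the asserted bands.
- Null calibrations use a 1000-feature universe: column standardization
  couples features at −1/(n−1), so sets that are a large fraction of a
  small universe are intrinsically conservative; large universes mirror
  real phosphoproteomes.
- The window-shuffle control averages 5 independent permutations so the
  chance-level estimate is not dominated by one draw.

## Known limitations

- Kinase activity assumes substrate z-scores are exchangeable and
  approximately normal; correlated substrates (shared peptides, shared
  pathways) inflate |Z|.
- The PSSM is position-independent; real kinase motifs have positional
  dependencies the model cannot express.
- Event ordering reports a single transition per cluster; oscillatory
  profiles are summarised by their first half-amplitude crossing only.
- Batch correction is location-only; multiplicative batch effects
  require a scale step that is out of scope.
- Gene matching in the concordance module is by exact symbol; no
  ortholog mapping is attempted.
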