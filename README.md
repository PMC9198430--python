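# myosignal

Kinase-signaling analysis for time-resolved and inhibitor-perturbed
phosphoproteome/proteome experiments, built around the C2C12 myogenic
differentiation design (myoblasts → myotubes over five days): infer
which kinases are active when, predict which phosphosites they act on,
attribute substrates to closely related kinases using paired inhibitor
profiles, and order the downstream pathway events in time.

The package ships a synthetic-data generator with fully planted ground
truth (kinase activities, recognition motifs, substrate assignments,
pathway memberships, batch effects, left-censored missingness), so every
stage of the pipeline is verifiable end to end without any external
download.

## What it computes

**Preprocessing** (`myosignal.preprocess`). Log2 LFQ intensity matrices
are presence-filtered (e.g. ≥4 quantified of 16 samples and ≥3 of 4
replicates in some time point), imputed in two stages — per-condition
draws from N(μ̂_c, σ̂_c) where ≥3 replicates are observed, then a
down-shifted normal N(μ_s − 1.8·σ_s, (0.3·σ_s)²) per sample for the
left-censored remainder — converted to log2 ratios against the reference
time point, batch-corrected, and cleaned by RUV against stable
(negative-control) features.

**Kinase activity** (`myosignal.kinact`). For kinase k with known
substrate set S_k and per-contrast standardized scores z_i, the activity
is the Stouffer statistic

    Z_k = Σ_{i∈S_k} z_i / √|S_k|

with a two-sided normal p and BH adjustment across kinases. For paired
inhibitor contrasts (PD = MAPK1/3 inhibitor, SP = MAPK8/9 inhibitor) the
same test runs along unit directions in the (z_PD, z_SP) plane — eight
directions at 45° steps, with "inhibited by PD only" = (−1, 0) — which
attributes inhibition to one treatment, the other, or both.

**Kinase-substrate prediction** (`myosignal.ksub`). Each site × kinase
pair gets a motif score (PSSM log-likelihood of the ±7 flanking window,
min-max normalised to [0, 1]), a profile score ((r + 1)/2 for the
Pearson correlation with the known substrates' centroid profile), and a
combined score S_m^w · S_p^(1−w). High-scoring candidates (S > 0.7) of
two kinase groups are dissected by inhibitor response: more inhibited
under PD ⇒ MAPK1/3-specific, under SP ⇒ MAPK8/9-specific. The signalome
network links kinases by the number of predicted substrate proteins
they share.

**Temporal clustering** (`myosignal.cluster`). Dynamically regulated
proteins (|log2FC| > 1 at ≥2 time points and ANOVA FDR ≤ 0.05) are
z-transformed and k-means-clustered over a sweep of k; each k is scored
by pathway enrichment (sum of −log10 Fisher p over BH-significant terms
per cluster) and the maximising k wins. Cluster mean profiles become
ordered up/down events timed at their half-amplitude crossing.

**Statistics** (`myosignal.stats`). Moderated t-test with
empirical-Bayes variance shrinkage — s²_post = (d₀s₀² + d·s²)/(d₀ + d)
with (s₀², d₀) estimated by method of moments on log s² — matching the
limma implementation to machine precision; one-way ANOVA; BH adjustment.

**Concordance** (`myosignal.concord`). Marker-gated single-cell
transcriptomes (Myf5+ or Myod1+, Myog−) correlated with proteome time
points over top highly variable genes, plus differentiation/fusion
index arithmetic from image-derived nuclei counts.

## Worked example

```python
from myosignal import pipeline

tc = pipeline.run_timecourse(seed=0)   # simulate -> preprocess -> infer
act = tc.activity
print(act[act["contrast"] == "30m-vs-0h"]
      .sort_values("Z", key=abs, ascending=False).head(3).to_string(index=False))
```

prints

```
kinase  contrast  n         Z            p            q
kin_07 30m-vs-0h 20 13.790518 2.906635e-43 2.906635e-42
kin_03 30m-vs-0h 19  7.887360 3.086452e-15 1.543226e-14
kin_00 30m-vs-0h 18 -6.128569 8.867287e-10 2.955762e-09
```

i.e. 30 minutes after differentiation induction, kinase `kin_07` is the
most strongly activated (Z = 13.8 over its 20 quantified substrates) and
`kin_00` is deactivated (Z = −6.1) — and indeed the generator planted a
negative 30m activity (−1.06) for `kin_00`. Across all ten simulated
kinases the inferred Z ranks the planted activities at Spearman ρ =
0.94–0.99 per contrast, and held-out substrates of each kinase are
recovered from background at AUROC 1.00 (`tc.report`).

The same flow is available from the shell:

```bash
myosignal run --out results/demo --seed 0          # full scenario + report.json
myosignal simulate --scenario timecourse --out data --seed 1
myosignal preprocess --phospho data/phospho.tsv --design data/design.tsv --out pre
myosignal kinact --ratios pre/ratios.tsv --design pre/design.tsv \
    --annotation data/annotation.tsv --out activity.tsv
```

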