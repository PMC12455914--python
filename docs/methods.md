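# Methods

This note documents the models and procedures implemented in `commstate`,
the defaults chosen where the methodology is genuinely open, and what the
synthetic cohorts do and do not establish about real data.

## Data model

The pipeline's unit of analysis is a sample × taxon integer count matrix
joined to per-sample metadata (subject, anatomical site ∈ {oral,
nasopharyngeal}, season ∈ autumn < winter < spring, age, sex, grade) and an
ASV → {phylum, order, family, genus} taxonomy. One sample per (subject,
site, season) is enforced as an invariant. Analyses run on **genus-level
relative abundance** by default: every stated result of this kind of study
is genus-indexed, and genus aggregation stabilizes profiles against ASV
splitting. ASV-level analysis is a config switch (`analysis_unit: asv`).
Taxa without a genus assignment are pooled into an `Unassigned` column that
participates in totals and distances but is excluded from enrichment and
association reporting. No abundance filtering is applied by default;
optional minimum-count / minimum-prevalence filters are logged when used.

## Alpha diversity

Per sample: bias-corrected Chao1 `S_obs + F1(F1-1) / (2(F2+1))` (F1, F2 =
singleton and doubleton counts; equals observed richness when F1 ≤ 1),
Shannon entropy in **natural log** (the convention of the R ecosystem
tooling this field uses), and Gini–Simpson `1 − Σ p²`. Counts are used as
sequenced; rarefaction to even depth is available (`rarefaction_depth`,
seeded multivariate-hypergeometric subsampling) but off by default — at
these library sizes (~3 × 10⁴) the indices are depth-stable, and discarding
reads costs precision.

Group contrasts: Wilcoxon rank-sum for two groups — exact enumeration of
the U distribution when n₁+n₂ ≤ 12 with no ties, otherwise the
tie-corrected normal approximation with continuity correction (the method
used is recorded in each result) — Kruskal–Wallis across seasons, and
ANOVA effect sizes for age × season. For the two-factor model both
classical η² (SS_term / SS_total, type-II decomposition) and partial η²
(SS_term / (SS_term + SS_resid)) are reported and labeled, since the two
flavors diverge exactly when effects are non-negligible. All p-values are
Benjamini–Hochberg adjusted within one family per diversity index.

## Beta diversity

Bray–Curtis `Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ)` on relative abundances (bounded [0, 1]).
PCoA is classical metric scaling: eigendecomposition of the double-centered
−½D² matrix; coordinates are eigenvectors scaled by √λ for positive
eigenvalues. Negative eigenvalues (Bray–Curtis is non-Euclidean) are
reported in the spectrum and their axes dropped; no correction is applied
by default because the leading axes are what downstream steps consume, and
additive corrections distort them. Cailliez correction is available as
`correction="cailliez"`.

PERMANOVA is the one-way distance-based decomposition: SS_total =
Σ_{i<j} d²ᵢⱼ / n, SS_within summed per group with its own divisor, pseudo-F
= (SS_b/(k−1)) / (SS_w/(n−k)). p = (1 + #{F_perm ≥ F_obs}) / (1 + B) under
seeded label shuffling with B = 999 by default; an `exhaustive` mode
enumerates every distinct labeling and reports the exact proportion (used
for small-n verification). Only single factors are handled — the study
design calls for site and season one at a time — so multi-factor
partitioning is deliberately out of scope.

### Tight-cluster extraction

The dense "core" of an ordination is identified by a deterministic
kNN-density rule: score each sample by its mean distance to its k = 5
nearest neighbors in the first two axes, keep samples at or below the 0.6
quantile of that score, link kept samples closer than the 0.25 quantile of
their pairwise distances, and return the largest connected component
(ties broken by smallest sample id). Both quantiles use the `higher`
interpolation so the limits quantile → 1 degenerate to keeping everything.
All three parameters are config-exposed and logged with every run; the
procedure is a reconstruction — density-based core extraction is not a
standardized step — so its output should be read qualitatively.

## Community state typing

Ward minimum-variance linkage is computed per (site, season) stratum with
the Lance–Williams recurrence on squared distances; reported heights are
√(Ward criterion) ("ward.D2" convention), so identical samples merge at
height 0 and heights are non-decreasing. Ties are broken deterministically
toward the lowest-numbered cluster pair. The default geometry is
**Euclidean on genus relative abundance** — Ward's objective is defined for
squared-Euclidean geometry — with correlation distance as an option for
users who want shape-based rather than mass-based grouping.

The cluster count k maximizes the mean silhouette over k ∈ [2, 8]
(configurable); the full silhouette trace is retained so the choice is
auditable, and a manual `k_override` (including k = 1, silhouette recorded
as undefined) covers the inspect-the-dendrogram workflow. Clusters are
named C1, C2, … by decreasing size within each stratum; community state
identity **across** seasons is established by matching the dominant
enriched genus (same top genus → same `<genus>-type` family label), and
every assignment is logged.

Cluster stability is scored by a plain column bootstrap: taxa are resampled
with replacement, the stratum is re-clustered, and each internal node gets
the fraction of replicates reproducing its exact leaf set (bootstrap
proportion, BP). Multiscale-bootstrap AU values are intentionally not
implemented: BP answers the same "is this split an artifact of which taxa
we observed" question with far less algorithmic surface.

Per-cluster dominant genera: Welch two-sample t of each genus inside vs
outside the cluster, BH-adjusted across the full (cluster × genus) family
of the stratum; `enriched` requires q < 0.05 **and** inside mean > outside
mean. Size-one clusters and zero-variance genera are flagged untestable
rather than silently dropped.

## Transition analysis

Subjects sampled at both seasons of an adjacent pair contribute one count
to the cluster → cluster transition matrix; unpaired subjects are counted
in an attrition summary, never silently discarded. Reported transition
counts are therefore bounded by the number of paired subjects. For each
ordered pair (i, j) the 2×2 table [[n(i→j), n(i→¬j)], [n(¬i→j), n(¬i→¬j)]]
is tested with a two-sided Fisher exact test (summing hypergeometric
outcomes no more probable than the observed one — verified against exact
rational enumeration for every table with N ≤ 30). The odds ratio is the
sample estimator ad/bc with Haldane–Anscombe +0.5 applied only when a cell
is zero; the conditional-MLE estimator is available as a config option.
This subject-level 2×2 construction is the only contingency consistent
with asking "is this particular movement enriched given where everyone
started and ended". BH runs within one (site, season-pair) family by
default; pooling across sites is a flag.

The transition network is a directed graph (node size = stratum membership,
edge weight = transition count, significance flag per edge) with
deterministic node/edge ordering, exported as GEXF and GraphML.

### Taxon association network

Genus co-occurrence is measured on CLR-transformed abundances (zeros
replaced by half the smallest nonzero fraction in the table, rows
re-closed) with Spearman rank correlation per genus pair; edges are kept at
BH q < 0.05 and |ρ| ≥ 0.3, and the hub is the maximum-degree genus (ties by
summed |ρ|). CLR removes the unit-sum artifact that forces spurious
negative correlations between raw proportions. The measure, transform and
thresholds are a labeled reconstruction (the output header says so): this
style of analysis has no single canonical recipe, and fewer than 10 samples
are refused outright because rank correlations are unstable there.

## Pipeline determinism

`run_all` executes the stages in method order under one validated config; a
serialized config copy and a run log land beside the outputs, and every
random draw derives from the single config seed, so identical config + seed
reruns are byte-identical. Stages always recompute rather than caching on
upstream hashes: a full run takes seconds at these problem sizes, and
unconditional recomputation removes a whole class of stale-cache
invalidation bugs while keeping the byte-identical-rerun guarantee trivial
to reason about.

## Synthetic cohorts

`simulate_cohort` draws, per subject and site, a latent community-state
trajectory: an initial archetype from a mixture, then Markov steps through
per-season-pair row-stochastic matrices. Each contributed sample draws
genus proportions from the archetype's Dirichlet and counts from a
multinomial at a lognormal library size (log-mean ln 30 000, log-sd 0.5) —
the standard overdispersed model for 16S counts. Genus counts are split
over 2 ASVs per genus at fixed 0.7/0.3 weights so rank aggregation is
exercised. Participation per (subject, site, season) is Bernoulli, giving
study-like sparsity.

The packaged `study_like_spec()` encodes the emulated study conditions:
119 subjects, two sites, three seasons; a 16-genus panel led by
Streptococcus, Moraxella, Proteus, Neisseria and Haemophilus; five
archetypes per site, each the shared background concentration vector
(total ≈ 28) with the dominant genus boosted to concentration 34 (dominant
mean share ≈ 0.55, total ≈ 60 — tight, well-separated states); an autumn
mixture carrying a Proteus-dominant state at 27% that drains toward the
Streptococcus/Neisseria states (its spring column is exactly zero, so
Proteus vanishes by spring); a rising Streptococcus occupancy over the
year; a ×2.5 initial-mixture tilt toward the Moraxella state for subjects
aged ≤ 7; and per-site, per-season participation probabilities
(oral 0.29/0.50/0.59, nasopharyngeal 0.34/0.46/0.70) that reproduce ~341
samples with ~10% of subjects present at all three seasons per site.
Subject ages follow the enrolled-population distribution (4–13 years,
mode 10), sexes the 57:62 female:male split, and grade = age − 4 ± 1;
classroom structure is not modeled because no analyzed statistic uses it.

Two auxiliary specs support calibration: `planted_transition_spec()` (two
seasons, one site, full participation, three states, one transition-matrix
row tilted 0.8 toward a single destination — one planted positive pair) and
`null_transition_spec()` (all rows equal the initial mixture, so origin and
destination are independent and every ordered pair is a true null).

**What the generator does not emulate.** Real cohorts have per-subject
overdispersion heterogeneity, contamination and batch structure, hundreds
of rare genera, site effects far stronger than the modest
archetype-occupancy differences planted here, and participation that
correlates with age and season. Passing the recovery tests therefore shows
the *machinery* is correct — clusters recoverable when states are separated,
planted transition enrichments detected at the stated n, null rates
calibrated — not that any particular real dataset will yield clean states.

## Verification problem sizes

The test suite and `scripts/acceptance.py` use: exhaustive Fisher
verification over all 46 375 tables with N ≤ 30; complete-enumeration
PERMANOVA at n ≤ 8; brute-force Ward-criterion search at n ≤ 7; community
state recovery over 20 study-like seeds (~340 samples each; median
adjusted Rand index against planted archetypes, pass at ≥ 0.9); planted
transition power over 50 seeds at 119 paired subjects (pass at ≥ 90%
detection, BH q < 0.05); null transition flag rate over 50 seeds (expected
≈ 5%, band 2–8%, Fisher's discreteness makes it run conservative); and
1 000 null replicates each for Wilcoxon (n = 18 + 18) and Welch-t
enrichment type-I calibration (band 5% ± 2%). These sizes make the checks
statistically meaningful while keeping the full suite under a minute.

## Known limitations

- One-way PERMANOVA only; no dispersion test accompanies it, so a
  significant factor can reflect spread as well as location differences.
- Bootstrap support is plain BP; deep, poorly separated splits will show
  lower support than multiscale-corrected methods would report.
- Tight-cluster extraction and the association network are reconstructions
  with exposed parameters, not standardized procedures; treat their exact
  memberships/edges as parameter-dependent.
- Cross-season state identity via dominant-genus matching conflates states
  that share a dominant genus but differ in their minor flora.
- The silhouette criterion prefers compact, well-separated states; gradual
  community drift (no discrete states) will still be forced into clusters —
  inspect the silhouette trace before interpreting transitions.
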