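# commstate

Community state typing and seasonal transition analysis for longitudinal
upper-respiratory microbiome cohorts.

`commstate` is built for study designs in which the same subjects are
swabbed at two anatomical sites (oral and nasopharyngeal) across several
seasons, 16S amplicon reads are denoised to an ASV count table, and the
questions are: how diverse is each community, do site and season structure
the communities, which recurring *community state types* exist at each time
point, and how do subjects move between those states over the school year?

Starting from three plain TSV tables — a sample × ASV count matrix, an ASV
taxonomy table, and per-sample subject/site/season/age/sex/grade metadata —
the package computes:

- **Alpha diversity** per sample: bias-corrected Chao1 richness
  (S_obs + F₁(F₁−1)/(2(F₂+1))), Shannon entropy H = −Σ pᵢ ln pᵢ (nats), and
  the Gini–Simpson index 1 − Σ pᵢ², with Wilcoxon rank-sum / Kruskal–Wallis
  contrasts across metadata strata, ANOVA η² effect sizes, and
  Benjamini–Hochberg adjustment.
- **Beta diversity**: Bray–Curtis dissimilarity
  BC(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ), classical PCoA, one-way PERMANOVA
  (pseudo-F with seeded permutation p-values), and extraction of the
  "tight" high-density sample set in ordination space.
- **Community state typing**: per (site, season) Ward minimum-variance
  clustering of genus-level relative abundances, cluster count chosen by
  mean silhouette (with a manual override), plain bootstrap support per
  dendrogram node, and Welch-t enrichment of dominant genera per cluster.
- **Transition analysis**: subject-level cluster-to-cluster transition
  matrices between adjacent seasons; each ordered pair (i → j) tested with
  a two-sided Fisher exact test on
  [[n(i→j), n(i→¬j)], [n(¬i→j), n(¬i→¬j)]], with Haldane–Anscombe odds
  ratios and BH adjustment per season pair; directed transition networks
  and CLR + Spearman genus association networks exported as GEXF/GraphML
  for Gephi.
- **Synthetic cohorts**: a Dirichlet-multinomial generator with latent
  Markov archetype trajectories, study-like participation sparsity, and
  full ground truth, so every stage above is verifiable end to end.

## Worked example

```python
import commstate as cs

spec = cs.reseed(cs.study_like_spec(), 1)      # 119-subject synthetic cohort
table, taxonomy, metadata, truth = cs.simulate_cohort(spec)

counts = cs.aggregate_by_rank(table, taxonomy, "genus")
rel = cs.to_relative(counts)
alpha = cs.alpha_diversity(counts)

meta = metadata.table
oral = alpha.loc[meta[meta.site == "oral"].index, "shannon"]
naso = alpha.loc[meta[meta.site == "nasopharyngeal"].index, "shannon"]
res = cs.wilcoxon_rank_sum(oral, naso)

dm = cs.bray_curtis(rel)
perm = cs.permanova(dm, meta.loc[rel.sample_ids, "season"],
                    n_permutations=999, seed=1, factor="season")

ids = sorted(metadata.stratum("nasopharyngeal", "winter"))
sub = rel.subset(ids)
sol = cs.select_k(cs.ward_cluster(sub), sub, 2, 8,
                  stratum=("nasopharyngeal", "winter"))
enr = cs.enrich_clusters(sub, sol)
```

prints (via the obvious `print` calls):

```
346 samples x 32 ASVs
Shannon oral vs nasopharyngeal: U=14552, p=0.667
PERMANOVA season: R2=0.025, p=0.001
winter nasopharyngeal: k=4 clusters over 52 samples, mean silhouette 0.786
cluster         genus  mean_inside  q_value
     C4   Haemophilus       0.6058   0.0001
     C1 Streptococcus       0.5709   0.0000
     C3     Moraxella       0.5631   0.0000
```

Reading: the generator planted five community states per site; in this
winter stratum four are occupied, the silhouette trace picks k = 4, and
each recovered cluster's enrichment test flags exactly the genus that
dominates its planted archetype (inside-cluster mean ≈ 0.55–0.6, BH
q ≪ 0.05).  The season PERMANOVA is significant but small — season shifts
state *occupancies* rather than wholesale composition.

The same flow is available from the shell:

```bash
commstate simulate --seed 1 --out data/
commstate run --out runs/demo --seed 1     # all stages, one run directory
```

`commstate run` writes alpha/beta diversity tables, PERMANOVA results,
cluster labels with silhouette traces and enrichment, Newick dendrograms,
transition matrices with Fisher tests, and GEXF/GraphML networks, plus a
cohort accounting report and a `run.log`; reruns with the same config and
seed are byte-identical.

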