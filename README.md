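# microguild

Guild-based analysis of two-arm dietary-fiber intervention studies of the
gut microbiome. The package takes an OTU count table, sample metadata,
short-chain fatty acid (SCFA) concentrations, and optional diet / stool-diary
tables, and runs a complete compositional analysis pipeline:

1. **Preprocessing** — low-abundance filtering (mean relative abundance
   ≥ 0.15% over all samples), rarefaction (multivariate-hypergeometric
   subsampling), relative abundance, and centered log-ratio (CLR) transform.
2. **Diversity** — Shannon/richness on rarefied counts, Aitchison (CLR
   Euclidean) distances, inter-/intra-subject dissimilarity summaries, and
   one-way PERMANOVA between treatment arms at each timepoint.
3. **Guild detection** — screen OTUs whose CLR shifts respond to treatment
   (one-sample signed-rank, p < 0.1), correlate shifts between OTUs across
   subjects (Spearman), convert to a 1 − ρ distance, cluster with complete
   linkage, and cut the dendrogram top-down wherever a PERMANOVA pseudo-F
   separates the two child clusters (p < 0.05). The default split test uses a
   selection-aware row-shuffle permutation null (see
   `cut_tree_by_permanova`); guild relative abundance is the sum of member
   OTUs.
4. **Co-response network** — permutation-tested Spearman network over CLR
   shifts (1000 permutations); edges kept at |ρ| ≥ 0.5 and BH-FDR q < 0.05.
5. **SCFA responses** — derived measures (total SCFA, percentages,
   propionate:butyrate ratio, branched SCFA), the W6-responder rule
   (sign of propionate ΔW6–W1), within-/between-group test batteries
   (Friedman + Dunn, Mann–Whitney), and trapezoidal stool-score AUC.
6. **Predictability screen** — PCA-reduced predictor blocks, best 1–2
   predictor subsets by sequential replacement, dose/sex adjustment, AICc and
   relative-AICc ranking, BH-FDR across the screen.
7. **Synthetic data** — a generator of full two-arm studies with planted
   co-response guilds, SCFA links, and temporal responder archetypes, plus
   recovery evaluators (adjusted Rand index, screen power) used as the
   pipeline's test harness.

## Test

```sh
python -m pytest -q tests/
```

The suite includes full-scale calibration studies (PERMANOVA type-I error,
guild-recovery ARI, network null control, screen power); expect a few
minutes on one CPU.

## Command line

```sh
# end-to-end on a synthetic study
microguild all --outdir out/ --seed 1

# individual stages
microguild simulate   --outdir out/sim --seed 1
microguild preprocess --counts out/sim/counts.tsv --outdir out/pre
microguild diversity  --rarefied out/pre/rarefied_counts.tsv \
                      --clr out/pre/clr.tsv \
                      --metadata out/sim/metadata.tsv --outdir out/div
microguild guilds     --clr out/pre/clr.tsv --relative out/pre/relative.tsv \
                      --metadata out/sim/metadata.tsv --outdir out/guilds
microguild network    --clr out/pre/clr.tsv --metadata out/sim/metadata.tsv \
                      --guild-assignment out/guilds/guild_assignment.tsv \
                      --outdir out/net
microguild scfa       --scfa out/sim/scfa.tsv --metadata out/sim/metadata.tsv \
                      --stool-diary out/sim/stool_diary.tsv --outdir out/scfa
microguild predict    --clr out/pre/clr.tsv --metadata out/sim/metadata.tsv \
                      --scfa out/sim/scfa.tsv \
                      --guild-relative out/guilds/guild_relative.tsv \
                      --diet out/sim/diet.tsv --outdir out/pred
```

All tables are UTF-8 TSV. Every artifact gets a JSON sidecar recording the
command, parameters, seed, and input hashes; reruns with the same seed
produce byte-identical outputs.

## Library overview

| module                  | contents |
|-------------------------|----------|
| `microguild.data_model` | `StudyDesign`, `AbundanceTable`, `ScfaProfile`, `StoolDiary`, readers/writers, `filter_low_abundance`, `rarefy`, `to_relative_abundance` |
| `microguild.stats`      | `clr_transform`, `aitchison_distance_matrix`, `alpha_diversity`, `beta_dispersion_summaries`, `permanova` (sampled or exact enumeration), rank-test battery, `friedman_dunn`, `bh_fdr` |
| `microguild.guilds`     | `compute_shift_matrix`, `screen_responsive_otus`, `shift_correlation_distance`, `complete_linkage_tree`, `cut_tree_by_permanova`, `guild_abundance_table`, `coresponse_network` |
| `microguild.scfa`       | `derive_scfa_measures`, `classify_w6_responder`, `responder_group_comparison`, `hedonic_auc` |
| `microguild.prediction` | `pca_reduce`, `best_subset_mlr`, `aicc`, `relative_aicc`, `predictability_screen` |
| `microguild.simulate`   | `SimConfig`, `generate_study`, `simulate_shift_matrix`, `evaluate_guild_recovery`, `evaluate_prediction_recovery` |

### A note on p values around selection steps

Two places in this pipeline test hypotheses that were themselves *selected*
by looking at the data, where naive tests are anti-conservative:

- **Dendrogram splits**: the tested 2-partition is the one complete linkage
  chose, so plain PERMANOVA label permutation grossly over-splits
  homogeneous clusters. The default `row_shuffle` split test permutes each
  subject's shifts across the node's OTUs (exact null invariance for an
  exchangeable factor model) and re-clusters each permuted dataset;
  `split_test="label"` restores the naive behaviour.
- **Best-subset regression**: `model_p` is the partial F test of the chosen
  predictors over the covariate-only baseline, `f_p` the overall F test, and
  `selection_p` a Freedman–Lane permutation of the entire subset search —
  the only one of the three that stays uniform under the null despite
  selection.
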