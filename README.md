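# m6apattern

Cohort-level analysis of N6-methyladenosine (m6A) regulation in lung
adenocarcinoma: consensus clustering of m6A-regulator expression into
modification patterns, pattern-derived gene clusters, a PCA-based
per-patient **m6A score**, and the downstream survival, immune, OSAHS
and tumor-mutation-burden associations.  The package is aimed at
computational biologists who want the full pipeline — or any single
statistic in it — as tested, seedable Python instead of a chain of R
package calls.

## The model in brief

Patients are clustered on a 23-gene m6A regulator panel (8 writers,
2 erasers, 13 readers) by subsampling consensus clustering: average
linkage on 1 − Pearson correlation, 2000 subsample iterations at
fraction 0.8, with k chosen by the delta-area elbow of the consensus
CDF.  Genes differential between the patterns (moderated t with
empirical-Bayes variance shrinkage; adjusted p < 0.01) define gene
clusters and feed a univariate Cox screen (Wald p < 0.05).  The
retained genes are standardised and summarised by PCA; with z the
standardised expression and w₁, w₂ the first two loading vectors, the
score is

    m6Ascore_i = Σ_{k=1,2} Σ_j z_ij · w_jk          (formula A)
    m6Ascore_i = Σ_{j∈G+} z_ij·w_j1 − Σ_{j∈G−} z_ij·w_j1   (formula B)

with G± the genes with positive/negative Cox coefficients.  The
formula is selected by bootstrap validation (stratified 70/30
train–test splits; mean test-set Harrell C-index wins).  Patients are
stratified at the maximally selected log-rank cutpoint, and the score
groups are tested against survival (KM, log-rank, Cox), OSAHS
prevalence (Fisher exact, AUC), and TMB (Spearman, median split, joint
score × TMB strata).  All survival machinery (KM, log-rank, Cox with
Efron ties, Harrell C, cutpoint search, AUC, Spearman, Fisher
enumeration, BH) is implemented in-package and checked against
independent oracles in the test-suite.

A synthetic cohort generator (`m6apattern.simulate`) plants two
regulator patterns, three signature-gene clusters spanning two
principal components, a proportional-hazards survival link, a logistic
OSAHS link and a negative-binomial TMB link — with the ground truth
returned alongside — so every stage has a recovery test.  See
`docs/methods.md` for the full model description and design choices.

## Worked example

Run the whole pipeline on a simulated 300-patient cohort:

```python
from m6apattern import PipelineConfig, run_full_pipeline

cfg = PipelineConfig(simulate=True, sim_n_samples=300, sim_delta=2.5,
                     consensus_iterations=200, bootstrap_iterations=50,
                     seed=7)
r = run_full_pipeline(cfg)
print(r.pattern_k, r.gene_cluster_k, len(r.degs), r.model.formula)
print(r.manifest["bootstrap"]["mean_cindex"])
print(r.score_table.cutpoint)
print(r.survival_stats["five_year_survival"])
print(r.associations["osahs"]["prevalence"])
print(r.associations["tmb"]["spearman_rho"])
```

prints (numbers from this exact run; the run is a pure function of the
seed):

```
2 3 60 A
{'A': 0.6774549424189651, 'B': 0.5612206593584885}
2.1577956428528087
{'high': 0.05072463768115942, 'low': 0.5763157894736841}
{'high': 0.6453488372093024, 'low': 0.359375}
0.46395988137592424
```

Reading it: consensus clustering found the two planted regulator
patterns and the three planted gene clusters; all 60 planted signature
genes survived as DEGs; bootstrap validation preferred formula A
(mean test C-index 0.68 vs 0.56), as it should when the hazard follows
both signature components.  At the selected cutpoint (2.16) the
high-score group has 5% five-year survival versus 58% in the low-score
group, a higher OSAHS prevalence (65% vs 36%), and TMB correlates with
the score (Spearman ρ = 0.46) — the planted directions of every
association.

The same run from the shell, with all tables written to `out/`:

```bash
m6a run --config cfg.yaml --seed 7 --outdir out/
m6a simulate --n 300 --delta 2.5 --seed 7 --outdir sim/   # cohort + truth
m6a cluster --expression sim/expression.tsv --k 2:4 --outdir cl/
```

Outputs are plain TSV/JSON plus a `run_manifest.yaml` recording the
seed and every threshold.

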