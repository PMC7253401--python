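# gliohub

A tested, reusable implementation of a multi-stage hub-gene screen for
grade-structured tumor cohorts, of the kind used to prioritize prognostic
biomarker candidates in diffuse glioma. The screen combines four evidence
streams over a discovery cohort (with normal tissue) and two tumor-only
replication cohorts with survival follow-up:

- **A — co-expression hubs.** A weighted gene co-expression network is
  built from the discovery cohort: similarity `S_ij = |cor(x_i, x_j)|`
  (unsigned), soft-thresholded adjacency `A = S^β` with β chosen so the
  degree distribution approximates a scale-free law (signed fit R² ≥ 0.9,
  largest mean connectivity), and the topological overlap matrix

      TOM_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
      ℓ_ij = Σ_u a_iu a_uj.

  Genes are clustered on `1 − TOM`, module eigengenes (first principal
  components) are correlated with WHO grade, and in each of the top four
  grade-linked modules the top 20% of genes by |module membership| is
  intersected with the top 20% by |grade significance|.
- **B — confirmed discovery DEGs.** Empirical-Bayes moderated t-tests
  (variance shrinkage via moment matching of log variances) for
  tumor-vs-normal and high-grade (III/IV) vs low-grade (I/II); genes
  significant at P < 0.001 and |log2FC| > 1 with the *same direction* in
  both contrasts are confirmed by a chi-square of expression tertiles
  (equal-width bins of the expression range) against grade group.
- **C — cross-cohort survival genes.** Per gene, the lowest-expressing
  30% of samples form a low group; log-rank, single-covariate Cox
  likelihood-ratio (Breslow ties) and death/alive chi-square tests
  compare the groups, with the mortality ratio
  `RR = (deaths_high/n_high) / (deaths_low/n_low)`. Genes significant at
  P < 0.001 in both replication cohorts with the same RR direction.
- **D — grade-monotone replication DEGs.** Same-direction DEGs in
  III-vs-II and IV-vs-III.

The key-gene report is **A ∩ B ∩ D**, annotated with C membership (the
screen observes, and does not enforce, that key genes are prognostic),
subnetwork connectivity among the top 1% of TOM edges, adjacent-grade
fold changes, RR and a tumor-vs-normal diagnostic AUC.

Because real registry data cannot ship with a package, a first-class
synthetic study generator (`gliohub.simulate`) plants all of this
structure — latent-factor modules tracking grade, hub genes with
calibrated fold changes, expression-dependent exponential survival — and
records the ground truth, so every stage and the whole screen are tested
by recovery of what was planted. See `docs/methods.md` for the generative
model and its limits.

## Worked example

```bash
python examples/05_full_pipeline.py
```

runs the whole screen on the default synthetic study (1200 genes; a
200-sample discovery cohort and two 300-sample replication cohorts) and
prints, among others:

```
"soft_power": 12, "n_modules": 5,
"n_result_a": 133, "n_result_b": 119, "n_result_c": 205, "n_result_d": 120,
"n_key_genes": 115, "n_key_in_c": 112

top key genes by subnetwork connectivity:
           connectivity  log2fc_III_vs_II  log2fc_IV_vs_III  cox_lrt_p     rr  in_c   auc
gene_0030         3.628             2.174             1.905        0.0  2.964  True  0.917
gene_0024         3.600             2.082             1.905        0.0  2.587  True  0.905
gene_0451         3.316            -2.236            -1.420        0.0  0.687  True  0.119

planted key-gene recovery: 95.8%; false inclusions: 0
```

Reading this: 115 genes survived all three gates (hub, differential,
grade-monotone); 112 of them are also cross-cohort prognostic. A gene
with RR ≈ 3 dies three times as often in its high-expression group;
`gene_0451` is a down-regulated protective gene (RR < 1, AUC < 0.5
because AUC is reported directionally). Of the 120 genes planted as
simultaneously hub, differential and prognostic, 95.8% were recovered
with no false inclusions.

The other examples exercise one stage each: cohort generation (01), the
network and module-trait analysis (02), the differential screens (03)
and the survival screen (04). A thin CLI wraps the same library:
`gliohub run-all --seed 1 --outdir run/`.

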