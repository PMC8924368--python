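# ticscore

Tumor-infiltrated immune cell (TIC) scoring from bulk expression data.

Bulk tumor transcriptomes mix malignant cells with infiltrating immune
cells, and the composition of that infiltrate carries prognostic and
therapeutic information — in immunologically unusual tumors such as uveal
melanoma, heavier T-cell infiltration tracks *worse* outcomes and immune
checkpoint blockade rarely works, so a quantitative per-patient summary of
the immune contexture is genuinely useful.  `ticscore` rebuilds that kind of
analysis as a tested, reusable Python library for computational biologists:
from raw expression matrices through immune-cell deconvolution, consensus
subtyping, differential expression, a one-number immune score per patient,
and the score's downstream associations with survival, mutations,
immunotherapy response, and drug sensitivity.

## The method

Given gene × sample expression from one or more platforms:

1. **Preprocess** — convert FPKM or counts to TPM, pool cohorts on
   log2(TPM+1), and remove batch effects with parametric empirical-Bayes
   location/scale adjustment (the ComBat model).
2. **Deconvolve** — estimate the fractions of 22 immune cell types per
   sample by ν-support-vector regression against a reference signature
   matrix (z-scored mixture and signature, ν ∈ {0.25, 0.5, 0.75}, lowest
   reconstruction RMSE wins, negative coefficients truncated, renormalized
   to sum to 1), with permutation p-values for fit significance.
3. **Subtype** — consensus-cluster samples on their cell fractions: 1000
   subsampled PAM (k-medoid) partitions per k, consensus matrix M(i,j) =
   co-clustering frequency, k chosen from the delta-area of the consensus
   CDF, final labels by Ward linkage on 1 − M.
4. **DEGs** — empirical-Bayes moderated t (one subtype vs the rest), keeping
   genes with BH-adjusted p < 0.05 and |log2FC| ≥ 1.5.
5. **Score** — cluster samples again on the DEG matrix; order the gene
   clusters along their expression gradient; split DEGs into feature **α**
   (positively correlated with the ordered cluster code) and feature **β**
   (negatively correlated); prune each set with Boruta (shadow-feature
   random-forest selection); then per sample

   TIC = PC1(α) − PC1(β)

   one oriented first principal component per feature set.  The fitted model
   (loadings, moments, orientations) projects onto external cohorts.
6. **Associate** — maximally selected log-rank cutpoint and Kaplan–Meier
   curves; per-gene mutation-frequency contrasts (Fisher exact) and TMB;
   response-rate and ROC/AUC analysis of the score as an immunotherapy
   predictor; and a two-stage drug screen (Spearman ρ below a per-source
   threshold, plus a low-vs-high score decile rank-sum test on drug AUC).

Because the real cohorts behind such analyses need controlled-access
downloads, the package ships a first-class synthetic-cohort generator
(`ticscore.synthetic`) that plants every piece of structure the pipeline is
supposed to find — mixing fractions, subtypes, expression programs, a latent
prognostic axis driving survival/response/drug links, and two
prognosis-linked mutation genes — so every stage is tested as a
parameter-recovery problem with known truth.

## Worked example

```bash
python examples/04_tic_score_survival.py
```

```
DEGs: 115  feature alpha: 8 genes  feature beta: 20 genes
Spearman(TIC score, latent prognostic axis) = 0.941
optimal cutpoint: -0.30  log-rank chi2 = 108.7  p = 1.9e-25
```

115 subtype-associated genes survive the DEG filter; the α/β split plus
Boruta keeps 8 + 20 of them; the resulting score ranks patients almost
exactly along the planted prognostic axis (ρ = 0.94), and splitting at the
optimal cutpoint separates survival decisively.  Projecting the same model
onto an independently drawn cohort predicts the planted immunotherapy
response with AUC ≈ 0.91 (`examples/05_immunotherapy_projection.py`), and
the drug screen recovers exactly the five planted compounds
(`examples/06_drug_screen.py`).

The other examples cover cohort simulation (`01`), deconvolution accuracy
(`02`), and consensus subtype selection (`03`).  A thin CLI wraps the same
functions (`ticscore simulate|preprocess|deconvolve|cluster|deg|score|
survival|mutation|screen|run`); `ticscore run --fast --out run/` executes
the whole pipeline on a simulated cohort and writes a checksum manifest.

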