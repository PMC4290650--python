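# multitox

Integrative prediction of multi-organ drug-induced toxicity from
gene-expression profiles.

New drugs frequently injure the liver or kidney, and the injuries surface
as histopathological findings — necrosis, cellular infiltration,
hypertrophy, hyaline casts, and so on. Given a normalized expression
profile of a treated animal, `multitox` predicts which findings will
present, in both organs at once. It is aimed at toxicogenomics
practitioners working with compound-annotated rat expression data (the
kind distributed by Open TG-GATEs) or any dataset with the same shape:
an expression matrix, a per-sample drug annotation, and a binary
sample × finding occurrence table.

## The model

Two layers:

1. **Individual pathology models.** For each finding *Fᵢ*, genes are
   ranked by a case-vs-control t-test and the top fraction (default 5%)
   forms the finding's signature. Because cases are typically rare, the
   model is an ensemble of *n* k-nearest-neighbor classifiers, each fitted
   on a *jackknife sample*: **all** confirmed cases plus a random subset of
   controls (default: as many controls as cases). Averaging the sub-model
   outputs gives the *pathology prediction score*

   *M_Fᵢ(s) = (1/n) Σₖ sub_M_Fᵢᵏ(s)* ∈ [0, 1].

2. **The integrative layer.** Findings co-occur — a toxic perturbation of
   shared pathways yields several symptoms — and that structure is
   measured by the Jaccard similarity of occurrence vectors,
   *S(Fᵢ,Fⱼ) = N₁₁/(N₀₁+N₁₀+N₁₁)*, row-normalized to
   *N(Fᵢ,Fⱼ) = S(Fᵢ,Fⱼ)/√(Σₘ S(Fᵢ,Fₘ)²)*. The *integrative prediction
   score* pools evidence across all findings:

   *IPS_Fᵢ(s) = Σₘ N(Fᵢ,Fₘ) · M_Fₘ(s)*.

   A finding whose own model is unreliable (too few cases) borrows the
   scores of findings it co-occurs with.

Evaluation is by k-fold cross-validation *in the unit of drugs* — all
samples of a compound share a fold, so no compound leaks across a split —
with signatures, models, and similarities refit inside every training
fold, and decision thresholds chosen on training scores to maximize
√(sensitivity × specificity).

A synthetic-data module generates drug-grouped datasets with latent
toxicity mechanisms, so the whole pipeline is testable without any
external database.

## Worked example

```sh
cat > design.yaml <<'EOF'
n_drugs: 12
samples_per_drug: 8
n_genes: 400
findings: ["liver:Necrosis", "liver:Hypertrophy", "kidney:Regeneration"]
mechanisms: 2
signature_size: 20
prevalence_target: 0.2
effect_size: 0.8
seed: 42
EOF
multitox simulate --config design.yaml --out demo/
multitox evaluate --expr demo/expression.tsv --ann demo/annotation.tsv \
                  --occ demo/occurrence.tsv --seed 42 --folds 4 --out report/
```

prints

```
            finding scorer  sensitivity  specificity      auc  threshold  n_cases  n_controls
     liver:Necrosis    PPS     0.631579     0.987013 0.956254   0.752000       19          77
     liver:Necrosis    IPS     0.631579     0.987013 0.952153   1.077738       19          77
  liver:Hypertrophy    PPS     0.684211     0.935065 0.917977   0.685000       19          77
  liver:Hypertrophy    IPS     0.578947     0.935065 0.913534   0.735009       19          77
kidney:Regeneration    PPS     0.631579     0.974026 0.950103   0.747000       19          77
kidney:Regeneration    IPS     0.631579     0.987013 0.952153   1.077738       19          77
```

Each row is one finding scored either by its individual model (PPS) or by
the integrative model (IPS): pooled held-out sensitivity and specificity
at the tuned threshold, ranking AUC, the mean tuned threshold, and the
case/control split. In this easy balanced design the two scorers are
close; the integrative layer pays off when a finding is rare and weakly
expressed but co-occurs with well-predicted findings (see
`multitox.imbalanced_codependent_design`, and the acceptance results
below). The same library surface is available in Python:
`simulate_dataset`, `train_pathology_model`, `compute_ips`,
`run_cross_validation`.

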