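# radiogcn

Noninvasive prediction of EGFR mutation status — exon-19 deletion (19Del),
exon-21 L858R (21L858R), or wild-type (WT) — for non-small-cell lung cancer
brain metastases, from four co-registered MRI sequences (T1-CE, T2W,
T2-FLAIR, DWI). For each lesion the package extracts a fixed registry of
1,290 radiomics features per sequence, standardizes them, fuses the four
per-sequence vectors with a learned attention mechanism, classifies lesions
with a GraphSAGE network on a cosine-similarity kNN graph, and averages
lesion probabilities into patient-level calls. It ships with the full
evaluation protocol (bootstrap AUC CIs, sensitivity/specificity/accuracy,
Cohen's κ, DeLong tests), a component × sequence-set ablation grid, and a
synthetic-data module (feature-table cohorts and 3-D image phantoms) that
makes every stage testable without clinical data.

It is intended for methods researchers in radiomics / medical-imaging ML who
want a complete, reproducible reference implementation of this
attention-fusion + graph-classifier design.

## The model

For a lesion with standardized per-sequence feature vectors
{f₁, …, f_K} (K = 4, d = 1,290):

```
u_k = tanh(W f_k + b)                 # per-sequence relevance embedding
w_k = exp(u_kᵀu) / Σ_j exp(u_jᵀu)     # softmax attention weight
f   = Σ_k w_k f_k                     # fused lesion vector
```

Lesions form a kNN graph (cosine similarity, k = 10) whose nodes are
classified by a 2-layer GraphSAGE network,
`h' = ReLU(W_self h + W_neigh · weighted-mean(neighbours) + b)`, with a
3-class softmax head; W, b, u and the SAGE weights are trained jointly by
class-weighted cross-entropy. A patient with lesion probability vectors
l₁…l_N receives `p_m = (1/N) Σ_i l_iᵐ`, renormalized to unit L1 norm.
Standardization is L2 row normalization followed by column MinMax fitted on
training rows only — used *instead of* feature selection. Prediction is
inductive: test lesions attach to their most similar training lesions and
never to each other.

## Worked example

```python
from radiogcn import RadioGCNClassifier, evaluate_predictions
from radiogcn.config import simulate_split_cohorts, tables_to_xy, validate_config

cfg = validate_config(None)   # 30 patients/class train, 10/class test
(train_tabs, train_man), (test_tabs, test_man) = simulate_split_cohorts(cfg)
Xtr, ytr, ptr = tables_to_xy(train_tabs, train_man)
Xte, yte, pte = tables_to_xy(test_tabs, test_man)

clf = RadioGCNClassifier(n_sequences=4, seed=0).fit(Xtr, ytr, patient_ids=ptr)
report = evaluate_predictions(yte, clf.predict_proba(Xte), pte, B=2000)
for cname, m in report["lesion"]["per_class"].items():
    print(f"lesion {cname}: AUC {m['auc']:.3f} ± {m['auc_ci_halfwidth']:.3f}")
print(f"patient overall accuracy {report['patient']['overall_accuracy']:.3f}, "
      f"kappa {report['patient']['kappa']:.3f}")
```

prints (seed 0):

```
lesion 19Del: AUC 1.000 ± 0.000
lesion 21L858R: AUC 0.999 ± 0.003
lesion WT: AUC 0.999 ± 0.003
patient overall accuracy 1.000, kappa 1.000
```

i.e. on the default synthetic cohort (class effect size 2, disjoint
per-sequence informative features, per-lesion artifact corruption) the full
model separates each mutation class essentially perfectly at the lesion
level, and averaging lesions makes the patient-level calls at least as good.

A `radiogcn` command-line tool wraps the library:
`radiogcn simulate|extract|pipeline|ablate` (see `--help`); `extract` runs
the NIfTI → 1,290-feature pipeline (resample to 3 × 0.25 × 0.25 mm, crop to
the mask bounding box, rescale to [0, 255], extract) on real image/mask
directories.

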