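# mirloc

Multi-label prediction of **miRNA subcellular localisation** across seven
compartments — cytoplasm, exosome, nucleolus, nucleus, extracellular
vesicle, microvesicle and mitochondrion — by fusing five heterogeneous
feature families:

1. **sequence similarity** — normalised Smith–Waterman scores,
   `SW(m1,m2) = sp(m1,m2) / √(sp(m1,m1)·sp(m2,m2))`;
2. **miRNA–disease network** — node2vec embeddings, where the similarity
   backbone combines ontology-based functional similarity
   `DSS(A,B) = Σ_{t∈T_A∩T_B}(SV_A(t)+SV_B(t)) / (Sem_A+Sem_B)` with a
   Gaussian interaction-profile kernel
   `GIP(i,j) = exp(−γ‖y_i−y_j‖²)`, `γ = γ'/mean_i‖y_i‖²`;
3. **miRNA–drug network** and 4. **miRNA–mRNA network** — node2vec
   embeddings of the other two bipartite association graphs;
5. **propagated mRNA localisation** — each miRNA inherits the
   degree-normalised mean of its target mRNAs' localisation annotations.

The three network branches are refined by **hypergraph convolution**
`X^{l+1} = σ(Â X^l W^l)` with `Â = D_v^{-1/2} H W B^{-1} Hᵀ D_v^{-1/2}`
(hyperedges = similarity neighbourhoods and shared-entity groups), then
all branches are projected to a common width, re-weighted by a softmax
**modality gate**, fused by **multi-head cross-attention**
(`Attention(Q,K,V) = softmax(QKᵀ/√d_k)V` with gated tokens as queries),
and classified by a residual MLP with seven sigmoid outputs trained with
binary cross-entropy.  Evaluation is k-fold cross-validation with pooled
out-of-fold per-compartment AUC / average precision.

The package is for computational biologists studying miRNA function who
have association networks and mRNA annotations but no (or partial)
experimental localisation labels.  Real corpora (RNALocate, HMDD,
miRTarBase, ncDR) are supported as user-supplied plain-text inputs and
never downloaded; a synthetic-data generator with a planted, verifiable
localisation signal makes every stage testable offline.

## Worked example

Generate a 120-miRNA synthetic dataset whose labels are planted through
the miRNA–mRNA channel (signal strength β = 0.8, 5% label noise), run the
full pipeline and 5-fold cross-validation:

```python
from mirloc.experiments import planted_signal_cv

report = planted_signal_cv(synth_seed=0, beta=0.8, scale="small", cv_seed=0)
print(report.to_table())
```

```
compartment	AUC	AUPR
cytoplasm	0.8524	0.8992
exosome	0.8124	0.7559
nucleolus	0.8812	0.7834
nucleus	0.7649	0.7655
extracellular vesicle	0.8784	0.8961
microvesicle	0.8048	0.8523
mitochondrion	0.7375	0.6759
mean	0.8188	0.8040
```

Each row is one compartment scored on pooled out-of-fold predictions: AUC
is the probability that a localised miRNA outranks a non-localised one,
AUPR the average precision under class imbalance.  Because 20% of
synthetic label rows are non-inherited and 5% of bits are flipped, even
the Bayes-optimal scorer tops out near 0.86–0.88 here — a mean AUC of
0.82 means the model recovers most of the recoverable signal.  Fitting a
single model prints a statsmodels-style summary:

```python
from mirloc.experiments import small_synth_config, small_feature_params, small_model_config
from mirloc.features import build_features
from mirloc.model import MirnaLocalizationModel
from mirloc.synth import generate

ds = generate(small_synth_config(0)).dataset
bundle = build_features(ds, small_feature_params(0))
results = MirnaLocalizationModel(bundle, ds.labels, small_model_config()).fit(seed=0)
print(results.summary())
```

```
Mirna localisation fusion model
===============================
miRNAs:            120
branches:          seq, disease, drug, mrna_net, mrna_loc
d_model/heads:     32/4
hypergraph layers: 3
parameters:        23048
epochs run:        60 (best @ 56)
final train BCE:   2.7145
best val BCE:      2.6055
seed:              0
```

`results.predict_proba()` returns the miRNA × 7 probability matrix;
`mirloc.evaluate.cross_validate`, `run_ablation` and `sweep_layers` drive
the evaluation protocols, and ablation flags (`no_hypergraph`,
`no_cross_attention`, `no_disease`, `no_drug`, `no_mrna`, `no_loc`)
rewire the model for component analysis.

A CLI mirrors the pipeline stages:

```bash
mirloc synth --out data/ --seed 0            # synthetic dataset
mirloc locfeat --data-dir data/ --out loc.tsv
mirloc cv --data-dir data/ --folds 5 --epochs 60
mirloc run --config run.yaml                 # cached end-to-end pipeline
```

Real datasets use the same plain-text formats: a FASTA of miRNA
sequences, two-column TSV edge lists for the three association networks,
a child/parent TSV for the disease hierarchy, and entity × 7 binary TSVs
for mRNA annotations and miRNA labels (see `mirloc.dataset.FILES`).

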