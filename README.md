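# lbmff

Drug–disease association prediction by multi-feature similarity fusion
and a layer-attention graph convolutional network.

Drug repositioning asks which approved or investigational drugs might
treat diseases outside their original indication. `lbmff` frames this as
bipartite link prediction: given a binary drug–disease association
matrix **A** ∈ {0,1}^{m×n} together with several heterogeneous
similarity sources, score every unknown pair.

## Method

1. **Per-measure similarities.** Drug–drug similarity from Morgan
   fingerprints (SMILES), side-effect profiles and target profiles, all
   via the Jaccard index S_ij = |X_i ∩ X_j| / |X_i ∪ X_j|; disease–disease
   similarity from the MeSH hierarchy viewed as a DAG, where each
   ancestor *n* of disease *d* contributes C_d(n) (C_d(d)=1, decaying by
   0.5 per level) and
   S_ij = Σ_{n ∈ N_i ∩ N_j} (C_i(n) + C_j(n)) / (DV(i) + DV(j)).
   Literature-semantic similarity enters through a pluggable provider:
   either a precomputed matrix produced by an external language model, or
   a built-in TF-IDF bag-of-words cosine over per-entity text.
2. **Fusion.** Comprehensive similarities are convex combinations,
   S^r = αS^chem + βS^side + γS^target + δ₁S^lit (α+β+γ+δ₁=1) and
   S^d = θS^mesh + δ₂S^lit (θ+δ₂=1), with weights found by grid search on
   a 0.01-step lattice against inner validation folds.
3. **Feature graph.** Fused similarities are normalized,
   ~S = D^{-1/2} S D^{-1/2}, and assembled into the block adjacency
   A_H = [[~S^r, A], [Aᵀ, ~S^d]].
4. **Encoder/decoder.** A two-layer GCN,
   H^{l+1} = ReLU(D̃^{-1/2} A_H D̃^{-1/2} H^l W^l), starting from
   H^0 = [[0, A],[Aᵀ, 0]] (test associations zeroed), with layer
   attention E = Σ_l a_l H^l (a_l initialized to 1/(l+1), learned), and a
   bilinear sigmoid decoder A′ = σ(E_r W E_dᵀ). Training minimizes
   class-weighted cross-entropy over all m·n cells; everything is plain
   numpy with hand-derived gradients and an Adam optimizer, so runs are
   exactly reproducible from a seed.
5. **Evaluation.** Five-fold cross-validation over the known positives,
   AUC/AUPR plus thresholded metrics (F1, accuracy, recall, specificity,
   precision), single-measure ablations on shared folds, and top-K
   ranking exports.

A self-contained synthetic generator (`lbmff.synthetic`) plants block
structure — drugs and diseases in matching blocks associate with
probability `p_in`, otherwise `p_out` — and ties every similarity source
to the same blocks with tunable informativeness, so the whole pipeline
is testable without any external downloads.

## Worked example

```python
from lbmff import SyntheticSpec, TrainConfig, cross_validate, generate

dataset, truth = generate(SyntheticSpec(seed=0))   # 20 drugs x 30 diseases, 2 blocks
report = cross_validate(dataset, weights="uniform",
                        config=TrainConfig(epochs=1000), seed=0)
print(report.summary().round(4).to_string())
```

```
        aupr     auc      f1     acc     rec     spe     pre
0     0.6050  0.9245  0.6047  0.8211  0.9286  0.8025  0.4483
1     0.6574  0.9312  0.6240  0.8760  0.7091  0.9043  0.5571
2     0.7541  0.9502  0.6667  0.8786  0.8364  0.8858  0.5542
3     0.6199  0.9340  0.6929  0.8971  0.8000  0.9136  0.6111
4     0.5511  0.9035  0.6053  0.8417  0.8364  0.8426  0.4742
mean  0.6375  0.9287  0.6387  0.8629  0.8221  0.8698  0.5290
std   0.0675  0.0152  0.0353  0.0275  0.0707  0.0416  0.0595
```

Each row is one held-out fold: the model ranks the masked positives
among all pairs unknown to training (AUC 0.93 means a held-out true
association outscores a random unknown pair 93% of the time; AUPR 0.64
against a ~5% positive prevalence). The thresholded metrics use an
F1-maximizing threshold chosen on an inner validation split of the
training fold.

The same pipeline is scriptable from the shell:

```sh
lbmff synth --seed 0 --out-dir data/
lbmff evaluate --config cfg.yaml --folds 5 --seed 0 --report report.json
lbmff rank --config cfg.yaml --mode per_drug --id DR003 --k 10 --out top.tsv
```

where `cfg.yaml` points at the TSV inputs (association edge list, SMILES
or substructure profiles, MeSH tree numbers, side-effect/target edge
lists, optional corpus or precomputed literature similarities).

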