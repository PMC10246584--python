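# scgpcl

Prototypical contrastive learning on a bipartite cell–gene graph for
clustering single-cell RNA-seq count data, with a splat-style count
simulator for end-to-end validation.

## The problem

Clustering cells from scRNA-seq counts is hard when the expression matrix
is sparse (technical dropout), when the between-cluster signal is weak, or
when cluster sizes are strongly imbalanced. Autoencoder-based methods
learn cell representations by reconstructing the counts, but with weak
signal the reconstruction target is mostly noise. This package instead
treats the data as a *bipartite graph* — cell nodes connected to the gene
nodes they express, edges weighted by the raw count — and learns cell
representations with a two-layer GraphSAGE encoder trained by three
losses:

* an **instance-wise InfoNCE loss** between two stochastically augmented
  views of the graph (subgraph sampling + feature masking), pulling the
  two views of the same cell together;
* a **prototypical contrastive loss** against k-means centroids computed
  at several granularities (K, 2K, 3K), which counteracts the sampling
  bias of instance-wise negatives and injects cluster-level structure;
* a **ZINB reconstruction loss**: counts are modelled per entry as
  `ZINB(x | π, μ, θ) = π·δ₀(x) + (1−π)·NB(x | μ, θ)` with a decoder
  producing mean (size-factor scaled), dispersion and dropout probability.

After pre-training, a DEC-style fine-tuning phase sharpens the clustering:
soft assignments `q_ik ∝ (1 + ‖h_i − c_k‖²/α)^{−(α+1)/2}` are driven
towards the self-sharpened target `p_ik ∝ q_ik²/f_k` by minimizing
`KL(P‖Q) + λ₃·l_ZINB`. See `docs/methods.md` for the full model, defaults
and numerical details.

Everything runs on NumPy/SciPy — gradients come from a small reverse-mode
autodiff engine shipped in `scgpcl.autodiff`, so there is no deep-learning
framework dependency.

## Worked example

```python
import numpy as np
from scgpcl import SimConfig, simulate_counts, fit_predict, TrainConfig, evaluate

cfg = SimConfig(n_cells=1000, n_genes=2000, group_probs=(1/3, 1/3, 1/3),
                de_fac_scale=1.0, dropout_mid=None, seed=0)
counts, truth = simulate_counts(cfg)          # (1000, 2000) int matrix
res = fit_predict(counts, config=TrainConfig(K=3, seed=0))
print(res.stop_reasons)
print(evaluate(truth, res.labels))
```

prints (about 40 s on one CPU):

```
{'pretrain': 'ari_converged@9', 'finetune': 'tol_converged@1'}
{'nmi': 1.0, 'ari': 1.0, 'ca': 1.0, 'macro_f1': 1.0, 'micro_f1': 1.0}
```

Three well-separated simulated groups (DE sigma 1.0, no dropout) are
recovered exactly: pre-training converged after 10 epochs (consecutive
epoch labelings agreed at ARI > 0.99), fine-tuning stopped as soon as no
cell changed its hard label, and all five concordance scores against the
simulation's ground truth are 1. On harder regimes (DE sigma 0.15) the
same pipeline reaches NMI 0.3–0.7 and matched accuracy 0.6–0.9 at this
problem size, with substantial seed-to-seed variability — the signal is
marginal at 1000 cells and grows with dataset size.

The same pipeline is available from the shell:

```bash
scgpcl simulate --case 2 --level 0.15 --seed 0 --out sim/
scgpcl fit --counts sim/matrix.mtx --k 3 --out run/ --seed 0
scgpcl eval --pred run/labels.csv --truth sim/labels.csv
scgpcl reproduce-fig2 --out sweep.csv --n-cells 600 --n-genes 1500
```

`fit` accepts dense CSV/TSV (cells × genes, `--transpose` to flip) or
MatrixMarket with 10x-style sidecars, and writes labels, embeddings, a
training log and a YAML run manifest that reproduces the run.

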