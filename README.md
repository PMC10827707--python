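# gruclust

Semi-supervised classification of DNA sequences: overlapping k-mer
tokenization, a supervised GRU feature extractor, and latent-space K-means
prediction of unlabelled sequences.

## The problem

Telling apart two classes of DNA sequence — for instance sequences derived
from transcription-factor binding experiments in two different cell lines —
usually requires large labelled training sets, which are expensive to
produce.  `gruclust` targets the semi-supervised setting: labelled
sequences train a recurrent feature extractor, and unlabelled sequences are
then classified *without their labels* by clustering their learned latent
representations.

The pipeline has three phases:

1. **Tokenize** — each sequence is split into overlapping k-mers (k = 2 by
   default; `CCTCCCGAGAGA` → `cc ct tc cc cc cg ga ag ga ag ga`) and mapped
   to integer ids through a frequency-ranked vocabulary (at most 4^k
   entries; id 0 is reserved for padding).
2. **Learn** — a recurrent network (token embedding → 200 GRU units →
   dense relu stack 128/64/32/16 with dropout → sigmoid unit) is trained on
   the labelled split with binary cross-entropy and early stopping.  The
   GRU cell follows the standard gating equations
   z = σ(W_z x + V_z h + b_z), r = σ(W_r x + V_r h + b_r),
   ĉ = tanh(W_C x + V_C (r ⊙ h) + b_C), h′ = z ⊙ h + (1 − z) ⊙ ĉ.
   The activations of the fourth feature layer (32 units) are the latent
   representation.
3. **Predict** — the unlabelled latents are clustered into c = 2 groups by
   a bespoke Lloyd K-means (each point joins the cluster with the nearest
   mean, a_b = Σ z_ib x_i / Σ z_ib), and each cluster is mapped to the
   class whose labelled-training latent mean is nearest.  Performance is
   reported as accuracy A = (TP+TN)/(TP+FP+FN+TN) with per-class precision
   P = TP/(TP+FP), recall R = TP/(TP+FN) and F1 = 2PR/(P+R).

Labelled data follow a 4:1 learn/test and 4:1 train/validation protocol
(20,000 sequences → 16,000/4,000 → 12,800/3,200), stratified by class.

BiGRU/LSTM/BiLSTM backbones and supervised comparator predictors
(random forest, support-vector regression, decision tree over the same
latents) are available for model comparison.  The recurrent engine is
implemented directly in NumPy (manual backpropagation through time), so
results are exactly reproducible under a seed.

## Worked example

Because real cell-line data must be fetched separately, the package ships a
generator that emulates a two-class benchmark by planting a class-specific
8-mer consensus motif (`AGATAAGA` vs `TTGCGCAA`, insertion probability 0.9)
into 100-bp uniform background sequence:

```python
from gruclust import PipelineConfig, run_pipeline

art = run_pipeline(PipelineConfig(epochs=16, early_stopping_patience=5,
                                  batch_size=64, seed=1, out_dir="run_output"))
print(art.report.to_text())
```

```
A (%): 93.50
Class  P (%)  R (%) F1 (%)
    0    100     87     93
    1     89    100     94
```

Read: of 800 held-out sequences predicted purely from their latent
clusters, 93.5% received the correct class; every sequence predicted as
class 0 really was class 0 (P = 100%), at the cost of recovering 87% of
the true class-0 sequences.
Roughly 10% of generated sequences carry no motif, so ~95% is the ceiling.
`run_output/` contains the vocabulary, model checkpoint, K-means centroids,
per-sequence predictions (`id,predicted_label,cluster,distance_to_centroid`),
the evaluation table and the per-epoch training history.

The same run from the shell:

```sh
gruclust run --seed 1 --out run_output
gruclust simulate --n-per-class 2000 --insertion-prob 0.9 --seed 1 --out data.csv
gruclust compare --backbones gru,bigru --predictors kmeans,tree --k-values 2 \
                 --gru-units 200 --out grid_out
```

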