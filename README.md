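# mcwnet

Marker-controlled watershed preprocessing and a hybrid attention-CNN-LSTM
classifier for three-class chest-radiograph-like images (normal vs. two
infectious-lung-disease patterns), implemented as a tested NumPy library
with a thin command-line interface.

The package is aimed at researchers who want to study this two-stage
pipeline — classical segmentation as a learned-model front end — without
access to clinical data: a seeded synthetic generator emulates the three
visual classes, so every stage from segmentation through training and
ablation runs reproducibly on a laptop.

## The method

**Stage 1 — marker-controlled watershed (MCW).** The grayscale image `f` is
reduced to its Sobel gradient magnitude `|∇f| = √(Gx² + Gy²)`. Foreground
markers are the regional maxima of an opening/closing-by-reconstruction
smoothed image (suppressed below an h-maxima height `h`); background
markers are the watershed ridge lines of the distance transform of the
thresholded dark region. Flooding the gradient surface from these markers
partitions the image into catchment basins `CatBas(m_j)` — one basin per
marker — separated by watershed ridge lines `Wshed(f)` (pixels reached
simultaneously by two basins, kept as label 0). The label map is rendered
to RGB (region colour keyed by intensity rank and mean) and resized to the
network input, 100 × 100 × 3.

**Stage 2 — the ACL network.** A 28-layer graph: two conv(16, 3×3)/BN/ReLU/
maxpool(3×3, stride 1) blocks, then an attention block in which a sigmoid
branch produces a per-pixel coefficient map `α ∈ (0,1)` multiplied
element-wise with the trunk features (`out = α × x`; an alternative `additive`
mode implements the explicit additive gate
`α = σ(φᵀ(w_xᵀx + w_gᵀg + b_g) + b_φ)`), then flatten → single-step
LSTM(100) with gates
`f_t, i_t, o_t = σ(W [x_t, h_{t−1}, C_{t−1}] + b)`,
`C_t = f_t·C_{t−1} + i_t·tanh(W_c[·] + b_c)`, `h_t = o_t·tanh(C_t)` →
FC(100) → ReLU → 40% dropout → FC(3) → softmax. Training uses SGDM
(momentum 0.9), learning rate 0.001, 5 epochs, minibatch 32, at 70–30,
80–20 or 90–10 stratified train/test splits.

**Evaluation.** Per class, one-vs-rest: Se = TP/(TP+FN), Sp = TN/(TN+FP),
Pr = TP/(TP+FP), F = 2TP/(2TP+FP+FN), plus overall accuracy and
trapezoidal one-vs-rest ROC/AUC. An ablation runner trains four variants
(full; no attention; no LSTM; neither) on identical splits.

All network layers, backpropagation and the SGDM loop are implemented in
NumPy inside the package (`mcwnet.nn`); the watershed flooding is an exact
Meyer priority-flood with deterministic tie-breaking.

## Worked example

```bash
python examples/04_train_and_evaluate.py
```

trains the full network on 120 synthetic images (40 per class, 90–10
split) and prints:

```
iterations: 20, loss 1.108 -> 0.490
final training accuracy: 0.963
test accuracy: 1.000

case ratio          class     Se     Sp     Pr  F-score    Acc
full 90-10     covid_like 1.0000 1.0000 1.0000   1.0000 1.0000
full 90-10         normal 1.0000 1.0000 1.0000   1.0000 1.0000
full 90-10 pneumonia_like 1.0000 1.0000 1.0000   1.0000 1.0000
```

The loss trace shows cross-entropy falling from chance (ln 3 ≈ 1.10); the
metric rows are one-vs-rest sensitivities, specificities, precisions and
F-scores on the 12 held-out images, all perfect here. The other example
scripts walk through dataset synthesis (`01`), the watershed stage with its
intermediate markers and basins (`02`), and the network's layer table and
ablation variants (`03`).

The same pipeline is scriptable from a shell:

```bash
mcwnet synth --out data/raw --n 60 --seed 7
mcwnet preprocess --data data/raw --out data/mcw
mcwnet train --data data/mcw --out runs/full --split 90-10 --variant full --seed 7
mcwnet describe --variant full
```

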