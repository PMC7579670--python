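# drhybrid

Diabetic-retinopathy (DR) severity grading toolkit: fundus-image
preprocessing, an ordinal-penalty "enhance cross-entropy" (E-CE) loss,
pluggable classifier backbones, three ensemble fusers over the base models'
softmax outputs, and the matching evaluation metrics — all runnable on one
CPU via a synthetic-data module.

## What is in here

| module | purpose |
|---|---|
| `drhybrid.imageprep` | black-border cropping (binarize + tight bbox), per-backbone resizing, affine/flip augmentation, manifest I/O |
| `drhybrid.losses` | component-averaged binary cross-entropy (CE), the E-CE loss = CE + `abs(G_true − G_pred)/(N−1)` ordinal penalty (hard argmax mode, or a differentiable expected-grade "soft" mode) |
| `drhybrid.backbones` | registry of the five published backbone configurations (input sizes, batch sizes, dropout-0.4 + 5-unit-softmax heads) plus a trainable `TinyCNN` for desk scale; training loop (RAdam, reduce-on-plateau) |
| `drhybrid.hybrid` | Hybrid-a (probability averaging), Hybrid-f (2048-unit dense fuser on the stacked 25-vector), Hybrid-c (three 256-filter 3×3 convolutions on the 5×5 probability matrix), training and persistence |
| `drhybrid.metrics` | 5×5 confusion matrices, trace accuracy, one-vs-rest sensitivity/specificity/precision/F1 (default positive grade 0, which is the collapse that reproduces the reference results) |
| `drhybrid.synthdata` | synthetic fundus-like images (grade-correlated lesions) and synthetic base-model outputs with an ordinal confusion kernel and the reference class imbalance |
| `drhybrid.pipeline`, `drhybrid.cli` | end-to-end orchestration and the `drhybrid` command |

No GPU deep-learning framework is assumed: all trainable models run on a
small bundled numpy engine (`drhybrid._nn`). The five named large backbones
are registered with their published contracts (sizes, heads) but use small
CPU stand-in trunks; requesting `pretrained=True` raises, since no weights
are available here. `TinyCNN` is the backbone actually trained in tests.

## CLI

```bash
drhybrid synth --n 200 --out-dir data --seed 7            # synthetic images + manifest
drhybrid preprocess -m data/manifest.csv -o prep --model TinyCNN --threshold 10
drhybrid train-basic --model TinyCNN --loss ece -m prep/manifest.csv \
    --epochs 20 --seed 7 --out-ckpt tiny.npz
drhybrid predict-basic --model-ckpt tiny.npz -m prep/manifest.csv -o outputs.csv
drhybrid synth-outputs --n 5000 --models 5 --accuracy 0.8 --seed 7 --out outputs.csv
drhybrid train-hybrid --kind c --outputs outputs.csv --epochs 10 --seed 7 \
    --out-ckpt fuser.npz
drhybrid predict --kind c --fuser-ckpt fuser.npz --outputs outputs.csv -o preds.csv
drhybrid evaluate --predictions preds.csv --positive-grade 0
drhybrid run --config pipeline.yaml --seed 7               # all stages from YAML
```

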