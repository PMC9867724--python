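# scanmil

Attention-based multiple-instance learning (MIL) for classifying volumetric
CT-like scans from weak, scan-level labels — with the surrounding apparatus a
study of such a classifier needs: baseline pooling operators and scan-level
classifiers, a repeated-split evaluation protocol with paired DeLong AUC
comparisons, attention-depth interpretability analyses, and a synthetic
phantom generator with slice-level ground truth for validating all of it.

The motivating application is opportunistic detection of diffuse lung
disease (e.g. emphysema) on low-dose CT acquired for lung-cancer screening,
where only scan-level visual scores are available and slice-level
annotation is impractical.

## The model

A scan is a *bag* X = {x_1, …, x_N} of axial slice *instances* ordered from
lung top to lung bottom. Instance truths y_j are latent; the scan label
follows the MIL rule

    Y = 0  iff  Σ_j y_j = 0,   else 1.

The classifier is the composition Ŷ = g(P f(X)):

- **f** — a *frozen* feature extractor applied per slice, followed by two
  trainable fully connected layers (ReLU, dropout 0.5) mapping to 512-dim
  instance embeddings. Two extractors are provided: a transfer-learning
  scheme (VGG19/ImageNet per-block pooled features, D_raw = 1472; requires a
  deep-learning runtime with downloadable weights) and a deterministic
  lightweight extractor (seeded random projection of per-block image
  statistics, D_raw = 512) that runs anywhere.
- **P** — a pooling operator across instances: attention pooling

      z = Σ_n a_n x_n,   a_n = softmax_n( wᵀ tanh(V x_nᵀ) ),

  with w ∈ R¹²⁸, V ∈ R¹²⁸ˣ⁵¹², or element-wise mean / max pooling baselines.
- **g** — an affine map 512 → 1 with sigmoid giving the scan probability.

Training uses bag-level binary cross entropy, Adam (β₁ = 0.9, β₂ = 0.99,
lr = 1e-4), early stopping after 7 non-improving validation epochs, and
70/10/20 train/val/test splits repeated 5 times; AUCs are compared with the
paired DeLong test, aggregating the per-repeat p-values by their median with
Bonferroni correction. The attention weights a_n double as interpretable
output: scaled to [0, 1] per scan and plotted against normalized lung depth,
summarized by the depth of maximum fitted attention, the attention-weighted
average depth, and the fitted-curve range, and used to rank slices for
top-k attended-feature prevalence analysis.

Non-MIL baselines: a noisy 2D slice classifier (scan label broadcast to
every slice; scan score = mean slice probability) and a fully 3D CNN
(volumes axially interpolated to a fixed 128 slices).

The trainable heads are implemented directly in numpy with hand-derived
gradients (verified against finite differences in the test suite); no
deep-learning framework is required.

## Worked example

```python
import scanmil as sm
from scanmil.features import build_feature_store
from scanmil.evaluation import roc_auc

# 60 synthetic scans, half positive, lesions concentrated at 20% lung depth
cfg = sm.PhantomConfig(n_scans=60, slices_per_scan=(15, 30), seed=7)
pairs = sm.generate_phantoms(cfg)
bags = [b for b, _ in pairs]
labels = {b.scan_id: b.label for b in bags}

store = build_feature_store(bags, "light")          # frozen per-slice features
results = sm.run_repeats(                            # 5 x 70/10/20 protocol
    lambda s: sm.MILHead(store.dim, pooling="attention", seed=s),
    store, labels, sm.TrainConfig(), master_seed=7,
)
aucs = [roc_auc(r.test_scores, r.test_labels)[0] for r in results]
print([round(a, 3) for a in aucs])
```

prints the five held-out AUCs, one per repeated split:

```
[1.0, 1.0, 1.0, 1.0, 1.0]
```

i.e. the attention head recovers the scan label perfectly from weak
supervision on this small, strong-signal cohort. The attention weights of a
trained model (`results[0].test_attention`) feed the depth analysis:

```python
profiles = [
    sm.AttentionProfile(sid, sm.normalized_depths(len(a)), a)
    for r in results for sid, a in r.test_attention.items() if labels[sid] == 1
]
curve = sm.fit_group_curve(profiles)
print(sm.influence_metrics(curve, profiles))
```

which prints

```
InfluenceMetrics(max_attention_depth=15.25, weighted_avg_depth=48.1599343319757, attention_range=21.286287408228567)
```

the three influence metrics in percent of lung depth (0% = lung top): the
fitted attention curve peaks at 15.3% depth, near the generator's
configured 20% lesion-depth mode — the model's attention concentrates in
the upper lung where the lesions were planted. The weighted average sits
near mid-lung because attention mass outside the few lesion slices is
spread over the whole depth range.

A command-line interface mirrors the library:

```bash
scanmil simulate --out phantoms/ --n-scans 60 --seed 7
scanmil extract  --manifest phantoms/manifest.csv --out feats.npz
scanmil train    --manifest phantoms/manifest.csv --features feats.npz \
                 --pooling attention --out run_attn/ --seed 7
scanmil attend   --manifest phantoms/manifest.csv --features feats.npz \
                 --slices phantoms/slices.csv --out attn/
```

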