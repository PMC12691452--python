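# wsip2p — patch-to-prediction MIL for whole-slide histology

`wsip2p` is a tested, reusable implementation of a patch-to-prediction
pipeline for classifying whole-slide images (WSIs) of ovarian carcinoma
into five histotypes (CC, MC, LGSC, HGSC, EC) under weak, slide-level
supervision. It covers the full path from gigapixel-scale slides to a
bag-level prediction:

1. **Tiling** — a W×H slide is cut into non-overlapping R×R tiles
   (`Nh = ⌊W/R⌋`, `Nv = ⌊H/R⌋`; a 16,000² slide yields at most 31×31 = 961
   tiles of 512²), dark/empty tiles are dropped by a brightness threshold
   (mean intensity < 25/255), and kept tiles are Lanczos-downscaled
   512 → 256 for an exact 4× memory reduction.
2. **MIL bags** — each slide becomes a *bag* of N = 50 tiles sharing one
   label (the "one-vs-50" representation), with training augmentations
   and stratified ratio/count/domain splits.
3. **Aggregation** — instance features `F ∈ R^{n×d}` are pooled into a bag
   vector by mean pooling, element-wise max pooling, gated-tanh attention
   `B = Σ_j α_j F_j` with `α = softmax(wᵀ tanh(V F_j))`, or **K-TOP**
   pooling: a learned scorer ranks the instances and only the top K
   (default K = 5) are averaged, with their softmax weights renormalized
   over the selection so the scorer stays on the gradient path.
4. **Classification & calibration** — a linear head over the bag vector
   with a temperature-scaled softmax `p_i = e^{z_i/τ} / Σ_j e^{z_j/τ}`,
   trained with AdamW + one-cycle scheduling on bag-level cross-entropy.
5. **Evaluation** — a confusion-matrix suite (accuracy, precision,
   recall, specificity, F1, balanced accuracy, Cohen's κ, macro
   one-vs-rest AUROC/AUPRC) and a leave-one-domain-out generalization
   protocol with domain gaps, Δ1/Δ2 difference tables and consistency
   labels.

Because the multi-institutional slide archive itself cannot be bundled,
the package ships a **synthetic multi-center WSI generator**: slides with
near-white background, class-specific informative texture covering a
configurable tissue fraction, tile-aligned near-black artifact blocks
(exercising the brightness filter), and per-domain hue/saturation stain
shifts emulating inter-institutional variability. Every stage of the
pipeline is tested end-to-end on these cohorts.

## Worked example

Train all four aggregators on a synthetic 4-domain cohort of 100 slides
(1024², ~8% informative tissue, bags of 50 tiles, 5 epochs):

```python
from wsip2p.experiments import planted_signal_experiment

acc = planted_signal_experiment(
    seed=0, aggregator_kinds=("mean", "max", "attention", "ktop")
)
print(acc)
```

```
{'mean': 0.75, 'max': 0.85, 'attention': 0.95, 'ktop': 0.95}
```

Each number is the held-out test accuracy of one aggregator. Only ~4 of
the 50 instances in a bag carry class signal, so plain averaging dilutes
it (0.75); max pooling keys on single strong instances (0.85); the
learned attention and top-K selection concentrate on the informative
instances and recover most of the signal (0.95). The same comparison is
the package's headline property: over multiple seeds, K-TOP matches or
beats mean pooling in the median.

The CLI exposes the same stages for shell use:

```bash
wsip2p synth --n-per-class 4 --n-domains 4 --size 2048 --seed 0 --out cohort/
wsip2p tile  --manifest cohort/manifest.csv --tile-size 512 --downscale 256 --out tiles/
wsip2p bags  --tiles tiles/tiles.csv --manifest cohort/manifest.csv --n 50 --seed 0 --out bags/
wsip2p train --manifest cohort/manifest.csv --aggregator ktop --k 5 --seed 0 --out run/
```

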