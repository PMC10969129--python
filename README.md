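# alshift

Uncertainty-based active learning for domain adaptation in binary image
screening, exercised end-to-end on a synthetic two-domain benchmark.

The pipeline mirrors a three-phase cross-domain protocol:

1. **Phase 1** — train a binary CNN on the source domain (weights `w1`),
   evaluate on the source test set (`M1`) and on the pooled two-domain test
   set (`Mav1`). The pooled score drops under domain shift.
2. **Phase 2** — pool-based active learning on the target domain, warm-started
   from `w1`: least-confidence scoring (`min(P, 1-P)`), top-n batch querying,
   oracle labeling, iterative retraining until the pool is fully labeled
   (weights `w12`), with a labeling-budget accuracy curve and a
   random-sampling control strategy.
3. **Phase 3** — train from scratch on the fully labeled target domain
   (weights `w2`) as the comparison condition.

Everything runs on CPU with a small numpy CNN (im2col convolutions, ReLU,
max pooling, global average pooling, 2-unit softmax head, Adagrad, manual
backprop) — no deep-learning framework required. Grad-CAM heatmaps are
computed from the same backward pass.

## Layout

| Module | Role |
| --- | --- |
| `alshift.synthetic` | seeded two-domain, two-class image benchmark generator (class signal = oriented bar / offset blob; domain nuisance = intensity mean shift, scale, texture noise) |
| `alshift.data_io` | `<root>/{train,test}/<class>/*.png` dataset reader/writer, resize + normalization |
| `alshift.network` | minimal numpy CNN engine with numeric-gradient-tested backprop |
| `alshift.classifier` | build / train / predict / snapshot / Grad-CAM contract |
| `alshift.active_learning` | least-confidence scoring, query selection, the m-iteration loop, random baseline |
| `alshift.domain_shift` | pooled intensity histograms + two-sample t-statistic (pooled & Welch) |
| `alshift.evaluation` | accuracy/precision/recall/F1/AUC, combined test sets, the snapshot-by-test-set evaluation matrix |
| `alshift.experiment` | three-phase orchestration, budget curves, Grad-CAM panels, run manifest |

## CLI

```bash
alshift dataset generate --spec spec.yaml --out data/D1
alshift dataset inspect data/D1
alshift shift compare data/D1 data/D2 --bins 50 --out report/
alshift classifier train --data data/D1 --out w1.npz --epochs 30 --lr 0.05
alshift classifier predict --weights w1.npz --data data/D2
alshift classifier explain --weights w1.npz --image img.png --out cam.png
alshift evaluate --weights w1.npz --weights w2.npz --tests data/D1 --tests data/D2
alshift al run --pool data/D2 --weights w1.npz --source-tests data/D1 \
    --l 50 --m 5 --strategy least_confidence --seed 0 --out al_out/
alshift experiment run --config config.yaml
```

`experiment run` takes a YAML file with `source_spec` / `target_spec`
(fields of `DomainShiftSpec`), optional `arch_config`, `train_config`
(defaults: batch size 32, 30 epochs max, Adagrad, lr 0.001, ReLU,
categorical cross-entropy), `al_l`, `al_m`, `al_strategy`, `n_seeds`,
`seed` and `output_dir`; see `tests/test_cli.py` for a complete example.
Outputs: `metrics.csv`, `budget_curve.csv`, `summary.csv`, `manifest.json`,
`plots/budget_curve.png`, `gradcam/*.png`.

## Notes on the desk-scale setup

* The default training hyperparameters follow the published protocol
  (batch 32, ≤30 epochs, Adagrad, lr 0.001, ReLU, categorical
  cross-entropy). The benchmark experiments raise the learning rate to 0.05
  because training a small CNN from scratch is not the same regime as
  fine-tuning an ImageNet backbone.
* The strong-shift benchmark (`alshift.synthetic.strong_shift_specs`)
  uses a +0.2 intensity mean shift and doubled texture noise in the target
  domain, with a bimodal per-image signal-amplitude mixture so that the
  pool has a minority of genuinely informative faint samples.
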