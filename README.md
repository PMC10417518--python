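# cattleseg

Semantic segmentation of cattle in multi-animal farm scenes, built around
an improved DeepLabV3+ design: a truncated MobileNetV2 encoder held at
output stride 16 by atrous convolution, an ASPP head, and a U-Net-style
layer-by-layer fusion decoder with squeeze-and-excitation (SE) channel
attention. The package is aimed at precision-livestock researchers who need
per-pixel cow/beef/background masks plus the standard evaluation toolkit —
and at anyone who wants a fully inspectable, pure-numpy implementation of
this architecture family.

Three classes are segmented: background (0), cow (1, dairy coat with dark
patches) and beef (2, uniform dark coat). The ablation grid of the design
is first-class:

| variant | decoder | SE attention |
|---------|------------------------------------------|----|
| `imp`   | layerwise: four 2× up-samplings, 3 fusions | yes |
| `m2u`   | layerwise: four 2× up-samplings, 3 fusions | no |
| `m2`    | original: two 4× up-samplings, 1 fusion    | no |

Evaluation uses the confusion-matrix suite: pixel accuracy
PA = (TP+TN)/(TP+FP+FN+TN), per-class pixel accuracy CPA = TP/(TP+FP),
MPA = ΣCPA/NC, IoU = TP/(TP+FP+FN) and MIoU = ΣIoU/NC. A synthetic scene
generator (textured ground, ellipse-composite animals, railing occluders)
and an atmospheric-scattering fog operator I = J·e^(−βd) + A·(1−e^(−βd))
make the whole pipeline runnable and testable without any real imagery.
Labelme polygon annotations and palette-PNG masks are supported for real
data.

Everything runs on a small numpy autodiff engine included in the package
(`cattleseg.nn`) — no GPU framework required. See `docs/methods.md` for the
model, the generator's scope, and all numerical choices.

## Worked example

```python
import numpy as np
from cattleseg.data import SceneRecipe, generate_dataset, split_dataset, make_eval_sets
from cattleseg.estimators import ImpDeepLabSegmenter

scenes = generate_dataset(200, SceneRecipe(canvas_size=(96, 96)), seed=11)
train_set, test_set = split_dataset(scenes, 0.8, seed=11)

est = ImpDeepLabSegmenter(variant="imp", widths="desk", epochs=12, seed=11)
est.fit(np.stack([s.image for s in train_set]),
        np.stack([s.mask for s in train_set]))

for name, subset in make_eval_sets(test_set, seed=11).items():
    r = est.evaluate(subset)
    print(f"{name:9s} PA={r.pa:.3f} MPA={r.mpa:.3f} MIoU={r.miou:.3f}")
```

Output (about three and a half minutes on one CPU core):

```
original  PA=0.816 MPA=0.665 MIoU=0.468
sunny     PA=0.990 MPA=0.947 MIoU=0.918
foggy     PA=0.624 MPA=0.327 MIoU=0.225
```

Reading: on the clear held-out scenes ("sunny") the model segments almost
every pixel correctly (MIoU 0.918). On the all-fogged copy of the same
scenes ("foggy") a model trained only on clear imagery collapses (MIoU
0.225) — fog robustness must be trained for, not assumed — and the mixed
50%-fogged set ("original") sits in between. `est.evaluate(...)` also
carries per-class CPA/IoU for cow and beef.

The estimator follows the scikit-learn protocol (`fit`/`predict`/`score`,
`get_params`, `clone`-compatible); `score` returns held-out MIoU. The
underlying library surface (`cattleseg.model`, `.training`, `.metrics`,
`.data`) exposes the same functionality piecewise, and the `cattleseg` CLI
wires it into replayable artifacts:

```bash
cattleseg generate --n-scenes 20 --size 96 --seed 1 --out scenes/
cattleseg split scenes/manifest.csv --ratio 0.8 --seed 1 --out split.csv
cattleseg train split.csv --variant imp --epochs 12 --seed 1 --out model.npz
cattleseg eval model.npz split.csv --testset foggy
cattleseg ablate split.csv --variants m2,m2u,imp --out ablation.csv
cattleseg run experiment.yaml        # full bundle with hashed manifest
```

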