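# visprobe

Distance-based perceptual property tests for layered visual feature
representations.

Psychophysics and single-unit physiology have catalogued a set of robust
regularities in how primates see: Thatcherized faces look grotesque only
upright, left–right mirror images are more confusable than up–down ones,
responses to multiple objects approximate the average of the responses to
each object alone, discriminability follows Weber's law, global shape
dominates local shape, objects decompose into natural parts, and so on.
Each of these can be recast as a statement about *distances* in a feature
space: for activation vectors **x**, **y** of two images at some layer,
with d(x, y) = ‖x − y‖, almost every effect becomes a contrast index

    (d_a − d_b) / (d_a + d_b) ∈ [−1, 1],

positive when the representation orders the relevant image pairs the way
perception does.  `visprobe` implements the full battery of twelve such
tests for *any* layer-wise feature extractor — a raw pixel layer, a bundled
seeded random convnet, analytic surrogates with exactly known response
laws, or a user-supplied network adapter — together with seeded synthetic
generators for all twelve stimulus families, so every index can be computed
and verified without external datasets or pretrained weights.

It is aimed at researchers in computational neuroscience and vision who
want to characterize which perceptual properties a representation does or
does not exhibit, and at method developers who need exact oracles for
representational-similarity pipelines.

## Worked example

Thatcher index across the layers of the seeded random reference convnet,
on 20 generated schematic faces:

```python
from visprobe import stimuli, features, indices

faces = stimuli.make_thatcher_set(20, seed=1, size=64)
net = features.reference_convnet(seed=0, input_size=64)
table = features.extract(net, faces)
prof = indices.thatcher_index(faces, table)
for k, s in enumerate(prof.layers):
    print(f"{s.name:9s} {s.kind:5s} {prof.mean[k]:+.3f} ± {prof.sem[k]:.3f}")
```

```
conv1     conv  -0.000 ± 0.000
relu1     relu  -0.011 ± 0.002
pool1     pool  -0.023 ± 0.004
conv2     conv  -0.025 ± 0.004
relu2     relu  -0.020 ± 0.004
pool2     pool  -0.035 ± 0.008
conv3     conv  -0.032 ± 0.008
relu3     relu  -0.025 ± 0.007
pool3     pool  +0.001 ± 0.008
fc1       fc    -0.085 ± 0.009
relu_fc1  relu  -0.046 ± 0.013
fc2       fc    -0.033 ± 0.017
```

Each row is the mean ± s.e.m. (n = 20 faces) of
(d_upright − d_inverted)/(d_upright + d_inverted), where d_upright is the
distance between a face and its eyes/mouth-flipped version upright and
d_inverted the same after rotating both images 180°.  The untrained network
shows no positive Thatcher effect at any depth — at the last fully
connected layer the index is −0.033 with |mean| > s.e.m., so the battery's
verdict for this property is **absent** (human perception gives a clearly
positive index).  The first convolution is linear, so its index is zero up
to rounding; a pure pixel representation gives exactly zero, which the test
suite asserts as a built-in null.

The whole battery, from the shell:

```bash
visprobe -v run --extractor refnet --seed 0 --size 64 --out battery_out
```

writes `results.csv` (one row per experiment × layer × measure, with mean,
s.e.m., n, exclusion tally, and the config hash) plus `summary.json` with
one presence verdict per experiment, and prints lines such as
`thatcher: absent`, `normalization: present`.  `visprobe generate -e weber`
exports any stimulus family as PNGs with a JSON metadata sidecar.

## What's in the box

- `visprobe.stimuli` — seeded generators for all twelve families
  (schematic faces with known eye/mouth boxes, mirror silhouettes,
  object/context scenes, multi-object displays, shape/morph/texture sets,
  bar-length ladders, size and pattern/surface tetrads, 3D line drawings,
  occlusion displays, natural/unnatural part objects, hierarchical shapes).
- `visprobe.features` — the extractor contract, preprocessing, pixel
  extractor, seeded random convnet, analytic surrogates, activation cache.
- `visprobe.metrics` — distances, contrast index, visual-activity
  selection, sparseness, slope fits, Weber correlations.
- `visprobe.indices` — the twelve experiment procedures.
- `visprobe.partsum` — the part-sum linear dissimilarity model
  (1176-equation design, least-squares fit, common-pair evaluation).
- `visprobe.battery` — configuration, orchestration, verdicts, reports,
  CLI.

See `docs/methods.md` for the definitions, numerical choices, and
limitations.

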