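[
 {
  "experiment": "thatcher",
  "observer": "human",
  "value": null,
  "units": "contrast index",
  "provenance": "Human Thatcher index derived from published similarity ratings of normal vs Thatcherized faces (7-point scale converted to dissimilarity = 7 - rating); shown as a dashed figure annotation in the source study, no numeric value printed."
 },
 {
  "experiment": "mirror",
  "observer": "monkey",
  "value": null,
  "units": "contrast index",
  "provenance": "Mirror confusion index estimated from published monkey inferotemporal (IT) firing-rate differences between objects and their horizontal/vertical mirror images; figure annotation only."
 },
 {
  "experiment": "scenes",
  "observer": "human",
  "value": null,
  "units": "naming accuracy",
  "provenance": "Human object-naming accuracy for congruent vs incongruent scenes from two published scene-context studies; reported in those studies, carried here as annotation."
 },
 {
  "experiment": "normalization",
  "observer": "monkey",
  "value": 0.5,
  "units": "slope (pairs)",
  "provenance": "Divisive normalization in high-level visual cortex: multi-object response equals the average of singleton responses, giving slope 0.5 for pairs and 0.33 for triplets."
 },
 {
  "experiment": "sparseness",
  "observer": "monkey",
  "value": null,
  "units": "correlation",
  "provenance": "Correlated selectivity of monkey IT neurons across reference shapes, morphlines, textures and silhouettes, from the prior single-unit study that introduced the stimulus battery; dashed figure annotation only."
 },
 {
  "experiment": "weber",
  "observer": "human",
  "value": null,
  "units": "r_rel - r_abs",
  "provenance": "Human value measured from visual search on the same bar stimuli, distance taken as reciprocal search time; dashed figure annotation only."
 },
 {
  "experiment": "relative_size",
  "observer": "monkey",
  "value": null,
  "units": "contrast index",
  "provenance": "Relative size index estimated from monkey IT neurons on the same tetrad stimuli (about 7% of neurons showed size interactions); dashed figure annotation only."
 },
 {
  "experiment": "surface_invariance",
  "observer": "monkey",
  "value": null,
  "units": "contrast index",
  "provenance": "Surface invariance index estimated from monkey IT neurons on pattern/surface tetrads; dashed figure annotation only."
 },
 {
  "experiment": "depth3d",
  "observer": "human",
  "value": null,
  "units": "contrast index",
  "provenance": "3D processing index computed from reciprocal human visual-search slopes on cuboid/Y-junction displays; dashed figure annotation only."
 },
 {
  "experiment": "occlusion",
  "observer": "human",
  "value": null,
  "units": "contrast index",
  "provenance": "Occlusion index computed from reciprocal human search slopes on occluded/unoccluded square-disk displays; dashed figure annotation only."
 },
 {
  "experiment": "parts",
  "observer": "human",
  "value": null,
  "units": "contrast index / correlation difference",
  "provenance": "Part processing index and natural part advantage computed from reciprocal human search slopes on objects broken at natural vs unnatural cuts; dashed figure annotations only."
 },
 {
  "experiment": "global_local",
  "observer": "human",
  "value": null,
  "units": "contrast index",
  "provenance": "Global advantage index computed from reciprocal human search times on hierarchical stimuli; dashed figure annotation only."
 }
]
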