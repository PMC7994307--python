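"""The twelve experiment procedures against analytic oracles."""

import numpy as np
import pytest

from visprobe import features, indices, stimuli
from visprobe.features import extract, pixel_extractor, surrogate_extractor

from conftest import constant_table


# ---------------------------------------------------------------------------
# Experiment 1: Thatcher


def test_thatcher_index_zero_for_pixels(thatcher_set, pixel):
    table = extract(pixel, thatcher_set)
    prof = indices.thatcher_index(thatcher_set, table)
    assert np.allclose(prof.mean, 0.0, atol=1e-12)
    assert np.all(prof.sem == 0.0)
    assert prof.n[0] == 4


def test_thatcher_index_constructed_distances():
    # one face, vectors placed so d_upright = 2, d_inverted = 1
    s = stimuli.StimulusSet(
        [np.zeros((8, 8), dtype=np.uint8)] * 4,
        [{"face_id": 0, "version": "normal", "orientation": "upright"},
         {"face_id": 0, "version": "thatcher", "orientation": "upright"},
         {"face_id": 0, "version": "normal", "orientation": "inverted"},
         {"face_id": 0, "version": "thatcher", "orientation": "inverted"}])
    table = constant_table([np.array([[0.0], [2.0], [5.0], [6.0]])])
    prof = indices.thatcher_index(s, table)
    assert prof.mean[0] == pytest.approx(1 / 3)


def test_thatcher_refnet_bounded(thatcher_set, refnet):
    table = extract(refnet, thatcher_set)
    prof = indices.thatcher_index(thatcher_set, table)
    ok = np.isfinite(prof.mean)
    assert ok.any()
    assert (np.abs(prof.mean[ok]) <= 1.0 + 1e-12).all()
    assert (prof.n[ok] == 4).all()


def test_thatcher_missing_role_errors(thatcher_set, pixel):
    broken = stimuli.StimulusSet(thatcher_set.images[:-1],
                                 thatcher_set.meta[:-1])
    table = extract(pixel, broken)
    with pytest.raises(KeyError):
        indices.thatcher_index(broken, table)


# ---------------------------------------------------------------------------
# Experiment 2: mirror confusion


def test_mirror_index_sign_for_symmetric_objects(pixel):
    size = 32
    v_sym = np.zeros((size, size), dtype=np.uint8)
    v_sym[4:10, 10:22] = 255  # symmetric about the vertical axis
    v_sym[20:26, 14:18] = 255
    h_sym = v_sym.T.copy()    # symmetric about the horizontal axis
    images, meta = [], []
    for oid, base in ((0, v_sym), (1, h_sym)):
        images += [base, base[:, ::-1].copy(), base[::-1].copy()]
        meta += [{"object_id": oid, "role": r}
                 for r in ("original", "v_mirror", "h_mirror")]
    s = stimuli.StimulusSet(images, meta)
    table = extract(pixel, s)
    mat = table.layer_matrix(0)
    per_layer = indices.mirror_confusion_index(s, table)
    # aggregate mixes +1 and -1; check per-object via constructed tables
    d_v0 = np.linalg.norm(mat[0] - mat[1])
    assert d_v0 == 0.0  # vertical mirror identical -> index +1 for object 0
    d_h1 = np.linalg.norm(mat[3] - mat[5])
    assert d_h1 == 0.0  # horizontal mirror identical -> index -1 for object 1
    assert per_layer.mean[0] == pytest.approx(0.0)


def test_mirror_index_zero_when_distances_equal(mirror_set):
    # constructed activations: all three versions equidistant
    vecs = np.zeros((len(mirror_set), 2))
    for i, m in enumerate(mirror_set.meta):
        if m["role"] == "v_mirror":
            vecs[i] = (m["object_id"], 1.0)
        elif m["role"] == "h_mirror":
            vecs[i] = (m["object_id"], -1.0)
        else:
            vecs[i] = (m["object_id"], 0.0)
    prof = indices.mirror_confusion_index(mirror_set, constant_table([vecs]))
    assert prof.mean[0] == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# Experiment 3: scenes


def test_scene_incongruence_perturbation_direction(scene_set):
    # additive context perturbation, larger for incongruent contexts
    rng = np.random.default_rng(0)
    base = {o: rng.uniform(0, 1, 8) for o in range(5)}
    vecs = []
    for m in scene_set.meta:
        v = base[m["object_id"]].copy()
        if m["role"] == "congruent":
            v += 0.05
        elif m["role"] == "incongruent":
            v += 0.50
        vecs.append(v)
    prof = indices.scene_incongruence_distance(scene_set,
                                               constant_table([np.array(vecs)]))
    assert prof.mean[0] > 0


def test_scene_incongruence_equidistant_is_zero(scene_set):
    vecs = []
    for m in scene_set.meta:
        x = {"isolated": 0.0, "congruent": 1.0, "incongruent": -1.0}[m["role"]]
        vecs.append([m["object_id"] * 10.0, x])
    prof = indices.scene_incongruence_distance(scene_set,
                                               constant_table([np.array(vecs)]))
    assert prof.mean[0] == pytest.approx(0.0)


def test_scene_accuracy_congruence_boost_and_topk_nesting(scene_set):
    sur = surrogate_extractor("context_classifier", {"seed": 1, "boost": 5.0})
    probs = features.predict_class_probabilities(sur, scene_set)
    top1 = indices.scene_incongruence_accuracy(scene_set, probs, k=1)
    top5 = indices.scene_incongruence_accuracy(scene_set, probs, k=5)
    assert top1[0] >= top1[1]          # congruent >= incongruent
    assert top5[0] >= top1[0] and top5[1] >= top1[1]
    with pytest.raises(ValueError):
        indices.scene_incongruence_accuracy(scene_set, probs, k=99)


def test_scene_accuracy_uniform_probs_deterministic_tiebreak(scene_set):
    n_classes = 5
    probs = np.full((len(scene_set), n_classes), 1.0 / n_classes)
    acc = indices.scene_incongruence_accuracy(scene_set, probs, k=1)
    # stable tie-break = class 0 wins; exactly the scenes labelled 0 are hits
    assert acc == (0.2, 0.2)


# ---------------------------------------------------------------------------
# Experiment 4: normalization slopes


def test_normalization_slopes_averager_exact(multiobject_set):
    table = extract(surrogate_extractor("averager", {"seed": 2}),
                    multiobject_set)
    sp = indices.normalization_slopes(multiobject_set, table)
    assert sp.slope_pairs[0] == pytest.approx(0.5, abs=1e-9)
    assert sp.slope_triplets[0] == pytest.approx(1 / 3, abs=1e-9)


def test_normalization_slopes_summer_is_one(multiobject_set):
    table = extract(surrogate_extractor("summer", {"seed": 2}),
                    multiobject_set)
    sp = indices.normalization_slopes(multiobject_set, table)
    assert sp.slope_pairs[0] == pytest.approx(1.0, abs=1e-9)
    assert sp.slope_triplets[0] == pytest.approx(1.0, abs=1e-9)


def test_normalization_nonselective_units_slope_half(multiobject_set):
    # unit-specific constant response to every display: y = c, x = 2c
    rng = np.random.default_rng(3)
    c = rng.uniform(1, 5, 20)
    vecs = np.tile(c, (len(multiobject_set), 1))
    # add tiny per-location variation so units pass the all-locations filter
    for i, m in enumerate(multiobject_set.meta):
        if m["role"] == "singleton":
            (obj, loc), = m["members"]
            vecs[i] = c + 1e-6 * obj * (loc + 1)
    table = constant_table([vecs])
    sp = indices.normalization_slopes(multiobject_set, table)
    assert sp.slope_pairs[0] == pytest.approx(0.5, abs=1e-3)


def test_normalization_no_selected_units_is_undefined(multiobject_set):
    vecs = np.ones((len(multiobject_set), 4))
    sp = indices.normalization_slopes(multiobject_set, constant_table([vecs]))
    assert not sp.defined(0)
    assert np.isnan(sp.slope_pairs[0])


# ---------------------------------------------------------------------------
# Experiment 5: correlated sparseness


def test_correlated_sparseness_shared_tuning_gives_unit_correlation(shape_set):
    # per-unit threshold governs responses on every subset identically:
    # sparseness patterns then agree across subsets -> r = 1
    rng = np.random.default_rng(4)
    n_units = 40
    thresholds = rng.uniform(0.1, 0.9, n_units)
    drive = rng.uniform(0, 1, len(shape_set))
    vecs = (drive[:, None] > thresholds[None, :]).astype(float)
    vecs += rng.uniform(0, 1e-9, vecs.shape)  # break exact zero variance
    sp = indices.correlated_sparseness(shape_set, constant_table([vecs]))
    assert sp.r_texture_shape[0] > 0.95


def test_correlated_sparseness_independent_tuning_near_zero(shape_set):
    rng = np.random.default_rng(5)
    vecs = rng.uniform(0, 1, (len(shape_set), 1000))
    sp = indices.correlated_sparseness(shape_set, constant_table([vecs]))
    assert abs(sp.r_texture_shape[0]) < 0.1
    assert sp.n_units_texture_shape[0] == 1000


def test_correlated_sparseness_excludes_single_set_units(shape_set):
    rng = np.random.default_rng(6)
    vecs = rng.uniform(0, 1, (len(shape_set), 10))
    tex = shape_set.indices(subset="texture")
    vecs[tex, 0] = 0.5  # unit 0 constant on textures -> inactive there
    sp = indices.correlated_sparseness(shape_set, constant_table([vecs]))
    assert sp.n_units_texture_shape[0] == 9


# ---------------------------------------------------------------------------
# Experiment 6: Weber


def test_weber_surrogate_signs(bar_set):
    t_lin = extract(surrogate_extractor("length_linear", {"seed": 7}), bar_set)
    assert indices.weber_index(bar_set, t_lin).difference[0] < 0
    t_log = extract(surrogate_extractor("length_log", {"seed": 7}), bar_set)
    assert indices.weber_index(bar_set, t_log).difference[0] > 0


def test_weber_pixel_bars_absolute_coding(bar_set, pixel):
    table = extract(pixel, bar_set)
    w = indices.weber_index(bar_set, table)
    assert w.difference[0] < 0


# ---------------------------------------------------------------------------
# Experiments 7-8: tetrads


def test_relative_size_ratio_coder_gives_plus_one(size_tetrads):
    table = extract(surrogate_extractor("size_ratio", {"seed": 8}),
                    size_tetrads)
    prof = indices.relative_size_index(size_tetrads, table)
    assert prof.mean[0] == pytest.approx(1.0)


def test_relative_size_total_size_coder_gives_minus_one(size_tetrads):
    # symmetric nonlinear coder of total size: r12 = r21 (d1 = 0) but
    # r11 != r22, so the entry survives interaction selection with index -1.
    # (A *linear* sum coder has zero interaction and is excluded by design.)
    vecs = np.array([[float(m["s1"] + m["s2"]) ** 2]
                     for m in size_tetrads.meta])
    prof = indices.relative_size_index(size_tetrads, constant_table([vecs]))
    assert prof.mean[0] == pytest.approx(-1.0)


def test_tetrad_selection_keeps_ceil_fraction(size_tetrads):
    rng = np.random.default_rng(9)
    n_units = 11
    vecs = rng.uniform(0, 1, (len(size_tetrads), n_units))
    prof = indices.relative_size_index(size_tetrads, constant_table([vecs]),
                                       top_fraction=0.07)
    n_entries = n_units * 6  # 6 tetrads
    expected = int(np.ceil(0.07 * n_entries))
    assert prof.n[0] + prof.excluded[0] == expected


def test_tetrad_label_swap_antisymmetry(size_tetrads):
    rng = np.random.default_rng(10)
    vecs = rng.uniform(0, 1, (len(size_tetrads), 5))
    prof = indices.relative_size_index(size_tetrads, constant_table([vecs]))
    # swapping congruent/incongruent roles = relabel s2 -> 3 - s2
    swapped_meta = [dict(m, s2=3 - m["s2"]) for m in size_tetrads.meta]
    swapped = stimuli.StimulusSet(size_tetrads.images, swapped_meta)
    prof_sw = indices.relative_size_index(swapped, constant_table([vecs]))
    assert prof_sw.mean[0] == pytest.approx(-prof.mean[0])


def test_surface_invariance_relative_coder_plus_one(surface_tetrads):
    # nonlinear coder of pattern-relative-to-surface level: congruent cells
    # (1,1)/(2,2) respond identically -> d2 = 0 -> index +1
    vecs_rel = np.array([[np.exp(m["pattern_level"] - m["surface_level"])]
                         for m in surface_tetrads.meta])
    prof = indices.surface_invariance_index(surface_tetrads,
                                            constant_table([vecs_rel]))
    assert prof.mean[0] == pytest.approx(1.0)
    assert np.all(np.abs(prof.mean[np.isfinite(prof.mean)]) <= 1.0)


def test_surface_invariance_retinal_coder_has_no_interaction(surface_tetrads):
    # a unit coding the retinal pattern level only: r11 = r12 and r21 = r22,
    # so d1 = d2 (index 0 cellwise) and the interaction is exactly zero ->
    # no entry survives selection and the layer is flagged undefined
    vecs_ret = np.array([[float(m["pattern_level"]) ** 2]
                         for m in surface_tetrads.meta])
    prof = indices.surface_invariance_index(surface_tetrads,
                                            constant_table([vecs_ret]))
    assert not prof.defined(0)


def test_tetrad_all_zero_interactions_undefined(size_tetrads):
    vecs = np.array([[float(m["s1"])] for m in size_tetrads.meta])
    # response depends only on s1: r11=r12, r21=r22 -> interaction 0
    prof = indices.relative_size_index(size_tetrads, constant_table([vecs]))
    assert not prof.defined(0)


# ---------------------------------------------------------------------------
# Experiment 9: 3D processing


def test_depth3d_constructed_distances(threed_set):
    vecs = np.zeros((len(threed_set), 1))
    for i, m in enumerate(threed_set.meta):
        if m["pair"] == "threed":
            vecs[i, 0] = {"a": 0.0, "b": 2.0}[m["version"]]
        elif m["pair"] == "control1":
            vecs[i, 0] = {"a": 5.0, "b": 7.0}[m["version"]]  # d = 2 -> index 0
        else:
            vecs[i, 0] = 9.0  # identical controls -> d2 = 0 -> index +1
    out = indices.depth3d_index(threed_set, constant_table([vecs]))
    assert out["control1"].mean[0] == pytest.approx(0.0)
    assert out["control2"].mean[0] == pytest.approx(1.0)


def test_depth3d_pixel_in_bounds(threed_set, pixel):
    out = indices.depth3d_index(threed_set, extract(pixel, threed_set))
    for prof in out.values():
        assert np.all(np.abs(prof.mean) <= 1.0)
        assert prof.n[0] == 3


# ---------------------------------------------------------------------------
# Experiment 10: occlusion


def test_occlusion_constructed_distances(occlusion_set):
    vecs = np.zeros((len(occlusion_set), 1))
    for i, m in enumerate(occlusion_set.meta):
        key = (m["effect"], m["role"])
        vecs[i, 0] = {
            ("occlusion", "unoccluded"): 0.0,
            ("occlusion", "occluded"): 0.0,    # d1 = 0
            ("occlusion", "control"): 3.0,     # d2 = 3 -> index +1
            ("depth_order", "square_front"): 0.0,
            ("depth_order", "disk_front"): 2.0,   # d1 = 2
            ("depth_order", "control_a"): 5.0,
            ("depth_order", "control_b"): 7.0,    # d2 = 2 -> index 0
        }[key]
    out = indices.occlusion_index(occlusion_set, constant_table([vecs]))
    assert out["occlusion"].mean[0] == pytest.approx(1.0)
    assert out["depth_order"].mean[0] == pytest.approx(0.0)


def test_occlusion_pixel_strictly_below_one(occlusion_set, pixel):
    out = indices.occlusion_index(occlusion_set, extract(pixel, occlusion_set))
    assert out["occlusion"].mean[0] < 1.0  # d1 > 0: displays differ


# ---------------------------------------------------------------------------
# Experiment 11: parts


def test_part_break_constructed_and_antisymmetry(part_set):
    rng = np.random.default_rng(11)
    vecs = rng.uniform(0, 1, (len(part_set), 6))
    table = constant_table([vecs])
    prof = indices.part_break_index(part_set, table)
    swapped_meta = []
    for m in part_set.meta:
        m = dict(m)
        if m.get("role") == "natural_break":
            m["role"] = "unnatural_break"
        elif m.get("role") == "unnatural_break":
            m["role"] = "natural_break"
        swapped_meta.append(m)
    swapped = stimuli.StimulusSet(part_set.images, swapped_meta)
    prof_sw = indices.part_break_index(swapped, table)
    assert prof_sw.mean[0] == pytest.approx(-prof.mean[0])
    assert prof.n[0] == 7


def test_part_break_zero_when_equidistant(part_set):
    vecs = np.zeros((len(part_set), 2))
    for i, m in enumerate(part_set.meta):
        if m["role"] == "natural_break":
            vecs[i] = (m["object_id"], 1.0)
        elif m["role"] == "unnatural_break":
            vecs[i] = (m["object_id"], -1.0)
        elif m["role"] == "whole":
            vecs[i] = (m["object_id"], 0.0)
        else:
            vecs[i] = (100 + i, 0.0)
    prof = indices.part_break_index(part_set, constant_table([vecs]))
    assert prof.mean[0] == pytest.approx(0.0)


def test_natural_part_advantage_generative(part_set):
    gen = surrogate_extractor("partsum_generative", {"seed": 12, "n_parts": 7})
    adv = indices.natural_part_advantage(part_set, gen)
    assert adv.r_natural[0] == pytest.approx(1.0, abs=1e-9)
    assert adv.advantage[0] > 0


def test_natural_part_advantage_pure_noise_mean_zero(part_set):
    class NoiseDistances:
        def __init__(self, seed):
            self.rng = np.random.default_rng(seed)

        def distance_matrix(self, stimuli_, idx):
            n = len(idx)
            m = self.rng.uniform(0.5, 1.5, (n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0.0)
            return m

    advs = [indices.natural_part_advantage(part_set, NoiseDistances(k)
                                           ).advantage[0]
            for k in range(100)]
    assert abs(float(np.mean(advs))) < 0.05


def test_natural_part_advantage_subsampling(part_set):
    gen = surrogate_extractor("partsum_generative", {"seed": 12, "n_parts": 7})
    adv = indices.natural_part_advantage(part_set, gen, n_pair_sample=492)
    assert adv.r_natural[0] == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# Experiment 12: global advantage


def test_global_advantage_extremes(hierarchical_set):
    t_g = extract(surrogate_extractor("global_only", {"seed": 13}),
                  hierarchical_set)
    p = indices.global_advantage_index(hierarchical_set, t_g, n_boot=20)
    assert p.mean[0] == pytest.approx(1.0)
    t_l = extract(surrogate_extractor("local_only", {"seed": 13}),
                  hierarchical_set)
    p = indices.global_advantage_index(hierarchical_set, t_l, n_boot=20)
    assert p.mean[0] == pytest.approx(-1.0)


def test_hierarchical_pair_counts(hierarchical_set):
    g_pairs, l_pairs = indices.hierarchical_pairs(hierarchical_set)
    assert len(g_pairs) == 147
    assert len(l_pairs) == 147


def test_global_advantage_incomplete_grid_errors(hierarchical_set):
    broken = stimuli.StimulusSet(hierarchical_set.images[:-1],
                                 hierarchical_set.meta[:-1])
    vecs = np.zeros((len(broken), 2))
    with pytest.raises(ValueError):
        indices.global_advantage_index(broken, constant_table([vecs]))
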