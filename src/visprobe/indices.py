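"""The twelve experiment procedures.

Each procedure maps a stimulus set plus an activation table to a per-layer
result — usually an :class:`~visprobe.metrics.IndexProfile` of a contrast
index (d_a − d_b)/(d_a + d_b), occasionally a specialised container
(normalization slopes, Weber correlations, sparseness correlations,
part-sum advantages).  Positive values indicate the perception-like
direction of each effect.

1.  :func:`thatcher_index` — upright vs inverted sensitivity to local face
    inversion.
2.  :func:`mirror_confusion_index` — horizontal vs vertical mirror distance.
3.  :func:`scene_incongruence_distance` / :func:`scene_incongruence_accuracy`
    — object-context congruence effects.
4.  :func:`normalization_slopes` — multi-object response vs summed singleton
    responses (slope 0.5 for pairs, 1/3 for triplets = divisive
    normalization).
5.  :func:`correlated_sparseness` — unit selectivity correlated across
    stimulus subsets.
6.  :func:`weber_index` — distances track relative, not absolute, length.
7.  :func:`relative_size_index` — interaction-selected two-part tetrads.
8.  :func:`surface_invariance_index` — pattern/surface tetrads.
9.  :func:`depth3d_index` — 3D shape pairs vs matched 2D controls.
10. :func:`occlusion_index` — occlusion and depth-order displays.
11. :func:`part_break_index` / :func:`natural_part_advantage` — natural vs
    unnatural part cuts and the part-sum model comparison.
12. :func:`global_advantage_index` — global vs local shape changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import partsum
from .features import ActivationTable, LayerSpec
from .metrics import (ContrastPair, IndexProfile, WeberResult,
                      aggregate_profile, contrast_index, distance, fit_slope,
                      pairwise_distances, select_visually_active,
                      weber_correlations)
from .stimuli import StimulusSet

__all__ = [
    "SlopeProfile",
    "SparsenessProfile",
    "PartAdvantageResult",
    "TetradResponses",
    "thatcher_index",
    "mirror_confusion_index",
    "scene_incongruence_distance",
    "scene_incongruence_accuracy",
    "normalization_slopes",
    "correlated_sparseness",
    "weber_index",
    "relative_size_index",
    "surface_invariance_index",
    "depth3d_index",
    "occlusion_index",
    "part_break_index",
    "natural_part_advantage",
    "global_advantage_index",
    "hierarchical_pairs",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass
class SlopeProfile:
    """Per-layer normalization slopes for pair and triplet displays."""

    layers: list[LayerSpec]
    slope_pairs: np.ndarray
    slope_triplets: np.ndarray
    n_points_pairs: np.ndarray
    n_points_triplets: np.ndarray
    n_units: np.ndarray

    def defined(self, k: int) -> bool:
        return bool(self.n_units[k] > 0)


@dataclass
class SparsenessProfile:
    """Per-layer sparseness correlations across units."""

    layers: list[LayerSpec]
    r_reference_morph: np.ndarray
    r_texture_shape: np.ndarray
    n_units_reference_morph: np.ndarray
    n_units_texture_shape: np.ndarray


@dataclass
class PartAdvantageResult:
    """Per-layer part-sum model correlations under the two decompositions."""

    layers: list[LayerSpec]
    r_natural: np.ndarray
    r_unnatural: np.ndarray

    @property
    def advantage(self) -> np.ndarray:
        return self.r_natural - self.r_unnatural


@dataclass(frozen=True)
class TetradResponses:
    """One unit's responses at the four cells of one tetrad."""

    unit: int
    tetrad: object
    r11: float
    r12: float
    r21: float
    r22: float

    @property
    def interaction(self) -> float:
        return abs(self.r11 + self.r22 - self.r12 - self.r21)


# ---------------------------------------------------------------------------
# helpers


def _per_item_profile(stimuli: StimulusSet, table: ActivationTable,
                      pair_rows, metric: str, name: str) -> IndexProfile:
    """Aggregate contrast indices for items given (item_id, row_a0, row_a1,
    row_b0, row_b1) tuples: d_a = d(a0, a1), d_b = d(b0, b1)."""
    per_layer = []
    for mat in table.activations:
        vals = []
        for item, a0, a1, b0, b1 in pair_rows:
            d_a = distance(mat[a0], mat[a1], metric)
            d_b = distance(mat[b0], mat[b1], metric)
            vals.append(contrast_index(ContrastPair(d_a, d_b, item)))
        per_layer.append(np.asarray(vals))
    return aggregate_profile(per_layer, table.layers, name=name)


# ---------------------------------------------------------------------------
# Experiment 1


def thatcher_index(stimuli: StimulusSet, table: ActivationTable,
                   metric: str = "euclidean") -> IndexProfile:
    """(d_upright − d_inverted)/(d_upright + d_inverted) per face and layer.

    d_upright is the normal-vs-thatcherized distance with both faces
    upright, d_inverted the same with both faces rotated 180°.  For a pixel
    representation the two distances are equal (inversion permutes pixels
    identically in both images), so the index is exactly zero.
    """
    face_ids = sorted({m["face_id"] for m in stimuli.meta})
    rows = []
    for f in face_ids:
        rows.append((
            f,
            stimuli.index(face_id=f, version="normal", orientation="upright"),
            stimuli.index(face_id=f, version="thatcher", orientation="upright"),
            stimuli.index(face_id=f, version="normal", orientation="inverted"),
            stimuli.index(face_id=f, version="thatcher", orientation="inverted"),
        ))
    return _per_item_profile(stimuli, table, rows, metric, "thatcher")


# ---------------------------------------------------------------------------
# Experiment 2


def mirror_confusion_index(stimuli: StimulusSet, table: ActivationTable,
                           metric: str = "euclidean") -> IndexProfile:
    """(d_horizontal − d_vertical)/(d_horizontal + d_vertical) per object.

    Positive when vertical (left-right) mirror pairs are closer than
    horizontal (up-down) mirror pairs, the direction seen in perception and
    high-level visual cortex.
    """
    object_ids = sorted({m["object_id"] for m in stimuli.meta})
    rows = []
    for o in object_ids:
        orig = stimuli.index(object_id=o, role="original")
        rows.append((o, orig, stimuli.index(object_id=o, role="h_mirror"),
                     orig, stimuli.index(object_id=o, role="v_mirror")))
    return _per_item_profile(stimuli, table, rows, metric, "mirror_confusion")


# ---------------------------------------------------------------------------
# Experiment 3


def scene_incongruence_distance(stimuli: StimulusSet, table: ActivationTable,
                                metric: str = "euclidean") -> IndexProfile:
    """Distance of each scene to the object's average feature vector.

    For each object the average feature vector is the mean over all of that
    object's images in the set (isolated object plus its scenes) — averaging
    only the two scenes would put the average at their midpoint and force
    the index to zero identically.  The per-object index contrasts the
    incongruent scene's distance to that average against the congruent
    scene's; a positive mean indicates an incongruence effect.
    """
    object_ids = sorted({m["object_id"] for m in stimuli.meta})
    cong, incong, members = {}, {}, {}
    for o in object_ids:
        cong[o] = stimuli.index(object_id=o, role="congruent")
        incong[o] = stimuli.index(object_id=o, role="incongruent")
        members[o] = stimuli.indices(object_id=o)
        n_scenes = len(stimuli.indices(object_id=o, role="congruent")) + \
            len(stimuli.indices(object_id=o, role="incongruent"))
        if n_scenes < 2:
            raise ValueError(f"object {o} has fewer than 2 scenes")
    per_layer = []
    for mat in table.activations:
        vals = []
        for o in object_ids:
            avg = mat[np.asarray(members[o])].mean(axis=0)
            d_i = distance(mat[incong[o]], avg, metric)
            d_c = distance(mat[cong[o]], avg, metric)
            vals.append(contrast_index(ContrastPair(d_i, d_c, o)))
        per_layer.append(np.asarray(vals))
    return aggregate_profile(per_layer, table.layers, name="scene_incongruence")


def scene_incongruence_accuracy(stimuli: StimulusSet, probs: np.ndarray,
                                k: int = 1) -> tuple[float, float]:
    """Top-k classification accuracy on (congruent, incongruent) scenes.

    Ties in probability are broken deterministically by ascending class
    index (stable sort on descending probability).
    """
    probs = np.asarray(probs)
    if probs.shape[0] != len(stimuli):
        raise ValueError("one probability row required per stimulus")
    if k > probs.shape[1]:
        raise ValueError(f"k={k} exceeds class count {probs.shape[1]}")
    hits = {"congruent": [], "incongruent": []}
    for row, m in zip(probs, stimuli.meta):
        role = m.get("role")
        if role not in hits:
            continue
        topk = np.argsort(-row, kind="stable")[:k]
        hits[role].append(int(m["label"]) in topk)
    out = []
    for role in ("congruent", "incongruent"):
        if not hits[role]:
            raise ValueError(f"no {role} scenes in the stimulus set")
        out.append(float(np.mean(hits[role])))
    return tuple(out)


# ---------------------------------------------------------------------------
# Experiment 4


def normalization_slopes(stimuli: StimulusSet, table: ActivationTable,
                         n_units_sample: int | None = None,
                         seed: int = 0) -> SlopeProfile:
    """OLS slope of multi-object responses vs summed singleton responses.

    Units are kept only if they respond differently to at least one image
    within **each** of the three singleton locations.  For every kept unit
    and multi-object display, x = sum of the unit's responses to the
    constituent singletons, y = its response to the display; points are
    pooled over units and displays and a free-intercept slope is fit for
    pairs and triplets separately.  An averaging response law gives slopes
    1/2 and 1/3; a summing law gives 1.
    """
    singleton_row = {}
    loc_subsets = {0: [], 1: [], 2: []}
    pair_rows, triplet_rows = [], []
    for i, m in enumerate(stimuli.meta):
        role = m.get("role")
        if role == "singleton":
            (obj, loc), = m["members"]
            singleton_row[(obj, loc)] = i
            loc_subsets[loc].append(i)
        elif role == "pair":
            pair_rows.append(i)
        elif role == "triplet":
            triplet_rows.append(i)
    if not singleton_row:
        raise ValueError("no singleton displays in the stimulus set")
    subsets = [np.asarray(loc_subsets[l]) for l in (0, 1, 2)]

    n_layers = len(table.layers)
    slopes_p = np.full(n_layers, np.nan)
    slopes_t = np.full(n_layers, np.nan)
    npts_p = np.zeros(n_layers, dtype=int)
    npts_t = np.zeros(n_layers, dtype=int)
    n_units = np.zeros(n_layers, dtype=int)
    rng = np.random.default_rng(seed)
    for kl, mat in enumerate(table.activations):
        keep = select_visually_active(mat, subsets=subsets)
        units = np.flatnonzero(keep)
        if units.size == 0:
            continue
        if n_units_sample is not None and units.size > n_units_sample:
            units = np.sort(rng.choice(units, n_units_sample, replace=False))
        n_units[kl] = units.size
        for rows, which in ((pair_rows, "p"), (triplet_rows, "t")):
            if not rows:
                continue
            xs, ys = [], []
            for r in rows:
                members = stimuli.meta[r]["members"]
                srows = [singleton_row[m] for m in members]
                xs.append(mat[np.asarray(srows)][:, units].sum(axis=0))
                ys.append(mat[r, units])
            x = np.concatenate(xs)
            y = np.concatenate(ys)
            pts = np.column_stack([x, y])
            if np.var(x) == 0:
                continue
            s = fit_slope(pts)
            if which == "p":
                slopes_p[kl], npts_p[kl] = s, len(x)
            else:
                slopes_t[kl], npts_t[kl] = s, len(x)
    return SlopeProfile(table.layers, slopes_p, slopes_t, npts_p, npts_t,
                        n_units)


# ---------------------------------------------------------------------------
# Experiment 5


def correlated_sparseness(stimuli: StimulusSet,
                          table: ActivationTable) -> SparsenessProfile:
    """Correlate unit sparseness across stimulus subsets, per layer.

    Reports the Pearson correlation across units between sparseness on the
    reference shapes and mean sparseness over the morphlines, and between
    sparseness on textures and on silhouette shapes.  A unit enters a
    correlation only if visually active (non-zero response variance) on
    both subsets involved; responses are min-max normalized per unit before
    the sparseness computation.  Layers with fewer than three eligible
    units are left undefined.
    """
    ref_rows = np.asarray(stimuli.indices(subset="reference"))
    tex_rows = np.asarray(stimuli.indices(subset="texture"))
    shape_rows = np.asarray(stimuli.indices(subset="shape"))
    lines = sorted({m["line"] for m in stimuli.meta if m.get("subset") == "morph"})
    morph_rows = {li: np.asarray(stimuli.indices(subset="morph", line=li))
                  for li in lines}
    all_morph = np.concatenate([morph_rows[li] for li in lines])
    if not (len(ref_rows) and len(tex_rows) and len(shape_rows) and lines):
        raise ValueError("shape-set roles missing from the stimulus set")

    n_layers = len(table.layers)
    r_rm = np.full(n_layers, np.nan)
    r_ts = np.full(n_layers, np.nan)
    n_rm = np.zeros(n_layers, dtype=int)
    n_ts = np.zeros(n_layers, dtype=int)
    for kl, mat in enumerate(table.activations):
        for pair_id in ("rm", "ts"):
            if pair_id == "rm":
                sub_a, sub_b = ref_rows, all_morph
            else:
                sub_a, sub_b = tex_rows, shape_rows
            active = select_visually_active(mat, subsets=[sub_a, sub_b])
            units = np.flatnonzero(active)
            if units.size < 3:
                continue
            rows_ab = np.concatenate([sub_a, sub_b])
            sub = mat[rows_ab][:, units].astype(np.float64)
            lo, hi = sub.min(axis=0), sub.max(axis=0)
            sub = (sub - lo) / (hi - lo)  # active units: hi > lo
            na = len(sub_a)
            sa = _sparseness_columns(sub[:na])
            if pair_id == "rm":
                vals, off = [], na
                for li in lines:
                    nli = len(morph_rows[li])
                    vals.append(_sparseness_columns(sub[off:off + nli]))
                    off += nli
                with np.errstate(invalid="ignore"):
                    sb = np.nanmean(np.stack(vals), axis=0)
            else:
                sb = _sparseness_columns(sub[na:])
            ok = np.isfinite(sa) & np.isfinite(sb)
            if ok.sum() < 3 or sa[ok].std() == 0 or sb[ok].std() == 0:
                continue
            r = float(np.corrcoef(sa[ok], sb[ok])[0, 1])
            if pair_id == "rm":
                r_rm[kl], n_rm[kl] = r, int(ok.sum())
            else:
                r_ts[kl], n_ts[kl] = r, int(ok.sum())
    return SparsenessProfile(table.layers, r_rm, r_ts, n_rm, n_ts)


def _sparseness_columns(resp: np.ndarray) -> np.ndarray:
    """Column-wise sparseness of a nonnegative (n_stimuli, n_units) block;
    nan for all-zero columns.  Matches :func:`visprobe.metrics.sparseness`."""
    n = resp.shape[0]
    mean_sq = (resp.sum(axis=0) / n) ** 2
    sum_sq = (resp ** 2).sum(axis=0) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        s = (1.0 - mean_sq / sum_sq) / (1.0 - 1.0 / n)
    s[sum_sq == 0] = np.nan
    return s


# ---------------------------------------------------------------------------
# Experiment 6


def weber_index(stimuli: StimulusSet, table: ActivationTable,
                metric: str = "euclidean") -> WeberResult:
    """Per-layer r_rel − r_abs for bar-length stimuli (positive = Weber)."""
    lengths = np.asarray([m["length"] for m in stimuli.meta], dtype=float)
    mats = np.stack([pairwise_distances(mat, metric)
                     for mat in table.activations])
    return weber_correlations(lengths, mats, table.layers)


# ---------------------------------------------------------------------------
# Experiments 7 and 8 (tetrads)


def _tetrad_contrast(stimuli: StimulusSet, table: ActivationTable,
                     group_tags: list[str], level_tags: tuple[str, str],
                     top_fraction: float, normalize: bool,
                     name: str) -> IndexProfile:
    """Shared interaction-selected tetrad index.

    For every (unit, tetrad) entry the interaction |r11 + r22 − r12 − r21|
    is computed; the top ``ceil(top_fraction · N)`` entries per layer are
    kept (stable tie-break in unit-major, tetrad-minor order) and scored
    with d1 = |r12 − r21| (incongruent cells), d2 = |r11 − r22| (congruent
    cells), index (d1 − d2)/(d1 + d2).
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    t1, t2 = level_tags
    groups = sorted({tuple(m[t] for t in group_tags) for m in stimuli.meta})
    cell_rows = []
    for gr in groups:
        tags = dict(zip(group_tags, gr))
        cell_rows.append([
            stimuli.index(**tags, **{t1: 1, t2: 1}),
            stimuli.index(**tags, **{t1: 1, t2: 2}),
            stimuli.index(**tags, **{t1: 2, t2: 1}),
            stimuli.index(**tags, **{t1: 2, t2: 2}),
        ])
    cell_rows = np.asarray(cell_rows)  # (n_tetrads, 4)

    n_layers = len(table.layers)
    means = np.full(n_layers, np.nan)
    sems = np.zeros(n_layers)
    ns = np.zeros(n_layers, dtype=int)
    excl = np.zeros(n_layers, dtype=int)
    for kl, mat in enumerate(table.activations):
        keep = select_visually_active(mat)
        units = np.flatnonzero(keep)
        if units.size == 0:
            continue
        sub = mat[:, units].astype(np.float64)
        if normalize:
            lo = sub.min(axis=0)
            hi = sub.max(axis=0)
            sub = (sub - lo) / (hi - lo)
        # responses at the four cells: (n_units, n_tetrads)
        r11 = sub[cell_rows[:, 0]].T
        r12 = sub[cell_rows[:, 1]].T
        r21 = sub[cell_rows[:, 2]].T
        r22 = sub[cell_rows[:, 3]].T
        interaction = np.abs(r11 + r22 - r12 - r21).ravel()  # unit-major
        if not np.any(interaction > 0):
            excl[kl] = interaction.size
            continue
        n_keep = math.ceil(top_fraction * interaction.size)
        order = np.argsort(-interaction, kind="stable")[:n_keep]
        d1 = np.abs(r12 - r21).ravel()[order]
        d2 = np.abs(r11 - r22).ravel()[order]
        total = d1 + d2
        defined = total > 0
        idx = np.where(defined, (d1 - d2) / np.where(total > 0, total, 1.0),
                       np.nan)
        ns[kl] = int(defined.sum())
        excl[kl] = int((~defined).sum())
        if ns[kl]:
            v = idx[defined]
            means[kl] = v.mean()
            sems[kl] = v.std(ddof=1) / np.sqrt(ns[kl]) if ns[kl] > 1 else 0.0
    return IndexProfile(table.layers, means, sems, ns, excl, name=name)


def relative_size_index(stimuli: StimulusSet, table: ActivationTable,
                        top_fraction: float = 0.07) -> IndexProfile:
    """Relative-size index on two-part size tetrads (top 7% interactions).

    Congruent cells (1,1)/(2,2) keep the part-size ratio; incongruent cells
    (1,2)/(2,1) change it.  A unit coding only the size ratio has r11 = r22
    so d2 = 0 and index +1; a unit summing the two sizes has d1 = 0 and
    index −1.
    """
    return _tetrad_contrast(stimuli, table, ["tetrad_id"], ("s1", "s2"),
                            top_fraction, normalize=False,
                            name="relative_size")


def surface_invariance_index(stimuli: StimulusSet, table: ActivationTable,
                             top_fraction: float = 0.09) -> IndexProfile:
    """Surface-invariance index on pattern×surface tetrads (top 9%).

    Responses are min-max normalized per unit before the interaction and
    index computation.  Units coding the pattern relative to the surface
    respond equally in the congruent cells, driving the index to +1.
    """
    return _tetrad_contrast(stimuli, table, ["pattern_id", "surface_id"],
                            ("pattern_level", "surface_level"),
                            top_fraction, normalize=True,
                            name="surface_invariance")


# ---------------------------------------------------------------------------
# Experiment 9


def depth3d_index(stimuli: StimulusSet, table: ActivationTable,
                  metric: str = "euclidean") -> dict[str, IndexProfile]:
    """3D-processing index against each of the two matched 2D controls.

    Per shape family, d1 is the distance between the two members of the 3D
    pair and d2 the distance between the members of a control pair carrying
    the same stroke difference; the index is (d1 − d2)/(d1 + d2), reported
    separately for control condition 1 and 2.
    """
    families = sorted({m["family"] for m in stimuli.meta})
    out = {}
    for cond in ("control1", "control2"):
        rows = []
        for fam in families:
            rows.append((
                fam,
                stimuli.index(family=fam, pair="threed", version="a"),
                stimuli.index(family=fam, pair="threed", version="b"),
                stimuli.index(family=fam, pair=cond, version="a"),
                stimuli.index(family=fam, pair=cond, version="b"),
            ))
        out[cond] = _per_item_profile(stimuli, table, rows, metric,
                                      f"depth3d_{cond}")
    return out


# ---------------------------------------------------------------------------
# Experiment 10


def occlusion_index(stimuli: StimulusSet, table: ActivationTable,
                    metric: str = "euclidean") -> dict[str, IndexProfile]:
    """Occlusion and depth-ordering indices (d2 − d1)/(d2 + d1).

    d1 is the distance between the displays differing only in occlusion
    status (or in depth order) and d2 the distance for the matched 2D
    feature control.  Positive = occlusion is discounted, as in perception.
    """
    occ = ("occlusion",
           stimuli.index(effect="occlusion", role="control"),
           stimuli.index(effect="occlusion", role="unoccluded"),
           stimuli.index(effect="occlusion", role="occluded"),
           stimuli.index(effect="occlusion", role="unoccluded"))
    dep = ("depth_order",
           stimuli.index(effect="depth_order", role="control_a"),
           stimuli.index(effect="depth_order", role="control_b"),
           stimuli.index(effect="depth_order", role="square_front"),
           stimuli.index(effect="depth_order", role="disk_front"))
    return {
        "occlusion": _per_item_profile(stimuli, table, [occ], metric,
                                       "occlusion"),
        "depth_order": _per_item_profile(stimuli, table, [dep], metric,
                                         "depth_order"),
    }


# ---------------------------------------------------------------------------
# Experiment 11A


def part_break_index(stimuli: StimulusSet, table: ActivationTable,
                     metric: str = "euclidean") -> IndexProfile:
    """(d_u − d_n)/(d_u + d_n): unnatural vs natural break distance.

    d_n and d_u are the distances from the intact object to its
    natural-break and unnatural-break versions; positive = natural parts
    are privileged, as in perception.
    """
    object_ids = sorted({m["object_id"] for m in stimuli.meta
                         if m.get("role") == "whole"})
    rows = []
    for o in object_ids:
        whole = stimuli.index(role="whole", object_id=o)
        rows.append((o, whole,
                     stimuli.index(role="unnatural_break", object_id=o),
                     whole,
                     stimuli.index(role="natural_break", object_id=o)))
    return _per_item_profile(stimuli, table, rows, metric, "part_break")


# ---------------------------------------------------------------------------
# Experiment 11B


def natural_part_advantage(stimuli: StimulusSet, table,
                           metric: str = "euclidean",
                           n_pair_sample: int | None = None,
                           seed: int = 0) -> PartAdvantageResult:
    """Part-sum model fit under natural vs unnatural part decompositions.

    Fits the part-sum model to all pairwise distances within each 49-object
    composite set (or to a seeded random subsample of ``n_pair_sample``
    equations that always retains the common pairs), evaluates each fit on
    the 21 pairwise distances between the 7 common objects, and reports
    r_natural − r_unnatural per layer.  ``table`` may be an
    :class:`ActivationTable` or any object exposing
    ``distance_matrix(stimuli, indices)`` (e.g. the part-sum generative
    surrogate).
    """
    sets = {}
    for s in ("natural", "unnatural"):
        idx = stimuli.indices(role="composite", set=s)
        if not idx:
            raise ValueError(f"no {s}-part composite objects in the set")
        objects = [(stimuli.meta[i]["left_part"], stimuli.meta[i]["right_part"])
                   for i in idx]
        design = partsum.build_design(objects, 1 + max(max(o) for o in objects))
        common = [k for k, (a, b) in enumerate(design.pairs)
                  if objects[a][0] == objects[a][1]
                  and objects[b][0] == objects[b][1]]
        sets[s] = (idx, design, common)

    if hasattr(table, "distance_matrix"):
        layers = [LayerSpec(0, "generative", "fc")]
        dist_mats = {s: [table.distance_matrix(stimuli, sets[s][0])]
                     for s in sets}
    else:
        layers = table.layers
        dist_mats = {}
        for s, (idx, _, _) in sets.items():
            dist_mats[s] = [pairwise_distances(mat[np.asarray(idx)], metric)
                            for mat in table.activations]

    r = {s: np.full(len(layers), np.nan) for s in sets}
    for s, (idx, design, common) in sets.items():
        if n_pair_sample is not None and n_pair_sample < len(design.pairs):
            rng = np.random.default_rng([seed, 11])
            others = np.setdiff1d(np.arange(len(design.pairs)), common)
            extra = max(0, n_pair_sample - len(common))
            rows = np.sort(np.concatenate(
                [common, rng.choice(others, extra, replace=False)]))
            design = partsum.PartSumDesign(
                design.matrix[rows], [design.pairs[k] for k in rows],
                design.objects, design.part_count, design.columns)
            common = [int(np.searchsorted(rows, c)) for c in common]
            sets[s] = (idx, design, common)
        for kl, dm in enumerate(dist_mats[s]):
            d = np.asarray([dm[a, b] for a, b in design.pairs])
            f = partsum.fit(design, d)
            r[s][kl] = partsum.evaluate(f, common)
    return PartAdvantageResult(list(layers), r["natural"], r["unnatural"])


# ---------------------------------------------------------------------------
# Experiment 12


def hierarchical_pairs(stimuli: StimulusSet) -> tuple[list, list]:
    """(global-change, local-change) image pairs from the g×l grid.

    Global-change pairs share the local shape and differ in global shape;
    local-change pairs share the global shape.  A complete 7×7 grid yields
    7 · C(7,2) = 147 pairs of each kind.
    """
    gs = sorted({m["g"] for m in stimuli.meta})
    ls = sorted({m["l"] for m in stimuli.meta})
    grid = {}
    for i, m in enumerate(stimuli.meta):
        grid[(m["g"], m["l"])] = i
    if len(grid) != len(gs) * len(ls):
        raise ValueError("incomplete hierarchical grid")
    g_pairs, l_pairs = [], []
    for l in ls:
        for a in range(len(gs)):
            for b in range(a + 1, len(gs)):
                g_pairs.append((grid[(gs[a], l)], grid[(gs[b], l)]))
    for g in gs:
        for a in range(len(ls)):
            for b in range(a + 1, len(ls)):
                l_pairs.append((grid[(g, ls[a])], grid[(g, ls[b])]))
    return g_pairs, l_pairs


def global_advantage_index(stimuli: StimulusSet, table: ActivationTable,
                           metric: str = "euclidean", n_boot: int = 1000,
                           seed: int = 0) -> IndexProfile:
    """(d_global − d_local)/(d_global + d_local) per layer.

    d_global is the mean distance over all pairs differing only in global
    shape, d_local over pairs differing only in local shape.  Since the
    index is a ratio of means, its s.e.m. is estimated by a seeded
    bootstrap over the two pair sets (``n_boot`` resamples).
    """
    g_pairs, l_pairs = hierarchical_pairs(stimuli)
    n_layers = len(table.layers)
    means = np.full(n_layers, np.nan)
    sems = np.zeros(n_layers)
    ns = np.zeros(n_layers, dtype=int)
    excl = np.zeros(n_layers, dtype=int)
    for kl, mat in enumerate(table.activations):
        dm = pairwise_distances(mat, metric)
        dg = np.asarray([dm[a, b] for a, b in g_pairs])
        dl = np.asarray([dm[a, b] for a, b in l_pairs])
        total = dg.mean() + dl.mean()
        if total == 0:
            excl[kl] = 1
            continue
        means[kl] = (dg.mean() - dl.mean()) / total
        ns[kl] = len(dg) + len(dl)
        rng = np.random.default_rng([seed, kl])
        boots = np.empty(n_boot)
        for b in range(n_boot):
            rg = dg[rng.integers(0, len(dg), len(dg))].mean()
            rl = dl[rng.integers(0, len(dl), len(dl))].mean()
            boots[b] = (rg - rl) / (rg + rl) if (rg + rl) > 0 else np.nan
        sems[kl] = float(np.nanstd(boots))
    return IndexProfile(table.layers, means, sems, ns, excl,
                        name="global_advantage")
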