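"""Seeded synthetic stimulus generators for the perceptual-property battery.

Every public generator is a pure function of its parameters and an integer
seed: regenerating with the same arguments reproduces bit-identical pixels.
All images are 8-bit grayscale rasters (``uint8``, origin top-left,
row-major) packaged in a :class:`StimulusSet` together with per-image
metadata tags that downstream index computations read.

Twelve stimulus families are covered, one per experiment in the battery:

1.  schematic faces with known eye/mouth boxes (Thatcher effect),
2.  asymmetric silhouettes plus mirror images (mirror confusion),
3.  objects composited on congruent/incongruent context textures,
4.  single/pair/triplet multi-object displays (normalization),
5.  reference shapes, morphlines, textures, silhouettes (selectivity),
6.  bars varying in length (Weber's law),
7.  two-part objects with independent part sizes (relative size),
8.  patterns on tilted surfaces (surface invariance),
9.  line drawings of 3D objects and matched 2D controls,
10. occlusion and depth-ordering displays,
11. objects with natural/unnatural part cuts and part recombinations,
12. hierarchical (global/local) shape stimuli.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.draw import disk as _sk_disk
from skimage.draw import line as _sk_line
from skimage.draw import polygon as _sk_polygon

__all__ = [
    "BoxRegion",
    "StimulusSet",
    "make_faces",
    "make_thatcher_set",
    "thatcherize",
    "invert_image",
    "make_mirror_set",
    "make_scenes",
    "make_multiobject_displays",
    "make_shape_sets",
    "default_length_ladder",
    "make_length_bars",
    "make_size_tetrads",
    "make_surface_tetrads",
    "make_3d_pairs",
    "make_occlusion_displays",
    "make_part_objects",
    "make_hierarchical_stimuli",
    "export_set",
]

DEFAULT_SIZE = 224
_BG = 0
_FG = 255


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class BoxRegion:
    """Axis-aligned pixel box, 0-based, half-open on bottom/right."""

    top: int
    left: int
    bottom: int
    right: int

    def __post_init__(self) -> None:
        if not (self.bottom > self.top and self.right > self.left):
            raise ValueError(f"degenerate box {self}")
        if self.top < 0 or self.left < 0:
            raise ValueError(f"negative box coordinates {self}")

    @property
    def height(self) -> int:
        return self.bottom - self.top

    @property
    def width(self) -> int:
        return self.right - self.left

    def slices(self) -> tuple[slice, slice]:
        return slice(self.top, self.bottom), slice(self.left, self.right)

    def within(self, shape: tuple[int, int]) -> bool:
        return self.bottom <= shape[0] and self.right <= shape[1]

    def overlaps(self, other: "BoxRegion") -> bool:
        return not (
            self.bottom <= other.top
            or other.bottom <= self.top
            or self.right <= other.left
            or other.right <= self.left
        )


@dataclass
class StimulusSet:
    """Ordered images plus aligned per-image metadata tags."""

    images: list[np.ndarray]
    meta: list[dict]
    seed: int | None = None
    name: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.images) != len(self.meta):
            raise ValueError("images and meta must have equal length")
        if self.images:
            shape = self.images[0].shape
            for k, im in enumerate(self.images):
                if im.shape != shape:
                    raise ValueError(f"image {k} shape {im.shape} != {shape}")
                _check_image(im)

    def __len__(self) -> int:
        return len(self.images)

    def __getitem__(self, i: int) -> tuple[np.ndarray, dict]:
        return self.images[i], self.meta[i]

    def indices(self, **tags) -> list[int]:
        """Indices of images whose meta matches all given key=value tags."""
        out = []
        for i, m in enumerate(self.meta):
            if all(m.get(k) == v for k, v in tags.items()):
                out.append(i)
        return out

    def index(self, **tags) -> int:
        """Unique index matching the tags; error if absent or ambiguous."""
        hits = self.indices(**tags)
        if len(hits) != 1:
            raise KeyError(f"tags {tags} matched {len(hits)} images, expected 1")
        return hits[0]


def _check_image(im: np.ndarray) -> None:
    if im.ndim not in (2, 3):
        raise ValueError("image must be H×W or H×W×3")
    if im.shape[0] < 8 or im.shape[1] < 8:
        raise ValueError("image must be at least 8×8")
    if not np.isfinite(np.asarray(im, dtype=float)).all():
        raise ValueError("image has non-finite values")
    lo, hi = float(np.min(im)), float(np.max(im))
    if lo < 0 or hi > 255:
        raise ValueError(f"image values [{lo}, {hi}] outside [0, 255]")


def _canvas(size: int, value: int = _BG) -> np.ndarray:
    return np.full((size, size), value, dtype=np.uint8)


# ---------------------------------------------------------------------------
# drawing primitives


def _fill_ellipse(img, cy, cx, ry, rx, value):
    yy, xx = np.ogrid[: img.shape[0], : img.shape[1]]
    mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    img[mask] = value
    return mask


def _thick_line(img, r0, c0, r1, c1, value, width=2):
    rr, cc = _sk_line(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
    h, w = img.shape
    for dr in range(-(width // 2), width - width // 2):
        for dc in range(-(width // 2), width - width // 2):
            r = np.clip(rr + dr, 0, h - 1)
            c = np.clip(cc + dc, 0, w - 1)
            img[r, c] = value


def _radial_blob_params(rng, n_harmonics=4, amp=0.22):
    """Parameter vector of a closed radial-contour blob r(θ)."""
    amps = rng.uniform(0.3, 1.0, n_harmonics) * amp / np.arange(1, n_harmonics + 1)
    phases = rng.uniform(0, 2 * np.pi, n_harmonics)
    return np.concatenate([amps, phases])


def _render_blob(size_hw, cy, cx, radius, params, value=_FG, img=None,
                 n_points=180, stretch=(1.0, 1.0)):
    """Rasterize a radial-contour blob from its parameter vector."""
    n = len(params) // 2
    amps, phases = params[:n], params[n:]
    theta = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    r = np.ones_like(theta)
    for k in range(n):
        r += amps[k] * np.cos((k + 2) * theta + phases[k])
    r = np.clip(r, 0.2, None) * radius
    rows = cy + stretch[0] * r * np.sin(theta)
    cols = cx + stretch[1] * r * np.cos(theta)
    if img is None:
        img = np.full(size_hw, _BG, dtype=np.uint8)
    rr, cc = _sk_polygon(rows, cols, shape=img.shape)
    img[rr, cc] = value
    return img


def _bandpass_texture(rng, size, sigma_lo, sigma_hi, lo=30, hi=225):
    """Band-pass filtered seeded noise, rescaled to [lo, hi]."""
    from scipy.ndimage import gaussian_filter

    noise = rng.standard_normal((size, size))
    band = gaussian_filter(noise, sigma_lo) - gaussian_filter(noise, sigma_hi)
    band -= band.min()
    rngspan = band.max()
    if rngspan == 0:  # pragma: no cover - degenerate noise
        rngspan = 1.0
    band = band / rngspan
    return (lo + band * (hi - lo)).astype(np.uint8)


# ---------------------------------------------------------------------------
# Experiment 1: faces / Thatcherization


def make_faces(n_faces: int, seed: int = 0, size: int = DEFAULT_SIZE) -> StimulusSet:
    """Schematic upright faces with exactly known eye and mouth boxes.

    Each face is an oval head with two eyes (iris high in the socket, brow
    above), a nose, and a smiling mouth, all jittered per face identity so
    faces differ across ids.  Meta carries three non-overlapping
    :class:`BoxRegion` entries (left eye, right eye, mouth) whose content is
    vertically asymmetric, so local inversion visibly changes the face.
    """
    if n_faces < 1:
        raise ValueError("n_faces must be >= 1")
    if size < 64:
        raise ValueError(f"size {size} too small to contain eye/mouth boxes")
    rng = np.random.default_rng(seed)
    images, meta = [], []
    for fid in range(n_faces):
        img = _canvas(size, _BG)
        cy = cx = size / 2
        head_ry = size * rng.uniform(0.38, 0.42)
        head_rx = size * rng.uniform(0.28, 0.32)
        _fill_ellipse(img, cy, cx, head_ry, head_rx, 190)

        eye_dy = -size * rng.uniform(0.10, 0.14)
        eye_dx = size * rng.uniform(0.11, 0.14)
        eye_r = size * rng.uniform(0.035, 0.045)
        boxes = []
        for side in (-1, 1):
            ey, ex = cy + eye_dy, cx + side * eye_dx
            _fill_ellipse(img, ey, ex, eye_r, eye_r * 1.4, 245)  # sclera
            _fill_ellipse(img, ey - eye_r * 0.35, ex, eye_r * 0.5, eye_r * 0.5, 20)
            # brow above the eye makes the box content vertically asymmetric
            _thick_line(img, ey - eye_r * 1.6, ex - eye_r * 1.4,
                        ey - eye_r * 1.8, ex + eye_r * 1.4, 40, width=2)
            pad = int(eye_r * 2.0)  # boxes stay clear of each other
            boxes.append(BoxRegion(int(ey) - pad, int(ex) - pad,
                                   int(ey) + pad, int(ex) + pad))

        nose_y = cy + size * 0.02
        _thick_line(img, cy - size * 0.04, cx, nose_y + size * 0.06, cx, 90, width=2)
        _thick_line(img, nose_y + size * 0.06, cx - size * 0.02,
                    nose_y + size * 0.06, cx + size * 0.02, 90, width=2)

        mouth_y = cy + size * rng.uniform(0.16, 0.20)
        mouth_rx = size * rng.uniform(0.07, 0.10)
        mouth_ry = size * rng.uniform(0.030, 0.040)
        # lower half of an ellipse: a smile, vertically asymmetric
        yy, xx = np.ogrid[:size, :size]
        e = ((yy - mouth_y) / mouth_ry) ** 2 + ((xx - cx) / mouth_rx) ** 2 <= 1.0
        img[e & (yy >= mouth_y)] = 60
        pad_y, pad_x = int(mouth_ry * 1.8), int(mouth_rx * 1.2)
        boxes.append(BoxRegion(int(mouth_y) - pad_y, int(cx) - pad_x,
                               int(mouth_y) + pad_y, int(cx) + pad_x))

        for b in boxes:
            if not b.within(img.shape):
                raise ValueError(f"size {size} too small: box {b} out of bounds")
        for i in range(len(boxes)):
            for j in range(i + 1, len(boxes)):
                if boxes[i].overlaps(boxes[j]):
                    raise ValueError(f"size {size} too small: boxes overlap")

        images.append(img)
        meta.append({
            "face_id": fid,
            "orientation": "upright",
            "version": "normal",
            "boxes": boxes,
        })
    return StimulusSet(images, meta, seed=seed, name="faces")


def thatcherize(image: np.ndarray, boxes: list[BoxRegion]) -> np.ndarray:
    """Vertically flip the pixel rows inside each box (local inversion).

    An involution: applying it twice restores the original image.  Boxes
    must lie within the image and must not overlap (a double flip on shared
    pixels would be ill-defined).
    """
    _check_image(image)
    for b in boxes:
        if not b.within(image.shape[:2]):
            raise ValueError(f"box {b} outside image bounds {image.shape}")
    for i in range(len(boxes)):
        for j in range(i + 1, len(boxes)):
            if boxes[i].overlaps(boxes[j]):
                raise ValueError(f"boxes {i} and {j} overlap")
    out = image.copy()
    for b in boxes:
        sy, sx = b.slices()
        out[sy, sx] = image[sy, sx][::-1]
    return out


def invert_image(image: np.ndarray) -> np.ndarray:
    """In-plane 180° rotation: output (i, j) = input (H−1−i, W−1−j)."""
    _check_image(image)
    return image[::-1, ::-1].copy()


def make_thatcher_set(n_faces: int, seed: int = 0,
                      size: int = DEFAULT_SIZE) -> StimulusSet:
    """Faces in all four conditions: {normal, thatcherized} × {upright, inverted}."""
    faces = make_faces(n_faces, seed=seed, size=size)
    images, meta = [], []
    for img, m in zip(faces.images, faces.meta):
        boxes = m["boxes"]
        that = thatcherize(img, boxes)
        for version, base in (("normal", img), ("thatcher", that)):
            for orient, px in (("upright", base), ("inverted", invert_image(base))):
                images.append(px)
                meta.append({"face_id": m["face_id"], "version": version,
                             "orientation": orient})
    return StimulusSet(images, meta, seed=seed, name="thatcher")


# ---------------------------------------------------------------------------
# Experiment 2: mirror images


def make_mirror_set(n_objects: int, seed: int = 0,
                    size: int = DEFAULT_SIZE) -> StimulusSet:
    """Asymmetric silhouettes with vertical- and horizontal-mirror companions.

    Half the base objects are 90°-rotated copies of the other half, so the
    set is balanced for elongation along either axis.  Vertical mirror =
    left-right flip (reflection about the vertical axis); horizontal mirror
    = up-down flip.
    """
    if n_objects % 2 != 0:
        raise ValueError("n_objects must be even")
    if n_objects < 2:
        raise ValueError("n_objects must be >= 2")
    rng = np.random.default_rng(seed)
    half = n_objects // 2
    bases = []
    while len(bases) < half:
        params = _radial_blob_params(rng, amp=0.35)
        img = _render_blob((size, size), size / 2, size / 2, size * 0.32,
                           params, stretch=(1.0, rng.uniform(1.1, 1.4)))
        # enforce asymmetry: must differ from both of its mirrors
        if np.array_equal(img, img[:, ::-1]) or np.array_equal(img, img[::-1]):
            continue  # pragma: no cover - essentially never for random blobs
        bases.append(img)
    bases = bases + [np.rot90(b).copy() for b in bases]

    images, meta = [], []
    for oid, base in enumerate(bases):
        for role, px in (("original", base),
                         ("v_mirror", base[:, ::-1].copy()),
                         ("h_mirror", base[::-1].copy())):
            images.append(px)
            meta.append({"object_id": oid, "role": role,
                         "rotated": oid >= half})
    return StimulusSet(images, meta, seed=seed, name="mirror")


# ---------------------------------------------------------------------------
# Experiment 3: scenes


def make_scenes(n_objects: int, seed: int = 0,
                size: int = DEFAULT_SIZE) -> StimulusSet:
    """Objects on congruent vs incongruent context textures.

    Each object class is associated by construction with one band-pass
    texture (its congruent context); the incongruent context is the next
    class's texture.  Object pixels and position are identical in both
    scenes of an object.
    """
    if n_objects < 2:
        raise ValueError("need >= 2 objects for an incongruent context")
    rng = np.random.default_rng(seed)
    contexts = []
    for k in range(n_objects):
        sigma = 1.0 + 6.0 * k / max(n_objects - 1, 1)
        contexts.append(_bandpass_texture(rng, size, sigma, sigma * 3, lo=30, hi=170))
    objects = []
    for _ in range(n_objects):
        params = _radial_blob_params(rng, amp=0.3)
        mask_img = _render_blob((size, size), size / 2, size / 2,
                                size * 0.18, params)
        objects.append(mask_img > 0)

    images, meta = [], []
    for oid in range(n_objects):
        mask = objects[oid]
        isolated = _canvas(size, 128)
        isolated[mask] = _FG
        entries = [
            ("isolated", isolated, None),
            ("congruent", None, oid),
            ("incongruent", None, (oid + 1) % n_objects),
        ]
        for role, px, ctx in entries:
            if px is None:
                px = contexts[ctx].copy()
                px[mask] = _FG
            images.append(px)
            meta.append({"object_id": oid, "role": role, "label": oid,
                         "context_id": ctx})
    return StimulusSet(images, meta, seed=seed, name="scenes")


# ---------------------------------------------------------------------------
# Experiment 4: multiple-object displays


def _three_locations(size: int, patch: int) -> list[tuple[int, int]]:
    """Row of three equally spaced non-overlapping patch centers."""
    gap = (size - 3 * patch) // 4
    if gap < 1:
        raise ValueError(f"three locations of patch {patch} overlap at size {size}")
    cy = size // 2
    xs = [gap + patch // 2 + k * (patch + gap) for k in range(3)]
    return [(cy, x) for x in xs]


def make_multiobject_displays(n_objects: int, n_pairs: int, n_triplets: int,
                              seed: int = 0,
                              size: int = DEFAULT_SIZE) -> StimulusSet:
    """Singleton, pair, and triplet displays on a blank ground.

    Produces ``n_objects × 3`` singletons (each object at each of three
    fixed horizontal locations), then ``n_pairs`` two-object and
    ``n_triplets`` three-object displays drawn by seeded random selection.
    Every multi-object display is the pixelwise composition of its
    singletons' object regions, so surrogate and additive models have an
    exact ground truth.
    """
    if n_objects < 3:
        raise ValueError("n_objects must be >= 3")
    rng = np.random.default_rng(seed)
    patch = size // 4
    locations = _three_locations(size, patch)

    sprites = []
    for _ in range(n_objects):
        params = _radial_blob_params(rng, amp=0.3)
        sprite = _render_blob((patch, patch), patch / 2, patch / 2,
                              patch * 0.42, params)
        sprites.append(sprite)

    def place(img, oid, loc):
        cy, cx = locations[loc]
        t, l = cy - patch // 2, cx - patch // 2
        region = img[t:t + patch, l:l + patch]
        np.maximum(region, sprites[oid], out=region)

    images, meta = [], []
    for oid in range(n_objects):
        for loc in range(3):
            img = _canvas(size)
            place(img, oid, loc)
            images.append(img)
            meta.append({"role": "singleton", "members": ((oid, loc),)})
    for _ in range(n_pairs):
        objs = rng.choice(n_objects, size=2, replace=False)
        locs = rng.choice(3, size=2, replace=False)
        members = tuple(sorted((int(o), int(l)) for o, l in zip(objs, locs)))
        img = _canvas(size)
        for o, l in members:
            place(img, o, l)
        images.append(img)
        meta.append({"role": "pair", "members": members})
    for _ in range(n_triplets):
        objs = rng.choice(n_objects, size=3, replace=False)
        locs = rng.permutation(3)
        members = tuple(sorted((int(o), int(l)) for o, l in zip(objs, locs)))
        img = _canvas(size)
        for o, l in members:
            place(img, o, l)
        images.append(img)
        meta.append({"role": "triplet", "members": members})
    return StimulusSet(images, meta, seed=seed, name="multiobject")


# ---------------------------------------------------------------------------
# Experiment 5: reference shapes, morphlines, textures, silhouettes


def make_shape_sets(seed: int = 0, size: int = DEFAULT_SIZE,
                    n_reference: int = 8, n_morphlines: int = 4,
                    n_steps: int = 5, n_textures: int = 128,
                    n_silhouettes: int = 128) -> StimulusSet:
    """Reference silhouettes, morphlines, textures and a silhouette set.

    Morphlines linearly interpolate the radial-contour parameter vectors of
    two reference shapes; step ``t = 0`` reproduces endpoint A exactly and
    ``t = 1`` endpoint B.
    """
    rng = np.random.default_rng(seed)
    ref_params = [_radial_blob_params(rng, amp=0.3) for _ in range(n_reference)]

    def render(params):
        return _render_blob((size, size), size / 2, size / 2, size * 0.3, params)

    images, meta = [], []
    for k, p in enumerate(ref_params):
        images.append(render(p))
        meta.append({"subset": "reference", "shape_id": k})
    for line in range(n_morphlines):
        a, b = (2 * line) % n_reference, (2 * line + 1) % n_reference
        for step, t in enumerate(np.linspace(0.0, 1.0, n_steps)):
            p = (1 - t) * ref_params[a] + t * ref_params[b]
            images.append(render(p))
            meta.append({"subset": "morph", "line": line, "step": step,
                         "t": float(t), "endpoints": (a, b)})
    for k in range(n_textures):
        sigma = 0.8 + 5.0 * rng.uniform()
        images.append(_bandpass_texture(rng, size, sigma, sigma * 3))
        meta.append({"subset": "texture", "texture_id": k})
    for k in range(n_silhouettes):
        params = _radial_blob_params(rng, amp=0.35)
        images.append(render(params))
        meta.append({"subset": "shape", "silhouette_id": k})
    return StimulusSet(images, meta, seed=seed, name="shapes")


# ---------------------------------------------------------------------------
# Experiment 6: bar lengths


def default_length_ladder(size: int = DEFAULT_SIZE) -> list[int]:
    """Geometric-plus-arithmetic bar-length ladder.

    Mixing geometric spacing (constant relative steps) with arithmetic
    spacing (constant absolute steps) decorrelates absolute and relative
    pairwise length differences, so the two Weber predictors are
    distinguishable.
    """
    geometric, L = [], 12.0
    while L < size * 0.9:
        geometric.append(int(round(L)))
        L *= 1.6
    step = size // 6
    arithmetic = list(range(step, int(size * 0.9), step))
    ladder = sorted(set(geometric) | set(arithmetic))
    return ladder


def make_length_bars(lengths: list[int] | None = None, seed: int = 0,
                     size: int = DEFAULT_SIZE,
                     thickness: int | None = None) -> StimulusSet:
    """One centered horizontal bar image per requested length."""
    if lengths is None:
        lengths = default_length_ladder(size)
    lengths = [int(x) for x in lengths]
    if any(x <= 0 for x in lengths):
        raise ValueError("lengths must be strictly positive")
    if len(set(lengths)) != len(lengths):
        raise ValueError("lengths must be distinct")
    if len(lengths) < 4:
        raise ValueError("need at least 4 distinct lengths")
    if max(lengths) > size - 2:
        raise ValueError(f"length {max(lengths)} exceeds image width {size}")
    if thickness is None:
        thickness = max(4, size // 28)
    images, meta = [], []
    cy, cx = size // 2, size // 2
    for L in lengths:
        img = _canvas(size)
        img[cy - thickness // 2: cy - thickness // 2 + thickness,
            cx - L // 2: cx - L // 2 + L] = _FG
        images.append(img)
        meta.append({"length": L})
    return StimulusSet(images, meta, seed=seed, name="bars")


# ---------------------------------------------------------------------------
# Experiment 7: two-part size tetrads


def make_size_tetrads(n_tetrads: int, seed: int = 0,
                      size: int = DEFAULT_SIZE,
                      scale_factor: float = 1.5) -> StimulusSet:
    """Two-part silhouettes with each part at one of two sizes.

    Each tetrad crosses the sizes of the top part (s1) and bottom part (s2)
    at levels 1 and 2; level 2 scales a part's radius by ``scale_factor``,
    so cell (2,2) is cell (1,1) with both parts scaled by the same factor.
    """
    if n_tetrads < 1:
        raise ValueError("n_tetrads must be >= 1")
    rng = np.random.default_rng(seed)
    images, meta = [], []
    base_r = size * 0.11
    for tid in range(n_tetrads):
        p_top = _radial_blob_params(rng, amp=0.3)
        p_bot = _radial_blob_params(rng, amp=0.3)
        cy_top, cy_bot, cx = size * 0.32, size * 0.68, size / 2
        for s1 in (1, 2):
            for s2 in (1, 2):
                img = _canvas(size)
                r1 = base_r * (scale_factor if s1 == 2 else 1.0)
                r2 = base_r * (scale_factor if s2 == 2 else 1.0)
                _render_blob((size, size), cy_top, cx, r1, p_top, img=img)
                _render_blob((size, size), cy_bot, cx, r2, p_bot, img=img)
                stem_w = max(2, size // 56)
                img[int(cy_top): int(cy_bot),
                    int(cx) - stem_w: int(cx) + stem_w] = _FG
                images.append(img)
                meta.append({"tetrad_id": tid, "s1": s1, "s2": s2,
                             "scale_factor": scale_factor})
    return StimulusSet(images, meta, seed=seed, name="size_tetrads")


# ---------------------------------------------------------------------------
# Experiment 8: pattern-on-surface tetrads


def make_surface_tetrads(n_patterns: int = 6, n_surfaces: int = 4,
                         seed: int = 0, size: int = DEFAULT_SIZE,
                         level_delta_deg: float = 14.0) -> StimulusSet:
    """Patterns superimposed on tilted surfaces, 2×2 per pattern–surface pair.

    Pattern tilt and surface tilt each take two levels separated by the same
    angular step, so the pattern-relative-to-surface angle is identical in
    the two congruent cells (1,1) and (2,2) of every tetrad.
    """
    if n_patterns < 1 or n_surfaces < 1:
        raise ValueError("n_patterns and n_surfaces must be >= 1")
    rng = np.random.default_rng(seed)
    pattern_base = rng.uniform(-8, 8, n_patterns)
    surface_base = rng.uniform(-8, 8, n_surfaces)
    pattern_rel = rng.uniform(25, 45, n_patterns)  # pattern offset from surface

    images, meta = [], []
    cy = cx = size / 2
    for pid in range(n_patterns):
        for sid in range(n_surfaces):
            for p_lvl in (1, 2):
                for s_lvl in (1, 2):
                    s_tilt = surface_base[sid] + (s_lvl - 1) * level_delta_deg
                    p_tilt = (surface_base[sid] + pattern_base[pid]
                              + pattern_rel[pid] + (p_lvl - 1) * level_delta_deg)
                    img = _canvas(size)
                    # surface: thick band at s_tilt
                    a = np.deg2rad(s_tilt)
                    dy, dx = np.sin(a), np.cos(a)
                    half = size * 0.42
                    _thick_line(img, cy - dy * half, cx - dx * half,
                                cy + dy * half, cx + dx * half, 120,
                                width=max(6, size // 14))
                    # pattern: three parallel strokes at p_tilt on the surface
                    b = np.deg2rad(p_tilt)
                    py, px = np.sin(b), np.cos(b)
                    span = size * 0.16
                    for off in (-0.25, 0.0, 0.25):
                        oy, ox = cy + dy * half * off * 2, cx + dx * half * off * 2
                        _thick_line(img, oy - py * span, ox - px * span,
                                    oy + py * span, ox + px * span, _FG,
                                    width=max(2, size // 56))
                    images.append(img)
                    meta.append({
                        "pattern_id": pid, "surface_id": sid,
                        "pattern_level": p_lvl, "surface_level": s_lvl,
                        "relative_tilt": float(p_tilt - s_tilt),
                        "congruent": p_lvl == s_lvl,
                    })
    return StimulusSet(images, meta, seed=seed, name="surface_tetrads")


# ---------------------------------------------------------------------------
# Experiment 9: 3D line drawings and 2D controls


def _draw_junction(img, cy, cx, arms, value, width):
    for angle, length in arms:
        a = np.deg2rad(angle)
        _thick_line(img, cy, cx, cy - np.sin(a) * length, cx + np.cos(a) * length,
                    value, width=width)


def make_3d_pairs(seed: int = 0, size: int = DEFAULT_SIZE) -> StimulusSet:
    """Line-drawing pairs probing 3D interpretation, with matched 2D controls.

    Three shape families (cuboid, cube, frustum).  Within a family, the two
    members of every pair differ only in a central junction drawn either as
    a Y junction or as an alternate junction; the surrounding context
    strokes (a hexagonal outline for the 3D pair, flat arrangements for the
    two control pairs) are kept outside the junction zone and identical
    within each pair, so the changed-stroke mask is identical across the
    three pairs of a family.
    """
    rng = np.random.default_rng(seed)
    width = int(rng.integers(2, 4))  # seeded stroke width
    images, meta = [], []
    families = ["cuboid", "cube", "frustum"]
    cy = cx = size // 2
    arm = size * 0.14
    for fid, fam in enumerate(families):
        tilt = {"cuboid": 0.0, "cube": 8.0, "frustum": -8.0}[fam]
        arms_a = [(90 + tilt, arm), (210 + tilt, arm), (330 + tilt, arm)]   # Y
        arms_b = [(90 + tilt, arm), (180 + tilt, arm), (0 + tilt, arm)]     # T
        junction_r = int(arm) + 3 * width  # context keeps clear of this zone

        def context_hex(img):
            R = size * 0.36
            pts = [(cy - R * np.sin(np.deg2rad(90 + 60 * k + tilt)),
                    cx + R * np.cos(np.deg2rad(90 + 60 * k + tilt)))
                   for k in range(6)]
            for k in range(6):
                r0, c0 = pts[k]
                r1, c1 = pts[(k + 1) % 6]
                _thick_line(img, r0, c0, r1, c1, _FG, width=width)

        def context_square(img):
            R = int(size * 0.36)
            img[cy - R: cy - R + width, cx - R: cx + R] = _FG
            img[cy + R - width: cy + R, cx - R: cx + R] = _FG
            img[cy - R: cy + R, cx - R: cx - R + width] = _FG
            img[cy - R: cy + R, cx + R - width: cx + R] = _FG

        def context_lines(img):
            R = int(size * 0.36)
            img[cy - R: cy - R + width, cx - R: cx + R] = _FG
            img[cy + R - width: cy + R, cx - R: cx + R] = _FG

        for pair, ctx in (("threed", context_hex), ("control1", context_square),
                          ("control2", context_lines)):
            for version, arms in (("a", arms_a), ("b", arms_b)):
                img = _canvas(size)
                ctx(img)
                # context zone check is by construction: R*sin(30°) > junction_r
                _draw_junction(img, cy, cx, arms, _FG, width)
                images.append(img)
                meta.append({"family": fam, "family_id": fid, "pair": pair,
                             "version": version, "junction_radius": junction_r})
    return StimulusSet(images, meta, seed=seed, name="threed")


# ---------------------------------------------------------------------------
# Experiment 10: occlusion displays


def make_occlusion_displays(seed: int = 0, size: int = DEFAULT_SIZE) -> StimulusSet:
    """Square–disk displays probing occlusion and depth-order sensitivity.

    Occlusion effect: a square with a disk beside it (unoccluded), the same
    square with the disk moved partially behind it (occluded), and a 2D
    control where the disk stays put but loses the same chord segment that
    occlusion would hide.  Depth-ordering effect: square-over-disk vs
    disk-over-square at identical positions (they differ only inside the
    overlap region), plus a 2D control pair with the lens-shaped overlap
    patch attached to either shape.
    """
    rng = np.random.default_rng(seed)
    r = size * rng.uniform(0.13, 0.15)
    half = int(size * 0.14)
    cy = size // 2
    sq_cx = int(size * 0.62)
    disk_far = int(size * 0.25)
    disk_near = int(sq_cx - half - r * 0.45)

    def square(img, value=_FG):
        img[cy - half: cy + half, sq_cx - half: sq_cx + half] = value

    def disk_mask(cx_):
        m = np.zeros((size, size), dtype=bool)
        rr, cc = _sk_disk((cy, cx_), r, shape=(size, size))
        m[rr, cc] = True
        return m

    images, meta = [], []

    def emit(img, effect, role, **extra):
        images.append(img)
        meta.append({"effect": effect, "role": role, **extra})

    far, near = disk_mask(disk_far), disk_mask(disk_near)
    sqm = np.zeros((size, size), dtype=bool)
    sqm[cy - half: cy + half, sq_cx - half: sq_cx + half] = True

    img = _canvas(size)
    img[far] = 140
    square(img)
    emit(img, "occlusion", "unoccluded",
         disk_boxes=((cy - int(r) - 1, disk_far - int(r) - 1,
                      cy + int(r) + 2, disk_far + int(r) + 2),
                     (cy - int(r) - 1, disk_near - int(r) - 1,
                      cy + int(r) + 2, disk_near + int(r) + 2)))

    img = _canvas(size)
    img[near] = 140
    square(img)  # square drawn last: disk partially behind it
    emit(img, "occlusion", "occluded", disk_boxes=meta[-1]["disk_boxes"])

    # control: disk at the far position, truncated by the chord that the
    # square would hide at the near position (same 2D feature difference)
    hidden = near & sqm
    off = disk_near - disk_far  # chord translated back to the far position
    truncated = far.copy()
    truncated[:, : size - off] &= ~hidden[:, off:]
    img = _canvas(size)
    img[truncated] = 140
    square(img)
    emit(img, "occlusion", "control", disk_boxes=meta[-1]["disk_boxes"])

    # depth ordering: identical positions, opposite draw order
    overlap_box = (int(cy - r) - 1, int(min(disk_near - r, sq_cx - half)) - 1,
                   int(cy + r) + 2, int(max(disk_near + r, sq_cx + half)) + 2)
    img = _canvas(size)
    img[near] = 140
    square(img)
    emit(img, "depth_order", "square_front", overlap_box=overlap_box)

    img = _canvas(size)
    square(img)
    img[near] = 140
    emit(img, "depth_order", "disk_front", overlap_box=overlap_box)

    # 2D controls: disjoint square and disk; the lens-shaped overlap patch
    # drawn adjacent to the square (a) or adjacent to the disk (b)
    lens = near & sqm
    rows, cols = np.nonzero(lens)
    for role, dx in (("control_a", int(size * 0.10)), ("control_b", -int(size * 0.10))):
        img = _canvas(size)
        img[far] = 140
        square(img)
        img[rows - int(r * 1.6), cols + dx] = 200
        emit(img, "depth_order", role, overlap_box=overlap_box)
    return StimulusSet(images, meta, seed=seed, name="occlusion")


# ---------------------------------------------------------------------------
# Experiment 11: part cuts and recombinations


def make_part_objects(seed: int = 0, size: int = DEFAULT_SIZE,
                      n_parts: int = 7) -> StimulusSet:
    """Two-part contour objects, part breaks, and part recombinations.

    Seven whole objects are built from a left blob and a right blob joined
    by a waist at a fixed column; the waist (a curvature minimum between the
    generating contours) is the natural cut, a fixed column offset into the
    right blob is the unnatural cut.  Break stimuli open a background gap at
    one cut, preserving foreground pixels.  Recombining left/right pieces
    across objects at either cut yields 49 natural-part and 49
    unnatural-part composites whose diagonals reproduce the 7 originals
    (the common set).
    """
    rng = np.random.default_rng(seed)
    cy = size // 2
    cut_nat = size // 2
    offset = size // 9
    cut_unnat = cut_nat + offset
    gap = size // 16
    radius = size * 0.17
    cx_left, cx_right = int(size * 0.30), int(size * 0.66)

    wholes = []
    for _ in range(n_parts):
        img = _canvas(size)
        _render_blob((size, size), cy, cx_left, radius,
                     _radial_blob_params(rng, amp=0.28), img=img)
        _render_blob((size, size), cy, cx_right, radius,
                     _radial_blob_params(rng, amp=0.28), img=img)
        waist = max(2, size // 40)
        img[cy - waist: cy + waist, cx_left: cx_right] = _FG
        wholes.append(img)

    def broken(img, cut):
        out = _canvas(size)
        out[:, :cut] = img[:, :cut]
        right = img[:, cut:size - gap]
        out[:, cut + gap:] = right
        return out

    def composite(left_img, right_img, cut):
        out = _canvas(size)
        out[:, :cut] = left_img[:, :cut]
        out[:, cut:] = right_img[:, cut:]
        return out

    images, meta = [], []
    for oid, img in enumerate(wholes):
        images.append(img)
        meta.append({"role": "whole", "object_id": oid})
        images.append(broken(img, cut_nat))
        meta.append({"role": "natural_break", "object_id": oid})
        images.append(broken(img, cut_unnat))
        meta.append({"role": "unnatural_break", "object_id": oid})
    for decomposition, cut in (("natural", cut_nat), ("unnatural", cut_unnat)):
        for i in range(n_parts):
            for j in range(n_parts):
                images.append(composite(wholes[i], wholes[j], cut))
                meta.append({"role": "composite", "set": decomposition,
                             "left_part": i, "right_part": j,
                             "common": i == j})
    return StimulusSet(images, meta, seed=seed, name="parts")


# ---------------------------------------------------------------------------
# Experiment 12: hierarchical stimuli


def _glyph_outline(kind: int, n: int, radius: float,
                   center: tuple[float, float]) -> np.ndarray:
    """n points along the outline of glyph `kind` (0..6), rows/cols array."""
    cy, cx = center
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    if kind == 0:      # circle
        pts = np.stack([cy + radius * np.sin(t), cx + radius * np.cos(t)], 1)
    elif kind in (1, 2, 3, 5):  # square, triangle, diamond, pentagon
        corners = {1: 4, 2: 3, 3: 4, 5: 5}[kind]
        rot = {1: np.pi / 4, 2: np.pi / 2, 3: 0.0, 5: np.pi / 2}[kind]
        verts = np.stack([cy + radius * np.sin(np.linspace(0, 2 * np.pi, corners,
                                                           endpoint=False) + rot),
                          cx + radius * np.cos(np.linspace(0, 2 * np.pi, corners,
                                                           endpoint=False) + rot)], 1)
        pts = _resample_polyline(np.vstack([verts, verts[:1]]), n)
    elif kind == 4:    # plus sign outline
        u = radius
        v = radius * 0.38
        verts = np.array([
            (-v, -u), (-v, -v), (-u, -v), (-u, v), (-v, v), (-v, u),
            (v, u), (v, v), (u, v), (u, -v), (v, -v), (v, -u)])
        verts = verts + np.array([cy, cx])
        pts = _resample_polyline(np.vstack([verts, verts[:1]]), n)
    else:              # kind == 6: hourglass / X outline
        u = radius
        verts = np.array([(-u, -u), (-u, u), (u, -u), (u, u)]) + np.array([cy, cx])
        pts = _resample_polyline(np.vstack([verts, verts[:1]]), n)
    return pts


def _resample_polyline(verts: np.ndarray, n: int) -> np.ndarray:
    seg = np.diff(verts, axis=0)
    lens = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0], np.cumsum(lens)])
    targets = np.linspace(0, cum[-1], n, endpoint=False)
    pts = np.empty((n, 2))
    for k, s in enumerate(targets):
        i = int(np.searchsorted(cum, s, side="right") - 1)
        i = min(i, len(seg) - 1)
        frac = (s - cum[i]) / lens[i] if lens[i] > 0 else 0.0
        pts[k] = verts[i] + frac * seg[i]
    return pts


def _glyph_mask(kind: int, radius: float, size: int) -> np.ndarray:
    """Filled glyph rendered in a (2r+3)² patch, returned as a bool mask."""
    patch = int(2 * radius + 4)
    c = patch / 2
    img = np.zeros((patch, patch), dtype=np.uint8)
    if kind == 6:
        # hourglass: two triangles
        for tri in ([(c - radius, c - radius), (c - radius, c + radius), (c, c)],
                    [(c + radius, c - radius), (c + radius, c + radius), (c, c)]):
            rr, cc = _sk_polygon([p[0] for p in tri], [p[1] for p in tri],
                                 shape=img.shape)
            img[rr, cc] = 1
    else:
        pts = _glyph_outline(kind, 60, radius, (c, c))
        rr, cc = _sk_polygon(pts[:, 0], pts[:, 1], shape=img.shape)
        img[rr, cc] = 1
        if kind == 0:
            rr, cc = _sk_disk((c, c), radius, shape=img.shape)
            img[rr, cc] = 1
    return img.astype(bool)


def make_hierarchical_stimuli(seed: int = 0, size: int = DEFAULT_SIZE,
                              n_shapes: int = 7,
                              n_elements: int = 16) -> StimulusSet:
    """Hierarchical stimuli: global shape g made of local elements of shape l.

    All 49 combinations of 7 shapes at the global scale and the same 7
    shapes at the local scale.  Element positions depend only on g; the
    element glyph depends only on l.
    """
    rng = np.random.default_rng(seed)
    del rng  # geometry is fully deterministic; seed kept for the contract
    R = size * 0.36
    r_loc = max(3, int(size * 0.045))
    center = (size / 2, size / 2)
    positions = {g: _glyph_outline(g, n_elements, R, center)
                 for g in range(n_shapes)}
    glyphs = {l: _glyph_mask(l, r_loc, size) for l in range(n_shapes)}

    images, meta = [], []
    for g in range(n_shapes):
        for l in range(n_shapes):
            img = _canvas(size)
            gl = glyphs[l]
            gh, gw = gl.shape
            for (py, px) in positions[g]:
                t = int(round(py)) - gh // 2
                le = int(round(px)) - gw // 2
                t = np.clip(t, 0, size - gh)
                le = np.clip(le, 0, size - gw)
                img[t:t + gh, le:le + gw][gl] = _FG
            images.append(img)
            meta.append({"g": g + 1, "l": l + 1})
    return StimulusSet(images, meta, seed=seed, name="hierarchical")


# ---------------------------------------------------------------------------
# export


def export_set(stimset: StimulusSet, directory: str | Path) -> Path:
    """Write a stimulus set as 8-bit PNGs plus a JSON metadata sidecar."""
    from PIL import Image as PILImage

    directory = Path(directory)
    out = directory / (stimset.name or "stimuli")
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for i, (img, m) in enumerate(zip(stimset.images, stimset.meta)):
        tagbits = "_".join(f"{k}-{m[k]}" for k in sorted(m)
                           if isinstance(m[k], (int, str, bool)))
        fname = f"{i:04d}_{tagbits[:80]}.png" if tagbits else f"{i:04d}.png"
        PILImage.fromarray(img).save(out / fname)
        records.append({"file": fname, **_jsonable(m)})
    sidecar = {"name": stimset.name, "seed": stimset.seed, "images": records}
    (out / "metadata.json").write_text(json.dumps(sidecar, indent=1))
    return out


def _jsonable(m: dict) -> dict:
    def conv(v):
        if isinstance(v, BoxRegion):
            return [v.top, v.left, v.bottom, v.right]
        if isinstance(v, (np.integer,)):
            return int(v)
        if isinstance(v, (np.floating,)):
            return float(v)
        if isinstance(v, (tuple, list)):
            return [conv(x) for x in v]
        return v

    return {k: conv(v) for k, v in m.items()}
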