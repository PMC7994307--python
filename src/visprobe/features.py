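"""Layer-wise feature extraction behind a uniform extractor contract.

An *extractor* is any object with

- ``layers``: an ordered list of :class:`LayerSpec`, and
- ``transform(stimuli) -> list[np.ndarray]``: one ``(n_stimuli, dim)``
  activation matrix per layer, aligned to the stimulus order.

Built-ins:

- :func:`pixel_extractor` — a single input layer whose unit activations are
  the image intensities (flattened row-major);
- :func:`reference_convnet` — a small randomly initialized convolutional
  network (conv → relu → pool blocks followed by fully connected layers),
  implemented in numpy with seeded Gaussian fan-in-scaled weights and no
  training;
- :func:`surrogate_extractor` — analytic responders that read stimulus
  metadata rather than pixels and realize a declared response law exactly
  (averaging/summing over display constituents, linear or logarithmic
  length tuning, global-only/local-only tuning, relative-size-ratio tuning,
  part-sum generative distances, and a context-boosted classifier).

External pretrained networks plug in through the same contract: any object
exposing ``layers`` and ``transform`` passes :func:`validate_extractor`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from .stimuli import StimulusSet

__all__ = [
    "LayerSpec",
    "ActivationTable",
    "preprocess",
    "extract",
    "validate_extractor",
    "pixel_extractor",
    "reference_convnet",
    "surrogate_extractor",
    "predict_class_probabilities",
    "save_table",
    "load_table",
]

#: Per-channel means subtracted during preprocessing (RGB).
DEFAULT_CHANNEL_MEANS = (123.68, 116.78, 103.94)


@dataclass(frozen=True)
class LayerSpec:
    """One processing stage: contiguous index, name, and operation kind."""

    index: int
    name: str
    kind: str  # input | conv | relu | pool | fc | softmax

    _KINDS = ("input", "conv", "relu", "pool", "fc", "softmax")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")


@dataclass
class ActivationTable:
    """Per-layer unit-response matrices aligned to a stimulus set."""

    layers: list[LayerSpec]
    activations: list[np.ndarray]  # one (n_stimuli, dim) matrix per layer
    n_stimuli: int

    def __post_init__(self) -> None:
        if len(self.layers) != len(self.activations):
            raise ValueError("one activation matrix required per layer")
        for spec, mat in zip(self.layers, self.activations):
            if mat.ndim != 2 or mat.shape[0] != self.n_stimuli:
                raise ValueError(
                    f"layer {spec.name}: expected ({self.n_stimuli}, dim) "
                    f"matrix, got {mat.shape}")
            if mat.size and not np.isfinite(mat).all():
                raise ValueError(f"layer {spec.name}: non-finite activations")
        idx = [s.index for s in self.layers]
        if idx != list(range(len(idx))):
            raise ValueError("layer indices must be contiguous from 0")

    def layer_matrix(self, layer: int | str) -> np.ndarray:
        if isinstance(layer, str):
            for s, m in zip(self.layers, self.activations):
                if s.name == layer:
                    return m
            raise KeyError(layer)
        return self.activations[layer]

    def last_layer_of_kind(self, kind: str) -> LayerSpec:
        hits = [s for s in self.layers if s.kind == kind]
        if not hits:
            raise ValueError(f"no layer of kind {kind!r}")
        return hits[-1]


# ---------------------------------------------------------------------------
# preprocessing


def preprocess(image: np.ndarray, target_size: int = 224,
               channel_means: tuple = DEFAULT_CHANNEL_MEANS) -> np.ndarray:
    """Resize, replicate grayscale to RGB if needed, subtract channel means.

    Output is float and may leave [0, 255] after mean subtraction.
    """
    if target_size < 8:
        raise ValueError("target_size must be >= 8")
    arr = np.asarray(image, dtype=np.float64)
    if not np.isfinite(arr).all():
        raise ValueError("non-finite input image")
    means = np.asarray(channel_means, dtype=np.float64)
    if arr.ndim == 2 and means.ndim == 1 and means.size == 3:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[0] != target_size or arr.shape[1] != target_size:
        arr = _sk_resize(arr, (target_size, target_size),
                         order=1, preserve_range=True, anti_aliasing=False)
    return arr - means


# ---------------------------------------------------------------------------
# extraction


def validate_extractor(extractor) -> None:
    if not hasattr(extractor, "layers") or not hasattr(extractor, "transform"):
        raise TypeError("extractor must expose .layers and .transform(stimuli)")
    for k, spec in enumerate(extractor.layers):
        if not isinstance(spec, LayerSpec):
            raise TypeError(f"layers[{k}] is not a LayerSpec")
    if [s.index for s in extractor.layers] != list(range(len(extractor.layers))):
        raise ValueError("extractor layer indices must be contiguous from 0")


def extract(extractor, stimuli: StimulusSet) -> ActivationTable:
    """Run the extractor on every stimulus and validate the result table."""
    validate_extractor(extractor)
    mats = extractor.transform(stimuli)
    if len(mats) != len(extractor.layers):
        raise ValueError("extractor returned wrong number of layer matrices")
    out = []
    for spec, mat in zip(extractor.layers, mats):
        mat = np.asarray(mat)
        if mat.ndim != 2 or mat.shape[0] != len(stimuli):
            raise ValueError(
                f"layer {spec.name}: dimension mismatch across stimuli "
                f"(got {mat.shape}, expected ({len(stimuli)}, dim))")
        out.append(mat)
    return ActivationTable(list(extractor.layers), out, len(stimuli))


# ---------------------------------------------------------------------------
# pixel extractor


class _PixelExtractor:
    """Single input layer: unit activations proportional to pixel brightness."""

    def __init__(self) -> None:
        self.layers = [LayerSpec(0, "pixels", "input")]

    def transform(self, stimuli: StimulusSet) -> list[np.ndarray]:
        if len(stimuli) == 0:
            return [np.empty((0, 0))]
        mat = np.stack([np.asarray(im, dtype=np.float64).ravel()
                        for im in stimuli.images])
        return [mat]


def pixel_extractor() -> _PixelExtractor:
    return _PixelExtractor()


# ---------------------------------------------------------------------------
# reference convnet


class _ReferenceConvNet:
    """Small untrained convnet with seeded Gaussian fan-in-scaled weights.

    Architecture (input replicated to 3 channels, ``input_size``²):
    three conv(3×3, same) → relu → maxpool(2×2) blocks, then two fully
    connected layers with a relu in between.  Biases are zero; weight std
    is 1/sqrt(fan-in), which keeps activation magnitudes comparable across
    depth so selectivity analyses are nondegenerate.
    """

    def __init__(self, seed: int, width_scale: float = 1.0,
                 input_size: int = 64) -> None:
        if width_scale <= 0:
            raise ValueError("width_scale must be > 0")
        self.seed = seed
        self.input_size = input_size
        rng = np.random.default_rng(seed)
        chans = [max(1, int(round(c * width_scale))) for c in (8, 16, 32)]
        self._convs = []
        in_c = 3
        for c in chans:
            fan_in = 9 * in_c
            w = rng.normal(0.0, 1.0 / np.sqrt(fan_in), (3, 3, in_c, c))
            self._convs.append(w.astype(np.float32))
            in_c = c
        spatial = input_size // 8  # three 2× poolings
        flat = spatial * spatial * chans[-1]
        fc_dims = [max(4, int(round(64 * width_scale))),
                   max(2, int(round(32 * width_scale)))]
        self._fcs = []
        d_in = flat
        for d_out in fc_dims:
            w = rng.normal(0.0, 1.0 / np.sqrt(d_in), (d_in, d_out))
            self._fcs.append(w.astype(np.float32))
            d_in = d_out

        specs, k = [], 0
        for b in range(3):
            for kind in ("conv", "relu", "pool"):
                specs.append(LayerSpec(k, f"{kind}{b + 1}", kind))
                k += 1
        specs.append(LayerSpec(k, "fc1", "fc")); k += 1
        specs.append(LayerSpec(k, "relu_fc1", "relu")); k += 1
        specs.append(LayerSpec(k, "fc2", "fc"))
        self.layers = specs

    @staticmethod
    def _conv2d(x: np.ndarray, w: np.ndarray) -> np.ndarray:
        """Same-padded 3×3 convolution via im2col; x is (H, W, Cin)."""
        h, wd, cin = x.shape
        xp = np.pad(x, ((1, 1), (1, 1), (0, 0)))
        cols = np.empty((h, wd, 9 * cin), dtype=np.float32)
        k = 0
        for dy in range(3):
            for dx in range(3):
                cols[:, :, k * cin:(k + 1) * cin] = xp[dy:dy + h, dx:dx + wd]
                k += 1
        return cols.reshape(h * wd, 9 * cin) @ w.reshape(9 * cin, -1)

    @staticmethod
    def _maxpool(x: np.ndarray) -> np.ndarray:
        h, w, c = x.shape
        x = x[: h - h % 2, : w - w % 2]
        return x.reshape(h // 2, 2, w // 2, 2, c).max(axis=(1, 3))

    def _forward(self, image: np.ndarray) -> list[np.ndarray]:
        x = preprocess(image, self.input_size).astype(np.float32)
        acts = []
        for w in self._convs:
            h, wd, _ = x.shape
            x = self._conv2d(x, w).reshape(h, wd, -1)
            acts.append(x.ravel().copy())
            x = np.maximum(x, 0.0)
            acts.append(x.ravel().copy())
            x = self._maxpool(x)
            acts.append(x.ravel().copy())
        v = x.ravel()
        v = v @ self._fcs[0]
        acts.append(v.copy())
        v = np.maximum(v, 0.0)
        acts.append(v.copy())
        v = v @ self._fcs[1]
        acts.append(v.copy())
        return acts

    def transform(self, stimuli: StimulusSet) -> list[np.ndarray]:
        per_layer: list[list[np.ndarray]] = [[] for _ in self.layers]
        for im in stimuli.images:
            for k, a in enumerate(self._forward(im)):
                per_layer[k].append(a)
        out = []
        for k, vecs in enumerate(per_layer):
            if vecs:
                out.append(np.stack(vecs))
            else:
                out.append(np.empty((0, 0), dtype=np.float32))
        return out


def reference_convnet(seed: int = 0, width_scale: float = 1.0,
                      input_size: int = 64) -> _ReferenceConvNet:
    return _ReferenceConvNet(seed, width_scale, input_size)


# ---------------------------------------------------------------------------
# analytic surrogates


def _stable_key(k) -> int:
    """Process-independent integer key for a tag value (crc32, not hash())."""
    import zlib

    return zlib.crc32(repr(k).encode()) % (2 ** 31)


def _tag_vector(seed: int, key, n_units: int, lo=0.0, hi=1.0) -> np.ndarray:
    """Deterministic per-tag random vector (stable across call order)."""
    keys = key if isinstance(key, (tuple, list)) else [key]
    rng = np.random.default_rng([seed] + [_stable_key(k) for k in keys])
    return rng.uniform(lo, hi, n_units)


class _Surrogate:
    """Meta-tag-driven responder realizing a declared response law exactly."""

    KINDS = ("averager", "summer", "length_linear", "length_log",
             "global_only", "local_only", "size_ratio",
             "partsum_generative", "context_classifier")

    def __init__(self, model_kind: str, params: dict | None = None) -> None:
        if model_kind not in self.KINDS:
            raise ValueError(f"unknown surrogate kind {model_kind!r}")
        self.kind = model_kind
        self.params = dict(params or {})
        self.seed = int(self.params.get("seed", 0))
        self.n_units = int(self.params.get("n_units", 50))
        self.layers = [LayerSpec(0, f"surrogate_{model_kind}", "fc")]

    # -- helpers ----------------------------------------------------------
    def _need(self, meta: dict, key: str):
        if key not in meta:
            raise KeyError(
                f"surrogate {self.kind!r} requires meta tag {key!r}")
        return meta[key]

    def _singleton_response(self, member) -> np.ndarray:
        obj, loc = member
        return _tag_vector(self.seed, ("member", obj, loc), self.n_units)

    def _vector(self, meta: dict) -> np.ndarray:
        kind = self.kind
        if kind in ("averager", "summer"):
            members = self._need(meta, "members")
            parts = np.stack([self._singleton_response(m) for m in members])
            return parts.mean(axis=0) if kind == "averager" else parts.sum(axis=0)
        if kind in ("length_linear", "length_log"):
            L = float(self._need(meta, "length"))
            gains = _tag_vector(self.seed, "gains", self.n_units, 0.5, 1.5)
            base = L if kind == "length_linear" else np.log(L)
            return gains * base
        if kind == "global_only":
            return _tag_vector(self.seed, ("g", self._need(meta, "g")),
                               self.n_units)
        if kind == "local_only":
            return _tag_vector(self.seed, ("l", self._need(meta, "l")),
                               self.n_units)
        if kind == "size_ratio":
            s1 = float(self._need(meta, "s1"))
            s2 = float(self._need(meta, "s2"))
            gains = _tag_vector(self.seed, "ratio_gains", self.n_units, 0.5, 1.5)
            return gains * (s1 / s2)
        raise ValueError(
            f"surrogate {kind!r} does not produce activation vectors")

    # -- extractor contract ------------------------------------------------
    def transform(self, stimuli: StimulusSet) -> list[np.ndarray]:
        if len(stimuli) == 0:
            return [np.empty((0, self.n_units))]
        return [np.stack([self._vector(m) for m in stimuli.meta])]

    # -- part-sum generative distances -------------------------------------
    def distance_matrix(self, stimuli: StimulusSet,
                        indices: list[int]) -> np.ndarray:
        """Pairwise distances generated from chosen C/X/W coefficients.

        Reads ``left_part``/``right_part`` meta tags; only defined for the
        ``partsum_generative`` kind.  The generative world is the *natural*
        decomposition: for stimuli tagged ``set='unnatural'`` the distances
        are produced from latent part labels that do not coincide with the
        tagged ones (the unnatural labelling misreads the true parts), so a
        part-sum fit using the tagged labels is imperfect by construction.
        """
        if self.kind != "partsum_generative":
            raise ValueError("distance_matrix requires kind='partsum_generative'")
        from . import partsum

        n_parts = int(self.params.get("n_parts", 7))
        objects = []
        for i in indices:
            m = stimuli.meta[i]
            left = int(self._need(m, "left_part"))
            right = int(self._need(m, "right_part"))
            if m.get("set") == "unnatural":
                right = (left + right) % n_parts  # latent true part
            objects.append((left, right))
        coef = self.params.get("coefficients")
        if coef is None:
            rng = np.random.default_rng(self.seed)
            coef = partsum.random_coefficients(n_parts, rng)
        design = partsum.build_design(objects, n_parts)
        d = design.matrix @ coef
        n = len(objects)
        mat = np.zeros((n, n))
        for k, (a, b) in enumerate(design.pairs):
            mat[a, b] = mat[b, a] = d[k]
        return mat

    # -- context classifier -------------------------------------------------
    def class_probabilities(self, stimuli: StimulusSet) -> np.ndarray:
        """Softmax class scores with a boost when the context matches the label."""
        if self.kind != "context_classifier":
            raise ValueError("class_probabilities requires kind='context_classifier'")
        n_classes = int(self.params.get("n_classes", 0))
        if n_classes <= 0:
            n_classes = 1 + max(int(m["label"]) for m in stimuli.meta)
        boost = float(self.params.get("boost", 3.0))
        rows = []
        for m in stimuli.meta:
            label = int(self._need(m, "label"))
            logits = _tag_vector(self.seed, ("logits", label), n_classes,
                                 -1.0, 1.0)
            logits = logits.copy()
            logits[label] += 1.0  # the object itself is informative
            ctx = m.get("context_id")
            if ctx is not None and int(ctx) == label:
                logits[label] += boost
            e = np.exp(logits - logits.max())
            rows.append(e / e.sum())
        return np.stack(rows)


def surrogate_extractor(model_kind: str, params: dict | None = None) -> _Surrogate:
    return _Surrogate(model_kind, params)


def predict_class_probabilities(extractor, stimuli: StimulusSet) -> np.ndarray:
    """Class-probability rows (sum to 1) for a classifier-capable extractor."""
    if not hasattr(extractor, "class_probabilities"):
        raise TypeError("extractor does not produce class probabilities")
    probs = np.asarray(extractor.class_probabilities(stimuli))
    if probs.ndim != 2 or probs.shape[0] != len(stimuli):
        raise ValueError("malformed class-probability table")
    if (probs < 0).any() or not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("rows must be nonnegative and sum to 1")
    return probs


# ---------------------------------------------------------------------------
# activation cache


def save_table(table: ActivationTable, directory: str | Path,
               extractor_id: str = "", seed: int | None = None,
               stimulus_hash: str = "") -> Path:
    """Write one .npy per layer plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "extractor": extractor_id,
        "seed": seed,
        "stimulus_hash": stimulus_hash,
        "n_stimuli": table.n_stimuli,
        "layers": [{"index": s.index, "name": s.name, "kind": s.kind,
                    "dim": int(table.activations[s.index].shape[1])}
                   for s in table.layers],
    }
    for s in table.layers:
        np.save(directory / f"layer_{s.index:02d}.npy",
                table.activations[s.index])
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return directory


def load_table(directory: str | Path) -> ActivationTable:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    layers = [LayerSpec(d["index"], d["name"], d["kind"])
              for d in manifest["layers"]]
    acts = [np.load(directory / f"layer_{s.index:02d}.npy") for s in layers]
    return ActivationTable(layers, acts, manifest["n_stimuli"])
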