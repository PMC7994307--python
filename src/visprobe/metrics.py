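"""Shared numerical primitives: distances, contrast indices, sparseness,
unit selection, slope fits, and Weber correlations.

All per-layer experiment procedures reduce to a handful of operations
defined here.  The central quantity is the contrast index

    (d_a − d_b) / (d_a + d_b)  ∈  [−1, 1],

a normalized difference of two dissimilarities.  Items with d_a + d_b = 0
are undefined; they are excluded from aggregation and counted in an
exclusion tally rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.stats import pearsonr

from .features import LayerSpec

__all__ = [
    "ContrastPair",
    "IndexProfile",
    "WeberResult",
    "SparsenessRecord",
    "distance",
    "pairwise_distances",
    "contrast_index",
    "aggregate_profile",
    "select_visually_active",
    "normalize_unit",
    "sparseness",
    "sparseness_correlation",
    "fit_slope",
    "weber_correlations",
    "reciprocal_distance",
]

#: Relative variance tolerance below which a unit counts as non-varying.
VARIANCE_RTOL = 1e-12

_METRICS = ("euclidean", "cityblock", "correlation")


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class ContrastPair:
    """Two paired nonnegative dissimilarities for one item."""

    d_a: float
    d_b: float
    item_id: object = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.d_a) and np.isfinite(self.d_b)):
            raise ValueError("dissimilarities must be finite")
        if self.d_a < 0 or self.d_b < 0:
            raise ValueError("dissimilarities must be nonnegative")


@dataclass
class IndexProfile:
    """Per-layer mean index with s.e.m., item count, and exclusion tally."""

    layers: list[LayerSpec]
    mean: np.ndarray        # nan where undefined
    sem: np.ndarray
    n: np.ndarray           # defined items per layer
    excluded: np.ndarray    # undefined items per layer
    name: str = ""

    def defined(self, k: int) -> bool:
        return bool(np.isfinite(self.mean[k]))

    def at_layer(self, name: str) -> tuple[float, float, int]:
        for k, s in enumerate(self.layers):
            if s.name == name:
                return float(self.mean[k]), float(self.sem[k]), int(self.n[k])
        raise KeyError(name)

    def to_records(self, experiment: str = "") -> list[dict]:
        return [{
            "experiment": experiment or self.name,
            "layer_index": s.index,
            "layer_name": s.name,
            "layer_kind": s.kind,
            "mean": float(self.mean[k]),
            "sem": float(self.sem[k]),
            "n": int(self.n[k]),
            "excluded": int(self.excluded[k]),
        } for k, s in enumerate(self.layers)]


@dataclass
class WeberResult:
    """Per-layer correlations with absolute vs relative length differences."""

    layers: list[LayerSpec]
    r_abs: np.ndarray
    r_rel: np.ndarray

    @property
    def difference(self) -> np.ndarray:
        """r_rel − r_abs; positive indicates Weber's-law-like coding."""
        return self.r_rel - self.r_abs


@dataclass
class SparsenessRecord:
    """Sparseness of one unit on each stimulus subset it was scored on."""

    unit: int
    S: dict = field(default_factory=dict)     # subset name -> S
    n: dict = field(default_factory=dict)     # subset name -> n stimuli


# ---------------------------------------------------------------------------
# distances


def distance(x: np.ndarray, y: np.ndarray, metric: str = "euclidean") -> float:
    """Dissimilarity between two unit-response vectors.

    Metrics: ``euclidean`` (default), ``cityblock``, or ``correlation``
    (one minus Pearson).  The correlation metric is undefined for
    zero-variance vectors.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if metric == "correlation":
        if np.var(x) == 0 or np.var(y) == 0:
            raise ValueError("correlation distance undefined for "
                             "zero-variance vector")
        return float(1.0 - pearsonr(x, y)[0])
    if metric == "cityblock":
        return float(np.abs(x - y).sum())
    return float(np.linalg.norm(x - y))


def pairwise_distances(mat: np.ndarray, metric: str = "euclidean",
                       condensed: bool = False) -> np.ndarray:
    """All pairwise dissimilarities between rows of an activation matrix."""
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    d = pdist(np.asarray(mat, dtype=np.float64), metric=metric)
    return d if condensed else squareform(d)


def cross_distances(a: np.ndarray, b: np.ndarray,
                    metric: str = "euclidean") -> np.ndarray:
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    return cdist(np.asarray(a, np.float64), np.asarray(b, np.float64),
                 metric=metric)


# ---------------------------------------------------------------------------
# contrast index and aggregation


def contrast_index(pair: ContrastPair) -> float:
    """(d_a − d_b)/(d_a + d_b); nan (undefined) when both are zero."""
    total = pair.d_a + pair.d_b
    if total == 0:
        return float("nan")
    return (pair.d_a - pair.d_b) / total


def aggregate_profile(per_layer_indices: list[np.ndarray],
                      layers: list[LayerSpec], name: str = "") -> IndexProfile:
    """Mean and s.e.m. (sd/√n) of per-item indices, per layer.

    Undefined items (nan) are excluded and tallied; a layer with zero
    defined items is flagged undefined (mean nan), never silently dropped.
    """
    if len(per_layer_indices) != len(layers):
        raise ValueError("one index array required per layer")
    means = np.full(len(layers), np.nan)
    sems = np.zeros(len(layers))
    ns = np.zeros(len(layers), dtype=int)
    excl = np.zeros(len(layers), dtype=int)
    for k, vals in enumerate(per_layer_indices):
        vals = np.asarray(vals, dtype=np.float64)
        ok = np.isfinite(vals)
        ns[k] = int(ok.sum())
        excl[k] = int((~ok).sum())
        if ns[k] == 0:
            continue
        v = vals[ok]
        means[k] = v.mean()
        sems[k] = v.std(ddof=1) / np.sqrt(ns[k]) if ns[k] > 1 else 0.0
    return IndexProfile(list(layers), means, sems, ns, excl, name=name)


# ---------------------------------------------------------------------------
# unit selection and normalization


def select_visually_active(mat: np.ndarray,
                           subsets: list[np.ndarray] | None = None,
                           tol: float | None = None) -> np.ndarray:
    """Boolean mask of units with above-tolerance response variance.

    ``mat`` is (n_stimuli, n_units).  With ``subsets`` given (lists of row
    indices), a unit is kept only if it varies within *every* subset — the
    all-locations rule used for multi-object displays.  The default
    tolerance is relative to the mean-square response (exact zero variance
    is fragile in floating arithmetic).
    """
    mat = np.asarray(mat, dtype=np.float64)
    if subsets is None:
        subsets = [np.arange(mat.shape[0])]
    if any(len(s) == 0 for s in subsets):
        raise ValueError("empty subset")
    keep = np.ones(mat.shape[1], dtype=bool)
    for rows in subsets:
        sub = mat[np.asarray(rows)]
        var = sub.var(axis=0)
        if tol is None:
            scale = np.mean(sub ** 2, axis=0)
            thresh = VARIANCE_RTOL * np.maximum(scale, np.finfo(float).tiny)
        else:
            thresh = tol
        keep &= var > thresh
    return keep


def normalize_unit(responses: np.ndarray) -> np.ndarray:
    """Affinely map a unit's responses so min → 0 and max → 1."""
    r = np.asarray(responses, dtype=np.float64)
    lo, hi = r.min(), r.max()
    if hi == lo:
        raise ValueError("constant unit cannot be normalized; pre-filter it")
    return (r - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# sparseness


def sparseness(responses: np.ndarray, n: int | None = None) -> float:
    """Population sparseness S of a nonnegative response vector.

        S = (1 − (Σrᵢ/n)² / Σ(rᵢ²/n)) / (1 − 1/n)

    S = 0 for a uniform vector, S = 1 for a one-hot vector; invariant to
    positive rescaling.  Undefined (nan) for an all-zero vector.
    """
    r = np.asarray(responses, dtype=np.float64)
    if n is None:
        n = r.size
    if n < 2:
        raise ValueError("sparseness requires n >= 2")
    if (r < 0).any():
        raise ValueError("responses must be nonnegative (normalize first)")
    sum_sq = float(np.sum(r ** 2)) / n
    if sum_sq == 0:
        return float("nan")
    mean_sq = (float(np.sum(r)) / n) ** 2
    return (1.0 - mean_sq / sum_sq) / (1.0 - 1.0 / n)


def sparseness_correlation(records: list[SparsenessRecord],
                           subset_a: str, subset_b: str) -> float:
    """Pearson correlation of unit sparseness between two stimulus subsets.

    Units lacking a defined S on either subset are skipped; at least three
    units are required.  Returns nan when either side has zero variance.
    """
    a, b = [], []
    for rec in records:
        sa, sb = rec.S.get(subset_a), rec.S.get(subset_b)
        if sa is None or sb is None:
            continue
        if np.isfinite(sa) and np.isfinite(sb):
            a.append(sa)
            b.append(sb)
    if len(a) < 3:
        raise ValueError(f"need >= 3 units with defined S on "
                         f"{subset_a!r} and {subset_b!r}, got {len(a)}")
    a, b = np.asarray(a), np.asarray(b)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(pearsonr(a, b)[0])


# ---------------------------------------------------------------------------
# fits and conversions


def fit_slope(points) -> float:
    """Ordinary least-squares slope (free intercept) of (x, y) points."""
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need >= 2 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    vx = np.var(x)
    if vx == 0:
        raise ValueError("var(x) = 0: slope undefined")
    return float(np.cov(x, y, bias=True)[0, 1] / vx)


def weber_correlations(lengths: np.ndarray, dist_mat: np.ndarray,
                       layers: list[LayerSpec] | None = None) -> WeberResult:
    """Correlate pairwise dissimilarities with absolute vs relative Δlength.

    For lengths Lᵢ the predictors over unordered pairs are |Lᵢ−Lⱼ| and
    |Lᵢ−Lⱼ| / (0.5 (Lᵢ+Lⱼ)).  ``dist_mat`` may be a single (n, n) distance
    matrix or a stack of per-layer matrices (n_layers, n, n).
    """
    L = np.asarray(lengths, dtype=np.float64)
    if L.size < 4 or len(np.unique(L)) < 4:
        raise ValueError("need >= 4 distinct lengths (2 make the predictors "
                         "collinear)")
    iu = np.triu_indices(L.size, k=1)
    d_abs = np.abs(L[:, None] - L[None, :])[iu]
    d_rel = (d_abs / (0.5 * (L[:, None] + L[None, :]))[iu])
    if np.corrcoef(d_abs, d_rel)[0, 1] > 1 - 1e-12:
        raise ValueError("absolute and relative differences are collinear "
                         "for these lengths")
    mats = np.asarray(dist_mat, dtype=np.float64)
    single = mats.ndim == 2
    if single:
        mats = mats[None]
    r_abs = np.empty(mats.shape[0])
    r_rel = np.empty(mats.shape[0])
    for k, m in enumerate(mats):
        d = m[iu]
        r_abs[k] = pearsonr(d, d_abs)[0] if d.std() > 0 else np.nan
        r_rel[k] = pearsonr(d, d_rel)[0] if d.std() > 0 else np.nan
    if layers is None:
        layers = [LayerSpec(k, f"layer{k}", "fc") for k in range(mats.shape[0])]
    return WeberResult(list(layers), r_abs, r_rel)


def reciprocal_distance(t: float) -> float:
    """Convert a search time or slope (s) into a perceptual distance 1/t."""
    if not np.isfinite(t) or t <= 0:
        raise ValueError("time/slope must be positive and finite")
    return 1.0 / t
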