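"""Part-sum linear model of whole-object dissimilarity.

Two-part objects AB and CD (parts at an ordered left/right location) are
assumed to have a dissimilarity that decomposes additively over part
relations:

    d(AB, CD) = C_AC + C_BD + X_AD + X_BC + W_AB + W_CD + constant

where C terms couple corresponding parts (same location), X terms couple
parts at opposite locations across the two objects, and W terms couple the
two parts within each object.  With objects built from ``p`` parts there
are C(p, 2) distinct unordered part pairs per term family; for p = 7 and
the full 7×7 object set this yields C(49, 2) = 1176 equations in
3·21 + 1 = 64 unknowns, solved by least squares.

Same-part relations (e.g. C_AA when both objects carry the same part at a
location) are mapped to zero: a shared part at the same location adds no
dissimilarity.  This convention keeps exactly C(p, 2) columns per family.
Part-pair indices are canonicalized unordered (i ≤ j); locations are
ordered (part 1 = left).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

__all__ = [
    "PartSumDesign",
    "PartSumFit",
    "build_design",
    "fit",
    "predict",
    "evaluate",
    "random_coefficients",
    "generate_distances",
]

_FAMILIES = ("C", "X", "W")


def _pair_index(i: int, j: int, p: int) -> int | None:
    """Column offset of unordered part pair {i, j} among C(p,2); None if i==j."""
    if i == j:
        return None
    a, b = (i, j) if i < j else (j, i)
    # pairs enumerated (0,1),(0,2),...,(0,p-1),(1,2),...
    return a * p - a * (a + 1) // 2 + (b - a - 1)


@dataclass
class PartSumDesign:
    """Incidence matrix of part relations for every unordered object pair."""

    matrix: np.ndarray               # (n_pairs, 3*C(p,2) + 1)
    pairs: list[tuple[int, int]]     # row -> (object index a, object index b)
    objects: list[tuple[int, int]]   # object -> (left part, right part)
    part_count: int
    columns: list[str]               # labelled C_i_j / X_i_j / W_i_j / const

    @property
    def n_terms(self) -> int:
        return self.matrix.shape[1]

    def row_of(self, a: int, b: int) -> int:
        key = (a, b) if a < b else (b, a)
        return self.pairs.index(key)


def build_design(objects: list[tuple[int, int]], part_count: int) -> PartSumDesign:
    """One equation row per unordered object pair.

    ``objects`` are ordered (left part, right part) label pairs with part
    ids in ``0..part_count-1``.  Duplicate objects are rejected: their
    self-distance rows would be identically zero.
    """
    objects = [(int(a), int(b)) for a, b in objects]
    for a, b in objects:
        if not (0 <= a < part_count and 0 <= b < part_count):
            raise ValueError(f"part id out of range in object ({a}, {b})")
    if len(set(objects)) != len(objects):
        raise ValueError("duplicate objects in the design")
    p = part_count
    n_rel = p * (p - 1) // 2
    n_cols = 3 * n_rel + 1
    n_obj = len(objects)
    pairs = [(a, b) for a in range(n_obj) for b in range(a + 1, n_obj)]
    mat = np.zeros((len(pairs), n_cols))
    for row, (a, b) in enumerate(pairs):
        A, B = objects[a]
        C_, D = objects[b]
        terms = (("C", A, C_), ("C", B, D),    # corresponding locations
                 ("X", A, D), ("X", B, C_),    # across locations
                 ("W", A, B), ("W", C_, D))    # within objects
        for fam, i, j in terms:
            col = _pair_index(i, j, p)
            if col is None:
                continue  # same-part relation contributes 0
            mat[row, _FAMILIES.index(fam) * n_rel + col] += 1.0
        mat[row, -1] = 1.0
    columns = [f"{fam}_{i}_{j}"
               for fam in _FAMILIES
               for i in range(p) for j in range(i + 1, p)] + ["const"]
    return PartSumDesign(mat, pairs, objects, p, columns)


@dataclass
class PartSumFit:
    """Least-squares solution of a part-sum design."""

    design: PartSumDesign
    coefficients: np.ndarray
    predicted: np.ndarray
    observed: np.ndarray
    rank: int
    rank_deficient: bool

    @property
    def residuals(self) -> np.ndarray:
        return self.observed - self.predicted

    def coefficient(self, label: str) -> float:
        return float(self.coefficients[self.design.columns.index(label)])


def fit(design: PartSumDesign, distances: np.ndarray) -> PartSumFit:
    """Least-squares coefficients; minimum-norm (with a warning) when the
    design is rank-deficient."""
    d = np.asarray(distances, dtype=np.float64).ravel()
    if d.size != design.matrix.shape[0]:
        raise ValueError(f"{d.size} distances for {design.matrix.shape[0]} "
                         "design rows")
    if not np.isfinite(d).all():
        raise ValueError("distances must be finite")
    coef, _, rank, _ = np.linalg.lstsq(design.matrix, d, rcond=None)
    deficient = rank < design.matrix.shape[1]
    if deficient:
        warnings.warn("rank-deficient part-sum design: returning the "
                      "minimum-norm solution", RuntimeWarning, stacklevel=2)
    return PartSumFit(design, coef, design.matrix @ coef, d, int(rank),
                      deficient)


def predict(design: PartSumDesign, coefficients: np.ndarray) -> np.ndarray:
    return design.matrix @ np.asarray(coefficients, dtype=np.float64)


def evaluate(fit_: PartSumFit, eval_rows: list[int],
             observed: np.ndarray | None = None) -> float:
    """Pearson correlation of observed vs predicted on designated rows."""
    rows = np.asarray(eval_rows, dtype=int)
    if rows.size < 3:
        raise ValueError("need >= 3 evaluation pairs")
    obs = (fit_.observed if observed is None
           else np.asarray(observed, dtype=np.float64))[rows]
    pred = fit_.predicted[rows]
    return float(pearsonr(obs, pred)[0])


def random_coefficients(part_count: int, rng: np.random.Generator) -> np.ndarray:
    """Positive coefficient vector (C, X, W families plus constant)."""
    n_rel = part_count * (part_count - 1) // 2
    coef = rng.uniform(0.5, 2.0, 3 * n_rel + 1)
    coef[-1] = 1.0
    return coef


def generate_distances(design: PartSumDesign, coefficients: np.ndarray,
                       noise_sd: float = 0.0,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Distances implied by known coefficients, with optional Gaussian noise."""
    d = predict(design, coefficients)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        d = d + rng.normal(0.0, noise_sd, d.size)
    return d
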