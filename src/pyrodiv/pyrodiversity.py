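"""Pyrodiversity as abundance-weighted functional dispersion (FDis).

Each grid cell is an *individual*; a unique discretized combination of the
four fire-regime traits (a fire history) is a *species* x_j with abundance
a_j equal to its pixel count; a landscape unit is the *community*. Histories
are compared with a Gower dissimilarity (range-scaled mean absolute trait
difference, tolerant of missing traits), embedded by principal-coordinates
analysis, and summarized as the abundance-weighted mean distance z_j of each
history from the community's abundance-weighted centroid c:

    FDis = sum_j a_j z_j / sum_j a_j

FDis is unitless, zero exactly when a single history is present, independent
of the number of histories, and invariant to uniform rescaling of the
abundances. Negative PCoA eigenvalues (Gower dissimilarities are not
Euclidean-embeddable in general) are handled with the signed squared-distance
correction of the original FDis definition: squared centroid distances are
the positive-axis part minus the negative-axis part, floored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .fire_records import LandscapeUnit
from .trait_surfaces import TraitStack

__all__ = [
    "HistoryTable",
    "DispersionResult",
    "tabulate_histories",
    "history_distance",
    "fdis",
    "pyrodiversity_of_unit",
    "local_pyrodiversity",
    "functional_richness",
]

TRAIT_NAMES = ("fri", "severity", "season", "patch")

_EIG_TOL = 1e-10


@dataclass
class HistoryTable:
    """Unique fire histories ("species") with pixel-count abundances.

    ``histories`` is an (n, 4) array in trait order (fri, severity, season,
    patch); NaN marks a missing trait (e.g. season of a never-burned pixel).
    ``trait_ranges`` are the fixed (min, max) per trait used for Gower
    scaling; ``trait_weights`` default to equal.
    """

    histories: np.ndarray
    abundances: np.ndarray
    trait_ranges: np.ndarray
    trait_weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.histories = np.atleast_2d(np.asarray(self.histories, dtype=float))
        self.abundances = np.asarray(self.abundances)
        self.trait_ranges = np.asarray(self.trait_ranges, dtype=float)
        if self.trait_weights is None:
            self.trait_weights = np.ones(self.histories.shape[1])
        self.trait_weights = np.asarray(self.trait_weights, dtype=float)
        if self.histories.shape[0] != self.abundances.shape[0]:
            raise ValueError("histories and abundances must align")
        if np.any(self.abundances <= 0):
            raise ValueError("abundances must be positive")
        if np.any(self.trait_weights < 0):
            raise ValueError("trait weights must be non-negative")

    @property
    def n_histories(self) -> int:
        return self.histories.shape[0]

    @property
    def n_pixels(self) -> int:
        return int(self.abundances.sum())


@dataclass
class DispersionResult:
    fdis: float
    centroid: np.ndarray
    distances: np.ndarray
    n_histories: int
    n_pixels: int


def tabulate_histories(
    stack: TraitStack,
    unit: LandscapeUnit,
    trait_weights: np.ndarray | None = None,
) -> HistoryTable:
    """Build the community table for one landscape unit.

    Counts every grid cell whose center lies in the unit polygon
    (intersected with the unit's flammable mask when present) and keys
    histories on the discretized trait tuples; missing values stay missing.
    """
    mask = stack.grid.mask_polygon(unit.geometry)
    if unit.flammable_mask is not None:
        mask &= np.asarray(unit.flammable_mask, dtype=bool)
    if not mask.any():
        raise ValueError(f"unit {unit.unit_id}: no grid cell centers inside the unit")
    return _table_from_mask(stack, mask, trait_weights)


def _table_from_mask(
    stack: TraitStack, mask: np.ndarray, trait_weights: np.ndarray | None = None
) -> HistoryTable:
    cols = {name: arr[mask] for name, arr in stack.trait_arrays().items()}
    df = pd.DataFrame(cols)
    counts = df.groupby(list(TRAIT_NAMES), dropna=False, sort=False).size()
    hist = np.array(counts.index.to_list(), dtype=float)
    ranges = np.array([stack.trait_ranges()[t] for t in TRAIT_NAMES])
    return HistoryTable(
        histories=hist,
        abundances=counts.to_numpy(),
        trait_ranges=ranges,
        trait_weights=trait_weights,
    )


def history_distance(table: HistoryTable) -> np.ndarray:
    """Gower dissimilarity matrix between histories.

    Per trait: |difference| scaled by the trait's fixed global range; the
    matrix entry is the weighted mean over traits observed in *both*
    histories (missing-trait pairs are excluded and the weights
    renormalized). Values lie in [0, 1].
    """
    X = table.histories
    n, t = X.shape
    spans = table.trait_ranges[:, 1] - table.trait_ranges[:, 0]
    if np.any(spans <= 0):
        raise ValueError("trait ranges must have positive span")
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for k in range(t):
        w = table.trait_weights[k]
        if w == 0:
            continue
        x = X[:, k]
        ok = np.isfinite(x)
        both = np.outer(ok, ok)
        diff = np.abs(np.subtract.outer(np.where(ok, x, 0.0), np.where(ok, x, 0.0)))
        num += w * both * diff / spans[k]
        den += w * both
    if np.any(den == 0):
        i, j = np.argwhere(den == 0)[0]
        raise ValueError(
            f"histories {i} and {j} share no observed traits; distance undefined"
        )
    D = num / den
    np.fill_diagonal(D, 0.0)
    return D


def _pcoa_axes(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate axes of a dissimilarity matrix.

    Returns (coords, signs): real coordinates on all non-null axes and the
    sign (+1/-1) of each axis's eigenvalue. Negative eigenvalues are kept —
    their axes contribute *negatively* to squared distances (the signed
    pseudo-Euclidean embedding reproduces the input dissimilarities
    exactly).
    """
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = J @ A @ J
    vals, vecs = eigh((B + B.T) / 2.0)
    scale = max(np.abs(vals).max(), 1.0)
    keep = np.abs(vals) > _EIG_TOL * scale
    vals, vecs = vals[keep], vecs[:, keep]
    coords = vecs * np.sqrt(np.abs(vals))
    return coords, np.sign(vals)


def fdis(table: HistoryTable) -> DispersionResult:
    """Abundance-weighted functional dispersion of a history table."""
    a = np.asarray(table.abundances, dtype=float)
    n = table.n_histories
    if n == 1:
        return DispersionResult(0.0, np.zeros(0), np.zeros(1), 1, table.n_pixels)
    D = history_distance(table)
    coords, signs = _pcoa_axes(D)
    w = a / a.sum()
    centroid = w @ coords
    delta2 = signs * (coords - centroid) ** 2
    z = np.sqrt(np.maximum(delta2.sum(axis=1), 0.0))
    return DispersionResult(
        fdis=float(w @ z),
        centroid=centroid,
        distances=z,
        n_histories=n,
        n_pixels=table.n_pixels,
    )


def pyrodiversity_of_unit(
    stack: TraitStack, unit: LandscapeUnit, trait_weights: np.ndarray | None = None
) -> DispersionResult:
    """FDis of the fire histories within a landscape unit."""
    return fdis(tabulate_histories(stack, unit, trait_weights))


def local_pyrodiversity(
    stack: TraitStack, point: tuple[float, float], radius_m: float
) -> DispersionResult:
    """FDis over cells whose centers lie within ``radius_m`` of ``point``
    (e.g. around a field survey location)."""
    mask = stack.grid.mask_disc(point[0], point[1], radius_m)
    if not mask.any():
        raise ValueError("no grid cell centers within the requested radius")
    return fdis(_table_from_mask(stack, mask))


def functional_richness(table: HistoryTable) -> float:
    """Convex-hull volume of complete-case histories in range-scaled trait
    space — an optional diagnostic only: it is sensitive to outliers and to
    sample size, which is why dispersion, not richness, is the headline
    pyrodiversity metric here."""
    from scipy.spatial import ConvexHull, QhullError

    X = table.histories
    full = np.all(np.isfinite(X), axis=1)
    lo = table.trait_ranges[:, 0]
    span = table.trait_ranges[:, 1] - lo
    pts = (X[full] - lo) / span
    if pts.shape[0] <= pts.shape[1]:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        return 0.0
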