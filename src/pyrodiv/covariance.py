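"""Covariance of fire-regime trait dispersion across landscape units.

FDis is a multivariate analogue of the abundance-weighted mean absolute
deviation, so each trait's contribution can be examined separately: per
unit, the weighted MAD of each trait over the unit's history table. The
sweep then correlates those per-trait dispersions across units while
progressively excluding units with few recorded fires — the question being
whether a single trait (e.g. severity) can stand in for the others, and
whether that redundancy survives in actively burning landscapes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fire_records import FireRecordSet, LandscapeUnit
from .pyrodiversity import TRAIT_NAMES, tabulate_histories
from .trait_surfaces import TraitStack

__all__ = ["TraitDispersionRow", "trait_dispersions", "correlation_sweep"]

MIN_UNITS_FOR_CORRELATION = 3


@dataclass
class TraitDispersionRow:
    """Per-unit fire count and per-trait dispersion (weighted MAD)."""

    unit_id: str
    n_fires: int
    fri: float
    severity: float
    season: float
    patch: float

    def as_dict(self) -> dict:
        return vars(self).copy()


def _weighted_mad(values: np.ndarray, weights: np.ndarray) -> float:
    """Abundance-weighted mean absolute deviation from the weighted mean."""
    ok = np.isfinite(values)
    if not ok.any():
        return float("nan")
    v, w = values[ok], weights[ok].astype(float)
    mean = np.average(v, weights=w)
    return float(np.average(np.abs(v - mean), weights=w))


def trait_dispersions(
    stack: TraitStack, unit: LandscapeUnit, records: FireRecordSet
) -> TraitDispersionRow:
    """Univariate dispersion of each trait within one unit.

    Dispersion is the abundance-weighted MAD over the unit's history table,
    skipping missing values per trait; ``n_fires`` counts record events
    whose perimeter intersects the unit polygon (regardless of the burned
    fraction).
    """
    table = tabulate_histories(stack, unit)
    disp = {
        name: _weighted_mad(table.histories[:, k], table.abundances)
        for k, name in enumerate(TRAIT_NAMES)
    }
    n_fires = sum(1 for ev in records.events if ev.perimeter.intersects(unit.geometry))
    return TraitDispersionRow(unit_id=unit.unit_id, n_fires=n_fires, **disp)


def correlation_sweep(
    rows: Sequence[TraitDispersionRow],
    min_fires_range: Iterable[int] = range(1, 16),
    method: str = "pearson",
) -> pd.DataFrame:
    """Trait-dispersion correlations across units, per minimum-fire filter.

    For each threshold t, units with ``n_fires >= t`` are kept and every
    trait pair correlated across them. Long-format output with columns
    ``threshold, trait_a, trait_b, r, n_units, defined``; a pair is flagged
    undefined (``defined=False``, ``r=NaN``) when fewer than three units
    survive the filter or a dispersion column has zero variance, rather
    than letting NaN propagate silently.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    df = pd.DataFrame([r.as_dict() for r in rows])
    out = []
    for thr in min_fires_range:
        sub = df[df["n_fires"] >= thr]
        for ta, tb in combinations(TRAIT_NAMES, 2):
            pair = sub[[ta, tb]].dropna()
            defined = len(pair) >= MIN_UNITS_FOR_CORRELATION and (
                pair[ta].nunique() > 1 and pair[tb].nunique() > 1
            )
            r = float(corr(pair[ta], pair[tb])[0]) if defined else float("nan")
            out.append(
                {
                    "threshold": thr,
                    "trait_a": ta,
                    "trait_b": tb,
                    "r": r,
                    "n_units": len(pair),
                    "defined": defined,
                }
            )
    return pd.DataFrame(out)


def correlation_matrix(sweep: pd.DataFrame, threshold: int) -> pd.DataFrame:
    """Symmetric 4x4 correlation matrix at one threshold (unit diagonal)."""
    m = pd.DataFrame(np.eye(4), index=list(TRAIT_NAMES), columns=list(TRAIT_NAMES))
    sub = sweep[sweep["threshold"] == threshold]
    for _, row in sub.iterrows():
        m.loc[row["trait_a"], row["trait_b"]] = row["r"]
        m.loc[row["trait_b"], row["trait_a"]] = row["r"]
    return m


def plot_sweep(sweep: pd.DataFrame, ax=None):
    """Plain line plot of r against the minimum-fire threshold per pair."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for (ta, tb), grp in sweep.groupby(["trait_a", "trait_b"]):
        ax.plot(grp["threshold"], grp["r"], marker="o", label=f"{ta}-{tb}")
    ax.set_xlabel("minimum fires per unit")
    ax.set_ylabel("correlation of trait dispersion")
    ax.legend(fontsize="small")
    return ax
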