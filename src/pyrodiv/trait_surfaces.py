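"""Per-pixel fire-regime trait surfaces with recency-weighted averaging.

Four traits summarize each pixel's fire history over the record window:

* **fri** — fire return interval (years): the recency-weighted mean of the
  interval sequence formed by successive burn years plus the open intervals
  to the first and final year of the record (a minimum estimate of
  frequency, suited to relative comparison).
* **severity** — recency-weighted mean composite burn index (CBI, 0-3).
* **season** — recency-weighted mean of cos(2*pi*(doy-1)/365), so that the
  first and last days of the year are adjacent (-1 = mid-year, +1 = Jan 1).
* **patch** — recency-weighted mean of ln(patch area in ha), where patches
  are connected components of the four CBI severity classes within each
  event's mosaic.

Recency weighting is by *fire order*, not elapsed time (time-based weighting
would confound the weights with the frequency trait itself): the k-th most
recent value gets raw weight ``(1 - decay)**(k-1)``, normalized to sum to 1.
``decay=0`` weights all events equally, ``decay=1`` keeps only the most
recent, and the default 0.5 halves the weight of each successively older
event.

Trait values are discretized (round-half-even) at fixed precisions — whole
years, 0.1 cosine units, 0.5 CBI, 0.1 log-ha — to bound the number of
distinct fire histories downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .fire_records import FireRecordSet
from .grid import GridSpec, Raster, read_ascii_grid, write_ascii_grid

__all__ = [
    "DecayConfig",
    "TraitPrecision",
    "PixelHistory",
    "TraitStack",
    "recency_weights",
    "fri_trait",
    "season_trait",
    "severity_trait",
    "delineate_patches",
    "build_trait_stack",
]

#: default order-decay rate: each prior event gets half the weight of the next
DEFAULT_DECAY = 0.5

#: CBI class breaks separating unchanged / low / moderate / high severity
SEVERITY_CLASS_BREAKS = (0.1, 1.25, 2.25)


@dataclass(frozen=True)
class DecayConfig:
    decay: float = DEFAULT_DECAY

    def __post_init__(self) -> None:
        if not 0.0 <= self.decay <= 1.0:
            raise ValueError(f"decay must lie in [0, 1], got {self.decay}")


@dataclass(frozen=True)
class TraitPrecision:
    """Discretization step of each trait (units: years, CBI, cosine, log-ha)."""

    fri: float = 1.0
    severity: float = 0.5
    season: float = 0.1
    patch: float = 0.1


@dataclass
class PixelHistory:
    """Aligned per-event records for one pixel, most-recent-first."""

    burn_years: list[int]
    severities: list[float]
    ignition_doys: list[int]
    patch_log_ha: list[float]

    def __post_init__(self) -> None:
        n = len(self.burn_years)
        if not (len(self.severities) == len(self.ignition_doys) == len(self.patch_log_ha) == n):
            raise ValueError("history lists must be aligned")
        if any(a <= b for a, b in zip(self.burn_years, self.burn_years[1:])):
            raise ValueError("burn_years must be strictly decreasing (most recent first)")


def recency_weights(n_events: int, decay: float) -> np.ndarray:
    """Normalized order-decay weights, most-recent-first.

    Raw weight of the k-th most recent event is ``(1 - decay)**(k-1)``; the
    vector is normalized to sum to one. This is the unique one-parameter
    geometric family with equal weights at ``decay=0``, successive halving
    at ``decay=0.5``, and most-recent-only at ``decay=1``.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if not 0.0 <= decay <= 1.0:
        raise ValueError(f"decay must lie in [0, 1], got {decay}")
    raw = (1.0 - decay) ** np.arange(n_events)
    return raw / raw.sum()


def _round_to(x, precision: float):
    """Round-half-even at a fixed precision (banker's rounding via np.round)."""
    return np.round(np.asarray(x, dtype=float) / precision) * precision


def fri_trait(
    burn_years: list[int] | np.ndarray,
    record_start: int,
    record_end: int,
    decay: float,
    precision: float = 1.0,
) -> float:
    """Recency-weighted fire return interval in (rounded) years.

    With burns y_1 < ... < y_n inside [record_start, record_end], the
    interval sequence, most-recent-first, is
    ``(record_end - y_n), (y_n - y_{n-1}), ..., (y_1 - record_start)``:
    the open interval since the last fire counts as the most recent so the
    current regime state dominates under recency weighting.
    """
    years = np.sort(np.asarray(burn_years, dtype=float))
    if years.size == 0:
        raise ValueError("fri_trait requires at least one burn year")
    if years[0] < record_start or years[-1] > record_end:
        raise ValueError("burn years must lie within the record window")
    bounds = np.concatenate(([record_start], years, [record_end]))
    intervals = np.diff(bounds)[::-1]  # most recent interval first
    w = recency_weights(intervals.size, decay)
    return float(_round_to(np.dot(w, intervals), precision))


def season_trait(
    ignition_doys: list[int] | np.ndarray, decay: float, precision: float = 0.1
) -> float:
    """Recency-weighted mean of the cosine-transformed ignition date.

    Day-of-year d maps to ``cos(2*pi*(d-1)/365)`` so Dec 31 and Jan 1 are
    adjacent on the cycle; a leap day (doy 366) wraps onto the Jan-1 value.
    """
    doys = np.asarray(ignition_doys, dtype=float)
    vals = np.cos(2.0 * np.pi * (doys - 1.0) / 365.0)
    w = recency_weights(vals.size, decay)
    return float(_round_to(np.dot(w, vals), precision))


def severity_trait(
    cbis: list[float] | np.ndarray, decay: float, precision: float = 0.5
) -> float:
    """Recency-weighted mean CBI, rounded to the nearest ``precision`` (0.5)."""
    vals = np.asarray(cbis, dtype=float)
    if vals.size and (vals.min() < 0.0 or vals.max() > 3.0):
        raise ValueError("CBI values must lie in [0, 3]")
    w = recency_weights(vals.size, decay)
    return float(np.clip(_round_to(np.dot(w, vals), precision), 0.0, 3.0))


def delineate_patches(
    severity: Raster,
    class_breaks: tuple[float, ...] = SEVERITY_CLASS_BREAKS,
    precision: float = 0.1,
) -> Raster:
    """Per-cell log patch size for one event's severity mosaic.

    The severity surface (NaN outside the burn) is classified into the
    unchanged / low / moderate / high CBI classes; connected components are
    found per class with 8-connectivity (diagonal neighbours connect); every
    burned cell is assigned ``ln(component area in ha)``, rounded
    half-even at ``precision`` log-ha.
    """
    data = severity.data
    valid = np.isfinite(data)
    classes = np.digitize(data, class_breaks)  # 0..len(breaks), NaN -> last bin
    out = np.full(data.shape, np.nan)
    structure = np.ones((3, 3), dtype=bool)  # 8-connectivity
    cell_ha = severity.grid.cell_area_ha
    for cls in range(len(class_breaks) + 1):
        mask = valid & (classes == cls)
        if not mask.any():
            continue
        labels, n = ndimage.label(mask, structure=structure)
        if n == 0:
            continue
        counts = np.bincount(labels.ravel())
        log_ha = np.full(n + 1, np.nan)
        log_ha[1:] = np.log(counts[1:] * cell_ha)
        out[mask] = log_ha[labels[mask]]
    return Raster(_round_to(out, precision), severity.grid)


@dataclass
class TraitStack:
    """The four aligned trait grids plus their provenance.

    Unburned cells carry ``fri = record length`` (the whole window passed
    without fire — a minimum-interval convention), ``severity = 0`` (no
    vegetation change) and missing (NaN) season and patch (no event to
    characterize).
    """

    fri: np.ndarray
    severity: np.ndarray
    season: np.ndarray
    patch: np.ndarray
    grid: GridSpec
    record_start: int
    record_end: int
    decay: float = DEFAULT_DECAY
    precision: TraitPrecision = field(default_factory=TraitPrecision)
    patch_range: tuple[float, float] = (-2.5, 13.0)

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.fri, self.severity, self.season, self.patch)}
        if shapes != {self.grid.shape}:
            raise ValueError("trait grids must all match the grid shape")

    @property
    def record_length(self) -> int:
        return self.record_end - self.record_start

    def trait_arrays(self) -> dict[str, np.ndarray]:
        return {
            "fri": self.fri,
            "severity": self.severity,
            "season": self.season,
            "patch": self.patch,
        }

    def trait_ranges(self) -> dict[str, tuple[float, float]]:
        """Fixed global scaling ranges used by the Gower distance downstream.

        Global (not per-unit) ranges keep dispersion values comparable
        across landscape units in a regional analysis.
        """
        return {
            "fri": (0.0, float(self.record_length)),
            "severity": (0.0, 3.0),
            "season": (-1.0, 1.0),
            "patch": self.patch_range,
        }

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, arr in self.trait_arrays().items():
            write_ascii_grid(out_dir / f"{name}.asc", Raster(arr, self.grid))
        meta = {
            "record_start": self.record_start,
            "record_end": self.record_end,
            "decay": self.decay,
            "precision": vars(self.precision),
            "patch_range": list(self.patch_range),
            "grid": self.grid.to_dict(),
        }
        with open(out_dir / "meta.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def read(cls, in_dir: str | Path) -> "TraitStack":
        in_dir = Path(in_dir)
        with open(in_dir / "meta.json") as fh:
            meta = json.load(fh)
        grid = GridSpec.from_dict(meta["grid"])
        arrs = {n: read_ascii_grid(in_dir / f"{n}.asc").data
                for n in ("fri", "severity", "season", "patch")}
        return cls(
            grid=grid,
            record_start=meta["record_start"],
            record_end=meta["record_end"],
            decay=meta["decay"],
            precision=TraitPrecision(**meta["precision"]),
            patch_range=tuple(meta["patch_range"]),
            **arrs,
        )


def build_trait_stack(
    records: FireRecordSet,
    grid: GridSpec | None = None,
    decay: DecayConfig | float = DEFAULT_DECAY,
    precision: TraitPrecision | None = None,
    patch_range: tuple[float, float] = (-2.5, 13.0),
    unburned_fri: int | None = None,
) -> TraitStack:
    """Assemble the four trait surfaces from a fire record set.

    Events are rasterized onto the analysis grid (cell-center rule), each
    event's severity mosaic is patch-delineated, and every burned pixel's
    history is reduced with the shared decay. Input event order is
    irrelevant: histories are rebuilt most-recent-first internally.

    ``unburned_fri`` overrides the return interval assigned to never-burned
    pixels; the default is the record span ``record_end - record_start``
    (33 for a 1985-2018 window — use 34 for an inclusive year count).
    """
    if isinstance(decay, DecayConfig):
        decay = decay.decay
    if not 0.0 <= decay <= 1.0:
        raise ValueError(f"decay must lie in [0, 1], got {decay}")
    prec = precision or TraitPrecision()
    grid = grid or records.grid

    # rasterize most-recent-first so per-pixel event lists come out ordered
    events = sorted(records.events, key=lambda e: e.sort_key, reverse=True)
    npix = grid.nrows * grid.ncols
    burned_lists: dict[int, dict[str, list]] = {}
    from .fire_records import rasterize_event

    for ev in events:
        mask, sev = rasterize_event(ev, grid)
        if not mask.any():
            continue
        patch = delineate_patches(
            Raster(np.where(mask, sev, np.nan), grid), precision=prec.patch
        ).data
        idx = np.flatnonzero(mask.ravel())
        sev_flat = sev.ravel()
        patch_flat = patch.ravel()
        for p in idx:
            h = burned_lists.setdefault(p, {"y": [], "s": [], "d": [], "pl": []})
            h["y"].append(ev.year)
            h["s"].append(float(sev_flat[p]))
            h["d"].append(ev.ignition_doy)
            h["pl"].append(float(patch_flat[p]))

    record_len = (
        unburned_fri
        if unburned_fri is not None
        else records.record_end - records.record_start
    )
    fri = np.full(npix, float(_round_to(record_len, prec.fri)))
    severity = np.zeros(npix)
    season = np.full(npix, np.nan)
    patch_arr = np.full(npix, np.nan)
    for p, h in burned_lists.items():
        fri[p] = fri_trait(h["y"], records.record_start, records.record_end,
                           decay, precision=prec.fri)
        severity[p] = severity_trait(np.clip(h["s"], 0.0, 3.0), decay,
                                     precision=prec.severity)
        season[p] = season_trait(h["d"], decay, precision=prec.season)
        w = recency_weights(len(h["pl"]), decay)
        patch_arr[p] = float(_round_to(np.dot(w, h["pl"]), prec.patch))

    shape = grid.shape
    return TraitStack(
        fri=fri.reshape(shape),
        severity=severity.reshape(shape),
        season=season.reshape(shape),
        patch=patch_arr.reshape(shape),
        grid=grid,
        record_start=records.record_start,
        record_end=records.record_end,
        decay=decay,
        precision=prec,
        patch_range=patch_range,
    )
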