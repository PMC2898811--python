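"""Study-region geometry: cells, populations, strata, nearest-neighbour order.

A study region is a set of administrative cells, each with a population
(optionally broken down by stratum) and, for each cell, a ranking of all
other cells by increasing centroid distance.  Tests combine a cell with its
``ell`` nearest neighbours; this module supplies those combined populations
and event totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RegionData",
    "EventCounts",
    "order_neighbours",
    "combined_population",
    "combined_events",
]

_EARTH_RADIUS_KM = 6371.0088


def _haversine_matrix(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Great-circle distance matrix (km) from decimal-degree coordinates."""
    phi = np.radians(lat)[:, None]
    lam = np.radians(lon)[:, None]
    dphi = phi - phi.T
    dlam = lam - lam.T
    a = np.sin(dphi / 2) ** 2 + np.cos(phi) * np.cos(phi.T) * np.sin(dlam / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def order_neighbours(
    cell_ids: Sequence[str],
    *,
    coordinates: np.ndarray | None = None,
    distances: np.ndarray | None = None,
    metric: str = "haversine",
) -> np.ndarray:
    """Rank every other cell by increasing distance from each cell.

    Parameters
    ----------
    cell_ids : sequence of unique identifiers (length I).
    coordinates : (I, 2) array; ``(lat, lon)`` in decimal degrees when
        ``metric='haversine'``, planar ``(x, y)`` when ``metric='euclidean'``.
    distances : (I, I) symmetric non-negative matrix; overrides coordinates.
    metric : 'haversine' or 'euclidean'.

    Returns
    -------
    (I, I) integer array; row ``i`` is ``(i, i_1, ..., i_{I-1})`` with the
    own cell first and the rest sorted by increasing distance.  Distance
    ties are broken by ascending cell identifier for reproducibility.
    """
    ids = list(cell_ids)
    I = len(ids)
    if len(set(ids)) != I:
        raise ValueError("duplicate cell ids")
    if distances is not None:
        d = np.asarray(distances, dtype=float)
        if d.shape != (I, I):
            raise ValueError(f"distance matrix must be {I}x{I}, got {d.shape}")
        if np.any(np.isnan(d)) or np.any(d < 0):
            raise ValueError("distance matrix must be complete and non-negative")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
    elif coordinates is not None:
        xy = np.asarray(coordinates, dtype=float)
        if xy.shape != (I, 2) or np.any(np.isnan(xy)):
            raise ValueError("coordinates must be a complete (I, 2) array")
        if metric == "haversine":
            d = _haversine_matrix(xy[:, 0], xy[:, 1])
        elif metric == "euclidean":
            diff = xy[:, None, :] - xy[None, :, :]
            d = np.sqrt((diff**2).sum(axis=-1))
        else:
            raise ValueError(f"unknown metric {metric!r}")
    else:
        raise ValueError("either coordinates or distances must be supplied")

    # ties broken by the (string) identifier, then stable-sorted by distance
    id_rank = np.argsort(np.argsort(np.asarray(ids, dtype=object)))
    order = np.empty((I, I), dtype=int)
    for i in range(I):
        others = np.array([j for j in range(I) if j != i], dtype=int)
        by_id = others[np.argsort(id_rank[others], kind="stable")]
        order[i, 0] = i
        order[i, 1:] = by_id[np.argsort(d[i, by_id], kind="stable")]
    return order


@dataclass(frozen=True)
class RegionData:
    """Cells, populations (optionally per-stratum) and neighbour ordering.

    ``populations`` has shape (I, S); ``strata`` is None for unstratified
    data (then S == 1).  ``neighbour_order`` row ``i`` is the permutation
    ``(i, i_1, ..., i_{I-1})`` of all cells, nearest first after the cell
    itself.
    """

    cell_ids: tuple[str, ...]
    populations: np.ndarray
    neighbour_order: np.ndarray
    strata: tuple[str, ...] | None = None

    def __post_init__(self):
        ids = tuple(str(c) for c in self.cell_ids)
        object.__setattr__(self, "cell_ids", ids)
        I = len(ids)
        if I < 1 or len(set(ids)) != I:
            raise ValueError("cell_ids must be non-empty and unique")
        pops = np.asarray(self.populations)
        if pops.ndim == 1:
            pops = pops[:, None]
        if pops.shape[0] != I:
            raise ValueError("populations and cell_ids length mismatch")
        if np.any(pops < 0) or not np.issubdtype(pops.dtype, np.integer):
            if not np.all(pops == np.floor(pops)) or np.any(pops < 0):
                raise ValueError("populations must be non-negative integers")
            pops = pops.astype(int)
        object.__setattr__(self, "populations", pops)
        if self.strata is not None:
            if len(self.strata) != pops.shape[1]:
                raise ValueError("strata labels and population columns mismatch")
            object.__setattr__(self, "strata", tuple(str(s) for s in self.strata))
        elif pops.shape[1] != 1:
            raise ValueError("multi-column populations require strata labels")
        order = np.asarray(self.neighbour_order, dtype=int)
        if order.shape != (I, I):
            raise ValueError(f"neighbour_order must be {I}x{I}")
        for i in range(I):
            if order[i, 0] != i or set(order[i]) != set(range(I)):
                raise ValueError(
                    f"neighbour_order row {i} is not a self-first permutation"
                )
        object.__setattr__(self, "neighbour_order", order)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_strata(self) -> int:
        return self.populations.shape[1]

    @property
    def cell_populations(self) -> np.ndarray:
        """Total population per cell, summed over strata."""
        return self.populations.sum(axis=1)

    @property
    def total_population(self) -> int:
        return int(self.populations.sum())

    def index_of(self, cell_id: str) -> int:
        try:
            return self.cell_ids.index(cell_id)
        except ValueError:
            raise KeyError(f"unknown cell id {cell_id!r}") from None


@dataclass(frozen=True)
class EventCounts:
    """Per-cell event data: a case-by-event-count histogram and/or totals.

    ``case_histogram`` has shape (I, S, Y): ``case_histogram[i, s, y-1]`` is
    the number of cases in cell ``i``, stratum ``s``, with exactly ``y``
    events.  When only aggregate event totals are known, ``case_histogram``
    is None and ``aggregate_events`` (shape (I, S)) must be given; then only
    the aggregate-event analysis (and the case analysis, if ``case_totals``
    is supplied) is possible.
    """

    case_histogram: np.ndarray | None = None
    aggregate_events: np.ndarray | None = None
    case_totals: np.ndarray | None = None

    def __post_init__(self):
        hist = self.case_histogram
        agg = self.aggregate_events
        if hist is None and agg is None:
            raise ValueError("either case_histogram or aggregate_events required")
        if hist is not None:
            hist = np.asarray(hist)
            if hist.ndim == 2:  # (I, Y) unstratified
                hist = hist[:, None, :]
            if hist.ndim != 3:
                raise ValueError("case_histogram must have shape (I, S, Y)")
            if np.any(hist < 0) or not np.all(hist == np.floor(hist)):
                raise ValueError("case counts must be non-negative integers")
            hist = hist.astype(int)
            object.__setattr__(self, "case_histogram", hist)
            y = np.arange(1, hist.shape[2] + 1)
            derived = (hist * y).sum(axis=2)
            if agg is not None:
                agg = np.asarray(agg)
                if agg.ndim == 1:
                    agg = agg[:, None]
                if not np.array_equal(agg, derived):
                    raise ValueError(
                        "aggregate_events inconsistent with case_histogram"
                    )
            agg = derived
        agg = np.asarray(agg)
        if agg.ndim == 1:
            agg = agg[:, None]
        if agg.ndim != 2 or np.any(agg < 0) or not np.all(agg == np.floor(agg)):
            raise ValueError("aggregate_events must be non-negative integers (I, S)")
        object.__setattr__(self, "aggregate_events", agg.astype(int))
        if self.case_totals is not None:
            ct = np.asarray(self.case_totals)
            if ct.ndim == 1:
                ct = ct[:, None]
            if np.any(ct < 0) or not np.all(ct == np.floor(ct)):
                raise ValueError("case_totals must be non-negative integers")
            object.__setattr__(self, "case_totals", ct.astype(int))

    @property
    def n_cells(self) -> int:
        return self.aggregate_events.shape[0]

    @property
    def n_strata(self) -> int:
        return self.aggregate_events.shape[1]

    @property
    def max_events_per_case(self) -> int:
        return 0 if self.case_histogram is None else self.case_histogram.shape[2]

    @property
    def events_per_cell(self) -> np.ndarray:
        """v_i: event total per cell, summed over strata."""
        return self.aggregate_events.sum(axis=1)

    @property
    def total_events(self) -> int:
        return int(self.aggregate_events.sum())

    @property
    def cases_per_cell(self) -> np.ndarray:
        """c_i: case total per cell (requires histogram or explicit totals)."""
        if self.case_histogram is not None:
            return self.case_histogram.sum(axis=(1, 2))
        if self.case_totals is not None:
            return self.case_totals.sum(axis=1)
        raise ValueError("case counts are not available (aggregate events only)")

    @property
    def total_cases(self) -> int:
        return int(self.cases_per_cell.sum())

    @property
    def class_marginals(self) -> np.ndarray:
        """C_{.ys}: region-wide case counts by event class, shape (S, Y)."""
        if self.case_histogram is None:
            raise ValueError("case histogram is not available")
        return self.case_histogram.sum(axis=0)


def _check_ell(region: RegionData, ell: int) -> int:
    ell = int(ell)
    if not 0 <= ell <= region.n_cells - 1:
        raise ValueError(f"ell must be in [0, {region.n_cells - 1}], got {ell}")
    return ell


def combined_population(
    region: RegionData, i: int, ell: int, stratum: int | None = None
):
    """Population of cell ``i`` and its ``ell`` nearest neighbours.

    Returns a scalar (total or single-stratum) or, with ``stratum=None`` on
    stratified data, the per-stratum vector n_{i:ell, s}.
    """
    ell = _check_ell(region, ell)
    members = region.neighbour_order[i, : ell + 1]
    pops = region.populations[members].sum(axis=0)
    if stratum is not None:
        return int(pops[stratum])
    return int(pops[0]) if region.n_strata == 1 else pops


def combined_events(
    region: RegionData,
    events: EventCounts,
    i: int,
    ell: int,
    stratum: int | None = None,
):
    """Event total over cell ``i`` and its ``ell`` nearest neighbours."""
    ell = _check_ell(region, ell)
    members = region.neighbour_order[i, : ell + 1]
    v = events.aggregate_events[members].sum(axis=0)
    if stratum is not None:
        return int(v[stratum])
    return int(v[0]) if events.n_strata == 1 else v
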