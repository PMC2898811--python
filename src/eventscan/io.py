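"""CSV readers/writers and input validation.

All inputs are plain UTF-8 CSV with a header row.  Identifiers are opaque
strings.

cells file      cell_id, [stratum,] population, [lat, lon | x, y]
                (one row per cell, or per cell x stratum)
distance file   square matrix: first column cell_id, remaining columns one
                per cell id
neighbours file cell_id, rank, neighbour_id   (rank 1 = closest)
events file     cell_id, [stratum,] y, count   (case histogram), or
                cell_id, [stratum,] events     (aggregate totals)
scenario file   y, probability
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cluster import ClusterTestResult
from .distributions import ScenarioDistribution
from .region import EventCounts, RegionData, order_neighbours

__all__ = [
    "CellTable",
    "read_cells",
    "read_distance_matrix",
    "read_neighbours",
    "read_events",
    "read_scenario",
    "load_region",
    "results_to_frame",
    "write_results",
]


class InputError(ValueError):
    """A named validation failure in an input file."""


@dataclass(frozen=True)
class CellTable:
    """Parsed cells file: ids, populations (I, S), optional coordinates."""

    cell_ids: tuple[str, ...]
    populations: np.ndarray
    strata: tuple[str, ...] | None
    coordinates: np.ndarray | None
    metric: str | None


def _read_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cell_id": str})
    df.columns = [c.strip().lower() for c in df.columns]
    if "cell_id" not in df.columns:
        raise InputError(f"{path}: missing required column 'cell_id'")
    return df


def read_cells(path) -> CellTable:
    df = _read_csv(path)
    if "population" not in df.columns:
        raise InputError(f"{path}: missing required column 'population'")
    if (df["population"] < 0).any():
        raise InputError(f"{path}: negative population")
    if "lat" in df.columns and "lon" in df.columns:
        coord_cols, metric = ("lat", "lon"), "haversine"
    elif "x" in df.columns and "y" in df.columns:
        coord_cols, metric = ("x", "y"), "euclidean"
    else:
        coord_cols, metric = None, None

    stratified = "stratum" in df.columns
    if stratified:
        dup = df.duplicated(subset=["cell_id", "stratum"])
        if dup.any():
            raise InputError(f"{path}: duplicate (cell_id, stratum) rows")
        cell_ids = tuple(df["cell_id"].drop_duplicates())
        strata = tuple(sorted(df["stratum"].astype(str).unique()))
        pivot = df.pivot_table(
            index="cell_id", columns="stratum", values="population",
            aggfunc="sum", fill_value=0,
        ).reindex(index=cell_ids, columns=strata, fill_value=0)
        pops = pivot.to_numpy(dtype=int)
    else:
        if df["cell_id"].duplicated().any():
            raise InputError(f"{path}: duplicate cell_id rows")
        cell_ids = tuple(df["cell_id"])
        strata = None
        pops = df["population"].to_numpy(dtype=int)[:, None]

    coords = None
    if coord_cols is not None:
        sub = df.drop_duplicates(subset="cell_id").set_index("cell_id")
        coords = sub.loc[list(cell_ids), list(coord_cols)].to_numpy(dtype=float)
        if np.any(np.isnan(coords)):
            missing = [cid for cid, bad in zip(cell_ids, np.isnan(coords).any(axis=1)) if bad]
            raise InputError(f"{path}: missing coordinates for cells {missing}")
    return CellTable(cell_ids, pops, strata, coords, metric)


def read_distance_matrix(path, cell_ids: Sequence[str]) -> np.ndarray:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    missing = set(cell_ids) - set(df.index) | set(cell_ids) - set(df.columns)
    if missing:
        raise InputError(f"{path}: distance matrix missing cells {sorted(missing)}")
    d = df.loc[list(cell_ids), list(cell_ids)].to_numpy(dtype=float)
    if np.any(np.isnan(d)):
        raise InputError(f"{path}: incomplete distance matrix")
    return d


def read_neighbours(path, cell_ids: Sequence[str]) -> np.ndarray:
    """Explicit ordering file; overrides any distance computation."""
    df = _read_csv(path)
    for col in ("rank", "neighbour_id"):
        if col not in df.columns:
            raise InputError(f"{path}: missing required column {col!r}")
    idx = {cid: k for k, cid in enumerate(cell_ids)}
    I = len(cell_ids)
    order = np.full((I, I), -1, dtype=int)
    order[:, 0] = np.arange(I)
    for cid, grp in df.groupby("cell_id"):
        if cid not in idx:
            raise InputError(f"{path}: unknown cell id {cid!r}")
        grp = grp.sort_values("rank")
        ranks = grp["rank"].to_numpy()
        if not np.array_equal(ranks, np.arange(1, I)):
            raise InputError(f"{path}: ranks for cell {cid!r} are not 1..{I - 1}")
        for r, nid in zip(ranks, grp["neighbour_id"].astype(str)):
            if nid not in idx:
                raise InputError(f"{path}: unknown neighbour id {nid!r}")
            order[idx[cid], r] = idx[nid]
    if (order < 0).any():
        bad = [cell_ids[i] for i in np.nonzero((order < 0).any(axis=1))[0]]
        raise InputError(f"{path}: no (or incomplete) neighbour ordering for {bad}")
    return order


def load_region(cells_path, distances_path=None, neighbours_path=None) -> RegionData:
    """Assemble a region from a cells file plus one source of ordering."""
    table = read_cells(cells_path)
    if neighbours_path is not None:
        order = read_neighbours(neighbours_path, table.cell_ids)
    elif distances_path is not None:
        d = read_distance_matrix(distances_path, table.cell_ids)
        order = order_neighbours(table.cell_ids, distances=d)
    elif table.coordinates is not None:
        order = order_neighbours(
            table.cell_ids, coordinates=table.coordinates, metric=table.metric
        )
    else:
        raise InputError(
            f"{cells_path}: no coordinates; a distance matrix or neighbours file is required"
        )
    return RegionData(table.cell_ids, table.populations, order, table.strata)


def read_events(path, region: RegionData) -> EventCounts:
    df = _read_csv(path)
    idx = {cid: k for k, cid in enumerate(region.cell_ids)}
    unknown = set(df["cell_id"]) - set(idx)
    if unknown:
        raise InputError(f"{path}: unknown cell ids {sorted(unknown)}")
    stratified = "stratum" in df.columns
    if stratified:
        if region.strata is None:
            raise InputError(f"{path}: events are stratified but the cells file is not")
        sidx = {s: k for k, s in enumerate(region.strata)}
        unknown_s = set(df["stratum"].astype(str)) - set(sidx)
        if unknown_s:
            raise InputError(f"{path}: unknown strata {sorted(unknown_s)}")
        srows = df["stratum"].astype(str).map(sidx).to_numpy()
    else:
        srows = np.zeros(len(df), dtype=int)
    S = region.n_strata if stratified else 1
    crows = df["cell_id"].map(idx).to_numpy()

    if "y" in df.columns and "count" in df.columns:
        if "events" in df.columns:
            raise InputError(f"{path}: mixing histogram ('y','count') and aggregate ('events') columns")
        if (df["count"] < 0).any() or (df["y"] < 1).any():
            raise InputError(f"{path}: counts must be non-negative and y >= 1")
        key_cols = ["cell_id", "stratum", "y"] if stratified else ["cell_id", "y"]
        if df.duplicated(subset=key_cols).any():
            raise InputError(f"{path}: duplicate {tuple(key_cols)} rows")
        Y = int(df["y"].max())
        hist = np.zeros((region.n_cells, S, Y), dtype=int)
        np.add.at(hist, (crows, srows, df["y"].to_numpy(dtype=int) - 1), df["count"].to_numpy(dtype=int))
        return EventCounts(case_histogram=hist)
    if "events" in df.columns:
        if (df["events"] < 0).any():
            raise InputError(f"{path}: negative event counts")
        agg = np.zeros((region.n_cells, S), dtype=int)
        np.add.at(agg, (crows, srows), df["events"].to_numpy(dtype=int))
        return EventCounts(aggregate_events=agg)
    raise InputError(
        f"{path}: expected histogram columns ('y', 'count') or aggregate column 'events'"
    )


def read_scenario(path, event_rate: float = 2e-3) -> ScenarioDistribution:
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("y", "probability"):
        if col not in df.columns:
            raise InputError(f"{path}: missing required column {col!r}")
    y = df["y"].to_numpy(dtype=int)
    if (y < 1).any() or len(set(y)) != len(y):
        raise InputError(f"{path}: y values must be unique integers >= 1")
    probs = np.zeros(int(y.max()))
    probs[y - 1] = df["probability"].to_numpy(dtype=float)
    return ScenarioDistribution(tuple(probs), event_rate=event_rate)


def results_to_frame(results: Sequence[ClusterTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in results],
            "method": [r.method for r in results],
            "k_star": [r.k_star for r in results],
            "ell": [r.ell for r in results],
            "observed": [r.observed for r in results],
            "expected": [round(r.expected, 1) for r in results],
            "oe_ratio": [round(r.oe_ratio, 1) for r in results],
            "p_value": [round(r.p_value, 3) for r in results],
            "p_value_full": [r.p_value for r in results],
            "significant": [r.significant for r in results],
            "w_stopped": [r.w_stopped for r in results],
        }
    )


def write_results(results: Sequence[ClusterTestResult], path) -> None:
    results_to_frame(results).to_csv(path, index=False)
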