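"""Per-cell cluster tests: statistic, cluster-size prescription, sequential testing.

Each cell is tested by combining it with nearest neighbours until a
pre-specified cluster size ``k*`` of events (or cases) is reached; the test
statistic ``ell`` is the number of neighbours needed, and the p-value is the
exact upper-tail probability of at least ``k*`` counts in the combined
population under the chosen null.  Four methods are supported:

* ``hc``  -- hypergeometric case analysis (counts are cases),
* ``ee``  -- exact event analysis (multiple hypergeometric),
* ``cpe`` -- compound Poisson event analysis,
* ``ae``  -- aggregate event analysis (occupancy numbers).

Cluster sizes are chosen per cell and per combination depth ``w`` as the
smallest ``k`` whose null upper tail is at most the nominal level ``alpha``
(the tail attained there is the effective level ``alpha*``); the sequential
scheme then tests at ``k*_i(0)``, and only if non-significant at
``k*_i(1)``, and so on, reporting the last test performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .distributions import (
    CompoundPoissonNull,
    EventClassMarginals,
    HypergeomCaseNull,
    MultipleHypergeomNull,
    OccupancyNull,
    ScenarioDistribution,
    StratifiedEventNull,
    StratifiedOccupancyNull,
)
from .region import EventCounts, RegionData, combined_population

__all__ = [
    "METHODS",
    "ClusterSizePlan",
    "ClusterTestResult",
    "build_null",
    "test_statistic",
    "significance",
    "choose_cluster_sizes",
    "sequential_test",
    "test_region",
]

METHODS = ("hc", "ee", "cpe", "ae")


@dataclass(frozen=True)
class ClusterSizePlan:
    """Per-cell, per-depth cluster sizes and their effective levels.

    ``k_star[i][j]`` is the cluster size for cell ``i`` at depth
    ``w_values[j]`` (the cell combined with ``w`` nearest neighbours);
    ``effective_alpha[i][j]`` is the null upper tail attained at that size.
    """

    alpha: float
    w_values: tuple[int, ...]
    method: str
    k_star: np.ndarray  # (I, len(w_values)) int
    effective_alpha: np.ndarray  # (I, len(w_values)) float


@dataclass(frozen=True)
class ClusterTestResult:
    """Outcome of the (sequential) test for one cell."""

    cell_id: str
    method: str
    k_star: int
    ell: int
    observed: int
    expected: float
    p_value: float
    significant: bool
    w_stopped: int
    threshold_reached: bool = True

    @property
    def oe_ratio(self) -> float:
        return self.observed / self.expected if self.expected > 0 else np.nan


def _method_counts(events: EventCounts, method: str) -> tuple[np.ndarray, int]:
    """Per-cell counts the method tests (cases for hc, events otherwise)."""
    if method == "hc":
        counts = events.cases_per_cell
    else:
        counts = events.events_per_cell
    return counts, int(counts.sum())


def build_null(
    region: RegionData,
    events: EventCounts,
    method: str,
    *,
    stratified: bool = False,
    scenario: ScenarioDistribution | None = None,
    cases_total: float | None = None,
):
    """Construct the method's null distribution object for this data set.

    For ``cpe`` the event-per-case distribution defaults to the observed
    class frequencies ``C_y / c`` and the case total to the observed ``c``;
    both can be overridden (``cases_total`` may be non-integer when derived
    from a rate).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    n = region.total_population
    if method == "hc":
        if stratified:
            raise ValueError("the case analysis has no stratified variant")
        return HypergeomCaseNull(events.total_cases, n)
    if method == "ae":
        if stratified:
            return StratifiedOccupancyNull(
                events.aggregate_events.sum(axis=0), region.populations.sum(axis=0)
            )
        return OccupancyNull(events.total_events, n)
    if events.case_histogram is None:
        raise ValueError(
            f"the {method.upper()} analysis requires the case-by-event-count "
            "histogram; only aggregate events were supplied"
        )
    if method == "ee":
        marg = events.class_marginals  # (S, Y)
        if stratified:
            return StratifiedEventNull(
                [
                    EventClassMarginals(tuple(marg[s]), int(region.populations[:, s].sum()))
                    for s in range(region.n_strata)
                ]
            )
        return MultipleHypergeomNull(EventClassMarginals(tuple(marg.sum(axis=0)), n))
    # cpe
    if stratified:
        raise ValueError("the compound Poisson analysis has no stratified variant")
    c = events.total_cases if cases_total is None else float(cases_total)
    if scenario is None:
        cls = events.class_marginals.sum(axis=0)
        scenario = ScenarioDistribution(tuple(cls / cls.sum()))
    return CompoundPoissonNull(scenario, c, n)


def test_statistic(
    region: RegionData, events: EventCounts, i: int, k_star: int, method: str = "ee"
) -> int | None:
    """Smallest number of nearest neighbours whose combination with cell
    ``i`` holds at least ``k_star`` events (cases for ``hc``); ``None`` when
    even the whole region falls short."""
    if k_star < 1:
        raise ValueError("k_star must be >= 1")
    counts, _ = _method_counts(events, method)
    cum = np.cumsum(counts[region.neighbour_order[i]])
    hits = np.nonzero(cum >= k_star)[0]
    return int(hits[0]) if hits.size else None


def _sample_size(region: RegionData, i: int, ell: int, stratified: bool):
    """m for the null: total combined population, or the per-stratum vector."""
    m = combined_population(region, i, ell)
    if stratified:
        return np.atleast_1d(m)
    return int(np.sum(m))


def significance(
    region: RegionData,
    events: EventCounts,
    i: int,
    k_star: int,
    ell: int,
    method: str = "ee",
    *,
    stratified: bool = False,
    null=None,
) -> float:
    """Exact p-value: upper-tail probability of at least ``k_star`` counts in
    the population of cell ``i`` combined with its ``ell`` nearest
    neighbours, under the method's null."""
    if null is None:
        null = build_null(region, events, method, stratified=stratified)
    return float(null.tail(k_star, _sample_size(region, i, ell, stratified)))


def _smallest_k(null, m, alpha: float) -> tuple[int, float]:
    """Smallest k >= 1 with upper tail <= alpha, and the tail attained."""
    max_count = getattr(null, "max_count", None)
    k = max(1, int(np.floor(null.mean(m))))
    # walk down then up so the scan starts near the bulk of the distribution
    while k > 1 and null.tail(k - 1, m) <= alpha:
        k -= 1
    while null.tail(k, m) > alpha:
        k += 1
        if max_count is not None and k > max_count:
            return k, 0.0
    return k, float(null.tail(k, m))


def choose_cluster_sizes(
    region: RegionData,
    events: EventCounts,
    alpha: float,
    method: str = "ee",
    w_values: Sequence[int] = (0, 1, 2),
    *,
    stratified: bool = False,
    null=None,
) -> ClusterSizePlan:
    """Cluster sizes k*_i(w): the smallest count whose null upper tail in the
    population of cell ``i`` plus its ``w`` nearest neighbours is <= alpha."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    w_values = tuple(int(w) for w in w_values)
    if any(w < 0 or w > region.n_cells - 1 for w in w_values):
        raise ValueError("w_values out of range")
    if null is None:
        null = build_null(region, events, method, stratified=stratified)
    I = region.n_cells
    k_star = np.zeros((I, len(w_values)), dtype=int)
    eff = np.zeros((I, len(w_values)))
    cache: dict = {}
    for i in range(I):
        for j, w in enumerate(w_values):
            m = _sample_size(region, i, w, stratified)
            key = tuple(np.atleast_1d(m).tolist())
            if key not in cache:
                cache[key] = _smallest_k(null, m, alpha)
            k_star[i, j], eff[i, j] = cache[key]
    return ClusterSizePlan(alpha, w_values, method, k_star, eff)


def sequential_test(
    region: RegionData,
    events: EventCounts,
    i: int,
    plan: ClusterSizePlan,
    *,
    stratified: bool = False,
    null=None,
) -> ClusterTestResult:
    """Test cell ``i`` at k*_i(w) for each depth in ascending order, stopping
    at the first significant result; otherwise the last test is reported."""
    if null is None:
        null = build_null(region, events, plan.method, stratified=stratified)
    counts, total = _method_counts(events, plan.method)
    n = region.total_population
    order = region.neighbour_order[i]
    cum = np.cumsum(counts[order])
    result = None
    for j, w in enumerate(plan.w_values):
        k = int(plan.k_star[i, j])
        hits = np.nonzero(cum >= k)[0]
        if hits.size:
            ell = int(hits[0])
            m = _sample_size(region, i, ell, stratified)
            p = float(null.tail(k, m))
            reached = True
        else:
            ell = region.n_cells - 1
            p = 1.0
            reached = False
        m_total = int(np.sum(_sample_size(region, i, ell, True)))
        result = ClusterTestResult(
            cell_id=region.cell_ids[i],
            method=plan.method,
            k_star=k,
            ell=ell,
            observed=int(cum[ell]),
            expected=m_total * total / n if n else np.nan,
            p_value=p,
            significant=p <= plan.alpha,
            w_stopped=w,
            threshold_reached=reached,
        )
        if result.significant:
            break
    return result


def test_region(
    region: RegionData,
    events: EventCounts,
    alpha: float = 0.05,
    method: str = "ee",
    *,
    w_values: Sequence[int] = (0, 1, 2),
    stratified: bool = False,
    plan: ClusterSizePlan | None = None,
    scenario: ScenarioDistribution | None = None,
    cases_total: float | None = None,
) -> tuple[list[ClusterTestResult], int]:
    """Run the sequential test on every cell.

    Returns the per-cell results (in cell order) and R_alpha, the number of
    cells significant at level ``alpha``.
    """
    null = build_null(
        region, events, method, stratified=stratified,
        scenario=scenario, cases_total=cases_total,
    )
    if plan is None:
        plan = choose_cluster_sizes(
            region, events, alpha, method, w_values, stratified=stratified, null=null
        )
    results = [
        sequential_test(region, events, i, plan, stratified=stratified, null=null)
        for i in range(region.n_cells)
    ]
    return results, sum(r.significant for r in results)
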