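"""Exact null distributions for counts of events (or cases) in a population sample.

Under the null hypothesis that every individual in the region is equally
likely to have events, independent of location, the number of events falling
in a sample of ``m`` of the ``n`` individuals follows one of four families,
depending on what is known about the event data:

* cases only           -> hypergeometric (``HypergeomCaseNull``)
* events per case      -> multiple hypergeometric (``MultipleHypergeomNull``)
* events per case,
  parametric model     -> compound Poisson (``CompoundPoissonNull``)
* aggregate events     -> occupancy-number counting (``OccupancyNull``)

Stratified variants condition the sampling within each population stratum and
convolve the per-stratum distributions.

All distributions expose ``pmf_array(m)`` (the full mass function on
``0..max_count``) and ``tail(k, m)`` (the upper-tail probability
``P(X >= k)``), the quantity the cluster tests consume.  Binomial
coefficients are evaluated through log-gamma and combined with log-sum-exp
for numerical stability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "EventClassMarginals",
    "ScenarioDistribution",
    "HypergeomCaseNull",
    "MultipleHypergeomNull",
    "CompoundPoissonNull",
    "OccupancyNull",
    "StratifiedEventNull",
    "StratifiedOccupancyNull",
    "hypergeom_pmf",
    "multiple_hypergeom_pmf",
    "multiple_hypergeom_tail",
    "compound_poisson_pmf",
    "occupancy_pmf",
    "stratified_pmf",
    "stratified_occupancy_pmf",
]

_LOG2 = np.log(2.0)


def _log_binom(a, b):
    """log C(a, b) with -inf outside the support 0 <= b <= a."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    out = np.full(np.broadcast(a, b).shape, -np.inf)
    ok = (b >= 0) & (b <= a)
    if np.any(ok):
        aa = np.where(ok, a, 1.0)
        bb = np.where(ok, b, 0.0)
        vals = gammaln(aa + 1) - gammaln(bb + 1) - gammaln(aa - bb + 1)
        out = np.where(ok, vals, out)
    return out if out.ndim else float(out)


def _check_count(name: str, value, allow_zero: bool = True) -> int:
    v = int(value)
    if v != value:
        raise ValueError(f"{name} must be an integer, got {value!r}")
    if v < 0 or (v == 0 and not allow_zero):
        raise ValueError(f"{name} must be {'non-negative' if allow_zero else 'positive'}, got {value!r}")
    return v


@dataclass(frozen=True)
class EventClassMarginals:
    """Region-wide case counts by number of events.

    ``class_counts[y-1]`` is the number of cases in the whole region with
    exactly ``y`` events, ``y = 1..Y``; ``total_population`` is the number of
    individuals the cases are drawn from.
    """

    class_counts: tuple[int, ...]
    total_population: int

    def __post_init__(self):
        counts = tuple(_check_count(f"class_counts[{i}]", c) for i, c in enumerate(self.class_counts))
        object.__setattr__(self, "class_counts", counts)
        object.__setattr__(self, "total_population", _check_count("total_population", self.total_population))
        if self.total_cases > self.total_population:
            raise ValueError("total cases exceed total population")

    @property
    def max_class(self) -> int:
        return len(self.class_counts)

    @property
    def total_cases(self) -> int:
        return int(sum(self.class_counts))

    @property
    def total_events(self) -> int:
        return int(sum((y + 1) * c for y, c in enumerate(self.class_counts)))


@dataclass(frozen=True)
class ScenarioDistribution:
    """Probability Q(y) that a case has exactly y events, plus an event rate.

    ``probabilities[y-1] = Q(y)`` on a finite support ``y = 1..Y``.  The
    ``event_rate`` is the expected number of events per unit population
    (e.g. ``2e-3`` for 2 events per 1000 population).
    """

    probabilities: tuple[float, ...]
    event_rate: float = 2e-3
    name: str = ""

    def __post_init__(self):
        q = np.asarray(self.probabilities, dtype=float)
        if q.ndim != 1 or q.size == 0:
            raise ValueError("probabilities must be a non-empty 1-D sequence")
        if np.any(q < 0):
            raise ValueError("probabilities must be non-negative")
        total = q.sum()
        if not np.isclose(total, 1.0, atol=5e-3):
            raise ValueError(f"probabilities sum to {total}, not 1")
        if not np.isclose(total, 1.0, atol=1e-12):
            warnings.warn(
                f"scenario probabilities sum to {total:.6g}; renormalizing",
                stacklevel=2,
            )
            q = q / total
        if self.event_rate < 0:
            raise ValueError("event_rate must be non-negative")
        object.__setattr__(self, "probabilities", tuple(q))

    @property
    def max_events_per_case(self) -> int:
        return len(self.probabilities)

    @property
    def mean_events_per_case(self) -> float:
        return float(sum((y + 1) * p for y, p in enumerate(self.probabilities)))


class HypergeomCaseNull:
    """Hypergeometric null for the number of cases in a population sample.

    With ``c`` cases among ``n`` individuals, the number of cases among
    ``m`` sampled individuals is hypergeometric.
    """

    def __init__(self, total_cases: int, total_population: int):
        self.c = _check_count("total_cases", total_cases)
        self.n = _check_count("total_population", total_population)
        if self.c > self.n:
            raise ValueError("total_cases exceeds total_population")
        self.max_count = self.c
        self._cache: dict[int, np.ndarray] = {}

    def pmf_array(self, m: int) -> np.ndarray:
        m = _check_count("m", m)
        if m > self.n:
            raise ValueError("sample population m exceeds total population")
        if m not in self._cache:
            x = np.arange(self.c + 1)
            logp = (
                _log_binom(self.c, x)
                + _log_binom(self.n - self.c, m - x)
                - _log_binom(self.n, m)
            )
            self._cache[m] = np.exp(logp)
        return self._cache[m]

    def pmf(self, x: int, m: int) -> float:
        x = _check_count("x", x)
        p = self.pmf_array(m)
        return float(p[x]) if x <= self.c else 0.0

    def tail(self, k: int, m: int) -> float:
        return _tail_from_pmf(self.pmf_array(m), k)

    def mean(self, m: int) -> float:
        return m * self.c / self.n if self.n else 0.0


def _tail_from_pmf(pmf: np.ndarray, k: int) -> float:
    """P(X >= k) from a dense pmf on 0..len-1, summing the shorter side."""
    k = int(k)
    if k <= 0:
        return 1.0
    if k >= pmf.size:
        return 0.0
    if k > pmf.size // 2:
        return float(min(1.0, pmf[k:].sum()))
    return float(max(0.0, 1.0 - pmf[:k].sum()))


class MultipleHypergeomNull:
    """Multiple-hypergeometric null for the number of events in a sample.

    The region holds ``C_y`` cases with exactly ``y`` events (``y = 1..Y``)
    among ``n`` individuals; the remaining ``n - c`` individuals have none.
    Sampling ``m`` individuals without replacement, the total number of
    events ``X = sum_y y * r_y`` (``r_y`` sampled from class ``y``) has mass

        M(x, m) = sum_{r} prod_y C(C_y, r_y) * C(n-c, m-t) / C(n, m),

    over non-negative ``r_y <= C_y`` with ``sum_y y*r_y = x`` and
    ``t = sum_y r_y``.

    The sum is evaluated by convolving the classes one at a time into the
    joint weight ``W[t, x] = sum prod_y C(C_y, r_y) / 2^c`` (each class
    kernel normalized to a Binomial(C_y, 1/2) mass so the accumulator stays
    in [0, 1]), stored once, then combined with the ``m``-dependent
    log-binomial terms by log-sum-exp for each requested sample size.
    """

    def __init__(self, marginals: EventClassMarginals):
        self.marginals = marginals
        self.n = marginals.total_population
        self.c = marginals.total_cases
        self.v = marginals.total_events
        self.max_count = self.v
        self._log_joint = self._build_log_joint()  # shape (c+1, v+1)
        self._cache: dict[int, np.ndarray] = {}

    def _build_log_joint(self) -> np.ndarray:
        from scipy.stats import binom

        W = np.ones((1, 1))
        # larger classes first keeps the running grid small while looping
        # over the new class's kernel
        order = sorted(
            range(self.marginals.max_class),
            key=lambda j: self.marginals.class_counts[j],
            reverse=True,
        )
        t_max = x_max = 0
        for j in order:
            cy = self.marginals.class_counts[j]
            if cy == 0:
                continue
            y = j + 1
            kernel = binom.pmf(np.arange(cy + 1), cy, 0.5)
            new = np.zeros((t_max + cy + 1, x_max + y * cy + 1))
            for r in range(cy + 1):
                if kernel[r] > 0.0:
                    new[r : r + t_max + 1, y * r : y * r + x_max + 1] += kernel[r] * W
            W = new
            t_max += cy
            x_max += y * cy
        full = np.zeros((self.c + 1, self.v + 1))
        full[: t_max + 1, : x_max + 1] = W
        with np.errstate(divide="ignore"):
            return np.log(full)

    def pmf_array(self, m: int) -> np.ndarray:
        m = _check_count("m", m)
        if m > self.n:
            raise ValueError("sample population m exceeds total population")
        if m not in self._cache:
            t = np.arange(self.c + 1)
            log_rest = _log_binom(self.n - self.c, m - t)  # (c+1,)
            log_terms = self._log_joint + log_rest[:, None]
            logp = logsumexp(log_terms, axis=0) + self.c * _LOG2 - _log_binom(self.n, m)
            self._cache[m] = np.exp(logp)
        return self._cache[m]

    def pmf(self, x: int, m: int) -> float:
        x = _check_count("x", x)
        p = self.pmf_array(m)
        return float(p[x]) if x <= self.v else 0.0

    def tail(self, k: int, m: int) -> float:
        return _tail_from_pmf(self.pmf_array(m), k)

    def mean(self, m: int) -> float:
        return m * self.v / self.n if self.n else 0.0


class CompoundPoissonNull:
    """Compound Poisson null for the number of events in a sample.

    The number of cases among ``m`` sampled individuals is modelled as
    Poisson with rate ``m * c / n`` and each case contributes an independent
    number of events drawn from ``Q``.  The mass function is evaluated with
    the Panjer recursion for compound Poisson sums:

        P(0) = exp(-lam),  P(x) = (lam / x) * sum_y y Q(y) P(x - y).

    ``total_cases`` may be non-integer (a rate), as when ``c = v / E[Q]`` is
    derived from an event rate.
    """

    def __init__(
        self,
        scenario: ScenarioDistribution,
        total_cases: float,
        total_population: int,
        tol: float = 1e-12,
    ):
        if total_cases < 0:
            raise ValueError("total_cases must be non-negative")
        self.scenario = scenario
        self.c = float(total_cases)
        self.n = _check_count("total_population", total_population)
        self.tol = float(tol)
        self._cache: dict[int, np.ndarray] = {}
        self.max_count = None  # unbounded support

    def _rate(self, m: int) -> float:
        return m * self.c / self.n if self.n else 0.0

    def pmf_array(self, m: int, upto: int | None = None) -> np.ndarray:
        """Mass on 0..x_max where the truncated tail is below ``tol``.

        ``upto`` extends the array at least that far regardless of coverage.
        """
        m = _check_count("m", m)
        if m > self.n:
            raise ValueError("sample population m exceeds total population")
        cached = self._cache.get(m)
        if cached is not None and (upto is None or cached.size > upto):
            return cached
        lam = self._rate(m)
        q = np.asarray(self.scenario.probabilities)
        yq = np.arange(1, q.size + 1) * q
        out = [np.exp(-lam)]
        total = out[0]
        x = 0
        target = 1.0 - self.tol
        while total < target or (upto is not None and x < upto):
            x += 1
            ymax = min(x, q.size)
            acc = 0.0
            for y in range(1, ymax + 1):
                acc += yq[y - 1] * out[x - y]
            out.append(lam * acc / x)
            total += out[-1]
            if x > 10_000_000:  # pragma: no cover - guard against runaway support
                raise RuntimeError("compound Poisson support did not converge")
        arr = np.asarray(out)
        self._cache[m] = arr
        return arr

    def pmf(self, x: int, m: int) -> float:
        x = _check_count("x", x)
        p = self.pmf_array(m, upto=x)
        return float(p[x]) if x < p.size else 0.0

    def tail(self, k: int, m: int) -> float:
        k = int(k)
        if k <= 0:
            return 1.0
        p = self.pmf_array(m, upto=k - 1)
        return float(max(0.0, 1.0 - p[:k].sum()))

    def mean(self, m: int) -> float:
        return self._rate(m) * self.scenario.mean_events_per_case


def _occ_log_ways(individuals: int, events: int) -> float | np.ndarray:
    """log of the number of ways to distribute ``events`` indistinguishable
    events among ``individuals`` people: C(u + e - 1, e), with the empty
    convention that 0 people can hold only 0 events."""
    u = np.asarray(individuals)
    e = np.asarray(events)
    out = _log_binom(u + e - 1, e)
    out = np.where((u == 0) & (e == 0), 0.0, out)
    out = np.where((u == 0) & (e > 0), -np.inf, out)
    return out if np.ndim(out) else float(out)


class OccupancyNull:
    """Occupancy-number null for aggregate events in a sample.

    When only the total number of events ``V`` among ``n`` individuals is
    known, events are treated as indistinguishable and every arrangement of
    the ``V`` events among the ``n`` individuals is taken as equally likely.
    The number landing on ``m`` sampled individuals has mass

        A(x, m) = C(m+x-1, x) * C(n-m+V-x-1, V-x) / C(n+V-1, V).
    """

    def __init__(self, total_events: int, total_population: int):
        self.v = _check_count("total_events", total_events)
        self.n = _check_count("total_population", total_population, allow_zero=False)
        self.max_count = self.v
        self._cache: dict[int, np.ndarray] = {}

    def pmf_array(self, m: int) -> np.ndarray:
        m = _check_count("m", m)
        if m > self.n:
            raise ValueError("sample population m exceeds total population")
        if m not in self._cache:
            x = np.arange(self.v + 1)
            logp = (
                _occ_log_ways(m, x)
                + _occ_log_ways(self.n - m, self.v - x)
                - _occ_log_ways(self.n, self.v)
            )
            self._cache[m] = np.exp(logp)
        return self._cache[m]

    def pmf(self, x: int, m: int) -> float:
        x = _check_count("x", x)
        p = self.pmf_array(m)
        return float(p[x]) if x <= self.v else 0.0

    def tail(self, k: int, m: int) -> float:
        return _tail_from_pmf(self.pmf_array(m), k)

    def mean(self, m: int) -> float:
        return m * self.v / self.n


class _StratifiedConvolution:
    """Convolution across strata of independent per-stratum nulls.

    Within each stratum the sample is drawn without replacement from that
    stratum's own population, so the per-stratum counts are independent and
    the total is their convolution.  ``m`` is a per-stratum vector of sample
    populations.
    """

    def __init__(self, parts: Sequence):
        if not parts:
            raise ValueError("at least one stratum required")
        self.parts = list(parts)
        self.max_count = int(sum(p.max_count for p in self.parts))
        self._cache: dict[tuple[int, ...], np.ndarray] = {}

    def pmf_array(self, m: Sequence[int]) -> np.ndarray:
        m = np.atleast_1d(np.asarray(m))
        if m.size != len(self.parts):
            raise ValueError(
                f"expected {len(self.parts)} per-stratum sample sizes, got {m.size}"
            )
        key = tuple(int(v) for v in m)
        if key not in self._cache:
            pmf = np.ones(1)
            for part, ms in zip(self.parts, key):
                pmf = np.convolve(pmf, part.pmf_array(ms))
            self._cache[key] = pmf
        return self._cache[key]

    def pmf(self, x: int, m: Sequence[int]) -> float:
        x = _check_count("x", x)
        p = self.pmf_array(m)
        return float(p[x]) if x < p.size else 0.0

    def tail(self, k: int, m: Sequence[int]) -> float:
        return _tail_from_pmf(self.pmf_array(m), k)

    def mean(self, m: Sequence[int]) -> float:
        return float(sum(p.mean(ms) for p, ms in zip(self.parts, np.atleast_1d(m))))


class StratifiedEventNull(_StratifiedConvolution):
    """Stratified multiple-hypergeometric null (one marginal set per stratum)."""

    def __init__(self, marginals: Sequence[EventClassMarginals]):
        super().__init__([MultipleHypergeomNull(ms) for ms in marginals])


class StratifiedOccupancyNull(_StratifiedConvolution):
    """Stratified occupancy-number null (per-stratum event totals)."""

    def __init__(self, total_events: Sequence[int], total_populations: Sequence[int]):
        if len(total_events) != len(total_populations):
            raise ValueError("total_events and total_populations differ in length")
        super().__init__(
            [OccupancyNull(v, n) for v, n in zip(total_events, total_populations)]
        )


# ---------------------------------------------------------------------------
# thin functional wrappers


def hypergeom_pmf(x: int, m: int, c: int, n: int) -> float:
    """P(exactly x cases among m sampled of n individuals, c cases total)."""
    return HypergeomCaseNull(c, n).pmf(x, m)


def multiple_hypergeom_pmf(x: int, m: int, marginals: EventClassMarginals) -> float:
    """P(exactly x events among m sampled individuals)."""
    return MultipleHypergeomNull(marginals).pmf(x, m)


def multiple_hypergeom_tail(k: int, m: int, marginals: EventClassMarginals) -> float:
    """P(at least k events among m sampled individuals)."""
    return MultipleHypergeomNull(marginals).tail(k, m)


def compound_poisson_pmf(
    x: int, m: int, cases_total: float, n: int, scenario: ScenarioDistribution
) -> float:
    return CompoundPoissonNull(scenario, cases_total, n).pmf(x, m)


def occupancy_pmf(x: int, m: int, total_events: int, n: int) -> float:
    return OccupancyNull(total_events, n).pmf(x, m)


def stratified_pmf(
    x: int, m_s: Sequence[int], marginals_s: Sequence[EventClassMarginals]
) -> float:
    return StratifiedEventNull(marginals_s).pmf(x, m_s)


def stratified_occupancy_pmf(
    x: int, m_s: Sequence[int], v_s: Sequence[int], n_s: Sequence[int]
) -> float:
    return StratifiedOccupancyNull(v_s, n_s).pmf(x, m_s)
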