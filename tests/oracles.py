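"""Brute-force enumeration oracles, independent of the package internals.

These enumerate every equally-likely configuration directly (all subsets of
individuals, or all arrangements of indistinguishable events) and are the
reference the exact distributions are checked against on small instances.
"""

from itertools import combinations

import numpy as np


def enum_sample_event_pmf(member_events, m):
    """Distribution of total events among ``m`` individuals sampled without
    replacement, by enumerating all C(n, m) subsets.

    ``member_events[j]`` is the number of events individual ``j`` has.
    Returns a dense pmf on 0..sum(member_events).
    """
    member_events = list(member_events)
    n = len(member_events)
    total = sum(member_events)
    pmf = np.zeros(total + 1)
    count = 0
    for subset in combinations(range(n), m):
        pmf[sum(member_events[j] for j in subset)] += 1
        count += 1
    return pmf / count


def members_from_classes(class_counts, n):
    """Individual event counts for a region: class_counts[y-1] cases with y
    events each, the rest of the n individuals with none."""
    members = []
    for y, cy in enumerate(class_counts, start=1):
        members.extend([y] * cy)
    members.extend([0] * (n - len(members)))
    return members


def enum_occupancy_pmf(n, V, m):
    """Distribution of events among the first ``m`` of ``n`` individuals when
    every arrangement of ``V`` indistinguishable events is equally likely.

    Enumerates all C(n+V-1, V) stars-and-bars configurations.
    """
    pmf = np.zeros(V + 1)
    count = 0
    # bar positions among n+V-1 slots determine the composition
    for bars in combinations(range(n + V - 1), n - 1):
        prev = -1
        parts = []
        for b in bars:
            parts.append(b - prev - 1)
            prev = b
        parts.append(n + V - 1 - prev - 1)
        pmf[sum(parts[:m])] += 1
        count += 1
    return pmf / count


def enum_stratified_event_pmf(class_counts_s, n_s, m_s):
    """Stratified sampling oracle: independent subset enumeration per stratum,
    convolved."""
    pmf = np.ones(1)
    for counts, n, m in zip(class_counts_s, n_s, m_s):
        part = enum_sample_event_pmf(members_from_classes(counts, n), m)
        pmf = np.convolve(pmf, part)
    return pmf


def enum_stratified_occupancy_pmf(v_s, n_s, m_s):
    pmf = np.ones(1)
    for v, n, m in zip(v_s, n_s, m_s):
        pmf = np.convolve(pmf, enum_occupancy_pmf(n, v, m))
    return pmf
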