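"""Independent brute-force oracles used to validate the vectorized
implementations. Deliberately naive: plain Python loops, no shared code with
the package internals beyond the data containers."""

from __future__ import annotations

import math


def poisson_tail_threshold(mu: float, alpha: float) -> int:
    """Smallest integer T with P(X >= T | Poisson(mu)) <= alpha, by direct
    summation of the pmf."""
    if mu == 0:
        return 1
    # P(X >= T) = 1 - P(X <= T-1); accumulate pmf terms
    pmf = math.exp(-mu)
    cdf = pmf
    t = 0
    while 1.0 - cdf > alpha:
        t += 1
        pmf *= mu / t
        cdf += pmf
        if t > 100 * (mu + 10):  # safety
            raise RuntimeError("tail summation did not terminate")
    return t + 1


def brute_force_detect(counts, thresholds, mus, method: str, merge_gap: int):
    """Exhaustive scan re-implementing the event rules: per-acquisition
    positivity, gap bridging, window sums and background subtraction.

    ``counts`` is a list of per-acquisition lists (row-major), thresholds
    and mus are per-element lists. Returns a list of dicts with window,
    gross and net counts per element index.
    """
    n_acq = len(counts)
    n_el = len(thresholds)

    def positive(i, j):
        if method == "iterative-sigma":
            return counts[i][j] > thresholds[j] + 1e-9
        return counts[i][j] >= thresholds[j]

    pos = [any(positive(i, j) for j in range(n_el)) for i in range(n_acq)]
    groups: list[list[int]] = []
    for i in range(n_acq):
        if not pos[i]:
            continue
        if groups and i - groups[-1][-1] - 1 <= merge_gap:
            groups[-1].append(i)
        else:
            groups.append([i])
    events = []
    for g in groups:
        start, end = g[0], g[-1] + 1
        gross = [sum(counts[t][e] for t in range(start, end)) for e in range(n_el)]
        net = [max(x - (end - start) * mus[e], 0.0) for e, x in enumerate(gross)]
        events.append({"window": (start, end), "gross": gross, "net": net})
    return events


def sphere_mass_fg(diameter_nm: float, density_kg_m3: float) -> float:
    """(pi/6) d^3 rho with explicit unit bookkeeping."""
    d_m = diameter_nm * 1e-9
    volume_m3 = math.pi / 6.0 * d_m**3
    return volume_m3 * density_kg_m3 * 1e18
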