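"""Independent brute-force oracles used by the test suite.

These deliberately recompute quantities by direct enumeration, sharing no code
with the package implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_ehh_curve(matrix, core: int, allele: int, cutoff: float):
    """EHH by explicit pair enumeration: a pair counts at extension site t iff
    the two haplotypes are equal on every site between core and t inclusive.

    Returns ((left_points, left_edge), (right_points, right_edge)).
    """
    carriers = [h for h in range(matrix.n_hap) if matrix.alleles[h, core] == allele]
    n = len(carriers)
    denom = n * (n - 1) // 2
    out = []
    for step in (-1, +1):
        pts = [(0.0, 1.0)]
        t = core + step
        edge = True
        while 0 <= t < matrix.n_site:
            lo, hi = min(core, t), max(core, t)
            num = sum(
                1
                for i, j in itertools.combinations(carriers, 2)
                if np.array_equal(
                    matrix.alleles[i, lo : hi + 1], matrix.alleles[j, lo : hi + 1]
                )
            )
            ehh = num / denom
            pts.append(
                (float(abs(int(matrix.positions[t]) - int(matrix.positions[core]))), ehh)
            )
            if ehh < cutoff:
                edge = False
                break
            t += step
        out.append((np.array(pts), edge))
    return out[0], out[1]


def brute_sl(matrix, core: int, allele: int) -> float:
    """Mean shared-segment length by per-pair site scanning."""
    carriers = [h for h in range(matrix.n_hap) if matrix.alleles[h, core] == allele]
    total = 0
    npairs = 0
    for i, j in itertools.combinations(carriers, 2):
        npairs += 1
        length = 1
        t = core - 1
        while t >= 0 and matrix.alleles[i, t] == matrix.alleles[j, t]:
            length += 1
            t -= 1
        t = core + 1
        while t < matrix.n_site and matrix.alleles[i, t] == matrix.alleles[j, t]:
            length += 1
            t += 1
        total += length
    return total / npairs


def runs_peak_oracle(abs_means, seed_thr: float, edge_thr: float):
    """Hysteresis peak spans by a runs formulation (not seed expansion):
    every maximal run of consecutive windows with |mean| >= edge_thr is a
    peak iff it contains at least one window with |mean| >= seed_thr.

    Returns a list of (first_window, last_window) index pairs.
    """
    spans = []
    i = 0
    m = list(abs_means)
    while i < len(m):
        if m[i] >= edge_thr:
            j = i
            while j + 1 < len(m) and m[j + 1] >= edge_thr:
                j += 1
            if any(m[k] >= seed_thr for k in range(i, j + 1)):
                spans.append((i, j))
            i = j + 1
        else:
            i += 1
    return spans


def exact_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exhaustive enumeration with exact-integer
    tie comparison via a Pascal-triangle binomial table."""
    N = a + b + c + d
    row = a + b
    col = a + c
    if row == 0 or col == 0 or row == N or col == N:
        return 1.0
    # Pascal triangle up to N
    C = [[1] * (k + 1) for k in range(N + 1)]
    for k in range(2, N + 1):
        for j in range(1, k):
            C[k][j] = C[k - 1][j - 1] + C[k - 1][j]
    lo = max(0, col - (N - row))
    hi = min(row, col)
    weights = {x: C[row][x] * C[N - row][col - x] for x in range(lo, hi + 1)}
    obs = weights[a]
    return sum(w for w in weights.values() if w <= obs) / sum(weights.values())
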