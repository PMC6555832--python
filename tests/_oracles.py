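"""Independent brute-force oracles used to cross-check the package.

Everything here is written as plain loops / first-principles formulas and is
deliberately kept independent of the implementations under test.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def per_base_bin_max(intervals, length, bin_size):
    """Bin maxima of the explicit per-base fragment depth array."""
    depth = [0] * length
    for start, end in intervals:
        for pos in range(start, end):
            depth[pos] += 1
    out = []
    for b0 in range(0, length, bin_size):
        chunk = depth[b0 : b0 + bin_size]
        out.append(max(chunk) if chunk else 0)
    return np.array(out, dtype=float)


def overlap_count_per_bin(intervals, length, bin_size):
    nbins = math.ceil(length / bin_size)
    out = [0] * nbins
    for start, end in intervals:
        for b in range(nbins):
            bs, be = b * bin_size, min((b + 1) * bin_size, length)
            if start < be and end > bs:
                out[b] += 1
    return np.array(out, dtype=float)


def smooth_loop(v, window):
    half = window // 2
    out = []
    for i in range(len(v)):
        lo = max(0, i - half)
        hi = min(len(v), i + half + 1)
        out.append(sum(v[lo:hi]) / (hi - lo))
    return np.array(out)


def rebin_loop(v, factor):
    out = []
    for i in range(0, len(v), factor):
        group = v[i : i + factor]
        out.append(sum(group) / len(group))
    return np.array(out)


def presence_scan(values, tau, min_bins, max_gap):
    """Threshold, bridge internal gaps <= max_gap, drop runs < min_bins —
    implemented as an explicit stateful scan."""
    present = [bool(x > tau) for x in values]
    n = len(present)
    # bridge gaps flanked by present bins
    i = 0
    bridged = list(present)
    while i < n:
        if not present[i]:
            j = i
            while j < n and not present[j]:
                j += 1
            if i > 0 and j < n and (j - i) <= max_gap:
                for k in range(i, j):
                    bridged[k] = True
            i = j
        else:
            i += 1
    # drop short runs
    out = list(bridged)
    i = 0
    while i < n:
        if bridged[i]:
            j = i
            while j < n and bridged[j]:
                j += 1
            if (j - i) < min_bins:
                for k in range(i, j):
                    out[k] = False
            i = j
        else:
            i += 1
    return np.array(out, dtype=bool)


def run_length_intervals(values, level):
    """(start, end) runs where values == level, by explicit scan."""
    runs = []
    start = None
    for i, v in enumerate(values):
        if v == level and start is None:
            start = i
        elif v != level and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(values)))
    return runs


def interval_union_size(intervals):
    """Total coverage of a list of (start, end) half-open intervals."""
    covered = set()
    for s, e in intervals:
        covered.update(range(s, e))
    return len(covered)


def ari_contingency(labels_a, labels_b):
    """Adjusted Rand index from the contingency-table closed form."""
    a = list(labels_a)
    b = list(labels_b)
    n = len(a)
    classes_a = sorted(set(a))
    classes_b = sorted(set(b))
    table = {(i, j): 0 for i in classes_a for j in classes_b}
    for x, y in zip(a, b):
        table[(x, y)] += 1

    def comb2(m):
        return m * (m - 1) // 2

    sum_ij = sum(comb2(c) for c in table.values())
    sum_i = sum(comb2(sum(table[(i, j)] for j in classes_b)) for i in classes_a)
    sum_j = sum(comb2(sum(table[(i, j)] for i in classes_a)) for j in classes_b)
    total = comb2(n)
    expected = sum_i * sum_j / total if total else 0.0
    max_index = (sum_i + sum_j) / 2
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def quintiles_by_sorting(expression_with_ids):
    """(gene_id, expression) pairs -> {gene_id: quintile} by explicit sorting
    with remainder bins allotted to the lowest quintiles."""
    ordered = sorted(expression_with_ids, key=lambda t: (t[1], t[0]))
    n = len(ordered)
    base, rem = divmod(n, 5)
    sizes = [base + (1 if i < rem else 0) for i in range(5)]
    names = ["I", "II", "III", "IV", "V"]
    out = {}
    pos = 0
    for name, size in zip(names, sizes):
        for gene_id, _ in ordered[pos : pos + size]:
            out[gene_id] = name
        pos += size
    return out


def metagene_single_gene(values, bin_size, chrom_length, start, end, body_slots, flank_bp):
    """Brute-force single-gene profile by per-position bin lookup."""
    def at(pos):
        clipped = min(max(pos, 0), chrom_length - 1)
        return values[min(int(clipped // bin_size), len(values) - 1)]

    n_flank = flank_bp // bin_size
    prof = []
    for i in range(n_flank):
        prof.append(at(start - flank_bp + (i + 0.5) * bin_size))
    for j in range(body_slots):
        prof.append(at(start + (j + 0.5) * (end - start) / body_slots))
    for i in range(n_flank):
        prof.append(at(end + (i + 0.5) * bin_size))
    return np.array(prof)


def sse_loop(pred, obs):
    total = 0.0
    for p, o in zip(pred, obs):
        total += (p - o) ** 2
    return total


def spearman_by_ranking(a, b):
    """Spearman rho via explicit average ranks and the Pearson formula."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    ra, rb = ranks(list(a)), ranks(list(b))
    n = len(ra)
    ma = sum(ra) / n
    mb = sum(rb) / n
    num = sum((x - ma) * (y - mb) for x, y in zip(ra, rb))
    den = math.sqrt(sum((x - ma) ** 2 for x in ra) * sum((y - mb) ** 2 for y in rb))
    return num / den


def ols_normal_equations(design, response):
    """(beta, se) by explicitly solving the normal equations."""
    X = np.asarray(design, dtype=float)
    z = np.asarray(response, dtype=float)
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ z)
    resid = z - X @ beta
    dof = len(z) - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    return beta, se

def poly_eval_exact(coefficients, d):
    """Arbitrary-precision term-by-term evaluation of the dependency
    polynomial using rational arithmetic."""
    a = [Fraction(str(c)) for c in coefficients]
    dd = Fraction(str(d))
    acc = Fraction(0)
    for n in range(1, 8):
        acc += a[n + 1] * dd**n
    return a[0] + a[1] * acc
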