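"""Independent brute-force reference implementations.

Every function here is a deliberately naive site-by-site / pair-by-pair
loop, written without reference to the package's vectorized code paths, so
the two can disagree only if one of them is wrong.
"""

import itertools
import math

import numpy as np

MISSING = -1


def filter_sites_loop(genotypes, maf_min, missingness_max):
    """Indices of retained sites, one site at a time."""
    keep = []
    n_samples = genotypes.shape[1]
    for i in range(genotypes.shape[0]):
        calls = [g for g in genotypes[i] if g != MISSING]
        if not calls:
            continue
        alt = sum(calls)
        af = alt / (2 * len(calls))
        maf = min(af, 1 - af)
        miss = (n_samples - len(calls)) / n_samples
        if maf >= maf_min and miss < missingness_max:
            keep.append(i)
    return keep


def pairwise_distance_loop(alleles):
    """p-distance over haplotype columns by double loop; NaN when undefined."""
    n = alleles.shape[1]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            diff = co = 0
            for s in range(alleles.shape[0]):
                a, b = alleles[s, i], alleles[s, j]
                if a != MISSING and b != MISSING:
                    co += 1
                    if a != b:
                        diff += 1
            D[i, j] = diff / co if co else np.nan
    return D


def f4_loop(freqs, positions, block_bp):
    """(f4, jackknife SE) by explicit site and block loops."""
    vals, pos = [], []
    for i in range(freqs.shape[0]):
        row = freqs[i]
        if all(math.isfinite(x) for x in row):
            vals.append((row[0] - row[1]) * (row[2] - row[3]))
            pos.append(positions[i])
    n = len(vals)
    est = sum(vals) / n
    blocks = {}
    for v, p in zip(vals, pos):
        blocks.setdefault(p // block_bp, []).append(v)
    g = len(blocks)
    if g < 2:
        return est, float("nan")
    sizes = [len(b) for b in blocks.values()]
    theta_mb = [
        (sum(vals) - sum(b)) / (n - len(b)) for b in blocks.values()
    ]
    total = sum(sizes)
    theta_j = g * est - sum(
        (1 - m / total) * t for m, t in zip(sizes, theta_mb)
    )
    var = 0.0
    for m, t in zip(sizes, theta_mb):
        h = total / m
        tau = h * est - (h - 1) * t
        var += (tau - theta_j) ** 2 / (h - 1)
    return est, math.sqrt(var / g)


def fd_window_loop(freqs, positions, windows, min_sites):
    """(fd, fdM, numerator, n_informative) per window by site loops."""
    out = []
    for (w_start, w_end) in windows:
        num = den23 = den13 = 0.0
        n_inf = 0
        any_site = False
        for i in range(freqs.shape[0]):
            if not (w_start <= positions[i] < w_end):
                continue
            p1, p2, p3, pO = freqs[i]
            if not all(math.isfinite(x) for x in (p1, p2, p3, pO)):
                continue
            any_site = True
            s_num = (1 - p1) * p2 * p3 * (1 - pO) - p1 * (1 - p2) * p3 * (1 - pO)
            pd = max(p2, p3)
            s_d23 = (1 - p1) * pd * pd * (1 - pO) - p1 * (1 - pd) * pd * (1 - pO)
            pe = max(p1, p3)
            s_d13 = (1 - pe) * p2 * pe * (1 - pO) - pe * (1 - p2) * pe * (1 - pO)
            num += s_num
            den23 += s_d23
            den13 += s_d13
            if s_num != 0 or s_d23 != 0:
                n_inf += 1
        fd = fdm = float("nan")
        numer = num if any_site else float("nan")
        if any_site and n_inf >= min_sites:
            if num > 0 and den23 > 0:
                fd = num / den23
            if num >= 0:
                if den23 > 0:
                    fdm = num / den23
            elif abs(den13) > 0:
                fdm = num / abs(den13)
        out.append((fd, fdm, numer, n_inf))
    return out


def pooled_pi_loop(genotypes, positions, windows):
    """(diff_sum, comp_sum) per window from per-site allele-pair counts."""
    out = []
    for (w_start, w_end) in windows:
        diff = comp = 0
        for i in range(genotypes.shape[0]):
            if not (w_start <= positions[i] < w_end):
                continue
            alleles = []
            for g in genotypes[i]:
                if g != MISSING:
                    alleles.extend([1] * g + [0] * (2 - g))
            n = len(alleles)
            if n < 2:
                continue
            for a, b in itertools.combinations(alleles, 2):
                comp += 1
                if a != b:
                    diff += 1
        out.append((diff, comp))
    return out


def transpoly_loop(genotypes, species_of_col, min_poly, min_copies):
    """Per-site trans-polymorphism flags by explicit rule application."""
    species = sorted(set(species_of_col))
    flags = []
    for i in range(genotypes.shape[0]):
        ref_tot = alt_tot = 0
        n_present = n_poly = 0
        for sp in species:
            ref = alt = 0
            for j, sp_j in enumerate(species_of_col):
                if sp_j != sp or genotypes[i, j] == MISSING:
                    continue
                alt += genotypes[i, j]
                ref += 2 - genotypes[i, j]
            ref_tot += ref
            alt_tot += alt
            if ref + alt > 0:
                n_present += 1
                if ref > 0 and alt > 0:
                    n_poly += 1
        if n_present > 3:
            rule = n_poly >= min_poly
        elif n_present >= 2:
            rule = n_poly == n_present
        else:
            rule = False
        flags.append(rule and ref_tot >= min_copies and alt_tot >= min_copies)
    return flags


def spearman_rho2_loop(x, y):
    """Squared Spearman correlation via explicit midranks and Pearson formula."""

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    sxx = sum((a - mx) ** 2 for a in rx)
    syy = sum((b - my) ** 2 for b in ry)
    r = sxy / math.sqrt(sxx * syy)
    return r * r


def weights_by_enumeration(tree, groups):
    """Topology weights by looping over every one-leaf-per-group tuple,
    resolving each quartet independently via the tree's splits."""
    from tigerwing.topo_weight import quartet_topology

    counts = {"ab|cd": 0, "ac|bd": 0, "ad|bc": 0}
    total = 0
    for a in groups[0]:
        for b in groups[1]:
            for c in groups[2]:
                for d in groups[3]:
                    counts[quartet_topology(tree, a, b, c, d)] += 1
                    total += 1
    return (
        counts["ab|cd"] / total,
        counts["ac|bd"] / total,
        counts["ad|bc"] / total,
    )


def blockperm_exhaustive(flag_midpoints_by_block, block_spans, t0, focal, observed):
    """Exact permutation p over all orderings of the blocks.

    ``flag_midpoints_by_block``: per block, offsets (midpoint - block start)
    of flagged windows.  Returns (p_value, null_counts).
    """
    n_blocks = len(block_spans)
    counts = []
    for order in itertools.permutations(range(n_blocks)):
        start = t0
        count = 0
        for b in order:
            for off in flag_midpoints_by_block[b]:
                if focal[0] <= start + off < focal[1]:
                    count += 1
            start += block_spans[b]
        counts.append(count)
    p = sum(1 for c in counts if c >= observed) / len(counts)
    return p, counts
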