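"""Deliberately simple brute-force reference implementations.

Everything here works per base or per bin with plain Python loops and no
shared code with the package, so agreement between the two routes is
meaningful evidence of correctness on small instances.
"""

from __future__ import annotations

import math


def brute_force_broad_peaks(values, bin_width, chrom_length,
                            peak_cutoff, link_cutoff, min_peak_length, max_link_gap):
    """Two-cutoff broad call by naive scanning; returns (start, end) bp pairs."""
    n = len(values)

    def runs(cutoff):
        out = []
        i = 0
        while i < n:
            if values[i] >= cutoff:
                j = i
                while j < n and values[j] >= cutoff:
                    j += 1
                out.append((i, j))
                i = j
            else:
                i += 1
        return out

    def bp(b0, b1):
        return (b0 * bin_width, min(b1 * bin_width, chrom_length))

    strong = [r for r in runs(peak_cutoff)
              if bp(*r)[1] - bp(*r)[0] >= min_peak_length]
    weak = runs(link_cutoff)
    # link weak segments separated by at most max_link_gap base pairs
    linked = []
    for b0, b1 in weak:
        if linked and (b0 - linked[-1][1]) * bin_width <= max_link_gap:
            linked[-1] = (linked[-1][0], b1)
        else:
            linked.append((b0, b1))
    peaks = []
    for b0, b1 in linked:
        if any(b0 <= s0 and s1 <= b1 for s0, s1 in strong):
            peaks.append(bp(b0, b1))
    return peaks


def per_base_overlap(region, annotation):
    """bp of a region covered by the union of annotation intervals,
    counted one base at a time."""
    chrom, start, end = region
    covered = 0
    for pos in range(start, end):
        for (c, s, e) in annotation:
            if c == chrom and s <= pos < e:
                covered += 1
                break
    return covered


def per_base_merge(regions, merge_distance=0):
    """Merge intervals via painting bases on a virtual chromosome set;
    gap <= merge_distance joins intervals."""
    by_chrom = {}
    for c, s, e in regions:
        by_chrom.setdefault(c, []).append((s, e))
    out = []
    for c in sorted(by_chrom):
        ivs = sorted(by_chrom[c])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s - cur_e <= merge_distance:
                cur_e = max(cur_e, e)
            else:
                out.append((c, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((c, cur_s, cur_e))
    return out


def count_associated(regions, annotation):
    """Number of regions overlapping >= 1 annotation interval, per base."""
    return sum(1 for r in regions if per_base_overlap(r, annotation) > 0)


def one_sided_t_p(t_stat, df):
    """P(T_df > t) by numerical integration of the t density (no scipy)."""
    def density(x):
        c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
        return c * (1 + x * x / df) ** (-(df + 1) / 2)

    # Simpson's rule from t to a far bound; the remaining tail is O(hi^-df)
    # and far below the comparison tolerance
    hi = max(t_stat + 500.0, 500.0)
    n = 200_001
    h = (hi - t_stat) / (n - 1)
    total = density(t_stat) + density(hi)
    for i in range(1, n - 1):
        total += density(t_stat + i * h) * (4 if i % 2 else 2)
    return total * h / 3


def quantile_normalize_reference(columns):
    """Independent quantile normalization: rank-wise means with tie spans
    averaged, written with explicit sorting and python loops."""
    n = len(columns[0])
    ref = [0.0] * n
    for col in columns:
        for r, v in enumerate(sorted(col)):
            ref[r] += v
    ref = [v / len(columns) for v in ref]
    out = []
    for col in columns:
        order = sorted(range(n), key=lambda i: (col[i], i))
        new = [0.0] * n
        r = 0
        while r < n:
            r2 = r
            while r2 + 1 < n and col[order[r2 + 1]] == col[order[r]]:
                r2 += 1
            tied_mean = sum(ref[r:r2 + 1]) / (r2 - r + 1)
            for k in range(r, r2 + 1):
                new[order[k]] = tied_mean
            r = r2 + 1
        out.append(new)
    return out
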