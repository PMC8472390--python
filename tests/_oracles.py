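"""Independent brute-force reference implementations used only by tests.

Everything here is written as plainly as possible (explicit loops, no shared
code with the package) so it can serve as an oracle for the vectorized
implementations.
"""

from __future__ import annotations

import numpy as np

MISSING = -1


def _is_opposite(g: int, mode: str) -> bool:
    if mode == "ROH":
        return g == 1
    return g in (0, 2)


def brute_window_scan(vec, params):
    """Per-SNP eligible-window proportion by re-enumerating every window."""
    n = len(vec)
    if n == 0:
        return []
    w = min(params.window_snps, n)
    good = [0] * n
    cover = [0] * n
    for start in range(0, n - w + 1):
        window = vec[start : start + w]
        n_opp = sum(1 for g in window if _is_opposite(g, params.mode))
        n_mis = sum(1 for g in window if g == MISSING)
        eligible = (
            n_opp <= params.max_opposite_in_window
            and n_mis <= params.max_missing_in_window
        )
        for j in range(start, start + w):
            cover[j] += 1
            if eligible:
                good[j] += 1
    return [g / c for g, c in zip(good, cover)]


def brute_detect_vector(vec, positions, params):
    """Full naive detector on one chromosome vector.

    Returns (start_bp, end_bp, n_snps, n_opposite, n_missing) tuples.
    """
    props = brute_window_scan(vec, params)
    member = [p > params.window_threshold for p in props]
    n = len(vec)
    # maximal blocks of consecutive members
    blocks = []
    j = 0
    while j < n:
        if member[j]:
            k = j
            while k + 1 < n and member[k + 1]:
                k += 1
            blocks.append((j, k))
            j = k + 1
        else:
            j += 1
    # gap splitting
    candidates = []
    for a, b in blocks:
        start = a
        for k in range(a, b + 1):
            if k == b or positions[k + 1] - positions[k] > params.max_gap_bp:
                candidates.append((start, k))
                start = k + 1
    out = []
    for a, b in candidates:
        n_snps = b - a + 1
        length = positions[b] - positions[a]
        if n_snps < params.min_snps_in_run:
            continue
        if length < params.min_length_bp:
            continue
        if length / n_snps > params.min_density_kb_per_snp * 1000:
            continue
        seg = vec[a : b + 1]
        n_opp = sum(1 for g in seg if _is_opposite(g, params.mode))
        n_mis = sum(1 for g in seg if g == MISSING)
        if n_opp > params.max_opposite_in_run:
            continue
        if n_mis > params.max_missing_in_run:
            continue
        out.append((int(positions[a]), int(positions[b]), n_snps, n_opp, n_mis))
    return out


def grid_ml_r2(counts, step=1e-4):
    """Maximum-likelihood r^2 by grid search over the double-het phase fraction.

    The two-locus haplotype distribution consistent with the observed
    genotype table is a one-parameter family in f, the coupling fraction
    among double heterozygotes; the genotype log-likelihood is evaluated on
    an f-grid and r^2 computed at the maximizing point.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    n_dh = counts[1, 1]
    fixed = np.zeros((2, 2))
    for g1 in range(3):
        for g2 in range(3):
            if g1 == 1 and g2 == 1:
                continue
            c = counts[g1, g2]
            if g1 != 1 and g2 != 1:
                fixed[g1 // 2, g2 // 2] += 2 * c
            elif g1 == 1:
                fixed[0, g2 // 2] += c
                fixed[1, g2 // 2] += c
            else:
                fixed[g1 // 2, 0] += c
                fixed[g1 // 2, 1] += c

    def log_likelihood(fs):
        # haplotype freqs are linear in the coupling fraction f
        fs = np.asarray(fs, dtype=float)
        p = np.empty((fs.size, 2, 2))
        p[:, 0, 0] = fixed[0, 0] + n_dh * fs
        p[:, 0, 1] = fixed[0, 1] + n_dh * (1 - fs)
        p[:, 1, 0] = fixed[1, 0] + n_dh * (1 - fs)
        p[:, 1, 1] = fixed[1, 1] + n_dh * fs
        p /= 2 * n
        # random union of gametes: P(g1, g2) = sum over consistent pairs
        probs = np.zeros((fs.size, 3, 3))
        for a1 in range(2):
            for a2 in range(2):
                for b1 in range(2):
                    for b2 in range(2):
                        probs[:, a1 + b1, a2 + b2] += p[:, a1, a2] * p[:, b1, b2]
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(counts[None] > 0, counts[None] * np.log(probs), 0.0)
        return ll.sum(axis=(1, 2)), p

    if n_dh:
        # coarse grid, then fine refinement around the maximum
        fs = np.arange(0.0, 1.0 + step / 2, step)
        ll, _ = log_likelihood(fs)
        f0 = fs[int(np.argmax(ll))]
        fine = np.clip(np.arange(f0 - 2 * step, f0 + 2 * step, step * 1e-3), 0.0, 1.0)
        ll, ps = log_likelihood(fine)
        p = ps[int(np.argmax(ll))]
    else:
        _, ps = log_likelihood([0.0])
        p = ps[0]
    pA = p[0, 0] + p[0, 1]
    pB = p[0, 0] + p[1, 0]
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom == 0:
        return None
    d = p[0, 0] - pA * pB
    return min(1.0, d * d / denom)


def haplotype_count_r2(hap_counts):
    """Direct r^2 from known (phase-unambiguous) haplotype counts.

    ``hap_counts`` is a 2x2 array of haplotype counts.
    """
    h = np.asarray(hap_counts, dtype=float)
    n = h.sum()
    p = h / n
    pA = p[0, 0] + p[0, 1]
    pB = p[0, 0] + p[1, 0]
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom == 0:
        return None
    d = p[0, 0] - pA * pB
    return d * d / denom


def brute_common_regions(islands_by_pop, lo, hi):
    """Half-step coverage scan over [lo, hi] for one chromosome.

    ``islands_by_pop``: list of (population, start, end) closed intervals.
    Returns (start, end, frozenset) regions; scan at half-bp resolution so
    closed-interval boundary sharing is resolved exactly.
    """
    xs = np.arange(2 * lo, 2 * hi + 1)  # doubled coordinates: integers + halves
    regions = []
    current = None  # (set, first_x, last_x)
    for x2 in xs:
        x = x2 / 2
        cover = frozenset(
            pop for pop, s, e in islands_by_pop if s <= x <= e
        )
        if current is not None and cover == current[0]:
            current = (cover, current[1], x)
            continue
        if current is not None and len(current[0]) >= 2:
            regions.append(
                (int(np.floor(current[1])), int(np.ceil(current[2])), current[0])
            )
        current = (cover, x, x)
    if current is not None and len(current[0]) >= 2:
        regions.append((int(np.floor(current[1])), int(np.ceil(current[2])), current[0]))
    return regions
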