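"""Numba inner loops for EHH class refinement.

EHH at a flanking SNP x is the probability that two carrier haplotypes
drawn at random are identical over the inclusive interval [core..x]. It is
computed by refining identity classes outward: classes start as the two
core-allele groups (a single class when the carriers are conditioned on
one core allele), then at each step the class id of a haplotype becomes
(old class, allele at the new SNP), re-compacted; EHH = sum over classes
of C(size, 2) / C(n_carriers, 2). EHH at the core itself is therefore the
core-site homozygosity — exactly 1 for allele-conditioned carrier sets.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0        # EHH dropped below the cutoff (proper truncation)
STATUS_END = 1       # ran off the chromosome end before decaying
STATUS_GAP = 2       # hit an inter-SNP gap larger than max_gap


@njit(cache=True)
def ehh_decay(hap, rows, core, step, pos, cutoff, max_gap, out_vals):
    """One-sided EHH until it drops below ``cutoff``.

    Writes EHH values (one per flanking SNP, the sub-cutoff point included)
    into ``out_vals`` and returns ``(n_points, status)``.
    """
    n = rows.shape[0]
    npairs = n * (n - 1) // 2
    n_snps = hap.shape[1]
    cls = np.empty(n, dtype=np.int64)
    for t in range(n):
        cls[t] = hap[rows[t], core]
    n_classes = 2
    m = 0
    status = STATUS_END
    prev_pos = pos[core]
    j = core
    while True:
        j += step
        if j < 0 or j >= n_snps:
            status = STATUS_END
            break
        gap = pos[j] - prev_pos
        if gap < 0:
            gap = -gap
        if gap > max_gap:
            status = STATUS_GAP
            break
        prev_pos = pos[j]
        lut = np.full(2 * n_classes, -1, dtype=np.int64)
        nc = 0
        for t in range(n):
            key = cls[t] * 2 + hap[rows[t], j]
            if lut[key] == -1:
                lut[key] = nc
                nc += 1
            cls[t] = lut[key]
        n_classes = nc
        counts = np.zeros(nc, dtype=np.int64)
        for t in range(n):
            counts[cls[t]] += 1
        s = 0
        for ci in range(nc):
            s += counts[ci] * (counts[ci] - 1) // 2
        e = s / npairs
        out_vals[m] = e
        m += 1
        if e < cutoff:
            status = STATUS_OK
            break
    return m, status


@njit(cache=True)
def ehh_pair_decay(hap, rows, in_a, core, step, pos, cutoff, max_gap,
                   stop_on_combined, out_a, out_b, out_c):
    """One-sided EHH for two haplotype subsets and their union in one pass.

    ``in_a`` marks membership of subset A within ``rows``; subset B is the
    complement. All three curves come from one identity-class refinement:
    two rows of a subset are identical over [core..x] iff they share the
    union's class. With ``stop_on_combined`` the walk stops after the
    union EHH drops below ``cutoff`` (XP-EHH shared truncation), otherwise
    after both subset EHHs have dropped (iHS per-allele truncation).
    Returns ``(m, status_a, status_b, status_c)``.
    """
    n = rows.shape[0]
    n_a = 0
    for t in range(n):
        if in_a[t]:
            n_a += 1
    n_b = n - n_a
    pairs_a = n_a * (n_a - 1) // 2
    pairs_b = n_b * (n_b - 1) // 2
    pairs_c = n * (n - 1) // 2
    cls = np.empty(n, dtype=np.int64)
    for t in range(n):
        cls[t] = hap[rows[t], core]
    n_classes = 2
    m = 0
    done_a = pairs_a == 0
    done_b = pairs_b == 0
    done_c = False
    status_a = STATUS_END
    status_b = STATUS_END
    status_c = STATUS_END
    n_snps = hap.shape[1]
    prev_pos = pos[core]
    j = core
    while True:
        j += step
        if j < 0 or j >= n_snps:
            break
        gap = pos[j] - prev_pos
        if gap < 0:
            gap = -gap
        if gap > max_gap:
            if not done_a:
                status_a = STATUS_GAP
            if not done_b:
                status_b = STATUS_GAP
            if not done_c:
                status_c = STATUS_GAP
            break
        prev_pos = pos[j]
        lut = np.full(2 * n_classes, -1, dtype=np.int64)
        nc = 0
        for t in range(n):
            key = cls[t] * 2 + hap[rows[t], j]
            if lut[key] == -1:
                lut[key] = nc
                nc += 1
            cls[t] = lut[key]
        n_classes = nc
        cnt_t = np.zeros(nc, dtype=np.int64)
        cnt_a = np.zeros(nc, dtype=np.int64)
        for t in range(n):
            cnt_t[cls[t]] += 1
            if in_a[t]:
                cnt_a[cls[t]] += 1
        s_a = 0
        s_b = 0
        s_c = 0
        for ci in range(nc):
            ct = cnt_t[ci]
            ca = cnt_a[ci]
            cb = ct - ca
            s_c += ct * (ct - 1) // 2
            s_a += ca * (ca - 1) // 2
            s_b += cb * (cb - 1) // 2
        e_a = s_a / pairs_a if pairs_a > 0 else 0.0
        e_b = s_b / pairs_b if pairs_b > 0 else 0.0
        e_c = s_c / pairs_c
        out_a[m] = e_a
        out_b[m] = e_b
        out_c[m] = e_c
        m += 1
        if not done_a and e_a < cutoff:
            done_a = True
            status_a = STATUS_OK
        if not done_b and e_b < cutoff:
            done_b = True
            status_b = STATUS_OK
        if not done_c and e_c < cutoff:
            done_c = True
            status_c = STATUS_OK
        if stop_on_combined:
            if done_c:
                break
        elif done_a and done_b:
            break
    return m, status_a, status_b, status_c


@njit(cache=True)
def ehh_fixed(hap, rows, core, step, n_steps, out_vals):
    """One-sided EHH over exactly ``n_steps`` flanking SNPs (no stopping)."""
    n = rows.shape[0]
    npairs = n * (n - 1) // 2
    cls = np.empty(n, dtype=np.int64)
    for t in range(n):
        cls[t] = hap[rows[t], core]
    n_classes = 2
    j = core
    for m in range(n_steps):
        j += step
        lut = np.full(2 * n_classes, -1, dtype=np.int64)
        nc = 0
        for t in range(n):
            key = cls[t] * 2 + hap[rows[t], j]
            if lut[key] == -1:
                lut[key] = nc
                nc += 1
            cls[t] = lut[key]
        n_classes = nc
        counts = np.zeros(nc, dtype=np.int64)
        for t in range(n):
            counts[cls[t]] += 1
        s = 0
        for ci in range(nc):
            s += counts[ci] * (counts[ci] - 1) // 2
        out_vals[m] = s / npairs
    return n_steps
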