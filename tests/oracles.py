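"""Independent brute-force oracles shared by the test modules.

These deliberately re-derive results from first principles (exhaustive
enumeration, direct definitions) and share no code with the implementation
they check.
"""

import math


def brute_force_windows(ae, snps, config, fold_range):
    """Enumerate every contiguous run of informative SNPs, test the window
    criteria directly, and keep maximal qualifying runs."""
    low, high = fold_range
    partial = high != float("inf")

    def ok(mean):
        return (low <= mean < high) if partial else (mean > low)

    by_chrom = {}
    for s in sorted(snps, key=lambda s: (s.chrom, s.pos)):
        if any(s.snp_id in pts and pts[s.snp_id].informative for pts in ae.values()):
            by_chrom.setdefault(s.chrom, []).append(s)
    segments = []
    for chrom_snps in by_chrom.values():
        seg = []
        for s in chrom_snps:
            if seg and s.pos - seg[-1].pos > config.window_gap_bp:
                segments.append(seg)
                seg = []
            seg.append(s)
        if seg:
            segments.append(seg)

    def qualifies(seg, i, j):
        ids = [s.snp_id for s in seg[i:j + 1]]
        n_pass = 0
        for pts in ae.values():
            mags = [pts[s].magnitude for s in ids if s in pts and pts[s].informative]
            if mags and ok(sum(mags) / len(mags)):
                n_pass += 1
        return n_pass >= config.min_children

    out = []
    for seg in segments:
        n = len(seg)
        for i in range(n):
            for j in range(i + config.min_window_snps - 1, n):
                if not qualifies(seg, i, j):
                    continue
                if i > 0 and qualifies(seg, i - 1, j):
                    continue
                if j < n - 1 and qualifies(seg, i, j + 1):
                    continue
                out.append(tuple(s.snp_id for s in seg[i:j + 1]))
    return sorted(out)


def fisher_two_sided(a, b, c, d):
    """Two-sided Fisher exact p by explicit hypergeometric enumeration."""
    r1, c1, n = a + b, a + c, a + b + c + d

    def hyper(k):
        return math.comb(c1, k) * math.comb(n - c1, r1 - k) / math.comb(n, r1)

    p_obs = hyper(a)
    return sum(
        hyper(k)
        for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
        if hyper(k) <= p_obs * (1 + 1e-9)
    )


def trio_transmissions(child, father, mother):
    """All (paternal, maternal) transmissions compatible with a trio."""
    child_alleles = tuple(sorted(child))
    return {
        (f, m)
        for f in set(father)
        for m in set(mother)
        if tuple(sorted(f + m)) == child_alleles
    }
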