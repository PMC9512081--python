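"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: base-resolution
bitmaps for interval arithmetic, and exact integer hypergeometric
enumeration for the two-sided Fisher test.
"""

from __future__ import annotations

from math import comb

import numpy as np

# numerator comparison equivalent to the 1e-7 relative tie tolerance
_TIE_NUM = 10_000_001
_TIE_DEN = 10_000_000


def bitmap(intervals, genome_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Base-resolution boolean coverage mask per chromosome."""
    masks = {c: np.zeros(l, dtype=bool) for c, l in genome_lengths.items()}
    for iv in intervals:
        masks[iv.chrom][iv.start:iv.end] = True
    return masks


def coverage_counts(sets, genome_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Per-base count of how many sets cover each base."""
    counts = {c: np.zeros(l, dtype=np.int32) for c, l in genome_lengths.items()}
    for s in sets:
        for c, m in bitmap(s, genome_lengths).items():
            counts[c] += m.astype(np.int32)
    return counts


def mask_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) pairs."""
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact integer enumeration over the support.

    Table probabilities share the denominator C(n, c1), so tables are
    compared by integer numerators N(k) = C(r1, k) * C(r2, c1 - k); a table
    qualifies when N(k) <= N(a) within the same relative tie tolerance the
    implementation documents.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    nums = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)}
    n_obs = nums[a]
    total = sum(v for v in nums.values() if v * _TIE_DEN <= n_obs * _TIE_NUM)
    return min(1.0, total / comb(n, c1))


def random_intervals(rng, genome_lengths: dict[str, int], n: int,
                     max_len: int = 300):
    """n random intervals across the genome (package-independent records)."""
    from peakenrich.intervals import GenomicInterval

    chroms = list(genome_lengths)
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, genome_lengths[chrom] - length + 1))
        out.append(GenomicInterval(chrom, start, start + length))
    return out
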