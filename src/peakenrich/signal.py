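"""Two-condition coverage comparison over gene bodies.

Coverage is a piecewise-constant track (bedGraph semantics; uncovered bases
read as 0). The comparison bins the genome on the same grid as
``intervals.tile_windows`` (trailing partial bin dropped), takes the log2
ratio of bin means with a pseudocount, aggregates bins to regions by
bin-midpoint containment, and contrasts per-gene means between
differential-expression classes with a two-sample t test.

Per-gene means — one value per gene — are the default unit entering the
t test, which avoids pseudoreplicating correlated bins within a gene;
``unit="bin"`` pools raw bin values instead for comparison with pipelines
that test bins directly.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .annotation import GeneTable
from .genome import GenomeSpec
from .intervals import IntervalSet

__all__ = [
    "SignalTrack",
    "BinnedLogRatio",
    "GeneClassComparison",
    "read_bedgraph",
    "write_bedgraph",
    "bin_log2_ratio",
    "mean_over_intervals",
    "two_sample_ttest",
    "gene_body_ratio_comparison",
]

logger = logging.getLogger(__name__)


class SignalTrack:
    """Genome-bound piecewise-constant coverage; uncovered bases are 0."""

    def __init__(self, genome: GenomeSpec,
                 data: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self.genome = genome
        self._data = {}
        lengths = genome.lengths()
        for chrom, (starts, ends, values) in data.items():
            if chrom not in lengths:
                raise ValueError(f"chromosome {chrom!r} absent from genome")
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if len(starts):
                if starts[0] < 0 or ends[-1] > lengths[chrom]:
                    raise ValueError(f"track interval out of bounds on {chrom}")
                if np.any(starts >= ends):
                    raise ValueError(f"empty track interval on {chrom}")
                if np.any(starts[1:] < ends[:-1]):
                    raise ValueError(f"overlapping track intervals on {chrom}")
                if np.any(~np.isfinite(values)) or np.any(values < 0):
                    raise ValueError(f"track values must be finite and >= 0 on {chrom}")
            self._data[chrom] = (starts, ends, values)

    @classmethod
    def from_bins(cls, genome: GenomeSpec, bin: int,
                  bin_values: Mapping[str, np.ndarray]) -> "SignalTrack":
        """Build a track from per-bin values on the uniform ``bin``-bp grid."""
        data = {}
        for chrom, vals in bin_values.items():
            vals = np.asarray(vals, dtype=float)
            starts = np.arange(len(vals), dtype=np.int64) * bin
            data[chrom] = (starts, starts + bin, vals)
        return cls(genome, data)

    def chroms(self) -> list[str]:
        return sorted(self._data)

    def intervals(self, chrom: str):
        return self._data.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64),
                                      np.empty(0, float)))

    def integral(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Integral of the track over [0, x) for each position x (vectorized)."""
        starts, ends, values = self.intervals(chrom)
        x = np.asarray(positions, dtype=np.int64)
        if len(starts) == 0:
            return np.zeros(len(x), dtype=float)
        cum = np.concatenate([[0.0], np.cumsum(values * (ends - starts))])
        j = np.searchsorted(starts, x, side="right")
        res = cum[j].copy()
        has = j > 0
        jm = np.maximum(j - 1, 0)
        res[has] -= values[jm][has] * np.maximum(ends[jm][has] - x[has], 0)
        return res


def read_bedgraph(path: str | Path, genome: GenomeSpec) -> SignalTrack:
    """Read a 4-column bedGraph into a SignalTrack.

    Overlapping records, negative values and unknown chromosomes are errors.
    """
    data: dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: bedGraph needs 4 columns")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: malformed record") from None
            data.setdefault(fields[0], []).append((start, end, value))
    arrays = {}
    for chrom, recs in data.items():
        arr = np.array(recs, dtype=float)
        arrays[chrom] = (arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64),
                         arr[:, 2])
    try:
        return SignalTrack(genome, arrays)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Write the track as bedGraph, coalescing adjacent equal-valued records."""
    with open(path, "w") as fh:
        for chrom in track.chroms():
            starts, ends, values = track.intervals(chrom)
            i = 0
            n = len(starts)
            while i < n:
                j = i
                while (j + 1 < n and ends[j] == starts[j + 1]
                       and values[j + 1] == values[i]):
                    j += 1
                fh.write(f"{chrom}\t{starts[i]}\t{ends[j]}\t{values[i]:g}\n")
                i = j + 1


@dataclass
class BinnedLogRatio:
    """Per-bin log2((meanA+psi)/(meanB+psi)) on the uniform bin grid."""

    genome: GenomeSpec
    bin: int
    pseudocount: float
    values: dict[str, np.ndarray]  # chrom -> one value per retained bin

    def bin_midpoints(self, chrom: str) -> np.ndarray:
        n = len(self.values.get(chrom, ()))
        return np.arange(n, dtype=np.int64) * self.bin + self.bin // 2


def bin_log2_ratio(a: SignalTrack, b: SignalTrack, bin: int = 50,
                   pseudocount: float = 1.0) -> BinnedLogRatio:
    """Binned log2 ratio of mean coverages, log2((meanA+psi)/(meanB+psi)).

    Bins align to the tiling grid (trailing partial bin dropped). A zero
    pseudocount is allowed only when no bin mean is zero in either track.
    """
    if a.genome != b.genome:
        raise ValueError("tracks are bound to different genomes")
    if bin < 1:
        raise ValueError("bin must be >= 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    values = {}
    for chrom, length in a.genome:
        n = length // bin
        edges = np.arange(n + 1, dtype=np.int64) * bin
        mean_a = np.diff(a.integral(chrom, edges)) / bin
        mean_b = np.diff(b.integral(chrom, edges)) / bin
        if pseudocount == 0 and (np.any(mean_a == 0) or np.any(mean_b == 0)):
            raise ValueError("pseudocount 0 with a zero-coverage bin "
                             f"on {chrom}")
        values[chrom] = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    return BinnedLogRatio(a.genome, bin, pseudocount, values)


def mean_over_intervals(ratio: BinnedLogRatio, regions: IntervalSet) -> np.ndarray:
    """Unweighted mean of bin values whose midpoints fall inside each region.

    Bin membership by midpoint containment avoids double-counting bins that
    straddle region edges. Regions containing no bin midpoint get ``nan``.
    Output follows the canonical iteration order of ``regions``.
    """
    out = []
    half = ratio.bin // 2
    for chrom in regions.chroms:
        vals = ratio.values.get(chrom, np.empty(0))
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        n = len(vals)
        rs, re = regions.starts(chrom), regions.ends(chrom)
        # bin i has midpoint i*bin + half; midpoints in [s, e) are lo..hi-1
        lo = np.clip(-(-(rs - half) // ratio.bin), 0, n)
        hi = np.clip(-(-(re - half) // ratio.bin), 0, n)
        m = np.full(len(rs), np.nan)
        nz = hi > lo
        m[nz] = (csum[hi[nz]] - csum[lo[nz]]) / (hi[nz] - lo[nz])
        out.append(m)
    return np.concatenate(out) if out else np.empty(0)


def two_sample_ttest(x: Sequence[float], y: Sequence[float],
                     variant: str = "student") -> tuple[float, float]:
    """Two-sample t test: pooled-variance Student (default) or Welch.

    Returns ``(t, two_sided_p)``. Degenerate zero-variance inputs: equal
    means give (0, 1); unequal means give (+/-inf, 0) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("groups must contain only finite values")
    if variant not in {"student", "welch"}:
        raise ValueError("variant must be 'student' or 'welch'")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        warnings.warn("zero variance with unequal means; p reported as 0")
        return math.copysign(math.inf, x.mean() - y.mean()), 0.0
    res = stats.ttest_ind(x, y, equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue)


@dataclass
class GeneClassComparison:
    """Per-gene mean log ratios by DE class, with class-vs-unchanged t tests."""

    gene_means: dict[str, float]  # gene_id -> mean log2 ratio (may be nan)
    classes: dict[str, str]  # gene_id -> {down, up, unchanged}
    tests: dict[str, tuple[float, int, float]] = field(default_factory=dict)
    # contrast name -> (t, df, two_sided_p)

    def class_values(self, label: str) -> np.ndarray:
        vals = [m for g, m in self.gene_means.items()
                if self.classes[g] == label and not math.isnan(m)]
        return np.asarray(vals, dtype=float)

    def to_json(self, path: str | Path | None = None) -> str:
        rec = {"tests": {k: {"t": t, "df": df, "p": p}
                         for k, (t, df, p) in self.tests.items()},
               "class_means": {c: float(self.class_values(c).mean())
                               for c in sorted(set(self.classes.values()))
                               if len(self.class_values(c))}}
        text = json.dumps(rec, indent=1)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


_VALID_CLASSES = {"down", "up", "unchanged"}


def gene_body_ratio_comparison(a: SignalTrack, b: SignalTrack, genes: GeneTable,
                               de_classes: Mapping[str, str], bin: int = 50,
                               pseudocount: float = 1.0,
                               variant: str = "student",
                               unit: str = "gene") -> GeneClassComparison:
    """Compare log2(A/B) over gene bodies between DE classes.

    Composes the binned log ratio, gene-body aggregation, and the down-vs-
    unchanged / up-vs-unchanged t tests. ``unit="gene"`` (default) tests one
    mean per gene; ``unit="bin"`` pools raw bin values per class. A class
    with fewer than 2 defined values is skipped and logged.
    """
    bad = set(de_classes.values()) - _VALID_CLASSES
    if bad:
        raise ValueError(f"unknown DE classes: {sorted(bad)}")
    if unit not in {"gene", "bin"}:
        raise ValueError("unit must be 'gene' or 'bin'")
    ratio = bin_log2_ratio(a, b, bin=bin, pseudocount=pseudocount)
    table = genes.subset([g for g in de_classes if g in genes])
    bodies = table.intervals()
    means = mean_over_intervals(ratio, bodies)
    gene_means = {}
    for iv, m in zip(bodies, means):
        gene_means[iv.name] = float(m)
    comparison = GeneClassComparison(gene_means, dict(de_classes))

    def group_values(label: str) -> np.ndarray:
        if unit == "gene":
            return comparison.class_values(label)
        parts = []
        half = ratio.bin // 2
        for chrom in bodies.chroms:
            vals = ratio.values.get(chrom, np.empty(0))
            names = bodies.names(chrom) or []
            rs, re = bodies.starts(chrom), bodies.ends(chrom)
            for i, name in enumerate(names):
                if de_classes.get(name) != label:
                    continue
                lo = max(0, -(-(rs[i] - half) // ratio.bin))
                hi = min(len(vals), -(-(re[i] - half) // ratio.bin))
                if hi > lo:
                    parts.append(vals[lo:hi])
        return np.concatenate(parts) if parts else np.empty(0)

    unchanged = group_values("unchanged")
    for label in ("down", "up"):
        vals = group_values(label)
        if len(vals) < 2 or len(unchanged) < 2:
            logger.info("class %s has < 2 defined values; comparison skipped", label)
            continue
        t, p = two_sample_ttest(vals, unchanged, variant=variant)
        df = len(vals) + len(unchanged) - 2
        comparison.tests[f"{label}_vs_unchanged"] = (t, df, p)
    return comparison
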