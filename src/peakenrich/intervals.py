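"""Genomic-interval data model and interval arithmetic.

Coordinates are 0-based half-open throughout (BED convention). Overlap
requires at least one shared base; abutting intervals such as [0,100) and
[100,200) do not overlap but DO merge at ``gap=0``, because merging joins
intervals whose gap is <= the parameter and abutment has gap 0. This matches
the defaults of the standard interval toolkits this package interoperates
with.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .genome import GenomeSpec

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "PeakClassLabels",
    "read_bed",
    "write_bed",
    "merge",
    "subtract",
    "overlaps_any",
    "overlap_bases",
    "distance",
    "tile_windows",
    "consensus",
    "shuffle",
    "classify_peaks",
]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand is not None and self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class _Chrom:
    """Column store for one chromosome: parallel arrays sorted by (start, end)."""

    __slots__ = ("starts", "ends", "names", "scores", "strands")

    def __init__(self, starts, ends, names=None, scores=None, strands=None):
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        self.names = names  # list[str|None] | None
        self.scores = scores  # list[float|None] | None
        self.strands = strands  # list[str|None] | None

    def sort(self) -> "_Chrom":
        order = np.lexsort((self.ends, self.starts))
        if np.array_equal(order, np.arange(len(order))):
            return self
        take = lambda xs: [xs[i] for i in order] if xs is not None else None
        return _Chrom(self.starts[order], self.ends[order], take(self.names),
                      take(self.scores), take(self.strands))

    def __len__(self) -> int:
        return len(self.starts)


class IntervalSet:
    """Per-chromosome sorted collections of intervals (peaks, repeats, windows ...).

    Iteration order is canonical: chromosomes sorted by name, intervals sorted
    by ``(start, end)`` within each chromosome. All per-interval vector outputs
    (overlap flags, region means) follow this order.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), label: str = "",
                 genome: GenomeSpec | None = None):
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        data: dict[str, _Chrom] = {}
        for chrom, ivs in by_chrom.items():
            names = [iv.name for iv in ivs]
            scores = [iv.score for iv in ivs]
            strands = [iv.strand for iv in ivs]
            data[chrom] = _Chrom(
                [iv.start for iv in ivs], [iv.end for iv in ivs],
                names if any(n is not None for n in names) else None,
                scores if any(s is not None for s in scores) else None,
                strands if any(s is not None for s in strands) else None,
            ).sort()
        self._data = data
        self.label = label
        if genome is not None:
            self.validate(genome)

    @classmethod
    def from_arrays(cls, data: dict[str, tuple], label: str = "",
                    genome: GenomeSpec | None = None, presorted: bool = False) -> "IntervalSet":
        """Fast constructor from ``{chrom: (starts, ends[, names[, strands]])}``."""
        obj = cls.__new__(cls)
        obj._data = {}
        obj.label = label
        for chrom, cols in data.items():
            starts, ends = cols[0], cols[1]
            names = cols[2] if len(cols) > 2 else None
            strands = cols[3] if len(cols) > 3 else None
            ch = _Chrom(starts, ends, names=names, strands=strands)
            if len(ch) == 0:
                continue
            if np.any(ch.starts < 0) or np.any(ch.starts >= ch.ends):
                raise ValueError(f"invalid interval coordinates on {chrom}")
            obj._data[chrom] = ch if presorted else ch.sort()
        if genome is not None:
            obj.validate(genome)
        return obj

    # -- basic protocol -----------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return sorted(c for c in self._data if len(self._data[c]))

    def starts(self, chrom: str) -> np.ndarray:
        ch = self._data.get(chrom)
        return ch.starts if ch is not None else np.empty(0, dtype=np.int64)

    def ends(self, chrom: str) -> np.ndarray:
        ch = self._data.get(chrom)
        return ch.ends if ch is not None else np.empty(0, dtype=np.int64)

    def names(self, chrom: str) -> list | None:
        ch = self._data.get(chrom)
        return ch.names if ch is not None else None

    def __len__(self) -> int:
        return sum(len(ch) for ch in self._data.values())

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in self.chroms:
            ch = self._data[chrom]
            for i in range(len(ch)):
                yield GenomicInterval(
                    chrom, int(ch.starts[i]), int(ch.ends[i]),
                    name=ch.names[i] if ch.names else None,
                    score=ch.scores[i] if ch.scores else None,
                    strand=ch.strands[i] if ch.strands else None,
                )

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return list(self) == list(other)

    def validate(self, genome: GenomeSpec) -> None:
        lengths = genome.lengths()
        for chrom in self._data:
            if chrom not in lengths:
                raise ValueError(f"chromosome {chrom!r} absent from genome")
            ch = self._data[chrom]
            if len(ch) and ch.ends.max() > lengths[chrom]:
                bad = int(np.argmax(ch.ends))
                raise ValueError(
                    f"interval {chrom}:{ch.starts[bad]}-{ch.ends[bad]} exceeds "
                    f"chromosome length {lengths[chrom]}"
                )

    def covered_bases(self) -> int:
        """Number of distinct bases covered by at least one interval."""
        total = 0
        for chrom in self._data:
            ms, me = _merge_arrays(self.starts(chrom), self.ends(chrom), 0)
            total += int((me - ms).sum())
        return total

    def subset(self, mask: Sequence[bool]) -> "IntervalSet":
        """Intervals where ``mask`` (in canonical iteration order) is True."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (len(self),):
            raise ValueError("mask length must equal number of intervals")
        data = {}
        off = 0
        for chrom in self.chroms:
            ch = self._data[chrom]
            m = mask[off:off + len(ch)]
            off += len(ch)
            take = lambda xs: [x for x, k in zip(xs, m) if k] if xs is not None else None
            data[chrom] = (ch.starts[m], ch.ends[m], take(ch.names), take(ch.strands))
        return IntervalSet.from_arrays(data, label=self.label, presorted=True)


# -- internal array helpers ---------------------------------------------------


def _merge_arrays(starts: np.ndarray, ends: np.ndarray, gap: int):
    """Merge sorted interval arrays joining intervals whose gap is <= ``gap``."""
    if len(starts) == 0:
        return starts, ends
    cummax = np.maximum.accumulate(ends)
    new = np.empty(len(starts), dtype=bool)
    new[0] = True
    new[1:] = starts[1:] > cummax[:-1] + gap
    idx = np.flatnonzero(new)
    out_starts = starts[idx]
    out_ends = np.empty(len(idx), dtype=np.int64)
    out_ends[:-1] = np.maximum.reduceat(cummax, idx)[:-1]
    out_ends[-1] = cummax[-1]
    return out_starts, out_ends


def _overlap_flags(qs, qe, ms, me):
    """Boolean flag per query: >=1 bp overlap with the merged subject arrays."""
    if len(ms) == 0 or len(qs) == 0:
        return np.zeros(len(qs), dtype=bool)
    idx = np.searchsorted(me, qs, side="right")
    inb = idx < len(ms)
    flags = np.zeros(len(qs), dtype=bool)
    flags[inb] = ms[idx[inb]] < qe[inb]
    return flags


def _coverage_prefix(ms: np.ndarray, me: np.ndarray):
    """Return F with F(x) = covered bases of the merged set in [0, x)."""
    cum = np.concatenate([[0], np.cumsum(me - ms)])

    def F(x):
        x = np.asarray(x, dtype=np.int64)
        j = np.searchsorted(ms, x, side="right")
        res = cum[j].copy()
        has = j > 0
        jm = np.maximum(j - 1, 0)
        res[has] -= np.maximum(me[jm][has] - x[has], 0)
        return res

    return F


# -- public operations --------------------------------------------------------


def merge(s: IntervalSet, gap: int = 0) -> IntervalSet:
    """Union of intervals, joining any pair whose gap is <= ``gap`` bp.

    Abutting intervals (gap 0) are joined at the default. Names/scores/strands
    are dropped: a merged region has no single provenance.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    data = {c: _merge_arrays(s.starts(c), s.ends(c), gap) for c in s.chroms}
    return IntervalSet.from_arrays(data, label=s.label, presorted=True)


def subtract(s: IntervalSet, excluded: IntervalSet) -> IntervalSet:
    """Remove every base of ``excluded`` from ``s``; intervals may be split."""
    data = {}
    for chrom in s.chroms:
        qs, qe = s.starts(chrom), s.ends(chrom)
        ms, me = _merge_arrays(excluded.starts(chrom), excluded.ends(chrom), 0)
        out_s, out_e = [], []
        lo = np.searchsorted(me, qs, side="right")
        hi = np.searchsorted(ms, qe, side="left")
        for i in range(len(qs)):
            cur = qs[i]
            for j in range(lo[i], hi[i]):
                if ms[j] > cur:
                    out_s.append(cur)
                    out_e.append(ms[j])
                cur = max(cur, me[j])
            if cur < qe[i]:
                out_s.append(cur)
                out_e.append(qe[i])
        data[chrom] = (np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64))
    return IntervalSet.from_arrays(data, label=s.label)


def overlaps_any(query: IntervalSet, subject: IntervalSet) -> np.ndarray:
    """Per query interval (canonical order), True iff >=1 bp overlaps ``subject``."""
    flags = []
    for chrom in query.chroms:
        ms, me = _merge_arrays(subject.starts(chrom), subject.ends(chrom), 0)
        flags.append(_overlap_flags(query.starts(chrom), query.ends(chrom), ms, me))
    return np.concatenate(flags) if flags else np.zeros(0, dtype=bool)


def overlap_bases(query: IntervalSet, subject: IntervalSet) -> np.ndarray:
    """Per query interval, the number of its bases covered by ``subject``."""
    out = []
    for chrom in query.chroms:
        ms, me = _merge_arrays(subject.starts(chrom), subject.ends(chrom), 0)
        if len(ms) == 0:
            out.append(np.zeros(len(query.starts(chrom)), dtype=np.int64))
            continue
        F = _coverage_prefix(ms, me)
        out.append(F(query.ends(chrom)) - F(query.starts(chrom)))
    return np.concatenate(out) if out else np.zeros(0, dtype=np.int64)


def distance(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Gap in bp between two intervals; 0 when overlapping or abutting.

    Returns ``None`` (a typed undefined sentinel, never a large number) when
    the intervals lie on different chromosomes.
    """
    if a.chrom != b.chrom:
        return None
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def tile_windows(genome: GenomeSpec, size: int,
                 excluded: IntervalSet | None = None) -> IntervalSet:
    """Tile each chromosome with non-overlapping ``size``-bp windows.

    The trailing partial window is dropped so all windows are equal-sized
    exchangeable units. Windows overlapping ``excluded`` by >=1 bp are removed.
    """
    if size < 1:
        raise ValueError("window size must be >= 1")
    data = {}
    for chrom, length in genome:
        n = length // size
        starts = np.arange(n, dtype=np.int64) * size
        ends = starts + size
        if excluded is not None and n:
            ms, me = _merge_arrays(excluded.starts(chrom), excluded.ends(chrom), 0)
            keep = ~_overlap_flags(starts, ends, ms, me)
            starts, ends = starts[keep], ends[keep]
        data[chrom] = (starts, ends)
    return IntervalSet.from_arrays(data, label=f"windows_{size}", presorted=True)


def consensus(sets: Sequence[IntervalSet], min_support: int | None = None) -> IntervalSet:
    """Maximal regions covered by at least ``min_support`` of the input sets.

    Support is counted per base and per set (a set covers a base if any of its
    intervals does). ``min_support`` defaults to ``len(sets)`` — the full
    intersection across replicates/antibodies; each output region is one
    consensus locus.
    """
    if not sets:
        raise ValueError("need at least one interval set")
    k = len(sets)
    if min_support is None:
        min_support = k
    if not 1 <= min_support <= k:
        raise ValueError(f"min_support must be in [1, {k}]")
    chroms = sorted({c for s in sets for c in s.chroms})
    data = {}
    for chrom in chroms:
        pos_parts, delta_parts = [], []
        for s in sets:
            ms, me = _merge_arrays(s.starts(chrom), s.ends(chrom), 0)
            pos_parts += [ms, me]
            delta_parts += [np.ones(len(ms), dtype=np.int64),
                            -np.ones(len(me), dtype=np.int64)]
        pos = np.concatenate(pos_parts)
        delta = np.concatenate(delta_parts)
        order = np.argsort(pos, kind="stable")
        pos, delta = pos[order], delta[order]
        upos, uidx = np.unique(pos, return_index=True)
        usum = np.add.reduceat(delta, uidx)
        support = np.cumsum(usum)
        above = support >= min_support
        start_idx = np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))
        end_idx = np.flatnonzero(~above & np.concatenate([[False], above[:-1]]))
        data[chrom] = (upos[start_idx], upos[end_idx])
    return IntervalSet.from_arrays(data, label="consensus", presorted=True)


_MAX_SHUFFLE_ATTEMPTS = 1000


def shuffle(s: IntervalSet, genome: GenomeSpec, excluded: IntervalSet | None = None,
            seed: int | np.random.Generator | None = None) -> IntervalSet:
    """Re-place each interval uniformly at random on its own chromosome.

    Lengths and per-chromosome counts are preserved; shuffled intervals may
    overlap one another. Placements overlapping ``excluded`` are rejection-
    sampled with a cap of 1,000 attempts per interval, so pathological
    exclusion coverage raises a loud error instead of looping forever.
    Deterministic given ``seed`` (an int or a ``numpy.random.Generator``).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths = genome.lengths()
    data = {}
    for chrom in s.chroms:
        if chrom not in lengths:
            raise ValueError(f"chromosome {chrom!r} absent from genome")
        L = lengths[chrom]
        ivlen = s.ends(chrom) - s.starts(chrom)
        max_start = L - ivlen
        if np.any(max_start < 0):
            bad = int(np.argmax(ivlen))
            raise ValueError(
                f"interval {chrom}:{s.starts(chrom)[bad]}-{s.ends(chrom)[bad]} "
                f"longer than chromosome ({L} bp)"
            )
        new_starts = rng.integers(0, max_start + 1)
        if excluded is not None:
            ms, me = _merge_arrays(excluded.starts(chrom), excluded.ends(chrom), 0)
            if len(ms):
                bad = _overlap_flags(new_starts, new_starts + ivlen, ms, me)
                attempts = 1
                while np.any(bad):
                    if attempts >= _MAX_SHUFFLE_ATTEMPTS:
                        i = int(np.flatnonzero(bad)[0])
                        raise ValueError(
                            f"could not place interval {chrom}:{s.starts(chrom)[i]}-"
                            f"{s.ends(chrom)[i]} outside exclusions after "
                            f"{_MAX_SHUFFLE_ATTEMPTS} attempts"
                        )
                    idx = np.flatnonzero(bad)
                    new_starts[idx] = rng.integers(0, max_start[idx] + 1)
                    bad[idx] = _overlap_flags(new_starts[idx], new_starts[idx] + ivlen[idx],
                                              ms, me)
                    attempts += 1
        data[chrom] = (new_starts, new_starts + ivlen)
    return IntervalSet.from_arrays(data, label=s.label)


@dataclass
class PeakClassLabels:
    """Euchromatic/heterochromatic partition of a peak set, with QC fractions.

    ``labels`` follows the canonical iteration order of the classified peaks.
    ``evidence_fractions`` reports, for each euchromatin-evidence set (open
    chromatin, active histone marks), the fraction of peaks overlapping it —
    reported as QC only; the dichotomy is driven by the heterochromatin marks.
    """

    labels: list[str]
    euchromatic: IntervalSet
    heterochromatic: IntervalSet
    fraction_euchromatic: float
    fraction_heterochromatic: float
    evidence_fractions: dict[str, float] = field(default_factory=dict)

    def peaks_in_class(self, peak_class: str) -> IntervalSet:
        if peak_class == "euchromatic":
            return self.euchromatic
        if peak_class == "heterochromatic":
            return self.heterochromatic
        raise KeyError(peak_class)


def classify_peaks(peaks: IntervalSet, heterochromatin_marks: IntervalSet,
                   euchromatin_evidence: Sequence[IntervalSet] = ()) -> PeakClassLabels:
    """Label each peak heterochromatic iff it overlaps the heterochromatin marks.

    Every other peak is euchromatic. Overlap fractions against each
    euchromatin-evidence set are reported as QC but do not affect the labels.
    """
    het = overlaps_any(peaks, heterochromatin_marks)
    n = len(peaks)
    labels = ["heterochromatic" if h else "euchromatic" for h in het]
    evidence = {}
    for i, ev in enumerate(euchromatin_evidence):
        key = ev.label or f"evidence_{i}"
        evidence[key] = float(np.mean(overlaps_any(peaks, ev))) if n else 0.0
    return PeakClassLabels(
        labels=labels,
        euchromatic=peaks.subset(~het),
        heterochromatic=peaks.subset(het),
        fraction_euchromatic=float(np.mean(~het)) if n else 0.0,
        fraction_heterochromatic=float(np.mean(het)) if n else 0.0,
        evidence_fractions=evidence,
    )


# -- BED I/O ------------------------------------------------------------------


def read_bed(path: str | Path, genome: GenomeSpec | None = None,
             label: str | None = None) -> IntervalSet:
    """Read BED3+ (tab-separated, 0-based half-open) into an IntervalSet.

    Lines starting with ``#``, ``track`` or ``browser`` are skipped. Malformed
    lines raise an error naming the line number.
    """
    ivs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates "
                    f"{fields[1]!r}/{fields[2]!r}"
                ) from None
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError:
                    raise ValueError(
                        f"{path}: line {lineno}: non-numeric score {fields[4]!r}"
                    ) from None
            strand = fields[5] if len(fields) > 5 and fields[5] != "." else None
            try:
                ivs.append(GenomicInterval(fields[0], start, end, name, score, strand))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    if label is None:
        label = Path(path).stem
    return IntervalSet(ivs, label=label, genome=genome)


def write_bed(s: IntervalSet, path: str | Path) -> None:
    """Write BED6 when any name/score/strand is present, else BED3."""
    bed6 = any(iv.name is not None or iv.score is not None or iv.strand is not None
               for iv in s)
    with open(path, "w") as fh:
        for iv in s:
            if bed6:
                score = "0" if iv.score is None else (
                    f"{iv.score:g}" if iv.score != int(iv.score) else str(int(iv.score)))
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                         f"{score}\t{iv.strand or '.'}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
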