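"""Gene models, gene sets, and region-to-gene association rules.

Two association conventions coexist, both exposed:

* Proximity (``proximal_gene_ids``) is measured from the gene BODY: a gene is
  proximal when its body lies within ``max_distance`` bp of a peak (overlap
  counts as distance 0). Equivalent to widening each gene by the distance and
  intersecting with peaks — ``extend_genes`` provides that formulation.
* Nearest-gene assignment (``nearest_gene``) is TSS-based: each peak midpoint
  is linked to the single nearest transcription start site within a cutoff,
  with an orientation-aware signed distance (upstream negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome import GenomeSpec
from .intervals import IntervalSet, _merge_arrays, _overlap_flags

__all__ = [
    "GeneModel",
    "GeneTable",
    "GeneSet",
    "TssDistanceHistogram",
    "read_genes",
    "read_gene_sets",
    "write_gene_sets",
    "proximal_gene_ids",
    "extend_genes",
    "nearest_gene",
    "tss_distance_histogram",
]

DEFAULT_BIOTYPE = "protein_coding"


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = DEFAULT_BIOTYPE

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: invalid body "
                             f"{self.chrom}:{self.start}-{self.end}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        """Strand-aware TSS coordinate: start for +, end-1 for -."""
        return self.start if self.strand == "+" else self.end - 1


class GeneTable:
    """Gene models indexed by unique gene_id."""

    def __init__(self, genes: Iterable[GeneModel], genome: GenomeSpec | None = None):
        self.genes = list(genes)
        self.by_id = {}
        for g in self.genes:
            if g.gene_id in self.by_id:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            self.by_id[g.gene_id] = g
        if genome is not None:
            lengths = genome.lengths()
            for g in self.genes:
                if g.chrom not in lengths:
                    raise ValueError(f"gene {g.gene_id}: chromosome {g.chrom!r} "
                                     f"absent from genome")
                if g.end > lengths[g.chrom]:
                    raise ValueError(f"gene {g.gene_id} exceeds chromosome length")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.by_id

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.by_id[gene_id]

    def ids(self) -> set[str]:
        return set(self.by_id)

    def subset(self, gene_ids: Iterable[str]) -> "GeneTable":
        return GeneTable(self.by_id[g] for g in gene_ids)

    def intervals(self) -> IntervalSet:
        """Gene bodies as an IntervalSet, names carrying gene ids."""
        return IntervalSet.from_arrays(self._arrays())

    def _arrays(self, flank: int = 0, lengths: Mapping[str, int] | None = None):
        data: dict[str, list] = {}
        for g in self.genes:
            data.setdefault(g.chrom, []).append(g)
        out = {}
        for chrom, gs in data.items():
            starts = np.array([g.start for g in gs], dtype=np.int64)
            ends = np.array([g.end for g in gs], dtype=np.int64)
            if flank:
                starts = np.maximum(starts - flank, 0)
                ends = ends + flank
                if lengths is not None:
                    ends = np.minimum(ends, lengths[chrom])
            out[chrom] = (starts, ends, [g.gene_id for g in gs],
                          [g.strand for g in gs])
        return out


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene ids (risk genes, regulator targets, ...)."""

    name: str
    members: frozenset[str]

    def __init__(self, name: str, members: Iterable[str]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "members", frozenset(members))

    def __len__(self) -> int:
        return len(self.members)


def read_genes(path: str | Path, biotype_map: str | Path | None = None,
               genome: GenomeSpec | None = None) -> GeneTable:
    """Read gene models from BED6 (gene_id in the name column).

    ``biotype_map`` is an optional two-column TSV mapping gene_id to biotype;
    unmapped genes default to protein_coding. Missing strand or duplicate ids
    are errors.
    """
    biotypes: dict[str, str] = {}
    if biotype_map is not None:
        with open(biotype_map) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"{biotype_map}: line {lineno}: expected 2 columns")
                biotypes[fields[0]] = fields[1]
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: gene BED needs 6 columns")
            if fields[5] not in {"+", "-"}:
                raise ValueError(f"{path}: line {lineno}: missing or invalid strand "
                                 f"{fields[5]!r}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from None
            gid = fields[3]
            genes.append(GeneModel(gid, fields[0], start, end, fields[5],
                                   biotype=biotypes.get(gid, DEFAULT_BIOTYPE)))
    return GeneTable(genes, genome=genome)


def read_gene_sets(path: str | Path) -> dict[str, GeneSet]:
    """Read gene sets from a two-column TSV: set_name, gene_id."""
    members: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected set_name<TAB>gene_id")
            members.setdefault(fields[0], set()).add(fields[1])
    return {name: GeneSet(name, ids) for name, ids in members.items()}


def write_gene_sets(sets: Mapping[str, GeneSet] | Sequence[GeneSet],
                    path: str | Path) -> None:
    seq = sets.values() if isinstance(sets, Mapping) else sets
    with open(path, "w") as fh:
        fh.write("#set_name\tgene_id\n")
        for gs in seq:
            for gid in sorted(gs.members):
                fh.write(f"{gs.name}\t{gid}\n")


def proximal_gene_ids(peaks: IntervalSet, genes: GeneTable,
                      max_distance: int = 50_000) -> set[str]:
    """Gene ids whose body lies within ``max_distance`` bp of any peak.

    Distance is the body-to-peak gap on the same chromosome; overlap counts
    as 0. ``max_distance=0`` therefore selects genes whose bodies overlap at
    least one peak.
    """
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    out: set[str] = set()
    arrays = genes._arrays()
    for chrom, (gs, ge, gids, _) in arrays.items():
        ms, me = _merge_arrays(peaks.starts(chrom), peaks.ends(chrom), 0)
        if len(ms) == 0:
            continue
        overlap = _overlap_flags(gs, ge, ms, me)
        # nearest peak entirely to the right / left of the gene body
        ridx = np.searchsorted(ms, ge, side="left")
        right_gap = np.where(ridx < len(ms), ms[np.minimum(ridx, len(ms) - 1)] - ge,
                             np.iinfo(np.int64).max)
        lidx = np.searchsorted(me, gs, side="right")
        left_gap = np.where(lidx > 0, gs - me[np.maximum(lidx, 1) - 1],
                            np.iinfo(np.int64).max)
        gap = np.minimum(right_gap, left_gap)
        gap[overlap] = 0
        for i in np.flatnonzero(gap <= max_distance):
            out.add(gids[i])
    return out


def extend_genes(genes: GeneTable, flank: int = 100_000,
                 genome: GenomeSpec | None = None) -> IntervalSet:
    """Widen each gene body by ``flank`` bp on both sides, clipped to the genome.

    Interval names carry gene ids, so overlapping the result with a peak set
    yields exactly the genes proximal at distance ``flank``.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    lengths = genome.lengths() if genome is not None else None
    return IntervalSet.from_arrays(genes._arrays(flank=flank, lengths=lengths))


def nearest_gene(peaks: IntervalSet, genes: GeneTable,
                 max_distance: int = 1_000_000) -> list[tuple[str | None, int | None]]:
    """Assign each peak to the single nearest gene TSS within ``max_distance``.

    The peak position is its midpoint (integer floor). The signed distance is
    negative when the midpoint lies upstream of the TSS in the gene's
    orientation. Ties on absolute distance resolve to the lower-coordinate
    TSS. Peaks with no TSS within the cutoff get ``(None, None)``.
    """
    per_chrom: dict[str, list[GeneModel]] = {}
    for g in genes.genes:
        per_chrom.setdefault(g.chrom, []).append(g)
    index = {}
    for chrom, gs in per_chrom.items():
        tss = np.array([g.tss for g in gs], dtype=np.int64)
        order = np.argsort(tss, kind="stable")
        index[chrom] = (tss[order], [gs[i] for i in order])
    out: list[tuple[str | None, int | None]] = []
    for iv in peaks:
        entry = index.get(iv.chrom)
        if entry is None:
            out.append((None, None))
            continue
        tss, gs = entry
        mid = iv.midpoint
        pos = int(np.searchsorted(tss, mid))
        best = None
        for j in (pos - 1, pos):
            if 0 <= j < len(tss):
                d = abs(mid - int(tss[j]))
                if best is None or d < best[0]:
                    best = (d, j)
        if best is None or best[0] > max_distance:
            out.append((None, None))
            continue
        g = gs[best[1]]
        signed = (mid - g.tss) if g.strand == "+" else (g.tss - mid)
        out.append((g.gene_id, int(signed)))
    return out


@dataclass
class TssDistanceHistogram:
    """Signed TSS-distance histogram (upstream negative) with half-open bins."""

    bin_edges: np.ndarray
    counts: np.ndarray
    unassigned: int

    @property
    def total(self) -> int:
        return int(self.counts.sum()) + self.unassigned


def tss_distance_histogram(assignments: Sequence[tuple[str | None, int | None]],
                           bin_edges: Sequence[int]) -> TssDistanceHistogram:
    """Bin nearest-gene signed distances into half-open bins ``[e_i, e_{i+1})``.

    Unassigned peaks and distances outside the edge range count as unassigned,
    so the histogram always conserves the number of input peaks.
    """
    edges = np.asarray(bin_edges, dtype=np.int64)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing with >= 2 edges")
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    unassigned = 0
    for gid, d in assignments:
        if gid is None or d < edges[0] or d >= edges[-1]:
            unassigned += 1
        else:
            counts[np.searchsorted(edges, d, side="right") - 1] += 1
    return TssDistanceHistogram(edges, counts, unassigned)
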