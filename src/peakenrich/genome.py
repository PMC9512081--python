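"""Genome coordinate frame: ordered chromosome names and lengths."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosomes with lengths; the coordinate frame for all interval sets.

    Parameters
    ----------
    chroms
        Sequence of ``(name, length_bp)`` pairs. Names must be unique and
        lengths positive. Order is preserved and stable for the lifetime of
        the object.
    """

    chroms: tuple[tuple[str, int], ...]

    def __init__(self, chroms: Iterable[tuple[str, int]]):
        chroms = tuple((str(n), int(l)) for n, l in chroms)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome")
        for n, l in chroms:
            if l < 1:
                raise ValueError(f"chromosome {n!r} has non-positive length {l}")
        object.__setattr__(self, "chroms", chroms)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chroms)

    def __contains__(self, name: str) -> bool:
        return name in self.lengths()

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.chroms)

    def __len__(self) -> int:
        return len(self.chroms)

    def lengths(self) -> dict[str, int]:
        return dict(self.chroms)

    def length(self, name: str) -> int:
        try:
            return self.lengths()[name]
        except KeyError:
            raise KeyError(f"chromosome {name!r} not in genome") from None

    def total_length(self) -> int:
        return sum(l for _, l in self.chroms)


def read_chrom_sizes(path: str | Path) -> GenomeSpec:
    """Read a two-column ``name<TAB>length`` chromosome-sizes file."""
    chroms = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {i}: expected 2 tab-separated columns")
            try:
                length = int(fields[1])
            except ValueError:
                raise ValueError(f"{path}: line {i}: length {fields[1]!r} is not an integer")
            chroms.append((fields[0], length))
    return GenomeSpec(chroms)


def write_chrom_sizes(genome: GenomeSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in genome:
            fh.write(f"{name}\t{length}\n")
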