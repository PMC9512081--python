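"""Empirical p-values by resampling and permutation.

Two null machines live here:

* ``gene_set_resampling_test`` — is the percentage of a target gene set lying
  near peaks higher than for random, size-matched draws from a background
  pool of genes?
* ``multiway_overlap_permutation_test`` — is the number of consensus loci
  shared by several peak sets higher than expected when each set is shuffled
  within its own chromosomes?

Both report the add-one empirical p-value (k+1)/(R+1), never zero, with a
floor of 1/(R+1); the raw exceedance count k is also emitted so a k/R
convention can be recovered. Draw order is documented and fixed: within each
test a single seeded generator produces the resampled sets (or the shuffles)
in replicate order, sets in input order within a replicate. Determinism is
promised within this implementation, not bit-level across languages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .annotation import GeneSet, GeneTable, proximal_gene_ids
from .genome import GenomeSpec
from .intervals import IntervalSet, consensus, shuffle

__all__ = [
    "ResamplingResult",
    "PermutationResult",
    "empirical_pvalue",
    "gene_set_resampling_test",
    "multiway_overlap_permutation_test",
]


def empirical_pvalue(observed: float, null_values: Sequence[float],
                     direction: str = "greater") -> float:
    """Add-one empirical p: (1 + #{null >= observed}) / (1 + R) for ``greater``.

    Ties count against the observation; the symmetric rule applies for
    ``less``. Never returns 0; the floor is exactly 1/(R+1).
    """
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0:
        raise ValueError("null_values must be non-empty")
    if direction == "greater":
        k = int(np.sum(null_values >= observed))
    elif direction == "less":
        k = int(np.sum(null_values <= observed))
    else:
        raise ValueError("direction must be 'greater' or 'less'")
    return (1 + k) / (1 + null_values.size)


@dataclass
class ResamplingResult:
    """Observed statistic vs R resampled values, with add-one empirical p."""

    observed_statistic: float
    resample_values: np.ndarray
    R: int
    empirical_p: float
    k: int  # number of resamples >= (or <=) the observation
    seed: int
    direction: str = "greater"

    def to_json(self, path: str | Path | None = None) -> str:
        rec = {"observed": self.observed_statistic, "R": self.R, "k": self.k,
               "empirical_p": self.empirical_p, "seed": self.seed,
               "direction": self.direction}
        text = json.dumps(rec, indent=1)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


@dataclass
class PermutationResult:
    observed_count: int
    permuted_counts: np.ndarray
    R: int
    empirical_p: float
    k: int
    seed: int
    direction: str = "greater"

    def to_json(self, path: str | Path | None = None) -> str:
        rec = {"observed": self.observed_count, "R": self.R, "k": self.k,
               "empirical_p": self.empirical_p, "seed": self.seed,
               "direction": self.direction}
        text = json.dumps(rec, indent=1)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def gene_set_resampling_test(target_set: GeneSet, background_pool: Iterable[str],
                             peaks: IntervalSet, genes: GeneTable,
                             max_distance: int = 50_000, R: int = 1000,
                             match_size: int | None = None,
                             seed: int = 0) -> ResamplingResult:
    """Empirical p for the percentage of target genes proximal to peaks.

    The observed statistic is the percentage of target-set members whose gene
    body lies within ``max_distance`` of a peak. R random gene sets are drawn
    uniformly WITHOUT replacement from ``background_pool``; each draw has the
    target set's size unless ``match_size`` fixes another size (e.g. the
    512-gene convention). Direction is greater; add-one p.
    """
    pool = sorted(set(background_pool))
    missing = (set(pool) | set(target_set.members)) - genes.ids()
    if missing:
        raise ValueError(f"genes absent from gene table: {sorted(missing)[:5]} ...")
    size = len(target_set) if match_size is None else int(match_size)
    if size > len(pool):
        raise ValueError(f"resample size {size} exceeds background pool "
                         f"size {len(pool)}")
    if size < 1:
        raise ValueError("resample size must be >= 1")
    relevant = genes.subset(set(pool) | set(target_set.members))
    proximal = proximal_gene_ids(peaks, relevant, max_distance)
    observed = 100.0 * len(target_set.members & proximal) / len(target_set)
    prox_flags = np.array([g in proximal for g in pool], dtype=bool)
    rng = np.random.default_rng(seed)
    values = np.empty(R, dtype=float)
    for r in range(R):
        idx = rng.choice(len(pool), size=size, replace=False)
        values[r] = 100.0 * prox_flags[idx].mean()
    k = int(np.sum(values >= observed))
    return ResamplingResult(observed, values, R, (1 + k) / (1 + R), k, seed)


def multiway_overlap_permutation_test(sets: Sequence[IntervalSet], genome: GenomeSpec,
                                      excluded: IntervalSet | None = None,
                                      min_support: int | None = None, R: int = 1000,
                                      seed: int = 0) -> PermutationResult:
    """Permutation p for the number of multi-set consensus loci.

    Observed statistic: the count of consensus loci supported by at least
    ``min_support`` of the sets (default: all of them). Null: every set is
    independently re-placed within its own chromosomes (length-preserving,
    avoiding ``excluded``), R times, recounting each time.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    observed = len(consensus(sets, min_support))
    rng = np.random.default_rng(seed)
    counts = np.empty(R, dtype=np.int64)
    for r in range(R):
        shuffled = [shuffle(s, genome, excluded=excluded, seed=rng) for s in sets]
        counts[r] = len(consensus(shuffled, min_support))
    k = int(np.sum(counts >= observed))
    return PermutationResult(observed, counts, R, (1 + k) / (1 + R), k, seed)
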