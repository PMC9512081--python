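"""Window-based transposable-element (repeat-family) enrichment.

The genome is tiled into non-overlapping fixed-size windows (100 bp by
default, blacklist-excluded). Each window is flagged for overlap with each
repeat family and with the peak set; the resulting per-family 2x2 table of
window counts feeds the odds ratio and Fisher exact test, with BH correction
across the families tested in one call. Windows — not bases, not peaks — are
the exchangeable unit, so a peak spanning several windows contributes several
peak-positive windows by construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .enrichment import ContingencyTable, bh_adjust, fisher_exact_two_sided, odds_ratio
from .genome import GenomeSpec
from .intervals import (IntervalSet, PeakClassLabels, overlap_bases, overlaps_any,
                        read_bed, tile_windows)

__all__ = [
    "FamilyEnrichmentResult",
    "read_repeats_bed",
    "repeat_family_enrichment",
    "enrichment_by_peak_class",
    "write_family_results_tsv",
]

logger = logging.getLogger(__name__)


@dataclass
class FamilyEnrichmentResult:
    family: str
    peak_class: str
    table: ContingencyTable  # unit = windows; total == retained windows
    odds_ratio: float
    p_value: float
    q_value: float


def read_repeats_bed(path: str | Path, genome: GenomeSpec | None = None
                     ) -> dict[str, IntervalSet]:
    """Read a family-labeled repeat annotation (BED6, family in name column)."""
    all_reps = read_bed(path, genome=genome)
    by_family: dict[str, list] = {}
    for iv in all_reps:
        if iv.name is None:
            raise ValueError(f"{path}: repeat record {iv.chrom}:{iv.start}-{iv.end} "
                             f"has no family name")
        by_family.setdefault(iv.name, []).append(iv)
    return {fam: IntervalSet(ivs, label=fam) for fam, ivs in sorted(by_family.items())}


def _window_flags(windows: IntervalSet, features: IntervalSet, window: int,
                  min_fraction: float) -> np.ndarray:
    if min_fraction <= 0:
        return overlaps_any(windows, features)
    need = max(1, int(math.ceil(min_fraction * window)))
    return overlap_bases(windows, features) >= need


def repeat_family_enrichment(peaks: IntervalSet,
                             repeats: Mapping[str, IntervalSet],
                             genome: GenomeSpec,
                             blacklist: IntervalSet | None = None,
                             window: int = 100,
                             min_fraction: float = 0.0,
                             peak_class: str = "all") -> list[FamilyEnrichmentResult]:
    """Per-family window-count enrichment of repeats within peaks.

    A window counts as overlapping a feature at >= 1 bp by default
    (``min_fraction`` optionally requires a minimum covered fraction of the
    window instead). BH correction spans the families of this call.
    """
    windows = tile_windows(genome, window, excluded=blacklist)
    n_windows = len(windows)
    if n_windows == 0:
        raise ValueError("no windows retained after blacklist exclusion")
    peak_flags = _window_flags(windows, peaks, window, min_fraction)
    n_peak = int(peak_flags.sum())
    results = []
    for family in sorted(repeats):
        fam_flags = _window_flags(windows, repeats[family], window, min_fraction)
        a = int(np.sum(fam_flags & peak_flags))
        b = int(fam_flags.sum()) - a
        c = n_peak - a
        d = n_windows - a - b - c
        t = ContingencyTable(a, b, c, d)
        results.append(FamilyEnrichmentResult(family, peak_class, t, odds_ratio(t),
                                              fisher_exact_two_sided(t), math.nan))
    qs = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
    return results


def enrichment_by_peak_class(peaks: IntervalSet, class_labels: PeakClassLabels,
                             repeats: Mapping[str, IntervalSet], genome: GenomeSpec,
                             blacklist: IntervalSet | None = None, window: int = 100,
                             min_fraction: float = 0.0
                             ) -> dict[str, list[FamilyEnrichmentResult]]:
    """Run the family enrichment separately per chromatin class of the peaks.

    BH correction is applied within each class's family of tests. An empty
    class yields an empty result list (logged), not an error.
    """
    out: dict[str, list[FamilyEnrichmentResult]] = {}
    for peak_class in ("euchromatic", "heterochromatic"):
        class_peaks = class_labels.peaks_in_class(peak_class)
        if len(class_peaks) == 0:
            logger.info("peak class %s is empty; skipping", peak_class)
            out[peak_class] = []
            continue
        out[peak_class] = repeat_family_enrichment(
            class_peaks, repeats, genome, blacklist=blacklist, window=window,
            min_fraction=min_fraction, peak_class=peak_class)
    return out


def write_family_results_tsv(results: Sequence[FamilyEnrichmentResult],
                             path: str | Path) -> None:
    """TSV including volcano-plot columns (log2 OR, -log10 q)."""
    with open(path, "w") as fh:
        fh.write("#family\tpeak_class\ta\tb\tc\td\todds_ratio\tp_value\tq_value\t"
                 "log2_odds_ratio\tneg_log10_q\n")
        for r in results:
            t = r.table
            l2 = math.log2(r.odds_ratio) if r.odds_ratio and r.odds_ratio > 0 \
                and math.isfinite(r.odds_ratio) else math.nan
            nlq = -math.log10(r.q_value) if r.q_value > 0 else math.inf
            fh.write(f"{r.family}\t{r.peak_class}\t{t.a}\t{t.b}\t{t.c}\t{t.d}\t"
                     f"{r.odds_ratio:g}\t{r.p_value:.6g}\t{r.q_value:.6g}\t"
                     f"{l2:g}\t{nlq:g}\n")
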