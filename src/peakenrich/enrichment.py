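"""Odds ratio, two-sided Fisher exact test, BH correction, and the
peak-proximity gene-set enrichment built from them.

The enrichment contrasts two indicator vectors over a declared gene universe:
membership in a gene set vs proximity of the gene body to a peak (within a
distance cutoff, 50 kb by default). The resulting 2x2 table is tested with
the two-sided Fisher exact test; q-values are BH-adjusted across exactly the
family of sets passed in one call, never pooled across calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .annotation import GeneSet, GeneTable, proximal_gene_ids
from .intervals import IntervalSet

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "odds_ratio",
    "fisher_exact_two_sided",
    "bh_adjust",
    "gene_set_enrichment",
    "write_enrichment_tsv",
]

#: Relative tolerance for the two-sided tie rule: a table counts toward the
#: p-value when its point probability is <= (1 + TIE_TOL) times the observed
#: table's. Documented so cross-language ports agree.
TIE_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: a = in-set & proximal, b = in-set only, c = proximal only,
    d = neither. The total equals the universe size in gene-set use."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise ValueError(f"counts must be non-negative integers, got {self}")

    def __iter__(self):
        return iter((self.a, self.b, self.c, self.d))

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def odds_ratio(table: ContingencyTable | tuple, haldane: bool = False) -> float:
    """Sample odds ratio (a*d)/(b*c).

    Returns ``+inf`` when b*c == 0 with a*d > 0, and ``nan`` (undefined
    sentinel) when both products are zero. With ``haldane=True`` the
    Haldane-Anscombe correction (+0.5 to every cell) is applied instead,
    which is always finite.
    """
    a, b, c, d = table
    if haldane:
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


def fisher_exact_two_sided(table: ContingencyTable | tuple) -> float:
    """Two-sided Fisher exact p-value by the point-probability rule.

    With margins fixed, sums the hypergeometric probabilities of every table
    whose point probability is at most that of the observed table (relative
    tie tolerance ``TIE_TOL``). Degenerate margins give p = 1.
    """
    a, b, c, d = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    k = np.arange(lo, hi + 1)
    logp = (
        gammaln(r1 + 1) - gammaln(k + 1) - gammaln(r1 - k + 1)
        + gammaln(r2 + 1) - gammaln(c1 - k + 1) - gammaln(r2 - c1 + k + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    mask = logp <= logp[a - lo] + math.log1p(TIE_TOL)
    return float(min(1.0, math.exp(logsumexp(logp[mask]))))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class EnrichmentResult:
    set_name: str
    table: ContingencyTable
    odds_ratio: float
    p_value: float
    q_value: float


def gene_set_enrichment(peaks: IntervalSet, genes: GeneTable,
                        universe: Iterable[str], gene_sets: Sequence[GeneSet],
                        max_distance: int = 50_000,
                        haldane: bool = False) -> list[EnrichmentResult]:
    """Test each gene set for enrichment of peak-proximal genes over a universe.

    The universe (e.g. all protein-coding genes) fixes the table total; set
    members are intersected with it before counting. One BH family = the sets
    of this call. A set with empty intersection yields boundary counts, not an
    error.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    missing = universe - genes.ids()
    if missing:
        raise ValueError(f"universe genes absent from gene table: "
                         f"{sorted(missing)[:5]} ...")
    proximal = proximal_gene_ids(peaks, genes.subset(universe), max_distance)
    results = []
    for gs in gene_sets:
        members = gs.members & universe
        a = len(members & proximal)
        b = len(members) - a
        c = len(proximal) - a
        d = len(universe) - a - b - c
        t = ContingencyTable(a, b, c, d)
        results.append(EnrichmentResult(gs.name, t, odds_ratio(t, haldane=haldane),
                                        fisher_exact_two_sided(t), math.nan))
    qs = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
    return results


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    """Write results as TSV; infinite odds ratios serialize as ``inf``."""
    with open(path, "w") as fh:
        fh.write("#set_name\ta\tb\tc\td\todds_ratio\tp_value\tq_value\n")
        for r in results:
            t = r.table
            fh.write(f"{r.set_name}\t{t.a}\t{t.b}\t{t.c}\t{t.d}\t"
                     f"{r.odds_ratio:g}\t{r.p_value:.6g}\t{r.q_value:.6g}\n")
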