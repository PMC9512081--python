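"""Seeded generator of complete synthetic regulatory-genomics studies.

A generated study bundles everything the analysis stages consume — a genome,
non-overlapping gene models (some in tight clusters), a target gene set with
planted peak proximity, several peak tracks with planted co-occupancy,
family-labeled repeat annotations with planted within-peak density, a
blacklist, and WT/KO coverage tracks with planted depletion over target gene
bodies — together with a manifest of the planted truths.

Determinism: one master seed feeds named substreams (genes, target set,
peaks, co-occupancy, repeats, signal, blacklist), so changing one component's
parameters never perturbs another component's draws. That property is what
makes paired planted/null comparisons meaningful.

Planting an odds ratio: rather than exposing a raw per-target placement
probability only, the generator can calibrate it against the realized
background proximity rate q0: with target odds ratio w, the target proximity
rate q1 solves odds(q1) = w * odds(q0), and the placement probability is
p_t = (q1 - q0) / (1 - q0). The realized p_t and q0 are recorded in the
manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .annotation import GeneModel, GeneSet, GeneTable, proximal_gene_ids, write_gene_sets
from .genome import GenomeSpec, write_chrom_sizes
from .intervals import GenomicInterval, IntervalSet, merge, shuffle, write_bed
from .signal import SignalTrack, write_bedgraph

__all__ = [
    "GenomeConfig", "GeneConfig", "PeakConfig", "CooccupancyConfig",
    "RepeatFamilyConfig", "SignalConfig", "BlacklistConfig", "StudyConfig",
    "StudyBundle", "generate_study", "null_variant",
]


@dataclass
class GenomeConfig:
    n_chroms: int = 4
    chrom_length: int = 10_000_000


@dataclass
class GeneConfig:
    n_genes: int = 2000
    min_length: int = 2_000
    max_length: int = 20_000  # gene lengths log-uniform on [min, max]
    min_gap: int = 1_000
    n_clusters: int = 20
    genes_per_cluster: int = 4
    cluster_span: int = 100_000  # genes of a cluster fit within this span


@dataclass
class PeakConfig:
    n_background: int = 100
    p_target: float | None = None  # explicit per-target placement probability
    planted_or: float | None = 5.0  # calibrate p_target to this odds ratio
    min_length: int = 200
    max_length: int = 800
    placement_window: int = 25_000  # planted peaks within +/- this of target genes
    proximity_distance: int = 50_000  # distance rule used for the calibration


@dataclass
class CooccupancyConfig:
    n_tracks: int = 3
    n_shared: int = 100  # loci copied into every track (with jitter)
    jitter: int = 20
    n_background_other: int = 100  # per non-primary track


@dataclass
class RepeatFamilyConfig:
    density_per_mb: float = 80.0
    peak_excess: float = 1.0  # within-peak density multiplier; 1 = neutral
    min_length: int = 100
    max_length: int = 400

    # NOTE on neutral families: the window-count test treats windows as
    # exchangeable, so a neutral family whose instances span several
    # consecutive windows shows inflated type-I error (correlated window
    # runs). The default neutral family is therefore a short simple-repeat
    # (microsatellite-like) family spanning ~1 window per instance.


@dataclass
class SignalConfig:
    enabled: bool = True
    bin: int = 50
    baseline: float = 50.0  # Poisson rate per bin
    ko_fold: float = 0.5  # KO rate multiplier over target gene bodies


@dataclass
class BlacklistConfig:
    n_regions: int = 10
    region_length: int = 10_000


def _default_repeats() -> dict[str, RepeatFamilyConfig]:
    return {
        "LINE": RepeatFamilyConfig(density_per_mb=80.0, peak_excess=8.0,
                                   min_length=500, max_length=3000),
        "Simple": RepeatFamilyConfig(density_per_mb=25.0, peak_excess=1.0,
                                     min_length=20, max_length=60),
    }


@dataclass
class StudyConfig:
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    genes: GeneConfig = field(default_factory=GeneConfig)
    target_set_size: int = 100
    target_cluster_fraction: float = 0.5  # fraction of targets drawn from clusters
    peaks: PeakConfig = field(default_factory=PeakConfig)
    cooccupancy: CooccupancyConfig = field(default_factory=CooccupancyConfig)
    repeats: dict[str, RepeatFamilyConfig] = field(default_factory=_default_repeats)
    signal: SignalConfig = field(default_factory=SignalConfig)
    blacklist: BlacklistConfig = field(default_factory=BlacklistConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        d = dict(d)
        kwargs = {}
        nested = {"genome": GenomeConfig, "genes": GeneConfig, "peaks": PeakConfig,
                  "cooccupancy": CooccupancyConfig, "signal": SignalConfig,
                  "blacklist": BlacklistConfig}
        for key, klass in nested.items():
            if key in d:
                kwargs[key] = klass(**d.pop(key))
        if "repeats" in d:
            kwargs["repeats"] = {name: RepeatFamilyConfig(**fam)
                                 for name, fam in d.pop("repeats").items()}
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class StudyBundle:
    """A complete synthetic study plus the manifest of its planted truths."""

    genome: GenomeSpec
    genes: GeneTable
    target_set: GeneSet
    background_pool: frozenset[str]
    peak_tracks: dict[str, IntervalSet]
    repeats: dict[str, IntervalSet]
    blacklist: IntervalSet
    wt: SignalTrack | None
    ko: SignalTrack | None
    manifest: dict
    config: StudyConfig

    @property
    def primary_peaks(self) -> IntervalSet:
        return next(iter(self.peak_tracks.values()))

    def de_classes(self) -> dict[str, str]:
        """Planted DE classes: target genes down, all others unchanged."""
        return {g.gene_id: ("down" if g.gene_id in self.target_set.members
                            else "unchanged") for g in self.genes.genes}

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["chrom_sizes"] = out / "chrom.sizes"
        write_chrom_sizes(self.genome, paths["chrom_sizes"])
        paths["genes"] = out / "genes.bed"
        write_bed(self.genes.intervals(), paths["genes"])
        paths["gene_sets"] = out / "genesets.tsv"
        write_gene_sets([self.target_set,
                         GeneSet("background", self.background_pool)],
                        paths["gene_sets"])
        for label, track in self.peak_tracks.items():
            paths[f"peaks_{label}"] = out / f"peaks_{label}.bed"
            write_bed(track, paths[f"peaks_{label}"])
        reps = []
        for fam in sorted(self.repeats):
            for iv in self.repeats[fam]:
                reps.append(GenomicInterval(iv.chrom, iv.start, iv.end, name=fam))
        paths["repeats"] = out / "repeats.bed"
        write_bed(IntervalSet(reps), paths["repeats"])
        paths["blacklist"] = out / "blacklist.bed"
        write_bed(self.blacklist, paths["blacklist"])
        if self.wt is not None:
            paths["wt"] = out / "wt.bedgraph"
            write_bedgraph(self.wt, paths["wt"])
            paths["ko"] = out / "ko.bedgraph"
            write_bedgraph(self.ko, paths["ko"])
        paths["manifest"] = out / "manifest.json"
        paths["manifest"].write_text(json.dumps(self.manifest, indent=1) + "\n")
        paths["config"] = out / "config.yaml"
        self.config.to_yaml(paths["config"])
        return paths


# -- internal helpers ---------------------------------------------------------


def _sample_lengths(rng, n, lo, hi):
    """Log-uniform integer lengths on [lo, hi]."""
    if n == 0:
        return np.empty(0, dtype=np.int64)
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n)).astype(np.int64)


def _place_uniform(rng, genome: GenomeSpec, n, min_len, max_len,
                   avoid: IntervalSet | None = None, max_attempts: int = 1000):
    """n intervals uniform on the genome (chromosome chosen by length),
    rejection-sampled against ``avoid``."""
    ivs = []
    names = [c for c, _ in genome]
    lens = np.array([l for _, l in genome], dtype=float)
    probs = lens / lens.sum()
    for _ in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        for attempt in range(max_attempts):
            ci = int(rng.choice(len(names), p=probs))
            chrom, L = names[ci], int(lens[ci])
            start = int(rng.integers(0, L - length + 1))
            iv = GenomicInterval(chrom, start, start + length)
            if avoid is None or not _hits(iv, avoid):
                ivs.append(iv)
                break
        else:
            raise ValueError("could not place interval outside avoided regions")
    return ivs


def _hits(iv: GenomicInterval, s: IntervalSet) -> bool:
    ms, me = s.starts(iv.chrom), s.ends(iv.chrom)
    if len(ms) == 0:
        return False
    i = int(np.searchsorted(me, iv.start, side="right"))
    return i < len(ms) and ms[i] < iv.end


def _generate_genes(rng, genome: GenomeSpec, cfg: GeneConfig):
    """Place non-overlapping genes (clusters as packed blocks) by
    stick-breaking the free space of each chromosome."""
    n_clustered = cfg.n_clusters * cfg.genes_per_cluster
    if n_clustered > cfg.n_genes:
        raise ValueError("n_clusters * genes_per_cluster exceeds n_genes")
    units = []  # each: list of (offset, length) within the unit, plus span
    for _ in range(cfg.n_clusters):
        lens = _sample_lengths(rng, cfg.genes_per_cluster, cfg.min_length,
                               cfg.max_length)
        gaps_needed = cfg.genes_per_cluster - 1
        min_span = int(lens.sum()) + gaps_needed * cfg.min_gap
        if min_span > cfg.cluster_span:
            raise ValueError(
                f"cluster_span {cfg.cluster_span} too small for "
                f"{cfg.genes_per_cluster} genes (need >= {min_span})")
        gmax = (cfg.cluster_span - int(lens.sum())) // max(gaps_needed, 1)
        gaps = rng.integers(cfg.min_gap, gmax + 1, size=gaps_needed)
        offsets, pos = [], 0
        for i, l in enumerate(lens):
            offsets.append((pos, int(l)))
            pos += int(l) + (int(gaps[i]) if i < gaps_needed else 0)
        units.append((offsets, pos, True))
    for l in _sample_lengths(rng, cfg.n_genes - n_clustered, cfg.min_length,
                             cfg.max_length):
        units.append(([(0, int(l))], int(l), False))
    order = rng.permutation(len(units))
    # assign units to chromosomes greedily by remaining capacity
    lengths = genome.lengths()
    capacity = {c: float(l) for c, l in genome}
    assigned: dict[str, list] = {c: [] for c in capacity}
    for ui in order:
        span = units[ui][1]
        chrom = max(capacity, key=lambda c: capacity[c])
        capacity[chrom] -= span + cfg.min_gap
        assigned[chrom].append(units[ui])
    genes, clustered_ids = [], []
    counter = 0
    for chrom in genome.names:
        chrom_units = assigned[chrom]
        if not chrom_units:
            continue
        spans = np.array([u[1] for u in chrom_units], dtype=np.int64)
        slack = lengths[chrom] - int(spans.sum()) - len(chrom_units) * cfg.min_gap
        if slack < 0:
            raise ValueError(
                f"genes do not fit on {chrom}: n_genes/gene lengths too large "
                f"for chrom_length {lengths[chrom]}")
        cuts = np.sort(rng.uniform(0, slack, size=len(chrom_units))).astype(np.int64)
        base = 0
        for i, (offsets, span, is_cluster) in enumerate(chrom_units):
            unit_start = int(cuts[i]) + base + i * cfg.min_gap
            base += span
            for off, l in offsets:
                counter += 1
                gid = f"g{counter:05d}"
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(GeneModel(gid, chrom, unit_start + off,
                                       unit_start + off + l, strand))
                if is_cluster:
                    clustered_ids.append(gid)
    return GeneTable(genes, genome=genome), clustered_ids


def _planted_p_target(planted_or: float, q0: float) -> float:
    """Placement probability giving target-vs-background odds ratio planted_or."""
    if q0 <= 0:
        return 1.0 if planted_or > 1 else 0.0
    if q0 >= 1:
        return 0.0
    odds1 = planted_or * q0 / (1 - q0)
    q1 = odds1 / (1 + odds1)
    return float(np.clip((q1 - q0) / (1 - q0), 0.0, 1.0))


def generate_study(config: StudyConfig | None = None,
                   out_dir: str | Path | None = None) -> StudyBundle:
    """Generate a full synthetic study; deterministic given ``config.seed``."""
    cfg = config or StudyConfig()
    streams = np.random.SeedSequence(cfg.seed).spawn(8)
    rng_genes = np.random.default_rng(streams[0])
    rng_target = np.random.default_rng(streams[1])
    rng_peaks = np.random.default_rng(streams[2])
    rng_coocc = np.random.default_rng(streams[3])
    rng_repeats = np.random.default_rng(streams[4])
    rng_signal = np.random.default_rng(streams[5])
    rng_blacklist = np.random.default_rng(streams[6])

    genome = GenomeSpec((f"chr{i + 1}", cfg.genome.chrom_length)
                        for i in range(cfg.genome.n_chroms))
    blacklist = merge(IntervalSet(_place_uniform(
        rng_blacklist, genome, cfg.blacklist.n_regions,
        cfg.blacklist.region_length, cfg.blacklist.region_length), label="blacklist"))

    genes, clustered_ids = _generate_genes(rng_genes, genome, cfg.genes)
    all_ids = sorted(genes.ids())

    # target set: a configurable share drawn from clustered genes
    n_from_clusters = min(round(cfg.target_cluster_fraction * cfg.target_set_size),
                          len(clustered_ids))
    clustered_sorted = sorted(clustered_ids)
    unclustered = sorted(set(all_ids) - set(clustered_ids))
    picked = list(rng_target.choice(clustered_sorted, size=n_from_clusters,
                                    replace=False))
    picked += list(rng_target.choice(unclustered,
                                     size=cfg.target_set_size - n_from_clusters,
                                     replace=False))
    target_set = GeneSet("target", picked)
    background_pool = frozenset(set(all_ids) - target_set.members)

    # peaks: primary background, shared co-occupancy loci, then planting
    background = _place_uniform(rng_peaks, genome, cfg.peaks.n_background,
                                cfg.peaks.min_length, cfg.peaks.max_length,
                                avoid=blacklist)
    shared = _place_uniform(rng_coocc, genome, cfg.cooccupancy.n_shared,
                            cfg.peaks.min_length, cfg.peaks.max_length,
                            avoid=blacklist)
    lengths = genome.lengths()

    def jittered(ivs):
        out = []
        j = cfg.cooccupancy.jitter
        for iv in ivs:
            shift = int(rng_coocc.integers(-j, j + 1)) if j else 0
            L = lengths[iv.chrom]
            start = int(np.clip(iv.start + shift, 0, L - len(iv)))
            out.append(GenomicInterval(iv.chrom, start, start + len(iv)))
        return out

    track_ivs = {f"track{t + 1}": [] for t in range(cfg.cooccupancy.n_tracks)}
    track_ivs["track1"] = list(background) + jittered(shared)
    for t in range(1, cfg.cooccupancy.n_tracks):
        track_ivs[f"track{t + 1}"] = jittered(shared) + _place_uniform(
            rng_coocc, genome, cfg.cooccupancy.n_background_other,
            cfg.peaks.min_length, cfg.peaks.max_length, avoid=blacklist)

    unplanted_primary = IntervalSet(track_ivs["track1"], label="track1")
    proximal0 = proximal_gene_ids(unplanted_primary, genes,
                                  cfg.peaks.proximity_distance)
    q0 = len(proximal0) / len(genes) if len(genes) else 0.0
    w = cfg.peaks.placement_window
    D = cfg.peaks.proximity_distance

    def plant_near(gid):
        g = genes[gid]
        length = int(rng_peaks.integers(cfg.peaks.min_length,
                                        cfg.peaks.max_length + 1))
        L = lengths[g.chrom]
        lo = max(0, g.start - w)
        hi = min(L - length, g.end + w - length)
        start = int(rng_peaks.integers(lo, hi + 1)) if hi >= lo else lo
        return GenomicInterval(g.chrom, start, start + length)

    planted = []
    p_t = 0.0
    targets_sorted = sorted(target_set.members)
    if cfg.peaks.p_target is not None:
        # mechanistic mode: literal per-target Bernoulli placement
        p_t = cfg.peaks.p_target
        for gid in targets_sorted:
            if rng_peaks.random() < p_t:
                planted.append(plant_near(gid))
    elif cfg.peaks.planted_or is not None:
        # calibrated mode: plant until the number of proximal targets reaches
        # a Binomial(n_t, q1) draw, with odds(q1) = planted_or * odds(q0).
        # Counting realized proximity keeps the planted odds ratio honest
        # when targets are clustered and one peak flips several neighbors.
        p_t = _planted_p_target(cfg.peaks.planted_or, q0)
        q1 = q0 + (1 - q0) * p_t
        n_goal = int(rng_peaks.binomial(len(targets_sorted), q1))
        prox_targets = {gid for gid in targets_sorted if gid in proximal0}
        order = rng_peaks.permutation(
            [gid for gid in targets_sorted if gid not in prox_targets])
        for gid in order:
            if len(prox_targets) >= n_goal:
                break
            if gid in prox_targets:
                continue
            peak = plant_near(gid)
            planted.append(peak)
            one_peak = IntervalSet([peak])
            prox_targets |= {t for t in proximal_gene_ids(
                one_peak, genes.subset(targets_sorted), D)}
    track_ivs["track1"] += planted
    peak_tracks = {label: IntervalSet(ivs, label=label)
                   for label, ivs in track_ivs.items()}

    # repeats: uniform genome-wide instances plus excess inside primary peaks
    repeats: dict[str, IntervalSet] = {}
    genome_mb = genome.total_length() / 1e6
    primary_merged = merge(peak_tracks["track1"])
    peak_mb = primary_merged.covered_bases() / 1e6
    peak_list = list(primary_merged)
    peak_weights = np.array([len(iv) for iv in peak_list], dtype=float)
    for fam in sorted(cfg.repeats):
        fam_cfg = cfg.repeats[fam]
        n_base = int(rng_repeats.poisson(fam_cfg.density_per_mb * genome_mb))
        ivs = _place_uniform(rng_repeats, genome, n_base, fam_cfg.min_length,
                             fam_cfg.max_length)
        if fam_cfg.peak_excess > 1 and peak_list:
            n_excess = int(rng_repeats.poisson(
                fam_cfg.density_per_mb * (fam_cfg.peak_excess - 1) * peak_mb))
            pw = peak_weights / peak_weights.sum()
            for _ in range(n_excess):
                pk = peak_list[int(rng_repeats.choice(len(peak_list), p=pw))]
                length = int(rng_repeats.integers(fam_cfg.min_length,
                                                  fam_cfg.max_length + 1))
                start = int(rng_repeats.integers(pk.start, pk.end))
                end = min(start + length, lengths[pk.chrom])
                ivs.append(GenomicInterval(pk.chrom, start, end))
        repeats[fam] = IntervalSet(ivs, label=fam)

    # signal: WT ~ Poisson(baseline) per bin; KO depleted over target bodies
    wt = ko = None
    if cfg.signal.enabled:
        target_bodies = genes.subset(sorted(target_set.members)).intervals()
        wt_bins, ko_bins = {}, {}
        for chrom, L in genome:
            n_bins = L // cfg.signal.bin
            mids = (np.arange(n_bins, dtype=np.int64) * cfg.signal.bin
                    + cfg.signal.bin // 2)
            ts, te = target_bodies.starts(chrom), target_bodies.ends(chrom)
            idx = np.searchsorted(te, mids, side="right")
            in_target = np.zeros(n_bins, dtype=bool)
            inb = idx < len(ts)
            in_target[inb] = ts[idx[inb]] <= mids[inb]
            rates = np.where(in_target, cfg.signal.baseline * cfg.signal.ko_fold,
                             cfg.signal.baseline)
            wt_bins[chrom] = rng_signal.poisson(cfg.signal.baseline, size=n_bins)
            ko_bins[chrom] = rng_signal.poisson(rates)
        wt = SignalTrack.from_bins(genome, cfg.signal.bin, wt_bins)
        ko = SignalTrack.from_bins(genome, cfg.signal.bin, ko_bins)

    manifest = {
        "seed": cfg.seed,
        "n_genes": len(genes),
        "n_clustered_genes": len(clustered_ids),
        "target_set_size": len(target_set),
        "planted_or": cfg.peaks.planted_or,
        "p_target_realized": p_t,
        "background_proximity_q0": q0,
        "n_planted_peaks": len(planted),
        "proximity_distance": cfg.peaks.proximity_distance,
        "placement_window": w,
        "shared_loci": [[iv.chrom, iv.start, iv.end] for iv in shared],
        "n_tracks": cfg.cooccupancy.n_tracks,
        "track_sizes": {lbl: len(t) for lbl, t in peak_tracks.items()},
        "repeat_families": {fam: dataclasses.asdict(fc)
                            for fam, fc in cfg.repeats.items()},
        "ko_fold": cfg.signal.ko_fold if cfg.signal.enabled else None,
    }
    bundle = StudyBundle(genome, genes, target_set, background_pool, peak_tracks,
                         repeats, blacklist, wt, ko, manifest, cfg)
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def null_variant(bundle: StudyBundle, which: str, seed: int = 0) -> StudyBundle:
    """Copy of the study with the planted structure destroyed for one component.

    ``gene_sets``: target set redrawn uniformly from all genes.
    ``peaks``: every track re-shuffled within chromosomes (blacklist avoided).
    ``signal``: KO regenerated with fold 1 (no depletion); WT kept.
    """
    rng = np.random.default_rng(seed)
    manifest = dict(bundle.manifest, null_variant=which, null_seed=seed)
    if which == "gene_sets":
        all_ids = sorted(bundle.genes.ids())
        picked = rng.choice(all_ids, size=len(bundle.target_set), replace=False)
        target = GeneSet(bundle.target_set.name, picked)
        pool = frozenset(set(all_ids) - target.members)
        return dataclasses.replace(bundle, target_set=target,
                                   background_pool=pool, manifest=manifest)
    if which == "peaks":
        tracks = {lbl: shuffle(t, bundle.genome, excluded=bundle.blacklist, seed=rng)
                  for lbl, t in bundle.peak_tracks.items()}
        return dataclasses.replace(bundle, peak_tracks=tracks, manifest=manifest)
    if which == "signal":
        cfg = bundle.config.signal
        ko_bins = {}
        for chrom, L in bundle.genome:
            n_bins = L // cfg.bin
            ko_bins[chrom] = rng.poisson(cfg.baseline, size=n_bins)
        ko = SignalTrack.from_bins(bundle.genome, cfg.bin, ko_bins)
        manifest["ko_fold"] = 1.0
        return dataclasses.replace(bundle, ko=ko, manifest=manifest)
    raise ValueError("which must be one of: gene_sets, peaks, signal")
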