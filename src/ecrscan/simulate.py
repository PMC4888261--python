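"""Synthetic genomes and site sets with the statistical structure the
scan assumes.

The generator emulates the inputs of a transgenerational epigenomics
study at desk scale: a multi-chromosome genome; a background gene
annotation in which roughly one third of genes sit inside pre-existing
clumps of 2-5 Mb (the genome's inherent gene clustering); and a set of
differentially methylated regions (DMRs), around a thousand sites, a
quarter of which fall inside those gene clumps. Optional planted regions
elevate local DMR density by an exact fold for recovery benchmarking.

All placement is seeded and reproducible; category totals (clumped /
uniform / planted) are allocated deterministically by rounding rather
than per-site coin flips, so they are exact and testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .genome import GenomeLayout, GenomicSite, SiteSet
from .scan import ClusterSet

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "RecoveryResult",
    "simulate_genome",
    "simulate_background_genes",
    "simulate_dmr_sites",
    "evaluate_recovery",
    "interval_jaccard",
]

_GENE_LEN = 1_000  # emitted gene interval length, bp
_DMR_LEN = 500  # emitted DMR interval length, bp
_PLACEMENT_RETRIES = 1_000


@dataclass
class SimulationConfig:
    """Study-scale defaults: ~10^3 sites on a 200 Mb, 5-chromosome genome.

    clump_fraction defaults to 1/3 (share of annotated genes inside
    inherent clumps) and dmr_in_clump_fraction to 0.25 (share of DMRs
    falling inside gene clumps); clump lengths are drawn uniformly from
    the 2-5 Mb range typical of regionally co-regulated gene clusters.
    planted_regions entries are (chrom, start, end, fold) with fold >= 1
    the target multiple of the uniform density inside the region.
    """

    n_chromosomes: int = 5
    chrom_length: int = 40_000_000
    n_background_genes: int = 3_000
    clump_fraction: float = 1 / 3
    n_clumps: int = 20
    clump_length: tuple[int, int] = (2_000_000, 5_000_000)
    n_dmr: int = 776
    dmr_in_clump_fraction: float = 0.25
    planted_regions: list[tuple[str, int, int, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.clump_length, int):
            self.clump_length = (self.clump_length, self.clump_length)
        for name, frac in [
            ("clump_fraction", self.clump_fraction),
            ("dmr_in_clump_fraction", self.dmr_in_clump_fraction),
        ]:
            if not 0 <= frac <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        if self.clump_length[1] > self.chrom_length:
            raise ValueError("clump_length exceeds chrom_length")
        for chrom, start, end, fold in self.planted_regions:
            if fold < 1:
                raise ValueError(f"planted fold must be >= 1, got {fold}")
            if not 0 <= start < end:
                raise ValueError(f"invalid planted region [{start}, {end})")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation: clump and planted intervals plus
    each site's provenance ('uniform' | 'clump' | 'planted')."""

    clumps: list[tuple[str, int, int]] = field(default_factory=list)
    planted_regions: list[tuple[str, int, int, float]] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            clumps=[tuple(c) for c in d["clumps"]],
            planted_regions=[tuple(r) for r in d["planted_regions"]],
            provenance=d["provenance"],
        )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def simulate_genome(config: SimulationConfig) -> GenomeLayout:
    """Chromosomes chr1..chrN of equal configured length."""
    if config.n_chromosomes <= 0:
        raise ValueError("need at least one chromosome")
    return GenomeLayout(
        (f"chr{i + 1}", config.chrom_length) for i in range(config.n_chromosomes)
    )


def _weighted_chrom(rng: np.random.Generator, genome: GenomeLayout) -> str:
    lengths = np.asarray([l for _, l in genome], dtype=float)
    return genome.names[rng.choice(len(lengths), p=lengths / lengths.sum())]


def _place_clumps(
    rng: np.random.Generator, genome: GenomeLayout, config: SimulationConfig
) -> list[tuple[str, int, int]]:
    clumps: list[tuple[str, int, int]] = []
    lo, hi = config.clump_length
    retries = 0
    while len(clumps) < config.n_clumps:
        if retries > _PLACEMENT_RETRIES:
            raise RuntimeError(
                f"could not place {config.n_clumps} non-overlapping clumps "
                f"after {_PLACEMENT_RETRIES} retries"
            )
        length = int(rng.integers(lo, hi + 1))
        chrom = _weighted_chrom(rng, genome)
        start = int(rng.integers(0, genome.length_of(chrom) - length + 1))
        cand = (chrom, start, start + length)
        if any(c == chrom and s < cand[2] and cand[1] < e for c, s, e in clumps):
            retries += 1
            continue
        clumps.append(cand)
    return clumps


def _emit_site(
    chrom: str, start: int, length: int, site_id: str, chrom_len: int
) -> GenomicSite:
    start = min(start, chrom_len - length)
    return GenomicSite(chrom, start, start + length, site_id, start + length // 2)


def simulate_background_genes(
    genome: GenomeLayout, config: SimulationConfig
) -> tuple[SiteSet, SyntheticTruth]:
    """Background gene annotation: clumped fraction inside non-overlapping
    clumps (clump chosen proportional to its length, position uniform
    within), remainder uniform genome-wide. Genes are 1 kb intervals."""
    rng = np.random.default_rng(config.seed)
    clumps = _place_clumps(rng, genome, config) if config.n_clumps > 0 else []
    n = config.n_background_genes
    n_clumped = _round_half_up(config.clump_fraction * n) if clumps else 0

    truth = SyntheticTruth(clumps=clumps)
    sites: list[GenomicSite] = []
    if clumps:
        lens = np.asarray([e - s for _, s, e in clumps], dtype=float)
        weights = lens / lens.sum()
    for i in range(n):
        sid = f"BKG_{i + 1}"
        if i < n_clumped:
            chrom, cs, ce = clumps[int(rng.choice(len(clumps), p=weights))]
            start = int(rng.integers(cs, max(cs + 1, ce - _GENE_LEN)))
            truth.provenance[sid] = "clump"
        else:
            chrom = _weighted_chrom(rng, genome)
            start = int(rng.integers(0, genome.length_of(chrom) - _GENE_LEN + 1))
            truth.provenance[sid] = "uniform"
        sites.append(_emit_site(chrom, start, _GENE_LEN, sid, genome.length_of(chrom)))
    return SiteSet("BKG", "gene", sites, genome), truth


def simulate_dmr_sites(
    genome: GenomeLayout, config: SimulationConfig, truth: SyntheticTruth
) -> tuple[SiteSet, SyntheticTruth]:
    """DMR sites: a configured fraction inside the background gene clumps,
    the rest uniform; planted regions topped up with extra sites so the
    in-region count equals round(fold * n_dmr * region_len / genome_len)
    exactly. DMRs are 500 bp intervals.
    """
    rng = np.random.default_rng(config.seed + 1)
    clumps = truth.clumps
    n = config.n_dmr
    n_clumped = _round_half_up(config.dmr_in_clump_fraction * n) if clumps else 0

    sites: list[GenomicSite] = []
    if clumps:
        lens = np.asarray([e - s for _, s, e in clumps], dtype=float)
        weights = lens / lens.sum()
    for i in range(n):
        sid = f"DMR_{i + 1}"
        if i < n_clumped:
            chrom, cs, ce = clumps[int(rng.choice(len(clumps), p=weights))]
            start = int(rng.integers(cs, max(cs + 1, ce - _DMR_LEN)))
            truth.provenance[sid] = "clump"
        else:
            chrom = _weighted_chrom(rng, genome)
            start = int(rng.integers(0, genome.length_of(chrom) - _DMR_LEN + 1))
            truth.provenance[sid] = "uniform"
        sites.append(_emit_site(chrom, start, _DMR_LEN, sid, genome.length_of(chrom)))

    n_extra_total = 0
    for chrom, rs, re, fold in config.planted_regions:
        if chrom not in genome:
            raise ValueError(f"planted region on unknown chromosome {chrom!r}")
        if re > genome.length_of(chrom):
            raise ValueError(f"planted region [{rs}, {re}) exceeds {chrom} length")
        if fold == 1:  # identity: the uniform background already has fold 1
            continue
        target = _round_half_up(fold * n * (re - rs) / genome.total_length)
        current = sum(1 for s in sites if s.chrom == chrom and rs <= s.point < re)
        for _ in range(max(0, target - current)):
            n_extra_total += 1
            sid = f"DMR_p{n_extra_total}"
            start = int(rng.integers(rs, max(rs + 1, re - _DMR_LEN)))
            sites.append(_emit_site(chrom, start, _DMR_LEN, sid, genome.length_of(chrom)))
            truth.provenance[sid] = "planted"
    truth.planted_regions = list(config.planted_regions)
    return SiteSet("DMR", "dmr", sites, genome), truth


def interval_jaccard(a: tuple[str, int, int], b: tuple[str, int, int]) -> float:
    """Length of intersection over length of union; 0 across chromosomes."""
    if a[0] != b[0]:
        return 0.0
    inter = max(0, min(a[2], b[2]) - max(a[1], b[1]))
    union = max(a[2], b[2]) - min(a[1], b[1])
    return inter / union if union else 0.0


@dataclass
class RecoveryResult:
    recall: float
    precision: float
    matches: list[tuple[int, str, float]]  # (planted index, cluster_id, jaccard)
    empty_called: bool = False


def evaluate_recovery(
    called: ClusterSet, truth: SyntheticTruth, jaccard_min: float
) -> RecoveryResult:
    """Match called clusters to planted regions by interval Jaccard.

    A planted region is recovered iff some called cluster reaches
    ``jaccard_min`` with it; recall = recovered / planted. Precision is
    matched clusters over called clusters; with no called clusters it is
    reported as 1 by convention, with ``empty_called`` set.
    """
    if not 0 < jaccard_min <= 1:
        raise ValueError(f"jaccard_min must be in (0, 1], got {jaccard_min}")
    planted = [(c, s, e) for c, s, e, _ in truth.planted_regions]
    matches: list[tuple[int, str, float]] = []
    matched_clusters: set[str] = set()
    recovered = 0
    for i, region in enumerate(planted):
        best = None
        for cl in called:
            j = interval_jaccard(region, (cl.chrom, cl.start, cl.end))
            if j >= jaccard_min:
                matched_clusters.add(cl.cluster_id)
                if best is None or j > best[2]:
                    best = (i, cl.cluster_id, j)
        if best is not None:
            recovered += 1
            matches.append(best)
    recall = recovered / len(planted) if planted else 1.0
    if len(called) == 0:
        return RecoveryResult(recall, 1.0, matches, empty_called=True)
    return RecoveryResult(recall, len(matched_clusters) / len(called), matches)
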