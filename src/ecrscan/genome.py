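"""Genomic coordinate model and plain-text I/O.

Coordinates are 0-based half-open (BED convention) everywhere. A genome is
an ordered list of named chromosomes with lengths (UCSC ``chrom.sizes``
style); site lists are BED3/BED4. Each site interval carries a single
representative *point* used for window counting, since the scan counts
sites rather than base-pair coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

import numpy as np

logger = logging.getLogger(__name__)

PointRule = Literal["midpoint", "start"]
SiteType = Literal["gene", "dmr"]

__all__ = [
    "GenomeLayout",
    "GenomicSite",
    "SiteSet",
    "read_genome",
    "read_sites",
    "write_sites",
    "write_clusters",
]


class GenomeLayout:
    """Ordered, named chromosomes with lengths.

    The chromosome order is preserved exactly as given; it defines the
    order of every downstream output. Unplaced scaffolds (e.g. ``chrUn``)
    are ordinary entries, so sites that cannot be assigned to a named
    chromosome remain scannable.
    """

    def __init__(self, chromosomes: Iterable[tuple[str, int]]):
        chroms = [(str(n), int(l)) for n, l in chromosomes]
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate chromosome name(s): {', '.join(dup)}")
        for name, length in chroms:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self.chromosomes: list[tuple[str, int]] = chroms
        self._lengths = dict(chroms)
        self._order = {n: i for i, n in enumerate(names)}

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def __len__(self) -> int:
        return len(self.chromosomes)

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.chromosomes)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeLayout) and self.chromosomes == other.chromosomes

    def length_of(self, name: str) -> int:
        return self._lengths[name]

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def order_index(self, name: str) -> int:
        """Rank of a chromosome in the layout; keys interval sort order."""
        return self._order[name]

    def __repr__(self) -> str:
        return f"GenomeLayout({len(self)} chromosomes, {self.total_length:,} bp)"


@dataclass(frozen=True)
class GenomicSite:
    """One countable site: an interval plus its representative point."""

    chrom: str
    start: int
    end: int
    site_id: str
    point: int

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"site {self.site_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if not self.start <= self.point < self.end:
            raise ValueError(
                f"site {self.site_id!r}: point {self.point} outside [{self.start}, {self.end})"
            )


class SiteSet:
    """A labeled collection of genomic sites tied to one genome layout."""

    def __init__(
        self,
        label: str,
        site_type: SiteType,
        sites: Iterable[GenomicSite],
        genome: GenomeLayout,
        n_dropped: int = 0,
    ):
        sites = list(sites)
        seen: set[str] = set()
        for s in sites:
            if s.chrom not in genome:
                raise ValueError(f"site {s.site_id!r} on unknown chromosome {s.chrom!r}")
            if s.end > genome.length_of(s.chrom):
                raise ValueError(
                    f"site {s.site_id!r} extends past end of {s.chrom} "
                    f"({s.end} > {genome.length_of(s.chrom)})"
                )
            if s.site_id in seen:
                raise ValueError(f"duplicate site_id {s.site_id!r} in set {label!r}")
            seen.add(s.site_id)
        self.label = label
        self.site_type: SiteType = site_type
        self.sites = sites
        self.genome = genome
        #: sites discarded at read time because their chromosome was absent
        self.n_dropped = n_dropped
        self._points_cache: dict[str, tuple[np.ndarray, list[str]]] | None = None

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[GenomicSite]:
        return iter(self.sites)

    def points_by_chrom(self) -> dict[str, tuple[np.ndarray, list[str]]]:
        """Per chromosome: sorted point array and site ids in the same order.

        Cached; the set is treated as immutable after construction.
        """
        if self._points_cache is None:
            cache: dict[str, tuple[np.ndarray, list[str]]] = {}
            by_chrom: dict[str, list[GenomicSite]] = {}
            for s in self.sites:
                by_chrom.setdefault(s.chrom, []).append(s)
            for chrom, ss in by_chrom.items():
                ss.sort(key=lambda s: (s.point, s.site_id))
                cache[chrom] = (
                    np.asarray([s.point for s in ss], dtype=np.int64),
                    [s.site_id for s in ss],
                )
            self._points_cache = cache
        return self._points_cache

    def __repr__(self) -> str:
        return f"SiteSet({self.label!r}, {self.site_type}, {len(self)} sites)"


def read_genome(path: str | Path) -> GenomeLayout:
    """Read a two-column whitespace-separated chromosome-sizes file.

    Lines are ``name  length``; extra columns are ignored, blank lines and
    ``#`` comments skipped. Order in the file is the layout order.
    """
    path = Path(path)
    chroms: list[tuple[str, int]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'name length', got {line!r}")
            try:
                length = int(fields[1])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: length {fields[1]!r} is not an integer"
                ) from None
            chroms.append((fields[0], length))
    return GenomeLayout(chroms)


def _representative_point(start: int, end: int, rule: PointRule) -> int:
    if rule == "midpoint":
        return (start + end) // 2
    if rule == "start":
        return start
    raise ValueError(f"unknown point_rule {rule!r}")


def read_sites(
    path: str | Path,
    label: str,
    site_type: SiteType,
    genome: GenomeLayout,
    point_rule: PointRule = "midpoint",
) -> SiteSet:
    """Read a BED3/BED4 site list into a :class:`SiteSet`.

    Records on chromosomes absent from ``genome`` are dropped; the count
    is logged and stored on the returned set as ``n_dropped``. A missing
    name column yields a synthesized id ``<label>_<n>``.
    """
    path = Path(path)
    sites: list[GenomicSite] = []
    n_dropped = 0
    n = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith(("track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED record needs >=3 fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if end <= start:
                raise ValueError(
                    f"{path}:{lineno}: empty or inverted interval [{start}, {end})"
                )
            if chrom not in genome:
                n_dropped += 1
                continue
            n += 1
            site_id = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else f"{label}_{n}"
            sites.append(
                GenomicSite(chrom, start, end, site_id, _representative_point(start, end, point_rule))
            )
    if n_dropped:
        logger.info(
            "%s: dropped %d site(s) on chromosomes absent from the genome layout",
            path,
            n_dropped,
        )
    return SiteSet(label, site_type, sites, genome, n_dropped=n_dropped)


def write_sites(sites: SiteSet, path: str | Path) -> None:
    """Write a SiteSet as BED4 (chrom, start, end, id)."""
    path = Path(path)
    with path.open("w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.site_id}\n")


def write_clusters(clusters, path: str | Path) -> None:
    """Write a ClusterSet as BED6+1.

    Columns: chrom, start, end, cluster_id, member-site count, strand
    placeholder ".", cluster p-value (scientific notation, 3 significant
    digits). Rows follow genome chromosome order, then start.
    """
    path = Path(path)
    genome = clusters.genome
    ordered = sorted(clusters.clusters, key=lambda c: (genome.order_index(c.chrom), c.start))
    with path.open("w") as fh:
        for c in ordered:
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.cluster_id}\t{c.n_sites}\t.\t{c.p_value:.2e}\n"
            )
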