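import numpy as np
import pytest

from ecrscan import GenomeLayout, GenomicSite, ScanParams, SiteSet


@pytest.fixture
def small_genome():
    return GenomeLayout([("chr1", 5_000_000), ("chr2", 3_000_000)])


@pytest.fixture
def toy_params():
    # small windows so toy genomes produce many windows
    return ScanParams(window_size=1_000_000, step=250_000, merge_gap=250_000)


def make_point_sites(genome, points, label="S", site_type="dmr", width=100):
    """Build a SiteSet whose representative points are exactly `points`.

    points: iterable of (chrom, position).
    """
    sites = []
    for i, (chrom, pos) in enumerate(points):
        length = genome.length_of(chrom)
        start = max(0, min(pos - width // 2, length - width))
        end = start + width
        if not start <= pos < end:  # near-edge points: shrink to a tight interval
            start, end = pos, min(pos + 1, length)
            if end <= start:
                start, end = length - 1, length
        sites.append(GenomicSite(chrom, start, end, f"{label}_{i + 1}", pos))
    return SiteSet(label, site_type, sites, genome)


@pytest.fixture
def make_sites():
    return make_point_sites


def random_point_sites(rng, genome, n, label="S"):
    """n sites with uniformly random points, chromosome chosen by length."""
    lengths = np.asarray([l for _, l in genome], dtype=float)
    chrom_idx = rng.choice(len(lengths), size=n, p=lengths / lengths.sum())
    pts = []
    for i, ci in enumerate(chrom_idx):
        name = genome.names[ci]
        pts.append((name, int(rng.integers(0, genome.length_of(name)))))
    return make_point_sites(genome, pts, label=label)
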