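"""Sliding-window over-representation scan and cluster calling.

The scan counts site points in fixed-size windows (default 2 Mb) advanced
by a fixed step (default 50 kb) along each chromosome, standardizes each
window's count against the mean and standard deviation of counts across
windows (a z-test), and merges significant windows (one-sided upper-tail
p below alpha) that overlap or lie within a gap threshold of each other
into clusters.

The null distribution is empirical: mu and sigma are the mean and sd of
the per-window counts themselves, pooled genome-wide by default, with a
per-chromosome option. Depleted windows (negative z) are never
significant; the test is one-sided for over-representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .genome import GenomeLayout, SiteSet

__all__ = [
    "ScanParams",
    "Window",
    "WindowScanResult",
    "Cluster",
    "ClusterSet",
    "DegenerateNullWarning",
    "make_windows",
    "count_in_windows",
    "score_windows",
    "call_clusters",
    "scan",
    "WindowClusterScanner",
]


class DegenerateNullWarning(UserWarning):
    """Raised when the window-count standard deviation is zero in a scope."""


@dataclass(frozen=True)
class ScanParams:
    """Parameters of one sliding-window scan.

    window_size and step are in bp; alpha is the per-window one-sided
    significance level; merge_gap is the largest base-pair gap between
    significant windows that still merges them. null_scope pools the
    empirical null genome-wide or per chromosome; sd_mode selects sample
    (n-1) or population sd; mt_correction optionally applies
    Benjamini-Hochberg before thresholding.
    """

    window_size: int = 2_000_000
    step: int = 50_000
    alpha: float = 0.05
    merge_gap: int = 50_000
    null_scope: Literal["genome", "per_chromosome"] = "genome"
    sd_mode: Literal["sample", "population"] = "sample"
    mt_correction: Literal["none", "bh"] = "none"

    def __post_init__(self):
        if not 0 < self.step <= self.window_size:
            raise ValueError(f"need 0 < step <= window_size, got {self.step}, {self.window_size}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.merge_gap < 0:
            raise ValueError(f"merge_gap must be >= 0, got {self.merge_gap}")
        if self.null_scope not in ("genome", "per_chromosome"):
            raise ValueError(f"unknown null_scope {self.null_scope!r}")
        if self.sd_mode not in ("sample", "population"):
            raise ValueError(f"unknown sd_mode {self.sd_mode!r}")
        if self.mt_correction not in ("none", "bh"):
            raise ValueError(f"unknown mt_correction {self.mt_correction!r}")


@dataclass
class Window:
    chrom: str
    start: int
    end: int
    count: int = 0
    z: float = float("nan")
    p: float = float("nan")


@dataclass
class WindowScanResult:
    """Windows in genome order plus the empirical null per scope.

    ``null_mean``/``null_sd`` map scope key -> value; the key is
    ``"genome"`` for the pooled null or a chromosome name for the
    per-chromosome null.
    """

    params: ScanParams
    windows: list[Window]
    null_mean: dict[str, float] = field(default_factory=dict)
    null_sd: dict[str, float] = field(default_factory=dict)

    def counts(self) -> np.ndarray:
        return np.asarray([w.count for w in self.windows], dtype=np.int64)

    def pvalues(self) -> np.ndarray:
        return np.asarray([w.p for w in self.windows], dtype=float)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "chrom": [w.chrom for w in self.windows],
                "start": [w.start for w in self.windows],
                "end": [w.end for w in self.windows],
                "count": [w.count for w in self.windows],
                "z": [w.z for w in self.windows],
                "p": [w.p for w in self.windows],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class Cluster:
    cluster_id: str
    chrom: str
    start: int
    end: int
    member_site_ids: list[str]
    n_sites: int
    p_value: float
    n_windows_merged: int


@dataclass
class ClusterSet:
    """Merged significant intervals for one scanned dataset."""

    label: str
    source_site_label: str
    clusters: list[Cluster]
    params: ScanParams
    genome: GenomeLayout

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)


def make_windows(genome: GenomeLayout, params: ScanParams) -> list[tuple[str, int, int]]:
    """Tile each chromosome with full-length sliding windows.

    A chromosome shorter than the window yields a single window covering
    it. Otherwise windows start at 0, step, 2*step, ... up to
    L - window_size, and a final right-anchored window [L - window_size, L)
    is added when the last regular start falls short of it, so every
    window keeps the full window size and trailing bases are never scanned
    with a truncated (count-depressing) window.
    """
    w, s = params.window_size, params.step
    windows: list[tuple[str, int, int]] = []
    for chrom, length in genome:
        if length <= w:
            windows.append((chrom, 0, length))
            continue
        last = length - w
        starts = list(range(0, last + 1, s))
        if starts[-1] != last:
            starts.append(last)
        windows.extend((chrom, st, st + w) for st in starts)
    return windows


def count_in_windows(
    windows: Sequence[tuple[str, int, int]], sites: SiteSet
) -> list[Window]:
    """Count site points per window (half-open; overlapping windows each count)."""
    pts = sites.points_by_chrom()
    out: list[Window] = []
    for chrom, start, end in windows:
        if chrom in pts:
            arr = pts[chrom][0]
            n = int(np.searchsorted(arr, end, side="left") - np.searchsorted(arr, start, side="left"))
        else:
            n = 0
        out.append(Window(chrom, start, end, count=n))
    return out


def score_windows(result: WindowScanResult) -> WindowScanResult:
    """Fill z and one-sided upper-tail normal p for every window, in place.

    Within each null scope, mu and sigma are the mean and sd of the
    observed window counts. A zero sigma (all counts equal) makes z
    undefined; every p in that scope is set to 1 and a
    DegenerateNullWarning is emitted.
    """
    params = result.params
    if params.null_scope == "genome":
        groups = {"genome": list(range(len(result.windows)))}
    else:
        groups = {}
        for i, w in enumerate(result.windows):
            groups.setdefault(w.chrom, []).append(i)

    ddof = 1 if params.sd_mode == "sample" else 0
    for key, idx in groups.items():
        if len(idx) < 2:
            raise ValueError(
                f"scope {key!r} has {len(idx)} window(s); need >=2 to estimate the null"
            )
        counts = np.asarray([result.windows[i].count for i in idx], dtype=float)
        mu = float(counts.mean())
        sd = float(counts.std(ddof=ddof))
        result.null_mean[key] = mu
        result.null_sd[key] = sd
        if sd == 0.0:
            warnings.warn(
                f"degenerate null in scope {key!r}: all window counts equal ({mu:g}); "
                "no window can be significant",
                DegenerateNullWarning,
                stacklevel=2,
            )
            for i in idx:
                result.windows[i].z = float("nan")
                result.windows[i].p = 1.0
            continue
        z = (counts - mu) / sd
        p = norm.sf(z)
        for j, i in enumerate(idx):
            result.windows[i].z = float(z[j])
            result.windows[i].p = float(p[j])
    return result


def _significance_mask(result: WindowScanResult) -> np.ndarray:
    p = result.pvalues()
    params = result.params
    if params.mt_correction == "bh":
        from statsmodels.stats.multitest import multipletests

        return multipletests(p, alpha=params.alpha, method="fdr_bh")[0]
    return p < params.alpha


def call_clusters(result: WindowScanResult, sites: SiteSet) -> ClusterSet:
    """Merge significant windows into clusters.

    Significant windows on the same chromosome whose intervals overlap or
    are separated by at most merge_gap bp merge transitively; a cluster
    spans the union of its windows. The cluster p-value is the minimum
    constituent-window p (reported as such). Member sites are the site
    points inside the span. Cluster ids are "<label>_c<k>" in genome order.
    """
    params = result.params
    sig = _significance_mask(result)
    genome = sites.genome
    pts = sites.points_by_chrom()

    # group significant windows per chromosome, in genome order
    per_chrom: dict[str, list[Window]] = {}
    for w, s in zip(result.windows, sig):
        if s:
            per_chrom.setdefault(w.chrom, []).append(w)

    clusters: list[Cluster] = []
    k = 0
    for chrom in genome.names:
        wins = sorted(per_chrom.get(chrom, []), key=lambda w: w.start)
        runs: list[list[Window]] = []
        for w in wins:
            if runs and w.start <= runs[-1][-1].end + params.merge_gap:
                runs[-1].append(w)
            else:
                runs.append([w])
        for run in runs:
            k += 1
            start = min(w.start for w in run)
            end = max(w.end for w in run)
            if chrom in pts:
                arr, ids = pts[chrom]
                lo = int(np.searchsorted(arr, start, side="left"))
                hi = int(np.searchsorted(arr, end, side="left"))
                members = ids[lo:hi]
            else:
                members = []
            clusters.append(
                Cluster(
                    cluster_id=f"{sites.label}_c{k}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    member_site_ids=list(members),
                    n_sites=len(members),
                    p_value=min(w.p for w in run),
                    n_windows_merged=len(run),
                )
            )
    return ClusterSet(
        label=sites.label,
        source_site_label=sites.label,
        clusters=clusters,
        params=params,
        genome=genome,
    )


def scan(
    sites: SiteSet, genome: GenomeLayout | None = None, params: ScanParams | None = None
) -> tuple[WindowScanResult, ClusterSet]:
    """Run the full scan: tile, count, score, call. Thin wrapper over
    :class:`WindowClusterScanner`."""
    params = params or ScanParams()
    est = WindowClusterScanner(
        window_size=params.window_size,
        step=params.step,
        alpha=params.alpha,
        merge_gap=params.merge_gap,
        null_scope=params.null_scope,
        sd_mode=params.sd_mode,
        mt_correction=params.mt_correction,
    )
    est.fit(sites, genome=genome)
    return est.result_, est.clusters_


class WindowClusterScanner(BaseEstimator):
    """Estimator interface to the sliding-window over-representation scan.

    Follows scikit-learn conventions: constructor stores parameters
    verbatim, ``fit`` validates and computes, fitted state lives in
    trailing-underscore attributes. ``X`` is a :class:`SiteSet`; the
    genome layout comes from the set itself unless overridden.

    Attributes
    ----------
    result_ : WindowScanResult
        Windows with counts, z-scores and p-values plus the empirical null.
    clusters_ : ClusterSet
        Merged significant windows.
    null_mean_, null_sd_ : dict
        Empirical null per scope (key "genome" or chromosome name).
    labels_ : numpy.ndarray
        Per-site cluster index in input order; -1 for sites outside every
        cluster.
    """

    def __init__(
        self,
        window_size: int = 2_000_000,
        step: int = 50_000,
        alpha: float = 0.05,
        merge_gap: int = 50_000,
        null_scope: str = "genome",
        sd_mode: str = "sample",
        mt_correction: str = "none",
    ):
        self.window_size = window_size
        self.step = step
        self.alpha = alpha
        self.merge_gap = merge_gap
        self.null_scope = null_scope
        self.sd_mode = sd_mode
        self.mt_correction = mt_correction

    def _params(self) -> ScanParams:
        return ScanParams(
            window_size=self.window_size,
            step=self.step,
            alpha=self.alpha,
            merge_gap=self.merge_gap,
            null_scope=self.null_scope,
            sd_mode=self.sd_mode,
            mt_correction=self.mt_correction,
        )

    def fit(self, X: SiteSet, y=None, genome: GenomeLayout | None = None):
        if not isinstance(X, SiteSet):
            raise TypeError(f"X must be a SiteSet, got {type(X).__name__}")
        params = self._params()
        genome = genome if genome is not None else X.genome
        windows = make_windows(genome, params)
        result = WindowScanResult(params=params, windows=count_in_windows(windows, X))
        score_windows(result)
        self.result_ = result
        self.clusters_ = call_clusters(result, X)
        member = {
            sid: k for k, c in enumerate(self.clusters_.clusters) for sid in c.member_site_ids
        }
        self.labels_ = np.asarray([member.get(s.site_id, -1) for s in X], dtype=np.int64)
        self.n_clusters_ = len(self.clusters_)
        return self

    def fit_predict(self, X: SiteSet, y=None) -> np.ndarray:
        return self.fit(X).labels_
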