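"""Config-driven orchestration: scan every dataset, call background gene
clusters, subtract, cross-tabulate overlaps, and summarize.

One YAML config drives a full run. Outputs are plain text (BED / TSV /
log) in a single directory, written deterministically so that identical
config and inputs reproduce byte-identical files; a DONE sentinel marks
a completed run.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .compare import overlap_matrix, percent_in_clusters, subtract_background
from .genome import GenomeLayout, SiteSet, read_genome, read_sites, write_clusters
from .scan import ClusterSet, ScanParams, scan

__all__ = ["DatasetSpec", "PipelineConfig", "run_pipeline", "summarize"]


@dataclass
class DatasetSpec:
    label: str
    path: str
    site_type: str = "gene"


@dataclass
class PipelineConfig:
    genome: str
    datasets: list[DatasetSpec]
    outdir: str
    background: str | None = None
    scan_params: ScanParams = field(default_factory=ScanParams)
    point_rule: str = "midpoint"
    seed: int = 0

    def __post_init__(self):
        labels = [d.label for d in self.datasets]
        if len(set(labels)) != len(labels):
            raise ValueError("dataset labels must be unique")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        datasets = [DatasetSpec(**d) for d in raw.pop("datasets")]
        sp = ScanParams(**raw.pop("scan_params", {}))
        return cls(datasets=datasets, scan_params=sp, **raw)


def _round_half_away(x: float) -> int:
    # the conventional presentation rounding (0.5 -> 1), not banker's
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


def summarize(cluster_sets: list[ClusterSet], site_sets: list[SiteSet]) -> pd.DataFrame:
    """One row per dataset: sites, clusters, sites-in-clusters, percent.

    ``percent_in_clusters`` is rounded half-away-from-zero for display;
    the unrounded value is kept in a parallel column.
    """
    by_label = {s.label: s for s in site_sets}
    for cs in cluster_sets:
        if cs.source_site_label not in by_label:
            raise ValueError(f"no site set for cluster set {cs.label!r}")
    rows = []
    for cs in cluster_sets:
        ss = by_label[cs.source_site_label]
        n_in, pct = percent_in_clusters(ss, cs) if len(ss) else (0, 0.0)
        rows.append(
            {
                "label": cs.label,
                "n_sites": len(ss),
                "n_clusters": len(cs),
                "n_sites_in_clusters": n_in,
                "percent_in_clusters": _round_half_away(pct),
                "percent_unrounded": round(pct, 4),
                "data_type": "Differential DNA Methylation" if ss.site_type == "dmr" else "Differential Gene Expression",
            }
        )
    return pd.DataFrame(rows)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis; returns the output directory.

    Per dataset: ``<label>_windows.tsv`` and ``<label>_clusters.bed``.
    With a background annotation: ``bkg_clusters.bed`` plus per-dataset
    retained/removed BEDs, and two overlap matrices (all sets including
    BKG, and retained sets after subtraction). Always: ``summary.tsv``
    and a parameter/provenance ``run.log``; ``DONE`` marks completion.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    done = outdir / "DONE"
    if done.exists():
        done.unlink()
    log: list[str] = [f"ecrscan {__version__}"]

    def stage(name):
        log.append(f"[stage] {name}")

    try:
        stage("read_genome")
        genome = read_genome(config.genome)
        log.append(f"genome: {config.genome} sha256:{_digest(Path(config.genome))} "
                   f"({len(genome)} chromosomes, {genome.total_length} bp)")
        log.append(f"params: {config.scan_params}")
        log.append(f"point_rule: {config.point_rule}  seed: {config.seed}")

        stage("read_sites")
        site_sets: list[SiteSet] = []
        for d in config.datasets:
            ss = read_sites(d.path, d.label, d.site_type, genome, config.point_rule)  # type: ignore[arg-type]
            log.append(f"dataset {d.label}: {d.path} sha256:{_digest(Path(d.path))} "
                       f"{len(ss)} sites, {ss.n_dropped} dropped")
            site_sets.append(ss)

        stage("scan_datasets")
        cluster_sets: list[ClusterSet] = []
        for ss in site_sets:
            result, clusters = scan(ss, genome, config.scan_params)
            result.write_tsv(outdir / f"{ss.label}_windows.tsv")
            write_clusters(clusters, outdir / f"{ss.label}_clusters.bed")
            log.append(f"scan {ss.label}: {len(clusters)} clusters")
            cluster_sets.append(clusters)

        bkg_sites = None
        bkg_clusters = None
        if config.background is not None:
            stage("scan_background")
            bkg_sites = read_sites(config.background, "BKG", "gene", genome, config.point_rule)  # type: ignore[arg-type]
            log.append(f"background: {config.background} sha256:{_digest(Path(config.background))} "
                       f"{len(bkg_sites)} sites, {bkg_sites.n_dropped} dropped")
            _, bkg_clusters = scan(bkg_sites, genome, config.scan_params)
            write_clusters(bkg_clusters, outdir / "bkg_clusters.bed")
            log.append(f"scan BKG: {len(bkg_clusters)} clusters")

            stage("subtract_background")
            retained_sets = []
            for cs in cluster_sets:
                res = subtract_background(cs, bkg_clusters)
                write_clusters(res.retained, outdir / f"{cs.label}_retained.bed")
                write_clusters(res.removed, outdir / f"{cs.label}_removed.bed")
                log.append(f"subtract {cs.label}: {res.n_retained} retained, {res.n_removed} removed")
                retained_sets.append(res.retained)

        stage("overlap_matrices")
        all_sets = cluster_sets + ([bkg_clusters] if bkg_clusters is not None else [])
        overlap_matrix(all_sets).write_tsv(outdir / "overlap_matrix.tsv")
        if bkg_clusters is not None:
            overlap_matrix(retained_sets).write_tsv(outdir / "overlap_matrix_minus_bkg.tsv")

        stage("summarize")
        sum_sets = list(cluster_sets)
        sum_sites = list(site_sets)
        if bkg_clusters is not None:
            sum_sets.append(bkg_clusters)
            sum_sites.append(bkg_sites)
        summarize(sum_sets, sum_sites).to_csv(outdir / "summary.tsv", sep="\t", index=False)
    except Exception as exc:
        log.append(f"[FAILED] {exc}")
        (outdir / "run.log").write_text("\n".join(log) + "\n")
        raise RuntimeError(f"pipeline failed at stage {log[-2] if len(log) > 1 else '?'}: {exc}") from exc

    (outdir / "run.log").write_text("\n".join(log) + "\n")
    done.write_text("ok\n")
    return outdir
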