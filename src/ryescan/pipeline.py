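"""End-to-end orchestration: simulate/load -> filter -> windowed stats ->
recombination classes -> outlier scans -> correlations -> GO enrichment.

The pipeline runs either on a :class:`~ryescan.simulate.SimulationConfig`
(writing the simulated bundle to disk first and reading it back through
the production readers, so every run also exercises the round-trip) or on
real input files (VCF, sample map, rho track, GFF3, gene->GO TSV). All
stage outputs are plain TSV/BED/JSON and a manifest records seeds, row
counts and output digests; reruns with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import recombination as rec
from . import scan as scan_mod
from . import simulate as sim
from . import variant_io as vio
from . import window_stats as ws

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RealInputs", "run_pipeline", "validate_inputs"]


@dataclass
class RealInputs:
    vcf: str
    sample_map: str
    rho_track: str
    gff: str | None = None
    gene2go: str | None = None
    genetic_map: str | None = None


@dataclass
class PipelineConfig:
    outdir: str
    simulation: sim.SimulationConfig | None = None
    real: RealInputs | None = None
    window_size: int = ws.DEFAULT_WINDOW_SIZE
    filter_spec: vio.FilterSpec = field(default_factory=vio.FilterSpec)
    low_q: float = 0.25
    high_q: float = 0.75
    outlier_q: float = 0.95
    alpha: float = 0.05
    min_entries: int = 5
    run_enrichment: bool = True
    planted_term: str = "GO:7999999"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.real is None):
            raise ValueError("exactly one of simulation config or real inputs must be set")
        for q in (self.low_q, self.high_q, self.outlier_q):
            if not 0 < q < 1:
                raise ValueError("quantiles must be in (0, 1)")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def validate_inputs(config: PipelineConfig) -> dict:
    """Pre-flight checks; returns {'errors': [...], 'warnings': [...]}."""
    errors: list[str] = []
    warnings_: list[str] = []
    if config.simulation is not None:
        return {"errors": errors, "warnings": warnings_}
    ri = config.real
    for name in ("vcf", "sample_map", "rho_track"):
        p = getattr(ri, name)
        if p is None or not Path(p).exists():
            errors.append(f"missing required input: {name} ({p})")
    if config.run_enrichment and (ri.gff is None or ri.gene2go is None):
        errors.append("enrichment enabled but gff/gene2go input missing")
    if errors:
        return {"errors": errors, "warnings": warnings_}

    matrix, _ = vio.read_vcf(ri.vcf, ri.sample_map)
    track = rec.read_rho_track(ri.rho_track)
    vcf_chroms = set(np.unique(matrix.chrom))
    track_chroms = set(track["chrom"])
    if not vcf_chroms & track_chroms:
        errors.append("no chromosome shared between VCF and rho track")
    if np.any(track["start"].to_numpy() % config.window_size != 0):
        errors.append(
            f"rho track windows are not aligned to the {config.window_size} bp grid"
        )
    if ri.gff is not None:
        genes = vio.read_gff3(ri.gff)
        if len(genes) and not (set(genes["chrom"]) & vcf_chroms):
            errors.append("no chromosome shared between VCF and gene annotation")
    return {"errors": errors, "warnings": warnings_}


def _simulate_bundle(config: PipelineConfig, outdir: Path) -> RealInputs:
    """Generate the synthetic bundle, write it, and return its file paths."""
    sc = config.simulation
    track, windows = sim.generate_recombination_track(sc)
    matrix, pops, truth = sim.simulate_variants(sc, track)
    matrix = sim.apply_gbs_noise(matrix, sc)
    low_windows = [i for i, c in enumerate(truth["rec_class"]) if c == rec.LOW]
    annotation = sim.generate_annotation(
        sc, track, planted_term=config.planted_term, planted_windows=low_windows
    )

    paths = RealInputs(
        vcf=str(outdir / "simulated.vcf"),
        sample_map=str(outdir / "sample_map.tsv"),
        rho_track=str(outdir / "rho_track.tsv"),
        gff=str(outdir / "genes.gff3"),
        gene2go=str(outdir / "gene2go.tsv"),
    )
    vio.write_vcf(matrix, paths.vcf, contig_lengths=sc.chrom_lengths)
    vio.write_sample_map(
        {s: ("annual" if i < sc.n_samples_pop1 else "perennial") for i, s in enumerate(matrix.samples)},
        paths.sample_map,
    )
    rec.write_rho_track(track, paths.rho_track)
    vio.write_gff3(annotation.genes, paths.gff)
    vio.write_gene2go(annotation.gene2go, paths.gene2go)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False, float_format="%.10g")
    return paths


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}

    stage = "inputs"
    try:
        if config.simulation is not None:
            inputs = _simulate_bundle(config, outdir)
        else:
            inputs = config.real
        report = validate_inputs(
            PipelineConfig(
                outdir=config.outdir, real=inputs, window_size=config.window_size,
                filter_spec=config.filter_spec, low_q=config.low_q, high_q=config.high_q,
                outlier_q=config.outlier_q, alpha=config.alpha,
                min_entries=config.min_entries, run_enrichment=config.run_enrichment,
                seed=config.seed,
            )
        )
        if report["errors"]:
            raise ValueError("; ".join(report["errors"]))

        stage = "read"
        matrix, pops = vio.read_vcf(inputs.vcf, inputs.sample_map)
        track = rec.read_rho_track(inputs.rho_track)
        manifest["stages"]["read"] = {"n_sites": matrix.n_sites, "n_samples": matrix.n_samples}

        stage = "filter"
        filtered, freport = vio.filter_sites(matrix, config.filter_spec)
        (outdir / "filter_report.json").write_text(freport.to_json())
        manifest["stages"]["filter"] = {
            "X": freport.n_input, "Y": freport.n_removed, "retained": freport.n_retained,
        }

        stage = "window_stats"
        windows = [
            ws.GenomicWindow(r.chrom, int(r.start), int(r.end))
            for r in track.itertuples(index=False)
        ]
        stats = ws.compute_window_stats(filtered, pops.pop1, pops.pop2, windows)
        stats["rho"] = track["rho"].to_numpy()

        stage = "classify"
        classification = rec.classify_windows(stats["rho"].to_numpy(), config.low_q, config.high_q)
        stats["rec_class"] = classification.classes

        annotation = None
        if inputs.gff is not None:
            genes = vio.read_gff3(inputs.gff)
            g2g = vio.read_gene2go(inputs.gene2go) if inputs.gene2go else pd.DataFrame(
                columns=["gene_id", "go_id", "go_class"]
            )
            annotation = vio.GeneAnnotation(genes=genes, gene2go=g2g)
            stats["gene_count"] = ws.gene_density(annotation, windows)
        ws.write_window_stats(stats, outdir / "window_stats.tsv")
        manifest["stages"]["window_stats"] = {
            "n_windows": len(stats),
            "n_defined": int(stats["fst"].notna().sum()),
            "class_counts": classification.counts,
        }

        stage = "scan"
        gw = scan_mod.scan_genome_wide(stats, config.outlier_q, classes=classification.classes)
        strat = scan_mod.scan_stratified(stats, classification.classes, config.outlier_q)
        scan_mod.write_outliers_bed(stats, gw, outdir / "outliers_genome_wide.bed")
        scan_mod.write_outliers_bed(stats, strat, outdir / "outliers_stratified.bed")
        panel = scan_mod.landscape_correlations(stats)
        (outdir / "correlations.json").write_text(panel.to_json())
        panel.panel.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
        manifest["stages"]["scan"] = {
            "genome_wide_outliers": gw.n_outliers,
            "genome_wide_outliers_low_rec": gw.n_outliers_low_rec,
            "threshold_z": gw.threshold,
            "stratified": strat.class_counts,
        }

        if config.run_enrichment and annotation is not None and len(annotation.gene2go):
            stage = "enrichment"
            outlier_windows = [w for w, f in zip(windows, gw.outlier) if f]
            gene_set = enr.extract_study_genes(annotation, outlier_windows)
            if gene_set.study:
                results = enr.run_sea(gene_set, alpha=config.alpha, min_entries=config.min_entries)
                results.to_csv(outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
                manifest["stages"]["enrichment"] = {
                    "n_study_genes": len(gene_set.study),
                    "n_terms_tested": len(results),
                    "n_significant": int(results["significant"].sum()) if len(results) else 0,
                }
            else:
                manifest["stages"]["enrichment"] = {"n_study_genes": 0, "skipped": True}
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    for p in sorted(outdir.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _digest(p)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
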