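"""Variant and annotation I/O, site filtering, and effective-length math.

Genotypes are stored as diploid ALT-allele dosages (0, 1, 2) with ``-1``
marking a missing call. VCF positions are 1-based (VCF convention); all
other coordinates in the package (windows, gene intervals) are 0-based
half-open, and the conversion happens only in the readers/writers here.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

logger = logging.getLogger(__name__)

__all__ = [
    "MISSING",
    "VariantMatrix",
    "Populations",
    "FilterSpec",
    "FilterReport",
    "EffectiveLengthInputs",
    "GeneAnnotation",
    "read_vcf",
    "write_vcf",
    "read_sample_map",
    "write_sample_map",
    "filter_sites",
    "classify_intergenic",
    "effective_length",
    "theta_from_length",
    "read_gff3",
    "write_gff3",
    "read_gene2go",
    "write_gene2go",
]


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed into a dosage matrix."""


@dataclass
class VariantMatrix:
    """Biallelic-oriented site x sample dosage matrix with per-site depth.

    ``alt`` may contain comma-separated alleles for multiallelic records;
    such sites survive reading but are removed by :func:`filter_sites`
    when ``biallelic_only`` is set.
    """

    chrom: np.ndarray  # str, per site
    pos: np.ndarray  # int, 1-based (VCF convention)
    ref: np.ndarray  # str
    alt: np.ndarray  # str, comma-separated if multiallelic
    genotypes: np.ndarray  # (n_sites, n_samples) int8 dosage, -1 missing
    depth: np.ndarray  # float, per-site read depth
    samples: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def missing_fraction(self) -> np.ndarray:
        """Per-site fraction of samples with a missing call."""
        if self.n_samples == 0:
            return np.zeros(self.n_sites)
        return (self.genotypes == MISSING).sum(axis=1) / self.n_samples

    def take_sites(self, index: np.ndarray) -> "VariantMatrix":
        return VariantMatrix(
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            genotypes=self.genotypes[index],
            depth=self.depth[index],
            samples=list(self.samples),
        )


@dataclass
class Populations:
    """Partition of the sample columns into exactly two populations."""

    names: tuple[str, str]
    indices: dict[str, np.ndarray]  # population name -> column indices

    @classmethod
    def from_samples(cls, samples: list[str], sample_map: dict[str, str]) -> "Populations":
        pops = sorted({sample_map[s] for s in samples})
        if len(pops) != 2:
            raise ValueError(f"expected exactly 2 populations, got {pops}")
        idx = {
            p: np.array([i for i, s in enumerate(samples) if sample_map[s] == p], dtype=int)
            for p in pops
        }
        return cls(names=(pops[0], pops[1]), indices=idx)

    @property
    def pop1(self) -> np.ndarray:
        return self.indices[self.names[0]]

    @property
    def pop2(self) -> np.ndarray:
        return self.indices[self.names[1]]


@dataclass
class FilterSpec:
    """Site filters: biallelic SNVs, missingness below 30%, depth in [10, 100].

    Missingness is a strict inequality (a site with exactly ``max_missing``
    missing data is removed); the depth bounds are inclusive.
    """

    biallelic_only: bool = True
    max_missing: float = 0.30
    min_depth: float = 10
    max_depth: float = 100

    def __post_init__(self) -> None:
        if not 0 <= self.max_missing <= 1:
            raise ValueError("max_missing must be in [0, 1]")
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must be <= max_depth")


@dataclass
class FilterReport:
    """X/Y bookkeeping for a filtering pass.

    ``n_input`` (X) = sites in, ``n_removed`` (Y) = sites out, and
    ``removed_by_rule`` counts every rule each site failed, so the
    per-rule counts may sum to more than Y.
    """

    n_input: int
    n_retained: int
    n_removed: int
    removed_by_rule: dict[str, int] = field(default_factory=dict)
    empty_output: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_retained": self.n_retained,
                "n_removed": self.n_removed,
                "removed_by_rule": self.removed_by_rule,
                "empty_output": self.empty_output,
            },
            indent=2,
        )


@dataclass
class EffectiveLengthInputs:
    """Inputs for the effective sequence length L = ((X - Y)/X) * N_seq.

    X: total SNV count before filtering; Y: SNVs removed by filtering;
    n_seq: basepairs covered by reads; mu: per-site per-generation
    mutation rate (used downstream for theta = 4*mu*L).
    """

    x_total: int
    y_filtered: int
    n_seq: float
    mu: float = 3.5e-9

    def __post_init__(self) -> None:
        if not 0 <= self.y_filtered <= self.x_total:
            raise ValueError("require 0 <= Y <= X")
        if self.n_seq <= 0:
            raise ValueError("N_seq must be positive")


@dataclass
class GeneAnnotation:
    """Gene intervals plus a flat gene -> GO-term mapping.

    ``genes`` columns: gene_id, chrom, start, end (0-based half-open).
    ``gene2go`` columns: gene_id, go_id, go_class.
    """

    genes: pd.DataFrame
    gene2go: pd.DataFrame

    def __post_init__(self) -> None:
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids in annotation")


# ---------------------------------------------------------------------------
# VCF


def read_sample_map(path) -> dict[str, str]:
    """Read a two-column (sample, population) TSV without header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"], dtype=str)
    return dict(zip(df["sample"], df["population"]))


def write_sample_map(sample_map: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for s, p in sample_map.items():
            fh.write(f"{s}\t{p}\n")


def read_vcf(path, sample_map: dict[str, str] | str) -> tuple[VariantMatrix, Populations]:
    """Read a VCF into a dosage matrix, keeping only mapped samples.

    Samples absent from ``sample_map`` are dropped with a warning; zero
    overlap is an error. Per-site depth uses INFO/DP when present, else
    the mean of per-sample FORMAT/DP.
    """
    from cyvcf2 import VCF

    if isinstance(sample_map, (str, bytes)) or hasattr(sample_map, "__fspath__"):
        sample_map = read_sample_map(sample_map)

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    all_samples = list(vcf.samples)
    keep = [s for s in all_samples if s in sample_map]
    dropped = [s for s in all_samples if s not in sample_map]
    if not keep:
        raise ValueError("no VCF samples overlap the sample map")
    if dropped:
        logger.warning("dropping %d samples absent from sample map: %s", len(dropped), dropped)
    keep_idx = np.array([all_samples.index(s) for s in keep], dtype=int)

    chroms, poss, refs, alts, dosages, depths = [], [], [], [], [], []
    for line_no, var in enumerate(vcf, start=1):
        try:
            # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
            gt = var.gt_types[keep_idx]
            dose = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
            dp = var.INFO.get("DP")
            if dp is None:
                fmt_dp = var.format("DP")
                dp = float(np.nanmean(fmt_dp)) if fmt_dp is not None else np.nan
            chroms.append(var.CHROM)
            poss.append(var.POS)
            refs.append(var.REF)
            alts.append(",".join(var.ALT) if var.ALT else ".")
            dosages.append(dose)
            depths.append(float(dp))
        except Exception as exc:
            raise VcfParseError(f"malformed VCF record #{line_no} in {path}: {exc}") from exc

    matrix = VariantMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        genotypes=np.array(dosages, dtype=np.int8).reshape(len(poss), len(keep)),
        depth=np.array(depths, dtype=float),
        samples=keep,
    )
    pops = Populations.from_samples(keep, sample_map)
    return matrix, pops


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: VariantMatrix, path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write the matrix as VCF 4.2 with GT calls and per-site INFO/DP."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for i in range(matrix.n_sites):
            dp = matrix.depth[i]
            info = f"DP={int(round(dp))}" if np.isfinite(dp) else "."
            gts = "\t".join(_GT_STRING[int(g)] for g in matrix.genotypes[i])
            fh.write(
                f"{matrix.chrom[i]}\t{matrix.pos[i]}\t.\t{matrix.ref[i]}\t"
                f"{matrix.alt[i]}\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Filtering


def filter_sites(matrix: VariantMatrix, spec: FilterSpec) -> tuple[VariantMatrix, FilterReport]:
    """Apply biallelic / missingness / depth site filters.

    A retained site has exactly two observed alleles (REF and ALT both
    seen among called genotypes), single-base REF and ALT, a missing
    fraction strictly below ``max_missing``, and depth inside the
    inclusive ``[min_depth, max_depth]`` band.
    """
    G = matrix.genotypes
    called = G != MISSING
    n_called = called.sum(axis=1)
    alt_count = np.where(called, G, 0).sum(axis=1)

    fail = {}
    if spec.biallelic_only:
        single_base = np.array(
            [len(r) == 1 and len(a) == 1 for r, a in zip(matrix.ref, matrix.alt)]
        )
        both_seen = (alt_count > 0) & (alt_count < 2 * n_called)
        fail["not_biallelic_snv"] = ~(single_base & both_seen)
    fail["missingness"] = matrix.missing_fraction >= spec.max_missing
    with np.errstate(invalid="ignore"):
        fail["depth_low"] = ~(matrix.depth >= spec.min_depth)
        fail["depth_high"] = ~(matrix.depth <= spec.max_depth)

    any_fail = np.zeros(matrix.n_sites, dtype=bool)
    for mask in fail.values():
        any_fail |= mask
    keep = ~any_fail

    report = FilterReport(
        n_input=matrix.n_sites,
        n_retained=int(keep.sum()),
        n_removed=int(any_fail.sum()),
        removed_by_rule={k: int(v.sum()) for k, v in fail.items()},
        empty_output=not keep.any(),
    )
    if report.empty_output:
        warnings.warn("all sites removed by filtering", stacklevel=2)
    return matrix.take_sites(keep), report


def classify_intergenic(matrix: VariantMatrix, annotation: GeneAnnotation) -> VariantMatrix:
    """Retain sites overlapping no gene interval (coordinate-based)."""
    keep = np.ones(matrix.n_sites, dtype=bool)
    pos0 = matrix.pos - 1  # VCF 1-based -> 0-based
    for chrom, sub in annotation.genes.groupby("chrom"):
        on_chrom = matrix.chrom == chrom
        if not on_chrom.any():
            continue
        p = pos0[on_chrom]
        inside = np.zeros(len(p), dtype=bool)
        for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
            inside |= (p >= s) & (p < e)
        keep[np.where(on_chrom)[0][inside]] = False
    return matrix.take_sites(keep)


# ---------------------------------------------------------------------------
# Effective length / theta


def effective_length(inputs: EffectiveLengthInputs) -> float:
    """Effective sequence length L = ((X - Y) / X) * N_seq."""
    if inputs.x_total == 0:
        raise ValueError("X (total SNV count) must be positive")
    return (inputs.x_total - inputs.y_filtered) / inputs.x_total * inputs.n_seq


def theta_from_length(mu: float, length: float) -> float:
    """Population-scaled mutation rate theta = 4 * mu * L."""
    if mu <= 0 or length <= 0:
        raise ValueError("mu and L must be positive")
    return 4.0 * mu * length


# ---------------------------------------------------------------------------
# Annotation I/O


def read_gff3(path) -> pd.DataFrame:
    """Read gene features from a GFF3 into (gene_id, chrom, start, end).

    GFF3 coordinates are 1-based inclusive; the returned intervals are
    0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    rows = []
    for gene in db.features_of_type("gene"):
        rows.append(
            {
                "gene_id": gene.id,
                "chrom": gene.seqid,
                "start": gene.start - 1,
                "end": gene.end,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def write_gff3(genes: pd.DataFrame, path) -> None:
    """Write gene intervals (0-based half-open) as GFF3 gene features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\tryescan\tgene\t{row.start + 1}\t{row.end}\t.\t+\t.\t"
                f"ID={row.gene_id}\n"
            )


def read_gene2go(path) -> pd.DataFrame:
    """Read a gene -> GO TSV tolerant of extra columns.

    The first three columns are taken as gene_id, go_id, go_class; a
    header line is detected and skipped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, header=None)
    if df.iloc[0, 0] in ("gene_id", "gene", "Gene_ID"):
        df = df.iloc[1:].reset_index(drop=True)
    df = df.iloc[:, :3]
    df.columns = ["gene_id", "go_id", "go_class"]
    return df


def write_gene2go(gene2go: pd.DataFrame, path) -> None:
    gene2go.to_csv(path, sep="\t", index=False, columns=["gene_id", "go_id", "go_class"])
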