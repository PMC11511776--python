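"""GO singular enrichment analysis (SEA) of outlier-window genes.

Genes whose start falls in a significantly differentiated window form the
study set; all annotated genes are the background. Each GO term annotated
to at least ``min_entries`` study genes is tested with a two-sided Fisher
exact test of the 2x2 table

        study  background-only
  term    a          c
  other   b          d

and p-values are adjusted by the Benjamini-Yekutieli step-up procedure,
which controls the FDR under arbitrary dependence between terms (GO terms
overlap heavily). The enrichment ratio of a term is a/(a+c): the share of
the genome's term-annotated genes that lie in the study set. The GO
hierarchy is not traversed — terms are tested exactly as annotated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .variant_io import GeneAnnotation
from .window_stats import GenomicWindow

__all__ = [
    "GeneSet",
    "extract_study_genes",
    "fisher_exact",
    "adjust_yekutieli",
    "enrichment_ratio",
    "run_sea",
    "top_terms",
]


@dataclass
class GeneSet:
    study: list[str]
    background: list[str]
    gene2go: pd.DataFrame  # gene_id, go_id, go_class

    def __post_init__(self) -> None:
        study, background = set(self.study), set(self.background)
        if len(study) != len(self.study) or len(background) != len(self.background):
            raise ValueError("gene ids must be unique")
        if not study <= background:
            raise ValueError("study genes must be a subset of the background")


def extract_study_genes(
    annotation: GeneAnnotation, outlier_windows: list[GenomicWindow]
) -> GeneSet:
    """Genes assigned (by start position) to an outlier window."""
    genes = annotation.genes
    study = []
    starts = genes["start"].to_numpy()
    chroms = genes["chrom"].to_numpy()
    ids = genes["gene_id"].to_numpy()
    for w in outlier_windows:
        hit = (chroms == w.chrom) & (starts >= w.start) & (starts < w.end)
        study.extend(ids[hit].tolist())
    return GeneSet(study=sorted(set(study)), background=sorted(set(ids)), gene2go=annotation.gene2go)


def fisher_exact(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Odds ratio and two-sided Fisher exact p for the 2x2 table.

    A zero row or column margin carries no information: p = 1 and the
    odds ratio is undefined (NaN).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table counts must be non-negative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return np.nan, 1.0
    odds, p = sps.fisher_exact([[a, c], [b, d]], alternative="two-sided")
    return float(odds), float(p)


def adjust_yekutieli(p_values) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p-values (input order kept)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def enrichment_ratio(n_significant_in_term: int, n_term_genome: int) -> float:
    """Share of a term's genome-wide genes that are in the study set."""
    if n_term_genome <= 0:
        raise ValueError("genome-wide term size must be positive")
    if not 0 <= n_significant_in_term <= n_term_genome:
        raise ValueError("study count must be within [0, genome term size]")
    return n_significant_in_term / n_term_genome


def run_sea(
    gene_set: GeneSet, alpha: float = 0.05, min_entries: int = 5
) -> pd.DataFrame:
    """Singular enrichment analysis over all GO terms.

    Terms with fewer than ``min_entries`` study genes are excluded before
    testing (they cannot meaningfully reject and would dilute the FDR
    correction). Output columns include both FDR-level and raw-p
    significance flags.
    """
    study = set(gene_set.study)
    background = set(gene_set.background)
    if not study or not background:
        raise ValueError("study and background gene sets must be non-empty")
    g2g = gene_set.gene2go[gene_set.gene2go["gene_id"].isin(background)]

    rows = []
    for (term, go_class), sub in g2g.groupby(["go_id", "go_class"], sort=True):
        term_genes = set(sub["gene_id"])
        a = len(term_genes & study)
        if a < min_entries:
            continue
        b = len(study) - a
        c = len(term_genes) - a
        d = len(background) - len(study) - c
        odds, p = fisher_exact(a, b, c, d)
        rows.append(
            {
                "term": term,
                "go_class": go_class,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "odds_ratio": odds,
                "p_raw": p,
                "enrichment_ratio": enrichment_ratio(a, a + c),
            }
        )
    if not rows:
        warnings.warn("no GO term passed the min_entries filter", stacklevel=2)
        return pd.DataFrame(
            columns=[
                "term", "go_class", "a", "b", "c", "d", "odds_ratio",
                "p_raw", "p_fdr", "enrichment_ratio", "significant", "significant_raw",
            ]
        )
    df = pd.DataFrame(rows)
    df["p_fdr"] = adjust_yekutieli(df["p_raw"].to_numpy())
    df["significant"] = df["p_fdr"] < alpha
    df["significant_raw"] = df["p_raw"] < alpha
    return df[
        [
            "term", "go_class", "a", "b", "c", "d", "odds_ratio",
            "p_raw", "p_fdr", "enrichment_ratio", "significant", "significant_raw",
        ]
    ]


def top_terms(results: pd.DataFrame, go_class: str, n: int = 10) -> pd.DataFrame:
    """Top terms of one GO class by enrichment ratio, then FDR p-value."""
    sub = results[results["go_class"] == go_class]
    return sub.sort_values(
        ["enrichment_ratio", "p_fdr"], ascending=[False, True]
    ).head(n).reset_index(drop=True)
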