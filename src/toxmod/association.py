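"""Per-variant allelic association tests, genotype PCA, and gene annotation.

Cases are samples in the high-toxicity class (grade 3-4), controls the
low-toxicity class (grade 0-1); intermediates (grade 2) are excluded from
testing.  The allelic test builds a 2x2 table of allele counts — two alleles
per called sample — and computes a two-sided Fisher exact p-value by exact
integer hypergeometric enumeration (sum of table probabilities no larger
than the observed table's probability).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel, VariantRecord

logger = logging.getLogger(__name__)

LOW, INTERMEDIATE, HIGH = "low", "intermediate", "high"
CASE, CONTROL, EXCLUDED = "case", "control", "excluded"

GRADE_COLUMNS = {
    "neutropenia": "grade_neutropenia",
    "leukopenia": "grade_leukopenia",
    "thrombocytopenia": "grade_thrombocytopenia",
    "maximal": "grade_maximal",
}


def toxicity_class(grade: int) -> str:
    """CTCAE grade -> low (0-1) / intermediate (2) / high (3-4)."""
    if grade <= 1:
        return LOW
    if grade == 2:
        return INTERMEDIATE
    return HIGH


@dataclass
class PhenotypeTable:
    """Per-sample CTCAE grades with derived toxicity classes."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "sample_id" not in self.table.columns:
            raise ValueError("phenotype table requires a sample_id column")
        for col in self.table.columns:
            if col.startswith("grade_"):
                vals = self.table[col]
                if not vals.isin(range(5)).all():
                    raise ValueError(f"{col}: grades must be integers 0-4")

    @classmethod
    def read(cls, path) -> "PhenotypeTable":
        return cls(pd.read_csv(path, sep="\t"))

    @property
    def samples(self) -> list[str]:
        return self.table["sample_id"].astype(str).tolist()

    def grades(self, phenotype: str) -> np.ndarray:
        return self.table[GRADE_COLUMNS[phenotype]].to_numpy()

    def classes(self, phenotype: str) -> np.ndarray:
        """Array of low/intermediate/high for the given phenotype."""
        return np.array([toxicity_class(g) for g in self.grades(phenotype)])

    def case_control(self, phenotype: str) -> np.ndarray:
        """Map classes to case/control/excluded for association testing."""
        mapping = {HIGH: CASE, LOW: CONTROL, INTERMEDIATE: EXCLUDED}
        return np.array([mapping[c] for c in self.classes(phenotype)])

    def class_counts(self, phenotype: str = "maximal") -> dict[str, int]:
        cls = self.classes(phenotype)
        return {k: int(np.sum(cls == k)) for k in (HIGH, INTERMEDIATE, LOW)}


@dataclass
class AssociationResult:
    variant_id: str
    phenotype: str
    a: int  # case alt alleles
    b: int  # case ref alleles
    c: int  # control alt alleles
    d: int  # control ref alleles
    p_value: float
    odds_ratio: float
    nominal: bool = False
    monomorphic: bool = False


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for a 2x2 table, by integer enumeration.

    Sums hypergeometric probabilities of all tables with the same margins
    whose probability is <= the observed table's; the comparison is done in
    exact integer arithmetic so ties are handled without float round-off.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = comb(r1, a) * comb(r2, c)
    total = comb(n, c1)
    acc = 0
    for k in range(lo, hi + 1):
        w = comb(r1, k) * comb(r2, c1 - k)
        if w <= obs:
            acc += w
    return acc / total


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)


def allelic_fisher(dosages: np.ndarray, classes: Sequence[str], variant_id: str = "", phenotype: str = "") -> AssociationResult:
    """Allelic Fisher exact test of alt-allele counts, cases vs controls.

    ``dosages`` are per-sample alt-allele counts (NaN = missing, dropped from
    the allele counts); ``classes`` values are case/control/excluded.
    """
    dosages = np.asarray(dosages, dtype=float)
    classes = np.asarray(classes)
    if not np.isin(classes, (CASE, CONTROL)).any():
        raise ValueError("all samples excluded: no cases or controls")
    case_called = (classes == CASE) & ~np.isnan(dosages)
    ctrl_called = (classes == CONTROL) & ~np.isnan(dosages)
    a = int(dosages[case_called].sum())
    b = 2 * int(case_called.sum()) - a
    c = int(dosages[ctrl_called].sum())
    d = 2 * int(ctrl_called.sum()) - c
    if a + c == 0 or b + d == 0:
        return AssociationResult(variant_id, phenotype, a, b, c, d, 1.0, 1.0, monomorphic=True)
    p = fisher_exact_two_sided(a, b, c, d)
    return AssociationResult(variant_id, phenotype, a, b, c, d, p, _odds_ratio(a, b, c, d))


def associate_all(matrix_dosages: np.ndarray, variant_ids: Sequence[str], classes: Sequence[str], phenotype: str = "") -> list[AssociationResult]:
    """Run :func:`allelic_fisher` over every column of a dosage matrix."""
    return [
        allelic_fisher(matrix_dosages[:, j], classes, variant_id=vid, phenotype=phenotype)
        for j, vid in enumerate(variant_ids)
    ]


def filter_nominal(results: Sequence[AssociationResult], alpha: float = 1e-3) -> list[AssociationResult]:
    """Subset of results with p <= alpha (inclusive), order preserved."""
    return [replace(r, nominal=True) for r in results if r.p_value <= alpha]


def results_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in results],
            "phenotype": [r.phenotype for r in results],
            "case_alt": [r.a for r in results],
            "case_ref": [r.b for r in results],
            "control_alt": [r.c for r in results],
            "control_ref": [r.d for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "p_value": [r.p_value for r in results],
            "nominal": [r.nominal for r in results],
            "monomorphic": [r.monomorphic for r in results],
        }
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_genotypes(dosages: np.ndarray, n_components: int = 2, max_missing: float = 0.05):
    """PCA of a samples x variants dosage matrix.

    Monomorphic and missing-heavy (> ``max_missing`` missing) variants are
    dropped; remaining missing values are imputed to the variant mean;
    columns are centred and scaled to unit variance before the SVD.
    Components are sign-fixed so the largest-magnitude loading is positive.

    Returns ``(coordinates, explained_variance)``.
    """
    X = np.asarray(dosages, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 samples")
    miss_frac = np.mean(np.isnan(X), axis=0)
    keep = miss_frac <= max_missing
    X = X[:, keep]
    col_mean = np.nanmean(X, axis=0)
    col_sd = np.nanstd(X, axis=0)
    poly = col_sd > 0
    X = X[:, poly]
    if X.shape[1] < n_components:
        raise ValueError(f"only {X.shape[1]} usable variants for {n_components} components")
    col_mean, col_sd = col_mean[poly], col_sd[poly]
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    Z = (X - col_mean) / col_sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    coords = U[:, :n_components] * S[:n_components]
    loadings = Vt[:n_components]
    for k in range(n_components):
        j = np.argmax(np.abs(loadings[k]))
        if loadings[k, j] < 0:
            coords[:, k] *= -1
            loadings[k] *= -1
    explained = S[:n_components] ** 2 / (X.shape[0] - 1)
    return coords, explained


# ---------------------------------------------------------------------------
# Genomic annotation
# ---------------------------------------------------------------------------

PROMOTER, EXON, INTRON, DISTAL = "promoter", "exon", "intron", "distal_intergenic"


def annotate_variant(
    variant: VariantRecord,
    gene_models: Sequence[GeneModel],
    promoter_window: tuple[int, int] = (-3000, 3000),
    exon_models: Sequence[GeneModel] | None = None,
) -> str:
    """Categorise a variant as promoter / exon / intron / distal_intergenic.

    Priority: promoter > exon > intron.  The promoter window is expressed in
    the transcription direction relative to the TSS.  Without exon models the
    whole gene body (outside promoters) counts as intron.
    """
    pos, chrom = variant.pos, variant.chrom
    in_body = False
    in_exon = False
    for g in gene_models:
        if g.chrom != chrom:
            continue
        if g.strand == "+":
            lo, hi = g.tss + promoter_window[0], g.tss + promoter_window[1]
        else:
            lo, hi = g.tss - promoter_window[1], g.tss - promoter_window[0]
        if lo <= pos <= hi:
            return PROMOTER
        if g.start <= pos <= g.end:
            in_body = True
    if exon_models is not None:
        for e in exon_models:
            if e.chrom == chrom and e.start <= pos <= e.end:
                in_exon = True
                break
    if in_exon:
        return EXON
    if in_body:
        return INTRON
    return DISTAL


def nearest_gene(
    variant: VariantRecord,
    gene_models: Sequence[GeneModel],
    max_distance: int = 3_000_000,
) -> tuple[str | None, int | None]:
    """Nearest protein-coding gene on the same chromosome within range.

    Distance is 0 inside the gene body, else the gap to the closer gene
    boundary.  Ties prefer the smaller start coordinate, then the
    lexicographically smaller gene id.
    """
    best: tuple[int, int, str] | None = None
    for g in gene_models:
        if g.chrom != variant.chrom:
            continue
        if g.start <= variant.pos <= g.end:
            dist = 0
        else:
            dist = min(abs(variant.pos - g.start), abs(variant.pos - g.end))
        if dist > max_distance:
            continue
        key = (dist, g.start, g.gene_id)
        if best is None or key < best:
            best = key
    if best is None:
        return None, None
    return best[2], best[0]


def map_variants_to_genes(
    variants: Sequence[VariantRecord],
    gene_models: Sequence[GeneModel],
    max_distance: int = 3_000_000,
    autosomal_only: bool = True,
) -> pd.DataFrame:
    """Map variants to their nearest protein-coding gene (seed-gene mapping)."""
    rows = []
    for v in variants:
        if autosomal_only and not v.is_autosomal:
            continue
        gene, dist = nearest_gene(v, gene_models, max_distance)
        if gene is not None:
            rows.append({"variant_id": v.variant_id, "gene_id": gene, "distance": dist})
    return pd.DataFrame(rows, columns=["variant_id", "gene_id", "distance"])
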