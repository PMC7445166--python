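"""Readers and writers for external formats, plus the variant QC filter.

Internal coordinates are 1-based inclusive everywhere (VCF/GFF3 native);
BED input is converted at the boundary.  All text inputs may be gzipped.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import networkx as nx

logger = logging.getLogger(__name__)

#: sentinel for a missing genotype in dosage arrays
MISSING = -1


@dataclass
class VariantRecord:
    """A bi-allelic variant with per-sample alt-allele dosages.

    ``genotypes`` holds values in {0, 1, 2, MISSING}; ``depths`` (optional)
    holds per-sample read depth, negative where unavailable.
    """

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    filter_label: str = "PASS"
    genotypes: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int8))
    depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: pos must be >= 1, got {self.pos}")
        g = np.asarray(self.genotypes, dtype=np.int8)
        bad = ~np.isin(g, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"{self.variant_id}: genotype values must be 0/1/2/missing")
        self.genotypes = g

    @property
    def genotyping_rate(self) -> float:
        g = self.genotypes
        if g.size == 0:
            return 0.0
        return float(np.mean(g != MISSING))

    @property
    def is_autosomal(self) -> bool:
        c = self.chrom.removeprefix("chr")
        return c.isdigit()


@dataclass(frozen=True)
class GeneModel:
    """A gene with 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


class GeneSetCollection(dict):
    """Mapping of set name -> ordered, duplicate-free tuple of gene ids."""

    def add(self, name: str, genes: Iterable[str]) -> None:
        seen: dict[str, None] = {}
        for g in genes:
            seen.setdefault(g, None)
        self[name] = tuple(seen)


@dataclass
class GenotypeMatrix:
    """Samples x variants additive dosage matrix (float, NaN = missing)."""

    samples: list[str]
    variant_ids: list[str]
    dosages: np.ndarray

    @classmethod
    def from_records(cls, records: Sequence[VariantRecord], samples: Sequence[str]) -> "GenotypeMatrix":
        n, m = len(samples), len(records)
        dos = np.full((n, m), np.nan)
        for j, rec in enumerate(records):
            g = rec.genotypes.astype(float)
            g[rec.genotypes == MISSING] = np.nan
            dos[:, j] = g
        return cls(list(samples), [r.variant_id for r in records], dos)

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.variant_ids.index(variant_id)]


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, sample_subset: Sequence[str] | None = None):
    """Read bi-allelic variants from a VCF 4.x file (via cyvcf2).

    Returns ``(records, samples)``.  Multi-allelic rows are excluded; missing
    genotypes (./.) become :data:`MISSING`.  An empty/None ``sample_subset``
    keeps every sample; sample order always follows the file.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # htslib reports malformed headers many ways
        raise ValueError(f"{path}: VCF parse error: {exc}") from exc
    all_samples = list(vcf.samples)
    if sample_subset:
        missing = [s for s in sample_subset if s not in all_samples]
        if missing:
            raise ValueError(f"sample(s) not in VCF: {', '.join(missing)}")
        vcf.set_samples(list(sample_subset))
    samples = list(vcf.samples)

    records: list[VariantRecord] = []
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        gt = np.asarray(v.gt_types, dtype=np.int8)  # 0/1/2, 3 = unknown
        genos = np.where(gt == 3, np.int8(MISSING), gt)
        dp = v.format("DP")
        depths = None
        if dp is not None:
            depths = dp.reshape(-1).astype(np.int64)
            depths[depths < 0] = -1  # htslib missing sentinel
            depths = depths.astype(np.int32)
        variant_id = v.ID or f"{v.CHROM}:{v.POS}:{v.REF}:{v.ALT[0]}"
        records.append(
            VariantRecord(
                variant_id=variant_id,
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=v.ALT[0],
                filter_label=v.FILTER or "PASS",
                genotypes=genos,
                depths=depths,
            )
        )
    return records, samples


def qc_filter_variants(
    records: Sequence[VariantRecord],
    min_genotyping_rate: float = 0.95,
    min_depth: int = 5,
    min_mean_depth: float = 10.0,
) -> list[VariantRecord]:
    """Keep PASS records with adequate call rate and (when present) depth.

    Depth rules: every called genotype must have depth >= ``min_depth`` and
    the record mean depth over all samples must be >= ``min_mean_depth``.
    Records without depth information skip the depth rules (logged once).
    """
    kept: list[VariantRecord] = []
    warned = False
    for rec in records:
        if rec.filter_label != "PASS":
            continue
        if rec.genotyping_rate < min_genotyping_rate:
            continue
        if rec.depths is None:
            if not warned:
                logger.warning("records lack depth information; depth rules skipped")
                warned = True
        else:
            called = rec.genotypes != MISSING
            dp = rec.depths
            if called.any() and (dp[called] < min_depth).any():
                continue
            valid = dp >= 0
            if valid.any() and float(dp[valid].mean()) < min_mean_depth:
                continue
        kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------

_EDGE_COLS = (("protein1", "protein2", "combined_score"), ("geneA", "geneB", "combined_score"))


def read_network(path: str | Path, min_score: int = 700) -> nx.Graph:
    """Read a STRING-style edge list into an undirected simple graph.

    Only edges with combined score strictly greater than ``min_score`` are
    kept.  Self-loops are dropped; duplicate edges keep the maximum score.
    """
    df = pd.read_csv(path, sep="\t")
    cols = None
    for cand in _EDGE_COLS:
        if all(c in df.columns for c in cand):
            cols = cand
            break
    if cols is None:
        if df.shape[1] < 3:
            raise ValueError(f"{path}: expected >= 3 columns (geneA, geneB, combined_score)")
        cols = tuple(df.columns[:3])
    a, b, s = (df[c] for c in cols)
    score = pd.to_numeric(s, errors="coerce")
    if score.isna().any():
        bad = int(np.flatnonzero(score.isna().to_numpy())[0])
        raise ValueError(f"{path}: non-numeric combined_score at data line {bad + 2}")
    graph = nx.Graph()
    for u, v, w in zip(a.astype(str), b.astype(str), score.astype(float)):
        if u == v or w <= min_score:
            continue
        if graph.has_edge(u, v):
            graph[u][v]["combined_score"] = max(graph[u][v]["combined_score"], w)
        else:
            graph.add_edge(u, v, combined_score=w)
    return graph


# ---------------------------------------------------------------------------
# Gene models / gene sets / tables
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name, description, members...)."""
    coll = GeneSetCollection()
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: GMT rows need name + description columns")
            coll.add(parts[0], parts[2:])
    return coll


def _gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_models(path: str | Path, format: str = "GFF3") -> list[GeneModel]:
    """Read gene models from BED (0-based half-open) or GFF3 (1-based).

    When a biotype is available only ``protein_coding`` genes are retained.
    """
    fmt = format.upper()
    if fmt not in ("BED", "GFF3"):
        raise ValueError(f"unknown gene model format: {format!r}")
    genes: list[GeneModel] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if fmt == "BED":
                chrom, start, end = f[0], int(f[1]) + 1, int(f[2])
                gene_id = f[3] if len(f) > 3 else f"{chrom}:{start}-{end}"
                strand = f[5] if len(f) > 5 else "+"
                genes.append(GeneModel(gene_id, chrom, start, end, strand))
            else:
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = _gff3_attributes(f[8])
                biotype = attrs.get("biotype") or attrs.get("gene_biotype") or attrs.get("gene_type") or "protein_coding"
                if biotype != "protein_coding":
                    continue
                gene_id = attrs.get("gene_id") or attrs.get("Name") or attrs.get("ID")
                if gene_id is None:
                    raise ValueError(f"{path}: gene row without gene_id/Name/ID attribute")
                genes.append(GeneModel(gene_id, f[0], int(f[3]), int(f[4]), f[6], biotype))
    return genes


def write_table(rows: pd.DataFrame | Iterable[dict], path: str | Path) -> None:
    """Write rows as a TSV with a header; floats use repr-stable formatting."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out
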