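"""Synthetic cohort generator.

Produces genotypes, CTCAE-style phenotype grades, a PPI network with a
planted dense module, gene models, and negative-binomial expression counts
with the statistical structure the downstream analysis assumes, so every
stage is testable without patient data.

Phenotypes follow a liability-threshold model: a logistic genetic score over
the planted causal variants plus logistic noise, rank-thresholded so the
three maximal-toxicity classes hit the configured sizes exactly (54/8/34 by
default).  The three component phenotypes re-threshold the same liability
with phenotype-specific noise and are clipped so the maximal grade is the
maximum of the three.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .association import PhenotypeTable
from .io_formats import GeneModel, GenotypeMatrix

CHROMOSOMES = [str(c) for c in range(1, 23)]
GENE_LENGTH = 20_000
GENE_SPACING = 200_000


@dataclass
class NetworkConfig:
    n_module_genes: int = 40
    n_background_genes: int = 400
    p_in: float = 0.8
    p_out: float = 0.02
    module_score_range: tuple[int, int] = (701, 999)
    background_score_range: tuple[int, int] = (150, 999)


@dataclass
class ExpressionConfig:
    n_cell_lines: int = 3
    n_replicates: int = 2
    nb_dispersion: float = 0.1
    treatment_log2fc: float = 2.0
    n_affected_module_genes: int = 10


@dataclass
class SimulationConfig:
    n_samples: int = 96
    n_variants: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_maf_range: tuple[float, float] = (0.2, 0.5)
    n_causal: int = 5
    causal_odds_ratio: float = 3.0
    class_counts: tuple[int, int, int] = (54, 8, 34)  # high, intermediate, low
    liability_noise_scale: float = 1.0  # scale of the logistic noise term
    phenotype_noise_sd: float = 1.0
    fraction_genic: float = 0.5
    missing_rate: float = 0.0
    network: NetworkConfig = field(default_factory=NetworkConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.network.p_in <= self.network.p_out:
            raise ValueError("p_in must exceed p_out")
        if self.n_causal > self.n_variants:
            raise ValueError("n_causal cannot exceed n_variants")
        if sum(self.class_counts) != self.n_samples:
            raise ValueError(
                f"class_counts {self.class_counts} must sum to n_samples={self.n_samples}; "
                "adjust the thresholds/counts"
            )


@dataclass
class SyntheticTruth:
    module_genes: set[str]
    causal_variants: dict[str, tuple[str, float]] = field(default_factory=dict)  # vid -> (gene, log OR)
    affected_genes: dict[str, set[str]] = field(default_factory=dict)            # drug -> genes


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

def simulate_network(config: SimulationConfig, seed: int | None = None) -> tuple[nx.Graph, SyntheticTruth]:
    """Planted-partition graph: dense module over a sparse background.

    Module-module pairs connect with probability p_in (scores uniform in the
    high-confidence range); any pair touching the background connects with
    probability p_out.
    """
    net = config.network
    if net.n_module_genes < 3:
        raise ValueError("planted module needs at least 3 genes")
    rng = np.random.default_rng(seed)
    module = [f"MG{i:04d}" for i in range(net.n_module_genes)]
    background = [f"BG{i:04d}" for i in range(net.n_background_genes)]
    graph = nx.Graph()
    graph.add_nodes_from(module + background)
    nodes = module + background
    in_module = np.array([n.startswith("MG") for n in nodes])
    m_lo, m_hi = net.module_score_range
    b_lo, b_hi = net.background_score_range
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            both = in_module[i] and in_module[j]
            p = net.p_in if both else net.p_out
            if rng.random() < p:
                lo, hi = (m_lo, m_hi) if both else (b_lo, b_hi)
                graph.add_edge(nodes[i], nodes[j], combined_score=float(rng.integers(lo, hi + 1)))
    return graph, SyntheticTruth(module_genes=set(module))


def simulate_gene_models(gene_ids) -> list[GeneModel]:
    """Deterministic genomic layout: genes cycled over chromosomes 1-22."""
    genes = []
    per_chrom: dict[str, int] = {}
    for i, gid in enumerate(sorted(gene_ids)):
        chrom = CHROMOSOMES[i % len(CHROMOSOMES)]
        idx = per_chrom.get(chrom, 0)
        per_chrom[chrom] = idx + 1
        start = 1 + idx * GENE_SPACING
        genes.append(GeneModel(gid, chrom, start, start + GENE_LENGTH - 1, "+" if i % 2 == 0 else "-"))
    return genes


# ---------------------------------------------------------------------------
# Genotypes and phenotypes
# ---------------------------------------------------------------------------

def _rank_classes(liability: np.ndarray, class_counts: tuple[int, int, int]) -> np.ndarray:
    """Assign high/intermediate/low by liability rank with exact counts."""
    n_high, n_int, _ = class_counts
    order = np.argsort(-liability, kind="mergesort")
    cls = np.empty(liability.size, dtype=object)
    cls[order[:n_high]] = "high"
    cls[order[n_high : n_high + n_int]] = "intermediate"
    cls[order[n_high + n_int :]] = "low"
    return cls


_GRADE_FOR_CLASS = {"high": (3, 4), "intermediate": (2, 2), "low": (0, 1)}


def _classes_to_grades(cls: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    lo = np.array([_GRADE_FOR_CLASS[c][0] for c in cls])
    hi = np.array([_GRADE_FOR_CLASS[c][1] for c in cls])
    return lo + (rng.random(cls.size) < 0.5) * (hi - lo)


def simulate_genotypes_phenotypes(
    config: SimulationConfig,
    truth: SyntheticTruth,
    seed: int | None = None,
    gene_models: list[GeneModel] | None = None,
    vcf_path: str | Path | None = None,
):
    """Hardy-Weinberg genotypes plus liability-threshold phenotypes.

    Causal variants are placed inside distinct planted-module genes; their
    ids, genes, and per-allele log odds ratios are recorded on ``truth``.
    Returns ``(GenotypeMatrix, PhenotypeTable, variant_table)`` and writes a
    VCF when ``vcf_path`` is given.
    """
    rng = np.random.default_rng(seed)
    n, m = config.n_samples, config.n_variants
    if gene_models is None:
        gene_models = simulate_gene_models(sorted(truth.module_genes))
    by_id = {g.gene_id: g for g in gene_models}
    module_with_models = sorted(set(truth.module_genes) & set(by_id))
    if len(module_with_models) < config.n_causal:
        raise ValueError("not enough planted-module genes with coordinates for causal variants")
    causal_genes = rng.choice(module_with_models, size=config.n_causal, replace=False)

    chrom = np.empty(m, dtype=object)
    pos = np.empty(m, dtype=np.int64)
    max_pos = max((g.end for g in gene_models), default=GENE_SPACING) + GENE_SPACING
    genic = rng.random(m) < config.fraction_genic
    host = rng.choice(len(gene_models), size=m)
    for j in range(m):
        if j < config.n_causal:
            g = by_id[causal_genes[j]]
            chrom[j], pos[j] = g.chrom, (g.start + g.end) // 2 + j  # distinct positions
        elif genic[j]:
            g = gene_models[host[j]]
            chrom[j], pos[j] = g.chrom, int(rng.integers(g.start, g.end + 1))
        else:
            chrom[j] = CHROMOSOMES[int(rng.integers(len(CHROMOSOMES)))]
            pos[j] = int(rng.integers(1, max_pos))
    variant_ids = [f"var{j:05d}" for j in range(m)]

    maf = rng.uniform(*config.maf_range, size=m)
    maf[: config.n_causal] = rng.uniform(*config.causal_maf_range, size=config.n_causal)
    dosages = rng.binomial(2, maf[None, :], size=(n, m)).astype(float)

    log_or = np.log(config.causal_odds_ratio)
    truth.causal_variants = {variant_ids[j]: (str(causal_genes[j]), float(log_or)) for j in range(config.n_causal)}
    genetic = dosages[:, : config.n_causal] @ np.full(config.n_causal, log_or)
    liability = genetic + rng.logistic(0.0, config.liability_noise_scale, size=n)

    cls_max = _rank_classes(liability, config.class_counts)
    grade_max = _classes_to_grades(cls_max, rng)
    component = {}
    pheno_liab = {}
    for name in ("neutropenia", "leukopenia", "thrombocytopenia"):
        liab_k = liability + rng.normal(0.0, config.phenotype_noise_sd, size=n)
        g_k = _classes_to_grades(_rank_classes(liab_k, config.class_counts), rng)
        component[name] = np.minimum(g_k, grade_max)
        pheno_liab[name] = liab_k
    # force max(component grades) == maximal grade
    names = list(component)
    liab_stack = np.column_stack([pheno_liab[k] for k in names])
    top = np.argmax(liab_stack, axis=1)
    for i in range(n):
        component[names[top[i]]][i] = grade_max[i]

    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan

    samples = [f"S{i:03d}" for i in range(n)]
    gm = GenotypeMatrix(samples, variant_ids, dosages)
    pheno = PhenotypeTable(
        pd.DataFrame(
            {
                "sample_id": samples,
                "grade_neutropenia": component["neutropenia"].astype(int),
                "grade_leukopenia": component["leukopenia"].astype(int),
                "grade_thrombocytopenia": component["thrombocytopenia"].astype(int),
                "grade_maximal": grade_max.astype(int),
            }
        )
    )
    vtable = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chrom": chrom,
            "pos": pos,
            "maf": maf,
            "causal": [v in truth.causal_variants for v in variant_ids],
        }
    )
    if vcf_path is not None:
        depths = rng.poisson(34, size=(n, m)) + 5
        write_vcf(vcf_path, gm, vtable, depths)
    return gm, pheno, vtable


def write_vcf(path: str | Path, gm: GenotypeMatrix, vtable: pd.DataFrame, depths: np.ndarray | None = None) -> None:
    """Write dosages as a minimal VCF 4.2 with GT (and DP when given)."""
    order = np.lexsort((vtable["pos"].to_numpy(), vtable["chrom"].astype(str).to_numpy()))
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if depths is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for c in sorted(set(vtable["chrom"].astype(str)), key=lambda x: (len(x), x)):
            sub = vtable[vtable["chrom"].astype(str) == c]
            fh.write(f"##contig=<ID={c},length={int(sub['pos'].max()) + GENE_SPACING}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples) + "\n")
        fmt = "GT:DP" if depths is not None else "GT"
        for j in order:
            row = vtable.iloc[j]
            jj = gm.variant_ids.index(row["variant_id"])
            cells = []
            for i in range(len(gm.samples)):
                d = gm.dosages[i, jj]
                gt = "./." if np.isnan(d) else gt_map[d]
                cells.append(f"{gt}:{int(depths[i, jj])}" if depths is not None else gt)
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['variant_id']}\tA\tG\t.\tPASS\t.\t{fmt}\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(config: SimulationConfig, truth: SyntheticTruth, seed: int | None = None):
    """Negative-binomial counts for 3 cell lines x {untreated, drugA, drugB} x replicates.

    drugA shifts the affected module genes in the first cell line, drugB in
    the last (line-specific treatment effects).  Returns ``(counts, lengths)``
    with genes as rows.
    """
    rng = np.random.default_rng(seed)
    expr = config.expression
    genes = sorted(truth.module_genes | set(f"BG{i:04d}" for i in range(config.network.n_background_genes)))
    n_genes = len(genes)
    lines = [f"CL{i + 1}" for i in range(expr.n_cell_lines)]
    conditions = ["untreated", "drugA", "drugB"]
    columns = [f"{ln}_{cond}_r{r + 1}" for ln in lines for cond in conditions for r in range(expr.n_replicates)]

    base = rng.lognormal(mean=4.0, sigma=1.0, size=n_genes)
    silent = rng.random(n_genes) < 0.2
    base[silent] = 0.05
    module_expressed = [g for g, s in zip(genes, silent) if g in truth.module_genes and not s]
    n_aff = min(expr.n_affected_module_genes, len(module_expressed))
    affected = rng.choice(module_expressed, size=n_aff, replace=False)
    truth.affected_genes = {"drugA": set(affected), "drugB": set(affected)}
    drug_line = {"drugA": lines[0], "drugB": lines[-1]}
    aff_idx = np.isin(genes, affected)

    fc = 2.0 ** expr.treatment_log2fc
    counts = np.zeros((n_genes, len(columns)), dtype=np.int64)
    for ci, col in enumerate(columns):
        ln, cond, _ = col.split("_")
        mean = base.copy()
        if cond in drug_line and ln == drug_line[cond] and expr.treatment_log2fc != 0:
            mean[aff_idx] = mean[aff_idx] * fc
        if expr.nb_dispersion > 0:
            r = 1.0 / expr.nb_dispersion
            counts[:, ci] = rng.negative_binomial(r, r / (r + mean))
        else:
            counts[:, ci] = rng.poisson(mean)
    lengths = pd.Series(rng.integers(500, 5001, size=n_genes), index=genes, name="length")
    return pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=columns), lengths


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

def write_dataset(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate every input the pipeline consumes and write it to ``outdir``.

    One RNG stream per generator, all spawned from ``config.rng_seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    s_net, s_geno, s_expr = np.random.SeedSequence(config.rng_seed).spawn(3)

    graph, truth = simulate_network(config, seed=s_net)
    gene_models = simulate_gene_models(graph.nodes)
    gm, pheno, vtable = simulate_genotypes_phenotypes(
        config, truth, seed=s_geno, gene_models=gene_models, vcf_path=outdir / "genotypes.vcf"
    )
    counts, lengths = simulate_expression(config, truth, seed=s_expr)

    paths = {
        "vcf": outdir / "genotypes.vcf",
        "phenotypes": outdir / "phenotypes.tsv",
        "network": outdir / "network.tsv",
        "gene_models": outdir / "genes.gff3",
        "expression": outdir / "expression_counts.tsv",
        "truth_causal": outdir / "truth_causal.tsv",
        "truth_module": outdir / "truth_module_genes.txt",
        "variants": outdir / "variants.tsv",
    }
    pheno.table.to_csv(paths["phenotypes"], sep="\t", index=False)
    with open(paths["network"], "w") as fh:
        fh.write("geneA\tgeneB\tcombined_score\n")
        for u, v, d in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{int(d['combined_score'])}\n")
    with open(paths["gene_models"], "w") as fh:
        fh.write("##gff-version 3\n")
        for g in gene_models:
            fh.write(
                f"{g.chrom}\ttoxmod\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID=gene:{g.gene_id};gene_id={g.gene_id};biotype=protein_coding\n"
            )
    expr_out = counts.copy()
    expr_out.insert(0, "length", lengths)
    expr_out.to_csv(paths["expression"], sep="\t")
    pd.DataFrame(
        [{"variant_id": v, "gene_id": g, "log_odds_ratio": b} for v, (g, b) in truth.causal_variants.items()]
    ).to_csv(paths["truth_causal"], sep="\t", index=False)
    with open(paths["truth_module"], "w") as fh:
        fh.writelines(f"{g}\n" for g in sorted(truth.module_genes))
    vtable.to_csv(paths["variants"], sep="\t", index=False)
    return paths
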