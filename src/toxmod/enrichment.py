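"""Overlap enrichment, p-value combination, TPM, and expression permutation."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    name: str
    overlap: int
    odds_ratio: float
    p_value: float
    p_adjusted: float
    adjust_method: str
    universe_size: int
    set_size: int = 0
    module_size: int = 0


def _table_or(a: int, b: int, c: int, d: int) -> float:
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)


def overlap_fisher(module_genes: Iterable[str], target_set: Iterable[str], universe: Iterable[str], name: str = "") -> EnrichmentResult:
    """Two-sided Fisher exact test of module/target overlap in a universe."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    module = set(module_genes) & universe
    target = set(target_set) & universe
    a = len(module & target)
    b = len(module - target)
    c = len(target - module)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(name, a, _table_or(a, b, c, d), float(p), float(p), "none", len(universe), len(target), len(module))


def fisher_method(p_values: Sequence[float]) -> float:
    """Fisher's method: X = -2 sum(ln p) ~ chi-square with 2k df."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(x, 2 * p.size))


def bonferroni(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m={m} is smaller than the number of p-values ({p.size})")
    return np.minimum(1.0, m * p)


def tpm(counts: pd.DataFrame, lengths: Sequence[float]) -> pd.DataFrame:
    """Transcripts per million from a genes x samples count matrix.

    ``lengths`` are gene lengths in bp, aligned with the count rows.  Each
    sample's TPM column sums to 1e6 (all-zero samples stay zero, warned).
    """
    lengths = np.asarray(lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.to_numpy(dtype=float) / lengths[:, None]
    totals = rate.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.warning("%d sample(s) have zero counts; TPM left at 0", int(zero.sum()))
        totals[zero] = 1.0
    out = 1e6 * rate / totals
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def expressed_set(tpm_matrix: pd.DataFrame, threshold: float = 1.0, min_samples: int = 2) -> set[str]:
    """Genes with TPM strictly above ``threshold`` in >= ``min_samples`` samples."""
    above = (tpm_matrix > threshold).sum(axis=1)
    return set(tpm_matrix.index[above >= min_samples])


def expression_permutation(
    module_genes: Iterable[str],
    background_genes: Sequence[str],
    expressed: set[str],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Permutation test: are more module genes expressed than chance?

    Draws ``|module|`` genes from the background without replacement
    ``n_perm`` times and counts how many fall in the expressed set.  The
    empirical p uses the +1 correction and so never returns 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    background = list(dict.fromkeys(background_genes))
    module = set(module_genes)
    if len(background) < len(module):
        raise ValueError("background smaller than module")
    outside = module - set(background)
    if outside:
        logger.info("dropping %d module gene(s) absent from background", len(outside))
        module -= outside
    observed = len(module & expressed)
    rng = np.random.default_rng(seed)
    bg = np.array(background)
    is_expr = np.isin(bg, list(expressed))
    counts = np.empty(n_perm, dtype=np.int64)
    m = len(module)
    for i in range(n_perm):
        idx = rng.choice(bg.size, size=m, replace=False)
        counts[i] = int(is_expr[idx].sum())
    p = (1 + int(np.sum(counts >= observed))) / (n_perm + 1)
    return {
        "observed": observed,
        "mean_permuted": float(counts.mean()),
        "sd_permuted": float(counts.std(ddof=1)) if n_perm > 1 else 0.0,
        "p_value": p,
        "n_perm": n_perm,
        "module_size": m,
        "background_size": len(background),
    }


def ora(
    gene_set_collection: Mapping[str, Sequence[str]],
    module_genes: Iterable[str],
    universe: Iterable[str],
    fdr_method: str = "BH",
) -> list[EnrichmentResult]:
    """One-sided over-representation of the module in each gene set.

    Uses the hypergeometric upper tail per set and BH (or Bonferroni)
    adjustment across sets; results sorted by adjusted p then name.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    module = set(module_genes) & universe
    names, raw = [], []
    partial: list[EnrichmentResult] = []
    for name, genes in gene_set_collection.items():
        target = set(genes) & universe
        a = len(module & target)
        b = len(module - target)
        c = len(target - module)
        d = len(universe) - a - b - c
        p = float(stats.hypergeom.sf(a - 1, len(universe), len(target), len(module)))
        names.append(name)
        raw.append(min(p, 1.0))
        partial.append(EnrichmentResult(name, a, _table_or(a, b, c, d), raw[-1], 1.0, fdr_method, len(universe), len(target), len(module)))
    if not partial:
        return []
    method = {"BH": "fdr_bh", "bonferroni": "bonferroni"}.get(fdr_method)
    if method is None:
        raise ValueError(f"unknown fdr_method: {fdr_method!r}")
    _, adj, _, _ = multipletests(raw, method=method)
    for r, q in zip(partial, adj):
        r.p_adjusted = float(q)
    partial.sort(key=lambda r: (r.p_adjusted, r.p_value, r.name))
    return partial
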