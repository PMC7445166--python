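import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from toxmod.enrichment import tpm
from toxmod.io_formats import read_gene_models, read_network, read_vcf
from toxmod.synthetic import (
    NetworkConfig,
    SimulationConfig,
    SyntheticTruth,
    simulate_expression,
    simulate_gene_models,
    simulate_genotypes_phenotypes,
    simulate_network,
    write_dataset,
)


def _truth(n=10):
    return SyntheticTruth(module_genes={f"MG{i:04d}" for i in range(n)})


class TestConfigValidation:
    def test_bad_maf(self):
        with pytest.raises(ValueError):
            SimulationConfig(maf_range=(0.0, 0.5))

    def test_p_in_le_p_out(self):
        with pytest.raises(ValueError):
            SimulationConfig(network=NetworkConfig(p_in=0.01, p_out=0.02))

    def test_causal_exceeds_variants(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_variants=3, n_causal=4)

    def test_class_counts_must_sum(self):
        with pytest.raises(ValueError, match="class_counts"):
            SimulationConfig(n_samples=90)


class TestSimulateNetwork:
    def test_p_in_one_gives_clique(self):
        cfg = SimulationConfig(network=NetworkConfig(n_module_genes=5, n_background_genes=3, p_in=1.0, p_out=0.0))
        g, truth = simulate_network(cfg, seed=0)
        module = sorted(truth.module_genes)
        for a, b in itertools.combinations(module, 2):
            assert g.has_edge(a, b)

    def test_p_out_zero_no_cross_edges(self):
        cfg = SimulationConfig(network=NetworkConfig(n_module_genes=5, n_background_genes=20, p_in=0.5, p_out=0.0))
        g, truth = simulate_network(cfg, seed=1)
        for a, b in g.edges:
            assert a in truth.module_genes and b in truth.module_genes

    def test_determinism(self):
        cfg = SimulationConfig()
        g1, _ = simulate_network(cfg, seed=9)
        g2, _ = simulate_network(cfg, seed=9)
        assert set(g1.edges) == set(g2.edges)

    def test_module_too_small(self):
        cfg = SimulationConfig(network=NetworkConfig(n_module_genes=3, n_background_genes=5))
        cfg.network.n_module_genes = 2  # bypass dataclass check to hit the operation's own guard
        with pytest.raises(ValueError):
            simulate_network(cfg, seed=0)

    def test_score_ranges(self):
        cfg = SimulationConfig(network=NetworkConfig(n_module_genes=10, n_background_genes=30, p_in=0.9, p_out=0.1))
        g, truth = simulate_network(cfg, seed=2)
        for a, b, d in g.edges(data=True):
            if a in truth.module_genes and b in truth.module_genes:
                assert 701 <= d["combined_score"] <= 999
            else:
                assert 150 <= d["combined_score"] <= 999


class TestGenotypesPhenotypes:
    def test_class_counts_enforced(self):
        cfg = SimulationConfig(n_variants=50, rng_seed=1)
        _, pheno, _ = simulate_genotypes_phenotypes(cfg, _truth(), seed=1)
        assert pheno.class_counts("maximal") == {"high": 54, "intermediate": 8, "low": 34}

    def test_maximal_is_max_of_components(self):
        cfg = SimulationConfig(n_variants=50)
        _, pheno, _ = simulate_genotypes_phenotypes(cfg, _truth(), seed=3)
        comps = np.vstack([pheno.grades(p) for p in ("neutropenia", "leukopenia", "thrombocytopenia")])
        np.testing.assert_array_equal(comps.max(axis=0), pheno.grades("maximal"))

    def test_maf_law_of_large_numbers(self):
        cfg = SimulationConfig(
            n_samples=10_000,
            class_counts=(5000, 1000, 4000),
            n_variants=10,
            maf_range=(0.3, 0.3 + 1e-9),
            causal_maf_range=(0.3, 0.3 + 1e-9),
        )
        gm, _, _ = simulate_genotypes_phenotypes(cfg, _truth(), seed=4)
        freqs = np.nanmean(gm.dosages, axis=0) / 2
        assert np.all(np.abs(freqs - 0.3) <= 0.01)

    def test_null_model_auc(self):
        # causal_odds_ratio = 1: genotype score is uninformative
        from toxmod.prediction import roc_auc

        cfg = SimulationConfig(n_variants=20, causal_odds_ratio=1.0)
        aucs = []
        for rep in range(200):
            gm, pheno, _ = simulate_genotypes_phenotypes(cfg, _truth(), seed=rep)
            cls = pheno.classes("maximal")
            keep = cls != "intermediate"
            score = gm.dosages[:, :5].sum(axis=1)
            auc, _ = roc_auc(score[keep], (cls[keep] == "high").astype(int))
            aucs.append(auc)
        assert abs(np.mean(aucs) - 0.5) <= 0.05

    def test_causal_variants_in_module_genes(self):
        cfg = SimulationConfig(n_variants=40)
        truth = _truth()
        models = simulate_gene_models(truth.module_genes | {f"BG{i:04d}" for i in range(20)})
        gm, _, vtable = simulate_genotypes_phenotypes(cfg, truth, seed=5, gene_models=models)
        by_id = {g.gene_id: g for g in models}
        assert len(truth.causal_variants) == cfg.n_causal
        genes = [g for g, _ in truth.causal_variants.values()]
        assert len(set(genes)) == cfg.n_causal  # distinct genes
        for vid, (gene, _) in truth.causal_variants.items():
            row = vtable.set_index("variant_id").loc[vid]
            g = by_id[gene]
            assert g.chrom == row["chrom"] and g.start <= row["pos"] <= g.end

    def test_causal_dosage_contrast(self):
        # mean dosage difference (high vs low) larger at causal than >= 95% of null
        cfg = SimulationConfig(n_variants=200, causal_odds_ratio=3.0)
        fracs = []
        for rep in range(200):
            gm, pheno, vtable = simulate_genotypes_phenotypes(cfg, _truth(), seed=1000 + rep)
            cls = pheno.classes("maximal")
            diff = np.abs(
                np.nanmean(gm.dosages[cls == "high"], axis=0) - np.nanmean(gm.dosages[cls == "low"], axis=0)
            )
            causal = vtable["causal"].to_numpy()
            fracs.append(np.mean(diff[~causal] < diff[causal].mean()))
        assert np.mean(fracs) >= 0.95

    def test_no_column_order_dependence(self):
        # null-column allele frequencies are unrelated to column position
        cfg = SimulationConfig(n_variants=2000, rng_seed=0)
        gm, _, vtable = simulate_genotypes_phenotypes(cfg, _truth(), seed=6)
        null = ~vtable["causal"].to_numpy()
        freqs = np.nanmean(gm.dosages[:, null], axis=0)
        idx = np.arange(null.sum())
        r = np.corrcoef(idx, freqs)[0, 1]
        assert abs(r) < 0.05

    def test_determinism(self):
        cfg = SimulationConfig(n_variants=30)
        a = simulate_genotypes_phenotypes(cfg, _truth(), seed=7)
        b = simulate_genotypes_phenotypes(cfg, _truth(), seed=7)
        np.testing.assert_array_equal(a[0].dosages, b[0].dosages)
        pd.testing.assert_frame_equal(a[1].table, b[1].table)


class TestSimulateExpression:
    def test_no_effect_when_log2fc_zero(self):
        cfg = SimulationConfig()
        cfg.expression.treatment_log2fc = 0.0
        cfg.expression.nb_dispersion = 0.01
        truth = _truth(30)
        counts, _ = simulate_expression(cfg, truth, seed=8)
        treated = counts.filter(like="drugA").mean(axis=1)
        untreated = counts.filter(like="untreated").mean(axis=1)
        expressed = untreated > 20
        ratio = (treated[expressed] + 1) / (untreated[expressed] + 1)
        assert np.abs(np.log2(ratio)).mean() < 0.3

    def test_tpm_proportional_with_constant_lengths(self):
        cfg = SimulationConfig()
        truth = _truth(20)
        counts, _ = simulate_expression(cfg, truth, seed=9)
        const_len = np.full(len(counts), 1000)
        mat = tpm(counts, const_len)
        col = counts.columns[0]
        expected = 1e6 * counts[col] / counts[col].sum()
        np.testing.assert_allclose(mat[col], expected, rtol=1e-9)

    def test_determinism(self):
        cfg = SimulationConfig()
        t1, t2 = _truth(20), _truth(20)
        c1, l1 = simulate_expression(cfg, t1, seed=10)
        c2, l2 = simulate_expression(cfg, t2, seed=10)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_series_equal(l1, l2)

    def test_layout(self):
        cfg = SimulationConfig()
        counts, lengths = simulate_expression(cfg, _truth(20), seed=11)
        assert counts.shape[1] == 18  # 3 lines x 3 conditions x 2 reps
        assert (lengths > 0).all()

    def test_affected_genes_shift(self):
        cfg = SimulationConfig()
        truth = _truth(30)
        counts, _ = simulate_expression(cfg, truth, seed=12)
        affected = sorted(truth.affected_genes["drugA"])
        treated = counts.loc[affected].filter(like="CL1_drugA").mean(axis=1)
        untreated = counts.loc[affected].filter(like="CL1_untreated").mean(axis=1)
        assert (treated > untreated).mean() > 0.8


class TestWriteDataset:
    def test_outputs_readable_and_consistent(self, tmp_path, small_config):
        paths = write_dataset(small_config, tmp_path / "ds")
        records, samples = read_vcf(paths["vcf"])
        assert len(samples) == 96
        assert len(records) == small_config.n_variants
        graph = read_network(paths["network"])
        genes = read_gene_models(paths["gene_models"], "GFF3")
        assert set(g.gene_id for g in genes) >= set(graph.nodes)
        truth = pd.read_csv(paths["truth_causal"], sep="\t")
        assert len(truth) == small_config.n_causal
        expr = pd.read_csv(paths["expression"], sep="\t", index_col=0)
        assert "length" in expr.columns

    def test_regenerate_identical(self, tmp_path, small_config):
        p1 = write_dataset(small_config, tmp_path / "a")
        p2 = write_dataset(small_config, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()
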