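"""End-to-end orchestration: genotypes + grades -> toxicity module -> model.

Two modes:

* ``main`` — association on all samples; module overlap >= 2 phenotypes;
  MCODE vertex weight percentage 0.5.  The train/validation split only
  affects model fitting and evaluation.
* ``validation`` — split first; association (and everything downstream)
  uses training samples only; overlap requires all 3 phenotypes; VWP 0.1.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, association as assoc, io_formats as io, network as netmod, prediction as pred

logger = logging.getLogger(__name__)

PHENOTYPES = ("neutropenia", "leukopenia", "thrombocytopenia")

MODE_DEFAULTS = {
    "main": {"min_overlap": 2, "vwp": 0.5, "split_first": False},
    "validation": {"min_overlap": 3, "vwp": 0.1, "split_first": True},
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    vcf: str = ""
    phenotypes: str = ""
    network: str = ""
    gene_models: str = ""
    gene_models_format: str = "GFF3"
    outdir: str = "results"
    mode: str = "main"
    alpha: float = 1e-3
    min_score: int = 700
    vwp: float | None = None            # None -> mode default
    min_overlap: int | None = None
    enrich_alpha: float = 0.05
    max_gene_distance: int = 3_000_000
    promoter_window: tuple[int, int] = (-3000, 3000)
    validation_fraction: float = 0.2
    n_perm: int = 100_000
    penalty_sd: float = 0.25
    cv_folds: int = 10
    n_lambda: int = 100
    quantiles: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9)
    seed: int = 0
    apply_qc: bool = True
    include_sex_chromosomes: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODE_DEFAULTS:
            raise ValueError(f"mode must be one of {sorted(MODE_DEFAULTS)}, got {self.mode!r}")
        d = MODE_DEFAULTS[self.mode]
        if self.vwp is None:
            self.vwp = d["vwp"]
        if self.min_overlap is None:
            self.min_overlap = d["min_overlap"]

    @property
    def split_first(self) -> bool:
        return MODE_DEFAULTS[self.mode]["split_first"]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    outdir: Path
    manifest: dict
    toxicity_module: netmod.ToxicityModule | None = None
    evaluation: dict | None = None
    files: dict[str, Path] = field(default_factory=dict)


def _stage(manifest: dict, name: str, **counts) -> None:
    manifest["stages"].append({"stage": name, **counts})
    logger.info("stage %-12s %s", name, " ".join(f"{k}={v}" for k, v in counts.items()))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": [],
    }
    result = PipelineResult(outdir, manifest)
    stage = "load"
    try:
        pheno = assoc.PhenotypeTable.read(config.phenotypes)
        records, samples = io.read_vcf(config.vcf, sample_subset=pheno.samples)
        if config.apply_qc:
            records = io.qc_filter_variants(records)
        gm = io.GenotypeMatrix.from_records(records, samples)
        # align phenotype rows with VCF sample order
        pheno = assoc.PhenotypeTable(
            pheno.table.set_index("sample_id").loc[samples].reset_index()
        )
        _stage(manifest, stage, samples=len(samples), variants=len(records))

        stage = "split"
        split = pred.stratified_split(pheno, config.validation_fraction, seed=config.seed)
        train_mask = np.isin(samples, split.training_samples)
        assoc_mask = train_mask if config.split_first else np.ones(len(samples), bool)
        _stage(
            manifest,
            stage,
            train=len(split.training_samples),
            validation=len(split.validation_samples),
            prediction_only=len(split.prediction_only),
        )

        stage = "associate"
        gene_models = io.read_gene_models(config.gene_models, config.gene_models_format)
        nominal_by_pheno: dict[str, list[assoc.AssociationResult]] = {}
        assoc_samples = [s for s, keep in zip(samples, assoc_mask) if keep]
        manifest["association_samples"] = assoc_samples
        for ph in PHENOTYPES:
            cc = pheno.case_control(ph)[assoc_mask]
            sub = gm.dosages[assoc_mask]
            results = assoc.associate_all(sub, gm.variant_ids, cc, phenotype=ph)
            nominal = assoc.filter_nominal(results, config.alpha)
            nominal_by_pheno[ph] = nominal
            frame = assoc.results_to_frame(results)
            frame["nominal"] = frame["p_value"] <= config.alpha
            io.write_table(frame, outdir / f"association_{ph}.tsv")
            _stage(manifest, f"associate:{ph}", tested=len(results), nominal=len(nominal))

        stage = "map-genes"
        rec_by_id = {r.variant_id: r for r in records}
        seeds_by_pheno: dict[str, set[str]] = {}
        variant_gene: dict[str, str] = {}
        for ph in PHENOTYPES:
            variants = [rec_by_id[r.variant_id] for r in nominal_by_pheno[ph]]
            mapping = assoc.map_variants_to_genes(
                variants, gene_models, config.max_gene_distance, autosomal_only=not config.include_sex_chromosomes
            )
            io.write_table(mapping, outdir / f"seed_genes_{ph}.tsv")
            seeds_by_pheno[ph] = set(mapping["gene_id"])
            variant_gene.update(dict(zip(mapping["variant_id"], mapping["gene_id"])))
            _stage(manifest, f"map-genes:{ph}", variants=len(mapping), genes=len(seeds_by_pheno[ph]))

        stage = "module"
        graph = io.read_network(config.network, config.min_score)
        weights = netmod.mcode_vertex_weights(graph)
        complexes = netmod.mcode_find_complexes(graph, weights, vwp=config.vwp)
        modules: dict[str, set[str]] = {}
        for ph in PHENOTYPES:
            mod = netmod.seed_module(graph, complexes, seeds_by_pheno[ph], config.enrich_alpha)
            modules[ph] = mod.genes
            io.write_table(
                pd.DataFrame(
                    {
                        "gene_id": sorted(mod.genes),
                        "is_seed": [g in mod.seeds_contained for g in sorted(mod.genes)],
                    }
                ),
                outdir / f"module_{ph}.tsv",
            )
            _stage(manifest, f"module:{ph}", genes=len(mod.genes), seeds=len(mod.seeds_contained))

        stage = "overlap"
        tox = netmod.toxicity_overlap(modules, config.min_overlap, variant_gene_map=variant_gene)
        result.toxicity_module = tox
        rows = []
        for g in sorted(tox.genes):
            memb = tox.membership[g]
            rows.append(
                {
                    "gene_id": g,
                    **{f"in_{p}": m for p, m in zip(tox.phenotypes, memb)},
                    "member_variants": ",".join(tox.member_variants.get(g, [])),
                }
            )
        io.write_table(pd.DataFrame(rows), outdir / "toxicity_module.tsv")
        _stage(manifest, stage, genes=len(tox.genes))

        stage = "select"
        candidates = sorted(v for v, g in variant_gene.items() if g in tox.genes)
        _stage(manifest, "candidates", variants=len(candidates))
        if not candidates:
            logger.warning("no candidate variants map to the toxicity module; stopping before selection")
            manifest["model"] = None
            _write_manifest(outdir, manifest)
            return result
        dosage_df = pd.DataFrame(gm.dosages, index=samples, columns=gm.variant_ids)[candidates]
        classes = pheno.classes("maximal")
        X_all = pred.impute_mode(dosage_df)
        y_all = pd.Series((classes == assoc.HIGH).astype(float), index=samples)
        X_train = X_all.loc[split.training_samples]
        y_train = y_all.loc[split.training_samples].to_numpy()
        X_test = X_all.loc[split.validation_samples]
        y_test = y_all.loc[split.validation_samples].to_numpy()

        freq = pred.random_lasso_frequencies(
            X_train,
            y_train,
            n_perm=config.n_perm,
            cv_folds=config.cv_folds,
            n_lambda=config.n_lambda,
            penalty_sd=config.penalty_sd,
            seed=config.seed,
        )
        io.write_table(freq.to_frame(), outdir / "selection_frequencies.tsv")
        _stage(manifest, stage, n_perm=config.n_perm, variants=len(candidates))

        stage = "evaluate"
        sets = pred.quantile_sets(freq, config.quantiles)
        evaluation = pred.evaluate_quantile_sets(
            sets, X_train, y_train, X_test if len(X_test) else None, y_test if len(X_test) else None,
            seed=config.seed, cv_folds=config.cv_folds, n_lambda=config.n_lambda,
        )
        result.evaluation = evaluation
        io.write_table(evaluation["table"], outdir / "quantile_aucs.tsv")
        model = evaluation["chosen_model"]
        io.write_table(model.to_frame(), outdir / "model_coefficients.tsv")

        probs = pred.predict_probability(model, X_all)
        split_label = np.where(
            np.isin(samples, split.training_samples), "training",
            np.where(np.isin(samples, split.validation_samples), "validation", "prediction_only"),
        )
        pred_frame = pd.DataFrame(
            {
                "sample_id": samples,
                "class": classes,
                "split": split_label,
                "probability": np.round(probs, 10),
            }
        )
        io.write_table(pred_frame, outdir / "predictions.tsv")
        tr_mask = np.isin(samples, split.training_samples)
        train_auc, roc_train = pred.roc_auc(probs[tr_mask], y_all.to_numpy()[tr_mask])
        io.write_table(roc_train, outdir / "roc_training.tsv")
        aucs = {"training": train_auc}
        if len(X_test):
            va_mask = np.isin(samples, split.validation_samples)
            test_auc, roc_test = pred.roc_auc(probs[va_mask], y_all.to_numpy()[va_mask])
            io.write_table(roc_test, outdir / "roc_validation.tsv")
            aucs["validation"] = test_auc
        manifest["model"] = {
            "chosen_quantile": evaluation["chosen_quantile"],
            "n_variants": len(model.variant_ids),
            "auc": aucs,
        }
        _stage(manifest, stage, chosen_quantile=evaluation["chosen_quantile"], **{f"auc_{k}": round(v, 4) for k, v in aucs.items()})
    except PipelineError:
        raise
    except Exception as exc:
        _write_manifest(outdir, manifest)
        raise PipelineError(stage, exc) from exc

    _write_manifest(outdir, manifest)
    result.files = {p.stem: p for p in outdir.glob("*.tsv")}
    return result


def _write_manifest(outdir: Path, manifest: dict) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def report(result_dir: str | Path) -> Path:
    """Summarise a finished (or partial) run: text summary + figures."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    result_dir = Path(result_dir)
    lines = []
    manifest_path = result_dir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        for st in manifest.get("stages", []):
            stage_name = st.get("stage", "?")
            extras = {k: v for k, v in st.items() if k != "stage"}
            lines.append(f"{stage_name}: " + ", ".join(f"{k}={v}" for k, v in extras.items()))
    else:
        lines.append("no manifest found; partial report")

    tox_path = result_dir / "toxicity_module.tsv"
    if tox_path.exists():
        tox = pd.read_csv(tox_path, sep="\t")
        lines.append(f"toxicity module: {len(tox)} genes" if len(tox) else "toxicity module is EMPTY")

    freq_path = result_dir / "selection_frequencies.tsv"
    if freq_path.exists():
        freq = pd.read_csv(freq_path, sep="\t")
        fig, ax = plt.subplots()
        ax.hist(freq["frequency"], bins=30)
        ax.set_xlabel("selection frequency")
        ax.set_ylabel("variants")
        fig.savefig(result_dir / "frequency_hist.png", dpi=120)
        plt.close(fig)

    pred_path = result_dir / "predictions.tsv"
    if pred_path.exists():
        preds = pd.read_csv(pred_path, sep="\t")
        fig, ax = plt.subplots()
        order = ["low", "intermediate", "high"]
        for i, cls in enumerate(order):
            vals = preds.loc[preds["class"] == cls, "probability"]
            ax.scatter(np.full(len(vals), i) + np.linspace(-0.15, 0.15, max(len(vals), 1)), vals, s=12)
        ax.set_xticks(range(3), order)
        ax.set_ylabel("predicted probability of high toxicity")
        fig.savefig(result_dir / "probability_strip.png", dpi=120)
        plt.close(fig)

    for roc_name in ("roc_training", "roc_validation"):
        roc_path = result_dir / f"{roc_name}.tsv"
        if roc_path.exists():
            roc = pd.read_csv(roc_path, sep="\t")
            fig, ax = plt.subplots()
            ax.plot(roc["fpr"], roc["tpr"], drawstyle="steps-post")
            ax.plot([0, 1], [0, 1], ls="--", c="gray")
            ax.set_xlabel("false positive rate")
            ax.set_ylabel("true positive rate")
            fig.savefig(result_dir / f"{roc_name}.png", dpi=120)
            plt.close(fig)

    summary = result_dir / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    return summary
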