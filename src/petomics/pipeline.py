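"""End-to-end pipeline orchestration.

Stage order is the fixed DAG: simulate -> petfeatures -> de -> integrate ->
select -> score. Every stage persists its artifacts as TSV/CSV in the output
directory and the run report records a SHA-256 hash per file plus the
headline metrics (per-set CV AUC aggregates, the final lasso signature, the
survival hazard ratio). Stage seeds are derived from the global seed by
stable hashing of stage names, so adding a stage never perturbs the
randomness of the others.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .config import CohortConfig
from .de import consensus_intersection, paired_de
from .exceptions import DependencyError
from .integration import mfa, spearman_screen
from .scoring import cox_hr, km_estimate, median_binarize, score_and_label, split_gene_groups
from .selection import CVScheme, aggregated_lasso, evaluate_feature_sets
from .synthetic import simulate_paired_expression, simulate_patient_kinetics, simulate_tcga_like

ALL_STAGES = ("simulate", "petfeatures", "de", "integrate", "select", "score")


def stage_seed(global_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Run configuration: cohort parameters, stage toggles, analysis knobs.

    The demo defaults use a reduced CV scheme (2 seeds x 3 repeats, 100
    trees) and 20 lasso seeds so a full run stays interactive; the study-
    scale scheme (10 x 10 x 10, 500 trees, 100 lasso seeds) is a config
    change away.
    """

    seed: int = 0
    outdir: str = "petomics_run"
    stages: tuple = ALL_STAGES
    cohort: CohortConfig = field(default_factory=CohortConfig)
    de_alpha: float = 0.05
    de_lfc: float = 1.0
    rho_threshold: float = 0.6
    p_threshold: float = 0.05
    cv_seeds: int = 2
    cv_repeats: int = 3
    cv_folds: int = 10
    cv_trees: int = 100
    lasso_seeds: int = 20
    lasso_folds: int = 10
    signature_size: tuple = (16, 6)  # planted Group1/Group2 sizes for scoring

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cohort = CohortConfig.from_dict(data.pop("cohort", {}))
        sig = data.pop("signature_size", (16, 6))
        stages = tuple(data.pop("stages", ALL_STAGES))
        return cls(cohort=cohort, signature_size=tuple(sig), stages=stages, **data)


@dataclass
class RunReport:
    config: dict
    stage_seeds: dict
    files: dict  # filename -> sha256
    metrics: dict

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {
                "config": self.config,
                "stage_seeds": self.stage_seeds,
                "files": self.files,
                "metrics": self.metrics,
            },
            indent=2,
            sort_keys=True,
            default=str,
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, log=print) -> RunReport:
    """Execute the enabled stages in DAG order; returns the run report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    metrics: dict = {}
    seeds = {s: stage_seed(config.seed, s) for s in ALL_STAGES}
    enabled = [s for s in ALL_STAGES if s in config.stages]

    def save(name: str, writer, obj):
        path = out / name
        writer(obj, path)
        files[name] = _sha256(path)

    def need(name: str, stage: str):
        path = out / name
        if not path.exists():
            raise DependencyError(f"stage '{stage}' requires missing artifact {name}")
        return path

    cohort = config.cohort
    cohort.seed = stage_seed(config.seed, "cohort")

    if "simulate" in enabled:
        log(f"[simulate] seed={seeds['simulate']}")
        expr, annot, truth = simulate_paired_expression(cohort)
        save("expression.tsv", pio.write_expression, expr)
        save("annotation.tsv", pio.write_annotation, annot)
        pio.write_gene_list(truth.de_gene_ids, out / "truth_de_genes.txt")
        files["truth_de_genes.txt"] = _sha256(out / "truth_de_genes.txt")
        pio.write_gene_list(truth.linked_gene_ids, out / "truth_linked_genes.txt")
        files["truth_linked_genes.txt"] = _sha256(out / "truth_linked_genes.txt")
        tacs, pet, kin_truth = simulate_patient_kinetics(cohort)
        save("tacs.csv", pio.write_tacs, tacs)
        save("pet_features.csv", pio.write_pet_features, pet)
        save("pet_features_normal.csv", pio.write_pet_features, kin_truth.normal_pet)
        # TCGA-like cohort scored with a planted signature: Group2 from the
        # latent-linked genes, Group1 from the remaining DE genes
        n1, n2 = config.signature_size
        g2 = truth.linked_gene_ids[:n2]
        g1 = [g for g in truth.de_gene_ids if g not in set(g2)][:n1]
        sig = {"group1": g1, "group2": g2}
        texpr, tsurv, ttruth = simulate_tcga_like(
            cohort.survival, sig, seed=stage_seed(config.seed, "tcga")
        )
        save("tcga_expression.tsv", pio.write_expression, texpr)
        save("tcga_survival.tsv", pio.write_survival, tsurv)
        pio.write_gene_list(g1 + g2, out / "signature_genes.txt")
        files["signature_genes.txt"] = _sha256(out / "signature_genes.txt")

    if "petfeatures" in enabled:
        need("tacs.csv", "petfeatures")
        # feature table already produced during simulation from the same TACs
        need("pet_features.csv", "petfeatures")
        log("[petfeatures] feature table present")

    if "de" in enabled:
        expr = pio.read_expression(need("expression.tsv", "de"))
        annot = pio.read_annotation(need("annotation.tsv", "de"))
        log(f"[de] {expr.shape[0]} genes, {expr.shape[1]} samples")
        results = {}
        comparisons = {"total": annot}
        if "metastatic" in annot.columns and annot["metastatic"].nunique() > 1:
            comparisons["non-metastatic"] = annot[annot["metastatic"] == 0]
            comparisons["metastatic"] = annot[annot["metastatic"] == 1]
        for label, ann in comparisons.items():
            res = paired_de(expr, ann, alpha=config.de_alpha, lfc_threshold=config.de_lfc)
            results[label] = res
            save(
                f"de_{label}.tsv",
                lambda df, p: df.to_csv(p, sep="\t", index_label="gene_id"),
                res,
            )
        if len(results) >= 2:
            cons = consensus_intersection(results)
            consensus = sorted(cons.intersection)
        else:
            consensus = sorted(results["total"].index[results["total"]["significant"]])
        pio.write_gene_list(consensus, out / "consensus_genes.txt")
        files["consensus_genes.txt"] = _sha256(out / "consensus_genes.txt")
        metrics["n_consensus_genes"] = len(consensus)

    if "integrate" in enabled:
        expr = pio.read_expression(need("expression.tsv", "integrate"))
        annot = pio.read_annotation(need("annotation.tsv", "integrate"))
        pet = pio.read_pet_features(need("pet_features.csv", "integrate"))
        consensus = pio.read_gene_list(need("consensus_genes.txt", "integrate"))
        log(f"[integrate] {len(consensus)} consensus genes x {pet.shape[1]} PET variables")
        tumor_map = annot[annot["condition"] == "tumor"].set_index("patient_id")["sample_id"]
        expr_cancer = expr.loc[consensus, tumor_map.to_numpy()]
        expr_cancer.columns = tumor_map.index  # patient-indexed
        assoc = spearman_screen(
            expr_cancer, pet, rho_thr=config.rho_threshold, p_thr=config.p_threshold
        )
        save("association.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False), assoc)
        passed = sorted(assoc.loc[assoc["passes_filter"], "gene"].unique())
        pio.write_gene_list(passed, out / "pet_correlated_genes.txt")
        files["pet_correlated_genes.txt"] = _sha256(out / "pet_correlated_genes.txt")
        res = mfa({"genes": expr_cancer.T, "pet": pet})
        summary = res.summary_frame()
        summary = summary.join(res.group_contribution.T.add_prefix("contrib_"))
        save("mfa_summary.tsv", lambda df, p: df.to_csv(p, sep="\t", index_label="dimension"),
             summary)
        metrics["n_pet_correlated_genes"] = len(passed)
        metrics["mfa_dim1_percent_variance"] = float(res.percent_variance[0])
        metrics["mfa_dim1_contrib"] = {
            b: float(res.group_contribution.loc[b, "Dim1"]) for b in res.group_contribution.index
        }

    if "select" in enabled:
        expr = pio.read_expression(need("expression.tsv", "select"))
        annot = pio.read_annotation(need("annotation.tsv", "select"))
        pet = pio.read_pet_features(need("pet_features.csv", "select"))
        gene_pool = pio.read_gene_list(need("pet_correlated_genes.txt", "select"))
        if not gene_pool:
            gene_pool = pio.read_gene_list(need("consensus_genes.txt", "select"))
        pet_normal = pio.read_pet_features(need("pet_features_normal.csv", "select"))
        log(f"[select] {len(gene_pool)} genes + {pet.shape[1]} PET variables")
        # tumor samples carry the tumor-VOI PET row of their patient, normal
        # samples the reference-tissue VOI row
        ann = annot.set_index("sample_id")
        gene_X = expr.loc[gene_pool].T
        labels = np.where(ann.loc[gene_X.index, "condition"] == "tumor", "cancer", "control")
        pet_rows = []
        for s in gene_X.index:
            pid = ann.loc[s, "patient_id"]
            src = pet if ann.loc[s, "condition"] == "tumor" else pet_normal
            pet_rows.append(src.loc[pid])
        pet_X = pd.DataFrame(np.asarray(pet_rows), index=gene_X.index, columns=pet.columns)
        scheme = CVScheme(
            n_folds=config.cv_folds,
            n_repeats=config.cv_repeats,
            seeds=tuple(stage_seed(config.seed, f"cv{i}") for i in range(config.cv_seeds)),
            n_trees=config.cv_trees,
        )
        perf = evaluate_feature_sets(gene_X, pet_X, labels, scheme)
        perf_rows = []
        for name, p in perf.items():
            for metric, ag in p["aggregate"].items():
                perf_rows.append(
                    {"feature_set": name, "metric": metric, "mean": ag["mean"], "sd": ag["sd"]}
                )
        save("cv_performance.tsv",
             lambda df, p: df.to_csv(p, sep="\t", index=False), pd.DataFrame(perf_rows))
        composite = pd.concat([gene_X, pet_X], axis=1)
        sel = aggregated_lasso(
            composite,
            labels,
            n_seeds=config.lasso_seeds,
            n_folds=config.lasso_folds,
            base_seed=seeds["select"],
        )
        save("selection_frequency.tsv",
             lambda s, p: s.rename("frequency").to_csv(p, sep="\t", index_label="feature"),
             sel.frequencies)
        pio.write_gene_list(sel.final_set, out / "final_signature.txt")
        files["final_signature.txt"] = _sha256(out / "final_signature.txt")
        metrics["cv_auc"] = {k: perf[k]["aggregate"]["auc"]["mean"] for k in perf}
        metrics["final_set"] = sel.final_set

    if "score" in enabled:
        texpr = pio.read_expression(need("tcga_expression.tsv", "score"))
        tsurv = pio.read_survival(need("tcga_survival.tsv", "score"))
        sig = pio.read_gene_list(need("signature_genes.txt", "score"))
        log(f"[score] {len(sig)} signature genes, {len(tsurv)} survival samples")
        normal_cols = [c for c in texpr.columns if c.startswith("N")]
        cancer_cols = [c for c in texpr.columns if c.startswith("C")]
        split = split_gene_groups(texpr[normal_cols], sig)
        binary = median_binarize(texpr[cancer_cols], sig)
        score = score_and_label(binary, split)
        save(
            "sample_scores.tsv",
            lambda df, p: df.to_csv(p, sep="\t", index_label="sample_id"),
            score.scores.join(score.labels.add_suffix("_label")).join(
                score.combined.rename("cluster")
            ),
        )
        surv = tsurv.set_index("sample_id").loc[score.combined.index].reset_index()
        surv["stratum"] = score.labels["Group2"].to_numpy()
        km_rows = []
        for level, grp in surv.groupby("stratum"):
            km = km_estimate(grp)
            km["stratum"] = level
            km_rows.append(km)
        save("km_curves.tsv",
             lambda df, p: df.to_csv(p, sep="\t", index=False), pd.concat(km_rows))
        comp = cox_hr(surv, reference="Low")
        save(
            "survival_comparison.tsv",
            lambda df, p: df.to_csv(p, sep="\t", index=False),
            pd.DataFrame(
                [
                    {
                        "comparison": "HighGroup2_vs_LowGroup2",
                        "logrank_chi2": comp.logrank_chi2,
                        "logrank_p": comp.logrank_p,
                        "hazard_ratio": comp.hazard_ratio,
                        "ci95_low": comp.ci95_low,
                        "ci95_high": comp.ci95_high,
                    }
                ]
            ),
        )
        metrics["cox_hr_high_vs_low_group2"] = comp.hazard_ratio
        metrics["logrank_p"] = comp.logrank_p

    report = RunReport(
        config={**{k: v for k, v in asdict(config).items() if k != "cohort"},
                "cohort": config.cohort.to_dict()},
        stage_seeds=seeds,
        files=dict(sorted(files.items())),
        metrics=metrics,
    )
    report.to_json(out / "run_report.json")
    return report
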