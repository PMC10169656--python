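"""End-to-end orchestration: differential -> activity -> model -> enrichment.

The pipeline runs once per genotype context (treated vs control within the
context), then compares contexts: overlap of significant features, the
correlation of inferred activity profiles, and node/edge differences of the
mechanistic models.  All stage outputs are plain text written in
deterministic order, so identical config + inputs + seed reproduce every
output byte for byte.  All randomness flows from one root seed through
per-stage derived seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .activity import (RegulonSet, combine_activities, compare_activity_profiles,
                       footprint_activity, phospho_score)
from .differential import (DifferentialTable, cluster_features,
                           compare_significant_sets, differential_stats,
                           replicate_correlation)
from .enrichment import kinase_set_enrichment, ora
from .network import (build_naive_network, connect_to_phenotype, model_diff,
                      validate_model)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""


@dataclass
class AnalysisConfig:
    """Declarative configuration of one pipeline run.

    Thresholds default to the conventions of the analysis: differential
    FDR < 0.1, enrichment FDR < 0.05, enrichment score > 3, four clusters,
    footprint regulons of at least 3 measured targets, 1000 permutations,
    phenotype ``DNA_damage`` reached with positive sign within 4 steps.
    """

    proteome: str = ""
    phospho: str = ""
    network: str = ""
    regulons: str = ""
    reg_sites: str = ""
    node_classes: str = ""
    gmt: str = ""
    phenotype: str = "DNA_damage"
    direction: int = 1
    fdr_diff: float = 0.1
    fdr_enrich: float = 0.05
    es_threshold: float = 3.0
    n_clusters: int = 4
    min_targets: int = 3
    n_perm: int = 1000
    max_len: int = 4
    t_test_flavor: str = "student"
    corr_floor: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        for name, val in (("fdr_diff", self.fdr_diff), ("fdr_enrich", self.fdr_enrich)):
            if not 0 < val <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {val}")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class InputBundle:
    proteome: fio.OmicsMatrix
    phospho: fio.OmicsMatrix
    network: "object"
    regulons: RegulonSet
    reg_sites: pd.DataFrame
    gmt: fio.GeneSetCollection | None = None


def load_inputs(config: AnalysisConfig) -> InputBundle:
    node_classes = {}
    if config.node_classes:
        df = pd.read_csv(config.node_classes, sep="\t", dtype=str)
        node_classes = dict(zip(df["node"], df["node_class"]))
    return InputBundle(
        proteome=fio.read_matrix(config.proteome, "proteome"),
        phospho=fio.read_matrix(config.phospho, "phospho"),
        network=fio.read_prior_network(config.network, phenotypes=(config.phenotype,),
                                       node_classes=node_classes),
        regulons=fio.read_regulons(config.regulons),
        reg_sites=fio.read_reg_sites(config.reg_sites) if config.reg_sites
        else pd.DataFrame(columns=["site", "protein", "effect"]),
        gmt=fio.read_gmt(config.gmt) if config.gmt else None,
    )


def validate_inputs(config: AnalysisConfig, bundle: InputBundle | None = None) -> dict:
    """Cross-check identifier consistency across the input bundle.

    Fatal: phenotype missing from the network; a genotype lacking a usable
    treated/control contrast.  Non-fatal: regulon targets or regulatory
    sites never measured (reported as orphan counts).
    """
    bundle = bundle or load_inputs(config)
    fatal: list[str] = []
    warnings: list[str] = []
    if config.phenotype not in bundle.network:
        fatal.append(f"phenotype {config.phenotype!r} absent from the prior network")
    genotypes = sorted(set(bundle.proteome.genotypes) | set(bundle.phospho.genotypes))
    for matrix, name in ((bundle.proteome, "proteome"), (bundle.phospho, "phospho")):
        for g in genotypes:
            for treatment in ("control", "treated"):
                n = len(matrix.columns_for(f"{g}.{treatment}"))
                if n < 2:
                    fatal.append(f"{name}: genotype {g!r} has {n} {treatment} samples (<2)")
    phos_feats = set(bundle.phospho.features)
    prot_feats = set(bundle.proteome.features)
    orphan_sites = sum(
        1 for _, reg in bundle.regulons.items() if reg.klass != "tf"
        for t, _ in reg.targets if t not in phos_feats
    )
    orphan_prot = sum(
        1 for _, reg in bundle.regulons.items() if reg.klass == "tf"
        for t, _ in reg.targets if t not in prot_feats
    )
    if orphan_sites:
        warnings.append(f"{orphan_sites} regulon phosphosite targets never measured")
    if orphan_prot:
        warnings.append(f"{orphan_prot} TF regulon protein targets never measured")
    orphan_reg = int((~bundle.reg_sites["site"].isin(phos_feats)).sum()) if len(bundle.reg_sites) else 0
    if orphan_reg:
        warnings.append(f"{orphan_reg} regulatory sites never measured")
    return {"fatal": fatal, "warnings": warnings, "genotypes": genotypes}


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonify(v) for v in sorted(obj)] if isinstance(obj, set) else [
            _jsonify(v) for v in obj
        ]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def _write_json(payload, path: Path) -> None:
    path.write_text(json.dumps(_jsonify(payload), indent=2, sort_keys=True) + "\n")


def _write_table(df: pd.DataFrame, path: Path, index_label=None) -> None:
    df.to_csv(path, sep="\t", lineterminator="\n",
              index=index_label is not None, index_label=index_label)


def _protein_universe(bundle: InputBundle) -> set[str]:
    hosts = {fio.PhosphositeID.parse(f).protein for f in bundle.phospho.features}
    return set(bundle.proteome.features) | hosts


def run_pipeline(config: AnalysisConfig, out_dir: str | Path) -> dict:
    """Execute every stage per genotype and write the run report.

    Returns the report dictionary (also written to ``out_dir/report.json``).
    Raises :class:`PipelineError` naming the failing stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(config.seed)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - reported with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    bundle = _stage("load_inputs", load_inputs, config)
    validation = _stage("validate_inputs", validate_inputs, config, bundle)
    if validation["fatal"]:
        raise PipelineError(f"stage 'validate_inputs' failed: {validation['fatal']}")
    genotypes = validation["genotypes"]
    node_classes = {n: bundle.network.node_class(n) for n in bundle.network.nodes}

    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "validation": validation,
        "contexts": {},
        "comparisons": {},
    }
    diff_prot_all: dict[str, DifferentialTable] = {}
    diff_phos_all: dict[str, DifferentialTable] = {}
    activities_all: dict[str, pd.DataFrame] = {}
    models: dict[str, object] = {}

    for genotype in genotypes:
        ctx_dir = out / "contexts" / genotype
        ctx_dir.mkdir(parents=True, exist_ok=True)
        ctx_seed = int(root.integers(2**31))
        contrast = (f"{genotype}.treated", f"{genotype}.control")

        diff_prot = _stage("differential", differential_stats, bundle.proteome,
                           contrast, config.fdr_diff, config.t_test_flavor)
        diff_phos = _stage("differential", differential_stats, bundle.phospho,
                           contrast, config.fdr_diff, config.t_test_flavor)
        diff_prot_all[genotype], diff_phos_all[genotype] = diff_prot, diff_phos
        _write_table(diff_prot.table, ctx_dir / "diff_proteome.tsv", "feature")
        _write_table(diff_phos.table, ctx_dir / "diff_phospho.tsv", "feature")

        corr_p, qc_p = _stage("replicate_qc", replicate_correlation, bundle.proteome,
                              config.corr_floor)
        corr_s, qc_s = _stage("replicate_qc", replicate_correlation, bundle.phospho,
                              config.corr_floor)
        _write_json({"proteome": qc_p, "phospho": qc_s}, ctx_dir / "qc.json")

        fp_kin = _stage("activity", footprint_activity, diff_phos,
                        bundle.regulons.subset(("kinase", "phosphatase")),
                        config.min_targets, config.n_perm, ctx_seed)
        fp_tf = _stage("activity", footprint_activity, diff_prot,
                       bundle.regulons.subset(("tf",)),
                       config.min_targets, config.n_perm, ctx_seed + 1)
        footprint = pd.concat([fp_kin, fp_tf]).sort_index()
        ps = _stage("activity", phospho_score, diff_phos, bundle.reg_sites,
                    True, node_classes)
        combined, conflicts = _stage("activity", combine_activities, footprint, ps)
        activities_all[genotype] = combined
        _write_table(combined, ctx_dir / "activities.tsv", "protein")
        _write_json({"conflicts": conflicts,
                     "skipped_footprint": footprint.attrs.get("skipped", [])},
                    ctx_dir / "activity_log.json")

        naive = _stage("model", build_naive_network, combined, bundle.network)
        model = _stage("model", connect_to_phenotype, naive, bundle.network,
                       config.phenotype, config.direction, config.max_len)
        problems = validate_model(model, max_len=config.max_len)
        if problems:
            raise PipelineError(f"stage 'model' failed: invalid model: {problems[:3]}")
        models[genotype] = model
        fio.write_model(model, ctx_dir / "model")

        enr_n = {}
        if bundle.gmt is not None:
            query = model.node_set() - {config.phenotype}
            result = _stage("enrichment", ora, query, bundle.gmt,
                            _protein_universe(bundle), config.fdr_enrich,
                            config.es_threshold)
            _write_table(result, ctx_dir / "enrichment.tsv")
            enr_n = {"n_sets_tested": int(len(result)),
                     "n_significant": int(result["significant"].sum()) if len(result) else 0}
        kse = _stage("enrichment", kinase_set_enrichment, diff_phos,
                     bundle.regulons.subset(("kinase", "phosphatase")), "up",
                     config.fdr_enrich, config.es_threshold)
        _write_table(kse, ctx_dir / "kinase_enrichment_up.tsv")

        sig_prot = sorted(diff_prot.significant_features())
        clusters = {}
        if len(sig_prot) >= config.n_clusters:
            assign = _stage("clustering", cluster_features, bundle.proteome,
                            config.n_clusters, sig_prot)
            _write_table(assign.to_frame(), ctx_dir / "clusters.tsv", "feature")
            clusters = {str(c): int((assign == c).sum())
                        for c in sorted(assign.unique())}

        recovered = combined[
            combined["method"].isin(["footprint", "combined"])
            & (combined["fdr"] < config.fdr_diff)
        ]
        report["contexts"][genotype] = {
            "differential": {
                "proteome": {"n_tested": int(len(diff_prot.table)),
                             "n_significant": int(len(diff_prot.significant_features())),
                             "n_excluded": len(diff_prot.excluded)},
                "phospho": {"n_tested": int(len(diff_phos.table)),
                            "n_significant": int(len(diff_phos.significant_features())),
                            "n_excluded": len(diff_phos.excluded),
                            "n_loc_filtered": diff_phos.n_loc_filtered},
            },
            "replicate_qc": {"proteome_warnings": len(qc_p["warnings"]),
                             "phospho_warnings": len(qc_s["warnings"])},
            "activities": {
                "n_total": int(len(combined)),
                "by_class": {k: int(v) for k, v in
                             combined["class"].value_counts().sort_index().items()},
                "by_method": {k: int(v) for k, v in
                              combined["method"].value_counts().sort_index().items()},
                "n_conflicts": len(conflicts),
            },
            "model": {"n_nodes": model.n_nodes, "n_edges": model.n_edges,
                      "n_paths": len(model.paths)},
            "enrichment": enr_n,
            "clusters": clusters,
            "recovered_regulators": {p: int(s) for p, s in
                                     recovered["sign"].sort_index().items()},
        }

    if len(genotypes) >= 2:
        report["comparisons"]["significant_overlap"] = {
            "proteome": {k: v for k, v in
                         compare_significant_sets(diff_prot_all).items()
                         if "count" in k or k == "per_context_counts"},
            "phospho": {k: v for k, v in
                        compare_significant_sets(diff_phos_all).items()
                        if "count" in k or k == "per_context_counts"},
        }
        pairs = [(a, b) for i, a in enumerate(genotypes) for b in genotypes[i + 1:]]
        report["comparisons"]["activity_correlation"] = {
            f"{a}|{b}": {k: v for k, v in
                         compare_activity_profiles(activities_all[a],
                                                   activities_all[b]).items()
                         if k != "shared"}
            for a, b in pairs
        }
        report["comparisons"]["model_diff"] = {
            f"{a}|{b}": {k: len(v) for k, v in model_diff(models[a], models[b]).items()}
            for a, b in pairs
        }

    _write_json(report, out / "report.json")
    return report
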