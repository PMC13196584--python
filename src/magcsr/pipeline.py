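"""End-to-end orchestration of the CSR trait analysis.

A single configured run executes: data loading or synthesis, optional
rarefaction (amplicon mode), square-root Bray-Curtis distances,
PERMANOVA / PERMDISP / CAP by disturbance level, community-aggregated
traits with level-mean Z-scores, CSR strategy assignment of genomes and
trait categories, DistLM + dbRDA on trait predictors with correlation
vector overlays, a SparCC network with Louvain modules mapped to
regimes, and a tabular report with a run log recording every seed and
threshold.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .csr import CSRModel
from .design import DisturbanceDesign
from .io import (Bundle, DEFAULT_RAREFACTION_DEPTH, rarefy, read_bundle_dir,
                 write_table)
from .multivariate import (DistLM, cap, permanova, permdisp, sqrt_bray_curtis,
                           upgma_similarity_clusters, vector_overlay)
from .network import (build_network, export_network, louvain_modules,
                      module_regime_association, sparcc_correlations)
from .synthetic import SyntheticConfig, generate_dataset
from .traits import (compute_cats, genome_size_welch_anova, normalize_traits,
                     quality_filter, to_relative_abundance, zscore_level_means)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All run parameters under one master seed.

    ``mode`` is ``"synthetic"`` (generate a planted-truth bundle),
    ``"mag"`` (genome tables, abundances used as given) or ``"amplicon"``
    (count tables rarefied before normalisation).
    """

    mode: str = "synthetic"
    input_dir: str | None = None
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    seed: int = 0
    rarefaction_depth: int = DEFAULT_RAREFACTION_DEPTH
    n_perm: int = 9999
    alpha: float = 0.05
    r_min: float = 0.20
    similarity_threshold: float = 85.0
    outdir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"] = self.synthetic.to_dict()
        return d


def _design_from_meta(meta: pd.DataFrame) -> DisturbanceDesign:
    levels = sorted(meta["level"].unique())
    freq = (meta.groupby("level")["frequency"].first()
            if "frequency" in meta else pd.Series(levels, index=levels))
    regime_of_level = meta.groupby("level")["regime"].first().to_dict()
    replicates = int(meta.groupby("level").size().min())
    day = int(meta["day"].iloc[0]) if "day" in meta else 0
    return DisturbanceDesign(
        frequencies=[freq[lvl] for lvl in levels],
        regime_of_level={int(k): v for k, v in regime_of_level.items()},
        replicates=replicates,
        day=day,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the report bundle and writes
    tables to ``config.outdir`` when set."""
    report: dict = {"config": config.to_dict()}
    stage = "load"
    try:
        if config.mode == "synthetic":
            syn = dataclasses.replace(config.synthetic, seed=config.seed)
            bundle = generate_dataset(syn)
            design = syn.design
        elif config.mode in ("mag", "amplicon"):
            if config.input_dir is None:
                raise ValueError(f"mode {config.mode!r} requires input_dir")
            bundle = read_bundle_dir(config.input_dir)
            design = _design_from_meta(bundle.sample_meta)
        else:
            raise ValueError(f"unknown mode {config.mode!r}")
        bundle.validate()
        meta = bundle.sample_meta
        regimes = meta["regime"]
        levels = meta["level"].astype(str)

        stage = "rarefy"
        counts = bundle.abundance
        if config.mode == "amplicon":
            counts = rarefy(counts, depth=config.rarefaction_depth,
                            seed=config.seed)
            meta = meta.loc[counts.index]
            regimes, levels = regimes.loc[counts.index], levels.loc[counts.index]
        rel = to_relative_abundance(counts)

        stage = "distances"
        dm = sqrt_bray_curtis(counts)
        report["distance_matrix"] = dm.to_frame()

        stage = "permanova/permdisp"
        pa = permanova(dm, levels, n_perm=config.n_perm, seed=config.seed)
        pdisp = permdisp(dm, levels, n_perm=config.n_perm, seed=config.seed)
        report["tests"] = pd.DataFrame([
            {"test": pa.name, "statistic": pa.statistic, "p": pa.p_value,
             "n_perm": pa.n_permutations, "seed": pa.seed},
            {"test": pdisp.name, "statistic": pdisp.statistic,
             "p": pdisp.p_value, "n_perm": pdisp.n_permutations,
             "seed": pdisp.seed},
        ])

        stage = "cap"
        cap_res = cap(dm, levels)
        report["cap_scores"] = cap_res.scores
        report["cap_loo_success"] = cap_res.loo_allocation_success
        report["cap_m"] = cap_res.m
        report["similarity_clusters"] = upgma_similarity_clusters(
            dm, config.similarity_threshold).to_frame()
        if bundle.function_metrics is not None and cap_res.scores.shape[1] >= 2:
            report["cap_vectors"] = vector_overlay(
                cap_res.scores, bundle.function_metrics, r_min=config.r_min)

        stage = "traits"
        keep = quality_filter(bundle.genome_meta)
        trait_counts = bundle.trait_counts.loc[keep.intersection(rel.columns)]
        fractions = normalize_traits(trait_counts)
        rel_kept = to_relative_abundance(rel[fractions.index])
        cats = compute_cats(rel_kept, fractions)
        report["cat_matrix"] = cats
        zmat, constant_traits = zscore_level_means(cats, design)
        report["zscore_level_means"] = zmat

        stage = "csr-genomes"
        genome_model = CSRModel(rel, regimes)
        genome_res = genome_model.fit(n_sim=config.n_perm,
                                      alpha=config.alpha, seed=config.seed)
        report["genome_assignments"] = genome_res.assignments
        report["genome_venn"] = genome_res.venn_counts()

        stage = "csr-traits"
        trait_model = CSRModel(cats, regimes)
        trait_res = trait_model.fit(n_sim=config.n_perm,
                                    alpha=config.alpha, seed=config.seed)
        report["trait_assignments"] = trait_res.assignments
        report["trait_venn"] = trait_res.venn_counts()

        stage = "genome-size-anova"
        sizes = bundle.genome_meta.loc[genome_res.assignments.index.intersection(
            bundle.genome_meta.index)]
        labels = genome_res.assignments["label"]
        groups = {}
        for s in ("C", "R", "S"):
            ids = labels.index[labels == s]
            vals = sizes.loc[sizes.index.intersection(ids), "genome_size_bp"]
            if len(vals) >= 2 and vals.var() > 0:
                groups[s] = vals.to_numpy(dtype=float)
        if len(groups) >= 2:
            wa = genome_size_welch_anova(groups)
            report["genome_size_welch"] = {
                "F": wa.F, "df1": wa.df1, "df2": wa.df2, "p": wa.p}

        stage = "distlm/dbrda"
        distlm_res = DistLM(dm, cats).fit()
        report["distlm_selected"] = distlm_res.selected
        report["distlm_aicc"] = distlm_res.aicc
        report["distlm_r2"] = distlm_res.r2
        report["distlm_trace"] = distlm_res.trace
        if distlm_res.selected:
            ord_res = distlm_res.dbrda()
            report["dbrda_scores"] = ord_res.scores
            report["dbrda_percent_fitted"] = ord_res.percent_fitted
            report["dbrda_percent_total"] = ord_res.percent_total
            if ord_res.scores.shape[1] >= 2:
                report["dbrda_vectors"] = vector_overlay(
                    ord_res.scores, cats[distlm_res.selected],
                    r_min=config.r_min)

        stage = "network"
        corr = sparcc_correlations(counts, seed=config.seed)
        graph = build_network(corr, r_min=config.r_min)
        mod = louvain_modules(graph, seed=config.seed)
        report["network_modularity_q"] = mod.q
        report["network_modules"] = pd.Series(mod.modules, name="module")
        report["module_regimes"] = module_regime_association(
            mod.modules, rel, regimes)
        report["_graph"] = graph

        if bundle.truth is not None:
            report["truth"] = bundle.truth.to_frame()

        if config.outdir is not None:
            _write_report(report, bundle, config)
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _write_report(report: dict, bundle: Bundle, config: PipelineConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(report["config"], fh, sort_keys=True)
    frames = {
        "distance_matrix": report["distance_matrix"],
        "tests": report["tests"],
        "cap_scores": report["cap_scores"],
        "similarity_clusters": report["similarity_clusters"],
        "cat_matrix": report["cat_matrix"],
        "zscore_level_means": report["zscore_level_means"],
        "genome_assignments": report["genome_assignments"],
        "trait_assignments": report["trait_assignments"],
        "distlm_trace": report["distlm_trace"],
        "module_regimes": report["module_regimes"],
    }
    for key in ("cap_vectors", "dbrda_scores", "dbrda_vectors", "truth"):
        if key in report:
            frames[key] = report[key]
    for name, df in frames.items():
        write_table(df if isinstance(df, pd.DataFrame) else df.to_frame(),
                    outdir / f"{name}.tsv")
    report["network_modules"].rename_axis("node").to_frame().to_csv(
        outdir / "network_modules.tsv", sep="\t")
    export_network(report["_graph"], dict(report["network_modules"]),
                   outdir / "network", layout_seed=config.seed)
    log_lines = [
        f"magcsr version: {__version__}",
        f"master seed: {config.seed}",
        f"mode: {config.mode}",
        f"n_perm: {config.n_perm}",
        f"alpha: {config.alpha}",
        f"r_min: {config.r_min}",
        f"rarefaction_depth: {config.rarefaction_depth}",
        f"similarity_threshold: {config.similarity_threshold}",
        f"samples: {len(report['distance_matrix'])}",
        f"genome venn: {report['genome_venn']}",
        f"trait venn: {report['trait_venn']}",
        f"distlm selected: {report['distlm_selected']}",
        f"distlm AICc: {report['distlm_aicc']:.4f}",
        f"distlm R2: {report['distlm_r2']:.6f}",
        f"network modularity Q: {report['network_modularity_q']:.6f}",
    ]
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
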