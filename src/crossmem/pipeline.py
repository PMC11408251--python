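"""End-to-end orchestration of the cross-species integration flow.

The pipeline ties the stages together in the order the analysis dictates:
normalize the human array -> correlate probes with the symptom score ->
mouse differential expression -> cross-species integration (broad and
strict gates, concordance) -> case-control curation -> target-gene
co-expression and gene-set enrichment -> CpG tripartite screen and
mediation. Each stage writes a TSV, the run writes a JSON summary with
every gate's count, and all randomness flows from one global seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import case_control_tests, correlate_with_phenotype
from .coexpression import coexpression_screen
from .containers import ExpressionMatrix
from .de import differential_expression
from .enrichment import GeneSetCollection, enrichment_test, read_gmt
from .integrate import (
    ThresholdSpec,
    build_integration_records,
    cross_species_concordance,
    curate_three_way,
    select_overlap,
)
from .io import read_expression, read_methylation, read_phenotypes
from .mediation import mediate_both_scales, tripartite_screen
from .preprocess import NormalizationParams, normalize_microarray

log = logging.getLogger("crossmem")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_stages"]


@dataclass
class PipelineConfig:
    """Paths, thresholds and settings of one reproducible run."""

    human_expression: str
    phenotypes: str
    mouse_expression: str
    mouse_samples: str
    output_dir: str
    methylation: str | None = None
    gene_sets: str | None = None
    phenotype_name: str = "reexperiencing"
    target_symbol: str = "PDE4B"
    coexpr_abs_r_min: float = 0.6
    mediation_group: str | None = "PTSD"  # diagnosis value, or None for all subjects
    n_boot: int = 5000
    seed: int = 0
    thresholds: ThresholdSpec = field(default_factory=ThresholdSpec)
    normalization: NormalizationParams = field(default_factory=NormalizationParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thresholds = ThresholdSpec(**raw.pop("thresholds", {}))
        normalization = NormalizationParams(**raw.pop("normalization", {}))
        return cls(thresholds=thresholds, normalization=normalization, **raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class PipelineResult:
    """Stage tables plus the gate-count summary of one run."""

    assoc: pd.DataFrame
    case_control: pd.DataFrame
    de_table: pd.DataFrame
    records: pd.DataFrame
    broad: pd.DataFrame
    hybrid: pd.DataFrame
    strict: pd.DataFrame
    curated: pd.DataFrame
    concordance: dict
    coexpr_probes: pd.DataFrame | None
    coexpr_genes: pd.DataFrame | None
    enrichment: pd.DataFrame | None
    tripartite: pd.DataFrame | None
    mediation: dict | None
    summary: dict


def _unique_genes(records: pd.DataFrame) -> int:
    return int(records["gene_symbol"].nunique()) if len(records) else 0


def run_stages(
    human_raw: ExpressionMatrix,
    pheno: pd.DataFrame,
    mouse_expr: ExpressionMatrix,
    methylation: pd.DataFrame | None = None,
    gene_sets: GeneSetCollection | None = None,
    thresholds: ThresholdSpec | None = None,
    normalization: NormalizationParams | None = None,
    phenotype_name: str = "reexperiencing",
    target_symbol: str = "PDE4B",
    coexpr_abs_r_min: float = 0.6,
    mediation_group: str | None = "PTSD",
    n_boot: int = 5000,
    seed: int = 0,
) -> PipelineResult:
    """Run every stage in memory and return all tables plus the summary.

    The methylation / enrichment stages are skipped (None in the result)
    when their inputs are not supplied. ``mediation_group`` restricts the
    tripartite screen and mediation model to subjects with that diagnosis
    (the symptom-correlation screen always uses the full cohort).
    """
    thresholds = thresholds or ThresholdSpec()
    normalization = normalization or NormalizationParams()

    log.info("normalizing human matrix: %d probes x %d samples",
             human_raw.n_features, human_raw.n_samples)
    human = normalize_microarray(human_raw, normalization)

    assoc = correlate_with_phenotype(human, pheno, phenotype_name)
    case_control = case_control_tests(
        human, pheno, covariate="age" if "age" in pheno.columns else None
    )
    de_table = differential_expression(mouse_expr)

    records = build_integration_records(assoc, de_table)
    broad = select_overlap(records, thresholds, gate="broad")
    hybrid = select_overlap(records, thresholds, gate="hybrid")
    strict = select_overlap(records, thresholds, gate="strict")
    concordance = (
        cross_species_concordance(broad) if len(broad[~broad["degenerate"]]) >= 3 else {}
    )
    curated = curate_three_way(strict, case_control, thresholds)

    coexpr_probes = coexpr_genes = enrich = None
    target_probes = assoc.index[assoc["symbol"].astype(str).str.upper() == target_symbol.upper()]
    if len(target_probes):
        # multi-probe targets: screen around the probe with the strongest
        # symptom correlation
        best = assoc.loc[target_probes, "pearson_r"].abs().idxmax()
        coexpr_probes, coexpr_genes = coexpression_screen(human, best, coexpr_abs_r_min)
        if gene_sets is not None:
            universe = set(human.symbols.dropna().astype(str).str.upper()) - {""}
            enrich = enrichment_test(set(coexpr_genes.index), gene_sets, universe)
    else:
        log.warning("target symbol %r not on the array; co-expression skipped", target_symbol)

    tri = mediation = None
    if methylation is not None and len(target_probes):
        subjects = pheno.index
        if mediation_group is not None:
            subjects = pheno.index[pheno["diagnosis"] == mediation_group]
        best = assoc.loc[target_probes, "pearson_r"].abs().idxmax()
        expr_vec = human.values.loc[best, human.sample_ids.intersection(subjects)]
        sympt = pheno.loc[subjects, phenotype_name]
        tri = tripartite_screen(methylation.loc[:, methylation.columns.intersection(subjects)],
                                expr_vec, sympt)
        hits = tri[tri["selected"] & tri["compatible"]]
        if len(hits):
            # mediate through the site with the strongest joint evidence
            top = (hits["p_meth_symptom"] + hits["p_meth_expr"]).idxmin()
            common = methylation.columns.intersection(expr_vec.index)
            x = methylation.loc[top, common]
            m = expr_vec.loc[common]
            y = pheno.loc[common, phenotype_name]
            ok = y.notna() & m.notna() & x.notna()
            if ok.sum() >= 10:
                results = mediate_both_scales(
                    x[ok], m[ok], y[ok], n_boot=n_boot, seed=seed
                )
                mediation = {"cpg": top, **{k: dataclasses.asdict(v) for k, v in results.items()}}

    abs_r = assoc["pearson_r"].abs()
    sig_r = assoc["defined"] & (abs_r > thresholds.human_abs_r_min)
    mouse_strict = (
        (de_table["q"] < thresholds.mouse_q_max)
        & (de_table["fc_linear"].abs() > thresholds.mouse_abs_fc_min)
    )
    summary = {
        "n_subjects": int(human.n_samples),
        "n_probes": int(human.n_features),
        "n_mouse_genes": int(mouse_expr.n_features),
        "n_universe_genes": int(records["gene_symbol"].nunique()),
        "n_human_probes_p": int((assoc["pearson_p"] < thresholds.human_p_max).sum()),
        "n_human_probes_r": int(sig_r.sum()),
        "n_human_probes_r_positive": int((sig_r & (assoc["pearson_r"] > 0)).sum()),
        "n_human_probes_r_negative": int((sig_r & (assoc["pearson_r"] < 0)).sum()),
        "n_mouse_genes_q": int((de_table["q"] < thresholds.mouse_q_alt).sum()),
        "n_mouse_genes_strict": int(mouse_strict.sum()),
        "n_mouse_strict_up": int((mouse_strict & (de_table["log2fc"] > 0)).sum()),
        "n_mouse_strict_down": int((mouse_strict & (de_table["log2fc"] < 0)).sum()),
        "n_broad_genes": _unique_genes(broad),
        "n_hybrid_genes": _unique_genes(hybrid),
        "n_strict_genes": _unique_genes(strict),
        "n_curated_genes": _unique_genes(curated),
        "consistent_fraction_broad": concordance.get("consistent_fraction"),
        "concordance_r": concordance.get("pearson_r"),
        "concordance_p": concordance.get("p"),
        "n_coexpr_probes": int(len(coexpr_probes)) if coexpr_probes is not None else None,
        "n_coexpr_genes": int(len(coexpr_genes)) if coexpr_genes is not None else None,
        "n_cpgs": int(len(tri)) if tri is not None else None,
        "n_cpgs_selected": int(tri["selected"].sum()) if tri is not None else None,
        "n_cpgs_selected_compatible": int((tri["selected"] & tri["compatible"]).sum())
        if tri is not None
        else None,
        "seed": seed,
    }
    return PipelineResult(
        assoc=assoc,
        case_control=case_control,
        de_table=de_table,
        records=records,
        broad=broad,
        hybrid=hybrid,
        strict=strict,
        curated=curated,
        concordance=concordance,
        coexpr_probes=coexpr_probes,
        coexpr_genes=coexpr_genes,
        enrichment=enrich,
        tripartite=tri,
        mediation=mediation,
        summary=summary,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based wrapper of :func:`run_stages` writing all stage outputs."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info(
            "crossmem %s on python %s; seed=%d; thresholds=%s",
            __version__, platform.python_version(), config.seed,
            dataclasses.asdict(config.thresholds),
        )
        stage = "read inputs"
        try:
            human_raw = read_expression(config.human_expression)
            pheno = read_phenotypes(config.phenotypes)
            mouse = read_expression(config.mouse_expression, config.mouse_samples)
            meth = read_methylation(config.methylation) if config.methylation else None
            sets = read_gmt(config.gene_sets) if config.gene_sets else None
            stage = "pipeline"
            result = run_stages(
                human_raw,
                pheno,
                mouse,
                methylation=meth,
                gene_sets=sets,
                thresholds=config.thresholds,
                normalization=config.normalization,
                phenotype_name=config.phenotype_name,
                target_symbol=config.target_symbol,
                coexpr_abs_r_min=config.coexpr_abs_r_min,
                mediation_group=config.mediation_group,
                n_boot=config.n_boot,
                seed=config.seed,
            )
        except Exception as exc:
            log.error("stage %r failed: %s", stage, exc)
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

        for name in ("assoc", "case_control", "de_table", "records", "broad",
                     "hybrid", "strict", "curated"):
            getattr(result, name).to_csv(outdir / f"{name}.tsv", sep="\t")
        for name in ("coexpr_probes", "coexpr_genes", "enrichment", "tripartite"):
            table = getattr(result, name)
            if table is not None:
                table.to_csv(outdir / f"{name}.tsv", sep="\t")
        payload = {"summary": result.summary, "concordance": result.concordance}
        if result.mediation is not None:
            payload["mediation"] = result.mediation
        with open(outdir / "summary.json", "w") as fh:
            json.dump(payload, fh, indent=2, default=float)
        log.info("summary: %s", result.summary)
        return result
    finally:
        log.removeHandler(handler)
        handler.close()
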