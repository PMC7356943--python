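"""End-to-end orchestration: simulate -> GRS -> diversity -> differential
abundance -> interaction models, with TSV reports and a reproducibility
manifest.

Every run writes a manifest (config + seed + package version) sufficient
to reproduce the run byte-for-byte.
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
from ._stats import mann_whitney
from .diffabund import lda_effect_size, rf_rank, zig_fit
from .grs import GRSBuilder, split_by_mean
from .interaction import interaction_model, predict_curve
from .prep import diversity_association, diversity_table, filter_features, relative_abundance
from .simulate import CohortConfig, default_microbiome_config, default_snp_panel, simulate_cohort
from . import io

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("simulate", "grs", "diversity", "diffabund", "interact")

_NON_GENOTYPE_COLS = {"sex", "age", "mets", "energy", "bmi", "true_grs"}


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Structured pipeline configuration.

    Defaults echo the analysis settings used throughout the package:
    screen threshold 0.20, confirmation threshold 0.10, 10% low-count
    filter, CSS normalization, LDA score threshold 2.0, 500 trees and 10
    repeats with a 70/30 split for the random forest.
    """

    stages: tuple = ALL_STAGES
    seed: int = 0
    outdir: str = "microgrs_run"
    # external inputs (used when the simulate stage is disabled)
    cohort_tsv: str | None = None
    abundance_tsv: str | None = None
    genotypes_vcf: str | None = None
    # simulation
    n_subjects: int = 360
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    n_families: int = 64
    focal_family: str = "Prevotellaceae"
    # GRS construction
    alpha1: float = 0.20
    merge_alpha: float = 0.05
    alpha2: float = 0.10
    min_frac: float = 0.10
    collinearity_r: float = 0.8
    # microbiome
    min_prevalence: float = 0.10
    min_total: int = 10
    css_quantile: object = "auto"
    lefse_alpha: float = 0.05
    lda_min: float = 2.0
    n_boot: int = 30
    rf_trees: int = 500
    rf_repeats: int = 10
    train_frac: float = 0.70

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise PipelineError(f"unknown stages: {sorted(unknown)}")
        for name, lo, hi in [
            ("alpha1", 0, 1), ("merge_alpha", 0, 1), ("alpha2", 0, 1),
            ("min_frac", 0, 1), ("collinearity_r", 0, 1),
            ("min_prevalence", 0, 1), ("lefse_alpha", 0, 1),
            ("train_frac", 0, 1),
        ]:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise PipelineError(f"{name}={v} outside [{lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return d


def _selection_report_table(builder: GRSBuilder, cohort: pd.DataFrame) -> pd.DataFrame:
    """Selection report shaped like the published coding table: per SNP the
    two codings, group sizes, sex-stratified group BMI means and the
    within-sex Mann-Whitney p-values, plus the selection diagnostics."""
    bmi = cohort["bmi"]
    sex = cohort["sex"]
    rows = []
    for coding in builder.codings_:
        row = {
            "snp": coding.snp_id,
            "non_risk_genotype": "+".join(sorted(coding.nonrisk_genotypes)) or ".",
            "risk_genotype": "+".join(sorted(coding.risk_genotypes)) or ".",
            "stage1_p": coding.stage1_p,
            "stage3_p": coding.stage3_p,
            "retained": coding.snp_id in builder.retained_snps_,
            "exclusion_reason": coding.exclusion_reason or "",
        }
        if coding.risk_genotypes and coding.nonrisk_genotypes:
            ind = coding.indicator(cohort[coding.snp_id]).dropna()
            y = bmi.loc[ind.index]
            s = sex.loc[ind.index]
            row["n_non_risk"] = int((ind == 0).sum())
            row["n_risk"] = int((ind == 1).sum())
            for sx, tag in [("female", "women"), ("male", "men")]:
                nr = y[(ind == 0) & (s == sx)]
                rk = y[(ind == 1) & (s == sx)]
                row[f"non_risk_{tag}_bmi"] = float(nr.mean()) if len(nr) else np.nan
                row[f"risk_{tag}_bmi"] = float(rk.mean()) if len(rk) else np.nan
                if len(nr) >= 1 and len(rk) >= 1:
                    row[f"p_{tag}"] = mann_whitney(
                        rk.to_numpy(), nr.to_numpy(), method="asymptotic"
                    ).pvalue
                else:
                    row[f"p_{tag}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Run the enabled stages; writes reports under ``config.outdir``.

    Stage dependencies are validated up front: grs needs a cohort,
    diffabund/interact need abundance data and (for GRS grouping) the grs
    stage.  Failures halt with the stage name; completed outputs remain.
    """
    stages = list(config.stages)
    outdir = Path(config.outdir)

    need_cohort = {"grs", "diversity", "diffabund", "interact"} & set(stages)
    if need_cohort and "simulate" not in stages and config.cohort_tsv is None:
        raise PipelineError(
            f"stages {sorted(need_cohort)} need a cohort: enable the simulate "
            "stage or provide cohort_tsv"
        )
    if {"diversity", "diffabund", "interact"} & set(stages) and \
            "simulate" not in stages and config.abundance_tsv is None:
        raise PipelineError("microbiome stages need abundance_tsv or the simulate stage")
    if {"diffabund", "interact"} & set(stages) and "grs" not in stages:
        raise PipelineError("diffabund and interact stages require the grs stage")

    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.to_dict(), "seed": config.seed,
                "microgrs_version": __version__}
    io.write_manifest(manifest, outdir / "manifest.yaml")

    state: dict = {}

    def stage(name):
        def deco(fn):
            if name in stages:
                logger.info("running stage %s", name)
                try:
                    fn()
                except PipelineError:
                    raise
                except Exception as e:  # halt with stage name, keep outputs
                    raise PipelineError(f"stage {name!r} failed: {e}") from e
            return fn
        return deco

    @stage("simulate")
    def _simulate():
        cc = CohortConfig(n_subjects=config.n_subjects, seed=config.seed, **config.cohort)
        mc = default_microbiome_config(config.n_families, config.focal_family)
        cohort, counts, specs = simulate_cohort(cc, mc)
        io.write_table(cohort, outdir / "cohort.tsv")
        io.write_table(counts, outdir / "abundance.tsv")
        io.write_snp_specs(specs, outdir / "snp_specs.tsv")
        state["cohort"], state["counts"] = cohort, counts

    if "cohort" not in state and need_cohort:
        if config.cohort_tsv:
            state["cohort"] = io.read_cohort_tsv(config.cohort_tsv)
            if config.genotypes_vcf:
                geno = io.read_genotypes_vcf(config.genotypes_vcf)
                state["cohort"] = state["cohort"].join(geno, how="inner")
        if config.abundance_tsv:
            state["counts"] = io.read_abundance_tsv(config.abundance_tsv)

    @stage("grs")
    def _grs():
        cohort = state["cohort"]
        genocols = [c for c in cohort.columns if c not in _NON_GENOTYPE_COLS]
        builder = GRSBuilder(
            alpha1=config.alpha1, merge_alpha=config.merge_alpha,
            alpha2=config.alpha2, min_frac=config.min_frac,
            collinearity_r=config.collinearity_r,
        ).fit(cohort[genocols], cohort["bmi"])
        state["builder"] = builder
        io.write_table(_selection_report_table(builder, cohort),
                       outdir / "selection_report.tsv", index=False)
        grs = builder.transform(cohort[genocols])
        groups = split_by_mean(grs)
        state["grs"] = grs
        state["grs_group"] = groups
        io.write_table(pd.DataFrame({"grs": grs, "grs_group": groups}),
                       outdir / "grs.tsv")

    @stage("diversity")
    def _diversity():
        counts, cohort = state["counts"], state["cohort"]
        div = diversity_table(counts)
        io.write_table(div, outdir / "diversity.tsv")
        shannon = div["shannon"]
        shannon.index = cohort.index
        assoc = [diversity_association(shannon, cohort["bmi"], cohort["sex"])
                 .assign(trait="bmi")]
        if "grs" in state:
            assoc.append(
                diversity_association(shannon, state["grs"], cohort["sex"])
                .assign(trait="grs")
            )
        io.write_table(pd.concat(assoc), outdir / "diversity_associations.tsv")

    @stage("diffabund")
    def _diffabund():
        counts, cohort = state["counts"], state["cohort"]
        filtered = filter_features(counts, config.min_prevalence, config.min_total)
        relab = relative_abundance(filtered)
        bmi_group = pd.Series(
            np.where(cohort["bmi"] < 25.0, "normalweight", "overweight+obese"),
            index=cohort.index,
        )
        groupings = {"bmi": bmi_group.to_numpy()}
        if "grs_group" in state:
            groupings["grs"] = state["grs_group"].reindex(cohort.index).to_numpy()
        for tag, labels in groupings.items():
            lefse = lda_effect_size(
                relab, labels, alpha=config.lefse_alpha, lda_min=config.lda_min,
                n_boot=config.n_boot, seed=config.seed,
            )
            io.write_table(lefse, outdir / f"lefse_{tag}.tsv")
            zig = zig_fit(filtered, labels, css_quantile=config.css_quantile)
            io.write_table(zig, outdir / f"zig_{tag}.tsv")
            ranking = rf_rank(
                relab, labels, n_trees=config.rf_trees,
                n_repeats=config.rf_repeats, train_frac=config.train_frac,
                seed=config.seed,
            )
            table = ranking.table.copy()
            table["mean_auc"] = float(np.mean(ranking.aucs))
            io.write_table(table, outdir / f"rf_{tag}.tsv")

    @stage("interact")
    def _interact():
        counts, cohort = state["counts"], state["cohort"]
        if config.focal_family not in counts.index:
            raise PipelineError(f"focal family {config.focal_family!r} absent")
        relab = relative_abundance(counts).loc[config.focal_family]
        relab.index = cohort.index
        grs = state["grs"]
        blocks = []
        curves = []
        for stratum in ("all", "male", "female"):
            fit = interaction_model(
                cohort["bmi"], relab, grs,
                cohort[["age", "mets", "energy", "sex"]], stratum=stratum,
            )
            block = fit.coef.copy()
            block.insert(0, "stratum", stratum)
            block["r2"] = fit.r2
            block["adj_r2"] = fit.adj_r2
            block["model_p"] = fit.f_pvalue
            block["n"] = fit.n
            blocks.append(block)
            curves.append(predict_curve(fit).assign(stratum=stratum))
        io.write_table(pd.concat(blocks), outdir / "interaction_models.tsv")
        io.write_table(pd.concat(curves, ignore_index=True),
                       outdir / "predicted_curves.tsv", index=False)

    return outdir
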