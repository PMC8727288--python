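"""Pipeline orchestration: simulate -> QC -> ancestry -> score -> associate.

Runs the whole analysis from a single YAML config and one seed, writing
every intermediate as a plain-text file so stages can be re-run
individually, and a manifest with the config hash and per-stage row counts
so cohort attrition is auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from . import assoc, scoring
from .ancestry import estimate_admixture_matrix
from .errors import ConfigurationError
from .genotypes import GenotypeMatrix, write_vcf
from .panel import SNPPanel
from .qc import duplicate_concordance, qc_filter, read_genotypes
from .samples import CONTROL, is_male, read_samples, validate_samples, write_samples
from .simdata import (ArtifactSpec, SimulationConfig, make_aim_panel,
                      make_panel, simulate_study)

log = logging.getLogger("cllprs")


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

class SimulationSection(BaseModel):
    n_snps: int = 41
    n_per_group: dict[str, int] = Field(
        default_factory=lambda: {CONTROL: 900, "LC_MBL": 140, "HC_MBL": 60,
                                 "CLL": 240})
    ancestry_mix: dict[str, float] = Field(
        default_factory=lambda: {"EUR": 0.70, "AFR": 0.25, "EAS": 0.05})
    category_intercepts: dict[str, float] = Field(
        default_factory=lambda: {"LC_MBL": -1.6, "HC_MBL": -2.4, "CLL": -1.3})
    category_prs_slopes: dict[str, float] = Field(
        default_factory=lambda: {"LC_MBL": math.log(1.75),
                                 "HC_MBL": math.log(2.14),
                                 "CLL": math.log(2.53)})
    age_effect: float = 0.06
    sex_effect: float = math.log(1.73)
    age_distribution: tuple[float, float, float, float] = (64.0, 10.0, 30.0, 100.0)
    male_fraction: float = 0.45
    n_aim_snps: int = 300
    aim_fst: float = 0.15
    anchor_prs_mean: float | None = 7.46  # pin E[PRS] to the published scale
    anchor_ancestry: str = "EUR"
    artifacts: dict = Field(default_factory=dict)

    def to_sim_config(self, seed: int) -> SimulationConfig:
        return SimulationConfig(
            n_snps=self.n_snps, n_per_group=dict(self.n_per_group),
            ancestry_mix=dict(self.ancestry_mix),
            category_intercepts=dict(self.category_intercepts),
            category_prs_slopes=dict(self.category_prs_slopes),
            age_effect=self.age_effect, sex_effect=self.sex_effect,
            age_distribution=tuple(self.age_distribution),
            male_fraction=self.male_fraction, seed=seed)


class InputSection(BaseModel):
    genotypes_vcf: str | None = None
    dosage_tsv: str | None = None
    panel_tsv: str
    samples_tsv: str
    cutoffs_json: str | None = None
    aim_dosage_tsv: str | None = None
    aim_panel_tsv: str | None = None

    @model_validator(mode="after")
    def _one_genotype_source(self):
        if (self.genotypes_vcf is None) == (self.dosage_tsv is None):
            raise ValueError("give exactly one of genotypes_vcf / dosage_tsv")
        return self


class QCSection(BaseModel):
    snp_call_min: float = 0.95
    sample_call_min: float = 0.90
    hwe_alpha: float = 1e-5
    drop_monomorphic: bool = True
    hwe_method: str = "exact"


class AncestrySection(BaseModel):
    enabled: bool = True
    ancestries: list[str] = Field(default_factory=lambda: ["EUR", "AFR", "EAS"])
    tol: float = 1e-6
    max_iter: int = 1000


class ScoringSection(BaseModel):
    missing_policy: str = "mean_impute"
    use_external_cutoffs: bool = True   # shipped EA reference boundaries
    top_percentile: float = 0.99


class ModelsSection(BaseModel):
    reference_quantile: str = "Q3"
    per_snp: bool = True
    min_aa_cases: int = 10
    min_aa_controls: int = 20


class PipelineConfig(BaseModel):
    seed: int = 0
    output_dir: str = "cllprs_run"
    log_level: str = "INFO"
    simulation: SimulationSection | None = None
    inputs: InputSection | None = None
    qc: QCSection = Field(default_factory=QCSection)
    ancestry: AncestrySection = Field(default_factory=AncestrySection)
    scoring: ScoringSection = Field(default_factory=ScoringSection)
    models: ModelsSection = Field(default_factory=ModelsSection)

    @model_validator(mode="after")
    def _one_source(self):
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError(
                "exactly one of the 'simulation' and 'inputs' sections "
                "must be present")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except Exception as exc:  # pydantic ValidationError
            raise ConfigurationError(str(exc)) from exc

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, out: Path) -> None:
    sim = config.simulation
    sc = sim.to_sim_config(config.seed)
    anchor = ((sim.anchor_ancestry, sim.anchor_prs_mean)
              if sim.anchor_prs_mean is not None else None)
    panel = make_panel(sim.n_snps, seed=config.seed, anchor=anchor)
    ref_ancs = sorted(set(config.ancestry.ancestries) | set(sc.ancestry_mix))
    aim_panel = make_aim_panel(sim.n_aim_snps, sim.aim_fst,
                               tuple(ref_ancs), seed=config.seed)
    art = ArtifactSpec(**sim.artifacts) if sim.artifacts else None
    study = simulate_study(panel, sc, aim_panel=aim_panel, artifact_spec=art)
    panel.to_tsv(out / "panel.tsv")
    aim_panel.to_tsv(out / "aim_panel.tsv")
    write_samples(study.samples, out / "samples.tsv")
    write_vcf(study.genotypes, panel, out / "genotypes.vcf")
    study.genotypes.to_dosage_tsv(out / "dosages.tsv")
    if study.aim_genotypes is not None:
        study.aim_genotypes.to_dosage_tsv(out / "aim_dosages.tsv")
    log.info("simulate: %d samples x %d variants (+%d AIMs)",
             study.genotypes.n_samples, study.genotypes.n_variants,
             sim.n_aim_snps)


def _load_stage_inputs(config: PipelineConfig, out: Path
                       ) -> tuple[SNPPanel, pd.DataFrame, GenotypeMatrix,
                                  GenotypeMatrix | None, SNPPanel | None]:
    if config.simulation is not None:
        panel = SNPPanel.from_tsv(out / "panel.tsv")
        samples = read_samples(out / "samples.tsv")
        genotypes = GenotypeMatrix.from_dosage_tsv(out / "dosages.tsv")
        aim_path = out / "aim_dosages.tsv"
        aim = GenotypeMatrix.from_dosage_tsv(aim_path) if aim_path.exists() else None
        aim_panel = (SNPPanel.from_tsv(out / "aim_panel.tsv")
                     if (out / "aim_panel.tsv").exists() else None)
        return panel, samples, genotypes, aim, aim_panel
    ins = config.inputs
    panel = SNPPanel.from_tsv(ins.panel_tsv)
    samples = read_samples(ins.samples_tsv)
    if ins.genotypes_vcf:
        genotypes, harmo = read_genotypes(ins.genotypes_vcf, panel)
        harmo.to_csv(out / "harmonization.tsv", sep="\t", index=False)
    else:
        genotypes = GenotypeMatrix.from_dosage_tsv(ins.dosage_tsv)
    aim = (GenotypeMatrix.from_dosage_tsv(ins.aim_dosage_tsv)
           if ins.aim_dosage_tsv else None)
    aim_panel = SNPPanel.from_tsv(ins.aim_panel_tsv) if ins.aim_panel_tsv else None
    return panel, samples, genotypes, aim, aim_panel


def stage_qc(config: PipelineConfig, out: Path) -> None:
    panel, samples, genotypes, _, _ = _load_stage_inputs(config, out)
    qcdir = out / "qc"
    qcdir.mkdir(exist_ok=True)
    filtered, report = qc_filter(
        genotypes, snp_call_min=config.qc.snp_call_min,
        sample_call_min=config.qc.sample_call_min,
        hwe_alpha=config.qc.hwe_alpha,
        drop_monomorphic=config.qc.drop_monomorphic,
        samples=samples, hwe_method=config.qc.hwe_method)
    # duplicate handling: any "<id>_dup" sample is checked against its source
    # for concordance and then dropped (the study kept one of each pair)
    dup_ids = [s for s in filtered.sample_ids if s.endswith("_dup")]
    sidx = {s: i for i, s in enumerate(filtered.sample_ids)}
    for dup in dup_ids:
        src = dup[:-len("_dup")]
        if src in sidx:
            conc = duplicate_concordance(filtered.dosage[sidx[src]],
                                         filtered.dosage[sidx[dup]])
            report.duplicate_concordances.append((src, dup, conc))
            report.removed_samples.append((dup, "duplicate"))
    if dup_ids:
        filtered = filtered.subset_samples(
            [s for s in filtered.sample_ids if not s.endswith("_dup")])
    report.to_tsv(qcdir / "report.tsv")
    pd.DataFrame([{"sample_id": s, "dup_id": d,
                   "concordance": "NA" if c is None else f"{c:.6f}"}
                  for s, d, c in report.duplicate_concordances]).to_csv(
        qcdir / "duplicates.tsv", sep="\t", index=False)
    filtered.to_dosage_tsv(qcdir / "dosages.tsv")
    kept = set(filtered.sample_ids)
    write_samples(samples[samples["sample_id"].isin(kept)],
                  qcdir / "samples.tsv")
    log.info("qc: kept %d/%d samples, %d/%d variants",
             filtered.n_samples, genotypes.n_samples,
             filtered.n_variants, genotypes.n_variants)


def stage_ancestry(config: PipelineConfig, out: Path) -> None:
    _, _, _, aim, aim_panel = _load_stage_inputs(config, out)
    samples = read_samples(out / "qc" / "samples.tsv")
    adir = out / "ancestry"
    adir.mkdir(exist_ok=True)
    if not config.ancestry.enabled or aim is None or aim_panel is None:
        samples = samples.copy()
        # no marker data: fall back to declared ancestry labels
        samples["ancestry_label"] = samples["ancestry"].map(
            {"EUR": "EA", "AFR": "AA"}).fillna("OTHER")
        write_samples(samples, adir / "samples.tsv")
        log.info("ancestry: skipped (no AIM data); using declared labels")
        return
    aim_sub = aim.subset_samples(
        [s for s in aim.sample_ids if s in set(samples["sample_id"])])
    ancs = [a for a in config.ancestry.ancestries
            if a in aim_panel.ancestries]
    res = estimate_admixture_matrix(aim_sub, aim_panel, ancs,
                                    tol=config.ancestry.tol,
                                    max_iter=config.ancestry.max_iter)
    res.to_csv(adir / "ancestry.tsv", sep="\t", index=False,
               float_format="%.6f")
    merged = samples.merge(res[["sample_id", "label"]], on="sample_id")
    merged = merged.rename(columns={"label": "ancestry_label"})
    write_samples(merged, adir / "samples.tsv")
    log.info("ancestry: %s", res["label"].value_counts().to_dict())


def stage_score(config: PipelineConfig, out: Path) -> None:
    if config.simulation is not None:
        panel = SNPPanel.from_tsv(out / "panel.tsv")
    else:
        panel = SNPPanel.from_tsv(config.inputs.panel_tsv)
    genotypes = GenotypeMatrix.from_dosage_tsv(out / "qc" / "dosages.tsv")
    samples = read_samples(out / "ancestry" / "samples.tsv")
    sdir = out / "scores"
    sdir.mkdir(exist_ok=True)
    scores = scoring.score_samples(genotypes, panel,
                                   missing_policy=config.scoring.missing_policy)
    scores = scores.merge(samples[["sample_id", "phenotype", "ancestry_label"]],
                          on="sample_id")
    for group in ("EA", "AA"):
        sub = scores[scores["ancestry_label"] == group]
        if not len(sub):
            continue
        ctl_scores = sub.loc[sub["phenotype"] == CONTROL,
                             "prs_weighted"].to_numpy(float)
        if group == "EA" and config.scoring.use_external_cutoffs:
            cutoffs = scoring.ea_reference_cutoffs()
        else:
            if len(np.unique(ctl_scores)) < 5:
                log.warning("score: too few %s controls for internal cutoffs",
                            group)
                continue
            cutoffs = scoring.reference_cutoffs(ctl_scores)
        cutoffs.to_json(sdir / f"cutoffs_{group}.json")
        sub = sub.copy()
        sub["quantile_category"] = [
            scoring.assign_quantile(s, cutoffs)
            for s in sub["prs_weighted"].to_numpy(float)]
        thresh = scoring.top_percentile_threshold(
            ctl_scores, config.scoring.top_percentile)
        sub["top_percentile_flag"] = sub["prs_weighted"] >= thresh
        sub.to_csv(sdir / f"scores_{group}.tsv", sep="\t", index=False,
                   float_format="%.6f")
        log.info("score: %s n=%d, cutoffs %s", group, len(sub),
                 np.round(cutoffs.boundaries, 3).tolist())


def _full_table(sub: pd.DataFrame, case_label: str, reference: str,
                top_percentile: float) -> pd.DataFrame:
    """Quintile + top-percentile + continuous + median + c-statistic rows."""
    y = (sub["phenotype"] != CONTROL).to_numpy(float)
    age = sub["age"].to_numpy(float)
    male = is_male(sub)
    prs = sub["prs_weighted"].to_numpy(float)
    prs_u = sub["prs_unweighted"].to_numpy(float)
    table = assoc.quintile_association(
        sub["quantile_category"].to_numpy(), y, age, male, reference=reference)
    rows = [table]

    top = sub["top_percentile_flag"].to_numpy(bool)
    in_ref = (sub["quantile_category"] == reference).to_numpy()
    keep = top | in_ref
    pct_cases_top = 100.0 * top[y == 1].mean() if (y == 1).any() else math.nan
    if keep.sum() and np.unique(y[keep]).size == 2 and top[keep].any():
        fit = assoc.fit_logistic(
            y[keep], np.column_stack([np.ones(keep.sum()),
                                      top[keep].astype(float),
                                      age[keep], male[keep]]),
            ["intercept", "top", "age", "male"])
        orr, lo, hi, p = assoc.odds_ratio_wald(fit, "top")
    else:
        orr = lo = hi = p = math.nan
    rows.append(pd.DataFrame([{
        "row": f"{int(top_percentile * 100)}th percentile vs {reference}",
        "pct_cases": pct_cases_top, "odds_ratio": orr, "ci_low": lo,
        "ci_high": hi, "p_value": p}]))

    cont_row, cont_fit = assoc.continuous_association(prs, y, age, male)
    rows.append(pd.DataFrame([cont_row]))
    cont_u_row, cont_u_fit = assoc.continuous_association(
        prs_u, y, age, male, label="Continuous unweighted")
    rows.append(pd.DataFrame([cont_u_row]))

    med_case = float(np.median(prs[y == 1])) if (y == 1).any() else math.nan
    med_ctl = float(np.median(prs[y == 0])) if (y == 0).any() else math.nan
    rows.append(pd.DataFrame([{"row": "PRS (median)",
                               "median_cases": med_case,
                               "median_controls": med_ctl}]))
    for label, fit in (("c-statistic", cont_fit),
                       ("c-statistic unweighted", cont_u_fit)):
        X = np.column_stack([np.ones(len(y)),
                             prs if label == "c-statistic" else prs_u,
                             age, male])
        try:
            auc, lo, hi = assoc.c_statistic(fit.predict(X), y)
        except Exception:
            auc = lo = hi = math.nan
        rows.append(pd.DataFrame([{"row": label, "odds_ratio": math.nan,
                                   "c_statistic": auc, "ci_low": lo,
                                   "ci_high": hi}]))
    out = pd.concat(rows, ignore_index=True)
    out.insert(0, "contrast", case_label)
    return out


def stage_associate(config: PipelineConfig, out: Path) -> dict:
    samples = read_samples(out / "ancestry" / "samples.tsv")
    adir = out / "assoc"
    adir.mkdir(exist_ok=True)
    counts: dict = {}
    ref = config.models.reference_quantile

    def load_scores(group):
        path = out / "scores" / f"scores_{group}.tsv"
        if not path.exists():
            return None
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        return df.merge(samples[["sample_id", "age", "sex"]], on="sample_id")

    ea = load_scores("EA")
    if ea is not None:
        present = set(ea["phenotype"])
        contrasts = {}
        if {"LC_MBL", "HC_MBL"} & present:
            contrasts["mbl"] = [c for c in ("LC_MBL", "HC_MBL") if c in present]
        for c in ("LC_MBL", "HC_MBL", "CLL"):
            if c in present:
                contrasts[c.lower()] = [c]
        tables = []
        for name, cases in contrasts.items():
            sub = ea[ea["phenotype"].isin([CONTROL] + cases)]
            tables.append(_full_table(sub, name, ref,
                                      config.scoring.top_percentile))
        if tables:
            pd.concat(tables, ignore_index=True).to_csv(
                adir / "tables_EA.tsv", sep="\t", index=False,
                float_format="%.6g")
        case_cats = [c for c in ("LC_MBL", "HC_MBL", "CLL") if c in present]
        extras = {}
        if len(case_cats) >= 2:
            het = assoc.heterogeneity_test(
                ea["phenotype"].to_numpy(), ea["prs_weighted"].to_numpy(float),
                ea["age"].to_numpy(float), is_male(ea), case_order=case_cats)
            extras["heterogeneity"] = {
                "lrt": het.lrt_statistic, "df": het.df, "p": het.p_het,
                "slopes": het.slopes.to_dict(orient="records")}
        groups = [ea.loc[ea["phenotype"] == c, "prs_weighted"].to_numpy(float)
                  for c in [CONTROL] + case_cats]
        h, p = assoc.kruskal_wallis(groups)
        extras["kruskal_wallis"] = {"H": h, "p": p,
                                    "groups": [CONTROL] + case_cats}
        with open(adir / "trend_EA.json", "w") as fh:
            json.dump(extras, fh, indent=1)
        if config.models.per_snp and (out / "qc" / "dosages.tsv").exists():
            geno = GenotypeMatrix.from_dosage_tsv(out / "qc" / "dosages.tsv")
            sub = ea[ea["phenotype"].isin(
                [CONTROL] + [c for c in ("LC_MBL", "HC_MBL") if c in present])]
            gsub = geno.subset_samples(
                [s for s in geno.sample_ids
                 if s in set(sub["sample_id"])])
            ordered = sub.set_index("sample_id").loc[gsub.sample_ids]
            assoc.per_snp_association(
                gsub, (ordered["phenotype"] != CONTROL).to_numpy(float),
                ordered["age"].to_numpy(float),
                (ordered["sex"] == "M").to_numpy(float)).to_csv(
                adir / "per_snp_EA.tsv", sep="\t", index=False,
                float_format="%.6g")
        counts["ea_analyzed"] = int(len(ea))

    aa = load_scores("AA")
    if aa is not None and "CLL" in set(aa["phenotype"]):
        n_case = int((aa["phenotype"] == "CLL").sum())
        n_ctl = int((aa["phenotype"] == CONTROL).sum())
        if (n_case >= config.models.min_aa_cases
                and n_ctl >= config.models.min_aa_controls):
            sub = aa[aa["phenotype"].isin([CONTROL, "CLL"])]
            _full_table(sub, "cll_aa", ref,
                        config.scoring.top_percentile).to_csv(
                adir / "tables_AA.tsv", sep="\t", index=False,
                float_format="%.6g")
            counts["aa_analyzed"] = int(len(sub))
    return counts


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the output directory.

    Deterministic given the config (including its seed): outputs carry no
    timestamps, so identical runs are byte-identical.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    if config.simulation is not None:
        stage_simulate(config, out)
    stage_qc(config, out)
    stage_ancestry(config, out)
    stage_score(config, out)
    counts = stage_associate(config, out)
    manifest = {
        "package": "cllprs", "version": __version__,
        "seed": config.seed, "config_hash": config.config_hash(),
        "config": config.model_dump(mode="json"),
        "stage_counts": _stage_counts(out) | counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


def _stage_counts(out: Path) -> dict:
    counts = {}
    for name, path in (("input_samples", out / "samples.tsv"),
                       ("qc_samples", out / "qc" / "samples.tsv"),
                       ("ancestry_samples", out / "ancestry" / "samples.tsv")):
        if path.exists():
            with open(path) as fh:
                counts[name] = sum(1 for _ in fh) - 1
    return counts


# ---------------------------------------------------------------------------
# Demo fixtures
# ---------------------------------------------------------------------------

def make_demo_fixtures(seed: int, out_dir) -> Path:
    """Write a small, fully reproducible fixture set (<=200 samples, 41 SNPs).

    European-ancestry only, clean genotypes (no injected artifacts), so the
    set passes QC untouched and is scorable against the shipped reference
    cutoffs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .simdata import EA_CONTROL_PRS_ANCHOR
    panel = make_panel(41, seed=seed, anchor=("EUR", EA_CONTROL_PRS_ANCHOR))
    sc = SimulationConfig(
        n_per_group={CONTROL: 120, "LC_MBL": 30, "HC_MBL": 20, "CLL": 30},
        ancestry_mix={"EUR": 1.0}, seed=seed)
    study = simulate_study(panel, sc)
    panel.to_tsv(out / "panel.tsv")
    write_samples(study.samples, out / "samples.tsv")
    write_vcf(study.genotypes, panel, out / "genotypes.vcf")
    study.genotypes.to_dosage_tsv(out / "dosages.tsv")
    return out
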