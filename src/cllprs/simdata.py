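"""Synthetic genotype-phenotype generator emulating a CLL/MBL case-control study.

Generates a SNP weight panel, Hardy-Weinberg genotypes with ancestry-specific
risk-allele frequencies, age/sex covariates, and a four-category outcome
(control / LC_MBL / HC_MBL / CLL) under a multinomial-logit model with graded
per-unit PRS effects. Case-control sampling to exact group sizes matches the
study design the downstream models assume; an artifact injector adds
missingness, Hardy-Weinberg distortions, duplicates, and monomorphic variants
so the QC stage has something real to remove.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError, SimulationError
from .genotypes import GenotypeMatrix
from .panel import FREQ_PREFIX, SNPPanel
from .rng import substream
from .samples import CONTROL, validate_samples

# Default study conditions: EA cohort group sizes and printed per-unit PRS
# effects for the three case categories; age effect ~ OR 1.8 per decade and
# sex effect OR 1.73 for male, on the log-odds scale.
DEFAULT_N_PER_GROUP = {CONTROL: 2631, "LC_MBL": 396, "HC_MBL": 164, "CLL": 696}
DEFAULT_SLOPES = {"LC_MBL": math.log(1.75), "HC_MBL": math.log(2.14),
                  "CLL": math.log(2.53)}
DEFAULT_INTERCEPTS = {"LC_MBL": -2.0, "HC_MBL": -3.0, "CLL": -2.0}
DEFAULT_WEIGHT_RANGE = (math.log(1.05), math.log(1.46))
#: printed control median of the published 41-SNP score; panels anchored to
#: this value keep the shipped external quintile cutoffs meaningful
EA_CONTROL_PRS_ANCHOR = 7.46
DEFAULT_FREQ_RANGES = {"EUR": (0.15, 0.70), "AFR": (0.08, 0.62),
                       "EAS": (0.10, 0.65)}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Effects are on the natural-log odds scale of a multinomial logit with
    ``control`` as the baseline category: log-odds(category c vs control) =
    intercept_c + slope_c * (PRS - E[PRS]) + age_effect * (age - 60)
    + sex_effect * (male - 1/2). Centering makes the intercepts interpretable
    as approximate log-odds for an average individual.
    """

    n_snps: int = 41
    n_per_group: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_GROUP))
    ancestry_mix: dict[str, float] = field(default_factory=lambda: {"EUR": 1.0})
    category_intercepts: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTERCEPTS))
    category_prs_slopes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SLOPES))
    age_effect: float = 0.06          # per year
    sex_effect: float = math.log(1.73)  # male vs female
    age_distribution: tuple[float, float, float, float] = (64.0, 10.0, 30.0, 100.0)
    male_fraction: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.ancestry_mix.values()) - 1.0) > 1e-8:
            raise ConfigurationError("ancestry_mix proportions must sum to 1")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ConfigurationError("group sizes must be >= 0")
        if CONTROL not in self.n_per_group:
            raise ConfigurationError(f"n_per_group must include {CONTROL!r}")
        cases = [c for c in self.n_per_group if c != CONTROL]
        if not cases:
            raise ConfigurationError("need at least one case category")
        for c in cases:
            if c not in self.category_intercepts or c not in self.category_prs_slopes:
                raise ConfigurationError(
                    f"missing intercept or slope for category {c!r}")
            if not math.isfinite(self.category_prs_slopes[c]):
                raise ConfigurationError(f"non-finite slope for {c!r}")
        mean, sd, lo, hi = self.age_distribution
        if sd <= 0 or lo >= hi:
            raise ConfigurationError("invalid age distribution")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ConfigurationError("male_fraction must be in [0, 1]")

    @property
    def case_categories(self) -> list[str]:
        return [c for c in self.n_per_group if c != CONTROL]


@dataclass
class ArtifactSpec:
    """QC artifacts to inject: missingness, HWE distortion, duplicates,
    monomorphic variants.

    ``hwe_violation_snps`` uses an inbreeding-like coefficient F with
    P(het) = 2f(1-f)(1-F): F > 0 gives a heterozygote deficit, F < 0 an
    excess.
    """

    snp_missing_rates: dict[str, float] = field(default_factory=dict)
    sample_missing_rates: dict[str, float] = field(default_factory=dict)
    hwe_violation_snps: list[tuple[str, float]] = field(default_factory=list)
    duplicate_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    monomorphic_snps: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rate in list(self.snp_missing_rates.values()) + \
                list(self.sample_missing_rates.values()) + \
                [d for _, _, d in self.duplicate_pairs]:
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"rate {rate} outside [0, 1]")
        for vid, f_coef in self.hwe_violation_snps:
            if not -1.0 <= f_coef <= 1.0:
                raise ConfigurationError(
                    f"distortion parameter {f_coef} for {vid} outside [-1, 1]")


# ---------------------------------------------------------------------------
# Panels
# ---------------------------------------------------------------------------

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def make_panel(n_snps: int,
               weight_range: tuple[float, float] = DEFAULT_WEIGHT_RANGE,
               freq_ranges: dict[str, tuple[float, float]] | None = None,
               seed: int = 0, prefix: str = "rs",
               anchor: tuple[str, float] | None = None) -> SNPPanel:
    """Draw a synthetic SNP weight panel.

    Weights are uniform on ``weight_range`` (log-OR scale); risk-allele
    frequencies are uniform per ancestry on ``freq_ranges``. Defaults place
    the expected PRS of a European-ancestry control near 7.5 with SD near 1,
    the scale of the published 41-SNP CLL score.

    ``anchor=(ancestry, value)`` rescales the drawn weights by a single
    constant so the expected HWE score in that ancestry equals ``value``
    exactly: it pins each random panel to the published score scale so
    externally derived quantile cutoffs stay meaningful. The rescale factor
    is close to 1, but anchored weights can land slightly outside
    ``weight_range``.
    """
    if n_snps < 0:
        raise ConfigurationError("n_snps must be >= 0")
    if weight_range[0] > weight_range[1]:
        raise ConfigurationError("weight_range lo > hi")
    freq_ranges = freq_ranges if freq_ranges is not None else DEFAULT_FREQ_RANGES
    for anc, (lo, hi) in freq_ranges.items():
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError(f"invalid frequency range for {anc}")
    rng = substream(seed, "make_panel")
    bases = np.array(list("ACGT"))
    risk_idx = rng.integers(0, 4, size=n_snps)
    # other allele: never the risk allele and never its strand complement,
    # so synthetic panels contain no palindromic (A/T, C/G) variants
    other = np.empty(n_snps, dtype="<U1")
    risk = bases[risk_idx]
    for i, r in enumerate(risk):
        choices = [b for b in "ACGT" if b != r and b != _COMPLEMENT[r]]
        other[i] = choices[rng.integers(0, len(choices))]
    table = pd.DataFrame({
        "variant_id": [f"{prefix}{i + 1:06d}" for i in range(n_snps)],
        "chrom": [str(1 + (i % 22)) for i in range(n_snps)],
        "pos": [100_000 + 10_000 * i for i in range(n_snps)],
        "risk_allele": risk,
        "other_allele": other,
        "weight_log_or": rng.uniform(*weight_range, size=n_snps),
    })
    for anc, (lo, hi) in freq_ranges.items():
        table[FREQ_PREFIX + anc] = rng.uniform(lo, hi, size=n_snps)
    if anchor is not None and n_snps > 0:
        anc, target = anchor
        if anc not in freq_ranges:
            raise ConfigurationError(f"anchor ancestry {anc!r} has no "
                                     "frequency range")
        expected = float((table["weight_log_or"]
                          * 2.0 * table[FREQ_PREFIX + anc]).sum())
        if expected <= 0:
            raise ConfigurationError("cannot anchor a zero-weight panel")
        table["weight_log_or"] *= target / expected
    return SNPPanel(table)


def make_aim_panel(n_snps: int = 300, fst: float = 0.15,
                   ancestries: tuple[str, ...] = ("EUR", "AFR", "EAS"),
                   seed: int = 0) -> SNPPanel:
    """Ancestry-informative marker panel under the Balding-Nichols model.

    Each variant has an ancestral frequency p ~ U(0.1, 0.9); per-ancestry
    frequencies are Beta(p(1-Fst)/Fst, (1-p)(1-Fst)/Fst) draws, giving the
    between-population differentiation the admixture estimator needs.
    Weights are zero: AIMs carry no risk information.
    """
    if not 0.0 < fst < 1.0:
        raise ConfigurationError("fst must be in (0, 1)")
    rng = substream(seed, "make_aim_panel")
    p = rng.uniform(0.1, 0.9, size=n_snps)
    shape = (1.0 - fst) / fst
    table = pd.DataFrame({
        "variant_id": [f"aim{i + 1:06d}" for i in range(n_snps)],
        "chrom": [str(1 + (i % 22)) for i in range(n_snps)],
        "pos": [50_000_000 + 10_000 * i for i in range(n_snps)],
        "risk_allele": "A",
        "other_allele": "C",
        "weight_log_or": 0.0,
    })
    for anc in ancestries:
        f = rng.beta(p * shape, (1.0 - p) * shape)
        table[FREQ_PREFIX + anc] = np.clip(f, 1e-4, 1.0 - 1e-4)
    return SNPPanel(table)


def expected_prs(panel: SNPPanel, ancestry_mix: dict[str, float]) -> float:
    """E[PRS] under HWE for the given ancestry mixture (weighted sum score)."""
    if len(panel) == 0:
        return 0.0
    f_mix = sum(prop * panel.freqs(anc) for anc, prop in ancestry_mix.items())
    return float(np.sum(panel.weights * 2.0 * f_mix))


# ---------------------------------------------------------------------------
# Genotypes and covariates
# ---------------------------------------------------------------------------

def simulate_genotypes(panel: SNPPanel, samples: pd.DataFrame,
                       seed: int = 0) -> GenotypeMatrix:
    """Binomial(2, f) dosages per variant, using each sample's ancestry.

    Variants are independent (no linkage disequilibrium) and in
    Hardy-Weinberg proportions within ancestry.
    """
    if "ancestry" not in samples.columns:
        raise InputError("sample table must have an 'ancestry' column")
    known = set(panel.ancestries)
    unknown = set(samples["ancestry"]) - known
    if unknown:
        raise InputError(f"ancestry labels not in panel: {sorted(unknown)}")
    rng = substream(seed, "simulate_genotypes")
    n, m = len(samples), len(panel)
    dosage = np.empty((n, m))
    for anc in sorted(set(samples["ancestry"])):
        rows = (samples["ancestry"] == anc).to_numpy()
        f = panel.freqs(anc)
        dosage[rows] = rng.binomial(2, f, size=(int(rows.sum()), m))
    return GenotypeMatrix(samples["sample_id"].tolist(), panel.variant_ids,
                          dosage)


def draw_covariates(n: int, config: SimulationConfig, seed: int = 0,
                    id_offset: int = 0) -> pd.DataFrame:
    """Ages (truncated normal), sexes, and discrete ancestry labels."""
    rng = substream(seed, f"draw_covariates:{id_offset}")
    mean, sd, lo, hi = config.age_distribution
    a, b = (lo - mean) / sd, (hi - mean) / sd
    ages = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n,
                               random_state=rng)
    males = rng.random(n) < config.male_fraction
    ancs = sorted(config.ancestry_mix)
    probs = np.array([config.ancestry_mix[a_] for a_ in ancs])
    labels = rng.choice(ancs, size=n, p=probs / probs.sum())
    return pd.DataFrame({
        "sample_id": [f"S{id_offset + i + 1:07d}" for i in range(n)],
        "age": np.round(ages, 1),
        "sex": np.where(males, "M", "F"),
        "phenotype": CONTROL,
        "cohort": "simulated",
        "ancestry": labels,
    })


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def category_probabilities(prs: np.ndarray, age: np.ndarray, male: np.ndarray,
                           config: SimulationConfig,
                           prs_center: float) -> tuple[list[str], np.ndarray]:
    """Multinomial-logit category probabilities, control as baseline."""
    cases = config.case_categories
    eta = np.zeros((len(prs), 1 + len(cases)))
    for k, c in enumerate(cases, start=1):
        eta[:, k] = (config.category_intercepts[c]
                     + config.category_prs_slopes[c] * (prs - prs_center)
                     + config.age_effect * (age - 60.0)
                     + config.sex_effect * (male - 0.5))
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    return [CONTROL] + cases, p


def simulate_phenotypes(genotypes: GenotypeMatrix, panel: SNPPanel,
                        samples: pd.DataFrame, config: SimulationConfig,
                        seed: int = 0) -> pd.DataFrame:
    """Assign outcome categories to every sample by the multinomial logit.

    Returns a copy of ``samples`` with the ``phenotype`` column filled; exact
    group sizes are the business of :func:`simulate_study`, which rejection-
    samples over repeated calls.
    """
    rng = substream(seed, "simulate_phenotypes")
    prs = genotypes.dosage @ panel.weights  # pool genotypes are complete
    center = expected_prs(panel, config.ancestry_mix)
    male = (samples["sex"] == "M").to_numpy(float)
    cats, p = category_probabilities(prs, samples["age"].to_numpy(float),
                                     male, config, center)
    u = rng.random(len(samples))
    idx = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
    out = samples.copy()
    out["phenotype"] = [cats[i] for i in idx]
    return out


@dataclass
class StudyData:
    """A complete simulated study: genotypes, sample table, optional AIMs."""

    genotypes: GenotypeMatrix
    samples: pd.DataFrame
    aim_genotypes: GenotypeMatrix | None = None


def simulate_study(panel: SNPPanel, config: SimulationConfig,
                   aim_panel: SNPPanel | None = None,
                   artifact_spec: ArtifactSpec | None = None,
                   max_oversample: int = 100) -> StudyData:
    """Case-control sample to exact group sizes.

    Draws pools of individuals, assigns categories under the generative
    model, and keeps the first ``n_per_group[c]`` of each category in draw
    order. Raises :class:`SimulationError` if the targets are not met after
    ``max_oversample`` times the total target size has been drawn.
    """
    targets = {c: int(n) for c, n in config.n_per_group.items()}
    total = sum(targets.values())
    kept: dict[str, list[pd.DataFrame]] = {c: [] for c in targets}
    kept_geno: dict[str, list[np.ndarray]] = {c: [] for c in targets}
    counts = {c: 0 for c in targets}
    drawn = 0
    chunk_i = 0
    chunk = max(4 * total, 2000)
    while any(counts[c] < targets[c] for c in targets):
        if drawn >= max_oversample * total:
            deficit = {c: targets[c] - counts[c] for c in targets
                       if counts[c] < targets[c]}
            raise SimulationError(
                f"could not reach group sizes after drawing {drawn} "
                f"individuals (cap {max_oversample}x); still short: {deficit}. "
                "Increase intercepts of the deficient categories.")
        pool = draw_covariates(chunk, config, seed=config.seed,
                               id_offset=drawn)
        geno = simulate_genotypes(panel, pool, seed=config.seed + chunk_i)
        pool = simulate_phenotypes(geno, panel, pool, config,
                                   seed=config.seed + chunk_i)
        for c in targets:
            need = targets[c] - counts[c]
            if need <= 0:
                continue
            rows = np.flatnonzero((pool["phenotype"] == c).to_numpy())[:need]
            if rows.size:
                kept[c].append(pool.iloc[rows])
                kept_geno[c].append(geno.dosage[rows])
                counts[c] += rows.size
        drawn += chunk
        chunk_i += 1
    order = [CONTROL] + config.case_categories
    samples = pd.concat([pd.concat(kept[c]) for c in order if kept[c]],
                        ignore_index=True)
    dosage = np.vstack([np.vstack(kept_geno[c]) for c in order if kept_geno[c]])
    genotypes = GenotypeMatrix(samples["sample_id"].tolist(),
                               panel.variant_ids, dosage)
    validate_samples(samples)
    aim_geno = None
    if aim_panel is not None:
        aim_geno = simulate_genotypes(aim_panel, samples,
                                      seed=config.seed + 900_001)
    if artifact_spec is not None:
        genotypes, samples = inject_artifacts(genotypes, artifact_spec,
                                              seed=config.seed,
                                              samples=samples)
    return StudyData(genotypes, samples, aim_geno)


# ---------------------------------------------------------------------------
# Artifacts
# ---------------------------------------------------------------------------

def inject_artifacts(genotypes: GenotypeMatrix, spec: ArtifactSpec,
                     seed: int = 0,
                     samples: pd.DataFrame | None = None
                     ) -> GenotypeMatrix | tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the artifact spec to a genotype matrix.

    Order: HWE distortion and monomorphic overwrites first (they regenerate
    calls), then missingness, then duplicate rows are appended. If a sample
    table is given, duplicate rows are appended to it too and both are
    returned.
    """
    rng = substream(seed, "inject_artifacts")
    g = genotypes.copy()
    vidx = {v: j for j, v in enumerate(g.variant_ids)}
    sidx = {s: i for i, s in enumerate(g.sample_ids)}

    for vid, f_coef in spec.hwe_violation_snps:
        if vid not in vidx:
            raise InputError(f"unknown variant id {vid!r}")
        j = vidx[vid]
        col = g.dosage[:, j]
        called = ~np.isnan(col)
        f = float(np.nanmean(col)) / 2.0
        p_het = 2.0 * f * (1.0 - f) * (1.0 - f_coef)
        p_hom_risk = f * f + f * (1.0 - f) * f_coef
        p_hom_other = 1.0 - p_het - p_hom_risk
        probs = np.array([p_hom_other, p_het, p_hom_risk])
        if (probs < -1e-12).any():
            raise ConfigurationError(
                f"distortion {f_coef} infeasible at frequency {f:.3f}")
        probs = np.clip(probs, 0.0, 1.0)
        probs /= probs.sum()
        col[called] = rng.choice([0.0, 1.0, 2.0], size=int(called.sum()),
                                 p=probs)

    for vid in spec.monomorphic_snps:
        if vid not in vidx:
            raise InputError(f"unknown variant id {vid!r}")
        j = vidx[vid]
        col = g.dosage[:, j]
        called = ~np.isnan(col)
        if called.any():
            vals, cnts = np.unique(col[called], return_counts=True)
            col[called] = vals[np.argmax(cnts)]

    for vid, rate in spec.snp_missing_rates.items():
        if vid not in vidx:
            raise InputError(f"unknown variant id {vid!r}")
        j = vidx[vid]
        mask = rng.random(g.n_samples) < rate
        g.dosage[mask, j] = np.nan
    for sid, rate in spec.sample_missing_rates.items():
        if sid not in sidx:
            raise InputError(f"unknown sample id {sid!r}")
        i = sidx[sid]
        mask = rng.random(g.n_variants) < rate
        g.dosage[i, mask] = np.nan

    dup_rows, dup_ids = [], []
    for src, new_id, disc in spec.duplicate_pairs:
        if src not in sidx:
            raise InputError(f"unknown sample id {src!r}")
        row = g.dosage[sidx[src]].copy()
        flip = (rng.random(g.n_variants) < disc) & ~np.isnan(row)
        for j in np.flatnonzero(flip):
            alts = [v for v in (0.0, 1.0, 2.0) if v != row[j]]
            row[j] = alts[rng.integers(0, 2)]
        dup_rows.append(row)
        dup_ids.append(new_id)
    if dup_rows:
        g = GenotypeMatrix(g.sample_ids + dup_ids, g.variant_ids,
                           np.vstack([g.dosage] + [r[None] for r in dup_rows]))

    if samples is not None:
        if dup_ids:
            src_rows = samples.set_index("sample_id").loc[
                [s for s, _, _ in spec.duplicate_pairs]].reset_index()
            src_rows["sample_id"] = dup_ids
            samples = pd.concat([samples, src_rows], ignore_index=True)
        return g, samples
    return g
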