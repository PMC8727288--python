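"""Inferential machinery for PRS case-control analysis.

Logistic regression by iteratively reweighted least squares (IRLS) with Wald
intervals, quintile and continuous association tables with a middle-quintile
reference, per-SNP log-additive models, a polytomous (multinomial)
heterogeneity likelihood-ratio test of PRS-slope equality across outcome
categories, the ROC c-statistic with a Hanley-McNeil confidence interval,
Kruskal-Wallis, and crude 2x2 machinery for exposure screens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .errors import InputError
from .genotypes import GenotypeMatrix
from .samples import CONTROL

Z95 = 1.959964  # two-sided 95% normal quantile

_ETA_CLIP = 30.0
_SEPARATION_BETA = 15.0


# ---------------------------------------------------------------------------
# Binary logistic regression (IRLS)
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """Maximum-likelihood logistic fit with Wald covariance."""

    names: list[str]
    beta: np.ndarray
    cov: np.ndarray = field(repr=False)
    log_likelihood: float
    n_iterations: int
    converged: bool
    n_used: int
    separated: bool = False

    def coef(self, term: str) -> float:
        return float(self.beta[self.names.index(term)])

    def se(self, term: str) -> float:
        i = self.names.index(term)
        return float(np.sqrt(self.cov[i, i]))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return expit(np.asarray(X, float) @ self.beta)


def _bernoulli_ll(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically safe log-likelihood: -log(1 + exp(-(2y-1) eta))
    s = (2.0 * y - 1.0) * eta
    return float(-np.logaddexp(0.0, -s).sum())


def fit_logistic(outcome: np.ndarray, design: np.ndarray,
                 names: list[str] | None = None, tol: float = 1e-10,
                 max_iter: int = 100) -> ModelFit:
    """IRLS logistic regression with step-halving.

    ``design`` must include the intercept column. Deviance is non-increasing
    across iterations (Newton steps are halved until the likelihood
    improves); the Wald covariance is the inverse observed information at
    the optimum. Complete or quasi-complete separation is detected by
    diverging coefficients and flagged -- estimates for such fits are not
    trustworthy and downstream reporting marks them non-estimable.
    """
    y = np.asarray(outcome, float)
    X = np.asarray(design, float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise InputError("design matrix not aligned to outcome")
    if not np.isin(y, (0.0, 1.0)).all():
        raise InputError("outcome must be binary 0/1")
    n, d = X.shape
    names = names or [f"x{j}" for j in range(d)]
    if y.min() == y.max():
        return ModelFit(names, np.full(d, np.nan), np.full((d, d), np.nan),
                        0.0, 0, False, n, separated=True)
    beta = np.zeros(d)
    ll = _bernoulli_ll(y, X @ beta)
    converged = False
    H = np.eye(d)
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        score = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            delta = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            break
        step = 1.0
        for _ in range(40):
            cand = beta + step * delta
            ll_new = _bernoulli_ll(y, X @ cand)
            if ll_new >= ll - 1e-14:
                break
            step *= 0.5
        beta = beta + step * delta
        if ll_new - ll < tol and np.abs(step * delta).max() < 1e-8:
            ll = max(ll, ll_new)
            converged = True
            break
        ll = ll_new
    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((d, d), np.nan)
    separated = bool(np.abs(beta).max() > _SEPARATION_BETA)
    return ModelFit(names, beta, cov, ll, it, converged and not separated,
                    n, separated=separated)


def odds_ratio_wald(fit: ModelFit, term: str, scale: float = 1.0
                    ) -> tuple[float, float, float, float]:
    """(OR, CI low, CI high, two-sided Wald p) for ``scale`` units of a term."""
    if term not in fit.names:
        raise InputError(f"term {term!r} not in fit")
    b, se = fit.coef(term), fit.se(term)
    if fit.separated or not np.isfinite(b) or not np.isfinite(se):
        return (math.nan, math.nan, math.nan, math.nan)
    if se == 0.0:
        orr = math.exp(scale * b)
        return (orr, orr, orr, 0.0 if b != 0 else 1.0)
    z = b / se
    p = 2.0 * stats.norm.sf(abs(z))
    return (math.exp(scale * b),
            math.exp(scale * (b - Z95 * se)),
            math.exp(scale * (b + Z95 * se)),
            float(p))


# ---------------------------------------------------------------------------
# Multinomial (polytomous) logistic regression
# ---------------------------------------------------------------------------

@dataclass
class MultinomialFit:
    """Baseline-category multinomial logit fit (control is the baseline)."""

    categories: list[str]        # case categories, baseline excluded
    names: list[str]             # design column names
    B: np.ndarray                # C x d coefficients
    cov: np.ndarray = field(repr=False)  # n_free x n_free, free-param order
    param_index: np.ndarray = field(repr=False)  # C x d -> free index
    log_likelihood: float
    n_iterations: int
    converged: bool


def fit_multinomial(y_codes: np.ndarray, design: np.ndarray,
                    categories: list[str], names: list[str] | None = None,
                    shared_cols: tuple[int, ...] = (),
                    tol: float = 1e-10, max_iter: int = 200
                    ) -> MultinomialFit:
    """Newton fit of a baseline-category multinomial logit.

    ``y_codes`` holds 0 for the baseline (control) and 1..C for case
    categories. Columns listed in ``shared_cols`` have a single coefficient
    shared across all case categories (the constrained model of the
    heterogeneity test); all other columns are category-specific.
    """
    y = np.asarray(y_codes, int)
    X = np.asarray(design, float)
    n, d = X.shape
    C = len(categories)
    if y.min() < 0 or y.max() > C:
        raise InputError("category codes out of range")
    names = names or [f"x{j}" for j in range(d)]
    # map (category, column) -> free parameter index
    param_index = np.zeros((C, d), dtype=int)
    n_free = 0
    shared_idx: dict[int, int] = {}
    for j in range(d):
        if j in shared_cols:
            shared_idx[j] = n_free
            n_free += 1
    for c in range(C):
        for j in range(d):
            if j in shared_cols:
                param_index[c, j] = shared_idx[j]
            else:
                param_index[c, j] = n_free
                n_free += 1
    Y = np.zeros((n, C))
    for c in range(C):
        Y[:, c] = (y == c + 1)

    def unpack(theta: np.ndarray) -> np.ndarray:
        return theta[param_index]

    def nll(theta: np.ndarray) -> float:
        eta = X @ unpack(theta).T                        # n x C
        m = np.maximum(0.0, eta.max(axis=1))
        lse = m + np.log(np.exp(-m) + np.exp(eta - m[:, None]).sum(axis=1))
        return float(lse.sum() - (Y * eta).sum())

    theta = np.zeros(n_free)
    f = nll(theta)
    converged = False
    it = 0
    Hf = np.eye(n_free)
    for it in range(1, max_iter + 1):
        B = unpack(theta)
        eta = np.clip(X @ B.T, -_ETA_CLIP, _ETA_CLIP)
        expeta = np.exp(eta)
        denom = 1.0 + expeta.sum(axis=1)
        P = expeta / denom[:, None]                      # n x C
        G = np.zeros((C, d))
        Hfull = np.zeros((C * d, C * d))
        for c in range(C):
            G[c] = X.T @ (P[:, c] - Y[:, c])
            for c2 in range(c, C):
                wcc = P[:, c] * ((1.0 if c == c2 else 0.0) - P[:, c2])
                blk = (X * wcc[:, None]).T @ X
                Hfull[c * d:(c + 1) * d, c2 * d:(c2 + 1) * d] = blk
                if c2 != c:
                    Hfull[c2 * d:(c2 + 1) * d, c * d:(c + 1) * d] = blk
        # project onto free parameters
        gf = np.zeros(n_free)
        np.add.at(gf, param_index.ravel(), G.ravel())
        A = np.zeros((C * d, n_free))
        A[np.arange(C * d), param_index.ravel()] = 1.0
        Hf = A.T @ Hfull @ A
        try:
            delta = np.linalg.solve(Hf, gf)
        except np.linalg.LinAlgError:
            break
        step = 1.0
        for _ in range(40):
            f_new = nll(theta - step * delta)
            if f_new <= f + 1e-14:
                break
            step *= 0.5
        theta = theta - step * delta
        if f - f_new < tol and np.abs(step * delta).max() < 1e-8:
            f = min(f, f_new)
            converged = True
            break
        f = f_new
    try:
        cov = np.linalg.inv(Hf)
    except np.linalg.LinAlgError:
        cov = np.full((n_free, n_free), np.nan)
    return MultinomialFit(list(categories), list(names), unpack(theta), cov,
                          param_index, -f, it, converged)


@dataclass
class HeterogeneityResult:
    """Likelihood-ratio test of PRS-slope equality across case categories."""

    lrt_statistic: float
    df: int
    p_het: float
    slopes: pd.DataFrame = field(repr=False)  # per-category slope, se, OR, CI
    converged: bool = True


def heterogeneity_test(categories: np.ndarray, prs: np.ndarray,
                       age: np.ndarray, male: np.ndarray,
                       case_order: list[str] | None = None
                       ) -> HeterogeneityResult:
    """Polytomous trend test: do PRS effects differ across case categories?

    Fits the unconstrained baseline-category multinomial logit
    (category-specific intercepts, PRS slopes, and age/sex effects) against
    the model constraining a single shared PRS slope; covariate effects stay
    category-specific in both so only slope equality is tested.
    LRT = 2 * delta log-likelihood on (#case categories - 1) df.
    """
    cats = pd.Series(categories)
    case_cats = case_order or sorted(c for c in cats.unique() if c != CONTROL)
    if CONTROL not in set(cats):
        raise InputError("control category required")
    if len(case_cats) < 1:
        raise InputError("need at least one case category")
    code = {c: i + 1 for i, c in enumerate(case_cats)}
    code[CONTROL] = 0
    y = cats.map(code).to_numpy(int)
    X = np.column_stack([np.ones_like(prs, dtype=float), prs, age, male])
    names = ["intercept", "prs", "age", "male"]
    full = fit_multinomial(y, X, case_cats, names)
    constrained = fit_multinomial(y, X, case_cats, names, shared_cols=(1,))
    lrt = max(0.0, 2.0 * (full.log_likelihood - constrained.log_likelihood))
    df = len(case_cats) - 1
    p = float(stats.chi2.sf(lrt, df)) if df > 0 else 1.0
    rows = []
    for c_i, c in enumerate(case_cats):
        b = full.B[c_i, 1]
        k = full.param_index[c_i, 1]
        se = float(np.sqrt(full.cov[k, k]))
        rows.append({"category": c, "slope": float(b), "se": se,
                     "or_per_unit": math.exp(b),
                     "ci_low": math.exp(b - Z95 * se),
                     "ci_high": math.exp(b + Z95 * se)})
    return HeterogeneityResult(float(lrt), df, p, pd.DataFrame(rows),
                               converged=full.converged and constrained.converged)


# ---------------------------------------------------------------------------
# Discrimination and rank tests
# ---------------------------------------------------------------------------

def c_statistic(predicted: np.ndarray, outcome: np.ndarray
                ) -> tuple[float, float, float]:
    """Concordance (ROC AUC) with a Hanley-McNeil 95% CI.

    Mann-Whitney form with half credit for ties; raises on a single-class
    outcome, for which concordance is undefined.
    """
    p = np.asarray(predicted, float)
    y = np.asarray(outcome, float)
    if ((p < 0) | (p > 1)).any():
        raise InputError("predicted values must be probabilities in [0, 1]")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise InputError("c-statistic undefined for a single-class outcome")
    ranks = stats.rankdata(p)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc * auc)
           + (n0 - 1) * (q2 - auc * auc)) / (n1 * n0)
    se = math.sqrt(max(var, 0.0))
    return (float(auc), max(0.0, float(auc - Z95 * se)),
            min(1.0, float(auc + Z95 * se)))


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Rank-based H with tie correction; chi-square p on (groups - 1) df."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise InputError("need >= 2 non-empty groups")
    allvals = np.concatenate([np.asarray(g, float) for g in groups])
    if np.unique(allvals).size == 1:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


# ---------------------------------------------------------------------------
# 2x2 tables and exposure screen
# ---------------------------------------------------------------------------

@dataclass
class TwoByTwoResult:
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    chisq_p: float
    fisher_p: float


def two_by_two(a: int, b: int, c: int, d: int,
               haldane: bool = False) -> TwoByTwoResult:
    """Crude OR = ad/bc with a Woolf CI, chi-square and Fisher p-values.

    Layout: a = exposed cases, b = exposed controls, c = unexposed cases,
    d = unexposed controls. With a zero cell the OR is non-estimable unless
    the Haldane-Anscombe 0.5 correction is requested; Fisher's p is exact
    either way.
    """
    if min(a, b, c, d) < 0:
        raise InputError("counts must be >= 0")
    table = np.array([[a, b], [c, d]], float)
    fisher_p = float(stats.fisher_exact([[a, b], [c, d]])[1])
    if table.sum() and not ((table.sum(axis=0) == 0).any()
                            or (table.sum(axis=1) == 0).any()):
        chisq_p = float(stats.chi2_contingency(table, correction=False)[1])
    else:
        chisq_p = math.nan
    aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d)) if haldane else (a, b, c, d)
    if min(aa, bb, cc, dd) == 0:
        return TwoByTwoResult(None, None, None, chisq_p, fisher_p)
    orr = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    return TwoByTwoResult(float(orr), float(orr * math.exp(-Z95 * se)),
                          float(orr * math.exp(Z95 * se)), chisq_p, fisher_p)


def exposure_screen(samples: pd.DataFrame, exposure_cols: list[str],
                    case_category: str) -> pd.DataFrame:
    """Crude tests plus age/sex-adjusted logistic ORs for each exposure.

    Binary exposures get a two-sided chi-square; continuous ones a two-sided
    t-test. Each exposure uses its own complete cases, so denominators vary
    with missingness and are reported per row.
    """
    keep = samples[samples["phenotype"].isin([CONTROL, case_category])]
    rows = []
    for col in exposure_cols:
        sub = keep.dropna(subset=[col, "age", "sex"])
        y = (sub["phenotype"] == case_category).to_numpy(float)
        x = sub[col].to_numpy(float)
        n_case, n_ctl = int(y.sum()), int((1 - y).sum())
        levels = np.unique(x)
        if levels.size < 2 or n_case == 0 or n_ctl == 0:
            rows.append({"exposure": col, "n_cases": n_case,
                         "n_controls": n_ctl, "crude_p": math.nan,
                         "adj_or": math.nan, "adj_ci_low": math.nan,
                         "adj_ci_high": math.nan, "adj_p": math.nan,
                         "note": "single_level"})
            continue
        if levels.size == 2 and set(levels) <= {0.0, 1.0}:
            a = int(((x == 1) & (y == 1)).sum())
            b = int(((x == 1) & (y == 0)).sum())
            c = int(((x == 0) & (y == 1)).sum())
            d = int(((x == 0) & (y == 0)).sum())
            crude_p = two_by_two(a, b, c, d).chisq_p
        else:
            crude_p = float(stats.ttest_ind(x[y == 1], x[y == 0],
                                            equal_var=False)[1])
        male = (sub["sex"] == "M").to_numpy(float)
        X = np.column_stack([np.ones(len(sub)), x,
                             sub["age"].to_numpy(float), male])
        fit = fit_logistic(y, X, ["intercept", col, "age", "male"])
        orr, lo, hi, p = odds_ratio_wald(fit, col)
        rows.append({"exposure": col, "n_cases": n_case, "n_controls": n_ctl,
                     "crude_p": crude_p, "adj_or": orr, "adj_ci_low": lo,
                     "adj_ci_high": hi, "adj_p": p,
                     "note": "separated" if fit.separated else ""})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Association tables (quintile + continuous + discrimination rows)
# ---------------------------------------------------------------------------

def quintile_association(categories: np.ndarray, outcome: np.ndarray,
                         age: np.ndarray, male: np.ndarray,
                         reference: str = "Q3") -> pd.DataFrame:
    """Adjusted ORs per quantile bin against the middle-quintile reference.

    One logistic fit with indicator terms for every non-reference bin plus
    age and sex; the reference row has OR 1 by construction. Cell counts and
    within-group percentages accompany every row.
    """
    cats = pd.Series(categories).astype(str)
    y = np.asarray(outcome, float)
    labels = sorted(cats.unique(), key=lambda s: (len(s), s))
    if reference not in labels:
        raise InputError(f"reference bin {reference!r} absent from data")
    terms = [q for q in labels if q != reference]
    X = np.column_stack([np.ones(len(y))]
                        + [(cats == q).to_numpy(float) for q in terms]
                        + [age, male])
    names = ["intercept"] + terms + ["age", "male"]
    fit = fit_logistic(y, X, names)
    n_case_tot, n_ctl_tot = int(y.sum()), int((1 - y).sum())
    rows = []
    for q in labels:
        in_q = (cats == q).to_numpy()
        n_case = int((y[in_q] == 1).sum())
        n_ctl = int((y[in_q] == 0).sum())
        if q == reference:
            est, lo, hi, p = 1.0, math.nan, math.nan, math.nan
            note = "reference"
        elif n_case == 0 and n_ctl == 0:
            est = lo = hi = p = math.nan
            note = "empty"
        else:
            est, lo, hi, p = odds_ratio_wald(fit, q)
            note = "non_estimable" if fit.separated else ""
        rows.append({"row": q, "n_cases": n_case,
                     "pct_cases": 100.0 * n_case / n_case_tot if n_case_tot else math.nan,
                     "n_controls": n_ctl,
                     "pct_controls": 100.0 * n_ctl / n_ctl_tot if n_ctl_tot else math.nan,
                     "odds_ratio": est, "ci_low": lo, "ci_high": hi,
                     "p_value": p, "note": note})
    out = pd.DataFrame(rows)
    out.attrs["fit"] = fit
    return out


def continuous_association(prs: np.ndarray, outcome: np.ndarray,
                           age: np.ndarray, male: np.ndarray,
                           label: str = "Continuous"
                           ) -> tuple[dict, ModelFit]:
    """Per-unit adjusted OR for a continuous score, plus the model's c-statistic."""
    y = np.asarray(outcome, float)
    X = np.column_stack([np.ones(len(y)), prs, age, male])
    fit = fit_logistic(y, X, ["intercept", "prs", "age", "male"])
    orr, lo, hi, p = odds_ratio_wald(fit, "prs")
    row = {"row": label, "odds_ratio": orr, "ci_low": lo, "ci_high": hi,
           "p_value": p, "note": "non_estimable" if fit.separated else ""}
    return row, fit


def per_snp_association(genotypes: GenotypeMatrix, outcome: np.ndarray,
                        age: np.ndarray, male: np.ndarray,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Log-additive per-variant ORs adjusted for age and sex.

    One fit per variant with the dosage as a single linear term; complete
    cases per variant. Nominal significance flags at ``alpha``; no
    multiple-testing correction (the panel variants are fixed a priori).
    """
    y_all = np.asarray(outcome, float)
    rows = []
    for j, vid in enumerate(genotypes.variant_ids):
        g = genotypes.dosage[:, j]
        ok = ~np.isnan(g)
        g_ok, y = g[ok], y_all[ok]
        if np.unique(g_ok).size < 2:
            rows.append({"variant_id": vid, "n": int(ok.sum()),
                         "odds_ratio": math.nan, "ci_low": math.nan,
                         "ci_high": math.nan, "p_value": math.nan,
                         "significant": False, "note": "monomorphic"})
            continue
        X = np.column_stack([np.ones(ok.sum()), g_ok, age[ok], male[ok]])
        fit = fit_logistic(y, X, ["intercept", "dosage", "age", "male"])
        orr, lo, hi, p = odds_ratio_wald(fit, "dosage")
        rows.append({"variant_id": vid, "n": int(ok.sum()),
                     "odds_ratio": orr, "ci_low": lo, "ci_high": hi,
                     "p_value": p,
                     "significant": bool(p < alpha) if np.isfinite(p) else False,
                     "note": "non_estimable" if fit.separated else ""})
    return pd.DataFrame(rows)
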