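"""Supervised admixture estimation and ancestry classification.

Each individual's genome is modeled as a mixture over K reference
populations with known allele frequencies: at variant j the risk-allele
dosage g_j is Binomial(2, p_j) with p_j = sum_k q_k f_kj, and the mixing
vector q on the K-simplex is estimated per individual by EM on the binomial
likelihood. Classification applies the study thresholds: African proportion
>= 50% -> AA, else European proportion > 80% -> EA, else OTHER.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .genotypes import GenotypeMatrix
from .panel import SNPPanel

_FREQ_CLAMP = 1e-6

AA_AFR_MIN = 0.50   # inclusive
EA_EUR_MIN = 0.80   # exclusive


@dataclass
class AncestryResult:
    """Per-individual admixture proportions with convergence diagnostics."""

    sample_id: str
    proportions: dict[str, float]
    log_likelihood: float
    n_iterations: int
    converged: bool

    @property
    def label(self) -> str:
        return classify_ancestry(self.proportions)


def classify_ancestry(proportions: dict[str, float]) -> str:
    """AA if AFR >= 0.50; else EA if EUR > 0.80; else OTHER."""
    if "AFR" not in proportions or "EUR" not in proportions:
        raise InputError("proportions must include AFR and EUR")
    if proportions["AFR"] >= AA_AFR_MIN:
        return "AA"
    if proportions["EUR"] > EA_EUR_MIN:
        return "EA"
    return "OTHER"


def admixture_log_likelihood(dosages: np.ndarray, freqs: np.ndarray,
                             q: np.ndarray) -> float:
    """Binomial log-likelihood of q given dosages (missing skipped)."""
    obs = ~np.isnan(dosages)
    g = dosages[obs]
    p = np.clip(freqs[obs] @ q, _FREQ_CLAMP, 1.0 - _FREQ_CLAMP)
    return float(np.sum(g * np.log(p) + (2.0 - g) * np.log1p(-p)))


def estimate_admixture(dosages: np.ndarray, ref_freqs: np.ndarray,
                       ancestries: list[str], tol: float = 1e-6,
                       max_iter: int = 1000,
                       sample_id: str = "") -> AncestryResult:
    """EM for one individual's admixture proportions.

    ``ref_freqs`` is variants x K risk-allele frequencies aligned to
    ``dosages``; frequencies are clamped away from 0/1 before the likelihood
    is evaluated. Starts at the uniform simplex point; the EM objective is
    concave in q for fixed frequencies, so the start affects only the
    iteration count. Log-likelihood is non-decreasing every iteration.
    """
    g = np.asarray(dosages, float)
    F = np.clip(np.asarray(ref_freqs, float), _FREQ_CLAMP, 1.0 - _FREQ_CLAMP)
    if F.ndim != 2 or F.shape[1] < 2:
        raise InputError("need a variants x K frequency matrix with K >= 2")
    if F.shape[1] != len(ancestries):
        raise InputError("ancestry labels do not match frequency columns")
    obs = ~np.isnan(g)
    if not obs.any():
        raise InputError("no non-missing dosages")
    g, F = g[obs], F[obs]
    n_obs = len(g)
    K = F.shape[1]
    q = np.full(K, 1.0 / K)
    ll = admixture_log_likelihood(g, F, q)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = np.clip(F @ q, _FREQ_CLAMP, 1.0 - _FREQ_CLAMP)
        # responsibilities of ancestry k for risk (r) and other (s) allele copies
        r = (q * F) / p[:, None]
        s = (q * (1.0 - F)) / (1.0 - p)[:, None]
        q = (g[:, None] * r + (2.0 - g)[:, None] * s).sum(axis=0) / (2.0 * n_obs)
        q = np.clip(q, 0.0, None)
        q /= q.sum()
        ll_new = admixture_log_likelihood(g, F, q)
        if ll_new - ll < tol:
            ll = max(ll, ll_new)
            converged = True
            break
        ll = ll_new
    return AncestryResult(sample_id=sample_id,
                          proportions={a: float(v)
                                       for a, v in zip(ancestries, q)},
                          log_likelihood=ll, n_iterations=it,
                          converged=converged)


def estimate_admixture_matrix(genotypes: GenotypeMatrix, panel: SNPPanel,
                              ancestries: list[str] | None = None,
                              tol: float = 1e-6, max_iter: int = 1000
                              ) -> pd.DataFrame:
    """Admixture proportions and labels for every sample in a matrix.

    Same EM as :func:`estimate_admixture` but batched over samples for
    speed (each sample's q is still an independent maximization). Variants
    are aligned by id between the genotype matrix and the reference panel;
    the result has one row per sample with q_<ancestry> columns, the
    classification label, and convergence diagnostics.
    """
    ancs = ancestries if ancestries is not None else panel.ancestries
    shared = [v for v in genotypes.variant_ids if v in set(panel.variant_ids)]
    if not shared:
        raise InputError("no shared variants between genotypes and panel")
    gsub = genotypes.subset_variants(shared)
    F = np.clip(panel.subset(shared).freq_matrix(ancs),
                _FREQ_CLAMP, 1.0 - _FREQ_CLAMP)          # J x K
    G = gsub.dosage                                      # n x J
    obs = ~np.isnan(G)
    if not obs.any(axis=1).all():
        bad = [gsub.sample_ids[i] for i in np.flatnonzero(~obs.any(axis=1))]
        raise InputError(f"samples with no non-missing dosages: {bad}")
    g0 = np.where(obs, G, 0.0)
    g2 = np.where(obs, 2.0 - G, 0.0)
    n_obs = obs.sum(axis=1)
    n, K = G.shape[0], F.shape[1]
    Q = np.full((n, K), 1.0 / K)

    def loglik(Q_):
        P = np.clip(Q_ @ F.T, _FREQ_CLAMP, 1.0 - _FREQ_CLAMP)
        return (g0 * np.log(P) + g2 * np.log1p(-P)).sum(axis=1)

    ll = loglik(Q)
    active = np.ones(n, dtype=bool)
    iters = np.zeros(n, dtype=int)
    for it in range(1, max_iter + 1):
        P = np.clip(Q @ F.T, _FREQ_CLAMP, 1.0 - _FREQ_CLAMP)   # n x J
        # responsibilities summed over variants, per ancestry
        num_r = (g0 / P) @ F * Q                               # n x K
        num_s = (g2 / (1.0 - P)) @ (1.0 - F) * Q
        Q_new = (num_r + num_s) / (2.0 * n_obs[:, None])
        Q_new = np.clip(Q_new, 0.0, None)
        Q_new /= Q_new.sum(axis=1, keepdims=True)
        Q = np.where(active[:, None], Q_new, Q)
        ll_new = loglik(Q)
        done = active & (ll_new - ll < tol)
        iters[done] = it
        active &= ~done
        ll = np.maximum(ll, ll_new)
        if not active.any():
            break
    iters[active] = max_iter
    rows = []
    for i, sid in enumerate(gsub.sample_ids):
        row = {"sample_id": sid}
        row.update({f"q_{a}": float(Q[i, k]) for k, a in enumerate(ancs)})
        row.update({"label": classify_ancestry(
                        {a: float(Q[i, k]) for k, a in enumerate(ancs)}),
                    "log_likelihood": float(ll[i]),
                    "n_iterations": int(iters[i]),
                    "converged": not bool(active[i])})
        rows.append(row)
    return pd.DataFrame(rows)
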