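"""Polygenic risk score computation and reference-based quantile assignment.

The weighted PRS is the plain weighted sum over panel SNPs of risk-allele
dosage times the SNP's log odds-ratio weight (no division by the weight sum
or SNP count -- the published score's control median of ~7.5 over 41 SNPs is
on the sum scale); the unweighted PRS is the raw risk-allele count. Quantile
categories come from reference-control cutoffs under the inverse empirical
CDF convention, with left-closed right-open bins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import InputError
from .genotypes import GenotypeMatrix
from .panel import SNPPanel

QUANTILE_METHOD = "inverted_cdf"  # quantile(p) = smallest x with CDF(x) >= p


@dataclass
class QuantileCutoffs:
    """Internal bin boundaries for quantile categories.

    ``boundaries`` are the k/n_bins reference quantiles (n_bins - 1 values,
    strictly increasing). Bins are left-closed right-open; scores below the
    first boundary fall in the first bin and scores at or above the last
    boundary in the last (open-ended extremes).
    """

    boundaries: tuple[float, ...]
    source: str = "internal_controls"
    n_reference: int = 0

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, float)
        if len(b) < 1 or not (np.diff(b) > 0).all():
            raise InputError("boundaries must be strictly increasing")
        self.boundaries = tuple(float(x) for x in b)

    @property
    def n_bins(self) -> int:
        return len(self.boundaries) + 1

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"boundaries": list(self.boundaries),
                       "source": self.source,
                       "n_reference": self.n_reference}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "QuantileCutoffs":
        with open(path) as fh:
            d = json.load(fh)
        return cls(tuple(d["boundaries"]), d.get("source", "external_reference"),
                   int(d.get("n_reference", 0)))


def ea_reference_cutoffs() -> QuantileCutoffs:
    """Published European-ancestry quintile cutoffs for the 41-SNP CLL score.

    Boundaries derived from 7983 external consortium controls; the full
    printed intervals span [4.32, 11.31) but only the four interior
    boundaries define the bins.
    """
    with resources.files("cllprs.data").joinpath(
            "ea_reference_cutoffs.json").open() as fh:
        d = json.load(fh)
    return QuantileCutoffs(tuple(d["boundaries"]), d["source"],
                           int(d["n_reference"]))


def compute_prs(dosages: np.ndarray, panel: SNPPanel,
                missing_policy: str = "mean_impute",
                impute_ancestry: str | None = None
                ) -> tuple[float, float, int] | tuple[None, None, int]:
    """Weighted and unweighted PRS for one individual.

    Returns (prs_weighted, prs_unweighted, n_missing). Under ``mean_impute``
    a missing dosage is replaced by twice the control risk-allele frequency
    (the panel's ``impute_ancestry`` column, default its first ancestry);
    under ``complete_only`` any missingness yields (None, None, n_missing).
    """
    g = np.asarray(dosages, float)
    if g.shape != (len(panel),):
        raise InputError("dosage vector not aligned to panel")
    miss = np.isnan(g)
    n_missing = int(miss.sum())
    if n_missing == len(panel) and len(panel) > 0:
        return None, None, n_missing
    if n_missing:
        if missing_policy == "complete_only":
            return None, None, n_missing
        if missing_policy != "mean_impute":
            raise InputError(f"unknown missing policy {missing_policy!r}")
        anc = impute_ancestry or panel.ancestries[0]
        g = g.copy()
        g[miss] = 2.0 * panel.freqs(anc)[miss]
    w = panel.weights
    return float(np.dot(w, g)), float(g.sum()), n_missing


def score_samples(genotypes: GenotypeMatrix, panel: SNPPanel,
                  cutoffs: QuantileCutoffs | None = None,
                  reference_scores: np.ndarray | None = None,
                  missing_policy: str = "mean_impute",
                  impute_ancestry: str | None = None,
                  top_percentile: float = 0.99) -> pd.DataFrame:
    """Score every sample; optionally attach quantile and top-percentile flags.

    Returns a DataFrame with sample_id, prs_weighted, prs_unweighted,
    n_missing_snps, and -- when cutoffs / reference scores are given --
    quantile_category (Q1..Qn) and top_percentile_flag.
    """
    sub = panel.subset(genotypes.variant_ids)
    aligned = genotypes.subset_variants(sub.variant_ids)
    rows = []
    for i, sid in enumerate(aligned.sample_ids):
        pw, pu, nm = compute_prs(aligned.dosage[i], sub, missing_policy,
                                 impute_ancestry)
        rows.append({"sample_id": sid, "prs_weighted": pw,
                     "prs_unweighted": pu, "n_missing_snps": nm})
    out = pd.DataFrame(rows)
    if cutoffs is not None:
        out["quantile_category"] = [
            assign_quantile(s, cutoffs) if s is not None and not np.isnan(s)
            else None
            for s in out["prs_weighted"].to_numpy(float)]
    if reference_scores is not None:
        thresh = top_percentile_threshold(reference_scores, top_percentile)
        out["top_percentile_flag"] = out["prs_weighted"] >= thresh
    return out


def reference_cutoffs(control_scores: np.ndarray, n_bins: int = 5,
                      source: str = "internal_controls") -> QuantileCutoffs:
    """Empirical k/n_bins quantile boundaries from reference control scores."""
    x = np.asarray(control_scores, float)
    x = x[~np.isnan(x)]
    if np.unique(x).size < n_bins:
        raise InputError(f"need >= {n_bins} distinct scores for {n_bins} bins")
    probs = np.arange(1, n_bins) / n_bins
    bounds = np.quantile(x, probs, method=QUANTILE_METHOD)
    return QuantileCutoffs(tuple(float(b) for b in bounds), source=source,
                           n_reference=len(x))


def assign_quantile(score: float, cutoffs: QuantileCutoffs) -> str:
    """Bin label (Q1..Qn) under left-closed right-open intervals.

    A score equal to a boundary belongs to the upper bin.
    """
    if np.isnan(score):
        raise InputError("cannot assign a quantile to NaN")
    idx = int(np.searchsorted(cutoffs.boundaries, score, side="right"))
    return f"Q{idx + 1}"


def top_percentile_threshold(reference_scores: np.ndarray,
                             percentile: float = 0.99) -> float:
    if not 0.0 < percentile < 1.0:
        raise InputError("percentile must be in (0, 1)")
    x = np.asarray(reference_scores, float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise InputError("empty reference score vector")
    return float(np.quantile(x, percentile, method=QUANTILE_METHOD))


def top_percentile_flag(score: float, reference_scores: np.ndarray,
                        percentile: float = 0.99) -> bool:
    """True iff the score reaches the reference percentile value."""
    return bool(score >= top_percentile_threshold(reference_scores, percentile))
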