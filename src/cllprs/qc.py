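"""Genotype input, risk-allele harmonization, and variant/sample QC filters.

Implements the standard pre-scoring QC of an array-based case-control study:
dropping samples with low call rates (or flagged sex discordance / genotyped
relatives), then monomorphic variants, variants with low call rates, and
variants in extreme Hardy-Weinberg disequilibrium by an exact conditional
test. Allele harmonization maps arbitrary VCF REF/ALT orientation (including
reverse-strand reporting) onto the weight panel's risk allele so published
weights apply to any genotype file.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .errors import InputError
from .genotypes import GenotypeMatrix
from .panel import SNPPanel
from .samples import CONTROL

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class Orientation(enum.Enum):
    """How a VCF (REF, ALT) pair maps onto a panel (risk, other) pair.

    DIRECT means (REF, ALT) == (risk, other), so the risk allele is REF and
    the risk dosage is 2 minus the ALT count; FLIPPED means the allele order
    is swapped and the risk dosage is the ALT count itself. The STRAND_FLIP
    variants are the same two cases after reverse-complementing REF/ALT.
    """

    DIRECT = "direct"
    FLIPPED = "flipped"
    STRAND_FLIP_DIRECT = "strand_flip_direct"
    STRAND_FLIP_FLIPPED = "strand_flip_flipped"
    AMBIGUOUS = "ambiguous"
    IRRECONCILABLE = "irreconcilable"

    @property
    def resolved(self) -> bool:
        return self not in (Orientation.AMBIGUOUS, Orientation.IRRECONCILABLE)

    @property
    def risk_is_alt(self) -> bool:
        if not self.resolved:
            raise ValueError(f"{self} has no dosage mapping")
        return self in (Orientation.FLIPPED, Orientation.STRAND_FLIP_FLIPPED)


def harmonize_alleles(vcf_ref: str, vcf_alt: str, panel_risk: str,
                      panel_other: str) -> Orientation:
    """Resolve VCF REF/ALT against the panel's risk/other alleles.

    All four orientations (allele order x strand) are enumerated; a unique
    match is returned. Palindromic pairs (A/T, C/G) match in two orientations
    with opposite dosage mappings and come back AMBIGUOUS; no match at all is
    IRRECONCILABLE.
    """
    for b in (vcf_ref, vcf_alt, panel_risk, panel_other):
        if b not in _COMPLEMENT:
            raise InputError(f"allele {b!r} is not a single base in ACGT")
    cref, calt = _COMPLEMENT[vcf_ref], _COMPLEMENT[vcf_alt]
    matches = [o for o, (r, a) in (
        (Orientation.DIRECT, (vcf_ref, vcf_alt)),
        (Orientation.FLIPPED, (vcf_alt, vcf_ref)),
        (Orientation.STRAND_FLIP_DIRECT, (cref, calt)),
        (Orientation.STRAND_FLIP_FLIPPED, (calt, cref)),
    ) if (r, a) == (panel_risk, panel_other)]
    if not matches:
        return Orientation.IRRECONCILABLE
    if len(matches) > 1:
        return Orientation.AMBIGUOUS
    return matches[0]


def read_genotypes(vcf_path, panel: SNPPanel, allow_ambiguous: bool = False
                   ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a VCF into risk-allele dosages aligned to the panel.

    Variant records are matched to the panel by ID; records not in the panel
    are counted and skipped. Returns the dosage matrix (panel order, columns
    restricted to harmonized variants) and a harmonization log with one row
    per panel-overlapping record (variant_id, orientation, kept).

    With ``allow_ambiguous`` a palindromic variant is scored assuming the
    file is on the panel's strand (allele identity only, no strand flip).
    """
    from cyvcf2 import VCF

    ptab = panel.table.set_index("variant_id")
    vcf = VCF(str(vcf_path), gts012=True)
    sample_ids = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    log_rows = []
    n_skipped = 0
    for rec in vcf:
        vid = rec.ID
        if vid is None or vid not in ptab.index:
            n_skipped += 1
            continue
        if not rec.ALT or len(rec.ALT) != 1:
            log_rows.append((vid, "multiallelic", False))
            continue
        orient = harmonize_alleles(rec.REF, rec.ALT[0],
                                   ptab.loc[vid, "risk_allele"],
                                   ptab.loc[vid, "other_allele"])
        if orient is Orientation.AMBIGUOUS and allow_ambiguous:
            # trust the file's strand: re-match on allele identity only
            if (rec.REF, rec.ALT[0]) == (ptab.loc[vid, "risk_allele"],
                                         ptab.loc[vid, "other_allele"]):
                orient = Orientation.DIRECT
            else:
                orient = Orientation.FLIPPED
        log_rows.append((vid, orient.value, orient.resolved))
        if not orient.resolved:
            continue
        alt_count = rec.gt_types.astype(float)  # 0/1/2 ALT copies, 3 missing
        alt_count[alt_count == 3] = np.nan
        cols[vid] = alt_count if orient.risk_is_alt else 2.0 - alt_count
    if not cols:
        raise InputError(f"no panel variants found in {vcf_path} "
                         f"({n_skipped} off-panel records skipped)")
    kept_ids = [v for v in panel.variant_ids if v in cols]
    dosage = np.column_stack([cols[v] for v in kept_ids])
    log = pd.DataFrame(log_rows, columns=["variant_id", "orientation", "kept"])
    log.attrs["n_off_panel"] = n_skipped
    return GenotypeMatrix(sample_ids, kept_ids, dosage), log


# ---------------------------------------------------------------------------
# Hardy-Weinberg tests
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom_risk: int, n_het: int, n_hom_other: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count whose conditional probability does not exceed
    that of the observed count (two-sided by probability ordering).
    """
    counts = (int(n_hom_risk), int(n_het), int(n_hom_other))
    if any(c < 0 for c in counts):
        raise InputError("genotype counts must be >= 0")
    n = sum(counts)
    if n < 1:
        raise InputError("need at least one genotype")
    n_a = 2 * counts[0] + counts[1]       # risk allele copies
    n_b = 2 * n - n_a
    rare = min(n_a, n_b)
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(het = h | n, n_a): multinomial over genotypes / binomial over alleles
    logp = (gammaln(n + 1) + gammaln(n_a + 1) + gammaln(n_b + 1)
            + hets * np.log(2.0)
            - gammaln((n_a - hets) / 2 + 1) - gammaln(hets + 1)
            - gammaln((n_b - hets) / 2 + 1) - gammaln(2 * n + 1))
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[hets == counts[1]]
    if p_obs.size == 0:  # parity violation cannot happen with integer counts
        raise InputError("inconsistent genotype counts")
    return float(min(1.0, p[p <= p_obs[0] * (1.0 + 1e-12)].sum()))


def hwe_chisq_test(n_hom_risk: int, n_het: int, n_hom_other: int) -> float:
    """Asymptotic 1-df chi-square Hardy-Weinberg test (option)."""
    n = n_hom_risk + n_het + n_hom_other
    if n < 1:
        raise InputError("need at least one genotype")
    f = (2 * n_hom_risk + n_het) / (2 * n)
    exp = np.array([(1 - f) ** 2, 2 * f * (1 - f), f ** 2]) * n
    obs = np.array([n_hom_other, n_het, n_hom_risk], dtype=float)
    if (exp == 0).any():
        return 1.0
    x2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(x2, df=1))


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Everything the QC stage removed and why, plus the statistics behind it."""

    removed_variants: list[tuple[str, str]] = field(default_factory=list)
    removed_samples: list[tuple[str, str]] = field(default_factory=list)
    hwe_pvalues: dict[str, float] = field(default_factory=dict)
    variant_call_rates: dict[str, float] = field(default_factory=dict)
    sample_call_rates: dict[str, float] = field(default_factory=dict)
    duplicate_concordances: list[tuple[str, str, float | None]] = field(
        default_factory=list)

    def to_tsv(self, path) -> None:
        rows = ([{"kind": "variant", "id": v, "reason": r}
                 for v, r in self.removed_variants]
                + [{"kind": "sample", "id": s, "reason": r}
                   for s, r in self.removed_samples])
        pd.DataFrame(rows, columns=["kind", "id", "reason"]).to_csv(
            path, sep="\t", index=False)


def genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    """(hom risk, het, hom other) counts from a dosage column."""
    called = col[~np.isnan(col)]
    return (int((called == 2).sum()), int((called == 1).sum()),
            int((called == 0).sum()))


def qc_filter(genotypes: GenotypeMatrix,
              snp_call_min: float = 0.95,
              sample_call_min: float = 0.90,
              hwe_alpha: float = 1e-5,
              drop_monomorphic: bool = True,
              samples: pd.DataFrame | None = None,
              hwe_method: str = "exact",
              ) -> tuple[GenotypeMatrix, QCReport]:
    """Apply variant- and sample-level filters with strict-inequality thresholds.

    Order of application: (1) flagged samples (sex discordance, genotyped
    relative, from the sample table when given) and samples with call rate
    below ``sample_call_min``; (2) monomorphic variants; (3) variants with
    call rate below ``snp_call_min``; (4) variants failing Hardy-Weinberg at
    ``hwe_alpha``, tested on retained samples -- controls only when phenotype
    labels are available. Every removal is recorded with a reason.
    """
    if not (0 < snp_call_min <= 1 and 0 < sample_call_min <= 1):
        raise InputError("call-rate thresholds must be in (0, 1]")
    hwe_test = {"exact": hwe_exact_test, "chisq": hwe_chisq_test}[hwe_method]
    report = QCReport()
    g = genotypes

    # (1) samples
    flagged: dict[str, str] = {}
    if samples is not None:
        st = samples.set_index("sample_id")
        for sid in g.sample_ids:
            if sid in st.index:
                if bool(st.loc[sid].get("sex_discordant", False)):
                    flagged[sid] = "sex_discordance"
                elif bool(st.loc[sid].get("has_genotyped_relative", False)):
                    flagged[sid] = "relative"
    rates = g.sample_call_rates()
    keep_samples = []
    for sid, rate in zip(g.sample_ids, rates):
        report.sample_call_rates[sid] = float(rate)
        if sid in flagged:
            report.removed_samples.append((sid, flagged[sid]))
        elif rate < sample_call_min:
            report.removed_samples.append((sid, "call_rate"))
        else:
            keep_samples.append(sid)
    g = g.subset_samples(keep_samples)

    # (2) monomorphic, (3) variant call rate, (4) HWE
    keep_variants = []
    control_rows = None
    if samples is not None and "phenotype" in samples.columns:
        ctl = set(samples.loc[samples["phenotype"] == CONTROL, "sample_id"])
        rows = np.array([s in ctl for s in g.sample_ids])
        if rows.any():
            control_rows = rows
    vrates = g.variant_call_rates()
    for j, vid in enumerate(g.variant_ids):
        report.variant_call_rates[vid] = float(vrates[j])
        col = g.dosage[:, j]
        called = col[~np.isnan(col)]
        if drop_monomorphic and called.size > 0 and np.unique(called).size == 1:
            report.removed_variants.append((vid, "monomorphic"))
            continue
        if vrates[j] < snp_call_min:
            report.removed_variants.append((vid, "call_rate"))
            continue
        hwe_col = col[control_rows] if control_rows is not None else col
        n2, n1, n0 = genotype_counts(hwe_col)
        if n2 + n1 + n0 > 0:
            p = hwe_test(n2, n1, n0)
            report.hwe_pvalues[vid] = p
            if p < hwe_alpha:
                report.removed_variants.append((vid, "hwe"))
                continue
        keep_variants.append(vid)
    return g.subset_variants(keep_variants), report


def duplicate_concordance(dosages_a: np.ndarray, dosages_b: np.ndarray
                          ) -> float | None:
    """Fraction of jointly called positions with equal dosage; None if none."""
    a = np.asarray(dosages_a, float)
    b = np.asarray(dosages_b, float)
    if a.shape != b.shape:
        raise InputError("dosage vectors must have equal length")
    both = ~np.isnan(a) & ~np.isnan(b)
    if not both.any():
        return None
    return float((a[both] == b[both]).mean())
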