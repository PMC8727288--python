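"""SNP weight panel: per-variant alleles, log-OR weights, ancestry frequencies.

The panel is the published set of risk variants that defines the polygenic
risk score: each variant carries its risk allele, the other allele, a
per-risk-allele weight on the natural-log odds-ratio scale, and the risk
allele frequency in one or more reference ancestries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_BASES = frozenset("ACGT")

#: TSV column prefix for per-ancestry risk-allele frequency columns.
FREQ_PREFIX = "freq_"


@dataclass
class SNPPanel:
    """Variant metadata table backing PRS computation and simulation.

    Parameters
    ----------
    table
        One row per variant with columns ``variant_id``, ``chrom``, ``pos``,
        ``risk_allele``, ``other_allele``, ``weight_log_or`` and one
        ``freq_<ancestry>`` column per reference ancestry (risk-allele
        frequency in [0, 1]).
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("variant_id", "chrom", "pos", "risk_allele", "other_allele",
                "weight_log_or")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValueError(f"panel table missing columns: {missing}")
        if t["variant_id"].duplicated().any():
            dups = t.loc[t["variant_id"].duplicated(), "variant_id"].tolist()
            raise ValueError(f"duplicate variant ids: {dups}")
        if len(t):
            for col in ("risk_allele", "other_allele"):
                bad = ~t[col].isin(list(_BASES))
                if bad.any():
                    raise ValueError(f"non-ACGT {col}: "
                                     f"{t.loc[bad, col].unique().tolist()}")
            if (t["risk_allele"] == t["other_allele"]).any():
                raise ValueError("risk_allele equals other_allele for some variants")
            if not np.isfinite(t["weight_log_or"].to_numpy(float)).all():
                raise ValueError("non-finite weights")
            for anc in self.ancestries:
                f = t[FREQ_PREFIX + anc].to_numpy(float)
                if ((f < 0) | (f > 1)).any() or not np.isfinite(f).all():
                    raise ValueError(f"frequencies for {anc} outside [0, 1]")
        self.table = t.reset_index(drop=True)

    # -- accessors -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.table)

    @property
    def variant_ids(self) -> list[str]:
        return self.table["variant_id"].tolist()

    @property
    def weights(self) -> np.ndarray:
        """Per-variant log-OR weights, aligned to :attr:`variant_ids`."""
        return self.table["weight_log_or"].to_numpy(float)

    @property
    def ancestries(self) -> list[str]:
        return [c[len(FREQ_PREFIX):] for c in self.table.columns
                if c.startswith(FREQ_PREFIX)]

    def freqs(self, ancestry: str) -> np.ndarray:
        """Risk-allele frequencies in the given reference ancestry."""
        col = FREQ_PREFIX + ancestry
        if col not in self.table.columns:
            raise KeyError(f"no frequency column for ancestry {ancestry!r}")
        return self.table[col].to_numpy(float)

    def freq_matrix(self, ancestries: list[str] | None = None) -> np.ndarray:
        """Variants x K matrix of risk-allele frequencies."""
        ancs = ancestries if ancestries is not None else self.ancestries
        return np.column_stack([self.freqs(a) for a in ancs])

    def subset(self, variant_ids: list[str]) -> "SNPPanel":
        keep = self.table[self.table["variant_id"].isin(set(variant_ids))]
        return SNPPanel(keep.copy())

    # -- IO ------------------------------------------------------------------

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "SNPPanel":
        return cls(pd.read_csv(path, sep="\t",
                               dtype={"variant_id": str, "chrom": str,
                                      "risk_allele": str, "other_allele": str}))
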