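"""Genotype matrix container and plain-text IO (dosage TSV, VCF).

Dosages are risk-allele counts in {0, 1, 2}; missing genotypes are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import SNPPanel


@dataclass
class GenotypeMatrix:
    """Samples x variants risk-allele dosage matrix.

    ``dosage`` is a float array with values in {0, 1, 2} and NaN for
    missing; rows align with ``sample_ids`` and columns with
    ``variant_ids``.
    """

    sample_ids: list[str]
    variant_ids: list[str]
    dosage: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.variant_ids)} variants")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be in {0, 1, 2} or missing")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("duplicate variant ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.sample_ids), list(self.variant_ids),
                              self.dosage.copy())

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), list(self.variant_ids),
                              self.dosage[rows])

    def subset_variants(self, variant_ids: list[str]) -> "GenotypeMatrix":
        idx = {v: j for j, v in enumerate(self.variant_ids)}
        cols = [idx[v] for v in variant_ids]
        return GenotypeMatrix(list(self.sample_ids), list(variant_ids),
                              self.dosage[:, cols])

    def variant_call_rates(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    def sample_call_rates(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosage).mean(axis=1)

    # -- IO ------------------------------------------------------------------

    def to_dosage_tsv(self, path) -> None:
        """Write samples x variants dosages, ``NA`` for missing."""
        df = pd.DataFrame(self.dosage, index=self.sample_ids,
                          columns=self.variant_ids)
        df.index.name = "sample_id"
        with np.errstate(invalid="ignore"):
            out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
        out.to_csv(path, sep="\t")

    @classmethod
    def from_dosage_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id",
                         na_values=["NA"])
        return cls([str(s) for s in df.index], [str(v) for v in df.columns],
                   df.to_numpy(float))


def write_vcf(matrix: GenotypeMatrix, panel: SNPPanel, path,
              flip_ref_alt: set[str] | None = None) -> None:
    """Write unphased diploid GT records for the panel variants.

    By default REF is the panel's other allele and ALT the risk allele, so a
    dosage of 1 is written ``0/1`` and 2 is ``1/1``. Variants listed in
    ``flip_ref_alt`` are written with REF = risk allele instead (dosage 2 ->
    ``0/0``), which exercises downstream allele harmonization.
    """
    flip = flip_ref_alt or set()
    ptab = panel.table.set_index("variant_id")
    order = sorted(range(matrix.n_variants),
                   key=lambda j: (str(ptab.loc[matrix.variant_ids[j], "chrom"]),
                                  int(ptab.loc[matrix.variant_ids[j], "pos"])))
    gt_for = {0.0: ("0/0", "1/1"), 1.0: ("0/1", "0/1"), 2.0: ("1/1", "0/0")}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        seen = []
        for j in order:
            chrom = str(ptab.loc[matrix.variant_ids[j], "chrom"])
            if chrom not in seen:
                seen.append(chrom)
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.sample_ids) + "\n")
        for j in order:
            vid = matrix.variant_ids[j]
            row = ptab.loc[vid]
            flipped = vid in flip
            ref, alt = ((row["risk_allele"], row["other_allele"]) if flipped
                        else (row["other_allele"], row["risk_allele"]))
            gts = []
            for d in matrix.dosage[:, j]:
                if np.isnan(d):
                    gts.append("./.")
                else:
                    gts.append(gt_for[d][1 if flipped else 0])
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{vid}\t{ref}\t{alt}"
                     f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")
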