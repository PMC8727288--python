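"""Sample (phenotype/covariate) table conventions and validation.

The sample table is a plain pandas DataFrame with one row per individual:

    sample_id   unique string
    age         years
    sex         "M" or "F"
    phenotype   outcome category, e.g. control / LC_MBL / HC_MBL / CLL
    cohort      free-text cohort label
    ancestry    ancestry label (simulation truth or classifier output)

Optional boolean columns ``sex_discordant`` and ``has_genotyped_relative``
carry precomputed QC flags (the array-level checks behind them are out of
scope here); additional columns (exposures, scores) pass through untouched.
"""

from __future__ import annotations

import pandas as pd

CONTROL = "control"
PHENOTYPES = (CONTROL, "LC_MBL", "HC_MBL", "CLL")

REQUIRED = ("sample_id", "age", "sex", "phenotype")


def validate_samples(df: pd.DataFrame) -> pd.DataFrame:
    """Check required columns and value domains; returns the table."""
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids")
    bad_sex = ~df["sex"].isin(["M", "F"])
    if bad_sex.any():
        raise ValueError(f"sex must be M/F, got {df.loc[bad_sex, 'sex'].unique()}")
    if (df["age"] < 0).any():
        raise ValueError("negative ages")
    return df


def write_samples(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_samples(df)


def is_male(df: pd.DataFrame):
    """0/1 male indicator used as the sex covariate in all models."""
    return (df["sex"] == "M").astype(float).to_numpy()
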