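import numpy as np
import pandas as pd
import pytest

from cllprs.panel import SNPPanel
from cllprs.genotypes import GenotypeMatrix


def toy_panel(freqs_eur, freqs_afr=None, weights=None):
    """Small hand-built panel; alleles chosen to be non-palindromic."""
    n = len(freqs_eur)
    tab = pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(n)],
        "chrom": ["1"] * n,
        "pos": [1000 + i for i in range(n)],
        "risk_allele": ["G"] * n,
        "other_allele": ["A"] * n,
        "weight_log_or": weights if weights is not None else [0.2] * n,
        "freq_EUR": freqs_eur,
    })
    if freqs_afr is not None:
        tab["freq_AFR"] = freqs_afr
    return SNPPanel(tab)


def matrix_from(dosage, sample_prefix="s", variant_prefix="v"):
    dosage = np.asarray(dosage, float)
    return GenotypeMatrix(
        [f"{sample_prefix}{i}" for i in range(dosage.shape[0])],
        [f"{variant_prefix}{j}" for j in range(dosage.shape[1])],
        dosage)


@pytest.fixture(scope="session")
def demo_dir(tmp_path_factory):
    """The small reproducible demo fixture set (200 samples, 41 SNPs)."""
    from cllprs.pipeline import make_demo_fixtures
    return make_demo_fixtures(1, tmp_path_factory.mktemp("demo") / "fixtures")
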