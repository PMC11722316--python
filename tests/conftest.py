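import numpy as np
import pandas as pd
import pytest

from defensim.chemostat import Environment


@pytest.fixture(scope="session")
def small_env() -> Environment:
    """Tiny matrix for fast unit tests of the stepping machinery."""
    return Environment(p0=4, Q=30, B=0.1, C=0.02, E=0.5, F=0.5, G=2.0,
                       T=0.5, phi0=1.0, psi0=0.1)


@pytest.fixture(scope="session")
def reference_env() -> Environment:
    """Reference PCD-sensitive ecology (reduced matrix p0=6, Q=200)."""
    return Environment(p0=6, Q=200, B=0.15, C=0.01, E=0.5, F=0.5, G=2.0,
                       T=0.5, phi0=1.0, psi0=0.1)


@pytest.fixture()
def toy_annotations() -> pd.DataFrame:
    """Hand-built single-genome annotation table.

    Layout on contig c1: one Immunity gene, an adjacent mutual-nearest
    toxin/antitoxin pair, a toxin--gene--antitoxin triple (intervening gene
    blocks the pair), one PDC gene and one unmapped gene.
    """
    rows = [
        # genome, species, glen, gene, contig, start, end, strand, system, role
        ("g1", "s1", 1_000_000, "imm1", "c1", 1_000, 2_499, "+", "CRISPR-Cas", "none"),
        ("g1", "s1", 1_000_000, "tox1", "c1", 10_000, 10_399, "+", "TA", "toxin"),
        ("g1", "s1", 1_000_000, "ant1", "c1", 10_500, 10_899, "-", "TA", "antitoxin"),
        ("g1", "s1", 1_000_000, "tox2", "c1", 20_000, 20_399, "+", "TA", "toxin"),
        ("g1", "s1", 1_000_000, "mid1", "c1", 20_450, 20_480, "+", "background", "other"),
        ("g1", "s1", 1_000_000, "ant2", "c1", 20_500, 20_899, "+", "TA", "antitoxin"),
        ("g1", "s1", 1_000_000, "pdc1", "c1", 30_000, 30_999, "+", "PDC", "none"),
        ("g1", "s1", 1_000_000, "unk1", "c1", 40_000, 40_999, "+", "mystery", "none"),
    ]
    from defensim.investment import ANNOTATION_COLUMNS

    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


@pytest.fixture()
def toy_classification() -> dict:
    return {"CRISPR-Cas": "Immunity", "CBASS": "PCD", "PDC": "undefined"}


@pytest.fixture()
def powerlaw_data():
    """Synthetic investments exactly from the generating model."""
    from defensim.synth import SyntheticConfig, gen_investment_table

    cfg = SyntheticConfig(seed=11, n_species=1500, alpha=0.554, beta=0.04,
                          epsilon=0.8)
    return gen_investment_table(cfg)


def spearman_sign(x, y) -> float:
    from scipy.stats import spearmanr

    rho = spearmanr(x, y).statistic
    return 0.0 if np.isnan(rho) else float(rho)
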