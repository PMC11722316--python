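"""Synthetic inputs for the comparative-genomics pipeline.

The statistical pipeline (investment computation, power-law regression,
abundance classification, deviation analysis) is exercised on synthetic
tables with the same structure the genomic and microbiome extracts have:

* per-species investments from the lognormal power-law errors-in-variables
  model ``I_PCD = beta * I_Imm**alpha`` with a latent per-species
  investment drawn log-uniformly;
* gene-annotation tables with planted defense genes and toxin/antitoxin
  modules of known ground truth (including negative cases);
* species x sample rank-abundance tables with planted consistently
  high- and low-abundant classes.

All generators are deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .investment import ANNOTATION_COLUMNS

__all__ = [
    "SyntheticConfig",
    "gen_investment_table",
    "gen_annotation_table",
    "gen_rank_abundance",
]


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic generators.

    Defaults emulate the real extracts: 4,657 species with positive
    investments (the power-law fit's sample size), latent log-investment
    uniform on [log 1e-4, log 1e-1], exponent ``alpha = 0.554``, and
    genome sizes lognormal around a 3.5 Mnt median.
    """

    seed: int = 0
    # investment table
    n_species: int = 4657
    alpha: float = 0.554
    beta: float = 0.04
    epsilon: float = 0.8
    latent_log_range: tuple[float, float] = (np.log(1e-4), np.log(1e-1))
    zero_fraction: float = 0.0
    genome_size_median: float = 3.5e6
    genome_size_log_sd: float = 0.35
    #: coupling of genome size to PCD investment (log-log slope), used to
    #: give the deviation analysis a planted size effect
    size_coupling: float = 0.0
    #: extra per-pathway investment columns (functional-system controls for
    #: the deviation analysis, including a random-profile set)
    n_pathways: int = 0
    pathway_coupling_sd: float = 0.5
    # rank-abundance table
    n_samples: int = 300
    n_high: int = 40
    n_low: int = 40
    n_ranked_species: int = 120
    class_separation: float = 3.0
    sample_noise: float = 1.0
    detection_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.n_high + self.n_low > self.n_ranked_species:
            raise ValueError("n_high + n_low must not exceed n_ranked_species")
        lo, hi = self.latent_log_range
        if not (lo < hi):
            raise ValueError("latent_log_range must be increasing")
        for name in ("epsilon", "genome_size_median", "genome_size_log_sd",
                     "sample_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def gen_investment_table(cfg: SyntheticConfig) -> pd.DataFrame:
    """Per-species investment records from the generating power law.

    ``I_Imm = I_best * LogNorm(eps)`` and
    ``I_PCD = beta * I_best**alpha * LogNorm(eps)``; a ``zero_fraction`` of
    records has one investment zeroed to exercise the zero filter; genome
    sizes are lognormal, optionally coupled to the latent investment.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.latent_log_range
    mu = rng.uniform(lo, hi, size=cfg.n_species)
    x = mu + rng.normal(0.0, cfg.epsilon, size=cfg.n_species)
    y = (np.log(cfg.beta) + cfg.alpha * mu
         + rng.normal(0.0, cfg.epsilon, size=cfg.n_species))
    log_size = (np.log(cfg.genome_size_median)
                + cfg.size_coupling * (mu - 0.5 * (lo + hi))
                + rng.normal(0.0, cfg.genome_size_log_sd, size=cfg.n_species))
    frame = pd.DataFrame(
        {
            "species_id": [f"sp{i:05d}" for i in range(cfg.n_species)],
            "genome_length": np.round(np.exp(log_size)),
            "I_Imm": np.exp(x),
            "I_PCD": np.exp(y),
        }
    )
    for k in range(cfg.n_pathways):
        slope = rng.normal(0.0, cfg.pathway_coupling_sd)
        frame[f"I_pathway{k:02d}"] = np.exp(
            rng.normal(np.log(3e-3), 0.5, size=cfg.n_species)
            + slope * (log_size - np.log(cfg.genome_size_median))
        )
    if cfg.zero_fraction > 0:
        n_zero = int(round(cfg.zero_fraction * cfg.n_species))
        idx = rng.choice(cfg.n_species, size=n_zero, replace=False)
        col = rng.random(n_zero) < 0.5
        frame.loc[idx[col], "I_Imm"] = 0.0
        frame.loc[idx[~col], "I_PCD"] = 0.0
    return frame


def gen_annotation_table(
    cfg: SyntheticConfig,
    n_genomes: int = 20,
    classification: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """Synthetic gene-annotation tables with planted ground truth.

    Each genome gets a planted Immunity gene, a planted PCD gene, a
    mutual-nearest toxin/antitoxin pair, a toxin-gene-antitoxin triple
    (no pair: intervening gene), a lone toxin (no pair: no counterpart),
    an excluded "PDC" gene, and background genes.  Returns
    ``(annotations, classification, truth)`` where ``truth`` holds the
    expected per-genome investments.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    cls = classification or {
        "CRISPR-Cas": "Immunity",
        "RM": "Immunity",
        "CBASS": "PCD",
        "AbiZ": "PCD",
        "PDC": "undefined",
        "mystery": "undefined",
    }
    rows = []
    truth_rows = []
    for g in range(n_genomes):
        genome = f"g{g:03d}"
        species = f"sp{g:03d}"
        glen = int(rng.integers(900_000, 1_100_000))
        pos = 1000
        gene_no = 0

        def add(length, system, role, gap=None):
            nonlocal pos, gene_no
            start = pos + int(gap if gap is not None else rng.integers(200, 2000))
            end = start + length - 1
            rows.append(
                (genome, species, glen, f"{genome}_{gene_no:03d}", "c1",
                 start, end, "+" if rng.random() < 0.5 else "-", system, role)
            )
            gene_no += 1
            pos = end
            return length

        imm_len = add(int(rng.integers(600, 3000)), "CRISPR-Cas", "none")
        add(int(rng.integers(500, 2000)), "background", "other")
        pcd_len = add(int(rng.integers(300, 1500)), "CBASS", "none")
        add(int(rng.integers(500, 2000)), "background", "other")
        # mutual-nearest adjacent TA pair -> counts toward PCD
        ta_len = add(int(rng.integers(250, 800)), "TA", "toxin")
        ta_len += add(int(rng.integers(250, 800)), "TA", "antitoxin", gap=80)
        add(int(rng.integers(500, 2000)), "background", "other", gap=5000)
        # planted negative: toxin-gene-antitoxin triple, no pair
        add(int(rng.integers(250, 800)), "TA", "toxin", gap=4000)
        add(int(rng.integers(200, 600)), "background", "other", gap=60)
        add(int(rng.integers(250, 800)), "TA", "antitoxin", gap=60)
        # planted negative: PDC gene, excluded from sums
        add(int(rng.integers(500, 2000)), "PDC", "none", gap=3000)
        truth_rows.append(
            {
                "genome_id": genome,
                "species_id": species,
                "genome_length": glen,
                "I_Imm": imm_len / glen,
                "I_PCD": (pcd_len + ta_len) / glen,
            }
        )
    annotations = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    return annotations, cls, pd.DataFrame(truth_rows)


def gen_rank_abundance(
    cfg: SyntheticConfig, return_truth: bool = False
):
    """Species x sample rank-abundance table with planted classes.

    Per-sample log-abundances are normal around a species baseline; the
    first ``n_high`` species get a baseline shifted up and the next
    ``n_low`` shifted down by ``class_separation`` (in units of the
    per-sample noise SD).  Ranks are assigned within a sample with larger
    rank = more abundant.  With ``detection_prob < 1`` species are missing
    from a fraction of samples, exercising the detection filter.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    ns, nsamp = cfg.n_ranked_species, cfg.n_samples
    species = np.array([f"sp{i:05d}" for i in range(ns)])
    base = rng.normal(0.0, 1.0, size=ns)
    shift = np.zeros(ns)
    shift[: cfg.n_high] = cfg.class_separation * cfg.sample_noise
    shift[cfg.n_high: cfg.n_high + cfg.n_low] = -cfg.class_separation * cfg.sample_noise
    logab = (base + shift)[:, None] + rng.normal(
        0.0, cfg.sample_noise, size=(ns, nsamp)
    )
    detected = rng.random((ns, nsamp)) < cfg.detection_prob
    records = []
    for j in range(nsamp):
        idx = np.nonzero(detected[:, j])[0]
        order = np.argsort(logab[idx, j])  # ascending: largest rank = most abundant
        for rank_m1, i in enumerate(idx[order]):
            records.append((species[i], f"sample{j:04d}", rank_m1 + 1))
    table = pd.DataFrame(records, columns=["species", "sample", "rank"])
    if return_truth:
        truth = {
            "high": list(species[: cfg.n_high]),
            "low": list(species[cfg.n_high: cfg.n_high + cfg.n_low]),
        }
        return table, truth
    return table
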