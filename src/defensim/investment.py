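"""Genomic investment in PCD vs immunity from gene-annotation tables.

Investment of a genome in a defense category is the fraction of genome
length (nucleotides) covered by genes of that category.  Defense systems
are classified as PCD, Immunity or undefined by a user-supplied mapping
(systems labelled "PDC", Phage Defense Candidate, and unmapped systems are
excluded).  Toxin-antitoxin modules enter the PCD category only as mutual
nearest toxin/antitoxin pairs with no intervening gene; unpaired toxin or
antitoxin genes are discarded.

Coordinates are 1-based inclusive (GFF convention).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "ANNOTATION_COLUMNS",
    "pair_toxin_antitoxin",
    "classify_defense_genes",
    "compute_investment",
]

ANNOTATION_COLUMNS = [
    "genome_id", "species_id", "genome_length", "gene_id", "contig",
    "start", "end", "strand", "system_label", "role",
]

#: "Phage Defense Candidate" labels are unclassifiable and noisy
EXCLUDED_SYSTEM_LABELS = {"PDC"}


def pair_toxin_antitoxin(genes: pd.DataFrame) -> list[tuple[str, str]]:
    """Mutual-nearest toxin/antitoxin pairs within one genome.

    A toxin and an antitoxin form a pair iff each is the other's closest
    counterpart (distance between gene starts, same contig) and no other
    annotated gene lies strictly between their intervals.  Each gene joins
    at most one pair; candidate genes are those whose ``role`` is ``toxin``
    or ``antitoxin`` (genes carrying additional functional profiles should
    be excluded upstream by labelling their role ``other``).

    Returns ``(toxin_gene_id, antitoxin_gene_id)`` tuples.
    """
    genes = genes.dropna(subset=["start", "end", "contig"])
    pairs: list[tuple[str, str]] = []
    for _, contig_genes in genes.groupby("contig", sort=True):
        cg = contig_genes.sort_values(["start", "gene_id"]).reset_index(drop=True)
        tox = cg[cg["role"] == "toxin"]
        ant = cg[cg["role"] == "antitoxin"]
        if tox.empty or ant.empty:
            continue
        t_nearest = {gid: _nearest(row_start, ant)
                     for gid, row_start in zip(tox["gene_id"], tox["start"])}
        a_nearest = {gid: _nearest(row_start, tox)
                     for gid, row_start in zip(ant["gene_id"], ant["start"])}
        for _, trow in tox.iterrows():
            a_id = t_nearest[trow["gene_id"]]
            if a_id is None or a_nearest.get(a_id) != trow["gene_id"]:
                continue
            arow = ant[ant["gene_id"] == a_id].iloc[0]
            if _has_intervening(cg, trow, arow):
                continue
            pairs.append((trow["gene_id"], a_id))
    return sorted(pairs)


def _nearest(start: float, candidates: pd.DataFrame):
    """gene_id of the candidate with the smallest start-distance; ties
    break to the smaller start coordinate, then gene_id."""
    if candidates.empty:
        return None
    d = (candidates["start"] - start).abs()
    order = np.lexsort(
        (candidates["gene_id"].to_numpy(), candidates["start"].to_numpy(), d.to_numpy())
    )
    return candidates["gene_id"].iloc[order[0]]


def _has_intervening(all_genes: pd.DataFrame, g1: pd.Series, g2: pd.Series) -> bool:
    """True if any other gene's interval lies strictly between g1 and g2."""
    left, right = (g1, g2) if g1["start"] <= g2["start"] else (g2, g1)
    others = all_genes[~all_genes["gene_id"].isin([g1["gene_id"], g2["gene_id"]])]
    between = (others["start"] > left["end"]) & (others["end"] < right["start"])
    return bool(between.any())


def classify_defense_genes(
    genes: pd.DataFrame, classification: dict[str, str]
) -> pd.DataFrame:
    """Tag each gene with a defense category.

    ``classification`` maps system labels to ``PCD`` / ``Immunity`` /
    ``undefined``.  Unmapped and ``PDC``-labelled systems become
    ``undefined`` (excluded from investment sums).  Toxin/antitoxin genes
    that form mutual-nearest pairs (per genome) are tagged ``PCD``;
    unpaired ones are dropped from the defense tally (category
    ``undefined``).
    """
    out = genes.copy()
    cat = out["system_label"].map(
        lambda s: "undefined" if s in EXCLUDED_SYSTEM_LABELS
        else classification.get(s, "undefined")
    )
    paired_ids: set[str] = set()
    ta_mask = out["role"].isin(["toxin", "antitoxin"])
    if ta_mask.any():
        for _, genome_genes in out.groupby("genome_id", sort=False):
            for t_id, a_id in pair_toxin_antitoxin(genome_genes):
                paired_ids.update((t_id, a_id))
        cat = cat.where(~ta_mask, "undefined")
        cat = cat.mask(out["gene_id"].isin(paired_ids), "PCD")
    out["category"] = cat
    return out


def compute_investment(
    genes: pd.DataFrame,
    classification: dict[str, str],
    seed: int = 0,
) -> pd.DataFrame:
    """Per-species genomic investments I_Imm and I_PCD.

    One representative genome is sampled per species (seeded); the
    investment per category is the fraction of genome length covered by
    the union of that category's gene intervals (overlaps counted once).
    """
    if (genes["genome_length"] <= 0).any():
        raise ValueError("genome_length must be positive for all records")
    tagged = classify_defense_genes(genes, classification)
    rng = np.random.default_rng(seed)
    rows = []
    for species, sp_genes in tagged.groupby("species_id", sort=True):
        genome_ids = sorted(sp_genes["genome_id"].unique())
        rep = genome_ids[rng.integers(len(genome_ids))]
        g = sp_genes[sp_genes["genome_id"] == rep]
        glen = float(g["genome_length"].iloc[0])
        rows.append(
            {
                "species_id": species,
                "genome_id": rep,
                "genome_length": glen,
                "I_Imm": _covered_length(g[g["category"] == "Immunity"]) / glen,
                "I_PCD": _covered_length(g[g["category"] == "PCD"]) / glen,
            }
        )
    return pd.DataFrame(rows)


def _covered_length(genes: pd.DataFrame) -> float:
    """Total nucleotides covered by the union of gene intervals
    (per contig; coordinates 1-based inclusive)."""
    total = 0
    for _, cg in genes.groupby("contig", sort=False):
        ivs = cg[["start", "end"]].sort_values("start").to_numpy()
        cur_s = cur_e = None
        for s, e in ivs:
            if cur_e is None:
                cur_s, cur_e = s, e
            elif s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        if cur_e is not None:
            total += cur_e - cur_s + 1
    return float(total)
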