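"""Pangenome gene-family profiles and the chiral-complexity enzyme model.

Builds genome x family relative-abundance matrices (percent of each
genome's total genes), selects the most abundant families, applies
per-family Z-score transforms, computes family-family Pearson
correlations, scores subgroup-specific paralog expansions, extracts
universal single-copy ortholog panels, and evaluates the
enzyme-requirement model for chirally complex substrates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class InputError(ValueError):
    """Raised when an input table violates a precondition."""


def compute_family_abundance(annotations: pd.DataFrame, genomes: pd.DataFrame,
                             families: Sequence[str] | None = None) -> pd.DataFrame:
    """Family x genome matrix of percent abundance of total genes.

    value(f, g) = 100 * (# genes of genome g annotated to family f) /
    total_genes(g).  Families absent from a genome are 0.  ``families``
    optionally declares the family universe (needed when the annotation
    table is empty); otherwise the universe is the families observed.
    """
    required = {"genome_id", "gene_id", "family_id"}
    if not required.issubset(annotations.columns):
        raise InputError(f"annotation table must have columns {sorted(required)}")
    genome_ids = list(genomes["genome_id"])
    totals = genomes.set_index("genome_id")["total_genes"]
    zero = totals[totals <= 0]
    if len(zero):
        raise InputError(f"genome(s) with total_genes = 0: {', '.join(zero.index)}")
    orphans = set(annotations["genome_id"]) - set(genome_ids)
    if orphans:
        raise InputError(f"annotations reference unknown genome(s): {sorted(orphans)}")

    counts = (annotations.groupby(["family_id", "genome_id"]).size().unstack(fill_value=0))
    fam_universe = sorted(set(families or []) | set(counts.index))
    counts = counts.reindex(index=fam_universe, columns=genome_ids, fill_value=0)
    abundance = 100.0 * counts.div(totals[genome_ids], axis=1)
    abundance.index.name = "family_id"
    return abundance


def select_top_families(matrix: pd.DataFrame, n: int) -> list[str]:
    """The ``n`` families with highest mean relative abundance across genomes.

    Ties are broken lexicographically by family identifier (smaller first).
    """
    if n < 1:
        raise InputError("n must be >= 1")
    if matrix.size == 0:
        raise InputError("abundance matrix is empty")
    means = matrix.mean(axis=1)
    order = sorted(means.index, key=lambda f: (-means[f], f))
    return order[: min(n, len(order))]


def zscore_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-family Z scores across genomes: Z = (x - mean) / sd, sample sd (n-1).

    Constant families (sd = 0) map to all-zero rows rather than erroring,
    since subset matrices routinely contain flat families.
    """
    if matrix.shape[1] < 2:
        raise InputError("Z-score transform needs >= 2 genomes (sample sd undefined)")
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    z = matrix.sub(mean, axis=0).div(sd.replace(0, np.nan), axis=0)
    return z.fillna(0.0)


def family_correlation(matrix: pd.DataFrame,
                       families: Sequence[str] | None = None) -> pd.DataFrame:
    """Pairwise Pearson r between family abundance profiles across genomes.

    Constant families give undefined correlations, reported as NaN
    (missing), never imputed as zero.
    """
    if matrix.shape[1] < 3:
        raise InputError("correlation needs >= 3 genomes")
    if families is not None:
        missing = set(families) - set(matrix.index)
        if missing:
            raise InputError(f"families not in matrix: {sorted(missing)}")
        matrix = matrix.loc[list(families)]
    corr = matrix.T.corr(method="pearson")
    # pandas puts 1.0 on the diagonal even for constant rows; mark those missing
    sd = matrix.std(axis=1, ddof=1)
    const = sd[sd == 0].index
    corr.loc[const, :] = np.nan
    corr.loc[:, const] = np.nan
    return corr


@dataclass
class ExpansionScore:
    """Subgroup-enrichment of one gene family.

    score = (mean abundance in subgroup + eps) / (mean abundance elsewhere
    + eps); max_copies is the family's largest raw copy count within the
    subgroup (NaN when raw counts are not supplied).
    """

    family: str
    subgroup: str
    score: float
    max_copies: float


def expansion_scores(matrix: pd.DataFrame, genomes: pd.DataFrame,
                     pseudocount: float = 0.01,
                     counts: pd.DataFrame | None = None) -> list[ExpansionScore]:
    """Mean-ratio expansion scores for every (family, subgroup) pair.

    ``counts`` is an optional genome x family raw copy-count matrix used
    to report max copies per subgroup alongside the abundance ratio.
    """
    if "subgroup" not in genomes.columns or genomes["subgroup"].isna().any():
        raise InputError("every genome needs a subgroup label")
    sub_of = genomes.set_index("genome_id")["subgroup"]
    cols = [g for g in matrix.columns if g in sub_of.index]
    if len(cols) < len(matrix.columns):
        raise InputError("abundance matrix contains genomes missing from the genome table")
    groups = sub_of[cols]
    out: list[ExpansionScore] = []
    for sg in sorted(groups.unique()):
        in_cols = [g for g in cols if groups[g] == sg]
        out_cols = [g for g in cols if groups[g] != sg]
        if not in_cols:
            logger.warning("subgroup %s has zero genomes; skipped", sg)
            continue
        mean_in = matrix[in_cols].mean(axis=1)
        mean_out = matrix[out_cols].mean(axis=1) if out_cols else pd.Series(0.0, index=matrix.index)
        score = (mean_in + pseudocount) / (mean_out + pseudocount)
        for fam in matrix.index:
            mc = float("nan")
            if counts is not None and fam in counts.columns:
                mc = float(counts.loc[counts.index.intersection(in_cols), fam].max())
            out.append(ExpansionScore(family=fam, subgroup=sg,
                                      score=float(score[fam]), max_copies=mc))
    return out


def expansion_table(scores: list[ExpansionScore]) -> pd.DataFrame:
    df = pd.DataFrame([vars(s) for s in scores])
    return df.sort_values("score", ascending=False, kind="mergesort").reset_index(drop=True)


def single_copy_panel(membership: pd.DataFrame) -> list[str]:
    """Clusters present at copy number exactly 1 in every genome of the set.

    ``membership`` maps (genome_id, cluster_id) -> copy_count; absent
    pairs count as copy 0, which excludes the cluster.
    """
    required = {"genome_id", "cluster_id", "copy_count"}
    if not required.issubset(membership.columns):
        raise InputError(f"membership table must have columns {sorted(required)}")
    if len(membership) == 0:
        return []
    wide = membership.pivot_table(index="cluster_id", columns="genome_id",
                                  values="copy_count", fill_value=0, aggfunc="sum")
    universal = wide.index[(wide == 1).all(axis=1)]
    return sorted(universal)


def enzyme_requirement(n_centers: int, racemization_available: bool) -> int:
    """Enzymes needed to degrade all stereoisomers of a compound.

    A compound with n chiral centers has 2^n stereoisomers; without
    racemases a dedicated degradative enzyme is needed for each, so the
    requirement grows as 2^n.  With a racemase available per center the
    stereoisomers interconvert and one degradative enzyme plus n
    racemases (n + 1 total) suffice.
    """
    if n_centers < 0:
        raise InputError("n_centers must be >= 0")
    if racemization_available:
        return n_centers + 1
    return 2**n_centers
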