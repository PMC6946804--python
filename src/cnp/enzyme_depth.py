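"""Taxon-specific enzyme-family abundance versus depth.

Per-sample family abundance is normalized within the focal taxon by the
count of single-copy marker genes — dividing the number of taxon genes
annotated to the family (e.g. flavin-dependent monooxygenases) by the
number of taxon genes hitting any panel cluster — which cancels both
sequencing depth and taxon abundance, leaving a per-cell copy-number
proxy.  Depth trends are summarized by Pearson correlation with a
two-sided t-based p-value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class InputError(ValueError):
    pass


@dataclass
class NormalizedAbundance:
    """One sample's single-copy-normalized family abundance (NaN = missing)."""

    sample_id: str
    depth: float
    family: str
    value: float


@dataclass
class DepthCorrelation:
    family: str
    r: float
    p_value: float
    n: int


def normalized_family_abundance(genes: pd.DataFrame, taxon: str, family: str,
                                single_copy_panel: Sequence[str],
                                depth: float = float("nan"),
                                sample_id: str | None = None) -> NormalizedAbundance:
    """Family gene count / single-copy gene count, within one sample and taxon.

    The denominator counts gene occurrences hitting any panel cluster
    (total single-copy genes), not distinct clusters.  A zero denominator
    yields a missing value (NaN) with a logged warning — never 0 or inf.
    """
    panel = set(single_copy_panel)
    if not panel:
        raise InputError("single-copy panel must be nonempty")
    sub = genes[genes["taxon"] == taxon]
    if sample_id is None:
        ids = sub["sample_id"].unique() if "sample_id" in sub.columns else ["?"]
        sample_id = str(ids[0]) if len(ids) else "?"
    elif "sample_id" in sub.columns:
        sub = sub[sub["sample_id"] == sample_id]
    n_family = int((sub["family_id"] == family).sum())
    n_scg = int(sub["family_id"].isin(panel).sum())
    if n_scg == 0:
        logger.warning("sample %s: zero single-copy genes for taxon %s; value missing",
                       sample_id, taxon)
        value = float("nan")
    else:
        value = n_family / n_scg
    return NormalizedAbundance(sample_id=sample_id, depth=depth, family=family, value=value)


def normalized_abundance_table(gene_taxon: pd.DataFrame, samples: pd.DataFrame,
                               taxon: str, family: str,
                               single_copy_panel: Sequence[str]) -> pd.DataFrame:
    """Per-sample normalized abundances as a tidy table (sample_id, depth_m, family, value)."""
    depth_of = samples.set_index("sample_id")["depth_m"]
    rows = []
    for sid in samples["sample_id"]:
        na = normalized_family_abundance(gene_taxon, taxon, family, single_copy_panel,
                                         depth=float(depth_of[sid]), sample_id=sid)
        rows.append(dict(sample_id=sid, depth_m=na.depth, family=family, value=na.value))
    return pd.DataFrame(rows)


def depth_correlation(values: Sequence[float] | pd.Series,
                      depths: Sequence[float] | pd.Series,
                      family: str = "", log_depth: bool = False) -> DepthCorrelation:
    """Pearson r between normalized abundance and depth.

    Missing values are excluded pairwise; < 3 usable pairs is an error;
    zero variance on either axis gives a missing (NaN) correlation with a
    diagnostic rather than a crash.  ``log_depth`` correlates against
    ln(depth) instead of linear meters.
    """
    v = np.asarray(values, dtype=float)
    d = np.asarray(depths, dtype=float)
    if v.shape != d.shape:
        raise InputError("values and depths must have equal length")
    ok = np.isfinite(v) & np.isfinite(d)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("depth_correlation: dropped %d missing pair(s)", dropped)
    v, d = v[ok], d[ok]
    if len(v) < 3:
        raise InputError(f"need >= 3 non-missing (value, depth) pairs, have {len(v)}")
    if log_depth:
        d = np.log(d)
    if np.std(v) == 0 or np.std(d) == 0:
        logger.warning("depth_correlation: zero variance; correlation undefined")
        return DepthCorrelation(family=family, r=float("nan"),
                                p_value=float("nan"), n=len(v))
    r, p = stats.pearsonr(v, d)
    return DepthCorrelation(family=family, r=float(r), p_value=float(p), n=len(v))


def per_genome_depth_correlation(genomes: pd.DataFrame, abundance: pd.DataFrame,
                                 family: str, log_depth: bool = False) -> DepthCorrelation:
    """Pearson r between a family's percent abundance per genome and depth of origin."""
    if family not in abundance.index:
        raise InputError(f"family {family!r} not in abundance matrix")
    depth = genomes.set_index("genome_id")["depth_origin_m"]
    common = [g for g in abundance.columns if g in depth.index]
    if len(common) < 3:
        raise InputError("need >= 3 genomes with known depth of origin")
    return depth_correlation(abundance.loc[family, common].to_numpy(),
                             depth[common].to_numpy(), family=family, log_depth=log_depth)


def select_samples(fractions: pd.DataFrame, min_fraction: float = 0.01) -> list[str]:
    """Samples whose focal-taxon read fraction is at least ``min_fraction``.

    The threshold is inclusive ("at least"); input order is preserved.
    Expects columns sample_id and fraction (on [0, 1]).
    """
    if len(fractions) == 0:
        return []
    f = fractions["fraction"].astype(float)
    if ((f < 0) | (f > 1)).any():
        raise InputError("fractions must lie in [0, 1]")
    return list(fractions.loc[f >= min_fraction, "sample_id"])
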