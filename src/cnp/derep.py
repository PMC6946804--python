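"""Genome-bin quality filtering, k-mer ANI estimation, and 99%-ANI dereplication.

Quality filtering applies strict thresholds on single-copy-marker
redundancy (< 1.1%) and contamination (< 5%).  Average nucleotide
identity between bins is estimated from the Jaccard similarity J of
canonical k-mer sets via the Mash distance identity
ANI = 1 + (1/k) * ln(2J / (1 + J)), which is accurate in the
near-identical regime where the dereplication threshold (ANI >= 0.99)
operates.  Bins joined by above-threshold edges form components; within
each component the highest-quality bin (Q = completeness - 5 x
contamination) is retained, unless an edge joins bins from the same
station, in which case the whole component is flagged for merging
(coassembly itself is out of scope).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from numpy.lib.stride_tricks import sliding_window_view

logger = logging.getLogger(__name__)


class InputError(ValueError):
    pass


def quality_filter(genomes: pd.DataFrame, max_redundancy: float = 1.1,
                   max_contamination: float = 5.0) -> list[str]:
    """Bins with redundancy < ``max_redundancy`` and contamination < ``max_contamination``.

    Both inequalities are strict: a bin at exactly 1.1% redundancy or
    exactly 5.0% contamination is excluded.
    """
    for col in ("redundancy", "contamination"):
        if col not in genomes.columns:
            raise InputError(f"genome table lacks a {col!r} column")
        bad = genomes.loc[genomes[col].isna(), "genome_id"]
        if len(bad):
            raise InputError(f"missing {col} for genome(s): {', '.join(bad)}")
    keep = (genomes["redundancy"] < max_redundancy) & (genomes["contamination"] < max_contamination)
    return list(genomes.loc[keep, "genome_id"])


@dataclass
class BinPairANI:
    bin_a: str
    bin_b: str
    ani: float  # fraction in [0, 1]
    shared_kmer_jaccard: float
    no_overlap: bool = False


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Canonical k-mer integer codes (min of forward and reverse-complement codes).

    Windows containing non-ACGT characters are dropped.
    """
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    code = np.full(arr.shape, 255, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        code[arr == b] = i
    n = len(code) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    valid = code != 255
    ok = np.ones(n, dtype=bool)
    bad = np.flatnonzero(~valid)
    for j in bad:  # rare in synthetic data; invalidate covering windows
        ok[max(0, j - k + 1): j + 1] = False
    weights_f = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    weights_r = 4 ** np.arange(k, dtype=np.int64)
    win = sliding_window_view(code, k)
    fwd = win @ weights_f
    rc = (3 - win) @ weights_r  # complement then reverse == reversed weights
    canon = np.minimum(fwd, rc)[ok]
    return np.unique(canon)


def estimate_ani(seq_a: str, seq_b: str, k: int = 21) -> BinPairANI:
    """Mash-style ANI from canonical k-mer Jaccard similarity.

    ANI = 1 + (1/k) ln(2J / (1 + J)), clamped to [0, 1].  Disjoint k-mer
    sets (J = 0) report ANI 0 with the ``no_overlap`` flag set.  Accepts
    raw sequence strings (multi-contig bins: concatenate via
    :func:`load_bin_sequence`).
    """
    if k < 1 or k % 2 == 0:
        raise InputError("k must be a positive odd integer")
    if len(seq_a) < k or len(seq_b) < k:
        raise InputError(f"sequences must be at least k={k} bases long")
    ka, kb = _kmer_codes(seq_a, k), _kmer_codes(seq_b, k)
    inter = len(np.intersect1d(ka, kb, assume_unique=True))
    union = len(ka) + len(kb) - inter
    j = inter / union if union else 0.0
    if j == 0.0:
        return BinPairANI("seqA", "seqB", ani=0.0, shared_kmer_jaccard=0.0, no_overlap=True)
    ani = 1.0 + np.log(2 * j / (1 + j)) / k
    return BinPairANI("seqA", "seqB", ani=float(np.clip(ani, 0.0, 1.0)),
                      shared_kmer_jaccard=float(j))


def load_bin_sequence(fasta_path: str | Path) -> str:
    """Concatenate all contigs of a bin FASTA into one string for k-mer extraction."""
    return "".join(str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta"))


def ani_matrix(bins: dict[str, str], k: int = 21) -> list[BinPairANI]:
    """All-vs-all ANI over a mapping of bin id -> sequence."""
    ids = sorted(bins)
    out = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            pair = estimate_ani(bins[a], bins[b], k=k)
            pair.bin_a, pair.bin_b = a, b
            out.append(pair)
    return out


@dataclass
class DereplicationDecision:
    bin: str
    action: str  # retain | discard | merge_candidate
    partner: str | None
    reason: str


def quality_score(completeness: float, contamination: float,
                  contamination_weight: float = 5.0) -> float:
    """Q = completeness - w x contamination (dRep-style combined score)."""
    return completeness - contamination_weight * contamination


def dereplicate(genomes: pd.DataFrame, pairs: Iterable[BinPairANI],
                threshold: float = 0.99,
                contamination_weight: float = 5.0) -> list[DereplicationDecision]:
    """Decide retain / discard / merge_candidate for every bin.

    Bins form a graph with edges where ANI >= ``threshold`` (inclusive).
    Components containing a same-station edge are flagged merge_candidate
    wholesale (candidates for coassembly); in every other multi-bin
    component the bin maximizing Q = completeness - 5 x contamination is
    retained (ties: larger size_bp, then lexicographically smaller id)
    and the rest are discarded naming it.  Station comes from the genome
    table's ``station`` column when present.

    Decisions partition the input and are independent of bin or pair
    input order.
    """
    if not (0 < threshold <= 1):
        raise InputError("threshold must be in (0, 1]")
    meta = genomes.set_index("genome_id")
    known = set(meta.index)
    g = nx.Graph()
    g.add_nodes_from(sorted(known))
    same_station_edges = set()
    for p in pairs:
        for b in (p.bin_a, p.bin_b):
            if b not in known:
                raise InputError(f"ANI pair references unknown bin {b!r}")
        if p.ani >= threshold:
            g.add_edge(p.bin_a, p.bin_b, ani=p.ani)
            if "station" in meta.columns and meta.loc[p.bin_a, "station"] == meta.loc[p.bin_b, "station"]:
                same_station_edges.add(frozenset((p.bin_a, p.bin_b)))

    def rank_key(b: str):
        q = quality_score(float(meta.loc[b, "completeness"]),
                          float(meta.loc[b, "contamination"]), contamination_weight)
        size = float(meta.loc[b, "size_bp"]) if "size_bp" in meta.columns else 0.0
        return (-q, -size, b)

    decisions = []
    for comp in nx.connected_components(g):
        members = sorted(comp, key=rank_key)
        if len(members) == 1:
            decisions.append(DereplicationDecision(members[0], "retain", None,
                                                   "no bin above ANI threshold"))
            continue
        has_same_station = any(frozenset((a, b)) in same_station_edges
                               for a, b in g.subgraph(comp).edges)
        if has_same_station:
            for b in members:
                partner = members[0] if b != members[0] else members[1]
                decisions.append(DereplicationDecision(
                    b, "merge_candidate", partner,
                    "component contains near-identical same-station bins"))
        else:
            best = members[0]
            decisions.append(DereplicationDecision(
                best, "retain", None,
                f"highest quality score in component of {len(members)}"))
            for b in members[1:]:
                decisions.append(DereplicationDecision(
                    b, "discard", best,
                    f"ANI >= {threshold:g} with higher-quality bin {best}"))
    decisions.sort(key=lambda d: d.bin)
    return decisions


def decisions_table(decisions: list[DereplicationDecision]) -> pd.DataFrame:
    return pd.DataFrame([vars(d) for d in decisions])
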