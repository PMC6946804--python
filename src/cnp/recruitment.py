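"""Fragment-recruitment: alignment parsing, filtering, and base-normalized matrices.

Reads arrive as BLAST-outfmt-6-style tabular alignments (the dialect is
configurable).  Alignments below the identity cutoff (default 80%,
matching common fragment-recruitment practice) or overlapping an rRNA
mask are discarded, and recruitment per (genome, sample) is reported as
aligned bases divided by total read bases in the sample — a
dimensionless fraction — alongside a genome-size-normalized per-Mbp
variant.

Coordinates: BED masks are 0-based half-open; tabular alignment
coordinates are 1-based inclusive and are converted at parse time, so
the internal representation is uniformly 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentDialect:
    """Zero-based column positions in a tab-separated alignment file."""

    query: int = 0
    subject: int = 1
    pident: int = 2
    length: int = 3
    sstart: int = 8
    send: int = 9
    bitscore: int | None = 11
    min_columns: int = 12


BLAST6 = AlignmentDialect()

ALIGNMENT_COLUMNS = ["read_id", "genome_id", "pct_identity", "aligned_bases",
                     "ref_start", "ref_end"]


def parse_alignments(stream: IO[str] | str | Path,
                     dialect: AlignmentDialect = BLAST6) -> pd.DataFrame:
    """Parse a tabular alignment stream into an alignment table.

    Returns a DataFrame with columns read_id, genome_id, pct_identity,
    aligned_bases, ref_start, ref_end (0-based half-open on the
    reference) and bit_score when the dialect provides one.  Raises
    :class:`ParseError` naming the offending line on malformed input.
    """
    close = False
    if isinstance(stream, (str, Path)):
        stream = open(stream)
        close = True
    rows = []
    try:
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < dialect.min_columns:
                raise ParseError(
                    f"line {lineno}: expected >= {dialect.min_columns} columns, got {len(parts)}")
            try:
                pident = float(parts[dialect.pident])
                length = int(parts[dialect.length])
                sstart = int(parts[dialect.sstart])
                send = int(parts[dialect.send])
                bits = float(parts[dialect.bitscore]) if dialect.bitscore is not None else 0.0
            except ValueError as e:
                raise ParseError(f"line {lineno}: {e}") from None
            if sstart < 1 or send < 1:
                raise ParseError(f"line {lineno}: reference coordinates must be >= 1 (1-based)")
            if length < 1:
                raise ParseError(f"line {lineno}: aligned length < 1")
            lo, hi = min(sstart, send), max(sstart, send)
            rows.append((parts[dialect.query], parts[dialect.subject], pident,
                         length, lo - 1, hi, bits))
    finally:
        if close:
            stream.close()
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS + ["bit_score"])


class MaskSet:
    """Per-genome exclusion intervals, stored normalized (sorted, merged).

    Intervals are 0-based half-open on each genome's concatenated contigs.
    """

    def __init__(self, intervals: dict[str, Iterable[tuple[int, int]]] | None = None):
        self._trees: dict[str, IntervalTree] = {}
        for genome, ivs in (intervals or {}).items():
            tree = IntervalTree()
            for start, end in ivs:
                if end <= start or start < 0:
                    raise InputError(f"bad mask interval ({start}, {end}) for {genome}")
                tree.addi(start, end)
            tree.merge_overlaps(strict=False)
            self._trees[genome] = tree

    @classmethod
    def from_bed(cls, path: str | Path) -> "MaskSet":
        """Load a BED3 file (chrom = genome id, 0-based half-open)."""
        bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                          usecols=[0, 1, 2], names=["genome_id", "start", "end"])
        intervals: dict[str, list[tuple[int, int]]] = {}
        for _, r in bed.iterrows():
            intervals.setdefault(str(r["genome_id"]), []).append((int(r["start"]), int(r["end"])))
        return cls(intervals)

    def overlaps(self, genome: str, start: int, end: int) -> bool:
        tree = self._trees.get(genome)
        return bool(tree.overlap(start, end)) if tree is not None else False

    def intervals(self, genome: str) -> list[tuple[int, int]]:
        tree = self._trees.get(genome)
        return sorted((iv.begin, iv.end) for iv in tree) if tree is not None else []


def filter_alignments(records: pd.DataFrame, min_identity: float = 80.0,
                      mask: MaskSet | None = None,
                      dedup_per_read: bool = True) -> pd.DataFrame:
    """Identity and rRNA-mask filtering.

    Retains records with pct_identity >= ``min_identity`` (the cutoff is
    inclusive) whose reference interval overlaps no mask interval by even
    a single base.  When ``dedup_per_read`` is on, multi-mapped reads are
    counted once per (read, genome): the best hit by bit score wins when
    available, otherwise the first occurrence.
    """
    if not (0 <= min_identity <= 100):
        raise InputError("min_identity must be in [0, 100]")
    kept = records[records["pct_identity"] >= min_identity]
    if mask is not None and len(kept):
        ok = [not mask.overlaps(g, s, e)
              for g, s, e in zip(kept["genome_id"], kept["ref_start"], kept["ref_end"])]
        kept = kept[ok]
    if dedup_per_read and len(kept):
        before = len(kept)
        if "bit_score" in kept.columns:
            kept = kept.sort_values("bit_score", ascending=False, kind="mergesort")
        subset = ["read_id", "genome_id"]
        if "sample_id" in kept.columns:
            subset = ["sample_id"] + subset
        kept = kept.drop_duplicates(subset=subset, keep="first").sort_index()
        if len(kept) != before:
            logger.info("deduplicated %d multi-hit alignment(s)", before - len(kept))
    return kept.reset_index(drop=True)


def compute_recruitment(records: pd.DataFrame, genomes: pd.DataFrame,
                        samples: pd.DataFrame,
                        order: list[str] | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-genome, per-sample recruitment matrices.

    Primary metric: R(g, s) = sum of aligned bases of g in s / total read
    bases of s (fraction).  Secondary: R_per_mbp(g, s) = R(g, s) /
    genome size in bp * 1e6.  ``records`` must carry a ``sample_id``
    column; ``order`` fixes the genome row order (e.g. tree order).
    """
    if "sample_id" not in records.columns:
        raise InputError("alignment records need a sample_id column for recruitment")
    known_g = set(genomes["genome_id"])
    known_s = set(samples["sample_id"])
    bad_g = set(records["genome_id"]) - known_g
    if bad_g:
        raise InputError(f"unknown genome id(s) in alignments: {sorted(bad_g)[:5]}")
    bad_s = set(records["sample_id"]) - known_s
    if bad_s:
        raise InputError(f"unknown sample id(s) in alignments: {sorted(bad_s)[:5]}")
    totals = samples.set_index("sample_id")["total_bases"]
    if (totals <= 0).any():
        zero = totals[totals <= 0].index
        raise InputError(f"sample(s) with total_bases <= 0: {list(zero)}")

    rows = order if order is not None else sorted(known_g)
    cols = list(samples["sample_id"])
    summed = (records.groupby(["genome_id", "sample_id"])["aligned_bases"].sum()
              .unstack(fill_value=0).reindex(index=rows, columns=cols, fill_value=0))
    frac = summed.div(totals[cols], axis=1).astype(float)
    size = genomes.set_index("genome_id")["size_bp"]
    per_mbp = frac.div(size[rows], axis=0) * 1e6
    frac.index.name = per_mbp.index.name = "genome_id"
    return frac, per_mbp
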