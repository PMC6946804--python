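"""Seeded generators for every input the pipeline consumes.

Each generator returns plain pandas tables shaped like the real inputs
(genome metadata, gene-family annotations, alignment tables, gene
catalogs, FTICR-MS peak lists, FASTA pairs) together with a *truth
record* describing the planted effects, so every downstream stage can be
tested by parameter recovery rather than against opaque fixtures.

All randomness flows from a single integer seed; each artifact draws
from its own named child generator so artifacts can be regenerated
independently.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

OXYGEN_MASS = 15.994915  # Da, monoisotopic
CARBON_MASS = 12.000000  # Da, monoisotopic (12C definition)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """Raised when a simulation config violates its invariants."""


def _child_rng(seed: int, label: str) -> np.random.Generator:
    """Named child generator: independent stream per artifact.

    Uses crc32 of the label (stable across processes, unlike ``hash``).
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]))


def _negbin(rng: np.random.Generator, mean, dispersion: float, size=None):
    """Negative binomial with mean ``mean`` and size parameter ``dispersion``.

    Variance = mean + mean^2 / dispersion; large dispersion -> Poisson-like.
    """
    mean = np.asarray(mean, dtype=float)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


# ---------------------------------------------------------------------------
# Pangenome
# ---------------------------------------------------------------------------

@dataclass
class PangenomeSimConfig:
    """Genomes grouped into subclades with planted paralog expansions.

    ``expansions`` is a list of ``(subgroup, family, planted_copy_mean)``
    triples: in the named subgroup the family's per-genome copy number is
    negative-binomial with that mean; everywhere else it stays at
    ``background_copy_mean``.
    """

    n_subgroups: int = 5
    genomes_per_subgroup: int = 20
    n_families: int = 300
    background_copy_mean: float = 2.0
    copy_dispersion: float = 5.0
    expansions: list[tuple[str, str, float]] = field(default_factory=list)
    depth_range_per_subgroup: dict[str, tuple[float, float]] | None = None
    n_single_copy_families: int = 30
    seed: int = 0

    @property
    def subgroups(self) -> list[str]:
        return [f"SG{i + 1:02d}" for i in range(self.n_subgroups)]

    @property
    def families(self) -> list[str]:
        return [f"FAM{i + 1:04d}" for i in range(self.n_families)]

    def validate(self) -> None:
        for name in ("n_subgroups", "genomes_per_subgroup", "n_families"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.background_copy_mean <= 0:
            raise ConfigError("background_copy_mean must be > 0")
        if self.n_single_copy_families < 0:
            raise ConfigError("n_single_copy_families must be >= 0")
        known_sg, known_fam = set(self.subgroups), set(self.families)
        for sg, fam, mean in self.expansions:
            if sg not in known_sg:
                raise ConfigError(f"expansions: unknown subgroup {sg!r}")
            if fam not in known_fam:
                raise ConfigError(f"expansions: family {fam!r} not in family universe")
            if mean <= 0:
                raise ConfigError(f"expansions: planted_copy_mean must be > 0 for {fam!r}")
        if self.depth_range_per_subgroup is not None:
            for sg, (lo, hi) in self.depth_range_per_subgroup.items():
                if lo < 0 or hi < lo:
                    raise ConfigError(f"depth_range_per_subgroup: bad range for {sg!r}")


def _default_depth_ranges(subgroups: Sequence[str]) -> dict[str, tuple[float, float]]:
    """Stack subgroups down the water column: epipelagic first, hadal last."""
    edges = np.geomspace(10, 6000, len(subgroups) + 1)
    return {sg: (float(edges[i]), float(edges[i + 1])) for i, sg in enumerate(subgroups)}


def generate_pangenome(config: PangenomeSimConfig):
    """Generate (genome table, annotation table, truth record).

    The annotation table has one row per gene copy (genome_id, gene_id,
    family_id).  Single-copy marker families (``SCG####``) are planted at
    exactly one copy per genome to support normalization-panel tests.
    """
    config.validate()
    rng = _child_rng(config.seed, "pangenome")
    subgroups = config.subgroups
    families = config.families
    scg_families = [f"SCG{i + 1:04d}" for i in range(config.n_single_copy_families)]
    depth_ranges = config.depth_range_per_subgroup or _default_depth_ranges(subgroups)

    exp_map = {(sg, fam): mean for sg, fam, mean in config.expansions}

    genome_rows, ann_rows = [], []
    n_fam = len(families)
    for si, sg in enumerate(subgroups):
        means = np.full(n_fam, config.background_copy_mean)
        for fi, fam in enumerate(families):
            if (sg, fam) in exp_map:
                means[fi] = exp_map[(sg, fam)]
        lo, hi = depth_ranges[sg]
        for gi in range(config.genomes_per_subgroup):
            gid = f"{sg}_bin{gi + 1:03d}"
            copies = _negbin(rng, means, config.copy_dispersion)
            total = int(copies.sum()) + len(scg_families)
            depth = float(rng.uniform(lo, hi))
            genome_rows.append(
                dict(
                    genome_id=gid,
                    subgroup=sg,
                    depth_origin_m=round(depth, 1),
                    total_genes=total,
                    completeness=round(float(rng.uniform(70, 100)), 2),
                    redundancy=round(float(rng.uniform(0, 1.0)), 3),
                    contamination=round(float(rng.uniform(0, 4.0)), 3),
                    size_bp=int(total * rng.uniform(900, 1100)),
                    station=f"ST{rng.integers(1, 1 + config.n_subgroups * 4):03d}",
                )
            )
            gene_no = 0
            for fi, fam in enumerate(families):
                for _ in range(int(copies[fi])):
                    gene_no += 1
                    ann_rows.append((gid, f"{gid}_g{gene_no:05d}", fam))
            for fam in scg_families:
                gene_no += 1
                ann_rows.append((gid, f"{gid}_g{gene_no:05d}", fam))

    genomes = pd.DataFrame(genome_rows)
    annotations = pd.DataFrame(ann_rows, columns=["genome_id", "gene_id", "family_id"])
    truth = {
        "expansions": [list(e) for e in config.expansions],
        "background_copy_mean": config.background_copy_mean,
        "single_copy_families": scg_families,
        "depth_range_per_subgroup": {k: list(v) for k, v in depth_ranges.items()},
        "seed": config.seed,
    }
    return genomes, annotations, truth


# ---------------------------------------------------------------------------
# Community / fragment recruitment
# ---------------------------------------------------------------------------

@dataclass
class NicheCurve:
    """Gaussian relative-abundance profile over depth (center m, width m, peak in [0,1])."""

    center: float
    width: float
    peak: float

    def __call__(self, depth) -> np.ndarray:
        d = np.asarray(depth, dtype=float)
        return self.peak * np.exp(-0.5 * ((d - self.center) / self.width) ** 2)


@dataclass
class CommunitySimConfig:
    """Depth-labeled metagenome samples with alignment records and gene catalogs."""

    depth_grid: Sequence[float] = field(default_factory=lambda: list(np.linspace(50, 5000, 20)))
    niche_curves: dict[str, NicheCurve] = field(default_factory=dict)
    reads_per_sample: int = 5000
    read_length: int = 100
    identity_mean: float = 95.0
    identity_sd: float = 4.0
    genes_per_sample: int = 5000
    other_taxon_fraction: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if len(self.depth_grid) == 0 or min(self.depth_grid) <= 0:
            raise ConfigError("depth_grid must be nonempty and strictly positive")
        for sg, curve in self.niche_curves.items():
            if not (0 <= curve.peak <= 1):
                raise ConfigError(f"niche_curves[{sg!r}].peak must be in [0, 1]")
        if self.reads_per_sample <= 0 or self.read_length <= 0:
            raise ConfigError("reads_per_sample and read_length must be > 0")


def generate_community(config: CommunitySimConfig, genomes: pd.DataFrame,
                       family_counts: pd.DataFrame | None = None):
    """Generate (sample table, alignment table, gene→taxon table).

    Reads are allocated to genomes by multinomial draw with weights
    proportional to the genome's subgroup niche-curve value at the sample
    depth (split evenly within a subgroup); the remaining probability
    mass is unaligned background, so per-sample aligned bases never
    exceed ``reads_per_sample * read_length``.

    ``family_counts`` (genomes x families raw copy counts, e.g. from
    :func:`generate_pangenome` annotations) drives the per-sample gene
    catalog: catalog genes are drawn genome-first (recruitment weights)
    then family (the genome's copy-number profile).  Without it the
    catalog contains only background taxa.
    """
    config.validate()
    if genomes is None or len(genomes) == 0:
        raise ValueError("genome table must be nonempty")
    rng = _child_rng(config.seed, "community")

    sub_of = genomes.set_index("genome_id")["subgroup"]
    size_of = genomes.set_index("genome_id")["size_bp"]
    gids = list(genomes["genome_id"])
    n_in_sub = genomes.groupby("subgroup")["genome_id"].count()

    samples, aln_rows, gene_rows = [], [], []
    for si, depth in enumerate(sorted(config.depth_grid)):
        sid = f"S{si + 1:03d}"
        total_bases = config.reads_per_sample * config.read_length
        samples.append(dict(sample_id=sid, station=f"ST{si + 1:03d}",
                            depth_m=float(depth), total_bases=total_bases))

        weights = np.zeros(len(gids))
        for gi, g in enumerate(gids):
            curve = config.niche_curves.get(sub_of[g])
            if curve is not None:
                weights[gi] = curve(depth) / n_in_sub[sub_of[g]]
        p_unaligned = max(0.0, 1.0 - weights.sum())
        probs = np.append(weights, p_unaligned)
        probs = probs / probs.sum()
        counts = rng.multinomial(config.reads_per_sample, probs)[:-1]

        read_no = 0
        for gi, g in enumerate(gids):
            n = int(counts[gi])
            if n == 0:
                continue
            idents = np.clip(rng.normal(config.identity_mean, config.identity_sd, n), 0, 100)
            glen = max(int(size_of[g]), config.read_length + 1)
            starts = rng.integers(1, glen - config.read_length + 1, n)
            for j in range(n):
                read_no += 1
                aln_rows.append((sid, f"{sid}_r{read_no:07d}", g,
                                 round(float(idents[j]), 2), config.read_length,
                                 int(starts[j]), int(starts[j]) + config.read_length - 1))

        # gene catalog: genome-first, then family within genome
        if family_counts is not None and weights.sum() > 0:
            n_taxon = int(round(config.genes_per_sample * (1 - config.other_taxon_fraction)))
            gprobs = weights / weights.sum()
            per_genome = rng.multinomial(n_taxon, gprobs)
            gno = 0
            for gi, g in enumerate(gids):
                n = int(per_genome[gi])
                if n == 0 or g not in family_counts.index:
                    continue
                fams = family_counts.columns.to_numpy()
                cnts = family_counts.loc[g].to_numpy(dtype=float)
                if cnts.sum() == 0:
                    continue
                picks = rng.multinomial(n, cnts / cnts.sum())
                for fam, k in zip(fams, picks):
                    for _ in range(int(k)):
                        gno += 1
                        gene_rows.append((sid, f"{sid}_gene{gno:06d}", "SAR202", fam))
            for j in range(config.genes_per_sample - n_taxon):
                gno += 1
                gene_rows.append((sid, f"{sid}_gene{gno:06d}", "other", "FAM_OTHER"))

    samples_df = pd.DataFrame(samples)
    alignments = pd.DataFrame(
        aln_rows,
        columns=["sample_id", "read_id", "genome_id", "pct_identity",
                 "aligned_bases", "ref_start", "ref_end"],
    )
    gene_taxon = pd.DataFrame(gene_rows, columns=["sample_id", "gene_id", "taxon", "family_id"])
    return samples_df, alignments, gene_taxon


# ---------------------------------------------------------------------------
# FTICR-MS peak lists
# ---------------------------------------------------------------------------

@dataclass
class PeakListSimConfig:
    """Peak lists with depth-increasing single-oxygen transformation frequency.

    Each base formula seeds a CH2-free carbon ladder (peaks spaced by one
    carbon, 12 Da) providing C-difference pairs; a depth-dependent
    fraction of ladder peaks gains an oxidation partner at +15.994915 Da.
    Oxidation is planted deterministically — the first
    ``round(p(depth) * n_candidates)`` candidates of a seed-fixed
    ordering — so the truth O:C ratio is monotone whenever p(depth) is.
    """

    n_base_formulas: int = 60
    mz_range: tuple[float, float] = (200.0, 700.0)
    chain_length_max: int = 4
    noise_peaks: int = 50
    oxidation_prob_vs_depth: Callable[[float], float] = field(
        default_factory=lambda: (lambda d: min(0.8, 0.05 + 0.75 * d / 5000.0)))
    seed: int = 0

    def validate(self) -> None:
        if self.n_base_formulas <= 0:
            raise ConfigError("n_base_formulas must be > 0")
        if self.chain_length_max < 1:
            raise ConfigError("chain_length_max must be >= 1")
        if self.mz_range[0] <= 0 or self.mz_range[1] <= self.mz_range[0]:
            raise ConfigError("mz_range must be positive and increasing")


@dataclass
class PeakList:
    """One sample's peak list: sorted, deduplicated neutral monoisotopic masses."""

    sample_id: str
    depth: float
    station: str
    mz: np.ndarray

    def __post_init__(self):
        mz = np.sort(np.asarray(self.mz, dtype=float))
        if len(mz) and mz[0] <= 0:
            raise ValueError("m/z values must be strictly positive")
        if len(mz):
            keep = np.concatenate([[True], np.diff(mz) > 1e-6])
            mz = mz[keep]
        self.mz = mz


def generate_peaklists(config: PeakListSimConfig, depths: Sequence[float]):
    """Generate one :class:`PeakList` per depth plus a truth record."""
    config.validate()
    if depths is None or len(depths) == 0:
        raise ValueError("depths must be nonempty")
    for d in depths:
        p = config.oxidation_prob_vs_depth(d)
        if not (0 <= p <= 1):
            raise ConfigError(f"oxidation probability {p} at depth {d} outside [0, 1]")

    rng = _child_rng(config.seed, "peaks")
    lo, hi = config.mz_range
    # base masses on an irrational-offset grid so accidental 12/16 Da
    # coincidences between unrelated ladders are rare
    base = np.sort(rng.uniform(lo, hi - config.chain_length_max * CARBON_MASS - OXYGEN_MASS,
                               config.n_base_formulas))
    chain_lens = rng.integers(1, config.chain_length_max + 1, config.n_base_formulas)
    ladder_peaks, c_pairs = [], 0
    for m0, L in zip(base, chain_lens):
        for j in range(int(L)):
            ladder_peaks.append(m0 + j * CARBON_MASS)
        c_pairs += int(L) - 1
    ladder_peaks = np.array(ladder_peaks)
    ox_order = rng.permutation(len(ladder_peaks))  # fixed across samples

    peaklists, truth_samples = [], []
    for si, depth in enumerate(sorted(depths)):
        sid = f"S{si + 1:03d}"
        p = config.oxidation_prob_vs_depth(depth)
        n_ox = int(round(p * len(ladder_peaks)))
        ox_peaks = ladder_peaks[ox_order[:n_ox]] + OXYGEN_MASS
        noise = rng.uniform(lo, hi, config.noise_peaks)
        mz = np.concatenate([ladder_peaks, ox_peaks, noise])
        peaklists.append(PeakList(sample_id=sid, depth=float(depth),
                                  station=f"ST{si + 1:03d}", mz=mz))
        truth_samples.append(dict(sample_id=sid, depth=float(depth),
                                  planted_o_pairs=n_ox, planted_c_pairs=c_pairs))
    truth = {"samples": truth_samples, "seed": config.seed,
             "oxygen_mass": OXYGEN_MASS, "carbon_mass": CARBON_MASS}
    return peaklists, truth


# ---------------------------------------------------------------------------
# Sequence pairs for ANI tests
# ---------------------------------------------------------------------------

def generate_sequence_pair(length: int, divergence: float, seed: int = 0):
    """A random sequence and a copy with i.i.d. substitutions at rate ``divergence``.

    Returns ``(record_a, record_b, n_substitutions)`` as Biopython
    SeqRecords; every substitution changes the base (uniform over the
    other three), so divergence 1 gives Hamming distance == length.
    """
    if not (0 <= divergence <= 1):
        raise ValueError(f"divergence must be in [0, 1], got {divergence}")
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = _child_rng(seed, "seqpair")
    codes = rng.integers(0, 4, length).astype(np.uint8)
    mutate = rng.random(length) < divergence
    shift = rng.integers(1, 4, length).astype(np.uint8)
    codes_b = codes.copy()
    codes_b[mutate] = (codes[mutate] + shift[mutate]) % 4
    seq_a = _BASES[codes].tobytes().decode()
    seq_b = _BASES[codes_b].tobytes().decode()
    n_subs = int(mutate.sum())
    rec_a = SeqRecord(Seq(seq_a), id="seqA", description=f"synthetic length={length}")
    rec_b = SeqRecord(Seq(seq_b), id="seqB",
                      description=f"synthetic divergence={divergence} substitutions={n_subs}")
    return rec_a, rec_b, n_subs


# ---------------------------------------------------------------------------
# Depth-trend gene catalogs (for normalized-abundance correlation tests)
# ---------------------------------------------------------------------------

def simulate_linear_depth_trend(n_samples: int = 100,
                                depth_range: tuple[float, float] = (50.0, 4000.0),
                                intercept: float = 0.05, slope: float = 5e-5,
                                noise_sd: float = 0.028,
                                scg_per_sample: int = 2000, seed: int = 0):
    """Gene catalogs with a planted linear family-vs-depth abundance trend.

    Per sample the normalized family abundance (family genes / single-copy
    genes) is ``intercept + slope * depth + N(0, noise_sd)``, truncated at
    zero.  The truth record carries the population Pearson r implied by the
    generating model on the evenly spaced depth grid:
    r = slope * sd(depth) / sqrt(slope^2 var(depth) + noise_sd^2).
    """
    rng = _child_rng(seed, "depth_trend")
    depths = np.linspace(*depth_range, n_samples)
    values = intercept + slope * depths + rng.normal(0, noise_sd, n_samples)
    values = np.clip(values, 0, None)
    rows = []
    for i, (d, v) in enumerate(zip(depths, values)):
        sid = f"S{i + 1:03d}"
        fam_count = int(round(v * scg_per_sample))
        rows.append(dict(sample_id=sid, depth_m=float(d),
                         family_genes=fam_count, scg_genes=scg_per_sample))
    var_d = float(np.var(depths))
    r_pop = slope * math.sqrt(var_d) / math.sqrt(slope**2 * var_d + noise_sd**2)
    truth = {"population_r": r_pop, "intercept": intercept, "slope": slope,
             "noise_sd": noise_sd, "seed": seed}
    return pd.DataFrame(rows), truth


def counts_to_gene_table(counts: pd.DataFrame, taxon: str = "SAR202",
                         family: str = "FMNO", scg_family: str = "SCG0001") -> pd.DataFrame:
    """Expand per-sample (family_genes, scg_genes) counts into a long gene→taxon table."""
    rows = []
    for _, r in counts.iterrows():
        g = 0
        for _ in range(int(r["family_genes"])):
            g += 1
            rows.append((r["sample_id"], f"{r['sample_id']}_g{g:06d}", taxon, family))
        for _ in range(int(r["scg_genes"])):
            g += 1
            rows.append((r["sample_id"], f"{r['sample_id']}_g{g:06d}", taxon, scg_family))
    return pd.DataFrame(rows, columns=["sample_id", "gene_id", "taxon", "family_id"])


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_pangenome(outdir: str | Path, genomes: pd.DataFrame,
                    annotations: pd.DataFrame, truth: dict) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genomes.to_csv(outdir / "genomes.csv", index=False)
    annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))


def write_community(outdir: str | Path, samples: pd.DataFrame,
                    alignments: pd.DataFrame, gene_taxon: pd.DataFrame) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples.to_csv(outdir / "samples.csv", index=False)
    alignments.to_csv(outdir / "alignments.tsv", sep="\t", index=False)
    gene_taxon.to_csv(outdir / "gene_taxon.tsv", sep="\t", index=False)


def write_peaklists(outdir: str | Path, peaklists: list[PeakList], truth: dict) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pl in peaklists:
        pd.DataFrame({"mz": pl.mz}).to_csv(outdir / f"peaks_{pl.sample_id}.csv", index=False)
        rows.append(dict(sample_id=pl.sample_id, station=pl.station, depth_m=pl.depth,
                         total_bases=0))
    pd.DataFrame(rows).to_csv(outdir / "peak_samples.csv", index=False)
    (outdir / "peaks_truth.json").write_text(json.dumps(truth, indent=2))
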