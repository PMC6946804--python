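"""End-to-end pipeline: config validation, stage ordering, run report.

The pipeline consumes the file formats the simulator writes (and that
real inputs can be coerced into): ``genomes.csv``, ``annotations.tsv``,
``samples.csv``, ``alignments.tsv``, ``gene_taxon.tsv``, a peak-list
directory, and optionally a BED mask and bin FASTA directory.  Stages
run in dependency order — QC/dereplication, pangenome profiles,
fragment recruitment, enzyme depth trends — with the mass-difference
stage independent.  Every default parameter mirrors the analysis it
reimplements: 80% minimum identity, 0.99 ANI threshold, top 50
families, 1% minimum sample fraction, < 1.1% redundancy and < 5%
contamination.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from cnp import __version__
from cnp import derep as derep_mod
from cnp import enzyme_depth as ed
from cnp import msdiff as ms
from cnp import profiles as prof
from cnp import recruitment as rec

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Config validation failure; message lists every problem found."""


_INPUT_KEYS = {"genomes", "annotations", "samples", "alignments", "gene_taxon",
               "peaks_dir", "peak_samples", "mask", "bins_dir"}
_REQUIRED_INPUTS = {"genomes", "annotations", "samples", "alignments", "gene_taxon"}
_STAGE_KEYS = {"derep", "profiles", "recruitment", "enzyme_depth", "msdiff"}

_PARAM_RANGES = {
    "top_n": (1, 10_000),
    "min_identity": (0.0, 100.0),
    "ani_threshold": (1e-9, 1.0),
    "tol_ppm": (1e-9, 1e4),
    "min_sample_fraction": (0.0, 1.0),
    "max_redundancy": (0.0, 100.0),
    "max_contamination": (0.0, 100.0),
    "kmer_size": (1, 63),
}

_PARAM_DEFAULTS = dict(top_n=50, min_identity=80.0, ani_threshold=0.99, tol_ppm=1.0,
                       min_sample_fraction=0.01, max_redundancy=1.1,
                       max_contamination=5.0, kmer_size=21,
                       taxon="SAR202", family="FMNO", seed=0)


@dataclass
class PipelineConfig:
    inputs: dict[str, str]
    stages: dict[str, bool]
    params: dict


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML pipeline config, applying defaults.

    Unknown keys, out-of-range parameters and missing input files are all
    reported together in a single :class:`ValidationError`.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    problems: list[str] = []
    if not isinstance(raw, dict):
        raise ValidationError("config must be a mapping")
    unknown_top = set(raw) - {"inputs", "stages", "params"}
    for key in sorted(unknown_top):
        problems.append(f"unknown top-level key: {key!r}")

    inputs = dict(raw.get("inputs") or {})
    for key in sorted(set(inputs) - _INPUT_KEYS):
        problems.append(f"unknown input key: {key!r}")
    for key in sorted(_REQUIRED_INPUTS - set(inputs)):
        problems.append(f"missing required input: {key!r}")
    base = Path(path).parent
    resolved = {}
    for key, val in inputs.items():
        if key not in _INPUT_KEYS:
            continue
        p = Path(val)
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            problems.append(f"input {key!r}: path does not exist: {p}")
        resolved[key] = str(p)

    stages = {k: True for k in _STAGE_KEYS}
    for key, val in dict(raw.get("stages") or {}).items():
        if key not in _STAGE_KEYS:
            problems.append(f"unknown stage: {key!r}")
        else:
            stages[key] = bool(val)

    params = dict(_PARAM_DEFAULTS)
    for key, val in dict(raw.get("params") or {}).items():
        if key not in _PARAM_DEFAULTS:
            problems.append(f"unknown parameter: {key!r}")
            continue
        params[key] = val
        if key in _PARAM_RANGES:
            lo, hi = _PARAM_RANGES[key]
            try:
                ok = lo <= float(val) <= hi
            except (TypeError, ValueError):
                ok = False
            if not ok:
                problems.append(f"parameter {key!r} out of range [{lo}, {hi}]: {val!r}")

    if problems:
        raise ValidationError("invalid config:\n  - " + "\n  - ".join(problems))
    return PipelineConfig(inputs=resolved, stages=stages, params=params)


@dataclass
class StageReport:
    name: str
    status: str  # ok | failed | skipped
    inputs_rows: dict[str, int] = field(default_factory=dict)
    outputs_rows: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    error: str | None = None


@dataclass
class RunReport:
    version: str
    seed: int
    params: dict
    stages: list[StageReport]

    @property
    def ok(self) -> bool:
        return all(s.status in ("ok", "skipped") for s in self.stages)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


def _write(df: pd.DataFrame, path: Path, report: StageReport, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)
    report.outputs_rows[path.name] = len(df)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> RunReport:
    """Run all enabled stages, writing outputs and a JSON run report to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = config.params
    report = RunReport(version=__version__, seed=int(p.get("seed", 0)),
                       params=dict(p), stages=[])

    genomes = pd.read_csv(config.inputs["genomes"])
    annotations = pd.read_csv(config.inputs["annotations"], sep="\t")
    samples = pd.read_csv(config.inputs["samples"])

    def run_stage(name, fn):
        sr = StageReport(name=name, status="ok")
        if not config.stages.get(name, True):
            sr.status = "skipped"
            report.stages.append(sr)
            logger.info("stage %s: skipped", name)
            return
        try:
            fn(sr)
        except Exception as e:  # stage isolation: later stages still report
            sr.status = "failed"
            sr.error = f"{type(e).__name__}: {e}"
            logger.error("stage %s failed: %s", name, sr.error)
        report.stages.append(sr)

    retained_genomes = genomes

    def stage_derep(sr: StageReport):
        nonlocal retained_genomes
        sr.inputs_rows["genomes"] = len(genomes)
        keep = derep_mod.quality_filter(genomes, p["max_redundancy"], p["max_contamination"])
        retained_genomes = genomes[genomes["genome_id"].isin(keep)].reset_index(drop=True)
        (outdir / "qc_retained.txt").write_text("\n".join(keep) + "\n")
        sr.outputs_rows["qc_retained.txt"] = len(keep)
        if "bins_dir" in config.inputs:
            bins = {f.stem: derep_mod.load_bin_sequence(f)
                    for f in sorted(Path(config.inputs["bins_dir"]).glob("*.fasta"))}
            pairs = derep_mod.ani_matrix(bins, k=int(p["kmer_size"]))
            ani_df = pd.DataFrame([vars(q) for q in pairs])
            _write(ani_df, outdir / "ani_pairs.tsv", sr, index=False)
            decisions = derep_mod.dereplicate(genomes[genomes["genome_id"].isin(bins)],
                                              pairs, threshold=p["ani_threshold"])
            _write(derep_mod.decisions_table(decisions), outdir / "decisions.tsv",
                   sr, index=False)

    def stage_profiles(sr: StageReport):
        sr.inputs_rows["annotations"] = len(annotations)
        ann = annotations[annotations["genome_id"].isin(retained_genomes["genome_id"])]
        abundance = prof.compute_family_abundance(ann, retained_genomes)
        _write(abundance, outdir / "abundance.tsv", sr)
        top = prof.select_top_families(abundance, int(p["top_n"]))
        sub = abundance.loc[top]
        _write(prof.zscore_transform(sub), outdir / "zscores.tsv", sr)
        _write(prof.family_correlation(sub), outdir / "correlations.tsv", sr)
        counts = (ann.groupby(["genome_id", "family_id"]).size().unstack(fill_value=0))
        scores = prof.expansion_scores(sub, retained_genomes, counts=counts)
        _write(prof.expansion_table(scores), outdir / "expansions.tsv", sr, index=False)

    def stage_recruitment(sr: StageReport):
        aln = pd.read_csv(config.inputs["alignments"], sep="\t")
        sr.inputs_rows["alignments"] = len(aln)
        mask = (rec.MaskSet.from_bed(config.inputs["mask"])
                if "mask" in config.inputs else None)
        if "bit_score" not in aln.columns:
            aln = aln.assign(bit_score=0.0)
        kept = rec.filter_alignments(aln, min_identity=float(p["min_identity"]), mask=mask)
        frac, per_mbp = rec.compute_recruitment(kept, retained_genomes if
                                                set(kept["genome_id"]) <= set(retained_genomes["genome_id"])
                                                else genomes, samples)
        _write(frac, outdir / "recruitment.tsv", sr)
        _write(per_mbp, outdir / "recruitment_per_mbp.tsv", sr)

    def stage_enzyme_depth(sr: StageReport):
        gene_taxon = pd.read_csv(config.inputs["gene_taxon"], sep="\t")
        sr.inputs_rows["gene_taxon"] = len(gene_taxon)
        membership = (annotations.groupby(["genome_id", "family_id"]).size()
                      .rename("copy_count").reset_index()
                      .rename(columns={"family_id": "cluster_id"}))
        panel = prof.single_copy_panel(membership)
        (outdir / "single_copy_panel.txt").write_text("\n".join(panel) + "\n")
        sr.outputs_rows["single_copy_panel.txt"] = len(panel)
        table = ed.normalized_abundance_table(gene_taxon, samples, p["taxon"],
                                              p["family"], panel)
        _write(table, outdir / "normalized_abundance.tsv", sr, index=False)
        corr = ed.depth_correlation(table["value"], table["depth_m"], family=p["family"])
        _write(pd.DataFrame([vars(corr)]), outdir / "depth_correlations.tsv", sr, index=False)

    def stage_msdiff(sr: StageReport):
        if "peaks_dir" not in config.inputs:
            sr.status = "skipped"
            return
        meta = pd.read_csv(config.inputs.get("peak_samples", config.inputs["samples"]))
        peaks_dir = Path(config.inputs["peaks_dir"])
        profiles = []
        for _, r in meta.iterrows():
            f = peaks_dir / f"peaks_{r['sample_id']}.csv"
            if not f.exists():
                continue
            pl = ms.read_peaklist_csv(f, r["sample_id"], float(r["depth_m"]),
                                      str(r.get("station", "")))
            profiles.append(ms.transformation_profile(pl, tol_ppm=float(p["tol_ppm"])))
        sr.inputs_rows["peak_lists"] = len(profiles)
        counts_df = pd.DataFrame([dict(sample_id=t.sample_id, **t.counts,
                                       o_to_c_ratio=t.o_to_c_ratio) for t in profiles])
        _write(counts_df, outdir / "transformation_counts.tsv", sr, index=False)
        _write(ms.depth_profile(profiles, meta), outdir / "depth_profile.tsv", sr, index=False)

    run_stage("derep", stage_derep)
    run_stage("profiles", stage_profiles)
    run_stage("recruitment", stage_recruitment)
    run_stage("enzyme_depth", stage_enzyme_depth)
    run_stage("msdiff", stage_msdiff)

    (outdir / "report.json").write_text(report.to_json())
    return report
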