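"""Parameter-recovery experiments over the synthetic generators.

Each function plants a known effect with :mod:`cnp.simulate`, runs the
corresponding analysis stage, and reports how often (or how closely) the
planted parameter is recovered.  These are the package's end-to-end
checks that the statistics do what they claim on data whose ground truth
is known; the problem sizes default to the study conditions the
generators encode.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from cnp import derep as derep_mod
from cnp import enzyme_depth as ed
from cnp import msdiff as ms
from cnp import profiles as prof
from cnp import recruitment as rec
from cnp import simulate as sim


def expansion_recovery_rate(n_replicates: int = 50, n_subgroups: int = 5,
                            genomes_per_subgroup: int = 20, n_families: int = 300,
                            n_planted: int = 5, fold: float = 10.0,
                            seed: int = 0) -> float:
    """Fraction of replicates where the planted (family, subgroup) pairs are
    exactly the top-``n_planted`` expansion scores.

    Plants ``n_planted`` expansions at ``fold`` times the background copy
    mean, one per subgroup, at a fresh seed per replicate.
    """
    hits = 0
    for i in range(n_replicates):
        cfg = sim.PangenomeSimConfig(
            n_subgroups=n_subgroups, genomes_per_subgroup=genomes_per_subgroup,
            n_families=n_families, background_copy_mean=2.0,
            expansions=[(f"SG{j + 1:02d}", f"FAM{10 * (j + 1):04d}", 2.0 * fold)
                        for j in range(n_planted)],
            seed=seed * 1009 + i)
        genomes, ann, truth = sim.generate_pangenome(cfg)
        matrix = prof.compute_family_abundance(ann, genomes)
        table = prof.expansion_table(prof.expansion_scores(matrix, genomes))
        top = set(zip(table["family"].head(n_planted), table["subgroup"].head(n_planted)))
        planted = {(fam, sg) for sg, fam, _ in truth["expansions"]}
        hits += top == planted
    return hits / n_replicates


def depth_trend_recovery(n_seeds: int = 20, n_samples: int = 100,
                         seed: int = 0) -> tuple[float, float]:
    """(mean recovered Pearson r, generating-model population r) for the
    planted linear normalized-abundance-vs-depth trend."""
    rs, pop_r = [], None
    for i in range(n_seeds):
        counts, truth = sim.simulate_linear_depth_trend(
            n_samples=n_samples, seed=seed * 1013 + i)
        pop_r = truth["population_r"]
        values = counts["family_genes"] / counts["scg_genes"]
        rs.append(ed.depth_correlation(values, counts["depth_m"]).r)
    return float(np.mean(rs)), float(pop_r)


def null_pvalue_rate(n_replicates: int = 1000, n: int = 50, alpha: float = 0.05,
                     seed: int = 0) -> float:
    """Fraction of p < alpha under independent values and depths (should be ~alpha)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        values = rng.random(n)
        depths = rng.uniform(50, 5000, n)
        hits += ed.depth_correlation(values, depths).p_value < alpha
    return hits / n_replicates


def _recruitment_brute_force(records: pd.DataFrame, genomes: pd.DataFrame,
                             samples: pd.DataFrame) -> pd.DataFrame:
    """Dict-and-loop oracle for the recruitment fraction matrix."""
    acc: dict[tuple[str, str], float] = {}
    for _, r in records.iterrows():
        acc[(r["genome_id"], r["sample_id"])] = (
            acc.get((r["genome_id"], r["sample_id"]), 0) + r["aligned_bases"])
    totals = dict(zip(samples["sample_id"], samples["total_bases"]))
    out = pd.DataFrame(0.0, index=sorted(genomes["genome_id"]),
                       columns=list(samples["sample_id"]))
    for (g, s), bases in acc.items():
        out.loc[g, s] = bases / totals[s]
    return out


def recruitment_oracle_max_abs_diff(n_instances: int = 20, seed: int = 0) -> float:
    """Max |fast - brute force| recruitment fraction over random <=10-genome instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n_g, n_s = int(rng.integers(2, 11)), int(rng.integers(1, 5))
        genomes = pd.DataFrame([dict(genome_id=f"G{i}", size_bp=int(rng.integers(1, 5) * 1e6))
                                for i in range(n_g)])
        samples = pd.DataFrame([dict(sample_id=f"S{j}",
                                     total_bases=int(rng.integers(1, 10) * 10_000))
                                for j in range(n_s)])
        n_rec = int(rng.integers(1, 60))
        records = pd.DataFrame([
            dict(sample_id=f"S{rng.integers(n_s)}", read_id=f"r{i}",
                 genome_id=f"G{rng.integers(n_g)}", pct_identity=95.0,
                 aligned_bases=int(rng.integers(50, 150)), ref_start=0, ref_end=100)
            for i in range(n_rec)])
        fast, _ = rec.compute_recruitment(records, genomes, samples)
        slow = _recruitment_brute_force(records, genomes, samples)
        worst = max(worst, float((fast - slow).abs().to_numpy().max()))
    return worst


def niche_center_recovery_rate(n_replicates: int = 50, seed: int = 0) -> float:
    """Fraction of replicates where the depth of maximum recruitment of the
    focal subgroup falls within one grid step of the generating niche center."""
    grid = np.linspace(200, 2000, 10)
    step = float(grid[1] - grid[0])
    genomes = pd.DataFrame(
        [dict(genome_id=f"A{i}", subgroup="SGA", size_bp=2_000_000) for i in range(5)]
        + [dict(genome_id=f"B{i}", subgroup="SGB", size_bp=2_000_000) for i in range(5)])
    rng = np.random.default_rng(seed)
    hits = 0
    for i in range(n_replicates):
        center = float(rng.choice(grid[2:-2]))
        curves = {"SGA": sim.NicheCurve(center, 400, 0.3),
                  "SGB": sim.NicheCurve(3000, 1000, 0.2)}
        cfg = sim.CommunitySimConfig(depth_grid=list(grid), niche_curves=curves,
                                     reads_per_sample=5000, seed=seed * 1019 + i)
        samples, aln, _ = sim.generate_community(cfg, genomes)
        frac, _ = rec.compute_recruitment(aln, genomes, samples)
        focal = frac.loc[[g for g in frac.index if g.startswith("A")]].sum(axis=0)
        depth_of = samples.set_index("sample_id")["depth_m"]
        hits += abs(depth_of[focal.idxmax()] - center) <= step
    return hits / n_replicates


def _msdiff_all_pairs(mz: np.ndarray, delta: float, tol_ppm: float) -> int:
    """Brute-force all-pairs oracle via the full difference matrix."""
    mz = np.asarray(mz)
    diff = mz[None, :] - mz[:, None]
    tol = tol_ppm * 1e-6 * mz[None, :]  # tolerance relative to the heavier peak
    match = np.abs(diff - delta) <= tol
    return int(np.triu(match, 1).sum())


def msdiff_oracle_agreement(n_instances: int = 200, seed: int = 0) -> float:
    """Fraction of random instances (n <= 500) where the windowed counter
    equals the all-pairs oracle for both the O and C transformations."""
    rng = np.random.default_rng(seed)
    agree = 0
    for i in range(n_instances):
        n = int(rng.integers(10, 501))
        mz = rng.uniform(150, 900, n)
        n_salt = int(rng.integers(0, max(2, n // 5)))
        salt = rng.choice(mz, n_salt) + rng.choice(
            [ms.OXYGEN.delta_mass, ms.CARBON.delta_mass], n_salt)
        pl = sim.PeakList(f"i{i}", 0.0, "", np.concatenate([mz, salt]))
        ok = all(ms.count_mass_differences(pl, t, tol_ppm=5.0)
                 == _msdiff_all_pairs(pl.mz, t.delta_mass, 5.0)
                 for t in (ms.OXYGEN, ms.CARBON))
        agree += ok
    return agree / n_instances


def msdiff_monotone_rate(n_replicates: int = 50, seed: int = 0) -> float:
    """Fraction of replicates where a planted monotone oxidation probability
    yields a non-decreasing computed O:C ratio across sorted depths."""
    depths = [100, 500, 1000, 2000, 4000]
    hits = 0
    for i in range(n_replicates):
        cfg = sim.PeakListSimConfig(n_base_formulas=50, noise_peaks=30,
                                    seed=seed * 1021 + i)
        peaklists, _ = sim.generate_peaklists(cfg, depths)
        ratios = [ms.transformation_profile(pl, tol_ppm=1.0).o_to_c_ratio
                  for pl in peaklists]
        hits += all(b >= a for a, b in zip(ratios, ratios[1:]))
    return hits / n_replicates


def ani_recovery_rate(n_seeds: int = 50, length: int = 1_000_000,
                      divergence: float = 0.01, k: int = 21,
                      lo: float = 0.985, hi: float = 0.995, seed: int = 0) -> float:
    """Fraction of generated 1%-divergence pairs whose estimated ANI lands in
    [lo, hi] (the Mash relation predicts ~0.990 at k = 21)."""
    hits = 0
    for i in range(n_seeds):
        a, b, _ = sim.generate_sequence_pair(length, divergence, seed=seed * 1031 + i)
        pair = derep_mod.estimate_ani(str(a.seq), str(b.seq), k=k)
        hits += lo <= pair.ani <= hi
    return hits / n_seeds
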