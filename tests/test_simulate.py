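"""Generator contracts: determinism, conservation, and planted-truth fidelity."""

import numpy as np
import pandas as pd
import pytest

from cnp import simulate as sim
from cnp.simulate import ConfigError


class TestPangenome:
    def test_seeded_determinism(self):
        cfg = sim.PangenomeSimConfig(n_subgroups=2, genomes_per_subgroup=3,
                                     n_families=20, seed=7)
        out1 = sim.generate_pangenome(cfg)
        out2 = sim.generate_pangenome(cfg)
        pd.testing.assert_frame_equal(out1[0], out2[0])
        pd.testing.assert_frame_equal(out1[1], out2[1])
        assert out1[2] == out2[2]

    def test_zero_expansions_empty_truth(self):
        cfg = sim.PangenomeSimConfig(n_subgroups=2, genomes_per_subgroup=2,
                                     n_families=10, seed=1)
        *_, truth = sim.generate_pangenome(cfg)
        assert truth["expansions"] == []

    def test_planted_copy_mean_recovered(self):
        """Mean copy count of the planted family tracks the generating mean.

        With 20 genomes per subgroup a 100-copy planted mean should be
        recovered within +/-15% in the planted subgroup, while other
        subgroups stay at background.
        """
        cfg = sim.PangenomeSimConfig(
            n_subgroups=3, genomes_per_subgroup=20, n_families=30,
            background_copy_mean=2.0, expansions=[("SG02", "FAM0003", 100.0)], seed=42)
        genomes, ann, _ = sim.generate_pangenome(cfg)
        counts = ann.groupby(["genome_id", "family_id"]).size().unstack(fill_value=0)
        sub = genomes.set_index("genome_id")["subgroup"]
        in_mean = counts.loc[sub[counts.index] == "SG02", "FAM0003"].mean()
        out_mean = counts.loc[sub[counts.index] != "SG02", "FAM0003"].mean()
        assert 85 <= in_mean <= 115
        assert out_mean < 5

    def test_every_genome_has_metadata(self, small_pangenome):
        _, genomes, ann, _ = small_pangenome
        assert genomes["total_genes"].gt(0).all()
        assert genomes["subgroup"].notna().all()
        assert set(ann["genome_id"]) == set(genomes["genome_id"])
        per_genome = ann.groupby("genome_id").size()
        assert (per_genome == genomes.set_index("genome_id")["total_genes"]).all()

    @pytest.mark.parametrize("field,value", [
        ("n_subgroups", 0), ("genomes_per_subgroup", -1), ("n_families", 0)])
    def test_invalid_config_names_field(self, field, value):
        cfg = sim.PangenomeSimConfig(**{field: value})
        with pytest.raises(ConfigError, match=field):
            sim.generate_pangenome(cfg)

    def test_unknown_planted_family_rejected(self):
        cfg = sim.PangenomeSimConfig(n_families=5, expansions=[("SG01", "NOPE", 10.0)])
        with pytest.raises(ConfigError, match="NOPE"):
            sim.generate_pangenome(cfg)


class TestCommunity:
    def test_zero_niche_recruits_nothing(self, small_pangenome, family_counts):
        _, genomes, _, _ = small_pangenome
        curves = {"SG01": sim.NicheCurve(100, 200, 0.0),
                  "SG02": sim.NicheCurve(800, 400, 0.3)}
        cfg = sim.CommunitySimConfig(depth_grid=[100.0, 1000.0], niche_curves=curves,
                                     reads_per_sample=500, seed=3)
        _, aln, _ = sim.generate_community(cfg, genomes, family_counts)
        sg1 = set(genomes.loc[genomes["subgroup"] == "SG01", "genome_id"])
        assert not set(aln["genome_id"]) & sg1

    def test_aligned_bases_conservation(self, small_community):
        cfg, samples, alignments, _ = small_community
        per_sample = alignments.groupby("sample_id")["aligned_bases"].sum()
        totals = samples.set_index("sample_id")["total_bases"]
        assert (per_sample <= totals[per_sample.index]).all()
        assert (totals == cfg.reads_per_sample * cfg.read_length).all()

    def test_single_genome_full_recruitment(self):
        genomes = pd.DataFrame([dict(genome_id="G1", subgroup="SG01",
                                     depth_origin_m=100, total_genes=10,
                                     size_bp=50_000, station="ST1")])
        cfg = sim.CommunitySimConfig(depth_grid=[100.0],
                                     niche_curves={"SG01": sim.NicheCurve(100, 1e9, 1.0)},
                                     reads_per_sample=300, read_length=100, seed=5)
        samples, aln, _ = sim.generate_community(cfg, genomes)
        assert aln["aligned_bases"].sum() == 300 * 100

    def test_gaussian_niche_argmax_at_center(self, small_pangenome, family_counts):
        """Recruitment peaks at the grid depth nearest the niche center."""
        _, genomes, _, _ = small_pangenome
        grid = [100.0, 400.0, 800.0, 1600.0, 3200.0]
        cfg = sim.CommunitySimConfig(
            depth_grid=grid, niche_curves={"SG02": sim.NicheCurve(800, 300, 0.5)},
            reads_per_sample=4000, seed=8)
        samples, aln, _ = sim.generate_community(cfg, genomes, family_counts)
        depth_of = samples.set_index("sample_id")["depth_m"]
        by_sample = aln.groupby("sample_id")["aligned_bases"].sum()
        assert depth_of[by_sample.idxmax()] == 800.0

    def test_empty_genome_table_rejected(self):
        cfg = sim.CommunitySimConfig(depth_grid=[100.0])
        with pytest.raises(ValueError, match="nonempty"):
            sim.generate_community(cfg, pd.DataFrame())


class TestPeakLists:
    def test_zero_oxidation_probability(self):
        cfg = sim.PeakListSimConfig(n_base_formulas=20, noise_peaks=5,
                                    oxidation_prob_vs_depth=lambda d: 0.0, seed=1)
        _, truth = sim.generate_peaklists(cfg, [100, 1000])
        assert all(s["planted_o_pairs"] == 0 for s in truth["samples"])

    def test_single_base_single_oxidation(self):
        cfg = sim.PeakListSimConfig(n_base_formulas=1, chain_length_max=1,
                                    noise_peaks=0,
                                    oxidation_prob_vs_depth=lambda d: 1.0, seed=2)
        peaklists, truth = sim.generate_peaklists(cfg, [500])
        assert truth["samples"][0]["planted_o_pairs"] == 1
        assert len(peaklists[0].mz) == 2
        assert peaklists[0].mz[1] - peaklists[0].mz[0] == pytest.approx(
            sim.OXYGEN_MASS, abs=1e-9)

    def test_truth_ratio_monotone_with_depth(self):
        cfg = sim.PeakListSimConfig(n_base_formulas=40, seed=3)
        _, truth = sim.generate_peaklists(cfg, [100, 500, 1000, 2000, 4000])
        ratios = [s["planted_o_pairs"] / s["planted_c_pairs"] for s in truth["samples"]]
        assert all(b >= a for a, b in zip(ratios, ratios[1:]))

    def test_empty_depths_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            sim.generate_peaklists(sim.PeakListSimConfig(), [])

    def test_peaklist_dedup_and_sort(self):
        pl = sim.PeakList("s", 0.0, "st", mz=[300.0, 100.0, 100.0 + 1e-9, 200.0])
        assert list(pl.mz) == [100.0, 200.0, 300.0]


class TestSequencePair:
    def test_zero_divergence_identical(self):
        a, b, n = sim.generate_sequence_pair(500, 0.0, seed=1)
        assert str(a.seq) == str(b.seq) and n == 0

    def test_full_divergence_all_changed(self):
        a, b, n = sim.generate_sequence_pair(500, 1.0, seed=2)
        assert n == 500
        assert all(x != y for x, y in zip(str(a.seq), str(b.seq)))

    def test_realized_substitutions_binomial(self):
        """At divergence 0.01 over 1e6 bases, count within 3 sd of 1e4."""
        _, _, n = sim.generate_sequence_pair(1_000_000, 0.01, seed=3)
        sd = (1_000_000 * 0.01 * 0.99) ** 0.5
        assert abs(n - 10_000) <= 3 * sd

    def test_divergence_out_of_range(self):
        with pytest.raises(ValueError, match="divergence"):
            sim.generate_sequence_pair(100, 1.5, seed=0)


def test_linear_depth_trend_truth_r():
    counts, truth = sim.simulate_linear_depth_trend(n_samples=50, seed=9)
    assert 0 < truth["population_r"] <= 1
    assert len(counts) == 50
    assert (counts["scg_genes"] > 0).all()
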