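"""Family-abundance matrices, Z-scores, correlations, expansions, chiral model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cnp import profiles as prof
from cnp.profiles import InputError


def _tiny_tables():
    genomes = pd.DataFrame([
        dict(genome_id="G1", subgroup="A", total_genes=100),
        dict(genome_id="G2", subgroup="A", total_genes=200),
        dict(genome_id="G3", subgroup="B", total_genes=50),
    ])
    ann = pd.DataFrame(
        [("G1", f"G1_g{i}", "FX") for i in range(4)]
        + [("G2", f"G2_g{i}", "FX") for i in range(10)]
        + [("G2", f"G2_gy{i}", "FY") for i in range(2)]
        + [("G3", "G3_g1", "FY")],
        columns=["genome_id", "gene_id", "family_id"])
    return genomes, ann


class TestAbundance:
    def test_direct_ratio(self):
        genomes, ann = _tiny_tables()
        m = prof.compute_family_abundance(ann, genomes)
        assert m.loc["FX", "G1"] == pytest.approx(4.0)   # 4 of 100 genes
        assert m.loc["FX", "G2"] == pytest.approx(5.0)
        assert m.loc["FX", "G3"] == 0.0

    def test_max_copy_genome_hits_four_percent(self):
        """A genome carrying 114 copies of a monooxygenase-like family among
        2,850 genes sits at the 4% relative-abundance ceiling."""
        genomes = pd.DataFrame([dict(genome_id="G", subgroup="IIIa", total_genes=2850)])
        ann = pd.DataFrame([("G", f"g{i}", "FMNO") for i in range(114)],
                           columns=["genome_id", "gene_id", "family_id"])
        m = prof.compute_family_abundance(ann, genomes)
        assert m.loc["FMNO", "G"] == pytest.approx(4.0)

    def test_empty_annotations_all_zero(self):
        genomes, _ = _tiny_tables()
        empty = pd.DataFrame(columns=["genome_id", "gene_id", "family_id"])
        m = prof.compute_family_abundance(empty, genomes, families=["F1", "F2"])
        assert m.shape == (2, 3) and (m.to_numpy() == 0).all()

    def test_zero_total_genes_named(self):
        genomes, ann = _tiny_tables()
        genomes.loc[0, "total_genes"] = 0
        with pytest.raises(InputError, match="G1"):
            prof.compute_family_abundance(ann, genomes)

    def test_orphan_genome_rejected(self):
        genomes, ann = _tiny_tables()
        ann.loc[0, "genome_id"] = "GHOST"
        with pytest.raises(InputError, match="GHOST"):
            prof.compute_family_abundance(ann, genomes)

    def test_column_sums_100_on_full_universe(self, small_pangenome):
        _, genomes, ann, _ = small_pangenome
        m = prof.compute_family_abundance(ann, genomes)
        assert np.allclose(m.sum(axis=0), 100.0, atol=1e-9)


class TestTopFamilies:
    def test_returns_n_sorted_by_mean(self):
        m = pd.DataFrame(np.arange(12, dtype=float).reshape(4, 3),
                         index=["F1", "F2", "F3", "F4"], columns=["G1", "G2", "G3"])
        assert prof.select_top_families(m, 2) == ["F4", "F3"]

    def test_n_exceeding_families_returns_all(self):
        m = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["Fa", "Fb"],
                         columns=["G1", "G2"])
        assert prof.select_top_families(m, 10) == ["Fb", "Fa"]

    def test_tie_broken_lexicographically(self):
        m = pd.DataFrame([[2.0, 2.0], [2.0, 2.0], [1.0, 1.0]],
                         index=["FB", "FA", "FC"], columns=["G1", "G2"])
        assert prof.select_top_families(m, 2) == ["FA", "FB"]

    def test_empty_matrix_rejected(self):
        with pytest.raises(InputError):
            prof.select_top_families(pd.DataFrame(), 5)


class TestZScore:
    def test_hand_computed_example(self):
        # sample sd of (1, 2, 3) is exactly 1
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["F"], columns=list("abc"))
        z = prof.zscore_transform(m)
        assert list(z.loc["F"]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_row_maps_to_zero(self):
        m = pd.DataFrame([[5.0, 5.0, 5.0]], index=["F"], columns=list("abc"))
        assert (prof.zscore_transform(m).loc["F"] == 0).all()

    def test_single_genome_rejected(self):
        m = pd.DataFrame([[1.0]], index=["F"], columns=["G"])
        with pytest.raises(InputError):
            prof.zscore_transform(m)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=8),
           st.floats(0.1, 10), st.floats(-5, 5))
    def test_affine_invariance(self, row, a, b):
        """Z(a*x + b) == Z(x) for a > 0 (affine rescaling drops out)."""
        x = pd.DataFrame([row], index=["F"], columns=[f"g{i}" for i in range(len(row))])
        z1 = prof.zscore_transform(x)
        z2 = prof.zscore_transform(a * x + b)
        assert np.allclose(z1, z2, atol=1e-7)

    def test_row_means_zero(self, small_pangenome):
        _, genomes, ann, _ = small_pangenome
        m = prof.compute_family_abundance(ann, genomes)
        z = prof.zscore_transform(m)
        assert np.abs(z.mean(axis=1)).max() < 1e-9


def _pearson_two_pass(x, y):
    """Independent brute-force oracle: explicit two-pass covariance/variance."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    cov = ((x - mx) * (y - my)).sum()
    return cov / np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())


class TestCorrelation:
    def test_self_correlation_unity(self):
        m = pd.DataFrame(np.random.default_rng(0).random((3, 5)),
                         index=["F1", "F2", "F3"])
        c = prof.family_correlation(m)
        assert np.allclose(np.diag(c), 1.0)

    def test_negation_about_mean(self):
        x = np.array([1.0, 4.0, 2.0, 6.0])
        m = pd.DataFrame([x, 2 * x.mean() - x], index=["F", "Fneg"])
        c = prof.family_correlation(m)
        assert c.loc["F", "Fneg"] == pytest.approx(-1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.random((10, 10)), index=[f"F{i}" for i in range(10)])
        c = prof.family_correlation(m)
        for i in range(10):
            for j in range(10):
                expected = _pearson_two_pass(m.iloc[i], m.iloc[j])
                assert abs(c.iloc[i, j] - expected) < 1e-12
        assert np.allclose(c, c.T, atol=0)
        assert (c.to_numpy() <= 1 + 1e-12).all() and (c.to_numpy() >= -1 - 1e-12).all()

    def test_constant_family_missing_not_zero(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]], index=["F", "Fconst"])
        c = prof.family_correlation(m)
        assert c.loc["F", "Fconst"] != c.loc["F", "Fconst"]  # NaN
        assert c.loc["Fconst", "Fconst"] != c.loc["Fconst", "Fconst"]

    def test_independent_families_near_zero(self):
        """Monte-Carlo null: independent families over 200 genomes give |r| < 0.2
        in at least 95% of seeded replicates."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            m = pd.DataFrame(rng.random((2, 200)), index=["F1", "F2"])
            r = prof.family_correlation(m).loc["F1", "F2"]
            hits += abs(r) < 0.2
        assert hits >= 95

    def test_too_few_genomes_rejected(self):
        with pytest.raises(InputError):
            prof.family_correlation(pd.DataFrame([[1.0, 2.0]], index=["F"]))


class TestExpansionScores:
    def test_planted_family_ranks_first(self, small_pangenome, family_counts):
        _, genomes, ann, truth = small_pangenome
        m = prof.compute_family_abundance(ann, genomes)
        scores = prof.expansion_scores(m, genomes, counts=family_counts)
        table = prof.expansion_table(scores)
        top = table.iloc[0]
        sg, fam, _ = truth["expansions"][0]
        assert (top["family"], top["subgroup"]) == (fam, sg)
        assert top["max_copies"] >= 1

    def test_uniform_family_scores_near_one(self):
        genomes = pd.DataFrame([dict(genome_id=f"G{i}", subgroup="A" if i < 3 else "B",
                                     total_genes=100) for i in range(6)])
        m = pd.DataFrame([[2.0] * 6], index=["F"], columns=[f"G{i}" for i in range(6)])
        scores = prof.expansion_scores(m, genomes, pseudocount=0.01)
        assert all(s.score == pytest.approx(1.0) for s in scores)

    def test_absent_family_pseudocount_limit(self):
        genomes = pd.DataFrame([dict(genome_id=f"G{i}", subgroup="A" if i < 2 else "B",
                                     total_genes=100) for i in range(4)])
        m = pd.DataFrame([[0.0] * 4], index=["F"], columns=[f"G{i}" for i in range(4)])
        scores = prof.expansion_scores(m, genomes, pseudocount=0.01)
        assert all(s.score == pytest.approx(1.0) for s in scores)


class TestSingleCopyPanel:
    def test_universal_single_copy_included_others_excluded(self):
        rows = []
        for g in ["G1", "G2", "G3"]:
            rows.append((g, "C_single", 1))
            rows.append((g, "C_multi", 2 if g == "G2" else 1))
        rows += [("G1", "C_missing", 1), ("G2", "C_missing", 1)]  # absent in G3
        mem = pd.DataFrame(rows, columns=["genome_id", "cluster_id", "copy_count"])
        assert prof.single_copy_panel(mem) == ["C_single"]

    def test_planted_panel_recovered(self, small_pangenome):
        """The generator plants universal single-copy marker families; the
        panel extractor must return exactly those."""
        _, genomes, ann, truth = small_pangenome
        mem = (ann.groupby(["genome_id", "family_id"]).size().rename("copy_count")
               .reset_index().rename(columns={"family_id": "cluster_id"}))
        panel = prof.single_copy_panel(mem)
        planted = sorted(truth["single_copy_families"])
        # background families may be single-copy by chance only if copy==1 in
        # every genome; planted markers are guaranteed members
        assert set(planted) <= set(panel)
        non_scg = [c for c in panel if not c.startswith("SCG")]
        wide = mem.pivot_table(index="cluster_id", columns="genome_id",
                               values="copy_count", fill_value=0)
        for c in non_scg:
            assert (wide.loc[c] == 1).all()


class TestEnzymeRequirement:
    def test_three_centers_without_racemization(self):
        """Three chiral centers -> 2^3 = 8 stereoisomer-specific enzymes."""
        assert prof.enzyme_requirement(3, racemization_available=False) == 8

    def test_three_centers_with_racemization(self):
        """One degradative enzyme + three racemases = 4."""
        assert prof.enzyme_requirement(3, racemization_available=True) == 4

    def test_achiral_compound_needs_one(self):
        assert prof.enzyme_requirement(0, False) == 1
        assert prof.enzyme_requirement(0, True) == 1

    @pytest.mark.parametrize("n", range(0, 12))
    def test_racemization_never_costs_more(self, n):
        """2^n >= n + 1, equality only at n in {0, 1}."""
        without = prof.enzyme_requirement(n, False)
        with_r = prof.enzyme_requirement(n, True)
        assert without >= with_r
        assert (without == with_r) == (n in (0, 1))

    def test_negative_centers_rejected(self):
        with pytest.raises(InputError):
            prof.enzyme_requirement(-1, True)
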