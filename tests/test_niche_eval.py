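import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from shmseq import fixtures, niche_eval


class TestStandardize:
    def test_sample_sd_convention(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        out = niche_eval.standardize(df, axis=1)
        assert np.allclose(out.loc["g"], [-1.0, 0.0, 1.0])

    def test_constant_row_dropped(self):
        df = pd.DataFrame([[1, 2, 3], [5, 5, 5]], index=["g1", "g2"],
                          columns=list("abc"))
        out = niche_eval.standardize(df)
        assert list(out.index) == ["g1"]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(5, 10)))
        once = niche_eval.standardize(df)
        twice = niche_eval.standardize(once)
        assert np.allclose(once, twice)

    def test_all_constant_rejected(self):
        df = pd.DataFrame([[1, 1], [2, 2]])
        with pytest.raises(ValueError):
            niche_eval.standardize(df)


class TestCellSpotSimilarity:
    def test_identical_profiles_give_unit_correlation(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(50)]
        profile = rng.normal(size=50)
        cells = pd.DataFrame({"c0": profile}, index=genes)
        spots = pd.DataFrame({"s0": profile, "s1": -profile}, index=genes)
        sim = niche_eval.cell_spot_similarity(cells, spots)
        assert np.isclose(sim.loc["c0", "s0"], 1.0)
        assert np.isclose(sim.loc["c0", "s1"], -1.0)

    def test_independent_vectors_have_small_correlation(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(1000)]
        cells = pd.DataFrame(rng.normal(size=(1000, 3)), index=genes,
                             columns=["c0", "c1", "c2"])
        spots = pd.DataFrame(rng.normal(size=(1000, 3)), index=genes,
                             columns=["s0", "s1", "s2"])
        sim = niche_eval.cell_spot_similarity(cells, spots)
        assert (sim.abs() < 0.1).all().all()

    def test_too_few_common_genes_rejected(self):
        cells = pd.DataFrame([[1.0], [2.0]], index=["g1", "g2"],
                             columns=["c"])
        spots = pd.DataFrame([[1.0]], index=["g1"], columns=["s"])
        with pytest.raises(ValueError, match="common genes"):
            niche_eval.cell_spot_similarity(cells, spots)


class TestClusterModules:
    @staticmethod
    def _two_block_matrix(rng, n_per_block=10, n_spots=40):
        pattern_a = np.concatenate([np.ones(n_spots // 2),
                                    -np.ones(n_spots // 2)])
        pattern_b = -pattern_a
        rows, names = [], []
        for i in range(n_per_block):
            rows.append(pattern_a + 0.05 * rng.normal(size=n_spots))
            names.append(f"a{i}")
        for i in range(n_per_block):
            rows.append(pattern_b + 0.05 * rng.normal(size=n_spots))
            names.append(f"b{i}")
        return pd.DataFrame(rows, index=names)

    def test_planted_two_block_recovery(self):
        rng = np.random.default_rng(3)
        df = self._two_block_matrix(rng)
        labels = niche_eval.cluster_modules(df, n_modules=2)
        a_labels = set(labels[[f"a{i}" for i in range(10)]])
        b_labels = set(labels[[f"b{i}" for i in range(10)]])
        assert len(a_labels) == 1 and len(b_labels) == 1
        assert a_labels != b_labels

    def test_singleton_modules(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(6, 8)),
                          index=[f"g{i}" for i in range(6)])
        labels = niche_eval.cluster_modules(df, n_modules=6)
        assert labels.nunique() == 6

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(5)
        df = self._two_block_matrix(rng)
        shuffled = df.sample(frac=1.0, random_state=1)
        l1 = niche_eval.cluster_modules(df, n_modules=2)
        l2 = niche_eval.cluster_modules(shuffled, n_modules=2)
        # partition identity: same co-membership for every gene pair
        for g1, g2 in itertools.combinations(df.index[:8], 2):
            assert (l1[g1] == l1[g2]) == (l2[g1] == l2[g2])

    def test_too_many_modules_rejected(self):
        df = pd.DataFrame(np.eye(3))
        with pytest.raises(ValueError):
            niche_eval.cluster_modules(df, n_modules=5)


class TestScaleCelltypeMeans:
    def test_marker_gene_scales_to_one(self):
        profiles = pd.DataFrame(
            {"c1": [10.0, 1.0], "c2": [10.0, 1.0], "c3": [2.0, 4.0]},
            index=["marker", "other"])
        labels = pd.Series({"c1": "A", "c2": "A", "c3": "B"})
        out = niche_eval.scale_celltype_means(profiles, labels)
        assert out.loc["marker", "A"] == 1.0

    def test_uniform_gene_is_all_ones(self):
        profiles = pd.DataFrame(
            {"c1": [5.0], "c2": [5.0]}, index=["g"])
        labels = pd.Series({"c1": "A", "c2": "B"})
        out = niche_eval.scale_celltype_means(profiles, labels)
        assert (out.loc["g"] == 1.0).all()

    def test_scaling_arithmetic(self):
        profiles = pd.DataFrame(
            {"c1": [2.0], "c2": [4.0], "c3": [8.0]}, index=["g"])
        labels = pd.Series({"c1": "A", "c2": "B", "c3": "C"})
        out = niche_eval.scale_celltype_means(profiles, labels)
        assert np.allclose(out.loc["g"], [0.25, 0.5, 1.0])

    def test_low_expression_gene_removed(self):
        profiles = pd.DataFrame(
            {"c1": [0.1, 10.0], "c2": [0.2, 10.0]}, index=["low", "high"])
        labels = pd.Series({"c1": "A", "c2": "B"})
        out = niche_eval.scale_celltype_means(profiles, labels, min_mean=1.0)
        assert list(out.index) == ["high"]


class TestPartitionSubmodules:
    def test_two_disjoint_marker_groups(self):
        scaled = pd.DataFrame(
            [[1.0, 0.0, 0.0], [0.9, 0.1, 0.0],
             [0.0, 0.0, 1.0], [0.1, 0.0, 0.9]],
            index=["m1", "m2", "n1", "n2"], columns=["A", "B", "C"])
        labels = niche_eval.partition_submodules(scaled)
        assert labels["m1"] == labels["m2"]
        assert labels["n1"] == labels["n2"]
        assert labels["m1"] != labels["n1"]

    def test_identical_rows_form_one_submodule(self):
        scaled = pd.DataFrame([[1.0, 0.5]] * 4,
                              index=[f"g{i}" for i in range(4)])
        assert niche_eval.partition_submodules(scaled).nunique() == 1

    def test_cutoff_one_gives_single_submodule(self):
        rng = np.random.default_rng(6)
        scaled = pd.DataFrame(np.abs(rng.normal(size=(6, 4))) + 0.1,
                              index=[f"g{i}" for i in range(6)])
        labels = niche_eval.partition_submodules(scaled, cutoff_frac=1.0)
        assert labels.nunique() == 1

    def test_single_gene_module(self):
        scaled = pd.DataFrame([[1.0, 0.2]], index=["g"])
        labels = niche_eval.partition_submodules(scaled)
        assert labels.tolist() == [1]


class TestEnrichCelltypes:
    def test_planted_markers_minimize_fdr_at_their_type(self):
        sig, cells, labels = fixtures.make_celltype_signatures(
            n_celltypes=6, n_genes=60, n_markers_per_type=6, seed=0)
        scaled = niche_eval.scale_celltype_means(cells, labels)
        markers = [f"gene{i:04d}" for i in range(6)]  # type ct00 markers
        out = niche_eval.enrich_celltypes(markers, scaled)
        best = out.loc[out["fdr"].idxmin(), "cell_type"]
        assert best == "ct00"

    def test_small_submodule_reported_untested(self):
        scaled = pd.DataFrame(np.ones((10, 3)),
                              index=[f"g{i}" for i in range(10)],
                              columns=["A", "B", "C"])
        out = niche_eval.enrich_celltypes(["g0", "g1"], scaled)
        assert not out["tested"].any()

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(7)
        n_genes = 400
        scaled = pd.DataFrame(rng.random((n_genes, 4)),
                              index=[f"g{i}" for i in range(n_genes)],
                              columns=list("ABCD"))
        pvals = []
        for start in range(0, n_genes, 20):
            sub = [f"g{i}" for i in range(start, start + 20)]
            out = niche_eval.enrich_celltypes(sub, scaled)
            pvals.extend(out["p"].dropna())
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestEnrichGenesets:
    def test_perfect_overlap_closed_form(self):
        universe = [f"g{i}" for i in range(20)]
        sub = universe[:10]
        sets = {"hit": universe[:10]}
        out = niche_eval.enrich_genesets(sub, sets, universe)
        assert np.isclose(out.iloc[0]["p"], 1.0 / math.comb(20, 10))

    def test_disjoint_set_has_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        out = niche_eval.enrich_genesets(universe[:5], {"s": universe[10:15]},
                                         universe)
        assert out.iloc[0]["p"] == 1.0

    def test_matches_bruteforce_tail_enumeration(self):
        universe = [f"g{i}" for i in range(25)]
        sub = universe[:8]
        members = universe[4:14]
        out = niche_eval.enrich_genesets(sub, {"s": members}, universe)
        # brute force: enumerate hypergeometric tail P(X >= k)
        N, K, n = 25, 10, 8
        k = len(set(sub) & set(members))
        tail = sum(math.comb(K, x) * math.comb(N - K, n - x)
                   for x in range(k, min(K, n) + 1)) / math.comb(N, n)
        assert np.isclose(out.iloc[0]["p"], tail)

    def test_bh_correction_step_up(self):
        # BH on p = (0.01, 0.02, 0.03) with m = 3 gives q = 0.03 for all
        from statsmodels.stats.multitest import multipletests
        q = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert np.allclose(q, 0.03)

    def test_fdr_threshold_flag(self):
        universe = [f"g{i}" for i in range(40)]
        out = niche_eval.enrich_genesets(
            universe[:10], {"hit": universe[:10], "miss": universe[30:]},
            universe)
        flags = dict(zip(out["set"], out["significant"]))
        assert flags["hit"] and not flags["miss"]

    def test_gmt_roundtrip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("s1\tdesc\tg1\tg2\ns2\tdesc\tg3\n")
        sets = niche_eval.read_gmt(path)
        assert sets == {"s1": ["g1", "g2"], "s2": ["g3"]}


class TestTp10k:
    def test_arithmetic(self):
        counts = pd.DataFrame({"c": [1.0, 1.0, 2.0]}, index=list("abc"))
        out = niche_eval.tp10k_normalize(counts)
        assert np.allclose(out["c"], [2500, 2500, 5000])

    def test_idempotent_on_normalized_input(self):
        counts = pd.DataFrame({"c": [2500.0, 7500.0]})
        out = niche_eval.tp10k_normalize(counts)
        assert np.allclose(out["c"], [2500, 7500])

    def test_columns_sum_to_10k(self):
        rng = np.random.default_rng(8)
        counts = pd.DataFrame(rng.integers(0, 50, size=(30, 5)).astype(float))
        out = niche_eval.tp10k_normalize(counts)
        assert np.allclose(out.sum(axis=0), 1e4)


class TestSelectVariableGenes:
    def test_equal_frequency_bins(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.poisson(5, size=(40, 30)).astype(float) + 0.5,
                          index=[f"g{i}" for i in range(40)])
        genes = niche_eval.select_variable_genes(df, n_bins=20, n_top=40)
        assert len(genes) == 40  # 2 genes per bin, all selected

    def test_planted_high_dispersion_recovered(self):
        rng = np.random.default_rng(10)
        n_genes, n_cells = 200, 60
        base = rng.poisson(10, size=(n_genes, n_cells)).astype(float)
        noisy = [5, 50, 120, 180]
        for g in noisy:
            # same mean as background but strongly bimodal: inflated CV
            vals = np.zeros(n_cells)
            vals[: n_cells // 2] = 20.0
            base[g] = rng.permutation(vals)
        df = pd.DataFrame(base, index=[f"g{i}" for i in range(n_genes)])
        genes = niche_eval.select_variable_genes(df, n_bins=10, n_top=40)
        assert set(f"g{i}" for i in noisy) <= set(genes)

    def test_deterministic(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.poisson(5, size=(60, 20)).astype(float) + 0.5)
        df.index = [f"g{i}" for i in range(60)]
        assert (niche_eval.select_variable_genes(df, 10, 30)
                == niche_eval.select_variable_genes(df, 10, 30))

    def test_consensus_by_recovery_rate(self):
        lists = [["a", "b", "c"], ["a", "b", "d"], ["a", "e", "f"]]
        top = niche_eval.consensus_variable_genes(lists, n_top=2)
        assert top == ["a", "b"]

    def test_too_many_requested_rejected(self):
        df = pd.DataFrame(np.ones((5, 4)))
        with pytest.raises(ValueError):
            niche_eval.select_variable_genes(df, n_bins=2, n_top=10)


class TestFilterNuclei:
    def test_hand_tallied_toy(self):
        genes = [f"g{i}" for i in range(30)] + ["mt1"]
        rng = np.random.default_rng(12)
        counts = pd.DataFrame(
            rng.integers(1, 5, size=(31, 5)).astype(float),
            index=genes, columns=[f"c{i}" for i in range(5)])
        counts.loc["mt1"] = [1, 1, 1, 1, 200]  # c4: high mito fraction
        counts.loc[:, "c0"] = 0.0
        counts.loc["g0", "c0"] = 1.0  # c0 detects only 1 gene
        out = niche_eval.filter_nuclei(counts, ["mt1"], min_genes=10,
                                       min_cells_per_gene=2,
                                       max_flagged_frac=0.30)
        assert "c0" not in out.columns  # too few genes
        assert "c4" not in out.columns  # mito fraction >= 0.3
        assert {"c1", "c2", "c3"} == set(out.columns)

    def test_min_genes_is_strict(self):
        genes = [f"g{i}" for i in range(800)]
        counts = pd.DataFrame(np.ones((800, 2)), index=genes,
                              columns=["exactly800", "more"])
        counts.loc["g799", "exactly800"] = 0.0  # 799 genes... adjust below
        counts["more"] += 0.0
        extra = pd.DataFrame(np.zeros((1, 2)), index=["g800"],
                             columns=counts.columns)
        extra.loc["g800", "more"] = 1.0
        counts = pd.concat([counts, extra])
        # exactly800 detects 799, more detects 801
        out = niche_eval.filter_nuclei(counts, [], min_genes=800,
                                       min_cells_per_gene=1)
        assert list(out.columns) == ["more"]

    def test_gene_in_too_few_cells_removed(self):
        genes = [f"g{i}" for i in range(20)]
        counts = pd.DataFrame(np.ones((20, 12)), index=genes,
                              columns=[f"c{i}" for i in range(12)])
        counts.loc["g0"] = 0.0
        counts.loc["g0", [f"c{i}" for i in range(9)]] = 1.0  # 9 < 10 cells
        out = niche_eval.filter_nuclei(counts, [], min_genes=10,
                                       min_cells_per_gene=10)
        assert "g0" not in out.index


class TestBrayCurtis:
    def test_identical_vectors(self):
        assert niche_eval.bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_support(self):
        assert niche_eval.bray_curtis([1, 0], [0, 2]) == 1.0

    def test_worked_arithmetic(self):
        assert np.isclose(niche_eval.bray_curtis([6, 1, 0], [10, 0, 7]), 0.5)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            u = rng.random(5)
            v = rng.random(5)
            d = niche_eval.bray_curtis(u, v)
            assert 0.0 <= d <= 1.0
            assert np.isclose(d, niche_eval.bray_curtis(v, u))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            niche_eval.bray_curtis([-1, 2], [1, 2])


class TestClassificationReport:
    def test_perfect_predictions(self):
        out = niche_eval.classification_report(["A", "B"], ["A", "B"])
        assert out["accuracy"] == 1.0 and out["fpr"] == 0.0

    def test_known_confusion(self):
        out = niche_eval.classification_report(list("AABB"), list("ABBB"))
        assert out["accuracy"] == 0.75
        assert out["fpr"] == 0.25  # 1 misassigned / 4 classified

    def test_all_unclassified_convention(self):
        out = niche_eval.classification_report(["A", "B"], [None, None])
        assert out["accuracy"] == 0.0 and out["fpr"] == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            niche_eval.classification_report([], [])


class TestSpotwiseAgreement:
    @staticmethod
    def _reads(rng, n=5000, n_spots=100):
        genera = rng.choice(["gA", "gB", "gC"], size=n, p=[0.5, 0.3, 0.2])
        spots = rng.choice([f"s{i}" for i in range(n_spots)], size=n)
        return list(genera), list(spots)

    def test_perfect_predictions(self):
        rng = np.random.default_rng(14)
        truth, spots = self._reads(rng)
        r = niche_eval.spotwise_abundance_agreement(truth, truth, spots,
                                                    group_size=20)
        assert np.isclose(r, 1.0)
        bc = niche_eval.spotwise_abundance_agreement(
            truth, truth, spots, group_size=20, metric="bray_curtis")
        assert np.isclose(bc, 0.0)

    def test_shuffled_predictions_near_zero(self):
        rng = np.random.default_rng(15)
        truth, spots = self._reads(rng, n=20000)
        pred = list(rng.choice(["gA", "gB", "gC"], size=len(truth)))
        r = niche_eval.spotwise_abundance_agreement(truth, pred, spots,
                                                    group_size=10)
        assert abs(r) < 0.9  # uncorrelated composition, far from perfect

    def test_deterministic_partition(self):
        rng = np.random.default_rng(16)
        truth, spots = self._reads(rng)
        a = niche_eval.spotwise_abundance_agreement(truth, truth, spots,
                                                    group_size=30, seed=5)
        b = niche_eval.spotwise_abundance_agreement(truth, truth, spots,
                                                    group_size=30, seed=5)
        assert a == b


class TestRegionResampling:
    @staticmethod
    def _signals(rng, dependent):
        rows_a, rows_b = [], []
        for sample in ("m1", "m2"):
            for region in ("R1", "R2", "R3", "R4", "R5"):
                base = rng.random()
                for _ in range(6):
                    va = base + 0.01 * rng.random()
                    vb = (2 * va + 1 if dependent else rng.random())
                    rows_a.append((sample, region, va))
                    rows_b.append((sample, region, vb))
        cols = ["sample", "region", "value"]
        return (pd.DataFrame(rows_a, columns=cols),
                pd.DataFrame(rows_b, columns=cols))

    def test_monotone_transform_gives_unit_rho(self):
        rng = np.random.default_rng(17)
        a, b = self._signals(rng, dependent=True)
        rho = niche_eval.region_resampling_correlation(a, b, n_reps=50, seed=0)
        assert rho > 0.95

    def test_independent_signals_near_zero(self):
        rng = np.random.default_rng(18)
        a, b = self._signals(rng, dependent=False)
        rho = niche_eval.region_resampling_correlation(a, b, n_reps=100,
                                                       seed=0)
        assert abs(rho) < 0.5

    def test_same_seed_identical(self):
        rng = np.random.default_rng(19)
        a, b = self._signals(rng, dependent=True)
        r1 = niche_eval.region_resampling_correlation(a, b, n_reps=20, seed=3)
        r2 = niche_eval.region_resampling_correlation(a, b, n_reps=20, seed=3)
        assert r1 == r2

    def test_unshared_region_excluded(self):
        cols = ["sample", "region", "value"]
        a = pd.DataFrame([("m", "R1", 1.0), ("m", "R2", 2.0),
                          ("m", "R3", 3.0)], columns=cols)
        b = pd.DataFrame([("m", "R1", 1.0), ("m", "R2", 2.0),
                          ("m", "R3", 3.0), ("m", "RX", 9.0)], columns=cols)
        rho = niche_eval.region_resampling_correlation(a, b, n_reps=5, seed=0)
        assert np.isclose(rho, 1.0)
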