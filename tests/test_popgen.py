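import numpy as np
import pandas as pd
import pytest

from dendrogwas import popgen, synth
from dendrogwas.core import GenotypeMatrix

from conftest import make_genotypes


# ---------------------------------------------------------------------------
# independent textbook oracle for Weir-Cockerham theta (two populations),
# written as plain per-locus loops straight from the published formulas


def wc_theta_oracle(calls1, calls2):
    num = den = 0.0
    r = 2
    for l in range(calls1.shape[1]):
        stats = []
        for calls in (calls1[:, l], calls2[:, l]):
            obs = calls[calls >= 0]
            n_i = len(obs)
            if n_i < 2:
                break
            p_i = obs.sum() / (2 * n_i)
            h_i = np.mean(obs == 1)
            stats.append((n_i, p_i, h_i))
        if len(stats) < 2:
            continue
        (n1, p1, h1), (n2, p2, h2) = stats
        nbar = (n1 + n2) / 2
        nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 / r - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


class TestFilterLoci:
    def test_all_heterozygous_locus_dropped(self):
        calls = np.ones((10, 2), dtype=np.int8)  # locus 0 all het
        calls[:, 1] = [0, 0, 0, 0, 0, 1, 1, 2, 2, 2]
        g = make_genotypes(calls)
        out, report = popgen.filter_loci(g)
        assert report.snps_dropped_het == 1
        assert out.n_snps == 1

    def test_maf_boundary_is_inclusive(self):
        """alt count 1 among 10 trees = MAF 0.05 retained; count 0 dropped."""
        calls = np.zeros((10, 2), dtype=np.int8)
        calls[0, 0] = 1  # MAF exactly 0.05
        g = make_genotypes(calls)
        out, report = popgen.filter_loci(g)
        assert out.n_snps == 1
        assert out.snp_ids[0] == g.snp_ids[0]
        assert report.snps_dropped_maf == 1

    def test_per_population_call_rate_matches_brute_force(self):
        """SNP missing in 2 trees of a 5-tree population (rate 0.6) dropped;
        the full survivor set matches an exhaustive re-application of the
        rules."""
        rng = np.random.default_rng(6)
        calls = rng.binomial(2, 0.5, (10, 10)).astype(np.int8)
        calls[0, 0] = -1
        calls[1, 0] = -1  # pop A call rate 3/5 = 0.6 at SNP 0
        pops = ["A"] * 5 + ["B"] * 5
        g = make_genotypes(calls, pops=pops)
        out, report = popgen.filter_loci(g)
        assert g.snp_ids[0] not in out.snp_ids
        # brute-force enumeration of the surviving loci
        survivors = []
        for j in range(10):
            col = calls[:, j]
            rate_a = (col[:5] >= 0).mean()
            rate_b = (col[5:] >= 0).mean()
            if rate_a < 0.8 or rate_b < 0.8:
                continue
            obs = col[col >= 0]
            if (obs == 1).mean() > 0.7:
                continue
            p = obs.sum() / (2 * len(obs))
            if min(p, 1 - p) < 0.05:
                continue
            survivors.append(g.snp_ids[j])
        assert out.snp_ids == survivors

    def test_low_callrate_tree_dropped(self):
        calls = np.zeros((4, 10), dtype=np.int8)
        calls[:, :] = 1
        calls[0, :8] = -1  # tree 0 call rate 0.2
        g = make_genotypes(calls)
        out, report = popgen.filter_loci(g, min_maf=0.0, max_obs_het=1.0)
        assert report.trees_dropped == ["t0"]
        assert out.n_trees == 3

    def test_idempotent(self, small_sim):
        g, _ = small_sim
        once, _ = popgen.filter_loci(g)
        twice, rep2 = popgen.filter_loci(once)
        assert np.array_equal(once.calls, twice.calls)
        assert rep2.snps_dropped_total == 0

    def test_all_removed_is_error(self):
        calls = np.ones((6, 2), dtype=np.int8)  # all loci fully heterozygous
        with pytest.raises(ValueError):
            popgen.filter_loci(make_genotypes(calls))


class TestImputation:
    def test_duplicate_column_recovers_masked_call(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 3, size=(30, 1), dtype=np.int8)
        calls = np.hstack([base, base, rng.integers(0, 3, (30, 8), dtype=np.int8)])
        calls[0, 0] = -1  # mask one call of the duplicated pair
        g = make_genotypes(calls)
        # l=1: the metric reduces to the perfect-LD duplicate column
        out = popgen.impute_ld_knn(g, k=3, l=1)
        assert out.calls[0, 0] == calls[0, 1]

    def test_no_missing_returned_unchanged(self, small_sim):
        g, _ = small_sim
        g2 = g.copy()
        g2.calls[g2.calls == -1] = 0
        out = popgen.impute_ld_knn(g2)
        assert np.array_equal(out.calls, g2.calls)

    def test_nonmissing_calls_untouched_and_complete(self, small_sim):
        g, _ = small_sim
        out = popgen.impute_ld_knn(g)
        assert not (out.calls == -1).any()
        obs = g.calls != -1
        assert np.array_equal(out.calls[obs], g.calls[obs])

    def test_beats_major_genotype_fill_on_ld_structure(self):
        """Masking experiment on LD-structured data (duplicated blocks)."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            base = rng.binomial(2, rng.uniform(0.2, 0.8, 40), (60, 40)).astype(np.int8)
            calls = np.hstack([base, base])  # strong LD structure
            mask = rng.random(calls.shape) < 0.05
            masked = calls.copy()
            masked[mask] = -1
            g = make_genotypes(masked)
            out = popgen.impute_ld_knn(g, k=5, l=10)
            acc_knn = (out.calls[mask] == calls[mask]).mean()
            # major-genotype fill baseline
            fill = masked.copy()
            for j in range(fill.shape[1]):
                col = fill[:, j]
                obs = col[col >= 0]
                vals, cnt = np.unique(obs, return_counts=True)
                col[col == -1] = vals[np.argmax(cnt)]
            acc_major = (fill[mask] == calls[mask]).mean()
            wins += acc_knn > acc_major
        assert wins >= 9


class TestDiversity:
    def test_hand_computed_single_snp(self):
        """[0,1,2,1]: Ho = 0.5, unbiased He = 2*0.25*(8/7), FIS = 0.125."""
        calls = np.array([[0], [1], [2], [1]], dtype=np.int8)
        d = popgen.diversity(make_genotypes(calls))[0]
        assert d.ho == pytest.approx(0.5)
        assert d.he == pytest.approx(2 * 0.25 * 8 / 7)
        assert d.fis == pytest.approx(1 - 0.5 / (2 * 0.25 * 8 / 7))
        assert d.fis == pytest.approx(0.125)

    def test_fixed_site_excluded_from_fis(self):
        calls = np.zeros((6, 1), dtype=np.int8)
        d = popgen.diversity(make_genotypes(calls))[0]
        assert d.ho == 0.0
        assert d.he == 0.0
        assert np.isnan(d.fis)

    def test_pi_per_bp_is_sum_over_length(self):
        calls = np.array([[0, 1], [1, 1], [2, 0], [1, 2]], dtype=np.int8)
        d = popgen.diversity(make_genotypes(calls), total_length_bp=1000)[0]
        ho, he, _ = popgen._pop_site_stats(calls)
        assert d.pi_per_bp == pytest.approx(np.nansum(he) / 1000)

    def test_singleton_population_rejected(self):
        calls = np.zeros((3, 2), dtype=np.int8)
        g = make_genotypes(calls, pops=["A", "A", "B"])
        with pytest.raises(ValueError):
            popgen.diversity(g)


class TestIndividualHeterozygosity:
    def test_counts_het_over_called(self):
        calls = np.array([[0, 1, 2, 1, -1]], dtype=np.int8)
        het = popgen.individual_heterozygosity(make_genotypes(calls))
        assert het.iloc[0] == pytest.approx(0.5)

    def test_all_homozygous_zero(self):
        calls = np.array([[0, 2, 0, 2]], dtype=np.int8)
        het = popgen.individual_heterozygosity(make_genotypes(calls))
        assert het.iloc[0] == 0.0

    def test_matches_hardy_weinberg_expectation(self):
        """Panmictic simulation: mean individual het ~ mean 2p(1-p)."""
        cfg = synth.SimConfig(n_pops=1, n_trees_per_pop=[300], n_snps=2000,
                              target_fst=0.0, missing_rate=0.0, seed=9)
        g, truth = synth.simulate_genotypes(cfg)
        p = truth.pop_freqs[0]
        expected = np.mean(2 * p * (1 - p))
        observed = popgen.individual_heterozygosity(g).mean()
        assert observed == pytest.approx(expected, abs=0.01)

    def test_zero_call_tree_rejected(self):
        calls = np.array([[-1, -1], [0, 1]], dtype=np.int8)
        with pytest.raises(ValueError):
            popgen.individual_heterozygosity(make_genotypes(calls))


class TestWcFst:
    def test_identical_balanced_pops_near_zero(self):
        # large balanced samples so the finite-sample correction is small
        block = np.array([[0], [1], [1], [2]] * 25, dtype=np.int8)
        calls = np.vstack([block, block])
        g = make_genotypes(np.tile(calls, (1, 20)), pops=["A"] * 100 + ["B"] * 100)
        theta = popgen.wc_fst(g, "A", "B")
        assert abs(theta) < 0.01

    def test_fixed_difference_is_one(self):
        calls = np.array([[0] * 30] * 8 + [[2] * 30] * 8, dtype=np.int8)
        g = make_genotypes(calls, pops=["A"] * 8 + ["B"] * 8)
        assert popgen.wc_fst(g, "A", "B") == pytest.approx(1.0)

    def test_matches_textbook_oracle_exactly(self):
        rng = np.random.default_rng(13)
        calls = rng.integers(0, 3, size=(20, 50)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.05] = -1
        pops = ["A"] * 10 + ["B"] * 10
        g = make_genotypes(calls, pops=pops)
        ours = popgen.wc_fst(g, "A", "B")
        oracle = wc_theta_oracle(calls[:10], calls[10:])
        assert ours == pytest.approx(oracle, abs=1e-12)

    def test_bootstrap_ci_brackets_estimate(self, small_sim):
        g, _ = small_sim
        res = popgen.pairwise_fst(g, n_boot=200, seed=1)
        for i, a in enumerate(res.populations):
            for b in res.populations[i + 1:]:
                assert res.ci_low.loc[a, b] <= res.fst.loc[a, b] <= res.ci_high.loc[a, b]

    def test_small_population_rejected(self):
        calls = np.zeros((3, 5), dtype=np.int8)
        g = make_genotypes(calls, pops=["A", "A", "B"])
        with pytest.raises(ValueError):
            popgen.pairwise_fst(g, n_boot=0)


class TestNeiDistance:
    def test_identical_frequencies_zero(self):
        block = np.array([[0], [1], [2], [1]], dtype=np.int8)
        calls = np.tile(np.vstack([block, block]), (1, 10))
        g = make_genotypes(calls, pops=["A"] * 4 + ["B"] * 4)
        D = popgen.nei_distance(g)
        assert D.loc["A", "B"] == pytest.approx(0.0, abs=1e-12)

    def test_fixed_alternative_alleles_infinite(self):
        calls = np.array([[0] * 5] * 4 + [[2] * 5] * 4, dtype=np.int8)
        g = make_genotypes(calls, pops=["A"] * 4 + ["B"] * 4)
        assert np.isinf(popgen.nei_distance(g).loc["A", "B"])

    def test_single_locus_hand_oracle(self):
        """p1 = 0.5, p2 = 0.6 -> D = -ln(J12 / sqrt(J1 J2))."""
        # pop A: 4 trees, alt count sum 4 of 8 -> p = 0.5
        a = np.array([[0], [1], [1], [2]], dtype=np.int8)
        # pop B: 5 trees, alt sum 6 of 10 -> p = 0.6
        b = np.array([[1], [1], [1], [1], [2]], dtype=np.int8)
        g = make_genotypes(np.vstack([a, b]), pops=["A"] * 4 + ["B"] * 5)
        j12 = 0.5 * 0.6 + 0.5 * 0.4
        j1 = 0.5**2 + 0.5**2
        j2 = 0.6**2 + 0.4**2
        expected = -np.log(j12 / np.sqrt(j1 * j2))
        assert popgen.nei_distance(g).loc["A", "B"] == pytest.approx(expected)


class TestAmova:
    def test_worked_example_f_indices(self):
        """Variance components 115.2/47.9/9405.6 reproduce the published
        F-indices and the 98.3% within-population share."""
        f = popgen.amova_f_indices(115.2, 47.9, 9405.6)
        assert round(f["FST"], 3) == 0.017
        assert round(f["FSC"], 3) == 0.005
        assert round(f["FCT"], 3) == 0.012
        assert round(f["pct_within"], 1) == 98.3

    def test_f_index_identity(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            sa, sb, sc = rng.uniform(0, 10, 3)
            f = popgen.amova_f_indices(sa, sb, sc)
            assert (1 - f["FCT"]) * (1 - f["FSC"]) == pytest.approx(
                1 - f["FST"], abs=1e-9
            )

    def test_identical_individuals_zero_components(self):
        calls = np.ones((12, 10), dtype=np.int8) * 2
        g = make_genotypes(calls, pops=["A"] * 4 + ["B"] * 4 + ["C"] * 4,
                           groups=["G1"] * 8 + ["G2"] * 4)
        res = popgen.amova(g, n_perm=0)
        assert res.sigma_a == pytest.approx(0.0, abs=1e-12)
        assert res.sigma_b == pytest.approx(0.0, abs=1e-12)
        assert res.sigma_c == pytest.approx(0.0, abs=1e-12)
        assert res.fst == 0.0

    def test_panmictic_null_small_fst_and_calibrated_p(self):
        ps, fsts = [], []
        for seed in range(5):
            cfg = synth.SimConfig(n_pops=4, n_trees_per_pop=[15] * 4, n_snps=400,
                                  target_fst=0.0, missing_rate=0.0, seed=100 + seed)
            g, _ = synth.simulate_genotypes(cfg)
            res = popgen.amova(g, n_perm=99, seed=seed)
            fsts.append(res.fst)
            ps.append(res.p_fst)
        assert all(abs(f) < 0.01 for f in fsts)
        assert sum(p > 0.05 for p in ps) >= 3

    def test_structured_simulation_recovers_hierarchy(self):
        cfg = synth.SimConfig(n_pops=4, n_trees_per_pop=[20] * 4, n_snps=1000,
                              target_fst=0.05, missing_rate=0.0, seed=21)
        g, _ = synth.simulate_genotypes(cfg)
        res = popgen.amova(g, n_perm=99, seed=0)
        # dosage-coded AMOVA FST sits on the 2F/(1+F) scale, ~0.095 at F=0.05
        assert 0.06 < res.fst < 0.13
        assert res.p_fst < 0.05
        assert (1 - res.fct) * (1 - res.fsc) == pytest.approx(1 - res.fst, abs=1e-9)

    def test_singleton_population_rejected(self):
        calls = np.zeros((5, 4), dtype=np.int8)
        g = make_genotypes(calls, pops=["A", "A", "B", "B", "C"])
        with pytest.raises(ValueError):
            popgen.amova(g, n_perm=0)


class TestPcaFreq:
    def test_separates_differentiated_pops(self):
        cfg = synth.SimConfig(n_pops=2, n_trees_per_pop=[30, 30], n_snps=800,
                              target_fst=0.15, missing_rate=0.0, seed=8)
        g, _ = synth.simulate_genotypes(cfg)
        scores, _ = popgen.pca_freq(g)
        a = scores.iloc[:30, 0]
        b = scores.iloc[30:, 0]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or \
            max(b.min(), a.min()) > min(b.max(), a.max()) or \
            (a.max() < b.min()) or (b.max() < a.min())

    def test_explained_variance_fractions(self, small_sim):
        g, _ = small_sim
        _, explained = popgen.pca_freq(g)
        assert np.all(explained >= 0)
        assert explained.sum() <= 1.0 + 1e-9

    def test_duplicate_trees_identical_scores(self):
        rng = np.random.default_rng(3)
        row = rng.integers(0, 3, 50).astype(np.int8)
        calls = np.vstack([row, row, rng.integers(0, 3, (8, 50)).astype(np.int8)])
        g = make_genotypes(calls)
        scores, _ = popgen.pca_freq(g)
        assert np.allclose(scores.iloc[0], scores.iloc[1], atol=1e-9)


def _dist(labels, vals):
    return pd.DataFrame(vals, index=labels, columns=labels)


class TestMantel:
    def test_affine_invariance_r_one(self):
        rng = np.random.default_rng(4)
        n = 6
        M = rng.uniform(1, 10, (n, n))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        labels = list("ABCDEF")
        r, _ = popgen.mantel(_dist(labels, M), _dist(labels, 2 * M), n_perm=99)
        assert r == pytest.approx(1.0)

    def test_anti_ordered_negative(self):
        labels = list("ABCD")
        d1 = np.abs(np.subtract.outer(np.arange(4), np.arange(4))).astype(float)
        d2 = d1.max() + 1 - d1
        np.fill_diagonal(d2, 0)
        r, _ = popgen.mantel(_dist(labels, d1), _dist(labels, d2), n_perm=99)
        assert r < 0

    def test_p_uniform_under_null(self):
        """Independent random matrices across seeds: p ~ Uniform(0,1)."""
        from scipy import stats as sps

        ps = []
        for seed in range(300):
            rng = np.random.default_rng(seed)
            n = 7
            mats = []
            for _ in range(2):
                M = rng.uniform(0, 1, (n, n))
                M = (M + M.T) / 2
                np.fill_diagonal(M, 0)
                mats.append(_dist(list("ABCDEFG"), M))
            _, p = popgen.mantel(mats[0], mats[1], n_perm=199, seed=seed)
            ps.append(p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_matches_skbio_r(self):
        from skbio.stats.distance import DistanceMatrix, mantel as sk_mantel

        rng = np.random.default_rng(5)
        n = 8
        mats = []
        for _ in range(2):
            M = rng.uniform(0, 1, (n, n))
            M = (M + M.T) / 2
            np.fill_diagonal(M, 0)
            mats.append(M)
        labels = [f"s{i}" for i in range(n)]
        r_ours, _ = popgen.mantel(_dist(labels, mats[0]), _dist(labels, mats[1]),
                                  n_perm=0)
        r_sk, _, _ = sk_mantel(DistanceMatrix(mats[0], labels),
                               DistanceMatrix(mats[1], labels), permutations=0)
        assert r_ours == pytest.approx(float(r_sk), abs=1e-10)

    def test_too_small_rejected(self):
        labels = ["A", "B"]
        M = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            popgen.mantel(_dist(labels, M), _dist(labels, M))


class TestGeography:
    def test_identical_coordinates_zero(self):
        pm = pd.DataFrame({"tree_id": ["a", "b"], "population": ["A", "B"],
                           "latitude": [52.0, 52.0], "longitude": [90.0, 90.0]})
        D = popgen.geographic_distance(pm)
        assert D.loc["A", "B"] == 0.0

    def test_one_degree_latitude(self):
        pm = pd.DataFrame({"tree_id": ["a", "b"], "population": ["A", "B"],
                           "latitude": [52.0, 53.0], "longitude": [90.0, 90.0]})
        D = popgen.geographic_distance(pm)
        assert D.loc["A", "B"] == pytest.approx(111.2, abs=0.5)

    def test_symmetry_and_missing_rejected(self):
        pm = pd.DataFrame({"tree_id": list("abc"), "population": list("ABC"),
                           "latitude": [52.0, 53.0, 51.5],
                           "longitude": [90.0, 91.0, 89.0]})
        D = popgen.geographic_distance(pm)
        assert np.allclose(D.to_numpy(), D.to_numpy().T)
        pm.loc[0, "latitude"] = np.nan
        with pytest.raises(ValueError):
            popgen.geographic_distance(pm)
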