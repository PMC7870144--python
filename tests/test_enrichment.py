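"""Count-matrix QC, Wilcoxon DEG calling and gene-set enrichment against
independent brute-force oracles."""
import itertools
import math

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ineuron import enrichment as E
from ineuron import synthetic as S


def binomial_tail_oracle(k, n, p):
    """Upper-tail P(X >= k) by direct pmf summation with exact binomials."""
    return sum(math.comb(n, i) * p ** i * (1 - p) ** (n - i)
               for i in range(k, n + 1))


def hypergeom_tail_oracle(k, N, K, n):
    """P(X >= k) drawing n from N containing K marked, by pmf summation."""
    denom = math.comb(N, n)
    return sum(math.comb(K, i) * math.comb(N - K, n - i) / denom
               for i in range(k, min(K, n) + 1))


def make_adata(x, batches=None, mito=None, groups=None):
    x = np.asarray(x)
    n_cells, n_genes = x.shape
    obs = pd.DataFrame(index=[f"c{i}" for i in range(n_cells)])
    obs["batch"] = batches if batches is not None else "b0"
    if groups is not None:
        obs["cluster"] = groups
    var = pd.DataFrame(index=[f"g{j}" for j in range(n_genes)])
    var["mito"] = mito if mito is not None else False
    return ad.AnnData(X=x.astype(np.float64), obs=obs, var=var)


class TestCellQC:
    def build(self, detected, mito_frac, n_genes=8000):
        # one cell expressing `detected` genes at count 1, with the first
        # gene mitochondrial carrying the requested transcript fraction
        x = np.zeros((1, n_genes))
        x[0, 1:detected] = 1.0
        total_nonmito = detected - 1
        x[0, 0] = mito_frac * total_nonmito / (1 - mito_frac)
        mito = np.zeros(n_genes, dtype=bool)
        mito[0] = True
        return make_adata(x, mito=mito)

    @pytest.mark.parametrize("detected, frac, kept", [
        (400, 0.01, False),    # too few genes
        (500, 0.01, True),
        (6000, 0.01, True),
        (6001, 0.01, False),   # too many genes
        (2000, 0.06, False),   # mitochondrial fraction above 5 %
        (2000, 0.05, True),
    ])
    def test_thresholds(self, detected, frac, kept):
        out = E.qc_cells(self.build(detected, frac))
        assert (out.n_obs == 1) is kept

    def test_requires_mito_flag(self):
        adata = make_adata(np.ones((2, 10)))
        del adata.var["mito"]
        with pytest.raises(ValueError, match="mito"):
            E.qc_cells(adata)

    def test_idempotent(self):
        adata, _ = S.simulate_counts(
            S.CountsGenParams(n_high_mito=4, n_low_depth=4), 3)
        once = E.qc_cells(adata)
        twice = E.qc_cells(once)
        assert list(once.obs_names) == list(twice.obs_names)

    def test_matches_generator_truth(self):
        adata, truth = S.simulate_counts(
            S.CountsGenParams(n_high_mito=5, n_low_depth=5), 4)
        out = E.qc_cells(adata)
        assert list(out.obs_names) == truth["qc_keep_cells"]


class TestGeneQC:
    def test_all_zero_gene_removed(self):
        x = np.ones((4, 3))
        x[:, 1] = 0.0
        out = E.qc_genes(make_adata(x))
        assert list(out.var_names) == ["g0", "g2"]

    def test_kept_if_any_batch_mean_exceeds_cutoff(self):
        # batch means 0.05 and 0.2 -> kept
        x = np.array([[0.05], [0.05], [0.2], [0.2]]) * np.array([[1.0]])
        x = np.array([[0.1, 1], [0.0, 1], [0.2, 1], [0.2, 1]])
        adata = make_adata(x, batches=["b0", "b0", "b1", "b1"])
        out = E.qc_genes(adata)
        assert "g0" in out.var_names  # batch b1 mean 0.2 > 0.1

    def test_matches_brute_force(self, rng):
        x = rng.poisson(0.12, size=(60, 40)).astype(float)
        batches = rng.choice(["b0", "b1", "b2"], size=60)
        out = E.qc_genes(make_adata(x, batches=batches))
        expected = []
        for j in range(40):
            means = [x[batches == b, j].mean() for b in ("b0", "b1", "b2")]
            if max(means) > 0.1:
                expected.append(f"g{j}")
        assert list(out.var_names) == expected

    def test_idempotent(self, rng):
        x = rng.poisson(0.2, size=(30, 50)).astype(float)
        adata = make_adata(x)
        once = E.qc_genes(adata)
        assert list(E.qc_genes(once).var_names) == list(once.var_names)


class TestFindDegs:
    def test_toy_pvalues_match_exact_enumeration(self, rng):
        # 3 vs 3 cells, tie-free expression -> the rank-sum p must equal the
        # exhaustive enumeration over all C(6,3) group assignments
        x = rng.lognormal(2.0, 0.5, size=(6, 5)).round(3)
        x += np.arange(5)[None, :] * 0.001  # break cross-gene ties
        adata = make_adata(x)
        res = E.find_degs(adata, np.array([1, 1, 1, 0, 0, 0], dtype=bool),
                          np.array([0, 0, 0, 1, 1, 1], dtype=bool))
        norm = E.normalize_cp10k_log1p(x)
        for j, p_obs in enumerate(res["p_value"]):
            vals = norm[:, j]
            obs_u = stats.mannwhitneyu(vals[:3], vals[3:],
                                       alternative="two-sided").statistic
            us = []
            for combo in itertools.combinations(range(6), 3):
                a = vals[list(combo)]
                b = vals[[i for i in range(6) if i not in combo]]
                u = sum((ai > bi) + 0.5 * (ai == bi) for ai in a for bi in b)
                us.append(u)
            us = np.array(us)
            p_exact = min(1.0, 2.0 * min((us <= obs_u).mean(),
                                         (us >= obs_u).mean()))
            assert p_obs == pytest.approx(p_exact, abs=1e-12)

    def test_planted_fold_change_recovered_small(self):
        # small matrix: gene QC only (the 500-genes-detected floor is tuned
        # to transcriptome-scale matrices)
        adata, truth = S.simulate_counts(S.CountsGenParams(
            n_genes=400, n_planted=30, n_cells_a=80, n_cells_b=80), 6)
        adata = E.qc_genes(adata)
        res = E.find_degs(adata, (adata.obs.group == "A").to_numpy(),
                          (adata.obs.group == "B").to_numpy())
        planted = set(truth["planted_genes"]) & set(adata.var_names)
        flagged = set(res.loc[res.deg_flag, "gene"])
        assert len(flagged & planted) / len(planted) >= 0.9

    def test_adjusted_p_never_below_raw(self, rng):
        x = rng.poisson(2.0, size=(20, 50)).astype(float)
        adata = make_adata(x)
        res = E.find_degs(adata, np.arange(20) < 10, np.arange(20) >= 10)
        assert (res.adjusted_p >= res.p_value - 1e-15).all()

    def test_deg_flag_definition(self, rng):
        x = rng.poisson(2.0, size=(20, 30)).astype(float)
        res = E.find_degs(make_adata(x), np.arange(20) < 10,
                          np.arange(20) >= 10)
        expected = (res.adjusted_p < 0.05) & (res.log2_fold_change > 0.25)
        assert (res.deg_flag == expected).all()

    def test_tiny_groups_rejected(self, rng):
        x = rng.poisson(2.0, size=(5, 10)).astype(float)
        with pytest.raises(ValueError, match="3 cells"):
            E.find_degs(make_adata(x), np.arange(5) < 2, np.arange(5) >= 2)


class TestBinomialEnrichment:
    def make_sets(self, members):
        return {"T": ("term", members)}

    def test_background_rate_not_enriched(self):
        # k/n = K/N exactly (5/100 vs 50/1000): p ~ 0.56
        bg = [f"g{i}" for i in range(1000)]
        degs = bg[:5] + bg[500:595]          # 100 DEGs, 5 in the term
        term = bg[:5] + bg[600:645]          # 50 genes, 5 of them DEGs
        res = E.binomial_enrichment(degs, self.make_sets(term), bg)
        assert res.p_value[0] == pytest.approx(
            binomial_tail_oracle(5, 100, 0.05), abs=1e-12)
        assert 0.4 < res.p_value[0] < 0.7
        assert not res.enriched_flag[0]

    def test_all_degs_in_term_closed_form(self):
        bg = [f"g{i}" for i in range(200)]
        degs = bg[:10]
        term = bg[:100]  # K/N = 0.5
        res = E.binomial_enrichment(degs, self.make_sets(term), bg)
        assert res.p_value[0] == pytest.approx(0.5 ** 10, rel=1e-9)

    def test_grid_matches_tail_summation(self):
        bg = [f"g{i}" for i in range(100)]
        for n in (5, 12, 25):
            for K in (6, 20, 45):
                for k in range(0, min(n, K) + 1, 3):
                    degs = bg[:k] + bg[K:K + n - k]
                    term = bg[:K]
                    res = E.binomial_enrichment(degs, self.make_sets(term),
                                                bg)
                    assert res.p_value[0] == pytest.approx(
                        binomial_tail_oracle(k, n, K / 100), abs=1e-12)

    def test_monotone_in_overlap(self):
        bg = [f"g{i}" for i in range(100)]
        term = bg[:30]
        last = 1.1
        for k in range(0, 11, 2):
            degs = bg[:k] + bg[50:60 - k]
            p = E.binomial_enrichment(degs, self.make_sets(term),
                                      bg).p_value[0]
            assert p < last + 1e-15
            last = p

    def test_empty_term_skipped(self):
        bg = [f"g{i}" for i in range(50)]
        sets = {"T": ("term", ["absent1", "absent2"])}
        res = E.binomial_enrichment(bg[:5], sets, bg)
        assert len(res) == 0

    def test_degs_outside_background_rejected(self):
        bg = [f"g{i}" for i in range(50)]
        with pytest.raises(ValueError, match="subset"):
            E.binomial_enrichment(["nope"], self.make_sets(bg[:5]), bg)


class TestFisherEnrichment:
    def test_matches_hypergeometric_summation(self):
        bg = [f"g{i}" for i in range(100)]
        degs = bg[:10]
        term = bg[:8] + bg[50:52]  # k = 8, K = 10
        res = E.fisher_enrichment_fdr(degs, {"T": ("t", term)}, bg)
        assert res.p_value[0] == pytest.approx(
            hypergeom_tail_oracle(8, 100, 10, 10), abs=1e-12)

    def test_zero_overlap_not_enriched(self):
        bg = [f"g{i}" for i in range(100)]
        res = E.fisher_enrichment_fdr(bg[:10], {"T": ("t", bg[50:60])}, bg)
        assert res.p_value[0] > 0.5
        assert not res.enriched_flag[0]

    def test_null_terms_controlled_by_bh(self, rng):
        bg = [f"g{i}" for i in range(300)]
        false_per_family = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            degs = list(r.choice(bg, size=30, replace=False))
            sets = {f"T{i}": ("t", list(r.choice(bg, size=20,
                                                 replace=False)))
                    for i in range(20)}
            res = E.fisher_enrichment_fdr(degs, sets, bg)
            false_per_family.append(int(res.enriched_flag.sum()))
        # expected false discoveries under BH at q=0.05 over m=20 null terms
        assert np.mean(false_per_family) <= 0.05 * 20


class TestBHProperties:
    def test_adjusted_monotone_in_rank(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(size=40)
        adj = multipletests(p, method="fdr_bh")[1]
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert (adj >= p - 1e-15).all()


class TestEnrichmentCorrelation:
    def test_self_correlation_is_one(self):
        prof = pd.DataFrame({"a": [0.01, 0.2, 0.5, 0.9],
                             "b": [0.01, 0.2, 0.5, 0.9]})
        r, mask = E.enrichment_correlation(prof)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert bool(mask.loc["a", "b"])

    def test_reversed_profile_anticorrelates(self):
        a = np.array([0.001, 0.01, 0.1, 0.5])
        prof = pd.DataFrame({"a": a, "b": a[::-1]})
        r, mask = E.enrichment_correlation(prof)
        assert r.loc["a", "b"] < 0
        assert not bool(mask.loc["a", "b"])

    def test_hand_computed_pearson(self):
        a = np.array([0.5, 0.1, 0.01, 0.2, 0.9])
        b = np.array([0.4, 0.2, 0.05, 0.3, 0.7])
        x, y = -np.log10(a), -np.log10(b)
        expected = (((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum()
                              * ((y - y.mean()) ** 2).sum()))
        r, _ = E.enrichment_correlation(pd.DataFrame({"a": a, "b": b}))
        assert r.loc["a", "b"] == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_profile_is_nan(self):
        prof = pd.DataFrame({"a": [0.1, 0.1, 0.1], "b": [0.1, 0.2, 0.3]})
        r, _ = E.enrichment_correlation(prof)
        assert math.isnan(r.loc["a", "b"])


class TestGmtIO:
    def test_round_trip(self, tmp_path):
        sets = {"GO:1": ("axonogenesis", ["A", "B", "C"]),
                "GO:2": ("synapse organization", ["B", "D"])}
        E.write_gmt(sets, tmp_path / "s.gmt")
        assert E.read_gmt(tmp_path / "s.gmt") == {
            k: (n, list(m)) for k, (n, m) in sets.items()}

    def test_duplicate_members_rejected(self, tmp_path):
        (tmp_path / "bad.gmt").write_text("T\tdesc\tA\tA\n")
        with pytest.raises(ValueError, match="duplicate"):
            E.read_gmt(tmp_path / "bad.gmt")


def test_mito_flag_from_symbols():
    flags = E.mito_flag_from_symbols(["MT-CO1", "ACTB", "mt-nd1"])
    assert flags.tolist() == [True, False, True]
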