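import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

import trflptools as t
from trflptools.permanova import DesignError, pairwise_table

SEASONS3 = ["spring"] * 5 + ["summer"] * 5 + ["autumn"] * 5


def _euclid(X):
    return squareform(pdist(np.atleast_2d(np.asarray(X, float).T).T))


class TestOneWayExactness:
    def test_pseudo_f_equals_classical_anova_f(self, rng):
        for _ in range(25):
            x = rng.normal(size=15)
            groups = pd.Series(SEASONS3)
            res = t.permanova(_euclid(x[:, None]), groups, n_perm=19, seed=0)
            f_classical = stats.f_oneway(x[:5], x[5:10], x[10:]).statistic
            assert res.table.iloc[0]["pseudo_F"] == pytest.approx(f_classical, rel=1e-10)

    def test_matches_scikit_bio(self, rng):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import permanova as sk_permanova

        X = rng.normal(size=(14, 6))
        d = squareform(pdist(X))
        groups = ["a"] * 7 + ["b"] * 7
        mine = t.permanova(d, pd.Series(groups), n_perm=19, seed=0)
        theirs = sk_permanova(SkDM(d), groups, permutations=19)
        assert mine.table.iloc[0]["pseudo_F"] == pytest.approx(
            theirs["test statistic"], rel=1e-10)


class TestTwoWay:
    def test_partition_sums_to_total(self, pot_matrix):
        res = t.permanova_two_way(t.euclidean_distances(pot_matrix), pot_matrix.meta,
                                  n_perm=19, seed=0)
        tab = res.table.set_index("term")
        parts = tab.loc[["season", "treatment", "season:treatment", "residual"], "SS"].sum()
        assert parts == pytest.approx(tab.loc["total", "SS"], rel=1e-8)

    def test_euclidean_ss_equals_columnwise_anova_ss(self, rng):
        """With Euclidean distance the multivariate SS per term is the sum of
        univariate two-way ANOVA SS over columns (brute-force oracle)."""
        X = rng.normal(size=(12, 4))
        meta = pd.DataFrame({
            "season": ["spring"] * 6 + ["summer"] * 6,
            "treatment": (["ambient"] * 3 + ["ozone"] * 3) * 2,
        }, index=[str(i) for i in range(12)])
        res = t.permanova_two_way(squareform(pdist(X)), meta, n_perm=9, seed=0)
        tab = res.table.set_index("term")

        def anova_ss(y):
            df = meta.assign(y=y)
            grand = y.mean()
            a = df.groupby("season")["y"].transform("mean")
            b = df.groupby("treatment")["y"].transform("mean")
            cell = df.groupby(["season", "treatment"])["y"].transform("mean")
            ss_a = ((a - grand) ** 2).sum()
            ss_b = ((b - grand) ** 2).sum()
            ss_ab = ((cell - a - b + grand) ** 2).sum()
            ss_res = ((y - cell) ** 2).sum()
            return ss_a, ss_b, ss_ab, ss_res

        sums = np.sum([anova_ss(X[:, j]) for j in range(X.shape[1])], axis=0)
        for term, expected in zip(["season", "treatment", "season:treatment", "residual"], sums):
            assert tab.loc[term, "SS"] == pytest.approx(expected, rel=1e-8)

    def test_matches_vegan_adonis2(self, tmp_path, pot_matrix):
        """Two-way sequential SS and pseudo-F agree with vegan's adonis2."""
        dm = t.euclidean_distances(pot_matrix)
        mine = t.permanova_two_way(dm, pot_matrix.meta, n_perm=9, seed=0).table.set_index("term")
        dm.to_frame().to_csv(tmp_path / "d.csv")
        pot_matrix.meta.to_csv(tmp_path / "meta.csv")
        script = tmp_path / "check.R"
        script.write_text(
            'suppressMessages(library(vegan))\n'
            'd <- as.dist(as.matrix(read.csv("d.csv", row.names=1, check.names=FALSE)))\n'
            'meta <- read.csv("meta.csv")\n'
            'res <- adonis2(d ~ season * treatment, data=meta, permutations=9, by="terms")\n'
            'write.csv(as.data.frame(res), "adonis.csv")\n'
        )
        subprocess.run(["Rscript", "check.R"], cwd=tmp_path, check=True,
                       capture_output=True)
        theirs = pd.read_csv(tmp_path / "adonis.csv", index_col=0)
        for term, r_term in [("season", "season"), ("treatment", "treatment"),
                             ("season:treatment", "season:treatment"),
                             ("residual", "Residual")]:
            assert mine.loc[term, "SS"] == pytest.approx(
                theirs.loc[r_term, "SumOfSqs"], rel=1e-6)
        for term in ["season", "treatment", "season:treatment"]:
            assert mine.loc[term, "pseudo_F"] == pytest.approx(theirs.loc[term, "F"], rel=1e-6)

    def test_planted_season_effect_detected(self, pot_matrix):
        res = t.permanova_two_way(t.euclidean_distances(pot_matrix), pot_matrix.meta,
                                  n_perm=999, seed=1)
        assert res.table.set_index("term").loc["season", "p"] < 0.05

    def test_identical_samples_degenerate(self):
        d = np.zeros((8, 8))
        meta = pd.DataFrame({"season": ["spring", "summer"] * 4,
                             "treatment": ["ambient"] * 4 + ["ozone"] * 4})
        with pytest.raises(DesignError, match="identical"):
            t.permanova_two_way(d, meta, n_perm=9)

    def test_single_level_factor_rejected(self, rng):
        d = squareform(pdist(rng.normal(size=(6, 2))))
        meta = pd.DataFrame({"season": ["spring"] * 6, "treatment": ["ambient", "ozone"] * 3})
        with pytest.raises(DesignError, match="season"):
            t.permanova_two_way(d, meta, n_perm=9)

    def test_p_invariant_to_level_relabeling(self, rng):
        X = rng.normal(size=(12, 3))
        d = squareform(pdist(X))
        meta = pd.DataFrame({"g": ["a"] * 6 + ["b"] * 6})
        p1 = t.permanova(d, meta, factors=("g",), interaction=False, n_perm=99, seed=5)
        meta2 = meta.replace({"a": "zebra", "b": "ant"})
        p2 = t.permanova(d, meta2, factors=("g",), interaction=False, n_perm=99, seed=5)
        assert p1.table.iloc[0]["p"] == p2.table.iloc[0]["p"]


class TestPairwise:
    def test_three_levels_give_three_comparisons(self, pot_matrix):
        out = t.pairwise_comparisons(t.euclidean_distances(pot_matrix), pot_matrix.meta,
                                     "season", n_perm=99, seed=0)
        assert len(out) == 3
        assert all(c.t >= 0 for c in out)

    def test_identical_groups_yield_null_result(self, rng):
        row = np.array([60.0, 30.0, 10.0])
        X = row + rng.normal(0, 0.01, size=(8, 3))  # two indistinguishable groups
        d = squareform(pdist(X))
        meta = pd.DataFrame({"g": ["a"] * 4 + ["b"] * 4})
        (c,) = t.pairwise_comparisons(d, meta["g"], n_perm=99, seed=0)
        assert c.p > 0.3

    def test_small_level_skipped_with_warning(self, rng):
        d = squareform(pdist(rng.normal(size=(5, 2))))
        labels = pd.Series(["a", "a", "b", "b", "c"])
        with pytest.warns(UserWarning, match="skipped"):
            out = t.pairwise_comparisons(d, labels, n_perm=19, seed=0)
        assert {(c.level_a, c.level_b) for c in out} == {("a", "b")}

    def test_holm_adjustment_monotone(self, pot_matrix):
        out = t.pairwise_comparisons(t.euclidean_distances(pot_matrix), pot_matrix.meta,
                                     "season", n_perm=99, seed=0, adjust="holm")
        tab = pairwise_table(out)
        assert (tab["p_adjusted"] >= tab["p"] - 1e-12).all()


class TestAsymptoticP:
    def test_p_near_half_at_distribution_mean(self, rng):
        fs = rng.gamma(3.0, 0.5, size=2000)
        p = t.asymptotic_p(float(fs.mean()), fs)
        assert 0.4 <= p <= 0.6

    def test_far_tail_beats_permutation_resolution(self, rng):
        fs = rng.gamma(3.0, 0.5, size=999)
        assert t.asymptotic_p(float(fs.max() * 20), fs) < 1.0 / 1000.0

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(ValueError):
            t.asymptotic_p(1.0, np.ones(100))

    def test_too_few_statistics_rejected(self, rng):
        with pytest.raises(ValueError):
            t.asymptotic_p(1.0, rng.gamma(2, 1, size=10))
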