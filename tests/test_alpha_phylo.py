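import math

import numpy as np
import pandas as pd
import pytest

from conftest import random_survey, random_tree
from fishdiv import alpha_phylo as ap
from fishdiv.tables import SurveyTable
from fishdiv.trees import Phylogeny


def brute_force_pd(community, tree: Phylogeny, include_root=True) -> float:
    """Independent oracle: mark every edge on each tip's root path, sum once.

    Without the root path, drop edges shared by ALL community tips (the
    path above the crown group).
    """
    marks = np.zeros(tree.edge_lengths.size, dtype=bool)
    per_tip = []
    for label in community:
        i = tree.tip_indices([label])[0]
        on_path = tree.edge_below[:, i]
        per_tip.append(on_path)
        marks |= on_path
    if not include_root:
        shared = np.logical_and.reduce(per_tip)
        marks &= ~shared
    return float(tree.edge_lengths[marks].sum())


class TestFaithPd:
    def test_full_community_is_total_length(self, three_tip_tree):
        assert ap.faith_pd(["A", "B", "C"], three_tip_tree) == 5.0

    def test_pair_traced_by_hand(self, three_tip_tree):
        assert ap.faith_pd(["A", "B"], three_tip_tree) == 3.0

    def test_single_species_root_path(self, three_tip_tree):
        assert ap.faith_pd(["C"], three_tip_tree) == 2.0
        assert ap.faith_pd(["C"], three_tip_tree, include_root=False) == 0.0

    def test_empty_community_rejected(self, three_tip_tree):
        with pytest.raises(ValueError):
            ap.faith_pd([], three_tip_tree)

    @pytest.mark.parametrize("include_root", [True, False])
    def test_matches_edge_union_oracle(self, include_root):
        rng = np.random.default_rng(11)
        for _ in range(200):
            tree = random_tree(rng, int(rng.integers(4, 15)))
            k = int(rng.integers(1, tree.n_tips + 1))
            comm = list(rng.choice(tree.tips, size=k, replace=False))
            assert ap.faith_pd(comm, tree, include_root) == pytest.approx(
                brute_force_pd(comm, tree, include_root), abs=1e-12)

    def test_monotone_under_species_addition(self):
        rng = np.random.default_rng(4)
        tree = random_tree(rng, 12)
        comm = list(rng.choice(tree.tips, size=4, replace=False))
        pd0 = ap.faith_pd(comm, tree)
        extra = [t for t in tree.tips if t not in comm][0]
        assert ap.faith_pd(comm + [extra], tree) >= pd0

    def test_agrees_with_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        from io import StringIO
        rng = np.random.default_rng(9)
        for _ in range(20):
            tree = random_tree(rng, 8)
            sk_tree = skbio.TreeNode.read(StringIO(tree.as_newick()))
            k = int(rng.integers(1, 9))
            comm = list(rng.choice(tree.tips, size=k, replace=False))
            counts = [1] * len(comm)
            expected = skbio.diversity.alpha.faith_pd(counts, comm, sk_tree)
            assert ap.faith_pd(comm, tree) == pytest.approx(expected, abs=1e-9)


class TestMpdVpd:
    def test_single_pair_is_its_distance(self, three_tip_tree):
        mpd, vpd = ap.mpd_vpd_abu({"A": 5, "C": 1}, three_tip_tree)
        assert mpd == pytest.approx(4.0) and vpd == pytest.approx(0.0)
        # abundances cannot matter for one pair
        mpd2, _ = ap.mpd_vpd_abu({"A": 500, "C": 1}, three_tip_tree)
        assert mpd2 == pytest.approx(mpd)

    def test_three_equal_tips_hand_values(self, three_tip_tree):
        mpd, vpd = ap.mpd_vpd_abu({"A": 2, "B": 2, "C": 2}, three_tip_tree)
        assert mpd == pytest.approx(10 / 3, abs=1e-12)
        assert vpd == pytest.approx(8 / 9, abs=1e-12)

    def test_single_species_missing(self, three_tip_tree):
        mpd, vpd = ap.mpd_vpd_abu({"A": 3}, three_tip_tree)
        assert math.isnan(mpd) and math.isnan(vpd)

    def test_equal_abundances_match_unweighted_double_loop(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            tree = random_tree(rng, int(rng.integers(3, 10)))
            k = int(rng.integers(2, tree.n_tips + 1))
            comm = list(rng.choice(tree.tips, size=k, replace=False))
            d = tree.patristic_matrix(comm)
            pairs = [d[i, j] for i in range(k) for j in range(i + 1, k)]
            mpd, vpd = ap.mpd_vpd_abu({c: 7 for c in comm}, tree)
            assert mpd == pytest.approx(np.mean(pairs), abs=1e-10)
            assert vpd == pytest.approx(np.var(pairs), abs=1e-10)

    def test_weighted_matches_explicit_double_loop(self):
        rng = np.random.default_rng(22)
        tree = random_tree(rng, 8)
        ab = {t: float(rng.integers(1, 30)) for t in tree.tips[:6]}
        labels = list(ab)
        f = np.array([ab[l] for l in labels])
        f = f / f.sum()
        d = tree.patristic_matrix(labels)
        num = den = 0.0
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                w = f[i] * f[j]
                num += w * d[i, j]
                den += w
        mpd, vpd = ap.mpd_vpd_abu(ab, tree)
        assert mpd == pytest.approx(num / den, abs=1e-10)
        var = sum(f[i] * f[j] * (d[i, j] - num / den) ** 2
                  for i in range(len(labels))
                  for j in range(i + 1, len(labels))) / den
        assert vpd == pytest.approx(var, abs=1e-10)


class TestSesNull:
    def _survey(self, tree, rng, n_sites=6):
        return random_survey(rng, n_sites, tree.tips, min_occ=2)

    def test_star_tree_mpd_invariant_gives_missing_ses(self):
        star = Phylogeny.from_newick("(A:1,B:1,C:1,D:1);")
        count = pd.DataFrame([[3, 1, 0, 0], [1, 2, 5, 1]],
                             index=["S1", "S2"], columns=list("ABCD"))
        sv = SurveyTable(count, count * 0.1)
        with pytest.warns(UserWarning, match="invariant under tip shuffle"):
            res = ap.ses_null(sv, star, "mpd_abu", n_perm=99, seed=0)
        assert res["ses"].isna().all()
        assert np.allclose(res["null_sd"], 0.0, atol=1e-12)

    def test_full_pool_community_pd_invariant(self):
        rng = np.random.default_rng(3)
        tree = random_tree(rng, 6)
        count = pd.DataFrame(np.ones((2, 6), dtype=int) * 2,
                             index=["S1", "S2"], columns=tree.tips)
        sv = SurveyTable(count, count * 0.1)
        with pytest.warns(UserWarning, match="invariant"):
            res = ap.ses_null(sv, tree, "pd", n_perm=99, seed=1)
        assert res["ses"].isna().all()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        tree = random_tree(rng, 10)
        sv = self._survey(tree, rng)
        a = ap.ses_null(sv, tree, "mpd_abu", n_perm=199, seed=42)
        b = ap.ses_null(sv, tree, "mpd_abu", n_perm=199, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_rank_p_range_and_add_one_rule(self):
        rng = np.random.default_rng(12)
        tree = random_tree(rng, 10)
        sv = self._survey(tree, rng)
        with pytest.warns(UserWarning, match="invariant"):
            res = ap.ses_null(sv, tree, "pd", n_perm=199, seed=0)
        informative = res[res["ses"].notna()]
        # add-one rule: never exactly 0; 1 only when obs tops every null
        assert ((informative["rank_p"] > 0)
                & (informative["rank_p"] <= 1)).all()
        assert res.loc[res["ses"].isna(), "rank_p"].isna().all()

    def test_calibration_on_random_communities(self):
        """Tip-shuffle SES over randomly assembled communities is ~N(0, 1)."""
        from fishdiv.synth import simulate_phylogeny

        tree = simulate_phylogeny(23, seed=7)
        rng = np.random.default_rng(11)
        sv = random_survey(rng, 60, tree.tips, min_occ=3)
        for metric in ("pd", "mpd_abu"):
            res = ap.ses_null(sv, tree, metric, n_perm=999, seed=3)
            assert abs(res["ses"].mean()) < 0.15
            assert 0.7 < res["ses"].std(ddof=1) < 1.3
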