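"""Rank-based regulon enrichment: quantile scores, NES, permutation oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from plateseq.activity import (
    Regulon,
    activity_matrix,
    nes,
    nes_permutation_oracle,
    rank_transform,
)


def simple_regulon(targets, modes=None, likelihoods=None):
    n = len(targets)
    return Regulon(
        "R",
        list(targets),
        np.ones(n) if modes is None else np.asarray(modes, float),
        np.ones(n) if likelihoods is None else np.asarray(likelihoods, float),
    )


class TestRankTransform:
    def test_closed_form_three_values(self):
        # values (5, 1, 9) have ranks (2, 1, 3); scores are the normal
        # quantiles of (1/6, 3/6, 5/6)
        got = rank_transform(np.array([5.0, 1.0, 9.0]))
        expected = sps.norm.ppf([3 / 6, 1 / 6, 5 / 6])
        assert np.allclose(got, expected)
        assert got[0] == pytest.approx(0.0)
        assert got[2] == pytest.approx(0.967421566, abs=1e-6)

    def test_negation_antisymmetry(self, rng):
        x = rng.normal(size=51)  # tie-free with probability 1
        assert np.allclose(rank_transform(-x), -rank_transform(x))

    def test_tied_maxima_share_averaged_score(self):
        got = rank_transform(np.array([1.0, 7.0, 7.0, 0.0]))
        assert got[1] == got[2]
        assert got[1] == pytest.approx(sps.norm.ppf((3.5 - 0.5) / 4))

    def test_constant_column_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="identical"):
            assert (rank_transform(np.array([2.0, 2.0, 2.0])) == 0).all()

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=30, unique=True))
    def test_monotone_in_input(self, values):
        x = np.array(values)
        scores = rank_transform(x)
        order = np.argsort(x)
        assert (np.diff(scores[order]) > 0).all()


class TestNes:
    def test_worked_top_m_closed_form(self):
        """m=4 unit-weight targets occupying the top 4 ranks of n=100:
        NES = sum of the four largest quantile scores / sqrt(4)."""
        x = np.arange(100, dtype=float)
        scores = pd.Series(rank_transform(x), index=[f"g{i}" for i in range(100)])
        reg = simple_regulon(["g96", "g97", "g98", "g99"])
        expected = sps.norm.ppf([0.965, 0.975, 0.985, 0.995]).sum() / 2.0
        assert nes(reg, scores, min_size=1) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(4.2588972, abs=1e-6)

    def test_mode_negation_negates_nes(self, rng):
        genes = [f"g{i}" for i in range(50)]
        scores = pd.Series(rank_transform(rng.normal(size=50)), index=genes)
        reg = simple_regulon(genes[:12], modes=rng.choice([-1.0, 1.0], 12),
                             likelihoods=rng.uniform(0.5, 1, 12))
        flipped = simple_regulon(reg.targets, modes=-reg.modes,
                                 likelihoods=reg.likelihoods)
        assert nes(flipped, scores) == pytest.approx(-nes(reg, scores))

    def test_score_negation_negates_nes(self, rng):
        genes = [f"g{i}" for i in range(51)]
        x = rng.normal(size=51)
        reg = simple_regulon(genes[:15])
        a = nes(reg, pd.Series(rank_transform(x), index=genes))
        b = nes(reg, pd.Series(rank_transform(-x), index=genes))
        assert a == pytest.approx(-b)

    def test_below_min_size_flagged_absent(self):
        scores = pd.Series(
            rank_transform(np.arange(20.0)), index=[f"g{i}" for i in range(20)]
        )
        reg = simple_regulon(["g1", "g2", "missing1", "missing2"])
        assert np.isnan(nes(reg, scores, min_size=3))
        assert not np.isnan(nes(reg, scores, min_size=2))

    def test_monotone_in_positive_mode_target(self, rng):
        genes = [f"g{i}" for i in range(40)]
        x = rng.normal(size=40)
        reg = simple_regulon(genes[:10])
        base_scores = pd.Series(rank_transform(x), index=genes)
        bumped = x.copy()
        bumped[0] = x.max() + 1  # push a mode-positive target to the top rank
        bumped_scores = pd.Series(rank_transform(bumped), index=genes)
        assert nes(reg, bumped_scores) >= nes(reg, base_scores)

    def test_null_moments(self, rng):
        """Random regulons on iid-normal quantile scores: NES mean ~ 0,
        variance ~ 1 (3 s.e. tolerance)."""
        genes = [f"g{i}" for i in range(300)]
        draws = []
        for _ in range(3000):
            scores = pd.Series(rank_transform(rng.normal(size=300)), index=genes)
            targets = rng.choice(genes, size=15, replace=False)
            reg = simple_regulon(targets, modes=rng.choice([-1.0, 1.0], 15),
                                 likelihoods=rng.uniform(0.5, 1, 15))
            draws.append(nes(reg, scores))
        draws = np.array(draws)
        assert abs(draws.mean()) < 3 / np.sqrt(draws.size)
        assert abs(draws.var(ddof=1) - 1.0) < 3 * np.sqrt(2 / draws.size) + 0.02


class TestActivityMatrix:
    def test_single_cell_equals_nes(self, rng):
        genes = [f"g{i}" for i in range(30)]
        sig = pd.DataFrame({"s0": rng.normal(size=30)}, index=genes)
        reg = simple_regulon(genes[:12])
        act = activity_matrix(sig, [reg], min_size=10)
        scores = pd.Series(rank_transform(sig["s0"].to_numpy()), index=genes)
        assert act.nes.loc["R", "s0"] == pytest.approx(nes(reg, scores))
        assert act.effective_size["R"] == 12

    def test_gene_order_invariance(self, rng):
        genes = [f"g{i}" for i in range(40)]
        sig = pd.DataFrame(rng.normal(size=(40, 3)), index=genes,
                           columns=["s0", "s1", "s2"])
        reg = simple_regulon(genes[5:20])
        a = activity_matrix(sig, [reg]).nes
        shuffled = sig.sample(frac=1, random_state=0)
        b = activity_matrix(shuffled, [reg]).nes
        assert np.allclose(a.values, b.values)

    def test_small_regulon_is_nan_flagged(self, rng):
        genes = [f"g{i}" for i in range(30)]
        sig = pd.DataFrame({"s0": rng.normal(size=30)}, index=genes)
        reg = simple_regulon(genes[:4])
        act = activity_matrix(sig, [reg], min_size=10)
        assert np.isnan(act.nes.loc["R", "s0"])


class TestPermutationOracle:
    def test_zero_scores_give_zero_z(self):
        genes = [f"g{i}" for i in range(50)]
        scores = pd.Series(np.zeros(50), index=genes)
        reg = simple_regulon(genes[:10])
        assert nes_permutation_oracle(reg, scores, n_perm=1000, seed=0) == 0.0

    def test_seeded_determinism(self, rng):
        genes = [f"g{i}" for i in range(60)]
        scores = pd.Series(rank_transform(rng.normal(size=60)), index=genes)
        reg = simple_regulon(genes[:12])
        a = nes_permutation_oracle(reg, scores, n_perm=2000, seed=5)
        b = nes_permutation_oracle(reg, scores, n_perm=2000, seed=5)
        assert a == b

    def test_agrees_with_analytic_nes(self, rng):
        genes = [f"g{i}" for i in range(500)]
        for case in range(5):
            scores = pd.Series(rank_transform(rng.normal(size=500)), index=genes)
            targets = rng.choice(genes, size=20, replace=False)
            reg = simple_regulon(targets, modes=rng.choice([-1.0, 1.0], 20),
                                 likelihoods=rng.uniform(0.5, 1, 20))
            analytic = nes(reg, scores)
            z = nes_permutation_oracle(reg, scores, n_perm=10000, seed=case)
            assert abs(analytic - z) < 0.15


def test_regulon_validation():
    with pytest.raises(ValueError, match="duplicate"):
        simple_regulon(["g1", "g1"])
    with pytest.raises(ValueError, match="modes"):
        simple_regulon(["g1"], modes=[2.0])
    with pytest.raises(ValueError, match="likelihoods"):
        simple_regulon(["g1"], likelihoods=[0.0])
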