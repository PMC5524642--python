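"""Normalization, vehicle-referenced signatures, top-k selection, MDS."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import orthogonal_procrustes

import plateseq as ps
from plateseq.signatures import (
    NormalizationError,
    classical_mds,
    signature,
    size_factors,
    top_differential,
    vst,
)


def frame(arr, samples=None):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"g{i}" for i in range(arr.shape[0])],
        columns=samples or [f"s{j}" for j in range(arr.shape[1])],
    )


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        f = frame([[5, 5], [9, 9], [2, 2]])
        assert np.allclose(size_factors(f), [1.0, 1.0])

    def test_doubled_column_closed_form(self):
        # column2 = 2*column1: median-of-ratios with geometric-mean-1 rescale
        # gives exactly (1/sqrt(2), sqrt(2))
        f = frame([[5, 10], [9, 18], [2, 4]])
        sf = size_factors(f)
        assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)], atol=1e-12)

    def test_single_sample_unit_factor(self):
        assert size_factors(frame([[5], [9]])).iloc[0] == 1.0

    def test_geometric_mean_is_one(self, rng):
        f = frame(rng.integers(1, 100, size=(40, 6)))
        sf = size_factors(f)
        assert np.exp(np.log(sf).mean()) == pytest.approx(1.0)

    def test_no_common_gene_raises(self):
        f = frame([[5, 0], [0, 9]])
        with pytest.raises(NormalizationError):
            size_factors(f)


class TestVst:
    @pytest.mark.parametrize("count,expected", [(0, 0.0), (7, 3.0), (1, 1.0)])
    def test_closed_form_at_unit_factor(self, count, expected):
        f = frame([[count], [count]])
        expr = vst(f, pseudocount=1.0)
        assert expr.values.iloc[0, 0] == pytest.approx(expected)

    def test_doubling_counts_and_factor_is_invariant(self, rng):
        f = frame(rng.integers(1, 50, size=(30, 3)))
        sf = size_factors(f)
        a = vst(f, factors=sf)
        doubled = f.copy()
        doubled["s1"] *= 2
        b = vst(doubled, factors=sf * pd.Series({"s0": 1.0, "s1": 2.0, "s2": 1.0}))
        assert np.allclose(a.values["s1"], b.values["s1"])

    def test_monotone_in_counts(self, rng):
        f = frame(np.sort(rng.integers(0, 100, size=(50, 1)), axis=0))
        expr = vst(f)
        assert (np.diff(expr.values["s0"]) >= 0).all()


class TestSignature:
    def test_identical_columns_give_zero_signatures(self):
        f = frame([[3, 3, 3], [1, 1, 1]])
        sig = signature(f, ["s0", "s1"])
        assert np.allclose(sig.values, 0.0)

    def test_vehicle_mean_is_zero_vector(self, rng):
        f = frame(rng.normal(5, 1, size=(40, 8)))
        controls = ["s0", "s3", "s5"]
        sig = signature(f, controls)
        assert np.abs(sig.values[controls].mean(axis=1)).max() < 1e-12

    def test_constant_offset_invariance(self, rng):
        f = frame(rng.normal(0, 1, size=(20, 6)))
        offset = rng.normal(0, 3, size=20)
        a = signature(f, ["s0", "s1"]).values
        b = signature(f.add(offset, axis=0), ["s0", "s1"]).values
        assert np.allclose(a, b)

    def test_no_vehicle_raises(self, rng):
        f = frame(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError, match="vehicle"):
            signature(f, [])

    def test_planted_lfc_recovered_in_signature(self, toy_tx):
        """A +2 log2-unit planting lands near +2 in the treated signatures."""
        plate = ps.design_plate(
            {"drugA": ps.PerturbationSpec({"G0001": 2.0})}, replicates=12
        )
        truth = ps.simulate_counts(toy_tx, plate, 200, 0.05, 20000, seed=8)
        sig = signature(vst(truth.realized_counts), plate)
        vals = sig.values.loc["G0001", plate.condition_samples()["drugA"]]
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 2.0) < 3 * se + 0.1


class TestTopDifferential:
    def test_single_nonzero_feature_wins(self):
        f = frame([[0, 0], [4, 4], [0, 0]])
        assert top_differential(f, {"c": ["s0", "s1"]}, k=1) == ["g1"]

    def test_sign_symmetric_rows_rank_adjacently(self):
        f = frame([[2, 2], [-2, -2], [0.5, 0.5], [0, 0]])
        top = top_differential(f, {"c": ["s0", "s1"]}, k=4)
        assert set(top[:2]) == {"g0", "g1"}

    def test_matches_brute_force_sort(self, rng):
        f = frame(rng.normal(size=(100, 8)))
        conditions = {"a": ["s0", "s1", "s2"], "b": ["s5", "s6"]}
        got = top_differential(f, conditions, k=100)
        scores = {
            g: max(abs(f.loc[g, s].mean()) for s in conditions.values())
            for g in f.index
        }
        expected = sorted(f.index, key=lambda g: (-scores[g], g))
        assert got == expected

    def test_k_truncates_with_warning(self, rng):
        f = frame(rng.normal(size=(5, 2)))
        with pytest.warns(UserWarning, match="truncating"):
            top = top_differential(f, {"c": ["s0", "s1"]}, k=10)
        assert len(top) == 5


class TestClassicalMds:
    def test_recovers_planted_2d_configuration(self, rng):
        pts = rng.normal(size=(12, 2))
        X = np.zeros((100, 12))
        X[:2, :] = pts.T  # 2-D points embedded in 100-D
        coords = classical_mds(frame(X), dims=2).to_numpy()
        centered = pts - pts.mean(axis=0)
        R, _ = orthogonal_procrustes(coords, centered)
        assert np.linalg.norm(coords @ R - centered) < 1e-8

    def test_identical_samples_coincide(self):
        f = frame([[1, 1, 4], [2, 2, 0], [3, 3, 1]])
        coords = classical_mds(f, dims=2)
        assert np.allclose(coords.loc["s0"], coords.loc["s1"], atol=1e-9)

    def test_collinear_samples_have_null_second_dimension(self):
        # samples at (2i, -i): collinear in feature space
        f = frame(np.vstack([np.arange(4) * 2.0, np.arange(4) * -1.0]))
        coords = classical_mds(f, dims=2)
        assert np.abs(coords["MDS2"]).max() < 1e-9

    def test_distances_preserved_for_low_rank_input(self, rng):
        X = rng.normal(size=(3, 8))  # rank <= 3 features
        f = frame(X)
        coords = classical_mds(f, dims=3).to_numpy()
        from scipy.spatial.distance import pdist

        assert np.allclose(pdist(X.T), pdist(coords), atol=1e-8)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="at least"):
            classical_mds(frame([[1, 2]]), dims=2)


def test_replicates_cluster_by_condition_in_mds(toy_tx):
    """Strong planted effects: within-condition embedded distances are
    smaller than between-condition distances."""
    conditions = {
        "drugA": ps.PerturbationSpec({g: 2.5 for g in ["G0001", "G0002", "G0003"]}),
        "drugB": ps.PerturbationSpec({g: -2.5 for g in ["G0004", "G0005", "G0006"]}),
    }
    plate = ps.design_plate(conditions, replicates=12)
    truth = ps.simulate_counts(toy_tx, plate, 100, 0.05, 8000, seed=9)
    sig = signature(vst(truth.realized_counts), plate)
    coords = classical_mds(sig.values, dims=2)
    groups = plate.condition_samples(include_vehicle=True)
    centroids = {c: coords.loc[s].mean(axis=0) for c, s in groups.items()}
    within = np.mean([
        np.linalg.norm(coords.loc[s] - centroids[c], axis=1).mean()
        for c, s in groups.items()
    ])
    between = np.mean([
        np.linalg.norm(centroids[a] - centroids[b])
        for a in groups for b in groups if a < b
    ])
    assert within < between
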