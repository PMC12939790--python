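"""SID/RSID harmonic-rank aggregation and quadrant classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metstab import (
    RunConfig,
    SimulationSpec,
    build_rank_table,
    orient_indices,
    quadrant_classify,
    rank_by_index,
    sid,
    sid_pipeline,
    simulate_met,
    to_matrix,
    compute_index_table,
    stability_table_frame,
)
from metstab.met_io import Role
from metstab.rank_aggregation import RankTable

from .oracles import harmonic_mean, pearson_r


def _table(values: dict) -> pd.DataFrame:
    g = len(next(iter(values.values())))
    df = pd.DataFrame(values)
    df.insert(0, "genotype", [f"G{i + 1}" for i in range(g)])
    return df


class TestOrientation:
    def test_index_identical_to_yield_as_is(self):
        y = np.array([5.0, 6.0, 7.0, 9.0])
        df = _table({"mean": y, "S2": y.copy()})
        (o,) = orient_indices(df, index_columns=["S2"])
        assert not o.inverted
        assert o.yield_correlation == pytest.approx(1.0)

    def test_negated_index_inverted(self):
        y = np.array([5.0, 6.0, 7.0, 9.0])
        df = _table({"mean": y, "b": 20.0 - y})
        (o,) = orient_indices(df, index_columns=["b"])
        assert o.inverted
        assert o.yield_correlation == pytest.approx(-1.0)

    def test_correlation_matches_oracle(self):
        rng = np.random.default_rng(2)
        y = rng.uniform(4, 10, size=8)
        v = rng.uniform(0, 2, size=8)
        df = _table({"mean": y, "W2": v})
        (o,) = orient_indices(df, index_columns=["W2"])
        assert o.yield_correlation == pytest.approx(
            pearson_r(v.tolist(), y.tolist()), rel=1e-10
        )

    def test_zero_variance_column_warns_as_is(self):
        df = _table({"mean": [5.0, 6.0, 7.0], "R2": [1.0, 1.0, 1.0]})
        with pytest.warns(UserWarning, match="variance"):
            (o,) = orient_indices(df, index_columns=["R2"])
        assert not o.inverted


class TestRankByIndex:
    def test_ascending(self):
        np.testing.assert_array_equal(rank_by_index(np.array([0.1, 0.2, 0.3])), [1, 2, 3])

    def test_inverted_reverses(self):
        np.testing.assert_array_equal(
            rank_by_index(np.array([0.1, 0.2, 0.3]), inverted=True), [3, 2, 1]
        )

    def test_tie_gets_average_rank(self):
        np.testing.assert_array_equal(rank_by_index(np.array([1.0, 1.0, 2.0])), [1.5, 1.5, 3])

    def test_missing_values_rank_last(self):
        ranks = rank_by_index(np.array([2.0, np.nan, 1.0]))
        np.testing.assert_array_equal(ranks, [2, 3, 1])

    def test_inverted_mixed_sign_still_reverses_order(self):
        vals = np.array([-1.5, 0.0, 2.0])
        np.testing.assert_array_equal(rank_by_index(vals, inverted=True), [3, 2, 1])


class TestSID:
    def _rank_table(self, ranks: dict, genotypes=None) -> RankTable:
        df = pd.DataFrame(ranks)
        genotypes = genotypes or tuple(f"G{i + 1}" for i in range(len(df)))
        df.index = list(genotypes)
        return RankTable(tuple(genotypes), df, ())

    def test_all_ones_gives_sid_one(self):
        rt = self._rank_table({"a": [1, 2, 3], "b": [1, 3, 2], "c": [1, 2, 3]})
        results = sid(rt)
        assert results[0].sid == pytest.approx(1.0)
        assert results[0].rsid == 1

    def test_harmonic_mean_of_2_4_4_is_3(self):
        rt = self._rank_table({"a": [2, 1, 3], "b": [4, 1, 2], "c": [4, 1, 2]})
        assert sid(rt)[0].sid == pytest.approx(3.0)

    def test_matches_harmonic_oracle(self):
        rng = np.random.default_rng(8)
        ranks = {k: rng.permutation(6) + 1 for k in "abcde"}
        rt = self._rank_table({k: v.tolist() for k, v in ranks.items()})
        for i, res in enumerate(sid(rt)):
            expected = harmonic_mean([ranks[k][i] for k in "abcde"])
            assert res.sid == pytest.approx(expected, rel=1e-12)

    def test_harmonic_le_arithmetic(self):
        rng = np.random.default_rng(1)
        rt = self._rank_table({k: (rng.permutation(10) + 1).tolist() for k in "abc"})
        for res in sid(rt):
            assert res.sid <= res.mean_rank + 1e-12

    def test_equality_iff_all_ranks_equal(self):
        rt = self._rank_table({"a": [2, 1], "b": [2, 1]})
        res = sid(rt)
        assert res[0].sid == pytest.approx(res[0].mean_rank)

    def test_rsid_is_permutation_when_distinct(self):
        rng = np.random.default_rng(4)
        rt = self._rank_table({k: (rng.permutation(7) + 1).tolist() for k in "abc"})
        rsids = sorted(r.rsid for r in sid(rt))
        if len(set(r.sid for r in sid(rt))) == 7:
            assert rsids == [1, 2, 3, 4, 5, 6, 7]

    def test_nonpositive_rank_rejected(self):
        rt = self._rank_table({"a": [0.0, 1.0]})
        with pytest.raises(ValueError):
            sid(rt)

    def test_missing_ranks_excluded_from_harmonic(self):
        rt = self._rank_table({"a": [2.0, 1.0], "b": [np.nan, 2.0]})
        res = sid(rt)
        assert res[0].sid == pytest.approx(2.0)  # only rank 2 survives


class TestInvariances:
    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_sid_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        g = 8
        df = _table(
            {
                "mean": rng.uniform(4, 10, size=g),
                "S2": rng.uniform(0.1, 2.0, size=g),
                "W2": rng.uniform(0.01, 1.0, size=g),
            }
        )
        df2 = df.copy()
        df2["S2"] = np.exp(df2["S2"])  # strictly increasing transform
        df2["W2"] = df2["W2"] ** 3 + 5.0
        rt1 = build_rank_table(df, index_columns=["S2", "W2"])
        rt2 = build_rank_table(df2, index_columns=["S2", "W2"])
        s1 = [r.sid for r in sid(rt1)]
        s2 = [r.sid for r in sid(rt2)]
        np.testing.assert_allclose(s1, s2, rtol=1e-12)

    def test_genotype_order_permutation(self):
        rng = np.random.default_rng(12)
        g = 9
        df = _table(
            {
                "mean": rng.uniform(4, 10, size=g),
                "S2": rng.uniform(0.1, 2.0, size=g),
                "CV": rng.uniform(5, 30, size=g),
                "W2": rng.uniform(0.01, 1.0, size=g),
            }
        )
        perm = rng.permutation(g)
        dfp = df.iloc[perm].reset_index(drop=True)
        cols = ["S2", "CV", "W2"]
        s1 = {r.genotype: r.sid for r in sid(build_rank_table(df, index_columns=cols))}
        s2 = {r.genotype: r.sid for r in sid(build_rank_table(dfp, index_columns=cols))}
        assert s1 == s2


class TestQuadrants:
    def test_best_corner_is_A(self):
        from metstab.rank_aggregation import SIDResult

        results = [
            SIDResult("G1", sid=1.0, rsid=1.0, mean_rank=1.0),
            SIDResult("G2", sid=2.0, rsid=2.0, mean_rank=2.0),
            SIDResult("G3", sid=3.0, rsid=3.0, mean_rank=3.0),
        ]
        out = quadrant_classify(results, {"G1": 9.0, "G2": 6.0, "G3": 3.0})
        assert out[0].quadrant == "A"
        assert out[2].quadrant == "C"  # min yield, worst rank

    def test_boundary_goes_to_favorable_side(self):
        from metstab.rank_aggregation import SIDResult

        results = [
            SIDResult("G1", 1.0, 1.0, 1.0),
            SIDResult("G2", 2.0, 2.0, 2.0),
            SIDResult("G3", 3.0, 3.0, 3.0),
        ]
        out = quadrant_classify(results, {"G1": 8.0, "G2": 6.0, "G3": 4.0})
        # G2 sits exactly on both means
        assert out[1].quadrant == "A"
        assert out[1].boundary

    def test_planted_stable_high_yield_lands_in_A(self):
        spec = SimulationSpec(
            g_lines=25, n_env=5, n_checks=0, interaction_rank=2,
            lambda_shares=(0.6, 0.4), sd_gei=0.5, sd_noise=0.0,
            planted_stable=2, planted_stable_advantage=2.5, seed=31,
        )
        records, truth = simulate_met(spec)
        m = to_matrix([r for r in records if r.role is Role.LINE])
        df = stability_table_frame(compute_index_table(m))
        _, results, flat = sid_pipeline(df)
        planted = flat[flat["genotype"].isin(truth.stable_genotypes)]
        assert (planted["quadrant"] == "A").all()
        assert planted["RSID"].max() <= 3


def test_sid_pipeline_emits_both_aggregates(augmented_matrix):
    df = stability_table_frame(compute_index_table(augmented_matrix))
    _, results, flat = sid_pipeline(df, RunConfig())
    assert {"SID", "RSID", "mean_rank", "quadrant"} <= set(flat.columns)
    assert len(flat) == augmented_matrix.n_genotypes
    # harmonic <= arithmetic for every genotype
    assert (flat["SID"] <= flat["mean_rank"] + 1e-12).all()


def test_yield_aligned_mode_applies_inversions(augmented_matrix):
    df = stability_table_frame(compute_index_table(augmented_matrix))
    rt = build_rank_table(df, mode="yield_aligned")
    # any index negatively correlated with yield must have reversed ranks
    # relative to plain ascending ranking
    for o in rt.orientations:
        vals = df[o.index].to_numpy(dtype=float)
        expected = rank_by_index(vals, o.inverted)
        np.testing.assert_array_equal(rt.ranks[o.index].to_numpy(), expected)
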