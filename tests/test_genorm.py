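"""geNorm: relative quantities, M values, iterative ranking, V series."""

import numpy as np
import pandas as pd
import pytest

from refstab.errors import InsufficientDataError, ParameterError
from refstab.genorm import (
    UNDETERMINED,
    RelativeQuantityMatrix,
    genorm_m,
    genorm_rank,
    genorm_stability,
    genorm_v_series,
    optimal_rg_count,
    to_relative_quantities,
)
from refstab.pairwise import delta_ct_stability

from conftest import make_ct, random_ct


def q_from_rows(rows, genes=None):
    arr = np.asarray(rows, dtype=float)
    genes = genes or [chr(ord("A") + i) for i in range(arr.shape[0])]
    cols = [f"S{j + 1}" for j in range(arr.shape[1])]
    return RelativeQuantityMatrix(pd.DataFrame(arr, index=genes, columns=cols))


ABC = [[1, 0.5, 0.25], [1, 0.5, 0.25], [1, 1, 0.5]]


# ------------------------------------------------------- naive re-implementation

def naive_m(q):
    """Independent brute-force M: explicit pair loops, numpy std only."""
    logq = np.log2(q.values)
    n = logq.shape[0]
    out = {}
    for i, gi in enumerate(q.gene_ids):
        vs = [np.std(logq[i] - logq[k], ddof=1) for k in range(n) if k != i]
        out[gi] = float(np.mean(vs))
    return out


def naive_exclusion_order(q):
    genes = list(q.gene_ids)
    removed = []
    frame = q.data
    while len(genes) > 2:
        m = naive_m(RelativeQuantityMatrix(frame.loc[genes]))
        worst = max(m.values())
        victim = sorted(g for g in genes if m[g] == worst)[-1]
        removed.append(victim)
        genes.remove(victim)
    return removed, sorted(genes)


def naive_v(q, ranking, n):
    sub = q.data.loc[list(ranking[: n + 1])].to_numpy()
    nf_n = np.prod(sub[:n], axis=0) ** (1 / n)
    nf_n1 = np.prod(sub, axis=0) ** (1 / (n + 1))
    return float(np.std(np.log2(nf_n / nf_n1), ddof=1))


class TestRelativeQuantities:
    def test_powers_of_two(self):
        q = to_relative_quantities(make_ct([[20, 21, 22]]))
        np.testing.assert_allclose(q.values, [[1, 0.5, 0.25]])

    def test_constant_gene_all_ones(self):
        q = to_relative_quantities(make_ct([[25, 25, 25]]))
        np.testing.assert_allclose(q.values, 1.0)

    def test_custom_efficiency(self):
        q = to_relative_quantities(make_ct([[20, 21, 22]]), efficiencies=1.9)
        np.testing.assert_allclose(q.values, [[1, 1 / 1.9, 1 / 1.9 ** 2]],
                                   rtol=1e-12)

    def test_row_maximum_is_one_at_min_ct(self, rng):
        q = to_relative_quantities(random_ct(rng, 6, 9))
        np.testing.assert_allclose(q.values.max(axis=1), 1.0, rtol=1e-12)
        assert (q.values > 0).all()

    def test_efficiency_at_most_one_rejected(self):
        with pytest.raises(ParameterError):
            to_relative_quantities(make_ct([[20, 21]]), efficiencies=1.0)

    def test_per_gene_efficiency_mapping(self):
        ct = make_ct([[20, 21], [20, 21]], genes=["A", "B"])
        q = to_relative_quantities(ct, {"A": 4.0})  # B defaults to 2.0
        np.testing.assert_allclose(q.values, [[1, 0.25], [1, 0.5]])


class TestGenormM:
    def test_hand_computed_abc(self):
        m = genorm_m(q_from_rows(ABC))
        np.testing.assert_allclose(
            m[["A", "B", "C"]], [0.28867513, 0.28867513, 0.57735027],
            atol=1e-8,
        )

    def test_proportional_genes_have_zero_m(self):
        m = genorm_m(q_from_rows([[1, 0.5, 0.25], [0.8, 0.4, 0.2]]))
        np.testing.assert_allclose(m, 0.0, atol=1e-12)

    def test_equals_delta_ct_pair_structure_at_e2(self, rng):
        ct = random_ct(rng, 7, 12)
        m = genorm_m(to_relative_quantities(ct))
        np.testing.assert_allclose(
            m.to_numpy(), delta_ct_stability(ct).values.to_numpy(),
            atol=1e-10,
        )

    def test_matches_naive_on_random(self, rng):
        for _ in range(5):
            q = to_relative_quantities(random_ct(rng, 5, 10))
            m = genorm_m(q)
            naive = naive_m(q)
            for g in q.gene_ids:
                assert m[g] == pytest.approx(naive[g], rel=1e-12)

    def test_invariant_to_sample_and_gene_scaling(self, rng):
        q = to_relative_quantities(random_ct(rng, 5, 8))
        scaled = q.data * rng.uniform(0.5, 2.0, size=q.data.shape[1])
        scaled = scaled.mul(
            rng.uniform(0.5, 2.0, size=q.data.shape[0]), axis=0
        )
        np.testing.assert_allclose(
            genorm_m(q).to_numpy(),
            genorm_m(RelativeQuantityMatrix(scaled)).to_numpy(),
            rtol=1e-9,
        )

    def test_single_gene_rejected(self):
        with pytest.raises(InsufficientDataError):
            genorm_m(q_from_rows([[1, 0.5]]))


class TestGenormRank:
    def test_worst_gene_removed_first(self):
        result = genorm_rank(q_from_rows(ABC))
        assert result.ranking == ["A", "B", "C"]
        assert result.exclusion_trace.loc[1, "C"] == pytest.approx(0.57735027)
        # round 2: only the final pair carries an M value
        assert np.isnan(result.exclusion_trace.loc[2, "C"])

    def test_matches_naive_exclusion_order(self, rng):
        for _ in range(5):
            q = to_relative_quantities(random_ct(rng, 6, 20))
            result = genorm_rank(q)
            removed, pair = naive_exclusion_order(q)
            assert result.ranking == pair + removed[::-1]

    def test_ranking_invariant_to_gene_input_order(self, rng):
        ct = random_ct(rng, 6, 10)
        q = to_relative_quantities(ct)
        shuffled = RelativeQuantityMatrix(q.data.iloc[::-1])
        assert genorm_rank(q).ranking == genorm_rank(shuffled).ranking

    def test_two_genes_rejected(self):
        with pytest.raises(InsufficientDataError):
            genorm_rank(q_from_rows([[1, 0.5], [1, 0.5]]))

    def test_stability_result_rank_policy(self, rng):
        q = to_relative_quantities(random_ct(rng, 5, 10))
        tied = genorm_stability(q, tied_pair=True)
        seq = genorm_stability(q, tied_pair=False)
        ranking = tied.detail.ranking
        assert tied.ranks[ranking[0]] == tied.ranks[ranking[1]] == 1
        assert tied.ranks[ranking[2]] == 3
        assert sorted(seq.ranks) == list(range(1, 6))


class TestVSeriesAndOptimalN:
    def test_hand_computed_v23(self):
        q = q_from_rows(ABC)
        v = genorm_v_series(q, ["A", "B", "C"])
        assert v[2] == pytest.approx(0.19245009, abs=1e-8)

    def test_identical_rows_give_zero_v(self):
        q = q_from_rows([[1, 0.5, 0.25]] * 4)
        v = genorm_v_series(q, ["A", "B", "C", "D"])
        assert all(val == pytest.approx(0.0, abs=1e-12) for val in v.values())

    def test_matches_naive_on_random(self, rng):
        for _ in range(5):
            q = to_relative_quantities(random_ct(rng, 5, 10))
            ranking = genorm_rank(q).ranking
            v = genorm_v_series(q, ranking)
            for n in range(2, 5):
                assert v[n] == pytest.approx(naive_v(q, ranking, n), rel=1e-10)

    @pytest.mark.parametrize(
        "series,expected",
        [({2: 0.12, 3: 0.10}, 2),
         ({2: 0.20, 3: 0.14, 4: 0.13}, 3),
         ({2: 0.20, 3: 0.18}, UNDETERMINED)],
    )
    def test_optimal_count_rule(self, series, expected):
        assert optimal_rg_count(series) == expected

    def test_empty_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            optimal_rg_count({})
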