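import itertools

import numpy as np
import pandas as pd
import pytest

from genefam.dormancy import (ExpressionMatrix, classify_candidates,
                              ddct_mean_se, ddct_relative_expression,
                              germination_index, germination_rate,
                              prepare_heatmap, read_germination_table)
from genefam.synthetic import simulate_expression, simulate_germination


class TestGerminationStatistics:
    @pytest.mark.parametrize(
        "counts, gi",
        [((50, 0, 0, 50), 1.0), ((0, 0, 50, 50), 1 / 3), ((0, 0, 0, 50), 0.0),
         ((10, 10, 10, 50), (30 + 20 + 10) / 150)],
    )
    def test_index_values(self, counts, gi):
        assert germination_index(*counts) == pytest.approx(gi)

    @pytest.mark.parametrize(
        "counts, gr", [((49, 0, 0, 50), 98.0), ((0, 0, 0, 50), 0.0)]
    )
    def test_rate_values(self, counts, gr):
        assert germination_rate(*counts) == pytest.approx(gr)

    @pytest.mark.parametrize(
        "counts", [(0, 0, 0, 0), (30, 30, 0, 50), (-1, 0, 0, 50)]
    )
    def test_invalid_counts_rejected(self, counts):
        with pytest.raises(ValueError):
            germination_index(*counts)
        with pytest.raises(ValueError):
            germination_rate(*counts)

    def test_exhaustive_small_inputs(self):
        """GI stays in [0,1], is bounded by GR/100, and strictly increases
        when one germination event moves to an earlier day."""
        N = 6
        for n1, n2, n3 in itertools.product(range(N + 1), repeat=3):
            if n1 + n2 + n3 > N:
                continue
            gi = germination_index(n1, n2, n3, N)
            assert 0.0 <= gi <= 1.0
            assert gi <= germination_rate(n1, n2, n3, N) / 100 + 1e-12
            if n2 > 0:
                assert germination_index(n1 + 1, n2 - 1, n3, N) > gi
            if n3 > 0:
                assert germination_index(n1, n2 + 1, n3 - 1, N) > gi

    def test_table_round_trip(self, tmp_path):
        records, _ = simulate_germination([("J411", "low")], seed=1)
        path = tmp_path / "germ.tsv"
        with open(path, "w") as fh:
            fh.write("variety\treplicate\tn1\tn2\tn3\tN\n")
            for r in records:
                fh.write(f"{r.variety}\t{r.replicate}\t{r.n1}\t{r.n2}\t"
                         f"{r.n3}\t{r.N}\n")
        assert read_germination_table(path) == records


class TestRelativeExpression:
    @pytest.mark.parametrize(
        "ddct, fold", [(0.0, 1.0), (-1.0, 2.0), (3.3219, 0.1)]
    )
    def test_fold_change(self, ddct, fold):
        # build Ct values realizing the requested ΔΔCt
        got = ddct_relative_expression(20.0 + ddct, 20.0, 18.0, 18.0)
        assert got == pytest.approx(fold, abs=1e-4)

    def test_missing_ct_rejected(self):
        with pytest.raises(ValueError):
            ddct_relative_expression(float("nan"), 20.0, 18.0, 18.0)

    def test_replicate_mean_and_se(self):
        mean, se = ddct_mean_se([20.0, 21.0], [20.0, 20.0], 18.0, 18.0)
        assert mean == pytest.approx((1.0 + 0.5) / 2)
        assert se > 0
        _, se0 = ddct_mean_se([20.0], [20.0], 18.0, 18.0)
        assert se0 == 0.0


def _tiny_matrix():
    values = pd.DataFrame(
        {
            "vL_T0_r1": [10.0, 1.0], "vL_T6_r1": [12.0, 1.0],
            "vH_T0_r1": [2.0, 1.0], "vH_T6_r1": [3.0, 1.0],
        },
        index=["up_low", "flat"],
    )
    meta = pd.DataFrame(
        {
            "variety": ["vL", "vL", "vH", "vH"],
            "timepoint": [0, 6, 0, 6],
            "dormancy_class": ["low", "low", "high", "high"],
            "replicate": [1, 1, 1, 1],
        },
        index=values.columns,
    )
    return ExpressionMatrix(values=values, metadata=meta)


class TestHeatmapPreparation:
    def test_rows_are_z_scored(self):
        matrix, _ = simulate_expression(n_genes=12, n_low_direction=2,
                                        n_high_direction=2, seed=5)
        hm = prepare_heatmap(matrix)
        z = hm.values.values
        nonconst = z.std(axis=1) > 0
        assert np.allclose(z[nonconst].mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z[nonconst].std(axis=1), 1, atol=1e-9)

    def test_constant_row_maps_to_zero(self):
        matrix = _tiny_matrix()
        hm = prepare_heatmap(matrix)
        assert np.allclose(hm.values.loc["flat"], 0.0)

    def test_duplicated_column_is_adjacent(self):
        matrix, _ = simulate_expression(n_genes=20, n_low_direction=3,
                                        n_high_direction=3, seed=6)
        values = matrix.values.copy()
        values["dup_of_first"] = values.iloc[:, 0]
        meta = matrix.metadata.copy()
        meta.loc["dup_of_first"] = meta.iloc[0]
        hm = prepare_heatmap(ExpressionMatrix(values=values, metadata=meta))
        order = hm.col_order
        i = order.index("dup_of_first")
        first = matrix.values.columns[0]
        assert first in (order[i - 1] if i else None,
                         order[i + 1] if i + 1 < len(order) else None)

    def test_planted_blocks_contiguous(self):
        """Two gene groups with opposite strong profiles cluster apart."""
        rng = np.random.default_rng(0)
        a = {f"a{i}": [100, 100, 1, 1] for i in range(4)}
        b = {f"b{i}": [1, 1, 100, 100] for i in range(4)}
        values = pd.DataFrame({**a, **b}).T
        values.columns = ["s1", "s2", "s3", "s4"]
        values += rng.uniform(0, 0.1, values.shape)
        meta = pd.DataFrame(
            {"variety": ["v"] * 4, "timepoint": [0, 0, 6, 6],
             "dormancy_class": ["low", "low", "high", "high"],
             "replicate": [1, 2, 1, 2]},
            index=values.columns,
        )
        hm = prepare_heatmap(ExpressionMatrix(values=values, metadata=meta))
        labels = ["a" if g.startswith("a") else "b" for g in hm.row_order]
        # one contiguous block each
        assert labels == sorted(labels) or labels == sorted(labels, reverse=True)


class TestCandidateClassifier:
    def test_shifted_gene_called_higher_in_low(self):
        calls = {c.gene_id: c.direction
                 for c in classify_candidates(_tiny_matrix())}
        assert calls["up_low"] == "higher_in_low_dormancy"
        assert calls["flat"] == "none"

    def test_crossing_profiles_are_none(self):
        values = pd.DataFrame(
            {"vL_T0_r1": [10.0], "vL_T6_r1": [1.0],
             "vH_T0_r1": [1.0], "vH_T6_r1": [10.0]},
            index=["crossing"],
        )
        meta = _tiny_matrix().metadata
        calls = classify_candidates(
            ExpressionMatrix(values=values, metadata=meta)
        )
        assert calls[0].direction == "none"

    def test_planted_direction_counts_recovered(self):
        matrix, truth = simulate_expression(seed=21)
        calls = classify_candidates(matrix)
        directions = [c.direction for c in calls]
        assert directions.count("higher_in_low_dormancy") == 13
        assert directions.count("higher_in_high_dormancy") == 8
        assert directions.count("none") == 44
        for c in calls:
            assert truth.facts["directions"][c.gene_id] == c.direction

    def test_column_permutation_invariance(self):
        matrix, _ = simulate_expression(n_genes=20, n_low_direction=4,
                                        n_high_direction=2, seed=9)
        rng = np.random.default_rng(1)
        cols = list(matrix.values.columns)
        rng.shuffle(cols)
        permuted = ExpressionMatrix(
            values=matrix.values[cols], metadata=matrix.metadata
        )
        assert classify_candidates(matrix) == classify_candidates(permuted)

    def test_missing_class_error(self):
        m = _tiny_matrix()
        low_only = m.values[["vL_T0_r1", "vL_T6_r1"]]
        with pytest.raises(ValueError):
            classify_candidates(
                ExpressionMatrix(values=low_only, metadata=m.metadata)
            )
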