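"""Differential expression: fold change, Welch test, BH, ddCt, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ruminet.diffexpr import (
    QpcrMeasurement,
    SampleDesign,
    adjust_fdr,
    cluster_order,
    ddct_fold_change,
    differential_table,
    log2_fold_change,
    select_degs,
)
from ruminet.diffexpr import test_differential as differential_pvalues
from ruminet.simulate import SimulationConfig, generate_dataset


def bh_stepup_oracle(p):
    """Textbook Benjamini-Hochberg step-up, written independently: sort the
    p-values, scale the i-th smallest by m/i, then enforce monotonicity from
    the largest down."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        adj[idx] = running_min
    return adj


class TestFoldChange:
    def test_group_mean_difference(self, tiny_matrix):
        matrix, design = tiny_matrix
        lfc = log2_fold_change(matrix, design)
        assert lfc["g1"] == pytest.approx(2.0)
        assert lfc["g2"] == pytest.approx(0.0)
        assert lfc["g3"] == pytest.approx(-1.5)

    def test_noiseless_planted_gene_recovers_exact_log2fc(self):
        cfg = SimulationConfig(seed=2, n_genes=50, de_fraction=0.2, noise_sd=0.0)
        matrix, design, truth = generate_dataset(cfg)
        lfc = log2_fold_change(matrix, design)
        for gene, planted in truth.de_genes.items():
            assert lfc[gene] == pytest.approx(planted, abs=1e-9)

    def test_fold_change_column_is_linear_scale(self, tiny_matrix):
        matrix, design = tiny_matrix
        table = differential_table(matrix, design)
        assert table.loc["g1", "fold_change"] == pytest.approx(4.0)
        assert table.loc["g2", "fold_change"] == pytest.approx(1.0)
        assert (table["fold_change"] >= 1.0).all()


class TestWelch:
    def test_identical_groups_give_p_one(self):
        samples = ["a1", "a2", "b1", "b2"]
        matrix = pd.DataFrame([[1.0, 2.0, 1.0, 2.0]], index=["g"], columns=samples)
        design = SampleDesign({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert differential_pvalues(matrix, design)["g"] == pytest.approx(1.0)

    def test_degenerate_zero_variance_rows(self):
        samples = ["a1", "a2", "b1", "b2"]
        matrix = pd.DataFrame(
            [[5.0, 5.0, 5.0, 5.0], [5.0, 5.0, 9.0, 9.0]],
            index=["flat", "shifted"], columns=samples,
        )
        design = SampleDesign({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        p = differential_pvalues(matrix, design)
        assert p["flat"] == 1.0
        assert p["shifted"] == 0.0

    def test_label_swap_symmetry(self, small_dataset):
        _, (matrix, design, _) = small_dataset
        swapped = SampleDesign(
            dict(design.items()), reference=design.condition_b
        )
        p1 = differential_pvalues(matrix, design)
        p2 = differential_pvalues(matrix, swapped)
        np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy(), rtol=1e-12)

    def test_planted_effect_with_tiny_noise_is_significant(self):
        cfg = SimulationConfig(seed=6, n_genes=100, de_fraction=0.1, noise_sd=0.01)
        matrix, design, truth = generate_dataset(cfg)
        p = differential_pvalues(matrix, design)
        assert (p[sorted(truth.de_genes)] < 1e-3).all()


class TestAdjustFdr:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            adjust_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_edge_cases(self):
        assert adjust_fdr([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(adjust_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            adjust_fdr([-0.1])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1, max_size=20,
        )
    )
    def test_matches_stepup_oracle(self, p):
        np.testing.assert_allclose(adjust_fdr(p), bh_stepup_oracle(p), atol=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1, max_size=20,
        )
    )
    def test_adjusted_at_least_raw_and_bounded(self, p):
        adj = adjust_fdr(p)
        assert (adj >= np.asarray(p) - 1e-15).all()
        assert (adj <= 1.0).all()


class TestSelection:
    def _record(self, fc, fdr, p=0.001, lfc=None):
        lfc = np.log2(fc) if lfc is None else lfc
        return pd.DataFrame(
            {"log2fc": [lfc], "fold_change": [fc], "p_raw": [p], "fdr": [fdr],
             "direction": ["up" if lfc >= 0 else "down"]},
            index=["g"],
        )

    def test_gates(self):
        assert select_degs(self._record(4.0, 0.01))["selected"].iloc[0]
        assert not select_degs(self._record(1.9, 0.001))["selected"].iloc[0]
        assert not select_degs(self._record(4.0, 0.2))["selected"].iloc[0]
        assert not select_degs(
            self._record(4.0, 0.01, p=0.05), p_threshold=0.01
        )["selected"].iloc[0]

    def test_planted_degs_recovered_with_signs(self):
        cfg = SimulationConfig(seed=13, n_genes=2000, de_fraction=0.075,
                               noise_sd=0.05)
        matrix, design, truth = generate_dataset(cfg)
        table = differential_table(matrix, design)
        selected = set(table.index[table["selected"]])
        assert selected == set(truth.de_genes)
        for gene, planted in truth.de_genes.items():
            expected = "up" if planted > 0 else "down"
            assert table.loc[gene, "direction"] == expected


class TestDdct:
    @pytest.mark.parametrize(
        "cts, expected",
        [
            ((20.0, 15.0, 20.0, 15.0), 1.0),   # ddCt = 0
            ((19.0, 15.0, 20.0, 15.0), 2.0),   # ddCt = -1, one-cycle doubling
            ((20.0, 15.0, 22.0, 15.0), 4.0),   # ddCt = -2
            ((22.0, 15.0, 20.0, 15.0), 0.25),  # ddCt = +2
        ],
    )
    def test_relative_expression(self, cts, expected):
        m = QpcrMeasurement(*cts)
        assert ddct_fold_change(m) == pytest.approx(expected)

    def test_nonfinite_ct_rejected(self):
        with pytest.raises(ValueError, match="ct_target_treated"):
            QpcrMeasurement(float("nan"), 15.0, 20.0, 15.0)


class TestClusterOrder:
    def test_output_is_permutation(self, small_dataset):
        _, (matrix, _, _) = small_dataset
        genes, samples = cluster_order(matrix)
        assert sorted(genes) == sorted(matrix.index)
        assert sorted(samples) == sorted(matrix.columns)

    def test_identical_rows_adjacent(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(6, 5))
        values[4] = values[1]  # row "e" duplicates row "b"
        matrix = pd.DataFrame(values, index=list("abcdez"), columns=range(5))
        genes, _ = cluster_order(matrix)
        assert abs(genes.index("b") - genes.index("e")) == 1

    def test_anticorrelated_modules_form_contiguous_blocks(self):
        rng = np.random.default_rng(1)
        latent = rng.normal(size=8)
        rows = {}
        for i in range(4):
            rows[f"p{i}"] = latent + rng.normal(0, 0.01, 8)
        for i in range(4):
            rows[f"n{i}"] = -latent + rng.normal(0, 0.01, 8)
        matrix = pd.DataFrame(rows).T
        genes, _ = cluster_order(matrix)
        labels = ["p" if g.startswith("p") else "n" for g in genes]
        switches = sum(a != b for a, b in zip(labels, labels[1:]))
        assert switches == 1

    def test_single_gene_identity(self):
        matrix = pd.DataFrame([[1.0, 2.0, 3.0]], index=["only"], columns=list("xyz"))
        genes, _ = cluster_order(matrix)
        assert genes == ["only"]

    def test_deterministic(self, small_dataset):
        _, (matrix, _, _) = small_dataset
        assert cluster_order(matrix) == cluster_order(matrix)
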