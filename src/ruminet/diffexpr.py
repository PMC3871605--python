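"""Differential expression on a two-condition log2 expression matrix.

Genes are called differential by a fold-change gate combined with a
Benjamini-Hochberg FDR gate on per-gene Welch t-test p-values, mirroring
the common microarray workflow of selecting probes with a 2-fold difference
at FDR < 5% (or 10%).  The per-gene test is pluggable so that an exact
permutation test can substitute at very small n.  A 2^-ddCt helper covers
relative qPCR quantification, and ``cluster_order`` produces the
deterministic gene/sample ordering used for heatmap-style reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SampleDesign",
    "QpcrMeasurement",
    "log2_fold_change",
    "test_differential",
    "adjust_fdr",
    "differential_table",
    "select_degs",
    "ddct_fold_change",
    "cluster_order",
]


class SampleDesign:
    """Assignment of samples to exactly two condition labels.

    The first label encountered (or the explicit ``reference``) is condition
    A, the baseline of every contrast; log2 fold changes are condition B
    minus condition A.
    """

    def __init__(self, labels: Mapping[str, str], reference: str | None = None):
        self._labels = dict(labels)
        conditions = list(dict.fromkeys(self._labels.values()))
        if len(conditions) != 2:
            raise ValueError(
                f"SampleDesign requires exactly two condition labels, got {conditions}"
            )
        if reference is not None:
            if reference not in conditions:
                raise ValueError(f"reference {reference!r} not among {conditions}")
            conditions = [reference] + [c for c in conditions if c != reference]
        self.condition_a, self.condition_b = conditions
        for cond in conditions:
            if len(self.samples(cond)) < 2:
                raise ValueError(f"condition {cond!r} has fewer than 2 samples")

    def __getitem__(self, sample: str) -> str:
        return self._labels[sample]

    def __len__(self) -> int:
        return len(self._labels)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SampleDesign)
            and self._labels == other._labels
            and self.condition_a == other.condition_a
        )

    @property
    def samples_all(self) -> list[str]:
        return list(self._labels)

    @property
    def conditions(self) -> tuple[str, str]:
        return (self.condition_a, self.condition_b)

    def samples(self, condition: str) -> list[str]:
        return [s for s, c in self._labels.items() if c == condition]

    def items(self):
        return self._labels.items()


@dataclass(frozen=True)
class QpcrMeasurement:
    """Cycle thresholds for one 2^-ddCt comparison.

    The target gene is normalized against a reference gene (e.g. beta-actin)
    in both the treated and the control sample.
    """

    ct_target_treated: float
    ct_reference_treated: float
    ct_target_control: float
    ct_reference_control: float

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")


def _split(matrix: pd.DataFrame, design: SampleDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    a = design.samples(design.condition_a)
    b = design.samples(design.condition_b)
    if not a:
        raise ValueError(f"condition {design.condition_a!r} has no samples in matrix")
    if not b:
        raise ValueError(f"condition {design.condition_b!r} has no samples in matrix")
    missing = [s for s in a + b if s not in matrix.columns]
    if missing:
        raise ValueError(f"design samples missing from matrix: {missing}")
    return matrix[a], matrix[b]


def log2_fold_change(matrix: pd.DataFrame, design: SampleDesign) -> pd.Series:
    """Per-gene log2 fold change: mean(condition B) - mean(condition A)."""
    xa, xb = _split(matrix, design)
    return (xb.mean(axis=1) - xa.mean(axis=1)).rename("log2fc")


def welch_p(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Row-wise Welch two-sample t-test p-values.

    Degenerate rows (zero variance in both groups) get p = 1 when the group
    means agree and p = 0 when they differ: no within-group noise makes any
    mean difference unambiguous.
    """
    res = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        same = np.isclose(xa.mean(axis=1), xb.mean(axis=1))
        p[degenerate & same] = 1.0
        p[degenerate & ~same] = 0.0
    return p


def test_differential(
    matrix: pd.DataFrame,
    design: SampleDesign,
    test: Callable[[np.ndarray, np.ndarray], np.ndarray] = welch_p,
) -> pd.Series:
    """Per-gene two-sample p-values (Welch's t-test by default)."""
    xa, xb = _split(matrix, design)
    if xa.shape[1] < 2 or xb.shape[1] < 2:
        raise ValueError("each condition needs >= 2 samples for a two-sample test")
    p = test(xa.to_numpy(), xb.to_numpy())
    return pd.Series(p, index=matrix.index, name="p_raw")


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_table(
    matrix: pd.DataFrame,
    design: SampleDesign,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    p_threshold: float | None = None,
    test: Callable[[np.ndarray, np.ndarray], np.ndarray] = welch_p,
) -> pd.DataFrame:
    """Full per-gene differential table with the selection flag applied.

    Columns: gene (index), log2fc, fold_change (2^|log2fc|, linear scale),
    p_raw, fdr, direction (up/down by sign of log2fc), selected.
    """
    lfc = log2_fold_change(matrix, design)
    p = test_differential(matrix, design, test=test)
    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "fold_change": np.exp2(np.abs(lfc)),
            "p_raw": p,
            "fdr": adjust_fdr(p.to_numpy()),
        }
    )
    table["direction"] = np.where(table["log2fc"] >= 0, "up", "down")
    return select_degs(
        table,
        fc_threshold=fc_threshold,
        fdr_threshold=fdr_threshold,
        p_threshold=p_threshold,
    )


def select_degs(
    records: pd.DataFrame,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    p_threshold: float | None = None,
) -> pd.DataFrame:
    """Apply the DEG gates: FC >= fc_threshold AND fdr < fdr_threshold
    AND (p_raw < p_threshold when given).  Returns the table with the
    ``selected`` column set."""
    out = records.copy()
    sel = (out["fold_change"] >= fc_threshold) & (out["fdr"] < fdr_threshold)
    if p_threshold is not None:
        sel &= out["p_raw"] < p_threshold
    out["selected"] = sel
    return out


def ddct_fold_change(m: QpcrMeasurement) -> float:
    """Relative expression 2^-ddCt.

    ddCt = (Ct_target - Ct_reference)_treated - (Ct_target - Ct_reference)_control.
    """
    ddct = (m.ct_target_treated - m.ct_reference_treated) - (
        m.ct_target_control - m.ct_reference_control
    )
    return float(2.0 ** (-ddct))


def _leaf_order(values: np.ndarray) -> np.ndarray:
    """Average-linkage leaf order under 1 - Pearson distance over rows."""
    if values.shape[0] < 2:
        return np.arange(values.shape[0])
    sd = values.std(axis=1)
    corr = np.corrcoef(values)
    # zero-variance rows have undefined r; treat them as uncorrelated
    corr[~np.isfinite(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    dist[sd == 0, :] = 1.0
    dist[:, sd == 0] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return hierarchy.leaves_list(link)


def cluster_order(matrix: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Deterministic hierarchical ordering of genes and samples.

    Average linkage on 1 - Pearson correlation, ties resolved by input
    order (SciPy's deterministic linkage).  Returns (gene_order,
    sample_order), each a permutation of the input identifiers.
    """
    gene_idx = _leaf_order(matrix.to_numpy())
    sample_idx = _leaf_order(matrix.to_numpy().T)
    return (
        [matrix.index[i] for i in gene_idx],
        [matrix.columns[i] for i in sample_idx],
    )
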