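"""Category (GO-style) enrichment of a selected gene list.

Each category with at least one background gene yields a 2x2 table

    =============  ========  ============
                   flagged   not flagged
    in category    nf        n - nf
    outside        Nf - nf   N - n - Nf + nf
    =============  ========  ============

scored by a two-sided Fisher exact test (minimum-likelihood convention)
and a Pearson chi-square test without continuity correction.  Two error
controls are reported side by side:

* the empirical FDR ``1 - Nk/T``, where Nk counts categories whose Fisher
  p is below their chi-square p among the T categories tested — a single
  global quantity attached to every record;
* Benjamini-Hochberg over the Fisher p-values, the practical per-category
  correction.

The enrichment ratio Re = (nf/n) / (Nf/N) measures how over-represented
flagged genes are inside the category relative to the whole background.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import adjust_fdr

__all__ = [
    "fisher_two_sided",
    "chi_square_p",
    "enrichment_ratio",
    "empirical_fdr",
    "enrich",
]


def _check_counts(nf: int, n: int, Nf: int, N: int) -> None:
    for name, v in (("nf", nf), ("n", n), ("Nf", Nf), ("N", N)):
        if v < 0 or v != int(v):
            raise ValueError(f"count {name} must be a non-negative integer, got {v}")
    if nf > n:
        raise ValueError(f"inconsistent counts: nf={nf} > n={n}")
    if nf > Nf:
        raise ValueError(f"inconsistent counts: nf={nf} > Nf={Nf}")
    if n > N:
        raise ValueError(f"inconsistent counts: n={n} > N={N}")
    if Nf > N:
        raise ValueError(f"inconsistent counts: Nf={Nf} > N={N}")
    if Nf - nf > N - n:
        raise ValueError(
            f"inconsistent counts: Nf-nf={Nf - nf} exceeds background outside "
            f"category N-n={N - n}"
        )


def fisher_two_sided(nf: int, n: int, Nf: int, N: int) -> float:
    """Two-sided Fisher exact p for the category 2x2 table.

    With margins fixed, the in-category flagged count X is hypergeometric
    (N, Nf, n); the two-sided p sums P(X = x) over every outcome whose
    probability does not exceed that of the observed table (the
    minimum-likelihood convention, as in SciPy/R).  Degenerate tables with
    an empty margin carry no information and return 1.
    """
    _check_counts(nf, n, Nf, N)
    if n == 0 or Nf == 0 or n == N or Nf == N:
        return 1.0
    support = np.arange(max(0, n + Nf - N), min(n, Nf) + 1)
    pmf = stats.hypergeom.pmf(support, N, Nf, n)
    observed = stats.hypergeom.pmf(nf, N, Nf, n)
    # tolerance guards against ties lost to floating point
    p = float(pmf[pmf <= observed * (1 + 1e-9)].sum())
    return min(p, 1.0)


def chi_square_p(nf: int, n: int, Nf: int, N: int) -> float:
    """Pearson chi-square p (1 df, no continuity correction) on the 2x2 table.

    A zero row or column margin leaves the statistic undefined; by
    convention p = 1 (no information).
    """
    _check_counts(nf, n, Nf, N)
    table = np.array([[nf, n - nf], [Nf - nf, N - n - Nf + nf]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    stat = stats.chi2_contingency(table, correction=False)[0]
    return float(stats.chi2.sf(stat, df=1))


def enrichment_ratio(nf: int, n: int, Nf: int, N: int) -> float:
    """Enrichment ratio Re = (nf/n) / (Nf/N)."""
    _check_counts(nf, n, Nf, N)
    for name, v in (("n", n), ("Nf", Nf), ("N", N)):
        if v == 0:
            raise ValueError(f"enrichment_ratio undefined: count {name} is zero")
    return (nf / n) / (Nf / N)


def empirical_fdr(p_fisher, p_chi2) -> float:
    """Global empirical FDR 1 - Nk/T.

    Nk counts the categories whose Fisher p is strictly below the paired
    chi-square p among the T categories tested.  The exact test is the more
    conservative reference; categories where the asymptotic chi-square p
    undercuts it are counted as potential false discoveries.
    """
    pf = np.asarray(p_fisher, dtype=float)
    pc = np.asarray(p_chi2, dtype=float)
    if pf.shape != pc.shape:
        raise ValueError("p_fisher and p_chi2 must have equal length")
    T = pf.size
    if T == 0:
        raise ValueError("empirical_fdr requires at least one record")
    Nk = int((pf < pc).sum())
    return 1.0 - Nk / T


def enrich(
    selected_genes: Iterable[str],
    annotation: Mapping[str, Iterable[str]] | pd.DataFrame,
    background_genes: Iterable[str],
) -> pd.DataFrame:
    """Score every annotated category against the selected gene list.

    Parameters
    ----------
    selected_genes : flagged genes (e.g. the DEG list); must all belong to
        the background.
    annotation : gene -> categories mapping, or a two-column DataFrame
        (gene, category).
    background_genes : the gene universe N; by convention the annotated
        genes of the expression matrix, configurable to all matrix genes.

    Returns
    -------
    DataFrame indexed by category with columns nf, n, Nf, N, p_fisher,
    p_chi2, fdr_empirical (global scalar repeated), fdr_bh, re, sorted by
    ascending p_fisher then category id.  Only categories intersecting the
    background are scored.
    """
    background = set(background_genes)
    selected = set(selected_genes)
    offenders = sorted(selected - background)
    if offenders:
        raise ValueError(f"selected genes absent from background: {offenders}")

    if isinstance(annotation, pd.DataFrame):
        pairs = annotation.iloc[:, :2].itertuples(index=False)
        gene2cats: dict[str, set[str]] = {}
        for gene, cat in pairs:
            gene2cats.setdefault(str(gene), set()).add(str(cat))
    else:
        gene2cats = {g: set(cs) for g, cs in annotation.items()}

    cat2genes: dict[str, set[str]] = {}
    for gene, cats in gene2cats.items():
        if gene not in background:
            continue
        for cat in cats:
            cat2genes.setdefault(cat, set()).add(gene)

    N = len(background)
    Nf = len(selected)
    rows = []
    for cat, genes in cat2genes.items():
        n = len(genes)
        nf = len(genes & selected)
        re = (nf / n) / (Nf / N) if (n > 0 and Nf > 0 and N > 0) else np.nan
        rows.append(
            {
                "category": cat,
                "nf": nf,
                "n": n,
                "Nf": Nf,
                "N": N,
                "p_fisher": fisher_two_sided(nf, n, Nf, N),
                "p_chi2": chi_square_p(nf, n, Nf, N),
                "re": re,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["nf", "n", "Nf", "N", "p_fisher", "p_chi2",
                     "fdr_empirical", "fdr_bh", "re"]
        ).rename_axis("category")

    table = pd.DataFrame(rows).set_index("category")
    table["fdr_empirical"] = empirical_fdr(table["p_fisher"], table["p_chi2"])
    table["fdr_bh"] = adjust_fdr(table["p_fisher"].to_numpy())
    table = (
        table.reset_index()
        .sort_values(["p_fisher", "category"], kind="mergesort")
        .set_index("category")
    )
    return table[
        ["nf", "n", "Nf", "N", "p_fisher", "p_chi2", "fdr_empirical", "fdr_bh", "re"]
    ]
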