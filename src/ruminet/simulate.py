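"""Synthetic two-condition expression data with planted structure.

Generates gene-by-sample log2 intensity matrices that mimic a small
two-group microarray contrast (a low- vs high-concentrate feeding trial
with 3 and 4 animals per group), together with the ground truth needed to
test every downstream stage:

* planted differentially expressed genes at a controllable log2 fold change,
* planted co-expression modules driven by a shared latent factor, tight
  enough to exercise a |r| > 0.999 edge rule when the residual noise is zero,
* category annotations that can over-sample the planted DE set, giving
  enrichment tests a known positive.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
child streams, so identical configurations reproduce byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .diffexpr import SampleDesign

__all__ = [
    "ModuleSpec",
    "SimulationConfig",
    "TruthTable",
    "generate_dataset",
    "generate_annotation",
]

CONDITION_A = "LC"
CONDITION_B = "HC"


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-expression module.

    Every member gene is an affine image of one latent factor per sample
    (loading +1 or -1, chosen at random) plus independent Gaussian residual
    noise.  With ``residual_sd == 0`` all within-module pairwise Pearson
    correlations are exactly +/-1 in any condition where the factor is
    active.  ``condition_specific`` restricts the factor to one condition;
    in the inactive condition members receive independent noise of the same
    scale, so the module contributes degree only to one network.
    """

    size: int
    latent_sd: float = 1.0
    residual_sd: float = 0.0
    condition_specific: Literal["both", "A_only", "B_only"] = "both"

    def __post_init__(self) -> None:
        if self.size < 3:
            raise ValueError(f"ModuleSpec.size must be >= 3, got {self.size}")
        if self.latent_sd <= 0:
            raise ValueError(f"ModuleSpec.latent_sd must be > 0, got {self.latent_sd}")
        if self.residual_sd < 0:
            raise ValueError(
                f"ModuleSpec.residual_sd must be >= 0, got {self.residual_sd}"
            )
        if self.condition_specific not in ("both", "A_only", "B_only"):
            raise ValueError(
                "ModuleSpec.condition_specific must be 'both', 'A_only' or "
                f"'B_only', got {self.condition_specific!r}"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Defaults reflect the study design this generator emulates: two diet
    groups of 3 (LC) and 4 (HC) animals, log2 intensities centred near 8,
    and a planted shift of log2FC = 2.0 (a 4-fold change, comfortably past
    an FC > 2 selection gate) for differential genes.
    """

    seed: int = 0
    n_genes: int = 2000
    n_samples_a: int = 3
    n_samples_b: int = 4
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    de_fraction: float = 0.05
    de_log2fc: float = 2.0
    noise_sd: float = 0.2
    modules: tuple[ModuleSpec, ...] = ()
    n_categories: int = 50
    category_size_range: tuple[int, int] = (10, 50)
    de_enrichment_boost: float = 1.0
    boosted_fraction: float = 0.1

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_samples_a", "n_samples_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError(
                f"de_fraction must be in [0, 1], got {self.de_fraction}"
            )
        if 0 < self.de_fraction and self.de_fraction * self.n_genes < 1:
            raise ValueError(
                "de_fraction * n_genes must be >= 1 when de_fraction > 0 "
                f"(got {self.de_fraction} * {self.n_genes})"
            )
        if self.de_log2fc <= 0:
            raise ValueError(f"de_log2fc must be positive, got {self.de_log2fc}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_categories < 0:
            raise ValueError(f"n_categories must be >= 0, got {self.n_categories}")
        lo, hi = self.category_size_range
        if not (0 < lo <= hi):
            raise ValueError(
                f"category_size_range must satisfy 0 < lo <= hi, got ({lo}, {hi})"
            )
        if self.de_enrichment_boost < 1:
            raise ValueError(
                f"de_enrichment_boost must be >= 1, got {self.de_enrichment_boost}"
            )
        if not 0.0 <= self.boosted_fraction <= 1.0:
            raise ValueError(
                f"boosted_fraction must be in [0, 1], got {self.boosted_fraction}"
            )
        total_module = sum(m.size for m in self.modules)
        if total_module > self.n_genes:
            raise ValueError(
                f"modules request {total_module} genes but n_genes={self.n_genes}"
            )

    @property
    def n_de(self) -> int:
        return int(round(self.de_fraction * self.n_genes))


@dataclass
class TruthTable:
    """Ground truth of one simulated dataset."""

    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> signed log2FC
    module_membership: dict[str, int] = field(default_factory=dict)
    category_map: dict[str, set[str]] = field(default_factory=dict)
    boosted_categories: set[str] = field(default_factory=set)

    def to_json_dict(self) -> dict:
        return {
            "de_genes": dict(sorted(self.de_genes.items())),
            "module_membership": dict(sorted(self.module_membership.items())),
            "category_map": {
                g: sorted(cats) for g, cats in sorted(self.category_map.items())
            },
            "boosted_categories": sorted(self.boosted_categories),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "TruthTable":
        return cls(
            de_genes={g: float(v) for g, v in d["de_genes"].items()},
            module_membership={g: int(v) for g, v in d["module_membership"].items()},
            category_map={g: set(v) for g, v in d["category_map"].items()},
            boosted_categories=set(d.get("boosted_categories", ())),
        )


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def _sample_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    a = [f"{CONDITION_A}{i + 1}" for i in range(config.n_samples_a)]
    b = [f"{CONDITION_B}{i + 1}" for i in range(config.n_samples_b)]
    return a, b


def generate_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, SampleDesign, TruthTable]:
    """Simulate a log2 expression matrix, its design, and the ground truth.

    Returns
    -------
    matrix : DataFrame, genes x samples, log2 intensities.
    design : SampleDesign mapping samples to the two condition labels
        (condition A = reference).
    truth : TruthTable with planted DE effects, module membership and, after
        :func:`generate_annotation`, the category map.

    Planted DE genes occupy the first ``n_de`` gene slots; condition B is
    shifted by the signed planted log2FC (half up, half down).  Modules are
    allocated preferentially from the planted DE set so that, as in the
    study this emulates, co-expressed modules survive DEG selection and
    enter the per-condition networks; module genes receive latent + residual
    variation in place of the global ``noise_sd`` noise.
    """
    root = np.random.SeedSequence(config.seed)
    ss_baseline, ss_noise, ss_sign, ss_module, ss_ann = root.spawn(5)

    n = config.n_genes
    n_a, n_b = config.n_samples_a, config.n_samples_b
    n_samples = n_a + n_b
    genes = _gene_ids(n)
    samples_a, samples_b = _sample_ids(config)

    rng_base = np.random.default_rng(ss_baseline)
    baseline = rng_base.normal(config.baseline_mean, config.baseline_sd, size=n)

    rng_noise = np.random.default_rng(ss_noise)
    values = baseline[:, None] + rng_noise.normal(
        0.0, config.noise_sd, size=(n, n_samples)
    )

    # planted DE: first n_de genes, alternating-free random signs
    n_de = config.n_de
    rng_sign = np.random.default_rng(ss_sign)
    signs = rng_sign.choice([1.0, -1.0], size=n_de)
    truth = TruthTable()
    for i in range(n_de):
        lfc = signs[i] * config.de_log2fc
        truth.de_genes[genes[i]] = float(lfc)
        values[i, n_a:] += lfc

    # planted modules, drawn from the DE pool first, then the tail genes
    rng_mod = np.random.default_rng(ss_module)
    cursor_de, cursor_free = 0, n - 1
    for m_idx, mod in enumerate(config.modules):
        members: list[int] = []
        while len(members) < mod.size and cursor_de < n_de:
            members.append(cursor_de)
            cursor_de += 1
        while len(members) < mod.size:
            members.append(cursor_free)
            cursor_free -= 1
        loadings = rng_mod.choice([1.0, -1.0], size=mod.size)
        latent = rng_mod.normal(0.0, mod.latent_sd, size=n_samples)
        # independent replacement noise where the factor is inactive
        inactive = rng_mod.normal(0.0, mod.latent_sd, size=(mod.size, n_samples))
        residual = rng_mod.normal(0.0, mod.residual_sd, size=(mod.size, n_samples))
        active = np.ones(n_samples, dtype=bool)
        if mod.condition_specific == "A_only":
            active[n_a:] = False
        elif mod.condition_specific == "B_only":
            active[:n_a] = False
        for row, g in enumerate(members):
            signal = np.where(active, loadings[row] * latent, inactive[row])
            # module variation replaces the global noise for member genes
            values[g] = baseline[g] + signal + residual[row]
            if genes[g] in truth.de_genes:
                values[g, n_a:] += truth.de_genes[genes[g]]
            truth.module_membership[genes[g]] = m_idx

    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                          columns=samples_a + samples_b)
    design = SampleDesign(
        {**{s: CONDITION_A for s in samples_a}, **{s: CONDITION_B for s in samples_b}}
    )

    generate_annotation(truth, config, rng=np.random.default_rng(ss_ann),
                        genes=genes)
    return matrix, design, truth


def generate_annotation(
    truth: TruthTable,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    genes: list[str] | None = None,
) -> dict[str, set[str]]:
    """Draw gene -> category annotations, optionally enriched in DE genes.

    A fraction ``boosted_fraction`` of the ``n_categories`` categories
    over-samples planted DE genes with sampling odds multiplied by
    ``de_enrichment_boost``; at boost 1 membership is independent of DE
    status.  ``math.inf`` is accepted as the limiting boost: boosted
    categories then contain only DE genes (provided enough exist).

    Fills ``truth.category_map`` / ``truth.boosted_categories`` and returns
    the category map.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[4])
    if genes is None:
        genes = _gene_ids(config.n_genes)
    truth.category_map = {}
    truth.boosted_categories = set()
    if config.n_categories == 0:
        return truth.category_map

    de_set = set(truth.de_genes)
    gene_arr = np.array(genes)
    is_de = np.array([g in de_set for g in genes], dtype=float)
    n_boosted = int(round(config.boosted_fraction * config.n_categories))
    lo, hi = config.category_size_range
    width = max(3, len(str(config.n_categories)))

    for c in range(config.n_categories):
        cat = f"CAT{c:0{width}d}"
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(genes))
        boosted = c < n_boosted and config.de_enrichment_boost > 1
        if boosted:
            truth.boosted_categories.add(cat)
            if math.isinf(config.de_enrichment_boost):
                weights = is_de.copy()
                if weights.sum() == 0:
                    weights = np.ones(len(genes))
                size = min(size, int((weights > 0).sum()))
            else:
                weights = np.where(is_de > 0, config.de_enrichment_boost, 1.0)
        else:
            weights = np.ones(len(genes))
        probs = weights / weights.sum()
        members = rng.choice(gene_arr, size=size, replace=False, p=probs)
        for g in members:
            truth.category_map.setdefault(str(g), set()).add(cat)
    return truth.category_map
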