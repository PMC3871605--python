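"""End-to-end orchestration: simulate/load -> DEG -> enrichment -> networks.

``run_pipeline`` chains every stage, writes each artifact as plain text
under the output directory, and records a JSON manifest (parameters, row
counts, SHA-256 checksums of every artifact) so a run is fully
reproducible: identical configuration + seed yields identical checksums.
``render_report`` turns a manifest into a human-readable markdown summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field

from . import __version__, diffexpr, enrichment, io, network
from .simulate import ModuleSpec, SimulationConfig, generate_dataset

logger = logging.getLogger("ruminet")

__all__ = ["RunConfig", "SimulateBlock", "run_pipeline", "render_report", "load_config"]


class ModuleBlock(BaseModel):
    size: int = Field(ge=3)
    latent_sd: float = Field(default=1.0, gt=0)
    residual_sd: float = Field(default=0.0, ge=0)
    condition_specific: str = "both"


class SimulateBlock(BaseModel):
    n_genes: int = Field(default=2000, gt=0)
    n_samples_a: int = Field(default=3, gt=0)
    n_samples_b: int = Field(default=4, gt=0)
    baseline_mean: float = 8.0
    baseline_sd: float = Field(default=2.0, ge=0)
    de_fraction: float = Field(default=0.075, ge=0, le=1)
    de_log2fc: float = Field(default=2.0, gt=0)
    noise_sd: float = Field(default=0.05, ge=0)
    # module latent scale kept well below the planted log2FC so that module
    # genes, which are drawn from the DE pool, still clear the FDR gate
    modules: list[ModuleBlock] = Field(
        default_factory=lambda: [
            ModuleBlock(size=6, latent_sd=0.2, condition_specific="both"),
            ModuleBlock(size=6, latent_sd=0.2, condition_specific="both"),
            ModuleBlock(size=6, latent_sd=0.2, condition_specific="A_only"),
            ModuleBlock(size=6, latent_sd=0.2, condition_specific="B_only"),
        ]
    )
    n_categories: int = Field(default=50, ge=0)
    category_size_range: tuple[int, int] = (10, 50)
    de_enrichment_boost: float = Field(default=20.0, ge=1)
    boosted_fraction: float = Field(default=0.1, ge=0, le=1)

    def to_simulation_config(self, seed: int) -> SimulationConfig:
        return SimulationConfig(
            seed=seed,
            n_genes=self.n_genes,
            n_samples_a=self.n_samples_a,
            n_samples_b=self.n_samples_b,
            baseline_mean=self.baseline_mean,
            baseline_sd=self.baseline_sd,
            de_fraction=self.de_fraction,
            de_log2fc=self.de_log2fc,
            noise_sd=self.noise_sd,
            modules=tuple(
                ModuleSpec(**m.model_dump()) for m in self.modules
            ),
            n_categories=self.n_categories,
            category_size_range=tuple(self.category_size_range),
            de_enrichment_boost=self.de_enrichment_boost,
            boosted_fraction=self.boosted_fraction,
        )


class RunConfig(BaseModel):
    """Validated configuration of one pipeline run.

    Either the three input paths (matrix, design, annotation) are given, or
    a ``simulate`` block describes a synthetic dataset to generate in
    place.  Every stage threshold is explicit: none of the study's gates
    (FC > 2, FDR < 0.05/0.10, p < 0.01, |r| > 0.999) is a hidden constant.
    """

    matrix: Optional[str] = None
    design: Optional[str] = None
    annotation: Optional[str] = None
    simulate: Optional[SimulateBlock] = None

    fc_threshold: float = Field(default=2.0, ge=1)
    fdr_threshold: float = Field(default=0.05, gt=0, le=1)
    p_threshold: Optional[float] = Field(default=None, gt=0, le=1)
    correlation_threshold: float = Field(default=0.999, ge=0, lt=1)

    seed: int = 0
    out_dir: str = "ruminet_out"

    def model_post_init(self, __context) -> None:
        if self.simulate is None:
            missing = [
                name for name in ("matrix", "design", "annotation")
                if getattr(self, name) is None
            ]
            if missing:
                raise ValueError(
                    "RunConfig needs either a 'simulate' block or paths for: "
                    + ", ".join(missing)
                )


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and return the manifest dict.

    Stages: simulate (optional) -> dge -> enrich -> network -> kcore ->
    regulators -> report.  Any stage failure raises StageError naming the
    stage; artifacts written so far are listed in the partial manifest
    saved alongside.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": json.loads(config.model_dump_json()),
        "stages": {},
        "artifacts": {},
    }

    def record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": path.name,
            "sha256": _sha256(path),
        }

    stage = "inputs"
    try:
        if config.simulate is not None:
            stage = "simulate"
            logger.info("[simulate] generating synthetic dataset (seed=%d)",
                        config.seed)
            sim = config.simulate.to_simulation_config(config.seed)
            matrix, design, truth = generate_dataset(sim)
            io.write_matrix(matrix, out / "matrix.tsv")
            io.write_design(design, out / "design.tsv")
            io.write_annotation(truth.category_map, out / "annotation.tsv")
            io.write_truth(truth, out / "truth.json")
            for name in ("matrix.tsv", "design.tsv", "annotation.tsv", "truth.json"):
                record(name.split(".")[0], out / name)
            annotation = io.read_annotation(out / "annotation.tsv")
            manifest["stages"]["simulate"] = {
                "n_genes": int(matrix.shape[0]),
                "n_samples": int(matrix.shape[1]),
                "n_planted_de": len(truth.de_genes),
                "n_modules": len(set(truth.module_membership.values())),
            }
        else:
            for name in ("matrix", "design", "annotation"):
                path = getattr(config, name)
                if not Path(path).exists():
                    raise FileNotFoundError(f"input '{name}' not found: {path}")
            matrix = io.read_matrix(config.matrix)
            design = io.read_design(config.design)
            annotation = io.read_annotation(config.annotation)

        stage = "dge"
        logger.info("[dge] %d genes, conditions %s vs %s",
                    matrix.shape[0], *design.conditions)
        degs = diffexpr.differential_table(
            matrix, design,
            fc_threshold=config.fc_threshold,
            fdr_threshold=config.fdr_threshold,
            p_threshold=config.p_threshold,
        )
        io.write_deg_table(degs, out / "degs.tsv")
        record("degs", out / "degs.tsv")
        selected = degs.index[degs["selected"]].tolist()
        manifest["stages"]["dge"] = {
            "n_genes": int(len(degs)),
            "n_selected": int(len(selected)),
            "n_up": int((degs["selected"] & (degs["direction"] == "up")).sum()),
            "n_down": int((degs["selected"] & (degs["direction"] == "down")).sum()),
        }

        stage = "cluster"
        if len(selected) >= 2:
            gene_order, sample_order = diffexpr.cluster_order(matrix.loc[selected])
        else:
            gene_order, sample_order = list(selected), list(matrix.columns)
        (out / "cluster_order.json").write_text(
            json.dumps({"genes": gene_order, "samples": sample_order}, indent=1)
            + "\n"
        )
        record("cluster_order", out / "cluster_order.json")

        stage = "enrich"
        annotated = sorted(set(annotation["gene"]) & set(matrix.index))
        background = annotated if annotated else list(matrix.index)
        enr = enrichment.enrich(
            [g for g in selected if g in set(background)], annotation, background
        )
        io.write_enrichment_table(enr, out / "enrichment.tsv")
        record("enrichment", out / "enrichment.tsv")
        manifest["stages"]["enrich"] = {
            "n_categories": int(len(enr)),
            "fdr_empirical": (
                float(enr["fdr_empirical"].iloc[0]) if len(enr) else None
            ),
            "top_categories": [
                {
                    "category": cat,
                    "p_fisher": float(row["p_fisher"]),
                    "re": float(row["re"]),
                }
                for cat, row in enr.head(5).iterrows()
            ],
        }

        stage = "network"
        nets = network.condition_networks(
            matrix, design,
            genes=selected if selected else None,
            threshold=config.correlation_threshold,
        )
        stage = "kcore"
        cores = {cond: network.kcore_decompose(net) for cond, net in nets.items()}
        net_summary = {}
        for cond, net in nets.items():
            kc = cores[cond]
            io.write_edge_list(net, out / f"edges_{cond}.tsv")
            io.write_node_table(net, kc.core_index, out / f"nodes_{cond}.tsv")
            io.write_graphml(net, kc.core_index, out / f"network_{cond}.graphml")
            io.write_sif(net, out / f"network_{cond}.sif")
            record(f"edges_{cond}", out / f"edges_{cond}.tsv")
            record(f"nodes_{cond}", out / f"nodes_{cond}.tsv")
            net_summary[cond] = {
                "n_nodes": net.number_of_nodes(),
                "n_edges": net.number_of_edges(),
                "max_k": kc.max_k,
                "max_core_size": len(kc.max_core_members),
            }
        manifest["stages"]["network"] = net_summary

        stage = "regulators"
        cond_a, cond_b = design.conditions
        regs = network.core_regulators(nets[cond_a], nets[cond_b])
        io.write_deg_table(regs, out / "core_regulators.tsv")
        record("core_regulators", out / "core_regulators.tsv")
        manifest["stages"]["regulators"] = {
            "n_genes": int(len(regs)),
            "top": [
                {"gene": g, "degree_diff": int(row["degree_diff"])}
                for g, row in regs.head(10).iterrows()
            ],
        }

        stage = "report"
        report = render_report(manifest)
        (out / "report.md").write_text(report)
        record("report", out / "report.md")
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        manifest["failed_stage"] = stage
        (out / "manifest.partial.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n"
        )
        raise StageError(stage, exc) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    logger.info("[done] manifest written to %s", manifest_path)
    return manifest


def render_report(manifest: dict) -> str:
    """Render a manifest into a markdown run summary (idempotent)."""
    lines = [
        "# ruminet run report",
        "",
        f"- version: {manifest['version']}",
        f"- seed: {manifest['seed']}",
        "",
    ]
    stages = manifest.get("stages", {})
    if "simulate" in stages:
        s = stages["simulate"]
        lines += [
            "## Synthetic dataset",
            "",
            f"- genes: {s['n_genes']}, samples: {s['n_samples']}",
            f"- planted DE genes: {s['n_planted_de']}, modules: {s['n_modules']}",
            "",
        ]
    if "dge" in stages:
        s = stages["dge"]
        lines += [
            "## Differential expression",
            "",
            f"- genes tested: {s['n_genes']}",
            f"- selected: {s['n_selected']} ({s['n_up']} up, {s['n_down']} down)",
            "",
        ]
    if "enrich" in stages:
        s = stages["enrich"]
        lines += ["## Category enrichment", ""]
        lines.append(f"- categories tested: {s['n_categories']}")
        if s.get("fdr_empirical") is not None:
            lines.append(f"- empirical FDR (1 - Nk/T): {s['fdr_empirical']:.4f}")
        if s["top_categories"]:
            lines.append("- top categories (by Fisher p):")
            for t in s["top_categories"]:
                lines.append(
                    f"    - {t['category']}: p = {t['p_fisher']:.3g}, "
                    f"Re = {t['re']:.2f}"
                )
        lines.append("")
    if "network" in stages:
        lines += ["## Co-expression networks", ""]
        for cond, s in stages["network"].items():
            lines.append(
                f"- {cond}: |V| = {s['n_nodes']}, |E| = {s['n_edges']}, "
                f"max k-core = {s['max_k']} ({s['max_core_size']} genes)"
            )
        lines.append("")
    if "regulators" in stages:
        s = stages["regulators"]
        lines += ["## Core regulator candidates (degree difference)", ""]
        if s["top"]:
            for t in s["top"]:
                lines.append(f"- {t['gene']}: degree_diff = {t['degree_diff']}")
        else:
            lines.append("- none (empty networks)")
        lines.append("")
    return "\n".join(lines)
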