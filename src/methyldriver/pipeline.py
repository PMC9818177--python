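"""End-to-end orchestration: simulate -> beta -> DMP/DMR -> DEG -> integrate
-> enrich -> dependency screen, as one seeded, logged run.

A run is configured by :class:`PipelineConfig` — either a
:class:`~methyldriver.synthetic_data.SimConfig` for a fully self-contained
synthetic run, or paths to user-supplied input tables.  Every intermediate
table is written to the output directory with deterministic formatting, and
a machine-readable ``summary.json`` records the count at each gate of the
funnel (probes flagged, regions flagged, DEGs, driver classes, enriched
terms, dependency hits) plus the config hash and seed, so two runs with the
same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import depscreen, enrichment, integration, methylome, transcriptome
from .io_formats import (
    GENE_REGIONS,
    CPG_REGIONS,
    ChannelLayout,
    read_annotation,
    read_gene_sets,
    read_matrix,
    read_sample_sheet,
    read_signal_table,
    write_gene_sets,
    write_matrix,
    write_results,
    write_signal_table,
)
from .synthetic_data import (
    GroundTruth,
    SimConfig,
    simulate_dependency,
    simulate_expression,
    simulate_gene_sets,
    simulate_methylation,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass(frozen=True)
class InputPaths:
    """Locations of user-supplied inputs for a non-synthetic run."""

    sample_sheet: str
    signals: str
    annotation: str
    expression: str
    gene_sets: str | None = None
    dep_expression: str | None = None
    dep_effect_a: str | None = None
    dep_effect_b: str | None = None


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and inputs of one pipeline run.

    Exactly one of ``sim`` (self-contained synthetic run) or ``inputs``
    (paths to real tables) must be set.  Threshold defaults mirror the
    screens' printed conventions: probe gate |delta-beta| > 0.1, region gate
    0.5, DEG fold-change gates 2 and 0.5, integration gates 0.1 / |log2FC| >
    1, all at raw p < 0.05, Bonferroni <= 0.05 for enrichment.
    """

    sim: SimConfig | None = None
    inputs: InputPaths | None = None
    beta_offset: float = 100.0
    probe_dbeta_min: float = 0.1
    region_dbeta_min: float = 0.5
    alpha: float = 0.05
    fc_up: float = 2.0
    fc_down: float = 0.5
    integrate_dbeta_min: float = 0.1
    log2fc_min: float = 1.0
    policy: str = integration.PROMOTER_FIRST
    enrich_threshold: float = 0.05
    top_k: int = 10
    dep_alpha: float = 0.05
    r_min: float = 0.0

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.inputs is None):
            raise ValueError("exactly one of sim or inputs must be set")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.fc_down >= self.fc_up:
            raise ValueError("fc_down must be below fc_up")

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        sim = SimConfig(**raw.pop("sim")) if "sim" in raw else None
        inputs = InputPaths(**raw.pop("inputs")) if "inputs" in raw else None
        return cls(sim=sim, inputs=inputs, **raw)


def _truth_to_json(truth: GroundTruth) -> dict:
    return {
        "driver_genes": dict(sorted(truth.driver_genes.items())),
        "dmr_regions": sorted(list(r) for r in truth.dmr_regions),
        "deg_genes": dict(sorted(truth.deg_genes.items())),
        "dep_correlated_genes": sorted(truth.dep_correlated_genes),
        "enriched_term": truth.enriched_term,
        "n_truncated_beta": truth.n_truncated_beta,
    }


def _recovery(found: set, planted: set) -> dict:
    tp = len(found & planted)
    recall = tp / len(planted) if planted else None
    precision = tp / len(found) if found else None
    return {"n_found": len(found), "n_planted": len(planted),
            "recall": recall, "precision": precision}


def run(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full funnel and write all tables under ``outdir``.

    Returns the run summary (also written as ``summary.json``).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": config.config_hash()}
    truth: GroundTruth | None = None

    stage = "inputs"
    try:
        if config.sim is not None:
            sim = config.sim
            summary["seed"] = sim.seed
            meth, unmeth, annot, truth = simulate_methylation(sim)
            expr = simulate_expression(sim, truth)
            panel, truth = simulate_dependency(sim, truth)
            gene_sets = simulate_gene_sets(sim, truth)
            sheet = sim.sample_sheet()
            write_signal_table(meth, unmeth, out / "signals.tsv")
            annot_out = annot.table.copy()
            annot_out.index.name = "probe_id"
            annot_out.to_csv(out / "annotation.tsv", sep="\t")
            sheet.to_frame().to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
            write_matrix(expr, out / "expression.tsv", index_name="gene")
            write_gene_sets(gene_sets, out / "gene_sets.gmt")
            with open(out / "ground_truth.json", "w") as handle:
                json.dump(_truth_to_json(truth), handle, indent=2, sort_keys=True)
        else:
            paths = config.inputs
            sheet = read_sample_sheet(paths.sample_sheet)
            meth, unmeth = read_signal_table(paths.signals, sheet, ChannelLayout())
            annot = read_annotation(paths.annotation)
            expr = read_matrix(paths.expression, sheet)
            gene_sets = read_gene_sets(paths.gene_sets) if paths.gene_sets else None
            panel = None
            if paths.dep_expression and paths.dep_effect_a and paths.dep_effect_b:
                dep_expr = read_matrix(paths.dep_expression)
                eff_a = pd.read_csv(paths.dep_effect_a, sep="\t", index_col=0).iloc[:, 0]
                eff_b = pd.read_csv(paths.dep_effect_b, sep="\t", index_col=0).iloc[:, 0]
                from .synthetic_data import DependencyPanel

                panel = DependencyPanel(dep_expr, eff_a.reindex(dep_expr.columns),
                                        eff_b.reindex(dep_expr.columns))

        stage = "beta"
        beta = methylome.compute_beta(meth, unmeth, offset=config.beta_offset)
        write_matrix(beta, out / "beta.tsv", index_name="probe_id")

        stage = "dmp"
        dmp = methylome.test_probes(beta, sheet, config.probe_dbeta_min, config.alpha)
        write_results(dmp, out / "dmp.tsv", kind="dmp")
        summary["n_probes"] = int(len(dmp))
        summary["n_probes_flagged"] = int(dmp["flagged"].sum())

        stage = "dmr"
        dmr_tables = {}
        for scheme, fname in ((methylome.GENE_REGION, "dmr_gene.tsv"),
                              (methylome.CPG_REGION, "dmr_cpg.tsv")):
            regions = methylome.aggregate_regions(beta, annot, scheme)
            sizes = methylome.region_sizes(beta, annot, scheme)
            dmr = methylome.test_regions(regions, sheet, config.region_dbeta_min,
                                         config.alpha, n_probes=sizes)
            write_results(dmr, out / fname, kind="dmr")
            dmr_tables[scheme] = dmr
            summary[f"n_regions_{scheme}"] = int(len(dmr))
            summary[f"n_regions_flagged_{scheme}"] = int(dmr["flagged"].sum())
        classes = GENE_REGIONS + CPG_REGIONS
        flagged_all = pd.concat(
            [t[t["flagged"]] for t in dmr_tables.values()], ignore_index=True
        )
        dist = methylome.summarize_region_distribution(flagged_all, classes)
        dist.to_csv(out / "dmr_distribution.tsv", sep="\t")

        stage = "deg"
        deg = transcriptome.test_genes(expr, sheet, config.fc_up, config.fc_down, config.alpha)
        write_results(deg, out / "deg.tsv", kind="deg")
        summary["n_genes"] = int(len(deg))
        summary["n_deg_flagged"] = int(deg["flagged"].sum())

        stage = "integrate"
        gene_meth = integration.resolve_gene_methylation(
            dmr_tables[methylome.GENE_REGION], config.policy, config.alpha
        )
        write_results(gene_meth, out / "gene_methylation.tsv", kind="gene_methylation")
        drivers, report = integration.select_driver_genes(
            gene_meth, deg, config.integrate_dbeta_min, config.log2fc_min, config.alpha
        )
        write_results(drivers, out / "drivers.tsv", kind="driver")
        summary.update({f"driver_{k}": v for k, v in report.items()})

        stage = "enrich"
        if gene_sets is not None and len(gene_sets):
            universe = sorted(expr.index)
            hits = enrichment.enrich(drivers["gene"], universe, gene_sets,
                                     config.enrich_threshold, config.top_k)
            write_results(hits, out / "enrichment_drivers.tsv", kind="enrichment")
            summary["n_enriched_terms"] = int(len(hits))

        stage = "depscreen"
        if panel is not None:
            corr_a = depscreen.correlate_dependency(panel, depscreen.ALGORITHM_A)
            hits_a = depscreen.select_positive(corr_a, config.dep_alpha, config.r_min)
            corr_b = depscreen.correlate_dependency(panel, depscreen.ALGORITHM_B)
            hits_b = depscreen.select_positive(corr_b, config.dep_alpha, config.r_min)
            inter = depscreen.intersect_screens(hits_a, hits_b)
            write_results(corr_a, out / "depscreen_a.tsv", kind="correlation")
            write_results(corr_b, out / "depscreen_b.tsv", kind="correlation")
            (out / "dep_intersection.txt").write_text("\n".join(inter) + ("\n" if inter else ""))
            summary["n_dep_hits_a"] = len(hits_a)
            summary["n_dep_hits_b"] = len(hits_b)
            summary["n_dep_intersection"] = len(inter)
            if gene_sets is not None and len(gene_sets):
                dep_universe = sorted(panel.expr.index)
                dep_enriched = enrichment.enrich(inter, dep_universe, gene_sets,
                                                 config.enrich_threshold, config.top_k)
                write_results(dep_enriched, out / "enrichment_dep.tsv", kind="enrichment")
                summary["n_dep_enriched_terms"] = int(len(dep_enriched))
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    if truth is not None:
        found_drivers = set(drivers["gene"])
        planted_drivers = set(truth.driver_genes)
        summary["recovery_drivers"] = _recovery(found_drivers, planted_drivers)
        summary["recovery_dep"] = _recovery(set(inter), set(truth.dep_correlated_genes))

    with open(out / "summary.json", "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
    logger.info("pipeline run complete: %s", out / "summary.json")
    return summary
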