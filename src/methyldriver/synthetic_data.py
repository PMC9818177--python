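"""Synthetic cohort generator with planted ground truth.

Emulates a small two-group methylation + expression array study (a handful
of case and control samples), a gene-set collection with one genuinely
enriched term, and a cell-line dependency panel in which a subset of genes'
expression correlates with a target gene's CRISPR gene-effect score.  Every
generator is a pure function of :class:`SimConfig` (seed included), so all
outputs are bit-reproducible.

The planted effects mirror the two methylation-driven gene classes: a
HYPO_UP driver is hypomethylated in cases at its promoter regions (negative
delta-beta) and over-expressed; a HYPER_DOWN driver is the mirror image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import (
    CASE,
    CONTROL,
    CPG_REGIONS,
    GENE_REGIONS,
    GeneSetCollection,
    ProbeAnnotation,
    SampleSheet,
)

logger = logging.getLogger(__name__)

HYPO_UP = "HYPO_UP"
HYPER_DOWN = "HYPER_DOWN"

#: Regions that carry the planted methylation shift for driver genes.
PLANTED_REGIONS = ("TSS1500", "TSS200")

#: Baseline beta means by CpG class: islands run low-methylated, shelves and
#: open sea high, shores intermediate (the classic bimodal array profile).
BASELINE_BETA_MEAN = {
    "ISLAND": 0.15,
    "N_SHORE": 0.45,
    "S_SHORE": 0.45,
    "N_SHELF": 0.75,
    "S_SHELF": 0.75,
    "OPEN_SEA": 0.70,
}
BASELINE_BETA_SD = 0.05

# Stage offsets for per-stage RNG substreams.
_STAGE_METH, _STAGE_EXPR, _STAGE_DEP, _STAGE_SETS = 1, 2, 3, 4


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, with defaults matching a small
    case/control array cohort (5 cases vs 6 controls).

    ``delta_beta`` is the planted methylation shift in beta units applied to
    driver promoter regions in CASE samples; ``log2fc`` the planted log2
    expression shift; ``dep_r`` the population expression-dependency
    correlation of planted genes in the cell-line panel.
    """

    n_case: int = 5
    n_control: int = 6
    n_genes: int = 2000
    probes_per_gene_region: int = 2
    n_driver_hypo_up: int = 20
    n_driver_hyper_down: int = 20
    delta_beta: float = 0.3
    log2fc: float = 2.0
    beta_noise_sd: float = 0.05
    expr_noise_sd: float = 0.5
    total_intensity_mean: float = 5000.0
    n_cell_lines: int = 100
    n_dep_correlated: int = 50
    dep_r: float = 0.6
    dep_algorithm_noise_sd: float = 1.1
    n_terms: int = 50
    enriched_term_overlap: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_case, self.n_control, self.n_genes, self.probes_per_gene_region,
            self.n_driver_hypo_up, self.n_driver_hyper_down, self.n_cell_lines,
            self.n_dep_correlated, self.n_terms,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if not 0.0 < self.delta_beta < 1.0:
            raise ValueError("delta_beta must lie in (0, 1)")
        if self.n_driver_hypo_up + self.n_driver_hyper_down > self.n_genes:
            raise ValueError("planted driver count exceeds n_genes")
        if not -1.0 < self.dep_r < 1.0 and self.dep_r != 1.0:
            raise ValueError("dep_r must lie in (-1, 1] ")
        if self.n_dep_correlated > self.n_genes:
            raise ValueError("n_dep_correlated exceeds n_genes")
        if not 0.0 <= self.enriched_term_overlap <= 1.0:
            raise ValueError("enriched_term_overlap must lie in [0, 1]")

    def gene_names(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def sample_sheet(self) -> SampleSheet:
        ids = [f"CASE{i}" for i in range(1, self.n_case + 1)] + [
            f"CTRL{i}" for i in range(1, self.n_control + 1)
        ]
        groups = [CASE] * self.n_case + [CONTROL] * self.n_control
        return SampleSheet(tuple(ids), tuple(groups))

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stage)])


@dataclass
class GroundTruth:
    """Planted truth for scoring every downstream stage.

    ``driver_genes`` maps gene -> HYPO_UP / HYPER_DOWN; ``dmr_regions`` is
    the set of (gene, gene_region) pairs that actually carry the planted
    methylation shift; ``deg_genes`` maps gene -> UP / DOWN.
    """

    driver_genes: dict = field(default_factory=dict)
    dmr_regions: set = field(default_factory=set)
    deg_genes: dict = field(default_factory=dict)
    dep_correlated_genes: frozenset = frozenset()
    enriched_term: str | None = None
    n_truncated_beta: int = 0


@dataclass(frozen=True)
class DependencyPanel:
    """Cell-line expression matrix plus the target gene's effect vectors
    under two scoring algorithms (CERES/Chronos analogs).

    ``effect_a`` / ``effect_b`` share cell-line ordering with ``expr``
    columns; more negative effect = stronger dependency.
    """

    expr: pd.DataFrame
    effect_a: pd.Series
    effect_b: pd.Series
    lineage: pd.Series | None = None

    def __post_init__(self) -> None:
        lines = list(self.expr.columns)
        if len(lines) < 3:
            raise ValueError("dependency panel needs at least 3 cell lines")
        for name, vec in (("effect_a", self.effect_a), ("effect_b", self.effect_b)):
            if list(vec.index) != lines:
                raise ValueError(f"{name} cell-line ordering differs from expr")
        if self.lineage is not None and list(self.lineage.index) != lines:
            raise ValueError("lineage cell-line ordering differs from expr")


def _assign_cpg_region(rng: np.random.Generator, gene_region: str) -> str:
    """Promoter-proximal regions are island-biased; distal ones sea/shelf-biased."""
    if gene_region in ("TSS1500", "TSS200", "UTR5", "FIRST_EXON"):
        probs = [0.55, 0.15, 0.15, 0.05, 0.05, 0.05]
    else:
        probs = [0.05, 0.10, 0.10, 0.20, 0.20, 0.35]
    return str(rng.choice(CPG_REGIONS, p=probs))


def simulate_methylation(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, ProbeAnnotation, GroundTruth]:
    """Simulate two-channel intensity matrices with planted driver regions.

    Each gene contributes one probe group per gene-annotation class.  Region
    baselines are drawn bimodally by CpG class; driver genes get their
    promoter-region baselines shifted by ``+/- delta_beta`` in CASE samples
    only.  Per-sample Gaussian beta noise is added and truncated to
    (0.001, 0.999), then intensities are synthesized as
    ``methylated = total * beta`` and ``unmethylated = total * (1 - beta)``.

    Returns ``(methylated, unmethylated, annotation, truth)``.
    """
    rng = config.rng(_STAGE_METH)
    genes = config.gene_names()
    sheet = config.sample_sheet()
    n_samples = len(sheet.sample_ids)
    is_case = np.array([g == CASE for g in sheet.groups])

    n_drivers = config.n_driver_hypo_up + config.n_driver_hyper_down
    driver_idx = rng.choice(config.n_genes, size=n_drivers, replace=False) if n_drivers else np.array([], dtype=int)
    truth = GroundTruth()
    for k, gi in enumerate(driver_idx):
        klass = HYPO_UP if k < config.n_driver_hypo_up else HYPER_DOWN
        truth.driver_genes[genes[gi]] = klass
        for region in PLANTED_REGIONS:
            truth.dmr_regions.add((genes[gi], region))
    truth.deg_genes = {
        g: ("UP" if k == HYPO_UP else "DOWN") for g, k in truth.driver_genes.items()
    }

    probe_rows = []
    base_means = []
    shifts = []
    k_probes = config.probes_per_gene_region
    for gi, gene in enumerate(genes):
        klass = truth.driver_genes.get(gene)
        for region in GENE_REGIONS:
            cpg = _assign_cpg_region(rng, region)
            planted = klass is not None and region in PLANTED_REGIONS
            if planted:
                # Mid-range baseline so the +/- delta_beta shift stays inside (0, 1).
                base = rng.uniform(0.4, 0.6)
                shift = -config.delta_beta if klass == HYPO_UP else config.delta_beta
            else:
                base = rng.normal(BASELINE_BETA_MEAN[cpg], BASELINE_BETA_SD)
                shift = 0.0
            for p in range(k_probes):
                probe_rows.append((f"cg_{gene}_{region}_{p}", gene, region, cpg))
                base_means.append(np.clip(base + rng.normal(0.0, 0.02), 0.05, 0.95))
                shifts.append(shift)

    n_probes = len(probe_rows)
    base_arr = np.asarray(base_means)[:, None]
    shift_arr = np.asarray(shifts)[:, None]
    intended = base_arr + shift_arr * is_case[None, :]
    noisy = intended + rng.normal(0.0, config.beta_noise_sd, size=(n_probes, n_samples))
    truncated = (noisy <= 0.001) | (noisy >= 0.999)
    truth.n_truncated_beta = int(truncated.sum())
    if truth.n_truncated_beta:
        logger.info("truncated %d beta values to (0.001, 0.999)", truth.n_truncated_beta)
    beta = np.clip(noisy, 0.001, 0.999)

    total = np.maximum(
        rng.normal(config.total_intensity_mean, 0.15 * config.total_intensity_mean,
                   size=(n_probes, n_samples)),
        0.05 * config.total_intensity_mean,
    )
    probe_ids = [r[0] for r in probe_rows]
    meth = pd.DataFrame(total * beta, index=probe_ids, columns=list(sheet.sample_ids))
    unmeth = pd.DataFrame(total * (1.0 - beta), index=probe_ids, columns=list(sheet.sample_ids))
    meth.index.name = unmeth.index.name = "probe_id"

    annot_frame = pd.DataFrame(
        probe_rows, columns=["probe_id", "gene", "gene_region", "cpg_region"]
    ).set_index("probe_id")
    return meth, unmeth, ProbeAnnotation(annot_frame), truth


def simulate_expression(config: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Simulate a log2 gene x sample expression matrix coupled to the truth.

    HYPO_UP driver genes get ``+log2fc`` added to CASE means, HYPER_DOWN
    ``-log2fc``; every other gene is exchangeable between groups.  Gaussian
    noise on the log2 scale.
    """
    rng = config.rng(_STAGE_EXPR)
    genes = config.gene_names()
    sheet = config.sample_sheet()
    is_case = np.array([g == CASE for g in sheet.groups])
    baseline = rng.normal(7.0, 1.5, size=config.n_genes)
    shift = np.zeros(config.n_genes)
    for gi, gene in enumerate(genes):
        klass = truth.driver_genes.get(gene)
        if klass == HYPO_UP:
            shift[gi] = config.log2fc
        elif klass == HYPER_DOWN:
            shift[gi] = -config.log2fc
    values = (
        baseline[:, None]
        + shift[:, None] * is_case[None, :]
        + rng.normal(0.0, config.expr_noise_sd, size=(config.n_genes, len(sheet.sample_ids)))
    )
    out = pd.DataFrame(values, index=genes, columns=list(sheet.sample_ids))
    out.index.name = "gene"
    return out


LINEAGES = ("thyroid", "lung", "breast", "colon", "skin")


def simulate_dependency(config: SimConfig, truth: GroundTruth | None = None
                        ) -> tuple[DependencyPanel, GroundTruth]:
    """Simulate the cell-line panel for the dependency-correlation screen.

    A latent target-dependency vector over cell lines (more negative in
    thyroid-lineage lines) is observed twice with independent algorithm
    noise, standing in for two gene-effect estimators.  ``n_dep_correlated``
    genes' expression tracks the latent vector at population correlation
    ``dep_r``; all other genes are independent noise.
    """
    if config.n_cell_lines < 10:
        raise ValueError("n_cell_lines must be >= 10")
    rng = config.rng(_STAGE_DEP)
    truth = truth if truth is not None else GroundTruth()
    genes = config.gene_names()
    lines = [f"CL{i:03d}" for i in range(1, config.n_cell_lines + 1)]
    lineage = pd.Series(rng.choice(LINEAGES, size=config.n_cell_lines), index=lines)

    latent = rng.normal(0.0, 1.0, size=config.n_cell_lines)
    latent = latent - 0.8 * (lineage.to_numpy() == "thyroid")
    z = (latent - latent.mean()) / latent.std()

    # Variance-controlled algorithm noise: each replicate's noise is made
    # sample-orthogonal to the latent vector and to the other replicate's
    # noise, with exact sample scale, so the inter-algorithm agreement of a
    # finite panel matches the configured regime rather than seed luck.
    noise_sd = config.dep_algorithm_noise_sd
    lc = latent - latent.mean()

    def _orthonormal_noise(against: list[np.ndarray]) -> np.ndarray:
        e = rng.normal(0.0, 1.0, config.n_cell_lines)
        e -= e.mean()
        for v in against:
            e -= (e @ v) / (v @ v) * v
        return e / e.std()

    e_a = _orthonormal_noise([lc])
    e_b = _orthonormal_noise([lc, e_a])
    effect_a = pd.Series(latent + noise_sd * e_a, index=lines)
    effect_b = pd.Series(latent + noise_sd * e_b, index=lines)

    dep_idx = (
        rng.choice(config.n_genes, size=config.n_dep_correlated, replace=False)
        if config.n_dep_correlated
        else np.array([], dtype=int)
    )
    dep_genes = frozenset(genes[i] for i in dep_idx)
    r = config.dep_r
    expr = rng.normal(6.0, 1.5, size=(config.n_genes, config.n_cell_lines))
    if len(dep_idx):
        eps = rng.normal(0.0, 1.0, size=(len(dep_idx), config.n_cell_lines))
        expr[dep_idx] = 6.0 + 1.5 * (r * z[None, :] + np.sqrt(max(0.0, 1.0 - r * r)) * eps)
    expr_df = pd.DataFrame(expr, index=genes, columns=lines)
    expr_df.index.name = "gene"

    truth.dep_correlated_genes = dep_genes
    return DependencyPanel(expr_df, effect_a, effect_b, lineage), truth


PLANTED_TERM = "TERM_PLANTED"


def simulate_gene_sets(config: SimConfig, truth: GroundTruth) -> GeneSetCollection:
    """Simulate random gene sets plus one term enriched for the planted genes.

    The planted term overlaps the driver genes (or, if no drivers were
    planted, the dependency-correlated genes) at ``enriched_term_overlap``;
    remaining members and all other terms are drawn uniformly from the
    simulated gene universe.
    """
    rng = config.rng(_STAGE_SETS)
    universe = np.array(config.gene_names())
    target = sorted(truth.driver_genes) if truth.driver_genes else sorted(truth.dep_correlated_genes)
    terms: dict[str, frozenset] = {}
    names: dict[str, str] = {}
    for t in range(1, config.n_terms + 1):
        size = int(rng.integers(10, 61))
        members = rng.choice(universe, size=size, replace=False)
        terms[f"TERM{t:04d}"] = frozenset(members)
        names[f"TERM{t:04d}"] = f"random term {t}"

    n_overlap = int(round(config.enriched_term_overlap * len(target)))
    overlap_genes = list(rng.choice(target, size=n_overlap, replace=False)) if n_overlap else []
    non_target = np.array(sorted(set(universe) - set(target)))
    n_filler = max(10, len(target) - n_overlap + 10)
    filler = rng.choice(non_target, size=n_filler, replace=False)
    planted = frozenset(overlap_genes) | frozenset(filler)
    terms[PLANTED_TERM] = planted
    names[PLANTED_TERM] = "planted enriched term"
    truth.enriched_term = PLANTED_TERM
    return GeneSetCollection(terms, names)
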