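"""Synthetic-data generators for every input the screens consume.

Real inputs (an NCI-60-style expression panel with GI50s; paired
sensitive/resistant replicate arrays with detection P values) are large
external datasets; these generators emulate their statistical structure so
every stage is testable offline:

* panels of ~60 samples whose log10(GI50) phenotype is standard normal,
  shifted into a plausible molar range, with probes planted at an exact
  population correlation rho via x = rho*z + sqrt(1-rho^2)*eps;
* 2-pair x 2-phenotype replicate designs with planted log2 fold changes
  applied directionally-congruently in every pair, over Gaussian log2
  noise (log-normal intensities);
* linear fluorescence kinetic traces (31 one-minute points).

All generators are pure functions of their spec, seed included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .assays import KineticTrace
from .io import (
    DrugResponseProfile,
    ExpressionMatrix,
    PairRecord,
    PairedDesign,
    ProbeGeneMap,
)


class SpecError(ValueError):
    """Invalid generator specification."""


# ---------------------------------------------------------------------------
# Panel generator (tier-1 substrate)
# ---------------------------------------------------------------------------


@dataclass
class PlantedCorrelation:
    probe_id: str
    target_rho: float
    gene_symbol: str | None = None

    def __post_init__(self) -> None:
        if not (-1.0 < self.target_rho < 1.0):
            raise SpecError(f"|target_rho| must be < 1, got {self.target_rho}")


@dataclass
class PanelSpec:
    """Cell-line panel with probes carrying specified population correlations
    to the log10(GI50) phenotype.  Defaults mirror a 60-line panel."""

    n_samples: int = 60
    n_probes: int = 1000
    planted: list[PlantedCorrelation] = field(default_factory=list)
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    log10_gi50_center: float = -5.5
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [p.probe_id for p in self.planted]
        if len(ids) != len(set(ids)):
            raise SpecError("duplicate planted probe IDs")
        if len(self.planted) > self.n_probes:
            raise SpecError("more planted probes than probes")


def gen_panel(
    spec: PanelSpec,
) -> tuple[ExpressionMatrix, DrugResponseProfile, ProbeGeneMap]:
    """Generate (expression, drug response, annotation) for a panel spec.

    log10(GI50) is standard normal around ``log10_gi50_center`` (default
    1e-7..1e-4 M range); a planted probe's expression is
    rho * z + sqrt(1-rho^2) * eps on the standardised phenotype z, so its
    population correlation with log10(GI50) equals ``target_rho`` exactly.
    Null probes are independent Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    samples = [f"CL{j + 1:02d}" for j in range(spec.n_samples)]
    z = rng.standard_normal(spec.n_samples)
    log10_gi50 = spec.log10_gi50_center + z
    gi50 = 10.0 ** log10_gi50
    z_std = (z - z.mean()) / z.std()

    probe_ids = [f"P{i + 1:05d}_at" for i in range(spec.n_probes)]
    values = spec.baseline_mean + spec.noise_sd * rng.standard_normal(
        (spec.n_probes, spec.n_samples)
    )
    gene_map: dict[str, str] = {
        pid: f"GENE{i + 1:05d}" for i, pid in enumerate(probe_ids)
    }
    planted_slots = rng.choice(spec.n_probes, size=len(spec.planted), replace=False)
    for slot, plant in zip(planted_slots, spec.planted):
        rho = plant.target_rho
        eps = rng.standard_normal(spec.n_samples)
        x = rho * z_std + math.sqrt(1.0 - rho * rho) * eps
        values[slot] = spec.baseline_mean + spec.noise_sd * x
        probe_ids[slot] = plant.probe_id
        if plant.gene_symbol is not None:
            gene_map[plant.probe_id] = plant.gene_symbol
        else:
            gene_map[plant.probe_id] = f"GENE{slot + 1:05d}"

    # drop stale keys for renamed slots
    gene_map = {pid: gene_map.get(pid, f"GENE_{pid}") for pid in probe_ids}
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=probe_ids, columns=samples), scale="log2"
    )
    response = DrugResponseProfile(samples, gi50)
    return expr, response, ProbeGeneMap(gene_map)


# ---------------------------------------------------------------------------
# Paired-experiment generator (tier-2 substrate)
# ---------------------------------------------------------------------------


@dataclass
class PlantedFoldChange:
    gene: str
    log2_fc: float  # sensitive minus resistant; sign encodes direction

    def __post_init__(self) -> None:
        if self.log2_fc == 0:
            raise SpecError("planted |log2_fc| must be > 0")


@dataclass
class PairedSpec:
    """Replicated sensitive/resistant pairs with planted congruent effects.

    Defaults mirror the study design: two pairs (a myeloma and a
    mantle-cell-lymphoma pair), 3 replicate arrays per cell line, Gaussian
    log2 noise.  Detection P values are near zero for expressed probes and
    uniform for an ``absent_fraction`` of null probes.
    """

    pairs: int = 2
    replicates_per_group: int = 3
    n_probes: int = 1000
    planted: list[PlantedFoldChange] = field(default_factory=list)
    probes_per_gene: Sequence[int] = (1,)
    noise_sd: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    absent_fraction: float = 0.3
    detected_p_scale: float = 1e-3
    pair_names: Sequence[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_group < 2:
            raise SpecError("replicates_per_group must be >= 2")
        genes = [p.gene for p in self.planted]
        if len(genes) != len(set(genes)):
            raise SpecError("duplicate planted genes")
        if not (0.0 <= self.absent_fraction < 1.0):
            raise SpecError("absent_fraction must be in [0, 1)")


def gen_paired_experiment(
    spec: PairedSpec,
) -> tuple[ExpressionMatrix, PairedDesign, ProbeGeneMap]:
    """Generate (expression with detection P, design, annotation).

    Planted genes are shifted by ``log2_fc`` in the sensitive groups of
    EVERY pair (directionally congruent).  Each gene carries a number of
    probes drawn from ``probes_per_gene``.  The matrix is emitted on the
    log2 scale, ready for the moderated test.
    """
    rng = np.random.default_rng(spec.seed)
    pair_names = list(spec.pair_names or [f"PAIR{k + 1}" for k in range(spec.pairs)])
    if len(pair_names) != spec.pairs:
        raise SpecError("pair_names length must equal pairs")

    pairs: list[PairRecord] = []
    sens_cols: list[int] = []
    sample_ids: list[str] = []
    for name in pair_names:
        sens = [f"{name}_S_{r + 1}" for r in range(spec.replicates_per_group)]
        res = [f"{name}_R_{r + 1}" for r in range(spec.replicates_per_group)]
        sens_cols.extend(range(len(sample_ids), len(sample_ids) + len(sens)))
        sample_ids.extend(sens + res)
        pairs.append(PairRecord(name, sens, res))
    design = PairedDesign(pairs)
    n_samples = len(sample_ids)

    # assign probes: planted genes first, then null genes
    probe_ids: list[str] = []
    gene_of: list[str] = []
    planted_fc: list[float] = []
    for plant in spec.planted:
        k = int(rng.choice(list(spec.probes_per_gene)))
        for j in range(k):
            probe_ids.append(f"{plant.gene}_p{j + 1}")
            gene_of.append(plant.gene)
            planted_fc.append(plant.log2_fc)
    if len(probe_ids) > spec.n_probes:
        raise SpecError("planted probes exceed n_probes")
    i = 0
    while len(probe_ids) < spec.n_probes:
        gene = f"NULL{i + 1:05d}"
        k = int(rng.choice(list(spec.probes_per_gene)))
        for j in range(k):
            if len(probe_ids) >= spec.n_probes:
                break
            probe_ids.append(f"{gene}_p{j + 1}")
            gene_of.append(gene)
            planted_fc.append(0.0)
        i += 1

    n_probes = len(probe_ids)
    baseline = spec.baseline_mean + spec.baseline_sd * rng.standard_normal(n_probes)
    values = baseline[:, None] + spec.noise_sd * rng.standard_normal(
        (n_probes, n_samples)
    )
    fc = np.asarray(planted_fc)
    values[:, sens_cols] += fc[:, None]

    # detection grid: expressed probes detected everywhere; a fraction of
    # null probes is "absent" (uniform detection P, like background beads)
    detection = spec.detected_p_scale * rng.random((n_probes, n_samples))
    null_idx = np.nonzero(fc == 0)[0]
    n_absent = int(round(spec.absent_fraction * n_probes))
    if n_absent > null_idx.size:
        raise SpecError("absent_fraction exceeds available null probes")
    absent = rng.choice(null_idx, size=n_absent, replace=False)
    detection[absent] = rng.random((n_absent, n_samples))

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=probe_ids, columns=sample_ids),
        pd.DataFrame(detection, index=probe_ids, columns=sample_ids),
        scale="log2",
    )
    return expr, design, ProbeGeneMap(dict(zip(probe_ids, gene_of)))


# ---------------------------------------------------------------------------
# Kinetic-trace generator (assay fixture)
# ---------------------------------------------------------------------------


def gen_kinetic_trace(
    slope: float,
    intercept: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "G6P",
) -> KineticTrace:
    """Linear fluorescence trace: 31 one-minute points, optional Gaussian noise."""
    if noise_sd < 0:
        raise SpecError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, 31.0)
    signal = intercept + slope * t + noise_sd * rng.standard_normal(t.size)
    return KineticTrace(times=t, signal=signal, label=label)


# ---------------------------------------------------------------------------
# Matched two-tier study (end-to-end fixture)
# ---------------------------------------------------------------------------

DEFAULT_OVERLAP_SENS = ("MYC",)
DEFAULT_OVERLAP_RES = ("VIM", "ACTN1", "THY1", "CCND1", "LGALS1", "G6PD")


@dataclass
class IntegratedStudy:
    panel_expr: ExpressionMatrix
    panel_response: DrugResponseProfile
    panel_map: ProbeGeneMap
    paired_expr: ExpressionMatrix
    paired_design: PairedDesign
    paired_map: ProbeGeneMap
    overlap_sens: tuple[str, ...]
    overlap_res: tuple[str, ...]


def gen_integrated_study(
    seed: int = 0,
    n_panel_probes: int = 6000,
    n_paired_probes: int = 6000,
    overlap_sens: Sequence[str] = DEFAULT_OVERLAP_SENS,
    overlap_res: Sequence[str] = DEFAULT_OVERLAP_RES,
    panel_rho: float = 0.65,
    paired_log2_fc: float = 1.5,
    extra_paired_sens: int = 19,
    extra_paired_res: int = 32,
) -> IntegratedStudy:
    """A matched panel + paired experiment with a planted integrated signature.

    The overlap genes are planted to pass both tiers: positive (resistance)
    genes at correlation +``panel_rho`` with log10(GI50) and lower expression
    in sensitive lines; the sensitivity gene mirrored.  Extra paired-only
    planted genes carry platform-specific symbols absent from the panel
    annotation, mimicking the partial overlap of two array platforms.
    """
    rng = np.random.default_rng(seed)
    planted_panel = [
        PlantedCorrelation(f"{g}_panel_at", +panel_rho, gene_symbol=g)
        for g in overlap_res
    ] + [
        PlantedCorrelation(f"{g}_panel_at", -panel_rho, gene_symbol=g)
        for g in overlap_sens
    ]
    panel_expr, panel_response, panel_map = gen_panel(
        PanelSpec(
            n_probes=n_panel_probes,
            planted=planted_panel,
            seed=int(rng.integers(2**31 - 1)),
        )
    )
    # resistance-associated genes sit HIGHER in resistant lines: negative
    # sensitive-minus-resistant log2 fold change
    planted_paired = (
        [PlantedFoldChange(g, -paired_log2_fc) for g in overlap_res]
        + [PlantedFoldChange(g, +paired_log2_fc) for g in overlap_sens]
        + [
            PlantedFoldChange(f"HT12ONLY_S{k + 1}", +paired_log2_fc)
            for k in range(extra_paired_sens)
        ]
        + [
            PlantedFoldChange(f"HT12ONLY_R{k + 1}", -paired_log2_fc)
            for k in range(extra_paired_res)
        ]
    )
    paired_expr, paired_design, paired_map = gen_paired_experiment(
        PairedSpec(
            n_probes=n_paired_probes,
            planted=planted_paired,
            pair_names=("MM", "MCL"),
            seed=int(rng.integers(2**31 - 1)),
        )
    )
    return IntegratedStudy(
        panel_expr,
        panel_response,
        panel_map,
        paired_expr,
        paired_design,
        paired_map,
        tuple(overlap_sens),
        tuple(overlap_res),
    )
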