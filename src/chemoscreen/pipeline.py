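"""End-to-end orchestration of the two-tier screen from one configuration.

Stage order: primary panel screen (Pearson r vs log10 GI50, ranked tables)
-> paired differential screen (detection filter, optional normalisation,
moderated tests, FDR, congruence rule) -> directional signature
intersection.  Outputs are byte-deterministic for identical inputs and
config, and a machine-readable manifest records input checksums, every
threshold as applied, the seed, and the package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlation import collapse_unique_transcripts, run_primary_screen
from .integration import GeneSignature, IntegratedSignature, intersect_signatures
from .io import (
    ExpressionMatrix,
    PairRecord,
    PairedDesign,
    read_drug_response,
    read_expression_matrix,
    read_probe_gene_map,
    write_correlation_table,
)
from .paired import (
    attach_fdr,
    congruence_filter,
    detection_filter,
    moderated_pair_test,
    normalize_log_quantile,
    records_to_frame,
)

logger = logging.getLogger("chemoscreen")


@dataclass
class Thresholds:
    alpha: float = 0.05  # tier-1 two-tailed significance cutoff
    detection_alpha: float = 0.01  # valid-signal detection P cutoff
    fc_min: float = 1.5  # linear fold-change threshold (exclusive)
    raw_alpha: float = 0.01  # per-pair raw P cutoff
    q_alpha: float = 0.05  # FDR cutoff on the combined P

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha out of range")
        if not (0.0 < self.detection_alpha < 1.0):
            raise ValueError("detection_alpha out of range")
        if not (self.fc_min > 1.0):
            raise ValueError("fc_min must exceed 1")
        if not (0.0 < self.raw_alpha < 1.0 and 0.0 < self.q_alpha < 1.0):
            raise ValueError("raw_alpha/q_alpha out of range")


@dataclass
class PipelineConfig:
    panel_expression: str
    panel_response: str
    panel_annotation: str
    paired_expression: str
    paired_detection: str | None
    paired_annotation: str
    design: str
    out_dir: str
    thresholds: Thresholds = field(default_factory=Thresholds)
    paired_scale: str = "log2"  # "raw" triggers log2+quantile normalisation
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thr = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)


def read_design(path: str | Path) -> PairedDesign:
    """Read the structured design config: pair name -> sample-ID lists."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    pairs = [
        PairRecord(p["name"], list(p["sensitive"]), list(p["resistant"]))
        for p in raw["pairs"]
    ]
    return PairedDesign(pairs)


def write_design(design: PairedDesign, path: str | Path) -> None:
    payload = {
        "pairs": [
            {
                "name": p.pair_name,
                "sensitive": list(p.sensitive_samples),
                "resistant": list(p.resistant_samples),
            }
            for p in design.pairs
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _signature_frame(sig: IntegratedSignature) -> pd.DataFrame:
    rows = [
        {"gene": g, "direction": "sensitivity_associated", "source": "both_screens"}
        for g in sorted(sig.sensitivity_overlap)
    ] + [
        {"gene": g, "direction": "resistance_associated", "source": "both_screens"}
        for g in sorted(sig.resistance_overlap)
    ]
    return pd.DataFrame(rows, columns=["gene", "direction", "source"])


def run_two_tier_screen(config: PipelineConfig) -> IntegratedSignature:
    """Execute panel screen -> paired screen -> integration; write all outputs.

    Writes ranked positive/negative correlation tables, the per-probe
    differential table, the integrated signature TSV, and ``manifest.json``.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds

    # ---- tier 1: panel screen
    try:
        panel_expr = read_expression_matrix(config.panel_expression)
        panel_resp = read_drug_response(config.panel_response)
        panel_map = read_probe_gene_map(config.panel_annotation)
        pos, neg = run_primary_screen(panel_expr, panel_resp, thr.alpha, panel_map)
        panel_res_genes, panel_sens_genes = collapse_unique_transcripts(
            pos, neg, panel_map
        )
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"primary screen failed: {exc}") from exc
    write_correlation_table(pos.records, out / "panel_resistance_associated.tsv")
    write_correlation_table(neg.records, out / "panel_sensitivity_associated.tsv")

    # ---- tier 2: paired screen
    try:
        paired_expr = read_expression_matrix(
            config.paired_expression,
            detection_path=config.paired_detection,
            scale=config.paired_scale,
        )
        paired_map = read_probe_gene_map(config.paired_annotation)
        design = read_design(config.design)
        if paired_expr.detection_p is not None:
            paired_expr = detection_filter(paired_expr, thr.detection_alpha)
        if paired_expr.scale == "raw":
            paired_expr = normalize_log_quantile(paired_expr)
        records = moderated_pair_test(paired_expr, design, probe_gene_map=paired_map)
        attach_fdr(records)
        paired_sens_genes, paired_res_genes = congruence_filter(
            records, thr.fc_min, thr.raw_alpha, thr.q_alpha
        )
    except Exception as exc:
        raise RuntimeError(f"paired screen failed: {exc}") from exc
    records_to_frame(records).to_csv(out / "paired_differential.tsv", sep="\t", index=False)

    # ---- tier 3: integration
    signature = intersect_signatures(
        GeneSignature.from_genes("primary_panel", "sensitivity_associated", panel_sens_genes),
        GeneSignature.from_genes("primary_panel", "resistance_associated", panel_res_genes),
        GeneSignature.from_genes("paired_lines", "sensitivity_associated", paired_sens_genes),
        GeneSignature.from_genes("paired_lines", "resistance_associated", paired_res_genes),
    )
    _signature_frame(signature).to_csv(out / "integrated_signature.tsv", sep="\t", index=False)

    inputs = {
        "panel_expression": config.panel_expression,
        "panel_response": config.panel_response,
        "panel_annotation": config.panel_annotation,
        "paired_expression": config.paired_expression,
        "paired_detection": config.paired_detection,
        "paired_annotation": config.paired_annotation,
        "design": config.design,
    }
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": asdict(thr),
        "inputs": {k: (_sha256(v) if v else None) for k, v in inputs.items()},
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.glob("*.tsv"))
        },
        "signature": {
            "sensitivity_overlap": sorted(signature.sensitivity_overlap),
            "resistance_overlap": sorted(signature.resistance_overlap),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return signature
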