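from pathlib import Path

import pytest

import chemoscreen as cs
from chemoscreen.io import (
    write_detection_p,
    write_drug_response,
    write_expression_matrix,
    write_probe_gene_map,
)
from chemoscreen.pipeline import PipelineConfig, write_design


@pytest.fixture(scope="session")
def small_study() -> cs.IntegratedStudy:
    """A compact matched two-tier study with the planted 1+6 overlap."""
    return cs.gen_integrated_study(
        seed=42, n_panel_probes=1200, n_paired_probes=1200
    )


def write_study(study: cs.IntegratedStudy, d: Path, seed: int = 0) -> PipelineConfig:
    """Serialise a study to TSVs and return a ready pipeline config."""
    write_expression_matrix(study.panel_expr, d / "panel_expr.tsv")
    write_drug_response(study.panel_response, d / "panel_resp.tsv")
    write_probe_gene_map(study.panel_map, d / "panel_annot.tsv")
    write_expression_matrix(study.paired_expr, d / "paired_expr.tsv")
    write_detection_p(study.paired_expr, d / "paired_det.tsv")
    write_probe_gene_map(study.paired_map, d / "paired_annot.tsv")
    write_design(study.paired_design, d / "design.yaml")
    return PipelineConfig(
        panel_expression=str(d / "panel_expr.tsv"),
        panel_response=str(d / "panel_resp.tsv"),
        panel_annotation=str(d / "panel_annot.tsv"),
        paired_expression=str(d / "paired_expr.tsv"),
        paired_detection=str(d / "paired_det.tsv"),
        paired_annotation=str(d / "paired_annot.tsv"),
        design=str(d / "design.yaml"),
        out_dir=str(d / "out"),
        seed=seed,
    )
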