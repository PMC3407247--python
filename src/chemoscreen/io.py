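"""Core data containers and tabular readers/writers.

Every stage of the screen consumes and emits plain tab-separated text:
a probe x sample expression matrix (optionally with a companion detection-P
grid of identical shape), a two-column drug-response table of molar GI50
concentrations, a probe -> gene-symbol annotation, and ranked correlation
tables following the Rank / Probe Set ID / Gene Symbol / r / P value layout.

Expression values are held in a :class:`pandas.DataFrame` with probes as
rows.  Missing cells are kept as NaN ("absent"), never coerced to zero;
downstream statistics use pairwise-complete observations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("chemoscreen")

CORRELATION_TABLE_COLUMNS = ["rank", "probe_set_id", "gene_symbol", "r", "p_value"]


class FormatError(ValueError):
    """Malformed input table (duplicate identifiers, bad header, ...)."""


class ParseError(ValueError):
    """A cell could not be parsed as a number."""


class AnnotationError(KeyError):
    """A probe has no gene-symbol annotation."""


class ContractError(ValueError):
    """An operation was called outside its contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Probe x sample expression grid.

    Parameters
    ----------
    values
        DataFrame with probe IDs as the index and sample IDs as columns.
        Log2 intensities unless ``scale`` is ``"raw"``.
    detection_p
        Optional per-entry detection P values in [0, 1], same shape as
        ``values``.
    scale
        ``"log2"`` (default) or ``"raw"`` for unlogged positive intensities.
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate probe ID: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample ID: {dup!r}")
        arr = self.values.to_numpy()
        if arr.size and np.isinf(arr).any():
            raise ValueError("expression values must be finite or absent (NaN)")
        if self.detection_p is not None:
            if self.detection_p.shape != self.values.shape:
                raise FormatError(
                    "detection-P grid shape "
                    f"{self.detection_p.shape} != expression shape {self.values.shape}"
                )
            dp = self.detection_p.to_numpy()
            with np.errstate(invalid="ignore"):
                if ((dp < 0) | (dp > 1)).any():
                    raise ValueError("detection P values must lie in [0, 1]")
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"unknown scale flag {self.scale!r}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        det = self.detection_p[list(sample_ids)] if self.detection_p is not None else None
        return ExpressionMatrix(self.values[list(sample_ids)], det, self.scale)


@dataclass
class DrugResponseProfile:
    """Per-sample GI50 (molar) and its base-10 logarithm — the tier-1 phenotype."""

    sample_ids: list[str]
    gi50: np.ndarray

    def __post_init__(self) -> None:
        self.gi50 = np.asarray(self.gi50, dtype=float)
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise FormatError("duplicate sample IDs in drug response profile")
        if self.gi50.shape != (len(self.sample_ids),):
            raise ValueError("gi50 length must match sample_ids")
        if not np.all(np.isfinite(self.gi50)) or np.any(self.gi50 <= 0):
            raise ValueError("GI50 concentrations must be finite and > 0")

    @property
    def log10_gi50(self) -> np.ndarray:
        return np.log10(self.gi50)

    def as_series(self) -> pd.Series:
        return pd.Series(self.log10_gi50, index=self.sample_ids, name="log10_gi50")


@dataclass
class ProbeGeneMap:
    """Many-probes-to-one-gene annotation."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        for probe, symbol in self.entries.items():
            if not symbol or not str(symbol).strip():
                raise ValueError(f"empty gene symbol for probe {probe!r}")

    def gene_for(self, probe_id: str) -> str:
        try:
            return self.entries[probe_id]
        except KeyError:
            raise AnnotationError(f"probe {probe_id!r} has no gene annotation") from None

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.entries


@dataclass
class PairRecord:
    pair_name: str
    sensitive_samples: list[str]
    resistant_samples: list[str]

    def __post_init__(self) -> None:
        if not self.sensitive_samples or not self.resistant_samples:
            raise ValueError(f"pair {self.pair_name!r}: both groups must be nonempty")
        if set(self.sensitive_samples) & set(self.resistant_samples):
            raise ValueError(f"pair {self.pair_name!r}: groups overlap")


@dataclass
class PairedDesign:
    """Sensitive/resistant group structure; the study design has two pairs
    (a myeloma pair and a mantle-cell-lymphoma pair), the type permits >= 1."""

    pairs: list[PairRecord]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("design needs at least one pair")
        names = [p.pair_name for p in self.pairs]
        if len(names) != len(set(names)):
            raise ValueError("duplicate pair names")

    def all_samples(self) -> list[str]:
        out: list[str] = []
        for p in self.pairs:
            out.extend(p.sensitive_samples)
            out.extend(p.resistant_samples)
        return out

    def validate_against(self, expr: ExpressionMatrix) -> None:
        missing = [s for s in self.all_samples() if s not in expr.values.columns]
        if missing:
            raise ValueError(f"design samples absent from expression matrix: {missing}")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, skiprows: int = 0) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path, sep="\t", index_col=0, skiprows=skiprows, float_precision="round_trip"
    )
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns.name = None
    return df


def _coerce_numeric(raw: pd.DataFrame) -> pd.DataFrame:
    """Validate an all-numeric body, naming the first offending cell."""
    numeric = pd.DataFrame(index=raw.index, dtype=float)
    for j, col in enumerate(raw.columns):
        series = raw[col]
        if series.dtype == object:  # at least one unparseable cell
            converted = pd.to_numeric(series, errors="coerce")
            as_str = series.astype(str)
            bad = converted.isna() & series.notna() & (as_str.str.strip() != "")
            if bad.any():
                i = int(np.nonzero(bad.to_numpy())[0][0])
                raise ParseError(
                    f"non-numeric cell at probe {raw.index[i]!r}, sample {col!r} "
                    f"(row {i + 1}, column {j + 1}): {series.iloc[i]!r}"
                )
            numeric[col] = converted.astype(float)
        else:
            numeric[col] = series.astype(float)
    return numeric


def read_expression_matrix(
    path: str | Path,
    dialect: str = "tsv",
    detection_path: str | Path | None = None,
    scale: str = "log2",
) -> ExpressionMatrix:
    """Read a probes-as-rows expression TSV.

    ``dialect="gct_like"`` skips two leading header lines (version tag and
    dimension line) before the table proper.  Empty cells become NaN
    ("absent"), never zero.  Duplicate probe or sample identifiers and
    non-numeric cells raise with the offending identifier / coordinates.
    """
    if dialect not in ("tsv", "gct_like"):
        raise ValueError(f"unknown dialect {dialect!r}")
    skip = 2 if dialect == "gct_like" else 0
    numeric = _coerce_numeric(_read_table(path, skiprows=skip))
    det = None
    if detection_path is not None:
        det = _coerce_numeric(_read_table(detection_path, skiprows=skip))
        det = det.reindex(index=numeric.index, columns=numeric.columns)
    return ExpressionMatrix(numeric, det, scale=scale)


def read_drug_response(path: str | Path) -> DrugResponseProfile:
    """Read the two-column ``sample_id <TAB> gi50_molar`` table."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    if df.shape[1] < 2:
        raise FormatError("drug response table needs two columns: sample_id, gi50_molar")
    samples = df.iloc[:, 0].tolist()
    if len(samples) != len(set(samples)):
        raise FormatError("sample repeated in drug response table")
    gi50 = pd.to_numeric(df.iloc[:, 1], errors="raise").to_numpy()
    return DrugResponseProfile(samples, gi50)


def read_probe_gene_map(path: str | Path) -> ProbeGeneMap:
    """Read ``probe_id <TAB> gene_symbol`` annotation."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    probes = df.iloc[:, 0].tolist()
    if len(probes) != len(set(probes)):
        raise FormatError("probe repeated in annotation table")
    return ProbeGeneMap(dict(zip(probes, df.iloc[:, 1].tolist())))


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


# %.17g round-trips every IEEE double bit-exactly
_FLOAT_FMT = "%.17g"


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="probe_id", float_format=_FLOAT_FMT)


def write_detection_p(expr: ExpressionMatrix, path: str | Path) -> None:
    if expr.detection_p is None:
        raise ValueError("matrix carries no detection-P grid")
    expr.detection_p.to_csv(
        path, sep="\t", index_label="probe_id", float_format=_FLOAT_FMT
    )


def write_drug_response(profile: DrugResponseProfile, path: str | Path) -> None:
    pd.DataFrame({"sample_id": profile.sample_ids, "gi50_molar": profile.gi50}).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def write_probe_gene_map(pmap: ProbeGeneMap, path: str | Path) -> None:
    pd.DataFrame(
        {"probe_id": list(pmap.entries), "gene_symbol": list(pmap.entries.values())}
    ).to_csv(path, sep="\t", index=False)


def write_correlation_table(records: Sequence, path: str | Path) -> None:
    """Write ranked correlation records in the published table layout.

    Columns: ``rank, probe_set_id, gene_symbol, r, p_value`` in rank order.
    Records must already be ranked 1..k.
    """
    ranks = [rec.rank for rec in records]
    if any(r is None for r in ranks) or ranks != list(range(1, len(records) + 1)):
        raise ContractError("records must be ranked 1..k before writing")
    df = pd.DataFrame(
        {
            "rank": ranks,
            "probe_set_id": [rec.probe_id for rec in records],
            "gene_symbol": [rec.gene_symbol for rec in records],
            "r": [repr(float(rec.r)) for rec in records],
            "p_value": [repr(float(rec.p_value)) for rec in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_correlation_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_set_id": str, "gene_symbol": str})
    missing = [c for c in CORRELATION_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"correlation table missing columns {missing}")
    return df
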