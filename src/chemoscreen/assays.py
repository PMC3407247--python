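"""Assay-level calculations: NADPH kinetics, G6PD-specific activity,
normalised cell death, and the geNorm qPCR normalisation factor.

The G6PD activity assay reads NADPH fluorescence (341 nm) every minute for
30 minutes; the enzymatic rate is the least-squares slope of signal against
time.  G6PD-specific activity excludes the downstream 6PGD contribution by
subtracting the 6PG-only rate from the G6P+6PG rate.  Flow-cytometric cell
death is normalised so that every untreated sample sits at exactly 0%.
qPCR loading is corrected by the geometric mean of reference-gene
quantities (the geNorm normalisation factor).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .io import ContractError

logger = logging.getLogger("chemoscreen")

SUBSTRATE_CONDITIONS = ("G6P", "6PG", "G6P+6PG")


@dataclass
class KineticTrace:
    """Fluorescence-vs-time trace for one substrate condition.

    Times in minutes, strictly increasing, at least 3 points.
    """

    times: np.ndarray
    signal: np.ndarray
    label: str = "G6P"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape:
            raise ValueError("times and signal must have equal length")
        if self.times.size < 3:
            raise ContractError("a kinetic trace needs >= 3 time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.label not in SUBSTRATE_CONDITIONS:
            raise ValueError(f"unknown substrate condition {self.label!r}")


@dataclass
class ViabilityMeasurement:
    """DAPI-negative (viable) fraction for one condition."""

    condition: str
    viable_fraction: float
    treated: bool
    matched_untreated_id: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.viable_fraction <= 1.0):
            raise ValueError("viable_fraction must lie in [0, 1]")


@dataclass
class QpcrMeasurement:
    gene: str
    relative_quantity: float
    is_reference: bool = False

    def __post_init__(self) -> None:
        if not (self.relative_quantity > 0):
            raise ValueError("relative_quantity must be positive")


def kinetic_rate(trace: KineticTrace) -> float:
    """Least-squares slope of signal vs time (signal units per minute)."""
    t = trace.times - trace.times.mean()
    s = trace.signal - trace.signal.mean()
    return float((t @ s) / (t @ t))


def kinetic_rate_stderr(trace: KineticTrace) -> float:
    """Analytic standard error of the fitted slope."""
    n = trace.times.size
    slope = kinetic_rate(trace)
    t = trace.times - trace.times.mean()
    resid = (trace.signal - trace.signal.mean()) - slope * t
    s2 = float(resid @ resid) / (n - 2)
    return math.sqrt(s2 / float(t @ t))


def g6pd_specific_activity(rate_both: float, rate_6pg: float) -> float:
    """G6PD-specific rate: total (G6P+6PG) minus 6PGD-only activity.

    May be negative with noisy rates; returned as-is with a warning, never
    clamped.
    """
    diff = float(rate_both) - float(rate_6pg)
    if diff < 0:
        logger.warning("negative G6PD-specific activity (%g); check rates", diff)
    return diff


def normalize_cell_death(
    treated: ViabilityMeasurement, untreated: ViabilityMeasurement
) -> float:
    """Normalised cell-death percentage relative to the matched untreated sample.

    100 - 100 * (treated viable fraction / untreated viable fraction); the
    untreated sample against itself is exactly 0%.  Values below 0 (treatment
    "improved" viability) are allowed and flagged.
    """
    if untreated.viable_fraction == 0:
        raise ValueError("untreated viable fraction is zero; cannot normalise")
    if treated is untreated or treated.viable_fraction == untreated.viable_fraction:
        return 0.0
    pct = 100.0 - 100.0 * (treated.viable_fraction / untreated.viable_fraction)
    if pct < 0:
        logger.warning("negative normalised cell death (%g%%)", pct)
    return pct


def genorm_normalization_factor(refs: list[QpcrMeasurement]) -> float:
    """Geometric mean of reference-gene relative quantities (geNorm factor)."""
    ref_quantities = [m.relative_quantity for m in refs if m.is_reference]
    if len(ref_quantities) < 2:
        raise ContractError("need >= 2 reference genes for a normalisation factor")
    logs = np.log(np.asarray(ref_quantities, dtype=float))
    return float(np.exp(logs.mean()))
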