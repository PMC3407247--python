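"""Tier-1 screen: per-probe Pearson correlation with log10(GI50).

Each probe's expression across a cell-line panel (typically 60 lines) is
correlated with the log10-transformed GI50 of the drug.  Significance uses
the classical conversion of the correlation coefficient to a Student-t
statistic,

    t = r * sqrt(df) / sqrt(1 - r^2),      df = n - 2,

followed by the two-tailed tail probability of the t distribution.
Significant probes are split by the sign of r into resistance-associated
(r > 0: high expression tracks high GI50) and sensitivity-associated
(r < 0) lists, ranked by descending |r|, and collapsed to unique gene
symbols.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import (
    ContractError,
    DrugResponseProfile,
    ExpressionMatrix,
    ProbeGeneMap,
)

logger = logging.getLogger("chemoscreen")

#: Smallest P reported for a correlation of exactly +/-1 (t is infinite).
P_FLOOR = float(np.finfo(float).tiny)


class DegenerateProbeError(ValueError):
    """Zero variance: Pearson r is undefined for this probe."""


class InsufficientDataError(ValueError):
    """Fewer than 3 pairwise-complete observations."""


@dataclass
class CorrelationRecord:
    """Per-probe tier-1 statistics (one row of the ranked output tables)."""

    probe_id: str
    gene_symbol: str
    n_used: int
    r: float
    t_stat: float
    df: int
    p_value: float
    rank: int | None = None


@dataclass
class DirectionalProbeList:
    """Significant probes sharing a sign of r, ranked by descending |r|."""

    direction: str  # "resistance_associated" (r > 0) | "sensitivity_associated" (r < 0)
    records: list[CorrelationRecord] = field(default_factory=list)

    @property
    def unique_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.gene_symbol)
        return list(seen)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation of two equal-length vectors.

    Pairwise-complete: entries where either value is missing are dropped.
    Raises :class:`InsufficientDataError` below 3 complete pairs and
    :class:`DegenerateProbeError` when either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise InsufficientDataError(f"only {x.size} complete pairs (need >= 3)")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise DegenerateProbeError("zero variance; correlation undefined")
    r = float(xc @ yc) / (sx * sy)
    return float(min(1.0, max(-1.0, r)))


def t_from_r(r: float, df: int) -> float:
    """Student-t statistic of a correlation coefficient: r*sqrt(df)/sqrt(1-r^2)."""
    if df < 1:
        raise ContractError(f"df must be >= 1, got {df}")
    if abs(r) > 1:
        raise ValueError(f"|r| must be <= 1, got {r}")
    if abs(r) == 1.0:
        return math.copysign(math.inf, r)
    return r * math.sqrt(df) / math.sqrt(1.0 - r * r)


def p_from_t(t: float, df: int) -> float:
    """Two-tailed Student-t tail probability; returns a value in (0, 1].

    An infinite t (|r| = 1 exactly) is reported as the smallest positive
    representable float rather than zero, preserving the (0, 1] contract.
    """
    if df < 1:
        raise ContractError(f"df must be >= 1, got {df}")
    if math.isinf(t):
        logger.warning("infinite t statistic: P below machine resolution")
        return P_FLOOR
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return max(min(p, 1.0), P_FLOOR)


def correlation_p(r: float, df: int) -> float:
    """Convenience composition p_from_t(t_from_r(r, df), df)."""
    return p_from_t(t_from_r(r, df), df)


def _screen_matrix(
    values: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised pairwise-complete per-row correlation with ``y``.

    Returns (r, n_used, degenerate_mask).  Rows with < 3 complete pairs or
    zero variance are flagged degenerate; their r is NaN.
    """
    finite = np.isfinite(values) & np.isfinite(y)[None, :]
    xm = np.where(finite, values, 0.0)
    ym = np.where(finite, y[None, :], 0.0)
    n = finite.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = xm.sum(axis=1) / n
        my = ym.sum(axis=1) / n
        xc = np.where(finite, values - mx[:, None], 0.0)
        yc = np.where(finite, y[None, :] - my[:, None], 0.0)
        sxx = (xc * xc).sum(axis=1)
        syy = (yc * yc).sum(axis=1)
        sxy = (xc * yc).sum(axis=1)
        r = sxy / np.sqrt(sxx * syy)
    degenerate = (n < 3) | (sxx <= 0) | (syy <= 0)
    r = np.where(degenerate, np.nan, np.clip(r, -1.0, 1.0))
    return r, n.astype(int), degenerate


def run_primary_screen(
    expr: ExpressionMatrix,
    response: DrugResponseProfile,
    alpha: float = 0.05,
    probe_gene_map: ProbeGeneMap | None = None,
) -> tuple[DirectionalProbeList, DirectionalProbeList]:
    """Correlate every probe with log10(GI50) and split significant hits.

    Returns ``(resistance_associated, sensitivity_associated)`` lists:
    records with two-tailed P < ``alpha``, partitioned by the sign of r
    (probes with r exactly 0 belong to neither), each ranked by descending
    |r| with ties broken by ascending probe ID.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ContractError(f"alpha must be in [0, 1], got {alpha}")
    common = [s for s in expr.sample_ids if s in set(response.sample_ids)]
    if len(common) < 3:
        raise ContractError(
            f"only {len(common)} samples shared between expression and response"
        )
    y = response.as_series().reindex(common).to_numpy()
    values = expr.values[common].to_numpy()
    r_all, n_all, degenerate = _screen_matrix(values, y)
    if degenerate.all():
        logger.warning("all probes degenerate; empty screen result")
    n_skipped = int(degenerate.sum())
    if n_skipped:
        logger.info("skipped %d degenerate probes (zero variance or n<3)", n_skipped)

    pos = DirectionalProbeList("resistance_associated")
    neg = DirectionalProbeList("sensitivity_associated")
    probe_ids = expr.probe_ids
    for i in np.nonzero(~degenerate)[0]:
        r = float(r_all[i])
        n_used = int(n_all[i])
        df = n_used - 2
        t = t_from_r(r, df)
        p = p_from_t(t, df)
        if p >= alpha or r == 0.0:
            continue
        pid = probe_ids[i]
        gene = probe_gene_map.gene_for(pid) if probe_gene_map is not None else pid
        rec = CorrelationRecord(pid, gene, n_used, r, t, df, p)
        (pos if r > 0 else neg).records.append(rec)

    for lst in (pos, neg):
        lst.records.sort(key=lambda rec: (-abs(rec.r), rec.probe_id))
        for k, rec in enumerate(lst.records, start=1):
            rec.rank = k
    return pos, neg


def collapse_unique_transcripts(
    positive: DirectionalProbeList,
    negative: DirectionalProbeList,
    probe_gene_map: ProbeGeneMap,
) -> tuple[set[str], set[str]]:
    """Collapse significant probes to unique gene symbols per direction.

    A gene whose probes land in both directions is removed from both sets
    and logged as conflicting (the conservative reading: an ambiguous sign
    cannot anchor a directional signature).
    """
    pos_genes = {probe_gene_map.gene_for(rec.probe_id) for rec in positive.records}
    neg_genes = {probe_gene_map.gene_for(rec.probe_id) for rec in negative.records}
    conflicts = pos_genes & neg_genes
    for gene in sorted(conflicts):
        logger.warning("gene %s has probes in both directions; excluded", gene)
    return pos_genes - conflicts, neg_genes - conflicts
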