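"""Tier-2 screen: moderated differential expression across sensitive/resistant pairs.

The secondary screen compares paired drug-sensitive and drug-resistant cell
lines (the study design: one multiple-myeloma pair and one mantle-cell-
lymphoma pair, replicated arrays per line).  The stages, in run order:

1. detection filtering — a probe is a valid signal if its detection P value
   beats the cutoff in at least one sample;
2. log2 + full quantile normalisation across samples;
3. per-probe empirical-Bayes variance moderation: residual variances are
   shrunk toward a prior (s0^2, d0) estimated by moment-matching the log
   residual variances against a scaled-F model, the classical moderated-t
   construction;
4. per-pair moderated t tests of sensitive-vs-resistant group means, with
   the intersection-union combined P = max over pairs;
5. Benjamini-Hochberg FDR on the combined P;
6. the congruence rule: a probe passes only if every pair shows the same
   direction, a linear fold change beyond the threshold, and a raw P below
   its cutoff, with the FDR q below its cutoff.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import ContractError, ExpressionMatrix, PairedDesign, ProbeGeneMap

logger = logging.getLogger("chemoscreen")


@dataclass
class ModerationParams:
    """Empirical-Bayes variance-shrinkage hyperparameters.

    ``prior_df`` may be ``math.inf`` (no excess dispersion: every probe
    shares one variance) and the moderated variance is the convex
    combination (prior_df*prior_var + df*s^2) / (prior_df + df).
    ``prior_df = 0`` switches shrinkage off (ordinary t), the limiting case.
    """

    prior_df: float
    prior_var: float

    def __post_init__(self) -> None:
        if not (self.prior_df >= 0):
            raise ValueError("prior_df must be >= 0 (possibly inf)")
        if not (self.prior_var > 0):
            raise ValueError("prior_var must be positive")


@dataclass
class PairStats:
    fold_change: float
    log2_fc: float
    moderated_t: float
    raw_p: float


@dataclass
class DifferentialRecord:
    """Per-probe tier-2 output: per-pair statistics plus combined P and q."""

    probe_id: str
    gene_symbol: str
    pair_stats: dict[str, PairStats]
    combined_p: float
    fdr_q: float = float("nan")
    congruent: bool = False
    direction: str = "none"  # higher_in_sensitive | higher_in_resistant | none


# ---------------------------------------------------------------------------
# Detection filter and normalisation
# ---------------------------------------------------------------------------


def detection_filter(expr: ExpressionMatrix, detection_alpha: float = 0.01) -> ExpressionMatrix:
    """Keep probes detected (P < ``detection_alpha``) in at least one sample."""
    if expr.detection_p is None:
        raise ContractError(
            "no detection-P grid present; disable the filter explicitly instead"
        )
    if not (0.0 < detection_alpha < 1.0):
        raise ContractError(f"detection_alpha must be in (0,1), got {detection_alpha}")
    keep = (expr.detection_p.to_numpy() < detection_alpha).any(axis=1)
    retained = expr.values.loc[keep]
    logger.info("detection filter: retained %d of %d probes", keep.sum(), expr.n_probes)
    return ExpressionMatrix(retained, expr.detection_p.loc[keep], scale=expr.scale)


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Full quantile normalisation: every column gets the mean sorted profile."""
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    reference = sorted_vals.mean(axis=1)
    out = np.empty_like(values)
    ranks = np.empty_like(order)
    rows = np.arange(values.shape[0])[:, None]
    np.put_along_axis(ranks, order, np.broadcast_to(rows, values.shape), axis=0)
    out = reference[ranks]
    return out


def normalize_log_quantile(expr: ExpressionMatrix) -> ExpressionMatrix:
    """log2-transform raw intensities, then quantile-normalise across samples."""
    if expr.scale != "raw":
        raise ContractError("normalize_log_quantile expects raw-scale intensities")
    values = expr.values.to_numpy()
    if np.nanmin(values) <= 0:
        raise ValueError(
            "nonpositive intensity encountered; configure an offset explicitly"
        )
    logged = np.log2(values)
    normed = quantile_normalize(logged)
    df = pd.DataFrame(normed, index=expr.values.index, columns=expr.values.columns)
    return ExpressionMatrix(df, expr.detection_p, scale="log2")


# ---------------------------------------------------------------------------
# Empirical-Bayes moderation
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    if y <= 0:
        return math.inf
    # trigamma(x) ~ 1/x for large x, ~ 1/x^2 near 0
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        tri_prime = float(special.polygamma(2, x))
        delta = tri * (1.0 - tri / y) / tri_prime
        x += delta
        if abs(delta) < 1e-10 * x:
            break
    return x


def estimate_moderation(residual_vars: np.ndarray, residual_df: int) -> ModerationParams:
    """Moment-match log residual variances to a scaled-F model.

    Under the hierarchical model s^2 ~ s0^2 * F(d, d0), log s^2 has variance
    trigamma(d/2) + trigamma(d0/2); the excess of the observed spread of
    log variances over the sampling term trigamma(d/2) identifies d0.  When
    there is no excess the prior is degenerate: d0 = inf and prior_var =
    the mean variance.
    """
    v = np.asarray(residual_vars, dtype=float)
    if residual_df < 1:
        raise ContractError("residual_df must be >= 1")
    if v.size < 50:
        raise ContractError(f"need >= 50 probes to estimate moderation, got {v.size}")
    if np.any(v < 0) or not np.all(np.isfinite(v)):
        raise ValueError("residual variances must be finite and >= 0")
    if np.all(v == 0):
        raise ValueError("all residual variances are zero; degenerate data")
    pos = v[v > 0]
    if pos.size < v.size:
        logger.warning("dropping %d zero variances from moderation fit", v.size - pos.size)
    d = float(residual_df)
    e = np.log(pos) - special.digamma(d / 2.0) + math.log(d / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    excess = e_var - float(special.polygamma(1, d / 2.0))
    if excess <= 0:
        return ModerationParams(prior_df=math.inf, prior_var=float(v.mean()))
    d0 = 2.0 * _trigamma_inverse(excess)
    log_s0sq = e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
    return ModerationParams(prior_df=d0, prior_var=float(math.exp(log_s0sq)))


def moderated_variance(s2: np.ndarray, df: float, params: ModerationParams) -> np.ndarray:
    """Posterior (shrunk) variance — convex combination of prior and sample."""
    s2 = np.asarray(s2, dtype=float)
    if math.isinf(params.prior_df):
        return np.full_like(s2, params.prior_var)
    if params.prior_df == 0:
        return s2.copy()
    return (params.prior_df * params.prior_var + df * s2) / (params.prior_df + df)


def moderated_pair_test(
    expr: ExpressionMatrix,
    design: PairedDesign,
    params: ModerationParams | None = None,
    probe_gene_map: ProbeGeneMap | None = None,
) -> list[DifferentialRecord]:
    """Per-probe, per-pair moderated t tests on a normalised log2 matrix.

    The residual variance is pooled over ALL design groups (the one-way
    layout over 2 pairs x 2 phenotypes), moderated with ``params`` (fitted
    from the data when omitted), and reused in every pair's contrast.  The
    combined P is the max over pairs — the intersection-union test for
    "deviates in every pair".
    """
    if expr.scale != "log2":
        raise ContractError("moderated_pair_test expects a log2-scale matrix")
    design.validate_against(expr)
    groups: list[list[str]] = []
    for pair in design.pairs:
        for grp in (pair.sensitive_samples, pair.resistant_samples):
            if len(grp) < 2:
                raise ValueError(
                    f"pair {pair.pair_name!r}: every group needs >= 2 replicates"
                )
            groups.append(grp)

    values = expr.values
    n_total = sum(len(g) for g in groups)
    n_groups = len(groups)
    resid_df = n_total - n_groups
    if resid_df < 1:
        raise ValueError("no residual degrees of freedom in design")

    # pooled within-group sums of squares across the full layout
    ss = np.zeros(expr.n_probes)
    group_means: dict[int, np.ndarray] = {}
    for gi, grp in enumerate(groups):
        sub = values[grp].to_numpy()
        mean = sub.mean(axis=1)
        group_means[gi] = mean
        ss += ((sub - mean[:, None]) ** 2).sum(axis=1)
    s2 = ss / resid_df

    if params is None:
        params = estimate_moderation(s2, resid_df)
    v_mod = moderated_variance(s2, resid_df, params)
    total_df = (
        math.inf if math.isinf(params.prior_df) else params.prior_df + resid_df
    )

    records: list[DifferentialRecord] = []
    probe_ids = expr.probe_ids
    per_pair: list[tuple[str, np.ndarray, np.ndarray, float]] = []
    for pi, pair in enumerate(design.pairs):
        m_sens = group_means[2 * pi]
        m_res = group_means[2 * pi + 1]
        scale = 1.0 / len(pair.sensitive_samples) + 1.0 / len(pair.resistant_samples)
        per_pair.append((pair.pair_name, m_sens, m_res, scale))

    dist = stats.norm if math.isinf(total_df) else stats.t(total_df)
    pair_arrays = []
    for name, m_sens, m_res, scale in per_pair:
        diff = m_sens - m_res
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / np.sqrt(v_mod * scale)
            t = np.where(
                v_mod == 0, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t
            )
        p = 2.0 * dist.sf(np.abs(t))
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        pair_arrays.append((name, diff, t, p))

    combined_p = np.max(np.vstack([p for _, _, _, p in pair_arrays]), axis=0)
    for i, pid in enumerate(probe_ids):
        gene = probe_gene_map.gene_for(pid) if probe_gene_map is not None else pid
        pstats = {
            name: PairStats(
                fold_change=float(2.0 ** diff[i]),
                log2_fc=float(diff[i]),
                moderated_t=float(t[i]),
                raw_p=float(p[i]),
            )
            for name, diff, t, p in pair_arrays
        }
        records.append(
            DifferentialRecord(pid, gene, pstats, combined_p=float(combined_p[i]))
        )
    return records


# ---------------------------------------------------------------------------
# FDR and congruence filtering
# ---------------------------------------------------------------------------


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    q(i) = min_{j >= i} m * p_(j) / j on the sorted p's, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def attach_fdr(records: list[DifferentialRecord]) -> None:
    """Populate ``fdr_q`` from the records' combined P values (in place)."""
    q = bh_fdr(np.array([rec.combined_p for rec in records]))
    for rec, qi in zip(records, q):
        rec.fdr_q = float(qi)


def congruence_filter(
    records: list[DifferentialRecord],
    fc_min: float = 1.5,
    raw_alpha: float = 0.01,
    q_alpha: float = 0.05,
) -> tuple[set[str], set[str]]:
    """Apply the directional-congruence rule and collapse to gene sets.

    A probe passes iff every pair shows the same direction with linear fold
    change strictly beyond ``fc_min`` (edge values exactly at the threshold
    fail) and raw P < ``raw_alpha``, and its FDR q on the combined P is
    below ``q_alpha``.  Returns ``(higher_in_sensitive genes,
    higher_in_resistant genes)`` with sign-conflicting genes removed from
    both (as in tier 1).
    """
    if not (fc_min > 1):
        raise ContractError(f"fc_min must exceed 1, got {fc_min}")
    sens_genes: set[str] = set()
    res_genes: set[str] = set()
    for rec in records:
        if math.isnan(rec.fdr_q):
            raise ContractError("fdr_q not populated; call attach_fdr first")
        stats_list = list(rec.pair_stats.values())
        signs = {np.sign(ps.log2_fc) for ps in stats_list}
        if len(signs) != 1 or 0.0 in signs:
            rec.congruent = False
            rec.direction = "none"
            continue
        up = stats_list[0].log2_fc > 0
        ok = all(
            (ps.fold_change > fc_min if up else ps.fold_change < 1.0 / fc_min)
            and ps.raw_p < raw_alpha
            for ps in stats_list
        )
        ok = ok and rec.fdr_q < q_alpha
        rec.congruent = ok
        rec.direction = (
            ("higher_in_sensitive" if up else "higher_in_resistant") if ok else "none"
        )
        if ok:
            (sens_genes if up else res_genes).add(rec.gene_symbol)
    conflicts = sens_genes & res_genes
    for gene in sorted(conflicts):
        logger.warning("gene %s congruent in both directions; excluded", gene)
    return sens_genes - conflicts, res_genes - conflicts


def records_to_frame(records: list[DifferentialRecord]) -> pd.DataFrame:
    """Flatten records into the output table: one row per probe."""
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "probe_id": rec.probe_id,
            "gene_symbol": rec.gene_symbol,
        }
        for name, ps in rec.pair_stats.items():
            row[f"{name}_fold_change"] = ps.fold_change
            row[f"{name}_log2_fc"] = ps.log2_fc
            row[f"{name}_moderated_t"] = ps.moderated_t
            row[f"{name}_raw_p"] = ps.raw_p
        row["combined_p"] = rec.combined_p
        row["fdr_q"] = rec.fdr_q
        row["direction"] = rec.direction
        row["congruent"] = rec.congruent
        rows.append(row)
    return pd.DataFrame(rows)
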