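"""Differential per-position nucleosome-count statistics.

Counts at TSS-relative positions (gene-summed, integer) are compared
between two conditions with a negative-binomial Wald test whose
per-observation normalization factors derive from the paired chromatin
inputs.  P-values are converted to local false discovery rates with a
two-component mixture estimator (Storey null proportion + Grenander
nonincreasing density), and positions are called significant when they
clear both a log2 fold-change and an lFDR threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeModel
from .profiles import build_track, tss_profile

__all__ = [
    "SampleInfo",
    "PositionCountMatrix",
    "DifferentialConfig",
    "build_position_counts",
    "normalization_factors",
    "estimate_dispersions",
    "nb_wald_test",
    "local_fdr",
    "call_significant",
    "huber_mean",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    condition: str
    is_input: bool = False
    pair_id: str | None = None  # links an IP sample to its input (same replicate)


@dataclass
class PositionCountMatrix:
    """Integer nucleosome counts at TSS-relative positions, per sample."""

    positions: np.ndarray  # (P,)
    counts: np.ndarray  # (P, S) nonnegative integers
    samples: list[SampleInfo]
    n_genes: int = 0

    def __post_init__(self) -> None:
        if self.counts.shape != (self.positions.size, len(self.samples)):
            raise ValueError("counts shape does not match positions x samples")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    def column(self, sample_id: str) -> np.ndarray:
        for j, s in enumerate(self.samples):
            if s.sample_id == sample_id:
                return self.counts[:, j]
        raise KeyError(sample_id)

    def ip_samples(self) -> list[SampleInfo]:
        return [s for s in self.samples if not s.is_input]

    def per_gene_average(self) -> np.ndarray:
        """Reporting transform: counts divided by the number of genes."""
        if self.n_genes <= 0:
            raise ValueError("n_genes unknown for this matrix")
        return self.counts / float(self.n_genes)


def build_position_counts(
    midpoints_by_sample: Mapping[str, Sequence[tuple[str, int, str, int]]],
    genome: GenomeModel,
    window: tuple[int, int],
    samples: Sequence[SampleInfo],
) -> PositionCountMatrix:
    """Gene-summed midpoint counts per TSS-relative position and sample.

    Positions whose count is zero in every sample are dropped.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty window")
    ids = [s.sample_id for s in samples]
    if set(ids) != set(midpoints_by_sample):
        raise ValueError("sample metadata does not match the midpoint mapping")
    cols = []
    for s in samples:
        track = build_track(midpoints_by_sample[s.sample_id], genome)
        prof = tss_profile(track, genome, window)
        cols.append(prof.counts)
    counts = np.stack(cols, axis=1)
    positions = np.arange(lo, hi + 1)
    keep = counts.sum(axis=1) > 0
    return PositionCountMatrix(
        positions=positions[keep],
        counts=counts[keep],
        samples=list(samples),
        n_genes=len(genome.genes),
    )


def normalization_factors(matrix: PositionCountMatrix) -> pd.DataFrame:
    """Input-derived per-position factors for every IP sample.

    For IP sample ``s`` paired with input ``t``:
    ``factor(p, s) = input_count(p, t) * (total_s / total_t)``, with zero
    input counts replaced by the smallest positive input count of ``t``,
    then rescaled to geometric mean one per sample.
    """
    inputs = {s.pair_id or s.sample_id: s for s in matrix.samples if s.is_input}
    out: dict[str, np.ndarray] = {}
    for s in matrix.ip_samples():
        if s.pair_id is None or s.pair_id not in inputs:
            raise ValueError(f"IP sample {s.sample_id!r} has no paired input")
        ip_col = matrix.column(s.sample_id)
        in_col = matrix.column(inputs[s.pair_id].sample_id).astype(float)
        if in_col.sum() == 0:
            raise ValueError(f"input for {s.sample_id!r} is empty")
        positive = in_col[in_col > 0]
        filled = np.where(in_col > 0, in_col, positive.min())
        raw = filled * (ip_col.sum() / in_col.sum())
        gmean = np.exp(np.mean(np.log(raw)))
        out[s.sample_id] = raw / gmean
    return pd.DataFrame(out, index=matrix.positions)


# ---------------------------------------------------------------------------
# negative-binomial Wald test
# ---------------------------------------------------------------------------


def _fit_group_mean(k: np.ndarray, f: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-row NB MLE of the condition mean q with mu = f * q, fixed alpha.

    Solved by iterating the weighted estimating equation
    ``q = sum(w k) / sum(w f)`` with ``w = 1 / (1 + alpha mu)``, which is
    the score equation of the NB likelihood in q.
    """
    q = np.maximum(np.mean(k / f, axis=1), 1e-8)
    for _ in range(50):
        mu = f * q[:, None]
        w = 1.0 / (1.0 + alpha[:, None] * mu)
        q_new = np.maximum((w * k).sum(axis=1) / (w * f).sum(axis=1), 1e-12)
        if np.allclose(q_new, q, rtol=1e-10, atol=1e-14):
            q = q_new
            break
        q = q_new
    return q


def estimate_dispersions(
    counts: np.ndarray,
    factors: np.ndarray,
    groups: Sequence[np.ndarray],
    *,
    floor: float = 1e-8,
    shrink: float = 0.5,
) -> np.ndarray:
    """Per-row NB dispersion: method of moments, shrunk toward a mean trend.

    Moments are pooled within conditions on factor-normalized counts; raw
    estimates are shrunk ``shrink`` of the way toward a robustly fitted
    ``alpha(mu) = a0 + a1/mu`` trend and floored.
    """
    y = counts / factors
    resid_var = np.zeros(counts.shape[0])
    mean_level = np.zeros(counts.shape[0])
    dof = 0
    for idx in groups:
        sub = y[:, idx]
        m = sub.mean(axis=1)
        if len(idx) > 1:
            resid_var += sub.var(axis=1, ddof=1) * (len(idx) - 1)
            dof += len(idx) - 1
        mean_level += m * len(idx)
    mean_level /= sum(len(idx) for idx in groups)
    mu = np.maximum(mean_level, 1e-8)
    if dof > 0:
        v = resid_var / dof
        raw = (v - mu) / mu**2
    else:
        raw = np.zeros_like(mu)
    raw = np.clip(raw, floor, 10.0)

    # robust trend alpha = a0 + a1/mu via median-based regression on 1/mu
    x = 1.0 / mu
    informative = raw > floor
    if informative.sum() >= 10:
        a1 = np.median((raw[informative] - np.median(raw[informative])) /
                       np.where(x[informative] - np.median(x[informative]) == 0, 1,
                                x[informative] - np.median(x[informative])))
        a1 = max(a1, 0.0)
        a0 = max(np.median(raw[informative] - a1 * x[informative]), floor)
    else:
        a0, a1 = max(np.median(raw), floor), 0.0
    trend = a0 + a1 * x
    alpha = (1.0 - shrink) * raw + shrink * trend
    return np.maximum(alpha, floor)


def nb_wald_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    factors_a: np.ndarray,
    factors_b: np.ndarray,
    dispersion: float | np.ndarray | None = None,
) -> pd.DataFrame:
    """Two-group NB Wald test with per-observation normalization factors.

    Rows are positions (or genes); columns replicates.  The mean model is
    ``mu = factor * q(condition)``; the Wald statistic compares
    ``log(q_b) - log(q_a)`` against its asymptotic standard error from the
    observed Fisher information ``I = sum mu / (1 + alpha mu)``.  With
    ``dispersion -> 0`` this reduces to the Poisson Wald test.
    """
    counts_a = np.atleast_2d(np.asarray(counts_a, dtype=float))
    counts_b = np.atleast_2d(np.asarray(counts_b, dtype=float))
    factors_a = np.atleast_2d(np.asarray(factors_a, dtype=float))
    factors_b = np.atleast_2d(np.asarray(factors_b, dtype=float))
    if (factors_a <= 0).any() or (factors_b <= 0).any():
        raise ValueError("normalization factors must be positive")
    n = counts_a.shape[0]
    allzero = (counts_a.sum(axis=1) + counts_b.sum(axis=1)) == 0
    if allzero.any():
        raise ValueError(
            f"{int(allzero.sum())} all-zero rows: drop null counts before testing"
        )

    if dispersion is None:
        counts = np.hstack([counts_a, counts_b])
        factors = np.hstack([factors_a, factors_b])
        groups = [
            np.arange(counts_a.shape[1]),
            np.arange(counts_a.shape[1], counts.shape[1]),
        ]
        alpha = estimate_dispersions(counts, factors, groups)
    else:
        alpha = np.broadcast_to(np.asarray(dispersion, dtype=float), (n,)).copy()
        alpha = np.maximum(alpha, 1e-12)

    qa = _fit_group_mean(counts_a, factors_a, alpha)
    qb = _fit_group_mean(counts_b, factors_b, alpha)

    mu_a = factors_a * qa[:, None]
    mu_b = factors_b * qb[:, None]
    info_a = (mu_a / (1.0 + alpha[:, None] * mu_a)).sum(axis=1)
    info_b = (mu_b / (1.0 + alpha[:, None] * mu_b)).sum(axis=1)
    se_log = np.sqrt(1.0 / np.maximum(info_a, 1e-12) + 1.0 / np.maximum(info_b, 1e-12))
    z = (np.log(qb) - np.log(qa)) / se_log
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "base_mean": (np.hstack([counts_a / factors_a, counts_b / factors_b])).mean(axis=1),
            "log2_fold_change": (np.log(qb) - np.log(qa)) / np.log(2.0),
            "wald_stat": z,
            "wald_p": pvals,
            "dispersion": alpha,
        }
    )


# ---------------------------------------------------------------------------
# local FDR
# ---------------------------------------------------------------------------


def _grenander_density(p_sorted: np.ndarray) -> np.ndarray:
    """Nonincreasing density on [0,1]: slopes of the least concave majorant
    of the empirical CDF, evaluated at each sorted p-value."""
    n = p_sorted.size
    x = np.concatenate(([0.0], p_sorted))
    y = np.arange(n + 1) / n
    # upper-hull (least concave majorant) via a monotone stack of slopes
    hull = [0]  # indices into x/y
    for i in range(1, n + 1):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            s1 = (y[k] - y[j]) / max(x[k] - x[j], 1e-300)
            s2 = (y[i] - y[k]) / max(x[i] - x[k], 1e-300)
            if s2 >= s1:
                hull.pop()
            else:
                break
        hull.append(i)
    dens = np.empty(n)
    for a, b in zip(hull[:-1], hull[1:]):
        slope = (y[b] - y[a]) / max(x[b] - x[a], 1e-300)
        dens[a:b] = slope  # p-values with index in (a, b] of x == (a-1, b-1] of p
    return dens


def local_fdr(
    p_values: Sequence[float] | np.ndarray,
    *,
    eta0: float | None = None,
    storey_lambda: float = 0.5,
    min_tests: int = 100,
) -> np.ndarray:
    """Local false discovery rate from the p-value mixture.

    The null proportion defaults to the Storey estimate at
    ``lambda = 0.5``; the marginal p-density is the Grenander
    (nonincreasing) estimator, and ``lfdr(p) = min(1, eta0 / f(p))``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < min_tests:
        raise ValueError(
            f"{p.size} p-values < required {min_tests}; pool more positions"
        )
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if eta0 is None:
        eta0 = min(1.0, (p > storey_lambda).sum() / ((1.0 - storey_lambda) * p.size))
    order = np.argsort(p, kind="stable")
    dens = _grenander_density(p[order])
    lfdr_sorted = np.minimum(1.0, eta0 / np.maximum(dens, 1e-300))
    lfdr_sorted = np.maximum.accumulate(lfdr_sorted)  # nondecreasing in p
    out = np.empty_like(lfdr_sorted)
    out[order] = lfdr_sorted
    return out


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (step-up)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# thresholding and robust location
# ---------------------------------------------------------------------------


@dataclass
class DifferentialConfig:
    """Significance thresholds for differential occupancy calls."""

    lfc_threshold: float = 0.05
    lfdr_threshold: float = 0.2
    dispersion_floor: float = 1e-8

    def __post_init__(self) -> None:
        if self.lfc_threshold <= 0 or self.lfdr_threshold <= 0:
            raise ValueError("thresholds must be positive")


def call_significant(results: pd.DataFrame, cfg: DifferentialConfig | None = None) -> pd.DataFrame:
    """Flag rows with |log2FC| above and lFDR strictly below the thresholds."""
    cfg = cfg or DifferentialConfig()
    out = results.copy()
    out["significant"] = (np.abs(out["log2_fold_change"]) > cfg.lfc_threshold) & (
        out["lfdr"] < cfg.lfdr_threshold
    )
    return out


def huber_mean(
    values: Sequence[float] | np.ndarray,
    k: float = 1.345,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> float:
    """Huber M-estimator of location with MAD scale (IRLS).

    Equals the arithmetic mean when no observation is downweighted; bounded
    between median and mean for one-sided contamination.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("huber_mean of empty input")
    scale = 1.4826 * np.median(np.abs(x - np.median(x)))
    if scale == 0:
        return float(np.median(x))
    mu = float(np.median(x))
    for _ in range(max_iter):
        r = np.abs(x - mu)
        w = np.minimum(1.0, k * scale / np.maximum(r, 1e-300))
        mu_new = float((w * x).sum() / w.sum())
        if abs(mu_new - mu) < tol:
            return mu_new
        mu = mu_new
    return mu
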