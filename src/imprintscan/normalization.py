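"""Intensity-dependent normalization of two-channel allele ratios.

The raw B-allele-style ratio beta = Xraw/(Xraw + Yraw) of array hybridization
drifts with total probe intensity.  Because genomic-DNA heterozygotes have a
known true allelic fraction of 0.5, they calibrate the drift: retained points
(total intensity above a floor) are split into intensity bins on the log10
total-intensity axis, the median beta per bin is regressed on bin center with
a quadratic y = b1*x + b2*x**2 + a, and each observation is corrected as

    beta_norm = beta_obs - beta_expected(x) + 0.5

so that post-normalization bin medians sit at 0.5.  Corrected cDNA betas are
then converted to allelic ratios beta/(1 - beta), clamped into [0.1, 10]
(more extreme ratios are indistinguishable from homozygous signal), and
summarized as a fold magnitude max(ratio, 1/ratio).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .config import RunConfig
from .io import IntensityRecord

__all__ = [
    "BetaObservation",
    "BiasCurve",
    "AEPoint",
    "UndefinedSignalError",
    "InsufficientDataError",
    "compute_beta",
    "beta_observation",
    "fit_bias_curve",
    "normalize_beta",
    "allelic_fold",
    "make_ae_points",
]


class UndefinedSignalError(ValueError):
    """Both channels are zero; beta is undefined."""


class InsufficientDataError(ValueError):
    """Too few calibration points to fit the bias curve."""


@dataclass(frozen=True)
class BetaObservation:
    sample_id: str
    snp_id: str
    assay: str
    beta_obs: float
    log_total: float


@dataclass
class BiasCurve:
    """Fitted expected-beta model over log10 total intensity.

    evaluate() clamps its argument to the fitted range (nearest-edge
    extrapolation); callers can test ``in_range`` to flag such points.
    """

    intensity_threshold: float
    bin_edges: np.ndarray  # n_bins + 1 edges over retained log_total range
    bin_centers: np.ndarray  # non-empty bins only
    bin_medians: np.ndarray  # median beta per non-empty bin
    n_points_per_bin: np.ndarray
    coef_a: float
    coef_b1: float
    coef_b2: float

    @property
    def x_min(self) -> float:
        return float(self.bin_edges[0])

    @property
    def x_max(self) -> float:
        return float(self.bin_edges[-1])

    def in_range(self, log_total: float) -> bool:
        return self.x_min <= log_total <= self.x_max

    def evaluate(self, log_total):
        x = np.clip(np.asarray(log_total, dtype=float), self.x_min, self.x_max)
        return self.coef_a + self.coef_b1 * x + self.coef_b2 * x * x


@dataclass(frozen=True)
class AEPoint:
    """Allelic-expression measurement at one sample x SNP."""

    sample_id: str
    snp_id: str
    beta_norm: float
    ratio: float
    magnitude: float
    overexpressed_allele: Optional[str]  # 'A', 'B' or None
    informative: bool


def compute_beta(x_raw: float, y_raw: float) -> tuple[float, float]:
    """Return (beta, log10 total intensity) for one two-channel measurement."""
    total = x_raw + y_raw
    if total <= 0:
        raise UndefinedSignalError("total intensity is zero; beta undefined")
    return x_raw / total, math.log10(total)


def beta_observation(record: IntensityRecord) -> BetaObservation:
    beta, log_total = compute_beta(record.x_raw, record.y_raw)
    return BetaObservation(record.sample_id, record.snp_id, record.assay, beta, log_total)


def fit_bias_curve(
    points: Iterable[BetaObservation], config: RunConfig | None = None
) -> BiasCurve:
    """Fit the quadratic bin-median bias curve on calibration heterozygotes.

    Points at or below the intensity floor are discarded; the retained
    log-intensity range is split into ``config.n_bins`` equal-occupancy
    bins (edges at quantiles, so every bin median is estimated from a
    comparable number of points even in the intensity tails); empty bins
    are dropped (not interpolated); the quadratic is a least-squares fit of
    bin medians on the median log-intensity of each bin.
    """
    config = config or RunConfig()
    log_floor = math.log10(config.intensity_threshold)
    pts = [p for p in points if p.log_total > log_floor]
    if not pts:
        raise InsufficientDataError("no calibration points above the intensity floor")
    x = np.array([p.log_total for p in pts])
    beta = np.array([p.beta_obs for p in pts])
    edges = np.quantile(x, np.linspace(0.0, 1.0, config.n_bins + 1))
    edges[0], edges[-1] = x.min(), x.max()
    # right-closed last bin so the max point is binned
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, config.n_bins - 1)
    centers, medians, counts = [], [], []
    for b in range(config.n_bins):
        mask = idx == b
        n = int(mask.sum())
        if n == 0:
            continue
        centers.append(float(np.median(x[mask])))
        medians.append(float(np.median(beta[mask])))
        counts.append(n)
    if len(centers) < config.min_nonempty_bins:
        raise InsufficientDataError(
            f"only {len(centers)} non-empty bins; need {config.min_nonempty_bins}"
        )
    # quadratic least squares: median ~ a + b1*x + b2*x^2
    cx = np.asarray(centers)
    design = np.column_stack([np.ones_like(cx), cx, cx * cx])
    coef, *_ = np.linalg.lstsq(design, np.asarray(medians), rcond=None)
    return BiasCurve(
        intensity_threshold=config.intensity_threshold,
        bin_edges=edges,
        bin_centers=cx,
        bin_medians=np.asarray(medians),
        n_points_per_bin=np.asarray(counts),
        coef_a=float(coef[0]),
        coef_b1=float(coef[1]),
        coef_b2=float(coef[2]),
    )


def normalize_beta(beta_obs: float, log_total: float, curve: BiasCurve) -> float:
    """Apply the fitted correction: beta_obs - expected(x) + 0.5, in [0, 1]."""
    value = beta_obs - float(curve.evaluate(log_total)) + 0.5
    return min(1.0, max(0.0, value))


def allelic_fold(
    beta_norm: float, config: RunConfig | None = None
) -> tuple[float, float, Optional[str]]:
    """Convert a normalized beta into (ratio, magnitude, overexpressed allele).

    ratio = beta/(1-beta) clamped into [clamp_low, clamp_high]; beta of
    exactly 0 or 1 maps to the clamp bounds (monoallelic signal).  The
    magnitude max(ratio, 1/ratio) is >= 1; the overexpressed allele is None
    when the clamped ratio is exactly 1.
    """
    config = config or RunConfig()
    if not 0.0 <= beta_norm <= 1.0:
        raise ValueError("beta_norm must lie in [0, 1]")
    if beta_norm >= 1.0:
        ratio = config.clamp_high
    elif beta_norm <= 0.0:
        ratio = config.clamp_low
    else:
        ratio = beta_norm / (1.0 - beta_norm)
        ratio = min(config.clamp_high, max(config.clamp_low, ratio))
    magnitude = max(ratio, 1.0 / ratio)
    if ratio > 1.0:
        allele: Optional[str] = "A"
    elif ratio < 1.0:
        allele = "B"
    else:
        allele = None
    return ratio, magnitude, allele


def make_ae_points(
    cdna: Iterable[IntensityRecord],
    gdna: Iterable[IntensityRecord],
    curve: BiasCurve,
    config: RunConfig | None = None,
) -> list[AEPoint]:
    """Pair cDNA with matched gDNA records and emit one AEPoint per pair.

    A point is informative only when the gDNA genotype is AB and both assays
    clear the intensity floor.  cDNA records with no matching gDNA record are
    skipped.  Non-informative points carry beta/ratio fields of the neutral
    value so downstream code can treat them uniformly.
    """
    config = config or RunConfig()
    gdna_by_key = {(r.sample_id, r.snp_id): r for r in gdna}
    points: list[AEPoint] = []
    for rec in cdna:
        g = gdna_by_key.get((rec.sample_id, rec.snp_id))
        if g is None:
            continue  # unmatched cDNA; nothing to gate on
        informative = (
            g.genotype == "AB"
            and g.total > config.intensity_threshold
            and rec.total > config.intensity_threshold
        )
        if not informative:
            points.append(
                AEPoint(rec.sample_id, rec.snp_id, 0.5, 1.0, 1.0, None, False)
            )
            continue
        beta, log_total = compute_beta(rec.x_raw, rec.y_raw)
        beta_norm = normalize_beta(beta, log_total, curve)
        if config.gdna_ratio_correction:
            g_beta, g_log_total = compute_beta(g.x_raw, g.y_raw)
            g_norm = normalize_beta(g_beta, g_log_total, curve)
            raw = _safe_ratio(beta_norm, config) / _safe_ratio(g_norm, config)
            ratio = min(config.clamp_high, max(config.clamp_low, raw))
            magnitude = max(ratio, 1.0 / ratio)
            allele = "A" if ratio > 1 else "B" if ratio < 1 else None
        else:
            ratio, magnitude, allele = allelic_fold(beta_norm, config)
        points.append(AEPoint(rec.sample_id, rec.snp_id, beta_norm, ratio, magnitude, allele, True))
    return points


def _safe_ratio(beta: float, config: RunConfig) -> float:
    if beta >= 1.0:
        return config.clamp_high
    if beta <= 0.0:
        return config.clamp_low
    return beta / (1.0 - beta)
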