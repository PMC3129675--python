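"""Beta computation, bias-curve fitting and allelic folds.

The quadratic fit is checked against an independent ordinary-least-squares
oracle (statsmodels on independently recomputed bin medians); the central
normalization invariant — bin medians at 0.5 after correction — is checked
on a large simulated heterozygote set carrying a known quadratic bias.
"""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from imprintscan.config import RunConfig
from imprintscan.io import IntensityRecord
from imprintscan.normalization import (
    BetaObservation,
    InsufficientDataError,
    UndefinedSignalError,
    allelic_fold,
    compute_beta,
    fit_bias_curve,
    make_ae_points,
    normalize_beta,
)


def _het_observations(rng, n, bias=(0.0, 0.0, 0.0), noise_sd=0.0,
                      x_lo=3.1, x_hi=4.5, slope=None):
    a, b1, b2 = bias
    x = rng.uniform(x_lo, x_hi, n)
    beta = 0.5 + a + b1 * x + b2 * x * x
    if slope is not None:  # linear-in-x truth, e.g. 0.5 + 0.05 (x - 3)
        beta = 0.5 + slope * (x - 3.0)
    beta = np.clip(beta + rng.normal(0, noise_sd, n), 0, 1)
    return [
        BetaObservation("s", f"snp{i}", "gDNA", float(b), float(xx))
        for i, (b, xx) in enumerate(zip(beta, x))
    ]


@pytest.mark.parametrize(
    "x_raw, y_raw, beta, log_total",
    [(500, 500, 0.5, 3.0), (900, 100, 0.9, 3.0), (10, 90, 0.1, 2.0)],
)
def test_compute_beta(x_raw, y_raw, beta, log_total):
    b, lt = compute_beta(x_raw, y_raw)
    assert b == pytest.approx(beta)
    assert lt == pytest.approx(log_total)


def test_compute_beta_zero_signal_is_undefined():
    with pytest.raises(UndefinedSignalError):
        compute_beta(0.0, 0.0)


def test_fit_matches_independent_ols_oracle(rng, config):
    obs = _het_observations(rng, 50_000, slope=0.05)
    curve = fit_bias_curve(obs, config)
    # oracle: recompute quantile bins and medians from scratch, fit with OLS
    x = np.array([o.log_total for o in obs])
    beta = np.array([o.beta_obs for o in obs])
    keep = x > math.log10(config.intensity_threshold)
    x, beta = x[keep], beta[keep]
    edges = np.quantile(x, np.linspace(0, 1, config.n_bins + 1))
    centers, medians = [], []
    for b in range(config.n_bins):
        lo, hi = edges[b], edges[b + 1]
        mask = (x > lo) & (x <= hi) if b else (x >= lo) & (x <= hi)
        if mask.any():
            centers.append(np.median(x[mask]))
            medians.append(np.median(beta[mask]))
    design = sm.add_constant(np.column_stack([centers, np.square(centers)]))
    fit = sm.OLS(medians, design).fit()
    assert curve.coef_a == pytest.approx(fit.params[0], abs=1e-9)
    assert curve.coef_b1 == pytest.approx(fit.params[1], abs=1e-9)
    assert curve.coef_b2 == pytest.approx(fit.params[2], abs=1e-9)


def test_fit_requires_points_above_intensity_floor(config):
    # total intensity 900 (log10 < 3) is below the 1,000 threshold
    obs = [BetaObservation("s", f"snp{i}", "gDNA", 0.5, math.log10(900)) for i in range(100)]
    with pytest.raises(InsufficientDataError):
        fit_bias_curve(obs, config)


def test_bias_free_hets_yield_flat_curve(rng, config):
    obs = _het_observations(rng, 20_000, noise_sd=0.02)
    curve = fit_bias_curve(obs, config)
    assert np.all(np.abs(curve.bin_medians - 0.5) < 0.01)
    assert abs(float(curve.evaluate(3.2)) - 0.5) < 0.005
    assert abs(float(curve.evaluate(4.4)) - 0.5) < 0.005


def test_normalized_bin_medians_recentre_at_half(rng, config):
    """The point of the procedure: post-correction medians sit at 0.5."""
    obs = _het_observations(rng, 50_000, bias=(-0.42, 0.19, -0.02), noise_sd=0.02)
    curve = fit_bias_curve(obs, config)
    norm = np.array([normalize_beta(o.beta_obs, o.log_total, curve) for o in obs])
    x = np.array([o.log_total for o in obs])
    idx = np.clip(np.searchsorted(curve.bin_edges, x, side="right") - 1, 0, config.n_bins - 1)
    for b in range(config.n_bins):
        mask = idx == b
        if mask.any():
            assert abs(np.median(norm[mask]) - 0.5) < 0.01
    assert abs(np.median(norm) - 0.5) < 0.005


@pytest.mark.parametrize(
    "beta_obs, expected_at_x, result",
    [(0.62, 0.60, 0.52), (0.57, 0.57, 0.5), (0.99, 0.40, 1.0)],
)
def test_normalize_beta_arithmetic(beta_obs, expected_at_x, result):
    from imprintscan.normalization import BiasCurve

    # a constant curve: a = expected value, b1 = b2 = 0
    curve = BiasCurve(
        intensity_threshold=1000.0,
        bin_edges=np.linspace(3, 5, 51),
        bin_centers=np.linspace(3, 5, 50),
        bin_medians=np.full(50, expected_at_x),
        n_points_per_bin=np.full(50, 10),
        coef_a=expected_at_x, coef_b1=0.0, coef_b2=0.0,
    )
    assert normalize_beta(beta_obs, 4.0, curve) == pytest.approx(result)


@pytest.mark.parametrize(
    "beta, ratio, magnitude, allele",
    [
        (0.5, 1.0, 1.0, None),
        (0.95, 10.0, 10.0, "A"),  # raw ratio 19 clamps to 10
        (0.25, 1 / 3, 3.0, "B"),
        (0.75, 3.0, 3.0, "A"),
        (1.0, 10.0, 10.0, "A"),
        (0.0, 0.1, 10.0, "B"),
    ],
)
def test_allelic_fold_values(beta, ratio, magnitude, allele, config):
    r, m, a = allelic_fold(beta, config)
    assert r == pytest.approx(ratio)
    assert m == pytest.approx(magnitude)
    assert a == allele


@settings(max_examples=200, deadline=None)
@given(beta=st.floats(min_value=0.0, max_value=1.0))
def test_allelic_fold_mirror_symmetry_and_clamp_idempotence(beta):
    config = RunConfig()
    r1, m1, a1 = allelic_fold(beta, config)
    r2, m2, a2 = allelic_fold(1.0 - beta, config)
    assert m1 == pytest.approx(m2)  # magnitude invariant under label swap
    assert r1 * r2 == pytest.approx(1.0, rel=1e-9)
    if a1 is not None:
        assert {a1, a2} == {"A", "B"}
    # clamping twice equals clamping once
    back = r1 / (1 + r1)  # beta that reproduces the clamped ratio
    assert allelic_fold(back, config)[0] == pytest.approx(r1, rel=1e-9)


def test_make_ae_points_informativeness_gates(config):
    from imprintscan.normalization import BiasCurve

    curve = BiasCurve(1000.0, np.linspace(3, 5, 51), np.linspace(3, 5, 50),
                      np.full(50, 0.5), np.full(50, 10), 0.5, 0.0, 0.0)
    gdna = [
        IntensityRecord("s", "hom", "gDNA", 3000, 10, "AA"),
        IntensityRecord("s", "het", "gDNA", 1500, 1500, "AB"),
        IntensityRecord("s", "dim", "gDNA", 1500, 1500, "AB"),
    ]
    cdna = [
        IntensityRecord("s", "hom", "cDNA", 2500, 30, "AA"),
        IntensityRecord("s", "het", "cDNA", 2700, 300, "AB"),
        IntensityRecord("s", "dim", "cDNA", 700, 100, "AB"),  # total 800 <= 1000
        IntensityRecord("s", "orphan", "cDNA", 900, 900, "AB"),  # no gDNA match
    ]
    points = {p.snp_id: p for p in make_ae_points(cdna, gdna, curve, config)}
    assert "orphan" not in points
    assert not points["hom"].informative  # gDNA homozygote
    assert not points["dim"].informative  # cDNA below the intensity floor
    assert points["het"].informative
    assert points["het"].ratio == pytest.approx(9.0)
    assert points["het"].overexpressed_allele == "A"
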