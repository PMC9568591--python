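"""OLS baseline, kernels, local weighted fits, bandwidth selection, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from ambientpop.gwr import (GWRConfig, GWRError, anchor_distance_matrix,
                            fit_gwr_loglinear, fit_ols_loglinear,
                            great_circle_km, kernel_weights,
                            residual_band_summary, select_bandwidth)
from ambientpop.synthetic import generate_coefficient_table
from ambientpop.zonal import CountyTable


def _table(lnT, lnP, lon=None, lat=None):
    n = len(lnT)
    return CountyTable(pd.DataFrame({
        "zone_id": [f"Z{i}" for i in range(n)],
        "population": np.exp(lnP),
        "lbs_total": np.exp(lnT),
        "n_cells": 1, "n_nodata_cells": 0,
        "anchor_lon": lon if lon is not None else np.linspace(100, 110, n),
        "anchor_lat": lat if lat is not None else np.linspace(30, 40, n),
    }))


# --- OLS ------------------------------------------------------------------

def test_ols_exact_on_collinear_points():
    """Points (0,1), (1,3), (2,5): exact fit a=2, b=1."""
    fit = fit_ols_loglinear(_table([0.0, 1.0, 2.0], [1.0, 3.0, 5.0]))
    assert fit.a == pytest.approx(2.0, abs=1e-12)
    assert fit.b == pytest.approx(1.0, abs=1e-12)
    assert fit.rss == pytest.approx(0.0, abs=1e-20)
    assert fit.r2 == pytest.approx(1.0)


def test_ols_constant_response_convention():
    fit = fit_ols_loglinear(_table([0.0, 1.0, 2.0], [4.0, 4.0, 4.0]))
    assert fit.a == pytest.approx(0.0, abs=1e-12)
    assert fit.b == pytest.approx(4.0)
    assert fit.r2 == 0.0


def test_ols_matches_normal_equations_oracle():
    rng = np.random.default_rng(3)
    x = rng.uniform(1, 8, 40)
    y = 1.1 * x + 0.3 + rng.normal(0, 0.2, 40)
    fit = fit_ols_loglinear(_table(x, y))
    # independent brute-force normal equations
    n = len(x)
    a = (n * (x * y).sum() - x.sum() * y.sum()) / (n * (x * x).sum() - x.sum() ** 2)
    b = (y.sum() - a * x.sum()) / n
    assert fit.a == pytest.approx(a, abs=1e-10)
    assert fit.b == pytest.approx(b, abs=1e-10)


def test_ols_nonpositive_value_names_zone():
    table = _table([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])
    table.data.loc[1, "lbs_total"] = 0.0
    with pytest.raises(GWRError, match="Z1"):
        fit_ols_loglinear(table)


def test_too_few_counties_rejected():
    with pytest.raises(GWRError, match="at least 3"):
        fit_ols_loglinear(_table([0.0, 1.0], [1.0, 2.0]))


# --- kernels --------------------------------------------------------------

@pytest.mark.parametrize("kernel", ["gaussian", "bisquare"])
def test_kernel_weight_one_at_center(kernel):
    assert kernel_weights(np.array([0.0]), 10.0, kernel)[0] == 1.0


def test_bisquare_closed_form():
    w = kernel_weights(np.array([10.0, 5.0]), 10.0, "bisquare")
    assert w[0] == 0.0
    assert w[1] == pytest.approx(0.5625)  # (1 - 0.25)^2


def test_gaussian_closed_form():
    w = kernel_weights(np.array([10.0]), 10.0, "gaussian")
    assert w[0] == pytest.approx(np.exp(-0.5))


def test_nonpositive_bandwidth_rejected():
    with pytest.raises(GWRError, match="bandwidth"):
        kernel_weights(np.array([1.0]), 0.0, "gaussian")


def test_great_circle_quarter_meridian():
    # pole to equator along a meridian: a quarter of the earth circumference
    d = great_circle_km(0.0, 0.0, 0.0, 90.0)
    assert d == pytest.approx(np.pi / 2 * 6371.0088, rel=1e-9)


# --- GWR ------------------------------------------------------------------

def test_infinite_bandwidth_reduces_to_ols():
    table, *_ = generate_coefficient_table(n_counties=50, seed=3)
    ols = fit_ols_loglinear(table)
    gwr = fit_gwr_loglinear(
        table, GWRConfig(kernel="gaussian", bandwidth_mode="fixed", bandwidth=1e9)
    )
    np.testing.assert_allclose(gwr.a, ols.a, atol=1e-8)
    np.testing.assert_allclose(gwr.b, ols.b, atol=1e-8)


def test_exact_recovery_constant_coefficients():
    """A noiseless table with constant (a, b) is recovered exactly at any
    bandwidth, with zero residuals and R2 = 1."""
    rng = np.random.default_rng(9)
    x = rng.uniform(1, 8, 60)
    y = 1.05 * x + 0.4
    table = _table(x, y, lon=rng.uniform(100, 110, 60), lat=rng.uniform(30, 40, 60))
    for bw in (10, 30):
        fit = fit_gwr_loglinear(table, GWRConfig(bandwidth=bw))
        np.testing.assert_allclose(fit.a, 1.05, atol=1e-8)
        np.testing.assert_allclose(fit.b, 0.4, atol=1e-8)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-10)
        assert fit.r2 == pytest.approx(1.0)


@pytest.mark.parametrize("n,kernel,mode,bw", [
    (50, "bisquare", "adaptive", 15),
    (50, "gaussian", "fixed", 150.0),
    (200, "bisquare", "adaptive", 40),
    (200, "gaussian", "fixed", 100.0),
])
def test_local_fit_matches_per_anchor_oracle(n, kernel, mode, bw):
    """Each (a_i, b_i) equals an independent sqrt-weighted lstsq solve."""
    table, *_ = generate_coefficient_table(n_counties=n, noise_sigma=0.1, seed=n)
    cfg = GWRConfig(kernel=kernel, bandwidth_mode=mode, bandwidth=bw)
    fit = fit_gwr_loglinear(table, cfg)
    D = anchor_distance_matrix(table)
    x = np.log(table.data["lbs_total"].to_numpy())
    y = np.log(table.data["population"].to_numpy())
    for i in range(n):
        radius = np.sort(D[i])[int(bw) - 1] if mode == "adaptive" else bw
        w = kernel_weights(D[i], radius, kernel)
        sw = np.sqrt(w)
        X = np.column_stack([x * sw, sw])
        coef, *_ = np.linalg.lstsq(X, y * sw, rcond=None)
        assert fit.a[i] == pytest.approx(coef[0], abs=1e-8)
        assert fit.b[i] == pytest.approx(coef[1], abs=1e-8)


def test_local_r2_in_unit_interval_and_sigma2_consistent():
    table, *_ = generate_coefficient_table(n_counties=80, noise_sigma=0.2, seed=4)
    fit = fit_gwr_loglinear(table, GWRConfig(bandwidth=20))
    assert ((fit.local_r2 >= 0) & (fit.local_r2 <= 1)).all()
    assert fit.sigma2 == pytest.approx(
        fit.rss / (len(table) - fit.effective_params)
    )
    assert fit.rss >= 0


def test_tiny_bandwidth_rejected_with_advice():
    table, *_ = generate_coefficient_table(n_counties=30, seed=5)
    with pytest.raises(GWRError, match="bandwidth"):
        fit_gwr_loglinear(
            table, GWRConfig(kernel="bisquare", bandwidth_mode="fixed", bandwidth=1e-6)
        )


# --- bandwidth selection --------------------------------------------------

@pytest.mark.parametrize("criterion", ["cv", "aicc"])
def test_fixed_bandwidth_search_agrees_with_grid_oracle(criterion):
    from ambientpop.gwr import _bandwidth_objective

    table, *_ = generate_coefficient_table(n_counties=60, noise_sigma=0.1, seed=8)
    cfg = GWRConfig(kernel="gaussian", bandwidth_mode="fixed",
                    selection_criterion=criterion)
    D = anchor_distance_matrix(table)
    best = select_bandwidth(table, cfg, distance_matrix=D)
    objective = _bandwidth_objective(table, cfg, D)
    offdiag = D[~np.eye(len(table), dtype=bool)]
    grid = np.logspace(np.log10(offdiag[offdiag > 0].min()),
                       np.log10(2 * D.max()), 200)
    scores = [objective(b) for b in grid]
    g_best = grid[int(np.argmin(scores))]
    # within one grid step of the dense-grid optimum
    step = np.log(grid[1]) - np.log(grid[0])
    assert abs(np.log(best) - np.log(g_best)) <= step + 1e-9


def test_adaptive_selection_interior_on_heterogeneous_data():
    table, *_ = generate_coefficient_table(n_counties=100, noise_sigma=0.05, seed=2)
    cfg = GWRConfig()
    k = select_bandwidth(table, cfg)
    assert 3 < k < 100


def test_constant_coefficient_ties_break_to_largest():
    """Noiseless constant-coefficient data: CV error is ~0 everywhere, so the
    tie-break returns the largest candidate neighbour count."""
    rng = np.random.default_rng(1)
    x = rng.uniform(1, 8, 30)
    y = 1.1 * x + 0.2
    table = _table(x, y, lon=rng.uniform(100, 110, 30), lat=rng.uniform(30, 40, 30))
    cfg = GWRConfig(selection_criterion="cv")
    k = select_bandwidth(table, cfg)
    assert k == 30


# --- residual summary -----------------------------------------------------

def _fit_with_residuals(resid, local_r2):
    table, *_ = generate_coefficient_table(n_counties=len(resid), seed=0)
    fit = fit_gwr_loglinear(table, GWRConfig(bandwidth=len(resid)))
    fit.residuals = np.asarray(resid, dtype=float)
    fit.local_r2 = np.asarray(local_r2, dtype=float)
    return fit


def test_residual_band_hand_count():
    fit = _fit_with_residuals([-0.2, 0.0, 0.2, 0.5], [1.0, 1.0, 1.0, 1.0])
    out = residual_band_summary(fit, [(-0.1, 0.3)])
    assert out["bands"][0]["count"] == 2
    assert out["bands"][0]["fraction"] == 0.5
    assert out["local_r2_count"] == 4


def test_zero_residuals_full_fraction():
    fit = _fit_with_residuals([0.0] * 5, [0.0] * 5)
    out = residual_band_summary(fit, [(-0.1, 0.3)])
    assert out["bands"][0]["fraction"] == 1.0


def test_empty_bands_rejected():
    fit = _fit_with_residuals([0.0] * 5, [0.0] * 5)
    with pytest.raises(GWRError, match="empty"):
        residual_band_summary(fit, [])
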