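"""Log-linear regression between county population and county LBS counts.

The model is ln(pop_i) = a_i * ln(count_i) + b_i + eps_i.  A global OLS fit
(spatially constant a, b) is the baseline; the geographically weighted fit
solves a separate weighted least-squares problem at every county anchor with
distance-decayed weights, yielding spatially varying coefficients, per-anchor
local R-squared and the usual GWR global diagnostics (RSS, R2, effective
parameter count from the hat-matrix trace, corrected AIC).

Distances are great-circle kilometres between county anchors.  Bandwidths are
either a fixed kernel radius in km or adaptive: at each anchor the radius is
the distance to its k-th nearest county (the anchor itself counted at rank 1).
Automatic selection minimises either the leave-one-out cross-validation score
(each county predicted with its own weight zeroed) or the corrected AIC;
ties break toward the larger (smoother) bandwidth.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np

from .zonal import CountyTable

logger = logging.getLogger("ambientpop")

EARTH_RADIUS_KM = 6371.0088
#: Gaussian bandwidth (km) large enough that all weights are 1 to machine precision.
GLOBAL_BANDWIDTH_KM = 1e9


class GWRError(ValueError):
    pass


@dataclass(frozen=True)
class GWRConfig:
    kernel: Literal["gaussian", "bisquare"] = "bisquare"
    bandwidth_mode: Literal["fixed", "adaptive"] = "adaptive"
    bandwidth: float | Literal["auto"] = "auto"
    selection_criterion: Literal["cv", "aicc"] = "aicc"
    min_nonzero_weights: int = 3

    def __post_init__(self) -> None:
        if self.kernel not in ("gaussian", "bisquare"):
            raise GWRError(f"unknown kernel '{self.kernel}'")
        if self.bandwidth_mode not in ("fixed", "adaptive"):
            raise GWRError(f"unknown bandwidth mode '{self.bandwidth_mode}'")
        if self.selection_criterion not in ("cv", "aicc"):
            raise GWRError(f"unknown selection criterion '{self.selection_criterion}'")
        if self.bandwidth != "auto":
            if not (float(self.bandwidth) > 0):
                raise GWRError("bandwidth must be positive or 'auto'")
            if self.bandwidth_mode == "adaptive" and int(self.bandwidth) < 3:
                raise GWRError("adaptive neighbor count must be >= 3")


@dataclass
class OLSFit:
    a: float
    b: float
    residuals: np.ndarray
    r2: float
    rss: float


@dataclass
class GWRFit:
    zone_ids: list[str]
    a: np.ndarray
    b: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    local_r2: np.ndarray
    local_r2_raw: np.ndarray
    r2: float
    rss: float
    aicc: float
    sigma2: float
    effective_params: float
    bandwidth_used: float
    config: GWRConfig

    def coefficients_for(self, zone_id: str) -> tuple[float, float]:
        i = self.zone_ids.index(zone_id)
        return float(self.a[i]), float(self.b[i])


def great_circle_km(
    lon1: np.ndarray, lat1: np.ndarray, lon2: np.ndarray, lat2: np.ndarray
) -> np.ndarray:
    """Haversine great-circle distance in kilometres (broadcasting)."""
    lam1, phi1, lam2, phi2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dphi = phi2 - phi1
    dlam = lam2 - lam1
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def anchor_distance_matrix(table: CountyTable) -> np.ndarray:
    lon = table.data["anchor_lon"].to_numpy()
    lat = table.data["anchor_lat"].to_numpy()
    return great_circle_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])


def kernel_weights(
    distances: np.ndarray, bandwidth: float | np.ndarray, kernel: str
) -> np.ndarray:
    """Distance-decay weights: gaussian exp(-0.5 (d/bw)^2) or bisquare
    (1-(d/bw)^2)^2 truncated at d >= bw."""
    bw = np.asarray(bandwidth, dtype=float)
    if np.any(bw <= 0):
        raise GWRError("bandwidth must be positive")
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise GWRError("distances must be non-negative")
    u = d / bw
    if kernel == "gaussian":
        return np.exp(-0.5 * u**2)
    if kernel == "bisquare":
        return np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0)
    raise GWRError(f"unknown kernel '{kernel}'")


def _log_table(table: CountyTable) -> tuple[np.ndarray, np.ndarray]:
    df = table.data
    bad = df.loc[(df["lbs_total"] <= 0) | (df["population"] <= 0), "zone_id"].tolist()
    if bad:
        raise GWRError(f"nonpositive count or population for zone(s): {bad}")
    return np.log(df["lbs_total"].to_numpy()), np.log(df["population"].to_numpy())


def fit_ols_loglinear(table: CountyTable) -> OLSFit:
    """Global least squares ln(pop) = a ln(count) + b."""
    if len(table) < 3:
        raise GWRError(f"need at least 3 counties, got {len(table)}")
    x, y = _log_table(table)
    X = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    a, b = float(coef[0]), float(coef[1])
    resid = y - (a * x + b)
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0.0:
        logger.warning("constant response: R2 reported as 0 by convention")
        r2 = 0.0
    else:
        r2 = 1.0 - rss / tss
    return OLSFit(a=a, b=b, residuals=resid, r2=r2, rss=rss)


def _weight_matrix(D: np.ndarray, bandwidth: float, config: GWRConfig) -> np.ndarray:
    """Row i holds the weights of all counties for the fit anchored at i."""
    if config.bandwidth_mode == "adaptive":
        k = int(bandwidth)
        n = D.shape[0]
        if not 3 <= k <= n:
            raise GWRError(f"adaptive neighbor count {k} outside [3, {n}]")
        # local radius = distance to the k-th nearest county (self at rank 1)
        radii = np.sort(D, axis=1)[:, k - 1]
        radii = np.maximum(radii, np.finfo(float).tiny)
        return kernel_weights(D, radii[:, None], config.kernel)
    return kernel_weights(D, float(bandwidth), config.kernel)


def _local_wls(
    x: np.ndarray, y: np.ndarray, W: np.ndarray, min_nonzero: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve the 2-parameter weighted normal equations for every anchor row of W.

    Returns (a, b, hat_diag_factor) where hat_diag_factor[i] =
    x_i^T (X^T W_i X)^{-1} x_i with x_i = (x_i, 1).
    """
    nz = (W > 0).sum(axis=1)
    if np.any(nz < min_nonzero):
        i = int(np.argmin(nz))
        raise GWRError(
            f"only {int(nz[i])} nonzero weights at anchor index {i}; "
            "increase the bandwidth"
        )
    sw = W.sum(axis=1)
    swx = W @ x
    swy = W @ y
    swxx = W @ (x * x)
    swxy = W @ (x * y)
    det = sw * swxx - swx**2
    # conditioning of the 2x2 normal matrix [[swxx, swx], [swx, sw]]
    tr = sw + swxx
    disc = np.sqrt(np.maximum(tr**2 - 4.0 * det, 0.0))
    lam_max = (tr + disc) / 2.0
    lam_min = (tr - disc) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.where(lam_min > 0, lam_max / lam_min, np.inf)
        a = (sw * swxy - swx * swy) / det
        b = (swy - a * swx) / sw
    # x_i^T M_i^{-1} x_i with M_i = [[swxx, swx], [swx, sw]]
    with np.errstate(divide="ignore", invalid="ignore"):
        hat_factor = (sw * x**2 - 2.0 * swx * x + swxx) / det
    bad = ~np.isfinite(a) | ~np.isfinite(b) | (cond > 1e12)
    for i in np.flatnonzero(bad):
        # rank-revealing fallback for ill-conditioned local systems
        sq = np.sqrt(W[i])
        X = np.column_stack([x * sq, sq])
        coef, res, rank, _ = np.linalg.lstsq(X, y * sq, rcond=None)
        if rank < 2:
            raise GWRError(f"singular local system at anchor index {i}")
        a[i], b[i] = coef
        M = np.array([[swxx[i], swx[i]], [swx[i], sw[i]]])
        xi_vec = np.array([x[i], 1.0])
        hat_factor[i] = xi_vec @ np.linalg.pinv(M) @ xi_vec
    return a, b, hat_factor


def fit_gwr_loglinear(
    table: CountyTable,
    config: GWRConfig = GWRConfig(),
    distance_matrix: np.ndarray | None = None,
) -> GWRFit:
    """Geographically weighted fit of the log-linear population/count relation."""
    if len(table) < 3:
        raise GWRError(f"need at least 3 counties, got {len(table)}")
    x, y = _log_table(table)
    D = anchor_distance_matrix(table) if distance_matrix is None else distance_matrix
    bandwidth = config.bandwidth
    if bandwidth == "auto":
        bandwidth = select_bandwidth(table, config, distance_matrix=D)
    W = _weight_matrix(D, bandwidth, config)
    a, b, hat_factor = _local_wls(x, y, W, config.min_nonzero_weights)
    n = len(x)
    fitted = a * x + b
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0.0:
        logger.warning("constant response: R2 reported as 0 by convention")
        r2 = 0.0
    else:
        r2 = 1.0 - rss / tss
    # hat-matrix diagonal: S_ii = w_i(i) * x_i^T M_i^{-1} x_i, w_i(i) = kernel(0) = 1
    trace_s = float((hat_factor * np.diagonal(W)).sum())
    sigma2 = rss / (n - trace_s) if n > trace_s else float("nan")
    aicc = _aicc(rss, n, trace_s)
    # local weighted R2 at each anchor, using that anchor's coefficients everywhere
    yhat_local = a[:, None] * x[None, :] + b[:, None]
    wres = W * (y[None, :] - yhat_local) ** 2
    ybar_w = (W @ y) / W.sum(axis=1)
    wtot = W * (y[None, :] - ybar_w[:, None]) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        local_r2_raw = 1.0 - wres.sum(axis=1) / wtot.sum(axis=1)
    local_r2 = np.clip(local_r2_raw, 0.0, 1.0)
    n_clamped = int((local_r2 != local_r2_raw).sum() + np.isnan(local_r2_raw).sum())
    if n_clamped:
        logger.info("clamped local R2 at %d anchors", n_clamped)
    local_r2 = np.nan_to_num(local_r2, nan=0.0)
    return GWRFit(
        zone_ids=list(table.data["zone_id"]),
        a=a, b=b, fitted=fitted, residuals=resid,
        local_r2=local_r2, local_r2_raw=local_r2_raw,
        r2=r2, rss=rss, aicc=aicc, sigma2=float(sigma2),
        effective_params=trace_s, bandwidth_used=float(bandwidth), config=config,
    )


def _aicc(rss: float, n: int, trace_s: float) -> float:
    """Corrected AIC for GWR (Hurvich-Simonoff-Tsai small-sample form)."""
    if not math.isfinite(trace_s) or n - 2 - trace_s <= 0:
        return math.inf
    if rss <= 0:
        return -math.inf
    sigma2_ml = rss / n
    return (
        n * math.log(sigma2_ml)
        + n * math.log(2.0 * math.pi)
        + n * (n + trace_s) / (n - 2.0 - trace_s)
    )


def _cv_score(
    x: np.ndarray, y: np.ndarray, W: np.ndarray, min_nonzero: int
) -> float:
    """Leave-one-out prediction RSS: anchor i predicted with its own weight zeroed."""
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    a, b, _ = _local_wls(x, y, W, min_nonzero)
    pred = a * x + b
    return float(((y - pred) ** 2).sum())


def _bandwidth_objective(
    table: CountyTable, config: GWRConfig, D: np.ndarray
) -> Callable[[float], float]:
    x, y = _log_table(table)

    def objective(bw: float) -> float:
        try:
            W = _weight_matrix(D, bw, config)
            if config.selection_criterion == "cv":
                return _cv_score(x, y, W, config.min_nonzero_weights)
            a, b, hat_factor = _local_wls(x, y, W, config.min_nonzero_weights)
            resid = y - (a * x + b)
            rss = float(resid @ resid)
            trace_s = float((hat_factor * np.diagonal(W)).sum())
            return _aicc(rss, len(x), trace_s)
        except GWRError:
            return math.inf

    return objective


def select_bandwidth(
    table: CountyTable,
    config: GWRConfig,
    distance_matrix: np.ndarray | None = None,
) -> float:
    """Pick the bandwidth minimising the CV or AICc score.

    Fixed mode: golden-section search on log-bandwidth over a bracket from the
    smallest positive nearest-neighbour distance to twice the grid diameter.
    Adaptive mode: integer ternary search over the neighbour count.  Ties
    break toward the larger bandwidth.
    """
    D = anchor_distance_matrix(table) if distance_matrix is None else distance_matrix
    objective = _bandwidth_objective(table, config, D)
    n = D.shape[0]
    if config.bandwidth_mode == "adaptive":
        best = _integer_ternary_search(objective, lo=max(3, config.min_nonzero_weights), hi=n)
    else:
        offdiag = D[~np.eye(n, dtype=bool)]
        pos = offdiag[offdiag > 0]
        if pos.size == 0:
            raise GWRError("all anchors coincide; fixed bandwidth undefined")
        lo = math.log(float(pos.min()))
        hi = math.log(2.0 * float(D.max()))
        best = math.exp(_golden_section(lambda t: objective(math.exp(t)), lo, hi))
    if not math.isfinite(objective(best)):
        raise GWRError("no candidate bandwidth satisfies the minimum-weights rule")
    logger.info("selected %s bandwidth %.6g (%s)",
                config.bandwidth_mode, best, config.selection_criterion)
    return float(best)


def _golden_section(
    f: Callable[[float], float], lo: float, hi: float, tol: float = 1e-4
) -> float:
    """Golden-section minimisation; on near-ties prefers the larger argument."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc < fd - 1e-12:  # strict improvement required to move left
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return b  # larger end of the final bracket (tie-break toward larger)


def _integer_ternary_search(
    f: Callable[[float], float], lo: int, hi: int
) -> int:
    """Ternary search over integers for a (near) unimodal objective.

    Ties break toward the larger value; falls back to the best endpoint when
    the bracket collapses.
    """
    cache: dict[int, float] = {}

    def g(k: int) -> float:
        if k not in cache:
            cache[k] = f(float(k))
        return cache[k]

    a, b = lo, hi
    while b - a > 2:
        m1 = a + (b - a) // 3
        m2 = b - (b - a) // 3
        if g(m1) < g(m2) - 1e-12:
            b = m2 - 1
        else:
            a = m1 + 1
    candidates = range(a, b + 1)
    # minimal score; among ties (within 1e-12) take the largest k
    best_val = min(g(k) for k in candidates)
    best = max(k for k in candidates if g(k) <= best_val + 1e-12)
    return best


def residual_band_summary(
    fit: GWRFit,
    bands: Sequence[tuple[float, float]],
    local_r2_threshold: float = 0.6,
) -> dict:
    """Count counties with residuals in each half-open band [lo, hi) and with
    local R2 above the threshold; fractions are over retained counties."""
    if not bands:
        raise GWRError("empty bands list")
    n = len(fit.residuals)
    out: dict = {"n_counties": n, "bands": []}
    for lo, hi in bands:
        count = int(((fit.residuals >= lo) & (fit.residuals < hi)).sum())
        out["bands"].append(
            {"lo": lo, "hi": hi, "count": count, "fraction": count / n}
        )
    count_r2 = int((fit.local_r2 > local_r2_threshold).sum())
    out["local_r2_threshold"] = local_r2_threshold
    out["local_r2_count"] = count_r2
    out["local_r2_fraction"] = count_r2 / n
    return out
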