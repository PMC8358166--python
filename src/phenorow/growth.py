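"""Nondecreasing growth-curve fitting for per-plant height series.

Plant height should not decrease over a growing season, but raw
per-image measurements are noisy and occasionally grossly wrong.  The
fit proceeds in two stages.  First an unconstrained curve mu_hat is
estimated by kernel (Nadaraya–Watson) smoothing on time rescaled to
[0, 1].  Second, the curve is monotonized by density inversion: a
kernel density is built from the fitted values mu_hat(i/N), and its
integral

    inv(t) = (1/N) * sum_i F((t − mu_hat(i/N)) / h_d)

(F the kernel CDF) is a nondecreasing estimate of the inverse growth
function; numerically inverting it over the observed height range
yields a nondecreasing curve.  Unlike isotonic regression, the result
is smooth, and it converges to the unconstrained curve when that curve
is already increasing and h_d is small.

Outlying measurements (dead pixels, occlusions, failed cuts) are
handled by a robust refit: observations whose first-fit residuals lie
strictly outside 3 interquartile ranges of the median residual are
dropped and the curve is fitted again.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


# ---------------------------------------------------------------------------
# kernels


def _epanechnikov(u: np.ndarray) -> np.ndarray:
    return np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u**2), 0.0)


def _epanechnikov_cdf(u: np.ndarray) -> np.ndarray:
    c = np.clip(u, -1.0, 1.0)
    return 0.75 * (c - c**3 / 3.0) + 0.5


_KERNELS = {"epanechnikov": (_epanechnikov, _epanechnikov_cdf)}


# ---------------------------------------------------------------------------
# configuration / results


@dataclass
class CurveConfig:
    """Tunable parameters of the growth-curve fit.

    smoother_bandwidth
        h_r, on the [0, 1]-rescaled time axis; None selects it by
        leave-one-out least-squares cross-validation over a small grid.
    inversion_bandwidth
        h_d, in height units, for the density used in monotonization;
        None uses 0.5 × a robust residual-scale estimate from the
        unconstrained fit.
    grid_size
        Number N of time-grid points i/N; None uses the number of
        observations (at least 50).
    outlier_k
        Residuals strictly outside outlier_k × IQR (about the median
        residual) are dropped before the refit.
    """

    smoother_bandwidth: float | None = None
    inversion_bandwidth: float | None = None
    kernel: str = "epanechnikov"
    grid_size: int | None = None
    outlier_k: float = 3.0
    inversion_points: int = 512
    cv_bandwidths: tuple[float, ...] = (0.03, 0.05, 0.08, 0.12, 0.18, 0.25)


@dataclass
class GrowthCurveFit:
    """Fitted nondecreasing growth curve and its diagnostics."""

    grid_times: np.ndarray  # original time scale
    fitted: np.ndarray  # nondecreasing curve on the grid
    unconstrained: np.ndarray  # kernel fit on the grid (after refit)
    t: np.ndarray  # observations used in the final fit
    y: np.ndarray
    residuals: np.ndarray  # final-fit residuals at retained points
    removed_indices: tuple[int, ...]  # indices into the original series
    r_squared: float
    smoother_bandwidth: float
    inversion_bandwidth: float

    def predict(self, t: np.ndarray) -> np.ndarray:
        """Fitted nondecreasing height at arbitrary times (interpolated)."""
        return np.interp(np.asarray(t, dtype=float), self.grid_times, self.fitted)

    def summary(self) -> str:
        lines = [
            "Nondecreasing growth-curve fit",
            f"  observations retained : {self.t.size}",
            f"  outliers removed      : {len(self.removed_indices)}",
            f"  smoother bandwidth h_r: {self.smoother_bandwidth:.4f} (rescaled time)",
            f"  inversion bandwidth h_d: {self.inversion_bandwidth:.3f} (height units)",
            f"  R-squared             : {self.r_squared:.4f}",
            f"  fitted range          : {self.fitted[0]:.1f} – {self.fitted[-1]:.1f} px",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot observations, removed outliers, and the fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.t, self.y, s=12, color="tab:gray", label="height (px)")
        ax.plot(self.grid_times, self.fitted, color="tab:green", lw=2, label="nondecreasing fit")
        ax.plot(self.grid_times, self.unconstrained, color="tab:orange", lw=1, ls="--", label="unconstrained")
        ax.set_xlabel("time")
        ax.set_ylabel("height (px)")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# smoothing


def kernel_smooth(
    t: np.ndarray,
    y: np.ndarray,
    bandwidth: float,
    kernel: str = "epanechnikov",
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Nadaraya–Watson estimate of y over [0, 1]-rescaled time.

    Returns ``(grid, mu_hat)`` where ``grid`` are the evaluation points
    on the rescaled axis (defaults to i/N, i = 1..N with N = len(t)).
    Weights renormalize automatically near the boundary; a grid point
    with no observation in its kernel support falls back to the value
    at the nearest observation.
    """
    t = np.asarray(t, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if t.size < 10:
        raise ValueError("need at least 10 observations")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    span = t.max() - t.min()
    if span == 0:
        raise ValueError("all observation times identical")
    x = (t - t.min()) / span
    if grid is None:
        n = t.size
        grid = np.arange(1, n + 1) / n
    kfun, _ = _KERNELS[kernel]
    w = kfun((grid[:, None] - x[None, :]) / bandwidth)
    wsum = w.sum(axis=1)
    mu = np.empty(grid.size)
    ok = wsum > 0
    mu[ok] = (w[ok] @ y) / wsum[ok]
    if not ok.all():
        for i in np.flatnonzero(~ok):
            mu[i] = y[np.argmin(np.abs(x - grid[i]))]
    return grid, mu


def select_bandwidth_cv(
    t: np.ndarray,
    y: np.ndarray,
    candidates=(0.03, 0.05, 0.08, 0.12, 0.18, 0.25),
    kernel: str = "epanechnikov",
) -> float:
    """Leave-one-out least-squares cross-validation for the NW bandwidth."""
    t = np.asarray(t, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    span = t.max() - t.min()
    x = (t - t.min()) / span
    kfun, _ = _KERNELS[kernel]
    best_h, best_score = None, np.inf
    for h in candidates:
        w = kfun((x[:, None] - x[None, :]) / h)
        np.fill_diagonal(w, 0.0)
        denom = w.sum(axis=1)
        if (denom == 0).any():
            continue  # too narrow: some point has no neighbor
        loo = (w @ y) / denom
        score = float(np.mean((y - loo) ** 2))
        if score < best_score:
            best_h, best_score = h, score
    if best_h is None:
        best_h = max(candidates)
    return best_h


# ---------------------------------------------------------------------------
# monotonization


def monotonize(
    mu_grid: np.ndarray,
    h_d: float,
    kernel: str = "epanechnikov",
    n_eval: int = 512,
) -> np.ndarray:
    """Nondecreasing version of a fitted curve, by density inversion.

    Builds inv(t) = (1/N) Σ_i F((t − mu_i)/h_d) on the observed height
    range [min mu, max mu] and inverts it numerically at the grid
    fractions i/N.  inv is nondecreasing in t, so the result is
    nondecreasing by construction; values clamp to the observed range.
    """
    mu = np.asarray(mu_grid, dtype=np.float64)
    if not np.all(np.isfinite(mu)):
        raise ValueError("fitted values must be finite")
    if h_d <= 0:
        raise ValueError("inversion bandwidth must be positive")
    _, kcdf = _KERNELS[kernel]
    n = mu.size
    lo, hi = mu.min(), mu.max()
    if hi == lo:
        return np.full(n, lo)
    heights = np.linspace(lo, hi, n_eval)
    inv = kcdf((heights[:, None] - mu[None, :]) / h_d).mean(axis=1)
    # target fractions i/N on the same scale as inv's range over [lo, hi]
    fracs = np.arange(1, n + 1) / n
    out = np.interp(fracs, inv, heights, left=lo, right=hi)
    return np.maximum.accumulate(out)  # guard against interp rounding


# ---------------------------------------------------------------------------
# full fit


def _robust_scale(residuals: np.ndarray) -> float:
    """MAD-based residual scale (falls back to SD, then to 1)."""
    r = np.asarray(residuals, dtype=np.float64)
    mad = np.median(np.abs(r - np.median(r)))
    s = 1.4826 * mad
    if s <= 0:
        s = float(np.std(r))
    return s if s > 0 else 1.0


def fit_growth_curve(t, y, config: CurveConfig | None = None) -> GrowthCurveFit:
    """Fit a nondecreasing growth curve with a 3×IQR outlier refit.

    First pass: kernel smoothing + monotonization.  Observations whose
    first-pass residuals lie strictly outside ``outlier_k`` × IQR of
    the median residual are removed, and the curve is fitted a second
    time on the remainder.  R² is 1 − SSE/SST over retained points.
    """
    cfg = config or CurveConfig()
    t = np.asarray(t, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if t.size != y.size:
        raise ValueError("t and y must have equal length")
    if t.size < 10:
        raise ValueError("need at least 10 observations")
    order = np.argsort(t, kind="stable")
    t, y = t[order], y[order]
    orig_idx = order

    h_r = cfg.smoother_bandwidth or select_bandwidth_cv(t, y, cfg.cv_bandwidths, cfg.kernel)

    def one_fit(tt, yy):
        n_grid = cfg.grid_size or max(tt.size, 50)
        grid = np.arange(1, n_grid + 1) / n_grid
        grid, mu = kernel_smooth(tt, yy, h_r, cfg.kernel, grid=grid)
        x = (tt - tt.min()) / (tt.max() - tt.min())
        resid_unc = yy - np.interp(x, grid, mu)
        h_d = cfg.inversion_bandwidth or max(0.5 * _robust_scale(resid_unc), 1e-8)
        mu_mon = monotonize(mu, h_d, cfg.kernel, cfg.inversion_points)
        fitted_obs = np.interp(x, grid, mu_mon)
        return grid, mu, mu_mon, fitted_obs, h_d

    _, _, _, fitted_obs, _ = one_fit(t, y)
    resid = y - fitted_obs
    med = np.median(resid)
    q75, q25 = np.percentile(resid, [75, 25])
    iqr = q75 - q25
    tol = cfg.outlier_k * iqr + 1e-9 * max(1.0, float(np.abs(y).max()))
    keep = np.abs(resid - med) <= tol
    removed = tuple(int(orig_idx[i]) for i in np.flatnonzero(~keep))
    if keep.sum() < 10:
        raise ValueError(
            f"only {int(keep.sum())} observations remain after outlier removal "
            f"(removed {len(removed)}); cannot refit"
        )

    t2, y2 = t[keep], y[keep]
    grid, mu, mu_mon, fitted_obs2, h_d = one_fit(t2, y2)
    resid2 = y2 - fitted_obs2
    sst = float(np.sum((y2 - y2.mean()) ** 2))
    sse = float(np.sum(resid2**2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    grid_times = t2.min() + grid * (t2.max() - t2.min())
    return GrowthCurveFit(
        grid_times=grid_times,
        fitted=mu_mon,
        unconstrained=mu,
        t=t2,
        y=y2,
        residuals=resid2,
        removed_indices=removed,
        r_squared=r2,
        smoother_bandwidth=h_r,
        inversion_bandwidth=h_d,
    )
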