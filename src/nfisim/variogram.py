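"""Spherical variogram model, Gaussian random fields, and universal kriging.

The stratum map of the inventory design is produced by universal kriging of a
stratum indicator observed at grid nodes, with logit-transformed elevation as
the trend covariate and a spherical variogram (zero nugget, sill 0.73, range
5600 m in the operational fit).  The same model family drives the synthetic
elevation fields used by the landscape generator, so variogram estimation,
field simulation and kriging live together in this module.

All distances are in metres; semivariance/covariance units follow the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = [
    "SphericalVariogram",
    "empirical_variogram",
    "fit_spherical_variogram",
    "simulate_gaussian_field",
    "simulate_grid_field",
    "universal_kriging",
]

#: Above this many observations the kriging system is solved in a moving
#: neighbourhood of the nearest points instead of globally.
GLOBAL_NEIGHBOURHOOD_MAX = 2000
NEIGHBOURHOOD_SIZE = 500


@dataclass(frozen=True)
class SphericalVariogram:
    """Spherical semivariogram gamma(h) = c0 + c*(1.5 h/a - 0.5 (h/a)^3).

    Parameters
    ----------
    nugget:
        Micro-scale variance c0 (>= 0), reached in the limit h -> 0+.
    sill:
        Total sill c0 + c; the semivariance for h >= `range_m`.
    range_m:
        Range a beyond which observations are uncorrelated.
    """

    nugget: float
    sill: float
    range_m: float

    def __post_init__(self) -> None:
        if self.nugget < 0:
            raise ValueError("nugget must be >= 0")
        if self.sill < self.nugget:
            raise ValueError("sill must be >= nugget (partial sill >= 0)")
        if self.range_m <= 0:
            raise ValueError("range must be > 0")

    @property
    def partial_sill(self) -> float:
        return self.sill - self.nugget

    def gamma(self, h):
        """Semivariance at lag distance(s) ``h``."""
        h = np.asarray(h, dtype=float)
        hr = np.minimum(h / self.range_m, 1.0)
        g = self.nugget + self.partial_sill * (1.5 * hr - 0.5 * hr**3)
        # gamma(0) = 0 by definition; the nugget is the limit from the right
        return np.where(h == 0.0, 0.0, g)

    def covariance(self, h):
        """Stationary covariance C(h) = sill - gamma(h)."""
        return self.sill - self.gamma(h)


def empirical_variogram(points, values, n_lags: int = 15, max_lag: float | None = None):
    """Method-of-moments semivariogram estimate from scattered data.

    Returns ``(lag_centers, semivariance, n_pairs)``; bins with no pairs are
    dropped.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    d = pdist(points)
    if max_lag is None:
        max_lag = d.max() / 2.0
    dv = pdist(values[:, None]) ** 2  # squared value differences per pair
    edges = np.linspace(0.0, max_lag, n_lags + 1)
    idx = np.digitize(d, edges) - 1
    lags, gammas, counts = [], [], []
    for k in range(n_lags):
        m = idx == k
        n = int(m.sum())
        if n == 0:
            continue
        lags.append(d[m].mean())
        gammas.append(0.5 * dv[m].mean())
        counts.append(n)
    return np.array(lags), np.array(gammas), np.array(counts, dtype=int)


def fit_spherical_variogram(lags, semivariance, n_pairs=None) -> SphericalVariogram:
    """Weighted least-squares fit of a spherical model to variogram points.

    Weights are ``sqrt(n_pairs)`` when pair counts are given, else uniform.
    Parameters are constrained non-negative.  All-zero semivariances yield a
    degenerate (sill 0) model with a warning.
    """
    lags = np.asarray(lags, dtype=float)
    gam = np.asarray(semivariance, dtype=float)
    if lags.size < 3:
        raise ValueError("need at least 3 lag bins to fit a spherical model")
    if not np.all(np.isfinite(gam)):
        raise ValueError("semivariances must be finite")
    if np.all(gam == 0):
        warnings.warn("all semivariances are zero; returning degenerate model")
        return SphericalVariogram(0.0, 0.0, float(lags.max()))

    w = np.sqrt(n_pairs) if n_pairs is not None else np.ones_like(lags)

    def model(theta, h):
        c0, c, a = theta
        hr = np.minimum(h / a, 1.0)
        return c0 + c * (1.5 * hr - 0.5 * hr**3)

    def resid(theta):
        return w * (model(theta, lags) - gam)

    gmax = gam.max()
    x0 = np.array([max(gam[0], 1e-10), max(gmax - gam[0], 1e-10), lags.max() / 2.0])
    sol = least_squares(
        resid,
        x0,
        bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    c0, c, a = sol.x
    # snap a numerically-zero nugget so downstream exact-interpolation holds
    if c0 < 1e-10 * max(gmax, 1.0):
        c0 = 0.0
    return SphericalVariogram(float(c0), float(c0 + c), float(a))


def simulate_gaussian_field(
    points, model: SphericalVariogram, rng: np.random.Generator, mean: float = 0.0
) -> np.ndarray:
    """Exact (Cholesky) simulation of a zero-mean Gaussian field at `points`.

    The covariance between two points at distance h is ``model.covariance(h)``,
    i.e. sill at h = 0 (nugget included as spatially uncorrelated noise).
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if model.sill == 0:
        return np.full(n, mean)
    h = squareform(pdist(points))
    cov = model.covariance(h)
    np.fill_diagonal(cov, model.sill)
    # tiny jitter keeps the factorization stable for near-duplicate points
    cov[np.diag_indices(n)] += 1e-10 * model.sill
    chol = np.linalg.cholesky(cov)
    return mean + chol @ rng.standard_normal(n)


def simulate_grid_field(
    extent,
    cell_size: float,
    model: SphericalVariogram,
    rng: np.random.Generator,
    max_sim_nodes: int = 4000,
):
    """Simulate a Gaussian field on a raster grid over ``extent``.

    For grids small enough, the field is simulated exactly at every cell
    centre.  Finer grids are handled by exact simulation on a coarser
    auxiliary lattice followed by bilinear interpolation — adequate for
    fields whose range is large relative to the cell size, which is the
    regime the landscape generator operates in (kilometre-scale ranges,
    16–100 m cells).

    Returns ``(field, xs, ys)`` where ``field`` has shape ``(ny, nx)`` with
    row 0 at the *south* edge, and ``xs``/``ys`` are cell-centre coordinates.
    """
    xmin, ymin, xmax, ymax = extent
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("extent must have positive area")
    if max(xmax - xmin, ymax - ymin) < model.range_m:
        warnings.warn(
            "extent is smaller than the variogram range; "
            "the range is not identifiable from one realization"
        )
    nx = max(int(np.ceil((xmax - xmin) / cell_size)), 1)
    ny = max(int(np.ceil((ymax - ymin) / cell_size)), 1)
    xs = xmin + cell_size * (np.arange(nx) + 0.5)
    ys = ymin + cell_size * (np.arange(ny) + 0.5)

    if nx * ny <= max_sim_nodes:
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        field = simulate_gaussian_field(pts, model, rng).reshape(ny, nx)
        return field, xs, ys

    # coarse exact simulation + bilinear refinement
    ratio = np.sqrt(nx * ny / max_sim_nodes)
    cnx = max(int(np.ceil(nx / ratio)) + 1, 2)
    cny = max(int(np.ceil(ny / ratio)) + 1, 2)
    cxs = np.linspace(xs[0], xs[-1], cnx)
    cys = np.linspace(ys[0], ys[-1], cny)
    gx, gy = np.meshgrid(cxs, cys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    coarse = simulate_gaussian_field(pts, model, rng).reshape(cny, cnx)
    from scipy.interpolate import RegularGridInterpolator

    interp = RegularGridInterpolator((cys, cxs), coarse, method="linear")
    gx, gy = np.meshgrid(xs, ys)
    field = interp(np.column_stack([gy.ravel(), gx.ravel()])).reshape(ny, nx)
    return field, xs, ys


def _dedup(points: np.ndarray, values: np.ndarray, trend: np.ndarray):
    """Average values observed at coincident locations (kriging system
    would otherwise be singular)."""
    rounded = np.round(points, 6)
    _, inv, counts = np.unique(rounded, axis=0, return_inverse=True, return_counts=True)
    if np.all(counts == 1):
        return points, values, trend
    n_u = counts.size
    pts = np.zeros((n_u, 2))
    val = np.zeros(n_u)
    trd = np.zeros((n_u, trend.shape[1]))
    np.add.at(pts, inv, points)
    np.add.at(val, inv, values)
    np.add.at(trd, inv, trend)
    return pts / counts[:, None], val / counts, trd / counts[:, None]


def universal_kriging(
    obs_points,
    obs_values,
    obs_covariate,
    pred_points,
    pred_covariate,
    model: SphericalVariogram,
) -> np.ndarray:
    """Universal-kriging prediction with a linear trend in one covariate.

    The trend basis is ``[1, covariate]``.  With a zero nugget the predictor
    interpolates exactly at observed locations.  Duplicate observation
    locations are averaged before assembling the system.  Beyond
    ``GLOBAL_NEIGHBOURHOOD_MAX`` observations, each prediction uses its
    ``NEIGHBOURHOOD_SIZE`` nearest observations.
    """
    obs_points = np.asarray(obs_points, dtype=float)
    obs_values = np.asarray(obs_values, dtype=float)
    pred_points = np.atleast_2d(np.asarray(pred_points, dtype=float))
    F_obs = np.column_stack([np.ones(len(obs_points)), np.asarray(obs_covariate, float)])
    F_pred = np.column_stack([np.ones(len(pred_points)), np.asarray(pred_covariate, float)])
    obs_points, obs_values, F_obs = _dedup(obs_points, obs_values, F_obs)
    n = obs_points.shape[0]
    if n < 2:
        raise ValueError("universal kriging needs at least 2 observations")

    if n > GLOBAL_NEIGHBOURHOOD_MAX:
        tree = cKDTree(obs_points)
        out = np.empty(len(pred_points))
        for i, (p, f0) in enumerate(zip(pred_points, F_pred)):
            _, idx = tree.query(p, k=min(NEIGHBOURHOOD_SIZE, n))
            out[i] = _uk_solve(
                obs_points[idx], obs_values[idx], F_obs[idx], p[None, :], f0[None, :], model
            )[0]
        return out
    return _uk_solve(obs_points, obs_values, F_obs, pred_points, F_pred, model)


def _uk_solve(pts, vals, F, pred_pts, F_pred, model) -> np.ndarray:
    # drop collinear trend columns (e.g. a constant covariate duplicates the
    # intercept) so the bordered system stays non-singular
    keep = [0]
    for j in range(1, F.shape[1]):
        cand = F[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
    F = F[:, keep]
    F_pred = F_pred[:, keep]
    n, p = F.shape
    C = model.covariance(squareform(pdist(pts)))
    np.fill_diagonal(C, model.sill)
    A = np.zeros((n + p, n + p))
    A[:n, :n] = C
    A[:n, n:] = F
    A[n:, :n] = F.T
    c0 = model.covariance(cdist(pts, pred_pts))
    rhs = np.vstack([c0, F_pred.T])
    try:
        lam = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        A[:n, :n] += np.eye(n) * 1e-8 * max(model.sill, 1.0)
        lam = np.linalg.solve(A, rhs)
    return vals @ lam[:n]
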